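import numpy as np
import pytest

from patchmorph.mesh import surface_area
from patchmorph.morphometry import surface_jacobian
from patchmorph.parcellate import patch_mean_features
from patchmorph.simulate import (
    ICV_REFERENCE,
    SimulationSpec,
    calibrate_atrophy_displacement,
    ellipsoid_area_thomsen,
    make_template_mesh,
    simulate_cohort,
    simulate_covariates,
    simulate_feature_matrix,
    simulate_subject_mesh,
)
from patchmorph.stats import fit_glm, build_design, Contrast


class TestTemplates:
    def test_icosphere_area_close_to_closed_form(self):
        spec = SimulationSpec(structure="icosphere", radius=10.37, subdivisions=3)
        m = make_template_mesh(spec)
        assert surface_area(m) == pytest.approx(4 * np.pi * 10.37**2, rel=0.02)

    def test_ellipsoid_area_close_to_thomsen(self):
        spec = SimulationSpec(structure="ellipsoid", semi_axes=(17.0, 8.0, 7.0), subdivisions=4)
        m = make_template_mesh(spec)
        assert surface_area(m) == pytest.approx(ellipsoid_area_thomsen(17, 8, 7), rel=0.02)

    def test_bent_tube_satisfies_mesh_invariants(self):
        m = make_template_mesh(SimulationSpec(structure="bent_tube"))
        m.validate(require_connected=True)

    def test_degenerate_parameters_rejected(self):
        with pytest.raises(ValueError):
            make_template_mesh(SimulationSpec(structure="icosphere", radius=-1.0))
        with pytest.raises(ValueError):
            make_template_mesh(SimulationSpec(structure="ellipsoid", semi_axes=(0, 1, 1)))


class TestCovariates:
    def test_default_cohort_structure(self):
        cov = simulate_covariates(SimulationSpec(seed=0), np.random.default_rng(0))
        df = cov.frame
        assert len(df) == 35
        assert (df["group"] == "HC").sum() == 21
        assert (df["group"] == "R").sum() == 9
        assert (df["group"] == "NR").sum() == 5
        # fixed within-group sex composition: 15/21, 7/9, 5/5 female
        assert df.loc[df.group == "HC", "sex"].sum() == 15
        assert df.loc[df.group == "R", "sex"].sum() == 7
        assert df.loc[df.group == "NR", "sex"].sum() == 5
        assert (df.group_long == "NR").sum() == 7

    def test_determinism(self):
        a = simulate_covariates(SimulationSpec(seed=3), np.random.default_rng(3)).frame
        b = simulate_covariates(SimulationSpec(seed=3), np.random.default_rng(3)).frame
        assert a.equals(b)


class TestFeatureMode:
    def test_intercept_only_noiseless_is_all_ones(self):
        spec = SimulationSpec(seed=0, atrophy=0.0, noise_sd=0.0,
                              beta_age=0.0, beta_sex=0.0, beta_icv=0.0)
        fm, _, _ = simulate_feature_matrix(spec)
        assert fm.values == pytest.approx(np.ones_like(fm.values))

    def test_noiseless_response_effect_is_exact(self):
        spec = SimulationSpec(seed=0, atrophy=0.15, noise_sd=0.0,
                              beta_age=0.0, beta_sex=0.0, beta_icv=0.0)
        fm, cov, truth = simulate_feature_matrix(spec)
        nr = cov.frame["group"].to_numpy() == "NR"
        t = truth["target_patch"]
        assert fm.values[t, nr] == pytest.approx(0.85)
        assert fm.values[t, ~nr] == pytest.approx(1.0)
        other = np.delete(fm.values, t, axis=0)
        assert other == pytest.approx(np.ones_like(other))

    def test_glm_recovers_generative_beta(self):
        """With noise, OLS on the alternative design recovers the injected
        response coefficient within 3 standard errors."""
        spec = SimulationSpec(seed=12, atrophy=0.15, noise_sd=0.05)
        fm, cov, truth = simulate_feature_matrix(spec)
        X, _, mask = build_design(cov, Contrast("NR_vs_HCandR"))
        fit = fit_glm(fm.values[:, mask], X)
        t = truth["target_patch"]
        n, p = X.shape
        sigma2 = fit.sse[t] / (n - p)
        se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[-1, -1])
        assert abs(fit.beta[t, -1] - (-0.15)) < 3 * se

    def test_same_seed_bit_identical(self):
        a, ca, _ = simulate_feature_matrix(SimulationSpec(seed=5))
        b, cb, _ = simulate_feature_matrix(SimulationSpec(seed=5))
        assert np.array_equal(a.values, b.values)
        assert ca.frame.equals(cb.frame)


@pytest.fixture(scope="module")
def cohort():
    spec = SimulationSpec(seed=21, subdivisions=2, mesh_noise_amp=0.05, atrophy=0.15)
    return simulate_cohort(spec, mode="mesh")


class TestMeshMode:
    def test_cohort_is_reproducible(self, cohort):
        spec = SimulationSpec(seed=21, subdivisions=2, mesh_noise_amp=0.05, atrophy=0.15)
        again = simulate_cohort(spec, mode="mesh")
        sid = cohort.covariates.subject_ids[0]
        assert np.array_equal(cohort.meshes[sid].vertices, again.meshes[sid].vertices)

    def test_identity_subject_equals_template(self, cohort):
        """Zero noise, zero effect, reference ICV -> the subject IS the template."""
        spec = SimulationSpec(seed=0, subdivisions=2, mesh_noise_amp=0.0, atrophy=0.0)
        template = cohort.template
        row = cohort.covariates.frame.iloc[0].copy()
        row["icv"] = ICV_REFERENCE
        row["group"] = "HC"
        subj = simulate_subject_mesh(template, row, spec, np.random.default_rng(0))
        assert np.allclose(subj.vertices, template.vertices)

    def test_calibrated_atrophy_hits_target_patch_mean(self, cohort):
        """A noiseless non-responder at reference ICV shows a target-patch
        mean expansion factor of 0.85 within 2%, other patches within 2% of 1."""
        spec = SimulationSpec(seed=0, subdivisions=2, mesh_noise_amp=0.0, atrophy=0.15)
        template, parc = cohort.template, cohort.parcellation
        disp = calibrate_atrophy_displacement(template, parc, 0, 0.15)
        row = cohort.covariates.frame.iloc[-1].copy()  # an NR subject
        row["icv"] = ICV_REFERENCE
        subj = simulate_subject_mesh(template, row, spec, np.random.default_rng(0),
                                     atrophy_displacement=disp)
        means = patch_mean_features(parc, surface_jacobian(template, subj).values)
        assert means[0] == pytest.approx(0.85, abs=0.02)
        assert np.all(np.abs(means[1:] - 1.0) < 0.02)

    def test_truth_manifest_records_design(self, cohort):
        t = cohort.truth
        assert t["atrophy"] == 0.15
        assert t["target_patch"] == 0
        assert t["seed"] == 21
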