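import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from patchmorph.mesh import TriangleMesh, surface_area, transform_rigid, vertex_areas, vertex_normals
from patchmorph.morphometry import (
    ExpansionField,
    FeatureMatrix,
    assemble_feature_matrix,
    build_template,
    rigid_align,
    surface_jacobian,
)
from patchmorph.parcellate import patch_mean_features, spectral_parcellate


def rmsd(a, b):
    return float(np.sqrt(np.mean(np.sum((a.vertices - b.vertices) ** 2, axis=1))))


class TestRigidAlign:
    def test_self_alignment_is_identity(self, icosphere):
        m = icosphere(3.0, 2)
        assert rmsd(rigid_align(m, m), m) < 1e-9

    def test_recovers_rigid_motion(self, icosphere):
        m = icosphere(3.0, 2)
        R = Rotation.from_euler("zxy", [30, 10, -70], degrees=True).as_matrix()
        moved = transform_rigid(m, R, np.array([5.0, -1.0, 2.0]))
        assert rmsd(rigid_align(moved, m), m) < 1e-6

    def test_scale_is_preserved_not_removed(self, icosphere):
        """Rigid (not similarity) Procrustes: a 1.2x copy keeps its size."""
        m = icosphere(3.0, 2)
        scaled = TriangleMesh(m.vertices * 1.2, m.faces)
        aligned = rigid_align(scaled, m)
        assert surface_area(aligned) == pytest.approx(surface_area(m) * 1.44, rel=1e-9)
        assert rmsd(aligned, m) > 0.1

    def test_matches_closed_form_procrustes_oracle(self, icosphere, rng):
        """Compare against an independent SVD Procrustes solution."""
        m = icosphere(3.0, 2)
        jittered = TriangleMesh(m.vertices + rng.normal(scale=0.05, size=m.vertices.shape), m.faces)
        aligned = rigid_align(jittered, m)
        P, Q = jittered.vertices, m.vertices
        Pc, Qc = P - P.mean(0), Q - Q.mean(0)
        U, _, Vt = np.linalg.svd(Pc.T @ Qc)
        D = np.diag([1, 1, np.sign(np.linalg.det(U @ Vt))])
        oracle = Pc @ (U @ D @ Vt) + Q.mean(0)
        assert np.allclose(aligned.vertices, oracle, atol=1e-9)

    def test_topology_mismatch_rejected(self, icosphere):
        with pytest.raises(ValueError, match="topology"):
            rigid_align(icosphere(1.0, 1), icosphere(1.0, 2))


class TestBuildTemplate:
    def test_identical_copies_give_the_copy(self, icosphere):
        m = icosphere(4.0, 2)
        tpl = build_template([m.copy(), m.copy(), m.copy()])
        assert rmsd(tpl, m) < 1e-9

    def test_concentric_spheres_average_radius(self, icosphere):
        small = icosphere(9.0, 2)
        big = TriangleMesh(small.vertices * (11.0 / 9.0), small.faces)
        tpl = build_template([small, big])
        radii = np.linalg.norm(tpl.vertices - tpl.vertices.mean(0), axis=1)
        assert radii.mean() == pytest.approx(10.0, rel=0.01)

    def test_input_order_irrelevant(self, icosphere, rng):
        m = icosphere(4.0, 2)
        subjects = [
            TriangleMesh(m.vertices + rng.normal(scale=0.1, size=m.vertices.shape), m.faces)
            for _ in range(4)
        ]
        t1 = build_template(subjects)
        t2 = build_template(subjects[::-1])
        assert rmsd(t1, t2) < 1e-6

    def test_mixed_topology_rejected(self, icosphere):
        with pytest.raises(ValueError, match="topolog"):
            build_template([icosphere(1.0, 1), icosphere(1.0, 2)])


class TestSurfaceJacobian:
    def test_identity_deformation(self, icosphere):
        m = icosphere(3.0, 2)
        assert surface_jacobian(m, m).values == pytest.approx(np.ones(m.n_vertices))

    def test_uniform_scale_squares(self, icosphere):
        m = icosphere(3.0, 2)
        scaled = TriangleMesh(m.vertices * 1.1, m.faces)
        assert surface_jacobian(m, scaled).values == pytest.approx(
            np.full(m.n_vertices, 1.21), rel=1e-9
        )

    def test_weighted_mean_equals_area_ratio(self, icosphere, rng):
        """Template-vertex-area weighted mean of the field is exactly the
        total-area ratio (algebraic identity)."""
        m = icosphere(3.0, 2)
        subj = TriangleMesh(m.vertices + rng.normal(scale=0.05, size=m.vertices.shape), m.faces)
        field = surface_jacobian(m, subj)
        wa = vertex_areas(m)
        assert np.average(field.values, weights=wa) == pytest.approx(
            surface_area(subj) / surface_area(m), rel=1e-12
        )

    def test_local_expansion_raises_patch_mean(self, icosphere):
        """Pushing one patch outward does not decrease its patch mean."""
        m = icosphere(5.0, 3)
        parc = spectral_parcellate(m, 4, seed=0)
        target = parc.labels == 0
        v = m.vertices.copy()
        v[target] += 0.3 * vertex_normals(m)[target]
        subj = TriangleMesh(v, m.faces)
        means = patch_mean_features(parc, surface_jacobian(m, subj).values)
        assert means[0] > 1.0

    def test_one_ring_method_agrees_for_uniform_scale(self, icosphere):
        m = icosphere(3.0, 2)
        scaled = TriangleMesh(m.vertices * 1.05, m.faces)
        f = surface_jacobian(m, scaled, method="one_ring")
        assert f.values == pytest.approx(np.full(m.n_vertices, 1.05**2), rel=1e-9)


class TestFeatureMatrix:
    def test_template_subject_column_is_ones(self, icosphere):
        m = icosphere(3.0, 2)
        parc = spectral_parcellate(m, 3, seed=0)
        fm = assemble_feature_matrix(parc, {"s1": surface_jacobian(m, m)})
        assert fm.values[:, 0] == pytest.approx(np.ones(3))

    def test_columns_follow_subject_order(self, icosphere):
        m = icosphere(3.0, 2)
        parc = spectral_parcellate(m, 3, seed=0)
        f1 = surface_jacobian(m, TriangleMesh(m.vertices * 1.1, m.faces))
        f2 = surface_jacobian(m, TriangleMesh(m.vertices * 1.2, m.faces))
        a = assemble_feature_matrix(parc, {"s1": f1, "s2": f2}, ["s1", "s2"])
        b = assemble_feature_matrix(parc, {"s1": f1, "s2": f2}, ["s2", "s1"])
        assert np.allclose(a.values, b.values[:, ::-1])

    def test_matches_direct_loop_oracle(self, icosphere, rng):
        m = icosphere(3.0, 2)
        parc = spectral_parcellate(m, 4, seed=0)
        fields = {}
        for s in range(3):
            vals = np.exp(rng.normal(scale=0.1, size=m.n_vertices))
            fields[f"s{s}"] = ExpansionField(vals)
        fm = assemble_feature_matrix(parc, fields)
        for j, sid in enumerate(fm.subject_ids):
            for lab in range(4):
                expect = fields[sid].values[parc.labels == lab].mean()
                assert fm.values[lab, j] == pytest.approx(expect, abs=1e-12)

    def test_duplicate_subject_ids_rejected(self, icosphere):
        m = icosphere(3.0, 2)
        parc = spectral_parcellate(m, 3, seed=0)
        f = surface_jacobian(m, m)
        with pytest.raises(ValueError, match="duplicate"):
            assemble_feature_matrix(parc, {"s1": f}, ["s1", "s1"])

    def test_roundtrip_tsv(self, icosphere, tmp_path, rng):
        vals = np.exp(rng.normal(scale=0.05, size=(4, 3)))
        fm = FeatureMatrix(vals, ["a", "b", "c"])
        path = str(tmp_path / "features.tsv")
        fm.save(path)
        back = FeatureMatrix.load(path)
        assert back.subject_ids == ["a", "b", "c"]
        assert np.allclose(back.values, vals, rtol=1e-10)


def test_log_scale_features(icosphere):
    """Log-Jacobian features: uniform scale s gives 2*log(s) at every patch."""
    m = icosphere(3.0, 2)
    parc = spectral_parcellate(m, 3, seed=0)
    f = surface_jacobian(m, TriangleMesh(m.vertices * 1.1, m.faces))
    fm = assemble_feature_matrix(parc, {"s1": f}, log=True)
    assert fm.scale == "log"
    assert fm.values[:, 0] == pytest.approx(np.full(3, 2 * np.log(1.1)), rel=1e-9)
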