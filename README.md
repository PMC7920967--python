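# patchmorph

Surface-patch morphometry for small subcortical structures (hippocampus,
amygdala), built for case-control shape studies where the question is not
"is the structure smaller?" but "*where* on its surface does it differ?".

Given per-subject triangulated surfaces that share vertex topology (or a
synthetic cohort generated by the package itself), the pipeline:

1. builds a population **template surface** by iterative rigid (Kabsch)
   alignment and vertex-wise averaging — size is deliberately *not*
   removed, so head-size effects stay in the data and are handled by the
   intracranial-volume (ICV) covariate;
2. **parcellates** the template into patches of ~150 mm² average area by
   spectral clustering: vertices are embedded with the low-frequency
   eigenvectors of the cotangent **Laplace–Beltrami operator** and
   clustered with k-means (a hippocampus-scale surface yields 9 patches,
   an amygdala-scale surface 4);
3. computes per-vertex **surface-Jacobian expansion factors**
   `J(v) = A_subject(v) / A_template(v)` (barycentric vertex-area ratio;
   >1 local expansion, <1 local atrophy) and patch-averages them into a
   patches × subjects feature matrix `Y`;
4. tests each patch with a **nested GLM**: the null model regresses the
   patch feature on intercept, age, sex and ICV; the alternative adds a
   group (treatment-response) indicator. The statistic is the residual
   sum-of-squares ratio
   `s_p = SSE_null(p) / SSE_alt(p) = 1 + F_p / (n − 5)`,
   with `F_p` the partial F statistic of the response column;
5. controls the **familywise error rate** across patches with a
   max-statistic permutation test: feature vectors are rearranged among
   subjects, the maximum `s_p` over patches forms the reference
   distribution, and a patch is significant when its observed statistic
   exceeds the distribution's 95th percentile (equivalently, adjusted
   p < 0.05 with the (1+b)/(1+B) convention).

The synthetic-cohort generator reproduces the design of a small lithium-
response imaging study — 21 healthy comparison subjects, 9 responders,
5 non-responders, with group-specific age/sex/ICV distributions — and can
inject a localized, area-calibrated atrophy effect (default 15% of one
patch) either at the feature level or directly into subject meshes, so
every stage of the pipeline is testable with known ground truth.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data. `01` simulates 35 subjects × 2 structures at mesh level (15% atrophy
injected into patch 0 of the "hippocampus", nothing into the "amygdala"),
`02` extracts expansion-factor features, `03` runs both contrasts with
10,000 permutations:

```text
$ python analysis/01_simulate_cohort.py
left_hippocampus: 35 subject surfaces, 9 patches, atrophy 15% in patch 0
left_amygdala: 35 subject surfaces, 4 patches, no injected effect

$ python analysis/02_extract_features.py
left_amygdala: 4 patches x 35 subjects, expansion factors in [0.894, 1.227]
left_hippocampus: 9 patches x 35 subjects, expansion factors in [0.814, 1.228]

$ python analysis/03_test_contrasts.py
       structure     contrast timepoint  patch       s_p  min_p_adj  significant  percent_atrophy
   left_amygdala      NR_vs_R     acute      0  1.237631   0.431157        False              NaN
   left_amygdala NR_vs_HCandR     acute      0  1.037525   0.513949        False              NaN
left_hippocampus      NR_vs_R     acute      0 10.462758   0.000100         True            19.13
left_hippocampus NR_vs_HCandR     acute      0  6.356959   0.000100         True            19.13
```

The test finds exactly the injected patch (adjusted p = 1/(10000+1), the
smallest attainable value) and nothing in the null structure. The raw
percent-atrophy readout (19.1%) overshoots the injected 15% because it
compares unadjusted group means and the non-responder group also has
smaller ICV; the GLM coefficient, which adjusts for ICV, recovers the
effect without that bias (see `analysis/05_parameter_recovery.py`).
`04_fwer_calibration.py` measures the empirical familywise error rate on
500 null cohorts: 5.6% for the literal feature-shuffle scheme and 5.0%
for Freedman–Lane residual permutation, both at the nominal 5% within
Monte-Carlo error.

The same pipeline is scriptable via the `patchmorph` CLI
(`simulate`, `mesh`, `template`, `patchify`, `features`, `test`,
`report`, `pipeline` subcommands; YAML config with CLI overrides).

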