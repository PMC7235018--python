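# Methods

This note documents the statistical model, the estimation procedure, the
synthetic study conditions, and the numerical choices made where the design
was genuinely open.

## Model and assumptions

The fusion model is a two-modality linear decomposition with shared subject
loadings: `X_k = A S_k + E_k` for fALFF and GMV feature matrices. Its
assumptions, in decreasing order of importance:

- **Shared mixing.** Both modalities express the same subject-wise
  component loadings. This is the joint-ICA premise; modality-specific
  mixing is out of scope.
- **Non-Gaussian sources.** The spatial maps are supergaussian (sparse,
  spatially compact activity), which is what makes the Infomax ICA stage
  identifiable.
- **Linear confounds.** Site enters as an additive per-site offset and age
  as a linear voxel-wise slope, so per-voxel OLS regression can remove
  them. Nonlinear and interaction effects are not modeled.
- **One clinical reference per cohort.** The reference score is assumed to
  correlate linearly with one component's loadings; the MCCA penalty
  rewards squared correlation and is therefore sign-blind.

## Estimation

1. **PCA** per modality to M components (column-demeaned SVD; sign fixed so
   each basis row's largest-magnitude entry is positive).
2. **Deflationary multiset CCA with reference.** Component j maximizes
   `J = Σ_{k1<k2} corr² + 2λ Σ_k corr(d_k, ref)²` subject to unit variance
   and decorrelation from that modality's earlier variates (enforced by
   projecting the score matrix onto the orthogonal complement). The
   coordinate ascent updates one modality at a time by solving the exact
   rank-restricted eigenproblem, so J is provably non-decreasing; the
   per-component objective trace is retained and asserted monotone in the
   tests. Initialization is deterministic (first principal direction of
   the deflated scores), so the MCCA stage consumes no randomness.
   After extraction, each component's variates are sign-aligned to the
   first modality (`corr(d_k, d_1) ≥ 0`): the squared-correlation objective
   is blind to per-modality sign flips, but the joint ICA stage needs
   consistently oriented variates — without alignment the per-modality
   mixing matrices differ by sign patterns and the shared-unmixing premise
   breaks.
3. **Associated maps.** `C_k = pinv(D_k) X_k`, row-demeaned before ICA (the
   removed row means are reported nowhere and do not affect loadings).
4. **Joint Infomax ICA.** Logistic nonlinearity, full-batch natural
   gradient on sphered data, identity-plus-seeded-perturbation
   initialization. The learning rate (default 0.03) anneals by 0.9 whenever
   successive updates turn by more than 60°; iteration stops when
   `max|ΔW| < 1e-6` or at 20 000 iterations (updates decay geometrically,
   so the cap mainly serves over-specified M where residual dimensions are
   near-Gaussian and drift slowly; a non-convergence warning is emitted
   honestly in that case). Non-finite blow-ups restart at halved rates, at
   most three times.
5. **Assembly.** `A_k = D_k W⁻¹`; each joint source row is flipped so its
   spatial skewness is positive, with loading columns following. This keeps
   orientation independent of the reference, which may legitimately
   correlate negatively with a component. Ties in later component selection
   break toward the lower index.

## Key parameters

| parameter | default | rationale |
|---|---|---|
| `n_components` (M) | 8 | desk-scale synthetic analyses; cohort-scale runs use 50 via config when subjects permit (M ≤ subjects − 1 enforced) |
| `lambda_ref` (λ) | 0.5 | balances inter-modality covariation against reference steering; 0 disables guidance |
| fALFF band | 0.01–0.08 Hz over (0, min(Nyquist, 0.25)] Hz | standard low-frequency band; the 0.25 Hz cap presumes TR = 2 s and is capped at Nyquist otherwise (logged) |
| `z_threshold` | 2.0 | strict `|Z| > 2`; boundary voxels excluded; positive and negative exceedances treated equally |
| `alpha` | 0.05 | BH-FDR level for both component selection and behavior correlation |

FDR families: component selection corrects across the component × modality
grid; behavior correlation corrects across the measures of one report. The
families are recorded in the result objects.

## fALFF numerics

Amplitude means `|DFT|` magnitude, not squared power. The series is
demeaned only (no detrend, no taper — linear trends belong to the nuisance
regression stage); the denominator excludes the DC bin; both numerator band
edges are inclusive at bin centers. Zero-total-amplitude voxels (e.g.
constant series) get fALFF 0 and are flagged rather than NaN.

## What the synthetic generator emulates — and what it does not

The generator reproduces the statistical structure the analysis assumes:
shared mixing across modalities, spatially compact supergaussian sources
(contiguous runs with amplitudes `±(1.5 + |Laplace(0.5)|)`, keeping active
voxels clear of the |Z|>2 noise floor while preserving heavy tails), a
reference score whose *empirical* correlation with the target loading
equals the configured ρ exactly (the noise direction is orthogonalized
against the loading before mixing — the naive `ρ·z + √(1−ρ²)·e`
construction has sampling error ≈ 0.06 at n = 100, larger than the
tolerance the downstream checks assume), additive site offsets and age
slopes, and i.i.d. Gaussian sensor noise. The default study conditions are
100 subjects, 250 + 200 voxels, 5 sources, ρ = 0.5 (configurable; the
guided analyses this emulates report loading–symptom correlations roughly
between 0.3 and 0.6), noise sd 0.5 per modality — at the generator's
source-amplitude scale this puts active-voxel signal variance near 2,
i.e. a clearly noisy but identifiable regime.

It does **not** emulate: spatial autocorrelation of real fMRI, hemodynamic
temporal structure, head motion, non-linear site effects, or registration
error between cohorts. Passing tests therefore demonstrate correctness of
the estimator and pipeline logic under the model's assumptions, not
robustness to everything real data can do.

The BOLD fixture generator synthesizes series in the frequency domain with
an exact split of spectral amplitude between the 0.01–0.08 Hz band and the
remaining detectable bins (random phases; real-valued Nyquist bin), so the
downstream fALFF of every voxel equals the requested fraction by
construction.

## Multi-group scenario and validation

`generate_group_scenario` gives every group its own mixing, reference and
non-target sources, but plants a common contiguous core inside the target
source's support (fraction `shared_mask_fraction`, default 0.6 in studies),
with group-specific remainders at disjoint locations. The study runner
reserves one extra generated cohort for validation; its behavior measures
are simulated with controlled correlations to the target loading (three
coupled measures at ρ 0.30–0.40, three null controls, one discretized
PANSS-like subscale). The runner refuses to correlate against a discovery
cohort unless `allow_circular` is set.

`run_study` operates on this synthetic scenario configuration; analyses of
real, file-based data compose the CLI stage commands (`falff`,
`build-features`, `fuse`, `overlap`, `correlate`) instead.

## Problem sizes

Tests and the acceptance script run at desk scale, chosen so the full suite
completes in a few minutes while every check retains headroom: fusion
recovery over 10–20 seeds at n = 100 subjects and M = 8; ICA recovery at
5 × 3000 samples over 10 seeds; overlap recovery over 3-group scenarios;
null error control at n = 144 subjects, 20 measures, 1000–2000 replicate
families. Under these conditions mean mixing-recovery correlation is
≈ 0.998, the reference target is identified in 100% of seeds, and the
planted common region is recovered with Jaccard ≈ 1.

## Known limitations

- The MCCA objective is a deflationary SSQCOR-style formulation; other
  multiset CCA objectives (MAXVAR, GENVAR) and joint (non-deflationary)
  solvers would give slightly different variates.
- Extended Infomax is not implemented; sub-Gaussian sources will not be
  recovered.
- With M well above the true source count, the surplus near-Gaussian
  dimensions make the ICA stopping criterion slow to reach and their maps
  are arbitrary; model-order selection is out of scope.
- The overlap stage requires identical voxel geometry across groups; no
  resampling or registration is performed.
- Correlation reporting assumes roughly linear brain–behavior relations;
  Spearman is offered only as a supplement for discrete scores.
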