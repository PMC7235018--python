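# symfuse

Symptom-guided multimodal neuroimaging fusion for transdiagnostic analysis.

Psychiatric disorders overlap in symptoms and, plausibly, in the brain
networks that carry them. `symfuse` implements a pipeline for finding such
shared networks from two imaging modalities — resting-state fMRI summarized
as fALFF (fractional amplitude of low-frequency fluctuations) and
structural MRI summarized as gray-matter volume (GMV) — using each
diagnostic group's symptom severity score to steer the decomposition. It is
aimed at researchers running fusion analyses across several clinical
cohorts (e.g. schizophrenia, depression, substance use, developmental
disorders) who then want to ask whether the symptom-related networks of
different disorders occupy common brain territory, and whether that common
territory tracks cognition in an independent cohort.

## The model

Each modality is a feature matrix `X_k` (subjects × voxels). The fusion
model assumes a shared subject-wise mixing,

    X_k = A · S_k + E_k ,   k = 1 (fALFF), 2 (GMV)

with `A` the loadings (subjects × M components) and `S_k` the spatial
source maps. Estimation proceeds in stages:

1. **PCA** of each modality to M dimensions.
2. **Multiset CCA with reference**: for each component, find unit-variance
   canonical variates `d_k` maximizing

       J = Σ_{k1<k2} corr(d_k1, d_k2)² + 2λ Σ_k corr(d_k, ref)²

   where `ref` is the standardized symptom score (PANSS total, AUDIT, FTQ,
   HAMD, ADIR, inattentive+impulsive, …). The λ term pulls one component's
   subject loadings toward the clinical score; λ=0 recovers plain multiset
   CCA. Components are extracted deflationarily, each modality update
   solving a small eigenproblem exactly, so J is non-decreasing.
3. **Joint Infomax ICA** on the concatenated least-squares back-projections
   of the variates, yielding maximally independent joint source maps and
   per-modality loadings `A_k = D_k W⁻¹`.

Downstream, the component whose loadings correlate with the symptom score
(Benjamini–Hochberg FDR across the component × modality grid) is Z-scored
and thresholded at |Z| > 2; thresholded maps from several diagnostic groups
are intersected into common-region masks; and the mean feature value inside
a common region is correlated (Pearson, plus Spearman for discrete scores,
BH-FDR across measures) with cognition and symptom subscales in a held-out
validation cohort — never in a cohort used for fusion, to avoid circular
analysis.

Because the clinical cohorts such analyses use are not redistributable, the
package ships a first-class synthetic-data module that generates
two-modality datasets with known mixing, a reference score whose
correlation with the target component's loading is controlled exactly, site
and age confounds, and a *planted* common region across simulated groups —
so every stage, and the pipeline end to end, is scored against ground
truth.

## Worked example

```python
import numpy as np
from symfuse import (SimulationConfig, SymptomGuidedFusion,
                     generate_joint_dataset, select_symptom_component)

cfg = SimulationConfig(n_subjects=100, ref_loading_corr=0.6, seed=7)
(x_falff, x_gmv), truth = generate_joint_dataset(cfg)

model = SymptomGuidedFusion([x_falff, x_gmv], truth.reference,
                            n_components=8, lambda_ref=0.5, seed=7)
res = model.fit()
print(res.summary())
```

```
Symptom-Guided Multimodal Fusion Results
==========================================================
Modalities:        fALFF, GMV
Subjects:          100
Components (M):    8
lambda (ref):      0.5
Unmixing cond. no: 4.01
----------------------------------------------------------
modality   comp  r(loading,ref)           p
fALFF         0          -0.589    1.17e-10
GMV           0          -0.601    3.71e-11
(best component per modality; full grid in ref_r)
==========================================================
```

The generator planted a reference–loading correlation of 0.6 on component
0; the fit recovers that component in both modalities with loading–
reference correlations near −0.6 (sign is a convention: maps are oriented
by positive spatial skewness). `select_symptom_component(res)` confirms the
FDR-based selection picks component 0 for both modalities, and the matched
|correlation| between estimated and true mixing columns is 0.998:

```python
sel = select_symptom_component(res)
sel.component            # {'fALFF': 0, 'GMV': 0}
```

The same objects drive the multi-group workflow: `generate_group_scenario`
plants a common region across groups, `threshold_map` / `overlap_masks`
recover it, and `correlate_with_measures` produces the FDR-starred
correlation table. `run_study` (or `symfuse run-study --config study.yaml`)
chains all stages with a hash manifest for reproducibility. The CLI also
exposes the stages individually (`simulate`, `falff`, `build-features`,
`fuse`, `overlap`, `correlate`) for file-based data.

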