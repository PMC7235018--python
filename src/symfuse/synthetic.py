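"""Synthetic multimodal datasets with known ground truth.

The generator emulates the statistical structure the fusion analysis assumes:
two modality feature matrices (stand-ins for fALFF and gray-matter volume)
sharing a single subject-wise mixing matrix, one component whose subject
loadings correlate with a clinical "symptom" reference score at a controlled
level, additive site/age confounds, and spatially compact supergaussian
source maps. A multi-group variant plants a common active-voxel region
across simulated diagnostic groups so the transdiagnostic overlap stage can
be scored against ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .falff import BoldSeries
from .features import FeatureMatrix

__all__ = [
    "SimulationConfig",
    "SyntheticGroundTruth",
    "generate_joint_dataset",
    "generate_bold_series",
    "generate_group_scenario",
]

#: spectral band used by the fALFF stage, repeated here for the BOLD fixture
_LOW_HZ, _HIGH_HZ, _TOTAL_HZ = 0.01, 0.08, 0.25

#: active-voxel amplitude model: sign * (offset + |Laplace(scale)|).
#: The offset keeps active voxels clear of the |Z|>2 threshold noise floor
#: while the Laplace tail keeps the sources supergaussian for ICA.
_AMP_OFFSET = 1.5
_AMP_SCALE = 0.5


@dataclass
class SimulationConfig:
    """Conditions for one synthetic two-modality dataset.

    Defaults are the desk-scale study conditions used throughout the test
    suite: 100 subjects, 5 spatially compact sources per modality, reference
    correlation 0.5 (within the range of loading-symptom correlations such
    analyses report), noise standard deviation 0.5 per modality.
    """

    n_subjects: int = 100
    n_voxels_per_modality: tuple[int, int] = (250, 200)
    n_sources: int = 5
    target_component: int = 0
    ref_loading_corr: float = 0.5
    noise_sd: float | tuple[float, float] = 0.5
    site_count: int = 2
    confound_effect_sd: float = 0.25
    source_sparsity: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sources > self.n_subjects:
            raise ValueError("n_sources must not exceed n_subjects")
        if not 0 <= self.target_component < self.n_sources:
            raise ValueError("target_component must index a source")
        if not 0.0 <= self.ref_loading_corr <= 1.0:
            raise ValueError("ref_loading_corr must lie in [0, 1]")
        if np.any(np.asarray(self.noise_sd) < 0):
            raise ValueError("noise_sd must be nonnegative")
        if not 0.0 < self.source_sparsity <= 1.0 / self.n_sources:
            raise ValueError(
                "source_sparsity must lie in (0, 1/n_sources] so that "
                "compact sources fit in disjoint voxel segments"
            )
        if self.site_count < 1:
            raise ValueError("site_count must be positive")

    @property
    def noise_sd_pair(self) -> tuple[float, float]:
        sd = self.noise_sd
        if np.isscalar(sd):
            return (float(sd), float(sd))
        return (float(sd[0]), float(sd[1]))


@dataclass
class SyntheticGroundTruth:
    """Everything needed to score recovery of a synthetic dataset."""

    mixing: np.ndarray                      # subjects x n_sources, shared
    sources: list[np.ndarray]               # per modality, n_sources x voxels
    reference: np.ndarray                   # subject "symptom" score
    confounds: pd.DataFrame                 # age, sex, site per subject
    active_masks: list[np.ndarray]          # per modality, n_sources x voxels bool
    target_component: int = 0
    config: SimulationConfig | None = field(default=None, repr=False)


def _source_support(
    v: int, n_sources: int, m: int, rng: np.random.Generator,
    overrides: dict[int, np.ndarray] | None = None,
) -> np.ndarray:
    """Boolean n_sources x v support masks: one contiguous run per source,
    each inside its own voxel segment so sources never overlap."""
    seg = v // n_sources
    if m > seg:
        raise ValueError("source support does not fit in its voxel segment")
    masks = np.zeros((n_sources, v), dtype=bool)
    for i in range(n_sources):
        if overrides is not None and i in overrides:
            masks[i] = overrides[i]
            continue
        start = i * seg + int(rng.integers(0, seg - m + 1))
        masks[i, start:start + m] = True
    return masks


def _fill_sources(masks: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Supergaussian amplitudes on the active voxels, zero elsewhere."""
    S = np.zeros(masks.shape, dtype=float)
    for i in range(masks.shape[0]):
        n_act = int(masks[i].sum())
        signs = rng.choice([-1.0, 1.0], size=n_act)
        S[i, masks[i]] = signs * (_AMP_OFFSET + np.abs(
            rng.laplace(0.0, _AMP_SCALE, size=n_act)))
    return S


def _make_reference(loading: np.ndarray, rho: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Score with *empirical* correlation exactly rho against the loading.

    The noise direction is orthogonalized against the standardized loading
    before mixing, so corr(reference, loading) == rho regardless of n.
    """
    z = (loading - loading.mean()) / loading.std()
    if rho >= 1.0:
        return z.copy()
    e = rng.standard_normal(loading.size)
    e = e - e.mean()
    e -= (e @ z) / (z @ z) * z          # empirical orthogonalization
    e /= e.std()
    return rho * z + np.sqrt(1.0 - rho**2) * e


def _confound_table(n: int, site_count: int,
                    rng: np.random.Generator) -> pd.DataFrame:
    return pd.DataFrame({
        "age": rng.uniform(18.0, 65.0, size=n),
        "sex": rng.choice(["F", "M"], size=n),
        "site": [f"site{j}" for j in rng.integers(0, site_count, size=n)],
    })


def _confound_effects(v: int, confounds: pd.DataFrame, effect_sd: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Additive per-site voxel offsets plus a linear voxelwise age slope."""
    n = len(confounds)
    eff = np.zeros((n, v))
    if effect_sd == 0.0:
        return eff
    sites = confounds["site"].to_numpy()
    for s in np.unique(sites):
        eff[sites == s] += rng.normal(0.0, effect_sd, size=v)
    age = confounds["age"].to_numpy(float)
    z_age = (age - age.mean()) / age.std()
    eff += np.outer(z_age, rng.normal(0.0, effect_sd, size=v))
    return eff


def generate_joint_dataset(
    config: SimulationConfig,
    subject_prefix: str = "sub",
) -> tuple[tuple[FeatureMatrix, FeatureMatrix], SyntheticGroundTruth]:
    """Draw one two-modality dataset X_k = A S_k + confounds + noise.

    The mixing matrix ``A`` (subject loadings) is shared across modalities —
    the joint-ICA premise — and the reference score is built to correlate
    with the target component's loading column at exactly
    ``config.ref_loading_corr``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, M = cfg.n_subjects, cfg.n_sources
    A = rng.standard_normal((n, M))
    confounds = _confound_table(n, cfg.site_count, rng)
    reference = _make_reference(A[:, cfg.target_component],
                                cfg.ref_loading_corr, rng)

    mats, sources, masks = [], [], []
    for k, (v, sd, tag) in enumerate(zip(cfg.n_voxels_per_modality,
                                         cfg.noise_sd_pair,
                                         ("fALFF", "GMV"))):
        m_act = max(1, round(cfg.source_sparsity * v))
        supp = _source_support(v, M, m_act, rng)
        S = _fill_sources(supp, rng)
        X = A @ S
        X += _confound_effects(v, confounds, cfg.confound_effect_sd, rng)
        if sd > 0:
            X += rng.normal(0.0, sd, size=X.shape)
        mats.append(FeatureMatrix(
            X, modality=tag,
            subject_ids=[f"{subject_prefix}-{i:04d}" for i in range(n)],
            provenance=[f"synthetic seed={cfg.seed} modality={k}"],
        ))
        sources.append(S)
        masks.append(supp)

    truth = SyntheticGroundTruth(
        mixing=A, sources=sources, reference=reference,
        confounds=confounds, active_masks=masks,
        target_component=cfg.target_component, config=cfg,
    )
    return (mats[0], mats[1]), truth


def generate_bold_series(
    n_voxels: int,
    n_timepoints: int,
    tr: float,
    band_power_fraction: float,
    seed: int,
    subject_id: str = "sim",
) -> BoldSeries:
    """BOLD-like series with a controlled low-frequency amplitude fraction.

    The series is synthesized in the frequency domain: the total spectral
    amplitude budget is split so that exactly ``band_power_fraction`` of it
    falls in the 0.01-0.08 Hz band and the rest is spread over the remaining
    detectable bins (up to min(Nyquist, 0.25 Hz)), with random phases per
    voxel. The downstream fALFF of every voxel therefore equals
    ``band_power_fraction`` by construction.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    if n_timepoints < 32:
        raise ValueError("need at least 32 timepoints")
    if not 0.0 <= band_power_fraction <= 1.0:
        raise ValueError("band_power_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n_timepoints, d=tr)
    nyq = 0.5 / tr
    in_band = (freqs >= _LOW_HZ) & (freqs <= _HIGH_HZ)
    total = (freqs > 0) & (freqs <= min(nyq, _TOTAL_HZ))
    out_band = total & ~in_band
    if not in_band.any():
        raise ValueError("no DFT bin falls inside the 0.01-0.08 Hz band")
    amp = np.zeros((n_voxels, freqs.size))
    amp[:, in_band] = band_power_fraction / in_band.sum()
    if out_band.any():
        amp[:, out_band] = (1.0 - band_power_fraction) / out_band.sum()
    elif band_power_fraction < 1.0:
        raise ValueError("no out-of-band bins available below Nyquist")
    phases = rng.uniform(0.0, 2.0 * np.pi, size=amp.shape)
    if n_timepoints % 2 == 0:
        # the Nyquist bin of an even-length real DFT is real-valued; a free
        # phase there would be truncated by irfft and bias the band fraction
        phases[:, -1] = np.round(phases[:, -1] / np.pi) * np.pi
    spectrum = amp * np.exp(1j * phases)
    data = np.fft.irfft(spectrum, n=n_timepoints, axis=1) * n_timepoints
    return BoldSeries(data=data, tr=tr, subject_id=subject_id)


def generate_group_scenario(
    shared_mask_fraction: float,
    n_groups: int,
    config: SimulationConfig,
) -> tuple[list[tuple[tuple[FeatureMatrix, FeatureMatrix], SyntheticGroundTruth]],
           list[np.ndarray]]:
    """Multi-group datasets whose target sources share a common voxel region.

    Each group gets its own mixing matrix, reference score and non-target
    sources, but the target source's active mask is the union of a *shared*
    contiguous core — identical across groups and occupying
    ``shared_mask_fraction`` of the support — and a group-specific remainder.
    Returns the per-group datasets and the per-modality shared ground-truth
    masks (the planted "common brain region").
    """
    if n_groups < 2:
        raise ValueError("need at least two groups")
    if not 0.0 <= shared_mask_fraction <= 1.0:
        raise ValueError("shared_mask_fraction must lie in [0, 1]")
    if shared_mask_fraction == 0.0:
        warnings.warn("shared_mask_fraction=0: groups share no target voxels; "
                      "overlap recovery is undefined")

    cfg = config
    t = cfg.target_component
    shared_masks: list[np.ndarray] = []
    target_masks: list[list[np.ndarray]] = []   # per modality, per group
    for v in cfg.n_voxels_per_modality:
        m_act = max(1, round(cfg.source_sparsity * v))
        m_shared = int(round(shared_mask_fraction * m_act))
        m_own = m_act - m_shared
        seg = v // cfg.n_sources
        if m_shared + n_groups * m_own > seg:
            raise ValueError("group-specific target supports do not fit in "
                             "the target voxel segment; lower sparsity or "
                             "n_groups")
        base = t * seg
        shared = np.zeros(v, dtype=bool)
        shared[base:base + m_shared] = True
        shared_masks.append(shared)
        per_group = []
        for g in range(n_groups):
            mask = shared.copy()
            start = base + m_shared + g * m_own
            mask[start:start + m_own] = True
            per_group.append(mask)
        target_masks.append(per_group)

    groups = []
    for g in range(n_groups):
        g_cfg = SimulationConfig(**{**cfg.__dict__, "seed": cfg.seed + 1000 * (g + 1)})
        rng = np.random.default_rng(g_cfg.seed)
        n, M = g_cfg.n_subjects, g_cfg.n_sources
        A = rng.standard_normal((n, M))
        confounds = _confound_table(n, g_cfg.site_count, rng)
        reference = _make_reference(A[:, t], g_cfg.ref_loading_corr, rng)
        mats, sources, masks = [], [], []
        for k, (v, sd, tag) in enumerate(zip(g_cfg.n_voxels_per_modality,
                                             g_cfg.noise_sd_pair,
                                             ("fALFF", "GMV"))):
            m_act = max(1, round(g_cfg.source_sparsity * v))
            supp = _source_support(v, M, m_act, rng,
                                   overrides={t: target_masks[k][g]})
            S = _fill_sources(supp, rng)
            X = A @ S
            X += _confound_effects(v, confounds, g_cfg.confound_effect_sd, rng)
            if sd > 0:
                X += rng.normal(0.0, sd, size=X.shape)
            mats.append(FeatureMatrix(
                X, modality=tag,
                subject_ids=[f"grp{g}-{i:04d}" for i in range(n)],
                provenance=[f"synthetic group={g} seed={g_cfg.seed}"],
            ))
            sources.append(S)
            masks.append(supp)
        groups.append(((mats[0], mats[1]), SyntheticGroundTruth(
            mixing=A, sources=sources, reference=reference,
            confounds=confounds, active_masks=masks,
            target_component=t, config=g_cfg,
        )))
    return groups, shared_masks
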