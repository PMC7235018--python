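"""Fractional amplitude of low-frequency fluctuations (fALFF).

fALFF summarizes per-voxel resting-state activity as the fraction of BOLD
spectral amplitude lying in the 0.01-0.08 Hz band relative to the whole
detectable spectrum (0 to min(Nyquist, 0.25) Hz). Nuisance signals (head
motion, white matter, CSF) are removed by per-voxel linear regression before
the spectral ratio is computed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .features import FeatureMatrix

logger = logging.getLogger(__name__)

LOW_HZ = 0.01
HIGH_HZ = 0.08
TOTAL_MAX_HZ = 0.25


@dataclass
class BoldSeries:
    """One subject's voxel time series.

    data : ndarray, shape (n_voxels, n_timepoints)
    tr : repetition time in seconds
    """

    data: np.ndarray
    tr: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be voxels x timepoints")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.data.shape[1] < 32:
            raise ValueError("need at least 32 timepoints")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite values in BOLD data")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass
class FalffMap:
    """Per-voxel fALFF values in [0, 1] with the bands that produced them."""

    values: np.ndarray
    band: tuple[float, float] = (LOW_HZ, HIGH_HZ)
    total_band: tuple[float, float] = (0.0, TOTAL_MAX_HZ)
    subject_id: str = ""
    zero_amplitude: np.ndarray = field(default=None)  # flags degenerate voxels

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.zero_amplitude is None:
            self.zero_amplitude = np.zeros(self.values.shape, dtype=bool)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite fALFF values")
        if np.any(self.values < 0) or np.any(self.values > 1 + 1e-12):
            raise ValueError("fALFF values must lie in [0, 1]")


def regress_nuisance(series: BoldSeries, confounds: np.ndarray) -> BoldSeries:
    """OLS-residualize every voxel's time series on [intercept | confounds].

    Residuals are orthogonal to every confound column. Rank-deficient
    confound matrices are handled by the least-squares pseudoinverse and
    flagged with a warning.
    """
    C = np.asarray(confounds, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if C.shape[0] != series.n_timepoints:
        raise ValueError("confound rows must equal timepoints")
    if C.shape[1] >= series.n_timepoints:
        raise ValueError("more confounds than timepoints")
    design = np.column_stack([np.ones(C.shape[0]), C])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        warnings.warn("rank-deficient confound matrix; dependent columns "
                      "resolved by pseudoinverse")
    Y = series.data.T                       # timepoints x voxels
    beta, *_ = np.linalg.lstsq(design, Y, rcond=None)
    resid = Y - design @ beta
    return BoldSeries(data=resid.T, tr=series.tr, subject_id=series.subject_id)


def _band_bins(n: int, tr: float) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks over rFFT bins for the numerator band and the
    denominator (0, min(Nyquist, 0.25)] Hz; both band edges inclusive."""
    freqs = np.fft.rfftfreq(n, d=tr)
    nyq = 0.5 / tr
    if nyq < HIGH_HZ:
        raise ValueError(
            f"band exceeds Nyquist: tr={tr} gives Nyquist {nyq:.4f} Hz "
            f"< {HIGH_HZ} Hz")
    hi = min(nyq, TOTAL_MAX_HZ)
    if hi < TOTAL_MAX_HZ:
        logger.info("denominator capped at Nyquist %.4f Hz (< %.2f Hz)",
                    nyq, TOTAL_MAX_HZ)
    numer = (freqs >= LOW_HZ) & (freqs <= HIGH_HZ)
    denom = (freqs > 0) & (freqs <= hi)
    return numer, denom


def compute_falff(series: BoldSeries) -> FalffMap:
    """Spectral-amplitude ratio per voxel.

    Each voxel's series is demeaned (no detrend, no taper), its DFT magnitude
    taken, and fALFF formed as the 0.01-0.08 Hz amplitude sum over the
    (0, min(Nyquist, 0.25)] Hz amplitude sum. Voxels with zero total
    amplitude (e.g. constant series) get fALFF 0 and are flagged.
    """
    numer_bins, denom_bins = _band_bins(series.n_timepoints, series.tr)
    demeaned = series.data - series.data.mean(axis=1, keepdims=True)
    amp = np.abs(np.fft.rfft(demeaned, axis=1))
    num = amp[:, numer_bins].sum(axis=1)
    den = amp[:, denom_bins].sum(axis=1)
    zero = den == 0.0
    values = np.zeros(num.shape)
    np.divide(num, den, out=values, where=~zero)
    values = np.clip(values, 0.0, 1.0)
    if zero.any():
        logger.warning("%d voxel(s) with zero spectral amplitude set to "
                       "fALFF=0", int(zero.sum()))
    return FalffMap(values=values, subject_id=series.subject_id,
                    zero_amplitude=zero)


def falff_group_stack(maps: list[FalffMap],
                      mask: np.ndarray | None = None) -> FeatureMatrix:
    """Stack per-subject fALFF maps into a subjects x voxels FeatureMatrix.

    Rows follow the input order; columns are the in-mask voxels in ascending
    voxel-index order. All maps must share geometry.
    """
    if not maps:
        raise ValueError("no maps to stack")
    n_vox = maps[0].values.size
    for i, m in enumerate(maps):
        if m.values.size != n_vox:
            raise ValueError(
                f"geometry mismatch for subject {m.subject_id or i}: "
                f"{m.values.size} voxels, expected {n_vox}")
    if mask is None:
        mask = np.ones(n_vox, dtype=bool)
    mask = np.asarray(mask, dtype=bool).ravel()
    if mask.size != n_vox:
        raise ValueError("mask geometry does not match maps")
    if not mask.any():
        raise ValueError("empty mask")
    values = np.stack([m.values.ravel()[mask] for m in maps])
    ids = [m.subject_id or f"subject-{i}" for i, m in enumerate(maps)]
    return FeatureMatrix(values, modality="fALFF", subject_ids=ids, mask=mask,
                         provenance=["falff_group_stack"])
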