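"""Transdiagnostic overlap and brain-behavior correlation.

Given per-group fusion results, this stage (1) selects the symptom-related
component per modality by FDR-corrected loading-reference correlation,
(2) thresholds its Z-scored spatial map at |Z| > 2 (positive and negative
exceedances treated equally), (3) intersects the thresholded masks across
diagnostic groups to define common regions, and (4) correlates the mean
feature value inside the common region with cognition/symptom measures in an
independent validation cohort, reporting Benjamini-Hochberg-corrected
Pearson (and, for discrete measures, Spearman) statistics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .features import FeatureMatrix
from .fusion import FusionResults, zscore_map

logger = logging.getLogger(__name__)

Z_THRESHOLD_DEFAULT = 2.0


@dataclass
class ComponentMap:
    """Z-scored spatial map of one component in one modality."""

    z_values: np.ndarray
    modality: str = ""
    component: int = -1
    group: str = ""

    def __post_init__(self) -> None:
        self.z_values = np.asarray(self.z_values, dtype=float).ravel()
        if not np.all(np.isfinite(self.z_values)):
            raise ValueError("non-finite Z values")


@dataclass
class OverlapMask:
    """Voxel mask common to several groups' thresholded component maps."""

    mask: np.ndarray
    groups: list[str] = field(default_factory=list)
    threshold: float = Z_THRESHOLD_DEFAULT
    modality: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool).ravel()

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class ComponentSelection:
    """Outcome of symptom-component selection for one fusion model.

    ``component[modality]`` is the chosen component index or ``None`` when
    no loading-reference correlation survives FDR for that modality.
    """

    component: dict[str, int | None]
    r: dict[str, float | None]
    p_fdr: dict[str, float | None]
    any_selected: bool = True

    def __bool__(self) -> bool:  # truthy when at least one modality selected
        return self.any_selected


def bh_fdr(p_values: np.ndarray, alpha: float = 0.05
           ) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up control of the false discovery rate.

    Returns (adjusted p-values, significance flags at ``alpha``). Adjusted
    p-values follow the usual step-up definition, capped at 1.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return p_adj, reject


def select_symptom_component(results: FusionResults, alpha: float = 0.05
                             ) -> ComponentSelection:
    """Pick the symptom-related component per modality.

    The loading-reference p-values are FDR-corrected jointly across the
    component x modality grid; among surviving entries in each modality, the
    component with the largest |r| is chosen (lowest index on exact ties,
    logged). A modality with no survivor maps to ``None``; if no modality
    survives the result is falsy rather than an exception.
    """
    if results.ref_r is None:
        raise ValueError("fusion results carry no reference correlations")
    r, p = results.ref_r, results.ref_p
    _, reject = bh_fdr(p.ravel(), alpha=alpha)
    reject = reject.reshape(p.shape)
    comp: dict[str, int | None] = {}
    r_out: dict[str, float | None] = {}
    p_out: dict[str, float | None] = {}
    p_adj = bh_fdr(p.ravel(), alpha=alpha)[0].reshape(p.shape)
    for k, name in enumerate(results.modalities):
        idx = np.flatnonzero(reject[k])
        if idx.size == 0:
            comp[name] = r_out[name] = p_out[name] = None
            continue
        absr = np.abs(r[k, idx])
        best = idx[np.flatnonzero(absr == absr.max())]
        if best.size > 1:
            logger.info("tie on |r| for modality %s among components %s; "
                        "lowest index chosen", name, best.tolist())
        j = int(best[0])
        comp[name] = j
        r_out[name] = float(r[k, j])
        p_out[name] = float(p_adj[k, j])
    any_sel = any(v is not None for v in comp.values())
    if not any_sel:
        logger.warning("no symptom-related component survives FDR in any "
                       "modality")
    return ComponentSelection(comp, r_out, p_out, any_selected=any_sel)


def threshold_map(cmap: ComponentMap | np.ndarray,
                  z_thresh: float = Z_THRESHOLD_DEFAULT) -> np.ndarray:
    """Boolean mask of voxels with |Z| strictly above the threshold."""
    if z_thresh <= 0:
        raise ValueError("z_thresh must be positive")
    z = cmap.z_values if isinstance(cmap, ComponentMap) else np.asarray(cmap)
    mask = np.abs(z) > z_thresh
    if not mask.any():
        warnings.warn("thresholded map is empty")
    return mask


def overlap_masks(masks: list[np.ndarray | OverlapMask],
                  groups: list[str] | None = None,
                  threshold: float = Z_THRESHOLD_DEFAULT,
                  modality: str = "") -> OverlapMask:
    """Voxelwise intersection of absolute-value threshold masks.

    Positive and negative symptom correlations are treated equally: the
    inputs are |Z|-threshold masks, so a voxel survives when every group
    exceeds the threshold in either direction.
    """
    arrs = [m.mask if isinstance(m, OverlapMask) else np.asarray(m, bool)
            for m in masks]
    if len(arrs) < 2:
        raise ValueError("need at least two masks to overlap")
    n = arrs[0].size
    if any(a.size != n for a in arrs):
        raise ValueError("mask geometry mismatch")
    out = arrs[0].copy()
    for a in arrs[1:]:
        out &= a
    if not out.any():
        warnings.warn("overlap mask is empty")
    if groups is None:
        groups = [f"group{i}" for i in range(len(arrs))]
    return OverlapMask(out, groups=list(groups), threshold=threshold,
                       modality=modality)


def roi_mean(X: FeatureMatrix | np.ndarray,
             mask: OverlapMask | np.ndarray) -> np.ndarray:
    """Per-subject mean of the feature values inside the overlap region."""
    values = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, float)
    m = mask.mask if isinstance(mask, OverlapMask) else np.asarray(mask, bool)
    if m.size != values.shape[1]:
        raise ValueError("mask geometry does not match feature matrix")
    if not m.any():
        raise ValueError("empty ROI mask")
    return values[:, m].mean(axis=1)


@dataclass
class CorrelationReport:
    """FDR-annotated correlations between an ROI mean and behavior measures.

    ``table`` rows: measure, n, pearson_r, pearson_p, spearman_rho,
    spearman_p, p_fdr, significant. The star convention flags rows whose
    BH-adjusted Pearson p falls below ``alpha``.
    """

    table: pd.DataFrame
    alpha: float = 0.05
    fdr_family: str = "pearson p across measures within this report"

    def __str__(self) -> str:
        out = self.table.copy()
        out["sig"] = np.where(out["significant"], "*", "")
        return out.to_string(index=False)


def correlate_with_measures(
    roi: np.ndarray,
    measures: pd.DataFrame,
    discrete_flags: dict[str, bool] | list[str] | None = None,
    alpha: float = 0.05,
    min_pairs: int = 10,
) -> CorrelationReport:
    """Correlate the ROI mean with each behavior measure.

    Pearson r/p for every measure; Spearman rho/p additionally for measures
    flagged discrete (e.g. symptom subscale scores). Missing values are
    dropped pairwise. BH-FDR is applied across the Pearson p column, and the
    ``significant`` flag stars rows with adjusted p < ``alpha``.
    """
    roi = np.asarray(roi, dtype=float).ravel()
    if isinstance(discrete_flags, (list, tuple, set)):
        discrete_flags = {m: True for m in discrete_flags}
    discrete_flags = discrete_flags or {}
    rows = []
    for name in measures.columns:
        y = measures[name].to_numpy(float)
        keep = np.isfinite(roi) & np.isfinite(y)
        n = int(keep.sum())
        if n < min_pairs:
            raise ValueError(f"measure {name!r}: only {n} complete pairs "
                             f"(need >= {min_pairs})")
        xv, yv = roi[keep], y[keep]
        if np.std(yv) == 0 or np.std(xv) == 0:
            rows.append((name, n, np.nan, np.nan, np.nan, np.nan))
            logger.warning("measure %r has zero variance; not computable",
                           name)
            continue
        r, p = stats.pearsonr(xv, yv)
        rho = sp = np.nan
        if discrete_flags.get(name, False):
            rho, sp = stats.spearmanr(xv, yv)
        rows.append((name, n, r, p, rho, sp))
    table = pd.DataFrame(rows, columns=[
        "measure", "n", "pearson_r", "pearson_p", "spearman_rho",
        "spearman_p"])
    computable = table["pearson_p"].notna()
    p_fdr = np.full(len(table), np.nan)
    sig = np.zeros(len(table), dtype=bool)
    if computable.any():
        adj, rej = bh_fdr(table.loc[computable, "pearson_p"].to_numpy(),
                          alpha=alpha)
        p_fdr[computable.to_numpy()] = adj
        sig[computable.to_numpy()] = rej
    table["p_fdr"] = p_fdr
    table["significant"] = sig
    return CorrelationReport(table=table, alpha=alpha)
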