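"""Feature-matrix construction: covariate regression and cross-modality normalization.

Each imaging modality is flattened into a subjects x voxels matrix. Before
fusion, per-voxel covariate effects (age, sex, acquisition site) are removed
by linear regression, and the modalities are rescaled to share a common
average sum of squares so that neither dominates the joint decomposition.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_COVARIATES = ("age", "sex", "site")


@dataclass
class FeatureMatrix:
    """Subjects x voxels feature matrix for one modality.

    Parameters
    ----------
    values : ndarray, shape (n_subjects, n_voxels)
        One row per subject, one column per in-mask voxel.
    modality : str
        Modality tag, e.g. ``"fALFF"`` or ``"GMV"``.
    subject_ids : list of str
        Unique subject identifiers, one per row.
    mask : ndarray of bool, optional
        Voxel mask in the source image geometry; ``mask.sum()`` must equal
        the number of columns. ``None`` for synthetic flat data.
    provenance : list of str
        Log of transforms applied to reach this matrix.
    """

    values: np.ndarray
    modality: str
    subject_ids: list[str]
    mask: np.ndarray | None = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (subjects x voxels)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")
        if len(self.subject_ids) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.subject_ids)} subject ids for "
                f"{self.values.shape[0]} rows"
            )
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("subject_ids must be unique")
        if self.mask is not None and int(np.sum(self.mask)) != self.values.shape[1]:
            raise ValueError("mask size does not match voxel count")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray, note: str) -> "FeatureMatrix":
        """Copy with new values and an appended provenance entry."""
        return replace(
            self, values=np.asarray(values, float),
            provenance=[*self.provenance, note],
        )


def _build_design(covars: pd.DataFrame, which: list[str]) -> tuple[np.ndarray, list[str]]:
    """Expand covariates into a centered numeric design (no intercept column).

    Continuous covariates are mean-centered; categorical ones are dummy-coded
    with the first level dropped. Constant columns are removed with a warning.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    for name in which:
        col = covars[name]
        if name in ("sex", "site") or col.dtype == object or isinstance(
            col.dtype, pd.CategoricalDtype
        ):
            dummies = pd.get_dummies(col.astype("category"), prefix=name,
                                     drop_first=True, dtype=float)
            for dname in dummies.columns:
                cols.append(dummies[dname].to_numpy(float))
                names.append(str(dname))
        else:
            cols.append(col.to_numpy(float))
            names.append(name)
    design_cols, kept = [], []
    for arr, name in zip(cols, names):
        centered = arr - arr.mean()
        if np.allclose(centered, 0.0):
            warnings.warn(f"covariate column {name!r} is constant; dropped")
            continue
        design_cols.append(centered)
        kept.append(name)
    if not design_cols:
        return np.empty((len(covars), 0)), []
    return np.column_stack(design_cols), kept


def regress_covariates(
    X: FeatureMatrix,
    covars: pd.DataFrame,
    which: list[str] | tuple[str, ...] = (),
) -> FeatureMatrix:
    """Remove linear covariate effects from every voxel column.

    Fits per-voxel ordinary least squares of the feature on an intercept plus
    the selected covariates (sex/site dummy-coded), and returns the residuals
    with each voxel's grand mean added back, so only covariate-explained
    variance is removed and the values stay on their original scale.

    Parameters
    ----------
    X : FeatureMatrix
    covars : DataFrame
        One row per subject of ``X``, in the same order.
    which : subset of {"age", "sex", "site"}
        Covariates to regress out. Empty means no-op.
    """
    which = list(which)
    unknown = set(which) - set(VALID_COVARIATES)
    if unknown:
        raise ValueError(f"unknown covariates: {sorted(unknown)}")
    if len(covars) != X.n_subjects:
        raise ValueError("covariate table row count does not match subjects")
    if not which:
        return X.with_values(X.values.copy(), "regress_covariates: none")

    if "site" in which:
        counts = covars["site"].value_counts()
        lonely = counts[counts == 1]
        if len(lonely):
            warnings.warn(
                f"site(s) with a single subject: {list(lonely.index)}; "
                "their effect is perfectly absorbed by the site dummy"
            )

    Z, kept = _build_design(covars, which)
    if Z.shape[1] == 0:
        return X.with_values(X.values.copy(), "regress_covariates: all-constant")
    rank = np.linalg.matrix_rank(Z)
    if rank < Z.shape[1]:
        warnings.warn("rank-deficient covariate design; dependent columns "
                      "handled by least-squares pseudoinverse")
    col_means = X.values.mean(axis=0)
    Xc = X.values - col_means
    beta, *_ = np.linalg.lstsq(Z, Xc, rcond=None)
    resid = Xc - Z @ beta
    out = resid + col_means
    return X.with_values(out, f"regress_covariates: {kept}")


def normalize_modalities(X_list: list[FeatureMatrix]) -> list[FeatureMatrix]:
    """Scale each modality so its mean square over all entries equals 1.

    A single positive scalar per modality; this equalizes the average sum of
    squares across modalities (computed across all subjects and all voxels)
    so the joint decomposition weights them evenly.
    """
    if len(X_list) < 2:
        raise ValueError("need at least two modalities to normalize jointly")
    ids0 = X_list[0].subject_ids
    for X in X_list[1:]:
        if X.subject_ids != ids0:
            raise ValueError("modalities must share subject order")
    out = []
    for X in X_list:
        ms = float(np.mean(X.values**2))
        if ms == 0.0:
            raise ValueError(f"modality {X.modality!r} is identically zero; "
                             "no valid scale")
        scale = 1.0 / np.sqrt(ms)
        out.append(X.with_values(X.values * scale,
                                 f"normalize_modalities: scale={scale:.6g}"))
    return out
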