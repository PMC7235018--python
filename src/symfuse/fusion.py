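"""Symptom-guided multimodal fusion: MCCA-with-reference + joint Infomax ICA.

The estimator jointly decomposes K modality feature matrices (subjects x
voxels) into M components sharing subject-wise loadings, steering one
component's loadings toward a clinical reference score:

1. per-modality PCA to M dimensions;
2. deflationary multiset CCA maximizing, for each component,
   ``sum_{k1<k2} corr(d_k1, d_k2)^2 + 2*lambda * sum_k corr(d_k, ref)^2``
   over unit-variance canonical variates ``d_k``;
3. least-squares back-projection of the variates to voxel-space maps;
4. joint Infomax ICA on the concatenated maps, yielding independent source
   maps and per-modality mixing (loading) matrices ``A_k = D_k W^{-1}``.

Loading-reference correlations identify the symptom-related component; its
Z-scored spatial maps feed the transdiagnostic overlap stage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .features import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "FusionConfig", "ReferenceVector", "FusionResults", "SymptomGuidedFusion",
    "pca_reduce", "mcca_with_reference", "associated_maps", "infomax_ica",
    "finalize", "zscore_map",
]


@dataclass
class FusionConfig:
    """Estimator settings.

    n_components : number of joint components M. Desk-scale analyses default
        to 8; cohort-scale runs use 50 when the subject count permits
        (M <= subjects - 1 is enforced at fit time).
    lambda_ref : weight of the reference-correlation term in the MCCA
        objective; 0 recovers plain multiset CCA.
    """

    n_components: int = 8
    lambda_ref: float = 0.5
    ica_max_iter: int = 20000
    ica_tol: float = 1e-6
    ica_learning_rate: float = 0.03
    mcca_max_iter: int = 5000
    mcca_tol: float = 1e-9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.lambda_ref < 0:
            raise ValueError("lambda_ref must be nonnegative")
        if self.ica_tol <= 0 or self.mcca_tol <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class ReferenceVector:
    """Per-subject clinical score used to steer the fusion."""

    scores: np.ndarray
    name: str = "reference"

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float).ravel()
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("reference contains non-finite values")
        if self.scores.std() == 0:
            raise ValueError("reference has zero variance")

    @property
    def standardized(self) -> np.ndarray:
        z = self.scores - self.scores.mean()
        return z / z.std()


def pca_reduce(X: np.ndarray, M: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Best rank-M approximation of the column-demeaned matrix.

    Returns (scores: subjects x M, basis: M x voxels, explained_variance
    fraction per component). Components are ordered by decreasing variance;
    each basis row's largest-magnitude entry is made positive so the
    decomposition is sign-deterministic.
    """
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(Xc.shape) * np.finfo(float).eps)) if s.size else 0
    if M > rank:
        raise ValueError(f"requested {M} components but rank is {rank}")
    U, s, Vt = U[:, :M], s[:M], Vt[:M]
    flip = np.sign(Vt[np.arange(M), np.argmax(np.abs(Vt), axis=1)])
    Vt = Vt * flip[:, None]
    scores = U * s * flip
    total_var = float(np.sum(np.linalg.svd(Xc, compute_uv=False) ** 2))
    explained = s**2 / total_var if total_var > 0 else np.zeros(M)
    return scores, Vt, explained


def _top_gen_eigvec(B: np.ndarray) -> np.ndarray:
    """Leading eigenvector of a small symmetric PSD matrix, sign-fixed."""
    vals, vecs = np.linalg.eigh(B)
    v = vecs[:, -1]
    j = int(np.argmax(np.abs(v)))
    return v * np.sign(v[j]) if v[j] != 0 else v


def _mcca_objective(ds: list[np.ndarray], ref: np.ndarray, lam: float) -> float:
    K = len(ds)
    J = 0.0
    for a in range(K):
        for b in range(a + 1, K):
            J += float(np.corrcoef(ds[a], ds[b])[0, 1] ** 2)
    if lam > 0:
        for d in ds:
            J += 2.0 * lam * float(np.corrcoef(d, ref)[0, 1] ** 2)
    return J


def mcca_with_reference(
    E_list: list[np.ndarray],
    ref: ReferenceVector | np.ndarray,
    config: FusionConfig,
) -> tuple[list[np.ndarray], list[list[float]]]:
    """Deflationary multiset CCA with a reference-correlation penalty.

    For components j = 1..M, finds unit-variance directions ``d_j^(k)`` in
    each modality's score space maximizing the sum of squared inter-modality
    correlations plus ``2*lambda`` times the squared correlations with the
    reference, with each ``d_j^(k)`` uncorrelated with that modality's
    previously extracted variates. Solved by coordinate ascent in which each
    modality update is an exact small eigenproblem, so the objective never
    decreases; iteration stops when the objective gain drops below
    ``mcca_tol``.

    Returns (canonical variates per modality, per-component objective traces).
    """
    if isinstance(ref, ReferenceVector):
        r = ref.standardized
    else:
        r = np.asarray(ref, float).ravel()
        r = (r - r.mean()) / r.std()
    E_list = [np.asarray(E, float) for E in E_list]
    n = E_list[0].shape[0]
    if any(E.shape[0] != n for E in E_list) or r.size != n:
        raise ValueError("all score matrices and the reference must share "
                         "the subject dimension")
    K = len(E_list)
    M = min(config.n_components, min(E.shape[1] for E in E_list))
    lam = config.lambda_ref
    Ec = [E - E.mean(axis=0) for E in E_list]
    rhat = r / np.linalg.norm(r)

    D = [np.zeros((n, 0)) for _ in range(K)]
    traces: list[list[float]] = []
    for j in range(M):
        # restrict to the orthogonal complement of previous variates
        bases = []
        for k in range(K):
            Rk = Ec[k]
            if D[k].shape[1]:
                Q, _ = np.linalg.qr(D[k])
                Rk = Rk - Q @ (Q.T @ Rk)
            U, s, _ = np.linalg.svd(Rk, full_matrices=False)
            keep = s > (s[0] * 1e-10 if s.size else 0)
            bases.append(U[:, keep])
        ds = [B[:, 0].copy() for B in bases]
        trace = [_mcca_objective(ds, r, lam)]
        for _ in range(config.mcca_max_iter):
            for k in range(K):
                U = bases[k]
                B = np.zeros((U.shape[1],) * 2)
                for k2 in range(K):
                    if k2 == k:
                        continue
                    u = U.T @ (ds[k2] / np.linalg.norm(ds[k2]))
                    B += np.outer(u, u)
                if lam > 0:
                    u = U.T @ rhat
                    B += 2.0 * lam * np.outer(u, u)
                alpha = _top_gen_eigvec(B)
                ds[k] = U @ alpha
            trace.append(_mcca_objective(ds, r, lam))
            if trace[-1] - trace[-2] < config.mcca_tol:
                break
        else:
            warnings.warn(
                f"MCCA component {j}: not converged after "
                f"{config.mcca_max_iter} iterations "
                f"(last objective delta {trace[-1] - trace[-2]:.3g})")
        traces.append(trace)
        # align signs across modalities (corr^2 objective is sign-blind, but
        # the joint ICA stage needs consistently oriented variates)
        for k in range(1, K):
            if np.corrcoef(ds[k], ds[0])[0, 1] < 0:
                ds[k] = -ds[k]
        for k in range(K):
            d = ds[k] - ds[k].mean()
            D[k] = np.column_stack([D[k], d / d.std()])
    return D, traces


def associated_maps(D_list: list[np.ndarray],
                    X_list: list[np.ndarray]) -> list[np.ndarray]:
    """Least-squares voxel-space maps C_k = pinv(D_k) X_k (so D_k C_k ~ X_k)."""
    C_list = []
    for D, X in zip(D_list, X_list):
        if np.linalg.matrix_rank(D) < D.shape[1]:
            raise ValueError("rank-deficient canonical variates")
        C_list.append(np.linalg.pinv(D) @ np.asarray(X, float))
    return C_list


def infomax_ica(
    C_concat: np.ndarray,
    config: FusionConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Infomax ICA (logistic nonlinearity, natural gradient) on M x V data.

    The data are row-demeaned and sphered; the unmixing weights start at a
    seeded perturbation of the identity and follow full-batch natural
    gradient steps ``dW = lr (I + (1 - 2g(u)) u^T / V) W``. The learning
    rate anneals when successive updates oscillate; iteration stops when
    ``max|dW| < ica_tol``. Non-finite blow-ups trigger up to three restarts
    at halved learning rates.

    Returns (unmixing W with sources = W @ demeaned data, sources S).
    """
    C = np.asarray(C_concat, dtype=float)
    if C.ndim != 2:
        raise ValueError("C_concat must be 2-D")
    M, V = C.shape
    Cc = C - C.mean(axis=1, keepdims=True)
    cov = Cc @ Cc.T / V
    evals, evecs = np.linalg.eigh(cov)
    if np.any(evals <= 0):
        raise ValueError("degenerate (rank-deficient) map matrix")
    sphere = evecs @ np.diag(evals**-0.5) @ evecs.T
    Xs = sphere @ Cc

    rng = np.random.default_rng(config.seed)
    W0 = np.eye(M) + 0.005 * rng.standard_normal((M, M))
    lr0 = config.ica_learning_rate
    eye = np.eye(M)
    for attempt in range(4):
        W = W0.copy()
        lr = lr0 / (2**attempt)
        prev_dW = None
        ok = True
        for it in range(config.ica_max_iter):
            U = W @ Xs
            Y = 1.0 / (1.0 + np.exp(-U))
            grad = (eye + (1.0 - 2.0 * Y) @ U.T / V) @ W
            dW = lr * grad
            if not np.all(np.isfinite(dW)):
                ok = False
                break
            W = W + dW
            if prev_dW is not None:
                cosang = np.sum(dW * prev_dW) / (
                    np.linalg.norm(dW) * np.linalg.norm(prev_dW) + 1e-300)
                if cosang < 0.5:        # oscillating: anneal
                    lr *= 0.9
            prev_dW = dW
            if np.max(np.abs(dW)) < config.ica_tol:
                logger.debug("infomax converged in %d iterations", it + 1)
                break
        else:
            warnings.warn(f"infomax ICA: no convergence after "
                          f"{config.ica_max_iter} iterations "
                          f"(max|dW|={np.max(np.abs(dW)):.3g})")
        if ok and np.all(np.isfinite(W)):
            W_total = W @ sphere
            return W_total, W_total @ Cc
        logger.warning("infomax blow-up; restarting with halved learning rate")
    raise RuntimeError("infomax ICA diverged after 3 restarts")


def zscore_map(map_row: np.ndarray) -> np.ndarray:
    """Z-score a spatial map with the population standard deviation."""
    v = np.asarray(map_row, dtype=float).ravel()
    sd = v.std()
    if sd == 0:
        raise ValueError("degenerate component map")
    return (v - v.mean()) / sd


@dataclass
class FusionResults:
    """Fitted fusion state: loadings, source maps and reference correlations.

    mixing[k] (subjects x M) holds the per-modality loadings A_k;
    joint_sources[k] (M x voxels_k) the modality's slice of the joint source
    maps; ref_r / ref_p the Pearson correlation of each loading column with
    the reference, per modality.
    """

    model: "SymptomGuidedFusion" = field(repr=False)
    canonical_variates: list[np.ndarray] = field(repr=False)
    assoc_maps: list[np.ndarray] = field(repr=False)
    ica_unmixing: np.ndarray = field(repr=False)
    joint_sources: list[np.ndarray] = field(repr=False)
    mixing: list[np.ndarray] = field(repr=False)
    ref_r: np.ndarray | None = None          # modalities x M
    ref_p: np.ndarray | None = None
    pca_bases: list[np.ndarray] = field(default=None, repr=False)
    pca_explained: list[np.ndarray] = field(default=None, repr=False)
    mcca_traces: list[list[float]] = field(default=None, repr=False)
    modality_names: list[str] | None = None

    @property
    def n_components(self) -> int:
        return self.ica_unmixing.shape[0]

    @property
    def modalities(self) -> list[str]:
        if self.modality_names is not None:
            return self.modality_names
        if self.model is not None:
            return self.model.modalities
        return [f"modality{k}" for k in range(len(self.mixing))]

    def zmap(self, modality_index: int, component: int) -> np.ndarray:
        """Z-scored spatial map of one component in one modality."""
        return zscore_map(self.joint_sources[modality_index][component])

    def summary(self) -> str:
        """Text summary in the spirit of a regression results table."""
        lines = []
        lines.append("Symptom-Guided Multimodal Fusion Results")
        lines.append("=" * 58)
        lines.append(f"Modalities:        {', '.join(self.modalities)}")
        lines.append(f"Subjects:          {self.mixing[0].shape[0]}")
        lines.append(f"Components (M):    {self.n_components}")
        lines.append(f"lambda (ref):      {self.model.config.lambda_ref}")
        cond = np.linalg.cond(self.ica_unmixing)
        lines.append(f"Unmixing cond. no: {cond:.3g}")
        if self.ref_r is not None:
            lines.append("-" * 58)
            lines.append(f"{'modality':<10}{'comp':>5}{'r(loading,ref)':>16}"
                         f"{'p':>12}")
            for k, name in enumerate(self.modalities):
                j = int(np.argmax(np.abs(self.ref_r[k])))
                lines.append(f"{name:<10}{j:>5}{self.ref_r[k, j]:>16.3f}"
                             f"{self.ref_p[k, j]:>12.3g}")
            lines.append("(best component per modality; full grid in ref_r)")
        lines.append("=" * 58)
        return "\n".join(lines)


def finalize(
    D_list: list[np.ndarray],
    W: np.ndarray,
    S: np.ndarray,
    V_split: list[int],
    ref: ReferenceVector | None = None,
    model: "SymptomGuidedFusion | None" = None,
    assoc_maps: list[np.ndarray] | None = None,
    **extras,
) -> FusionResults:
    """Assemble per-modality mixing and sources from the joint ICA solve.

    ``A_k = D_k W^{-1}``; the joint source matrix is split at ``V_split``
    into per-modality maps. Each component is oriented so its concatenated
    spatial map has positive skewness (loading signs follow), a convention
    that leaves the reference free to correlate with either sign.
    """
    if abs(np.linalg.det(W)) < 1e-300:
        raise ValueError("singular unmixing matrix")
    Winv = np.linalg.inv(W)
    mixing = [D @ Winv for D in D_list]
    S = S.copy()
    flips = np.where(stats.skew(S, axis=1) < 0, -1.0, 1.0)
    S *= flips[:, None]
    for A in mixing:
        A *= flips[None, :]
    bounds = np.cumsum([0, *V_split])
    joint_sources = [S[:, bounds[i]:bounds[i + 1]] for i in range(len(V_split))]
    ref_r = ref_p = None
    if ref is not None:
        z = ref.standardized
        M = S.shape[0]
        ref_r = np.zeros((len(mixing), M))
        ref_p = np.ones((len(mixing), M))
        for k, A in enumerate(mixing):
            for j in range(M):
                ref_r[k, j], ref_p[k, j] = stats.pearsonr(A[:, j], z)
    return FusionResults(
        model=model, canonical_variates=D_list,
        assoc_maps=assoc_maps if assoc_maps is not None else [],
        ica_unmixing=W, joint_sources=joint_sources, mixing=mixing,
        ref_r=ref_r, ref_p=ref_p, **extras,
    )


class SymptomGuidedFusion:
    """Fusion model over K modality feature matrices and a reference score.

    Parameters
    ----------
    X_list : list of FeatureMatrix (or plain subjects x voxels arrays)
        One matrix per modality, identical subject order.
    reference : ReferenceVector or array-like
        Per-subject clinical score steering the decomposition.
    config : FusionConfig, optional
        Estimator settings; keyword arguments override individual fields.

    Examples
    --------
    >>> model = SymptomGuidedFusion([x_falff, x_gmv], panss,
    ...                             n_components=8, lambda_ref=0.5, seed=1)
    >>> res = model.fit()
    >>> print(res.summary())
    """

    def __init__(self, X_list, reference, config: FusionConfig | None = None,
                 **config_overrides):
        if config is None:
            config = FusionConfig(**config_overrides)
        elif config_overrides:
            config = FusionConfig(**{**config.__dict__, **config_overrides})
        self.config = config
        self.modalities = []
        self._X = []
        for k, X in enumerate(X_list):
            if isinstance(X, FeatureMatrix):
                self.modalities.append(X.modality)
                self._X.append(X.values)
            else:
                self.modalities.append(f"modality{k}")
                self._X.append(np.asarray(X, float))
        if len(self._X) < 2:
            raise ValueError("need at least two modalities")
        n = self._X[0].shape[0]
        if any(x.shape[0] != n for x in self._X):
            raise ValueError("modalities must share the subject dimension")
        if not isinstance(reference, ReferenceVector):
            reference = ReferenceVector(np.asarray(reference, float))
        if reference.scores.size != n:
            raise ValueError("reference length must match subjects")
        self.reference = reference
        M = self.config.n_components
        if M > n - 1:
            raise ValueError(f"n_components={M} exceeds subjects-1={n - 1}")
        if any(M > x.shape[1] for x in self._X):
            raise ValueError("n_components exceeds voxel count of a modality")

    def fit(self) -> FusionResults:
        cfg = self.config
        M = cfg.n_components
        Xc = [x - x.mean(axis=0) for x in self._X]
        scores, bases, explained = [], [], []
        for x in Xc:
            E, B, ev = pca_reduce(x, M)
            scores.append(E)
            bases.append(B)
            explained.append(ev)
        D_list, traces = mcca_with_reference(scores, self.reference, cfg)
        C_list = associated_maps(D_list, Xc)
        C_list = [C - C.mean(axis=1, keepdims=True) for C in C_list]
        V_split = [C.shape[1] for C in C_list]
        C_concat = np.hstack(C_list)
        W, S = infomax_ica(C_concat, cfg)
        return finalize(
            D_list, W, S, V_split, ref=self.reference, model=self,
            assoc_maps=C_list, pca_bases=bases, pca_explained=explained,
            mcca_traces=traces,
        )
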