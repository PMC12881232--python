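"""Health process manifold: discriminant embedding with Laplacian eigenmaps.

The phenotypic-state score V places each sample on a one-(or low-)dimensional
"health process manifold" anchored by two cohorts: a background group with the
optimal phenotype and a target group with the worst phenotype.  The projection
``Y = X C`` is chosen to simultaneously (i) separate the two anchor groups --
maximising ``tr(C' B C)`` with ``B`` the rank-1 between-group scatter of the
mean difference -- and (ii) preserve local sample neighbourhoods, minimising
``tr(C' X' L X C)`` where ``L = D - W`` is the graph Laplacian of the sample
correlation graph.  Both goals combine into the trace-ratio objective

    max_C  tr(C' B C) / tr(C' S C),      S = X' L X,

whose d leading directions are eigenvectors of ``S^{-1} B``.  Because B has
rank one there is a single discriminant direction; any further requested
dimensions are filled with the smallest-eigenvalue directions of S restricted
to the orthogonal complement (pure Laplacian-eigenmap axes), which preserves
the manifold-visualisation intent.

The user-facing entry point is :class:`HealthManifold` (a model object built
from an :class:`~hsm.data.ExpressionMatrix` and a
:class:`~hsm.data.CohortDesign`) whose :meth:`~HealthManifold.fit` returns a
:class:`ManifoldResults` that can score new samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.model_selection import StratifiedKFold

from ._correlation import pearson_matrix
from .data import CohortDesign, ExpressionMatrix

__all__ = [
    "HealthManifold",
    "ManifoldResults",
    "VScores",
    "FeatureStability",
    "DegenerateManifoldError",
    "sample_adjacency",
    "laplacian",
    "between_scatter",
    "fit_manifold",
    "cv_feature_selection",
    "combine_v_axes",
]


class DegenerateManifoldError(ValueError):
    """Raised when the two anchor groups cannot define a manifold
    (identical group means, or a numerically singular scatter)."""


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def sample_adjacency(X: ExpressionMatrix | np.ndarray, mode: str = "clamp") -> np.ndarray:
    """Sample-sample adjacency from Pearson correlation of expression rows.

    ``mode='clamp'`` (default) sets negative correlations to 0 so the graph
    Laplacian stays positive semidefinite; ``mode='abs'`` uses |PCC| instead.
    The diagonal is zero.
    """
    values = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, float)
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("adjacency needs >=2 samples and >=2 features")
    r = pearson_matrix(values, rowvar=True)
    if mode == "clamp":
        W = np.maximum(r, 0.0)
    elif mode == "abs":
        W = np.abs(r)
    else:
        raise ValueError(f"unknown adjacency mode {mode!r}")
    np.fill_diagonal(W, 0.0)
    return 0.5 * (W + W.T)


def laplacian(W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Graph Laplacian ``L = D - W`` and degree matrix D of a symmetric,
    nonnegative, zero-diagonal weight matrix."""
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("W must be square")
    if not np.allclose(W, W.T, atol=1e-10):
        raise ValueError("W must be symmetric")
    if np.any(W < -1e-12):
        raise ValueError("W must be nonnegative")
    D = np.diag(W.sum(axis=1))
    return D - W, D


def between_scatter(XH: ExpressionMatrix | np.ndarray, XD: ExpressionMatrix | np.ndarray) -> np.ndarray:
    """Rank-1 between-group scatter: outer product of the target-minus-
    background mean-difference vector with itself."""
    if isinstance(XH, ExpressionMatrix) and isinstance(XD, ExpressionMatrix):
        if XH.feature_ids != XD.feature_ids:
            raise ValueError("background and target groups have mismatched features")
        VH, VD = XH.values, XD.values
    else:
        VH, VD = np.asarray(XH, float), np.asarray(XD, float)
        if VH.shape[1] != VD.shape[1]:
            raise ValueError("background and target groups have mismatched features")
    diff = VD.mean(axis=0) - VH.mean(axis=0)
    return np.outer(diff, diff)


def _fix_sign(c: np.ndarray) -> np.ndarray:
    """Deterministic eigenvector sign: largest-|component| entry positive."""
    i = int(np.argmax(np.abs(c)))
    return c if c[i] >= 0 else -c


def _solve_projection(
    VH: np.ndarray,
    VD: np.ndarray,
    d: int,
    epsilon: float | None,
    weight_mode: str,
) -> tuple[np.ndarray, float, float]:
    """Core solver. Returns (C, epsilon_used, trace_ratio_dim1)."""
    m, p = VH.shape
    n = VD.shape[0]
    if m + n < 3:
        raise ValueError("need at least 3 anchor samples in total")
    if d < 1:
        raise ValueError("embedding dimension d must be >= 1")
    if d > p:
        raise ValueError(f"d={d} exceeds number of features p={p}")

    Xall = np.vstack([VH, VD])
    W = sample_adjacency(Xall, mode=weight_mode)
    L, _ = laplacian(W)
    Sigma = Xall.T @ L @ Xall
    Sigma = 0.5 * (Sigma + Sigma.T)

    if epsilon is None:
        tr = float(np.trace(Sigma))
        epsilon = 1e-6 * tr / p if tr > 0 else 1e-6

    diff = VD.mean(axis=0) - VH.mean(axis=0)
    scale = max(np.abs(VH).max(initial=0.0), np.abs(VD).max(initial=0.0), 1.0)
    if np.linalg.norm(diff) <= 1e-12 * scale:
        raise DegenerateManifoldError(
            "background and target group means coincide (B = 0); "
            "the manifold direction is undefined"
        )

    A = Sigma + epsilon * np.eye(p)
    try:
        cho = linalg.cho_factor(A)
        c1 = linalg.cho_solve(cho, diff)
    except linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            f"scatter matrix numerically singular (epsilon={epsilon:g}); "
            "increase the ridge epsilon"
        ) from e
    nrm = np.linalg.norm(c1)
    if not np.isfinite(nrm) or nrm == 0:
        raise np.linalg.LinAlgError(
            f"scatter matrix numerically singular (epsilon={epsilon:g}); "
            "increase the ridge epsilon"
        )
    c1 = _fix_sign(c1 / nrm)
    ratio = float((c1 @ np.outer(diff, diff) @ c1) / (c1 @ A @ c1))

    cols = [c1]
    if d > 1:
        # Remaining axes: smallest-eigenvalue directions of Sigma on the
        # orthogonal complement of c1 (Laplacian-eigenmap axes).
        Q = linalg.null_space(c1[None, :])
        Sq = Q.T @ Sigma @ Q
        Sq = 0.5 * (Sq + Sq.T)
        evals, evecs = linalg.eigh(Sq)
        for j in range(d - 1):
            v = Q @ evecs[:, j]
            v = _fix_sign(v / np.linalg.norm(v))
            cols.append(v)
    C = np.column_stack(cols)
    return C, float(epsilon), ratio


# ---------------------------------------------------------------------------
# scores
# ---------------------------------------------------------------------------

@dataclass
class VScores:
    """Per-sample phenotypic-state scores.

    ``v_raw`` is the first embedding coordinate (the raw V score);
    ``v_neg`` is the oriented -V (larger = closer to the target phenotype);
    ``v_neg_scaled`` rescales ``v_neg`` to [0, 1] over the anchor samples,
    so later samples may fall outside the unit interval.
    """

    sample_ids: list[str]
    v_raw: np.ndarray
    v_neg: np.ndarray
    v_neg_scaled: np.ndarray
    extra_dims: np.ndarray | None = None
    stage_labels: list[str] | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "v_raw": self.v_raw,
                "v_neg": self.v_neg,
                "v_neg_scaled": self.v_neg_scaled,
            },
            index=pd.Index(self.sample_ids, name="sample_id"),
        )
        if self.extra_dims is not None and self.extra_dims.shape[1] > 0:
            for j in range(self.extra_dims.shape[1]):
                df[f"dim{j + 2}"] = self.extra_dims[:, j]
        if self.stage_labels is not None:
            df["stage"] = self.stage_labels
        return df


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class HealthManifold:
    """Discriminant Laplacian-eigenmap model of the health process.

    Parameters
    ----------
    X : ExpressionMatrix
        Cohort expression data (samples x features); must contain every
        sample named in ``design``.
    design : CohortDesign
        Background (optimal-phenotype) and target (worst-phenotype) anchors,
        plus optional held-out test samples.
    d : int
        Embedding dimension (the V score is always dimension 1).
    epsilon : float, optional
        Ridge added to the Laplacian scatter ``S = X'LX``; defaults to
        ``1e-6 * trace(S)/p``, which keeps the solve well-posed when p
        exceeds the anchor-sample count (the usual omics regime).
    weight_mode : {'clamp', 'abs'}
        How negative sample correlations enter the adjacency.
    """

    def __init__(
        self,
        X: ExpressionMatrix,
        design: CohortDesign,
        d: int = 1,
        epsilon: float | None = None,
        weight_mode: str = "clamp",
    ) -> None:
        design.validate_against(X)
        self.X = X
        self.design = design
        self.d = int(d)
        self.epsilon = epsilon
        self.weight_mode = weight_mode

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        background: list[str],
        target: list[str],
        test: list[str] | None = None,
        **kwargs,
    ) -> "HealthManifold":
        X = ExpressionMatrix.from_frame(df)
        return cls(X, CohortDesign(background, target, test or []), **kwargs)

    def fit(self) -> "ManifoldResults":
        XH = self.X.take_samples(self.design.background_ids)
        XD = self.X.take_samples(self.design.target_ids)
        C, eps, ratio = _solve_projection(
            XH.values, XD.values, self.d, self.epsilon, self.weight_mode
        )
        res = ManifoldResults(
            model=self,
            C=C,
            feature_ids=list(self.X.feature_ids),
            d=self.d,
            epsilon=eps,
            trace_ratio=ratio,
        )
        res._set_anchors(self.X, self.design)
        return res


@dataclass
class ManifoldResults:
    """Fitted manifold: projection matrix plus orientation/scaling anchors."""

    model: HealthManifold | None
    C: np.ndarray
    feature_ids: list[str]
    d: int
    epsilon: float
    trace_ratio: float
    orientation_sign: float = 1.0
    anchor_min: float = 0.0
    anchor_max: float = 1.0
    anchor_background_mean: float = 0.0
    anchor_target_mean: float = 1.0

    def _raw_scores(self, X: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray]:
        lookup = {f: i for i, f in enumerate(X.feature_ids)}
        missing = [f for f in self.feature_ids if f not in lookup]
        if missing:
            raise ValueError(f"matrix lacks model features: {missing[:10]}")
        idx = np.array([lookup[f] for f in self.feature_ids], dtype=int)
        Y = X.values[:, idx] @ self.C
        return Y[:, 0], Y[:, 1:]

    def _set_anchors(self, X: ExpressionMatrix, design: CohortDesign) -> None:
        """Fix orientation so -V is larger for the target group, then min-max
        anchors over all scored samples (the whole fitting matrix)."""
        v_raw, _ = self._raw_scores(X)
        bg = X.sample_index(design.background_ids)
        tg = X.sample_index(design.target_ids)
        if np.ptp(v_raw) <= 1e-15 * max(1.0, np.abs(v_raw).max()):
            raise DegenerateManifoldError("all raw V scores identical; cannot orient/scale")
        # v_neg = -orientation_sign * v_raw; choose sign so target mean > background mean
        self.orientation_sign = 1.0 if (-v_raw[tg]).mean() > (-v_raw[bg]).mean() else -1.0
        v_neg = -self.orientation_sign * v_raw
        self.anchor_min = float(v_neg.min())
        self.anchor_max = float(v_neg.max())
        span = self.anchor_max - self.anchor_min
        self.anchor_background_mean = float((v_neg[bg].mean() - self.anchor_min) / span)
        self.anchor_target_mean = float((v_neg[tg].mean() - self.anchor_min) / span)

    def predict(self, X: ExpressionMatrix) -> VScores:
        """Score samples on the fitted manifold (anchors are *not* refitted,
        so out-of-range samples may score outside [0, 1])."""
        v_raw, extra = self._raw_scores(X)
        v_neg = -self.orientation_sign * v_raw
        span = self.anchor_max - self.anchor_min
        scaled = (v_neg - self.anchor_min) / span
        return VScores(
            list(X.sample_ids), v_raw, v_neg, scaled, extra,
            list(X.stage_labels) if X.stage_labels else None,
        )

    # statsmodels-flavoured alias
    score = predict

    def summary(self) -> str:
        model = self.model
        lines = [
            "Health process manifold (discriminant Laplacian eigenmap)",
            "=" * 58,
            f"features (p):          {len(self.feature_ids)}",
            f"embedding dim (d):     {self.d}",
            f"ridge epsilon:         {self.epsilon:.3e}",
            f"trace ratio (dim 1):   {self.trace_ratio:.4g}",
            f"orientation sign:      {self.orientation_sign:+.0f}",
            f"-V anchors [min,max]:  [{self.anchor_min:.4g}, {self.anchor_max:.4g}]",
            f"scaled bg/target mean: {self.anchor_background_mean:.3f} / "
            f"{self.anchor_target_mean:.3f}",
        ]
        if model is not None:
            lines.insert(2, f"background / target n: {len(model.design.background_ids)}"
                            f" / {len(model.design.target_ids)}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "feature_ids": self.feature_ids,
            "C": self.C.tolist(),
            "d": self.d,
            "epsilon": self.epsilon,
            "trace_ratio": self.trace_ratio,
            "orientation_sign": self.orientation_sign,
            "anchors": {
                "min": self.anchor_min,
                "max": self.anchor_max,
                "background_mean": self.anchor_background_mean,
                "target_mean": self.anchor_target_mean,
            },
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "ManifoldResults":
        a = payload["anchors"]
        return cls(
            model=None,
            C=np.asarray(payload["C"], dtype=float),
            feature_ids=list(payload["feature_ids"]),
            d=int(payload["d"]),
            epsilon=float(payload["epsilon"]),
            trace_ratio=float(payload["trace_ratio"]),
            orientation_sign=float(payload["orientation_sign"]),
            anchor_min=float(a["min"]),
            anchor_max=float(a["max"]),
            anchor_background_mean=float(a["background_mean"]),
            anchor_target_mean=float(a["target_mean"]),
        )


def fit_manifold(
    XH: ExpressionMatrix,
    XD: ExpressionMatrix,
    d: int = 1,
    epsilon: float | None = None,
    weight_mode: str = "clamp",
) -> ManifoldResults:
    """Functional form of the fit: build the model from separate background
    and target matrices and return the fitted results (anchors included)."""
    if XH.feature_ids != XD.feature_ids:
        raise ValueError("background and target groups have mismatched features")
    values = np.vstack([XH.values, XD.values])
    ids = list(XH.sample_ids) + list(XD.sample_ids)
    stages = None
    if XH.stage_labels and XD.stage_labels:
        stages = list(XH.stage_labels) + list(XD.stage_labels)
    X = ExpressionMatrix(values, ids, list(XH.feature_ids), stages)
    design = CohortDesign(list(XH.sample_ids), list(XD.sample_ids))
    return HealthManifold(X, design, d=d, epsilon=epsilon, weight_mode=weight_mode).fit()


# ---------------------------------------------------------------------------
# tenfold feature-stability filter
# ---------------------------------------------------------------------------

@dataclass
class FeatureStability:
    """Per-feature loading stability across cross-validation folds.

    ``cv`` is sd/|mean| of the per-fold first-axis loadings (sign-aligned
    first); small cv marks a stable feature.  ``kept`` flags the features in
    the lowest ``retain_fraction`` quantile of cv (ties kept).
    """

    feature_ids: list[str]
    coefficients: np.ndarray  # folds x p
    cv: np.ndarray
    kept: np.ndarray
    retain_fraction: float

    @property
    def kept_ids(self) -> list[str]:
        return [f for f, k in zip(self.feature_ids, self.kept) if k]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cv": self.cv, "kept": self.kept},
            index=pd.Index(self.feature_ids, name="feature_id"),
        )


def cv_feature_selection(
    X: ExpressionMatrix,
    design: CohortDesign,
    folds: int = 10,
    retain_fraction: float = 0.70,
    seed: int = 0,
    epsilon: float | None = None,
    weight_mode: str = "clamp",
) -> FeatureStability:
    """Stability-filter features by the coefficient of variation of their
    discriminant loadings across stratified cross-validation folds.

    Each fold refits the manifold on 9/10 of the anchor samples and records
    the first-axis loading of every feature.  Eigenvector sign is arbitrary
    per fold, so fold vectors are first flipped into positive correlation
    with the fold-average vector; then cv = sd/|mean| per feature (|mean|
    floored at 1e-12; floored features get cv = +inf and are dropped).
    """
    if folds < 2:
        raise ValueError("need at least 2 folds")
    design.validate_against(X)
    bg = list(design.background_ids)
    tg = list(design.target_ids)
    ids = bg + tg
    labels = np.array([0] * len(bg) + [1] * len(tg))
    values = X.take_samples(ids).values
    p = X.n_features

    min_group = min(len(bg), len(tg))
    eff_folds = min(folds, min_group)
    if eff_folds < folds:
        warnings.warn(
            f"smallest group has {min_group} samples; using {eff_folds} folds",
            stacklevel=2,
        )
    if eff_folds < 2:
        raise ValueError("each group needs at least 2 samples for folding")

    skf = StratifiedKFold(n_splits=eff_folds, shuffle=True, random_state=seed)
    coeffs = np.zeros((eff_folds, p))
    for i, (train, _test) in enumerate(skf.split(values, labels)):
        VH = values[train][labels[train] == 0]
        VD = values[train][labels[train] == 1]
        C, _, _ = _solve_projection(VH, VD, 1, epsilon, weight_mode)
        coeffs[i] = C[:, 0]

    # sign-align folds to the fold-average vector (one pass)
    ref = coeffs.mean(axis=0)
    if np.linalg.norm(ref) < 1e-12:
        ref = coeffs[0]
    flips = np.where(coeffs @ ref < 0, -1.0, 1.0)
    coeffs = coeffs * flips[:, None]

    mean = coeffs.mean(axis=0)
    sd = coeffs.std(axis=0, ddof=1)
    denom = np.abs(mean)
    cv = np.where(denom > 1e-12, sd / np.maximum(denom, 1e-12), np.inf)

    if retain_fraction >= 1.0:
        kept = np.ones(p, dtype=bool)
    else:
        finite = cv[np.isfinite(cv)]
        if finite.size == 0:
            raise ValueError("all features have degenerate loadings; nothing to keep")
        thr = np.quantile(finite, retain_fraction)
        kept = cv <= thr
    return FeatureStability(list(X.feature_ids), coeffs, cv, kept, retain_fraction)


# ---------------------------------------------------------------------------
# combining several V axes
# ---------------------------------------------------------------------------

def combine_v_axes(axis_scores: list[VScores]) -> np.ndarray:
    """Combine several per-axis V scorings (e.g. metabolite classes) into one
    score via the first principal component of the stacked oriented -V values,
    oriented to correlate positively with the mean of the input axes (so the
    target-high convention is preserved)."""
    if len(axis_scores) < 2:
        raise ValueError("need at least 2 axes to combine")
    ids0 = axis_scores[0].sample_ids
    for vs in axis_scores[1:]:
        if vs.sample_ids != ids0:
            raise ValueError("axes score different sample sets")
    M = np.column_stack([vs.v_neg for vs in axis_scores])
    Mc = M - M.mean(axis=0)
    cov = np.cov(Mc, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    pc1 = evecs[:, -1]
    scores = Mc @ pc1
    axis_mean = Mc.mean(axis=1)
    dot = scores @ axis_mean
    if abs(dot) < 1e-12 * max(1.0, np.abs(scores).max()):
        dot = scores @ Mc[:, 0]  # axes cancel exactly; orient against axis 1
    if dot < 0:
        scores = -scores
    return scores


# small helper used by tests/demos: raw trace-ratio objective of a direction
def trace_ratio_objective(c: np.ndarray, B: np.ndarray, Sigma: np.ndarray) -> float:
    c = np.asarray(c, float)
    denom = float(c @ Sigma @ c)
    if denom <= 0:
        return -np.inf
    return float(c @ B @ c) / denom
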