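"""Homeostatic potential U: curvature of per-gene local potential landscapes.

A unit (an individual with repeated measurements, or a cohort stage with >=3
samples) is scored as follows.  A coexpression network is built from the
unit's samples (|PCC| above a threshold and correlation-test p below a
threshold).  For every feature, the feature plus its first-order neighbours
form a local module; the module's samples are projected onto their first two
principal components, a bivariate Gaussian is fitted there, and the local
potential landscape is U(x) = -log P(x).  The Hessian of a Gaussian -log
density is the constant matrix Sigma^-1, so the minimum principal curvature
at the mean is analytically 1/lambda_max(Sigma) = 1/var(PC1).  The unit's
global U score is the mean of the k smallest local curvatures: a unit whose
dominant modules have inflated, tightly correlated variation (the dynamic-
network-biomarker signature of an approaching tipping point) gets a low U.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._correlation import pearson_matrix, pearson_pvalues
from .data import ExpressionMatrix

__all__ = [
    "LocalModule",
    "LocalPotential",
    "GlobalU",
    "HomeostaticPotential",
    "PotentialResults",
    "feature_network",
    "local_module",
    "local_potential",
    "global_u",
    "score_cohort_u",
]


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def feature_network(
    X: ExpressionMatrix | np.ndarray,
    pcc_threshold: float = 0.7,
    p_threshold: float = 0.01,
) -> np.ndarray:
    """Boolean feature-feature adjacency: edge iff |PCC| > pcc_threshold and
    the two-sided correlation-test p-value < p_threshold.  Needs >=3 samples
    (the p-value is undefined below that)."""
    values = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, float)
    n = values.shape[0]
    if n < 3:
        raise ValueError("feature network needs at least 3 samples")
    r = pearson_matrix(values)
    p = pearson_pvalues(r, n)
    adj = (np.abs(r) > pcc_threshold) & (p < p_threshold)
    np.fill_diagonal(adj, False)
    return adj


@dataclass
class LocalModule:
    """A feature plus its first-order coexpression neighbours."""

    center_feature: str
    neighbor_ids: list[str]
    data: np.ndarray  # samples x (1 + n_neighbors), center column first

    def __post_init__(self) -> None:
        if self.center_feature in self.neighbor_ids:
            raise ValueError("center feature cannot be its own neighbor")
        if self.data.shape[1] != 1 + len(self.neighbor_ids):
            raise ValueError("module data width mismatch")
        if self.data.shape[1] < 2:
            raise ValueError("local module needs at least 2 columns")


def local_module(
    adj: np.ndarray,
    X: ExpressionMatrix,
    center: str,
) -> LocalModule:
    """Extract the local module of ``center``: the feature plus its network
    neighbours in sorted-ID order.  An isolated feature is paired with its
    single highest-|PCC| partner so a bivariate fit is always possible."""
    try:
        ci = X.feature_ids.index(center)
    except ValueError:
        raise KeyError(f"unknown feature {center!r}") from None
    nbr = np.flatnonzero(adj[ci])
    if nbr.size == 0:
        best = np.abs(pearson_matrix(X.values)[ci])
        best[ci] = -np.inf
        # ties resolved toward the smallest feature ID for determinism
        order = sorted(range(len(best)), key=lambda j: (-best[j], X.feature_ids[j]))
        nbr = np.array([order[0]])
    ids = sorted(X.feature_ids[j] for j in nbr)
    idx = [ci] + [X.feature_ids.index(f) for f in ids]
    return LocalModule(center, ids, X.values[:, idx])


@dataclass
class LocalPotential:
    """Minimum principal curvature of one feature's local landscape."""

    center_feature: str
    lambda_min: float
    module_size: int
    pc_variances: tuple[float, float]


def local_potential(module: LocalModule, jitter: bool = False) -> LocalPotential:
    """Fit the bivariate Gaussian landscape on the module's first two
    principal components and return its minimum principal curvature.

    For a Gaussian, Hessian(-log pdf) = Sigma^-1 everywhere, so the minimum
    curvature equals 1/var(PC1) exactly; the PC variances are the two leading
    eigenvalues of the module's sample covariance.
    """
    V = module.data
    n, q = V.shape
    if n < 3:
        raise ValueError("local potential needs at least 3 samples")
    cov = np.cov(V, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    evals = np.linalg.eigvalsh(cov)[::-1]  # descending
    l1 = float(evals[0])
    l2 = float(evals[1]) if len(evals) > 1 else 0.0
    if l2 <= 1e-12:
        if not jitter:
            raise ValueError(
                f"singular local covariance for {module.center_feature!r} "
                "(identical samples?); pass jitter=True to regularise"
            )
        l1 += 1e-10
        l2 += 1e-10
    # Sigma_loc of the PC1/PC2 scores is diag(l1, l2); min eig of its inverse:
    return LocalPotential(module.center_feature, 1.0 / l1, q, (l1, l2))


@dataclass
class GlobalU:
    """Global homeostatic potential of one unit: mean of the k smallest
    local curvatures (ascending sort, ties broken by feature ID)."""

    unit_id: str
    u_score: float
    k: int
    n_samples: int
    local_scores: pd.Series  # lambda_min per feature, ascending


def global_u(locals_: list[LocalPotential], k: int = 20, unit_id: str = "unit",
             n_samples: int = 0) -> GlobalU:
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(locals_):
        raise ValueError(f"k={k} exceeds number of features ({len(locals_)})")
    order = sorted(locals_, key=lambda lp: (lp.lambda_min, lp.center_feature))
    series = pd.Series(
        [lp.lambda_min for lp in order],
        index=[lp.center_feature for lp in order],
        name="lambda_min",
    )
    u = float(series.iloc[:k].mean())
    return GlobalU(unit_id, u, k, n_samples, series)


def _score_unit(
    X: ExpressionMatrix,
    unit_id: str,
    k: int,
    pcc_threshold: float,
    p_threshold: float,
    jitter: bool,
) -> GlobalU:
    adj = feature_network(X, pcc_threshold, p_threshold)
    locals_ = [
        local_potential(local_module(adj, X, f), jitter=jitter)
        for f in X.feature_ids
    ]
    return global_u(locals_, k=min(k, X.n_features), unit_id=unit_id,
                    n_samples=X.n_samples)


def score_cohort_u(
    X: ExpressionMatrix,
    unit_labels: list[str] | None = None,
    k: int = 20,
    pcc_threshold: float = 0.7,
    p_threshold: float = 0.01,
    jitter: bool = False,
) -> tuple[list[GlobalU], list[str]]:
    """Score every unit (group of samples sharing a label) independently:
    network, modules, curvature and global U are all computed from the unit's
    own samples.  Units with fewer than 3 samples are skipped with a warning;
    their labels are returned in the second element."""
    labels = unit_labels if unit_labels is not None else X.stage_labels
    if labels is None:
        labels = ["all"] * X.n_samples
    if len(labels) != X.n_samples:
        raise ValueError("unit_labels length must equal number of samples")
    results: list[GlobalU] = []
    skipped: list[str] = []
    for unit in sorted(set(labels), key=lambda u: (labels.index(u))):
        ids = [s for s, l in zip(X.sample_ids, labels) if l == unit]
        if len(ids) < 3:
            warnings.warn(
                f"unit {unit!r} has {len(ids)} samples (<3); skipped", stacklevel=2
            )
            skipped.append(unit)
            continue
        results.append(
            _score_unit(X.take_samples(ids), unit, k, pcc_threshold, p_threshold, jitter)
        )
    return results, skipped


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class HomeostaticPotential:
    """Model object: homeostatic-potential scoring of a cohort split into
    units (individuals or stages with repeated samples).

    Parameters
    ----------
    X : ExpressionMatrix
    units : list of str, optional
        Per-sample unit labels; defaults to ``X.stage_labels`` and, failing
        that, a single unit containing every sample.
    k : int
        Number of lowest-curvature features averaged into the global U score
        (capped at the feature count at scoring time).
    pcc_threshold, p_threshold : float
        Coexpression-network edge thresholds used for the local modules.
    """

    def __init__(
        self,
        X: ExpressionMatrix,
        units: list[str] | None = None,
        k: int = 20,
        pcc_threshold: float = 0.7,
        p_threshold: float = 0.01,
        jitter: bool = False,
    ) -> None:
        self.X = X
        self.units = units
        self.k = int(k)
        self.pcc_threshold = float(pcc_threshold)
        self.p_threshold = float(p_threshold)
        self.jitter = bool(jitter)
        if self.k <= 0:
            raise ValueError("k must be positive")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, units: list[str] | None = None,
                       **kwargs) -> "HomeostaticPotential":
        return cls(ExpressionMatrix.from_frame(df), units=units, **kwargs)

    def fit(self) -> "PotentialResults":
        scores, skipped = score_cohort_u(
            self.X, self.units, self.k, self.pcc_threshold, self.p_threshold,
            self.jitter,
        )
        return PotentialResults(self, scores, skipped)


class PotentialResults:
    """Per-unit global U scores plus the full local-curvature landscapes."""

    def __init__(self, model: HomeostaticPotential, scores: list[GlobalU],
                 skipped: list[str]) -> None:
        self.model = model
        self.unit_scores = {g.unit_id: g for g in scores}
        self.skipped_units = skipped

    def u_table(self) -> pd.DataFrame:
        rows = [
            {"unit_id": g.unit_id, "u_score": g.u_score, "k": g.k,
             "n_samples": g.n_samples}
            for g in self.unit_scores.values()
        ]
        return pd.DataFrame(rows).set_index("unit_id")

    def local_table(self) -> pd.DataFrame:
        frames = {u: g.local_scores for u, g in self.unit_scores.items()}
        return pd.DataFrame(frames)

    def summary(self) -> str:
        m = self.model
        lines = [
            "Homeostatic potential (local-landscape minimum curvature)",
            "=" * 57,
            f"features:         {m.X.n_features}",
            f"k (lowest curvatures averaged): {min(m.k, m.X.n_features)}",
            f"network edge rule: |PCC| > {m.pcc_threshold}, p < {m.p_threshold}",
            "",
            self.u_table().to_string(),
        ]
        if self.skipped_units:
            lines.append(f"skipped units (<3 samples): {self.skipped_units}")
        return "\n".join(lines)
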