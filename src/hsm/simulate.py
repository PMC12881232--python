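"""Synthetic cohorts with the statistical structure the scores assume.

Two generators:

* :func:`simulate_unit` draws one multi-sample unit whose designated module
  features follow an equicorrelated multivariate normal.  In the *stable*
  regime the module has correlation ``rho_stable`` and unit marginal
  variance; in the *critical* regime the correlation rises to
  ``rho_critical`` and the marginal variance is multiplied by
  ``var_inflation`` -- the dynamic-network-biomarker signature of a system
  approaching a tipping point.  Non-module features are independent noise.

* :func:`simulate_health_trajectory` stacks several such units into a staged
  cohort whose mean drifts along a fixed sparse signal direction (the module
  features) from a background phenotype (stage 0) to a target phenotype
  (last stage), the setting the manifold V score is designed to recover.

:func:`evaluate_u_accuracy` is the validation harness: it repeatedly draws a
stable and a critical unit, scores both with the global U, and reports the
fraction of replicate pairs in which the critical unit scores lower.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .data import CohortDesign, ExpressionMatrix
from .potential import _score_unit

__all__ = [
    "SimConfig",
    "simulate_unit",
    "simulate_health_trajectory",
    "trajectory_design",
    "evaluate_u_accuracy",
]


@dataclass
class SimConfig:
    """Generator settings; the defaults are the package's frozen reference
    condition (a moderate tipping-point effect; see docs/methods.md).

    drift is the per-stage mean shift of the module features in marginal-sd
    units; rho_* are within-module equicorrelations; var_inflation multiplies
    the module's marginal variance in the critical regime.
    """

    n_features: int = 50
    module_size: int = 10
    n_samples_per_unit: int = 10
    n_stages: int = 4
    drift: float = 1.0
    rho_stable: float = 0.2
    rho_critical: float = 0.6
    var_inflation: float = 3.2
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.rho_stable < self.rho_critical < 1):
            raise ValueError("need 0 <= rho_stable < rho_critical < 1")
        if self.var_inflation < 1:
            raise ValueError("var_inflation must be >= 1")
        if self.module_size > self.n_features:
            raise ValueError("module_size cannot exceed n_features")
        if self.module_size < 2:
            raise ValueError("module_size must be >= 2")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


def _module_cholesky(q: int, rho: float, var: float) -> np.ndarray:
    """Cholesky factor of var * ((1-rho) I + rho J); PD for -1/(q-1)<rho<1."""
    S = var * ((1 - rho) * np.eye(q) + rho * np.ones((q, q)))
    try:
        return np.linalg.cholesky(S)
    except np.linalg.LinAlgError as e:
        raise ValueError(f"module covariance not positive definite (rho={rho})") from e


def _feature_ids(n: int) -> list[str]:
    return [f"g{j:04d}" for j in range(n)]


def simulate_unit(
    cfg: SimConfig,
    state: str = "stable",
    rng: np.random.Generator | None = None,
    sample_prefix: str = "s",
    stage_label: str | None = None,
) -> ExpressionMatrix:
    """One multi-sample unit: the first ``module_size`` features are the
    equicorrelated module, the rest independent N(0, noise_sd^2) noise."""
    if state not in ("stable", "critical"):
        raise ValueError(f"unknown state {state!r}")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    q, p, n = cfg.module_size, cfg.n_features, cfg.n_samples_per_unit
    rho = cfg.rho_stable if state == "stable" else cfg.rho_critical
    var = cfg.noise_sd**2 * (1.0 if state == "stable" else cfg.var_inflation)
    Lc = _module_cholesky(q, rho, var)
    values = np.empty((n, p))
    values[:, :q] = rng.standard_normal((n, q)) @ Lc.T
    values[:, q:] = cfg.noise_sd * rng.standard_normal((n, p - q))
    ids = [f"{sample_prefix}{i:03d}" for i in range(n)]
    stages = [stage_label] * n if stage_label is not None else None
    return ExpressionMatrix(values, ids, _feature_ids(p), stages)


def simulate_health_trajectory(
    cfg: SimConfig,
    states: list[str] | None = None,
    rng: np.random.Generator | None = None,
) -> ExpressionMatrix:
    """Staged cohort: stage s has its module-feature means shifted by
    ``s * drift`` (in marginal-sd units) along the sparse signal direction.
    ``states`` optionally assigns 'stable'/'critical' covariance per stage
    (default: all stable).  Stage 0 is the background phenotype, the last
    stage the target."""
    if cfg.n_stages < 2:
        raise ValueError("need at least 2 stages")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if states is None:
        states = ["stable"] * cfg.n_stages
    if len(states) != cfg.n_stages:
        raise ValueError("states must list one regime per stage")
    blocks, ids, stages = [], [], []
    for s in range(cfg.n_stages):
        unit = simulate_unit(cfg, states[s], rng=rng, sample_prefix=f"st{s}_")
        shifted = unit.values.copy()
        shifted[:, : cfg.module_size] += s * cfg.drift * cfg.noise_sd
        blocks.append(shifted)
        ids.extend(unit.sample_ids)
        stages.extend([f"stage_{s}"] * unit.n_samples)
    return ExpressionMatrix(np.vstack(blocks), ids, _feature_ids(cfg.n_features), stages)


def trajectory_design(X: ExpressionMatrix) -> CohortDesign:
    """Cohort design for a simulated trajectory: first stage = background,
    last stage = target, everything else = test."""
    if X.stage_labels is None:
        raise ValueError("matrix has no stage labels")
    stages = sorted(set(X.stage_labels))
    first, last = stages[0], stages[-1]
    bg = [s for s, st in zip(X.sample_ids, X.stage_labels) if st == first]
    tg = [s for s, st in zip(X.sample_ids, X.stage_labels) if st == last]
    other = [s for s, st in zip(X.sample_ids, X.stage_labels) if st not in (first, last)]
    return CohortDesign(bg, tg, other)


def evaluate_u_accuracy(
    cfg: SimConfig,
    n_samples: int = 3,
    reps: int = 500,
    seed: int = 0,
    k: int = 20,
    pcc_threshold: float = 0.7,
    p_threshold: float = 0.01,
    rule: str = "pairwise",
    u_threshold: float | None = None,
) -> float:
    """Accuracy of the global U score at separating critical from stable
    units, estimated over ``reps`` independently simulated unit pairs with
    ``n_samples`` samples each.

    ``rule='pairwise'`` (default) counts a success when U(critical) <
    U(stable); ``rule='threshold'`` classifies each unit against a fixed
    ``u_threshold`` and counts a success when both units are classified
    correctly.
    """
    if n_samples < 3:
        raise ValueError("U scoring needs at least 3 samples per unit")
    if reps < 1:
        raise ValueError("need at least 1 replicate")
    if rule not in ("pairwise", "threshold"):
        raise ValueError(f"unknown rule {rule!r}")
    if rule == "threshold" and u_threshold is None:
        raise ValueError("threshold rule needs u_threshold")
    rng = np.random.default_rng(seed)
    cfg_n = replace(cfg, n_samples_per_unit=n_samples)
    k_eff = min(k, cfg.n_features)
    successes = 0
    for _ in range(reps):
        stable = simulate_unit(cfg_n, "stable", rng=rng)
        critical = simulate_unit(cfg_n, "critical", rng=rng)
        u_s = _score_unit(stable, "stable", k_eff, pcc_threshold, p_threshold,
                          jitter=True).u_score
        u_c = _score_unit(critical, "critical", k_eff, pcc_threshold, p_threshold,
                          jitter=True).u_score
        if rule == "pairwise":
            successes += u_c < u_s
        else:
            successes += (u_c < u_threshold) and (u_s >= u_threshold)
    return successes / reps
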