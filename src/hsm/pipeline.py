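"""End-to-end HSM run: normalise, screen, fit V, score U, DNB report, plot.

The four pipeline steps are (1) load and z-score the expression table,
optionally restricting to a curated feature list; (2) optionally stability-
filter features by tenfold cross-validated discriminant loadings; (3) fit the
health process manifold and score every sample's V; (4) score every unit's
global U, compute the DNB report of the lowest-curvature gene set, and draw
the combined -V / -U scatter.  Outputs are TSV tables, a JSON model dump and
a PNG figure; a failed stage removes any partial outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import yaml

from .data import (
    CohortDesign,
    ExpressionMatrix,
    read_cohort_design,
    read_expression_tsv,
    read_feature_list,
    subset_features,
    zscore_normalize,
)
from .dnb import dnb_index
from .manifold import HealthManifold, cv_feature_selection
from .potential import HomeostaticPotential

log = logging.getLogger("hsm")

__all__ = ["RunConfig", "run_hsm", "plot_manifold"]


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    expression: Path
    design: Path
    out_dir: Path
    feature_list: Path | None = None
    units: Path | None = None  # YAML mapping unit -> sample IDs; default: design groups
    orientation: str = "samples-in-rows"
    d: int = 1
    cv_select: bool = False
    retain_fraction: float = 0.70
    folds: int = 10
    k: int = 20
    pcc_threshold: float = 0.7
    p_threshold: float = 0.01
    epsilon: float | None = None
    seed: int = 0
    zscore: bool = True
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in raw.items() if k in known}
        extra = {k: v for k, v in raw.items() if k not in known}
        for key in ("expression", "design", "out_dir", "feature_list", "units"):
            if kwargs.get(key) is not None:
                kwargs[key] = Path(kwargs[key])
        return cls(extra=extra, **kwargs)

    def validate(self) -> None:
        for key in ("expression", "design"):
            p = getattr(self, key)
            if not Path(p).exists():
                raise FileNotFoundError(f"{key} file not found: {p}")
        for key in ("feature_list", "units"):
            p = getattr(self, key)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{key} file not found: {p}")
        if self.d < 1:
            raise ValueError("d must be >= 1")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not (0 < self.retain_fraction <= 1):
            raise ValueError("retain_fraction must be in (0, 1]")
        if not (0 <= self.pcc_threshold <= 1):
            raise ValueError("pcc_threshold must be in [0, 1]")


def _load_units(path: Path, X: ExpressionMatrix) -> list[str]:
    mapping = yaml.safe_load(Path(path).read_text())
    labels = {}
    for unit, ids in mapping.items():
        for s in ids:
            labels[str(s)] = str(unit)
    missing = [s for s in X.sample_ids if s not in labels]
    if missing:
        raise ValueError(f"units file does not cover samples: {missing[:10]}")
    return [labels[s] for s in X.sample_ids]


def _design_units(design: CohortDesign, X: ExpressionMatrix) -> list[str]:
    label = {}
    for s in design.background_ids:
        label[s] = "background"
    for s in design.target_ids:
        label[s] = "target"
    for s in design.test_ids:
        label.setdefault(s, "test")
    return [label.get(s, "other") for s in X.sample_ids]


def plot_manifold(v_means: dict[str, float], u_scores: dict[str, float],
                  path: Path) -> None:
    """Scatter of per-unit mean -V (scaled) against -U; following the
    presentation convention, 'worse' is up and to the right."""
    units = sorted(set(v_means) & set(u_scores))
    fig, ax = plt.subplots(figsize=(5, 4))
    xs = [v_means[u] for u in units]
    ys = [-u_scores[u] for u in units]
    ax.scatter(xs, ys, c=range(len(units)), cmap="viridis", s=60, zorder=3)
    for u, x, y in zip(units, xs, ys):
        ax.annotate(u, (x, y), fontsize=8, xytext=(4, 4),
                    textcoords="offset points")
    ax.set_xlabel("-V (scaled phenotypic state)")
    ax.set_ylabel("-U (transition risk)")
    ax.set_title("Health state manifold")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def run_hsm(config: RunConfig) -> dict[str, Path]:
    """Execute the full pipeline; returns a name -> path map of outputs."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    stage = "setup"
    try:
        stage = "load"
        log.info("loading expression from %s", config.expression)
        X = read_expression_tsv(config.expression, orientation=config.orientation)
        design = read_cohort_design(config.design)
        design.validate_against(X)
        if config.k > X.n_features:
            raise ValueError(
                f"k={config.k} exceeds feature count {X.n_features}"
            )

        stage = "normalise"
        if config.feature_list is not None:
            keep = read_feature_list(config.feature_list)
            X, skipped = subset_features(X, keep)
            log.info("feature screen kept %d features (%d unknown IDs skipped)",
                     X.n_features, skipped)
        if config.zscore:
            X = zscore_normalize(X)

        stage = "cv-selection"
        if config.cv_select:
            stab = cv_feature_selection(
                X, design, folds=config.folds,
                retain_fraction=config.retain_fraction, seed=config.seed,
                epsilon=config.epsilon,
            )
            X, _ = subset_features(X, stab.kept_ids)
            path = out_dir / "feature_stability.tsv"
            stab.to_frame().to_csv(path, sep="\t")
            outputs["feature_stability"] = path
            log.info("CV stability filter kept %d/%d features",
                     len(stab.kept_ids), len(stab.feature_ids))

        stage = "fit-v"
        res = HealthManifold(X, design, d=config.d, epsilon=config.epsilon).fit()
        vs = res.predict(X)
        path = out_dir / "v_scores.tsv"
        vs.to_frame().to_csv(path, sep="\t", float_format="%.10g")
        outputs["v_scores"] = path
        path = out_dir / "manifold_model.json"
        path.write_text(json.dumps(res.to_dict(), indent=1))
        outputs["manifold_model"] = path

        stage = "score-u"
        if config.units is not None:
            unit_labels = _load_units(config.units, X)
        elif X.stage_labels is not None:
            unit_labels = list(X.stage_labels)
        else:
            unit_labels = _design_units(design, X)
        pot = HomeostaticPotential(
            X, units=unit_labels, k=config.k,
            pcc_threshold=config.pcc_threshold, p_threshold=config.p_threshold,
        ).fit()
        path = out_dir / "u_scores.tsv"
        pot.u_table().to_csv(path, sep="\t", float_format="%.10g")
        outputs["u_scores"] = path

        stage = "dnb"
        dnb_rows = []
        for unit, g in pot.unit_scores.items():
            gene_set = list(g.local_scores.index[: g.k])
            ids = [s for s, l in zip(X.sample_ids, unit_labels) if l == unit]
            d = dnb_index(X.take_samples(ids), gene_set, epsilon=1e-6)
            dnb_rows.append(
                {"unit_id": unit, "sd_in": d.sd_in, "pcc_in": d.pcc_in,
                 "pcc_out": d.pcc_out, "i_dnb": d.i_dnb}
            )
        import pandas as pd

        path = out_dir / "dnb.tsv"
        pd.DataFrame(dnb_rows).set_index("unit_id").to_csv(
            path, sep="\t", float_format="%.10g"
        )
        outputs["dnb"] = path

        stage = "plot"
        vframe = vs.to_frame()
        vframe["unit"] = unit_labels
        v_means = vframe.groupby("unit")["v_neg_scaled"].mean().to_dict()
        u_map = {u: g.u_score for u, g in pot.unit_scores.items()}
        path = out_dir / "manifold.png"
        plot_manifold(v_means, u_map, path)
        outputs["plot"] = path

        stage = "provenance"
        echo = {k: (str(v) if isinstance(v, Path) else v)
                for k, v in vars(config).items()}
        path = out_dir / "run_config.yaml"
        path.write_text(yaml.safe_dump(echo, sort_keys=True))
        outputs["config"] = path
    except Exception as e:
        for p in outputs.values():
            try:
                p.unlink()
            except OSError:
                pass
        raise RuntimeError(f"HSM pipeline failed at stage {stage!r}: {e}") from e
    return outputs
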