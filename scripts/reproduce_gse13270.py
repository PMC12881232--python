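#!/usr/bin/env python
"""Optional real-data reproduction on the GEO rat diabetes time course.

Requires network access: downloads the GSE13270 series matrix (liver
expression of Goto-Kakizaki vs Wistar-Kyoto rats at ages 4-20 weeks under
normal or high-fat diet), z-scores a user-supplied diabetes gene list,
fits the health process manifold with the 4-week WKY normal-diet group as
background and the 20-week GK high-fat group as target, and prints the
scaled -V group means plus the DNB report (PCC_in, edge count) of the
20 lowest-curvature genes at the 8-week GK normal-diet stage.

This script is illustrative: the curated gene list used in the original
analysis ships with that study's supplement and must be provided as a text
file (one gene symbol per line) via --gene-list.

Usage:
  python scripts/reproduce_gse13270.py --gene-list t2dm_genes.txt --out out/
"""

from __future__ import annotations

import argparse
import gzip
import io
import re
import urllib.request
from pathlib import Path

import numpy as np
import pandas as pd

from hsm.data import CohortDesign, ExpressionMatrix, read_feature_list, zscore_normalize, subset_features
from hsm.dnb import dnb_index, network_edges
from hsm.manifold import HealthManifold
from hsm.potential import HomeostaticPotential

MATRIX_URL = (
    "https://ftp.ncbi.nlm.nih.gov/geo/series/GSE13nnn/GSE13270/matrix/"
    "GSE13270_series_matrix.txt.gz"
)


def fetch_series_matrix(url: str = MATRIX_URL) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return (expression probes x samples, sample metadata)."""
    raw = urllib.request.urlopen(url, timeout=120).read()
    text = gzip.decompress(raw).decode("utf-8", errors="replace")
    meta_rows = {}
    table_lines = []
    in_table = False
    for line in text.splitlines():
        if line.startswith("!series_matrix_table_begin"):
            in_table = True
            continue
        if line.startswith("!series_matrix_table_end"):
            in_table = False
            continue
        if in_table:
            table_lines.append(line)
        elif line.startswith("!Sample_"):
            key, *vals = line.split("\t")
            meta_rows.setdefault(key.lstrip("!"), []).append(
                [v.strip('"') for v in vals]
            )
    expr = pd.read_csv(io.StringIO("\n".join(table_lines)), sep="\t", index_col=0)
    meta = pd.DataFrame(
        {k: v[0] for k, v in meta_rows.items() if len(v[0]) == expr.shape[1]}
    )
    meta.index = expr.columns
    return expr, meta


def parse_groups(meta: pd.DataFrame) -> pd.Series:
    """Group label '<strain>-<age>wk-<diet>' from sample titles."""
    title_col = next(c for c in meta.columns if "title" in c.lower())
    def label(t: str) -> str:
        strain = "GK" if re.search("GK", t, re.I) else "WKY"
        age = re.search(r"(\d+)\s*w", t, re.I)
        diet = "HFD" if re.search("high|HF", t, re.I) else "ND"
        return f"{strain}-{age.group(1) if age else '?'}wk-{diet}"
    return meta[title_col].map(label)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--gene-list", type=Path, required=True,
                    help="curated diabetes-associated gene symbols, one per line")
    ap.add_argument("--out", type=Path, default=Path("gse13270_out"))
    args = ap.parse_args()

    expr, meta = fetch_series_matrix()
    groups = parse_groups(meta)
    X = ExpressionMatrix(
        expr.to_numpy(dtype=float).T,
        list(expr.columns),
        list(expr.index.astype(str)),
        list(groups),
    )
    genes = read_feature_list(args.gene_list)
    X, skipped = subset_features(X, genes)
    print(f"{X.n_features} gene-list features matched ({skipped} absent)")
    X = zscore_normalize(X)

    def ids(g): return [s for s, l in zip(X.sample_ids, X.stage_labels) if l == g]

    design = CohortDesign(ids("WKY-4wk-ND"), ids("GK-20wk-HFD"))
    res = HealthManifold(X, design).fit()
    vs = res.predict(X).to_frame()
    vs["group"] = X.stage_labels
    v_means = vs.groupby("group")["v_neg_scaled"].mean().sort_values()
    print("\nScaled -V group means:")
    print(v_means.to_string())

    pot = HomeostaticPotential(X, units=list(X.stage_labels), k=20, jitter=True).fit()
    print("\nGlobal U per group:")
    print(pot.u_table().to_string())

    unit = "GK-8wk-ND"
    g = pot.unit_scores[unit]
    top20 = list(g.local_scores.index[:20])
    Xu = X.take_samples(ids(unit))
    d = dnb_index(Xu, top20, epsilon=1e-6)
    edges = network_edges(Xu, top20)
    print(f"\n{unit}: PCC_in={d.pcc_in:.3f}, edges among top 20 = {edges}")

    args.out.mkdir(parents=True, exist_ok=True)
    vs.to_csv(args.out / "v_scores.tsv", sep="\t")
    pot.u_table().to_csv(args.out / "u_scores.tsv", sep="\t")


if __name__ == "__main__":
    main()
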