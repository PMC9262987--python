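"""Linkage between DEMs and a chosen gene set (default: IL6, IL1B, TNF).

Builds the edge list behind a Sankey-style view: every validated
(miRNA, gene) interaction whose gene is in the set and whose miRNA is a
DEM in at least one condition, annotated with both conditions' fold
changes and significance. Edges where the miRNA is a DEM in only one
condition are still kept — the other side is simply flagged non-DEM
(the gray edges of such a plot). Rows with an absolute log2FC difference
of at least ``flag_threshold`` (default 1) between conditions are flagged,
and opposite significant directions are marked discordant.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ._util import normalize_mirna_id, round_half_up
from .countmatrix import ValidationError
from .dem import ContrastResult
from .enrichment import dedupe_pairs

#: canonical inflammatory trio, HGNC symbols
DEFAULT_GENE_SET = ("IL6", "IL1B", "TNF")

#: notation variants seen in the literature, mapped to HGNC symbols
GENE_ALIASES = {
    "IL-6": "IL6",
    "IL6": "IL6",
    "IL-1B": "IL1B",
    "IL-1β": "IL1B",
    "IL1β": "IL1B",
    "IL1B": "IL1B",
    "TNF-α": "TNF",
    "TNFα": "TNF",
    "TNF-A": "TNF",
    "TNFA": "TNF",
    "TNF": "TNF",
}

LINKAGE_COLUMNS = [
    "mirna_id", "gene_id", "log2fc_lean", "q_lean", "log2fc_obese", "q_obese",
    "dem_lean", "dem_obese", "direction_lean", "direction_obese",
    "abs_fc_diff", "flagged", "discordant",
]


def canonical_gene(gene: str) -> str:
    g = gene.strip()
    return GENE_ALIASES.get(g.upper(), GENE_ALIASES.get(g, g))


def build_linkage(lean: ContrastResult, obese: ContrastResult,
                  pairs: pd.DataFrame, gene_set=DEFAULT_GENE_SET,
                  flag_threshold: float = 1.0,
                  q_threshold: float = 0.01) -> pd.DataFrame:
    """One row per (miRNA, gene) edge into the gene set.

    A miRNA enters when it is a DEM (Q < q_threshold) in at least one of
    the two contrasts; both conditions' statistics are carried on every
    row. An empty result (gene set absent from the pair table, or no DEM
    targets it) is returned with a warning, not an error.
    """
    gene_set = {canonical_gene(g) for g in gene_set}
    if not gene_set:
        raise ValidationError("gene_set must be non-empty")
    if set(lean.table.index) != set(obese.table.index):
        raise ValidationError("contrasts cover different miRNA universes")

    pairs = dedupe_pairs(pairs)
    gene_col = pairs["Target Gene"].astype(str).map(canonical_gene)
    sub = pairs[gene_col.isin(gene_set)].assign(
        _gene=gene_col[gene_col.isin(gene_set)]
    )
    key_to_id = {normalize_mirna_id(m): m for m in lean.table.index}

    dem_l = set(map(normalize_mirna_id, lean.dem_ids()))
    dem_o = set(map(normalize_mirna_id, obese.dem_ids()))

    rows = []
    for _, pr in sub.iterrows():
        key = normalize_mirna_id(str(pr["miRNA"]))
        if key not in key_to_id:
            continue
        if key not in dem_l and key not in dem_o:
            continue
        mid = key_to_id[key]
        fc_l = float(lean.table.at[mid, "log2fc"])
        fc_o = float(obese.table.at[mid, "log2fc"])
        q_l = float(lean.table.at[mid, "qvalue"])
        q_o = float(obese.table.at[mid, "qvalue"])
        d_l = str(lean.table.at[mid, "direction"])
        d_o = str(obese.table.at[mid, "direction"])
        diff = abs(fc_l - fc_o)
        rows.append({
            "mirna_id": mid,
            "gene_id": pr["_gene"],
            "log2fc_lean": fc_l,
            "q_lean": q_l,
            "log2fc_obese": fc_o,
            "q_obese": q_o,
            "dem_lean": key in dem_l,
            "dem_obese": key in dem_o,
            "direction_lean": d_l,
            "direction_obese": d_o,
            "abs_fc_diff": diff,
            "flagged": diff >= flag_threshold,
            "discordant": (fc_l != 0 and fc_o != 0 and np.sign(fc_l) != np.sign(fc_o)
                           and d_l != "none" and d_o != "none"),
        })
    if not rows:
        warnings.warn("no DEM targets the requested gene set", stacklevel=2)
        return pd.DataFrame(columns=LINKAGE_COLUMNS)
    return pd.DataFrame(rows, columns=LINKAGE_COLUMNS)


def tally_directions(rows: pd.DataFrame) -> dict:
    """Distinct-miRNA direction tallies per condition.

    A miRNA targeting several genes in the set counts once. Reports, for
    each condition, the up/down counts among distinct linked miRNAs, the
    down percentage (raw and rounded half-up), and per-gene miRNA counts.
    """
    if rows is None or len(rows) == 0:
        return {
            "n_mirnas_distinct": 0,
            "lean": {"n_up": 0, "n_down": 0, "pct_down": 0, "pct_down_raw": 0.0},
            "obese": {"n_up": 0, "n_down": 0, "pct_down": 0, "pct_down_raw": 0.0},
            "per_gene_mirna_counts": {},
        }
    dedup = rows.drop_duplicates(subset=["mirna_id", "gene_id"])
    per_mirna = dedup.drop_duplicates(subset=["mirna_id"])
    n = len(per_mirna)
    out = {"n_mirnas_distinct": n, "per_gene_mirna_counts":
           dedup.groupby("gene_id")["mirna_id"].nunique().to_dict()}
    for cond in ("lean", "obese"):
        d = per_mirna[f"direction_{cond}"]
        n_down = int((d == "down").sum())
        n_up = int((d == "up").sum())
        pct_raw = 100.0 * n_down / n if n else 0.0
        out[cond] = {
            "n_up": n_up,
            "n_down": n_down,
            "pct_down": round_half_up(pct_raw),
            "pct_down_raw": pct_raw,
        }
    return out


def sankey_edges(rows: pd.DataFrame) -> pd.DataFrame:
    """Sankey-ready edge list: source miRNA, target gene, unit value, and
    a color class per condition (up/down/none + dem/non_dem)."""
    if len(rows) == 0:
        return pd.DataFrame(columns=["source", "target", "value",
                                     "class_lean", "class_obese"])
    def cls(direction, is_dem):
        return f"{direction}_{'dem' if is_dem else 'non_dem'}"
    return pd.DataFrame({
        "source": rows["mirna_id"],
        "target": rows["gene_id"],
        "value": 1,
        "class_lean": [cls(d, s) for d, s in
                       zip(rows["direction_lean"], rows["dem_lean"])],
        "class_obese": [cls(d, s) for d, s in
                        zip(rows["direction_obese"], rows["dem_obese"])],
    })
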