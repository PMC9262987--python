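"""DEM category algebra across the lean and obese contrasts.

A miRNA significant (Q < q_sig) in both L_Ag and O_Ag is a *common* DEM;
one significant in a single contrast is *condition-specific* only when the
other contrast is clearly non-significant (Q >= q_ns). The dual-threshold
definition leaves a gap: significant in one contrast with the other's Q in
[q_sig, q_ns) is neither common nor specific — those miRNAs get an
explicit *indeterminate* category so the five categories always partition
the miRNA universe.

Common DEMs are further split by which condition carries the larger
fold-change magnitude ("strong" categories) and summarized by the
concordance of their per-condition log2FCs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._util import round_half_up
from .countmatrix import ValidationError
from .dem import ContrastResult

CATEGORIES = ("common", "lean_specific", "obese_specific", "indeterminate", "non_dem")
STRONG_LABELS = (
    "Lean_Strong_Up", "Lean_Strong_Down",
    "Obese_Strong_Up", "Obese_Strong_Down",
    "Tie", "discordant",
)


@dataclass
class ConcordanceStats:
    """Concordance of common-DEM log2FCs between the two conditions:
    Pearson r, the OLS fit of obese FC on lean FC, and how the points fall
    around the y = x equality line, split by shared direction."""

    n_common: int
    pearson_r: float
    slope: float
    intercept: float
    n_up_above: int      # up-DEMs with FC_obese > FC_lean
    n_up_below: int
    n_up_on_line: int
    n_down_above: int
    n_down_below: int
    n_down_on_line: int
    n_discordant: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def classify_dems(lean: ContrastResult, obese: ContrastResult,
                  q_sig: float = 0.01, q_ns: float = 0.05) -> pd.DataFrame:
    """Assign every miRNA to exactly one category from the two contrasts.

    Returns a DataFrame indexed by miRNA id with columns q_lean, q_obese,
    log2fc_lean, log2fc_obese, direction_lean, direction_obese, category,
    strong_side. Untested miRNAs (NaN Q) are treated as clearly
    non-significant. ``strong_side`` is filled for common DEMs only.
    """
    if not q_sig < q_ns:
        raise ValidationError("q_sig must be < q_ns")
    left = set(lean.table.index)
    right = set(obese.table.index)
    if left != right:
        diff = sorted(left ^ right)
        raise ValidationError(f"contrasts cover different miRNA universes: {diff[:20]}")

    idx = lean.table.index
    q_l = lean.table["qvalue"].to_numpy(dtype=float)
    q_o = obese.table.loc[idx, "qvalue"].to_numpy(dtype=float)
    fc_l = lean.table["log2fc"].to_numpy(dtype=float)
    fc_o = obese.table.loc[idx, "log2fc"].to_numpy(dtype=float)

    sig_l = np.nan_to_num(q_l, nan=1.0) < q_sig
    sig_o = np.nan_to_num(q_o, nan=1.0) < q_sig
    excl_l = ~(np.nan_to_num(q_l, nan=1.0) < q_ns)   # clearly non-significant
    excl_o = ~(np.nan_to_num(q_o, nan=1.0) < q_ns)

    category = np.full(idx.size, "non_dem", dtype=object)
    category[sig_l & sig_o] = "common"
    category[sig_l & ~sig_o & excl_o] = "lean_specific"
    category[sig_o & ~sig_l & excl_l] = "obese_specific"
    category[(sig_l & ~sig_o & ~excl_o) | (sig_o & ~sig_l & ~excl_l)] = "indeterminate"

    def _direction(sig, fc):
        return np.where(sig & (fc > 0), "up", np.where(sig & (fc < 0), "down", "none"))

    table = pd.DataFrame(
        {
            "q_lean": q_l,
            "q_obese": q_o,
            "log2fc_lean": fc_l,
            "log2fc_obese": fc_o,
            "direction_lean": _direction(sig_l, fc_l),
            "direction_obese": _direction(sig_o, fc_o),
            "category": category,
        },
        index=idx,
    )
    table["strong_side"] = strong_categories(table)
    return table


def strong_categories(table: pd.DataFrame) -> pd.Series:
    """Label each common DEM by the condition with the stronger change.

    For concordant up-DEMs: ``Lean_Strong_Up`` when the lean fold change is
    larger, ``Obese_Strong_Up`` when the obese one is. For concordant
    down-DEMs the *more negative* side wins (more strongly downregulated).
    Exact equality is ``Tie``; common DEMs whose directions disagree go to
    a ``discordant`` bucket; non-common miRNAs get ``not_applicable``.
    """
    out = pd.Series("not_applicable", index=table.index, dtype=object)
    common = table["category"] == "common"
    for mid in table.index[common]:
        fc_l = table.at[mid, "log2fc_lean"]
        fc_o = table.at[mid, "log2fc_obese"]
        d_l = table.at[mid, "direction_lean"]
        d_o = table.at[mid, "direction_obese"]
        if d_l != d_o:
            out.at[mid] = "discordant"
        elif fc_l == fc_o:
            out.at[mid] = "Tie"
        elif d_l == "up":
            out.at[mid] = "Lean_Strong_Up" if fc_l > fc_o else "Obese_Strong_Up"
        else:
            out.at[mid] = "Lean_Strong_Down" if fc_l < fc_o else "Obese_Strong_Down"
    return out


def concordance(table: pd.DataFrame) -> ConcordanceStats:
    """Pearson r and OLS of obese log2FC on lean log2FC over common DEMs,
    plus counts of points above/below/on the y = x line per direction."""
    common = table[table["category"] == "common"]
    if len(common) < 3:
        raise ValidationError(
            f"need at least 3 common DEMs for concordance, have {len(common)}"
        )
    x = common["log2fc_lean"].to_numpy(dtype=float)
    y = common["log2fc_obese"].to_numpy(dtype=float)
    r = float(stats.pearsonr(x, y).statistic)
    fit = stats.linregress(x, y)

    concordant = common["direction_lean"] == common["direction_obese"]
    up = concordant & (common["direction_lean"] == "up")
    down = concordant & (common["direction_lean"] == "down")
    above = y > x
    below = y < x
    on = y == x
    return ConcordanceStats(
        n_common=len(common),
        pearson_r=r,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n_up_above=int((up & above).sum()),
        n_up_below=int((up & below).sum()),
        n_up_on_line=int((up & on).sum()),
        n_down_above=int((down & above).sum()),
        n_down_below=int((down & below).sum()),
        n_down_on_line=int((down & on).sum()),
        n_discordant=int((~concordant).sum()),
    )


def summarize_overlap(table: pd.DataFrame, lean: ContrastResult,
                      obese: ContrastResult) -> dict:
    """Headline set statistics: common-DEM count, the percent of each
    contrast's DEMs that are common (rounded half-up for reporting, raw
    ratio retained), per-direction common counts, and specific counts.
    """
    n_common = int((table["category"] == "common").sum())
    n_lean = lean.n_dems
    n_obese = obese.n_dems
    pct_lean_raw = 100.0 * n_common / n_lean if n_lean else 0.0
    pct_obese_raw = 100.0 * n_common / n_obese if n_obese else 0.0

    common = table[table["category"] == "common"]
    concordant = common["direction_lean"] == common["direction_obese"]
    strong_counts = (
        table.loc[table["category"] == "common", "strong_side"]
        .value_counts().to_dict()
    )
    return {
        "n_common": n_common,
        "n_dems_lean": n_lean,
        "n_dems_obese": n_obese,
        "pct_of_lean_common": round_half_up(pct_lean_raw),
        "pct_of_obese_common": round_half_up(pct_obese_raw),
        "pct_of_lean_common_raw": pct_lean_raw,
        "pct_of_obese_common_raw": pct_obese_raw,
        "n_common_up": int((concordant & (common["direction_lean"] == "up")).sum()),
        "n_common_down": int((concordant & (common["direction_lean"] == "down")).sum()),
        "n_common_discordant": int((~concordant).sum()),
        "n_lean_specific": int((table["category"] == "lean_specific").sum()),
        "n_lean_specific_up": int(((table["category"] == "lean_specific")
                                   & (table["direction_lean"] == "up")).sum()),
        "n_lean_specific_down": int(((table["category"] == "lean_specific")
                                     & (table["direction_lean"] == "down")).sum()),
        "n_obese_specific": int((table["category"] == "obese_specific").sum()),
        "n_obese_specific_up": int(((table["category"] == "obese_specific")
                                    & (table["direction_obese"] == "up")).sum()),
        "n_obese_specific_down": int(((table["category"] == "obese_specific")
                                      & (table["direction_obese"] == "down")).sum()),
        "n_indeterminate": int((table["category"] == "indeterminate").sum()),
        "n_non_dem": int((table["category"] == "non_dem").sum()),
        "strong_counts": strong_counts,
    }
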