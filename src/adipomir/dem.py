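"""Differential miRNA expression: normalization, NB Wald test, BH FDR.

This is a deliberately simple, self-contained negative-binomial DE stage in
the DESeq2 style: median-of-ratios size factors, per-miRNA
method-of-moments dispersion (no shrinkage toward a trend), a Wald test on
the log2 fold change of group-mean normalized counts referred to a t
distribution with residual degrees of freedom, and Benjamini-Hochberg
Q-values. It omits DESeq2's dispersion shrinkage, Cook's-distance
outlier filtering, and fold-change shrinkage; externally produced DE tables
in the same schema can be read in with :func:`read_contrast` so a full
DESeq2 run can replace this stage without touching anything downstream.

Conventions: ``log2fc`` is group_b relative to group_a (positive = up in
group_b); a miRNA is called "up"/"down" only when its Q-value clears the
working threshold. miRNAs with zero counts in every tested sample are
reported with undefined p/Q and excluded from the BH denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .countmatrix import CountMatrix, ValidationError

DISPERSION_FLOOR = 1e-8
#: pseudo-mean added to both group means when one of them is zero, so the
#: fold change of a group that is entirely off stays finite.
ZERO_MEAN_PSEUDO = 0.5

DE_TABLE_COLUMNS = ["base_mean", "log2fc", "se", "pvalue", "qvalue", "direction"]


@dataclass
class ContrastResult:
    """Per-miRNA DE statistics for one contrast (Ag, L_Ag or O_Ag).

    ``table`` is indexed by miRNA id with columns base_mean, log2fc, se,
    pvalue, qvalue, direction. Direction is "up"/"down" only below the
    stored Q threshold, "none" otherwise.
    """

    contrast: str
    table: pd.DataFrame
    q_threshold: float = 0.01

    @property
    def n_up(self) -> int:
        return int((self.table["direction"] == "up").sum())

    @property
    def n_down(self) -> int:
        return int((self.table["direction"] == "down").sum())

    @property
    def n_dems(self) -> int:
        return self.n_up + self.n_down

    def dem_ids(self) -> list[str]:
        """miRNAs significant at the stored Q threshold."""
        sig = self.table["qvalue"] < self.q_threshold
        return list(self.table.index[sig.fillna(False)])

    def write(self, path: str | Path) -> None:
        out = self.table.copy()
        out.index.name = "mirna_id"
        with open(path, "w") as fh:
            fh.write(f"# contrast={self.contrast}\tq_threshold={self.q_threshold}\n")
            out.to_csv(fh, sep="\t")


def read_contrast(path: str | Path, contrast: str | None = None,
                  q_threshold: float = 0.01) -> ContrastResult:
    """Read a DE table TSV in this package's schema (or DESeq2 output
    renamed to it). A leading ``#`` comment line with contrast metadata is
    honored when present."""
    name = contrast
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        meta = dict(
            kv.split("=", 1) for kv in first[1:].strip().split("\t") if "=" in kv
        )
        name = name or meta.get("contrast")
        q_threshold = float(meta.get("q_threshold", q_threshold))
    table = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    missing = set(DE_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValidationError(f"DE table missing columns: {sorted(missing)}")
    return ContrastResult(contrast=name or "unnamed", table=table[DE_TABLE_COLUMNS],
                          q_threshold=q_threshold)


def size_factors(counts: pd.DataFrame | CountMatrix) -> pd.Series:
    """Median-of-ratios size factors against the geometric-mean reference.

    For each miRNA expressed in every sample, the reference is its
    geometric mean across samples; a sample's factor is the median of its
    count-to-reference ratios. Raises when no miRNA is expressed in all
    samples (such a matrix needs a pseudo-reference strategy this package
    does not implement).
    """
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    mat = counts.to_numpy(dtype=float)
    all_pos = (mat > 0).all(axis=1)
    if not all_pos.any():
        raise ValidationError(
            "no miRNA has nonzero counts in every sample; median-of-ratios "
            "is undefined (consider a pseudo-reference fallback upstream)"
        )
    logs = np.log(mat[all_pos])
    log_geomean = logs.mean(axis=1)
    factors = np.exp(np.median(logs - log_geomean[:, None], axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (Q-values).

    NaN entries (untested hypotheses) are passed through and do not enter
    the denominator m. Output order matches input order; monotonicity of
    the adjusted values is enforced along the sorted p-values.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    tested = ~np.isnan(p)
    pt = p[tested]
    if ((pt < 0) | (pt > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = pt.size
    if m == 0:
        return out
    order = np.argsort(pt, kind="mergesort")
    ranked = pt[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    out[tested] = q
    return out


def _mom_dispersion(norm: np.ndarray, inv_sf: np.ndarray,
                    groups: list[np.ndarray]) -> np.ndarray:
    """Per-miRNA method-of-moments NB dispersion, pooled across groups.

    With variance model Var(K/s) = mu/s + alpha*mu^2, the within-group
    sample variance v satisfies E[v] ~ mu*mean(1/s) + alpha*mu^2, giving
    alpha_hat = (v - m*mean(1/s)) / m^2 per group; estimates are pooled by
    degrees of freedom and floored at a small positive value (negative
    moment estimates mean "at most Poisson").
    """
    num = np.zeros(norm.shape[0])
    den = 0.0
    for idx in groups:
        sub = norm[:, idx]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        mean_inv = inv_sf[idx].mean()
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha_g = (v - m * mean_inv) / np.square(m)
        alpha_g = np.where(m > 0, alpha_g, 0.0)
        df = len(idx) - 1
        num += df * np.nan_to_num(alpha_g)
        den += df
    alpha = num / den
    return np.maximum(alpha, DISPERSION_FLOOR)


def call_dems(counts: CountMatrix, group_a, group_b,
              q_threshold: float = 0.01, contrast: str = "contrast",
              size_factors_override: pd.Series | None = None) -> ContrastResult:
    """Negative-binomial Wald test of group_b vs group_a.

    Parameters
    ----------
    counts
        Raw count matrix; only the samples in the two groups are used.
    group_a, group_b
        Disjoint sample-id collections, each of size >= 2. group_a is the
        reference (e.g. preAC), group_b the treatment (e.g. AC): positive
        log2fc means higher in group_b.
    q_threshold
        Working significance level on BH Q-values for the up/down calls.
    size_factors_override
        Per-sample factors to use instead of the median-of-ratios estimate
        (e.g. factors from a larger experiment, or all-ones in tests).
    """
    group_a, group_b = list(group_a), list(group_b)
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValidationError(f"groups overlap: {sorted(overlap)}")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValidationError("each group needs at least 2 samples")
    unknown = (set(group_a) | set(group_b)) - set(counts.sample_ids)
    if unknown:
        raise ValidationError(f"unknown sample ids: {sorted(unknown)}")

    use = group_a + group_b
    sub = counts.counts[use]
    if size_factors_override is not None:
        sf = pd.Series(size_factors_override, dtype=float).reindex(use)
        if sf.isna().any() or (sf <= 0).any():
            raise ValidationError("size factor override must be positive for every sample")
    else:
        sf = size_factors(sub)
    norm = sub.to_numpy(dtype=float) / sf.to_numpy()
    inv_sf = 1.0 / sf.to_numpy()
    ia = np.array([use.index(s) for s in group_a])
    ib = np.array([use.index(s) for s in group_b])

    tested = sub.to_numpy().sum(axis=1) > 0
    alpha = _mom_dispersion(norm, inv_sf, [ia, ib])

    m_a = norm[:, ia].mean(axis=1)
    m_b = norm[:, ib].mean(axis=1)
    base_mean = norm.mean(axis=1)

    # pseudo-mean only when one side is entirely off, so exact integer
    # ratios (e.g. 40 vs 10 -> log2fc 2) are preserved
    zero_side = ((m_a == 0) | (m_b == 0)) & tested
    m_a_adj = np.where(zero_side, m_a + ZERO_MEAN_PSEUDO, m_a)
    m_b_adj = np.where(zero_side, m_b + ZERO_MEAN_PSEUDO, m_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(m_b_adj / m_a_adj)

    def se_log2_mean(mu_adj, mu, idx):
        # model-based Var of the group mean of normalized counts,
        # delta-method to the log2 scale
        var_mean = (mu[:, None] * inv_sf[idx][None, :]
                    + alpha[:, None] * np.square(mu)[:, None]).sum(axis=1) / len(idx) ** 2
        # a fully-off group still gets sampling noise from the pseudo-mean
        var_mean = np.where(mu == 0, ZERO_MEAN_PSEUDO * inv_sf[idx].mean() / len(idx),
                            var_mean)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.sqrt(var_mean) / (mu_adj * np.log(2))

    se = np.sqrt(se_log2_mean(m_a_adj, m_a, ia) ** 2
                 + se_log2_mean(m_b_adj, m_b, ib) ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = log2fc / se
    z = np.where((log2fc == 0), 0.0, z)
    # t reference with residual df: the dispersion entering the SE is
    # estimated from the same few samples, and a standard-normal reference
    # is visibly anti-conservative at these group sizes
    df_resid = len(group_a) + len(group_b) - 2
    pvalue = np.where(tested, 2.0 * stats.t.sf(np.abs(z), df_resid), np.nan)
    pvalue = np.where(tested & ~np.isfinite(pvalue), 1.0, pvalue)

    qvalue = bh_adjust(pvalue)
    sig = qvalue < q_threshold
    direction = np.where(sig & (log2fc > 0), "up",
                         np.where(sig & (log2fc < 0), "down", "none"))

    table = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": np.where(tested, log2fc, np.nan),
            "se": np.where(tested, se, np.nan),
            "pvalue": pvalue,
            "qvalue": qvalue,
            "direction": np.where(tested, direction, "none"),
        },
        index=sub.index,
    )
    return ContrastResult(contrast=contrast, table=table, q_threshold=q_threshold)


def call_standard_contrasts(counts: CountMatrix,
                            q_threshold: float = 0.01) -> dict[str, ContrastResult]:
    """The three contrasts of the study design, each against the pooled
    preAC control: Ag (all AC), L_Ag (lean AC), O_Ag (obese AC)."""
    pre = counts.samples(cell_type="preAC")
    ac = counts.samples(cell_type="AC")
    ac_lean = counts.samples(cell_type="AC", condition="lean")
    ac_obese = counts.samples(cell_type="AC", condition="obese")
    return {
        "Ag": call_dems(counts, pre, ac, q_threshold, contrast="Ag"),
        "L_Ag": call_dems(counts, pre, ac_lean, q_threshold, contrast="L_Ag"),
        "O_Ag": call_dems(counts, pre, ac_obese, q_threshold, contrast="O_Ag"),
    }
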