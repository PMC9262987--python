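"""DEM target mapping and the permutation test of DEG enrichment.

Joins a DEM list against a table of experimentally validated miRNA->mRNA
interactions (miRTarBase MTI-export dialect), then asks whether the
distinct target genes contain more differentially expressed genes (DEGs)
than expected by chance. The null draws gene sets of the same size from
the protein-coding universe without replacement, which makes the exact
hypergeometric distribution the closed-form oracle for the permutation
null — both are provided, the Monte-Carlo version as the headline
procedure and the hypergeometric one as its cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._util import normalize_mirna_id
from .countmatrix import ValidationError


@dataclass
class MappingSummary:
    """Result of joining a DEM set to the pair table."""

    n_dems_matched: int
    n_interactions: int
    n_distinct_target_genes: int
    target_genes: set[str]
    matched_dems: set[str] = field(default_factory=set)


@dataclass
class EnrichmentResult:
    """Observed DEG percentage among target genes against the permutation
    null. ``empirical_p`` uses the add-one estimator (r+1)/(n_iter+1), so
    it can never be exactly zero."""

    n_targets: int
    n_target_degs: int
    observed_pct: float
    null_mean_pct: float
    null_sd_pct: float
    empirical_p: float
    n_iter: int
    seed: int
    null_pcts: np.ndarray | None = None

    def as_dict(self, include_null: bool = False) -> dict:
        d = {
            "n_targets": self.n_targets,
            "n_target_degs": self.n_target_degs,
            "observed_pct": self.observed_pct,
            "null_mean_pct": self.null_mean_pct,
            "null_sd_pct": self.null_sd_pct,
            "empirical_p": self.empirical_p,
            "n_iter": self.n_iter,
            "seed": self.seed,
        }
        if include_null and self.null_pcts is not None:
            d["null_pcts"] = [float(x) for x in self.null_pcts]
        return d


def read_target_pairs(path: str | Path, headerless: bool = False) -> pd.DataFrame:
    """Read a miRNA->target-gene pair table.

    The default dialect is the miRTarBase MTI export: a header containing
    columns named ``miRNA`` and ``Target Gene`` (any extra columns such as
    support type or references are carried through). With
    ``headerless=True`` a bare two-column TSV is accepted instead.
    Pairs are deduplicated on the normalized (miRNA, gene) key.
    """
    if headerless:
        pairs = pd.read_csv(path, sep="\t", header=None,
                            names=["miRNA", "Target Gene"])
    else:
        pairs = pd.read_csv(path, sep="\t")
        missing = {"miRNA", "Target Gene"} - set(pairs.columns)
        if missing:
            raise ValidationError(
                f"pair table missing columns {sorted(missing)}; "
                "use headerless=True for a bare two-column file"
            )
    return dedupe_pairs(pairs)


def dedupe_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    """Drop duplicate (miRNA, gene) pairs under id normalization."""
    if pairs.empty:
        return pairs
    key_m = pairs["miRNA"].astype(str).map(normalize_mirna_id)
    key_g = pairs["Target Gene"].astype(str).str.strip()
    if (key_m == "").any() or (key_g == "").any():
        raise ValidationError("pair table contains empty miRNA or gene ids")
    keep = ~pd.DataFrame({"m": key_m, "g": key_g}).duplicated()
    return pairs[keep].reset_index(drop=True)


def map_targets(dems, pairs: pd.DataFrame) -> MappingSummary:
    """Join a DEM id collection to the pair table.

    ``dems`` may be a ContrastResult (its significant miRNAs are used) or
    any iterable of miRNA ids. Matching is on normalized ids; interactions
    are counted after deduplication, distinct target genes as the union of
    the matched DEMs' targets.
    """
    if pairs is None or len(pairs) == 0:
        raise ValidationError("empty pair table")
    dem_ids = dems.dem_ids() if hasattr(dems, "dem_ids") else list(dems)
    dem_keys = {normalize_mirna_id(str(d)) for d in dem_ids}

    pairs = dedupe_pairs(pairs)
    keys = pairs["miRNA"].astype(str).map(normalize_mirna_id)
    hit = keys.isin(dem_keys)
    matched = pairs[hit]
    genes = set(matched["Target Gene"].astype(str).str.strip())
    return MappingSummary(
        n_dems_matched=int(keys[hit].nunique()),
        n_interactions=int(hit.sum()),
        n_distinct_target_genes=len(genes),
        target_genes=genes,
        matched_dems=set(keys[hit]),
    )


def permutation_enrichment(target_genes, degs, universe, n_iter: int = 10000,
                           seed: int = 0, keep_null: bool = False) -> EnrichmentResult:
    """Permutation test: is the DEG percentage among target genes higher
    than in random same-size gene sets?

    Each iteration draws ``len(target_genes)`` genes from the universe
    without replacement and records the percentage that are DEGs;
    ``empirical_p`` is the add-one upper-tail estimate against the
    observed percentage. Deterministic for fixed seed and inputs.
    """
    target_genes = set(target_genes)
    degs = set(degs)
    universe = list(universe)
    uni_set = set(universe)
    if n_iter < 1:
        raise ValidationError("n_iter must be >= 1")
    if len(target_genes) > len(uni_set):
        raise ValidationError("target set larger than universe")
    outside = target_genes - uni_set
    if outside:
        raise ValidationError(
            f"target genes outside universe: {sorted(outside)[:20]}"
        )
    if not degs <= uni_set:
        raise ValidationError(
            f"DEGs outside universe: {sorted(degs - uni_set)[:20]}"
        )

    k = len(target_genes)
    observed_pct = 100.0 * len(target_genes & degs) / k if k else 0.0

    is_deg = np.fromiter((g in degs for g in universe), dtype=bool,
                         count=len(universe))
    rng = np.random.default_rng(seed)
    null_counts = np.empty(n_iter, dtype=np.int64)
    for i in range(n_iter):
        sample = rng.choice(len(universe), size=k, replace=False)
        null_counts[i] = is_deg[sample].sum()
    null_pcts = 100.0 * null_counts / k if k else np.zeros(n_iter)

    r = int((null_pcts >= observed_pct).sum())
    return EnrichmentResult(
        n_targets=k,
        n_target_degs=len(target_genes & degs),
        observed_pct=observed_pct,
        null_mean_pct=float(null_pcts.mean()),
        null_sd_pct=float(null_pcts.std(ddof=1)) if n_iter > 1 else 0.0,
        empirical_p=(r + 1) / (n_iter + 1),
        n_iter=n_iter,
        seed=seed,
        null_pcts=null_pcts if keep_null else None,
    )


def hypergeometric_oracle(k: int, n_degs: int, n_universe: int,
                          observed: int) -> tuple[float, float]:
    """Closed-form null for the permutation test.

    For a size-``k`` sample drawn without replacement from a universe of
    ``n_universe`` genes containing ``n_degs`` DEGs, returns the expected
    DEG percentage (100*D/G) and the exact upper-tail probability
    P(X >= observed) under the hypergeometric distribution.
    """
    if not (0 <= observed <= k <= n_universe and 0 <= n_degs <= n_universe):
        raise ValidationError(
            f"infeasible counts: observed={observed}, k={k}, "
            f"D={n_degs}, G={n_universe}"
        )
    expected_pct = 100.0 * n_degs / n_universe
    tail = float(stats.hypergeom.sf(observed - 1, n_universe, n_degs, k))
    return expected_pct, tail


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line; blank lines and ``#`` comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out
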