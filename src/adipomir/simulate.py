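"""Seeded synthetic miRNA-seq data with planted differential expression.

Generates everything the downstream analysis consumes — a count matrix
with the preAC/AC x lean/obese design, truth labels for every planted
effect, a validated-target-style pair table with controllable DEG
enrichment, and the DEG / gene-universe lists — so the whole pipeline is
testable without access-controlled data.

The emulated design: a pooled preadipocyte control (all preAC samples are
drawn from one shared expression profile regardless of condition) against
two adipocyte groups, lean and obese. Planted miRNA classes:

* ``common_up`` / ``common_down`` — shifted in both AC groups; a random
  half additionally get ``strong_delta`` extra |log2FC| on one condition
  (the planted "strong" side).
* ``lean_specific_*`` / ``obese_specific_*`` — shifted in one AC group
  only.
* ``null`` — no shift anywhere.

Counts are negative-binomial with variance mu + alpha*mu^2 and per-sample
library-size scaling; identical spec + seed reproduces byte-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._util import child_seed
from .countmatrix import CountMatrix, ValidationError

CLASSES = (
    "null",
    "common_up",
    "common_down",
    "lean_specific_up",
    "lean_specific_down",
    "obese_specific_up",
    "obese_specific_down",
)

#: default DEG fraction of the gene universe (the permutation null level
#: observed in adipose-tissue mRNA data is about 15%)
DEFAULT_DEG_FRACTION = 0.15


@dataclass
class SimulationSpec:
    """Parameters of one synthetic experiment.

    Defaults mirror the study design this package targets: 13 preAC
    samples (7 lean + 6 obese; the per-condition split of the controls is
    a declared choice, the design only fixes the total) and 14 AC samples
    (7 + 7), with roughly 30% of miRNAs differentially expressed in both
    conditions and a few percent condition-specific.

    ``dispersion`` is the NB alpha in Var = mu + alpha*mu^2 (scalar or one
    value per miRNA). ``effect_size_common`` / ``effect_size_specific``
    are planted |log2FC|; ``strong_delta`` is the extra |log2FC| added on
    one condition for half of the common DEMs. ``library_size_range``
    bounds the expected total counts per sample.
    """

    n_mirnas: int = 2000
    n_pre_lean: int = 7
    n_pre_obese: int = 6
    n_ac_lean: int = 7
    n_ac_obese: int = 7
    baseline_log2_mean_range: tuple[float, float] = (3.0, 10.0)
    dispersion: float | np.ndarray = 0.1
    class_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "common": 0.30,
            "lean_specific": 0.03,
            "obese_specific": 0.03,
        }
    )
    effect_size_common: float = 2.0
    effect_size_specific: float = 2.0
    strong_delta: float = 1.0
    library_size_range: tuple[float, float] = (5e5, 2e6)
    seed: int = 0

    def validate(self) -> None:
        if self.n_mirnas < 1:
            raise ValidationError("n_mirnas must be >= 1")
        for name in ("n_pre_lean", "n_pre_obese", "n_ac_lean", "n_ac_obese"):
            if getattr(self, name) < 2:
                raise ValidationError(f"{name} must be >= 2")
        disp = np.asarray(self.dispersion, dtype=float)
        if (disp <= 0).any():
            raise ValidationError("dispersion must be > 0")
        if disp.ndim == 1 and disp.size != self.n_mirnas:
            raise ValidationError("per-miRNA dispersion must have length n_mirnas")
        fracs = dict(self.class_fractions)
        unknown = set(fracs) - {"common", "lean_specific", "obese_specific"}
        if unknown:
            raise ValidationError(f"unknown class_fractions keys: {sorted(unknown)}")
        if any(f < 0 for f in fracs.values()):
            raise ValidationError("class_fractions must be nonnegative")
        if sum(fracs.values()) > 1 + 1e-12:
            raise ValidationError("class_fractions must sum to <= 1")
        for name in ("effect_size_common", "effect_size_specific", "strong_delta"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ValidationError("library_size_range must satisfy 0 < lo <= hi")
        lo2, hi2 = self.baseline_log2_mean_range
        if not lo2 <= hi2:
            raise ValidationError("baseline_log2_mean_range must be ordered")


@dataclass
class TruthLabels:
    """Ground truth of one simulation: per-miRNA class and planted log2FCs
    (``mirnas``: true_class, true_log2fc_lean, true_log2fc_obese,
    strong_side), plus the planted DEG labels and target pairs once the
    target table has been generated."""

    mirnas: pd.DataFrame
    genes: pd.DataFrame | None = None
    pairs: pd.DataFrame | None = None

    def of_class(self, *classes: str) -> list[str]:
        mask = self.mirnas["true_class"].isin(classes)
        return list(self.mirnas.index[mask])


def _assign_classes(spec: SimulationSpec, rng: np.random.Generator) -> pd.DataFrame:
    n = spec.n_mirnas
    fracs = spec.class_fractions
    n_common = int(round(fracs.get("common", 0.0) * n))
    n_lean = int(round(fracs.get("lean_specific", 0.0) * n))
    n_obese = int(round(fracs.get("obese_specific", 0.0) * n))
    if n_common + n_lean + n_obese > n:
        raise ValidationError("class fractions allocate more miRNAs than exist")

    ids = [f"sim-miR-{i + 1}" for i in range(n)]
    order = rng.permutation(n)
    true_class = np.array(["null"] * n, dtype=object)
    fc_lean = np.zeros(n)
    fc_obese = np.zeros(n)
    strong_side = np.array(["not_applicable"] * n, dtype=object)

    pos = 0
    common_idx = order[pos:pos + n_common]
    pos += n_common
    lean_idx = order[pos:pos + n_lean]
    pos += n_lean
    obese_idx = order[pos:pos + n_obese]

    sign = rng.choice([1.0, -1.0], size=n_common)
    fc_lean[common_idx] = sign * spec.effect_size_common
    fc_obese[common_idx] = sign * spec.effect_size_common
    true_class[common_idx] = np.where(sign > 0, "common_up", "common_down")
    # a random half of common DEMs get extra magnitude on a random side
    is_strong = rng.random(n_common) < 0.5
    side = rng.choice(["lean", "obese"], size=n_common)
    delta = spec.strong_delta
    for j, mi in enumerate(common_idx):
        if not is_strong[j] or delta == 0:
            continue
        if side[j] == "lean":
            fc_lean[mi] += np.sign(fc_lean[mi]) * delta
            strong_side[mi] = "lean"
        else:
            fc_obese[mi] += np.sign(fc_obese[mi]) * delta
            strong_side[mi] = "obese"

    sign = rng.choice([1.0, -1.0], size=n_lean)
    fc_lean[lean_idx] = sign * spec.effect_size_specific
    true_class[lean_idx] = np.where(sign > 0, "lean_specific_up", "lean_specific_down")
    sign = rng.choice([1.0, -1.0], size=n_obese)
    fc_obese[obese_idx] = sign * spec.effect_size_specific
    true_class[obese_idx] = np.where(sign > 0, "obese_specific_up", "obese_specific_down")

    if spec.effect_size_common == 0:
        true_class[common_idx] = "null"
        strong_side[common_idx] = "not_applicable"
    if spec.effect_size_specific == 0:
        true_class[lean_idx] = "null"
        true_class[obese_idx] = "null"

    return pd.DataFrame(
        {
            "true_class": true_class,
            "true_log2fc_lean": fc_lean,
            "true_log2fc_obese": fc_obese,
            "strong_side": strong_side,
        },
        index=pd.Index(ids, name="mirna_id"),
    )


def generate_counts(spec: SimulationSpec) -> tuple[CountMatrix, TruthLabels]:
    """Draw one seeded count matrix and its truth labels.

    preAC samples of both conditions share a single baseline profile (the
    pooled common control); AC group means are the baseline shifted by the
    planted per-condition log2FCs. Per-sample library scaling multiplies
    every mean so that expected column totals land in
    ``library_size_range``.
    """
    spec.validate()
    rng_truth = np.random.default_rng(child_seed(spec.seed, "truth"))
    truth_mirnas = _assign_classes(spec, rng_truth)

    rng = np.random.default_rng(child_seed(spec.seed, "counts"))
    lo, hi = spec.baseline_log2_mean_range
    base_mu = 2.0 ** rng.uniform(lo, hi, size=spec.n_mirnas)

    sample_defs: list[tuple[str, str, str]] = []
    for i in range(spec.n_pre_lean):
        sample_defs.append((f"preAC_lean_{i + 1}", "preAC", "lean"))
    for i in range(spec.n_pre_obese):
        sample_defs.append((f"preAC_obese_{i + 1}", "preAC", "obese"))
    for i in range(spec.n_ac_lean):
        sample_defs.append((f"AC_lean_{i + 1}", "AC", "lean"))
    for i in range(spec.n_ac_obese):
        sample_defs.append((f"AC_obese_{i + 1}", "AC", "obese"))

    fc_lean = truth_mirnas["true_log2fc_lean"].to_numpy()
    fc_obese = truth_mirnas["true_log2fc_obese"].to_numpy()
    profiles = {
        ("preAC", "lean"): base_mu,
        ("preAC", "obese"): base_mu,  # pooled common control
        ("AC", "lean"): base_mu * 2.0 ** fc_lean,
        ("AC", "obese"): base_mu * 2.0 ** fc_obese,
    }

    lib_lo, lib_hi = spec.library_size_range
    lib_sizes = rng.uniform(lib_lo, lib_hi, size=len(sample_defs))

    alpha = np.broadcast_to(np.asarray(spec.dispersion, dtype=float),
                            (spec.n_mirnas,))
    nb_n = 1.0 / alpha

    cols = {}
    for (sid, ct, cond), lib in zip(sample_defs, lib_sizes):
        mu = profiles[(ct, cond)]
        scale = lib / mu.sum()
        mean_s = mu * scale
        # NB(mean, alpha): numpy parameterization n = 1/alpha, p = n/(n+mean)
        p = nb_n / (nb_n + mean_s)
        cols[sid] = rng.negative_binomial(nb_n, p)
    counts = pd.DataFrame(cols, index=truth_mirnas.index)
    meta = pd.DataFrame(
        {
            "cell_type": [ct for _, ct, _ in sample_defs],
            "condition": [cond for _, _, cond in sample_defs],
        },
        index=pd.Index([sid for sid, _, _ in sample_defs], name="sample_id"),
    )
    return CountMatrix(counts=counts, sample_meta=meta), TruthLabels(mirnas=truth_mirnas)


def generate_target_table(
    truth: TruthLabels,
    n_genes: int = 20000,
    edges_per_mirna: int | dict[str, int] = 12,
    enrichment_factor: float = 1.8,
    seed: int = 0,
    deg_fraction: float = DEFAULT_DEG_FRACTION,
    mapped_fraction: float = 0.45,
    inflammatory_genes: tuple[str, ...] = ("IL6", "IL1B", "TNF"),
    n_inflammatory_mirnas: int = 25,
) -> tuple[pd.DataFrame, set[str], list[str]]:
    """Build a validated-target-style pair table with planted enrichment.

    Each miRNA enters the table with probability ``mapped_fraction`` (real
    validated-interaction databases cover only part of any DEM list) and
    receives ``edges_per_mirna`` distinct target genes (an int, or a dict
    of per-miRNA overrides on top of that default). Targets of planted
    DEMs are DEGs with probability ``enrichment_factor`` times the
    universe DEG fraction; targets of null miRNAs are drawn uniformly.

    To exercise the inflammatory-linkage stage, the last
    ``len(inflammatory_genes)`` universe ids are renamed to those symbols
    and ``n_inflammatory_mirnas`` planted DEMs each get one extra edge
    into the trio (set ``n_inflammatory_mirnas=0`` to disable).

    Returns ``(pairs, degs, universe)``: a DataFrame with columns
    ``miRNA`` and ``Target Gene``, the DEG id set, and the full gene-
    universe list. Also fills ``truth.genes`` / ``truth.pairs`` in place.
    """
    if enrichment_factor < 1:
        raise ValidationError("enrichment_factor must be >= 1")
    n_degs = int(round(deg_fraction * n_genes))
    if n_genes <= n_degs:
        raise ValidationError("n_genes must exceed the DEG count")
    p_deg = enrichment_factor * n_degs / n_genes
    if p_deg > 1:
        raise ValidationError(
            f"requested enrichment infeasible: factor {enrichment_factor} x "
            f"DEG fraction {n_degs / n_genes:.3f} exceeds 1"
        )

    rng = np.random.default_rng(child_seed(seed, "targets"))
    universe = [f"GENE{i + 1:05d}" for i in range(n_genes)]
    if inflammatory_genes and n_inflammatory_mirnas > 0:
        if n_genes < len(inflammatory_genes):
            raise ValidationError("universe too small for inflammatory genes")
        for i, sym in enumerate(inflammatory_genes):
            universe[n_genes - len(inflammatory_genes) + i] = sym
    deg_idx = rng.choice(n_genes, size=n_degs, replace=False)
    is_deg = np.zeros(n_genes, dtype=bool)
    is_deg[deg_idx] = True
    degs = {universe[i] for i in deg_idx}
    deg_pool = np.flatnonzero(is_deg)
    nondeg_pool = np.flatnonzero(~is_deg)

    overrides = edges_per_mirna if isinstance(edges_per_mirna, dict) else {}
    default_k = edges_per_mirna if isinstance(edges_per_mirna, int) else 12

    rows_mirna: list[str] = []
    rows_gene: list[str] = []
    planted_flag: list[bool] = []
    planted_classes = {c for c in CLASSES if c != "null"}
    for mirna_id, row in truth.mirnas.iterrows():
        k = int(overrides.get(mirna_id, default_k))
        if k == 0:
            continue
        if rng.random() >= mapped_fraction and mirna_id not in overrides:
            continue
        is_planted = row["true_class"] in planted_classes
        if is_planted:
            n_deg_targets = rng.binomial(k, p_deg)
            n_deg_targets = min(n_deg_targets, deg_pool.size)
            chosen = np.concatenate([
                rng.choice(deg_pool, size=n_deg_targets, replace=False),
                rng.choice(nondeg_pool, size=k - n_deg_targets, replace=False),
            ])
        else:
            chosen = rng.choice(n_genes, size=min(k, n_genes), replace=False)
        for gi in chosen:
            rows_mirna.append(mirna_id)
            rows_gene.append(universe[gi])
            planted_flag.append(bool(is_planted))

    if inflammatory_genes and n_inflammatory_mirnas > 0:
        planted_ids = [m for m, row in truth.mirnas.iterrows()
                       if row["true_class"] in planted_classes]
        n_link = min(n_inflammatory_mirnas, len(planted_ids))
        linked = rng.choice(planted_ids, size=n_link, replace=False)
        for m in linked:
            gene = inflammatory_genes[int(rng.integers(len(inflammatory_genes)))]
            rows_mirna.append(m)
            rows_gene.append(gene)
            planted_flag.append(True)

    pairs = pd.DataFrame({"miRNA": rows_mirna, "Target Gene": rows_gene})
    dup = pairs.duplicated(subset=["miRNA", "Target Gene"])
    if dup.any():
        pairs = pairs[~dup].reset_index(drop=True)
        planted_flag = [f for f, d in zip(planted_flag, dup) if not d]
    truth.genes = pd.DataFrame({"is_deg": is_deg},
                               index=pd.Index(universe, name="gene_id"))
    truth.pairs = pairs.assign(is_planted_target=planted_flag)
    return pairs, degs, universe


# ----------------------------------------------------------------- dataset I/O

def write_dataset(out_dir: str | Path, spec: SimulationSpec,
                  counts: CountMatrix, truth: TruthLabels,
                  pairs: pd.DataFrame | None = None,
                  degs: set[str] | None = None,
                  universe: list[str] | None = None) -> dict[str, Path]:
    """Write every simulated artifact as plain text and return the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.tsv",
        "sample_sheet": out / "samples.tsv",
        "truth": out / "truth_mirnas.tsv",
        "spec": out / "simulation.yaml",
    }
    counts.write(paths["counts"], paths["sample_sheet"])
    truth.mirnas.to_csv(paths["truth"], sep="\t")
    cfg = asdict(spec)
    cfg["dispersion"] = (
        float(spec.dispersion) if np.ndim(spec.dispersion) == 0
        else list(map(float, np.asarray(spec.dispersion)))
    )
    cfg["baseline_log2_mean_range"] = list(spec.baseline_log2_mean_range)
    cfg["library_size_range"] = list(spec.library_size_range)
    with open(paths["spec"], "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    if pairs is not None:
        paths["pairs"] = out / "target_pairs.tsv"
        pairs.to_csv(paths["pairs"], sep="\t", index=False)
    if degs is not None:
        paths["degs"] = out / "degs.txt"
        paths["degs"].write_text("\n".join(sorted(degs)) + "\n")
    if universe is not None:
        paths["universe"] = out / "universe.txt"
        paths["universe"].write_text("\n".join(universe) + "\n")
    return paths
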