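"""End-to-end pipeline: counts -> contrasts -> categories -> enrichment ->
inflammatory linkage -> run summary.

Each stage reads and writes the documented plain-text schemas, so any
stage's input can be replaced by externally produced files (e.g. a real
DESeq2 table instead of the built-in DE stage). The run summary collects
every headline statistic with a provenance block (seed, package version,
config echo) and is byte-identical across reruns of the same config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from ._util import child_seed
from .countmatrix import CountMatrix, ValidationError
from .dem import ContrastResult, call_standard_contrasts, read_contrast
from .enrichment import (map_targets, permutation_enrichment, read_gene_list,
                         read_target_pairs)
from .linkage import DEFAULT_GENE_SET, build_linkage, sankey_edges, tally_directions
from .sets import classify_dems, concordance, summarize_overlap


@dataclass
class RunConfig:
    """Paths and parameters of one full pipeline run."""

    counts: str
    sample_sheet: str
    pairs: str
    degs: str
    universe: str
    out_dir: str
    gene_set: tuple[str, ...] = DEFAULT_GENE_SET
    q_sig: float = 0.01
    q_ns: float = 0.05
    flag_threshold: float = 1.0
    n_iter: int = 10000
    seed: int = 0
    pairs_headerless: bool = False

    def validate(self) -> None:
        if not self.q_sig < self.q_ns:
            raise ValidationError("q_sig must be < q_ns")
        if self.n_iter < 1:
            raise ValidationError("n_iter must be >= 1")
        for name in ("counts", "sample_sheet", "pairs", "degs", "universe"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise ValidationError(f"input path for '{name}' not found: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        cfg = yaml.safe_load(Path(path).read_text()) or {}
        cfg.update({k: v for k, v in overrides.items() if v is not None})
        if "gene_set" in cfg:
            cfg["gene_set"] = tuple(cfg["gene_set"])
        return cls(**cfg)


def _stage(name):
    """Decorator-free stage wrapper: re-raise with the stage name."""
    class _Ctx:
        def __enter__(self):
            return self
        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"stage '{name}' failed: {exc}") from exc
            return False
    return _Ctx()


class _StageError(RuntimeError):
    pass


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return (and write) the run summary.

    Writes per-contrast DE tables, the category table, the concordance and
    overlap summaries, the enrichment JSON, the linkage edge lists, and
    ``summary.json`` into ``config.out_dir``. Deterministic given the
    config, including the seed.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    with _stage("load"):
        cm = CountMatrix.read(config.counts, config.sample_sheet)
        pairs = read_target_pairs(config.pairs, headerless=config.pairs_headerless)
        degs = set(read_gene_list(config.degs))
        universe = read_gene_list(config.universe)

    with _stage("call-dems"):
        contrasts = call_standard_contrasts(cm, q_threshold=config.q_sig)
        for name, res in contrasts.items():
            res.write(out / f"de_{name}.tsv")

    with _stage("classify"):
        table = classify_dems(contrasts["L_Ag"], contrasts["O_Ag"],
                              q_sig=config.q_sig, q_ns=config.q_ns)
        table.index.name = "mirna_id"
        table.to_csv(out / "categories.tsv", sep="\t")
        overlap = summarize_overlap(table, contrasts["L_Ag"], contrasts["O_Ag"])
        try:
            conc = concordance(table).as_dict()
        except ValidationError:
            conc = None

    with _stage("enrich"):
        dem_union = sorted(set(contrasts["L_Ag"].dem_ids())
                           | set(contrasts["O_Ag"].dem_ids()))
        if dem_union:
            mapping = map_targets(dem_union, pairs)
        else:
            mapping = None
        if mapping is not None and mapping.n_distinct_target_genes > 0:
            enr = permutation_enrichment(
                mapping.target_genes & set(universe), degs, universe,
                n_iter=config.n_iter,
                seed=child_seed(config.seed, "enrichment"),
            )
            enr_dict = enr.as_dict()
            enr_status = "ok"
        else:
            enr_dict = None
            enr_status = "no targets"
        with open(out / "enrichment.json", "w") as fh:
            json.dump({"status": enr_status, "result": enr_dict}, fh, indent=2)

    with _stage("linkage"):
        rows = build_linkage(contrasts["L_Ag"], contrasts["O_Ag"], pairs,
                             gene_set=config.gene_set,
                             flag_threshold=config.flag_threshold,
                             q_threshold=config.q_sig)
        rows.to_csv(out / "linkage.tsv", sep="\t", index=False)
        sankey_edges(rows).to_csv(out / "sankey_edges.tsv", sep="\t", index=False)
        tallies = tally_directions(rows)

    with _stage("report"):
        summary = {
            "contrasts": {
                name: {"n_dems": res.n_dems, "n_up": res.n_up, "n_down": res.n_down}
                for name, res in contrasts.items()
            },
            "overlap": overlap,
            "concordance": conc,
            "mapping": (
                {
                    "n_dems_matched": mapping.n_dems_matched,
                    "n_interactions": mapping.n_interactions,
                    "n_distinct_target_genes": mapping.n_distinct_target_genes,
                }
                if mapping is not None else None
            ),
            "enrichment": {"status": enr_status, "result": enr_dict},
            "linkage": tallies,
            "provenance": {
                "package": "adipomir",
                "version": __version__,
                "seed": config.seed,
                "config": _config_echo(config),
            },
        }
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def _config_echo(config: RunConfig) -> dict:
    d = asdict(config)
    d["gene_set"] = list(config.gene_set)
    return d
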