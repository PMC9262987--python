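# Methods

## The analysis

`adipomir` implements the downstream statistics of a two-condition
adipogenesis miRNA study. The design contrasts mature adipocytes (AC)
against a pooled preadipocyte (preAC) control in three ways: all ACs vs
all preACs (`Ag`), lean ACs vs the pooled preACs (`L_Ag`), and obese ACs
vs the pooled preACs (`O_Ag`). Everything downstream of the count matrix —
differential-miRNA (DEM) calling, the common/specific/strong category
algebra, fold-change concordance, validated-target joining, the
permutation test of DEG enrichment among DEM targets, and the
inflammatory-gene linkage — is implemented here; read processing,
alignment and quantification are out of scope and assumed done upstream.

## Differential expression stage

The DE engine is a documented simplified stand-in for DESeq2, kept
self-contained on purpose:

* **Normalization** — median-of-ratios size factors: for each miRNA with
  nonzero counts in every sample the reference is its geometric mean;
  a sample's factor is the median of its count/reference ratios. A matrix
  with no such miRNA raises an error (a pseudo-reference fallback is
  advised but not implemented).
* **Dispersion** — per-miRNA method-of-moments on normalized counts under
  the NB variance model Var(K/s) = μ/s + αμ², pooled across the two
  groups by degrees of freedom and floored at 1e-8. No shrinkage toward a
  mean–dispersion trend, no Cook's filtering, no fold-change shrinkage.
* **Test** — Wald statistic log2FC/SE, where log2FC is the log2 ratio of
  group-mean normalized counts (a pseudo-mean of 0.5 is added to both
  groups only when one group mean is exactly zero, so exact integer
  ratios are preserved) and the SE comes from the model-based variance of
  each group mean by the delta method. The statistic is referred to a
  **t distribution with n_a + n_b − 2 degrees of freedom** rather than a
  standard normal: the dispersion entering the SE is estimated from the
  same handful of samples, and at the design's group sizes (13 vs 14, or
  6 vs 6 in the calibration suite) the normal reference is measurably
  anti-conservative (null p<0.05 fraction ≈ 0.08) while the t reference
  calibrates at the nominal level (≈ 0.05, asserted in the test suite).
* **Multiple testing** — Benjamini–Hochberg step-up over tested miRNAs
  only; all-zero miRNAs carry undefined p/Q and do not enter the BH
  denominator. No independent filtering or baseMean filtering is applied.
  DEM status is Q < 0.01 by default with direction by the sign of log2FC;
  no fold-change cutoff.

Because the engine diverges from DESeq2 numerics, `read_contrast` accepts
externally produced DE tables in the same TSV schema, so a real DESeq2 run
can replace this stage. The test suite cross-checks the stage against
pyDESeq2 on a small fixture: size factors agree to machine precision and
log2FC estimates correlate at r > 0.99.

## Category algebra

With q_sig = 0.01 and q_ns = 0.05 (both parameters):

* **common** — Q < q_sig in both L_Ag and O_Ag;
* **lean_specific / obese_specific** — Q < q_sig in one contrast and
  Q ≥ q_ns in the other;
* **indeterminate** — significant in one contrast with the other's Q in
  [q_sig, q_ns): the dual-threshold definition leaves these unclassified,
  and naming them keeps the five categories an exact partition of the
  miRNA universe;
* **non_dem** — everything else. Untested miRNAs (undefined Q) count as
  clearly non-significant.

Common DEMs with concordant directions are split into strong categories by
fold-change magnitude: `Lean_Strong_Up` when the lean log2FC exceeds the
obese one (and symmetrically), with downregulated DEMs compared on the
more-negative side; exact equality is `Tie`. Discordant-direction common
DEMs (up in one contrast, down in the other — such pairs do occur) go to a
separate `discordant` bucket rather than erroring. Concordance statistics
(Pearson r, OLS of obese on lean log2FC, counts around the y = x line per
direction) are computed over common DEMs only and require at least three.

Reported percentages (e.g. the share of a contrast's DEMs that are common)
are rounded half-up to integers, with the raw ratios always retained.

## Target enrichment

DEM ids are joined to a validated miRNA→mRNA pair table (miRTarBase
MTI-export dialect: header columns `miRNA` and `Target Gene`; a headerless
two-column dialect is accepted by flag). Matching keys are
whitespace-stripped, lowercased ids; arm suffixes are kept and
mature-vs-precursor mapping is not attempted. Interactions are counted
after (miRNA, gene) deduplication; target genes are counted as distinct
genes, and the gene universe is an explicit input file, so annotation
dependence is externalized.

The enrichment null draws `|target set|` genes from the universe without
replacement per iteration (10,000 by default) and records the DEG
percentage; the empirical p uses the add-one estimator (r+1)/(n_iter+1).
Sampling without replacement makes the exact hypergeometric distribution
the closed-form oracle, and `hypergeometric_oracle` is checked against the
Monte-Carlo null in the tests (mean within 4 MC standard errors, tail
probability likewise on small instances).

## Inflammatory linkage

A (miRNA, gene) edge enters the linkage when the gene is in the requested
set (default IL6, IL1B, TNF, with an alias map for IL-6/IL-1β/TNF-α
notation) and the miRNA is a DEM in at least one condition; the non-DEM
side is kept and flagged, mirroring a Sankey plot's gray edges. Rows with
|log2FC_lean − log2FC_obese| ≥ 1 (parameter) are flagged, and significant
opposite directions are marked discordant. Direction tallies count
distinct miRNAs, not edges.

## Synthetic data

The generator emulates the study design so every stage is testable
without access-controlled data. Defaults, chosen once as the package's
study conditions:

| parameter | default | rationale |
|---|---|---|
| design | 7+6 preAC / 7+7 AC | totals 13/14 as in the emulated design; the per-condition split of controls is a declared choice |
| n_mirnas | 2000 | desk-scale matrix at realistic miRNome size |
| baseline log2 mean | U(3, 10) | spans lowly to highly expressed miRNAs |
| dispersion α | 0.1 | typical bulk small-RNA overdispersion |
| class fractions | 30% common, 3% + 3% specific | yields DEM counts of the same order as the emulated study |
| effect sizes | 2.0 (common and specific), strong Δ = 1.0 on a random half of common DEMs | recoverable but not trivial at n≈7 per group |
| library sizes | U(5e5, 2e6) | realistic per-sample depth spread |
| gene universe | 20,000 genes, 15% DEGs | protein-coding scale; the null DEG level sits near 15% |
| target table | 45% of miRNAs mapped, 12 edges each, 1.8× DEG enrichment among planted-DEM targets | matches the order of the validated-database coverage the analysis assumes |

preAC samples of both conditions are drawn from one shared profile (they
are used as a common control); AC means are the baseline times 2^(planted
log2FC) per condition. Counts are NB(μ, α) with per-sample scaling so
column totals land at the drawn library size; doubling the library-size
range doubles expected column sums without touching the truth labels. A
single global seed feeds deterministic per-stream child seeds (truth,
counts, targets, permutation), so single stages rerun reproducibly.
The last three universe ids are renamed IL6/IL1B/TNF and 25 planted DEMs
get one extra edge into them, so the linkage stage is exercised
end-to-end.

What the generator does **not** emulate: isomiRs and precursor/mature
structure, mean–dispersion trends, correlated miRNAs, batch effects,
sample-quality outliers, or biased target databases. Passing tests
therefore demonstrate correctness of the statistics under the stated
model, not robustness to those real-data features.

## Numerical choices and degenerate inputs

* BH is implemented directly (step-up with monotonicity enforcement, NaN
  passthrough) and is cross-checked against statsmodels in the tests.
* Ties in the strong categories require exact fold-change equality; no
  tolerance is applied.
* `concordance` errors below three common DEMs; the pipeline records the
  concordance block as null instead of failing the run.
* An empty linkage result (gene set absent from the pair table) is a
  warning with zero rows, not an error.
* All randomness in the pipeline flows from one config seed; written
  outputs carry no timestamps, so identical configs reproduce
  byte-identical files.

## Problem sizes in the shipped checks

The test suite and the acceptance script run the default 2000-miRNA
design, a 20,000-gene universe with 10,000 permutation iterations, and a
2000-miRNA null calibration at 6 vs 6; the full suite completes in a few
seconds on one CPU.

## Known limitations

* The DE stage is not DESeq2; Q-values will differ from a DESeq2 analysis
  of the same counts (use the external-table path for exact replication).
* The permutation universe is taken as given; whether unexpressed genes
  belong in the denominator is the caller's decision.
* Percent tallies treat each distinct miRNA once; edge-weighted summaries
  can be derived from the emitted linkage table if needed.
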