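# cleavemap

Analytics for variant × target cleavage-activity maps of high-fidelity
programmable nucleases. The package covers the full analysis path:

* **`cleavemap.activity`** — read long-format raw activity tables
  (EGFP-disruption or NGS indel percentages), subtract dead-nuclease
  background, normalize to WT, quantize to two decimals, call
  cleaved/not-cleaved at a threshold (default 0.20), aggregate
  mismatch-mixture screens, and apply the external high-throughput
  dataset filters (perfect-N20 protospacers, complete data, WT indel
  ≥ 15%).
* **`cleavemap.rule`** — order variants by fidelity and targets by
  cleavability, fit the per-variant staircase boundary that separates
  cleaved from non-cleaved cells, count outliers, and score the fit with
  the pooled G-mean (√(sensitivity × specificity)) and per-variant
  rank-based ROC/AUC. Includes a brute-force optimal-ordering oracle for
  testing.
* **`cleavemap.latent`** — synthetic data generator built on a linear
  latent-threshold model: per-target activating contribution `c`,
  per-variant inhibition `f` (WT = 0), per-mismatch-position penalty `m`;
  a cell is cleaved iff `c > f (+ m)`. Cleaved cells scatter in a
  WT-normalized band (default 0.70–1.20), non-cleaved cells sit near
  zero, and tables are emitted as raw percentages so the whole
  normalization path is exercised. Includes parameter-recovery scoring.
* **`cleavemap.screen`** — the two-step target-matched variant screen:
  a rough screen with WT plus three quartile-bracketing probes, then a
  fine screen of the untested variants inside the bracket, selecting the
  highest-fidelity variant above the activity floor (default 0.50) with
  ≤ 2 candidates nominated for genome-wide off-target confirmation.
  Also enumerates single-mismatch guide designs.
* **`cleavemap.kinetics`** — one-phase exponential decay fits
  (`y = A·exp(−t/τ) + c`, plateau fixed at 0 by default) of plasmid
  cleavage time courses, per-replicate; rate summaries per group and a
  Welch-t / Mann-Whitney comparison helper.
* **`cleavemap.amplicon`** — amplicon read tallies from SAM alignments:
  eligibility (≥ 75% match over the reference's first 20 bp), indel
  calls within ±2 bp of the cut site, dsODN 15-mer tag counting, HDR
  edit fractions; plus a seeded aligned-read simulator.
* **`cleavemap.config` / `cleavemap.cli`** — JSON-configured, seeded,
  bit-reproducible pipeline and a `cleavemap` CLI.

## CLI

```sh
cleavemap simulate --n-targets 50 --n-variants 19 --seed 1 -o raw.tsv
cleavemap normalize raw.tsv -o matrix.tsv
cleavemap fit-rule matrix.tsv -o fit/          # map.tsv + rulefit.json
cleavemap roc matrix.tsv -o roc.tsv
cleavemap kinetics timecourses.tsv -o fits.tsv
cleavemap tally --sam reads.sam --ref amplicon.fa --protospacer GTC...GAC
cleavemap run-all --config config.json -o bundle/
```

`run-all` writes a deterministic artifact bundle (raw table, normalized
matrix, ordered map with boundary, rule fit, ROC points, screen outcomes,
provenance with a config digest); re-running the same config reproduces
byte-identical files.

## Notes on conventions

* Normalized activities are quantized to two decimals before
  thresholding, so 0.195 rounds to 0.20 and is called cleaved.
* Undefined cells (WT signal not above background) propagate as missing,
  never as zero, and are excluded from every count and mean.
* Amplicon coordinates are 0-based half-open internally; the cut site is
  an inter-base offset 3 nt upstream of the PAM.
* "Indels without mismatches" is interpreted as counting gap operations
  only: substitutions elsewhere in a read do not disqualify it.
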