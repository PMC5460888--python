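# mmrscreen

Analysis pipeline for an oligonucleotide-directed mutagenesis screen that
classifies missense variants in a DNA mismatch-repair (MMR) gene as
MMR-abrogating or not. The package covers the complete desk-side analysis
layer of the screen plus seeded stochastic simulators of every assay:

- **`mmrscreen.screen`** — per-colony genotype classification (LOH /
  background / confirmed mutant), aggregation of antisense and sense
  targeting rounds, the two-independent-colonies pathogenicity call,
  immunoblot protein quantification, and screen sensitivity/specificity
  with zero-failure lower bounds `100*(n-1)/n`.
- **`mmrscreen.rates`** — slippage-rate estimation from reporter
  fluctuation-assay colony counts by solving `0.6*G = N*p*log(N*p)`
  (bracketed root-finding; natural log by default, base-10 available),
  replicate summaries with below-detection handling, fold changes with
  nearest-10 display rounding, mutagen-induced mutation frequencies, and
  the one-tailed Welch t-test with star annotations.
- **`mmrscreen.simulate`** — seeded simulators: binomial targeting/LOH/
  background survivor model with hypergeometric colony picking
  (calibrated so non-LOH picked fractions average ~40% for abrogating and
  ~6% for neutral variants), a Luria–Delbrück-style fluctuation assay with
  synchronous doubling generations and jackpot clones, Poisson mutagenesis
  counts, and targeting-oligo design (sense/antisense).
- **`mmrscreen.io` / `mmrscreen.pipeline` / `mmrscreen.cli`** — TSV/JSON
  readers and writers with exact round-tripping, stage orchestration, and
  the command-line interface.
- **`mmrscreen.datasets`** — bundled fixture tables transcribing the
  study's 35 screened variants (9 proof-of-principle + 26 of uncertain
  significance) and their picked-colony panels.

## Command-line usage

```sh
# classify colony panels and call each variant
mmrscreen --outdir out classify \
    --variants src/mmrscreen/data/variants.tsv \
    --colonies src/mmrscreen/data/colonies.tsv

# evaluate the calls against the truth labels
mmrscreen --outdir out evaluate --variants src/mmrscreen/data/variants.tsv

# slippage rates with folds and Welch stars against a reference line
mmrscreen --outdir out rates --fluctuation fluctuation.tsv --reference ctrl

# mutagenesis mutation frequencies
mmrscreen --outdir out mnng --mnng mnng.tsv

# simulate a full synthetic dataset (colonies, fluctuation, mnng, truth.json)
mmrscreen --config config.yaml --seed 7 simulate

# collect everything in outdir into a Markdown report
mmrscreen --outdir out report
```

All stages are deterministic under a fixed `--seed`; two runs with the
same configuration produce byte-identical outputs.

## File formats

Tab-separated tables with mandatory headers (see `mmrscreen/io.py`):
`variants.tsv`, `colonies.tsv` (one row per picked colony, `allele_pcr`
in `{both, wt_lost}`, `sequence_call` in `{mut, wt, nt}`),
`fluctuation.tsv` (one row per replicate), `mnng.tsv`. Outputs:
`calls.tsv`, `fractions.tsv`, `rates.tsv`, `mnng_freq.tsv`,
`performance.json`, `report.md`.
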