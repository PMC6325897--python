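# ma-mutkit

Analysis toolkit for mutation-accumulation (MA) experiments in clonal
diploids: de novo SNM / MNM / small-INDEL identification, loss-of-
heterozygosity (LOH) event detection and mechanism classification,
per-generation mutation-rate and spectrum statistics with treatment
comparisons, and life-history mutational parameters (intrinsic rate of
increase, mutational bias, mutational variance / heritability). A
first-class synthetic-experiment generator produces complete MA datasets
with known ground truth so every stage is verifiable offline.

## What's inside

| module | role |
|---|---|
| `ma_mutkit.simulate` | diploid ancestor (~0.7% heterozygosity), per-line SNM/INDEL/LOH planting, read-count table emulation (Poisson depth, binomial alleles, miscalls), life-history records with configured mutational bias and variance |
| `ma_mutkit.calling` | callable-site masks (focal depth >= 6, every other line >= 1), single-divergent-line candidate detection, exact-binomial consistency filtering, het-to-hom routing, MNM grouping (50 bp), small-INDEL calls (< 50 bp) |
| `ma_mutkit.loh` | LOH-callable runs (>= 200 bp, gaps <= 6 bp), Het-Hom site detection, event assembly (>= 2 sites over >= 200 bp, no interior het), min/max/average sizing, multi-scaffold merging by chromosome, gene-conversion vs hemizygous-deletion classification at standardized relative coverage 0.75 |
| `ma_mutkit.rates` | per-line and pooled rates (n / (C x g)), LOH rates (events/gen, bp/gen, per bp/gen), AT-corrected 6-class spectrum chi-squared, spectrum homogeneity, ANOVA / Kruskal-Wallis treatment tests, rate-vs-generations regression |
| `ma_mutkit.lifehist` | partial life tables, Euler-Lotka r (bracketed root; stochastic projection cross-check), anchored weighted-least-squares mutational bias (dM), variance-component CV_m / dCV_m, V_M/V_E, broad-sense H2, treatment-interaction / divergence / Bartlett tests |
| `ma_mutkit.cli` / `io` / `report` | TSV/VCF/BED/CSV readers and writers, YAML config, end-to-end report |

## CLI

```bash
ma-mutkit simulate  --config cfg.yaml --out sim/ --seed 1
ma-mutkit call-snm  --table sim/calls.tsv.gz --meta sim/lines.tsv --alpha 0.05 --eps 0.01 --out calls/
ma-mutkit call-loh  --table sim/calls.tsv.gz --meta sim/lines.tsv --chrom-map sim/chrom_map.tsv --out loh/
ma-mutkit rates     --table sim/calls.tsv.gz --meta sim/lines.tsv --out rates/
ma-mutkit lifehist  --data sim/life_history.csv --out lh/
ma-mutkit report    --config cfg.yaml --out report/ --seed 1   # whole chain
```

Config is YAML with `simulate:` and `run:` sections; every threshold
default matches the published filtering rules (6 reads, 200 bp, 6 bp
gaps, 0.75 coverage ratio, 50 bp windows) and unknown keys are rejected.
Exit codes: 0 ok, 1 validation error, 2 runtime error.

## Conventions

- Coordinates are 0-based half-open internally, 1-based in VCF-style
  output, 0-based half-open in BED.
- Rates are per diploid site per generation (a site counts once, not per
  haploid copy).
- Substitutions collapse to 6 classes keyed by the ancestral base pair
  (A:T vs G:C origin).
- All randomness flows from a single seed; identical seed + config gives
  byte-identical outputs at every stage.
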