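# barnet

Analysis toolkit for barcoded rabies-virus neuroanatomy experiments: from
virus-library sequencing reads and per-cell barcode observations to
multiplexed retrograde projection maps and transsynaptic
barcode-sharing-network inference.

## What it does

- **`barnet.library_tools`** — extract (barcode, UMI) pairs from library
  FASTQ reads between fixed flanks, build UMI-deduplicated barcode frequency
  tables, compute minimum-Hamming-distance profiles, and match observed cell
  barcodes to libraries with a mismatch budget (prefix comparison, 15 of
  20 bases by default; ambiguous two-library matches are a distinct outcome).
- **`barnet.cell_calling`** — cell QC (counts/genes thresholds), linguistic
  sequence complexity filtering, within-cell barcode error correction
  (2-mismatch merge toward the most abundant barcode), count-threshold
  barcode calling with per-cell primary calls, and source/presynaptic role
  assignment from glycoprotein transcript counts (source ≥ 2, exactly 1
  excluded, 0 presynaptic; a `conventional` profile with threshold 12 is
  available).
- **`barnet.network_inference`** — barcode-sharing networks with the
  single-source / multi-source / no-source / lost-source classification
  (lost-source requires ≥ 5 cells), the binomial barcode-multiplicity model,
  a Monte-Carlo posterior over the number of independent infection events
  (uniform prior on [M, C]; exact enumeration for tiny libraries), the
  source-ledger decomposition into single / double-labeled / connected
  pairs, source-detection-fraction bounds, and the
  95%-single-infection barcode-frequency threshold.
- **`barnet.convergence`** — converging-pair counts per subclass pair over
  filtered networks, a random-connectivity expectation scaled to the
  observed total, bias ratios, and permutation p-values from shuffling
  subclass labels over participating cells.
- **`barnet.retrograde`** — projection-target assignment via library
  matching, area × subclass projection matrices, per-cubelet projection
  probabilities, the unweighted variance-explained decomposition
  (area / subclass / type / type-by-area) with a shuffled-area control, and
  the conservative false-positive-rate upper bound (1+FP)/(FP+TN).
- **`barnet.synthetic_data`** — complete synthetic experiments with ground
  truth: log-normal library skew, infections drawn by library frequency,
  negative-binomial presynaptic spread, inter-source connections with
  scaled secondary spread, source death, direct (glycoprotein-independent)
  infection, leaky glycoprotein expression, and per-base read errors. Also
  a null / planted-convergence network generator for calibration studies.

## CLI

```bash
# synthetic experiments (cells.tsv, barcode_reads.tsv, truth.json, library.tsv)
barnet simulate transsynaptic --seed 1 --out sim/
barnet simulate retrograde --seed 1 --out retro/ --projection-prob 0.25

# library quantification and matching
barnet library build --fastq reads.fastq --flank5 ACAAAATGCCGGAGC \
    --flank3 GTCGACTCTAGAGGA --out library.tsv
barnet library match --queries queries.tsv --library lib1.tsv \
    --library lib2.tsv --out matches.tsv

# barcode calling (profiles: retrograde = 6 reads, transsynaptic = 8 reads)
barnet cells call --reads sim/barcode_reads.tsv --cells sim/cells.tsv \
    --profile transsynaptic --out calls.tsv

# networks, posterior, ledger
barnet networks infer --calls calls.tsv --library sim/library.tsv \
    --mc-reps 2000 --seed 1 --out networks/

# convergence
barnet convergence --calls calls.tsv --cells sim/cells.tsv \
    --library sim/library.tsv --n-iter 10000 --seed 1 --out conv/

# retrograde projections
barnet retrograde assign --calls calls.tsv --library retro/library1.tsv \
    --library retro/library2.tsv --site library1=VISal --site library2=LGd \
    --out projections.tsv
barnet retrograde matrix --assignments projections.tsv --cells retro/cells.tsv \
    --out matrices/
barnet retrograde variance --assignments projections.tsv \
    --cells retro/cells.tsv --target VISal --out variance/
```

## Layout

```
src/barnet/          the package (one module per pipeline stage)
tests/               pytest suite; test_acceptance.py holds the criteria
scripts/acceptance.py
```
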