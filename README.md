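# dialibopt

Tools to calibrate and trim *in silico* predicted DIA spectral libraries
against the DIA data they will be used to analyze, and to validate the
resulting libraries with a ground-truth species-mixture benchmark.

## The problem

Peptide-centric DIA analysis extracts signals using a spectral library:
precursors (modified peptide + charge) with annotated fragment-ion
intensities, a normalized retention time (iRT), and protein mappings.
Libraries predicted by fragmentation models are complete but generic —
fragment intensity patterns depend strongly on the instrument's collision
energy (CE), predicted retention times are on the model's own scale, and a
whole-proteome library is far wider than any single experiment detects.
`dialibopt` optimizes a predicted library against the data at hand in four
steps:

1. **CE selection.** Spectra predicted across a CE grid (NCE 20–40, 21
   variants per precursor) are stored in a nonredundant SQLite *warehouse*.
   Observed consensus spectra from a spectrum-centric search of the DIA
   data are compared with every variant using the normalized spectral dot
   product over annotation-matched fragments,

   `dp(x, y) = Σ_matched x_i·y_i / √(Σ x_i² · Σ y_i²) ∈ [0, 1]`,

   and, per peptide-length × charge bin, the CE maximizing the median dot
   product is selected (the CE-LZ policy; a single global fixed CE is also
   available).
2. **RT recalibration (`_RT`).** Anchor peptides with known iRT map the
   observed RT (seconds) to the iRT scale by least squares; a monotone
   piecewise-linear calibration from predicted to observed iRT is fitted on
   a random 25 % of the calibration targets and replaces every library iRT.
3. **Protein subsetting (`_Pr`).** The library is restricted to protein
   groups identified in a relaxed first-pass analysis (5 % protein-level
   FDR by default).
4. **Transition filtering (`_Tr`).** Each spectrum keeps its 6–14 most
   intense fragments; spectra left with fewer than the minimum are dropped.

Libraries are judged with a two-species mixture design: condition A and B
mix two proteomes at inverted ratios (6:1 and 1:6), so every analyte's
cross-condition ratio has a known expectation, and an identification is
*valid* when its observed linear-scale ratio is within ±20 % of it.
Quality metrics cover precision (IQR of log2 fold changes), accuracy
(KDE-mode offset from the expected log2 ratio), and replicate CVs.

A seeded synthetic-data generator (`dialibopt.synthgen`) emulates all
inputs with planted ground truth, so the entire workflow is testable
without instrument data.

## Worked example

```sh
dialibopt simulate --preset ce-recovery --seed 1 --out scratch/sim
dialibopt build-warehouse --in scratch/sim --out scratch/wh.sqlite
dialibopt calibrate-ce --calib scratch/sim/calibration.tsv \
    --warehouse scratch/wh.sqlite --out scratch/ce_map.json
```

which prints

```
wrote 21 CE tables + calibration library to scratch/sim
2400 precursors x 21 CE -> 34000 stored intensity sets (scratch/wh.sqlite)
24 bins (0 fallback), global CE 29 -> scratch/ce_map.json
```

2400 precursors (24 length × charge bins, 100 each) were predicted at 21
collision energies; content-hash deduplication stores the 50 400 spectra as
34 000 distinct intensity sets (the generator's CE response is symmetric
about each optimum, so mirrored energies share a payload). CE calibration
recovers an optimal energy for each of the 24 bins (none fell below the
precursor floor), and the pooled optimum for a fixed-CE workflow is NCE 29. The planted optima are in
`scratch/sim/truth.json` for comparison. The same stages are available as
library functions (`build_warehouse`, `score_all`, `select_ce_per_bin`,
`fit_calibration`, `subset_proteins`, `top_n_transitions`,
`ratio_validate`, …) and as one chained pipeline (`dialibopt run`, or
`dialibopt.run_pipeline`).

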