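# Methods

## Library model and formats

The canonical in-memory model is a keyed set of precursor records
(`(modified_sequence, precursor_charge)` is the key; modification tags such
as `(UniMod:4)` are kept verbatim and never chemically interpreted) with
annotated fragments `(ion_type ∈ {b, y}, ordinal, fragment charge,
intensity, optional m/z)`. Readers accept both the legacy TPP/OpenMS
OpenSwath column names (`FullUniModPeptideName`, `LibraryIntensity`,
`NormalizedRetentionTime`, …) and snake_case synonyms, since exports vary
between toolchains; the iRT is taken from the normalized-retention-time
column, which is where spectrum-centric conversion pipelines place it.
Writers emit rows in a fixed order (precursor key, then ion type, ordinal,
fragment charge) so files are byte-reproducible; fragment m/z values absent
from predictions are filled from monoisotopic residue masses (pyteomics).
Species are inferred from protein accessions via a configurable regex
(default: the `_MOUSE` / `_YEAST` suffix convention).

Prediction-model constraints restrict usable precursors to the 20 canonical
residues, lengths 7–30 and charges 2–3; `filter_predictable` enforces these
and reports removals per reason.

## Spectral warehouse

The warehouse holds one predicted intensity set per precursor per grid
energy (default NCE 20–40 inclusive, 21 variants) plus one
prediction-native iRT. Storage is a single-file SQLite database
(`PRAGMA user_version = 1`) with three content tables: `precursor`,
`payload` (intensity sets keyed by SHA-1 of their canonical JSON), and a
`spectrum` reference table mapping `(precursor, ce)` to a payload.
Identical spectra at different energies therefore occupy one row —
"nonredundant" is realized as content-hash deduplication, and retrieval is
bit-identical with deduplication on or off (tested). Builds fail loudly if
any precursor is missing from some per-CE table or the grid does not match
the supplied tables.

## Collision-energy selection

Observed and predicted spectra are both annotated transition lists, so
fragments are paired by exact annotation rather than m/z-tolerance binning.
The similarity score is the normalized dot product

    dp = Σ_matched I_obs·I_pred / sqrt(Σ_all I_obs² · Σ_all I_pred²),

in which unmatched fragments contribute to the norms only; it is symmetric,
lies in [0, 1] and is invariant under positive rescaling of either
spectrum. Scores are binned by (peptide length, charge); per bin the CE
with the largest **median** score wins (the median follows the per-bin
score distributions this procedure is built around, and is robust to the
skewed tails multiplicative noise produces). Ties break to the lowest CE —
deterministic, and conservative in that lower-energy spectra are less
fragmented. Bins with fewer than `min_bin_n = 20` precursors inherit the
global (pooled-median) optimum and are flagged as fallback; real
calibration data shows hundreds of precursors per bin, so the floor only
guards sparse edge bins.

## Retention-time calibration

Anchor peptides with known iRT values (defaults: the published values of
the 11-peptide commercial iRT kit) define the observed-RT → iRT line by
least squares. Outlier anchors are removed once using externally
studentized residuals (threshold 3) and the line refit; internal
studentization was rejected because a single gross outlier among ~11
anchors inflates the pooled scale enough to mask itself.

The predicted-iRT → observed-iRT calibration is fitted on a uniform random
25 % of the calibration targets (seeded; the sampling scheme is a package
choice, as is the family). The default family is monotone piecewise linear
with 10 quantile knots — knot values are local averages repaired to
monotonicity by pool-adjacent-violators, and extrapolation beyond the
outer knots is linear with the edge-segment slopes. A plain linear fit is
available via `kind="linear"`. The held-out 75 % provides the reported
residual MAD. After PAVA the map may contain flat segments, so rank order
is preserved weakly; a completely flat repair is rejected as degenerate.
`apply_rt` replaces every library iRT and appends the `_RT` provenance tag.

## Scope refinement

First-pass analysis reports are read in the DIA-NN main-report dialect
(`Q.Value`, `PG.Q.Value`, `Protein.Group`, …) with an alias table.
`detectable_proteins` collects protein groups at a relaxed 5 % protein
FDR; `subset_proteins` keeps records sharing an accession with that set
(accession mode, the default, tolerates grouping differences between the
library and the report; exact group-string matching is available).
`top_n_transitions` keeps each spectrum's 14 most intense fragments and
drops records left with fewer than 6 — "6–14" is read as the permitted
final range; `keep_short=True` reverses the drop. Tie-breaks (lower
ordinal, then b before y, then lower fragment charge) are fully
deterministic so written libraries are byte-reproducible.

## Mixture benchmark

Ratios use means of replicate intensities per condition (geometric mean is
exposed; the condition aggregator is a package choice). Validity is the
inclusive band `(1−tol)·r ≤ observed ≤ (1+tol)·r` with `tol = 0.20`,
evaluated with a 1e-9 relative epsilon so exact-boundary ratios are not
lost to floating-point rounding. Preprocessing removes entries with
log2-intensity ≤ 0 (intensity ≤ 1) and can median-normalize runs (each run
scaled so run-level log2 medians equal their grand median). The mode of a
log2 fold-change distribution is the argmax of a Gaussian KDE (Silverman
bandwidth) on a 512-point grid; CV is the per-analyte sd/mean within a
condition's replicates. A deliberately simple per-analyte intensity-sum
quantifier is included for end-to-end synthetic runs; pairwise-ratio
protein quantification (MaxLFQ-style) is out of scope — quant matrices are
inputs.

## Synthetic data generator

The generator plants known answers for every stage:

* **CE response.** Each (length, charge) bin has a true optimum
  `μ = clip(round(22 + 0.4·(L−7) + 5·(z−2)), 20, 40)` — increasing in
  length and charge. Each fragment's intensity follows a Gaussian in CE
  centered at μ, `I_f(c) = base_f · exp(−(c−μ)²/(2σ_f²))`, with
  **per-fragment widths** σ_f drawn uniformly in σ_CE ± 2 (default σ_CE
  = 4). A single shared width would rescale the whole spectrum uniformly,
  which a scale-invariant dot product cannot see; fragment-specific decay
  rates make the relative pattern drift with |c−μ| while every fragment
  still peaks exactly at μ, so similarity to the spectrum at μ decreases
  monotonically with distance (tested). The response is symmetric about μ,
  so mirrored energies produce identical spectra — visible as warehouse
  deduplication.
* **Observed spectra** are the predicted spectra at the bin's true μ with
  multiplicative lognormal noise (σ = 0.15 in the recovery study, the
  level at which per-bin medians over 100 precursors still pin the optimum
  to ±1). Sequences are i.i.d. uniform over canonical residues; base
  intensities are Dirichlet-distributed.
* **Retention times.** True iRT is uniform on [−20, 120]; observed RT in
  seconds is `intercept + slope·iRT` plus an optional tanh component
  (amplitude 400 s in the `rt-recovery` preset — a mild S-shaped
  gradient distortion) and Gaussian noise; predicted iRT carries its own
  linear offset. Anchors are generated at the kit peptides' known iRTs.
* **Quantities.** Analyte base abundance is lognormal (log-mean 1e5);
  condition A scales each analyte by its species ratio (6 for one species,
  1/6 for the other, matching a 6:1 / 1:6 two-proteome design); replicates
  carry multiplicative lognormal noise; an optional planted fraction of
  "bad" analytes is pushed 3× out of band.

Seeding uses one root seed with CRC32-separated substreams per artifact,
so outputs are byte-identical across processes for a fixed seed.

What the generator does *not* emulate: real fragmentation physics (no
mobile-proton or cleavage-site preferences), chromatographic peak shape,
interference/co-elution, missing values, or decoys. Passing recovery tests
therefore demonstrates the estimators are correct and well-conditioned
under the stated noise model — not that the selected CE or calibrated RT
would match any particular instrument.

## Pipeline and determinism

`run_pipeline` applies the stages in the fixed order CE → RT → protein →
transitions; the provenance JSON records package version, configuration,
and per-stage in/out counts. Variant names concatenate the stage tags
(e.g. `CE-LZ_RT_Pr_Tr`). Any stage failure raises an error naming the
stage with the preceding stages' library attached, so partial outputs can
be retained. With identical inputs, configuration and seed, the written
library and metric files are byte-identical (tested).

## Problem sizes

Study-scale runs in the tests and the acceptance script use 24 bins × 100
precursors × 21 energies (50 400 spectra) for CE recovery, 160 targets for
RT recovery, and 2 000 analytes for the mixture benchmark — sizes at which
all planted parameters are comfortably identifiable while a full run
completes in well under a minute each.

## Known limitations

* The noisy-validity analytic cross-check uses one run per condition,
  where the log-ratio error is exactly N(0, 2σ²); means of several
  lognormal replicates have no closed-form band probability.
* The piecewise RT map is continuous but not smooth; quantile knots can be
  sparse in the iRT tails, where the fit degrades to the edge-segment
  line.
* Protein subsetting assumes the library and report share an accession
  space; a complete mismatch is detected only as the zero-retained error.
* The CE grid is integral and selection is per-bin argmax; no interpolation
  between grid energies is attempted.
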