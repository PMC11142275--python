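# Methods

Models, parameter choices, numerical conventions, and limitations of the
`cytosar` package. Problem sizes quoted here were chosen to fit a single
CPU; all are configuration, not code.

## Synthetic data model

The generator produces per-well event tables with ground truth on every
event; it is the package's validation substrate, not a biophysical
simulator.

- **Markers.** Eleven functional readouts (p-AKT, p-ERK1/2, p-S6 S235/236,
  p-S6 S240/244, p-4EBP1, γH2AX, Ki67, p-HH3, p-STAT3, p-STAT5, c-CAS3).
  Per-cell values are drawn normal on arcsinh scale (baseline location in
  [0.6, 1.6], spread in [0.25, 0.4], fixed per panel), then mapped to raw
  fluorescence by `sinh(z) * cofactor` and floored at 0. Default cofactor
  6000; overrides: Ki67 and p-STAT5 25000; p-S6 (both sites), p-STAT3,
  p-HH3, p-4EBP1 12000; barcode dyes 150.
- **Effect signatures.** A treatment shifts chosen markers additively on
  arcsinh scale. Built-in subclass signatures: regular rocaglates (RR):
  γH2AX +0.6, c-CAS3 +0.4, p-ERK1/2 −0.3; amidino-rocaglates (ADR):
  γH2AX −0.3, p-4EBP1 −0.4, p-AKT +0.6, p-STAT5 +0.6; rocaglate
  pyrimidinones (RP): γH2AX +1.2, p-4EBP1 +0.3, p-ERK1/2 −0.6, c-CAS3
  +0.5, plus a rare *island* (default fraction 0.025) with γH2AX +2.5,
  p-4EBP1 +1.5, Ki67 +0.8, p-ERK1/2 +0.8, p-S6 S240/244 +0.8; cytotoxic
  controls: c-CAS3 +1.0, γH2AX +0.4. Island membership is a per-event
  Bernoulli draw recorded in the `gt_island` ground-truth channel.
- **Scatter, viability, uptake.** FSC-A/FSC-H/SSC-A and the two QC dyes
  are log-normal. Doublets (default 3%) double area channels but not
  height, so the FSC-A/FSC-H ratio gate removes them; `gt_doublet`
  records the truth.
- **Barcoding.** 8 × 6 two-dye intensity grid (48 wells). Dye levels are
  normal on arcsinh scale, centers `1.0 + 0.5 * level`, spread 0.08
  (centers sit 6.25 standard deviations apart), optional 2 × 2 spillover
  mixing. Measured debarcoding accuracy at these settings is ~99.9% with
  <1% of events unassigned at confidence 0.9.
- **Dose-response wells.** One well per dose; each cell is marker-positive
  with probability given by a true 4PL curve, positives shifted +4.0
  arcsinh units; `gt_positive` records the truth, and
  `positive_cutoff()` returns the midpoint threshold the readout uses.

Scope: the generator makes *independent* Gaussians per marker — no
marker-marker covariance, no acquisition drift, no spectral spillover
beyond the optional barcode-dye mixing, no dead-cell autofluorescence.
It is sufficient to validate the estimators' correctness, not to
benchmark their robustness to instrument artifacts.

## Preprocessing

- Arcsinh scaling `asinh(x / cofactor)` applies to functional channels by
  default; the table records which channels are scaled, and double
  scaling raises.
- QC gates (ratio, rectangle, threshold) apply sequentially; the report
  lists events in/passed/removed per gate. Default singlet gate:
  FSC-A/FSC-H ratio in [0.75, 1.25].
- Well summaries report medians, IQRs, and arbitrary percentiles per
  marker, with explicit NaN rows (and a warning) for expected-but-empty
  wells.

## Debarcoding

Per-dye 1-D Gaussian mixtures (spherical, one component per level,
quantile-initialized, fixed seed, `reg_covar` 1e-6). A fitted weight
below 1/(20 · levels) fails loudly, naming the dye. Events are assigned
to the per-dye posterior argmax; assignment confidence is the product of
the dye posteriors, and events below `min_confidence` (default 0.9) stay
unassigned rather than guessed.

## T-REX (KNN enrichment)

- Equal subsampling without replacement per condition (if one group is
  smaller, all groups downsample to it, logged).
- Default embedding: scikit-learn Barnes–Hut t-SNE, perplexity 60, early
  exaggeration 12, PCA initialization, `learning_rate="auto"`, fixed
  seed. UMAP is a selectable backend. Degenerate inputs (all rows
  identical) receive a 1e-6 seeded jitter because the Barnes–Hut tree
  cannot partition coincident points.
- Neighbor search is exact: chunked pairwise squared distances with a
  stable argsort, so distance ties break by event index and results are
  bit-reproducible. scikit-learn's neighbor searches do not define tie
  order, which is why this primitive is hand-rolled.
- A cell is a "red" hotspot when ≥ 95% of its k = 60 nearest neighbors
  are from the test condition, "blue" when ≤ 5%; degree of difference
  D = (red + blue) / total.
- Island gates are simple polygons; membership uses the even-odd crossing
  rule with half-open edges so shared boundaries are never double-counted.
  Self-intersecting or <3-vertex polygons raise. Empty groups are
  reported as missing, not 0%.

### Embedding iteration budget

Published cytometry workflows often run ~10,000 t-SNE iterations; on one
CPU that is ~90 min for 20,000 cells and adds nothing to the analyses
here. The package default is 750 gradient-descent iterations (the
scikit-learn default family). The vehicle-null acceptance computations
use 250 iterations: at 20,000 cells that is ~75 s per embedding versus
~400 s at 750. The null result is invariant to the iteration count —
the two samples are exchangeable draws from one distribution, so no
embedding at any refinement can separate them beyond the hotspot cutoffs;
measured D is 0.0% at both 250 and 750 iterations.

## MEM

Raw score per marker: `|MAG_pop − MAG_ref| + IQR_ref / IQR_pop − 1`,
negated when `MAG_pop < MAG_ref` (magnitudes are arcsinh-scale medians).
Conventions:

- Zero population magnitude (|median| ≤ 1e-12) zeroes the whole score,
  including the IQR term.
- Zero population IQR is floored at 0.5 and the marker flagged.
- The statistical-null reference has magnitude 0 for every marker and IQR
  equal to the median feature IQR of the population; a population
  reference takes its own medians/IQRs.
- Scale normalization maps scores to ±10 by dividing by the largest
  |raw| score — hence the top-enriched marker of any population scores
  exactly ±10.
- Labels render markers with |scaled| above a threshold (default 5),
  sorted by descending rounded score then name: `γH2AX+10, p-4EBP1+7`.

## Screening statistics

- Fold change: difference of arcsinh-scaled medians (0 = no change,
  antisymmetric). An `arcsinh_ratio` variant is provided for comparison
  but maps "no change" to asinh(1) ≠ 0.
- Hit threshold: vehicle median + 3 × IQR over pooled vehicle fold
  changes (default) or per readout; a compound is a hit when any readout
  strictly exceeds it.
- Rank-sum test: exact Mann–Whitney enumeration when the pooled sample is
  ≤ 12 and tie-free, otherwise the normal approximation with midrank-tie
  and continuity corrections; identical constant samples give p = 1.
- 4PL: `f(x) = c + (d − c) / (1 + (x/e)^b)`, fit by Levenberg–Marquardt
  least squares over `(b, c, d, log e)` so EC50 stays positive. Dose 0
  is evaluated as the limit (d for b > 0, else c). The parameterization
  has the identity `(b, c, d) ≡ (−b, d, c)`; fits are canonicalized to
  c ≤ d. Needs ≥ 5 distinct dose levels; constant responses raise.
- Clustered heatmaps: scipy hierarchical clustering (average linkage,
  Euclidean), inputs sorted by label first so leaf order is permutation
  invariant; missing values are imputed as 0 (= no change) and counted.

### Hit-calling false-positive rate

The median + 3 × IQR rule is not a guaranteed-zero-false-positive rule.
With many vehicle wells the per-well probability that a held-out vehicle
exceeds the threshold on at least one of 11 readouts plateaus near
5 × 10⁻⁴ (a ~4σ-equivalent bound applied to the max of correlated
readouts). With only 3–4 vehicle wells, IQR sampling noise raises this
to ~1–2% per trial, measured empirically on the generator. Screens
wanting a hard guarantee need more vehicle wells, not a different rule;
the test suite exercises the well-estimated regime (16 vehicle wells).

## Pipeline and reproducibility

`run_pipeline` derives one sub-seed per stage from
`numpy.random.SeedSequence(seed)` (all sub-seeds < 2³¹) and writes
`manifest.json` with the package version, every seed, and every
threshold. Outputs: plate map, QC report, per-compound screen summary
with hit flags and percent-positive, chemotype composition, per-subclass
T-REX summaries, the island MEM label when ≥ 50 red-hotspot cells exist,
and optional dose-response fits. `make_report` renders a Markdown report
idempotently and notes omitted stages.

## Problem sizes and runtimes (one CPU)

| Task | Size | Time |
| --- | --- | --- |
| t-SNE embedding, 250 iter | 20,000 × 11 | ~75 s |
| t-SNE embedding, 750 iter | 20,000 × 11 | ~400 s |
| Exact KNN (k = 60) | 20,000 cells | ~45 s |
| Debarcode 48 wells | 48,000 events | ~5 s |
| Full pipeline, default config | 48 × 2,000 cells | ~10 min |
| Full test suite | — | ~15 min |
| Acceptance script | 5 null embeddings | ~11 min |

## Limitations

- Synthetic data only; FCS I/O is a minimal float32 list-mode
  reader/writer with package-specific keywords for roles, cofactors, and
  annotations — it round-trips its own files and plain list-mode FCS 3.1,
  not vendor extensions (spillover matrices, log amplification, int/double
  data types).
- The generator's independence assumptions (see above) understate real
  marker covariance; T-REX D values on synthetic treated-vs-vehicle
  comparisons are therefore cleaner than on instrument data.
- Barnes–Hut t-SNE is approximate (θ = 0.5) and its layout depends on
  the seed; only seed-fixed runs are reproducible, and neighbor
  *fractions*, not coordinates, are the supported statistic.
- The exact rank-sum path enumerates only small samples (≤ 12 pooled);
  larger samples use the asymptotic approximation.
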