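# Methods

`muroct` quantifies retinal structure in volumetric mouse OCT: it segments
each B-scan into ten classes (vitreous, eight retinal layers or layer
aggregates, sub-RPE tissue), projects the per-sample classification onto
anatomically valid boundary surfaces, converts boundaries to en-face
thickness maps in micrometres, screens every A-scan with three quality
criteria, summarises the maps over a 3 x 3 grid of regions of interest
(B1–B9) plus the whole imaged area, accumulates those summaries into a
normative database stratified by group, age, eye, layer and region, and runs
the longitudinal statistical battery. A synthetic phantom generator stands in
for the scanner so that every stage can be validated against known ground
truth.

## Volume geometry and units

A volume is a stack of `n_bscans` B-scans of `n_ascans` A-scans with
`n_samples` axial samples (default 512 x 512 x 1024). The axial scale is
1.4 mm of imaging depth over the sampled range, i.e. 1.3672 um per sample at
the default depth; reduced volumes keep the physical depth and coarsen the
sampling. En-face row 0 is superior; after left-eye mirroring, the left half
of every map is temporal. Lateral units remain grid points (no lateral
calibration is attempted).

## The synthetic phantom

Each phantom retina is eight stacked layers. The thickness of layer *k* at
en-face position (r, c) and age *a* is

    t_k(r, c, a) = base_k(a) + g_k (r/(R-1) - 1/2) + s_k (1/2 - c/(C-1)) + u_k,

floored at 1 um, where `base_k(a)` interpolates the published longitudinal
group means piecewise-linearly through the seven imaged ages (1, 2, 3, 4, 8,
12, 16 months), `g_k` is a superior->inferior gradient (inner layers thicken
toward the optic disc below the imaged patch; OPL, photoreceptor segments and
RPE thicken away from it; TRT totals +8 um), `s_k` a temporal->nasal
asymmetry (temporal thicker, +4 um on TRT), and `u_k ~ N(0, sd_k)` a
per-(animal, layer) effect that persists across ages and eyes, with `sd_k`
taken from the published SD columns (averaged over ages). Both spatial terms
are centred, so the grid mean of every field equals `base_k(a)` exactly —
this is the calibration the tests assert to 0.01 um. Gradient and asymmetry
amplitudes are plausible magnitudes read off the published en-face maps, not
fitted values.

Boundary 0 (vitreous-RNFL) carries a deterministic tilt (30 um
superior-inferior, 12 um temporal-nasal across the grid). The tilt cancels
out of every thickness difference; its purpose is realism — an acquired
retina never lies flat in the scan window — and it keeps the fractional parts
of boundary positions wrapping across the grid, so integer-sample boundary
quantisation averages out of grid means instead of biasing them.

Rendering assigns sample `s` of an A-scan to class `k` iff `b_k <= s <
b_{k+1}` and draws its intensity as `reflectivity_class x Gamma(1/sigma^2,
sigma^2)` (unit-mean multiplicative speckle, default sigma = 0.2, a moderate
level consistent with frame-averaged small-animal OCT), scaled to uint16.
The default reflectivity ladder (0.04, 0.85, 0.50, 0.20, 0.55, 0.14, 0.38,
0.62, 0.95, 0.12 for vitreous, the eight layers and sub-RPE) mimics the
alternating bright/dark banding of rodent scans; every adjacent interface has
Michelson contrast >= 0.2, and with default speckle the quality screen
excludes about 4–6% of A-scans — the same range as the per-block exclusion
percentages reported for real acquisitions. Left-eye volumes are rendered
with temporal on the right, so the mirroring rule downstream is meaningful.

Corruption, for QC testing, either flattens a chosen fraction of A-scans to
their own mean (zero boundary contrast) or zeroes them, optionally inside a
region mask.

What the phantom does **not** model: vessel shadows, motion artifacts,
within-volume spatial noise covariance, optical light propagation, or the
optic disc itself (the imaged patch sits directly above the disc; its
proximity appears only as the linear gradient). Tests passing on phantoms
therefore validate the machinery — geometry, calibration, QC logic,
statistics — not robustness to those real-data effects.

## Segmentation network

A small U-type fully convolutional encoder-decoder, implemented directly on
numpy (im2col convolutions, explicit backward passes, Adam): `depth` = 3
pooling levels, two 3 x 3 convolutions + ReLU per level, channel widths
8-16-32-64, nearest-neighbour upsampling with skip concatenation, and a 1 x 1
output convolution over 10 classes. Inputs are two channels: the B-scan
normalised by its 99.5th intensity percentile, and a normalised axial-depth
coordinate that anchors classes whose reflectivity alone is ambiguous.
Training minimises pixel-wise softmax cross-entropy, one B-scan per step,
learning rate 3e-3, 30 epochs by default (20 suffice for the desk-scale runs;
the loss trajectory is recorded on the model). Weight initialisation and
shuffling derive from the config seed, so runs are bit-reproducible on a
fixed backend. At desk scale (32 training B-scans of 128 x 256) the held-out
mean foreground Dice exceeds 0.98 after 20 epochs.

No transfer to real scanner data is claimed; the network is trained and
evaluated on phantoms only.

## Monotone boundary projection

Per-sample classifications need not respect layer order. For each A-scan
with per-class scores `S[s, c]` (softmax probabilities, or 1/0 for hard
labels) the projection finds cuts `0 <= c_0 <= ... <= c_8 <= n` maximising
the total score of the induced monotone labelling. A suffix dynamic program
`T[s][c] = max(S[s][c] + T[s+1][c], T[s][c+1])` (O(n x classes)) gives the
optimum; a greedy forward walk that advances the class as early as the suffix
values permit returns the lexicographically smallest optimal cut vector
(layers pushed upward), making ties deterministic. Boundaries are integer cut
indices; no sub-sample refinement. The implementation is validated against
exhaustive enumeration of all monotone cut vectors on small instances,
including the tie-break.

## Thickness and quality control

Layer thickness is `(b_{k+1} - b_k)` and total retinal thickness
`(b_8 - b_0)`, both times microns-per-sample, so TRT is the sum of the eight
layers by construction. A-scans with crossing boundaries are marked invalid,
never negative.

Three criteria screen each A-scan; failing any one excludes it:

1. **Contrast** — across each boundary, the Michelson-style contrast
   `|I_below - I_above| / (I_below + I_above + eps)` of mean intensities over
   axial windows of at most `w = 3` samples must reach `c = 0.05`. Windows
   are clipped to the extent of the adjoining layer: a fixed window would
   leak across layers thinner than `w` and report spuriously low contrast on
   perfectly clean data.
2. **Consistency** — a boundary that differs from **all four** neighbouring
   A-scans by more than `J = 15` samples is a segmentation glitch. Requiring
   disagreement with every neighbour flags the displaced A-scan without
   flagging its (healthy) neighbours.
3. **Distribution** — per layer, a robust z-score against the volume's own
   median and MAD must stay within `z* = 4`. The MAD is floored at one axial
   sample (in um): integer cuts quantise near-flat layers to a single
   dominant value, MAD collapses to zero, and without the floor the A-scans
   one quantisation step away — precisely those carrying the sub-sample
   information — would all be discarded.

The published pipeline names these three criteria but not their formulas or
thresholds; the forms above are this package's surrogates, with every
threshold exposed in `QCParams` and logged in output metadata.

Left-eye maps are mirrored (columns reversed), the map is cropped by one
pixel per side (512 -> 510, the unique symmetric crop), and partitioned into
3 x 3 equal blocks, B1 top-left (superior-temporal) to B9 bottom-right,
row-major. A block is discarded entirely when its excluded fraction is
strictly above 10% (2890 of 28900 excluded A-scans retain the block; 2891
drop it). Block means/SDs use retained A-scans only; the whole-area summary
uses every retained A-scan of the crop regardless of block fate. Any grid
whose trimmed dimensions divide by 3 is accepted, which lets reduced phantoms
(e.g. 128 -> 126 -> 3 x 42) exercise the identical code path. No
interpolation is performed over excluded A-scans.

## Normative database and deviation scores

Entries are means/SDs **across volumes** (never across A-scans) per group x
age x eye x layer x region, with the raw per-volume values retained. Eyes are
kept separate by default (an option pools them, matching the published
overall tables). Kernel-density summaries use a Gaussian kernel with
Silverman's bandwidth (scipy), a minimum bandwidth for degenerate
zero-variance input, and quartiles always computed from the empirical values.
Longitudinal block maps are min-max normalised per layer across all
(block, age) cells; a constant layer maps to 0.5 by convention. The published
figure this emulates does not define its normalisation; the choice is
recorded in the database metadata.

A subject's block value `x` is scored against its matched entry as
`z = (x - mean)/sd` with two-sided Gaussian tail probability
`p = 2(1 - Phi(|z|))`, flagged when `p < alpha`. The Gaussian form is
justified by the observation that the overwhelming majority of thickness
distributions pass the normality screen; a nonparametric percentile mode
(rank among the raw normative values) is provided. Blocks without a usable
entry (missing, n < 2, zero SD) are reported not-evaluable and never flagged.
Under the null the flag rate calibrates to alpha within binomial error.

## Statistics

* **Normality** — Kolmogorov-Smirnov with estimated mean/SD (Lilliefors
  situation), alpha = 0.10. Because the classical KS table is invalid with
  estimated parameters, the null distribution of the statistic is simulated
  (m = 2000 replicates, seeded, cached per sample size); `p = (1 + #{D_null
  >= D_obs}) / (m + 1)`. Zero-variance samples are never normal.
* **Two-group comparisons** — Welch's t-test (unequal variances; group SDs
  plainly differ, and Welch is the safe default — a pooled option exists via
  scipy) when both samples pass the screen, Mann-Whitney U otherwise (exact
  distribution for tie-free samples up to n = 20, normal approximation with
  tie correction beyond). Bonferroni correction with m = 8 for the eight
  layers compared at each time point; TRT is its own single-test family.
  `welch_from_summary` reproduces the test from printed mean/SD/N triples.
* **Longitudinal** — complete cases only (subjects measured at every
  requested age). One-way repeated-measures ANOVA with subjects as blocks
  (F = MS_time / MS_(time x subject)), computed from the sum-of-squares
  decomposition in-module (degenerate inputs — constant tables — need exact
  handling); the Friedman test replaces it when any time point fails the
  screen. No sphericity correction by default (a Greenhouse-Geisser option
  exists). The two-way (mixed-design) ANOVA for group, time and group x time
  delegates to `pingouin.mixed_anova`.
* **Post-hoc** — Tukey-Kramer on the repeated-measures error term:
  `q = |mean_i - mean_j| / sqrt(MS_err / n)` referred to the studentized
  range distribution with k levels and (k-1)(n-1) df. At k = 2 this reduces
  exactly to the paired comparison on the same error term.
* Significance levels 5%, 1%, 0.1% throughout, reported as stars.

All tests are calibration-checked under matched null simulations (type-I
error within two binomial standard errors of nominal at 500 replicates;
Tukey-Kramer family-wise error <= 0.07 at alpha = 0.05).

## Problem sizes and determinism

The test and acceptance runs use reduced volumes — 32–128 B-scans, 128
A-scans, 256–512 samples — which preserve the full code path (8-layer
anatomy, QC, 3 x 3 blocks) at desk scale; the defaults for real-geometry
volumes remain 512 x 512 x 1024. Every source of randomness (phantom
rendering, cohort effects, network initialisation and shuffling, Monte-Carlo
nulls) flows from explicit seeds, and the pipeline's tabular outputs are
byte-identical across runs with the same configuration.

## Known limitations

* The QC formulas and the abnormality score are declared surrogates: the
  published pipeline references unpublished criteria and prior work for both.
* The phantom's between-animal variation is a single additive effect per
  (animal, layer); real longitudinal covariance is richer, so the
  repeated-measures simulations probe correctness of the tests, not their
  power on real data.
* Boundaries are integer sample indices; per-A-scan thickness is quantised at
  the axial sampling (grid averages are unbiased thanks to the tilt, but
  single-A-scan values are not sub-sample accurate).
* B-scan file order is taken as lexicographic filename order, and en-face
  orientation conventions are fixed by this package; no claim is made that
  they match any particular scanner export.
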