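# muroct

Quantification of murine retinal structure from volumetric OCT: layer
segmentation, en-face thickness mapping with quality control, normative
thickness databases, and longitudinal group statistics — together with a
calibrated synthetic phantom generator, so the entire pipeline is testable
without animal data.

## The problem

Optical coherence tomography images the mouse retina as a volume of 512
B-scans × 512 A-scans × 1024 axial samples (1.4 mm depth, ≈1.37 µm per
sample). Tracking how the thickness of the retina and of its layers changes
with age — and how a disease model departs from wild-type — requires:

1. classifying every axial sample into one of ten classes: vitreous, the
   eight retinal layers/aggregates (RNFL-GCL, IPL, INL, OPL, ONL, ILS, OLS,
   RPE, inner to outer), and sub-RPE tissue, with a small U-type
   encoder–decoder network;
2. projecting the per-sample classification onto anatomically valid
   boundary surfaces b₀ ≤ b₁ ≤ … ≤ b₈ (a dynamic program maximising the
   classification score over all monotone labelings, O(n·classes) per
   A-scan);
3. converting boundaries to µm thickness maps, tₖ = (b₍ₖ₊₁₎ − bₖ)·µm/sample,
   TRT = (b₈ − b₀)·µm/sample, screening each A-scan for boundary contrast,
   neighbour consistency and distributional outliers, mirroring left eyes,
   and summarising a central 510 × 510 crop over 3 × 3 blocks B1–B9
   (a block is dropped when >10% of its A-scans fail QC);
4. building a normative database (mean/SD/N per group × age × eye × layer ×
   region, across volumes) that supports kernel-density summaries and
   per-subject deviation probabilities p = 2(1 − Φ(|x − µ|/σ)); and
5. the statistical battery: Kolmogorov–Smirnov normality screening at 10%
   (Monte-Carlo null, parameters estimated), Welch's t / Mann–Whitney U with
   Bonferroni correction across layers, complete-case repeated-measures
   ANOVA or Friedman over age, mixed-design ANOVA for group × time, and
   Tukey–Kramer post-hoc comparisons on the studentized range.

Phantom retinas with exact ground-truth boundaries emulate the acquisitions:
per-layer age trajectories calibrated to published longitudinal group means,
a superior→inferior gradient toward the optic disc, temporal→nasal
asymmetry, persistent per-animal random effects, multiplicative gamma
speckle, and optional corrupted A-scans for exercising QC.

## Worked example

End-to-end on a simulated cohort (two groups, eight animals each, both eyes,
reduced 32 × 128 × 256 volumes):

```python
from muroct import PipelineConfig, run_pipeline
from muroct.config import CohortConfig

cfg = PipelineConfig(
    seed=7,
    out_dir="demo_out",
    cohort=CohortConfig(groups=["WT", "3xTg-AD"], ages=[1], n_animals=8,
                        shape=(32, 128, 256)),
)
paths = run_pipeline(cfg)
```

`demo_out/group_means.csv` then holds the group × age table (mean (SD) µm
per layer over the whole imaged area, eyes pooled):

```
  group  age_months  RNFL-GCL          IPL  ...          RPE           TRT
     WT           1  13.90 (0.79)  50.34 (1.19)  21.14 (1.72)  211.29 (4.39)
3xTg-AD           1  13.04 (0.73)  47.74 (0.75)  19.54 (1.50)  201.32 (2.53)
```

i.e. the simulated transgenic cohort is ≈10 µm thinner in total retinal
thickness, and `demo_out/stats_report.csv` reports the per-eye Welch test of
that gap (OS: t = −5.36, p = 2.2 × 10⁻⁴, `***`). Per-volume block summaries,
the normative database and pairwise longitudinal matrices are written
alongside.

Single steps are plain functions. Testing a printed summary pair directly:

```python
from muroct import welch_from_summary
res = welch_from_summary(199.17, 3.96, 59, 194.98, 4.51, 78)
# -> t = 5.774, df = 132.0, p = 5.27e-08, stars '***'
```

A CLI mirrors the pipeline (`muroct simulate | train | segment | thickness |
normative | stats | run-all`, with `--config`, `--seed`, `--out`).

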