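# tilquant

Quantitative, machine-learning scoring of tumor-infiltrating lymphocytes
(TILs) in H&E histology, with optimal cut-point discovery and survival
analysis. Built for pathology and biomarker researchers who want a
reproducible, pathologist-independent TILs measurement — particularly in
muscle-invasive bladder cancer, where visual TILs scoring suffers from
inter-observer variability — and for methodologists who want every stage of
such a pipeline testable against exact synthetic ground truth.

## What it computes

The pipeline follows the stages of a cell-level TILs analysis:

1. **Stain deconvolution** — per-channel optical density
   `OD = −log₁₀(I/I₀)` is additive across stains (Beer–Lambert); per-image
   H&E stain vectors are estimated from the dominant plane of foreground OD
   pixels and the image is unmixed into hematoxylin/eosin density channels.
2. **Watershed cell detection** on the hematoxylin OD channel at a 0.5 µm/px
   working resolution (background radius 8 µm, Gaussian σ 1.5 µm, OD
   threshold 0.1, nucleus area 10–400 µm², maximum background intensity 2),
   with non-overlapping cell boundaries from a distance-limited Voronoi
   expansion.
3. **Per-cell features** — intensity statistics per compartment
   (nucleus/cell/cytoplasm) and stain, nucleus shape descriptors, and
   Gaussian-weighted neighbourhood-smoothed variants at 25 µm and 50 µm.
4. **MLP cell classification** into tumor / immune / stroma / ignore.
5. **The four TILs variables** from classified counts T (TILs), U (tumor),
   S (stroma) in an analyzed area A (mm²):

   | variable | definition |
   |---|---|
   | eTILs%  | 100 · T / (T + U) |
   | esTILs% | 100 · T / (T + S) |
   | etTILs% | 100 · T / (T + U + S) |
   | eaTILs  | T / A  (per mm²) |

6. **Optimal cut-point** — the maximally selected log-rank statistic scanned
   over all admissible thresholds (X-tile style), with Miller–Siegmund
   multiplicity-corrected p-values (or a seeded permutation null).
7. **Survival** — Kaplan–Meier with Greenwood CIs, and Cox
   proportional-hazards models (Efron ties, Newton–Raphson) for univariate
   and covariate-adjusted hazard ratios.

Because real cohort slides are not distributable, a first-class synthetic
module generates (a) H&E-like tiles from a Beer–Lambert rendering of
class-specific nuclei with exact truth tables, and (b) proportional-hazards
cohorts whose hazard depends on a dichotomized TILs score — so every stage,
from pixels to hazard ratios, is validated by parameter recovery.

## Worked example

```
$ python examples/05_cutpoint_and_survival.py
recovered cut-point: 13.35% (true change-point 13.2%)
log-rank chi-square 77.6, corrected p 2.15e-16 (raw 1.25e-18; correction pays for scanning 305 candidate thresholds)
24-month survival: high-TILs 0.79, low-TILs 0.38
univariate eTILs HR 0.306 (95% CI 0.232-0.404)
multivariate eTILs HR 0.293 (adjusted for age, pT, pN, stage, LVI)
HR < 1: high TILs associate with longer overall survival.
```

A cohort of 380 synthetic patients is generated with a true eTILs
change-point at 13.2% (hazard 3× higher below it). The scan re-discovers the
threshold at 13.35%, the Kaplan–Meier curves separate strongly at 24 months,
and the Cox hazard ratios ≈ 0.3 mean the high-TILs group dies at under a
third of the low-group rate — the adjusted estimate shows the effect is not
explained by age, stage or lymphovascular invasion.

The other examples cover each capability on its own: stain deconvolution
(`01`), cell detection against ground truth (`02`, precision/recall 1.000 on
the default 200-cell scene), classifier training (`03`, held-out accuracy
0.975), TILs scoring and region pooling (`04`), and the full
pixels-to-eTILs pipeline (`06`, per-patient error ≤ 0.34 points). A thin
`tilquant` CLI exposes the same stages (`tilquant simulate tile`,
`segment`, `score`, `cutpoint`, `survival`, `run`).

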