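# Methods

This note documents the models, parameter choices and numerical decisions
behind `isoscreen`, and what the synthetic-data generator does and does not
emulate.

## Screen normalization and hit calling

Signals are normalized to the **Inhibition score**
I = (1 − signal/median(DMSO)) × 100. The DMSO median is computed **per
plate** by default: control wells share plate-level effects (dispensing,
reader gain, edge temperature) with the treated wells on the same plate, so
a per-plate baseline cancels them; a per-run pooled baseline is available
via `score_screen(pool="run")`. The median of an even number of controls is
the mean of the central two values. I-scores are never clipped — negative
values record growth stimulation and are informative for hit calling.

Replicates are aggregated as the mean of per-well I-scores with the sample
standard deviation (ddof = 1; 0 for a single replicate). Because the
I-score is affine in signal, averaging per-well scores equals scoring the
averaged normalized signal, so aggregation order is immaterial; the test
suite verifies this on a noiseless screen.

Efficacy and selectivity thresholds are **strict** inequalities at 50:
efficacious ⇔ max over the panel > 50; line-selective ⇔ > 50 in exactly one
line and < 50 in all others. A score of exactly 50 passes neither side, so
such compounds fall to `other_selective_pattern` (or `inactive`); the
threshold is configurable. When two screened doses are present, the profile
matrix defaults to the max over doses per line — a compound active at
either dose counts — and the aggregation rule is recorded in the profile
metadata.

Profiles are clustered by complete-linkage agglomeration on Euclidean
distances between compound rows, implemented in-package so the tie-break is
deterministic: among equal-distance candidate pairs, the pair whose
smallest member ids sort first merges first, and at every merge the cluster
containing the lexicographically smaller id becomes the left child. Merge
heights are checked against both an O(n³) brute-force oracle and
`scipy.cluster.hierarchy.linkage(method="complete")` in the tests.

## 4PL dose-response

Viability is modeled as v(d) = bottom + (top − bottom)/(1 + (d/ec50)^hill).
The optimizer (Levenberg–Marquardt via `scipy.optimize.least_squares`)
works in (bottom, log span, log hill, log ec50) coordinates, which enforces
top ≥ bottom, hill > 0 and ec50 > 0 without explicit bounds.
Initialization: top = max response, bottom = min response, ec50 =
geometric-mean dose, hill = 1, with one restart from a perturbed start.
Constant responses, vanished spans (< 10⁻³ %) or midpoints more than 10⁴×
outside the dose range are flagged degenerate and unconverged. Fits are
unconstrained by default; `bottom=0, top=100` can be pinned for constrained
fits.

Two potency readouts are kept distinct deliberately: **ED50 ≡ ec50** (the
relative midpoint) and **absolute IC50**, the closed-form solution of
v(d) = 50, defined only when bottom < 50 < top. They coincide only for
(bottom, top) = (0, 100). Line selectivity is flagged at fold =
ed50_reference/ed50_target ≥ 10, inclusive at exactly 10. The modulator
shift is IC50(alone)/IC50(+modulator), > 1 meaning sensitization.

## Bliss Independence

"Response" is fractional inhibition f = clip(1 − viability/100, 0, 1) —
the clipping keeps f inside the probabilistic domain of the Bliss union
formula E = f_A + f_B − f_A·f_B; raw viabilities remain available in the
matrix files for audit. The combination index is the difference
CI = E − observed (not a ratio), which reproduces the conventional sign
rule: CI < 0 synergy, CI > 0 antagonism. Expected values are computed from
the single-agent margins of the same replicate-averaged matrix. Interior
cells where either single agent already inhibits ≥ 99% are flagged
saturated and excluded from the mean/min summaries, since E is pinned near
1 there and the score is numerically meaningless. Per-cell scores and the
aggregate summaries are both emitted.

## Direct-target calling

Peaks are shortlisted at fold enrichment ≥ 5 and pileup ≥ 25 (inclusive)
with q < 0.01 (strict). Coordinates are 0-based half-open; peak–TSS
distance is 0 for containment, otherwise the distance to the nearest peak
boundary (start or end − 1). Summit positions are not part of the record
schema, so boundary anchoring is the natural choice. A gene is called when
distance < 10 000 bp (strict) and |log2FC| > 1.5 (strict, absolute —
both induced and repressed genes qualify; the sign is retained in the
output). The per-chromosome search is vectorized over sorted peak arrays;
its contract is exact agreement with an all-pairs oracle, which the tests
enforce at 100 × 100 scale. Genes present in the DEG table but missing
from the TSS table are skipped with a warning.

## Synthetic-data generator

The generator is first-class package code and defines the study conditions
for the acceptance-level tests.

* **Truth model.** Per-compound, per-line Hill inhibition
  f(d) = emax·d^h/(ed50^h + d^h) — the 4PL family the fitter assumes, so
  noiseless recovery is exact by construction.
* **Noise.** Multiplicative log-normal on well signal with log-mean 0 and
  σ = √ln(1 + cv²), so the factor's coefficient of variation equals
  `noise_cv`. Plate-reader error is signal-proportional and positive, which
  a log-normal captures; the default cv is 0.05. An optional per-plate
  log-scale shift exists for robustness experiments and defaults to 0.
* **Layout.** 384-well plates (16 × 24), one plate series per
  (line, replicate); DMSO controls occupy fixed right-most columns
  (16 wells/plate by default), treated wells fill the remaining columns
  row-major. Replicates never share a plate.
* **Default screen.** 3 lines × 200 compounds at 0.1 and 1 µM in
  triplicate: 17 mutant-line-selective compounds (ed50 0.03–0.07 µM in the
  target line, 30–80 µM elsewhere), 8 selective for each other line, 10
  pan-active, 6 two-line-active, the rest inactive (ed50 300–1000 µM). At
  the screened doses the selective compounds reach ~65–95% inhibition in
  their target line and ≤ ~3% elsewhere, leaving > 3σ margins to the 50%
  threshold at cv = 0.05, so exact recovery is the expected behaviour, not
  luck.
* **Dose matrices.** True combination inhibition is
  clip(f_A + f_B − f_A·f_B + δ, 0, 1) with the planted Bliss deviation δ
  applied to combination wells only. The demo panel plants δ = +0.2
  (synergy) in the mutant-like line, −0.1 (antagonism) in the wild-type
  line and 0 in the null line, mirroring the qualitative contrast such
  combinations show across p53 genotypes.
* **Genomic fixtures.** Genes on two synthetic chromosomes, TSS spaced
  100 kb apart so no peak can qualify a neighbour. Planted targets get a
  shortlist-passing peak within 8 kb and |log2FC| in 2–4; decoys violate
  exactly one condition each (peak 20–40 kb away / peak failing exactly one
  shortlist criterion / |log2FC| ≤ 1.2), cycling the three kinds. Offsets
  deliberately avoid the strict 10 kb and 1.5 boundaries so correctness
  does not hinge on tie-breaking.
* **Determinism.** All randomness descends from the single config seed via
  `SeedSequence([seed, crc32(label)])` child streams, one per
  (line, replicate), matrix or fixture — outputs are byte-identical across
  runs and insensitive to generation order.

What the generator does **not** emulate: spatial plate artifacts (edge
effects, dispenser drift, cross-talk), compound-specific curve shapes
beyond the Hill family, correlated replicate noise, realistic peak shapes
or read-level sequencing data. Passing tests therefore demonstrate the
correctness of the analysis logic under the stated noise model, not
robustness to every artifact of real plate data.

## Problem sizes and runtime

Acceptance-level checks run at the study scale stated above (200 compounds
× 3 lines × 2 doses × 3 replicates ≈ 4 × 10³ wells; 5 × 5 dose matrices
× 3 replicates; 100 noisy 4PL fits at 8 doses; 100 × 100 peak/gene
instances); the full suite completes in well under a minute on one CPU.

## Known limitations

* Bootstrap/profile-likelihood confidence intervals for 4PL parameters are
  not implemented; `residual_sum_squares` is the only fit diagnostic.
* The Bliss module implements the difference-form CI only (no Loewe, ZIP
  or HSA alternatives).
* `ish_score` resolves the rubric's gaps at non-integer means with the
  half-open bins [0,1), [1,4), [4,10), [10,16), [16,∞).
* The Olive Tail Moment is the intensity-difference form; the canonical
  centroid-distance variant is available by passing
  `tail_centroid_distance` explicitly.
* Plate-screen I/O supports the long (tidy) CSV format only; vendor export
  formats must be converted upstream.
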