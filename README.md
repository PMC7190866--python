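# isoscreen

Analysis toolkit for **isogenic cell-line panel drug screens** — the setting
where a parental line (e.g. p53-null) and engineered derivatives (wild-type
p53, a gain-of-function p53 missense mutant) are screened side by side to
find compounds that kill one genotype selectively. The package covers the
full downstream analysis of such a screen: vehicle-normalized inhibition
scoring, line-selectivity hit calling, inhibition-profile clustering,
dose-response potency comparison, Bliss Independence synergy scoring, and
annotation of "direct target" genes from binding peaks plus differential
expression. A seeded synthetic-data generator emulates every input, so the
whole pipeline is testable end to end without external data.

## The statistics at its core

**Inhibition score.** Each treated well's signal (luminescence/absorbance)
is normalized against the vehicle (DMSO) wells of its plate:

    I-score(c) = (1 − signal(c) / median(signal_DMSO)) × 100

so 0 means no effect, 100 means complete kill, and negative values
(growth stimulation) are preserved. A compound is *efficacious* when its
replicate-averaged I-score strictly exceeds 50 in at least one line, and
*line-selective* when it exceeds 50 in exactly one line while staying
strictly below 50 in every other. Profiles are hierarchically clustered
with complete linkage on Euclidean distances.

**4PL dose-response.** Viability v(d) is fit with the four-parameter
logistic v(d) = bottom + (top − bottom) / (1 + (d/ec50)^hill). The curve
midpoint ec50 is reported as ED50; the absolute IC50 is the 50%-viability
crossing. Selectivity across lines is flagged at ≥ 10-fold ED50 difference;
sensitization by a fixed modulator is quantified as IC50(alone)/IC50(+mod).

**Bliss Independence.** For single-agent fractional inhibitions f_A, f_B,
the expected combination inhibition is f_A + f_B − f_A·f_B, and the per
dose-pair combination index is CI = expected − observed, so CI < 0 is
synergy and CI > 0 antagonism.

**Direct targets.** A gene is called a direct target when a shortlisted
binding peak (enrichment ≥ 5-fold, pileup ≥ 25, q < 0.01) lies strictly
within 10 kb of its TSS and its |log2 fold-change| strictly exceeds 1.5.

Small formula-defined assay readouts (comet-assay Olive Tail Moment,
RNA-ISH 0–4 scoring, DAB positivity, densitometry fold-ratio, caliper tumor
volume, cohort mutation frequency) are included in `isoscreen.assays`.

## Worked example

```python
import numpy as np
from isoscreen import synthetic, scoring, bliss

# seeded 3-line x 200-compound screen at 0.1/1 uM, triplicates, 5% CV noise
truths, planted = synthetic.example_screen_truths(7, n_compounds=200)
cfg = synthetic.SimConfig(seed=7, noise_cv=0.05, n_replicates=3)
screen = synthetic.generate_single_dose_screen(cfg, truths, [0.1, 1.0])

profile = scoring.build_profile(
    scoring.aggregate(scoring.score_screen(screen)), panel=screen.panel)
calls = scoring.call_hits(profile)
sel = [c.compound_id for c in calls if c.selectivity_class == "p53_R158G_selective"]
print(len(sel), "mutant-selective hits")        # 17 p53_R158G-selective hits
print(profile.matrix.loc[sel[0]].round(1).to_dict())
# {'p53_R158G': 97.6, 'p53_WT': 3.1, 'p53_NULL': 6.8}

# Bliss synergy contrast across the panel for a planted drug pair
drug_a = synthetic.CompoundTruth("cisplatin_like",
    {ln: synthetic.LinePotency(3.0) for ln in screen.panel})
drug_b = synthetic.CompoundTruth("modulator_like",
    {ln: synthetic.LinePotency(5.0) for ln in screen.panel})
inter = synthetic.InteractionTruth({"p53_R158G": 0.2, "p53_WT": -0.1, "p53_NULL": 0.0})
for ln in screen.panel:
    m = synthetic.generate_dose_matrix(cfg, drug_a, drug_b, inter,
        np.geomspace(0.1, 10, 5), np.geomspace(0.03, 3, 5), ln)
    print(ln, f"mean interior CI = {bliss.bliss_surface(m).mean_score:+.3f}")
# p53_R158G mean interior CI = -0.182   (synergy: planted delta +0.2)
# p53_WT    mean interior CI = +0.099   (antagonism: planted delta -0.1)
# p53_NULL  mean interior CI = +0.007   (independence: planted delta 0)
```

The first block plants 17 compounds potent only in the mutant line (ED50
~0.05 µM there, ~50 µM elsewhere) among 183 others and recovers exactly
those 17 from the noisy screen. The second block shows the combination
index recovering the sign and magnitude of the planted Bliss deviation in
each line.

The same pipeline is available from the shell:

```sh
isoscreen demo --seed 7 --out-dir demo   # simulate -> score -> hits -> fit
                                         # -> synergy -> targets + manifest
isoscreen validate demo/screen.csv --format 384
isoscreen score demo/screen.csv --out iscores.csv
isoscreen hits iscores.csv --threshold 50
```

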