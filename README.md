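# chewmix

Analysis toolkit for the **two-coloured chewing-gum mixing test**, an
objective measure of masticatory performance (MP) used in dental research
and geriatric oral-function assessment.  A subject chews a red/green gum
specimen, the flattened bolus is scanned on both sides, and the degree of
colour mixing quantifies chewing function.

The package provides the full measurement-and-inference chain:

* **Segmentation** — isolates the bolus from the scanner background with a
  colour-based algorithm: CIE L\*a\*b\* conversion, mean-shift superpixels to
  estimate the background colour from the image corners, a log colour
  distance map `d_i = log‖x_i − bg‖`, and deterministic two-class k-means
  with spatial (centre-of-image) cluster selection.
* **VhH statistic** — the MP score: the population variance of the 256-bin
  hue histogram of the pooled bolus pixels of both sides,
  `VhH = Σ c_k²/B − (n/B)²`.  Fully mixed boluses concentrate their pixels
  in one intermediate-hue bin and maximise VhH.
* **Statistics** — the repeated-measures battery applied to 3-session
  cohorts: paired-t systematic-error check, Shapiro–Wilk/Lilliefors
  normality screening, η² for the age–consumption association, Mauchly's
  sphericity test with Greenhouse–Geisser/Huynh–Feldt corrections, Type III
  3×3 mixed ANOVA (SESSION within, consumption group CGC between),
  Bonferroni session contrasts on estimated marginal means, Levene, Welch F
  with Games–Howell pairwise comparisons, and a normal/identity GEE with
  robust sandwich covariance.
* **Synthetic data** — wafer images with a known mixing degree and exact
  ground-truth masks, and cohort generators with the study's demographic
  structure, for validation and power/recovery simulation.

See `docs/methods.md` for the models, conventions and limitations.

## Worked example

```python
import numpy as np
from chewmix import WaferSpec, generate_wafer, segment, measure_sample, dice

for m in (0.0, 0.5, 1.0):              # latent mixing degree
    sides = []
    for side_seed in (11, 12):
        img, truth = generate_wafer(WaferSpec(mixing_degree=m, seed=side_seed))
        res = segment(img)
        sides.append((res, truth))
    meas = measure_sample(sides[0][0].pixels, sides[1][0].pixels)
    d = np.mean([dice(r.mask, t) for r, t in sides])
    print(f"m={m:4}  vhh={meas.vhh:12.1f}  n_pixels={meas.n_pixels}  mean_dice={d:.3f}")
```

prints

```
m= 0.0  vhh=     47542.1  n_pixels=30746  mean_dice=1.000
m= 0.5  vhh=    103840.7  n_pixels=30746  mean_dice=1.000
m= 1.0  vhh=    636345.0  n_pixels=30747  mean_dice=1.000
```

VhH rises monotonically with the mixing degree (an unmixed bolus spreads its
pixels over two hue clusters; a fully mixed one concentrates them near
yellow), while the segmentation recovers the ground-truth bolus mask
essentially perfectly (Dice 1.000) at every mixing level.

On the inference side, a synthetic 265-subject cohort with the default
effect structure:

```python
from chewmix import CohortSpec, generate_cohort
from chewmix import stats as cs

cohort = generate_cohort(CohortSpec(seed=1))          # 265 subjects x 3 sessions
anova = cs.mixed_anova(cohort)
s, row = anova.sphericity, anova.within.loc[0]
print(f"Mauchly W={s.W:.3f} (p={s.p:.3f})  correction={anova.correction}")
print(f"SESSION F({row['df']:.3f}, {anova.within.loc[2,'df']:.3f})"
      f" = {row['F']:.3f}, partial eta2={row['partial_eta_sq']:.3f}")
gee = cs.fit_gee(cohort).table.set_index("term")
print(f"GEE Age B = {gee.loc['Age','B']:.3e} (robust SE {gee.loc['Age','se']:.2e})")
```

prints

```
Mauchly W=0.977 (p=0.048)  correction=huynh-feldt
SESSION F(1.985, 519.995) = 78.553, partial eta2=0.231
GEE Age B = -4.182e+04 (robust SE 1.06e+04)
```

The session effect is detected with Huynh–Feldt-corrected degrees of freedom
(2·ε and 2(N−g)·ε), and the GEE recovers the simulated age slope
(−4.51×10⁴ VhH units per year) within its robust standard error.

## Command line

```bash
chewmix simulate-cohort --n-subjects 265 --seed 1 --out cohort.csv
chewmix simulate-images --n-samples 10 --seed 1 --out imgs/
chewmix segment --in imgs/ --out seg/ --save-masks
chewmix vhh --in imgs/ --pairs imgs/manifest.json --out measurements.csv
chewmix analyze --cohort cohort.csv --out report/      # tables 3-7 + report.json
chewmix run --pairs imgs/manifest.json --cohort cohort.csv --out out/
```

External per-subject datasets (CSV or spreadsheet) are ingested with a
caller-supplied column map (`chewmix.read_supplementary`), since deposited
supplementary tables rarely share a column layout.

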