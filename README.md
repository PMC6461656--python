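# earwound

Quantification pipeline for longitudinal intravital two-photon imaging of
wound-healing angiogenesis in the mouse ear, together with a synthetic-study
generator that emulates the full experimental design so that every stage of
the pipeline is testable without animal data.

## The problem

After a small transsection wound in the ear of a mouse expressing GCaMP2 in
arterial endothelial cells, new arterial sprouts grow from the **distal**
stump of each cut artery into the wound, elongate over days, and eventually
restore perfusion across the wound — partly directly, partly through newly
formed artery-to-vein **anastomoses** on either side. The pipeline turns the
three acquisition types of such a study into quantitative readouts:

1. **Anatomy stacks** (green/GCaMP channel) → sprout counts and wall-to-tip
   lengths per side, via segmentation + skeleton analysis
   (`earwound.sprouts`).
2. **Tracer injections** (red/Texas-Red channel, 0.66 frames/s, 30 baseline
   frames) → per-ROI arrival times t(A)…t(D) (ROIs A, B proximal; C, D
   distal), arrival differences Δt_{j−i} = t(j) − t(i), the integral flow
   measure |Δt_{B−A}| + |Δt_{C−B}| + |Δt_{D−C}|, perfusion calls
   (Δt < 66.66 s) and anastomosis calls (|Δt| < 1.3 s)
   (`earwound.perfusion`).
3. **22-minute GCaMP time series** → ΔF/F normalization and Ca²⁺ transient
   counts per region (proximal vs distal) (`earwound.calcium`).

The statistics layer (`earwound.stats`) fits the study's models on the tidy
cohort table: a Poisson generalized mixed model (Laplace approximation) for
sprout counts over days post-transection (dpt), reported on the count scale;
a linear mixed model for mean sprout length; mixed linear regressions with a
treatment × time interaction (random intercept per animal) for the perfusion
metrics, with Holm–Bonferroni-corrected post-hoc contrasts; a through-origin
mixed regression of perfused on total sprout counts (slope = perfused
fraction); and Wilcoxon / Fisher / Mann–Whitney tests for the categorical
readouts.

## The generator

`earwound.sim` builds calibrated vascular scenes (1 × 1 mm field of view,
300 µm wound band, stumps terminating on the wound edges, parallel
GCaMP-negative veins) and draws ground truth at the study's observed effect
sizes: distal-only sprout births as a Poisson process (1.5 sprouts/dpt from
3.5 dpt), a mean-length slope of 10.4 µm/dpt, Bernoulli perfusion of 2/3
per sprout, anastomosis probabilities 0.9/0.8 (proximal/distal) at 4 dpt
rising to 1 by 6 dpt, wound transit times falling from 4.74 ± 6.62 s at
4 dpt to 0 at 8 dpt, and Ca²⁺ transient trains peaking at 5 events per
22 min at 5 dpt with strong distal ≫ proximal asymmetry. Treatment arms
(sunitinib, AZD4547, and their combination, from 1 dpt) multiply birth,
elongation and anastomosis rates down. Scenes, trace CSVs, TIFF stacks and
the tidy cohort table are all reproducible byte-for-byte from one master
seed. See `docs/methods.md` for the model details and limitations.

## Worked example

```python
from earwound.sim import simulate_cohort
from earwound.analysis import run_stats

table, _ = simulate_cohort(groups={"control": 10}, seed=42)
fits = run_stats(table)
g = fits["sprout_count_glmm"].slopes["count_per_dpt"]
l = fits["sprout_length_lmm"].slopes["dpt"]
r = fits["perfused_ratio"].slopes["total"]
print(f"sprout count slope : {g[0]:.2f} +- {g[1]:.2f} sprouts/dpt")
print(f"sprout length slope: {l[0]:.2f} +- {l[1]:.2f} um/dpt")
print(f"perfused fraction  : {r[0]:.3f} +- {r[1]:.3f}")
```

prints

```
sprout count slope : 1.62 +- 0.21 sprouts/dpt
sprout length slope: 10.32 +- 0.60 um/dpt
perfused fraction  : 0.648 +- 0.060
```

i.e. the pipeline recovers the generating sprout birth rate (1.5/dpt), the
population length slope (10.4 µm/dpt) and the perfusion probability (2/3)
within two standard errors on a 10-animal control cohort.

The same chain is available from the shell:

```sh
earwound all --seed 42 --out study/
# study/ground_truth.csv  study/traces/  study/cohort_measured.csv
# study/fits.json         study/panels/*.svg + *.csv
```

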