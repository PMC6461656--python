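# Methods

This note documents the models behind the `earwound` generator and
quantification pipeline: what is simulated, how each readout is computed,
which parameters matter, and what the synthetic validation does and does
not establish about real data.

## Vascular scene

A scene is an axis-aligned geometric model on a calibrated micrometre grid:
a 1 × 1 mm field of view with a 300 µm wound band across its middle
(`scene.wound_width_um`). Each transsected artery contributes a proximal
stump (terminating on the proximal wound edge) and a distal stump whose
end bends into a short *terminal bar* running along the distal cut face;
sprouts emerge from eight well-separated anchor points on the bar's wall.
The bar serves two purposes: it reflects the anatomy of a vessel truncated
by a millimetres-long cut, and it keeps rendered sprouts resolvable as
distinct skeleton branches at the imaging scale (3.9 µm/px at 256 px).
A GCaMP-negative vein runs parallel to each artery at 60 µm offset, so
every stump has an anastomosis partner within reach. All geometry is
deterministic given the scene seed.

## Sprout dynamics

Sprout births on the distal stump follow a homogeneous Poisson process with
rate `birth_rate_per_day` (default 1.5/day) starting at `onset_dpt`
(default 3.5, the first day sprouts are detectable), so the cumulative
count at session t is Poisson with mean 1.5 · (t − 3.5). No proximal
sprouts are ever generated under default parameters — the study's central
asymmetry. Each sprout grows linearly along a straight path into the wound
at a per-sprout tip speed drawn from a lognormal distribution
(CV `elongation_cv`, default 0.3).

The headline `elongation_um_per_day` parameter (default 10.4) is the slope
of the *session-mean* sprout length as estimated by the longitudinal mixed
model — the quantity the length analysis reports. Two corrections connect
it to the per-sprout tip speed. First, with ongoing uniform births the mean
sprout age grows at only half a day per day, so the mean tip speed must be
about twice the population slope. Second, zero-sprout sessions yield a
*missing* (not zero) mean length; this missingness is informative (whether
an early session exists correlates with birth times), which raises the
random-intercept LMM's estimand about 17% above the marginal slope (pooled
OLS is unbiased at the marginal slope; verified by simulation). The
per-sprout tip speed is therefore fixed at `TIP_SPEED_MULTIPLIER = 1.71`
times the nominal slope, calibrated so that the LMM applied to the default
design estimates the nominal value (E[slope] = 10.33 ± 0.21 over 60
simulated cohorts).

Perfusion is a per-sprout Bernoulli flag with probability `p_perfused`
(default 2/3), constant over time, so the cohort's perfused/total ratio is
flat across sessions by construction.

## Tracer arrival times

Arrival times are sampled along the perfusion path, not solved
hydrodynamically. Per session (4, 6 or 8 dpt): anastomosis indicators per
side are Bernoulli with dpt-dependent probabilities (control: proximal
0.9/1.0/1.0, distal 0.8/1.0/1.0 at 4/6/8 dpt); t(A) is a baseline offset
(20 s, the 30-frame pre-injection recording) plus a lognormal circulation
time (median 10 s — the study never reports circulation time, and only
differences matter downstream); t(B) = t(A) + |N(0.5, 0.3)| s capped at
1.1 s when the proximal anastomosis exists, censored otherwise. The wound
crossing Δt_{C−B} is drawn from a lognormal moment-matched to the session's
mean/SD trajectory (4.74 ± 6.62 s at 4 dpt, ~1 s at 6 dpt, exactly 0 at
8 dpt); the lognormal respects the positivity of a transit time and
reproduces the printed mean without truncation bias. The distal stump fills
retrograde from its own anastomosis (t(D) before t(C), so Δt_{D−C} < 0)
or slowly anterograde across the wound when only the sprout route exists.
Compartments with no feeding route are censored, and censoring is
path-consistent: removing an anastomosis never makes a downstream arrival
earlier.

`wound_connected` requires at least one perfused sprout of length ≥
`span_threshold_um` (default 20 µm). Sprouts never traverse the full
300 µm band at the observed growth rates; functional crossing in the study
happens through connections to vessels in the wound vicinity, which the
threshold represents. With the default dynamics P(connected) ≈ 0.1/0.8/0.97
at 4/6/8 dpt. No acceptance-bearing quantity depends on this probability.

## Trace and image rendering

Two rendering routes share the acquisition parameters (frame period 2/3 s
for perfusion — reconciling "0.66 frames/s", 100 frames ≈ 66.7 s and the
20 s/30-frame baseline — 0.66 s for the 2000-frame calcium sessions).

*Trace level* (`sim.traces`): each ROI's red trace is baseline +
exponential-saturation fill (τ = 0.25 s, a fast bolus front) from its
arrival time, with Gaussian noise at `trace_amplitude / trace_snr`
(default SNR 10); GCaMP region traces are F₀ · (1 + ΔF/F) with transients
as amplitude · exp(−t/τ) kernels (τ = 5 s, amplitude lognormal around 1.0
ΔF/F) and ΔF/F-scale noise (SD 0.05).

*Image level* (`imaging.render`): vessels are soft-edged tubes (sigmoid
radial profile, edge 0.5 px, hard support beyond the 1% level) with a
Gaussian z-extent around each vessel's depth; the red channel fills each
compartment from its arrival time; veins appear only in red; calcium mode
modulates the green artery signal regionally; Poisson shot noise plus
Gaussian read noise are added last. Rendering then extracting reproduces
ground-truth arrivals within one frame (exactly, on noise-free renders).

## Quantification

**Arrival detection** estimates the baseline mean m and SD s over the first
30 frames and declares arrival at the first sustained excursion
(≥ `min_consecutive` = 2 frames) above m + k·s (k = 3). The reported time
interpolates the crossing of the *half-rise* level (midway between
baseline and the post-arrival plateau): unlike the k·s level, the
half-rise level does not scale with noise, making the timing stable across
SNR (≥95% of arrivals within ±1 frame down to SNR 5). A flat baseline
falls back to an absolute SD floor. Compartments with no sustained
crossing are censored; censored Δt values are excluded from regressions
and enter only the categorical analyses, as "not perfused".

**Anastomosis** per side: |Δt_{B−A}| (proximal) or |Δt_{D−C}| (distal)
strictly below 1.3 s (≈ two frame periods); absolute values, because a
fast retrograde fill equally indicates a vein connection. **Perfusion**
per compartment: Δt defined and below the 66.66 s window (the 100-frame
minimum recording), applied uniformly even to 300-frame recordings for
comparability.

**Sprout morphometry**: maximum-intensity z-projection → Gaussian smoothing
(σ = 1 px) → Otsu threshold (with a robust blank-image guard) →
morphological opening → small-object removal → skeletonization. Sprouts
are skeleton branches that attach to a stump trunk and enter the wound
band; each wound-entry defines one sprout whose path runs from the trunk
attachment to the deepest reachable tip (ties broken deterministically
towards the lexicographically smallest pixel). The path is trimmed at the
root to the parent wall (leading pixels thicker than 1.3× the branch's
own EDT half-width belong to the trunk lumen) and the tip is extended to
the mask boundary minus the local tube radius to undo skeleton end
erosion. Length is the Euclidean polyline length × pixel size; branches
below 10 µm are discarded. At 3.9 µm/px, sprouts shorter than roughly one
parent radius (~15–20 µm) protrude too few pixels beyond the parent mask
to survive skeletonization — a genuine resolution floor mirrored in the
test fixtures. Candidate entries whose out-of-band walk finds no junction
within 30 px are trunk ends poking into the band, not sprouts.

**Perfused-sprout counting** tests each detected skeleton against the red
projection: a sprout is perfused iff ≥ 50% (closed boundary) of its path
pixels exceed the robust red baseline (median + 3 × 1.4826·MAD). The
first 4 pixels of each path (keeping at least 3 tip pixels) are excluded
because they abut the parent trunk, whose own tracer halo would otherwise
be attributed to the sprout. Residual bias of the recovered perfused
fraction is ≈ +0.03: sprouts sharing an anchor at high counts merge into
one detection whose perfusion call follows the longer member.

**Calcium**: ΔF/F uses a running 20th-percentile baseline over a 60 s
window (floored to avoid division blow-up); transients are maximal runs
above median + 3 robust SDs lasting ≥ 2 s, with sub-second gaps merged
and runs split where an inter-peak trough falls below half the smaller
peak — without the split, overlapping transients (~3% of events at the
peak rate with τ = 5 s) would be merged and the mean count undershoots.
Counts are reported per full 22-minute session and region.

## Statistics

All longitudinal models use a random intercept per animal only. The
Poisson mixed model is fit by the Laplace approximation
(`PoissonBayesMixedGLM.fit_map`) with the canonical log link; because the
study reports the slope in sprouts per day, the fit is converted to the
count scale as the secant (μ(t_max) − μ(t_min))/(t_max − t_min) of the
fitted mean over the observed dpt range, with a delta-method standard
error on (intercept, slope). The interaction model
`value ~ group × dpt` reports per-group time slopes, a Wald omnibus F on
the interaction terms, and Holm-corrected pairwise group contrasts at
every observed session time (the post-hoc family; 6 pairs × sessions for
four groups). The through-origin perfused/total regression uses a mixed
model when animals contribute repeated measures and reduces to
through-origin least squares when each animal contributes one observation
(the random intercept is then unidentifiable). Holm's step-down is
implemented directly and cross-checked in the tests against an
independent smallest-rejecting-alpha oracle; Fisher's exact test is
cross-checked against a hypergeometric enumeration.

## Numerical and design choices

- Frame period fixed at 2/3 s for perfusion recordings; 0.66 s for the
  2000-frame calcium sessions (22 min exactly).
- Pixel coordinates are 0-based (row, col), origin top-left, recorded in
  every file's metadata; ROI polygons use pixel-center inclusion.
- Per-animal random streams are derived by hashing (master seed,
  animal id), so enlarging a cohort never perturbs existing animals;
  re-running any stage with the same seed reproduces outputs
  byte-identically.
- ROIs A–D are squares on the stump centreline at 250/50 µm (proximal)
  and 50/250 µm (distal) from the wound edges — the study does not state
  its offsets; these are symmetric by choice.
- Simulation sizes in the validation suite (10-animal control cohorts,
  200-session Monte-Carlo batches, 10⁴-session classification runs) were
  chosen to keep standard errors a few percent of the target quantities.

## What the synthetic validation shows — and does not

Passing tests establish that the pipeline recovers the generating effect
sizes under the study design: the right slopes, fractions, transit times
and classification rates, with correct censoring propagation and
deterministic reproducibility. The generator deliberately omits several
features of real intravital data: motion and pulsation artefacts (frames
are aligned by construction), scattering and depth-dependent attenuation,
vessel tortuosity and diameter variation, tracer recirculation and
photobleaching, and spatially heterogeneous GCaMP expression. Detection
parameters validated here should therefore be treated as starting points,
not guarantees, for real acquisitions. Two statistical caveats carry over
to real data: the LMM length slope is an estimand of the *design*
(missingness included), not a pure biological rate; and transit-time
regressions are heteroscedastic across days (SD shrinks from 6.62 s to 0),
which the homoscedastic mixed model ignores when weighting.
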