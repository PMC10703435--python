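# Methods

`phagedrop` quantifies the growth and phage-induced lysis of bacterial
populations confined in anchored picoliter droplets, from fluorescence
time-lapse images or from per-compartment signal trajectories.  Because no
public droplet image data exist for this assay, the package ships a
first-class synthetic-data generator whose statistical structure matches
what the analytics assume; every downstream stage is validated against it.

## The analysis procedure

A droplet's (or microplate well's) signal trajectory `v(t)` — mean
fluorescence over a circular ROI, or absorbance — is analyzed as follows.

**Sliding-window log-slope.**  Ordinary least-squares slopes of
`ln v` versus `t` are computed over a 40-min sliding window advancing one
sample at a time.  The window holds `floor(40/dt) + 1` samples: 14 points
at the 3-min droplet frame interval, 11 points at the 4-min plate-reader
interval.  Excluded samples (out-of-focus frames) and non-positive values
are dropped; a window must consist of consecutive retained samples, so
windows straddling a gap are skipped rather than shrunk.

**Growth rate and doubling time.**  The growth rate μ is the maximum
window slope whose center lies in a preset search interval — droplets
36–120 min, plate reader 20–120 min, or 38–200 / 24–200 min for the slower
RNA-phage conditions — and the doubling time is `ln 2 / μ` (undefined when
μ ≤ 0).  Times are measured from phage mixing; the first droplet frame
falls at the dead time (~12 min) after mixing.

**Lysis onset ("inflection point").**  Scanning the window slopes in time
order, the onset of net bacteriolysis is the first transition from a
positive slope to a non-positive one; the reported time is the middle
sample of the triggering window.  For the even, 14-point window the middle
is defined as the earlier of the two central samples.  An optional
persistence parameter can require k consecutive non-positive windows
(default 1, the literal first sign change).  The scan starts at the
beginning of the growth-rate search interval to skip loading transients.

**Efficacy readouts.**  Fold-changes are plain signal ratios
`v(t_query)/v(t_ref)` (a fold *decrease* is the inverse ratio).  The kill
fraction is `100 × (1 − v(t_query)/v(t_ref))`, clamped to [0, 100] at
reporting; by default `t_ref` is the trajectory's lysis onset (a peak
proxy) and `t_query` the last retained sample.  Cohort summaries report
mean ± SD of doubling times and onset times and the fraction of
trajectories with an onset (the "declined" fraction).  Group comparisons
use the two-tailed two-sample heteroscedastic (Welch) t-test, implemented
from the closed formulas with Welch–Satterthwaite degrees of freedom.

## Image extraction

The pipeline mirrors the standard flat-field/mask/ROI routine, in a fixed
order:

1. **Shading correction.**  The corrector is the pixel-wise median
   projection through a stack of flat-field frames (a fluorescein-coated
   slide imaged at several positions), divided by its own median pixel so
   its median is 1.  The median projection is robust to a bright artifact
   in any single frame.  Every data frame is divided by the corrector.
2. **Background masking.**  A per-frame threshold maps background pixels
   to 0.  The threshold strategy is pluggable — `fixed` (user value),
   `otsu` (default; unsupervised and reproducible), or `percentile` — since
   the original per-frame values are not recoverable.  Masks are built on
   shading-corrected frames, and the corrected frame is multiplied by its
   binary mask.
3. **ROI extraction.**  Each droplet is read out as the arithmetic mean
   over a circular ROI.  Pixels use 0-based coordinates with centers at
   integers; a pixel belongs to the disc when
   `(x−cx)² + (y−cy)² ≤ r²`.  This convention makes ROI means
   bit-reproducible and is tested against brute-force enumeration.
   ROIs come from a CSV table (taking precedence) or a circular Hough
   transform on one frame.  An integrated (summed) readout is available
   alongside the mean.

Out-of-focus frames are dropped from analysis, not interpolated: a frame
is flagged either from a user-supplied exclusion list or automatically
when its variance-of-Laplacian focus metric falls below a configurable
fraction (default 0.5) of the stack median.

## The synthetic-data generator

The simulator is a discrete-time per-droplet stochastic process with the
frame interval as its step:

* **Loading.**  Cells per droplet are Poisson with mean `CFU/mL × V`
  (~14 cells at 5×10⁸ CFU/mL in a 28 pL droplet, inside the 10–40 cell
  loading aim); free phage are Poisson with mean `MOI × CFU/mL × V`.  The
  MOI is shared across droplets because samples are premixed before
  digitization.
* **Growth.**  Each droplet draws one growth rate from a lognormal with
  mean `mu_mean` (default ln 2/24 min⁻¹) and CV `mu_cv` (default 0.33,
  echoing the observed ±8 min spread around a 24-min doubling time).
  Susceptible biomass grows deterministically by `exp(μ dt)` per step up to
  a hard carrying capacity (default 10⁴ cells): fluorescence tracks
  biomass, and clonal biomass in exponential balanced growth is
  deterministic even though single-cell division times are not.  Biomass is
  therefore held as a continuous variable; infected, lysed and phage
  counts are integers.
* **Infection and lysis.**  Within a step each free phage adsorbs with
  probability `min(1, a · n_susceptible · dt)`; an adsorbed phage converts
  one cell-equivalent of biomass (a sub-cell residual counts as one cell,
  so infection can run a droplet to extinction) into an infected cell that
  lyses exactly one latent period later, releasing a burst drawn uniformly
  from the species range.  Infected cells do not divide; by default they
  remain fully fluorescent until lysis (configurable).
* **Resistance.**  A droplet's founding lineage is insusceptible with
  probability `resistant_fraction`, reproducing the observed heterogeneous
  non-declining subpopulations under RNA-phage challenge.  Resistance is a
  lineage property of the droplet, which is what makes the declined
  fraction binomial across droplets.
* **Measurement.**  Frames are recorded from the dead time (default
  12 min, the midpoint of the 11–14 min handling delay) at `dt` = 3 min.
  The signal is `signal_per_cell × (susceptible + infected) +
  baseline_signal`, times multiplicative Gaussian noise of CV
  `noise_cv` (default 5%), clipped at zero.  The baseline (default 0.1 AU
  = one tenth of a cell) models lysis debris and imperfect background
  zeroing; without it a fully lysed droplet would read exactly zero and
  its decline would be invisible to log-slope analysis — real droplet
  assays measure ≥99% killed, not 100%.

Phage presets carry published kinetics: T7 latent period 30 min (its
30 °C value, the assay temperature) with bursts of 179–182; MS2 90 min,
2000–2100; Qβ 105 min, 90–776.  No in-droplet adsorption rates have been
measured, so `adsorption_rate` is an effective free parameter.  The
presets were calibrated once, during model design, to reproduce the
qualitative phenotypes of the droplet data: T7 at 3×10⁻⁴ (populations rise
severalfold before the lysis wave; mean onset lands between the latent
period and latent + 40 min at MOI 1) and MS2/Qβ at 5×10⁻⁵ (F-pilus
adsorption is much slower, so growth continues until after the first
burst).

The default `duration_min` of 200 min covers all three phage phenotypes
while keeping uninfected droplets below the carrying capacity; at the
capacity plateau, multiplicative noise around a zero slope would otherwise
trigger spurious sign-change onsets in resistant subpopulations.  Longer
runs should raise the capacity accordingly, or use a persistence/min-slope
guard when scanning for onsets.

**Image rendering.**  Synthetic frames are
`shading × (background + Σ cell kernels)`, with optional Poisson shot
noise.  The shading field is a smooth, strictly positive Gaussian vignette.
Cells are Gaussian kernels (σ default 0.8 μm) of fixed integrated
intensity placed uniformly in 30-μm-radius droplet discs (the trap
radius); re-randomizing positions each frame emulates motility.  A
configurable fraction of cells is rendered defocused: a 2.5× wider kernel
conserving 80% of the integrated intensity, mimicking signal spread away
from the mid-droplet focal plane.

### What the generator does *not* emulate

Autoaggregation (clumps with sub-linear fluorescence), GFP expression
noise and maturation delay, phage-resistance *mutations* arising during
the run (only standing resistance), lysis-timing variability (the latent
period is fixed), nutrient depletion (the capacity is a hard cap, not a
gradual slowdown), spatial phage diffusion within a droplet, and focal
drift. Passing tests therefore demonstrate that the analytics correctly
recover known ground truth under the stated statistical structure — not
that the pipeline is robust to every artifact of real microscopy data.

## Numerical choices

* OLS slopes are computed by the closed normal-equation form on windowed
  views; agreement with an independent least-squares oracle to 1e-10
  relative is enforced by test.
* Zero/negative signals are dropped before the log transform (with a
  warning) rather than offset by a pseudo-count, which would bias slopes
  at low signal.
* Doubling-time means over heterogeneous cohorts are means of per-droplet
  `ln 2/μ̂`; note `E[ln2/μ] > ln2/E[μ]` (Jensen), while the max-slope
  estimator is biased slightly high under measurement noise — at the
  default 5% noise the two effects largely offset.
* ROI membership is inclusive (`≤ r²`); ties on the boundary are part of
  the disc.  The oblate-spheroid volume uses 1 pL = 10³ μm³.
* Per-droplet RNG substreams are spawned from one seed sequence, so an
  experiment is reproducible bit for bit and droplets are independent.

## Problem sizes

Validation cohorts use 100–200 droplets of ~67 frames each, the rendered
round-trip uses two droplets over 51 frames of 256×256 px, and the Welch
calibration uses 2000 replicates; these sizes give binomial/SEM margins
well inside the asserted tolerances while the whole suite runs in
seconds.

## Known limitations

* The onset detector is the literal first sign change; on long noisy
  plateaus (saturated or fully-infected populations) it will eventually
  fire by chance.  Use `persistence` > 1 and the preset `min_time`, and
  keep run lengths matched to the capacity, as the defaults do.
* Absolute cell-number calibration (signal per cell) is arbitrary; all
  readouts are ratios or rates, as in the assay itself.
* The Hough-based ROI auto-detection is a convenience for synthetic
  frames; manually drawn ROI tables are expected for real data.
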