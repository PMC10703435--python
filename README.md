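# phagedrop

Quantifying bacteria–phage population dynamics in picoliter droplets.

Droplet microfluidics combined with fluorescence time-lapse microscopy is
an emerging way to screen bacteriophages as antibacterial agents: an
*E. coli* culture carrying a constitutive GFP reporter is mixed with phage,
digitized into ~28 pL anchored droplets (~10–40 cells each, Poisson
loaded), and each droplet's mean fluorescence is followed for hours as a
proxy for its population size.  `phagedrop` implements the quantitative
core of such assays for microbiologists and microfluidics developers:

* **growth analytics** — sliding-window log-slope growth rates
  (μ = max slope of ln v(t) over a 40-min window; doubling time ln 2/μ),
  lysis-onset detection (the first positive→negative slope transition),
  fold-changes, kill fractions, cohort summaries, and Welch's
  heteroscedastic t-test for group comparisons;
* **image extraction** — flat-field (shading) correction from a median
  projection, per-frame background masking, circular-ROI mean intensities,
  and out-of-focus frame exclusion;
* **assay arithmetic** — CFU/PFU densities from plate counts, MOI,
  oblate-spheroid droplet volumes, Poisson occupancy;
* **a synthetic-data generator** — a stochastic per-droplet
  bacteria–phage simulator (Poisson loading, lognormal growth-rate
  heterogeneity, latent-period lysis with species-specific burst sizes,
  resistant lineages) and a fluorescence frame renderer (shading,
  background, per-cell Gaussian kernels, defocus, shot noise), so the
  whole pipeline is testable without any experimental download.

Phage presets ship for T7 (latent period 30 min at the 30 °C assay
temperature, burst 179–182), MS2 (90 min, 2000–2100) and Qβ (105 min,
90–776).  See `docs/methods.md` for the model and its assumptions.

## Worked example

Simulate 100 droplets of *E. coli* challenged with T7 at MOI 1 and
quantify the phage's efficacy:

```python
import numpy as np
from phagedrop import (SimParams, T7, simulate_experiment,
                       cohort_summary, kill_fraction)

params = SimParams(moi=1.0, seed=11)   # ~14 cells and ~14 T7 per 28 pL droplet
trajs = simulate_experiment(params, T7, 100, rng=11)
table, summary = cohort_summary(trajs, preset="droplet")
kills = [kill_fraction(t, min_time=36.0) for t in trajs]
print(f"declined fraction : {summary['declined_fraction']:.2f}")
print(f"time to decline   : {summary['inflection_min_mean']:.0f} "
      f"+/- {summary['inflection_min_sd']:.0f} min")
print(f"mean kill fraction: {np.mean(kills):.1f} %")
```

```
declined fraction : 1.00
time to decline   : 60 +/- 13 min
mean kill fraction: 99.8 %
```

Every droplet population collapses: lysis begins on average 60 min after
mixing (the 30-min T7 latent period plus the time for the lysis wave to
overtake growth and reach the 40-min detection window), and 99.8% of each
population is killed relative to its size at lysis onset.  Swapping in the
`QBETA` preset at MOI 14 moves the mean onset past 140 min; adding
`resistant_fraction=0.37` to an `MS2` run leaves ~37% of droplets growing
— the three qualitative phenotypes the assay distinguishes.

The same analytics run from the shell:

```sh
phagedrop simulate --n-droplets 24 --phage T7 --moi 1 --seed 1 --out traj.csv
phagedrop analyze-growth --traj traj.csv --preset droplet --out-dir results/
phagedrop calc volume --diameter-um 60 --height-um 15
# {"volume_pl": 28.274333882308134, "volume_pl_rounded": 28}
```

`phagedrop analyze-images --stack s.tif --flatfield f.tif --rois rois.csv
--out traj.csv` extracts trajectories from a multi-page TIFF (with a YAML
sidecar holding the frame interval), and `phagedrop run --config c.yaml
--out out/` chains simulate → render → analyze-images → analyze-growth
with a reproducibility manifest.

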