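"""Parameter containers for the droplet bacteria-phage simulator and renderer.

Defaults describe a droplet assay at 30 degrees C: ~28 pL anchored droplets
loaded from an exponentially growing E. coli culture at ~5e8 CFU/mL (mean
occupancy ~14 cells), imaged every 3 min starting ~12 min after mixing.
Phage presets carry the latent periods and burst-size ranges reported for
T7, MS2 and Qbeta.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

LN2 = math.log(2.0)


@dataclass(frozen=True)
class PhageParams:
    """Kinetic parameters of an obligately lytic phage species.

    Attributes
    ----------
    name : str
        Species label.
    latent_period_min : float
        Time from adsorption to lysis of the host cell, in minutes.
    burst_size_range : (int, int)
        Inclusive range of phage particles released per lysed cell; each
        lysis event draws a burst uniformly from this range.
    adsorption_rate : float
        Per-phage, per-minute probability scale: within one time step of
        length ``dt`` a free phage adsorbs with probability
        ``min(1, adsorption_rate * n_susceptible * dt)``.  No measured
        in-droplet value exists; preset values are effective rates chosen
        so that at MOI ~1 a population grows severalfold before the lysis
        wave, as droplet fluorescence traces show.
    """

    name: str
    latent_period_min: float
    burst_size_range: tuple[int, int]
    adsorption_rate: float = 3e-4

    def __post_init__(self) -> None:
        if self.latent_period_min <= 0:
            raise ValueError("latent_period_min must be > 0")
        lo, hi = self.burst_size_range
        if not (isinstance(lo, int) and isinstance(hi, int)):
            raise ValueError("burst_size_range must be a pair of ints")
        if not (1 <= lo <= hi):
            raise ValueError("burst_size_range must satisfy 1 <= low <= high")
        if self.adsorption_rate < 0:
            raise ValueError("adsorption_rate must be >= 0")


#: DNA phage with a short replication cycle (~30 min at 30 C) and high
#: killing efficacy; adsorption is fast (receptors on the cell surface).
T7 = PhageParams("T7", latent_period_min=30.0, burst_size_range=(179, 182),
                 adsorption_rate=3e-4)
#: RNA phage adsorbing to F-pili; long replication cycle, very large burst,
#: and much slower adsorption than T7 (pilus attachment is rate limiting).
MS2 = PhageParams("MS2", latent_period_min=90.0, burst_size_range=(2000, 2100),
                  adsorption_rate=5e-5)
#: RNA phage adsorbing to F-pili; longest replication cycle of the three.
QBETA = PhageParams("Qbeta", latent_period_min=105.0, burst_size_range=(90, 776),
                    adsorption_rate=5e-5)

PHAGE_PRESETS: dict[str, PhageParams] = {"T7": T7, "MS2": MS2, "Qbeta": QBETA}


@dataclass(frozen=True)
class SimParams:
    """Study conditions for a simulated droplet experiment.

    Attributes
    ----------
    cfu_per_ml : float
        Bacterial density of the loaded culture (cells/mL).
    droplet_volume_pl : float
        Droplet volume in picoliters.
    moi : float
        Multiplicity of infection: ratio of phage particles to bacterial
        cells in the premixed sample.
    mu_mean : float
        Mean per-droplet exponential growth rate, 1/min.
    mu_cv : float
        Coefficient of variation of the lognormal across-droplet growth-rate
        distribution (one rate drawn per droplet).
    resistant_fraction : float
        Probability that a droplet's founding lineage is insusceptible and
        never lyses.
    signal_per_cell : float
        Fluorescence units contributed by one cell equivalent.
    baseline_signal : float
        Residual signal (AU) present even with no intact cells: lysis
        debris and imperfect background zeroing.  Keeps fully lysed
        droplets measurable instead of reading exactly zero.
    noise_cv : float
        Multiplicative measurement noise CV applied per frame.
    dead_time_min : float
        Minutes between phage mixing (t = 0) and the first recorded frame.
    dt_min : float
        Frame interval in minutes.
    duration_min : float
        Total simulated time from mixing, minutes.
    carrying_capacity_cells : float
        Hard cap on cells per droplet (growth stops at the cap).
    infected_fluorescent : bool
        Whether infected, not-yet-lysed cells contribute full signal.
    seed : int or None
        Default RNG seed used when no explicit seed is passed.
    """

    cfu_per_ml: float = 5e8
    droplet_volume_pl: float = 28.0
    moi: float = 0.0
    mu_mean: float = LN2 / 24.0
    mu_cv: float = 0.33
    resistant_fraction: float = 0.0
    signal_per_cell: float = 1.0
    baseline_signal: float = 0.1
    noise_cv: float = 0.05
    dead_time_min: float = 12.0
    dt_min: float = 3.0
    duration_min: float = 200.0
    carrying_capacity_cells: float = 1e4
    infected_fluorescent: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        nonneg = (
            "cfu_per_ml", "droplet_volume_pl", "moi", "mu_mean", "mu_cv",
            "signal_per_cell", "baseline_signal", "noise_cv", "dead_time_min", "duration_min",
            "carrying_capacity_cells",
        )
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.dt_min <= 0:
            raise ValueError("dt_min must be > 0")
        if not 0.0 <= self.resistant_fraction <= 1.0:
            raise ValueError("resistant_fraction must be in [0, 1]")

    @property
    def mean_cells_per_droplet(self) -> float:
        """Poisson mean occupancy, cfu_per_ml * volume_pl * 1e-9."""
        return self.cfu_per_ml * self.droplet_volume_pl * 1e-9


@dataclass(frozen=True)
class ShadingFieldSpec:
    """Smooth multiplicative illumination field, strictly positive.

    field(x, y) = 1 + amplitude * exp(-r^2 / (2 sigma^2)) with r measured
    from ``center_frac`` (fractions of the image size) and sigma equal to
    ``sigma_frac`` times the smaller image dimension.  ``amplitude`` > -1
    keeps the field positive everywhere.
    """

    amplitude: float = 0.3
    sigma_frac: float = 0.6
    center_frac: tuple[float, float] = (0.5, 0.5)

    def __post_init__(self) -> None:
        if self.amplitude <= -1.0:
            raise ValueError("amplitude must be > -1 for a positive field")
        if self.sigma_frac <= 0:
            raise ValueError("sigma_frac must be > 0")


@dataclass(frozen=True)
class OpticsParams:
    """Geometry and imaging parameters of the synthetic renderer.

    Droplets are discs of radius ``droplet_radius_um`` (default 30 um, the
    radius of a 60-um circular trap) at the listed centers (in um, x right /
    y down, 0-based pixel centers at integer coordinates).  Each cell is a
    Gaussian kernel of sigma ``cell_sigma_um`` carrying an integrated
    intensity of ``cell_intensity``; a fraction ``defocus_fraction`` of cells
    is rendered with a ``defocus_scale``-times wider kernel conserving
    ``defocus_conserved_fraction`` of the integrated intensity.
    """

    image_size_px: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.65
    droplet_centers_um: tuple[tuple[float, float], ...] = ((83.2, 83.2),)
    droplet_radius_um: float = 30.0
    shading: ShadingFieldSpec = field(default_factory=ShadingFieldSpec)
    background_level: float = 50.0
    cell_sigma_um: float = 0.8
    cell_intensity: float = 200.0
    defocus_fraction: float = 0.3
    defocus_scale: float = 2.5
    defocus_conserved_fraction: float = 0.8
    shot_noise: bool = False

    def __post_init__(self) -> None:
        h, w = self.image_size_px
        if h <= 0 or w <= 0:
            raise ValueError("image_size_px must be positive")
        for name in ("pixel_size_um", "droplet_radius_um", "cell_sigma_um",
                     "cell_intensity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.background_level < 0:
            raise ValueError("background_level must be >= 0")
        if not 0.0 <= self.defocus_fraction <= 1.0:
            raise ValueError("defocus_fraction must be in [0, 1]")
        if self.defocus_scale < 1.0:
            raise ValueError("defocus_scale must be >= 1")
        if not 0.0 < self.defocus_conserved_fraction <= 1.0:
            raise ValueError("defocus_conserved_fraction must be in (0, 1]")
        if not self.droplet_centers_um:
            raise ValueError("at least one droplet center is required")
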