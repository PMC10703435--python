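"""Stochastic per-droplet bacteria-phage dynamics.

The model is a discrete-time per-cell process with a fixed time step equal
to the frame interval:

* Loading is Poissonian: cells ~ Poisson(cfu_per_ml x V) and free phage
  ~ Poisson(MOI x cfu_per_ml x V), with the MOI shared across droplets
  because samples are premixed before digitization.
* Susceptible biomass grows deterministically by exp(mu_d * dt) per step
  (one lognormal growth rate mu_d per droplet) until a hard carrying
  capacity; the fluorescence readout tracks biomass, which in a clonal,
  exponentially elongating population is exactly exponential even though
  individual division times are stochastic.
* Each free phage adsorbs within a step with probability
  min(1, adsorption_rate * n_susceptible * dt); an adsorbed phage converts
  one cell-equivalent of susceptible biomass into an infected cell.
* An infected cell lyses exactly one latent period after infection,
  releasing a burst drawn uniformly from the species' burst-size range.
* A droplet's founding lineage is resistant with probability
  ``resistant_fraction``; resistant lineages never adsorb phage.

Frames are recorded on the simulation grid from ``dead_time_min`` onwards
(t = 0 at phage mixing), with multiplicative Gaussian measurement noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import PhageParams, SimParams
from .trajectory import Trajectory

__all__ = [
    "DropletState",
    "load_droplet",
    "simulate_droplet",
    "simulate_experiment",
    "first_lysis_time",
]

_TOL = 1e-9


@dataclass
class DropletState:
    """Per-droplet bookkeeping at one time point.

    ``n_susceptible`` is held as continuous biomass in cell equivalents so
    that uninfected growth is exactly exponential; ``n_infected``,
    ``n_lysed`` and ``n_free_phage`` are integer counts.
    """

    t: float
    n_susceptible: float
    n_infected: int
    n_lysed: int
    n_free_phage: int
    resistant: bool = False

    def __post_init__(self) -> None:
        if self.n_susceptible < 0:
            raise ValueError("n_susceptible must be >= 0")
        for name in ("n_infected", "n_lysed", "n_free_phage"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n_fluorescent(self) -> float:
        return self.n_susceptible + self.n_infected


def as_rng(seed) -> np.random.Generator:
    """Coerce None / int / SeedSequence / Generator into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def load_droplet(params: SimParams, rng=None) -> DropletState:
    """Draw the Poisson loading of one droplet at mixing time (t = 0).

    Cells ~ Poisson(cfu_per_ml x V x 1e-9) and free phage ~ Poisson(MOI x
    same mean).  Zero-cell droplets are legal outputs.
    """
    rng = as_rng(rng)
    mean_cells = params.mean_cells_per_droplet
    n_cells = int(rng.poisson(mean_cells))
    n_phage = int(rng.poisson(params.moi * mean_cells))
    resistant = bool(rng.random() < params.resistant_fraction)
    return DropletState(
        t=0.0,
        n_susceptible=float(n_cells),
        n_infected=0,
        n_lysed=0,
        n_free_phage=n_phage,
        resistant=resistant,
    )


def _draw_growth_rate(params: SimParams, rng: np.random.Generator) -> float:
    """One per-droplet rate from a lognormal with mean mu_mean and CV mu_cv."""
    if params.mu_cv == 0.0 or params.mu_mean == 0.0:
        return params.mu_mean
    s2 = math.log1p(params.mu_cv**2)
    return float(rng.lognormal(math.log(params.mu_mean) - 0.5 * s2, math.sqrt(s2)))


def simulate_droplet(
    params: SimParams,
    phage: PhageParams | None,
    rng=None,
    traj_id: str = "d0000",
) -> tuple[list[DropletState], Trajectory]:
    """Simulate one droplet and return (state snapshots, noisy trajectory).

    Snapshots are recorded at every step of the simulation grid
    (t = 0, dt, 2 dt, ...); the trajectory records frames at grid times
    >= ``dead_time_min``.
    """
    rng = as_rng(rng)
    if phage is not None and params.dt_min >= phage.latent_period_min:
        raise ValueError(
            "dt_min must be smaller than the phage latent period; the update "
            "rule would otherwise skip the infected stage"
        )
    state0 = load_droplet(params, rng)
    mu = _draw_growth_rate(params, rng)

    dt = params.dt_min
    growth = math.exp(mu * dt)
    cap = params.carrying_capacity_cells
    n_steps = int(math.floor(params.duration_min / dt + _TOL))

    ns = state0.n_susceptible
    ni = 0
    nl = 0
    nf = state0.n_free_phage
    pending: list[tuple[float, int]] = []  # (lysis time, cell count)

    states: list[DropletState] = []
    times: list[float] = []
    values: list[float] = []

    for k in range(n_steps + 1):
        t = k * dt
        if k > 0:
            if pending:
                due = [e for e in pending if e[0] <= t + _TOL]
                if due:
                    pending = [e for e in pending if e[0] > t + _TOL]
                    for _, count in due:
                        ni -= count
                        nl += count
                        lo, hi = phage.burst_size_range
                        nf += int(rng.integers(lo, hi + 1, size=count).sum())
            if (
                phage is not None
                and not state0.resistant
                and nf > 0
                and ns > 0.0
            ):
                p = min(1.0, phage.adsorption_rate * ns * dt)
                k_ads = int(rng.binomial(nf, p))
                # a sub-cell biomass residual counts as one infectable cell,
                # so infection can run a droplet to extinction
                k_ads = min(k_ads, int(math.ceil(ns)))
                if k_ads > 0:
                    nf -= k_ads
                    ns = max(ns - k_ads, 0.0)
                    ni += k_ads
                    pending.append((t + phage.latent_period_min, k_ads))
            # growth of susceptible biomass, capped at carrying capacity
            ns = min(ns * growth, max(cap - ni, ns))
        states.append(
            DropletState(
                t=t,
                n_susceptible=ns,
                n_infected=ni,
                n_lysed=nl,
                n_free_phage=nf,
                resistant=state0.resistant,
            )
        )
        if t >= params.dead_time_min - _TOL:
            pop = ns + (ni if params.infected_fluorescent else 0)
            v = params.signal_per_cell * pop + params.baseline_signal
            if params.noise_cv > 0:
                v *= 1.0 + rng.normal(0.0, params.noise_cv)
            times.append(t)
            values.append(max(v, 0.0))

    traj = Trajectory(id=traj_id, times=np.array(times), values=np.array(values))
    return states, traj


def simulate_experiment(
    params: SimParams,
    phage: PhageParams | None,
    n_droplets: int,
    rng=None,
    return_states: bool = False,
):
    """Simulate ``n_droplets`` independent droplets.

    Each droplet draws its own loading, growth rate and resistance flag from
    a deterministic per-droplet substream, so a fixed seed reproduces the
    experiment bit for bit.  Returns a list of trajectories, or
    (trajectories, state histories) when ``return_states`` is set.
    """
    if n_droplets < 0:
        raise ValueError("n_droplets must be >= 0")
    if isinstance(rng, np.random.SeedSequence):
        ss = rng
    elif isinstance(rng, np.random.Generator):
        ss = np.random.SeedSequence(int(rng.integers(2**31)))
    else:
        ss = np.random.SeedSequence(rng if rng is not None else params.seed)
    trajs: list[Trajectory] = []
    all_states: list[list[DropletState]] = []
    for i, child in enumerate(ss.spawn(n_droplets)):
        states, traj = simulate_droplet(
            params, phage, np.random.default_rng(child), traj_id=f"d{i:04d}"
        )
        trajs.append(traj)
        if return_states:
            all_states.append(states)
    if return_states:
        return trajs, all_states
    return trajs


def first_lysis_time(states: list[DropletState]) -> float:
    """Time of the first lysis event in a droplet's history (nan if none)."""
    for s in states:
        if s.n_lysed > 0:
            return s.t
    return float("nan")
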