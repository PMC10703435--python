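"""Growth-rate, lysis-onset and cohort analytics for droplet trajectories.

The core procedure mirrors the spreadsheet analysis used for droplet and
plate-reader growth curves: ordinary least-squares slopes of ln(signal)
versus time over a 40-min sliding window (14 points at 3-min droplet
sampling, 11 points at 4-min plate-reader sampling), with

* growth rate mu = the maximum slope within a preset search interval and
  doubling time ln2 / mu,
* the lysis onset ("inflection point") = the middle time point of the first
  window whose slope turns from positive to non-positive,
* fold-changes / kill fractions as simple signal ratios, and
* Welch's heteroscedastic two-sample t-test for group comparisons.

Samples that are excluded or non-positive are dropped; a window must
consist of consecutive retained samples, so windows straddling gaps are
skipped rather than shrunk.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

from .trajectory import Trajectory

__all__ = [
    "SEARCH_PRESETS",
    "SlopeSeries",
    "GrowthResult",
    "InflectionResult",
    "GroupTestResult",
    "window_points",
    "sliding_slopes",
    "growth_rate",
    "find_inflection",
    "fold_change",
    "fold_decrease",
    "kill_fraction",
    "cohort_summary",
    "welch_t_test",
]

LN2 = math.log(2.0)

#: Named search intervals (minutes) for the maximum-slope growth rate:
#: DNA-phage/plain growth curves start at 36 min (droplets) / 20 min
#: (plate reader); the slower RNA-phage curves are searched to 200 min.
SEARCH_PRESETS: dict[str, tuple[float, float]] = {
    "droplet": (36.0, 120.0),
    "plate": (20.0, 120.0),
    "droplet-rna": (38.0, 200.0),
    "plate-rna": (24.0, 200.0),
}


@dataclass
class SlopeSeries:
    """Sliding-window slopes of ln(signal) versus time.

    ``window_centers`` is the mean of each window's time points;
    ``middle_times`` is the middle sample of each window (for an even
    window length, the earlier of the two central samples) and is the time
    reported for lysis onsets.
    """

    window_centers: np.ndarray
    middle_times: np.ndarray
    slopes: np.ndarray
    window_points: int
    window_min: float

    def __len__(self) -> int:
        return int(self.slopes.size)


@dataclass
class GrowthResult:
    """Maximum-slope growth rate and derived doubling time."""

    mu: float  # 1/min
    doubling_time: float  # minutes; nan when mu <= 0
    search_interval: tuple[float, float]
    argmax_center: float

    @property
    def defined(self) -> bool:
        """Whether the doubling time is defined (mu > 0)."""
        return self.mu > 0


@dataclass
class InflectionResult:
    """First positive-to-negative slope transition (lysis onset)."""

    found: bool
    time_min: float
    window_index: int


@dataclass
class GroupTestResult:
    """Welch two-sample t-test outcome."""

    t_statistic: float
    df: float
    p_two_sided: float


def window_points(dt_min: float, window_min: float = 40.0) -> int:
    """Number of samples in a sliding window: floor(window/dt) + 1."""
    if dt_min <= 0:
        raise ValueError("dt_min must be > 0")
    n = int(math.floor(window_min / dt_min + 1e-9)) + 1
    if n < 2:
        raise ValueError(
            f"window of {window_min:g} min holds fewer than 2 samples at "
            f"dt = {dt_min:g} min; a slope needs at least 2 points"
        )
    return n


def sliding_slopes(
    traj: Trajectory,
    window_min: float = 40.0,
    dt_min: float | None = None,
) -> SlopeSeries:
    """OLS slopes of ln(value) vs time over every full sliding window.

    Excluded samples and non-positive values are dropped (the latter with a
    warning); windows are formed only from runs of consecutive retained
    samples and advance one sample at a time.
    """
    retained = traj.retained_mask()
    nonpos = retained & (traj.values <= 0)
    if nonpos.any():
        warnings.warn(
            f"trajectory {traj.id!r}: dropping {int(nonpos.sum())} "
            "non-positive samples before log transform",
            stacklevel=2,
        )
        retained &= traj.values > 0
    idx = np.flatnonzero(retained)
    if dt_min is None:
        if traj.times.size < 2:
            raise ValueError("cannot infer dt_min from fewer than 2 samples")
        dt_min = float(np.median(np.diff(traj.times)))
    npts = window_points(dt_min, window_min)
    if idx.size < npts:
        raise ValueError(
            f"trajectory {traj.id!r}: {idx.size} retained samples, "
            f"need at least {npts} for one window"
        )
    centers, mids, slopes = [], [], []
    runs = np.split(idx, np.flatnonzero(np.diff(idx) != 1) + 1)
    mid_offset = (npts - 1) // 2
    for run in runs:
        if run.size < npts:
            continue
        t = traj.times[run]
        y = np.log(traj.values[run])
        tw = sliding_window_view(t, npts)
        yw = sliding_window_view(y, npts)
        tbar = tw.mean(axis=1)
        ybar = yw.mean(axis=1)
        dt_c = tw - tbar[:, None]
        num = (dt_c * (yw - ybar[:, None])).sum(axis=1)
        den = (dt_c**2).sum(axis=1)
        centers.append(tbar)
        mids.append(tw[:, mid_offset])
        slopes.append(num / den)
    if not centers:
        raise ValueError(
            f"trajectory {traj.id!r}: no run of {npts} consecutive retained samples"
        )
    return SlopeSeries(
        window_centers=np.concatenate(centers),
        middle_times=np.concatenate(mids),
        slopes=np.concatenate(slopes),
        window_points=npts,
        window_min=window_min,
    )


def _resolve_interval(search_interval) -> tuple[float, float]:
    if isinstance(search_interval, str):
        try:
            return SEARCH_PRESETS[search_interval]
        except KeyError:
            raise ValueError(
                f"unknown preset {search_interval!r}; known: {sorted(SEARCH_PRESETS)}"
            ) from None
    lo, hi = search_interval
    if hi <= lo:
        raise ValueError("empty search interval")
    return float(lo), float(hi)


def growth_rate(
    traj: Trajectory,
    search_interval="droplet",
    window_min: float = 40.0,
    dt_min: float | None = None,
) -> GrowthResult:
    """Maximum sliding-window slope within the search interval.

    ``search_interval`` is a preset name or an explicit (t_lo, t_hi) in
    minutes; only windows whose center lies inside it compete.  The
    doubling time is ln2/mu, reported as nan when mu <= 0.
    """
    lo, hi = _resolve_interval(search_interval)
    ss = sliding_slopes(traj, window_min=window_min, dt_min=dt_min)
    sel = (ss.window_centers >= lo) & (ss.window_centers <= hi)
    if not sel.any():
        raise ValueError(
            f"trajectory {traj.id!r}: no window center inside [{lo:g}, {hi:g}] min"
        )
    slopes = ss.slopes[sel]
    centers = ss.window_centers[sel]
    j = int(np.argmax(slopes))
    mu = float(slopes[j])
    doubling = LN2 / mu if mu > 0 else float("nan")
    return GrowthResult(
        mu=mu,
        doubling_time=doubling,
        search_interval=(lo, hi),
        argmax_center=float(centers[j]),
    )


def find_inflection(
    slopes: SlopeSeries,
    min_time: float = 0.0,
    persistence: int = 1,
) -> InflectionResult:
    """First window where the sliding slope turns from positive to negative.

    Scanning in time order over windows with center >= ``min_time``, the
    transition fires at the first index i with slope[i] > 0 followed by
    ``persistence`` consecutive windows with slope <= 0; the reported time
    is the middle time point of window i+1.  ``found`` is False when no
    transition exists.
    """
    if persistence < 1:
        raise ValueError("persistence must be >= 1")
    if len(slopes) < 2:
        raise ValueError("need at least 2 windows to detect a transition")
    s = slopes.slopes
    c = slopes.window_centers
    for i in range(len(s) - persistence):
        if c[i] < min_time:
            continue
        if s[i] > 0 and np.all(s[i + 1 : i + 1 + persistence] <= 0):
            return InflectionResult(
                found=True,
                time_min=float(slopes.middle_times[i + 1]),
                window_index=i + 1,
            )
    return InflectionResult(found=False, time_min=float("nan"), window_index=-1)


def fold_change(traj: Trajectory, t_ref: float, t_query: float, atol: float = 1e-6) -> float:
    """Signal ratio value(t_query) / value(t_ref)."""
    v_ref = traj.value_at(t_ref, atol=atol)
    v_query = traj.value_at(t_query, atol=atol)
    if v_ref == 0:
        raise ValueError(f"trajectory {traj.id!r}: zero reference value at t={t_ref:g}")
    return v_query / v_ref


def fold_decrease(traj: Trajectory, t_ref: float, t_query: float, atol: float = 1e-6) -> float:
    """An 'x-fold decrease': value(t_ref) / value(t_query)."""
    v_ref = traj.value_at(t_ref, atol=atol)
    v_query = traj.value_at(t_query, atol=atol)
    if v_query == 0:
        raise ValueError(f"trajectory {traj.id!r}: zero value at t={t_query:g}")
    return v_ref / v_query


def kill_fraction(
    traj: Trajectory,
    t_ref: float | None = None,
    t_query: float | None = None,
    window_min: float = 40.0,
    min_time: float = 0.0,
    atol: float = 1e-6,
) -> float:
    """Percentage of the population killed between two time points.

    100 x (1 - value(t_query)/value(t_ref)), clamped to [0, 100] at
    reporting.  ``t_ref`` defaults to the trajectory's lysis-onset time (a
    peak proxy); ``t_query`` defaults to the last retained sample.
    """
    if t_ref is None:
        infl = find_inflection(sliding_slopes(traj, window_min=window_min), min_time=min_time)
        if not infl.found:
            raise ValueError(
                f"trajectory {traj.id!r}: no lysis onset found to anchor t_ref"
            )
        t_ref = infl.time_min
    if t_query is None:
        retained = np.flatnonzero(traj.retained_mask())
        t_query = float(traj.times[retained[-1]])
    v_ref = traj.value_at(t_ref, atol=atol)
    v_query = traj.value_at(t_query, atol=atol)
    if v_ref == 0:
        raise ValueError(f"trajectory {traj.id!r}: zero reference value at t={t_ref:g}")
    pct = 100.0 * (1.0 - v_query / v_ref)
    return float(min(max(pct, 0.0), 100.0))


def cohort_summary(
    trajectories: list[Trajectory],
    preset="droplet",
    window_min: float = 40.0,
    min_time: float | None = None,
    persistence: int = 1,
) -> tuple[pd.DataFrame, dict]:
    """Per-trajectory growth and lysis-onset results plus cohort statistics.

    ``min_time`` for the onset scan defaults to the start of the growth-rate
    search interval, which skips loading transients.  The cohort summary
    reports mean +/- SD of defined doubling times, mean +/- SD of onset
    times among trajectories with an onset, and the fraction of
    trajectories that declined (onset found).
    """
    if not trajectories:
        raise ValueError("empty cohort")
    lo, hi = _resolve_interval(preset)
    if min_time is None:
        min_time = lo
    rows = []
    for traj in trajectories:
        mu = doubling = np.nan
        onset = np.nan
        declined = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                gr = growth_rate(traj, search_interval=(lo, hi), window_min=window_min)
                mu, doubling = gr.mu, gr.doubling_time
            except ValueError:
                pass
            try:
                ss = sliding_slopes(traj, window_min=window_min)
                infl = find_inflection(ss, min_time=min_time, persistence=persistence)
                declined = infl.found
                onset = infl.time_min if infl.found else np.nan
            except ValueError:
                pass
        rows.append(
            {
                "id": traj.id,
                "mu_per_min": mu,
                "doubling_min": doubling,
                "declined": declined,
                "inflection_min": onset,
            }
        )
    table = pd.DataFrame(rows)
    doublings = table["doubling_min"].dropna()
    onsets = table["inflection_min"].dropna()
    summary = {
        "n_trajectories": len(table),
        "doubling_min_mean": float(doublings.mean()) if len(doublings) else float("nan"),
        "doubling_min_sd": float(doublings.std(ddof=1)) if len(doublings) > 1 else 0.0,
        "inflection_min_mean": float(onsets.mean()) if len(onsets) else float("nan"),
        "inflection_min_sd": float(onsets.std(ddof=1)) if len(onsets) > 1 else 0.0,
        "declined_fraction": float(table["declined"].mean()),
    }
    return table, summary


def welch_t_test(group_a, group_b) -> GroupTestResult:
    """Two-tailed two-sample heteroscedastic (Welch) t-test.

    t = (mean_a - mean_b) / sqrt(s_a^2/n_a + s_b^2/n_b), with
    Welch-Satterthwaite degrees of freedom and a two-sided p-value from the
    t distribution.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("degenerate groups: both variances are zero")
    sa = va / a.size
    sb = vb / b.size
    se2 = sa + sb
    t = float((a.mean() - b.mean()) / math.sqrt(se2))
    df = float(se2**2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1)))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return GroupTestResult(t_statistic=t, df=df, p_two_sided=p)
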