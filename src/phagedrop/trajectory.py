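"""The central analysis object: one droplet's (or well's) signal versus time."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Trajectory:
    """Fluorescence (or absorbance) signal of one compartment over time.

    Parameters
    ----------
    id : str
        Label of the droplet or well.
    times : array of float
        Sampling times in minutes, strictly increasing.
    values : array of float
        Signal in arbitrary units, non-negative.
    excluded : frozenset of int
        Indices of samples flagged unusable (e.g. out-of-focus frames).
        Flagged samples are kept in place but skipped by the analytics.
    """

    id: str
    times: np.ndarray
    values: np.ndarray
    excluded: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError(f"trajectory {self.id!r}: times must be strictly increasing")
        if np.any(~np.isfinite(self.times)) or np.any(~np.isfinite(self.values)):
            raise ValueError(f"trajectory {self.id!r}: non-finite entries")
        if np.any(self.values < 0):
            raise ValueError(f"trajectory {self.id!r}: negative signal values")
        self.excluded = frozenset(int(i) for i in self.excluded)
        if any(i < 0 or i >= self.times.size for i in self.excluded):
            raise ValueError(f"trajectory {self.id!r}: excluded index out of range")

    def __len__(self) -> int:
        return int(self.times.size)

    def retained_mask(self) -> np.ndarray:
        """Boolean mask of samples not flagged as excluded."""
        mask = np.ones(self.times.size, dtype=bool)
        if self.excluded:
            mask[list(self.excluded)] = False
        return mask

    def value_at(self, t: float, atol: float = 1e-6) -> float:
        """Signal at time ``t`` (minutes).

        The sample time must match ``t`` within ``atol`` and must not be
        excluded; otherwise a ``ValueError`` is raised.
        """
        if self.times.size == 0:
            raise ValueError(f"trajectory {self.id!r} is empty")
        i = int(np.argmin(np.abs(self.times - t)))
        if abs(self.times[i] - t) > atol:
            raise ValueError(
                f"trajectory {self.id!r}: no sample at t={t:g} min "
                f"(nearest is {self.times[i]:g})"
            )
        if i in self.excluded:
            raise ValueError(f"trajectory {self.id!r}: sample at t={t:g} min is excluded")
        return float(self.values[i])
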