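"""Enumeration and dosing arithmetic for droplet phage assays.

Viable-count densities (CFU/mL from colony counts, PFU/mL from plaque
counts), multiplicity of infection, the oblate-spheroid droplet volume of a
circular trap, and expected Poisson occupancy per droplet.

Unit conventions, fixed in one place: 1 pL = 1e3 um^3 and 1 mL = 1e9 pL;
the dilution factor is the plated fraction of the original concentration
(e.g. 1e-6), so a smaller factor yields a larger density estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

__all__ = [
    "UM3_PER_PL",
    "PL_PER_ML",
    "AssayCounts",
    "DropletGeometry",
    "parse_dilution",
    "density_per_ml",
    "moi",
    "droplet_volume_pl",
    "expected_cells_per_droplet",
    "Occupancy",
]

UM3_PER_PL = 1e3
PL_PER_ML = 1e9


@dataclass(frozen=True)
class AssayCounts:
    """Colonies or plaques counted on one plate.

    ``dilution_factor`` is the fraction of the original concentration that
    was plated; ``volume_ml`` is the plated volume in mL.
    """

    n_units: int
    dilution_factor: float
    volume_ml: float

    def __post_init__(self) -> None:
        if self.n_units < 0 or self.n_units != int(self.n_units):
            raise ValueError("n_units must be a non-negative integer")
        if not 0.0 < self.dilution_factor <= 1.0:
            raise ValueError("dilution_factor must be in (0, 1]")
        if self.volume_ml <= 0:
            raise ValueError("volume_ml must be > 0")


@dataclass(frozen=True)
class DropletGeometry:
    """Trap geometry: equatorial diameter and polar height, micrometers."""

    diameter_um: float = 60.0
    height_um: float = 15.0

    def __post_init__(self) -> None:
        if self.diameter_um < 0 or self.height_um < 0:
            raise ValueError("dimensions must be >= 0")


def parse_dilution(value) -> float:
    """Parse a dilution factor given as a float or a '10^-6'-style string."""
    if isinstance(value, str):
        text = value.strip().replace(" ", "")
        if "^" in text:
            base, exponent = text.split("^", 1)
            value = float(base) ** float(exponent)
        else:
            value = float(text)
    value = float(value)
    if not 0.0 < value <= 1.0:
        raise ValueError("dilution factor must be in (0, 1]")
    return value


def density_per_ml(counts: AssayCounts) -> float:
    """CFU/mL or PFU/mL: n_units / (dilution_factor x plated volume)."""
    return counts.n_units / (counts.dilution_factor * counts.volume_ml)


def moi(
    pfu_per_ml: float,
    v_phage_ml: float,
    cfu_per_ml: float,
    v_culture_ml: float,
) -> float:
    """Multiplicity of infection: phage particles per bacterial cell."""
    cells = cfu_per_ml * v_culture_ml
    if cells <= 0:
        raise ValueError("the mixture must contain bacterial cells")
    return (pfu_per_ml * v_phage_ml) / cells


def droplet_volume_pl(geom: DropletGeometry) -> float:
    """Oblate-spheroid droplet volume in picoliters.

    V = (4/3) pi (d/2)^2 (h/2) in um^3, converted at 1 pL = 1e3 um^3.
    For the 60 um x 15 um trap this gives 9000 pi um^3 ~= 28 pL.
    """
    a = geom.diameter_um / 2.0
    c = geom.height_um / 2.0
    volume_um3 = (4.0 / 3.0) * math.pi * a * a * c
    return volume_um3 / UM3_PER_PL


class Occupancy(NamedTuple):
    """Expected Poisson loading of one droplet."""

    mean_cells: float
    p_empty: float


def expected_cells_per_droplet(cfu_per_ml: float, volume_pl: float) -> Occupancy:
    """Mean cells per droplet, cfu_per_ml x volume_pl / 1e9, and P(empty)."""
    if cfu_per_ml < 0 or volume_pl < 0:
        raise ValueError("inputs must be >= 0")
    mean = cfu_per_ml * volume_pl / PL_PER_ML
    return Occupancy(mean_cells=mean, p_empty=math.exp(-mean))
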