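"""Synthetic fluorescence frame renderer.

Emulates the imaging conditions the extraction pipeline has to undo:
a smooth multiplicative shading (illumination) field, an additive uniform
background, cells as Gaussian intensity kernels confined to droplet discs
(a configurable fraction rendered wider and dimmer to mimic out-of-focus
cells), and optional Poisson shot noise:

    image = shading * (background + sum of cell kernels), then shot noise.

All geometry is specified in micrometers and converted through the pixel
size; cells are placed uniformly within their droplet disc each frame,
which emulates the within-droplet motility that reshuffles cells between
frames.
"""

from __future__ import annotations

import math

import numpy as np

from .images import CircularROI, FrameStack
from .params import OpticsParams
from .simulate import DropletState, as_rng

__all__ = [
    "shading_field",
    "place_cells",
    "render_frame",
    "render_stack",
    "render_flatfield",
    "droplet_rois",
]


def shading_field(optics: OpticsParams) -> np.ndarray:
    """Evaluate the strictly positive multiplicative illumination field."""
    h, w = optics.image_size_px
    spec = optics.shading
    cy = spec.center_frac[1] * (h - 1)
    cx = spec.center_frac[0] * (w - 1)
    sigma = spec.sigma_frac * min(h, w)
    yy, xx = np.mgrid[0:h, 0:w]
    field = 1.0 + spec.amplitude * np.exp(
        -((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * sigma**2)
    )
    return field


def place_cells(counts, optics: OpticsParams, rng=None) -> np.ndarray:
    """Place cells uniformly inside droplet discs; returns (N, 2) um coords.

    ``counts`` is one integer per droplet in ``optics.droplet_centers_um``
    (a scalar is broadcast to all droplets).
    """
    rng = as_rng(rng)
    centers = optics.droplet_centers_um
    counts = np.broadcast_to(np.asarray(counts, dtype=int), (len(centers),))
    if np.any(counts < 0):
        raise ValueError("cell counts must be >= 0")
    points = []
    for (cx, cy), n in zip(centers, counts):
        if n == 0:
            continue
        r = optics.droplet_radius_um * np.sqrt(rng.random(n))
        theta = rng.random(n) * 2.0 * np.pi
        points.append(np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta)]))
    if not points:
        return np.empty((0, 2))
    return np.vstack(points)


def _check_inside_droplets(positions_um: np.ndarray, optics: OpticsParams) -> None:
    if positions_um.size == 0:
        return
    ok = np.zeros(len(positions_um), dtype=bool)
    for cx, cy in optics.droplet_centers_um:
        d2 = (positions_um[:, 0] - cx) ** 2 + (positions_um[:, 1] - cy) ** 2
        ok |= d2 <= optics.droplet_radius_um**2
    if not ok.all():
        raise ValueError("cell positions outside every droplet disc")


def _add_kernel(img: np.ndarray, x: float, y: float, sigma: float, total: float) -> None:
    """Accumulate a 2-D Gaussian of integrated intensity ``total`` (in px)."""
    h, w = img.shape
    half = max(3, int(math.ceil(5.0 * sigma)))
    x0, x1 = int(math.floor(x)) - half, int(math.floor(x)) + half + 1
    y0, y1 = int(math.floor(y)) - half, int(math.floor(y)) + half + 1
    x0, x1 = max(x0, 0), min(x1, w)
    y0, y1 = max(y0, 0), min(y1, h)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1) - x
    ys = np.arange(y0, y1) - y
    amp = total / (2.0 * np.pi * sigma**2)
    img[y0:y1, x0:x1] += amp * np.exp(
        -(ys[:, None] ** 2 + xs[None, :] ** 2) / (2.0 * sigma**2)
    )


def render_frame(cells, optics: OpticsParams, rng=None) -> np.ndarray:
    """Render one fluorescence frame.

    ``cells`` may be a ``DropletState`` (its fluorescent population is
    rounded and placed in every droplet), an int or sequence of per-droplet
    counts, or an (N, 2) array of explicit cell positions in micrometers
    (which must fall inside a droplet disc).
    """
    rng = as_rng(rng)
    if isinstance(cells, DropletState):
        cells = int(round(cells.n_fluorescent))
    cells_arr = np.asarray(cells)
    if cells_arr.ndim == 2 and cells_arr.shape[1] == 2:
        positions = np.asarray(cells_arr, dtype=float)
        _check_inside_droplets(positions, optics)
    else:
        positions = place_cells(cells_arr, optics, rng)

    h, w = optics.image_size_px
    img = np.full((h, w), float(optics.background_level))
    sigma_px = optics.cell_sigma_um / optics.pixel_size_um
    n = len(positions)
    if n:
        defocused = rng.random(n) < optics.defocus_fraction
        for (x_um, y_um), blur in zip(positions, defocused):
            x = x_um / optics.pixel_size_um
            y = y_um / optics.pixel_size_um
            if blur:
                _add_kernel(
                    img, x, y,
                    sigma_px * optics.defocus_scale,
                    optics.cell_intensity * optics.defocus_conserved_fraction,
                )
            else:
                _add_kernel(img, x, y, sigma_px, optics.cell_intensity)
    img *= shading_field(optics)
    if optics.shot_noise:
        img = rng.poisson(img).astype(float)
    return img


def render_stack(
    counts_per_frame,
    optics: OpticsParams,
    dt_min: float,
    t0_min: float = 0.0,
    rng=None,
) -> FrameStack:
    """Render a time-lapse stack from per-frame (per-droplet) cell counts."""
    rng = as_rng(rng)
    frames = [render_frame(c, optics, rng) for c in counts_per_frame]
    return FrameStack(frames=np.stack(frames), dt_min=dt_min, t0_min=t0_min)


def render_flatfield(
    optics: OpticsParams,
    level: float = 1000.0,
    n_frames: int = 5,
    noise_sd: float = 0.0,
    rng=None,
) -> FrameStack:
    """Render a flat-field calibration stack (uniform fluorescein slide).

    Each frame is ``shading * level`` plus optional Gaussian read noise;
    the extraction pipeline builds its shading corrector from this stack.
    """
    rng = as_rng(rng)
    base = shading_field(optics) * level
    frames = [
        base + (rng.normal(0.0, noise_sd, base.shape) if noise_sd > 0 else 0.0)
        for _ in range(n_frames)
    ]
    return FrameStack(frames=np.stack(frames), dt_min=1.0)


def droplet_rois(optics: OpticsParams, margin_um: float = 3.0) -> list[CircularROI]:
    """Circular ROIs covering each droplet disc plus a small margin."""
    r_px = (optics.droplet_radius_um + margin_um) / optics.pixel_size_um
    return [
        CircularROI(
            cx=cx / optics.pixel_size_um,
            cy=cy / optics.pixel_size_um,
            r=r_px,
            id=f"roi{i:02d}",
        )
        for i, (cx, cy) in enumerate(optics.droplet_centers_um)
    ]
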