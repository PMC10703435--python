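"""Fluorescence image-extraction pipeline.

Re-implements the droplet quantification routine as code: flat-field
(shading) correction by a normalized median-projection corrector, per-frame
background masking so that pixels not covered by fluorescent cells read
exactly zero, and mean-intensity extraction over a circular ROI anchored on
each droplet.  The fixed order is: correct, mask (built on the corrected
frame), multiply, then extract.

Pixel convention: 0-based coordinates with pixel centers at integers,
x to the right (columns), y down (rows).  A pixel belongs to a circular ROI
when (x - cx)^2 + (y - cy)^2 <= r^2; this makes ROI means bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .trajectory import Trajectory

__all__ = [
    "FrameStack",
    "ShadingCorrector",
    "CircularROI",
    "build_shading_corrector",
    "apply_shading_correction",
    "background_mask",
    "subtract_background",
    "roi_pixel_mask",
    "mean_roi_intensity",
    "integrated_roi_intensity",
    "extract_trajectories",
    "focus_metric",
    "flag_out_of_focus",
    "detect_rois",
]


@dataclass
class FrameStack:
    """Ordered single-channel frames with a fixed frame interval.

    ``t0_min`` is the time of frame 0 relative to the experiment's time
    origin (e.g. the dead time between phage mixing and the first image).
    """

    frames: np.ndarray  # (T, H, W)
    dt_min: float
    t0_min: float = 0.0
    excluded_frames: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        if self.dt_min <= 0:
            raise ValueError("dt_min must be > 0")
        self.excluded_frames = frozenset(int(i) for i in self.excluded_frames)
        if any(i < 0 or i >= len(self.frames) for i in self.excluded_frames):
            raise ValueError("excluded frame index out of range")

    def __len__(self) -> int:
        return int(self.frames.shape[0])

    @property
    def times_min(self) -> np.ndarray:
        return self.t0_min + self.dt_min * np.arange(len(self))


@dataclass
class ShadingCorrector:
    """Multiplicative illumination field, normalized to median 1."""

    image: np.ndarray

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        if self.image.ndim != 2:
            raise ValueError("corrector must be a 2-D image")
        if np.any(self.image <= 0):
            raise ValueError("corrector pixels must be strictly positive")


@dataclass(frozen=True)
class CircularROI:
    """Circular region of interest around one anchored droplet."""

    cx: float
    cy: float
    r: float
    id: str = "roi"

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("ROI radius must be > 0")

    def check_inside(self, shape: tuple[int, int]) -> None:
        h, w = shape
        if (self.cx - self.r < -0.5 or self.cx + self.r > w - 0.5
                or self.cy - self.r < -0.5 or self.cy + self.r > h - 0.5):
            raise ValueError(f"ROI {self.id!r} extends outside the image")


def build_shading_corrector(flatfield) -> ShadingCorrector:
    """Pixel-wise median projection through a flat-field stack, divided by
    its own median pixel value.

    The median projection makes the corrector robust to occasional bright
    artifacts in individual flat-field frames.
    """
    frames = flatfield.frames if isinstance(flatfield, FrameStack) else np.asarray(flatfield, float)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3 or frames.shape[0] < 1:
        raise ValueError("flat-field stack must contain at least one frame")
    med = np.median(frames, axis=0)
    norm = np.median(med)
    if norm <= 0:
        raise ValueError("degenerate flat-field: non-positive median")
    image = med / norm
    if np.any(image <= 0):
        raise ValueError("degenerate flat-field: non-positive pixels after normalization")
    return ShadingCorrector(image=image)


def apply_shading_correction(frame: np.ndarray, corrector: ShadingCorrector) -> np.ndarray:
    """Pixel-wise division of a frame by the corrector field."""
    frame = np.asarray(frame, dtype=float)
    if frame.shape != corrector.image.shape:
        raise ValueError("frame and corrector shapes differ")
    return frame / corrector.image


def background_mask(
    frame: np.ndarray,
    strategy: str = "otsu",
    threshold: float | None = None,
    q: float = 50.0,
) -> np.ndarray:
    """Binary mask: 1 where the pixel is strictly above the frame threshold.

    Strategies: ``"fixed"`` uses the user-supplied ``threshold``; ``"otsu"``
    finds the per-frame Otsu threshold; ``"percentile"`` thresholds at the
    q-th percentile of the frame.
    """
    frame = np.asarray(frame, dtype=float)
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite pixels")
    if strategy == "fixed":
        if threshold is None:
            raise ValueError("strategy 'fixed' requires a threshold value")
        th = float(threshold)
    elif strategy == "otsu":
        if frame.max() == frame.min():
            raise ValueError("Otsu threshold undefined on a constant frame")
        th = float(threshold_otsu(frame))
    elif strategy == "percentile":
        th = float(np.percentile(frame, q))
    else:
        raise ValueError(f"unknown masking strategy {strategy!r}")
    return (frame > th).astype(np.uint8)


def subtract_background(frame: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Multiply the frame by the binary mask, zeroing background pixels."""
    frame = np.asarray(frame, dtype=float)
    mask = np.asarray(mask)
    if frame.shape != mask.shape:
        raise ValueError("frame and mask shapes differ")
    return frame * mask


def roi_pixel_mask(roi: CircularROI, shape: tuple[int, int]) -> np.ndarray:
    """Boolean membership mask of pixel centers inside the ROI disc."""
    h, w = shape
    yy, xx = np.ogrid[0:h, 0:w]
    return (xx - roi.cx) ** 2 + (yy - roi.cy) ** 2 <= roi.r**2


def mean_roi_intensity(frame: np.ndarray, roi: CircularROI) -> float:
    """Arithmetic mean over pixels whose centers fall inside the ROI disc."""
    frame = np.asarray(frame, dtype=float)
    roi.check_inside(frame.shape)
    mask = roi_pixel_mask(roi, frame.shape)
    n = int(mask.sum())
    if n == 0:
        raise ValueError(f"ROI {roi.id!r} covers no pixel centers")
    return float(frame[mask].sum() / n)


def integrated_roi_intensity(frame: np.ndarray, roi: CircularROI) -> float:
    """Summed intensity over the ROI disc (optional integrated readout)."""
    frame = np.asarray(frame, dtype=float)
    roi.check_inside(frame.shape)
    mask = roi_pixel_mask(roi, frame.shape)
    if not mask.any():
        raise ValueError(f"ROI {roi.id!r} covers no pixel centers")
    return float(frame[mask].sum())


def extract_trajectories(
    stack: FrameStack,
    corrector: ShadingCorrector,
    rois: list[CircularROI],
    strategy: str = "otsu",
    threshold: float | None = None,
    q: float = 50.0,
) -> list[Trajectory]:
    """Run the full pipeline on a stack and return one trajectory per ROI.

    Every frame is corrected, masked and extracted; frames listed in
    ``stack.excluded_frames`` are still measured but their indices are
    carried into ``Trajectory.excluded`` so the analytics skip them.
    Times are ``t0_min + index * dt_min``.
    """
    if len(stack) == 0:
        raise ValueError("empty frame stack")
    if not rois:
        raise ValueError("no ROIs supplied")
    for roi in rois:
        roi.check_inside(stack.frames.shape[1:])
    masks = {roi.id: roi_pixel_mask(roi, stack.frames.shape[1:]) for roi in rois}
    counts = {rid: int(m.sum()) for rid, m in masks.items()}
    if any(c == 0 for c in counts.values()):
        raise ValueError("an ROI covers no pixel centers")
    values = {roi.id: [] for roi in rois}
    for frame in stack.frames:
        corrected = apply_shading_correction(frame, corrector)
        mask = background_mask(corrected, strategy=strategy, threshold=threshold, q=q)
        cleaned = subtract_background(corrected, mask)
        for roi in rois:
            m = masks[roi.id]
            values[roi.id].append(float(cleaned[m].sum() / counts[roi.id]))
    times = stack.times_min
    return [
        Trajectory(
            id=roi.id,
            times=times.copy(),
            values=np.maximum(np.array(values[roi.id]), 0.0),
            excluded=stack.excluded_frames,
        )
        for roi in rois
    ]


def focus_metric(frame: np.ndarray) -> float:
    """Variance of the Laplacian; low values indicate defocused frames."""
    return float(np.var(ndimage.laplace(np.asarray(frame, dtype=float))))


def flag_out_of_focus(stack: FrameStack, fraction: float = 0.5) -> frozenset:
    """Indices whose focus metric falls below ``fraction`` x stack median."""
    metrics = np.array([focus_metric(f) for f in stack.frames])
    cutoff = fraction * np.median(metrics)
    return frozenset(int(i) for i in np.flatnonzero(metrics < cutoff))


def detect_rois(
    frame: np.ndarray,
    radius_px: float,
    n_rois: int,
    radius_tolerance_px: float = 5.0,
) -> list[CircularROI]:
    """Locate droplet ROIs by a circular Hough transform on one frame.

    Intended as a fallback when no manually drawn ROI table is available;
    a user-supplied ROI CSV always takes precedence.
    """
    from skimage.feature import canny
    from skimage.transform import hough_circle, hough_circle_peaks

    frame = np.asarray(frame, dtype=float)
    span = frame.max() - frame.min()
    if span == 0:
        raise ValueError("cannot detect ROIs on a constant frame")
    edges = canny((frame - frame.min()) / span, sigma=2.0)
    radii = np.arange(
        max(3, int(radius_px - radius_tolerance_px)),
        int(radius_px + radius_tolerance_px) + 1,
    )
    accum = hough_circle(edges, radii)
    _, cxs, cys, rads = hough_circle_peaks(
        accum, radii, total_num_peaks=n_rois, min_xdistance=int(radius_px), min_ydistance=int(radius_px)
    )
    return [
        CircularROI(cx=float(x), cy=float(y), r=float(r), id=f"roi{i:02d}")
        for i, (x, y, r) in enumerate(zip(cxs, cys, rads))
    ]
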