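"""Tablet detection in top-down frames and calibrated area measurement.

The tablet carries a red dye so that it stands out against the pink
silicone tongue.  Detection therefore works on a red-dominance transform
``R - max(G, B)`` rather than plain grayscale edges: the dyed tablet has a
much larger red excess than either the tongue or the acrylic palate, and
the transform is insensitive to overall illumination shifts.  The
thresholded mask is morphologically closed, hole-filled, and reduced to
its sufficiently large connected components; the reported area is the
pixel count of those components divided by the square of the px/mm scale.

Detached fragments above the minimum component size are counted by
default ("all" mode), because washed-away particles contribute to the
measured area during disintegration; a largest-component-only mode is
available for cores-only analysis.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure, morphology

from .cycle import CompressionCycleSpec
from .errors import InvalidInputError

__all__ = [
    "SegmentationParams",
    "TabletMask",
    "ImageStack",
    "segment_tablet",
    "calibrate_scale",
    "area_mm2",
    "load_image_stack",
    "measure_stack",
]

MIN_FRAME_DIM = 16


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable parameters of tablet segmentation.

    threshold : int or None
        Fixed cut on the red-dominance transform (0-255 scale).  ``None``
        selects an automatic Otsu threshold per frame, with a bimodality
        guard (``min_contrast``) so that a frame without any tablet does
        not get half its background labelled as tablet.
    min_component_px : int
        Connected components smaller than this are discarded as noise
        while sub-millimetre fragments (>= 3x3 px at 10 px/mm) survive.
    fragment_mode : {"all", "largest"}
        Whether all surviving components or only the largest one count
        toward the measured area.
    min_contrast : int
        Minimum separation (in dominance units) between the mean of the
        above- and below-threshold classes for an automatic threshold to
        be accepted; otherwise the frame is declared tablet-free.
    """

    threshold: int | None = None
    min_component_px: int = 9
    fragment_mode: str = "all"
    min_contrast: int = 40
    closing_radius: int = 2

    def __post_init__(self) -> None:
        if self.fragment_mode not in ("all", "largest"):
            raise InvalidInputError("fragment_mode must be 'all' or 'largest'")
        if self.min_component_px < 1:
            raise InvalidInputError("min_component_px must be >= 1")


@dataclass(frozen=True)
class TabletMask:
    """Binary tablet mask plus its summary statistics."""

    mask: np.ndarray
    component_count: int
    area_px: int

    def __post_init__(self) -> None:
        if self.area_px != int(self.mask.sum()):
            raise InvalidInputError("area_px must equal the number of true pixels")


@dataclass
class ImageStack:
    """Ordered top-down colour frames with timing and scale metadata."""

    frames: list[np.ndarray]
    timestamps_ms: np.ndarray
    scale_px_per_mm: float
    provenance: str = ""

    def __post_init__(self) -> None:
        self.timestamps_ms = np.asarray(self.timestamps_ms, dtype=float)
        if len(self.frames) != len(self.timestamps_ms):
            raise InvalidInputError("one timestamp per frame required")
        if len(self.frames) == 0:
            raise InvalidInputError("stack must contain at least one frame")
        if np.any(np.diff(self.timestamps_ms) <= 0):
            raise InvalidInputError("timestamps must be strictly increasing")
        if self.scale_px_per_mm <= 0:
            raise InvalidInputError("scale_px_per_mm must be positive")
        shape0 = self.frames[0].shape
        if any(f.shape != shape0 for f in self.frames):
            raise InvalidInputError("all frames must share the same dimensions")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def duration_ms(self) -> float:
        return float(self.timestamps_ms[-1])


def red_dominance(frame: np.ndarray) -> np.ndarray:
    """Red-excess transform R - max(G, B), clipped at zero."""
    rgb = frame.astype(np.int16)
    dom = rgb[..., 0] - np.maximum(rgb[..., 1], rgb[..., 2])
    return np.clip(dom, 0, None).astype(np.uint8)


def _auto_threshold(dom: np.ndarray, params: SegmentationParams) -> int | None:
    """Otsu threshold on the dominance image, or None if unimodal."""
    if dom.max() == dom.min():
        return None
    t = filters.threshold_otsu(dom)
    above = dom[dom > t]
    below = dom[dom <= t]
    if above.size == 0 or below.size == 0:
        return None
    if float(above.mean()) - float(below.mean()) < params.min_contrast:
        return None  # no bimodal red structure: tablet-free frame
    return int(t)


def segment_tablet(
    frame: np.ndarray, params: SegmentationParams | None = None
) -> TabletMask:
    """Segment the dyed tablet in one top-down colour frame.

    Pipeline: red-dominance transform -> threshold (fixed or automatic)
    -> morphological closing of the contour -> hole filling -> size
    filtering of connected components.  An empty mask (area 0) is a
    valid result for a tablet-free frame, not an error.
    """
    params = params or SegmentationParams()
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[2] < 3:
        raise InvalidInputError("frame must be an H x W x 3 colour raster")
    if frame.shape[0] < MIN_FRAME_DIM or frame.shape[1] < MIN_FRAME_DIM:
        raise InvalidInputError(
            f"frame dimensions must be at least {MIN_FRAME_DIM}x{MIN_FRAME_DIM}"
        )

    dom = red_dominance(frame)
    if params.threshold is not None:
        thr: int | None = int(params.threshold)
    else:
        thr = _auto_threshold(dom, params)
    if thr is None:
        empty = np.zeros(dom.shape, dtype=bool)
        return TabletMask(empty, 0, 0)

    raw = dom > thr
    if params.closing_radius > 0:
        raw = morphology.closing(raw, morphology.disk(params.closing_radius))
    filled = ndimage.binary_fill_holes(raw)

    labels, n = measure.label(filled, return_num=True)
    if n == 0:
        return TabletMask(np.zeros(dom.shape, dtype=bool), 0, 0)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    keep = np.flatnonzero(sizes >= params.min_component_px)
    if keep.size == 0:
        return TabletMask(np.zeros(dom.shape, dtype=bool), 0, 0)
    if params.fragment_mode == "largest":
        keep = np.array([keep[np.argmax(sizes[keep])]])
    mask = np.isin(labels, keep)
    return TabletMask(mask, int(keep.size), int(mask.sum()))


def calibrate_scale(reference_length_mm: float, reference_length_px: float) -> float:
    """Spatial scale (px/mm) from a reference object of known length."""
    if reference_length_mm <= 0 or reference_length_px <= 0:
        raise InvalidInputError("reference lengths must be positive")
    return reference_length_px / reference_length_mm


def area_mm2(mask: TabletMask | int, scale_px_per_mm: float) -> float:
    """Convert a mask (or raw pixel count) to calibrated area in mm^2."""
    if scale_px_per_mm <= 0:
        raise InvalidInputError("scale_px_per_mm must be positive")
    area_px = mask.area_px if isinstance(mask, TabletMask) else int(mask)
    return area_px / scale_px_per_mm**2


_FRAME_RE = re.compile(r"frame_(\d+)\.(png|tif|tiff)$", re.IGNORECASE)


def load_image_stack(
    directory: str | Path,
    scale_px_per_mm: float | None = None,
    fps: float | None = None,
) -> ImageStack:
    """Load a PNG/TIFF frame sequence (``frame_%06d.png``) as an ImageStack.

    If the directory contains a ``manifest.json`` written by the synthetic
    generator (or a compatible acquisition tool), timestamps and scale are
    taken from it; otherwise ``fps`` and ``scale_px_per_mm`` must be given
    and timestamps are assigned as ``k * 1000 / fps``.
    """
    directory = Path(directory)
    paths = sorted(p for p in directory.iterdir() if _FRAME_RE.search(p.name))
    if not paths:
        raise InvalidInputError(f"no frame_*.png/tiff files found in {directory}")
    frames = [np.asarray(iio.imread(p))[..., :3] for p in paths]

    manifest_path = directory / "manifest.json"
    timestamps = None
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        timestamps = manifest.get("frame_times_ms")
        scale_px_per_mm = scale_px_per_mm or manifest.get("px_per_mm")
    if timestamps is None:
        if fps is None:
            raise InvalidInputError(
                "fps required when the stack has no manifest timestamps"
            )
        timestamps = [k * 1000.0 / fps for k in range(len(frames))]
    if scale_px_per_mm is None:
        raise InvalidInputError("scale_px_per_mm required (no manifest scale)")
    return ImageStack(
        frames=frames,
        timestamps_ms=np.asarray(timestamps, dtype=float),
        scale_px_per_mm=float(scale_px_per_mm),
        provenance=str(directory),
    )


def measure_stack(
    stack: ImageStack,
    params: SegmentationParams | None = None,
    spec: CompressionCycleSpec | None = None,
) -> pd.DataFrame:
    """Per-frame area table: frame_index, time_ms, area_px, area_mm2, components."""
    spec = spec or CompressionCycleSpec()
    rows = []
    for i, (frame, t_ms) in enumerate(zip(stack.frames, stack.timestamps_ms)):
        m = segment_tablet(frame, params)
        rows.append(
            {
                "frame_index": i,
                "time_ms": float(t_ms),
                "area_px": m.area_px,
                "area_mm2": area_mm2(m, stack.scale_px_per_mm),
                "component_count": m.component_count,
            }
        )
    return pd.DataFrame(rows)
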