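"""Avoidance distance from a segmentation mask.

The avoidance distance of one CFP image is the mean Euclidean distance from
the pixels along the inner perimeter of the fish distribution — i.e. the
outer boundary of the fish-free region — to the structure centre, converted
to metres.  Flight responses (category ``out_of_range``) carry the maximum
instrumented range and a ``censored`` flag so downstream statistics can keep
them (conservatively underestimating the flight magnitude) or filter them.
``invalid`` images have no numeric distance and are excluded from analysis
tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import NotMeasurableError
from .segmentation import SegmentationMask

__all__ = ["AvoidanceMeasurement", "inner_contour", "avoidance_distance", "measurements_table"]


@dataclass(frozen=True)
class AvoidanceMeasurement:
    """One avoidance distance with its phase/treatment labels."""

    distance: float  # metres
    censored: bool
    category: str
    phase: str = ""
    level: str = ""
    pen: str = ""
    depth: float = float("nan")
    replicate: int = 0
    n_frames: int = 0

    def __post_init__(self):
        if self.distance < 0:
            raise ValueError("distance must be >= 0")


def inner_contour(mask: SegmentationMask) -> np.ndarray:
    """Ordered (row, col) boundary pixels of the fish-free region.

    The boundary is the set of fish-free pixels with at least one
    non-fish-free 4-neighbour (raster edges count as outside), which is the
    one-pixel-thick 8-connected contour a boundary-tracing pass would
    produce; pixels are returned ordered by bearing angle.  For an
    ``out_of_range`` mask this is the pixel circle at the maximum
    instrumented range.

    Raises
    ------
    NotMeasurableError
        For category ``invalid`` (no fish-free region exists).
    """
    if mask.category == "invalid":
        raise NotMeasurableError("an invalid image has no measurable contour")
    region = mask.fish_free
    if not region.any():
        raise NotMeasurableError("fish-free region is empty")
    cross = ndimage.generate_binary_structure(2, 1)
    interior = ndimage.binary_erosion(region, structure=cross, border_value=0)
    boundary = region & ~interior
    rows, cols = np.nonzero(boundary)
    angles = np.arctan2(mask.centre[0] - rows, cols - mask.centre[1])
    order = np.argsort(angles, kind="stable")
    return np.column_stack([rows[order], cols[order]])


def avoidance_distance(
    mask: SegmentationMask, metres_per_pixel: float | None = None
) -> AvoidanceMeasurement:
    """Mean contour-pixel distance to the structure centre, in metres.

    ``out_of_range`` masks return exactly the maximum range with
    ``censored=True``; ``invalid`` raises :class:`NotMeasurableError`.
    """
    if mask.category == "invalid":
        raise NotMeasurableError("an invalid image has no avoidance distance")
    mpp = metres_per_pixel if metres_per_pixel is not None else mask.metres_per_pixel
    if mpp <= 0:
        raise ValueError("metres_per_pixel must be positive")

    meta = dict(
        category=mask.category,
        phase=mask.phase,
        level=mask.level,
        pen=mask.pen,
        depth=mask.depth,
        replicate=mask.replicate,
        n_frames=mask.n_frames,
    )
    if mask.category == "out_of_range":
        return AvoidanceMeasurement(distance=mask.config.max_range, censored=True, **meta)

    contour = inner_contour(mask)
    d = np.hypot(contour[:, 0] - mask.centre[0], contour[:, 1] - mask.centre[1])
    return AvoidanceMeasurement(distance=float(d.mean() * mpp), censored=False, **meta)


def measurements_table(measurements: Iterable[AvoidanceMeasurement]) -> pd.DataFrame:
    """Tidy table of measurements, one row per (event, phase)."""
    rows = [
        dict(
            replicate=m.replicate,
            pen=m.pen,
            depth=m.depth,
            level=m.level,
            phase=m.phase,
            category=m.category,
            censored=m.censored,
            distance_m=m.distance,
            n_frames=m.n_frames,
        )
        for m in measurements
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "replicate",
            "pen",
            "depth",
            "level",
            "phase",
            "category",
            "censored",
            "distance_m",
            "n_frames",
        ],
    )
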