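"""Sonar frame model and conversion between (bearing, range) echo space and
centred circular-scan raster images.

A 360-degree mechanical scanning sonar (e.g. a Ping360) sweeps a single beam
through ``n_bearings`` discrete bearings per revolution and records
``n_range_bins`` echo-strength samples along each beam.  One revolution is a
:class:`ScanFrame`; painting its samples onto a centred square raster gives a
:class:`CircularScanImage`, the representation on which fish-presence
accumulation and segmentation operate.

Coordinate convention (fixed here because only radial distances matter
downstream): bearing 0 points along +x, bearings increase counter-clockwise,
and the image y-axis points up (row index decreases with increasing y).
Range sample ``j`` lies at radius ``j * range_resolution`` from the
transducer, so sample 0 sits on the axis and the outermost sample stays
strictly inside ``max_range``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SonarConfig",
    "ScanFrame",
    "CircularScanImage",
    "render_frame",
    "image_to_polar",
]


@dataclass(frozen=True)
class SonarConfig:
    """Geometry and timing of one scanning sonar.

    Parameters
    ----------
    n_bearings
        Bearing bins per revolution (>= 8).
    n_range_bins
        Echo samples per bearing (>= 2).
    range_resolution
        Metres per range bin; ``max_range = n_range_bins * range_resolution``.
    scan_period
        Seconds per full revolution (a Ping360 needs roughly 8 s).
    exclusion_radius
        Radius of the structure/self-echo zone that is ignored by the
        segmentation, in metres.
    """

    n_bearings: int = 400
    n_range_bins: int = 200
    range_resolution: float = 0.05
    scan_period: float = 8.0
    exclusion_radius: float = 0.5

    def __post_init__(self):
        if self.n_bearings < 8:
            raise ValueError(f"n_bearings must be >= 8, got {self.n_bearings}")
        if self.n_range_bins < 2:
            raise ValueError(f"n_range_bins must be >= 2, got {self.n_range_bins}")
        if self.range_resolution <= 0:
            raise ValueError("range_resolution must be positive")
        if self.scan_period <= 0:
            raise ValueError("scan_period must be positive")
        if not 0 <= self.exclusion_radius < self.max_range:
            raise ValueError(
                f"exclusion_radius must lie in [0, max_range={self.max_range}), "
                f"got {self.exclusion_radius}"
            )

    @property
    def max_range(self) -> float:
        """Maximum instrumented range in metres."""
        return self.n_range_bins * self.range_resolution

    def bearing_angles(self) -> np.ndarray:
        """Bearing-bin centre angles in radians, CCW from +x."""
        return 2.0 * np.pi * np.arange(self.n_bearings) / self.n_bearings

    def sample_ranges(self) -> np.ndarray:
        """Radii of the range samples in metres (sample j at j * resolution)."""
        return np.arange(self.n_range_bins) * self.range_resolution


@dataclass(frozen=True)
class ScanFrame:
    """One sonar revolution: bearing-indexed intensity vectors.

    ``intensities`` has shape ``(n_bearings, n_range_bins)`` and is
    non-negative; ``t_start`` is the trial clock at revolution start.
    """

    config: SonarConfig
    intensities: np.ndarray
    t_start: float = 0.0

    def __post_init__(self):
        arr = np.asarray(self.intensities)
        expected = (self.config.n_bearings, self.config.n_range_bins)
        if arr.shape != expected:
            raise ValueError(f"intensities shape {arr.shape} != config shape {expected}")
        if np.any(arr < 0):
            raise ValueError("echo intensities must be non-negative")
        object.__setattr__(self, "intensities", arr)

    @property
    def t_end(self) -> float:
        return self.t_start + self.config.scan_period


@dataclass(frozen=True)
class CircularScanImage:
    """Centred square raster of one revolution's echoes.

    The side length is odd so the sonar axis maps to the single centre pixel
    ``centre = (row, col)``.  Every pixel farther than the instrumented
    maximum range from the centre is exactly zero.
    """

    pixels: np.ndarray
    centre: tuple[int, int]
    metres_per_pixel: float
    t_start: float = 0.0
    t_end: float = 0.0

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] != px.shape[1]:
            raise ValueError(f"raster must be square, got shape {px.shape}")
        if px.shape[0] % 2 == 0:
            raise ValueError("raster side length must be odd")
        object.__setattr__(self, "pixels", px)

    @property
    def side(self) -> int:
        return self.pixels.shape[0]


def _raster_geometry(config: SonarConfig, metres_per_pixel: float) -> tuple[int, int]:
    """Half-width (pixels) and odd side length covering max_range."""
    half = int(np.ceil(config.max_range / metres_per_pixel))
    return half, 2 * half + 1


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round half away from zero: symmetric under negation, so quarter-turn
    bearing shifts rotate the raster exactly (np.rint's half-to-even is not).
    Values within 1e-9 of a half-integer are snapped first, so the same
    physical coordinate reached through different trigonometric paths
    (cos(a + 90deg) vs -sin(a)) rounds identically."""
    q = np.round(x * 2.0) / 2.0
    x = np.where(np.abs(x - q) < 1e-9, q, x)
    return np.trunc(x + np.copysign(0.5, x))


def _sample_pixel_coords(config: SonarConfig, metres_per_pixel: float, half: int):
    """(row, col) raster coordinates of every (bearing, range) sample."""
    theta = config.bearing_angles()[:, None]
    r = config.sample_ranges()[None, :]
    col = half + _round_half_away(r * np.cos(theta) / metres_per_pixel).astype(np.intp)
    row = half - _round_half_away(r * np.sin(theta) / metres_per_pixel).astype(np.intp)
    return row, col


def render_frame(frame: ScanFrame, metres_per_pixel: float) -> CircularScanImage:
    """Paint one revolution's polar samples onto a centred raster.

    Each sample at (bearing theta, range r) contributes its intensity to the
    pixel nearest ``centre + (r cos(theta), r sin(theta)) / metres_per_pixel``;
    overlapping contributions combine by maximum (presence semantics, robust
    to double-painting at small radii where many bearings share a pixel).

    Raises
    ------
    ValueError
        If ``metres_per_pixel`` is not positive or exceeds the range
        resolution (which would alias adjacent range bins apart).
    """
    if metres_per_pixel <= 0:
        raise ValueError("metres_per_pixel must be positive")
    cfg = frame.config
    if metres_per_pixel > cfg.range_resolution + 1e-12:
        raise ValueError(
            f"metres_per_pixel ({metres_per_pixel}) must not exceed the range "
            f"resolution ({cfg.range_resolution})"
        )
    half, side = _raster_geometry(cfg, metres_per_pixel)
    row, col = _sample_pixel_coords(cfg, metres_per_pixel, half)
    pixels = np.zeros((side, side), dtype=np.float64)
    flat = row.ravel() * side + col.ravel()
    np.maximum.at(pixels.ravel(), flat, np.asarray(frame.intensities, dtype=np.float64).ravel())
    return CircularScanImage(
        pixels=pixels,
        centre=(half, half),
        metres_per_pixel=metres_per_pixel,
        t_start=frame.t_start,
        t_end=frame.t_end,
    )


def image_to_polar(image: CircularScanImage, config: SonarConfig) -> np.ndarray:
    """Sample a circular-scan raster back onto the (bearing, range) grid.

    Nearest-pixel lookup, the exact inverse of :func:`render_frame` on sparse
    frames whose echoes are separated by more than one pixel footprint.
    Returns an array of shape ``(n_bearings, n_range_bins)``.
    """
    mpp = image.metres_per_pixel
    half = image.centre[0]
    if image.centre[0] != image.centre[1] or half != (image.side - 1) // 2:
        raise ValueError("image centre must be the central pixel of the raster")
    if half * mpp < config.max_range - config.range_resolution:
        raise ValueError("raster does not cover the configured max range")
    row, col = _sample_pixel_coords(config, mpp, half)
    return image.pixels[row, col]
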