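"""Three-category segmentation of CFP images and fish-free-region masks.

Every CFP image maps to exactly one category:

``pattern``
    A clear annular fish distribution; the fish-free region is the
    star-shaped area around the structure bounded by the school's inner
    perimeter.
``out_of_range``
    No fish anywhere in the instrumented volume (flight response); the
    fish-free region is the full scan disc.
``invalid``
    Noisy or unclear data with no measurable fish-free area; the mask is
    empty.

Two backends produce these masks.  The default classical backend is a
deterministic radial-profile algorithm; a trainable backend (a per-pixel
multilayer perceptron over multi-scale intensity and geometry features,
:class:`TrainableSegmenter`) can be fitted on labelled synthetic data and is
dispatched through the same :func:`segment` surface.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import gaussian, threshold_otsu
from skimage.transform import resize

from .cfp import CFPImage
from .errors import ConfigurationError
from .simulate import SchoolParams, SonarConfig, make_invalid_frames, make_schedule, simulate_frames
from .cfp import accumulate_cfp

__all__ = [
    "SegmentationMask",
    "ClassicalSegParams",
    "segment_classical",
    "segment",
    "TrainableSegmenter",
    "train_segmenter",
    "synthetic_training_set",
]

CATEGORIES = ("pattern", "out_of_range", "invalid")


@dataclass(frozen=True)
class SegmentationMask:
    """Category plus binary fish-free raster for one CFP image."""

    category: str
    fish_free: np.ndarray  # bool raster, True = fish-free
    centre: tuple[int, int]
    metres_per_pixel: float
    config: SonarConfig
    backend: str = "classical"
    phase: str = ""
    level: str = ""
    pen: str = ""
    depth: float = float("nan")
    replicate: int = 0
    n_frames: int = 0

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        object.__setattr__(self, "fish_free", np.asarray(self.fish_free, dtype=bool))


@dataclass(frozen=True)
class ClassicalSegParams:
    """Tunables of the deterministic radial-profile backend.

    ``echo_threshold`` is either an absolute intensity (default 0.5, half the
    nominal unit echo amplitude) or the string ``"otsu"`` for a data-driven
    threshold over pixels outside the exclusion radius.  ``coverage_min`` is
    the minimal fraction of bearings with any echo required to call
    ``pattern`` rather than ``out_of_range``.  ``noise_max`` is the maximal
    admissible fraction of above-threshold pixels strictly inside the fitted
    fish-free region; beyond it the image is ``invalid``.
    """

    echo_threshold: float | str = 0.5
    coverage_min: float = 0.05
    noise_max: float = 0.02
    smoothing_window: int = 9
    erode_margin_px: int = 2
    structure_margin_bins: int = 2
    speckle_window: int = 5  # px; neighbourhood for the isolated-pixel filter
    speckle_min_neighbours: int = 2
    dense_fraction_max: float = 0.25  # above-threshold fraction marking saturation

    def __post_init__(self):
        if isinstance(self.echo_threshold, str) and self.echo_threshold != "otsu":
            raise ValueError("echo_threshold must be a number or 'otsu'")
        for name in ("coverage_min", "noise_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be odd and >= 1")
        if self.erode_margin_px < 0:
            raise ValueError("erode_margin_px must be >= 0")
        if self.structure_margin_bins < 0:
            raise ValueError("structure_margin_bins must be >= 0")
        if self.speckle_window < 1 or self.speckle_window % 2 == 0:
            raise ValueError("speckle_window must be odd and >= 1")
        if self.speckle_min_neighbours < 0:
            raise ValueError("speckle_min_neighbours must be >= 0")
        if not 0.0 <= self.dense_fraction_max <= 1.0:
            raise ValueError("dense_fraction_max must lie in [0, 1]")


def _pixel_geometry(shape: tuple[int, int], centre: tuple[int, int], mpp: float):
    """Per-pixel radius (m) and bearing angle (rad, CCW from +x, y-up)."""
    rows = np.arange(shape[0])[:, None]
    cols = np.arange(shape[1])[None, :]
    y = (centre[0] - rows) * mpp
    x = (cols - centre[1]) * mpp
    return np.hypot(x, y), np.arctan2(y, x)


def _sample_polar(image: CFPImage, array: np.ndarray | None = None):
    """Nearest-pixel samples of the CFP on the sonar's (bearing, range) grid."""
    from .sonar import _sample_pixel_coords

    cfg = image.config
    row, col = _sample_pixel_coords(cfg, image.metres_per_pixel, image.centre[0])
    src = image.pixels if array is None else array
    return src[row, col]


def _circular_median(profile: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return profile
    return ndimage.median_filter(profile, size=window, mode="wrap")


def segment_classical(
    image: CFPImage, params: ClassicalSegParams | None = None
) -> SegmentationMask:
    """Deterministic three-category segmentation of one CFP image.

    Steps: binarise at the echo threshold ignoring the exclusion zone; per
    bearing take the nearest above-threshold radius (max range where none
    exists); too few covered bearings means the fish fled the instrumented
    volume (``out_of_range``); otherwise smooth the radial profile with a
    circular moving median and take the star-shaped region inside it as the
    fish-free candidate.  If the region, eroded radially by a small margin to
    discount ordinary boundary roughness, still contains too many echoes —
    or has no measurable area at all — the image is ``invalid``.
    """
    params = params or ClassicalSegParams()
    cfg = image.config
    mpp = image.metres_per_pixel

    ranges = cfg.sample_ranges()
    # the structure's own echo hugs the exclusion zone; keep a small guard band
    excl = cfg.exclusion_radius + params.structure_margin_bins * cfg.range_resolution
    usable = ranges > excl
    radius_map, angle_map = _pixel_geometry(image.pixels.shape, image.centre, mpp)

    if params.echo_threshold == "otsu":
        polar = _sample_polar(image)
        samples = polar[:, usable].ravel()
        thr = threshold_otsu(samples) if np.ptp(samples) > 0 else float(samples[0])
    else:
        thr = float(params.echo_threshold)

    # binarise in image space and drop isolated speckle pixels: a single stray
    # near the centre is sampled by many adjacent bearings and would carve a
    # wide false notch into the radial profile.  Real echo blobs always have
    # above-threshold company nearby, at any raster resolution.
    above_img = (image.pixels > thr) & (radius_map > excl)
    if params.speckle_min_neighbours > 0:
        w = params.speckle_window
        neighbours = ndimage.uniform_filter(
            above_img.astype(float), size=w, mode="constant"
        ) * (w * w) - above_img
        above_img &= neighbours >= params.speckle_min_neighbours - 0.5

    above = _sample_polar(image, above_img)
    above[:, ~usable] = False
    has_echo = above.any(axis=1)
    coverage = float(has_echo.mean())
    meta = dict(
        centre=image.centre,
        metres_per_pixel=mpp,
        config=cfg,
        phase=image.phase,
        level=image.level,
        pen=image.pen,
        depth=image.depth,
        replicate=image.replicate,
        n_frames=image.n_frames,
        backend="classical",
    )

    if coverage < params.coverage_min:
        return SegmentationMask(
            category="out_of_range", fish_free=radius_map <= cfg.max_range + 1e-9, **meta
        )

    first_idx = np.argmax(above, axis=1)
    rho = np.where(has_echo, ranges[first_idx], cfg.max_range)
    rho_hat = _circular_median(rho, params.smoothing_window)

    bearing_bin = (
        np.rint(angle_map / (2 * np.pi / cfg.n_bearings)).astype(int) % cfg.n_bearings
    )
    fish_free = radius_map < rho_hat[bearing_bin]

    # saturation check: an unusable noisy scan is densely above threshold
    # across the whole instrumented annulus, unlike any real school band
    annulus = (radius_map > excl) & (radius_map <= cfg.max_range)
    dense_fraction = float(above_img[annulus].mean())
    if dense_fraction > params.dense_fraction_max:
        return SegmentationMask(
            category="invalid", fish_free=np.zeros_like(fish_free), **meta
        )

    margin = params.erode_margin_px * mpp
    inner = (radius_map < rho_hat[bearing_bin] - margin) & (radius_map > excl)
    n_inner = int(inner.sum())
    if n_inner > 0:
        noise_frac = float((inner & above_img).sum()) / n_inner
        if noise_frac > params.noise_max:
            return SegmentationMask(
                category="invalid", fish_free=np.zeros_like(fish_free), **meta
            )
    return SegmentationMask(category="pattern", fish_free=fish_free, **meta)


# ---------------------------------------------------------------------------
# Trainable backend
# ---------------------------------------------------------------------------


class TrainableSegmenter:
    """Per-pixel trainable fish-free classifier over multi-scale features.

    Each pixel is described by its intensity at several Gaussian smoothing
    scales (on a common intensity normalisation learned from the training
    set) plus its normalised radius from the structure centre; a small
    multilayer perceptron maps the feature vector to a fish-free
    probability.  Thresholding the probability raster at 0.5 gives the mask;
    the category is then derived from the mask by the same rules that define
    the mask invariants: a near-full disc is a flight response
    (``out_of_range``), a near-empty mask is ``invalid``, anything else is a
    ``pattern`` whose fish-free region is the connected component containing
    the centre pixel.
    """

    def __init__(
        self,
        resolution: int = 64,
        hidden_layer_sizes: Sequence[int] = (24, 16),
        scales: Sequence[float] = (0.0, 1.0, 2.0, 4.0),
        max_iter: int = 600,
        pixels_per_image: int = 400,
        full_disc_min: float = 0.98,
        empty_max: float = 0.02,
        seed: int = 0,
    ):
        self.resolution = int(resolution)
        self.hidden_layer_sizes = tuple(hidden_layer_sizes)
        self.scales = tuple(scales)
        self.max_iter = int(max_iter)
        self.pixels_per_image = int(pixels_per_image)
        self.full_disc_min = float(full_disc_min)
        self.empty_max = float(empty_max)
        self.seed = int(seed)
        self._mlp = None
        self._intensity_scale = 1.0

    # -- features ----------------------------------------------------------

    def _features(self, image: CFPImage) -> np.ndarray:
        res = self.resolution
        px = resize(
            np.asarray(image.pixels, dtype=float),
            (res, res),
            order=1,
            anti_aliasing=True,
            preserve_range=True,
        )
        px = px / self._intensity_scale
        chans = [px if s == 0 else gaussian(px, sigma=s, preserve_range=True) for s in self.scales]
        c = (res - 1) / 2.0
        rr, cc = np.meshgrid(np.arange(res), np.arange(res), indexing="ij")
        radius = np.hypot(rr - c, cc - c) / c
        chans.append(radius)
        return np.stack([ch.ravel() for ch in chans], axis=1)

    def _resize_mask(self, mask: np.ndarray) -> np.ndarray:
        res = self.resolution
        return (
            resize(mask.astype(float), (res, res), order=0, preserve_range=True) > 0.5
        )

    # -- training ----------------------------------------------------------

    def fit(self, dataset: Sequence[tuple[CFPImage, SegmentationMask]]) -> "TrainableSegmenter":
        from sklearn.neural_network import MLPClassifier

        if not dataset:
            raise ValueError("training dataset is empty")
        cats = {m.category for _, m in dataset}
        missing = set(CATEGORIES) - cats
        if missing:
            raise ValueError(f"training dataset is missing categories: {sorted(missing)}")

        self._intensity_scale = float(
            np.median([np.percentile(img.pixels, 99) for img, _ in dataset])
        )
        if self._intensity_scale <= 0:
            self._intensity_scale = 1.0

        rng = np.random.default_rng(self.seed)
        xs, ys = [], []
        for img, mask in dataset:
            feats = self._features(img)
            label = self._resize_mask(mask.fish_free).ravel()
            idx = rng.choice(feats.shape[0], size=min(self.pixels_per_image, feats.shape[0]), replace=False)
            xs.append(feats[idx])
            ys.append(label[idx])
        X = np.concatenate(xs)
        y = np.concatenate(ys)
        self._mlp = MLPClassifier(
            hidden_layer_sizes=self.hidden_layer_sizes,
            max_iter=self.max_iter,
            random_state=self.seed,
        )
        self._mlp.fit(X, y)
        return self

    # -- prediction --------------------------------------------------------

    def predict(self, image: CFPImage) -> SegmentationMask:
        if self._mlp is None:
            raise ConfigurationError("trainable backend has not been fitted")
        res = self.resolution
        prob = self._mlp.predict_proba(self._features(image))[:, list(self._mlp.classes_).index(True)]
        small = prob.reshape(res, res) >= 0.5

        mask = (
            resize(small.astype(float), image.pixels.shape, order=0, preserve_range=True)
            > 0.5
        )
        radius_map, _ = _pixel_geometry(image.pixels.shape, image.centre, image.metres_per_pixel)
        disc = radius_map <= image.config.max_range + 1e-9
        mask &= disc

        meta = dict(
            centre=image.centre,
            metres_per_pixel=image.metres_per_pixel,
            config=image.config,
            phase=image.phase,
            level=image.level,
            pen=image.pen,
            depth=image.depth,
            replicate=image.replicate,
            n_frames=image.n_frames,
            backend="dl",
        )
        # judge fullness/emptiness away from the extreme edge, where resizing
        # always frays the prediction
        disc_eval = radius_map <= 0.95 * image.config.max_range
        frac = float(mask[disc_eval].mean())
        if frac >= self.full_disc_min:
            return SegmentationMask(category="out_of_range", fish_free=disc, **meta)
        if frac <= self.empty_max:
            return SegmentationMask(
                category="invalid", fish_free=np.zeros_like(mask), **meta
            )
        labels, _ = ndimage.label(mask)
        centre_lab = labels[image.centre]
        if centre_lab == 0:
            return SegmentationMask(
                category="invalid", fish_free=np.zeros_like(mask), **meta
            )
        return SegmentationMask(category="pattern", fish_free=labels == centre_lab, **meta)


def train_segmenter(
    dataset: Sequence[tuple[CFPImage, SegmentationMask]],
    model_config: dict | None = None,
    seed: int = 0,
) -> TrainableSegmenter:
    """Fit the trainable backend on labelled (CFP, mask) pairs.

    The dataset must contain all three categories; training is deterministic
    given the seed up to floating-point reduction order.
    """
    seg = TrainableSegmenter(seed=seed, **(model_config or {}))
    return seg.fit(dataset)


def segment(
    image: CFPImage,
    backend: str = "classical",
    params: ClassicalSegParams | None = None,
    model: TrainableSegmenter | None = None,
    overrides: dict | None = None,
) -> SegmentationMask:
    """Dispatch segmentation to the requested backend.

    ``overrides`` maps an image id (``"{level}/{replicate}/{phase}"``) to a
    category, supporting the manual-correction pathway: the override replaces
    the predicted category (with the canonical mask for out_of_range/invalid;
    a pattern override keeps the predicted mask).
    """
    if backend == "classical":
        mask = segment_classical(image, params)
    elif backend == "dl":
        if model is None:
            raise ConfigurationError("backend 'dl' requires a trained model")
        mask = model.predict(image)
    else:
        raise ConfigurationError(f"unknown segmentation backend {backend!r}")

    if overrides:
        key = f"{image.level}/{image.replicate}/{image.phase}"
        if key in overrides:
            cat = overrides[key]
            if cat not in CATEGORIES:
                raise ConfigurationError(f"override category {cat!r} unknown")
            radius_map, _ = _pixel_geometry(
                image.pixels.shape, image.centre, image.metres_per_pixel
            )
            if cat == "out_of_range":
                mask = replace(mask, category=cat, fish_free=radius_map <= image.config.max_range + 1e-9)
            elif cat == "invalid":
                mask = replace(mask, category=cat, fish_free=np.zeros(image.pixels.shape, bool))
            else:
                mask = replace(mask, category=cat)
    return mask


# ---------------------------------------------------------------------------
# Labelled synthetic data for the trainable backend
# ---------------------------------------------------------------------------


def synthetic_training_set(
    n_per_category: int,
    config: SonarConfig | None = None,
    metres_per_pixel: float = 0.1,
    seed: int = 0,
) -> list[tuple[CFPImage, SegmentationMask]]:
    """Generate labelled (CFP, mask) pairs of all three categories.

    Pattern images come from short simulated bursts of the annular school at
    a random baseline radius, labelled with the ground-truth inner disc;
    out-of-range images contain background noise only (full-disc label);
    invalid images are saturated noise bursts (empty label).
    """
    config = config or SonarConfig(n_bearings=120, n_range_bins=50, range_resolution=0.1)
    rng = np.random.default_rng(seed)
    sched = make_schedule(["none"], 1, duration=60, break_duration=60, order="sequential", start=120)
    window = (0.0, 4.0 * config.scan_period)
    pairs: list[tuple[CFPImage, SegmentationMask]] = []

    radius_lo = config.exclusion_radius + 0.5
    radius_hi = 0.7 * config.max_range
    for i in range(n_per_category):
        r_true = float(rng.uniform(radius_lo, radius_hi))
        params = SchoolParams(
            n_agents=80,
            baseline_radius=r_true,
            radial_spread=0.3,
            out_of_range_flag=False,
        )
        frames, _ = simulate_frames(
            params, sched, config, seed=int(rng.integers(2**31)), span=window[1]
        )
        img = accumulate_cfp(frames, window, metres_per_pixel)
        radius_map, _ = _pixel_geometry(img.pixels.shape, img.centre, metres_per_pixel)
        label = radius_map < r_true
        pairs.append(
            (
                img,
                SegmentationMask(
                    category="pattern",
                    fish_free=label,
                    centre=img.centre,
                    metres_per_pixel=metres_per_pixel,
                    config=config,
                    backend="label",
                ),
            )
        )

    for i in range(n_per_category):
        params = SchoolParams(n_agents=0)
        frames, _ = simulate_frames(
            params, sched, config, seed=int(rng.integers(2**31)), span=window[1]
        )
        img = accumulate_cfp(frames, window, metres_per_pixel)
        radius_map, _ = _pixel_geometry(img.pixels.shape, img.centre, metres_per_pixel)
        pairs.append(
            (
                img,
                SegmentationMask(
                    category="out_of_range",
                    fish_free=radius_map <= config.max_range,
                    centre=img.centre,
                    metres_per_pixel=metres_per_pixel,
                    config=config,
                    backend="label",
                ),
            )
        )

    for i in range(n_per_category):
        frames = make_invalid_frames(
            config, burst_level=3.0, n_frames=4, seed=int(rng.integers(2**31))
        )
        img = accumulate_cfp(frames, window, metres_per_pixel)
        pairs.append(
            (
                img,
                SegmentationMask(
                    category="invalid",
                    fish_free=np.zeros(img.pixels.shape, bool),
                    centre=img.centre,
                    metres_per_pixel=metres_per_pixel,
                    config=config,
                    backend="label",
                ),
            )
        )
    return pairs
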