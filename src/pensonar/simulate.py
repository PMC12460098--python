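"""Synthetic treatment schedules and sonar frame streams with known
ground-truth avoidance behaviour.

The generator emulates the study system: a school of fish distributed as a
noisy annulus around a centred structure inside a net pen.  When a
point-source stimulus (a tone, a light) switches on at the structure, the
school's inner radius rises from its baseline ``r0`` toward
``r0 * (1 + delta)`` with a first-order time constant, and relaxes back after
the stimulus ends.  ``delta > 0`` encodes avoidance, ``delta < 0`` attraction,
and a school driven beyond the instrumented range (with
``out_of_range_flag``) emulates a flight response.

Each frame adds, on top of the agents' echo blobs, multiplicative lognormal
speckle, additive exponential background noise, and a bright ring artifact at
the exclusion radius standing in for the structure's own echo.  Everything is
deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .sonar import ScanFrame, SonarConfig

__all__ = [
    "ScheduleEvent",
    "TreatmentSchedule",
    "SchoolParams",
    "TrialGroundTruth",
    "make_schedule",
    "school_radius",
    "simulate_frames",
    "make_invalid_frames",
]


@dataclass(frozen=True)
class ScheduleEvent:
    level: str
    onset: float
    duration: float
    replicate: int  # per-level counter, 1-based


@dataclass(frozen=True)
class TreatmentSchedule:
    """Ordered, non-overlapping stimulus events with fixed breaks."""

    events: tuple[ScheduleEvent, ...]
    break_duration: float
    repetitions: int

    def __post_init__(self):
        evs = tuple(self.events)
        for a, b in zip(evs, evs[1:]):
            if b.onset - a.onset < a.duration + self.break_duration - 1e-9:
                raise ValueError(
                    "consecutive onsets must be separated by at least "
                    "duration + break_duration"
                )
        object.__setattr__(self, "events", evs)

    @property
    def levels(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for e in self.events:
            seen.setdefault(e.level, None)
        return tuple(seen)

    @property
    def span(self) -> float:
        """Trial end time: last offset plus room for the after window."""
        last = self.events[-1]
        return last.onset + 2.0 * last.duration + 60.0


def make_schedule(
    levels: Sequence[str],
    repetitions: int,
    duration: float = 60.0,
    break_duration: float = 600.0,
    order: str = "random",
    seed: int | None = None,
    start: float | None = None,
) -> TreatmentSchedule:
    """Build a treatment schedule of ``len(levels) * repetitions`` events.

    ``order="random"`` is a seeded shuffle of the level multiset (each level
    still occurs exactly ``repetitions`` times); ``order="sequential"``
    cycles through the levels in the given order.  The first onset defaults
    to ``duration + break_duration`` so a full pre-stimulus window exists.
    """
    if not levels:
        raise ValueError("level list must not be empty")
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    if duration <= 0 or break_duration <= 0:
        raise ValueError("duration and break_duration must be positive")
    if order not in ("random", "sequential"):
        raise ValueError(f"unknown order {order!r}")

    if order == "sequential":
        sequence = [lvl for _ in range(repetitions) for lvl in levels]
    else:
        rng = np.random.default_rng(seed)
        multiset = np.repeat(np.asarray(levels, dtype=object), repetitions)
        sequence = list(rng.permutation(multiset))

    t0 = float(start) if start is not None else duration + break_duration
    counts: dict[str, int] = {}
    events = []
    for k, lvl in enumerate(sequence):
        counts[lvl] = counts.get(lvl, 0) + 1
        events.append(
            ScheduleEvent(
                level=str(lvl),
                onset=t0 + k * (duration + break_duration),
                duration=duration,
                replicate=counts[lvl],
            )
        )
    return TreatmentSchedule(
        events=tuple(events), break_duration=break_duration, repetitions=repetitions
    )


@dataclass(frozen=True)
class SchoolParams:
    """Behavioural and acoustic parameters of the synthetic school.

    ``displacement_factor`` (delta) is the dimensionless ground-truth effect:
    the during-exposure inner radius is ``baseline_radius * (1 + delta)``.
    ``radial_spread`` is the sigma of the half-normal outward scatter of the
    agents around the inner radius, so the inner perimeter stays crisp.
    Intensity parameters are on an arbitrary echo scale with the nominal
    single-fish echo at ``echo_amplitude``.
    """

    n_agents: int = 150
    baseline_radius: float = 2.0
    radial_spread: float = 0.5
    displacement_factor: float = 0.0
    relaxation_tau: float = 1.0
    swim_angular_speed: float = 0.1  # rad/s, slow milling around the pen centre
    echo_amplitude: float = 1.0
    speckle_cv: float = 0.3
    background_noise_level: float = 0.05
    out_of_range_flag: bool = False
    blob_sigma_range: float = 2.0  # range bins
    blob_sigma_bearing: float = 1.0  # bearing bins

    def __post_init__(self):
        if self.n_agents < 0:
            raise ValueError("n_agents must be >= 0")
        if self.baseline_radius <= 0:
            raise ValueError("baseline_radius must be positive")
        if self.radial_spread < 0:
            raise ValueError("radial_spread must be >= 0")
        if 1.0 + self.displacement_factor <= 0:
            raise ValueError("1 + displacement_factor must be positive")
        if self.relaxation_tau <= 0:
            raise ValueError("relaxation_tau must be positive")
        if self.speckle_cv < 0 or self.background_noise_level < 0:
            raise ValueError("noise parameters must be >= 0")


@dataclass(frozen=True)
class TrialGroundTruth:
    """Per-frame true inner radius and phase labels for one simulated trial."""

    t: np.ndarray  # frame start times, s
    true_radius: np.ndarray  # r(t) at frame starts, m
    phase: tuple[str, ...]  # before/during/after/break per frame
    level: tuple[str, ...]  # event level per frame ("" outside any window)
    replicate: tuple[int, ...]  # event replicate per frame (0 outside)
    schedule: TreatmentSchedule
    seed: int


def _delta_for(params: SchoolParams, level: str, delta_by_level) -> float:
    if delta_by_level is not None and level in delta_by_level:
        return float(delta_by_level[level])
    return params.displacement_factor


def school_radius(
    params: SchoolParams,
    t,
    schedule: TreatmentSchedule,
    delta_by_level: Mapping[str, float] | None = None,
):
    """Ground-truth inner radius r(t) of the school, in metres.

    First-order exponential approach toward ``r0 * (1 + delta)`` after each
    onset and decay back toward ``r0`` after each offset, both with time
    constant ``relaxation_tau``.  The decay contribution is truncated to zero
    at five time constants past the offset so the baseline holds exactly
    between events.  Accepts a scalar or array ``t``.
    """
    t_arr = np.asarray(t, dtype=float)
    r0 = params.baseline_radius
    tau = params.relaxation_tau
    out = np.full(t_arr.shape, r0, dtype=float)
    for ev in schedule.events:
        delta = _delta_for(params, ev.level, delta_by_level)
        if delta == 0.0:
            continue
        amp = r0 * delta
        off = ev.onset + ev.duration
        during = (t_arr >= ev.onset) & (t_arr < off)
        out[during] += amp * (1.0 - np.exp(-(t_arr[during] - ev.onset) / tau))
        after = (t_arr >= off) & (t_arr < off + 5.0 * tau)
        peak = amp * (1.0 - math.exp(-ev.duration / tau))
        out[after] += peak * np.exp(-(t_arr[after] - off) / tau)
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(out)
    return out


def _frame_phase(t_start: float, schedule: TreatmentSchedule, trim: float = 5.0):
    """(phase, level, replicate) of the frame starting at ``t_start``."""
    for ev in schedule.events:
        if ev.onset - ev.duration + trim <= t_start < ev.onset - trim:
            return "before", ev.level, ev.replicate
        if ev.onset + trim <= t_start < ev.onset + ev.duration - trim:
            return "during", ev.level, ev.replicate
        if ev.onset + ev.duration + trim <= t_start < ev.onset + 2 * ev.duration - trim:
            return "after", ev.level, ev.replicate
    return "break", "", 0


def _paint_agents(
    arr: np.ndarray,
    bearings: np.ndarray,
    radii: np.ndarray,
    params: SchoolParams,
    config: SonarConfig,
    rng: np.random.Generator,
) -> None:
    """Paint one Gaussian echo blob per agent onto the polar array, in place.

    Blobs combine with the existing array by maximum (presence semantics);
    each blob's amplitude carries an independent lognormal speckle draw with
    the configured coefficient of variation.
    """
    nb, nr = config.n_bearings, config.n_range_bins
    in_range = radii <= (nr - 1) * config.range_resolution
    if not np.any(in_range):
        return
    b0 = np.rint(bearings[in_range] / (2 * np.pi / nb)).astype(int) % nb
    j0 = np.rint(radii[in_range] / config.range_resolution).astype(int)
    n = b0.size

    cv = params.speckle_cv
    if cv > 0:
        sig = math.sqrt(math.log1p(cv * cv))
        amp = params.echo_amplitude * rng.lognormal(-0.5 * sig * sig, sig, size=n)
    else:
        amp = np.full(n, params.echo_amplitude)

    sb, sr = params.blob_sigma_bearing, params.blob_sigma_range
    db = np.arange(-int(math.ceil(3 * sb)), int(math.ceil(3 * sb)) + 1)
    dj = np.arange(-int(math.ceil(3 * sr)), int(math.ceil(3 * sr)) + 1)
    kernel = np.exp(-0.5 * (db[:, None] / sb) ** 2 - 0.5 * (dj[None, :] / sr) ** 2)

    bb = (b0[:, None, None] + db[None, :, None]) % nb
    jj = j0[:, None, None] + dj[None, None, :]
    flat = bb * nr + jj  # broadcasts to (n_agents, len(db), len(dj))
    vals = amp[:, None, None] * kernel[None, :, :]
    ok = np.broadcast_to((jj >= 0) & (jj < nr), flat.shape)
    np.maximum.at(arr.ravel(), flat[ok], vals[ok])


def simulate_frames(
    params: SchoolParams,
    schedule: TreatmentSchedule,
    config: SonarConfig,
    seed: int = 0,
    delta_by_level: Mapping[str, float] | None = None,
    span: float | None = None,
) -> tuple[list[ScanFrame], TrialGroundTruth]:
    """Simulate the full stream of sonar revolutions for one trial.

    Agents hold angular positions advancing at ``swim_angular_speed`` and
    radial positions resampled every revolution as ``r(t) + |N(0, spread)|``.
    A bright ring artifact at the exclusion radius emulates the structure
    echo.  Raises ``ValueError`` when the ground-truth radius leaves the
    instrumented range without ``out_of_range_flag``.
    """
    if params.baseline_radius <= config.exclusion_radius:
        raise ValueError("baseline_radius must exceed the exclusion radius")
    span = float(span) if span is not None else schedule.span
    n_frames = int(math.floor(span / config.scan_period))
    t_starts = np.arange(n_frames) * config.scan_period
    r_t = school_radius(params, t_starts, schedule, delta_by_level)
    if not params.out_of_range_flag and np.any(r_t > config.max_range):
        raise ValueError(
            "ground-truth radius exceeds max_range; set out_of_range_flag to "
            "simulate a flight response"
        )

    rng = np.random.default_rng(seed)
    nb, nr = config.n_bearings, config.n_range_bins
    theta0 = rng.uniform(0.0, 2 * np.pi, size=params.n_agents)
    ring_bin = int(round(config.exclusion_radius / config.range_resolution))
    ring_bins = [j for j in (ring_bin - 1, ring_bin, ring_bin + 1) if 0 <= j < nr]

    frames: list[ScanFrame] = []
    phases, levels, reps = [], [], []
    for k, t in enumerate(t_starts):
        if params.background_noise_level > 0:
            arr = rng.exponential(params.background_noise_level, size=(nb, nr))
        else:
            arr = np.zeros((nb, nr))
        arr[:, ring_bins] = np.maximum(arr[:, ring_bins], 2.0 * params.echo_amplitude)
        if params.n_agents:
            bearings = theta0 + params.swim_angular_speed * t
            radii = r_t[k] + np.abs(rng.normal(0.0, params.radial_spread, params.n_agents))
            _paint_agents(arr, bearings, radii, params, config, rng)
        frames.append(ScanFrame(config=config, intensities=arr, t_start=float(t)))
        ph, lvl, rep = _frame_phase(float(t), schedule)
        phases.append(ph)
        levels.append(lvl)
        reps.append(rep)

    gt = TrialGroundTruth(
        t=t_starts,
        true_radius=r_t,
        phase=tuple(phases),
        level=tuple(levels),
        replicate=tuple(reps),
        schedule=schedule,
        seed=seed,
    )
    return frames, gt


def make_invalid_frames(
    config: SonarConfig,
    burst_level: float = 3.0,
    n_frames: int = 8,
    seed: int = 0,
    t_start: float = 0.0,
) -> list[ScanFrame]:
    """Frames saturated with broadband high-intensity noise (no annulus).

    Emulates acoustic interference bursts that render a scan unusable.
    ``burst_level`` is the mean of the exponential noise, typically well
    above the echo amplitude; ``burst_level = 0`` degenerates to empty
    background-only frames.
    """
    if burst_level < 0:
        raise ValueError("burst_level must be >= 0")
    rng = np.random.default_rng(seed)
    nb, nr = config.n_bearings, config.n_range_bins
    frames = []
    for k in range(n_frames):
        if burst_level > 0:
            arr = rng.exponential(burst_level, size=(nb, nr))
        else:
            arr = np.zeros((nb, nr))
        frames.append(
            ScanFrame(config=config, intensities=arr, t_start=t_start + k * config.scan_period)
        )
    return frames
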