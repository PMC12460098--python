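"""End-to-end orchestration: simulate -> CFP -> segment -> measure -> stats.

:func:`run_pipeline` takes one :class:`RunConfig`, runs every stage with a
single propagated seed, writes the artifact set (frames, CFP TIFFs, mask
PNGs, tidy measurements CSV, stats CSVs, a manifest and a log) and returns
the in-memory results.  A stage failure on one event is logged with the
event id and the run continues; a run yielding zero valid triplets raises
:class:`~pensonar.errors.PipelineError`.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from . import io as pio
from .cfp import PHASES, accumulate_cfp, phase_windows
from .errors import ConfigurationError, EmptyWindowError, NotMeasurableError, PipelineError
from .metrics import avoidance_distance, measurements_table
from .permanova import Design, Factor, PairwiseResult, PermanovaResult, pairwise, permanova
from .segmentation import ClassicalSegParams, TrainableSegmenter, segment
from .simulate import SchoolParams, make_invalid_frames, make_schedule, simulate_frames
from .sonar import SonarConfig

__all__ = ["RunConfig", "RunResult", "run_pipeline", "make_fixtures"]

log = logging.getLogger("pensonar")


@dataclass(frozen=True)
class RunConfig:
    """Full configuration of one reproducible pipeline run."""

    levels: tuple[str, ...] = ("stim",)
    delta_by_level: dict = field(default_factory=dict)
    repetitions: int = 3
    duration: float = 60.0
    break_duration: float = 600.0
    order: str = "random"
    trim: float = 5.0
    metres_per_pixel: float = 0.05
    sonar: SonarConfig = field(default_factory=SonarConfig)
    school: SchoolParams = field(default_factory=SchoolParams)
    seg_params: ClassicalSegParams | None = None
    backend: str = "classical"
    pen: str = "A"
    depth: float = 8.0
    n_perm: int = 999
    run_stats: bool = True
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self):
        if not self.levels:
            raise ConfigurationError("at least one treatment level is required")
        for lvl in self.delta_by_level:
            if lvl not in self.levels:
                raise ConfigurationError(f"delta given for unknown level {lvl!r}")
        if self.backend not in ("classical", "dl"):
            raise ConfigurationError(f"unknown backend {self.backend!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "sonar" in raw:
            raw["sonar"] = SonarConfig(**raw["sonar"])
        if "school" in raw:
            raw["school"] = SchoolParams(**raw["school"])
        if "seg_params" in raw and raw["seg_params"] is not None:
            raw["seg_params"] = ClassicalSegParams(**raw["seg_params"])
        if "levels" in raw:
            raw["levels"] = tuple(raw["levels"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        raw["levels"] = list(self.levels)
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))


@dataclass
class RunResult:
    measurements: pd.DataFrame
    stats: PermanovaResult | None
    pairwise_timing: dict[str, PairwiseResult]
    excluded: list[dict]
    out_dir: Path | None


def _prepare_out_dir(out_dir: str | None) -> Path | None:
    if out_dir is None:
        return None
    p = Path(out_dir)
    try:
        p.mkdir(parents=True, exist_ok=True)
        (p / ".write_probe").write_text("")
        (p / ".write_probe").unlink()
    except OSError as exc:
        raise ConfigurationError(f"output directory {p} is not writable: {exc}") from exc
    return p


def run_pipeline(config: RunConfig, model: TrainableSegmenter | None = None) -> RunResult:
    """Execute one full trial analysis from a single seed."""
    out = _prepare_out_dir(config.out_dir)
    if out is not None:
        handler = logging.FileHandler(out / "run.log")
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(handler)
    try:
        return _run(config, out, model)
    finally:
        if out is not None:
            log.removeHandler(handler)
            handler.close()


def _run(config: RunConfig, out: Path | None, model) -> RunResult:
    seg_params = config.seg_params or ClassicalSegParams(
        echo_threshold=0.5 * config.school.echo_amplitude
    )
    schedule = make_schedule(
        list(config.levels),
        config.repetitions,
        duration=config.duration,
        break_duration=config.break_duration,
        order=config.order,
        seed=config.seed,
    )
    frames, gt = simulate_frames(
        config.school,
        schedule,
        config.sonar,
        seed=config.seed,
        delta_by_level=config.delta_by_level or None,
    )
    log.info("simulated %d frames over %d events", len(frames), len(schedule.events))
    if out is not None:
        pio.save_frames(frames, out / "frames.zarr")
        pio.save_schedule(schedule, out / "schedule.json")
        pd.DataFrame(
            dict(t=gt.t, true_radius_m=gt.true_radius, phase=gt.phase,
                 level=gt.level, replicate=gt.replicate)
        ).to_csv(out / "ground_truth.csv", index=False)

    measurements, excluded = [], []
    for ev in schedule.events:
        event_id = f"{ev.level}/r{ev.replicate}"
        try:
            windows = phase_windows(
                ev.onset, ev.duration, config.trim, level=ev.level, replicate=ev.replicate
            )
        except ValueError as exc:
            excluded.append(dict(event=event_id, stage="windows", reason=str(exc)))
            log.warning("event %s: %s", event_id, exc)
            continue
        for phase in PHASES:
            try:
                img = accumulate_cfp(frames, windows[phase], config.metres_per_pixel)
                img = img.with_meta(
                    phase=phase, level=ev.level, pen=config.pen,
                    depth=config.depth, replicate=ev.replicate,
                )
                mask = segment(img, backend=config.backend, params=seg_params, model=model)
                m = avoidance_distance(mask)
            except (EmptyWindowError, NotMeasurableError) as exc:
                excluded.append(dict(event=event_id, stage=phase, reason=str(exc)))
                log.warning("event %s %s excluded: %s", event_id, phase, exc)
                continue
            log.info(
                "event %s %s: category=%s distance=%.3f m",
                event_id, phase, mask.category, m.distance,
            )
            measurements.append(m)
            if out is not None:
                stem = f"{ev.level}_r{ev.replicate}_{phase}"
                pio.save_cfp(img, out / f"cfp_{stem}.tiff")
                pio.save_mask(mask, out / f"mask_{stem}.png", params=seg_params)

    tab = measurements_table(measurements)
    complete = (
        tab.groupby(["level", "replicate"], observed=True)["phase"].count() == 3
        if len(tab)
        else pd.Series(dtype=int)
    )
    if len(tab) == 0 or not complete.any():
        raise PipelineError("run produced zero valid before/during/after triplets")

    stats = None
    pw: dict[str, PairwiseResult] = {}
    if config.run_stats:
        factors = [Factor("phase", "fixed")]
        if len(config.levels) > 1:
            factors.append(Factor("level", "fixed"))
        design = Design.full_factorial(factors, response="distance_m")
        stats = permanova(tab, design, n_perm=config.n_perm, seed=config.seed)
        for lvl in config.levels:
            try:
                pw[lvl] = pairwise(
                    tab, "phase", n_perm=config.n_perm, seed=config.seed,
                    stratum={"level": lvl},
                )
            except Exception as exc:  # degenerate strata are logged, not fatal
                log.warning("pairwise for level %s failed: %s", lvl, exc)

    if out is not None:
        tab.to_csv(out / "measurements.csv", index=False)
        if stats is not None:
            stats.table.to_csv(out / "permanova.csv", index=False)
            pd.concat(
                [r.table.assign(level=lvl) for lvl, r in pw.items()], ignore_index=True
            ).to_csv(out / "pairwise_timing.csv", index=False)
        manifest = dict(
            seed=config.seed,
            config_hash=pio.params_hash(replace(config, out_dir=None)),
            n_events=len(schedule.events),
            n_measurements=len(tab),
            n_excluded=len(excluded),
            version=_package_version(),
        )
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))

    return RunResult(
        measurements=tab, stats=stats, pairwise_timing=pw,
        excluded=excluded, out_dir=out,
    )


def _package_version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("pensonar")
    except PackageNotFoundError:
        return "unknown"


def make_fixtures(seed: int = 0, out_dir: str | Path = "fixtures") -> Path:
    """Write a deterministic miniature trial used by the test suite.

    Two levels x two replicates on a coarse 101 x 101 raster: a ``tone``
    level with a moderate avoidance displacement (pattern images) and a
    ``flight`` level driving the school beyond sonar range (out_of_range
    images), plus a stream of saturated noise frames (invalid images), so
    all three segmentation categories occur.  Break durations are shortened
    relative to the field protocol to keep the fixture miniature.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = SonarConfig(
        n_bearings=120, n_range_bins=50, range_resolution=0.2,
        scan_period=8.0, exclusion_radius=0.6,
    )
    school = SchoolParams(
        n_agents=80, baseline_radius=2.0, radial_spread=0.4,
        out_of_range_flag=True, blob_sigma_range=1.5,
    )
    schedule = make_schedule(
        ["tone", "flight"], 2, duration=60.0, break_duration=120.0,
        order="sequential", seed=seed,
    )
    frames, gt = simulate_frames(
        school, schedule, config, seed=seed,
        delta_by_level={"tone": 0.3, "flight": 8.0},
    )
    pio.save_frames(frames, out / "frames.zarr")
    pio.save_schedule(schedule, out / "schedule.json")
    pd.DataFrame(
        dict(t=gt.t, true_radius_m=gt.true_radius, phase=gt.phase,
             level=gt.level, replicate=gt.replicate)
    ).to_csv(out / "ground_truth.csv", index=False)
    invalid = make_invalid_frames(config, burst_level=3.0, n_frames=8, seed=seed)
    pio.save_frames(invalid, out / "invalid_frames.zarr")
    meta = dict(seed=seed, metres_per_pixel=0.2, delta_by_level={"tone": 0.3, "flight": 8.0})
    (out / "fixture.json").write_text(json.dumps(meta, indent=1))
    return out
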