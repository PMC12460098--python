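"""On-disk formats for the pipeline artifacts.

Frame streams are stored as one chunked 3-D array (frame x bearing x range)
with a JSON sidecar holding the sonar configuration and frame timestamps;
CFP images as 16-bit single-channel TIFF (intensity rescaled, scale recorded
in the sidecar); masks as 8-bit PNG (0 = fish/unknown, 255 = fish-free).
Every raster gets a ``<name>.json`` sidecar with its metadata.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import shutil
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import zarr

from .cfp import CFPImage
from .segmentation import SegmentationMask
from .simulate import ScheduleEvent, TreatmentSchedule
from .sonar import ScanFrame, SonarConfig

__all__ = [
    "save_frames",
    "load_frames",
    "save_cfp",
    "load_cfp",
    "save_mask",
    "save_schedule",
    "load_schedule",
    "params_hash",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def params_hash(obj) -> str:
    """Stable short hash of a dataclass/dict parameter set."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def save_frames(frames: list[ScanFrame], path: str | Path) -> Path:
    """Write a frame stream as a chunked array plus JSON sidecar."""
    path = Path(path)
    if path.exists():
        shutil.rmtree(path)
    stack = np.stack([f.intensities for f in frames]).astype(np.float32)
    zarr.save_array(str(path), stack)
    cfg = frames[0].config
    meta = dict(
        config=dataclasses.asdict(cfg),
        t_starts=[f.t_start for f in frames],
    )
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def load_frames(path: str | Path) -> list[ScanFrame]:
    path = Path(path)
    stack = np.asarray(zarr.load(str(path)))
    meta = json.loads(_sidecar(path).read_text())
    cfg = SonarConfig(**meta["config"])
    return [
        ScanFrame(config=cfg, intensities=stack[i], t_start=t)
        for i, t in enumerate(meta["t_starts"])
    ]


def save_cfp(image: CFPImage, path: str | Path) -> Path:
    """Write a CFP image as 16-bit TIFF plus JSON sidecar."""
    path = Path(path)
    peak = float(image.pixels.max())
    scale = 65535.0 / peak if peak > 0 else 1.0
    tifffile.imwrite(path, (image.pixels * scale).astype(np.uint16))
    meta = dict(
        intensity_scale=scale,
        centre=list(image.centre),
        metres_per_pixel=image.metres_per_pixel,
        window=list(image.window),
        n_frames=image.n_frames,
        phase=image.phase,
        level=image.level,
        pen=image.pen,
        depth=image.depth,
        replicate=image.replicate,
        config=dataclasses.asdict(image.config),
    )
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def load_cfp(path: str | Path) -> CFPImage:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    raw = tifffile.imread(path).astype(float) / meta["intensity_scale"]
    return CFPImage(
        pixels=raw,
        centre=tuple(meta["centre"]),
        metres_per_pixel=meta["metres_per_pixel"],
        window=tuple(meta["window"]),
        n_frames=meta["n_frames"],
        config=SonarConfig(**meta["config"]),
        phase=meta["phase"],
        level=meta["level"],
        pen=meta["pen"],
        depth=meta["depth"],
        replicate=meta["replicate"],
    )


def save_mask(mask: SegmentationMask, path: str | Path, params=None) -> Path:
    """Write a mask as 8-bit PNG (255 = fish-free) plus JSON sidecar."""
    path = Path(path)
    iio.imwrite(path, (mask.fish_free.astype(np.uint8) * 255))
    meta = dict(
        category=mask.category,
        backend=mask.backend,
        phase=mask.phase,
        level=mask.level,
        replicate=mask.replicate,
        params_hash=params_hash(params) if params is not None else None,
    )
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def save_schedule(schedule: TreatmentSchedule, path: str | Path) -> Path:
    path = Path(path)
    meta = dict(
        break_duration=schedule.break_duration,
        repetitions=schedule.repetitions,
        events=[dataclasses.asdict(e) for e in schedule.events],
    )
    path.write_text(json.dumps(meta, indent=1))
    return path


def load_schedule(path: str | Path) -> TreatmentSchedule:
    meta = json.loads(Path(path).read_text())
    return TreatmentSchedule(
        events=tuple(ScheduleEvent(**e) for e in meta["events"]),
        break_duration=meta["break_duration"],
        repetitions=meta["repetitions"],
    )
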