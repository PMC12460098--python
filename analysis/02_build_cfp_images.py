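#!/usr/bin/env python
"""Build trimmed before/during/after CFP images for every stimulus event.

Each 60-s phase loses its first and last 5 s (treatment transitions), so one
CFP accumulates the revolutions fully inside a 50-s window, pixelwise by
maximum.  Images go to scratch/cfp/ as 16-bit TIFFs; an index table with
frame counts goes to results/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from pensonar import accumulate_cfp, phase_windows
from pensonar.cfp import PHASES
from pensonar.io import load_frames, load_schedule, save_cfp


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--scratch", type=Path, default=Path("scratch/trials"))
    ap.add_argument("--out", type=Path, default=Path("scratch/cfp"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--mpp", type=float, default=0.05, help="metres per pixel")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    meta = json.loads((args.scratch / "meta.json").read_text())
    rows = []
    for pen in meta["pens"]:
        frames = load_frames(args.scratch / f"pen{pen}.zarr")
        schedule = load_schedule(args.scratch / f"pen{pen}_schedule.json")
        for ev in schedule.events:
            w = phase_windows(ev.onset, ev.duration, trim=5.0,
                              level=ev.level, replicate=ev.replicate)
            for phase in PHASES:
                img = accumulate_cfp(frames, w[phase], args.mpp).with_meta(
                    phase=phase, level=ev.level, pen=pen, replicate=ev.replicate
                )
                name = f"pen{pen}_{ev.level}_r{ev.replicate}_{phase}.tiff"
                save_cfp(img, args.out / name)
                rows.append(dict(pen=pen, level=ev.level, replicate=ev.replicate,
                                 phase=phase, n_frames=img.n_frames, file=name))
    index = pd.DataFrame(rows)
    index.to_csv(args.results / "cfp_index.csv", index=False)
    print(f"built {len(index)} CFP images "
          f"({index.n_frames.min()}-{index.n_frames.max()} revolutions each)")


if __name__ == "__main__":
    main()
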