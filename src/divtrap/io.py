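"""File formats: multi-page TIFF stacks, indexed PNG masks, JSON records.

All tables are CSV with a header row; records are JSON lines; images are
TIFF/PNG. Movie metadata travels in a JSON sidecar next to the TIFF.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from divtrap.lifespan import LifespanRecord
from divtrap.roi import RoiSet, TrapMovie
from divtrap.trapsynth.render import SynthScene


def save_trap_movie(movie: TrapMovie, path: str | Path) -> None:
    path = Path(path)
    tifffile.imwrite(path, movie.frames.astype(np.float32))
    meta = {
        "frame_interval_min": movie.frame_interval_min,
        "channel_names": movie.channel_names,
        "roi_id": movie.roi_id,
        "origin": list(movie.origin),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_trap_movie(path: str | Path) -> TrapMovie:
    path = Path(path)
    frames = np.asarray(tifffile.imread(path), dtype=np.float64)
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return TrapMovie(
        frames=frames,
        frame_interval_min=meta.get("frame_interval_min", 5.0),
        channel_names=meta.get("channel_names", ["brightfield"]),
        roi_id=meta.get("roi_id", path.stem),
        origin=tuple(meta.get("origin", (0, 0))),
    )


def save_roiset(rois: RoiSet, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "centers": [list(c) for c in rois.centers],
                "box_size": list(rois.box_size),
                "template_id": rois.template_id,
                "scores": rois.scores,
            },
            indent=2,
        )
    )


def load_roiset(path: str | Path) -> RoiSet:
    d = json.loads(Path(path).read_text())
    return RoiSet(
        centers=[tuple(c) for c in d["centers"]],
        box_size=tuple(d["box_size"]),
        template_id=d.get("template_id", "template"),
        scores=d.get("scores", []),
    )


def write_scene(scene: SynthScene, out_dir: str | Path) -> None:
    """Movie as TIFF, masks as per-frame indexed PNG, truth as JSON, trace CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_trap_movie(scene.movie, out_dir / "movie.tif")
    mask_dir = out_dir / "masks"
    nuc_dir = out_dir / "nucleus_masks"
    mask_dir.mkdir(exist_ok=True)
    nuc_dir.mkdir(exist_ok=True)
    for t in range(scene.masks.shape[0]):
        iio.imwrite(mask_dir / f"frame{t:04d}.png", scene.masks[t].astype(np.uint8))
        iio.imwrite(nuc_dir / f"frame{t:04d}.png", scene.nucleus_masks[t].astype(np.uint8))
    truth = scene.truth
    (out_dir / "groundtruth.json").write_text(
        json.dumps(
            {
                "budding_frames": truth.budding_frames,
                "sep_frame": truth.sep_frame,
                "sep_generation": truth.sep_generation,
                "death_frame": truth.death_frame,
                "end_reason": truth.end_reason,
                "labels": truth.per_frame_labels,
                "cycle_durations_min": truth.cycle_durations_min,
            },
            indent=2,
        )
    )
    pd.DataFrame(
        {
            "frame": np.arange(len(scene.nuclear_intensity_trace)),
            "nuclear_intensity": scene.nuclear_intensity_trace,
        }
    ).to_csv(out_dir / "nuclear_trace.csv", index=False)


def records_to_jsonl(records: list[LifespanRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(json.dumps(asdict(r)) + "\n")


def records_from_jsonl(path: str | Path) -> list[LifespanRecord]:
    records = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                records.append(LifespanRecord(**json.loads(line)))
    return records


def records_to_csv(records: list[LifespanRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        row = asdict(r)
        row["budding_frames"] = ";".join(str(b) for b in r.budding_frames)
        row["cycle_durations_min"] = ";".join(str(d) for d in r.cycle_durations_min)
        row["fallback_events"] = ";".join(str(b) for b in r.fallback_events)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
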