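"""Disk formats: gaze-log CSVs, mask PNGs, case/reads tables, manifest.

One gaze log per read, with the recording-level fields (sampling rate,
duration, image size) carried as ``# key: value`` comment lines ahead of
the CSV header so a log round-trips without a sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .design import CaseSpec, cases_to_frame, frame_to_cases
from .metrics import GazeRecording
from .simulate import StudyBundle

__all__ = [
    "write_gaze_csv",
    "read_gaze_csv",
    "write_mask_png",
    "read_mask_png",
    "write_dataset",
    "load_cases",
]

_GAZE_FIELDS = ("sampling_rate_hz", "duration_s", "image_width", "image_height")


def write_gaze_csv(rec: GazeRecording, path: str | Path) -> None:
    path = Path(path)
    header = {
        "sampling_rate_hz": rec.sampling_rate,
        "duration_s": rec.duration,
        "image_width": rec.image_width,
        "image_height": rec.image_height,
    }
    with open(path, "w") as fh:
        for key, val in header.items():
            fh.write(f"# {key}: {val}\n")
        fh.write("t_sec,x_px,y_px,valid\n")
        for t, x, y, v in zip(rec.t, rec.x, rec.y, rec.valid):
            fh.write(f"{t:.6f},{x:.2f},{y:.2f},{int(v)}\n")


def read_gaze_csv(path: str | Path) -> GazeRecording:
    path = Path(path)
    meta: dict[str, float] = {}
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            key, _, val = line.lstrip("# ").partition(":")
            meta[key.strip()] = float(val)
    missing = set(_GAZE_FIELDS) - set(meta)
    if missing:
        raise ValueError(f"{path}: gaze log lacks header fields {sorted(missing)}")
    df = pd.read_csv(path, skiprows=skip)
    return GazeRecording(
        t=df["t_sec"].to_numpy(),
        x=df["x_px"].to_numpy(),
        y=df["y_px"].to_numpy(),
        valid=df["valid"].to_numpy().astype(bool),
        sampling_rate=meta["sampling_rate_hz"],
        duration=meta["duration_s"],
        image_width=int(meta["image_width"]),
        image_height=int(meta["image_height"]),
    )


def write_mask_png(mask: np.ndarray, path: str | Path) -> None:
    Image.fromarray((np.asarray(mask, dtype=bool) * np.uint8(255))).save(path)


def read_mask_png(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L")) > 127


def write_dataset(bundle: StudyBundle, outdir: str | Path, write_masks: bool = True) -> Path:
    """Write a simulated study to disk: case table, reads, latent truth,
    per-read gaze logs, per-case masks, and a manifest tying them together.

    Returns the manifest path.  Output layout::

        outdir/cases.csv  reads.csv  latent.csv  manifest.csv
        outdir/masks/<case>.png
        outdir/gaze/<reader>_s<session>_<case>.csv
    """
    outdir = Path(outdir)
    (outdir / "gaze").mkdir(parents=True, exist_ok=True)
    cases_to_frame(bundle.cases).to_csv(outdir / "cases.csv", index=False)
    bundle.reads_table.to_csv(outdir / "reads.csv", index=False)
    bundle.latent_table.to_csv(outdir / "latent.csv", index=False)
    if write_masks:
        (outdir / "masks").mkdir(exist_ok=True)
        for case in bundle.cases:
            write_mask_png(bundle.mask_for(case), outdir / "masks" / f"{case.case_id}.png")
    manifest_rows = []
    for read in bundle.reads:
        rel = f"gaze/{read.reader}_s{read.session}_{read.case_id}.csv"
        write_gaze_csv(read.recording, outdir / rel)
        manifest_rows.append(
            {
                "reader": read.reader,
                "session": read.session,
                "case_id": read.case_id,
                "condition": read.condition,
                "gaze_file": rel,
                "mask_file": f"masks/{read.case_id}.png" if write_masks else "",
                "n_samples": read.recording.n_samples,
                "n_valid": read.recording.n_valid,
            }
        )
    manifest = outdir / "manifest.csv"
    pd.DataFrame(manifest_rows).to_csv(manifest, index=False)
    with open(outdir / "generator.json", "w") as fh:
        json.dump({"seed": bundle.config.seed, "n_reads": len(bundle.reads)}, fh, indent=1)
    return manifest


def load_cases(path: str | Path) -> list[CaseSpec]:
    return frame_to_cases(pd.read_csv(path))
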