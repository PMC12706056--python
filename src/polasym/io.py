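"""Reading and writing datasets: TIFF images, CSV tables, JSON, YAML."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .afm import ForceCurve
from .frap import FrapTrace
from .lineage import Genealogy
from .synthetic_data import SnapshotDataset, SyntheticCell, GroundTruth

__all__ = [
    "save_snapshot_dataset",
    "load_snapshot_images",
    "save_genealogy",
    "load_frap_traces_csv",
    "save_frap_traces_csv",
    "load_force_curves",
]


def save_snapshot_dataset(ds: SnapshotDataset, outdir: str | Path) -> Path:
    """Write masks (16-bit TIFF), channels (32-bit float TIFF), the
    ground-truth CSV and a YAML config into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for i, cell in enumerate(ds.cells):
        tifffile.imwrite(outdir / f"cell_{i:04d}_mask.tif", cell.mask.astype(np.uint16))
        for name, chan in cell.channels.items():
            tifffile.imwrite(outdir / f"cell_{i:04d}_{name}.tif", chan.astype(np.float32))
    ds.table.to_csv(outdir / "ground_truth.csv", index=False)
    cfg = {"seed": ds.seed, "n_cells": len(ds.cells)}
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return outdir


def load_snapshot_images(indir: str | Path) -> list[dict]:
    """Load per-cell masks and channels written by ``save_snapshot_dataset``."""
    indir = Path(indir)
    cells = []
    for mask_path in sorted(indir.glob("cell_*_mask.tif")):
        stem = mask_path.name[: -len("_mask.tif")]
        channels = {}
        for chan_path in sorted(indir.glob(f"{stem}_*.tif")):
            name = chan_path.name[len(stem) + 1: -len(".tif")]
            if name == "mask":
                continue
            channels[name] = tifffile.imread(chan_path)
        cells.append({"mask": tifffile.imread(mask_path), "channels": channels})
    if not cells:
        raise FileNotFoundError(f"no cell_*_mask.tif files under {indir}")
    return cells


def save_genealogy(gen: Genealogy, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(gen.to_json_dict(), fh, indent=1, sort_keys=True)


def save_frap_traces_csv(traces: list[FrapTrace], path: str | Path) -> None:
    rows = []
    for t in traces:
        for i in range(len(t.times_s)):
            rows.append(
                {
                    "cell_id": t.cell_id,
                    "time_s": t.times_s[i],
                    "intensity": t.raw_intensity[i],
                    "is_control": t.is_control,
                    "bleach_index": t.bleach_index,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def load_frap_traces_csv(path: str | Path, bleach_index: int | None = None) -> list[FrapTrace]:
    """Load traces from a tidy CSV (cell_id, time_s, intensity, is_control)."""
    df = pd.read_csv(path)
    traces = []
    for cid, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("time_s")
        bi = bleach_index
        if bi is None:
            bi = int(grp["bleach_index"].iloc[0]) if "bleach_index" in grp else 0
        traces.append(
            FrapTrace(
                grp["time_s"].to_numpy(),
                grp["intensity"].to_numpy(),
                bleach_index=bi,
                is_control=bool(grp["is_control"].iloc[0]) if "is_control" in grp else False,
                cell_id=cid,
            )
        )
    return traces


def load_force_curves(indir: str | Path) -> list[ForceCurve]:
    """Load per-curve CSVs (columns z_nm, force_nN) plus an optional
    manifest.json with per-curve position / label / spring constant."""
    indir = Path(indir)
    manifest = {}
    mpath = indir / "manifest.json"
    if mpath.exists():
        manifest = json.loads(mpath.read_text())
    curves = []
    for path in sorted(indir.glob("*.csv")):
        df = pd.read_csv(path)
        meta = manifest.get(path.stem, {})
        curves.append(
            ForceCurve(
                df["z_nm"].to_numpy(),
                df["force_nN"].to_numpy(),
                spring_constant_N_per_m=meta.get("spring_constant_N_per_m", 0.35),
                position=meta.get("position"),
                cell_id=meta.get("cell_id"),
                label=meta.get("label"),
            )
        )
    if not curves:
        raise FileNotFoundError(f"no curve CSVs under {indir}")
    return curves
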