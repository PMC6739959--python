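"""File formats: TPS landmark files, wide coordinate CSV, slider and
specimen tables, Newick trees.

Round-tripping (write then read) preserves every coordinate bit-exactly;
parsers never reorder points or tips — order is part of the homology
contract.  Slider tables are 1-based in files (the morphometrics
convention) and 0-based in memory.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import List, Sequence

import numpy as np
import pandas as pd

from .geometry import LandmarkConfiguration, SliderTable
from .phylo import Phylogeny

__all__ = [
    "TpsParseError",
    "read_tps",
    "write_tps",
    "read_coords_csv",
    "write_coords_csv",
    "read_sliders",
    "write_sliders",
    "read_specimen_table",
    "read_newick",
    "write_newick",
]

VALID_GROUPS = {"subterranean", "non-subterranean"}


class TpsParseError(ValueError):
    pass


def read_tps(path, apply_scale: bool = False) -> List[LandmarkConfiguration]:
    """Read a tpsDig-dialect TPS file.

    Each record starts with ``LM=<k>`` followed by k coordinate lines and
    optional ``ID=``, ``IMAGE=``, ``SCALE=`` lines.  SCALE is stored on the
    configuration but multiplied into the coordinates only when
    ``apply_scale`` is true (shape analysis is scale-invariant after GPA, so
    raw storage is the default).
    """
    path = Path(path)
    configs: List[LandmarkConfiguration] = []
    record_points: list = []
    expected_k = None
    rec_id = None
    scale = None
    meta: dict = {}
    start_line = 0
    n_records = 0

    def flush(line_no):
        nonlocal record_points, expected_k, rec_id, scale, meta, n_records
        if expected_k is None:
            return
        if len(record_points) != expected_k:
            raise TpsParseError(
                f"{path.name}: record starting at line {start_line} "
                f"(id={rec_id!r}) declares LM={expected_k} but has "
                f"{len(record_points)} coordinate lines")
        n_records += 1
        pts = np.array(record_points, dtype=float)
        if apply_scale and scale is not None:
            pts = pts * scale
        configs.append(LandmarkConfiguration(
            specimen_id=rec_id if rec_id is not None else f"record_{n_records}",
            points=pts, scale_factor=scale, metadata=dict(meta)))
        record_points, expected_k, rec_id, scale, meta = [], None, None, None, {}

    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith("LM="):
                flush(line_no)
                start_line = line_no
                try:
                    expected_k = int(line.split("=", 1)[1])
                except ValueError:
                    raise TpsParseError(
                        f"{path.name}:{line_no}: bad LM count {line!r}")
            elif upper.startswith("ID="):
                rec_id = line.split("=", 1)[1].strip()
            elif upper.startswith("SCALE="):
                try:
                    scale = float(line.split("=", 1)[1])
                except ValueError:
                    raise TpsParseError(
                        f"{path.name}:{line_no}: bad SCALE {line!r}")
            elif upper.startswith("IMAGE="):
                meta["image"] = line.split("=", 1)[1].strip()
            elif "=" in line and not _looks_numeric(line):
                key = line.split("=", 1)[0].strip().lower()
                meta[key] = line.split("=", 1)[1].strip()
            else:
                if expected_k is None:
                    raise TpsParseError(
                        f"{path.name}:{line_no}: coordinate line before LM=")
                parts = line.split()
                if len(parts) != 2:
                    raise TpsParseError(
                        f"{path.name}:{line_no}: expected two coordinates, "
                        f"got {line!r}")
                try:
                    record_points.append((float(parts[0]), float(parts[1])))
                except ValueError:
                    raise TpsParseError(
                        f"{path.name}:{line_no}: non-numeric coordinate "
                        f"{line!r}")
    flush(line_no=-1)
    return configs


def _looks_numeric(line: str) -> bool:
    try:
        [float(x) for x in line.split()]
        return True
    except ValueError:
        return False


def write_tps(configs: Sequence[LandmarkConfiguration], path,
              strict: bool = False) -> None:
    """Write configurations in the dialect read by :func:`read_tps`.

    Coordinates are written with ``repr`` precision so the round trip is
    bit-exact.  With ``strict``, all configurations must share one k.
    """
    if strict and configs:
        ks = {c.k for c in configs}
        if len(ks) > 1:
            raise ValueError(f"mixed landmark counts under strict mode: {ks}")
    path = Path(path)
    with open(path, "w") as fh:
        for c in configs:
            fh.write(f"LM={c.k}\n")
            for x, y in c.points:
                fh.write(f"{float(x)!r} {float(y)!r}\n")
            if "image" in c.metadata:
                fh.write(f"IMAGE={c.metadata['image']}\n")
            fh.write(f"ID={c.specimen_id}\n")
            if c.scale_factor is not None:
                fh.write(f"SCALE={c.scale_factor!r}\n")


def read_coords_csv(path) -> List[LandmarkConfiguration]:
    """Wide CSV: one row per specimen, columns id, x1, y1, ..., xk, yk."""
    df = pd.read_csv(path, dtype={"id": str}, float_precision="round_trip")
    if "id" not in df.columns:
        raise ValueError("coordinate CSV requires an 'id' column")
    coord_cols = [c for c in df.columns if c != "id"]
    k = len(coord_cols) // 2
    expected = [f"{ax}{i}" for i in range(1, k + 1) for ax in ("x", "y")]
    if coord_cols != expected:
        raise ValueError("coordinate columns must be x1,y1,...,xk,yk in order")
    out = []
    for _, row in df.iterrows():
        pts = row[coord_cols].to_numpy(dtype=float).reshape(k, 2)
        out.append(LandmarkConfiguration(specimen_id=row["id"], points=pts))
    return out


def write_coords_csv(configs: Sequence[LandmarkConfiguration], path) -> None:
    k = configs[0].k if configs else 0
    cols = [f"{ax}{i}" for i in range(1, k + 1) for ax in ("x", "y")]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id"] + cols)
        for c in configs:
            if c.k != k:
                raise ValueError("mixed landmark counts in CSV export")
            w.writerow([c.specimen_id] + [repr(float(v)) for v in c.points.ravel()])


def read_sliders(path) -> SliderTable:
    """Slider CSV with header before,slider,after; 1-based in the file,
    converted to 0-based indices in memory."""
    df = pd.read_csv(path)
    need = ["before", "slider", "after"]
    if list(df.columns) != need:
        raise ValueError(f"slider table must have columns {need}")
    return SliderTable(rows=df.to_numpy(dtype=int) - 1)


def write_sliders(table: SliderTable, path) -> None:
    pd.DataFrame(table.rows + 1,
                 columns=["before", "slider", "after"]).to_csv(path, index=False)


def read_specimen_table(path) -> pd.DataFrame:
    """Specimen table CSV: specimen_id, species, group, structure.

    Validates that each specimen_id appears once per structure and that each
    species maps to exactly one group.
    """
    df = pd.read_csv(path, dtype=str)
    need = {"specimen_id", "species", "group", "structure"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"specimen table missing columns: {sorted(missing)}")
    bad = set(df["group"]) - VALID_GROUPS
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")
    dup = df.duplicated(subset=["specimen_id", "structure"])
    if dup.any():
        raise ValueError(
            f"duplicate specimen_id within a structure: "
            f"{sorted(df.loc[dup, 'specimen_id'].unique())}")
    g = df.groupby("species")["group"].nunique()
    if (g > 1).any():
        raise ValueError(
            f"species mapped to multiple groups: {sorted(g[g > 1].index)}")
    return df


def read_newick(path) -> Phylogeny:
    """Read a single rooted Newick tree with branch lengths."""
    text = Path(path).read_text().strip()
    if text.count("(") != text.count(")"):
        raise ValueError("unbalanced parentheses in Newick file")
    return Phylogeny.from_newick(text)


def write_newick(tree: Phylogeny, path) -> None:
    Path(path).write_text(tree.as_newick() + "\n")
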