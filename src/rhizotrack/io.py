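"""File formats: TIFF stacks, CSV records/trajectories, JSON sidecars.

All intermediate formats carry a format version; readers reject unknown
major versions.  Stacks are multi-page TIFF (one page per z-slice) with
voxel sizes, time and origin in the image description; records and
trajectories are plain CSV with a versioned comment header; forests,
lineages, motions and manifests are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .registration import RigidMotion
from .tracking import AssignmentForest
from .types import RECORD_FIELDS, ImageStack, NucleusRecord

__all__ = [
    "read_stack",
    "write_stack",
    "read_records",
    "write_records",
    "read_forest",
    "write_forest",
    "write_motions",
    "read_motions",
    "write_ground_truth",
    "FORMAT_VERSION",
]

FORMAT_VERSION = "1.0"
_MAJOR = FORMAT_VERSION.split(".")[0]


class ParseError(ValueError):
    """Malformed input file, with location information where possible."""


def _check_version(version: str, path) -> None:
    if version.split(".")[0] != _MAJOR:
        raise ParseError(
            f"{path}: format version {version} not supported "
            f"(reader major version {_MAJOR})"
        )


def write_stack(path, stack: ImageStack) -> None:
    """One TIFF page per z-slice; physical metadata in the description."""
    meta = {
        "format_version": FORMAT_VERSION,
        "voxel_sizes": list(stack.voxel_sizes),
        "time": stack.time,
        "origin": list(stack.origin),
    }
    tifffile.imwrite(
        path,
        stack.voxels.astype(np.float32),
        photometric="minisblack",
        description=json.dumps(meta),
    )


def read_stack(path) -> ImageStack:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray().astype(np.float64)
        desc = tif.pages[0].description
    try:
        meta = json.loads(desc)
    except (TypeError, json.JSONDecodeError) as exc:
        raise ParseError(f"{path}: missing or malformed stack metadata") from exc
    _check_version(meta.get("format_version", "0"), path)
    return ImageStack(
        voxels=data,
        voxel_sizes=tuple(meta["voxel_sizes"]),
        time=float(meta["time"]),
        origin=tuple(meta["origin"]),
    )


def records_to_dataframe(records: list[NucleusRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            (
                r.id,
                r.time,
                r.centroid[0],
                r.centroid[1],
                r.centroid[2],
                r.max_intensity,
                r.mean_intensity,
                r.voxel_count,
                r.lateral_size,
                r.lateral_eccentricity,
                r.axial_size,
            )
        )
    return pd.DataFrame(rows, columns=list(RECORD_FIELDS))


def dataframe_to_records(df: pd.DataFrame) -> list[NucleusRecord]:
    out = []
    for row in df.itertuples(index=False):
        out.append(
            NucleusRecord(
                id=int(row.id),
                time=float(row.time),
                centroid=np.array([row.x, row.y, row.z], dtype=float),
                max_intensity=float(row.max_intensity),
                mean_intensity=float(row.mean_intensity),
                voxel_count=int(row.voxel_count),
                lateral_size=float(row.lateral_size),
                lateral_eccentricity=float(row.lateral_eccentricity),
                axial_size=float(row.axial_size),
            )
        )
    return out


def write_records(path, records: list[NucleusRecord]) -> None:
    df = records_to_dataframe(records)
    with open(path, "w") as fh:
        fh.write(f"# rhizotrack records v{FORMAT_VERSION}\n")
        df.to_csv(fh, index=False)


def read_records(path) -> list[NucleusRecord]:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# rhizotrack records v"):
            raise ParseError(f"{path}:1: missing records header")
        _check_version(header.rsplit("v", 1)[1], path)
        try:
            df = pd.read_csv(fh)
        except pd.errors.ParserError as exc:
            raise ParseError(f"{path}: {exc}") from exc
    missing = set(RECORD_FIELDS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if df[list(RECORD_FIELDS)].isna().any().any():
        bad = int(np.nonzero(df.isna().any(axis=1).to_numpy())[0][0])
        raise ParseError(f"{path}: incomplete row at data line {bad + 1}")
    return dataframe_to_records(df)


def write_forest(path, forest: AssignmentForest) -> None:
    payload = {
        "format_version": FORMAT_VERSION,
        "n_records": forest.n_records,
        "links": [list(map(int, link)) for link in forest.links],
    }
    Path(path).write_text(json.dumps(payload))


def read_forest(path) -> AssignmentForest:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON at offset {exc.pos}") from exc
    _check_version(payload.get("format_version", "0"), path)
    return AssignmentForest(
        links=[tuple(link) for link in payload["links"]],
        n_records=int(payload["n_records"]),
    )


def write_motions(path, motions: list[RigidMotion]) -> None:
    payload = {
        "format_version": FORMAT_VERSION,
        "motions": [
            {
                "rotation": m.rotation.tolist(),
                "translation": m.translation.tolist(),
                "residual": m.residual,
            }
            for m in motions
        ],
    }
    Path(path).write_text(json.dumps(payload))


def read_motions(path) -> list[RigidMotion]:
    payload = json.loads(Path(path).read_text())
    _check_version(payload.get("format_version", "0"), path)
    return [
        RigidMotion(
            np.array(m["rotation"]),
            np.array(m["translation"]),
            float(m["residual"]),
        )
        for m in payload["motions"]
    ]


def write_ground_truth(csv_path, lineage_path, state) -> None:
    """Ground truth as CSV (one row per nucleus per frame) and the
    lineage (parent -> daughters with division frames) as JSON."""
    from .synthetic import ground_truth_to_dataframe

    df = ground_truth_to_dataframe(state)
    with open(csv_path, "w") as fh:
        fh.write(f"# rhizotrack ground truth v{FORMAT_VERSION}\n")
        df.to_csv(fh, index=False)
    lineage = {
        "format_version": FORMAT_VERSION,
        "divisions": [
            {
                "parent": int(d.parent_id),
                "daughters": [int(x) for x in d.daughter_ids],
                "t_index": int(d.t_index),
                "axis": [float(v) for v in d.axis],
                "displacements": [float(v) for v in d.displacements],
            }
            for d in state.divisions
        ],
    }
    Path(lineage_path).write_text(json.dumps(lineage))
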