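"""Landmark dataset input/output: TPS files and tabular CSV.

TPS dialect supported: ``LM=<k>`` followed by k whitespace-separated
coordinate rows, then optional ``IMAGE=`` (ignored), ``ID=`` and
``SCALE=`` records.  SCALE multiplies the raw coordinates (digitizers
typically store pixels with a mm-per-pixel scale factor).  Species labels
are taken either from a sidecar mapping (specimen_id -> species) or from
the ID naming convention ``specimen|species[|replicate]`` that
:func:`write_dataset` emits.

Coordinates are written with 6 decimal places; round-trips are exact at
that precision.
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from .containers import LandmarkConfiguration, MorphoDataset

__all__ = ["read_tps", "read_landmark_csv", "write_dataset"]

_PRECISION = 6


def _parse_id(raw: str, species_map: Optional[Mapping[str, str]]):
    parts = raw.split("|")
    specimen = parts[0]
    species = parts[1] if len(parts) > 1 else None
    replicate = int(parts[2]) if len(parts) > 2 else None
    if species_map is not None:
        species = species_map.get(specimen, species)
    if species is None:
        raise ValueError(
            f"no species label for specimen {specimen!r}: use 'id|species' IDs "
            "or provide a species_map"
        )
    return specimen, species, replicate


def read_tps(
    path: Union[str, Path],
    species_map: Optional[Mapping[str, str]] = None,
    flip_y: bool = False,
) -> MorphoDataset:
    """Read a TPS landmark file into a validated dataset.

    A missing SCALE record leaves coordinates in their stored unit with a
    warning (shape analysis is scale-free, but centroid sizes then lack a
    unit).  ``flip_y`` negates y for data digitized in image convention
    (y axis pointing down); mixing conventions within one dataset cannot be
    detected and must be avoided upstream.
    """
    lines = Path(path).read_text().splitlines()
    configs = []
    i = 0
    block = 0
    expected_k: Optional[int] = None
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM="):
            raise ValueError(f"expected LM= record at line {i + 1}, got {line!r}")
        k = int(line.split("=", 1)[1])
        block += 1
        coords = np.empty((k, 2))
        for j in range(k):
            i += 1
            parts = lines[i].split()
            coords[j] = (float(parts[0]), float(parts[1]))
        raw_id = f"block{block}"
        scale = None
        i += 1
        while i < len(lines):
            rec = lines[i].strip()
            upper = rec.upper()
            if upper.startswith("LM=") or not rec:
                break
            if upper.startswith("ID="):
                raw_id = rec.split("=", 1)[1].strip()
            elif upper.startswith("SCALE="):
                scale = float(rec.split("=", 1)[1])
            elif upper.startswith("IMAGE="):
                pass
            else:
                raise ValueError(f"unrecognised TPS record at line {i + 1}: {rec!r}")
            i += 1
        if expected_k is None:
            expected_k = k
        elif k != expected_k:
            raise ValueError(
                f"inconsistent landmark count in record {raw_id!r}: "
                f"LM={k}, expected LM={expected_k}"
            )
        if scale is None:
            warnings.warn(
                f"record {raw_id!r} has no SCALE=; coordinates passed through "
                "unscaled",
                stacklevel=2,
            )
        else:
            coords = coords * scale
        if flip_y:
            coords[:, 1] *= -1.0
        specimen, species, replicate = _parse_id(raw_id, species_map)
        configs.append(
            LandmarkConfiguration(
                specimen_id=specimen,
                species=species,
                landmarks=coords,
                replicate=replicate,
            )
        )
    return MorphoDataset(configs)


def read_landmark_csv(path: Union[str, Path]) -> MorphoDataset:
    """Read landmarks from CSV columns specimen_id, species[, replicate], x1..yk."""
    df = pd.read_csv(path)
    required = {"specimen_id", "species"}
    if not required <= set(df.columns):
        raise ValueError(f"missing required columns: {sorted(required - set(df.columns))}")
    coord_cols = [c for c in df.columns if c[0] in "xy" and c[1:].isdigit()]
    k = len(coord_cols) // 2
    ordered = [f"{axis}{i}" for i in range(1, k + 1) for axis in ("x", "y")]
    if sorted(coord_cols) != sorted(ordered):
        raise ValueError(f"coordinate columns must be x1,y1..x{k},y{k}")
    configs = []
    for row_number, row in enumerate(df.itertuples(index=False), start=2):
        rec = row._asdict()
        vals = [rec[c] for c in ordered]
        if any(pd.isna(v) for v in vals):
            bad = ordered[next(i for i, v in enumerate(vals) if pd.isna(v))]
            raise ValueError(f"missing coordinate {bad!r} at row {row_number}")
        coords = np.array(vals, dtype=float).reshape(k, 2)
        rep = rec.get("replicate")
        configs.append(
            LandmarkConfiguration(
                specimen_id=str(rec["specimen_id"]),
                species=str(rec["species"]),
                landmarks=coords,
                replicate=None if rep is None or pd.isna(rep) else int(rep),
            )
        )
    return MorphoDataset(configs)


def write_dataset(
    dataset: MorphoDataset, path: Union[str, Path], format: str = "csv"
) -> None:
    """Serialize a dataset to TPS or CSV (lossless at 6 decimal places)."""
    path = Path(path)
    if format == "tps":
        out = []
        for c in dataset:
            out.append(f"LM={c.k}")
            for x, y in c.landmarks:
                out.append(f"{x:.{_PRECISION}f} {y:.{_PRECISION}f}")
            ident = c.specimen_id + "|" + c.species
            if c.replicate is not None:
                ident += f"|{c.replicate}"
            out.append(f"ID={ident}")
            out.append("SCALE=1.0")
        path.write_text("\n".join(out) + "\n")
    elif format == "csv":
        k = dataset.k
        header = ["specimen_id", "species", "replicate"] + [
            f"{axis}{i}" for i in range(1, k + 1) for axis in ("x", "y")
        ]
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(header)
            for c in dataset:
                row = [
                    c.specimen_id,
                    c.species,
                    "" if c.replicate is None else c.replicate,
                ] + [f"{v:.{_PRECISION}f}" for v in c.landmarks.reshape(-1)]
                writer.writerow(row)
    else:
        raise ValueError(f"unknown format {format!r}; use 'tps' or 'csv'")
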