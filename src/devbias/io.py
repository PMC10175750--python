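"""Readers and writers for landmark files (TPS, long/wide CSV).

TPS records are blocks of the form::

    LM=11
    x1 y1
    ...
    IMAGE=specimen_left_1.jpg
    ID=specimen_a

Factor columns (individual, side, measurement, ...) come either from a
sidecar CSV keyed by ``specimen_id`` or from the long-CSV columns directly.
All numeric output files carry '#'-prefixed metadata header lines.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .data import FACTOR_COLUMNS, LandmarkConfiguration, ShapeDataset


class ParseError(ValueError):
    """Malformed landmark file; the message names the offending line."""


def _parse_tps(path: Path) -> list[dict]:
    records: list[dict] = []
    current: dict | None = None
    remaining = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith("LM="):
                if current is not None and remaining:
                    raise ParseError(
                        f"{path}:{lineno}: new LM= block while {remaining} "
                        "landmark lines were still expected"
                    )
                try:
                    n = int(line.split("=", 1)[1])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad LM= count") from exc
                current = {"coords": [], "meta": {}}
                records.append(current)
                remaining = n
            elif "=" in line and not line[0].isdigit() and not line[0] in "+-.":
                if current is None:
                    raise ParseError(f"{path}:{lineno}: metadata before any LM= block")
                key, value = line.split("=", 1)
                current["meta"][key.upper()] = value.strip()
            else:
                if current is None:
                    raise ParseError(f"{path}:{lineno}: coordinates before any LM= block")
                if remaining == 0:
                    raise ParseError(f"{path}:{lineno}: more coordinate lines than LM= declared")
                parts = line.split()
                if len(parts) != 2:
                    raise ParseError(f"{path}:{lineno}: expected 'x y', got {line!r}")
                try:
                    current["coords"].append((float(parts[0]), float(parts[1])))
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-numeric coordinate") from exc
                remaining -= 1
    if current is not None and remaining:
        raise ParseError(f"{path}: file ended with {remaining} landmark lines missing")
    if not records:
        raise ParseError(f"{path}: no LM= records found")
    return records


def _specimen_fields(meta: dict, index: int) -> tuple[str, str, int]:
    """Derive (specimen_id, side, replicate) from TPS metadata.

    IDs of the form ``name_left_2`` / ``name_R_1`` encode side and replicate;
    otherwise side defaults to 'none' and replicate to 1.
    """
    ident = meta.get("ID") or meta.get("IMAGE") or f"specimen_{index}"
    ident = str(ident)
    side, replicate = "none", 1
    parts = ident.split("_")
    core = parts
    if len(parts) >= 3 and parts[-1].isdigit():
        side_token = parts[-2].lower()
        if side_token in ("left", "l"):
            side, replicate, core = "left", int(parts[-1]), parts[:-2]
        elif side_token in ("right", "r"):
            side, replicate, core = "right", int(parts[-1]), parts[:-2]
        elif side_token == "none":
            side, replicate, core = "none", int(parts[-1]), parts[:-2]
    return "_".join(core), side, replicate


def read_landmarks(path: str | Path, format: str = "tps",
                   factors: str | Path | pd.DataFrame | None = None) -> ShapeDataset:
    """Read a landmark file into a :class:`ShapeDataset`.

    Parameters
    ----------
    path : file path
    format : 'tps' or 'csv' (long format with columns
        specimen_id, side, measurement, landmark, x, y)
    factors : optional sidecar factor CSV (or DataFrame) keyed by
        ``specimen_id``; merged onto the per-observation factor table.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tps":
        records = _parse_tps(path)
        counts = {len(r["coords"]) for r in records}
        if len(counts) != 1:
            raise ValueError(f"{path}: inconsistent landmark counts {sorted(counts)}")
        observations, rows = [], []
        for i, rec in enumerate(records):
            sid, side, rep = _specimen_fields(rec["meta"], i)
            observations.append(LandmarkConfiguration(sid, side, rep, np.array(rec["coords"])))
            rows.append({"individual": sid, "side": side, "measurement": rep})
        table = pd.DataFrame(rows)
    elif format == "csv":
        df = pd.read_csv(path, comment="#")
        needed = {"specimen_id", "landmark", "x", "y"}
        missing = needed - set(df.columns)
        if missing:
            raise ParseError(f"{path}: missing columns {sorted(missing)}")
        if "side" not in df.columns:
            df["side"] = "none"
        if "measurement" not in df.columns:
            df["measurement"] = 1
        observations, rows = [], []
        keys = ["specimen_id", "side", "measurement"]
        for (sid, side, rep), grp in df.groupby(keys, sort=False):
            grp = grp.sort_values("landmark")
            if grp["landmark"].duplicated().any():
                raise ValueError(f"{path}: duplicated landmark index for specimen {sid!r}")
            observations.append(
                LandmarkConfiguration(str(sid), str(side), int(rep),
                                      grp[["x", "y"]].to_numpy())
            )
            rows.append({"individual": str(sid), "side": str(side), "measurement": int(rep)})
        counts = {o.n_landmarks for o in observations}
        if len(counts) != 1:
            raise ValueError(f"{path}: inconsistent landmark counts {sorted(counts)}")
        table = pd.DataFrame(rows)
    else:
        raise ValueError(f"unknown format {format!r}")

    if factors is not None:
        side_table = factors if isinstance(factors, pd.DataFrame) else pd.read_csv(factors, comment="#")
        if "specimen_id" not in side_table.columns:
            raise ValueError("factor sidecar must have a specimen_id column")
        keep = ["specimen_id"] + [c for c in side_table.columns if c in FACTOR_COLUMNS]
        merged = table.merge(side_table[keep], left_on="individual",
                             right_on="specimen_id", how="left",
                             suffixes=("", "_sidecar"))
        merged = merged.drop(columns=["specimen_id"])
        for col in list(merged.columns):
            if col.endswith("_sidecar"):
                base = col[: -len("_sidecar")]
                merged[base] = merged[col].where(merged[col].notna(), merged[base])
                merged = merged.drop(columns=[col])
        table = merged[[c for c in merged.columns if c in FACTOR_COLUMNS]]
    return ShapeDataset(observations, table)


def write_tps(dataset: ShapeDataset, path: str | Path) -> None:
    """Write a dataset as a TPS file, encoding side/replicate into the ID."""
    with open(path, "w") as fh:
        for obs in dataset.observations:
            fh.write(f"LM={obs.n_landmarks}\n")
            for x, y in obs.coords:
                fh.write(f"{x:.10g} {y:.10g}\n")
            fh.write(f"ID={obs.specimen_id}_{obs.side}_{obs.replicate}\n")


def write_long_csv(dataset: ShapeDataset, path: str | Path, meta: dict | None = None) -> None:
    """Write observations in long format (one row per landmark)."""
    rows = []
    for obs in dataset.observations:
        for j, (x, y) in enumerate(obs.coords, start=1):
            rows.append((obs.specimen_id, obs.side, obs.replicate, j, x, y))
    df = pd.DataFrame(rows, columns=["specimen_id", "side", "measurement", "landmark", "x", "y"])
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, index=False)
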