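"""HDF5 result archive: all intermediate and final results of a run, plus the
processing parameters, in one self-describing file.

Layout (version ``myceliotrack_layout = 1``)::

    /                       attrs: myceliotrack_layout
    /positions/<id>/
        params              JSON of the fully materialised RunConfig
        drift_offsets       (T, 2) int, registration translations
        timestamps_s        (T,) float
        calibration_um_per_px  scalar dataset
        images/frame_NNN    optional raw frames (off by default)
        masks/frame_NNN     gzip'd uint8 binary masks
        skeletons/frame_NNN gzip'd uint8 skeletons
        graphs/frame_NNN    GraphML document as a UTF-8 string
        tables/position_timeseries/... one dataset per column
        tables/track_summary/...
        tables/hypha_timeseries/...
        summary             JSON of the derived summary

Tables are stored column-wise (numeric columns as native dtypes, text columns
as UTF-8 variable-length strings, missing values as NaN / empty string) with
the column order in an attribute, so a re-run with identical inputs and
parameters produces element-wise identical tables.
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd

from .pipeline import PositionResult
from .skeleton_graph import to_graphml

LAYOUT_VERSION = 1
TABLE_NAMES = ("position_timeseries", "track_summary", "hypha_timeseries")

_STR = h5py.string_dtype(encoding="utf-8")


def _write_table(group: h5py.Group, name: str, df: pd.DataFrame) -> None:
    g = group.create_group(name)
    g.attrs["columns"] = json.dumps(list(df.columns))
    g.attrs["n_rows"] = len(df)
    for col in df.columns:
        values = df[col]
        if values.dtype == object or pd.api.types.is_string_dtype(values):
            data = values.fillna("").astype(str).to_numpy()
            g.create_dataset(col, data=data, dtype=_STR)
        elif pd.api.types.is_bool_dtype(values):
            g.create_dataset(col, data=values.to_numpy(dtype=np.uint8))
            g[col].attrs["bool"] = 1
        else:
            g.create_dataset(col, data=values.to_numpy())


def _read_table(group: h5py.Group) -> pd.DataFrame:
    columns = json.loads(group.attrs["columns"])
    n_rows = int(group.attrs["n_rows"])
    data = {}
    for col in columns:
        ds = group[col]
        values = ds[()]
        if ds.dtype == _STR or h5py.check_string_dtype(ds.dtype):
            values = np.asarray([v.decode() if isinstance(v, bytes) else v
                                 for v in values], dtype=object)
        elif ds.attrs.get("bool"):
            values = values.astype(bool)
        data[col] = values
    df = pd.DataFrame(data, columns=columns)
    assert len(df) == n_rows
    return df


def write_archive(path, results: Sequence[PositionResult],
                  store_images: bool = False) -> Path:
    """Write one or more position results atomically to an HDF5 archive.

    The file is assembled under ``<path>.tmp`` and moved into place on
    success; a failed write leaves only the quarantined temporary file.
    """
    path = Path(path)
    tmp = path.with_name(path.name + ".tmp")
    try:
        with h5py.File(tmp, "w") as f:
            f.attrs["myceliotrack_layout"] = LAYOUT_VERSION
            positions = f.create_group("positions")
            for res in results:
                g = positions.create_group(res.position_id)
                g.create_dataset("params", data=res.config.to_json(), dtype=_STR)
                g.create_dataset(
                    "summary", data=json.dumps(res.summary.to_dict()), dtype=_STR
                )
                g.create_dataset("timestamps_s", data=res.stack.timestamps)
                g.create_dataset("calibration_um_per_px",
                                 data=res.stack.calibration)
                offsets = (res.stack.drift_offsets
                           if res.stack.drift_offsets is not None
                           else np.zeros((len(res.stack), 2), dtype=int))
                g.create_dataset("drift_offsets", data=offsets)

                masks = g.create_group("masks")
                skels = g.create_group("skeletons")
                graphs = g.create_group("graphs")
                for i, (m, s, gr) in enumerate(
                    zip(res.masks, res.skeletons, res.graphs)
                ):
                    key = f"frame_{i:03d}"
                    masks.create_dataset(
                        key, data=m.mask.astype(np.uint8),
                        compression="gzip", compression_opts=4,
                    )
                    skels.create_dataset(
                        key, data=s.pixels.astype(np.uint8),
                        compression="gzip", compression_opts=4,
                    )
                    graphs.create_dataset(key, data=to_graphml(gr), dtype=_STR)
                if store_images:
                    images = g.create_group("images")
                    for i, frame in enumerate(res.stack.frames):
                        images.create_dataset(
                            f"frame_{i:03d}", data=frame,
                            compression="gzip", compression_opts=4,
                        )

                tables = g.create_group("tables")
                _write_table(tables, "position_timeseries",
                             res.position_timeseries)
                _write_table(tables, "track_summary", res.track_summary)
                _write_table(tables, "hypha_timeseries", res.hypha_timeseries)
    except Exception:
        raise
    os.replace(tmp, path)
    return path


def list_positions(path) -> list[str]:
    with h5py.File(path, "r") as f:
        return sorted(f["positions"].keys())


def read_table(path, table_name: str, position: str | None = None) -> pd.DataFrame:
    """Read a stored table back as a DataFrame.

    An unknown table name raises a KeyError listing the available tables.
    """
    with h5py.File(path, "r") as f:
        positions = sorted(f["positions"].keys())
        if position is None:
            position = positions[0]
        tables = f[f"positions/{position}/tables"]
        if table_name not in tables:
            raise KeyError(
                f"no table {table_name!r} in position {position!r}; "
                f"available: {sorted(tables.keys())}"
            )
        return _read_table(tables[table_name])


def read_params(path, position: str | None = None) -> dict:
    with h5py.File(path, "r") as f:
        positions = sorted(f["positions"].keys())
        if position is None:
            position = positions[0]
        raw = f[f"positions/{position}/params"][()]
        return json.loads(raw.decode() if isinstance(raw, bytes) else raw)


def read_summary(path, position: str | None = None) -> dict:
    with h5py.File(path, "r") as f:
        positions = sorted(f["positions"].keys())
        if position is None:
            position = positions[0]
        raw = f[f"positions/{position}/summary"][()]
        return json.loads(raw.decode() if isinstance(raw, bytes) else raw)


def export_tsv(path, table_name: str, out_path,
               position: str | None = None) -> Path:
    """Export a stored table as UTF-8 TSV (header row, missing values empty)."""
    df = read_table(path, table_name, position)
    out_path = Path(out_path)
    df.to_csv(out_path, sep="\t", index=False, na_rep="", encoding="utf-8")
    return out_path


def export_graphml(path, frame: int, out_path,
                   position: str | None = None) -> Path:
    with h5py.File(path, "r") as f:
        positions = sorted(f["positions"].keys())
        if position is None:
            position = positions[0]
        raw = f[f"positions/{position}/graphs/frame_{frame:03d}"][()]
    out_path = Path(out_path)
    out_path.write_text(raw.decode() if isinstance(raw, bytes) else raw,
                        encoding="utf-8")
    return out_path


def validate_archive(path) -> list[str]:
    """Check the archive is self-describing and complete; return problems."""
    problems: list[str] = []
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        return [f"cannot open archive: {exc}"]
    with f:
        if f.attrs.get("myceliotrack_layout") != LAYOUT_VERSION:
            problems.append("missing or unexpected myceliotrack_layout attribute")
        if "positions" not in f:
            problems.append("missing /positions group")
            return problems
        if not len(f["positions"]):
            problems.append("archive contains no positions")
        for pid, g in f["positions"].items():
            for member in ("params", "summary", "timestamps_s",
                           "calibration_um_per_px", "drift_offsets",
                           "masks", "skeletons", "graphs", "tables"):
                if member not in g:
                    problems.append(f"position {pid}: missing {member}")
            if "tables" in g:
                for t in TABLE_NAMES:
                    if t not in g["tables"]:
                        problems.append(f"position {pid}: missing table {t}")
                    elif "columns" not in g["tables"][t].attrs:
                        problems.append(
                            f"position {pid}: table {t} lacks column metadata"
                        )
            if all(k in g for k in ("masks", "skeletons", "graphs", "timestamps_s")):
                n = len(g["timestamps_s"])
                for grp in ("masks", "skeletons", "graphs"):
                    if len(g[grp]) != n:
                        problems.append(
                            f"position {pid}: {grp} has {len(g[grp])} frames, "
                            f"expected {n}"
                        )
    return problems
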