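"""Readers/writers for feature tables, metadata, manifests and tracks.

Canonical on-disk layout for one experiment directory::

    features_prestim.csv    wells x features, one file per period
    features_bluelight.csv
    features_poststim.csv
    metadata.csv            well_id, group, strain, drug, dose_uM, day, bad_well
    ground_truth.json       planted effects (synthetic runs only)
    manifest.json           feature name -> units/period/window
    tracks.h5               skeleton containers (optional)

All tabular interchange is CSV; tracks use HDF5.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

from . import PERIODS
from .synthetic_data import StimulusSchedule, Track, TrackSet, WormParams

__all__ = [
    "read_feature_table", "write_feature_table",
    "read_experiment", "write_experiment",
    "read_metadata", "write_tracks", "read_tracks",
    "write_manifest", "read_manifest",
]

log = logging.getLogger(__name__)


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index_label="well_id")


def read_feature_table(path, manifest: Mapping[str, dict] | None = None
                       ) -> pd.DataFrame:
    """Read a wells-by-features CSV.

    Duplicate well ids are an error; columns absent from ``manifest`` are
    loaded but reported; manifest features absent from the table produce a
    warning.  Undefined markers (empty cells/NaN) are preserved.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path} is empty: no feature table present")
    table = pd.read_csv(path, index_col="well_id")
    if table.index.has_duplicates:
        dups = table.index[table.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate well_id entries: {dups}")
    if manifest is not None:
        unknown = [c for c in table.columns if c not in manifest]
        missing = [c for c in manifest if c not in table.columns]
        if unknown:
            log.warning("%s: columns not in manifest: %s", path, unknown)
        if missing:
            log.warning("%s: manifest features missing: %s", path, missing)
    return table


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path)
    required = {"well_id", "group", "day", "bad_well"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    return meta


def write_experiment(outdir, tables: Mapping[str, pd.DataFrame],
                     metadata: pd.DataFrame, ground_truth=None,
                     manifest: Mapping[str, dict] | None = None) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for period, table in tables.items():
        write_feature_table(table, outdir / f"features_{period}.csv")
    metadata.to_csv(outdir / "metadata.csv", index=False)
    if ground_truth is not None:
        ground_truth.to_json(outdir / "ground_truth.json")
    if manifest is not None:
        write_manifest(manifest, outdir / "manifest.json")
    return outdir


def read_experiment(indir, periods: Sequence[str] = PERIODS
                    ) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    indir = Path(indir)
    manifest = None
    mpath = indir / "manifest.json"
    if mpath.exists():
        manifest = read_manifest(mpath)
    tables = {p: read_feature_table(indir / f"features_{p}.csv", manifest)
              for p in periods if (indir / f"features_{p}.csv").exists()}
    if not tables:
        raise FileNotFoundError(f"no features_<period>.csv files in {indir}")
    meta = read_metadata(indir / "metadata.csv")
    return tables, meta


def write_manifest(manifest: Mapping[str, dict], path) -> None:
    with open(path, "w") as fh:
        json.dump(dict(manifest), fh, indent=1, sort_keys=True)


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_tracks(trackset: TrackSet, path) -> None:
    """Store a TrackSet as HDF5: per-track coords/widths/times/modes."""
    with h5py.File(path, "w") as fh:
        sched = fh.create_group("schedule")
        s = trackset.schedule
        sched.attrs["frame_rate"] = s.frame_rate
        sched.attrs["period_durations"] = s.period_durations
        sched.attrs["pulse_starts"] = s.pulse_starts
        sched.attrs["pulse_duration"] = s.pulse_duration
        p = fh.create_group("params")
        for k, v in vars(trackset.params).items():
            if isinstance(v, (int, float)):
                p.attrs[k] = v
        for i, tr in enumerate(trackset.tracks):
            g = fh.create_group(f"track_{i:04d}")
            g.create_dataset("coords", data=tr.coords, compression="gzip")
            g.create_dataset("widths", data=tr.widths, compression="gzip")
            g.create_dataset("times", data=tr.times)
            g.create_dataset("modes", data=np.array(
                [m.encode() for m in tr.modes]))


def read_tracks(path) -> TrackSet:
    with h5py.File(path, "r") as fh:
        s = fh["schedule"].attrs
        schedule = StimulusSchedule(
            frame_rate=float(s["frame_rate"]),
            period_durations=tuple(float(x) for x in s["period_durations"]),
            pulse_starts=tuple(float(x) for x in s["pulse_starts"]),
            pulse_duration=float(s["pulse_duration"]),
        )
        pa = dict(fh["params"].attrs)
        params = WormParams(
            length_um=float(pa.get("length_um", 1000.0)),
            width_um=float(pa.get("width_um", 100.0)),
            n_points=int(pa.get("n_points", 49)),
            speed_um_s=float(pa.get("speed_um_s", 300.0)),
        )
        tracks = []
        for name in sorted(k for k in fh if k.startswith("track_")):
            g = fh[name]
            tracks.append(Track(
                coords=g["coords"][()],
                widths=g["widths"][()],
                times=g["times"][()],
                modes=np.array([m.decode() for m in g["modes"][()]],
                               dtype=object),
            ))
    return TrackSet(tracks=tracks, schedule=schedule, params=params)
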