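"""Readers/writers for the native on-disk cohort format.

Layout (all plain text, diffable)::

    cohort_dir/
      cohort.json                   index: format_version, cell + animal ids
      cells/<cell_id>/cell.json     metadata, protocols, sweep manifest
      cells/<cell_id>/sweeps/<protocol>_s<k>.csv
                                    columns: time_s, voltage_mV, current_pA
      animals/<animal_id>/animal.json
      animals/<animal_id>/sessions/session<k>_trial<j>.csv
                                    columns: time_s, emg

Metadata round-trips bit-exactly (JSON, sorted keys); series round-trip to
the declared float precision (voltage/current 1e-4, EMG 1e-5).
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    MissingMetadataError,
    NativeFormatError,
    NonMonotonicTimeError,
    SeriesLengthMismatchError,
)
from .model import (
    FORMAT_VERSION,
    Animal,
    CellQC,
    CellRecord,
    Cohort,
    EMGTrial,
    Session,
    StimulusProtocol,
    Sweep,
)

SWEEP_FLOAT_FMT = "%.6f,%.4f,%.4f"   # time_s, voltage_mV, current_pA
TRIAL_FLOAT_FMT = "%.6f,%.5f"        # time_s, emg


def _require(d: dict, key: str, ctx: str):
    if key not in d:
        raise MissingMetadataError(f"{ctx}: missing required key {key!r}")
    return d[key]


def _dump_json(path: Path, obj: dict):
    path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def _load_json(path: Path) -> dict:
    if not path.is_file():
        raise MissingMetadataError(f"metadata file not found: {path}")
    return json.loads(path.read_text())


# --------------------------------------------------------------------- write
def write_native_cohort(cohort: Cohort, path) -> Path:
    """Write a cohort to ``path`` (created if needed). Deterministic bytes."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    index = {
        "format_version": cohort.format_version,
        "cells": [c.cell_id for c in cohort.cells],
        "animals": [a.animal_id for a in cohort.animals],
    }
    _dump_json(root / "cohort.json", index)
    for cell in cohort.cells:
        _write_cell(root, cell)
    for animal in cohort.animals:
        _write_animal(root, animal)
    return root


def _sweep_filename(protocol_name: str, sweep_index: int) -> str:
    return f"{protocol_name}_s{sweep_index}.csv"


def _write_cell(root: Path, cell: CellRecord):
    cdir = root / "cells" / cell.cell_id
    (cdir / "sweeps").mkdir(parents=True, exist_ok=True)
    protocols = {}
    manifest = []
    for pname in sorted(cell.sweeps):
        sweeps = cell.sweeps[pname]
        if sweeps:
            protocols[pname] = sweeps[0].protocol.to_dict()
        for sw in sweeps:
            fname = _sweep_filename(pname, sw.sweep_index)
            manifest.append({
                "protocol": pname,
                "sweep_index": sw.sweep_index,
                "file": f"sweeps/{fname}",
                "sample_rate_hz": sw.sample_rate_hz,
                "duration_s": sw.duration_s,
                "n_samples": sw.n_samples,
                "holding_mV": sw.holding_mV,
            })
            _write_sweep_csv(cdir / "sweeps" / fname, sw)
    meta = {
        "format_version": FORMAT_VERSION,
        "cell_id": cell.cell_id,
        "group": cell.group,
        "condition": cell.condition,
        "spontaneous_threshold_mV": cell.spontaneous_threshold_mV,
        "resting_potential_mV": cell.resting_potential_mV,
        "qc": cell.qc.to_dict() if cell.qc is not None else None,
        "protocols": protocols,
        "sweeps": manifest,
    }
    _dump_json(cdir / "cell.json", meta)


def _write_sweep_csv(path: Path, sw: Sweep):
    t = sw.time_s()
    with open(path, "w") as fh:
        fh.write("time_s,voltage_mV,current_pA\n")
        np.savetxt(fh, np.column_stack([t, sw.voltage_mV, sw.command_current_pA]),
                   fmt=SWEEP_FLOAT_FMT, delimiter=",")


def _write_animal(root: Path, animal: Animal):
    adir = root / "animals" / animal.animal_id
    (adir / "sessions").mkdir(parents=True, exist_ok=True)
    sessions_meta = []
    for sess in animal.sessions:
        trials_meta = []
        for j, tr in enumerate(sess.trials):
            fname = f"session{sess.session_index}_trial{j}.csv"
            trials_meta.append({
                "file": f"sessions/{fname}",
                "trial_type": tr.trial_type,
                "sample_rate_hz": tr.sample_rate_hz,
                "n_samples": len(tr.emg),
                "cs_onset_s": tr.cs_onset_s,
                "cs_duration_s": tr.cs_duration_s,
                "trace_duration_s": tr.trace_duration_s,
                "us_onset_s": tr.us_onset_s,
            })
            t = np.arange(len(tr.emg)) / tr.sample_rate_hz
            with open(adir / "sessions" / fname, "w") as fh:
                fh.write("time_s,emg\n")
                np.savetxt(fh, np.column_stack([t, tr.emg]),
                           fmt=TRIAL_FLOAT_FMT, delimiter=",")
        sessions_meta.append({
            "session_index": sess.session_index,
            "paradigm": sess.paradigm,
            "trials": trials_meta,
        })
    meta = {
        "format_version": FORMAT_VERSION,
        "animal_id": animal.animal_id,
        "group": animal.group,
        "paradigm": animal.paradigm,
        "sessions": sessions_meta,
    }
    _dump_json(adir / "animal.json", meta)


# ---------------------------------------------------------------------- read
def read_native_cohort(path) -> Cohort:
    """Read a cohort directory written by :func:`write_native_cohort`."""
    root = Path(path)
    index = _load_json(root / "cohort.json")
    _require(index, "format_version", "cohort.json")
    cells = [_read_cell(root, cid) for cid in _require(index, "cells", "cohort.json")]
    animals = [_read_animal(root, aid)
               for aid in _require(index, "animals", "cohort.json")]
    return Cohort(cells=cells, animals=animals,
                  format_version=index["format_version"])


def _read_series_csv(path: Path, columns, n_expected: int) -> list:
    if not path.is_file():
        raise NativeFormatError(f"series file not found: {path}")
    df = pd.read_csv(path)
    for col in columns:
        if col not in df.columns:
            raise NativeFormatError(f"{path}: missing column {col!r}")
    if len(df) != n_expected:
        raise SeriesLengthMismatchError(
            f"{path}: {len(df)} rows but metadata declares {n_expected}")
    t = df["time_s"].to_numpy()
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise NonMonotonicTimeError(f"{path}: time_s is not strictly increasing")
    return [df[c].to_numpy() for c in columns[1:]]


def _read_cell(root: Path, cell_id: str) -> CellRecord:
    cdir = root / "cells" / cell_id
    meta = _load_json(cdir / "cell.json")
    ctx = f"cells/{cell_id}/cell.json"
    protocols = {name: StimulusProtocol.from_dict(d)
                 for name, d in _require(meta, "protocols", ctx).items()}
    sweeps: dict = {}
    for entry in _require(meta, "sweeps", ctx):
        pname = _require(entry, "protocol", ctx)
        n = _require(entry, "n_samples", ctx)
        v, i = _read_series_csv(cdir / entry["file"],
                                ["time_s", "voltage_mV", "current_pA"], n)
        sw = Sweep(
            sample_rate_hz=_require(entry, "sample_rate_hz", ctx),
            voltage_mV=v, command_current_pA=i,
            protocol=protocols[pname],
            sweep_index=_require(entry, "sweep_index", ctx),
            duration_s=_require(entry, "duration_s", ctx),
            holding_mV=entry.get("holding_mV"),
        )
        sweeps.setdefault(pname, []).append(sw)
    qc_d = meta.get("qc")
    return CellRecord(
        cell_id=_require(meta, "cell_id", ctx),
        group=_require(meta, "group", ctx),
        spontaneous_threshold_mV=_require(meta, "spontaneous_threshold_mV", ctx),
        resting_potential_mV=_require(meta, "resting_potential_mV", ctx),
        condition=_require(meta, "condition", ctx),
        sweeps=sweeps,
        qc=CellQC.from_dict(qc_d) if qc_d else None,
    )


def _read_animal(root: Path, animal_id: str) -> Animal:
    adir = root / "animals" / animal_id
    meta = _load_json(adir / "animal.json")
    ctx = f"animals/{animal_id}/animal.json"
    sessions = []
    for sm in _require(meta, "sessions", ctx):
        trials = []
        for tm in _require(sm, "trials", ctx):
            (emg,) = _read_series_csv(adir / tm["file"], ["time_s", "emg"],
                                      _require(tm, "n_samples", ctx))
            trials.append(EMGTrial(
                sample_rate_hz=_require(tm, "sample_rate_hz", ctx),
                emg=emg,
                cs_onset_s=_require(tm, "cs_onset_s", ctx),
                trial_type=_require(tm, "trial_type", ctx),
                cs_duration_s=tm.get("cs_duration_s", 0.250),
                trace_duration_s=tm.get("trace_duration_s", 0.500),
                us_onset_s=tm.get("us_onset_s"),
            ))
        sessions.append(Session(
            session_index=_require(sm, "session_index", ctx),
            trials=trials,
            paradigm=_require(sm, "paradigm", ctx),
        ))
    return Animal(animal_id=_require(meta, "animal_id", ctx),
                  group=_require(meta, "group", ctx),
                  paradigm=_require(meta, "paradigm", ctx),
                  sessions=sessions)
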