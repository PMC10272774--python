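"""Session CSV / JSON serialization.

A recording is stored as one CSV with a sampling-rate header comment and
columns ``time, ch1..chm, Ax, Ay, Az``; synthetic protocols additionally
write a JSON sidecar per recording with the generating ground truth, and
a protocol manifest.  Decompositions serialize to JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .decompose import SynergyDecomposition
from .errors import DataError
from .kinematics import AccelTrace
from .preprocess import EnvelopeMatrix
from .synthetic import GroundTruth, Recording, SessionSet

_RATE_PREFIX = "# sampling_rate_hz:"


def write_session(path, emg: EnvelopeMatrix, accel: AccelTrace | None = None):
    path = Path(path)
    n = emg.n
    data = {"time": np.arange(n) / emg.sampling_rate}
    for name, row in zip(emg.channel_names, emg.values):
        data[name] = row
    if accel is not None:
        if accel.n != n:
            raise DataError("EMG and accelerometer lengths differ")
        data["Ax"], data["Ay"], data["Az"] = accel.ax, accel.ay, accel.az
    frame = pd.DataFrame(data)
    with open(path, "w") as fh:
        fh.write(f"{_RATE_PREFIX} {emg.sampling_rate}\n")
        if accel is not None and accel.g_ref is not None:
            fh.write(f"# g_ref: {accel.g_ref}\n")
        frame.to_csv(fh, index=False, float_format="%.10g")


@dataclass
class RawSession:
    """Unvalidated signal matrix for data that is not yet an envelope
    (raw sEMG may be negative)."""

    values: np.ndarray
    sampling_rate: float
    channel_names: list[str]


def read_session(path, raw: bool = False):
    """Load a session CSV.

    Returns ``(EnvelopeMatrix, AccelTrace | None)``; with ``raw=True``
    the EMG columns are returned as a :class:`RawSession` without the
    envelope non-negativity validation.
    """
    path = Path(path)
    sampling_rate = None
    g_ref = None
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            if line.startswith(_RATE_PREFIX):
                sampling_rate = float(line.split(":", 1)[1])
            elif line.startswith("# g_ref:"):
                g_ref = float(line.split(":", 1)[1])
    if sampling_rate is None:
        raise DataError(f"{path}: missing '{_RATE_PREFIX}' header")
    frame = pd.read_csv(path, skiprows=skip)
    accel_cols = [c for c in ("Ax", "Ay", "Az") if c in frame.columns]
    channels = [c for c in frame.columns if c not in ("time", *accel_cols)]
    values = frame[channels].to_numpy().T
    if raw:
        emg = RawSession(values, sampling_rate, channels)
    else:
        emg = EnvelopeMatrix(values, sampling_rate, channels)
    accel = None
    if len(accel_cols) == 3:
        accel = AccelTrace(
            frame["Ax"].to_numpy(),
            frame["Ay"].to_numpy(),
            frame["Az"].to_numpy(),
            sampling_rate,
            g_ref=g_ref,
        )
    return emg, accel


def _truth_to_dict(t: GroundTruth) -> dict:
    return {
        "C_true": t.C_true.tolist(),
        "S_true": t.S_true.tolist(),
        "angle_true": t.angle_true.tolist(),
        "day_gains": t.day_gains.tolist(),
        "day_c_offsets": t.day_c_offsets.tolist(),
        "noise_sigma": t.noise_sigma,
        "n_cycles": t.n_cycles,
        "samples_per_cycle": t.samples_per_cycle,
        "sampling_rate": t.sampling_rate,
        "g_ref": t.g_ref,
    }


def _truth_from_dict(d: dict) -> GroundTruth:
    return GroundTruth(
        C_true=np.asarray(d["C_true"]),
        S_true=np.asarray(d["S_true"]),
        angle_true=np.asarray(d["angle_true"]),
        day_gains=np.asarray(d["day_gains"]),
        day_c_offsets=np.asarray(d["day_c_offsets"]),
        noise_sigma=d["noise_sigma"],
        n_cycles=d["n_cycles"],
        samples_per_cycle=d["samples_per_cycle"],
        sampling_rate=d["sampling_rate"],
        g_ref=d["g_ref"],
    )


def _rec_stem(rec: Recording) -> str:
    return f"sub{rec.subject:02d}_day{rec.day}_set{rec.set_index}"


def write_protocol(session_set: SessionSet, out_dir):
    """One CSV + ground-truth JSON per recording, plus protocol.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "sampling_rate": session_set.sampling_rate,
        "group_labels": session_set.group_labels,
        "recordings": [],
    }
    for rec in session_set.recordings:
        stem = _rec_stem(rec)
        write_session(out_dir / f"{stem}.csv", rec.emg, rec.accel)
        with open(out_dir / f"{stem}.truth.json", "w") as fh:
            json.dump(_truth_to_dict(rec.truth), fh)
        manifest["recordings"].append(
            {
                "subject": rec.subject,
                "day": rec.day,
                "set": rec.set_index,
                "group": rec.group,
                "file": f"{stem}.csv",
            }
        )
    with open(out_dir / "protocol.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def read_protocol(in_dir) -> SessionSet:
    in_dir = Path(in_dir)
    with open(in_dir / "protocol.json") as fh:
        manifest = json.load(fh)
    recordings = []
    for entry in manifest["recordings"]:
        emg, accel = read_session(in_dir / entry["file"])
        truth_path = in_dir / entry["file"].replace(".csv", ".truth.json")
        with open(truth_path) as fh:
            truth = _truth_from_dict(json.load(fh))
        recordings.append(
            Recording(
                entry["subject"], entry["day"], entry["set"],
                emg, accel, entry["group"], truth,
            )
        )
    return SessionSet(recordings, manifest["sampling_rate"])


def decomposition_to_json(dec: SynergyDecomposition) -> dict:
    out = {
        "C": dec.C.tolist(),
        "S": dec.S.tolist(),
        "method": dec.method,
        "r": dec.r,
        "n_iter": dec.n_iter,
        "objective_trace": np.asarray(dec.objective_trace).tolist(),
        "vaf": dec.vaf,
        "converged": dec.converged,
        "notes": dec.notes,
    }
    if dec.mean is not None:
        out["mean"] = dec.mean.tolist()
    return out


def decomposition_from_json(d: dict) -> SynergyDecomposition:
    return SynergyDecomposition(
        C=np.asarray(d["C"]),
        S=np.asarray(d["S"]),
        method=d["method"],
        r=d["r"],
        n_iter=d["n_iter"],
        objective_trace=np.asarray(d["objective_trace"]),
        vaf=d["vaf"],
        mean=np.asarray(d["mean"]) if "mean" in d else None,
        converged=d.get("converged", True),
        notes=list(d.get("notes", [])),
    )
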