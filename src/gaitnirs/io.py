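"""File I/O: SNIRF (HDF5) and flat-CSV recordings, clinical tables, β-maps.

SNIRF files follow the v1.0 layout (``/formatVersion``, ``/nirs/data1`` with
``dataTimeSeries``/``time``/``measurementList``, ``/nirs/probe``,
``/nirs/stim1`` and ``/nirs/metaDataTags``) so that third-party readers can
open them; the full montage/paradigm payload additionally round-trips through
a custom ``gaitnirsMeta`` metadata tag.  The CSV dialect is long-format
``time,channel,wavelength,intensity`` with a JSON sidecar for metadata.
Intensity units are arbitrary (relative CW counts); concentrations are µM;
optode coordinates are schematic millimetres.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .glm import BetaMap
from .montage import Montage
from .paradigm import Paradigm
from .recording import Recording
from .stats import ClinicalRecord

__all__ = [
    "write_snirf",
    "read_snirf",
    "write_recording_csv",
    "read_recording_csv",
    "read_recording",
    "write_recording",
    "write_clinical_csv",
    "read_clinical_csv",
    "write_ground_truth",
    "read_ground_truth",
    "betamaps_to_frame",
    "write_betamaps",
    "read_betamaps",
]


def _meta_payload(rec: Recording) -> str:
    return json.dumps(
        {
            "montage": rec.montage.to_dict(),
            "paradigm": rec.paradigm.to_dict(),
            "fs": rec.fs,
            "wavelengths": list(rec.wavelengths),
            "subject": rec.subject,
            "session": rec.session,
            "meta": rec.meta,
        }
    )


def _str_ds(group: h5py.Group, name: str, value: str) -> None:
    group.create_dataset(name, data=np.bytes_(value))


def write_snirf(recording: Recording, path: str | Path) -> Path:
    """Write a recording as a SNIRF v1.0 HDF5 file."""
    path = Path(path)
    rec = recording
    n, n_ch, n_wl = rec.intensity.shape
    src_labels = list(rec.montage.sources)
    det_labels = list(rec.montage.detectors)
    with h5py.File(path, "w") as f:
        _str_ds(f, "formatVersion", "1.0")
        nirs = f.create_group("nirs")
        tags = nirs.create_group("metaDataTags")
        _str_ds(tags, "SubjectID", rec.subject)
        _str_ds(tags, "MeasurementDate", "2022-01-01")
        _str_ds(tags, "MeasurementTime", "00:00:00")
        _str_ds(tags, "LengthUnit", "mm")
        _str_ds(tags, "TimeUnit", "s")
        _str_ds(tags, "FrequencyUnit", "Hz")
        _str_ds(tags, "Session", rec.session)
        _str_ds(tags, "gaitnirsMeta", _meta_payload(rec))

        data = nirs.create_group("data1")
        # column k = channel c, wavelength w with k = 2c + w
        data.create_dataset(
            "dataTimeSeries", data=rec.intensity.reshape(n, n_ch * n_wl)
        )
        data.create_dataset("time", data=rec.time)
        for c, ch in enumerate(rec.montage.channels):
            for w in range(n_wl):
                ml = data.create_group(f"measurementList{c * n_wl + w + 1}")
                ml.create_dataset(
                    "sourceIndex", data=src_labels.index(ch.source) + 1, dtype="i4"
                )
                ml.create_dataset(
                    "detectorIndex", data=det_labels.index(ch.detector) + 1, dtype="i4"
                )
                ml.create_dataset("wavelengthIndex", data=w + 1, dtype="i4")
                ml.create_dataset("dataType", data=1, dtype="i4")  # CW amplitude
                ml.create_dataset("dataTypeIndex", data=1, dtype="i4")

        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(rec.wavelengths, dtype=float))
        probe.create_dataset(
            "sourcePos3D",
            data=np.array([[*rec.montage.sources[s], 0.0] for s in src_labels]),
        )
        probe.create_dataset(
            "detectorPos3D",
            data=np.array([[*rec.montage.detectors[d], 0.0] for d in det_labels]),
        )
        probe.create_dataset(
            "sourceLabels", data=np.array([np.bytes_(s) for s in src_labels])
        )
        probe.create_dataset(
            "detectorLabels", data=np.array([np.bytes_(d) for d in det_labels])
        )

        stim = nirs.create_group("stim1")
        _str_ds(stim, "name", "active")
        onsets = np.asarray(rec.paradigm.block_onsets, dtype=float)
        stim.create_dataset(
            "data",
            data=np.column_stack(
                [onsets, np.full_like(onsets, rec.paradigm.active_duration), np.ones_like(onsets)]
            ),
        )
    return path


def read_snirf(path: str | Path) -> Recording:
    """Read a SNIRF file written by :func:`write_snirf` back into a Recording."""
    path = Path(path)
    try:
        with h5py.File(path, "r") as f:
            if "nirs" not in f or "data1" not in f["nirs"]:
                raise ValueError(f"{path}: not a SNIRF file (missing /nirs/data1)")
            tags = f["nirs/metaDataTags"]
            if "gaitnirsMeta" not in tags:
                raise ValueError(f"{path}: missing gaitnirsMeta tag; foreign SNIRF files are out of scope")
            meta = json.loads(tags["gaitnirsMeta"][()].decode())
            series = f["nirs/data1/dataTimeSeries"][()]
    except OSError as exc:
        raise ValueError(f"{path}: malformed or truncated HDF5 file ({exc})") from exc
    montage = Montage.from_dict(meta["montage"])
    n_wl = len(meta["wavelengths"])
    n = series.shape[0]
    if series.shape[1] != montage.n_channels * n_wl:
        raise ValueError(
            f"{path}: dataTimeSeries has {series.shape[1]} columns, expected "
            f"{montage.n_channels * n_wl}"
        )
    return Recording(
        montage=montage,
        paradigm=Paradigm.from_dict(meta["paradigm"]),
        fs=meta["fs"],
        intensity=series.reshape(n, montage.n_channels, n_wl),
        wavelengths=tuple(meta["wavelengths"]),
        subject=meta["subject"],
        session=meta["session"],
        meta=meta["meta"],
    )


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_recording_csv(recording: Recording, path: str | Path) -> Path:
    """Long-format CSV (time, channel, wavelength, intensity) + JSON sidecar."""
    path = Path(path)
    n, n_ch, n_wl = recording.intensity.shape
    t = np.repeat(recording.time, n_ch * n_wl)
    ch = np.tile(np.repeat(np.arange(1, n_ch + 1), n_wl), n)
    wl = np.tile(np.asarray(recording.wavelengths), n_ch * n)
    pd.DataFrame(
        {
            "time": t,
            "channel": ch,
            "wavelength": wl,
            "intensity": recording.intensity.reshape(-1),
        }
    ).to_csv(path, index=False)
    _sidecar(path).write_text(_meta_payload(recording))
    return path


def read_recording_csv(path: str | Path) -> Recording:
    path = Path(path)
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise ValueError(f"{path}: missing metadata sidecar {sidecar.name}")
    meta = json.loads(sidecar.read_text())
    df = pd.read_csv(path)
    required = {"time", "channel", "wavelength", "intensity"}
    if set(df.columns) != required:
        raise ValueError(f"{path}: expected columns {sorted(required)}, got {list(df.columns)}")
    montage = Montage.from_dict(meta["montage"])
    n_wl = len(meta["wavelengths"])
    n_ch = montage.n_channels
    if len(df) % (n_ch * n_wl) != 0:
        raise ValueError(
            f"{path}: {len(df)} rows is not a multiple of channels x wavelengths "
            f"({n_ch} x {n_wl}); file truncated?"
        )
    n = len(df) // (n_ch * n_wl)
    intensity = df["intensity"].to_numpy().reshape(n, n_ch, n_wl)
    return Recording(
        montage=montage,
        paradigm=Paradigm.from_dict(meta["paradigm"]),
        fs=meta["fs"],
        intensity=intensity,
        wavelengths=tuple(meta["wavelengths"]),
        subject=meta["subject"],
        session=meta["session"],
        meta=meta["meta"],
    )


def write_recording(recording: Recording, path: str | Path, format: str = "snirf") -> Path:
    if format == "snirf":
        return write_snirf(recording, path)
    if format == "csv":
        return write_recording_csv(recording, path)
    raise ValueError(f"unknown format {format!r} (expected 'snirf' or 'csv')")


def read_recording(path: str | Path, format: str = "snirf") -> Recording:
    if format == "snirf":
        return read_snirf(path)
    if format == "csv":
        return read_recording_csv(path)
    raise ValueError(f"unknown format {format!r} (expected 'snirf' or 'csv')")


_MAS_JOINTS = ("hip", "knee", "ankle")


def write_clinical_csv(records: list[ClinicalRecord], path: str | Path) -> Path:
    """Clinical table: subject, gmfcs, gmfm88_<session>, mas_<joint>_<session>."""
    path = Path(path)
    rows = []
    for r in records:
        row: dict[str, object] = {"subject": r.subject, "gmfcs": r.gmfcs}
        for sess, v in r.gmfm88.items():
            row[f"gmfm88_{sess}"] = v
        if r.mas:
            for joint in _MAS_JOINTS:
                for sess, v in r.mas.get(joint, {}).items():
                    row[f"mas_{joint}_{sess}"] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_clinical_csv(path: str | Path) -> list[ClinicalRecord]:
    df = pd.read_csv(path)
    if "subject" not in df.columns or "gmfcs" not in df.columns:
        raise ValueError(f"{path}: clinical table needs 'subject' and 'gmfcs' columns")
    out = []
    for _, row in df.iterrows():
        gmfm = {
            c.removeprefix("gmfm88_"): float(row[c])
            for c in df.columns
            if c.startswith("gmfm88_") and pd.notna(row[c])
        }
        mas: dict[str, dict[str, float]] = {}
        for c in df.columns:
            if c.startswith("mas_") and pd.notna(row[c]):
                _, joint, sess = c.split("_", 2)
                mas.setdefault(joint, {})[sess] = float(row[c])
        out.append(
            ClinicalRecord(
                subject=str(row["subject"]),
                gmfcs=int(row["gmfcs"]),
                gmfm88=gmfm,
                mas=mas or None,
            )
        )
    return out


def write_ground_truth(truths: dict, path: str | Path) -> Path:
    """Ground-truth sidecar: JSON keyed by subject."""
    path = Path(path)
    payload = {}
    for subject, t in truths.items():
        payload[subject] = {
            "beta_hbo": t.beta_hbo.tolist(),
            "superficial_gain": t.superficial_gain.tolist(),
            "hhb_ratio": t.hhb_ratio,
            "noise_sd": t.noise_sd,
            "age": t.age,
        }
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_ground_truth(path: str | Path) -> dict:
    from .synthetic import GroundTruth

    payload = json.loads(Path(path).read_text())
    return {
        s: GroundTruth(
            beta_hbo=np.asarray(d["beta_hbo"]),
            superficial_gain=np.asarray(d["superficial_gain"]),
            hhb_ratio=d["hhb_ratio"],
            noise_sd=d["noise_sd"],
            age=d["age"],
        )
        for s, d in payload.items()
    }


def betamaps_to_frame(betamaps: list[BetaMap]) -> pd.DataFrame:
    """Tidy interchange frame: subject, session, channel, chromophore, beta, se."""
    return pd.DataFrame([r for m in betamaps for r in m.to_records()])


def write_betamaps(betamaps: list[BetaMap], path: str | Path) -> Path:
    path = Path(path)
    betamaps_to_frame(betamaps).to_csv(path, index=False)
    return path


def read_betamaps(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject", "session", "channel", "chromophore", "beta"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: β table needs columns {sorted(required)}")
    return df
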