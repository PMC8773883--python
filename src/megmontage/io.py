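"""Serialization glue: lead fields and recordings to HDF5 with JSON
sidecars, report tables to CSV, and optional ingestion from FIF files."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .geometry import (
    MAGNETOMETER,
    PLANAR_GRADIOMETER,
    DEFAULT_GRAD_BASELINE,
    DEFAULT_GRAD_NOISE_SD,
    DEFAULT_MAG_NOISE_SD,
    SensorArray,
    SensorChannel,
    SphereModel,
)
from .forward import LeadField
from .simulate import Recording

__all__ = [
    "save_leadfield",
    "load_leadfield",
    "save_recording",
    "load_recording",
    "sensor_array_from_fif",
    "recording_from_fif",
    "recording_to_fif",
]


def save_leadfield(lf: LeadField, path: str | Path) -> None:
    """Lead field to HDF5 (matrix) + JSON sidecar (labels, units, sphere)."""
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("matrix", data=lf.matrix)
    sidecar = {
        "row_channels": lf.row_channels,
        "col_components": [list(c) for c in lf.col_components],
        "units": "T/(A·m) magnetometer rows, T/m/(A·m) gradiometer rows",
        "sphere_center_m": lf.sphere.center.tolist(),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def load_leadfield(path: str | Path) -> LeadField:
    import h5py

    path = Path(path)
    with h5py.File(path, "r") as f:
        matrix = f["matrix"][()]
    d = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return LeadField(
        matrix=matrix,
        row_channels=d["row_channels"],
        col_components=[tuple(c) for c in d["col_components"]],
        sphere=SphereModel(center=d["sphere_center_m"]),
    )


def save_recording(rec: Recording, path: str | Path) -> None:
    """Recording to HDF5 (data) + JSON sidecar (fs, array, annotations)."""
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data)
    sidecar = {
        "fs": rec.fs,
        "annotations": rec.annotations,
        "array": json.loads(rec.array.to_json()),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def load_recording(path: str | Path) -> Recording:
    import h5py

    path = Path(path)
    with h5py.File(path, "r") as f:
        data = f["data"][()]
    d = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return Recording(
        data=data,
        fs=d["fs"],
        array=SensorArray.from_json(json.dumps(d["array"])),
        annotations=d.get("annotations", {}),
    )


# --------------------------------------------------------------------------
# FIF ingestion (optional; requires mne)

def _channels_from_info(info) -> list[SensorChannel]:
    from mne.io.constants import FIFF

    channels = []
    for ch in info["chs"]:
        loc = np.asarray(ch["loc"], dtype=float)
        pos = loc[:3]
        ex, ez = loc[3:6], loc[9:12]
        if ch["coil_type"] in (
            FIFF.FIFFV_COIL_VV_MAG_W,
            FIFF.FIFFV_COIL_VV_MAG_T1,
            FIFF.FIFFV_COIL_VV_MAG_T2,
            FIFF.FIFFV_COIL_VV_MAG_T3,
            FIFF.FIFFV_COIL_POINT_MAGNETOMETER,
        ):
            channels.append(
                SensorChannel(
                    name=ch["ch_name"],
                    position=pos,
                    orientation=ez / np.linalg.norm(ez),
                    kind=MAGNETOMETER,
                    noise_sd=DEFAULT_MAG_NOISE_SD,
                )
            )
        elif ch["coil_type"] in (
            FIFF.FIFFV_COIL_VV_PLANAR_W,
            FIFF.FIFFV_COIL_VV_PLANAR_T1,
            FIFF.FIFFV_COIL_VV_PLANAR_T2,
            FIFF.FIFFV_COIL_VV_PLANAR_T3,
        ):
            channels.append(
                SensorChannel(
                    name=ch["ch_name"],
                    position=pos,
                    orientation=ex / np.linalg.norm(ex),
                    kind=PLANAR_GRADIOMETER,
                    noise_sd=DEFAULT_GRAD_NOISE_SD,
                    baseline=DEFAULT_GRAD_BASELINE,
                    field_axis=ez / np.linalg.norm(ez),
                )
            )
    if not channels:
        raise ValueError("no MEG channels found in the FIF info block")
    return channels


def sensor_array_from_fif(source) -> SensorArray:
    """SensorArray from a FIF file path or an mne ``Info`` object.

    Magnetometer orientation comes from the coil normal (loc[9:12]);
    planar-gradiometer differencing axes from the coil x-axis (loc[3:6]).
    Channel noise SDs default to the standard per-kind values.
    """
    import mne

    info = source if isinstance(source, mne.Info) else mne.io.read_info(source, verbose="error")
    return SensorArray(channels=_channels_from_info(info), frame="device")


def recording_to_fif(rec: Recording, path: str | Path) -> None:
    """Export a recording's channels to a raw FIF file (requires mne).

    Channel positions go to loc[:3]; the differencing axis (gradiometers)
    to the coil x-axis loc[3:6] and the field axis to the coil normal
    loc[9:12], mirroring :func:`sensor_array_from_fif`.
    """
    import mne

    ch_types = [
        "mag" if c.kind == MAGNETOMETER else "grad" for c in rec.array.channels
    ]
    info = mne.create_info(rec.array.names, rec.fs, ch_types=ch_types)
    with info._unlock():
        for ch, chan in zip(info["chs"], rec.array.channels):
            loc = np.zeros(12)
            loc[:3] = chan.position
            if chan.kind == MAGNETOMETER:
                loc[9:12] = chan.orientation
                loc[3:6] = _any_orthonormal(chan.orientation)
            else:
                loc[3:6] = chan.orientation
                loc[9:12] = chan.field_axis
            loc[6:9] = np.cross(loc[9:12], loc[3:6])
            ch["loc"] = loc
    raw = mne.io.RawArray(rec.data, info, verbose="error")
    raw.save(path, overwrite=True, verbose="error")


def _any_orthonormal(v: np.ndarray) -> np.ndarray:
    helper = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    out = np.cross(v, helper)
    return out / np.linalg.norm(out)


def recording_from_fif(path: str | Path) -> Recording:
    """Load a raw FIF recording's MEG channels into a Recording."""
    import mne

    raw = mne.io.read_raw_fif(path, preload=True, verbose="error")
    array = sensor_array_from_fif(raw.info)
    picks = [raw.ch_names.index(n) for n in array.names]
    return Recording(
        data=raw.get_data()[picks],
        fs=float(raw.info["sfreq"]),
        array=array,
        annotations={"kind": "fif", "path": str(path)},
    )
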