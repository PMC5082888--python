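"""File formats: intensity CSV, minimal SNIRF subset, tidy TSV outputs.

The intensity CSV is long-format (``time_s, channel, wavelength_nm,
intensity``) where ``channel`` is a physical pair label.  SNIRF support is
a minimal conformant subset for continuous-wave amplitude data
(``/nirs1/data1`` with a measurementList and probe wavelengths), not the
full specification.  Every TSV output carries the package version and a
configuration hash in a header comment so reruns are verifiable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigError, DataError
from .recording import IntensityRecording


def config_hash(config: dict) -> str:
    """Stable short hash of a (JSON-serializable) configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


def output_header(config: dict | None = None) -> str:
    h = config_hash(config or {})
    return f"# nirsbundle {__version__}  config_hash={h}\n"


def write_tsv(frame: pd.DataFrame, path, config: dict | None = None, float_format="%.10g") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(output_header(config))
        frame.to_csv(fh, sep="\t", index=False, float_format=float_format)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# intensity CSV

def write_intensity_csv(recording: IntensityRecording, path) -> None:
    frame = recording.to_frame()
    frame.to_csv(path, index=False, float_format="%.12g")


def read_intensity_csv(path, i_in: float = 1.0) -> IntensityRecording:
    try:
        frame = pd.read_csv(path)
    except Exception as exc:
        raise DataError(f"{path}: unreadable intensity CSV ({exc})") from exc
    return IntensityRecording.from_frame(frame, i_in=i_in)


# ---------------------------------------------------------------------------
# minimal SNIRF subset (continuous-wave amplitude)

def write_snirf(recording: IntensityRecording, path) -> None:
    labels = sorted(recording.data)
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs1")
        data1 = nirs.create_group("data1")
        cols = []
        ml_index = 0
        for label in labels:
            for w, _wl in enumerate(recording.wavelengths):
                cols.append(recording.data[label][:, w])
                ml_index += 1
                ml = data1.create_group(f"measurementList{ml_index}")
                ml.create_dataset("sourceIndex", data=np.int32(1))
                ml.create_dataset("detectorIndex", data=np.int32(ml_index))
                ml.create_dataset("wavelengthIndex", data=np.int32(w + 1))
                ml.create_dataset("dataType", data=np.int32(1))  # CW amplitude
                ml.create_dataset("channelLabel", data=label)
        data1.create_dataset("dataTimeSeries", data=np.column_stack(cols))
        data1.create_dataset("time", data=recording.time_s)
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(recording.wavelengths))


def read_snirf(path, i_in: float = 1.0) -> IntensityRecording:
    with h5py.File(path, "r") as f:
        if "nirs1/data1" not in f:
            raise DataError(f"{path}: /nirs1/data1 missing (not a supported SNIRF subset)")
        data1 = f["nirs1/data1"]
        time = np.asarray(data1["time"])
        series = np.asarray(data1["dataTimeSeries"])
        wavelengths = tuple(float(w) for w in np.asarray(f["nirs1/probe/wavelengths"]))
        n_ml = series.shape[1]
        data: dict[str, np.ndarray] = {}
        for m in range(1, n_ml + 1):
            ml = data1[f"measurementList{m}"]
            label = ml["channelLabel"][()]
            label = label.decode() if isinstance(label, bytes) else str(label)
            w = int(np.asarray(ml["wavelengthIndex"])) - 1
            arr = data.setdefault(label, np.full((time.size, len(wavelengths)), np.nan))
            arr[:, w] = series[:, m - 1]
    for label, arr in data.items():
        if np.any(np.isnan(arr)):
            raise DataError(f"pair {label!r}: missing wavelength column in SNIRF file")
    dt = np.diff(time)
    if time.size < 2 or np.any(dt <= 0):
        raise DataError("non-monotone or too-short SNIRF time vector")
    fs = 1.0 / float(np.median(dt))
    return IntensityRecording(
        time_s=time, wavelengths=wavelengths, data=data, fs_hz=fs, i_in=i_in
    )


def read_intensity(path, i_in: float = 1.0) -> IntensityRecording:
    """Dispatch on extension: .csv -> long CSV, .snirf/.h5 -> SNIRF subset."""
    suffix = Path(path).suffix.lower()
    if suffix == ".csv":
        return read_intensity_csv(path, i_in=i_in)
    if suffix in (".snirf", ".h5", ".hdf5"):
        return read_snirf(path, i_in=i_in)
    raise ConfigError(f"{path}: unknown intensity format {suffix!r}")


# ---------------------------------------------------------------------------
# concentration / stats exports

def concentrations_frame(conc: dict) -> pd.DataFrame:
    rows = []
    for cid in sorted(conc):
        cs = conc[cid]
        rows.append(
            pd.DataFrame(
                {
                    "time_s": cs.time,
                    "channel": cid,
                    "C_HbO_uM": cs.hbo,
                    "C_HbR_uM": cs.hbr,
                    "mode": cs.mode,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
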