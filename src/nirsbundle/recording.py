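"""In-memory container for dual-wavelength intensity recordings."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError


@dataclass
class IntensityRecording:
    """Detected light intensities per physical emitter-detector pair.

    ``data[pair_label]`` is a (T, W) array over ``wavelengths``; pair labels
    follow the layout convention ("B<k>S" for bundle k's short pair, "C<i>"
    for gradient channel i's long pair).  ``i_in`` is the common incident
    intensity reference.
    """

    time_s: np.ndarray
    wavelengths: tuple[float, ...]
    data: dict[str, np.ndarray]
    fs_hz: float
    i_in: float = 1.0

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        n = self.time_s.size
        for label, arr in self.data.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (n, len(self.wavelengths)):
                raise DataError(
                    f"pair {label}: expected shape {(n, len(self.wavelengths))}, got {arr.shape}"
                )
            self.data[label] = arr

    @property
    def n_samples(self) -> int:
        return self.time_s.size

    def intensity(self, pair_label: str, wavelength_nm: float) -> np.ndarray:
        try:
            col = self.wavelengths.index(wavelength_nm)
        except ValueError:
            raise DataError(f"wavelength {wavelength_nm} nm not in recording") from None
        if pair_label not in self.data:
            raise DataError(f"unknown pair {pair_label!r}")
        return self.data[pair_label][:, col]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: time_s, channel, wavelength_nm, intensity."""
        rows = []
        for label in sorted(self.data):
            arr = self.data[label]
            for w, wl in enumerate(self.wavelengths):
                rows.append(
                    pd.DataFrame(
                        {
                            "time_s": self.time_s,
                            "channel": label,
                            "wavelength_nm": wl,
                            "intensity": arr[:, w],
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, i_in: float = 1.0) -> "IntensityRecording":
        required = {"time_s", "channel", "wavelength_nm", "intensity"}
        missing = required - set(frame.columns)
        if missing:
            raise DataError(f"intensity table missing columns: {sorted(missing)}")
        wavelengths = tuple(sorted(frame["wavelength_nm"].unique()))
        if len(wavelengths) < 2:
            raise DataError(
                f"dual-wavelength recording requires >= 2 wavelengths, found {list(wavelengths)}"
            )
        labels = sorted(frame["channel"].unique())
        time = None
        data = {}
        for label in labels:
            sub = frame[frame["channel"] == label]
            cols = []
            for wl in wavelengths:
                s = sub[sub["wavelength_nm"] == wl].sort_values("time_s")
                if s.empty:
                    raise DataError(f"pair {label!r}: missing wavelength {wl} nm")
                if time is None:
                    time = s["time_s"].to_numpy()
                elif s.shape[0] != time.size:
                    raise DataError(f"pair {label!r}: inconsistent sample count")
                cols.append(s["intensity"].to_numpy())
            data[str(label)] = np.column_stack(cols)
        if time is None or time.size < 2:
            raise DataError("intensity table too short (need >= 2 samples)")
        dt = np.diff(time)
        if np.any(dt <= 0):
            bad = int(np.argmax(dt <= 0)) + 1
            raise DataError(f"non-monotone timestamps (first offending sample {bad})")
        med = float(np.median(dt))
        dev = np.abs(dt - med) / med
        if np.any(dev > 0.01):
            bad = int(np.argmax(dev > 0.01)) + 1
            raise DataError(
                f"irregular timestamps beyond 1% tolerance (first offending sample {bad})"
            )
        fs = 1.0 / med
        for label, arr in data.items():
            if np.any(arr <= 0):
                raise DataError(f"pair {label!r}: non-positive intensities")
        return cls(time_s=time, wavelengths=wavelengths, data=data, fs_hz=fs, i_in=i_in)
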