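"""Photon-transport arithmetic for continuous-wave dual-wavelength NIRS.

Forward model: light of wavelength λ traversing an emitter-detector path of
length l is attenuated as I_out = I_in·exp(−μ(t,λ)·l), with
μ = μ_a(t,λ) + μ_s(λ).  The scattering coefficient is taken constant in
space and linear in wavelength, μ_s(λ) = γ1·(1 − γ2·λ).  The absorption
coefficient is the extinction-weighted sum of the hemoglobin species,
μ_a = a_HbO(λ)·C_HbO(t) + a_HbR(λ)·C_HbR(t).

The bundled-optode estimator approximates μ by the *spatial absorbance
gradient* between a long and a short emitter-detector pair of the same
bundle, g(t,λ) = (A_long − A_short)/δl.  Because any additive absorbance
component common to both pairs (superficial/scalp signal) cancels in the
difference, the gradient isolates the shared tissue attenuation.  Solving
the two-wavelength system

    g(t,λk) − μ_s(λk) = a_HbO(λk)·C_HbO(t) + a_HbR(λk)·C_HbR(t)

for the two concentrations yields *absolute* C_HbO(t), C_HbR(t) in μM.

The conventional modified Beer-Lambert law (MBLL) baseline is also
provided: it converts single-channel attenuation *changes* into
concentration *changes* via a differential pathlength factor, and is the
comparison method throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .errors import ConfigError, DataError, GeometryError

log = logging.getLogger(__name__)

DEFAULT_WAVELENGTHS = (760.0, 830.0)


@dataclass(frozen=True)
class OpticalModelParams:
    """Scattering-model constants and operating wavelengths.

    gamma1 (mm⁻¹) and gamma2 (nm⁻¹) parameterize μ_s(λ) = γ1·(1 − γ2·λ);
    the defaults are standard adult-head values.
    """

    gamma1: float = 1.45
    gamma2: float = 4.5e-4
    wavelengths: tuple[float, ...] = DEFAULT_WAVELENGTHS

    def __post_init__(self) -> None:
        if self.gamma1 <= 0:
            raise ConfigError("gamma1 must be > 0")
        for wl in self.wavelengths:
            if not (0 <= self.gamma2 * wl < 1):
                raise ConfigError(
                    f"gamma2*lambda = {self.gamma2 * wl:.4g} outside [0, 1) "
                    f"at {wl} nm: scattering coefficient would be <= 0"
                )


def scattering_coefficient(wavelength_nm: float, params: OpticalModelParams) -> float:
    """μ_s(λ) = γ1·(1 − γ2·λ), in mm⁻¹."""
    mus = params.gamma1 * (1.0 - params.gamma2 * wavelength_nm)
    if mus <= 0:
        raise ConfigError(f"mu_s({wavelength_nm} nm) = {mus:.4g} <= 0")
    return mus


@dataclass(frozen=True)
class ExtinctionTable:
    """Hemoglobin extinction coefficients per wavelength, mm⁻¹·μM⁻¹ (ln base).

    ``eps`` rows follow ``wavelengths``; columns are (HbO, HbR).  The 2x2
    matrix must be invertible for the two-wavelength system to be solvable;
    its condition number is reported in error messages and logs.
    """

    wavelengths: tuple[float, ...]
    eps: tuple[tuple[float, float], ...]
    source: str = "unspecified"

    def __post_init__(self) -> None:
        if len(self.eps) != len(self.wavelengths):
            raise ConfigError("one (eps_HbO, eps_HbR) row per wavelength required")

    @property
    def matrix(self) -> np.ndarray:
        return np.asarray(self.eps, dtype=float)

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix))

    def eps_for(self, wavelength_nm: float) -> tuple[float, float]:
        for wl, row in zip(self.wavelengths, self.eps):
            if abs(wl - wavelength_nm) < 0.5:
                return row
        raise ConfigError(f"no extinction entry for {wavelength_nm} nm")

    @classmethod
    def from_tsv(cls, path) -> "ExtinctionTable":
        wls, rows = [], []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line.startswith("wavelength"):
                    continue
                wl, hbo, hbr = line.split("\t")
                wls.append(float(wl))
                rows.append((float(hbo), float(hbr)))
        return cls(wavelengths=tuple(wls), eps=tuple(rows), source=str(path))

    @classmethod
    def default(cls) -> "ExtinctionTable":
        """Prahl compilation values at 760/830 nm (see the shipped TSV)."""
        ref = resources.files("nirsbundle.data") / "extinction_default.tsv"
        with resources.as_file(ref) as p:
            table = cls.from_tsv(p)
        return ExtinctionTable(
            wavelengths=table.wavelengths,
            eps=table.eps,
            source="Prahl compilation (Gratzer/Kollias), ln-based mm^-1 uM^-1",
        )


@dataclass
class ConcentrationSeries:
    """HbO/HbR time courses of one channel, μM.

    ``mode`` records whether the values are absolute concentrations (bundled
    gradient method) or concentration changes (MBLL baseline).
    """

    hbo: np.ndarray
    hbr: np.ndarray
    fs_hz: float
    mode: str = "absolute"  # "absolute" | "differential"
    channel_id: int | None = None

    def __post_init__(self) -> None:
        self.hbo = np.asarray(self.hbo, dtype=float)
        self.hbr = np.asarray(self.hbr, dtype=float)
        if self.hbo.shape != self.hbr.shape:
            raise DataError("HbO and HbR series must have equal length")
        if self.mode not in ("absolute", "differential"):
            raise ConfigError(f"unknown mode {self.mode!r}")

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.hbo.size) / self.fs_hz


def absorbance(i_in, i_out) -> np.ndarray:
    """A = −ln(I_out/I_in); equals μ·l under the homogeneous forward model."""
    i_in = np.asarray(i_in, dtype=float)
    i_out = np.asarray(i_out, dtype=float)
    if np.any(i_in <= 0):
        raise DataError("non-positive incident intensity")
    if np.any(i_out <= 0):
        bad = int(np.argmax(np.atleast_1d(i_out <= 0)))
        raise DataError(f"non-positive detected intensity (first offending sample {bad})")
    return -np.log(i_out / i_in)


def absorbance_gradient(a_short, a_long, delta_l: float) -> np.ndarray:
    """Spatial absorbance gradient g(t) = (A_long − A_short)/δl, mm⁻¹.

    Any additive component common to both absorbance series cancels in the
    numerator — this is the superficial-noise-removal step.
    """
    a_short = np.asarray(a_short, dtype=float)
    a_long = np.asarray(a_long, dtype=float)
    if a_short.shape != a_long.shape:
        raise DataError("short/long absorbance series must have equal length")
    if delta_l <= 0:
        raise GeometryError("delta_l must be > 0 (degenerate channel pair)")
    return (a_long - a_short) / delta_l


def invert_concentrations(
    g_l1,
    g_l2,
    ext: ExtinctionTable,
    params: OpticalModelParams | None = None,
    mus: tuple[float, float] | None = None,
    fs_hz: float = 1.0,
    channel_id: int | None = None,
    max_condition: float = 1e6,
) -> ConcentrationSeries:
    """Absolute HbO/HbR from the two-wavelength absorbance gradients.

    Per sample, [C_HbO; C_HbR] = E⁻¹ · [g(λ1) − μ_s(λ1); g(λ2) − μ_s(λ2)],
    where E is the 2x2 extinction matrix.  Linear in the gradients.  ``mus``
    overrides the scattering model (used in controlled tests); otherwise it
    is computed from ``params``.

    Negative output concentrations are physically meaningless but are *not*
    clipped — they signal model mismatch and trigger a logged warning.
    """
    params = params or OpticalModelParams()
    g1 = np.asarray(g_l1, dtype=float)
    g2 = np.asarray(g_l2, dtype=float)
    if g1.shape != g2.shape:
        raise DataError("gradients must share a common time base")
    E = ext.matrix
    if E.shape != (2, 2):
        raise ConfigError("two wavelengths required for the 2x2 inversion")
    cond = ext.condition_number
    if not np.isfinite(cond) or cond > max_condition:
        raise ConfigError(
            f"extinction matrix singular/ill-conditioned (condition number {cond:.3g})"
        )
    if mus is None:
        mus = tuple(scattering_coefficient(wl, params) for wl in ext.wavelengths)
    rhs = np.vstack([g1 - mus[0], g2 - mus[1]])
    conc = np.linalg.solve(E, rhs)
    if np.any(conc < 0):
        log.warning(
            "channel %s: negative concentrations in output (model mismatch?)",
            channel_id,
        )
    return ConcentrationSeries(
        hbo=conc[0], hbr=conc[1], fs_hz=fs_hz, mode="absolute", channel_id=channel_id
    )


def forward_intensity(
    c_hbo,
    c_hbr,
    distance_l: float,
    ext: ExtinctionTable,
    params: OpticalModelParams | None = None,
    i_in: float = 1.0,
) -> dict[float, np.ndarray]:
    """Detected intensity per wavelength for given concentration time courses.

    I_out(t,λ) = I_in·exp(−(a_HbO(λ)·C_HbO + a_HbR(λ)·C_HbR + μ_s(λ))·l).
    """
    params = params or OpticalModelParams()
    if distance_l <= 0:
        raise GeometryError("distance_l must be > 0")
    c_hbo = np.asarray(c_hbo, dtype=float)
    c_hbr = np.asarray(c_hbr, dtype=float)
    if not (np.all(np.isfinite(c_hbo)) and np.all(np.isfinite(c_hbr))):
        raise DataError("non-finite concentrations")
    out = {}
    for wl in ext.wavelengths:
        e_hbo, e_hbr = ext.eps_for(wl)
        mu = e_hbo * c_hbo + e_hbr * c_hbr + scattering_coefficient(wl, params)
        out[wl] = i_in * np.exp(-mu * distance_l)
    return out


def mbll_delta(
    i_out: dict[float, np.ndarray],
    distance_l: float,
    ext: ExtinctionTable,
    dpf: float = 6.0,
    reference: str | dict[float, float] = "first",
    fs_hz: float = 1.0,
    channel_id: int | None = None,
    rest_samples: int | None = None,
) -> ConcentrationSeries:
    """Differential concentrations via the modified Beer-Lambert law.

    ΔA(t,λ) = −ln(I/I_ref); ΔC = E⁻¹·(ΔA/(l·DPF)).  ``reference`` selects the
    attenuation baseline: ``"first"`` (first sample), ``"rest-mean"`` (mean
    over the first ``rest_samples`` samples), or an explicit per-wavelength
    mapping.  DPF defaults to 6.0 at both wavelengths.
    """
    if distance_l <= 0:
        raise GeometryError("distance_l must be > 0")
    if dpf <= 0:
        raise ConfigError("dpf must be > 0")
    wavelengths = tuple(ext.wavelengths)
    d_mu = []
    for wl in wavelengths:
        series = np.asarray(i_out[wl], dtype=float)
        if np.any(series <= 0):
            raise DataError(f"non-positive intensity at {wl} nm")
        if isinstance(reference, dict):
            ref = float(reference[wl])
        elif reference == "first":
            ref = float(series[0])
        elif reference == "rest-mean":
            n = rest_samples if rest_samples is not None else series.size
            ref = float(series[:n].mean())
        else:
            raise ConfigError(f"unknown reference {reference!r}")
        if ref <= 0:
            raise DataError("non-positive reference intensity")
        d_a = -np.log(series / ref)
        d_mu.append(d_a / (distance_l * dpf))
    conc = np.linalg.solve(ext.matrix, np.vstack(d_mu))
    return ConcentrationSeries(
        hbo=conc[0], hbr=conc[1], fs_hz=fs_hz, mode="differential", channel_id=channel_id
    )
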