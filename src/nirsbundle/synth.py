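"""Forward simulator: intensity recordings with known ground truth.

The simulator emulates the acquisition of a 32-optode, 48-channel,
dual-wavelength (760/830 nm) recording at 1.81 Hz over a 320 s randomized
block paradigm.  For every physical emitter-detector pair it composes, in
absorbance space,

    A(t,λ) = [μ_s(λ) + a_HbO(λ)·C_HbO(t) + a_HbR(λ)·C_HbR(t)]·l
             + s_b(t,λ) + ε(t,λ),

where the concentration time courses carry the baseline, the HRF-shaped
task responses of the designated responding channels, slow drift, and the
cerebral fraction of the systemic oscillations; s_b is a superficial
(scalp) term shared by *all* pairs of bundle b — the structure the gradient
method cancels — carrying low-frequency scalp noise plus the superficial
fraction of the systemic oscillations; ε is white measurement noise.
Intensities are I_out = I_in·exp(−A).  All components are returned
separately so every pipeline stage can be tested against ground truth.

Systemic oscillations (cardiac ~1.1 Hz, respiratory ~0.3 Hz, Mayer
~0.1 Hz) use random-walk phase diffusion rather than strict periodicity:
the 30 s trial period is an exact multiple of the Mayer period, and a
phase-locked sinusoid would never average out across trials.  Note the
cardiac line aliases to |1.1 − 1.81| = 0.71 Hz under 1.81 Hz sampling,
still above the 0.15 Hz low-pass cut-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .activation import HRFParams, design_regressor
from .errors import ConfigError
from .geometry import ProbeLayout, default_layout
from .optics import ExtinctionTable, OpticalModelParams, scattering_coefficient
from .paradigm import Paradigm, generate_paradigm  # noqa: F401  (re-export)
from .recording import IntensityRecording

DEFAULT_FS_HZ = 1.81


@dataclass
class GroundTruth:
    """True concentration model underlying a simulated recording.

    ``responding`` maps each condition to the set of gradient-channel ids
    that carry its response; ``amplitudes`` gives the peak HbO excursion in
    μM (HbR responds with opposite sign scaled by ``hbr_ratio``).  Exact
    forward-inverse amplitude recovery holds when a responding set covers
    whole bundles, so the short pair shares the response attenuation (the
    neighboring-channel homogeneity assumption of the gradient model);
    partial bundles are allowed but recover with a geometric inflation.
    """

    baseline_hbo_um: float = 5.0
    baseline_hbr_um: float = 3.4
    amplitudes_um: dict = field(default_factory=lambda: {"little": 0.35, "thumb": 0.25})
    responding: dict = field(default_factory=dict)
    hbr_ratio: float = -0.33
    hbo_true: dict | None = None  # channel id -> series, filled by the simulator
    hbr_true: dict | None = None

    def __post_init__(self) -> None:
        for cond, amp in self.amplitudes_um.items():
            if amp < 0:
                raise ConfigError(f"amplitude for {cond!r} must be >= 0")


def default_ground_truth(layout: ProbeLayout | None = None) -> GroundTruth:
    """Default truth: the two conditions each activate one whole bundle.

    With the default montage, "little" drives bundle 4 and "thumb" bundle 5
    (adjacent medial/lateral patches), i.e. six gradient channels each.
    """
    layout = layout or default_layout()
    by_bundle: dict[int, list[int]] = {}
    for c in layout.channels:
        by_bundle.setdefault(c.bundle_id, []).append(c.id)
    bundle_ids = sorted(by_bundle)
    b_little = bundle_ids[min(3, len(bundle_ids) - 1)]
    b_thumb = bundle_ids[min(4, len(bundle_ids) - 1)]
    return GroundTruth(
        responding={
            "little": set(by_bundle[b_little]),
            "thumb": set(by_bundle[b_thumb]),
        }
    )


@dataclass
class NoiseConfig:
    """Noise model amplitudes (all >= 0) and the mandatory seed.

    Amplitudes of the physiological terms are in μM (concentration domain);
    ``superficial_sd`` and ``white_sd`` are in absorbance units.  The
    default white level was chosen so that the per-channel concentration
    noise is roughly 10% of the default 0.3 μM-scale response on a typical
    gradient baseline (see docs/methods.md for the propagation arithmetic).
    """

    seed: int = 0
    drift_range_um: float = 0.5
    superficial_sd: float = 0.01
    superficial_cutoff_hz: float = 0.05
    cardiac_hz: float = 1.1
    cardiac_um: float = 0.1
    resp_hz: float = 0.3
    resp_um: float = 0.1
    mayer_hz: float = 0.1
    mayer_um: float = 0.05
    cerebral_fraction: float = 0.3
    phase_diffusion: float = 0.15  # rad / sqrt(s)
    white_sd: float = 6e-5

    def __post_init__(self) -> None:
        for name in (
            "drift_range_um",
            "superficial_sd",
            "cardiac_um",
            "resp_um",
            "mayer_um",
            "white_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0 <= self.cerebral_fraction <= 1:
            raise ConfigError("cerebral_fraction must be in [0, 1]")


@dataclass
class SimulationResult:
    recording: IntensityRecording
    paradigm: Paradigm
    truth: GroundTruth
    layout: ProbeLayout
    components: dict


def _oscillation(rng, t, freq_hz, amp, diffusion):
    """amp·sin(2πft + φ(t)) with random-walk phase φ (breaks trial locking)."""
    if amp == 0:
        return np.zeros_like(t)
    dt = float(t[1] - t[0]) if t.size > 1 else 1.0
    phi0 = rng.uniform(0, 2 * np.pi)
    walk = np.cumsum(rng.normal(0.0, diffusion * np.sqrt(dt), size=t.size))
    return amp * np.sin(2 * np.pi * freq_hz * t + phi0 + walk)


def _smoothed_noise(rng, n, fs_hz, cutoff_hz, sd):
    """Low-frequency Gaussian noise with unit-calibrated standard deviation."""
    if sd == 0:
        return np.zeros(n)
    from scipy import signal

    white = rng.normal(size=n)
    sos = signal.butter(2, min(cutoff_hz, 0.45 * fs_hz), "low", fs=fs_hz, output="sos")
    smooth = signal.sosfiltfilt(sos, white)
    s = smooth.std()
    return smooth * (sd / s) if s > 0 else np.zeros(n)


def simulate_experiment(
    layout: ProbeLayout | None = None,
    truth: GroundTruth | None = None,
    paradigm: Paradigm | None = None,
    noise: NoiseConfig | None = None,
    fs_hz: float = DEFAULT_FS_HZ,
    ext: ExtinctionTable | None = None,
    params: OpticalModelParams | None = None,
    hrf_params: HRFParams | None = None,
    i_in: float = 1.0,
) -> SimulationResult:
    """Generate a dual-wavelength intensity recording with known truth.

    Deterministic given ``noise.seed``; identical seeds produce bit-identical
    recordings.  The true per-channel concentration series (baseline plus
    task response, excluding nuisance terms) are stored on the returned
    ground truth, and every nuisance component is returned in
    ``components``.
    """
    layout = layout if layout is not None else default_layout()
    truth = truth if truth is not None else default_ground_truth(layout)
    noise = noise if noise is not None else NoiseConfig()
    ext = ext or ExtinctionTable.default()
    params = params or OpticalModelParams(wavelengths=ext.wavelengths)
    if paradigm is None:
        paradigm = generate_paradigm(noise.seed)

    n = int(round(paradigm.total_duration_s * fs_hz))
    t = np.arange(n) / fs_hz
    rng = np.random.default_rng(noise.seed)

    # HRF-shaped condition responses, peak-normalized so amplitude == peak μM
    cond_response: dict[str, np.ndarray] = {}
    for cond in paradigm.conditions:
        reg = design_regressor(paradigm, fs_hz, n, hrf_params, condition=cond)
        m = reg.max()
        cond_response[cond] = reg / m if m > 0 else reg

    # cerebral + superficial split of the systemic oscillations
    osc = (
        _oscillation(rng, t, noise.cardiac_hz, noise.cardiac_um, noise.phase_diffusion)
        + _oscillation(rng, t, noise.resp_hz, noise.resp_um, noise.phase_diffusion)
        + _oscillation(rng, t, noise.mayer_hz, noise.mayer_um, noise.phase_diffusion)
    )
    osc_cerebral = noise.cerebral_fraction * osc
    osc_superficial_um = (1.0 - noise.cerebral_fraction) * osc

    mus = {wl: scattering_coefficient(wl, params) for wl in ext.wavelengths}
    eps = {wl: ext.eps_for(wl) for wl in ext.wavelengths}

    # per-channel true concentrations (baseline + responses, no nuisance)
    hbo_true: dict[int, np.ndarray] = {}
    hbr_true: dict[int, np.ndarray] = {}
    response_of: dict[int, np.ndarray] = {}
    for c in layout.channels:
        resp = np.zeros(n)
        for cond, chans in truth.responding.items():
            if c.id in chans:
                resp = resp + truth.amplitudes_um.get(cond, 0.0) * cond_response[cond]
        response_of[c.id] = resp
        hbo_true[c.id] = truth.baseline_hbo_um + resp
        hbr_true[c.id] = truth.baseline_hbr_um + truth.hbr_ratio * resp
    truth.hbo_true = hbo_true
    truth.hbr_true = hbr_true

    # bundle-common response for the short pair: defined when all gradient
    # channels of the bundle carry the identical response series
    bundle_common: dict[int, np.ndarray] = {}
    for b in layout.bundles:
        resps = [response_of[c.id] for c in layout.channels if c.bundle_id == b.id]
        if resps and all(np.array_equal(r, resps[0]) for r in resps[1:]):
            bundle_common[b.id] = resps[0]
        else:
            bundle_common[b.id] = np.zeros(n)

    # superficial common-mode per bundle per wavelength (absorbance units)
    superficial: dict[int, dict[float, np.ndarray]] = {}
    for b in layout.bundles:
        per_wl = {}
        scalp = _smoothed_noise(rng, n, fs_hz, noise.superficial_cutoff_hz, noise.superficial_sd)
        for wl in ext.wavelengths:
            e_hbo, e_hbr = eps[wl]
            # scalp oscillation expressed in absorbance via an effective 5 mm path
            osc_abs = (e_hbo + 0.5 * e_hbr) * osc_superficial_um * 5.0
            per_wl[wl] = scalp + osc_abs
        superficial[b.id] = per_wl

    drift: dict[str, np.ndarray] = {}
    white: dict[str, dict[float, np.ndarray]] = {}
    data: dict[str, np.ndarray] = {}
    tau = t / t[-1] if n > 1 else t

    def _drift_um(label: str) -> np.ndarray:
        coeffs = rng.uniform(-1.0, 1.0, size=4) * noise.drift_range_um
        d = sum(ck * tau ** (k + 1) for k, ck in enumerate(coeffs))
        drift[label] = d
        return d

    def _pair_absorbance(label, c_hbo, c_hbr, l_mm, bundle_id):
        cols = []
        white[label] = {}
        for wl in ext.wavelengths:
            e_hbo, e_hbr = eps[wl]
            mu = mus[wl] + e_hbo * c_hbo + e_hbr * c_hbr
            eps_noise = rng.normal(0.0, noise.white_sd, size=n) if noise.white_sd > 0 else np.zeros(n)
            white[label][wl] = eps_noise
            cols.append(mu * l_mm + superficial[bundle_id][wl] + eps_noise)
        return np.column_stack(cols)

    for b in layout.bundles:
        d_um = _drift_um(b.short_pair_label)
        c_hbo = truth.baseline_hbo_um + bundle_common[b.id] + osc_cerebral + d_um
        c_hbr = truth.baseline_hbr_um + truth.hbr_ratio * (bundle_common[b.id] + osc_cerebral + d_um)
        data[b.short_pair_label] = _pair_absorbance(
            b.short_pair_label, c_hbo, c_hbr, b.short_separation, b.id
        )
    for c in layout.channels:
        d_um = _drift_um(c.pair_label)
        c_hbo = hbo_true[c.id] + osc_cerebral + d_um
        c_hbr = truth.baseline_hbr_um + truth.hbr_ratio * (response_of[c.id] + osc_cerebral + d_um)
        data[c.pair_label] = _pair_absorbance(
            c.pair_label, c_hbo, c_hbr, c.distance_l, c.bundle_id
        )

    intensities = {label: i_in * np.exp(-arr) for label, arr in data.items()}
    recording = IntensityRecording(
        time_s=t,
        wavelengths=tuple(ext.wavelengths),
        data=intensities,
        fs_hz=fs_hz,
        i_in=i_in,
    )
    components = {
        "oscillation_cerebral_um": osc_cerebral,
        "oscillation_superficial_um": osc_superficial_um,
        "superficial_absorbance": superficial,
        "drift_um": drift,
        "white_absorbance": white,
        "condition_response": cond_response,
    }
    return SimulationResult(
        recording=recording, paradigm=paradigm, truth=truth, layout=layout, components=components
    )
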