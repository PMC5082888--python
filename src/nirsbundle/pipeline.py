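"""End-to-end orchestration: intensities -> concentrations -> statistics.

Two estimators share the downstream path: the bundled-optode gradient
method (absolute concentrations; superficial common-mode cancelled) and
the conventional MBLL baseline (differential concentrations of each long
channel alone).  Downstream: baseline correction, low-pass filtering,
per-condition epoching and averaging, activation mapping, CNR and HR
summaries.
"""

from __future__ import annotations

import logging
import time as _time
from dataclasses import dataclass

import numpy as np

from . import metrics as metrics_mod
from .activation import ActivationConfig, ActivationMap, HRFParams, build_activation_map
from .errors import ConfigError
from .geometry import ProbeLayout
from .metrics import CNRConfig, HRSummary, average_epochs, cnr, epoch_trials, hr_summary
from .optics import (
    ConcentrationSeries,
    ExtinctionTable,
    OpticalModelParams,
    absorbance,
    absorbance_gradient,
    invert_concentrations,
    mbll_delta,
)
from .paradigm import Paradigm
from .preprocess import PreprocessConfig, preprocess_series
from .recording import IntensityRecording

log = logging.getLogger(__name__)


def recover_bundled(
    recording: IntensityRecording,
    layout: ProbeLayout,
    ext: ExtinctionTable | None = None,
    params: OpticalModelParams | None = None,
) -> dict[int, ConcentrationSeries]:
    """Absolute HbO/HbR per gradient channel via the two-pair inversion."""
    ext = ext or ExtinctionTable.default()
    params = params or OpticalModelParams(wavelengths=ext.wavelengths)
    out: dict[int, ConcentrationSeries] = {}
    short_abs: dict[tuple[int, float], np.ndarray] = {}
    for b in layout.bundles:
        for wl in recording.wavelengths:
            short_abs[(b.id, wl)] = absorbance(
                recording.i_in, recording.intensity(b.short_pair_label, wl)
            )
    for c in layout.channels:
        grads = []
        for wl in recording.wavelengths:
            a_long = absorbance(recording.i_in, recording.intensity(c.pair_label, wl))
            grads.append(absorbance_gradient(short_abs[(c.bundle_id, wl)], a_long, c.delta_l))
        out[c.id] = invert_concentrations(
            grads[0], grads[1], ext, params, fs_hz=recording.fs_hz, channel_id=c.id
        )
    return out


def recover_mbll(
    recording: IntensityRecording,
    layout: ProbeLayout,
    ext: ExtinctionTable | None = None,
    dpf: float = 6.0,
    reference: str = "rest-mean",
    rest_s: float = 20.0,
) -> dict[int, ConcentrationSeries]:
    """Differential HbO/HbR per gradient channel's long pair via MBLL."""
    ext = ext or ExtinctionTable.default()
    rest_samples = int(round(rest_s * recording.fs_hz))
    out: dict[int, ConcentrationSeries] = {}
    for c in layout.channels:
        i_out = {wl: recording.intensity(c.pair_label, wl) for wl in recording.wavelengths}
        out[c.id] = mbll_delta(
            i_out,
            c.distance_l,
            ext,
            dpf=dpf,
            reference=reference,
            rest_samples=rest_samples,
            fs_hz=recording.fs_hz,
            channel_id=c.id,
        )
    return out


@dataclass
class PipelineResult:
    concentrations: dict[int, ConcentrationSeries]
    hbo_clean: dict[int, np.ndarray]
    avg_by_condition: dict[str, dict[int, np.ndarray]]
    sd_by_condition: dict[str, dict[int, np.ndarray]]
    maps: dict[str, ActivationMap]
    cnr_by_condition: dict[str, dict[int, float]]
    summaries: dict[str, HRSummary]
    aggregate: dict
    compare: tuple[float, float] | None
    mode: str


def run_pipeline(
    recording: IntensityRecording,
    layout: ProbeLayout,
    paradigm: Paradigm,
    method: str = "bundled",
    ext: ExtinctionTable | None = None,
    params: OpticalModelParams | None = None,
    pre_cfg: PreprocessConfig | None = None,
    act_cfg: ActivationConfig | None = None,
    cnr_cfg: CNRConfig | None = None,
    hrf_params: HRFParams | None = None,
    dpf: float = 6.0,
) -> PipelineResult:
    """Full analysis of one recording with either estimator.

    Stages: concentration recovery, per-channel baseline correction and
    low-pass filtering of HbO, per-condition epoching/averaging, activation
    mapping, per-channel CNR, HR summaries of the ROI-average response, the
    across-condition aggregate table, and the two-condition comparison test.
    """
    pre_cfg = pre_cfg or PreprocessConfig()
    act_cfg = act_cfg or ActivationConfig()
    cnr_cfg = cnr_cfg or CNRConfig()
    fs = recording.fs_hz

    t0 = _time.perf_counter()
    if method == "bundled":
        conc = recover_bundled(recording, layout, ext, params)
    elif method == "mbll":
        conc = recover_mbll(recording, layout, ext, dpf=dpf)
    else:
        raise ConfigError(f"unknown method {method!r}")
    log.info("concentrations (%s): %d channels in %.2f s", method, len(conc), _time.perf_counter() - t0)

    hbo_clean = {cid: preprocess_series(cs.hbo, fs, pre_cfg) for cid, cs in conc.items()}

    window = act_cfg.epoch_window_s
    conditions = list(paradigm.conditions)
    avg_by_condition: dict[str, dict[int, np.ndarray]] = {}
    sd_by_condition: dict[str, dict[int, np.ndarray]] = {}
    epochs_by_condition: dict[str, dict[int, list[np.ndarray]]] = {}
    for cond in conditions:
        avgs, sds, eps = {}, {}, {}
        for cid, y in hbo_clean.items():
            epochs = epoch_trials(y, fs, paradigm, condition=cond, window_s=window)
            eps[cid] = epochs
            avgs[cid], sds[cid] = average_epochs(epochs)
        avg_by_condition[cond] = avgs
        sd_by_condition[cond] = sds
        epochs_by_condition[cond] = eps

    maps = {
        cond: build_activation_map(
            avg_by_condition[cond], layout, fs, act_cfg, hrf_params, condition=cond
        )
        for cond in conditions
    }

    cnr_by_condition = {}
    for cond in conditions:
        vals = {}
        for cid, avg in avg_by_condition[cond].items():
            try:
                vals[cid] = cnr(avg, fs, onset_s=0.0, config=cnr_cfg, t0_series_s=window[0])
            except Exception:  # zero-variance degenerate channels
                vals[cid] = float("nan")
        cnr_by_condition[cond] = vals

    # representative HR per condition: average over the ROI (active channels)
    summaries: dict[str, HRSummary] = {}
    for cond in conditions:
        active = maps[cond].active_channels()
        chans = active if active else sorted(avg_by_condition[cond])
        roi_avg = np.mean([avg_by_condition[cond][cid] for cid in chans], axis=0)
        summaries[cond] = hr_summary(roi_avg, fs, epoch_window_s=window, condition=cond)

    aggregate = (
        metrics_mod.aggregate_conditions(list(summaries.values()))
        if len(summaries) >= 2
        else {}
    )

    compare = None
    if len(conditions) >= 2:
        a_cond, b_cond = conditions[0], conditions[1]
        roi_a = maps[a_cond].active_channels() or sorted(hbo_clean)
        roi_b = maps[b_cond].active_channels() or sorted(hbo_clean)
        ep_a = [e for cid in roi_a for e in epochs_by_condition[a_cond][cid]]
        ep_b = [e for cid in roi_b for e in epochs_by_condition[b_cond][cid]]
        try:
            compare = metrics_mod.compare_conditions(ep_a, ep_b, fs, epoch_window_s=window)
        except Exception as exc:
            log.warning("condition comparison skipped: %s", exc)

    return PipelineResult(
        concentrations=conc,
        hbo_clean=hbo_clean,
        avg_by_condition=avg_by_condition,
        sd_by_condition=sd_by_condition,
        maps=maps,
        cnr_by_condition=cnr_by_condition,
        summaries=summaries,
        aggregate=aggregate,
        compare=compare,
        mode=method,
    )
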