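"""Epoching, trial averaging, contrast-to-noise ratio, and HR summaries.

CNR compares the task window (6–16 s post-onset) against the pre-onset
rest window (−6–0 s):

    CNR = (mean_task − mean_rest) / sqrt(var_task + var_rest),

with sample variances (denominator n − 1).  Hemodynamic-response summary
statistics (mean, peak, time-to-peak, skewness) are computed on the
trial-averaged epoch over a response window, and a two-sample t-test
compares per-trial summaries between conditions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

from .errors import ConfigError, DataError
from .paradigm import Paradigm

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CNRConfig:
    task_window_s: tuple[float, float] = (6.0, 16.0)
    rest_window_s: tuple[float, float] = (-6.0, 0.0)

    def __post_init__(self) -> None:
        t0, t1 = self.task_window_s
        r0, r1 = self.rest_window_s
        if t1 <= t0 or r1 <= r0:
            raise ConfigError("CNR windows must be nonempty")
        if max(t0, r0) < min(t1, r1):
            raise ConfigError("CNR task and rest windows must not overlap")


@dataclass
class HRSummary:
    """Scalar description of one averaged hemodynamic response."""

    mean: float
    peak: float
    time_to_peak_s: float
    skewness: float
    condition: str | None = None
    skew_defined: bool = True


def epoch_trials(
    series,
    fs_hz: float,
    paradigm: Paradigm,
    condition: str | None = None,
    window_s: tuple[float, float] = (-6.0, 24.0),
) -> list[np.ndarray]:
    """Cut per-trial epochs around each matching onset.

    The default window (−6 to 24 s) covers both the CNR rest window and the
    4–14 s response-mean window.  Epochs that would run past the recording
    bounds are dropped with a warning.
    """
    y = np.asarray(series, dtype=float)
    if y.ndim != 1:
        raise DataError("epoch_trials expects a 1-D series")
    w0, w1 = window_s
    n = int(round((w1 - w0) * fs_hz))
    epochs = []
    for onset in paradigm.onsets(condition):
        i0 = int(round((onset + w0) * fs_hz))
        if i0 < 0 or i0 + n > y.size:
            log.warning("dropping epoch at onset %.1f s: exceeds recording bounds", onset)
            continue
        epochs.append(y[i0 : i0 + n].copy())
    return epochs


def average_epochs(epochs) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean and one-standard-deviation band across epochs."""
    if len(epochs) == 0:
        raise DataError("average_epochs requires at least one epoch")
    lengths = {len(e) for e in epochs}
    if len(lengths) != 1:
        raise DataError(f"epoch length mismatch: {sorted(lengths)}")
    arr = np.asarray(epochs, dtype=float)
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1) if arr.shape[0] > 1 else np.zeros(mean.size)
    return mean, sd


def _window_slice(fs_hz: float, t0_series: float, w0: float, w1: float, n: int) -> slice:
    i0 = int(round((w0 - t0_series) * fs_hz))
    i1 = int(round((w1 - t0_series) * fs_hz))
    if i0 < 0 or i1 > n or i1 <= i0:
        raise DataError(f"window [{w0}, {w1}] s outside series")
    return slice(i0, i1)


def cnr(
    series,
    fs_hz: float,
    onset_s: float,
    config: CNRConfig | None = None,
    t0_series_s: float = 0.0,
) -> float:
    """Contrast-to-noise ratio of one response around one onset.

    ``t0_series_s`` is the time of the first sample (e.g. −6 relative to
    onset for a default epoch when ``onset_s=0``).  Windows are interpreted
    relative to ``onset_s``.
    """
    config = config or CNRConfig()
    y = np.asarray(series, dtype=float)
    task = y[_window_slice(fs_hz, t0_series_s - onset_s, *config.task_window_s, y.size)]
    rest = y[_window_slice(fs_hz, t0_series_s - onset_s, *config.rest_window_s, y.size)]
    var_task = float(np.var(task, ddof=1))
    var_rest = float(np.var(rest, ddof=1))
    denom = var_task + var_rest
    if denom == 0:
        raise DataError("zero total variance: CNR undefined")
    return float((task.mean() - rest.mean()) / math.sqrt(denom))


def hr_summary(
    avg_epoch,
    fs_hz: float,
    epoch_window_s: tuple[float, float] = (-6.0, 24.0),
    response_window_s: tuple[float, float] = (0.0, 20.0),
    condition: str | None = None,
) -> HRSummary:
    """Mean, peak, time-to-peak and skewness of an averaged response.

    Time-to-peak is reported relative to the task onset (t = 0 of the epoch
    window).  Skewness is the adjusted Fisher-Pearson sample skewness; for a
    constant window it is undefined and reported as 0 with a flag.
    """
    y = np.asarray(avg_epoch, dtype=float)
    w0 = epoch_window_s[0]
    sl = _window_slice(fs_hz, w0, *response_window_s, y.size)
    win = y[sl]
    if win.size == 0:
        raise DataError("empty response window")
    peak_idx = int(np.argmax(win))
    t_grid = w0 + np.arange(y.size) / fs_hz
    skew_defined = bool(np.ptp(win) > 0)
    skew = float(stats.skew(win, bias=False)) if skew_defined else 0.0
    return HRSummary(
        mean=float(win.mean()),
        peak=float(win.max()),
        time_to_peak_s=float(t_grid[sl][peak_idx]),
        skewness=skew,
        condition=condition,
        skew_defined=skew_defined,
    )


def _round_half_up(x: float, ndigits: int = 2) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def aggregate_pair(a: float, b: float, ndigits: int = 2) -> tuple[float, float]:
    """Mean ± sample SD of two condition values, reported at ``ndigits`` d.p.

    Reporting uses decimal (half-up) rounding on the printed inputs so that
    exact ties such as 9.665 round to 9.67, as in conventional tables.
    """
    da, db = Decimal(repr(float(a))), Decimal(repr(float(b)))
    mean = (da + db) / 2
    sd = abs(da - db) / Decimal(2).sqrt()
    q = Decimal(1).scaleb(-ndigits)
    return (
        float(mean.quantize(q, rounding=ROUND_HALF_UP)),
        float(sd.quantize(q, rounding=ROUND_HALF_UP)),
    )


def aggregate_conditions(summaries: list[HRSummary], ndigits: int = 2) -> dict:
    """Across-condition mean ± sample SD for each HR summary field.

    Returns a mapping field -> (mean, sd) with values rounded half-up at
    ``ndigits`` decimal places for reporting.
    """
    if len(summaries) < 2:
        raise DataError("aggregate_conditions requires >= 2 condition summaries")
    out = {}
    for name in ("mean", "peak", "time_to_peak_s", "skewness"):
        vals = [getattr(s, name) for s in summaries]
        if len(vals) == 2:
            out[name] = aggregate_pair(vals[0], vals[1], ndigits)
        else:
            out[name] = (
                _round_half_up(float(np.mean(vals)), ndigits),
                _round_half_up(float(np.std(vals, ddof=1)), ndigits),
            )
    return out


def compare_conditions(
    epochs_a,
    epochs_b,
    fs_hz: float,
    epoch_window_s: tuple[float, float] = (-6.0, 24.0),
    summary_window_s: tuple[float, float] = (4.0, 14.0),
) -> tuple[float, float]:
    """Two-sample t-test on per-trial response summaries of two conditions.

    Each trial is summarized by its mean over ``summary_window_s`` (the same
    4–14 s window used by the activation map); the two groups of summaries
    enter an independent two-sample t-test (two-sided p).
    """
    if len(epochs_a) < 2 or len(epochs_b) < 2:
        raise DataError("compare_conditions requires >= 2 epochs per condition")

    def _means(epochs):
        out = []
        for e in epochs:
            y = np.asarray(e, dtype=float)
            sl = _window_slice(fs_hz, epoch_window_s[0], *summary_window_s, y.size)
            out.append(float(y[sl].mean()))
        return out

    a, b = _means(epochs_a), _means(epochs_b)
    if np.var(a) + np.var(b) == 0:
        raise DataError("degenerate variance in both groups: t-test undefined")
    t_val, p_val = stats.ttest_ind(a, b)
    return float(t_val), float(p_val)
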