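"""ThT / curcumin fluorescence aggregation kinetics.

Preprocessing follows the plate-assay convention: subtract the signal
of a protein-free control well (buffer + dye), then normalize to the
maximum observed signal, clipping small negative excursions at zero.
ThT and curcumin fluorescence both report fibril formation and are
treated as a single channel.

The lag phase is extracted by the tangent-intercept construction
standard in amyloid kinetics: the steepest 5-point sliding linear fit
defines the growth tangent, and the lag time is where that tangent
crosses the pre-transition baseline.  For a logistic curve of rate k
centred at t0 this gives exactly t0 - 2/k, independent of plateau
level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ThTCurve", "KineticsSummary", "preprocess", "lag_time",
           "average_replicates"]


@dataclass
class ThTCurve:
    """One well's fluorescence time course."""

    time_h: np.ndarray
    signal: np.ndarray
    replicate_id: str = ""
    condition: str = ""  # e.g. curcumin concentration label

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time_h.shape != self.signal.shape or self.time_h.ndim != 1:
            raise ValueError("time_h and signal must be equal-length 1D arrays")
        if self.time_h.size < 10:
            raise ValueError("need at least 10 time points")
        if np.any(np.diff(self.time_h) <= 0):
            raise ValueError("time_h must be strictly increasing")

    @property
    def interval_h(self) -> float:
        return float(np.median(np.diff(self.time_h)))


@dataclass(frozen=True)
class KineticsSummary:
    """Extracted descriptors of a sigmoidal aggregation curve."""

    lag_h: float
    t50_h: float
    max_slope: float  # a.u./h
    plateau: float
    has_transition: bool = True


def preprocess(raw: ThTCurve, control: ThTCurve) -> ThTCurve:
    """Control-subtract and normalize a fluorescence curve to max = 1.

    The control is interpolated onto the raw time grid when the grids
    disagree by more than one sampling interval.  Negative values after
    subtraction are clipped at zero.  Raises when no signal remains
    (flat or all-negative curve).
    """
    if (control.time_h.shape == raw.time_h.shape
            and np.max(np.abs(control.time_h - raw.time_h)) <= raw.interval_h):
        ctrl = control.signal
    else:
        ctrl = np.interp(raw.time_h, control.time_h, control.signal)
    corrected = np.clip(raw.signal - ctrl, 0.0, None)
    peak = corrected.max()
    if peak <= 0:
        raise ValueError("no signal above control after subtraction")
    return ThTCurve(raw.time_h, corrected / peak,
                    replicate_id=raw.replicate_id, condition=raw.condition)


def average_replicates(curves: list[ThTCurve], condition: str = "") -> ThTCurve:
    """Mean curve of replicate wells sharing a time grid."""
    if not curves:
        raise ValueError("no curves to average")
    t = curves[0].time_h
    for c in curves[1:]:
        if c.time_h.shape != t.shape or np.max(np.abs(c.time_h - t)) > curves[0].interval_h:
            raise ValueError("replicates must share a time grid")
    mean = np.mean([c.signal for c in curves], axis=0)
    return ThTCurve(t, mean, replicate_id="mean",
                    condition=condition or curves[0].condition)


def lag_time(curve: ThTCurve, window: int = 5,
             baseline_fraction: float = 0.1) -> KineticsSummary:
    """Extract lag time, midpoint and growth rate from a (preprocessed)
    sigmoidal curve.

    max_slope comes from a ``window``-point sliding linear fit;
    lag_h is the intercept of the max-slope tangent with the
    pre-transition baseline (mean of points below ``baseline_fraction``
    of the rise before the transition); t50_h is the first upward
    crossing of half-amplitude, linearly interpolated.

    A curve that never rises above half of its span is reported with
    ``has_transition=False`` and NaN descriptors.
    """
    t, y = curve.time_h, curve.signal
    lo, hi = float(y.min()), float(y.max())
    span = hi - lo
    if span <= 0:
        return KineticsSummary(np.nan, np.nan, np.nan, hi, has_transition=False)

    half = lo + 0.5 * span
    above = np.flatnonzero(y >= half)
    if above.size == 0:
        return KineticsSummary(np.nan, np.nan, np.nan, hi, has_transition=False)

    # sliding OLS slopes
    n = t.size
    w = min(window, n)
    slopes = np.full(n, -np.inf)
    for k in range(n - w + 1):
        ts, ys = t[k:k + w], y[k:k + w]
        slopes[k] = np.polyfit(ts, ys, 1)[0]
    k_best = int(np.argmax(slopes))
    max_slope = float(slopes[k_best])
    if max_slope <= 0:
        return KineticsSummary(np.nan, np.nan, np.nan, hi, has_transition=False)
    t_mid = float(np.mean(t[k_best:k_best + w]))
    y_mid = float(np.mean(y[k_best:k_best + w]))

    # pre-transition baseline: early points below a fraction of the rise
    pre = y[:above[0]] if above[0] > 0 else y[:1]
    low_mask = pre <= lo + baseline_fraction * span
    baseline = float(pre[low_mask].mean()) if np.any(low_mask) else lo

    lag = t_mid - (y_mid - baseline) / max_slope
    lag = max(lag, float(t[0]))

    # first upward half-crossing, interpolated
    j = int(above[0])
    if j == 0:
        t50 = float(t[0])
    else:
        t50 = float(np.interp(half, [y[j - 1], y[j]], [t[j - 1], t[j]]))
    return KineticsSummary(lag_h=lag, t50_h=t50, max_slope=max_slope,
                           plateau=hi, has_transition=True)
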