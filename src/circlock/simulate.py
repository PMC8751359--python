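"""Integration, oscillation classification and period/phase summaries.

Two oscillation detectors are provided:

* :func:`detect_oscillation_fft` — spectral: drop the leading transient,
  subtract the mean and require a dominant nonzero-frequency peak.
* :func:`detect_oscillation_events` — event-location: a two-pass procedure
  that records the upward crossings of one component through its own mean
  and accepts the run as oscillating when the last three inter-event gaps
  are equal to within ``gap_tol`` (default 1e-3 time units).

Batch variants backed by the compiled kernels live at the bottom; they are
what the Monte-Carlo scans in :mod:`circlock.analysis` use.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import _kernels

__all__ = [
    "Trajectory",
    "OscillationVerdict",
    "IntegrationError",
    "NonOscillatoryError",
    "integrate",
    "detect_oscillation_fft",
    "detect_oscillation_events",
    "phase_durations",
]

#: default detector settings (package decisions, kept in one place)
TRANSIENT_FRACTION = 0.3
REL_AMPLITUDE_MIN = 0.01
PEAK_MEDIAN_RATIO = 5.0
EVENT_GAP_TOL = 1e-3
EVENT_HORIZON = 300.0


class IntegrationError(RuntimeError):
    """The ODE solver failed to advance to the end of the time span."""


class NonOscillatoryError(ValueError):
    """A phase/period summary was requested for a non-oscillatory series."""


@dataclass
class Trajectory:
    """Time grid plus per-species series (times strictly increasing)."""

    times: np.ndarray
    values: np.ndarray  # shape (n_times, n_species)
    names: Sequence[str]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != self.times.shape[0]:
            raise ValueError("times and values have mismatched lengths")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trajectory contains non-finite values")

    def series(self, name: str) -> np.ndarray:
        return self.values[:, list(self.names).index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.names)).assign(
            time=self.times
        )[["time", *self.names]]

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        df = pd.read_csv(path)
        names = [c for c in df.columns if c != "time"]
        return cls(df["time"].to_numpy(), df[names].to_numpy(), names)


@dataclass
class OscillationVerdict:
    """Boolean oscillation flag with period estimate and evidence."""

    oscillating: bool
    period: Optional[float]
    method: str  # "fft" | "events"
    evidence: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.oscillating and not (self.period and self.period > 0):
            raise ValueError("oscillating verdicts need a positive period")
        if not self.oscillating:
            self.period = None

    def to_json(self) -> str:
        payload = {
            "oscillating": bool(self.oscillating),
            "period": self.period,
            "method": self.method,
            "evidence": {k: _jsonable(v) for k, v in self.evidence.items()},
        }
        return json.dumps(payload)


def _jsonable(v):
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    return v


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------


def integrate(rhs: Callable, y0, t_span, t_eval=None, args=(),
              rtol: float = 1e-6, atol: float = 1e-9,
              method: str = "LSODA",
              names: Optional[Sequence[str]] = None) -> Trajectory:
    """Integrate ``dy/dt = rhs(t, y, *args)`` with a stiff-capable solver.

    Raises :class:`IntegrationError` (carrying the solver message) on
    failure.  Sub-tolerance negative concentrations (> -1e-12) are clipped
    to zero in the returned trajectory.
    """
    y0 = np.asarray(y0, dtype=float)
    if not np.all(np.isfinite(y0)):
        raise ValueError("initial state must be finite")
    t0, t1 = float(t_span[0]), float(t_span[1])
    if not t1 > t0:
        raise ValueError("t_span must be increasing")
    sol = solve_ivp(rhs, (t0, t1), y0, t_eval=t_eval, args=args or None,
                    rtol=rtol, atol=atol, method=method)
    if not sol.success:
        raise IntegrationError(
            f"solver failed: {sol.message} (reached t = {sol.t[-1]:.6g})"
        )
    values = sol.y.T
    tiny = (values < 0) & (values > -1e-12)
    if np.any(tiny):
        values = np.where(tiny, 0.0, values)
    if names is None:
        names = [f"y{i}" for i in range(y0.size)]
    return Trajectory(sol.t, values, names)


# ---------------------------------------------------------------------------
# FFT detector
# ---------------------------------------------------------------------------


def _fft_peak(series: np.ndarray, dt: float):
    """(period, peak_power, rel_amplitude, median_ratio) of the dominant
    nonzero-frequency component, with parabolic sub-bin refinement."""
    n = series.size
    mu = series.mean()
    power = np.abs(np.fft.rfft(series - mu))
    freqs = np.fft.rfftfreq(n, dt)
    if power.size < 3:
        return np.nan, 0.0, 0.0, 0.0
    k = int(np.argmax(power[1:]) + 1)
    peak = power[k]
    med = float(np.median(power[1:]))
    rel_amp = 2.0 * peak / n / max(abs(mu), 1e-300)
    # parabolic interpolation of the peak position
    fk = freqs[k]
    if 1 <= k < power.size - 1:
        pm, p0, pp = power[k - 1], power[k], power[k + 1]
        denom = pm - 2.0 * p0 + pp
        if denom < 0:
            shift = 0.5 * (pm - pp) / denom
            fk = freqs[k] + shift * (freqs[1] - freqs[0])
    period = 1.0 / fk if fk > 0 else np.nan
    ratio = peak / med if med > 0 else np.inf
    return period, float(peak), float(rel_amp), float(ratio)


def detect_oscillation_fft(series, dt: float,
                           transient_fraction: float = TRANSIENT_FRACTION,
                           rel_amplitude_min: float = REL_AMPLITUDE_MIN,
                           peak_median_ratio: float = PEAK_MEDIAN_RATIO,
                           min_length: int = 32) -> OscillationVerdict:
    """Classify a uniformly sampled series as oscillating via its spectrum.

    The leading ``transient_fraction`` of the series is discarded and the
    mean subtracted.  The series is oscillating iff the dominant
    nonzero-frequency peak has relative amplitude >= ``rel_amplitude_min``
    of the series mean and exceeds ``peak_median_ratio`` times the median
    spectral amplitude.  Both thresholds reject flat and noise-only spectra
    while keeping small-amplitude limit cycles.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if series.size < min_length:
        raise ValueError(f"series too short ({series.size} < {min_length})")
    tail = series[int(transient_fraction * series.size):]
    period, peak, rel_amp, ratio = _fft_peak(tail, dt)
    oscillating = bool(
        np.isfinite(period)
        and rel_amp >= rel_amplitude_min
        and ratio >= peak_median_ratio
    )
    return OscillationVerdict(
        oscillating=oscillating,
        period=period if oscillating else None,
        method="fft",
        evidence={
            "peak_power": peak,
            "relative_amplitude": rel_amp,
            "peak_median_ratio": ratio,
            "window_hours": tail.size * dt,
        },
    )


# ---------------------------------------------------------------------------
# event-location detector
# ---------------------------------------------------------------------------


def detect_oscillation_events(rhs: Callable, y0, args=(),
                              horizon: float = EVENT_HORIZON,
                              component: int = 0,
                              gap_tol: float = EVENT_GAP_TOL,
                              mean_dt: float = 0.05,
                              rtol: float = 1e-6, atol: float = 1e-9
                              ) -> OscillationVerdict:
    """Two-pass event-location oscillation test.

    Pass one integrates over ``horizon`` and takes the mean of the selected
    component on a uniform grid.  Pass two re-integrates with the solver's
    event machinery recording every time the component crosses that mean
    with positive slope.  The run is oscillating iff at least three events
    occurred and the last three satisfy ``|(te1-te2) - (te2-te3)| < gap_tol``;
    the period estimate is ``te1 - te2``.
    """
    y0 = np.asarray(y0, dtype=float)
    t_eval = np.arange(0.0, horizon + mean_dt / 2, mean_dt)
    first = integrate(rhs, y0, (0.0, horizon), t_eval=t_eval, args=args,
                      rtol=rtol, atol=atol)
    level = float(first.values[:, component].mean())

    def crossing(t, y, *a):
        return y[component] - level

    crossing.direction = 1.0
    sol = solve_ivp(rhs, (0.0, horizon), y0, args=args or None, rtol=rtol,
                    atol=atol, method="LSODA", events=crossing, dense_output=False)
    if not sol.success:
        raise IntegrationError(f"solver failed: {sol.message}")
    times = sol.t_events[0]
    return _event_verdict(times, level, gap_tol)


def _event_verdict(times: np.ndarray, level: float,
                   gap_tol: float) -> OscillationVerdict:
    times = np.asarray(times, dtype=float)
    if times.size < 3:
        return OscillationVerdict(False, None, "events",
                                  {"n_events": int(times.size), "level": level})
    te1, te2, te3 = times[-1], times[-2], times[-3]
    gap_diff = abs((te1 - te2) - (te2 - te3))
    oscillating = bool(gap_diff < gap_tol)
    return OscillationVerdict(
        oscillating=oscillating,
        period=(te1 - te2) if oscillating else None,
        method="events",
        evidence={
            "event_times": times[-3:],
            "gap_difference": float(gap_diff),
            "level": level,
            "n_events": int(times.size),
        },
    )


# ---------------------------------------------------------------------------
# phase durations
# ---------------------------------------------------------------------------


def phase_durations(times, series, prominence: Optional[float] = None):
    """(tau1, tau2): rise (trough->peak) and fall (peak->trough) durations.

    Measured on the last complete cycle of the series; the input must
    contain at least two full cycles after transient removal.
    """
    from scipy.signal import find_peaks

    times = np.asarray(times, dtype=float)
    series = np.asarray(series, dtype=float)
    if prominence is None:
        prominence = 0.05 * (series.max() - series.min())
    if prominence <= 0:
        raise NonOscillatoryError("series is flat")
    peaks, _ = find_peaks(series, prominence=prominence)
    troughs, _ = find_peaks(-series, prominence=prominence)
    if peaks.size < 2 or troughs.size < 2:
        raise NonOscillatoryError(
            f"need >= 2 peaks and troughs, found {peaks.size}/{troughs.size}"
        )
    t_peaks = times[peaks]
    t_troughs = times[troughs]
    # last trough that is followed by a peak and then another trough
    for t_tr in t_troughs[::-1]:
        after_peak = t_peaks[t_peaks > t_tr]
        if not after_peak.size:
            continue
        t_pk = after_peak[0]
        after_tr = t_troughs[t_troughs > t_pk]
        if not after_tr.size:
            continue
        return float(t_pk - t_tr), float(after_tr[0] - t_pk)
    raise NonOscillatoryError("no complete trough->peak->trough cycle found")


# ---------------------------------------------------------------------------
# compiled batch variants
# ---------------------------------------------------------------------------

_RHS_KERNELS = {
    "core": _kernels.rhs_core,
    "ttfl": _kernels.rhs_ttfl,
    "chain": _kernels.rhs_chain,
    "detailed": _kernels.rhs_detailed,
    "network": _kernels.rhs_network,
}

MAX_STEPS = 5_000_000


def integrate_fast(model: str, pvec, y0, tgrid, rtol=1e-6, atol=1e-9):
    """Grid integration through the compiled DP5(4) driver."""
    rhs = _RHS_KERNELS[model]
    Y, ok = _kernels.integrate_grid(rhs, np.asarray(pvec, float),
                                    np.asarray(y0, float),
                                    np.asarray(tgrid, float), rtol, atol,
                                    MAX_STEPS)
    if not ok:
        raise IntegrationError(f"compiled integration failed for {model}")
    return Y


def batch_classify_fft(model: str, param_rows: np.ndarray, y0_rows: np.ndarray,
                       t_end: float, dt: float, component: int,
                       rtol=1e-6, atol=1e-9,
                       transient_fraction=TRANSIENT_FRACTION,
                       rel_amplitude_min=REL_AMPLITUDE_MIN,
                       peak_median_ratio=PEAK_MEDIAN_RATIO):
    """FFT-classify many parameter rows; returns (oscillating, period) arrays.

    Rows whose integration fails count as non-oscillating (flagged by a NaN
    period *and* False verdict; failures are rare and logged by callers).
    """
    rhs = _RHS_KERNELS[model]
    tgrid = np.arange(0.0, t_end + dt / 2, dt)
    n = param_rows.shape[0]
    osc = np.zeros(n, dtype=bool)
    periods = np.full(n, np.nan)
    start = int(transient_fraction * tgrid.size)
    tails = np.empty((n, tgrid.size - start))
    ok_rows = np.zeros(n, dtype=bool)
    for i in range(n):
        Y, ok = _kernels.integrate_grid(rhs, param_rows[i], y0_rows[i], tgrid,
                                        rtol, atol, MAX_STEPS)
        ok_rows[i] = ok
        if ok:
            tails[i] = Y[start:, component]
    if not np.any(ok_rows):
        return osc, periods
    idx = np.where(ok_rows)[0]
    block = tails[idx]
    mu = block.mean(axis=1, keepdims=True)
    spec = np.abs(np.fft.rfft(block - mu, axis=1))
    freqs = np.fft.rfftfreq(block.shape[1], dt)
    k = np.argmax(spec[:, 1:], axis=1) + 1
    rows = np.arange(idx.size)
    peak = spec[rows, k]
    med = np.median(spec[:, 1:], axis=1)
    rel_amp = 2.0 * peak / block.shape[1] / np.maximum(np.abs(mu[:, 0]), 1e-300)
    good = (rel_amp >= rel_amplitude_min) & (peak >= peak_median_ratio * med)
    # parabolic refinement
    kk = np.clip(k, 1, spec.shape[1] - 2)
    pm = spec[rows, kk - 1]
    p0 = spec[rows, kk]
    pp = spec[rows, kk + 1]
    denom = pm - 2.0 * p0 + pp
    shift = np.where(denom < 0, 0.5 * (pm - pp) / np.where(denom == 0, 1, denom), 0.0)
    f_peak = freqs[k] + shift * (freqs[1] - freqs[0])
    with np.errstate(divide="ignore"):
        per = np.where(f_peak > 0, 1.0 / f_peak, np.nan)
    osc[idx] = good
    periods[idx[good]] = per[good]
    return osc, periods


def batch_classify_events(model: str, param_rows: np.ndarray,
                          y0_rows: np.ndarray,
                          horizon: float = EVENT_HORIZON, component: int = 0,
                          gap_tol: float = EVENT_GAP_TOL,
                          mean_dt: float = 0.05,
                          rtol=1e-6, atol=1e-9, max_events: int = 512):
    """Event-classify many parameter rows with the compiled two-pass
    procedure; returns (oscillating, period) arrays."""
    rhs = _RHS_KERNELS[model]
    n = param_rows.shape[0]
    osc = np.zeros(n, dtype=bool)
    periods = np.full(n, np.nan)
    buf = np.empty(max_events)
    for i in range(n):
        level, ok = _kernels.series_mean(rhs, param_rows[i], y0_rows[i], 0.0,
                                         horizon, component, mean_dt, rtol,
                                         atol, MAX_STEPS)
        if not ok:
            continue
        nev, ok = _kernels.upward_crossings(rhs, param_rows[i], y0_rows[i],
                                            0.0, horizon, level, component,
                                            rtol, atol, MAX_STEPS, buf)
        if not ok or nev < 3:
            continue
        te1, te2, te3 = buf[nev - 1], buf[nev - 2], buf[nev - 3]
        if abs((te1 - te2) - (te2 - te3)) < gap_tol:
            osc[i] = True
            periods[i] = te1 - te2
    return osc, periods
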