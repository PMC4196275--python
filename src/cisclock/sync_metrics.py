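"""Synchronization and oscillation measurements.

Two complementary measures quantify synchrony on the lattice:

* the neighbor correlation function ``C(t)`` -- for each cell the
  deviation of its concentration from the population mean is multiplied
  by the deviation of the average concentration of its neighbors, and
  the products are averaged over cells.  C falls to zero under perfect
  synchronization, oscillates otherwise, and turns negative for
  anti-synchronized (salt-and-pepper) configurations;
* the order parameter ``R`` -- modulus of the mean unit phasor over the
  per-cell oscillation phases, 1 at perfect synchrony and ~n^-1/2 for
  incoherent populations.  Phases are obtained by piecewise-linear
  interpolation between successive peaks of each cell's time series
  (2*pi per cycle).

Periods are mean peak-to-peak intervals after burn-in; a trace is
flagged damped when the cycle amplitudes of its mean field decay
persistently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .tissue import Tissue

__all__ = [
    "SyncReport", "correlation_C", "phase_series", "order_R",
    "estimate_period_amplitude", "classify_outcome", "compute_sync_report",
    "time_to_sync",
]

OUTCOMES = ("synchronized", "waves", "anti_synchronized", "damped")


def correlation_C(snapshot: np.ndarray, tissue: Tissue,
                  normalized: bool = False) -> float:
    """Neighbor correlation of one lattice snapshot.

    ``C = (1/M) * sum_i (c_i - cbar) * (mean_{j in nb(i)} c_j - cbar)``
    with ``cbar`` the population mean.  Zero for uniform snapshots,
    negative for checkerboards.  With ``normalized=True`` the value is
    divided by the spatial variance (for cross-size comparison; 0 is
    returned for uniform snapshots).
    """
    snapshot = np.asarray(snapshot, dtype=float)
    if snapshot.shape != (tissue.n_cells,):
        raise ValueError(
            f"snapshot must cover all {tissue.n_cells} cells; got {snapshot.shape}")
    if tissue.n_cells < 2:
        raise ValueError("correlation requires at least 2 cells")
    dev = snapshot - snapshot.mean()
    nb_dev = tissue.W @ snapshot - snapshot.mean()
    c = float(np.mean(dev * nb_dev))
    if normalized:
        var = float(np.mean(dev ** 2))
        return c / var if var > 0 else 0.0
    return c


def phase_series(values: np.ndarray, times: np.ndarray,
                 min_prominence_frac: float = 0.05) -> np.ndarray:
    """Per-cell oscillation phase at every time (radians).

    ``values`` is (n_times, n_cells).  For each cell, peaks of its series
    define phase multiples of 2*pi; between peaks the phase grows
    linearly.  Before the first / after the last peak the phase is
    extrapolated with the cell's mean period.  Cells with fewer than two
    peaks get NaN phases (non-oscillating).
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    n_t, n_cells = values.shape
    phases = np.full((n_t, n_cells), np.nan)
    for c in range(n_cells):
        x = values[:, c]
        prom = min_prominence_frac * (x.max() - x.min())
        if prom <= 0:
            continue
        peaks, _ = find_peaks(x, prominence=prom)
        if len(peaks) < 2:
            continue
        t_pk = times[peaks]
        # cycle index k at peak k; phase = 2*pi * interpolated cycle coordinate
        cycle = np.interp(times, t_pk, np.arange(len(t_pk), dtype=float))
        period = np.diff(t_pk).mean()
        before = times < t_pk[0]
        after = times > t_pk[-1]
        cycle[before] = (times[before] - t_pk[0]) / period
        cycle[after] = (len(t_pk) - 1) + (times[after] - t_pk[-1]) / period
        phases[:, c] = 2.0 * np.pi * cycle
    return phases


def order_R(window: np.ndarray, times: np.ndarray | None = None,
            ) -> tuple[float, bool]:
    """Kuramoto order parameter of a per-cell window (n_times, n_cells).

    Returns ``(R, confident)`` where ``R`` is the modulus of the mean
    unit phasor of the per-cell phases at the final time of the window.
    ``confident`` is False when any cell failed phase extraction (fewer
    than two peaks), in which case non-oscillating cells are excluded
    from the average; R is NaN if no cell oscillates.
    """
    window = np.asarray(window, dtype=float)
    if times is None:
        times = np.arange(window.shape[0], dtype=float)
    phases = phase_series(window, np.asarray(times, dtype=float))
    final = phases[-1]
    ok = np.isfinite(final)
    confident = bool(ok.all())
    if not ok.any():
        return float("nan"), False
    r = np.abs(np.exp(1j * final[ok]).mean())
    return float(r), confident


def order_R_series(values: np.ndarray, times: np.ndarray) -> np.ndarray:
    """R at every recorded time, from peak-interpolated phases."""
    phases = phase_series(np.asarray(values, dtype=float),
                          np.asarray(times, dtype=float))
    import warnings as _warnings
    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows -> NaN
        z = np.exp(1j * phases)
        r = np.abs(np.nanmean(np.where(np.isfinite(phases), z, np.nan), axis=1))
    return r


@dataclass
class PeriodAmplitude:
    period: float
    amplitude: tuple[float, float]
    damped: bool


def estimate_period_amplitude(series: np.ndarray, dt: float,
                              burn_in_min: float = 0.0,
                              damped_ratio: float = 0.98,
                              persistence: int = 4,
                              floor_frac: float = 0.02) -> PeriodAmplitude:
    """Period, amplitude range and damping flag of one time series.

    Period is the mean peak-to-peak interval after ``burn_in_min``;
    amplitude is (min, max) over the final third of the series.  The
    series is damped when the peak-to-trough cycle amplitudes decay
    persistently -- the last ``persistence`` successive amplitude ratios
    all below ``damped_ratio`` -- or when the oscillation has died
    outright (fewer than 2 peaks after burn-in, or the late cycle
    amplitude has fallen below ``floor_frac`` of the largest cycle).
    """
    series = np.asarray(series, dtype=float)
    start = int(round(burn_in_min / dt))
    if start >= len(series) - 2:
        raise ValueError("series shorter than burn-in")
    x = series[start:]
    span = x.max() - x.min()
    final = x[2 * len(x) // 3:]
    amplitude = (float(final.min()), float(final.max()))
    if span <= 0:
        return PeriodAmplitude(float("nan"), amplitude, True)
    peaks, _ = find_peaks(x, prominence=0.02 * span)
    troughs, _ = find_peaks(-x, prominence=0.02 * span)
    if len(peaks) < 2:
        return PeriodAmplitude(float("nan"), amplitude, True)
    period = float(np.diff(peaks).mean() * dt)
    # cycle amplitude: peak height minus the next trough
    amps = []
    for pk in peaks:
        later = troughs[troughs > pk]
        if len(later):
            amps.append(x[pk] - x[later[0]])
    amps = np.asarray(amps)
    damped = False
    if len(amps) >= 2:
        if amps[-1] < floor_frac * amps.max():
            damped = True
        ratios = amps[1:] / np.maximum(amps[:-1], 1e-300)
        k = min(persistence, len(ratios))
        if k >= 2 and np.all(ratios[-k:] < damped_ratio):
            damped = True
    return PeriodAmplitude(period, amplitude, damped)


@dataclass
class SyncReport:
    """Synchronization summary of one simulation trace."""

    times: np.ndarray
    C_series: np.ndarray
    R_series: np.ndarray
    period: float
    amplitude: tuple[float, float]
    outcome: str
    time_to_sync: float

    def summary(self) -> dict:
        return {
            "period_min": self.period,
            "amplitude_min": self.amplitude[0],
            "amplitude_max": self.amplitude[1],
            "outcome": self.outcome,
            "time_to_sync_min": self.time_to_sync,
        }


def time_to_sync(R_series: np.ndarray, times: np.ndarray,
                 rho: float = 0.9) -> float:
    """First time R exceeds ``rho`` and stays above it to the end (inf if never)."""
    R = np.asarray(R_series, dtype=float)
    below = np.where(~(R > rho))[0]
    if len(below) == 0:
        return float(times[0])
    if below[-1] == len(R) - 1:
        return float("inf")
    return float(times[below[-1] + 1])


def classify_outcome(values: np.ndarray, times: np.ndarray, tissue: Tissue,
                     dt_record: float | None = None,
                     eps_frac: float = 0.01, rho: float = 0.9,
                     late_frac: float = 0.2, death_frac: float = 0.1) -> str:
    """Label a fixed-size lattice trace with exactly one outcome.

    * ``damped`` -- the cells oscillated early but their activity has
      died out: the cell-averaged temporal std in the late window fell
      below ``death_frac`` of its early value (this also covers decay
      into a static salt-and-pepper pattern);
    * else ``anti_synchronized`` -- late-window mean of C(t) below -eps
      (oscillating or static checkerboard);
    * else ``synchronized`` -- late-window R above ``rho`` throughout and
      |C| within eps of zero;
    * else ``waves`` -- persistent oscillation, neither coherent nor
      anti-correlated (regions locked to different phases).

    eps is ``eps_frac`` times the temporal variance of the late mean
    field (the oscillation power sets the natural scale of C), floored
    at 1e-12.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    if dt_record is None:
        dt_record = float(times[1] - times[0])
    n_t = len(times)
    n_late = max(2, int(late_frac * n_t))
    late = slice(n_t - n_late, n_t)
    early = slice(int(0.1 * n_t), int(0.1 * n_t) + max(2, n_t // 3))

    act_early = float(values[early].std(axis=0).mean())
    act_late = float(values[late].std(axis=0).mean())
    if act_early > 1e-9 and act_late < death_frac * act_early:
        return "damped"

    C_late = np.array([correlation_C(values[i], tissue)
                       for i in range(n_t - n_late, n_t)])
    mean_field = values.mean(axis=1)
    eps = max(eps_frac * float(np.var(mean_field[late])), 1e-12)
    if np.mean(C_late) < -eps:
        return "anti_synchronized"
    R = order_R_series(values, times)
    R_late = R[late]
    finite = R_late[np.isfinite(R_late)]
    if len(finite) and np.all(finite > rho) and np.mean(np.abs(C_late)) < eps:
        return "synchronized"
    return "waves"


def compute_sync_report(values: np.ndarray, times: np.ndarray, tissue: Tissue,
                        rho: float = 0.9) -> SyncReport:
    """Full synchronization report for a fixed-size lattice trace."""
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    C = np.array([correlation_C(values[i], tissue) for i in range(len(times))])
    R = order_R_series(values, times)
    dt_record = float(times[1] - times[0])
    pa = estimate_period_amplitude(values.mean(axis=1), dt_record,
                                   burn_in_min=float(times[-1]) * 0.1)
    outcome = classify_outcome(values, times, tissue, dt_record, rho=rho)
    return SyncReport(times=times, C_series=C, R_series=R, period=pa.period,
                      amplitude=pa.amplitude, outcome=outcome,
                      time_to_sync=time_to_sync(R, times, rho=rho))
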