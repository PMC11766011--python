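"""Whole-cell gating analysis: sweep features, IV/conductance, Boltzmann and
recovery fits, and group statistics.

The chain mirrors standard patch-clamp practice: signed peak detection
(inward currents negative), time to peak and 50%-decay per sweep, current
density by capacitance normalization, chord conductance
``G = I / (V - V_rev)`` normalized to its maximum, a Boltzmann fit of the
activation or availability curve, a constrained bi-exponential fit of
recovery, and unpaired two-sample t statistics.

Fits use deterministic multi-start least squares (scipy); no randomness.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .ephys_synth import TraceSet

logger = logging.getLogger(__name__)

__all__ = [
    "SweepFeatures",
    "IVCurve",
    "BoltzmannFit",
    "RecoveryFit",
    "GroupComparison",
    "sweep_features",
    "iv_curve",
    "estimate_vrev",
    "conductance_curve",
    "fit_boltzmann",
    "fit_recovery",
    "compare_groups",
    "analyze_iv",
    "analyze_availability",
    "analyze_recovery",
]


@dataclass
class SweepFeatures:
    """Signed peak, latency to peak, and 50%-decay time of one sweep (ms, pA)."""

    peak_current: float
    time_to_peak: float
    decay50: float | None
    defined: bool = True


@dataclass
class IVCurve:
    """Per-voltage peak current (pA) and current density (pA/pF)."""

    voltages: np.ndarray
    peaks: np.ndarray
    densities: np.ndarray
    capacitance: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"voltage_mV": self.voltages, "peak_pA": self.peaks,
                             "density_pA_per_pF": self.densities})


@dataclass
class BoltzmannFit:
    """Fitted half-point and slope (both mV, k > 0) with standard errors.

    ``amplitude`` is 1 for fits of pre-normalized data; pipelines that fit
    the curve maximum as a free scale report it here.
    """

    v_half: float
    k: float
    se_v_half: float
    se_k: float
    rss: float
    form: str                   # "activation" | "availability"
    n: int
    low_confidence: bool = False
    amplitude: float = 1.0
    se_amplitude: float = 0.0

    def predict(self, v):
        v = np.asarray(v, dtype=float)
        if self.form == "activation":
            return 1.0 / (1.0 + np.exp((self.v_half - v) / self.k))
        return 1.0 / (1.0 + np.exp((v - self.v_half) / self.k))


@dataclass
class RecoveryFit:
    """Bi-exponential recovery parameters with tau_fast < tau_slow enforced.

    ``amplitude`` is the fitted full-recovery level (1 unless fitted freely
    to absorb normalization error in the control peak).
    """

    a_fast: float
    tau_fast: float
    tau_slow: float
    se_a_fast: float
    se_tau_fast: float
    se_tau_slow: float
    rss: float
    n: int
    single_exponential_warning: bool = False
    amplitude: float = 1.0

    def predict(self, dt):
        dt = np.asarray(dt, dtype=float)
        return self.amplitude * (
            1.0 - self.a_fast * np.exp(-dt / self.tau_fast)
            - (1.0 - self.a_fast) * np.exp(-dt / self.tau_slow))


@dataclass
class GroupComparison:
    """Unpaired two-sample t comparison (two-sided)."""

    mean_a: float
    sem_a: float
    n_a: int
    mean_b: float
    sem_b: float
    n_b: int
    t: float
    p: float
    df: float


def sweep_features(time: np.ndarray, current: np.ndarray,
                   onset: float = 0.0) -> SweepFeatures:
    """Peak (signed extremum of |I| after onset), time to peak, and 50% decay.

    ``decay50`` is the time from the peak until |I| first returns to half the
    peak magnitude (linearly interpolated), or None when never reached.
    An all-zero trace yields a flagged, undefined feature set.
    """
    time = np.asarray(time, dtype=float)
    current = np.asarray(current, dtype=float)
    if len(time) < 10:
        raise ValueError("trace must have at least 10 samples")
    mask = time >= onset
    if not mask.any():
        raise ValueError("trace does not cover the pulse onset")
    t = time[mask]
    i = current[mask]
    if np.allclose(i, 0.0):
        return SweepFeatures(0.0, math.nan, None, defined=False)
    k = int(np.argmax(np.abs(i)))
    peak = float(i[k])
    time_to_peak = float(t[k] - onset)
    half = 0.5 * abs(peak)
    decay50 = None
    tail = np.abs(i[k:])
    below = np.flatnonzero(tail <= half)
    if len(below):
        j = below[0]
        if j == 0:
            decay50 = 0.0
        else:
            t0, t1 = t[k + j - 1], t[k + j]
            y0, y1 = tail[j - 1], tail[j]
            frac = (y0 - half) / (y0 - y1) if y0 != y1 else 1.0
            decay50 = float(t0 + frac * (t1 - t0) - t[k])
    return SweepFeatures(peak, time_to_peak, decay50)


def iv_curve(traces: TraceSet, capacitance: float) -> IVCurve:
    """Per-voltage peak current and current density (peak / capacitance)."""
    if capacitance <= 0:
        raise ValueError(f"capacitance must be positive, got {capacitance}")
    voltages = np.array(sorted(traces.sweeps))
    peaks = np.array([sweep_features(traces.time, traces.sweeps[v]).peak_current
                      for v in voltages])
    return IVCurve(voltages, peaks, peaks / capacitance, capacitance)


def estimate_vrev(iv: IVCurve) -> float:
    """Reversal potential by linear interpolation at the most depolarized
    zero crossing of the IV curve."""
    v, i = iv.voltages, iv.peaks
    zero = np.flatnonzero(i == 0.0)
    crossing = None
    for j in range(len(v) - 1):
        if i[j] * i[j + 1] < 0:
            crossing = j
    if crossing is None:
        if len(zero):
            return float(v[zero[-1]])
        raise ValueError("IV curve has no zero crossing; supply v_rev explicitly")
    j = crossing
    return float(v[j] + (0.0 - i[j]) * (v[j + 1] - v[j]) / (i[j + 1] - i[j]))


def conductance_curve(iv: IVCurve, v_rev: float,
                      exclusion_window: float = 5.0) -> pd.DataFrame:
    """Chord conductance ``G = I/(V - v_rev)`` normalized by its maximum.

    Voltages within ``exclusion_window`` mV of ``v_rev`` are dropped with a
    warning (the chord transform is ill-conditioned there).
    """
    keep = np.abs(iv.voltages - v_rev) > exclusion_window
    if not keep.all():
        logger.warning("dropped %d IV points within %.1f mV of v_rev",
                       int((~keep).sum()), exclusion_window)
    v = iv.voltages[keep]
    g = iv.peaks[keep] / (v - v_rev)
    g_max = g.max()
    if g_max <= 0:
        logger.warning("all-zero conductance curve; normalization undefined")
        g_norm = np.zeros_like(g)
    else:
        g_norm = g / g_max
    return pd.DataFrame({"voltage_mV": v, "g_nS": g, "g_norm": g_norm})


def _boltzmann(form: str):
    if form == "activation":
        return lambda v, v_half, k: 1.0 / (1.0 + np.exp((v_half - v) / k))
    if form == "availability":
        return lambda v, v_half, k: 1.0 / (1.0 + np.exp((v - v_half) / k))
    raise ValueError(f"unknown Boltzmann form {form!r}")


def fit_boltzmann(voltages, y, form: str = "activation",
                  free_amplitude: bool = False) -> BoltzmannFit:
    """Least-squares Boltzmann fit with deterministic multi-start initialization.

    Starts: v_half at the sample closest to half-maximum; k in {2, 5, 10} mV.
    Best residual sum of squares wins; ties prefer the smallest k.  Data not
    spanning both tails (min y > 0.3 or max y < 0.7 of the amplitude) or
    fewer than 5 points set the low-confidence flag.

    With ``free_amplitude`` the model is ``A * boltzmann(V)`` with the scale
    fitted too — the standard way to estimate the curve maximum from the fit
    rather than from the noisiest single point.
    """
    v = np.asarray(voltages, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(v) != len(y) or len(v) < 3:
        raise ValueError("need at least 3 (V, y) pairs")
    func = _boltzmann(form)
    amp0 = float(y[np.argmax(np.abs(y))]) if free_amplitude else 1.0
    if amp0 == 0.0:
        amp0 = 1.0
    scaled = y / amp0 if free_amplitude else y
    low_confidence = bool(len(v) < 5 or scaled.min() > 0.3 or scaled.max() < 0.7)
    v_half0 = float(v[np.argmin(np.abs(scaled - 0.5))])
    best = None
    for k0 in (2.0, 5.0, 10.0):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                if free_amplitude:
                    model = lambda vv, v_half, k, a: a * func(vv, v_half, k)
                    popt, pcov = optimize.curve_fit(
                        model, v, y, p0=[v_half0, k0, amp0],
                        bounds=([-np.inf, 1e-3, -np.inf], [np.inf, 1e3, np.inf]),
                        maxfev=10000)
                else:
                    popt, pcov = optimize.curve_fit(
                        func, v, y, p0=[v_half0, k0],
                        bounds=([-np.inf, 1e-3], [np.inf, 1e3]), maxfev=10000)
        except RuntimeError:
            continue
        amp = popt[2] if free_amplitude else 1.0
        rss = float(np.sum((amp * func(v, popt[0], popt[1]) - y) ** 2))
        if best is None or rss < best[0] - 1e-12 or (
                abs(rss - best[0]) <= 1e-12 and popt[1] < best[1][1]):
            best = (rss, popt, pcov)
    if best is None:
        raise RuntimeError(
            f"Boltzmann fit failed to converge from all starts "
            f"(n={len(v)}, y range {y.min():.3g}..{y.max():.3g})")
    rss, popt, pcov = best
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    return BoltzmannFit(
        v_half=float(popt[0]), k=float(popt[1]),
        se_v_half=float(se[0]), se_k=float(se[1]),
        rss=rss, form=form, n=len(v), low_confidence=low_confidence,
        amplitude=float(popt[2]) if free_amplitude else 1.0,
        se_amplitude=float(se[2]) if free_amplitude else 0.0)


def _recovery_model(dt, a_fast, tau_fast, tau_slow):
    return (1.0 - a_fast * np.exp(-dt / tau_fast)
            - (1.0 - a_fast) * np.exp(-dt / tau_slow))


def fit_recovery(intervals, fractions, free_amplitude: bool = False) -> RecoveryFit:
    """Constrained bi-exponential fit of recovery from inactivation.

    ``R(dt) = 1 - a_fast*exp(-dt/tau_fast) - (1-a_fast)*exp(-dt/tau_slow)``
    with a_fast in [0, 1] and tau_fast < tau_slow (components swapped after
    the fit when needed).  ``free_amplitude`` multiplies the model by a
    fitted full-recovery level, absorbing normalization error of the
    control peak.  A tau ratio below 3 flags effectively single-exponential
    data; degenerate (all-recovered) data returns a flagged trivial fit.
    """
    dt = np.asarray(intervals, dtype=float)
    y = np.asarray(fractions, dtype=float)
    if len(dt) < 6:
        raise ValueError("need at least 6 recovery intervals")
    if dt.max() / max(dt.min(), 1e-12) < 10.0:
        raise ValueError("recovery intervals must span at least one decade")
    if np.allclose(y, 1.0, atol=1e-6):
        logger.warning("degenerate recovery data (all points fully recovered)")
        return RecoveryFit(0.5, dt.min(), dt.max(), math.nan, math.nan, math.nan,
                           rss=float(np.sum((y - 1.0) ** 2)), n=len(dt),
                           single_exponential_warning=True)
    span = dt.max()
    starts = [(0.5, 0.05 * span, 0.5 * span),
              (0.5, 0.01 * span, 0.2 * span),
              (0.8, 0.02 * span, 0.8 * span)]
    if free_amplitude:
        model = lambda t, a, tf, ts, amp: amp * _recovery_model(t, a, tf, ts)
        bounds = ([0.0, 1e-6, 1e-6, 0.1], [1.0, 1e6, 1e6, 10.0])
        starts = [p0 + (1.0,) for p0 in starts]
    else:
        model = _recovery_model
        bounds = ([0.0, 1e-6, 1e-6], [1.0, 1e6, 1e6])
    best = None
    for p0 in starts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                popt, pcov = optimize.curve_fit(
                    model, dt, y, p0=list(p0), bounds=bounds, maxfev=20000)
        except RuntimeError:
            continue
        rss = float(np.sum((model(dt, *popt) - y) ** 2))
        if best is None or rss < best[0]:
            best = (rss, popt, pcov)
    if best is None:
        raise RuntimeError("recovery fit failed to converge from all starts")
    rss, popt, pcov = best
    a_fast, tau_fast, tau_slow = (float(x) for x in popt[:3])
    amplitude = float(popt[3]) if free_amplitude else 1.0
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    se_a, se_tf, se_ts = (float(x) for x in se[:3])
    if tau_fast > tau_slow:
        tau_fast, tau_slow = tau_slow, tau_fast
        se_tf, se_ts = se_ts, se_tf
        a_fast = 1.0 - a_fast
    warn = bool(tau_slow / max(tau_fast, 1e-12) < 3.0)
    if warn:
        logger.warning("recovery tau ratio < 3; data look single-exponential")
    return RecoveryFit(a_fast, tau_fast, tau_slow, se_a, se_tf, se_ts,
                       rss=rss, n=len(dt), single_exponential_warning=warn,
                       amplitude=amplitude)


def compare_groups(a, b) -> GroupComparison:
    """Unpaired two-sample Student t test (two-sided).

    Raw value lists use the pooled-variance statistic; ``(mean, sem, n)``
    summary tuples use the Welch-style statistic from the SEMs.
    """
    def is_summary(x):
        return isinstance(x, tuple) and len(x) == 3

    if is_summary(a) and is_summary(b):
        mean_a, sem_a, n_a = float(a[0]), float(a[1]), int(a[2])
        mean_b, sem_b, n_b = float(b[0]), float(b[1]), int(b[2])
        se2 = sem_a ** 2 + sem_b ** 2
        if se2 == 0:
            t = 0.0
            df = float(n_a + n_b - 2)
            p = 1.0
        else:
            t = (mean_a - mean_b) / math.sqrt(se2)
            df = se2 ** 2 / (sem_a ** 4 / (n_a - 1) + sem_b ** 4 / (n_b - 1))
            p = float(2.0 * stats.t.sf(abs(t), df))
    else:
        xa = np.asarray(a, dtype=float)
        xb = np.asarray(b, dtype=float)
        if len(xa) < 2 or len(xb) < 2:
            raise ValueError("need n >= 2 per group for raw value lists")
        mean_a, mean_b = float(xa.mean()), float(xb.mean())
        sem_a = float(xa.std(ddof=1) / math.sqrt(len(xa)))
        sem_b = float(xb.std(ddof=1) / math.sqrt(len(xb)))
        n_a, n_b = len(xa), len(xb)
        df = float(n_a + n_b - 2)
        if xa.std(ddof=1) == 0 and xb.std(ddof=1) == 0:
            t = 0.0
            p = 1.0 if mean_a == mean_b else 0.0
            if mean_a != mean_b:
                t = math.inf if mean_a > mean_b else -math.inf
        else:
            res = stats.ttest_ind(xa, xb, equal_var=True)
            t, p = float(res.statistic), float(res.pvalue)
    return GroupComparison(mean_a, sem_a, n_a, mean_b, sem_b, n_b, t, p, df)


# ---------------------------------------------------------------------------
# Protocol-level pipelines
# ---------------------------------------------------------------------------

def _smooth(current: np.ndarray, window: int = 5) -> np.ndarray:
    if len(current) < window:
        return current
    kernel = np.ones(window)
    # Normalize by actual window coverage so trace edges are not dragged
    # toward zero (a zero-padded boxcar fakes a decay at the last samples).
    return (np.convolve(current, kernel, mode="same")
            / np.convolve(np.ones_like(current), kernel, mode="same"))


def _robust_peak(time: np.ndarray, current: np.ndarray) -> float:
    """Noise-robust sweep peak for the conductance transform.

    The raw signed extremum of a noisy trace is biased away from zero (a
    maximum over many samples).  A lightly smoothed copy locates the peak;
    when the sweep is plateau-shaped (never decays to half the smoothed
    peak) or indistinguishable from noise, the unbiased estimate is the
    mean of the last quarter of samples; otherwise the raw extremum is kept.
    """
    smooth = _smooth(current)
    noise_sd = float(np.std(current - smooth))
    feats = sweep_features(time, smooth)
    tail_mean = float(current[3 * len(current) // 4:].mean())
    if not feats.defined:
        return 0.0
    insignificant = abs(feats.peak_current) < 6.0 * noise_sd / math.sqrt(5.0)
    # Clearly-decaying sweeps keep the raw extremum (the conventional peak);
    # everything else (plateau or noise-dominated) gets the tail mean.
    decaying = abs(tail_mean) < 0.3 * abs(feats.peak_current)
    if decaying and not insignificant:
        return sweep_features(time, current).peak_current
    return tail_mean


def _shared_peak_time(time: np.ndarray, sweeps: dict[float, np.ndarray]) -> int:
    """Index of the common peak time across same-voltage test sweeps.

    Averaging sweeps before locating the extremum suppresses noise, and
    reading every sweep at the one shared sample keeps the readout unbiased
    (no per-sweep max-selection bias).
    """
    mean_trace = np.mean([sweeps[k] for k in sweeps], axis=0)
    return int(np.argmax(np.abs(_smooth(mean_trace))))


def analyze_iv(traces: TraceSet, capacitance: float,
               v_rev: float | None = None) -> dict:
    """IV pipeline: peaks/density, reversal estimate, chord conductance,
    activation Boltzmann fit (free amplitude), and per-sweep features."""
    iv = iv_curve(traces, capacitance)
    voltages = iv.voltages
    robust = np.array([_robust_peak(traces.time, traces.sweeps[v])
                       for v in voltages])
    robust_iv = IVCurve(voltages, robust, robust / capacitance, capacitance)
    if v_rev is None:
        v_rev = estimate_vrev(robust_iv)
    curve = conductance_curve(robust_iv, v_rev)
    fit = fit_boltzmann(curve["voltage_mV"], curve["g_norm"],
                        form="activation", free_amplitude=True)
    curve = curve.assign(g_norm=curve["g_norm"] / fit.amplitude)
    feats = {v: sweep_features(traces.time, traces.sweeps[v])
             for v in sorted(traces.sweeps)}
    return {"iv": iv, "v_rev": v_rev, "conductance": curve,
            "activation_fit": fit, "features": feats}


def analyze_availability(traces: TraceSet) -> dict:
    """SSI / fast-SSI pipeline: test-pulse peaks vs prepulse voltage fitted
    with the availability Boltzmann (free amplitude).

    All test pulses share one voltage, so peaks are read at the common peak
    time of the sweep average; the curve maximum comes from the fitted
    amplitude rather than the noisiest single sweep.
    """
    voltages = np.array(sorted(traces.sweeps))
    k = _shared_peak_time(traces.time, traces.sweeps)
    peaks = np.array([traces.sweeps[v][k] for v in voltages])
    if np.abs(peaks).max() == 0:
        raise ValueError("all test-pulse peaks are zero; cannot normalize")
    fit = fit_boltzmann(voltages, peaks, form="availability", free_amplitude=True)
    y = peaks / fit.amplitude
    return {"voltages": voltages, "availability": y, "fit": fit}


def analyze_recovery(traces: TraceSet) -> dict:
    """Two-pulse recovery pipeline: test-pulse peaks normalized to the
    conditioning (label 0) peak, fitted with the bi-exponential model.
    Peaks are read at the common peak time of the sweep average."""
    if 0.0 not in traces.sweeps:
        raise ValueError("recovery trace set lacks the conditioning sweep (label 0)")
    k = _shared_peak_time(traces.time, traces.sweeps)
    control = traces.sweeps[0.0][k]
    if control == 0:
        raise ValueError("conditioning sweep peak is zero; cannot normalize")
    intervals = np.array(sorted(v for v in traces.sweeps if v > 0))
    fractions = np.array([traces.sweeps[dt][k] / control for dt in intervals])
    fit = fit_recovery(intervals, fractions, free_amplitude=True)
    return {"intervals": intervals, "fractions": fractions, "fit": fit}
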