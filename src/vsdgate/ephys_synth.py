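"""Synthetic whole-cell sodium-current sweeps from a known gating truth.

One activation gate (exponent 1) and one availability gate relax
mono-exponentially toward Boltzmann steady states; sweep current is
``I(t) = g_max * (V - v_rev) * m(t) * h(t)`` plus per-sample Gaussian
noise.  Recovery from inactivation is generated from an explicit
two-population mixture (fast/slow fractions), since a single gate cannot
produce bi-exponential recovery.  Four protocols are supported: an IV
family of depolarizing steps, steady-state inactivation with a 500 ms
prepulse, the same with a 20 ms prepulse (fast inactivation), and
two-pulse recovery.  Prepulses are applied analytically (the recorded
time base is the test pulse, with the pulse start at t = 0).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "GatingParams",
    "ProtocolSpec",
    "TraceSet",
    "gate_states",
    "simulate_protocol",
    "preset_truth",
    "preset_params",
    "PRESETS",
]

TauFunction = Callable[[np.ndarray], np.ndarray]


def default_tau_m(v):
    """Activation time constant, ms: 0.15 + 2.0*exp(-((V+45)/15)^2)."""
    v = np.asarray(v, dtype=float)
    return 0.15 + 2.0 * np.exp(-(((v + 45.0) / 15.0) ** 2))


def default_tau_h(v):
    """Inactivation time constant, ms: 1.0 + 40.0*exp(-((V+70)/20)^2)."""
    v = np.asarray(v, dtype=float)
    return 1.0 + 40.0 * np.exp(-(((v + 70.0) / 20.0) ** 2))


def constant_tau(value: float) -> TauFunction:
    def tau(v):
        return np.full_like(np.asarray(v, dtype=float), value)
    return tau


@dataclass
class GatingParams:
    """Generative truth for the synthetic currents.

    Voltages in mV, times in ms, conductance in nS, currents in pA.
    ``act_*`` parameterize the activation Boltzmann
    ``m_inf(V) = 1/(1 + exp((v_half - V)/k))``; ``inact_*`` the availability
    Boltzmann ``h_inf(V) = 1/(1 + exp((V - v_half)/k))``.
    """

    g_max: float = 50.0
    v_rev: float = 40.0
    act_v_half: float = -38.4
    act_k: float = 5.4
    inact_v_half: float = -86.6
    inact_k: float = 5.6
    tau_m: TauFunction = field(default=default_tau_m)
    tau_h: TauFunction = field(default=default_tau_h)
    a_fast: float = 0.8
    tau_fast: float = 24.51
    tau_slow: float = 241.1
    noise_sd: float = 0.0
    capacitance: float = 9.0

    def __post_init__(self) -> None:
        if self.act_k <= 0 or self.inact_k <= 0:
            raise ValueError("slope factors must be positive")
        if not 0.0 <= self.a_fast <= 1.0:
            raise ValueError("a_fast must lie in [0, 1]")
        if self.tau_fast >= self.tau_slow:
            raise ValueError("tau_fast must be smaller than tau_slow")
        if self.g_max <= 0:
            raise ValueError("g_max must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def m_inf(self, v):
        v = np.asarray(v, dtype=float)
        return 1.0 / (1.0 + np.exp((self.act_v_half - v) / self.act_k))

    def h_inf(self, v):
        v = np.asarray(v, dtype=float)
        return 1.0 / (1.0 + np.exp((v - self.inact_v_half) / self.inact_k))

    def recovered_fraction(self, dt):
        dt = np.asarray(dt, dtype=float)
        return (1.0 - self.a_fast * np.exp(-dt / self.tau_fast)
                - (1.0 - self.a_fast) * np.exp(-dt / self.tau_slow))

    def snapshot(self) -> dict:
        keys = ("g_max", "v_rev", "act_v_half", "act_k", "inact_v_half", "inact_k",
                "a_fast", "tau_fast", "tau_slow", "noise_sd", "capacitance")
        return {k: getattr(self, k) for k in keys}


def gate_states(params: GatingParams, v: float, t, m0: float, h0: float):
    """Closed-form gate values after ``t`` ms at voltage ``v`` from (m0, h0)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    m_inf = params.m_inf(v)
    h_inf = params.h_inf(v)
    m = m_inf + (m0 - m_inf) * np.exp(-t / params.tau_m(np.asarray(v)))
    h = h_inf + (h0 - h_inf) * np.exp(-t / params.tau_h(np.asarray(v)))
    return m, h


@dataclass
class ProtocolSpec:
    """Voltage-protocol description; construct via the classmethods."""

    kind: str                       # IV | SSI | FAST_SSI | RECOVERY
    holding: float = -100.0
    sample_rate: float = 20.0       # kHz (samples per ms)
    test_voltage: float = -15.0
    test_duration: float = 20.0     # ms
    prepulse_duration: float = 0.0  # ms (SSI/FAST_SSI)
    voltages: np.ndarray | None = None
    intervals: np.ndarray | None = None
    conditioning_voltage: float = -15.0
    conditioning_duration: float = 500.0

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.voltages is not None:
            self.voltages = np.asarray(self.voltages, dtype=float)
        if self.intervals is not None:
            self.intervals = np.asarray(self.intervals, dtype=float)

    @classmethod
    def iv(cls, v_start: float = -80.0, v_stop: float = 60.0, v_step: float = 5.0,
           duration: float = 40.0, holding: float = -100.0,
           sample_rate: float = 20.0) -> "ProtocolSpec":
        n = (v_stop - v_start) / v_step
        if abs(n - round(n)) > 1e-9:
            raise ValueError("voltage step must divide the span exactly")
        voltages = v_start + v_step * np.arange(int(round(n)) + 1)
        return cls(kind="IV", holding=holding, sample_rate=sample_rate,
                   test_duration=duration, voltages=voltages)

    @classmethod
    def ssi(cls, prepulse_duration: float = 500.0, v_start: float = -120.0,
            v_stop: float = 10.0, v_step: float = 5.0, test_voltage: float = -15.0,
            test_duration: float = 20.0, holding: float = -100.0,
            sample_rate: float = 20.0) -> "ProtocolSpec":
        n = (v_stop - v_start) / v_step
        if abs(n - round(n)) > 1e-9:
            raise ValueError("voltage step must divide the span exactly")
        voltages = v_start + v_step * np.arange(int(round(n)) + 1)
        kind = "SSI" if prepulse_duration >= 100.0 else "FAST_SSI"
        return cls(kind=kind, holding=holding, sample_rate=sample_rate,
                   test_voltage=test_voltage, test_duration=test_duration,
                   prepulse_duration=prepulse_duration, voltages=voltages)

    @classmethod
    def fast_ssi(cls, **kwargs) -> "ProtocolSpec":
        kwargs.setdefault("prepulse_duration", 20.0)
        return cls.ssi(**kwargs)

    @classmethod
    def recovery(cls, intervals=None, conditioning_voltage: float = -15.0,
                 conditioning_duration: float = 500.0, test_voltage: float = -15.0,
                 test_duration: float = 20.0, holding: float = -100.0,
                 sample_rate: float = 20.0) -> "ProtocolSpec":
        if intervals is None:
            intervals = np.geomspace(1.0, 5000.0, 16)
        return cls(kind="RECOVERY", holding=holding, sample_rate=sample_rate,
                   test_voltage=test_voltage, test_duration=test_duration,
                   intervals=np.asarray(intervals, dtype=float),
                   conditioning_voltage=conditioning_voltage,
                   conditioning_duration=conditioning_duration)

    @property
    def time(self) -> np.ndarray:
        """Shared sweep time base, ms, starting at the pulse onset (t = 0)."""
        n = int(round(self.test_duration * self.sample_rate)) + 1
        return np.arange(n) / self.sample_rate

    def sweep_labels(self) -> np.ndarray:
        if self.kind == "RECOVERY":
            return np.concatenate([[0.0], self.intervals])  # 0 = conditioning pulse
        return self.voltages

    def to_dict(self) -> dict:
        out = {"kind": self.kind, "holding": self.holding,
               "sample_rate": self.sample_rate, "test_voltage": self.test_voltage,
               "test_duration": self.test_duration,
               "prepulse_duration": self.prepulse_duration,
               "conditioning_voltage": self.conditioning_voltage,
               "conditioning_duration": self.conditioning_duration}
        if self.voltages is not None:
            out["voltages"] = self.voltages.tolist()
        if self.intervals is not None:
            out["intervals"] = self.intervals.tolist()
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "ProtocolSpec":
        data = dict(data)
        if "voltages" in data:
            data["voltages"] = np.asarray(data["voltages"], dtype=float)
        if "intervals" in data:
            data["intervals"] = np.asarray(data["intervals"], dtype=float)
        return cls(**data)


@dataclass
class TraceSet:
    """Protocol-tagged sweeps on a shared time base, plus the generating truth."""

    protocol: ProtocolSpec
    time: np.ndarray
    sweeps: dict[float, np.ndarray]
    truth: dict
    seed: int | None = None

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sweeps.values()}
        if len(lengths) > 1:
            raise ValueError("all sweeps must have equal length")
        if self.time[0] != 0.0:
            raise ValueError("time base must start at the pulse onset (t = 0)")

    def to_frame(self) -> pd.DataFrame:
        """Long format: sweep_id, voltage_or_interval, time_ms, current_pA."""
        frames = []
        for sweep_id, (label, current) in enumerate(self.sweeps.items()):
            frames.append(pd.DataFrame({
                "sweep_id": sweep_id,
                "voltage_or_interval": label,
                "time_ms": self.time,
                "current_pA": current,
            }))
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path, sidecar_path=None) -> None:
        self.to_frame().to_csv(path, index=False)
        if sidecar_path is not None:
            meta = {"protocol": self.protocol.to_dict(), "truth": self.truth,
                    "seed": self.seed}
            with open(sidecar_path, "w") as fh:
                json.dump(meta, fh, indent=2)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, protocol: ProtocolSpec,
                   truth: dict | None = None, seed: int | None = None) -> "TraceSet":
        sweeps: dict[float, np.ndarray] = {}
        time = None
        for label, group in frame.groupby("voltage_or_interval", sort=False):
            group = group.sort_values("time_ms")
            sweeps[float(label)] = group["current_pA"].to_numpy(dtype=float)
            if time is None:
                time = group["time_ms"].to_numpy(dtype=float)
        return cls(protocol, time, sweeps, truth or {}, seed)


def _sweep_current(params: GatingParams, v: float, t: np.ndarray,
                   m0: float, h0: float) -> np.ndarray:
    m, h = gate_states(params, v, t, m0, h0)
    return params.g_max * (v - params.v_rev) * m * h


def simulate_protocol(params: GatingParams, protocol: ProtocolSpec,
                      seed: int | None = None) -> TraceSet:
    """Generate one :class:`TraceSet` under a protocol from the gating truth.

    IV sweeps step from holding; SSI/FAST_SSI relax h analytically over the
    prepulse before the test pulse; RECOVERY scales availability at the test
    pulse by the two-population recovered fraction (sweep label 0 is the
    conditioning/control pulse).  Noise is seeded Gaussian per sample.
    """
    rng = np.random.default_rng(seed)
    t = protocol.time
    m_hold = float(params.m_inf(protocol.holding))
    h_hold = float(params.h_inf(protocol.holding))
    sweeps: dict[float, np.ndarray] = {}

    if protocol.kind == "IV":
        for v in protocol.voltages:
            sweeps[float(v)] = _sweep_current(params, float(v), t, m_hold, h_hold)
    elif protocol.kind in ("SSI", "FAST_SSI"):
        # h relaxes analytically over the prepulse; the test pulse starts
        # from holding-state activation (brief repolarization gap), so all
        # test sweeps share identical kinetics scaled by availability.
        length = protocol.prepulse_duration
        for vpre in protocol.voltages:
            h_inf_pre = float(params.h_inf(vpre))
            tau_pre = float(params.tau_h(np.asarray(float(vpre))))
            h_start = h_inf_pre + (h_hold - h_inf_pre) * np.exp(-length / tau_pre)
            sweeps[float(vpre)] = _sweep_current(
                params, protocol.test_voltage, t, m_hold, float(h_start))
    elif protocol.kind == "RECOVERY":
        # Label 0: control/conditioning pulse from full holding availability.
        sweeps[0.0] = _sweep_current(params, protocol.conditioning_voltage, t,
                                     m_hold, h_hold)
        for dt in protocol.intervals:
            frac = float(params.recovered_fraction(dt))
            sweeps[float(dt)] = _sweep_current(params, protocol.test_voltage, t,
                                               m_hold, frac * h_hold)
    else:
        raise ValueError(f"unknown protocol kind {protocol.kind!r}")

    if params.noise_sd > 0:
        for label in sweeps:
            sweeps[label] = sweeps[label] + rng.normal(
                0.0, params.noise_sd, size=len(t))

    return TraceSet(protocol=protocol, time=t, sweeps=sweeps,
                    truth=params.snapshot(), seed=seed)


# ---------------------------------------------------------------------------
# Shipped presets: WT and R219E gating truths (activation / availability /
# fast availability / recovery parameter sets).
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PresetTruth:
    act_v_half: float
    act_k: float
    inact_v_half: float
    inact_k: float
    fast_inact_v_half: float
    fast_inact_k: float
    a_fast: float
    tau_fast: float
    tau_slow: float


PRESETS: dict[str, PresetTruth] = {
    "WT": PresetTruth(act_v_half=-38.4, act_k=5.4,
                      inact_v_half=-86.6, inact_k=5.6,
                      fast_inact_v_half=-65.9, fast_inact_k=8.5,
                      a_fast=0.8, tau_fast=24.51, tau_slow=241.1),
    "R219E": PresetTruth(act_v_half=-46.1, act_k=5.8,
                         inact_v_half=-92.0, inact_k=5.5,
                         fast_inact_v_half=-77.0, fast_inact_k=9.8,
                         a_fast=0.8, tau_fast=59.12, tau_slow=404.7),
}


def preset_truth(name: str) -> PresetTruth:
    try:
        return PRESETS[name.upper() if name.upper() in PRESETS else name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")


def preset_params(name: str, protocol_kind: str = "IV",
                  noise_sd: float = 0.0) -> GatingParams:
    """Gating truth for a preset, tuned per protocol.

    ``IV`` freezes inactivation during the brief test pulse (very slow
    tau_h) so the extracted conductance curve equals the generating
    activation Boltzmann; ``FAST_SSI`` swaps in the fast-inactivation
    Boltzmann with a short constant tau_h so the 20 ms prepulse
    equilibrates; ``SSI`` and ``RECOVERY`` use the default voltage-dependent
    time constants (the 500 ms prepulse equilibrates against them).
    """
    truth = preset_truth(name)
    base = dict(act_v_half=truth.act_v_half, act_k=truth.act_k,
                inact_v_half=truth.inact_v_half, inact_k=truth.inact_k,
                a_fast=truth.a_fast, tau_fast=truth.tau_fast,
                tau_slow=truth.tau_slow, noise_sd=noise_sd)
    kind = protocol_kind.upper().replace("-", "_")
    if kind == "IV":
        return GatingParams(**base, tau_h=constant_tau(1e4))
    if kind == "FAST_SSI":
        base.update(inact_v_half=truth.fast_inact_v_half,
                    inact_k=truth.fast_inact_k)
        return GatingParams(**base, tau_h=constant_tau(1.5))
    if kind in ("SSI", "RECOVERY"):
        return GatingParams(**base)
    raise ValueError(f"unknown protocol kind {protocol_kind!r}")
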