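"""Intrinsic excitability and AP-waveform analysis of current-clamp traces.

Implements the measurements behind passive membrane properties (RMP, input
resistance, capacitance via the membrane time constant), ramp-evoked firing
(spike count, rheobase), and per-spike waveform features gauged on the
phase-plane plot (threshold, amplitude, half-width, maximal rise slope,
fast afterhyperpolarization).

Conventions
-----------
* Spike detection: upward crossing of a dV/dt criterion (default
  20 mV/ms) with refractory enforcement (default 2 ms).
* AP threshold: the voltage at which the slope of the phase-plane curve
  (dV/dt as a function of V, restricted to the upstroke) is maximal.
* AP amplitude is threshold-to-peak; fAHP amplitude is referenced to
  threshold and its delay to the AP peak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import curve_fit
from scipy.signal import savgol_filter

from .errors import (ContaminatedBaselineError, FitError, ProtocolError,
                     ThresholdUndefinedError, UndefinedRatioError)
from .trace import ProtocolSpec, Trace

__all__ = [
    "SpikeSegment", "SpikeFeatures", "PassiveProps", "RampResult",
    "SpikeDetectConfig", "measure_rmp", "detect_spikes", "ap_threshold",
    "ap_features", "analyze_ramp", "passive_from_step",
]


@dataclass
class SpikeDetectConfig:
    """Detection and gauging configuration (all exposed, defaults
    conventional)."""

    dvdt_threshold: float = 20.0     # mV/ms upward-crossing criterion
    refractory_ms: float = 2.0
    pre_peak_ms: float = 5.0         # segment span before the AP peak
    post_peak_ms: float = 20.0       # segment span (and fAHP search) after
    smooth_window: int = 5           # Savitzky-Golay window, samples
    smooth_polyorder: int = 3
    upsample: int = 10               # spline refinement for phase-plane math
    min_dvdt_range: float = 10.0     # mV/ms; below -> degenerate phase plane
    # phase-plane analysis stops once dV/dt exceeds this ceiling: beyond the
    # initiation region the voltage advances many mV per sample at 20 kHz
    # and the curve's slope is no longer constrained by the data
    dvdt_ceiling: float = 50.0


@dataclass
class SpikeSegment:
    """One detected AP: samples spanning [peak − pre, peak + post]."""

    v: np.ndarray          # mV
    dt_ms: float
    peak_index: int        # index of the AP peak within v
    t_peak: float          # s, absolute
    t_cross: float         # s, absolute time of the dV/dt criterion crossing


@dataclass
class SpikeFeatures:
    """Waveform features of a single AP (units: mV, ms, mV/ms)."""

    threshold: float
    amplitude: float          # threshold to peak
    half_width: float
    max_rise_slope: float
    fahp_amp: float | None    # below threshold; None if not found
    fahp_delay: float | None  # from AP peak


@dataclass
class PassiveProps:
    """Passive membrane properties: RMP (mV), R_N (MΩ), C_m (pF),
    tau_m (ms)."""

    rmp: float | None
    r_n: float
    c_m: float
    tau_m: float


@dataclass
class RampResult:
    n_spikes: int
    rheobase: float | None     # pA; None when the ramp evokes no spike
    spike_times: list[float] = field(default_factory=list)
    from_potential: float | None = None  # mV


def measure_rmp(trace: Trace, window: tuple[float, float] = (0.0, 0.5),
                config: SpikeDetectConfig | None = None) -> float:
    """Mean voltage over a pre-stimulus baseline window (≥ 100 ms).

    Raises :class:`ContaminatedBaselineError` if spikes are detected in the
    window, or if nonzero command current overlaps it.
    """
    t0, t1 = window
    if t1 - t0 < 0.1:
        raise ValueError("baseline window must be at least 100 ms")
    sub = trace.slice(t0, t1)
    if sub.v.size == 0:
        raise ValueError("window lies outside the trace")
    if sub.i_cmd is not None and np.any(np.abs(sub.i_cmd) > 1e-9):
        raise ContaminatedBaselineError(
            "baseline window overlaps injected current")
    cfg = config or SpikeDetectConfig()
    if sub.dt * 1000.0 <= 0.1:
        # dV/dt crossings alone false-trigger on broadband noise; demand a
        # spike-sized excursion above the window median as well
        median = float(np.median(sub.v))
        spikes = [s for s in detect_spikes(sub, cfg)
                  if s.v[s.peak_index] - median > 20.0]
        if spikes:
            raise ContaminatedBaselineError(
                "spikes detected in baseline window")
    return float(sub.v.mean())


def detect_spikes(trace: Trace,
                  config: SpikeDetectConfig | None = None) -> list[SpikeSegment]:
    """Detect APs as upward dV/dt-criterion crossings with refractory
    enforcement; zero detections is a valid outcome.

    Requires dt ≤ 0.1 ms.  Each detection yields a :class:`SpikeSegment`
    spanning [peak − 5 ms, peak + 20 ms], clipped to the trace.
    """
    cfg = config or SpikeDetectConfig()
    dt_ms = trace.dt * 1000.0
    if dt_ms > 0.1 + 1e-12:
        raise ValueError("spike detection requires dt <= 0.1 ms")
    v = trace.v
    if v.size < 3:
        return []
    dvdt = np.gradient(v, dt_ms)
    above = dvdt >= cfg.dvdt_threshold
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    segments: list[SpikeSegment] = []
    last_cross_ms = -math.inf
    n_post = round(cfg.post_peak_ms / dt_ms)
    n_pre = round(cfg.pre_peak_ms / dt_ms)
    for k in crossings:
        t_cross_ms = k * dt_ms
        if t_cross_ms - last_cross_ms < cfg.refractory_ms:
            continue
        last_cross_ms = t_cross_ms
        k_peak = k + int(np.argmax(v[k:min(v.size, k + n_post)]))
        a = max(0, k_peak - n_pre)
        b = min(v.size, k_peak + n_post + 1)
        segments.append(SpikeSegment(
            v=v[a:b].copy(), dt_ms=dt_ms, peak_index=k_peak - a,
            t_peak=trace.t0 + k_peak * trace.dt,
            t_cross=trace.t0 + k * trace.dt))
    return segments


def _phase_plane(segment: SpikeSegment, cfg: SpikeDetectConfig):
    """Refined (V, dV/dt) curve on the upstroke (start to dV/dt maximum)."""
    v = segment.v[:segment.peak_index + 1]
    if v.size < max(5, cfg.smooth_window):
        raise ThresholdUndefinedError("upstroke too short for analysis")
    if cfg.smooth_window > 2:
        v = savgol_filter(v, cfg.smooth_window, cfg.smooth_polyorder)
    t = np.arange(v.size) * segment.dt_ms
    spline = CubicSpline(t, v)
    tf = np.linspace(t[0], t[-1], v.size * cfg.upsample)
    vf = spline(tf)
    df = spline(tf, 1)
    imax = int(np.argmax(df))
    vf, df = vf[:imax + 1], df[:imax + 1]
    over = np.flatnonzero(df > cfg.dvdt_ceiling)
    if over.size and over[0] > 2:
        vf, df = vf[:over[0]], df[:over[0]]
    return vf, df


def ap_threshold(segment: SpikeSegment,
                 config: SpikeDetectConfig | None = None) -> float:
    """AP threshold from the phase-plane plot.

    The first derivative of voltage is formed as a function of voltage on
    the upstroke (segment start to the dV/dt maximum); threshold is the
    voltage at which the slope of this curve, d(dV/dt)/dV, is maximal.
    The segment is spline-refined before differencing because at 20 kHz the
    voltage advances several mV per sample mid-upstroke.

    Raises :class:`ThresholdUndefinedError` for a degenerate (near-constant
    slope) phase plane, e.g. a linear voltage ramp.
    """
    cfg = config or SpikeDetectConfig()
    vv, dd = _phase_plane(segment, cfg)
    if dd.size < 3 or (dd.max() - dd.min()) < cfg.min_dvdt_range:
        raise ThresholdUndefinedError(
            "phase plane is degenerate (dV/dt nearly constant)")
    dV = np.diff(vv)
    ok = dV > 1e-9
    if not np.any(ok):
        raise ThresholdUndefinedError("no rising voltage on the upstroke")
    slope = np.diff(dd)[ok] / dV[ok]
    vmid = (0.5 * (vv[:-1] + vv[1:]))[ok]
    return float(vmid[int(np.argmax(slope))])


def ap_features(segment: SpikeSegment, threshold: float,
                config: SpikeDetectConfig | None = None) -> SpikeFeatures:
    """Gauge one AP given its threshold.

    amplitude = peak − threshold; half-width = time between the two
    crossings of threshold + amplitude/2 (linear interpolation between
    samples); max rise slope = max dV/dt on the upstroke; fAHP = threshold −
    post-peak minimum within the search window, delay from the AP peak.
    The fAHP is flagged as absent (None) when no interior minimum exists.
    """
    cfg = config or SpikeDetectConfig()
    v, dt = segment.v, segment.dt_ms
    kp = segment.peak_index
    peak = float(v[kp])
    if threshold >= peak:
        raise ValueError("threshold must lie below the AP peak")
    amplitude = peak - threshold
    half = threshold + amplitude / 2.0

    def cross_time(i0: int, i1: int) -> float:
        """Linear-interpolated crossing of `half` between samples i0, i1."""
        v0, v1 = v[i0], v[i1]
        frac = (half - v0) / (v1 - v0)
        return (i0 + frac * (i1 - i0)) * dt

    rise = np.flatnonzero((v[:kp] < half) & (v[1:kp + 1] >= half))
    fall = np.flatnonzero((v[kp:-1] >= half) & (v[kp + 1:] < half)) + kp
    if rise.size == 0 or fall.size == 0:
        raise ValueError("half-amplitude level not crossed on both flanks")
    t_up = cross_time(rise[-1], rise[-1] + 1)
    t_down = cross_time(fall[0], fall[0] + 1)
    half_width = t_down - t_up

    dvdt = np.gradient(v, dt)
    max_rise = float(dvdt[:kp + 1].max())

    n_win = min(v.size - 1, kp + round(cfg.post_peak_ms / dt))
    fahp_amp = fahp_delay = None
    if n_win > kp + 1:
        post = v[kp:n_win + 1]
        kmin = int(np.argmin(post))
        # strict interior local minimum only: a minimum on the window edge
        # or a monotone decay into a flat tail is not an afterhyperpolarization
        if (0 < kmin < post.size - 1 and post[kmin] < post[kmin - 1]
                and post[kmin] < post[kmin + 1]):
            depth = threshold - float(post[kmin])
            if depth >= 0:
                fahp_amp = depth
                fahp_delay = kmin * dt
    return SpikeFeatures(threshold=float(threshold), amplitude=amplitude,
                         half_width=half_width, max_rise_slope=max_rise,
                         fahp_amp=fahp_amp, fahp_delay=fahp_delay)


def analyze_ramp(trace: Trace, protocol: ProtocolSpec,
                 config: SpikeDetectConfig | None = None) -> RampResult:
    """Spike count and rheobase for a depolarizing current ramp.

    Rheobase is the injected current, by the linear map of time to current,
    at the first AP's dV/dt-criterion crossing.  Spike counting is
    restricted to the ramp epoch.  When the ramp evokes no spike, rheobase
    is undefined (None) and n_spikes = 0; rheobase values obtained with
    steeper ramps may be pooled externally into rheobase summaries but are
    kept out of spike-count summaries.
    """
    if protocol.kind != "ramp":
        raise ProtocolError("analyze_ramp requires a ramp protocol")
    i0 = float(protocol["i_start_pa"])
    i1 = float(protocol["i_end_pa"])
    dur = float(protocol["duration_s"])
    t_start = float(protocol.params.get(
        "t_start_s", trace.meta.get("t_start_s", 0.0)))
    segs = detect_spikes(trace, config)
    in_ramp = [s for s in segs if t_start <= s.t_cross <= t_start + dur]
    pre = trace.slice(max(trace.t0, t_start - 0.2), t_start)
    from_potential = float(pre.v.mean()) if pre.v.size else None
    if not in_ramp:
        return RampResult(n_spikes=0, rheobase=None, spike_times=[],
                          from_potential=from_potential)
    first = in_ramp[0]
    rheobase = i0 + (i1 - i0) * (first.t_cross - t_start) / dur
    return RampResult(n_spikes=len(in_ramp), rheobase=float(rheobase),
                      spike_times=[s.t_peak for s in in_ramp],
                      from_potential=from_potential)


def passive_from_step(trace: Trace, protocol: ProtocolSpec,
                      fit_tol: float = 1e-8) -> PassiveProps:
    """Passive properties from a subthreshold current step.

    R_N = steady-state ΔV/ΔI; tau_m from a single-exponential fit to the
    relaxation after step onset; C_m = tau_m / R_N.  Raises
    :class:`UndefinedRatioError` on a zero-amplitude step and
    :class:`FitError` if the exponential fit fails.
    """
    if protocol.kind not in ("step", "membrane_test"):
        raise ProtocolError("passive_from_step requires a step protocol")
    amp = float(protocol.params.get("i_step_pa", 0.0))
    if amp == 0.0:
        raise UndefinedRatioError("zero-amplitude step: R_N undefined")
    onset = float(protocol.params.get("onset_s", 0.0))
    dur = float(protocol["duration_s"])
    base = trace.slice(max(trace.t0, onset - 0.1), onset)
    if base.v.size == 0:
        raise ProtocolError("no pre-step baseline available")
    v_base = float(base.v.mean())
    steady = trace.slice(onset + 0.75 * dur, onset + dur)
    v_ss = float(steady.v.mean())
    dv = v_ss - v_base
    r_n = dv / amp * 1000.0  # mV/pA = GΩ -> MΩ
    if r_n <= 0:
        raise FitError("non-positive input resistance; response inverted?")

    relax = trace.slice(onset, onset + dur)
    t_ms = (relax.t - onset) * 1000.0
    y = relax.v

    def model(t, tau, v_inf, v0):
        return v_inf + (v0 - v_inf) * np.exp(-t / tau)

    try:
        popt, _ = curve_fit(model, t_ms, y,
                            p0=(max(1.0, abs(r_n) * 0.08), v_ss, v_base),
                            maxfev=10000)
    except RuntimeError as exc:
        raise FitError(f"exponential fit did not converge: {exc}") from exc
    tau_m = float(popt[0])
    if tau_m <= 0 or not np.isfinite(tau_m):
        raise FitError(f"non-physical time constant {tau_m}")
    c_m = tau_m / r_n * 1000.0  # ms/MΩ = nF -> pF
    rmp = v_base if trace.i_cmd is None or not np.any(
        np.abs(trace.i_cmd[:base.v.size]) > 1e-9) else None
    return PassiveProps(rmp=rmp, r_n=r_n, c_m=c_m, tau_m=tau_m)
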