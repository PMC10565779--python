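"""Adaptive-exponential integrate-and-fire (AdEx) forward model.

Stands in for recorded CA1 pyramidal cells: a single compartment with leak
(E_L, R), capacitance C, exponential spike initiation (V_T, Delta_T), hard
reset with spike-triggered and subthreshold adaptation (b, a, tau_w).
Fixed-step Euler at dt = 0.05 ms by default, matching a 20 kHz acquisition
rate.  With a = b = 0 and Delta_T -> 0 the model reduces to a leaky
integrate-and-fire cell whose subthreshold response is the analytic RC
solution; the test suite checks convergence to that limit.

Units: mV, pA, MΩ, pF, nS, ms.  Note MΩ·pF = µs, so tau_m(ms) =
R(MΩ)·C(pF)/1000; leak conductance g_L(nS) = 1000/R(MΩ).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import SimulationError
from ..trace import ProtocolSpec, Trace

__all__ = ["NeuronParams", "simulate_neuron", "build_current"]

_EXP_ARG_MAX = 30.0  # clip for the spike-initiation exponential


@dataclass
class NeuronParams:
    """AdEx parameters for a pyramidal-like cell.

    Defaults approximate a CA1 pyramidal neuron: resting potential −73 mV,
    input resistance 200 MΩ, capacitance 80 pF (membrane time constant
    16 ms), spike threshold region near −50 mV.
    """

    E_L: float = -73.0      # resting potential, mV
    R: float = 200.0        # input resistance, MΩ
    C: float = 80.0         # capacitance, pF
    V_T: float = -50.0      # spike-initiation threshold, mV
    Delta_T: float = 2.0    # slope factor, mV
    V_reset: float = -60.0  # post-spike reset, mV
    V_peak: float = 20.0    # spike cutoff, mV
    tau_w: float = 100.0    # adaptation time constant, ms
    a: float = 0.0          # subthreshold adaptation, nS
    b: float = 0.0          # spike-triggered adaptation increment, pA
    noise_sd: float = 0.0   # additive recording noise, mV

    def __post_init__(self) -> None:
        if min(self.R, self.C, self.Delta_T, self.tau_w) <= 0:
            raise ValueError("R, C, Delta_T, tau_w must be positive")
        if self.V_reset >= self.V_peak:
            raise ValueError("V_reset must lie below V_peak")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def g_L(self) -> float:
        """Leak conductance, nS."""
        return 1000.0 / self.R

    @property
    def tau_m(self) -> float:
        """Membrane time constant, ms."""
        return self.R * self.C / 1000.0


def build_current(protocol: ProtocolSpec, dt_ms: float) -> tuple[np.ndarray, float]:
    """Command-current waveform (pA) for a current-clamp protocol.

    Returns ``(i_cmd, t_start_s)`` where ``t_start_s`` is the onset of the
    active epoch (ramp/step start) within the sweep.  Ramps include a
    0.5 s zero-current pre-epoch (baseline for RMP) and 0.2 s tail unless
    the protocol overrides ``pre_s``/``post_s``.
    """
    dt_s = dt_ms / 1000.0
    if protocol.kind == "ramp":
        pre = float(protocol.params.get("pre_s", 0.5))
        post = float(protocol.params.get("post_s", 0.2))
        dur = float(protocol["duration_s"])
        n_pre = round(pre / dt_s)
        n_ramp = round(dur / dt_s)
        n_post = round(post / dt_s)
        ramp = np.linspace(float(protocol["i_start_pa"]),
                           float(protocol["i_end_pa"]), n_ramp,
                           endpoint=False)
        i = np.concatenate([np.zeros(n_pre), ramp, np.zeros(n_post)])
        return i, n_pre * dt_s
    if protocol.kind == "step":
        onset = float(protocol["onset_s"])
        dur = float(protocol["duration_s"])
        post = float(protocol.params.get("post_s", 0.1))
        n = round((onset + dur + post) / dt_s)
        i = np.zeros(n)
        k0, k1 = round(onset / dt_s), round((onset + dur) / dt_s)
        i[k0:k1] = float(protocol["i_step_pa"])
        return i, onset
    if protocol.kind == "membrane_test":
        # rendered as a small biphasic current step pair in current clamp
        amp = float(protocol.params.get("i_step_pa", -25.0))
        onset = float(protocol.params.get("onset_s", 0.1))
        dur = float(protocol.params.get("duration_s", 0.2))
        n = round((onset + 2 * dur + 0.1) / dt_s)
        i = np.zeros(n)
        k0 = round(onset / dt_s)
        k1 = round((onset + dur) / dt_s)
        k2 = round((onset + 2 * dur) / dt_s)
        i[k0:k1] = amp
        i[k1:k2] = -amp
        return i, onset
    if protocol.kind == "baseline":
        dur = float(protocol.params.get("duration_s", 1.0))
        return np.zeros(round(dur / dt_s)), 0.0
    raise SimulationError(
        f"protocol kind {protocol.kind!r} is not a current-clamp protocol")


def simulate_neuron(params: NeuronParams, protocol: ProtocolSpec,
                    seed: int = 0, dt_ms: float = 0.05) -> Trace:
    """Euler-integrate the AdEx model under a current-clamp protocol.

    Spikes are detected when V crosses ``V_peak``; the crossing sample is
    clipped to ``V_peak`` (drawing the spike), then V resets and the
    adaptation current increments by ``b``.  Recording noise (``noise_sd``)
    is added to the integrated trace so the dynamics stay deterministic;
    identical seed and inputs give an identical trace.

    Raises :class:`SimulationError` if |V| exceeds 1e4 mV.
    """
    i_cmd, t_start = build_current(protocol, dt_ms)
    n = i_cmd.size
    v = np.empty(n)
    V = params.E_L
    w = 0.0
    gl, C, dT, Vt = params.g_L, params.C, params.Delta_T, params.V_T
    spike_samples = []
    for k in range(n):
        if V >= params.V_peak:
            v[k] = params.V_peak
            spike_samples.append(k)
            V = params.V_reset
            w += params.b
            continue
        v[k] = V
        exp_arg = min((V - Vt) / dT, _EXP_ARG_MAX)
        dV = (-gl * (V - params.E_L) + gl * dT * np.exp(exp_arg)
              - w + i_cmd[k]) / C
        dw = (params.a * (V - params.E_L) - w) / params.tau_w
        V += dt_ms * dV
        w += dt_ms * dw
        # a step above V_peak is the (clipped) spike upstroke, not
        # instability; runaway hyperpolarization or NaN is
        if not np.isfinite(V) or V < -1e4 or (V > 1e4 and V < params.V_peak):
            raise SimulationError(f"integration unstable at sample {k}")
    if params.noise_sd > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, params.noise_sd, size=n)
    meta = {
        "generator": "adex",
        "params": params,
        "protocol": protocol,
        "seed": seed,
        "t_start_s": t_start,
        "spike_samples_true": spike_samples,
    }
    return Trace(t0=0.0, dt=dt_ms / 1000.0, v=v, i_cmd=i_cmd, meta=meta)
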