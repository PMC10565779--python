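"""Renderer for extracellular field-potential sweeps.

Each stimulus renders three components on a flat baseline:

* a brief biphasic stimulus artifact (0.1 ms up, 0.1 ms down);
* the fiber volley (FV), a Gaussian-shaped negativity of fixed amplitude
  (optionally scaled per pulse via ``fv_scale``), reflecting the compound
  presynaptic spike;
* the field postsynaptic potential (fPSP), a negative difference-of-
  exponentials scaled by the pulse's relative amplitude.

Closed-form peak values of both components are returned as ground-truth
landmarks, so measurement code can be checked by construction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from ..errors import TruncatedSweepWarning
from ..trace import FieldSweep, ProtocolSpec

__all__ = ["FieldKinetics", "synthesize_field_sweeps", "fpsp_kernel"]


@dataclass
class FieldKinetics:
    """Waveform kinetics of one evoked field response.

    Latencies are measured from stimulus (artifact) onset, in ms.  The
    default FV amplitude of 0.5 mV matches the amplitude conventionally
    targeted during 0.1 Hz baseline stimulation of FV-isolated recordings.
    """

    fv_amp: float = 0.5          # mV, trough depth
    fv_latency: float = 1.5      # ms to FV trough
    fv_width: float = 1.0        # ms FWHM of the Gaussian FV
    fpsp_latency: float = 3.0    # ms to fPSP onset
    fpsp_tau_rise: float = 1.5   # ms
    fpsp_tau_decay: float = 8.0  # ms
    artifact_amp: float = 5.0    # mV
    noise_sd: float = 0.0        # mV

    def __post_init__(self) -> None:
        if min(self.fv_latency, self.fv_width, self.fpsp_latency,
               self.fpsp_tau_rise, self.fpsp_tau_decay) <= 0:
            raise ValueError("latencies, widths and taus must be positive")
        if self.fpsp_latency <= self.fv_latency:
            raise ValueError("fPSP onset must follow the fiber volley")
        if self.fpsp_tau_rise >= self.fpsp_tau_decay:
            raise ValueError("rise tau must be shorter than decay tau")

    @property
    def fpsp_peak_delay(self) -> float:
        """Delay from fPSP onset to its peak, ms (closed form)."""
        tr, td = self.fpsp_tau_rise, self.fpsp_tau_decay
        return tr * td / (td - tr) * math.log(td / tr)


def fpsp_kernel(tau_ms: np.ndarray, kinetics: FieldKinetics) -> np.ndarray:
    """Unit-peak difference-of-exponentials, evaluated at times ``tau_ms``
    from fPSP onset (zero before onset)."""
    tr, td = kinetics.fpsp_tau_rise, kinetics.fpsp_tau_decay
    tp = kinetics.fpsp_peak_delay
    norm = math.exp(-tp / td) - math.exp(-tp / tr)
    out = np.where(tau_ms >= 0,
                   np.exp(-np.maximum(tau_ms, 0) / td)
                   - np.exp(-np.maximum(tau_ms, 0) / tr), 0.0)
    return out / norm


def _stim_schedule(protocol: ProtocolSpec, n_amps: int,
                   pre_s: float) -> list[list[float]]:
    """Group stimulus-onset times into sweeps.  Long inter-stimulus gaps
    (> 2 s) are emitted as separate single-stimulus sweeps."""
    kind = protocol.kind
    if kind == "paired_pulse":
        isi = float(protocol["isi_ms"]) / 1000.0
        return [[pre_s, pre_s + isi]]
    if kind == "train":
        isi = 1.0 / float(protocol["frequency_hz"])
        n = int(protocol["n_pulses"])
        if n != n_amps:
            raise ValueError("amplitude vector length must equal n_pulses")
        if isi > 2.0:
            return [[pre_s] for _ in range(n)]
        return [[pre_s + k * isi for k in range(n)]]
    if kind == "baseline" or kind == "sp_lfs":
        return [[pre_s] for _ in range(n_amps)]
    if kind == "pp_lfs":
        isi = float(protocol["isi_ms"]) / 1000.0
        if n_amps % 2:
            raise ValueError("pp_lfs needs an even amplitude vector")
        return [[pre_s, pre_s + isi] for _ in range(n_amps // 2)]
    raise ValueError(f"cannot render protocol kind {kind!r}")


def synthesize_field_sweeps(amplitudes, kinetics: FieldKinetics,
                            protocol: ProtocolSpec, seed: int = 0,
                            dt_s: float = 5e-5, base_amp_mv: float = 1.5,
                            fv_scale=None) -> list[FieldSweep]:
    """Render field sweeps for a stimulation protocol.

    Parameters
    ----------
    amplitudes : sequence of float
        Relative fPSP amplitude per stimulus (e.g. from
        :func:`~hippoquant.synth.stp.simulate_stp_train`); the absolute peak
        of pulse ``n`` is ``base_amp_mv * amplitudes[n]``.
    fv_scale : sequence of float, optional
        Per-pulse scale of the fiber volley (default 1 everywhere); used to
        emulate FV suppression during low-frequency stimulation.

    Returns a list of :class:`FieldSweep` whose ``landmarks`` carry the
    ground truth per stimulus (component amplitudes and peak times).  A
    :class:`TruncatedSweepWarning` is issued when an fPSP would peak after
    the next stimulus arrives.
    """
    amps = np.asarray(amplitudes, dtype=float)
    if amps.size == 0 or np.any(amps < 0):
        raise ValueError("amplitudes must be a non-empty, non-negative vector")
    if fv_scale is None:
        fv_scale = np.ones(amps.size)
    else:
        fv_scale = np.asarray(fv_scale, dtype=float)
        if fv_scale.shape != amps.shape:
            raise ValueError("fv_scale must match amplitudes in length")

    pre_s = 0.05
    schedule = _stim_schedule(protocol, amps.size, pre_s)
    tail_s = (kinetics.fpsp_latency + 10 * kinetics.fpsp_tau_decay) / 1000.0
    rng = np.random.default_rng(seed)
    sigma_ms = kinetics.fv_width / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    art_n = max(1, round(1e-4 / dt_s))  # samples per artifact half-phase

    sweeps: list[FieldSweep] = []
    idx = 0
    for stim_times in schedule:
        n_samp = round((stim_times[-1] + tail_s) / dt_s)
        t_ms = np.arange(n_samp) * dt_s * 1000.0
        v = np.zeros(n_samp)
        landmarks = []
        for j, s in enumerate(stim_times):
            amp = base_amp_mv * amps[idx]
            fva = kinetics.fv_amp * fv_scale[idx]
            s_ms = s * 1000.0
            k0 = round(s / dt_s)
            v[k0:k0 + art_n] += kinetics.artifact_amp
            v[k0 + art_n:k0 + 2 * art_n] -= kinetics.artifact_amp
            v -= fva * np.exp(-((t_ms - (s_ms + kinetics.fv_latency)) ** 2)
                              / (2.0 * sigma_ms ** 2))
            v -= amp * fpsp_kernel(t_ms - (s_ms + kinetics.fpsp_latency),
                                   kinetics)
            peak_t = (s_ms + kinetics.fpsp_latency
                      + kinetics.fpsp_peak_delay) / 1000.0
            if j + 1 < len(stim_times) and peak_t > stim_times[j + 1]:
                warnings.warn(
                    "fPSP peaks after the next stimulus; responses overlap",
                    TruncatedSweepWarning, stacklevel=2)
            landmarks.append({
                "stim_index": idx,
                "t_stim": s,
                "artifact_window": (s, s + 2 * art_n * dt_s),
                "fv_trough_t": s + kinetics.fv_latency / 1000.0,
                "fv_amp": fva,
                "fpsp_peak_t": peak_t,
                "fpsp_amp": amp,
            })
            idx += 1
        if kinetics.noise_sd > 0:
            v = v + rng.normal(0.0, kinetics.noise_sd, size=n_samp)
        sweeps.append(FieldSweep(dt=dt_s, v=v, stim_times=list(stim_times),
                                 landmarks=landmarks,
                                 meta={"generator": "fieldsim", "seed": seed,
                                       "protocol": protocol,
                                       "base_amp_mv": base_amp_mv}))
    return sweeps
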