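"""Deterministic short-term plasticity model (facilitation/depression).

A Tsodyks–Markram-style two-state recurrence drives the synthetic synapse:
``u`` is the utilization (release probability) rising with facilitation,
``R`` the fraction of recoverable resources depleted by release.  At pulse
``n`` the response reads ``u_n * R_n``; amplitudes are reported relative to
the first pulse.

State-update order (fixed; conventions differ between implementations):

1. read the response ``u_n * R_n``;
2. facilitate: ``u <- u + U * (1 - u)``;
3. deplete by the released fraction: ``R <- R - u_n * R_n`` (the fraction
   read in step 1, i.e. pre-facilitation ``u``);
4. decay to the next pulse: ``u`` relaxes to ``U`` with ``tau_f``, ``R``
   recovers to 1 with ``tau_d``.

With ``U = 1`` the train is purely depressing; in the low-frequency limit
(ISI much longer than both time constants) every amplitude returns to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["STPParams", "simulate_stp_train", "stp_amplitudes_isi"]


@dataclass
class STPParams:
    """Facilitation/depression state-model parameters.

    ``U``: baseline release fraction in (0, 1]; ``tau_f``: facilitation decay
    (ms); ``tau_d``: recovery from depression (ms); ``A``: absolute scale of
    the first-pulse response (mV of fPSP amplitude, or mV/ms if slopes are
    rendered).
    """

    U: float = 0.2
    tau_f: float = 200.0
    tau_d: float = 500.0
    A: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.U <= 1.0:
            raise ValueError("U must be in (0, 1]")
        if self.tau_f <= 0 or self.tau_d <= 0:
            raise ValueError("tau_f and tau_d must be positive")
        if self.A <= 0:
            raise ValueError("A must be positive")


def stp_amplitudes_isi(params: STPParams, isi_ms: float,
                       n_pulses: int) -> np.ndarray:
    """Relative amplitudes for ``n_pulses`` at a fixed inter-stimulus
    interval (ms). First pulse is 1 by construction."""
    if n_pulses < 1:
        raise ValueError("n_pulses must be >= 1")
    if isi_ms <= 0:
        raise ValueError("isi_ms must be positive")
    U = params.U
    u, R = U, 1.0
    first = u * R
    out = np.empty(n_pulses)
    ef = np.exp(-isi_ms / params.tau_f)
    ed = np.exp(-isi_ms / params.tau_d)
    for k in range(n_pulses):
        released = u * R
        out[k] = released / first
        u_post = u + U * (1.0 - u)
        R_post = R - released
        u = U + (u_post - U) * ef
        R = 1.0 + (R_post - 1.0) * ed
    return out


def simulate_stp_train(params: STPParams, frequency_hz: float,
                       n_pulses: int) -> np.ndarray:
    """Relative response amplitudes of a regular train at ``frequency_hz``."""
    if frequency_hz <= 0:
        raise ValueError("frequency must be positive")
    return stp_amplitudes_isi(params, 1000.0 / frequency_hz, n_pulses)
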