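"""Shared fixtures and independent oracles.

The oracles here deliberately re-derive quantities by brute force (fine-step
integration, dense-grid finite differences, hand-stepped recurrences) and
stay independent of the library code paths they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from hippoquant.field import MeasureConfig, build_template
from hippoquant.synth import FieldKinetics, synthesize_field_sweeps
from hippoquant.trace import ProtocolSpec


def make_sigmoid_upstroke(a: float, b: float, v_half: float, k: float,
                          v0: float = -70.0, v_stop: float = 10.0,
                          dt_ms: float = 0.05, refine: int = 1) -> np.ndarray:
    """Integrate dV/dt = a + b·sigmoid((V − v_half)/k) on a grid 200·refine
    finer than the output sampling; the phase-plane curvature d(dV/dt)/dV of
    this waveform peaks exactly at v_half."""
    h = dt_ms / (200 * refine)
    sample_every = 200
    V = v0
    vs = [V]
    i = 0
    while V < v_stop and i < 5_000_000:
        V += h * (a + b / (1.0 + np.exp(-(V - v_half) / k)))
        i += 1
        if i % sample_every == 0:
            vs.append(V)
    return np.array(vs)


def dense_grid_threshold(v: np.ndarray, dt_ms: float,
                         dvdt_ceiling: float = 50.0) -> float:
    """Brute-force phase-plane threshold: raw finite differences on a dense
    sampling, argmax of d(dV/dt)/dV on the upstroke (restricted, like the
    operator's definition, to the initiation region below the dV/dt
    ceiling)."""
    dvdt = np.gradient(v, dt_ms)
    imax = int(np.argmax(dvdt))
    vv, dd = v[:imax + 1], dvdt[:imax + 1]
    over = np.flatnonzero(dd > dvdt_ceiling)
    if over.size and over[0] > 2:
        vv, dd = vv[:over[0]], dd[:over[0]]
    dv = np.diff(vv)
    ok = dv > 1e-12
    slope = np.diff(dd)[ok] / dv[ok]
    vmid = (0.5 * (vv[:-1] + vv[1:]))[ok]
    return float(vmid[int(np.argmax(slope))])


def hand_stepped_stp(U: float, tau_f: float, tau_d: float, isi_ms: float,
                     n: int) -> np.ndarray:
    """Explicit recurrence oracle for the facilitation/depression synapse
    (read u·R, facilitate u, deplete R by the read fraction, decay)."""
    u, R = U, 1.0
    first = u * R
    out = []
    for _ in range(n):
        released = u * R
        out.append(released / first)
        u = u + U * (1.0 - u)
        R = R - released
        u = U + (u - U) * np.exp(-isi_ms / tau_f)
        R = 1.0 + (R - 1.0) * np.exp(-isi_ms / tau_d)
    return np.array(out)


@pytest.fixture(scope="session")
def kinetics() -> FieldKinetics:
    return FieldKinetics()


@pytest.fixture(scope="session")
def baseline_sweep(kinetics):
    """Noise-free single-stimulus baseline sweep (unit relative amplitude)."""
    return synthesize_field_sweeps(
        [1.0], kinetics, ProtocolSpec("baseline", {"frequency_hz": 0.1}),
        seed=0)[0]


@pytest.fixture(scope="session")
def template_config(baseline_sweep) -> MeasureConfig:
    """Measurement config with the baseline-derived subtraction template."""
    tmpl, amp = build_template(baseline_sweep)
    return MeasureConfig(subtract_template=True, template=tmpl,
                         template_amp=amp)
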