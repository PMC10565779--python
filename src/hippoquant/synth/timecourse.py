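"""Ground-truth generators for long-term plasticity time courses.

Emits per-sweep response measures (fPSP slopes) sampled at the 0.1 Hz
pacing used between induction protocols: a flat baseline at ``pre_level``
followed by an exponential approach to ``post_level`` after induction at
t = 0.  Deterministic given a seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["simulate_plasticity_timecourse", "simulate_fv_series"]


def simulate_plasticity_timecourse(pre_level: float, post_level: float,
                                   tau_onset_min: float,
                                   baseline_min: float = 10.0,
                                   followup_min: float = 60.0,
                                   rate_hz: float = 0.1,
                                   noise_sd: float = 0.0,
                                   seed: int = 0):
    """Simulate a baseline-normalizable plasticity experiment.

    Returns ``(t_min, values)``: sweep times in minutes (baseline sweeps at
    negative times, induction at t = 0) and the response measure per sweep.
    ``values`` follow ``post + (pre - post) * exp(-t / tau)`` for t > 0.
    Multiplicative Gaussian noise of fractional SD ``noise_sd`` is applied
    per sweep.
    """
    if pre_level <= 0 or post_level <= 0:
        raise ValueError("levels must be positive")
    if tau_onset_min <= 0:
        raise ValueError("tau_onset_min must be positive")
    dt_min = 1.0 / (rate_hz * 60.0)
    t_base = np.arange(-baseline_min, 0, dt_min)
    t_post = np.arange(dt_min, followup_min + dt_min / 2, dt_min)
    t = np.concatenate([t_base, t_post])
    level = np.where(t < 0, pre_level,
                     post_level + (pre_level - post_level)
                     * np.exp(-np.maximum(t, 0) / tau_onset_min))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        level = level * (1.0 + rng.normal(0.0, noise_sd, size=t.size))
    return t, level


def simulate_fv_series(lfs_level: float, recovery_level: float,
                       tau_recovery_min: float = 5.0,
                       baseline_min: float = 10.0,
                       lfs_min: float = 15.0,
                       followup_min: float = 40.0,
                       rate_hz: float = 0.1,
                       noise_sd: float = 0.0,
                       seed: int = 0):
    """Fiber-volley amplitude series across an LFS experiment.

    Baseline at 1.0; during the LFS epoch (t in [0, lfs_min]) the FV drops
    to ``lfs_level``; afterwards it relaxes exponentially toward
    ``recovery_level``.  Returns ``(t_min, fv_values)`` with induction
    starting at t = 0.
    """
    if not (0 < lfs_level <= 1.5 and 0 < recovery_level <= 1.5):
        raise ValueError("levels must be positive fractions of baseline")
    dt_min = 1.0 / (rate_hz * 60.0)
    t = np.arange(-baseline_min, lfs_min + followup_min + dt_min / 2, dt_min)
    fv = np.ones_like(t)
    during = (t >= 0) & (t < lfs_min)
    after = t >= lfs_min
    fv[during] = lfs_level
    fv[after] = recovery_level + (lfs_level - recovery_level) * np.exp(
        -(t[after] - lfs_min) / tau_recovery_min)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        fv = fv * (1.0 + rng.normal(0.0, noise_sd, size=t.size))
    return t, fv
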