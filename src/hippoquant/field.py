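"""Field-potential quantification: sweep landmarks, input–output curves,
paired-pulse ratios, frequency-facilitation trains, long-term plasticity
time courses, and fiber-volley trajectories.

Measurement conventions
-----------------------
* FV amplitude: pre-stimulus baseline to trough, magnitude positive.
* fPSP amplitude: baseline to extremum of the (negative-going) response,
  magnitude positive.
* fPSP slope: least-squares line through the samples between 20% and 80%
  of the peak on the rising phase of the response magnitude, mV/ms.
* Paired-pulse ratio uses amplitudes; LTP/DP/LTD time courses use slopes;
  input–output curves use amplitudes.
* Train facilitation is normalized to the pre-train 0.1 Hz baseline mean
  (not to the first pulse of the train).
* Overlapping responses at short intervals are handled by subtracting a
  scaled template of the preceding response (template from a baseline
  average), switchable to raw measurement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import (TruncatedSweepWarning, UndefinedRatioError,
                     UnstableBaselineWarning)
from .trace import FieldSweep, ProtocolSpec

__all__ = [
    "MeasureConfig", "SweepMeasures", "IOCurve", "TrainResult",
    "PlasticityTimecourse", "TuningCurve",
    "measure_sweep", "build_template", "io_curve", "paired_pulse_ratio",
    "ppr_series_summary", "analyze_train", "tuning_curve",
    "plasticity_quantify", "fv_trajectory",
]


@dataclass
class MeasureConfig:
    """Windows (ms, relative to stimulus onset) and options for
    :func:`measure_sweep`."""

    baseline_ms: float = 5.0            # pre-stimulus baseline span
    artifact_blank_ms: float = 0.5      # blanked after stimulus onset
    fv_window_ms: tuple[float, float] = (0.5, 2.5)
    fpsp_window_ms: tuple[float, float] = (2.5, 40.0)
    slope_bounds: tuple[float, float] = (0.2, 0.8)
    subtract_template: bool = False
    template: np.ndarray | None = None  # response kernel sampled at sweep dt
    template_amp: float | None = None   # fPSP amplitude of the template
    min_amp_mv: float = 0.0             # noise floor for ratio denominators


@dataclass
class SweepMeasures:
    """Per-stimulus landmark measures (magnitudes positive)."""

    fv_amp: float            # mV
    fpsp_amp: float          # mV
    fpsp_slope: float        # mV/ms, 20-80% rising phase
    fpsp_peak_t: float       # s, within sweep
    stim_intensity: float | None = None  # µA
    t: float = 0.0           # stimulus time within the experiment, s
    truncated: bool = False


def _slope_20_80(y: np.ndarray, dt_ms: float, peak_idx: int,
                 bounds: tuple[float, float]) -> float:
    """LSQ slope of the response magnitude between the bound fractions of
    the peak, on the rising limb only.  Exactly invariant to vertical
    offset (y is already baseline-subtracted) and to time shift."""
    lo, hi = bounds
    peak = y[peak_idx]
    if peak <= 0:
        return 0.0
    seg = y[:peak_idx + 1]
    sel = np.flatnonzero((seg >= lo * peak) & (seg <= hi * peak))
    if sel.size < 2:
        # fewer than two samples in the band: fall back to the two samples
        # bracketing the band centre
        k = int(np.searchsorted(seg, 0.5 * peak))
        k = min(max(k, 1), peak_idx)
        sel = np.array([k - 1, k])
    t = sel * dt_ms
    coef = np.polyfit(t, seg[sel], 1)
    return float(coef[0])


def measure_sweep(sweep: FieldSweep,
                  config: MeasureConfig | None = None) -> list[SweepMeasures]:
    """Measure FV and fPSP landmarks for every stimulus in a sweep.

    The artifact window is blanked; the baseline is the mean over the
    window preceding the *first* stimulus (later pre-stimulus spans in a
    train are contaminated by previous responses).  With
    ``subtract_template`` enabled, each measured response subtracts a
    scaled copy of the configured template before the next stimulus is
    measured (sequential peeling), which removes overlap at short
    inter-stimulus intervals.
    """
    cfg = config or MeasureConfig()
    dt_ms = sweep.dt * 1000.0
    v = sweep.v.copy()
    stims = sorted(sweep.stim_times)
    if not stims:
        raise ValueError("sweep has no stimulus times")

    def idx(t_s: float) -> int:
        return int(round(t_s / sweep.dt))

    k_first = idx(stims[0])
    k_b0 = max(0, k_first - round(cfg.baseline_ms / dt_ms))
    if k_first <= k_b0:
        raise ValueError("no pre-stimulus baseline available")
    baseline = float(v[k_b0:k_first].mean())

    out: list[SweepMeasures] = []
    for j, s in enumerate(stims):
        k_s = idx(s)
        k_blank = min(v.size, k_s + max(1, round(cfg.artifact_blank_ms / dt_ms)))
        v[k_s:k_blank] = baseline
        # fiber volley
        a = k_s + round(cfg.fv_window_ms[0] / dt_ms)
        b = min(v.size, k_s + round(cfg.fv_window_ms[1] / dt_ms))
        fv_amp = baseline - float(v[a:b].min()) if b > a else 0.0
        # fPSP window, clipped at the next stimulus
        a = k_s + round(cfg.fpsp_window_ms[0] / dt_ms)
        b = k_s + round(cfg.fpsp_window_ms[1] / dt_ms)
        truncated = False
        if j + 1 < len(stims):
            nxt = idx(stims[j + 1])
            if b > nxt:
                b = nxt
                truncated = True
        b = min(v.size, b)
        if b - a < 3:
            raise ValueError("fPSP window empty; check stimulus spacing")
        y = baseline - v[a:b]  # response magnitude, positive
        # prefer an interior local maximum: the monotonically decaying FV
        # tail at the window edge must not masquerade as a tiny fPSP peak
        interior = np.flatnonzero((y[1:-1] > y[:-2]) & (y[1:-1] >= y[2:])) + 1
        k_peak = (int(interior[np.argmax(y[interior])]) if interior.size
                  else int(np.argmax(y)))
        if truncated and k_peak >= y.size - 1:
            warnings.warn("fPSP peak not reached before next stimulus",
                          TruncatedSweepWarning, stacklevel=2)
        fpsp_amp = float(y[k_peak])
        slope = _slope_20_80(y, dt_ms, k_peak, cfg.slope_bounds)
        out.append(SweepMeasures(
            fv_amp=fv_amp, fpsp_amp=fpsp_amp, fpsp_slope=slope,
            fpsp_peak_t=(a + k_peak) * sweep.dt,
            stim_intensity=sweep.stim_intensity, t=s, truncated=truncated))
        if cfg.subtract_template and cfg.template is not None:
            scale = fpsp_amp / cfg.template_amp
            tmpl = cfg.template
            b_t = min(v.size, k_s + tmpl.size)
            v[k_s:b_t] -= scale * tmpl[:b_t - k_s]
    return out


def build_template(baseline_sweep: FieldSweep,
                   config: MeasureConfig | None = None
                   ) -> tuple[np.ndarray, float]:
    """Extract a single-response template from a baseline sweep with one
    stimulus: the baseline-subtracted waveform from stimulus onset onward,
    with the artifact span zeroed, plus its fPSP amplitude.

    Use as ``cfg.template, cfg.template_amp = build_template(sweep)``.
    """
    cfg = config or MeasureConfig()
    if len(baseline_sweep.stim_times) != 1:
        raise ValueError("template sweep must contain exactly one stimulus")
    m = measure_sweep(baseline_sweep, MeasureConfig(
        baseline_ms=cfg.baseline_ms, artifact_blank_ms=cfg.artifact_blank_ms,
        fv_window_ms=cfg.fv_window_ms, fpsp_window_ms=cfg.fpsp_window_ms))[0]
    dt_ms = baseline_sweep.dt * 1000.0
    k_s = int(round(baseline_sweep.stim_times[0] / baseline_sweep.dt))
    k_b0 = max(0, k_s - round(cfg.baseline_ms / dt_ms))
    base = float(baseline_sweep.v[k_b0:k_s].mean())
    tmpl = baseline_sweep.v[k_s:] - base
    tmpl = tmpl.copy()
    tmpl[:max(1, round(cfg.artifact_blank_ms / dt_ms))] = 0.0
    return tmpl, m.fpsp_amp


@dataclass
class IOCurve:
    """Input–output relation: fPSP amplitude versus stimulus intensity."""

    intensities: np.ndarray  # µA, ascending
    amplitudes: np.ndarray   # mV

    def intensity_for_fraction(self, fraction: float) -> float:
        """Smallest intensity achieving ``fraction`` of the maximal
        amplitude, by monotone linear interpolation."""
        if not 0.0 < fraction <= 1.0:
            raise ValueError("fraction must be in (0, 1]")
        target = fraction * float(self.amplitudes.max())
        env = np.maximum.accumulate(self.amplitudes)  # monotone envelope
        if target > env[-1]:
            raise ValueError("requested fraction unreachable")
        k = int(np.searchsorted(env, target))
        if k == 0 or env[k] == target:
            return float(self.intensities[k])
        x0, x1 = self.intensities[k - 1], self.intensities[k]
        y0, y1 = env[k - 1], env[k]
        return float(x0 + (target - y0) / (y1 - y0) * (x1 - x0))


def io_curve(sweeps: list[FieldSweep], config: MeasureConfig | None = None,
             monotone_tol: float = 0.05) -> IOCurve:
    """Build an input–output curve from sweeps at graded intensities.

    Requires ≥ 4 intensities.  A decrease of more than ``monotone_tol``
    (fractional) between consecutive intensities triggers a warning; the
    curve is still returned.
    """
    if len(sweeps) < 4:
        raise ValueError("need at least 4 intensities for an I-O curve")
    pairs = []
    for sw in sweeps:
        if sw.stim_intensity is None:
            raise ValueError("every sweep needs stim_intensity")
        pairs.append((float(sw.stim_intensity),
                      measure_sweep(sw, config)[0].fpsp_amp))
    pairs.sort()
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    drops = (y[:-1] - y[1:]) / np.maximum(y[:-1], 1e-12)
    if np.any(drops > monotone_tol):
        warnings.warn("I-O curve is non-monotone beyond tolerance",
                      UserWarning, stacklevel=2)
    return IOCurve(intensities=x, amplitudes=y)


def paired_pulse_ratio(sweep: FieldSweep,
                       config: MeasureConfig | None = None) -> float:
    """PPR = second/first fPSP (amplitude measure) of a 2-stimulus sweep."""
    if len(sweep.stim_times) != 2:
        raise ValueError("paired-pulse sweep must contain exactly 2 stimuli")
    cfg = config or MeasureConfig()
    m = measure_sweep(sweep, cfg)
    if m[0].fpsp_amp <= cfg.min_amp_mv or m[0].fpsp_amp <= 0:
        raise UndefinedRatioError("first fPSP at or below the noise floor")
    return m[1].fpsp_amp / m[0].fpsp_amp


def ppr_series_summary(pprs) -> float:
    """Summary of a PPR series across an induction protocol:
    (mean of the last 20 PPRs) / (first PPR)."""
    arr = np.asarray(pprs, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 PPRs")
    return float(arr[-20:].mean() / arr[0])


@dataclass
class TrainResult:
    trajectory_pct: np.ndarray   # % of baseline, one value per pulse
    last10_mean_pct: float
    max_facilitation_pct: float
    frequency_hz: float | None = None


def analyze_train(responses, baseline: float, frequency_hz: float | None = None,
                  last_n: int = 10) -> TrainResult:
    """Normalize a train of responses to the pre-train baseline mean.

    Returns the full trajectory (% of baseline), the mean of the last
    ``last_n`` pulses (pulses 91–100 of a 100-pulse train) and the maximal
    facilitation.
    """
    if baseline is None or baseline <= 0:
        raise ValueError("a positive pre-train baseline is required")
    arr = np.asarray(responses, dtype=float)
    if arr.size == 0:
        raise ValueError("empty train")
    traj = arr / baseline * 100.0
    return TrainResult(trajectory_pct=traj,
                       last10_mean_pct=float(traj[-last_n:].mean()),
                       max_facilitation_pct=float(traj.max()),
                       frequency_hz=frequency_hz)


@dataclass
class TuningCurve:
    """Per-frequency maximal facilitation and last-10 mean, % of baseline."""

    frequencies: np.ndarray
    max_pct: np.ndarray
    last10_pct: np.ndarray


def tuning_curve(trains: list[TrainResult]) -> TuningCurve:
    """Collect train results into a frequency tuning curve (≥ 2 unique
    frequencies; duplicates rejected)."""
    if len(trains) < 1:
        raise ValueError("need at least one train")
    freqs = [t.frequency_hz for t in trains]
    if any(f is None or f <= 0 for f in freqs):
        raise ValueError("every train needs a positive frequency")
    if len(set(freqs)) != len(freqs):
        raise ValueError("duplicate frequencies in tuning-curve input")
    order = np.argsort(freqs)
    return TuningCurve(
        frequencies=np.asarray(freqs, dtype=float)[order],
        max_pct=np.array([trains[k].max_facilitation_pct for k in order]),
        last10_pct=np.array([trains[k].last10_mean_pct for k in order]))


@dataclass
class PlasticityTimecourse:
    """Baseline-normalized plasticity time course with window summaries."""

    t_min: np.ndarray
    normalized_pct: np.ndarray
    epochs: dict
    window_means: dict          # name -> (mean %, sem, n)
    induction_mean_pct: float | None = None
    baseline_stable: bool = True


def _window_stats(t: np.ndarray, y: np.ndarray,
                  win: tuple[float, float]) -> tuple[float, float, int]:
    sel = (t >= win[0]) & (t <= win[1])
    n = int(sel.sum())
    if n == 0:
        raise ValueError(f"no sweeps in window {win}")
    vals = y[sel]
    sem = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return float(vals.mean()), sem, n


def plasticity_quantify(t_min, values, epochs: dict,
                        windows: dict[str, tuple[float, float]],
                        drift_tol_pct_per_10min: float = 5.0
                        ) -> PlasticityTimecourse:
    """Normalize a timed response series to its baseline epoch and summarize
    post-induction windows.

    ``epochs`` maps ``baseline`` / ``induction`` (optional) / ``followup``
    to (t_start, t_end) in minutes; ``windows`` maps summary names to
    follow-up intervals (e.g. 51–60 min post-induction).  Baseline drift
    beyond the tolerance raises an :class:`UnstableBaselineWarning` and
    flags the result.  The baseline-epoch mean of the normalized series is
    100% by construction.
    """
    t = np.asarray(t_min, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.size == 0:
        raise ValueError("t_min and values must be equal-length, non-empty")
    b0, b1 = epochs["baseline"]
    bsel = (t >= b0) & (t < b1)
    if not np.any(bsel):
        raise ValueError("baseline epoch contains no sweeps")
    base = float(y[bsel].mean())
    if base <= 0:
        raise ValueError("non-positive baseline mean")
    pct = y / base * 100.0

    stable = True
    if bsel.sum() > 2:
        coef = np.polyfit(t[bsel], pct[bsel], 1)
        if abs(coef[0]) * 10.0 > drift_tol_pct_per_10min:
            stable = False
            warnings.warn("baseline drifts beyond tolerance",
                          UnstableBaselineWarning, stacklevel=2)

    f0, f1 = epochs["followup"]
    wmeans = {}
    for name, win in windows.items():
        if win[0] < f0 - 1e-9 or win[1] > f1 + 1e-9:
            raise ValueError(f"window {name!r} lies outside the follow-up epoch")
        wmeans[name] = _window_stats(t, pct, win)

    induction_mean = None
    if "induction" in epochs:
        i0, i1 = epochs["induction"]
        isel = (t >= i0) & (t < i1)
        if np.any(isel):
            induction_mean = float(pct[isel].mean())
    return PlasticityTimecourse(t_min=t, normalized_pct=pct, epochs=epochs,
                                window_means=wmeans,
                                induction_mean_pct=induction_mean,
                                baseline_stable=stable)


def fv_trajectory(t_min, fv_amps, epochs: dict,
                  windows: dict[str, tuple[float, float]],
                  noise_floor_mv: float = 0.0) -> PlasticityTimecourse:
    """Normalized fiber-volley amplitude time course with window summaries.

    Sweeps whose FV falls at or below the noise floor are excluded (count
    reported in ``epochs['n_excluded']``); an all-excluded series is an
    error.  Windows typically cover the last 5 min of LFS and the
    35–40 min post-LFS span.
    """
    t = np.asarray(t_min, dtype=float)
    fv = np.asarray(fv_amps, dtype=float)
    keep = fv > noise_floor_mv
    n_excluded = int((~keep).sum())
    if not np.any(keep):
        raise UndefinedRatioError("all sweeps below the FV noise floor")
    # FV windows may lie inside the induction epoch, so windows are checked
    # against the whole recording span rather than the follow-up alone.
    t, fv = t[keep], fv[keep]
    b0, b1 = epochs["baseline"]
    bsel = (t >= b0) & (t < b1)
    if not np.any(bsel):
        raise ValueError("baseline epoch contains no sweeps")
    pct = fv / float(fv[bsel].mean()) * 100.0
    wmeans = {name: _window_stats(t, pct, win) for name, win in windows.items()}
    ep = dict(epochs)
    ep["n_excluded"] = n_excluded
    return PlasticityTimecourse(t_min=t, normalized_pct=pct, epochs=ep,
                                window_means=wmeans)
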