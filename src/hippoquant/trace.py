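"""Shared data model and IO for episodic recordings.

Canonical internal units: membrane potential in mV, current in pA, waveform
feature times in ms, epoch/stimulus times in s.  All readers convert on
ingest.  Sample ``k`` of a trace maps to ``t0 + k * dt`` (0-based); stimulus
times refer to the onset of the stimulus artifact.

The shipped on-disk dialect is a delimited numeric file (CSV/TSV) with an
optional time column plus one or more signal columns, accompanied by a JSON
sidecar declaring sampling, units, channel roles and the stimulation
protocol.  Vendor binary episodic formats are supported only through the
:data:`SWEEP_READERS` adapter registry; none is bundled.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .errors import FormatError, ProtocolError

__all__ = [
    "Trace",
    "FieldSweep",
    "ProtocolSpec",
    "ResultTable",
    "read_sweeps",
    "write_sweeps",
    "write_results",
    "read_results",
    "liquid_junction_correct",
    "PROTOCOL_REQUIRED_PARAMS",
    "SWEEP_READERS",
]

#: Tolerated jitter of the time column relative to the declared sampling
#: interval: max |Δt − dt| ≤ 0.01·dt.
SAMPLING_JITTER_TOL = 0.01


@dataclass
class Trace:
    """A uniformly sampled current-clamp voltage trace.

    Parameters
    ----------
    t0 : float
        Time of the first sample, seconds.
    dt : float
        Sampling interval, seconds (20 kHz recordings -> 5e-5).
    v : ndarray
        Membrane potential samples, mV.
    i_cmd : ndarray, optional
        Injected command current, pA, same length as ``v``.
    meta : dict
        Free-form provenance (cell id, region ``dorsal``/``ventral``,
        genotype, protocol, applied corrections).
    """

    t0: float
    dt: float
    v: np.ndarray
    i_cmd: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not np.all(np.isfinite(self.v)):
            raise ValueError("voltage samples must be finite")
        if self.i_cmd is not None:
            self.i_cmd = np.asarray(self.i_cmd, dtype=float)
            if self.i_cmd.shape != self.v.shape:
                raise ValueError("i_cmd must have the same length as v")

    @property
    def t(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.v.size) * self.dt

    @property
    def duration(self) -> float:
        return self.v.size * self.dt

    def slice(self, t_start: float, t_end: float) -> "Trace":
        """Sub-trace covering [t_start, t_end) in absolute time."""
        k0 = max(0, int(math.ceil((t_start - self.t0) / self.dt - 1e-9)))
        k1 = min(self.v.size, int(math.floor((t_end - self.t0) / self.dt + 1e-9)))
        return Trace(
            t0=self.t0 + k0 * self.dt,
            dt=self.dt,
            v=self.v[k0:k1].copy(),
            i_cmd=None if self.i_cmd is None else self.i_cmd[k0:k1].copy(),
            meta=dict(self.meta),
        )


@dataclass
class FieldSweep:
    """One stimulus-locked extracellular field-potential sweep.

    ``v`` holds the field potential in mV; ``stim_times`` are artifact-onset
    times in seconds (strictly increasing, within the sweep span).
    ``landmarks`` optionally carries per-stimulus ground truth or annotations
    (artifact window, fiber-volley trough, fPSP peak).
    """

    dt: float
    v: np.ndarray
    stim_times: list[float] = field(default_factory=list)
    stim_intensity: float | None = None  # µA
    landmarks: list[dict] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        st = list(self.stim_times)
        if any(b <= a for a, b in zip(st, st[1:])):
            raise ValueError("stim_times must be strictly increasing")
        span = self.v.size * self.dt
        if st and (st[0] < 0 or st[-1] >= span):
            raise ValueError("stim_times must lie within the sweep span")
        self.stim_times = st

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.v.size) * self.dt


#: Required parameters per protocol kind.  Durations are seconds,
#: currents pA, frequencies Hz, inter-stimulus intervals ms.
PROTOCOL_REQUIRED_PARAMS: dict[str, tuple[str, ...]] = {
    "ramp": ("i_start_pa", "i_end_pa", "duration_s"),
    "step": ("i_step_pa", "onset_s", "duration_s"),
    "membrane_test": ("v_step_mv",),
    "io_curve": ("intensities_ua",),
    "paired_pulse": ("isi_ms",),
    "train": ("frequency_hz", "n_pulses"),
    "hfs": ("frequency_hz", "duration_s", "n_trains", "intertrain_s"),
    "depotentiation": ("frequency_hz", "duration_s", "delay_s"),
    "pp_lfs": ("frequency_hz", "duration_s", "isi_ms"),
    "sp_lfs": ("frequency_hz", "duration_s"),
    "baseline": ("frequency_hz",),
}

_POSITIVE_PARAMS = ("frequency_hz", "duration_s", "isi_ms", "n_pulses",
                    "intertrain_s", "n_trains")


@dataclass
class ProtocolSpec:
    """Descriptor of a stimulation/recording protocol.

    ``kind`` is one of :data:`PROTOCOL_REQUIRED_PARAMS`; ``params`` must be
    complete for that kind.  Extra parameters (e.g. ``t_start_s`` of a ramp
    within its sweep) are allowed and preserved.
    """

    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.kind not in PROTOCOL_REQUIRED_PARAMS:
            raise ProtocolError(f"unknown protocol kind {self.kind!r}")
        missing = [p for p in PROTOCOL_REQUIRED_PARAMS[self.kind]
                   if p not in self.params]
        if missing:
            raise ProtocolError(
                f"protocol {self.kind!r} missing required params: {missing}")
        for name in _POSITIVE_PARAMS:
            if name in self.params and not np.all(np.asarray(self.params[name]) > 0):
                raise ProtocolError(f"{name} must be positive in {self.kind!r}")

    def __getitem__(self, key: str):
        return self.params[key]


class ResultTable:
    """Long-format result container keyed by (unit id, measure name).

    Every value carries units and a group label; duplicate keys are
    rejected.  Serializes to/from CSV losslessly for finite doubles
    (NaN round-trips through an empty cell).
    """

    COLUMNS = ("unit", "measure", "value", "units", "group")

    def __init__(self) -> None:
        self._rows: list[tuple] = []
        self._keys: set[tuple[str, str]] = set()

    def add(self, unit: str, measure: str, value: float, units: str,
            group: str = "") -> None:
        key = (str(unit), str(measure))
        if key in self._keys:
            raise ValueError(f"duplicate result key {key}")
        self._keys.add(key)
        self._rows.append((str(unit), str(measure), float(value), str(units),
                           str(group)))

    def __len__(self) -> int:
        return len(self._rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self._rows, columns=list(self.COLUMNS))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ResultTable":
        table = cls()
        for _, row in df.iterrows():
            table.add(row["unit"], row["measure"], row["value"], row["units"],
                      "" if pd.isna(row["group"]) else row["group"])
        return table

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ResultTable):
            return NotImplemented
        if len(self) != len(other):
            return False
        for a, b in zip(sorted(self._rows), sorted(other._rows)):
            if a[:2] != b[:2] or a[3:] != b[3:]:
                return False
            va, vb = a[2], b[2]
            if not (va == vb or (math.isnan(va) and math.isnan(vb))):
                return False
        return True


def write_results(table: ResultTable, path: str | Path) -> None:
    """Write a :class:`ResultTable` as CSV (header: unit, measure, value,
    units, group). Floats use ``repr`` precision so re-reading reproduces the
    table bit-exactly for finite values; NaN serializes as an empty cell."""
    df = table.to_frame()
    df["value"] = df["value"].map(lambda x: "" if math.isnan(x) else repr(x))
    df.to_csv(path, index=False)


def read_results(path: str | Path) -> ResultTable:
    df = pd.read_csv(path, dtype={"unit": str, "measure": str, "units": str,
                                  "group": str}, keep_default_na=False,
                     na_values=[""], float_precision="round_trip")
    df["value"] = pd.to_numeric(df["value"])
    df["group"] = df["group"].fillna("")
    return ResultTable.from_frame(df)


# ---------------------------------------------------------------------------
# Sweep IO (delimited + JSON sidecar dialect)
# ---------------------------------------------------------------------------

#: Adapter registry for vendor episodic formats.  Keys are format names,
#: values are callables (path, sidecar_dict) -> list of sweeps.  The bundled
#: dialect handles delimited text only.
SWEEP_READERS: dict[str, Callable] = {}

_VOLT_SCALE = {"mV": 1.0, "V": 1e3, "uV": 1e-3, "µV": 1e-3}
_CURR_SCALE = {"pA": 1.0, "nA": 1e3}
_TIME_SCALE = {"s": 1.0, "ms": 1e-3}


def _load_sidecar(sidecar: str | Path) -> dict:
    try:
        with open(sidecar) as fh:
            return json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot parse sidecar {sidecar}: {exc}") from exc


def _read_delimited(path: str | Path) -> pd.DataFrame:
    p = Path(path)
    sep = "\t" if p.suffix.lower() in (".tsv", ".tab") else ","
    try:
        df = pd.read_csv(p, sep=sep)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise FormatError(f"cannot parse {p}: {exc}") from exc
    if df.empty:
        raise FormatError(f"{p} contains no data rows")
    return df


def read_sweeps(path: str | Path, sidecar: str | Path):
    """Read delimited sweeps with a JSON sidecar into typed objects.

    Sidecar fields
    --------------
    ``type``            "trace" (default) or "field"
    ``dt_s``            sampling interval, seconds (or give a time column)
    ``time_column``     column name holding sample times
    ``time_units``      "s" (default) or "ms"
    ``units``           map column -> unit, e.g. {"v": "mV", "i": "pA"}
    ``channels``        map role -> column, e.g. {"v": "v1", "i": "i1"};
                        absent -> every non-time column is one voltage sweep
    ``protocol``        {"kind": ..., "params": {...}}
    ``stim_times_s``    field sweeps: artifact-onset times, s
    ``stim_intensity_ua``  field sweeps: stimulus intensity, µA
    ``meta``            free-form provenance merged into each sweep

    Returns a list of :class:`Trace` or :class:`FieldSweep`.  Raises
    :class:`FormatError` on empty files, missing sampling information, or a
    time column whose jitter exceeds 1% of ``dt``.
    """
    side = _load_sidecar(sidecar)
    fmt = side.get("format", "delimited")
    if fmt != "delimited":
        if fmt in SWEEP_READERS:
            return SWEEP_READERS[fmt](path, side)
        raise FormatError(f"no reader registered for format {fmt!r}")

    df = _read_delimited(path)
    tscale = _TIME_SCALE.get(side.get("time_units", "s"))
    if tscale is None:
        raise FormatError(f"unknown time units {side.get('time_units')!r}")

    time_col = side.get("time_column")
    dt = side.get("dt_s")
    t0 = 0.0
    if time_col is not None:
        if time_col not in df.columns:
            raise FormatError(f"time column {time_col!r} not in file")
        tvals = df[time_col].to_numpy(dtype=float) * tscale
        if tvals.size < 2:
            raise FormatError("need at least two samples to infer sampling")
        diffs = np.diff(tvals)
        inferred = float(np.median(diffs))
        declared = float(dt) if dt is not None else inferred
        if np.max(np.abs(diffs - declared)) > SAMPLING_JITTER_TOL * declared:
            raise FormatError(
                "non-uniform sampling: time-stamp jitter exceeds 1% of dt")
        dt = declared
        t0 = float(tvals[0])
    elif dt is None:
        raise FormatError("sidecar declares neither dt_s nor time_column")
    dt = float(dt)

    units = side.get("units", {})
    channels = side.get("channels")
    protocol = side.get("protocol")
    if protocol is not None:
        protocol = ProtocolSpec(protocol["kind"], dict(protocol.get("params", {})))
    meta = dict(side.get("meta", {}))
    if protocol is not None:
        meta["protocol"] = protocol

    def vscale(col: str) -> float:
        unit = units.get(col, "mV")
        if unit not in _VOLT_SCALE:
            raise FormatError(f"unknown voltage unit {unit!r} for {col!r}")
        return _VOLT_SCALE[unit]

    sweeps: list = []
    if side.get("type", "trace") == "field":
        sig_cols = [c for c in df.columns if c != time_col]
        for col in sig_cols:
            sweeps.append(FieldSweep(
                dt=dt,
                v=df[col].to_numpy(dtype=float) * vscale(col),
                stim_times=list(side.get("stim_times_s", [])),
                stim_intensity=side.get("stim_intensity_ua"),
                meta=dict(meta),
            ))
        return sweeps

    if channels:
        vcol = channels.get("v")
        if vcol is None or vcol not in df.columns:
            raise FormatError("channels must map 'v' to an existing column")
        icol = channels.get("i")
        i_cmd = None
        if icol is not None:
            iunit = units.get(icol, "pA")
            if iunit not in _CURR_SCALE:
                raise FormatError(f"unknown current unit {iunit!r}")
            i_cmd = df[icol].to_numpy(dtype=float) * _CURR_SCALE[iunit]
        sweeps.append(Trace(t0=t0, dt=dt,
                            v=df[vcol].to_numpy(dtype=float) * vscale(vcol),
                            i_cmd=i_cmd, meta=dict(meta)))
    else:
        for col in df.columns:
            if col == time_col:
                continue
            sweeps.append(Trace(t0=t0, dt=dt,
                                v=df[col].to_numpy(dtype=float) * vscale(col),
                                meta=dict(meta)))
    return sweeps


def write_sweeps(sweeps: Iterable[Trace], path: str | Path,
                 sidecar: str | Path, protocol: ProtocolSpec | None = None,
                 meta: dict | None = None) -> None:
    """Write traces as the delimited+JSON dialect :func:`read_sweeps` reads.

    All traces must share ``dt``; one column per trace (``v0``, ``v1``, ...),
    plus ``i0`` if the first trace carries a command channel.
    """
    sweeps = list(sweeps)
    if not sweeps:
        raise ValueError("no sweeps to write")
    dt = sweeps[0].dt
    if any(abs(s.dt - dt) > 1e-12 for s in sweeps):
        raise ValueError("all sweeps must share dt")
    data = {f"v{k}": s.v for k, s in enumerate(sweeps)}
    units = {f"v{k}": "mV" for k in range(len(sweeps))}
    channels = None
    if len(sweeps) == 1 and sweeps[0].i_cmd is not None:
        data["i0"] = sweeps[0].i_cmd
        units["i0"] = "pA"
        channels = {"v": "v0", "i": "i0"}
    pd.DataFrame(data).to_csv(path, index=False)
    side = {"format": "delimited", "type": "trace", "dt_s": dt,
            "units": units, "meta": meta or {}}
    if channels:
        side["channels"] = channels
    if protocol is not None:
        side["protocol"] = {"kind": protocol.kind, "params": protocol.params}
    with open(sidecar, "w") as fh:
        json.dump(side, fh, indent=1, sort_keys=True)


def liquid_junction_correct(trace: Trace, offset_mv: float) -> Trace:
    """Shift all voltage samples by −offset (liquid-junction correction).

    The applied correction accumulates in ``meta['ljp_correction_mv']`` so
    repeated application is auditable; correcting with +x then −x restores
    the original samples.
    """
    if not math.isfinite(offset_mv):
        raise ValueError("offset must be finite")
    meta = dict(trace.meta)
    meta["ljp_correction_mv"] = meta.get("ljp_correction_mv", 0.0) + offset_mv
    return Trace(t0=trace.t0, dt=trace.dt, v=trace.v - offset_mv,
                 i_cmd=None if trace.i_cmd is None else trace.i_cmd.copy(),
                 meta=meta)
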