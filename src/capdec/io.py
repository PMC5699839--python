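"""Readers and writers for traces, transfer functions, filters and configs.

The portable trace format is two-column plain text (time_s, current_A) with
``# key = value`` header comments carrying the sampling interval, the time
origin and free-form protocol metadata.  All floats are written with 17
significant digits, so write -> read round trips are bit-exact.  Axon Binary
Format (.abf) reading is an optional extra (install ``capdec[abf]``); the
package is fully functional on text traces alone.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .circuit import CurrentTrace, StimulusProtocol
from .filters import DigitalFilter
from .transfer import TransferFunction

__all__ = [
    "RecordBundle",
    "UnsupportedFormatError",
    "TraceParseError",
    "read_text_trace",
    "write_text_trace",
    "read_transfer",
    "write_transfer",
    "read_filter",
    "write_filter",
    "read_config",
    "protocol_from_config",
    "write_series_csv",
    "read_abf",
]

_FLOAT = "%.17g"


class UnsupportedFormatError(RuntimeError):
    """The requested file format needs an optional dependency that is absent."""


class TraceParseError(ValueError):
    """A text trace file is malformed; carries the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass
class RecordBundle:
    """One or more traces plus the protocol and provenance they came with."""

    traces: list[CurrentTrace]
    protocol: StimulusProtocol | None = None
    meta: dict = field(default_factory=dict)


def write_text_trace(trace: CurrentTrace, path) -> None:
    """Write a trace as two-column text with a metadata header."""
    with open(path, "w") as fh:
        fh.write("# capdec-trace v1\n")
        fh.write(f"# dt = {_FLOAT % trace.dt}\n")
        fh.write(f"# t0_offset = {_FLOAT % trace.t0_offset}\n")
        if trace.meta:
            fh.write(f"# meta = {json.dumps(trace.meta, default=float)}\n")
        fh.write("# time_s\tcurrent_A\n")
        for i, v in enumerate(trace.samples):
            t = trace.t0_offset + i * trace.dt
            fh.write(f"{_FLOAT % t}\t{_FLOAT % v}\n")


def read_text_trace(path) -> CurrentTrace:
    """Read a two-column text trace written by :func:`write_text_trace`.

    The header ``dt`` is authoritative for the sampling interval; the time
    column is redundant and only checked loosely.  Malformed rows raise
    :class:`TraceParseError` with the line number.
    """
    dt = None
    t0 = 0.0
    meta: dict = {}
    samples: list[float] = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    key = key.strip()
                    val = val.strip()
                    if key == "dt":
                        dt = float(val)
                    elif key == "t0_offset":
                        t0 = float(val)
                    elif key == "meta":
                        meta = json.loads(val)
                continue
            parts = line.split()
            if len(parts) != 2:
                raise TraceParseError(f"expected two columns, got {len(parts)}", ln)
            try:
                samples.append(float(parts[1]))
            except ValueError as exc:
                raise TraceParseError(str(exc), ln) from None
    if dt is None:
        raise TraceParseError("missing '# dt = ...' header", 0)
    return CurrentTrace(np.array(samples), dt, t0, meta)


def write_transfer(H: TransferFunction, path) -> None:
    """Serialize H_S as CSV: bin frequency (Hz), real, imaginary."""
    with open(path, "w") as fh:
        fh.write("# capdec-transfer v1\n")
        fh.write(f"# f_samp = {_FLOAT % H.f_samp}\n")
        fh.write("freq_hz,real,imag\n")
        for f, h in zip(H.freqs, H.h):
            fh.write(f"{_FLOAT % f},{_FLOAT % h.real},{_FLOAT % h.imag}\n")


def read_transfer(path) -> TransferFunction:
    f_samp = None
    re_parts: list[float] = []
    im_parts: list[float] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("f_samp"):
                    f_samp = float(body.partition("=")[2])
                continue
            if line.startswith("freq_hz"):
                continue
            _, re_s, im_s = line.split(",")
            re_parts.append(float(re_s))
            im_parts.append(float(im_s))
    if f_samp is None:
        raise TraceParseError("missing '# f_samp = ...' header", 0)
    return TransferFunction(np.array(re_parts) + 1j * np.array(im_parts), f_samp)


def write_filter(filt: DigitalFilter, path) -> None:
    """Export recursive-filter coefficients as plain text for cross-checks."""
    with open(path, "w") as fh:
        fh.write("# capdec-filter v1\n")
        fh.write(f"f_samp = {_FLOAT % filt.f_samp}\n")
        fh.write(f"f_c = {_FLOAT % filt.f_c}\n")
        fh.write(f"order = {filt.order}\n")
        fh.write("b = " + " ".join(_FLOAT % v for v in filt.b) + "\n")
        fh.write("a = " + " ".join(_FLOAT % v for v in filt.a) + "\n")


def read_filter(path) -> DigitalFilter:
    fields: dict = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            fields[key.strip()] = val.strip()
    return DigitalFilter(
        b=np.array([float(v) for v in fields["b"].split()]),
        a=np.array([float(v) for v in fields["a"].split()]),
        f_samp=float(fields["f_samp"]),
        f_c=float(fields["f_c"]),
        order=int(fields["order"]),
    )


def read_config(path) -> dict:
    """Load a flat key-value configuration file (YAML syntax).

    Documented keys: ``v_stim_mV, period_ms, f_samp_kHz, n_periods, holding_mV,
    seed, c_m_pF, r_m_MOhm, r_a_MOhm, r_seal_GOhm, c_p_pF`` plus free extras.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a flat key-value mapping")
    return cfg


def protocol_from_config(cfg: dict) -> StimulusProtocol:
    """Build a stimulation protocol from the documented config keys."""
    return StimulusProtocol(
        v_stim=float(cfg["v_stim_mV"]) * 1e-3,
        t_s=float(cfg["period_ms"]) * 1e-3,
        f_samp=float(cfg["f_samp_kHz"]) * 1e3,
        n_periods=int(cfg.get("n_periods", 1)),
        holding=float(cfg.get("holding_mV", 0.0)) * 1e-3,
    )


def write_series_csv(df: pd.DataFrame, path, f_s: float | None = None) -> None:
    """Write an impedance-estimate series as CSV with a time column.

    Columns are kept in SI units (F, Ohm, C); ``time_s`` is derived from the
    period index when the stimulation frequency is given.
    """
    out = df.copy()
    if f_s is not None and "period" in out.columns and "time_s" not in out.columns:
        out.insert(0, "time_s", out["period"] / f_s)
    out.to_csv(path, index=False, float_format=_FLOAT)


def read_abf(path) -> RecordBundle:
    """Read current sweeps from an Axon Binary Format file (optional).

    Requires the ``pyabf`` extra; without it an
    :class:`UnsupportedFormatError` is raised so that callers can fall back
    to the text format.  Each sweep becomes one trace; the digitization rate
    and channel metadata are surfaced in ``meta``.
    """
    try:
        import pyabf  # type: ignore
    except ImportError as exc:
        raise UnsupportedFormatError(
            "ABF reading requires the optional 'pyabf' dependency "
            "(pip install capdec[abf]); use the text trace format instead"
        ) from exc
    abf = pyabf.ABF(str(path))
    dt = 1.0 / abf.dataRate
    traces = []
    for sweep in range(abf.sweepCount):
        abf.setSweep(sweep)
        traces.append(
            CurrentTrace(
                np.asarray(abf.sweepY, dtype=float),
                dt,
                0.0,
                {"source": str(path), "sweep": sweep, "units": abf.sweepUnitsY},
            )
        )
    meta = {
        "source": str(path),
        "f_samp": float(abf.dataRate),
        "n_sweeps": int(abf.sweepCount),
        "protocol": getattr(abf, "protocol", ""),
    }
    return RecordBundle(traces=traces, meta=meta)
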