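"""Record-level orchestration and synthetic validation experiments.

Ties the simulator, the filter emulation, the deconvolution and the fitting
together into the full measurement chain

    simulate -> low-pass filter -> deconvolve -> segment -> fit -> C_M/R_M/R_A

and implements the validation studies that characterize the chain: the
accuracy sweep over random circuit triplets, the access-resistance cross-talk
study, the capacitance-resolution study under access-resistance fluctuation,
the seal-resistance sweep, and the event classifier that separates true
membrane-capacitance steps from seal and parasitic artefacts.

Each stimulation period is measured from its own settled mini-record: enough
warm-up periods are simulated (and discarded) for the circuit to reach its
periodic orbit and for the recursive filter memory to be flushed, so the
retained integer-period window satisfies the circular-convolution model of
the frequency-domain deconvolution exactly.  Parameter sweeps are therefore
quasi-static — the circuit is constant within each analysed period.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .circuit import (
    ROOM_TEMPERATURE_K,
    CircuitParams,
    CurrentTrace,
    StimulusProtocol,
    InvalidParameterError,
    random_triplets,
    simulate_square_wave,
    time_constant,
)
from .filters import DigitalFilter, apply_filter, design_bessel4
from .fitting import (
    analyze_square_record,
    per_period_means,
    standard_procedure_fit,
    thermal_limit,
)
from .transfer import TransferFunction, deconvolve

__all__ = [
    "RA_SIGMA_DEFAULTS",
    "ImpedanceSeries",
    "EventCall",
    "EventThresholds",
    "protocol_for",
    "measure_record",
    "reduce_bandwidth",
    "tune_standard_zero_time",
    "accuracy_experiment",
    "crosstalk_experiment",
    "resolution_vs_ra_fluctuation",
    "seal_sweep_experiment",
    "simulate_event_series",
    "detect_step",
    "classify_event",
    "default_thresholds",
]

#: Access-resistance fluctuation magnitudes (ohms) of the resolution study.
RA_SIGMA_DEFAULTS = (22.6e3, 45.2e3, 90.4e3, 135.6e3, 180.8e3, 361.7e3, 452.1e3)


class NoStepError(ValueError):
    """The analysed window contains no detectable step."""


@dataclass
class ImpedanceSeries:
    """Per-period impedance estimates with their stimulation/analysis rates.

    ``data`` holds one row per period (columns ``c_m, r_m, r_a, q_c, ...``),
    ``f_s`` is the stimulation frequency, ``bandwidth`` the current analysis
    bandwidth and ``m`` the block size already applied (1 for raw series).
    """

    data: pd.DataFrame
    f_s: float
    bandwidth: float | None = None
    m: int = 1

    def __post_init__(self) -> None:
        if self.bandwidth is None:
            self.bandwidth = self.f_s


@dataclass
class EventThresholds:
    """Decision levels for the event classifier.

    ``c_m_sigma`` / ``q_c_sigma`` are absolute noise scales (F and C; the
    thermal-noise floor of the configuration is the natural choice) and a
    change is "significant" above ``k_sig`` times the scale.  Resistance
    changes are judged relative to the pre-event level with fractional
    tolerance ``r_rel``.  ``k_detect`` scales the step-detection threshold.
    """

    c_m_sigma: float
    q_c_sigma: float
    r_rel: float = 0.01
    k_sig: float = 3.0
    k_detect: float = 5.0


@dataclass
class EventCall:
    """One classified step event in an impedance series."""

    onset: int
    d_c_m: float
    d_r_m: float
    d_r_a: float
    d_q_c: float
    classification: str


def default_thresholds(
    c_m: float,
    r_a: float,
    r_m: float,
    v_stim: float,
    bandwidth: float = 50.0,
    t_abs: float = ROOM_TEMPERATURE_K,
) -> EventThresholds:
    """Thresholds tied to the thermal-noise floor of the configuration."""
    sig = thermal_limit(c_m, r_a, v_stim, bandwidth, t_abs)
    divider = r_m / (r_m + r_a)
    return EventThresholds(c_m_sigma=sig, q_c_sigma=v_stim * divider**2 * sig)


def protocol_for(
    params: CircuitParams,
    v_stim: float,
    f_samp: float,
    n_periods: int = 2,
    halfs_per_tau: float = 6.0,
    min_half_samples: int = 8,
    holding: float = 0.0,
) -> StimulusProtocol:
    """Stimulation protocol matched to a circuit: each half-period spans
    ``halfs_per_tau`` charging time constants (optimal resolution at 6,
    i.e. a 12-tau period), rounded to an integer number of samples and
    clamped to at least ``min_half_samples`` samples per half-period."""
    tau = time_constant(params)
    n_half = max(min_half_samples, int(round(halfs_per_tau * tau * f_samp)))
    return StimulusProtocol(
        v_stim=v_stim,
        t_s=2 * n_half / f_samp,
        f_samp=f_samp,
        n_periods=n_periods,
        holding=holding,
    )


def _warmup_periods(filt: DigitalFilter, protocol: StimulusProtocol) -> int:
    return max(5, int(np.ceil(filt.memory_samples() / protocol.samples_per_period)) + 1)


def measure_record(
    params: CircuitParams,
    protocol: StimulusProtocol,
    filt: DigitalFilter,
    path: str = "deconvolution",
    zero_time: float | None = None,
    blank_head: float = 0.0,
    warmup: int | None = None,
) -> pd.DataFrame:
    """Simulate, filter and analyse one settled record; per-period estimates.

    ``path='deconvolution'`` reconstructs the record with the filter's exact
    transfer function before fitting; ``path='standard'`` fits the filtered
    record directly with 60-us blanking and peak extrapolation to
    ``zero_time`` (or tunes the zero time on the record when None).
    """
    w = _warmup_periods(filt, protocol) if warmup is None else warmup
    x = simulate_square_wave(params, protocol.with_periods(w + protocol.n_periods))
    y = apply_filter(x, filt)
    n = protocol.n_periods * protocol.samples_per_period
    retained = CurrentTrace(y.samples[-n:], y.dt)
    if path == "deconvolution":
        H = TransferFunction.from_filter(filt, n)
        rec = deconvolve(retained, H)
        df = analyze_square_record(rec, protocol, blank_head=blank_head)
    elif path == "standard":
        grid = None if zero_time is None else np.array([zero_time])
        df, _, _ = standard_procedure_fit(retained, protocol, zero_time_grid=grid)
    else:
        raise InvalidParameterError(f"unknown analysis path {path!r}")
    return per_period_means(df)


def reduce_bandwidth(series: ImpedanceSeries, bandwidth: float) -> ImpedanceSeries:
    """Reduce the analysis bandwidth by non-overlapping block averaging.

    The block size is ``m = round(f_s / B)`` (at least 1); a trailing
    incomplete block is dropped.  ``B`` must not exceed the stimulation
    frequency.
    """
    if bandwidth > series.f_s:
        raise InvalidParameterError("bandwidth cannot exceed the stimulation frequency")
    m = max(1, int(round(series.f_s / bandwidth)))
    if m == 1:
        return ImpedanceSeries(series.data.copy(), series.f_s, bandwidth, series.m)
    df = series.data
    n_blocks = len(df) // m
    if n_blocks < 1:
        raise InvalidParameterError("series shorter than one averaging block")
    trimmed = df.iloc[: n_blocks * m]
    groups = np.repeat(np.arange(n_blocks), m)
    num = trimmed.select_dtypes(include=[np.number])
    out = num.groupby(groups).mean().reset_index(drop=True)
    return ImpedanceSeries(out, series.f_s, bandwidth, series.m * m)


def tune_standard_zero_time(
    filt: DigitalFilter,
    params: CircuitParams,
    v_stim: float,
    f_samp: float,
    seed: int = 0,
    sigma_ra: float = 100e3,
    n_periods: int = 50,
    blank_head: float = 60e-6,
) -> float:
    """Calibrate the zero-time correction of the standard procedure.

    A record with the access resistance jittering period by period is
    simulated and the zero time minimizing the |C_M - R_A| correlation over
    the record is selected, exactly as done on real recordings before an
    experiment.
    """
    protocol = protocol_for(params, v_stim, f_samp, n_periods=n_periods)
    rng = np.random.default_rng(seed)
    ras = np.clip(rng.normal(params.r_a, sigma_ra, n_periods), 0.2 * params.r_a, None)
    w = _warmup_periods(filt, protocol)
    per_period = [params] * w + [params.replace(r_a=float(r)) for r in ras]
    x = simulate_square_wave(per_period, protocol.with_periods(w + n_periods))
    y = apply_filter(x, filt)
    n = n_periods * protocol.samples_per_period
    retained = CurrentTrace(y.samples[-n:], y.dt)
    _, t_z, _ = standard_procedure_fit(retained, protocol, blank_head=blank_head)
    return t_z


def accuracy_experiment(
    n_triplets: int = 100,
    seed: int = 0,
    v_stim: float = 80e-3,
    f_samp: float = 100e3,
    f_c: float = 10e3,
) -> pd.DataFrame:
    """Accuracy of the deconvolution chain over random circuit triplets.

    For each uniformly drawn (C_M, R_M, R_A) triplet a filtered record at the
    optimal 12-tau period is reconstructed and analysed; the table reports
    the absolute current-parameter errors (d_tau, d_i_s, d_i_p against the
    theoretical values V/R_A and V/(R_M+R_A)) and the relative circuit-
    parameter errors against the seeded values, as functions of tau.
    """
    filt = design_bessel4(f_c, f_samp)
    rows = []
    for trip in random_triplets(n_triplets, seed):
        p = trip.to_circuit()
        tau = time_constant(p)
        protocol = protocol_for(p, v_stim, f_samp)
        m = measure_record(p, protocol, filt).iloc[0]
        i_p_th = v_stim / p.r_a - v_stim / (p.r_m + p.r_a)
        i_s_th = v_stim / (p.r_m + p.r_a)
        rows.append(
            dict(
                tau=tau,
                c_m=p.c_m, r_m=p.r_m, r_a=p.r_a,
                d_tau=m.tau - tau,
                d_i_s=m.i_s - i_s_th,
                d_i_p=m.i_p - i_p_th,
                rel_c_m=(m.c_m - p.c_m) / p.c_m,
                rel_r_m=(m.r_m - p.r_m) / p.r_m,
                rel_r_a=(m.r_a - p.r_a) / p.r_a,
            )
        )
    return pd.DataFrame(rows)


def crosstalk_experiment(
    n_pairs: int = 100,
    seed: int = 0,
    perturb: tuple[str, float] = ("r_a", 1e6),
    v_stim: float = 80e-3,
    f_samp: float = 100e3,
    f_c: float = 10e3,
    include_standard: bool = True,
) -> pd.DataFrame:
    """Cross-talk of a single-parameter change into the other estimates.

    For each random triplet a sibling differing only in ``perturb`` (default:
    access resistance increased by 1 MOhm) is measured with the same
    protocol, and the estimate differences are tabulated for the
    deconvolution path and, optionally, for the standard blank-and-
    extrapolate procedure with a pre-calibrated zero time.
    """
    field_name, delta = perturb
    filt = design_bessel4(f_c, f_samp)
    t_z = None
    if include_standard:
        t_z = tune_standard_zero_time(
            filt, CircuitParams(50e-12, 200e6, 5e6), v_stim, f_samp, seed=seed
        )
    rows = []
    for trip in random_triplets(n_pairs, seed):
        p0 = trip.to_circuit()
        p1 = p0.replace(**{field_name: getattr(p0, field_name) + delta})
        protocol = protocol_for(p0, v_stim, f_samp)
        row = dict(tau=time_constant(p0), c_m=p0.c_m, r_m=p0.r_m, r_a=p0.r_a)
        for path, suffix in (("deconvolution", ""), ("standard", "_std")):
            if path == "standard" and not include_standard:
                continue
            m0 = measure_record(p0, protocol, filt, path=path, zero_time=t_z).iloc[0]
            m1 = measure_record(p1, protocol, filt, path=path, zero_time=t_z).iloc[0]
            row[f"d_c_m{suffix}"] = m1.c_m - m0.c_m
            row[f"d_r_m{suffix}"] = m1.r_m - m0.r_m
            row[f"d_r_a{suffix}"] = m1.r_a - m0.r_a
        rows.append(row)
    return pd.DataFrame(rows)


def resolution_vs_ra_fluctuation(
    seed: int = 0,
    sigma_ra: tuple[float, ...] = RA_SIGMA_DEFAULTS,
    n_periods: int = 500,
    c_m: float = 50e-12,
    r_m: float = 200e6,
    r_a: float = 5e6,
    v_stim: float = 20e-3,
    f_samp: float = 100e3,
    f_c: float = 10e3,
    bandwidth: float = 50.0,
    t_abs: float = ROOM_TEMPERATURE_K,
    include_standard: bool = True,
) -> pd.DataFrame:
    """Capacitance resolution limited by access-resistance fluctuation.

    The access resistance jitters randomly (normal, clipped positive) around
    its mean, period by period; the records are otherwise noiseless, so any
    spread of the C_M estimates is pure R_A -> C_M cross-talk.  The standard
    deviation of the C_M series after reduction to ``bandwidth`` is reported
    for each fluctuation magnitude, together with the thermal-noise
    resolution floor of the same configuration for comparison.
    """
    filt = design_bessel4(f_c, f_samp)
    base = CircuitParams(c_m=c_m, r_m=r_m, r_a=r_a)
    protocol = protocol_for(base, v_stim, f_samp)
    floor = thermal_limit(c_m, r_a, v_stim, bandwidth, t_abs)
    t_z = None
    if include_standard:
        t_z = tune_standard_zero_time(filt, base, v_stim, f_samp, seed=seed)
    rng = np.random.default_rng(seed)
    rows = []
    for s in sigma_ra:
        ras = np.clip(rng.normal(r_a, s, n_periods), 0.2 * r_a, None)
        series = {"deconvolution": [], "standard": []}
        for r in ras:
            p = base.replace(r_a=float(r))
            series["deconvolution"].append(
                measure_record(p, protocol, filt).iloc[0].c_m
            )
            if include_standard:
                series["standard"].append(
                    measure_record(
                        p, protocol, filt, path="standard", zero_time=t_z
                    ).iloc[0].c_m
                )
        row = dict(sigma_ra=s, thermal_floor=floor, f_s=protocol.f_s)
        for path in ("deconvolution", "standard"):
            if not series[path]:
                continue
            raw = ImpedanceSeries(pd.DataFrame({"c_m": series[path]}), protocol.f_s)
            red = reduce_bandwidth(raw, bandwidth)
            row[f"sigma_c_m_{path}"] = float(red.data["c_m"].std(ddof=1))
            row["m"] = red.m
        rows.append(row)
    return pd.DataFrame(rows)


def seal_sweep_experiment(
    c_m: float = 140e-12,
    r_m: float = 500e6,
    r_a: float = 4e6,
    v_stim: float = 20e-3,
    f_samp: float = 100e3,
    f_c: float = 10e3,
    r_seal_start: float = 1e9,
    r_seal_stop: float = 150e9,
    r_seal_step: float = 100e6,
    halfs_per_tau: float = 3.0,
    include_infinite: bool = True,
) -> pd.DataFrame:
    """Apparent circuit parameters as the seal resistance degrades.

    The seal resistance is stepped period by period from ``r_seal_start`` to
    ``r_seal_stop`` (default 1 -> 150 GOhm in 100 MOhm increments, with a
    6-tau stimulation period) and the apparent C_M, R_M, R_A and the
    capacitive charge Q_C are tabulated; an ideal-seal row (R_Seal infinite)
    is appended for reference.  The leak shifts the apparent C_M and R_M
    strongly below about 10 GOhm while leaving R_A nearly untouched and Q_C
    exactly unchanged.
    """
    filt = design_bessel4(f_c, f_samp)
    n_steps = int(round((r_seal_stop - r_seal_start) / r_seal_step)) + 1
    seals = list(r_seal_start + r_seal_step * np.arange(n_steps))
    if include_infinite:
        seals.append(math.inf)
    base = CircuitParams(c_m=c_m, r_m=r_m, r_a=r_a)
    protocol = protocol_for(base, v_stim, f_samp, halfs_per_tau=halfs_per_tau)
    rows = []
    for r_seal in seals:
        p = base.replace(r_seal=float(r_seal))
        m = measure_record(p, protocol, filt).iloc[0]
        rows.append(
            dict(r_seal=r_seal, c_m=m.c_m, r_m=m.r_m, r_a=m.r_a, q_c=m.q_c,
                 tau=m.tau)
        )
    return pd.DataFrame(rows)


def simulate_event_series(
    kind: str,
    base: CircuitParams | None = None,
    v_stim: float = 60e-3,
    f_samp: float = 100e3,
    f_c: float = 10e3,
    n_periods: int = 40,
    change_at: int = 20,
    c_m_step: float = 0.3e-12,
    r_seal_step: tuple[float, float] = (100e9, 10e9),
    c_p_step: float = 1.8e-12,
) -> ImpedanceSeries:
    """Synthetic impedance time series containing one step event.

    ``kind``: 'capacitance' (a true membrane-capacitance step),
    'seal' (a drop of the seal resistance) or 'parasitic' (a step of the
    uncompensated pipette capacitance).  The series is measured with the
    deconvolution path, period by period.
    """
    if base is None:
        base = CircuitParams(c_m=140e-12, r_m=500e6, r_a=4e6, r_seal=r_seal_step[0])
    filt = design_bessel4(f_c, f_samp)
    protocol = protocol_for(base, v_stim, f_samp)
    if kind == "capacitance":
        after = base.replace(c_m=base.c_m + c_m_step)
    elif kind == "seal":
        after = base.replace(r_seal=r_seal_step[1])
    elif kind == "parasitic":
        after = base.replace(c_p=base.c_p + c_p_step)
    else:
        raise InvalidParameterError(f"unknown event kind {kind!r}")
    rows = []
    for i in range(n_periods):
        p = base if i < change_at else after
        m = measure_record(p, protocol, filt).iloc[0]
        rows.append(dict(period=i, c_m=m.c_m, r_m=m.r_m, r_a=m.r_a, q_c=m.q_c))
    return ImpedanceSeries(pd.DataFrame(rows), protocol.f_s)


def detect_step(x: np.ndarray, k: float = 5.0, sigma_floor: float = 0.0) -> int:
    """Two-sided CUSUM change-point detector on a 1-D series.

    The noise scale is the robust (MAD-based) standard deviation of the
    series' first differences, floored at ``sigma_floor``; an alarm requires
    the cumulative excursion to exceed ``k`` times the scale.  Returns the
    onset index (first sample after the change).  Raises
    :class:`NoStepError` when no alarm fires.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise NoStepError("series too short for step detection")
    d = np.diff(x)
    sigma = max(1.4826 * float(np.median(np.abs(d - np.median(d)))), sigma_floor)
    if sigma <= 0:
        sigma = max(abs(np.mean(x)) * 1e-12, 1e-300)
    baseline = float(np.median(x[: max(2, x.size // 4)]))
    drift = 0.5 * sigma
    g_pos = g_neg = 0.0
    alarm = -1
    for i, v in enumerate(x):
        g_pos = max(0.0, g_pos + (v - baseline) - drift)
        g_neg = max(0.0, g_neg - (v - baseline) - drift)
        if g_pos > k * sigma or g_neg > k * sigma:
            alarm = i
            break
    if alarm < 0:
        raise NoStepError("no step detected")
    # refine the onset as the largest jump near the alarm
    lo = max(1, alarm - 5)
    hi = min(x.size - 1, alarm + 5)
    onset = lo + int(np.argmax(np.abs(np.diff(x[lo - 1 : hi + 1]))))
    return onset


def classify_event(
    window: ImpedanceSeries | pd.DataFrame,
    thresholds: EventThresholds,
) -> EventCall:
    """Classify the step in an impedance window by its cross-trace signature.

    - a C_M step mirrored in Q_C with stable R_M and R_A is a true
      membrane-capacitance change;
    - an anti-correlated C_M/R_M step with stable R_A and Q_C is a
      seal-resistance artefact;
    - a correlated C_M/R_A step is a parasitic-capacitance artefact;
    - anything else is unclassified.
    """
    df = window.data if isinstance(window, ImpedanceSeries) else window
    c = df["c_m"].to_numpy()
    onset = detect_step(c, k=thresholds.k_detect, sigma_floor=thresholds.c_m_sigma)
    if onset < 2 or onset > len(df) - 2:
        raise NoStepError("step too close to the window edge")
    pre = df.iloc[: onset]
    post = df.iloc[onset:]
    delta = {col: float(post[col].median() - pre[col].median())
             for col in ("c_m", "r_m", "r_a", "q_c")}

    sig_c = abs(delta["c_m"]) > thresholds.k_sig * thresholds.c_m_sigma
    sig_q = abs(delta["q_c"]) > thresholds.k_sig * thresholds.q_c_sigma
    sig_rm = abs(delta["r_m"]) > thresholds.r_rel * abs(float(pre["r_m"].median()))
    sig_ra = abs(delta["r_a"]) > thresholds.r_rel * abs(float(pre["r_a"].median()))
    q_consistent = sig_q and delta["q_c"] * delta["c_m"] > 0

    if sig_c and sig_rm and delta["c_m"] * delta["r_m"] < 0 and not sig_ra and not sig_q:
        label = "seal-artefact"
    elif sig_c and not sig_rm and not sig_ra and q_consistent:
        label = "true-capacitance"
    elif sig_c and sig_ra:
        label = "parasitic-artefact"
    else:
        label = "unclassified"
    return EventCall(
        onset=onset,
        d_c_m=delta["c_m"],
        d_r_m=delta["r_m"],
        d_r_a=delta["r_a"],
        d_q_c=delta["q_c"],
        classification=label,
    )
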