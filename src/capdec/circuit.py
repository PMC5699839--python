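"""Equivalent-circuit simulation of whole-cell patch-clamp current responses.

The recorded cell is represented by the standard three-element whole-cell
circuit: membrane capacitance ``C_M`` in parallel with membrane resistance
``R_M``, both in series with the pipette access resistance ``R_A``.  Two
non-idealities can be added: a finite pipette-membrane seal resistance
``R_Seal`` (a constant leak path from the command potential to ground) and a
parasitic pipette capacitance ``C_P`` that is charged directly by the command
voltage, i.e. not attenuated by ``R_A``.

The voltage-clamp current response of the ideal circuit to a voltage step of
amplitude ``V`` applied at t = 0 from rest is

    I(t) = V * [ e^(-t/tau) / R_A + (1 - e^(-t/tau)) / (R_M + R_A) ]

with the charging time constant

    tau = C_M * R_M * R_A / (R_M + R_A).

A finite seal adds the constant term ``V / R_Seal``.  The module also carries
an exact state-based simulator for continuous bipolar square-wave stimulation
(the membrane-capacitor voltage is propagated analytically across half-period
boundaries, so no steady-state assumption is made), a bi-exponential
fusion-pore current generator, Johnson (thermal) current noise, and the
uniform random generator of circuit-parameter triplets used by the
validation experiments.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import constants

__all__ = [
    "ROOM_TEMPERATURE_K",
    "TRIPLET_RANGES",
    "CircuitParams",
    "StimulusProtocol",
    "CurrentTrace",
    "ParameterTriplet",
    "time_constant",
    "simulate_step",
    "simulate_square_wave",
    "simulate_fusion_current",
    "fusion_tau2",
    "add_thermal_noise",
    "random_triplets",
]

#: Laboratory temperature (about 23 degrees C) used as the default for all
#: thermal-noise calculations, in kelvin.
ROOM_TEMPERATURE_K = 296.15

#: Uniform sampling ranges of the random circuit-parameter triplets:
#: (low, high) in the reporting units pF, GOhm and MOhm respectively.
TRIPLET_RANGES = {
    "c_m_pF": (5.0, 200.0),
    "r_m_GOhm": (0.02, 2.0),
    "r_a_MOhm": (2.0, 20.0),
}


class InvalidParameterError(ValueError):
    """A circuit or protocol parameter violates its physical constraints."""


@dataclass(frozen=True)
class CircuitParams:
    """Electrical model of one whole-cell recording configuration.

    Parameters are in SI units: farads and ohms.  ``r_seal`` may be infinite
    (ideal seal) and ``c_p`` may be zero (fully compensated pipette).
    """

    c_m: float
    r_m: float
    r_a: float
    r_seal: float = math.inf
    c_p: float = 0.0

    def __post_init__(self) -> None:
        if not (self.r_m > 0 and self.r_a > 0 and self.r_seal > 0):
            raise InvalidParameterError("resistances must be positive")
        if self.c_m < 0 or self.c_p < 0:
            raise InvalidParameterError("capacitances must be non-negative")

    def replace(self, **changes) -> "CircuitParams":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class StimulusProtocol:
    """Bipolar square-wave stimulation protocol.

    ``v_stim`` is the FULL step amplitude in volts (peak to peak of the
    bipolar wave): a "+/-40 mV" protocol has ``v_stim = 0.08``.  The command
    potential alternates between ``holding - v_stim/2`` and
    ``holding + v_stim/2``, starting with the positive half-period.
    """

    v_stim: float
    t_s: float
    f_samp: float
    n_periods: int = 1
    holding: float = 0.0

    def __post_init__(self) -> None:
        if self.t_s <= 0 or self.f_samp <= 0:
            raise InvalidParameterError("t_s and f_samp must be positive")
        if self.n_periods < 1:
            raise InvalidParameterError("n_periods must be >= 1")
        n = self.t_s * self.f_samp
        if abs(n - round(n)) > 1e-6 * max(1.0, n):
            raise InvalidParameterError(
                "t_s * f_samp must be an integer number of samples"
            )
        n = int(round(n))
        if n % 2 != 0:
            raise InvalidParameterError("a period must hold two equal half-periods")
        if n // 2 < 8:
            raise InvalidParameterError("need at least 8 samples per half-period")

    @property
    def dt(self) -> float:
        return 1.0 / self.f_samp

    @property
    def samples_per_period(self) -> int:
        return int(round(self.t_s * self.f_samp))

    @property
    def samples_per_half(self) -> int:
        return self.samples_per_period // 2

    @property
    def half_duration(self) -> float:
        return self.samples_per_half * self.dt

    @property
    def f_s(self) -> float:
        """Stimulation frequency in Hz."""
        return 1.0 / self.t_s

    def with_periods(self, n_periods: int) -> "StimulusProtocol":
        return dataclasses.replace(self, n_periods=n_periods)


@dataclass
class CurrentTrace:
    """Uniformly sampled current record.

    ``t0_offset`` is the time of the first sample relative to the step onset;
    synthetic records use 0 (sample 0 lies exactly at the onset).  ``meta``
    carries free-form provenance written into text headers on export.
    """

    samples: np.ndarray
    dt: float
    t0_offset: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.dt <= 0:
            raise InvalidParameterError("dt must be positive")
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise InvalidParameterError("a trace needs at least two samples")
        if not np.all(np.isfinite(self.samples)):
            raise InvalidParameterError("trace samples must be finite")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def f_samp(self) -> float:
        return 1.0 / self.dt

    @property
    def times(self) -> np.ndarray:
        return self.t0_offset + self.dt * np.arange(self.samples.size)

    def copy_with(self, samples: np.ndarray, **meta) -> "CurrentTrace":
        merged = dict(self.meta)
        merged.update(meta)
        return CurrentTrace(np.array(samples, dtype=float), self.dt,
                            self.t0_offset, merged)


@dataclass(frozen=True)
class ParameterTriplet:
    """One random draw of (C_M, R_M, R_A) in the reporting units pF/GOhm/MOhm."""

    c_m_pF: float
    r_m_GOhm: float
    r_a_MOhm: float

    def to_circuit(self, r_seal: float = math.inf, c_p: float = 0.0) -> CircuitParams:
        return CircuitParams(
            c_m=self.c_m_pF * 1e-12,
            r_m=self.r_m_GOhm * 1e9,
            r_a=self.r_a_MOhm * 1e6,
            r_seal=r_seal,
            c_p=c_p,
        )


def time_constant(params: CircuitParams) -> float:
    """Charging time constant tau = C_M * (R_M || R_A) in seconds."""
    if params.c_m <= 0:
        raise InvalidParameterError("time constant requires c_m > 0")
    return params.c_m * params.r_m * params.r_a / (params.r_m + params.r_a)


def _leak(params: CircuitParams, v: float) -> float:
    return 0.0 if math.isinf(params.r_seal) else v / params.r_seal


def simulate_step(
    params: CircuitParams,
    v_step: float,
    duration: float,
    dt: float,
    holding: float = 0.0,
) -> CurrentTrace:
    """Current response to a single voltage step applied at t = 0 from rest.

    The cell is assumed equilibrated at ``holding`` before the step; the
    command jumps to ``holding + v_step`` at sample 0.  A finite seal adds the
    constant leak of the post-step command potential; a nonzero ``c_p``
    contributes a one-sample charge impulse ``c_p * v_step / dt`` at onset
    (the physical parasitic charging is faster than one sample).
    """
    if duration < dt:
        raise InvalidParameterError("duration must cover at least one sample")
    n = int(round(duration / dt))
    t = dt * np.arange(n)
    tau = time_constant(params)
    v_cmd = holding + v_step
    decay = np.exp(-t / tau)
    i = v_step * (decay / params.r_a + (1.0 - decay) / (params.r_m + params.r_a))
    # contribution of the pre-step equilibrium at the holding potential
    i += holding / (params.r_m + params.r_a)
    i += _leak(params, v_cmd)
    if params.c_p > 0:
        i[0] += params.c_p * v_step / dt
    return CurrentTrace(i, dt, 0.0, {"v_step": v_step, "holding": holding})


def simulate_square_wave(
    params: CircuitParams | Sequence[CircuitParams],
    protocol: StimulusProtocol,
    initial_membrane_voltage: float | None = None,
) -> CurrentTrace:
    """Exact simulation of the response to continuous bipolar stimulation.

    The single state variable is the voltage across the membrane capacitor;
    it is updated analytically over every half-period, so half-periods are
    exact exponentials that carry the true transient history across
    boundaries.  ``params`` may be one :class:`CircuitParams` (constant
    circuit) or one per period, which lets the circuit change at period
    boundaries (access-resistance siblings, seal sweeps, capacitance steps).
    """
    if isinstance(params, CircuitParams):
        per_period = [params] * protocol.n_periods
    else:
        per_period = list(params)
        if len(per_period) != protocol.n_periods:
            raise InvalidParameterError(
                f"need one parameter set per period: got {len(per_period)} "
                f"for {protocol.n_periods} periods"
            )

    n_half = protocol.samples_per_half
    dt = protocol.dt
    t_half = protocol.half_duration
    t = dt * np.arange(n_half)

    p0 = per_period[0]
    if initial_membrane_voltage is None:
        u = protocol.holding * p0.r_m / (p0.r_m + p0.r_a)
    else:
        u = float(initial_membrane_voltage)

    out = np.empty(2 * protocol.n_periods * n_half)
    v_prev = protocol.holding
    for h in range(2 * protocol.n_periods):
        p = per_period[h // 2]
        sign = 1.0 if h % 2 == 0 else -1.0
        v_cmd = protocol.holding + sign * protocol.v_stim / 2.0
        tau = time_constant(p)
        u_inf = v_cmd * p.r_m / (p.r_m + p.r_a)
        u_t = u_inf + (u - u_inf) * np.exp(-t / tau)
        seg = (v_cmd - u_t) / p.r_a + _leak(p, v_cmd)
        if p.c_p > 0:
            seg[0] += p.c_p * (v_cmd - v_prev) / dt
        out[h * n_half : (h + 1) * n_half] = seg
        u = u_inf + (u - u_inf) * math.exp(-t_half / tau)
        v_prev = v_cmd
    return CurrentTrace(
        out,
        dt,
        0.0,
        {
            "v_stim": protocol.v_stim,
            "t_s": protocol.t_s,
            "f_samp": protocol.f_samp,
            "n_periods": protocol.n_periods,
            "holding": protocol.holding,
        },
    )


def fusion_tau2(c_v: float, g_p: float) -> float:
    """Slow time constant of a fusion event: vesicle capacitance over pore
    conductance, tau2 = C_v / G_p."""
    if c_v <= 0 or g_p <= 0:
        raise InvalidParameterError("c_v and g_p must be positive")
    return c_v / g_p


def simulate_fusion_current(
    base,
    i_p2: float,
    tau2: float,
    duration: float,
    dt: float,
) -> CurrentTrace:
    """Bi-exponential current of a cell with a vesicle connected by a fusion
    pore:

        I(t) = I_S + I_P * e^(-t/tau) + I_P2 * e^(-t/tau2)

    ``base`` supplies the three-element components (anything with ``i_s``,
    ``i_p`` and ``tau`` attributes, or an ``(i_s, i_p, tau)`` tuple); the slow
    component has amplitude ``i_p2`` and time constant ``tau2 = C_v / G_p``.
    """
    if tau2 <= 0:
        raise InvalidParameterError("tau2 must be positive")
    if hasattr(base, "i_s"):
        i_s, i_p, tau = base.i_s, base.i_p, base.tau
    else:
        i_s, i_p, tau = base
    n = int(round(duration / dt))
    t = dt * np.arange(n)
    i = i_s + i_p * np.exp(-t / tau) + i_p2 * np.exp(-t / tau2)
    return CurrentTrace(i, dt, 0.0, {"tau2": tau2, "i_p2": i_p2})


def add_thermal_noise(
    trace: CurrentTrace,
    r: float,
    t_abs: float = ROOM_TEMPERATURE_K,
    seed: int | np.random.Generator | None = None,
) -> CurrentTrace:
    """Add zero-mean white Johnson current noise of a resistance ``r``.

    The per-sample standard deviation is ``sqrt(4 k T B / r)`` with the noise
    bandwidth ``B = f_samp / 2`` (white within the sampled band).  At zero
    absolute temperature the trace is returned unchanged except for a copy.
    """
    if r <= 0:
        raise InvalidParameterError("r must be positive")
    if t_abs < 0:
        raise InvalidParameterError("t_abs must be non-negative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    sigma = math.sqrt(4.0 * constants.k * t_abs * (trace.f_samp / 2.0) / r)
    noise = rng.normal(0.0, sigma, size=len(trace)) if sigma > 0 else 0.0
    return trace.copy_with(trace.samples + noise, noise_sigma=sigma)


def random_triplets(n: int, seed: int | np.random.Generator | None = None) -> list[ParameterTriplet]:
    """Draw ``n`` independent uniform (C_M, R_M, R_A) triplets.

    The ranges are C_M in [5, 200] pF, R_M in [0.02, 2] GOhm and R_A in
    [2, 20] MOhm, sampled independently and uniformly.
    """
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    c_lo, c_hi = TRIPLET_RANGES["c_m_pF"]
    m_lo, m_hi = TRIPLET_RANGES["r_m_GOhm"]
    a_lo, a_hi = TRIPLET_RANGES["r_a_MOhm"]
    return [
        ParameterTriplet(
            c_m_pF=rng.uniform(c_lo, c_hi),
            r_m_GOhm=rng.uniform(m_lo, m_hi),
            r_a_MOhm=rng.uniform(a_lo, a_hi),
        )
        for _ in range(n)
    ]
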