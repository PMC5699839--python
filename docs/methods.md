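# Methods

`capdec` measures whole-cell membrane impedance from current responses to
bipolar square-wave voltage stimulation, after first undoing the distortion
that the recording path's low-pass output filter imprints on every record.
This note documents the model, the conventions and the numerical choices, and
states what the synthetic validation experiments do and do not demonstrate.

## The equivalent circuit and its response

A homogeneously voltage-clamped cell in the whole-cell configuration is
modelled by three elements: the membrane capacitance `C_M` in parallel with
the membrane resistance `R_M`, in series with the pipette access resistance
`R_A`. Two non-idealities extend the model: a finite pipette–membrane seal
resistance `R_Seal` (a leak from the command potential directly to ground)
and a parasitic pipette capacitance `C_P` charged by the command voltage
without `R_A` attenuation.

The ideal response to a voltage step `V` applied at `t = 0` from rest is

    I(t) = V [ e^(−t/τ)/R_A + (1 − e^(−t/τ))/(R_M + R_A) ]  + V/R_Seal ,
    τ    = C_M R_M R_A / (R_M + R_A) ,

with peak `I_P = V/R_A` and steady level `I_S = V/(R_M + R_A)`. Inverting a
fitted response `I(t) = I_S + I_P e^(−t/τ)` gives

    R_A = V_Stim/(I_P + I_S),   R_M = V_Stim/I_S − R_A,
    C_M = τ (1/R_M + 1/R_A).

**Voltage convention.** A "±A mV" protocol alternates the command between
−A and +A around the holding potential; the step seen at every half-period
boundary, and the `V_Stim` used in the inversion formulas, is the full
peak-to-peak amplitude `2A`. Only this convention makes the inversion
consistent with re-referencing each half-period to the preceding one.

**Simulator.** `simulate_square_wave` is exact: the single state variable
(the membrane-capacitor voltage) is propagated analytically across
half-period boundaries, so no steady-state assumption enters and every
half-period is a true exponential carrying the full transient history.
Parameters may change at period boundaries, which is how the cross-talk
siblings, the seal sweep and the capacitance-step events are produced.
`C_P` is rendered as a one-sample charge impulse `C_P ΔV / dt` at each step
onset: the physical parasitic charging is much faster than one 10 µs sample
because it is not slowed by `R_A`.

## Filter emulation

The amplifier's 10 kHz 4-pole Bessel output filter is emulated digitally by
impulse invariance: the magnitude-normalized analog prototype (−3 dB at
`f_c`, the convention of amplifier data sheets; a delay-normalized prototype
would be roughly twice as fast) is expanded in partial fractions, the poles
are mapped by `z = e^(p/f_samp)` with the conventional `1/f_samp` gain, and
the result is rescaled to exact unity DC gain, removing the small aliasing
bias of the method at zero frequency. Below the corner the digital magnitude
matches the analog one within 1 % when sampling at ten times the corner.

The step response of the 10 kHz / 100 kHz design reaches half of its final
amplitude at 32.9 µs. Sample `n` of the discrete step response is assigned
the time `(n + 1/2)/f_samp`: the running sum of an impulse-invariant filter
is the midpoint-rule integral of the analog impulse response, so the
half-sample shift removes the discretization bias — the value then agrees
with the analog prototype's 32.94 µs independently of the sampling rate, and
with hardware measurements of such filters (≈34 µs) within the alignment of
one sample.

## Transfer function and deconvolution

The recorded current is the convolution of the input current with the
impulse response `h` of the signal path. `h` is obtained from a measured
record pair — the response to a one-sample voltage impulse with a resistor
grounded (R+C) and ungrounded (C), each averaged over thousands of repeats —
by subtraction; its FFT normalized to unity at DC is the system frequency
characteristic `H_S`. (The "0–1 normalization" is interpreted as DC-gain
normalization: `H_S(0) = 1`, magnitudes ≤ 1 for a low-pass path.) For
synthetic work, `H_S` of the known digital filter is evaluated exactly from
its rational transfer function on the FFT bin grid.

Reconstruction divides the record's FFT bin-wise by `H_S` and inverse
transforms, taking the real part (the residual imaginary part is asserted
below 1e−9 of the signal RMS). The division treats the record as circularly
convolved, which is exact when the record holds an integer number of
stimulation periods of a settled periodic stimulus; the package therefore
deconvolves whole records without windowing, and the simulator-driven
experiments discard enough warm-up periods that both the circuit (state
error < e^(−60)) and the filter memory (< 1e−16) are settled before the
retained window starts. With a measured, noisy `H_S`, a Tikhonov-style guard
`Y conj(H)/(|H|² + ε)` is available (recommended ε ≈ 1e−6 of the peak
`|H|²`); for the exact synthetic `H_S` the default is ε = 0. Uncancelled
parasitic capacitance survives reconstruction as an onset disturbance; it is
removed either by subtracting a cell-attached record before deconvolution or
by blanking the first ~60 µs of each half-period from the fit (an explicit
option, off by default).

## Half-period fitting and re-referencing

Records are segmented into half-periods, folded to positive-going
relaxations, and fitted by unweighted Levenberg–Marquardt with analytic
Jacobian (`xtol = ftol = gtol = 1e−15`, ≤ 600 evaluations). Initial guesses:
steady level from the tail mean (last 10 % of samples, ≥ 2), amplitude from
the first usable sample, τ from a log-linear regression of the early
transient. A segment whose transient amplitude is indistinguishable from
zero (pure resistor) is returned flagged, with τ = NaN, never as an
exception.

Because a half-period spans a finite number of time constants (6τ at the
optimal period), the preceding half-period never settles completely and raw
tail levels are biased by O(e^(−6)) of the transient amplitude — enough to
corrupt `R_M` by the factor `R_M/R_A` and `R_A` by ~0.25 %. The package
therefore references each half-period to the preceding *fit*, not to raw
samples:

* the steady level entering `R_M = V/I_S − R_A` is the difference of
  consecutive fitted asymptotes (asymptotes are state-independent, so this
  is exact in any settling state);
* the peak entering `R_A = V/(I_P + I_S)` is referenced to the preceding
  fit extrapolated to the boundary instant — by continuity of the
  membrane-capacitor voltage the current discontinuity at a command step is
  exactly `V_Stim/R_A`, again in any settling state.

With this convention the inversion recovers the seeded parameters of
noiseless synthetic records to numerical precision (~1e−10 relative) even
for 3τ half-periods, and the two half-period estimates of each period are
averaged. The capacitive charge is the discrete integral
`Q_C = dt Σ (I(n) − I_S)` of the fitted half-period above its own asymptote;
it is independent of both the leak level and the re-reference constant.

**Comparison baseline.** The conventional procedure fits the *filtered*
record with the first 60 µs of each half-period blanked and extrapolates the
peak to an assumed step instant ("zero time"). The zero time is tuned on a
0.1 µs grid (default 0–60 µs) to minimize the absolute Pearson correlation
between the `C_M` and `R_A` series of a calibration record in which `R_A`
jitters — the practical criterion used at the rig; the exact
window/weighting of that criterion is not standardized, and plain
whole-record Pearson correlation is used here. Because the blanked fit is
still contaminated by the filter transient (the filter modes decay only
~e^(−2.5) within 60 µs), this baseline carries the access-resistance
cross-talk that the reconstruction path eliminates.

**Five-element (fusion-pore) model.** A vesicle of capacitance `C_v`
connected through a pore of conductance `G_p` adds a slow exponential with
`τ₂ = C_v/G_p`. The bi-exponential fit is seeded from the three-element fit
(slow component at `0.1 I_P`, `5τ`), components are ordered by time
constant, and the model is preferred when it improves the SSE at least
2-fold (configurable). `C_v` may be supplied (e.g. the observed `C_M` step)
or estimated from the slow component's charge `I_P2 τ₂ / V_Stim`; `G_p`
follows as `C_v/τ₂`. A fitted `τ₂` collapsing below the sampling interval is
reported as a fully open pore (conductance no longer calculable) rather than
a number.

## Noise model and resolution

Johnson current noise of a resistance `R` is white within the sampled band:
per-sample standard deviation `sqrt(4 k T (f_samp/2)/R)` at the default
laboratory temperature 296.15 K (~23 °C). The corresponding resolution limit
of the capacitance estimate at analysis bandwidth `B` is

    σC_M = C_M sqrt(4 k T B R_A) / V_Stim .

Bandwidth reduction averages non-overlapping blocks of `m = round(f_S/B)`
per-period estimates (minimum 1; the rounding is nearest-integer, which the
plain ratio `m = f_S/B` leaves open).

## Validation experiments: scales and what they show

All experiments run from a seed, bit-for-bit reproducibly, and analyse each
stimulation period from its own settled mini-record (quasi-static sweeps:
parameters constant within a period). Default problem sizes are chosen so
the full suite runs in well under a minute on one core:

* **Accuracy sweep** — 100 random triplets, `C_M ∈ [5, 200]` pF,
  `R_M ∈ [0.02, 2]` GΩ, `R_A ∈ [2, 20]` MΩ, ±40 mV, 12τ periods, noiseless.
  Observed relative errors are at float precision (≤ 1e−13), far inside the
  printed bounds (`C_M` ≤ 0.02 %, `R_A` ≤ 0.03 % for τ > 100 µs, `R_M`
  ≤ 0.1 % for τ > 500 µs). Accuracy simulations are run noiseless because
  they characterize the systematic error of the chain; noise enters only the
  resolution studies.
* **Cross-talk** — 100 sibling pairs differing by +1 MΩ in `R_A` (or
  +100 MΩ in `R_M`): the recovered `ΔR_A` is 1.0000 MΩ and `ΔC_M` stays
  below 1e−9 fF (bounds: 0.9995 ± 0.001 MΩ; < 1 fF; < 0.2 fF for the `R_M`
  sibling). The standard baseline on the same records shows errors up to
  hundreds of fF.
* **Resolution vs `R_A` fluctuation** — (50 pF, 200 MΩ, 5 MΩ, ±10 mV),
  seven fluctuation magnitudes from 22.6 to 452.1 kΩ, 200 periods each at
  50 Hz bandwidth: the reconstruction path's cross-talk contribution to
  σC_M is ≥ 10 orders below the ~5 fF thermal floor (bound: ≥ 3 orders);
  the baseline's grows monotonically with the fluctuation.
* **Seal sweep** — (140 pF, 500 MΩ, 4 MΩ, ±10 mV, 6τ period), `R_Seal`
  from 1 to 150 GΩ in 100 MΩ steps: `Q_C` constant to < 1e−14 relative
  while apparent `C_M`/`R_M` shift strongly below ~10 GΩ and `R_A` moves
  < 0.5 %. (One published figure legend prints this configuration as
  "140 fF"; a 140 fF cell at 4 MΩ would charge in ~0.5 µs, unresolvable at
  100 kHz, so the 140 pF of the accompanying text is used.)
* **Event classification** — deterministic rules on step changes in the
  (C_M, R_M, R_A, Q_C) series, detected by a two-sided CUSUM with a
  MAD-based scale floored at the thermal σC_M (k = 5): a `C_M` step
  mirrored in `Q_C` with stable `R_M`, `R_A` is a true capacitance change; an
  anti-correlated `C_M`/`R_M` step with stable `R_A` and `Q_C` is a seal
  artefact; a correlated `C_M`/`R_A` step is a parasitic artefact.
  Significance thresholds default to 3× the thermal floor for `C_M` and its
  charge equivalent for `Q_C`, and 1 % relative for the resistances.

## What the synthetic data do not emulate

The generator reproduces the equivalent circuit, the output filter and
white Johnson noise. It does not model amplifier/headstage dynamics or
feedback-resistor noise, 1/f noise, dielectric loss, voltage- or
temperature-dependent capacitance, solution exchange, multi-compartment
(non-isopotential) cells, or drift of the transfer function between its
measurement and use. Passing tests therefore demonstrate the correctness
and numerical headroom of the processing chain, not the field performance
of a rig; on real data the achievable resolution is set by the thermal
floor, 1/f excess noise and the stability of `C_P` and `R_Seal`.

## Numerical notes

* Records must contain an integer, even number of samples per period with
  at least 8 per half-period; fits need ≥ 4 usable samples after blanking.
* Protocols are generated by rounding `6τ f_samp` to an integer half-period
  length; the analysis is exact for any half-period length, so the rounding
  does not bias the estimates.
* Deconvolution with ε = 0 refuses exactly-zero `H_S` bins; the 4-pole
  Bessel's response never vanishes on the bin grid (its minimum on the unit
  circle is ~1e−2 at Nyquist for the 10 kHz/100 kHz design, bounding noise
  amplification at ~100×).
* Non-physical inversions (non-positive `I_S`, `I_P + I_S` or `R_M`) are
  flagged per half-period, not raised; flagged rows carry NaN parameters.
* All internal units are SI (F, Ω, V, A, s); only the reporting layer and
  the CLI use pF/MΩ/GΩ/fF/mV.
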