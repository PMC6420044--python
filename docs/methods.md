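# Methods

## Model

The simulator integrates the passive cable equation on a tree of
compartments. Each compartment obeys

    C_i dV_i/dt = -g_L,i (V_i - eps_L) - sum_s g_s(t) (V_i - eps_s)
                  + sum_j g_a,ij (V_j - V_i) + I_inj,i ,

with all potentials relative to the resting potential, in the consistent
unit triple mV / nA / μS (capacitance nF, resistance MΩ, time ms).
Membrane area uses frustum lateral area per segment (sphere area for a
single-point soma); axial coupling between compartment centres sums the
two half-segment frustum resistances R = Ra·l/(π r₁r₂). The soma is always
collapsed to a single isopotential compartment, matching the point-soma
assumption of the static theory.

Synaptic inputs are conductance transients g(t) ∝ |e^(−t/τ_d) − e^(−t/τ_r)|,
peak-normalized so the labelled amplitude is the maximum of the waveform
regardless of the sign order of the two exponentials (the printed
difference of exponentials is negative for τ_r < τ_d; normalizing by the
analytic extremum honours the stated rise/decay constants and amplitude
either way). Canonical kernels: 5/7.8 ms rise/decay at 2.5 nS for the
AMPA-like E input and 6/18 ms at 4 nS for the GABA_A-like I input;
reversals +70 mV (E) and −10 mV (I) relative to a −70 mV rest, with the
shifted inhibitory variant at −20 mV (i.e. −90 mV absolute).

## Numerics

Time integration is an implicit trapezoid (Crank–Nicolson) scheme with one
exact linear solve per step and synaptic conductances evaluated at the
half step; it is unconditionally stable at the default dt = 0.1 ms and
second-order accurate (halving dt moves peak measured currents by <0.5% on
the packaged fixtures). For passive models only the synapse-site diagonal
entries of the system matrix change between steps, so the constant part is
LU-factorized once and each step applies a rank-s Sherman–Morrison–Woodbury
correction; this path is verified against the dense per-step solve to
machine precision. Models with gating channels take the dense path, with
gates advanced by the exponential (Rush–Larsen) update.

The ideal somatic clamp is imposed by node substitution: the clamped row of
the linear system is replaced by V = holding, and the clamp current is
recovered from the eliminated balance equation. The clamped voltage is
therefore pinned exactly, not approximately; series-resistance and
electrode artifacts are out of scope. The measured synaptic current is
defined as baseline − clamp current, where the baseline is the steady
holding current read just before stimulus onset; an excitatory input held
below its reversal yields a positive measured current. Estimation uses
only the post-settle window (default settle 120 ms in protocol runs): the
clamp's charging transient is not synaptic current. The
per-time-point I-V fit is unweighted ordinary least squares, the
traditional method reads (k, b) per time point, and the intercept method
solves the two intercept equations at the two inhibitory reversals.

Degenerate inputs: zero-length morphology segments are collapsed with a
warning; equal rise and decay constants are rejected (alpha-function
kernels are not supported); holding levels equal to a reversal potential
are excluded from per-level conductance extraction but kept in the I-V
regression, which has no singularity there.

## Reference conductances and error metrics

Two reference extractors are provided. The intercept reference applies the
I-V intercept to a single-polarity input (b(t)/ε), which is exact in the
static small-conductance limit and is the default reference for method
comparisons. The point-model reference inverts the somatic point equation
on the unclamped voltage, g_eff = (c dV/dt + g_L V)/(ε − V), with c and
g_L taken from the somatic input resistance and membrane time constant; it
is exact for a point neuron and a few-percent approximation on compact
cables (centred differencing; samples where V crosses ε are masked).

Error metrics: peak-amplitude relative error |max(est) − max(ref)|/max(ref),
and time-averaged relative error ∫|est − ref|dt / ∫|ref|dt. The ratio of
integrals avoids division by a near-zero reference. Negative excursions of
estimated traces are preserved and flagged, never clipped: unphysical
negativity is a diagnostic finding about the estimator, not a numerical
defect.

## Synthetic fixtures and study conditions

No reconstructed morphology is bundled; all fixtures are generated in
code (SWC import is supported for users with their own reconstructions).

* **Point neuron** — 20 μm spherical soma; the regime where the
  traditional method is exact, used for identities and calibration.
* **Ball-and-stick** — 20 μm soma with a 400 × 2 μm dendrite.
* **Long-dendrite neuron** — 20 μm soma, one 2600 × 4 μm main dendrite and
  five 400 × 3 μm side branches (somatic input resistance ≈ 60 MΩ,
  membrane time constant 20 ms). The geometry was chosen so the somatic
  prefactor K_XS/K_SS spans ≈0.95 at 100 μm down to ≈0.2 at the distal end
  of the main dendrite — the range over which the slope-and-intercept
  method degrades from a few percent to near-total failure with negative
  inhibitory estimates — while keeping input resistances physiological.
* **Random branched tree** — seeded stochastic branching with tortuous
  ("zig-zag") segments, used for reciprocity properties and the
  reversal-invariance experiment.

Passive parameters default to Ra = 150 Ω·cm, Cm = 1 μF/cm²,
Rm = 20 kΩ·cm² (generic pyramidal-cell values, user-overridable). Clamp
protocols use five holding levels, −20…+20 mV relative (−90…−50 mV
absolute). Location scans use a co-located E/I pair at 0.3/0.48 nS —
single-synapse scale, preserving the 1:1.6 E:I ratio of the canonical
kernels — so the pair stays in the regime where the effective conductance
is first-order in the local conductance and the scan isolates the
estimator mechanism rather than strong-shunt corrections; the canonical
2.5/4 nS compound amplitudes are used for the 100 μm protocol and
everywhere else. Distributed-input conditions draw a fixed count of
round(rate × window/1000) uniformly timed events per site (reproducible
totals rather than Poisson draws) with uniform seeded site placement, at
reduced scale (≈200 ms windows) to keep full runs to seconds.

The reversal-invariance experiment sweeps the absolute E reversal over
−50…50 mV in ten even values and the absolute I reversal below rest in
five even values from −74 to −90 mV. The inhibitory sweep deliberately
excludes the resting potential itself (−70 mV absolute): at zero driving
force the intercept estimate b/ε is singular, so "five even increments"
are taken stepping down from that excluded endpoint.

Active membrane is limited to a generic gating-channel interface shipping
a textbook squid-axon Na/K pair at low density; it exists to demonstrate
that transfer-resistance reciprocity holds approximately in a weakly
active membrane near rest, not to reproduce any specific cell's channel
complement.

## What the synthetic conditions do and do not show

Passing tests establish the mechanism: exact agreement of the closed-form
three-port algebra with brute-force solves, exact passive reciprocity, the
first-order proportionality between local and effective conductance, the
closed-form SIM error laws (including the −ε_I:ε_E error ratio and
guaranteed under-estimation), IM's second-order recovery, and the
SIM-negativity/IM-robustness contrast on spatial cables. They do not
certify quantitative error percentages for any real neuron: those depend
on the specific morphology, channel densities, electrode series
resistance, and recording noise, none of which the passive synthetic
fixtures emulate. Relatedly, the IM static recovery error is a curve in
g·K (second order in the conductance), not a universal percentage; the
packaged assertions state its scaling and its sub-percent value deep in
the first-order regime.

## Design choices

* Ideal clamp by row substitution rather than a large-conductance
  penalty: exactness by construction, no stiffness penalty.
* k is reported as the negated OLS slope of current on holding voltage
  (convention I = −kV + b), unweighted because the protocol gives equal
  trust to each level.
* "Time-averaged relative error" is fixed as the ratio of integrals
  definition above; "peak-amplitude relative error" compares peak
  amplitudes, not the peak of the pointwise error.
* The synaptic-current baseline is re-measured per holding level (each
  level has its own holding current).
* All randomness (tree growth, schedules, noise) flows through explicit
  integer seeds via `numpy.random.default_rng`; identical configuration
  and seed give bit-identical outputs.

## Known limitations

Static theory is first-order in the local conductances and treats the
soma as a point; time-dependent inputs are handled empirically by the
per-time-point regression rather than by an asymptotic extension of the
static analysis. The estimators assume repeatable inputs across holding
levels (a multi-trial protocol) and subthreshold, spike-free traces.
Axons, spines, NMDA-type voltage dependence, temperature effects, and
stochastic channel noise are out of scope.
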