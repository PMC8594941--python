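# Methods

`rodribbon` is a forward model of whole-cell voltage-clamp recordings from
mouse rod photoreceptors together with the measurement chain used to analyse
them. This note documents the model, its assumptions, the parameters that
matter, and the choices made where the design was genuinely open.

## Equivalent circuit and the sine+dc decomposition

The cell is the standard three-element patch-clamp circuit: series
conductance `G_s = 1/R_a` between pipette and membrane, and a membrane that
is a capacitance `C_m` in parallel with a leak `G_m` (reversal `E_leak`).
Defaults are the recorded soma-ribbon averages: `C_m` = 1.02 pF, `R_a` =
29.7 MΩ, `G_m` = 0.5 nS, giving a clamp time constant
`τ = C_m/(G_s+G_m)` ≈ 30 µs. All internal arithmetic uses the coherent unit
system (mV, pA, nS, pF, ms), in which pA = nS·mV and ms = pF/nS.

The integrator treats the command as piecewise linear between samples and
the coefficients as constant per step, for which the one-step update is
exact; constant-coefficient spans run through a vectorised IIR filter and
time-varying spans (fusing capacitance, Cl(Ca) conductance) through a
renormalised blocked scan. Recordings are synthesised on a 1 µs internal
grid and decimated to the protocol rate (20 kHz for capacitance protocols,
50 kHz for I-V families); at 1 µs the piecewise-linear representation of
the 2 kHz probe sine is accurate to <0.5% even for a low-`R_a` (τ = 5 µs)
cell.

Capacitance is estimated by the sine+dc method: a 2 kHz, 50 mV
peak-to-peak sine about −70 mV probes the complex admittance
`Y(ω) = G_s(G_m + iωC_m)/(G_s + G_m + iωC_m)`; together with the DC
conductance `G_t = G_sG_m/(G_s+G_m)` the circuit is inverted in closed form
per one-cycle bin (0.5 ms):

    G_s = (A² + B² − A·G_t)/(A − G_t),  G_m = G_s·G_t/(G_s − G_t),
    C_m = G_s²·B / (ω[(G_s − A)² + B²]),    Y = A + iB.

Bins whose command does not match the sine template (steps, holds) carry a
stimulation flag; bins whose inversion is non-physical are flagged invalid,
never clipped. Estimating `G_t` requires a leak reversal different from the
holding potential; `E_leak` defaults to 0 mV and is an explicit parameter
of the decomposition (hardware lock-ins make the same assumption
internally). Because bins are one sine cycle, the estimate stream has a
2 kHz bin rate; the hardware-style 2.9 kHz output filter stage is therefore
not applicable and only display filtering (e.g. 20 or 200 Hz, 4-pole Bessel
or FFT brick wall) is provided.

Noise-free round trips (decompose(simulate(θ)) = θ) recover all three
parameters within 2% over `C_m` 0.5–2 pF, `R_a` 10–60 MΩ, `G_m` 0–2 nS, and
programmed capacitance steps are conserved within 2% regardless of where in
a bin they fall.

## Ca_v1.4 current

The calcium current is phenomenological, matching how such recordings are
fitted rather than a Markov gating scheme:

* steady state: ohmic driving force with Boltzmann activation,
  `I_∞(V) = G_max(V − V_rev)/(1 + exp((V − V_½)/k))`, with wild-type
  `G_max` = 0.30 pA/mV, `V_rev` = +44.6 mV, `V_½` = −24.0 mV, `k` = −6.2 mV/e.
  With the conventional negative slope factor the activation term must be
  written with `+(V − V_½)/k` for the curve to rise with depolarisation and
  reproduce the fitted values (−14.8 pA at −10 mV).
* kinetics: a fixed 250 µs onset delay, then a single-exponential approach
  with τ_activ(V, EGTA) interpolated log-linearly in V between anchors —
  10 mM EGTA: 1.09/0.489/0.18 ms at −30/−20/0 mV; 0.5 mM EGTA:
  0.55/0.310/0.16 ms. Weak buffering accelerates opening (facilitation);
  the ribbonless preset disables facilitation by using the fast anchor set
  for both buffering conditions. Outside the anchor span the edge-segment
  log-slope is extended (floored at 50 µs).
* inactivation: `h(t) = 1 − f·(1 − exp(−(t − t_on)/τ_inact))` with
  `f` = 0.31 and `τ_inact` = 19.46 ms (wild type), engaging after
  `t_on` = 3.5 ms. The onset term is a deliberate design choice: recorded
  traces rise to clean plateaus over the ~3 ms activation-fit window, and
  an inactivation term that sags inside that window would bias every fitted
  τ_activ (non-uniformly in voltage) and shift the recovered `V_½` by about
  +1 mV. With the onset, the model still reproduces the printed 200 ms
  behaviour: initial peak −13.4 pA (reported −13.2 ± 0.8), 31% decay,
  τ = 19.46 ms. The trade-off is that the −18 mV plateau peak sits at the
  full `I_∞` = −13.6 pA rather than a few percent below it.
* deactivation: on repolarisation the open fraction relaxes with
  τ_deactiv = 200 µs through the instantaneous driving force (the tail
  current); 200 µs keeps the current at baseline well within 1 ms of
  repolarisation while carrying enough tail charge that the
  ΔC_m-versus-duration curve has the observed curvature between 0.5 and
  1 ms steps.

## Ca²⁺-activated Cl⁻ current

TMEM16-type chloride channels sit outside the Ca²⁺ nanodomain: 10 mM EGTA
blocks them entirely (the conductance is disabled), 0.5 mM EGTA lets them
activate. The model is a conductance that targets
`g_∞ = 0.17 nS/pA × |peak I_Ca(V)|`, develops sigmoidally during the step
(internal gate with τ_act = 4 ms, squared — the channels follow slowly
accumulating bulk Ca²⁺, so early contamination of the activation-fit window
is quadratic, not linear), and relaxes with τ_deact = 5 ms at rest. Outward
rectification (factor 0.05 above `E_Cl`) limits the outward current during
the step while leaving the inward tail at −70 mV full-sized: a 10 ms step
to −18 mV yields a ≈ −45 pA tail, the scale implied by the printed tail I-V
fit (`G_max` 1.41 pA/mV at a −19 mV driving force). `E_Cl` = −51 mV follows
from the Nernst equation applied to the total chloride of the shipped
solution recipes at 31 °C (the midpoint of the 30–32 °C bath range). None
of the Cl kinetics are printed in the source study; these constants are
calibrated to its qualitative statements (slow outward development; tails
of tens of pA; charge integrals compromised only for steps >3 ms).

## Release model

Fusion is driven by cumulative Ca²⁺ charge:
`ΔC_m(t) = c_sv·N_rrp·(1 − exp(−Q(t − δ)/Q_e))` with `c_sv` = 37.6 aF per
vesicle, `Q_e` = 4.66 fC per e-fold, `δ` = 200 µs of fusion latency beyond
the channel delay (total stimulus-to-fusion delay ≈ 0.45 ms), and
`N_rrp` = 87 (wild type) or 22 (ribbonless). The drive is the evoked charge
only — the step window plus 5 ms of tail — because the standing
sub-threshold current at −70 mV is balanced by refill in the cell and must
not deplete the pool over the seconds-long sine segments. Pool refill
between episodes (nominally 8 s apart) is instantaneous; endocytosis is not
modelled quantitatively.

With a constant 12 pA current this gives exponential depletion with
τ = Q_e/|I| ≈ 0.39 ms — the sub-0.4 ms emptying that is the study's
headline.

## Synthetic recordings

`synthesize_recording` renders the protocol on the fine grid, runs the
channel models, folds the fused capacitance into the circuit ODE as a
time-varying `C_m(t)` (so the lock-in decomposition is exercised honestly),
adds the Cl(Ca) conductance with its own reversal, injects the Ca²⁺ current,
decimates, and adds white Gaussian current noise (σ is a knob; 0.5 pA is a
realistic default and every quantitative contract runs at σ = 0). Bundles
store ground truth (clean `I_Ca`, true ΔC_m trajectory) and a compensated
current — the total minus a passive-only simulation that shares the
capacitance trajectory, standing in for an amplifier whose C-slow
compensation tracks the cell. Kinetic fits operate on the compensated
current by default; analyses whose target is the channel kinetics
themselves (the τ_activ facilitation ratio) use the clean `I_Ca` channel,
because the uncompensated ~30 µs series-resistance filter adds ≈ +12 µs to
every fitted τ and would compress the −30/0 mV ratio from 3.44 to ≈ 3.2 —
real recordings suppress this with series-resistance compensation, which is
not otherwise modelled.

Protocol layout compresses the dead time between episodes (8 s nominally)
to a 50 ms hold, since refill is instantaneous and the inter-episode span
carries no information; the nominal interval is kept as metadata. Segment
durations are whole sine cycles so estimation bins never straddle
boundaries.

## Measurement chain

* ΔC_m: mean of 50 ms of valid bins after the step minus 50 ms before;
  under 0.5 mM EGTA the post window starts 75 ms late so the Cl(Ca) tail
  conductance has relaxed. ΔG_m and ΔG_s are reported identically.
  Baseline sweeps use the 5–15 ms vs 85–95 ms window convention.
* activation fits: single-exponential rise starting 250 µs after the step,
  nominally 3 ms long (2 ms under 0.5 mM EGTA at −10 mV and above), capped
  just past the current extremum so late drift cannot drag the asymptote.
  Peak-I_Ca is the fitted asymptote relative to the pre-step baseline
  (`i0 + amp − baseline`; with 2–3 samples on a fast rise, least squares
  may split the asymptote between offset and amplitude).
* I-V fits: the modified Boltzmann over all voltages; the simple sigmoid
  over the foot (−60 mV up to the voltage of maximal current). On the
  model's curve the simple-form midpoint lands near −27.8 mV (reported
  "−28.7 ± 0.4"); the half-maximal tail amplitude falls between −30 and
  −20 mV on the 10 mV grid.
* pool fits: `A(1 − exp(−(t − t₀)/τ))` versus step duration with `t₀ ≥ 0`
  a fitted release-onset delay. The delay term departs from the plain
  two-parameter form: the printed duration-response means (0.14 fF at
  0.5 ms, 2.11 at 1 ms, …) are incompatible with a τ of ~350 µs unless the
  model carries an onset offset — exactly the "~0.5 ms fusion delay" the
  data show, and the exponential-association form of the original fitting
  software includes such an offset. Fixing `t₀ = 0` is available and
  recovers the plain form.
* ΔC_m vs Q_Ca: `A(1 − exp(−Q/Q_e))`, after excluding points from steps
  >3 ms under 0.5 mM EGTA (the Cl current corrupts their charge integral).
  Q is integrated (trapezoid) from the compensated current over the step
  plus 2 ms of tail.
* group statistics: unpaired two-sided Student's t-test (equal variance;
  Welch by flag), means ± SE.

All fits run through lmfit (Levenberg–Marquardt) with data-driven seeds and
a 3-point multistart on time constants; non-convergence flags the result
rather than raising.

## End-to-end behaviour and known limitations

The full wild-type pipeline (noise off) yields τ_depletion ≈ 0.37 ms and
amplitude ≈ 3.24 fF over the 0.5–9 ms range, `Q_e` ≈ 4.5 fC, `V_½` ≈
−24.0 mV, τ_inact ≈ 19.46 ms, and a τ_activ(−30)/τ_activ(0) ratio of 3.4
under 0.5 mM EGTA; the ribbonless pipeline yields ≈ 0.81 fF (~21–22
vesicles), about 24% of wild type.

One published contrast is outside what this model class can produce: the
>10-fold ΔC_m contrast between buffering conditions at 0.5 ms steps. The
only EGTA-dependent quantities in the model are τ_activ (489 vs 310 µs at
−20 mV) and the Cl(Ca) switch, which bound the evoked-charge contrast in a
0.2 ms window at ≈1.6-fold, and the concave charge-to-release mapping
shrinks it further (≈1.3-fold end to end). The published 0.5 ms charge and
tail values are not mutually consistent under any single-exponential
activation model either; the package therefore asserts only the direction
of the contrast end-to-end, while the ≥10-fold ratio is a property of the
published group means shipped in `reference.py`.

The synthetic data also do not emulate: cell-to-cell parameter scatter
(every bundle is the mean cell; reported SEs and p-values are not
reproducible at desk scale), rundown or adaptation over the session, seal
leaks, stray-capacitance artefacts, endocytosis (an optional decoration
only), or Ca²⁺ diffusion/buffer kinetics (EGTA acts only through the
τ_activ anchor set and the Cl switch). Passing tests therefore demonstrate
the internal consistency of the measurement chain and the model's agreement
with the published point estimates, not robustness to biological
variability.

The ERG module is likewise metric-oriented: gamma-function a- and b-lobes
(100 µV and 420 µV maxima, half-saturating at 0.1 and 0.006 cd·s/m², the
b-lobe delayed 25 ms so the a-trough window is genotype-pure), flash series
0.0003–0.278 cd·s/m², 24 kHz sampling, ten averages per intensity emulated
as σ/√10 noise, FFT filtering at 400/20 Hz for a-/b-wave measurement. The
ribbonless preset scales only the b-lobe, by 0.52→0.38 across the series;
with the trough-to-peak amplitude convention the measured cohort-mean
b-wave rate-of-rise ratio comes out ≈2.1 (inside the published two- to
threefold band). Absolute µV amplitudes are invented; only ratios,
invariances and the rate ≡ amplitude/time-to-peak identity are contractual.

## Problem sizes

Default analyses use: four to six step durations per capacitance series
(one compressed recording, ~2 s simulated at 20 kHz), twelve 10 ms steps
per I-V family at 50 kHz, one 200 ms step for inactivation, seven flash
intensities per ERG cohort. These sizes reproduce every point estimate the
package targets; nothing in the method depends on longer recordings.
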