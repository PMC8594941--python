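# rodribbon

Simulation and analysis of whole-cell recordings from the mouse rod
photoreceptor ribbon synapse.

Rod photoreceptors signal "no light" by releasing glutamate continually
from a single ribbon-type active zone. How large the readily releasable
pool (RRP) of synaptic vesicles is, and how fast Ca_v1.4 channel gating
empties it, can be measured by whole-cell membrane-capacitance recording:
each fusing vesicle adds ~37.6 aF to the membrane, so a depolarisation-
evoked capacitance jump ΔC_m counts vesicles. This package implements both
sides of that experiment for wild-type and ribbonless (Ribeye-knockout)
parameter sets:

* a **forward simulator** — three-element voltage-clamp circuit, Ca_v1.4
  current with EGTA-dependent activation kinetics (facilitation),
  Ca²⁺-activated Cl⁻ current, and charge-driven RRP depletion folded into
  the circuit as a time-varying capacitance;
* the **measurement chain** — "sine+dc" lock-in decomposition of the
  current into C_m/G_m/G_s, ΔC_m quantification, exponential kinetic fits,
  simple and modified Boltzmann I-V fits, pool-size and charge-coupling
  fits, vesicle conversion, and scotopic ERG a-/b-wave metrics.

The central quantities: the membrane admittance
`Y(ω) = G_s(G_m + iωC_m)/(G_s + G_m + iωC_m)` inverted per sine cycle for
(C_m, G_m, G_s); the modified Boltzmann I-V
`I = G_max(V − V_rev)/(1 + exp((V − V_½)/k))`; pool depletion
`ΔC_m = A(1 − e^{−Q_Ca/Q_e})` with `A = N_rrp·c_sv`. Wild-type presets:
`N_rrp` = 87 vesicles, `Q_e` = 4.66 fC, `V_½` = −24.0 mV, τ_inact =
19.46 ms; ribbonless: `N_rrp` = 22, 0.66× conductance, no facilitation.
See `docs/methods.md` for the full model description.

## Worked example

Simulate the core experiment — a wild-type rod, 10 mM EGTA in the pipette,
voltage steps from −70 to −18 mV of increasing duration, each bracketed by
2 kHz sine segments — then run the full analysis:

```python
from rodribbon import synthesize_step_series
from rodribbon.analysis import analyze_step_series

bundle = synthesize_step_series("wt", egta_mM=10.0,
                                durations_ms=(0.5, 1, 3, 9))
res = analyze_step_series(bundle)
print(res["episodes"][["duration_ms", "delta_cm_fF", "q_ca_fC", "n_sv"]])
pf, qf = res["pool_fit"], res["q_fit"]
print(f"tau_depletion = {pf['tau_ms']*1e3:.0f} us, "
      f"RRP = {pf['amplitude_fF']:.2f} fF")
print(f"Q_e = {qf['q_e_fC']:.2f} fC")
```

Output:

```
   duration_ms  delta_cm_fF     q_ca_fC  n_sv
0          0.5     1.498360    2.763623    40
1          1.0     2.788597    8.914511    74
2          3.0     3.240793   35.473478    86
3          9.0     3.242100  112.978932    86
tau_depletion = 371 us, RRP = 3.24 fF
Q_e = 4.48 fC
```

Reading: release saturates within ~3 ms of depolarisation; the saturating-
exponential fit says the pool (≈3.24 fF ≈ 86 vesicles) empties with a time
constant under 0.4 ms once fusion starts, and ΔC_m versus the integrated
Ca²⁺ charge says ~4.5 fC of entry releases 63% of the pool. The same
pipeline with the `"ko"` preset gives a pool of ≈0.81 fF (~22 vesicles) —
the ribbonless phenotype.

A thin CLI wraps the same calls:

```
rodribbon simulate --preset wt --egta 10 --protocol steps --out rec.h5
rodribbon analyze --bundle rec.h5 --report report/
rodribbon reproduce --experiment genotype
rodribbon erg --genotype ko --seed 1
```

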