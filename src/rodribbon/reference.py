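"""Published reference values for comparison with synthetic analyses.

Group means (± SE where given) from the wild-type / ribbonless mouse rod
capacitance study that this package models.  They are inputs for
comparison functions and reporting, not quantities the package computes.
"""

#: evoked dC_m (fF) group means by (genotype, EGTA mM, step duration ms)
DELTA_CM_MEANS_FF = {
    ("wt", 10.0, 0.5): 0.14,
    ("wt", 10.0, 1.0): 2.11,
    ("wt", 10.0, 3.0): 2.99,
    ("wt", 10.0, 30.0): 3.54,
    ("wt", 0.5, 0.5): 1.51,
    ("wt", 0.5, 1.0): 2.44,
    ("wt", 0.5, 3.0): 3.24,
    ("ko", 10.0, 1.0): 0.21,
    ("ko", 10.0, 3.0): 0.68,
    ("ko", 0.5, 1.0): 0.70,
    ("ko", 0.5, 3.0): 0.86,
}

#: pool-depletion fits (fit range ms -> (tau_ms, amplitude_fF))
POOL_FITS = {
    ("wt", (0.5, 9.0)): (0.348, 3.27),
    ("wt", (0.5, 30.0)): (0.383, 3.43),
    ("ko", (0.5, 30.0)): (0.560, 0.84),
}

#: dC_m vs Q_Ca pooled fit: amplitude (fF) and e-fold charge (fC)
DCM_VS_Q_FIT = {"amplitude_fF": 3.31, "q_e_fC": 4.66}

#: I_Ca tail amplitudes after 0.5 ms steps to -18 mV, pA, by EGTA (mM)
TAIL_05MS_PA = {0.5: -12.5, 10.0: -7.4}

#: reported RRP sizes in vesicles
RRP_SV = {"wt": 87, "ko": 22}
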