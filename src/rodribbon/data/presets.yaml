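# Genotype parameter presets.  "wt" carries the wild-type calibration;
# "ko" is the ribbonless (Ribeye-null) preset: ~34% smaller maximal Ca
# conductance, a 22-SV pool, no buffering-dependent facilitation of
# activation kinetics, and weaker inactivation.
wt:
  circuit: {c_m_pF: 1.02, r_a_MOhm: 29.7, g_m_nS: 0.5, e_leak_mV: 0.0}
  cav:
    g_max_pA_per_mV: 0.30
    v_rev_mV: 44.6
    v_half_mV: -24.0
    slope_mV: -6.2
    activation_delay_ms: 0.25
    inact_fraction: 0.31
    tau_inact_ms: 19.46
    tau_deactiv_ms: 0.20
    facilitation: true
  clca: {coupling_nS_per_pA: 0.17, depol_gain: 0.15, tau_act_ms: 4.0,
         tau_deact_ms: 5.0, e_cl_mV: -51.0}
  release: {n_rrp: 87, c_sv_aF: 37.6, q_e_fC: 4.66, fusion_delay_ms: 0.2}
ko:
  circuit: {c_m_pF: 1.02, r_a_MOhm: 29.7, g_m_nS: 0.5, e_leak_mV: 0.0}
  cav:
    g_max_pA_per_mV: 0.198   # 0.66 x wt
    v_rev_mV: 44.6
    v_half_mV: -24.0
    slope_mV: -6.2
    activation_delay_ms: 0.25
    inact_fraction: 0.19
    tau_inact_ms: 19.46
    tau_deactiv_ms: 0.20
    facilitation: false
  clca: {coupling_nS_per_pA: 0.068, depol_gain: 0.15, tau_act_ms: 4.0,
         tau_deact_ms: 5.0, e_cl_mV: -51.0}
  release: {n_rrp: 22, c_sv_aF: 37.6, q_e_fC: 4.66, fusion_delay_ms: 0.2}
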