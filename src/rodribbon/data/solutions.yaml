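# Recording-solution recipes for mouse retinal slice patch-clamp work.
# Each component lists its total concentration (mM) and the ions it
# dissociates into as {species: count-per-formula-unit}; charges are keyed
# separately so electroneutrality can be checked.  Non-dissociating or
# chelated components (HEPES, glucose, EGTA, MgATP, CsCH3SO4 as a weakly
# dissociating methanesulfonate pair for chloride bookkeeping purposes)
# still list their ion inventory explicitly.
extracellular:
  name: mouse extracellular solution (2 mM Ca)
  side: extracellular
  temperature_C: 31.0
  components:
    - {species: NaCl,      mM: 105,   ions: {Na+: 1, Cl-: 1}}
    - {species: KCl,       mM: 2.5,   ions: {K+: 1, Cl-: 1}}
    - {species: TEA-Cl,    mM: 35,    ions: {TEA+: 1, Cl-: 1}}
    - {species: CsCl,      mM: 5,     ions: {Cs+: 1, Cl-: 1}}
    - {species: CaCl2,     mM: 2,     ions: {Ca2+: 1, Cl-: 2}}
    - {species: MgCl2,     mM: 1,     ions: {Mg2+: 1, Cl-: 2}}
    - {species: TFB-TBOA,  mM: 0.003, ions: {}}
    - {species: HEPES,     mM: 15,    ions: {}}
intracellular_10egta:
  name: intracellular, 10 mM EGTA
  side: intracellular
  temperature_C: 31.0
  components:
    - {species: CsCH3SO4,  mM: 105,   ions: {Cs+: 1, CH3SO4-: 1}}
    - {species: TEA-Cl,    mM: 20,    ions: {TEA+: 1, Cl-: 1}}
    - {species: MgCl2,     mM: 1,     ions: {Mg2+: 1, Cl-: 2}}
    - {species: MgATP,     mM: 5,     ions: {}}
    - {species: NaGTP,     mM: 0.2,   ions: {Na+: 1, GTP-: 1}}
    - {species: HEPES,     mM: 10,    ions: {}}
    - {species: EGTA,      mM: 10,    ions: {}}
intracellular_05egta:
  name: intracellular, 0.5 mM EGTA
  side: intracellular
  temperature_C: 31.0
  components:
    - {species: CsCH3SO4,  mM: 112,   ions: {Cs+: 1, CH3SO4-: 1}}
    - {species: TEA-Cl,    mM: 20,    ions: {TEA+: 1, Cl-: 1}}
    - {species: MgCl2,     mM: 1,     ions: {Mg2+: 1, Cl-: 2}}
    - {species: MgATP,     mM: 5,     ions: {}}
    - {species: NaGTP,     mM: 0.2,   ions: {Na+: 1, GTP-: 1}}
    - {species: HEPES,     mM: 10,    ions: {}}
    - {species: EGTA,      mM: 0.5,   ions: {}}
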