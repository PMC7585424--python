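# Reference carbon budget of the lake DIC pool: printed (rounded) fluxes
# (mmolC m-2 d-1) and isotopic constraints (permil).  Organic-derived terms
# are tied to d13C_DIC through eps_ph; the methanogenesis-derived epsilons
# come from the porewater CH4 / sedimentary organic carbon balance.
eps_ph: 26.2
eps_resp: 0.0
eps_co2_meth: 53.6
eps_ch4_meth: 53.6
eps_oxy: 4.7
eps_deg: 6.2
eps_carb: 4.1   # carbonate precipitates heavier than DIC (+16.2 vs +12.1)
delta_det: -26.7
delta_mag: -2.7
measured_delta_dic: 12.1
fluxes:
  respiration: 214.0
  co2_methanogenic: 120.0
  ch4_oxidation: 43.0
  detrital: 133.0
  magmatic: 18.0
  photosynthesis: 404.0
  co2_degassing: 123.0
  carbonate: 1.9
constrained:
  respiration: measured
  co2_methanogenic: derived
  ch4_oxidation: derived
  detrital: derived
  magmatic: derived
  photosynthesis: measured
  co2_degassing: measured
  carbonate: measured
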