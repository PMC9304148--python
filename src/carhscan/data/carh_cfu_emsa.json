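{
  "description": "Ground-truth Hill parameters for the CarH_Cfu EMSA worked example: apparent KD 35 nM for the natural promoter probe, cooperative binding (h = 2, two dimers binding stepwise), full amplitude. Concentrations are the natural-probe titration series in nM.",
  "amplitude": 1.0,
  "kd_nm": 35.0,
  "hill_h": 2.0,
  "concentrations_nm": [0.1, 0.25, 0.5, 1.0, 5.0, 10.0, 100.0],
  "protomer_mr_kda": 35.0,
  "dark_dimer_apparent_mr_kda": 59.0,
  "light_monomer_apparent_mr_kda": 31.0
}
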