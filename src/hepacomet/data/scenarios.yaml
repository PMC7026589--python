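# Landmark scenarios: canonical conditions used throughout tests, examples
# and calibration.  Schema per block:
#   agent, dose, time_h, cell_line, genotype, hu_arac/ket/anf, vehicle
# Omitted keys take DamageScenario defaults (WT genotype, 1 h, no inhibitors).

untreated:
  agent: uv_c
  dose: 0.0
  time_h: 1.0
  cell_line: fibroblast
  vehicle: true

uv_1h:
  agent: uv_c
  dose: 5.0          # J/m2
  time_h: 1.0
  cell_line: fibroblast

uv_1h_huarac:
  agent: uv_c
  dose: 5.0
  time_h: 1.0
  cell_line: fibroblast
  hu_arac: true

uv_1h_xpg_null_huarac:
  agent: uv_c
  dose: 5.0
  time_h: 1.0
  cell_line: fibroblast
  genotype: XPG_null
  hu_arac: true

uv_1h_xpg_e791a:
  agent: uv_c
  dose: 5.0
  time_h: 1.0
  cell_line: fibroblast
  genotype: XPG_E791A

huarac_only:
  agent: uv_c
  dose: 0.0
  time_h: 1.0
  cell_line: HepaRG
  hu_arac: true
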