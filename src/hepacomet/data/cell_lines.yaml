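# Cell-model presets: CYP450 activity scalars (relative to HepaRG = 1.0)
# and residual enzyme fractions under the CYP inhibitors.
# Schema per block:
#   cyp_scalars: {enzyme: activity multiplier >= 0}
#   inhibitor_residuals: {ket: <CYP3A4 fraction left at 5 uM KET>,
#                         anf: <CYP1-family fraction left at 25 uM ANF>}

HepaRG:
  description: metabolically competent hepatic line (reference activities)
  cyp_scalars: {CYP3A4: 1.0, CYP1A2: 1.0, CYP2E1: 1.0}
  inhibitor_residuals: {ket: 0.01, anf: 0.02}

HepG2:
  description: hepatoma line; >100-fold lower CYP3A4, >10-fold lower CYP1A2
  cyp_scalars: {CYP3A4: 0.01, CYP1A2: 0.1, CYP2E1: 0.1}
  inhibitor_residuals: {ket: 0.1, anf: 0.02}

TK6:
  description: lymphoblastoid line without CYP450 expression
  cyp_scalars: {CYP3A4: 0.0, CYP1A2: 0.0, CYP2E1: 0.0}
  inhibitor_residuals: {ket: 0.01, anf: 0.02}

fibroblast:
  description: immortalized human fibroblasts (UV work; no CYP dependence)
  cyp_scalars: {}
  inhibitor_residuals: {ket: 0.01, anf: 0.02}

mouse_hepatocyte:
  description: primary mouse hepatocytes (WT or Xpa-/- via scenario genotype)
  cyp_scalars: {CYP3A4: 1.0, CYP1A2: 1.0, CYP2E1: 1.0}
  inhibitor_residuals: {ket: 0.01, anf: 0.02}
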