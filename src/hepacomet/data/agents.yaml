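# Agent presets: how each test article turns dose into DNA lesions, and its
# Hill-type viability curve.  Schema (one block per agent):
#   mechanism:   bulky_NER | ber_methylating | direct_ssb | crosslinker | inert
#   dose_unit:   native unit of `screen_doses` and of lesion/crosslink yields
#   lesion_yield:    lesions per cell per unit dose per unit enzyme activity
#   crosslink_yield: crosslinks per cell per unit dose (crosslinkers only)
#   activating_enzyme: CYP whose activity scalar gates lesion formation
#   viability: {d50: <dose at 50% survival>, hill: <slope>}
#   screen_doses: default dose ladder for screening (vehicle added by caller)
#
# NOTE ON EFFECT SIZES: the per-chemical lesion yields below are free model
# parameters, not measured quantities.  They were chosen once so that the
# reference screen outcome pattern (which compounds score positive with and
# without repair-synthesis inhibitors, at roughly which doses) emerges from
# the statistical caller under the default study design.  They should not be
# read as potency estimates for the real compounds.

etoposide:
  mechanism: bulky_NER        # stabilized topoisomerase-II lesions, modeled
  dose_unit: uM               # as trapping-revealed substrates
  lesion_yield: 1350.0
  viability: {d50: 80.0, hill: 1.2}
  screen_doses: [1.25, 2.5, 5.0, 10.0]

dat_2_4:
  mechanism: bulky_NER        # 2,4-diaminotoluene; requires oxidation
  dose_unit: mM
  lesion_yield: 1350.0
  activating_enzyme: CYP1A2
  viability: {d50: 80.0, hill: 1.2}
  screen_doses: [1.25, 2.5, 5.0, 10.0]

cyclophosphamide:
  mechanism: bulky_NER        # CYP-activated alkylating pro-drug
  dose_unit: mM
  lesion_yield: 2700.0
  activating_enzyme: CYP3A4
  viability: {d50: 80.0, hill: 1.2}
  screen_doses: [1.25, 2.5, 5.0, 10.0]

pca:
  mechanism: inert            # p-chloroaniline: in-vivo genotoxin, but no
  dose_unit: mM               # direct DNA damage in this assay
  lesion_yield: 0.0
  viability: {d50: 5.0, hill: 2.0}   # ~50% death at the 5 mM top dose
  screen_doses: [0.625, 1.25, 2.5, 5.0]

ndma:
  mechanism: ber_methylating  # N-nitrosodimethylamine, CYP2E1-activated;
  dose_unit: mM               # methyl adducts yield BER intermediates that
  lesion_yield: 6300.0        # are comet-visible without trapping
  activating_enzyme: CYP2E1
  viability: {d50: 160.0, hill: 1.2}
  screen_doses: [2.5, 5.0, 10.0, 20.0]

hydroquinone:
  mechanism: bulky_NER
  dose_unit: mM
  lesion_yield: 41000.0
  viability: {d50: 0.2, hill: 2.0}   # cytotoxic at its genotoxic dose
  screen_doses: [0.04, 0.08, 0.165, 0.33]

benzo_a_pyrene:
  mechanism: bulky_NER        # BPDE-dG adducts after CYP1-family activation
  dose_unit: uM
  lesion_yield: 2700.0
  activating_enzyme: CYP1A2
  viability: {d50: 80.0, hill: 1.2}
  screen_doses: [1.25, 2.5, 5.0, 10.0]

chloramphenicol:
  mechanism: bulky_NER
  dose_unit: mM
  lesion_yield: 4400.0
  viability: {d50: 2.8, hill: 3.0}   # < 50% survival only at the top dose
  screen_doses: [0.39, 0.78, 1.55, 3.1]

cisplatin:
  mechanism: crosslinker      # inter/intrastrand crosslinks retard migration
  dose_unit: uM
  lesion_yield: 0.0
  crosslink_yield: 150.0
  viability: {d50: 320.0, hill: 1.2}
  screen_doses: [5.0, 10.0, 20.0, 40.0]

aflatoxin_b1:
  mechanism: bulky_NER        # AFB1-N7-dG after CYP3A4 epoxidation
  dose_unit: uM
  lesion_yield: 33000.0
  activating_enzyme: CYP3A4
  viability: {d50: 24.0, hill: 1.2}
  screen_doses: [0.1, 0.3, 1.0, 3.0]

h2o2:
  mechanism: direct_ssb       # oxidative breaks, deposited directly
  dose_unit: uM
  lesion_yield: 50.0
  viability: {d50: 800.0, hill: 1.2}
  screen_doses: [10.0, 25.0, 50.0, 100.0]
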