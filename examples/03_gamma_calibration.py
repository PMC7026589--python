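"""Build the gamma standard curve and convert a chemical response to SSBs.

Gamma radiation deposits a known 1000 single-strand breaks per Gy, so a
dose ladder (0-9 Gy) calibrates % tail DNA in absolute breaks per cell.
The origin-forced slope (SSBs per point of background-corrected % tail)
then converts any treatment's readout into an SSB estimate; negative
estimates are background-correction artefacts and are flagged no-change.
"""

from hepacomet import model_only_evaluate
from hepacomet.calibration import estimate_ssb
from hepacomet.pipeline import simulate_calibration_curve
from hepacomet.presets import make_scenario

curve = simulate_calibration_curve(cell_line="HepaRG", n_wells=3, sigma_well=1.0, seed=5)
print(curve.to_frame().round(2).to_string(index=False))
print(f"\nslope: {curve.slope:.0f} SSBs per point of delta % tail (R2 = {curve.r_squared:.4f})")

vehicle = model_only_evaluate(make_scenario("aflatoxin_b1", 0.0, hu_arac=True, vehicle=True))
for dose in (0.3, 1.0, 3.0):
    treated = model_only_evaluate(make_scenario("aflatoxin_b1", dose, hu_arac=True))
    est = estimate_ssb(curve, treated, vehicle)
    tag = " (no change)" if est.no_change else ""
    print(f"AFB1 {dose:4.1f} uM + HU/AraC: delta %T = {est.delta_tail:6.2f} "
          f"-> {est.ssb:8.0f} SSBs/cell{tag}")
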