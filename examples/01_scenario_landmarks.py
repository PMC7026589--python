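"""Evaluate the damage model's canonical scenarios (no imaging).

The trapping mechanism in one table: untreated cells sit at the basal
~10% tail DNA; 5 J/m2 of UV-C barely moves the readout (~20% at 1 h)
because repair intermediates are resealed as fast as they are made;
blocking repair synthesis with HU/AraC traps those intermediates and
drives the same exposure to ~74% — the assay's saturation region —
while incision-dead genotypes (XPG-null) stay at baseline.
"""

from hepacomet import model_only_evaluate
from hepacomet.presets import landmark_scenarios

for name, scenario in landmark_scenarios().items():
    pct = model_only_evaluate(scenario)
    print(f"{name:24s} {pct:6.2f} % tail DNA")

print()
print("The UV+HU/AraC : UV-only ratio is the trapping gain "
      "(~4x, capped by assay saturation at 75%).")
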