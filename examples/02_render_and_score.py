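"""Render a synthetic CometChip field and score it blind.

Builds three replicate wells of the trapped-UV condition (48 microwells
each, 240 um pitch), registers the lattice from image content alone,
segments every comet with the head-reflection rule and compares the
per-well median % tail DNA with the generator's ground truth.
"""

import numpy as np

from hepacomet import model_only_evaluate
from hepacomet.presets import agent_preset, make_scenario
from hepacomet.quant import quantify_field, register_grid
from hepacomet.synth import make_condition_images

scenario = make_scenario("uv_c", 5.0, cell_line_name="fibroblast", hu_arac=True)
preset = agent_preset("uv_c")
truth = model_only_evaluate(scenario, preset)

medians = []
for well, (field, manifest) in enumerate(
    make_condition_images(scenario, preset, n_wells=3, grid_shape=(8, 6), seed=42)
):
    grid = register_grid(field)
    records = quantify_field(field, grid)
    clean = records[(records["flags"] == "") & records["percent_tail"].notna()]
    medians.append(clean["percent_tail"].median())
    print(
        f"well {well}: pitch {grid.pitch_um:6.1f} um, "
        f"{len(clean)} clean comets, median {medians[-1]:5.2f} % tail"
    )

print(f"\nmodel truth        {truth:5.2f} % tail DNA")
print(f"pipeline estimate  {np.mean(medians):5.2f} % tail DNA "
      f"(difference {np.mean(medians) - truth:+.2f} points)")
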