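"""Simulate the nine-compound genotoxicity screen, with and without trapping.

Each compound is tested at four doses plus vehicle, three wells per
condition, in two arms (with and without HU/AraC).  Dose series are called
by one-way ANOVA + one-sided Dunnett tests on well medians; the verdict
table reports the modal call over five replicate simulated screens.
Without trapping only the methylating agent NDMA (a BER substrate) scores
positive; trapping reveals the bulky-lesion compounds, while the
crosslinker cisplatin and the indirect-acting PCA stay negative.
"""

from hepacomet import RunConfig, consensus_screen, simulate_screen

config = RunConfig(seed=7)

# one full screen, with its per-dose detail
result = simulate_screen(config)
print(result.report_text())

# the replicated consensus verdicts
table = consensus_screen(config, n_reps=5)
print("\nConsensus over 5 replicate screens:")
print(table.to_string(index=False))

n_with = ((table["arm"] == "hu_arac") & (table["verdict"] == "+")).sum()
n_without = ((table["arm"] == "no_inhibitor") & (table["verdict"] == "+")).sum()
print(f"\npositives with HU/AraC: {n_with}/9; without: {n_without}/9")
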