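"""Trait coding and per-color summary statistics.

Builds the default synthetic study (47 species with min/median/max trait
ranges, ordinal floral traits, binned colors), then prints the grand mean,
SD and coefficient of variation of each continuous trait per color group —
the table a field botanist would scan to see whether red-flowered species
are less variable than white or pink ones.
"""

from campion import summarize_by_color
from campion.synthetic import SyntheticScenario, simulate_study

tree, table, occurrences, truth = simulate_study(SyntheticScenario(seed=0))
summary = summarize_by_color(table)

cont = summary.continuous
print("coefficient of variation (%) by color group:\n")
print(cont.pivot(index="trait", columns="group", values="cv").round(1)
      [["white", "pink", "red", "all"]])
print("\nA consistently smaller red column means red-flowering species are "
      "phenotypically tighter than the rest — here planted by the generator's "
      "red-shrink contrast (factor "
      f"{truth['red_shrink']}).")
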