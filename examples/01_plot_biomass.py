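"""Per-tree allometric biomass, plot aggregation and species shares.

Builds a six-tree mini inventory, applies the power-law allometric model
W = a * D**b * H**c with the package's published default coefficients,
and aggregates to plot and species level.
"""

import pandas as pd

from forestagb import plot_biomass, species_share, tree_agb

trees = pd.DataFrame(
    {
        "plot_id": ["P1", "P1", "P1", "P2", "P2", "P2"],
        "species": ["Quercus mongolica", "Quercus mongolica", "Betula platyphylla",
                    "Larix gmelinii", "Quercus mongolica", "Betula platyphylla"],
        "dbh_cm": [22.0, 31.5, 14.0, 40.0, 18.5, 9.0],
        "height_m": [14.0, 18.0, 11.0, 22.0, 12.5, 8.0],
    }
)

print("single tree, D=22 cm, H=14 m ->", round(tree_agb(22.0, 14.0), 2), "biomass units")
print("\nper-plot totals (sum of member trees):")
print(plot_biomass(trees).to_string(index=False))
print("\nspecies shares of total biomass (fractions sum to 1):")
print(species_share(trees).round(3).to_string(index=False))
print("\nLarger, taller trees dominate: one 40 cm larch outweighs several")
print("small birches, which is why the species shares are so skewed.")
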