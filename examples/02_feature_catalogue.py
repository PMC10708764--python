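"""The 86-variable predictor catalogue from a synthetic raster stack.

Simulates a small inventory plus a co-registered optical/SAR/terrain
stack, then extracts per-plot bands, vegetation indices, GLCM texture
measures, backscatter and terrain variables.
"""

from forestagb import SimulationConfig, assemble_catalogue, generate_inventory, generate_raster_stack

cfg = SimulationConfig(n_plots=40, outlier_fraction=0.0, seed=1)
inventory = generate_inventory(cfg)
stack, pixels = generate_raster_stack(cfg, grid_shape=(32, 32), inventory=inventory)
_, plots, _ = inventory

catalogue = assemble_catalogue(plots.merge(pixels, on="plot_id"), stack, window_size=7, levels=32)

print(f"{len(catalogue)} plots x {len(catalogue.columns) - 1} variables")
print("\nfirst plot, a few entries:")
cols = ["B2", "B5", "NDVI", "NDPI", "B6Mean", "VVEntropy", "Altitude", "Canopy closure"]
print(catalogue[["plot_id"] + cols].head(3).round(4).to_string(index=False))
print("\nBands are reflectances in [0,1]; NDVI/NDPI are band ratios that rise")
print("with green biomass; B6Mean and VVEntropy are Haralick texture measures")
print("of the 7x7 window around each plot pixel (32 grey levels).")
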