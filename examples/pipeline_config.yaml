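# Pipeline configuration for `forestagb demo --config pipeline_config.yaml`.
# Omitted keys keep their defaults (shown here for the main knobs).
seed: 0
n_plots: 354                  # plots in the simulated inventory
nonlinearity_strength: 1.0    # 0 = biomass affine in features
outlier_fraction: 0.5423728813559322   # (354-162)/354: leaves 162 after screening
grid_shape: [48, 48]          # raster stack size (pixels)
window_size: 7                # GLCM texture window
levels: 32                    # grey levels for texture quantization
alpha: 0.01                   # predictor-selection significance level
hidden_size: 10               # network hidden units
max_epochs: 150               # LM training budget
swarm_size: 30
pso_iterations: 100
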