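"""End-to-end orchestration of the biomass-inversion workflow.

``run_pipeline`` chains simulate -> raster -> feature catalogue ->
screening -> three model fits (stepwise linear, LM network, PSO network)
-> held-out evaluation -> biomass map, writing every stage's tables and
the effective configuration into an artifact directory.  Reruns with the
same config and seed reproduce every numeric output.

A single global seed fans out to per-stage seeds through a fixed
SeedSequence derivation, so any stage can be reproduced in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation, features, linear, mapping, network, pso, screening
from .synthetic import SimulationConfig, generate_inventory, generate_raster_stack

__all__ = ["PipelineConfig", "run_pipeline", "stage_seeds"]

log = logging.getLogger("forestagb")


@dataclasses.dataclass
class PipelineConfig:
    seed: int = 0
    n_plots: int = 354
    nonlinearity_strength: float = 1.0
    outlier_fraction: float = (354 - 162) / 354
    grid_shape: tuple[int, int] = (48, 48)
    window_size: int = 7
    levels: int = 32
    alpha: float = 0.01
    hidden_size: int = 10
    max_epochs: int = 150
    swarm_size: int = 30
    pso_iterations: int = 100
    split_ratios: tuple[float, float, float] = (0.70, 0.15, 0.15)
    outlier_rule: str = "mean_sd_iterative"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("grid_shape", "split_ratios"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def stage_seeds(seed: int, n: int = 4) -> list[int]:
    """Deterministic per-stage seeds (< 2**31) derived from the global seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage and write artifacts under ``outdir``.

    Returns a summary dict (retained plot count, selected predictors,
    comparison table, best model name, output paths).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash()
    seed_sim, seed_split, seed_mlp, seed_pso = stage_seeds(config.seed)

    # --- simulate ------------------------------------------------------------
    sim = SimulationConfig(
        n_plots=config.n_plots,
        nonlinearity_strength=config.nonlinearity_strength,
        outlier_fraction=config.outlier_fraction,
        seed=seed_sim,
    )
    trees, plots, truth = generate_inventory(sim)
    stack, plot_pixels = generate_raster_stack(
        sim, config.grid_shape, inventory=(trees, plots, truth), margin=config.window_size // 2
    )
    trees.to_csv(out / "trees.csv", index=False)
    plots.to_csv(out / "plots.csv", index=False)
    (out / "truth.json").write_text(truth.to_json())
    mapping.write_stack(stack, out / "stack.tif", metadata={"config_hash": cfg_hash})
    log.info("simulated %d plots on a %s grid", config.n_plots, config.grid_shape)

    # --- features ------------------------------------------------------------
    plot_meta = plots.merge(plot_pixels, on="plot_id")
    catalogue = features.assemble_catalogue(
        plot_meta, stack, window_size=config.window_size, levels=config.levels
    )
    catalogue.to_csv(out / "features.csv", index=False)

    # --- screening -----------------------------------------------------------
    retained, removal_log = screening.remove_outliers(
        plots, rule=config.outlier_rule
    )
    removal_log.to_csv(out / "removed_plots.csv", index=False)
    feats_kept = catalogue[catalogue["plot_id"].isin(retained["plot_id"])].reset_index(drop=True)
    y = retained.set_index("plot_id").loc[feats_kept["plot_id"], "agb"].to_numpy()
    corr = screening.correlation_table(feats_kept, y)
    corr.to_csv(out / "correlation.csv", index=False)
    selected = screening.select_predictors(corr, alpha=config.alpha)
    (out / "selected_predictors.json").write_text(json.dumps(selected, indent=2))
    log.info("retained %d plots; %d predictors at p<%g", len(retained), len(selected), config.alpha)
    if not selected:
        raise RuntimeError("screening selected no predictors; cannot fit models")

    # --- fit the three models ------------------------------------------------
    X = feats_kept[selected]
    split = network.split_dataset(len(X), config.split_ratios, seed=seed_split)
    Xtr, ytr = X.iloc[split.train], y[split.train]

    lin_spec, lin_report = linear.stepwise_fit(Xtr, ytr)
    (out / "model_linear.json").write_text(lin_spec.to_json())

    mlp_cfg = network.MLPConfig(
        n_inputs=X.shape[1],
        hidden_size=config.hidden_size,
        max_epochs=config.max_epochs,
        seed=seed_mlp,
    )
    bp_weights, bp_hist = network.train_mlp_lm(X, y, mlp_cfg, split)
    bp_hist.to_csv(out / "history_bp.csv", index=False)

    pso_cfg = pso.PSOConfig(
        swarm_size=config.swarm_size, max_iterations=config.pso_iterations, seed=seed_pso
    )
    pso_weights, pso_hist = pso.pso_train_mlp(X, y, mlp_cfg, pso_cfg, split)
    pso_hist.to_csv(out / "history_pso.csv", index=False)

    # --- evaluate ------------------------------------------------------------
    Xte, yte = X.iloc[split.test], y[split.test]
    preds = {
        "stepwise-linear": lin_spec.predict(Xte),
        "bp-network": bp_weights.predict(Xte),
        "pso-network": pso_weights.predict(Xte),
    }
    report = evaluation.compare_models(preds, yte)
    report.to_csv(out / "report.csv", index=False)
    scatter = pd.DataFrame({"observed": yte, **{k: v for k, v in preds.items()}})
    scatter.to_csv(out / "scatter.csv", index=False)

    # --- map with the best model ---------------------------------------------
    best_name = report.loc[report["r2_cod"].idxmax(), "model"]
    best_model = {
        "stepwise-linear": lin_spec,
        "bp-network": bp_weights,
        "pso-network": pso_weights,
    }[best_name]
    grid = mapping.invert_raster(
        best_model, stack, window_size=config.window_size, levels=config.levels
    )
    grid.metadata["config_hash"] = cfg_hash
    grid.metadata["model"] = str(best_name)
    mapping.write_grid(grid, out / "agb_map.tif")

    manifest = {
        "config": dataclasses.asdict(config),
        "config_hash": cfg_hash,
        "stage_seeds": {
            "simulate": seed_sim,
            "split": seed_split,
            "mlp": seed_mlp,
            "pso": seed_pso,
        },
        "n_plots": config.n_plots,
        "n_retained": int(len(retained)),
        "n_selected_predictors": len(selected),
        "best_model": str(best_name),
        "linear_fit": {k: v for k, v in lin_report.items() if k != "trace"},
        "outputs": sorted(p.name for p in out.iterdir()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return {
        "retained": len(retained),
        "selected": selected,
        "report": report,
        "best_model": str(best_name),
        "outdir": str(out),
    }
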