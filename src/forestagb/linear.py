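"""Linear biomass models: the published regression and stepwise refitting.

The published model is a frozen eight-predictor ordinary-least-squares
equation relating plot biomass to altitude, canopy closure, three
vegetation indices, one SAR texture, one optical texture and one band:

    Biomass = -243.422 + 0.090*Altitude + 125.943*Canopy closure
              - 156.917*ARVI + 73.454*EVI + 148.340*RVI
              + 34.447*VVEntropy + 24.306*B6Mean - 245.049*B6

It is shipped as a versioned constant (the calibration data are not
public and cannot be refit); :func:`stepwise_fit` exists to build
analogous models on synthetic or user data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["LinearModelSpec", "published_model", "predict_linear", "stepwise_fit"]


@dataclass
class LinearModelSpec:
    """Intercept + named coefficients, with optional per-term statistics."""

    intercept: float
    coefficients: dict[str, float]
    std_errors: dict[str, float] | None = None
    t_values: dict[str, float] | None = None
    p_values: dict[str, float] | None = None
    name: str = "linear"

    @property
    def required_features(self) -> list[str]:
        return list(self.coefficients)

    def predict(self, features) -> np.ndarray:
        return predict_linear(self, features)

    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "intercept": self.intercept,
                "coefficients": self.coefficients,
                "std_errors": self.std_errors,
                "t_values": self.t_values,
                "p_values": self.p_values,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "LinearModelSpec":
        d = json.loads(text)
        return cls(
            intercept=d["intercept"],
            coefficients=d["coefficients"],
            std_errors=d.get("std_errors"),
            t_values=d.get("t_values"),
            p_values=d.get("p_values"),
            name=d.get("name", "linear"),
        )


def published_model() -> LinearModelSpec:
    """The frozen published stepwise-regression equation."""
    return LinearModelSpec(
        intercept=-243.422,
        coefficients={
            "Altitude": 0.090,
            "Canopy closure": 125.943,
            "ARVI": -156.917,
            "EVI": 73.454,
            "RVI": 148.340,
            "VVEntropy": 34.447,
            "B6Mean": 24.306,
            "B6": -245.049,
        },
        name="published-stepwise",
    )


def predict_linear(spec: LinearModelSpec, features) -> np.ndarray | float:
    """Evaluate intercept + sum(coef_i * x_i) on a feature mapping or frame.

    ``features`` may be a dict (single sample) or a DataFrame (one row per
    sample).  Every coefficient's feature must be present; a missing one
    raises KeyError naming it.
    """
    scalar = isinstance(features, dict)
    if scalar:
        features = pd.DataFrame([features])
    out = np.full(len(features), spec.intercept, dtype=float)
    for name, coef in spec.coefficients.items():
        if name not in features.columns:
            raise KeyError(f"missing feature {name!r} required by model {spec.name!r}")
        out += coef * features[name].to_numpy(dtype=float)
    return float(out[0]) if scalar else out


def _ols(X: pd.DataFrame, y: np.ndarray):
    return sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()


def stepwise_fit(
    X: pd.DataFrame,
    y,
    entry_p: float = 0.05,
    removal_p: float = 0.10,
    max_steps: int = 200,
) -> tuple[LinearModelSpec, dict]:
    """Forward-entry / backward-removal stepwise OLS.

    At each step the candidate with the smallest entry p-value below
    ``entry_p`` is added, then included terms whose p-value exceeds
    ``removal_p`` are dropped (largest first), until neither rule fires.
    Constant columns are rejected up front.

    Returns ``(spec, report)`` where report holds r_squared, adj_r_squared,
    f_pvalue, n_obs and the selection trace.  A model with no entered terms
    is returned as intercept-only.
    """
    y = np.asarray(y, dtype=float)
    if len(X) != len(y):
        raise ValueError("X and y length mismatch")
    const = [c for c in X.columns if X[c].nunique() <= 1]
    if const:
        raise ValueError(f"constant columns not allowed: {const}")
    included: list[str] = []
    trace: list[str] = []
    for _ in range(max_steps):
        changed = False
        # forward entry
        candidates = [c for c in X.columns if c not in included]
        best_p, best_c = entry_p, None
        base_rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(X))] + [X[c] for c in included]))
        for c in candidates:
            design = np.column_stack([np.ones(len(X))] + [X[k] for k in included + [c]])
            if np.linalg.matrix_rank(design) <= base_rank:
                continue  # candidate collinear with what is already in
            res = _ols(X[included + [c]], y)
            p = res.pvalues.get(c, 1.0)
            if p < best_p:
                best_p, best_c = p, c
        if best_c is not None:
            included.append(best_c)
            trace.append(f"enter {best_c} (p={best_p:.3g})")
            changed = True
        # backward removal
        while included:
            res = _ols(X[included], y)
            pv = res.pvalues.drop("const", errors="ignore")
            worst = pv.idxmax()
            if pv[worst] > removal_p:
                included.remove(worst)
                trace.append(f"remove {worst} (p={pv[worst]:.3g})")
                changed = True
            else:
                break
        if not changed:
            break
    else:
        raise RuntimeError(f"stepwise selection did not stabilize; trace: {trace}")

    if included:
        res = _ols(X[included], y)
        params = res.params
        spec = LinearModelSpec(
            intercept=float(params["const"]),
            coefficients={c: float(params[c]) for c in included},
            std_errors={c: float(res.bse[c]) for c in included},
            t_values={c: float(res.tvalues[c]) for c in included},
            p_values={c: float(res.pvalues[c]) for c in included},
            name="stepwise",
        )
        report = {
            "r_squared": float(res.rsquared),
            "adj_r_squared": float(res.rsquared_adj),
            "f_pvalue": float(res.f_pvalue),
            "n_obs": int(res.nobs),
            "trace": trace,
        }
    else:
        spec = LinearModelSpec(intercept=float(y.mean()), coefficients={}, name="stepwise")
        report = {
            "r_squared": 0.0,
            "adj_r_squared": 0.0,
            "f_pvalue": float("nan"),
            "n_obs": len(y),
            "trace": trace,
        }
    return spec, report
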