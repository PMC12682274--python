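"""Covariate attribution: which demographics drive eta, and in which direction.

A gradient-boosted regression-tree model predicts each ego's fitted eta from
species, sex, age, ego-network size, group size, habitat and the
species-by-age / species-by-sex interactions.  The model is explanatory, not
predictive: it is fit on the full table (no held-out split) and interrogated
three ways:

* global feature importance — normalized total gain per feature;
* per-ego Shapley attributions — exact TreeSHAP, so the base value plus the
  per-feature attributions reconstructs every prediction to machine
  precision (local accuracy);
* partial-dependence curves — model output over a grid of one focal
  feature, with the remaining numeric features held at their medians and
  categorical features at their modes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import xgboost as xgb

from .network_io import IndividualMeta

__all__ = [
    "FEATURES",
    "CATEGORICAL_FEATURES",
    "AttributionResult",
    "build_feature_table",
    "fit_attribution_model",
    "shap_attributions",
    "partial_dependence",
    "attribution_analysis",
]

#: predictor columns, in canonical order
FEATURES = (
    "species",
    "sex",
    "age",
    "ego_size",
    "group_size",
    "habitat",
    "species_x_age",
    "species_x_sex",
)
#: 0/1 indicator columns (held at their mode in partial dependence)
CATEGORICAL_FEATURES = frozenset({"species", "sex", "habitat", "species_x_sex"})

DEFAULT_HYPERPARAMS: dict = {
    "max_depth": 3,
    "n_estimators": 300,
    "learning_rate": 0.1,
    "objective": "reg:squarederror",
    "tree_method": "exact",
}

MIN_ROWS = 30


@dataclass(frozen=True)
class AttributionResult:
    """Bundle of global importance, Shapley matrix and PDP curves."""

    global_importance: Mapping[str, float]
    shap_matrix: pd.DataFrame  # one row per ego, one column per feature
    base_value: float
    pdp_curves: Mapping[str, pd.DataFrame]  # feature -> (grid value, prediction)


def build_feature_table(
    eta_estimates: pd.DataFrame, meta: Iterable[IndividualMeta] | pd.DataFrame
) -> pd.DataFrame:
    """Join fitted etas with demographics into the model's feature table.

    ``eta_estimates`` needs columns ego_id, eta, L (ego-network size) and
    group_size.  Encoding: chimpanzee = 1, male = 1, zoo = 1; the
    interaction columns are exact products of their parents (species_x_age
    uses age in years, pre-standardization).
    """
    if isinstance(meta, pd.DataFrame):
        meta_df = meta
    else:
        meta_df = pd.DataFrame(
            [
                {"individual_id": m.individual_id, "species": m.species,
                 "sex": m.sex, "age": m.age, "habitat": m.habitat}
                for m in meta
            ]
        )
    merged = eta_estimates.merge(
        meta_df[["individual_id", "species", "sex", "age", "habitat"]],
        left_on="ego_id",
        right_on="individual_id",
        how="left",
        suffixes=("", "_meta"),
    )
    if merged["species"].isna().any():
        missing = merged.loc[merged["species"].isna(), "ego_id"].tolist()
        raise ValueError(f"egos missing from metadata: {missing[:5]}")
    table = pd.DataFrame(
        {
            "ego_id": merged["ego_id"],
            "eta": merged["eta"].astype(float),
            "species": (merged["species"] == "chimpanzee").astype(float),
            "sex": (merged["sex"] == "male").astype(float),
            "age": merged["age"].astype(float),
            "ego_size": merged["L"].astype(float),
            "group_size": merged["group_size"].astype(float),
            "habitat": (merged["habitat"] == "zoo").astype(float),
        }
    )
    table["species_x_age"] = table["species"] * table["age"]
    table["species_x_sex"] = table["species"] * table["sex"]
    if table[list(FEATURES) + ["eta"]].isna().any().any():
        raise ValueError("feature table contains missing values")
    return table


def fit_attribution_model(
    table: pd.DataFrame,
    hyperparams: Mapping | None = None,
    seed: int = 0,
) -> tuple[xgb.XGBRegressor, dict[str, float]]:
    """Fit the boosted-tree model and return it with normalized global importance.

    Importance is total gain per feature normalized to sum 1 (features never
    used by any tree score 0).  Deterministic given the seed.
    """
    if len(table) < MIN_ROWS:
        raise ValueError(f"need at least {MIN_ROWS} rows to fit, got {len(table)}")
    params = dict(DEFAULT_HYPERPARAMS)
    if hyperparams:
        params.update(hyperparams)
    model = xgb.XGBRegressor(random_state=seed, n_jobs=1, **params)
    X = table[list(FEATURES)]
    model.fit(X, table["eta"].to_numpy())
    raw = model.get_booster().get_score(importance_type="total_gain")
    total = sum(raw.values())
    importance = {f: (raw.get(f, 0.0) / total if total > 0 else 0.0) for f in FEATURES}
    return model, importance


def shap_attributions(
    model: xgb.XGBRegressor, table: pd.DataFrame
) -> tuple[pd.DataFrame, float]:
    """Exact TreeSHAP attributions: one signed value per ego and feature.

    Local accuracy holds by construction: base_value + row sum equals the
    model prediction for every ego.
    """
    booster = model.get_booster()
    if booster.feature_names != list(FEATURES):
        raise ValueError(
            f"feature schema mismatch: model has {booster.feature_names}"
        )
    dmat = xgb.DMatrix(table[list(FEATURES)])
    contribs = booster.predict(dmat, pred_contribs=True)
    shap_matrix = pd.DataFrame(contribs[:, :-1], columns=list(FEATURES))
    if "ego_id" in table.columns:
        shap_matrix.insert(0, "ego_id", table["ego_id"].to_numpy())
    base_value = float(contribs[0, -1])
    return shap_matrix, base_value


def partial_dependence(
    model: xgb.XGBRegressor,
    table: pd.DataFrame,
    feature: str,
    grid_size: int = 20,
) -> pd.DataFrame:
    """Model output over a grid of one feature, others pinned at median/mode.

    Numeric features get a quantile grid of up to ``grid_size`` points;
    categorical (indicator) features are evaluated at their observed levels.
    Single-point conditioning: the non-focal features are fixed at their
    median (numeric) or mode (categorical), not averaged over.
    """
    if feature not in FEATURES:
        raise KeyError(f"unknown feature {feature!r}; expected one of {FEATURES}")
    if feature in CATEGORICAL_FEATURES:
        grid = np.sort(table[feature].unique())
    else:
        qs = np.linspace(0.0, 1.0, grid_size)
        grid = np.unique(table[feature].quantile(qs, interpolation="linear").to_numpy())
    base = {}
    for f in FEATURES:
        col = table[f]
        base[f] = float(col.mode().iloc[0]) if f in CATEGORICAL_FEATURES else float(col.median())
    rows = []
    for g in grid:
        row = dict(base)
        row[feature] = float(g)
        rows.append(row)
    X = pd.DataFrame(rows, columns=list(FEATURES))
    preds = model.predict(X)
    return pd.DataFrame({feature: grid.astype(float), "prediction": preds.astype(float)})


def attribution_analysis(
    table: pd.DataFrame,
    hyperparams: Mapping | None = None,
    seed: int = 0,
    grid_size: int = 20,
) -> AttributionResult:
    """Convenience wrapper: fit, attribute and trace PDPs for all features."""
    model, importance = fit_attribution_model(table, hyperparams, seed)
    shap_matrix, base_value = shap_attributions(model, table)
    pdps = {f: partial_dependence(model, table, f, grid_size) for f in FEATURES}
    return AttributionResult(
        global_importance=importance,
        shap_matrix=shap_matrix,
        base_value=base_value,
        pdp_curves=pdps,
    )
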