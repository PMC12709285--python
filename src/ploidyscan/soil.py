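"""Soil-chemistry table handling: imputation, PCA and oriented PC1 scores.

The calcareous-siliceous gradient is summarized by the first principal
component of the column-standardized soil table.  PC1 is oriented so that
the pH_H2O loading is negative: calcareous populations (high pH, high Ca,
high CEC) then sit at negative scores and siliceous at positive ones,
making the score sign convention deterministic across linear-algebra
backends.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PREDICTORS = ["pH_H2O", "pH_KCl", "bioavailable_Ca"]


def impute_soil(table: pd.DataFrame) -> tuple:
    """Fill missing soil measurements from linear models on the three
    always-measured predictors (pH H2O, pH KCl, bioavailable Ca).

    For each incomplete column an OLS model is fitted on the complete rows
    and missing entries are replaced by fitted values; observed cells are
    never altered.  Returns (completed table, boolean flag frame marking
    imputed cells)."""
    for col in PREDICTORS:
        if col not in table.columns:
            raise ValueError(f"predictor column {col} absent")
        if table[col].isna().any():
            raise ValueError(f"predictor column {col} has missing values")
    value_cols = [c for c in table.columns if c != "population"]
    out = table.copy()
    flags = pd.DataFrame(False, index=table.index, columns=value_cols)
    X_all = np.column_stack([np.ones(len(table))] + [table[c].to_numpy(float) for c in PREDICTORS])
    for col in value_cols:
        if col in PREDICTORS or not table[col].isna().any():
            continue
        complete = table[col].notna().to_numpy()
        if complete.sum() < len(PREDICTORS) + 1:
            raise ValueError(f"column {col}: fewer complete rows than predictors + 1")
        beta, *_ = np.linalg.lstsq(X_all[complete], table.loc[complete, col].to_numpy(float), rcond=None)
        fitted = X_all @ beta
        holes = ~complete
        out.loc[holes, col] = fitted[holes]
        flags.loc[holes, col] = True
    return out, flags


def soil_pca(table: pd.DataFrame) -> dict:
    """Column-standardized PCA of the complete soil table.

    Returns dict with ``scores`` (population x PC DataFrame), ``loadings``
    (variable x PC), ``variance_fraction`` and ``pc1`` (population ->
    oriented PC1 score Series).  Zero-variance columns are dropped with a
    warning; PC1 sign is fixed so the pH_H2O loading is negative."""
    value_cols = [c for c in table.columns if c != "population"]
    data = table[value_cols].to_numpy(float)
    if np.isnan(data).any():
        raise ValueError("soil table has missing values; impute first")
    sd = data.std(axis=0, ddof=0)
    keep = sd > 0
    dropped = [c for c, k in zip(value_cols, keep) if not k]
    if dropped:
        logger.warning("dropping zero-variance soil columns: %s", dropped)
    cols = [c for c, k in zip(value_cols, keep) if k]
    z = (data[:, keep] - data[:, keep].mean(axis=0)) / sd[keep]

    u, s_vals, vt = np.linalg.svd(z, full_matrices=False)
    scores = u * s_vals
    loadings = vt.T
    var_frac = s_vals**2 / (s_vals**2).sum()

    if "pH_H2O" in cols:
        j = cols.index("pH_H2O")
        if loadings[j, 0] > 0:
            loadings[:, 0] *= -1
            scores[:, 0] *= -1

    pc_names = [f"PC{i + 1}" for i in range(scores.shape[1])]
    scores_df = pd.DataFrame(scores, columns=pc_names)
    scores_df.insert(0, "population", table["population"].to_numpy())
    loadings_df = pd.DataFrame(loadings, index=cols, columns=pc_names)
    pc1 = pd.Series(scores[:, 0], index=table["population"].to_numpy(), name="soil_pc1")
    return {
        "scores": scores_df,
        "loadings": loadings_df,
        "variance_fraction": var_frac,
        "pc1": pc1,
    }
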