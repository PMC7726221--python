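"""Phenotype preparation: normality transform, outliers, BMI, fixed effects."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats


def boxcox_fit(values, shift: bool = False) -> tuple[float, np.ndarray]:
    """Profile-likelihood Box-Cox fit.

    Returns ``(lambda, transformed)`` with the transform
    (y^lambda - 1)/lambda for lambda != 0 and log(y) at lambda = 0, where
    lambda maximizes the profile log-likelihood.  Values must be strictly
    positive; with ``shift=True`` a constant is added first so the minimum
    becomes 1 (the shift is not undone).
    """
    values = np.asarray(values, dtype=float)
    if np.any(~np.isfinite(values)):
        raise ValueError("values must be finite")
    if shift:
        values = values - values.min() + 1.0
    if np.any(values <= 0):
        raise ValueError("values must be positive (use shift=True)")
    transformed, lam = stats.boxcox(values)
    return float(lam), transformed


def boxcox_loglik(values, lam: float) -> float:
    """Profile log-likelihood of the Box-Cox parameter (for diagnostics)."""
    return float(stats.boxcox_llf(lam, np.asarray(values, dtype=float)))


def remove_outliers(values, sd_threshold: float = 10.0):
    """Single-pass removal of values more than ``sd_threshold`` SDs from the mean.

    Mean and SD are computed once on all non-missing values before any
    removal, so the reported SD distances refer to the original sample.
    Returns ``(kept, removed)`` where ``removed`` is a frame with the
    original index, value and SD distance of each removed record.
    """
    if sd_threshold <= 0:
        raise ValueError("sd_threshold must be positive")
    series = pd.Series(np.asarray(values, dtype=float))
    observed = series.dropna()
    if len(observed) < 3:
        raise ValueError("need at least 3 non-missing values")
    mean = observed.mean()
    sd = observed.std(ddof=1)
    if sd == 0:
        warnings.warn("zero standard deviation; no outliers removable")
        return series, pd.DataFrame(columns=["value", "sd_distance"])
    dist = (series - mean).abs() / sd
    bad = dist > sd_threshold
    removed = pd.DataFrame({"value": series[bad], "sd_distance": dist[bad]})
    return series[~bad], removed


def compute_bmi(weight_kg, height_cm):
    """Body mass index: weight in kg over squared height in meters."""
    weight_kg = np.asarray(weight_kg, dtype=float)
    height_cm = np.asarray(height_cm, dtype=float)
    if np.any(height_cm <= 0):
        raise ValueError("height must be positive")
    return weight_kg / (height_cm / 100.0) ** 2


def build_design(
    pheno: pd.DataFrame,
    factors: list | None = None,
    covariates: list | None = None,
) -> tuple[np.ndarray, list]:
    """Fixed-effect design matrix: intercept, factor dummies, covariates.

    Classification variables are expanded to full-rank indicator columns
    with the first level as reference (a single-level factor contributes
    nothing beyond the intercept); covariates enter as numeric columns.
    Missing covariate values for phenotyped rows are an error.  Returns
    ``(X, column_names)`` aligned with the rows of ``pheno``.
    """
    factors = factors or []
    covariates = covariates or []
    n = len(pheno)
    cols = [np.ones(n)]
    names = ["intercept"]
    for f in factors:
        if f not in pheno.columns:
            raise KeyError(f"factor column {f!r} not found")
        col = pheno[f]
        if col.isna().any():
            raise ValueError(f"missing values in factor {f!r}")
        levels = pd.unique(col)
        for level in levels[1:]:  # first level is the reference
            cols.append((col == level).to_numpy(dtype=float))
            names.append(f"{f}[{level}]")
    for c in covariates:
        if c not in pheno.columns:
            raise KeyError(f"covariate column {c!r} not found")
        col = pheno[c].to_numpy(dtype=float)
        if np.any(~np.isfinite(col)):
            raise ValueError(f"missing values in covariate {c!r}")
        cols.append(col)
        names.append(c)
    return np.column_stack(cols), names
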