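"""Ten-fold cross-validation of the six prediction-model variants.

Model variants (by the components they include):

1. SNP additive + SNP dominance + haplotype additive
2. SNP additive + haplotype additive
3. SNP dominance + haplotype additive
4. haplotype additive only
5. SNP additive + SNP dominance
6. SNP additive only

Observed prediction accuracy is the Pearson correlation between the
phenotypic values of validation individuals and their predicted total
genetic values, averaged over folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .greml_gblup import greml_fit, gblup_predict

MODEL_COMPONENTS = {
    1: ("snp_additive", "snp_dominance", "hap_additive"),
    2: ("snp_additive", "hap_additive"),
    3: ("snp_dominance", "hap_additive"),
    4: ("hap_additive",),
    5: ("snp_additive", "snp_dominance"),
    6: ("snp_additive",),
}

HAPLOTYPE_MODELS = (1, 2, 3, 4)
SNP_MODELS = (5, 6)


@dataclass
class ModelSpec:
    model_id: int

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_COMPONENTS:
            raise ValueError(f"unknown model id {self.model_id}; must be 1..6")

    @property
    def components(self) -> tuple:
        return MODEL_COMPONENTS[self.model_id]

    @property
    def has_haplotypes(self) -> bool:
        return self.model_id in HAPLOTYPE_MODELS


@dataclass
class FoldPlan:
    assignments: np.ndarray  # fold index per phenotyped individual
    k: int
    seed: int

    def fold_mask(self, fold: int) -> np.ndarray:
        return self.assignments == fold


@dataclass
class AccuracyResult:
    model_id: int
    blocking: str
    per_fold: np.ndarray
    mean: float
    sd: float


def make_folds(ids, k: int = 10, seed: int = 0) -> FoldPlan:
    """Random fold assignment; first k-1 folds of equal size ceil(n/k), the
    last fold takes the (generally smaller) remainder.

    When n is divisible by k all folds are equal.  If nine full folds of
    ceil(n/k) would exhaust the sample the plan falls back to the most even
    split, with a warning.
    """
    n = len(ids)
    if n < k:
        raise ValueError(f"need at least k={k} individuals, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    assignments = np.empty(n, dtype=int)

    size = int(np.ceil(n / k))
    if n % k == 0:
        sizes = [n // k] * k
    elif (k - 1) * size < n:
        sizes = [size] * (k - 1) + [n - (k - 1) * size]
    else:
        warnings.warn("equal-first-folds rule infeasible; using most even split")
        base = n // k
        extra = n % k
        sizes = [base + (1 if i < extra else 0) for i in range(k)]
    start = 0
    for fold, s in enumerate(sizes):
        assignments[order[start : start + s]] = fold
        start += s
    return FoldPlan(assignments=assignments, k=k, seed=seed)


def cross_validate(
    y: np.ndarray,
    X: np.ndarray,
    grms: dict,
    model: ModelSpec,
    plan: FoldPlan,
    blocking: str = "",
    refit_per_fold: bool = True,
    full_fit=None,
) -> AccuracyResult:
    """Cross-validated observed accuracy of one model on one blocking.

    Per fold, validation phenotypes are omitted from variance-component
    estimation and from the GBLUP equations; the GRMs cover all
    individuals, so validation individuals still receive predictions.
    With ``refit_per_fold=False`` variance components from ``full_fit``
    (or a single full-data fit) are reused across folds, mimicking
    fast-validation practice.
    """
    y = np.asarray(y, dtype=float).ravel()
    sub = {name: grms[name] for name in model.components}
    if not refit_per_fold and full_fit is None:
        full_fit = greml_fit(y, X, sub)

    per_fold = []
    for fold in range(plan.k):
        val = plan.fold_mask(fold)
        train = ~val
        if val.sum() < 3:
            warnings.warn(f"fold {fold} has < 3 validation phenotypes; skipped")
            continue
        fit = greml_fit(y[train], X[train], {k: g[np.ix_(train, train)] for k, g in sub.items()}) if refit_per_fold else full_fit
        pred = gblup_predict(fit, sub, y, X, train_mask=train)
        acc = float(np.corrcoef(y[val], pred["total"][val])[0, 1])
        per_fold.append(acc)

    per_fold = np.asarray(per_fold)
    return AccuracyResult(
        model_id=model.model_id,
        blocking=blocking,
        per_fold=per_fold,
        mean=float(per_fold.mean()),
        sd=float(per_fold.std(ddof=1)) if per_fold.size > 1 else 0.0,
    )


def accuracy_gain(acc_hap: float, acc_snp_best: float) -> float:
    """Percent accuracy gain of a haplotype model over the best SNP model."""
    if acc_snp_best == 0:
        raise ZeroDivisionError("SNP baseline accuracy is zero")
    return 100.0 * (acc_hap - acc_snp_best) / acc_snp_best


def model_grid(
    y: np.ndarray,
    X: np.ndarray,
    grm_sets: dict,
    models,
    plan: FoldPlan,
    refit_per_fold: bool = True,
) -> pd.DataFrame:
    """Run every (blocking, model) cell and summarize accuracy and gains.

    ``grm_sets`` maps a blocking label to its component-GRM dict (SNP GRMs
    may be shared between labels).  The summary reports mean and SD
    accuracy per cell, the percent gain of each haplotype model over the
    best SNP model, and flags the best cell.  SNP models are fit once per
    distinct SNP-GRM set, not per blocking label.
    """
    rows = []
    snp_results: dict[int, AccuracyResult] = {}
    for mid in models:
        if mid in SNP_MODELS:
            label, grms = next(iter(grm_sets.items()))
            snp_results[mid] = cross_validate(
                y, X, grms, ModelSpec(mid), plan, blocking="snp", refit_per_fold=refit_per_fold
            )
    best_snp = max((r.mean for r in snp_results.values()), default=np.nan)

    for label, grms in grm_sets.items():
        for mid in models:
            if mid in SNP_MODELS:
                res = snp_results[mid]
            else:
                res = cross_validate(
                    y, X, grms, ModelSpec(mid), plan, blocking=label, refit_per_fold=refit_per_fold
                )
            gain = (
                accuracy_gain(res.mean, best_snp)
                if (mid in HAPLOTYPE_MODELS and np.isfinite(best_snp))
                else np.nan
            )
            rows.append((res.blocking if mid in SNP_MODELS else label, mid, res.mean, res.sd, gain))
    df = pd.DataFrame(rows, columns=["blocking", "model", "mean", "sd", "gain_pct"])
    df = df.drop_duplicates(subset=["blocking", "model"]).reset_index(drop=True)
    df["best"] = df["mean"] == df["mean"].max()
    return df
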