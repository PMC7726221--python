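"""GREML variance-component estimation and GBLUP prediction.

The model is y = Xb + sum_i u_i + e with u_i ~ N(0, sigma_i^2 G_i) for the
relationship matrices G_i supplied (SNP additive, SNP dominance, haplotype
additive) and e ~ N(0, sigma_e^2 I); one record per individual.  Variance
components maximize the restricted likelihood; estimation uses EM-REML
steps for robustness near boundaries with average-information (AI)
acceleration once components are interior, negative updates truncated at a
small floor.  Heritability of component i is sigma_i^2 over the sum of all
estimated variance components.

GBLUP solves the mixed-model equations in relationship-matrix form:
b_hat = (X'V^-1 X)^-1 X'V^-1 y on training records and
u_hat_i = sigma_i^2 G_i[:, train] V_train^-1 (y - X b_hat), which yields
predictions for all individuals, including those whose phenotypes were
masked out of the fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

_EM_ITERS = 3  # pure EM warm-up before AI steps


@dataclass
class FitResult:
    variance_components: dict  # component name -> sigma^2 (includes "residual")
    heritabilities: dict  # component name -> sigma_i^2 / sum(sigma^2)
    beta: np.ndarray
    log_likelihood: float
    converged: bool
    n_iter: int
    component_names: list = field(default_factory=list)

    @property
    def phenotypic_variance(self) -> float:
        return float(sum(self.variance_components.values()))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (name, self.variance_components[name], self.heritabilities[name])
            for name in (*self.component_names, "residual")
        ]
        df = pd.DataFrame(rows, columns=["component", "variance", "heritability"])
        df["logL"] = self.log_likelihood
        df["iterations"] = self.n_iter
        df["converged"] = self.converged
        return df


def _reml_pieces(y, X, gs, theta):
    """V-derived quantities shared by likelihood, gradient and AI matrix."""
    n = y.size
    v = theta[-1] * np.eye(n)
    for g, th in zip(gs, theta[:-1]):
        v += th * g
    c, low = cho_factor(v, lower=True)
    logdet_v = 2.0 * np.sum(np.log(np.diag(c)))
    vinv = cho_solve((c, low), np.eye(n))
    vinv_x = vinv @ X
    m = X.T @ vinv_x
    sign, logdet_m = np.linalg.slogdet(m)
    if sign <= 0:
        raise np.linalg.LinAlgError("X'V^-1X not positive definite")
    minv = np.linalg.inv(m)
    p = vinv - vinv_x @ minv @ vinv_x.T
    py = p @ y
    loglik = -0.5 * (logdet_v + logdet_m + float(y @ py))
    return p, py, loglik


def _loglik_only(y, X, gs, theta):
    try:
        return _reml_pieces(y, X, gs, theta)[2]
    except np.linalg.LinAlgError:
        return -np.inf


def greml_fit(
    y: np.ndarray,
    X: np.ndarray,
    grms: dict,
    tol: float = 1e-8,
    max_iter: int = 200,
    init: dict | None = None,
) -> FitResult:
    """REML fit of variance components for the supplied relationship matrices.

    Parameters
    ----------
    y, X
        Phenotypes (complete) and full-rank fixed-effect design for the
        fitted individuals.
    grms
        Ordered mapping of component name to n x n relationship matrix.
    tol
        Relative log-likelihood convergence tolerance (parameter changes
        must also settle below 1e-6 relative).
    init
        Optional starting variance components by name (plus "residual").

    Non-convergence within ``max_iter`` yields ``converged=False`` on the
    result, not an exception.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = y.size
    if X.shape[0] != n:
        raise ValueError("X row count does not match y")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("X is rank deficient")
    names = list(grms.keys())
    gs = [np.asarray(grms[k], dtype=float) for k in names]
    for g in gs:
        if g.shape != (n, n):
            raise ValueError("GRM shape does not match y")

    vary = float(np.var(y, ddof=1))
    if vary == 0:
        raise ValueError("phenotype has zero variance")
    floor = 1e-8 * vary
    c = len(gs)
    if init is not None:
        theta = np.array([init[k] for k in names] + [init["residual"]], dtype=float)
    else:
        theta = np.full(c + 1, vary / (c + 1))
    theta = np.maximum(theta, floor)

    p, py, loglik = _reml_pieces(y, X, gs, theta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        gpy = [g @ py for g in gs] + [py]
        tr_pg = [float(np.einsum("ij,ji->", p, g)) for g in gs] + [float(np.trace(p))]
        ytpgpy = [float(py @ t) for t in gpy]
        grad = np.array([-0.5 * (tr_pg[i] - ytpgpy[i]) for i in range(c + 1)])

        use_ai = it > _EM_ITERS
        new_theta = None
        if use_ai:
            pt = [p @ t for t in gpy]
            ai = 0.5 * np.array([[float(gpy[i] @ pt[j]) for j in range(c + 1)] for i in range(c + 1)])
            try:
                delta = np.linalg.solve(ai, grad)
            except np.linalg.LinAlgError:
                delta = None
            if delta is not None:
                step = 1.0
                for _ in range(12):
                    cand = np.maximum(theta + step * delta, floor)
                    ll = _loglik_only(y, X, gs, cand)
                    if ll >= loglik - 1e-10:
                        new_theta = cand
                        break
                    step *= 0.5
        if new_theta is None:  # EM update (guaranteed ascent direction)
            new_theta = np.array(
                [
                    max(theta[i] + theta[i] ** 2 / n * (ytpgpy[i] - tr_pg[i]), floor)
                    for i in range(c + 1)
                ]
            )

        try:
            p, py, new_loglik = _reml_pieces(y, X, gs, new_theta)
        except np.linalg.LinAlgError:
            warnings.warn("REML update produced singular V; stopping early")
            break
        rel_ll = abs(new_loglik - loglik) / (abs(loglik) + 1.0)
        rel_th = np.max(np.abs(new_theta - theta) / (np.abs(theta) + floor))
        theta, loglik = new_theta, new_loglik
        if rel_ll < tol and rel_th < 1e-6:
            converged = True
            break

    if not converged:
        warnings.warn(f"GREML did not converge in {it} iterations")

    p, py, loglik = _reml_pieces(y, X, gs, theta)
    beta = _gls_beta(y, X, gs, theta)

    total = float(theta.sum())
    variance_components = {name: float(th) for name, th in zip(names, theta[:-1])}
    variance_components["residual"] = float(theta[-1])
    heritabilities = {k: v / total for k, v in variance_components.items()}
    return FitResult(
        variance_components=variance_components,
        heritabilities=heritabilities,
        beta=beta,
        log_likelihood=loglik,
        converged=converged,
        n_iter=it,
        component_names=names,
    )


def _build_v(gs, theta, n):
    v = theta[-1] * np.eye(n)
    for g, th in zip(gs, theta[:-1]):
        v += th * g
    return v


def _gls_beta(y, X, gs, theta):
    v = _build_v(gs, theta, y.size)
    c, low = cho_factor(v, lower=True)
    vinv_y = cho_solve((c, low), y)
    vinv_x = cho_solve((c, low), X)
    return np.linalg.solve(X.T @ vinv_x, X.T @ vinv_y)


def gblup_predict(
    fit: FitResult,
    grms: dict,
    y: np.ndarray,
    X: np.ndarray,
    train_mask: np.ndarray,
) -> dict:
    """GBLUP of genetic values for all individuals from training records.

    ``train_mask`` is a boolean vector over all individuals; phenotypes of
    masked-out individuals never enter the equations, but their GRM rows do,
    which is what yields their predictions.  Returns a dict with ``beta``,
    one n-vector per genetic component, and their sum under ``total``.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    train = np.asarray(train_mask, dtype=bool)
    names = fit.component_names
    gs = [np.asarray(grms[k], dtype=float) for k in names]
    sigmas = [fit.variance_components[k] for k in names]
    sigma_e = fit.variance_components["residual"]

    yt = y[train]
    xt = X[train]
    nt = yt.size
    vt = sigma_e * np.eye(nt)
    for g, s in zip(gs, sigmas):
        vt += s * g[np.ix_(train, train)]
    try:
        cf = cho_factor(vt, lower=True)
    except np.linalg.LinAlgError:
        ridge = 1e-8 * float(np.mean(np.diag(vt)))
        warnings.warn(f"training V not positive definite; adding ridge {ridge:g}")
        cf = cho_factor(vt + ridge * np.eye(nt), lower=True)

    vinv_y = cho_solve(cf, yt)
    vinv_x = cho_solve(cf, xt)
    beta = np.linalg.solve(xt.T @ vinv_x, xt.T @ vinv_y)
    r = cho_solve(cf, yt - xt @ beta)

    out = {"beta": beta}
    total = np.zeros(y.size)
    for name, g, s in zip(names, gs, sigmas):
        u = s * (g[:, train] @ r)
        out[name] = u
        total += u
    out["total"] = total
    return out


def per_locus_heritability(
    fit: FitResult,
    mm,
    grms: dict,
    y: np.ndarray,
    X: np.ndarray,
    snp_map: pd.DataFrame,
    blockset=None,
) -> dict:
    """Back-solved per-SNP and per-block heritability profiles.

    Effects are recovered from the fitted model as
    effect = (sigma^2 / k) W' V^-1 (y - X b_hat); the heritability of SNP i
    is var(W[:, i]) * effect_i^2 / sigma_P^2 and the heritability of a
    haplotype block is the sample variance of the block's fitted
    genetic-value vector over sigma_P^2.  Returns a dict of frames keyed by
    component, each with chrom, pos_start, pos_end, locus_id, heritability.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    names = fit.component_names
    gs = [np.asarray(grms[k], dtype=float) for k in names]
    theta = np.array([fit.variance_components[k] for k in names] + [fit.variance_components["residual"]])
    v = _build_v(gs, theta, y.size)
    cf = cho_factor(v, lower=True)
    resid = y - X @ fit.beta
    vinv_r = cho_solve(cf, resid)
    sigma_p = fit.phenotypic_variance

    profiles: dict[str, pd.DataFrame] = {}

    def snp_profile(w, k, sigma2):
        effects = (sigma2 / k) * (w.T @ vinv_r)
        col_var = w.var(axis=0, ddof=1)
        h2 = col_var * effects**2 / sigma_p
        return pd.DataFrame(
            {
                "chrom": snp_map["chrom"].to_numpy(),
                "pos_start": snp_map["pos"].to_numpy(),
                "pos_end": snp_map["pos"].to_numpy(),
                "locus_id": [f"snp{i}" for i in range(len(snp_map))],
                "heritability": h2,
            }
        )

    if "snp_additive" in names and mm.w_alpha is not None:
        profiles["snp_additive"] = snp_profile(
            mm.w_alpha, mm.k_alpha, fit.variance_components["snp_additive"]
        )
    if "snp_dominance" in names and mm.w_delta is not None:
        profiles["snp_dominance"] = snp_profile(
            mm.w_delta, mm.k_delta, fit.variance_components["snp_dominance"]
        )
    if "hap_additive" in names and mm.w_alpha_h is not None:
        if blockset is None:
            raise ValueError("blockset required for haplotype profile")
        sigma2 = fit.variance_components["hap_additive"]
        effects = (sigma2 / mm.k_alpha_h) * (mm.w_alpha_h.T @ vinv_r)
        rows = []
        for block in blockset.blocks:
            sl = mm.hap_block_slices[block.block_id]
            gv = mm.w_alpha_h[:, sl] @ effects[sl]
            pos = snp_map.loc[block.snp_indices, "pos"]
            rows.append(
                (
                    block.chrom,
                    int(pos.min()),
                    int(pos.max()),
                    block.block_id,
                    float(gv.var(ddof=1) / sigma_p),
                )
            )
        profiles["hap_additive"] = pd.DataFrame(
            rows, columns=["chrom", "pos_start", "pos_end", "locus_id", "heritability"]
        )
    return profiles
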