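"""Rank-based (Wilcoxon-score) linear regression.

Slopes minimize Jaeckel's dispersion

    D(beta) = sum_i a(R(e_i)) * e_i,   e = y - X beta,

with Wilcoxon scores a(i) = sqrt(12) * (i/(n+1) - 1/2) and midranks for
ties.  D is convex and piecewise linear, invariant to the intercept, so the
intercept is estimated afterwards as the median of the residuals.  Standard
errors use the scale parameter tau = (sqrt(12) * integral f^2)^{-1},
estimated by the Koul-Sievers-McKean device: the length of the
distribution-free signed-rank confidence interval built from the Walsh
averages of the residuals is asymptotically 2 * z_{alpha/2} * tau / sqrt(n),
so tau is read off that length (alpha = 0.05 acts as the bandwidth constant,
with a sqrt(n / (n - p - 1)) degrees-of-freedom correction).

This estimator is highly efficient under Gaussian errors (ARE ~ 0.955
versus least squares) and resistant to gross response outliers, which is
why it is the covariate-adjustment engine for the metabolite-metabolite
screens.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import ConcentrationMatrix
from .screen import bh_adjust

_SQRT12 = np.sqrt(12.0)


def _wilcoxon_scores(e: np.ndarray) -> np.ndarray:
    n = e.size
    r = stats.rankdata(e)
    return _SQRT12 * (r / (n + 1.0) - 0.5)


def jaeckel_dispersion(beta: np.ndarray, y: np.ndarray, X: np.ndarray) -> float:
    """Wilcoxon-score dispersion of the residuals y - X beta."""
    e = y - X @ beta
    return float(_wilcoxon_scores(e) @ e)


def ksm_tau(residuals: np.ndarray, n_params: int, conf: float = 0.95) -> float:
    """Koul-Sievers-McKean estimate of the Wilcoxon scale parameter tau.

    Uses the length of the (1 - alpha) signed-rank confidence interval over
    the ordered Walsh averages of the residuals.
    """
    e = np.asarray(residuals, dtype=float)
    n = e.size
    if n < 10:
        raise ValueError("too few residuals to estimate tau")
    z = stats.norm.ppf((1.0 + conf) / 2.0)
    i, j = np.triu_indices(n)
    walsh = np.sort((e[i] + e[j]) / 2.0)
    m = walsh.size
    mean_w = n * (n + 1) / 4.0
    sd_w = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
    k = int(np.floor(mean_w - z * sd_w))
    k = max(k, 0)
    lo, hi = walsh[k], walsh[m - 1 - k]
    tau = np.sqrt(n) * (hi - lo) / (2.0 * z)
    # degrees-of-freedom correction, as in standard rank-regression software
    df = max(n - n_params - 1, 1)
    return float(tau * np.sqrt(n / df))


@dataclass
class RankFitResult:
    """Fitted rank regression: intercept + slopes, Wald inference."""

    coefficients: np.ndarray  # [intercept, slopes...]
    se: np.ndarray  # slopes only
    tau_hat: float
    p_values: np.ndarray  # slopes only
    converged: bool
    n_used: int
    dispersion: float

    @property
    def intercept(self) -> float:
        return float(self.coefficients[0])

    @property
    def slopes(self) -> np.ndarray:
        return self.coefficients[1:]


def wilcoxon_rank_fit(y, design, *, tol: float = 1e-8, max_iter: int = 100) -> RankFitResult:
    """Fit y ~ design by minimizing the Wilcoxon-score dispersion.

    ``design`` holds the slope columns only (no intercept column; the
    dispersion is intercept-invariant and the intercept is the residual
    median).  Minimization uses the classical Newton-type iteration for
    rank regression: from the least-squares start, step
    tau * (X'X)^{-1} X' a(R(e)) with step-halving whenever the dispersion
    fails to decrease (D is convex and piecewise linear, so the
    least-squares start is consistent and the scaled gradient step is the
    natural quasi-Newton direction).  Columns are standardized internally
    for conditioning.  Convergence: slope change below ``tol``.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("response and design have incompatible shapes")
    if n <= p + 2:
        raise ValueError(f"need n > p + 2 observations (n={n}, p={p})")
    col_sd = X.std(axis=0, ddof=1)
    if np.any(col_sd == 0):
        raise ValueError("design matrix is rank deficient (constant column)")
    Xs = (X - X.mean(axis=0)) / col_sd
    if np.linalg.matrix_rank(Xs) < p:
        raise ValueError("design matrix is rank deficient")

    yc = y - y.mean()
    beta, *_ = np.linalg.lstsq(Xs, yc, rcond=None)
    H_inv = np.linalg.inv(Xs.T @ Xs)
    e0 = yc - Xs @ beta
    tau0 = ksm_tau(e0 if n <= 400 else e0[:400], p)  # step scale only
    if tau0 <= 0 or not np.isfinite(tau0):
        tau0 = 1.0

    d_old = float(_wilcoxon_scores(yc - Xs @ beta) @ (yc - Xs @ beta))
    converged = False
    lam = 1.0  # warm-started step length across iterations
    scale = max(1.0, float(np.max(np.abs(beta))))
    for _ in range(max_iter):
        e = yc - Xs @ beta
        step = tau0 * (H_inv @ (Xs.T @ _wilcoxon_scores(e)))
        lam = min(1.0, 2.0 * lam)
        for _half in range(30):
            cand = beta + lam * step
            d_new = float(_wilcoxon_scores(yc - Xs @ cand) @ (yc - Xs @ cand))
            if d_new <= d_old:
                break
            lam *= 0.5
        else:
            converged = True  # at a kink: no descent along the step direction
            break
        moved = np.max(np.abs(lam * step))
        improved = d_old - d_new
        beta, d_old = cand, d_new
        if moved < tol * scale or improved < 1e-11 * (abs(d_old) + 1.0):
            converged = True
            break
    else:
        # ran out of iterations creeping along the flat valley floor of the
        # piecewise-linear dispersion; tiny final moves still count as converged
        converged = moved < 1e-6 * scale

    beta = beta / col_sd  # back to the original column scale
    resid = y - X @ beta
    Xc = X - X.mean(axis=0)
    intercept = float(np.median(resid))
    tau = ksm_tau(resid, p)
    XtX_inv = np.linalg.inv(Xc.T @ Xc)
    se = tau * np.sqrt(np.diag(XtX_inv))
    df = n - p - 1
    with np.errstate(divide="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf)
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=df)
    return RankFitResult(
        coefficients=np.concatenate([[intercept], beta]),
        se=se,
        tau_hat=tau,
        p_values=pvals,
        converged=converged,
        n_used=n,
        dispersion=d_old,
    )


def adjusted_pairwise_screen(
    X: ConcentrationMatrix,
    Y: ConcentrationMatrix,
    covariates: pd.DataFrame | None,
    covariate_set: list[str] | tuple[str, ...] = (),
    *,
    model_label: str = "model1",
    scale: str = "natural",
    fdr_level: float = 0.10,
) -> pd.DataFrame:
    """Covariate-adjusted bipartite screen via rank regression.

    For every (x, y) metabolite pair, fits ``y ~ x + covariates`` with
    Wilcoxon scores on complete cases and reports the x slope, its SE and
    two-sided p, with BH q over the whole screen.  ``scale`` chooses
    natural concentrations or their natural logs (missing stays missing).
    """
    if scale not in {"natural", "log"}:
        raise ValueError("scale must be 'natural' or 'log'")
    covariate_set = list(covariate_set)
    if covariate_set:
        if covariates is None:
            raise ValueError("covariate_set given without a covariate table")
        unknown = [c for c in covariate_set if c not in covariates.columns]
        if unknown:
            raise KeyError(f"unknown covariates: {unknown}")
        if list(covariates.index) != list(X.values.index):
            raise ValueError("covariates not aligned to matrix rows")
    if list(X.values.index) != list(Y.values.index):
        raise ValueError("matrices must be row-aligned to the same dyads")

    xv = X.values.to_numpy(dtype=float)
    yv = Y.values.to_numpy(dtype=float)
    if scale == "log":
        with np.errstate(divide="ignore"):
            xv = np.where(xv > 0, np.log(xv), np.nan)
            yv = np.where(yv > 0, np.log(yv), np.nan)
    C = (
        covariates[covariate_set].to_numpy(dtype=float)
        if covariate_set
        else np.empty((xv.shape[0], 0))
    )
    c_ok = ~np.isnan(C).any(axis=1) if covariate_set else np.ones(xv.shape[0], bool)

    rows = []
    for i, cx in enumerate(X.values.columns):
        for j, cy in enumerate(Y.values.columns):
            ok = c_ok & ~np.isnan(xv[:, i]) & ~np.isnan(yv[:, j])
            n_used = int(ok.sum())
            flag = ""
            est = se = p = np.nan
            if n_used <= C.shape[1] + 3:
                flag = "insufficient_n"
            else:
                design = np.column_stack([xv[ok, i], C[ok]])
                try:
                    fit = wilcoxon_rank_fit(yv[ok, j], design)
                    est, se, p = fit.slopes[0], fit.se[0], fit.p_values[0]
                    if not fit.converged:
                        flag = "nonconvergence"
                except (ValueError, np.linalg.LinAlgError) as exc:
                    flag = f"fit_error:{type(exc).__name__}"
            rows.append(
                {
                    "feature_x": cx,
                    "compartment_x": X.compartment,
                    "feature_y": cy,
                    "compartment_y": Y.compartment,
                    "estimate": est,
                    "se": se,
                    "p_value": p,
                    "n_used": n_used,
                    "model": model_label,
                    "flag": flag,
                }
            )
    result = pd.DataFrame(rows)
    result["q_value"] = np.nan
    testable = result["flag"].isin(["", "nonconvergence"]) & result["p_value"].notna()
    if testable.any():
        result.loc[testable, "q_value"] = bh_adjust(
            result.loc[testable, "p_value"].to_numpy()
        )
    result["significant"] = result["q_value"] < fdr_level
    return result
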