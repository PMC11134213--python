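"""Spearman correlation screens with Benjamini-Hochberg FDR control.

Each screen (all pairs within one metabolome, or all bipartite pairs
between two metabolomes) forms one FDR family; the reporting rule
downstream is two-sided q < 0.10.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import ConcentrationMatrix

#: below this many pairwise-complete observations a pair is not testable
MIN_PAIRWISE_N = 5
#: n below which the exact permutation null is used instead of the t reference
EXACT_P_MAX_N = 9


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} m * p_(j) / j over the ordered p-values, capped at
    1 and returned in the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho as the Pearson correlation of midranks."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.corrcoef(rx, ry)[0, 1])


def _t_p_value(rho: float, n: int) -> float:
    """Two-sided p from the t approximation on rho."""
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def _exact_p_value(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Exact permutation p for tiny n by full enumeration of y orderings."""
    ry = stats.rankdata(y)
    rx = stats.rankdata(x)
    n = len(rx)
    count = 0
    total = 0
    tol = 1e-12
    for perm in permutations(range(n)):
        rho = np.corrcoef(rx, ry[list(perm)])[0, 1]
        if abs(rho) >= abs(rho_obs) - tol:
            count += 1
        total += 1
    return count / total


def spearman_screen(
    X: ConcentrationMatrix,
    Y: ConcentrationMatrix | None = None,
    *,
    p_method: str = "auto",
    fdr_level: float = 0.10,
) -> pd.DataFrame:
    """Pairwise Spearman screen; bipartite if ``Y`` given, else within ``X``.

    Pairs use pairwise-complete observations (missing values excluded per
    pair, no imputation).  Pairs with a constant column or fewer than
    ``MIN_PAIRWISE_N`` complete observations are flagged and excluded from
    the FDR family.  Returns one row per pair with rho, two-sided p, BH q,
    ``n_used``, a ``significant`` indicator at ``fdr_level`` and a ``flag``.
    """
    if p_method not in {"auto", "t", "exact"}:
        raise ValueError("p_method must be one of auto/t/exact")
    self_mode = Y is None
    Yv = X.values if self_mode else Y.values
    if not self_mode and list(X.values.index) != list(Yv.index):
        raise ValueError("matrices must be row-aligned to the same dyads")

    Xv = X.values
    comp_x = X.compartment
    comp_y = comp_x if self_mode else Y.compartment
    cols_x = list(Xv.columns)
    cols_y = list(Yv.columns)

    rows = []
    xa = Xv.to_numpy(dtype=float)
    ya = Yv.to_numpy(dtype=float)
    for i, cx in enumerate(cols_x):
        j_start = i + 1 if self_mode else 0
        for j in range(j_start, len(cols_y)):
            cy = cols_y[j]
            x = xa[:, i]
            y = ya[:, j]
            ok = ~(np.isnan(x) | np.isnan(y))
            n_used = int(ok.sum())
            flag = ""
            rho = np.nan
            p = np.nan
            if n_used < MIN_PAIRWISE_N:
                flag = "insufficient_n"
            else:
                xs, ys = x[ok], y[ok]
                rho = _spearman_rho(xs, ys)
                if np.isnan(rho):
                    flag = "constant_column"
                else:
                    use_exact = p_method == "exact" or (
                        p_method == "auto" and n_used <= EXACT_P_MAX_N
                    )
                    p = (
                        _exact_p_value(xs, ys, rho)
                        if use_exact
                        else _t_p_value(rho, n_used)
                    )
            rows.append(
                {
                    "feature_x": cx,
                    "compartment_x": comp_x,
                    "feature_y": cy,
                    "compartment_y": comp_y,
                    "estimate": rho,
                    "p_value": p,
                    "n_used": n_used,
                    "flag": flag,
                }
            )
    result = pd.DataFrame(rows)
    result["q_value"] = np.nan
    testable = result["flag"] == ""
    if testable.any():
        result.loc[testable, "q_value"] = bh_adjust(
            result.loc[testable, "p_value"].to_numpy()
        )
    result["significant"] = result["q_value"] < fdr_level
    return result


def write_screen_tsv(result: pd.DataFrame, path) -> None:
    cols = [
        "feature_x",
        "compartment_x",
        "feature_y",
        "compartment_y",
        "estimate",
        "p_value",
        "q_value",
        "n_used",
        "significant",
        "flag",
    ]
    extra = [c for c in result.columns if c not in cols]
    result[cols + extra].to_csv(path, sep="\t", index=False)
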