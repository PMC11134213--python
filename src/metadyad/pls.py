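"""Canonical-mode (sparse) partial least squares between two metabolomes.

The multivariate core of the pipeline.  Given two preprocessed blocks
X (n x p) and Y (n x q) — covariates partialled out by least squares, then
columns centered and scaled — each component seeks unit-norm weight
vectors a, b maximizing cov(Xa, Yb), optionally with a per-component
sparsity budget enforced by soft-thresholding (keep the k
largest-magnitude entries, shrink them toward zero by the (k+1)-th
magnitude).  Canonical mode deflates each block on its *own* latent
variate, modelling a bidirectional relationship rather than predicting Y
from X.

Component count is chosen by the coefficient of prediction Q^2 in
leave-one-out cross-validation, and the first latent covariance is tested
against a permutation null obtained by re-fitting after permuting the rows
of Y (9999 permutations by default).  Relevance networks summarize the
fitted association structure as a bipartite graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

#: conventional Q^2 retention threshold for a significant component
Q2_LIMIT = 0.0975


# ---------------------------------------------------------------------------
# preprocessing


def residualize(M, covariates) -> np.ndarray:
    """Replace each column of M by its least-squares residual on covariates.

    ``covariates`` must include an intercept column (or be passed through
    :func:`covariate_design`); exact orthogonality of the output to every
    covariate column is the contract.
    """
    M = np.asarray(M, dtype=float)
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if M.shape[0] != C.shape[0]:
        raise ValueError("row mismatch between data and covariates")
    if np.isnan(M).any() or np.isnan(C).any():
        raise ValueError("residualize requires complete rows")
    if np.linalg.matrix_rank(C) < C.shape[1]:
        raise np.linalg.LinAlgError("covariate design is rank deficient")
    coef, *_ = np.linalg.lstsq(C, M, rcond=None)
    return M - C @ coef


def covariate_design(covariates: pd.DataFrame, names) -> np.ndarray:
    """Numeric design matrix [1, covariates] for partialling out."""
    D = covariates[list(names)].to_numpy(dtype=float)
    return np.column_stack([np.ones(D.shape[0]), D])


def center_scale(M) -> np.ndarray:
    """Columns to mean 0, unit variance (ddof=1); constant columns error."""
    M = np.asarray(M, dtype=float)
    mu = M.mean(axis=0)
    sd = M.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0).tolist()
        raise ValueError(f"constant columns cannot be scaled: {bad}")
    return (M - mu) / sd


# ---------------------------------------------------------------------------
# the sparse canonical PLS fit


def soft_threshold_keep(v: np.ndarray, keep: int) -> np.ndarray:
    """Keep the ``keep`` largest-|.| entries, shrunk by the next magnitude."""
    v = np.asarray(v, dtype=float)
    if keep >= v.size:
        return v.copy()
    if keep < 1:
        raise ValueError("keep budget must be >= 1")
    mags = np.abs(v)
    lam = np.partition(mags, v.size - keep - 1)[v.size - keep - 1]
    out = np.sign(v) * np.maximum(mags - lam, 0.0)
    if not np.any(out):
        raise ValueError("all-zero loading after soft-thresholding")
    return out


@dataclass
class PLSFit:
    """A fitted canonical (sparse) PLS model for one block pair."""

    n_components: int
    loadings_x: np.ndarray  # p x H unit-norm weight vectors
    loadings_y: np.ndarray  # q x H
    scores_x: np.ndarray  # n x H  (t_h)
    scores_y: np.ndarray  # n x H  (u_h)
    covariances: np.ndarray  # cov(t_h, u_h), H
    variance_explained_x: np.ndarray  # per component
    variance_explained_y: np.ndarray
    keep_x: tuple[int, ...]
    keep_y: tuple[int, ...]
    # regression loadings used for deflation / prediction of new samples
    reg_x: np.ndarray = field(repr=False, default=None)  # p x H: X_h^T t / t^T t
    reg_y: np.ndarray = field(repr=False, default=None)  # q x H: Y_h^T u / u^T u
    y_on_t: np.ndarray = field(repr=False, default=None)  # q x H: Y_h^T t / t^T t
    n_iter: tuple[int, ...] = ()

    @property
    def variance_explained_pair(self) -> np.ndarray:
        """Mean of the two blocks' per-component proportions."""
        return 0.5 * (self.variance_explained_x + self.variance_explained_y)


def _budgets(keep, width: int, H: int) -> tuple[int, ...]:
    if keep is None:
        return (width,) * H
    if np.isscalar(keep):
        keep = (int(keep),) * H
    keep = tuple(int(k) for k in keep)
    if len(keep) != H:
        raise ValueError("one keep budget per component required")
    if any(k < 1 or k > width for k in keep):
        raise ValueError(f"keep budgets must lie in [1, {width}]")
    return keep


def fit_canonical_pls(
    X,
    Y,
    n_components: int = 1,
    keep_x=None,
    keep_y=None,
    *,
    tol: float = 1e-10,
    max_iter: int = 2000,
) -> PLSFit:
    """Fit canonical-mode (sparse) PLS by alternating NIPALS updates.

    Per component: a ∝ soft_threshold(X'u), t = Xa; b ∝ soft_threshold(Y't),
    u = Yb, iterated until the loading change falls below ``tol``.  With
    full budgets the first loading pair equals the leading singular-vector
    pair of X'Y.  Canonical deflation removes each block's own score.  The
    sign convention fixes each x-loading's largest-magnitude entry positive.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("blocks must share the sample axis")
    if n_components < 1:
        raise ValueError("need at least one component")
    n, p = X.shape
    q = Y.shape[1]
    kx = _budgets(keep_x, p, n_components)
    ky = _budgets(keep_y, q, n_components)

    Xd, Yd = X.copy(), Y.copy()
    A = np.zeros((p, n_components))
    B = np.zeros((q, n_components))
    T = np.zeros((n, n_components))
    U = np.zeros((n, n_components))
    Cx = np.zeros((p, n_components))
    Cy = np.zeros((q, n_components))
    Dy = np.zeros((q, n_components))
    iters = []
    for h in range(n_components):
        u = Yd[:, np.argmax(Yd.var(axis=0))].copy()
        if not np.any(u):
            raise ValueError("degenerate (all-zero) block during deflation")
        a = np.zeros(p)
        b = np.zeros(q)
        it = 0
        for it in range(1, max_iter + 1):
            a_new = soft_threshold_keep(Xd.T @ u, kx[h])
            a_new /= np.linalg.norm(a_new)
            t = Xd @ a_new
            b_new = soft_threshold_keep(Yd.T @ t, ky[h])
            b_new /= np.linalg.norm(b_new)
            u = Yd @ b_new
            if max(np.max(np.abs(a_new - a)), np.max(np.abs(b_new - b))) < tol:
                a, b = a_new, b_new
                break
            a, b = a_new, b_new
        else:
            raise RuntimeError(f"component {h + 1} did not converge in {max_iter} iterations")
        iters.append(it)
        t = Xd @ a
        u = Yd @ b
        imax = np.argmax(np.abs(a))
        if a[imax] < 0:  # flip the pair together so cov(t, u) is unchanged
            a, b, t, u = -a, -b, -t, -u
        A[:, h], B[:, h], T[:, h], U[:, h] = a, b, t, u
        cx = Xd.T @ t / (t @ t)
        cy = Yd.T @ u / (u @ u)
        Dy[:, h] = Yd.T @ t / (t @ t)
        Cx[:, h], Cy[:, h] = cx, cy
        Xd = Xd - np.outer(t, cx)
        Yd = Yd - np.outer(u, cy)

    cov = np.einsum("ij,ij->j", T, U) / (n - 1)
    ssx = np.sum(X**2)
    ssy = np.sum(Y**2)
    tn = np.sum(T**2, axis=0)
    un = np.sum(U**2, axis=0)
    vex = np.sum((X.T @ T) ** 2, axis=0) / tn / ssx
    vey = np.sum((Y.T @ U) ** 2, axis=0) / un / ssy
    return PLSFit(
        n_components=n_components,
        loadings_x=A,
        loadings_y=B,
        scores_x=T,
        scores_y=U,
        covariances=cov,
        variance_explained_x=vex,
        variance_explained_y=vey,
        keep_x=kx,
        keep_y=ky,
        reg_x=Cx,
        reg_y=Cy,
        y_on_t=Dy,
        n_iter=tuple(iters),
    )


def variance_explained(fit: PLSFit, X, Y) -> pd.DataFrame:
    """Per-block, per-component proportion of (preprocessed) variance.

    For block X and component h this is the squared Frobenius norm of the
    rank-1 reconstruction from t_h divided by ||X||_F^2 (and u_h for Y);
    the ``pair`` column averages the two blocks.  Scores are mutually
    orthogonal within a block under canonical deflation, so the per-block
    proportions sum to at most 1.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != fit.scores_x.shape[0]:
        raise ValueError("fit and data have mismatched sample counts")
    tn = np.sum(fit.scores_x**2, axis=0)
    un = np.sum(fit.scores_y**2, axis=0)
    vx = np.sum((X.T @ fit.scores_x) ** 2, axis=0) / tn / np.sum(X**2)
    vy = np.sum((Y.T @ fit.scores_y) ** 2, axis=0) / un / np.sum(Y**2)
    return pd.DataFrame(
        {
            "component": np.arange(1, fit.n_components + 1),
            "x": vx,
            "y": vy,
            "pair": 0.5 * (vx + vy),
        }
    )


# ---------------------------------------------------------------------------
# Q^2 component selection


def _predict_fold(fit: PLSFit, x_new: np.ndarray, y_new: np.ndarray):
    """Walk a held-out sample through the fitted components.

    Yields, per component h, the pair (y residual entering h, predicted
    contribution of component h), following the train-set deflation chain.
    """
    xr = x_new.copy()
    yr = y_new.copy()
    for h in range(fit.n_components):
        t = xr @ fit.loadings_x[:, h]
        yhat = t * fit.y_on_t[:, h]
        yield yr.copy(), yhat
        u = yr @ fit.loadings_y[:, h]
        xr = xr - t * fit.reg_x[:, h]
        yr = yr - u * fit.reg_y[:, h]


def select_components_q2(
    X,
    Y,
    max_components: int = 3,
    keep_x=None,
    keep_y=None,
    *,
    q2_limit: float = Q2_LIMIT,
) -> tuple[int, pd.DataFrame]:
    """Choose the number of latent variate pairs by leave-one-out Q^2.

    For each component h: PRESS_h is the leave-one-out prediction error of
    the Y residual entering component h from the X score of component h;
    RSS_{h-1} is the full-fit residual sum of squares of Y after h-1
    components (RSS_0 = ||Y||^2).  Q^2_h = 1 - PRESS_h / RSS_{h-1};
    components are retained while Q^2_h >= ``q2_limit`` (0.0975, the
    conventional rule).  Returns (retained count, table).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = X.shape[0]
    if n < 10:
        raise ValueError("leave-one-out Q^2 needs at least 10 samples")
    H = min(max_components, X.shape[1], Y.shape[1], n - 2)

    full = fit_canonical_pls(X, Y, H, keep_x, keep_y)
    rss = [float(np.sum(Y**2))]
    Yd = Y.copy()
    for h in range(H):
        u = full.scores_y[:, h]
        Yd = Yd - np.outer(u, full.reg_y[:, h])
        rss.append(float(np.sum(Yd**2)))

    press = np.zeros(H)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[:] = True
        mask[i] = False
        try:
            f = fit_canonical_pls(X[mask], Y[mask], H, keep_x, keep_y)
        except (ValueError, RuntimeError):
            continue  # degenerate fold; its PRESS contribution is skipped
        for h, (yres, yhat) in enumerate(_predict_fold(f, X[i], Y[i])):
            press[h] += float(np.sum((yres - yhat) ** 2))

    q2 = 1.0 - press / np.array(rss[:-1])
    table = pd.DataFrame(
        {
            "component": np.arange(1, H + 1),
            "press": press,
            "rss_prev": rss[:-1],
            "q2": q2,
        }
    )
    retained = 0
    for h in range(H):
        if q2[h] >= q2_limit:
            retained += 1
        else:
            break
    return retained, table


def tune_sparsity(
    X,
    Y,
    grid_x=None,
    grid_y=None,
) -> tuple[int, int]:
    """Choose first-component keep budgets maximizing leave-one-out Q^2_1.

    Sequential search (budget for X with Y dense, then Y given X), over a
    grid defaulting to {5, 10, 15, ..., block width}.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    p, q = X.shape[1], Y.shape[1]
    if grid_x is None:
        grid_x = sorted(set(list(range(5, p, 5)) + [p]))
    if grid_y is None:
        grid_y = sorted(set(list(range(5, q, 5)) + [q]))

    def q2_of(kx, ky):
        _, tab = select_components_q2(X, Y, 1, keep_x=kx, keep_y=ky)
        return float(tab["q2"].iloc[0])

    best_kx = max(grid_x, key=lambda k: q2_of(k, q))
    best_ky = max(grid_y, key=lambda k: q2_of(best_kx, k))
    return int(best_kx), int(best_ky)


# ---------------------------------------------------------------------------
# permutation significance of the first latent covariance


@dataclass
class PermutationResult:
    """Permutation test of cov(t1, u1) against row-permuted Y."""

    observed_statistic: float
    B: int
    count_ge: int
    p_value: float
    seed: int | None

    def to_dict(self) -> dict:
        return {
            "observed_covariance": self.observed_statistic,
            "permutations": self.B,
            "count_ge": self.count_ge,
            "p_value": self.p_value,
            "seed": self.seed,
        }


def permutation_test_covariance(
    X,
    Y,
    B: int = 9999,
    seed: int | None = None,
    keep_x=None,
    keep_y=None,
) -> PermutationResult:
    """One-sided permutation p for the first latent-variate covariance.

    The observed statistic is cov(t1, u1); each of the B permutations
    shuffles the rows of the (already residualized) Y block and refits the
    first component with the same sparsity budgets.  p = (count_ge + 1) /
    (B + 1), the add-one estimator, so p >= 1/(B + 1).
    """
    if B < 1:
        raise ValueError("need at least one permutation")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    rng = np.random.default_rng(seed)
    kx = None if keep_x is None else (np.atleast_1d(keep_x)[0],)
    ky = None if keep_y is None else (np.atleast_1d(keep_y)[0],)
    obs = float(fit_canonical_pls(X, Y, 1, kx, ky).covariances[0])
    count = 0
    for _ in range(B):
        perm = rng.permutation(Y.shape[0])
        try:
            stat = float(fit_canonical_pls(X, Y[perm], 1, kx, ky).covariances[0])
        except (ValueError, RuntimeError):
            continue  # degenerate permutation counts as non-exceeding
        if stat >= obs:
            count += 1
    p = (count + 1) / (B + 1)
    return PermutationResult(obs, B, count, p, seed)


# ---------------------------------------------------------------------------
# relevance networks


@dataclass
class RelevanceNetwork:
    """Bipartite association graph between two metabolomes."""

    graph: nx.Graph
    similarity: pd.DataFrame  # p x q
    threshold: float

    @property
    def edges(self) -> pd.DataFrame:
        rows = [
            {
                "node_x": a if self.graph.nodes[a]["block"] == "x" else b,
                "node_y": b if self.graph.nodes[a]["block"] == "x" else a,
                "similarity": d["similarity"],
                "sign": d["sign"],
            }
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["node_x", "node_y", "similarity", "sign"])

    def write_edge_tsv(self, path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


def relevance_network(
    fit: PLSFit,
    X,
    Y,
    threshold: float = 0.5,
    x_names=None,
    y_names=None,
    x_block: str = "X",
    y_block: str = "Y",
) -> RelevanceNetwork:
    """Bipartite relevance network from the retained latent variates.

    The similarity between variable x_i and y_j is
    s_ij = sum_h corr(x_i, z_h) * corr(y_j, z_h) with the shared reference
    variate z_h = (t_h + u_h) / 2.  Edges connect only variables from
    different blocks and require |s_ij| >= ``threshold``; the edge sign is
    the sign of s_ij (positive/negative association).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n, p = X.shape
    q = Y.shape[1]
    x_names = list(x_names) if x_names is not None else [f"x{i}" for i in range(p)]
    y_names = list(y_names) if y_names is not None else [f"y{j}" for j in range(q)]

    Z = 0.5 * (fit.scores_x + fit.scores_y)

    def col_corr(M, z):
        Mc = M - M.mean(axis=0)
        zc = z - z.mean()
        denom = np.sqrt(np.sum(Mc**2, axis=0) * np.sum(zc**2))
        with np.errstate(invalid="ignore", divide="ignore"):
            return (Mc.T @ zc) / denom

    S = np.zeros((p, q))
    for h in range(fit.n_components):
        cx = col_corr(X, Z[:, h])
        cy = col_corr(Y, Z[:, h])
        S += np.outer(cx, cy)
    sim = pd.DataFrame(S, index=x_names, columns=y_names)

    g = nx.Graph()
    for name in x_names:
        g.add_node(f"{x_block}:{name}", block="x", compartment=x_block, label=name)
    for name in y_names:
        g.add_node(f"{y_block}:{name}", block="y", compartment=y_block, label=name)
    ii, jj = np.where(np.abs(S) >= threshold)
    for i, j in zip(ii, jj):
        g.add_edge(
            f"{x_block}:{x_names[i]}",
            f"{y_block}:{y_names[j]}",
            similarity=float(S[i, j]),
            sign=int(np.sign(S[i, j])),
        )
    return RelevanceNetwork(g, sim, threshold)
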