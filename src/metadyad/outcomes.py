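"""Multinomial logistic models of neurodevelopmental outcome.

The three-level outcome (TD reference, ASD, non-TD) is modelled with
multinomial logistic regression on latent-variate scores or single
metabolite concentrations, with covariate adjustment.  Exponentiated
coefficients are reported as relative risks (RR) with 95% Wald intervals —
strictly they are relative risk *ratios* of the multinomial logit, the
conventional label in this literature is kept.  Uncertainty in predicted
probability curves is propagated by simulating coefficient vectors from
the asymptotic normal sampling distribution and averaging predictions over
the observed covariate values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import DyadCohort, OUTCOME_CLASSES


@dataclass
class MultinomialModel:
    """Fitted multinomial logit with a designated reference class."""

    classes: tuple[str, ...]  # reference first
    reference: str
    terms: tuple[str, ...]  # const + predictor names
    coef: pd.DataFrame  # non-reference classes x terms
    se: pd.DataFrame
    p_values: pd.DataFrame
    rr: pd.DataFrame  # exp(coef), slopes only meaningful
    rr_lo: pd.DataFrame
    rr_hi: pd.DataFrame
    cov: np.ndarray  # covariance of vec(coef) in class-major order
    llf: float
    converged: bool
    separation: bool
    n_used: int
    exog_names: tuple[str, ...] = field(default=())

    @property
    def non_reference(self) -> tuple[str, ...]:
        return self.classes[1:]

    def linear_predictor(self, exog: np.ndarray, coef_matrix: np.ndarray) -> np.ndarray:
        """Class probabilities for an exog matrix and coefficient matrix."""
        eta = np.zeros((exog.shape[0], len(self.classes)))
        eta[:, 1:] = exog @ coef_matrix.T
        eta -= eta.max(axis=1, keepdims=True)
        prob = np.exp(eta)
        prob /= prob.sum(axis=1, keepdims=True)
        return prob


def fit_multinomial(
    outcome,
    predictors: pd.DataFrame,
    reference: str = "TD",
    *,
    maxiter: int = 200,
) -> MultinomialModel:
    """Maximum-likelihood multinomial logit, Newton iterations.

    ``outcome`` holds class labels; rows with a missing label or predictor
    are dropped.  The covariance comes from the inverse observed
    information.  Quasi-complete separation is flagged (any fitted
    probability above 1 - 1e-8) rather than silently regularized.
    """
    y = pd.Series(outcome).reset_index(drop=True)
    X = pd.DataFrame(predictors).reset_index(drop=True)
    ok = y.notna() & X.notna().all(axis=1)
    y, X = y[ok], X.loc[ok]
    n_used = int(ok.sum())
    observed = [c for c in y.unique()]
    if reference not in observed:
        raise ValueError(f"reference class {reference!r} not observed")
    if len(observed) < 2:
        raise ValueError("outcome must have at least two observed classes")
    if (X.std(ddof=1) == 0).any():
        bad = X.columns[X.std(ddof=1) == 0].tolist()
        raise ValueError(f"constant predictor columns: {bad}")

    # reference first, remaining classes in canonical outcome order
    canonical = [c for c in OUTCOME_CLASSES if c in observed and c != reference]
    extra = sorted(c for c in observed if c not in OUTCOME_CLASSES and c != reference)
    classes = (reference, *canonical, *extra)
    codes = y.map({c: i for i, c in enumerate(classes)}).to_numpy()

    exog = sm.add_constant(X.astype(float), has_constant="add")
    model = sm.MNLogit(codes, exog)
    try:
        res = model.fit(method="newton", maxiter=maxiter, disp=0)
        converged = bool(res.mle_retvals.get("converged", True))
    except np.linalg.LinAlgError as exc:
        raise RuntimeError(f"multinomial fit failed: {exc}") from exc

    terms = tuple(exog.columns)
    params = np.asarray(res.params)  # (k, J-1), columns follow classes[1:]
    coef = pd.DataFrame(params.T, index=list(classes[1:]), columns=terms)
    se = pd.DataFrame(np.asarray(res.bse).T, index=list(classes[1:]), columns=terms)
    pvals = pd.DataFrame(
        np.asarray(res.pvalues).T, index=list(classes[1:]), columns=terms
    )
    z = 1.959963984540054
    with np.errstate(over="ignore"):  # separation can push RRs to inf
        rr = np.exp(coef)
        rr_lo = np.exp(coef - z * se)
        rr_hi = np.exp(coef + z * se)

    fitted = res.predict()
    separation = bool(np.max(fitted) > 1 - 1e-8)

    return MultinomialModel(
        classes=classes,
        reference=reference,
        terms=terms,
        coef=coef,
        se=se,
        p_values=pvals,
        rr=rr,
        rr_lo=rr_lo,
        rr_hi=rr_hi,
        cov=np.asarray(res.cov_params()),
        llf=float(res.llf),
        converged=converged,
        separation=separation,
        n_used=n_used,
        exog_names=terms,
    )


@dataclass
class ProbabilityCurve:
    """Simulated outcome probabilities along a predictor grid."""

    predictor: str
    grid: np.ndarray
    classes: tuple[str, ...]
    mean: pd.DataFrame  # grid x classes
    lower: pd.DataFrame
    upper: pd.DataFrame
    n_draws: int
    seed: int | None
    averaging: str = "observed-value"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cls in self.classes:
            for gi, g in enumerate(self.grid):
                rows.append(
                    {
                        "predictor": self.predictor,
                        "grid": g,
                        "class": cls,
                        "mean": self.mean.iloc[gi][cls],
                        "lower": self.lower.iloc[gi][cls],
                        "upper": self.upper.iloc[gi][cls],
                    }
                )
        return pd.DataFrame(rows)


def simulate_probability_curves(
    model: MultinomialModel,
    predictor: str,
    grid,
    data: pd.DataFrame,
    n_draws: int = 1000,
    seed: int | None = None,
) -> ProbabilityCurve:
    """Estimated probabilities with simulation-based 95% intervals.

    Coefficient vectors are drawn from N(estimate, covariance); for each
    draw and grid value the predictor column is set to the grid value for
    every observed covariate row (observed-value averaging) and the mean
    softmax probabilities are recorded.  Intervals are the 2.5/97.5
    percentiles over draws.
    """
    if not model.converged:
        raise ValueError("cannot simulate from a non-converged model")
    if predictor not in model.terms:
        raise KeyError(f"{predictor!r} is not a model term")
    grid = np.asarray(grid, dtype=float)
    slope_terms = [t for t in model.terms if t != "const"]
    X = data[slope_terms].dropna().astype(float)
    exog = np.column_stack([np.ones(len(X)), X.to_numpy()])
    pred_col = model.terms.index(predictor)

    mean_vec = model.coef.to_numpy().ravel()  # class-major
    cov = np.asarray(model.cov, dtype=float)
    if cov.shape != (mean_vec.size, mean_vec.size):
        raise ValueError("covariance dimension does not match coefficients")
    eigmin = np.linalg.eigvalsh((cov + cov.T) / 2).min()
    if eigmin < -1e-10:
        raise np.linalg.LinAlgError("coefficient covariance is not positive semidefinite")

    rng = np.random.default_rng(seed)
    if np.allclose(cov, 0):
        draws = np.tile(mean_vec, (n_draws, 1))
    else:
        draws = rng.multivariate_normal(mean_vec, cov, size=n_draws, method="svd")

    J1 = len(model.classes) - 1
    k = len(model.terms)
    out = np.empty((n_draws, grid.size, len(model.classes)))
    ex = exog.copy()
    for d in range(n_draws):
        # statsmodels covariance is ordered equation-by-equation (class-major)
        cm = draws[d].reshape(J1, k)
        for gi, g in enumerate(grid):
            ex[:, pred_col] = g
            out[d, gi] = model.linear_predictor(ex, cm).mean(axis=0)

    mean = out.mean(axis=0)
    lo = np.percentile(out, 2.5, axis=0)
    hi = np.percentile(out, 97.5, axis=0)
    cols = list(model.classes)
    return ProbabilityCurve(
        predictor=predictor,
        grid=grid,
        classes=model.classes,
        mean=pd.DataFrame(mean, columns=cols),
        lower=pd.DataFrame(lo, columns=cols),
        upper=pd.DataFrame(hi, columns=cols),
        n_draws=n_draws,
        seed=seed,
    )


def _transform_predictor(values: pd.Series, transform: str) -> pd.Series:
    if transform == "log_z":
        x = np.log(values.where(values > 0))
        return (x - x.mean()) / x.std(ddof=1)
    if transform == "z":
        return (values - values.mean()) / values.std(ddof=1)
    if transform == "raw":
        return values
    raise ValueError("transform must be log_z, z or raw")


def metabolite_outcome_screen(
    cohort: DyadCohort,
    metabolite: str | dict[str, str],
    covariate_sets: dict[str, list[str]],
    *,
    reference: str = "TD",
    transform: str = "log_z",
) -> pd.DataFrame:
    """Unadjusted and adjusted outcome models for one metabolite per tissue.

    ``metabolite`` is either one name looked up in every compartment or a
    mapping compartment -> name.  ``covariate_sets`` maps a model label
    (e.g. "unadjusted", "adjusted") to covariate name lists.  Returns one
    row per tissue x model x contrast with RR, 95% CI and p.
    """
    rows = []
    for comp, matrix in sorted(cohort.matrices.items()):
        name = metabolite.get(comp) if isinstance(metabolite, dict) else metabolite
        if name is None:
            continue
        if name not in matrix.values.columns:
            raise KeyError(f"metabolite {name!r} absent from {comp}")
        raw = matrix.values[name]
        if raw.dropna().nunique() <= 1:
            raise ValueError(f"metabolite {name!r} is constant in {comp}")
        pred = _transform_predictor(raw, transform).rename(name)
        for label, cov_names in covariate_sets.items():
            frame = pd.DataFrame({name: pred})
            if cov_names:
                if cohort.covariates is None:
                    raise ValueError("covariate set given without covariates")
                frame = pd.concat(
                    [frame, cohort.covariates[list(cov_names)].astype(float)], axis=1
                )
            model = fit_multinomial(cohort.outcome, frame, reference=reference)
            for cls in model.non_reference:
                rows.append(
                    {
                        "tissue": comp,
                        "metabolite": name,
                        "model": label,
                        "contrast": f"{cls} vs {reference}",
                        "rr": model.rr.loc[cls, name],
                        "ci_lower": model.rr_lo.loc[cls, name],
                        "ci_upper": model.rr_hi.loc[cls, name],
                        "p_value": model.p_values.loc[cls, name],
                        "n_used": model.n_used,
                        "converged": model.converged,
                        "separation": model.separation,
                    }
                )
    return pd.DataFrame(rows)
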