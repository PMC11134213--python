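"""Synthetic mother-infant dyad cohorts with known latent structure.

The generator emulates the statistical assumptions the analysis pipeline
makes about quantitative NMR metabolomics of the maternal-placental-fetal
unit: log-normal concentrations, block-shared latent factors linking
compartments (by default a single placenta <-> cord-serum factor and no
maternal sharing), within-compartment latent factors producing the dense
within-tissue correlation real metabolite panels show, covariate
confounding on the log scale, and a three-class neurodevelopmental outcome
(TD reference, ASD, non-TD) drawn from a multinomial logit whose linear
predictor uses the latent factor scores and covariates.

Everything planted is returned as :class:`GroundTruth` so that recovery
tests can score the pipeline against the generating mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import json
import numpy as np
import pandas as pd

from .cohort import COMPARTMENTS, ConcentrationMatrix, DyadCohort, OUTCOME_CLASSES

#: covariate columns the generator produces, mirroring the dyad covariate model
BINARY_COVARIATES = (
    "maternal_education",
    "race_ethnicity",
    "home_ownership",
    "prenatal_vitamin_month1",
    "fetal_sex",
    "delivery_mode",
    "metabolic_condition",
)


def _pair_key(a: str, b: str) -> tuple[str, str]:
    ia, ib = COMPARTMENTS.index(a), COMPARTMENTS.index(b)
    return (a, b) if ia <= ib else (b, a)


@dataclass
class SyntheticCohortConfig:
    """Generating conditions for a synthetic dyad cohort.

    Defaults follow the cohort the pipeline is designed for: 107 dyads with
    complete fully-adjusted covariates, metabolite panels of 48 (maternal
    serum), 54 (placenta) and 44 (cord serum), one shared placenta-cord
    factor and no maternal sharing, and outcome base rates 57/30/13%
    (TD/ASD/non-TD).  Factor and noise scales are on the natural-log
    concentration scale.
    """

    n_dyads: int = 107
    p_per_block: Mapping[str, int] = field(
        default_factory=lambda: {"maternal_serum": 48, "placenta": 54, "cord_serum": 44}
    )
    n_shared_factors: Mapping[tuple[str, str], int] = field(
        default_factory=lambda: {
            ("maternal_serum", "placenta"): 0,
            ("maternal_serum", "cord_serum"): 0,
            ("placenta", "cord_serum"): 1,
        }
    )
    n_within_factors: Mapping[str, int] = field(
        default_factory=lambda: {c: 2 for c in COMPARTMENTS}
    )
    loading_sparsity: float = 0.3
    factor_strength: float = 1.0
    within_factor_strength: float = 0.6
    noise_sd: float = 0.5
    #: per-covariate scale of N(0, sd) metabolite effects on the log scale
    covariate_effect_sd: Mapping[str, float] = field(
        default_factory=lambda: {
            "gestational_age_at_delivery": 0.15,
            "metabolic_condition": 0.15,
            "fetal_sex": 0.10,
        }
    )
    covariate_effect_sparsity: float = 0.5
    #: per-class coefficients on factor scores (keys are factor names)
    outcome_coefficients: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "ASD": {},
            "nonTD": {"shared:placenta~cord_serum:0": -2.0},
        }
    )
    outcome_base_probs: tuple[float, float, float] = (0.57, 0.30, 0.13)
    log_intercept_mean: float = np.log(100.0)
    log_intercept_sd: float = 1.0
    #: fraction of each metabolite's lowest values censored as non-detected;
    #: 0 mirrors targeted-profiling output, where every fitted compound gets
    #: a concentration — raise it to exercise missing-data handling
    censor_frac: float = 0.0
    #: number of metabolites per block with heavy censoring (for filter tests)
    low_detection_metabolites: Mapping[str, int] = field(default_factory=dict)
    low_detection_frac: float = 0.5
    missing_covariate_dyads: int = 0
    missing_outcome_dyads: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.n_dyads < 10:
            raise ValueError("n_dyads must be at least 10")
        if any(p < 2 for p in self.p_per_block.values()):
            raise ValueError("each block needs at least 2 metabolites")
        if not 0 <= self.loading_sparsity < 1:
            raise ValueError("loading_sparsity must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not np.isclose(sum(self.outcome_base_probs), 1.0):
            raise ValueError("outcome_base_probs must sum to 1")


@dataclass
class GroundTruth:
    """Everything the generator planted, for recovery scoring."""

    factor_scores: pd.DataFrame  # dyads x factors
    loadings: dict[str, pd.DataFrame]  # block -> metabolites x factors
    covariate_effects: dict[str, pd.DataFrame]  # block -> covariates x metabolites
    outcome_coefficients: dict[str, dict[str, float]]
    outcome_base_probs: tuple[float, float, float]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "factor_scores": self.factor_scores.to_dict(orient="index"),
            "loadings": {b: df.to_dict(orient="index") for b, df in self.loadings.items()},
            "covariate_effects": {
                b: df.to_dict(orient="index") for b, df in self.covariate_effects.items()
            },
            "outcome_coefficients": {
                c: dict(v) for c, v in self.outcome_coefficients.items()
            },
            "outcome_base_probs": list(self.outcome_base_probs),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _simulate_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Covariate table matching the dyad covariate model.

    Two kinds of continuous covariates (an ordinal calendar year over six
    levels and gestational ages in days, sd 10) plus Bernoulli(0.5)
    binaries for the dichotomized social and clinical covariates.
    """
    cov = pd.DataFrame(index=pd.RangeIndex(n))
    cov["birth_year"] = rng.integers(2009, 2015, size=n)
    cov["gestational_age_at_collection"] = np.round(rng.normal(236.0, 10.0, size=n), 1)
    cov["gestational_age_at_delivery"] = np.round(rng.normal(273.0, 10.0, size=n), 1)
    cov["fasting_time"] = np.round(rng.gamma(shape=2.5, scale=35.0, size=n), 1)
    for name in BINARY_COVARIATES:
        cov[name] = rng.integers(0, 2, size=n)
    return cov


def _standardize(col: pd.Series) -> np.ndarray:
    x = col.to_numpy(dtype=float)
    sd = x.std(ddof=1)
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def generate_cohort(
    config: SyntheticCohortConfig | None = None, seed: int | None = None
) -> tuple[DyadCohort, GroundTruth]:
    """Draw one cohort; bit-reproducible from ``config.seed`` (or ``seed``)."""
    config = config or SyntheticCohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_dyads
    blocks = list(config.p_per_block)
    for b in blocks:
        if b not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {b!r}")

    dyad_ids = [f"D{i + 1:04d}" for i in range(n)]
    mother_ids = [f"M{i + 1:04d}" for i in range(n)]
    covariates = _simulate_covariates(n, rng)
    covariates.index = pd.Index(dyad_ids, name="dyad_id")

    # latent factors: shared across block pairs, then within-block
    factor_names: list[str] = []
    factor_blocks: dict[str, list[str]] = {}
    for (a, b), k in sorted(config.n_shared_factors.items(), key=lambda kv: kv[0]):
        a, b = _pair_key(a, b)
        for j in range(k):
            name = f"shared:{a}~{b}:{j}"
            factor_names.append(name)
            factor_blocks[name] = [a, b]
    for blk in blocks:
        for j in range(int(config.n_within_factors.get(blk, 0))):
            name = f"within:{blk}:{j}"
            factor_names.append(name)
            factor_blocks[name] = [blk]
    scores = pd.DataFrame(
        rng.standard_normal((n, len(factor_names))),
        index=dyad_ids,
        columns=factor_names,
    )

    # standardized covariate design used for confounding effects
    cov_std = {c: _standardize(covariates[c]) for c in config.covariate_effect_sd}

    matrices: dict[str, ConcentrationMatrix] = {}
    loadings: dict[str, pd.DataFrame] = {}
    cov_effects: dict[str, pd.DataFrame] = {}
    for blk in blocks:
        p = int(config.p_per_block[blk])
        mets = [f"{blk[:3]}_met{j + 1:02d}" for j in range(p)]
        L = pd.DataFrame(0.0, index=mets, columns=factor_names)
        for name in factor_names:
            strength = (
                config.factor_strength
                if name.startswith("shared:")
                else config.within_factor_strength
            )
            if blk in factor_blocks[name]:
                lam = rng.standard_normal(p) * strength
                lam[rng.random(p) < config.loading_sparsity] = 0.0
                L[name] = lam
        E = pd.DataFrame(0.0, index=list(config.covariate_effect_sd), columns=mets)
        for cname, sd in config.covariate_effect_sd.items():
            eff = rng.standard_normal(p) * sd
            eff[rng.random(p) < config.covariate_effect_sparsity] = 0.0
            E.loc[cname] = eff
        intercepts = rng.normal(config.log_intercept_mean, config.log_intercept_sd, p)
        logC = (
            intercepts
            + scores.to_numpy() @ L.to_numpy().T
            + rng.normal(0.0, config.noise_sd, (n, p))
        )
        if len(E.index):
            logC = logC + np.column_stack([cov_std[c] for c in E.index]) @ E.to_numpy()
        values = pd.DataFrame(np.exp(logC), index=dyad_ids, columns=mets)
        values.index.name = "dyad_id"

        # left-censoring below the detection limit
        n_low = int(config.low_detection_metabolites.get(blk, 0))
        low_cols = list(rng.choice(p, size=n_low, replace=False)) if n_low else []
        for j, met in enumerate(mets):
            frac = config.low_detection_frac if j in low_cols else config.censor_frac
            if frac <= 0:
                continue
            lod = np.quantile(values[met], frac)
            values.loc[values[met] < lod, met] = np.nan
        matrices[blk] = ConcentrationMatrix(blk, values)
        loadings[blk] = L
        cov_effects[blk] = E

    # outcome from a multinomial logit, TD as reference class
    base = np.asarray(config.outcome_base_probs, dtype=float)
    eta = np.zeros((n, 3))
    eta[:, 1] = np.log(base[1] / base[0])
    eta[:, 2] = np.log(base[2] / base[0])
    for ci, cls in enumerate(OUTCOME_CLASSES[1:], start=1):
        for key, coef in config.outcome_coefficients.get(cls, {}).items():
            if key in scores.columns:
                eta[:, ci] += coef * scores[key].to_numpy()
            elif key in covariates.columns:
                eta[:, ci] += coef * _standardize(covariates[key])
            elif key.startswith(("shared:", "within:")):
                continue  # factor removed by the config (e.g. a null cohort)
            else:
                raise KeyError(f"outcome coefficient on unknown term {key!r}")
    prob = np.exp(eta - eta.max(axis=1, keepdims=True))
    prob /= prob.sum(axis=1, keepdims=True)
    draws = rng.random(n)
    cum = prob.cumsum(axis=1)
    codes = (draws[:, None] > cum).sum(axis=1)
    outcome = pd.Series(
        [OUTCOME_CLASSES[c] for c in codes], index=dyad_ids, name="outcome", dtype=object
    )

    if config.missing_outcome_dyads:
        idx = rng.choice(n, size=config.missing_outcome_dyads, replace=False)
        outcome.iloc[idx] = np.nan
    if config.missing_covariate_dyads:
        idx = rng.choice(n, size=config.missing_covariate_dyads, replace=False)
        covariates.iloc[idx, covariates.columns.get_loc("metabolic_condition")] = np.nan

    cohort = DyadCohort(
        dyad_ids=dyad_ids,
        mother_ids=mother_ids,
        matrices=matrices,
        covariates=covariates,
        outcome=outcome,
        manifest={"generator": "synthetic", "seed": int(config.seed if seed is None else seed)},
    )
    truth = GroundTruth(
        factor_scores=scores,
        loadings=loadings,
        covariate_effects=cov_effects,
        outcome_coefficients={c: dict(v) for c, v in config.outcome_coefficients.items()},
        outcome_base_probs=tuple(config.outcome_base_probs),
    )
    return cohort, truth


def generate_null_cohort(
    config: SyntheticCohortConfig | None = None, seed: int | None = None
) -> DyadCohort:
    """As :func:`generate_cohort` with every shared factor removed.

    Blocks are then mutually independent given covariates; outcome effects
    tied to shared factors are dropped with them.
    """
    config = config or SyntheticCohortConfig()
    null_shared = {k: 0 for k in config.n_shared_factors}
    out_coef = {
        cls: {k: v for k, v in terms.items() if not k.startswith("shared:")}
        for cls, terms in config.outcome_coefficients.items()
    }
    null_cfg = replace(
        config, n_shared_factors=null_shared, outcome_coefficients=out_coef
    )
    cohort, _ = generate_cohort(null_cfg, seed=seed)
    return cohort


def write_cohort(
    cohort: DyadCohort, truth: GroundTruth | None, out_dir: str | Path
) -> None:
    """Emit the CSV formats the readers consume, plus ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for comp, m in cohort.matrices.items():
        m.values.to_csv(out / f"{comp}.csv", na_rep="")
    if cohort.covariates is not None:
        cohort.covariates.to_csv(out / "covariates.csv")
    if cohort.outcome is not None:
        cohort.outcome.to_csv(out / "outcome.csv")
    cohort.write_manifest(out / "manifest.json")
    if truth is not None:
        truth.to_json(out / "ground_truth.json")
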