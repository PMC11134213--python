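"""Configuration-driven orchestration of the full integration analysis.

Stage order mirrors the analysis design: detection filter -> dyad pairing
-> bipartite Spearman screens -> covariate-adjusted rank-regression
screens (model 1 minimal, model 2 fully adjusted) -> and, only for block
pairs where a screen found at least one q < 0.10 association, the
multivariate stage: partial out model-2 covariates, center/scale,
(sparse) canonical PLS, Q^2 component selection, permutation test of the
first latent covariance, relevance network, and multinomial outcome
models on the latent-variate scores.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    ConcentrationMatrix,
    DyadCohort,
    filter_detection,
    pair_dyads,
    read_concentration_table,
)
from .outcomes import fit_multinomial, metabolite_outcome_screen
from .pls import (
    center_scale,
    covariate_design,
    fit_canonical_pls,
    permutation_test_covariance,
    relevance_network,
    residualize,
    select_components_q2,
    tune_sparsity,
    variance_explained,
)
from .rankreg import adjusted_pairwise_screen
from .screen import spearman_screen, write_screen_tsv
from .simulate import SyntheticCohortConfig, generate_cohort

log = logging.getLogger("metadyad.pipeline")

DEFAULT_MODEL1 = ["birth_year", "gestational_age_at_delivery"]
DEFAULT_MODEL2 = DEFAULT_MODEL1 + [
    "fetal_sex",
    "maternal_education",
    "race_ethnicity",
    "home_ownership",
    "prenatal_vitamin_month1",
    "metabolic_condition",
]


@dataclass
class PipelineConfig:
    """Everything one run needs; loadable from YAML."""

    output_dir: str = "metadyad_run"
    seed: int = 0
    synthetic: dict | None = None  # overrides for SyntheticCohortConfig
    inputs: dict | None = None  # paths: matrices {comp: path}, covariates, outcome
    pairs: list[tuple[str, str]] = field(
        default_factory=lambda: [
            ("maternal_serum", "placenta"),
            ("maternal_serum", "cord_serum"),
            ("placenta", "cord_serum"),
        ]
    )
    covariate_sets: dict[str, list[str]] = field(
        default_factory=lambda: {"model1": list(DEFAULT_MODEL1), "model2": list(DEFAULT_MODEL2)}
    )
    fdr_level: float = 0.10
    detection_min_frac: float = 0.8
    exclusion_list: list[str] = field(default_factory=list)
    # scale for the rank-regression screens; log by default because raw
    # lognormal concentrations put extreme leverage on the Wald reference
    screen_scale: str = "log"
    pls_max_components: int = 3
    pls_permutations: int = 9999
    pls_sparsity: str = "auto"  # auto: sparse iff n < p + q
    pls_tol: float = 1e-10
    network_threshold: float = 0.5
    outcome_metabolite: str | dict | None = None
    outcome_reference: str = "TD"
    run_outcome_models: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.fdr_level < 1:
            raise ValueError("fdr_level must lie in (0, 1)")
        if self.pls_permutations < 1:
            raise ValueError("need at least one permutation")
        if not self.pairs:
            raise ValueError("at least one compartment pair required")
        self.pairs = [tuple(p) for p in self.pairs]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)


def _stage_seeds(master: int, n: int = 16) -> list[int]:
    """Independent child seeds (< 2^31) derived from the master seed."""
    state = np.random.SeedSequence(master).generate_state(n, dtype=np.uint32)
    return [int(s & 0x7FFFFFFF) for s in state]


def _load_cohort(config: PipelineConfig, gen_seed: int) -> DyadCohort:
    if config.synthetic is not None or config.inputs is None:
        overrides = dict(config.synthetic or {})
        overrides.setdefault("seed", gen_seed)
        if "n_shared_factors" in overrides:
            overrides["n_shared_factors"] = {
                tuple(k.split("~")) if isinstance(k, str) else tuple(k): v
                for k, v in overrides["n_shared_factors"].items()
            }
        cfg = SyntheticCohortConfig(**overrides)
        cohort, _ = generate_cohort(cfg)
        return cohort
    paths = config.inputs
    matrices = {
        comp: read_concentration_table(path, comp)
        for comp, path in paths["matrices"].items()
    }
    covariates = pd.read_csv(paths["covariates"], index_col=0) if "covariates" in paths else None
    outcome = None
    if "outcome" in paths:
        outcome = pd.read_csv(paths["outcome"], index_col=0).iloc[:, 0]
    if "registry" in paths:
        registry = pd.read_csv(paths["registry"])
        required = set()
        for a, b in config.pairs:
            required |= {a, b}
        return pair_dyads(matrices, registry, required, covariates, outcome)
    dyads = list(next(iter(matrices.values())).values.index)
    return DyadCohort(
        dyad_ids=dyads,
        mother_ids=[f"M_{d}" for d in dyads],
        matrices=matrices,
        covariates=covariates,
        outcome=outcome,
    )


def _log_block(matrix: ConcentrationMatrix) -> pd.DataFrame:
    """Natural-log concentrations; zeros become missing."""
    vals = matrix.values.where(matrix.values > 0)
    return np.log(vals)


def _pls_stage(
    cohort: DyadCohort,
    pair: tuple[str, str],
    config: PipelineConfig,
    perm_seed: int,
    out_dir: Path,
) -> dict[str, Any]:
    a, b = pair
    model2 = config.covariate_sets.get("model2", [])
    logx = _log_block(cohort.matrices[a])
    logy = _log_block(cohort.matrices[b])
    cov = cohort.covariates[model2] if model2 else pd.DataFrame(index=logx.index)
    ok = logx.notna().all(axis=1) & logy.notna().all(axis=1) & cov.notna().all(axis=1)
    keep = ok[ok].index
    Xl, Yl = logx.loc[keep], logy.loc[keep]
    n, p, q = len(keep), Xl.shape[1], Yl.shape[1]
    if n < 10:
        return {"skipped": True, "reason": "fewer than 10 complete dyads"}

    if model2:
        design = covariate_design(cohort.covariates.loc[keep], model2)
        Xr = residualize(Xl.to_numpy(), design)
        Yr = residualize(Yl.to_numpy(), design)
    else:
        Xr, Yr = Xl.to_numpy(), Yl.to_numpy()
    Xs, Ys = center_scale(Xr), center_scale(Yr)

    sparse = config.pls_sparsity == "sparse" or (
        config.pls_sparsity == "auto" and n < p + q
    )
    keep_x = keep_y = None
    if sparse:
        kx, ky = tune_sparsity(Xs, Ys)
        keep_x, keep_y = kx, ky
        log.info("pair %s-%s: sparse PLS, tuned keep=(%d, %d)", a, b, kx, ky)

    retained, q2_table = select_components_q2(
        Xs, Ys, config.pls_max_components, keep_x=keep_x, keep_y=keep_y
    )
    n_comp = max(retained, 1)  # always examine the first latent pair
    fit = fit_canonical_pls(
        Xs,
        Ys,
        n_comp,
        keep_x=None if keep_x is None else (keep_x,) * n_comp,
        keep_y=None if keep_y is None else (keep_y,) * n_comp,
        tol=config.pls_tol,
    )
    ve = variance_explained(fit, Xs, Ys)
    perm = permutation_test_covariance(
        Xs, Ys, B=config.pls_permutations, seed=perm_seed, keep_x=keep_x, keep_y=keep_y
    )
    q2_table.to_csv(out_dir / "q2.tsv", sep="\t", index=False)
    ve.to_csv(out_dir / "variance_explained.tsv", sep="\t", index=False)

    significant = perm.p_value < 0.05
    network_info = None
    if significant and retained >= 1:
        net = relevance_network(
            fit,
            Xs,
            Ys,
            threshold=config.network_threshold,
            x_names=list(Xl.columns),
            y_names=list(Yl.columns),
            x_block=a,
            y_block=b,
        )
        net.write_edge_tsv(out_dir / "relevance_edges.tsv")
        net.write_graphml(out_dir / "relevance_network.graphml")
        network_info = {
            "n_edges": int(net.graph.number_of_edges()),
            "threshold": config.network_threshold,
        }

    outcome_info = {}
    if config.run_outcome_models and cohort.outcome is not None:
        scores = {
            f"{a}_variate1": fit.scores_x[:, 0],
            f"{b}_variate1": fit.scores_y[:, 0],
        }
        for label, vec in scores.items():
            z = (vec - vec.mean()) / vec.std(ddof=1)
            frame = pd.DataFrame({label: z}, index=keep)
            if model2:
                frame = pd.concat(
                    [frame, cohort.covariates.loc[keep, model2].astype(float)], axis=1
                )
            try:
                m = fit_multinomial(
                    cohort.outcome.loc[keep], frame, reference=config.outcome_reference
                )
                outcome_info[label] = {
                    cls: {
                        "rr": float(m.rr.loc[cls, label]),
                        "ci": [
                            float(m.rr_lo.loc[cls, label]),
                            float(m.rr_hi.loc[cls, label]),
                        ],
                        "p": float(m.p_values.loc[cls, label]),
                    }
                    for cls in m.non_reference
                }
                outcome_info[label]["n_used"] = m.n_used
                outcome_info[label]["converged"] = m.converged
            except (ValueError, RuntimeError) as exc:
                outcome_info[label] = {"error": str(exc)}

    summary = {
        "skipped": False,
        "n_dyads": n,
        "sparse": sparse,
        "keep_x": keep_x,
        "keep_y": keep_y,
        "retained_components": retained,
        "q2": [round(float(v), 10) for v in q2_table["q2"]],
        "first_pair_covariance": round(float(fit.covariances[0]), 10),
        "variance_explained_first_pair": round(float(ve["pair"].iloc[0]), 10),
        "permutation": perm.to_dict(),
        "significant": bool(significant),
        "network": network_info,
        "outcome_models": outcome_info,
    }
    return summary


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the full analysis; returns (and writes) the run summary."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    t0 = time.time()
    seeds = _stage_seeds(config.seed)
    log.info("metadyad %s, master seed %d, stage seeds %s", __version__, config.seed, seeds)

    try:
        cohort = _load_cohort(config, seeds[0])
        filter_reports = {}
        for comp in list(cohort.matrices):
            filtered, report = filter_detection(
                cohort.matrices[comp], config.detection_min_frac, config.exclusion_list
            )
            cohort.matrices[comp] = filtered
            filter_reports[comp] = report.to_dict()
            log.info("filter %s: dropped %d metabolites", comp, report.n_dropped)

        summary: dict[str, Any] = {
            "package_version": __version__,
            "seed": config.seed,
            "stage_seeds": seeds,
            "n_dyads": cohort.n_dyads,
            "filter_reports": filter_reports,
            "fdr_level": config.fdr_level,
            "pairs": {},
        }

        for idx, (a, b) in enumerate(config.pairs):
            pair_name = f"{a}__{b}"
            pair_dir = out / pair_name
            pair_dir.mkdir(exist_ok=True)
            X, Y = cohort.matrices[a], cohort.matrices[b]
            try:
                sp = spearman_screen(X, Y, fdr_level=config.fdr_level)
            except ValueError as exc:
                raise RuntimeError(f"stage spearman_screen[{pair_name}]: {exc}") from exc
            write_screen_tsv(sp, pair_dir / "spearman_screen.tsv")
            screens = {"spearman": int(sp["significant"].sum())}
            adj_sig = 0
            for label, cov_names in config.covariate_sets.items():
                adj = adjusted_pairwise_screen(
                    X,
                    Y,
                    cohort.covariates,
                    cov_names,
                    model_label=label,
                    scale=config.screen_scale,
                    fdr_level=config.fdr_level,
                )
                write_screen_tsv(adj, pair_dir / f"adjusted_screen_{label}.tsv")
                screens[label] = int(adj["significant"].sum())
                if label == "model2":
                    adj_sig = screens[label]
            gate = screens["spearman"] > 0 or adj_sig > 0
            pair_summary: dict[str, Any] = {
                "significant_pairs": screens,
                "pls_gate_open": bool(gate),
            }
            if gate:
                log.info("pair %s: screens significant, running PLS", pair_name)
                pair_summary["pls"] = _pls_stage(
                    cohort, (a, b), config, seeds[2 + idx], pair_dir
                )
            else:
                log.info("pair %s: no significant screen pairs, PLS skipped", pair_name)
                pair_summary["pls"] = {
                    "skipped": True,
                    "reason": "no significant screen associations",
                }
            summary["pairs"][pair_name] = pair_summary

        if config.outcome_metabolite is not None and cohort.outcome is not None:
            covariate_sets = {"unadjusted": [], "adjusted": config.covariate_sets.get("model2", [])}
            try:
                tab = metabolite_outcome_screen(
                    cohort,
                    config.outcome_metabolite,
                    covariate_sets,
                    reference=config.outcome_reference,
                )
                tab.to_csv(out / "metabolite_outcome.tsv", sep="\t", index=False)
                summary["metabolite_outcome"] = json.loads(
                    tab.to_json(orient="records")
                )
            except (KeyError, ValueError, RuntimeError) as exc:
                summary["metabolite_outcome"] = {"error": str(exc)}

        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        cohort.write_manifest(out / "cohort_manifest.json")
        log.info("pipeline finished in %.1f s", time.time() - t0)
        return summary
    finally:
        log.removeHandler(handler)
        handler.close()
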