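"""Cohort data model: concentration matrices, covariates, dyad pairing.

A *dyad* is a mother-infant pair contributing specimens from up to three
compartments: maternal third-trimester serum (nmol/L), placental tissue
collected at delivery (nmol/g) and umbilical cord serum (nmol/L).  The
concentrations come from quantitative NMR, so values are absolute and
non-negative; metabolites that fall below the detection limit in a sample
are recorded as missing rather than zero (a configuration switch elsewhere
lets zeros be read as missing too).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

COMPARTMENTS = ("maternal_serum", "placenta", "cord_serum")
#: measurement units per compartment (serum per litre, tissue per gram)
UNITS = {"maternal_serum": "nmol/L", "placenta": "nmol/g", "cord_serum": "nmol/L"}
OUTCOME_CLASSES = ("TD", "ASD", "nonTD")


def _check_compartment(compartment: str) -> str:
    if compartment not in COMPARTMENTS:
        raise ValueError(
            f"unknown compartment {compartment!r}; expected one of {COMPARTMENTS}"
        )
    return compartment


@dataclass
class ConcentrationMatrix:
    """Samples x metabolites concentrations for one compartment.

    ``values`` is a DataFrame indexed by sample id with metabolite columns;
    missing (not-detected) entries are NaN.  ``missing_mask`` is derived.
    """

    compartment: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_compartment(self.compartment)
        if self.values.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate metabolite ids")
        vals = self.values.to_numpy(dtype=float)
        if np.nanmin(vals, initial=np.inf) < 0:
            raise ValueError("negative concentrations are not permitted")

    @property
    def sample_ids(self) -> list:
        return list(self.values.index)

    @property
    def metabolite_ids(self) -> list:
        return list(self.values.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Boolean mask, True where the metabolite was not detected."""
        return self.values.isna()

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[1]

    @property
    def units(self) -> str:
        return UNITS[self.compartment]

    def detection_fraction(self) -> pd.Series:
        """Per-metabolite fraction of samples in which it was detected."""
        return 1.0 - self.missing_mask.mean(axis=0)

    def subset_samples(self, sample_ids: Sequence) -> "ConcentrationMatrix":
        return ConcentrationMatrix(self.compartment, self.values.loc[list(sample_ids)])


def read_concentration_table(
    path: str | Path, compartment: str, *, zeros_as_missing: bool = False
) -> ConcentrationMatrix:
    """Read a delimited concentration table (first column sample id).

    Blank cells are treated as below the detection limit.  With
    ``zeros_as_missing`` explicit zeros are also interpreted as
    non-detected, the alternative reading of quantitation software output.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    if len(header) != len(set(header)):  # pandas mangles duplicates silently
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"duplicate metabolite ids in header: {dupes}")
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    if raw.index.has_duplicates:
        dupes = raw.index[raw.index.duplicated()].tolist()
        raise ValueError(f"duplicate sample ids: {dupes}")
    values = raw.replace({"": np.nan, "NA": np.nan}).apply(pd.to_numeric)
    if zeros_as_missing:
        values = values.mask(values == 0)
    return ConcentrationMatrix(compartment, values)


def write_concentration_table(m: ConcentrationMatrix, path: str | Path) -> None:
    """Write a matrix back to delimited text; NaN becomes a blank cell."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    m.values.to_csv(path, sep=sep, na_rep="")


@dataclass
class FilterReport:
    """Which metabolites the detection filter removed and why."""

    min_frac: float
    dropped_low_detection: list[str]
    dropped_excluded: list[str]

    @property
    def n_dropped(self) -> int:
        return len(self.dropped_low_detection) + len(self.dropped_excluded)

    def to_dict(self) -> dict:
        return {
            "min_frac": self.min_frac,
            "dropped_low_detection": list(self.dropped_low_detection),
            "dropped_excluded": list(self.dropped_excluded),
        }


def filter_detection(
    m: ConcentrationMatrix,
    min_frac: float = 0.8,
    exclusion_list: Iterable[str] = (),
) -> tuple[ConcentrationMatrix, FilterReport]:
    """Drop metabolites identified in less than ``min_frac`` of samples.

    The boundary is retained: a metabolite detected in exactly
    ``min_frac`` of samples stays.  ``exclusion_list`` names metabolites
    removed regardless of detection (e.g. known preparation contaminants).
    """
    if not 0 < min_frac <= 1:
        raise ValueError("min_frac must lie in (0, 1]")
    excl = set(exclusion_list)  # names absent from the panel are ignored
    frac = m.detection_fraction()
    low = [c for c in m.metabolite_ids if frac[c] < min_frac and c not in excl]
    by_list = [c for c in m.metabolite_ids if c in excl]
    keep = [c for c in m.metabolite_ids if c not in set(low) | set(by_list)]
    report = FilterReport(min_frac, low, by_list)
    return ConcentrationMatrix(m.compartment, m.values[keep]), report


@dataclass
class DyadCohort:
    """Paired compartment matrices, covariates and outcome per dyad.

    All compartment matrices are row-aligned to ``dyad_ids``; covariates
    are indexed by dyad id; ``outcome`` holds one of TD/ASD/nonTD or NaN.
    """

    dyad_ids: list
    mother_ids: list
    matrices: dict[str, ConcentrationMatrix]
    covariates: pd.DataFrame | None = None
    outcome: pd.Series | None = None
    manifest: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.dyad_ids) != len(set(self.dyad_ids)):
            raise ValueError("dyad ids must be unique")
        if len(self.mother_ids) != len(set(self.mother_ids)):
            raise ValueError("each mother may contribute at most one dyad")
        if len(self.mother_ids) != len(self.dyad_ids):
            raise ValueError("mother_ids and dyad_ids must be aligned")
        for comp, m in self.matrices.items():
            _check_compartment(comp)
            if list(m.values.index) != list(self.dyad_ids):
                raise ValueError(f"{comp} matrix rows not aligned to dyad order")
        if self.covariates is not None and list(self.covariates.index) != list(
            self.dyad_ids
        ):
            raise ValueError("covariate rows not aligned to dyad order")
        if self.outcome is not None:
            if list(self.outcome.index) != list(self.dyad_ids):
                raise ValueError("outcome not aligned to dyad order")
            bad = set(self.outcome.dropna()) - set(OUTCOME_CLASSES)
            if bad:
                raise ValueError(f"unknown outcome labels: {sorted(bad)}")

    @property
    def n_dyads(self) -> int:
        return len(self.dyad_ids)

    def subset(self, dyad_ids: Sequence) -> "DyadCohort":
        keep = list(dyad_ids)
        pos = {d: i for i, d in enumerate(self.dyad_ids)}
        mothers = [self.mother_ids[pos[d]] for d in keep]
        return DyadCohort(
            dyad_ids=keep,
            mother_ids=mothers,
            matrices={c: m.subset_samples(keep) for c, m in self.matrices.items()},
            covariates=None if self.covariates is None else self.covariates.loc[keep],
            outcome=None if self.outcome is None else self.outcome.loc[keep],
            manifest=dict(self.manifest),
        )

    def write_manifest(self, path: str | Path) -> None:
        """Persist pairing decisions and filter reports as JSON."""
        payload = dict(self.manifest)
        payload["n_dyads"] = self.n_dyads
        payload["compartments"] = sorted(self.matrices)
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def pair_dyads(
    matrices: Mapping[str, ConcentrationMatrix],
    registry: pd.DataFrame,
    required: Iterable[str],
    covariates: pd.DataFrame | None = None,
    outcome: pd.Series | None = None,
) -> DyadCohort:
    """Assemble independent mother-infant dyads from per-compartment samples.

    ``registry`` has one row per sample with columns ``sample_id``,
    ``dyad_id``, ``mother_id``, ``pregnancy_year`` and optionally
    ``family_id`` (defaults to the mother).  Rules applied, in order:

    1. a dyad qualifies only if every required compartment has a sample;
    2. a mother enrolled through several pregnancies contributes only the
       first (earliest ``pregnancy_year``) qualifying one;
    3. an infant whose older sibling (same ``family_id``, earlier year) is
       already retained is excluded, keeping pregnancies independent.
    """
    required = set(required)
    if len(required) < 2:
        raise ValueError("at least two required compartments expected")
    missing_req = required - set(matrices)
    if missing_req:
        raise ValueError(f"required compartments without matrices: {sorted(missing_req)}")

    reg = registry.copy()
    if "family_id" not in reg.columns:
        reg["family_id"] = reg["mother_id"]
    reg_by_sample = reg.set_index("sample_id")
    if reg_by_sample.index.has_duplicates:
        raise ValueError("registry sample_id entries must be unique")

    # map each dyad to the compartments for which a sample exists
    dyad_samples: dict[object, dict[str, object]] = {}
    for comp, m in matrices.items():
        for sid in m.sample_ids:
            if sid not in reg_by_sample.index:
                raise KeyError(f"sample {sid!r} in {comp} matrix absent from registry")
            did = reg_by_sample.at[sid, "dyad_id"]
            dyad_samples.setdefault(did, {})[comp] = sid

    dyads = reg.drop_duplicates("dyad_id").set_index("dyad_id")
    qualifying = [d for d, comps in dyad_samples.items() if required <= set(comps)]
    dropped_incomplete = sorted(
        str(d) for d in dyad_samples if d not in set(qualifying)
    )

    # first available pregnancy per mother
    qual = dyads.loc[qualifying, ["mother_id", "family_id", "pregnancy_year"]]
    qual = qual.sort_values(["pregnancy_year", "mother_id"], kind="stable")
    first_by_mother = qual[~qual["mother_id"].duplicated(keep="first")]
    dropped_later_pregnancy = sorted(
        str(d) for d in qual.index.difference(first_by_mother.index)
    )

    # sibling exclusion: keep only the earliest retained child per family
    kept, seen_families, dropped_sibling = [], set(), []
    for did, row in first_by_mother.iterrows():
        if row["family_id"] in seen_families:
            dropped_sibling.append(str(did))
        else:
            seen_families.add(row["family_id"])
            kept.append(did)

    kept = [d for d in dyad_samples if d in set(kept)]  # stable input order
    mothers = [dyads.at[d, "mother_id"] for d in kept]

    out_matrices = {}
    for comp in sorted(required):
        sids = [dyad_samples[d][comp] for d in kept]
        vals = matrices[comp].values.loc[sids]
        vals.index = pd.Index(kept, name="dyad_id")
        out_matrices[comp] = ConcentrationMatrix(comp, vals)

    cov = None
    if covariates is not None:
        cov = covariates.loc[kept]
    out = None
    if outcome is not None:
        out = outcome.loc[kept]

    manifest = {
        "required_compartments": sorted(required),
        "dropped_incomplete": dropped_incomplete,
        "dropped_later_pregnancy": dropped_later_pregnancy,
        "dropped_younger_sibling": sorted(dropped_sibling),
    }
    return DyadCohort(kept, mothers, out_matrices, cov, out, manifest)


def complete_case(
    cohort: DyadCohort, covariate_set: Sequence[str]
) -> tuple[DyadCohort, list]:
    """Restrict to dyads with no missing values among named covariates.

    Returns the sub-cohort and the list of dropped dyad ids.
    """
    if cohort.covariates is None:
        raise ValueError("cohort carries no covariate table")
    unknown = [c for c in covariate_set if c not in cohort.covariates.columns]
    if unknown:
        raise KeyError(f"unknown covariates: {unknown}")
    ok = cohort.covariates[list(covariate_set)].notna().all(axis=1)
    keep = [d for d in cohort.dyad_ids if ok.loc[d]]
    dropped = [d for d in cohort.dyad_ids if not ok.loc[d]]
    sub = cohort.subset(keep)
    sub.manifest["complete_case_dropped"] = [str(d) for d in dropped]
    return sub, dropped
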