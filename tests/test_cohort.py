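import numpy as np
import pandas as pd
import pytest

from metadyad.cohort import (
    ConcentrationMatrix,
    complete_case,
    filter_detection,
    pair_dyads,
    read_concentration_table,
    write_concentration_table,
)
from metadyad.simulate import SyntheticCohortConfig, generate_cohort


def _write(tmp_path, text, name="m.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadWrite:
    def test_round_trip_preserves_values_mask_and_order(self, small_matrix, tmp_path):
        path = tmp_path / "rt.tsv"
        write_concentration_table(small_matrix, path)
        back = read_concentration_table(path, "placenta")
        pd.testing.assert_frame_equal(back.values, small_matrix.values)
        assert back.metabolite_ids == small_matrix.metabolite_ids
        assert back.sample_ids == small_matrix.sample_ids
        assert back.missing_mask.equals(small_matrix.missing_mask)

    def test_no_blanks_gives_all_false_mask(self, tmp_path):
        p = _write(tmp_path, "id,a,b\nS1,1,2\nS2,3,4\nS3,5,6\n")
        m = read_concentration_table(p, "cord_serum")
        assert m.values.shape == (3, 2)
        assert not m.missing_mask.to_numpy().any()

    def test_blank_cell_marks_exactly_that_entry_missing(self, tmp_path):
        p = _write(tmp_path, "id,a,b\nS1,1,\nS2,3,4\n")
        m = read_concentration_table(p, "maternal_serum")
        assert m.missing_mask.to_numpy().sum() == 1
        assert bool(m.missing_mask.loc["S1", "b"])

    def test_duplicate_metabolite_header_rejected(self, tmp_path):
        p = _write(tmp_path, "id,a,a\nS1,1,2\n")
        with pytest.raises(ValueError, match="duplicate metabolite"):
            read_concentration_table(p, "placenta")

    def test_duplicate_sample_id_rejected(self, tmp_path):
        p = _write(tmp_path, "id,a\nS1,1\nS1,2\n")
        with pytest.raises(ValueError, match="duplicate sample"):
            read_concentration_table(p, "placenta")

    def test_negative_concentration_rejected(self, tmp_path):
        p = _write(tmp_path, "id,a\nS1,-1\n")
        with pytest.raises(ValueError, match="negative"):
            read_concentration_table(p, "placenta")

    def test_non_numeric_cell_rejected(self, tmp_path):
        p = _write(tmp_path, "id,a\nS1,abc\n")
        with pytest.raises(ValueError):
            read_concentration_table(p, "placenta")

    def test_zeros_as_missing_switch(self, tmp_path):
        p = _write(tmp_path, "id,a\nS1,0\nS2,2\n")
        strict = read_concentration_table(p, "placenta")
        loose = read_concentration_table(p, "placenta", zeros_as_missing=True)
        assert not strict.missing_mask.to_numpy().any()
        assert bool(loose.missing_mask.loc["S1", "a"])


class TestDetectionFilter:
    @staticmethod
    def _matrix(detected_counts, n=10):
        cols = {}
        for j, k in enumerate(detected_counts):
            col = np.full(n, np.nan)
            col[:k] = 1.0 + j
            cols[f"m{j}"] = col
        return ConcentrationMatrix(
            "placenta", pd.DataFrame(cols, index=[f"S{i}" for i in range(n)])
        )

    def test_below_threshold_dropped_boundary_kept(self):
        m = self._matrix([7, 8, 10])
        out, report = filter_detection(m, min_frac=0.8)
        # detected in 7/10 < 80% -> dropped; exactly 8/10 = 80% -> retained
        assert out.metabolite_ids == ["m1", "m2"]
        assert report.dropped_low_detection == ["m0"]

    def test_exclusion_list_drops_fully_detected_metabolite(self):
        m = self._matrix([10, 10])
        out, report = filter_detection(m, exclusion_list=["m1"])
        assert out.metabolite_ids == ["m0"]
        assert report.dropped_excluded == ["m1"]

    def test_idempotent(self):
        m = self._matrix([7, 8, 9, 10])
        once, _ = filter_detection(m)
        twice, report2 = filter_detection(once)
        pd.testing.assert_frame_equal(once.values, twice.values)
        assert report2.n_dropped == 0

    def test_invalid_min_frac(self):
        m = self._matrix([10])
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                filter_detection(m, min_frac=bad)


def _registry(rows):
    return pd.DataFrame(
        rows, columns=["sample_id", "dyad_id", "mother_id", "family_id", "pregnancy_year"]
    )


def _comp_matrix(comp, sample_ids, rng):
    vals = pd.DataFrame(
        rng.lognormal(size=(len(sample_ids), 3)),
        index=sample_ids,
        columns=[f"{comp[:3]}{j}" for j in range(3)],
    )
    return ConcentrationMatrix(comp, vals)


class TestPairDyads:
    def test_first_pregnancy_kept_for_repeat_mothers(self, rng):
        reg = _registry(
            [
                ("P1", "d2010", "momA", "famA", 2010),
                ("C1", "d2010", "momA", "famA", 2010),
                ("P2", "d2012", "momA", "famA", 2012),
                ("C2", "d2012", "momA", "famA", 2012),
            ]
        )
        mats = {
            "placenta": _comp_matrix("placenta", ["P1", "P2"], rng),
            "cord_serum": _comp_matrix("cord_serum", ["C1", "C2"], rng),
        }
        cohort = pair_dyads(mats, reg, {"placenta", "cord_serum"})
        assert cohort.dyad_ids == ["d2010"]
        assert cohort.manifest["dropped_later_pregnancy"] == ["d2012"]

    def test_younger_sibling_excluded(self, rng):
        # different mothers (so the pregnancy rule cannot fire) linked as siblings
        reg = _registry(
            [
                ("P1", "older", "momA", "famX", 2010),
                ("C1", "older", "momA", "famX", 2010),
                ("P2", "younger", "momB", "famX", 2013),
                ("C2", "younger", "momB", "famX", 2013),
            ]
        )
        mats = {
            "placenta": _comp_matrix("placenta", ["P1", "P2"], rng),
            "cord_serum": _comp_matrix("cord_serum", ["C1", "C2"], rng),
        }
        cohort = pair_dyads(mats, reg, {"placenta", "cord_serum"})
        assert cohort.dyad_ids == ["older"]
        assert cohort.manifest["dropped_younger_sibling"] == ["younger"]

    def test_dyad_missing_required_compartment_excluded(self, rng):
        reg = _registry(
            [
                ("P1", "full", "momA", "famA", 2011),
                ("C1", "full", "momA", "famA", 2011),
                ("P2", "placenta_only", "momB", "famB", 2011),
            ]
        )
        mats = {
            "placenta": _comp_matrix("placenta", ["P1", "P2"], rng),
            "cord_serum": _comp_matrix("cord_serum", ["C1"], rng),
        }
        cohort = pair_dyads(mats, reg, {"placenta", "cord_serum"})
        assert cohort.dyad_ids == ["full"]
        assert "placenta_only" in cohort.manifest["dropped_incomplete"]

    def test_unregistered_sample_is_an_error(self, rng):
        reg = _registry([("P1", "d1", "momA", "famA", 2011)])
        mats = {
            "placenta": _comp_matrix("placenta", ["P1"], rng),
            "cord_serum": _comp_matrix("cord_serum", ["GHOST"], rng),
        }
        with pytest.raises(KeyError, match="GHOST"):
            pair_dyads(mats, reg, {"placenta", "cord_serum"})

    def test_mother_ids_injective(self, rng):
        reg = _registry(
            [
                ("P1", "d1", "momA", "famA", 2010),
                ("C1", "d1", "momA", "famA", 2010),
                ("P2", "d2", "momB", "famB", 2011),
                ("C2", "d2", "momB", "famB", 2011),
            ]
        )
        mats = {
            "placenta": _comp_matrix("placenta", ["P1", "P2"], rng),
            "cord_serum": _comp_matrix("cord_serum", ["C1", "C2"], rng),
        }
        cohort = pair_dyads(mats, reg, {"placenta", "cord_serum"})
        assert len(set(cohort.mother_ids)) == len(cohort.dyad_ids)


class TestCompleteCase:
    def test_no_missing_unchanged(self, small_cohort):
        cohort, _ = small_cohort
        sub, dropped = complete_case(cohort, ["metabolic_condition", "fetal_sex"])
        assert dropped == []
        assert sub.n_dyads == cohort.n_dyads

    def test_missing_covariate_dyads_dropped(self):
        cfg = SyntheticCohortConfig(n_dyads=30, missing_covariate_dyads=2, seed=5)
        cohort, _ = generate_cohort(cfg)
        sub, dropped = complete_case(cohort, ["metabolic_condition"])
        assert len(dropped) == 2
        assert sub.n_dyads == 28
        assert sub.covariates["metabolic_condition"].notna().all()

    def test_cohort_of_111_with_4_missing_retains_107(self):
        cfg = SyntheticCohortConfig(n_dyads=111, missing_covariate_dyads=4, seed=3)
        cohort, _ = generate_cohort(cfg)
        sub, _ = complete_case(cohort, ["metabolic_condition", "home_ownership"])
        assert sub.n_dyads == 107

    def test_unknown_covariate_errors(self, small_cohort):
        cohort, _ = small_cohort
        with pytest.raises(KeyError):
            complete_case(cohort, ["no_such_covariate"])
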