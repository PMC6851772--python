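"""Acute filtering, coverage, and effect-distribution summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from moaconsensus import (
    AcuteConfig,
    complete_acute_subset,
    coverage_stats,
    distribution_by_moa,
    filter_acute,
)


def _studies(rows):
    return pd.DataFrame(
        rows, columns=["id", "species", "trophic_level", "endpoint", "duration_h", "effect_mg_L"]
    )


def _results(assignments):
    return pd.DataFrame(
        [{"id": i, "code": "NNNN", "consensus_moa": m, "confidence": 3} for i, m in assignments]
    )


class TestFilterAcute:
    def test_fish_window_bounds_inclusive(self):
        st_ = _studies(
            [
                ("a", "x", "fish", "LC50", 24.0, 1.0),
                ("a", "x", "fish", "LC50", 96.0, 1.0),
                ("a", "x", "fish", "LC50", 120.0, 1.0),
                ("a", "x", "fish", "LC50", 12.0, 1.0),
                ("a", "x", "fish", "EC50", 96.0, 1.0),
            ]
        )
        out = filter_acute(st_)
        assert list(out["duration_h"]) == [24.0, 96.0]

    def test_unknown_trophic_level_errors(self):
        with pytest.raises(ValueError, match="amphibian"):
            filter_acute(_studies([("a", "x", "amphibian", "LC50", 96.0, 1.0)]))

    def test_empty_input(self):
        assert filter_acute(_studies([])).empty

    def test_algae_window_starts_at_48(self):
        st_ = _studies(
            [
                ("a", "x", "algae", "EC50", 24.0, 1.0),
                ("a", "x", "algae", "EC50", 48.0, 1.0),
            ]
        )
        assert list(filter_acute(st_)["duration_h"]) == [48.0]


class TestCoverage:
    def test_chemical_vs_study_fractions(self):
        res = _results([("a", "N"), ("b", "S")])
        st_ = _studies(
            [("a", "x", "fish", "LC50", 96.0, 1.0)]
            + [("b", "x", "fish", "LC50", 96.0, 1.0)] * 3
        )
        cov = coverage_stats(res, st_).set_index("consensus_moa")
        assert cov.loc["N", "frac_chemicals"] == 0.5
        assert cov.loc["S", "frac_chemicals"] == 0.5
        assert cov.loc["N", "frac_studies"] == 0.25
        assert cov.loc["S", "frac_studies"] == 0.75

    def test_all_u(self):
        res = _results([("a", "U"), ("b", "U")])
        st_ = _studies([("a", "x", "fish", "LC50", 96.0, 1.0)])
        cov = coverage_stats(res, st_)
        assert list(cov["consensus_moa"]) == ["U"]
        assert cov["frac_chemicals"].iloc[0] == 1.0
        assert cov["frac_studies"].iloc[0] == 1.0

    def test_orphan_studies_excluded_with_warning(self, caplog):
        res = _results([("a", "N")])
        st_ = _studies(
            [
                ("a", "x", "fish", "LC50", 96.0, 1.0),
                ("ghost", "x", "fish", "LC50", 96.0, 1.0),
            ]
        )
        with caplog.at_level("WARNING"):
            cov = coverage_stats(res, st_)
        assert cov["n_studies"].sum() == 1
        assert "1 study record" in caplog.text


class TestDistribution:
    def test_median_of_decade_spaced_effects(self):
        res = _results([("a", "N")])
        st_ = _studies(
            [("a", "x", "fish", "LC50", 96.0, e) for e in (1, 10, 100, 1000, 10000)]
        )
        out = distribution_by_moa(st_, res)
        assert out["median"].item() == pytest.approx(2.0)
        assert out["n_studies"].item() == 5

    def test_single_study_collapses_quartiles(self):
        res = _results([("a", "N")])
        out = distribution_by_moa(_studies([("a", "x", "fish", "LC50", 96.0, 7.0)]), res)
        row = out.iloc[0]
        assert row["min"] == row["q1"] == row["median"] == row["q3"] == row["max"]

    def test_empty_groups_omitted(self):
        res = _results([("a", "N"), ("b", "S")])
        st_ = _studies([("a", "x", "fish", "LC50", 96.0, 1.0)])
        out = distribution_by_moa(st_, res)
        assert list(out["consensus_moa"]) == ["N"]

    def test_quartile_ordering_invariant(self):
        rng = np.random.default_rng(0)
        effects = 10.0 ** rng.normal(0, 1, 101)
        res = _results([("a", "N")])
        st_ = _studies([("a", "x", "fish", "LC50", 96.0, e) for e in effects])
        row = distribution_by_moa(st_, res).iloc[0]
        assert row["min"] <= row["q1"] <= row["median"] <= row["q3"] <= row["max"]

    @given(st.lists(st.floats(-3, 3), min_size=1, max_size=60))
    @settings(max_examples=100, deadline=None)
    def test_quantiles_match_sort_based_oracle(self, logs):
        res = _results([("a", "N")])
        st_ = _studies([("a", "x", "fish", "LC50", 96.0, 10.0 ** v) for v in logs])
        row = distribution_by_moa(st_, res).iloc[0]
        # brute-force type-7 quantile: sort and linearly interpolate ranks
        xs = np.sort(np.asarray(logs, dtype=float))

        def q7(p):
            h = (len(xs) - 1) * p
            lo = int(np.floor(h))
            hi = min(lo + 1, len(xs) - 1)
            return xs[lo] + (h - lo) * (xs[hi] - xs[lo])

        assert row["q1"] == pytest.approx(q7(0.25), abs=1e-9)
        assert row["median"] == pytest.approx(q7(0.5), abs=1e-9)
        assert row["q3"] == pytest.approx(q7(0.75), abs=1e-9)

    def test_duplicate_study_keeps_min_max(self):
        res = _results([("a", "N")])
        rows = [("a", "x", "fish", "LC50", 96.0, e) for e in (0.5, 2.0, 8.0, 30.0)]
        base = distribution_by_moa(_studies(rows), res).iloc[0]
        dup = distribution_by_moa(_studies(rows + [rows[1]]), res).iloc[0]
        assert dup["min"] == base["min"] and dup["max"] == base["max"]

    def test_group_sizes_reconcile_with_input(self, study_table):
        res = _results([("c1", "N"), ("c2", "S"), ("c3", "U"), ("c4", "U")])
        acute = filter_acute(study_table)
        out = distribution_by_moa(acute, res, by_trophic_level=True)
        assert out["n_studies"].sum() == len(acute)

    def test_per_chemical_median_option(self):
        res = _results([("a", "N"), ("b", "N")])
        st_ = _studies(
            [("a", "x", "fish", "LC50", 96.0, e) for e in (1.0, 1.0, 1.0)]
            + [("b", "x", "fish", "LC50", 96.0, 100.0)]
        )
        pooled = distribution_by_moa(st_, res).iloc[0]["median"]
        per_chem = distribution_by_moa(st_, res, per_chemical_median=True).iloc[0]["median"]
        assert pooled == pytest.approx(0.0)
        assert per_chem == pytest.approx(1.0)  # chemicals weighted equally


class TestCompleteAcuteSubset:
    def test_requires_all_three_trophic_levels(self):
        st_ = _studies(
            [
                ("full", "x", "fish", "LC50", 96.0, 1.0),
                ("full", "x", "invertebrate", "EC50", 48.0, 1.0),
                ("full", "x", "algae", "EC50", 72.0, 1.0),
                ("partial", "x", "fish", "LC50", 96.0, 1.0),
                ("partial", "x", "algae", "EC50", 72.0, 1.0),
            ]
        )
        assert complete_acute_subset(st_) == ["full"]

    def test_empty(self):
        assert complete_acute_subset(_studies([])) == []
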