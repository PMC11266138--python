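"""Disproportionality estimators, signal criteria, and the vectorised screen."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from faersig.signals import (
    ContingencyTable,
    DisproportionalityScreen,
    SignalCriteria,
    compute_ebgm,
    compute_ic,
    compute_prr,
    compute_ror,
    compute_stats,
    evaluate_criteria,
    screen_all,
)

from conftest import naive_cells, naive_stats

UNIFORM = ContingencyTable(5, 5, 5, 5)
HAND = ContingencyTable(10, 20, 30, 240)

cells_strategy = st.tuples(
    st.integers(1, 500), st.integers(1, 5000),
    st.integers(1, 5000), st.integers(1, 10**6),
)


class TestFormulaUnits:
    def test_uniform_table_is_null(self):
        assert compute_ror(UNIFORM)[0] == pytest.approx(1.0)
        prr, chi2 = compute_prr(UNIFORM)
        assert prr == pytest.approx(1.0)
        assert chi2 == pytest.approx(0.0)
        assert compute_ic(UNIFORM)[0] == pytest.approx(0.0)
        assert compute_ebgm(UNIFORM)[0] == pytest.approx(1.0)

    def test_hand_computed_table(self):
        """Frozen values computed by hand from the defining formulas."""
        ror, l95, u95 = compute_ror(HAND)
        assert ror == pytest.approx(4.00)
        assert l95 == pytest.approx(1.7119, abs=1e-4)
        assert u95 == pytest.approx(9.3465, abs=1e-4)
        prr, chi2 = compute_prr(HAND)
        assert prr == pytest.approx(3.0)
        assert chi2 == pytest.approx(11.5385, abs=1e-4)
        assert compute_ic(HAND)[0] == pytest.approx(math.log2(2.5), abs=1e-12)
        ebgm, ebgm05 = compute_ebgm(HAND)
        assert ebgm == pytest.approx(2.5)
        assert ebgm05 == pytest.approx(1.0699, abs=1e-4)

    def test_swap_invariance_and_prr_asymmetry(self):
        sw = HAND.swapped()
        assert compute_ror(sw)[0] == pytest.approx(compute_ror(HAND)[0])
        assert compute_prr(sw)[1] == pytest.approx(compute_prr(HAND)[1])  # chi2
        assert compute_ic(sw)[0] == pytest.approx(compute_ic(HAND)[0])
        assert compute_ebgm(sw)[0] == pytest.approx(compute_ebgm(HAND)[0])
        assert compute_prr(sw)[0] != pytest.approx(compute_prr(HAND)[0])

    def test_zero_cell_gives_undefined_not_error(self):
        t = ContingencyTable(3, 0, 7, 100)
        assert math.isnan(compute_ror(t)[0])
        assert math.isnan(compute_ebgm(t)[0])

    def test_negative_or_empty_table_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 2, 3, 4)
        with pytest.raises(ValueError):
            ContingencyTable(0, 0, 0, 0)


@given(cells_strategy)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_estimator_invariants_on_random_tables(cells):
    a, b, c, d = cells
    t = ContingencyTable(a, b, c, d)
    stats = compute_stats(t)
    # interval ordering
    assert stats["ror_l95"] <= stats["ror"] <= stats["ror_u95"]
    assert stats["ebgm05"] <= stats["ebgm"]
    # shared-variance identity holds exactly
    assert stats["ebgm05"] / stats["ebgm"] == pytest.approx(
        stats["ror_l95"] / stats["ror"], rel=1e-12
    )
    # default-mode identity: IC is exactly log2 of the relative reporting ratio
    assert stats["ic"] == pytest.approx(math.log2(stats["ebgm"]), abs=1e-12)
    # b<->c swap invariance for all but PRR
    sw = compute_stats(t.swapped())
    for key in ("ror", "chi2", "ic", "ebgm"):
        assert sw[key] == pytest.approx(stats[key], rel=1e-12)


def test_point_estimates_increase_strictly_in_a():
    lo = compute_stats(ContingencyTable(5, 50, 70, 1000))
    hi = compute_stats(ContingencyTable(6, 50, 70, 1000))
    for key in ("ror", "prr", "ic", "ebgm"):
        assert hi[key] > lo[key]


class TestCriteria:
    def test_small_count_vetoes_even_huge_ror(self):
        stats = compute_stats(ContingencyTable(2, 1, 1, 10_000))
        flags = evaluate_criteria(stats, SignalCriteria())
        assert not any(flags.values())

    def test_uniform_table_never_flags(self):
        flags = evaluate_criteria(compute_stats(UNIFORM), SignalCriteria())
        assert not any(flags.values())

    def test_undefined_statistics_never_flag(self):
        stats = compute_stats(ContingencyTable(5, 0, 9, 1000))
        flags = evaluate_criteria(stats, SignalCriteria())
        assert not flags["flag_ror"] and not flags["flag_ebgm"]

    def test_strong_association_flags_all_four(self):
        stats = compute_stats(ContingencyTable(40, 400, 100, 100_000))
        flags = evaluate_criteria(stats, SignalCriteria())
        assert flags["signal"] and all(flags.values())

    def test_combined_is_conjunction(self):
        # PRR just below 2: other rules may pass, combined must not
        t = ContingencyTable(30, 1000, 153, 10_000)
        stats = compute_stats(t)
        flags = evaluate_criteria(stats, SignalCriteria())
        assert flags["signal"] == all(
            flags[k] for k in ("flag_ror", "flag_prr", "flag_ic", "flag_ebgm")
        )


def _pair_frame(rows):
    return pd.DataFrame(rows, columns=["primaryid", "pt", "is_member"])


class TestScreen:
    def test_single_pt_toy_background(self):
        frame = screen_all(_pair_frame([("1", "X", True), ("2", "X", False)]))
        assert len(frame) == 1
        assert frame.loc[0, "a"] == 1 and frame.loc[0, "c"] == 1

    def test_duplicate_pairs_rejected(self):
        with pytest.raises(ValueError, match="duplicated"):
            screen_all(_pair_frame([("1", "X", True), ("1", "X", True)]))

    def test_rows_sorted_by_descending_cooccurrence(self, small_clean):
        from faersig.cohort import CohortSpec, select_cohort

        _, clean, _, _ = small_clean
        cohort = select_cohort(clean, CohortSpec(drug_name_patterns=["OSELTAMIVIR", "TAMIFLU"]))
        frame = DisproportionalityScreen.from_cohort(cohort).fit().frame
        assert (frame["a"].diff().dropna() <= 0).all()
        assert (frame["a"] >= 1).all()

    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_vectorized_screen_equals_naive_per_report_recount(self, seed):
        """Dual route: cells by per-row iteration, statistics re-derived in
        plain scalar math, compared at 1e-12 relative tolerance."""
        from faersig.cohort import CohortSpec, select_cohort
        from faersig.dedup import clean_snapshot
        from faersig.synth import default_config, generate_snapshot

        snap, _ = generate_snapshot(default_config(250, seed=seed))
        clean, _ = clean_snapshot(snap)
        cohort = select_cohort(clean, CohortSpec(drug_name_patterns=["OSELTAMIVIR", "TAMIFLU"]))
        frame = DisproportionalityScreen.from_cohort(cohort).fit().frame
        rows = list(
            cohort.pair_table[["primaryid", "pt", "is_member"]].itertuples(index=False)
        )
        assert len(frame) > 0
        for _, row in frame.iterrows():
            a, b, c, d = naive_cells(rows, row["pt"])
            assert (a, b, c, d) == (row["a"], row["b"], row["c"], row["d"])
            expect = naive_stats(a, b, c, d)
            for key, val in expect.items():
                assert row[key] == pytest.approx(val, rel=1e-12), (row["pt"], key)

    def test_zero_cell_correction_defines_otherwise_undefined_rows(self):
        rows = [("1", "X", True), ("2", "Y", False), ("3", "Y", False)]
        plain = screen_all(_pair_frame(rows))
        assert math.isnan(plain.loc[plain["pt"] == "X", "ror"].iloc[0])
        corrected = screen_all(_pair_frame(rows), zero_cell_correction=0.5)
        assert np.isfinite(corrected.loc[corrected["pt"] == "X", "ror"].iloc[0])

    def test_summary_mentions_drug_and_counts(self, small_clean):
        from faersig.cohort import CohortSpec, select_cohort

        _, clean, _, _ = small_clean
        cohort = select_cohort(clean, CohortSpec(drug_name_patterns=["OSELTAMIVIR", "TAMIFLU"]))
        res = DisproportionalityScreen.from_cohort(cohort, drug="oseltamivir").fit()
        text = res.summary()
        assert "oseltamivir" in text and f"signals: {res.n_signals}" in text
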