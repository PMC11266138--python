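"""Age parsing, target-drug matching, cohort selection, descriptive tables."""

import math

import pandas as pd
import pytest

from faersig.cohort import (
    CohortSpec,
    assign_age_group,
    concomitant_summary,
    descriptive_summary,
    match_target_drug,
    parse_age_years,
    select_cohort,
)
from faersig.synth import default_config, generate_snapshot

from conftest import make_snapshot

TARGET_PATTERNS = ["OSELTAMIVIR", "TAMIFLU"]


@pytest.mark.parametrize(
    "value,code,expected",
    [
        (18, "YR", 18.0),
        (6, "MON", 0.5),
        (2, "DEC", 20.0),  # decades: independently, 2 decades = 20 years
        (52, "WK", 1.0),
        (365, "DY", 1.0),
        (8760, "HR", 1.0),
    ],
)
def test_parse_age_years_unit_table(value, code, expected):
    assert parse_age_years(value, code) == pytest.approx(expected)


def test_parse_age_unknown_code_or_missing_value_gives_missing():
    assert math.isnan(parse_age_years(5, "FORTNIGHT"))
    assert math.isnan(parse_age_years(float("nan"), "YR"))
    assert math.isnan(parse_age_years(None, "YR"))


@pytest.mark.parametrize(
    "years,group",
    [(0.0, "0-1"), (1.9, "0-1"), (2.0, "2-5"), (5.99, "2-5"),
     (6.0, "6-12"), (12.99, "6-12"), (13.0, "13-18"), (18.0, "13-18")],
)
def test_age_group_bins(years, group):
    assert assign_age_group(years) == group


def test_age_group_out_of_range_errors():
    with pytest.raises(ValueError):
        assign_age_group(18.5)
    with pytest.raises(ValueError):
        assign_age_group(-0.1)


class TestDrugMatching:
    def _mentions(self, *names):
        return pd.DataFrame(
            {"drugname": names, "prod_ai": [""] * len(names)}
        )

    def test_substring_match_with_dose_suffix(self):
        got = match_target_drug(self._mentions("TAMIFLU 75MG"), TARGET_PATTERNS)
        assert got.tolist() == [True]

    def test_trade_name_needed_when_generic_absent(self):
        m = self._mentions("BALOXAVIR MARBOXIL")
        assert match_target_drug(m, ["XOFLUZA"]).tolist() == [False]
        assert match_target_drug(m, ["XOFLUZA", "BALOXAVIR"]).tolist() == [True]

    def test_matches_active_ingredient_field(self):
        m = pd.DataFrame({"drugname": ["UNKNOWN BRAND"], "prod_ai": ["OSELTAMIVIR PHOSPHATE"]})
        assert match_target_drug(m, TARGET_PATTERNS).tolist() == [True]

    def test_decoy_prefixes_never_match_long_patterns(self):
        """Generated vocabulary decoys share a 3-letter prefix with the target;
        8+-letter patterns must produce zero false matches."""
        cfg = default_config(3000, seed=77)
        snapshot, truth = generate_snapshot(cfg)
        mask = match_target_drug(snapshot.drugs, TARGET_PATTERNS)
        matched_ai = set(snapshot.drugs.loc[mask, "prod_ai"])
        assert matched_ai == {"OSELTAMIVIR PHOSPHATE"}


class TestSelectCohort:
    def test_no_target_ps_mentions_gives_empty_cohort(self):
        snap = make_snapshot(
            [("1", "1", "20200101", 5, "YR", "F")],
            drug_rows=[("1", "1", "PS", "IBUPROFEN", "IBUPROFEN")],
            event_rows=[("1", "X")],
        )
        cohort = select_cohort(snap, CohortSpec(drug_name_patterns=TARGET_PATTERNS))
        assert cohort.n_members == 0
        assert len(cohort.pair_table) == 1  # background still populated

    def test_member_count_matches_generator_truth(self, small_clean):
        _, clean, truth, _ = small_clean
        cohort = select_cohort(clean, CohortSpec(drug_name_patterns=TARGET_PATTERNS))
        cases = truth.cases
        expected = cases[
            (~cases["deleted"])
            & (cases["ps_drug"] == "OSELTAMIVIR")
            & (cases["age_years"] <= 18)
        ]
        assert cohort.n_members == len(expected)
        assert cohort.member_primaryids == set(expected["survivor_primaryid"])

    def test_ps_exclusive_drops_reports_with_second_ps_ingredient(self):
        snap = make_snapshot(
            [("1", "1", "20200101", 5, "YR", "F"), ("2", "2", "20200101", 5, "YR", "F")],
            drug_rows=[
                ("1", "1", "PS", "TAMIFLU", "OSELTAMIVIR"),
                ("1", "2", "PS", "IBUPROFEN", "IBUPROFEN"),
                ("2", "1", "PS", "TAMIFLU", "OSELTAMIVIR"),
                ("2", "2", "C", "IBUPROFEN", "IBUPROFEN"),
            ],
            event_rows=[("1", "X"), ("2", "X")],
        )
        spec = CohortSpec(drug_name_patterns=TARGET_PATTERNS, ps_exclusive=True)
        assert select_cohort(snap, spec).member_primaryids == {"2"}
        spec = CohortSpec(drug_name_patterns=TARGET_PATTERNS, ps_exclusive=False)
        assert select_cohort(snap, spec).member_primaryids == {"1", "2"}

    def test_missing_age_excluded_from_stratum(self):
        snap = make_snapshot(
            [("1", "1", "20200101", None, "", "F"), ("2", "2", "20200101", 5, "YR", "F")],
            drug_rows=[
                ("1", "1", "PS", "TAMIFLU", "OSELTAMIVIR"),
                ("2", "1", "PS", "TAMIFLU", "OSELTAMIVIR"),
            ],
            event_rows=[("1", "X"), ("2", "X")],
        )
        cohort = select_cohort(snap, CohortSpec(drug_name_patterns=TARGET_PATTERNS))
        assert cohort.member_primaryids == {"2"}

    def test_widening_age_window_never_shrinks_cohort(self, small_clean):
        _, clean, _, _ = small_clean
        sizes = []
        for age_max in (5.0, 12.0, 18.0):
            spec = CohortSpec(drug_name_patterns=TARGET_PATTERNS, age_max_years=age_max)
            sizes.append(select_cohort(clean, spec).n_members)
        assert sizes == sorted(sizes)

    def test_pair_table_has_no_duplicate_pairs(self, small_clean):
        _, clean, _, _ = small_clean
        cohort = select_cohort(clean, CohortSpec(drug_name_patterns=TARGET_PATTERNS))
        assert not cohort.pair_table.duplicated(["primaryid", "pt"]).any()


class TestDescriptives:
    def test_empty_cohort_gives_empty_tallies(self):
        snap = make_snapshot(
            [("1", "1", "20200101", 5, "YR", "F")],
            event_rows=[("1", "X")],
        )
        cohort = select_cohort(snap, CohortSpec(drug_name_patterns=TARGET_PATTERNS))
        assert descriptive_summary(cohort).empty

    def test_tallies_equal_generator_truth_exactly(self, small_clean):
        _, clean, truth, _ = small_clean
        cohort = select_cohort(clean, CohortSpec(drug_name_patterns=TARGET_PATTERNS))
        summary = descriptive_summary(cohort)
        members = truth.cases[
            truth.cases["survivor_primaryid"].isin(cohort.member_primaryids)
        ]
        sex_counts = summary[summary["characteristic"] == "Gender"].set_index("subgroup")["n"]
        truth_sex = members["sex"].replace({"": "Unknown", "F": "Female", "M": "Male"}).value_counts()
        for label, n in truth_sex.items():
            assert sex_counts.get(label, 0) == n
        # age-group counts + missing = cohort size (generator plants no
        # missing ages inside the age window, so missing count is zero here)
        grp = summary[summary["characteristic"] == "Age group"]["n"].sum()
        assert grp == cohort.n_members

    def test_age_mean_sd_matches_numpy_on_members(self, small_clean):
        _, clean, truth, _ = small_clean
        cohort = select_cohort(clean, CohortSpec(drug_name_patterns=TARGET_PATTERNS))
        summary = descriptive_summary(cohort)
        label = summary.loc[summary["characteristic"] == "Age", "subgroup"].iloc[0]
        members = truth.cases[
            truth.cases["survivor_primaryid"].isin(cohort.member_primaryids)
        ]
        expect = f"{members['age_years'].mean():.2f} ± {members['age_years'].std(ddof=1):.2f}"
        assert expect in label


class TestConcomitants:
    def test_no_concomitants_gives_empty_ranking(self):
        snap = make_snapshot(
            [("1", "1", "20200101", 5, "YR", "F")],
            drug_rows=[("1", "1", "PS", "TAMIFLU", "OSELTAMIVIR")],
            event_rows=[("1", "X")],
        )
        cohort = select_cohort(snap, CohortSpec(drug_name_patterns=TARGET_PATTERNS))
        assert concomitant_summary(cohort).empty

    def test_counts_match_direct_recount_of_mentions(self, small_clean):
        """Oracle: count non-PS, non-target mention rows straight off the table."""
        _, clean, _, _ = small_clean
        cohort = select_cohort(clean, CohortSpec(drug_name_patterns=TARGET_PATTERNS))
        ranked = concomitant_summary(cohort)
        drugs = clean.drugs[clean.drugs["primaryid"].isin(cohort.member_primaryids)]
        manual = {}
        for _, row in drugs.iterrows():
            if row["role_cod"] == "PS":
                continue
            if "OSELTAMIVIR" in row["prod_ai"] or "TAMIFLU" in row["drugname"]:
                continue
            key = row["prod_ai"] or row["drugname"]
            manual[key] = manual.get(key, 0) + 1
        got = dict(zip(ranked["drug"], ranked["n"]))
        assert got == manual
        assert ranked["share"].sum() == pytest.approx(1.0)
        # ties rank alphabetically
        assert list(ranked["drug"]) == sorted(
            ranked["drug"], key=lambda d: (-got[d], d)
        )
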