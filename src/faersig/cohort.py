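"""Target-drug, primary-suspect pediatric cohorting and descriptive tables.

The analysis population is built in two steps: restrict the deduplicated
snapshot to the pediatric stratum (age 0–18 years inclusive after unit
conversion; reports with missing age are excluded), then flag the reports
in which the target drug is the primary suspect (PS).  With the exclusive
PS policy (default) a report qualifies only when every PS mention matches
the target, so no other active ingredient shares the blame.

The unit of downstream counting is the unique (report, preferred term)
pair; the pair table spans the whole background stratum with a membership
flag, ready for contingency building.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AGE_CODES, RawSnapshot

logger = logging.getLogger(__name__)

#: multiplicative factors converting (value, unit code) to years
AGE_UNIT_TO_YEARS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.0,
    "DY": 1.0 / 365.0,
    "HR": 1.0 / 8760.0,
}

AGE_GROUP_LABELS = ("0-1", "2-5", "6-12", "13-18")
_AGE_GROUP_EDGES = (0.0, 2.0, 6.0, 13.0, 18.0 + 1e-9)


def parse_age_years(age_value: float | None, age_code: str | None) -> float:
    """Convert an (age value, unit code) pair to years.

    Missing value propagates; an unknown unit code yields missing with a
    warning rather than an error, since FAERS carries occasional junk codes.
    """
    if age_value is None or (isinstance(age_value, float) and np.isnan(age_value)):
        return float("nan")
    code = (age_code or "").upper()
    if code not in AGE_CODES:
        logger.warning("unknown age unit code %r; treating age as missing", age_code)
        return float("nan")
    return float(age_value) * AGE_UNIT_TO_YEARS[code]


def parse_age_years_vec(age: pd.Series, age_cod: pd.Series) -> pd.Series:
    """Vectorised :func:`parse_age_years` over DEMO columns."""
    factors = age_cod.str.upper().map(AGE_UNIT_TO_YEARS)
    n_unknown = int((factors.isna() & age.notna() & (age_cod.str.strip() != "")).sum())
    if n_unknown:
        logger.warning("%d rows with unknown age unit code treated as missing age", n_unknown)
    return age * factors


def assign_age_group(years: float) -> str:
    """Bin an in-range pediatric age into 0-1 / 2-5 / 6-12 / 13-18 years."""
    if not (0.0 <= years <= 18.0):
        raise ValueError(f"age {years} outside the pediatric range [0, 18]")
    idx = int(np.searchsorted(_AGE_GROUP_EDGES, years, side="right")) - 1
    return AGE_GROUP_LABELS[min(idx, len(AGE_GROUP_LABELS) - 1)]


_PUNCT = re.compile(r"[^A-Z0-9 ]+")
_WS = re.compile(r"\s+")


def normalize_drug_name(name: str) -> str:
    """Uppercase, strip punctuation, collapse whitespace."""
    return _WS.sub(" ", _PUNCT.sub(" ", str(name).upper())).strip()


def match_target_drug(drug_mentions: pd.DataFrame, patterns: list[str]) -> pd.Series:
    """Boolean mask: mention matches iff any pattern is a substring of the
    normalised drugname or active ingredient (case-insensitive)."""
    pats = [normalize_drug_name(p) for p in patterns]
    name = drug_mentions["drugname"].map(normalize_drug_name)
    ai = drug_mentions["prod_ai"].map(normalize_drug_name)
    mask = pd.Series(False, index=drug_mentions.index)
    for p in pats:
        if not p:
            continue
        mask |= name.str.contains(p, regex=False) | ai.str.contains(p, regex=False)
    return mask


@dataclass
class CohortSpec:
    """Cohort definition: name patterns, age window, PS policy, background."""

    drug_name_patterns: list[str]
    age_min_years: float = 0.0
    age_max_years: float = 18.0
    ps_exclusive: bool = True
    background_scope: str = "stratum"  # 'stratum' (age window) or 'full'

    def __post_init__(self) -> None:
        if not self.drug_name_patterns:
            raise ValueError("at least one drug name pattern is required")
        if self.age_min_years > self.age_max_years:
            raise ValueError("age_min_years must not exceed age_max_years")
        if self.background_scope not in {"stratum", "full"}:
            raise ValueError("background_scope must be 'stratum' or 'full'")


@dataclass
class CohortResult:
    """Cohort members, their pair table, and the background they sit in.

    ``pair_table`` has one row per unique (primaryid, pt) pair across the
    background, with ``is_member`` flagging pairs from cohort reports and
    ``sex`` carried along for stratified reruns.
    """

    spec: CohortSpec
    member_primaryids: frozenset[str]
    pair_table: pd.DataFrame
    background: pd.DataFrame  # background reports with parsed age_years
    drugs: pd.DataFrame = field(repr=False, default=None)  # mentions within background

    @property
    def n_members(self) -> int:
        return len(self.member_primaryids)

    @property
    def n_member_pairs(self) -> int:
        return int(self.pair_table["is_member"].sum())


def select_cohort(snapshot: RawSnapshot, spec: CohortSpec) -> CohortResult:
    """Build the cohort and its background pair table from a clean snapshot."""
    reports = snapshot.reports.copy()
    reports["age_years"] = parse_age_years_vec(reports["age"], reports["age_cod"])
    in_stratum = reports["age_years"].between(spec.age_min_years, spec.age_max_years)
    stratum = reports[in_stratum.fillna(False)]

    background = stratum if spec.background_scope == "stratum" else reports
    bg_ids = set(background["primaryid"])

    drugs = snapshot.drugs[snapshot.drugs["primaryid"].isin(bg_ids)]
    ps = drugs[drugs["role_cod"] == "PS"]
    is_target = match_target_drug(ps, spec.drug_name_patterns)
    # member candidates must sit in the pediatric stratum regardless of scope
    stratum_ids = set(stratum["primaryid"])
    with_target_ps = set(ps.loc[is_target, "primaryid"]) & stratum_ids
    if spec.ps_exclusive:
        with_other_ps = set(ps.loc[~is_target, "primaryid"])
        members = frozenset(with_target_ps - with_other_ps)
    else:
        members = frozenset(with_target_ps)
    if not members:
        logger.warning("empty cohort for patterns %s", spec.drug_name_patterns)

    pairs = (
        snapshot.events[snapshot.events["primaryid"].isin(bg_ids)][["primaryid", "pt"]]
        .drop_duplicates()
        .reset_index(drop=True)
    )
    pairs["is_member"] = pairs["primaryid"].isin(members)
    pairs = pairs.merge(
        background[["primaryid", "sex"]], on="primaryid", how="left", validate="m:1"
    )
    return CohortResult(
        spec=spec,
        member_primaryids=members,
        pair_table=pairs,
        background=background.reset_index(drop=True),
        drugs=drugs.reset_index(drop=True),
    )


def _tally(series: pd.Series, total: int, characteristic: str) -> pd.DataFrame:
    counts = series.value_counts(dropna=False)
    return pd.DataFrame(
        {
            "characteristic": characteristic,
            "subgroup": [str(k) if k == k and k != "" else "Unknown" for k in counts.index],
            "n": counts.to_numpy(),
            "pct": np.round(100.0 * counts.to_numpy() / total, 2) if total else 0.0,
        }
    )


def descriptive_summary(cohort: CohortResult, snapshot: RawSnapshot | None = None) -> pd.DataFrame:
    """Demographic tallies for cohort members: long table of
    (characteristic, subgroup, n, pct) plus the age mean ± SD row.

    Proportions are over cohort size.  Outcome tallies are included when the
    snapshot carries an OUTC table.
    """
    members = cohort.background[
        cohort.background["primaryid"].isin(cohort.member_primaryids)
    ]
    n = len(members)
    blocks: list[pd.DataFrame] = []
    if n == 0:
        return pd.DataFrame(columns=["characteristic", "subgroup", "n", "pct"])

    sex = members["sex"].replace({"": "Unknown", "F": "Female", "M": "Male"})
    blocks.append(_tally(sex, n, "Gender"))

    ages = members["age_years"].dropna()
    blocks.append(
        pd.DataFrame(
            {
                "characteristic": ["Age"],
                "subgroup": [
                    f"Mean ± SD: {ages.mean():.2f} ± {ages.std(ddof=1):.2f}"
                    if len(ages) > 1
                    else "Mean ± SD: n/a"
                ],
                "n": [len(ages)],
                "pct": [round(100.0 * len(ages) / n, 2)],
            }
        )
    )
    groups = members["age_years"].dropna().map(assign_age_group)
    grp_counts = groups.value_counts().reindex(AGE_GROUP_LABELS, fill_value=0)
    blocks.append(
        pd.DataFrame(
            {
                "characteristic": "Age group",
                "subgroup": [f"{g} years" for g in grp_counts.index],
                "n": grp_counts.to_numpy(),
                "pct": np.round(100.0 * grp_counts.to_numpy() / n, 2),
            }
        )
    )
    if "occp_cod" in members:
        blocks.append(_tally(members["occp_cod"], n, "Reporter"))
    if "reporter_country" in members:
        blocks.append(_tally(members["reporter_country"], n, "Country"))
    years = members["fda_dt"].dt.year.astype("Int64")
    blocks.append(_tally(years, n, "Year"))
    if snapshot is not None and snapshot.outcomes is not None:
        outc = snapshot.outcomes[
            snapshot.outcomes["primaryid"].isin(cohort.member_primaryids)
        ]
        blocks.append(_tally(outc["outc_cod"], n, "Outcome"))
    return pd.concat(blocks, ignore_index=True)


def concomitant_summary(cohort: CohortResult, top: int | None = None) -> pd.DataFrame:
    """Ranked co-medication mentions within member reports.

    Counts non-PS, non-target drug mentions (the counting unit is the
    mention, not the report); shares are over total concomitant mentions.
    Ties rank alphabetically.
    """
    drugs = cohort.drugs[cohort.drugs["primaryid"].isin(cohort.member_primaryids)]
    is_target = match_target_drug(drugs, cohort.spec.drug_name_patterns)
    conc = drugs[(drugs["role_cod"] != "PS") & ~is_target].copy()
    if conc.empty:
        return pd.DataFrame(columns=["drug", "n", "share"])
    name = conc["prod_ai"].map(normalize_drug_name)
    name = name.where(name != "", conc["drugname"].map(normalize_drug_name))
    counts = name.value_counts()
    out = (
        pd.DataFrame({"drug": counts.index, "n": counts.to_numpy()})
        .sort_values(["n", "drug"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    out["share"] = out["n"] / out["n"].sum()
    return out.head(top) if top else out
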