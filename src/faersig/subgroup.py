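"""Gender-stratified reruns of the disproportionality screen.

Each stratum reruns the full screen with both the cohort membership and
the background restricted to reports of that sex (missing-sex reports are
excluded from both strata), so every stratum compares target-drug
reporting against its own same-sex pediatric background.  The discordance
list collects PTs flagged in exactly one stratum.
"""

from __future__ import annotations

from dataclasses import replace

import pandas as pd

from .cohort import CohortResult
from .signals import DisproportionalityScreen, ScreenResults, SignalCriteria

STRATA = ("F", "M")


def stratify(cohort: CohortResult) -> dict[str, CohortResult]:
    """Split a cohort into same-sex sub-cohorts with same-sex backgrounds."""
    out: dict[str, CohortResult] = {}
    for sex in STRATA:
        bg = cohort.background[cohort.background["sex"] == sex]
        ids = set(bg["primaryid"])
        pairs = cohort.pair_table[cohort.pair_table["primaryid"].isin(ids)].reset_index(drop=True)
        out[sex] = replace(
            cohort,
            member_primaryids=frozenset(cohort.member_primaryids & ids),
            pair_table=pairs,
            background=bg.reset_index(drop=True),
            drugs=cohort.drugs[cohort.drugs["primaryid"].isin(ids)].reset_index(drop=True),
        )
    return out


def subgroup_signals(
    cohort: CohortResult,
    criteria: SignalCriteria | None = None,
    **screen_kwargs,
) -> tuple[dict[str, ScreenResults], pd.DataFrame]:
    """Per-stratum screen results plus the discordance list.

    Returns ``(results, discordance)`` where ``results`` maps 'F'/'M' to
    :class:`ScreenResults` and ``discordance`` lists PTs whose combined
    signal flag is set in exactly one stratum.
    """
    results: dict[str, ScreenResults] = {}
    for sex, sub in stratify(cohort).items():
        res = DisproportionalityScreen.from_cohort(sub, criteria=criteria, **screen_kwargs).fit()
        res.frame.insert(1, "stratum", sex)
        results[sex] = res
    flagged = {sex: set(res.signals["pt"]) for sex, res in results.items()}
    only_f = flagged["F"] - flagged["M"]
    only_m = flagged["M"] - flagged["F"]
    discordance = pd.DataFrame(
        {
            "pt": sorted(only_f) + sorted(only_m),
            "flagged_in": ["F"] * len(only_f) + ["M"] * len(only_m),
        }
    )
    return results, discordance
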