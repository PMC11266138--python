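"""Two-step report deduplication for spontaneous-report snapshots.

A FAERS case may appear as several report versions (follow-ups) sharing a
``caseid`` but carrying distinct ``primaryid``s.  Cleaning follows the FDA
recommendation: first drop every version of a case that appears on a
deleted-case list, then keep a single version per case — the one with the
latest FDA receipt date, ties broken by the higher primaryid (numeric
interpretation).  Deletion runs before version selection so a deleted case
can never resurrect an older version.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .io import RawSnapshot, primaryid_sort_key

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DedupAudit:
    """Record counts emitted by the cleaning steps."""

    n_reports_in: int
    n_deleted_reports: int
    n_cases: int
    n_versions_dropped: int
    n_reports_out: int


def apply_deletions(snapshot: RawSnapshot) -> RawSnapshot:
    """Remove every report whose caseid is on the deletion list.

    Drug and event rows belonging to removed reports go with them.  An
    empty deletion list is the identity.
    """
    if not snapshot.deleted_caseids:
        return snapshot
    keep = snapshot.reports.loc[
        ~snapshot.reports["caseid"].isin(snapshot.deleted_caseids), "primaryid"
    ]
    return snapshot.restrict(keep)


def deduplicate(snapshot: RawSnapshot) -> RawSnapshot:
    """Keep one report version per case: latest fda_dt, then higher primaryid.

    Cases whose versions all lack a receipt date keep the largest
    primaryid (logged).  Idempotent, and insensitive to input row order.
    """
    reports = snapshot.reports
    n_missing_dt_cases = int(
        (~reports["fda_dt"].notna().groupby(reports["caseid"]).max()).sum()
    )
    if n_missing_dt_cases:
        logger.warning(
            "%d case(s) have no parseable fda_dt on any version; keeping largest primaryid",
            n_missing_dt_cases,
        )
    keys = primaryid_sort_key(reports["primaryid"])
    ordered = (
        pd.concat([reports[["primaryid", "caseid", "fda_dt"]], keys], axis=1)
        .sort_values(
            ["caseid", "fda_dt", "_pid_num", "_pid_str"],
            na_position="first",
            kind="mergesort",
        )
    )
    survivors = ordered.groupby("caseid", sort=False).tail(1)["primaryid"]
    return snapshot.restrict(survivors)


def clean_snapshot(snapshot: RawSnapshot) -> tuple[RawSnapshot, DedupAudit]:
    """Apply deletions then deduplication; return the survivor snapshot + audit."""
    n_in = snapshot.n_reports
    after_del = apply_deletions(snapshot)
    n_deleted = n_in - after_del.n_reports
    out = deduplicate(after_del)
    audit = DedupAudit(
        n_reports_in=n_in,
        n_deleted_reports=n_deleted,
        n_cases=out.reports["caseid"].nunique(),
        n_versions_dropped=after_del.n_reports - out.n_reports,
        n_reports_out=out.n_reports,
    )
    return out, audit
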