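"""Shared fixtures: hand-crafted snapshots, generated snapshots, naive oracles."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from faersig.dedup import clean_snapshot
from faersig.io import RawSnapshot
from faersig.synth import default_config, generate_snapshot


def make_snapshot(
    demo_rows: list[tuple],
    drug_rows: list[tuple] | None = None,
    event_rows: list[tuple] | None = None,
    deleted: set[str] = frozenset(),
) -> RawSnapshot:
    """Build a snapshot from terse tuples.

    demo_rows: (primaryid, caseid, fda_dt 'YYYYMMDD' or None, age, age_cod, sex)
    drug_rows: (primaryid, drug_seq, role_cod, drugname, prod_ai)
    event_rows: (primaryid, pt)
    """
    reports = pd.DataFrame(
        demo_rows,
        columns=["primaryid", "caseid", "fda_dt", "age", "age_cod", "sex"],
    )
    reports["fda_dt"] = pd.to_datetime(reports["fda_dt"], format="%Y%m%d", errors="coerce")
    reports["age"] = pd.to_numeric(reports["age"], errors="coerce")
    reports["occp_cod"] = "MD"
    reports["reporter_country"] = "US"
    drugs = pd.DataFrame(
        drug_rows or [],
        columns=["primaryid", "drug_seq", "role_cod", "drugname", "prod_ai"],
    )
    events = pd.DataFrame(event_rows or [], columns=["primaryid", "pt"])
    return RawSnapshot(
        reports=reports,
        drugs=drugs,
        events=events,
        deleted_caseids=frozenset(str(c) for c in deleted),
        provenance=["fixture"],
    )


@pytest.fixture(scope="session")
def small_generated():
    """One modest generated snapshot with defaults, plus its truth."""
    cfg = default_config(2000, seed=424242)
    snapshot, truth = generate_snapshot(cfg)
    return cfg, snapshot, truth


@pytest.fixture(scope="session")
def small_clean(small_generated):
    cfg, snapshot, truth = small_generated
    clean, audit = clean_snapshot(snapshot)
    return cfg, clean, truth, audit


# ---------------------------------------------------------------------------
# independent oracles (plain-Python re-derivations, no faersig internals)

def naive_cells(pair_rows: list[tuple[str, str, bool]], pt: str) -> tuple[int, int, int, int]:
    """Count 2x2 cells by iterating pair rows one at a time."""
    a = b = c = d = 0
    for _pid, row_pt, member in pair_rows:
        if member and row_pt == pt:
            a += 1
        elif member:
            b += 1
        elif row_pt == pt:
            c += 1
        else:
            d += 1
    return a, b, c, d


def naive_stats(a: int, b: int, c: int, d: int) -> dict[str, float]:
    """Direct transcription of the four estimators, scalar math only."""
    n = a + b + c + d
    out: dict[str, float] = {}
    if min(a, b, c, d) > 0:
        sigma = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        ror = a * d / (b * c)
        out["ror"] = ror
        out["ror_l95"] = ror * math.exp(-1.96 * sigma)
        out["ror_u95"] = ror * math.exp(1.96 * sigma)
        ebgm = a * n / ((a + b) * (a + c))
        out["ebgm"] = ebgm
        out["ebgm05"] = ebgm * math.exp(-1.96 * sigma)
    if c > 0 and (a + b) > 0:
        out["prr"] = (a / (a + b)) / (c / (c + d))
        out["chi2"] = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    if a > 0:
        out["ic"] = math.log2(a * n / ((a + b) * (a + c)))
        g11, a1, b1 = 1.0, 1.0, 1.0
        al, be = 2.0, 2.0
        gam = g11 * (n + al) * (n + be) / ((a + b + a1) * (a + c + b1))
        v = (1 / math.log(2) ** 2) * (
            (n - a + gam - g11) / ((a + g11) * (1 + n + gam))
            + (n - (a + b) + al - a1) / ((a + b + a1) * (1 + n + al))
            + (n - (a + c) + be - b1) / ((a + c + b1) * (1 + n + be))
        )
        out["ic025"] = out["ic"] - 2 * math.sqrt(v)
    return out
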