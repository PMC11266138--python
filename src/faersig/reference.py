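"""Published reference signal rows for validating the screen formulas.

The bundled table transcribes signal-strength rows (co-occurrence count,
ROR with 95% CI, PRR with χ², IC with IC025, EBGM with EBGM05) from a
published pediatric pharmacovigilance screen of the two oral influenza
antivirals.  Together with the inversion oracle these rows let the
implementation be checked against published output at desk scale, without
the multi-gigabyte source database.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_reference_rows() -> pd.DataFrame:
    """The bundled reference signal table (one row per published PT)."""
    with resources.files("faersig.data").joinpath("reference_signals.tsv").open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def reference_row(drug: str, pt: str) -> pd.Series:
    """Look up one reference row by drug label and preferred term."""
    df = load_reference_rows()
    hit = df[(df["drug"] == drug) & (df["pt"] == pt)]
    if len(hit) != 1:
        raise KeyError(f"no unique reference row for ({drug!r}, {pt!r})")
    return hit.iloc[0]
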