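"""PT → system-organ-class mapping and SOC-level aggregation.

MedDRA content is licensed, so the mapping arrives as a user-supplied
two-column table (or from the synthetic generator's vocabulary).  PTs and
SOCs are opaque strings here; multi-axial PTs must declare a single
primary SOC.  PTs absent from the map aggregate under ``UNMAPPED``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

UNMAPPED = "UNMAPPED"


@dataclass(frozen=True)
class PtSocMap:
    """Primary PT→SOC mapping (unique PT keys)."""

    mapping: dict[str, str]

    def __len__(self) -> int:
        return len(self.mapping)

    def get(self, pt: str) -> str:
        return self.mapping.get(pt, UNMAPPED)


def load_pt_soc_map(path: str | Path) -> PtSocMap:
    """Load a two-column delimited (pt, soc) file (TSV; header optional).

    A PT listed twice with the same SOC collapses silently; conflicting
    SOCs for one PT are an error.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        return PtSocMap({})
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns[:2]) != ["pt", "soc"]:
        # headerless two-column file
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                         header=None, names=["pt", "soc"])
    df = df[["pt", "soc"]].drop_duplicates()
    dup = df["pt"].duplicated(keep=False)
    if dup.any():
        bad = sorted(df.loc[dup, "pt"].unique())
        raise ValueError(f"conflicting primary SOC for PT(s): {bad[:5]}")
    return PtSocMap(dict(zip(df["pt"], df["soc"])))


def pt_soc_map_from_frame(frame: pd.DataFrame) -> PtSocMap:
    """Build a map from a DataFrame with ``pt`` and ``soc`` columns."""
    df = frame[["pt", "soc"]].drop_duplicates()
    if df["pt"].duplicated().any():
        raise ValueError("conflicting primary SOC assignments")
    return PtSocMap(dict(zip(df["pt"], df["soc"])))


def map_pts(pts: pd.Series, pt_soc_map: PtSocMap) -> pd.Series:
    return pts.map(lambda p: pt_soc_map.get(p))


def soc_summary(
    table: pd.DataFrame,
    pt_soc_map: PtSocMap,
    signals_only: bool = False,
) -> pd.DataFrame:
    """Per-SOC pair counts, shares, and signal counts.

    Accepts either a screen results frame (columns ``pt``/``a`` and
    optionally ``signal``) or a raw pair table (``pt`` rows counted with
    weight one each).  Shares are of the total pair count in the rows
    aggregated; the UNMAPPED share is reported separately on its own row.
    """
    df = table.copy()
    if "a" not in df.columns:
        df = df.groupby("pt", as_index=False).size().rename(columns={"size": "a"})
    if signals_only and "signal" in df.columns:
        df = df[df["signal"]]
    df["soc"] = map_pts(df["pt"], pt_soc_map)
    agg = {"n_pairs": ("a", "sum")}
    if "signal" in df.columns:
        agg["n_signals"] = ("signal", "sum")
    out = df.groupby("soc", as_index=False).agg(**agg)
    total = out["n_pairs"].sum()
    out["share"] = out["n_pairs"] / total if total else 0.0
    return out.sort_values("n_pairs", ascending=False, kind="mergesort").reset_index(drop=True)
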