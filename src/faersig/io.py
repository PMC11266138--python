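"""Readers and writers for FAERS-dialect quarterly ASCII tables.

FAERS quarterly extracts ship as ``$``-delimited text files with a single
header line and no quoting (DEMO, DRUG, REAC, plus optional OUTC), together
with plain-text lists of deleted case identifiers.  Schemas drift across
quarters, so reading is permissive: known columns are normalised, unknown
columns are carried along untouched, and free text is decoded as Latin-1 so
that dirty bytes never abort a load.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

DELIMITER = "$"

#: valid age unit codes (DEMO.age_cod)
AGE_CODES = frozenset({"DEC", "YR", "MON", "WK", "DY", "HR"})

#: valid drug role codes (DRUG.role_cod): primary suspect, secondary
#: suspect, concomitant, interacting
ROLE_CODES = frozenset({"PS", "SS", "C", "I"})

# canonical column sets per table kind; extras are preserved as-is
_REQUIRED: Mapping[str, tuple[str, ...]] = {
    "demo": ("primaryid", "caseid", "fda_dt"),
    "drug": ("primaryid", "drug_seq", "role_cod", "drugname"),
    "reac": ("primaryid", "pt"),
    "outc": ("primaryid", "outc_cod"),
}
_OPTIONAL: Mapping[str, tuple[str, ...]] = {
    "demo": ("age", "age_cod", "sex", "occp_cod", "reporter_country"),
    "drug": ("prod_ai",),
    "reac": (),
    "outc": (),
}
# header variants seen across quarters, mapped onto canonical names
_RENAMES: Mapping[str, str] = {
    "gndr_cod": "sex",
    "isr": "primaryid",
    "case": "caseid",
}


def _read_delimited(path: str | Path) -> pd.DataFrame:
    """Read a ``$``-delimited file as raw strings (no quoting, Latin-1)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FAERS table not found: {path}")
    df = pd.read_csv(
        path,
        sep=DELIMITER,
        dtype=str,
        encoding="latin-1",
        keep_default_na=False,
        quoting=csv.QUOTE_NONE,
        engine="python",
    )
    df.columns = [c.strip().lower() for c in df.columns]
    return df.rename(columns=_RENAMES)


def read_table(path: str | Path, table_kind: str) -> pd.DataFrame:
    """Read one FAERS ASCII table into a normalised DataFrame.

    Parameters
    ----------
    path : str or Path
        ``$``-delimited file with a header line.
    table_kind : {'demo', 'drug', 'reac', 'outc'}
        Which FAERS module the file belongs to.

    Returns
    -------
    DataFrame
        One row per data line.  Canonical columns are normalised
        (``fda_dt`` parsed to datetime, ``age`` to float); unparseable
        dates/ages become missing with a logged warning, the row is kept.
        Unknown columns are preserved verbatim.

    Raises
    ------
    ValueError
        If the header lacks a required column for ``table_kind``.
    """
    kind = table_kind.lower()
    if kind not in _REQUIRED:
        raise ValueError(f"unknown table kind {table_kind!r}")
    df = _read_delimited(path)
    missing = [c for c in _REQUIRED[kind] if c not in df.columns]
    if missing:
        raise ValueError(
            f"malformed header in {path}: missing required column(s) {missing}"
        )
    for col in _OPTIONAL[kind]:
        if col not in df.columns:
            df[col] = ""
    for col in df.columns:
        if df[col].dtype == object:
            df[col] = df[col].str.strip()

    if kind == "demo":
        parsed = pd.to_datetime(df["fda_dt"], format="%Y%m%d", errors="coerce")
        n_bad = int((parsed.isna() & (df["fda_dt"] != "")).sum())
        if n_bad:
            logger.warning("%s: %d unparseable fda_dt values kept as missing", path, n_bad)
        df["fda_dt"] = parsed
        age_num = pd.to_numeric(df["age"].replace("", None), errors="coerce")
        n_bad = int((age_num.isna() & (df["age"] != "")).sum())
        if n_bad:
            logger.warning("%s: %d unparseable age values kept as missing", path, n_bad)
        df["age"] = age_num
        df["age_cod"] = df["age_cod"].str.upper()
        df["sex"] = df["sex"].str.upper().where(df["sex"].str.upper().isin(["F", "M"]), "")
    elif kind == "drug":
        df["role_cod"] = df["role_cod"].str.upper()
    elif kind == "reac":
        df = df[df["pt"] != ""].reset_index(drop=True)
    return df


def read_deleted_cases(paths: Iterable[str | Path]) -> frozenset[str]:
    """Union of case identifiers across zero or more deleted-case list files.

    Each file holds one caseid per line; an optional ``caseid`` header line
    is skipped.  A missing file is a hard error.
    """
    deleted: set[str] = set()
    for path in paths:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"deleted-case list not found: {path}")
        for i, line in enumerate(path.read_text(encoding="latin-1").splitlines()):
            tok = line.strip().split(DELIMITER)[0].strip()
            if not tok:
                continue
            if i == 0 and tok.lower() in {"caseid", "case_id", "case"}:
                continue
            deleted.add(tok)
    return frozenset(deleted)


@dataclass
class RawSnapshot:
    """Parsed multi-table FAERS extract plus deletion list and provenance.

    ``reports``/``drugs``/``events`` hold the DEMO/DRUG/REAC rows;
    ``outcomes`` optionally holds OUTC rows for descriptive tallies.
    Referential orphans (drug/event rows whose primaryid has no DEMO row)
    are counted, not dropped.
    """

    reports: pd.DataFrame
    drugs: pd.DataFrame
    events: pd.DataFrame
    deleted_caseids: frozenset[str] = frozenset()
    outcomes: pd.DataFrame | None = None
    provenance: list[str] = field(default_factory=list)
    referential_warnings: int = 0

    @property
    def n_reports(self) -> int:
        return len(self.reports)

    def restrict(self, primaryids: Iterable[str]) -> "RawSnapshot":
        """Return a snapshot restricted to the given report identifiers."""
        keep = set(primaryids)
        out = replace(
            self,
            reports=self.reports[self.reports["primaryid"].isin(keep)].reset_index(drop=True),
            drugs=self.drugs[self.drugs["primaryid"].isin(keep)].reset_index(drop=True),
            events=self.events[self.events["primaryid"].isin(keep)].reset_index(drop=True),
        )
        if self.outcomes is not None:
            out.outcomes = self.outcomes[
                self.outcomes["primaryid"].isin(keep)
            ].reset_index(drop=True)
        return out


def assemble_snapshot(
    quarters: Sequence[Mapping[str, pd.DataFrame | str]],
    deleted_caseids: Iterable[str] = (),
) -> RawSnapshot:
    """Concatenate per-quarter table sets into one snapshot.

    Parameters
    ----------
    quarters
        Each element maps ``'demo'``/``'drug'``/``'reac'`` (and optionally
        ``'outc'``) to a DataFrame from :func:`read_table`, plus an optional
        ``'source'`` label recorded as provenance.
    deleted_caseids
        Case identifiers from :func:`read_deleted_cases`.

    Raises
    ------
    ValueError
        If ``quarters`` is empty.
    """
    if len(quarters) == 0:
        raise ValueError("assemble_snapshot needs at least one quarter of tables")
    demo = pd.concat([q["demo"] for q in quarters], ignore_index=True)
    drug = pd.concat([q["drug"] for q in quarters], ignore_index=True)
    reac = pd.concat([q["reac"] for q in quarters], ignore_index=True)
    outc_parts = [q["outc"] for q in quarters if "outc" in q]
    outc = pd.concat(outc_parts, ignore_index=True) if outc_parts else None
    provenance = [str(q.get("source", f"quarter-{i}")) for i, q in enumerate(quarters)]

    known = set(demo["primaryid"])
    n_orphan = int((~drug["primaryid"].isin(known)).sum())
    n_orphan += int((~reac["primaryid"].isin(known)).sum())
    if n_orphan:
        logger.warning("%d drug/event rows reference an unknown primaryid", n_orphan)
    return RawSnapshot(
        reports=demo,
        drugs=drug,
        events=reac,
        outcomes=outc,
        deleted_caseids=frozenset(str(c) for c in deleted_caseids),
        provenance=provenance,
        referential_warnings=n_orphan,
    )


def _format_for_write(df: pd.DataFrame, kind: str) -> pd.DataFrame:
    out = df.copy()
    if kind == "demo":
        if pd.api.types.is_datetime64_any_dtype(out["fda_dt"]):
            out["fda_dt"] = out["fda_dt"].dt.strftime("%Y%m%d").fillna("")
        out["age"] = out["age"].map(
            lambda v: "" if pd.isna(v) else (f"{v:g}")
        )
    for col in out.columns:
        out[col] = out[col].astype(str).str.replace(DELIMITER, " ", regex=False)
    return out


def write_table(df: pd.DataFrame, path: str | Path, table_kind: str) -> None:
    """Write a table back out in the ``$``-delimited FAERS dialect."""
    out = _format_for_write(df, table_kind.lower())
    out.to_csv(path, sep=DELIMITER, index=False, quoting=csv.QUOTE_NONE, encoding="latin-1")


def write_snapshot(snapshot: RawSnapshot, outdir: str | Path, tag: str = "SYNTH") -> dict[str, Path]:
    """Write a snapshot as DEMO/DRUG/REAC (+ deleted list) files; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "demo": outdir / f"DEMO{tag}.txt",
        "drug": outdir / f"DRUG{tag}.txt",
        "reac": outdir / f"REAC{tag}.txt",
        "deleted": outdir / f"DELETED{tag}.txt",
    }
    write_table(snapshot.reports, paths["demo"], "demo")
    write_table(snapshot.drugs, paths["drug"], "drug")
    write_table(snapshot.events, paths["reac"], "reac")
    paths["deleted"].write_text(
        "\n".join(sorted(snapshot.deleted_caseids)) + ("\n" if snapshot.deleted_caseids else ""),
        encoding="latin-1",
    )
    return paths


def primaryid_sort_key(series: pd.Series) -> pd.DataFrame:
    """Sort keys implementing 'higher primaryid' with numeric interpretation.

    Identifiers are compared as integers when they parse; non-numeric ids
    fall back to lexicographic order and always sort below numeric ones.
    Returns a two-column frame usable as stable sort keys.
    """
    numeric = pd.to_numeric(series, errors="coerce")
    return pd.DataFrame({"_pid_num": numeric.fillna(float("-inf")), "_pid_str": series.astype(str)})
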