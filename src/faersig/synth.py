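"""Synthetic spontaneous-report generator with planted ground truth.

Emits snapshots in the same multi-table shape the readers consume —
report versions sharing a caseid with increasing receipt dates and
primaryids, a deleted-case list, demographics with mixed age unit codes,
one primary-suspect drug per report plus concomitant mentions, and
per-report preferred-term lists — so every pipeline stage can be tested
offline against known truth.

Each preferred term occurs in a report as an independent Bernoulli event
with probability proportional to its configured marginal (scaled so the
mean event count per report is ``1 + events_lambda``); a report that
draws no event at all receives one PT from the marginal distribution so
every report carries at least one event.  Planted drug–event
associations multiply the PT's occurrence probability by the rate ratio
whenever the report's primary suspect (and, for sex-restricted signals,
its sex) matches, so the planted inclusion-rate ratio equals the
configured value by construction.  Planted PTs should stay rare
(marginal probability ≤ 0.01 in the default vocabulary) so the reporting
odds ratio tracks the planted rate ratio.

All randomness flows from a single integer seed through per-table
substreams, so identical configurations reproduce byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import AGE_UNIT_TO_YEARS
from .io import RawSnapshot
from .soc import PtSocMap, pt_soc_map_from_frame


@dataclass(frozen=True)
class DrugSpec:
    name: str
    prod_ai: str
    prob: float
    trade: str | None = None  # alternative drugname used for ~40% of mentions


@dataclass(frozen=True)
class EventSpec:
    pt: str
    soc: str
    prob: float


@dataclass(frozen=True)
class PlantedSignal:
    """A drug–event association with reporting-rate ratio ``rate_ratio``,
    optionally restricted to one sex stratum."""

    drug: str
    pt: str
    rate_ratio: float
    sex: str | None = None


@dataclass
class SynthConfig:
    """Generator parameters; ``seed`` is mandatory for reproducibility."""

    n_cases: int
    drugs: list[DrugSpec]
    events: list[EventSpec]
    seed: int
    planted: list[PlantedSignal] = field(default_factory=list)
    events_lambda: float = 1.5
    concomitant_lambda: float = 0.8
    duplicate_rate: float = 0.08
    deletion_rate: float = 0.02
    pediatric_frac: float = 0.35
    missing_age_prob: float = 0.05
    sex_probs: dict[str, float] = field(
        default_factory=lambda: {"F": 0.44, "M": 0.48, "": 0.08}
    )
    reporter_probs: dict[str, float] = field(
        default_factory=lambda: {"MD": 0.20, "PH": 0.12, "OT": 0.08, "CN": 0.55, "LW": 0.01, "": 0.04}
    )
    country_probs: dict[str, float] = field(
        default_factory=lambda: {"US": 0.60, "JP": 0.12, "CN": 0.05, "DE": 0.04, "FR": 0.04, "GB": 0.15}
    )
    year_probs: dict[int, float] = field(
        default_factory=lambda: {2019: 0.30, 2020: 0.35, 2021: 0.10, 2022: 0.15, 2023: 0.10}
    )
    n_orphan_events: int = 0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name, probs in [
            ("drugs", [d.prob for d in self.drugs]),
            ("events", [e.prob for e in self.events]),
            ("sex_probs", list(self.sex_probs.values())),
            ("reporter_probs", list(self.reporter_probs.values())),
            ("country_probs", list(self.country_probs.values())),
            ("year_probs", list(self.year_probs.values())),
        ]:
            total = float(np.sum(probs))
            if not np.isclose(total, 1.0, atol=1e-6):
                raise ValueError(f"{name} probabilities sum to {total}, expected 1")
        event_probs = {e.pt: e.prob for e in self.events}
        drug_names = {d.name for d in self.drugs}
        for sig in self.planted:
            if sig.rate_ratio <= 0:
                raise ValueError(f"rate_ratio must be positive: {sig}")
            if sig.drug not in drug_names:
                raise ValueError(f"planted signal references unknown drug {sig.drug!r}")
            if sig.pt not in event_probs:
                raise ValueError(f"planted signal references unknown PT {sig.pt!r}")
            scale = 1.0 + self.events_lambda
            if event_probs[sig.pt] * sig.rate_ratio * scale >= 1.0:
                raise ValueError(
                    f"rate_ratio {sig.rate_ratio} drives the per-report "
                    f"probability of {sig.pt!r} above 1"
                )

    @property
    def pt_soc_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"pt": [e.pt for e in self.events], "soc": [e.soc for e in self.events]}
        )

    def pt_soc_map(self) -> PtSocMap:
        return pt_soc_map_from_frame(self.pt_soc_frame)


@dataclass
class TruthTable:
    """Ground truth for one generated snapshot."""

    planted: pd.DataFrame  # drug, pt, rate_ratio, sex
    cases: pd.DataFrame  # caseid, survivor_primaryid, n_versions, deleted, ps_drug, sex, age_years

    @property
    def n_deleted_cases(self) -> int:
        return int(self.cases["deleted"].sum())

    @property
    def surviving_caseids(self) -> frozenset[str]:
        return frozenset(self.cases.loc[~self.cases["deleted"], "caseid"])


#: default SOC labels used by the bundled vocabulary
_DEFAULT_SOCS = (
    "Psychiatric disorders",
    "Gastrointestinal disorders",
    "General disorders and administration site conditions",
    "Injury, poisoning and procedural complications",
    "Skin and subcutaneous tissue disorders",
    "Nervous system disorders",
    "Respiratory, thoracic and mediastinal disorders",
    "Infections and infestations",
    "Eye disorders",
    "Immune system disorders",
)


def default_config(
    n_cases: int,
    seed: int,
    target_prob: float = 0.08,
    planted: list[PlantedSignal] | None = None,
    n_pts: int = 120,
    **overrides,
) -> SynthConfig:
    """Study-shaped default configuration.

    The drug vocabulary holds a two-name target ("OSELTAMIVIR"/"TAMIFLU"),
    a second antiviral, common pediatric co-medications, and ~5% decoy
    names sharing a three-letter prefix with the target.  The event
    vocabulary spreads ``n_pts`` preferred terms over ten organ classes
    with Zipf-like marginals; the first few PTs are reserved rare terms
    (marginal 0.004) intended for planting.
    """
    other = 1.0 - target_prob
    drugs = [
        DrugSpec("OSELTAMIVIR", "OSELTAMIVIR PHOSPHATE", target_prob, trade="TAMIFLU"),
        DrugSpec("BALOXAVIR MARBOXIL", "BALOXAVIR MARBOXIL", other * 0.06, trade="XOFLUZA"),
        DrugSpec("ACETAMINOPHEN", "ACETAMINOPHEN", other * 0.22),
        DrugSpec("IBUPROFEN", "IBUPROFEN", other * 0.18),
        DrugSpec("AMOXICILLIN", "AMOXICILLIN", other * 0.14),
        DrugSpec("AZITHROMYCIN", "AZITHROMYCIN", other * 0.10),
        DrugSpec("CEFTRIAXONE", "CEFTRIAXONE SODIUM", other * 0.08),
        DrugSpec("CARBOCYSTEINE", "CARBOCYSTEINE", other * 0.07),
        DrugSpec("SALBUTAMOL", "SALBUTAMOL SULFATE", other * 0.06),
        DrugSpec("PREDNISOLONE", "PREDNISOLONE", other * 0.05),
        # decoys sharing the target's 3-letter prefix (~5% of mentions)
        DrugSpec("OSEDRONATE", "OSEDRONATE SODIUM", other * 0.025),
        DrugSpec("OSENOL", "OSENOL", other * 0.015),
    ]
    # rare reserved PTs first (planting slots), then a Zipf tail
    n_reserved = 6
    reserved_mass = 0.004 * n_reserved
    ranks = np.arange(1, n_pts - n_reserved + 1, dtype=float)
    zipf = 1.0 / ranks
    zipf *= (1.0 - reserved_mass) / zipf.sum()
    events = [
        EventSpec(f"PT_{i:03d}", _DEFAULT_SOCS[i % len(_DEFAULT_SOCS)], 0.004)
        for i in range(n_reserved)
    ] + [
        EventSpec(
            f"PT_{i + n_reserved:03d}",
            _DEFAULT_SOCS[(i + n_reserved) % len(_DEFAULT_SOCS)],
            float(p),
        )
        for i, p in enumerate(zipf)
    ]
    if planted is None:
        planted = [
            PlantedSignal("OSELTAMIVIR", "PT_000", 10.0),
            PlantedSignal("OSELTAMIVIR", "PT_001", 4.0),
            PlantedSignal("OSELTAMIVIR", "PT_002", 8.0, sex="F"),
        ]
    return SynthConfig(
        n_cases=n_cases, drugs=drugs, events=events, seed=seed, planted=planted, **overrides
    )


def _choice(rng: np.random.Generator, keys: list, probs: list[float], n: int) -> np.ndarray:
    p = np.asarray(probs, dtype=float)
    return rng.choice(np.asarray(keys, dtype=object), size=n, p=p / p.sum())


def _sample_ages(rng: np.random.Generator, cfg: SynthConfig, n: int):
    """Sample (value, unit code, true years); integer values in unit scale."""
    pediatric = rng.random(n) < cfg.pediatric_frac
    codes = np.empty(n, dtype=object)
    values = np.empty(n, dtype=float)
    # pediatric unit mixture: mostly years, infants in finer units
    ped_units = rng.choice(
        np.array(["YR", "MON", "WK", "DY", "HR"], dtype=object),
        size=n, p=[0.70, 0.15, 0.05, 0.08, 0.02],
    )
    adult_units = rng.choice(np.array(["YR", "DEC"], dtype=object), size=n, p=[0.90, 0.10])
    hi = {"YR": 18, "MON": 216, "WK": 936, "DY": 6570, "HR": 1000}
    for unit, cap in hi.items():
        m = pediatric & (ped_units == unit)
        codes[m] = unit
        values[m] = rng.integers(0, cap + 1, size=int(m.sum()))
    m = ~pediatric & (adult_units == "YR")
    codes[m] = "YR"
    values[m] = rng.integers(19, 91, size=int(m.sum()))
    m = ~pediatric & (adult_units == "DEC")
    codes[m] = "DEC"
    values[m] = rng.integers(2, 10, size=int(m.sum()))
    years = values * np.array([AGE_UNIT_TO_YEARS[c] for c in codes])
    missing = rng.random(n) < cfg.missing_age_prob
    values[missing] = np.nan
    codes[missing] = ""
    years[missing] = np.nan
    return values, codes, years


def _event_weight_groups(cfg: SynthConfig, ps_drug: np.ndarray, sex: np.ndarray):
    """Yield (row indices, per-PT weight vector) honouring planted signals."""
    base = np.array([e.prob for e in cfg.events], dtype=float)
    pt_idx = {e.pt: i for i, e in enumerate(cfg.events)}
    planted_drugs = {s.drug for s in cfg.planted}
    plain = ~np.isin(ps_drug, list(planted_drugs)) if planted_drugs else np.ones(len(ps_drug), bool)
    if plain.any():
        yield np.flatnonzero(plain), base
    for drug in sorted(planted_drugs):
        sigs = [s for s in cfg.planted if s.drug == drug]
        for sex_val in ("F", "M", ""):
            rows = np.flatnonzero((ps_drug == drug) & (sex == sex_val))
            if rows.size == 0:
                continue
            w = base.copy()
            for s in sigs:
                if s.sex is None or s.sex == sex_val:
                    w[pt_idx[s.pt]] *= s.rate_ratio
            yield rows, w


def generate_snapshot(config: SynthConfig) -> tuple[RawSnapshot, TruthTable]:
    """Generate one snapshot plus its ground truth.

    Reports for a duplicated case repeat the case's drug/event content
    under each version's primaryid, with receipt dates non-decreasing in
    version order (occasionally tied, exercising the primaryid
    tie-break).  The generated frames use the same canonical columns the
    readers produce, so writing and re-reading them round-trips.
    """
    cfg = config
    n = cfg.n_cases
    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(cfg.seed).spawn(6)]
    rng_demo, rng_drug, rng_evt, rng_dup, rng_del, rng_misc = streams

    caseids = np.array([str(10_000_000 + i) for i in range(n)], dtype=object)
    sex = _choice(rng_demo, list(cfg.sex_probs), list(cfg.sex_probs.values()), n)
    reporter = _choice(rng_demo, list(cfg.reporter_probs), list(cfg.reporter_probs.values()), n)
    country = _choice(rng_demo, list(cfg.country_probs), list(cfg.country_probs.values()), n)
    year = _choice(rng_demo, list(cfg.year_probs), list(cfg.year_probs.values()), n).astype(int)
    age_val, age_cod, age_years = _sample_ages(rng_demo, cfg, n)

    dup = rng_dup.random(n) < cfg.duplicate_rate
    n_versions = np.where(dup, rng_dup.integers(2, 4, size=n), 1)
    base_date = (
        pd.to_datetime({"year": year, "month": rng_demo.integers(1, 13, n), "day": rng_demo.integers(1, 29, n)})
        if n
        else pd.Series([], dtype="datetime64[ns]")
    )
    deleted = rng_del.random(n) < cfg.deletion_rate

    drug_names = np.array([d.name for d in cfg.drugs], dtype=object)
    ps_idx = rng_drug.choice(len(cfg.drugs), size=n, p=np.array([d.prob for d in cfg.drugs]))
    ps_drug = drug_names[ps_idx]
    n_conc = np.minimum(rng_drug.poisson(cfg.concomitant_lambda, size=n), 5)

    # per-case event PT sets: independent per-PT Bernoulli occurrence,
    # scaled to a mean of (1 + events_lambda) events per report
    n_pts = len(cfg.events)
    scale = 1.0 + cfg.events_lambda
    pts_arr = np.array([e.pt for e in cfg.events], dtype=object)
    case_pts: list[np.ndarray] = [None] * n
    for rows, w in _event_weight_groups(cfg, ps_drug, sex):
        q = np.minimum(w * scale, 1.0 - 1e-12)
        hits = rng_evt.random((rows.size, n_pts)) < q[None, :]
        # empty draws fall back to one PT from the group's distribution
        empty = np.flatnonzero(~hits.any(axis=1))
        if empty.size:
            fallback = rng_evt.choice(n_pts, size=empty.size, p=w / w.sum())
            hits[empty, fallback] = True
        for j, i in enumerate(rows):
            case_pts[i] = pts_arr[hits[j]]

    # expand cases into report versions
    demo_rows, drug_rows, evt_rows = [], [], []
    survivor_pid = np.empty(n, dtype=object)
    trade_flip = rng_misc.random(n) < 0.4
    dose_flip = rng_misc.random(n) < 0.3
    drug_probs = np.array([d.prob for d in cfg.drugs])
    all_conc = rng_drug.choice(len(cfg.drugs), size=int(n_conc.sum()), p=drug_probs)
    conc_offsets = np.concatenate([[0], np.cumsum(n_conc)])
    for i in range(n):
        k = int(n_versions[i])
        date = base_date.iloc[i]
        spec = cfg.drugs[ps_idx[i]]
        ps_name = spec.trade if (spec.trade and trade_flip[i]) else spec.name
        if dose_flip[i]:
            ps_name = f"{ps_name} 75MG"
        conc_idx = all_conc[conc_offsets[i] : conc_offsets[i + 1]]
        for v in range(1, k + 1):
            pid = f"{caseids[i]}{v}"
            if v > 1:
                # follow-ups arrive later; ~20% on the same day (tie-break)
                gap = 0 if rng_dup.random() < 0.2 else int(rng_dup.integers(1, 180))
                date = date + pd.Timedelta(days=gap)
            demo_rows.append(
                (pid, caseids[i], date, age_val[i], age_cod[i], sex[i], reporter[i], country[i])
            )
            drug_rows.append((pid, "1", "PS", ps_name, spec.prod_ai))
            for s_no, ci in enumerate(conc_idx, start=2):
                cspec = cfg.drugs[ci]
                drug_rows.append((pid, str(s_no), "C", cspec.name, cspec.prod_ai))
            for pt in case_pts[i]:
                evt_rows.append((pid, pt))
        survivor_pid[i] = pid

    reports = pd.DataFrame(
        demo_rows,
        columns=["primaryid", "caseid", "fda_dt", "age", "age_cod", "sex", "occp_cod", "reporter_country"],
    )
    reports["fda_dt"] = pd.to_datetime(reports["fda_dt"])
    reports["age"] = pd.to_numeric(reports["age"])
    drugs = pd.DataFrame(
        drug_rows, columns=["primaryid", "drug_seq", "role_cod", "drugname", "prod_ai"]
    )
    events = pd.DataFrame(evt_rows, columns=["primaryid", "pt"])
    for i in range(cfg.n_orphan_events):
        events.loc[len(events)] = (f"99999999{i:03d}", pts_arr[i % n_pts])

    snapshot = RawSnapshot(
        reports=reports,
        drugs=drugs,
        events=events,
        deleted_caseids=frozenset(caseids[deleted]),
        provenance=[f"synth(seed={cfg.seed}, n_cases={n})"],
        referential_warnings=cfg.n_orphan_events,
    )
    truth = TruthTable(
        planted=pd.DataFrame(
            [(s.drug, s.pt, s.rate_ratio, s.sex or "") for s in cfg.planted],
            columns=["drug", "pt", "rate_ratio", "sex"],
        ),
        cases=pd.DataFrame(
            {
                "caseid": caseids,
                "survivor_primaryid": survivor_pid,
                "n_versions": n_versions,
                "deleted": deleted,
                "ps_drug": ps_drug,
                "sex": sex,
                "age_years": age_years,
            }
        ),
    )
    return snapshot, truth


@dataclass(frozen=True)
class RecoveryReport:
    """How well a screen recovered the planted associations."""

    sensitivity: float  # flagged fraction among planted pairs with a >= min_a
    n_eligible: int
    false_flag_rate: float  # combined-flag rate among non-planted pairs with a >= 3
    n_null: int
    log_ror_bias: float  # mean(log ROR - log rate_ratio) over eligible pairs


def estimate_recovery(
    truth: TruthTable,
    results_frame: pd.DataFrame,
    drug: str | None = None,
    min_a: int = 10,
    stratum: str | None = None,
) -> RecoveryReport:
    """Score a screen results frame against the planted truth.

    ``stratum`` names the sex stratum the frame was computed in (None for
    the unstratified screen).  Sex-restricted planted pairs only count
    toward sensitivity/bias when scored in their own stratum, since the
    pooled screen dilutes them with unaffected reports.
    """
    planted = truth.planted
    if drug is not None:
        planted = planted[planted["drug"] == drug]
    planted = planted[planted["sex"].isin(["", stratum or ""])]
    merged = planted.merge(results_frame, on="pt", how="inner", suffixes=("_true", ""))
    eligible = merged[merged["a"] >= min_a]
    sensitivity = float(eligible["signal"].mean()) if len(eligible) else float("nan")
    with np.errstate(invalid="ignore"):
        bias = (
            float(np.nanmean(np.log(eligible["ror"]) - np.log(eligible["rate_ratio"])))
            if len(eligible)
            else float("nan")
        )
    null = results_frame[
        (~results_frame["pt"].isin(truth.planted["pt"])) & (results_frame["a"] >= 3)
    ]
    false_rate = float(null["signal"].mean()) if len(null) else float("nan")
    return RecoveryReport(
        sensitivity=sensitivity,
        n_eligible=len(eligible),
        false_flag_rate=false_rate,
        n_null=len(null),
        log_ror_bias=bias,
    )
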