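"""Four-algorithm disproportionality screening over drug–event pair tables.

For each preferred term the screen forms the 2×2 contingency table of
unique (report, PT) pairs —

    a  target drug & event      b  target drug & other events
    c  other drugs & event      d  other drugs & other events

with N = a+b+c+d — and evaluates four estimators:

* **ROR** = ad/(bc), with the log-normal 95% interval
  ``exp(ln ROR ± 1.96 σ)``, σ² = 1/a + 1/b + 1/c + 1/d;
* **PRR** = [a/(a+b)] / [c/(c+d)], with the Pearson χ² statistic
  (no continuity correction);
* **IC** (BCPNN information component), default form
  ``log2(a·N / ((a+b)(a+c)))`` with IC025 = IC − 2√V(IC) using the
  closed-form BCPNN posterior variance; an optional shrinkage mode applies
  the full Bayesian prior to the point estimate as well;
* **EBGM**, here the relative reporting ratio ``a·N/((a+b)(a+c))`` with
  EBGM05 = exp(ln EBGM − 1.96 σ) sharing σ with the ROR interval (no
  gamma-Poisson hyperparameter shrinkage).

A pair is a signal when all four criteria hold simultaneously:
ROR lower bound > 1, PRR ≥ 2 with χ² ≥ 4, IC025 > 0, EBGM05 ≥ 2,
each additionally requiring a ≥ 3 co-occurrences.  Statistics undefined
because of a zero cell never flag (a Haldane 0.5 correction is available
behind a switch, off by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

LN2 = np.log(2.0)
Z95 = 1.96


@dataclass(frozen=True)
class ContingencyTable:
    """Cells of one (drug, event) 2×2 table of unique (report, PT) pairs."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")
        if self.n == 0:
            raise ValueError("empty contingency table")

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    def swapped(self) -> "ContingencyTable":
        """b↔c swapped table (the alternative cell labelling)."""
        return ContingencyTable(self.a, self.c, self.b, self.d)


@dataclass(frozen=True)
class SignalCriteria:
    """Signal thresholds; defaults are the standard published criteria."""

    min_count: int = 3
    ror_lower_gt: float = 1.0
    prr_min: float = 2.0
    chi2_min: float = 4.0
    ic025_gt: float = 0.0
    ebgm05_min: float = 2.0


def _sigma(a, b, c, d):
    with np.errstate(divide="ignore"):
        return np.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)


def compute_ror(t: ContingencyTable) -> tuple[float, float, float]:
    """Reporting odds ratio with two-sided 95% CI; NaN if any cell is zero."""
    a, b, c, d = t.a, t.b, t.c, t.d
    if min(a, b, c, d) <= 0:
        return (np.nan, np.nan, np.nan)
    ror = (a * d) / (b * c)
    shift = Z95 * _sigma(a, b, c, d)
    return (ror, ror * np.exp(-shift), ror * np.exp(shift))


def compute_prr(t: ContingencyTable) -> tuple[float, float]:
    """Proportional reporting ratio and Pearson χ² (no Yates correction)."""
    a, b, c, d = t.a, t.b, t.c, t.d
    n = t.n
    if (a + b) == 0 or (c + d) == 0 or c == 0:
        return (np.nan, np.nan)
    prr = (a / (a + b)) / (c / (c + d))
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    chi2 = n * (a * d - b * c) ** 2 / denom if denom > 0 else np.nan
    return (prr, chi2)


def _bcpnn_variance(a, b, c, d):
    """Closed-form BCPNN posterior variance of the IC (Bate 1998 priors)."""
    n = a + b + c + d
    alpha1 = beta1 = 1.0
    alpha = beta = 2.0
    gamma11 = 1.0
    gamma = gamma11 * (n + alpha) * (n + beta) / ((a + b + alpha1) * (a + c + beta1))
    return (1.0 / LN2**2) * (
        (n - a + gamma - gamma11) / ((a + gamma11) * (1.0 + n + gamma))
        + (n - (a + b) + alpha - alpha1) / ((a + b + alpha1) * (1.0 + n + alpha))
        + (n - (a + c) + beta - beta1) / ((a + c + beta1) * (1.0 + n + beta))
    )


def compute_ic(t: ContingencyTable, shrinkage: bool = False) -> tuple[float, float]:
    """Information component and its lower bound IC − 2√V(IC).

    Default mode is the plain observed/expected log2 ratio; shrinkage mode
    applies the BCPNN Bayesian prior to the point estimate too.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    n = t.n
    if (a + b) == 0 or (a + c) == 0 or a == 0:
        return (np.nan, np.nan)
    if shrinkage:
        alpha1 = beta1 = 1.0
        alpha = beta = 2.0
        gamma11 = 1.0
        gamma = gamma11 * (n + alpha) * (n + beta) / ((a + b + alpha1) * (a + c + beta1))
        ic = np.log2(
            (a + gamma11) * (n + alpha) * (n + beta)
            / ((n + gamma) * (a + b + alpha1) * (a + c + beta1))
        )
    else:
        ic = np.log2(a * n / ((a + b) * (a + c)))
    v = _bcpnn_variance(a, b, c, d)
    return (ic, ic - 2.0 * np.sqrt(v))


def compute_ebgm(t: ContingencyTable) -> tuple[float, float]:
    """Relative reporting ratio a·N/((a+b)(a+c)) and its lower 95% bound.

    The lower one-sided bound shares σ with the ROR interval:
    EBGM05 = exp(ln EBGM − 1.96 σ), hence EBGM05/EBGM = ROR_l95/ROR exactly.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if min(a, b, c, d) <= 0:
        return (np.nan, np.nan)
    ebgm = a * t.n / ((a + b) * (a + c))
    return (ebgm, ebgm * np.exp(-Z95 * _sigma(a, b, c, d)))


def shared_variance_ebgm05(ebgm: float, ror: float, ror_l95: float) -> float:
    """EBGM05 implied by the shared variance term: EBGM × (ROR_l95/ROR).

    Both the ROR interval and the EBGM lower bound scale the point estimate
    by exp(−1.96 σ) with the same σ, so the ratio transfers between them.
    """
    return ebgm * (ror_l95 / ror)


def compute_stats(t: ContingencyTable, ic_shrinkage: bool = False) -> dict[str, float]:
    """All four estimators and bounds for one table, as a flat dict."""
    ror, l95, u95 = compute_ror(t)
    prr, chi2 = compute_prr(t)
    ic, ic025 = compute_ic(t, shrinkage=ic_shrinkage)
    ebgm, ebgm05 = compute_ebgm(t)
    return {
        "a": t.a, "b": t.b, "c": t.c, "d": t.d,
        "ror": ror, "ror_l95": l95, "ror_u95": u95,
        "prr": prr, "chi2": chi2,
        "ic": ic, "ic025": ic025,
        "ebgm": ebgm, "ebgm05": ebgm05,
    }


def evaluate_criteria(stats: dict[str, float], criteria: SignalCriteria) -> dict[str, bool]:
    """Per-algorithm flags and their conjunction; a < min_count vetoes all."""
    a_ok = stats["a"] >= criteria.min_count

    def ok(value, test) -> bool:
        return bool(a_ok and np.isfinite(value) and test(value))

    flags = {
        "flag_ror": ok(stats["ror_l95"], lambda v: v > criteria.ror_lower_gt),
        "flag_prr": ok(stats["prr"], lambda v: v >= criteria.prr_min)
        and ok(stats["chi2"], lambda v: v >= criteria.chi2_min),
        "flag_ic": ok(stats["ic025"], lambda v: v > criteria.ic025_gt),
        "flag_ebgm": ok(stats["ebgm05"], lambda v: v >= criteria.ebgm05_min),
    }
    flags["signal"] = all(flags.values())
    return flags


def build_contingency(pair_table: pd.DataFrame, pt: str) -> ContingencyTable:
    """2×2 cells for one PT from a pair table with an ``is_member`` flag."""
    member = pair_table["is_member"].to_numpy(dtype=bool)
    hit = (pair_table["pt"] == pt).to_numpy()
    a = int((member & hit).sum())
    b = int((member & ~hit).sum())
    c = int((~member & hit).sum())
    d = int((~member & ~hit).sum())
    return ContingencyTable(a, b, c, d)


def _screen_frame(
    pair_table: pd.DataFrame,
    criteria: SignalCriteria,
    ic_shrinkage: bool,
    zero_cell_correction: float,
) -> pd.DataFrame:
    """Vectorised per-PT statistics over the whole pair table."""
    member = pair_table["is_member"].astype(bool)
    n_total = len(pair_table)
    n_member = int(member.sum())

    counts = (
        pair_table.assign(is_member=member)
        .groupby("pt", sort=False)["is_member"]
        .agg(total="size", member="sum")
        .reset_index()
    )
    counts = counts[counts["member"] >= 1]

    a = counts["member"].to_numpy(dtype=float)
    b = float(n_member) - a
    c = counts["total"].to_numpy(dtype=float) - a
    d = float(n_total - n_member) - c
    if zero_cell_correction > 0:
        zero = (a == 0) | (b == 0) | (c == 0) | (d == 0)
        a = a + zero_cell_correction * zero
        b = b + zero_cell_correction * zero
        c = c + zero_cell_correction * zero
        d = d + zero_cell_correction * zero
    n = a + b + c + d

    with np.errstate(divide="ignore", invalid="ignore"):
        sigma = _sigma(a, b, c, d)
        ror = np.where((b > 0) & (c > 0) & (a > 0) & (d > 0), a * d / (b * c), np.nan)
        ror_l95 = ror * np.exp(-Z95 * sigma)
        ror_u95 = ror * np.exp(Z95 * sigma)
        prr = np.where((c > 0) & (a + b > 0), (a / (a + b)) / (c / (c + d)), np.nan)
        denom = (a + b) * (c + d) * (a + c) * (b + d)
        chi2 = np.where(denom > 0, n * (a * d - b * c) ** 2 / denom, np.nan)
        rrr = np.where((a > 0) & (a + b > 0) & (a + c > 0), a * n / ((a + b) * (a + c)), np.nan)
        if ic_shrinkage:
            gamma = (n + 2.0) * (n + 2.0) / ((a + b + 1.0) * (a + c + 1.0))
            ic = np.log2(
                (a + 1.0) * (n + 2.0) * (n + 2.0)
                / ((n + gamma) * (a + b + 1.0) * (a + c + 1.0))
            )
        else:
            ic = np.log2(rrr)
        vic = _bcpnn_variance(a, b, c, d)
        ic025 = ic - 2.0 * np.sqrt(vic)
        ebgm = rrr
        ebgm05 = ebgm * np.exp(-Z95 * sigma)

    frame = pd.DataFrame(
        {
            "pt": counts["pt"].to_numpy(),
            "a": a.astype(int), "b": b.astype(int),
            "c": c.astype(int), "d": d.astype(int),
            "ror": ror, "ror_l95": ror_l95, "ror_u95": ror_u95,
            "prr": prr, "chi2": chi2,
            "ic": ic, "ic025": ic025,
            "ebgm": ebgm, "ebgm05": ebgm05,
        }
    )
    a_ok = frame["a"] >= criteria.min_count
    fin = lambda col: np.isfinite(frame[col].to_numpy())
    frame["flag_ror"] = a_ok & fin("ror_l95") & (frame["ror_l95"] > criteria.ror_lower_gt)
    frame["flag_prr"] = (
        a_ok
        & fin("prr") & (frame["prr"] >= criteria.prr_min)
        & fin("chi2") & (frame["chi2"] >= criteria.chi2_min)
    )
    frame["flag_ic"] = a_ok & fin("ic025") & (frame["ic025"] > criteria.ic025_gt)
    frame["flag_ebgm"] = a_ok & fin("ebgm05") & (frame["ebgm05"] >= criteria.ebgm05_min)
    frame["signal"] = frame[["flag_ror", "flag_prr", "flag_ic", "flag_ebgm"]].all(axis=1)
    return frame.sort_values(
        ["a", "pt"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


class DisproportionalityScreen:
    """Disproportionality model over a drug–event pair table.

    Parameters
    ----------
    pair_table : DataFrame
        Unique (primaryid, pt) pairs with a boolean ``is_member`` column
        flagging pairs from target-drug reports (see
        :func:`faersig.cohort.select_cohort`).
    drug : str
        Label carried into results tables.
    criteria : SignalCriteria, optional
    ic_shrinkage : bool
        Use the Bayesian-shrunk IC point estimate instead of the plain
        observed/expected form.
    zero_cell_correction : float
        Haldane-style constant added to all four cells of tables with a
        zero cell (0 disables; undefined statistics then never flag).
    """

    def __init__(
        self,
        pair_table: pd.DataFrame,
        drug: str = "target",
        criteria: SignalCriteria | None = None,
        ic_shrinkage: bool = False,
        zero_cell_correction: float = 0.0,
    ) -> None:
        required = {"primaryid", "pt", "is_member"}
        if not required <= set(pair_table.columns):
            raise ValueError(f"pair_table must have columns {sorted(required)}")
        if pair_table.duplicated(["primaryid", "pt"]).any():
            raise ValueError("pair_table contains duplicated (primaryid, pt) rows")
        self.pair_table = pair_table
        self.drug = drug
        self.criteria = criteria or SignalCriteria()
        self.ic_shrinkage = ic_shrinkage
        self.zero_cell_correction = zero_cell_correction

    @classmethod
    def from_cohort(cls, cohort, **kwargs) -> "DisproportionalityScreen":
        """Build a screen from a :class:`~faersig.cohort.CohortResult`."""
        drug = kwargs.pop("drug", cohort.spec.drug_name_patterns[0])
        return cls(cohort.pair_table, drug=drug, **kwargs)

    def contingency(self, pt: str) -> ContingencyTable:
        return build_contingency(self.pair_table, pt)

    def fit(self) -> "ScreenResults":
        """Screen every PT with at least one member co-occurrence."""
        frame = _screen_frame(
            self.pair_table, self.criteria, self.ic_shrinkage, self.zero_cell_correction
        )
        frame.insert(0, "drug", self.drug)
        return ScreenResults(self, frame)


class ScreenResults:
    """Fitted screen: per-PT estimates, interval bounds, and signal flags.

    ``frame`` holds one row per PT (a ≥ 1), sorted by descending
    co-occurrence count, with columns drug, pt, a–d, the four estimators
    with their bounds, per-criterion flags, and the combined ``signal``.
    """

    def __init__(self, model: DisproportionalityScreen, frame: pd.DataFrame) -> None:
        self.model = model
        self.frame = frame

    @property
    def signals(self) -> pd.DataFrame:
        """Rows meeting all four criteria simultaneously."""
        return self.frame[self.frame["signal"]].reset_index(drop=True)

    @property
    def n_signals(self) -> int:
        return int(self.frame["signal"].sum())

    def with_soc(self, pt_soc_map) -> pd.DataFrame:
        """Results frame with a ``soc`` column from a PT→SOC mapping."""
        from .soc import map_pts  # local import to avoid a cycle

        frame = self.frame.copy()
        frame.insert(2, "soc", map_pts(frame["pt"], pt_soc_map))
        return frame

    def summary(self, top: int = 20) -> str:
        """Plain-text summary table of the strongest rows."""
        n_member = int(self.model.pair_table["is_member"].sum())
        lines = [
            "Disproportionality screen",
            "=" * 60,
            f"drug: {self.model.drug}",
            f"background pairs: {len(self.model.pair_table)}"
            f"  (member pairs: {n_member})",
            f"PTs screened: {len(self.frame)}   signals: {self.n_signals}",
            "-" * 60,
        ]
        cols = ["pt", "a", "ror", "ror_l95", "ror_u95", "prr", "chi2",
                "ic", "ic025", "ebgm", "ebgm05", "signal"]
        show = self.frame[cols].head(top).copy()
        for c in cols[2:-1]:
            show[c] = show[c].map(lambda v: f"{v:.2f}" if np.isfinite(v) else "--")
        lines.append(show.to_string(index=False))
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<ScreenResults drug={self.model.drug!r} "
            f"n_pts={len(self.frame)} n_signals={self.n_signals}>"
        )


def screen_all(
    pair_table: pd.DataFrame,
    drug: str = "target",
    criteria: SignalCriteria | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Functional wrapper: fit a :class:`DisproportionalityScreen`, return the frame."""
    return DisproportionalityScreen(pair_table, drug=drug, criteria=criteria, **kwargs).fit().frame
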