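"""Recover contingency cells from published disproportionality statistics.

ROR, χ², IC and EBGM are all symmetric under swapping the off-diagonal
cells b and c, so a published quadruple (a, ROR, ROR lower bound, EBGM)
pins down the symmetric functions s = b+c and p = b·c together with d,
via three relations:

* ``ROR = a·d / p``
* ``σ² = (ln(ROR / ROR_l95) / 1.96)² = 1/a + 1/d + s/p``
* ``EBGM = a·N / ((a+b)(a+c)) = a·N / (a² + a·s + p)`` with ``N = a+s+d``

Eliminating p and s leaves a single equation in d, solved by bracketed
root-finding over a wide logarithmic range.  Every b↔c-symmetric
statistic is then a closed form in (a, s, p, d) — for instance
``(a+b)(a+c) = a² + a·s + p`` and ``(b+d)(c+d) = d² + d·s + p`` — so χ²,
IC, EBGM and the interval bounds can be recomputed without ever splitting
s and p into individual cells.  The split (the roots of
``x² − s·x + p = 0``) exists only when s² ≥ 4p; it is needed solely for
the asymmetric PRR, which takes one value per (b, c) assignment.  This
turns published signal-table rows into desk-scale checks without access
to the source database.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as _dc_replace

import numpy as np
from scipy.optimize import brentq

from .signals import Z95, ContingencyTable, compute_ic, compute_prr


@dataclass(frozen=True)
class RecoveredCells:
    """Solution of the inversion: symmetric cells plus optional split."""

    a: float
    s: float  # b + c
    p: float  # b * c
    d: float
    residuals: dict[str, float]
    #: number of distinct consistent solutions found; >1 means the inputs do
    #: not pin the cells down (e.g. ROR = EBGM makes the system rank-deficient)
    n_candidates: int = 1

    @property
    def n(self) -> float:
        return self.a + self.s + self.d

    @property
    def has_real_split(self) -> bool:
        """Whether s² ≥ 4p, i.e. real individual (b, c) cells exist."""
        return self.s * self.s >= 4.0 * self.p * (1.0 - 1e-9)

    @property
    def bc_assignments(self) -> tuple[tuple[float, float], tuple[float, float]]:
        """The two (b, c) root pairs of x² − s·x + p = 0 (larger-b first)."""
        disc = self.s * self.s - 4.0 * self.p
        if disc < 0:
            if disc > -1e-6 * self.s * self.s:
                disc = 0.0
            else:
                raise ValueError(
                    "s^2 < 4p: the symmetric solution admits no real (b, c) split"
                )
        root = math.sqrt(disc)
        hi, lo = (self.s + root) / 2.0, (self.s - root) / 2.0
        return ((hi, lo), (lo, hi))

    def table(self, assignment: int = 0) -> ContingencyTable:
        b, c = self.bc_assignments[assignment]
        return ContingencyTable(self.a, b, c, self.d)


def _forward(a: float, s: float, p: float, d: float) -> tuple[float, float, float]:
    """(ROR, σ, EBGM) implied by symmetric cells."""
    n = a + s + d
    ror = a * d / p
    sigma = math.sqrt(1.0 / a + 1.0 / d + s / p)
    ebgm = a * n / (a * a + a * s + p)
    return ror, sigma, ebgm


def recover_cells(
    a: float,
    ror: float,
    ror_l95: float,
    ebgm: float,
    d_bounds: tuple[float, float] = (1e2, 1e8),
    n_grid: int = 600,
    rel_tol: float = 5e-3,
) -> RecoveredCells:
    """Solve for (s, p, d) from a published (a, ROR, ROR_l95, EBGM) row.

    Scans d over a log-spaced grid inside ``d_bounds`` for sign changes of
    the EBGM residual, polishes each bracket with Brent's method, and keeps
    the candidate whose recomputed inputs best reproduce the originals
    (preferring candidates that admit a real (b, c) split).  Raises
    ``ValueError`` naming the offending inputs when no candidate
    reproduces all three inputs within ``rel_tol`` relative error.
    """
    if min(a, ror, ror_l95, ebgm) <= 0:
        raise ValueError("all inputs must be positive")
    if ror_l95 >= ror:
        raise ValueError("ror_l95 must lie below ror")
    sigma = math.log(ror / ror_l95) / Z95
    sig2 = sigma * sigma

    def s_of(d: float) -> float:
        return (sig2 - 1.0 / a - 1.0 / d) * a * d / ror

    def p_of(d: float) -> float:
        return a * d / ror

    def g(logd: float) -> float:
        d = math.exp(logd)
        s = s_of(d)
        if s <= 0:
            return math.inf
        p = p_of(d)
        n = a + s + d
        return ebgm * (a * a + a * s + p) - a * n

    lo, hi = (math.log(b) for b in d_bounds)
    grid = np.linspace(lo, hi, n_grid)
    vals = np.array([g(x) for x in grid])
    candidates: list[RecoveredCells] = []
    for i in range(len(grid) - 1):
        v0, v1 = vals[i], vals[i + 1]
        if not (np.isfinite(v0) and np.isfinite(v1)) or v0 * v1 > 0:
            continue
        logd = brentq(g, grid[i], grid[i + 1], xtol=1e-13, rtol=1e-14)
        d = math.exp(logd)
        s, p = s_of(d), p_of(d)
        if s <= 0 or p <= 0:
            continue
        r_ror, r_sigma, r_ebgm = _forward(a, s, p, d)
        residuals = {
            "ror": abs(r_ror / ror - 1.0),
            "sigma": abs(r_sigma / sigma - 1.0),
            "ebgm": abs(r_ebgm / ebgm - 1.0),
        }
        candidates.append(RecoveredCells(a=a, s=s, p=p, d=d, residuals=residuals))
    good = [c for c in candidates if max(c.residuals.values()) < rel_tol]
    if not good:
        raise ValueError(
            f"no consistent cells for a={a}, ror={ror}, ror_l95={ror_l95}, "
            f"ebgm={ebgm} within d bounds {d_bounds}"
        )
    distinct: list[RecoveredCells] = []
    for c in sorted(good, key=lambda c: c.d):
        if not distinct or abs(c.d / distinct[-1].d - 1.0) > 1e-6:
            distinct.append(c)
    best = min(distinct, key=lambda c: (not c.has_real_split, max(c.residuals.values())))
    return _dc_replace(best, n_candidates=len(distinct))


def predict_statistic(cells: RecoveredCells, which: str):
    """Evaluate a screening statistic on recovered cells.

    Symmetric statistics ('ror', 'ror_l95', 'chi2', 'ic', 'ebgm',
    'ebgm05') are closed forms in (a, s, p, d) and never require the
    (b, c) split.  'prr' returns a tuple with the value under each
    assignment, and 'ic025' needs the individual margins; both raise when
    no real split exists.
    """
    a, s, p, d = cells.a, cells.s, cells.p, cells.d
    n = cells.n
    m_ab_ac = a * a + a * s + p  # (a+b)(a+c)
    m_bd_cd = d * d + d * s + p  # (b+d)(c+d)
    sigma = math.sqrt(1.0 / a + 1.0 / d + s / p)
    if which == "ror":
        return a * d / p
    if which == "ror_l95":
        return (a * d / p) * math.exp(-Z95 * sigma)
    if which == "chi2":
        return n * (a * d - p) ** 2 / (m_ab_ac * m_bd_cd)
    if which == "ic":
        return math.log2(a * n / m_ab_ac)
    if which == "ebgm":
        return a * n / m_ab_ac
    if which == "ebgm05":
        return (a * n / m_ab_ac) * math.exp(-Z95 * sigma)
    if which == "ic025":
        return compute_ic(cells.table(0))[1]
    if which == "prr":
        return (compute_prr(cells.table(0))[0], compute_prr(cells.table(1))[0])
    raise ValueError(f"unknown statistic {which!r}")
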