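# Methods

## Scope and data model

`faersig` implements a spontaneous-report disproportionality screen of
the kind used for post-marketing drug safety surveillance on the FDA
Adverse Event Reporting System (FAERS). The raw material is the set of
quarterly multi-table extracts: DEMO (one row per report version), DRUG
(one row per drug mention with a role code), REAC (one row per reported
preferred term, PT), plus plain lists of deleted case identifiers. A
*case* may appear as several report versions (follow-ups) sharing a
`caseid` under distinct `primaryid`s.

The counting unit throughout is the **unique (report, PT) pair**. A
report contributes one pair per distinct PT it lists; the background for
a screen is the set of all pairs in the chosen scope, and the 2×2 table
for a (drug, PT) combination partitions those pairs by membership of the
drug's cohort and occurrence of the PT.

## Cleaning

Cleaning is two-step and order matters:

1. **Deletions.** Any report whose `caseid` appears on a deleted-case
   list is removed, together with its drug and event rows. Deletion
   lists from multiple quarters are applied as a cumulative union.
2. **Version selection.** Among the remaining versions of a case, the
   survivor is the one with the latest FDA receipt date (`fda_dt`); ties
   are broken by the higher `primaryid`, comparing identifiers as
   integers where they parse (non-numeric identifiers fall back to
   lexicographic order and sort below numeric ones). If no version of a
   case carries a parseable date, the largest `primaryid` survives and a
   warning is logged.

Running deletions first guarantees a deleted case can never "resurrect"
an older version. The operation is idempotent and insensitive to input
row order; both properties are tested.

Only exact `caseid` duplicates are collapsed. Probabilistic detection of
duplicates filed under different case identifiers is out of scope, so
residual duplicates in real data can inflate counts.

## Cohort definition

The pediatric stratum is **0 ≤ age ≤ 18 years inclusive** after unit
conversion (DEC×10, YR×1, MON/12, WK/52, DY/365, HR/8760); reports with
missing or unconvertible age are excluded from the stratum rather than
imputed. Cohort members are stratum reports in which the target drug has
role `PS` (primary suspect). Drug matching is case-insensitive substring
search of user-supplied name patterns (generic plus trade names) against
the drug name and active-ingredient fields, after uppercasing, stripping
punctuation and collapsing whitespace; no external drug dictionary is
consulted. With the default exclusive-PS policy a report qualifies only
if *every* PS mention matches the target, so no other ingredient shares
primary suspicion; the policy is configurable because multi-PS reports
are rare but real.

The background defaults to the pediatric stratum itself (members are
contrasted against all other pediatric pairs) and can be switched to the
full deduplicated database. Concomitant-medication tables count non-PS,
non-target *mentions* (not reports), ranked with alphabetical
tie-breaks.

## The four estimators

With cells *a, b, c, d* (target∧event, target∧other-events,
other-drugs∧event, neither) and *N = a+b+c+d*:

| Estimator | Point form | Interval / test | Signal rule |
|---|---|---|---|
| ROR | *ad/(bc)* | `exp(ln ROR ± 1.96σ)`, σ² = 1/a+1/b+1/c+1/d | lower bound > 1, a ≥ 3 |
| PRR | [a/(a+b)]/[c/(c+d)] | Pearson χ², no continuity correction | PRR ≥ 2, χ² ≥ 4, a ≥ 3 |
| IC | log₂[aN/((a+b)(a+c))] | IC025 = IC − 2√V(IC), BCPNN variance | IC025 > 0, a ≥ 3 |
| EBGM | aN/((a+b)(a+c)) | EBGM05 = exp(ln EBGM − 1.96σ), same σ as ROR | EBGM05 ≥ 2, a ≥ 3 |

The combined signal is the conjunction of all four rules, which by
construction can never flag more often than the strictest single rule.

Two deliberate departures from textbook Bayesian practice, matching the
non-shrunk forms this screen is meant to reproduce:

- **EBGM is the plain relative reporting ratio**, not a gamma-Poisson
  shrinkage estimate: no hyperparameters are fitted, and its lower bound
  shares the lognormal σ with the ROR interval, making
  EBGM05/EBGM = ROR_l95/ROR an exact identity. Published screens of this
  family print exactly these values (their IC equals log₂ EBGM to
  rounding on every row we transcribed, which is only possible if no
  shrinkage was applied), and the identity is what makes the inversion
  oracle below work.
- **IC defaults to the unshrunk observed/expected log-ratio.** The
  Bayesian (Bate 1998) prior-shrunk point estimate is available behind
  `ic_shrinkage=True`. IC025 always uses the closed-form BCPNN posterior
  variance with the standard priors (α₁=β₁=1, α=β=2, γ₁₁=1); printed
  IC025 values in the literature vary with implementation detail and are
  not treated as reproducible benchmarks.

**Zero cells.** Any zero cell leaves the affected statistics undefined
(NaN) and undefined statistics never flag. A Haldane-style correction
(add a constant, conventionally 0.5, to all four cells of affected
tables) is available via `zero_cell_correction` but off by default, so
default output matches the uncorrected formulas.

## Gender subgroups

Each stratum re-runs the identical screen with membership *and*
background restricted to reports of one sex; missing-sex reports drop
out of both strata. Comparing each sex against its own same-sex
background keeps the stratum's expectation internally consistent; the
pooled background remains available through the configuration. The
discordance list is the set of PTs flagged in exactly one stratum. No
formal interaction test between strata is computed.

## SOC aggregation

PT→SOC mapping is a user-supplied two-column table (MedDRA is licensed
content and not bundled); PTs and SOCs are opaque strings, multi-axial
PTs must declare one primary SOC, and unmapped PTs aggregate under
`UNMAPPED` on their own row. Per-SOC output is the summed pair counts,
their share of the total, and the number of combined signals.

## Synthetic-report generator

The generator emulates the structural features of the real extracts that
the pipeline's correctness depends on: multi-table structure keyed by
report/case identifiers; duplicate case versions (default 8% of cases,
2–3 versions) with non-decreasing receipt dates, occasionally tied to
exercise the primaryid tie-break; a deletion list (default 2% of cases);
demographics with mixed age unit codes (integer values in YR/MON/WK/DY/HR
for children, YR/DEC for adults, 35% pediatric, 5% missing age), sex
including missing (44/48/8%), reporter, country and year categoricals;
one PS drug per case from a vocabulary containing the two-name target,
common pediatric co-medications and ~5% decoy names sharing the target's
three-letter prefix; 0–5 concomitant mentions; and per-report PT lists.

**Event model.** Each PT occurs in a report as an independent Bernoulli
draw with probability `marginal × (1 + λ)` (λ = 1.5, giving a mean of
2.5 events per report); a report drawing no event receives one PT from
the normalized weight vector so every report has at least one event. A
planted (drug, PT, rate ratio) association — optionally restricted to
one sex — multiplies that PT's occurrence probability by the rate ratio
whenever the report's PS drug (and sex) matches. Because occurrence is
Bernoulli per PT, the member/non-member inclusion ratio equals the
configured rate ratio by construction; sampling PTs *without
replacement* from a reweighted multinomial was rejected because its
inclusion probabilities are concave in the weights, which attenuates
planted ratios by tens of percent. Planted PTs default to marginal
probability 0.004 so that pair-level reporting odds ratios track the
planted rate ratio (measured mean log-ROR bias across 20 seeds:
−0.03/+0.02/+0.01 for rate ratios 2/5/10).

All randomness derives from one integer seed through per-table
substreams, so equal configurations produce byte-identical files.

**What the generator does not emulate** — and hence what passing tests
do not establish about real FAERS data: free-text drug-name noise beyond
simple decoys (no misspellings, salts, combination products), reporting
biases and event correlations (events are conditionally independent
given the drug), temporal reporting trends, duplicates filed under
different caseids, and real MedDRA vocabulary structure. Results on real
extracts additionally depend on name-pattern completeness and the
supplied PT→SOC map.

## Inversion oracle

ROR, χ², IC and EBGM are symmetric under swapping b and c, so a
published row (a, ROR, ROR lower bound, EBGM) constrains only
s = b+c, p = b·c and d, through

    ROR = a·d/p
    σ²  = (ln(ROR/ROR_l95)/1.96)² = 1/a + 1/d + s/p
    EBGM = a·N/(a² + a·s + p),   N = a + s + d.

Eliminating p and s leaves one equation in d, solved by scanning a
600-point logarithmic grid over d ∈ [10², 10⁸] for sign changes and
polishing each bracket with Brent's method (xtol 10⁻¹³). A candidate is
accepted when re-evaluating the three inputs from (s, p, d) reproduces
them within 0.5% — the tolerance implied by inputs printed to 3–4
significant figures. Every b↔c-symmetric statistic is then a closed form
in (a, s, p, d), e.g. χ² = N(ad−p)²/[(a²+as+p)(d²+ds+p)], and never
requires splitting s and p into individual cells; only the asymmetric
PRR (reported for both assignments) and IC025 need the real roots of
x² − s·x + p = 0.

Conditioning caveats, all surfaced by the implementation:

- s multiplies the *small difference* σ² − 1/a − 1/d, so for small-count
  rows the printed rounding of the ROR lower bound dominates and
  individual cells are unreliable even when χ²/IC/EBGM05 (which are
  stable functions of the inputs) reproduce to a fraction of a percent.
  Rows whose rounded inputs admit no consistent solution raise a
  `ValueError` naming them.
- When ROR = EBGM (e.g. b = a) the system is rank-deficient: a
  one-parameter family of tables shares identical statistics.
  `recover_cells` reports the number of distinct solutions found
  (`n_candidates`); cell identity is only asserted when it is 1.

On the 64 transcribed benchmark rows, 48 invert cleanly; recovered cells
reproduce published χ² to <0.2% and IC to <0.007, and the
shared-variance identity holds within 0.35% on every row.

## Numerical and testing choices

- Screens are vectorised per-PT groupbys; a pure-Python per-row recount
  with independently re-derived scalar formulas serves as the oracle, at
  exact cell equality and 10⁻¹² relative statistic tolerance, across 50
  generated snapshots.
- Sorting is stable (mergesort) everywhere a tie-break is meaningful:
  screen rows by descending a then PT name; concomitants by count then
  name; forest data by SOC, descending a, then PT.
- Simulation sizes in the test suite were chosen to keep the whole suite
  in the low minutes on a single core while giving each check adequate
  counts: 20 seeds × 30,000 cases for rate-ratio recovery (expected
  co-occurrence ≥ 25 at the smallest ratio), 100 replicates × 20,000
  cases for interval coverage of a null rate ratio, 45,000 cases
  (≈10⁵ background pairs) for the all-null conjunction check.
- Degenerate inputs: empty cohorts produce valid empty, schema-stable
  outputs; header-only files parse to empty tables; unparseable dates or
  ages become missing values with warnings, never row drops.

## Known limitations

Disproportionality measures reporting association, not risk or
causation; no multiple-testing adjustment is applied (deliberately, to
match the screen this package reproduces); the EBGM/IC forms are the
printed non-shrunk variants, so small-count rows are noisier than under
true empirical-Bayes shrinkage; the full-database replication of a
multi-gigabyte FAERS pull is supported by the same code path (file
ingestion is tested on generated FAERS-format files) but is not part of
the desk-scale test suite.
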