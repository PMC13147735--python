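"""Per-symptom exact-test screening between patient groups.

For each catalogued symptom a 2x2 table (group x present/absent) is tested
with Fisher's exact test (two-sided, point-probability method: the p-value
sums the hypergeometric probabilities of all tables with the same margins
whose probability does not exceed that of the observed table). Effect sizes
are conditional maximum-likelihood odds ratios — the value maximising
Fisher's noncentral hypergeometric likelihood given all margins, which is
what R's ``fisher.test`` reports and shrinks toward 1 relative to the sample
odds ratio. Familywise error over the symptom list is controlled with the
Holm step-down adjustment.

Orientation note: odds ratios are reported as (odds of the symptom among the
comparator group) / (odds among cases) — the direction used in the published
screening table — so values BELOW 1 mark case-enriched symptoms. This is the
reverse of the conventional case-exposure odds ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact as _scipy_fisher
from scipy.stats.contingency import odds_ratio as _scipy_odds_ratio
from statsmodels.stats.multitest import multipletests

from .cohort import Cohort

COMPARATORS = ("controls", "non_cases")


class DegenerateTableError(ValueError):
    """Both margins of one orientation are empty; the odds ratio is undefined."""


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 count table with fixed orientation.

    ``a``/``b``: cases with the symptom present/absent;
    ``c``/``d``: comparator patients with the symptom present/absent.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"count {name}={v!r} must be a non-negative integer")
        if self.a + self.b == 0 or self.c + self.d == 0:
            raise ValueError("each row of the 2x2 table needs at least one observation")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def transposed_groups(self) -> "ContingencyTable":
        return ContingencyTable(self.c, self.d, self.a, self.b)


@dataclass(frozen=True)
class ScreeningConfig:
    alpha: float = 0.05
    candidate_threshold: float = 0.001
    comparator: str = "controls"
    use_adjusted_for_threshold: bool = False
    with_odds_ratio: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")
        if not 0 < self.candidate_threshold < 1:
            raise ValueError("candidate_threshold must be in (0,1)")
        if self.comparator not in COMPARATORS:
            raise ValueError(f"comparator must be one of {COMPARATORS}")


@dataclass
class ScreeningResult:
    symptom_id: str
    organ_system: str
    table: ContingencyTable
    case_count: int
    case_denominator: int
    comparator_count: int
    comparator_denominator: int
    p_raw: float
    p_holm: float
    odds_ratio_cmle: float
    odds_ratio_haldane: float
    candidate: bool
    testable: bool = True


def fisher_exact_2x2(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p-value (point-probability method).

    Degenerate symptom margins (no patient has the symptom, or all do) carry
    no information; they return p = 1.0 with a warning.
    """
    if table.a + table.c == 0 or table.b + table.d == 0:
        warnings.warn("degenerate symptom margin; returning p = 1", stacklevel=2)
        return 1.0
    return float(
        _scipy_fisher([[table.a, table.b], [table.c, table.d]], alternative="two-sided")[1]
    )


def odds_ratio_cmle(table: ContingencyTable) -> float:
    """Conditional-MLE odds ratio oriented comparator-odds / case-odds.

    Boundary tables (a zero cell making the conditional likelihood monotone)
    return 0.0 or ``inf`` exactly. Degenerate symptom margins raise
    :class:`DegenerateTableError`.
    """
    if table.a + table.c == 0 or table.b + table.d == 0:
        raise DegenerateTableError(
            "odds ratio undefined: symptom margin is degenerate "
            f"(a+c={table.a + table.c}, b+d={table.b + table.d})"
        )
    # comparator row first so the conditional MLE estimates comparator/case odds
    res = _scipy_odds_ratio(
        [[table.c, table.d], [table.a, table.b]], kind="conditional"
    )
    return float(res.statistic)


def odds_ratio_haldane(table: ContingencyTable) -> float:
    """Haldane-Anscombe (+0.5 cells) sample odds ratio, comparator/case oriented.

    Finite auxiliary estimate for boundary tables whose conditional MLE is
    exactly 0 or infinite.
    """
    a, b, c, d = (x + 0.5 for x in (table.a, table.b, table.c, table.d))
    return float((c * b) / (d * a))


def holm_adjust(p_values) -> list[float]:
    """Holm step-down adjusted p-values, returned in the input order.

    The i-th smallest raw p is multiplied by (m - i + 1), a running maximum
    enforces monotonicity and values are capped at 1.
    """
    p = list(p_values)
    if not p:
        return []
    if any(not 0 <= x <= 1 for x in p):
        raise ValueError("p-values must lie in [0,1]")
    return list(multipletests(p, method="holm")[1])


def screen_cohort(cohort: Cohort, config: ScreeningConfig | None = None) -> list[ScreeningResult]:
    """Exact-test screening of every catalogued symptom.

    Denominators are pairwise complete (unknown symptom states are excluded
    per symptom). Symptoms with zero non-missing observations in either group
    are flagged untestable and excluded from the Holm family. Results are
    ordered by organ system then descending case prevalence, mirroring the
    published screening table layout.
    """
    config = config or ScreeningConfig()
    df = cohort.frame
    counts = cohort.group_counts
    comparator_group = "control" if config.comparator == "controls" else "non_case"
    if counts["case"] == 0 or counts[comparator_group] == 0:
        raise ValueError(
            f"screening needs non-empty case and {comparator_group} groups"
        )
    case_df = df[df["group"] == "case"]
    comp_df = df[df["group"] == comparator_group]
    results: list[ScreeningResult] = []
    for sid in cohort.catalog.symptom_ids:
        ca, cu = case_df[sid], comp_df[sid]
        case_n = int(ca.notna().sum())
        comp_n = int(cu.notna().sum())
        a = int((ca == 1).sum())
        c = int((cu == 1).sum())
        if case_n == 0 or comp_n == 0:
            results.append(ScreeningResult(
                symptom_id=sid, organ_system=cohort.catalog.organ_system(sid),
                table=None, case_count=a, case_denominator=case_n,
                comparator_count=c, comparator_denominator=comp_n,
                p_raw=np.nan, p_holm=np.nan, odds_ratio_cmle=np.nan,
                odds_ratio_haldane=np.nan, candidate=False, testable=False,
            ))
            continue
        table = ContingencyTable(a, case_n - a, c, comp_n - c)
        p = fisher_exact_2x2(table)
        if config.with_odds_ratio:
            try:
                or_cmle = odds_ratio_cmle(table)
            except DegenerateTableError:
                or_cmle = np.nan
            or_hald = odds_ratio_haldane(table)
        else:
            or_cmle = np.nan
            or_hald = np.nan
        results.append(ScreeningResult(
            symptom_id=sid, organ_system=cohort.catalog.organ_system(sid),
            table=table, case_count=a, case_denominator=case_n,
            comparator_count=c, comparator_denominator=comp_n,
            p_raw=p, p_holm=np.nan, odds_ratio_cmle=or_cmle,
            odds_ratio_haldane=or_hald, candidate=False, testable=True,
        ))
    testable = [r for r in results if r.testable]
    adjusted = holm_adjust([r.p_raw for r in testable])
    for r, ph in zip(testable, adjusted):
        r.p_holm = float(ph)
        basis = r.p_holm if config.use_adjusted_for_threshold else r.p_raw
        r.candidate = bool(basis < config.candidate_threshold)
    organ_order = {"neurological": 0, "visceral": 1, "skeletal": 2, "other": 3}
    results.sort(key=lambda r: (
        organ_order.get(r.organ_system, 9),
        -(r.case_count / r.case_denominator if r.case_denominator else -1.0),
        r.symptom_id,
    ))
    return results


def screening_frame(results: list[ScreeningResult]) -> pd.DataFrame:
    """Tabular screening report (one row per symptom)."""
    return pd.DataFrame([{
        "symptom_id": r.symptom_id,
        "organ_system": r.organ_system,
        "case_n": r.case_count,
        "case_pct": (100.0 * r.case_count / r.case_denominator
                     if r.case_denominator else np.nan),
        "comparator_n": r.comparator_count,
        "comparator_pct": (100.0 * r.comparator_count / r.comparator_denominator
                           if r.comparator_denominator else np.nan),
        "p_raw": r.p_raw,
        "p_holm": r.p_holm,
        "odds_ratio_cmle": r.odds_ratio_cmle,
        "odds_ratio_haldane": r.odds_ratio_haldane,
        "candidate": r.candidate,
        "testable": r.testable,
    } for r in results])
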