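"""Clinical evaluation of matched/unmatched calls against binary response.

The central object is the 2x2 table (a = matched responders, b = matched
non-responders, c = unmatched responders, d = unmatched non-responders).
From it: the odds ratio (a*d)/(b*c) with the Woolf log-space 95% CI, the
two-sided Fisher exact test, precision a/(a+b), the overall response rate
(a+c)/n, the relative precision increase over ORR with a one-sided z-test,
average precision over the full score range with a label-permutation test,
and OR-vs-coverage curves.  ``reconstruct_table`` recovers a 2x2 table from
printed summary statistics (cohort size, responder count, and rounded
targets for OR / precision / CI bounds) by exhaustive enumeration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score

logger = logging.getLogger(__name__)

__all__ = [
    "ResponseTable",
    "build_table",
    "odds_ratio_ci",
    "fisher_exact",
    "average_precision",
    "coverage_curve",
    "precision_increase_test",
    "permutation_test_ap",
    "reconstruct_table",
    "evaluate_response",
]


@dataclass(frozen=True)
class ResponseTable:
    a: int  # matched responders
    b: int  # matched non-responders
    c: int  # unmatched responders
    d: int  # unmatched non-responders

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def orr(self) -> float:
        return (self.a + self.c) / self.n

    @property
    def precision(self) -> float:
        if self.a + self.b == 0:
            raise ValueError("no matched patients; precision undefined")
        return self.a / (self.a + self.b)

    @property
    def sensitivity(self) -> float:
        return self.a / (self.a + self.c)

    @property
    def coverage(self) -> float:
        return (self.a + self.b) / self.n


def build_table(matched, responded) -> ResponseTable:
    """Cross-tabulate matched flags against binary response labels.

    ``matched`` and ``responded`` are aligned pandas Series or arrays;
    patients with missing labels are excluded (count logged).
    """
    m = pd.Series(matched)
    r = pd.Series(responded)
    if isinstance(matched, pd.Series) and isinstance(responded, pd.Series):
        common = m.index.intersection(r.index)
        dropped = max(len(m), len(r)) - len(common)
        if dropped:
            logger.info("excluded %d patients with missing labels", dropped)
        m, r = m.loc[common], r.loc[common]
    if len(m) == 0:
        raise ValueError("no patients with both a matched flag and a response label")
    mb = m.astype(bool).to_numpy()
    rb = r.astype(bool).to_numpy()
    return ResponseTable(
        a=int(np.sum(mb & rb)), b=int(np.sum(mb & ~rb)),
        c=int(np.sum(~mb & rb)), d=int(np.sum(~mb & ~rb)),
    )


def odds_ratio_ci(table: ResponseTable, z: float = 1.96) -> tuple[float, float, float]:
    """Odds ratio with the Woolf (log) confidence interval.

    OR = (a*d)/(b*c); CI = exp(ln OR +/- z*sqrt(1/a + 1/b + 1/c + 1/d)).
    When any cell is zero the Haldane +0.5 correction is applied to all
    cells (logged).  A table with an empty matched or unmatched margin has
    no defined OR.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if a + b == 0 or c + d == 0:
        raise ValueError("a+b = 0 or c+d = 0: odds ratio undefined")
    if min(a, b, c, d) == 0:
        logger.warning("zero cell: Haldane +0.5 correction applied")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return float(or_), float(np.exp(np.log(or_) - z * se)), float(np.exp(np.log(or_) + z * se))


def fisher_exact(table: ResponseTable, alternative: str = "two-sided") -> float:
    """Fisher exact p for the 2x2 table.

    Default is the two-sided convention (sum of probabilities of all tables
    with the observed margins whose probability does not exceed the
    observed).  ``alternative="greater"`` gives the one-sided test of
    OR > 1, which is what a significance claim of the odds ratio being
    larger than 1 corresponds to.
    """
    return float(
        stats.fisher_exact(
            [[table.a, table.b], [table.c, table.d]], alternative=alternative
        )[1]
    )


def average_precision(scores, labels) -> float:
    """Non-interpolated step AP over descending unique thresholds, ties
    grouped; equals the mean precision at the positives' thresholds."""
    y = np.asarray(labels, dtype=int)
    if y.sum() == 0:
        raise ValueError("no positive labels; AP undefined")
    return float(average_precision_score(y, np.asarray(scores, dtype=float)))


def coverage_curve(
    scores, labels, coverage_range: tuple[float, float] = (0.1, 0.9)
) -> pd.DataFrame:
    """OR as a function of coverage over unique score thresholds.

    Coverage = fraction of patients with score >= threshold.  Only
    thresholds with coverage inside ``coverage_range`` are reported (the
    extremes are measurement noise).  Degenerate tables at a threshold get
    OR = NaN with a flag.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.size < 10:
        raise ValueError("need at least 10 patients for a coverage curve")
    rows = []
    for thr in np.unique(s)[::-1]:
        matched = s >= thr
        cov = matched.mean()
        if not coverage_range[0] <= cov <= coverage_range[1]:
            continue
        t = ResponseTable(
            a=int((matched & (y == 1)).sum()), b=int((matched & (y == 0)).sum()),
            c=int((~matched & (y == 1)).sum()), d=int((~matched & (y == 0)).sum()),
        )
        if min(t.a, t.b, t.c, t.d) == 0:
            # zero cell: the OR at this threshold is undefined/infinite and
            # reported missing rather than continuity-corrected
            or_, lo, hi, degenerate = np.nan, np.nan, np.nan, True
        else:
            or_, lo, hi = odds_ratio_ci(t)
            degenerate = False
        rows.append((float(thr), float(cov), or_, lo, hi, degenerate))
    return pd.DataFrame(
        rows, columns=["threshold", "coverage", "odds_ratio", "ci_low", "ci_high", "degenerate"]
    )


def precision_increase_test(table: ResponseTable) -> tuple[float, float]:
    """Relative precision increase over ORR, with a one-sided z-test.

    Returns (100 * (precision - ORR) / ORR, p) where p tests the matched
    group's response proportion against the cohort ORR as null proportion
    over the a+b matched patients.
    """
    if table.a + table.b == 0:
        raise ValueError("no matched patients")
    orr = table.orr
    if orr == 0:
        raise ValueError("ORR is zero; relative increase undefined")
    prec = table.precision
    n_m = table.a + table.b
    se = np.sqrt(orr * (1 - orr) / n_m)
    zstat = (prec - orr) / se
    return float(100.0 * (prec - orr) / orr), float(stats.norm.sf(zstat))


def permutation_test_ap(scores, labels, n_permutations: int = 999, seed: int = 0) -> float:
    """One-sided label-permutation test of AP.

    p = (1 + #{permuted AP >= observed}) / (B + 1); scores fixed, labels
    permuted; fully determined by the seed.
    """
    if n_permutations < 99:
        raise ValueError("need at least 99 permutations")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    observed = average_precision(s, y)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        if average_precision(s, rng.permutation(y)) >= observed - 1e-12:
            hits += 1
    return float((1 + hits) / (n_permutations + 1))


def _round_to(x: float, target: float, decimals: int) -> bool:
    return round(x, decimals) == round(target, decimals)


def reconstruct_table(
    n: int, n_responders: int, constraints: dict, decimals: dict | None = None
) -> list[ResponseTable]:
    """Recover 2x2 tables from printed summary statistics.

    Enumerates every (matched-group size m, matched responders a) with
    0 <= a <= min(m, R) and keeps the tables satisfying all rounded
    constraints.  ``constraints`` may contain ``or`` (2 dp),
    ``precision_pct`` (1 dp), ``ci_low``/``ci_high`` (2 dp); rounding
    precisions can be overridden through ``decimals``.  Returns all
    satisfying tables (empty when the constraints are inconsistent); the
    reconstruction is unique when exactly one is returned.
    """
    dec = {"or": 2, "precision_pct": 1, "ci_low": 2, "ci_high": 2}
    if decimals:
        dec.update(decimals)
    out: list[ResponseTable] = []
    level = logger.level
    logger.setLevel(logging.ERROR)  # quiet Haldane notes during enumeration
    try:
        out = _enumerate_tables(n, n_responders, constraints, dec)
    finally:
        logger.setLevel(level)
    if not out:
        logger.warning(
            "no 2x2 table with n=%d, R=%d satisfies %s", n, n_responders, constraints
        )
    return out


def _enumerate_tables(n, n_responders, constraints, dec) -> list[ResponseTable]:
    out: list[ResponseTable] = []
    for m in range(1, n):
        for a in range(0, min(m, n_responders) + 1):
            b = m - a
            c = n_responders - a
            d = n - m - c
            if c < 0 or d < 0:
                continue
            t = ResponseTable(a, b, c, d)
            if "precision_pct" in constraints:
                if not _round_to(100.0 * a / m, constraints["precision_pct"], dec["precision_pct"]):
                    continue
            needs_or = [k for k in ("or", "ci_low", "ci_high") if k in constraints]
            if needs_or:
                try:
                    or_, lo, hi = odds_ratio_ci(t)
                except ValueError:
                    continue
                vals = {"or": or_, "ci_low": lo, "ci_high": hi}
                if not all(_round_to(vals[k], constraints[k], dec[k]) for k in needs_or):
                    continue
            out.append(t)
    return out


def evaluate_response(ems_scores: pd.Series, labels: pd.Series, threshold: float = 0.54) -> dict:
    """Full evaluation report from EMS scores and binary response labels."""
    common = ems_scores.index.intersection(labels.index)
    s = ems_scores.loc[common]
    y = labels.loc[common].astype(int)
    table = build_table(s >= threshold, y)
    report: dict = {
        "n": table.n,
        "table": {"a": table.a, "b": table.b, "c": table.c, "d": table.d},
        "orr": table.orr,
        "coverage": table.coverage,
        "fisher_p": fisher_exact(table),
        "average_precision": average_precision(s.to_numpy(), y.to_numpy()),
    }
    try:
        or_, lo, hi = odds_ratio_ci(table)
        report.update({"odds_ratio": or_, "ci_low": lo, "ci_high": hi})
    except ValueError as exc:
        report.update({"odds_ratio": None, "ci_low": None, "ci_high": None,
                       "odds_ratio_note": str(exc)})
    try:
        report["precision"] = table.precision
        inc, p_inc = precision_increase_test(table)
        report["precision_increase_pct"] = inc
        report["precision_increase_p"] = p_inc
        report["sensitivity"] = table.sensitivity
    except ValueError as exc:
        report["precision_note"] = str(exc)
    return report
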