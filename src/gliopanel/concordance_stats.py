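"""Cross-modality concordance statistics.

Contingency tables and diagnostic metrics (sensitivity, specificity, PPV,
NPV, accuracy) with the underlying integer fractions retained, a per-score
p53 IHC concordance ledger, and group-mean comparisons (equal-variance
two-tailed t tests with one-way ANOVA; Welch behind a flag).  Percentages are
exact fractions rounded only for display; undefined metrics (zero
denominator) are reported as absent, never as 0.  No multiple-testing
correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .errors import MissingDataError


@dataclass
class ContingencyTable:
    """2×2 cross-tabulation of a predicted vs a reference binary call."""

    tp: int
    fp: int
    fn: int
    tn: int
    positive_label: str = "positive"
    reference_name: str = "reference"
    n_excluded: int = 0

    def __post_init__(self) -> None:
        for cell in (self.tp, self.fp, self.fn, self.tn):
            if cell < 0:
                raise ValueError("contingency cells must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class Fraction:
    """An exact integer fraction with its real value."""

    numerator: int
    denominator: int

    @property
    def value(self) -> float:
        return self.numerator / self.denominator

    def percent(self, decimals: int = 1) -> float:
        return round(100.0 * self.value, decimals)


@dataclass
class DiagnosticMetrics:
    """Diagnostic test metrics; each retained as an exact fraction.  A metric
    whose denominator is zero is None (absent), not 0."""

    sensitivity: Optional[Fraction]
    specificity: Optional[Fraction]
    ppv: Optional[Fraction]
    npv: Optional[Fraction]
    accuracy: Optional[Fraction]


def cross_tabulate(
    pred: Sequence,
    ref: Sequence,
    positive,
    positive_label: str = "positive",
    reference_name: str = "reference",
    exclude=("not_done",),
) -> ContingencyTable:
    """Cross-tabulate predicted vs reference categorical calls.

    Pairs where either column carries an excluded token (``not_done`` by
    default) are dropped and counted in ``n_excluded``; remaining cells
    conserve the input count.  Raises on length mismatch.
    """
    if len(pred) != len(ref):
        raise ValueError(f"length mismatch: {len(pred)} predictions vs {len(ref)} references")
    tp = fp = fn = tn = excluded = 0
    exclude = set(exclude)
    for p, r in zip(pred, ref):
        if p in exclude or r in exclude:
            excluded += 1
            continue
        p_pos = p == positive
        r_pos = r == positive
        if p_pos and r_pos:
            tp += 1
        elif p_pos:
            fp += 1
        elif r_pos:
            fn += 1
        else:
            tn += 1
    return ContingencyTable(
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        positive_label=positive_label,
        reference_name=reference_name,
        n_excluded=excluded,
    )


def _fraction(num: int, den: int) -> Optional[Fraction]:
    return Fraction(num, den) if den > 0 else None


def diagnostic_metrics(table: ContingencyTable) -> DiagnosticMetrics:
    """Sensitivity tp/(tp+fn), specificity tn/(tn+fp), PPV tp/(tp+fp),
    NPV tn/(tn+fn), accuracy (tp+tn)/total — as retained fractions."""
    return DiagnosticMetrics(
        sensitivity=_fraction(table.tp, table.tp + table.fn),
        specificity=_fraction(table.tn, table.tn + table.fp),
        ppv=_fraction(table.tp, table.tp + table.fp),
        npv=_fraction(table.tn, table.tn + table.fn),
        accuracy=_fraction(table.tp + table.tn, table.total),
    )


# ---------------------------------------------------------------------------
# p53 IHC concordance ledger
# ---------------------------------------------------------------------------

#: what each observed p53 IHC score predicts about TP53 mutation presence;
#: score 2 is ambiguous and counts as a prediction failure regardless
P53_SCORE_EXPECTATION: Mapping[str, Optional[bool]] = {
    "0": True,   # absent staining: truncating mutation suspected
    "1": False,  # wildtype pattern
    "2": None,   # ambiguous
    "3": True,   # strong labeling: missense mutation suspected
}


@dataclass
class P53ScoreSummary:
    n: int
    n_mutated: int
    n_failures: int


@dataclass
class P53Ledger:
    per_score: dict[str, P53ScoreSummary]
    failures: Fraction

    @property
    def n_total(self) -> int:
        return self.failures.denominator


def discordance_ledger(pairs: Sequence[tuple[object, bool]]) -> P53Ledger:
    """Per-score p53 IHC vs TP53-sequencing concordance.

    ``pairs`` are (observed IHC score 0-3, TP53 mutated by sequencing).  A
    case counts as a prediction failure when the score's expectation about
    mutation presence is wrong, and always when the score is 2 (ambiguous
    staining, confirmatory sequencing required).
    """
    per_score: dict[str, P53ScoreSummary] = {
        s: P53ScoreSummary(0, 0, 0) for s in ("0", "1", "2", "3")
    }
    total = failures = 0
    for score, mutated in pairs:
        score = str(score)
        if score not in per_score:
            raise ValueError(f"unknown p53 score {score!r}")
        summary = per_score[score]
        summary.n += 1
        total += 1
        if mutated:
            summary.n_mutated += 1
        expectation = P53_SCORE_EXPECTATION[score]
        if expectation is None or expectation != bool(mutated):
            summary.n_failures += 1
            failures += 1
    return P53Ledger(per_score=per_score, failures=Fraction(failures, total) if total else Fraction(0, 0))


# ---------------------------------------------------------------------------
# group-mean comparisons
# ---------------------------------------------------------------------------


@dataclass
class GroupComparison:
    pairwise: dict[tuple[str, str], tuple[float, float]]  # (t, p) per pair
    anova_f: float
    anova_p: float


def compare_group_means(
    groups: Mapping[str, Sequence[float]],
    equal_var: bool = True,
) -> GroupComparison:
    """Pairwise unpaired two-tailed t tests (Student's equal-variance by
    default, Welch with ``equal_var=False``) and a one-way ANOVA across all
    groups.  Requires at least two groups, each with n ≥ 2 and not all
    values identical across a compared pair."""
    names = list(groups)
    if len(names) < 2:
        raise MissingDataError("group comparison requires at least two groups")
    arrays = {}
    for name in names:
        arr = np.asarray(groups[name], dtype=float)
        if arr.size < 2:
            raise MissingDataError(f"group {name!r} has fewer than 2 observations")
        arrays[name] = arr

    pairwise = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            xa, xb = arrays[a], arrays[b]
            if np.var(xa) == 0 and np.var(xb) == 0:
                raise MissingDataError(
                    f"groups {a!r} and {b!r} are both constant; t statistic undefined"
                )
            t_stat, p_val = stats.ttest_ind(xa, xb, equal_var=equal_var)
            pairwise[(a, b)] = (float(t_stat), float(p_val))

    f_stat, f_p = stats.f_oneway(*arrays.values())
    return GroupComparison(pairwise=pairwise, anova_f=float(f_stat), anova_p=float(f_p))
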