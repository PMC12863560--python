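"""Median-split group construction and partition comparison.

The conventional way to type drug takers is a median split: subjects at
or above the sample median of some intake variable are "high takers"
(HT), the rest "low takers" (LT).  This module builds those partitions,
quantifies how unstable they are across doses, and cross-tabulates them
against each other and against model-based clusters.

Tie rule: a subject sitting exactly on the median goes to the HIGH group
by default.  With an odd cohort (n = 11) the standard sample median is a
data point, so the tie rule decides the group sizes; "high" yields the
5-low/6-high splits used throughout the reference analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTable, VariableTable
from .stats import WelchResult, welch_t

__all__ = [
    "GroupAssignment",
    "CrossTab",
    "DistinctnessSummary",
    "median_split",
    "split_consistency",
    "compare_partitions",
    "distinctness_summary",
]


@dataclass(frozen=True)
class GroupAssignment:
    """A two-group partition from a median split."""

    variable: str
    median: float
    low_ids: tuple[str, ...]
    high_ids: tuple[str, ...]
    tie_rule: str

    @property
    def subjects(self) -> set[str]:
        return set(self.low_ids) | set(self.high_ids)

    def group_of(self, subject: str) -> str:
        if subject in self.low_ids:
            return "low"
        if subject in self.high_ids:
            return "high"
        raise KeyError(subject)

    def to_dict(self):
        return {"variable": self.variable, "median": self.median,
                "low_ids": list(self.low_ids), "high_ids": list(self.high_ids),
                "tie_rule": self.tie_rule}


def median_split(values, variable: str = "", tie_rule: str = "high") -> GroupAssignment:
    """Split subjects at the sample median of ``values``.

    ``values`` maps subject id → value.  The median is the standard
    sample median (mean of the middle two for even n).  Values strictly
    above go high, strictly below go low; exact ties go to the group
    named by ``tie_rule``.
    """
    if tie_rule not in {"high", "low"}:
        raise ValueError("tie_rule must be 'high' or 'low'")
    items = list(values.items())
    if len(items) < 2:
        raise ValueError("need >= 2 subjects to median-split")
    vals = np.array([v for _, v in items], dtype=float)
    med = float(np.median(vals))
    low, high = [], []
    for (s, v), _ in zip(items, vals):
        if v > med or (v == med and tie_rule == "high"):
            high.append(s)
        else:
            low.append(s)
    return GroupAssignment(variable=variable, median=med,
                           low_ids=tuple(low), high_ids=tuple(high),
                           tie_rule=tie_rule)


def split_consistency(cohort: CohortTable, tie_rule: str = "high"):
    """Median-split the cohort at every dose and measure (in)stability.

    Returns ``(assignments, stability, high_counts)`` where
    ``assignments`` is one :class:`GroupAssignment` per dose,
    ``stability`` is a dose × dose DataFrame counting, for each pair of
    doses, how many subjects keep the same membership at both (diagonal
    = cohort size), and ``high_counts`` maps each subject to the number
    of doses at which it lands in the high group.
    """
    if cohort.n_doses < 2:
        raise ValueError("need >= 2 doses")
    assignments = []
    member = np.zeros((cohort.n_subjects, cohort.n_doses), dtype=bool)
    for j, d in enumerate(cohort.doses):
        values = dict(zip(cohort.subjects, cohort.responses[:, j]))
        ga = median_split(values, variable=f"d{d:g}", tie_rule=tie_rule)
        assignments.append(ga)
        for i, s in enumerate(cohort.subjects):
            member[i, j] = s in ga.high_ids
    agree = np.zeros((cohort.n_doses, cohort.n_doses), dtype=int)
    for a in range(cohort.n_doses):
        for b in range(cohort.n_doses):
            agree[a, b] = int(np.sum(member[:, a] == member[:, b]))
    labels = [f"d{d:g}" for d in cohort.doses]
    stability = pd.DataFrame(agree, index=labels, columns=labels)
    high_counts = {s: int(member[i].sum()) for i, s in enumerate(cohort.subjects)}
    return assignments, stability, high_counts


@dataclass
class CrossTab:
    """Contingency between two partitions of the same subjects."""

    counts: pd.DataFrame                 # rows: partition 1, cols: partition 2
    #: share of each *column* group drawn from each row group, the "4/5 of
    #: cluster 1" style; rows sum handled in of_row.
    of_column: pd.DataFrame
    of_row: pd.DataFrame                 # share of each row group, "80%" style

    def to_dict(self):
        return {"counts": {r: self.counts.loc[r].to_dict()
                           for r in self.counts.index},
                "of_column": {r: self.of_column.loc[r].to_dict()
                              for r in self.of_column.index},
                "of_row": {r: self.of_row.loc[r].to_dict()
                           for r in self.of_row.index}}


def _membership(partition):
    """subject -> group-name mapping from any partition-like object."""
    if isinstance(partition, GroupAssignment):
        out = {s: "low" for s in partition.low_ids}
        out.update({s: "high" for s in partition.high_ids})
        return out
    if hasattr(partition, "labels"):  # ClusterResult
        return {s: f"cluster{c + 1}" for s, c in partition.labels.items()}
    if isinstance(partition, dict):
        return {s: str(g) for s, g in partition.items()}
    if isinstance(partition, (tuple, list)) and len(partition) == 2:
        out = {s: "group1" for s in partition[0]}
        out.update({s: "group2" for s in partition[1]})
        return out
    raise TypeError(f"cannot interpret partition of type {type(partition).__name__}")


def compare_partitions(p1, p2) -> CrossTab:
    """Cross-tabulate two partitions over the same subject universe.

    Composition is reported both ways: ``of_column`` divides each cell by
    its column total (the "4/5 of cluster 1" fractions when clusters are
    the columns) and ``of_row`` by its row total (the "80% of LT" view).
    Swapping arguments transposes the counts.
    """
    m1, m2 = _membership(p1), _membership(p2)
    if set(m1) != set(m2):
        raise ValueError("partitions cover different subject sets")
    rows = sorted(set(m1.values()))
    cols = sorted(set(m2.values()))
    counts = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    for s in m1:
        counts.loc[m1[s], m2[s]] += 1
    of_column = counts / counts.sum(axis=0)
    of_row = counts.div(counts.sum(axis=1), axis=0)
    return CrossTab(counts, of_column, of_row)


@dataclass
class DistinctnessSummary:
    """Per-variable Welch verdicts for a two-group partition."""

    per_variable: dict[str, WelchResult]
    alpha: float

    @property
    def fraction_significant(self) -> float:
        if not self.per_variable:
            return 0.0
        return sum(r.p < self.alpha for r in self.per_variable.values()) / len(
            self.per_variable)

    @property
    def significant_variables(self) -> list[str]:
        return [v for v, r in self.per_variable.items() if r.p < self.alpha]

    def to_dict(self):
        return {"alpha": self.alpha,
                "fraction_significant": self.fraction_significant,
                "per_variable": {v: r.to_dict()
                                 for v, r in self.per_variable.items()}}


def distinctness_summary(table: VariableTable, partition,
                         alpha: float = 0.05) -> DistinctnessSummary:
    """Welch's t per variable; fraction of variables with p < alpha.

    How "different" are two groups across a panel of variables?  The
    answer is deliberately crude — the same uncorrected per-variable
    testing used to claim HT/LT are distinct phenotypes — so that
    partitions can be compared on equal footing.
    """
    member = _membership(partition)
    groups = sorted(set(member.values()))
    if len(groups) != 2:
        raise ValueError("need exactly 2 groups")
    idx_a = [i for i, s in enumerate(table.subjects) if member.get(s) == groups[0]]
    idx_b = [i for i, s in enumerate(table.subjects) if member.get(s) == groups[1]]
    if min(len(idx_a), len(idx_b)) < 2:
        raise ValueError("each group needs n >= 2")
    per = {}
    for j, v in enumerate(table.variables):
        per[v] = welch_t(table.values[idx_a, j], table.values[idx_b, j])
    return DistinctnessSummary(per, alpha)
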