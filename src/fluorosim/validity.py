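"""Construct / face / content validity analysis.

Participants are grouped by prior dynamic-hip-screw caseload — novices
(< 10 cases), intermediates (10-39), experts (>= 40) — and the five
objective metrics are compared across cohorts with nonparametric rank
tests: a Kruskal-Wallis omnibus at alpha = 5 %, followed when significant
by pairwise Mann-Whitney U tests whose p-values are multiplied by 3 (the
number of pairwise comparisons, capped at 1.0) to keep the family alpha
at 0.05.  Cohort contrasts are additionally summarized as integer percent
differences of the cohort medians, using the larger median as denominator
and round-half-up.  Face and content validity come from 7-point Likert
statements, where a response of 5, 6 or 7 counts as agreement.

For small samples the Mann-Whitney and Kruskal-Wallis p-values are exact:
computed by full enumeration of every relabeling of the pooled
observations, with mid-rank tie handling.  Larger samples use the standard
tie-corrected chi-square / normal approximations (with continuity
correction for Mann-Whitney).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from fluorosim.errors import (
    BothZeroError,
    EmptyCohortError,
    EmptyGroupError,
    InsufficientGroupsError,
    NegativeCountError,
    OutOfScaleError,
)
from fluorosim.simulator import SessionMetrics

Cohort = Literal["novice", "intermediate", "expert"]

COHORTS: tuple[Cohort, ...] = ("novice", "intermediate", "expert")
METRIC_NAMES = ("tad_mm", "cor_pct", "time_s", "n_radiographs", "n_retries")

#: Pairwise post-hoc family size: three cohort pairs.
POSTHOC_FAMILY = 3

#: Largest pooled n for which Mann-Whitney p is computed by enumeration.
MWU_EXACT_MAX_N = 12

#: Largest pooled n for which an exact Kruskal-Wallis p is offered.
KW_EXACT_MAX_N = 8

COHORT_CSV_COLUMNS = [
    "id", "dhs_count", "pgy", "tad_mm", "cor_pct", "time_s",
    "n_radiographs", "n_retries", "q1", "q2", "q3", "q4",
]


@dataclass(frozen=True)
class ParticipantRecord:
    """One surgeon's caseload, objective metrics and Likert answers."""

    id: str
    dhs_count: int
    pgy: int
    metrics: SessionMetrics
    likert: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if self.dhs_count < 0:
            raise NegativeCountError("dhs_count cannot be negative")
        if len(self.likert) != 4 or not all(1 <= q <= 7 for q in self.likert):
            raise OutOfScaleError("likert must be 4 integers in [1, 7]")

    @property
    def cohort(self) -> Cohort:
        return assign_cohort(self.dhs_count)


@dataclass(frozen=True)
class TestResult:
    """Rank-test outcome: statistic, raw p and (for post-hoc) adjusted p."""

    statistic: float
    raw_p: float
    method: Literal["kruskal_wallis", "mann_whitney"]
    adjusted_p: float | None = None


def assign_cohort(dhs_count: int) -> Cohort:
    """Experience cohort from DHS caseload: <10 / 10-39 / >=40."""
    if dhs_count < 0:
        raise NegativeCountError(f"dhs_count {dhs_count} < 0")
    if dhs_count < 10:
        return "novice"
    if dhs_count < 40:
        return "intermediate"
    return "expert"


def cohort_medians(
    records: Sequence[ParticipantRecord], metric_name: str
) -> dict[Cohort, float]:
    """Per-cohort median of one metric (even-n: midpoint of the two
    central order statistics)."""
    if metric_name not in METRIC_NAMES:
        raise ValueError(f"unknown metric {metric_name!r}")
    groups = group_metric(records, metric_name)
    return {c: float(np.median(v)) for c, v in groups.items()}


def group_metric(
    records: Sequence[ParticipantRecord], metric_name: str
) -> dict[Cohort, list[float]]:
    """Metric values split by cohort, all three cohorts required non-empty."""
    groups: dict[Cohort, list[float]] = {c: [] for c in COHORTS}
    for r in records:
        groups[r.cohort].append(float(getattr(r.metrics, metric_name)))
    for c, v in groups.items():
        if not v:
            raise EmptyCohortError(f"cohort {c!r} has no members")
    return groups


# -- rank statistics --------------------------------------------------------

def _tie_term(pooled: np.ndarray) -> float:
    """sum over tie groups of (t^3 - t)."""
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def _h_statistic(groups: list[np.ndarray]) -> float:
    """Tie-corrected Kruskal-Wallis H from mid-ranks; 0 when all tied."""
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = stats.rankdata(pooled)
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start:start + g.size]
        start += g.size
        h += r.sum() ** 2 / g.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    correction = 1.0 - _tie_term(pooled) / (n ** 3 - n)
    if correction <= 0.0:  # every observation identical
        return 0.0
    return h / correction


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U for the first sample, 0.5 credit per tie."""
    ranks = stats.rankdata(np.concatenate([a, b]))
    r_a = float(ranks[: a.size].sum())
    return r_a - a.size * (a.size + 1) / 2.0


def _group_index_partitions(n: int, sizes: Sequence[int]):
    """Yield all distinct assignments of indices 0..n-1 into ordered groups
    of the given sizes (each assignment a tuple of index tuples)."""
    def rec(remaining: tuple, sizes_left: Sequence[int]):
        if len(sizes_left) == 1:
            yield (remaining,)
            return
        k = sizes_left[0]
        for chosen in combinations(remaining, k):
            chosen_set = set(chosen)
            rest = tuple(i for i in remaining if i not in chosen_set)
            for tail in rec(rest, sizes_left[1:]):
                yield (chosen,) + tail

    yield from rec(tuple(range(n)), list(sizes))


def kruskal_wallis(
    groups: Sequence[Sequence[float]], exact: bool | None = None
) -> TestResult:
    """Kruskal-Wallis omnibus test over two or more groups.

    The statistic is the tie-corrected mid-rank H.  By default the p-value
    comes from the chi-square approximation with k-1 degrees of freedom;
    with ``exact=True`` (or by default when pooled n <= 8) it is the exact
    permutation p: the fraction of all relabelings of the pooled values
    into groups of the observed sizes whose H is at least the observed H.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size == 0 for g in gs):
        raise InsufficientGroupsError("need >= 2 non-empty groups")
    n = sum(g.size for g in gs)
    if n < 3:
        raise InsufficientGroupsError("need pooled n >= 3")
    h = _h_statistic(gs)
    if exact is None:
        exact = n <= KW_EXACT_MAX_N
    if exact:
        pooled = np.concatenate(gs)
        sizes = [g.size for g in gs]
        total = 0
        extreme = 0
        for part in _group_index_partitions(n, sizes):
            total += 1
            h_perm = _h_statistic([pooled[list(idx)] for idx in part])
            if h_perm >= h - 1e-12:
                extreme += 1
        p = extreme / total
    else:
        p = float(stats.chi2.sf(h, df=len(gs) - 1))
    return TestResult(statistic=h, raw_p=p, method="kruskal_wallis")


def mann_whitney_u(
    a: Sequence[float], b: Sequence[float], exact: bool | None = None
) -> TestResult:
    """Two-sided Mann-Whitney U test.

    For pooled n <= 12 (the study's largest cohort pair is 8 + 11 = 19,
    still enumerable, but 12 keeps the default cheap) the p-value is exact:
    over all C(n, n_a) relabelings of the pooled values, the fraction whose
    U deviates from its null mean n_a n_b / 2 by at least the observed
    deviation.  Larger samples use the tie-corrected normal approximation
    with continuity correction.
    """
    av = np.asarray(a, dtype=float)
    bv = np.asarray(b, dtype=float)
    if av.size == 0 or bv.size == 0:
        raise EmptyGroupError("both groups must be non-empty")
    u = _u_statistic(av, bv)
    n_a, n_b = av.size, bv.size
    n = n_a + n_b
    mu = n_a * n_b / 2.0
    if exact is None:
        exact = n <= MWU_EXACT_MAX_N
    if exact:
        pooled = np.concatenate([av, bv])
        dev = abs(u - mu)
        total = 0
        extreme = 0
        idx_all = frozenset(range(n))
        for idx_a in combinations(range(n), n_a):
            total += 1
            rest = list(idx_all.difference(idx_a))
            u_perm = _u_statistic(pooled[list(idx_a)], pooled[rest])
            if abs(u_perm - mu) >= dev - 1e-12:
                extreme += 1
        p = extreme / total
    else:
        tie = _tie_term(np.concatenate([av, bv]))
        var = n_a * n_b / 12.0 * ((n + 1) - tie / (n * (n - 1)))
        if var <= 0:  # all observations tied
            p = 1.0
        else:
            z = (abs(u - mu) - 0.5) / math.sqrt(var)
            p = min(1.0, 2.0 * float(stats.norm.sf(max(z, 0.0))))
    return TestResult(statistic=u, raw_p=p, method="mann_whitney")


def adjust_p(raw_p: float, k: int = POSTHOC_FAMILY) -> float:
    """Multiplicity correction: ``min(k * p, 1.0)`` (k = 3 cohort pairs)."""
    if not (0.0 <= raw_p <= 1.0):
        raise ValueError(f"raw_p {raw_p} outside [0, 1]")
    if k < 1:
        raise ValueError("k must be >= 1")
    return min(k * raw_p, 1.0)


def percent_difference(m1: float, m2: float) -> int:
    """Integer percent difference between two medians.

    ``round_half_up(100 * |m1 - m2| / max(m1, m2))`` — the larger median is
    the denominator.

    Raises
    ------
    BothZeroError
        When both medians are zero (no scale to compare against).
    """
    if max(abs(m1), abs(m2)) == 0:
        raise BothZeroError("both medians are zero")
    frac = 100.0 * abs(m1 - m2) / max(m1, m2)
    return int(math.floor(frac + 0.5))


def likert_agreement(responses: Sequence[int]) -> tuple[int, float]:
    """Count and proportion of responses scoring 5-7 (agreement)."""
    for r in responses:
        if not (1 <= r <= 7):
            raise OutOfScaleError(f"Likert response {r} outside [1, 7]")
    count = sum(1 for r in responses if r >= 5)
    return count, count / len(responses)


# -- study report -----------------------------------------------------------

COHORT_PAIRS: tuple[tuple[Cohort, Cohort], ...] = (
    ("novice", "intermediate"),
    ("novice", "expert"),
    ("intermediate", "expert"),
)


def validity_report(records: Sequence[ParticipantRecord]) -> dict:
    """Full construct/face/content-validity analysis of a cohort table.

    Returns a dict with three sections:

    * ``"medians"`` — per metric: per-cohort medians plus the
      Kruskal-Wallis H and p.
    * ``"pairwise"`` — per metric and cohort pair: integer percent
      difference of the medians and the x3-adjusted Mann-Whitney p.
    * ``"likert"`` — per statement: agreement count and proportion.
    """
    medians_section: dict = {}
    pairwise_section: dict = {}
    for metric in METRIC_NAMES:
        groups = group_metric(records, metric)
        med = {c: float(np.median(groups[c])) for c in COHORTS}
        kw = kruskal_wallis([groups[c] for c in COHORTS], exact=False)
        medians_section[metric] = {
            "medians": med, "kw_h": kw.statistic, "kw_p": kw.raw_p,
        }
        pairs = {}
        for c1, c2 in COHORT_PAIRS:
            try:
                pct = percent_difference(med[c1], med[c2])
            except BothZeroError:
                pct = None
            mwu = mann_whitney_u(groups[c1], groups[c2])
            pairs[f"{c1}_vs_{c2}"] = {
                "pct_diff": pct,
                "u": mwu.statistic,
                "raw_p": mwu.raw_p,
                "adjusted_p": adjust_p(mwu.raw_p),
            }
        pairwise_section[metric] = pairs

    likert_section = {}
    for i in range(4):
        responses = [r.likert[i] for r in records]
        count, prop = likert_agreement(responses)
        likert_section[f"q{i + 1}"] = {
            "agree": count, "n": len(responses), "proportion": prop,
        }
    return {
        "medians": medians_section,
        "pairwise": pairwise_section,
        "likert": likert_section,
    }


def format_report(report: dict) -> str:
    """Aligned-text rendering of :func:`validity_report` output."""
    lines = ["Median performance of each cohort",
             f"{'metric':<16}{'novice':>10}{'intermed':>10}{'expert':>10}{'KW p':>10}"]
    for metric, row in report["medians"].items():
        m = row["medians"]
        lines.append(
            f"{metric:<16}{m['novice']:>10.3g}{m['intermediate']:>10.3g}"
            f"{m['expert']:>10.3g}{row['kw_p']:>10.3g}"
        )
    lines.append("")
    lines.append("Percent difference (adjusted Mann-Whitney p) between cohorts")
    lines.append(f"{'metric':<16}{'nov-int':>16}{'nov-exp':>16}{'int-exp':>16}")
    for metric, pairs in report["pairwise"].items():
        cells = []
        for key in ("novice_vs_intermediate", "novice_vs_expert",
                    "intermediate_vs_expert"):
            cell = pairs[key]
            pct = "--" if cell["pct_diff"] is None else str(cell["pct_diff"])
            cells.append(f"{pct} ({cell['adjusted_p']:.2g})")
        lines.append(f"{metric:<16}{cells[0]:>16}{cells[1]:>16}{cells[2]:>16}")
    lines.append("")
    lines.append("Likert agreement (score >= 5)")
    for q, row in report["likert"].items():
        lines.append(f"  {q}: {row['agree']}/{row['n']} ({row['proportion']:.0%})")
    return "\n".join(lines)


# -- CSV I/O ----------------------------------------------------------------

def records_to_frame(records: Sequence[ParticipantRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "id": r.id, "dhs_count": r.dhs_count, "pgy": r.pgy,
            **r.metrics.to_dict() | {"cor_pct": r.metrics.cor_pct},
            "q1": r.likert[0], "q2": r.likert[1],
            "q3": r.likert[2], "q4": r.likert[3],
        })
    return pd.DataFrame(rows, columns=COHORT_CSV_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[ParticipantRecord]:
    records = []
    for _, row in df.iterrows():
        metrics = SessionMetrics(
            tad_mm=float(row["tad_mm"]), cor_pct=float(row["cor_pct"]),
            time_s=float(row["time_s"]),
            n_radiographs=int(row["n_radiographs"]),
            n_retries=int(row["n_retries"]),
        )
        records.append(ParticipantRecord(
            id=str(row["id"]), dhs_count=int(row["dhs_count"]),
            pgy=int(row["pgy"]), metrics=metrics,
            likert=(int(row["q1"]), int(row["q2"]),
                    int(row["q3"]), int(row["q4"])),
        ))
    return records


def load_cohort_csv(path: str | Path) -> list[ParticipantRecord]:
    return frame_to_records(pd.read_csv(path))


def save_cohort_csv(records: Sequence[ParticipantRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)
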