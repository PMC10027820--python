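"""Reader-level statistics: comprehension ability, correlations, group tests.

The comprehension ability score combines three behavioral measures into one
within-cohort index: post-reading assessment accuracy, a standardized
silent-reading test score (e.g. GSRT), and total reading time. Reading time
is first reversed (cohort maximum minus raw time, so that faster reading
scores higher), each component is z-scored within the cohort with the
sample (n-1) standard deviation, and the three z-scores are summed with
equal weights.

Group comparisons use Student's pooled-variance two-sample t-test
(df = n1 + n2 - 2) with Cohen's d on the pooled standard deviation, the
convention under which a 26 + 26 median split reports df = 50.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .fixation_io import Scanpath, TextStimulus

logger = logging.getLogger(__name__)

__all__ = [
    "ReaderOutcome",
    "GroupComparison",
    "comprehension_score",
    "pearson",
    "split_groups",
    "t_test_ind",
    "function_word_time_share",
    "metric_score_table",
    "read_behavioral_csv",
    "write_behavioral_csv",
]


class UndefinedStatisticError(ValueError):
    """A statistic is undefined on this input (constant component, zero variance)."""


@dataclass(frozen=True)
class ReaderOutcome:
    """Behavioral outcomes for one reader; ability is filled by
    :func:`comprehension_score`."""

    participant_id: str
    assessment_score: float
    gsrt_score: float
    total_reading_time_ms: float
    comprehension_ability: float | None = None


@dataclass(frozen=True)
class GroupComparison:
    metric: str
    mean_a: float
    mean_b: float
    t: float
    df: int
    p: float
    cohen_d: float


def _zscores(x: np.ndarray, name: str) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise UndefinedStatisticError(
            f"component {name!r} is constant across the cohort; z-score undefined"
        )
    return (x - x.mean()) / sd


def comprehension_score(cohort: Sequence[ReaderOutcome]) -> list[ReaderOutcome]:
    """Fill the combined comprehension ability score for a cohort.

    ability_i = z(assessment_i) + z(gsrt_i) + z(max_j RT_j - RT_i)
    """
    if len(cohort) < 2:
        raise UndefinedStatisticError("comprehension score needs a cohort of >= 2 readers")
    assessment = np.array([r.assessment_score for r in cohort], dtype=float)
    gsrt = np.array([r.gsrt_score for r in cohort], dtype=float)
    rt = np.array([r.total_reading_time_ms for r in cohort], dtype=float)
    reversed_rt = rt.max() - rt
    ability = (
        _zscores(assessment, "assessment_score")
        + _zscores(gsrt, "gsrt_score")
        + _zscores(reversed_rt, "reversed reading time")
    )
    return [replace(r, comprehension_ability=float(a)) for r, a in zip(cohort, ability)]


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r with two-tailed p from the t transform (n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise UndefinedStatisticError("pearson needs at least 3 observations")
    if x.std() == 0 or y.std() == 0:
        raise UndefinedStatisticError("constant input; correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def split_groups(
    cohort: Sequence[ReaderOutcome],
) -> tuple[list[ReaderOutcome], list[ReaderOutcome]]:
    """Median split by comprehension ability into (skilled, less_skilled).

    The split is stable: ties at the boundary are broken by participant-id
    order (logged). An odd cohort places the median reader in the lower
    (less-skilled) group.
    """
    if len(cohort) < 2:
        raise ValueError("split_groups needs >= 2 readers")
    if any(r.comprehension_ability is None for r in cohort):
        raise ValueError("call comprehension_score before split_groups")
    ordered = sorted(
        cohort, key=lambda r: (-r.comprehension_ability, r.participant_id)
    )
    n_top = len(cohort) // 2
    boundary = ordered[n_top - 1].comprehension_ability
    if n_top < len(ordered) and ordered[n_top].comprehension_ability == boundary:
        logger.info("ability tie at the median boundary; split by participant_id order")
    return ordered[:n_top], ordered[n_top:]


def t_test_ind(
    a: Sequence[float], b: Sequence[float], metric: str = ""
) -> GroupComparison:
    """Student's pooled-variance independent-samples t-test with Cohen's d."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 observations")
    n1, n2 = len(a), len(b)
    pooled_var = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    if pooled_var == 0:
        raise UndefinedStatisticError("zero pooled variance; t-test undefined")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    d = (a.mean() - b.mean()) / np.sqrt(pooled_var)
    return GroupComparison(
        metric=metric,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        t=float(t),
        df=n1 + n2 - 2,
        p=float(p),
        cohen_d=float(d),
    )


def function_word_time_share(scanpath: Scanpath, stimulus: TextStimulus) -> float:
    """Proportion of total fixation time spent on function words."""
    if stimulus.function_word_flags is None:
        raise ValueError(f"stimulus {stimulus.text_id!r} carries no function-word flags")
    total = scanpath.total_duration_ms
    if total <= 0:
        raise UndefinedStatisticError("zero total fixation duration")
    on_function = sum(
        e.duration_ms
        for e in scanpath.entries
        if stimulus.is_function_word(e.sentence_index, e.word_index)
    )
    return float(on_function / total)


def metric_score_table(table: pd.DataFrame | Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Pairwise Pearson r / p matrix over reader-level metric columns.

    ``table`` holds one row per reader and one column per variable (the five
    network metrics plus the comprehension ability score). Returns a square
    DataFrame whose cells are ``(r, p)`` tuples; the diagonal is (1.0, 0.0).
    Exact p-values are reported; significance starring is left to the caller.
    """
    df = pd.DataFrame(table)
    cols = list(df.columns)
    out = pd.DataFrame(index=cols, columns=cols, dtype=object)
    for i, ci in enumerate(cols):
        for j, cj in enumerate(cols):
            if i == j:
                out.loc[ci, cj] = (1.0, 0.0)
            else:
                out.loc[ci, cj] = pearson(df[ci].to_numpy(), df[cj].to_numpy())
    return out


def read_behavioral_csv(path) -> list[ReaderOutcome]:
    """Behavioral CSV: participant, assessment, gsrt, total_rt_ms."""
    df = pd.read_csv(path)
    required = {"participant", "assessment", "gsrt", "total_rt_ms"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"behavioral file missing column(s): {sorted(missing)}")
    return [
        ReaderOutcome(
            participant_id=str(row.participant),
            assessment_score=float(row.assessment),
            gsrt_score=float(row.gsrt),
            total_reading_time_ms=float(row.total_rt_ms),
        )
        for row in df.itertuples()
    ]


def write_behavioral_csv(cohort: Sequence[ReaderOutcome], path) -> None:
    pd.DataFrame(
        {
            "participant": [r.participant_id for r in cohort],
            "assessment": [r.assessment_score for r in cohort],
            "gsrt": [r.gsrt_score for r in cohort],
            "total_rt_ms": [r.total_reading_time_ms for r in cohort],
        }
    ).to_csv(path, index=False)
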