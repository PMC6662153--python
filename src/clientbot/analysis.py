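"""Outcome computations for a training study.

Per-phase skill percentages (open questions, reflections, and their
combination) are computed per participant, compared between arms with the
two-sample Wilcoxon rank-sum test (exact permutation p-value for small
samples, normal approximation with midranks, tie correction and continuity
correction otherwise), supplemented by a chi-square dropout test, one- and
two-sample t-tests for satisfaction, and the headline relative-increase
arithmetic (integer percent, truncated toward zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .coder import SkillLabel
from .corpus import tokenize
from .curriculum import Arm, Phase, PHASE_ORDER, SessionLog

__all__ = [
    "PhaseStats",
    "GroupComparison",
    "SatisfactionScores",
    "skill_percentages",
    "unique_utterance_pct",
    "wilcoxon_rank_sum",
    "chi_square_2x2",
    "one_sample_t",
    "two_sample_t",
    "relative_increase",
    "summarize_study",
    "StudySummary",
    "code_satisfaction_option",
]


@dataclass
class PhaseStats:
    """Skill-code tabulation for one phase: counts, percentages of total
    utterances, and the combined reflection-or-open-question percentage."""

    phase: str
    counts: dict[SkillLabel, int]
    n: int
    percentages: dict[SkillLabel, float]
    combined: float  # reflections or open questions, percent


@dataclass
class GroupComparison:
    kind: str  # "wilcoxon_W" | "chi_square" | "t"
    statistic: float
    p_value: float
    df: float | None = None
    effect_size_d: float | None = None


def skill_percentages(labels: Sequence[SkillLabel], phase: str | Phase) -> PhaseStats:
    """Tabulate skill codes and divide by the number of utterances."""
    labels = [SkillLabel(l) for l in labels]
    n = len(labels)
    if n == 0:
        raise ValueError("no utterances to tabulate")
    counts = {lab: 0 for lab in SkillLabel}
    for l in labels:
        counts[l] += 1
    pct = {lab: 100.0 * c / n for lab, c in counts.items()}
    combined = 100.0 * (counts[SkillLabel.OPEN_QUESTION] + counts[SkillLabel.REFLECTION]) / n
    name = phase.value if isinstance(phase, Phase) else str(phase)
    return PhaseStats(name, counts, n, pct, combined)


def unique_utterance_pct(utterances: Sequence[str]) -> float:
    """Percent of a participant's utterances that are distinct after
    normalization (tokenize, rejoin)."""
    if not utterances:
        raise ValueError("no utterances")
    normalized = [" ".join(tokenize(u)) for u in utterances]
    return 100.0 * len(set(normalized)) / len(normalized)


_EXACT_LIMIT = 12


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> GroupComparison:
    """Two-sample Wilcoxon rank-sum (Mann–Whitney) test, two-sided.

    The statistic W is the sum of midranks of ``x`` in the pooled sample.
    With at most 12 observations in total the p-value is computed by exact
    enumeration of all rank assignments; otherwise by the normal
    approximation with tie and continuity corrections.  Cohen's d from the
    raw values is attached as a descriptive effect size.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    nx, ny = x.size, y.size
    n = nx + ny
    ranks = stats.rankdata(np.concatenate([x, y]))
    w = float(ranks[:nx].sum())
    if n <= _EXACT_LIMIT:
        sums = np.fromiter(
            (ranks[list(c)].sum() for c in combinations(range(n), nx)), dtype=float
        )
        eps = 1e-9
        p_low = np.mean(sums <= w + eps)
        p_high = np.mean(sums >= w - eps)
        p = min(1.0, 2.0 * min(p_low, p_high))
    else:
        mean_w = nx * (n + 1) / 2.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)))
        var_w = nx * ny / 12.0 * ((n + 1) - tie_term)
        if var_w <= 0:
            p = 1.0
        else:
            diff = w - mean_w
            cc = 0.5 * np.sign(diff)
            z = (diff - cc) / np.sqrt(var_w)
            p = float(2.0 * stats.norm.sf(abs(z)))
        p = min(1.0, p)
    d = None
    sp2 = _pooled_var(x, y)
    if sp2 > 0:
        d = float((x.mean() - y.mean()) / np.sqrt(sp2))
    return GroupComparison("wilcoxon_W", w, p, effect_size_d=d)


def _pooled_var(x: np.ndarray, y: np.ndarray) -> float:
    nx, ny = x.size, y.size
    if nx + ny <= 2:
        return 0.0
    sx = x.var(ddof=1) if nx > 1 else 0.0
    sy = y.var(ddof=1) if ny > 1 else 0.0
    return float(((nx - 1) * sx + (ny - 1) * sy) / (nx + ny - 2))


def chi_square_2x2(table: Sequence[Sequence[float]], correction: bool = False
                   ) -> GroupComparison:
    """Pearson chi-square on a 2x2 count table, 1 df, no continuity
    correction unless requested."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined: zero margin")
    stat, p, df, _ = stats.chi2_contingency(t, correction=correction)
    return GroupComparison("chi_square", float(stat), float(p), df=float(df))


def one_sample_t(scores: Sequence[float], null_value: float = 3.0) -> GroupComparison:
    """One-sample t-test against a reference value (default: the neutral
    satisfaction score of 3)."""
    a = np.asarray(scores, dtype=float)
    if a.size < 2:
        raise ValueError("need at least 2 observations")
    if a.var(ddof=1) == 0:
        raise ValueError("t undefined: zero variance")
    t, p = stats.ttest_1samp(a, null_value)
    d = float((a.mean() - null_value) / a.std(ddof=1))
    return GroupComparison("t", float(t), float(p), df=float(a.size - 1), effect_size_d=d)


def two_sample_t(x: Sequence[float], y: Sequence[float]) -> GroupComparison:
    """Pooled-variance two-sample t-test with Cohen's d."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 observations per group")
    sp2 = _pooled_var(x, y)
    if sp2 == 0:
        if x.mean() == y.mean():
            return GroupComparison("t", 0.0, 1.0, df=float(x.size + y.size - 2),
                                   effect_size_d=0.0)
        raise ValueError("t undefined: zero variance")
    t, p = stats.ttest_ind(x, y, equal_var=True)
    d = float((x.mean() - y.mean()) / np.sqrt(sp2))
    return GroupComparison("t", float(t), float(p), df=float(x.size + y.size - 2),
                           effect_size_d=d)


def relative_increase(treatment_mean: float, control_mean: float) -> int:
    """Headline arithmetic: integer percent increase of treatment over
    control, truncated toward zero."""
    if control_mean <= 0:
        raise ValueError("control mean must be positive")
    return int(100.0 * (treatment_mean - control_mean) / control_mean)


# -- satisfaction -----------------------------------------------------------

_OPTION_CODES = {
    "strongly disagree": 1,
    "disagree": 2,
    "agree": 4,
    "strongly agree": 5,
}


def code_satisfaction_option(option: str) -> int:
    """Map a response option to the 1–5 satisfaction coding (3 = neutral)."""
    key = option.strip().lower()
    if key in ("neutral", ""):
        return 3
    if key not in _OPTION_CODES:
        raise ValueError(f"unknown response option: {option!r}")
    return _OPTION_CODES[key]


@dataclass
class SatisfactionScores:
    items: dict[str, int]

    def __post_init__(self) -> None:
        for k, v in self.items.items():
            if v not in (1, 2, 3, 4, 5):
                raise ValueError(f"score for {k!r} must be in 1..5")

    def subscale_mean(self, prefix: str = "") -> float:
        vals = [v for k, v in self.items.items() if k.startswith(prefix)]
        if not vals:
            raise ValueError(f"no items with prefix {prefix!r}")
        return float(np.mean(vals))


# -- full-study summary ------------------------------------------------------

MEASURES = ("open_questions", "reflections", "combined")


@dataclass
class StudySummary:
    """Six-phase arm comparison table plus optional dropout and satisfaction
    tests."""

    table: dict[str, dict[str, dict]]  # phase -> measure -> row
    dropout: GroupComparison | None = None
    satisfaction: dict[str, GroupComparison] | None = None
    per_participant: dict[str, list[dict]] = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for phase in (p.value for p in PHASE_ORDER):
            for measure in MEASURES:
                cell = self.table[phase][measure]
                rows.append({"phase": phase, "measure": measure, **cell})
        return pd.DataFrame(rows)


def _participant_phase_percentages(log: SessionLog) -> dict[str, dict[str, float]]:
    """Per-phase OQ/RE/combined percentages for one participant."""
    labels_by_phase: dict[str, list[SkillLabel]] = {}
    for e in log.events:
        if e["kind"] in ("trainee", "posttest"):
            labels_by_phase.setdefault(e["phase"], []).append(SkillLabel(e["label"]))
    out = {}
    for phase, labels in labels_by_phase.items():
        ps = skill_percentages(labels, phase)
        out[phase] = {
            "open_questions": ps.percentages[SkillLabel.OPEN_QUESTION],
            "reflections": ps.percentages[SkillLabel.REFLECTION],
            "combined": ps.combined,
        }
    return out


def summarize_study(logs: Iterable[SessionLog],
                    dropout_counts: Sequence[Sequence[int]] | None = None
                    ) -> StudySummary:
    """Build the six-phase arm-comparison table from completed session logs.

    Rows follow the fixed phase order; each row carries control and
    treatment means of the per-participant percentages and the rank-sum
    p-value.  ``dropout_counts`` is an optional 2x2
    [[treatment completed, dropped], [control completed, dropped]] table.
    Satisfaction tests are included when logs carry satisfaction answers.
    """
    logs = list(logs)
    by_arm: dict[Arm, list[SessionLog]] = {Arm.TREATMENT: [], Arm.CONTROL: []}
    for log in logs:
        by_arm[Arm(log.arm)].append(log)
    if not by_arm[Arm.TREATMENT] or not by_arm[Arm.CONTROL]:
        raise ValueError("need at least one session log per arm")
    pp = {arm: [_participant_phase_percentages(l) for l in arm_logs]
          for arm, arm_logs in by_arm.items()}
    table: dict[str, dict[str, dict]] = {}
    for phase in (p.value for p in PHASE_ORDER):
        table[phase] = {}
        for measure in MEASURES:
            tvals = [d[phase][measure] for d in pp[Arm.TREATMENT] if phase in d]
            cvals = [d[phase][measure] for d in pp[Arm.CONTROL] if phase in d]
            row: dict = {"control_mean": float(np.mean(cvals)) if cvals else None,
                         "treatment_mean": float(np.mean(tvals)) if tvals else None}
            if tvals and cvals:
                cmp_ = wilcoxon_rank_sum(tvals, cvals)
                row.update(W=cmp_.statistic, p_value=cmp_.p_value,
                           effect_size_d=cmp_.effect_size_d)
            table[phase][measure] = row
    dropout = chi_square_2x2(dropout_counts) if dropout_counts is not None else None
    satisfaction = None
    sats = {arm: [float(np.mean(list(l.satisfaction.values())))
                  for l in arm_logs if l.satisfaction]
            for arm, arm_logs in by_arm.items()}
    if sats[Arm.TREATMENT] and sats[Arm.CONTROL]:
        overall = sats[Arm.TREATMENT] + sats[Arm.CONTROL]
        satisfaction = {
            "overall_vs_neutral": one_sample_t(overall, 3.0),
            "by_arm": two_sample_t(sats[Arm.TREATMENT], sats[Arm.CONTROL]),
        }
    return StudySummary(table=table, dropout=dropout, satisfaction=satisfaction,
                        per_participant={arm.value: v for arm, v in pp.items()})
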