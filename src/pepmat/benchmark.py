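"""Leave-one-protein-out evaluation and assessment statistics.

Every peptide (functional and control) is scored with all records from its
source protein removed from both comparison sets, so the evaluation never
learns from and applies information to peptides of the same protein.  Pooled
scores are min-max normalized with the functional class positive, then
summarized as a ROC curve and rank-based AUC, a precision-recall curve, an
MCC curve over thresholds 0.00-1.00 in 0.01 steps (whose maximum defines the
operational cutoff), and a one-tailed Welch t-test of functional > control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .align import GapPenalties
from .io import PeptideSet, SubstitutionMatrix
from .similarity import ScoreTable, content_score, loo_score
from .train import grid_search_gaps, matrix_l1_distance

MCC_THRESHOLDS = np.round(np.arange(0, 101) * 0.01, 2)


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> Tuple[list, float]:
    """ROC points and rank-based (Mann-Whitney) AUC; ties count one half.

    Returns ``(points, auc)`` where points run from (0,0) to (1,1) with both
    coordinates non-decreasing, and label True marks the positive class.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative")
    ranks = stats.rankdata(scores)  # average ranks handle ties
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    order = np.argsort(-scores, kind="stable")
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and scores[order[j]] == scores[order[i]]:
            if labels[order[j]]:
                tp += 1
            else:
                fp += 1
            j += 1
        points.append((fp / n_neg, tp / n_pos))
        i = j
    return points, float(auc)


def precision_recall(scores: Sequence[float], labels: Sequence[bool]) -> list:
    """Precision-recall points sweeping thresholds from high to low scores."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("precision-recall needs at least one positive")
    order = np.argsort(-scores, kind="stable")
    points = []
    tp = fp = 0
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and scores[order[j]] == scores[order[i]]:
            if labels[order[j]]:
                tp += 1
            else:
                fp += 1
            j += 1
        points.append((tp / n_pos, tp / (tp + fp)))
        i = j
    return points


def mcc(tp: int, fp: int, fn: int, tn: int) -> float:
    """Matthews correlation coefficient; 0 when any marginal is zero."""
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def mcc_curve(scores: Sequence[float], labels: Sequence[bool]) -> list:
    """MCC at each of the 101 thresholds 0.00-1.00 (step 0.01).

    Scores must already be normalized to [0,1]; a peptide is predicted
    positive iff its score is >= the threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    curve = []
    for t in MCC_THRESHOLDS:
        predicted = scores >= t
        tp = int((predicted & labels).sum())
        fp = int((predicted & ~labels).sum())
        fn = int((~predicted & labels).sum())
        tn = int((~predicted & ~labels).sum())
        curve.append((float(t), mcc(tp, fp, fn, tn)))
    return curve


def best_mcc_threshold(curve: Sequence[Tuple[float, float]]) -> Tuple[float, float]:
    """(threshold, mcc) at the curve maximum; ties break toward the lowest threshold."""
    best = max(curve, key=lambda pair: (pair[1], -pair[0]))
    return best


def welch_one_tailed(sample_a: Sequence[float], sample_b: Sequence[float]) -> Tuple[float, float]:
    """Welch's unequal-variance t-test, one-tailed for mean(A) > mean(B)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 0.5
        return (math.inf, 0.0) if a.mean() > b.mean() else (-math.inf, 1.0)
    result = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
    return float(result.statistic), float(result.pvalue)


@dataclass
class BenchmarkResult:
    score_table: ScoreTable
    roc_points: list
    auc: float
    pr_points: list
    mcc_points: list
    best_threshold: float
    best_mcc: float
    t_statistic: float
    p_value: float

    def curves_to_tsv(self, path_prefix: str) -> None:
        with open(f"{path_prefix}.roc.tsv", "w") as out:
            out.write("fpr\ttpr\n")
            for fpr, tpr in self.roc_points:
                out.write(f"{fpr:.6g}\t{tpr:.6g}\n")
        with open(f"{path_prefix}.pr.tsv", "w") as out:
            out.write("recall\tprecision\n")
            for recall, precision in self.pr_points:
                out.write(f"{recall:.6g}\t{precision:.6g}\n")
        with open(f"{path_prefix}.mcc.tsv", "w") as out:
            out.write("threshold\tmcc\n")
            for t, value in self.mcc_points:
                out.write(f"{t:.2f}\t{value:.6g}\n")


def summarize_scores(table: ScoreTable) -> BenchmarkResult:
    """All assessment statistics from a pooled score table."""
    labels = [label == "functional" for label in table.labels]
    roc_points, auc = roc_auc(table.normalized, labels)
    pr_points = precision_recall(table.normalized, labels)
    mcc_points = mcc_curve(table.normalized, labels)
    threshold, best = best_mcc_threshold(mcc_points)
    functional_scores = table.normalized[np.asarray(labels)]
    control_scores = table.normalized[~np.asarray(labels)]
    t_stat, p = welch_one_tailed(functional_scores, control_scores)
    return BenchmarkResult(
        score_table=table,
        roc_points=roc_points,
        auc=auc,
        pr_points=pr_points,
        mcc_points=mcc_points,
        best_threshold=threshold,
        best_mcc=best,
        t_statistic=t_stat,
        p_value=p,
    )


def loo_benchmark(
    functional: PeptideSet,
    control: PeptideSet,
    matrix: Optional[SubstitutionMatrix],
    gaps: Optional[GapPenalties],
    scorer: str = "matrix",
) -> BenchmarkResult:
    """Leave-one-protein-out benchmark over both sets.

    ``scorer`` is ``matrix`` (alignment-based discrimination score) or
    ``content`` (amino-acid-composition baseline, no alignment).
    """
    if scorer not in ("matrix", "content"):
        raise ValueError(f"unknown scorer {scorer!r}")
    records, raw, labels = [], [], []
    for peptide_set, label in ((functional, "functional"), (control, "control")):
        for rec in peptide_set:
            if scorer == "matrix":
                value = loo_score(rec, functional, control, matrix, gaps)
            else:
                value = content_score(rec, functional, control)
            records.append(rec)
            raw.append(value)
            labels.append(label)
    table = ScoreTable(records=records, raw=np.array(raw), labels=labels)
    return summarize_scores(table)


@dataclass
class SurveyEntry:
    matrix: SubstitutionMatrix
    gaps: GapPenalties
    result: BenchmarkResult


@dataclass
class Leaderboard:
    entries: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def to_tsv(self, path) -> None:
        with open(path, "w") as out:
            out.write("matrix\tauc\tbest_mcc\tbest_threshold\tt\tp\tgap_open\tgap_extend\n")
            for e in self.entries:
                r = e.result
                out.write(
                    f"{e.matrix.id}\t{r.auc:.4f}\t{r.best_mcc:.4f}\t{r.best_threshold:.2f}\t"
                    f"{r.t_statistic:.4g}\t{r.p_value:.4g}\t{e.gaps.open}\t{e.gaps.extend}\n"
                )

    def score_strips_to_tsv(self, path) -> None:
        """Per-matrix normalized score strips (one row per peptide per matrix)."""
        with open(path, "w") as out:
            out.write("matrix\tprotein_id\tsequence\tnormalized\tlabel\n")
            for e in self.entries:
                t = e.result.score_table
                for rec, norm, label in zip(t.records, t.normalized, t.labels):
                    out.write(f"{e.matrix.id}\t{rec.protein_id}\t{rec.sequence}\t{norm:.6g}\t{label}\n")


def matrix_survey(
    functional: PeptideSet,
    control: PeptideSet,
    matrices: Sequence[SubstitutionMatrix],
    objective: str = "diff4",
    background: Optional[Sequence[PeptideSet]] = None,
) -> Leaderboard:
    """Benchmark many starting matrices, gap-trained per matrix, sorted by AUC."""
    if not matrices:
        raise ValueError("survey needs at least one matrix")
    entries = []
    for matrix in matrices:
        gaps = grid_search_gaps(
            functional, control, matrix, objective=objective, background=background
        )
        result = loo_benchmark(functional, control, matrix, gaps)
        entries.append(SurveyEntry(matrix=matrix, gaps=gaps, result=result))
    entries.sort(key=lambda e: -e.result.auc)
    return Leaderboard(entries=entries)


def improvement_correlation(before: Sequence[SurveyEntry], after: Sequence[SurveyEntry]) -> float:
    """Pearson correlation between matrix L1 training distance and AUC gain.

    Entries are paired positionally: ``before[k]`` and ``after[k]`` hold the
    same matrix pre- and post-training.
    """
    if len(before) != len(after):
        raise ValueError("before/after surveys differ in length")
    if len(before) < 3:
        raise ValueError("need at least 3 matrix pairs")
    distances = [matrix_l1_distance(b.matrix, a.matrix) for b, a in zip(before, after)]
    gains = [a.result.auc - b.result.auc for b, a in zip(before, after)]
    if np.std(distances) == 0 or np.std(gains) == 0:
        raise ValueError("zero variance in distances or AUC gains")
    r, _ = stats.pearsonr(distances, gains)
    return float(r)
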