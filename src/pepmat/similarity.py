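"""Set-level total similarity scores and training objectives.

The total similarity score (TSS) between two peptide sets is the mean, over
all ordered cross pairs, of the global alignment score divided by the mean of
the two peptide lengths.  When a set is compared against itself, self pairs
are excluded so self-alignment scores cannot dominate.

Four training objectives combine the pairings of a functional set F and a
control set N (subscripts: ff = F vs F, fn = F vs N, nn = N vs N, nf = N vs F):

* ``diff2``     = TSS.ff - TSS.fn
* ``diff4``     = TSS.ff + TSS.nn - TSS.fn - TSS.nf  (the default)
* ``quotient``  = TSS.ff * TSS.nn / (TSS.fn * TSS.nf)
* ``margin3``   = 3rd-lowest functional per-peptide score minus 3rd-highest
  control per-peptide score, on min-max-normalized leave-one-protein-out
  scores (the 3rd order statistic allows for outliers)

Per-peptide discrimination uses the difference form with same-protein
exclusion: all records sharing the query's source protein are removed from
both sets before scoring, so information never leaks between peptides of the
same protein.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .align import GapPenalties, _tss_sum, encode_set
from .io import ALPHABET, PeptideRecord, PeptideSet, SubstitutionMatrix

OBJECTIVE_VARIANTS = ("diff2", "diff4", "quotient", "margin3")


def tss(
    set_a: PeptideSet,
    set_b: PeptideSet,
    matrix: SubstitutionMatrix,
    gaps: GapPenalties,
    same_set: Optional[bool] = None,
) -> float:
    """Length- and size-normalized total similarity between two peptide sets.

    ``same_set`` forces self-pair exclusion; by default it is inferred from
    object identity of the two sets.
    """
    if len(set_a) == 0 or len(set_b) == 0:
        raise ValueError("TSS of an empty set is undefined")
    if same_set is None:
        same_set = set_a is set_b
    if same_set and len(set_a) < 2:
        raise ValueError("self-set TSS needs at least 2 records (self pairs are excluded)")
    seqs_a, lens_a = encode_set(set_a)
    seqs_b, lens_b = encode_set(set_b)
    total, count = _tss_sum(
        seqs_a,
        lens_a,
        seqs_b,
        lens_b,
        matrix.extended(),
        np.int64(gaps.open),
        np.int64(gaps.extend),
        same_set,
    )
    return total / count


@dataclass
class TSSComponents:
    ff: float
    fn: float
    nn: float
    nf: float

    def combine(self, variant: str) -> float:
        if variant == "diff2":
            return self.ff - self.fn
        if variant == "diff4":
            return self.ff + self.nn - self.fn - self.nf
        if variant == "quotient":
            denom = self.fn * self.nf
            if denom == 0:
                raise ValueError("quotient objective undefined: TSS.fn * TSS.nf == 0")
            return self.ff * self.nn / denom
        raise ValueError(f"unknown objective variant {variant!r}")


def tss_components(
    functional: PeptideSet,
    control: PeptideSet,
    matrix: SubstitutionMatrix,
    gaps: GapPenalties,
) -> TSSComponents:
    """The four set-pair TSS values used by the combination objectives."""
    return TSSComponents(
        ff=tss(functional, functional, matrix, gaps, same_set=True),
        fn=tss(functional, control, matrix, gaps, same_set=False),
        nn=tss(control, control, matrix, gaps, same_set=True),
        nf=tss(control, functional, matrix, gaps, same_set=False),
    )


def loo_score(
    query: PeptideRecord,
    functional: PeptideSet,
    control: PeptideSet,
    matrix: SubstitutionMatrix,
    gaps: GapPenalties,
) -> float:
    """Discrimination score for one peptide with same-protein leave-out.

    All records from the query's source protein (including the query itself)
    are removed from both sets; the score is TSS(query, functional') minus
    TSS(query, control').
    """
    functional_rest = _exclude(functional, query)
    control_rest = _exclude(control, query)
    if len(functional_rest) == 0 or len(control_rest) == 0:
        raise ValueError(
            f"excluding protein {query.protein_id!r} empties a comparison set"
        )
    single = PeptideSet([query], name="query")
    return tss(single, functional_rest, matrix, gaps, same_set=False) - tss(
        single, control_rest, matrix, gaps, same_set=False
    )


def _exclude(peptides: PeptideSet, query: PeptideRecord) -> PeptideSet:
    kept = [
        r
        for r in peptides
        if r.protein_id != query.protein_id and r.key != query.key
    ]
    return PeptideSet(kept, name=peptides.name)


def _normalize(values: np.ndarray) -> np.ndarray:
    """Min-max map to [0,1]; a constant vector maps to 0.5 everywhere."""
    lo, hi = float(np.min(values)), float(np.max(values))
    if hi == lo:
        return np.full_like(np.asarray(values, dtype=float), 0.5)
    return (np.asarray(values, dtype=float) - lo) / (hi - lo)


def _margin3(
    functional: PeptideSet,
    control: PeptideSet,
    matrix: SubstitutionMatrix,
    gaps: GapPenalties,
) -> float:
    if len(functional) < 3 or len(control) < 3:
        raise ValueError("margin3 needs at least 3 records per set")
    f_scores = [loo_score(r, functional, control, matrix, gaps) for r in functional]
    n_scores = [loo_score(r, functional, control, matrix, gaps) for r in control]
    pooled = _normalize(np.array(f_scores + n_scores))
    f_norm = np.sort(pooled[: len(f_scores)])
    n_norm = np.sort(pooled[len(f_scores):])
    return float(f_norm[2] - n_norm[-3])


def tssf(
    functional: PeptideSet,
    control: PeptideSet,
    matrix: SubstitutionMatrix,
    gaps: GapPenalties,
    variant: str = "diff4",
) -> float:
    """Evaluate one of the four training objectives."""
    if variant not in OBJECTIVE_VARIANTS:
        raise ValueError(f"unknown objective variant {variant!r}; expected {OBJECTIVE_VARIANTS}")
    if variant == "margin3":
        return _margin3(functional, control, matrix, gaps)
    return tss_components(functional, control, matrix, gaps).combine(variant)


def make_objective(
    functional: PeptideSet,
    control: PeptideSet,
    variant: str = "diff4",
    background: Optional[Sequence[PeptideSet]] = None,
) -> Callable[[SubstitutionMatrix, GapPenalties], float]:
    """Bind datasets into an objective callable ``f(matrix, gaps) -> value``.

    Background sets are appended to the control side for objective evaluation
    only; they never enter assessment.
    """
    if background:
        extra = [r for bset in background for r in bset]
        control = PeptideSet(list(control.records) + extra, name=control.name + "+background")

    def objective(matrix: SubstitutionMatrix, gaps: GapPenalties) -> float:
        return tssf(functional, control, matrix, gaps, variant=variant)

    return objective


# ---------------------------------------------------------------------------
# Amino-acid-content baseline
# ---------------------------------------------------------------------------

def _smoothed_frequency(counts: Counter, residue: str, total: int) -> float:
    return (counts[residue] + 1) / (total + len(ALPHABET))


def content_score(
    query: PeptideRecord,
    functional: PeptideSet,
    control: PeptideSet,
    exclude_same_protein: bool = True,
) -> float:
    """Positional-information-free baseline: mean log-ratio of residue
    proportions in the functional versus control set (add-one smoothing).
    """
    if exclude_same_protein:
        functional = _exclude(functional, query)
        control = _exclude(control, query)
    if len(functional) == 0 or len(control) == 0:
        raise ValueError(
            f"excluding protein {query.protein_id!r} empties a comparison set"
        )
    f_counts = Counter("".join(functional.sequences))
    n_counts = Counter("".join(control.sequences))
    f_total = sum(f_counts.values())
    n_total = sum(n_counts.values())
    terms = [
        math.log(
            _smoothed_frequency(f_counts, aa, f_total)
            / _smoothed_frequency(n_counts, aa, n_total)
        )
        for aa in query.sequence
    ]
    return float(np.mean(terms))


@dataclass
class ScoreTable:
    """Per-peptide scores: raw, min-max-normalized to [0,1], and label."""

    records: list
    raw: np.ndarray
    labels: list

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        self.normalized = _normalize(self.raw)

    def __len__(self) -> int:
        return len(self.records)

    def to_tsv(self, path) -> None:
        with open(path, "w") as out:
            out.write("protein_id\tsequence\traw\tnormalized\tlabel\n")
            for rec, raw, norm, label in zip(
                self.records, self.raw, self.normalized, self.labels
            ):
                out.write(f"{rec.protein_id}\t{rec.sequence}\t{raw:.6g}\t{norm:.6g}\t{label}\n")
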