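"""Global (Needleman-Wunsch) alignment with affine gap penalties.

This is the single scoring kernel every other module calls.  The gap model
follows the FASTA convention: a gap of length L costs ``open + (L-1)*extend``
(both penalties negative), and terminal gaps are penalized (global-global
semantics).  With an asymmetric matrix the FIRST sequence is the query and
indexes matrix rows; the second indexes columns.

Two implementations coexist: a numba-compiled score-only Gotoh kernel used in
all set-level computations (training evaluates the objective thousands of
times), and a pure-Python traceback variant returning the aligned strings.
Both produce identical scores; the DP is integer throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from numba import njit

from .io import PeptideSet, SubstitutionMatrix, encode_sequence

GAP_OPEN_RANGE = (-16, -1)
GAP_EXTEND_RANGE = (-8, -1)

NEG_INF = np.int64(-(10**15))


@dataclass(frozen=True)
class GapPenalties:
    """Integer affine gap penalties: ``open`` for the first gap residue,
    ``extend`` for each additional one.  Both are negative."""

    open: int
    extend: int

    def __post_init__(self) -> None:
        if not (GAP_OPEN_RANGE[0] <= self.open <= GAP_OPEN_RANGE[1]):
            raise ValueError(f"gap open {self.open} outside {GAP_OPEN_RANGE}")
        if not (GAP_EXTEND_RANGE[0] <= self.extend <= GAP_EXTEND_RANGE[1]):
            raise ValueError(f"gap extend {self.extend} outside {GAP_EXTEND_RANGE}")


@dataclass(frozen=True)
class AlignmentResult:
    score: int
    aligned_query: str
    aligned_target: str


@njit(cache=False)
def _nw_score(q, t, S, gop, gex):  # pragma: no cover - compiled
    m = q.shape[0]
    n = t.shape[0]
    NEG = -(10**15)
    M = np.empty(n + 1, np.int64)
    X = np.empty(n + 1, np.int64)  # gap in target (consumes query)
    Y = np.empty(n + 1, np.int64)  # gap in query (consumes target)
    M[0] = 0
    X[0] = NEG
    Y[0] = NEG
    for j in range(1, n + 1):
        M[j] = NEG
        X[j] = NEG
        Y[j] = gop + (j - 1) * gex
    for i in range(1, m + 1):
        prev_M0 = M[0]
        prev_X0 = X[0]
        M[0] = NEG
        X[0] = gop + (i - 1) * gex
        Y[0] = NEG
        diag_M = prev_M0
        diag_X = prev_X0
        diag_Y = NEG  # the previous row's Y[0] is always -inf
        for j in range(1, n + 1):
            up_M = M[j]
            up_X = X[j]
            up_Y = Y[j]
            best_diag = diag_M
            if diag_X > best_diag:
                best_diag = diag_X
            if diag_Y > best_diag:
                best_diag = diag_Y
            m_new = best_diag + S[q[i - 1], t[j - 1]]
            x_new = up_M + gop
            if up_X + gex > x_new:
                x_new = up_X + gex
            if up_Y + gop > x_new:
                x_new = up_Y + gop
            y_new = M[j - 1] + gop
            if Y[j - 1] + gex > y_new:
                y_new = Y[j - 1] + gex
            if X[j - 1] + gop > y_new:
                y_new = X[j - 1] + gop
            diag_M = up_M
            diag_X = up_X
            diag_Y = up_Y
            M[j] = m_new
            X[j] = x_new
            Y[j] = y_new
    best = M[n]
    if X[n] > best:
        best = X[n]
    if Y[n] > best:
        best = Y[n]
    return best


@njit(cache=False)
def _tss_sum(seqs_a, lens_a, seqs_b, lens_b, S, gop, gex, exclude_diag):  # pragma: no cover
    total = 0.0
    count = 0
    for i in range(lens_a.shape[0]):
        for j in range(lens_b.shape[0]):
            if exclude_diag and i == j:
                continue
            score = _nw_score(seqs_a[i, : lens_a[i]], seqs_b[j, : lens_b[j]], S, gop, gex)
            meanlen = 0.5 * (lens_a[i] + lens_b[j])
            total += score / meanlen
            count += 1
    return total, count


@njit(cache=False)
def _window_scores(protein, wlen, seqs, lens, S, gop, gex):  # pragma: no cover
    nwin = protein.shape[0] - wlen + 1
    out = np.empty(nwin, np.float64)
    for w in range(nwin):
        window = protein[w : w + wlen]
        total = 0.0
        for j in range(lens.shape[0]):
            score = _nw_score(window, seqs[j, : lens[j]], S, gop, gex)
            total += score / (0.5 * (wlen + lens[j]))
        out[w] = total / lens.shape[0]
    return out


def nw_score(query: str, target: str, matrix: SubstitutionMatrix, gaps: GapPenalties) -> int:
    """Optimal global alignment score (no traceback)."""
    if not query or not target:
        raise ValueError("cannot align an empty sequence")
    return int(
        _nw_score(
            encode_sequence(query),
            encode_sequence(target),
            matrix.extended(),
            np.int64(gaps.open),
            np.int64(gaps.extend),
        )
    )


def encode_set(peptides: PeptideSet) -> Tuple[np.ndarray, np.ndarray]:
    """Pack a peptide set into a padded index array + length vector for the kernels."""
    if len(peptides) == 0:
        raise ValueError("empty peptide set")
    lens = np.array([len(r.sequence) for r in peptides], dtype=np.int64)
    seqs = np.zeros((len(peptides), int(lens.max())), dtype=np.int64)
    for i, rec in enumerate(peptides):
        seqs[i, : lens[i]] = rec.encoded()
    return seqs, lens


# traceback states
_M, _X, _Y = 0, 1, 2


def nw_align(
    query: str, target: str, matrix: SubstitutionMatrix, gaps: GapPenalties
) -> AlignmentResult:
    """Optimal global alignment with traceback.

    Ties are broken deterministically: diagonal (match state), then gap in
    target, then gap in query; the score is unaffected by tie-breaking.
    """
    if not query or not target:
        raise ValueError("cannot align an empty sequence")
    q = encode_sequence(query)
    t = encode_sequence(target)
    S = matrix.extended()
    gop, gex = gaps.open, gaps.extend
    m, n = len(q), len(t)

    score = np.full((3, m + 1, n + 1), NEG_INF, dtype=np.int64)
    ptr = np.zeros((3, m + 1, n + 1), dtype=np.int8)  # predecessor state
    score[_M, 0, 0] = 0
    for i in range(1, m + 1):
        score[_X, i, 0] = gop + (i - 1) * gex
        ptr[_X, i, 0] = _M if i == 1 else _X
    for j in range(1, n + 1):
        score[_Y, 0, j] = gop + (j - 1) * gex
        ptr[_Y, 0, j] = _M if j == 1 else _Y

    def argbest(candidates):
        # candidates: list of (score, state) in preference order M, X, Y
        best_s, best_state = candidates[0]
        for s, st in candidates[1:]:
            if s > best_s:
                best_s, best_state = s, st
        return best_s, best_state

    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s, st = argbest(
                [(score[k, i - 1, j - 1], k) for k in (_M, _X, _Y)]
            )
            score[_M, i, j] = s + S[q[i - 1], t[j - 1]]
            ptr[_M, i, j] = st

            s, st = argbest(
                [
                    (score[_M, i - 1, j] + gop, _M),
                    (score[_X, i - 1, j] + gex, _X),
                    (score[_Y, i - 1, j] + gop, _Y),
                ]
            )
            score[_X, i, j] = s
            ptr[_X, i, j] = st

            s, st = argbest(
                [
                    (score[_M, i, j - 1] + gop, _M),
                    (score[_X, i, j - 1] + gop, _X),
                    (score[_Y, i, j - 1] + gex, _Y),
                ]
            )
            score[_Y, i, j] = s
            ptr[_Y, i, j] = st

    final, state = argbest([(score[k, m, n], k) for k in (_M, _X, _Y)])
    aq, at = [], []
    i, j = m, n
    while i > 0 or j > 0:
        prev = ptr[state, i, j]
        if state == _M:
            aq.append(query[i - 1])
            at.append(target[j - 1])
            i -= 1
            j -= 1
        elif state == _X:
            aq.append(query[i - 1])
            at.append("-")
            i -= 1
        else:
            aq.append("-")
            at.append(target[j - 1])
            j -= 1
        state = prev
    return AlignmentResult(int(final), "".join(reversed(aq)), "".join(reversed(at)))


def alignment_score(
    aligned_query: str, aligned_target: str, matrix: SubstitutionMatrix, gaps: GapPenalties
) -> int:
    """Re-score a gapped alignment pair under the affine gap model."""
    if len(aligned_query) != len(aligned_target):
        raise ValueError("aligned strings differ in length")
    S = matrix.extended()
    total = 0
    in_gap_q = in_gap_t = False
    for a, b in zip(aligned_query, aligned_target):
        if a == "-" and b == "-":
            raise ValueError("double-gap column")
        if a == "-":
            total += gaps.extend if in_gap_q else gaps.open
            in_gap_q, in_gap_t = True, False
        elif b == "-":
            total += gaps.extend if in_gap_t else gaps.open
            in_gap_q, in_gap_t = False, True
        else:
            total += int(S[encode_sequence(a)[0], encode_sequence(b)[0]])
            in_gap_q = in_gap_t = False
    return total
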