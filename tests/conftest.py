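"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

import pepmat as pm
from pepmat.io import encode_sequence


def brute_force_score(query: str, target: str, matrix, gaps) -> int:
    """Exhaustively enumerate every global alignment and return the best score.

    Independent of the DP implementation: walks all move sequences (match,
    gap-in-target, gap-in-query) with affine gap accounting on the
    accumulated path.  Exponential; only for short sequences.
    """
    S = matrix.extended()
    q = encode_sequence(query)
    t = encode_sequence(target)
    gop, gex = gaps.open, gaps.extend
    best = [-(10**9)]

    def rec(i: int, j: int, acc: int, last: str) -> None:
        if i == len(q) and j == len(t):
            if acc > best[0]:
                best[0] = acc
            return
        if i < len(q) and j < len(t):
            rec(i + 1, j + 1, acc + int(S[q[i], t[j]]), "M")
        if i < len(q):
            rec(i + 1, j, acc + (gex if last == "X" else gop), "X")
        if j < len(t):
            rec(i, j + 1, acc + (gex if last == "Y" else gop), "Y")

    rec(0, 0, 0, "")
    return best[0]


def pair_count_auc(scores, labels) -> float:
    """AUC by exhaustive concordant-pair counting (ties count one half)."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


@pytest.fixture(scope="session")
def identity1():
    """Match 1 / mismatch 0 matrix."""
    return pm.identity_matrix(match=1, mismatch=0, id="id1")


@pytest.fixture(scope="session")
def gaps21():
    return pm.GapPenalties(-2, -1)


@pytest.fixture(scope="session")
def toy_sets():
    """Small separable functional/control sets over several proteins."""
    functional = pm.PeptideSet(
        [
            pm.PeptideRecord("QPQQPPQQ", "F1", label="functional"),
            pm.PeptideRecord("QQPPQQPQ", "F2", label="functional"),
            pm.PeptideRecord("PQQPQPQQ", "F3", label="functional"),
            pm.PeptideRecord("QPPQQPQP", "F4", label="functional"),
        ],
        name="functional",
    )
    control = pm.PeptideSet(
        [
            pm.PeptideRecord("AILVAGMW", "N1", label="control"),
            pm.PeptideRecord("GVAILMWA", "N2", label="control"),
            pm.PeptideRecord("LIVAGWMA", "N3", label="control"),
            pm.PeptideRecord("VAGLIMAW", "N4", label="control"),
        ],
        name="control",
    )
    return functional, control


@pytest.fixture(scope="session")
def small_synthetic():
    """Two-family planted-motif dataset, small enough for fast tests."""
    spec = pm.SyntheticSpec(
        n_families=2,
        peptides_per_family=5,
        substitution_noise=0.1,
        length_range=(8, 20),
        seed=42,
    )
    return pm.synthetic_dataset(spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
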