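"""Gap-penalty grid search and staged substitution-matrix refinement.

Training maximizes a set-discrimination objective (see
:mod:`pepmat.similarity`) by perturbing whole matrix columns (target/dataset
residue), whole rows (query residue) or single cells, as integers clamped to
[-19, 19].  Two move policies exist:

* **greedy** - every candidate shift (each axis element, both directions) is
  evaluated and the single best strictly-improving one applied, repeating
  until no shift improves;
* **modified Monte Carlo** - a random axis element is shifted by a random
  signed magnitude below the current matrix value range, one greedy pass is
  run on the same axis to locally maximize, and the combined step is kept
  only if it strictly improved the objective; the search stops after
  ``patience`` consecutive rejected attempts.

Gap penalties are fixed once by exhaustive grid search before any matrix
perturbation (they are volatile if retrained during refinement).  The default
stage order starts with columns, which empirically trains more reliably than
starting with rows.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Tuple

import numpy as np

from .align import GAP_EXTEND_RANGE, GAP_OPEN_RANGE, GapPenalties
from .io import ALPHABET, SCORE_MAX, SCORE_MIN, PeptideSet, SubstitutionMatrix
from .similarity import make_objective

DEFAULT_STAGES = ("greedy_columns", "greedy_rows", "mc_columns", "mc_rows")
ALL_STAGES = (
    "greedy_columns",
    "greedy_rows",
    "greedy_cells",
    "mc_columns",
    "mc_rows",
    "mc_cells",
)
DEFAULT_SEED = 1837

Objective = Callable[[SubstitutionMatrix, GapPenalties], float]


@dataclass(frozen=True)
class TraceStep:
    stage: str
    axis: str
    element: str  # residue letter for rows/columns, "QA/TA"-style pair for cells
    delta: int
    objective_before: float
    objective_after: float
    accepted: bool


@dataclass
class TrainingTrace:
    steps: list = field(default_factory=list)

    def append(self, step: TraceStep) -> None:
        self.steps.append(step)

    def extend(self, other: "TrainingTrace") -> None:
        self.steps.extend(other.steps)

    def __len__(self) -> int:
        return len(self.steps)

    def __iter__(self):
        return iter(self.steps)

    @property
    def accepted_steps(self) -> list:
        return [s for s in self.steps if s.accepted]

    def to_jsonl(self, path) -> None:
        import json

        with open(path, "w") as out:
            for s in self.steps:
                out.write(json.dumps(s.__dict__) + "\n")


@dataclass
class TrainingConfig:
    objective: str = "diff4"
    stage_order: Tuple[str, ...] = DEFAULT_STAGES
    unit_step: int = 1
    mc_patience: int = 5
    seed: int = DEFAULT_SEED
    include_background_sets: bool = True

    def __post_init__(self) -> None:
        if self.mc_patience < 1:
            raise ValueError("mc_patience must be >= 1")
        if self.unit_step < 1:
            raise ValueError("unit_step must be >= 1")
        for stage in self.stage_order:
            if stage not in ALL_STAGES:
                raise ValueError(f"unknown stage {stage!r}; expected one of {ALL_STAGES}")


def grid_search_gaps(
    functional: PeptideSet,
    control: PeptideSet,
    matrix: SubstitutionMatrix,
    objective="diff4",
    background: Optional[Sequence[PeptideSet]] = None,
) -> GapPenalties:
    """Exhaustive integer grid search over gap penalties.

    Evaluates the objective at all 16 x 8 = 128 (open, extend) combinations in
    [-16, -1] x [-8, -1] and returns the maximizer; ties break toward the
    smallest |open|, then the smallest |extend|.

    ``objective`` may be a variant name or a callable ``f(gaps) -> value``.
    """
    if callable(objective):
        evaluate = objective
    else:
        bound = make_objective(functional, control, variant=objective, background=background)
        evaluate = lambda gaps: bound(matrix, gaps)  # noqa: E731

    best: Optional[GapPenalties] = None
    best_value = -np.inf
    # |open| and |extend| ascending, so the first maximum wins ties.
    for gap_open in range(GAP_OPEN_RANGE[1], GAP_OPEN_RANGE[0] - 1, -1):
        for gap_extend in range(GAP_EXTEND_RANGE[1], GAP_EXTEND_RANGE[0] - 1, -1):
            gaps = GapPenalties(gap_open, gap_extend)
            value = evaluate(gaps)
            if value > best_value:
                best_value = value
                best = gaps
    assert best is not None
    return best


def _axis_elements(axis: str):
    if axis == "columns" or axis == "rows":
        return list(range(20))
    if axis == "cells":
        return list(itertools.product(range(20), repeat=2))
    raise ValueError(f"unknown axis {axis!r}")


def _element_name(axis: str, element) -> str:
    if axis == "cells":
        return f"{ALPHABET[element[0]]}/{ALPHABET[element[1]]}"
    return ALPHABET[element]


def _shifted(scores: np.ndarray, axis: str, element, delta: int) -> np.ndarray:
    new = scores.copy()
    if axis == "columns":
        new[:, element] = np.clip(new[:, element] + delta, SCORE_MIN, SCORE_MAX)
    elif axis == "rows":
        new[element, :] = np.clip(new[element, :] + delta, SCORE_MIN, SCORE_MAX)
    else:
        i, j = element
        new[i, j] = min(SCORE_MAX, max(SCORE_MIN, new[i, j] + delta))
    return new


def greedy_pass(
    matrix: SubstitutionMatrix,
    axis: str,
    objective: Objective,
    gaps: GapPenalties,
    unit_step: int = 1,
    stage_name: Optional[str] = None,
) -> Tuple[SubstitutionMatrix, TrainingTrace]:
    """Greedy hill climb on one axis until no single shift improves.

    Each iteration evaluates every axis element in both directions
    (+/- unit_step applied to the whole column/row/cell, clamped) and applies
    the best strictly-improving shift.  Ties break by alphabet order, then
    the positive direction.
    """
    stage = stage_name or f"greedy_{axis}"
    trace = TrainingTrace()
    elements = _axis_elements(axis)
    current = matrix
    current_value = objective(current, gaps)
    while True:
        best_candidate = None  # (value, element_order, direction_order, scores, element, delta)
        for order, element in enumerate(elements):
            for direction_order, delta in enumerate((unit_step, -unit_step)):
                shifted = _shifted(current.scores, axis, element, delta)
                if np.array_equal(shifted, current.scores):
                    continue  # fully clamped; cannot change the objective
                value = objective(current.with_scores(shifted), gaps)
                if value <= current_value:
                    continue
                key = (-value, order, direction_order)
                if best_candidate is None or key < best_candidate[0]:
                    best_candidate = (key, shifted, element, delta, value)
        if best_candidate is None:
            break
        _, shifted, element, delta, value = best_candidate
        trace.append(
            TraceStep(
                stage=stage,
                axis=axis,
                element=_element_name(axis, element),
                delta=delta,
                objective_before=current_value,
                objective_after=value,
                accepted=True,
            )
        )
        current = current.with_scores(shifted)
        current_value = value
    return current, trace


def mc_pass(
    matrix: SubstitutionMatrix,
    axis: str,
    objective: Objective,
    gaps: GapPenalties,
    rng: np.random.Generator,
    patience: int = 5,
    unit_step: int = 1,
    stage_name: Optional[str] = None,
) -> Tuple[SubstitutionMatrix, TrainingTrace]:
    """Modified Monte Carlo refinement of one axis.

    Each attempt shifts a random axis element by a random signed magnitude in
    [1, D-1] where D is the current matrix's max-min value range (magnitude 1
    when D <= 1), locally maximizes with one greedy pass on the same axis,
    and keeps the combined step only on strict improvement.  Stops after
    ``patience`` consecutive rejections.
    """
    if patience < 1:
        raise ValueError("patience must be >= 1")
    stage = stage_name or f"mc_{axis}"
    trace = TrainingTrace()
    elements = _axis_elements(axis)
    current = matrix
    current_value = objective(current, gaps)
    consecutive_failures = 0
    while consecutive_failures < patience:
        element = elements[int(rng.integers(len(elements)))]
        spread = int(current.scores.max() - current.scores.min())
        magnitude = 1 if spread <= 1 else int(rng.integers(1, spread))
        sign = 1 if rng.integers(2) == 1 else -1
        delta = sign * magnitude
        shifted = current.with_scores(_shifted(current.scores, axis, element, delta))
        maximized, _ = greedy_pass(
            shifted, axis, objective, gaps, unit_step=unit_step, stage_name=stage
        )
        value = objective(maximized, gaps)
        accepted = value > current_value
        trace.append(
            TraceStep(
                stage=stage,
                axis=axis,
                element=_element_name(axis, element),
                delta=delta,
                objective_before=current_value,
                objective_after=value if accepted else current_value,
                accepted=accepted,
            )
        )
        if accepted:
            current = maximized
            current_value = value
            consecutive_failures = 0
        else:
            consecutive_failures += 1
    return current, trace


def train_matrix(
    functional: PeptideSet,
    control: PeptideSet,
    start_matrix: SubstitutionMatrix,
    config: Optional[TrainingConfig] = None,
    background_sets: Optional[Sequence[PeptideSet]] = None,
) -> Tuple[SubstitutionMatrix, GapPenalties, TrainingTrace]:
    """Full training run: gap grid search once, then the configured stages.

    Background sets (extra presumed-non-functional peptides) are appended to
    the control side for objective evaluation only; they are never part of
    assessment.  The returned matrix may be asymmetric: row and column shifts
    treat the query and dataset residue roles independently.
    """
    config = config or TrainingConfig()
    background = background_sets if (background_sets and config.include_background_sets) else None
    objective_fn = make_objective(
        functional, control, variant=config.objective, background=background
    )
    gaps = grid_search_gaps(
        functional, control, start_matrix, objective=lambda g: objective_fn(start_matrix, g)
    )
    rng = np.random.default_rng(config.seed)
    matrix = start_matrix
    trace = TrainingTrace()
    for stage in config.stage_order:
        policy, axis = stage.split("_", 1)
        if policy == "greedy":
            matrix, stage_trace = greedy_pass(
                matrix, axis, objective_fn, gaps, unit_step=config.unit_step, stage_name=stage
            )
        else:
            matrix, stage_trace = mc_pass(
                matrix,
                axis,
                objective_fn,
                gaps,
                rng,
                patience=config.mc_patience,
                unit_step=config.unit_step,
                stage_name=stage,
            )
        trace.extend(stage_trace)
    trained = matrix.with_scores(
        matrix.scores, id=(start_matrix.id + "-trained") if start_matrix.id else "trained"
    )
    return trained, gaps, trace


def matrix_l1_distance(a: SubstitutionMatrix, b: SubstitutionMatrix) -> int:
    """Arithmetic (elementwise L1) distance between two matrices."""
    if a.scores.shape != b.scores.shape:
        raise ValueError("matrices have different shapes")
    return int(np.abs(a.scores - b.scores).sum())
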