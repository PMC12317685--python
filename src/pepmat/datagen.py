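"""Synthetic data generation: decoy controls, random-composition background
peptides, and fully synthetic planted-motif datasets.

Decoys are sampled from the functional proteins' never-observed regions,
matched in number and length to the functional peptides, falling back to
random other proteins when a protein's free stretches are exhausted.
Background peptides are i.i.d. draws from a residue composition (by default a
UniProt-like table).  The planted-motif generator emulates the structure of a
pellicle-peptide-style study: each family shares a motif of position classes
(interchangeable residue sets such as carboxyl/amide {D,E,N,Q}, hydroxyl
{S,T,Y}, or proline runs) tiled across the peptide at a random phase - the
repetitive low-complexity texture of real mineral-binding peptides - with a
per-position noise probability; each functional peptide is embedded in a synthetic
source protein with its span recorded, so scanning, recapture and decoy
construction are all testable without external data.

Everything is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .io import PeptideRecord, PeptideSet

# Swiss-Prot-style average residue frequencies (fractions of all residues),
# renormalized below so the 20 standard residues sum to exactly 1.
_UNIPROT_RAW: Dict[str, float] = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0138,
    "Q": 0.0393, "E": 0.0675, "G": 0.0707, "H": 0.0227, "I": 0.0596,
    "L": 0.0966, "K": 0.0584, "M": 0.0242, "F": 0.0386, "P": 0.0470,
    "S": 0.0656, "T": 0.0534, "W": 0.0109, "Y": 0.0292, "V": 0.0687,
}
UNIPROT_COMPOSITION: Dict[str, float] = {
    aa: freq / sum(_UNIPROT_RAW.values()) for aa, freq in _UNIPROT_RAW.items()
}

LENGTH_RANGE_DEFAULT = (8, 36)

# Default motif families: position classes emulating chemically interchangeable
# residue groups seen in mineral-binding peptides (adjacent carboxyl/amide,
# alternating hydroxyls, proline runs).
DEFAULT_MOTIFS: Tuple[Tuple[frozenset, ...], ...] = (
    # adjacent carboxyl/amide residues (calcium-facing)
    tuple(frozenset(s) for s in ("DE", "DENQ", "DENQ", "DE", "NQ", "DENQ")),
    # alternating hydroxyl moieties (phosphate-facing)
    tuple(frozenset(s) for s in ("STY", "AG", "STY", "AG", "STY", "AG", "STY")),
    # proline-rich stretch stabilizing extended conformations
    tuple(frozenset(s) for s in ("P", "P", "QA", "P", "P", "QA", "P")),
)


def _composition_arrays(composition: Dict[str, float]) -> Tuple[np.ndarray, np.ndarray]:
    letters = np.array(list(composition.keys()))
    probs = np.array(list(composition.values()), dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError(f"composition frequencies sum to {probs.sum()}, not 1")
    return letters, probs


@dataclass
class SyntheticSpec:
    """Parameters of a planted-motif synthetic dataset.

    ``peptides_per_family`` may be one integer for all families or a
    per-family sequence.  ``substitution_noise`` is the probability that a
    motif position is drawn from the background composition instead of its
    class.  Source proteins carry one functional peptide each (recorded
    span) between background flanks.
    """

    n_families: int = 3
    peptides_per_family: "int | Sequence[int]" = 7
    length_range: Tuple[int, int] = LENGTH_RANGE_DEFAULT
    motifs: Optional[Sequence[Sequence[frozenset]]] = None
    substitution_noise: float = 0.2
    background_composition: Dict[str, float] = field(
        default_factory=lambda: dict(UNIPROT_COMPOSITION)
    )
    flank_length: Tuple[int, int] = (20, 60)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.substitution_noise <= 1:
            raise ValueError("substitution_noise must be in [0,1]")
        if self.length_range[0] > self.length_range[1]:
            raise ValueError("invalid length_range")
        _composition_arrays(self.background_composition)
        if self.motifs is None:
            if self.n_families > len(DEFAULT_MOTIFS):
                raise ValueError(
                    f"only {len(DEFAULT_MOTIFS)} default motif families exist; "
                    "pass explicit motifs"
                )
            self.motifs = DEFAULT_MOTIFS[: self.n_families]
        if len(self.motifs) != self.n_families:
            raise ValueError("one motif definition required per family")

    @property
    def family_sizes(self) -> List[int]:
        if isinstance(self.peptides_per_family, int):
            return [self.peptides_per_family] * self.n_families
        sizes = list(self.peptides_per_family)
        if len(sizes) != self.n_families:
            raise ValueError("peptides_per_family sequence length must equal n_families")
        return sizes


def random_peptides(
    composition: Dict[str, float],
    lengths: Sequence[int],
    n: int,
    seed: int,
    label: str = "control",
    id_prefix: str = "RND",
) -> PeptideSet:
    """``n`` i.i.d.-composition peptides; lengths cycle through ``lengths``.

    Each record gets a unique synthetic protein id.
    """
    letters, probs = _composition_arrays(composition)
    rng = np.random.default_rng(seed)
    records = []
    for k in range(n):
        length = int(lengths[k % len(lengths)])
        seq = "".join(rng.choice(letters, size=length, p=probs))
        records.append(PeptideRecord(seq, f"{id_prefix}{k:04d}", label=label))
    return PeptideSet(records, name="random-background")


def sample_decoys(
    proteins: PeptideSet,
    functional_spans: Dict[str, Sequence[Tuple[int, int]]],
    lengths: Sequence[int],
    seed: int,
) -> PeptideSet:
    """Length-matched decoy fragments avoiding all functional spans.

    For each requested length a start position is drawn uniformly among
    placements that do not overlap any functional span, preferring the
    protein at the same cursor position and falling back to random other
    proteins.  Sampling is without replacement of (protein, start, length)
    triples.  Raises if some length cannot be placed anywhere.
    """
    rng = np.random.default_rng(seed)
    proteins_list = list(proteins.records)
    used: set = set()
    records = []
    unplaced = []
    for k, length in enumerate(lengths):
        order = [proteins_list[k % len(proteins_list)]]
        others = [p for p in proteins_list if p is not order[0]]
        rng.shuffle(others)
        order.extend(others)
        placed = False
        for protein in order:
            spans = functional_spans.get(protein.protein_id, [])
            candidates = [
                start
                for start in range(len(protein.sequence) - length + 1)
                if all(start + length <= s or start >= e for s, e in spans)
                and (protein.protein_id, start, length) not in used
            ]
            if not candidates:
                continue
            start = int(candidates[int(rng.integers(len(candidates)))])
            used.add((protein.protein_id, start, length))
            records.append(
                PeptideRecord(
                    protein.sequence[start : start + length],
                    protein.protein_id,
                    span=(start, start + length),
                    label="control",
                )
            )
            placed = True
            break
        if not placed:
            unplaced.append(length)
    if unplaced:
        raise ValueError(f"could not place decoys of lengths {unplaced} in any protein")
    return PeptideSet(records, name="decoys")


def _sample_motif_tiled(motif, length: int, rng, letters, probs, noise: float) -> str:
    """Sample a peptide by tiling the motif's position classes across ``length``.

    The tiling starts at a random phase, mimicking the repetitive
    low-complexity character of mineral-binding peptides; each position is
    drawn from its class, or from the background with probability ``noise``.
    """
    phase = int(rng.integers(len(motif)))
    out = []
    for k in range(length):
        position_class = motif[(phase + k) % len(motif)]
        if rng.random() < noise:
            out.append(str(rng.choice(letters, p=probs)))
        else:
            choices = sorted(position_class)
            out.append(choices[int(rng.integers(len(choices)))])
    return "".join(out)


def synthetic_dataset(spec: SyntheticSpec) -> Tuple[PeptideSet, PeptideSet, PeptideSet]:
    """Generate (functional, control, source proteins) per a SyntheticSpec.

    Functional peptides tile their family motif across their whole length;
    controls are pure background with matched lengths; each functional
    peptide is embedded in one synthetic source protein whose span is
    recorded on both the peptide and usable for recapture tests.
    """
    rng = np.random.default_rng(spec.seed)
    letters, probs = _composition_arrays(spec.background_composition)
    lo, hi = spec.length_range

    functional_records = []
    protein_records = []
    peptide_index = 0
    for family, size in enumerate(spec.family_sizes):
        motif = spec.motifs[family]
        for _ in range(size):
            length = int(rng.integers(lo, hi + 1))
            peptide = _sample_motif_tiled(
                motif, length, rng, letters, probs, spec.substitution_noise
            )
            protein_id = f"SYN{peptide_index:03d}"
            flank_a = int(rng.integers(*spec.flank_length))
            flank_b = int(rng.integers(*spec.flank_length))
            protein_seq = (
                "".join(rng.choice(letters, size=flank_a, p=probs))
                + peptide
                + "".join(rng.choice(letters, size=flank_b, p=probs))
            )
            span = (flank_a, flank_a + length)
            functional_records.append(
                PeptideRecord(peptide, protein_id, span=span, label="functional")
            )
            protein_records.append(PeptideRecord(protein_seq, protein_id))
            peptide_index += 1

    functional = PeptideSet(functional_records, name="synthetic-functional")
    peptide_lengths = [len(r.sequence) for r in functional]
    control = random_peptides(
        spec.background_composition,
        peptide_lengths,
        n=len(functional),
        seed=spec.seed + 1,
        label="control",
        id_prefix="CTL",
    )
    proteins = PeptideSet(protein_records, name="synthetic-proteins")
    return functional, control, proteins


def functional_spans_by_protein(functional: PeptideSet) -> Dict[str, list]:
    """Group recorded spans by source protein (for decoys and recapture)."""
    spans: Dict[str, list] = {}
    for rec in functional:
        if rec.span is None:
            raise ValueError(f"record {rec.sequence!r} has no span")
        spans.setdefault(rec.protein_id, []).append(rec.span)
    return spans
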