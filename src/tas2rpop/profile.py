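"""Receptor-family alignment variability profile.

Given a multiple alignment of the receptor protein sequences (aligned
FASTA, produced upstream) and, per receptor, the 1-based ungapped residue
positions carrying variants (optionally flagged PHI), tally how many
receptors are polymorphic at each alignment column and how variability and
PHI sites distribute over labeled substructures (extracellular loops,
transmembrane helices, intracellular loops; the N-terminus is grouped with
the ELs and the C-terminus with the ILs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from Bio import SeqIO

from .io import _iter_rows, write_tsv

logger = logging.getLogger(__name__)

SUBSTRUCTURE_CLASSES = ("EL", "TM", "IL")

GAP_CHARS = "-."


@dataclass
class Substructure:
    """A labeled interval of alignment columns (1-based inclusive)."""

    label: str
    cls: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.cls not in SUBSTRUCTURE_CLASSES:
            raise ValueError(f"substructure class must be one of {SUBSTRUCTURE_CLASSES}")
        if self.end < self.start:
            raise ValueError(f"{self.label}: end < start")


@dataclass
class AlignmentProfile:
    """Per-column variability counts over an aligned receptor family."""

    n_columns: int
    receptors: List[str]
    variable_receptors: List[set]   # per column: receptors with >= 1 variant there
    phi_flags: np.ndarray           # per column: any PHI variant maps there
    substructures: List[Substructure] = field(default_factory=list)

    @property
    def column_counts(self) -> np.ndarray:
        return np.array([len(s) for s in self.variable_receptors], dtype=np.int64)

    @property
    def n_variable_columns(self) -> int:
        return int((self.column_counts > 0).sum())


def read_alignment(path) -> Dict[str, str]:
    """Aligned FASTA -> {receptor: aligned sequence}; lengths must agree."""
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise ValueError("empty alignment")
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValueError("sequences have unequal aligned lengths")
    return seqs


def residue_to_column(aligned_seq: str, residue_index: int) -> int:
    """Map a 1-based ungapped residue index to its 1-based alignment column."""
    count = 0
    for col, ch in enumerate(aligned_seq, start=1):
        if ch not in GAP_CHARS:
            count += 1
            if count == residue_index:
                return col
    raise ValueError(f"residue index {residue_index} beyond ungapped length {count}")


def column_to_residue(aligned_seq: str, column: int) -> Optional[int]:
    """Inverse of :func:`residue_to_column`; None when the column is a gap."""
    if not 1 <= column <= len(aligned_seq):
        raise ValueError("column outside alignment")
    if aligned_seq[column - 1] in GAP_CHARS:
        return None
    return sum(1 for ch in aligned_seq[:column] if ch not in GAP_CHARS)


def map_variants_to_columns(
    alignment: Mapping[str, str],
    variant_residues: Mapping[str, Sequence[Tuple[int, bool]]],
    substructures: Sequence[Substructure] = (),
) -> AlignmentProfile:
    """Project per-receptor variant residues onto alignment columns.

    ``variant_residues``: receptor -> [(residue_index, is_phi), ...] with
    1-based ungapped indices.  A residue index beyond a receptor's ungapped
    length raises, naming receptor and index.
    """
    receptors = sorted(alignment)
    n_cols = len(next(iter(alignment.values())))
    variable: List[set] = [set() for _ in range(n_cols)]
    phi = np.zeros(n_cols, dtype=bool)
    for receptor, residues in variant_residues.items():
        if receptor not in alignment:
            raise ValueError(f"receptor {receptor!r} absent from alignment")
        seq = alignment[receptor]
        for residue_index, is_phi in residues:
            try:
                col = residue_to_column(seq, residue_index)
            except ValueError as exc:
                raise ValueError(f"{receptor}: {exc}") from None
            variable[col - 1].add(receptor)
            if is_phi:
                phi[col - 1] = True
    return AlignmentProfile(
        n_columns=n_cols,
        receptors=receptors,
        variable_receptors=variable,
        phi_flags=phi,
        substructures=list(substructures),
    )


def read_substructures(source) -> List[Substructure]:
    """Substructure TSV: label, class (EL/TM/IL), start, end (1-based
    inclusive alignment columns)."""
    subs = []
    for row in _iter_rows(source, expect_header=True):
        if len(row) < 4:
            raise ValueError("substructure row needs 4 columns: label class start end")
        subs.append(Substructure(row[0], row[1], int(row[2]), int(row[3])))
    return subs


def substructure_tally(profile: AlignmentProfile) -> Dict[str, Tuple[int, int]]:
    """Per-substructure (n_variable_columns, n_phi_columns).

    The substructure intervals must partition the alignment columns exactly;
    a column outside every interval (or covered twice) is an error.
    """
    if not profile.substructures:
        raise ValueError("no substructure intervals provided")
    coverage = np.zeros(profile.n_columns, dtype=np.int64)
    for sub in profile.substructures:
        if sub.end > profile.n_columns:
            raise ValueError(f"{sub.label} extends beyond the alignment")
        coverage[sub.start - 1 : sub.end] += 1
    if np.any(coverage != 1):
        bad = int(np.flatnonzero(coverage != 1)[0]) + 1
        raise ValueError(f"substructures do not partition the alignment (column {bad})")
    counts = profile.column_counts
    tally: Dict[str, Tuple[int, int]] = {}
    for sub in profile.substructures:
        sl = slice(sub.start - 1, sub.end)
        tally[sub.label] = (
            int((counts[sl] > 0).sum()),
            int(profile.phi_flags[sl].sum()),
        )
    return tally


def write_profile(profile: AlignmentProfile, path: str) -> None:
    """Per-column counts TSV: column, n_variable_receptors, phi."""
    write_tsv(
        path,
        ["column", "n_variable_receptors", "phi"],
        (
            (i + 1, len(profile.variable_receptors[i]), int(profile.phi_flags[i]))
            for i in range(profile.n_columns)
        ),
    )
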