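"""Candidate neoepitope enumeration and expression filtering.

Every coding mutation that changes the protein spawns candidate 9-mer
peptides: all distinct windows of nine amino acids of the mutant protein that
overlap a mutated residue (up to nine for an internal missense change, fewer
near the termini; for frameshifts, every window touching the novel C-terminal
sequence through its new stop).  Candidates can then be restricted to
expressed genes via a TPM table; MHC-binding prediction is an external
hand-off and out of scope here.

A simple clonality annotation is included: the cancer-cell fraction of each
mutation is estimated as CCF = VAF * (purity*CN + 2*(1-purity)) /
(purity*multiplicity) and mutations with CCF >= 0.75 are labeled clonal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

WINDOW = 9
DEFAULT_MIN_TPM = 1.0
DEFAULT_CLONAL_CCF = 0.75


@dataclass(frozen=True)
class Peptide:
    """A candidate 9-mer neoepitope."""

    sequence: str
    protein_id: str
    mutated_position: int  # 1-based position of (first) mutated residue in peptide
    mutation_id: str
    expressed: bool = True

    def __post_init__(self) -> None:
        if len(self.sequence) != WINDOW:
            raise ValueError("peptides must be exactly 9 residues")
        if not (1 <= self.mutated_position <= WINDOW):
            raise ValueError("mutated position must fall inside the peptide")


@dataclass
class ProteinMutation:
    """An amino-acid-level change at 1-based position ``position``.

    ``kind`` is ``missense`` (alt_aa replaces ref_aa) or ``frameshift``
    (``novel_tail`` replaces everything from ``position`` to the new stop).
    A missense with alt_aa == ref_aa is synonymous and yields no peptides.
    """

    mutation_id: str
    protein_id: str
    position: int
    kind: str = "missense"
    ref_aa: str = ""
    alt_aa: str = ""
    novel_tail: str = ""
    gene: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in {"missense", "frameshift"}:
            raise ValueError(f"unknown mutation kind {self.kind!r}")


def mutant_protein(sequence: str, mutation: ProteinMutation) -> tuple[str, int, int]:
    """Apply the mutation; returns (mutant sequence, first, last mutated position).

    Positions are 1-based on the mutant sequence.  Raises ``ValueError`` when
    the mutation position falls outside the protein.
    """
    p = mutation.position
    if not (1 <= p <= len(sequence)):
        raise ValueError(f"position {p} outside protein of length {len(sequence)}")
    if mutation.kind == "missense":
        mut = sequence[: p - 1] + mutation.alt_aa + sequence[p:]
        return mut, p, p
    mut = sequence[: p - 1] + mutation.novel_tail
    return mut, p, len(mut)


def enumerate_neoepitopes(
    protein_sequence: str, mutation: ProteinMutation
) -> list[Peptide]:
    """All distinct 9-mers of the mutant protein overlapping a mutated residue.

    Synonymous changes return an empty list.  Duplicate window sequences are
    reported once (first occurrence).
    """
    if mutation.kind == "missense" and mutation.alt_aa == mutation.ref_aa:
        return []
    mut, first, last = mutant_protein(protein_sequence, mutation)
    if len(mut) < WINDOW:
        return []
    peptides: list[Peptide] = []
    seen: set[str] = set()
    start_lo = max(1, first - WINDOW + 1)
    start_hi = min(last, len(mut) - WINDOW + 1)
    for start in range(start_lo, start_hi + 1):
        window = mut[start - 1 : start - 1 + WINDOW]
        if window in seen:
            continue
        seen.add(window)
        mut_pos = max(first - start + 1, 1)
        peptides.append(
            Peptide(window, mutation.protein_id, mut_pos, mutation.mutation_id)
        )
    return peptides


def filter_expressed(
    peptides: Sequence[Peptide],
    expression: Optional[Mapping[str, float]] = None,
    gene_of: Optional[Mapping[str, str]] = None,
    min_tpm: float = DEFAULT_MIN_TPM,
) -> list[Peptide]:
    """Keep peptides whose source gene is expressed at >= ``min_tpm``.

    Without an expression table the list passes through unchanged (expression
    data is used only "where available").  ``gene_of`` maps protein ids to
    gene ids; absent, protein ids are looked up directly.
    """
    if expression is None:
        return list(peptides)
    kept = []
    for pep in peptides:
        gene = gene_of.get(pep.protein_id, pep.protein_id) if gene_of else pep.protein_id
        if expression.get(gene, 0.0) >= min_tpm:
            kept.append(pep)
    return kept


def cancer_cell_fraction(
    vaf: float, purity: float, copy_number: float, multiplicity: float = 1.0
) -> float:
    """CCF under the standard purity/copy-number adjustment of the VAF."""
    if purity <= 0:
        raise ValueError("purity must be positive")
    return vaf * (purity * copy_number + 2.0 * (1.0 - purity)) / (purity * multiplicity)


def neoantigen_clonality(
    mutations: Sequence[Mapping[str, float]],
    purity: float,
    clonal_ccf: float = DEFAULT_CLONAL_CCF,
) -> tuple[list[bool], float]:
    """Per-mutation clonal flags and the clonal fraction of the cohort.

    Each mutation mapping supplies ``vaf``, optional ``copy_number``
    (default 2) and optional ``multiplicity`` (default 1).
    """
    flags = [
        cancer_cell_fraction(
            m["vaf"], purity, m.get("copy_number", 2.0), m.get("multiplicity", 1.0)
        )
        >= clonal_ccf
        for m in mutations
    ]
    fraction = sum(flags) / len(flags) if flags else 0.0
    return flags, fraction
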