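"""Genetic-code tables and per-position codon degeneracy classes.

The load estimators partition codon positions into 0-, 2- and 4-fold
degenerate classes under a genetic code. The pipeline default is the
vertebrate mitochondrial code (NCBI translation table 2: AGA/AGG are stops,
ATA is Met, TGA is Trp), which is the code of the bovine mitochondrial
protein-coding genes the pipeline analyses.

A position is 4-fold degenerate when all three single-base alternatives at
that position yield a sense codon for the same amino acid, 0-fold when none
does, and 2-fold otherwise. Changes that create a stop codon are
nonsynonymous for classification purposes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Data import CodonTable

from .errors import InputError

BASES = "ACGT"
PURINES = frozenset("AG")

#: all 64 codons in lexicographic ACGT order; index = 16*b1 + 4*b2 + b3
CODONS = tuple(a + b + c for a in BASES for b in BASES for c in BASES)
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}

STOP = "*"


def is_transition(base_a: str, base_b: str) -> bool:
    """True when the unordered base pair is purine-purine or pyrimidine-pyrimidine."""
    return base_a != base_b and (base_a in PURINES) == (base_b in PURINES)


@dataclass(frozen=True)
class GeneticCode:
    """A complete 64-codon translation table.

    Attributes
    ----------
    table_id:
        NCBI translation-table number (1 = standard, 2 = vertebrate mito).
    codon_to_aa:
        Maps every codon to a one-letter amino acid, or ``"*"`` for stops.
    """

    table_id: int
    codon_to_aa: dict[str, str] = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.codon_to_aa) != 64:
            raise InputError(
                f"genetic code table {self.table_id}: expected 64 codons, "
                f"got {len(self.codon_to_aa)}"
            )

    @property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(c for c, aa in self.codon_to_aa.items() if aa == STOP)

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(c for c in CODONS if self.codon_to_aa[c] != STOP)

    def is_stop(self, codon: str) -> bool:
        return self.codon_to_aa.get(codon) == STOP

    def translate(self, codon: str) -> str:
        try:
            return self.codon_to_aa[codon]
        except KeyError:
            raise InputError(f"not an unambiguous codon: {codon!r}") from None


@lru_cache(maxsize=None)
def build_code(table_id: int = 2) -> GeneticCode:
    """Build a :class:`GeneticCode` from the NCBI table registry.

    Table 2 (vertebrate mitochondrial) is the pipeline default; table 1 is
    supported for nuclear data. Unknown table ids raise :class:`InputError`.
    """
    try:
        ncbi = CodonTable.unambiguous_dna_by_id[table_id]
    except KeyError:
        raise InputError(f"unsupported translation table: {table_id}") from None
    mapping = {}
    for codon in CODONS:
        if codon in ncbi.stop_codons:
            mapping[codon] = STOP
        else:
            mapping[codon] = ncbi.forward_table[codon]
    return GeneticCode(table_id=table_id, codon_to_aa=mapping)


def is_synonymous_change(codon: str, pos: int, new_base: str, code: GeneticCode) -> bool:
    """Whether replacing ``codon[pos]`` by ``new_base`` preserves the amino acid.

    A change producing a stop codon is nonsynonymous. ``codon`` must be a
    sense codon.
    """
    if code.is_stop(codon):
        raise InputError(f"stop codon has no synonymy class: {codon}")
    if new_base == codon[pos]:
        raise InputError("new_base equals the current base; not a change")
    mutated = codon[:pos] + new_base + codon[pos + 1 :]
    aa_new = code.translate(mutated)
    return aa_new != STOP and aa_new == code.translate(codon)


def degeneracy(codon: str, code: GeneticCode) -> tuple[int, int, int]:
    """Degeneracy class (0, 2 or 4) of each of the three codon positions.

    Raises :class:`InputError` for stop or ambiguous codons; ambiguous codons
    are excluded upstream by the pairwise counters.
    """
    return _degeneracy_cached(codon, code.table_id)


@lru_cache(maxsize=None)
def _degeneracy_cached(codon: str, table_id: int) -> tuple[int, int, int]:
    code = build_code(table_id)
    if codon not in CODON_INDEX:
        raise InputError(f"not an unambiguous codon: {codon!r}")
    if code.is_stop(codon):
        raise InputError(f"degeneracy undefined for stop codon {codon}")
    triple = []
    for pos in range(3):
        n_syn = sum(
            1
            for b in BASES
            if b != codon[pos] and is_synonymous_change(codon, pos, b, code)
        )
        triple.append(4 if n_syn == 3 else (0 if n_syn == 0 else 2))
    return tuple(triple)


def degeneracy_table(code: GeneticCode) -> dict[str, tuple[int, int, int]]:
    """Degeneracy triples for every sense codon (for export/inspection)."""
    return {c: degeneracy(c, code) for c in code.sense_codons}
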