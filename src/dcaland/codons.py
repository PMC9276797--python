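"""Genetic-code utilities: 1-SNP codon neighborhoods.

Every codon has exactly nine single-nucleotide neighbors (three positions ×
three alternative bases). Classifying them against the source amino acid
gives the synonymous / non-synonymous / stop partition, and collapsing the
non-stop neighbors to amino acids gives the 1-SNP-reachable amino-acid set
used to restrict entropies and to drive the neutral simulator. Only the
standard genetic code (translation table 1) is supported.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio.Data import CodonTable
from Bio.Seq import Seq

NUCLEOTIDES = "ACGT"
STOP = "*"

_table = CodonTable.unambiguous_dna_by_id[1]


class GeneticCode:
    """Standard genetic code as a codon → amino acid (or ``*``) map."""

    def __init__(self) -> None:
        self.forward: dict[str, str] = dict(_table.forward_table)
        for stop in _table.stop_codons:
            self.forward[stop] = STOP
        assert len(self.forward) == 64
        self.stop_codons = frozenset(_table.stop_codons)
        self.sense_codons = frozenset(c for c, aa in self.forward.items() if aa != STOP)

    def translate(self, codon: str) -> str:
        codon = codon.upper()
        if codon not in self.forward:
            raise ValueError(f"invalid codon {codon!r}")
        return self.forward[codon]

    def is_stop(self, codon: str) -> bool:
        return self.translate(codon) == STOP

    def synonymous_codons(self, aa: str) -> list[str]:
        return sorted(c for c in self.sense_codons if self.forward[c] == aa)


STANDARD_CODE = GeneticCode()

SYNONYMOUS = "synonymous"
NONSYNONYMOUS = "nonsynonymous"
STOP_CLASS = "stop"


@lru_cache(maxsize=None)
def snp_neighbors(codon: str) -> tuple[tuple[str, str, str], ...]:
    """The 9 single-nucleotide neighbors of ``codon``.

    Returns tuples ``(neighbor_codon, class, encoded)`` where class is
    synonymous / nonsynonymous / stop and ``encoded`` is the neighbor's
    amino acid (or ``*``).
    """
    codon = codon.upper()
    if len(codon) != 3 or any(n not in NUCLEOTIDES for n in codon):
        raise ValueError(f"invalid codon {codon!r}")
    source_aa = STANDARD_CODE.translate(codon)
    out = []
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            neighbor = codon[:pos] + nt + codon[pos + 1 :]
            aa = STANDARD_CODE.translate(neighbor)
            if aa == STOP:
                cls = STOP_CLASS
            elif aa == source_aa:
                cls = SYNONYMOUS
            else:
                cls = NONSYNONYMOUS
            out.append((neighbor, cls, aa))
    assert len(out) == 9
    return tuple(out)


def one_snp_amino_acids(codon: str, include_native: bool = True) -> set[str]:
    """Amino acids reachable from a sense codon by one SNP (stops excluded).

    With ``include_native`` (default, as used for restricted entropies) the
    source amino acid is part of the set, since it is reachable with zero
    mutations and via synonymous neighbors.
    """
    source_aa = STANDARD_CODE.translate(codon)
    if source_aa == STOP:
        raise ValueError(f"stop codon {codon!r} has no amino-acid neighborhood")
    reachable = {aa for _, cls, aa in snp_neighbors(codon) if cls == NONSYNONYMOUS}
    if include_native:
        reachable.add(source_aa)
    return reachable


def count_neighbor_classes(codon: str) -> dict[str, int]:
    counts = {SYNONYMOUS: 0, NONSYNONYMOUS: 0, STOP_CLASS: 0}
    for _, cls, _ in snp_neighbors(codon):
        counts[cls] += 1
    return counts


@dataclass
class CodonReference:
    """Codon layer of a reference protein: one sense codon per residue."""

    codons: list[str]

    def __post_init__(self) -> None:
        for c in self.codons:
            if STANDARD_CODE.is_stop(c):
                raise ValueError(f"reference codon {c!r} is a stop codon")

    def __len__(self) -> int:
        return len(self.codons)

    def protein(self) -> str:
        return "".join(STANDARD_CODE.translate(c) for c in self.codons)

    def is_consistent_with(self, protein: str) -> bool:
        return self.protein() == protein.upper()


def read_codon_reference(path) -> CodonReference:
    """Load the reference CDS from a nucleotide FASTA (in frame, no stop)."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one CDS record in {path}, found {len(records)}")
    seq = str(records[0].seq).upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise ValueError("CDS length is not divisible by 3")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if codons and STANDARD_CODE.is_stop(codons[-1]):
        codons = codons[:-1]
    return CodonReference(codons)


def calibration_sites(codon_ref: CodonReference) -> list[int]:
    """1-based positions whose codon has exactly three synonymous 1-SNP neighbors.

    These (four-fold degenerate third positions, mostly) anchor the
    synonymous-diversity calibration of the neutral simulator.
    """
    sites = []
    for pos, codon in enumerate(codon_ref.codons, start=1):
        if count_neighbor_classes(codon)[SYNONYMOUS] == 3:
            sites.append(pos)
    return sites


def translate_cds(seq: str) -> str:
    return str(Seq(seq).translate(table=1))
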