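"""State space shared by all landscape models.

The training alphabet has 21 states: the 20 canonical amino acids in
alphabetical one-letter order, plus the alignment gap ``-`` as a full 21st
state. Entropies and conditional distributions downstream restrict their
support to the amino acids; the gap state only participates in training and
in energy evaluation of gapped contexts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
GAP: str = "-"


@dataclass(frozen=True)
class Alphabet:
    """Ordered symbol set with a bijective symbol↔state-index map.

    The gap is always the last state, so the first ``q - 1`` states are the
    residue states and slicing ``[:q-1]`` drops the gap everywhere.
    """

    symbols: str = AMINO_ACIDS + GAP
    index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be unique")
        if self.symbols[-1] != GAP:
            raise ValueError("gap must be the last alphabet state")
        object.__setattr__(self, "index", {s: i for i, s in enumerate(self.symbols)})

    @property
    def q(self) -> int:
        return len(self.symbols)

    @property
    def n_residues(self) -> int:
        """Number of non-gap states (20 for the standard protein alphabet)."""
        return self.q - 1

    @property
    def gap_state(self) -> int:
        return self.q - 1

    def encode(self, seq: str) -> list[int]:
        return [self.index[c] for c in seq]

    def decode(self, states) -> str:
        return "".join(self.symbols[int(s)] for s in states)

    def __len__(self) -> int:
        return self.q

    def __eq__(self, other) -> bool:
        return isinstance(other, Alphabet) and self.symbols == other.symbols


DEFAULT_ALPHABET = Alphabet()


def reduced_alphabet(q: int) -> Alphabet:
    """Alphabet with ``q - 1`` residue states plus gap (for small test models)."""
    if not 2 <= q <= 21:
        raise ValueError("q must be between 2 and 21")
    return Alphabet(AMINO_ACIDS[: q - 1] + GAP)
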