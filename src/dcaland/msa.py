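"""Alignment handling: reading, validation, filtering, reweighting.

Alignments are stored column-encoded as an ``(M, L)`` integer matrix over
the 21-state alphabet. Sequence reweighting follows the standard DCA
convention: the weight of a sequence is the reciprocal of the number of
alignment members (itself included) within identity ``1 - theta``, with
``theta = 0.2`` by default, and the effective depth ``m_eff`` is the sum of
weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

from dcaland.alphabet import DEFAULT_ALPHABET, Alphabet

logger = logging.getLogger(__name__)


class AlignmentError(ValueError):
    """Malformed or unusable alignment."""


class TooFewSequencesError(AlignmentError):
    """Training filter left fewer sequences than the minimum (default 200)."""


@dataclass
class MSA:
    """An aligned set of protein sequences over the 21-state alphabet.

    Attributes
    ----------
    ids : list of str
        Unique sequence identifiers, in file order.
    matrix : ndarray of shape (M, L), dtype int8
        State-encoded residues.
    alphabet : Alphabet
    reference_id : str or None
        Designated reference sequence, if any.
    """

    ids: list[str]
    matrix: np.ndarray
    alphabet: Alphabet = field(default_factory=lambda: DEFAULT_ALPHABET)
    reference_id: str | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.ndim != 2:
            raise AlignmentError("MSA matrix must be 2-dimensional")
        if len(self.ids) != self.matrix.shape[0]:
            raise AlignmentError("number of ids does not match number of rows")
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentError("duplicate sequence ids in alignment")
        if self.reference_id is not None and self.reference_id not in self.ids:
            raise AlignmentError(f"reference id {self.reference_id!r} not in alignment")

    @property
    def M(self) -> int:
        return self.matrix.shape[0]

    @property
    def L(self) -> int:
        return self.matrix.shape[1]

    def row(self, seq_id: str) -> np.ndarray:
        return self.matrix[self.ids.index(seq_id)]

    def sequence(self, seq_id: str) -> str:
        return self.alphabet.decode(self.row(seq_id))

    def reference_row(self) -> np.ndarray:
        if self.reference_id is None:
            raise AlignmentError("MSA has no designated reference")
        return self.row(self.reference_id)

    def subset_sequences(self, keep: np.ndarray) -> "MSA":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        ids = [self.ids[i] for i in keep]
        ref = self.reference_id if self.reference_id in ids else None
        return MSA(ids, self.matrix[keep], self.alphabet, ref)

    def subset_columns(self, cols: np.ndarray) -> "MSA":
        cols = np.asarray(cols)
        if cols.dtype == bool:
            cols = np.flatnonzero(cols)
        return MSA(list(self.ids), self.matrix[:, cols], self.alphabet, self.reference_id)


@dataclass
class SequenceWeights:
    """Per-sequence clustering weights at identity threshold ``1 - theta``."""

    weights: dict[str, float]
    theta: float
    m_eff: float

    def vector(self, msa: MSA) -> np.ndarray:
        return np.array([self.weights[i] for i in msa.ids])


@dataclass
class ColumnMap:
    """1-based mapping between retained MSA columns and reference positions."""

    msa_col: np.ndarray  # 1-based column index in the source MSA
    ref_pos: np.ndarray  # 1-based position in the ungapped reference
    analyzable: np.ndarray  # bool mask over the retained columns

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"msa_col": self.msa_col, "ref_pos": self.ref_pos, "analyzable": self.analyzable}
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_msa(
    path,
    format: str = "fasta",
    alphabet: Alphabet = DEFAULT_ALPHABET,
    reference_id: str | None = None,
) -> MSA:
    """Read an aligned FASTA file into an :class:`MSA`.

    Lowercase letters are uppercased, ``.`` gaps are normalized to ``-``,
    and symbols outside the alphabet (``X``, ``B``, ``Z``, ...) are replaced
    by the gap state; the number of such replacements is logged.
    """
    if format != "fasta":
        raise ValueError(f"unsupported alignment format: {format!r}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no sequences found in {path}")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise AlignmentError("duplicate sequence ids in alignment")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise AlignmentError(f"ragged alignment: sequence lengths {sorted(lengths)}")
    L = lengths.pop()
    if L == 0:
        raise AlignmentError("alignment has zero columns")

    gap_state = alphabet.gap_state
    matrix = np.empty((len(records), L), dtype=np.int8)
    n_substituted = 0
    for m, rec in enumerate(records):
        s = str(rec.seq).upper().replace(".", "-")
        for j, c in enumerate(s):
            state = alphabet.index.get(c)
            if state is None:
                state = gap_state
                n_substituted += 1
            matrix[m, j] = state
    if n_substituted:
        logger.info(
            "replaced %d non-canonical symbols with gaps while reading %s",
            n_substituted,
            path,
        )
    msa = MSA(ids, matrix, alphabet, reference_id)
    msa.n_substituted = n_substituted
    return msa


def write_msa(msa: MSA, path) -> None:
    with open(path, "w") as fh:
        for i, sid in enumerate(msa.ids):
            fh.write(f">{sid}\n{msa.alphabet.decode(msa.matrix[i])}\n")


def project_to_reference(msa: MSA, reference_id: str) -> tuple[MSA, ColumnMap]:
    """Drop columns where the reference is gapped (inserts relative to it).

    Returns the restricted MSA and a 1-based :class:`ColumnMap` from retained
    MSA columns to reference positions ``1..L_ref``.
    """
    if reference_id not in msa.ids:
        raise AlignmentError(f"reference id {reference_id!r} not in alignment")
    ref = msa.matrix[msa.ids.index(reference_id)]
    keep = ref != msa.alphabet.gap_state
    if not keep.any():
        raise AlignmentError("empty projection: reference is entirely gaps")
    cols = np.flatnonzero(keep)
    projected = msa.subset_columns(cols)
    projected.reference_id = reference_id
    cmap = ColumnMap(
        msa_col=cols + 1,
        ref_pos=np.arange(1, cols.size + 1),
        analyzable=np.ones(cols.size, dtype=bool),
    )
    return projected, cmap


def mask_gappy_columns(msa: MSA, max_gap_frac: float = 0.2) -> np.ndarray:
    """Mask of columns whose gap fraction is ≤ ``max_gap_frac``.

    Columns gapped in more than 20% of sequences (default) are excluded
    from every downstream entropy and score analysis.
    """
    if msa.M == 0:
        raise AlignmentError("empty alignment")
    gap_frac = (msa.matrix == msa.alphabet.gap_state).mean(axis=0)
    return gap_frac <= max_gap_frac


def sequence_identity(a: np.ndarray | str, b: np.ndarray | str, alphabet: Alphabet = DEFAULT_ALPHABET) -> float:
    """Fraction of identical residues between two aligned sequences.

    Positions gapped in both sequences are excluded from the denominator; a
    gap aligned to a residue counts as a mismatch (so identity(x, x) = 1).
    """
    a = np.asarray(alphabet.encode(a) if isinstance(a, str) else a)
    b = np.asarray(alphabet.encode(b) if isinstance(b, str) else b)
    if a.shape != b.shape:
        raise AlignmentError("sequence length mismatch")
    gap = alphabet.gap_state
    both_gap = (a == gap) & (b == gap)
    compared = int((~both_gap).sum())
    if compared == 0:
        return 1.0
    matches = int(((a == b) & ~both_gap).sum())
    return matches / compared


def _pairwise_identity_matrix(matrix: np.ndarray, gap_state: int, chunk: int = 256) -> np.ndarray:
    """Dense M×M identity matrix (both-gap positions excluded per pair)."""
    M, L = matrix.shape
    is_gap = matrix == gap_state
    ident = np.empty((M, M))
    for start in range(0, M, chunk):
        stop = min(start + chunk, M)
        eq = matrix[start:stop, None, :] == matrix[None, :, :]
        both_gap = is_gap[start:stop, None, :] & is_gap[None, :, :]
        compared = L - both_gap.sum(axis=2)
        matches = (eq & ~both_gap).sum(axis=2)
        with np.errstate(invalid="ignore"):
            ident[start:stop] = np.where(compared > 0, matches / np.maximum(compared, 1), 1.0)
    return ident


def compute_weights(msa: MSA, theta: float = 0.2) -> SequenceWeights:
    """Cluster-based sequence weights: w_m = 1 / #{m' : identity(m, m') ≥ 1 − θ}.

    The neighbor set includes the sequence itself, so 0 < w ≤ 1 and
    1 ≤ m_eff ≤ M.
    """
    if msa.M == 0:
        raise AlignmentError("empty alignment")
    ident = _pairwise_identity_matrix(msa.matrix, msa.alphabet.gap_state)
    n_neighbors = (ident >= 1.0 - theta).sum(axis=1)
    w = 1.0 / n_neighbors
    weights = {sid: float(wi) for sid, wi in zip(msa.ids, w)}
    return SequenceWeights(weights=weights, theta=theta, m_eff=float(w.sum()))


def filter_training_sequences(
    msa: MSA,
    reference: np.ndarray | str | None = None,
    max_ref_identity: float = 0.9,
    max_seq_gap_frac: float = 0.1,
    min_sequences: int = 200,
) -> MSA:
    """Apply the training-alignment curation filters.

    Removes sequences with identity to the reference above
    ``max_ref_identity`` (default: >90%) and sequences whose gap fraction
    exceeds ``max_seq_gap_frac`` (default: >10%). Raises
    :class:`TooFewSequencesError` if fewer than ``min_sequences`` survive —
    a model must not be trained on such a family.
    """
    if reference is None:
        reference = msa.reference_row()
    ref = np.asarray(msa.alphabet.encode(reference) if isinstance(reference, str) else reference)
    if ref.shape[0] != msa.L:
        raise AlignmentError("reference length does not match alignment")
    gap = msa.alphabet.gap_state
    keep = np.ones(msa.M, dtype=bool)
    gap_frac = (msa.matrix == gap).mean(axis=1)
    keep &= gap_frac <= max_seq_gap_frac
    for m in range(msa.M):
        if keep[m] and sequence_identity(msa.matrix[m], ref, msa.alphabet) > max_ref_identity:
            keep[m] = False
    out = msa.subset_sequences(keep)
    if out.M < min_sequences:
        raise TooFewSequencesError(
            f"only {out.M} sequences remain after filtering (< {min_sequences}); "
            "model should not be trained for this family"
        )
    return out
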