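"""Potts and independent landscape models and their elementary queries.

A Potts model assigns every aligned sequence (a_1, ..., a_L) a statistical
energy

    E(a) = − Σ_{i<j} J_ij(a_i, a_j) − Σ_i h_i(a_i),

lower meaning more compatible with the protein family. The score of a
single substitution α→β at site i in a fixed background is the energy
difference

    ΔE_i = h_i(α) − h_i(β) + Σ_{j≠i} [J_ij(α, a_j) − J_ij(β, a_j)],

positive predicting a deleterious change. Exponentiating the site terms
and normalizing over the 20 amino acids (gaps are excluded from the
support, since only substitutions are modeled) turns the landscape into a
conditional distribution at each site given the rest of the sequence.

The independent model keeps only reweighted per-column frequencies and is
the non-epistatic baseline throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np

from dcaland.alphabet import DEFAULT_ALPHABET, Alphabet


class ModelFormatError(ValueError):
    """Unreadable or incompatible serialized model."""


def _encode(seq, alphabet: Alphabet) -> np.ndarray:
    if isinstance(seq, str):
        return np.asarray(alphabet.encode(seq), dtype=np.int64)
    return np.asarray(seq, dtype=np.int64)


@dataclass
class PottsModel:
    """Pairwise (epistatic) landscape with fields ``h`` and couplings ``J``.

    Attributes
    ----------
    h : ndarray (L, q)
        Per-site fields.
    J : ndarray (L, L, q, q)
        Couplings with ``J[i, j] == J[j, i].T`` and zero diagonal blocks.
    gauge : str
        ``"raw"`` or ``"zero-sum"``.
    metadata : dict
        Free-form training provenance (m_eff, regularization, ...).
    """

    h: np.ndarray
    J: np.ndarray
    alphabet: Alphabet = field(default_factory=lambda: DEFAULT_ALPHABET)
    gauge: str = "raw"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        self.J = np.asarray(self.J, dtype=float)
        L, q = self.h.shape
        if self.J.shape != (L, L, q, q):
            raise ValueError(f"J shape {self.J.shape} incompatible with h shape {self.h.shape}")
        if q != self.alphabet.q:
            raise ValueError(f"q={q} does not match alphabet size {self.alphabet.q}")

    @property
    def L(self) -> int:
        return self.h.shape[0]

    @property
    def q(self) -> int:
        return self.h.shape[1]

    def coupling(self, i: int, j: int) -> np.ndarray:
        """The q×q coupling block for the ordered site pair (i, j), 0-based."""
        return self.J[i, j]

    def validate_symmetry(self, atol: float = 1e-8) -> bool:
        return bool(
            np.allclose(self.J, np.transpose(self.J, (1, 0, 3, 2)), atol=atol)
            and np.allclose(self.J[np.arange(self.L), np.arange(self.L)], 0.0, atol=atol)
        )


@dataclass
class IndependentModel:
    """Per-site reweighted frequencies over the 21 states (incl. gap)."""

    f: np.ndarray  # (L, q), rows sum to 1
    alphabet: Alphabet = field(default_factory=lambda: DEFAULT_ALPHABET)
    pseudocount: float = 0.01
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        if not np.allclose(self.f.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("site frequencies must sum to 1")

    @property
    def L(self) -> int:
        return self.f.shape[0]

    @property
    def q(self) -> int:
        return self.f.shape[1]

    def residue_frequencies(self, site: int) -> np.ndarray:
        """Gap-excluded, renormalized frequencies over the q−1 residue states."""
        fa = self.f[site, : self.alphabet.n_residues].astype(float)
        total = fa.sum()
        if total <= 0.0:
            raise ValueError(f"site {site} is entirely gaps; mask it upstream")
        return fa / total


@dataclass
class ConditionalDistribution:
    """Distribution over the residue states at one site, given a context."""

    site: int  # 1-based position
    probs: np.ndarray  # (q−1,) over the amino acids, sums to 1
    context_id: str = ""
    alphabet: Alphabet = field(default_factory=lambda: DEFAULT_ALPHABET)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (self.alphabet.n_residues,):
            raise ValueError("probs must cover exactly the residue states")

    def entropy_bits(self) -> float:
        p = self.probs[self.probs > 0]
        return float(-(p * np.log2(p)).sum())


def statistical_energy(model: PottsModel, seq) -> float:
    """Potts energy E(a) = −Σ_{i<j} J_ij(a_i,a_j) − Σ_i h_i(a_i)."""
    a = _encode(seq, model.alphabet)
    if a.shape[0] != model.L:
        raise ValueError(f"sequence length {a.shape[0]} != model length {model.L}")
    idx = np.arange(model.L)
    field_term = model.h[idx, a].sum()
    # ordered-pair sum counts each unordered pair twice; diagonal blocks are zero
    coupling_term = model.J[idx[:, None], idx[None, :], a[:, None], a[None, :]].sum() / 2.0
    return float(-coupling_term - field_term)


def _site_logits(model: PottsModel, a: np.ndarray, site: int) -> np.ndarray:
    """h_i(·) + Σ_{j≠i} J_ij(·, a_j) for all q states at ``site`` (0-based)."""
    contrib = model.J[site, np.arange(model.L), :, a]  # (L, q); row `site` is zero
    return model.h[site] + contrib.sum(axis=0)


def mutation_score(model: PottsModel, context, site: int, from_aa: str, to_aa: str) -> float:
    """ΔE of substituting ``from_aa``→``to_aa`` at 1-based ``site`` in ``context``.

    Positive = predicted deleterious. Identical to the energy difference
    between mutant and context sequences.
    """
    a = _encode(context, model.alphabet)
    i = site - 1
    alpha = model.alphabet.index[from_aa]
    beta = model.alphabet.index[to_aa]
    if a[i] != alpha:
        raise ValueError(
            f"context carries {model.alphabet.symbols[a[i]]!r} at site {site}, not {from_aa!r}"
        )
    logits = _site_logits(model, a, i)
    return float(logits[alpha] - logits[beta])


def conditional_probabilities(
    model: PottsModel, context, site: int, context_id: str = ""
) -> ConditionalDistribution:
    """P_i(β | a_\\i) ∝ exp{h_i(β) + Σ_{j≠i} J_ij(β, a_j)} over the residues.

    The gap state is excluded from the support. Uses a max-shifted softmax
    for numerical stability.
    """
    a = _encode(context, model.alphabet)
    i = site - 1
    logits = _site_logits(model, a, i)[: model.alphabet.n_residues]
    logits = logits - logits.max()
    w = np.exp(logits)
    return ConditionalDistribution(
        site=site, probs=w / w.sum(), context_id=context_id, alphabet=model.alphabet
    )


def ind_probabilities(
    model: IndependentModel, site: int, pseudocount: float | None = None
) -> ConditionalDistribution:
    """Smoothed, gap-excluded site distribution of the independent model.

    p_i(β) = (1 − α) f̃_i(β) + α / n_residues, with f̃ the frequencies
    renormalized over the residue states and α the pseudocount.
    """
    alpha = model.pseudocount if pseudocount is None else pseudocount
    ft = model.residue_frequencies(site - 1)
    n = model.alphabet.n_residues
    probs = (1.0 - alpha) * ft + alpha / n
    return ConditionalDistribution(site=site, probs=probs, context_id="IND", alphabet=model.alphabet)


def rank_amino_acid(dist: ConditionalDistribution, aa: str) -> int:
    """Rank of ``aa`` (1 = most probable); ties break alphabetically."""
    idx = dist.alphabet.index[aa]
    if idx >= dist.alphabet.n_residues:
        raise ValueError("rank is defined for amino acids only")
    p = dist.probs
    greater = int((p > p[idx]).sum())
    tied_before = int(((p[:idx] == p[idx])).sum())
    return 1 + greater + tied_before


def gauge_transform(model: PottsModel, target: str = "zero-sum") -> PottsModel:
    """Re-gauge the model; energies change only by an additive constant.

    In the zero-sum gauge every row and column of each coupling block and
    every field vector sums to zero, which makes coupling magnitudes
    comparable across pairs (needed for Frobenius scores and the inverse
    participation ratio).
    """
    if target != "zero-sum":
        raise ValueError(f"unknown gauge {target!r}")
    J = model.J
    row_mean = J.mean(axis=3, keepdims=True)  # mean over b
    col_mean = J.mean(axis=2, keepdims=True)  # mean over a
    grand = J.mean(axis=(2, 3), keepdims=True)
    J_zs = J - row_mean - col_mean + grand
    # absorb the row means into the fields: h'_i(a) += Σ_{j≠i} (mean_b J_ij(a,b) − mean_ab J_ij)
    h_shift = (row_mean - grand)[:, :, :, 0].sum(axis=1)  # (L, q)
    h_new = model.h + h_shift
    h_new = h_new - h_new.mean(axis=1, keepdims=True)
    return PottsModel(
        h=h_new, J=J_zs, alphabet=model.alphabet, gauge="zero-sum", metadata=dict(model.metadata)
    )


def save_model(model: PottsModel | IndependentModel, path) -> None:
    """Serialize a model to a single HDF5 container."""
    with h5py.File(path, "w") as fh:
        fh.attrs["format_version"] = 1
        fh.attrs["alphabet"] = model.alphabet.symbols
        fh.attrs["metadata"] = json.dumps(model.metadata)
        if isinstance(model, PottsModel):
            fh.attrs["kind"] = "potts"
            fh.attrs["gauge"] = model.gauge
            fh.create_dataset("h", data=model.h)
            fh.create_dataset("J", data=model.J, compression="gzip")
        else:
            fh.attrs["kind"] = "independent"
            fh.attrs["pseudocount"] = model.pseudocount
            fh.create_dataset("f", data=model.f)


def load_model(path) -> PottsModel | IndependentModel:
    """Load a model written by :func:`save_model`; energies round-trip exactly."""
    try:
        fh = h5py.File(path, "r")
    except OSError as exc:
        raise ModelFormatError(f"cannot read model file {path}: {exc}") from exc
    with fh:
        symbols = fh.attrs["alphabet"]
        alphabet = Alphabet(str(symbols))
        metadata = json.loads(fh.attrs.get("metadata", "{}"))
        kind = fh.attrs["kind"]
        if kind == "potts":
            return PottsModel(
                h=fh["h"][()],
                J=fh["J"][()],
                alphabet=alphabet,
                gauge=str(fh.attrs["gauge"]),
                metadata=metadata,
            )
        if kind == "independent":
            return IndependentModel(
                f=fh["f"][()],
                alphabet=alphabet,
                pseudocount=float(fh.attrs["pseudocount"]),
                metadata=metadata,
            )
        raise ModelFormatError(f"unknown model kind {kind!r}")
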