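"""Synthetic landscapes and sequence data with known ground truth.

Everything the analysis consumes can be generated here: a planted Potts
landscape (Gaussian fields, Gaussian couplings on a known set of site
pairs), a global homolog sample from it (Gibbs sampling), a local strain
panel of mostly low-frequency variation around a reference (Poisson
mutation supply thinned by purifying acceptance), a series of increasingly
diverged sequences evolved under the same acceptance rule, and a codon
layer for the neutral simulator. All generators are pure functions of
their seed and parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from dcaland.alphabet import DEFAULT_ALPHABET, Alphabet, reduced_alphabet
from dcaland.codons import STANDARD_CODE, CodonReference
from dcaland.models import PottsModel, mutation_score
from dcaland.msa import MSA


@dataclass
class PlantedLandscape:
    """A Potts model with known planted couplings."""

    model: PottsModel
    coupled_pairs: list[tuple[int, int]]  # 0-based, i < j
    coupling_scale: float
    field_scale: float
    seed: int


def make_potts(
    L: int,
    q: int = 21,
    n_pairs: int = 0,
    coupling_scale: float = 1.0,
    field_scale: float = 1.0,
    seed: int = 0,
) -> PlantedLandscape:
    """Plant a random Potts landscape.

    Fields are i.i.d. N(0, field_scale²); the q×q coupling blocks of
    ``n_pairs`` distinct random site pairs are i.i.d. N(0, coupling_scale²);
    J is exactly zero elsewhere (raw gauge).
    """
    max_pairs = L * (L - 1) // 2
    if n_pairs > max_pairs:
        raise ValueError(f"n_pairs={n_pairs} exceeds {max_pairs} available pairs")
    rng = np.random.default_rng(seed)
    alphabet = DEFAULT_ALPHABET if q == 21 else reduced_alphabet(q)
    h = rng.normal(0.0, field_scale, size=(L, q)) if field_scale > 0 else np.zeros((L, q))
    J = np.zeros((L, L, q, q))
    all_pairs = [(i, j) for i in range(L) for j in range(i + 1, L)]
    chosen = rng.choice(len(all_pairs), size=n_pairs, replace=False) if n_pairs else []
    pairs = sorted(all_pairs[k] for k in np.atleast_1d(chosen))
    for i, j in pairs:
        block = rng.normal(0.0, coupling_scale, size=(q, q)) if coupling_scale > 0 else np.zeros((q, q))
        J[i, j] = block
        J[j, i] = block.T
    model = PottsModel(
        h=h,
        J=J,
        alphabet=alphabet,
        gauge="raw",
        metadata={"planted": True, "seed": seed, "n_pairs": n_pairs},
    )
    return PlantedLandscape(
        model=model,
        coupled_pairs=pairs,
        coupling_scale=coupling_scale,
        field_scale=field_scale,
        seed=seed,
    )


def _gibbs_sweep(
    S: np.ndarray, h: np.ndarray, J: np.ndarray, order: np.ndarray, rng: np.random.Generator
) -> None:
    """One in-place Gibbs sweep over all sites for a batch of chains."""
    B, L = S.shape
    q = h.shape[1]
    for i in order:
        logits = np.broadcast_to(h[i], (B, q)).copy()
        for j in range(L):
            if j == i:
                continue
            logits += J[i, j][:, S[:, j]].T
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=1, keepdims=True)
        u = rng.random(B)
        S[:, i] = (p.cumsum(axis=1) < u[:, None]).sum(axis=1)


def sample_msa(
    model: PottsModel,
    M: int,
    n_sweeps: int = 100,
    thin: int = 10,
    seed: int = 0,
    n_chains: int = 64,
    id_prefix: str = "sample",
) -> MSA:
    """Sample M sequences from the Potts distribution by Gibbs sampling.

    Runs ``n_chains`` parallel chains from random starts, each burned in for
    ``n_sweeps`` full sweeps; records are then taken from each chain every
    ``thin`` sweeps until M sequences are collected. For J = 0 each site
    update is an exact draw from softmax(h_i). Site order is a fresh seeded
    permutation every sweep.
    """
    if M <= 0:
        raise ValueError("M must be positive")
    rng = np.random.default_rng(seed)
    L, q = model.L, model.q
    B = min(n_chains, M)
    S = rng.integers(0, q, size=(B, L))
    for _ in range(n_sweeps):
        _gibbs_sweep(S, model.h, model.J, rng.permutation(L), rng)
    records = [S.copy()]
    n_rounds = int(np.ceil(M / B)) - 1
    for _ in range(n_rounds):
        for _ in range(thin):
            _gibbs_sweep(S, model.h, model.J, rng.permutation(L), rng)
        records.append(S.copy())
    matrix = np.concatenate(records, axis=0)[:M].astype(np.int8)
    ids = [f"{id_prefix}_{k}" for k in range(M)]
    return MSA(ids, matrix, model.alphabet)


def _acceptance(delta_e: float, selection_strength: float) -> float:
    """Purifying retention probability exp(−s·max(0, ΔE)): deleterious
    proposals are thinned, neutral or beneficial ones always kept."""
    return float(np.exp(-selection_strength * max(0.0, delta_e)))


def make_strain_panel(
    model: PottsModel,
    reference,
    M_strains: int,
    mu: float = 1.0,
    selection_strength: float = 1.0,
    seed: int = 0,
    id_prefix: str = "strain",
) -> MSA:
    """A local panel of strains around ``reference`` with mostly rare variants.

    Each strain proposes K ~ Poisson(mu) substitutions (site uniform, target
    amino acid uniform over the other residues), applied sequentially and
    each retained with probability exp(−s·max(0, ΔE)) in the strain's
    current background.
    """
    rng = np.random.default_rng(seed)
    alphabet = model.alphabet
    ref = np.asarray(alphabet.encode(reference) if isinstance(reference, str) else reference)
    n_res = alphabet.n_residues
    matrix = np.empty((M_strains, model.L), dtype=np.int8)
    for m in range(M_strains):
        seq = ref.copy()
        for _ in range(rng.poisson(mu)):
            site = int(rng.integers(0, model.L)) + 1
            current = int(seq[site - 1])
            if current >= n_res:
                continue
            target = int(rng.integers(0, n_res - 1))
            if target >= current:
                target += 1
            de = mutation_score(
                model, seq, site, alphabet.symbols[current], alphabet.symbols[target]
            )
            if rng.random() < _acceptance(de, selection_strength):
                seq[site - 1] = target
        matrix[m] = seq
    return MSA([f"{id_prefix}_{m}" for m in range(M_strains)], matrix, alphabet)


def make_divergence_series(
    model: PottsModel,
    reference,
    n_accepted_steps: int,
    selection_strength: float = 1.0,
    seed: int = 0,
    record_every: int = 1,
    allow_back_mutations: bool = False,
    max_proposals: int | None = None,
) -> list[np.ndarray]:
    """Sequences at increasing divergence from ``reference``.

    Substitutions are proposed one at a time and accepted with the same
    purifying rule as :func:`make_strain_panel`; the sequence is recorded
    after every ``record_every`` accepted steps. With back-mutations
    disallowed (default) a site is substituted at most once, so divergence
    is non-decreasing along the series. The reference itself is the first
    entry.
    """
    rng = np.random.default_rng(seed)
    alphabet = model.alphabet
    ref = np.asarray(alphabet.encode(reference) if isinstance(reference, str) else reference)
    n_res = alphabet.n_residues
    seq = ref.copy()
    series = [seq.copy()]
    touched: set[int] = set()
    accepted = 0
    proposals = 0
    budget = max_proposals if max_proposals is not None else max(200 * n_accepted_steps, 1000)
    while accepted < n_accepted_steps and proposals < budget:
        proposals += 1
        site = int(rng.integers(0, model.L)) + 1
        if not allow_back_mutations and (site in touched):
            continue
        current = int(seq[site - 1])
        if current >= n_res:
            continue
        target = int(rng.integers(0, n_res - 1))
        if target >= current:
            target += 1
        de = mutation_score(model, seq, site, alphabet.symbols[current], alphabet.symbols[target])
        if rng.random() < _acceptance(de, selection_strength):
            seq[site - 1] = target
            touched.add(site)
            accepted += 1
            if accepted % record_every == 0:
                series.append(seq.copy())
    if accepted % record_every != 0 or accepted == 0:
        if not np.array_equal(series[-1], seq):
            series.append(seq.copy())
    return series


def assign_codons(protein_seq: str, seed: int = 0) -> CodonReference:
    """A consistent codon layer: per residue, a uniform synonymous codon."""
    rng = np.random.default_rng(seed)
    codons = []
    for aa in protein_seq.upper():
        options = STANDARD_CODE.synonymous_codons(aa)
        if not options:
            raise ValueError(f"{aa!r} is not a codable amino acid")
        codons.append(options[int(rng.integers(0, len(options)))])
    return CodonReference(codons)


def low_energy_reference(
    model: PottsModel, seed: int = 0, n_sweeps: int = 50
) -> np.ndarray:
    """A locally energy-minimal gap-free sequence (greedy quench from a sample).

    Useful as a synthetic "reference strain": each sweep sets every site to
    its conditional-argmax amino acid until a fixed point.
    """
    rng = np.random.default_rng(seed)
    n_res = model.alphabet.n_residues
    seq = rng.integers(0, n_res, size=model.L)
    for _ in range(n_sweeps):
        changed = False
        for i in rng.permutation(model.L):
            logits = model.h[i].copy()
            for j in range(model.L):
                if j != i:
                    logits += model.J[i, j, :, seq[j]]
            best = int(np.argmax(logits[:n_res]))
            if best != seq[i]:
                seq[i] = best
                changed = True
        if not changed:
            break
    return seq
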