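"""Epistatic cost of mutation combinations, divergence analysis, IPR, structure.

Epistasis is the deviation from additivity of mutational effects: for a
mutation set the epistatic cost is ΔΔE = ΔE_total − Σ ΔE_single, where each
single mutation is inserted individually into the same background. For a
pair of substitutions (α_i→β_i, α_j→β_j) this collapses onto the four
coupling entries

    ΔΔE_ij = J_ij(α_i, β_j) + J_ij(β_i, α_j) − J_ij(β_i, β_j) − J_ij(α_i, α_j),

so negative values mean positive epistasis (the mutations are better
together than their summed individual effects). The inverse participation
ratio of a site's squared couplings to the rest of the reference sequence
measures how concentrated its epistatic interactions are; its reciprocal
over L is the effective proportion of coupled residues. IPR is
gauge-dependent and is computed in the zero-sum gauge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dcaland.models import PottsModel, mutation_score, statistical_energy
from dcaland.msa import MSA

DIVERGENCE_BIN_EDGES = [0.0, 0.05, 0.10, 0.15, 0.20, 0.25, 1.0]
DIVERGENCE_BIN_LABELS = ["<5%", "5-10%", "10-15%", "15-20%", "20-25%", ">25%"]


@dataclass
class EpistasisRecord:
    """One mutation set in one background, with its additivity deviation."""

    sites: list[int]  # 1-based
    from_aas: list[str]
    to_aas: list[str]
    delta_e_singles: list[float]
    delta_e_total: float
    delta_delta_e: float
    coupling_terms: dict[str, float] = field(default_factory=dict)
    background_id: str = ""


def _encode(seq, alphabet):
    if isinstance(seq, str):
        return np.asarray(alphabet.encode(seq), dtype=np.int64)
    return np.asarray(seq, dtype=np.int64)


def epistatic_cost_set(
    model: PottsModel, background, mutations: list[tuple[int, str, str]], background_id: str = ""
) -> EpistasisRecord:
    """Epistatic cost of an arbitrary mutation set (1-based sites).

    ``mutations`` are ``(site, from_aa, to_aa)`` at distinct sites; the cost
    is ΔE of all mutations together minus the sum of the individually
    inserted single-mutation ΔEs. A single mutation has cost 0 exactly.
    """
    a = _encode(background, model.alphabet)
    sites = [m[0] for m in mutations]
    if len(set(sites)) != len(sites):
        raise ValueError("mutations must be at distinct sites")
    singles = []
    mutant = a.copy()
    for site, from_aa, to_aa in mutations:
        singles.append(mutation_score(model, a, site, from_aa, to_aa))
        mutant[site - 1] = model.alphabet.index[to_aa]
    total = statistical_energy(model, mutant) - statistical_energy(model, a)
    return EpistasisRecord(
        sites=sites,
        from_aas=[m[1] for m in mutations],
        to_aas=[m[2] for m in mutations],
        delta_e_singles=singles,
        delta_e_total=total,
        delta_delta_e=total - sum(singles),
        background_id=background_id,
    )


def epistatic_cost_pair(
    model: PottsModel,
    background,
    mut_i: tuple[int, str, str],
    mut_j: tuple[int, str, str],
    background_id: str = "",
) -> EpistasisRecord:
    """Epistatic cost of a mutation pair, via the four coupling entries.

    Records both the coupling-formula ΔΔE and the underlying J terms; the
    value is identical (to rounding) to the energy-based set computation.
    """
    (site_i, alpha_i, beta_i) = mut_i
    (site_j, alpha_j, beta_j) = mut_j
    if site_i == site_j:
        raise ValueError("pair mutations must be at distinct sites")
    rec = epistatic_cost_set(model, background, [mut_i, mut_j], background_id)
    ai, bi = model.alphabet.index[alpha_i], model.alphabet.index[beta_i]
    aj, bj = model.alphabet.index[alpha_j], model.alphabet.index[beta_j]
    Jij = model.J[site_i - 1, site_j - 1]
    terms = {
        "J(alpha_i,beta_j)": float(Jij[ai, bj]),
        "J(beta_i,alpha_j)": float(Jij[bi, aj]),
        "J(beta_i,beta_j)": float(Jij[bi, bj]),
        "J(alpha_i,alpha_j)": float(Jij[ai, aj]),
    }
    ddE = (
        terms["J(alpha_i,beta_j)"]
        + terms["J(beta_i,alpha_j)"]
        - terms["J(beta_i,beta_j)"]
        - terms["J(alpha_i,alpha_j)"]
    )
    rec.coupling_terms = terms
    rec.delta_delta_e = ddE
    return rec


def _differences(a: np.ndarray, b: np.ndarray, gap_state: int):
    """Fixed differences (both non-gap, different) and gap-difference count."""
    gap_a = a == gap_state
    gap_b = b == gap_state
    gap_diff = int((gap_a != gap_b).sum())
    both = ~gap_a & ~gap_b
    fixed = np.flatnonzero(both & (a != b))
    return fixed, gap_diff, both


def double_mutant_scan(model: PottsModel, panel: MSA, reference) -> pd.DataFrame:
    """Every panel sequence with exactly two substitutions and no gap
    difference vs the reference: (ΔE_ij, ΔE_i + ΔE_j, ΔΔE)."""
    alphabet = model.alphabet
    ref = _encode(reference, alphabet)
    rows = []
    for m, sid in enumerate(panel.ids):
        seq = panel.matrix[m].astype(np.int64)
        fixed, gap_diff, _ = _differences(ref, seq, alphabet.gap_state)
        if gap_diff != 0 or fixed.size != 2:
            continue
        muts = [
            (int(p) + 1, alphabet.symbols[ref[p]], alphabet.symbols[seq[p]]) for p in fixed
        ]
        rec = epistatic_cost_set(model, ref, muts, background_id=sid)
        rows.append(
            {
                "sequence_id": sid,
                "site_i": muts[0][0],
                "site_j": muts[1][0],
                "delta_e_total": rec.delta_e_total,
                "delta_e_sum": sum(rec.delta_e_singles),
                "delta_delta_e": rec.delta_delta_e,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["sequence_id", "site_i", "site_j", "delta_e_total", "delta_e_sum", "delta_delta_e"],
    )


def divergence_bin(fraction: float) -> str:
    for hi, label in zip(DIVERGENCE_BIN_EDGES[1:], DIVERGENCE_BIN_LABELS):
        if fraction < hi or label == DIVERGENCE_BIN_LABELS[-1]:
            return label
    return DIVERGENCE_BIN_LABELS[-1]


def divergence_epistasis(
    model: PottsModel,
    pairs: list[tuple],
    background_choice: str = "first",
    max_gap_difference: int = 1,
) -> pd.DataFrame:
    """Epistatic cost between homologous sequence pairs, binned by divergence.

    Each pair is (id_a, seq_a, id_b, seq_b) or (seq_a, seq_b), aligned in
    model coordinates. Pairs with more than ``max_gap_difference`` gap
    differences are dropped. The divergence fraction counts differing
    positions among those non-gap in both; the cost inserts all fixed
    differences into the designated background (default: first sequence).
    """
    if background_choice not in ("first", "second"):
        raise ValueError("background_choice must be 'first' or 'second'")
    alphabet = model.alphabet
    rows = []
    for pair in pairs:
        if len(pair) == 4:
            id_a, seq_a, id_b, seq_b = pair
        else:
            seq_a, seq_b = pair
            id_a, id_b = "a", "b"
        a = _encode(seq_a, alphabet)
        b = _encode(seq_b, alphabet)
        if background_choice == "second":
            a, b = b, a
            id_a, id_b = id_b, id_a
        fixed, gap_diff, both = _differences(a, b, alphabet.gap_state)
        if gap_diff > max_gap_difference:
            continue
        n_compared = int(both.sum())
        frac = fixed.size / n_compared if n_compared else 0.0
        muts = [(int(p) + 1, alphabet.symbols[a[p]], alphabet.symbols[b[p]]) for p in fixed]
        if muts:
            rec = epistatic_cost_set(model, a, muts, background_id=id_a)
            ddE = rec.delta_delta_e
        else:
            ddE = 0.0
        rows.append(
            {
                "id_a": id_a,
                "id_b": id_b,
                "n_fixed_differences": int(fixed.size),
                "gap_differences": gap_diff,
                "divergence": frac,
                "bin": divergence_bin(frac),
                "delta_delta_e": ddE,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "id_a", "id_b", "n_fixed_differences", "gap_differences",
            "divergence", "bin", "delta_delta_e",
        ],
    )


def fixed_difference_couplings(
    model: PottsModel, seq_a, seq_b, background: str = "first", max_gap_difference: int = 1
) -> pd.DataFrame:
    """Pairwise epistatic cost for every unordered pair of fixed differences.

    With k fixed differences this yields k(k−1)/2 coupling values, evaluated
    in the designated background sequence.
    """
    alphabet = model.alphabet
    a = _encode(seq_a, alphabet)
    b = _encode(seq_b, alphabet)
    if background == "second":
        a, b = b, a
    elif background != "first":
        raise ValueError("background must be 'first' or 'second'")
    fixed, gap_diff, _ = _differences(a, b, alphabet.gap_state)
    if gap_diff > max_gap_difference:
        raise ValueError(
            f"pair has {gap_diff} gap differences (> {max_gap_difference}); excluded by the gap filter"
        )
    rows = []
    for x in range(fixed.size):
        for y in range(x + 1, fixed.size):
            pi, pj = int(fixed[x]), int(fixed[y])
            rec = epistatic_cost_pair(
                model,
                a,
                (pi + 1, alphabet.symbols[a[pi]], alphabet.symbols[b[pi]]),
                (pj + 1, alphabet.symbols[a[pj]], alphabet.symbols[b[pj]]),
            )
            rows.append(
                {"site_i": pi + 1, "site_j": pj + 1, "delta_delta_e": rec.delta_delta_e}
            )
    return pd.DataFrame(rows, columns=["site_i", "site_j", "delta_delta_e"])


def ipr(model: PottsModel, reference, site: int) -> tuple[float, float]:
    """Inverse participation ratio of site couplings, and the effective
    proportion of coupled residues.

    IPR_i = Σ_{j≠i} (J_ij(a_i, a_j)² / Σ_k J_ik(a_i, a_k)²)² on the reference
    sequence; the effective proportion is 1 / (IPR_i · L). Requires the
    zero-sum gauge (the quantity is gauge-dependent). Returns (nan, nan)
    when all couplings at the site vanish.
    """
    if model.gauge != "zero-sum":
        raise ValueError("ipr requires a zero-sum gauge model")
    a = _encode(reference, model.alphabet)
    i = site - 1
    j_idx = np.array([j for j in range(model.L) if j != i])
    Jsq = model.J[i, j_idx, a[i], a[j_idx]] ** 2
    total = Jsq.sum()
    if total <= 0.0:
        return float("nan"), float("nan")
    shares = Jsq / total
    ipr_val = float((shares**2).sum())
    return ipr_val, 1.0 / (ipr_val * model.L)


def ipr_profile(model: PottsModel, reference) -> pd.DataFrame:
    rows = []
    for site in range(1, model.L + 1):
        v, prop = ipr(model, reference, site)
        rows.append({"ref_pos": site, "ipr": v, "effective_proportion": prop})
    return pd.DataFrame(rows)


def residue_pair_distances(
    coords: dict[int, np.ndarray], pairs: list[tuple[int, int]], contact_cutoff: float = 10.0
) -> pd.DataFrame:
    """Minimum heavy-atom distance (Å) per residue pair, with contact flags.

    ``coords`` maps reference positions to (n_atoms, 3) coordinate arrays.
    Pairs with an unmapped residue are reported with NaN distance rather
    than silently dropped; contacts are strict ``< contact_cutoff``.
    """
    rows = []
    for i, j in pairs:
        ci, cj = coords.get(i), coords.get(j)
        if ci is None or cj is None or len(ci) == 0 or len(cj) == 0:
            rows.append({"site_i": i, "site_j": j, "distance": np.nan, "contact": pd.NA})
            continue
        ci = np.atleast_2d(np.asarray(ci, dtype=float))
        cj = np.atleast_2d(np.asarray(cj, dtype=float))
        d = np.sqrt(((ci[:, None, :] - cj[None, :, :]) ** 2).sum(axis=2)).min()
        rows.append(
            {"site_i": i, "site_j": j, "distance": float(d), "contact": bool(d < contact_cutoff)}
        )
    return pd.DataFrame(rows, columns=["site_i", "site_j", "distance", "contact"])


def load_residue_coordinates(pdb_path, chain: str | None = None) -> dict[int, np.ndarray]:
    """Heavy-atom coordinates per residue number from a PDB file (via biotite)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    structure = pdb.PDBFile.read(str(pdb_path)).get_structure(model=1)
    mask = structure.element != "H"
    if chain is not None:
        mask &= structure.chain_id == chain
    atoms = structure[mask]
    coords: dict[int, np.ndarray] = {}
    for res_id in np.unique(atoms.res_id):
        coords[int(res_id)] = atoms.coord[atoms.res_id == res_id]
    return coords
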