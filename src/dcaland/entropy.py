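"""Site-entropy profiles: context-independent vs context-dependent variability.

The context-independent entropy (CIE) of a site is the Shannon entropy (in
bits) of its amino-acid frequencies across distant homologs; the
context-dependent entropy (CDE) is the entropy of the Potts conditional
distribution at that site given the full reference-sequence background. The
information gain IG = CIE − CDE measures how many bits of site variability
the genetic context removes: 1 bit halves the effective number of
admissible amino acids. Both entropies run over the 20 amino acids only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from dcaland.models import (
    ConditionalDistribution,
    IndependentModel,
    PottsModel,
    conditional_probabilities,
)

CATEGORY_CONSERVED = "conserved-everywhere"
CATEGORY_VARIABLE = "variable-both"
CATEGORY_CONTEXT = "context-conserved"


@dataclass
class SiteProfile:
    """Entropy summary of one reference position (1-based)."""

    ref_pos: int
    cie: float
    cde: float
    ig: float
    cie_1snp: float | None = None
    cde_1snp: float | None = None
    category: str | None = None


def _entropy_bits(p: np.ndarray) -> float:
    p = np.asarray(p, dtype=float)
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def cie(ind: IndependentModel, site: int) -> float:
    """Column entropy (bits) of gap-excluded, renormalized frequencies at ``site`` (1-based)."""
    return _entropy_bits(ind.residue_frequencies(site - 1))


def cde(model: PottsModel, reference, site: int) -> float:
    """Entropy (bits) of the conditional distribution at ``site`` in the reference context."""
    return conditional_probabilities(model, reference, site).entropy_bits()


def information_gain(cie_bits: float, cde_bits: float) -> float:
    """IG = CIE − CDE (bits); 1 bit ⇔ halving of the effective amino-acid repertoire."""
    return cie_bits - cde_bits


def restrict_to_1snp(
    dist: ConditionalDistribution, allowed: set[str]
) -> ConditionalDistribution:
    """Zero out amino acids outside ``allowed`` and renormalize.

    ``allowed`` is typically the 1-SNP-reachable set of the underlying codon
    and must include the native amino acid (reachable with zero SNPs).
    """
    if not allowed:
        raise ValueError("allowed amino-acid set is empty")
    mask = np.zeros_like(dist.probs)
    for aa in allowed:
        idx = dist.alphabet.index[aa]
        if idx >= dist.alphabet.n_residues:
            raise ValueError(f"{aa!r} is not an amino acid")
        mask[idx] = 1.0
    restricted = dist.probs * mask
    total = restricted.sum()
    if total <= 0.0:
        raise ValueError("allowed set has zero probability mass in the distribution")
    return ConditionalDistribution(
        site=dist.site,
        probs=restricted / total,
        context_id=dist.context_id,
        alphabet=dist.alphabet,
    )


def classify_site(cie_bits: float, cde_bits: float, entropy_threshold: float = 1.0) -> str:
    if cie_bits < entropy_threshold:
        return CATEGORY_CONSERVED
    if cde_bits < entropy_threshold:
        return CATEGORY_CONTEXT
    return CATEGORY_VARIABLE


def classify_sites(
    profile: pd.DataFrame, entropy_threshold: float = 1.0
) -> tuple[pd.Series, dict[str, float]]:
    """Per-site category labels and the three category fractions.

    A site with CIE below the threshold is conserved everywhere regardless
    of context; otherwise the CDE decides whether the context conserves it.
    The 1-bit default corresponds to fewer than two effective amino acids.
    """
    labels = profile.apply(
        lambda r: classify_site(r["cie"], r["cde"], entropy_threshold), axis=1
    )
    n = len(labels)
    fractions = {
        cat: float((labels == cat).sum()) / n if n else float("nan")
        for cat in (CATEGORY_CONSERVED, CATEGORY_VARIABLE, CATEGORY_CONTEXT)
    }
    return labels, fractions


def site_profiles(
    model: PottsModel,
    ind: IndependentModel,
    reference,
    sites: list[int] | None = None,
    one_snp_allowed: dict[int, set[str]] | None = None,
    entropy_threshold: float = 1.0,
) -> pd.DataFrame:
    """Per-site CIE/CDE/IG table (1-based ``ref_pos``), with optional
    1-SNP-restricted entropies where an allowed set is supplied."""
    if sites is None:
        sites = list(range(1, model.L + 1))
    rows = []
    for site in sites:
        cie_b = cie(ind, site)
        cond = conditional_probabilities(model, reference, site)
        cde_b = cond.entropy_bits()
        row = {
            "ref_pos": site,
            "cie": cie_b,
            "cde": cde_b,
            "ig": information_gain(cie_b, cde_b),
            "cie_1snp": np.nan,
            "cde_1snp": np.nan,
        }
        if one_snp_allowed and site in one_snp_allowed:
            allowed = one_snp_allowed[site]
            raw = ConditionalDistribution(
                site=site,
                probs=ind.residue_frequencies(site - 1),
                context_id="IND-raw",
                alphabet=ind.alphabet,
            )
            row["cie_1snp"] = restrict_to_1snp(raw, allowed).entropy_bits()
            row["cde_1snp"] = restrict_to_1snp(cond, allowed).entropy_bits()
        rows.append(row)
    df = pd.DataFrame(rows)
    labels, _ = classify_sites(df, entropy_threshold)
    df["category"] = labels
    return df
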