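"""Within-species panels: allele frequencies, conservation calls, model confrontation.

A strain panel is an alignment of close orthologs of the reference. Per site
we count amino-acid alleles (gaps are missing data), call the consensus and
major (>50%) allele, and classify the site as conserved (no non-consensus
residue at all), polymorphic (non-consensus frequency ≥ 5% by default) or
low-polymorphic-excluded in between. Model confrontation then asks how the
landscape ranks native amino acids and observed alleles, and how the scores
of observed polymorphisms compare to null mutations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from dcaland.models import (
    IndependentModel,
    PottsModel,
    conditional_probabilities,
    ind_probabilities,
    mutation_score,
    rank_amino_acid,
)
from dcaland.msa import MSA

STATUS_CONSERVED = "conserved"
STATUS_LOW = "low-polymorphic-excluded"
STATUS_POLYMORPHIC = "polymorphic"


@dataclass
class SiteAlleleTable:
    """Per-site amino-acid counts across a strain panel.

    ``counts`` has shape (L, n_residues); gaps and unknowns are counted in
    ``missing`` and excluded from frequency denominators. Sites where fewer
    than half the strains are non-missing are flagged unusable.
    """

    counts: np.ndarray
    missing: np.ndarray
    consensus: np.ndarray  # residue state per site (argmax of counts)
    usable: np.ndarray  # bool per site
    alphabet: object
    n_strains: int

    @property
    def L(self) -> int:
        return self.counts.shape[0]

    def n_effective(self, site: int) -> int:
        return int(self.counts[site - 1].sum())

    def frequencies(self, site: int) -> np.ndarray:
        c = self.counts[site - 1].astype(float)
        total = c.sum()
        return c / total if total > 0 else c

    def consensus_aa(self, site: int) -> str:
        return self.alphabet.symbols[int(self.consensus[site - 1])]

    def major_allele(self, site: int) -> str | None:
        """Amino acid with frequency > 0.5 at the site, if any."""
        f = self.frequencies(site)
        best = int(np.argmax(f))
        return self.alphabet.symbols[best] if f[best] > 0.5 else None

    def minor_alleles(self, site: int, threshold: float = 0.05) -> list[tuple[str, float]]:
        """Alleles with frequency in [threshold, 0.5], sorted by descending frequency."""
        f = self.frequencies(site)
        out = [
            (self.alphabet.symbols[s], float(f[s]))
            for s in range(len(f))
            if threshold <= f[s] <= 0.5
        ]
        return sorted(out, key=lambda t: (-t[1], t[0]))


def allele_frequencies(panel: MSA, reference_id: str | None = None) -> SiteAlleleTable:
    """Count amino-acid alleles per site; gaps are missing data."""
    if panel.M == 0:
        raise ValueError("empty strain panel")
    n = panel.alphabet.n_residues
    counts = np.zeros((panel.L, n), dtype=np.int64)
    for s in range(n):
        counts[:, s] = (panel.matrix == s).sum(axis=0)
    missing = panel.M - counts.sum(axis=1)
    consensus = counts.argmax(axis=1)
    usable = counts.sum(axis=1) >= 0.5 * panel.M
    return SiteAlleleTable(
        counts=counts,
        missing=missing,
        consensus=consensus,
        usable=usable,
        alphabet=panel.alphabet,
        n_strains=panel.M,
    )


def classify_site_status(
    table: SiteAlleleTable, threshold: float = 0.05, inclusive: bool = True
) -> pd.DataFrame:
    """Per-site status: conserved / polymorphic / low-polymorphic-excluded.

    Conserved means zero non-consensus residues observed. Polymorphic means
    the total non-consensus frequency reaches ``threshold`` (inclusive by
    default, matching the "at least 5%" rule). Unusable sites (mostly
    missing) get status NaN.
    """
    rows = []
    for site in range(1, table.L + 1):
        if not table.usable[site - 1]:
            rows.append({"ref_pos": site, "status": np.nan, "nonconsensus_freq": np.nan})
            continue
        c = table.counts[site - 1]
        total = c.sum()
        noncons = total - c[table.consensus[site - 1]]
        freq = noncons / total if total else 0.0
        if noncons == 0:
            status = STATUS_CONSERVED
        elif (freq >= threshold) if inclusive else (freq > threshold):
            status = STATUS_POLYMORPHIC
        else:
            status = STATUS_LOW
        rows.append({"ref_pos": site, "status": status, "nonconsensus_freq": freq})
    return pd.DataFrame(rows)


def _distribution(model, reference, site: int):
    if isinstance(model, PottsModel):
        return conditional_probabilities(model, reference, site)
    if isinstance(model, IndependentModel):
        return ind_probabilities(model, site)
    raise TypeError(f"unsupported model type {type(model)!r}")


def native_rank_profile(model, reference, sites: list[int] | None = None) -> pd.DataFrame:
    """Rank of the reference amino acid at each site, plus the rank-1 fraction.

    Gapped reference positions are skipped. Returns a frame with columns
    ``ref_pos`` and ``rank``; the rank-1 fraction is in ``frame.attrs``.
    """
    alphabet = model.alphabet
    ref = np.asarray(alphabet.encode(reference) if isinstance(reference, str) else reference)
    if sites is None:
        sites = [s + 1 for s in range(len(ref))]
    rows = []
    for site in sites:
        state = int(ref[site - 1])
        if state >= alphabet.n_residues:
            continue
        dist = _distribution(model, ref, site)
        rows.append({"ref_pos": site, "rank": rank_amino_acid(dist, alphabet.symbols[state])})
    df = pd.DataFrame(rows, columns=["ref_pos", "rank"])
    df.attrs["rank1_fraction"] = float((df["rank"] == 1).mean()) if len(df) else float("nan")
    return df


def allele_rank_profile(
    model,
    reference,
    table: SiteAlleleTable,
    threshold: float = 0.05,
    sites: list[int] | None = None,
) -> pd.DataFrame:
    """Ranks of major (>50%) and minor (5–50%) alleles at polymorphic sites,
    evaluated in the reference-strain context."""
    status = classify_site_status(table, threshold)
    poly = status[status["status"] == STATUS_POLYMORPHIC]["ref_pos"].tolist()
    if sites is not None:
        poly = [s for s in poly if s in set(sites)]
    alphabet = model.alphabet
    ref = np.asarray(alphabet.encode(reference) if isinstance(reference, str) else reference)
    rows = []
    for site in poly:
        dist = _distribution(model, ref, site)
        major = table.major_allele(site)
        if major is not None:
            rows.append(
                {"ref_pos": site, "allele": major, "kind": "major",
                 "frequency": float(table.frequencies(site)[alphabet.index[major]]),
                 "rank": rank_amino_acid(dist, major)}
            )
        for aa, freq in table.minor_alleles(site, threshold):
            rows.append(
                {"ref_pos": site, "allele": aa, "kind": "minor",
                 "frequency": freq, "rank": rank_amino_acid(dist, aa)}
            )
    return pd.DataFrame(rows, columns=["ref_pos", "allele", "kind", "frequency", "rank"])


def score_observed_polymorphisms(
    model: PottsModel,
    reference,
    table: SiteAlleleTable,
    threshold: float = 0.05,
    sites: list[int] | None = None,
) -> pd.DataFrame:
    """ΔE of every non-reference allele at frequency ≥ threshold, in the
    reference context. Alleles equal to the reference amino acid are not
    mutations and are excluded."""
    alphabet = model.alphabet
    ref = np.asarray(alphabet.encode(reference) if isinstance(reference, str) else reference)
    site_set = None if sites is None else set(sites)
    rows = []
    for site in range(1, table.L + 1):
        if not table.usable[site - 1] or (site_set is not None and site not in site_set):
            continue
        ref_state = int(ref[site - 1])
        if ref_state >= alphabet.n_residues:
            continue
        freqs = table.frequencies(site)
        native = alphabet.symbols[ref_state]
        for s in range(alphabet.n_residues):
            if s == ref_state or freqs[s] < threshold:
                continue
            aa = alphabet.symbols[s]
            rows.append(
                {"ref_pos": site, "allele": aa, "frequency": float(freqs[s]),
                 "delta_e": mutation_score(model, ref, site, native, aa)}
            )
    return pd.DataFrame(rows, columns=["ref_pos", "allele", "frequency", "delta_e"])


def sample_null_mutations(
    model: PottsModel,
    ind: IndependentModel | None,
    reference,
    mode: str = "random",
    n: int = 1000,
    seed: int = 0,
    sites: list[int] | None = None,
) -> np.ndarray:
    """ΔE scores of null mutations in the reference context.

    ``mode="random"``: site uniform over analyzable sites, target amino acid
    uniform over the 19 non-native. ``mode="ind"``: site uniform, target
    drawn from the independent model's probabilities excluding the native.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    alphabet = model.alphabet
    ref = np.asarray(alphabet.encode(reference) if isinstance(reference, str) else reference)
    if sites is None:
        sites = [s + 1 for s in range(model.L) if ref[s] < alphabet.n_residues]
    rng = np.random.default_rng(seed)
    scores = np.empty(n)
    for k in range(n):
        site = int(rng.choice(sites))
        native_state = int(ref[site - 1])
        if mode == "random":
            choices = [s for s in range(alphabet.n_residues) if s != native_state]
            target = int(rng.choice(choices))
        elif mode == "ind":
            if ind is None:
                raise ValueError("mode='ind' requires an independent model")
            p = ind_probabilities(ind, site).probs.copy()
            p[native_state] = 0.0
            p /= p.sum()
            target = int(rng.choice(alphabet.n_residues, p=p))
        else:
            raise ValueError(f"unknown null mode {mode!r}")
        scores[k] = mutation_score(
            model, ref, site, alphabet.symbols[native_state], alphabet.symbols[target]
        )
    return scores
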