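# Methods

## The model

`dcaland` works with two statistical landscapes inferred from alignments of
distantly related protein homologs.

The **Potts (epistatic) model** assigns each aligned sequence
(a₁, …, a_L) over the 21-state alphabet (20 amino acids + gap) a
statistical energy

    E(a) = − Σ_{i<j} J_ij(a_i, a_j) − Σ_i h_i(a_i)

where the fields h_i capture single-site conservation and the couplings
J_ij capture pairwise epistatic constraints. Lower energy means more
compatible with the family. The **independent (IND) model** keeps only
per-column amino-acid frequencies f_i(β), computed after the same sequence
reweighting as the Potts fit; it is the non-epistatic baseline every
context-dependent quantity is compared against.

Derived quantities:

- **Mutation score** ΔE_i = h_i(α) − h_i(β) + Σ_{j≠i}[J_ij(α, a_j) −
  J_ij(β, a_j)]: the energy cost of substituting α→β at site i in a fixed
  background; positive = predicted deleterious. It is algebraically equal
  to the full energy difference between mutant and background, which the
  tests verify to 1e-10 on thousands of random instances.
- **Conditional distribution** P_i(β | a_\i) ∝ exp{h_i(β) + Σ_{j≠i}
  J_ij(β, a_j)}, normalized over the 20 amino acids. Gaps are excluded
  from the support: the models are about substitutions, not indels. The
  softmax is max-shifted for numerical stability.
- **CIE / CDE / IG.** The context-independent entropy of a site is the
  Shannon entropy (bits) of its gap-excluded, renormalized column
  frequencies; the context-dependent entropy is the entropy of the
  conditional distribution in the reference background; the information
  gain IG = CIE − CDE measures how many bits of variability the context
  removes (1 bit halves the effective amino-acid repertoire). Both
  entropies live in [0, log₂20 ≈ 4.32].
- **Epistatic cost** ΔΔE = ΔE_total − Σ ΔE_single for a mutation set; for
  a pair it reduces to the four coupling entries J_ij(α_i,β_j) +
  J_ij(β_i,α_j) − J_ij(β_i,β_j) − J_ij(α_i,α_j). Negative = positive
  epistasis (the mutations are better together).
- **IPR.** The inverse participation ratio of a site's normalized squared
  couplings J_ij(a_i, a_j)² along the reference sequence; 1/(IPR·L) is the
  effective proportion of residues coupled to the site. The quantity is
  gauge-dependent; it is always computed in the zero-sum gauge, where it is
  well defined and comparable across sites (the library refuses to compute
  it in any other gauge).

## Inference

The Potts model is fitted by **asymmetric pseudolikelihood maximization**:
for each site i the weighted conditional likelihood of column i given the
rest is maximized over (h_i, {J_ij}) with an L2 penalty, each site's
problem being smooth and convex; L-BFGS-B solves it to a projected-gradient
tolerance of 1e-5 (500 iterations maximum; non-converged sites are logged
and flagged in metadata). The two directed estimates of each coupling
block are averaged, J_ij ← (J_ij^(i) + (J_ji^(j))ᵀ)/2, and the result is
shifted to the zero-sum gauge.

Conventions that matter for reproducing numbers:

- **Reweighting**: w_m = 1/#{m′ : identity(m, m′) ≥ 0.8} (θ = 0.2), with
  the sequence itself included; m_eff = Σ w. Identity excludes positions
  gapped in both sequences from the denominator and counts a gap aligned
  to a residue as a mismatch, so identity(x, x) = 1.
- **Regularization**: λ_h = λ_J = 0.01 by default. The conditional
  negative log-likelihood is normalized by m_eff and the penalty
  λ_h‖h_i‖² + λ_J Σ_j ‖J_ij‖² is added once per directed block
  (`reg_scale="per_meff"`); the unnormalized variant is available as
  `reg_scale="per_sum"`. Gradients are analytic and validated against
  central finite differences to 1e-5 relative error.
- **Gap treatment**: the gap is a full 21st state during training and
  energy evaluation (contexts may be gapped), but is dropped from the
  support of conditional distributions and from all entropies.
- **Training filters**: sequences with more than 10% gaps or more than 90%
  identity to the reference are removed; columns gapped in more than 20%
  of sequences are excluded from all entropy/score analyses; a family with
  200 or fewer surviving sequences is refused (equality passes every
  filter — the thresholds are strict "more than" rules).
- **Coupling scores**: per-pair Frobenius norms of the amino-acid (gap
  excluded) sub-blocks of zero-sum J, with the average-product correction
  S_ij − S̄_i S̄_j / S̄ using full-matrix means, which annihilates rank-one
  score matrices exactly.
- **Ranks**: the rank of an amino acid in a distribution counts strictly
  greater probabilities, with exact ties broken alphabetically so ranks
  are a deterministic permutation of 1–20.
- **IND smoothing**: a pseudocount α = 0.01 mixes the renormalized
  frequencies with the uniform distribution, p = (1−α)f̃ + α/20; without
  it unseen amino acids would carry zero probability and infinite
  surprise. Raw frequencies remain available (the 1-SNP-restricted CIE
  uses them, matching the frequency-vector restriction it is defined by).

## Codon layer and the neutral simulator

The 1-SNP neighborhood of a codon is its nine single-nucleotide neighbors
(standard genetic code only), classified as synonymous, non-synonymous, or
stop. The amino acids reachable by one SNP (stops excluded, native
included) bound the short-term repertoire of a site; restricted CIE/CDE
variants renormalize the distributions over this set.

The neutral simulator asks how much amino-acid polymorphism would be
expected at each site if evolution were neutral apart from the landscape:

1. **Calibration.** At codons with exactly three synonymous 1-SNP
   neighbors, N ~ Poisson(λ) mutations are drawn uniformly over those
   three and each is kept with probability 1/2; the distinct-codon count
   (1–4) is recorded. λ runs over a grid (2–5, step 0.1; 20 replicates
   per value; ties toward smaller λ) and the value whose mean matches the
   observed synonymous diversity is selected. A useful closed form checks
   the machinery: each neighbor survives with probability 1 − e^{−λ/6},
   so the expected count is 1 + 3(1 − e^{−λ/6}).
2. **Evolution.** Every site draws N ~ Poisson(λ) of its nine neighbor
   codons with equal probability (a Jukes–Cantor-style mutation process).
   Stop codons are rejected outright — the conditional distributions have
   no stop state, so no acceptance probability is defined for them. A
   sense draw encoding β is accepted with probability
   P(β)/(P(β) + P(ref)), with P the Potts conditionals in the reference
   context; this is invariant to any common rescaling of the two
   conditionals. A site is polymorphic when ≥2 amino acids survive.

## Synthetic data: what it emulates and what it does not

The generators produce every input the analysis needs, with known ground
truth:

- `make_potts` plants Gaussian fields (scale 1.0) and Gaussian coupling
  blocks (scale 1.0) on a known set of site pairs; J is exactly zero
  elsewhere.
- `sample_msa` draws a "global homolog sample" by Gibbs sampling. It runs
  up to 64 parallel chains (vectorized site updates across chains), each
  burned in for `n_sweeps` full sweeps with records taken every `thin`
  sweeps thereafter; for J = 0 every site update is an exact draw, which
  the marginal-frequency tests exploit.
- `make_strain_panel` emulates a within-species panel: each strain applies
  K ~ Poisson(μ) random substitutions to the reference, each retained with
  probability exp(−s·max(0, ΔE)). This retention rule is a deliberately
  simple stand-in for purifying selection: neutral and beneficial
  proposals always survive, deleterious ones are exponentially thinned.
- `make_divergence_series` evolves the reference by the same acceptance
  rule one substitution at a time, recording intermediates; by default a
  site is substituted at most once, so divergence grows monotonically.
- `assign_codons` draws a uniform synonymous codon per residue, giving a
  consistent nucleotide layer for the neutral simulator.
- The synthetic "reference strain" is a greedy energy quench
  (`low_energy_reference`), i.e., a local minimum of the landscape — the
  analogue of a wild-type sequence well adapted to its constraints.

What the fixtures do **not** emulate: phylogenetic correlation among the
training sequences (each Gibbs sample is essentially independent), shared
ancestry within the strain panel (every strain mutates independently from
the reference, so reaching a 5% allele frequency requires recurrent
mutation), indels, and codon-usage or transition/transversion bias.
Passing tests therefore demonstrate that the estimators and simulators
are correct under the model's own assumptions, not that the biological
conclusions transfer to any real alignment.

## Study conditions

The desk-scale planted study used by the test suite and the acceptance
script: L = 30 sites, q = 8 states, 20 planted coupled pairs
(coupling and field scales 1.0), M = 2,000 Gibbs samples, θ = 0.2
reweighting, λ = 0.01 regularization. The strain panel holds 1,000 strains
at μ = 15 proposed substitutions per strain and selection strength s = 2;
this mutation supply is deliberately high because independent strains
must rediscover an allele recurrently for it to reach the 5% frequency
threshold at L = 30 (real panels reach such frequencies through shared
descent instead). Divergence series run 20 replicates of 12 accepted
substitutions each, recorded after every step. The neutral-simulation
recovery study uses a 400-residue random protein (~115 calibration sites),
generating the observed synonymous statistic at λ* = 3.0 with 20
replicates and calibrating with an independent seed.

## Numerical choices and degenerate inputs

0·log 0 ≡ 0 throughout by continuity. All-gap columns are fatal in
probability queries and must be masked upstream (`mask_gappy_columns`).
Sites whose couplings to the reference are all zero report IPR as missing
rather than dividing by zero. Sequences with more than one gap difference
are excluded from pairwise epistasis, and panel sites with under 50%
non-missing strains are dropped from status calls. Model serialization is
a single HDF5 container (alphabet, gauge, h, J, metadata); a round trip
reproduces energies to 1e-12, and alphabet or format mismatches fail
loudly instead of silently reordering states.

One global seed fans out to per-stage seeds as the first four bytes of
SHA-256("<seed>:<stage>") mod 2³¹, so pipeline stages are independently
reproducible.

## Known limitations

Pseudolikelihood couplings carry a finite-sampling noise floor of order
1/√m_eff per entry; at desk scale, coupling norms from truly independent
data are small relative to planted couplings but not near-zero, and the
suite tests exactly that contrast (shrinkage with depth, separation from
planted pairs). The IPR depends on the chosen gauge; values from other
conventions are not comparable. `fit_plm` holds the full (L, L, q, q)
coupling tensor in memory, which is comfortable for single domains but
not for genome-scale concatenations. The CLI covers single-protein
analyses; joint multi-protein landscapes are out of scope.
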