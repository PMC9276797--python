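"""Epistatic costs, divergence binning, IPR, residue distances."""

import numpy as np
import pytest

import dcaland as d
from dcaland.alphabet import DEFAULT_ALPHABET, reduced_alphabet
from dcaland.epistasis import divergence_bin, ipr_profile
from conftest import random_model, random_residue_sequence


def toy_coupled_model(L=2, q=21):
    """J_12(A, A) = 0.5 only; zero fields."""
    alphabet = DEFAULT_ALPHABET if q == 21 else reduced_alphabet(q)
    J = np.zeros((L, L, q, q))
    J[0, 1, 0, 0] = 0.5
    J[1, 0, 0, 0] = 0.5
    return d.PottsModel(h=np.zeros((L, q)), J=J, alphabet=alphabet)


class TestEpistaticCostPair:
    def test_zero_couplings_have_zero_cost(self):
        model = d.PottsModel(h=np.ones((3, 21)), J=np.zeros((3, 3, 21, 21)))
        rec = d.epistatic_cost_pair(model, "AAA", (1, "A", "C"), (3, "A", "D"))
        assert rec.delta_delta_e == 0.0

    def test_toy_double_mutant_hand_value(self):
        rec = d.epistatic_cost_pair(toy_coupled_model(), "AA", (1, "A", "C"), (2, "A", "C"))
        assert rec.delta_delta_e == pytest.approx(-0.5)

    def test_coupling_formula_matches_energy_oracle(self, rng):
        for k in range(50):
            model = random_model(seed=100 + k).model
            seq = random_residue_sequence(model, rng)
            i, j = rng.choice(model.L, size=2, replace=False) + 1
            bi = int(rng.integers(0, model.alphabet.n_residues))
            bj = int(rng.integers(0, model.alphabet.n_residues))
            mut_i = (int(i), model.alphabet.symbols[seq[i - 1]], model.alphabet.symbols[bi])
            mut_j = (int(j), model.alphabet.symbols[seq[j - 1]], model.alphabet.symbols[bj])
            rec = d.epistatic_cost_pair(model, seq, mut_i, mut_j)
            oracle = rec.delta_e_total - sum(rec.delta_e_singles)
            assert rec.delta_delta_e == pytest.approx(oracle, abs=1e-10)

    def test_symmetric_in_the_two_mutations(self, rng):
        model = random_model(seed=42).model
        seq = random_residue_sequence(model, rng)
        mut_i = (1, model.alphabet.symbols[seq[0]], "C")
        mut_j = (4, model.alphabet.symbols[seq[3]], "D")
        a = d.epistatic_cost_pair(model, seq, mut_i, mut_j).delta_delta_e
        b = d.epistatic_cost_pair(model, seq, mut_j, mut_i).delta_delta_e
        assert a == pytest.approx(b, abs=1e-12)

    def test_same_site_is_fatal(self):
        model = toy_coupled_model()
        with pytest.raises(ValueError):
            d.epistatic_cost_pair(model, "AA", (1, "A", "C"), (1, "A", "D"))


class TestEpistaticCostSet:
    def test_single_mutation_is_exactly_additive(self):
        model = random_model(seed=8).model
        seq = np.zeros(model.L, dtype=int)
        rec = d.epistatic_cost_set(model, seq, [(2, "A", "C")])
        assert rec.delta_delta_e == pytest.approx(0.0, abs=1e-12)

    def test_two_mutations_match_pair_computation(self, rng):
        model = random_model(seed=9).model
        seq = random_residue_sequence(model, rng)
        muts = [(1, model.alphabet.symbols[seq[0]], "C"),
                (3, model.alphabet.symbols[seq[2]], "E")]
        set_rec = d.epistatic_cost_set(model, seq, muts)
        pair_rec = d.epistatic_cost_pair(model, seq, muts[0], muts[1])
        assert set_rec.delta_delta_e == pytest.approx(pair_rec.delta_delta_e, abs=1e-12)

    def test_any_set_on_zero_couplings_is_additive(self):
        model = d.PottsModel(h=np.ones((5, 21)), J=np.zeros((5, 5, 21, 21)))
        muts = [(1, "A", "C"), (2, "A", "D"), (4, "A", "W")]
        rec = d.epistatic_cost_set(model, "AAAAA", muts)
        assert rec.delta_delta_e == pytest.approx(0.0, abs=1e-12)

    def test_duplicate_sites_are_fatal(self):
        model = toy_coupled_model()
        with pytest.raises(ValueError):
            d.epistatic_cost_set(model, "AA", [(1, "A", "C"), (1, "A", "D")])


class TestDoubleMutantScan:
    def _panel(self, rows):
        return d.MSA([f"s{i}" for i in range(len(rows))],
                     np.array([DEFAULT_ALPHABET.encode(r) for r in rows]))

    def test_no_double_mutants_gives_empty_table(self):
        model = toy_coupled_model()
        table = d.double_mutant_scan(model, self._panel(["AA", "CA"]), "AA")
        assert len(table) == 0

    def test_constructed_double_mutant_hand_value(self):
        model = toy_coupled_model()
        table = d.double_mutant_scan(model, self._panel(["CC"]), "AA")
        assert len(table) == 1
        row = table.iloc[0]
        assert row["delta_e_total"] - row["delta_e_sum"] == pytest.approx(-0.5)

    def test_gapped_double_mutants_are_excluded(self):
        model = d.PottsModel(h=np.zeros((3, 21)), J=np.zeros((3, 3, 21, 21)))
        table = d.double_mutant_scan(model, self._panel(["CC-"]), "AAA")
        assert len(table) == 0


class TestDivergenceEpistasis:
    def test_identical_pair(self):
        model = toy_coupled_model(L=4)
        table = d.divergence_epistasis(model, [("AAAA", "AAAA")])
        row = table.iloc[0]
        assert row["divergence"] == 0.0
        assert row["delta_delta_e"] == 0.0
        assert row["bin"] == "<5%"

    @pytest.mark.parametrize(
        "frac,label",
        [(0.0, "<5%"), (0.04, "<5%"), (0.05, "5-10%"), (0.12, "10-15%"),
         (0.2, "20-25%"), (0.3, ">25%")],
    )
    def test_binning_rule(self, frac, label):
        assert divergence_bin(frac) == label

    def test_gap_filter_drops_pairs(self):
        model = d.PottsModel(h=np.zeros((4, 21)), J=np.zeros((4, 4, 21, 21)))
        table = d.divergence_epistasis(model, [("AAAA", "CC--")])  # 2 gap differences
        assert len(table) == 0

    def test_median_cost_non_increasing_with_divergence(self, planted, reference):
        pairs = []
        for s in range(20):
            series = d.make_divergence_series(
                planted.model, reference, 12, selection_strength=2.0, seed=200 + s,
                record_every=1,
            )
            pairs.extend((reference, seq) for seq in series[1:])
        table = d.divergence_epistasis(planted.model, pairs)
        medians = table.groupby("bin")["delta_delta_e"].median()
        ordered = [medians[b] for b in
                   ["<5%", "5-10%", "10-15%", "15-20%", "20-25%", ">25%"] if b in medians]
        from scipy.stats import spearmanr

        rho = spearmanr(range(len(ordered)), ordered).statistic
        assert rho <= 0


class TestFixedDifferenceCouplings:
    def test_fourteen_differences_give_91_pairs(self):
        L = 20
        model = d.PottsModel(h=np.zeros((L, 21)), J=np.zeros((L, L, 21, 21)))
        a = "A" * L
        b = "C" * 14 + "A" * (L - 14)
        table = d.fixed_difference_couplings(model, a, b)
        assert len(table) == 91

    def test_fewer_than_two_differences_give_empty_list(self):
        model = toy_coupled_model(L=4)
        assert len(d.fixed_difference_couplings(model, "AAAA", "AAAA")) == 0
        assert len(d.fixed_difference_couplings(model, "AAAA", "CAAA")) == 0

    def test_zero_couplings_score_zero(self):
        L = 6
        model = d.PottsModel(h=np.zeros((L, 21)), J=np.zeros((L, L, 21, 21)))
        table = d.fixed_difference_couplings(model, "AAAAAA", "CCCAAA")
        assert np.allclose(table["delta_delta_e"], 0.0)

    def test_planted_pair_has_maximal_cost(self):
        # one strong planted coupling; the fixed-difference pair spanning it
        # must dominate all other pairs
        L, q = 8, 6
        alphabet = reduced_alphabet(q)
        J = np.zeros((L, L, q, q))
        J[1, 5, :, :] = 0.0
        J[1, 5, 0, 0] = 3.0  # favors A-A
        J[5, 1] = J[1, 5].T
        model = d.gauge_transform(
            d.PottsModel(h=np.zeros((L, q)), J=J, alphabet=alphabet)
        )
        a = "AAAAAAAA"
        b = "ACCCACCA"[:L]
        table = d.fixed_difference_couplings(model, a, b)
        top = table.loc[table["delta_delta_e"].abs().idxmax()]
        assert {int(top["site_i"]), int(top["site_j"])} == {2, 6}


class TestIpr:
    def _model(self, L, q, blocks):
        alphabet = reduced_alphabet(q) if q < 21 else DEFAULT_ALPHABET
        J = np.zeros((L, L, q, q))
        for (i, j, a, b), v in blocks.items():
            J[i, j, a, b] = v
            J[j, i, b, a] = v
        m = d.PottsModel(h=np.zeros((L, q)), J=J, alphabet=alphabet)
        m.gauge = "zero-sum"  # constructed directly in the analysis gauge
        return m

    def test_single_coupling_gives_ipr_one(self):
        model = self._model(5, 4, {(0, 1, 0, 0): 0.7})
        seq = np.zeros(5, dtype=int)
        value, prop = d.ipr(model, seq, 1)
        assert value == pytest.approx(1.0)
        assert prop == pytest.approx(1 / 5)

    def test_two_equal_couplings_at_l3(self):
        model = self._model(3, 4, {(0, 1, 0, 0): 0.5, (0, 2, 0, 0): 0.5})
        value, prop = d.ipr(model, np.zeros(3, dtype=int), 1)
        assert value == pytest.approx(0.5)
        assert prop == pytest.approx(2 / 3)

    def test_uniform_couplings_give_inverse_l_minus_one(self):
        L = 7
        blocks = {(0, j, 0, 0): 0.4 for j in range(1, L)}
        model = self._model(L, 4, blocks)
        value, _ = d.ipr(model, np.zeros(L, dtype=int), 1)
        assert value == pytest.approx(1 / (L - 1))

    def test_all_zero_couplings_reported_missing(self):
        model = self._model(4, 4, {})
        value, prop = d.ipr(model, np.zeros(4, dtype=int), 1)
        assert np.isnan(value) and np.isnan(prop)

    def test_bounds_on_fitted_model(self, fitted_potts, reference):
        profile = ipr_profile(fitted_potts, reference)
        ok = profile.dropna()
        L = fitted_potts.L
        assert ((ok["ipr"] >= 1 / (L - 1) - 1e-9) & (ok["ipr"] <= 1 + 1e-9)).all()
        assert ((ok["effective_proportion"] > 0)
                & (ok["effective_proportion"] <= (L - 1) / L + 1e-9)).all()


class TestResiduePairDistances:
    def test_shared_atom_is_a_contact(self):
        coords = {1: np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]]),
                  2: np.array([[0.0, 0.0, 0.0]])}
        table = d.residue_pair_distances(coords, [(1, 2)])
        assert table.iloc[0]["distance"] == 0.0
        assert bool(table.iloc[0]["contact"])

    def test_distant_residues_are_not_contacts(self):
        coords = {1: np.array([[0.0, 0.0, 0.0]]), 2: np.array([[50.0, 0.0, 0.0]])}
        table = d.residue_pair_distances(coords, [(1, 2)])
        assert table.iloc[0]["distance"] == pytest.approx(50.0)
        assert not bool(table.iloc[0]["contact"])

    def test_minimum_over_atom_pairs_matches_brute_force(self, rng):
        coords = {i: rng.normal(size=(4, 3)) for i in (1, 2, 3)}
        pairs = [(1, 2), (1, 3), (2, 3)]
        table = d.residue_pair_distances(coords, pairs)
        for (i, j), dist in zip(pairs, table["distance"]):
            brute = min(
                float(np.linalg.norm(x - y)) for x in coords[i] for y in coords[j]
            )
            assert dist == pytest.approx(brute)

    def test_unmapped_residue_reported_missing(self):
        coords = {1: np.array([[0.0, 0.0, 0.0]])}
        table = d.residue_pair_distances(coords, [(1, 9)])
        assert len(table) == 1
        assert np.isnan(table.iloc[0]["distance"])
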