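"""Energies, mutation scores, conditional distributions, gauge, serialization."""

import numpy as np
import pytest

import dcaland as d
from dcaland.alphabet import DEFAULT_ALPHABET, reduced_alphabet
from dcaland.models import ModelFormatError
from conftest import random_model, random_residue_sequence


def zero_model(L=4, q=21):
    alphabet = DEFAULT_ALPHABET if q == 21 else reduced_alphabet(q)
    return d.PottsModel(h=np.zeros((L, q)), J=np.zeros((L, L, q, q)), alphabet=alphabet)


def two_site_toy():
    """Binary toy: h_1(A)=1, J_12(A,A)=0.5 over states {A, C, gap}."""
    alphabet = reduced_alphabet(3)
    h = np.zeros((2, 3))
    h[0, 0] = 1.0
    J = np.zeros((2, 2, 3, 3))
    J[0, 1, 0, 0] = 0.5
    J[1, 0, 0, 0] = 0.5
    return d.PottsModel(h=h, J=J, alphabet=alphabet)


class TestStatisticalEnergy:
    def test_zero_model_energy_is_zero(self):
        assert d.statistical_energy(zero_model(), "ACD-") == 0.0

    def test_two_site_hand_value(self):
        assert d.statistical_energy(two_site_toy(), "AA") == pytest.approx(-1.5)

    def test_additivity_along_mutation_path_without_couplings(self, rng):
        planted = d.make_potts(6, q=5, n_pairs=0, field_scale=1.0, seed=3)
        model = planted.model
        a = random_residue_sequence(model, rng)
        b = random_residue_sequence(model, rng)
        total = d.statistical_energy(model, b) - d.statistical_energy(model, a)
        path_sum, cur = 0.0, a.copy()
        for i in range(model.L):
            if cur[i] != b[i]:
                path_sum += d.mutation_score(
                    model, cur, i + 1,
                    model.alphabet.symbols[cur[i]], model.alphabet.symbols[b[i]],
                )
                cur[i] = b[i]
        assert path_sum == pytest.approx(total, abs=1e-10)

    def test_length_mismatch_is_fatal(self):
        with pytest.raises(ValueError):
            d.statistical_energy(zero_model(L=4), "ACD")


class TestMutationScore:
    def test_identity_mutation_scores_zero(self):
        model = random_model(seed=1).model
        seq = np.zeros(model.L, dtype=int)
        assert d.mutation_score(model, seq, 1, "A", "A") == 0.0

    def test_field_only_difference_without_couplings(self):
        model = d.make_potts(5, q=6, n_pairs=0, field_scale=1.0, seed=2).model
        seq = np.zeros(model.L, dtype=int)
        expected = model.h[2, 0] - model.h[2, 3]
        got = d.mutation_score(model, seq, 3, "A", model.alphabet.symbols[3])
        assert got == pytest.approx(expected, abs=1e-12)

    def test_context_mismatch_is_fatal(self):
        model = random_model(seed=1).model
        seq = np.zeros(model.L, dtype=int)
        with pytest.raises(ValueError, match="context"):
            d.mutation_score(model, seq, 1, "C", "D")

    def test_matches_energy_difference_oracle(self, rng):
        for k in range(50):
            model = random_model(seed=k).model
            seq = random_residue_sequence(model, rng)
            site = int(rng.integers(0, model.L)) + 1
            beta = int(rng.integers(0, model.alphabet.n_residues))
            score = d.mutation_score(
                model, seq, site,
                model.alphabet.symbols[seq[site - 1]], model.alphabet.symbols[beta],
            )
            mutant = seq.copy()
            mutant[site - 1] = beta
            oracle = d.statistical_energy(model, mutant) - d.statistical_energy(model, seq)
            assert score == pytest.approx(oracle, abs=1e-10)


class TestConditionalProbabilities:
    def test_zero_model_is_uniform_over_20(self):
        dist = d.conditional_probabilities(zero_model(), "ACDE", 2)
        assert np.allclose(dist.probs, 1 / 20)

    def test_two_site_toy_hand_value(self):
        dist = d.conditional_probabilities(two_site_toy(), "AA", 1)
        assert dist.probs[0] == pytest.approx(1 / (1 + np.exp(-1.5)), abs=1e-9)

    def test_normalized_for_random_models(self, rng):
        for k in range(10):
            model = random_model(seed=k).model
            seq = random_residue_sequence(model, rng)
            site = int(rng.integers(0, model.L)) + 1
            dist = d.conditional_probabilities(model, seq, site)
            assert dist.probs.sum() == pytest.approx(1.0, abs=1e-9)
            assert (dist.probs >= 0).all()

    def test_invariant_under_gauge_transform(self, rng):
        model = random_model(seed=9).model
        zs = d.gauge_transform(model)
        seq = random_residue_sequence(model, rng)
        for site in (1, model.L // 2, model.L):
            p_raw = d.conditional_probabilities(model, seq, site).probs
            p_zs = d.conditional_probabilities(zs, seq, site).probs
            assert np.allclose(p_raw, p_zs, atol=1e-9)


class TestIndProbabilities:
    def _ind(self, f):
        return d.IndependentModel(f=np.asarray(f)[None, :], pseudocount=0.0)

    def test_raw_frequencies_pass_through(self):
        f = np.zeros(21)
        f[0] = f[1] = 0.5
        dist = d.ind_probabilities(self._ind(f), 1)
        assert dist.probs[0] == pytest.approx(0.5)
        assert dist.probs[1] == pytest.approx(0.5)
        assert dist.probs[2:].sum() == 0.0

    def test_full_smoothing_is_uniform(self):
        f = np.zeros(21)
        f[0] = 1.0
        dist = d.ind_probabilities(self._ind(f), 1, pseudocount=1.0)
        assert np.allclose(dist.probs, 1 / 20)

    def test_gap_mass_is_renormalized_away(self):
        f = np.zeros(21)
        f[0], f[20] = 0.9, 0.1
        dist = d.ind_probabilities(self._ind(f), 1)
        assert dist.probs[0] == pytest.approx(1.0)

    def test_all_gap_column_is_fatal(self):
        f = np.zeros(21)
        f[20] = 1.0
        with pytest.raises(ValueError):
            d.ind_probabilities(self._ind(f), 1)


class TestRankAminoAcid:
    def _dist(self, probs):
        return d.ConditionalDistribution(site=1, probs=np.asarray(probs))

    def test_argmax_ranks_first(self):
        p = np.full(20, 0.02)
        p[5] = 1 - p.sum() + p[5]
        dist = self._dist(p / p.sum())
        assert d.rank_amino_acid(dist, DEFAULT_ALPHABET.symbols[5]) == 1

    def test_uniform_ties_break_alphabetically(self):
        dist = self._dist(np.full(20, 1 / 20))
        assert d.rank_amino_acid(dist, "A") == 1
        assert d.rank_amino_acid(dist, "C") == 2
        assert d.rank_amino_acid(dist, "Y") == 20

    def test_counting_rule(self):
        p = np.zeros(20)
        p[0], p[1], p[2] = 0.5, 0.3, 0.2
        assert d.rank_amino_acid(self._dist(p), "C") == 2

    def test_ranks_form_a_permutation(self, rng):
        p = rng.random(20)
        dist = self._dist(p / p.sum())
        ranks = sorted(d.rank_amino_acid(dist, aa) for aa in DEFAULT_ALPHABET.symbols[:20])
        assert ranks == list(range(1, 21))


class TestGaugeTransform:
    def test_zero_sum_invariants(self):
        zs = d.gauge_transform(random_model(seed=4).model)
        assert np.allclose(zs.J.sum(axis=2), 0.0, atol=1e-9)
        assert np.allclose(zs.J.sum(axis=3), 0.0, atol=1e-9)
        assert np.allclose(zs.h.sum(axis=1), 0.0, atol=1e-9)

    def test_energy_differences_preserved(self, rng):
        model = random_model(seed=5).model
        zs = d.gauge_transform(model)
        for _ in range(10):
            a = random_residue_sequence(model, rng)
            b = random_residue_sequence(model, rng)
            raw = d.statistical_energy(model, a) - d.statistical_energy(model, b)
            transformed = d.statistical_energy(zs, a) - d.statistical_energy(zs, b)
            assert raw == pytest.approx(transformed, abs=1e-9)

    def test_fixed_point(self):
        zs = d.gauge_transform(random_model(seed=6).model)
        again = d.gauge_transform(zs)
        assert np.allclose(zs.J, again.J, atol=1e-12)
        assert np.allclose(zs.h, again.h, atol=1e-12)


class TestSerialization:
    def test_round_trip_preserves_energies(self, tmp_path, rng):
        model = random_model(seed=7).model
        path = tmp_path / "model.h5"
        d.save_model(model, path)
        loaded = d.load_model(path)
        for _ in range(20):
            seq = random_residue_sequence(model, rng)
            assert d.statistical_energy(model, seq) == pytest.approx(
                d.statistical_energy(loaded, seq), abs=1e-12
            )

    def test_independent_model_round_trip(self, tmp_path, ind_model):
        path = tmp_path / "ind.h5"
        d.save_model(ind_model, path)
        loaded = d.load_model(path)
        assert np.allclose(loaded.f, ind_model.f)

    def test_truncated_file_is_fatal(self, tmp_path):
        path = tmp_path / "junk.h5"
        path.write_bytes(b"\x89HDF\r\n\x1a\nbroken")
        with pytest.raises(ModelFormatError):
            d.load_model(path)
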