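"""Folding engine vs the exhaustive enumeration oracle."""

import numpy as np
import pytest
from scipy.special import logsumexp

from psifold.energy import PseudoEnergyModel, evaluate_energy
from psifold.folding import (count_structures, enumerate_structures,
                             mfe_fold, partition_function, sample_structures)
from psifold.reactivity import ContextDistributions, ReactivityProfile
from psifold.structure import SecondaryStructure


def _random_sequences(n_cases, min_len=6, max_len=14, seed=0):
    rng = np.random.default_rng(seed)
    for _ in range(n_cases):
        n = int(rng.integers(min_len, max_len + 1))
        yield "".join(rng.choice(list("ACGU"), n))


def _oracle(seq, model, pseudo=None):
    structs = enumerate_structures(seq, model, pseudo)
    energies = np.array([e for _, e in structs])
    return structs, energies


class TestEvaluateEnergy:
    def test_open_chain_scores_zero(self, default_model):
        s = SecondaryStructure.open_chain("ACGUACGUAC")
        assert evaluate_energy(s, default_model) == 0.0

    def test_hand_summed_helix(self, toy_model):
        # 4-pair helix (AU outermost), 4-nt hairpin loop:
        # 3 stacks x (-2.0) + hairpin 5.0 + one AU end 0.5 = -0.5
        s = SecondaryStructure.from_dotbracket("AGGGAAAACCCU",
                                               "((((....))))")
        assert evaluate_energy(s, toy_model) == pytest.approx(-0.5)

    def test_additive_over_exterior_segments(self, default_model):
        left = SecondaryStructure.from_dotbracket("GGGAAAACCC",
                                                  "(((....)))")
        right = SecondaryStructure.from_dotbracket("GGCAAAAGCC",
                                                   "(((....)))")
        joint = SecondaryStructure.from_dotbracket(
            left.sequence + right.sequence, "(((....)))(((....)))")
        assert evaluate_energy(joint, default_model) == pytest.approx(
            evaluate_energy(left, default_model)
            + evaluate_energy(right, default_model))


class TestEnumerationOracle:
    def test_unpairable_sequence_has_single_structure(self, default_model):
        structs = enumerate_structures("AAAA", default_model)
        assert len(structs) == 1
        assert structs[0][0].n_pairs == 0

    @pytest.mark.parametrize("seq", ["GGGAAACCC", "GCAUCGAUGCA",
                                     "ACGUACGUACGUAU"])
    def test_count_matches_independent_recursion(self, seq, default_model):
        structs = enumerate_structures(seq, default_model)
        assert len(structs) == count_structures(seq)
        assert len({s for s, _ in structs}) == len(structs)

    def test_refuses_long_sequences(self, default_model):
        with pytest.raises(ValueError, match="limited"):
            enumerate_structures("A" * 21, default_model)


class TestPartitionFunction:
    def test_unpairable_sequence(self, default_model):
        log_z, P = partition_function("AAAAAAAA", default_model)
        assert log_z == 0.0
        assert np.all(P == 0.0)

    def test_matches_oracle_on_random_sequences(self, default_model):
        """log Z and every P(i,j) equal the brute-force sums to 1e-9."""
        for seq in _random_sequences(60, seed=101):
            structs, energies = _oracle(seq, default_model)
            log_z_oracle = logsumexp(-energies / default_model.RT)
            log_z, P = partition_function(seq, default_model)
            assert log_z == pytest.approx(log_z_oracle, rel=1e-9, abs=1e-9)
            weights = np.exp(-energies / default_model.RT - log_z_oracle)
            P_oracle = np.zeros_like(P)
            for (s, _), w in zip(structs, weights):
                for i, j in s.pairs:
                    P_oracle[i, j] += w
                    P_oracle[j, i] += w
            assert np.abs(P - P_oracle).max() < 1e-9

    def test_paired_probability_bounded(self, default_model):
        _, P = partition_function("GGGCAAAAGCCCAUGGCC", default_model)
        per_nt = P.sum(axis=1)
        assert np.all(per_nt <= 1.0 + 1e-12)

    def test_pseudo_energy_neutral_for_all_sentinel_profile(
            self, default_model):
        seq = "GGGCAAAAGCCC"
        profile = ReactivityProfile(np.arange(1, 13),
                                    np.array(list(seq)),
                                    np.full(12, -999.0))
        pseudo = PseudoEnergyModel(ContextDistributions.from_gamma())
        ref = partition_function(seq, default_model)
        res = partition_function(seq, default_model, pseudo, profile)
        assert res[0] == ref[0]
        assert np.array_equal(res[1], ref[1])

    def test_matches_oracle_with_pseudo_energies(self, default_model):
        seq = "GGGCAAAAGCCC"
        rng = np.random.default_rng(3)
        profile = ReactivityProfile(np.arange(1, 13),
                                    np.array(list(seq)),
                                    rng.gamma(2.0, 0.3, 12))
        pseudo = PseudoEnergyModel(ContextDistributions.from_gamma())
        bound = pseudo.bind(profile)
        structs, energies = _oracle(seq, default_model, bound)
        log_z_oracle = logsumexp(-energies / default_model.RT)
        log_z, _ = partition_function(seq, default_model, pseudo, profile)
        assert log_z == pytest.approx(log_z_oracle, rel=1e-9)

    def test_raising_reactivity_lowers_paired_probability(
            self, default_model):
        """Monotone response of the probing restraint."""
        seq = "GGGCAAAAGCCC"
        pseudo = PseudoEnergyModel(ContextDistributions.from_gamma())
        probs = []
        for r2 in (0.05, 0.5, 2.0):
            react = np.full(12, -999.0)
            react[1] = r2  # position 2, paired in the main hairpin
            profile = ReactivityProfile(np.arange(1, 13),
                                        np.array(list(seq)), react)
            _, P = partition_function(seq, default_model, pseudo, profile)
            probs.append(P.sum(axis=1)[2])
        assert probs[0] > probs[1] > probs[2]


class TestMfe:
    def test_all_a_sequence_open_chain(self, default_model):
        s = mfe_fold("AAAAAAAAAA", default_model)
        assert s.n_pairs == 0

    def test_energy_matches_oracle_minimum(self, default_model):
        for seq in _random_sequences(40, seed=7):
            _, energies = _oracle(seq, default_model)
            s = mfe_fold(seq, default_model)
            assert evaluate_energy(s, default_model) == pytest.approx(
                energies.min(), abs=1e-9)

    def test_planted_hairpin_recovered(self, js60, config60):
        s = mfe_fold(js60.sequence, config60.model, config60.pseudo,
                     config60.profile)
        planted = set(js60.true_structure.pairs)
        assert planted <= set(s.pairs)


class TestSampling:
    def test_unpairable_sequence_samples_open_chain(self, default_model):
        ens = sample_structures("AAAAAAAA", default_model, n=20, seed=1)
        assert all(m.n_pairs == 0 for m in ens)

    def test_same_seed_reproduces_different_seed_differs(
            self, default_model):
        seq = "GGGCAAAAGCCCGAAAGGC"
        a = sample_structures(seq, default_model, n=50, seed=9)
        b = sample_structures(seq, default_model, n=50, seed=9)
        c = sample_structures(seq, default_model, n=50, seed=10)
        assert all(x == y for x, y in zip(a, b))
        assert any(x != y for x, y in zip(a, c))

    def test_frequencies_match_boltzmann_probabilities(self, default_model):
        """Empirical structure frequencies vs oracle, 4 sigma, n=10000."""
        seq = "GGGAAACCCA"
        structs, energies = _oracle(seq, default_model)
        p = np.exp(-energies / default_model.RT)
        p /= p.sum()
        n = 10000
        ens = sample_structures(seq, default_model, n=n, seed=42)
        from collections import Counter
        counts = Counter(tuple(m.pairs) for m in ens)
        for (s, _), pi in zip(structs, p):
            freq = counts.get(tuple(s.pairs), 0) / n
            se = np.sqrt(pi * (1 - pi) / n)
            assert abs(freq - pi) <= 4 * se + 1.5 / n

    def test_pairing_rates_match_pair_probability_matrix(self, js60,
                                                         config60):
        n = 2000
        ens = sample_structures(js60.sequence, config60.model,
                                config60.pseudo, config60.profile,
                                n=n, seed=4)
        _, P = partition_function(js60.sequence, config60.model,
                                  config60.pseudo, config60.profile)
        freq = np.zeros_like(P)
        for m in ens:
            for i, j in m.pairs:
                freq[i, j] += 1 / n
                freq[j, i] += 1 / n
        sd = np.sqrt(P * (1 - P) / n)
        within = np.abs(freq - P) <= 4 * sd + 2.5 / n
        assert within.mean() > 0.999
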