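import itertools

import numpy as np
import pytest

from psifold.junction import JunctionSequence, apply_mutation, parse_mutation
from psifold.motifs import (MotifPWM, SpliceSiteModel, delta_strength,
                            enumerate_kmer_scores, pwm_delta,
                            pwm_from_hexamers, rbp_delta,
                            splice_site_delta)
from psifold.synthetic import default_motif_pwms, gen_hexamer_sets

_BASES = "ACGU"


def _brute_force_threshold(pwm):
    scores = [sum(pwm.matrix[p, _BASES.index(b)]
                  for p, b in enumerate(kmer))
              for kmer in ("".join(t) for t in
                           itertools.product(_BASES, repeat=pwm.width))]
    return float(np.percentile(scores, 95))


def _brute_force_delta(pwm, js, mutant):
    """Scan every allowed window of both alleles; apply the filter."""
    from psifold.motifs import _window_bounds
    lo, hi = _window_bounds(pwm, js)
    total = 0.0
    for s in range(lo, hi + 1):
        wt_win = js.sequence[s - 1:s - 1 + pwm.width]
        mut_win = mutant[s - 1:s - 1 + pwm.width]
        if wt_win == mut_win:
            continue
        if max(pwm.score(wt_win), pwm.score(mut_win)) > pwm.threshold:
            total += pwm.score(mut_win) - pwm.score(wt_win)
    return total


class TestPwmConstruction:
    def test_all_hexamers_give_zero_pwm_without_pseudocount(self):
        all_hex = ("".join(t) for t in itertools.product(_BASES, repeat=6))
        pwm = pwm_from_hexamers(all_hex, "ESE", pseudocount=0.0)
        assert np.abs(pwm.matrix).max() < 1e-12

    def test_single_hexamer_maximizes_its_own_bases(self):
        pwm = pwm_from_hexamers(["GGGGGG"], "ESS")
        g = _BASES.index("G")
        for p in range(6):
            assert pwm.matrix[p].argmax() == g

    def test_half_frequency_maps_to_weight_one(self):
        # two k-mers agreeing at no position: each base freq 0.5
        pwm = pwm_from_hexamers(["AAAAAA", "CCCCCC"], "ISE",
                                pseudocount=0.0)
        a = _BASES.index("A")
        assert pwm.matrix[0, a] == pytest.approx(1.0)  # log2(0.5/0.25)

    def test_mixed_widths_rejected(self):
        with pytest.raises(ValueError, match="width"):
            pwm_from_hexamers(["AAAA", "AAAAA"], "ESE")


class TestThreshold:
    def test_zero_pwm_has_zero_threshold(self):
        pwm = MotifPWM("z", "ESE", np.zeros((6, 4)), threshold=None)
        assert pwm.threshold == 0.0

    def test_matches_brute_force_percentile(self):
        for cat, clusters in gen_hexamer_sets(seed=1,
                                              n_per_category=1).items():
            pwm = pwm_from_hexamers(clusters[0], cat)
            assert pwm.threshold == pytest.approx(
                _brute_force_threshold(pwm))

    def test_scaling_linearity(self):
        pwm = pwm_from_hexamers(["ACGUAC", "ACGUAA", "ACGAAC"], "ESE")
        scaled = MotifPWM("s", "ESE", 3.0 * pwm.matrix, threshold=None)
        assert scaled.threshold == pytest.approx(3.0 * pwm.threshold)

    def test_enumeration_covers_all_kmers(self):
        m = np.zeros((4, 4))
        m[0, 1] = 1.0  # C at position 1 scores 1
        scores = enumerate_kmer_scores(m)
        assert len(scores) == 256
        assert (scores == 1.0).sum() == 64


@pytest.fixture(scope="module")
def setting():
    js = JunctionSequence(
        "GAACCGUAGCUAGGCAUCGAAGGCAUCGGAUCCAAGGUAAGUAUCGGAUACGGAUAAC"
        "CAGGCAUCG", 30)
    sre, rbp = default_motif_pwms(seed=4)
    return js, tuple(sre), tuple(rbp)


class TestDeltaStrength:

    def test_identity_mutation_gives_all_zero(self, setting):
        js, sre, rbp = setting
        d = delta_strength(sre, js, js.sequence, rbp_pwms=rbp)
        assert d.delta_ss == 0.0 and d.enhancer == 0.0 and d.silencer == 0.0
        assert all(v == 0.0 for v in d.per_pwm.values())

    def test_below_threshold_windows_contribute_nothing(self, setting):
        js, _, _ = setting
        # a PWM that loves a motif absent from both alleles near the edit
        pwm = pwm_from_hexamers(["GGGGGG"], "ESE")
        mutant = js.sequence[:9] + "U" + js.sequence[10:]
        assert pwm_delta(pwm, js, mutant, [10]) == 0.0

    def test_matches_exhaustive_window_oracle(self, setting):
        js, sre, rbp = setting
        rng = np.random.default_rng(0)
        for _ in range(12):
            pos = int(rng.integers(1, len(js) + 1))
            ref = js.sequence[pos - 1]
            alt = rng.choice([b for b in _BASES if b != ref])
            mutant = js.sequence[:pos - 1] + alt + js.sequence[pos:]
            for pwm in sre + rbp:
                assert pwm_delta(pwm, js, mutant, [pos]) == pytest.approx(
                    _brute_force_delta(pwm, js, mutant))

    def test_locality_windows_not_covering_edit_unchanged(self, setting):
        js, sre, _ = setting
        pwm = sre[0]
        pos = 15
        mutant = js.sequence[:pos - 1] + (
            "A" if js.sequence[pos - 1] != "A" else "C") + js.sequence[pos:]
        wt_scores = pwm.scan(js.sequence)
        mut_scores = pwm.scan(mutant)
        for s in range(len(wt_scores)):
            covers = s + 1 <= pos <= s + pwm.width
            if not covers:
                assert wt_scores[s] == mut_scores[s]

    def test_swapping_alleles_negates_deltas(self, setting):
        js, sre, rbp = setting
        mutant = js.sequence[:19] + (
            "G" if js.sequence[19] != "G" else "A") + js.sequence[20:]
        js_mut = JunctionSequence(mutant, js.junction_offset)
        fwd = delta_strength(sre, js, mutant, rbp_pwms=rbp)
        rev = delta_strength(sre, js_mut, js.sequence, rbp_pwms=rbp)
        for name in fwd.per_pwm:
            assert fwd.per_pwm[name] == pytest.approx(-rev.per_pwm[name])

    def test_category_average_of_nonzero_deltas(self, setting):
        js, _, _ = setting
        # two ESE PWMs, one unaffected: category mean is over non-zeros
        hit = pwm_from_hexamers([js.sequence[9:15]], "ESE", name="hit")
        miss = pwm_from_hexamers(["GGGGGG"], "ESE", name="miss")
        mutant = js.sequence[:11] + (
            "A" if js.sequence[11] != "A" else "C") + js.sequence[12:]
        d = delta_strength((hit, miss), js, mutant)
        assert d.per_pwm["miss"] == 0.0
        assert d.per_category["ESE"] == pytest.approx(d.per_pwm["hit"])


class TestSpliceSiteDelta:
    def test_mutation_outside_nine_mer_scores_zero(self):
        js = JunctionSequence("G" * 20 + "GUAAGU" + "A" * 24, 20)
        mutant, _ = apply_mutation(js, parse_mutation("+19A>C"))
        assert splice_site_delta(js, mutant) == 0.0

    def test_wild_type_scores_zero(self):
        js = JunctionSequence("G" * 20 + "GUAAGU" + "A" * 24, 20)
        assert splice_site_delta(js, js.sequence) == 0.0

    def test_toy_matrix_lookup(self):
        matrix = np.zeros((9, 4))
        matrix[7, 2] = 1.0   # +5 position, G weight 1; A weight 0
        model = SpliceSiteModel(matrix)
        js = JunctionSequence("C" * 20 + "GUAAAU" + "C" * 10, 20)
        mutant, _ = apply_mutation(js, parse_mutation("+5A>G"))
        assert splice_site_delta(js, mutant, model) == pytest.approx(1.0)

    def test_default_model_favors_canonical_donor(self):
        model = SpliceSiteModel()
        assert model.score("CAGGUAAGU") > model.score("CAGCUAAGU")


class TestRbpDelta:
    def test_no_motif_near_mutation_gives_zero(self):
        js = JunctionSequence("A" * 40, 20)
        pwm = pwm_from_hexamers(["GGGGGG"], "RBP-inclusion")
        mutant = js.sequence[:4] + "C" + js.sequence[5:]
        assert rbp_delta((pwm,), js, mutant) == (0.0, 0.0)

    def test_single_affected_inclusion_pwm(self):
        js = JunctionSequence("AAGGGGGGAA" + "A" * 30, 20)
        pwm = pwm_from_hexamers(["GGGGGG"], "RBP-inclusion")
        mutant = js.sequence[:4] + "C" + js.sequence[5:]
        ex, inc = rbp_delta((pwm,), js, mutant)
        assert ex == 0.0
        assert inc == pytest.approx(
            _brute_force_delta(pwm, js, mutant))
        assert inc < 0  # motif destroyed
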