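import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psifold.energetics import (FOOTPRINTS, JunctionRegion,
                                count_footprint_from_coordinates,
                                delta_g_unfold, ensemble_unfolding_stats,
                                exon_independence_scan, footprint_region,
                                splice_site_region, unfold_region)
from psifold.energy import evaluate_energy
from psifold.folding import StructureEnsemble, sample_structures
from psifold.junction import JunctionSequence
from psifold.structure import SecondaryStructure
from psifold.synthetic import make_synthetic_coordinates


class TestUnfoldRegion:
    def test_region_without_pairs_is_identity(self):
        s = SecondaryStructure.from_dotbracket("GGGAAAACCCAAAA",
                                               "(((....)))....")
        assert unfold_region(s, 11, 14) == s

    def test_hairpin_inside_region_opens_fully(self):
        s = SecondaryStructure.from_dotbracket("GGGAAAACCC", "(((....)))")
        assert unfold_region(s, 1, 10).n_pairs == 0

    def test_matches_brute_force_pair_filter(self, js60, config60):
        ens = sample_structures(js60.sequence, config60.model,
                                config60.pseudo, config60.profile,
                                n=50, seed=2)
        start, end = 20, 33
        for s in ens:
            opened = unfold_region(s, start, end)
            expected = [(i, j) for i, j in s.pairs
                        if not (start <= i <= end or start <= j <= end)]
            assert opened.pairs == expected

    @settings(max_examples=30, deadline=None)
    @given(st.integers(1, 50), st.integers(0, 9), st.integers(0, 9))
    def test_region_monotonicity(self, start, grow_left, grow_right):
        """A larger region never removes fewer pairs."""
        seq = ("GGCGC" + "A" * 8 + "GCGCC") * 3
        pairs = []
        for block in range(3):
            off = block * 18
            pairs += [(off + k, off + 19 - k) for k in range(1, 6)]
        s = SecondaryStructure.from_pairs(seq, pairs)
        end = min(start + 5, len(seq))
        lo = max(1, start - grow_left)
        hi = min(len(seq), end + grow_right)
        removed_small = set(s.pairs) - set(unfold_region(s, start, end).pairs)
        removed_big = set(s.pairs) - set(unfold_region(s, lo, hi).pairs)
        assert removed_small <= removed_big


class TestDeltaGUnfold:
    def test_zero_when_region_unpaired(self, default_model):
        s = SecondaryStructure.from_dotbracket("GGGAAAACCCAAAAA",
                                               "(((....))).....")
        js = JunctionSequence(s.sequence, 11)
        assert delta_g_unfold(s, JunctionRegion(1, 4), js,
                              default_model) == 0.0

    def test_toy_hairpin_costs_its_stability(self, toy_model):
        # unfolding the whole hairpin leaves the open chain (energy 0),
        # so the cost is minus the folded energy: -(-0.5) = 0.5
        s = SecondaryStructure.from_dotbracket("AGGGAAAACCCU",
                                               "((((....))))")
        js = JunctionSequence(s.sequence, 6)
        cost = delta_g_unfold(s, JunctionRegion(6, 6), js, toy_model)
        assert cost == pytest.approx(0.5)
        assert cost == pytest.approx(-evaluate_energy(s, toy_model))

    def test_nonnegative_across_sampled_ensemble(self, js234, config234):
        ens = sample_structures(js234.sequence, config234.model,
                                config234.pseudo, config234.profile,
                                n=1000, seed=6)
        region = footprint_region("Bact")
        vals = [delta_g_unfold(s, region, js234, config234.model,
                               config234.pseudo) for s in ens]
        assert min(vals) >= 0.0


class TestEnsembleStats:
    def test_identical_members_have_zero_spread(self, js60, default_model):
        s = js60.true_structure
        ens = StructureEnsemble(js60.sequence, tuple([s] * 10), seed=0)
        stats = ensemble_unfolding_stats(ens, splice_site_region(), js60,
                                         default_model)
        assert stats.sd == 0.0 and stats.skew == 0.0 and stats.kurtosis == 0.0
        assert stats.mean == pytest.approx(
            delta_g_unfold(s, splice_site_region(), js60, default_model))

    def test_two_member_moments(self, js60, default_model, monkeypatch):
        stats_values = np.array([2.0, 4.0])
        import psifold.energetics as en
        calls = iter(stats_values.tolist() + [0.0])
        monkeypatch.setattr(en, "delta_g_unfold",
                            lambda *a, **k: next(calls))
        ens = StructureEnsemble(js60.sequence,
                                tuple([js60.true_structure] * 2), seed=0)
        stats = en.ensemble_unfolding_stats(ens, splice_site_region(),
                                            js60, default_model)
        assert stats.mean == pytest.approx(3.0)
        assert stats.sd == pytest.approx(1.0)  # population SD

    def test_moments_match_direct_recomputation(self, js234, config234):
        ens = sample_structures(js234.sequence, config234.model,
                                config234.pseudo, config234.profile,
                                n=120, seed=9)
        stats = ensemble_unfolding_stats(ens, footprint_region("Bact"),
                                         js234, config234.model,
                                         config234.pseudo, config234.profile)
        v = stats.values
        assert stats.mean == pytest.approx(v.mean())
        assert stats.sd == pytest.approx(v.std())
        m2 = ((v - v.mean()) ** 2).mean()
        m3 = ((v - v.mean()) ** 3).mean()
        m4 = ((v - v.mean()) ** 4).mean()
        assert stats.skew == pytest.approx(m3 / m2 ** 1.5)
        assert stats.kurtosis == pytest.approx(m4 / m2 ** 2 - 3.0)
        assert stats.n == 120

    def test_doubling_n_is_stable(self, js234, config234):
        region = footprint_region("Bact")
        stats1 = ensemble_unfolding_stats(
            sample_structures(js234.sequence, config234.model,
                              config234.pseudo, config234.profile,
                              n=400, seed=13),
            region, js234, config234.model, config234.pseudo,
            config234.profile)
        stats2 = ensemble_unfolding_stats(
            sample_structures(js234.sequence, config234.model,
                              config234.pseudo, config234.profile,
                              n=800, seed=14),
            region, js234, config234.model, config234.pseudo,
            config234.profile)
        tol = 4 * stats1.sd / np.sqrt(400)
        assert abs(stats1.mean - stats2.mean) < tol


class TestFootprints:
    @pytest.mark.parametrize("stage,width", [
        ("PreB", 10), ("B", 27), ("PreBact", 29), ("Bact", 43)])
    def test_builtin_widths(self, stage, width):
        assert footprint_region(stage).width == width

    def test_bact_interval_on_study_junction(self, js234):
        region = footprint_region("Bact", js234)
        assert region.resolve(js234) == (82, 124)
        assert region.width == 43

    def test_splice_site_is_nine_nt(self):
        assert splice_site_region().width == 9

    def test_extent_overflow_raises(self):
        js = JunctionSequence("ACGUACGUAC", 5)
        with pytest.raises(ValueError, match="overflow"):
            footprint_region("Bact", js)

    @pytest.mark.parametrize("counts", [(12, 31), (10, 17), (9, 20),
                                        (2, 8), (0, 0)])
    def test_counts_from_synthetic_coordinates(self, counts, tmp_path):
        n_ex, n_in = counts
        path = tmp_path / "fixture.pdb"
        make_synthetic_coordinates(n_ex, n_in, path)
        assert count_footprint_from_coordinates(path, "R", n_ex) == counts

    def test_counts_match_footprint_table(self, tmp_path):
        for stage, (n_ex, n_in) in FOOTPRINTS.items():
            path = tmp_path / f"{stage}.pdb"
            make_synthetic_coordinates(n_ex, n_in, path)
            assert count_footprint_from_coordinates(
                path, "R", n_ex) == (n_ex, n_in)

    def test_missing_chain_raises(self, tmp_path):
        path = tmp_path / "fixture.pdb"
        make_synthetic_coordinates(3, 3, path)
        with pytest.raises(KeyError):
            count_footprint_from_coordinates(path, "Z", 3)


class TestExonIndependenceScan:
    def test_self_contained_exon_stays_at_one(self, default_model):
        # exon is a strong hairpin; the extension is unpairable A's
        seq = "GGGGGCCAAAAGGCCCCC" + "A" * 12
        js = JunctionSequence(seq, 18)
        out = exon_independence_scan(js, (1, 18), model=default_model)
        folded = out[out.n_pairs > 0]
        assert len(folded) > 0
        assert (folded.fraction_intra == 1.0).all()

    def test_complementary_extension_breaks_independence(self,
                                                         default_model):
        # the extension can invade: reverse complement of the exon 5' side
        seq = "GGGGGAAAA" + "UUUUCCCCC"
        js = JunctionSequence(seq, 9)
        out = exon_independence_scan(js, (1, 9), model=default_model)
        assert out.iloc[-1].fraction_intra < 1.0

    def test_no_pairs_flagged_as_one(self, default_model):
        js = JunctionSequence("A" * 20, 10)
        out = exon_independence_scan(js, (1, 10), model=default_model)
        assert (out.fraction_intra == 1.0).all()
        assert (out.n_pairs == 0).all()
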