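"""Diversity, neutrality, AMOVA, distances, Mantel, summary vectors."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phylogeoabc.popgen import (
    STAT_NAMES,
    _ewens_log_pmf,
    amova_phist,
    diversity_indices,
    fus_fs,
    fus_fs_from_counts,
    group_distances,
    mantel_test,
    mismatch_distribution,
    net_distance,
    neutrality_p_value,
    r2_statistic,
    summary_vector,
    tajimas_d,
    tajimas_d_from_counts,
)
from phylogeoabc.seq_data import LocusAlignment, PopulationMap

from conftest import random_alignment


class TestDiversityIndices:
    def test_two_haplotypes_even_counts(self, worked_examples):
        d = diversity_indices(worked_examples["west_Rhod"]["alignment"])
        assert d.Hd == pytest.approx(2 / 3, abs=1e-12)
        assert round(d.Hd, 2) == 0.67
        assert round(d.Hd_sd, 1) == 0.2

    def test_two_haplotypes_skewed_counts(self, worked_examples):
        d = diversity_indices(worked_examples["west_SiaH"]["alignment"])
        assert d.Hd == pytest.approx(0.5, abs=1e-12)

    def test_all_distinct_max_diversity(self, worked_examples):
        d = diversity_indices(worked_examples["west_16S"]["alignment"])
        assert d.Hd == pytest.approx(1.0)
        assert round(d.Hd_sd, 2) == 0.27
        assert d.pi == pytest.approx((4 / 3) / 1035)

    def test_monomorphic(self, worked_examples):
        d = diversity_indices(worked_examples["west_ND2"]["alignment"])
        assert (d.Hd, d.pi, d.S) == (0.0, 0.0, 0)

    def test_h_between_one_and_n_and_kbar_below_s(self, rng):
        for _ in range(10):
            aln = random_alignment(rng, n=12, length=40, alphabet="AC")
            d = diversity_indices(aln)
            assert 1 <= d.h <= d.n
            assert d.k_bar <= d.S or d.S == 0


class TestTajimasD:
    def test_sign_matches_kbar_excess(self):
        # n=4: one singleton -> negative, doubleton -> positive
        assert tajimas_d_from_counts(4, 1, 0.5) < 0
        assert tajimas_d_from_counts(4, 1, 2 / 3) > 0

    def test_invariant_alignment_is_zero(self, worked_examples):
        assert tajimas_d(worked_examples["west_ND2"]["alignment"]).value == 0.0

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            tajimas_d_from_counts(2, 1, 0.5)

    def test_neutral_expectation_near_zero(self):
        # frequency-weighted mix of singleton/doubleton sites at n=20
        # keeps D near 0 when k-bar matches S/a1
        n, S = 20, 10
        a1 = sum(1 / i for i in range(1, n))
        assert tajimas_d_from_counts(n, S, S / a1) == pytest.approx(0.0)


class TestFusFs:
    def test_ewens_pmf_matches_partition_enumeration(self):
        """Stirling-based Pr(K=k) equals a direct sum of the Ewens
        sampling formula over integer partitions (n <= 8)."""
        from sympy.utilities.iterables import partitions

        for n in (4, 6, 8):
            for theta in (0.5, 1.7):
                by_k = np.zeros(n + 1)
                denom = math.prod(theta + i for i in range(n))
                for part in partitions(n):
                    a = part  # {part_size: multiplicity}
                    k = sum(a.values())
                    p = math.factorial(n) / denom
                    for j, aj in a.items():
                        p *= theta**aj / (j**aj * math.factorial(aj))
                    by_k[k] += p
                got = np.exp(_ewens_log_pmf(n, theta))
                assert np.allclose(got[1:], by_k[1:], atol=1e-12)

    def test_large_sample_no_overflow(self):
        # n ~ 300 with moderate theta stays finite
        val = fus_fs_from_counts(300, 25, 5.0)
        assert math.isfinite(val)

    def test_monomorphic_convention(self, worked_examples):
        assert fus_fs(worked_examples["west_ND2"]["alignment"]).value == 0.0

    def test_degenerate_single_haplotype_with_diversity(self):
        with pytest.raises(ValueError, match="degenerate"):
            fus_fs_from_counts(4, 1, 0.5)


class TestR2:
    def test_no_singletons_case(self, worked_examples):
        r2 = r2_statistic(worked_examples["west_Rhod"]["alignment"])
        assert r2.value == pytest.approx(1 / 3, abs=1e-12)

    def test_invariant_is_zero(self, worked_examples):
        assert r2_statistic(worked_examples["west_ND2"]["alignment"]).value == 0.0

    def test_folded_singleton_counting(self):
        # one site where the MAJOR allele is the singleton carrier
        seqs = (("a", "AA"), ("b", "CA"), ("c", "CA"), ("d", "CA"))
        aln = LocusAlignment("x", seqs)
        # sequence a carries the rare allele at site 1 -> U = (1,0,0,0)
        val = r2_statistic(aln).value
        k = 3 / 6 * 1.0  # three pairs differ at one site
        expected = math.sqrt(
            ((1 - k / 2) ** 2 + 3 * (k / 2) ** 2) / 4
        ) / 1
        assert val == pytest.approx(expected)


class TestNeutralityPValues:
    def test_d_zero_is_central_under_null(self):
        from phylogeoabc.popgen import NeutralityResult

        p = neutrality_p_value(
            NeutralityResult("D", 0.0), n=20, S=8, reps=400, seed=5
        )
        assert 0.3 < p < 0.7

    def test_star_expansion_gives_small_p(self):
        """All-singleton data (star genealogy) should reject neutrality."""
        from phylogeoabc.popgen import NeutralityResult

        n, S = 50, 20
        k_bar = S * 2 * (n - 1) / (n * (n - 1))  # all sites singletons
        d_obs = tajimas_d_from_counts(n, S, k_bar)
        assert d_obs < -1.5
        p = neutrality_p_value(
            NeutralityResult("D", d_obs), n=n, S=S, reps=1000, seed=7
        )
        assert p < 0.05

    def test_too_few_replicates_rejected(self):
        from phylogeoabc.popgen import NeutralityResult

        with pytest.raises(ValueError):
            neutrality_p_value(NeutralityResult("D", 0.0), 10, 5, reps=10)

    def test_invariant_data_is_na(self):
        from phylogeoabc.popgen import NeutralityResult

        p = neutrality_p_value(NeutralityResult("D", 0.0), 10, 0, reps=100)
        assert math.isnan(p)


def test_bonferroni_scales_and_caps():
    from phylogeoabc.popgen import bonferroni_correct

    out = bonferroni_correct([0.01, 0.2, 0.9])
    assert out == pytest.approx([0.03, 0.6, 1.0])


class TestMismatch:
    def test_monomorphic_mass_at_zero(self, worked_examples):
        h = mismatch_distribution(worked_examples["west_ND2"]["alignment"])
        assert h.frequencies == {0: 1.0}

    def test_west_16s_enumeration(self, worked_examples):
        h = mismatch_distribution(worked_examples["west_16S"]["alignment"])
        assert h.frequencies[1] == pytest.approx(2 / 3)
        assert h.frequencies[2] == pytest.approx(1 / 3)

    def test_sums_to_one_with_mean_kbar(self, rng):
        aln = random_alignment(rng, n=20, length=30)
        h = mismatch_distribution(aln)
        assert sum(h.frequencies.values()) == pytest.approx(1.0)
        d = diversity_indices(aln)
        assert h.mean() == pytest.approx(d.k_bar)


def _fixed_difference_alignment(per_group=5):
    a = "AAAA"
    b = "TTTT"
    seqs = tuple(
        [(f"x{i}", a) for i in range(per_group)]
        + [(f"y{i}", b) for i in range(per_group)]
    )
    pm = PopulationMap(
        {f"x{i}": ("X", "x") for i in range(per_group)}
        | {f"y{i}": ("Y", "y") for i in range(per_group)}
    )
    return LocusAlignment("fix", seqs), pm


class TestAmova:
    def test_fixed_difference_gives_phist_one(self):
        aln, pm = _fixed_difference_alignment()
        res = amova_phist(aln, pm, permutations=199, seed=0)
        assert res.phi_st == pytest.approx(1.0)
        assert res.pct_among == pytest.approx(100.0)
        assert res.p_value < 0.05

    def test_percentages_sum_to_hundred(self, rng, three_group_popmap):
        aln = random_alignment(rng, n=6, length=40)
        res = amova_phist(aln, three_group_popmap, permutations=0)
        assert res.pct_among + res.pct_within == pytest.approx(100.0, abs=1e-9)

    def test_matches_brute_force_ss_decomposition(self, rng, three_group_popmap):
        """Variance components recomputed from first principles."""
        from phylogeoabc.seq_data import pairwise_difference_matrix

        aln = random_alignment(rng, n=6, length=40)
        res = amova_phist(aln, three_group_popmap, permutations=0)
        d = pairwise_difference_matrix(aln).astype(float)
        n, G = 6, 3
        groups = [[0, 1], [2, 3], [4, 5]]
        ss_total = sum(d[i, j] for i in range(n) for j in range(i + 1, n)) / n
        ss_within = sum(
            sum(d[i, j] for i in g for j in g if i < j) / len(g)
            for g in groups
        )
        ss_among = ss_total - ss_within
        sigma_w = ss_within / (n - G)
        n_prime = (n - sum(len(g) ** 2 for g in groups) / n) / (G - 1)
        sigma_a = (ss_among / (G - 1) - sigma_w) / n_prime
        assert res.sigma_among == pytest.approx(sigma_a)
        assert res.sigma_within == pytest.approx(sigma_w)
        assert res.phi_st == pytest.approx(sigma_a / (sigma_a + sigma_w))

    def test_invariant_under_group_relabeling_and_row_order(self, rng):
        aln = random_alignment(rng, n=9, length=30)
        pm1 = PopulationMap(
            {f"s{i}": (["P", "Q", "R"][i % 3], "l") for i in range(9)}
        )
        pm2 = PopulationMap(
            {f"s{i}": (["zz", "aa", "mm"][i % 3], "l") for i in range(9)}
        )
        r1 = amova_phist(aln, pm1, permutations=0)
        r2 = amova_phist(aln, pm2, permutations=0)
        assert r1.phi_st == pytest.approx(r2.phi_st)
        # permute sequence order
        perm = list(range(9))[::-1]
        seqs = tuple(aln.sequences[i] for i in perm)
        r3 = amova_phist(LocusAlignment("p", seqs), pm1, permutations=0)
        assert r1.phi_st == pytest.approx(r3.phi_st)

    def test_panmictic_split_has_null_phist(self):
        """Random halves of one panmictic sample: Phi_ST centred on 0
        and permutation p roughly uniform."""
        rng = np.random.default_rng(99)
        phis, ps = [], []
        for _ in range(60):
            aln = random_alignment(rng, n=12, length=60)
            pm = PopulationMap(
                {f"s{i}": ("A" if i < 6 else "B", "l") for i in range(12)}
            )
            res = amova_phist(aln, pm, permutations=49, seed=int(rng.integers(2**31)))
            if not math.isnan(res.phi_st):
                phis.append(res.phi_st)
                ps.append(res.p_value)
        assert abs(np.mean(phis)) < 0.05
        assert 0.25 < np.mean(ps) < 0.75

    def test_identical_sequences_undefined(self):
        seqs = tuple((f"s{i}", "AAAA") for i in range(4))
        pm = PopulationMap(
            {f"s{i}": ("A" if i < 2 else "B", "l") for i in range(4)}
        )
        with pytest.warns(UserWarning, match="identical"):
            res = amova_phist(LocusAlignment("m", seqs), pm, permutations=0)
        assert math.isnan(res.phi_st)


class TestGroupDistances:
    def test_net_identity_holds(self, rng, three_group_popmap):
        aln = random_alignment(rng, n=6, length=40)
        gd = group_distances(aln, three_group_popmap)
        for (gx, gy), net in gd.net.items():
            assert net == pytest.approx(
                gd.raw[(gx, gy)] - (gd.within[gx] + gd.within[gy]) / 2
            )

    def test_identical_groups_have_zero_net(self):
        seqs = tuple((f"s{i}", "ACGTT") for i in range(4))
        pm = PopulationMap(
            {f"s{i}": ("A" if i < 2 else "B", "l") for i in range(4)}
        )
        gd = group_distances(LocusAlignment("m", seqs), pm)
        assert gd.net[("A", "B")] == 0.0

    def test_singleton_group_flagged_with_zero_pi(self):
        seqs = (("a", "AAAA"), ("b", "AAAT"), ("c", "TTTT"))
        pm = PopulationMap(
            {"a": ("X", "l"), "b": ("X", "l"), "c": ("Y", "l")}
        )
        gd = group_distances(LocusAlignment("m", seqs), pm)
        assert gd.within["Y"] == 0.0
        assert gd.small_groups == ("Y",)

    @given(
        st.floats(0, 100), st.floats(0, 10), st.floats(0, 10)
    )
    @settings(max_examples=50, deadline=None)
    def test_net_distance_formula(self, raw, px, py):
        assert net_distance(raw, px, py) == raw - (px + py) / 2


class TestMantel:
    @staticmethod
    def _sym(rng, n):
        m = rng.random((n, n)) * 10
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        return m

    def test_affine_relation_gives_r_one(self, rng):
        m1 = self._sym(rng, 5)
        m2 = 2 * m1 + 3
        np.fill_diagonal(m2, 0)
        r, _ = mantel_test(m1, m2, permutations=99, seed=0)
        assert r == pytest.approx(1.0)

    def test_exhaustive_p_matches_manual_enumeration(self, rng):
        m1 = self._sym(rng, 4)
        m2 = self._sym(rng, 4)
        r_obs, p = mantel_test(m1, m2, permutations=100, seed=0)
        iu = np.triu_indices(4, 1)
        rs = []
        for perm in itertools.permutations(range(4)):
            pm2 = m2[np.ix_(perm, perm)]
            rs.append(np.corrcoef(m1[iu], pm2[iu])[0, 1])
        assert p == pytest.approx(np.mean(np.array(rs) >= r_obs))

    def test_p_uniform_under_independence(self):
        rng = np.random.default_rng(3)
        ps = []
        for _ in range(200):
            m1 = self._sym(rng, 10)
            m2 = self._sym(rng, 10)
            _, p = mantel_test(
                m1, m2, permutations=49, seed=int(rng.integers(2**31))
            )
            ps.append(p)
        assert 0.4 < np.mean(ps) < 0.6

    def test_agrees_with_scikit_bio(self, rng):
        from skbio.stats.distance import DistanceMatrix, mantel

        m1 = self._sym(rng, 8)
        m2 = self._sym(rng, 8)
        r_ours, _ = mantel_test(m1, m2, permutations=99, seed=1)
        r_skbio, _, _ = mantel(
            DistanceMatrix(m1), DistanceMatrix(m2), permutations=0
        )
        assert r_ours == pytest.approx(r_skbio)

    def test_constant_matrix_is_na(self):
        m = np.ones((4, 4)) - np.eye(4)
        r, p = mantel_test(m, m, permutations=10)
        assert math.isnan(r)


class TestSummaryVector:
    def _dataset(self, rng):
        names = ["L1", "L2", "L3", "L4"]
        pm_map = {}
        alns = {}
        for name in names:
            mat = rng.choice(list("ACGT"), size=(9, 20))
            seqs = tuple(
                (f"{name}_{i}", "".join(r)) for i, r in enumerate(mat)
            )
            alns[name] = LocusAlignment(name, seqs)
            for i in range(9):
                pm_map[f"{name}_{i}"] = (["N", "S", "W"][i % 3], "l")
        return alns, PopulationMap(pm_map)

    def test_best_vector_length_on_four_loci_three_groups(self, rng):
        alns, pm = self._dataset(rng)
        vec = summary_vector(alns, pm, ("ss", "D", "pib"))
        assert len(vec) == 4 * (1 + 1 + 3)

    def test_single_stat_single_locus(self, rng):
        alns, pm = self._dataset(rng)
        one = {"L1": alns["L1"]}
        assert len(summary_vector(one, pm, ("pi",))) == 1

    def test_values_match_standalone_operations(self, rng):
        alns, pm = self._dataset(rng)
        vec = summary_vector(alns, pm, STAT_NAMES)
        named = dict(zip(vec.names, vec.values))
        for name, aln in alns.items():
            d = diversity_indices(aln)
            assert named[f"{name}:pi"] == pytest.approx(d.pi)
            assert named[f"{name}:ss"] == d.S
            assert named[f"{name}:D"] == pytest.approx(tajimas_d(aln).value)
            gd = group_distances(aln, pm)
            for (gx, gy), raw in gd.raw.items():
                assert named[f"{name}:pib:{gx}-{gy}"] == pytest.approx(
                    raw / aln.length
                )

    def test_unknown_stat_rejected(self, rng):
        alns, pm = self._dataset(rng)
        with pytest.raises(ValueError, match="unknown"):
            summary_vector(alns, pm, ("ss", "bogus"))
        with pytest.raises(ValueError, match="empty"):
            summary_vector(alns, pm, ())
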