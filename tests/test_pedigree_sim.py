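import numpy as np
import pytest
from scipy import stats

from rohkin.pedigree_sim import (
    GenomeMap,
    meiosis,
    offspring_to_frame,
    simulate_mating,
    simulation_envelope,
)

GM = GenomeMap.scaled(n_chrom=4, chrom_mb=80.0)


class TestMeiosis:
    def _founder_haps(self, length_bp):
        h1 = (np.array([float(length_bp)]), np.array([0]))
        h2 = (np.array([float(length_bp)]), np.array([1]))
        return h1, h2

    def test_zero_genetic_length_copies_one_parent(self):
        rng = np.random.default_rng(0)
        haps = self._founder_haps(50_000_000)
        picks = set()
        for _ in range(50):
            ends, labels = meiosis(haps, 50_000_000, 0.0, rng)
            assert len(labels) == 1
            picks.add(int(labels[0]))
        assert picks == {0, 1}  # both parents chosen across draws

    def test_crossover_count_is_poisson_mean_one_per_morgan(self):
        rng = np.random.default_rng(1)
        haps = self._founder_haps(100_000_000)  # 1 Morgan at 1 cM/Mb
        n_trials = 5000
        counts = []
        for _ in range(n_trials):
            ends, labels = meiosis(haps, 100_000_000, 1.0, rng)
            counts.append(len(labels) - 1)  # label switches = effective crossovers
        # effective switches are odd/even-filtered crossovers; compare with
        # the analytic expectation: switch count mean = Poisson(1) thinned by
        # adjacent-segment merging is still ~1 for two distinct parents
        mean = np.mean(counts)
        se = np.std(counts) / np.sqrt(n_trials)
        assert abs(mean - 1.0) < 3 * se + 0.02

    def test_breakpoints_uniform_kolmogorov_smirnov(self):
        rng = np.random.default_rng(2)
        haps = self._founder_haps(100_000_000)
        bps = []
        while len(bps) < 5000:
            ends, labels = meiosis(haps, 100_000_000, 1.0, rng)
            bps.extend(float(e) / 1e8 for e in ends[:-1])
        p = stats.kstest(bps, "uniform").pvalue
        assert p > 0.01


class TestMatingTypes:
    @pytest.mark.parametrize("mtype,f_expected", [
        ("incest", 0.25),
        ("avuncular", 0.125),
        ("first_cousin", 0.0625),
        ("second_cousin", 0.015625),
    ])
    def test_mean_autozygosity_matches_analytic_kinship(self, mtype, f_expected):
        offs = simulate_mating(mtype, GM, n_offspring=600, seed=11)
        fa = np.array([o.f_auto for o in offs])
        se = fa.std(ddof=1) / np.sqrt(len(fa))
        assert abs(fa.mean() - f_expected) < 3 * se

    def test_unrelated_parents_give_zero_autozygosity(self):
        offs = simulate_mating("unrelated", GM, n_offspring=30, seed=3)
        assert all(o.f_auto == 0.0 and not o.autozygous_tracts for o in offs)

    def test_unknown_mating_type_lists_valid_types(self):
        with pytest.raises(ValueError, match="second_cousin"):
            simulate_mating("cousins_thrice_removed", GM, n_offspring=1, seed=0)

    def test_sibling_incest_variant_also_quarter(self):
        offs = simulate_mating("incest", GM, n_offspring=400, seed=4,
                               incest_variant="sibling")
        fa = np.array([o.f_auto for o in offs])
        se = fa.std(ddof=1) / np.sqrt(len(fa))
        assert abs(fa.mean() - 0.25) < 3 * se

    def test_double_first_cousin_variant_eighth(self):
        offs = simulate_mating("avuncular", GM, n_offspring=400, seed=5,
                               avuncular_variant="double_first_cousin")
        fa = np.array([o.f_auto for o in offs])
        se = fa.std(ddof=1) / np.sqrt(len(fa))
        assert abs(fa.mean() - 0.125) < 3 * se


class TestTractProperties:
    def test_tract_sum_never_exceeds_genome(self):
        offs = simulate_mating("incest", GM, n_offspring=200, seed=6)
        for o in offs:
            total = sum(e - s for _, s, e in o.autozygous_tracts)
            assert total <= GM.total_bp

    def test_tracts_non_overlapping_and_sorted(self):
        offs = simulate_mating("first_cousin", GM, n_offspring=100, seed=7)
        for o in offs:
            by_chrom = {}
            for c, s, e in o.autozygous_tracts:
                by_chrom.setdefault(c, []).append((s, e))
            for tr in by_chrom.values():
                for (s1, e1), (s2, e2) in zip(tr, tr[1:]):
                    assert e1 <= s2

    def test_incest_tracts_longer_than_second_cousin(self):
        """Recent consanguinity produces disproportionately long tracts."""
        inc = simulate_mating("incest", GM, n_offspring=300, seed=8)
        sc = simulate_mating("second_cousin", GM, n_offspring=300, seed=9)

        def mean_len(offs):
            lens = [e - s for o in offs for _, s, e in o.autozygous_tracts]
            return np.mean(lens)

        assert mean_len(inc) > mean_len(sc)

    def test_same_seed_reproduces_identical_output(self):
        a = simulate_mating("first_cousin", GM, n_offspring=50, seed=12)
        b = simulate_mating("first_cousin", GM, n_offspring=50, seed=12)
        assert offspring_to_frame(a).equals(offspring_to_frame(b))

    def test_different_seeds_agree_in_mean_within_mc_error(self):
        a = simulate_mating("first_cousin", GM, n_offspring=500, seed=13)
        b = simulate_mating("first_cousin", GM, n_offspring=500, seed=14)
        fa = np.array([o.f_auto for o in a])
        fb = np.array([o.f_auto for o in b])
        se = np.sqrt(fa.var() / len(fa) + fb.var() / len(fb))
        assert abs(fa.mean() - fb.mean()) < 4 * se


class TestEnvelopes:
    def test_duplicated_points_give_zero_covariance(self):
        offs = simulate_mating("incest", GM, n_offspring=1, seed=15)
        dup = [offs[0], offs[0], offs[0]]
        env = simulation_envelope({"incest": dup})["incest"]
        assert np.allclose(env.cov, 0.0)

    def test_incest_cloud_right_of_second_cousin(self):
        offs = {
            "incest": simulate_mating("incest", GM, n_offspring=100, seed=16),
            "second_cousin": simulate_mating("second_cousin", GM, n_offspring=100, seed=17),
        }
        env = simulation_envelope(offs)
        assert env["incest"].mean[1] > env["second_cousin"].mean[1]

    def test_hull_contains_all_member_points(self):
        offs = simulate_mating("first_cousin", GM, n_offspring=80, seed=18)
        env = simulation_envelope({"first_cousin": offs})["first_cousin"]
        from scipy.spatial import Delaunay

        pts = np.array([[o.nroh_gt_threshold, o.sroh_gt_threshold_mb] for o in offs])
        hull = Delaunay(env.hull_points)
        assert (hull.find_simplex(pts) >= 0).all()
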