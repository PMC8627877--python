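import random

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from strmonitor import monitor as mon
from strmonitor.diversity import AlleleFrequencyTable, allele_frequencies

from _oracle import exact_permutation_pvalue, pearson_statistic
from conftest import make_table, random_table


def _freq_table(freqs, cohort="c", locus="L0", n_typed=500):
    counts = {a: max(1, int(round(p * 2 * n_typed))) for a, p in freqs.items()}
    first = next(iter(counts))
    if sum(counts.values()) % 2:
        counts[first] += 1
    total = sum(counts.values())
    freqs = {a: c / total for a, c in counts.items()}
    return AlleleFrequencyTable(cohort, locus, total // 2, counts, freqs)


class TestClassification:
    def test_threshold_application(self):
        f = _freq_table({"O": 0.742, "K": 0.2, "M": 0.04, "P": 0.018})
        c = mon.classify_alleles(f)
        assert set(c.rare) == {"M", "P"}
        assert set(c.common) == {"O"}
        assert set(c.intermediate) == {"K"}

    def test_exact_threshold_is_not_rare(self):
        # "below 0.05" is strict: an allele at exactly 0.05 is intermediate
        f = _freq_table({"A": 0.95, "B": 0.05}, n_typed=100)
        c = mon.classify_alleles(f, rare_threshold=0.05)
        assert "B" not in c.rare
        assert "B" in c.intermediate

    def test_unique_by_set_difference(self):
        focal = _freq_table({"X": 0.01, "A": 0.99})
        ref = _freq_table({"A": 1.0}, cohort="other")
        c = mon.classify_alleles(focal, references=[ref])
        assert set(c.unique) == {"X"}

    def test_no_references_means_no_unique_calls(self):
        c = mon.classify_alleles(_freq_table({"X": 1.0}))
        assert c.unique == {}

    def test_mismatched_reference_locus_rejected(self):
        focal = _freq_table({"A": 1.0}, locus="L0")
        ref = _freq_table({"A": 1.0}, locus="L1")
        with pytest.raises(ValueError, match="locus"):
            mon.classify_alleles(focal, references=[ref])

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1])
    def test_thresholds_must_be_in_open_interval(self, bad):
        f = _freq_table({"A": 1.0})
        with pytest.raises(ValueError):
            mon.classify_alleles(f, rare_threshold=bad)

    @given(
        st.lists(st.floats(0.01, 1.0), min_size=1, max_size=8),
        st.floats(0.01, 0.3),
        st.floats(0.3, 0.9),
    )
    def test_partition_property(self, weights, rare_thr, common_thr):
        """Every observed allele lands in exactly one class when common >= rare."""
        total = sum(weights)
        freqs = {chr(65 + i): w / total for i, w in enumerate(weights)}
        f = _freq_table(freqs, n_typed=10000)
        c = mon.classify_alleles(f, rare_threshold=rare_thr, common_threshold=common_thr)
        buckets = [set(c.common), set(c.intermediate), set(c.rare)]
        union = set().union(*buckets)
        assert union == set(f.freqs)
        assert sum(len(b) for b in buckets) == len(union)


class TestCompareCohorts:
    def _two_cohort_table(self, pairs_a, pairs_b, locus="L0"):
        rows = [(f"a{i}", "a", [p]) for i, p in enumerate(pairs_a)]
        rows += [(f"b{i}", "b", [p]) for i, p in enumerate(pairs_b)]
        return make_table(rows, [locus])

    def test_identical_cohorts_are_null(self):
        pairs = [("K", "K"), ("K", "L"), ("L", "M"), ("M", "M")]
        pairs_b = [(a, b) for a, b in pairs]
        t = self._two_cohort_table(pairs, pairs_b)
        c = mon.compare_cohorts(t, "a", "b")
        lc = c.per_locus[0]
        assert lc.statistic == 0.0
        assert lc.p_value == 1.0
        assert lc.gained == {} and lc.lost == {}
        assert lc.genotype_statistic == 0.0
        assert lc.genotype_p_value == 1.0

    def test_hand_evaluated_pearson_statistic(self):
        # copy counts a:{K:30,L:10} vs b:{K:10,L:30} -> chi2 = 20 on the 2x2
        pairs_a = [("K", "K")] * 15 + [("L", "L")] * 5
        pairs_b = [("K", "K")] * 5 + [("L", "L")] * 15
        t = self._two_cohort_table(pairs_a, pairs_b)
        c = mon.compare_cohorts(t, "a", "b")
        assert c.per_locus[0].statistic == pytest.approx(20.0)
        assert c.per_locus[0].df == 1

    def test_statistic_matches_scipy_on_dense_tables(self):
        rng = random.Random(3)
        for _ in range(20):
            t = random_table(rng, n_samples=30, n_loci=1, cohorts=("a", "b"),
                             alphabet="KLM", missing_rate=0.0)
            if {"a", "b"} - set(t.cohorts()):
                continue
            c = mon.compare_cohorts(t, "a", "b")
            lc = c.per_locus[0]
            obs = np.array(
                [
                    [lc.freqs_a.get(al, 0) * 2 * sum(1 for r in t.samples if r.cohort == "a"),
                     lc.freqs_b.get(al, 0) * 2 * sum(1 for r in t.samples if r.cohort == "b")]
                    for al in sorted(set(lc.freqs_a) | set(lc.freqs_b))
                ]
            )
            if (obs.sum(axis=1) == 0).any() or obs.shape[0] < 2:
                continue
            expected = sps.chi2_contingency(obs, correction=False)
            assert lc.statistic == pytest.approx(expected.statistic, abs=1e-9)
            assert lc.p_value == pytest.approx(expected.pvalue, abs=1e-9)

    def test_gained_lost_inventory(self):
        t = self._two_cohort_table(
            [("K", "K"), ("H", "K")], [("K", "P"), ("K", "S")]
        )
        lc = mon.compare_cohorts(t, "a", "b").per_locus[0]
        assert set(lc.gained) == {"P", "S"}
        assert set(lc.lost) == {"H"}
        assert set(lc.shared_ratio) == {"K"}
        assert not set(lc.gained) & set(lc.lost)

    def test_monotone_in_frequency_shift(self):
        """Widening a 2-allele frequency gap at fixed n never lowers chi2."""
        prev = -1.0
        for shift in range(0, 10):
            ca = {"K": 20 + shift, "L": 20 - shift}
            cb = {"K": 20 - shift, "L": 20 + shift}
            stat = pearson_statistic(ca, cb)
            obs = np.array([[ca["K"], cb["K"]], [ca["L"], cb["L"]]], dtype=float)
            stat2, _ = mon.pearson_chi2(obs)
            assert stat2 == pytest.approx(stat, abs=1e-9)
            assert stat2 >= prev
            prev = stat2

    def test_permutation_matches_exhaustive_enumeration(self):
        rng = random.Random(17)
        checked = 0
        while checked < 5:
            pairs = [
                (rng.choice("KL"), rng.choice("KL")) for _ in range(8)
            ]
            t = self._two_cohort_table(pairs[:4], pairs[4:])
            c = mon.compare_cohorts(t, "a", "b", test="permutation",
                                    n_perm=20000, seed=123)
            lc = c.per_locus[0]
            obs, p_exact = exact_permutation_pvalue(pairs, 4)
            assert lc.statistic == pytest.approx(obs, abs=1e-9)
            # (1+X)/(1+B) vs exact enumeration: Monte-Carlo error only
            mc_err = 3 * (p_exact * (1 - p_exact) / 20000) ** 0.5 + 1e-4
            assert lc.p_value == pytest.approx(p_exact, abs=mc_err + 0.01)
            checked += 1

    def test_permutation_seed_reproducible(self):
        t = self._two_cohort_table(
            [("K", "K"), ("K", "L")] * 5, [("L", "L"), ("K", "L")] * 5
        )
        p1 = mon.compare_cohorts(t, "a", "b", test="permutation", n_perm=500, seed=9)
        p2 = mon.compare_cohorts(t, "a", "b", test="permutation", n_perm=500, seed=9)
        assert p1.per_locus[0].p_value == p2.per_locus[0].p_value

    def test_fisher_collapse_on_2x2(self):
        pairs_a = [("K", "K")] * 15 + [("L", "L")] * 5
        pairs_b = [("K", "K")] * 5 + [("L", "L")] * 15
        t = self._two_cohort_table(pairs_a, pairs_b)
        c = mon.compare_cohorts(t, "a", "b", test="fisher")
        lc = c.per_locus[0]
        _, p22 = sps.fisher_exact([[30, 10], [10, 30]])
        # two symmetric alleles -> Bonferroni x2, capped at 1
        assert lc.p_value == pytest.approx(min(1.0, 2 * p22))
        assert lc.per_allele_p["K"] == pytest.approx(p22)

    def test_holm_adjustment_across_loci(self):
        rng = random.Random(31)
        t = random_table(rng, n_samples=40, n_loci=4, cohorts=("a", "b"),
                         missing_rate=0.0)
        c = mon.compare_cohorts(t, "a", "b")
        raw = [lc.p_value for lc in c.per_locus]
        holm = [lc.p_holm for lc in c.per_locus]
        assert all(h >= r - 1e-12 for r, h in zip(raw, holm))
        assert all(0 <= h <= 1 for h in holm)

    def test_bad_arguments(self, tiny_table):
        with pytest.raises(ValueError, match="test"):
            mon.compare_cohorts(tiny_table, "2000", "2000", test="anova")
        with pytest.raises(ValueError, match="n_perm"):
            mon.compare_cohorts(tiny_table, "2000", "2000",
                                test="permutation", n_perm=10)
        with pytest.raises(KeyError):
            mon.compare_cohorts(tiny_table, "2000", "1990")

    def test_genotype_counts_reported(self):
        t = self._two_cohort_table(
            [("K", "K"), ("K", "L"), ("L", "K")], [("K", "K")]
        )
        lc = mon.compare_cohorts(t, "a", "b").per_locus[0]
        assert (lc.n_genotypes_a, lc.n_genotypes_b) == (2, 1)


class TestPermutationCalibration:
    def test_type_i_error_near_alpha(self):
        """Label shuffling under a true null rejects at about the nominal rate."""
        rng = np.random.default_rng(2718)
        import strmonitor as sm

        rejections = 0
        n_rep = 300
        for _ in range(n_rep):
            seed = int(rng.integers(2**31))
            t, _ = sm.simulate(
                sm.SimulationConfig(seed=seed, n_loci=1, f=0.0, drift_sd=0.0,
                                    cohorts=(("a", 50), ("b", 50)))
            )
            c = sm.compare_cohorts(t, "a", "b", test="permutation",
                                   n_perm=400, seed=seed)
            if c.per_locus[0].p_value < 0.05:
                rejections += 1
        rate = rejections / n_rep
        assert 0.02 <= rate <= 0.08


class TestTrajectory:
    def test_fold_change_series(self):
        t1 = _freq_table({"A": 0.2, "B": 0.8}, cohort="2000")
        t2 = _freq_table({"A": 0.167, "B": 0.833}, cohort="2010")
        (a, b) = mon.frequency_trajectory([t1, t2])
        assert a.allele == "A"
        assert a.folds[0] == pytest.approx(1.0)
        assert a.folds[1] == pytest.approx(0.167 / 0.2, abs=1e-3)
        # rendered the other way round: "1.2 times less frequent"
        assert 0.2 / 0.167 == pytest.approx(1.2, abs=0.01)

    def test_constant_frequency_all_folds_one(self):
        ts = [_freq_table({"A": 0.5, "B": 0.5}, cohort=c) for c in "xyz"]
        for traj in mon.frequency_trajectory(ts):
            assert all(f == pytest.approx(1.0) for f in traj.folds)

    def test_gained_allele_flagged_no_fold(self):
        t1 = _freq_table({"A": 1.0}, cohort="2000")
        t2 = _freq_table({"A": 0.9, "X": 0.1}, cohort="2010")
        trajs = {tr.allele: tr for tr in mon.frequency_trajectory([t1, t2])}
        x = trajs["X"]
        assert x.gained
        assert all(f is None for f in x.folds)

    def test_locus_mismatch_rejected(self):
        t1 = _freq_table({"A": 1.0}, locus="L0")
        t2 = _freq_table({"A": 1.0}, locus="L1")
        with pytest.raises(ValueError, match="inconsistent"):
            mon.frequency_trajectory([t1, t2])

    def test_needs_two_cohorts(self):
        with pytest.raises(ValueError):
            mon.frequency_trajectory([_freq_table({"A": 1.0})])


class TestReports:
    def test_comparison_tsv_statuses(self):
        t = make_table(
            [
                ("a1", "a", [("K", "K")]),
                ("a2", "a", [("H", "K")]),
                ("b1", "b", [("K", "P")]),
            ],
            ["L0"],
        )
        tsv = mon.comparison_to_tsv(mon.compare_cohorts(t, "a", "b"))
        statuses = {
            line.split("\t")[1]: line.split("\t")[5]
            for line in tsv.strip().split("\n")[1:]
        }
        assert statuses == {"H": "lost", "K": "shared", "P": "gained"}

    def test_classification_tsv_flags(self):
        focal = _freq_table({"O": 0.742, "K": 0.2, "M": 0.04, "X": 0.018})
        ref = _freq_table({"O": 0.5, "K": 0.3, "M": 0.2}, cohort="ref")
        c = mon.classify_alleles(focal, references=[ref])
        tsv = mon.classification_to_tsv([c])
        flags = {
            line.split("\t")[2]: line.split("\t")[5]
            for line in tsv.strip().split("\n")[1:]
        }
        assert flags["M"] == "*"     # rare
        assert flags["X"] == "**"    # unique (and rare)
        assert flags["O"] == ""
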