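"""Population statistics: allele frequencies, heterozygosity, F_ST, HWE."""

import math

import numpy as np
import pytest

from diagmsat.popgen import (
    GenotypeMatrix,
    Individual,
    allele_frequencies,
    bonferroni_threshold,
    genotype_counts_at,
    heterozygosities,
    hwe_exact_test,
    shared_allele_frequency_mass,
    shared_private_alleles,
    wc_fst,
)


def _gm(pop_rows, loci=("L1",)):
    """Build a GenotypeMatrix from {pop: [[(a,b), ...], ...]} rows."""
    individuals, rows = [], []
    for pop, geno_rows in pop_rows.items():
        for i, r in enumerate(geno_rows):
            individuals.append(Individual(f"{pop}_{i}", pop))
            rows.append(list(r))
    return GenotypeMatrix(individuals, list(loci), np.array(rows, dtype=np.int64))


def wc_theta_oracle(calls1, calls2):
    """Independent scalar transliteration of the 1984 two-sample theta.

    Written directly from the published component formulas with r=2 and no
    shared code with the package implementation.
    """
    n1, n2 = len(calls1), len(calls2)
    r = 2.0
    nbar = (n1 + n2) / 2.0
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1.0)
    alleles = sorted({a for g in calls1 + calls2 for a in g})
    A = B = C = 0.0
    for al in alleles:
        p1 = sum(g.count(al) for g in calls1) / (2.0 * n1)
        p2 = sum(g.count(al) for g in calls2) / (2.0 * n2)
        h1 = sum(1 for g in calls1 if g.count(al) == 1) / n1
        h2 = sum(1 for g in calls2 if g.count(al) == 1) / n2
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar)
            - (r - 1) / r * s2
            - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
        A, B, C = A + a, B + b, C + c
    return A / (A + B + C)


class TestAlleleFrequencies:
    def test_hand_counted_example(self):
        gm = _gm({"A": [[(101, 101)], [(101, 103)], [(103, 103)], [(101, 101)]]})
        t = allele_frequencies(gm, "A")
        assert t.freqs["L1"] == {101: pytest.approx(5 / 8), 103: pytest.approx(3 / 8)}
        assert t.n_genotyped["L1"] == 4

    def test_missing_calls_excluded(self):
        gm = _gm({"A": [[(101, 101)], [(0, 0)], [(101, 103)]]})
        t = allele_frequencies(gm, "A")
        assert t.n_genotyped["L1"] == 2
        assert sum(t.freqs["L1"].values()) == pytest.approx(1.0)
        assert t.freqs["L1"][101] == pytest.approx(3 / 4)

    def test_frequencies_sum_to_one_random(self):
        rng = np.random.default_rng(2)
        calls = rng.integers(101, 110, size=(30, 5, 2))
        gm = GenotypeMatrix(
            [Individual(f"i{i}", "A") for i in range(30)],
            [f"L{j}" for j in range(5)],
            calls,
        )
        t = allele_frequencies(gm, "A")
        for locus in gm.loci:
            assert sum(t.freqs[locus].values()) == pytest.approx(1.0)

    def test_unknown_population_rejected(self):
        gm = _gm({"A": [[(101, 101)]]})
        with pytest.raises(KeyError):
            allele_frequencies(gm, "Z")


class TestHeterozygosity:
    def test_hand_computed(self):
        gm = _gm({"A": [[(101, 103)], [(101, 101)], [(101, 103)], [(103, 103)]]})
        ho, he = heterozygosities(gm, "A", "L1")
        assert ho == pytest.approx(0.5)
        assert he == pytest.approx(1 - 0.5**2 - 0.5**2)

    def test_monomorphic(self):
        gm = _gm({"A": [[(101, 101)], [(101, 101)]]})
        assert heterozygosities(gm, "A", "L1") == (0.0, 0.0)

    def test_all_heterozygous(self):
        gm = _gm({"A": [[(101, 103)], [(101, 103)]]})
        ho, he = heterozygosities(gm, "A", "L1")
        assert ho == 1.0 and he == pytest.approx(0.5)


class TestSharedPrivate:
    def test_counts_and_proportion(self):
        gm = _gm(
            {
                "A": [[(101, 103)], [(103, 105)]],
                "B": [[(103, 107)], [(107, 107)]],
            }
        )
        fa = allele_frequencies(gm, "A")
        fb = allele_frequencies(gm, "B")
        shared, priv_a, priv_b, prop = shared_private_alleles(fa, fb, "L1")
        assert (shared, priv_a, priv_b) == (1, 2, 1)
        assert prop == pytest.approx(1 / 4)
        # frequency-weighted companion: mean of 103's mass in each pool
        mass = shared_allele_frequency_mass(fa, fb, "L1")
        assert mass == pytest.approx((2 / 4 + 1 / 4) / 2)

    def test_disjoint_pools(self):
        gm = _gm({"A": [[(101, 101)]], "B": [[(105, 105)]]})
        fa, fb = allele_frequencies(gm, "A"), allele_frequencies(gm, "B")
        assert shared_private_alleles(fa, fb, "L1")[:1] == (0,)
        assert shared_allele_frequency_mass(fa, fb, "L1") == 0.0

    def test_identical_pools(self):
        gm = _gm({"A": [[(101, 103)]], "B": [[(101, 103)]]})
        fa, fb = allele_frequencies(gm, "A"), allele_frequencies(gm, "B")
        assert shared_private_alleles(fa, fb, "L1")[3] == 1.0
        assert shared_allele_frequency_mass(fa, fb, "L1") == pytest.approx(1.0)

    def test_unknown_locus(self):
        gm = _gm({"A": [[(101, 101)]], "B": [[(101, 101)]]})
        fa, fb = allele_frequencies(gm, "A"), allele_frequencies(gm, "B")
        with pytest.raises(KeyError):
            shared_private_alleles(fa, fb, "NOPE")


class TestWcFst:
    def test_fixed_difference_is_one(self):
        gm = _gm({"A": [[(101, 101)]] * 20, "B": [[(103, 103)]] * 20})
        per, multi = wc_fst(gm, "A", "B")
        assert per["L1"] == pytest.approx(1.0)
        assert multi == pytest.approx(1.0)

    def test_monomorphic_is_nan(self):
        gm = _gm({"A": [[(101, 101)]] * 5, "B": [[(101, 101)]] * 5})
        per, multi = wc_fst(gm, "A", "B")
        assert math.isnan(per["L1"]) and math.isnan(multi)

    def test_matches_independent_transliteration(self):
        rng = np.random.default_rng(31)
        for trial in range(25):
            n1, n2 = int(rng.integers(5, 40)), int(rng.integers(5, 40))
            k = int(rng.integers(2, 6))
            c1 = [tuple(rng.integers(101, 101 + k, size=2)) for _ in range(n1)]
            c2 = [tuple(rng.integers(101, 101 + k, size=2)) for _ in range(n2)]
            alleles = {a for g in c1 + c2 for a in g}
            if len(alleles) < 2:
                continue
            gm = _gm({"A": [[g] for g in c1], "B": [[g] for g in c2]})
            per, _ = wc_fst(gm, "A", "B")
            assert per["L1"] == pytest.approx(wc_theta_oracle(c1, c2), abs=1e-12)

    def test_null_mean_near_zero(self):
        # both samples from one pool: E[theta] ~ 0 (unbiasedness of the
        # estimator); average over replicates must be small
        rng = np.random.default_rng(17)
        vals = []
        for _ in range(500):
            calls = rng.choice([101, 103, 105], size=(40, 1, 2), p=[0.5, 0.3, 0.2])
            gm = GenotypeMatrix(
                [Individual(f"i{i}", "A" if i < 20 else "B") for i in range(40)],
                ["L1"],
                calls,
            )
            per, _ = wc_fst(gm, "A", "B")
            vals.append(per["L1"])
        assert abs(np.mean(vals)) < 0.01

    def test_invariant_to_population_order_and_labels(self):
        rng = np.random.default_rng(8)
        calls = rng.integers(101, 106, size=(30, 3, 2))
        inds = [Individual(f"i{i}", "X" if i < 14 else "Y") for i in range(30)]
        gm = GenotypeMatrix(inds, ["L1", "L2", "L3"], calls)
        per_xy, multi_xy = wc_fst(gm, "X", "Y")
        per_yx, multi_yx = wc_fst(gm, "Y", "X")
        assert multi_xy == pytest.approx(multi_yx)
        for locus in gm.loci:
            assert per_xy[locus] == pytest.approx(per_yx[locus])

    def test_multilocus_is_component_ratio_not_mean(self):
        # unbalanced information content: the ratio-of-sums estimate must
        # differ from the naive mean of per-locus estimates
        gm = _gm(
            {
                "A": [[(101, 101), (101, 103)]] * 10 + [[(101, 101), (103, 103)]] * 10,
                "B": [[(103, 103), (101, 103)]] * 10 + [[(103, 103), (101, 101)]] * 10,
            },
            loci=("L1", "L2"),
        )
        per, multi = wc_fst(gm, "A", "B")
        naive = np.mean([per["L1"], per["L2"]])
        assert multi != pytest.approx(naive, abs=1e-6)


class TestHweExact:
    def test_hand_enumerable_example(self):
        # 2 alleles, n=5: AA=2 AB=2 BB=1; verify against direct enumeration
        obs = {(1, 1): 2, (1, 2): 2, (2, 2): 1}
        p = hwe_exact_test(obs, method="enumeration")
        # allele counts: A=6, B=4, n=5 -> possible hetero counts 0,2,4
        def prob(n_ab):
            n_aa = (6 - n_ab) // 2
            n_bb = (4 - n_ab) // 2
            return (
                math.factorial(5)
                * 2**n_ab
                * math.factorial(6)
                * math.factorial(4)
                / (
                    math.factorial(10)
                    * math.factorial(n_aa)
                    * math.factorial(n_ab)
                    * math.factorial(n_bb)
                )
            )
        probs = {h: prob(h) for h in (0, 2, 4)}
        expected = sum(v for v in probs.values() if v <= probs[2] + 1e-12)
        assert p == pytest.approx(expected, rel=1e-9)

    def test_probabilities_sum_to_one(self):
        # the least probable array's p-value aside, the most extreme check:
        # perfect HWE-looking array should give p close to 1
        obs = {(1, 1): 9, (1, 2): 12, (2, 2): 4}
        assert hwe_exact_test(obs, method="enumeration") > 0.5

    def test_monomorphic_returns_one(self):
        assert hwe_exact_test({(1, 1): 30}) == 1.0

    def test_extreme_heterozygote_excess_small_p(self):
        obs = {(1, 2): 30}
        p = hwe_exact_test(obs, method="enumeration")
        assert p < 0.01

    def test_monte_carlo_agrees_with_enumeration(self):
        obs = {(1, 1): 5, (1, 2): 3, (2, 2): 6, (1, 3): 2, (3, 3): 4}
        exact = hwe_exact_test(obs, method="enumeration")
        mc = hwe_exact_test(obs, method="monte_carlo", reps=50_000, seed=4)
        assert mc == pytest.approx(exact, abs=0.01)

    def test_enumeration_overflow_raises(self):
        obs = {(i, j): 3 for i in range(1, 9) for j in range(i, 9)}
        with pytest.raises(OverflowError):
            hwe_exact_test(obs, method="enumeration", max_enumeration=100)

    def test_auto_falls_back_to_monte_carlo(self):
        obs = {(i, j): 3 for i in range(1, 9) for j in range(i, 9)}
        p = hwe_exact_test(obs, method="auto", max_enumeration=100, reps=2000, seed=1)
        assert 0.0 < p <= 1.0

    def test_null_uniformity_of_pvalues(self):
        # data simulated under HWE: p-values should be super-uniform-ish;
        # check rejection rate at alpha=0.05 is not inflated
        rng = np.random.default_rng(55)
        rejections = 0
        trials = 200
        for _ in range(trials):
            geno = rng.choice([101, 103], size=(30, 2), p=[0.6, 0.4])
            counts = {}
            for a, b in geno:
                key = (int(min(a, b)), int(max(a, b)))
                counts[key] = counts.get(key, 0) + 1
            if hwe_exact_test(counts, method="enumeration") < 0.05:
                rejections += 1
        # exact conditional test is conservative; allow up to ~8% by chance
        assert rejections / trials <= 0.08

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test({})
        with pytest.raises(ValueError):
            hwe_exact_test({(1, 2): 5}, method="bogus")

    def test_genotype_counts_at_roundtrip(self):
        gm = _gm({"A": [[(101, 103)], [(103, 101)], [(101, 101)], [(0, 0)]]})
        counts = genotype_counts_at(gm, "A", "L1")
        assert counts == {(101, 103): 2, (101, 101): 1}


class TestBonferroni:
    def test_threshold(self):
        assert bonferroni_threshold(0.05, 12) == pytest.approx(0.05 / 12)
        assert bonferroni_threshold(0.05, 1) == 0.05

    def test_invalid(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.0, 5)
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)
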