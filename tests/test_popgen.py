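import math

import numpy as np
import pytest

from gencmr import popgen
from gencmr.popgen import LocusFrequencies
from gencmr.synthetic import (
    SimulationConfig,
    TrueIndividual,
    TruePopulation,
    simulate_genotypes,
)


def _founders(n):
    return TruePopulation(
        [TrueIndividual(f"I{i:04d}", "female", (0, 0), 1, None, i) for i in range(n)],
        config_seed=0,
    )


def _freq(locus="L1", **freqs):
    return LocusFrequencies(locus, dict(freqs), n=50)


class TestAlleleFrequencies:
    def test_direct_count(self):
        genos = [{"L1": (100, 100)}, {"L1": (100, 102)}]
        f = popgen.allele_frequencies(genos, "L1")
        assert f.freqs == {100: 0.75, 102: 0.25}
        assert f.n == 2

    def test_missing_excluded_from_denominator(self):
        genos = [{"L1": (100, 100)}, {"L1": (0, 0)}]
        f = popgen.allele_frequencies(genos, "L1")
        assert f.n == 1 and f.freqs == {100: 1.0}

    def test_all_missing_raises(self):
        with pytest.raises(ValueError, match="typed"):
            popgen.allele_frequencies([{"L1": (0, 0)}], "L1")

    def test_founder_frequency_recovery(self):
        cfg = SimulationConfig(allele_freqs={"L1": {100: 0.7, 102: 0.3}}, seed=4)
        g = simulate_genotypes(_founders(500), cfg)
        f = popgen.allele_frequencies(list(g.values()), "L1")
        se = math.sqrt(0.7 * 0.3 / 1000)
        assert abs(f.freqs[100] - 0.7) < 3 * se


class TestDiversity:
    def test_closed_form_two_alleles_all_heterozygous(self):
        genos = [{"L1": (100, 102)}] * 10
        f = popgen.allele_frequencies(genos, "L1")
        d = popgen.locus_diversity(f, genos)
        assert d.He == pytest.approx(0.5)
        assert d.Ho == 1.0
        assert d.Fis == pytest.approx(-1.0)
        assert d.Ne == pytest.approx(2.0)
        assert d.Na == 2

    def test_fis_is_one_minus_ho_over_he(self):
        """Convention check against the published rounding: Ho=0.815,
        He=0.885 must give Fis printed as 0.079."""
        assert round((0.885 - 0.815) / 0.885, 3) == 0.079

    def test_unbiased_he_ratio_exact(self):
        genos = [{"L1": (100, 102)}, {"L1": (100, 100)}, {"L1": (102, 102)}]
        f = popgen.allele_frequencies(genos, "L1")
        d = popgen.locus_diversity(f, genos)
        assert d.UHe / d.He == pytest.approx(2 * f.n / (2 * f.n - 1))

    def test_monomorphic_locus_flagged(self):
        genos = [{"L1": (100, 100)}] * 5
        f = popgen.allele_frequencies(genos, "L1")
        d = popgen.locus_diversity(f, genos)
        assert d.He == 0.0 and d.Fis is None


class TestPid:
    def test_closed_form_two_equifrequent_alleles(self):
        res = popgen.pid_sib([_freq(a=0.5, b=0.5)])
        assert res.pid_locus[0] == pytest.approx(0.375)
        assert res.pidsib_locus[0] == pytest.approx(0.59375)

    def test_cumulative_never_increases(self):
        freqs = [
            _freq("L1", a=0.5, b=0.5),
            _freq("L2", a=0.25, b=0.25, c=0.25, d=0.25),
            _freq("L3", a=0.9, b=0.1),
        ]
        res = popgen.pid_sib(freqs)
        assert all(
            later <= earlier + 1e-15
            for earlier, later in zip(res.pidsib_cumulative, res.pidsib_cumulative[1:])
        )
        # identity is always easier between random pairs than between sibs
        for pid, sib in zip(res.pid_locus, res.pidsib_locus):
            assert pid <= sib

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            popgen.pid_sib([])


class TestHwe:
    def test_equilibrium_table_high_p(self):
        counts = {(100, 100): 25, (100, 102): 50, (102, 102): 25}
        res = popgen.hwe_exact(counts, batches=10, iterations=200, seed=1)
        assert res.p > 0.5

    def test_monomorphic_p_one(self):
        assert popgen.hwe_exact({(100, 100): 30}).p == 1.0

    def test_monte_carlo_matches_enumeration(self):
        counts = {(100, 100): 4, (100, 102): 2, (102, 102): 6}
        exact = popgen.hwe_enumerate(counts)
        res = popgen.hwe_exact(counts, batches=20, iterations=500, seed=2)
        mc_se = max(res.se, 1e-3)
        assert abs(res.p - exact) < 3 * mc_se

    def test_type_one_error_rate(self):
        """Data simulated under equilibrium rejects at ~alpha."""
        rng = np.random.default_rng(9)
        rejections = 0
        nrep = 200
        for _ in range(nrep):
            alleles = rng.choice([100, 102], size=(60, 2), p=[0.6, 0.4])
            counts = {}
            for a, b in np.sort(alleles, axis=1):
                counts[(a, b)] = counts.get((a, b), 0) + 1
            p = popgen.hwe_exact(counts, batches=5, iterations=100,
                                 seed=int(rng.integers(2**31))).p
            rejections += p <= 0.05
        rate = rejections / nrep
        assert abs(rate - 0.05) < 0.045  # 3 binomial SE, exact test is conservative


class TestBonferroni:
    def test_single_p_threshold_is_alpha(self):
        assert popgen.bonferroni([0.04]) == [True]
        assert popgen.bonferroni([0.06]) == [False]

    def test_eight_tests_arithmetic(self):
        flags = popgen.bonferroni([0.004] + [0.5] * 7)
        assert flags[0] is True and not any(flags[1:])  # 0.004 < 0.05/8

    def test_all_ones_none_significant(self):
        assert not any(popgen.bonferroni([1.0] * 5))


class TestErrorRates:
    def test_error_free_rates_zero(self):
        consensus = {"L1": (100, 102)}
        groups = [(consensus, [consensus, consensus])]
        out = popgen.error_rates(groups, ["L1"])
        assert out["L1"].dropout == 0.0 and out["L1"].false_allele == 0.0

    def test_constructed_dropout_rate(self):
        consensus = {"L1": (100, 102)}
        obs = [consensus] * 9 + [{"L1": (100, 100)}]
        groups = [(consensus, obs)]
        out = popgen.error_rates(groups, ["L1"])
        assert out["L1"].dropout == pytest.approx(0.1)

    def test_no_replicates_undefined(self):
        groups = [({"L1": (100, 102)}, [{"L1": (100, 102)}])]
        out = popgen.error_rates(groups, ["L1"])
        assert out["L1"].dropout is None and out["L1"].false_allele is None

    def test_false_allele_counted(self):
        consensus = {"L1": (100, 102)}
        groups = [(consensus, [consensus, {"L1": (100, 104)}])]
        out = popgen.error_rates(groups, ["L1"])
        assert out["L1"].false_allele == pytest.approx(0.5)


def _sim_freqs(genotypes, loci):
    genos = list(genotypes.values())
    return {l: popgen.allele_frequencies(genos, l) for l in loci}


class TestQgRelatedness:
    def test_identical_genotypes_near_one(self):
        cfg = SimulationConfig(seed=5)
        g = simulate_genotypes(_founders(50), cfg)
        freqs = _sim_freqs(g, cfg.loci)
        ids = list(g)
        r = popgen.qg_relatedness(g[ids[0]], g[ids[0]], freqs)
        assert r > 0.8

    def test_mean_pairwise_centering(self):
        """With sample-estimated frequencies the all-pairs mean is ~ -1/(n-1)."""
        cfg = SimulationConfig(seed=6)
        g = simulate_genotypes(_founders(190), cfg)
        freqs = _sim_freqs(g, cfg.loci)
        m = popgen.qg_matrix(list(g.values()), freqs)
        off = m[np.triu_indices(190, 1)]
        assert abs(np.nanmean(off) - (-1 / 189)) < 0.004

    def test_parent_offspring_near_half(self):
        inds = []
        for i in range(150):
            inds.append(TrueIndividual(f"M{i:03d}", "female", (0, 0), 1, None, i))
            inds.append(TrueIndividual(f"O{i:03d}", "female", (0, 0), 1, f"M{i:03d}", i))
        pop = TruePopulation(inds, config_seed=0)
        cfg = SimulationConfig(seed=7)
        g = simulate_genotypes(pop, cfg)
        freqs = _sim_freqs(g, cfg.loci)
        rs = [
            popgen.qg_relatedness(g[f"M{i:03d}"], g[f"O{i:03d}"], freqs)
            for i in range(150)
        ]
        assert abs(np.mean(rs) - 0.5) < 0.05

    def test_no_shared_loci_undefined(self):
        freqs = {"L1": _freq("L1", a=0.5, b=0.5), "L2": _freq("L2", a=0.5, b=0.5)}
        assert popgen.qg_relatedness({"L1": (1, 1)}, {"L2": (1, 1)}, freqs) is None

    def test_matrix_symmetric_nan_diagonal(self):
        cfg = SimulationConfig(seed=8)
        g = simulate_genotypes(_founders(12), cfg)
        freqs = _sim_freqs(g, cfg.loci)
        m = popgen.qg_matrix(list(g.values()), freqs)
        assert np.isnan(np.diag(m)).all()
        mask = ~np.isnan(m)
        assert (mask == mask.T).all() and np.allclose(m[mask], m.T[mask])


class TestMlKinship:
    def test_parent_offspring_likelihood_dominates_unrelated_sharing(self):
        """Sharing a low-frequency allele at every locus favors PO over U
        (chance sharing of a rare allele is unlikely)."""
        freqs = {"L1": LocusFrequencies("L1", {100: 0.1, 102: 0.1, 104: 0.1, 106: 0.7}, 50)}
        g1 = {"L1": (100, 102)}
        g2 = {"L1": (100, 104)}  # shares the rare allele 100
        res = popgen.ml_kinship(g1, g2, freqs)
        assert res.loglik["parent-offspring"] >= res.loglik["unrelated"] - 1e-12

    def test_no_shared_alleles_excludes_parent_offspring(self):
        freqs = {"L1": LocusFrequencies("L1", {100: 0.25, 102: 0.25, 104: 0.25, 106: 0.25}, 50)}
        res = popgen.ml_kinship({"L1": (100, 102)}, {"L1": (104, 106)}, freqs)
        assert res.loglik["parent-offspring"] == -math.inf
        assert res.category in {"unrelated", "half-sib", "full-sib"}

    def test_full_sibs_beat_unrelated_in_majority(self):
        rng = np.random.default_rng(10)
        cfg = SimulationConfig(seed=11)
        # build 200 full-sib pairs: shared mother and shared sire per pair
        inds = []
        for i in range(200):
            inds.append(TrueIndividual(f"M{i:03d}", "female", (0, 0), 1, None, i))
            inds.append(TrueIndividual(f"A{i:03d}", "female", (0, 0), 1, f"M{i:03d}", i))
            inds.append(TrueIndividual(f"B{i:03d}", "female", (0, 0), 1, f"M{i:03d}", i))
        pop = TruePopulation(inds, config_seed=0)
        g = simulate_genotypes(pop, cfg)
        freqs = _sim_freqs(g, cfg.loci)
        fs_wins = 0
        for i in range(200):
            res = popgen.ml_kinship(g[f"A{i:03d}"], g[f"B{i:03d}"], freqs)
            fs_wins += res.loglik["full-sib"] > res.loglik["unrelated"]
        assert fs_wins > 100

    def test_order_classes(self):
        assert "parent-offspring" in popgen.FIRST_ORDER
        assert "half-sib" in popgen.SECOND_ORDER
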