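import dataclasses
import subprocess
import textwrap
from datetime import date as Date

import numpy as np
import pytest

from gencmr import identify, popgen, sociality
from gencmr.synthetic import simulate_genotypes, simulate_population, simulate_survey

from conftest import make_sample

LOCI = [f"L{i}" for i in range(1, 9)]


def _individual(iid, sex="female", hap="H1", samples=()):
    return identify.Individual(
        individual_id=iid, consensus={}, sex=sex, haplotype=hap, samples=list(samples)
    )


def _pair_at(iid1, iid2, distance, same_day=True, same_freshness=True):
    g1 = {f"L{i}": (100, 102 + 2 * i) for i in range(1, 9)}
    g2 = {f"L{i}": (104, 106 + 2 * i) for i in range(1, 9)}
    s1 = make_sample(sample_id=f"{iid1}-s", genotype=g1, freshness="f1")
    s2 = make_sample(
        sample_id=f"{iid2}-s",
        genotype=g2,
        x=distance,
        date=Date(2013, 7, 1) if same_day else Date(2013, 7, 2),
        freshness="f1" if same_freshness else "f2",
    )
    return [_individual(iid1, samples=[s1]), _individual(iid2, samples=[s2])]


class TestAssociations:
    @pytest.mark.parametrize("radius, expected", [(75.0, 0), (100.0, 1), (250.0, 1)])
    def test_threshold_geometry(self, radius, expected):
        inds = _pair_at("A", "B", 80.0)
        assert len(sociality.find_associations(inds, radius)) == expected

    def test_different_days_never_associate(self):
        inds = _pair_at("A", "B", 10.0, same_day=False)
        assert sociality.find_associations(inds, 250.0) == set()

    def test_different_freshness_never_associates(self):
        inds = _pair_at("A", "B", 10.0, same_freshness=False)
        assert sociality.find_associations(inds, 250.0) == set()

    def test_flagged_aged_samples_excluded(self):
        inds = _pair_at("A", "B", 10.0)
        for ind in inds:
            ind.samples[0] = dataclasses.replace(ind.samples[0], freshness_class="aged")
        assert sociality.find_associations(inds, 250.0) == set()

    def test_own_samples_never_associate(self):
        s1 = make_sample(sample_id="s1")
        s2 = make_sample(sample_id="s2", x=10.0)
        ind = _individual("A", samples=[s1, s2])
        assert sociality.find_associations([ind], 250.0) == set()

    def test_codeposited_group_pairs_recovered(self, small_config):
        """Same-visit detections of one group sit within the group spread,
        so a 100 m radius finds them."""
        pop = simulate_population(small_config)
        g = simulate_genotypes(pop, small_config)
        records, truth = simulate_survey(pop, g, small_config, return_truth=True)
        # ground truth co-depositions: same cohort, different individuals
        by_cohort = {}
        for r in records:
            by_cohort.setdefault(r.freshness_class, set()).add(truth[r.sample_id])
        expected = set()
        for members in by_cohort.values():
            members = sorted(members)
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    expected.add((members[i], members[j]))
        assert expected, "no co-depositions in simulation"
        inds = [
            _individual(iid, samples=[r for r in records if truth[r.sample_id] == iid])
            for iid in sorted({truth[r.sample_id] for r in records})
        ]
        got = sociality.find_associations(inds, 100.0)
        assert expected <= got  # full sensitivity at 100 m

    def test_edge_nesting_across_radii(self, small_config):
        pop = simulate_population(small_config)
        g = simulate_genotypes(pop, small_config)
        records, truth = simulate_survey(pop, g, small_config, return_truth=True)
        inds = [
            _individual(iid, samples=[r for r in records if truth[r.sample_id] == iid])
            for iid in sorted({truth[r.sample_id] for r in records})
        ]
        e75 = sociality.find_associations(inds, 75.0)
        e100 = sociality.find_associations(inds, 100.0)
        e250 = sociality.find_associations(inds, 250.0)
        assert e75 <= e100 <= e250


class TestNetwork:
    def test_no_associations_empty_network(self):
        net = sociality.build_network([], [])
        assert net.number_of_nodes() == 0

    def test_triangle_single_component(self):
        inds = [_individual(i) for i in "ABC"]
        net = sociality.build_network(
            [("A", "B"), ("B", "C"), ("A", "C")], inds, {("A", "B"): 0.5}
        )
        stats = sociality.component_stats(net)
        assert stats.n_components == 1
        assert stats.n_edges == 3 and stats.n_vertices == 3

    def test_female_only_is_subgraph(self):
        inds = [
            _individual("A", "female"),
            _individual("B", "male"),
            _individual("C", "female"),
            _individual("D", "unknown"),
        ]
        assoc = [("A", "B"), ("A", "C"), ("C", "D")]
        full = sociality.build_network(assoc, inds)
        females = sociality.build_network(
            assoc, inds, include_males=False, include_unknown_sex=False
        )
        assert set(females.nodes) <= set(full.nodes)
        assert set(females.edges) <= {tuple(sorted(e)) for e in full.edges}
        assert set(females.nodes) == {"A", "C"}

    def test_no_isolated_vertices(self):
        inds = [_individual(i) for i in "AB"]
        net = sociality.build_network([("A", "B")], inds + [_individual("Z")])
        assert "Z" not in net.nodes

    def test_degree_invariant(self):
        inds = [_individual(i) for i in "ABCDE"]
        net = sociality.build_network(
            [("A", "B"), ("C", "D"), ("D", "E")], inds
        )
        st = sociality.component_stats(net)
        assert st.n_components <= st.n_vertices <= 2 * st.n_edges


class TestComponentStats:
    def test_monomorphic_pair(self):
        inds = [_individual("A", hap="H1"), _individual("B", hap="H1")]
        net = sociality.build_network([("A", "B")], inds)
        st = sociality.component_stats(net)
        assert st.prop_monomorphic == 1.0

    def test_mixed_haplotypes_polymorphic(self):
        inds = [_individual("A", hap="H1"), _individual("B", hap="H2")]
        net = sociality.build_network([("A", "B")], inds)
        st = sociality.component_stats(net)
        assert st.prop_monomorphic == 0.0

    def test_unhaplotyped_female_makes_component_unassessable(self):
        inds = [_individual("A", hap="H1"), _individual("B", hap=None)]
        net = sociality.build_network([("A", "B")], inds)
        st = sociality.component_stats(net)
        assert st.n_multi_female == 1
        assert st.n_assessable == 0 and st.prop_monomorphic is None

    def test_published_proportion_arithmetic(self):
        """12 monomorphic out of 22 assessable multi-female components is
        the printed 54.5%."""
        assert round(12 / 22 * 100, 1) == 54.5

    def test_within_component_relatedness_exceeds_population_mean(self, small_config):
        cfg = dataclasses.replace(small_config, female_dispersal_prob=0.0, seed=19)
        pop = simulate_population(cfg)
        g = simulate_genotypes(pop, cfg)
        records, truth = simulate_survey(pop, g, cfg, return_truth=True)
        by_id = pop.by_id()
        detected = sorted({truth[r.sample_id] for r in records})
        inds = []
        for iid in detected:
            t = by_id[iid]
            inds.append(
                identify.Individual(
                    individual_id=iid,
                    consensus=g[iid],
                    sex=t.sex,
                    haplotype=f"H{t.haplotype_id}",
                    samples=[r for r in records if truth[r.sample_id] == iid],
                )
            )
        freqs = {l: popgen.allele_frequencies([i.consensus for i in inds], l) for l in cfg.loci}
        qg = popgen.qg_matrix([i.consensus for i in inds], freqs)
        ids = [i.individual_id for i in inds]
        rel = {
            (ids[i], ids[j]): qg[i, j]
            for i in range(len(ids))
            for j in range(i + 1, len(ids))
            if np.isfinite(qg[i, j])
        }
        assoc = sociality.find_associations(inds, 100.0)
        net = sociality.build_network(assoc, inds, rel)
        st = sociality.component_stats(net, rel)
        assert st.mean_dyadic_r is not None
        assert st.mean_dyadic_r > np.nanmean(qg[np.triu_indices(len(ids), 1)])


class TestMantel:
    def test_thresholded_copy_detected(self, rng):
        n = 25
        r = rng.normal(size=(n, n))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 0.0)
        a = (r > 0.3).astype(float)
        stat, p = sociality.mantel_test(a, r, permutations=499, seed=1)
        assert stat > 0 and p < 0.05

    def test_relabeling_equivariance(self, rng):
        n = 15
        r = rng.normal(size=(n, n)); r = (r + r.T) / 2; np.fill_diagonal(r, 0)
        a = (rng.random((n, n)) < 0.3).astype(float)
        a = np.maximum(a, a.T); np.fill_diagonal(a, 0)
        stat1, _ = sociality.mantel_test(a, r, permutations=99, seed=2)
        perm = rng.permutation(n)
        stat2, _ = sociality.mantel_test(
            a[np.ix_(perm, perm)], r[np.ix_(perm, perm)], permutations=99, seed=2
        )
        assert stat1 == pytest.approx(stat2)

    def test_constant_matrix_rejected(self):
        a = np.zeros((5, 5))
        r = np.eye(5)
        with pytest.raises(ValueError, match="constant"):
            sociality.mantel_test(a, r)

    def test_statistic_matches_vegan(self, rng, tmp_path):
        """Cross-check the Mantel correlation against the R vegan package."""
        n = 12
        r = rng.normal(size=(n, n)); r = (r + r.T) / 2; np.fill_diagonal(r, 0)
        a = (rng.random((n, n)) < 0.4).astype(float)
        a = np.maximum(a, a.T); np.fill_diagonal(a, 0)
        stat, _ = sociality.mantel_test(a, r, permutations=99, seed=3)
        np.savetxt(tmp_path / "a.txt", a)
        np.savetxt(tmp_path / "r.txt", r)
        script = textwrap.dedent(
            f"""
            suppressMessages(library(vegan))
            a <- as.dist(as.matrix(read.table('{tmp_path}/a.txt')))
            r <- as.dist(as.matrix(read.table('{tmp_path}/r.txt')))
            m <- mantel(a, r, permutations = 99)
            cat(sprintf('%.10f', m$statistic))
            """
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=120
        )
        assert out.returncode == 0, out.stderr
        assert stat == pytest.approx(float(out.stdout.strip()), abs=1e-8)
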