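import itertools
import math

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plastovar.kmer import (DistanceMatrix, FrequencyMatrix, aaf_distance,
                            bootstrap_support, canonical, compare_k,
                            count_kmers, distance_matrix, nj_tree,
                            rf_distance, shared_proportion)
from plastovar.records import PlastomeRecord, revcomp

dna = st.text(alphabet="ACGT", min_size=5, max_size=60)


def table(record_id, seq, k=3, circular=False):
    return count_kmers(PlastomeRecord(id=record_id, sequence=seq,
                                      circular=circular), k)


class TestCounting:
    def test_linear_example(self):
        t = table("s", "ACGTA", k=3)
        assert t.counts == {"ACG": 2, "GTA": 1}

    def test_circular_wraps_origin(self):
        t = table("s", "ACGT", k=2, circular=True)
        assert t.counts == {"AC": 2, "CG": 1, "TA": 1}

    def test_k_exceeds_length(self):
        with pytest.raises(ValueError):
            table("s", "ACGTA", k=6)

    def test_n_windows_skipped(self):
        t = table("s", "ACGNACG", k=3)
        assert t.n_kmers_total == 2  # only the two N-free windows

    @settings(derandomize=True, max_examples=60)
    @given(dna)
    def test_revcomp_invariance(self, seq):
        a = table("a", seq, k=4) if len(seq) >= 4 else None
        b = table("b", revcomp(seq), k=4) if len(seq) >= 4 else None
        assert a.counts == b.counts

    @settings(derandomize=True, max_examples=60)
    @given(dna, st.booleans())
    def test_total_window_count(self, seq, circular):
        k = 4
        t = table("s", seq, k=k, circular=circular)
        assert t.n_kmers_total == (len(seq) if circular else len(seq) - k + 1)


class TestSharedProportion:
    def test_identical_tables(self):
        t = table("s", "ACGTACGTAC")
        assert shared_proportion(t, t) == 1.0

    def test_disjoint_sets(self):
        a = table("a", "AAACAAAC")
        b = table("b", "GGTGGTGG")
        assert shared_proportion(a, b) == 0.0

    def test_min_denominator(self):
        # A has 2 distinct canonical 3-mers, B has 3; intersection 1 -> 1/2
        a, b = table("a", "ACGTA"), table("b", "ACGCCCAAA")
        shared = len(set(a.counts) & set(b.counts))
        assert shared_proportion(a, b) == shared / min(len(a.counts), len(b.counts))

    def test_mismatched_k_rejected(self):
        with pytest.raises(ValueError):
            shared_proportion(table("a", "ACGTA", k=3), table("b", "ACGTA", k=4))


class TestAafDistance:
    def test_identical_zero(self):
        t = table("s", "ACGTACGTAC")
        assert aaf_distance(t, t) == (0.0, False)

    def test_closed_form(self):
        # proportion 1/2 at k=3 -> -ln(0.5)/3
        a, b = table("a", "ACGTA"), table("b", "ACGCCCAAA")
        d, flagged = aaf_distance(a, b)
        assert not flagged
        assert d == pytest.approx(-math.log(0.5) / 3, abs=1e-9)
        assert d == pytest.approx(0.23105, abs=1e-5)

    def test_zero_proportion_capped_or_error(self):
        a = table("a", "AAACAAAC")
        b = table("b", "GGTGGTGG")
        with pytest.raises(ValueError):
            aaf_distance(a, b)
        assert aaf_distance(a, b, cap=5.0) == (5.0, True)

    def test_symmetry(self):
        a, b = table("a", "ACGTACCA"), table("b", "ACGTGGTA")
        assert aaf_distance(a, b) == aaf_distance(b, a)


class TestDistanceMatrix:
    def test_identical_samples_all_zero(self):
        ts = [table(f"s{i}", "ACGTACGTAC") for i in range(3)]
        dm = distance_matrix(ts)
        assert np.all(dm.values == 0)

    def test_symmetric_equals_transpose(self, small_population):
        _cfg, records, _t, _b = small_population
        dm = distance_matrix([count_kmers(r, 21) for r in records[:4]])
        assert np.array_equal(dm.values, dm.values.T)
        assert np.all(np.diag(dm.values) == 0)

    def test_pair_error_names_pair(self):
        ts = [table("alpha", "AAACAAAC"), table("beta", "GGTGGTGG")]
        with pytest.raises(ValueError, match="alpha.*beta"):
            distance_matrix(ts)

    def test_hybrid_closer_to_own_parent(self, small_population):
        _cfg, records, truth, _b = small_population
        tabs = {r.id: count_kmers(r, 31) for r in records}
        for hybrid, parent in truth.hybrid_parents.items():
            other = "S4" if parent == "S1" else "S1"
            d_own, _ = aaf_distance(tabs[hybrid], tabs[parent])
            d_other, _ = aaf_distance(tabs[hybrid], tabs[other])
            assert d_own < d_other


def _five_leaf_topologies():
    """All 15 unrooted binary 5-leaf topologies as pairs of cherry sets."""
    leaves = list("ABCDE")
    tops = set()
    for c1 in itertools.combinations(leaves, 2):
        rest = [x for x in leaves if x not in c1]
        for c2 in itertools.combinations(rest, 2):
            tops.add(frozenset([frozenset(c1), frozenset(c2)]))
    return tops


def _fits_additively(top, d, labels):
    """Four-point check: each cherry's within-pair sum dominates every cross
    pairing with leaves outside it."""
    idx = {l: i for i, l in enumerate(labels)}
    for cherry in top:
        x, y = sorted(cherry)
        others = [l for l in labels if l not in cherry]
        for u, v in itertools.combinations(others, 2):
            lhs = d[idx[x], idx[y]] + d[idx[u], idx[v]]
            cross1 = d[idx[x], idx[u]] + d[idx[y], idx[v]]
            cross2 = d[idx[x], idx[v]] + d[idx[y], idx[u]]
            if not (lhs < cross1 - 1e-12 and lhs < cross2 - 1e-12):
                return False
    return True


class TestNeighborJoining:
    labels = list("ABCDE")
    # additive distances on tree ((A:2,B:3):1,(C:2,D:4):2,E:6)
    tree_newick = "((A:2,B:3):1,(C:2,D:4):2,E:6);"

    def _matrix(self):
        tree = dendropy.Tree.get(data=self.tree_newick, schema="newick")
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        n = len(self.labels)
        d = np.zeros((n, n))
        for i, a in enumerate(self.labels):
            for j, b in enumerate(self.labels):
                if i != j:
                    d[i, j] = pdm.distance(taxa[a], taxa[b])
        return d

    def test_recovers_additive_topology_against_enumeration_oracle(self):
        d = self._matrix()
        fitting = [t for t in _five_leaf_topologies()
                   if _fits_additively(t, d, self.labels)]
        assert len(fitting) == 1  # the generating topology, uniquely
        (expected,) = fitting
        assert expected == frozenset({frozenset("AB"), frozenset("CD")})
        tree = nj_tree(DistanceMatrix(labels=self.labels, values=d))
        truth = dendropy.Tree.get(data=self.tree_newick, schema="newick")
        assert rf_distance(tree, truth) == 0

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
        tree = nj_tree(DistanceMatrix(labels=["A", "B", "C"], values=d))
        bl = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert bl["A"] == pytest.approx(0.1)
        assert bl["B"] == pytest.approx(0.2)
        assert bl["C"] == pytest.approx(0.4)

    def test_tight_pair_joined_first(self):
        # near-star matrix with one tight pair (A,B)
        d = np.full((4, 4), 1.0)
        np.fill_diagonal(d, 0)
        d[0, 1] = d[1, 0] = 0.1
        tree = nj_tree(DistanceMatrix(labels=list("ABCD"), values=d))
        cherries = [frozenset(k.taxon.label for k in n.child_nodes())
                    for n in tree.preorder_node_iter()
                    if len(n.child_nodes()) == 2
                    and all(k.is_leaf() for k in n.child_nodes())]
        assert frozenset("AB") in cherries

    def test_fewer_than_three_rejected(self):
        d = np.array([[0, 1.0], [1.0, 0]])
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(labels=["A", "B"], values=d))

    def test_agrees_with_skbio_on_random_additive_matrices(self):
        import random

        import skbio
        for trial in range(5):
            tree = dendropy.simulate.treesim.birth_death_tree(
                birth_rate=1.0, death_rate=0.0, num_extant_tips=7,
                rng=random.Random(trial))
            for e in tree.edges():
                if e.length is None:
                    e.length = 0.5
            pdm = tree.phylogenetic_distance_matrix()
            taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
            labels = [t.label for t in taxa]
            d = np.array([[0 if a is b else pdm.distance(a, b) for b in taxa]
                          for a in taxa])
            mine = nj_tree(DistanceMatrix(labels=labels, values=d))
            theirs = dendropy.Tree.get(
                data=str(skbio.tree.nj(skbio.DistanceMatrix(d, ids=labels))),
                schema="newick")
            assert rf_distance(mine, theirs) == 0


class TestBootstrap:
    def _freq(self, small_population):
        _cfg, records, _t, _b = small_population
        core = [count_kmers(r, 31) for r in records if r.id.startswith("S")]
        return FrequencyMatrix.from_tables(core)

    def test_single_rep_support_binary(self, small_population):
        sup = bootstrap_support(self._freq(small_population), n_reps=1, seed=0)
        assert set(sup.values()) <= {0.0, 100.0}

    def test_fixed_seed_reproducible(self, small_population):
        f = self._freq(small_population)
        assert bootstrap_support(f, 20, seed=3) == bootstrap_support(f, 20, seed=3)

    def test_separated_clades_high_support(self, small_population):
        sup = bootstrap_support(self._freq(small_population), n_reps=100, seed=1)
        # splits are keyed by the side not containing S1
        assert sup[frozenset({"S3", "S4"})] >= 95
        assert sup[frozenset({"S5", "S6"})] >= 95


class TestCompareK:
    def test_congruent_ks_on_separated_clades(self, small_population):
        _cfg, records, _t, _b = small_population
        core = [r for r in records if r.id.startswith("S")]
        res = compare_k(core, ks=[25, 31, 35], cap=5.0)
        assert all(row["rf"] == 0 for row in res["congruence"])

    def test_single_k_no_pairs(self, small_population):
        _cfg, records, _t, _b = small_population
        res = compare_k(records[:4], ks=[21], cap=5.0)
        assert res["congruence"] == []

    def test_k_longer_than_sequence_rejected(self, tiny_record):
        with pytest.raises(ValueError):
            compare_k([tiny_record], ks=[25])


class TestMonotonicity:
    def test_distance_increases_with_branch_length(self):
        """Expected AAF distance grows with guide-tree branch length
        (rank correlation over branch-length levels)."""
        from plastovar.simulate import SimulationConfig, simulate_population
        means = []
        for bl in (0.05, 0.2, 0.6):
            dists = []
            for seed in range(5):
                cfg = SimulationConfig(seed=seed, n_samples=2,
                                       lsc_len=2000, ir_len=400, ssc_len=300,
                                       star_branch_length=bl)
                records, _t, _b = simulate_population(cfg)
                tabs = [count_kmers(r, 21) for r in records]
                dists.append(aaf_distance(tabs[0], tabs[1])[0])
            means.append(np.mean(dists))
        assert means[0] < means[1] < means[2]
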