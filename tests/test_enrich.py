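"""GO enrichment, redundancy filter, semantic distance, term clustering."""

from fractions import Fraction
from math import comb

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from chronode import (AnnotationSet, EnrichedTerm, fisher_enrichment,
                      reduce_redundancy, term_distance, distance_matrix,
                      cluster_terms, x_value, read_gmt)


def hypergeom_tail_oracle(k, M, K, n):
    """Exact rational upper-tail P(X >= k) for the 2x2 over-representation
    table, via binomial coefficients (independent of scipy)."""
    total = comb(M, n)
    return float(sum(Fraction(comb(K, i) * comb(M - K, n - i), total)
                     for i in range(k, min(K, n) + 1)))


def _term(term, overlap, module_size, annotated, p, sigma_bic=0.0, genes=None):
    return EnrichedTerm(term=term, overlap=overlap, module_size=module_size,
                        annotated=annotated, universe=1000, p_value=p,
                        member_genes=tuple(genes or [f"x{i}" for i in range(overlap)]),
                        sigma_bic=sigma_bic)


class TestFisherEnrichment:
    def _annotation(self, term_genes, universe):
        return AnnotationSet(term_genes=term_genes, universe=universe)

    def test_p_matches_exact_tail_oracle(self):
        rng = np.random.default_rng(0)
        universe = [f"g{i}" for i in range(60)]
        for trial in range(30):
            K = int(rng.integers(3, 30))
            n = int(rng.integers(3, 30))
            ann_genes = set(rng.choice(universe, size=K, replace=False))
            module = set(rng.choice(universe, size=n, replace=False))
            k = len(ann_genes & module)
            if k == 0:
                continue
            ann = self._annotation({"T": ann_genes}, universe)
            res = fisher_enrichment(module, ann, p_cutoff=1.0)
            assert res[0].p_value == pytest.approx(
                hypergeom_tail_oracle(k, 60, K, n), abs=1e-12)

    def test_term_without_module_genes_excluded(self):
        universe = [f"g{i}" for i in range(20)]
        ann = self._annotation({"T": {"g10", "g11"}}, universe)
        assert fisher_enrichment({"g0", "g1"}, ann, p_cutoff=1.0) == []

    def test_maximal_enrichment_is_significant(self):
        universe = [f"g{i}" for i in range(100)]
        term_set = set(universe[:10])
        ann = self._annotation({"T": term_set}, universe)
        res = fisher_enrichment(term_set, ann, p_cutoff=0.01)
        assert len(res) == 1 and res[0].p_value <= 0.01

    def test_kme_filter_restricts_module(self):
        universe = [f"g{i}" for i in range(50)]
        ann = self._annotation({"T": set(universe[:5])}, universe)
        kme = pd.Series(0.5, index=universe)
        kme[universe[:3]] = 0.9
        res = fisher_enrichment(set(universe[:10]), ann, p_cutoff=1.0, kme=kme)
        assert res[0].module_size == 3

    def test_sigma_bic_summed_from_gene_scores(self):
        universe = [f"g{i}" for i in range(30)]
        ann = self._annotation({"T": {"g0", "g1", "g2"}}, universe)
        scores = pd.Series(np.arange(30.0), index=universe)
        res = fisher_enrichment(set(universe[:5]), ann, p_cutoff=1.0,
                                gene_scores=scores)
        assert res[0].sigma_bic == pytest.approx(0.0 + 1.0 + 2.0)


class TestReduceRedundancy:
    def test_three_criteria(self):
        # overlap 5 of module 200, background 400 -> kept by criterion 1
        t1 = _term("a", 5, 200, 400, 1e-3)
        # overlap 4 of module 20 (20% >= 15%) -> kept by criterion 2
        t2 = _term("b", 4, 20, 400, 1e-3)
        # overlap 4, module 200 (2%), background 400 (1%) -> dropped
        t3 = _term("c", 4, 200, 400, 1e-3)
        # overlap 3, background 10 (30% >= 15%) -> kept by criterion 3
        t4 = _term("d", 3, 200, 10, 1e-3)
        kept = reduce_redundancy([t1, t2, t3, t4])
        assert [t.term for t in kept] == ["a", "b", "d"]

    def test_pure_filter_subset_and_idempotent(self):
        terms = [_term(chr(97 + i), i, 100, 50, 1e-3) for i in range(8)]
        once = reduce_redundancy(terms)
        assert set(t.term for t in once) <= set(t.term for t in terms)
        assert reduce_redundancy(once) == once


class TestXValue:
    def test_worked_example(self):
        assert x_value(1e-3, 100.0) == pytest.approx(300.0)

    def test_monotonicity(self):
        assert x_value(1e-4, 50.0) > x_value(1e-3, 50.0)
        assert x_value(1e-3, 200.0) > x_value(1e-3, 100.0)


class TestTermDistance:
    def _annotation_with_ontology(self):
        g = nx.DiGraph()  # edges child -> parent
        g.add_edges_from([("t1", "root"), ("t2", "root"), ("t3", "t1")])
        universe = [f"g{i}" for i in range(10)]
        return AnnotationSet(term_genes={"t1": set(universe[:4]),
                                         "t2": set(universe[4:8]),
                                         "t3": set(universe[:3])},
                             universe=universe, ontology=g)

    def test_self_distance_zero(self):
        ann = self._annotation_with_ontology()
        t = _term("t1", 4, 10, 4, 1e-3, genes=[f"g{i}" for i in range(4)])
        assert term_distance(t, t, ann) == 0.0

    def test_disjoint_terms_distance_one(self):
        g = nx.DiGraph()
        g.add_node("t1"); g.add_node("t2")
        ann = AnnotationSet(term_genes={}, universe={"a", "b"}, ontology=g)
        ta = _term("t1", 1, 10, 5, 1e-3, genes=["a"])
        tb = _term("t2", 1, 10, 5, 1e-3, genes=["b"])
        assert term_distance(ta, tb, ann) == pytest.approx(1.0)

    def test_symmetry(self):
        ann = self._annotation_with_ontology()
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(10)]
        for _ in range(100):
            ga = list(rng.choice(genes, size=3, replace=False))
            gb = list(rng.choice(genes, size=3, replace=False))
            ta = _term(rng.choice(["t1", "t2", "t3"]), 3, 10, 4, 1e-3, genes=ga)
            tb = _term(rng.choice(["t1", "t2", "t3"]), 3, 10, 4, 1e-3, genes=gb)
            assert term_distance(ta, tb, ann) == pytest.approx(
                term_distance(tb, ta, ann), abs=1e-12)

    def test_cyclic_ontology_rejected(self):
        g = nx.DiGraph()
        g.add_edges_from([("a", "b"), ("b", "a")])
        with pytest.raises(ValueError, match="acyclic"):
            AnnotationSet(term_genes={}, universe=set(), ontology=g)


def dbscan_oracle(D, eps, min_pts):
    """Brute-force density-reachability expansion (independent of sklearn)."""
    n = D.shape[0]
    neighbors = [set(np.where(D[i] <= eps)[0]) for i in range(n)]  # self-inclusive
    core = [i for i in range(n) if len(neighbors[i]) >= min_pts]
    labels = [-1] * n
    cid = 0
    for c in core:
        if labels[c] != -1:
            continue
        frontier = [c]
        labels[c] = cid
        while frontier:
            p = frontier.pop()
            if len(neighbors[p]) >= min_pts:
                for q in neighbors[p]:
                    if labels[q] == -1:
                        labels[q] = cid
                        frontier.append(q)
        cid += 1
    return labels


class TestClusterTerms:
    def test_single_term_is_its_own_representative(self):
        t = _term("only", 5, 20, 10, 1e-4, sigma_bic=10.0)
        clusters = cluster_terms([t], np.zeros((1, 1)))
        assert len(clusters) == 1
        assert clusters[0].representative.term == "only"

    def test_xvalue_beats_smaller_p_with_less_bic(self):
        a = _term("a", 5, 20, 10, 1e-3, sigma_bic=100.0)  # x = 300
        b = _term("b", 5, 20, 10, 1e-4, sigma_bic=50.0)   # x = 200
        D = np.array([[0.0, 0.1], [0.1, 0.0]])
        clusters = cluster_terms([a, b], D, eps=0.5, min_pts=2)
        assert len(clusters) == 1
        assert clusters[0].representative.term == "a"

    def test_membership_matches_reachability_oracle(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(size=(30, 2))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        eps, min_pts = 0.25, 3
        terms = [_term(f"t{i}", 3, 10, 5, 1e-3) for i in range(30)]
        clusters = cluster_terms(terms, D, eps=eps, min_pts=min_pts)
        oracle = dbscan_oracle(D, eps, min_pts)
        mine = {}
        for cl in clusters:
            for t in cl.members:
                mine[int(t.term[1:])] = cl.cluster_id
        # compare partitions of points the oracle assigns to clusters
        oracle_groups = {}
        for i, lab in enumerate(oracle):
            if lab >= 0:
                oracle_groups.setdefault(lab, set()).add(i)
        mine_groups = {}
        for i, lab in mine.items():
            mine_groups.setdefault(lab, set()).add(i)
        # noise points become singletons in ours; drop them for comparison
        mine_nonsingleton = {frozenset(g) for g in mine_groups.values() if len(g) > 1}
        oracle_nonsingleton = {frozenset(g) for g in oracle_groups.values() if len(g) > 1}
        assert mine_nonsingleton == oracle_nonsingleton

    def test_two_planted_clumps_give_two_representatives(self):
        """Two clumps of near-duplicate terms yield exactly two clusters at
        the default radius."""
        rng = np.random.default_rng(3)
        universe = [f"g{i}" for i in range(40)]
        clump_a = set(universe[:10])
        clump_b = set(universe[20:30])
        terms, term_genes = [], {}
        for i in range(4):
            ga = set(rng.choice(sorted(clump_a), 8, replace=False))
            gb = set(rng.choice(sorted(clump_b), 8, replace=False))
            terms.append(_term(f"a{i}", len(ga), 20, 10, 1e-3, sigma_bic=10 + i,
                               genes=sorted(ga)))
            terms.append(_term(f"b{i}", len(gb), 20, 10, 1e-3, sigma_bic=20 + i,
                               genes=sorted(gb)))
            term_genes[f"a{i}"] = ga
            term_genes[f"b{i}"] = gb
        ann = AnnotationSet(term_genes=term_genes, universe=universe)
        D = distance_matrix(terms, ann)
        clusters = cluster_terms(terms, D)  # default eps/min_pts
        reps = sorted(cl.representative.term for cl in clusters)
        assert len(clusters) == 2
        assert reps == ["a3", "b3"]  # highest sigma_bic at equal p wins


class TestGmt:
    def test_round_trip(self, tmp_path):
        path = tmp_path / "ann.gmt"
        path.write_text("T1\tfirst term\tg1\tg2\tg3\nT2\tsecond\tg2\tg4\n")
        genes, names = read_gmt(path)
        assert genes == {"T1": {"g1", "g2", "g3"}, "T2": {"g2", "g4"}}
        assert names["T2"] == "second"

    def test_malformed_line_rejected(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("T1\tonly-description\n")
        with pytest.raises(ValueError, match="malformed"):
            read_gmt(path)
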