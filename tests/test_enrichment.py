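"""Hypergeometric over-representation, correction, and the functional map."""

import io
import random

import numpy as np
import pytest

from interolognet.enrichment import (
    AnnotationSet,
    adjust,
    build_functional_map,
    cohens_kappa,
    enrich,
    jaccard,
    write_enrichment_tsv,
)
from interolognet.synthetic import generate_annotation

import oracles


def ann_from(term_sets, universe):
    records = [
        (protein, term, f"name {term}", "biological_process")
        for term, proteins in term_sets.items()
        for protein in proteins
    ]
    return AnnotationSet.from_records(records, universe=universe)


class TestEnrich:
    def test_textbook_overlap(self):
        # N=10, K=4, n=5, k=4: exactly C(6,1)/C(10,5) = 6/252
        universe = [f"P{i}" for i in range(10)]
        ann = ann_from({"GO:1": universe[:4]}, universe)
        (r,) = enrich(universe[:4] + ["P9"], ann)
        assert r.k == 4 and r.K == 4 and r.n == 5 and r.N == 10
        assert r.p == pytest.approx(6 / 252, rel=1e-12)

    def test_term_annotating_everything_has_p_one(self):
        universe = [f"P{i}" for i in range(8)]
        ann = ann_from({"GO:1": universe}, universe)
        (r,) = enrich(universe[:3], ann)
        assert r.p == pytest.approx(1.0)

    def test_zero_overlap_terms_absent(self):
        universe = [f"P{i}" for i in range(8)]
        ann = ann_from({"GO:1": universe[:2], "GO:2": universe[6:]}, universe)
        results = enrich(universe[:2], ann)
        assert [r.term_id for r in results] == ["GO:1"]

    def test_members_outside_universe_dropped(self):
        universe = [f"P{i}" for i in range(6)]
        ann = ann_from({"GO:1": universe[:3]}, universe)
        (r,) = enrich(universe[:3] + ["ALIEN"], ann)
        assert r.n == 3

    def test_empty_universe_is_error(self):
        with pytest.raises(ValueError):
            enrich(["P1"], AnnotationSet())

    def test_matches_exhaustive_enumeration_oracle(self):
        rng = random.Random(13)
        for _ in range(25):
            N = rng.randint(4, 12)
            universe = [f"P{i}" for i in range(N)]
            K = rng.randint(1, N)
            n = rng.randint(1, N)
            ann = ann_from({"GO:X": universe[:K]}, universe)
            members = rng.sample(universe, n)
            results = enrich(members, ann)
            k = len(set(members) & set(universe[:K]))
            if k == 0:
                assert results == []
                continue
            expected = oracles.hypergeom_upper_tail_by_enumeration(N, K, n, k)
            assert results[0].p == pytest.approx(float(expected), abs=1e-12)

    def test_sorted_by_p(self):
        universe = [f"P{i}" for i in range(12)]
        ann = ann_from({"GO:weak": universe[:8], "GO:strong": universe[:3]}, universe)
        results = enrich(universe[:3], ann)
        assert [r.term_id for r in results] == ["GO:strong", "GO:weak"]


class TestAdjust:
    def res(self, p, term="GO:1"):
        from interolognet.enrichment import EnrichmentResult

        return EnrichmentResult(term, term, 1, 1, 1, 10, p)

    def test_single_test_bh_equals_raw(self):
        (r,) = adjust([self.res(0.03)])
        assert r.p_adj == pytest.approx(0.03)

    def test_bh_step_up_by_hand(self):
        # step-up: 0.03*3/3, min trailing for 0.02*3/2 and 0.01*3/1 -> all 0.03
        results = adjust([self.res(p, f"GO:{i}") for i, p in enumerate([0.01, 0.02, 0.03])])
        assert [r.p_adj for r in results] == pytest.approx([0.03, 0.03, 0.03])

    def test_bonferroni_caps_at_one(self):
        results = adjust([self.res(p, f"GO:{i}") for i, p in enumerate([0.5, 0.9])],
                         method="bonferroni")
        assert [r.p_adj for r in results] == pytest.approx([1.0, 1.0])

    def test_monotone_in_p(self):
        rng = random.Random(3)
        ps = sorted(rng.random() for _ in range(20))
        adjusted = adjust([self.res(p, f"GO:{i}") for i, p in enumerate(ps)])
        q = [r.p_adj for r in adjusted]
        assert all(a <= b + 1e-15 for a, b in zip(q, q[1:]))
        assert all(r.p_adj >= r.p for r in adjusted)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            adjust([self.res(0.1)], method="holmes")


class TestOverlapStatistics:
    def test_identical_sets_have_kappa_one(self):
        domain = frozenset("ABCDEFGH")
        s = frozenset("ABC")
        assert cohens_kappa(s, s, domain) == pytest.approx(1.0)

    def test_disjoint_sets_have_nonpositive_kappa(self):
        domain = frozenset("ABCDEFGH")
        assert cohens_kappa(frozenset("ABC"), frozenset("DEF"), domain) <= 0.0

    def test_kappa_known_value(self):
        # domain of 10; a=2 both, b=1, c=1, d=6 -> po=0.8, pe=0.58
        domain = frozenset(f"P{i}" for i in range(10))
        s1 = frozenset(["P0", "P1", "P2"])
        s2 = frozenset(["P0", "P1", "P3"])
        expected = (0.8 - 0.58) / (1 - 0.58)
        assert cohens_kappa(s1, s2, domain) == pytest.approx(expected)

    def test_jaccard(self):
        assert jaccard(frozenset("AB"), frozenset("BC")) == pytest.approx(1 / 3)
        assert jaccard(frozenset(), frozenset()) == 0.0


class TestFunctionalMap:
    def setup_results(self):
        universe = [f"P{i}" for i in range(40)]
        members = universe[:20]
        term_sets = {
            "GO:A": universe[:10],
            "GO:B": universe[:10],          # identical to A -> kappa 1
            "GO:C": universe[10:20],        # disjoint from A within members
            "GO:small": universe[:7],       # overlap below min_proteins
        }
        ann = ann_from(term_sets, universe)
        return adjust(enrich(members, ann)), ann, members

    def test_edges_and_filters(self):
        results, ann, members = self.setup_results()
        fmap = build_functional_map(results, ann, member_set=members,
                                    min_proteins=8, alpha=1.0)
        assert set(fmap.terms) == {"GO:A", "GO:B", "GO:C"}
        assert fmap.graph.has_edge("GO:A", "GO:B")
        assert not fmap.graph.has_edge("GO:A", "GO:C")

    def test_min_proteins_excludes_significant_small_term(self):
        universe = [f"P{i}" for i in range(100)]
        ann = ann_from({"GO:tiny": universe[:7]}, universe)
        results = adjust(enrich(universe[:7], ann))
        assert results[0].p_adj < 1e-6  # highly significant...
        fmap = build_functional_map(results, ann, member_set=universe[:7])
        assert fmap.terms == []  # ...but fewer than 8 members from the set

    def test_order_invariance(self):
        results, ann, members = self.setup_results()
        forward = build_functional_map(results, ann, member_set=members, alpha=1.0)
        backward = build_functional_map(list(reversed(results)), ann,
                                        member_set=members, alpha=1.0)
        assert set(forward.graph.edges) == set(backward.graph.edges)
        assert forward.groups() == backward.groups()

    def test_group_label_is_most_significant_member(self):
        results, ann, members = self.setup_results()
        fmap = build_functional_map(results, ann, member_set=members, alpha=1.0)
        for label, terms in fmap.groups().items():
            best = min(terms, key=lambda t: fmap.graph.nodes[t]["result"].p_adj)
            assert label == fmap.graph.nodes[best]["result"].term_name

    def test_requires_adjusted_results(self):
        universe = [f"P{i}" for i in range(10)]
        ann = ann_from({"GO:1": universe[:5]}, universe)
        with pytest.raises(ValueError, match="p_adj"):
            build_functional_map(enrich(universe[:5], ann), ann)


class TestPlantedTermRecovery:
    def test_planted_term_ranks_first_in_most_seeded_runs(self):
        universe = [f"H{i:03d}" for i in range(300)]
        machine = universe[:60]
        hits = 0
        n_runs = 100
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            rows, planted = generate_annotation(
                universe, machine, n_terms=15, planted_term_effect=0.6,
                background_rate=0.05, rng=rng,
            )
            ann = AnnotationSet.from_records(rows, universe=universe)
            results = enrich(machine, ann)
            if results and results[0].term_id == planted:
                hits += 1
        assert hits >= 95


class TestIO:
    def test_tsv_and_gaf_readers(self, tmp_path):
        tsv = "protein\tterm_id\tterm_name\tnamespace\nP1\tGO:1\tgrowth\tbiological_process\n"
        ann = AnnotationSet.from_tsv(io.StringIO(tsv))
        assert ann.terms["GO:1"].proteins == {"P1"}
        gaf = (
            "!gaf-version: 2.1\n"
            "UniProtKB\tP07900\tHSP90AA1\t\tGO:0006457\tPMID:1\tIDA\t\tP\t\t\t"
            "protein\ttaxon:9606\t20110101\tUniProt\n"
        )
        ann = AnnotationSet.from_gaf(io.StringIO(gaf))
        assert ann.terms["GO:0006457"].proteins == {"HSP90AA1"}

    def test_namespace_filter(self):
        records = [("P1", "GO:1", "x", "biological_process"),
                   ("P1", "GO:2", "y", "molecular_function")]
        ann = AnnotationSet.from_records(records, namespace="biological_process")
        assert set(ann.terms) == {"GO:1"}

    def test_with_universe_restricts(self):
        records = [("P1", "GO:1", "x", ""), ("P2", "GO:1", "x", "")]
        ann = AnnotationSet.from_records(records).with_universe(["P1", "P3"])
        assert ann.universe == {"P1", "P3"}
        assert ann.terms["GO:1"].proteins == {"P1"}

    def test_write_enrichment_tsv(self, tmp_path):
        universe = [f"P{i}" for i in range(10)]
        ann = ann_from({"GO:1": universe[:4]}, universe)
        results = adjust(enrich(universe[:4], ann))
        path = tmp_path / "enrichment.tsv"
        write_enrichment_tsv(results, path)
        lines = path.read_text().splitlines()
        assert lines[0].startswith("term_id\t")
        assert lines[1].startswith("GO:1\t")
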