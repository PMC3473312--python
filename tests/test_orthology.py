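"""RBH classification: best-hit ranking, reciprocity, the category
partition, coverage curation, and planted-truth recovery."""

from dataclasses import dataclass

import numpy as np
import pytest

from orthoprof.orthology import (
    CategoryAssignment, best_hits, category_counts, category_label,
    classify_proteins, curate_coverage, enumerate_categories,
    pair_specific_proteins, reciprocal_best_hits,
)


@dataclass
class FakeHit:
    query: str
    subject: str
    evalue: float
    bits: float
    qstart: int = 1
    qend: int = 100
    qlen: int = 100

    @property
    def query_coverage(self):
        return (self.qend - self.qstart + 1) / self.qlen


ORGS = {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "c1": "C"}


class TestBestHits:
    def test_single_hit_is_best(self):
        best = best_hits([FakeHit("a1", "b1", 1e-20, 80)], 1e-10, ORGS)
        assert best[("a1", "B")].subject == "b1"

    def test_above_cutoff_discarded(self):
        assert best_hits([FakeHit("a1", "b1", 1e-5, 30)], 1e-10, ORGS) == {}

    def test_tie_on_evalue_broken_by_bits_then_subject(self):
        hits = [FakeHit("a1", "b1", 1e-20, 45), FakeHit("a1", "b2", 1e-20, 50)]
        best = best_hits(hits, 1e-10, ORGS)
        assert best[("a1", "B")].subject == "b2"
        hits = [FakeHit("a1", "b2", 1e-20, 50), FakeHit("a1", "b1", 1e-20, 50)]
        assert best_hits(hits, 1e-10, ORGS)[("a1", "B")].subject == "b1"


class TestReciprocity:
    def test_mutual_best_forms_pair(self):
        best = best_hits(
            [FakeHit("a1", "b1", 1e-20, 80), FakeHit("b1", "a1", 1e-20, 80)],
            1e-10, ORGS)
        assert reciprocal_best_hits(best, ORGS) == {frozenset({"a1", "b1"})}

    def test_one_sided_best_is_no_pair(self):
        best = best_hits(
            [FakeHit("a1", "b1", 1e-20, 80), FakeHit("b1", "a2", 1e-30, 90)],
            1e-10, ORGS)
        assert reciprocal_best_hits(best, ORGS) == set()

    def test_pair_relation_symmetric_on_fixture(self, standard_best, org_of):
        pairs = reciprocal_best_hits(standard_best, org_of)
        for pair in pairs:
            p, q = sorted(pair)
            assert standard_best[(p, org_of[q])].subject == q
            assert standard_best[(q, org_of[p])].subject == p


class TestClassification:
    def test_isolated_protein_gets_singleton_category(self):
        assignments = classify_proteins(set(), ORGS)
        by_id = {a.protein_id: a for a in assignments}
        assert by_id["c1"].category == frozenset({"C"})

    def test_categories_partition_the_universe(self, standard_assignments, org_of):
        assert len(standard_assignments) == len(org_of)
        assert {a.protein_id for a in standard_assignments} == set(org_of)

    def test_category_always_contains_own_organism(self, standard_assignments):
        for a in standard_assignments:
            assert a.organism in a.category

    def test_planted_categories_recovered(self, standard_dataset, standard_assignments):
        truth = standard_dataset.truth.set_index("protein_id")
        correct = sum(
            a.category == frozenset(truth.loc[a.protein_id, "pattern"].split("+"))
            for a in standard_assignments
        )
        assert correct / len(standard_assignments) >= 0.99

    def test_relaxing_cutoff_never_shrinks_categories(self):
        rng = np.random.default_rng(21)
        ids = list(ORGS)
        hits = []
        for q in ids:
            for s in ids:
                if ORGS[q] != ORGS[s]:
                    hits.append(FakeHit(q, s, float(10.0 ** -int(rng.integers(0, 40))), float(rng.integers(20, 90))))
        for strict, loose in [(1e-30, 1e-20), (1e-20, 1e-5), (1e-10, 1.0)]:
            cat_strict = {a.protein_id: a.category for a in classify_proteins(
                reciprocal_best_hits(best_hits(hits, strict, ORGS), ORGS), ORGS)}
            cat_loose = {a.protein_id: a.category for a in classify_proteins(
                reciprocal_best_hits(best_hits(hits, loose, ORGS), ORGS), ORGS)}
            for pid in ids:
                assert cat_strict[pid] <= cat_loose[pid]


class TestCategoryEnumeration:
    @pytest.mark.parametrize("k,expected", [(1, 1), (2, 3), (4, 15), (5, 31)])
    def test_counts(self, k, expected):
        orgs = [f"org{i}" for i in range(k)]
        cats = enumerate_categories(orgs)
        assert len(cats) == expected
        assert len(set(cats)) == expected

    def test_ordered_by_size_then_name(self):
        cats = enumerate_categories(["b", "a", "c"])
        labels = [category_label(c) for c in cats]
        assert labels == ["a", "b", "c", "a+b", "a+c", "b+c", "a+b+c"]

    def test_zero_organisms_rejected(self):
        with pytest.raises(ValueError):
            enumerate_categories([])


class TestCuration:
    def _assignment(self, pid="a1", org="A", cat=("A", "B"), partner="b1"):
        return CategoryAssignment(pid, org, frozenset(cat), {"B": partner})

    def test_zero_threshold_is_vacuous(self):
        a = self._assignment()
        best = {("a1", "B"): FakeHit("a1", "b1", 1e-20, 80, qstart=1, qend=10)}
        kept, rejected = curate_coverage([a], best, min_cov=0.0, organisms=["A", "B"])
        assert kept == [a] and len(rejected) == 0

    def test_low_coverage_protein_rejected(self):
        a = self._assignment()
        best = {("a1", "B"): FakeHit("a1", "b1", 1e-20, 80, qstart=1, qend=10)}  # 10%
        kept, rejected = curate_coverage([a], best, min_cov=0.20, organisms=["A", "B"])
        assert kept == [] and list(rejected["protein_id"]) == ["a1"]

    def test_scope_restricts_to_pair_categories(self):
        triple = CategoryAssignment("a1", "A", frozenset({"A", "B", "C"}),
                                    {"B": "b1", "C": "c1"})
        best = {("a1", "B"): FakeHit("a1", "b1", 1e-20, 80, qstart=1, qend=10),
                ("a1", "C"): FakeHit("a1", "c1", 1e-20, 80, qstart=1, qend=10)}
        kept, rejected = curate_coverage([triple], best, min_cov=0.20,
                                         scope="pairs", organisms=["A", "B", "C"])
        assert kept == [triple]
        kept, rejected = curate_coverage([triple], best, min_cov=0.20,
                                         scope="all", organisms=["A", "B", "C"])
        assert list(rejected["protein_id"]) == ["a1"]

    def test_unknown_scope_category_rejected(self):
        with pytest.raises(ValueError):
            curate_coverage([], {}, scope=[frozenset({"A", "Z"})], organisms=["A", "B"])

    def test_exactly_planted_fragments_rejected(self, standard_dataset,
                                                standard_assignments, standard_best):
        kept, rejected = curate_coverage(
            standard_assignments, standard_best, min_cov=0.20,
            organisms=standard_dataset.config.organisms)
        truth = standard_dataset.truth
        planted = set(truth.loc[truth["is_fragment"], "protein_id"])
        assert set(rejected["protein_id"]) == planted
        assert len(kept) == len(standard_assignments) - len(planted)


class TestCountsAndExtraction:
    def test_empty_assignments_give_zero_table(self):
        counts = category_counts([], ["A", "B"])
        assert counts.shape == (3, 2)
        assert counts.to_numpy().sum() == 0

    def test_grand_total_conserved(self, standard_assignments, standard_dataset):
        counts = category_counts(standard_assignments, standard_dataset.config.organisms)
        assert counts.to_numpy().sum() == len(standard_assignments)

    def test_all_fifteen_categories_populated(self, standard_assignments, standard_dataset):
        counts = category_counts(standard_assignments, standard_dataset.config.organisms)
        assert len(counts) == 15
        assert (counts.sum(axis=1) > 0).all()

    def test_exact_category_match_semantics(self):
        a_abc = CategoryAssignment("p1", "A", frozenset({"A", "B", "C"}),
                                   {"B": "q", "C": "r"})
        a_ab = CategoryAssignment("p2", "A", frozenset({"A", "B"}), {"B": "s"})
        got = pair_specific_proteins([a_abc, a_ab], {"A", "B"})
        assert got == ["p2"]

    def test_singleton_query_returns_lineage_specific(self):
        a1 = CategoryAssignment("p1", "A", frozenset({"A"}), {})
        a2 = CategoryAssignment("p2", "A", frozenset({"A", "B"}), {"B": "x"})
        assert pair_specific_proteins([a1, a2], {"A"}) == ["p1"]

    def test_planted_pair_family_members_extracted(self, standard_dataset,
                                                   standard_assignments):
        truth = standard_dataset.truth
        orgs = sorted(standard_dataset.config.organisms)[:2]
        label = "+".join(orgs)
        expected = set(truth.loc[(truth["pattern"] == label)
                                 & (truth["family"] != "decoy"), "protein_id"])
        got = set(pair_specific_proteins(standard_assignments, orgs))
        assert got == expected
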