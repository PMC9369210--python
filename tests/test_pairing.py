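"""The three pairing strategies, their tie rules and matching oracles."""

import numpy as np
import pytest

from complexmsa import pair_genomic, pair_phylogeny, pair_string

from conftest import make_annotated
from oracles import lexmin_maximal_matching, min_total_matchings, rank_match_bruteforce


class TestPairGenomic:
    def test_within_window_paired_with_dgene(self):
        a = make_annotated("A", [{"acc": "a1", "gene": ("g1", 5)}])
        b = make_annotated("B", [{"acc": "b1", "gene": ("g1", 7)}])
        out = pair_genomic(a, b)
        assert [(r.accession_A, r.accession_B) for r in out] == [("a1", "b1")]
        assert out[0].detail["dgene"] == 2
        assert out[0].stage == "genomic"

    @pytest.mark.parametrize("idx_b", [5, 26])  # distance 0 and 21
    def test_outside_window_not_paired(self, idx_b):
        a = make_annotated("A", [{"acc": "a1", "gene": ("g1", 5)}])
        b = make_annotated("B", [{"acc": "b1", "gene": ("g1", idx_b)}])
        assert pair_genomic(a, b) == []

    def test_different_genomes_not_paired(self):
        a = make_annotated("A", [{"acc": "a1", "gene": ("g1", 5)}])
        b = make_annotated("B", [{"acc": "b1", "gene": ("g2", 6)}])
        assert pair_genomic(a, b) == []

    def test_closest_competitor_wins(self):
        # two A hits (indices 5, 9) compete for one B hit at 6
        a = make_annotated("A", [
            {"acc": "a5", "gene": ("g1", 5)},
            {"acc": "a9", "gene": ("g1", 9)},
        ])
        b = make_annotated("B", [{"acc": "b6", "gene": ("g1", 6)}])
        out = pair_genomic(a, b)
        assert [(r.accession_A, r.accession_B) for r in out] == [("a5", "b6")]
        assert out[0].detail["dgene"] == 1
        # agrees with exhaustive min-total-distance enumeration
        cands = [((1, "a5", "b6"), "a5", "b6"), ((3, "a9", "b6"), "a9", "b6")]
        best = min_total_matchings(cands)
        assert len(best) == 1
        assert [(a_, b_) for _, a_, b_ in best[0]] == [("a5", "b6")]

    def test_unannotated_hits_skipped(self):
        a = make_annotated("A", [{"acc": "a1"}])
        b = make_annotated("B", [{"acc": "b1", "gene": ("g1", 3)}])
        assert pair_genomic(a, b) == []

    def test_one_to_one_and_window_invariants(self, annotated):
        aA, aB = annotated
        out = pair_genomic(aA, aB)
        accs_a = [r.accession_A for r in out]
        accs_b = [r.accession_B for r in out]
        assert len(accs_a) == len(set(accs_a))
        assert len(accs_b) == len(set(accs_b))
        for r in out:
            assert 1 <= r.detail["dgene"] <= 20
            ga = aA.gene[r.accession_A]
            gb = aB.gene[r.accession_B]
            assert ga.genome_id == gb.genome_id
            assert abs(ga.gene_index - gb.gene_index) == r.detail["dgene"]

    def test_row_order_does_not_matter(self, family):
        from complexmsa import MonomerMSA, annotate

        shuffled = MonomerMSA(
            chain_label="A",
            query=family.msaA.query,
            rows=[family.msaA.query] + family.msaA.hits[::-1],
        )
        aB = annotate(family.msaB, family.bundle)
        out1 = pair_genomic(annotate(family.msaA, family.bundle), aB)
        out2 = pair_genomic(annotate(shuffled, family.bundle), aB)
        key = lambda r: (r.accession_A, r.accession_B)
        assert sorted(map(key, out1)) == sorted(map(key, out2))


def _random_genomic_instance(rng, n_genomes=2, max_per_side=3):
    """A random small instance (<= 6 candidates per genome)."""
    specs_a, specs_b = [], []
    k = 0
    for g in range(n_genomes):
        for i in range(rng.integers(1, max_per_side + 1)):
            specs_a.append({"acc": f"a{k}", "gene": (f"g{g}", int(rng.integers(0, 30))),
                            "n_mut": int(rng.integers(0, 4))})
            k += 1
        for i in range(rng.integers(1, max_per_side + 1)):
            specs_b.append({"acc": f"b{k}", "gene": (f"g{g}", int(rng.integers(0, 30))),
                            "n_mut": int(rng.integers(0, 4))})
            k += 1
    return make_annotated("A", specs_a), make_annotated("B", specs_b)


class TestGenomicMatchingOracle:
    def test_greedy_equals_exhaustive_lexmin(self):
        """Greedy resolution picks, among all maximal one-to-one matchings,
        the lexicographically smallest key sequence — checked exhaustively
        on 40 random small instances."""
        rng = np.random.default_rng(1234)
        for _ in range(40):
            a, b = _random_genomic_instance(rng)
            out = pair_genomic(a, b)
            cands = []
            for ra in a.hits:
                la = a.gene.get(ra.accession)
                for rb in b.hits:
                    lb = b.gene.get(rb.accession)
                    if la and lb and la.genome_id == lb.genome_id:
                        d = abs(la.gene_index - lb.gene_index)
                        if 1 <= d <= 20:
                            key = (d, -(ra.identity_to_query + rb.identity_to_query) / 2,
                                   ra.accession, rb.accession)
                            cands.append((key, ra.accession, rb.accession))
            oracle = lexmin_maximal_matching(cands)
            assert [(r.accession_A, r.accession_B) for r in out] == [
                (a_, b_) for _, a_, b_ in oracle
            ]


class TestPairPhylogeny:
    def test_rank_matching_truncates_to_min(self):
        a = make_annotated("A", [
            {"acc": "aHigh", "taxid": 7, "n_mut": 1},
            {"acc": "aLow", "taxid": 7, "n_mut": 3},
        ], L=20)
        b = make_annotated("B", [
            {"acc": "bTop", "taxid": 7, "n_mut": 0},
            {"acc": "bMid", "taxid": 7, "n_mut": 2},
            {"acc": "bBot", "taxid": 7, "n_mut": 5},
        ], L=20)
        out = pair_phylogeny(a, b)
        assert [(r.accession_A, r.accession_B) for r in out] == [
            ("aHigh", "bTop"), ("aLow", "bMid")
        ]
        assert out[0].detail == {"taxid": 7, "rank": 1}
        assert out[1].detail == {"taxid": 7, "rank": 2}

    def test_taxid_on_one_side_only_contributes_nothing(self):
        a = make_annotated("A", [{"acc": "a1", "taxid": 7}])
        b = make_annotated("B", [{"acc": "b1", "taxid": 8}])
        assert pair_phylogeny(a, b) == []

    def test_single_hit_each_side(self):
        a = make_annotated("A", [{"acc": "a1", "taxid": 7}])
        b = make_annotated("B", [{"acc": "b1", "taxid": 7}])
        out = pair_phylogeny(a, b)
        assert [(r.accession_A, r.accession_B) for r in out] == [("a1", "b1")]

    def test_evalue_breaks_identity_ties(self):
        a = make_annotated("A", [
            {"acc": "aSlow", "taxid": 7, "n_mut": 1, "evalue": 1e-3},
            {"acc": "aFast", "taxid": 7, "n_mut": 1, "evalue": 1e-9},
        ], L=20)
        b = make_annotated("B", [
            {"acc": "b1", "taxid": 7, "n_mut": 0},
            {"acc": "b2", "taxid": 7, "n_mut": 2},
        ], L=20)
        out = pair_phylogeny(a, b)
        assert out[0].accession_A == "aFast"  # smaller e-value ranks first

    def test_matches_per_species_bruteforce(self):
        rng = np.random.default_rng(99)
        for _ in range(30):
            specs_a = [
                {"acc": f"a{i}", "taxid": int(rng.integers(1, 4)),
                 "n_mut": int(rng.integers(0, 8))}
                for i in range(rng.integers(1, 7))
            ]
            specs_b = [
                {"acc": f"b{i}", "taxid": int(rng.integers(1, 4)),
                 "n_mut": int(rng.integers(0, 8))}
                for i in range(rng.integers(1, 7))
            ]
            a = make_annotated("A", specs_a, L=20)
            b = make_annotated("B", specs_b, L=20)
            out = pair_phylogeny(a, b)
            expected = []
            for taxid in sorted({s["taxid"] for s in specs_a} & {s["taxid"] for s in specs_b}):
                ha = [(s["acc"], 1 - s["n_mut"] / 20) for s in specs_a if s["taxid"] == taxid]
                hb = [(s["acc"], 1 - s["n_mut"] / 20) for s in specs_b if s["taxid"] == taxid]
                expected.extend(rank_match_bruteforce(ha, hb))
            assert [(r.accession_A, r.accession_B) for r in out] == expected


class TestPairString:
    def links(self, *triples):
        return {tuple(sorted((p, q))): s for p, q, s in triples}

    def test_linked_ids_paired(self):
        a = make_annotated("A", [{"acc": "a1", "netid": "nA"}])
        b = make_annotated("B", [{"acc": "b1", "netid": "nB"}])
        out = pair_string(a, b, self.links(("nA", "nB", 900)))
        assert [(r.accession_A, r.accession_B) for r in out] == [("a1", "b1")]
        assert out[0].detail["combined_score"] == 900

    def test_no_link_no_pairs(self):
        a = make_annotated("A", [{"acc": "a1", "netid": "nA"}])
        b = make_annotated("B", [{"acc": "b1", "netid": "nB"}])
        assert pair_string(a, b, {}) == []

    def test_highest_score_partner_wins(self):
        a = make_annotated("A", [{"acc": "a1", "netid": "nA"}])
        b = make_annotated("B", [
            {"acc": "bStrong", "netid": "nS"},
            {"acc": "bWeak", "netid": "nW"},
        ])
        links = self.links(("nA", "nS", 900), ("nA", "nW", 400))
        out = pair_string(a, b, links)
        assert [(r.accession_A, r.accession_B) for r in out] == [("a1", "bStrong")]
        # exhaustive max-weight check on the same toy instance
        cands = [((-900, "a1", "bStrong"), "a1", "bStrong"),
                 ((-400, "a1", "bWeak"), "a1", "bWeak")]
        oracle = lexmin_maximal_matching(cands)
        assert [(a_, b_) for _, a_, b_ in oracle] == [("a1", "bStrong")]

    def test_min_score_excludes_weak_links(self):
        a = make_annotated("A", [{"acc": "a1", "netid": "nA"}])
        b = make_annotated("B", [{"acc": "b1", "netid": "nB"}])
        assert pair_string(a, b, self.links(("nA", "nB", 400)), min_score=700) == []


class TestOptimalFlag:
    def test_optimal_recovers_blocked_cardinality(self):
        # greedy's first pick (the unique distance-1 candidate) blocks the
        # only partner of the second A hit; the optimal assignment keeps both
        a = make_annotated("A", [
            {"acc": "a0", "gene": ("g1", 0)},
            {"acc": "a4", "gene": ("g1", 4)},
        ])
        b = make_annotated("B", [
            {"acc": "b5", "gene": ("g1", 5)},
            {"acc": "b24", "gene": ("g1", 24)},
        ])
        greedy = pair_genomic(a, b)  # takes (a4,b5) at distance 1, stranding a0
        assert [(r.accession_A, r.accession_B) for r in greedy] == [("a4", "b5")]
        optimal = pair_genomic(a, b, method="optimal")
        assert {(r.accession_A, r.accession_B) for r in optimal} == {
            ("a0", "b5"), ("a4", "b24")
        }
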