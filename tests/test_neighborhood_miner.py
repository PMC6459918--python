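"""Hit filtering, gene-gap arithmetic, dndCD pairing and neighbourhood
category classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thioscape import (
    GeneAnnotation,
    HomologyHit,
    SimConfig,
    classify_dnd_system,
    classify_pbe_neighborhood,
    cooccurrence_summary,
    filter_hits,
    gene_gap,
    locate_dndCD_pairs,
    locate_pbe_loci,
)
from thioscape.neighborhood_miner import fraction_with_partner, hits_to_annotations
from thioscape.synthetic_data import gen_defence_annotations
from conftest import naive_interval_gap


def _hit(evalue, aln_len, query_len=100, query="dndC", genome="gA"):
    return HomologyHit(
        query_id=query, query_len=query_len, subject_genome=genome,
        subject_prot="p", pct_identity=80.0, aln_len=aln_len, evalue=evalue,
        subject_contig="c", subject_start=0, subject_end=300, strand="+")


class TestFilterHits:
    def test_boundary_evalue_kept(self):
        assert filter_hits([_hit(1e-10, 50)]) == [_hit(1e-10, 50)]

    def test_boundary_coverage_kept(self):
        assert len(filter_hits([_hit(1e-20, 30, query_len=100)])) == 1

    def test_just_over_boundaries_dropped(self):
        assert filter_hits([_hit(1.0000001e-10, 50)]) == []
        assert filter_hits([_hit(1e-20, 29, query_len=100)]) == []

    def test_order_preserved_and_empty_ok(self):
        hits = [_hit(1e-20, 90, genome=g) for g in "abc"]
        assert [h.subject_genome for h in filter_hits(hits)] == ["a", "b", "c"]
        assert filter_hits([]) == []

    def test_keeps_exactly_generator_truth(self):
        from thioscape.synthetic_data import gen_homology_hits
        anns, _ = gen_defence_annotations(
            SimConfig(seed=2, category_counts={"pbe_both": 10}))
        qlens = {"dndC": 300, "dndD": 500, "pbeA": 250, "pbeC": 400, "mtase": 280}
        hits, labels = gen_homology_hits(anns, qlens, n_decoys=50, seed=3)
        kept = filter_hits(hits)
        assert kept == [h for h, ok in zip(hits, labels) if ok]


class TestGeneGap:
    def test_abutting_is_zero(self):
        assert gene_gap((0, 10), (10, 20)) == 0

    def test_simple_gap(self):
        assert gene_gap((0, 10), (15, 20)) == 5

    def test_overlap_is_zero_and_symmetric(self):
        assert gene_gap((0, 10), (5, 20)) == 0
        assert gene_gap((15, 20), (0, 10)) == 5

    def test_different_contigs_not_comparable(self):
        assert gene_gap((0, 10), (15, 20), "c1", "c2") is None

    @given(st.integers(0, 10_000), st.integers(1, 500),
           st.integers(0, 10_000), st.integers(1, 500))
    @settings(derandomize=True, max_examples=300)
    def test_matches_exhaustive_oracle_and_is_symmetric(self, a0, la, b0, lb):
        a, b = (a0, a0 + la), (b0, b0 + lb)
        assert gene_gap(a, b) == naive_interval_gap(a, b)
        assert gene_gap(a, b) == gene_gap(b, a)


class TestDndCDPairing:
    def _ann(self, sym, start, end, genome="g1", contig="c0"):
        return GeneAnnotation(genome, sym, contig, start, end)

    def test_close_pair_found(self):
        anns = [self._ann("dndC", 100, 400), self._ann("dndD", 500, 900)]
        loci, unpaired = locate_dndCD_pairs(anns)
        assert len(loci) == 1 and unpaired == []
        assert loci[0].span == (100, 900) and loci[0].pair_gap == 100

    def test_gap_just_over_limit_rejected(self):
        anns = [self._ann("dndC", 0, 100), self._ann("dndD", 5_101, 5_400)]
        loci, unpaired = locate_dndCD_pairs(anns)
        assert loci == [] and len(unpaired) == 2

    def test_gap_exactly_at_limit_kept(self):
        anns = [self._ann("dndC", 0, 100), self._ann("dndD", 5_100, 5_400)]
        loci, _ = locate_dndCD_pairs(anns)
        assert len(loci) == 1 and loci[0].pair_gap == 5_000

    def test_nearest_chosen_tie_breaks_to_smaller_start(self):
        anns = [self._ann("dndC", 1_000, 1_100),
                self._ann("dndD", 0, 500),       # gap 500
                self._ann("dndD", 1_300, 1_800)] # gap 200 -> nearest
        loci, unpaired = locate_dndCD_pairs(anns)
        assert loci[0].span == (1_000, 1_800)
        # symmetric tie: equal gaps on both sides -> smaller start wins
        anns2 = [self._ann("dndC", 1_000, 1_100),
                 self._ann("dndD", 400, 800),     # gap 200
                 self._ann("dndD", 1_300, 1_700)] # gap 200
        loci2, _ = locate_dndCD_pairs(anns2)
        assert loci2[0].span == (400, 1_100)

    def test_exhaustive_pairing_on_random_layouts(self):
        rng = np.random.default_rng(21)
        for trial in range(30):
            anns = []
            for k in range(int(rng.integers(1, 4))):
                s = int(rng.integers(0, 20_000))
                anns.append(self._ann("dndC", s, s + 300))
            for k in range(int(rng.integers(1, 4))):
                s = int(rng.integers(0, 20_000))
                anns.append(self._ann("dndD", s, s + 300))
            loci, unpaired = locate_dndCD_pairs(anns)
            # every reported pair is within limit, every gene accounted once
            assert all(l.pair_gap <= 5_000 for l in loci)
            assert 2 * len(loci) + len(unpaired) == len(anns)


class TestClassification:
    def _ann(self, sym, start, end, genome="g1"):
        return GeneAnnotation(genome, sym, "c0", start, end)

    def _locus(self, anns):
        loci, _ = locate_dndCD_pairs(anns)
        assert len(loci) == 1
        return loci[0]

    def test_fgh_close_no_pbe_is_dndFGH(self):
        anns = [self._ann("dndC", 0, 300), self._ann("dndD", 400, 900),
                self._ann("dndF", 1_900, 2_200), self._ann("dndG", 2_300, 2_600),
                self._ann("dndH", 2_700, 3_000)]
        c = classify_dnd_system(self._locus(anns), anns)
        assert c.category == "dndFGH" and c.has_dndFGH and not c.has_pbeAC

    def test_missing_one_fgh_gene_not_counted(self):
        anns = [self._ann("dndC", 0, 300), self._ann("dndD", 400, 900),
                self._ann("dndF", 1_900, 2_200), self._ann("dndG", 2_300, 2_600)]
        assert classify_dnd_system(self._locus(anns), anns).category == "none"

    def test_both_cassettes_present(self):
        anns = [self._ann("dndC", 30_000, 30_300), self._ann("dndD", 30_400, 30_900),
                self._ann("dndF", 32_000, 32_300), self._ann("dndG", 32_400, 32_700),
                self._ann("dndH", 32_800, 33_100),
                self._ann("pbeA", 25_000, 25_500), self._ann("pbeC", 25_600, 26_100)]
        c = classify_dnd_system(self._locus(anns), anns)
        assert c.category == "both"

    def test_window_boundary_inclusive(self):
        # farthest gene (dndH) exactly 20 kb away counts; 20,001 bp does not
        base = [self._ann("dndC", 0, 300), self._ann("dndD", 400, 900)]
        fgh = lambda off: [self._ann("dndF", 17_000, 17_300),
                           self._ann("dndG", 18_000, 18_300),
                           self._ann("dndH", 900 + off, 1_200 + off)]
        at = classify_dnd_system(self._locus(base), base + fgh(20_000))
        over = classify_dnd_system(self._locus(base), base + fgh(20_001))
        assert at.has_dndFGH and not over.has_dndFGH

    def test_pbe_dnd_at_500bp_no_mtase(self):
        anns = [self._ann("pbeA", 0, 500), self._ann("pbeC", 600, 1_100),
                self._ann("dndC", 1_600, 1_900), self._ann("dndD", 2_000, 2_500)]
        (locus,) = locate_pbe_loci(anns)
        c = classify_pbe_neighborhood(locus, anns)
        assert c.category == "dnd_only" and c.has_dndCD and not c.has_mtase

    def test_pbe_solitary_when_nothing_within_10kb(self):
        anns = [self._ann("pbeA", 0, 500), self._ann("pbeC", 600, 1_100),
                self._ann("mtase", 12_000, 12_900)]
        (locus,) = locate_pbe_loci(anns)
        assert classify_pbe_neighborhood(locus, anns).category == "solitary"

    def test_overlap_counts_as_within_window(self):
        anns = [self._ann("pbeA", 0, 500), self._ann("pbeC", 600, 1_100),
                self._ann("mtase", 1_000, 1_900)]
        (locus,) = locate_pbe_loci(anns)
        assert classify_pbe_neighborhood(locus, anns).has_mtase

    @pytest.mark.parametrize("seed", range(100))
    def test_classifier_recovers_planted_categories(self, seed):
        rng = np.random.default_rng(seed)
        cats = ["pbe_dnd_only", "pbe_mtase_only", "pbe_both", "pbe_solitary",
                "dnd_with_dndFGH", "dnd_alone", "dnd_with_pbe", "dnd_with_both"]
        counts = {c: int(rng.integers(0, 3)) for c in cats}
        if sum(counts.values()) == 0:
            counts["pbe_both"] = 1
        lo = int(rng.integers(0, 4_000))
        cfg = SimConfig(seed=seed, category_counts=counts,
                        gap_range=(lo, lo + int(rng.integers(1, 5_000))))
        anns, truth = gen_defence_annotations(cfg)
        by_genome = {}
        for a in anns:
            by_genome.setdefault(a.genome_id, []).append(a)
        pbe_map = {"pbe_dnd_only": "dnd_only", "pbe_mtase_only": "mtase_only",
                   "pbe_both": "both", "pbe_solitary": "solitary"}
        dnd_map = {"dnd_with_dndFGH": "dndFGH", "dnd_alone": "none",
                   "dnd_with_pbe": "pbe", "dnd_with_both": "both"}
        for gid, planted in truth.items():
            genes = by_genome[gid]
            if planted in pbe_map:
                (locus,) = locate_pbe_loci(genes)
                got = classify_pbe_neighborhood(locus, genes).category
                assert got == pbe_map[planted], (gid, planted, got)
            else:
                loci, _ = locate_dndCD_pairs(genes)
                got = classify_dnd_system(loci[0], genes).category
                assert got == dnd_map[planted], (gid, planted, got)

    def test_window_monotonicity(self):
        anns, _ = gen_defence_annotations(
            SimConfig(seed=77, category_counts={"pbe_dnd_only": 6,
                                                "pbe_solitary": 6},
                      gap_range=(0, 9_000)))
        by_genome = {}
        for a in anns:
            by_genome.setdefault(a.genome_id, []).append(a)
        for w_small, w_big in ((2_000, 10_000), (10_000, 40_000)):
            n_small = n_big = 0
            for gid, genes in by_genome.items():
                (locus,) = locate_pbe_loci(genes)
                n_small += classify_pbe_neighborhood(locus, genes, w_small).has_dndCD
                n_big += classify_pbe_neighborhood(locus, genes, w_big).has_dndCD
            assert n_big >= n_small


class TestSummaries:
    def _pbe_classifications(self, counts):
        cfg = SimConfig(seed=99, category_counts=counts)
        anns, _ = gen_defence_annotations(cfg)
        by_genome = {}
        for a in anns:
            by_genome.setdefault(a.genome_id, []).append(a)
        out = []
        for genes in by_genome.values():
            for locus in locate_pbe_loci(genes):
                out.append(classify_pbe_neighborhood(locus, genes))
        return out

    def test_partition_property(self):
        cls = self._pbe_classifications({"pbe_dnd_only": 7, "pbe_mtase_only": 5,
                                         "pbe_both": 3, "pbe_solitary": 4})
        summary = cooccurrence_summary(cls)
        assert sum(k for k, _ in summary.values()) == len(cls)

    def test_single_category_is_100_percent(self):
        cls = self._pbe_classifications({"pbe_solitary": 5})
        assert cooccurrence_summary(cls) == {"solitary": (5, 100.0)}

    def test_percent_rounding_to_one_decimal(self):
        cls = self._pbe_classifications({"pbe_dnd_only": 2, "pbe_solitary": 1})
        assert cooccurrence_summary(cls)["dnd_only"] == (2, 66.7)

    def test_empty_input_error(self):
        with pytest.raises(ValueError):
            cooccurrence_summary([])

    def test_fraction_with_partner(self):
        cls = self._pbe_classifications({"pbe_dnd_only": 3, "pbe_both": 1,
                                         "pbe_mtase_only": 4})
        k, pct = fraction_with_partner(cls, "has_dndCD")
        assert k == 4 and pct == 50.0


class TestHitsToAnnotations:
    def test_best_hit_per_genome_query(self):
        hits = [_hit(1e-20, 50), _hit(1e-60, 60), _hit(1e-40, 70, genome="gB")]
        anns = hits_to_annotations(hits)
        assert len(anns) == 2
        assert {a.genome_id for a in anns} == {"gA", "gB"}
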