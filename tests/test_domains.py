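"""Island caller against a brute-force oracle, replicate intersection
algebra, summaries, the strict >80% gene rule and distance filtering."""


import numpy as np
import pytest

from padscan.core import GeneAnnotation, GenomeLayout, Interval
from padscan.domains import (DomainSet, IslandParams, assign_enriched_genes,
                             call_islands, clip_to_arms, domain_summary,
                             filter_pericentromere_distance,
                             intersect_replicates, tissue_overlap)
from padscan.tracks import BinnedTrack

W = 1000


def _track(counts_by_chrom):
    return BinnedTrack(window=W,
                       values={c: np.asarray(v, float)
                               for c, v in counts_by_chrom.items()},
                       normalization="raw")


def _layout_for(counts_by_chrom):
    return GenomeLayout(chromosomes=[(c, len(v) * W)
                                     for c, v in counts_by_chrom.items()])


from oracles import oracle_islands  # noqa: E402


# ------------------------------------------------------------------ calling


class TestCallIslands:
    def test_flat_background_yields_nothing(self):
        counts = {"chr1": np.full(200, 10.0)}
        islands = call_islands(_track(counts), _track({"chr1": np.full(200, 10.0)}),
                               _layout_for(counts), IslandParams())
        assert islands == []

    def test_single_high_run_gives_one_island(self):
        chip = np.full(200, 5.0)
        chip[100:110] = 55.0  # ~10x the genome mean
        counts = {"chr1": chip}
        islands = call_islands(_track(counts), _track({"chr1": np.full(200, 5.0)}),
                               _layout_for(counts), IslandParams())
        assert len(islands) == 1
        iv = islands[0].interval
        assert (iv.start, iv.end) == (100_000, 110_000)

    @pytest.mark.parametrize("gap_kb,expected", [(4, 2), (3, 1)])
    def test_gap_rule_boundary(self, gap_kb, expected):
        chip = np.full(300, 5.0)
        chip[100:110] = 60.0
        chip[110 + gap_kb:120 + gap_kb] = 60.0
        counts = {"chr1": chip}
        islands = call_islands(_track(counts), _track({"chr1": np.full(300, 5.0)}),
                               _layout_for(counts), IslandParams())
        assert len(islands) == expected

    def test_control_depth_rescaling_invariant(self, rng):
        chip = rng.poisson(8.0, size=400).astype(float)
        chip[50:70] += 40
        ctrl = rng.poisson(8.0, size=400).astype(float)
        counts = {"chr1": chip}
        layout = _layout_for(counts)
        a = call_islands(_track(counts), _track({"chr1": ctrl}), layout)
        b = call_islands(_track(counts), _track({"chr1": ctrl * 7.0}), layout)
        assert [(i.interval.start, i.interval.end) for i in a] == \
               [(i.interval.start, i.interval.end) for i in b]
        np.testing.assert_allclose([i.qvalue for i in a], [i.qvalue for i in b],
                                   atol=1e-12)

    def test_empty_control_falls_back_to_background(self, caplog):
        chip = np.full(200, 5.0)
        chip[20:30] = 60.0
        counts = {"chr1": chip}
        with caplog.at_level("WARNING"):
            islands = call_islands(_track(counts), _track({"chr1": np.zeros(200)}),
                                   _layout_for(counts), IslandParams())
        assert "empty control" in caplog.text
        assert len(islands) == 1

    def test_matches_brute_force_oracle_on_random_instances(self):
        """Implementation vs direct-scan oracle on random 500-window
        instances with spiked enriched runs."""
        params = IslandParams()
        rng = np.random.default_rng(2024)
        for _ in range(10):
            chip = rng.poisson(7.0, size=500).astype(float)
            for _ in range(rng.integers(1, 6)):
                s = int(rng.integers(0, 480))
                chip[s:s + int(rng.integers(3, 15))] += rng.integers(15, 50)
            ctrl = rng.poisson(7.0, size=500).astype(float)
            counts = {"chr1": chip}
            mine = call_islands(_track(counts), _track({"chr1": ctrl}),
                                _layout_for(counts), params)
            ref = oracle_islands({"chr1": chip}, {"chr1": ctrl}, params)
            assert [(i.interval.chrom, i.interval.start, i.interval.end)
                    for i in mine] == [(c, s, e) for c, s, e, _, _ in ref]
            np.testing.assert_allclose([i.pvalue for i in mine],
                                       [p for *_, p, _ in ref], atol=1e-9)
            np.testing.assert_allclose([i.qvalue for i in mine],
                                       [q for *_, q in ref], atol=1e-9)

    def test_bh_qvalues_monotone_in_p_rank(self, rng):
        chip = rng.poisson(6.0, size=500).astype(float)
        chip[50:60] += 30
        chip[200:204] += 25
        chip[400:420] += 35
        counts = {"chr1": chip}
        islands = call_islands(_track(counts), _track({"chr1": rng.poisson(6.0, 500).astype(float)}),
                               _layout_for(counts), IslandParams(fdr=0.5))
        by_p = sorted(islands, key=lambda i: i.pvalue)
        qs = [i.qvalue for i in by_p]
        assert all(a <= b + 1e-15 for a, b in zip(qs, qs[1:]))
        assert all(i.qvalue >= i.pvalue for i in islands)


# ------------------------------------------------------------------ algebra


def _dset(triples, provenance="replicate_call"):
    return DomainSet("t", [Interval(c, s, e) for c, s, e in triples],
                     provenance=provenance)


class TestIntersectReplicates:
    def test_partial_overlap(self):
        out = intersect_replicates(_dset([("chr1", 0, 10_000)]),
                                   _dset([("chr1", 5_000, 15_000)]))
        assert [(i.start, i.end) for i in out.intervals] == [(5_000, 10_000)]

    def test_disjoint_gives_empty(self):
        out = intersect_replicates(_dset([("chr1", 0, 1_000)]),
                                   _dset([("chr1", 5_000, 6_000)]))
        assert out.intervals == []

    def test_idempotent_commutative(self, rng):
        a = _dset([("chr1", int(s), int(s) + 2_000)
                   for s in range(0, 50_000, 5_000)])
        b = _dset([("chr1", int(s) + 1_000, int(s) + 4_000)
                   for s in range(0, 50_000, 5_000)])
        ab = intersect_replicates(a, b)
        ba = intersect_replicates(b, a)
        assert ab.intervals == ba.intervals
        assert intersect_replicates(a, a).intervals == a.intervals
        assert intersect_replicates(ab, a).intervals == ab.intervals


class TestSummary:
    def test_coverage_fraction(self):
        layout = GenomeLayout(chromosomes=[("chr1", 10_000_000)])
        s = domain_summary(_dset([("chr1", 0, 1_000_000)], "intersected"), layout)
        assert s["genome_coverage"] == pytest.approx(0.10)

    def test_median_length(self):
        layout = GenomeLayout(chromosomes=[("chr1", 1_000_000)])
        s = domain_summary(_dset([("chr1", 0, 5_000), ("chr1", 10_000, 19_000),
                                  ("chr1", 30_000, 50_000)], "intersected"), layout)
        assert s["median_length"] == 9_000

    def test_empty_set(self):
        layout = GenomeLayout(chromosomes=[("chr1", 1_000_000)])
        s = domain_summary(_dset([], "intersected"), layout)
        assert s["genome_coverage"] == 0 and s["median_length"] is None

    def test_clip_to_arms_removes_pericentromeric_bp(self, small_layout):
        doms = _dset([("chr1", 390_000, 410_000), ("chr1", 450_000, 460_000),
                      ("chr1", 700_000, 710_000)], "intersected")
        clipped = clip_to_arms(doms, small_layout)
        assert [(i.start, i.end) for i in clipped.intervals] == \
               [(390_000, 400_000), (700_000, 710_000)]


class TestEnrichedGenes:
    def _gene(self, s, e, gid="g"):
        return GeneAnnotation(gid, Interval("chr1", s, e))

    def test_exactly_80_percent_not_enriched(self):
        doms = _dset([("chr1", 0, 800)], "intersected")
        assert assign_enriched_genes([self._gene(0, 1000)], doms) == {"g": False}

    def test_fully_contained_enriched(self):
        doms = _dset([("chr1", 0, 10_000)], "intersected")
        assert assign_enriched_genes([self._gene(100, 900)], doms) == {"g": True}

    def test_union_across_two_domains(self):
        doms = _dset([("chr1", 0, 500), ("chr1", 600, 1_000)], "intersected")
        # covered 500 + 400 = 900 of 1000 -> 0.9 > 0.8
        assert assign_enriched_genes([self._gene(0, 1000)], doms) == {"g": True}


class TestDistanceFilter:
    def test_exactly_one_mb_kept(self, rng):
        layout = GenomeLayout(chromosomes=[("chr1", 10_000_000)],
                              pericentromere={"chr1": (5_000_000, 7_000_000)})
        item = Interval("chr1", 3_900_000, 4_000_000)  # distance exactly 1 Mb
        assert filter_pericentromere_distance([item], layout) == [item]
        closer = Interval("chr1", 3_900_001, 4_000_001)
        assert filter_pericentromere_distance([closer], layout) == []

    def test_inside_pericentromere_removed(self):
        layout = GenomeLayout(chromosomes=[("chr1", 10_000_000)],
                              pericentromere={"chr1": (5_000_000, 7_000_000)})
        assert filter_pericentromere_distance(
            [Interval("chr1", 5_500_000, 5_600_000)], layout) == []

    def test_larger_cutoff_removes_superset(self, rng):
        layout = GenomeLayout(chromosomes=[("chr1", 10_000_000)],
                              pericentromere={"chr1": (5_000_000, 7_000_000)})
        items = [Interval("chr1", int(s), int(s) + 10_000)
                 for s in rng.integers(0, 9_900_000, size=200)]
        kept1 = set(map(id, filter_pericentromere_distance(items, layout, 1_000_000)))
        kept2 = set(map(id, filter_pericentromere_distance(items, layout, 2_000_000)))
        assert kept2 <= kept1


class TestTissueOverlap:
    def test_identical_sets_single_cell(self):
        cells = tissue_overlap({"a": {"g1", "g2"}, "b": {"g1", "g2"}})
        assert cells == {("a", "b"): 2}

    def test_disjoint_sets(self):
        cells = tissue_overlap({"a": {"g1"}, "b": {"g2"}})
        assert cells == {("a",): 1, ("b",): 1}

    def test_matches_brute_force_enumeration(self, rng):
        genes = [f"g{i}" for i in range(200)]
        sets = {t: {g for g in genes if rng.random() < 0.4}
                for t in ("root", "leaf", "flower")}
        cells = tissue_overlap(sets)
        assert sum(cells.values()) == len(set().union(*sets.values()))
        for key, count in cells.items():
            brute = sum(
                1 for g in genes
                if all(g in sets[t] for t in key)
                and all(g not in sets[t] for t in sets if t not in key))
            assert count == brute
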