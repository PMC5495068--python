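"""Generator behaviour: geometry, coverage targets, intensity model,
annotation densities, Hi-C construction, methylation model, determinism."""

import numpy as np
import pytest
from scipy import stats as sps

from padscan.core import GenomeLayout
from padscan.intervals import by_chrom, overlap_bp, total_bp
from padscan.simulate import (SimulationConfig, SyntheticTruth,
                              compartment_labels, generate_dataset,
                              simulate_annotations, simulate_fragments,
                              simulate_hic, simulate_layout,
                              simulate_methylation, simulate_true_domains,
                              substream, _sample_lengths)


class TestLayout:
    def test_pericentromere_centred_with_fraction(self):
        cfg = SimulationConfig(n_chromosomes=1, chromosome_length=3_000_000,
                               pericentromere_fraction=0.2)
        layout = simulate_layout(cfg)
        assert layout.peri("chr1") == (1_200_000, 1_800_000)
        cs, ce = layout.centromere["chr1"]
        assert (cs, ce) == (1_400_000, 1_600_000)

    def test_zero_fraction_means_whole_arm(self):
        cfg = SimulationConfig(n_chromosomes=1, pericentromere_fraction=0.0)
        layout = simulate_layout(cfg)
        assert layout.arms("chr1") == [(0, cfg.chromosome_length)]

    def test_five_chromosomes_same_rule(self):
        layout = simulate_layout(SimulationConfig())
        assert len(layout.chromosomes) == 5
        peris = {layout.peri(c) for c in layout.names}
        assert peris == {(1_200_000, 1_800_000)}

    def test_fraction_one_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(pericentromere_fraction=1.0)


class TestTrueDomains:
    def test_coverage_within_one_point_of_target(self):
        cfg = SimulationConfig(seed=3)
        layout = simulate_layout(cfg)
        domains = simulate_true_domains(layout, cfg)
        frac = domains.total_bp / layout.total_arm_bp
        assert abs(frac - cfg.domain_coverage) < 0.01

    def test_domains_on_arms_with_spacing(self):
        cfg = SimulationConfig(seed=5)
        layout = simulate_layout(cfg)
        domains = simulate_true_domains(layout, cfg)
        prev = None
        for iv in domains.intervals:
            ps, pe = layout.peri(iv.chrom)
            assert iv.end <= ps or iv.start >= pe  # never touches pericentromere
            if prev is not None and prev.chrom == iv.chrom:
                gap = iv.start - prev.end
                # same-arm neighbours keep >= spacing (cross-peri gap is larger)
                assert gap >= cfg.domain_spacing
            prev = iv

    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(seed=11)
        layout = simulate_layout(cfg)
        a = simulate_true_domains(layout, cfg)
        b = simulate_true_domains(layout, cfg)
        assert a.intervals == b.intervals

    def test_length_sampler_median(self, rng):
        lengths = _sample_lengths(rng, 10_000, 9_000.0, 0.6, 2_000)
        assert abs(np.median(lengths) - 9_000) / 9_000 < 0.05

    def test_infeasible_coverage_raises(self):
        cfg = SimulationConfig(domain_coverage=0.75,
                               pericentromere_fraction=0.05, domain_spacing=60_000)
        layout = simulate_layout(cfg)
        with pytest.raises(ValueError, match="coverage"):
            simulate_true_domains(layout, cfg)


class TestFragments:
    def test_closed_form_domain_fraction(self):
        # fold 3 over 10% of a single chromosome without pericentromere:
        # P(fragment in domain) = 0.3 / (0.3 + 0.9) = 0.25
        cfg = SimulationConfig(n_chromosomes=1, chromosome_length=1_000_000,
                               pericentromere_fraction=0.0, gfp_fold=3.0,
                               n_fragments=100_000, seed=2)
        layout = simulate_layout(cfg)
        from padscan.core import Interval
        from padscan.domains import DomainSet
        domains = DomainSet("t", [Interval("chr1", 450_000, 550_000)],
                            provenance="intersected")
        fs = simulate_fragments(layout, domains, cfg, "GFP", 1)
        assert fs.total == cfg.n_fragments
        mids = np.array([(f.start + f.end) // 2 for f in fs.fragments])
        frac = np.mean((mids >= 450_000) & (mids < 550_000))
        assert abs(frac - 0.25) < 0.01

    def test_fold_one_matches_igg(self):
        cfg = SimulationConfig(n_chromosomes=1, chromosome_length=1_000_000,
                               pericentromere_fraction=0.0, gfp_fold=1.0,
                               n_fragments=10_000, seed=4)
        layout = simulate_layout(cfg)
        domains = simulate_true_domains(layout, cfg)
        gfp = simulate_fragments(layout, domains, cfg, "GFP", 1)
        igg = simulate_fragments(layout, domains, cfg, "IgG", 1)
        ks = sps.ks_2samp([f.start for f in gfp.fragments],
                          [f.start for f in igg.fragments])
        assert ks.pvalue > 0.01

    def test_replicates_differ_but_igg_uniform(self):
        cfg = SimulationConfig(seed=6, n_fragments=5_000)
        layout = simulate_layout(cfg)
        domains = simulate_true_domains(layout, cfg)
        r1 = simulate_fragments(layout, domains, cfg, "GFP", 1)
        r2 = simulate_fragments(layout, domains, cfg, "GFP", 2)
        assert r1.fragments != r2.fragments
        assert r1.total == r2.total == cfg.n_fragments


class TestAnnotations:
    def test_te_density_ratio_recovered(self):
        cfg = SimulationConfig(seed=8)
        layout = simulate_layout(cfg)
        domains = simulate_true_domains(layout, cfg)
        genes, _, te_class, te_peripheral = simulate_annotations(layout, domains, cfg)
        tes = [g for g in genes if g.biotype == "TE_gene"]
        dom = by_chrom(domains.intervals)
        inside_bp = domains.total_bp
        outside_bp = layout.total_arm_bp - inside_bp
        n_in = 0
        for t in tes:
            arr = dom.get(t.interval.chrom, np.zeros((0, 2), int))
            k = np.searchsorted(arr[:, 0], t.interval.start, side="right") - 1
            if k >= 0 and t.interval.start < arr[k, 1]:
                n_in += 1
        n_out = len(tes) - n_in
        ratio = (n_in / inside_bp) / (n_out / outside_bp)
        assert abs(ratio - cfg.te_density_ratio) / cfg.te_density_ratio < 0.2
        assert set(te_class.values()) <= {"CMT2-dependent", "RdDM-dependent"}
        assert set(te_class) == set(te_peripheral)

    def test_enriched_pc_genes_lower_expressed(self):
        cfg = SimulationConfig(seed=9)
        layout = simulate_layout(cfg)
        domains = simulate_true_domains(layout, cfg)
        genes, enriched, _, _ = simulate_annotations(layout, domains, cfg)
        pc = [g for g in genes if g.biotype == "protein_coding"]
        inside = [g.expression for g in pc if enriched[g.gene_id]]
        outside = [g.expression for g in pc if not enriched[g.gene_id]]
        assert np.median(inside) < np.median(outside)

    def test_identical_given_seed(self):
        cfg = SimulationConfig(seed=10)
        layout = simulate_layout(cfg)
        domains = simulate_true_domains(layout, cfg)
        a = simulate_annotations(layout, domains, cfg)
        b = simulate_annotations(layout, domains, cfg)
        assert a[0] == b[0] and a[2] == b[2]


class TestHiC:
    def test_matrix_exactly_symmetric_and_positive(self):
        cfg = SimulationConfig(seed=12)
        layout = simulate_layout(cfg)
        domains = simulate_true_domains(layout, cfg)
        labels = compartment_labels(layout, domains, cfg.hic_binsize)
        mats = simulate_hic(layout, labels, cfg)
        m = mats["chr1"]
        assert m.shape == (150, 150)
        np.testing.assert_array_equal(m, m.T)
        assert (m > 0).all()

    def test_compartment_labels_cover_pericentromere(self):
        cfg = SimulationConfig(seed=12)
        layout = simulate_layout(cfg)
        domains = simulate_true_domains(layout, cfg)
        labels = compartment_labels(layout, domains, cfg.hic_binsize)
        ps, pe = layout.peri("chr1")
        peri_bins = slice(ps // cfg.hic_binsize, pe // cfg.hic_binsize)
        assert labels["chr1"][peri_bins].all()


class TestMethylation:
    @staticmethod
    def _one_te_truth(cfg, te_class):
        from padscan.core import GeneAnnotation, Interval
        from padscan.domains import DomainSet
        te = GeneAnnotation("TE00001", Interval("chr1", 100_000, 110_000),
                            biotype="TE_gene")
        truth = SyntheticTruth(
            domains=DomainSet("t", [Interval("chr1", 100_000, 110_000)],
                              provenance="intersected"),
            compartments={}, te_class={"TE00001": te_class},
            te_peripheral={"TE00001": True}, gene_enriched={})
        return te, truth

    def test_values_in_unit_interval(self):
        cfg = SimulationConfig(seed=13)
        te, truth = self._one_te_truth(cfg, "CMT2-dependent")
        tracks = simulate_methylation(truth, [te], cfg, "WT")
        for context, df in tracks.items():
            assert df["value"].between(0, 1).all()

    def test_cmt2_loss_factor_on_cmt2_dependent_te(self):
        cfg = SimulationConfig(seed=14)
        te, truth = self._one_te_truth(cfg, "CMT2-dependent")
        wt = simulate_methylation(truth, [te], cfg, "WT")["CHH"]["value"].mean()
        mut = simulate_methylation(truth, [te], cfg, "cmt2-like")["CHH"]["value"].mean()
        assert mut / wt == pytest.approx(cfg.cmt2_loss, rel=0.25)

    def test_drm_mutant_spares_cmt2_dependent_te(self):
        cfg = SimulationConfig(seed=14)
        te, truth = self._one_te_truth(cfg, "CMT2-dependent")
        wt = simulate_methylation(truth, [te], cfg, "WT")["CHH"]["value"].mean()
        mut = simulate_methylation(truth, [te], cfg, "drm12-like")["CHH"]["value"].mean()
        assert mut == pytest.approx(wt, rel=0.15)

    def test_met1_zeroes_cg(self):
        cfg = SimulationConfig(seed=15)
        te, truth = self._one_te_truth(cfg, "RdDM-dependent")
        cg = simulate_methylation(truth, [te], cfg, "met1-like")["CG"]
        assert (cg["value"] == 0).all()

    def test_unknown_genotype_rejected(self):
        cfg = SimulationConfig(seed=15)
        te, truth = self._one_te_truth(cfg, "RdDM-dependent")
        with pytest.raises(ValueError, match="genotype"):
            simulate_methylation(truth, [te], cfg, "ros1-like")


class TestDeterminism:
    def test_full_dataset_reproducible(self):
        cfg = SimulationConfig(seed=21, n_fragments=2_000, n_chromosomes=2,
                               chromosome_length=1_000_000)
        a = generate_dataset(cfg, genotypes=("WT",))
        b = generate_dataset(cfg, genotypes=("WT",))
        assert a.truth.domains.intervals == b.truth.domains.intervals
        assert a.fragments["GFP_rep1"].fragments == b.fragments["GFP_rep1"].fragments
        np.testing.assert_array_equal(a.hic["chr1"], b.hic["chr1"])
        assert a.methylation["WT"]["CHH"].equals(b.methylation["WT"]["CHH"])

    def test_substreams_independent(self):
        a = substream(7, "fragments", "GFP", 1).integers(0, 1 << 30, 5)
        b = substream(7, "fragments", "GFP", 2).integers(0, 1 << 30, 5)
        assert not np.array_equal(a, b)


def test_written_dataset_parses_with_readers(tmp_path):
    from padscan import io as pio
    from padscan.simulate import write_dataset
    cfg = SimulationConfig(seed=22, n_chromosomes=2, chromosome_length=1_000_000,
                           n_fragments=2_000)
    ds = generate_dataset(cfg, genotypes=("WT",))
    paths = write_dataset(ds, tmp_path / "sim")
    layout = pio.read_layout(paths["layout.tsv"])
    assert layout.chromosomes == ds.layout.chromosomes
    frags = pio.read_fragments(paths["fragments_GFP_rep1.bed"], layout=layout)
    assert frags.total == cfg.n_fragments
    genes = pio.read_gff3_genes(paths["genes.gff3"],
                                expression=pio.read_expression_tsv(paths["expression.tsv"]))
    assert len(genes) == len(ds.genes)
    mat = pio.read_dense_matrix(paths["hic_chr1.tsv"])
    assert mat.shape[0] == cfg.chromosome_length // cfg.hic_binsize
    assert len(pio.read_bedpe(paths["loops.bedpe"])) == cfg.n_loops
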