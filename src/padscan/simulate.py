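"""Synthetic multi-chromosome datasets with known ground truth.

The generator emulates the statistical structure the analysis assumes:
a small multi-chromosome genome with pericentromeres; "peripheral"
domains embedded on chromosome arms that enrich pull-down fragment
counts over an IgG-like uniform background (the pericentromere is
enriched too, mirroring chromocenter tethering); biotype-annotated
genes/TEs whose densities and expression depend on domain membership;
a two-compartment block Hi-C matrix with distance decay whose blocks
track the domain signal; CG/CHG/CHH methylation for two TE classes
whose CHH levels respond to distinct simulated pathways (CMT2-like vs
RdDM-like); chromatin loops; and optional i.i.d. nucleotide sequence.

All randomness flows from one root seed through named substreams, so a
dataset is a pure function of (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import intervals as ivops
from . import io as pio
from .core import FragmentSet, GeneAnnotation, GenomeLayout, Interval
from .domains import DomainSet

GENOTYPES = ("WT", "met1-like", "cmt3-like", "cmt2-like", "drm12-like")
CONTEXTS = ("CG", "CHG", "CHH")
TE_CLASSES = ("CMT2-dependent", "RdDM-dependent")


def substream(seed: int, *tokens) -> np.random.Generator:
    """Named child RNG of a root seed (documented per-component substreams)."""
    key = [zlib.crc32(str(t).encode()) for t in tokens]
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *key]))


@dataclass
class SimulationConfig:
    # genome geometry
    n_chromosomes: int = 5
    chromosome_length: int = 3_000_000
    pericentromere_fraction: float = 0.2
    # true peripheral domains (on arms)
    domain_coverage: float = 0.15          # fraction of arm bp
    domain_median_bp: float = 9_000.0      # log-normal median
    domain_log_sd: float = 0.6
    domain_min_bp: int = 2_000
    domain_spacing: int = 6_000            # >= 2 x caller gap G
    # fragments
    gfp_fold: float = 3.0                  # enrichment in domains + pericentromere
    n_fragments: int = 200_000             # per sample
    fragment_length: int = 200
    n_replicates: int = 2
    # annotations
    pc_density: float = 1 / 6_000          # protein-coding genes per arm bp
    pc_median_bp: float = 2_000.0
    pc_log_sd: float = 0.4
    te_density_outside: float = 1 / 50_000
    te_density_ratio: float = 4.0          # inside-domain / outside density
    te_median_bp: float = 3_000.0
    te_log_sd: float = 0.5
    pseudogene_density: float = 1 / 150_000
    # expression (arbitrary units, log-normal)
    expr_log_sd: float = 1.0
    pc_expr_log_mean: float = math.log(8.0)
    pc_expr_log_mean_enriched: float = math.log(2.0)
    te_expr_log_mean: float = math.log(1.0)
    # Hi-C
    hic_binsize: int = 20_000
    hic_decay_exponent: float = 1.0
    hic_contrast: float = 0.6
    hic_noise_sd: float = 0.1
    # methylation: baselines by context for (peripheral, interior) TEs
    meth_baselines: dict = field(default_factory=lambda: {
        "CG": (0.85, 0.75), "CHG": (0.60, 0.45), "CHH": (0.35, 0.22)})
    meth_window: int = 100
    meth_concentration: float = 30.0       # Beta concentration of window noise
    cmt2_bias: float = 0.8                 # P(CMT2-dependent | TE in a domain)
    cmt2_loss: float = 0.2                 # CHH factor on CMT2-dep TEs in cmt2-like
    drm_loss: float = 0.2                  # CHH factor on RdDM-dep TEs in drm12-like
    cmt3_chg_factor: float = 0.3
    # sequence
    gc_inside: float = 0.38
    gc_outside: float = 0.36
    # loops
    n_loops: int = 300
    loop_anchor_bp: int = 4_000
    loop_intra_frac: float = 0.45
    loop_across_frac: float = 0.15
    # reproducibility
    seed: int = 7

    def __post_init__(self) -> None:
        for name in ("pericentromere_fraction", "domain_coverage", "cmt2_bias",
                     "loop_intra_frac", "loop_across_frac",
                     "gc_inside", "gc_outside"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.pericentromere_fraction >= 1:
            raise ValueError("pericentromere_fraction must be < 1")
        if self.gfp_fold < 1:
            raise ValueError("gfp_fold must be >= 1")
        if self.domain_coverage >= 1 - self.pericentromere_fraction:
            raise ValueError("domain coverage target exceeds the arm fraction")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Ground truth of one synthetic dataset, for recovery tests."""

    domains: DomainSet
    compartments: dict[str, np.ndarray]        # per 20-kb bin: 1 peripheral, 0 not
    te_class: dict[str, str]                   # te_id -> CMT2/RdDM-dependent
    te_peripheral: dict[str, bool]             # te_id -> located in a true domain
    gene_enriched: dict[str, bool]             # gene_id -> true enrichment flag


def simulate_layout(config: SimulationConfig) -> GenomeLayout:
    """Genome layout: pericentromere centred on each chromosome midpoint
    with the configured fraction; centromere = its central third."""
    chroms, peri, cen = [], {}, {}
    for i in range(config.n_chromosomes):
        name = f"chr{i + 1}"
        L = config.chromosome_length
        chroms.append((name, L))
        half = int(round(L * config.pericentromere_fraction / 2))
        mid = L // 2
        ps, pe = mid - half, mid + half
        peri[name] = (ps, pe)
        third = (pe - ps) // 3
        cen[name] = (ps + third, pe - third)
    return GenomeLayout(chromosomes=chroms, centromere=cen, pericentromere=peri)


def _sample_lengths(rng: np.random.Generator, n: int, median: float,
                    log_sd: float, min_bp: int) -> np.ndarray:
    raw = rng.lognormal(mean=math.log(median), sigma=log_sd, size=n)
    return np.maximum(np.round(raw).astype(np.int64), min_bp)


def simulate_true_domains(layout: GenomeLayout, config: SimulationConfig,
                          rng: np.random.Generator | None = None) -> DomainSet:
    """Place non-overlapping true domains on chromosome arms.

    Per arm, log-normal lengths are accumulated until the running total is
    as close as possible to the arm's coverage target; domains are placed
    with at least ``domain_spacing`` bp between each other and the arm
    ends (so called islands never bridge into the pericentromere).
    """
    rng = rng if rng is not None else substream(config.seed, "domains")
    out: list[Interval] = []
    for chrom in layout.names:
        for arm_start, arm_end in layout.arms(chrom):
            arm_len = arm_end - arm_start
            target = config.domain_coverage * arm_len
            lengths: list[int] = []
            total = 0
            while True:
                cand = int(_sample_lengths(rng, 1, config.domain_median_bp,
                                           config.domain_log_sd,
                                           config.domain_min_bp)[0])
                if total + cand > target and abs(total + cand - target) >= abs(total - target):
                    break
                lengths.append(cand)
                total += cand
            n = len(lengths)
            if n == 0:
                continue
            spacing = config.domain_spacing
            required = total + spacing * (n + 1)
            if required > arm_len:
                raise ValueError(
                    f"cannot place {total} domain bp with {spacing} bp spacing "
                    f"on a {arm_len} bp arm; lower the coverage target")
            extra = arm_len - required
            # split the slack over the n+1 gaps
            parts = rng.dirichlet(np.ones(n + 1)) * extra
            gaps = spacing + np.floor(parts).astype(np.int64)
            pos = arm_start
            order = rng.permutation(n)
            for k in range(n):
                pos += int(gaps[k])
                length = lengths[order[k]]
                out.append(Interval(chrom, pos, pos + length))
                pos += length
    return DomainSet(tissue="synthetic", intervals=out, provenance="intersected")


def _enriched_segments(layout: GenomeLayout, domains: DomainSet,
                       include_peri: bool = True) -> dict[str, np.ndarray]:
    by = domains.by_chrom()
    segs = {}
    for chrom in layout.names:
        parts = [by.get(chrom, np.zeros((0, 2), dtype=np.int64))]
        if include_peri:
            ps, pe = layout.peri(chrom)
            if pe > ps:
                parts.append(np.array([[ps, pe]], dtype=np.int64))
        segs[chrom] = ivops.merge(np.concatenate(parts)) if any(len(p) for p in parts) \
            else np.zeros((0, 2), dtype=np.int64)
    return segs


def simulate_fragments(
    layout: GenomeLayout,
    truth: SyntheticTruth | DomainSet,
    config: SimulationConfig,
    sample_kind: str,
    replicate: int = 1,
    rng: np.random.Generator | None = None,
) -> FragmentSet:
    """Draw fragments from a piecewise-constant intensity.

    IgG: uniform over the genome. GFP: baseline intensity times
    ``gfp_fold`` inside true domains and inside pericentromeres. Exactly
    ``n_fragments`` fragments of fixed length are drawn.
    """
    if sample_kind not in ("GFP", "IgG"):
        raise ValueError("sample_kind must be GFP or IgG")
    domains = truth.domains if isinstance(truth, SyntheticTruth) else truth
    rng = rng if rng is not None else substream(config.seed, "fragments",
                                               sample_kind, replicate)
    enriched = _enriched_segments(layout, domains)
    seg_chrom, seg_bounds, seg_w = [], [], []
    for chrom, length in layout.chromosomes:
        pieces = enriched[chrom]
        cuts = np.unique(np.concatenate([[0, length], pieces.ravel()]))
        mids = (cuts[:-1] + cuts[1:]) / 2
        inside = np.zeros(len(mids), dtype=bool)
        if len(pieces):
            idx = np.searchsorted(pieces[:, 0], mids, side="right") - 1
            ok = idx >= 0
            inside[ok] = mids[ok] < pieces[idx[ok], 1]
        for (s, e), is_in in zip(zip(cuts[:-1], cuts[1:]), inside):
            w = config.gfp_fold if (sample_kind == "GFP" and is_in) else 1.0
            seg_chrom.append(chrom)
            seg_bounds.append((int(s), int(e)))
            seg_w.append(w * (e - s))
    p = np.asarray(seg_w) / np.sum(seg_w)
    counts = rng.multinomial(config.n_fragments, p)
    frags: list[Interval] = []
    flen = config.fragment_length
    for (chrom, (s, e)), c in zip(zip(seg_chrom, seg_bounds), counts):
        if c == 0:
            continue
        starts = np.sort(rng.integers(s, e, size=c))
        chrom_len = layout.length(chrom)
        for st in starts:
            frags.append(Interval(chrom, int(st), int(min(st + flen, chrom_len))))
    label = f"{sample_kind}_rep{replicate}"
    return FragmentSet(label=label, fragments=frags)


def _poisson_process(rng: np.random.Generator, segments: list[tuple[str, int, int]],
                     density: float) -> list[tuple[str, int]]:
    out = []
    for chrom, s, e in segments:
        n = rng.poisson(density * (e - s))
        for pos in np.sort(rng.integers(s, e, size=n)):
            out.append((chrom, int(pos)))
    return out


def simulate_annotations(
    layout: GenomeLayout,
    domains: DomainSet,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[GeneAnnotation], dict[str, bool], dict[str, str], dict[str, bool]]:
    """Genes/TEs/pseudogenes with expression; returns (genes, gene_enriched,
    te_class, te_peripheral).

    TE density inside true domains is ``te_density_ratio`` times the
    outside density; protein-coding genes whose span is >80% inside true
    domains draw expression from the lower-mean component. TEs are kept
    non-overlapping. TE pathway class: inside-domain TEs are
    CMT2-dependent with probability ``cmt2_bias``, outside TEs
    RdDM-dependent with the same probability.
    """
    rng = rng if rng is not None else substream(config.seed, "annotations")
    by = domains.by_chrom()
    inside_segs: list[tuple[str, int, int]] = []
    outside_segs: list[tuple[str, int, int]] = []
    arm_segs: list[tuple[str, int, int]] = []
    for chrom in layout.names:
        dom = ivops.merge(by.get(chrom, np.zeros((0, 2), dtype=np.int64)))
        for a_s, a_e in layout.arms(chrom):
            arm = np.array([[a_s, a_e]], dtype=np.int64)
            arm_segs.append((chrom, a_s, a_e))
            for s, e in ivops.intersect(dom, arm):
                inside_segs.append((chrom, int(s), int(e)))
            for s, e in ivops.intersect(ivops.complement(dom, layout.length(chrom)), arm):
                outside_segs.append((chrom, int(s), int(e)))

    genes: list[GeneAnnotation] = []
    te_class: dict[str, str] = {}
    te_peripheral: dict[str, bool] = {}
    merged_dom = {c: ivops.merge(arr) for c, arr in by.items()}

    def frac_in_domains(chrom: str, s: int, e: int) -> float:
        m = merged_dom.get(chrom)
        if m is None or len(m) == 0:
            return 0.0
        return float(ivops.overlap_bp(np.array([[s, e]]), m)[0]) / (e - s)

    # protein-coding genes: uniform density over arms
    pc_sites = _poisson_process(rng, arm_segs, config.pc_density)
    pc_lens = _sample_lengths(rng, len(pc_sites), config.pc_median_bp,
                              config.pc_log_sd, 200)
    gene_enriched: dict[str, bool] = {}
    for i, ((chrom, pos), length) in enumerate(zip(pc_sites, pc_lens)):
        end = min(pos + int(length), layout.length(chrom))
        if end - pos < 200:
            continue
        gid = f"PC{i + 1:05d}"
        enriched = frac_in_domains(chrom, pos, end) > 0.8
        mu = (config.pc_expr_log_mean_enriched if enriched
              else config.pc_expr_log_mean)
        expr = float(rng.lognormal(mu, config.expr_log_sd))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneAnnotation(gid, Interval(chrom, pos, end, strand=strand),
                                    strand=strand, biotype="protein_coding",
                                    expression=expr))
        gene_enriched[gid] = enriched

    # TE genes: two-density Poisson process, placed without self-overlap
    # by rejection sampling inside each segment (post-hoc thinning would
    # depress the realized inside-domain density below the configured ratio)
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in layout.names}

    def try_place(chrom: str, seg_s: int, seg_e: int, length: int) -> tuple[int, int] | None:
        for _ in range(30):
            pos = int(rng.integers(seg_s, seg_e))
            end = min(pos + length, layout.length(chrom))
            if end - pos < 300:
                continue
            if all(end <= s or pos >= e for s, e in placed[chrom]):
                placed[chrom].append((pos, end))
                return pos, end
        return None

    te_raw: list[tuple[str, int, int]] = []
    for segs, density in ((outside_segs, config.te_density_outside),
                          (inside_segs, config.te_density_outside * config.te_density_ratio)):
        for chrom, seg_s, seg_e in segs:
            n = rng.poisson(density * (seg_e - seg_s))
            lens = _sample_lengths(rng, n, config.te_median_bp,
                                   config.te_log_sd, 300)
            for length in lens:
                spot = try_place(chrom, seg_s, seg_e, int(length))
                if spot is not None:
                    te_raw.append((chrom, spot[0], spot[1]))
    te_raw.sort()
    ti = 0
    for chrom, s, e in te_raw:
        ti += 1
        tid = f"TE{ti:05d}"
        peripheral = frac_in_domains(chrom, s, e) > 0.8
        if peripheral:
            cls = TE_CLASSES[0] if rng.random() < config.cmt2_bias else TE_CLASSES[1]
        else:
            cls = TE_CLASSES[1] if rng.random() < config.cmt2_bias else TE_CLASSES[0]
        strand = "+" if rng.random() < 0.5 else "-"
        expr = float(rng.lognormal(config.te_expr_log_mean, config.expr_log_sd))
        genes.append(GeneAnnotation(tid, Interval(chrom, s, e, strand=strand),
                                    strand=strand, biotype="TE_gene", expression=expr))
        te_class[tid] = cls
        te_peripheral[tid] = peripheral
        gene_enriched[tid] = peripheral

    # pseudogenes: sparse, domain-biased like TEs
    ps_sites = _poisson_process(rng, inside_segs + outside_segs,
                                config.pseudogene_density)
    for i, (chrom, pos) in enumerate(ps_sites):
        end = min(pos + 1_000, layout.length(chrom))
        gid = f"PS{i + 1:04d}"
        genes.append(GeneAnnotation(gid, Interval(chrom, pos, end),
                                    biotype="pseudogene",
                                    expression=float(rng.lognormal(0.0, config.expr_log_sd))))
        gene_enriched[gid] = frac_in_domains(chrom, pos, end) > 0.8
    genes.sort(key=lambda g: (g.interval.chrom, g.interval.start))
    return genes, gene_enriched, te_class, te_peripheral


def compartment_labels(layout: GenomeLayout, domains: DomainSet,
                       binsize: int) -> dict[str, np.ndarray]:
    """Per-bin truth: 1 when >=50% of the bin overlaps domains or the
    pericentromere (the implicitly peripheral block)."""
    segs = _enriched_segments(layout, domains)
    labels = {}
    for chrom, length in layout.chromosomes:
        n = length // binsize
        starts = np.arange(n, dtype=np.int64) * binsize
        ov = ivops.overlap_bp(np.stack([starts, starts + binsize], axis=1),
                              segs[chrom])
        labels[chrom] = (ov >= binsize // 2).astype(int)
    return labels


def simulate_hic(
    layout: GenomeLayout,
    truth_labels: dict[str, np.ndarray],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, np.ndarray]:
    """Block-plus-decay contact matrices at ``hic_binsize`` resolution.

    contact(i, j) = (1 + |i - j|)^(-alpha) * (1 + contrast * same_label)
    * exp(eps_ij) with symmetric Gaussian log-noise of sd
    ``hic_noise_sd``. Matrices are exactly symmetric and positive.
    """
    rng = rng if rng is not None else substream(config.seed, "hic")
    out = {}
    for chrom, labels in truth_labels.items():
        n = len(labels)
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        decay = (1.0 + d) ** (-config.hic_decay_exponent)
        same = np.equal.outer(labels, labels)
        base = decay * (1.0 + config.hic_contrast * same)
        eps = rng.normal(0.0, config.hic_noise_sd, size=(n, n))
        eps = np.triu(eps) + np.triu(eps, 1).T
        out[chrom] = base * np.exp(eps)
    return out


def simulate_methylation(
    truth: SyntheticTruth,
    tes: list[GeneAnnotation],
    config: SimulationConfig,
    genotype: str,
    rng: np.random.Generator | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-context 100-bp-window methylation tracks over TE bodies.

    Window means follow context baselines (higher on peripheral TEs),
    scaled by genotype: met1-like zeroes CG everywhere; cmt3-like reduces
    CHG everywhere; cmt2-like multiplies CHH by ``cmt2_loss`` on
    CMT2-dependent TEs only; drm12-like does the same on RdDM-dependent
    TEs. Window noise is Beta-distributed around the mean.
    """
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}; expected one of {GENOTYPES}")
    rng = rng if rng is not None else substream(config.seed, "methylation", genotype)
    w = config.meth_window
    kappa = config.meth_concentration
    rows: dict[str, list[tuple[str, int, int, float]]] = {c: [] for c in CONTEXTS}
    for te in tes:
        peripheral = truth.te_peripheral.get(te.gene_id, False)
        cls = truth.te_class.get(te.gene_id, TE_CLASSES[1])
        iv = te.interval
        w0 = (iv.start // w) * w
        starts = np.arange(w0, iv.end, w, dtype=np.int64)
        for context in CONTEXTS:
            hi, lo = config.meth_baselines[context]
            mu = hi if peripheral else lo
            if genotype == "met1-like" and context == "CG":
                mu = 0.0
            elif genotype == "cmt3-like" and context == "CHG":
                mu *= config.cmt3_chg_factor
            elif genotype == "cmt2-like" and context == "CHH" \
                    and cls == "CMT2-dependent":
                mu *= config.cmt2_loss
            elif genotype == "drm12-like" and context == "CHH" \
                    and cls == "RdDM-dependent":
                mu *= config.drm_loss
            if mu <= 0:
                vals = np.zeros(len(starts))
            elif mu >= 1:
                vals = np.ones(len(starts))
            else:
                vals = rng.beta(mu * kappa, (1 - mu) * kappa, size=len(starts))
            for s, v in zip(starts, vals):
                rows[context].append((iv.chrom, int(s), int(s + w), float(v)))
    return {c: pd.DataFrame(r, columns=["chrom", "start", "end", "value"])
            for c, r in rows.items()}


def simulate_sequence(
    layout: GenomeLayout,
    domains: DomainSet,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, str]:
    """i.i.d. nucleotide sequence with configurable GC inside/outside domains."""
    rng = rng if rng is not None else substream(config.seed, "sequence")
    enriched = _enriched_segments(layout, domains, include_peri=False)
    letters = np.frombuffer(b"ACGT", dtype=np.uint8)
    out = {}
    for chrom, length in layout.chromosomes:
        arr = np.empty(length, dtype=np.uint8)
        cuts = np.unique(np.concatenate([[0, length], enriched[chrom].ravel()]))
        for s, e in zip(cuts[:-1], cuts[1:]):
            mid = (s + e) / 2
            pieces = enriched[chrom]
            inside = False
            if len(pieces):
                k = np.searchsorted(pieces[:, 0], mid, side="right") - 1
                inside = k >= 0 and mid < pieces[k, 1]
            gc = config.gc_inside if inside else config.gc_outside
            p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
            arr[s:e] = rng.choice(letters, size=e - s, p=p)
        out[chrom] = arr.tobytes().decode("ascii")
    return out


def simulate_loops(
    layout: GenomeLayout,
    domains: DomainSet,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[tuple[Interval, Interval]]:
    """Chromatin loops with a configured intra/across/outside class mix."""
    rng = rng if rng is not None else substream(config.seed, "loops")
    a = config.loop_anchor_bp
    by = {c: ivops.merge(arr) for c, arr in domains.by_chrom().items()}
    big = [(c, int(s), int(e)) for c, arr in by.items()
           for s, e in arr if e - s >= 2 * a + 1000]
    outside = []
    for chrom, length in layout.chromosomes:
        comp = ivops.complement(by.get(chrom, np.zeros((0, 2), dtype=np.int64)), length)
        outside += [(chrom, int(s), int(e)) for s, e in comp if e - s >= a + 1000]

    def pick_anchor(seg: tuple[str, int, int]) -> Interval:
        chrom, s, e = seg
        start = int(rng.integers(s, e - a))
        return Interval(chrom, start, start + a)

    loops = []
    for _ in range(config.n_loops):
        u = rng.random()
        if u < config.loop_intra_frac and big:
            chrom, s, e = big[rng.integers(len(big))]
            s1 = int(rng.integers(s, e - a))
            s2 = int(rng.integers(s, e - a))
            loops.append((Interval(chrom, min(s1, s2), min(s1, s2) + a),
                          Interval(chrom, max(s1, s2), max(s1, s2) + a)))
        elif u < config.loop_intra_frac + config.loop_across_frac and big and outside:
            seg_in = big[rng.integers(len(big))]
            cands = [o for o in outside if o[0] == seg_in[0]]
            seg_out = cands[rng.integers(len(cands))]
            pair = sorted([pick_anchor(seg_in), pick_anchor(seg_out)],
                          key=lambda iv: iv.start)
            loops.append((pair[0], pair[1]))
        else:
            chrom = layout.names[rng.integers(len(layout.names))]
            cands = [o for o in outside if o[0] == chrom]
            pair = sorted([pick_anchor(cands[rng.integers(len(cands))]),
                           pick_anchor(cands[rng.integers(len(cands))])],
                          key=lambda iv: iv.start)
            loops.append((pair[0], pair[1]))
    return loops


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    layout: GenomeLayout
    truth: SyntheticTruth
    fragments: dict[str, FragmentSet]          # "GFP_rep1", "IgG_rep1", ...
    genes: list[GeneAnnotation]
    hic: dict[str, np.ndarray]
    methylation: dict[str, dict[str, pd.DataFrame]]  # genotype -> context -> track
    loops: list[tuple[Interval, Interval]]

    @property
    def tes(self) -> list[GeneAnnotation]:
        return [g for g in self.genes if g.biotype == "TE_gene"]

    @property
    def expression(self) -> dict[str, float]:
        return {g.gene_id: g.expression for g in self.genes}


def generate_dataset(config: SimulationConfig,
                     genotypes: tuple[str, ...] = GENOTYPES) -> SyntheticDataset:
    """Generate a full dataset; deterministic given (config, config.seed)."""
    layout = simulate_layout(config)
    domains = simulate_true_domains(layout, config)
    genes, gene_enriched, te_class, te_peripheral = simulate_annotations(
        layout, domains, config)
    labels = compartment_labels(layout, domains, config.hic_binsize)
    truth = SyntheticTruth(domains=domains, compartments=labels,
                           te_class=te_class, te_peripheral=te_peripheral,
                           gene_enriched=gene_enriched)
    fragments = {}
    for kind in ("GFP", "IgG"):
        for rep in range(1, config.n_replicates + 1):
            fs = simulate_fragments(layout, truth, config, kind, rep)
            fragments[fs.label] = fs
    hic = simulate_hic(layout, labels, config)
    tes = [g for g in genes if g.biotype == "TE_gene"]
    methylation = {g: simulate_methylation(truth, tes, config, g)
                   for g in genotypes}
    loops = simulate_loops(layout, domains, config)
    return SyntheticDataset(config=config, layout=layout, truth=truth,
                            fragments=fragments, genes=genes, hic=hic,
                            methylation=methylation, loops=loops)


def write_dataset(ds: SyntheticDataset, outdir: str | os.PathLike,
                  write_sequence: bool = False) -> dict[str, str]:
    """Write every component in the formats the readers consume."""
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}

    def p(name: str) -> str:
        paths[name] = os.path.join(outdir, name)
        return paths[name]

    pio.write_layout(ds.layout, p("layout.tsv"))
    pio.write_bed(ds.truth.domains.intervals, p("true_domains.bed"))
    for label, fs in ds.fragments.items():
        pio.write_fragments(fs, p(f"fragments_{label}.bed"))
    pio.write_gff3_genes(ds.genes, p("genes.gff3"))
    pio.write_expression_tsv(ds.expression, p("expression.tsv"))
    for chrom, mat in ds.hic.items():
        pio.write_dense_matrix(mat, p(f"hic_{chrom}.tsv"))
    for genotype, tracks in ds.methylation.items():
        tag = genotype.replace("-like", "")
        for context, df in tracks.items():
            pio.write_bedgraph(df, p(f"meth_{tag}_{context}.bedGraph"))
    pio.write_bedpe(ds.loops, p("loops.bedpe"))
    if write_sequence:
        seqs = simulate_sequence(ds.layout, ds.truth.domains, ds.config)
        pio.write_fasta(seqs, p("genome.fa"))
    truth_json = {
        "te_class": ds.truth.te_class,
        "te_peripheral": ds.truth.te_peripheral,
        "gene_enriched": ds.truth.gene_enriched,
        "compartments": {c: v.tolist() for c, v in ds.truth.compartments.items()},
    }
    with open(p("truth.json"), "w") as fh:
        json.dump(truth_json, fh)
    return paths
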