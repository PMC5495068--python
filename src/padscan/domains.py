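"""Broad-domain (island) calling and domain bookkeeping.

The caller follows the island framework used for broad heterochromatic
marks: the genome is tiled into W-bp windows, windows with fragment
counts improbably high under a genome-wide Poisson background are
eligible, eligible windows separated by at most G bp of ineligible
windows are chained into islands, and each island is scored by the
Poisson upper tail of its aggregate count against the larger of the
depth-scaled control and the genome background. Islands passing a
Benjamini-Hochberg FDR cut are kept. Replicate calls are intersected at
bp level into the final periphery-enriched domain set.

Defaults are W = 1000 bp, G = 3000 bp, FDR < 0.01.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import intervals as ivops
from .core import GeneAnnotation, GenomeLayout, Interval
from .tracks import BinnedTrack

log = logging.getLogger(__name__)


@dataclass
class IslandParams:
    window: int = 1000           # W
    gap: int = 3000              # G, multiple of W
    fdr: float = 0.01
    p_eligible: float = 0.2      # window eligibility Poisson tail threshold
    lambda_floor: float = 1e-3   # background floor, windows/window

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.gap % self.window != 0:
            raise ValueError("gap must be a multiple of window")
        if not (0 < self.fdr < 1):
            raise ValueError("fdr must be in (0, 1)")


@dataclass
class Island:
    interval: Interval
    chip_count: float
    control_scaled: float
    score: float      # sum of -log10 window eligibility p over eligible windows
    pvalue: float
    qvalue: float = float("nan")


@dataclass
class DomainSet:
    """Sorted enriched intervals; non-overlap enforced for called sets."""

    tissue: str
    intervals: list[Interval]
    provenance: str = "replicate_call"  # replicate_call | intersected | shifted

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        if self.provenance in ("replicate_call", "intersected"):
            prev: Interval | None = None
            for iv in self.intervals:
                if prev is not None and iv.chrom == prev.chrom and iv.start < prev.end:
                    raise ValueError(
                        f"overlapping domains {prev.chrom}:{prev.start}-{prev.end} "
                        f"and {iv.chrom}:{iv.start}-{iv.end}")
                prev = iv

    def by_chrom(self) -> dict[str, np.ndarray]:
        return ivops.by_chrom(self.intervals)

    @property
    def total_bp(self) -> int:
        return sum(len(iv) for iv in self.intervals)


def _poisson_upper_tail(count: float, lam: float) -> float:
    # P(X >= count) for X ~ Poisson(lam)
    return float(stats.poisson.sf(np.ceil(count) - 1, lam))


def call_islands(
    chip: BinnedTrack,
    control: BinnedTrack | None,
    layout: GenomeLayout,
    params: IslandParams = IslandParams(),
) -> list[Island]:
    """Call enriched islands from raw W-bp count tracks.

    ``chip`` and ``control`` must be raw counts at ``params.window``.
    With an empty (or missing) control the island test falls back to the
    genome background alone, with a logged warning. Control depth scaling
    is internal, so the output is invariant under uniform rescaling of
    control depth.
    """
    if chip.normalization != "raw":
        raise ValueError("call_islands expects raw count tracks")
    if chip.window != params.window:
        raise ValueError(f"chip track window {chip.window} != W {params.window}")
    total_windows = sum(len(v) for v in chip.values.values())
    chip_total = chip.total()
    lam_bg = max(chip_total / total_windows, params.lambda_floor)

    control_total = control.total() if control is not None else 0.0
    use_control = control_total > 0
    if not use_control:
        log.warning("call_islands: empty control; using genome background only")
        scale = 0.0
    else:
        if control.window != params.window:
            raise ValueError("control track window mismatch")
        scale = chip_total / control_total

    gap_windows = params.gap // params.window
    islands: list[Island] = []
    for chrom, length in layout.chromosomes:
        counts = chip.values[chrom]
        pvals = stats.poisson.sf(counts - 1, lam_bg)
        eligible = np.flatnonzero(pvals < params.p_eligible)
        if len(eligible) == 0:
            continue
        # chain eligible windows allowing <= gap_windows ineligible between
        breaks = np.flatnonzero(np.diff(eligible) - 1 > gap_windows)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(eligible) - 1]])
        for a, b in zip(starts, ends):
            w0, w1 = int(eligible[a]), int(eligible[b])
            span = slice(w0, w1 + 1)
            chip_agg = float(counts[span].sum())
            n_windows = w1 - w0 + 1
            ctrl_scaled = float(control.values[chrom][span].sum()) * scale if use_control else 0.0
            mean = max(ctrl_scaled, lam_bg * n_windows)
            p = _poisson_upper_tail(chip_agg, mean)
            score = float(-np.log10(np.maximum(pvals[eligible[a:b + 1]], 1e-300)).sum())
            iv = Interval(chrom, w0 * params.window,
                          min((w1 + 1) * params.window, length))
            islands.append(Island(iv, chip_agg, ctrl_scaled, score, p))

    _bh_adjust(islands)
    kept = [isl for isl in islands if isl.qvalue < params.fdr]
    return kept


def _bh_adjust(islands: list[Island]) -> None:
    """Benjamini-Hochberg q-values, in place."""
    m = len(islands)
    if m == 0:
        return
    order = np.argsort([isl.pvalue for isl in islands], kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        val = islands[idx].pvalue * m / rank_from_top
        prev = min(prev, val)
        q[idx] = prev
    for isl, qv in zip(islands, q):
        isl.qvalue = float(qv)


def islands_to_domains(islands: list[Island], tissue: str = "") -> DomainSet:
    """Wrap kept islands as a domain set; BED score column is -log10 q."""
    ivs = [Interval(isl.interval.chrom, isl.interval.start, isl.interval.end,
                    score=-np.log10(max(isl.qvalue, 1e-300)))
           for isl in islands]
    return DomainSet(tissue=tissue, intervals=ivs, provenance="replicate_call")


def intersect_replicates(rep1: DomainSet, rep2: DomainSet) -> DomainSet:
    """bp-level intersection of two replicate domain sets."""
    a, b = rep1.by_chrom(), rep2.by_chrom()
    out: list[Interval] = []
    for chrom in sorted(set(a) & set(b)):
        for s, e in ivops.intersect(a[chrom], b[chrom]):
            out.append(Interval(chrom, int(s), int(e)))
    return DomainSet(tissue=rep1.tissue or rep2.tissue, intervals=out,
                     provenance="intersected")


def clip_to_arms(domains: DomainSet, layout: GenomeLayout) -> DomainSet:
    """Restrict a domain set to chromosome arms (drop pericentromeric bp)."""
    by = domains.by_chrom()
    out: list[Interval] = []
    for chrom in layout.names:
        if chrom not in by:
            continue
        arms = np.array(layout.arms(chrom), dtype=np.int64).reshape(-1, 2)
        for s, e in ivops.intersect(by[chrom], arms):
            out.append(Interval(chrom, int(s), int(e)))
    return DomainSet(tissue=domains.tissue, intervals=out, provenance=domains.provenance)


def domain_summary(domains: DomainSet, layout: GenomeLayout) -> dict:
    """Coverage and size summary of a (non-overlapping) domain set."""
    total = domains.total_bp
    arm_clipped = clip_to_arms(domains, layout)
    lengths = [len(iv) for iv in domains.intervals]
    return {
        "count": len(domains.intervals),
        "genome_coverage": total / layout.total_bp,
        "arm_coverage": (arm_clipped.total_bp / layout.total_arm_bp
                         if layout.total_arm_bp else 0.0),
        "median_length": float(statistics.median(lengths)) if lengths else None,
        "total_bp": total,
    }


def assign_enriched_genes(
    genes: list[GeneAnnotation], domains: DomainSet, threshold: float = 0.8
) -> dict[str, bool]:
    """Flag genes whose transcribed region overlaps domains by strictly >80%."""
    merged = {c: ivops.merge(arr) for c, arr in domains.by_chrom().items()}
    idx_by_chrom: dict[str, list[int]] = {}
    for k, g in enumerate(genes):
        idx_by_chrom.setdefault(g.interval.chrom, []).append(k)
    enriched = np.zeros(len(genes), dtype=bool)
    for chrom, idxs in idx_by_chrom.items():
        m = merged.get(chrom)
        if m is None or len(m) == 0:
            continue
        q = np.array([[genes[k].interval.start, genes[k].interval.end]
                      for k in idxs], dtype=np.int64)
        ov = ivops.overlap_bp(q, m)
        enriched[idxs] = ov / (q[:, 1] - q[:, 0]) > threshold
    return {g.gene_id: bool(enriched[k]) for k, g in enumerate(genes)}


def filter_pericentromere_distance(
    items: list[Interval], layout: GenomeLayout, min_dist: int = 1_000_000
) -> list[Interval]:
    """Keep items at least ``min_dist`` bp (inclusive) from the pericentromere.

    Items overlapping the pericentromere are removed. Chromosomes without
    an annotated pericentromere keep all their items.
    """
    out = []
    for iv in items:
        ps, pe = layout.peri(iv.chrom)
        if ps >= pe:
            out.append(iv)
            continue
        if iv.end <= ps:
            dist = ps - iv.end
        elif iv.start >= pe:
            dist = iv.start - pe
        else:
            continue  # overlaps pericentromere
        if dist >= min_dist:
            out.append(iv)
    return out


def tissue_overlap(gene_sets: dict[str, set[str]]) -> dict[tuple[str, ...], int]:
    """Exclusive Venn-cell counts of enriched-gene sets across tissues.

    Returns a mapping from the sorted tuple of tissues sharing a gene
    (the Venn cell) to the number of genes exactly in that cell. Cells
    sum to the size of the union.
    """
    if len(gene_sets) < 2:
        raise ValueError("need at least two tissues")
    universe = set().union(*gene_sets.values())
    cells: dict[tuple[str, ...], int] = {}
    for gene in universe:
        key = tuple(sorted(t for t, s in gene_sets.items() if gene in s))
        cells[key] = cells.get(key, 0) + 1
    return cells
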