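"""Permutation nulls, gene-class enrichment, loop classification and
expression comparisons.

The null model preserves the genomic arrangement of the called domains:
each domain is translated by +/-50 kb or +/-100 kb (sign and magnitude
drawn independently per domain each round), and the statistic of
interest is recomputed on the shifted set. Empirical p-values use the
standard +1 correction so they are never zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from . import intervals as ivops
from .core import GeneAnnotation, GenomeLayout, Interval
from .domains import DomainSet, assign_enriched_genes

log = logging.getLogger(__name__)

DEFAULT_MAGNITUDES = (50_000, 100_000)


@dataclass
class ShiftNull:
    statistic: str
    observed: float
    null: np.ndarray
    magnitudes: tuple[int, ...]
    p_greater: float
    p_less: float
    p_two_sided: float
    seed: int | None = None


@dataclass
class LoopClassCounts:
    intra: int
    across: int
    outside: int
    excluded_trans: int = 0

    @property
    def total(self) -> int:
        return self.intra + self.across + self.outside


def shift_domains(
    domains: DomainSet,
    layout: GenomeLayout,
    rng: np.random.Generator,
    magnitudes: tuple[int, ...] = DEFAULT_MAGNITUDES,
) -> DomainSet:
    """Translate each domain by an independently drawn signed magnitude.

    Domains pushed past a chromosome edge are reflected back inside
    (about the edge), preserving the length multiset and the count.
    Overlaps created by shifting are left as-is.
    """
    out: list[Interval] = []
    for iv in domains.intervals:
        chrom_len = layout.length(iv.chrom)
        if len(iv) > chrom_len:
            raise ValueError(f"domain longer than chromosome {iv.chrom}")
        mag = int(rng.choice(magnitudes))
        sign = 1 if rng.random() < 0.5 else -1
        s, e = iv.start + sign * mag, iv.end + sign * mag
        if s < 0:
            s, e = -e, -s                       # reflect about 0
            if s < 0:                           # straddled the edge: slide flush
                s, e = 0, e - s
        if e > chrom_len:
            s, e = 2 * chrom_len - e, 2 * chrom_len - s  # reflect about the end
            if e > chrom_len:
                s, e = chrom_len - (e - s), chrom_len
        # shifts larger than the chromosome: slide flush to the nearer edge
        if s < 0:
            s, e = 0, e - s
        if e > chrom_len:
            s, e = chrom_len - (e - s), chrom_len
        out.append(Interval(iv.chrom, s, e))
    return DomainSet(tissue=domains.tissue, intervals=out, provenance="shifted")


def count_genes_in_domains(
    genes: list[GeneAnnotation],
    domains: DomainSet,
    biotype: str | None = None,
) -> int:
    """Number of genes enriched (strict >80% overlap) with matching biotype."""
    pool = [g for g in genes if biotype is None or g.biotype == biotype]
    flags = assign_enriched_genes(pool, domains)
    return sum(flags[g.gene_id] for g in pool)


def permutation_test(
    statistic,
    domains: DomainSet,
    layout: GenomeLayout,
    n_perm: int = 999,
    magnitudes: tuple[int, ...] = DEFAULT_MAGNITUDES,
    seed: int | None = None,
    name: str = "statistic",
) -> ShiftNull:
    """Coordinate-shift permutation test of ``statistic(domains)``.

    The null is built by recomputing the statistic on ``n_perm``
    independently shifted domain sets. One-sided empirical p-values use
    (1 + #{null >= observed}) / (n_perm + 1); the two-sided p doubles the
    smaller tail, capped at 1.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    observed = float(statistic(domains))
    null = np.empty(n_perm)
    for i in range(n_perm):
        shifted = shift_domains(domains, layout, rng, magnitudes=magnitudes)
        try:
            null[i] = float(statistic(shifted))
        except Exception as exc:
            raise RuntimeError(f"statistic failed on permutation {i}: {exc}") from exc
    p_greater = (1 + int((null >= observed).sum())) / (n_perm + 1)
    p_less = (1 + int((null <= observed).sum())) / (n_perm + 1)
    p_two = min(1.0, 2 * min(p_greater, p_less))
    return ShiftNull(name, observed, null, tuple(magnitudes),
                     p_greater, p_less, p_two, seed=seed)


def _anchor_domain(anchor: Interval, merged: dict[str, np.ndarray]) -> int | None:
    """Index of the domain holding >50% of the anchor's bp, else None."""
    arr = merged.get(anchor.chrom)
    if arr is None or len(arr) == 0:
        return None
    q = np.array([[anchor.start, anchor.end]])
    # per-domain overlap: domains are merged, so test each row
    best_idx, best_ov = None, 0
    lo = np.searchsorted(arr[:, 1], anchor.start, side="right")
    hi = np.searchsorted(arr[:, 0], anchor.end, side="left")
    for i in range(lo, hi):
        ov = min(anchor.end, arr[i, 1]) - max(anchor.start, arr[i, 0])
        if ov > best_ov:
            best_ov, best_idx = ov, i
    if best_idx is not None and best_ov > 0.5 * len(anchor):
        return int(best_idx)
    return None


def classify_loops(
    loops: list[tuple[Interval, Interval]], domains: DomainSet
) -> LoopClassCounts:
    """Classify loops as intra-domain / across-boundary / outside.

    An anchor belongs to a domain when >50% of its bp fall inside that
    single domain. intra: both anchors in the same domain; across: exactly
    one anchor in a domain, or the two anchors in different domains;
    outside: neither anchor in a domain. Trans-chromosomal loops are
    excluded and counted separately.
    """
    merged = {c: ivops.merge(arr) for c, arr in domains.by_chrom().items()}
    # give each merged row a global id so same-domain tests work across chroms
    offsets = {}
    off = 0
    for c in sorted(merged):
        offsets[c] = off
        off += len(merged[c])
    intra = across = outside = trans = 0
    for a, b in loops:
        if a.chrom != b.chrom:
            trans += 1
            continue
        da = _anchor_domain(a, merged)
        db = _anchor_domain(b, merged)
        ga = None if da is None else offsets[a.chrom] + da
        gb = None if db is None else offsets[b.chrom] + db
        if ga is None and gb is None:
            outside += 1
        elif ga is not None and gb is not None and ga == gb:
            intra += 1
        else:
            across += 1
    if trans:
        log.info("classify_loops: excluded %d trans-chromosomal loops", trans)
    return LoopClassCounts(intra=intra, across=across, outside=outside,
                           excluded_trans=trans)


def rank_sum_compare(a, b) -> dict[str, float]:
    """Mann-Whitney U comparison of two value sets.

    Uses the exact null distribution when the pooled sample is small
    (n_A + n_B <= 12) and untied, otherwise the tie-corrected normal
    approximation with continuity correction. Returns the U statistic of
    the first sample and the two-sided p-value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    untied = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= 12 and untied) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return {"U": float(res.statistic), "p": float(res.pvalue)}


def matched_control_genes(
    genes: list[GeneAnnotation],
    enriched_ids: set[str],
    n: int = 3000,
    n_bins: int = 20,
    seed: int | None = None,
) -> list[str]:
    """Sample control genes matching the enriched expression distribution.

    The enriched genes' expression values are split into ``n_bins``
    quantile bins; controls are drawn from the non-enriched pool
    proportionally to bin occupancy, without replacement per bin (with
    replacement only when a bin's pool is exhausted, logged).
    """
    rng = np.random.default_rng(seed)
    enr = [g for g in genes if g.gene_id in enriched_ids]
    pool = [g for g in genes if g.gene_id not in enriched_ids]
    if not enr:
        raise ValueError("no enriched genes")
    if not pool:
        raise ValueError("non-enriched pool is empty")
    expr = np.array([g.expression for g in enr])
    n_bins_eff = min(n_bins, len(np.unique(expr)))
    if n_bins_eff < n_bins:
        log.warning("matched_control_genes: reducing bins %d -> %d "
                    "(few distinct expression values)", n_bins, n_bins_eff)
    edges = np.quantile(expr, np.linspace(0, 1, n_bins_eff + 1))
    edges[0], edges[-1] = -np.inf, np.inf

    def bin_of(values: np.ndarray) -> np.ndarray:
        return np.clip(np.searchsorted(edges, values, side="right") - 1,
                       0, n_bins_eff - 1)

    enr_bins = bin_of(expr)
    pool_expr = np.array([g.expression for g in pool])
    pool_bins = bin_of(pool_expr)
    # apportion n across bins by occupancy (largest remainder)
    counts = np.bincount(enr_bins, minlength=n_bins_eff)
    raw = n * counts / counts.sum()
    take = np.floor(raw).astype(int)
    rem = n - take.sum()
    if rem > 0:
        order = np.argsort(-(raw - take), kind="stable")
        take[order[:rem]] += 1
    chosen: list[str] = []
    for b in range(n_bins_eff):
        want = int(take[b])
        if want == 0:
            continue
        members = np.flatnonzero(pool_bins == b)
        if len(members) >= want:
            pick = rng.choice(members, size=want, replace=False)
        else:
            log.warning("matched_control_genes: bin %d pool exhausted "
                        "(%d < %d); sampling with replacement", b, len(members), want)
            if len(members) == 0:
                members = np.arange(len(pool))
            pick = rng.choice(members, size=want, replace=True)
        chosen.extend(pool[i].gene_id for i in pick)
    return chosen
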