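"""Boundary-anchored and length-normalised metaprofiles.

Two anchor geometries: (1) domain-boundary profiles, where 100-bp
windows in a +/-20-kb flank are oriented so positive positions point
into the domain and averaged across boundaries (for binary marks the
mean is the percent of windows enriched); (2) scaled TE-body metaplots,
where each element's per-window methylation is linearly rescaled onto a
fixed number of body bins so the boundaries of all elements align,
strand-aware.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import intervals as ivops
from .core import GeneAnnotation, GenomeLayout, Interval
from .domains import DomainSet
from .tracks import BinnedTrack

log = logging.getLogger(__name__)


@dataclass
class MetaProfile:
    kind: str                 # "domain_boundary" | "scaled_body"
    positions: np.ndarray     # bp offsets (boundary) or body-bin index (body)
    mean: np.ndarray
    n: np.ndarray
    group: str = ""

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.positions) > 0):
            raise ValueError("profile axis must be strictly increasing")


def _boundary_anchors(domains: DomainSet, layout: GenomeLayout,
                      flank: int) -> list[tuple[str, int, int]]:
    """(chrom, boundary bp, direction) anchors; direction +1 means the
    domain lies to the right. Boundaries whose flank leaves the
    chromosome are dropped."""
    anchors = []
    for iv in domains.intervals:
        chrom_len = layout.length(iv.chrom)
        if iv.start - flank >= 0 and iv.start + flank <= chrom_len:
            anchors.append((iv.chrom, iv.start, +1))
        if iv.end - flank >= 0 and iv.end + flank <= chrom_len:
            anchors.append((iv.chrom, iv.end, -1))
    return anchors


def boundary_profile(
    mark,
    domains: DomainSet,
    layout: GenomeLayout,
    flank: int = 20_000,
    window: int = 100,
    group: str = "",
) -> MetaProfile:
    """Average a mark around domain boundaries, oriented into the domain.

    ``mark`` is either a list of intervals (binary mark: a window scores
    1 when it overlaps any mark region) or a 100-bp :class:`BinnedTrack`
    (numeric: a window scores its track value). Positions are window-start
    offsets; positive offsets point into the domain.
    """
    anchors = _boundary_anchors(domains, layout, flank)
    if not anchors:
        raise ValueError("no usable domain boundaries (flanks exit chromosomes)")
    offsets = np.arange(-flank, flank, window, dtype=np.int64)
    binary = not isinstance(mark, BinnedTrack)
    if binary:
        merged = {c: ivops.merge(arr) for c, arr in ivops.by_chrom(mark).items()}
    acc = np.zeros(len(offsets))
    cnt = np.zeros(len(offsets))
    for chrom, pos, direction in anchors:
        if direction > 0:
            starts = pos + offsets
        else:
            starts = pos - offsets - window
        ends = starts + window
        if binary:
            m = merged.get(chrom, np.zeros((0, 2), dtype=np.int64))
            ov = ivops.overlap_bp(np.stack([starts, ends], axis=1), m)
            vals = (ov > 0).astype(float)
            ok = np.ones(len(offsets), dtype=bool)
        else:
            if mark.window != window:
                raise ValueError("numeric track window must match the profile window")
            track = mark.values[chrom]
            tmask = mark.mask[chrom]
            idx = starts // window
            ok = (idx >= 0) & (idx < len(track))
            vals = np.zeros(len(offsets))
            vals[ok] = track[idx[ok]]
            ok = ok & ~np.where(ok, tmask[np.clip(idx, 0, len(track) - 1)], True)
        acc[ok] += vals[ok]
        cnt[ok] += 1
    if not cnt.any():
        raise ValueError("no boundary contributed any window")
    mean = np.divide(acc, cnt, out=np.full_like(acc, np.nan), where=cnt > 0)
    return MetaProfile(kind="domain_boundary", positions=offsets, mean=mean,
                       n=cnt.astype(int), group=group)


def scaled_body_profile(
    track: BinnedTrack,
    features: list[Interval],
    n_body_bins: int = 40,
    group: str = "",
) -> MetaProfile:
    """Length-normalised metaplot of a per-window track over feature bodies.

    Each feature's 100-bp-window values are expanded to bp resolution and
    averaged within ``n_body_bins`` equal body bins, so the boundaries of
    all features align and every feature contributes to every bin. Minus-
    strand features are reversed. Features shorter than one track window
    are skipped (counted in a log message).
    """
    if not features:
        raise ValueError("no features")
    w = track.window
    sums = np.zeros(n_body_bins)
    counts = np.zeros(n_body_bins, dtype=int)
    skipped = 0
    for feat in features:
        length = len(feat)
        if length < w:
            skipped += 1
            continue
        vals = track.values[feat.chrom]
        tmask = track.mask[feat.chrom]
        b0, b1 = feat.start // w, -(-feat.end // w)
        win_vals = np.where(tmask[b0:b1], np.nan, vals[b0:b1])
        bp = np.repeat(win_vals, w)[feat.start - b0 * w: feat.start - b0 * w + length]
        if feat.strand == "-":
            bp = bp[::-1]
        edges = np.round(np.linspace(0, length, n_body_bins + 1)).astype(int)
        with np.errstate(invalid="ignore"):
            bin_means = np.array([
                np.nanmean(bp[edges[i]:edges[i + 1]]) if edges[i] < edges[i + 1]
                else np.nan
                for i in range(n_body_bins)
            ])
        ok = ~np.isnan(bin_means)
        sums[ok] += bin_means[ok]
        counts[ok] += 1
    if skipped:
        log.info("scaled_body_profile: skipped %d features shorter than one window",
                 skipped)
    if not counts.any():
        raise ValueError("no feature contributed to the profile")
    mean = np.divide(sums, counts, out=np.full_like(sums, np.nan), where=counts > 0)
    return MetaProfile(kind="scaled_body", positions=np.arange(n_body_bins),
                       mean=mean, n=counts, group=group)


def group_tes_by_location(
    tes: list[GeneAnnotation] | list[Interval],
    domains: DomainSet,
    threshold: float = 0.8,
) -> tuple[list, list]:
    """Partition TEs into (peripheral, non-peripheral) by the strict >80%
    domain-overlap rule used for gene enrichment."""
    merged = {c: ivops.merge(arr) for c, arr in domains.by_chrom().items()}
    peripheral, interior = [], []
    for te in tes:
        iv = te.interval if isinstance(te, GeneAnnotation) else te
        m = merged.get(iv.chrom, np.zeros((0, 2), dtype=np.int64))
        ov = ivops.overlap_bp(np.array([[iv.start, iv.end]]), m)[0]
        (peripheral if ov / len(iv) > threshold else interior).append(te)
    return peripheral, interior


@dataclass
class ProfileContrast:
    positions: np.ndarray
    difference: np.ndarray   # mutant - WT per bin
    ratio: np.ndarray        # (mutant + c) / (WT + c)
    mean_difference: float


def genotype_contrast(
    profile_wt: MetaProfile, profile_mut: MetaProfile, pseudocount: float = 0.01
) -> ProfileContrast:
    """Per-bin mutant-vs-WT difference and ratio of two matched profiles."""
    if (profile_wt.kind != profile_mut.kind
            or len(profile_wt.positions) != len(profile_mut.positions)
            or np.any(profile_wt.positions != profile_mut.positions)):
        raise ValueError("profiles have mismatched axes")
    diff = profile_mut.mean - profile_wt.mean
    ratio = (profile_mut.mean + pseudocount) / (profile_wt.mean + pseudocount)
    return ProfileContrast(positions=profile_wt.positions, difference=diff,
                           ratio=ratio, mean_difference=float(np.nanmean(diff)))
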