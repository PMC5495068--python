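"""Binned coverage tracks and log2 pull-down/control signal.

The RE-ChIP signal is summarised as fixed-window fragment counts per
chromosome (50-kb windows for chromosome-scale overviews, 20-kb for
compartment comparison, 1-kb for island calling, 100-bp for boundary
metaprofiles), depth-normalised to fragments-per-million, and contrasted
against the IgG control as log2((GFP + c) / (IgG + c)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import FragmentSet, GenomeLayout

log = logging.getLogger(__name__)


@dataclass
class BinnedTrack:
    """Fixed-window numeric vectors per chromosome with a mask of undefined bins."""

    window: int
    values: dict[str, np.ndarray]
    normalization: str = "raw"  # "raw" | "per-million" | "log2-ratio"
    total_fragments: int | None = None
    mask: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, v in self.values.items():
            if chrom not in self.mask:
                self.mask[chrom] = np.zeros(len(v), dtype=bool)

    def n_bins(self, chrom: str) -> int:
        return len(self.values[chrom])

    def total(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))

    def to_bedgraph(self) -> pd.DataFrame:
        rows = []
        for chrom, v in self.values.items():
            starts = np.arange(len(v), dtype=np.int64) * self.window
            keep = ~self.mask[chrom]
            rows.append(pd.DataFrame({
                "chrom": chrom,
                "start": starts[keep],
                "end": starts[keep] + self.window,
                "value": v[keep],
            }))
        return pd.concat(rows, ignore_index=True)


def n_bins(length: int, window: int) -> int:
    return -(-length // window)  # ceil


def bin_fragments(fragments: FragmentSet, layout: GenomeLayout, window: int) -> BinnedTrack:
    """Count fragments per window, assigning each fragment by its midpoint.

    Fragments on chromosomes absent from the layout are skipped with a
    counted warning. The bin total equals the number of assigned fragments.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    lengths = dict(layout.chromosomes)
    values = {c: np.zeros(n_bins(l, window), dtype=np.int64) for c, l in layout.chromosomes}
    skipped = 0
    per_chrom: dict[str, list[int]] = {c: [] for c in lengths}
    for frag in fragments.fragments:
        if frag.chrom not in lengths:
            skipped += 1
            continue
        mid = (frag.start + frag.end) // 2
        per_chrom[frag.chrom].append(min(mid // window, len(values[frag.chrom]) - 1))
    for chrom, bins in per_chrom.items():
        if bins:
            values[chrom] += np.bincount(np.asarray(bins), minlength=len(values[chrom]))
    if skipped:
        log.warning("bin_fragments: skipped %d fragments on unknown chromosomes", skipped)
    return BinnedTrack(window=window, values={c: v.astype(float) for c, v in values.items()},
                       normalization="raw", total_fragments=fragments.total)


def normalize_per_million(track: BinnedTrack) -> BinnedTrack:
    """Scale a raw count track to fragments-per-million of the sample total."""
    if track.normalization != "raw":
        raise ValueError("normalize_per_million expects a raw track")
    total = track.total_fragments if track.total_fragments else track.total()
    if total == 0:
        raise ValueError("cannot normalise a track with zero total fragments")
    values = {c: v * (1e6 / total) for c, v in track.values.items()}
    return BinnedTrack(window=track.window, values=values, normalization="per-million",
                       total_fragments=track.total_fragments,
                       mask={c: m.copy() for c, m in track.mask.items()})


def log2_ratio(gfp: BinnedTrack, igg: BinnedTrack, pseudocount: float = 0.5) -> BinnedTrack:
    """log2((GFP + c) / (IgG + c)) per bin on matched per-million tracks.

    Bins where both inputs are zero come out as exactly 0.
    """
    if gfp.window != igg.window:
        raise ValueError(f"window mismatch: {gfp.window} vs {igg.window}")
    if set(gfp.values) != set(igg.values):
        raise ValueError("chromosome sets differ between tracks")
    if gfp.normalization != "per-million" or igg.normalization != "per-million":
        raise ValueError("log2_ratio expects per-million tracks")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    values = {}
    mask = {}
    for chrom in gfp.values:
        g, i = gfp.values[chrom], igg.values[chrom]
        if len(g) != len(i):
            raise ValueError(f"bin count mismatch on {chrom}")
        values[chrom] = np.log2((g + pseudocount) / (i + pseudocount))
        mask[chrom] = gfp.mask[chrom] | igg.mask[chrom]
    return BinnedTrack(window=gfp.window, values=values,
                       normalization="log2-ratio", mask=mask)


def bedgraph_to_track(df: pd.DataFrame, layout: GenomeLayout, window: int,
                      normalization: str = "per-million") -> BinnedTrack:
    """Rebuild a fixed-window BinnedTrack from bedGraph rows.

    Rows must be window-aligned; bins absent from the bedGraph are masked.
    """
    values, mask = {}, {}
    for chrom, length in layout.chromosomes:
        nb = n_bins(length, window)
        v = np.zeros(nb)
        m = np.ones(nb, dtype=bool)
        sub = df[df["chrom"] == chrom]
        if len(sub):
            if ((sub["start"] % window) != 0).any():
                raise ValueError(f"bedGraph rows on {chrom} not aligned to window {window}")
            idx = (sub["start"] // window).to_numpy()
            v[idx] = sub["value"].to_numpy()
            m[idx] = False
        values[chrom] = v
        mask[chrom] = m
    return BinnedTrack(window=window, values=values, normalization=normalization,
                       mask=mask)


def gc_track(seq: str, window: int = 100, step: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window GC fraction of a sequence.

    Returns (window start positions, GC fractions); windows containing N
    (or any non-ACGT character) are NaN.
    """
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    if len(seq) < window:
        raise ValueError("sequence shorter than one window")
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    is_gc = ((arr == ord("G")) | (arr == ord("C"))).astype(np.int64)
    is_acgt = np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8)).astype(np.int64)
    cum_gc = np.concatenate([[0], np.cumsum(is_gc)])
    cum_ok = np.concatenate([[0], np.cumsum(is_acgt)])
    starts = np.arange(0, len(seq) - window + 1, step, dtype=np.int64)
    gc = (cum_gc[starts + window] - cum_gc[starts]) / window
    ok = (cum_ok[starts + window] - cum_ok[starts]) == window
    gc = np.where(ok, gc, np.nan)
    return starts, gc
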