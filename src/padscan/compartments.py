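"""Hi-C correlation/PCA compartment analysis per chromosome arm.

Chromosome-arm contact submatrices (20-kb bins) are converted to
Spearman correlation matrices, the first principal component of the
column-centred correlation matrix is extracted, and its sign is oriented
so that it correlates positively with the nuclear-periphery ChIP signal.
Bins with oriented PC1 > 0 are labelled peripheral-like (the repressed,
B-type compartment); the rest interior-like. A telomere-anchored
correlation profile with valley detection covers the distal-arm analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .core import GenomeLayout
from .tracks import BinnedTrack

log = logging.getLogger(__name__)

MIN_ARM_BINS = 10


@dataclass
class CompartmentResult:
    arm_id: str
    bin_indices: np.ndarray          # chromosome bin index of each arm bin
    pc1: np.ndarray                  # oriented PC1 score per arm bin (NaN = masked)
    labels: np.ndarray               # +1 peripheral-like, -1 interior-like, 0 masked
    orientation: int                 # sign applied to the raw PC1
    rho: float                       # Spearman rho(PC1, periphery signal)
    masked: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))


def split_arms(
    matrix: np.ndarray, layout: GenomeLayout, chrom: str, binsize: int
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Split a whole-chromosome matrix into arm submatrices.

    Left arm: bins entirely left of the pericentromere; right arm: bins
    entirely right of it. Bins touching the pericentromere belong to
    neither arm. Arms with fewer than 10 bins are skipped with a warning.
    """
    n = matrix.shape[0]
    ps, pe = layout.peri(chrom)
    if ps >= pe:
        idx = np.arange(n)
        return {f"{chrom}": (matrix, idx)}
    n_left = ps // binsize                      # bins with end <= ps
    first_right = -(-pe // binsize)             # first bin with start >= pe
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    left = np.arange(0, n_left)
    right = np.arange(first_right, n)
    for name, idx in ((f"{chrom}_L", left), (f"{chrom}_R", right)):
        if len(idx) < MIN_ARM_BINS:
            if len(idx) > 0:
                log.warning("split_arms: arm %s has %d bins (<%d); skipped",
                            name, len(idx), MIN_ARM_BINS)
            continue
        out[name] = (matrix[np.ix_(idx, idx)], idx)
    return out


def oe_normalize(mat: np.ndarray) -> np.ndarray:
    """Observed/expected distance normalisation of a contact matrix.

    Each diagonal is divided by its mean, removing the genomic-distance
    decay that otherwise dominates row correlations; the compartment
    (plaid) structure is what remains. Standard preprocessing for
    correlation/PCA compartment calling.
    """
    n = mat.shape[0]
    out = np.array(mat, dtype=float)
    for d in range(n):
        idx = np.arange(n - d)
        vals = out[idx, idx + d]
        with np.errstate(invalid="ignore"):
            exp = np.nanmean(vals)
        if not np.isfinite(exp) or exp == 0:
            continue
        out[idx, idx + d] = vals / exp
        out[idx + d, idx] = vals / exp
    return out


def _pair_spearman(x: np.ndarray, y: np.ndarray, drop: tuple[int, int]) -> float:
    """Spearman correlation of two matrix rows, excluding the two diagonal
    positions of the pair and any NaN columns."""
    keep = np.ones(len(x), dtype=bool)
    keep[list(drop)] = False
    keep &= ~np.isnan(x) & ~np.isnan(y)
    xv, yv = x[keep], y[keep]
    if len(xv) < 3 or np.ptp(xv) == 0 or np.ptp(yv) == 0:
        return np.nan
    rho = stats.spearmanr(xv, yv).statistic
    return float(rho)


def spearman_matrix(mat: np.ndarray) -> np.ndarray:
    """Pairwise Spearman correlation of matrix rows.

    Entry (i, j) correlates rows i and j over all bins except i and j
    themselves (the raw diagonal, dominated by self-contacts, is excluded
    from the rank vectors) and except masked (NaN) bins. Rows with zero
    variance are masked (NaN row/column). Output is symmetric with unit
    diagonal.
    """
    n = mat.shape[0]
    if mat.shape[0] != mat.shape[1]:
        raise ValueError("matrix must be square")
    variances = np.array([np.nanvar(row) for row in mat])
    valid = ~np.isnan(variances) & (variances > 0) & ~np.all(np.isnan(mat), axis=1)
    if not valid.any():
        raise ValueError("all rows constant; correlation undefined")
    out = np.full((n, n), np.nan)
    for i in range(n):
        if not valid[i]:
            continue
        out[i, i] = 1.0
        for j in range(i + 1, n):
            if not valid[j]:
                continue
            rho = _pair_spearman(mat[i], mat[j], (i, j))
            out[i, j] = out[j, i] = rho
    return out


def pc1(corr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First principal component scores of a correlation matrix.

    Masked (NaN) rows are removed before the decomposition, the matrix is
    column-centred, and scores are the projection onto the leading right
    singular vector; masked bins are reinserted as NaN. Returns
    ``(scores, valid_mask)``.
    """
    n = corr.shape[0]
    valid = ~np.all(np.isnan(corr), axis=1)
    sub = corr[np.ix_(valid, valid)]
    if np.isnan(sub).any():
        # a bin unmasked overall but undefined against some partner:
        # impute with the column mean so the decomposition stays dense
        col_mean = np.nanmean(sub, axis=0)
        nan_r, nan_c = np.nonzero(np.isnan(sub))
        sub = sub.copy()
        sub[nan_r, nan_c] = col_mean[nan_c]
    centered = sub - sub.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    v = vt[0]
    resid = np.linalg.norm(centered.T @ (centered @ v) - (s[0] ** 2) * v)
    if resid > 1e-8 * max(s[0] ** 2, 1.0):
        raise RuntimeError(f"PCA eigen-equation residual {resid:.3g} too large")
    scores_sub = centered @ v
    scores = np.full(n, np.nan)
    scores[valid] = scores_sub
    return scores, valid


def orient_and_label(
    scores: np.ndarray,
    signal: np.ndarray,
    arm_id: str = "",
    bin_indices: np.ndarray | None = None,
) -> CompartmentResult:
    """Fix the PC1 sign against the periphery signal and label bins.

    The orientation sign is chosen so that Spearman rho(PC1, signal) >= 0;
    bins with oriented PC1 > 0 are peripheral-like (+1), the rest
    interior-like (-1); masked bins are 0.
    """
    scores = np.asarray(scores, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if len(scores) != len(signal):
        raise ValueError("PC1 and signal must share the binning")
    ok = ~np.isnan(scores) & ~np.isnan(signal)
    if ok.sum() >= 2 and np.ptp(signal[ok]) > 0 and np.ptp(scores[ok]) > 0:
        rho = float(stats.spearmanr(scores[ok], signal[ok]).statistic)
    else:
        log.warning("orient_and_label: correlation undefined; defaulting to +")
        rho = np.nan
    sign = -1 if (not np.isnan(rho) and rho < 0) else 1
    oriented = sign * scores
    rho_oriented = abs(rho) if not np.isnan(rho) else np.nan
    labels = np.zeros(len(scores), dtype=int)
    labels[~np.isnan(oriented) & (oriented > 0)] = 1
    labels[~np.isnan(oriented) & (oriented <= 0)] = -1
    if bin_indices is None:
        bin_indices = np.arange(len(scores))
    return CompartmentResult(
        arm_id=arm_id, bin_indices=np.asarray(bin_indices), pc1=oriented,
        labels=labels, orientation=sign, rho=rho_oriented,
        masked=np.flatnonzero(np.isnan(scores)))


def arm_signal(track: BinnedTrack, chrom: str, bin_indices: np.ndarray,
               n_chrom_bins: int) -> np.ndarray:
    """Periphery-signal values for the given chromosome bins of a track."""
    v = track.values[chrom]
    out = np.full(n_chrom_bins, np.nan)
    out[: len(v)] = np.where(track.mask[chrom][: n_chrom_bins], np.nan, v[:n_chrom_bins])
    return out[bin_indices]


def compartments_for_chromosome(
    matrix: np.ndarray, layout: GenomeLayout, chrom: str, binsize: int,
    signal: BinnedTrack, distance_normalize: bool = True,
) -> list[CompartmentResult]:
    """Run the full per-arm compartment analysis for one chromosome.

    Arm submatrices are distance-normalised (observed/expected) before the
    Spearman correlation so PC1 reflects compartments rather than position
    along the arm; set ``distance_normalize=False`` for matrices that are
    already decay-free.
    """
    if signal.window != binsize:
        raise ValueError("signal track binning must match the matrix binsize")
    results = []
    for arm_id, (sub, idx) in split_arms(matrix, layout, chrom, binsize).items():
        if distance_normalize:
            sub = oe_normalize(sub)
        corr = spearman_matrix(sub)
        scores, _ = pc1(corr)
        sig = arm_signal(signal, chrom, idx, matrix.shape[0])
        results.append(orient_and_label(scores, sig, arm_id=arm_id, bin_indices=idx))
    return results


def telomere_profile(
    matrix: np.ndarray, binsize: int = 20_000, span: int = 6_000_000,
    terminal_bin: int = 0,
) -> np.ndarray:
    """Correlation of each distal bin with the chromosome terminus.

    ``curve[i]`` is the Spearman correlation-matrix entry between bin i
    and the terminal bin (the first 20 kb), for bins within ``span`` of
    the terminus. The terminal bin itself has curve value 1.
    """
    n = matrix.shape[0]
    if n * binsize < span:
        raise ValueError(f"chromosome ({n * binsize} bp) shorter than span {span}")
    if np.all(np.isnan(matrix[terminal_bin])) or np.nanvar(matrix[terminal_bin]) == 0:
        raise ValueError("terminal bin is masked; profile undefined")
    n_out = span // binsize
    curve = np.empty(n_out)
    for i in range(n_out):
        if i == terminal_bin:
            curve[i] = 1.0
        else:
            curve[i] = _pair_spearman(matrix[terminal_bin], matrix[i],
                                      (terminal_bin, i))
    return curve


def detect_valleys(
    curve: np.ndarray, k: int = 10, depth: float = 0.1
) -> list[tuple[int, int, float]]:
    """Find local valleys of a correlation curve.

    The curve is detrended with a running median of half-width ``k`` bins;
    a valley is a maximal run of bins where (trend - curve) > ``depth``.
    Returns (start_bin, end_bin_exclusive, max_depth) triples.
    """
    curve = np.asarray(curve, dtype=float)
    if len(curve) <= 2 * k + 1:
        raise ValueError("curve too short for the smoothing half-width")
    trend = ndimage.median_filter(curve, size=2 * k + 1, mode="nearest")
    resid = trend - curve
    below = resid > depth
    out = []
    i = 0
    while i < len(below):
        if below[i]:
            j = i
            while j < len(below) and below[j]:
                j += 1
            out.append((i, j, float(resid[i:j].max())))
            i = j
        else:
            i += 1
    return out
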