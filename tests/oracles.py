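"""Independent brute-force oracles shared by the unit and acceptance suites.

Deliberately naive re-derivations (direct scans, pmf summation) that share
no code path with the library implementation they check.
"""

import math

import numpy as np


def pois_sf_sum(k: int, lam: float) -> float:
    """P(X >= k) for X ~ Poisson(lam), by direct pmf summation."""
    if k <= 0:
        return 1.0
    term = math.exp(-lam)
    cdf = term
    for i in range(1, k):
        term *= lam / i
        cdf += term
    return max(0.0, min(1.0, 1.0 - cdf))


def oracle_islands(chip: dict, control: dict, params):
    """Direct-scan island caller: window eligibility, gap assembly, island
    Poisson tails and Benjamini-Hochberg, all computed from first
    principles. Returns (chrom, start, end, p, q) tuples passing the FDR."""
    total_windows = sum(len(v) for v in chip.values())
    chip_total = sum(float(np.sum(v)) for v in chip.values())
    lam = max(chip_total / total_windows, params.lambda_floor)
    ctrl_total = sum(float(np.sum(v)) for v in control.values()) if control else 0.0
    scale = chip_total / ctrl_total if ctrl_total > 0 else 0.0
    raw = []
    for chrom, counts in chip.items():
        elig = [i for i, c in enumerate(counts)
                if pois_sf_sum(int(math.ceil(c)), lam) < params.p_eligible]
        groups = []
        for i in elig:
            if groups and (i - groups[-1][-1] - 1) * params.window <= params.gap:
                groups[-1].append(i)
            else:
                groups.append([i])
        for g in groups:
            w0, w1 = g[0], g[-1]
            agg = float(np.sum(counts[w0:w1 + 1]))
            ctrl = float(np.sum(control[chrom][w0:w1 + 1])) * scale if ctrl_total else 0.0
            mean = max(ctrl, lam * (w1 - w0 + 1))
            p = pois_sf_sum(int(math.ceil(agg)), mean)
            raw.append((chrom, w0 * params.window, (w1 + 1) * params.window, p))
    m = len(raw)
    order = sorted(range(m), key=lambda i: raw[i][3])
    q = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, raw[i][3] * m / rank)
        q[i] = prev
    return [(c, s, e, p, qv) for (c, s, e, p), qv in zip(raw, q)
            if qv < params.fdr]
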