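"""Independent brute-force oracles, written as literal loop transcriptions of
the definitions and kept free of the package's optimized code paths."""

from __future__ import annotations

import math

import numpy as np


def tmm_factors_brute(counts: np.ndarray, logratio_trim: float = 0.30,
                      abs_intensity_trim: float = 0.05,
                      weighting: bool = True) -> np.ndarray:
    """Loop-based TMM: reference by 75th-percentile CPM closest to the mean,
    pairwise doubly trimmed weighted mean of M values, geometric-mean
    rescaling.  Proportional column pairs (all |M| below 1e-10) get factor 1."""
    counts = np.asarray(counts, dtype=float)
    n_genes, n_samples = counts.shape
    lib = counts.sum(axis=0)
    q75 = [float(np.percentile(counts[:, k] / lib[k] * 1e6, 75))
           for k in range(n_samples)]
    mean75 = sum(q75) / n_samples
    ref = min(range(n_samples), key=lambda k: (abs(q75[k] - mean75), k))

    factors = []
    for k in range(n_samples):
        ms, as_, ws = [], [], []
        for g in range(n_genes):
            yk, yr = counts[g, k], counts[g, ref]
            if yk > 0 and yr > 0:
                pk, pr = yk / lib[k], yr / lib[ref]
                ms.append(math.log2(pk / pr))
                as_.append(0.5 * math.log2(pk * pr))
                ws.append(1.0 / ((lib[k] - yk) / (lib[k] * yk)
                                 + (lib[ref] - yr) / (lib[ref] * yr)))
        n = len(ms)
        if max(abs(m) for m in ms) < 1e-10:
            factors.append(1.0)
            continue
        drop_m = int(math.floor(n * logratio_trim))
        drop_a = int(math.floor(n * abs_intensity_trim))
        order_m = sorted(range(n), key=lambda i: (ms[i], i))
        order_a = sorted(range(n), key=lambda i: (as_[i], i))
        keep_m = set(order_m[drop_m:n - drop_m])
        keep_a = set(order_a[drop_a:n - drop_a])
        keep = keep_m & keep_a
        if not keep:
            keep = set(range(n))
        num = den = 0.0
        for i in keep:
            w = ws[i] if weighting else 1.0
            num += w * ms[i]
            den += w
        factors.append(2.0 ** (num / den))
    log_gm = sum(math.log(f) for f in factors) / n_samples
    return np.array([f / math.exp(log_gm) for f in factors])


def filter_keep_brute(counts: np.ndarray, mode: str, cpm_threshold: float,
                      sample_fraction: float) -> list[int]:
    """Per-gene scan of the low-expression filter."""
    counts = np.asarray(counts, dtype=float)
    lib = counts.sum(axis=0)
    kept = []
    for g in range(counts.shape[0]):
        cpm = [counts[g, k] / lib[k] * 1e6 for k in range(counts.shape[1])]
        n = len(cpm)
        if mode == "cpm_gt1":
            if sum(c > cpm_threshold for c in cpm) / n >= sample_fraction:
                kept.append(g)
        else:
            if sum(c == 0 for c in cpm) / n <= sample_fraction:
                kept.append(g)
    return kept


def frequency_brute(sets: dict[str, set[str]]) -> dict[str, int]:
    """Membership counting, one gene and cohort at a time."""
    genes = set()
    for s in sets.values():
        genes |= s
    return {g: sum(1 for s in sets.values() if g in s) for g in genes}


def average_linkage_heights_brute(d: np.ndarray) -> list[float]:
    """Naive agglomerative average linkage: merge heights in order."""
    d = np.asarray(d, dtype=float)
    clusters: list[list[int]] = [[i] for i in range(d.shape[0])]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                dist = np.mean([d[a, b] for a in clusters[i] for b in clusters[j]])
                if best is None or dist < best[0]:
                    best = (dist, i, j)
        dist, i, j = best
        heights.append(dist)
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return heights
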