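"""Independent brute-force oracles for the texture and statistics code.

Everything here is deliberately naive — plain python loops, flood fill,
exact combinatorics — so that agreement with the vectorized package code
is meaningful.  Only used by the test suite.
"""

from __future__ import annotations

import math

import numpy as np

NEIGHBOURS26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def _in_bounds(p, shape):
    return all(0 <= c < n for c, n in zip(p, shape))


def glcm_counts_oracle(levels, mask, directions):
    """Symmetrized co-occurrence counts by looping over every voxel pair."""
    G = int(levels[mask].max()) if mask.any() else 0
    counts = np.zeros((G, G), dtype=np.int64)
    shape = levels.shape
    for v in np.argwhere(mask):
        for d in directions:
            w = tuple(v + np.asarray(d))
            if _in_bounds(w, shape) and mask[w]:
                a, b = levels[tuple(v)] - 1, levels[w] - 1
                counts[a, b] += 1
                counts[b, a] += 1
    return counts


def glcm_features_oracle(levels, mask, directions, G):
    counts = np.zeros((G, G), dtype=np.int64)
    shape = levels.shape
    for v in np.argwhere(mask):
        for d in directions:
            w = tuple(v + np.asarray(d))
            if _in_bounds(w, shape) and mask[w]:
                counts[levels[tuple(v)] - 1, levels[w] - 1] += 1
                counts[levels[w] - 1, levels[tuple(v)] - 1] += 1
    p = counts / counts.sum()
    feats = {"Homogeneity": 0.0, "Energy": 0.0, "Contrast_GLCM": 0.0,
             "Dissimilarity": 0.0, "Entropy": 0.0}
    mu_i = mu_j = 0.0
    for i in range(G):
        for j in range(G):
            pij = p[i, j]
            feats["Homogeneity"] += pij / (1 + abs(i - j))
            feats["Energy"] += pij**2
            feats["Contrast_GLCM"] += pij * (i - j) ** 2
            feats["Dissimilarity"] += pij * abs(i - j)
            if pij > 0:
                feats["Entropy"] -= pij * math.log2(pij)
            mu_i += (i + 1) * pij
            mu_j += (j + 1) * pij
    var_i = sum(((i + 1) - mu_i) ** 2 * p[i, j] for i in range(G) for j in range(G))
    var_j = sum(((j + 1) - mu_j) ** 2 * p[i, j] for i in range(G) for j in range(G))
    if var_i > 0 and var_j > 0:
        cov = sum(
            ((i + 1) - mu_i) * ((j + 1) - mu_j) * p[i, j]
            for i in range(G)
            for j in range(G)
        )
        feats["Correlation"] = cov / math.sqrt(var_i * var_j)
    else:
        feats["Correlation"] = float("nan")
    return feats, counts


def glrlm_counts_oracle(levels, mask, directions, G):
    """Run counts by explicit line walking in each direction."""
    shape = levels.shape
    runs = {}  # (g, length) -> count
    for d in directions:
        d = np.asarray(d)
        visited = np.zeros(shape, dtype=bool)
        for v in np.argwhere(mask):
            prev = v - d
            if _in_bounds(tuple(prev), shape) and mask[tuple(prev)] and levels[
                tuple(prev)
            ] == levels[tuple(v)]:
                continue  # not a run start
            g = levels[tuple(v)]
            length = 1
            w = v + d
            while _in_bounds(tuple(w), shape) and mask[tuple(w)] and levels[tuple(w)] == g:
                length += 1
                w = w + d
            runs[(g, length)] = runs.get((g, length), 0) + 1
    rmax = max((r for (_, r) in runs), default=1)
    counts = np.zeros((G, rmax), dtype=np.int64)
    for (g, r), c in runs.items():
        counts[g - 1, r - 1] = c
    return counts


def glrlm_features_oracle(levels, mask, directions, G):
    M = glrlm_counts_oracle(levels, mask, directions, G).astype(float)
    R = M.sum()
    N = int(mask.sum())
    out = {k: 0.0 for k in ("SRE", "LRE", "LGRE", "HGRE", "SRLGE", "SRHGE",
                            "LRLGE", "LRHGE")}
    for gi in range(M.shape[0]):
        for ri in range(M.shape[1]):
            n = M[gi, ri]
            if n == 0:
                continue
            g, r = gi + 1.0, ri + 1.0
            out["SRE"] += n / r**2
            out["LRE"] += n * r**2
            out["LGRE"] += n / g**2
            out["HGRE"] += n * g**2
            out["SRLGE"] += n / (g**2 * r**2)
            out["SRHGE"] += n * g**2 / r**2
            out["LRLGE"] += n * r**2 / g**2
            out["LRHGE"] += n * g**2 * r**2
    out = {k: v / R for k, v in out.items()}
    out["GLNUr"] = sum(M[gi, :].sum() ** 2 for gi in range(M.shape[0])) / R
    out["RLNU"] = sum(M[:, ri].sum() ** 2 for ri in range(M.shape[1])) / R
    out["RP"] = R / (N * len(directions))
    return out


def zones_oracle(levels, mask, G):
    """Zone counts via explicit flood fill (26-connectivity)."""
    shape = levels.shape
    visited = np.zeros(shape, dtype=bool)
    zones = {}  # (g, size) -> count
    for v0 in np.argwhere(mask):
        v0 = tuple(v0)
        if visited[v0]:
            continue
        g = levels[v0]
        stack = [v0]
        visited[v0] = True
        size = 0
        while stack:
            v = stack.pop()
            size += 1
            for d in NEIGHBOURS26:
                w = tuple(np.asarray(v) + d)
                if (
                    _in_bounds(w, shape)
                    and mask[w]
                    and not visited[w]
                    and levels[w] == g
                ):
                    visited[w] = True
                    stack.append(w)
        zones[(g, size)] = zones.get((g, size), 0) + 1
    smax = max((s for (_, s) in zones), default=1)
    counts = np.zeros((G, smax), dtype=np.int64)
    for (g, s), c in zones.items():
        counts[g - 1, s - 1] = c
    return counts


def glzlm_features_oracle(levels, mask, G):
    M = zones_oracle(levels, mask, G).astype(float)
    Z = M.sum()
    N = int(mask.sum())
    out = {k: 0.0 for k in ("SZE", "LZE", "LGZE", "HGZE", "SZLGE", "SZHGE",
                            "LZLGE", "LZHGE")}
    for gi in range(M.shape[0]):
        for si in range(M.shape[1]):
            n = M[gi, si]
            if n == 0:
                continue
            g, s = gi + 1.0, si + 1.0
            out["SZE"] += n / s**2
            out["LZE"] += n * s**2
            out["LGZE"] += n / g**2
            out["HGZE"] += n * g**2
            out["SZLGE"] += n / (g**2 * s**2)
            out["SZHGE"] += n * g**2 / s**2
            out["LZLGE"] += n * s**2 / g**2
            out["LZHGE"] += n * g**2 * s**2
    out = {k: v / Z for k, v in out.items()}
    out["GLNUz"] = sum(M[gi, :].sum() ** 2 for gi in range(M.shape[0])) / Z
    out["ZLNU"] = sum(M[:, si].sum() ** 2 for si in range(M.shape[1])) / Z
    out["ZP"] = Z / N
    return out


def ngldm_oracle(levels, mask, G):
    """Dependence matrix and difference-form features by per-voxel scans."""
    shape = levels.shape
    Q = np.zeros((G, 27), dtype=np.int64)
    n_i = np.zeros(G)
    s_i = np.zeros(G)
    N_valid = 0
    for v in np.argwhere(mask):
        v = tuple(v)
        g = levels[v]
        dep = 0
        nb_levels = []
        for d in NEIGHBOURS26:
            w = tuple(np.asarray(v) + d)
            if _in_bounds(w, shape) and mask[w]:
                nb_levels.append(levels[w])
                if levels[w] == g:
                    dep += 1
        Q[g - 1, dep] += 1
        if nb_levels:
            N_valid += 1
            n_i[g - 1] += 1
            s_i[g - 1] += abs(g - sum(nb_levels) / len(nb_levels))
    nan = float("nan")
    if N_valid == 0:
        return Q, {"Coarseness": nan, "Contrast_NGLDM": nan, "Busyness": nan}
    p_i = n_i / N_valid
    present = [i for i in range(G) if p_i[i] > 0]
    Ng = len(present)
    ps = sum(p_i[i] * s_i[i] for i in present)
    coarse = 1.0 / ps if ps > 0 else nan
    if Ng >= 2:
        contrast = (
            sum(
                p_i[i] * p_i[j] * ((i + 1) - (j + 1)) ** 2
                for i in present
                for j in present
            )
            / (Ng * (Ng - 1))
            * (sum(s_i[i] for i in present) / N_valid)
        )
        denom = sum(
            abs((i + 1) * p_i[i] - (j + 1) * p_i[j]) for i in present for j in present
        )
        busy = ps / denom if denom > 0 else nan
    else:
        contrast = busy = nan
    return Q, {"Coarseness": coarse, "Contrast_NGLDM": contrast, "Busyness": busy}


# ---------------------------------------------------------------------------
# statistics oracles


def fisher_two_sided_oracle(table):
    """Two-sided Fisher p by exhaustive enumeration with exact combinatorics."""
    a, b = int(table[0][0]), int(table[0][1])
    c, d = int(table[1][0]), int(table[1][1])
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        if x < 0 or x > r1 or c1 - x < 0 or c1 - x > r2:
            return 0.0
        return math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)

    p_obs = prob(a)
    total = 0.0
    for x in range(0, min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-7):
            total += px
    return min(total, 1.0)


def binormal_auc(mu_pos, sd_pos, mu_neg, sd_neg):
    """Closed-form AUC when both classes are Gaussian."""
    from scipy.stats import norm

    return float(norm.cdf((mu_pos - mu_neg) / math.sqrt(sd_pos**2 + sd_neg**2)))


def rank_auc_oracle(values, labels):
    """AUC by exhaustive concordant-pair counting (ties count one half)."""
    values = np.asarray(values, float)
    labels = np.asarray(labels, int)
    pos = values[labels == 1]
    neg = values[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else 0.5 if p == q else 0.0
    return total / (len(pos) * len(neg))
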