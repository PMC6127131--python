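"""Grey-level texture features on a masked, discretized SUV image.

Implements the classical 3-D texture families used in PET radiomics:

* histogram statistics (skewness, kurtosis, entropy, energy),
* grey-level co-occurrence matrix (GLCM),
* grey-level run-length matrix (GLRLM),
* neighbourhood grey-level difference statistics (NGLDM),
* grey-level zone-length matrix (GLZLM, also known as size-zone matrix).

The image is first discretized to ``G`` grey levels (uniform bins between
the in-mask minimum and maximum; 64 by default).  GLCM and GLRLM accumulate
a single matrix over all 13 unique 3-D directions at Chebyshev distance 1;
zones and neighbourhoods use 26-connectivity.  Voxel pairs, runs, zones and
neighbourhoods never cross the mask boundary.  Directions are counted on
the index grid; voxel anisotropy does not enter the direction weighting.

Degenerate cases (a constant region, a single voxel) yield flagged NaN
values rather than exceptions; the modeling stage drops flagged features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import SUVVolume, VOIMask

__all__ = [
    "DiscretizedVolume",
    "all_directions",
    "discretize",
    "glcm_matrix",
    "glcm_features",
    "glrlm_matrix",
    "glrlm_features",
    "glzlm_matrix",
    "glzlm_features",
    "ngldm_matrix",
    "ngldm_features",
    "histogram_features",
    "extract_features",
    "FEATURE_NAMES",
    "TEXTURE_FEATURE_NAMES",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)

#: the full named feature set, in output order
FEATURE_NAMES = [
    # histogram
    "SkewnessH", "KurtosisH", "EntropyH", "EnergyH",
    # GLCM
    "Homogeneity", "Energy", "Contrast_GLCM", "Correlation", "Entropy", "Dissimilarity",
    # GLRLM
    "SRE", "LRE", "LGRE", "HGRE", "SRLGE", "SRHGE", "LRLGE", "LRHGE",
    "GLNUr", "RLNU", "RP",
    # NGLDM
    "Coarseness", "Contrast_NGLDM", "Busyness",
    # GLZLM
    "SZE", "LZE", "LGZE", "HGZE", "SZLGE", "SZHGE", "LZLGE", "LZHGE",
    "GLNUz", "ZLNU", "ZP",
]

TEXTURE_FEATURE_NAMES = FEATURE_NAMES


def all_directions() -> list[tuple[int, int, int]]:
    """The 13 unique 3-D offsets at Chebyshev distance 1 (half of the 26)."""
    dirs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                if (dx, dy, dz) > (0, 0, 0):
                    dirs.append((dx, dy, dz))
    return dirs


_NEIGHBOURS26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


@dataclass
class DiscretizedVolume:
    """Integer grey levels 1..G inside the mask, 0 outside."""

    levels: np.ndarray
    mask: np.ndarray
    n_levels: int
    bin_edges: np.ndarray = field(default=None)

    def __post_init__(self):
        self.levels = np.asarray(self.levels, dtype=np.int64)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.levels.shape != self.mask.shape or self.levels.ndim != 3:
            raise ValueError("levels and mask must be identical 3-D arrays")
        inside = self.levels[self.mask]
        if inside.size and (inside.min() < 1 or inside.max() > self.n_levels):
            raise ValueError("in-mask levels must lie in [1, G]")
        if np.any(self.levels[~self.mask] != 0):
            raise ValueError("out-of-mask levels must be 0")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def _as_array(x, want_bool=False):
    if isinstance(x, SUVVolume):
        return x.voxels
    if isinstance(x, VOIMask):
        return x.voxels
    a = np.asarray(x)
    return a.astype(bool) if want_bool else a


def discretize(
    suv,
    mask,
    n_levels: int = 64,
    bounds: tuple[float, float] | None = None,
) -> DiscretizedVolume:
    """Uniform-width discretization of in-mask SUV values to 1..G.

    Bins span ``bounds`` (default: in-mask min..max); the upper bound maps
    to level G.  A constant region maps entirely to level 1.
    """
    img = _as_array(suv)
    m = _as_array(mask, want_bool=True)
    if img.shape != m.shape:
        raise ValueError("image and mask shapes differ")
    if not m.any():
        raise ValueError("mask is empty")
    vals = img[m]
    lo, hi = bounds if bounds is not None else (vals.min(), vals.max())
    levels = np.zeros(img.shape, dtype=np.int64)
    if hi <= lo:
        levels[m] = 1
    else:
        lv = 1 + np.floor((img[m] - lo) / (hi - lo) * n_levels).astype(np.int64)
        levels[m] = np.clip(lv, 1, n_levels)
    return DiscretizedVolume(levels, m, n_levels, np.linspace(lo, hi, n_levels + 1))


def _crop(disc: DiscretizedVolume):
    """Crop to the mask bounding box (pure speed optimisation)."""
    idx = np.argwhere(disc.mask)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return disc.levels[sl], disc.mask[sl]


def _pair_slices(shape, d):
    """Aligned slice tuples (src, dst) so that ``a[src]`` are values at voxel
    v and ``a[dst]`` the values at v + d, elementwise."""
    src, dst = [], []
    for n, o in zip(shape, d):
        if o == 0:
            src.append(slice(None))
            dst.append(slice(None))
        elif o > 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    return tuple(src), tuple(dst)


# ---------------------------------------------------------------------------
# GLCM


def glcm_matrix(disc: DiscretizedVolume, directions=None) -> np.ndarray:
    """Symmetrized, normalized co-occurrence matrix accumulated over directions."""
    levels, mask = _crop(disc)
    G = disc.n_levels
    dirs = directions if directions is not None else all_directions()
    counts = np.zeros((G, G), dtype=np.int64)
    for d in dirs:
        src, dst = _pair_slices(levels.shape, d)
        valid = mask[src] & mask[dst]
        a = levels[src][valid] - 1
        b = levels[dst][valid] - 1
        np.add.at(counts, (a, b), 1)
    counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise ValueError("no valid in-mask voxel pair in any direction")
    return counts / total


def glcm_features(disc: DiscretizedVolume, directions=None) -> dict[str, float]:
    p = glcm_matrix(disc, directions)
    G = disc.n_levels
    i = np.arange(1, G + 1, dtype=float)
    I, J = np.meshgrid(i, i, indexing="ij")
    diff = np.abs(I - J)
    feats = {
        "Homogeneity": float((p / (1.0 + diff)).sum()),
        "Energy": float((p**2).sum()),
        "Contrast_GLCM": float((p * diff**2).sum()),
        "Dissimilarity": float((p * diff).sum()),
    }
    nz = p > 0
    feats["Entropy"] = float(-(p[nz] * np.log2(p[nz])).sum())
    mu_i = float((I * p).sum())
    mu_j = float((J * p).sum())
    var_i = float(((I - mu_i) ** 2 * p).sum())
    var_j = float(((J - mu_j) ** 2 * p).sum())
    if var_i > 0 and var_j > 0:
        cov = float(((I - mu_i) * (J - mu_j) * p).sum())
        feats["Correlation"] = cov / np.sqrt(var_i * var_j)
    else:
        feats["Correlation"] = float("nan")  # constant region: undefined
    return feats


# ---------------------------------------------------------------------------
# GLRLM


def glrlm_matrix(disc: DiscretizedVolume, directions=None) -> np.ndarray:
    """Run-length counts ``M[g-1, r-1]`` accumulated over directions.

    A run is a maximal straight segment of in-mask voxels sharing one grey
    level; runs are broken by the mask boundary.
    """
    levels, mask = _crop(disc)
    G = disc.n_levels
    dirs = directions if directions is not None else all_directions()
    rmax = max(levels.shape)
    counts = np.zeros((G, rmax), dtype=np.int64)
    shape = np.asarray(levels.shape)
    for d in dirs:
        dvec = np.asarray(d)
        # run starts: in-mask voxels whose (v - d) predecessor is absent or differs
        src, dst = _pair_slices(levels.shape, tuple(-x for x in d))
        same = (levels[src] == levels[dst]) & mask[src] & mask[dst]
        interior_same = np.zeros(levels.shape, dtype=bool)
        interior_same[src] = same
        starts = np.argwhere(mask & ~interior_same)
        if starts.size == 0:
            continue
        # walk each run forward until level changes or mask/grid ends
        pos = starts.copy()
        run_len = np.ones(len(starts), dtype=np.int64)
        start_levels = levels[tuple(starts.T)]
        active = np.ones(len(starts), dtype=bool)
        while active.any():
            nxt = pos[active] + dvec
            inb = np.all((nxt >= 0) & (nxt < shape), axis=1)
            cont = np.zeros(inb.shape, dtype=bool)
            if inb.any():
                coords = tuple(nxt[inb].T)
                cont[inb] = mask[coords] & (levels[coords] == start_levels[active][inb])
            idx_active = np.flatnonzero(active)
            advancing = idx_active[cont]
            run_len[advancing] += 1
            pos[advancing] += dvec
            active[idx_active[~cont]] = False
        np.add.at(counts, (start_levels - 1, run_len - 1), 1)
    # trim trailing all-zero run-length columns
    used = np.flatnonzero(counts.sum(axis=0))
    rmax_used = used[-1] + 1 if used.size else 1
    return counts[:, :rmax_used]


def glrlm_features(disc: DiscretizedVolume, directions=None) -> dict[str, float]:
    dirs = directions if directions is not None else all_directions()
    M = glrlm_matrix(disc, dirs).astype(float)
    R = M.sum()
    if R == 0:
        raise ValueError("mask is empty")
    N = disc.n_voxels
    g = np.arange(1, M.shape[0] + 1, dtype=float)[:, None]
    r = np.arange(1, M.shape[1] + 1, dtype=float)[None, :]
    return {
        "SRE": float((M / r**2).sum() / R),
        "LRE": float((M * r**2).sum() / R),
        "LGRE": float((M / g**2).sum() / R),
        "HGRE": float((M * g**2).sum() / R),
        "SRLGE": float((M / (g**2 * r**2)).sum() / R),
        "SRHGE": float((M * g**2 / r**2).sum() / R),
        "LRLGE": float((M * r**2 / g**2).sum() / R),
        "LRHGE": float((M * g**2 * r**2).sum() / R),
        "GLNUr": float((M.sum(axis=1) ** 2).sum() / R),
        "RLNU": float((M.sum(axis=0) ** 2).sum() / R),
        "RP": float(R / (N * len(dirs))),
    }


# ---------------------------------------------------------------------------
# GLZLM (size-zone)


def glzlm_matrix(disc: DiscretizedVolume) -> np.ndarray:
    """Zone counts ``M[g-1, s-1]``: 26-connected components of equal level."""
    levels, mask = _crop(disc)
    G = disc.n_levels
    max_size = int(mask.sum())
    counts = np.zeros((G, max_size), dtype=np.int64)
    for g in np.unique(levels[mask]):
        lab, n = ndimage.label(levels == g, structure=_CONN26)
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        np.add.at(counts, (g - 1, sizes - 1), 1)
    used = np.flatnonzero(counts.sum(axis=0))
    smax_used = used[-1] + 1 if used.size else 1
    return counts[:, :smax_used]


def glzlm_features(disc: DiscretizedVolume) -> dict[str, float]:
    M = glzlm_matrix(disc).astype(float)
    Z = M.sum()
    if Z == 0:
        raise ValueError("mask is empty")
    N = disc.n_voxels
    g = np.arange(1, M.shape[0] + 1, dtype=float)[:, None]
    s = np.arange(1, M.shape[1] + 1, dtype=float)[None, :]
    return {
        "SZE": float((M / s**2).sum() / Z),
        "LZE": float((M * s**2).sum() / Z),
        "LGZE": float((M / g**2).sum() / Z),
        "HGZE": float((M * g**2).sum() / Z),
        "SZLGE": float((M / (g**2 * s**2)).sum() / Z),
        "SZHGE": float((M * g**2 / s**2).sum() / Z),
        "LZLGE": float((M * s**2 / g**2).sum() / Z),
        "LZHGE": float((M * g**2 * s**2).sum() / Z),
        "GLNUz": float((M.sum(axis=1) ** 2).sum() / Z),
        "ZLNU": float((M.sum(axis=0) ** 2).sum() / Z),
        "ZP": float(Z / N),
    }


# ---------------------------------------------------------------------------
# NGLDM


def ngldm_matrix(disc: DiscretizedVolume) -> np.ndarray:
    """Dependence matrix ``Q[g-1, d]``: voxels of level g whose 26-neighbour
    set contains exactly d in-mask voxels of the same level (d in 0..26)."""
    levels, mask = _crop(disc)
    G = disc.n_levels
    dep = np.zeros(levels.shape, dtype=np.int64)
    for d in _NEIGHBOURS26:
        src, dst = _pair_slices(levels.shape, d)
        dep[src] += ((levels[src] == levels[dst]) & mask[src] & mask[dst]).astype(np.int64)
    Q = np.zeros((G, 27), dtype=np.int64)
    np.add.at(Q, (levels[mask] - 1, dep[mask]), 1)
    return Q


def _neighbour_mean_diff(disc: DiscretizedVolume):
    """Per-voxel |level - mean(in-mask 26-neighbour levels)|; voxels with no
    in-mask neighbour are excluded (returned validity mask)."""
    levels, mask = _crop(disc)
    nsum = np.zeros(levels.shape, dtype=float)
    ncnt = np.zeros(levels.shape, dtype=np.int64)
    for d in _NEIGHBOURS26:
        src, dst = _pair_slices(levels.shape, d)
        nb_in = mask[dst]
        nsum[src] += np.where(nb_in, levels[dst], 0)
        ncnt[src] += nb_in.astype(np.int64)
    valid = mask & (ncnt > 0)
    diff = np.zeros(levels.shape, dtype=float)
    diff[valid] = np.abs(levels[valid] - nsum[valid] / ncnt[valid])
    return levels, valid, diff


def ngldm_features(disc: DiscretizedVolume) -> dict[str, float]:
    """Coarseness, Contrast and Busyness in the grey-level-difference form.

    With p_i the fraction of (neighbourhood-having) voxels at level i and
    s_i the summed absolute difference between level i voxels and their
    neighbourhood mean level:

    * Coarseness = 1 / sum_i p_i s_i
    * Contrast   = [sum_{i,j} p_i p_j (i-j)^2 / (Ng (Ng-1))] * [sum_i s_i / N]
    * Busyness   = sum_i p_i s_i / sum_{i,j} |i p_i - j p_j|   (p_i, p_j > 0)

    Degenerate inputs (constant region, single voxel) return flagged NaN.
    """
    levels, valid, diff = _neighbour_mean_diff(disc)
    G = disc.n_levels
    N = int(valid.sum())
    nan = float("nan")
    if N == 0:
        return {"Coarseness": nan, "Contrast_NGLDM": nan, "Busyness": nan}
    lv = levels[valid]
    n_i = np.bincount(lv - 1, minlength=G).astype(float)
    s_i = np.bincount(lv - 1, weights=diff[valid], minlength=G)
    p_i = n_i / N
    present = p_i > 0
    Ng = int(present.sum())
    i = np.arange(1, G + 1, dtype=float)
    ps = float((p_i * s_i).sum())
    coarseness = 1.0 / ps if ps > 0 else nan
    if Ng >= 2:
        pi = p_i[present]
        ii = i[present]
        si = s_i[present]
        contrast = float(
            (pi[:, None] * pi[None, :] * (ii[:, None] - ii[None, :]) ** 2).sum()
            / (Ng * (Ng - 1))
            * (si.sum() / N)
        )
        denom = float(np.abs(ii[:, None] * pi[:, None] - ii[None, :] * pi[None, :]).sum())
        busyness = ps / denom if denom > 0 else nan
    else:
        contrast = nan
        busyness = nan
    return {"Coarseness": coarseness, "Contrast_NGLDM": contrast, "Busyness": busyness}


# ---------------------------------------------------------------------------
# Histogram


def histogram_features(suv, mask, n_levels: int = 64) -> dict[str, float]:
    """First-order statistics of in-mask SUV values.

    Skewness and kurtosis are the conventional standardized moments
    (``m3 / m2^1.5`` and non-excess ``m4 / m2^2``) of the raw values;
    entropy (bits) and energy come from the G-bin discretized histogram.
    Zero in-mask variance yields flagged NaN skewness/kurtosis.
    """
    img = _as_array(suv)
    m = _as_array(mask, want_bool=True)
    vals = img[m].astype(float)
    if vals.size < 3:
        raise ValueError("need >= 3 in-mask voxels for histogram statistics")
    c = vals - vals.mean()
    m2 = float((c**2).mean())
    if m2 > 0:
        skew = float((c**3).mean() / m2**1.5)
        kurt = float((c**4).mean() / m2**2)
    else:
        skew = kurt = float("nan")
    disc = discretize(img, m, n_levels)
    p = np.bincount(disc.levels[m] - 1, minlength=n_levels) / vals.size
    nz = p > 0
    return {
        "SkewnessH": skew,
        "KurtosisH": kurt,
        "EntropyH": float(-(p[nz] * np.log2(p[nz])).sum()),
        "EnergyH": float((p**2).sum()),
    }


def extract_features(
    suv,
    mask,
    n_levels: int = 64,
    bounds: tuple[float, float] | None = None,
) -> tuple[dict[str, float], list[str]]:
    """Full named feature vector for one masked image.

    Returns ``(features, qc_flags)`` where ``qc_flags`` names the features
    that came out NaN through a degenerate-case guard.  Deterministic: the
    same input always yields the identical vector.
    """
    disc = discretize(suv, mask, n_levels, bounds)
    feats: dict[str, float] = {}
    feats.update(histogram_features(suv, mask, n_levels))
    feats.update(glcm_features(disc))
    feats.update(glrlm_features(disc))
    feats.update(ngldm_features(disc))
    feats.update(glzlm_features(disc))
    ordered = {name: feats[name] for name in FEATURE_NAMES}
    qc = [name for name, v in ordered.items() if not np.isfinite(v)]
    return ordered, qc
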