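"""Gray-level discretization and the five texture-matrix families.

All matrices operate on a fixed-bin-count discretization of the masked
intensities (levels 1..Ng, 0 as the out-of-mask sentinel) and use the full
3D 26-neighborhood / 13 unique directions at Chebyshev distance 1.

Conventions (stated explicitly because published tools differ):

* GLCM: pair counts over the 13 unique direction offsets, both orders
  (symmetrized), pooled over directions and normalized to sum 1.
* GLRLM: run counts along each of the 13 directions, summed over
  directions. RunPercentage divides by Np * 13 (each voxel belongs to one
  run per direction).
* GLSZM: zones are 26-connected components of equal level.
* GLDM: alpha = 0 by default; the matrix column j in 0..26 counts
  *qualifying neighbors*; feature formulas use the dependence size
  j + 1 so low-dependence emphases are finite.
* NGTDM: s_i sums |level - mean 26-neighbor level| over masked voxels of
  level i that have at least one masked neighbor.

Degenerate inputs (single gray level, single voxel, empty pair/zone sets)
map to the documented 0/1 conventions rather than NaN.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, EmptyVOIError

# the 13 unique 3D direction offsets at Chebyshev distance 1
DIRECTIONS_13 = [
    d
    for d in itertools.product((-1, 0, 1), repeat=3)
    if d > (0, 0, 0)
]
OFFSETS_26 = [d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]

_EPS = np.finfo(np.float64).tiny


@dataclass
class DiscretizedVOI:
    """Levels 1..ng on the mask bounding box; 0 marks out-of-mask voxels."""

    levels: np.ndarray
    ng: int
    bin_edges: np.ndarray
    spacing: tuple[float, float, float]

    @property
    def n_voxels(self) -> int:
        return int((self.levels > 0).sum())


@dataclass
class TextureMatrix:
    family: str
    matrix: np.ndarray
    ng: int
    n_voxels: int
    extra: dict | None = None


def discretize(volume, mask, n_bins=32, spacing=(1.0, 1.0, 1.0)) -> DiscretizedVOI:
    """Fixed-bin-count quantization of masked intensities.

    The masked minimum maps to level 1 and the maximum to level ``n_bins``.
    A constant region collapses to a single level (Ng = 1), which is a
    documented degenerate path rather than an error.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyVOIError("cannot discretize an empty mask")
    if n_bins < 2:
        raise ConfigurationError("n_bins must be >= 2")
    vol = np.asarray(volume, dtype=np.float64)
    vals = vol[mask]
    lo, hi = float(vals.min()), float(vals.max())
    bbox = tuple(slice(int(i.min()), int(i.max()) + 1) for i in np.nonzero(mask))
    sub_mask = mask[bbox]
    levels = np.zeros(sub_mask.shape, dtype=np.int32)
    if hi == lo:
        levels[sub_mask] = 1
        return DiscretizedVOI(levels, 1, np.array([lo, hi]), tuple(spacing))
    edges = np.linspace(lo, hi, n_bins + 1)
    lv = np.minimum(((vals - lo) / (hi - lo) * n_bins).astype(np.int32) + 1, n_bins)
    levels[sub_mask] = lv
    return DiscretizedVOI(levels, n_bins, edges, tuple(spacing))


def _shift_pairs(arr: np.ndarray, offset):
    """Views of arr and arr shifted by offset, trimmed to the overlap."""
    src = []
    dst = []
    for n, o in zip(arr.shape, offset):
        if o >= 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    return arr[tuple(src)], arr[tuple(dst)]


def build_glcm(d: DiscretizedVOI) -> TextureMatrix:
    """Symmetric gray-level co-occurrence matrix, pooled over 13 directions,
    normalized to sum 1 (zero matrix if no in-mask voxel pairs exist)."""
    ng = d.ng
    counts = np.zeros((ng, ng), dtype=np.float64)
    L = d.levels
    for off in DIRECTIONS_13:
        a, b = _shift_pairs(L, off)
        valid = (a > 0) & (b > 0)
        if not valid.any():
            continue
        idx = (a[valid].astype(np.int64) - 1) * ng + (b[valid] - 1)
        c = np.bincount(idx, minlength=ng * ng).reshape(ng, ng)
        counts += c + c.T
    total = counts.sum()
    if total > 0:
        counts /= total
    return TextureMatrix("glcm", counts, ng, d.n_voxels)


def build_glrlm(d: DiscretizedVOI) -> TextureMatrix:
    """Run-length matrix R(i, r), runs along 13 directions summed."""
    ng = d.ng
    L = d.levels
    max_len = int(np.ceil(np.sqrt(3) * max(L.shape))) + 1
    counts = np.zeros((ng, max_len), dtype=np.float64)
    nonzero = L > 0
    for off in DIRECTIONS_13:
        # run starts: in-mask voxels whose predecessor along -off differs
        prev_arr = np.zeros_like(L)
        prev_arr[tuple(slice(o, n) if o >= 0 else slice(0, n + o) for n, o in zip(L.shape, off))] = L[
            tuple(slice(0, n - o) if o >= 0 else slice(-o, n) for n, o in zip(L.shape, off))
        ]
        starts = nonzero & (prev_arr != L)
        pos = np.argwhere(starts)
        if pos.size == 0:
            continue
        lev = L[starts]
        run_len = np.ones(len(pos), dtype=np.int64)
        active = np.arange(len(pos))
        cur = pos.copy()
        step = np.array(off)
        while active.size:
            cur_a = cur[active] + step
            inside = np.all((cur_a >= 0) & (cur_a < L.shape), axis=1)
            cont = np.zeros(active.size, dtype=bool)
            if inside.any():
                vals = L[tuple(cur_a[inside].T)]
                cont[inside] = vals == lev[active[inside]]
            run_len[active[cont]] += 1
            cur[active[cont]] = cur_a[cont]
            active = active[cont]
        np.add.at(counts, (lev - 1, run_len - 1), 1.0)
    used = max(1, int(np.max(np.nonzero(counts.sum(axis=0))[0])) + 1) if counts.any() else 1
    return TextureMatrix(
        "glrlm", counts[:, :used], ng, d.n_voxels, extra={"n_directions": len(DIRECTIONS_13)}
    )


def build_glszm(d: DiscretizedVOI) -> TextureMatrix:
    """Size-zone matrix S(i, s): 26-connected components of equal level."""
    ng = d.ng
    L = d.levels
    structure = np.ones((3, 3, 3), dtype=bool)
    zones: list[tuple[int, int]] = []
    for g in range(1, ng + 1):
        lab, n = ndimage.label(L == g, structure=structure)
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        zones.extend((g, int(s)) for s in sizes)
    max_size = max((s for _, s in zones), default=1)
    counts = np.zeros((ng, max_size), dtype=np.float64)
    for g, s in zones:
        counts[g - 1, s - 1] += 1.0
    return TextureMatrix("glszm", counts, ng, d.n_voxels)


def build_gldm(d: DiscretizedVOI, alpha: float = 0.0) -> TextureMatrix:
    """Dependence matrix P(i, j): voxels of level i with exactly j of their
    26 in-mask neighbors within |level difference| <= alpha. Sums to Np."""
    if alpha < 0:
        raise ConfigurationError("alpha must be >= 0")
    ng = d.ng
    L = d.levels
    dep = np.zeros(L.shape, dtype=np.int32)
    for off in OFFSETS_26:
        a, b = _shift_pairs(L, off)
        sel_src = tuple(
            slice(0, n - o) if o >= 0 else slice(-o, n) for n, o in zip(L.shape, off)
        )
        ok = (a > 0) & (b > 0) & (np.abs(a.astype(np.int64) - b) <= alpha)
        dep[sel_src] += ok
    counts = np.zeros((ng, 27), dtype=np.float64)
    inmask = L > 0
    np.add.at(counts, (L[inmask] - 1, dep[inmask]), 1.0)
    return TextureMatrix("gldm", counts, ng, d.n_voxels, extra={"alpha": alpha})


def build_ngtdm(d: DiscretizedVOI) -> TextureMatrix:
    """Neighborhood gray-tone difference table: per level i the voxel count
    n_i and the summed absolute difference s_i between the level and the
    mean of its in-mask 26-neighborhood."""
    ng = d.ng
    L = d.levels
    nb_sum = np.zeros(L.shape, dtype=np.float64)
    nb_cnt = np.zeros(L.shape, dtype=np.int32)
    for off in OFFSETS_26:
        sel_src = tuple(
            slice(0, n - o) if o >= 0 else slice(-o, n) for n, o in zip(L.shape, off)
        )
        a, b = _shift_pairs(L, off)
        ok = b > 0
        nb_sum[sel_src] += np.where(ok, b, 0)
        nb_cnt[sel_src] += ok
    valid = (L > 0) & (nb_cnt > 0)
    diffs = np.abs(L[valid] - nb_sum[valid] / nb_cnt[valid])
    lv = L[valid] - 1
    n_i = np.bincount(lv, minlength=ng).astype(np.float64)
    s_i = np.bincount(lv, weights=diffs, minlength=ng)
    table = np.stack([n_i, s_i], axis=1)
    return TextureMatrix("ngtdm", table, ng, int(valid.sum()))


# ---------------------------------------------------------------------------
# feature formulas per family
# ---------------------------------------------------------------------------

def _entropy(p):
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum()) if p.size else 0.0


def glcm_features(tm: TextureMatrix) -> dict[str, float]:
    p = tm.matrix
    ng = tm.ng
    if p.sum() == 0:  # single masked voxel: no pairs
        p = np.zeros_like(p)
        degenerate = True
    else:
        degenerate = False
    i = np.arange(1, ng + 1)[:, None]
    j = np.arange(1, ng + 1)[None, :]
    px = p.sum(axis=1)
    mu = float((px * np.arange(1, ng + 1)).sum())
    sigma2 = float((px * (np.arange(1, ng + 1) - mu) ** 2).sum())
    k_diff = np.arange(0, ng)
    p_diff = np.array([p[np.abs(i - j) == k].sum() for k in k_diff])
    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.array([p[(i + j) == k].sum() for k in k_sum])
    da = float((p_diff * k_diff).sum())
    out = {
        "Autocorrelation": float((p * i * j).sum()),
        "JointAverage": mu,
        "ClusterProminence": float((p * (i + j - 2 * mu) ** 4).sum()),
        "ClusterShade": float((p * (i + j - 2 * mu) ** 3).sum()),
        "ClusterTendency": float((p * (i + j - 2 * mu) ** 2).sum()),
        "Contrast": float((p * (i - j) ** 2).sum()),
        "Correlation": (
            1.0 if sigma2 <= 1e-12 else float(((p * i * j).sum() - mu * mu) / sigma2)
        ),
        "DifferenceAverage": da,
        "DifferenceEntropy": _entropy(p_diff),
        "DifferenceVariance": float((p_diff * (k_diff - da) ** 2).sum()),
        "Id": float((p / (1.0 + np.abs(i - j))).sum()),
        "Idm": float((p / (1.0 + (i - j) ** 2)).sum()),
        "Idmn": float((p / (1.0 + ((i - j) ** 2) / ng**2)).sum()),
        "Idn": float((p / (1.0 + np.abs(i - j) / ng)).sum()),
        "InverseVariance": float((p[i != j] / ((i - j) ** 2)[i != j].astype(float)).sum()),
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": _entropy(p.ravel()),
        "MaximumProbability": float(p.max()),
        "SumEntropy": _entropy(p_sum),
        "SumSquares": float((p * (i - mu) ** 2).sum()),
    }
    if degenerate:
        out["Correlation"] = 1.0
    return out


def glrlm_features(tm: TextureMatrix) -> dict[str, float]:
    R = tm.matrix
    ng = tm.ng
    nr = R.sum()
    if nr == 0:
        return {k: 0.0 for k in GLRLM_FEATURES}
    i = np.arange(1, ng + 1)[:, None].astype(float)
    r = np.arange(1, R.shape[1] + 1)[None, :].astype(float)
    p = R / nr
    ri = R.sum(axis=1)
    rr = R.sum(axis=0)
    mu_i = float((p * i).sum())
    mu_r = float((p * r).sum())
    n_dir = (tm.extra or {}).get("n_directions", 1)
    return {
        "ShortRunEmphasis": float((R / r**2).sum() / nr),
        "LongRunEmphasis": float((R * r**2).sum() / nr),
        "GrayLevelNonUniformity": float((ri**2).sum() / nr),
        "GrayLevelNonUniformityNormalized": float((ri**2).sum() / nr**2),
        "RunLengthNonUniformity": float((rr**2).sum() / nr),
        "RunLengthNonUniformityNormalized": float((rr**2).sum() / nr**2),
        "RunPercentage": float(nr / (tm.n_voxels * n_dir)),
        "GrayLevelVariance": float((p * (i - mu_i) ** 2).sum()),
        "RunVariance": float((p * (r - mu_r) ** 2).sum()),
        "RunEntropy": _entropy(p.ravel()),
        "LowGrayLevelRunEmphasis": float((R / i**2).sum() / nr),
        "HighGrayLevelRunEmphasis": float((R * i**2).sum() / nr),
        "ShortRunLowGrayLevelEmphasis": float((R / (i**2 * r**2)).sum() / nr),
        "ShortRunHighGrayLevelEmphasis": float((R * i**2 / r**2).sum() / nr),
    }


def glszm_features(tm: TextureMatrix) -> dict[str, float]:
    S = tm.matrix
    ng = tm.ng
    nz = S.sum()
    if nz == 0:
        return {k: 0.0 for k in GLSZM_FEATURES}
    i = np.arange(1, ng + 1)[:, None].astype(float)
    s = np.arange(1, S.shape[1] + 1)[None, :].astype(float)
    p = S / nz
    si = S.sum(axis=1)
    ss = S.sum(axis=0)
    mu_i = float((p * i).sum())
    mu_s = float((p * s).sum())
    return {
        "SmallAreaEmphasis": float((S / s**2).sum() / nz),
        "LargeAreaEmphasis": float((S * s**2).sum() / nz),
        "GrayLevelNonUniformity": float((si**2).sum() / nz),
        "GrayLevelNonUniformityNormalized": float((si**2).sum() / nz**2),
        "SizeZoneNonUniformity": float((ss**2).sum() / nz),
        "SizeZoneNonUniformityNormalized": float((ss**2).sum() / nz**2),
        "ZonePercentage": float(nz / tm.n_voxels),
        "GrayLevelVariance": float((p * (i - mu_i) ** 2).sum()),
        "ZoneVariance": float((p * (s - mu_s) ** 2).sum()),
        "ZoneEntropy": _entropy(p.ravel()),
        "LowGrayLevelZoneEmphasis": float((S / i**2).sum() / nz),
        "HighGrayLevelZoneEmphasis": float((S * i**2).sum() / nz),
        "SmallAreaLowGrayLevelEmphasis": float((S / (i**2 * s**2)).sum() / nz),
        "LargeAreaHighGrayLevelEmphasis": float((S * i**2 * s**2).sum() / nz),
    }


def gldm_features(tm: TextureMatrix) -> dict[str, float]:
    P = tm.matrix
    ng = tm.ng
    nz = P.sum()  # equals Np by construction
    if nz == 0:
        return {k: 0.0 for k in GLDM_FEATURES}
    i = np.arange(1, ng + 1)[:, None].astype(float)
    # dependence size = qualifying-neighbor count + 1 (includes the voxel)
    jv = (np.arange(P.shape[1]) + 1)[None, :].astype(float)
    p = P / nz
    pi = P.sum(axis=1)
    pj = P.sum(axis=0)
    mu_j = float((p * jv).sum())
    return {
        "SmallDependenceEmphasis": float((P / jv**2).sum() / nz),
        "LargeDependenceEmphasis": float((P * jv**2).sum() / nz),
        "GrayLevelNonUniformity": float((pi**2).sum() / nz),
        "DependenceNonUniformity": float((pj**2).sum() / nz),
        "GrayLevelVariance": float((p * (i - float((p * i).sum())) ** 2).sum()),
        "DependenceVariance": float((p * (jv - mu_j) ** 2).sum()),
        "DependenceEntropy": _entropy(p.ravel()),
        "LowGrayLevelEmphasis": float((P / i**2).sum() / nz),
        "HighGrayLevelEmphasis": float((P * i**2).sum() / nz),
        "SmallDependenceLowGrayLevelEmphasis": float((P / (i**2 * jv**2)).sum() / nz),
        "LargeDependenceLowGrayLevelEmphasis": float((P * jv**2 / i**2).sum() / nz),
    }


NGTDM_COARSENESS_CAP = 1e6


def ngtdm_features(tm: TextureMatrix) -> dict[str, float]:
    n_i = tm.matrix[:, 0]
    s_i = tm.matrix[:, 1]
    nvp = n_i.sum()
    ng = tm.ng
    if nvp == 0:
        return {k: 0.0 for k in NGTDM_FEATURES}
    p_i = n_i / nvp
    iv = np.arange(1, ng + 1).astype(float)
    ngp = int((p_i > 0).sum())
    ps = float((p_i * s_i).sum())
    coarseness = NGTDM_COARSENESS_CAP if ps == 0 else min(1.0 / ps, NGTDM_COARSENESS_CAP)
    if ngp <= 1:
        contrast = 0.0
    else:
        contrast = float(
            (p_i[:, None] * p_i[None, :] * (iv[:, None] - iv[None, :]) ** 2).sum()
            / (ngp * (ngp - 1))
            * (s_i.sum() / nvp)
        )
    mask = p_i > 0
    ipi = iv[mask] * p_i[mask]
    # denominator sums |i*p_i - j*p_j| over ordered pairs i != j with both
    # probabilities positive (the diagonal contributes zero)
    denom = float(np.abs(ipi[:, None] - ipi[None, :]).sum())
    busyness = 0.0 if denom == 0 else float(ps / denom)
    pv = p_i[mask]
    sv = s_i[mask]
    ivm = iv[mask]
    dif = np.abs(ivm[:, None] - ivm[None, :])
    complexity = float(
        (dif * (pv[:, None] * sv[:, None] + pv[None, :] * sv[None, :]) /
         (pv[:, None] + pv[None, :])).sum() / nvp
    )
    ssum = float(s_i.sum())
    strength = 0.0 if ssum == 0 else float(
        ((pv[:, None] + pv[None, :]) * (ivm[:, None] - ivm[None, :]) ** 2).sum() / ssum
    )
    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


GLCM_FEATURES = tuple(glcm_features(TextureMatrix("glcm", np.ones((2, 2)) / 4, 2, 4)))
GLRLM_FEATURES = (
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
    "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis",
)
GLSZM_FEATURES = (
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage", "GrayLevelVariance",
    "ZoneVariance", "ZoneEntropy", "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)
GLDM_FEATURES = (
    "SmallDependenceEmphasis", "LargeDependenceEmphasis",
    "GrayLevelNonUniformity", "DependenceNonUniformity", "GrayLevelVariance",
    "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
)
NGTDM_FEATURES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")

FAMILY_BUILDERS = {
    "glcm": build_glcm,
    "glrlm": build_glrlm,
    "glszm": build_glszm,
    "gldm": build_gldm,
    "ngtdm": build_ngtdm,
}
FAMILY_FEATURES = {
    "glcm": glcm_features,
    "glrlm": glrlm_features,
    "glszm": glszm_features,
    "gldm": gldm_features,
    "ngtdm": ngtdm_features,
}
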