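"""Exhaustive brute-force oracles for the texture-matrix families.

Everything here is written as directly as possible (explicit voxel loops,
flood fill, run walking) and stays independent of the vectorized
implementations it checks.
"""

import itertools

import numpy as np

DIRS_13 = [d for d in itertools.product((-1, 0, 1), repeat=3) if d > (0, 0, 0)]
NEIGH_26 = [d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]


def _inside(shape, p):
    return all(0 <= c < n for c, n in zip(p, shape))


def glcm_oracle(levels, ng):
    counts = np.zeros((ng, ng))
    shape = levels.shape
    for p in np.ndindex(shape):
        if levels[p] == 0:
            continue
        for d in DIRS_13:
            q = tuple(a + b for a, b in zip(p, d))
            if _inside(shape, q) and levels[q] > 0:
                counts[levels[p] - 1, levels[q] - 1] += 1
                counts[levels[q] - 1, levels[p] - 1] += 1
    total = counts.sum()
    return counts / total if total > 0 else counts


def glrlm_oracle(levels, ng):
    shape = levels.shape
    runs = []
    for d in DIRS_13:
        for p in np.ndindex(shape):
            if levels[p] == 0:
                continue
            prev = tuple(a - b for a, b in zip(p, d))
            if _inside(shape, prev) and levels[prev] == levels[p]:
                continue  # not a run start
            length = 1
            q = tuple(a + b for a, b in zip(p, d))
            while _inside(shape, q) and levels[q] == levels[p]:
                length += 1
                q = tuple(a + b for a, b in zip(q, d))
            runs.append((levels[p], length))
    max_len = max((l for _, l in runs), default=1)
    mat = np.zeros((ng, max_len))
    for g, l in runs:
        mat[g - 1, l - 1] += 1
    return mat


def glszm_oracle(levels, ng):
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    for p in np.ndindex(shape):
        if levels[p] == 0 or seen[p]:
            continue
        g = levels[p]
        stack = [p]
        seen[p] = True
        size = 0
        while stack:
            q = stack.pop()
            size += 1
            for d in NEIGH_26:
                r = tuple(a + b for a, b in zip(q, d))
                if _inside(shape, r) and not seen[r] and levels[r] == g:
                    seen[r] = True
                    stack.append(r)
        zones.append((g, size))
    max_size = max((s for _, s in zones), default=1)
    mat = np.zeros((ng, max_size))
    for g, s in zones:
        mat[g - 1, s - 1] += 1
    return mat


def gldm_oracle(levels, ng, alpha=0):
    shape = levels.shape
    mat = np.zeros((ng, 27))
    for p in np.ndindex(shape):
        if levels[p] == 0:
            continue
        dep = 0
        for d in NEIGH_26:
            q = tuple(a + b for a, b in zip(p, d))
            if _inside(shape, q) and levels[q] > 0 and abs(int(levels[q]) - int(levels[p])) <= alpha:
                dep += 1
        mat[levels[p] - 1, dep] += 1
    return mat


def ngtdm_oracle(levels, ng):
    shape = levels.shape
    n_i = np.zeros(ng)
    s_i = np.zeros(ng)
    for p in np.ndindex(shape):
        if levels[p] == 0:
            continue
        neigh = []
        for d in NEIGH_26:
            q = tuple(a + b for a, b in zip(p, d))
            if _inside(shape, q) and levels[q] > 0:
                neigh.append(levels[q])
        if not neigh:
            continue
        n_i[levels[p] - 1] += 1
        s_i[levels[p] - 1] += abs(levels[p] - sum(neigh) / len(neigh))
    return np.stack([n_i, s_i], axis=1)


# --- direct-summation formulas for the nine named features, computed from
# --- the brute-force matrices above

def idmn_oracle(levels, ng):
    p = glcm_oracle(levels, ng)
    s = 0.0
    for i in range(1, ng + 1):
        for j in range(1, ng + 1):
            s += p[i - 1, j - 1] / (1.0 + ((i - j) ** 2) / ng**2)
    return s


def gldm_named_oracle(levels, ng):
    mat = gldm_oracle(levels, ng)
    nz = mat.sum()
    ldlgle = sdlgle = dv = 0.0
    mu_j = 0.0
    for i in range(1, ng + 1):
        for j in range(27):
            mu_j += (mat[i - 1, j] / nz) * (j + 1)
    for i in range(1, ng + 1):
        for j in range(27):
            pij = mat[i - 1, j]
            jj = j + 1  # dependence size including the center voxel
            ldlgle += pij * jj**2 / i**2
            sdlgle += pij / (i**2 * jj**2)
            dv += (pij / nz) * (jj - mu_j) ** 2
    return {
        "LargeDependenceLowGrayLevelEmphasis": ldlgle / nz,
        "SmallDependenceLowGrayLevelEmphasis": sdlgle / nz,
        "DependenceVariance": dv,
    }


def zone_percentage_oracle(levels, ng):
    mat = glszm_oracle(levels, ng)
    return mat.sum() / (levels > 0).sum()


def busyness_oracle(levels, ng):
    table = ngtdm_oracle(levels, ng)
    n_i, s_i = table[:, 0], table[:, 1]
    nvp = n_i.sum()
    if nvp == 0:
        return 0.0
    p_i = n_i / nvp
    num = float((p_i * s_i).sum())
    den = 0.0
    for i in range(1, ng + 1):
        for j in range(1, ng + 1):
            if i != j and p_i[i - 1] > 0 and p_i[j - 1] > 0:
                den += abs(i * p_i[i - 1] - j * p_i[j - 1])
    return 0.0 if den == 0 else num / den


def firstorder_named_oracle(values):
    x = np.sort(np.asarray(values, dtype=float))
    q1, q3 = np.percentile(x, [25, 75])
    return {"Maximum": float(x[-1]), "InterquartileRange": float(q3 - q1)}


def auc_pair_counting(scores, labels):
    """AUC by exhaustive concordant/tied pair counting."""
    pos = [s for s, y in zip(scores, labels) if y == max(labels)]
    neg = [s for s, y in zip(scores, labels) if y != max(labels)]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def random_instance(rng, max_side=6, max_ng=4):
    """A random small discretized instance (levels array + ng)."""
    shape = tuple(int(rng.integers(2, max_side + 1)) for _ in range(3))
    ng = int(rng.integers(1, max_ng + 1))
    levels = rng.integers(1, ng + 1, size=shape).astype(np.int32)
    mask = rng.random(shape) < 0.75
    if not mask.any():
        mask.flat[0] = True
    levels[~mask] = 0
    return levels, ng
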