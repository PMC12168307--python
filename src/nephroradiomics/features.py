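"""Radiomic feature bank: first-order, shape, and texture features.

The default bank is 16 shape features (computed once on the original-grid
mask) plus 82 intensity features (18 first-order + 64 texture) for each of
the 15 derived image types, for 1246 named columns per subject and image
sequence. Column names follow the ``<imagetype>_<family>_<feature>``
convention, e.g. ``wavelet-LLL_gldm_LargeDependenceLowGrayLevelEmphasis``.
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull

from .errors import EmptyVOIError, FeatureComputationError
from .filters import DEFAULT_FILTER_BANK, FilterBankConfig, derive_image_types
from .texture import (
    FAMILY_BUILDERS,
    FAMILY_FEATURES,
    DiscretizedVOI,
    TextureMatrix,
    discretize,
)

DEFAULT_N_BINS = 32


def _load_manifest() -> dict:
    with resources.files("nephroradiomics.data").joinpath("feature_bank.json").open() as fh:
        return json.load(fh)


_MANIFEST = None


def default_bank_manifest() -> dict:
    """The packaged versioned bank manifest (families, features, image types)."""
    global _MANIFEST
    if _MANIFEST is None:
        _MANIFEST = _load_manifest()
    return _MANIFEST


def bank_feature_names(manifest: dict | None = None) -> list[str]:
    """All column names the manifest resolves to, in canonical order."""
    m = manifest or default_bank_manifest()
    names = [f"original_shape_{f}" for f in m["shape"]]
    for itype in m["image_types"]:
        for family in ("firstorder", "glcm", "glrlm", "glszm", "gldm", "ngtdm"):
            names += [f"{itype}_{family}_{f}" for f in m[family]]
    if len(set(names)) != len(names):
        raise FeatureComputationError("duplicate feature names in manifest")
    return names


# ---------------------------------------------------------------------------
# first-order features (18)
# ---------------------------------------------------------------------------

FIRSTORDER_FEATURES = (
    "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile",
    "90Percentile", "Maximum", "Mean", "Median", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
)


def firstorder_features(values, voxel_volume_mm3=1.0, n_bins=DEFAULT_N_BINS) -> dict[str, float]:
    """First-order statistics of the masked intensities.

    Entropy/Uniformity use the same fixed-bin-count histogram as the
    texture discretization. Skewness is 0 and Kurtosis 0 for a constant
    region (documented degenerate convention); Kurtosis is the
    non-excess (Pearson) moment ratio otherwise.
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size == 0:
        raise EmptyVOIError("no masked values")
    mean = float(x.mean())
    var = float(x.var())
    p10, q1, med, q3, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    if np.ptp(x) == 0:
        probs = np.array([1.0])
    else:
        hist, _ = np.histogram(x, bins=n_bins)
        probs = hist[hist > 0] / x.size
    sd = np.sqrt(var)
    robust = x[(x >= p10) & (x <= p90)]
    return {
        "Energy": float((x**2).sum()),
        "TotalEnergy": float(voxel_volume_mm3 * (x**2).sum()),
        "Entropy": float(-(probs * np.log2(probs)).sum()),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(med),
        "InterquartileRange": float(q3 - q1),
        "Range": float(np.ptp(x)),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": float(np.abs(robust - robust.mean()).mean()),
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "Skewness": 0.0 if sd == 0 else float(((x - mean) ** 3).mean() / sd**3),
        "Kurtosis": 0.0 if sd == 0 else float(((x - mean) ** 4).mean() / sd**4),
        "Variance": var,
        "Uniformity": float((probs**2).sum()),
    }


# ---------------------------------------------------------------------------
# shape features (16), voxel-based, on the original-geometry mask
# ---------------------------------------------------------------------------

SHAPE_FEATURES = (
    "VoxelVolume", "VoxelCount", "SurfaceArea", "SurfaceVolumeRatio",
    "Sphericity", "Compactness1", "Compactness2", "SphericalDisproportion",
    "Maximum3DDiameter", "MajorAxisLength", "MinorAxisLength",
    "LeastAxisLength", "Elongation", "Flatness", "Extent",
    "BoundingBoxVolume",
)


def _surface_area_mm2(mask, spacing):
    """Total area of exposed voxel faces."""
    area = 0.0
    face_areas = (
        spacing[1] * spacing[2],  # faces normal to axis 0
        spacing[0] * spacing[2],
        spacing[0] * spacing[1],
    )
    padded = np.pad(mask, 1)
    for axis, fa in enumerate(face_areas):
        d = np.diff(padded.astype(np.int8), axis=axis)
        area += np.abs(d).sum() * fa
    return float(area)


def shape_features(mask, spacing) -> dict[str, float]:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyVOIError("empty mask has no shape")
    spacing = np.asarray(spacing, dtype=float)
    n = int(mask.sum())
    voxel = float(np.prod(spacing))
    volume = n * voxel
    area = _surface_area_mm2(mask, spacing)
    idx = np.argwhere(mask).astype(np.float64) * spacing
    centered = idx - idx.mean(axis=0)
    if n > 1:
        cov = centered.T @ centered / n
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        eig = np.clip(eig, 0.0, None)
    else:
        eig = np.zeros(3)
    major, minor, least = (4.0 * np.sqrt(e) for e in eig)
    # surface voxels suffice for the maximum diameter; the convex hull
    # reduces the pairwise search further
    surf = mask & ~ndimage.binary_erosion(mask)
    pts = np.argwhere(surf).astype(np.float64) * spacing
    if len(pts) >= 5:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except Exception:
            pass
    if len(pts) == 1:
        max_diam = 0.0
    else:
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
        max_diam = float(np.sqrt(d2.max()))
    bbox_edges = idx.max(axis=0) - idx.min(axis=0) + spacing
    bbox_vol = float(np.prod(bbox_edges))
    r_equiv = (3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    return {
        "VoxelVolume": volume,
        "VoxelCount": float(n),
        "SurfaceArea": area,
        "SurfaceVolumeRatio": area / volume,
        "Sphericity": float(np.pi ** (1 / 3) * (6 * volume) ** (2 / 3) / area),
        "Compactness1": float(volume / (np.sqrt(np.pi) * area**1.5)),
        "Compactness2": float(36 * np.pi * volume**2 / area**3),
        "SphericalDisproportion": float(area / (4 * np.pi * r_equiv**2)),
        "Maximum3DDiameter": max_diam,
        "MajorAxisLength": float(major),
        "MinorAxisLength": float(minor),
        "LeastAxisLength": float(least),
        "Elongation": float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 1.0,
        "Flatness": float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 1.0,
        "Extent": volume / bbox_vol,
        "BoundingBoxVolume": bbox_vol,
    }


# ---------------------------------------------------------------------------
# named-feature dispatch and the full bank
# ---------------------------------------------------------------------------

def compute_feature(matrix_or_values, feature_name: str, **kwargs) -> float:
    """Evaluate one named feature from a texture matrix or a value array.

    For texture families pass the :class:`TextureMatrix`; for first-order
    pass the masked intensity values.
    """
    if isinstance(matrix_or_values, TextureMatrix):
        tm = matrix_or_values
        table = FAMILY_FEATURES[tm.family](tm)
        if feature_name not in table:
            raise FeatureComputationError(
                f"unknown {tm.family} feature {feature_name!r}"
            )
        return table[feature_name]
    table = firstorder_features(matrix_or_values, **kwargs)
    if feature_name not in table:
        raise FeatureComputationError(f"unknown first-order feature {feature_name!r}")
    return table[feature_name]


def intensity_features_for_image(volume, mask, spacing, n_bins=DEFAULT_N_BINS):
    """All 82 intensity features (per manifest families) for one image type."""
    vals = np.asarray(volume, dtype=np.float64)[np.asarray(mask, dtype=bool)]
    voxel = float(np.prod(spacing))
    out = {("firstorder", k): v for k, v in firstorder_features(vals, voxel, n_bins).items()}
    d = discretize(volume, mask, n_bins=n_bins, spacing=spacing)
    for family, builder in FAMILY_BUILDERS.items():
        tm = builder(d)
        for k, v in FAMILY_FEATURES[family](tm).items():
            out[(family, k)] = v
    return out


def compute_feature_vector(
    volume,
    mask,
    spacing,
    manifest: dict | None = None,
    filter_cfg: FilterBankConfig = DEFAULT_FILTER_BANK,
    noise_seed: int = 0,
) -> pd.Series:
    """The full named feature vector for one image volume and mask.

    Shape features are computed once on the original-geometry mask; the 82
    intensity features are repeated per derived image type. Any NaN/Inf
    raises, naming the offending feature.
    """
    m = manifest or default_bank_manifest()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyVOIError("empty mask")
    n_bins = int(m.get("n_bins", DEFAULT_N_BINS))
    values: dict[str, float] = {}
    shp = shape_features(mask, spacing)
    for f in m["shape"]:
        values[f"original_shape_{f}"] = shp[f]
    images = derive_image_types(volume, spacing, filter_cfg, seed=noise_seed)
    for itype in m["image_types"]:
        if itype not in images:
            raise FeatureComputationError(f"manifest image type {itype!r} not derived")
        feats = intensity_features_for_image(images[itype], mask, spacing, n_bins)
        for family in ("firstorder", "glcm", "glrlm", "glszm", "gldm", "ngtdm"):
            for f in m[family]:
                values[f"{itype}_{family}_{f}"] = feats[(family, f)]
    vec = pd.Series(values, dtype=np.float64)
    bad = vec.index[~np.isfinite(vec.to_numpy())]
    if len(bad):
        raise FeatureComputationError(f"non-finite feature values: {list(bad[:5])}")
    return vec


def feature_table(subjects, which: str, manifest=None,
                  filter_cfg: FilterBankConfig = DEFAULT_FILTER_BANK,
                  noise_seed: int = 0) -> pd.DataFrame:
    """Feature matrix (subjects x features) for one sequence ('t2w' or 'adc')."""
    rows = {}
    for subj in subjects:
        vol = subj.t2w if which == "t2w" else subj.adc
        rows[subj.subject_id] = compute_feature_vector(
            vol, subj.mask, subj.spacing, manifest=manifest,
            filter_cfg=filter_cfg, noise_seed=noise_seed,
        )
    df = pd.DataFrame(rows).T
    df.index.name = "subject_id"
    return df


def restricted_manifest(image_types, base: dict | None = None) -> dict:
    """A manifest limited to a subset of image types (same families)."""
    m = dict(base or default_bank_manifest())
    missing = [t for t in image_types if t not in m["image_types"]]
    if missing:
        raise FeatureComputationError(f"unknown image types: {missing}")
    m["image_types"] = list(image_types)
    return m
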