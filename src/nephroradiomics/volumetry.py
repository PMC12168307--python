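"""VOI volumetry and normative renal-volume banding.

Per-kidney volumes are voxel counts times the voxel volume (native grid, no
resampling); total renal volume is the sum of left and right. Totals are
compared against a packaged normative table of mean +/- 2 SD total renal
volume for normal children aged 6-48 months in half-year bands, and the
age-volume relationship is summarized per genotype class with Pearson
correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import matplotlib
import numpy as np
import pandas as pd
from scipy import stats

from .cohort import SubjectVolumes
from .errors import DegenerateInputError, EmptyVOIError, RangeError

matplotlib.use("Agg")


@dataclass(frozen=True)
class VOISummary:
    subject_id: str
    left_volume_cm3: float
    right_volume_cm3: float
    total_volume_cm3: float
    mean_t2_intensity: float
    mean_adc: float


@dataclass(frozen=True)
class NormativeBand:
    age_lo: float
    age_hi: float
    upper_cm3: float
    mean_cm3: float
    lower_cm3: float


def _load_normative_table() -> pd.DataFrame:
    with resources.files("nephroradiomics.data").joinpath(
        "normative_renal_volume.csv"
    ).open() as fh:
        return pd.read_csv(fh)


_NORMATIVE = None


def normative_table() -> pd.DataFrame:
    global _NORMATIVE
    if _NORMATIVE is None:
        _NORMATIVE = _load_normative_table()
    return _NORMATIVE.copy()


def compute_voi_summary(subject: SubjectVolumes) -> VOISummary:
    """Volumes (cm^3) and masked mean intensities for one subject.

    Means are taken over the union of both parenchyma masks on the raw
    (unfiltered) images.
    """
    left = subject.mask_left.astype(bool)
    right = subject.mask_right.astype(bool)
    if not left.any() or not right.any():
        raise EmptyVOIError(f"empty parenchyma mask for {subject.subject_id}")
    voxel_cm3 = float(np.prod(subject.spacing)) / 1000.0
    left_vol = int(left.sum()) * voxel_cm3
    right_vol = int(right.sum()) * voxel_cm3
    union = left | right
    return VOISummary(
        subject_id=subject.subject_id,
        left_volume_cm3=left_vol,
        right_volume_cm3=right_vol,
        total_volume_cm3=left_vol + right_vol,
        mean_t2_intensity=float(subject.t2w[union].mean()),
        mean_adc=float(subject.adc[union].mean()),
    )


def normative_lookup(age_months: float) -> NormativeBand:
    """Normative band for the half-year interval containing ``age_months``.

    Bands are half-open [lo, lo+6); 48 months exactly is out of range.
    """
    table = normative_table()
    if not (6 <= age_months < 48):
        raise RangeError(f"age {age_months} months outside the tabulated range [6, 48)")
    row = table[(table.age_lo_months <= age_months) & (age_months < table.age_hi_months)]
    r = row.iloc[0]
    return NormativeBand(
        age_lo=float(r.age_lo_months),
        age_hi=float(r.age_hi_months),
        upper_cm3=float(r.upper_cm3),
        mean_cm3=float(r.mean_cm3),
        lower_cm3=float(r.lower_cm3),
    )


def classify_vs_normative(total_volume_cm3: float, band: NormativeBand) -> str:
    """'above' iff strictly above the mean+2SD limit; 'below' iff strictly
    under mean-2SD; otherwise 'within'."""
    if total_volume_cm3 > band.upper_cm3:
        return "above"
    if total_volume_cm3 < band.lower_cm3:
        return "below"
    return "within"


def age_volume_correlation(ages, volumes) -> tuple[float, float, int]:
    """Pearson r between age and total volume with two-sided t-transform p."""
    ages = np.asarray(ages, dtype=float)
    volumes = np.asarray(volumes, dtype=float)
    if ages.size != volumes.size or ages.size < 3:
        raise DegenerateInputError("need >= 3 paired observations")
    if np.ptp(ages) == 0 or np.ptp(volumes) == 0:
        raise DegenerateInputError("constant series has undefined correlation")
    r, p = stats.pearsonr(ages, volumes)
    return float(r), float(p), int(ages.size)


def volumetry_table(subjects, clinical: pd.DataFrame) -> pd.DataFrame:
    """VOI summaries for a cohort, with normative classification per subject."""
    ages = clinical.set_index("subject_id")["age_months"]
    rows = []
    for subj in subjects:
        s = compute_voi_summary(subj)
        age = float(ages.loc[s.subject_id])
        band = normative_lookup(min(age, 47.99))
        rows.append(
            {
                "subject_id": s.subject_id,
                "left_volume_cm3": s.left_volume_cm3,
                "right_volume_cm3": s.right_volume_cm3,
                "total_volume_cm3": s.total_volume_cm3,
                "mean_t2_intensity": s.mean_t2_intensity,
                "mean_adc": s.mean_adc,
                "normative_upper_cm3": band.upper_cm3,
                "vs_normative": classify_vs_normative(s.total_volume_cm3, band),
            }
        )
    return pd.DataFrame(rows)


def per_class_correlations(vol_table: pd.DataFrame, clinical: pd.DataFrame) -> pd.DataFrame:
    merged = vol_table.merge(clinical[["subject_id", "age_months", "class_label"]], on="subject_id")
    rows = []
    for label, grp in merged.groupby("class_label"):
        try:
            r, p, n = age_volume_correlation(grp.age_months, grp.total_volume_cm3)
        except DegenerateInputError:
            r, p, n = np.nan, np.nan, len(grp)
        rows.append({"class_label": label, "pearson_r": r, "p_value": p, "n": n})
    return pd.DataFrame(rows)


def plot_age_volume(vol_table: pd.DataFrame, clinical: pd.DataFrame, path) -> None:
    """Scatter of age vs total volume per class with normative band lines."""
    import matplotlib.pyplot as plt

    merged = vol_table.merge(clinical[["subject_id", "age_months", "class_label"]], on="subject_id")
    fig, ax = plt.subplots(figsize=(7, 5))
    for label, grp in merged.groupby("class_label"):
        ax.scatter(grp.age_months, grp.total_volume_cm3, label=label, alpha=0.7)
    table = normative_table()
    mid = (table.age_lo_months + table.age_hi_months) / 2
    for col, style in (("upper_cm3", "--"), ("mean_cm3", "-"), ("lower_cm3", ":")):
        ax.plot(mid, table[col], style, color="green", alpha=0.6, label=col)
    ax.set_xlabel("age (months)")
    ax.set_ylabel("total renal volume (cm^3)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
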