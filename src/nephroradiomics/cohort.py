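"""Synthetic renal MRI phantom cohorts.

Generates paired T2-weighted and ADC volumes with parenchyma masks plus a
clinical covariate table, emulating the statistical structure of a
two-genotype Beckwith-Wiedemann cohort: the renal-predisposition subtype
(paternal UPD of 11p15 pooled with IC1 gain of imprinting) has larger total
renal volume, a weaker age-volume correlation, coarser parenchymal texture
and a higher rate of cyst-like renal inclusions than the IC2 subtype.

Kidneys are modelled as axis-aligned superellipsoids (long axis
cranio-caudal) with a concentric excluded cavity standing in for the renal
collecting system, so masks are parenchyma-only. Parenchymal texture is a
Gaussian random field whose correlation length is the per-class
heterogeneity dial.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import gamma

from .errors import CapacityError, ConfigurationError, RangeError

CLASS_RENAL = "UPD+IC1"
CLASS_NONRENAL = "IC2"
CLASS_LABELS = (CLASS_RENAL, CLASS_NONRENAL)

FLAG_NAMES = (
    "hemihypertrophy",
    "macrosomia",
    "nevus_flammeus",
    "ear_creases_pits",
    "omphalocele_umbilical_hernia",
    "renal_anomaly",
    "nonrenal_abdominal_anomaly",
)

AGE_RANGE_MONTHS = (6, 48)

# Superellipsoid exponent and kidney semi-axis ratios (z : y : x); the
# collecting-system cavity is the same shape scaled by CAVITY_FRACTION.
SUPERELLIPSOID_EXPONENT = 2.5
AXIS_RATIOS = (1.0, 0.42, 0.34)
CAVITY_FRACTION = 0.35


@dataclass(frozen=True)
class VolumeModel:
    """Linear model of total renal volume (cm^3) against age (months)."""

    intercept_cm3: float
    slope_cm3_per_month: float
    noise_sd_cm3: float

    def __post_init__(self) -> None:
        if self.noise_sd_cm3 < 0:
            raise ConfigurationError("volume noise SD must be >= 0")

    def draw(self, age_months: float, rng: np.random.Generator) -> float:
        mu = self.intercept_cm3 + self.slope_cm3_per_month * age_months
        # symmetric truncation keeps the mean/median while bounding the
        # geometry that must fit on the voxel grid
        eps = float(np.clip(rng.standard_normal(), -2.33, 2.33))
        return float(mu + self.noise_sd_cm3 * eps)

    def analytic_age_volume_r(self, age_sd_months: float) -> float:
        """Pearson r implied by the variance decomposition of the model."""
        s = self.slope_cm3_per_month * age_sd_months
        return s / float(np.hypot(s, self.noise_sd_cm3))


@dataclass(frozen=True)
class TextureModel:
    """Gaussian-random-field texture: correlation length and amplitude."""

    corr_length_mm: float
    amplitude: float


@dataclass(frozen=True)
class LesionModel:
    """Cyst-like hyperintense inclusions: per-subject occurrence rate."""

    rate: float
    radius_mm: tuple[float, float] = (3.0, 6.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate <= 1.0:
            raise ConfigurationError("lesion rate must lie in [0, 1]")


@dataclass(frozen=True)
class ADCModel:
    """Between-subject mean/SD of parenchymal ADC (1e-6 mm^2/s scale)."""

    mean: float
    sd: float
    texture_amplitude: float = 80.0


@dataclass(frozen=True)
class GridSpec:
    shape: tuple[int, int, int] = (96, 96, 36)
    spacing_mm: tuple[float, float, float] = (0.9375, 0.9375, 5.0)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing_mm):
            raise ConfigurationError("voxel spacing components must be > 0")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


@dataclass(frozen=True)
class CohortSpec:
    """Full parameterization of a two-class synthetic cohort."""

    n_per_class: int = 25
    age_range: tuple[int, int] = AGE_RANGE_MONTHS
    volume_model: dict[str, VolumeModel] = field(default_factory=dict)
    texture_model: dict[str, TextureModel] = field(default_factory=dict)
    lesion_model: dict[str, LesionModel] = field(default_factory=dict)
    adc_model: dict[str, ADCModel] = field(default_factory=dict)
    clinical_rates: dict[str, dict[str, float]] = field(default_factory=dict)
    male_rate: dict[str, float] = field(default_factory=dict)
    grid: GridSpec = field(default_factory=GridSpec)
    master_seed: int = 0
    t2_base: float = 370.0
    t2_background: float = 60.0

    def __post_init__(self) -> None:
        if self.n_per_class < 2:
            raise ConfigurationError("n_per_class must be >= 2")
        for rates in self.clinical_rates.values():
            for name, r in rates.items():
                if not 0.0 <= r <= 1.0:
                    raise ConfigurationError(f"rate for {name} outside [0,1]")

    def to_jsonable(self) -> dict:
        return _spec_to_jsonable(self)


def _spec_to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _spec_to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _spec_to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_spec_to_jsonable(v) for v in obj]
    return obj


def default_cohort_spec(
    n_per_class: int = 25,
    master_seed: int = 0,
    grid: GridSpec | None = None,
    null: bool = False,
) -> CohortSpec:
    """Study-condition cohort.

    Volume models are calibrated so the renal-predisposition class has
    median total volume near 116 cm^3 with age-volume correlation near
    0.38, and the IC2 class median near 91 cm^3 with correlation near 0.71
    (the implied r is slope*SD_age/SD_vol with SD_age ~ 12.4 months for
    integer ages uniform on [6, 48]).

    With ``null=True`` both classes share the IC2 models (no class signal),
    for calibration runs.
    """
    renal = dict(
        volume=VolumeModel(90.4, 0.949, 28.3),
        texture=TextureModel(corr_length_mm=6.0, amplitude=60.0),
        lesion=LesionModel(rate=0.375),
        adc=ADCModel(mean=1340.13, sd=67.53),
        rates={
            "hemihypertrophy": 11 / 24,
            "macrosomia": 11 / 24,
            "nevus_flammeus": 3 / 24,
            "ear_creases_pits": 4 / 24,
            "omphalocele_umbilical_hernia": 9 / 24,
            "renal_anomaly": 9 / 24,
            "nonrenal_abdominal_anomaly": 7 / 24,
        },
        male=10 / 24,
    )
    nonrenal = dict(
        volume=VolumeModel(58.6, 1.20, 14.8),
        texture=TextureModel(corr_length_mm=3.0, amplitude=60.0),
        lesion=LesionModel(rate=0.08),
        adc=ADCModel(mean=1343.81, sd=75.81),
        rates={
            "hemihypertrophy": 9 / 25,
            "macrosomia": 6 / 25,
            "nevus_flammeus": 9 / 25,
            "ear_creases_pits": 10 / 25,
            "omphalocele_umbilical_hernia": 17 / 25,
            "renal_anomaly": 2 / 25,
            "nonrenal_abdominal_anomaly": 0.0,
        },
        male=17 / 25,
    )
    if null:
        renal = nonrenal
    return CohortSpec(
        n_per_class=n_per_class,
        volume_model={CLASS_RENAL: renal["volume"], CLASS_NONRENAL: nonrenal["volume"]},
        texture_model={CLASS_RENAL: renal["texture"], CLASS_NONRENAL: nonrenal["texture"]},
        lesion_model={CLASS_RENAL: renal["lesion"], CLASS_NONRENAL: nonrenal["lesion"]},
        adc_model={CLASS_RENAL: renal["adc"], CLASS_NONRENAL: nonrenal["adc"]},
        clinical_rates={CLASS_RENAL: dict(renal["rates"]), CLASS_NONRENAL: dict(nonrenal["rates"])},
        male_rate={CLASS_RENAL: renal["male"], CLASS_NONRENAL: nonrenal["male"]},
        grid=grid if grid is not None else GridSpec(),
        master_seed=master_seed,
    )


def coarse_grid() -> GridSpec:
    """Down-sampled grid for fast runs: 1.5x coarser in-plane."""
    return GridSpec(shape=(64, 64, 28), spacing_mm=(1.40625, 1.40625, 5.0))


@dataclass
class SubjectVolumes:
    """Paired T2WI/ADC arrays with left/right parenchyma masks."""

    subject_id: str
    t2w: np.ndarray
    adc: np.ndarray
    mask_left: np.ndarray
    mask_right: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.t2w, self.adc, self.mask_left, self.mask_right)}
        if len(shapes) != 1:
            raise ConfigurationError("subject arrays must share one shape")
        if np.logical_and(self.mask_left, self.mask_right).any():
            raise ConfigurationError("left/right masks overlap")

    @property
    def mask(self) -> np.ndarray:
        return np.logical_or(self.mask_left, self.mask_right)


@dataclass(frozen=True)
class ClinicalRecord:
    subject_id: str
    age_months: int
    sex: str
    class_label: str
    flags: dict[str, int]

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ConfigurationError(f"unknown class label {self.class_label!r}")
        extra = set(self.flags) - set(FLAG_NAMES)
        if extra:
            raise ConfigurationError(f"undeclared flags: {sorted(extra)}")


def superellipsoid_volume(a: float, b: float, c: float, p: float = SUPERELLIPSOID_EXPONENT) -> float:
    """Analytic volume of |x/a|^p + |y/b|^p + |z/c|^p <= 1.

    V = 8abc * Gamma(1+1/p)^3 / Gamma(1+3/p); p=2 recovers 4*pi*abc/3.
    """
    return 8.0 * a * b * c * gamma(1 + 1 / p) ** 3 / gamma(1 + 3 / p)


def _subject_rng(master_seed: int, stream: int, index: int) -> np.random.Generator:
    # Documented substream layout: entropy tuple (master_seed, stream, index);
    # stream 0 = phantom imagery, stream 1 = clinical covariates.
    return np.random.default_rng([master_seed, stream, index])


def _rasterize_superellipsoid(shape, spacing, center_mm, semi_mm, p):
    coords = [
        (np.arange(n) * s - c) / ax
        for n, s, c, ax in zip(shape, spacing, center_mm, semi_mm)
    ]
    zz = np.abs(coords[0])[:, None, None] ** p
    yy = np.abs(coords[1])[None, :, None] ** p
    xx = np.abs(coords[2])[None, None, :] ** p
    return (zz + yy + xx) <= 1.0


def _gaussian_random_field(shape, spacing, corr_length_mm, rng):
    """Unit-variance correlated field: Gaussian-smoothed white noise."""
    white = rng.standard_normal(shape)
    sigma_vox = [corr_length_mm / s for s in spacing]
    f = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="wrap")
    sd = f.std()
    if sd == 0:
        return np.zeros(shape)
    return (f - f.mean()) / sd


def _solve_semi_axes(parenchyma_mm3: float, ratio_jitter, p=SUPERELLIPSOID_EXPONENT):
    """Semi-axes (z,y,x) of an outer shell whose shell-minus-cavity volume
    equals the target parenchymal volume."""
    shell_mm3 = parenchyma_mm3 / (1.0 - CAVITY_FRACTION**3)
    rz, ry, rx = (r * j for r, j in zip(AXIS_RATIOS, ratio_jitter))
    g = 8.0 * gamma(1 + 1 / p) ** 3 / gamma(1 + 3 / p)
    a = (shell_mm3 / (g * rz * ry * rx)) ** (1 / 3)
    return a * rz, a * ry, a * rx


# T2 lesion contrast, in units of the texture amplitude: well above the
# 6-SD envelope of the unit-variance random field.
LESION_SD_MULTIPLE = 10.0


def generate_kidney_phantom(
    spec: CohortSpec,
    class_label: str,
    age_months: float,
    subject_seed: int,
    subject_id: str | None = None,
) -> SubjectVolumes:
    """Build one subject's T2WI/ADC volumes and parenchyma masks.

    The total parenchymal mask volume matches the draw from the class
    volume model up to rasterization error (of order one voxel volume per
    surface voxel).
    """
    lo, hi = spec.age_range
    if not lo <= age_months <= hi:
        raise RangeError(f"age {age_months} outside [{lo}, {hi}] months")
    for d, name in (
        (spec.volume_model, "volume_model"),
        (spec.texture_model, "texture_model"),
        (spec.lesion_model, "lesion_model"),
        (spec.adc_model, "adc_model"),
    ):
        if class_label not in d:
            raise ConfigurationError(f"{name} missing class {class_label!r}")

    rng = np.random.default_rng(subject_seed)
    shape, spacing = spec.grid.shape, spec.grid.spacing_mm
    extent_mm = [n * s for n, s in zip(shape, spacing)]

    total_cm3 = max(30.0, spec.volume_model[class_label].draw(age_months, rng))
    left_fraction = float(np.clip(rng.normal(0.5, 0.02), 0.45, 0.55))
    targets_mm3 = (total_cm3 * left_fraction * 1000.0, total_cm3 * (1 - left_fraction) * 1000.0)

    masks = []
    shells = []
    for k, target in enumerate(targets_mm3):
        jitter = 1.0 + rng.uniform(-0.08, 0.08, size=3)
        az, ay, ax = _solve_semi_axes(target, jitter)
        # arrays are indexed (x, y, z): the kidney long axis runs along the
        # slice direction z (last axis); lateral placement along axis 0
        qx = extent_mm[0] / 4.0
        cx = qx if k == 0 else 3.0 * qx
        cx += rng.uniform(-1.5, 1.5)
        cy = extent_mm[1] / 2.0 + rng.uniform(-3.0, 3.0)
        cz = extent_mm[2] / 2.0 + rng.uniform(-5.0, 5.0)
        margin = 1.0  # mm clearance to the grid boundary
        if (
            az + margin > min(cz, extent_mm[2] - cz)
            or ay + margin > min(cy, extent_mm[1] - cy)
            or ax + margin > min(cx, extent_mm[0] - cx)
        ):
            raise CapacityError(
                f"kidney of {target / 1000:.1f} cm^3 does not fit grid {shape} "
                f"at spacing {spacing}"
            )
        center = (cx, cy, cz)
        semi = (ax, ay, az)
        shell = _rasterize_superellipsoid(shape, spacing, center, semi, SUPERELLIPSOID_EXPONENT)
        cavity = _rasterize_superellipsoid(
            shape, spacing, center, tuple(CAVITY_FRACTION * s for s in semi), SUPERELLIPSOID_EXPONENT
        )
        masks.append(shell & ~cavity)
        shells.append(shell)
    mask_left, mask_right = masks
    if not (mask_left.any() and mask_right.any()):
        raise CapacityError("rasterized mask is empty; grid too coarse for target volume")

    tex = spec.texture_model[class_label]
    adc_model = spec.adc_model[class_label]
    parenchyma = mask_left | mask_right
    cavity_region = (shells[0] | shells[1]) & ~parenchyma

    t2 = np.full(shape, spec.t2_background, dtype=np.float64)
    t2 += 5.0 * rng.standard_normal(shape)
    field_t2 = _gaussian_random_field(shape, spacing, tex.corr_length_mm, rng)
    t2[parenchyma] = spec.t2_base + tex.amplitude * field_t2[parenchyma]
    t2[cavity_region] = 800.0  # collecting-system fluid is T2-hyperintense

    subject_adc_mean = rng.normal(adc_model.mean, adc_model.sd)
    adc = np.full(shape, 300.0, dtype=np.float64)
    adc += 20.0 * rng.standard_normal(shape)
    field_adc = _gaussian_random_field(shape, spacing, tex.corr_length_mm, rng)
    adc[parenchyma] = subject_adc_mean + adc_model.texture_amplitude * field_adc[parenchyma]
    adc[cavity_region] = 3000.0

    lesion = spec.lesion_model[class_label]
    if rng.random() < lesion.rate:
        n_lesions = 1 + rng.poisson(0.7)
        vox_idx = np.argwhere(parenchyma)
        for _ in range(n_lesions):
            ci = vox_idx[rng.integers(len(vox_idx))]
            radius = rng.uniform(*lesion.radius_mm)
            sphere = _rasterize_superellipsoid(
                shape, spacing,
                tuple(c * s for c, s in zip(ci, spacing)),
                (radius, radius, radius), 2.0,
            )
            blob = sphere & parenchyma
            t2[blob] = spec.t2_base + LESION_SD_MULTIPLE * tex.amplitude
            adc[blob] = subject_adc_mean + LESION_SD_MULTIPLE * adc_model.texture_amplitude

    return SubjectVolumes(
        subject_id=subject_id or f"s{subject_seed}",
        t2w=t2,
        adc=adc,
        mask_left=mask_left.astype(np.uint8),
        mask_right=mask_right.astype(np.uint8),
        spacing=spacing,
    )


def subject_seed_for(spec: CohortSpec, index: int) -> int:
    """Deterministic per-subject seed below 2^31, hashed from the master seed."""
    h = hashlib.sha256(f"{spec.master_seed}:{index}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def generate_clinical_table(spec: CohortSpec) -> list[ClinicalRecord]:
    """Draw the per-subject clinical covariates (ages, sex, phenotype flags)."""
    records = []
    index = 0
    for label in CLASS_LABELS:
        rates = spec.clinical_rates.get(label)
        if rates is None:
            raise ConfigurationError(f"clinical_rates missing class {label!r}")
        missing = set(FLAG_NAMES) - set(rates)
        if missing:
            raise ConfigurationError(f"missing rates for flags: {sorted(missing)}")
        for i in range(spec.n_per_class):
            rng = _subject_rng(spec.master_seed, 1, index)
            age = int(rng.integers(spec.age_range[0], spec.age_range[1] + 1))
            sex = "M" if rng.random() < spec.male_rate.get(label, 0.5) else "F"
            flags = {name: int(rng.random() < rates[name]) for name in FLAG_NAMES}
            short = "updic1" if label == CLASS_RENAL else "ic2"
            records.append(
                ClinicalRecord(
                    subject_id=f"{short}-{i:03d}",
                    age_months=age,
                    sex=sex,
                    class_label=label,
                    flags=flags,
                )
            )
            index += 1
    return records


def clinical_table_to_frame(records: list[ClinicalRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"subject_id": r.subject_id, "age_months": r.age_months, "sex": r.sex,
               "class_label": r.class_label}
        row.update(r.flags)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class CohortBundle:
    spec: CohortSpec
    subjects: list[SubjectVolumes]
    clinical: pd.DataFrame
    manifest: dict


def generate_cohort(spec: CohortSpec, out_dir: str | Path | None = None) -> CohortBundle:
    """Generate the full cohort; optionally write NIfTI + CSV + manifest.

    Re-running with the same spec reproduces identical arrays and files.
    """
    records = generate_clinical_table(spec)
    subjects = []
    seeds = {}
    for index, rec in enumerate(records):
        seed = subject_seed_for(spec, index)
        seeds[rec.subject_id] = seed
        subjects.append(
            generate_kidney_phantom(
                spec, rec.class_label, rec.age_months, seed, subject_id=rec.subject_id
            )
        )
    clinical = clinical_table_to_frame(records)
    manifest = {
        "spec": spec.to_jsonable(),
        "subject_seeds": seeds,
        "n_subjects": len(subjects),
    }
    bundle = CohortBundle(spec=spec, subjects=subjects, clinical=clinical, manifest=manifest)
    if out_dir is not None:
        write_cohort(bundle, out_dir)
    return bundle


def write_cohort(bundle: CohortBundle, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sp = bundle.spec.grid.spacing_mm
    affine = np.diag([sp[0], sp[1], sp[2], 1.0])  # arrays are indexed (x, y, z)
    for subj in bundle.subjects:
        for name, arr, dtype in (
            ("t2w", subj.t2w, np.float32),
            ("adc", subj.adc, np.float32),
            ("mask_left", subj.mask_left, np.uint8),
            ("mask_right", subj.mask_right, np.uint8),
        ):
            img = nib.Nifti1Image(arr.astype(dtype), affine)
            img.header.set_zooms(sp)
            nib.save(img, out / f"{subj.subject_id}_{name}.nii.gz")
    bundle.clinical.to_csv(out / "clinical.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=2, sort_keys=True)
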