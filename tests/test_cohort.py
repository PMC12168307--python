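import dataclasses

import numpy as np
import pytest
from scipy import ndimage

from nephroradiomics.cohort import (
    CLASS_NONRENAL,
    CLASS_RENAL,
    FLAG_NAMES,
    CohortSpec,
    GridSpec,
    VolumeModel,
    coarse_grid,
    default_cohort_spec,
    generate_clinical_table,
    generate_cohort,
    generate_kidney_phantom,
    superellipsoid_volume,
    _rasterize_superellipsoid,
)
from nephroradiomics.errors import CapacityError, ConfigurationError, RangeError


def test_rasterized_volume_matches_analytic_within_surface_error():
    """Voxelized superellipsoid volume agrees with the closed form up to one
    voxel volume per surface voxel (spacing 1x1x5 mm, ~100 cm^3 target)."""
    spacing = (1.0, 1.0, 5.0)
    semi = (25.0, 30.0, 55.0)  # analytic ellipsoid ~ 4*pi*abc/3 = 172.7 cm^3
    for p in (2.0, 2.5):
        m = _rasterize_superellipsoid((100, 100, 40), spacing, (50, 50, 100), semi, p)
        analytic = superellipsoid_volume(*semi, p)
        voxel = float(np.prod(spacing))
        n_surf = int((m & ~ndimage.binary_erosion(m)).sum())
        assert abs(m.sum() * voxel - analytic) <= voxel * n_surf


def test_superellipsoid_volume_reduces_to_ellipsoid():
    a, b, c = 3.0, 4.0, 5.0
    assert superellipsoid_volume(a, b, c, 2.0) == pytest.approx(4 / 3 * np.pi * a * b * c)


def test_phantom_total_volume_calibration(coarse_spec):
    """Mean generated total volume tracks the class volume model (2 SE)."""
    model = coarse_spec.volume_model[CLASS_RENAL]
    age = 24
    vox = coarse_spec.grid.voxel_volume_mm3
    vols = []
    for i in range(120):
        s = generate_kidney_phantom(coarse_spec, CLASS_RENAL, age, 5000 + i)
        vols.append((int(s.mask_left.sum()) + int(s.mask_right.sum())) * vox / 1000)
    target = model.intercept_cm3 + model.slope_cm3_per_month * age
    se = model.noise_sd_cm3 / np.sqrt(len(vols))
    assert abs(np.mean(vols) - target) < 2 * se


def test_phantom_determinism_and_mask_geometry(coarse_spec, phantom):
    again = generate_kidney_phantom(coarse_spec, CLASS_RENAL, 15, 20240615)
    for attr in ("t2w", "adc", "mask_left", "mask_right"):
        assert np.array_equal(getattr(phantom, attr), getattr(again, attr))
    assert phantom.mask_left.any() and phantom.mask_right.any()
    assert not np.logical_and(phantom.mask_left, phantom.mask_right).any()


def test_zero_lesion_rate_stays_inside_texture_envelope():
    spec = default_cohort_spec(master_seed=3, grid=coarse_grid(), null=True)
    lesion_free = {k: dataclasses.replace(v, rate=0.0) for k, v in spec.lesion_model.items()}
    spec = dataclasses.replace(spec, lesion_model=lesion_free)
    tex = spec.texture_model[CLASS_RENAL]
    for i in range(10):
        s = generate_kidney_phantom(spec, CLASS_RENAL, 20, 900 + i)
        vals = s.t2w[s.mask.astype(bool)]
        assert vals.max() < spec.t2_base + 6 * tex.amplitude


def test_age_out_of_range_rejected(coarse_spec):
    with pytest.raises(RangeError):
        generate_kidney_phantom(coarse_spec, CLASS_RENAL, 60, 1)


def test_unrealizable_volume_raises_capacity_error():
    spec = default_cohort_spec(master_seed=0, grid=coarse_grid())
    huge = {k: VolumeModel(2000.0, 0.0, 0.0) for k in spec.volume_model}
    spec = dataclasses.replace(spec, volume_model=huge)
    with pytest.raises(CapacityError):
        generate_kidney_phantom(spec, CLASS_RENAL, 20, 1)


def test_clinical_rates_recovered_within_three_binomial_se():
    spec = default_cohort_spec(n_per_class=2000, master_seed=17)
    records = generate_clinical_table(spec)
    for label in (CLASS_RENAL, CLASS_NONRENAL):
        sub = [r for r in records if r.class_label == label]
        for flag in ("omphalocele_umbilical_hernia", "renal_anomaly"):
            p = spec.clinical_rates[label][flag]
            se = np.sqrt(p * (1 - p) / len(sub))
            emp = np.mean([r.flags[flag] for r in sub])
            assert abs(emp - p) < 3 * se


def test_rate_one_flags_every_record():
    spec = default_cohort_spec(n_per_class=30, master_seed=2)
    ones = {cls: {f: 1.0 for f in FLAG_NAMES} for cls in spec.clinical_rates}
    spec = dataclasses.replace(spec, clinical_rates=ones)
    records = generate_clinical_table(spec)
    assert all(all(r.flags[f] == 1 for f in FLAG_NAMES) for r in records)


def test_missing_flag_rate_is_configuration_error():
    spec = default_cohort_spec(n_per_class=5, master_seed=2)
    incomplete = {cls: {"macrosomia": 0.5} for cls in spec.clinical_rates}
    spec = dataclasses.replace(spec, clinical_rates=incomplete)
    with pytest.raises(ConfigurationError):
        generate_clinical_table(spec)


def test_contingency_direction_recovered_at_study_size():
    """At n=25/class with the study flag rates, the direction of the
    omphalocele effect (higher in the IC2 class) is recovered in >= 80%
    of replicates."""
    hits = 0
    reps = 200
    for rep in range(reps):
        spec = default_cohort_spec(n_per_class=25, master_seed=10_000 + rep)
        records = generate_clinical_table(spec)
        rates = {}
        for label in (CLASS_RENAL, CLASS_NONRENAL):
            sub = [r.flags["omphalocele_umbilical_hernia"] for r in records
                   if r.class_label == label]
            rates[label] = np.mean(sub)
        hits += rates[CLASS_NONRENAL] > rates[CLASS_RENAL]
    assert hits / reps >= 0.80


def test_age_volume_correlation_calibration():
    """Sample r(age, volume) at n=200 is within 0.1 of the analytic target
    slope*SD_age/SD_vol for both class models."""
    rng = np.random.default_rng(5)
    age_sd = np.sqrt((43**2 - 1) / 12)  # integer ages uniform on [6, 48]
    spec = default_cohort_spec()
    for label in (CLASS_RENAL, CLASS_NONRENAL):
        model = spec.volume_model[label]
        ages = rng.integers(6, 49, 200)
        vols = np.array([model.draw(a, rng) for a in ages])
        r = np.corrcoef(ages, vols)[0, 1]
        assert abs(r - model.analytic_age_volume_r(age_sd)) < 0.1


def test_cohort_reproducibility_and_file_counts(tmp_path):
    spec = default_cohort_spec(n_per_class=3, master_seed=9, grid=coarse_grid())
    b1 = generate_cohort(spec, out_dir=tmp_path / "run1")
    b2 = generate_cohort(spec, out_dir=tmp_path / "run2")
    assert b1.clinical.equals(b2.clinical)
    for s1, s2 in zip(b1.subjects, b2.subjects):
        assert np.array_equal(s1.t2w, s2.t2w)
        assert np.array_equal(s1.mask_left, s2.mask_left)
    for d in ("run1", "run2"):
        files = sorted((tmp_path / d).iterdir())
        niftis = [f for f in files if f.name.endswith(".nii.gz")]
        assert len(niftis) == 6 * 4
        assert (tmp_path / d / "clinical.csv").exists()
        assert (tmp_path / d / "manifest.json").exists()


def test_spec_invariants_enforced():
    with pytest.raises(ConfigurationError):
        CohortSpec(n_per_class=1)
    with pytest.raises(ConfigurationError):
        GridSpec(spacing_mm=(1.0, -1.0, 5.0))
    with pytest.raises(ConfigurationError):
        VolumeModel(50.0, 1.0, -1.0)
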