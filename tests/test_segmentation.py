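"""Threshold segmentation and volumetry tests.

The central oracle is the Gaussian tail: brain voxels drawn i.i.d. from
Normal(mean, sd) and thresholded at mean +/- k*sd are flagged with
probability 2(1 - Phi(k)), about 4.55% at k = 2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from necrovol import (
    ImageVolume,
    IntensityThresholds,
    PhantomSpec,
    ReferenceStats,
    ScanGeometry,
    brain_mask,
    compute_reference_stats,
    expected_noise_fraction,
    generate_phantom,
    save_volume,
    segment_lesion,
    thresholds,
    volumetry_batch,
    voxel_volume,
)
from necrovol.synthetic import LesionSpec


def _uniform_volume(geometry, value, modality="T2", **kw):
    return ImageVolume(np.full(geometry.shape, float(value)), geometry, modality=modality, **kw)


# --------------------------------------------------------- reference stats


def test_reference_stats_hand_built_grids(small_geometry):
    """All brain voxels at 100 except one voxel at 104: mean ~100, small sd."""
    g = small_geometry
    mask = np.zeros(g.shape, dtype=bool)
    mask[5:9, 10:30, 10:30] = True
    v1 = _uniform_volume(g, 100.0)
    v2 = _uniform_volume(g, 100.0)
    v2.data[6, 15, 15] = 104.0
    stats = compute_reference_stats([v1, v2], [mask, mask], "T2")
    n = 2 * mask.sum()
    assert stats.n_voxels == n
    assert stats.mean == pytest.approx(100.0 + 4.0 / n)
    assert 0 < stats.sd < 0.2


def test_reference_stats_zero_variance_rejected(small_geometry):
    mask = np.zeros(small_geometry.shape, dtype=bool)
    mask[5:9, 10:30, 10:30] = True
    v = _uniform_volume(small_geometry, 100.0)
    with pytest.raises(ValueError, match="variance"):
        compute_reference_stats([v], [mask], "T2")


def test_reference_stats_law_of_large_numbers():
    """Pooled stats over >=1e5 Normal(500, 25) voxels land within +/-1 of truth."""
    vols, masks = [], []
    for s in (601, 602):  # full study geometry: ~6.7e4 brain voxels each
        v, b, _ = generate_phantom(PhantomSpec(seed=s))
        vols.append(v)
        masks.append(b)
    stats = compute_reference_stats(vols, masks, "T2")
    assert stats.n_voxels >= 1e5
    assert stats.mean == pytest.approx(500.0, abs=1.0)
    assert stats.sd == pytest.approx(25.0, abs=1.0)


def test_reference_stats_modality_filtering_and_errors(control_phantoms):
    vols, masks = control_phantoms
    with pytest.raises(ValueError, match="modality"):
        compute_reference_stats(vols, masks, "T1post")
    empty = [np.zeros_like(m) for m in masks]
    with pytest.raises(ValueError, match="empty"):
        compute_reference_stats(vols, empty, "T2")


# --------------------------------------------------------------- thresholds


@pytest.mark.parametrize(
    "mean,sd,k,expected",
    [
        (500.0, 25.0, 2.0, (450.0, 550.0)),
        (500.0, 25.0, 0.5, (487.5, 512.5)),
        (0.0, 1.0, 2.0, (-2.0, 2.0)),
    ],
)
def test_thresholds_formula(mean, sd, k, expected):
    stats = ReferenceStats("T2", mean, sd, 100)
    t = thresholds(stats, k=k)
    assert (t.lower, t.upper) == pytest.approx(expected)


def test_thresholds_invalid_k():
    stats = ReferenceStats("T2", 500.0, 25.0, 100)
    with pytest.raises(ValueError, match="k"):
        thresholds(stats, k=0.0)
    with pytest.raises(ValueError):
        IntensityThresholds(lower=10.0, upper=5.0)


# --------------------------------------------------------------- brain mask


def test_auto_brain_mask_recovers_ellipsoid(small_geometry):
    spec = PhantomSpec(
        geometry=small_geometry, brain_semiaxes_vox=(5.0, 17.0, 17.0), seed=11
    )
    vol, truth, _ = generate_phantom(spec)
    mask = brain_mask(vol)
    dice = 2 * (mask & truth).sum() / (mask.sum() + truth.sum())
    assert dice >= 0.99


def test_provided_mask_passthrough(small_geometry):
    vol = _uniform_volume(small_geometry, 100.0)
    provided = np.zeros(small_geometry.shape, dtype=bool)
    provided[3:6, 5:9, 5:9] = True
    out = brain_mask(vol, method="provided", provided=provided)
    assert np.array_equal(out, provided)


def test_all_zero_volume_has_no_brain(small_geometry):
    vol = _uniform_volume(small_geometry, 0.0)
    with pytest.raises(ValueError, match="no brain"):
        brain_mask(vol)


def test_auto_mask_deterministic(small_geometry):
    spec = PhantomSpec(
        geometry=small_geometry, brain_semiaxes_vox=(5.0, 17.0, 17.0), seed=3
    )
    vol, _, _ = generate_phantom(spec)
    assert np.array_equal(brain_mask(vol), brain_mask(vol))


# ----------------------------------------------------------- segment_lesion


def test_segment_null_case(small_geometry):
    """A volume sitting exactly at the reference mean has zero lesion."""
    vol = _uniform_volume(small_geometry, 500.0)
    mask = np.ones(small_geometry.shape, dtype=bool)
    thr = IntensityThresholds(450.0, 550.0, 2.0)
    res = segment_lesion(vol, mask, thr)
    assert res.n_hyper == res.n_hypo == 0
    assert res.volume_mm3 == 0.0


def test_segment_block_exact_volume():
    """A 10x10x4 block at +5 sd inside a quiet brain: 400 voxels -> ~2.747 mm^3."""
    geom = ScanGeometry()  # study geometry
    data = np.full(geom.shape, 500.0)
    data[5:9, 40:50, 40:50] = 500.0 + 5 * 25.0
    vol = ImageVolume(data, geom)
    mask = np.ones(geom.shape, dtype=bool)
    res = segment_lesion(vol, mask, IntensityThresholds(450.0, 550.0, 2.0))
    assert res.n_hyper == 400 and res.n_hypo == 0
    assert res.volume_mm3 == pytest.approx(400 * voxel_volume(geom), rel=1e-12)
    assert res.volume_mm3 == pytest.approx(2.747, abs=0.001)


def test_hypo_and_hyper_both_count(small_geometry):
    data = np.full(small_geometry.shape, 500.0)
    data[2:4, 5:10, 5:10] = 600.0  # hyper
    data[6:8, 5:10, 5:10] = 400.0  # hypo
    vol = ImageVolume(data, small_geometry)
    res = segment_lesion(
        vol, np.ones(small_geometry.shape, dtype=bool), IntensityThresholds(450, 550, 2)
    )
    assert res.n_hyper == 2 * 5 * 5
    assert res.n_hypo == 2 * 5 * 5
    assert res.n_lesion == res.n_hyper + res.n_hypo


def test_noise_only_false_positive_rate(control_phantoms):
    """Flagged fraction on pure noise matches 2(1-Phi(2)) within 3 binomial SEs."""
    vols, masks = control_phantoms
    stats = compute_reference_stats(vols, masks, "T2")
    thr = thresholds(stats, k=2.0)
    p = expected_noise_fraction(2.0)
    assert p == pytest.approx(2 * (1 - norm.cdf(2.0)), rel=1e-12)
    total_flagged = 0
    total_vox = 0
    for vol, mask in zip(vols, masks):
        res = segment_lesion(vol, mask, thr)
        total_flagged += res.n_lesion
        total_vox += int(mask.sum())
    se = np.sqrt(p * (1 - p) / total_vox)
    assert total_flagged / total_vox == pytest.approx(p, abs=3 * se)


def test_volume_is_integer_voxel_count(control_phantoms):
    """Reported volume divided by voxel volume is always an integer count."""
    vols, masks = control_phantoms
    stats = compute_reference_stats(vols, masks, "T2")
    thr = thresholds(stats, k=1.5)
    res = segment_lesion(vols[0], masks[0], thr)
    count = res.volume_mm3 / voxel_volume(vols[0].geometry)
    assert count == pytest.approx(round(count), abs=1e-9)
    assert round(count) == res.n_lesion


def test_lesion_volume_monotone_in_k(control_phantoms):
    vols, masks = control_phantoms
    stats = compute_reference_stats(vols, masks, "T2")
    volumes = [
        segment_lesion(vols[0], masks[0], thresholds(stats, k=k)).volume_mm3
        for k in (0.5, 1.0, 1.5, 2.0, 3.0, 5.0)
    ]
    assert all(a >= b for a, b in zip(volumes, volumes[1:]))


def test_translation_equivariance(control_phantoms):
    """Shifting intensities and thresholds by a constant leaves the mask unchanged."""
    vols, masks = control_phantoms
    stats = compute_reference_stats(vols, masks, "T2")
    thr = thresholds(stats, k=2.0)
    res = segment_lesion(vols[0], masks[0], thr)
    shifted = ImageVolume(vols[0].data + 123.0, vols[0].geometry, modality="T2")
    thr_shifted = IntensityThresholds(thr.lower + 123.0, thr.upper + 123.0, thr.k)
    res_shifted = segment_lesion(shifted, masks[0], thr_shifted)
    assert np.array_equal(res.mask, res_shifted.mask)


def test_min_cluster_filter_removes_isolated_voxels(small_geometry):
    data = np.full(small_geometry.shape, 500.0)
    data[7, 24, 24] = 700.0  # isolated voxel
    data[3:5, 5:9, 5:9] = 700.0  # 32-voxel cluster
    vol = ImageVolume(data, small_geometry)
    mask = np.ones(small_geometry.shape, dtype=bool)
    thr = IntensityThresholds(450, 550, 2)
    assert segment_lesion(vol, mask, thr).n_lesion == 33
    filtered = segment_lesion(vol, mask, thr, min_cluster_voxels=2)
    assert filtered.n_lesion == 32
    assert not filtered.mask[7, 24, 24]


def test_segment_shape_mismatch(small_geometry):
    vol = _uniform_volume(small_geometry, 500.0)
    with pytest.raises(ValueError, match="shape"):
        segment_lesion(vol, np.ones((2, 2, 2), dtype=bool), IntensityThresholds(450, 550))


# ---------------------------------------------------------- volumetry batch


def _write_cohort(tmp_path, geometry, specs):
    rows = []
    for subject_id, modality, week, scheme, lesion_mm3, seed in specs:
        mean, sd = (500.0, 25.0) if modality == "T2" else (400.0, 20.0)
        lesion = None
        if lesion_mm3 > 0:
            c = (geometry.n_slices // 2, geometry.matrix_rows // 2, geometry.matrix_cols // 2)
            lesion = LesionSpec(center=c, target_volume_mm3=lesion_mm3)
        spec = PhantomSpec(
            geometry=geometry, brain_semiaxes_vox=(5.0, 17.0, 17.0),
            brain_mean=mean, brain_sd=sd, lesion=lesion, seed=seed,
        )
        vol, _, les = generate_phantom(spec)
        vol.modality = modality
        path = tmp_path / f"{subject_id}_{modality}_w{week}.nii.gz"
        save_volume(vol, path)
        rows.append(
            dict(subject_id=subject_id, scheme_label=scheme, week=week,
                 modality=modality, path=str(path), is_control=0,
                 true_mm3=les.sum() * voxel_volume(geometry))
        )
    return pd.DataFrame(rows)


@pytest.fixture(scope="module")
def reference_by_modality(control_phantoms, small_geometry):
    vols, masks = control_phantoms
    t2 = compute_reference_stats(vols, masks, "T2")
    t1_vols = []
    for s in range(3):
        spec = PhantomSpec(
            geometry=small_geometry, brain_semiaxes_vox=(5.0, 17.0, 17.0),
            brain_mean=400.0, brain_sd=20.0, seed=800 + s,
        )
        v, b, _ = generate_phantom(spec)
        v.modality = "T1post"
        t1_vols.append((v, b))
    t1 = compute_reference_stats([v for v, _ in t1_vols], [b for _, b in t1_vols], "T1post")
    return {"T2": t2, "T1post": t1}


def test_volumetry_batch_recovers_known_volumes(tmp_path, small_geometry, reference_by_modality):
    manifest = _write_cohort(
        tmp_path, small_geometry,
        [("m1", "T2", 3.0, "5x20", 4.0, 21), ("m2", "T2", 3.0, "5x20", 8.0, 22),
         ("m3", "T2", 3.0, "10x10", 0.0, 23)],
    )
    records, failures = volumetry_batch(manifest, reference_by_modality, k=2.0)
    assert not failures and len(records) == 3
    merged = records.merge(manifest[["subject_id", "true_mm3"]], on="subject_id")
    # corrected volume within one boundary shell plus 3 SEs of the
    # false-positive fluctuation (coarse 0.049 mm^3 voxels here)
    p = 2 * norm.sf(2.0)
    n_brain = reference_by_modality["T2"].n_voxels // 3  # voxels per test brain
    se_fp = np.sqrt(n_brain * p * (1 - p)) * voxel_volume(small_geometry)
    err = (merged["volume_noise_corrected_mm3"] - merged["true_mm3"]).abs()
    assert (err < 1.5 + 3 * se_fp).all()


def test_volumetry_batch_per_modality_thresholds(tmp_path, small_geometry, reference_by_modality):
    manifest = _write_cohort(
        tmp_path, small_geometry,
        [("m1", "T2", 2.0, "5x18", 0.0, 31), ("m2", "T1post", 2.0, "5x18", 0.0, 32)],
    )
    records, _ = volumetry_batch(manifest, reference_by_modality, k=2.0)
    t2 = records[records.modality == "T2"].iloc[0]
    t1 = records[records.modality == "T1post"].iloc[0]
    # distinct cut-offs prove per-modality thresholds were applied
    assert t2.thr_upper > 540 and t1.thr_upper < 460
    assert t2.thr_lower > t1.thr_upper


def test_volumetry_batch_empty_manifest(reference_by_modality):
    empty = pd.DataFrame(
        columns=["subject_id", "scheme_label", "week", "modality", "path", "is_control"]
    )
    records, failures = volumetry_batch(empty, reference_by_modality)
    assert records.empty and not failures


def test_volumetry_batch_skips_unreadable(tmp_path, small_geometry, reference_by_modality):
    manifest = _write_cohort(
        tmp_path, small_geometry, [("m1", "T2", 1.0, "5x20", 0.0, 41)]
    )
    bad = dict(subject_id="mX", scheme_label="5x20", week=1.0, modality="T2",
               path=str(tmp_path / "missing.nii.gz"), is_control=0, true_mm3=0.0)
    manifest = pd.concat([manifest, pd.DataFrame([bad])], ignore_index=True)
    records, failures = volumetry_batch(manifest, reference_by_modality)
    assert len(records) == 1
    assert failures == [str(tmp_path / "missing.nii.gz")]
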