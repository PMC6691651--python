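"""Threshold-based lesion segmentation and volumetry.

A lesion is defined as brain voxels whose intensity lies more than k
standard deviations (default k = 2) above or below the mean intensity of a
lesion-free reference cohort; hyper- and hypointense voxels both count.
Lesion volume is the flagged-voxel count times the voxel unit volume.
T1-post-contrast and T2 volumes are processed independently.

Under pure i.i.d. Gaussian noise at the reference parameters, thresholding
flags an expected fraction 2(1 - Phi(k)) of brain voxels (about 4.55% at
k = 2).  ``expected_noise_volume`` provides this closed form so callers can
bias-correct volumes measured on noisy images.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import norm
from skimage.filters import threshold_otsu

from .geometry import ImageVolume, ScanGeometry, load_volume, voxel_volume

__all__ = [
    "ReferenceStats",
    "IntensityThresholds",
    "LesionResult",
    "compute_reference_stats",
    "thresholds",
    "brain_mask",
    "segment_lesion",
    "expected_noise_fraction",
    "expected_noise_volume",
    "volumetry_batch",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReferenceStats:
    """Normal-cohort intensity statistics pooled over brain-masked voxels."""

    modality: str
    mean: float
    sd: float
    n_voxels: int
    source_subjects: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError(
                f"reference SD must be > 0 (degenerate reference), got {self.sd}"
            )
        if self.n_voxels < 2:
            raise ValueError(f"need >= 2 reference voxels, got {self.n_voxels}")


@dataclass(frozen=True)
class IntensityThresholds:
    """Symmetric mean +/- k*SD intensity cut-offs."""

    lower: float
    upper: float
    k: float = 2.0

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValueError(f"k must be > 0, got {self.k}")
        if not self.lower < self.upper:
            raise ValueError(f"lower ({self.lower}) must be < upper ({self.upper})")


@dataclass
class LesionResult:
    mask: np.ndarray
    n_hyper: int
    n_hypo: int
    volume_mm3: float
    modality: str
    subject_id: str
    week: float
    thresholds: IntensityThresholds | None = None
    #: volume minus the expected noise false-positive volume, floored at 0
    volume_noise_corrected_mm3: float | None = None

    @property
    def n_lesion(self) -> int:
        return self.n_hyper + self.n_hypo


def compute_reference_stats(
    control_volumes: list[ImageVolume],
    brain_masks: list[np.ndarray],
    modality: str,
) -> ReferenceStats:
    """Pool mean and SD over all brain-masked voxels of the control cohort.

    Only volumes of the requested modality contribute.  SD uses the n-1
    (unbiased) estimator; a zero-variance cohort is rejected as degenerate.
    """
    if len(control_volumes) != len(brain_masks):
        raise ValueError("control_volumes and brain_masks must be the same length")
    pooled = []
    subjects = []
    for vol, mask in zip(control_volumes, brain_masks):
        if vol.modality != modality:
            continue
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != vol.data.shape:
            raise ValueError(
                f"mask shape {mask.shape} does not match volume shape {vol.data.shape}"
            )
        if not mask.any():
            raise ValueError(f"empty brain mask for subject {vol.subject_id!r}")
        pooled.append(vol.data[mask])
        subjects.append(vol.subject_id)
    if not pooled:
        raise ValueError(f"no control volumes of modality {modality!r}")
    values = np.concatenate(pooled)
    if values.size < 2:
        raise ValueError("need >= 2 pooled reference voxels")
    sd = float(np.std(values, ddof=1))
    if sd == 0.0:
        raise ValueError("reference cohort has zero intensity variance")
    return ReferenceStats(
        modality=modality,
        mean=float(np.mean(values)),
        sd=sd,
        n_voxels=int(values.size),
        source_subjects=tuple(subjects),
    )


def thresholds(stats: ReferenceStats, k: float = 2.0) -> IntensityThresholds:
    """Mean +/- k*SD cut-offs from reference statistics."""
    if not k > 0:
        raise ValueError(f"k must be > 0, got {k}")
    return IntensityThresholds(
        lower=stats.mean - k * stats.sd, upper=stats.mean + k * stats.sd, k=k
    )


def brain_mask(
    volume: ImageVolume,
    method: str = "auto",
    provided: np.ndarray | None = None,
) -> np.ndarray:
    """Brain mask: user-provided, or Otsu + largest component + closing.

    The automatic method thresholds the volume with Otsu's method, keeps the
    largest 6-connected 3-D component and applies a morphological closing
    with a 3x3x3 structuring element.  It is deterministic for a fixed
    volume.
    """
    if method == "provided":
        if provided is None:
            raise ValueError("method='provided' requires a mask array")
        mask = np.asarray(provided, dtype=bool)
        if mask.shape != volume.data.shape:
            raise ValueError(
                f"provided mask shape {mask.shape} does not match "
                f"volume shape {volume.data.shape}"
            )
        if not mask.any():
            raise ValueError("provided brain mask is empty")
        return mask
    if method != "auto":
        raise ValueError(f"unknown brain-mask method {method!r}")
    data = volume.data
    if np.ptp(data) == 0:
        raise ValueError("no brain found: volume has constant intensity")
    thr = threshold_otsu(data)
    fg = data > thr
    if not fg.any():
        raise ValueError("no brain found: Otsu foreground is empty")
    labels, n = ndimage.label(fg)
    if n == 0:
        raise ValueError("no brain found")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    mask = labels == int(np.argmax(counts))
    mask = ndimage.binary_closing(mask, structure=np.ones((3, 3, 3), dtype=bool))
    if not mask.any():
        raise ValueError("no brain found after morphological cleanup")
    return mask


def expected_noise_fraction(k: float) -> float:
    """Expected flagged fraction 2(1 - Phi(k)) under pure Gaussian noise."""
    return float(2.0 * norm.sf(k))


def expected_noise_volume(k: float, n_mask_voxels: int, geometry: ScanGeometry) -> float:
    """Expected false-positive volume (mm^3) over a noise-only mask."""
    return expected_noise_fraction(k) * n_mask_voxels * voxel_volume(geometry)


def segment_lesion(
    volume: ImageVolume,
    mask: np.ndarray,
    thr: IntensityThresholds,
    min_cluster_voxels: int = 0,
) -> LesionResult:
    """Flag brain voxels beyond the intensity thresholds and report volume.

    ``min_cluster_voxels`` optionally removes flagged 26-connected clusters
    smaller than the given size (default 0: no filtering).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != volume.data.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match volume shape {volume.data.shape}"
        )
    data = volume.data
    hyper = mask & (data > thr.upper)
    hypo = mask & (data < thr.lower)
    lesion = hyper | hypo
    if min_cluster_voxels > 0 and lesion.any():
        structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
        labels, n = ndimage.label(lesion, structure=structure)
        counts = np.bincount(labels.ravel())
        keep = counts >= min_cluster_voxels
        keep[0] = False
        lesion = keep[labels]
        hyper &= lesion
        hypo &= lesion
    n_hyper = int(hyper.sum())
    n_hypo = int(hypo.sum())
    v_vox = voxel_volume(volume.geometry)
    vol_mm3 = (n_hyper + n_hypo) * v_vox
    corrected = max(
        0.0, vol_mm3 - expected_noise_volume(thr.k, int(mask.sum()), volume.geometry)
    )
    return LesionResult(
        mask=lesion,
        n_hyper=n_hyper,
        n_hypo=n_hypo,
        volume_mm3=vol_mm3,
        modality=volume.modality,
        subject_id=volume.subject_id,
        week=volume.week,
        thresholds=thr,
        volume_noise_corrected_mm3=corrected,
    )


def volumetry_batch(
    manifest: pd.DataFrame | str | Path,
    stats_by_modality: dict[str, ReferenceStats],
    k: float = 2.0,
    mask_dir: str | Path | None = None,
    min_cluster_voxels: int = 0,
    expected_geometry: ScanGeometry | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Segment every non-control manifest row and tabulate lesion volumes.

    The manifest needs columns subject_id, scheme_label, week, modality,
    path and (optionally) is_control.  Rows whose volume cannot be read are
    skipped with a logged warning and reported in the returned failure list.
    Thresholds are derived per modality from ``stats_by_modality`` and the
    cut-off values used are logged and included in the output.

    Returns ``(records, failures)`` where records has one row per
    (subject, week, modality) with columns subject_id, scheme_label, week,
    modality, n_hyper, n_hypo, volume_mm3, volume_noise_corrected_mm3,
    thr_lower, thr_upper.
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest, comment="#")
    if "is_control" in manifest.columns:
        manifest = manifest[manifest["is_control"].astype(int) == 0]
    thr_by_modality = {m: thresholds(s, k=k) for m, s in stats_by_modality.items()}
    for m, t in thr_by_modality.items():
        log.info("modality %s: thresholds [%.4f, %.4f] (k=%g)", m, t.lower, t.upper, k)
    rows: list[dict] = []
    failures: list[str] = []
    if manifest.empty:
        log.warning("volumetry_batch: manifest is empty")
    for rec in manifest.itertuples(index=False):
        modality = str(rec.modality)
        if modality not in thr_by_modality:
            log.warning("no reference stats for modality %r; skipping %s", modality, rec.path)
            failures.append(str(rec.path))
            continue
        try:
            vol = load_volume(
                rec.path,
                expected_geometry,
                modality=modality,
                subject_id=str(rec.subject_id),
                week=float(rec.week),
            )
        except Exception as exc:  # noqa: BLE001 - any unreadable volume is skipped
            log.warning("skipping unreadable volume %s: %s", rec.path, exc)
            failures.append(str(rec.path))
            continue
        if mask_dir is not None:
            mask_path = Path(mask_dir) / f"{rec.subject_id}_mask.nii.gz"
            bm = (
                np.asanyarray(load_volume(mask_path).data) > 0
                if mask_path.exists()
                else brain_mask(vol)
            )
        else:
            bm = brain_mask(vol)
        thr = thr_by_modality[modality]
        res = segment_lesion(vol, bm, thr, min_cluster_voxels=min_cluster_voxels)
        rows.append(
            {
                "subject_id": str(rec.subject_id),
                "scheme_label": str(rec.scheme_label),
                "week": float(rec.week),
                "modality": modality,
                "n_hyper": res.n_hyper,
                "n_hypo": res.n_hypo,
                "volume_mm3": res.volume_mm3,
                "volume_noise_corrected_mm3": res.volume_noise_corrected_mm3,
                "thr_lower": thr.lower,
                "thr_upper": thr.upper,
            }
        )
    columns = [
        "subject_id", "scheme_label", "week", "modality", "n_hyper", "n_hypo",
        "volume_mm3", "volume_noise_corrected_mm3", "thr_lower", "thr_upper",
    ]
    return pd.DataFrame(rows, columns=columns), failures
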