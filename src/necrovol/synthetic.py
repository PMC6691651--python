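"""Seeded synthetic phantoms and longitudinal cohorts with known truth.

The generator emulates the statistical structure the threshold-volumetry
analysis assumes: an ellipsoidal "brain" of i.i.d. Gaussian voxels around a
reference mean, lesions as contiguous hyper- or hypointense regions of
known voxel count, lesion onset a few weeks after irradiation with
saturating growth to a plateau, between-animal spread as a lognormal
frailty on the plateau, and early censoring of the most severely affected
arm.  It makes no attempt at anatomical realism or MR physics; intensities
are arbitrary units.

Everything is a pure function of its spec and seed: the same inputs yield
bit-identical volumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import ImageVolume, STUDY_GEOMETRY, ScanGeometry, save_volume, voxel_volume

__all__ = [
    "LesionSpec",
    "PhantomSpec",
    "GrowthModelParams",
    "Arm",
    "CohortDesign",
    "generate_phantom",
    "growth_curve",
    "generate_cohort",
    "generate_histology",
    "study_like_design",
    "MODALITY_INTENSITY",
]

log = logging.getLogger(__name__)

#: Default (mean, SD) intensity per modality, arbitrary units.
MODALITY_INTENSITY = {"T2": (500.0, 25.0), "T1post": (400.0, 20.0)}


@dataclass(frozen=True)
class LesionSpec:
    """A contiguous lesion of known target volume inside the brain."""

    center: tuple[int, int, int]
    target_volume_mm3: float
    shape: str = "ellipsoid"  # or "block"
    intensity_offset_in_sd: float = 5.0  # signed: positive=hyper, negative=hypo

    def __post_init__(self) -> None:
        if self.shape not in ("ellipsoid", "block"):
            raise ValueError(f"lesion shape must be ellipsoid or block, got {self.shape!r}")
        if not self.target_volume_mm3 > 0:
            raise ValueError("target_volume_mm3 must be > 0")
        if self.intensity_offset_in_sd == 0:
            raise ValueError("intensity_offset_in_sd must be nonzero")


@dataclass(frozen=True)
class PhantomSpec:
    geometry: ScanGeometry = STUDY_GEOMETRY
    brain_center: tuple[int, int, int] | None = None  # defaults to grid centre
    brain_semiaxes_vox: tuple[float, float, float] = (8.0, 45.0, 45.0)
    background_level: float = 50.0
    brain_mean: float = 500.0
    brain_sd: float = 25.0
    lesion: LesionSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.brain_sd >= 0:
            raise ValueError("brain_sd must be >= 0")
        if any(not a > 0 for a in self.brain_semiaxes_vox):
            raise ValueError("brain semi-axes must be positive")


def _ellipsoid_mask(
    shape: tuple[int, int, int],
    center: tuple[float, float, float],
    semiaxes: tuple[float, float, float],
) -> np.ndarray:
    zz, rr, cc = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return (
        ((zz - center[0]) / semiaxes[0]) ** 2
        + ((rr - center[1]) / semiaxes[1]) ** 2
        + ((cc - center[2]) / semiaxes[2]) ** 2
    ) <= 1.0


def _lesion_mask(spec: PhantomSpec, brain: np.ndarray) -> np.ndarray:
    """Nearest-N voxels to the lesion centre in mm space (exact count).

    Euclidean mm distance gives a ball (an ellipsoid in anisotropic voxel
    units); Chebyshev mm distance gives a block.  The whole selected region
    must lie inside the brain, else the spec is rejected.
    """
    les = spec.lesion
    assert les is not None
    geom = spec.geometry
    n_target = int(round(les.target_volume_mm3 / voxel_volume(geom)))
    if n_target < 1:
        raise ValueError(
            f"target volume {les.target_volume_mm3} mm^3 is below one voxel"
        )
    res_r, res_c = geom.inplane_resolution()
    spacing = np.array([geom.slice_thickness_mm, res_r, res_c])
    zz, rr, cc = np.indices(brain.shape)
    delta = np.stack(
        [
            (zz - les.center[0]) * spacing[0],
            (rr - les.center[1]) * spacing[1],
            (cc - les.center[2]) * spacing[2],
        ]
    )
    if les.shape == "ellipsoid":
        dist = np.sqrt((delta**2).sum(axis=0))
    else:
        dist = np.abs(delta).max(axis=0)
    flat = np.argsort(dist, axis=None, kind="stable")[:n_target]
    mask = np.zeros(brain.shape, dtype=bool)
    mask.ravel()[flat] = True
    if not brain[mask].all():
        raise ValueError(
            "lesion exceeds the brain ellipsoid; move its centre or shrink it"
        )
    return mask


def generate_phantom(spec: PhantomSpec) -> tuple[ImageVolume, np.ndarray, np.ndarray]:
    """Build one phantom: (volume, true brain mask, true lesion mask).

    Background voxels sit at ``background_level``; brain voxels are i.i.d.
    Normal(brain_mean, brain_sd); lesion voxels get an additional offset of
    ``intensity_offset_in_sd * brain_sd``.
    """
    geom = spec.geometry
    shape = geom.shape
    center = spec.brain_center or (shape[0] // 2, shape[1] // 2, shape[2] // 2)
    brain = _ellipsoid_mask(shape, center, spec.brain_semiaxes_vox)
    if not brain.any():
        raise ValueError("brain ellipsoid does not intersect the grid")
    rng = np.random.default_rng(spec.seed)
    data = np.full(shape, spec.background_level, dtype=float)
    data[brain] = rng.normal(spec.brain_mean, spec.brain_sd, size=int(brain.sum()))
    if spec.lesion is not None:
        lesion = _lesion_mask(spec, brain)
        data[lesion] += spec.lesion.intensity_offset_in_sd * spec.brain_sd
    else:
        lesion = np.zeros(shape, dtype=bool)
    vol = ImageVolume(data=data, geometry=geom)
    return vol, brain, lesion


@dataclass(frozen=True)
class GrowthModelParams:
    """Saturating lesion growth: 0 before onset, then plateau*(1-e^{-rt})."""

    plateau_mm3: float
    rate_per_week: float = 1.0
    onset_week: float = 3.0
    censor_week: float | None = None

    def __post_init__(self) -> None:
        if not self.plateau_mm3 > 0:
            raise ValueError("plateau_mm3 must be > 0")
        if not self.rate_per_week > 0:
            raise ValueError("rate_per_week must be > 0")
        if self.onset_week < 0:
            raise ValueError("onset_week must be >= 0")


def growth_curve(params: GrowthModelParams, week: float) -> float:
    """Expected lesion volume (mm^3) at a given week; NaN once censored."""
    if week < 0:
        raise ValueError(f"week must be >= 0, got {week}")
    if params.censor_week is not None and week > params.censor_week:
        return float("nan")
    if week < params.onset_week:
        return 0.0
    return params.plateau_mm3 * (
        1.0 - float(np.exp(-params.rate_per_week * (week - params.onset_week)))
    )


@dataclass(frozen=True)
class Arm:
    scheme_label: str
    n_subjects: int
    growth: GrowthModelParams

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")


@dataclass(frozen=True)
class CohortDesign:
    arms: tuple[Arm, ...]
    weeks: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 6.0)
    modalities: tuple[str, ...] = ("T2", "T1post")
    noise_sd_mm3: float = 0.3
    frailty_sigma: float = 0.2
    lesion_offset_sd: float = 5.0
    n_controls: int = 4
    geometry: ScanGeometry = STUDY_GEOMETRY
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.arms:
            raise ValueError("design needs at least one arm")
        if list(self.weeks) != sorted(self.weeks):
            raise ValueError("weeks must be sorted ascending")


def study_like_design(
    geometry: ScanGeometry = STUDY_GEOMETRY,
    n_per_arm: int = 6,
    seed: int = 0,
) -> CohortDesign:
    """A design mirroring the study's arm structure.

    Four fractionated arms (5x20, 10x10, 5x18, 10x9) plus single-fraction
    80, 90 and 100 Gy comparison arms; the 100 Gy arm is censored after
    week 2 (early sacrifice).  Growth plateaus encode the observed
    equivalences: 100 Gy-total fractionated arms grow like 1x90, 90 Gy-total
    arms like 1x80.
    """
    g = GrowthModelParams
    arms = (
        Arm("5x20", n_per_arm, g(plateau_mm3=12.0)),
        Arm("10x10", n_per_arm, g(plateau_mm3=12.0)),
        Arm("5x18", n_per_arm, g(plateau_mm3=9.0)),
        Arm("10x9", n_per_arm, g(plateau_mm3=9.0)),
        Arm("1x80", max(2, n_per_arm - 1), g(plateau_mm3=9.0)),
        Arm("1x90", max(2, n_per_arm - 1), g(plateau_mm3=12.0)),
        Arm("1x100", max(2, n_per_arm - 3), g(plateau_mm3=15.0, onset_week=2.0, censor_week=2.0)),
    )
    return CohortDesign(arms=arms, geometry=geometry, seed=seed)


def _phantom_for(
    design: CohortDesign,
    modality: str,
    true_volume: float,
    seed: int,
) -> tuple[ImageVolume, np.ndarray, np.ndarray]:
    mean, sd = MODALITY_INTENSITY[modality]
    lesion = None
    if true_volume >= voxel_volume(design.geometry):
        shape = design.geometry.shape
        lesion = LesionSpec(
            center=(shape[0] // 2, shape[1] // 2, shape[2] // 2),
            target_volume_mm3=true_volume,
            intensity_offset_in_sd=design.lesion_offset_sd,
        )
    spec = PhantomSpec(
        geometry=design.geometry,
        brain_semiaxes_vox=_default_semiaxes(design.geometry),
        brain_mean=mean,
        brain_sd=sd,
        lesion=lesion,
        seed=seed,
    )
    return generate_phantom(spec)


def _default_semiaxes(geometry: ScanGeometry) -> tuple[float, float, float]:
    # ~2/5 of each grid extent: a brain that fills the FOV like a mouse head
    return (
        max(1.0, 0.4 * geometry.n_slices),
        max(1.0, 0.35 * geometry.matrix_rows),
        max(1.0, 0.35 * geometry.matrix_cols),
    )


def generate_cohort(
    design: CohortDesign,
    out_dir: str | Path,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the full cohort on disk; return (manifest, ground truth).

    Per subject x week x modality a phantom is written whose true lesion
    volume is the growth curve times a subject-level lognormal frailty plus
    Gaussian measurement noise (floored at 0).  Censored arms emit no
    records after their censor week.  Lesion-free control phantoms are
    emitted with ``is_control=1``.  The manifest is directly consumable by
    :func:`necrovol.segmentation.volumetry_batch`; the truth table records
    every realized lesion's voxel count.
    """
    if seed is not None:
        design = replace(design, seed=seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    root_ss = np.random.SeedSequence(design.seed)
    arm_seeds = root_ss.spawn(len(design.arms) + 1)
    manifest_rows: list[dict] = []
    truth_rows: list[dict] = []
    v_vox = voxel_volume(design.geometry)

    for arm, arm_ss in zip(design.arms, arm_seeds[:-1]):
        subj_seeds = arm_ss.spawn(arm.n_subjects)
        for i, subj_ss in enumerate(subj_seeds):
            subject_id = f"{arm.scheme_label}_m{i + 1:02d}"
            subj_rng = np.random.default_rng(subj_ss)
            frailty = float(
                np.exp(subj_rng.normal(0.0, design.frailty_sigma))
            )
            for week in design.weeks:
                expected = growth_curve(arm.growth, week)
                if np.isnan(expected):
                    continue  # censored: no record
                for modality in design.modalities:
                    # measurement noise perturbs realized lesions only;
                    # before onset there is nothing to measure
                    if expected > 0.0:
                        noisy = expected * frailty + float(
                            subj_rng.normal(0.0, design.noise_sd_mm3)
                        )
                        true_volume = max(0.0, noisy)
                    else:
                        true_volume = 0.0
                    phantom_seed = int(subj_rng.integers(0, 2**31 - 1))
                    vol, brain, lesion = _phantom_for(
                        design, modality, true_volume, phantom_seed
                    )
                    vol.modality = modality
                    vol.subject_id = subject_id
                    vol.week = float(week)
                    fname = f"{subject_id}_w{week:g}_{modality}.nii.gz"
                    save_volume(vol, out_dir / fname)
                    manifest_rows.append(
                        {
                            "subject_id": subject_id,
                            "scheme_label": arm.scheme_label,
                            "week": float(week),
                            "modality": modality,
                            "path": str(out_dir / fname),
                            "is_control": 0,
                        }
                    )
                    n_les = int(lesion.sum())
                    truth_rows.append(
                        {
                            "subject_id": subject_id,
                            "scheme_label": arm.scheme_label,
                            "week": float(week),
                            "modality": modality,
                            "true_volume_mm3": n_les * v_vox,
                            "n_lesion_voxels": n_les,
                            "n_brain_voxels": int(brain.sum()),
                            "frailty": frailty,
                        }
                    )

    ctrl_rng = np.random.default_rng(arm_seeds[-1])
    for i in range(design.n_controls):
        subject_id = f"CTRL_m{i + 1:02d}"
        for modality in design.modalities:
            phantom_seed = int(ctrl_rng.integers(0, 2**31 - 1))
            vol, brain, _ = _phantom_for(design, modality, 0.0, phantom_seed)
            vol.modality = modality
            vol.subject_id = subject_id
            fname = f"{subject_id}_{modality}.nii.gz"
            save_volume(vol, out_dir / fname)
            manifest_rows.append(
                {
                    "subject_id": subject_id,
                    "scheme_label": "control",
                    "week": 0.0,
                    "modality": modality,
                    "path": str(out_dir / fname),
                    "is_control": 1,
                }
            )

    manifest = pd.DataFrame(manifest_rows)
    truth = pd.DataFrame(truth_rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    truth.to_csv(out_dir / "truth.csv", index=False)
    return manifest, truth


#: grade labels for the ordinal 0-3 histology scale
HISTOLOGY_SCALE = ("none", "mild", "moderate", "severe")


def generate_histology(design: CohortDesign, seed: int | None = None) -> pd.DataFrame:
    """Terminal histology grades (ordinal 0-3) per subject.

    Expected grade saturates with the arm's lesion plateau; jittered and
    clipped to the scale.  Censored arms (sacrificed before study end)
    yield no histology rows.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    rows = []
    for arm in design.arms:
        if arm.growth.censor_week is not None:
            continue
        expected = 3.0 * (1.0 - np.exp(-arm.growth.plateau_mm3 / 8.0))
        for i in range(arm.n_subjects):
            grade = int(np.clip(round(expected + rng.normal(0.0, 0.5)), 0, 3))
            rows.append(
                {
                    "subject_id": f"{arm.scheme_label}_m{i + 1:02d}",
                    "scheme_label": arm.scheme_label,
                    "grade": grade,
                }
            )
    return pd.DataFrame(rows)
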