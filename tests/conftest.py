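"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from necrovol import PhantomSpec, ScanGeometry, generate_phantom

#: small grid used where full study geometry would just burn time
SMALL_GEOMETRY = ScanGeometry(
    matrix_rows=48, matrix_cols=48, fov_mm=(15.0, 15.0),
    n_slices=14, slice_thickness_mm=0.5,
)


@pytest.fixture(scope="session")
def small_geometry() -> ScanGeometry:
    return SMALL_GEOMETRY


@pytest.fixture(scope="session")
def control_phantoms():
    """Three lesion-free small phantoms with their true brain masks (T2 scale)."""
    vols, masks = [], []
    for s in range(3):
        spec = PhantomSpec(
            geometry=SMALL_GEOMETRY, brain_semiaxes_vox=(5.0, 17.0, 17.0), seed=900 + s
        )
        v, b, _ = generate_phantom(spec)
        v.subject_id = f"ctrl{s}"
        vols.append(v)
        masks.append(b)
    return vols, masks


# ------------------------------------------------------------------ oracles


def brute_force_two_way_F(df: pd.DataFrame) -> dict[str, float]:
    """Two-way ANOVA F statistics from first principles (balanced designs).

    Classic sums-of-squares decomposition from cell/marginal means; valid
    when every (scheme, week) cell has the same count, where Type I/II/III
    coincide.  Independent of statsmodels.
    """
    y = df["volume_mm3"].to_numpy(dtype=float)
    A = df["scheme_label"].to_numpy()
    B = df["week"].to_numpy()
    gm = y.mean()
    a_levels, b_levels = np.unique(A), np.unique(B)
    ss_a = sum((y[A == a].mean() - gm) ** 2 * (A == a).sum() for a in a_levels)
    ss_b = sum((y[B == b].mean() - gm) ** 2 * (B == b).sum() for b in b_levels)
    ss_ab = 0.0
    ss_e = 0.0
    for a in a_levels:
        for b in b_levels:
            cell = y[(A == a) & (B == b)]
            ss_ab += len(cell) * (
                cell.mean() - y[A == a].mean() - y[B == b].mean() + gm
            ) ** 2
            ss_e += ((cell - cell.mean()) ** 2).sum()
    df_a = len(a_levels) - 1
    df_b = len(b_levels) - 1
    df_ab = df_a * df_b
    df_e = len(y) - len(a_levels) * len(b_levels)
    mse = ss_e / df_e
    return {
        "scheme": ss_a / df_a / mse,
        "week": ss_b / df_b / mse,
        "scheme:week": ss_ab / df_ab / mse,
    }


def brute_force_one_way_F(values: np.ndarray, groups: np.ndarray) -> float:
    """One-way ANOVA F from the raw between/within decomposition."""
    values = np.asarray(values, dtype=float)
    gm = values.mean()
    levels = np.unique(groups)
    ss_between = sum(
        (values[groups == g].mean() - gm) ** 2 * (groups == g).sum() for g in levels
    )
    ss_within = sum(
        ((values[groups == g] - values[groups == g].mean()) ** 2).sum() for g in levels
    )
    df_b = len(levels) - 1
    df_w = len(values) - len(levels)
    return (ss_between / df_b) / (ss_within / df_w)


def balanced_measurements(
    rng: np.random.Generator,
    schemes: list[str],
    weeks: list[float],
    reps: int,
    scheme_offsets: dict[str, float] | None = None,
    mu: float = 5.0,
    sigma: float = 1.0,
) -> pd.DataFrame:
    """A balanced tidy measurement table with i.i.d. Gaussian cell noise."""
    offsets = scheme_offsets or {}
    rows = []
    for s in schemes:
        for w in weeks:
            for r in range(reps):
                rows.append(
                    {
                        "subject_id": f"{s}_w{w}_r{r}",
                        "scheme_label": s,
                        "week": w,
                        "modality": "T2",
                        "volume_mm3": rng.normal(mu + offsets.get(s, 0.0), sigma),
                    }
                )
    return pd.DataFrame(rows)
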