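"""Linear-quadratic dose-equivalence engine.

Converts fractionated irradiation schemes (n fractions of d Gy) into the
biologically effective dose

    BED = (n d) (1 + d / (alpha/beta))

and the single-fraction equivalent dose (SFED), the single dose that yields
the same BED.  Setting n = 1 and d = SFED in the BED expression gives a
quadratic in SFED whose non-negative root is

    SFED = (-1 + sqrt(1 + 4 BED / (alpha/beta))) / (2 / (alpha/beta)).

The alpha/beta ratio (Gy) is the linear-quadratic tissue parameter: low
(2-3 Gy) for late-responding tissue such as cerebrum, around 10 Gy for
early-responding tissue and tumour.  No time-factor or repopulation term is
included; this is the basic LQ form.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import pandas as pd

__all__ = [
    "FractionationScheme",
    "AlphaBetaRatio",
    "DoseMetrics",
    "bed",
    "sfed_from_bed",
    "dose_metrics",
    "scheme_table",
    "DEFAULT_SCHEMES",
    "DEFAULT_ALPHA_BETAS",
]

TISSUE_CLASSES = ("late_cerebrum", "early_tumor", "other")

_LABEL_RE = re.compile(r"^\s*(\d+)\s*[xX×]\s*([0-9.]+)\s*$")


@dataclass(frozen=True)
class FractionationScheme:
    """A regimen of ``n`` fractions of ``d`` Gy each."""

    n: int
    d: float
    label: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.n, (int,)) or isinstance(self.n, bool):
            raise ValueError(f"fraction count n must be an integer, got {self.n!r}")
        if self.n < 1:
            raise ValueError(f"fraction count n must be >= 1, got {self.n}")
        if not self.d > 0:
            raise ValueError(f"dose per fraction d must be > 0 Gy, got {self.d}")
        if not self.label:
            object.__setattr__(self, "label", f"{self.n}x{self.d:g}")

    @property
    def total_dose(self) -> float:
        """Total physical dose n*d in Gy."""
        return self.n * self.d

    @classmethod
    def from_label(cls, label: str) -> "FractionationScheme":
        """Parse an ``"NxD"`` string such as ``"5x20"`` or ``"10x9.5"``."""
        m = _LABEL_RE.match(label)
        if m is None:
            raise ValueError(f"cannot parse scheme label {label!r}; expected 'NxD'")
        return cls(n=int(m.group(1)), d=float(m.group(2)))


@dataclass(frozen=True)
class AlphaBetaRatio:
    """Linear-quadratic alpha/beta tissue parameter in Gy."""

    value: float
    tissue_class: str = "other"

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError(f"alpha/beta must be > 0 Gy, got {self.value}")
        if self.tissue_class not in TISSUE_CLASSES:
            raise ValueError(
                f"tissue_class must be one of {TISSUE_CLASSES}, got {self.tissue_class!r}"
            )


AlphaBetaLike = Union[AlphaBetaRatio, float, int]


def _as_alpha_beta(ab: AlphaBetaLike) -> AlphaBetaRatio:
    if isinstance(ab, AlphaBetaRatio):
        return ab
    return AlphaBetaRatio(float(ab))


@dataclass(frozen=True)
class DoseMetrics:
    """BED and SFED of one scheme at one alpha/beta ratio (all Gy)."""

    scheme: FractionationScheme
    alpha_beta: AlphaBetaRatio
    bed: float
    sfed: float


def bed(scheme: FractionationScheme, ab: AlphaBetaLike) -> float:
    """Biologically effective dose (n d)(1 + d/(alpha/beta)), in Gy."""
    ab = _as_alpha_beta(ab)
    return scheme.total_dose * (1.0 + scheme.d / ab.value)


def sfed_from_bed(bed_gy: float, ab: AlphaBetaLike) -> float:
    """Single-fraction equivalent dose for a given BED, in Gy.

    The non-negative root of ``SFED (1 + SFED/(alpha/beta)) = BED``.
    """
    ab = _as_alpha_beta(ab)
    if bed_gy < 0:
        raise ValueError(f"BED must be non-negative, got {bed_gy}")
    return (-1.0 + math.sqrt(1.0 + 4.0 * bed_gy / ab.value)) / (2.0 / ab.value)


def dose_metrics(scheme: FractionationScheme, ab: AlphaBetaLike) -> DoseMetrics:
    """Compute BED then SFED for one scheme at one alpha/beta ratio."""
    ab = _as_alpha_beta(ab)
    b = bed(scheme, ab)
    return DoseMetrics(scheme=scheme, alpha_beta=ab, bed=b, sfed=sfed_from_bed(b, ab))


# The four schemes of the study and the conventional alpha/beta grid:
# 2-3 Gy late-responding cerebrum, 10 Gy early-responding tissue/tumour.
DEFAULT_SCHEMES: tuple[FractionationScheme, ...] = (
    FractionationScheme(5, 20.0),
    FractionationScheme(10, 10.0),
    FractionationScheme(5, 18.0),
    FractionationScheme(10, 9.0),
)

DEFAULT_ALPHA_BETAS: tuple[AlphaBetaRatio, ...] = (
    AlphaBetaRatio(2.0, "late_cerebrum"),
    AlphaBetaRatio(3.0, "late_cerebrum"),
    AlphaBetaRatio(10.0, "early_tumor"),
)


def scheme_table(
    schemes: Sequence[FractionationScheme] | None = None,
    ab_values: Sequence[AlphaBetaLike] | None = None,
) -> pd.DataFrame:
    """One row per (scheme, alpha/beta) with n, d, total dose, BED and SFED.

    Defaults regenerate the study's twelve-row dose-equivalence table
    (schemes 5x20, 10x10, 5x18, 10x9 at alpha/beta 2, 3 and 10 Gy).
    """
    if schemes is None:
        schemes = DEFAULT_SCHEMES
    if ab_values is None:
        ab_values = DEFAULT_ALPHA_BETAS
    schemes = list(schemes)
    abs_ = [_as_alpha_beta(a) for a in ab_values]
    if not schemes:
        raise ValueError("scheme list is empty")
    if not abs_:
        raise ValueError("alpha/beta list is empty")
    rows = []
    for ab in abs_:
        for s in schemes:
            m = dose_metrics(s, ab)
            rows.append(
                {
                    "label": s.label,
                    "n": s.n,
                    "d_Gy": s.d,
                    "total_Gy": s.total_dose,
                    "alpha_beta_Gy": ab.value,
                    "BED_Gy": m.bed,
                    "SFED_Gy": m.sfed,
                }
            )
    return pd.DataFrame(rows)
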