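"""Longitudinal cohort statistics for lesion volumes and histology grades.

Lesion volumes are compared across irradiation schemes and imaging weeks
with a fixed-effects two-way ANOVA (scheme, week, interaction; Type III
sums of squares with sum-to-zero contrasts, since real designs are
unbalanced) followed by Tukey-Kramer adjusted pairwise scheme comparisons
at each week.  Histology grades are compared across schemes with a one-way
ANOVA plus Tukey-Kramer post-hoc, treating ordinal grades as numeric.

The module follows a Model/Results design: ``LesionVolumeModel(data)`` and
``HistologyGradeModel(data)`` are built from tidy DataFrames; ``fit()``
returns an :class:`AnovaTukeyResults` carrying the ANOVA table, per-factor
F and p values, the pairwise comparison table and a ``summary()`` text
report.

Repeated scans of the same animal are treated as independent observations
(a fixed-effects design); within-subject correlation is not modelled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "LesionVolumeModel",
    "HistologyGradeModel",
    "AnovaTukeyResults",
    "two_way_anova_tukey",
    "one_way_anova_tukey",
    "summarize_longitudinal",
    "validate_measurements",
]

log = logging.getLogger(__name__)

MEASUREMENT_COLUMNS = ("subject_id", "scheme_label", "week", "modality", "volume_mm3")


def validate_measurements(records: pd.DataFrame) -> pd.DataFrame:
    """Check the tidy measurement table: required columns, key uniqueness."""
    missing = [c for c in MEASUREMENT_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"measurement table is missing columns {missing}")
    dup = records.duplicated(subset=["subject_id", "week", "modality"])
    if dup.any():
        keys = records.loc[dup, ["subject_id", "week", "modality"]].iloc[0].tolist()
        raise ValueError(
            f"(subject_id, week, modality) must be unique; duplicate key {keys}"
        )
    if (records["volume_mm3"] < 0).any():
        raise ValueError("lesion volumes must be non-negative")
    return records


@dataclass
class AnovaTukeyResults:
    """ANOVA factors with their F/p statistics plus Tukey pairwise table."""

    factors: list[str]
    F_per_factor: dict[str, float]
    p_per_factor: dict[str, float]
    anova_table: pd.DataFrame
    pairwise: pd.DataFrame
    alpha: float = 0.05
    dropped_terms: list[str] = field(default_factory=list)
    response: str = "volume_mm3"

    def summary(self) -> str:
        lines = [f"ANOVA on {self.response} (Type III where applicable)"]
        if self.dropped_terms:
            lines.append(f"  dropped inestimable terms: {', '.join(self.dropped_terms)}")
        lines.append(self.anova_table.to_string())
        if not self.pairwise.empty:
            lines.append("")
            lines.append(f"Tukey-Kramer pairwise comparisons (alpha={self.alpha:g})")
            lines.append(self.pairwise.to_string(index=False))
        return "\n".join(lines)


def _tukey_rows(values: np.ndarray, groups: np.ndarray, alpha: float) -> list[dict]:
    res = pairwise_tukeyhsd(values, groups, alpha=alpha)
    frame = pd.DataFrame(
        res.summary().data[1:], columns=[str(c) for c in res.summary().data[0]]
    )
    rows = []
    for _, r in frame.iterrows():
        rows.append(
            {
                "group_a": r["group1"],
                "group_b": r["group2"],
                "mean_diff": float(r["meandiff"]),
                "adjusted_p": float(r["p-adj"]),
                "reject": bool(r["reject"]),
            }
        )
    return rows


class LesionVolumeModel:
    """Two-way fixed-effects model of lesion volume by scheme and week.

    Parameters
    ----------
    data
        Tidy measurement table with columns subject_id, scheme_label, week,
        modality, volume_mm3.
    modality
        Which modality's records to analyse; required if the table mixes
        modalities (T1-post and T2 are analysed independently).
    """

    def __init__(self, data: pd.DataFrame, modality: str | None = None):
        data = validate_measurements(pd.DataFrame(data))
        modalities = sorted(data["modality"].unique())
        if modality is not None:
            data = data[data["modality"] == modality]
            if data.empty:
                raise ValueError(f"no records of modality {modality!r}")
        elif len(modalities) > 1:
            raise ValueError(
                f"table mixes modalities {modalities}; select one via modality="
            )
        self.modality = modality if modality is not None else modalities[0]
        self.data = data.reset_index(drop=True)
        schemes = self.data["scheme_label"].nunique()
        weeks = self.data["week"].nunique()
        if schemes < 2:
            raise ValueError(
                f"need >= 2 schemes, got {schemes} (all records in one scheme)"
            )
        if weeks < 2:
            raise ValueError(f"need >= 2 weeks, got {weeks} (all records in one week)")
        if float(np.var(self.data["volume_mm3"])) == 0.0:
            raise ValueError("zero total variance in volume_mm3; ANOVA is degenerate")

    @classmethod
    def from_csv(cls, path, modality: str | None = None) -> "LesionVolumeModel":
        return cls(pd.read_csv(path, comment="#"), modality=modality)

    def _interaction_estimable(self) -> bool:
        cells = self.data.groupby(["scheme_label", "week"], observed=True).size()
        n_schemes = self.data["scheme_label"].nunique()
        n_weeks = self.data["week"].nunique()
        return len(cells) == n_schemes * n_weeks

    def fit(self, alpha: float = 0.05, tukey: bool = True) -> AnovaTukeyResults:
        """Fit the two-way ANOVA; Tukey-Kramer scheme contrasts per week."""
        df = self.data.copy()
        df["scheme"] = df["scheme_label"].astype(str)
        df["week_f"] = df["week"].astype(str)
        dropped: list[str] = []
        formula = "volume_mm3 ~ C(scheme, Sum) * C(week_f, Sum)"
        if not self._interaction_estimable():
            formula = "volume_mm3 ~ C(scheme, Sum) + C(week_f, Sum)"
            dropped.append("scheme:week interaction (empty design cells)")
            log.warning("interaction dropped: design has empty scheme x week cells")
        fit = smf.ols(formula, data=df).fit()
        table = sm.stats.anova_lm(fit, typ=3)
        rename = {}
        for idx in table.index:
            if "scheme" in idx and "week_f" in idx:
                rename[idx] = "scheme:week"
            elif "scheme" in idx:
                rename[idx] = "scheme"
            elif "week_f" in idx:
                rename[idx] = "week"
        table = table.rename(index=rename)
        factors = [f for f in ("scheme", "week", "scheme:week") if f in table.index]
        F = {f: float(table.loc[f, "F"]) for f in factors}
        p = {f: float(table.loc[f, "PR(>F)"]) for f in factors}
        pairwise_rows: list[dict] = []
        if tukey:
            for week, sub in df.groupby("week"):
                if sub["scheme"].nunique() < 2:
                    continue
                # need residual df within the week for the studentized range
                if len(sub) <= sub["scheme"].nunique():
                    continue
                for row in _tukey_rows(
                    sub["volume_mm3"].to_numpy(), sub["scheme"].to_numpy(), alpha
                ):
                    row["week"] = float(week)
                    pairwise_rows.append(row)
        pairwise = pd.DataFrame(
            pairwise_rows,
            columns=["week", "group_a", "group_b", "mean_diff", "adjusted_p", "reject"],
        )
        return AnovaTukeyResults(
            factors=factors,
            F_per_factor=F,
            p_per_factor=p,
            anova_table=table,
            pairwise=pairwise,
            alpha=alpha,
            dropped_terms=dropped,
        )


class HistologyGradeModel:
    """One-way ANOVA of (numeric) histology grade across schemes."""

    def __init__(self, data: pd.DataFrame):
        data = pd.DataFrame(data)
        for col in ("subject_id", "scheme_label", "grade"):
            if col not in data.columns:
                raise ValueError(f"histology table is missing column {col!r}")
        counts = data.groupby("scheme_label").size()
        small = counts[counts < 2]
        if len(counts) < 2:
            raise ValueError("need >= 2 histology groups")
        if not small.empty:
            raise ValueError(
                f"groups with < 2 records: {sorted(small.index.tolist())}"
            )
        self.data = data.reset_index(drop=True)

    def fit(self, alpha: float = 0.05) -> AnovaTukeyResults:
        df = self.data.copy()
        df["grade"] = df["grade"].astype(float)
        fit = smf.ols("grade ~ C(scheme_label)", data=df).fit()
        table = sm.stats.anova_lm(fit, typ=2)
        table = table.rename(index=lambda s: "scheme" if "scheme_label" in s else s)
        F = {"scheme": float(table.loc["scheme", "F"])}
        p = {"scheme": float(table.loc["scheme", "PR(>F)"])}
        rows = _tukey_rows(
            df["grade"].to_numpy(), df["scheme_label"].to_numpy(), alpha
        )
        pairwise = pd.DataFrame(
            rows, columns=["group_a", "group_b", "mean_diff", "adjusted_p", "reject"]
        )
        return AnovaTukeyResults(
            factors=["scheme"],
            F_per_factor=F,
            p_per_factor=p,
            anova_table=table,
            pairwise=pairwise,
            alpha=alpha,
            response="grade",
        )


def two_way_anova_tukey(
    records: pd.DataFrame,
    modality: str | None = None,
    alpha: float = 0.05,
    tukey: bool = True,
) -> AnovaTukeyResults:
    """Functional wrapper: ``LesionVolumeModel(records, modality).fit()``."""
    return LesionVolumeModel(records, modality=modality).fit(alpha=alpha, tukey=tukey)


def one_way_anova_tukey(records: pd.DataFrame, alpha: float = 0.05) -> AnovaTukeyResults:
    """Functional wrapper: ``HistologyGradeModel(records).fit()``."""
    return HistologyGradeModel(records).fit(alpha=alpha)


def summarize_longitudinal(records: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD and count per (scheme, week, modality) cell.

    SD is reported as missing (NaN) for singleton cells.
    """
    validate_measurements(records)
    out = (
        records.groupby(["scheme_label", "week", "modality"], observed=True)[
            "volume_mm3"
        ]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else np.nan, n="size")
        .reset_index()
    )
    return out
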