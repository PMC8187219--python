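"""Cohort-level Monte-Carlo analysis of the toric translation ratio.

:class:`ToricTranslationModel` wraps a cohort of pseudophakic eyes (loaded
from CSV, a DataFrame, or drawn synthetically) and, on :meth:`fit`, runs
the per-case chain — back-solve the effective lens position from the
postoperative refraction, compute the fully correcting toric IOL, form the
torus-to-astigmatism translation ratio — and the sensitivity regression
panel. The fitted :class:`ToricTranslationResults` carries the per-case
table, the ratio summary statistics, the regressions, the exclusion log,
and the under-/overcorrection bounds implied by applying a fixed standard
factor across the observed ratio range.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .constants import DEFAULT_CONSTANTS, OpticalConstants
from .population import COHORT_COLUMNS, PopulationParams, generate_cohort
from .regression import RankDeficiencyError, RegressionResult, linear_fit
from . import optics

__all__ = [
    "ToricTranslationModel",
    "ToricTranslationResults",
    "MisestimationBounds",
    "EmptyCohortError",
    "analyze_case",
    "summarize_ratio",
    "misestimation_bounds",
    "REGRESSION_PANEL",
]


class EmptyCohortError(ValueError):
    """No valid cases to summarize."""


@dataclass(frozen=True)
class MisestimationBounds:
    """Worst-case cylinder misestimation when a fixed translation factor is
    applied to eyes spanning a ratio range.

    An eye whose true ratio exceeds the standard factor receives too little
    torus (undercorrection); one below it receives too much
    (overcorrection). Both are percentages of the required correction.
    """

    standard_factor: float
    ratio_low: float
    ratio_high: float
    undercorrection_pct: float
    overcorrection_pct: float

    def to_dict(self) -> dict:
        return {
            "standard_factor": self.standard_factor,
            "ratio_low": self.ratio_low,
            "ratio_high": self.ratio_high,
            "undercorrection_pct": self.undercorrection_pct,
            "overcorrection_pct": self.overcorrection_pct,
        }


def misestimation_bounds(
    standard_factor: float, ratio_low: float, ratio_high: float
) -> MisestimationBounds:
    """Percent under-/overcorrection of the refractive cylinder when
    ``standard_factor`` is applied to eyes with true ratios in
    ``[ratio_low, ratio_high]``: 100*(true - assumed)/true at each end."""
    if not standard_factor > 0:
        raise ValueError("standard_factor must be positive")
    if not 0 < ratio_low <= ratio_high:
        raise ValueError("need 0 < ratio_low <= ratio_high")
    under = (
        100.0 * (ratio_high - standard_factor) / ratio_high
        if ratio_high > standard_factor
        else 0.0
    )
    over = (
        100.0 * (standard_factor - ratio_low) / ratio_low
        if ratio_low < standard_factor
        else 0.0
    )
    return MisestimationBounds(standard_factor, ratio_low, ratio_high, under, over)


def analyze_case(
    record: optics.EyeRecord,
    constants: OpticalConstants = DEFAULT_CONSTANTS,
) -> optics.CaseResult:
    """Full per-case chain: ELP back-solve, then the fully correcting toric
    IOL at that lens position. Never raises on a flaggable case — failures
    come back as invalid :class:`~toricratio.optics.CaseResult` rows."""
    reason = record.validation_error()
    if reason is not None:
        return optics.CaseResult(valid=False, reason=reason, case_id=record.case_id)
    try:
        elp = optics.solve_elp(record, constants)
    except optics.ElpSolveError:
        return optics.CaseResult(
            valid=False, reason="elp_out_of_range", case_id=record.case_id
        )
    return optics.full_correction_tiol(
        record.r_flat,
        record.r_steep,
        record.axial_length,
        elp,
        constants,
        case_id=record.case_id,
    )


def summarize_ratio(ratios: np.ndarray | pd.Series) -> dict:
    """Mean, SD (n-1), median (midpoint for even n), min, max of the
    translation ratio over the valid cases."""
    r = np.asarray(ratios, dtype=float)
    r = r[np.isfinite(r)]
    if r.size == 0:
        raise EmptyCohortError("no valid translation ratios to summarize")
    return {
        "n": int(r.size),
        "mean": float(r.mean()),
        "sd": float(r.std(ddof=1)) if r.size > 1 else math.nan,
        "median": float(np.median(r)),
        "min": float(r.min()),
        "max": float(r.max()),
    }


#: sensitivity panel: name -> (response column, predictor columns)
REGRESSION_PANEL: dict[str, tuple[str, tuple[str, ...]]] = {
    "ratio_on_k_eq": ("ratio", ("k_eq_d",)),
    "ratio_on_astigmatism": ("ratio", ("astig_d",)),
    "ratio_on_elp": ("ratio", ("elp_mm",)),
    "ratio_on_axial_length": ("ratio", ("axial_length_mm",)),
    "elp_on_axial_length": ("elp_mm", ("axial_length_mm",)),
    "p_eq_on_axial_length": ("p_eq_d", ("axial_length_mm",)),
    "p_eq_on_elp": ("p_eq_d", ("elp_mm",)),
    "p_eq_on_k_eq": ("p_eq_d", ("k_eq_d",)),
    "p_eq_on_elp_axial_length": ("p_eq_d", ("elp_mm", "axial_length_mm")),
}


def sensitivity_report(
    cases: pd.DataFrame,
) -> dict[str, RegressionResult | str]:
    """Fit the full sensitivity panel on the valid cases of a per-case
    table. A model that cannot be fitted (rank deficiency, too few rows)
    is reported as an explanatory string; the others still fit."""
    valid = cases[cases["valid"]]
    out: dict[str, RegressionResult | str] = {}
    for name, (response, predictors) in REGRESSION_PANEL.items():
        try:
            out[name] = linear_fit(valid.loc[:, list(predictors)], valid[response])
        except RankDeficiencyError as exc:
            out[name] = f"not_fitted: {exc}"
    return out


def _records_from_frame(cohort: pd.DataFrame) -> tuple[list[optics.EyeRecord], dict]:
    required = [c for c in COHORT_COLUMNS if c != "id"]
    missing = [c for c in required if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table is missing columns: {missing}")
    has_id = "id" in cohort.columns
    has_dist = "meas_distance_m" in cohort.columns
    records: list[optics.EyeRecord] = []
    rejected: dict[str, int] = {}
    rejected_rows: list[int] = []
    for i, row in enumerate(cohort.itertuples(index=False)):
        d = row._asdict()
        try:
            rec = optics.EyeRecord(
                r_flat=float(d["r_flat_mm"]),
                r_steep=float(d["r_steep_mm"]),
                axial_length=float(d["axial_length_mm"]),
                acd_phakic=float(d["acd_mm"]),
                p_iol_implanted=float(d["p_iol_d"]),
                postop_sphere=float(d["postop_sphere_d"]),
                postop_cylinder=float(d["postop_cyl_d"]),
                case_id=str(d["id"]) if has_id else str(i),
                meas_distance_m=(
                    float(d["meas_distance_m"])
                    if has_dist and pd.notna(d["meas_distance_m"])
                    else None
                ),
            )
        except (TypeError, ValueError):
            rejected["unparseable_row"] = rejected.get("unparseable_row", 0) + 1
            rejected_rows.append(i)
            continue
        reason = rec.validation_error()
        if reason is not None:
            rejected[reason] = rejected.get(reason, 0) + 1
            rejected_rows.append(i)
            continue
        records.append(rec)
    return records, {"counts": rejected, "rows": rejected_rows}


class ToricTranslationModel:
    """Translation-ratio analysis of a pseudophakic cohort.

    Parameters
    ----------
    cohort : pandas.DataFrame
        One row per eye in the canonical dialect
        ``id, r_flat_mm, r_steep_mm, axial_length_mm, acd_mm, p_iol_d,
        postop_sphere_d, postop_cyl_d[, meas_distance_m]``.
    constants : OpticalConstants, optional
        Fixed optical assumptions; defaults to the standard model.

    Rows failing the biometric plausibility checks are rejected at
    construction and itemized in :attr:`rejected`.
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        constants: OpticalConstants = DEFAULT_CONSTANTS,
    ) -> None:
        self.constants = constants
        self.n_input = int(len(cohort))
        self.records, self.rejected = _records_from_frame(cohort)
        self.population_params: Optional[PopulationParams] = None
        self.truth: Optional[pd.DataFrame] = None

    @classmethod
    def from_csv(
        cls, path: str | Path, constants: OpticalConstants = DEFAULT_CONSTANTS
    ) -> "ToricTranslationModel":
        """Load a cohort CSV (comma, period decimal, UTF-8, header)."""
        cohort = pd.read_csv(path, encoding="utf-8")
        if cohort.empty:
            raise EmptyCohortError(f"cohort file {path} contains no rows")
        return cls(cohort, constants)

    @classmethod
    def from_synthetic(
        cls,
        params: PopulationParams | None = None,
        constants: OpticalConstants = DEFAULT_CONSTANTS,
    ) -> "ToricTranslationModel":
        """Draw a synthetic cohort (see :mod:`toricratio.population`) and
        wrap it; the latent truth table is kept on the model."""
        params = params or PopulationParams()
        cohort, truth = generate_cohort(params, constants, with_truth=True)
        m = cls(cohort, constants)
        m.population_params = params
        m.truth = truth
        return m

    def fit(self) -> "ToricTranslationResults":
        """Run the per-case analysis and the sensitivity panel."""
        rows = []
        for rec in self.records:
            powers = optics.MeridionalPowers.from_radii(
                rec.r_flat, rec.r_steep, self.constants
            )
            res = analyze_case(rec, self.constants)
            rows.append(
                {
                    "id": rec.case_id,
                    "elp_mm": res.elp,
                    "p_flat_d": res.p_flat_meridian,
                    "p_steep_d": res.p_steep_meridian,
                    "p_eq_d": res.p_equivalent,
                    "torus_d": res.torus,
                    "astig_d": powers.astigmatism,
                    "ratio": res.translation_ratio,
                    "valid": res.valid,
                    "reason": res.reason,
                    "axial_length_mm": rec.axial_length,
                    "k_eq_d": powers.k_equivalent,
                }
            )
        cases = pd.DataFrame(
            rows,
            columns=[
                "id",
                "elp_mm",
                "p_flat_d",
                "p_steep_d",
                "p_eq_d",
                "torus_d",
                "astig_d",
                "ratio",
                "valid",
                "reason",
                "axial_length_mm",
                "k_eq_d",
            ],
        )
        if len(cases) == 0 or not cases["valid"].any():
            raise EmptyCohortError("no valid cases in the cohort")
        exclusions = (
            cases.loc[~cases["valid"], "reason"].value_counts().to_dict()
        )
        for reason, count in self.rejected["counts"].items():
            exclusions[reason] = exclusions.get(reason, 0) + count
        ratio_summary = summarize_ratio(cases.loc[cases["valid"], "ratio"])
        regressions = sensitivity_report(cases)
        return ToricTranslationResults(
            model=self,
            cases=cases,
            ratio_summary=ratio_summary,
            regressions=regressions,
            exclusions=exclusions,
        )


class ToricTranslationResults:
    """Fitted translation-ratio analysis.

    Attributes
    ----------
    cases : pandas.DataFrame
        Per-case derived quantities joined to the biometry used by the
        regressions; invalid cases carry NaN and a reason code.
    ratio_summary : dict
        Mean/SD/median/min/max of the translation ratio over valid cases.
    regressions : dict
        Name -> :class:`~toricratio.regression.RegressionResult` (or an
        explanatory string for a degenerate model).
    exclusions : dict
        Reason -> count, covering load-time rejects and analysis flags.
    """

    def __init__(self, model, cases, ratio_summary, regressions, exclusions) -> None:
        self.model = model
        self.cases = cases
        self.ratio_summary = ratio_summary
        self.regressions = regressions
        self.exclusions = exclusions

    @property
    def n_valid(self) -> int:
        return int(self.cases["valid"].sum())

    @property
    def n_excluded(self) -> int:
        return int(sum(self.exclusions.values()))

    def misestimation_bounds(
        self,
        standard_factor: float = 1.4,
        ratio_low: float | None = None,
        ratio_high: float | None = None,
    ) -> MisestimationBounds:
        """Under-/overcorrection bounds for a fixed factor; the ratio range
        defaults to the observed min/max of this cohort."""
        return misestimation_bounds(
            standard_factor,
            self.ratio_summary["min"] if ratio_low is None else ratio_low,
            self.ratio_summary["max"] if ratio_high is None else ratio_high,
        )

    def to_report(self) -> dict:
        """JSON-ready report: constants echo, counts, exclusion log, ratio
        summary, fixed-factor bounds and the regression panel."""
        report = {
            "tool": {"name": "toricratio", "version": __version__},
            "constants": self.model.constants.to_dict(),
            "n_input": self.model.n_input,
            "n_valid": self.n_valid,
            "n_excluded": self.n_excluded,
            "exclusions": dict(sorted(self.exclusions.items())),
            "ratio_summary": self.ratio_summary,
            "misestimation_bounds": self.misestimation_bounds().to_dict(),
            "regressions": {
                name: (res.to_dict() if isinstance(res, RegressionResult) else res)
                for name, res in self.regressions.items()
            },
        }
        if self.model.population_params is not None:
            report["population_params"] = self.model.population_params.to_dict()
        return report

    def save_report(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_report(), indent=2, sort_keys=True))

    def save_cases(self, path: str | Path) -> None:
        """Per-case CSV for scatter-plot reproduction."""
        cols = [
            "id",
            "elp_mm",
            "p_flat_d",
            "p_steep_d",
            "p_eq_d",
            "torus_d",
            "astig_d",
            "ratio",
            "valid",
            "reason",
        ]
        self.cases.loc[:, cols].to_csv(
            path, index=False, float_format="%.10g", encoding="utf-8"
        )

    def summary(self) -> str:
        """Human-readable summary table."""
        s = self.ratio_summary
        lines = [
            "Toric translation-ratio analysis",
            "================================",
            f"cases: {self.model.n_input} in, {self.n_valid} valid, "
            f"{self.n_excluded} excluded {dict(sorted(self.exclusions.items()))}",
            (
                f"translation ratio: mean {s['mean']:.4f} +/- {s['sd']:.4f}  "
                f"median {s['median']:.4f}  range [{s['min']:.4f}, {s['max']:.4f}]"
            ),
        ]
        b = self.misestimation_bounds()
        lines.append(
            f"fixed factor {b.standard_factor}: undercorrection up to "
            f"{b.undercorrection_pct:.1f} %, overcorrection up to "
            f"{b.overcorrection_pct:.1f} %"
        )
        lines.append("")
        header = (
            f"{'model':<28}{'intercept':>11}{'slope(s)':>22}"
            f"{'adjR2':>8}{'|R|':>7}  class"
        )
        lines.append(header)
        lines.append("-" * len(header))
        for name, res in self.regressions.items():
            if isinstance(res, RegressionResult):
                slopes = ", ".join(f"{c:+.4f}" for c in res.coef[1:])
                lines.append(
                    f"{name:<28}{res.intercept:>11.4f}{slopes:>22}"
                    f"{res.adj_r2:>8.3f}{res.abs_r:>7.3f}  {res.cohen_class}"
                )
            else:
                lines.append(f"{name:<28}{res}")
        return "\n".join(lines)

    # legacy alias
    summary_text = summary
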