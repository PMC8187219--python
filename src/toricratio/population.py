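"""Synthetic biometry cohorts with simulated surgery and noisy refraction.

No raw clinical cohort ships with the package, so analyses run on synthetic
eyes whose joint structure mirrors a cataract-surgery population: axial
length and mean corneal radius are near-normal, corneal astigmatism is
right-skewed with few high astigmats, and the true capsular-bag lens
position rises linearly with axial length. Surgery is simulated by
implanting the emmetropizing equivalent-power IOL rounded to the
manufacturing grid, and the postoperative refraction is observed through
measurement noise and chart quantization.

Each record draws from its own deterministic substream of the global seed,
so enlarging a cohort extends it without reshuffling earlier eyes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .constants import DEFAULT_CONSTANTS, OpticalConstants
from . import optics

__all__ = [
    "PopulationParams",
    "TrueEye",
    "sample_biometry",
    "simulate_surgery",
    "generate_cohort",
    "COHORT_COLUMNS",
]

#: CSV dialect shared with the analysis input
COHORT_COLUMNS = [
    "id",
    "r_flat_mm",
    "r_steep_mm",
    "axial_length_mm",
    "acd_mm",
    "p_iol_d",
    "postop_sphere_d",
    "postop_cyl_d",
]

_TRUTH_COLUMNS = ["id", "elp_true_mm", "se_true_d"]


@dataclass(frozen=True)
class PopulationParams:
    """Distributional knobs of the synthetic cohort.

    Defaults describe a generic cataract population: AL ~ N(23.5, 1.96) mm
    truncated to [20, 30]; mean corneal radius ~ N(7.7, 0.26) mm; corneal
    astigmatism ~ 0.25 D + Gamma(shape 2, scale 0.5); true lens position
    ELP = 1.1772 + 0.1513*AL + N(0, 0.45) mm truncated to [2.5, 7]. IOL
    powers come in 0.5 D steps; refraction is read to 0.25 D with 0.25 D
    measurement noise. ``al_k_corr`` couples axial length to corneal power
    (default 0: independent).
    """

    n: int = 16744
    seed: int = 1
    al_mean: float = 23.5
    al_sd: float = 1.96
    r_mean: float = 7.7
    r_sd: float = 0.26
    astig_shape: float = 2.0
    astig_scale: float = 0.5
    astig_min: float = 0.25
    elp_intercept: float = 1.1772
    elp_slope: float = 0.1513
    elp_resid_sd: float = 0.45
    al_k_corr: float = 0.0
    iol_step: float = 0.5
    refr_noise_sd: float = 0.25
    refr_step: float = 0.25
    acd_mean: float = 3.2
    acd_sd: float = 0.35

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("cohort size n must be non-negative")
        for name in ("al_sd", "r_sd", "elp_resid_sd", "refr_noise_sd", "acd_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.astig_min < 0:
            raise ValueError("astig_min must be non-negative")
        if self.astig_shape <= 0 or self.astig_scale < 0:
            raise ValueError("invalid astigmatism Gamma parameters")
        if self.iol_step <= 0 or self.refr_step <= 0:
            raise ValueError("iol_step and refr_step must be positive")
        if not -1.0 <= self.al_k_corr <= 1.0:
            raise ValueError("al_k_corr must lie in [-1, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationParams":
        valid = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - valid
        if unknown:
            raise ValueError(f"unknown population keys: {sorted(unknown)}")
        return cls(**d)


@dataclass(frozen=True)
class TrueEye:
    """Latent generator state: biometry plus the true lens position and the
    noise-free postoperative SE (filled in by :func:`simulate_surgery`)."""

    case_id: str
    r_flat: float
    r_steep: float
    axial_length: float
    acd_phakic: float
    elp_true: float
    p_iol_implanted: float = math.nan
    se_true: float = math.nan


def _record_rng(seed: int, index: int) -> np.random.Generator:
    # Per-record substream: record i is identical regardless of cohort size.
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    if sd == 0.0:
        return min(max(mean, lo), hi)
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x
    raise RuntimeError("truncated-normal rejection sampling failed to converge")


def _sample_one_biometry(
    params: PopulationParams,
    rng: np.random.Generator,
    constants: OpticalConstants,
    case_id: str,
) -> TrueEye:
    p = params
    while True:
        z_al = rng.standard_normal()
        z_r = rng.standard_normal()
        al = p.al_mean + p.al_sd * z_al
        if not 20.0 <= al <= 30.0:
            continue
        # positive AL-K correlation means longer eyes get flatter corneas
        # (larger radii), hence the sign flip on z_al for the radius draw
        c = p.al_k_corr
        r_mean_eye = p.r_mean + p.r_sd * (-c * z_al + math.sqrt(1.0 - c * c) * z_r)
        astig = p.astig_min + (
            rng.gamma(p.astig_shape, p.astig_scale) if p.astig_scale > 0 else 0.0
        )
        if not 5.0 < r_mean_eye < 11.0:
            continue
        k_eq = optics.keratometric_power(r_mean_eye, constants)
        k_flat = k_eq - 0.5 * astig
        k_steep = k_eq + 0.5 * astig
        if k_flat <= 0:
            continue
        scale = (constants.n_keratometer - 1.0) * 1000.0
        r_flat = scale / k_flat
        r_steep = scale / k_steep
        if not (5.0 < r_steep <= r_flat < 11.0):
            continue
        elp_mu = p.elp_intercept + p.elp_slope * al
        if p.elp_resid_sd == 0.0:
            elp_true = min(max(elp_mu, 2.5), 7.0)
        else:
            try:
                elp_true = _truncated_normal(rng, elp_mu, p.elp_resid_sd, 2.5, 7.0)
            except RuntimeError:
                continue
        if not elp_true < al - 1.0:
            continue
        acd = _truncated_normal(rng, p.acd_mean, p.acd_sd, 1.5, 5.0)
        return TrueEye(
            case_id=case_id,
            r_flat=r_flat,
            r_steep=r_steep,
            axial_length=al,
            acd_phakic=acd,
            elp_true=elp_true,
        )


def sample_biometry(
    params: PopulationParams,
    constants: OpticalConstants = DEFAULT_CONSTANTS,
) -> list[TrueEye]:
    """Draw ``params.n`` synthetic eyes (biometry and true lens position
    only; surgery fields left unset)."""
    return [
        _sample_one_biometry(params, _record_rng(params.seed, i), constants, str(i))
        for i in range(params.n)
    ]


def _quantize(x: float, step: float) -> float:
    return step * round(x / step)


def simulate_surgery(
    eye: TrueEye,
    params: PopulationParams,
    rng: np.random.Generator,
    constants: OpticalConstants = DEFAULT_CONSTANTS,
) -> tuple[optics.EyeRecord, TrueEye]:
    """Implant the emmetropizing IOL and observe the refraction.

    The implanted power is the emmetropizing equivalent power at the true
    lens position, snapped to the manufacturing grid; the true residual SE
    follows from the forward model, and the observed SE adds Gaussian
    measurement noise and chart quantization. Only the spherical equivalent
    is consumed downstream, so the record carries it as the sphere with a
    zero cylinder.
    """
    powers = optics.MeridionalPowers.from_radii(eye.r_flat, eye.r_steep, constants)
    p_exact = optics.emmetropizing_power(
        powers.k_equivalent, eye.axial_length, eye.elp_true, constants
    )
    p_iol = _quantize(p_exact, params.iol_step)
    se_true = optics.predicted_postop_se(
        powers.k_equivalent, eye.axial_length, p_iol, eye.elp_true, constants
    )
    se_obs = se_true
    if params.refr_noise_sd > 0:
        se_obs += rng.normal(0.0, params.refr_noise_sd)
    se_obs = _quantize(se_obs, params.refr_step)
    record = optics.EyeRecord(
        r_flat=eye.r_flat,
        r_steep=eye.r_steep,
        axial_length=eye.axial_length,
        acd_phakic=eye.acd_phakic,
        p_iol_implanted=p_iol,
        postop_sphere=se_obs,
        postop_cylinder=0.0,
        case_id=eye.case_id,
    )
    return record, replace(eye, p_iol_implanted=p_iol, se_true=se_true)


def generate_cohort(
    params: PopulationParams,
    constants: OpticalConstants = DEFAULT_CONSTANTS,
    with_truth: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a full cohort table in the analysis CSV dialect.

    Returns the cohort DataFrame, or ``(cohort, truth)`` when
    ``with_truth`` is set; the truth table holds the latent lens position
    and noise-free SE per eye. Eyes whose simulated surgery is optically
    degenerate are resampled within their substream (counted in
    ``cohort.attrs['n_resampled']``).
    """
    rows: list[dict] = []
    truth_rows: list[dict] = []
    n_resampled = 0
    for i in range(params.n):
        rng = _record_rng(params.seed, i)
        while True:
            eye = _sample_one_biometry(params, rng, constants, str(i))
            try:
                record, eye = simulate_surgery(eye, params, rng, constants)
            except (optics.DegeneratePropagationError, ValueError):
                n_resampled += 1
                continue
            break
        rows.append(
            {
                "id": record.case_id,
                "r_flat_mm": record.r_flat,
                "r_steep_mm": record.r_steep,
                "axial_length_mm": record.axial_length,
                "acd_mm": record.acd_phakic,
                "p_iol_d": record.p_iol_implanted,
                "postop_sphere_d": record.postop_sphere,
                "postop_cyl_d": record.postop_cylinder,
            }
        )
        truth_rows.append(
            {"id": eye.case_id, "elp_true_mm": eye.elp_true, "se_true_d": eye.se_true}
        )
    cohort = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    cohort.attrs["n_resampled"] = n_resampled
    if with_truth:
        return cohort, pd.DataFrame(truth_rows, columns=_TRUTH_COLUMNS)
    return cohort


def write_cohort_csv(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write the cohort in the canonical dialect (comma, period decimal,
    UTF-8, header), with stable float formatting for byte-identical runs."""
    cohort.to_csv(path, index=False, float_format="%.10g", encoding="utf-8")
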