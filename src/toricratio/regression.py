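"""Linear-regression summaries in the reporting style of the cohort study.

Simple and multiple ordinary least squares, each reported as coefficients
with standard errors, adjusted R², the correlation magnitude
|R| = sqrt(max(adj R², 0)), a p-value (slope t-test for simple models, the
overall F-test otherwise) and the Cohen effect-size class of |R|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["RegressionResult", "RankDeficiencyError", "linear_fit", "cohen_class"]


class RankDeficiencyError(ValueError):
    """Design matrix is rank deficient (or has too few rows to fit)."""


#: Cohen bands for |R|, upper edge inclusive
_COHEN_BINS = (
    (0.1, "negligible"),
    (0.3, "small"),
    (0.5, "moderate"),
    (1.0, "large"),
)


def cohen_class(abs_r: float) -> str:
    """Classify a correlation magnitude per Cohen: negligible |R| <= 0.1,
    small 0.1 < |R| <= 0.3, moderate 0.3 < |R| <= 0.5, large |R| > 0.5."""
    if not 0.0 <= abs_r <= 1.0:
        raise ValueError(f"|R| must lie in [0, 1], got {abs_r}")
    for upper, label in _COHEN_BINS:
        if abs_r <= upper:
            return label
    return "large"  # pragma: no cover - abs_r == 1.0 handled above


@dataclass(frozen=True)
class RegressionResult:
    """One fitted model: names and coefficients (intercept first),
    per-coefficient standard errors, adjusted R², |R|, p, n and the Cohen
    class of |R|."""

    names: tuple[str, ...]
    coef: tuple[float, ...]
    se: tuple[float, ...]
    adj_r2: float
    abs_r: float
    p_value: float
    n: int
    cohen_class: str

    @property
    def intercept(self) -> float:
        return self.coef[0]

    @property
    def slope(self) -> float:
        """Slope of a simple (single-predictor) model."""
        if len(self.coef) != 2:
            raise ValueError("slope is only defined for simple regression")
        return self.coef[1]

    def coefficient(self, name: str) -> float:
        return self.coef[self.names.index(name)]

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "coef": list(self.coef),
            "se": list(self.se),
            "adj_r2": self.adj_r2,
            "abs_r": self.abs_r,
            "p_value": self.p_value,
            "n": self.n,
            "cohen_class": self.cohen_class,
        }


def linear_fit(
    design: pd.DataFrame | np.ndarray,
    response: np.ndarray | pd.Series,
    names: list[str] | None = None,
) -> RegressionResult:
    """OLS of ``response`` on the predictor columns of ``design`` (an
    intercept is added internally).

    Raises :class:`RankDeficiencyError` when the intercept-augmented design
    is rank deficient or there are not more observations than coefficients.
    """
    if isinstance(design, pd.DataFrame):
        if names is None:
            names = list(design.columns)
        x = design.to_numpy(dtype=float)
    else:
        x = np.asarray(design, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        if names is None:
            names = [f"x{i + 1}" for i in range(x.shape[1])]
    y = np.asarray(response, dtype=float)
    n, p = x.shape
    if y.shape != (n,):
        raise ValueError("response length does not match design rows")
    if n <= p + 1:
        raise RankDeficiencyError(f"need more than {p + 1} observations, got {n}")
    exog = sm.add_constant(x, has_constant="add")
    if np.linalg.matrix_rank(exog) < p + 1:
        raise RankDeficiencyError("design matrix is rank deficient")

    with np.errstate(divide="ignore", invalid="ignore"):
        fit = sm.OLS(y, exog).fit()
        adj_r2 = float(fit.rsquared_adj)
        # simple model: slope t-test; multiple model: overall F-test
        p_value = float(fit.pvalues[1]) if p == 1 else float(fit.f_pvalue)
    if not np.isfinite(adj_r2):  # response without variance
        adj_r2 = 0.0
    abs_r = float(np.sqrt(max(adj_r2, 0.0)))
    if np.isnan(p_value):  # zero residual variance: 0/0 test statistic
        p_value = 1.0 if np.allclose(fit.params[1:], 0.0) else 0.0
    return RegressionResult(
        names=("intercept", *names),
        coef=tuple(float(c) for c in fit.params),
        se=tuple(float(s) for s in fit.bse),
        adj_r2=adj_r2,
        abs_r=abs_r,
        p_value=p_value,
        n=n,
        cohen_class=cohen_class(abs_r),
    )
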