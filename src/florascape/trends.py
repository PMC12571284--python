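"""Demographic arithmetic and trend statistics.

Covers the couplings reported alongside the LULC/biodiversity accounting:
population densities and growth multiples, Pearson correlations between
species densities and population density (with the customary significance
stars), and least-squares trend fits on linear, quadratic, exponential and
logarithmic scales.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import ValidationError

MODELS = ("linear", "polynomial-2", "exponential", "logarithmic")


def population_density(population: float, area_km2: float) -> float:
    """People per km²."""
    if area_km2 <= 0:
        raise ValidationError("area must be > 0")
    return population / area_km2


def growth_multiple(p0: float, p1: float) -> float:
    """Ratio p1/p0 (e.g. a 28-fold population increase)."""
    if p0 <= 0:
        raise ValidationError("baseline must be > 0")
    return p1 / p0


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class CorrelationResult:
    r: float
    n: int
    p_value: float
    stars: str
    labels: tuple[str, str] = ("x", "y")


def pearson(x, y, labels: tuple[str, str] = ("x", "y")) -> CorrelationResult:
    """Pearson product-moment correlation with a two-sided p-value from the
    t transform; requires n ≥ 3 and non-degenerate variance in both
    arguments."""
    xa = np.asarray(x, float)
    ya = np.asarray(y, float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-d vectors")
    if xa.size < 3:
        raise ValidationError("Pearson correlation needs n >= 3")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValidationError("zero variance in one of the arguments")
    res = stats.pearsonr(xa, ya)
    r, p = float(res.statistic), float(res.pvalue)
    return CorrelationResult(r, xa.size, p, significance_stars(p), labels)


@dataclass
class TrendFit:
    """A least-squares trend on its fitted scale.

    coefficients: linear (a, b) for y = a + b·x; polynomial-2 (a, b, c) for
    y = a + b·x + c·x²; exponential (a, b) for y = a·e^(b·x) (fitted as
    ln y = ln a + b·x); logarithmic (a, b) for y = a + b·ln x.  R² is
    reported on the fitted (possibly transformed) scale.
    """

    model: str
    coefficients: tuple[float, ...]
    r2: float
    n: int

    def predict(self, x):
        xa = np.asarray(x, float)
        c = self.coefficients
        if self.model == "linear":
            return c[0] + c[1] * xa
        if self.model == "polynomial-2":
            return c[0] + c[1] * xa + c[2] * xa**2
        if self.model == "exponential":
            return c[0] * np.exp(c[1] * xa)
        if self.model == "logarithmic":
            return c[0] + c[1] * np.log(xa)
        raise ValidationError(f"unknown model {self.model!r}")


def _ls(design: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    yhat = design @ coef
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return coef, r2


def fit_trend(x, y, model: str = "linear") -> TrendFit:
    """Least-squares fit of the chosen trend model.

    Transformed-scale fits: exponential regresses ln y on x (all y must be
    > 0), logarithmic regresses y on ln x (all x must be > 0); domain
    violations raise naming the offending points.
    """
    if model not in MODELS:
        raise ValidationError(f"unknown model {model!r}; choose from {MODELS}")
    xa = np.asarray(x, float)
    ya = np.asarray(y, float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-d vectors")
    n_coef = 3 if model == "polynomial-2" else 2
    if xa.size < n_coef:
        raise ValidationError(f"{model} fit needs at least {n_coef} points")

    if model == "logarithmic":
        bad = np.flatnonzero(xa <= 0)
        if bad.size:
            raise ValidationError(
                f"logarithmic fit needs x > 0; offending indices {bad.tolist()}"
            )
        coef, r2 = _ls(np.column_stack([np.ones_like(xa), np.log(xa)]), ya)
        return TrendFit(model, (float(coef[0]), float(coef[1])), r2, xa.size)
    if model == "exponential":
        bad = np.flatnonzero(ya <= 0)
        if bad.size:
            raise ValidationError(
                f"exponential fit needs y > 0; offending indices {bad.tolist()}"
            )
        coef, r2 = _ls(np.column_stack([np.ones_like(xa), xa]), np.log(ya))
        return TrendFit(model, (float(np.exp(coef[0])), float(coef[1])), r2, xa.size)
    if model == "polynomial-2":
        coef, r2 = _ls(np.column_stack([np.ones_like(xa), xa, xa**2]), ya)
        return TrendFit(model, tuple(float(v) for v in coef), r2, xa.size)
    coef, r2 = _ls(np.column_stack([np.ones_like(xa), xa]), ya)
    return TrendFit(model, (float(coef[0]), float(coef[1])), r2, xa.size)
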