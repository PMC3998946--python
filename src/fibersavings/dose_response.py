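"""Dose-response estimation: per-gram prevalence reduction from grouped data.

The cohort model applies the per-gram reduction r multiplicatively:
prevalence at intake x relative to the reference category is
``p(x)/p(x1) = 1 - r (x - x1)``. The estimator here fits that same line to
grouped (e.g. quintile) exposure-prevalence data by weighted least squares
through the fixed point (x1, 1), so a fitted r plugs directly into the
model. Working on relative prevalence makes the estimate exactly invariant
to rescaling all prevalences by a common factor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .params import DoseResponse

__all__ = [
    "ExposureCategory",
    "GroupedExposureData",
    "DoseResponseFit",
    "fit_per_gram_reduction",
    "simulate_grouped_data",
]


class ExposureCategory(BaseModel):
    """One exposure group: median fiber intake, prevalence, optional size."""

    model_config = ConfigDict(validate_assignment=True)

    median_intake: float = Field(ge=0)
    prevalence: float = Field(gt=0.0, le=1.0)
    n: Optional[float] = Field(default=None, gt=0)


class GroupedExposureData(BaseModel):
    """Grouped exposure-prevalence data with strictly increasing intakes."""

    model_config = ConfigDict(validate_assignment=True)

    categories: list[ExposureCategory] = Field(min_length=2)

    @model_validator(mode="after")
    def _increasing(self) -> "GroupedExposureData":
        intakes = [c.median_intake for c in self.categories]
        if any(b <= a for a, b in zip(intakes, intakes[1:])):
            raise ValueError(
                f"median intakes must be strictly increasing, got {intakes}"
            )
        return self


@dataclass(frozen=True)
class DoseResponseFit:
    """Fit result: model-ready clipped estimate plus the raw WLS slope.

    ``raw_slope`` can leave [0, 1] under noise; ``dose_response`` carries
    the clipped value the cohort model accepts. ``se`` and ``ci95`` are the
    slope's normal-theory standard error and 95% confidence interval.
    """

    dose_response: DoseResponse
    raw_slope: float
    se: float
    ci95: tuple[float, float]

    @property
    def per_gram_reduction(self) -> float:
        return self.dose_response.per_gram_reduction


def fit_per_gram_reduction(data: GroupedExposureData) -> DoseResponseFit:
    """Weighted least-squares fit of ``p_k/p_1 = 1 - r (x_k - x_1)``.

    Category sizes ``n`` weight the fit (uniform weights if absent). The
    reference category contributes no information (its relative prevalence
    is 1 by construction), so with two categories the fit is the exact
    two-point slope.
    """
    cats = data.categories
    x = np.array([c.median_intake for c in cats])
    p = np.array([c.prevalence for c in cats])
    w = np.array([c.n if c.n is not None else 1.0 for c in cats])
    dx = x - x[0]
    y = 1.0 - p / p[0]  # so the model is y = r * dx, no intercept
    fit = sm.WLS(y, dx, weights=w).fit()
    raw = float(fit.params[0])
    if all(c.n is not None for c in cats):
        # Delta-method SE under binomial category counts. The shared
        # reference denominator correlates all relative prevalences, a
        # component residual-based errors cannot see, so the residual WLS
        # interval undercovers; propagating binomial variance through the
        # ratio gives the honest normal-theory interval.
        coef = w * dx / float(np.sum(w * dx * dx))
        grad = -coef / p[0]
        grad[0] = float(np.sum(coef * p)) / p[0] ** 2
        var_p = p * (1.0 - p) / w
        se = float(np.sqrt(np.sum(grad * grad * var_p)))
        lo, hi = raw - 1.959963984540054 * se, raw + 1.959963984540054 * se
    else:
        # group sizes unknown: residual-based WLS interval is all there is
        se = float(fit.bse[0])
        lo, hi = (float(v) for v in np.asarray(fit.conf_int())[0])
    return DoseResponseFit(
        dose_response=DoseResponse(per_gram_reduction=min(1.0, max(0.0, raw))),
        raw_slope=raw,
        se=se,
        ci95=(lo, hi),
    )


def simulate_grouped_data(
    true_r: float,
    p_ref: float,
    intakes: Sequence[float],
    n_per_group: int,
    seed: int,
) -> GroupedExposureData:
    """Binomial sampling of grouped data on the assumed dose-response line.

    Cases in category k are drawn Binomial(n, p_ref (1 - r (x_k - x_1))).
    A half-count continuity correction keeps an all-zero draw inside the
    valid prevalence domain (0, 1]; it is vanishingly rare at the group
    sizes used for validation.
    """
    x = np.asarray(intakes, dtype=float)
    probs = p_ref * (1.0 - true_r * (x - x[0]))
    if np.any(probs <= 0) or np.any(probs > 1):
        raise ValueError(
            f"implied prevalences {probs.tolist()} leave (0, 1]; "
            "reduce true_r or the intake span"
        )
    rng = np.random.default_rng(seed)
    cases = rng.binomial(n_per_group, probs)
    prevalence = np.where(cases > 0, cases, 0.5) / n_per_group
    return GroupedExposureData(
        categories=[
            ExposureCategory(median_intake=xi, prevalence=pi, n=n_per_group)
            for xi, pi in zip(x, prevalence)
        ]
    )
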