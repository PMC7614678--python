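"""Posterior and predictive distributions for the two-group mean difference.

The new experiment compares two arms with a common variance sigma0^2; the
data enter only through the sufficient statistic ``xbar_Delta``, the
difference in sample means, whose sampling variance is
``(1/n_A + 1/n_B) sigma0^2``.  With the collective normal prior
N(V_mean, V) for mu_Delta this gives conjugate normal updates when sigma0^2
is known.  When sigma0^2 is unknown it carries an inverse-gamma prior
Inv-Gamma(c/2, c V / 2) — equivalently ``c V / sigma0^2 ~ chi^2(c)`` — and
the marginal posterior of mu_Delta is proportional to the product of a
normal kernel (the prior) and a nonstandardised t kernel (the integrated
likelihood), normalised here by quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, NamedTuple

import numpy as np
from scipy import integrate, stats

from .priors import CollectivePrior

__all__ = [
    "DesignSpec",
    "VariancePrior",
    "PosteriorSummary",
    "PredictiveSummary",
    "posterior_known_variance",
    "predictive_distribution",
    "marginal_posterior_unknown_variance",
    "log_odds_summary",
    "LogOddsSummary",
]


@dataclass(frozen=True)
class DesignSpec:
    """Group sizes of the new experiment (real-valued for continuous solves)."""

    n_a: float
    n_b: float

    def __post_init__(self) -> None:
        if not (self.n_a > 0 and self.n_b > 0):
            raise ValueError("group sizes must be positive")

    @property
    def effective_size(self) -> float:
        """n_A n_B / (n_A + n_B), the precision-relevant size; N/4 when equal."""
        return self.n_a * self.n_b / (self.n_a + self.n_b)

    @property
    def variance_factor(self) -> float:
        """1/n_A + 1/n_B, multiplying sigma0^2 in the sampling variance."""
        return 1.0 / self.n_a + 1.0 / self.n_b

    @property
    def total(self) -> float:
        return self.n_a + self.n_b

    @classmethod
    def equal(cls, total: float) -> "DesignSpec":
        return cls(total / 2.0, total / 2.0)


@dataclass(frozen=True)
class VariancePrior:
    """Known value of, or inverse-gamma prior for, the common variance.

    Unknown mode encodes sigma0^2 ~ Inv-Gamma(c/2, scale) with
    ``scale = c V / 2`` where V is the collective prior variance; ``c`` acts
    as prior degrees of freedom tying sigma0^2 to V (large c => sigma0^2
    concentrated at V).
    """

    mode: str  # "known" | "unknown"
    sigma0_sq: float | None = None
    c: float | None = None
    scale: float | None = None

    def __post_init__(self) -> None:
        if self.mode == "known":
            if self.sigma0_sq is None or not self.sigma0_sq > 0:
                raise ValueError("known mode requires sigma0_sq > 0")
        elif self.mode == "unknown":
            if self.c is None or not self.c > 0:
                raise ValueError("unknown mode requires degrees of freedom c > 0")
            if self.scale is None or not self.scale > 0:
                raise ValueError("unknown mode requires scale > 0")
        else:
            raise ValueError(f"mode must be 'known' or 'unknown', got {self.mode!r}")

    @classmethod
    def known(cls, sigma0_sq: float) -> "VariancePrior":
        return cls(mode="known", sigma0_sq=sigma0_sq)

    @classmethod
    def unknown(cls, c: float, scale: float) -> "VariancePrior":
        return cls(mode="unknown", c=c, scale=scale)

    @property
    def mean_sigma0_sq(self) -> float:
        """E[sigma0^2]; requires c > 2 in unknown mode."""
        if self.mode == "known":
            return float(self.sigma0_sq)
        if self.c <= 2:
            raise ValueError(
                f"E[sigma0^2] requires c > 2 (inverse-gamma mean condition); got c={self.c}"
            )
        return 2.0 * self.scale / (self.c - 2.0)

    def distribution(self):
        """scipy frozen Inv-Gamma(c/2, scale) distribution (unknown mode)."""
        if self.mode != "unknown":
            raise ValueError("distribution() is defined for the unknown mode only")
        return stats.invgamma(self.c / 2.0, scale=self.scale)


@dataclass(frozen=True)
class PosteriorSummary:
    """Normal posterior N(mean, variance) for mu_Delta given sigma0^2."""

    mean: float
    variance: float

    def __post_init__(self) -> None:
        if not self.variance > 0:
            raise ValueError("posterior variance must be positive")

    @property
    def sd(self) -> float:
        return math.sqrt(self.variance)

    def hpd_fixed_length(self, length: float) -> tuple[float, float]:
        """HPD interval of the given length — symmetric about the mean."""
        return self.mean - length / 2.0, self.mean + length / 2.0

    def coverage_fixed_length(self, length: float) -> float:
        """Posterior probability of the length-l HPD interval about the mean."""
        return float(2.0 * stats.norm.cdf(length / (2.0 * self.sd)) - 1.0)

    def credible_length(self, coverage: float) -> float:
        """Length of the HPD interval with the given coverage probability."""
        z = stats.norm.ppf(0.5 + coverage / 2.0)
        return float(2.0 * z * self.sd)


@dataclass(frozen=True)
class PredictiveSummary:
    """Marginal (pre-posterior) normal law of the statistic Xbar_Delta."""

    mean: float
    variance: float


def posterior_known_variance(
    prior: CollectivePrior,
    xbar_delta: float,
    design: DesignSpec,
    sigma0_sq: float,
) -> PosteriorSummary:
    """Conjugate normal update of the collective prior by xbar_Delta.

    Posterior precision is the sum of the prior precision 1/V and the data
    precision 1/((1/n_A + 1/n_B) sigma0^2); the posterior mean is the
    precision-weighted average of the prior mean and xbar_Delta.
    """
    if not sigma0_sq > 0:
        raise ValueError("sigma0_sq must be positive")
    data_var = design.variance_factor * sigma0_sq
    post_var = 1.0 / (1.0 / prior.variance + 1.0 / data_var)
    post_mean = post_var * (prior.mean / prior.variance + xbar_delta / data_var)
    return PosteriorSummary(mean=post_mean, variance=post_var)


def predictive_distribution(
    prior: CollectivePrior, design: DesignSpec, vp: VariancePrior | float
) -> PredictiveSummary:
    """Marginal law of Xbar_Delta, unconditional on mu_Delta.

    ``vp`` is either a known-mode VariancePrior or a sigma0^2 value to
    condition on (the unknown-variance case conditions on a drawn sigma0^2).
    Mean is the prior mean; variance is (1/n_A + 1/n_B) sigma0^2 + V.
    """
    if isinstance(vp, VariancePrior):
        if vp.mode != "known":
            raise ValueError(
                "predictive_distribution needs a sigma0^2 value; pass a known-mode "
                "prior or a float to condition on"
            )
        sigma0_sq = vp.sigma0_sq
    else:
        sigma0_sq = float(vp)
    if not sigma0_sq > 0:
        raise ValueError("sigma0_sq must be positive")
    return PredictiveSummary(
        mean=prior.mean,
        variance=design.variance_factor * sigma0_sq + prior.variance,
    )


def marginal_posterior_unknown_variance(
    prior: CollectivePrior,
    xbar_delta: float,
    design: DesignSpec,
    vp: VariancePrior,
) -> Callable[[np.ndarray], np.ndarray]:
    """Normalised marginal posterior density of mu_Delta, sigma0^2 integrated out.

    The density is proportional to the normal prior kernel times a
    nonstandardised t kernel with location xbar_Delta, squared scale
    ``(1/n_A + 1/n_B) V`` and ``c`` degrees of freedom.  The normalising
    constant is computed by adaptive quadrature on a window of ±15 combined
    scales around the kernels' locations.
    """
    if vp.mode != "unknown":
        raise ValueError("marginal posterior requires an unknown-mode variance prior")
    v = prior.variance
    t_scale = math.sqrt(design.variance_factor * v)
    c = float(vp.c)

    def kernel(x):
        x = np.asarray(x, dtype=float)
        log_norm = -((x - prior.mean) ** 2) / (2.0 * v)
        log_t = -(c + 1.0) / 2.0 * np.log1p(
            (x - xbar_delta) ** 2 / (c * t_scale**2)
        )
        return np.exp(log_norm + log_t)

    spread = math.sqrt(v) + t_scale
    lo = min(prior.mean, xbar_delta) - 15.0 * spread
    hi = max(prior.mean, xbar_delta) + 15.0 * spread
    z, err = integrate.quad(kernel, lo, hi, epsabs=1e-10, limit=200)
    if not np.isfinite(z) or z <= 0 or err > 1e-6 * z:
        raise ArithmeticError(
            f"normalisation quadrature failed: integral={z}, abserr={err}"
        )

    def density(x):
        out = kernel(x) / z
        return float(out) if np.ndim(x) == 0 else out

    return density


class LogOddsSummary(NamedTuple):
    mean: float
    variance: float
    continuity_corrected: bool


def log_odds_summary(table) -> LogOddsSummary:
    """Normal summary of the log-odds ratio from a 2x2 count table.

    ``table`` is [[a, b], [c, d]] with rows = arms and columns =
    event/no-event.  Returns the Wald summary: mean log((a d)/(b c)),
    variance 1/a + 1/b + 1/c + 1/d.  If any cell is zero, 0.5 is added to
    every cell (Haldane–Anscombe) and the result is flagged.  A zero row or
    column margin is an error — the odds ratio is then unidentified.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be a 2x2 array of nonnegative counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("a zero row or column margin leaves the odds ratio undefined")
    corrected = bool(np.any(t == 0))
    if corrected:
        t = t + 0.5
    a, b = t[0]
    c, d = t[1]
    return LogOddsSummary(
        mean=float(math.log(a * d / (b * c))),
        variance=float(1 / a + 1 / b + 1 / c + 1 / d),
        continuity_corrected=corrected,
    )
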