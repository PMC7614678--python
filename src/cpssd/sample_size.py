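"""Sample size solvers for the average coverage, length and variance criteria.

All three criteria control an average property of the posterior of the
two-group mean difference mu_Delta, averaged over the predictive law of the
yet-unobserved data (a pre-posterior analysis):

* ACC — the fixed-length-l0 HPD interval about the posterior mean must have
  average coverage at least 1 - alpha;
* ALC — the 1 - alpha0 HPD credible interval must have average length at
  most l;
* APVC — the average posterior variance must be at most eps0.

With a known common variance sigma0^2, the ACC (= ALC) and APVC reduce to
closed-form bounds on the effective size n_A n_B/(n_A + n_B):

    e >= (4 z_{alpha/2}^2 / l0^2 - 1/V) sigma0^2        (ACC/ALC)
    e >= (1/eps0 - 1/V) sigma0^2                        (APVC)

where V is the collective prior variance.  With sigma0^2 unknown and
sigma0^2 ~ Inv-Gamma(c/2, cV/2), the ACC and APVC substitute
E[sigma0^2] = cV/(c-2); the ALC has no closed form and is solved by an
integer search on the total size, the expected interval length being
evaluated by quadrature over the variance prior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .posterior import VariancePrior
from .priors import CollectivePrior, CommensuratePriorSpec, HistoricalSummary, collective_prior

__all__ = [
    "CriterionSpec",
    "SampleSizeResult",
    "effective_size",
    "per_group_from_effective",
    "acc_known",
    "alc_known",
    "apvc_known",
    "variance_prior_from_collective",
    "acc_unknown",
    "alc_unknown",
    "apvc_unknown",
    "expected_hpd_length",
    "comparison_modes",
]

_CRITERIA = ("acc", "alc", "apvc")


@dataclass(frozen=True)
class CriterionSpec:
    """Which criterion to control and at what target levels.

    ACC requires ``hpd_length`` (l0) and ``coverage`` (1 - alpha); ALC
    requires ``hpd_length`` (l) and ``coverage`` (1 - alpha0); APVC requires
    ``variance_target`` (eps0).
    """

    criterion: str
    hpd_length: float | None = None
    coverage: float | None = None
    variance_target: float | None = None

    def __post_init__(self) -> None:
        crit = self.criterion.lower()
        object.__setattr__(self, "criterion", crit)
        if crit not in _CRITERIA:
            raise ValueError(f"criterion must be one of {_CRITERIA}, got {crit!r}")
        if crit in ("acc", "alc"):
            if self.hpd_length is None or not self.hpd_length > 0:
                raise ValueError(f"{crit} requires a positive hpd_length")
            if self.coverage is None or not 0.0 < self.coverage < 1.0:
                raise ValueError(f"{crit} requires coverage in (0, 1)")
        else:
            if self.variance_target is None or not self.variance_target > 0:
                raise ValueError("apvc requires a positive variance_target")

    @property
    def z(self) -> float:
        """Standard-normal quantile z_{alpha/2} for the coverage target."""
        if self.coverage is None:
            raise ValueError("no coverage level on an APVC spec")
        return float(stats.norm.ppf(0.5 + self.coverage / 2.0))


@dataclass(frozen=True)
class SampleSizeResult:
    """Solution of a sample-size criterion.

    ``continuous_total`` solves the criterion with equality (0 when the
    prior alone already meets the target, flagged by ``binding``);
    ``integer_total`` is the smallest integer total whose balanced split
    under the allocation ratio satisfies the criterion.  ALC solutions are
    found directly on the integers, and their ``continuous_total`` echoes
    the integer value.
    """

    criterion: str
    continuous_total: float
    continuous_per_group: tuple[float, float]
    integer_total: int
    integer_per_group: tuple[int, int]
    binding: bool
    allocation_ratio: float = 1.0
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "criterion": self.criterion,
            "continuous_total": self.continuous_total,
            "continuous_per_group": list(self.continuous_per_group),
            "integer_total": self.integer_total,
            "integer_per_group": list(self.integer_per_group),
            "binding": self.binding,
            "allocation_ratio": self.allocation_ratio,
            "diagnostics": self.diagnostics,
        }


def effective_size(n_a: float, n_b: float) -> float:
    """n_A n_B / (n_A + n_B); equals N/4 under equal allocation, total N."""
    if not (n_a > 0 and n_b > 0):
        raise ValueError("group sizes must be positive")
    return n_a * n_b / (n_a + n_b)


def per_group_from_effective(e: float, ratio: float = 1.0) -> tuple[float, float]:
    """Invert the effective size for n_B = ratio * n_A.

    Solving e = n_A n_B/(n_A + n_B) with n_B = R n_A gives
    n_A = e (1 + R)/R and n_B = e (1 + R).
    """
    if not e >= 0:
        raise ValueError("effective size must be nonnegative")
    if not ratio > 0:
        raise ValueError("allocation ratio must be positive")
    return e * (1.0 + ratio) / ratio, e * (1.0 + ratio)


def _integer_split(total: int, ratio: float) -> tuple[int, int]:
    """Integer group sizes summing to ``total`` that maximise the effective size.

    The effective size n_A(N - n_A)/N is concave in n_A with maximiser
    N/(1 + R) for n_A; the best integer split is its floor or ceiling.
    """
    target = total / (1.0 + ratio)
    best = None
    for n_a in {math.floor(target), math.ceil(target)}:
        n_a = min(max(n_a, 1), total - 1)
        n_b = total - n_a
        e = effective_size(n_a, n_b)
        if best is None or e > best[0]:
            best = (e, n_a, n_b)
    return best[1], best[2]


def _smallest_integer_total(required_e: float, ratio: float) -> tuple[int, tuple[int, int]]:
    """Smallest integer total whose best split reaches the required effective size."""
    if required_e <= 0:
        return 0, (0, 0)
    n = max(2, math.floor(required_e * (1.0 + ratio) ** 2 / ratio))
    while True:
        n_a, n_b = _integer_split(n, ratio)
        if effective_size(n_a, n_b) >= required_e:
            return n, (n_a, n_b)
        n += 1


def _closed_form_result(
    criterion: str, required_e: float, ratio: float, diagnostics: dict
) -> SampleSizeResult:
    if required_e <= 0:
        return SampleSizeResult(
            criterion=criterion,
            continuous_total=0.0,
            continuous_per_group=(0.0, 0.0),
            integer_total=0,
            integer_per_group=(0, 0),
            binding=True,
            allocation_ratio=ratio,
            diagnostics=diagnostics,
        )
    n_a, n_b = per_group_from_effective(required_e, ratio)
    int_total, int_split = _smallest_integer_total(required_e, ratio)
    return SampleSizeResult(
        criterion=criterion,
        continuous_total=n_a + n_b,
        continuous_per_group=(n_a, n_b),
        integer_total=int_total,
        integer_per_group=int_split,
        binding=False,
        allocation_ratio=ratio,
        diagnostics=diagnostics,
    )


def acc_known(
    prior: CollectivePrior,
    spec: CriterionSpec,
    sigma0_sq: float,
    allocation_ratio: float = 1.0,
) -> SampleSizeResult:
    """ACC solution for known sigma0^2.

    Solves e >= (4 z^2 / l0^2 - 1/V) sigma0^2 for the effective size; the
    prior is binding (zero sample size) when 4 z^2/l0^2 <= 1/V.
    """
    if spec.criterion not in ("acc", "alc"):
        raise ValueError("acc_known requires an ACC (or ALC) criterion spec")
    if not sigma0_sq > 0:
        raise ValueError("sigma0_sq must be positive")
    z = spec.z
    required_e = (4.0 * z**2 / spec.hpd_length**2 - 1.0 / prior.variance) * sigma0_sq
    diag = {
        "prior_variance": prior.variance,
        "sigma0_sq": sigma0_sq,
        "z": z,
        "required_effective_size": required_e,
    }
    return _closed_form_result(spec.criterion, required_e, allocation_ratio, diag)


def alc_known(
    prior: CollectivePrior,
    spec: CriterionSpec,
    sigma0_sq: float,
    allocation_ratio: float = 1.0,
) -> SampleSizeResult:
    """ALC solution for known sigma0^2 — identical to the ACC at (l, alpha0).

    With the variance known, the posterior standard deviation is a fixed
    function of the design, so the credible-interval length is
    deterministic and controlling its average is the same constraint as
    controlling average coverage of a fixed-length interval.
    """
    return acc_known(prior, spec, sigma0_sq, allocation_ratio)


def apvc_known(
    prior: CollectivePrior,
    spec: CriterionSpec,
    sigma0_sq: float,
    allocation_ratio: float = 1.0,
) -> SampleSizeResult:
    """APVC solution for known sigma0^2: e >= (1/eps0 - 1/V) sigma0^2."""
    if spec.criterion != "apvc":
        raise ValueError("apvc_known requires an APVC criterion spec")
    if not sigma0_sq > 0:
        raise ValueError("sigma0_sq must be positive")
    required_e = (1.0 / spec.variance_target - 1.0 / prior.variance) * sigma0_sq
    diag = {
        "prior_variance": prior.variance,
        "sigma0_sq": sigma0_sq,
        "required_effective_size": required_e,
    }
    return _closed_form_result("apvc", required_e, allocation_ratio, diag)


def variance_prior_from_collective(prior: CollectivePrior, c: float) -> VariancePrior:
    """Inverse-gamma prior Inv-Gamma(c/2, cV/2) for the unknown sigma0^2.

    Equivalent to c V / sigma0^2 ~ chi^2(c); E[sigma0^2] = cV/(c-2) for
    c > 2, so large c ties sigma0^2 to the collective prior variance V.
    """
    if not c > 0:
        raise ValueError("degrees of freedom c must be positive")
    return VariancePrior.unknown(c=c, scale=c * prior.variance / 2.0)


def acc_unknown(
    prior: CollectivePrior,
    spec: CriterionSpec,
    vp: VariancePrior,
    allocation_ratio: float = 1.0,
) -> SampleSizeResult:
    """ACC solution for unknown sigma0^2: the known-variance bound at E[sigma0^2]."""
    if vp.mode != "unknown":
        raise ValueError("acc_unknown requires an unknown-mode variance prior")
    e_sigma = vp.mean_sigma0_sq  # raises for c <= 2
    res = acc_known(prior, spec, e_sigma, allocation_ratio)
    diag = dict(res.diagnostics, c=vp.c, expected_sigma0_sq=e_sigma)
    diag.pop("sigma0_sq", None)
    return SampleSizeResult(
        criterion=res.criterion,
        continuous_total=res.continuous_total,
        continuous_per_group=res.continuous_per_group,
        integer_total=res.integer_total,
        integer_per_group=res.integer_per_group,
        binding=res.binding,
        allocation_ratio=allocation_ratio,
        diagnostics=diag,
    )


def apvc_unknown(
    prior: CollectivePrior,
    spec: CriterionSpec,
    vp: VariancePrior,
    allocation_ratio: float = 1.0,
) -> SampleSizeResult:
    """APVC solution for unknown sigma0^2: the known-variance bound at E[sigma0^2]."""
    if vp.mode != "unknown":
        raise ValueError("apvc_unknown requires an unknown-mode variance prior")
    e_sigma = vp.mean_sigma0_sq
    res = apvc_known(prior, spec, e_sigma, allocation_ratio)
    diag = dict(res.diagnostics, c=vp.c, expected_sigma0_sq=e_sigma)
    diag.pop("sigma0_sq", None)
    return SampleSizeResult(
        criterion="apvc",
        continuous_total=res.continuous_total,
        continuous_per_group=res.continuous_per_group,
        integer_total=res.integer_total,
        integer_per_group=res.integer_per_group,
        binding=res.binding,
        allocation_ratio=allocation_ratio,
        diagnostics=diag,
    )


def expected_hpd_length(
    prior_variance: float,
    e: float,
    vp: VariancePrior,
    coverage: float,
) -> float:
    """Average 1-alpha0 HPD length over the variance prior, by quadrature.

    Computes 2 z_{alpha0/2} E[(1/V + e/sigma0^2)^{-1/2}] with
    sigma0^2 ~ Inv-Gamma(c/2, scale).  The expectation is taken on the
    precision scale u = 1/sigma0^2 ~ Gamma(c/2, rate = scale), where the
    integrand (1/V + e u)^{-1/2} is bounded by sqrt(V); integrating over the
    Gamma quantile function keeps the integral on (0, 1) and well behaved
    for every c > 0.
    """
    if vp.mode != "unknown":
        raise ValueError("expected_hpd_length requires an unknown-mode variance prior")
    z = float(stats.norm.ppf(0.5 + coverage / 2.0))
    if e <= 0:
        return 2.0 * z * math.sqrt(prior_variance)
    gam = stats.gamma(vp.c / 2.0, scale=1.0 / vp.scale)

    def integrand(q):
        u = gam.ppf(q)
        return (1.0 / prior_variance + e * u) ** -0.5

    val, _ = integrate.quad(integrand, 0.0, 1.0, epsabs=1e-10, limit=200)
    return 2.0 * z * val


def alc_unknown(
    prior: CollectivePrior,
    spec: CriterionSpec,
    vp: VariancePrior,
    allocation_ratio: float = 1.0,
    *,
    step: int = 1,
    n_max: int = 1_000_000,
) -> SampleSizeResult:
    """ALC solution for unknown sigma0^2 by integer search on the total size.

    Finds the smallest integer total N (multiples of ``step``) whose best
    integer split under the allocation ratio gives an average 1-alpha0 HPD
    length of at most l.  The expected length is strictly decreasing in the
    effective size, so a bisection between a lower bound of 2 and an upper
    bound from the ACC solution (or geometric expansion when c <= 2) finds
    the boundary; the expected lengths at N and N - step are reported.
    """
    if spec.criterion != "alc":
        raise ValueError("alc_unknown requires an ALC criterion spec")
    if vp.mode != "unknown":
        raise ValueError("alc_unknown requires an unknown-mode variance prior")
    if step < 1:
        raise ValueError("step must be a positive integer")
    v = prior.variance
    target = spec.hpd_length

    def length_at(total: int) -> float:
        n_a, n_b = _integer_split(total, allocation_ratio)
        return expected_hpd_length(v, effective_size(n_a, n_b), vp, spec.coverage)

    # prior alone already short enough -> nothing to accrue
    if expected_hpd_length(v, 0.0, vp, spec.coverage) <= target:
        return SampleSizeResult(
            criterion="alc",
            continuous_total=0.0,
            continuous_per_group=(0.0, 0.0),
            integer_total=0,
            integer_per_group=(0, 0),
            binding=True,
            allocation_ratio=allocation_ratio,
            diagnostics={"prior_variance": v, "c": vp.c},
        )

    lo = 2
    if vp.c > 2:
        # ALC <= ACC at matching (l, alpha0) by Jensen's inequality
        acc_spec = CriterionSpec("acc", hpd_length=target, coverage=spec.coverage)
        hi = max(lo + step, acc_unknown(prior, acc_spec, vp, allocation_ratio).integer_total + step)
    else:
        hi = lo + step
    hi = min(hi, n_max)
    while length_at(hi) > target:
        if hi >= n_max:
            raise ArithmeticError(
                f"ALC target {target} unreachable below total {n_max}: "
                f"expected length at {n_max} is {length_at(n_max):.4f}"
            )
        hi = min(hi * 2, n_max)
    if length_at(lo) <= target:
        hi = lo
    # bisect on k where total = step * k: smallest total with length <= target
    lo_k, hi_k = math.ceil(lo / step), math.ceil(hi / step)
    while lo_k < hi_k:
        mid = (lo_k + hi_k) // 2
        if length_at(step * mid) <= target:
            hi_k = mid
        else:
            lo_k = mid + 1
    total = step * hi_k
    n_a, n_b = _integer_split(total, allocation_ratio)
    diag = {
        "prior_variance": v,
        "c": vp.c,
        "expected_length_at_solution": length_at(total),
        "expected_length_below": length_at(total - step) if total - step >= 2 else None,
        "step": step,
    }
    return SampleSizeResult(
        criterion="alc",
        continuous_total=float(total),
        continuous_per_group=(float(n_a), float(n_b)),
        integer_total=total,
        integer_per_group=(n_a, n_b),
        binding=False,
        allocation_ratio=allocation_ratio,
        diagnostics=diag,
    )


_OPTIMAL_C = 1e6  # large prior dof: sigma0^2 essentially pinned at V


def _solve(
    prior: CollectivePrior,
    spec: CriterionSpec,
    vp: VariancePrior,
    ratio: float,
) -> SampleSizeResult:
    if vp.mode == "known":
        fn = {"acc": acc_known, "alc": alc_known, "apvc": apvc_known}[spec.criterion]
        return fn(prior, spec, vp.sigma0_sq, ratio)
    fn = {"acc": acc_unknown, "alc": alc_unknown, "apvc": apvc_unknown}[spec.criterion]
    return fn(prior, spec, vp, ratio)


def comparison_modes(
    sources: list[HistoricalSummary],
    prior_spec: CommensuratePriorSpec,
    criterion: CriterionSpec,
    *,
    variance: str = "known",
    sigma0_sq: float | None = None,
    c: float | None = None,
    allocation_ratio: float = 1.0,
    modes: tuple[str, ...] = (
        "robust",
        "no_robustification",
        "no_borrowing",
        "single_source",
        "optimal",
    ),
) -> pd.DataFrame:
    """Sample sizes under the comparison strategies for borrowing.

    Modes: ``robust`` uses the elicited w_k; ``no_robustification`` sets all
    w_k = 0 (full borrowing through the precise Gamma component);
    ``no_borrowing`` sets all w_k = 1 (equal p_k, maximal inflation);
    ``single_source`` uses the most informative N(m_k, s_k^2) directly as
    the prior; ``optimal`` is the perfectly-commensurate benchmark with
    sigma0^2 equated to the collective prior variance (known case) or a
    variance prior with very large c (unknown case).
    """
    if variance not in ("known", "unknown"):
        raise ValueError("variance must be 'known' or 'unknown'")
    if variance == "known" and (sigma0_sq is None or not sigma0_sq > 0):
        raise ValueError("known variance requires sigma0_sq > 0")
    if variance == "unknown" and (c is None or not c > 0):
        raise ValueError("unknown variance requires degrees of freedom c")

    rows = []
    for mode in modes:
        if mode == "robust":
            prior = collective_prior(sources, prior_spec)
        elif mode == "no_robustification":
            prior = collective_prior(
                [HistoricalSummary(s.mean, s.variance, 0.0, s.label) for s in sources],
                prior_spec,
            )
        elif mode == "no_borrowing":
            prior = collective_prior(
                [HistoricalSummary(s.mean, s.variance, 1.0, s.label) for s in sources],
                prior_spec,
            )
        elif mode == "single_source":
            best = min(sources, key=lambda s: s.variance)
            prior = CollectivePrior(
                mean=best.mean,
                variance=best.variance,
                components=((1.0, best.mean, best.variance),),
            )
        elif mode == "optimal":
            prior = collective_prior(sources, prior_spec)
        else:
            raise ValueError(f"unknown comparison mode {mode!r}")

        if variance == "known":
            sig = prior.variance if mode == "optimal" else sigma0_sq
            vp = VariancePrior.known(sig)
        else:
            vp = variance_prior_from_collective(
                prior, _OPTIMAL_C if mode == "optimal" else c
            )
        res = _solve(prior, criterion, vp, allocation_ratio)
        rows.append(
            {
                "mode": mode,
                "criterion": criterion.criterion,
                "prior_mean": prior.mean,
                "prior_variance": prior.variance,
                "continuous_total": res.continuous_total,
                "integer_total": res.integer_total,
                "binding": res.binding,
            }
        )
    return pd.DataFrame(rows)
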