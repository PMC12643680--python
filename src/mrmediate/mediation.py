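"""Product-of-coefficients mediation with delta-method uncertainty.

For a pathway exposure → mediator → outcome with total effect β₀ (log-odds
per SD), exposure→mediator effect β₁ (SD per SD) and mediator→outcome effect
β₂ (log-odds per SD):

    indirect (mediated) effect = β₁·β₂
    direct effect              = β₀ − β₁·β₂
    mediation proportion       = β₁·β₂ / β₀

The first-order (Sobel) delta variance of the product is
β₂²·se₁² + β₁²·se₂² (an exact second-order term + se₁²·se₂² is available by
flag); a seeded Monte-Carlo alternative draws the coefficients from their
sampling normals and reads percentile intervals, approximating
distribution-of-the-product intervals.  When the indirect and total effects
have opposite signs the mediation is inconsistent and no proportion is
reported (the mediated effect and its CI still are).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .mr_core import Z95, DEFAULT_SEED


class UndefinedProportionError(ZeroDivisionError):
    """Mediation proportion is undefined for a zero total effect."""


@dataclass(frozen=True)
class MediationInput:
    """The three pathway coefficients with (optional) standard errors.

    SEs may be omitted (None) when only point arithmetic is wanted, e.g. when
    reproducing a published coefficient table that prints no SEs; operations
    that need them raise.  Supplied SEs must be positive.
    """

    beta0: float
    beta1: float
    beta2: float
    se0: float | None = None
    se1: float | None = None
    se2: float | None = None

    def __post_init__(self) -> None:
        for name in ("se0", "se1", "se2"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be positive when supplied")

    def _need(self, *names: str) -> None:
        missing = [n for n in names if getattr(self, n) is None]
        if missing:
            raise ValueError(f"operation requires standard errors: {missing}")

    @classmethod
    def from_or(cls, or0: float, beta1: float, beta2: float,
                se0: float | None = None, se1: float | None = None,
                se2: float | None = None) -> "MediationInput":
        """Build from a total-effect odds ratio: β₀ = ln(OR)."""
        if or0 <= 0:
            raise ValueError("odds ratio must be positive")
        return cls(beta0=float(np.log(or0)), beta1=beta1, beta2=beta2,
                   se0=se0, se1=se1, se2=se2)


@dataclass
class MediationResult:
    """Full decomposition for one pathway (Table-style row)."""

    beta0: float
    beta1: float
    beta2: float
    indirect: float
    direct: float
    consistent: bool
    proportion: float | None = None
    indirect_se: float | None = None
    indirect_ci: tuple[float, float] | None = None
    proportion_ci: tuple[float, float] | None = None
    pval: float | None = None


def indirect_effect(inp: MediationInput) -> float:
    """Point mediated effect β₁·β₂ (no SEs needed)."""
    return inp.beta1 * inp.beta2


def direct_effect(inp: MediationInput) -> float:
    """Point direct effect β₀ − β₁·β₂ (no SEs needed)."""
    return inp.beta0 - inp.beta1 * inp.beta2


def mediation_effect(inp: MediationInput, second_order: bool = False
                     ) -> tuple[float, float, tuple[float, float]]:
    """Mediated effect with delta-method SE and 95% CI.

    First-order (Sobel) variance β₂²se₁² + β₁²se₂² by default; with
    ``second_order`` the exact product-variance term se₁²se₂² is added.
    """
    inp._need("se1", "se2")
    ind = indirect_effect(inp)
    var = inp.beta2**2 * inp.se1**2 + inp.beta1**2 * inp.se2**2
    if second_order:
        var += inp.se1**2 * inp.se2**2
    se = float(np.sqrt(var))
    return ind, se, (ind - Z95 * se, ind + Z95 * se)


def mediation_effect_mc(inp: MediationInput, n_draws: int = 500_000,
                        seed: int = DEFAULT_SEED
                        ) -> tuple[float, tuple[float, float]]:
    """Monte-Carlo percentile 95% CI for β₁·β₂ (product-distribution style)."""
    inp._need("se1", "se2")
    rng = np.random.default_rng(seed)
    prod = (rng.normal(inp.beta1, inp.se1, n_draws)
            * rng.normal(inp.beta2, inp.se2, n_draws))
    lo, hi = np.quantile(prod, [0.025, 0.975])
    return indirect_effect(inp), (float(lo), float(hi))


def is_consistent(inp: MediationInput) -> bool:
    """Consistent mediation: indirect and total effects share a sign."""
    return bool(np.sign(indirect_effect(inp)) == np.sign(inp.beta0))


def mediation_proportion(inp: MediationInput, mc: bool = False,
                         n_draws: int = 100_000, seed: int = DEFAULT_SEED
                         ) -> tuple[float | None,
                                    tuple[float, float] | None, bool]:
    """Mediation proportion β₁·β₂/β₀ with delta-method CI.

    Returns (proportion, CI, consistent).  With inconsistent mediation
    (opposite signs) the proportion and its CI are None — the decomposition
    still holds but the share is uninterpretable.  The delta CI uses the
    gradient (−β₁β₂/β₀², β₂/β₀, β₁/β₀); ``mc`` switches to a seeded
    Monte-Carlo percentile interval over normal draws of the three betas.
    """
    if inp.beta0 == 0:
        raise UndefinedProportionError("total effect beta0 is zero")
    consistent = is_consistent(inp)
    if not consistent:
        return None, None, False
    prop = indirect_effect(inp) / inp.beta0
    if inp.se0 is None or inp.se1 is None or inp.se2 is None:
        return float(prop), None, True
    if mc:
        rng = np.random.default_rng(seed)
        b0 = rng.normal(inp.beta0, inp.se0, n_draws)
        b0 = b0[b0 != 0]
        draws = (rng.normal(inp.beta1, inp.se1, len(b0))
                 * rng.normal(inp.beta2, inp.se2, len(b0))) / b0
        lo, hi = np.quantile(draws, [0.025, 0.975])
    else:
        g = np.array([-indirect_effect(inp) / inp.beta0**2,
                      inp.beta2 / inp.beta0, inp.beta1 / inp.beta0])
        var = float(g @ (np.array([inp.se0, inp.se1, inp.se2]) ** 2 * g))
        se = np.sqrt(var)
        lo, hi = prop - Z95 * se, prop + Z95 * se
    return float(prop), (float(lo), float(hi)), True


def mediation_pvalue(inp: MediationInput) -> float:
    """Sobel-type two-sided normal p for the mediated effect."""
    ind, se, _ = mediation_effect(inp)
    if ind == 0:
        return 1.0
    return float(2 * stats.norm.sf(abs(ind) / se))


def mediate(inp: MediationInput, second_order: bool = False) -> MediationResult:
    """Full decomposition; uncertainty fields filled when SEs are supplied."""
    ind = indirect_effect(inp)
    res = MediationResult(beta0=inp.beta0, beta1=inp.beta1, beta2=inp.beta2,
                          indirect=ind, direct=direct_effect(inp),
                          consistent=is_consistent(inp))
    if inp.beta0 != 0:
        prop, ci, cons = mediation_proportion(inp)
        res.proportion, res.proportion_ci = prop, ci
    if inp.se1 is not None and inp.se2 is not None:
        _, res.indirect_se, res.indirect_ci = mediation_effect(
            inp, second_order=second_order)
        res.pval = mediation_pvalue(inp)
    return res
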