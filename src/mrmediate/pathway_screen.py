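"""Three-leg pathway screening and candidate assembly.

A candidate pathway exposure → mediator → outcome requires significant
exposure→outcome, exposure→mediator and mediator→outcome legs (primary IVW
p below the screening alpha; optionally Benjamini–Hochberg adjusted) and a
non-significant reverse outcome→exposure leg.  Mediation is then computed
for each candidate from the three primary leg estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from .summary_io import AssociationTable, NoOverlapError, harmonize
from .iv_selection import LDMatrix, SelectionParams, PRESETS, select_instruments
from .mr_core import MREstimate, MRSettings, ivw, run_all_methods
from .sensitivity import (SensitivityReport, choose_ivw_model, cochran_q,
                          drop_outliers, sensitivity_report)
from .mediation import MediationInput, MediationResult, mediate

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LegSettings:
    """Knobs shared by every leg of a screen."""

    mr: MRSettings = MRSettings()
    presso_n_sim: int = 1000
    run_presso: bool = True
    significance: float = 0.05
    reverse: bool = True
    reverse_params: SelectionParams = PRESETS["cytokine_outcome"]
    palindrome_eaf_window: float = 0.08


@dataclass
class LegResult:
    """MR results for one exposure→outcome direction."""

    exposure_name: str
    outcome_name: str
    estimable: bool
    estimates: list[MREstimate] = field(default_factory=list)
    primary: MREstimate | None = None
    sensitivity: SensitivityReport | None = None
    corrected_estimates: list[MREstimate] | None = None  # outlier-free refit
    reverse_pval: float | None = None
    pval_adj: float | None = None
    egger_flag: bool = False  # intercept test fired; downgrade, not exclude
    note: str = ""

    @property
    def primary_pval(self) -> float | None:
        return self.primary.pval if self.primary is not None else None


@dataclass
class CandidatePathway:
    """A screened exposure→mediator→outcome triple with its mediation."""

    exposure: str
    mediator: str
    outcome: str
    leg_xo: LegResult
    leg_xm: LegResult
    leg_mo: LegResult
    mediation: MediationResult


def _ivw_pval(exposure: AssociationTable, outcome: AssociationTable,
              ld: LDMatrix | None, params: SelectionParams,
              settings: LegSettings) -> float | None:
    """Primary-method p-value of a bare leg (used for the reverse direction)."""
    instruments = select_instruments(exposure, ld, params)
    if len(instruments) < 2:
        return None
    sub = exposure.subset(instruments["snp"])
    try:
        h = harmonize(sub, outcome, settings.palindrome_eaf_window)
    except NoOverlapError:
        return None
    if h.n_retained < 2:
        return None
    _, _, q_pval = cochran_q(h)
    return ivw(h, choose_ivw_model(q_pval)).pval


def run_leg(exposure: AssociationTable, outcome: AssociationTable,
            params: SelectionParams, settings: LegSettings = LegSettings(),
            ld: LDMatrix | None = None) -> LegResult:
    """Full MR analysis of one leg.

    Pipeline: select instruments from the exposure GWAS, harmonize against
    the outcome, run the method battery with the IVW model chosen by the
    heterogeneity rule, run the sensitivity suite, and record the reverse
    (outcome→exposure) IVW p-value under the outcome-preset thresholds.
    When MR-PRESSO's global test fires and flags outliers, all methods are
    re-run on the outlier-free set; the corrected primary estimate is
    reported as primary and the uncorrected fit kept alongside.  A leg with
    fewer than two surviving instruments is marked non-estimable (a single
    instrument still yields a non-primary Wald ratio).
    """
    result = LegResult(exposure.trait_name, outcome.trait_name, estimable=False)

    instruments = select_instruments(exposure, ld, params)
    if len(instruments) == 0:
        result.note = "no instruments survive selection"
        return result
    sub = exposure.subset(instruments["snp"])
    try:
        h = harmonize(sub, outcome, settings.palindrome_eaf_window)
    except NoOverlapError:
        result.note = "no instrument overlaps the outcome GWAS"
        return result
    if h.n_retained == 0:
        result.note = "all shared instruments dropped in harmonization"
        return result

    result.estimates = run_all_methods(h, settings.mr)
    if h.n_retained == 1:
        result.note = "single instrument: Wald ratio only, non-primary"
        return result
    result.estimable = True
    result.primary = next(e for e in result.estimates if e.is_primary)

    result.sensitivity = sensitivity_report(
        h, n_sim=settings.presso_n_sim, seed=settings.mr.seed,
        significance=settings.significance, run_presso=settings.run_presso)
    sens = result.sensitivity
    if (sens.egger_intercept_pval is not None
            and sens.egger_intercept_pval < settings.significance):
        result.egger_flag = True
    if (sens.presso_global_pval is not None
            and sens.presso_global_pval < settings.significance
            and sens.presso_outliers
            and h.n_retained - len(sens.presso_outliers) >= 2):
        h_corr = drop_outliers(h, sens.presso_outliers)
        result.corrected_estimates = run_all_methods(h_corr, settings.mr)
        result.primary = next(e for e in result.corrected_estimates
                              if e.is_primary)
        result.note = (f"MR-PRESSO removed {len(sens.presso_outliers)} "
                       "outlier(s); corrected fit is primary")

    if settings.reverse:
        result.reverse_pval = _ivw_pval(outcome, exposure, ld,
                                        settings.reverse_params, settings)
    return result


def adjust_pvalues(pvals, method: str = "fdr_bh") -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, order-preserving."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    if ((pvals <= 0) | (pvals > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(pvals, method=method)[1]


def attach_bh(legs: list[LegResult]) -> None:
    """Fill ``pval_adj`` across one family of legs (in place).

    The family convention is all exposures against one (outcome, leg-type);
    callers group legs accordingly before calling.
    """
    est = [leg for leg in legs if leg.primary is not None]
    if not est:
        return
    adj = adjust_pvalues([leg.primary.pval for leg in est])
    for leg, p in zip(est, adj):
        leg.pval_adj = float(p)


@dataclass(frozen=True)
class ScreenRule:
    """Candidate rule: per-leg alpha and reverse-direction exclusion."""

    alpha: float = 0.05
    use_adjusted: bool = False
    reverse_alpha: float = 0.05


def _leg_passes(leg: LegResult | None, rule: ScreenRule) -> bool:
    if leg is None or not leg.estimable:
        return False
    p = leg.pval_adj if rule.use_adjusted else leg.primary.pval
    return p is not None and p < rule.alpha


def assemble_pathways(legs_xo: list[LegResult], legs_xm: list[LegResult],
                      legs_mo: list[LegResult],
                      rule: ScreenRule = ScreenRule(),
                      return_exclusions: bool = False):
    """Assemble candidate pathways from the three leg collections.

    A triple (X, M, Y) is a candidate iff legs X→Y, X→M and M→Y all pass the
    rule and the reverse Y→X direction is not significant (reverse p ≥
    ``rule.reverse_alpha``; an inestimable reverse leg does not exclude).
    Mediation is computed from the three primary betas and SEs.  Output
    order follows sorted (X, M, Y) labels, independent of input ordering.
    """
    if rule.use_adjusted:
        for legs in (legs_xo, legs_xm, legs_mo):
            for leg in legs:
                if leg.pval_adj is None and leg.primary is not None:
                    raise ValueError(
                        "use_adjusted requires attach_bh on every leg family")
    xo = {(l.exposure_name, l.outcome_name): l for l in legs_xo}
    xm = {(l.exposure_name, l.outcome_name): l for l in legs_xm}
    mo = {(l.exposure_name, l.outcome_name): l for l in legs_mo}
    exposures = sorted({x for x, _ in xo} | {x for x, _ in xm})
    mediators = sorted({m for m, _ in mo} | {m for _, m in xm})
    outcomes = sorted({y for _, y in xo} | {y for _, y in mo})

    candidates: list[CandidatePathway] = []
    exclusions: list[tuple[tuple[str, str, str], str]] = []
    for x in exposures:
        for m_ in mediators:
            for y in outcomes:
                l_xo, l_xm, l_mo = xo.get((x, y)), xm.get((x, m_)), mo.get((m_, y))
                if not (_leg_passes(l_xo, rule) and _leg_passes(l_xm, rule)
                        and _leg_passes(l_mo, rule)):
                    continue
                if (l_xo.reverse_pval is not None
                        and l_xo.reverse_pval < rule.reverse_alpha):
                    exclusions.append(
                        ((x, m_, y),
                         f"reverse {y}->{x} leg significant "
                         f"(p={l_xo.reverse_pval:.3g})"))
                    logger.info("excluded pathway %s->%s->%s: reverse leg "
                                "p=%.3g", x, m_, y, l_xo.reverse_pval)
                    continue
                inp = MediationInput(
                    beta0=l_xo.primary.beta, se0=l_xo.primary.se,
                    beta1=l_xm.primary.beta, se1=l_xm.primary.se,
                    beta2=l_mo.primary.beta, se2=l_mo.primary.se)
                candidates.append(CandidatePathway(
                    exposure=x, mediator=m_, outcome=y,
                    leg_xo=l_xo, leg_xm=l_xm, leg_mo=l_mo,
                    mediation=mediate(inp)))
    if return_exclusions:
        return candidates, exclusions
    return candidates


@dataclass
class ScreenResult:
    legs_xo: list[LegResult]
    legs_xm: list[LegResult]
    legs_mo: list[LegResult]
    candidates: list[CandidatePathway]
    exclusions: list[tuple[tuple[str, str, str], str]]


def run_screen(exposures: dict[str, AssociationTable],
               mediators: dict[str, AssociationTable],
               outcomes: dict[str, AssociationTable],
               exposure_params: SelectionParams = PRESETS["immune"],
               mediator_params: SelectionParams = PRESETS["cytokine_outcome"],
               settings: LegSettings = LegSettings(),
               rule: ScreenRule = ScreenRule(),
               ld: LDMatrix | None = None) -> ScreenResult:
    """Run every leg of an exposure × mediator × outcome grid and assemble.

    Exposure-origin legs use ``exposure_params`` for instrument selection;
    mediator-origin legs use ``mediator_params``.  BH adjustment is attached
    within each (outcome, leg-type) family across exposures.
    """
    legs_xo = [run_leg(ex, out, exposure_params, settings, ld)
               for ex in exposures.values() for out in outcomes.values()]
    legs_xm = [run_leg(ex, med, exposure_params, settings, ld)
               for ex in exposures.values() for med in mediators.values()]
    legs_mo = [run_leg(med, out, mediator_params, settings, ld)
               for med in mediators.values() for out in outcomes.values()]
    for legs, key in ((legs_xo, 1), (legs_xm, 1), (legs_mo, 1)):
        by_outcome: dict[str, list[LegResult]] = {}
        for leg in legs:
            by_outcome.setdefault(leg.outcome_name, []).append(leg)
        for fam in by_outcome.values():
            attach_bh(fam)
    candidates, exclusions = assemble_pathways(
        legs_xo, legs_xm, legs_mo, rule, return_exclusions=True)
    return ScreenResult(legs_xo, legs_xm, legs_mo, candidates, exclusions)
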