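"""Heterogeneity and pleiotropy diagnostics.

Three diagnostics gate the MR pipeline: Cochran's Q (heterogeneity of the
per-variant ratios; p < 0.05 switches the primary IVW model to multiplicative
random effects), the Egger intercept test (directional pleiotropy), and
MR-PRESSO (simulation-based global pleiotropy test with per-variant outlier
flagging and a distortion test for the effect of removing flagged outliers).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .summary_io import HarmonizedSet, harmonized_from_arrays
from . import mr_core
from .mr_core import InsufficientInstrumentsError

HETEROGENEITY_ALPHA = 0.05


def cochran_q(h: HarmonizedSet) -> tuple[float, int, float]:
    """Cochran's Q about the fixed-effects IVW slope.

    Q = Σ wⱼ(ratioⱼ − β_ivw)² with first-order ratio weights wⱼ = bxⱼ²/syⱼ²;
    the reference distribution is chi-square with J − 1 df.
    """
    bx, _, by, sy = h.arrays()
    if len(bx) < 2:
        raise InsufficientInstrumentsError("cochran_q needs >= 2 instruments")
    q = mr_core.cochran_q_value(bx, by, sy)
    df = len(bx) - 1
    return q, df, float(stats.chi2.sf(q, df))


def choose_ivw_model(q_pval: float) -> str:
    """Heterogeneity rule: multiplicative random effects iff Q p < 0.05.

    The boundary p = 0.05 itself keeps fixed effects (strict inequality).
    """
    if not (0 <= q_pval <= 1):
        raise ValueError("q_pval must lie in [0, 1]")
    return "multiplicative_random" if q_pval < HETEROGENEITY_ALPHA else "fixed"


def egger_intercept_test(h: HarmonizedSet) -> tuple[float, float, float]:
    """(intercept, SE, two-sided t p-value with J−2 df) from the Egger fit."""
    est = mr_core.mr_egger(h)
    return est.intercept, est.intercept_se, est.intercept_pval


@dataclass
class PressoResult:
    """MR-PRESSO global, outlier and distortion results."""

    rss_obs: float
    global_pval: float
    outlier_pvals: dict[str, float]  # Bonferroni-adjusted, per SNP
    outliers: list[str]
    distortion_pval: float | None
    n_sim: int
    seed: int


def _loo_slopes(bx, by, w):
    """Leave-one-out IVW slopes, vectorized over the left-out index."""
    sxy, sxx = np.sum(w * bx * by), np.sum(w * bx**2)
    return (sxy - w * bx * by) / (sxx - w * bx**2)


def _rss_terms(bx, by, w):
    """Per-variant weighted squared residuals about the LOO expected values."""
    return w * (by - _loo_slopes(bx, by, w) * bx) ** 2


def mr_presso(h: HarmonizedSet, n_sim: int = 1000,
              seed: int = mr_core.DEFAULT_SEED,
              significance: float = 0.05) -> PressoResult:
    """MR pleiotropy residual sum and outlier test.

    The observed residual sum of squares uses leave-one-out IVW expected
    values.  ``n_sim`` parametric draws of the outcome effects under the
    no-pleiotropy model give the null distribution; the global p-value is
    (1 + #{RSS_sim ≥ RSS_obs}) / (n_sim + 1).  Per-variant squared residuals
    are compared to their own simulated distributions (Bonferroni-adjusted);
    variants below ``significance`` are flagged.  When outliers are found, a
    distortion test compares the all-variant vs outlier-free IVW difference
    to the distribution over random outlier-sized removals.
    """
    bx, _, by, sy = h.arrays()
    snps = h.retained["snp"].to_numpy()
    J = len(bx)
    if J < 4:
        raise InsufficientInstrumentsError("mr_presso needs >= 4 instruments")
    rng = np.random.default_rng(seed)
    w = 1.0 / sy**2

    loo = _loo_slopes(bx, by, w)
    obs_terms = _rss_terms(bx, by, w)
    rss_obs = float(obs_terms.sum())

    # parametric simulations under the no-pleiotropy LOO model
    by_sim = rng.normal(loo * bx, sy, size=(n_sim, J))
    sxy_sim = by_sim @ (w * bx)
    sxx = np.sum(w * bx**2)
    loo_sim = (sxy_sim[:, None] - (w * bx) * by_sim) / (sxx - w * bx**2)
    sim_terms = w * (by_sim - loo_sim * bx) ** 2
    rss_sim = sim_terms.sum(axis=1)

    global_pval = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))

    raw_p = (1 + np.sum(sim_terms >= obs_terms, axis=0)) / (n_sim + 1)
    adj_p = np.minimum(raw_p * J, 1.0)
    outliers = [str(s) for s, p in zip(snps, adj_p) if p < significance]
    outlier_pvals = {str(s): float(p) for s, p in zip(snps, adj_p)}

    distortion_pval = None
    if outliers and len(outliers) < J - 1:
        keep = ~np.isin(snps, outliers)
        b_all = np.sum(w * bx * by) / sxx
        b_out = (np.sum(w[keep] * bx[keep] * by[keep])
                 / np.sum(w[keep] * bx[keep] ** 2))
        d_obs = b_all - b_out
        k = len(outliers)
        d_perm = np.empty(n_sim)
        for t in range(n_sim):
            drop = rng.choice(J, size=k, replace=False)
            m = np.ones(J, dtype=bool)
            m[drop] = False
            d_perm[t] = b_all - (np.sum(w[m] * bx[m] * by[m])
                                 / np.sum(w[m] * bx[m] ** 2))
        distortion_pval = float(
            (1 + np.sum(np.abs(d_perm) >= abs(d_obs))) / (n_sim + 1))

    return PressoResult(rss_obs=rss_obs, global_pval=global_pval,
                        outlier_pvals=outlier_pvals, outliers=outliers,
                        distortion_pval=distortion_pval, n_sim=n_sim,
                        seed=seed)


@dataclass
class SensitivityReport:
    """Bundle of the three diagnostics for one exposure–outcome leg."""

    q_stat: float
    q_df: int
    q_pval: float
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_pval: float | None = None
    presso_global_pval: float | None = None
    presso_outliers: list[str] = field(default_factory=list)
    presso_distortion_pval: float | None = None
    n_sim: int | None = None
    seed: int | None = None


def sensitivity_report(h: HarmonizedSet, n_sim: int = 1000,
                       seed: int = mr_core.DEFAULT_SEED,
                       significance: float = 0.05,
                       run_presso: bool = True) -> SensitivityReport:
    """Run every diagnostic whose minimum instrument count is met."""
    q, df, q_p = cochran_q(h)
    report = SensitivityReport(q_stat=q, q_df=df, q_pval=q_p)
    if h.n_retained >= 3:
        report.egger_intercept, report.egger_intercept_se, \
            report.egger_intercept_pval = egger_intercept_test(h)
    if run_presso and h.n_retained >= 4:
        presso = mr_presso(h, n_sim=n_sim, seed=seed,
                           significance=significance)
        report.presso_global_pval = presso.global_pval
        report.presso_outliers = presso.outliers
        report.presso_distortion_pval = presso.distortion_pval
        report.n_sim = n_sim
        report.seed = seed
    return report


def drop_outliers(h: HarmonizedSet, outliers: list[str]) -> HarmonizedSet:
    """Harmonized set with the flagged variants removed."""
    r = h.retained
    keep = ~r["snp"].isin(set(outliers))
    sub = r.loc[keep]
    return harmonized_from_arrays(
        sub["beta_exp"].to_numpy(), sub["se_exp"].to_numpy(),
        sub["beta_out"].to_numpy(), sub["se_out"].to_numpy(),
        snp_ids=sub["snp"].tolist(),
        exposure_name=h.exposure_name, outcome_name=h.outcome_name)
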