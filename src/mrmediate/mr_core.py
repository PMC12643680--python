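"""Two-sample MR estimators on harmonized summary statistics.

Six methods are provided: inverse-variance-weighted meta-analysis under
fixed and multiplicative-random-effects error models, MR-Egger regression,
the weighted median, and the simple and weighted mode estimators, plus the
single-variant Wald ratio used when only one instrument survives.  All causal
effects are per SD of the exposure; odds ratios are exp(beta).

IVW is computed as a weighted regression of outcome on exposure effects
through the origin with weights 1/se_out² — algebraically the inverse-variance
weighted mean of per-variant Wald ratios with first-order weights.  The
multiplicative-random-effects SE inflates the fixed SE by
max(1, sqrt(Q/(J−1))) where Q is Cochran's heterogeneity statistic.  Egger
adds an intercept (its deviation from zero measures directional pleiotropy)
and uses a t reference with J−2 degrees of freedom.  Median and mode SEs come
from a seeded parametric bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .summary_io import HarmonizedSet

Z95 = float(stats.norm.ppf(0.975))

DEFAULT_SEED = 20240101
DEFAULT_N_BOOT = 1000

#: minimum number of instruments per method
MIN_INSTRUMENTS = {
    "wald_ratio": 1,
    "ivw_fe": 2,
    "ivw_mre": 2,
    "weighted_median": 2,
    "simple_mode": 2,
    "weighted_mode": 2,
    "egger": 3,
}


class InsufficientInstrumentsError(ValueError):
    pass


@dataclass
class MREstimate:
    """One method's causal estimate (per-SD scale, with OR transform)."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    or_: float
    or_ci_low: float
    or_ci_high: float
    n_snp: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pval: float | None = None
    is_primary: bool = False


def _estimate(method: str, beta: float, se: float, n_snp: int,
              t_df: int | None = None, **kw) -> MREstimate:
    """Assemble an MREstimate with CI and p from a normal or t reference."""
    if t_df is not None:
        crit = float(stats.t.ppf(0.975, t_df))
        pval = float(2 * stats.t.sf(abs(beta / se), t_df)) if se > 0 else (
            1.0 if beta == 0 else 0.0)
    else:
        crit = Z95
        pval = float(2 * stats.norm.sf(abs(beta / se))) if se > 0 else (
            1.0 if beta == 0 else 0.0)
    lo, hi = beta - crit * se, beta + crit * se
    return MREstimate(method=method, beta=float(beta), se=float(se),
                      ci_low=lo, ci_high=hi, pval=pval,
                      or_=float(np.exp(beta)), or_ci_low=float(np.exp(lo)),
                      or_ci_high=float(np.exp(hi)), n_snp=int(n_snp), **kw)


def _require(h: HarmonizedSet, k: int, method: str):
    bx, sx, by, sy = h.arrays()
    if len(bx) < k:
        raise InsufficientInstrumentsError(
            f"{method} needs >= {k} instruments, got {len(bx)}")
    return bx, sx, by, sy


def wald_ratio(h: HarmonizedSet) -> MREstimate:
    """Single-instrument causal estimate beta_out/beta_exp (first-order SE)."""
    bx, _, by, sy = _require(h, 1, "wald_ratio")
    if bx[0] == 0:
        raise ZeroDivisionError("wald_ratio undefined for beta_exp = 0")
    return _estimate("wald_ratio", by[0] / bx[0], sy[0] / abs(bx[0]), 1)


def cochran_q_value(bx, by, sy) -> float:
    """Cochran's Q about the fixed-effects IVW slope (first-order weights)."""
    w = 1.0 / sy**2
    slope = np.sum(w * bx * by) / np.sum(w * bx**2)
    return float(np.sum(w * (by - slope * bx) ** 2))


def ivw(h: HarmonizedSet, model: str = "fixed") -> MREstimate:
    """Inverse-variance-weighted estimate (regression through the origin).

    ``model`` is "fixed" or "multiplicative_random"; the latter scales the SE
    by max(1, sqrt(Q/(J−1))), never shrinking below the fixed-effects SE.
    """
    if model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown IVW model {model!r}")
    bx, _, by, sy = _require(h, 2, "ivw")
    w = 1.0 / sy**2
    sww = np.sum(w * bx**2)
    beta = float(np.sum(w * bx * by) / sww)
    se = float(sww**-0.5)
    name = "ivw_fe"
    if model == "multiplicative_random":
        q = cochran_q_value(bx, by, sy)
        se *= max(1.0, np.sqrt(q / (len(bx) - 1)))
        name = "ivw_mre"
    return _estimate(name, beta, se, len(bx))


def mr_egger(h: HarmonizedSet) -> MREstimate:
    """MR-Egger: WLS of beta_out on beta_exp with intercept, weights 1/se_out².

    Exposure effects are first oriented non-negative (flipping each pair's
    signs jointly), so the intercept estimates the average directional
    pleiotropic effect.  Slope and intercept use a t reference with J−2 df
    and the estimated residual scale.
    """
    bx, _, by, sy = _require(h, 3, "egger")
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    if np.ptp(bx) == 0:
        raise ValueError("degenerate design: no variation in exposure betas")
    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=1.0 / sy**2).fit()
    inter, slope = fit.params
    inter_se, slope_se = fit.bse
    df_resid = len(bx) - 2
    inter_p = float(2 * stats.t.sf(abs(inter / inter_se), df_resid))
    return _estimate("egger", slope, slope_se, len(bx), t_df=df_resid,
                     intercept=float(inter), intercept_se=float(inter_se),
                     intercept_pval=inter_p)


def _weighted_median_value(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weighted-median percentile rule with linear interpolation at p = 0.5."""
    order = np.argsort(ratios, kind="stable")
    r, w = ratios[order], weights[order]
    w = w / w.sum()
    s = np.cumsum(w)
    p = s - w / 2
    return float(np.interp(0.5, p, r))


def _bootstrap_se(h: HarmonizedSet, statistic, n_boot: int, seed: int) -> float:
    """Parametric-bootstrap SE: redraw effects from their sampling normals."""
    bx, sx, by, sy = h.arrays()
    rng = np.random.default_rng(seed)
    J = len(bx)
    bxs = rng.normal(bx, sx, size=(n_boot, J))
    bys = rng.normal(by, sy, size=(n_boot, J))
    vals = np.array([statistic(bxs[b], bys[b], sy) for b in range(n_boot)])
    return float(np.std(vals, ddof=1))


def weighted_median(h: HarmonizedSet, n_boot: int = DEFAULT_N_BOOT,
                    seed: int = DEFAULT_SEED) -> MREstimate:
    """Weighted median of per-variant Wald ratios.

    Weights are inverse first-order ratio variances (beta_exp²/se_out²); the
    estimate is consistent when variants contributing at least half the
    weight are valid instruments.  SE from a seeded parametric bootstrap.
    """
    bx, _, by, sy = _require(h, 2, "weighted_median")

    def stat(bx_, by_, sy_):
        ok = bx_ != 0
        return _weighted_median_value(by_[ok] / bx_[ok],
                                      bx_[ok] ** 2 / sy_[ok] ** 2)

    beta = stat(bx, by, sy)
    se = _bootstrap_se(h, stat, n_boot, seed)
    return _estimate("weighted_median", beta, se, len(bx))


def _kde_mode(ratios: np.ndarray, weights: np.ndarray,
              bandwidth_factor: float, n_grid: int = 512) -> float:
    """Mode of a weighted normal-kernel density over the Wald ratios.

    Bandwidth is a modified Silverman rule on the ratios,
    0.9·min(sd, mad)·J^(−1/5), scaled by ``bandwidth_factor``.
    """
    sd = np.std(ratios, ddof=1) if len(ratios) > 1 else 0.0
    mad = stats.median_abs_deviation(ratios, scale="normal")
    s = 0.9 * min(sd, mad) * len(ratios) ** (-0.2)
    hbw = bandwidth_factor * s
    if not np.isfinite(hbw) or hbw <= 0:
        # degenerate spread: fall back to the weighted median of ratios
        return _weighted_median_value(ratios, weights)
    grid = np.linspace(ratios.min() - 3 * hbw, ratios.max() + 3 * hbw, n_grid)
    dens = np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / hbw) ** 2)
    dens = dens @ (weights / weights.sum())
    return float(grid[np.argmax(dens)])


def mode_estimator(h: HarmonizedSet, weighted: bool = False,
                   bandwidth_factor: float = 1.0,
                   n_boot: int = DEFAULT_N_BOOT,
                   seed: int = DEFAULT_SEED) -> MREstimate:
    """Simple or weighted mode of the Wald-ratio density.

    Consistent when the largest group of variants sharing a ratio value are
    valid (ZEMPA); the weighted variant weights kernels by inverse ratio
    variance.  SE from a seeded parametric bootstrap.
    """
    if bandwidth_factor <= 0:
        raise ValueError("bandwidth_factor must be positive")
    bx, _, by, sy = _require(h, 2, "mode")

    def stat(bx_, by_, sy_):
        ok = bx_ != 0
        r = by_[ok] / bx_[ok]
        w = bx_[ok] ** 2 / sy_[ok] ** 2 if weighted else np.ones(ok.sum())
        return _kde_mode(r, w, bandwidth_factor)

    beta = stat(bx, by, sy)
    se = _bootstrap_se(h, stat, n_boot, seed)
    return _estimate("weighted_mode" if weighted else "simple_mode",
                     beta, se, len(bx))


@dataclass(frozen=True)
class MRSettings:
    """Shared knobs for the method battery."""

    n_boot: int = DEFAULT_N_BOOT
    seed: int = DEFAULT_SEED
    bandwidth_factor: float = 1.0
    ivw_model: str = "auto"  # "auto" applies the heterogeneity rule


def run_all_methods(h: HarmonizedSet,
                    settings: MRSettings = MRSettings()) -> list[MREstimate]:
    """Run every estimator whose minimum instrument count is met.

    With a single retained pair only the Wald ratio is returned (flagged
    non-primary).  Otherwise both IVW variants, the weighted median and both
    modes run; Egger joins from three instruments.  The primary estimate is
    the IVW variant selected by the heterogeneity rule (multiplicative random
    effects when Cochran's Q has p < 0.05, fixed effects otherwise), unless
    ``settings.ivw_model`` forces one.
    """
    from .sensitivity import choose_ivw_model, cochran_q  # cycle-free import

    J = h.n_retained
    if J == 0:
        raise InsufficientInstrumentsError("no retained instrument pairs")
    if J == 1:
        return [wald_ratio(h)]

    estimates = [ivw(h, "fixed"), ivw(h, "multiplicative_random")]
    estimates.append(weighted_median(h, settings.n_boot, settings.seed))
    estimates.append(mode_estimator(h, False, settings.bandwidth_factor,
                                    settings.n_boot, settings.seed))
    estimates.append(mode_estimator(h, True, settings.bandwidth_factor,
                                    settings.n_boot, settings.seed))
    if J >= 3:
        estimates.append(mr_egger(h))

    if settings.ivw_model == "auto":
        _, _, q_pval = cochran_q(h)
        primary_name = ("ivw_mre" if choose_ivw_model(q_pval)
                        == "multiplicative_random" else "ivw_fe")
    else:
        primary_name = ("ivw_mre" if settings.ivw_model
                        == "multiplicative_random" else "ivw_fe")
    return [replace(e, is_primary=(e.method == primary_name))
            for e in estimates]
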