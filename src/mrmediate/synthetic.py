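"""Synthetic GWAS summary statistics with known causal structure.

Two generators share one configuration:

* :func:`simulate_triplet` draws individual-level genotypes in three disjoint
  cohorts (honoring the two-sample assumption), builds an exposure trait
  X = Σγⱼ Gⱼ + ε (SD 1), a mediator M = β₁X + Σδⱼ Gⱼ + ε (SD 1; the δ are
  mediator-specific variants so that the mediator→outcome leg has its own
  instruments), and an outcome liability
  (β₀ − β₁β₂)·X + β₂·M + Σ αⱼ Gⱼ + ε dichotomized at the prevalence
  threshold, then computes per-variant summary statistics (logistic
  regression for the binary outcome, OLS otherwise).

* :func:`simulate_summary_direct` draws the per-variant summary effects
  directly from the same effect model with sampling noise implied by cohort
  size and allele frequency — a fast path for large replicate calibration
  suites.

All randomness flows from one seed through `numpy.random.SeedSequence`
spawning, so identical configurations are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .summary_io import AssociationTable, STANDARD_COLUMNS
from .iv_selection import LDMatrix

#: non-palindromic allele pairs; palindrome handling is exercised by
#: hand-built fixtures, not by generated data
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]


class ConfigError(ValueError):
    """Infeasible simulation configuration (e.g. variance budget exceeded)."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic exposure→mediator→outcome system.

    Defaults emulate the summary-data regime of immune-trait style GWAS: a
    small exposure cohort (n 3757), a mid-sized quantitative mediator cohort
    (n 8293) and a case-control outcome cohort (n 20,000 at 10% prevalence),
    with 30 independent instruments strong enough to clear F > 10.
    ``gamma_scale`` is the typical per-variant exposure effect in trait-SD
    units per allele; effects vary uniformly within ``effect_spread`` of it
    with random sign.
    """

    n_snp: int = 30
    n_exp: int = 3757
    n_med: int = 8293
    n_out: int = 20_000
    maf_range: tuple[float, float] = (0.2, 0.5)
    gamma_scale: float = 0.2
    beta0_true: float = 0.2
    beta1_true: float = 0.3
    beta2_true: float = 0.2
    pleio_mean: float = 0.0
    pleio_sd: float = 0.0
    prop_invalid: float = 0.0
    ld_blocks: tuple[int, float] | None = None  # (block size, within-block r²)
    prevalence: float | None = 0.1  # None -> quantitative outcome
    n_snp_med: int | None = None    # mediator-specific variants (default n_snp)
    effect_spread: tuple[float, float] = (0.8, 1.2)
    positive_effects: bool = False  # orient all variant effects trait-increasing
    sample_overlap: float = 0.0     # exposure/outcome cohort overlap fraction
    seed: int = 20240101

    def __post_init__(self) -> None:
        if not 0 <= self.prop_invalid <= 1 or not 0 <= self.sample_overlap <= 1:
            raise ConfigError("fractions must lie in [0, 1]")
        if min(self.n_exp, self.n_med, self.n_out) < 100:
            raise ConfigError("cohort sizes must be at least 100")
        if self.n_snp < 1:
            raise ConfigError("need at least one instrument")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must lie within (0, 0.5]")
        if self.prevalence is not None and not 0 < self.prevalence < 1:
            raise ConfigError("prevalence must lie in (0, 1)")

    @property
    def m_med(self) -> int:
        return self.n_snp if self.n_snp_med is None else self.n_snp_med


@dataclass
class TruthRecord:
    """Ground truth of one simulated system, for recovery tests."""

    beta0_true: float
    beta1_true: float
    beta2_true: float
    indirect_true: float
    proportion_true: float | None
    invalid_snp_ids: list[str]
    seed: int

    def to_dict(self) -> dict:
        return asdict(self)


def _draw_effects(rng, m, scale, spread, positive=False):
    sign = np.ones(m) if positive else rng.choice([-1.0, 1.0], size=m)
    return sign * scale * rng.uniform(spread[0], spread[1], size=m)


def _snp_frame(snp_ids, chrom, pos, ea, oa, eaf, beta, se, n):
    z = np.divide(beta, se, out=np.zeros_like(np.asarray(beta, float)),
                  where=np.asarray(se) > 0)
    pval = np.clip(2 * stats.norm.sf(np.abs(z)), np.nextafter(0, 1), 1.0)
    return pd.DataFrame({
        "snp": snp_ids, "chrom": chrom, "pos": pos,
        "effect_allele": ea, "other_allele": oa, "eaf": eaf,
        "beta": beta, "se": se, "pval": pval, "n": n,
    })[STANDARD_COLUMNS]


def _panel_layout(rng, m):
    """Allele pairs and genome positions for a panel of m variants.

    Variants are spread across chromosomes far beyond any clumping window so
    that independent variants never clump; LD-block members are placed within
    100 kb of each other instead (handled by the caller).
    """
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    ea = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    oa = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])
    chrom = (np.arange(m) % 22 + 1).astype(str)
    pos = 1_000_000 + (np.arange(m) // 22) * 50_000_000
    return ea, oa, chrom, pos.astype(int)


def _block_structure(cfg: SimConfig):
    """(correlation matrix or None, positions override) for exposure variants."""
    if cfg.ld_blocks is None:
        return None
    size, r2 = cfg.ld_blocks
    if size < 1 or not 0 <= r2 <= 1:
        raise ConfigError("ld_blocks must be (size >= 1, r2 in [0, 1])")
    rho = float(np.sqrt(r2))
    m = cfg.n_snp
    corr = np.eye(m)
    for start in range(0, m, size):
        stop = min(start + size, m)
        corr[start:stop, start:stop] = rho
    np.fill_diagonal(corr, 1.0)
    return corr


def _ld_from_corr(snp_ids, corr, m_extra) -> LDMatrix:
    m = len(snp_ids)
    r2 = np.eye(m)
    if corr is not None:
        k = corr.shape[0]
        r2[:k, :k] = corr**2
    return LDMatrix(list(snp_ids), r2)


def _genotypes(rng, n, maf, corr=None):
    """Genotype matrix (n, m): binomial alleles, optionally block-correlated.

    Correlated blocks use a Gaussian copula per haplotype; the realized
    allelic correlation is mildly attenuated relative to the latent one.
    """
    m = len(maf)
    if corr is None:
        return rng.binomial(2, maf, size=(n, m)).astype(float)
    chol = np.linalg.cholesky(corr + 1e-10 * np.eye(m))
    thresh = stats.norm.ppf(maf)
    g = np.zeros((n, m))
    for _hap in range(2):
        z = rng.standard_normal((n, m)) @ chol.T
        g += (z < thresh).astype(float)
    return g


def _marginal_ols(G, y):
    """Per-variant simple linear regression, vectorized."""
    n = len(y)
    gc = G - G.mean(axis=0)
    yc = y - y.mean()
    sgg = np.einsum("ij,ij->j", gc, gc)
    beta = (gc.T @ yc) / sgg
    sse = np.sum(yc**2) - beta**2 * sgg
    se = np.sqrt(np.maximum(sse, 1e-300) / (n - 2) / sgg)
    return beta, se


def _marginal_logistic(G, y):
    """Per-variant logistic regression (intercept + allele count)."""
    import statsmodels.api as sm
    m = G.shape[1]
    beta = np.empty(m)
    se = np.empty(m)
    for j in range(m):
        X = sm.add_constant(G[:, j])
        fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
        beta[j] = fit.params[1]
        se[j] = fit.bse[1]
    return beta, se


def _truth(cfg: SimConfig, invalid_ids) -> TruthRecord:
    indirect = cfg.beta1_true * cfg.beta2_true
    prop = indirect / cfg.beta0_true if cfg.beta0_true != 0 else None
    return TruthRecord(cfg.beta0_true, cfg.beta1_true, cfg.beta2_true,
                       indirect, prop, list(invalid_ids), cfg.seed)


def _pick_invalid(rng, cfg, snp_ids):
    k = int(round(cfg.prop_invalid * cfg.n_snp))
    idx = rng.choice(cfg.n_snp, size=k, replace=False) if k else np.array([], int)
    alpha = np.zeros(cfg.n_snp)
    if k:
        alpha[idx] = rng.normal(cfg.pleio_mean, cfg.pleio_sd, size=k)
    return alpha, [snp_ids[i] for i in np.sort(idx)]


def simulate_summary_direct(cfg: SimConfig):
    """Draw per-variant summary statistics directly (fast path).

    Returns (exposure, mediator, outcome AssociationTables, LDMatrix,
    TruthRecord).  Each table covers the full panel (exposure variants then
    mediator-specific variants); sampling SEs are 1/sqrt(n·v·2p(1−p)) with
    v = prevalence·(1 − prevalence) for the binary outcome and 1 otherwise.
    """
    ss = np.random.SeedSequence(cfg.seed).spawn(4)
    rng_par, rng_x, rng_m, rng_y = (np.random.default_rng(s) for s in ss)

    m_exp, m_med = cfg.n_snp, cfg.m_med
    m_all = m_exp + m_med
    maf = rng_par.uniform(*cfg.maf_range, size=m_all)
    het = 2 * maf * (1 - maf)
    gamma = _draw_effects(rng_par, m_exp, cfg.gamma_scale, cfg.effect_spread,
                          cfg.positive_effects)
    delta = _draw_effects(rng_par, m_med, cfg.gamma_scale, cfg.effect_spread,
                          cfg.positive_effects)
    snp_ids = ([f"rsX{i:04d}" for i in range(m_exp)]
               + [f"rsM{i:04d}" for i in range(m_med)])
    alpha, invalid_ids = _pick_invalid(rng_par, cfg, snp_ids)
    ea, oa, chrom, pos = _panel_layout(rng_par, m_all)

    corr = _block_structure(cfg)
    if corr is not None:
        # tagged variants: block members proxy the lead signal at strength rho
        rho_mat = corr.copy()
        lead = np.zeros(m_exp)
        size = cfg.ld_blocks[0]
        for start in range(0, m_exp, size):
            lead[start:min(start + size, m_exp)] = gamma[start]
        gamma = np.where(np.arange(m_exp) % size == 0, gamma,
                         np.sqrt(cfg.ld_blocks[1]) * lead)
        # co-locate block members so clumping windows apply
        for start in range(0, m_exp, size):
            stop = min(start + size, m_exp)
            chrom[start:stop] = chrom[start]
            pos[start:stop] = pos[start] + 10_000 * np.arange(stop - start)

    def noisy(true, se, rng, corr_mat=None):
        if corr_mat is None:
            return true + rng.normal(0.0, se)
        chol = np.linalg.cholesky(corr_mat + 1e-10 * np.eye(len(true)))
        return true + se * (chol @ rng.standard_normal(len(true)))

    # exposure: own variants only
    se_x = 1.0 / np.sqrt(cfg.n_exp * het)
    true_x = np.concatenate([gamma, np.zeros(m_med)])
    bx = noisy(true_x[:m_exp], se_x[:m_exp], rng_x, corr) if corr is not None \
        else true_x[:m_exp] + rng_x.normal(0.0, se_x[:m_exp])
    bx = np.concatenate([bx, rng_x.normal(0.0, se_x[m_exp:])])

    # mediator: inherits beta1*gamma at exposure variants, own delta
    se_m = 1.0 / np.sqrt(cfg.n_med * het)
    true_m = np.concatenate([cfg.beta1_true * gamma, delta])
    bm = true_m + rng_m.normal(0.0, se_m)

    # outcome: total exposure effect + pleiotropy; beta2*delta at mediator SNPs
    v = cfg.prevalence * (1 - cfg.prevalence) if cfg.prevalence else 1.0
    se_y = 1.0 / np.sqrt(cfg.n_out * v * het)
    true_y = np.concatenate([cfg.beta0_true * gamma + alpha,
                             cfg.beta2_true * delta])
    by = true_y + rng_y.normal(0.0, se_y)

    def table(name, ttype, beta, se, n):
        return AssociationTable(name, ttype, _snp_frame(
            snp_ids, chrom, pos, ea, oa, maf, beta, se, n))

    exposure = table("exposure", "quantitative", bx, se_x, cfg.n_exp)
    mediator = table("mediator", "quantitative", bm, se_m, cfg.n_med)
    outcome = table("outcome", "binary" if cfg.prevalence else "quantitative",
                    by, se_y, cfg.n_out)
    ld = _ld_from_corr(snp_ids, corr, m_med)
    return exposure, mediator, outcome, ld, _truth(cfg, invalid_ids)


def simulate_triplet(cfg: SimConfig):
    """Individual-level simulation in three disjoint cohorts.

    Returns the same 5-tuple as :func:`simulate_summary_direct`, with the LD
    matrix estimated empirically from the exposure-cohort genotypes.  Raises
    :class:`ConfigError` when the implied trait variance budget exceeds 1.
    """
    ss = np.random.SeedSequence(cfg.seed).spawn(4)
    rng_par, rng_x, rng_m, rng_y = (np.random.default_rng(s) for s in ss)

    m_exp, m_med = cfg.n_snp, cfg.m_med
    m_all = m_exp + m_med
    maf = rng_par.uniform(*cfg.maf_range, size=m_all)
    het = 2 * maf * (1 - maf)
    gamma = _draw_effects(rng_par, m_exp, cfg.gamma_scale, cfg.effect_spread,
                          cfg.positive_effects)
    delta = _draw_effects(rng_par, m_med, cfg.gamma_scale, cfg.effect_spread,
                          cfg.positive_effects)
    snp_ids = ([f"rsX{i:04d}" for i in range(m_exp)]
               + [f"rsM{i:04d}" for i in range(m_med)])
    alpha, invalid_ids = _pick_invalid(rng_par, cfg, snp_ids)
    ea, oa, chrom, pos = _panel_layout(rng_par, m_all)

    gamma_full = np.concatenate([gamma, np.zeros(m_med)])
    delta_full = np.concatenate([np.zeros(m_exp), delta])
    alpha_full = np.concatenate([alpha, np.zeros(m_med)])

    var_gx = float(np.sum(gamma_full**2 * het))
    if var_gx >= 0.95:
        raise ConfigError(f"exposure genetic variance {var_gx:.2f} exceeds budget")
    var_gm = cfg.beta1_true**2 + float(np.sum(delta_full**2 * het))
    if var_gm >= 0.95:
        raise ConfigError(f"mediator variance budget {var_gm:.2f} exceeds 0.95")
    direct = cfg.beta0_true - cfg.beta1_true * cfg.beta2_true
    var_y = (direct**2 + cfg.beta2_true**2
             + 2 * direct * cfg.beta2_true * cfg.beta1_true
             + float(np.sum(alpha_full**2 * het)))
    if var_y >= 0.95:
        raise ConfigError(f"outcome liability budget {var_y:.2f} exceeds 0.95")

    corr_exp = _block_structure(cfg)
    corr_all = None
    if corr_exp is not None:
        corr_all = np.eye(m_all)
        corr_all[:m_exp, :m_exp] = corr_exp
        size = cfg.ld_blocks[0]
        for start in range(0, m_exp, size):
            stop = min(start + size, m_exp)
            chrom[start:stop] = chrom[start]
            pos[start:stop] = pos[start] + 10_000 * np.arange(stop - start)

    def draw_cohort(rng, n):
        G = _genotypes(rng, n, maf, corr_all)
        x = G @ gamma_full + rng.normal(0, np.sqrt(1 - var_gx), n)
        return G, x

    # exposure cohort
    G_x, x_x = draw_cohort(rng_x, cfg.n_exp)
    bx, sx = _marginal_ols(G_x, x_x)

    # mediator cohort
    G_m, x_m = draw_cohort(rng_m, cfg.n_med)
    eps_m_sd = np.sqrt(1 - var_gm)
    med = (cfg.beta1_true * x_m + G_m @ delta_full
           + rng_m.normal(0, eps_m_sd, cfg.n_med))
    bm, sm = _marginal_ols(G_m, med)

    # outcome cohort (optionally overlapping the exposure cohort)
    G_y, x_y = draw_cohort(rng_y, cfg.n_out)
    k = int(round(cfg.sample_overlap * min(cfg.n_exp, cfg.n_out)))
    if k:
        G_y[:k], x_y[:k] = G_x[:k], x_x[:k]
    med_y = (cfg.beta1_true * x_y + G_y @ delta_full
             + rng_y.normal(0, eps_m_sd, cfg.n_out))
    liab = (direct * x_y + cfg.beta2_true * med_y + G_y @ alpha_full
            + rng_y.normal(0, np.sqrt(max(1 - var_y, 1e-6)), cfg.n_out))
    if cfg.prevalence is not None:
        y = (liab > np.quantile(liab, 1 - cfg.prevalence)).astype(float)
        by, sy = _marginal_logistic(G_y, y)
        out_type = "binary"
    else:
        by, sy = _marginal_ols(G_y, liab)
        out_type = "quantitative"

    eaf_emp = G_x.mean(axis=0) / 2
    eaf_emp = np.clip(eaf_emp, 1e-4, 1 - 1e-4)

    def table(name, ttype, beta, se, n):
        return AssociationTable(name, ttype, _snp_frame(
            snp_ids, chrom, pos, ea, oa, eaf_emp, beta, se, n))

    exposure = table("exposure", "quantitative", bx, sx, cfg.n_exp)
    mediator = table("mediator", "quantitative", bm, sm, cfg.n_med)
    outcome = table("outcome", out_type, by, sy, cfg.n_out)

    r2_emp = np.corrcoef(G_x.T) ** 2
    r2_emp = np.clip((r2_emp + r2_emp.T) / 2, 0.0, 1.0)
    np.fill_diagonal(r2_emp, 1.0)
    ld = LDMatrix(snp_ids, r2_emp)
    return exposure, mediator, outcome, ld, _truth(cfg, invalid_ids)


@dataclass
class GridData:
    """A synthetic screening grid of exposures × mediators × outcomes."""

    exposures: dict[str, AssociationTable]
    mediators: dict[str, AssociationTable]
    outcomes: dict[str, AssociationTable]
    ld: LDMatrix
    planted: tuple[str, str, str]
    truth: TruthRecord


def simulate_screen_grid(cfg: SimConfig, n_exposures: int = 5,
                         n_mediators: int = 3, n_outcomes: int = 2,
                         planted: tuple[int, int, int] = (0, 0, 0)) -> GridData:
    """A multi-trait panel with exactly one planted mediated pathway.

    Every trait owns ``cfg.n_snp`` variants; each trait's table covers the
    full union panel so that forward and reverse legs are both estimable.
    Only the planted (exposure, mediator, outcome) triple carries nonzero
    β₁, β₂ and total effect β₀; every other trait pair is null.  Outcome
    traits receive own-variant effects at twice ``gamma_scale`` so their
    instruments clear genome-wide-style selection in the case-control SE
    regime.
    """
    ss = np.random.SeedSequence(cfg.seed).spawn(2)
    rng_par, rng_noise = (np.random.default_rng(s) for s in ss)

    labels = ([f"X{i + 1}" for i in range(n_exposures)]
              + [f"M{j + 1}" for j in range(n_mediators)]
              + [f"Y{k + 1}" for k in range(n_outcomes)])
    n_traits = len(labels)
    m = cfg.n_snp
    m_all = n_traits * m
    maf = rng_par.uniform(*cfg.maf_range, size=m_all)
    het = 2 * maf * (1 - maf)
    snp_ids = [f"rs{t}_{i:03d}" for t in labels for i in range(m)]
    ea, oa, chrom, pos = _panel_layout(rng_par, m_all)

    def own_slice(t_idx):
        return slice(t_idx * m, (t_idx + 1) * m)

    own_effects = {}
    for t, lab in enumerate(labels):
        scale = cfg.gamma_scale * (2.0 if lab.startswith("Y") else 1.0)
        own_effects[lab] = _draw_effects(rng_par, m, scale, cfg.effect_spread,
                                         cfg.positive_effects)

    px, pm, py = planted
    lx, lm, ly = labels[px], labels[n_exposures + pm], labels[n_exposures + n_mediators + py]

    v = cfg.prevalence * (1 - cfg.prevalence) if cfg.prevalence else 1.0
    se_by_kind = {
        "X": 1.0 / np.sqrt(cfg.n_exp * het),
        "M": 1.0 / np.sqrt(cfg.n_med * het),
        "Y": 1.0 / np.sqrt(cfg.n_out * v * het),
    }
    n_by_kind = {"X": cfg.n_exp, "M": cfg.n_med, "Y": cfg.n_out}

    def build(lab, t_idx):
        kind = lab[0]
        true = np.zeros(m_all)
        true[own_slice(t_idx)] = own_effects[lab]
        if lab == lm:  # planted mediator inherits the exposure signal
            true[own_slice(px)] += cfg.beta1_true * own_effects[lx]
        if lab == ly:  # planted outcome: total effect + mediator leg
            true[own_slice(px)] += cfg.beta0_true * own_effects[lx]
            true[own_slice(n_exposures + pm)] += (
                cfg.beta2_true * own_effects[lm])
        se = se_by_kind[kind]
        beta = true + rng_noise.normal(0.0, se)
        ttype = ("binary" if kind == "Y" and cfg.prevalence else "quantitative")
        return AssociationTable(lab, ttype, _snp_frame(
            snp_ids, chrom, pos, ea, oa, maf, beta, se, n_by_kind[kind]))

    tables = {lab: build(lab, t) for t, lab in enumerate(labels)}
    return GridData(
        exposures={lab: tables[lab] for lab in labels if lab.startswith("X")},
        mediators={lab: tables[lab] for lab in labels if lab.startswith("M")},
        outcomes={lab: tables[lab] for lab in labels if lab.startswith("Y")},
        ld=LDMatrix.identity(snp_ids),
        planted=(lx, lm, ly),
        truth=_truth(cfg, []),
    )
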