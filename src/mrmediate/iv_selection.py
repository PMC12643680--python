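"""Instrument selection: p-value filter, greedy LD clumping, strength filter.

The instrument-strength statistics follow the summary-data formulas
R² = β² / (β² + se²·n) (proportion of trait variance explained by one variant)
and F = R²·(n − 2) / (1 − R²); variants with F below ``f_min`` (default 10,
the conventional weak-instrument cutoff) are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .summary_io import AssociationTable

logger = logging.getLogger(__name__)


@dataclass
class LDMatrix:
    """Pairwise LD r² between named variants (symmetric, unit diagonal)."""

    snp_ids: list[str]
    r2: np.ndarray
    positions: np.ndarray | None = None
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        m = len(self.snp_ids)
        if self.r2.shape != (m, m):
            raise ValueError("LD matrix shape does not match snp_ids")
        if not np.allclose(self.r2, self.r2.T, atol=1e-8):
            raise ValueError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-8):
            raise ValueError("LD matrix diagonal must be 1")
        if (self.r2 < -1e-12).any() or (self.r2 > 1 + 1e-12).any():
            raise ValueError("LD r² entries must lie in [0, 1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    @classmethod
    def identity(cls, snp_ids) -> "LDMatrix":
        return cls(list(snp_ids), np.eye(len(snp_ids)))

    def lookup(self, snp_a: str, snp_b: str) -> float | None:
        """r² between two variants, or None when either is absent."""
        ia, ib = self._index.get(snp_a), self._index.get(snp_b)
        if ia is None or ib is None:
            return None
        return float(self.r2[ia, ib])


def read_ld(path) -> LDMatrix:
    """Read LD r² from a square-matrix file or a long triplet file.

    The square format has a header row of SNP ids and one labelled row per
    SNP; the triplet format has columns (snp_a, snp_b, r2), symmetrized on
    read with missing pairs treated as r² = 0.
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    cols = [c.lower() for c in df.columns]
    if cols[:3] == ["snp_a", "snp_b", "r2"]:
        snps = sorted(set(df.iloc[:, 0]) | set(df.iloc[:, 1]))
        idx = {s: i for i, s in enumerate(snps)}
        mat = np.eye(len(snps))
        for a, b, r2 in df.itertuples(index=False):
            mat[idx[a], idx[b]] = mat[idx[b], idx[a]] = float(r2)
        return LDMatrix(snps, mat)
    # square layout: first column is the row label
    snps = list(df.columns[1:])
    return LDMatrix(snps, df.iloc[:, 1:].to_numpy(dtype=float))


def write_ld(ld: LDMatrix, path) -> None:
    out = pd.DataFrame(ld.r2, columns=ld.snp_ids)
    out.insert(0, "snp", ld.snp_ids)
    out.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class SelectionParams:
    """Thresholds of the instrument-selection pipeline."""

    p_threshold: float
    clump_r2: float
    clump_window_kb: float
    f_min: float = 10.0

    def __post_init__(self) -> None:
        if min(self.p_threshold, self.clump_r2, self.clump_window_kb,
               self.f_min) <= 0:
            raise ValueError("selection parameters must be strictly positive")
        if self.clump_r2 > 1:
            raise ValueError("clump_r2 must lie in (0, 1]")


#: named threshold profiles: a permissive one for high-dimensional molecular
#: exposures and a stringent genome-wide one for outcomes/mediators
PRESETS = {
    "immune": SelectionParams(1e-5, 0.1, 500.0),
    "cytokine_outcome": SelectionParams(5e-6, 0.001, 10_000.0),
}


def variance_explained(beta, se, n):
    """Per-variant proportion of trait variance explained, β²/(β² + se²·n)."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    n = np.asarray(n, dtype=float)
    if (n <= 2).any():
        raise ValueError("sample size must exceed 2")
    if (se <= 0).any():
        raise ValueError("se must be positive")
    out = beta**2 / (beta**2 + se**2 * n)
    return out.item() if out.ndim == 0 else out


def f_statistic(r2, n):
    """Instrument F-statistic, R²·(n − 2)/(1 − R²)."""
    r2 = np.asarray(r2, dtype=float)
    n = np.asarray(n, dtype=float)
    if (r2 < 0).any() or (r2 >= 1).any():
        raise ValueError("r2 must lie in [0, 1)")
    if (n <= 2).any():
        raise ValueError("sample size must exceed 2")
    out = r2 * (n - 2) / (1 - r2)
    return out.item() if out.ndim == 0 else out


def clump(table: AssociationTable, ld: LDMatrix | None,
          params: SelectionParams) -> AssociationTable:
    """Greedy LD clumping by ascending p-value.

    Repeatedly retain the remaining variant with the smallest p (ties broken
    lexicographically by SNP id) and discard every remaining variant on the
    same chromosome within ``clump_window_kb`` of it whose r² with it is at
    least ``clump_r2``.  Variants absent from the LD matrix are treated as
    LD-independent (warned once).  Retained rows keep the input order.
    """
    df = table.df
    order = sorted(range(len(df)),
                   key=lambda i: (df["pval"].iat[i], df["snp"].iat[i]))
    chrom = df["chrom"].to_numpy()
    pos = df["pos"].to_numpy(dtype=float)
    snp = df["snp"].to_numpy()
    window = params.clump_window_kb * 1000.0

    missing_warned = False
    alive = np.ones(len(df), dtype=bool)
    retained: list[int] = []
    for i in order:
        if not alive[i]:
            continue
        retained.append(i)
        alive[i] = False
        near = alive & (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= window)
        for j in np.flatnonzero(near):
            r2 = ld.lookup(snp[i], snp[j]) if ld is not None else None
            if r2 is None:
                if ld is not None and not missing_warned:
                    logger.warning(
                        "clump: variant pair absent from LD matrix treated as "
                        "independent (first: %s~%s)", snp[i], snp[j])
                    missing_warned = True
                continue
            if r2 >= params.clump_r2:
                alive[j] = False
    keep = sorted(retained)
    return AssociationTable(table.trait_name, table.trait_type,
                            df.iloc[keep].reset_index(drop=True))


def select_instruments(table: AssociationTable, ld: LDMatrix | None,
                       params: SelectionParams) -> pd.DataFrame:
    """Full instrument-selection pipeline.

    Filter to p < ``p_threshold``, clump, compute per-survivor R² and F, and
    drop weak instruments (F < ``f_min``).  Returns one row per instrument
    with the association columns plus ``r2_explained`` and ``f_stat``; an
    empty frame is a valid result.
    """
    hits = table.df[table.df["pval"] < params.p_threshold]
    if hits.empty:
        return table.df.iloc[:0].assign(r2_explained=[], f_stat=[])
    clumped = clump(
        AssociationTable(table.trait_name, table.trait_type,
                         hits.reset_index(drop=True)),
        ld, params)
    df = clumped.df.copy()
    df["r2_explained"] = variance_explained(df["beta"], df["se"], df["n"])
    df["f_stat"] = f_statistic(df["r2_explained"], df["n"])
    strong = df[df["f_stat"] >= params.f_min].reset_index(drop=True)
    logger.info("%s: %d hit(s) -> %d clumped -> %d instrument(s) with F>=%g",
                table.trait_name, len(hits), len(df), len(strong), params.f_min)
    return strong
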