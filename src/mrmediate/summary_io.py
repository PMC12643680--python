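"""Reading, validation, and harmonization of GWAS summary statistics.

Summary associations are carried as :class:`pandas.DataFrame` objects with a
fixed column schema wrapped in :class:`AssociationTable`.  Harmonization aligns
an exposure table and an outcome table to a common effect allele following the
standard two-sample MR convention: matching orientations are kept, swapped
alleles flip the outcome beta, strand flips are resolved by complementing, and
palindromic variants with ambiguous allele frequency are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical internal column order for summary-statistic frames
STANDARD_COLUMNS = [
    "snp", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]

#: on-disk header names -> internal names (the canonical tab-delimited dialect)
DEFAULT_COLUMN_MAP = {
    "SNP": "snp",
    "CHR": "chrom",
    "POS": "pos",
    "EA": "effect_allele",
    "OA": "other_allele",
    "EAF": "eaf",
    "BETA": "beta",
    "SE": "se",
    "P": "pval",
    "N": "n",
}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class SummaryFormatError(ValueError):
    """A summary-statistics file is malformed (e.g. missing mandatory columns)."""


class EmptyInputError(ValueError):
    """No valid association rows survive validation."""


class NoOverlapError(ValueError):
    """Exposure and outcome tables share no variants."""


def _complement_allele(allele: str) -> str | None:
    """Reverse-strand complement of a simple allele; None when undefined."""
    try:
        return "".join(_COMPLEMENT[b] for b in allele)
    except KeyError:
        return None


def is_palindromic(a1: str, a2: str) -> bool:
    """True for A/T or G/C variants, whose strand cannot be resolved from alleles."""
    return _complement_allele(a1) == a2


@dataclass
class AssociationTable:
    """A validated per-SNP association table for one trait.

    ``df`` holds one row per variant with :data:`STANDARD_COLUMNS`; ``snp``
    values are unique.  Betas are on the log-odds scale for binary traits and
    in SD units for quantitative traits.
    """

    trait_name: str
    trait_type: str  # "quantitative" | "binary"
    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "binary"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        missing = [c for c in STANDARD_COLUMNS if c not in self.df.columns]
        if missing:
            raise SummaryFormatError(f"missing columns: {missing}")
        if self.df["snp"].duplicated().any():
            dups = self.df.loc[self.df["snp"].duplicated(), "snp"].tolist()
            raise SummaryFormatError(f"duplicate snp ids: {dups[:5]}")

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, trait_name: str,
                   trait_type: str = "quantitative") -> "AssociationTable":
        """Validate a raw frame, dropping rows that violate record invariants."""
        df = df.copy()
        for col in ("effect_allele", "other_allele"):
            df[col] = df[col].astype(str).str.upper()
        for col in ("pos", "eaf", "beta", "se", "pval", "n"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
        ok = (
            (df["se"] > 0)
            & np.isfinite(df["beta"])
            & (df["pval"] > 0) & (df["pval"] <= 1)
            & (df["n"] > 0)
            & (df["effect_allele"].str.len() > 0)
            & (df["other_allele"].str.len() > 0)
            & (df["effect_allele"] != df["other_allele"])
            & (df["eaf"].isna() | ((df["eaf"] > 0) & (df["eaf"] < 1)))
        )
        n_bad = int((~ok).sum())
        if n_bad:
            logger.warning("%s: dropped %d invalid row(s)", trait_name, n_bad)
        df = df.loc[ok].reset_index(drop=True)
        if df.empty:
            raise EmptyInputError(f"{trait_name}: no valid association rows")
        return cls(trait_name=trait_name, trait_type=trait_type,
                   df=df[STANDARD_COLUMNS])

    def subset(self, snp_ids) -> "AssociationTable":
        """Row subset by SNP id, preserving this table's row order."""
        keep = self.df["snp"].isin(set(snp_ids))
        return AssociationTable(self.trait_name, self.trait_type,
                                self.df.loc[keep].reset_index(drop=True))


def read_summary_stats(path, column_map: dict[str, str] | None = None,
                       trait_type: str = "quantitative",
                       trait_name: str | None = None) -> AssociationTable:
    """Read a tab-delimited summary-statistics table (gzip transparently).

    ``column_map`` maps file header names to internal names; by default the
    canonical SNP/CHR/POS/EA/OA/EAF/BETA/SE/P/N header is expected.  Rows that
    violate the association-record invariants are dropped with a logged count;
    a missing mandatory column raises :class:`SummaryFormatError` and an empty
    result raises :class:`EmptyInputError`.
    """
    column_map = dict(column_map or DEFAULT_COLUMN_MAP)
    raw = pd.read_csv(path, sep="\t", compression="infer",
                      float_precision="round_trip")
    missing = [src for src in column_map if src not in raw.columns]
    if missing:
        raise SummaryFormatError(f"{path}: missing mandatory column(s) {missing}")
    df = raw.rename(columns=column_map)
    wanted = set(column_map.values())
    if not set(STANDARD_COLUMNS) <= wanted:
        raise SummaryFormatError(
            f"column_map does not cover {sorted(set(STANDARD_COLUMNS) - wanted)}")
    name = trait_name if trait_name is not None else str(path)
    return AssociationTable.from_frame(df[STANDARD_COLUMNS], name, trait_type)


def write_summary_stats(table: AssociationTable, path) -> None:
    """Write the canonical tab-delimited dialect (full float precision)."""
    out = table.df.rename(columns={v: k for k, v in DEFAULT_COLUMN_MAP.items()})
    out.to_csv(path, sep="\t", index=False)


@dataclass
class HarmonizedSet:
    """Exposure/outcome association pairs aligned to the exposure effect allele.

    ``pairs`` has columns snp, beta_exp, se_exp, beta_out, se_out, eaf, action;
    ``action`` is one of kept / flipped / dropped_palindromic /
    dropped_incompatible.  Dropped pairs are excluded from estimation.
    """

    exposure_name: str
    outcome_name: str
    pairs: pd.DataFrame = field(repr=False)

    _RETAINED = ("kept", "flipped")

    @property
    def retained(self) -> pd.DataFrame:
        return self.pairs[self.pairs["action"].isin(self._RETAINED)]

    @property
    def n_retained(self) -> int:
        return int(self.pairs["action"].isin(self._RETAINED).sum())

    def arrays(self):
        """(beta_exp, se_exp, beta_out, se_out) of retained pairs, as ndarrays."""
        r = self.retained
        return (r["beta_exp"].to_numpy(), r["se_exp"].to_numpy(),
                r["beta_out"].to_numpy(), r["se_out"].to_numpy())


def _orient(ea_x, oa_x, ea_y, oa_y):
    """Classify outcome orientation vs exposure: 'same', 'swap' or None."""
    if ea_y == ea_x and oa_y == oa_x:
        return "same"
    if ea_y == oa_x and oa_y == ea_x:
        return "swap"
    return None


def harmonize(exposure: AssociationTable, outcome: AssociationTable,
              palindrome_eaf_window: float = 0.08) -> HarmonizedSet:
    """Align outcome associations to the exposure effect allele.

    The variant intersection is taken on SNP id.  Swapped alleles flip the
    outcome beta sign and replace its EAF by 1 − EAF; strand flips (e.g. A/G
    reported as T/C) are resolved by complementing the outcome alleles before
    matching.  Palindromic variants are dropped when either EAF is missing or
    within ``palindrome_eaf_window`` of 0.5 (default window [0.42, 0.58]);
    otherwise their orientation is inferred from EAF agreement.  Allele sets
    that match no orientation are dropped as incompatible.
    """
    if len(exposure) == 0 or len(outcome) == 0:
        raise EmptyInputError("harmonize requires non-empty tables")
    merged = exposure.df.merge(outcome.df, on="snp", suffixes=("_exp", "_out"))
    if merged.empty:
        raise NoOverlapError(
            f"no shared variants between {exposure.trait_name!r} "
            f"and {outcome.trait_name!r}")

    lo, hi = 0.5 - palindrome_eaf_window, 0.5 + palindrome_eaf_window
    rows = []
    for row in merged.itertuples(index=False):
        ea_x, oa_x = row.effect_allele_exp, row.other_allele_exp
        ea_y, oa_y = row.effect_allele_out, row.other_allele_out
        beta_out, eaf_out = row.beta_out, row.eaf_out

        if is_palindromic(ea_x, oa_x):
            ambiguous = (
                pd.isna(row.eaf_exp) or pd.isna(eaf_out)
                or lo <= row.eaf_exp <= hi or lo <= eaf_out <= hi
            )
            if ambiguous or _orient(ea_x, oa_x, ea_y, oa_y) is None:
                action = "dropped_palindromic"
            else:
                # strand is unknowable from alleles; infer from frequency side
                same_side = (row.eaf_exp < 0.5) == (eaf_out < 0.5)
                action = "kept" if same_side else "flipped"
                if action == "flipped":
                    beta_out, eaf_out = -beta_out, 1.0 - eaf_out
        else:
            orient = _orient(ea_x, oa_x, ea_y, oa_y)
            if orient is None:
                cea, coa = _complement_allele(ea_y), _complement_allele(oa_y)
                if cea is not None:
                    orient = _orient(ea_x, oa_x, cea, coa)
            if orient is None:
                action = "dropped_incompatible"
            elif orient == "same":
                action = "kept"
            else:
                action = "flipped"
                beta_out = -beta_out
                if not pd.isna(eaf_out):
                    eaf_out = 1.0 - eaf_out

        rows.append({
            "snp": row.snp,
            "beta_exp": row.beta_exp, "se_exp": row.se_exp,
            "beta_out": beta_out, "se_out": row.se_out,
            "eaf": row.eaf_exp if not pd.isna(row.eaf_exp) else eaf_out,
            "action": action,
        })
    pairs = pd.DataFrame(rows)
    n_drop = int((~pairs["action"].isin(HarmonizedSet._RETAINED)).sum())
    if n_drop:
        logger.info("harmonize %s~%s: dropped %d of %d shared variants",
                    exposure.trait_name, outcome.trait_name, n_drop, len(pairs))
    return HarmonizedSet(exposure.trait_name, outcome.trait_name, pairs)


def harmonized_from_arrays(beta_exp, se_exp, beta_out, se_out,
                           snp_ids=None, exposure_name="exposure",
                           outcome_name="outcome") -> HarmonizedSet:
    """Build a HarmonizedSet directly from aligned effect arrays.

    Convenience constructor for simulated or already-aligned data, where the
    alleles are by construction on a common strand and effect allele.
    """
    beta_exp = np.asarray(beta_exp, dtype=float)
    if snp_ids is None:
        snp_ids = [f"snp{i}" for i in range(len(beta_exp))]
    pairs = pd.DataFrame({
        "snp": snp_ids,
        "beta_exp": beta_exp,
        "se_exp": np.asarray(se_exp, dtype=float),
        "beta_out": np.asarray(beta_out, dtype=float),
        "se_out": np.asarray(se_out, dtype=float),
        "eaf": np.nan,
        "action": "kept",
    })
    return HarmonizedSet(exposure_name, outcome_name, pairs)
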