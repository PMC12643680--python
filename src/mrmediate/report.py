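"""Tidy result tables, human-readable reports, and run manifests.

Every numeric cell in a formatted report round-trips through the tidy
tables: formatting reads the tidy frame, it never recomputes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from .mr_core import MREstimate
from .mediation import MediationResult
from .pathway_screen import LegResult, CandidatePathway

_VERSION = "0.1.0"


def estimates_frame(legs: list[LegResult]) -> pd.DataFrame:
    """One row per (exposure, outcome, method) across legs."""
    rows = []
    for leg in legs:
        for est in leg.estimates:
            rows.append({
                "exposure": leg.exposure_name, "outcome": leg.outcome_name,
                "method": est.method, "beta": est.beta, "se": est.se,
                "ci_low": est.ci_low, "ci_high": est.ci_high,
                "pval": est.pval, "or": est.or_,
                "or_ci_low": est.or_ci_low, "or_ci_high": est.or_ci_high,
                "n_snp": est.n_snp, "primary": est.is_primary,
                "pval_adj": leg.pval_adj if est.is_primary else None,
                "reverse_pval": leg.reverse_pval if est.is_primary else None,
            })
    return pd.DataFrame(rows)


def sensitivity_frame(legs: list[LegResult]) -> pd.DataFrame:
    rows = []
    for leg in legs:
        s = leg.sensitivity
        if s is None:
            continue
        rows.append({
            "exposure": leg.exposure_name, "outcome": leg.outcome_name,
            "q_stat": s.q_stat, "q_df": s.q_df, "q_pval": s.q_pval,
            "egger_intercept": s.egger_intercept,
            "egger_intercept_se": s.egger_intercept_se,
            "egger_intercept_pval": s.egger_intercept_pval,
            "presso_global_pval": s.presso_global_pval,
            "presso_outliers": ";".join(s.presso_outliers),
            "presso_distortion_pval": s.presso_distortion_pval,
            "n_sim": s.n_sim, "seed": s.seed,
        })
    return pd.DataFrame(rows)


def mediation_frame(pathways: list[CandidatePathway]) -> pd.DataFrame:
    """Mediation table mirroring the worked-example column layout."""
    rows = []
    for p in pathways:
        m = p.mediation
        rows.append(_mediation_row(p.exposure, p.mediator, p.outcome, m))
    return pd.DataFrame(rows)


def _mediation_row(exposure: str, mediator: str, outcome: str,
                   m: MediationResult) -> dict:
    ci = m.indirect_ci
    return {
        "exposure": exposure, "mediator": mediator, "outcome": outcome,
        "beta0": m.beta0, "beta1": m.beta1, "beta2": m.beta2,
        "direct_effect": m.direct, "mediation_effect": m.indirect,
        "mediation_ci_low": ci[0] if ci else None,
        "mediation_ci_high": ci[1] if ci else None,
        "mediation_proportion_pct": (100 * m.proportion
                                     if m.proportion is not None else None),
        "consistent": m.consistent, "pval": m.pval,
    }


def format_mediation_report(df: pd.DataFrame, digits: int = 4) -> str:
    """Fixed-width text rendition of a mediation table ("NA" when
    inconsistent)."""
    show = df.copy()
    for col in show.columns:
        if show[col].dtype.kind == "f":
            show[col] = show[col].map(
                lambda v: "NA" if pd.isna(v) else f"{v:.{digits}g}")
    show = show.fillna("NA")
    return show.to_string(index=False)


def format_forest(df: pd.DataFrame, digits: int = 4) -> str:
    """Forest-style text table of MR estimates (one row per method)."""
    if "or" in df.columns:  # tidy on-disk name; "or" is not an identifier
        df = df.rename(columns={"or": "or_"})
    lines = []
    for (exp, out), grp in df.groupby(["exposure", "outcome"], sort=False):
        lines.append(f"{exp} -> {out}")
        for row in grp.itertuples(index=False):
            star = "*" if row.primary else " "
            lines.append(
                f"  {star}{row.method:<16} OR {row.or_:.{digits}g} "
                f"({row.or_ci_low:.{digits}g}-{row.or_ci_high:.{digits}g}) "
                f"p={row.pval:.3g} nSNP={row.n_snp}")
    return "\n".join(lines)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance snapshot written once per output directory."""

    config: dict
    seeds: dict
    version: str = _VERSION
    input_digests: dict = field(default_factory=dict)
    timestamp: str = ""

    @classmethod
    def create(cls, config: dict, seeds: dict,
               input_paths: dict[str, str] | None = None) -> "RunManifest":
        digests = {name: _sha256(Path(p))
                   for name, p in (input_paths or {}).items()}
        return cls(config=config, seeds=seeds, input_digests=digests,
                   timestamp=datetime.now(timezone.utc).isoformat())

    def write(self, out_dir: Path) -> Path:
        path = Path(out_dir) / "manifest.json"
        path.write_text(json.dumps(asdict(self), indent=2, default=str))
        return path
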