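#!/usr/bin/env python
"""Generate the synthetic GWAS system used throughout the analysis.

Writes exposure/mediator/outcome summary-statistic tables with a planted
mediated pathway (β₀ 0.2, β₁ 0.3, β₂ 0.2 → mediation proportion 0.3), the
LD reference, and the ground-truth record under results/sim/.
"""

import json
from pathlib import Path

from mrmediate.iv_selection import write_ld
from mrmediate.summary_io import write_summary_stats
from mrmediate.synthetic import SimConfig, simulate_summary_direct

OUT = Path(__file__).resolve().parent.parent / "results" / "sim"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(seed=20240101)
    exposure, mediator, outcome, ld, truth = simulate_summary_direct(cfg)
    for name, table in (("exposure", exposure), ("mediator", mediator),
                        ("outcome", outcome)):
        write_summary_stats(table, OUT / f"{name}.tsv")
    write_ld(ld, OUT / "ld.tsv")
    (OUT / "truth.json").write_text(json.dumps(truth.to_dict(), indent=2))
    print(f"wrote {len(exposure)}-variant tables for 3 traits to {OUT}")
    print(f"planted truth: beta0={truth.beta0_true}, beta1={truth.beta1_true},"
          f" beta2={truth.beta2_true},"
          f" mediation proportion={truth.proportion_true}")


if __name__ == "__main__":
    main()
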