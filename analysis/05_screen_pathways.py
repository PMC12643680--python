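#!/usr/bin/env python
"""Three-leg pathway screen on a synthetic exposure×mediator×outcome grid.

Simulates a 5×3×2 grid with one planted mediated pathway, runs every
forward and reverse leg, assembles candidates under the default rule
(IVW p < 0.05 on all three legs, non-significant reverse leg), and writes
the candidate mediation table.
"""

from pathlib import Path

from mrmediate.experiments import screen_recovery
from mrmediate.mr_core import MRSettings
from mrmediate.pathway_screen import LegSettings, run_screen
from mrmediate.report import mediation_frame
from mrmediate.synthetic import SimConfig, simulate_screen_grid

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 20240101


def main() -> None:
    grid = simulate_screen_grid(SimConfig(seed=SEED))
    settings = LegSettings(mr=MRSettings(n_boot=100, seed=SEED),
                           presso_n_sim=200)
    res = run_screen(grid.exposures, grid.mediators, grid.outcomes,
                     settings=settings, ld=grid.ld)
    med = mediation_frame(res.candidates)
    med.to_csv(OUT / "screen_mediation.tsv", sep="\t", index=False)
    print(f"planted pathway: {' -> '.join(grid.planted)}")
    print(f"candidates found: "
          f"{[(c.exposure, c.mediator, c.outcome) for c in res.candidates]}")
    print(f"exclusions: {res.exclusions or 'none'}")

    rec = screen_recovery(n_seeds=10, seed=SEED)
    print(f"\nrecovery over 10 replicate grids: exact "
          f"{rec.exact_recovery_rate:.0%}, planted found "
          f"{rec.planted_found_rate:.0%}, false candidates/seed "
          f"{rec.mean_false_candidates:.2f}")


if __name__ == "__main__":
    main()
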