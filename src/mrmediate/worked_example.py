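"""Published worked-example coefficients for the mediation calculus.

Four immune-cell → cytokine → lung-cancer pathways from a published mediating
MR coefficient table serve as the package's worked example: each row carries
the total-effect odds ratio per SD of the exposure (β₀ = ln OR), the
exposure→mediator effect β₁ and the mediator→outcome effect β₂.  Standard
errors are not printed in the source table, so only the point decomposition
(mediated effect, direct effect, mediation proportion, consistency) is
reproducible from these inputs.

The IL-16 row is the canonical inconsistent-mediation case: its mediated
effect opposes the total effect, so no proportion is reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mediation import MediationInput


@dataclass(frozen=True)
class WorkedExampleRow:
    exposure: str
    mediator: str
    outcome: str
    or0: float   # total-effect odds ratio per SD of the exposure
    beta1: float  # exposure -> mediator, SD per SD
    beta2: float  # mediator -> outcome, log-odds per SD

    @property
    def beta0(self) -> float:
        return float(np.log(self.or0))

    def mediation_input(self) -> MediationInput:
        return MediationInput(beta0=self.beta0, beta1=self.beta1,
                              beta2=self.beta2)


WORKED_EXAMPLE = [
    WorkedExampleRow("BAFF-R on IgD+ CD24+ B cell", "MIF", "LUAD",
                     or0=1.0168, beta1=-0.047, beta2=-0.050),
    WorkedExampleRow("CD39 on CD39+ secreting CD4 Treg", "IL-2", "SCLC",
                     or0=1.0306, beta1=-0.043, beta2=-0.060),
    WorkedExampleRow("CD39 on CD39+ secreting CD4 Treg", "IL-6", "SCLC",
                     or0=1.0306, beta1=-0.026, beta2=-0.06),
    WorkedExampleRow("CD28 on CD39+ CD4+ T cell", "IL-16", "LUSC",
                     or0=1.0335, beta1=-0.088, beta2=0.06),
]
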