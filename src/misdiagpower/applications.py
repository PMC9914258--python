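"""Re-analysis of two published ME/CFS case-control studies under misdiagnosis.

Two bundled parameter sets drive the simulations:

* ``steiner_snps`` -- five candidate-gene SNP associations from a study of
  305 ME/CFS patients (Canadian Consensus Criteria, infectious onset) versus
  201 healthy controls.  The reported effects are allele-based: the control
  non-reference allele frequency theta0 and the allelic odds ratio, so each
  genotyped subject contributes two chromosomes and the simulated group
  sizes are 2*n0 and 2*n1.  Genotyping is treated as error-free.
* ``cliff_serology`` -- antibody seropositivity for six herpesviruses
  (HSV1, HSV2, EBV, CMV, VZV, HHV6) in 251 severely affected ME/CFS
  patients versus 107 controls.  Seropositivity came from a mean + 2 SD
  cut-off in a seronegative reference population, which under normality
  implies specificity about 0.975; sensitivity is assumed equal, so
  pi_se = pi_sp = 0.975.

Both sets also ship the originally printed confidence intervals and
p-values; these are provenance only and play no role in the simulations.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_model import ContingencyTable2x2, ScenarioParams
from .power import DEFAULT_REPLICATES, PowerCurve, power_curve

__all__ = [
    "StudyFactor",
    "STUDY_NAMES",
    "load_study_fixtures",
    "study_power_curves",
    "OddsRatioCI",
    "odds_ratio_with_ci",
]

STUDY_NAMES = ("steiner_snps", "cliff_serology")


@dataclass(frozen=True)
class StudyFactor:
    """One candidate causal factor from a published study.

    ``copies_per_subject`` is the number of sampling units each enrolled
    subject contributes to the 2x2 table (2 for allele-based genetic
    factors, 1 otherwise); effective group sizes scale accordingly.
    """

    label: str
    theta0: float
    delta_t: float
    n0: int
    n1: int
    pi_se: float = 1.0
    pi_sp: float = 1.0
    copies_per_subject: int = 1
    significant_in_original: bool = False
    gene: str | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    p_value: float | None = None

    @property
    def effective_n0(self) -> int:
        return self.copies_per_subject * self.n0

    @property
    def effective_n1(self) -> int:
        return self.copies_per_subject * self.n1

    def scenario(self, gamma: float = 0.0, alpha: float = 0.05) -> ScenarioParams:
        return ScenarioParams(
            theta0=self.theta0,
            gamma=gamma,
            n0=self.effective_n0,
            n1=self.effective_n1,
            delta_t=self.delta_t,
            pi_se=self.pi_se,
            pi_sp=self.pi_sp,
            alpha=alpha,
        )


def load_study_fixtures(name: str) -> list[StudyFactor]:
    """Load one of the bundled study parameter sets by name."""
    if name not in STUDY_NAMES:
        raise ValueError(f"unknown study {name!r}; known: {', '.join(STUDY_NAMES)}")
    path = resources.files("misdiagpower").joinpath("data", f"{name}.csv")
    with resources.as_file(path) as p:
        df = pd.read_csv(p)
    factors = []
    for rec in df.to_dict("records"):
        gene = rec.get("gene")
        factors.append(
            StudyFactor(
                label=str(rec["label"]),
                theta0=float(rec["theta0"]),
                delta_t=float(rec["delta_t"]),
                n0=int(rec["n0"]),
                n1=int(rec["n1"]),
                pi_se=float(rec["pi_se"]),
                pi_sp=float(rec["pi_sp"]),
                copies_per_subject=int(rec["copies_per_subject"]),
                significant_in_original=bool(rec["significant_in_original"]),
                gene=None if pd.isna(gene) else str(gene),
                ci_low=float(rec["ci_low"]),
                ci_high=float(rec["ci_high"]),
                p_value=float(rec["p_value"]),
            )
        )
    return factors


def study_power_curves(
    factors: Iterable[StudyFactor],
    gamma_grid: Sequence[float] | np.ndarray | None = None,
    replicates: int = DEFAULT_REPLICATES,
    seed: int = 0,
    yates: bool = False,
) -> dict[str, PowerCurve]:
    """Power versus misdiagnosis rate for each study factor.

    Protective factors (odds ratio below 1) are handled by the same odds
    inversion, yielding a factor probability below theta0 in genuine cases.
    """
    return {
        f.label: power_curve(
            f.scenario(), gamma_grid, replicates, seed, yates=yates
        )
        for f in factors
    }


class OddsRatioCI(NamedTuple):
    odds_ratio: float
    ci_low: float
    ci_high: float
    level: float
    corrected: bool = False


def odds_ratio_with_ci(
    table: ContingencyTable2x2 | np.ndarray, level: float = 0.95
) -> OddsRatioCI:
    """Sample odds ratio with a Woolf (log-normal) confidence interval.

    For a :class:`ContingencyTable2x2` the ratio is the odds of the factor
    in cases over controls; for a raw 2x2 array ``[[a, b], [c, d]]`` it is
    ``(a*d)/(b*c)``.  Zero cells trigger the Haldane-Anscombe 0.5 continuity
    adjustment, flagged in the result.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    if isinstance(table, ContingencyTable2x2):
        cells = np.array(
            [
                [table.cases_present, table.cases_absent],
                [table.controls_present, table.controls_absent],
            ],
            dtype=float,
        )
    else:
        cells = np.asarray(table, dtype=float)
        if cells.shape != (2, 2):
            raise ValueError(f"expected a 2x2 table, got shape {cells.shape}")
    if cells.sum() <= 0:
        raise ValueError("table total must be positive")
    corrected = bool(np.any(cells == 0))
    if corrected:
        cells = cells + 0.5
    a, b = cells[0]
    c, d = cells[1]
    log_or = np.log(a * d / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.5 + level / 2.0)
    return OddsRatioCI(
        odds_ratio=float(np.exp(log_or)),
        ci_low=float(np.exp(log_or - z * se)),
        ci_high=float(np.exp(log_or + z * se)),
        level=level,
        corrected=corrected,
    )
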