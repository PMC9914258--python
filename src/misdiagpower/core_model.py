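"""Closed-form probability model for case-control studies under misdiagnosis.

A diagnosed case group is modelled as a mixture of *genuine* cases, in which
a binary causal factor (an allele, an infection, a seropositive status) is
present with probability ``theta1_star``, and *apparent* cases -- patients of
some other condition -- in which the factor behaves exactly as in healthy
controls (probability ``theta0``).  The mixing weight ``gamma`` is the
misdiagnosis rate.  Optionally, the factor itself is read through an
imperfect binary classifier with sensitivity ``pi_se`` and specificity
``pi_sp`` (e.g. a serological cut-off), which mixes true and false positives
into the observed counts.

The association test throughout is Pearson's chi-square on the observed
2x2 table, without continuity correction by default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import stats

__all__ = [
    "ScenarioParams",
    "ContingencyTable2x2",
    "Chi2Result",
    "invert_odds_ratio",
    "odds_ratio_of_probs",
    "case_exposure_prob",
    "case_exposure_prob_serology",
    "control_observed_prob",
    "pearson_chi2",
    "pearson_chi2_counts",
]


def _as_prob(name: str, value: float) -> float:
    """Validate and return a probability, naming the offending field on error."""
    try:
        x = float(value)
    except (TypeError, ValueError):
        raise ValueError(f"{name} must be a number in [0, 1], got {value!r}") from None
    if not math.isfinite(x) or not 0.0 <= x <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value!r}")
    return x


def _as_odds_ratio(name: str, value: float) -> float:
    try:
        x = float(value)
    except (TypeError, ValueError):
        raise ValueError(f"{name} must be a positive number, got {value!r}") from None
    if not math.isfinite(x) or x <= 0.0:
        raise ValueError(f"{name} must be a finite positive odds ratio, got {value!r}")
    return x


def invert_odds_ratio(delta_t: float, theta0: float) -> float:
    """Probability of the factor in genuine cases implied by an odds ratio.

    Solves ``odds(theta1_star) = delta_t * odds(theta0)`` for ``theta1_star``:

        theta1_star = delta_t * theta0 / (1 - theta0 + delta_t * theta0)

    Valid for protective effects (``delta_t < 1``) as well; returns ``theta0``
    unchanged at the boundaries ``theta0 in {0, 1}`` for any ``delta_t``.
    """
    delta_t = _as_odds_ratio("delta_t", delta_t)
    theta0 = _as_prob("theta0", theta0)
    return delta_t * theta0 / (1.0 - theta0 + delta_t * theta0)


def odds_ratio_of_probs(p1: float, p0: float) -> float:
    """Odds ratio ``odds(p1)/odds(p0)``; requires both probabilities interior."""
    p1 = _as_prob("p1", p1)
    p0 = _as_prob("p0", p0)
    if not (0.0 < p0 < 1.0 and 0.0 < p1 < 1.0):
        raise ValueError("odds ratio undefined for boundary probabilities")
    return (p1 / (1.0 - p1)) / (p0 / (1.0 - p0))


def case_exposure_prob(gamma: float, theta0: float, theta1_star: float) -> float:
    """Marginal probability of the factor being present in diagnosed cases.

    The case group mixes apparent cases (factor probability ``theta0``, weight
    ``gamma``) with genuine cases (``theta1_star``, weight ``1 - gamma``):

        theta1 = gamma * theta0 + (1 - gamma) * theta1_star
    """
    gamma = _as_prob("gamma", gamma)
    theta0 = _as_prob("theta0", theta0)
    theta1_star = _as_prob("theta1_star", theta1_star)
    return gamma * theta0 + (1.0 - gamma) * theta1_star


def case_exposure_prob_serology(
    gamma: float,
    theta0: float,
    theta1_star: float,
    pi_se: float,
    pi_sp: float,
) -> float:
    """Probability that a diagnosed case is *classified* factor-positive.

    Extends :func:`case_exposure_prob` to an imperfect binary classifier with
    sensitivity ``pi_se`` and specificity ``pi_sp``: each truly-positive
    individual is observed positive with probability ``pi_se`` and each
    truly-negative one with probability ``1 - pi_sp``:

        theta1 = pi_se*gamma*theta0 + (1-pi_sp)*gamma*(1-theta0)
               + pi_se*(1-gamma)*theta1_star + (1-pi_sp)*(1-gamma)*(1-theta1_star)

    Reduces exactly to :func:`case_exposure_prob` when ``pi_se == pi_sp == 1``.
    """
    gamma = _as_prob("gamma", gamma)
    theta0 = _as_prob("theta0", theta0)
    theta1_star = _as_prob("theta1_star", theta1_star)
    pi_se = _as_prob("pi_se", pi_se)
    pi_sp = _as_prob("pi_sp", pi_sp)
    return (
        pi_se * gamma * theta0
        + (1.0 - pi_sp) * gamma * (1.0 - theta0)
        + pi_se * (1.0 - gamma) * theta1_star
        + (1.0 - pi_sp) * (1.0 - gamma) * (1.0 - theta1_star)
    )


def control_observed_prob(theta0: float, pi_se: float, pi_sp: float) -> float:
    """Probability that a control is classified factor-positive.

    ``pi_se*theta0 + (1-pi_sp)*(1-theta0)``; equals ``theta0`` for a perfect
    classifier.
    """
    theta0 = _as_prob("theta0", theta0)
    pi_se = _as_prob("pi_se", pi_se)
    pi_sp = _as_prob("pi_sp", pi_sp)
    return pi_se * theta0 + (1.0 - pi_sp) * (1.0 - theta0)


@dataclass(frozen=True)
class ScenarioParams:
    """One simulation scenario for a case-control study under misdiagnosis.

    Exactly one of ``delta_t`` (odds ratio in genuine cases vs controls) or
    ``theta1_star`` (factor probability in genuine cases) must be supplied;
    the other is derived.  ``n0`` and ``n1`` are the fixed group sizes of
    controls and diagnosed cases (sampling units: subjects, or chromosomes
    for allele-based studies).

    Parameters
    ----------
    theta0
        Probability of the causal factor in controls and in apparent cases.
    gamma
        Misdiagnosis rate: probability that a diagnosed case is apparent.
    n0, n1
        Group sizes (controls, diagnosed cases).
    delta_t
        True odds ratio relating genuine cases to controls.
    theta1_star
        Probability of the factor in genuine cases.
    pi_se, pi_sp
        Sensitivity and specificity of the factor classification (default 1:
        the factor is measured without error).
    alpha
        Significance level of the chi-square test.
    """

    theta0: float
    gamma: float
    n0: int
    n1: int
    delta_t: float | None = None
    theta1_star: float | None = None
    pi_se: float = 1.0
    pi_sp: float = 1.0
    alpha: float = 0.05
    _effect_given: str = field(init=False, repr=False, compare=False, default="")

    def __post_init__(self) -> None:
        object.__setattr__(self, "theta0", _as_prob("theta0", self.theta0))
        object.__setattr__(self, "gamma", _as_prob("gamma", self.gamma))
        object.__setattr__(self, "pi_se", _as_prob("pi_se", self.pi_se))
        object.__setattr__(self, "pi_sp", _as_prob("pi_sp", self.pi_sp))
        if not (isinstance(self.n0, (int, np.integer)) and self.n0 >= 1):
            raise ValueError(f"n0 must be a positive integer, got {self.n0!r}")
        if not (isinstance(self.n1, (int, np.integer)) and self.n1 >= 1):
            raise ValueError(f"n1 must be a positive integer, got {self.n1!r}")
        object.__setattr__(self, "n0", int(self.n0))
        object.__setattr__(self, "n1", int(self.n1))
        alpha = float(self.alpha)
        if not (math.isfinite(alpha) and 0.0 < alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha!r}")
        object.__setattr__(self, "alpha", alpha)

        if (self.delta_t is None) == (self.theta1_star is None):
            raise ValueError(
                "exactly one of delta_t or theta1_star must be given"
            )
        if self.delta_t is not None:
            dt = _as_odds_ratio("delta_t", self.delta_t)
            object.__setattr__(self, "delta_t", dt)
            if self.theta0 in (0.0, 1.0):
                warnings.warn(
                    "theta0 is 0 or 1: odds ratio is uninformative, "
                    "theta1_star pinned to theta0",
                    stacklevel=2,
                )
                object.__setattr__(self, "theta1_star", self.theta0)
            else:
                object.__setattr__(
                    self, "theta1_star", invert_odds_ratio(dt, self.theta0)
                )
            object.__setattr__(self, "_effect_given", "delta_t")
        else:
            t1s = _as_prob("theta1_star", self.theta1_star)
            object.__setattr__(self, "theta1_star", t1s)
            if 0.0 < self.theta0 < 1.0 and 0.0 < t1s < 1.0:
                object.__setattr__(
                    self, "delta_t", odds_ratio_of_probs(t1s, self.theta0)
                )
            object.__setattr__(self, "_effect_given", "theta1_star")

    def with_gamma(self, gamma: float) -> "ScenarioParams":
        """Copy of this scenario at a different misdiagnosis rate."""
        kwargs = dict(
            theta0=self.theta0,
            gamma=gamma,
            n0=self.n0,
            n1=self.n1,
            pi_se=self.pi_se,
            pi_sp=self.pi_sp,
            alpha=self.alpha,
        )
        if self._effect_given == "delta_t":
            kwargs["delta_t"] = self.delta_t
        else:
            kwargs["theta1_star"] = self.theta1_star
        return ScenarioParams(**kwargs)

    def case_prob(self) -> float:
        """Observed-positive probability among diagnosed cases (marginal)."""
        return case_exposure_prob_serology(
            self.gamma, self.theta0, self.theta1_star, self.pi_se, self.pi_sp
        )

    def control_prob(self) -> float:
        """Observed-positive probability among controls."""
        return control_observed_prob(self.theta0, self.pi_se, self.pi_sp)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Observed 2x2 table: factor present/absent by control/case group."""

    controls_present: int
    controls_absent: int
    cases_present: int
    cases_absent: int

    def __post_init__(self) -> None:
        for name in (
            "controls_present",
            "controls_absent",
            "cases_present",
            "cases_absent",
        ):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
            object.__setattr__(self, name, int(v))

    @property
    def n0(self) -> int:
        return self.controls_present + self.controls_absent

    @property
    def n1(self) -> int:
        return self.cases_present + self.cases_absent

    @property
    def total(self) -> int:
        return self.n0 + self.n1

    def to_array(self) -> np.ndarray:
        """Rows: factor present/absent; columns: controls/cases."""
        return np.array(
            [
                [self.controls_present, self.cases_present],
                [self.controls_absent, self.cases_absent],
            ],
            dtype=float,
        )


class Chi2Result(NamedTuple):
    statistic: float
    p_value: float
    degenerate: bool = False


def pearson_chi2(
    table: ContingencyTable2x2 | np.ndarray, yates: bool = False
) -> Chi2Result:
    """Pearson's chi-square test of association on a 2x2 table.

    Computes ``sum((O - E)^2 / E)`` over the four cells, with expected counts
    from the row and column margins, and a p-value from the chi-square
    distribution with one degree of freedom.  With ``yates=True``, ``|O - E|``
    is reduced by 0.5 (floored at zero) before squaring.

    A table with an empty row or column margin carries no evidence against
    independence; it is flagged ``degenerate`` and given ``p_value = 1`` so
    that power estimates remain defined for every replicate.
    """
    obs = table.to_array() if isinstance(table, ContingencyTable2x2) else np.asarray(
        table, dtype=float
    )
    if obs.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {obs.shape}")
    if obs.sum() <= 0:
        raise ValueError("table total must be positive")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        return Chi2Result(0.0, 1.0, degenerate=True)
    expected = np.outer(rows, cols) / obs.sum()
    diff = np.abs(obs - expected)
    if yates:
        diff = np.maximum(diff - 0.5, 0.0)
    statistic = float(np.sum(diff**2 / expected))
    p_value = float(stats.chi2.sf(statistic, df=1))
    return Chi2Result(statistic, p_value)


def pearson_chi2_counts(
    controls_present: np.ndarray,
    cases_present: np.ndarray,
    n0: int,
    n1: int,
    yates: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised chi-square over many 2x2 tables with fixed column sums.

    Parameters are arrays of observed-positive counts per group; the
    remaining cells are ``n0 - controls_present`` and ``n1 - cases_present``.
    Uses the closed form ``N*(ad - bc)^2 / (r1*r2*n0*n1)`` (with the optional
    ``N/2`` continuity reduction of ``|ad - bc|``), which is algebraically
    identical to the cell-wise formula of :func:`pearson_chi2`.  Degenerate
    tables (empty row margin) get statistic 0 and p-value 1.
    """
    a = np.asarray(controls_present, dtype=float)
    b = np.asarray(cases_present, dtype=float)
    n_tot = float(n0 + n1)
    r1 = a + b
    r2 = n_tot - r1
    cross = np.abs(a * (n1 - b) - b * (n0 - a))
    if yates:
        cross = np.maximum(cross - n_tot / 2.0, 0.0)
    ok = (r1 > 0) & (r2 > 0)
    statistic = np.zeros_like(a)
    denom = r1 * r2 * float(n0) * float(n1)
    statistic[ok] = n_tot * cross[ok] ** 2 / denom[ok]
    p_value = np.where(ok, stats.chi2.sf(statistic, df=1), 1.0)
    statistic = np.where(ok, statistic, 0.0)
    return statistic, p_value
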