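"""Replicate 2x2 tables under a misdiagnosis scenario.

Two equivalent samplers are provided.  :func:`sample_table` draws the
observed table directly from the marginal product-binomial model: the
observed-positive count is Binomial(n0, p0) in controls and Binomial(n1, p1)
in cases, with p0/p1 the closed-form observed-positive probabilities.
:func:`sample_latent_table` instead simulates the latent structure -- the
apparent/genuine split of the cases, true factor status per stratum, and the
per-individual classification -- and only then collapses to the observed
table.  Marginalising the latent sampler reproduces the direct sampler's
distribution exactly, which is enforced by the test suite.

All randomness flows through numpy Generators.  :func:`substream` derives
order-independent streams from a root seed and an integer key, so grid runs
give identical results regardless of execution order or subsetting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_model import ContingencyTable2x2, ScenarioParams

__all__ = [
    "substream",
    "scenario_key",
    "sample_table",
    "sample_tables",
    "LatentTable",
    "sample_latent_table",
]


def substream(seed: int, *key: int) -> np.random.Generator:
    """Independent generator for (root seed, integer key path)."""
    return np.random.default_rng(
        np.random.SeedSequence(int(seed), spawn_key=tuple(int(k) for k in key))
    )


def scenario_key(params: ScenarioParams) -> tuple[int, ...]:
    """Canonical integer key of a scenario, excluding gamma.

    Keys depend only on parameter values (probabilities discretised at 1e-4),
    so the same scenario reached through different grids runs the same
    stream.
    """
    return (
        int(round(params.theta0 * 10_000)),
        int(round(params.theta1_star * 10_000)),
        int(round(params.pi_se * 10_000)),
        int(round(params.pi_sp * 10_000)),
        params.n0,
        params.n1,
    )


def sample_table(
    params: ScenarioParams, rng: np.random.Generator
) -> ContingencyTable2x2:
    """One observed 2x2 table from the product-binomial sampling model."""
    a = int(rng.binomial(params.n0, params.control_prob()))
    b = int(rng.binomial(params.n1, params.case_prob()))
    return ContingencyTable2x2(
        controls_present=a,
        controls_absent=params.n0 - a,
        cases_present=b,
        cases_absent=params.n1 - b,
    )


def sample_tables(
    params: ScenarioParams, replicates: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Observed-positive counts (controls, cases) for many replicates at once.

    Column sums are fixed at ``n0``/``n1`` by design, so the two returned
    arrays determine the full tables.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    a = rng.binomial(params.n0, params.control_prob(), size=replicates)
    b = rng.binomial(params.n1, params.case_prob(), size=replicates)
    return a, b


@dataclass(frozen=True)
class LatentTable:
    """Augmented counts with latent case status and true factor status.

    Each 2x2 block is indexed ``[true factor status][observed class]`` with
    0 = absent/negative and 1 = present/positive.  ``apparent_cases`` and
    ``genuine_cases`` partition the diagnosed case group; controls carry no
    genuine/apparent split.
    """

    controls: np.ndarray
    genuine_cases: np.ndarray
    apparent_cases: np.ndarray

    @property
    def n_apparent(self) -> int:
        return int(self.apparent_cases.sum())

    @property
    def n_genuine(self) -> int:
        return int(self.genuine_cases.sum())

    def marginalize(self) -> ContingencyTable2x2:
        """Collapse latent dimensions to the observed 2x2 table."""
        cases = self.genuine_cases + self.apparent_cases
        return ContingencyTable2x2(
            controls_present=int(self.controls[:, 1].sum()),
            controls_absent=int(self.controls[:, 0].sum()),
            cases_present=int(cases[:, 1].sum()),
            cases_absent=int(cases[:, 0].sum()),
        )


def _classify_stratum(
    m: int, theta: float, pi_se: float, pi_sp: float, rng: np.random.Generator
) -> np.ndarray:
    """True-by-observed 2x2 counts for m individuals with factor prob theta."""
    present = int(rng.binomial(m, theta))
    absent = m - present
    true_pos = int(rng.binomial(present, pi_se))
    false_pos = int(rng.binomial(absent, 1.0 - pi_sp))
    return np.array(
        [[absent - false_pos, false_pos], [present - true_pos, true_pos]],
        dtype=np.int64,
    )


def sample_latent_table(
    params: ScenarioParams, rng: np.random.Generator
) -> LatentTable:
    """One augmented table from the hierarchical (latent) sampling model.

    Cases are first split Binomial(n1, gamma) into apparent and genuine; the
    true factor status is then drawn per stratum (probability ``theta0`` for
    controls and apparent cases, ``theta1_star`` for genuine cases); finally
    the observed classification is drawn per individual with sensitivity
    ``pi_se`` and specificity ``pi_sp``, assumed identical for everyone.
    """
    n_apparent = int(rng.binomial(params.n1, params.gamma))
    n_genuine = params.n1 - n_apparent
    controls = _classify_stratum(
        params.n0, params.theta0, params.pi_se, params.pi_sp, rng
    )
    genuine = _classify_stratum(
        n_genuine, params.theta1_star, params.pi_se, params.pi_sp, rng
    )
    apparent = _classify_stratum(
        n_apparent, params.theta0, params.pi_se, params.pi_sp, rng
    )
    return LatentTable(
        controls=controls, genuine_cases=genuine, apparent_cases=apparent
    )
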