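"""Monte-Carlo power estimation and misdiagnosis-tolerance thresholds.

Power is the proportion of simulated 2x2 tables in which Pearson's
chi-square test rejects independence at level alpha.  A *power curve* scans
the misdiagnosis rate gamma over a grid (default 0 to 1 in steps of 0.01);
the *maximum tolerable misdiagnosis rate* is the largest grid gamma at which
the (smoothed) power still reaches a target, 80% by default.

Because raw Monte-Carlo curves are noisy while the true power is
non-increasing in gamma, the threshold search first applies an antitonic
(decreasing isotonic) regression to the curve; a raw mode is available.

``run_table2_grid`` and ``run_table3_grid`` sweep the standard scenario
grids: effect sizes ``delta_t`` in {1.25, 1.5, 2, 3, 5, 10} by control
prevalences {0.05, 0.1, 0.25, 0.5} for a perfectly measured factor, and
classifier sensitivities/specificities in {0.8, 0.9, 0.925, 0.975, 1.0} at
the fixed moderate effect (delta_t=3, theta0=0.25), each across group sizes
{100, 250, 500, 1000, 2500, 5000}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .core_model import ScenarioParams, pearson_chi2_counts
from .simulator import sample_tables, scenario_key, substream

__all__ = [
    "DEFAULT_GAMMA_GRID",
    "DELTA_T_GRID",
    "THETA0_GRID",
    "N_GRID",
    "PI_GRID",
    "DEFAULT_REPLICATES",
    "PowerEstimate",
    "PowerCurve",
    "ThresholdResult",
    "estimate_power",
    "power_curve",
    "max_gamma_for_power",
    "run_table2_grid",
    "run_table3_grid",
    "pivot_wide",
]

logger = logging.getLogger(__name__)

DEFAULT_GAMMA_GRID: np.ndarray = np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 2)
DELTA_T_GRID: tuple[float, ...] = (1.25, 1.5, 2.0, 3.0, 5.0, 10.0)
THETA0_GRID: tuple[float, ...] = (0.05, 0.1, 0.25, 0.5)
N_GRID: tuple[int, ...] = (100, 250, 500, 1000, 2500, 5000)
PI_GRID: tuple[float, ...] = (0.8, 0.9, 0.925, 0.975, 1.0)
DEFAULT_REPLICATES: int = 10_000


class PowerEstimate(NamedTuple):
    power: float
    mc_se: float
    replicates: int


def _mc_se(p_hat: float | np.ndarray, replicates: int) -> float | np.ndarray:
    return np.sqrt(p_hat * (1.0 - p_hat) / replicates)


def estimate_power(
    params: ScenarioParams,
    replicates: int = DEFAULT_REPLICATES,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    yates: bool = False,
) -> PowerEstimate:
    """Rejection probability of the chi-square test under one scenario.

    Simulates ``replicates`` product-binomial tables and returns the
    proportion with p-value below ``params.alpha``, with its binomial
    Monte-Carlo standard error.  Supply either an explicit generator or a
    seed (a scenario-keyed substream is derived from it).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if rng is None:
        rng = substream(
            0 if seed is None else seed,
            *scenario_key(params),
            int(round(params.gamma * 10_000)),
        )
    a, b = sample_tables(params, replicates, rng)
    _, p_values = pearson_chi2_counts(a, b, params.n0, params.n1, yates=yates)
    p_hat = float(np.mean(p_values < params.alpha))
    return PowerEstimate(p_hat, float(_mc_se(p_hat, replicates)), replicates)


@dataclass(frozen=True)
class PowerCurve:
    """Estimated rejection probability along a misdiagnosis-rate grid."""

    gamma_grid: np.ndarray
    power_hat: np.ndarray
    mc_se: np.ndarray
    replicates: int
    params: ScenarioParams
    seed: int
    yates: bool = False

    def __post_init__(self) -> None:
        if len(self.gamma_grid) != len(self.power_hat):
            raise ValueError("gamma_grid and power_hat lengths differ")

    def power_at(self, gamma: float) -> float:
        """Estimated power at a grid point (exact grid match required)."""
        idx = np.flatnonzero(np.isclose(self.gamma_grid, gamma))
        if idx.size == 0:
            raise ValueError(f"gamma={gamma} is not on the grid")
        return float(self.power_hat[idx[0]])

    def smoothed(self) -> np.ndarray:
        """Antitonic (monotone non-increasing) fit to the raw curve."""
        return IsotonicRegression(increasing=False).fit_transform(
            self.gamma_grid, self.power_hat
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gamma": self.gamma_grid,
                "power_hat": self.power_hat,
                "mc_se": self.mc_se,
            }
        )


def power_curve(
    params: ScenarioParams,
    gamma_grid: Sequence[float] | np.ndarray | None = None,
    replicates: int = DEFAULT_REPLICATES,
    seed: int = 0,
    yates: bool = False,
) -> PowerCurve:
    """Power as a function of the misdiagnosis rate gamma.

    One :func:`estimate_power` call per grid point, each on an independent
    substream keyed by (seed, scenario, grid index), so curves are
    reproducible and order-independent.  ``params.gamma`` is ignored.
    """
    grid = DEFAULT_GAMMA_GRID if gamma_grid is None else np.asarray(
        gamma_grid, dtype=float
    )
    if grid.size == 0:
        raise ValueError("gamma_grid must be non-empty")
    if np.any(grid < 0) or np.any(grid > 1) or np.any(np.diff(grid) <= 0):
        raise ValueError("gamma_grid must be strictly increasing within [0, 1]")
    key = scenario_key(params)
    p_hat = np.empty(grid.size)
    for i, g in enumerate(grid):
        rng = substream(seed, *key, i)
        est = estimate_power(
            params.with_gamma(float(g)), replicates, rng=rng, yates=yates
        )
        p_hat[i] = est.power
    return PowerCurve(
        gamma_grid=grid,
        power_hat=p_hat,
        mc_se=_mc_se(p_hat, replicates),
        replicates=replicates,
        params=params,
        seed=seed,
        yates=yates,
    )


@dataclass(frozen=True)
class ThresholdResult:
    """Largest grid gamma whose (smoothed) power meets the target."""

    gamma_max: float | None
    target_power: float
    curve: PowerCurve
    smoothed: bool


def max_gamma_for_power(
    curve: PowerCurve, target: float = 0.80, smooth: bool = True
) -> ThresholdResult:
    """Maximum tolerable misdiagnosis rate for a target power.

    With ``smooth=True`` (default) the raw curve is first replaced by its
    antitonic regression, which stabilises the threshold against Monte-Carlo
    noise; the result is the largest grid gamma whose power is at least
    ``target``, or ``None`` when even gamma=0 falls short.
    """
    if not 0.0 < target < 1.0:
        raise ValueError(f"target power must be in (0, 1), got {target!r}")
    values = curve.smoothed() if smooth else curve.power_hat
    idx = np.flatnonzero(values >= target)
    gamma_max = float(curve.gamma_grid[idx[-1]]) if idx.size else None
    return ThresholdResult(
        gamma_max=gamma_max, target_power=target, curve=curve, smoothed=smooth
    )


def _threshold_row(
    params: ScenarioParams,
    gamma_grid: np.ndarray | None,
    replicates: int,
    seed: int,
    target: float,
    smooth: bool,
    yates: bool,
) -> tuple[ThresholdResult, dict]:
    result = max_gamma_for_power(
        power_curve(params, gamma_grid, replicates, seed, yates=yates),
        target=target,
        smooth=smooth,
    )
    row = {
        "gamma_max": np.nan if result.gamma_max is None else result.gamma_max,
        "power_at_gamma0": result.curve.power_hat[0],
        "replicates": replicates,
        "seed": seed,
    }
    return result, row


def run_table2_grid(
    n_values: Iterable[int] = N_GRID,
    delta_values: Iterable[float] = DELTA_T_GRID,
    theta0_values: Iterable[float] = THETA0_GRID,
    replicates: int = DEFAULT_REPLICATES,
    seed: int = 0,
    gamma_grid: Sequence[float] | np.ndarray | None = None,
    target: float = 0.80,
    smooth: bool = True,
    yates: bool = False,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Misdiagnosis-tolerance thresholds over the (delta_t, theta0, n) grid.

    Perfect factor classification (pi_se = pi_sp = 1).  Returns a long-format
    frame with one row per scenario cell; ``gamma_max`` is NaN where the
    target power is unreachable even without misdiagnosis.
    """
    n_values, delta_values, theta0_values = (
        list(n_values),
        list(delta_values),
        list(theta0_values),
    )
    if not (n_values and delta_values and theta0_values):
        raise ValueError("all grids must be non-empty")
    rows = []
    for delta_t, theta0, n in product(delta_values, theta0_values, n_values):
        params = ScenarioParams(
            theta0=theta0, gamma=0.0, n0=n, n1=n, delta_t=delta_t, alpha=alpha
        )
        _, row = _threshold_row(
            params, gamma_grid, replicates, seed, target, smooth, yates
        )
        rows.append({"delta_t": delta_t, "theta0": theta0, "n": n, **row})
        logger.info(
            "table2 cell delta_t=%s theta0=%s n=%s -> gamma_max=%s",
            delta_t, theta0, n, rows[-1]["gamma_max"],
        )
    return pd.DataFrame(rows)


def run_table3_grid(
    pi_se_values: Iterable[float] = PI_GRID,
    pi_sp_values: Iterable[float] = PI_GRID,
    n_values: Iterable[int] = N_GRID,
    replicates: int = DEFAULT_REPLICATES,
    seed: int = 0,
    delta_t: float = 3.0,
    theta0: float = 0.25,
    gamma_grid: Sequence[float] | np.ndarray | None = None,
    target: float = 0.80,
    smooth: bool = True,
    yates: bool = False,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Thresholds over the classifier (pi_se, pi_sp, n) grid.

    The effect is fixed at a moderate association (delta_t=3, theta0=0.25 by
    default); sampling uses the observed-positive probabilities that mix true
    and false positives.
    """
    pi_se_values, pi_sp_values, n_values = (
        list(pi_se_values),
        list(pi_sp_values),
        list(n_values),
    )
    if not (pi_se_values and pi_sp_values and n_values):
        raise ValueError("all grids must be non-empty")
    rows = []
    for pi_se, pi_sp, n in product(pi_se_values, pi_sp_values, n_values):
        params = ScenarioParams(
            theta0=theta0,
            gamma=0.0,
            n0=n,
            n1=n,
            delta_t=delta_t,
            pi_se=pi_se,
            pi_sp=pi_sp,
            alpha=alpha,
        )
        _, row = _threshold_row(
            params, gamma_grid, replicates, seed, target, smooth, yates
        )
        rows.append(
            {
                "delta_t": delta_t,
                "theta0": theta0,
                "pi_se": pi_se,
                "pi_sp": pi_sp,
                "n": n,
                **row,
            }
        )
        logger.info(
            "table3 cell pi_se=%s pi_sp=%s n=%s -> gamma_max=%s",
            pi_se, pi_sp, n, rows[-1]["gamma_max"],
        )
    return pd.DataFrame(rows)


def pivot_wide(
    df: pd.DataFrame,
    index: str | Sequence[str],
    columns: str,
    values: str = "gamma_max",
) -> pd.DataFrame:
    """Pivot a long-format threshold table to a wide layout."""
    return df.pivot_table(
        index=index, columns=columns, values=values, dropna=False, sort=False
    )
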