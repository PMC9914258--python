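"""Power-versus-misdiagnosis plots."""

from __future__ import annotations

from typing import Mapping

import matplotlib

matplotlib.use("Agg")  # headless-safe; callers can switch backends first

import matplotlib.pyplot as plt

from .power import PowerCurve

__all__ = ["plot_power_curves"]


def plot_power_curves(
    curves: Mapping[str, PowerCurve],
    target: float = 0.80,
    alpha: float | None = 0.05,
    ax: plt.Axes | None = None,
) -> plt.Axes:
    """Plot one or more power curves with target-power and alpha guides.

    The upper dashed line marks the target power, the lower one the
    significance level (the power floor reached when every case is
    misdiagnosed).
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for label, curve in curves.items():
        ax.plot(curve.gamma_grid, curve.power_hat, label=label, lw=1.2)
    ax.axhline(target, ls="--", c="grey", lw=0.8)
    if alpha is not None:
        ax.axhline(alpha, ls="--", c="grey", lw=0.8)
    ax.set_xlabel("misdiagnosis rate $\\gamma$")
    ax.set_ylabel(r"power $1-\beta$")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    if len(curves) > 1:
        ax.legend(fontsize=8)
    return ax
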