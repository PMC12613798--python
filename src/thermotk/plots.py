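"""Arrhenius-plot helpers (ln k against 1/T with the fitted line)."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .arrhenius_fit import RegressionResult  # noqa: E402

__all__ = ["plot_arrhenius"]


def plot_arrhenius(records: pd.DataFrame, fit: Optional[RegressionResult],
                   path: Union[str, Path], *, title: str = "",
                   color_by_log_dow: bool = True) -> None:
    """Scatter ln k vs 1/T, optionally colored by log D_ow, with fit line."""
    x = 1.0 / records["temperature_K"].to_numpy(dtype=float)
    y = np.log(records["k"].to_numpy(dtype=float))
    fig, ax = plt.subplots(figsize=(5, 4))
    if color_by_log_dow and records["log_dow"].notna().any():
        sc = ax.scatter(x, y, c=records["log_dow"], cmap="coolwarm", s=12, alpha=0.7)
        fig.colorbar(sc, ax=ax, label=r"log $D_{ow}$")
    else:
        ax.scatter(x, y, s=12, alpha=0.7, color="tab:blue")
    if fit is not None:
        grid = np.linspace(x.min(), x.max(), 50)
        ax.plot(grid, fit.intercept + fit.slope_K * grid, color="black",
                label=f"slope = {fit.slope_K:.0f} K")
        ax.legend(frameon=False)
    ax.set_xlabel("1/T [1/K]")
    ax.set_ylabel("ln k")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
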