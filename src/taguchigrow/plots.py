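"""Optional plotting helpers (matplotlib required, imported lazily).

Off by default everywhere in the pipeline; call these directly to render
the classic Taguchi figures.
"""

from __future__ import annotations

from pathlib import Path

from .design import DesignMatrix
from .interactions import cell_means
from .sn import MainEffectsTable, SNTable

__all__ = ["main_effects_plot", "interaction_plot"]


def main_effects_plot(me: MainEffectsTable, path: str | Path | None = None):
    """Mean S/N versus level, one panel per factor."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    factors = me.factors
    fig, axes = plt.subplots(1, len(factors), figsize=(2.2 * len(factors), 3),
                             sharey=True)
    for ax, factor in zip(axes, factors):
        ax.plot([1, 2, 3], me.level_means(factor), "o-")
        ax.axhline(me.grand_mean_db, color="gray", lw=0.5, ls="--")
        ax.set_title(factor, fontsize=9)
        ax.set_xticks([1, 2, 3])
    axes[0].set_ylabel("mean S/N (dB)")
    fig.suptitle(f"{me.species} {me.parameter}: main effects")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def interaction_plot(
    dm: DesignMatrix,
    sn: SNTable,
    factor_a: str,
    factor_b: str,
    path: str | Path | None = None,
):
    """Two-line raw cell-mean profile plot for one factor pair."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mat = cell_means(dm, sn, factor_a, factor_b)
    fig, ax = plt.subplots(figsize=(4, 3))
    for level_a in (1, 2, 3):
        ax.plot([1, 2, 3], mat.loc[level_a], "o-", label=f"{factor_a}={level_a}")
    ax.set_xlabel(f"{factor_b} level")
    ax.set_ylabel("mean S/N (dB)")
    ax.set_xticks([1, 2, 3])
    ax.legend(fontsize=8)
    ax.set_title(f"{sn.species} {sn.parameter}: {factor_a} x {factor_b}")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
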