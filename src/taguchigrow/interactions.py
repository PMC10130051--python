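"""Two-factor interaction screening via cell means and non-parallelism.

An interaction plot draws, for a factor pair (A, B), the mean S/N of the
runs at each (level of A, level of B) cell; parallel profile lines mean the
two factors act additively.  On the 27-run strength-2 array every one of
the 9 cells averages exactly 3 runs, so cell means are always defined.

Parallelism is quantified here as the largest absolute non-additive
residual of a 3x3 cell-mean matrix:

    score = max_ij | cell_ij - (row_i + col_j - grand) |

which is 0 exactly when the matrix is additive (lines exactly parallel).
A pair is flagged as interacting when its score exceeds a threshold,
by default 10 % of the larger of the two factors' deltas.

One subtlety of the saturated array: with six of the thirteen orthogonal
directions in use, every column lies in the GF(3) span of some other column
pair (EC equals CO2 + LED, for instance), so the *raw* cell means of a pair
absorb the main effects of the columns it aliases — a purely additive
response still yields bent raw profiles.  Screening therefore scores the
cell means of the main-effects residual S/N (observed minus the additive
main-effects prediction), which is identically zero for additive data and
isolates genuine pairwise structure; :func:`cell_means` keeps returning the
raw matrices that the classic interaction plot draws.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DesignMatrix
from .sn import MainEffectsTable, SNTable, main_effects

__all__ = [
    "InteractionSummary",
    "cell_means",
    "nonparallelism_score",
    "interaction_summary",
    "rank_pairs",
]

#: interacting-flag threshold, as a fraction of the larger factor delta
DEFAULT_THRESHOLD_FRACTION = 0.10

#: absolute floor (dB) below which a score is numerical noise, not signal
SCORE_NOISE_FLOOR_DB = 1e-9


def cell_means(
    dm: DesignMatrix, sn: SNTable, factor_a: str, factor_b: str
) -> pd.DataFrame:
    """3x3 matrix of mean S/N; rows = levels of ``factor_a``, cols of ``factor_b``."""
    if factor_a == factor_b:
        raise ValueError("factor_a and factor_b must differ")
    for f in (factor_a, factor_b):
        if f not in dm.factor_order:
            raise KeyError(f"factor {f!r} not in design")
    values = sn.sn.loc[dm.runs]
    ca, cb = dm.column(factor_a), dm.column(factor_b)
    mat = np.empty((3, 3))
    for i, j in itertools.product(range(3), range(3)):
        runs = ca.index[(ca == i + 1) & (cb == j + 1)]
        if len(runs) == 0:
            raise ValueError(
                f"empty cell ({i + 1},{j + 1}) for pair ({factor_a},{factor_b}); "
                "design is not strength-2 balanced"
            )
        mat[i, j] = float(values.loc[runs].mean())
    return pd.DataFrame(
        mat,
        index=pd.Index([1, 2, 3], name=factor_a),
        columns=pd.Index([1, 2, 3], name=factor_b),
    )


def nonparallelism_score(cells: pd.DataFrame | np.ndarray) -> float:
    """Max absolute non-additive residual of a cell-mean matrix, in dB.

    Zero iff the matrix is exactly additive, i.e. the two interaction-plot
    profile lines are exactly parallel.
    """
    m = np.asarray(cells, dtype=float)
    if not np.all(np.isfinite(m)):
        raise ValueError("cell means must be finite")
    resid = m - (
        m.mean(axis=1, keepdims=True) + m.mean(axis=0, keepdims=True) - m.mean()
    )
    return float(np.max(np.abs(resid)))


@dataclass
class InteractionSummary:
    """Non-parallelism screening of all factor pairs for one parameter."""

    species: str
    parameter: str
    pairs: pd.DataFrame = field(repr=False)
    # columns: factor_a, factor_b, score_db (alias-adjusted, drives the
    # flag), raw_score_db (non-parallelism of the plotted raw profiles),
    # threshold_db, interacting
    cells: dict[tuple[str, str], pd.DataFrame] = field(default_factory=dict, repr=False)


def interaction_summary(
    dm: DesignMatrix,
    sn: SNTable,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
    me: MainEffectsTable | None = None,
) -> InteractionSummary:
    """Score every factor pair of the design (15 pairs for 6 factors).

    Each pair's interacting threshold is ``threshold_fraction`` times the
    larger of the two factors' deltas, so the flag compares the pair's
    non-additive signal against the scale of its own main effects.
    """
    if threshold_fraction < 0:
        raise ValueError("threshold_fraction must be >= 0")
    if me is None:
        me = main_effects(dm, sn)
    deltas = me.table["delta_db"]
    # residual S/N: observed minus the additive main-effects prediction,
    # so aliased main effects cannot masquerade as pairwise interaction
    values = sn.sn.loc[dm.runs]
    residual = values - me.grand_mean_db
    for factor in dm.factor_order:
        level_effect = me.level_means(factor) - me.grand_mean_db
        residual = residual - dm.column(factor).map(
            {k: level_effect[k - 1] for k in (1, 2, 3)}
        )
    residual_sn = SNTable(sn.species, sn.parameter, residual, sn.criterion)
    rows = []
    cells = {}
    order = dm.factor_order
    for i, fa in enumerate(order):
        for fb in order[i + 1 :]:
            mat = cell_means(dm, sn, fa, fb)
            score = nonparallelism_score(cell_means(dm, residual_sn, fa, fb))
            thr = threshold_fraction * max(float(deltas[fa]), float(deltas[fb]))
            rows.append(
                {
                    "factor_a": fa,
                    "factor_b": fb,
                    "score_db": score,
                    "raw_score_db": nonparallelism_score(mat),
                    "threshold_db": thr,
                    "interacting": score > max(thr, SCORE_NOISE_FLOOR_DB),
                }
            )
            cells[(fa, fb)] = mat
    pairs = pd.DataFrame(rows)
    return InteractionSummary(sn.species, sn.parameter, pairs, cells)


def rank_pairs(
    summary: InteractionSummary, threshold: float | None = None
) -> pd.DataFrame:
    """Pairs sorted by descending score; ``interacting = score > threshold``.

    With ``threshold=None`` each pair keeps its own delta-scaled threshold
    from the summary; a numeric threshold (dB, >= 0) applies uniformly.
    """
    out = summary.pairs.sort_values(
        "score_db", ascending=False, kind="stable"
    ).reset_index(drop=True)
    if threshold is not None:
        if threshold < 0:
            raise ValueError("threshold must be >= 0")
        out["threshold_db"] = float(threshold)
        out["interacting"] = out["score_db"] > max(
            float(threshold), SCORE_NOISE_FLOOR_DB
        )
    return out
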