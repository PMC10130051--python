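"""Signal-to-noise ratios, main-effects tables, delta ranking, best levels.

The Taguchi analysis summarises each run's response as a dB-scale
signal-to-noise (S/N) ratio and then averages S/N over the nine runs at each
level of each factor.  Three classic criteria are provided:

- larger-is-better:   S/N = -10 log10( (1/n) sum 1/y_i^2 )
- smaller-is-better:  S/N = -10 log10( (1/n) sum y_i^2 )
- nominal-is-best:    S/N =  10 log10( ybar^2 / s^2 )

The study publishes one mean per run (n = 1), for which larger-is-better
reduces to ``20 log10(y)`` — a strictly monotone transform, so argmax
decisions on mean S/N per level coincide with argmax on mean log response.

Factor importance is ranked by *delta*, the range (max - min) of a factor's
three level-mean S/N values; rank 1 is the largest delta.  Ties are broken
by design-column order and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data import ResponseTable
from .design import DesignMatrix

__all__ = [
    "SNTable",
    "MainEffectsTable",
    "SNDomainError",
    "IncompleteDesignError",
    "sn_ratio",
    "compute_sn_table",
    "main_effects",
    "best_levels",
]

CRITERIA = ("larger", "smaller", "nominal")


class SNDomainError(ValueError):
    """Input values outside the domain of the requested S/N criterion."""


class IncompleteDesignError(ValueError):
    """Response table does not cover every design run."""


def sn_ratio(values: Sequence[float], criterion: str = "larger") -> float:
    """Signal-to-noise ratio in dB of one run's observation(s).

    For a single larger-is-better value this is ``20 log10(y)``.
    """
    y = np.asarray(values, dtype=float)
    if y.size == 0:
        raise SNDomainError("empty value list")
    if criterion == "larger":
        if np.any(y <= 0):
            raise SNDomainError(
                "larger-is-better S/N requires strictly positive values"
            )
        return float(-10.0 * np.log10(np.mean(1.0 / y**2)))
    if criterion == "smaller":
        return float(-10.0 * np.log10(np.mean(y**2)))
    if criterion == "nominal":
        if y.size < 2:
            raise SNDomainError("nominal-is-best S/N needs at least 2 values")
        s2 = float(np.var(y, ddof=1))
        if s2 == 0.0:
            raise SNDomainError("zero variance: nominal-is-best S/N is infinite")
        return float(10.0 * np.log10(np.mean(y) ** 2 / s2))
    raise ValueError(f"unknown criterion {criterion!r}; expected one of {CRITERIA}")


@dataclass
class SNTable:
    """Per-run S/N values (dB) for one parameter of one species."""

    species: str
    parameter: str
    sn: pd.Series = field(repr=False)  # indexed by run
    criterion: str = "larger"

    @property
    def runs(self) -> list[int]:
        return list(self.sn.index)


def compute_sn_table(
    responses: ResponseTable,
    parameter: str,
    criterion: str = "larger",
    runs: Iterable[int] = range(1, 28),
) -> SNTable:
    """S/N value of every run for one parameter.

    The study maximises every response, so the criterion defaults to
    larger-is-better.  All runs in ``runs`` (the full design by default)
    must be present.
    """
    values = responses.series(parameter)
    expected = list(runs)
    missing = sorted(set(expected) - set(values.index))
    if missing:
        raise IncompleteDesignError(
            f"parameter {parameter!r}: missing run(s) {missing}"
        )
    values = values.loc[expected]
    sn = values.map(lambda v: sn_ratio([v], criterion))
    sn.name = "sn_db"
    return SNTable(responses.species, parameter, sn, criterion)


@dataclass
class MainEffectsTable:
    """Per-factor level-mean S/N with delta ranking.

    ``table`` is indexed by factor (in design order) with columns
    ``level1_db, level2_db, level3_db, delta_db, rank, best_level,
    best_tied, delta_tied``.
    """

    parameter: str
    table: pd.DataFrame = field(repr=False)
    grand_mean_db: float = 0.0
    species: str = ""

    @property
    def factors(self) -> list[str]:
        return list(self.table.index)

    def level_means(self, factor: str) -> np.ndarray:
        row = self.table.loc[factor]
        return np.array([row["level1_db"], row["level2_db"], row["level3_db"]])


def main_effects(dm: DesignMatrix, sn: SNTable) -> MainEffectsTable:
    """Level-mean S/N, delta and rank for every factor of the design.

    On a balanced array each level mean averages 9 runs, so the unweighted
    mean of a factor's three level means equals the grand mean.  Delta ties
    are broken by design-column order (earlier column gets the better rank)
    and flagged in ``delta_tied``; best-level ties take the lowest level and
    are flagged in ``best_tied``.  Comparisons use exact dB values.
    """
    if set(dm.runs) != set(sn.runs):
        raise IncompleteDesignError(
            f"design runs and S/N runs differ: {sorted(set(dm.runs) ^ set(sn.runs))}"
        )
    values = sn.sn.loc[dm.runs]
    grand = float(values.mean())
    rows = []
    for factor in dm.factor_order:
        codes = dm.column(factor)
        means = [float(values[codes[codes == k].index].mean()) for k in (1, 2, 3)]
        delta = max(means) - min(means)
        best = int(np.argmin([-m for m in means])) + 1  # first (lowest) argmax
        rows.append(
            {
                "factor": factor,
                "level1_db": means[0],
                "level2_db": means[1],
                "level3_db": means[2],
                "delta_db": delta,
                "best_level": best,
                "best_tied": means.count(max(means)) > 1,
            }
        )
    table = pd.DataFrame(rows).set_index("factor")
    # rank 1 = largest delta; ties keep design-column order (stable sort)
    order = table["delta_db"].to_numpy()
    rank = np.empty(len(order), dtype=int)
    rank[np.argsort(-order, kind="stable")] = np.arange(1, len(order) + 1)
    table["rank"] = rank
    deltas = list(table["delta_db"])
    table["delta_tied"] = [deltas.count(d) > 1 for d in deltas]
    return MainEffectsTable(sn.parameter, table, grand, sn.species)


def best_levels(me: MainEffectsTable) -> dict[str, int]:
    """Coded level with maximal mean S/N per factor (ties -> lowest level)."""
    return {f: int(me.table.loc[f, "best_level"]) for f in me.factors}
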