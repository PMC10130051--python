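"""Additive optimum prediction and confirmation-test error.

The Taguchi optimum prediction assumes main effects add on the S/N scale:

    eta_hat = eta_bar + sum_f ( m[f, level(f)] - eta_bar )

where ``eta_bar`` is the grand-mean S/N and ``m[f, k]`` the mean S/N at
level ``k`` of factor ``f``.  With one observation per run and the
larger-is-better criterion, S/N = 20 log10(y), so a predicted S/N maps back
to response units via ``y = 10^(S/N / 20)``.

A confirmation run at the predicted optimum yields the "expected" value;
its relative deviation from the prediction,

    error % = 100 * |expected - predicted| / expected,

is the study's figure of merit for the whole procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .design import FACTORS, FactorSpec
from .sn import MainEffectsTable, best_levels

__all__ = [
    "OptimumPrediction",
    "predict_sn_optimum",
    "predict_response",
    "confirmation_error",
    "predict_optimum",
]


def predict_sn_optimum(me: MainEffectsTable, levels: Mapping[str, int]) -> float:
    """Additive-model S/N (dB) at the factor setting ``levels``."""
    missing = [f for f in me.factors if f not in levels]
    if missing:
        raise KeyError(f"no level given for factor(s) {missing}")
    eta = me.grand_mean_db
    for factor in me.factors:
        level = levels[factor]
        if level not in (1, 2, 3):
            raise KeyError(f"factor {factor!r}: invalid level {level!r}")
        eta += float(me.level_means(factor)[level - 1]) - me.grand_mean_db
    return float(eta)


def predict_response(sn_db: float) -> float:
    """Back-transform a larger-is-better S/N at n = 1 to response units."""
    return float(10.0 ** (sn_db / 20.0))


def confirmation_error(expected: float, predicted: float) -> float:
    """Relative error percent between a confirmation run and the prediction.

    ``100 * |expected - predicted| / expected``; reports round to 2 decimals,
    the computation does not.
    """
    if expected <= 0:
        raise ValueError(f"expected value must be positive, got {expected}")
    return float(100.0 * abs(expected - predicted) / expected)


@dataclass
class OptimumPrediction:
    """Predicted optimum setting and response for one parameter."""

    species: str
    parameter: str
    levels: dict[str, int]                  # coded best level per factor
    physical: dict[str, object]             # decoded physical settings
    predicted_sn_db: float
    predicted_response: float
    expected_response: float | None = None  # confirmation-run measurement
    error_pct: float | None = field(default=None)

    def __post_init__(self) -> None:
        if self.expected_response is not None and self.error_pct is None:
            self.error_pct = confirmation_error(
                self.expected_response, self.predicted_response
            )


def predict_optimum(
    me: MainEffectsTable,
    factors: Sequence[FactorSpec] = FACTORS,
    expected_response: float | None = None,
) -> OptimumPrediction:
    """Best level per factor plus the additive S/N and response prediction."""
    levels = best_levels(me)
    by_name = {f.name: f for f in factors}
    physical = {f: by_name[f].physical(k) for f, k in levels.items() if f in by_name}
    sn_db = predict_sn_optimum(me, levels)
    return OptimumPrediction(
        species=me.species,
        parameter=me.parameter,
        levels=levels,
        physical=physical,
        predicted_sn_db=sn_db,
        predicted_response=predict_response(sn_db),
        expected_response=expected_response,
    )
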