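"""L27(3^6) orthogonal-array construction, validation and level decoding.

The 27-run, three-level Taguchi array is built from the base-3 expansion of
the run index: run ``i`` (0-based) has base digits ``a = i // 9``,
``b = (i // 3) % 3`` and ``c = i % 3``, and every array column is a linear
form ``x*a + y*b + z*c (mod 3)`` over GF(3).  Two columns are orthogonal of
strength 2 exactly when their coefficient vectors are linearly independent,
so up to 13 mutually orthogonal three-level columns exist (one per projective
direction of GF(3)^3).

The first six coefficient vectors in :data:`L27_COLUMNS` are fixed to the
column assignment of the study design this package reproduces (CO2 slowest,
night temperature fastest); the remaining seven are the other projective
directions, used when more factors are requested.
"""

from __future__ import annotations

import numbers
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FactorSpec",
    "DesignMatrix",
    "FACTORS",
    "FACTOR_NAMES",
    "LED_PPFD",
    "L27_COLUMNS",
    "DesignError",
    "InvalidCodingError",
    "CapacityError",
    "BalanceReport",
    "generate_l27",
    "validate_orthogonality",
    "decode_levels",
    "encode_levels",
    "read_design",
    "write_design",
    "read_factor_catalog",
    "write_factor_catalog",
]


class DesignError(ValueError):
    """Invalid design matrix or factor specification."""


class InvalidCodingError(DesignError):
    """A design cell holds a value outside the coded level set {1, 2, 3}."""


class CapacityError(DesignError):
    """More columns requested than the 27-run array can host (13)."""


# GF(3) coefficient vectors (on the base digits a, b, c of the run index),
# one per column.  The first six reproduce the study's printed trial matrix
# cell-for-cell; the rest are the remaining projective directions of GF(3)^3.
L27_COLUMNS: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0),  # CO2: changes every 9 runs
    (0, 1, 0),  # LED: changes every 3 runs
    (1, 1, 0),  # EC
    (2, 1, 0),  # day temperature
    (0, 0, 1),  # night temperature: changes every run
    (1, 0, 1),  # relative humidity
    (0, 1, 1),
    (0, 1, 2),
    (1, 0, 2),
    (1, 1, 1),
    (1, 1, 2),
    (1, 2, 1),
    (1, 2, 2),
)

FACTOR_NAMES: tuple[str, ...] = (
    "co2",
    "led",
    "ec",
    "day_temp",
    "night_temp",
    "humidity",
)


@dataclass(frozen=True)
class FactorSpec:
    """One controllable factor with its three physical level values.

    Parameters
    ----------
    name
        Short identifier (e.g. ``"ec"``).
    levels
        Ordered triple of physical values for coded levels 1..3.  Numeric
        levels must be strictly increasing; label levels (e.g. LED recipe
        names) only need to be distinct.
    units
        Unit string carried as metadata (``ppm``, ``dS m^-1`` ...).
    """

    name: str
    levels: tuple
    units: str = ""

    def __post_init__(self) -> None:
        levels = tuple(self.levels)
        object.__setattr__(self, "levels", levels)
        if len(levels) != 3:
            raise DesignError(f"factor {self.name!r}: exactly 3 levels required")
        if len(set(levels)) != 3:
            raise DesignError(f"factor {self.name!r}: levels must be distinct")
        if all(isinstance(v, numbers.Real) for v in levels):
            if not (levels[0] < levels[1] < levels[2]):
                raise DesignError(
                    f"factor {self.name!r}: numeric levels must be strictly increasing"
                )

    def physical(self, coded: int):
        """Physical value for coded level ``coded`` in {1, 2, 3}."""
        if coded not in (1, 2, 3):
            raise InvalidCodingError(f"coded level {coded!r} outside {{1,2,3}}")
        return self.levels[coded - 1]

    def encode(self, value) -> int:
        """Coded level (1..3) of a physical value."""
        try:
            return self.levels.index(value) + 1
        except ValueError:
            raise DesignError(
                f"value {value!r} is not a level of factor {self.name!r}"
            ) from None


#: The study's factor catalog: six environmental factors, three levels each.
#: LED recipes: W = white only, WRF = white + deep red + far red; the trailing
#: number is the PPFD (photosynthetic photon flux density) in umol m^-2 s^-1.
FACTORS: tuple[FactorSpec, ...] = (
    FactorSpec("co2", (400, 600, 800), "ppm"),
    FactorSpec("led", ("W122", "WRF122", "WRF244"), "recipe"),
    FactorSpec("ec", (0.7, 0.9, 1.2), "dS m^-1"),
    FactorSpec("day_temp", (15, 22, 26), "degC"),
    FactorSpec("night_temp", (10, 15, 20), "degC"),
    FactorSpec("humidity", (35, 55, 75), "%"),
)

#: PPFD component of each LED recipe label.
LED_PPFD: dict[str, int] = {"W122": 122, "WRF122": 122, "WRF244": 244}


@dataclass
class DesignMatrix:
    """Coded run matrix: rows are runs 1..n, cells are levels in {1, 2, 3}."""

    codes: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.codes.empty:
            raise DesignError("design matrix is empty")
        self.codes = self.codes.astype(int)
        self.codes.index.name = "run"
        for run, row in self.codes.iterrows():
            for factor, cell in row.items():
                if cell not in (1, 2, 3):
                    raise InvalidCodingError(
                        f"run {run}, factor {factor!r}: coded level {cell} "
                        "outside {1,2,3}"
                    )

    @property
    def factor_order(self) -> list[str]:
        return list(self.codes.columns)

    @property
    def runs(self) -> list[int]:
        return list(self.codes.index)

    @property
    def n_runs(self) -> int:
        return len(self.codes)

    def column(self, factor: str) -> pd.Series:
        return self.codes[factor]

    def __eq__(self, other) -> bool:  # cell-for-cell identity
        return isinstance(other, DesignMatrix) and self.codes.equals(other.codes)


def generate_l27(n_factors: int = 6) -> DesignMatrix:
    """Build the 27-run strength-2 orthogonal array for ``n_factors`` columns.

    Deterministic and seed-free.  For ``n_factors = 6`` the result equals the
    study's printed trial matrix row-for-row (run 1 = (1,1,1,1,1,1), run 27 =
    (3,3,2,1,3,2)); extra columns up to 13 use the remaining orthogonal
    directions.
    """
    if n_factors < 1:
        raise DesignError("n_factors must be >= 1")
    if n_factors > len(L27_COLUMNS):
        raise CapacityError(
            f"L27 supports at most {len(L27_COLUMNS)} three-level columns, "
            f"got {n_factors}"
        )
    idx = np.arange(27)
    base = np.stack([idx // 9, (idx // 3) % 3, idx % 3], axis=1)
    cols = {}
    for j in range(n_factors):
        name = FACTOR_NAMES[j] if j < len(FACTOR_NAMES) else f"f{j + 1}"
        cols[name] = (base @ np.array(L27_COLUMNS[j])) % 3 + 1
    codes = pd.DataFrame(cols, index=pd.RangeIndex(1, 28, name="run"))
    return DesignMatrix(codes)


@dataclass
class BalanceReport:
    """Outcome of the orthogonality audit of a design matrix."""

    level_counts: pd.DataFrame          # factor x level occurrence counts
    pair_counts: dict[tuple[str, str], pd.DataFrame]
    unbalanced_columns: list[str]
    unbalanced_pairs: list[tuple[str, str]]

    @property
    def passed(self) -> bool:
        return not self.unbalanced_columns and not self.unbalanced_pairs


def validate_orthogonality(dm: DesignMatrix) -> BalanceReport:
    """Audit level balance and strength-2 pair balance by exhaustive counting.

    Each column of a valid 27-run array holds every level exactly 9 times and
    each ordered level pair of any two columns occurs exactly 3 times.
    """
    n = dm.n_runs
    per_level, per_pair = n // 3, n // 9
    levels = [1, 2, 3]
    counts = pd.DataFrame(
        {f: [int((dm.codes[f] == k).sum()) for k in levels] for f in dm.factor_order},
        index=pd.Index(levels, name="level"),
    ).T
    bad_cols = [f for f in dm.factor_order if not (counts.loc[f] == per_level).all()]
    pair_counts: dict[tuple[str, str], pd.DataFrame] = {}
    bad_pairs: list[tuple[str, str]] = []
    order = dm.factor_order
    for i, fa in enumerate(order):
        for fb in order[i + 1 :]:
            tab = pd.crosstab(dm.codes[fa], dm.codes[fb]).reindex(
                index=levels, columns=levels, fill_value=0
            )
            pair_counts[(fa, fb)] = tab
            if not (tab.to_numpy() == per_pair).all():
                bad_pairs.append((fa, fb))
    return BalanceReport(counts, pair_counts, bad_cols, bad_pairs)


def _match_factors(dm: DesignMatrix, factors: Sequence[FactorSpec]) -> list[FactorSpec]:
    by_name = {f.name: f for f in factors}
    missing = [f for f in dm.factor_order if f not in by_name]
    if missing:
        raise DesignError(f"no FactorSpec for design column(s) {missing}")
    return [by_name[f] for f in dm.factor_order]


def decode_levels(
    dm: DesignMatrix, factors: Sequence[FactorSpec] = FACTORS
) -> pd.DataFrame:
    """Replace coded levels by the matching factor's physical values.

    The result is invertible back to ``dm`` via :func:`encode_levels`.
    """
    specs = _match_factors(dm, factors)
    out = {}
    for spec in specs:
        out[spec.name] = [spec.physical(int(c)) for c in dm.codes[spec.name]]
    return pd.DataFrame(out, index=dm.codes.index.copy())


def encode_levels(
    physical: pd.DataFrame, factors: Sequence[FactorSpec] = FACTORS
) -> DesignMatrix:
    """Inverse of :func:`decode_levels`: physical values back to coded levels."""
    by_name = {f.name: f for f in factors}
    cols = {}
    for name in physical.columns:
        if name not in by_name:
            raise DesignError(f"no FactorSpec for column {name!r}")
        cols[name] = [by_name[name].encode(v) for v in physical[name]]
    return DesignMatrix(pd.DataFrame(cols, index=physical.index.copy()))


def write_design(dm: DesignMatrix, path: str | Path) -> None:
    """Write the coded design as CSV (``run,co2,led,...``)."""
    dm.codes.to_csv(path)


def read_design(path: str | Path) -> DesignMatrix:
    codes = pd.read_csv(path, comment="#", index_col="run")
    return DesignMatrix(codes)


def write_factor_catalog(
    factors: Sequence[FactorSpec], path: str | Path
) -> None:
    """Save a factor catalog as YAML (name -> levels, units)."""
    import yaml

    payload = {
        f.name: {"levels": list(f.levels), "units": f.units} for f in factors
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_factor_catalog(path: str | Path) -> tuple[FactorSpec, ...]:
    """Load a YAML factor catalog written by :func:`write_factor_catalog`."""
    import yaml

    payload = yaml.safe_load(Path(path).read_text())
    return tuple(
        FactorSpec(name, tuple(entry["levels"]), entry.get("units", ""))
        for name, entry in payload.items()
    )
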