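"""Response-table data model, packaged study fixtures and CSV I/O.

Measurements live in long format: one row per (species, run, parameter,
value).  The packaged fixtures transcribe the study's published 27-run mean
tables for lettuce and basil — seven growth/chlorophyll parameters and ten
leaf micro/macro elements per species, each value the mean of three
replicates (raw replicates are not published, so every downstream
signal-to-noise computation treats each run as a single observation).
See ``fixtures/provenance.md`` for how ambiguous printed cells were resolved.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "PARAMETER_CATALOG",
    "GROWTH_PARAMETERS",
    "ELEMENT_PARAMETERS",
    "ResponseTable",
    "ResponseValidationError",
    "load_fixture",
    "load_confirmation",
    "read_responses",
    "write_responses",
]


class ResponseValidationError(ValueError):
    """One or more response records violate the table schema.

    ``errors`` lists every problem found (with row numbers where known),
    not just the first.
    """

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


#: parameter name -> (units, group)
PARAMETER_CATALOG: dict[str, tuple[str, str]] = {
    "no_leaf": ("count", "growth"),
    "leaf_area": ("cm^2", "growth"),
    "fresh_leaf": ("g", "growth"),
    "dry_leaf": ("g", "growth"),
    "fresh_root": ("g", "growth"),
    "dry_root": ("g", "growth"),
    "chlorophyll": ("mg g^-1 FW", "chlorophyll"),
    "Fe": ("mg kg^-1 DW", "micro_element"),
    "Zn": ("mg kg^-1 DW", "micro_element"),
    "Cu": ("mg kg^-1 DW", "micro_element"),
    "Mn": ("mg kg^-1 DW", "micro_element"),
    "B": ("mg kg^-1 DW", "micro_element"),
    "N": ("% DW", "macro_element"),
    "P": ("% DW", "macro_element"),
    "K": ("% DW", "macro_element"),
    "Ca": ("% DW", "macro_element"),
    "Mg": ("% DW", "macro_element"),
}

GROWTH_PARAMETERS = tuple(
    p for p, (_, g) in PARAMETER_CATALOG.items() if g in ("growth", "chlorophyll")
)
ELEMENT_PARAMETERS = tuple(
    p for p, (_, g) in PARAMETER_CATALOG.items() if g.endswith("_element")
)

SPECIES = ("lettuce", "basil")

# fixture file per (species, table)
_FIXTURE_FILES = {
    ("lettuce", "growth"): "lettuce_growth.csv",
    ("basil", "growth"): "basil_growth.csv",
    ("lettuce", "elements"): "lettuce_elements.csv",
    ("basil", "elements"): "basil_elements.csv",
}


@dataclass
class ResponseTable:
    """Long-format measurement table for one species.

    ``records`` columns: ``run`` (int), ``parameter`` (str), ``value``
    (float).  ``replicate_semantics`` records whether each value is a
    published mean of three replicates or a single observation.
    """

    species: str
    records: pd.DataFrame = field(repr=False)
    replicate_semantics: str = "mean_of_3"

    def __post_init__(self) -> None:
        errors = _validate_records(self.records)
        if errors:
            raise ResponseValidationError(errors)
        self.records = (
            self.records[["run", "parameter", "value"]]
            .astype({"run": int, "value": float})
            .reset_index(drop=True)
        )

    @property
    def parameters(self) -> list[str]:
        return list(dict.fromkeys(self.records["parameter"]))

    @property
    def runs(self) -> list[int]:
        return sorted(self.records["run"].unique())

    def value(self, run: int, parameter: str) -> float:
        sel = self.records[
            (self.records["run"] == run) & (self.records["parameter"] == parameter)
        ]
        if sel.empty:
            raise KeyError(f"no value for run {run}, parameter {parameter!r}")
        return float(sel["value"].iloc[0])

    def series(self, parameter: str) -> pd.Series:
        """All runs' values for one parameter, indexed by run."""
        sel = self.records[self.records["parameter"] == parameter]
        if sel.empty:
            raise KeyError(f"parameter {parameter!r} not in table")
        return sel.set_index("run")["value"].sort_index()

    def subset(self, parameters: Iterable[str]) -> "ResponseTable":
        keep = set(parameters)
        return ResponseTable(
            self.species,
            self.records[self.records["parameter"].isin(keep)].copy(),
            self.replicate_semantics,
        )


def _validate_records(records: pd.DataFrame) -> list[str]:
    errors: list[str] = []
    required = {"run", "parameter", "value"}
    missing = required - set(records.columns)
    if missing:
        return [f"missing column(s) {sorted(missing)}"]
    dup = records.duplicated(subset=["run", "parameter"], keep=False)
    if dup.any():
        for (run, par), grp in records[dup].groupby(["run", "parameter"]):
            rows = ", ".join(str(i + 2) for i in grp.index)  # header = row 1
            errors.append(
                f"duplicate (run {run}, parameter {par!r}) at CSV rows {rows}"
            )
    for i, row in records.iterrows():
        try:
            v = float(row["value"])
        except (TypeError, ValueError):
            errors.append(f"row {i + 2}: non-numeric value {row['value']!r}")
            continue
        if v <= 0:
            errors.append(
                f"row {i + 2}: non-positive value {v} for (run {row['run']}, "
                f"{row['parameter']!r}); larger-is-better analysis needs y > 0"
            )
        run = row["run"]
        if not float(run).is_integer() or not 1 <= int(run):
            errors.append(f"row {i + 2}: invalid run identifier {run!r}")
    return errors


def _fixture_path(name: str) -> Path:
    return Path(str(importlib.resources.files("taguchigrow") / "fixtures" / name))


def load_fixture(species: str, group: str = "all") -> ResponseTable:
    """Load a packaged 27-run study table.

    Parameters
    ----------
    species
        ``"lettuce"`` or ``"basil"``.
    group
        ``"growth"`` (growth parameters + chlorophyll), ``"elements"``
        (ten leaf micro/macro elements), ``"all"``, or a fine-grained
        catalog group (``"chlorophyll"``, ``"micro_element"``,
        ``"macro_element"``).
    """
    if species not in SPECIES:
        raise KeyError(f"unknown species {species!r}; expected one of {SPECIES}")
    fine = None
    if group in ("chlorophyll",):
        table_keys, fine = ["growth"], group
    elif group in ("micro_element", "macro_element"):
        table_keys, fine = ["elements"], group
    elif group == "growth":
        table_keys = ["growth"]
    elif group == "elements":
        table_keys = ["elements"]
    elif group == "all":
        table_keys = ["growth", "elements"]
    else:
        raise KeyError(f"unknown parameter group {group!r}")
    frames = [
        pd.read_csv(_fixture_path(_FIXTURE_FILES[(species, k)])) for k in table_keys
    ]
    records = pd.concat(frames, ignore_index=True)
    if fine is not None:
        keep = [p for p, (_, g) in PARAMETER_CATALOG.items() if g == fine]
        records = records[records["parameter"].isin(keep)]
    return ResponseTable(species, records.drop(columns="species"))


def load_confirmation() -> pd.DataFrame:
    """Published confirmation-test summary (both species).

    Columns: ``species, parameter, sn_db, expected, predicted, error_pct``,
    exactly as printed in the study.  ``expected`` is the confirmation-run
    measurement at the predicted optimum; ``predicted`` the additive-model
    value; ``error_pct`` the reported relative error.
    """
    return pd.read_csv(_fixture_path("confirmation.csv"))


def read_responses(path: str | Path, species: str | None = None) -> ResponseTable:
    """Read a response CSV (``species,run,parameter,value`` or without the
    species column when ``species`` is given).

    Validation problems are aggregated into a single
    :class:`ResponseValidationError` listing every offending row.
    """
    df = pd.read_csv(path, comment="#")
    if "species" in df.columns:
        found = df["species"].unique()
        if species is None:
            if len(found) != 1:
                raise ResponseValidationError(
                    [f"file holds multiple species {sorted(found)}; pass species="]
                )
            species = str(found[0])
        else:
            df = df[df["species"] == species]
        df = df.drop(columns="species")
    elif species is None:
        raise ResponseValidationError(["no species column and none given"])
    return ResponseTable(species, df)


def write_responses(table: ResponseTable, path: str | Path) -> None:
    """Write a response table as ``species,run,parameter,value`` CSV."""
    out = table.records.copy()
    out.insert(0, "species", table.species)
    out.to_csv(path, index=False)
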