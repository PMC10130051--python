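"""Chlorophyll quantification from acetone-extract absorbance readings.

Implements the study's printed equations verbatim:

    chl_a = (12.25 * A663.2 - A646.8) * V / (1000 * W)
    chl_b = (25.51 * A646.8 - A663.2) * V / (1000 * W)
    chl   = chl_b - chl_a            ("as_printed" total)

with V the extract volume (mL) and W the fresh sample mass (g); the result
is mg per g fresh weight.  The printed ``V/1000 x W`` is read as
``V / (1000 * W)`` — the only dimensionally sensible form for a per-gram
concentration.

The printed total (chl_b - chl_a) and the coefficient values differ from
the conventional spectrophotometric equations; a ``"sum"`` mode
(chl_a + chl_b) is provided alongside the literal ``"as_printed"`` mode
rather than silently correcting the source.  Negative concentrations are
possible when one absorbance dominates; they are flagged, never clamped.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "AbsorbanceRecord",
    "chl_a",
    "chl_b",
    "chl_total",
    "process_absorbance",
    "read_absorbance",
]

TOTAL_MODES = ("as_printed", "sum")


@dataclass(frozen=True)
class AbsorbanceRecord:
    """One spectrophotometer reading of an 80 % acetone extract.

    ``a663_2``/``a646_8``: absorbances at 663.2 / 646.8 nm (dimensionless);
    ``volume_ml``: extract volume V in mL; ``mass_g``: fresh mass W in g.
    """

    a663_2: float
    a646_8: float
    volume_ml: float = 5.0
    mass_g: float = 0.1

    def __post_init__(self) -> None:
        if self.a663_2 < 0 or self.a646_8 < 0:
            raise ValueError("absorbances must be >= 0")
        if self.volume_ml <= 0:
            raise ValueError("extract volume must be > 0")
        if self.mass_g <= 0:
            raise ValueError("sample mass must be > 0")

    @property
    def _norm(self) -> float:
        return self.volume_ml / (1000.0 * self.mass_g)


def chl_a(rec: AbsorbanceRecord) -> float:
    """Chlorophyll a, mg per g fresh weight."""
    return (12.25 * rec.a663_2 - rec.a646_8) * rec._norm


def chl_b(rec: AbsorbanceRecord) -> float:
    """Chlorophyll b, mg per g fresh weight."""
    return (25.51 * rec.a646_8 - rec.a663_2) * rec._norm


def chl_total(rec: AbsorbanceRecord, mode: str = "as_printed") -> float:
    """Total chlorophyll: ``chl_b - chl_a`` (as_printed) or ``chl_a + chl_b`` (sum)."""
    if mode not in TOTAL_MODES:
        raise ValueError(f"mode must be one of {TOTAL_MODES}, got {mode!r}")
    a, b = chl_a(rec), chl_b(rec)
    return b - a if mode == "as_printed" else a + b


def process_absorbance(df: pd.DataFrame, mode: str = "as_printed") -> pd.DataFrame:
    """Batch-evaluate an absorbance table.

    Input columns: ``sample_id, a663_2, a646_8, volume_ml, mass_g``.
    Output adds ``chl_a, chl_b, chl_total, total_mode, quality_flag``;
    the flag is ``"negative"`` when any concentration is below zero.
    """
    rows = []
    for _, r in df.iterrows():
        rec = AbsorbanceRecord(
            float(r["a663_2"]),
            float(r["a646_8"]),
            float(r["volume_ml"]),
            float(r["mass_g"]),
        )
        a, b = chl_a(rec), chl_b(rec)
        tot = chl_total(rec, mode)
        rows.append(
            {
                **r,
                "chl_a": a,
                "chl_b": b,
                "chl_total": tot,
                "total_mode": mode,
                "quality_flag": "negative" if min(a, b, tot) < 0 else "ok",
            }
        )
    return pd.DataFrame(rows)


def read_absorbance(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
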