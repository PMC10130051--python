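"""End-to-end analysis bundle and reproduction report.

``run_full_analysis`` ties the stages together for every parameter of both
species: per-run S/N, main-effects/delta ranking, best levels, additive
optimum prediction and interaction screening, plus a machine-readable
``reproduction.json`` that compares the computed best physical levels for
the headline fresh-leaf responses against the study's stated optima
(lettuce: EC 0.9 dS m^-1, LED WRF244, day/night 15/10 degC, RH 75 %;
basil: EC 1.2 dS m^-1, LED WRF244, day/night 26/20 degC, RH 55 %).

Artifacts are deterministic: every file carries the package version and the
SHA-256 of the input tables in a metadata header, and timestamps go only to
the log.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .data import ResponseTable, load_fixture
from .design import FACTORS, DesignMatrix, generate_l27
from .interactions import InteractionSummary, interaction_summary, rank_pairs
from .optimum import OptimumPrediction, predict_optimum
from .sn import IncompleteDesignError, MainEffectsTable, compute_sn_table, main_effects

__all__ = [
    "AnalysisConfig",
    "AnalysisBundle",
    "ConfigurationError",
    "REPRODUCTION_CLAIMS",
    "run_full_analysis",
]

logger = logging.getLogger("taguchigrow")


class ConfigurationError(ValueError):
    """Invalid analysis configuration (raised before any computation)."""


#: Stated optimal physical settings for the headline fresh-leaf response.
REPRODUCTION_CLAIMS: dict[str, dict[str, object]] = {
    "lettuce": {
        "ec": 0.9,
        "led": "WRF244",
        "day_temp": 15,
        "night_temp": 10,
        "humidity": 75,
    },
    "basil": {
        "ec": 1.2,
        "led": "WRF244",
        "day_temp": 26,
        "night_temp": 20,
        "humidity": 55,
    },
}
_CLAIM_PARAMETER = "fresh_leaf"


@dataclass
class AnalysisConfig:
    """Configuration for the end-to-end pipeline."""

    species: Sequence[str] = ("lettuce", "basil")
    parameters: Sequence[str] | None = None      # None = every fixture parameter
    criterion: str = "larger"
    interaction_threshold_fraction: float = 0.10
    chlorophyll_mode: str = "as_printed"
    out_dir: str | Path | None = None
    formats: Sequence[str] = ("csv", "json")
    responses: Mapping[str, ResponseTable] | None = None  # None = packaged fixtures

    def validate(self) -> None:
        from .chlorophyll import TOTAL_MODES
        from .sn import CRITERIA

        if self.criterion not in CRITERIA:
            raise ConfigurationError(f"unknown criterion {self.criterion!r}")
        if self.interaction_threshold_fraction < 0:
            raise ConfigurationError("interaction threshold must be >= 0")
        if self.chlorophyll_mode not in TOTAL_MODES:
            raise ConfigurationError(
                f"unknown chlorophyll mode {self.chlorophyll_mode!r}"
            )
        bad = [f for f in self.formats if f not in ("csv", "json")]
        if bad:
            raise ConfigurationError(f"unknown format(s) {bad}")
        if self.responses is None:
            unknown = [s for s in self.species if s not in ("lettuce", "basil")]
            if unknown:
                raise ConfigurationError(
                    f"no packaged fixture for species {unknown}"
                )


@dataclass
class AnalysisBundle:
    """Everything the pipeline computes, keyed by (species, parameter)."""

    design: DesignMatrix
    main_effects: dict[tuple[str, str], MainEffectsTable]
    predictions: dict[tuple[str, str], OptimumPrediction]
    interactions: dict[tuple[str, str], InteractionSummary]
    reproduction: dict
    skipped: list[dict] = field(default_factory=list)


def _input_checksums(responses: Mapping[str, ResponseTable]) -> dict[str, str]:
    out = {}
    for species, table in sorted(responses.items()):
        csv_bytes = table.records.to_csv(index=False).encode()
        out[species] = hashlib.sha256(csv_bytes).hexdigest()
    return out


def _metadata(checksums: dict[str, str]) -> dict:
    return {"package": "taguchigrow", "version": __version__, "inputs_sha256": checksums}


def run_full_analysis(config: AnalysisConfig) -> AnalysisBundle:
    """Run S/N analysis, optimum prediction and interaction screening.

    Parameters missing runs are skipped with a logged reason rather than
    aborting the bundle.  When ``config.out_dir`` is set, writes
    ``main_effects.csv``, ``predictions.(csv|json)``, ``interactions.csv``
    and ``reproduction.json``.
    """
    config.validate()
    dm = generate_l27(6)
    responses = config.responses or {
        s: load_fixture(s, "all") for s in config.species
    }
    me_all: dict[tuple[str, str], MainEffectsTable] = {}
    pred_all: dict[tuple[str, str], OptimumPrediction] = {}
    inter_all: dict[tuple[str, str], InteractionSummary] = {}
    skipped: list[dict] = []
    for species in config.species:
        table = responses[species]
        params = config.parameters or table.parameters
        for parameter in params:
            try:
                sn = compute_sn_table(table, parameter, config.criterion)
            except (IncompleteDesignError, KeyError) as exc:
                reason = str(exc)
                skipped.append(
                    {"species": species, "parameter": parameter, "reason": reason}
                )
                logger.warning("skip %s/%s: %s", species, parameter, reason)
                continue
            me = main_effects(dm, sn)
            me_all[(species, parameter)] = me
            pred_all[(species, parameter)] = predict_optimum(me, FACTORS)
            inter_all[(species, parameter)] = interaction_summary(
                dm, sn, config.interaction_threshold_fraction, me
            )
            logger.info(
                "analyzed %s/%s: %d runs, top factor %s",
                species,
                parameter,
                len(sn.runs),
                me.table["rank"].idxmin(),
            )
    reproduction = _reproduction_report(pred_all, _input_checksums(responses))
    bundle = AnalysisBundle(dm, me_all, pred_all, inter_all, reproduction, skipped)
    if config.out_dir is not None:
        _write_bundle(bundle, config)
    return bundle


def _reproduction_report(
    predictions: Mapping[tuple[str, str], OptimumPrediction],
    checksums: dict[str, str],
) -> dict:
    checks = []
    for species, claims in REPRODUCTION_CLAIMS.items():
        key = (species, _CLAIM_PARAMETER)
        if key not in predictions:
            continue
        physical = predictions[key].physical
        for factor, claimed in claims.items():
            computed = physical[factor]
            checks.append(
                {
                    "species": species,
                    "parameter": _CLAIM_PARAMETER,
                    "factor": factor,
                    "claimed": claimed,
                    "computed": computed,
                    "match": computed == claimed,
                }
            )
    return {
        **_metadata(checksums),
        "checks": checks,
        "all_match": all(c["match"] for c in checks) and bool(checks),
    }


def _csv_header(checksums: dict[str, str]) -> str:
    sums = ",".join(f"{k}={v}" for k, v in checksums.items())
    return f"# taguchigrow {__version__}\n# inputs_sha256: {sums}\n"


def _write_bundle(bundle: AnalysisBundle, config: AnalysisConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    checksums = bundle.reproduction["inputs_sha256"]
    header = _csv_header(checksums)

    me_rows = []
    for (species, parameter), me in bundle.main_effects.items():
        for factor in me.factors:
            r = me.table.loc[factor]
            me_rows.append(
                {
                    "species": species,
                    "parameter": parameter,
                    "factor": factor,
                    "level1_db": r["level1_db"],
                    "level2_db": r["level2_db"],
                    "level3_db": r["level3_db"],
                    "delta_db": r["delta_db"],
                    "rank": int(r["rank"]),
                }
            )
    pred_rows = []
    for (species, parameter), p in bundle.predictions.items():
        row = {"species": species, "parameter": parameter}
        row.update({f"level_{f}": k for f, k in p.levels.items()})
        row.update({f"physical_{f}": v for f, v in p.physical.items()})
        row["predicted_sn_db"] = p.predicted_sn_db
        row["predicted_response"] = p.predicted_response
        pred_rows.append(row)
    inter_rows = []
    for (species, parameter), s in bundle.interactions.items():
        ranked = rank_pairs(s)
        ranked.insert(0, "parameter", parameter)
        ranked.insert(0, "species", species)
        inter_rows.append(ranked)

    if "csv" in config.formats:
        for name, frame in (
            ("main_effects.csv", pd.DataFrame(me_rows)),
            ("predictions.csv", pd.DataFrame(pred_rows)),
            ("interactions.csv", pd.concat(inter_rows, ignore_index=True)),
        ):
            path = out / name
            path.write_text(header + frame.to_csv(index=False))
    if "json" in config.formats:
        payload = {**_metadata(checksums), "predictions": pred_rows}
        (out / "predictions.json").write_text(json.dumps(payload, indent=2) + "\n")
    (out / "reproduction.json").write_text(
        json.dumps(bundle.reproduction, indent=2, sort_keys=True) + "\n"
    )
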