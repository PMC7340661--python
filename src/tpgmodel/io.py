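"""Cohort-table serialization, run configuration and manifests.

Cohort tables travel as UTF-8 comma-delimited text with the canonical
header (see :data:`tpgmodel.cohort.COHORT_COLUMNS`); unknown columns are
preserved verbatim. Configs, fit reports and evaluation reports are flat
JSON documents; every CLI run drops a manifest (config snapshot, seed,
package version, timestamp) next to its outputs so any output file can
be regenerated from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, Union

import pandas as pd

from . import __version__
from .cohort import COHORT_COLUMNS, CohortConfig
from .evaluation import EvaluationReport
from .fitting import FitResult
from .hemodynamics import ModelCoefficients

__all__ = [
    "read_cohort",
    "write_cohort",
    "write_manifest",
    "coefficients_to_dict",
    "coefficients_from_dict",
    "write_fit_report",
    "write_evaluation_report",
]

_NUMERIC = ["multiplier", "ava_cm2", "q_l_s", "v_max_m_s", "tpg_true_mmhg"]
_MANDATORY = COHORT_COLUMNS


def write_cohort(records: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a cohort table as CSV, canonical columns first."""
    extras = [c for c in records.columns if c not in COHORT_COLUMNS]
    records[COHORT_COLUMNS + extras].to_csv(path, index=False)


def read_cohort(path: Union[str, Path]) -> pd.DataFrame:
    """Read and validate a cohort table.

    Errors name the offending data row (1-based, excluding the header)
    and column. Unknown columns are preserved; row order is kept.
    """
    frame = pd.read_csv(path)
    missing = [c for c in _MANDATORY if c not in frame.columns]
    if missing:
        raise ValueError(f"cohort file {path} is missing mandatory columns {missing}")
    for col in _NUMERIC:
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = converted.isna() & frame[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise ValueError(
                f"non-numeric value {frame[col][row - 1]!r} in column {col!r} at row {row}"
            )
        if converted.isna().any():
            row = int(converted.isna().idxmax()) + 1
            raise ValueError(f"missing value in column {col!r} at row {row}")
        frame[col] = converted
    nonpos = frame["ava_cm2"] <= 0
    if nonpos.any():
        row = int(nonpos.idxmax()) + 1
        raise ValueError(
            f"non-positive aortic valve area {frame['ava_cm2'][row - 1]} at row {row}"
        )
    frame["excluded"] = frame["excluded"].astype(bool)
    frame["exclusion_reason"] = frame["exclusion_reason"].fillna("").astype(str)
    return frame


# ---------------------------------------------------------------------------
# JSON reports and manifests
# ---------------------------------------------------------------------------

def coefficients_to_dict(coeffs: ModelCoefficients) -> dict:
    out = {"c": coeffs.c, "alpha": coeffs.alpha, "beta": coeffs.beta}
    for name, ci in (("c", coeffs.ci_c), ("alpha", coeffs.ci_alpha), ("beta", coeffs.ci_beta)):
        if ci is not None:
            out[f"ci_{name}"] = list(ci)
    return out


def coefficients_from_dict(data: dict) -> ModelCoefficients:
    kwargs = {k: data[k] for k in ("c", "alpha", "beta")}
    for name in ("c", "alpha", "beta"):
        ci = data.get(f"ci_{name}")
        if ci is not None:
            kwargs[f"ci_{name}"] = tuple(ci)
    return ModelCoefficients(**kwargs)


def _config_snapshot(config: CohortConfig) -> dict:
    snap = dataclasses.asdict(config)
    snap["truth_coeffs"] = coefficients_to_dict(config.truth_coeffs)
    snap["q_range"] = [config.q_range[0], "inf" if config.q_range[1] == float("inf") else config.q_range[1]]
    return snap


def write_manifest(
    path: Union[str, Path], config: CohortConfig, seed: int, command: str
) -> None:
    """Record how an output was produced: config snapshot, seed, version, time."""
    manifest = {
        "command": command,
        "seed": seed,
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "cohort_config": _config_snapshot(config),
    }
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")


def write_fit_report(path: Union[str, Path], fit: FitResult, ci: ModelCoefficients) -> None:
    report = fit.summary()
    report["ci_c"] = list(ci.ci_c)
    report["ci_alpha"] = list(ci.ci_alpha)
    report["ci_beta"] = list(ci.ci_beta)
    Path(path).write_text(json.dumps(report, indent=2, default=float) + "\n")


def write_evaluation_report(
    path: Union[str, Path], reports: Dict[str, EvaluationReport]
) -> None:
    Path(path).write_text(
        json.dumps({k: v.to_dict() for k, v in reports.items()}, indent=2) + "\n"
    )
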