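"""Lossless read/write of hazard parameter files (YAML, key per coefficient).

Recovery files use snake_case field names; recurrence files use the
published human-readable row labels.  Unknown keys and missing required
keys are schema errors, never silent defaults.  The published calibrated
values ship as package data and load via :func:`published_recovery` /
:func:`published_recurrence`.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Any

import yaml

from .hazards import (
    RECURRENCE_ROW_LABELS,
    RecoveryParameters,
    RecurrenceParameters,
    UnknownCoefficientError,
)

__all__ = [
    "ParameterSchemaError",
    "read_recovery_params",
    "write_recovery_params",
    "read_recurrence_params",
    "write_recurrence_params",
    "published_recovery",
    "published_recurrence",
]

_RECOVERY_KEYS = ("alpha", "age_19_25", "age_26_45", "age_46_65", "age_66_plus", "log_time")


class ParameterSchemaError(ValueError):
    """A parameter file does not match the coefficient schema."""


def _load_mapping(path: Path | str) -> dict[str, Any]:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ParameterSchemaError(f"{path}: expected a mapping of coefficient -> value")
    return data


def _coerce_reals(data: dict[str, Any], path: Path | str) -> dict[str, float]:
    out = {}
    for k, v in data.items():
        if not isinstance(v, (int, float)) or isinstance(v, bool):
            raise ParameterSchemaError(f"{path}: coefficient {k!r} is not a number: {v!r}")
        out[k] = float(v)
    return out


def read_recovery_params(path: Path | str) -> RecoveryParameters:
    data = _coerce_reals(_load_mapping(path), path)
    missing = [k for k in _RECOVERY_KEYS if k not in data]
    extra = [k for k in data if k not in _RECOVERY_KEYS]
    if missing:
        raise ParameterSchemaError(f"{path}: missing recovery keys {missing}")
    if extra:
        raise ParameterSchemaError(f"{path}: unknown recovery keys {extra}")
    return RecoveryParameters(**data)


def write_recovery_params(params: RecoveryParameters, path: Path | str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.as_dict(), fh, sort_keys=False)


def read_recurrence_params(path: Path | str) -> RecurrenceParameters:
    data = _coerce_reals(_load_mapping(path), path)
    missing = [k for k in RECURRENCE_ROW_LABELS if k not in data]
    if missing:
        raise ParameterSchemaError(f"{path}: missing recurrence keys {missing}")
    try:
        return RecurrenceParameters(data)
    except UnknownCoefficientError as exc:
        raise ParameterSchemaError(f"{path}: {exc}") from exc


def write_recurrence_params(params: RecurrenceParameters, path: Path | str) -> None:
    # Preserve table row order for human diffing.
    ordered = {k: params.coefficients[k] for k in RECURRENCE_ROW_LABELS}
    with open(path, "w") as fh:
        yaml.safe_dump(ordered, fh, sort_keys=False)


def _data_path(name: str):
    return resources.files("mdesim.data").joinpath(name)


def published_recovery() -> RecoveryParameters:
    """The packaged published recovery-equation coefficients."""
    with resources.as_file(_data_path("recovery_published.yaml")) as p:
        return read_recovery_params(p)


def published_recurrence() -> RecurrenceParameters:
    """The packaged published recurrence-equation coefficients."""
    with resources.as_file(_data_path("recurrence_published.yaml")) as p:
        return read_recurrence_params(p)
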