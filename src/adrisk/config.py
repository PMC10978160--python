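"""YAML/JSON configuration loading.

A config file may override any subset of: the failure-mode RPN matrix
(``rpn_matrix``), the monitoring band edges (``bins``), the alert glove
values (``agv``) and the spread statistic (``spread_stat``).  Anything
not supplied inherits the packaged defaults.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Union

import yaml

from .arl import RPNMatrix, load_matrix
from .errors import ConfigError
from .monitoring import SPREAD_STATS
from .scoring import (
    AGVConfig,
    AGVValues,
    BinTable,
    OrdinalBins,
    default_agv_config,
    default_bin_table,
)

__all__ = ["AssessConfig", "load_config", "parse_config"]

_BIN_KEYS = ("n_detected", "surface_spread", "pct_surfaces", "pct_gloves")


@dataclass(frozen=True)
class AssessConfig:
    """Fully resolved assessment configuration."""

    matrix: RPNMatrix
    bins: BinTable
    agv: AGVConfig
    spread_stat: str = "p90"


def _parse_bins(section: Mapping) -> BinTable:
    defaults = default_bin_table()
    resolved = {}
    for key in _BIN_KEYS:
        if key in section:
            entry = section[key]
            try:
                edges = tuple(float(e) for e in entry["edges"])
            except (KeyError, TypeError, ValueError):
                raise ConfigError(f"bins.{key}: need an 'edges' list of four numbers")
            inclusive = tuple(
                bool(b) for b in entry.get("inclusive", (True, True, True, True))
            )
            resolved[key] = OrdinalBins(edges, inclusive)
        else:
            resolved[key] = getattr(defaults, key)
    return BinTable(**resolved)


def _parse_agv_values(entry: Mapping, path: str) -> AGVValues:
    try:
        values = AGVValues(
            p90=float(entry["p90"]), p95=float(entry["p95"]), loq=float(entry["loq"])
        )
    except (KeyError, TypeError, ValueError):
        raise ConfigError(f"{path}: need numeric p90, p95 and loq")
    values.glove_bins()  # reject non-monotone thresholds eagerly
    return values


def _parse_agv(section: Mapping) -> AGVConfig:
    default = (
        _parse_agv_values(section["default"], "agv.default")
        if "default" in section
        else default_agv_config().default
    )
    per_drug = {
        drug: _parse_agv_values(entry, f"agv.per_drug.{drug}")
        for drug, entry in section.get("per_drug", {}).items()
    }
    return AGVConfig(default=default, per_drug=per_drug)


def parse_config(raw: Optional[Mapping]) -> AssessConfig:
    """Resolve a raw config mapping over the packaged defaults."""
    raw = raw or {}
    spread_stat = raw.get("spread_stat", "p90")
    if spread_stat not in SPREAD_STATS:
        raise ConfigError(
            f"spread_stat {spread_stat!r} unknown; choose from {sorted(SPREAD_STATS)}"
        )
    return AssessConfig(
        matrix=load_matrix(raw.get("rpn_matrix")),
        bins=_parse_bins(raw.get("bins", {})),
        agv=_parse_agv(raw.get("agv", {})),
        spread_stat=spread_stat,
    )


def load_config(path: Union[str, Path, None]) -> AssessConfig:
    """Load a YAML (or JSON) config file; ``None`` yields pure defaults."""
    if path is None:
        return parse_config(None)
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if raw is not None and not isinstance(raw, Mapping):
        raise ConfigError(f"{path}: top level must be a mapping")
    return parse_config(raw)
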