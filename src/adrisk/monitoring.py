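"""Wipe/glove monitoring campaigns and their five-parameter reduction.

A campaign is a collection of surface-wipe and glove samples taken at
the start and end of work shifts, each analysed for one antineoplastic
analyte and reported as a load in pg/cm2 with a limit of quantification
(LOQ).  Loads below the LOQ are censored and count as non-positive.

For risk scoring a campaign is reduced, per (hazard group, preparation
mode) stratum, to five monitoring parameters: number of distinct
analytes detected, surface contamination spread (an upper quantile of
positive wipe loads), percentage of positive wipes, glove contamination
spread, and percentage of positive gloves.
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np

from .arl import PrepMode
from .catalog import ADGroup, DrugRecord, group_members
from .errors import EmptyStratumError, ParseError, ReferentialError, SchemaError

__all__ = [
    "Medium",
    "ShiftPhase",
    "SampleRecord",
    "MonitoringCampaign",
    "MonitoringSummary",
    "load_campaign",
    "summarize_group",
    "SPREAD_STATS",
]

#: Named spread statistics: quantile (linear interpolation) of the
#: positive-record loads.
SPREAD_STATS: dict[str, float] = {"median": 0.5, "p90": 0.9, "p95": 0.95, "max": 1.0}


class Medium(enum.Enum):
    SURFACE = "surface"
    GLOVE = "glove"


class ShiftPhase(enum.Enum):
    START = "start"
    END = "end"


@dataclass(frozen=True)
class SampleRecord:
    """One analyte measurement on one wipe or glove sample.

    ``load`` is the measured analyte load in pg/cm2, or ``None`` when
    the result is below the LOQ (censored).  A record is *positive* iff
    its load is quantifiable, i.e. at or above the LOQ.
    """

    sample_id: str
    hospital_id: str
    prep_mode: PrepMode
    medium: Medium
    location: str
    shift_phase: ShiftPhase
    drug_id: str
    load: Optional[float]
    loq: float

    def __post_init__(self) -> None:
        if not self.loq > 0:
            raise ParseError(f"sample {self.sample_id!r}: loq must be > 0")
        if self.load is not None and self.load < 0:
            raise ParseError(f"sample {self.sample_id!r}: negative load")

    @property
    def positive(self) -> bool:
        return self.load is not None and self.load >= self.loq


@dataclass
class MonitoringCampaign:
    """A set of sample records plus free-form metadata (campaign id, dates)."""

    records: list[SampleRecord]
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class MonitoringSummary:
    """The five monitoring parameters for one (group, mode) stratum.

    Spreads are ``None`` when no positive record exists in that medium
    (reported downstream as below-LOQ).  ``*_spread_analyte`` is the
    drug whose load attains the spread quantile, used to resolve
    per-drug alert glove values.
    """

    group: ADGroup
    prep_mode: PrepMode
    n_detected_ads: int
    surface_spread: Optional[float]
    pct_surfaces_positive: float
    glove_spread: Optional[float]
    pct_gloves_positive: float
    n_surface_records: int = 0
    n_glove_records: int = 0
    surface_spread_analyte: Optional[str] = None
    glove_spread_analyte: Optional[str] = None

    def __post_init__(self) -> None:
        for pct in (self.pct_surfaces_positive, self.pct_gloves_positive):
            if not 0.0 <= pct <= 100.0:
                raise ValueError(f"percentage out of [0, 100]: {pct}")
        for spread in (self.surface_spread, self.glove_spread):
            if spread is not None and spread < 0:
                raise ValueError(f"spread must be >= 0: {spread}")


_CAMPAIGN_COLUMNS = (
    "sample_id",
    "hospital_id",
    "prep_mode",
    "medium",
    "location",
    "shift_phase",
    "drug_id",
    "load_pg_cm2",
    "loq_pg_cm2",
)

#: Literal token accepted in the load column for censored results.
BELOW_LOQ_TOKEN = "<LOQ"


def load_campaign(
    path: Union[str, Path],
    catalog: Sequence[DrugRecord],
    metadata: Optional[Mapping] = None,
) -> MonitoringCampaign:
    """Load a samples CSV into a validated :class:`MonitoringCampaign`.

    The load column accepts a numeric pg/cm2 value or the literal token
    ``<LOQ``.  Every ``drug_id`` must exist in ``catalog``; a numeric
    load below the row's LOQ is kept as-is (the record simply counts as
    non-positive).
    """
    path = Path(path)
    known = {d.drug_id for d in catalog}
    records: list[SampleRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, header row required")
        missing = [c for c in _CAMPAIGN_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"{path}: missing mandatory column(s): {missing}")
        for row in reader:
            sample_id = row["sample_id"].strip() or f"line {reader.line_num}"
            drug_id = row["drug_id"].strip()
            if drug_id not in known:
                raise ReferentialError(
                    f"sample {sample_id!r}: drug {drug_id!r} not in catalog"
                )
            raw_load = row["load_pg_cm2"].strip()
            if raw_load == BELOW_LOQ_TOKEN or raw_load == "":
                load: Optional[float] = None
            else:
                try:
                    load = float(raw_load)
                except ValueError:
                    raise ParseError(
                        f"sample {sample_id!r}: load not numeric nor "
                        f"{BELOW_LOQ_TOKEN!r}: {raw_load!r}"
                    )
                if load < 0:
                    raise ParseError(f"sample {sample_id!r}: negative load {load}")
            try:
                loq = float(row["loq_pg_cm2"])
            except ValueError:
                raise ParseError(
                    f"sample {sample_id!r}: LOQ not numeric: {row['loq_pg_cm2']!r}"
                )
            try:
                records.append(
                    SampleRecord(
                        sample_id=sample_id,
                        hospital_id=row["hospital_id"].strip(),
                        prep_mode=PrepMode(row["prep_mode"].strip()),
                        medium=Medium(row["medium"].strip()),
                        location=row["location"].strip(),
                        shift_phase=ShiftPhase(row["shift_phase"].strip()),
                        drug_id=drug_id,
                        load=load,
                        loq=loq,
                    )
                )
            except ValueError as exc:
                raise ParseError(f"sample {sample_id!r}: {exc}") from exc
    return MonitoringCampaign(records=records, metadata=dict(metadata or {}))


def _spread(
    positives: list[SampleRecord], q: float
) -> tuple[Optional[float], Optional[str]]:
    """Quantile of positive loads and the analyte attaining it.

    The attaining analyte is the drug of the positive record with the
    smallest load at or above the (linearly interpolated) quantile
    value; ties break lexicographically on drug id for determinism.
    """
    if not positives:
        return None, None
    loads = np.array([r.load for r in positives], dtype=float)
    value = float(np.quantile(loads, q))
    at_or_above = [r for r in positives if r.load >= value]
    if at_or_above:
        attaining = min(at_or_above, key=lambda r: (r.load, r.drug_id))
    else:  # numerical guard; the max always satisfies load >= value
        attaining = max(positives, key=lambda r: (r.load, r.drug_id))
    return value, attaining.drug_id


def summarize_group(
    campaign: MonitoringCampaign,
    group: ADGroup,
    mode: PrepMode,
    catalog: Sequence[DrugRecord],
    *,
    spread_stat: str = "p90",
    shift_phase: Optional[ShiftPhase] = None,
) -> MonitoringSummary:
    """Reduce a campaign to the five monitoring parameters for one stratum.

    Records are filtered to drugs belonging to ``group`` and to
    ``mode``; start- and end-of-shift samples are pooled unless
    ``shift_phase`` restricts to one phase.  Percentages are
    100 x positives / records per medium; the spread is the configured
    quantile (default 90th percentile) of positive loads per medium;
    detected ADs are distinct analytes with at least one positive record
    in either medium.

    Raises
    ------
    EmptyStratumError
        If no record at all matches the stratum (an assessment for that
        cell must be skipped, not reported as zero risk).
    """
    if spread_stat not in SPREAD_STATS:
        raise ValueError(
            f"unknown spread_stat {spread_stat!r}; choose from {sorted(SPREAD_STATS)}"
        )
    q = SPREAD_STATS[spread_stat]
    drugs = group_members(catalog, group)
    relevant = [
        r
        for r in campaign.records
        if r.prep_mode is mode
        and r.drug_id in drugs
        and (shift_phase is None or r.shift_phase is shift_phase)
    ]
    if not relevant:
        raise EmptyStratumError(
            f"no monitoring records for group {group.value!r} "
            f"under {mode.value!r} preparation"
        )
    by_medium = {m: [r for r in relevant if r.medium is m] for m in Medium}
    positives = {m: [r for r in by_medium[m] if r.positive] for m in Medium}

    def pct(m: Medium) -> float:
        total = len(by_medium[m])
        return 100.0 * len(positives[m]) / total if total else 0.0

    surface_spread, surface_analyte = _spread(positives[Medium.SURFACE], q)
    glove_spread, glove_analyte = _spread(positives[Medium.GLOVE], q)
    detected = {r.drug_id for m in Medium for r in positives[m]}
    return MonitoringSummary(
        group=group,
        prep_mode=mode,
        n_detected_ads=len(detected),
        surface_spread=surface_spread,
        pct_surfaces_positive=pct(Medium.SURFACE),
        glove_spread=glove_spread,
        pct_gloves_positive=pct(Medium.GLOVE),
        n_surface_records=len(by_medium[Medium.SURFACE]),
        n_glove_records=len(by_medium[Medium.GLOVE]),
        surface_spread_analyte=surface_analyte,
        glove_spread_analyte=glove_analyte,
    )
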