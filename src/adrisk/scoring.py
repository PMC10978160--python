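"""Measured Risk Levels (MRL) and the four-level risk classification.

Each of the five monitoring parameters is mapped to an ordinal RPN 1–5
through a five-band rubric; the MRL is the sum of the five RPNs (range
5–25) and is compared against the Acceptable Risk Level (ARL) of the
same (group, preparation-mode) cell:

=============  =============================================
MRL <= ARL     risk under control
MRL = ARL + 1  moderate risk, should be mitigated
MRL = ARL + 2  severe uncontrolled risk, should be mitigated
MRL > ARL + 2  high uncontrolled risk, mitigation mandatory
=============  =============================================

Glove contamination spread is binned against Alert Glove Values (AGV):
the band edges are LOQ, one tenth of the AGV 90th percentile, the AGV
90th percentile itself, and one tenth of the AGV 95th percentile.  The
packaged AGV defaults are synthetic placeholders — real alert values
come from a laboratory's own prior glove-monitoring campaigns — and any
configuration whose edges are not strictly increasing is rejected
rather than reordered.

The published rubric's printed bands have small gaps and overlaps
(e.g. "<3 %" followed by "4–6 %", "6–8 %" followed by "8–10 %"); a
scoring function must be total, so bands are implemented as contiguous
half-open real intervals on the printed edges, upper-edge-inclusive on
the lower band.  The two deviations from the literal text are a count
of exactly 6 detected ADs falling in the top band, and a surface spread
of exactly 100 pg/cm2 falling in the top band.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .arl import PrepMode, RPN_MAX, RPN_MIN
from .catalog import ADGroup
from .errors import ConfigError
from .monitoring import MonitoringSummary

__all__ = [
    "OrdinalBins",
    "BinTable",
    "AGVConfig",
    "AGVValues",
    "default_bin_table",
    "default_agv_config",
    "rpn_n_detected",
    "rpn_surface_spread",
    "rpn_pct_surfaces",
    "rpn_glove_spread",
    "rpn_pct_gloves",
    "sum_rpns",
    "compute_mrl",
    "classify",
    "MRLProfile",
    "RiskLevel",
    "RiskAssessment",
]

#: Canonical order of the five monitoring parameters.
PARAMETERS = (
    "n_detected_ads",
    "surface_spread",
    "pct_surfaces",
    "glove_spread",
    "pct_gloves",
)


@dataclass(frozen=True)
class OrdinalBins:
    """Five contiguous bands over [0, inf) mapping a value to RPN 1–5.

    ``edges`` are the four internal boundaries in increasing order;
    ``inclusive[i]`` says whether a value equal to ``edges[i]`` belongs
    to the lower band.
    """

    edges: tuple[float, float, float, float]
    inclusive: tuple[bool, bool, bool, bool] = (True, True, True, True)

    def __post_init__(self) -> None:
        if len(self.edges) != 4 or len(self.inclusive) != 4:
            raise ConfigError("bins need exactly four internal edges")
        if not all(a < b for a, b in zip(self.edges, self.edges[1:])):
            raise ConfigError(f"bin edges must be strictly increasing: {self.edges}")

    def score(self, value: float) -> int:
        if value < 0:
            raise ValueError(f"binned value must be >= 0, got {value}")
        for i, (edge, incl) in enumerate(zip(self.edges, self.inclusive)):
            if value < edge or (incl and value == edge):
                return i + 1
        return 5


@dataclass(frozen=True)
class BinTable:
    """Band tables for the four parameters with fixed numeric edges.

    Glove contamination spread is not listed here: its edges derive from
    the AGV configuration (see :class:`AGVConfig`).
    """

    n_detected: OrdinalBins
    surface_spread: OrdinalBins
    pct_surfaces: OrdinalBins
    pct_gloves: OrdinalBins


def default_bin_table() -> BinTable:
    """The published monitoring rubric with gap/overlap resolution.

    * detected ADs: 0–1 / 2 / 3 / 4–5 / >=6
    * surface spread (pg/cm2): <=10 / (10,30] / (30,50] / (50,100) / >=100
    * % positive surfaces: <=3 / (3,6] / (6,9] / (9,12] / >12
    * % positive gloves:   <=2 / (2,5] / (5,8] / (8,10] / >10
    """
    return BinTable(
        n_detected=OrdinalBins((1, 2, 3, 5)),
        surface_spread=OrdinalBins((10, 30, 50, 100), (True, True, True, False)),
        pct_surfaces=OrdinalBins((3, 6, 9, 12)),
        pct_gloves=OrdinalBins((2, 5, 8, 10)),
    )


@dataclass(frozen=True)
class AGVValues:
    """Alert glove values for one analyte: the 90th and 95th percentile
    reference levels (pg/cm2) plus the glove-assay LOQ."""

    p90: float
    p95: float
    loq: float

    def glove_bins(self) -> OrdinalBins:
        """Glove-spread bands in printed row order:
        <LOQ / [LOQ, p90/10] / (p90/10, p90] / (p90, p95/10] / >p95/10.

        A value equal to the AGV 95th percentile therefore scores 5.
        Edges that are not strictly increasing (including p95 <= p95/10's
        implied ordering p90 < p95/10, i.e. p95 > 10*p90) are rejected.
        """
        edges = (self.loq, self.p90 / 10.0, self.p90, self.p95 / 10.0)
        ordered = edges + (self.p95,)
        if not all(a < b for a, b in zip(ordered, ordered[1:])):
            raise ConfigError(
                "AGV glove bands must be strictly increasing "
                f"(loq, p90/10, p90, p95/10, p95) = {ordered}; "
                "refusing to reorder"
            )
        return OrdinalBins(edges, (False, True, True, True))


@dataclass(frozen=True)
class AGVConfig:
    """Per-drug alert glove values with a global default fallback."""

    default: AGVValues
    per_drug: Mapping[str, AGVValues] = field(default_factory=dict)

    def resolve(self, drug_id: Optional[str]) -> AGVValues:
        if drug_id is not None and drug_id in self.per_drug:
            return self.per_drug[drug_id]
        return self.default


def default_agv_config() -> AGVConfig:
    """Synthetic placeholder AGVs (p90=10, p95=150, loq=0.1 pg/cm2).

    Non-authoritative: real alert glove values must come from a
    laboratory's own reference glove-monitoring distribution.
    """
    return AGVConfig(default=AGVValues(p90=10.0, p95=150.0, loq=0.1))


def rpn_n_detected(count: int, bins: BinTable) -> int:
    """RPN for the number of distinct detected analytes."""
    if count < 0:
        raise ValueError(f"detected-AD count must be >= 0, got {count}")
    return bins.n_detected.score(count)


def rpn_surface_spread(value: Optional[float], bins: BinTable) -> int:
    """RPN for surface contamination spread; ``None`` (below LOQ) scores 1."""
    if value is None:
        return 1
    return bins.surface_spread.score(value)


def rpn_pct_surfaces(pct: float, bins: BinTable) -> int:
    """RPN for the percentage of positive wipe samples."""
    if not 0.0 <= pct <= 100.0:
        raise ValueError(f"percentage out of [0, 100]: {pct}")
    return bins.pct_surfaces.score(pct)


def rpn_glove_spread(
    value: Optional[float], agv: AGVConfig, drug_id: Optional[str] = None
) -> int:
    """RPN for glove contamination spread against the alert glove values
    of ``drug_id`` (global default when unknown); ``None`` scores 1."""
    bins = agv.resolve(drug_id).glove_bins()
    if value is None:
        return 1
    return bins.score(value)


def rpn_pct_gloves(pct: float, bins: BinTable) -> int:
    """RPN for the percentage of positive gloves."""
    if not 0.0 <= pct <= 100.0:
        raise ValueError(f"percentage out of [0, 100]: {pct}")
    return bins.pct_gloves.score(pct)


@dataclass(frozen=True)
class MRLProfile:
    """The five monitoring RPNs and their sum for one stratum."""

    group: ADGroup
    prep_mode: PrepMode
    rpns: Mapping[str, int]
    mrl: int

    def __post_init__(self) -> None:
        if set(self.rpns) != set(PARAMETERS):
            raise ValueError(f"rpns must cover exactly {PARAMETERS}")
        if self.mrl != sum(self.rpns.values()):
            raise ValueError("mrl must equal the sum of the five RPNs")
        if not 5 * RPN_MIN <= self.mrl <= 5 * RPN_MAX:
            raise ValueError(f"mrl out of [5, 25]: {self.mrl}")


def sum_rpns(rpns: Sequence[int]) -> int:
    """Sum five RPN components into an MRL (or ARL), validating bounds."""
    if len(rpns) != 5:
        raise ValueError(f"expected five RPN components, got {len(rpns)}")
    for r in rpns:
        if not RPN_MIN <= r <= RPN_MAX:
            raise ValueError(f"RPN component out of [1, 5]: {r}")
    return int(sum(rpns))


def compute_mrl(
    summary: MonitoringSummary, bins: BinTable, agv: AGVConfig
) -> MRLProfile:
    """Score the five monitoring parameters of a summary and sum to the MRL.

    The glove-spread band uses the AGV of the analyte attaining the
    glove spread quantile, falling back to the global default.
    """
    rpns = {
        "n_detected_ads": rpn_n_detected(summary.n_detected_ads, bins),
        "surface_spread": rpn_surface_spread(summary.surface_spread, bins),
        "pct_surfaces": rpn_pct_surfaces(summary.pct_surfaces_positive, bins),
        "glove_spread": rpn_glove_spread(
            summary.glove_spread, agv, summary.glove_spread_analyte
        ),
        "pct_gloves": rpn_pct_gloves(summary.pct_gloves_positive, bins),
    }
    return MRLProfile(
        group=summary.group,
        prep_mode=summary.prep_mode,
        rpns=rpns,
        mrl=sum_rpns(list(rpns.values())),
    )


class RiskLevel(enum.Enum):
    """Four-level risk strip for the MRL-vs-ARL comparison."""

    UNDER_CONTROL = "under_control"
    MODERATE = "moderate"
    SEVERE = "severe"
    HIGH = "high"


#: Human wording for each level, as used in reports.
RISK_LEVEL_LEGEND = {
    RiskLevel.UNDER_CONTROL: "risk under control",
    RiskLevel.MODERATE: "moderate risk that should be mitigated",
    RiskLevel.SEVERE: "severe uncontrolled risk that should be mitigated",
    RiskLevel.HIGH: "high uncontrolled risk, mitigation mandatory",
}


@dataclass(frozen=True)
class RiskAssessment:
    """MRL vs ARL verdict for one stratum."""

    mrl: int
    arl: int
    delta: int
    level: RiskLevel
    group: Optional[ADGroup] = None
    prep_mode: Optional[PrepMode] = None


def classify(
    mrl: int,
    arl: int,
    group: Optional[ADGroup] = None,
    prep_mode: Optional[PrepMode] = None,
) -> RiskAssessment:
    """Place an MRL on the four-level risk strip relative to its ARL.

    delta = MRL - ARL; delta <= 0 is under control (the strip defines no
    band below equality), +1 moderate, +2 severe, anything above high.
    """
    for name, value in (("mrl", mrl), ("arl", arl)):
        if not 5 * RPN_MIN <= value <= 5 * RPN_MAX:
            raise ValueError(f"{name} out of [5, 25]: {value}")
    delta = mrl - arl
    if delta <= 0:
        level = RiskLevel.UNDER_CONTROL
    elif delta == 1:
        level = RiskLevel.MODERATE
    elif delta == 2:
        level = RiskLevel.SEVERE
    else:
        level = RiskLevel.HIGH
    return RiskAssessment(
        mrl=mrl, arl=arl, delta=delta, level=level, group=group, prep_mode=prep_mode
    )
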