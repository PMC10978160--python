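"""Published reference data from the four-hospital FMECA study.

These tables are inputs and regression anchors, not computations: the
group membership lists, the printed ARL row, and the monitoring-derived
component RPNs with their printed MRL sums and risk labels, for all 16
(hazard group, preparation mode) cells.

Two kinds of internal inconsistency in the published monitoring table
are preserved verbatim and surfaced programmatically rather than
silently corrected:

* in two cells (corrosive/manual, one-concentration/manual) the printed
  component RPNs do not sum to the printed MRL —
  :func:`component_sum_discrepancies`;
* in several cells the printed risk label disagrees with the risk-strip
  rule applied to the printed MRL and ARL —
  :func:`label_discrepancies`.

The ARL-side and MRL-side tables also print slightly different member
lists for the unstable group; both are kept (``GROUP_MEMBERS`` and
``ALT_UNSTABLE_MEMBERS``).
"""

from __future__ import annotations

from .arl import PrepMode
from .catalog import ADGroup
from .scoring import PARAMETERS, RiskLevel, classify, sum_rpns

__all__ = [
    "GROUP_MEMBERS",
    "ALT_UNSTABLE_MEMBERS",
    "REFERENCE_ARL",
    "REFERENCE_MONITORING_RPNS",
    "REFERENCE_PRINTED_MRL",
    "REFERENCE_PRINTED_LABEL",
    "component_sum_discrepancies",
    "label_discrepancies",
]

M, A = PrepMode.MANUAL, PrepMode.AUTOMATED

#: Drug ids per hazard group as printed in the ARL table header.  The
#: corrosive list's "TX" is read as PTX (paclitaxel), consistent with
#: the monitoring table and the prose.
GROUP_MEMBERS: dict[ADGroup, frozenset[str]] = {
    ADGroup.POWDER: frozenset(
        "MITC DC DNR IP FTM VNB GEM CP MP VND PMX TPT RTX".split()
    ),
    ADGroup.LIQUID: frozenset(
        "VNC EPI DXR IRT 5-FU PTX BSF CarboPt CisPt CTB DTX ETP "
        "GEM IDC MT OxaliPt PMX VNR".split()
    ),
    ADGroup.CORROSIVE: frozenset("BSF PTX 5-FU".split()),
    ADGroup.ONE_CONCENTRATION: frozenset("RTX FTM DNR VNB BSF".split()),
    ADGroup.UNSTABLE: frozenset("DXR FTM MP MITC VNC MT".split()),
    ADGroup.NO_HOLDER_CASING: frozenset(
        "VND VNC VNR TPT RTX MITC MP IP IDC DXR EPI CP CarboPt".split()
    ),
    ADGroup.HIGH_AVG_CONCENTRATION: frozenset(
        "CP IP DC GEM MP PMX IRT PTX 5-FU".split()
    ),
    ADGroup.POORLY_SOLUBLE: frozenset("5-FU CP".split()),
}

#: The monitoring table prints a shorter unstable-group list (the DXR
#: entry is the Miocet liposomal product); kept verbatim.
ALT_UNSTABLE_MEMBERS: frozenset[str] = frozenset("DXR FTM MP MITC".split())

#: Printed ARL bottom row (also the column sums of the default matrix).
REFERENCE_ARL: dict[tuple[ADGroup, PrepMode], int] = {
    (ADGroup.POWDER, M): 17, (ADGroup.POWDER, A): 15,
    (ADGroup.LIQUID, M): 13, (ADGroup.LIQUID, A): 12,
    (ADGroup.CORROSIVE, M): 16, (ADGroup.CORROSIVE, A): 12,
    (ADGroup.ONE_CONCENTRATION, M): 17, (ADGroup.ONE_CONCENTRATION, A): 15,
    (ADGroup.UNSTABLE, M): 16, (ADGroup.UNSTABLE, A): 14,
    (ADGroup.NO_HOLDER_CASING, M): 18, (ADGroup.NO_HOLDER_CASING, A): 16,
    (ADGroup.HIGH_AVG_CONCENTRATION, M): 17, (ADGroup.HIGH_AVG_CONCENTRATION, A): 14,
    (ADGroup.POORLY_SOLUBLE, M): 16, (ADGroup.POORLY_SOLUBLE, A): 14,
}

#: Monitoring component RPNs per cell, in PARAMETERS order
#: (n_detected, surface_spread, pct_surfaces, glove_spread, pct_gloves).
REFERENCE_MONITORING_RPNS: dict[tuple[ADGroup, PrepMode], tuple[int, ...]] = {
    (ADGroup.POWDER, M): (3, 5, 3, 4, 5),
    (ADGroup.POWDER, A): (3, 5, 2, 4, 5),
    (ADGroup.LIQUID, M): (3, 3, 3, 3, 2),
    (ADGroup.LIQUID, A): (3, 3, 3, 1, 1),
    (ADGroup.CORROSIVE, M): (1, 5, 1, 4, 2),
    (ADGroup.CORROSIVE, A): (1, 5, 2, 4, 1),
    (ADGroup.ONE_CONCENTRATION, M): (2, 4, 4, 4, 2),
    (ADGroup.ONE_CONCENTRATION, A): (2, 3, 4, 3, 2),
    (ADGroup.UNSTABLE, M): (2, 4, 3, 3, 2),
    (ADGroup.UNSTABLE, A): (2, 3, 3, 4, 2),
    (ADGroup.NO_HOLDER_CASING, M): (3, 5, 4, 4, 5),
    (ADGroup.NO_HOLDER_CASING, A): (2, 4, 4, 3, 5),
    (ADGroup.HIGH_AVG_CONCENTRATION, M): (3, 5, 4, 3, 3),
    (ADGroup.HIGH_AVG_CONCENTRATION, A): (3, 5, 3, 3, 2),
    (ADGroup.POORLY_SOLUBLE, M): (2, 5, 3, 3, 5),
    (ADGroup.POORLY_SOLUBLE, A): (2, 5, 3, 2, 4),
}

#: Printed MRL row (not always the component sum; see
#: :func:`component_sum_discrepancies`).
REFERENCE_PRINTED_MRL: dict[tuple[ADGroup, PrepMode], int] = {
    (ADGroup.POWDER, M): 20, (ADGroup.POWDER, A): 19,
    (ADGroup.LIQUID, M): 14, (ADGroup.LIQUID, A): 11,
    (ADGroup.CORROSIVE, M): 15, (ADGroup.CORROSIVE, A): 13,
    (ADGroup.ONE_CONCENTRATION, M): 18, (ADGroup.ONE_CONCENTRATION, A): 14,
    (ADGroup.UNSTABLE, M): 14, (ADGroup.UNSTABLE, A): 14,
    (ADGroup.NO_HOLDER_CASING, M): 21, (ADGroup.NO_HOLDER_CASING, A): 18,
    (ADGroup.HIGH_AVG_CONCENTRATION, M): 18, (ADGroup.HIGH_AVG_CONCENTRATION, A): 16,
    (ADGroup.POORLY_SOLUBLE, M): 18, (ADGroup.POORLY_SOLUBLE, A): 16,
}

#: Printed assessed-risk row.
REFERENCE_PRINTED_LABEL: dict[tuple[ADGroup, PrepMode], RiskLevel] = {
    (ADGroup.POWDER, M): RiskLevel.HIGH, (ADGroup.POWDER, A): RiskLevel.HIGH,
    (ADGroup.LIQUID, M): RiskLevel.MODERATE, (ADGroup.LIQUID, A): RiskLevel.MODERATE,
    (ADGroup.CORROSIVE, M): RiskLevel.MODERATE,
    (ADGroup.CORROSIVE, A): RiskLevel.MODERATE,
    (ADGroup.ONE_CONCENTRATION, M): RiskLevel.MODERATE,
    (ADGroup.ONE_CONCENTRATION, A): RiskLevel.MODERATE,
    (ADGroup.UNSTABLE, M): RiskLevel.MODERATE,
    (ADGroup.UNSTABLE, A): RiskLevel.MODERATE,
    (ADGroup.NO_HOLDER_CASING, M): RiskLevel.HIGH,
    (ADGroup.NO_HOLDER_CASING, A): RiskLevel.SEVERE,
    (ADGroup.HIGH_AVG_CONCENTRATION, M): RiskLevel.MODERATE,
    (ADGroup.HIGH_AVG_CONCENTRATION, A): RiskLevel.SEVERE,
    (ADGroup.POORLY_SOLUBLE, M): RiskLevel.SEVERE,
    (ADGroup.POORLY_SOLUBLE, A): RiskLevel.SEVERE,
}


def component_sum_discrepancies() -> dict[tuple[ADGroup, PrepMode], tuple[int, int]]:
    """Cells where the printed component RPNs do not sum to the printed
    MRL, as ``{cell: (component_sum, printed_mrl)}``."""
    out = {}
    for cell, rpns in REFERENCE_MONITORING_RPNS.items():
        total = sum_rpns(rpns)
        if total != REFERENCE_PRINTED_MRL[cell]:
            out[cell] = (total, REFERENCE_PRINTED_MRL[cell])
    return out


def label_discrepancies() -> dict[tuple[ADGroup, PrepMode], tuple[RiskLevel, RiskLevel]]:
    """Cells where the risk-strip rule applied to the printed MRL and ARL
    disagrees with the printed label, as ``{cell: (rule, printed)}``."""
    out = {}
    for cell, printed in REFERENCE_PRINTED_LABEL.items():
        rule = classify(REFERENCE_PRINTED_MRL[cell], REFERENCE_ARL[cell]).level
        if rule is not printed:
            out[cell] = (rule, printed)
    return out
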