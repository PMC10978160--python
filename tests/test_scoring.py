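"""Monitoring rubric bands, MRL summation and the risk strip."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from adrisk.arl import PrepMode
from adrisk.catalog import ADGroup
from adrisk.errors import ConfigError
from adrisk.monitoring import MonitoringSummary
from adrisk.reference import (
    REFERENCE_ARL,
    REFERENCE_MONITORING_RPNS,
    REFERENCE_PRINTED_LABEL,
    REFERENCE_PRINTED_MRL,
    component_sum_discrepancies,
    label_discrepancies,
)
from adrisk.scoring import (
    AGVConfig,
    AGVValues,
    RiskLevel,
    classify,
    compute_mrl,
    default_agv_config,
    default_bin_table,
    rpn_glove_spread,
    rpn_n_detected,
    rpn_pct_gloves,
    rpn_pct_surfaces,
    rpn_surface_spread,
    sum_rpns,
)

M, A = PrepMode.MANUAL, PrepMode.AUTOMATED


# --- band examples ----------------------------------------------------


@pytest.mark.parametrize(
    "count,expected",
    [(0, 1), (1, 1), (2, 2), (3, 3), (4, 4), (5, 4), (6, 5), (40, 5)],
)
def test_detected_ad_count_bands(bins, count, expected):
    assert rpn_n_detected(count, bins) == expected


@pytest.mark.parametrize(
    "value,expected",
    [
        (None, 1),
        (0.0, 1),
        (10.0, 1),
        (10.1, 2),
        (30.0, 2),
        (40.0, 3),
        (50.0, 3),
        (51.0, 4),
        (99.0, 4),
        (100.0, 5),
        (120.0, 5),
    ],
)
def test_surface_spread_bands(bins, value, expected):
    assert rpn_surface_spread(value, bins) == expected


@pytest.mark.parametrize(
    "pct,expected",
    [(0.0, 1), (2.0, 1), (3.0, 1), (4.5, 2), (6.0, 2), (7.0, 3), (9.0, 3),
     (10.0, 4), (12.0, 4), (13.0, 5), (100.0, 5)],
)
def test_pct_surfaces_bands(bins, pct, expected):
    assert rpn_pct_surfaces(pct, bins) == expected


@pytest.mark.parametrize(
    "pct,expected",
    [(0.0, 1), (2.0, 1), (4.0, 2), (5.0, 2), (6.0, 3), (8.0, 3), (9.0, 4),
     (10.0, 4), (12.0, 5)],
)
def test_pct_gloves_bands(bins, pct, expected):
    assert rpn_pct_gloves(pct, bins) == expected


def test_glove_spread_bands_anchor_on_agv_percentiles(agv):
    values = agv.default  # p90=10, p95=150, loq=0.1
    assert rpn_glove_spread(None, agv) == 1
    assert rpn_glove_spread(0.05, agv) == 1  # under LOQ
    assert rpn_glove_spread(values.loq, agv) == 2
    assert rpn_glove_spread(values.p90 / 10, agv) == 2
    assert rpn_glove_spread(values.p90 / 10 + 1e-9, agv) == 3
    assert rpn_glove_spread(values.p90, agv) == 3
    assert rpn_glove_spread(values.p95 / 10, agv) == 4
    assert rpn_glove_spread(values.p95, agv) == 5
    assert rpn_glove_spread(10 * values.p95, agv) == 5


def test_per_drug_agv_overrides_default():
    agv = AGVConfig(
        default=AGVValues(p90=10.0, p95=150.0, loq=0.1),
        per_drug={"CP": AGVValues(p90=100.0, p95=1500.0, loq=0.1)},
    )
    assert rpn_glove_spread(50.0, agv, "CP") == 3  # within CP's (p90/10, p90]
    assert rpn_glove_spread(50.0, agv, "MITC") == 5  # default thresholds


def test_non_monotone_agv_thresholds_are_rejected_not_reordered():
    # p95/10 = 5 undercuts p90 = 10: printed band order would be violated
    with pytest.raises(ConfigError, match="increasing"):
        AGVValues(p90=10.0, p95=50.0, loq=0.1).glove_bins()
    with pytest.raises(ConfigError, match="increasing"):
        AGVValues(p90=10.0, p95=150.0, loq=2.0).glove_bins()


@pytest.mark.parametrize(
    "fn,bad",
    [
        (rpn_n_detected, -1),
        (rpn_surface_spread, -0.5),
        (rpn_pct_surfaces, -1.0),
        (rpn_pct_surfaces, 101.0),
        (rpn_pct_gloves, 120.0),
    ],
)
def test_out_of_domain_inputs_are_rejected(bins, fn, bad):
    with pytest.raises(ValueError):
        fn(bad, bins)


# --- totality & monotonicity vs a linear-scan oracle ------------------

INF = float("inf")
# (lo, hi, lo_inclusive, hi_inclusive) per band, built from the printed
# rubric edges independently of OrdinalBins
ORACLE_BANDS = {
    "n_detected": [(0, 1, True, True), (1, 2, False, True), (2, 3, False, True),
                   (3, 5, False, True), (5, INF, False, True)],
    "surface_spread": [(0, 10, True, True), (10, 30, False, True),
                       (30, 50, False, True), (50, 100, False, False),
                       (100, INF, True, True)],
    "pct_surfaces": [(0, 3, True, True), (3, 6, False, True), (6, 9, False, True),
                     (9, 12, False, True), (12, 100, False, True)],
    "pct_gloves": [(0, 2, True, True), (2, 5, False, True), (5, 8, False, True),
                   (8, 10, False, True), (10, 100, False, True)],
}


def scan_score(value, bands):
    hits = [
        i + 1
        for i, (lo, hi, lo_in, hi_in) in enumerate(bands)
        if (value > lo or (lo_in and value == lo))
        and (value < hi or (hi_in and value == hi))
    ]
    assert len(hits) == 1, f"bands not a partition at {value}: {hits}"
    return hits[0]


@given(st.integers(0, 50))
def test_count_band_matches_oracle_and_is_total(bins, count):
    assert rpn_n_detected(count, bins) == scan_score(count, ORACLE_BANDS["n_detected"])


@given(st.floats(0.0, 1e6, allow_nan=False))
def test_surface_spread_matches_oracle_and_is_total(bins, value):
    assert rpn_surface_spread(value, bins) == scan_score(
        value, ORACLE_BANDS["surface_spread"]
    )


@pytest.mark.parametrize("param,fn", [("pct_surfaces", rpn_pct_surfaces),
                                      ("pct_gloves", rpn_pct_gloves)])
@given(pct=st.floats(0.0, 100.0, allow_nan=False))
def test_percentage_bands_match_oracle_and_are_total(bins, param, fn, pct):
    assert fn(pct, bins) == scan_score(pct, ORACLE_BANDS[param])


@given(st.lists(st.floats(0.0, 1e6, allow_nan=False), min_size=2, max_size=2))
def test_band_mappings_are_weakly_monotone(bins, agv, pair):
    lo, hi = sorted(pair)
    assert rpn_surface_spread(lo, bins) <= rpn_surface_spread(hi, bins)
    assert rpn_glove_spread(lo, agv) <= rpn_glove_spread(hi, agv)
    lo_pct, hi_pct = min(lo, 100.0), min(hi, 100.0)
    assert rpn_pct_surfaces(lo_pct, bins) <= rpn_pct_surfaces(hi_pct, bins)
    assert rpn_pct_gloves(lo_pct, bins) <= rpn_pct_gloves(hi_pct, bins)


# --- MRL summation and classification ---------------------------------


def summary_from(n, s_spread, s_pct, g_spread, g_pct):
    return MonitoringSummary(
        group=ADGroup.POWDER,
        prep_mode=M,
        n_detected_ads=n,
        surface_spread=s_spread,
        pct_surfaces_positive=s_pct,
        glove_spread=g_spread,
        pct_gloves_positive=g_pct,
    )


@given(
    n=st.integers(0, 12),
    s_spread=st.one_of(st.none(), st.floats(0, 500, allow_nan=False)),
    s_pct=st.floats(0, 100, allow_nan=False),
    g_spread=st.one_of(st.none(), st.floats(0, 500, allow_nan=False)),
    g_pct=st.floats(0, 100, allow_nan=False),
)
def test_compute_mrl_equals_sum_of_individual_rpns(
    bins, agv, n, s_spread, s_pct, g_spread, g_pct
):
    summary = summary_from(n, s_spread, s_pct, g_spread, g_pct)
    profile = compute_mrl(summary, bins, agv)
    expected = (
        rpn_n_detected(n, bins)
        + rpn_surface_spread(s_spread, bins)
        + rpn_pct_surfaces(s_pct, bins)
        + rpn_glove_spread(g_spread, agv)
        + rpn_pct_gloves(g_pct, bins)
    )
    assert profile.mrl == expected
    assert 5 <= profile.mrl <= 25


def test_mrl_of_published_powder_manual_components_is_20(bins, agv):
    assert sum_rpns((3, 5, 3, 4, 5)) == 20


def test_mrl_of_published_no_holder_automated_components_is_18():
    assert sum_rpns((2, 4, 4, 3, 5)) == 18


def test_all_minimum_rpns_sum_to_5():
    assert sum_rpns((1, 1, 1, 1, 1)) == 5


@pytest.mark.parametrize(
    "mrl,arl,level",
    [
        (20, 17, RiskLevel.HIGH),
        (18, 16, RiskLevel.SEVERE),
        (13, 12, RiskLevel.MODERATE),
        (12, 12, RiskLevel.UNDER_CONTROL),
        (5, 25, RiskLevel.UNDER_CONTROL),
        (25, 5, RiskLevel.HIGH),
    ],
)
def test_risk_strip_classification(mrl, arl, level):
    verdict = classify(mrl, arl)
    assert verdict.level is level
    assert verdict.delta == mrl - arl


@given(st.integers(5, 25), st.integers(5, 24))
def test_classification_is_monotone_in_mrl(arl, mrl):
    order = [
        RiskLevel.UNDER_CONTROL,
        RiskLevel.MODERATE,
        RiskLevel.SEVERE,
        RiskLevel.HIGH,
    ]
    lower = order.index(classify(mrl, arl).level)
    upper = order.index(classify(mrl + 1, arl).level)
    assert lower <= upper


def test_classify_rejects_out_of_range_levels():
    with pytest.raises(ValueError):
        classify(4, 17)
    with pytest.raises(ValueError):
        classify(20, 26)


# --- golden reproduction of the published assessment ------------------

CONSISTENT_CELLS = [
    cell
    for cell in REFERENCE_MONITORING_RPNS
    if cell not in component_sum_discrepancies()
]


def test_fourteen_of_sixteen_published_columns_sum_consistently():
    assert len(CONSISTENT_CELLS) == 14
    assert set(component_sum_discrepancies()) == {
        (ADGroup.CORROSIVE, M),
        (ADGroup.ONE_CONCENTRATION, M),
    }


@pytest.mark.parametrize("cell", CONSISTENT_CELLS, ids=lambda c: f"{c[0].value}-{c[1].value}")
def test_component_sums_reproduce_published_mrl(cell):
    assert sum_rpns(REFERENCE_MONITORING_RPNS[cell]) == REFERENCE_PRINTED_MRL[cell]


# cells where the printed label agrees with the risk-strip rule applied
# to the printed MRL and ARL; the classifier must reproduce all of them
AGREEING_CELLS = [
    cell for cell in REFERENCE_PRINTED_LABEL if cell not in label_discrepancies()
]


def test_expected_set_of_label_agreeing_cells():
    assert set(AGREEING_CELLS) == {
        (ADGroup.POWDER, M), (ADGroup.POWDER, A),
        (ADGroup.LIQUID, M),
        (ADGroup.CORROSIVE, A),
        (ADGroup.ONE_CONCENTRATION, M),
        (ADGroup.NO_HOLDER_CASING, M), (ADGroup.NO_HOLDER_CASING, A),
        (ADGroup.HIGH_AVG_CONCENTRATION, M), (ADGroup.HIGH_AVG_CONCENTRATION, A),
        (ADGroup.POORLY_SOLUBLE, M), (ADGroup.POORLY_SOLUBLE, A),
    }


@pytest.mark.parametrize("cell", AGREEING_CELLS, ids=lambda c: f"{c[0].value}-{c[1].value}")
def test_classifier_reproduces_published_labels_where_rule_and_print_agree(cell):
    verdict = classify(REFERENCE_PRINTED_MRL[cell], REFERENCE_ARL[cell])
    assert verdict.level is REFERENCE_PRINTED_LABEL[cell]


def test_divergent_printed_labels_are_flagged_not_adopted():
    flagged = label_discrepancies()
    assert (ADGroup.LIQUID, A) in flagged
    assert (ADGroup.UNSTABLE, M) in flagged and (ADGroup.UNSTABLE, A) in flagged
    for rule_level, printed in flagged.values():
        assert rule_level is not printed
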