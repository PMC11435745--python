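"""DPC estimators, intake tiers, EDI/%ADI and the nine-scenario engine."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

import fishres as fr
from fishres.exposure_risk import ExposureError

NG_PER_MG = 1e6


def summary(detections=(), loq=5.0, n_tests=20, species="eel", pesticide="lufenuron"):
    return fr.DetectionSummary(
        pesticide=pesticide, species=species, n_tests=n_tests,
        detections=tuple(detections), loq=loq,
    )


# ---------------------------------------------------------------------------
# DPC estimators
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "detections,loq,n,expected",
    [
        ((10.0,), 5.0, 20, 5.25),  # (10 + 19*5)/20
        ((), 5.0, 20, 5.0),  # all censored -> LOQ
        ((10.0,) * 20, 5.0, 20, 10.0),  # no censoring
    ],
)
def test_dpc_option_a_loq_substitution(detections, loq, n, expected):
    assert fr.dpc_option_a(summary(detections, loq, n)) == pytest.approx(expected)


def test_dpc_options_b_and_c_over_detections_only():
    assert fr.dpc_option_b(summary((10.0,))) == 10.0
    assert fr.dpc_option_b(summary((8.0, 12.0))) == 10.0
    assert fr.dpc_option_c(summary((8.0, 12.0))) == 12.0
    for est in (fr.dpc_option_b, fr.dpc_option_c):
        with pytest.raises(ExposureError):
            est(summary(()))


detections_st = st.lists(st.floats(min_value=5.0, max_value=500.0), min_size=1, max_size=20)


@given(detections=detections_st)
def test_option_c_equals_brute_force_scan(detections):
    s = summary(detections)
    best = detections[0]
    for d in detections[1:]:
        if d > best:
            best = d
    assert fr.dpc_option_c(s) == best


@given(detections=detections_st, loq=st.floats(min_value=0.5, max_value=5.0))
def test_estimator_ordering(detections, loq):
    s = summary(detections, loq=loq)
    assert fr.dpc_option_a(s) <= max(loq, fr.dpc_option_c(s)) + 1e-12
    assert fr.dpc_option_b(s) <= fr.dpc_option_c(s) + 1e-12


# ---------------------------------------------------------------------------
# Intake tiers
# ---------------------------------------------------------------------------


def test_intake_tiers_against_survey_table(consumption):
    assert fr.intake_for_tier(2, "eel", consumption) == 24.24
    assert fr.intake_for_tier(1, "eel", consumption) == 1.32
    assert fr.intake_for_tier(3, "eel", consumption) == pytest.approx(320.85)
    # alternative aggregation rules
    assert fr.intake_for_tier(1, "eel", consumption, tier1_rule="sum_all_species") == pytest.approx(11.55)
    assert fr.intake_for_tier(3, "eel", consumption, tier3_rule="detected_species") == 24.24
    with pytest.raises(ExposureError):
        fr.intake_for_tier(2, "eel", [c for c in consumption if c.species != "eel"])


# ---------------------------------------------------------------------------
# EDI and %ADI
# ---------------------------------------------------------------------------


def test_edi_is_intake_times_concentration():
    assert fr.compute_edi(24.24, 5.25) == pytest.approx(127.26)
    assert fr.compute_edi(24.24, 10.0) == pytest.approx(242.4)
    assert fr.compute_edi(0.0, 123.0) == 0.0


def test_percent_adi_unit_conversion(lufenuron_tox):
    assert fr.format_percent_adi(fr.percent_adi(127.26, lufenuron_tox)) == "0.0141"
    assert fr.format_percent_adi(fr.percent_adi(242.4, lufenuron_tox)) == "0.0269"
    # an EDI equal to the per-person budget is exactly 100%
    budget = lufenuron_tox.adi * lufenuron_tox.body_weight * NG_PER_MG
    assert fr.percent_adi(budget, lufenuron_tox) == pytest.approx(100.0)


@given(
    edi=st.floats(min_value=0.0, max_value=1e6),
    adi=st.floats(min_value=1e-4, max_value=10.0),
    bw=st.floats(min_value=30.0, max_value=120.0),
    factor=st.floats(min_value=1.01, max_value=10.0),
)
def test_percent_adi_monotonicity(edi, adi, bw, factor):
    tox = fr.ToxRef(pesticide="lufenuron", adi=adi, body_weight=bw)
    base = fr.percent_adi(edi, tox)
    # nondecreasing in EDI
    assert fr.percent_adi(edi * factor, tox) >= base
    if edi > 0:
        # strictly decreasing in ADI and in body weight
        assert fr.percent_adi(edi, tox.model_copy(update={"adi": adi * factor})) < base
        assert fr.percent_adi(edi, tox.model_copy(update={"body_weight": bw * factor})) < base


# ---------------------------------------------------------------------------
# Scenario engine
# ---------------------------------------------------------------------------


def test_lufenuron_scenarios_match_reported_tier2_range(
    lufenuron_summary, consumption, lufenuron_tox
):
    ra = fr.run_scenarios(lufenuron_summary, consumption, lufenuron_tox)
    by_id = {s.scenario_id: s for s in ra.scenarios}
    assert fr.format_percent_adi(by_id[4].percent_adi) == "0.0141"
    assert fr.format_percent_adi(by_id[6].percent_adi) == "0.0269"
    # one detection makes the detections-mean and maximum coincide
    assert by_id[5].percent_adi == by_id[6].percent_adi
    assert all(c == "minimal" for c in ra.classification)
    assert [s.scenario_id for s in ra.scenarios] == list(range(1, 10))


def test_zero_detections_emit_not_evaluable_b_and_c(consumption, lufenuron_tox):
    ra = fr.run_scenarios(summary(()), consumption, lufenuron_tox)
    for sc, cls in zip(ra.scenarios, ra.classification):
        if sc.dpc_option == "A":
            assert sc.evaluable and cls == "minimal"
        else:
            assert not sc.evaluable and cls == "not evaluable"


def test_threshold_semantics(lufenuron_summary, consumption, lufenuron_tox):
    ra = fr.run_scenarios(
        lufenuron_summary, consumption, lufenuron_tox, threshold=0.01
    )
    # tier-2/3 scenarios exceed a 0.01% threshold
    assert "concern" in ra.classification


def brute_force_scenarios(s, consumption, tox, tier1_rule, tier3_rule):
    """Independent enumeration of all nine (tier, option) pairs."""
    means = {c.species: c.mean_intake for c in consumption}
    extremes = {c.species: c.extreme_intake for c in consumption}
    out = {}
    for tier in (1, 2, 3):
        if tier == 2:
            dfi = extremes[s.species]
        elif tier == 1:
            dfi = means[s.species] if tier1_rule == "detected_species" else sum(means.values())
        else:
            dfi = extremes[s.species] if tier3_rule == "detected_species" else sum(extremes.values())
        for option in "ABC":
            if option == "A":
                dpc = (sum(s.detections) + s.loq * (s.n_tests - len(s.detections))) / s.n_tests
            elif not s.detections:
                continue
            elif option == "B":
                dpc = sum(s.detections) / len(s.detections)
            else:
                dpc = max(s.detections)
            out[(tier, option)] = dfi * dpc / (tox.adi * tox.body_weight * NG_PER_MG) * 100.0
    return out


@given(
    detections=st.lists(st.floats(min_value=5.0, max_value=200.0), min_size=0, max_size=20),
    adi=st.floats(min_value=1e-3, max_value=1.0),
    tier1_rule=st.sampled_from(["detected_species", "sum_all_species"]),
    tier3_rule=st.sampled_from(["detected_species", "sum_all_species"]),
)
def test_scenario_engine_equals_brute_force_oracle(
    consumption, lufenuron_tox, detections, adi, tier1_rule, tier3_rule
):
    s = summary(detections)
    tox = lufenuron_tox.model_copy(update={"adi": adi})
    ra = fr.run_scenarios(
        s, consumption, tox, tier1_rule=tier1_rule, tier3_rule=tier3_rule
    )
    oracle = brute_force_scenarios(s, consumption, tox, tier1_rule, tier3_rule)
    for sc in ra.scenarios:
        key = (sc.intake_tier, sc.dpc_option)
        if not sc.evaluable:
            assert key not in oracle
            continue
        assert math.isclose(sc.percent_adi, oracle[key], rel_tol=1e-12)
    # within each tier, option C dominates option B
    by_id = {s_.scenario_id: s_ for s_ in ra.scenarios}
    for b_id, c_id in ((2, 3), (5, 6), (8, 9)):
        if by_id[b_id].evaluable:
            assert by_id[c_id].percent_adi >= by_id[b_id].percent_adi


def test_mismatched_toxref_rejected(lufenuron_summary, consumption):
    tox = fr.ToxRef(pesticide="dichlorvos", adi=0.004)
    with pytest.raises(ExposureError, match="toxicology reference"):
        fr.run_scenarios(lufenuron_summary, consumption, tox)


# ---------------------------------------------------------------------------
# Consumption imputation
# ---------------------------------------------------------------------------


def test_impute_half_minimum_of_similar_species():
    table = [
        fr.ConsumptionRecord(species="chinese muddy loach", mean_intake=0.96, extreme_intake=43.68),
        fr.ConsumptionRecord(species="eel", mean_intake=1.32, extreme_intake=24.24),
    ]
    groups = {"fish": ["chinese muddy loach", "eel", "carp"]}
    done = fr.impute_consumption(table, ["carp"], groups)
    carp = next(c for c in done if c.species == "carp")
    assert (carp.mean_intake, carp.extreme_intake, carp.imputed) == (0.48, 12.12, True)
    # single observed member: half that species' values
    solo = fr.impute_consumption(table[:1], ["carp"], groups)
    carp = next(c for c in solo if c.species == "carp")
    assert (carp.mean_intake, carp.extreme_intake) == (0.48, 21.84)
    # no gaps -> identity
    assert fr.impute_consumption(table, [], groups) == table
    with pytest.raises(ExposureError):
        fr.impute_consumption([], ["carp"], groups)


# ---------------------------------------------------------------------------
# Detection table
# ---------------------------------------------------------------------------


def residues_with_one_detection():
    recs = []
    for i in range(20):
        detected = i == 7
        recs.append(
            fr.ResidueRecord(
                sample_id=f"eel-{i:03d}", species="eel", pesticide="lufenuron",
                concentration=10.0 if detected else None, censored=not detected,
            )
        )
    return recs


def test_detection_table_counts_and_loq_resolution():
    limits = [fr.LimitEntry(pesticide="lufenuron", matrix="fish", lod=0.4, loq=5.0)]
    out = fr.detection_table(residues_with_one_detection(), limits)
    assert len(out) == 1
    s = out[0]
    assert (s.pesticide, s.species, s.n_tests) == ("lufenuron", "eel", 20)
    assert s.detections == (10.0,)
    assert s.loq == 5.0  # resolved via the fish matrix class


def test_detection_table_integrity_errors():
    limits = [fr.LimitEntry(pesticide="lufenuron", matrix="default", lod=0.4, loq=5.0)]
    recs = residues_with_one_detection()
    with pytest.raises(ExposureError, match="duplicate"):
        fr.detection_table(recs + [recs[0]], limits)
    with pytest.raises(ExposureError, match="no LOD/LOQ"):
        fr.detection_table(recs, [])
    # a detection below its resolved LOQ is inconsistent
    low = fr.ResidueRecord(
        sample_id="eel-xxx", species="eel", pesticide="lufenuron",
        concentration=2.0, censored=False,
    )
    with pytest.raises(ExposureError, match="below LOQ"):
        fr.detection_table(recs + [low], limits)


def test_all_censored_input_gives_empty_detection_lists():
    limits = [fr.LimitEntry(pesticide="lufenuron", matrix="default", lod=0.4, loq=5.0)]
    recs = [
        fr.ResidueRecord(
            sample_id=f"carp-{i}", species="carp", pesticide="lufenuron", censored=True
        )
        for i in range(5)
    ]
    out = fr.detection_table(recs, limits)
    assert len(out) == 1 and out[0].detections == ()
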