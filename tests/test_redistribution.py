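import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from burdenkit.core import CauseList, UNMAPPED, total_weight
from burdenkit.errors import ConfigurationError, ValidationError
from burdenkit.redistribution import (
    RedistributionRule,
    apply_direct_evidence,
    apply_proportional,
    build_indirect_mcod_distribution,
    load_rules,
    redistribute,
)

from conftest import death, make_cause


def cause_weights(records, cause_list):
    out = {}
    for r in records:
        c = cause_list.map_code(r.ucod)
        out[c] = out.get(c, 0.0) + r.weight
    return out


def naive_indirect_counter(records, target_cause, cause_list):
    """Independent double-loop tally of the associated-cause pattern."""
    tallies = {}
    for r in records:
        mentions = False
        for code in r.associated:
            if cause_list.map_code(code) == target_cause:
                mentions = True
        if not mentions:
            continue
        ucod = cause_list.map_code(r.ucod)
        if ucod == UNMAPPED or cause_list[ucod].is_redistribution_source:
            continue
        tallies[ucod] = tallies.get(ucod, 0.0) + r.weight
    total = sum(tallies.values())
    return {c: w / total for c, w in tallies.items()} if total > 0 else {}


class TestIndirectMcod:
    def test_derived_tally(self, toy_cause_list):
        records = (
            [death(f"a{i}", "I21", ["A41"]) for i in range(2)]
            + [death("b", "J18", ["A41"])]
            + [death(f"c{i}", "I21") for i in range(5)]
        )
        dist = build_indirect_mcod_distribution(records, "sepsis", toy_cause_list)
        assert dist == pytest.approx({"chd": 2 / 3, "pneumonia": 1 / 3})

    def test_no_mentions_gives_empty_distribution(self, toy_cause_list):
        records = [death("a", "I21"), death("b", "J18")]
        assert build_indirect_mcod_distribution(records, "sepsis", toy_cause_list) == {}

    def test_source_coded_mentioners_excluded(self, toy_cause_list):
        # the R99-coded death mentions septicaemia but cannot feed the pattern
        records = [death("a", "R99", ["A41"]), death("b", "I21", ["A41"])]
        dist = build_indirect_mcod_distribution(records, "sepsis", toy_cause_list)
        assert dist == pytest.approx({"chd": 1.0})

    def test_order_independence(self, toy_cause_list):
        records = [
            death("a", "I21", ["A41"], weight=0.3),
            death("b", "J18", ["A40"], weight=1.7),
            death("c", "C34", ["A41"], weight=2.0),
        ]
        forward = build_indirect_mcod_distribution(records, "sepsis", toy_cause_list)
        backward = build_indirect_mcod_distribution(
            records[::-1], "sepsis", toy_cause_list
        )
        assert forward == backward


class TestDirectEvidence:
    def test_cup_split_arithmetic(self, toy_cause_list):
        rule = RedistributionRule(
            source_cause="cup",
            method="direct",
            probability_table={"cup": 0.70, "lung_ca": 0.18, "colorectal_ca": 0.12},
        )
        records = [death(f"r{i}", "C80") for i in range(10)]
        out = apply_direct_evidence(records, rule, toy_cause_list)
        weights = cause_weights(out, toy_cause_list)
        assert weights == pytest.approx({"cup": 7.0, "lung_ca": 1.8, "colorectal_ca": 1.2})
        assert total_weight(out) == pytest.approx(10.0, rel=1e-12)
        # retained records keep their original code and are settled
        retained = [r for r in out if toy_cause_list.map_code(r.ucod) == "cup"]
        assert all(r.ucod == "C80" and r.settled for r in retained)

    def test_identity_table_keeps_records(self, toy_cause_list):
        rule = RedistributionRule(
            source_cause="cup", method="direct", probability_table={"cup": 1.0}
        )
        records = [death("r1", "C80.9", age=55, weight=2.0)]
        (out,) = apply_direct_evidence(records, rule, toy_cause_list)
        assert (out.ucod, out.age, out.weight) == ("C80.9", 55, 2.0)

    def test_bad_table_sum_rejected(self, toy_cause_list):
        with pytest.raises(ValidationError):
            RedistributionRule(
                source_cause="cup", method="direct",
                probability_table={"cup": 0.6, "lung_ca": 0.6},
            )


class TestProportional:
    def _rule(self, targets):
        return RedistributionRule(
            source_cause="ill_defined", method="proportional", target_causes=targets
        )

    def test_proportional_arithmetic(self, toy_cause_list):
        records = [death(f"r{i}", "R99") for i in range(100)]
        out = apply_proportional(
            records, self._rule(("chd", "stroke")),
            {"chd": 300.0, "stroke": 100.0}, toy_cause_list,
        )
        weights = cause_weights(out, toy_cause_list)
        assert weights == pytest.approx({"chd": 75.0, "stroke": 25.0})

    def test_single_target(self, toy_cause_list):
        out = apply_proportional(
            [death("r", "R99", weight=3.0)], self._rule(("chd",)),
            {"chd": 10.0}, toy_cause_list,
        )
        assert cause_weights(out, toy_cause_list) == pytest.approx({"chd": 3.0})

    def test_zero_base_falls_back_to_uniform(self, toy_cause_list, caplog):
        targets = ("chd", "stroke", "pneumonia", "lung_ca")
        with caplog.at_level("WARNING"):
            out = apply_proportional(
                [death(f"r{i}", "R99") for i in range(100)],
                self._rule(targets), {}, toy_cause_list,
            )
        weights = cause_weights(out, toy_cause_list)
        assert weights == pytest.approx({t: 25.0 for t in targets})
        assert any("uniform" in rec.message for rec in caplog.records)


def standard_rules():
    return [
        RedistributionRule(
            source_cause="sepsis", method="indirect_mcod"
        ),
        RedistributionRule(
            source_cause="cup", method="direct",
            probability_table={"cup": 0.7, "lung_ca": 0.2, "colorectal_ca": 0.1},
        ),
        RedistributionRule(
            source_cause="unspec_ca", method="direct",
            probability_table={"cup": 0.4, "lung_ca": 0.6},
        ),
        RedistributionRule(
            source_cause="ill_defined", method="proportional",
            target_causes=("chd", "stroke", "pneumonia"),
        ),
    ]


class TestRedistribute:
    def test_noop_without_source_records(self, toy_cause_list):
        records = [death("a", "I21"), death("b", "J18", ["A41"])]
        out, report = redistribute(records, standard_rules(), toy_cause_list)
        assert cause_weights(out, toy_cause_list) == cause_weights(
            records, toy_cause_list
        )
        assert report.redistributed_fraction == 0.0

    def test_conservation_on_mixed_fixture(self, toy_cause_list):
        rng = np.random.default_rng(42)
        codes = ["I21", "J18", "C34", "C18", "I60", "A41", "R99", "C80", "C76"]
        records = [
            death(
                f"r{i}",
                codes[rng.integers(len(codes))],
                ["A41"] if rng.random() < 0.3 else [],
                weight=float(rng.random() + 0.5),
            )
            for i in range(1000)
        ]
        out, report = redistribute(records, standard_rules(), toy_cause_list)
        assert total_weight(out) == pytest.approx(total_weight(records), rel=1e-9)
        assert report.total_weight_out == pytest.approx(report.total_weight_in, rel=1e-9)

    def test_only_retained_weight_stays_on_sources(self, toy_cause_list):
        records = [death(f"r{i}", c) for i, c in enumerate(["A41", "R99", "C76", "C80", "I21"])]
        out, _ = redistribute(records, standard_rules(), toy_cause_list)
        for r in out:
            cause = toy_cause_list.map_code(r.ucod)
            if toy_cause_list[cause].is_redistribution_source:
                assert r.settled and cause == "cup"

    def test_cascade_matches_closed_form(self, toy_cause_list):
        # unspecified site -> {cup 0.4, lung 0.6}; cup -> {cup 0.7, lung 0.2, crc 0.1}
        records = [death(f"r{i}", "C76") for i in range(100)]
        out, _ = redistribute(records, standard_rules(), toy_cause_list)
        weights = cause_weights(out, toy_cause_list)
        # hand-multiplied two-step composition of the two tables
        assert weights == pytest.approx(
            {
                "cup": 100 * 0.4 * 0.7,
                "lung_ca": 100 * (0.6 + 0.4 * 0.2),
                "colorectal_ca": 100 * 0.4 * 0.1,
            }
        )

    def test_idempotent(self, toy_cause_list):
        rng = np.random.default_rng(7)
        codes = ["I21", "J18", "A40", "R00", "C80", "C76", "C33"]
        records = [
            death(f"r{i}", codes[rng.integers(len(codes))],
                  ["A41"] if rng.random() < 0.5 else [])
            for i in range(200)
        ]
        once, _ = redistribute(records, standard_rules(), toy_cause_list)
        twice, report = redistribute(once, standard_rules(), toy_cause_list)
        assert report.redistributed_fraction == 0.0
        assert cause_weights(twice, toy_cause_list) == pytest.approx(
            cause_weights(once, toy_cause_list), rel=1e-12
        )

    def test_report_shares(self, toy_cause_list):
        # 10 sepsis (indirect), 10 ill-defined (proportional), 80 specific
        records = (
            [death(f"s{i}", "A41") for i in range(10)]
            + [death(f"i{i}", "R54") for i in range(10)]
            + [death(f"c{i}", "I21", ["A41"]) for i in range(40)]
            + [death(f"p{i}", "J18") for i in range(40)]
        )
        out, report = redistribute(records, standard_rules(), toy_cause_list)
        assert report.redistributed_fraction == pytest.approx(0.2)
        assert report.method_shares == pytest.approx(
            {"indirect_mcod": 0.5, "proportional": 0.5}
        )
        # septicaemia weight follows the mention pattern (all mentions are CHD);
        # the proportional base then sees the already-redistributed CHD weight
        weights = cause_weights(out, toy_cause_list)
        assert weights["chd"] == pytest.approx(40 + 10 + 10 * 50 / 90)
        assert weights["pneumonia"] == pytest.approx(40 + 10 * 40 / 90)

    def test_within_group_accounting(self, toy_cause_list):
        records = [death("a", "C76")]  # cancer-group source
        _, report = redistribute(records, standard_rules(), toy_cause_list)
        # every destination, including the unknown-primary cascade, is a cancer
        assert report.within_group_fraction == pytest.approx(1.0)

    def test_missing_rule_rejected(self, toy_cause_list):
        with pytest.raises(ConfigurationError) as exc:
            redistribute([death("a", "I21")], standard_rules()[:2], toy_cause_list)
        assert "ill_defined" in str(exc.value) or "unspec_ca" in str(exc.value)

    def test_cycle_rejected(self):
        cl = CauseList(
            [
                make_cause("a", "g", ["A00"], source=True),
                make_cause("b", "g", ["B00"], source=True),
                make_cause("c", "g", ["C00"]),
            ]
        )
        rules = [
            RedistributionRule("a", "direct", probability_table={"b": 1.0}),
            RedistributionRule("b", "direct", probability_table={"a": 1.0}),
        ]
        with pytest.raises(ConfigurationError) as exc:
            redistribute([death("r", "A00")], rules, cl)
        assert "cyc" in str(exc.value).lower()

    def test_duplicate_rule_rejected(self, toy_cause_list):
        rules = standard_rules() + [standard_rules()[0]]
        with pytest.raises(ConfigurationError):
            redistribute([], rules, toy_cause_list)

    def test_empty_indirect_falls_back_within_group(self, toy_cause_list):
        # nothing mentions septicaemia -> fallback proportional over infections
        # group; that group has no specific member, so over all specific causes
        records = [death("a", "A41"), death("b", "I21"), death("c", "I21")]
        out, _ = redistribute(records, standard_rules(), toy_cause_list)
        weights = cause_weights(out, toy_cause_list)
        assert weights["chd"] == pytest.approx(3.0)

    def test_stochastic_mode_conserves_and_reproduces(self, toy_cause_list):
        records = [death(f"r{i}", "C80") for i in range(50)]
        out1, _ = redistribute(
            records, standard_rules(), toy_cause_list, stochastic=True, seed=11
        )
        out2, _ = redistribute(
            records, standard_rules(), toy_cause_list, stochastic=True, seed=11
        )
        assert total_weight(out1) == pytest.approx(50.0, rel=1e-12)
        assert [(r.record_id, r.ucod, r.weight) for r in out1] == [
            (r.record_id, r.ucod, r.weight) for r in out2
        ]
        with pytest.raises(ConfigurationError):
            redistribute(records, standard_rules(), toy_cause_list, stochastic=True)


class TestRulesFile:
    def test_load_round_trip(self, tmp_path, toy_cause_list):
        path = tmp_path / "rules.yaml"
        path.write_text(
            """
rules:
  - {source: cup, method: direct, table: {cup: 0.7, lung_ca: 0.3}}
  - {source: sepsis, method: combination, direct_share: 0.2,
     table: {pneumonia: 1.0}}
  - {source: ill_defined, method: proportional, targets: [chd, stroke]}
  - {source: unspec_ca, method: direct, table: {lung_ca: 1.0}}
"""
        )
        rules = load_rules(path, toy_cause_list)
        assert [r.method for r in rules] == [
            "direct", "combination", "proportional", "direct",
        ]

    def test_unknown_target_rejected(self, tmp_path, toy_cause_list):
        path = tmp_path / "rules.yaml"
        path.write_text("rules:\n  - {source: cup, method: direct, table: {nope: 1.0}}\n")
        with pytest.raises(ConfigurationError):
            load_rules(path, toy_cause_list)


@st.composite
def record_fixture(draw):
    codes = ["I21", "I60", "J18", "C34", "C18", "A41", "A40", "R99", "C80", "C76"]
    n = draw(st.integers(min_value=1, max_value=25))
    records = []
    for i in range(n):
        ucod = draw(st.sampled_from(codes))
        assoc = draw(st.lists(st.sampled_from(codes), max_size=2))
        weight = draw(
            st.floats(min_value=0.01, max_value=5.0, allow_nan=False)
        )
        records.append(death(f"r{i}", ucod, assoc, weight=weight))
    return records


class TestConservationProperty:
    @given(records=record_fixture())
    @settings(max_examples=150, deadline=None)
    def test_orchestrator_conserves_weight(self, records):
        cl = CauseList(
            [
                make_cause("chd", "cardiovascular", ["I20-I25"]),
                make_cause("stroke", "cardiovascular", ["I60-I64"]),
                make_cause("pneumonia", "respiratory", ["J12-J18"]),
                make_cause("lung_ca", "cancer", ["C33-C34"]),
                make_cause("colorectal_ca", "cancer", ["C18-C20"]),
                make_cause("sepsis", "infections", ["A40-A41"], source=True),
                make_cause("cup", "cancer", ["C80"], source=True),
                make_cause("unspec_ca", "cancer", ["C76"], source=True),
                make_cause("ill_defined", "ill-defined", ["R00-R99"], source=True),
            ]
        )
        out, report = redistribute(records, standard_rules(), cl)
        assert math.isclose(
            total_weight(out), total_weight(records), rel_tol=1e-9, abs_tol=1e-9
        )
        assert 0.0 <= report.redistributed_fraction <= 1.0
        assert 0.0 <= report.within_group_fraction <= 1.0


class TestOracleEquivalence:
    def test_matches_naive_double_loop(self, toy_cause_list):
        rng = np.random.default_rng(123)
        codes = ["I21", "I22", "J15", "C34", "C18", "A41", "A40", "R99", "C80"]
        for _ in range(20):
            n = int(rng.integers(5, 2000))
            records = [
                death(
                    f"r{i}",
                    codes[rng.integers(len(codes))],
                    [codes[rng.integers(len(codes))] for _ in range(rng.integers(0, 3))],
                    weight=float(rng.random() + 0.1),
                )
                for i in range(n)
            ]
            fast = build_indirect_mcod_distribution(records, "sepsis", toy_cause_list)
            slow = naive_indirect_counter(records, "sepsis", toy_cause_list)
            assert fast == pytest.approx(slow, rel=1e-12)
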