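"""Phenotype engine: code groups, composites, quantitative traits, progression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phewaskit import core, phenotypes
from phewaskit.core import CodeSet, CodeSetMember, EventTable, PhenotypeColumn, PhenotypeMatrix
from phewaskit.phenotypes import (
    AllOf, AnyOf, BuildOptions, NotRule, Predicate, QuantTraitSpec,
    build_phenotype_matrix, collapse_correlated, drug_response, evaluate_composite,
    extract_quantitative, map_code_groups, stratify_by_sex, trajectory_slope,
    age_of_onset, event_count,
)


def _participants(n, sexes=None):
    return pd.DataFrame({
        "eid": [f"P{i+1}" for i in range(n)],
        "sex": sexes or ["female"] * n,
        "birth_date": pd.to_datetime(["1950-01-01"] * n),
    })


def _events(rows):
    """rows: (eid, source, vocab, code, date, value)."""
    df = pd.DataFrame(rows, columns=["eid", "source", "vocab", "code", "date", "value"])
    df["date"] = pd.to_datetime(df["date"])
    df["unit"] = "NA"
    return EventTable(df)


COPD = CodeSet("copd", (CodeSetMember("ICD10", "J44", "prefix"),))
ASTHMA = CodeSet("asthma", (CodeSetMember("ICD10", "J45", "prefix"),))


class TestMapCodeGroups:
    MAP = phenotypes.CodeGroupMap(
        pd.DataFrame({
            "vocab": ["ICD10", "ICD10"], "pattern": ["J44", "J45"],
            "match_mode": ["prefix", "prefix"],
            "group_id": ["G_COPD", "G_ASTHMA"],
            "group_label": ["COPD", "Asthma"],
        }),
        exclusions={"G_COPD": ["G_ASTHMA"], "G_ASTHMA": ["G_COPD"]},
    )

    def test_distinct_date_case_and_single_event_control(self):
        pp = _participants(2)
        ev = _events([
            ("P1", "hospital", "ICD10", "J44.1", "2010-01-01", np.nan),
            ("P1", "hospital", "ICD10", "J44.9", "2011-01-01", np.nan),
            ("P2", "hospital", "ICD10", "J44.1", "2010-01-01", np.nan),
        ])
        m = map_code_groups(ev, self.MAP, min_count=2, participants=pp)
        assert m.values.loc["P1", "G_COPD"] == 1.0
        assert m.values.loc["P2", "G_COPD"] == 0.0

    def test_same_day_duplicates_count_once(self):
        pp = _participants(1)
        ev = _events([
            ("P1", "hospital", "ICD10", "J44.1", "2010-01-01", np.nan),
            ("P1", "hospital", "ICD10", "J44.9", "2010-01-01", np.nan),
        ])
        m = map_code_groups(ev, self.MAP, min_count=2, participants=pp)
        assert m.values.loc["P1", "G_COPD"] == 0.0  # one distinct date only

    def test_exclusion_group_case_becomes_missing(self):
        pp = _participants(3)
        ev = _events([
            ("P1", "hospital", "ICD10", "J45.0", "2009-01-01", np.nan),
            ("P1", "hospital", "ICD10", "J45.1", "2010-01-01", np.nan),
            ("P2", "hospital", "ICD10", "J44.1", "2010-01-01", np.nan),
            ("P2", "hospital", "ICD10", "J44.1", "2011-01-01", np.nan),
        ])
        m = map_code_groups(ev, self.MAP, min_count=2, participants=pp)
        # P1 is an asthma case, so excluded from COPD controls
        assert np.isnan(m.values.loc["P1", "G_COPD"])
        assert np.isnan(m.values.loc["P2", "G_ASTHMA"])
        assert m.values.loc["P3", "G_COPD"] == 0.0

    def test_case_control_missing_partition_cohort(self):
        pp = _participants(3)
        ev = _events([
            ("P1", "hospital", "ICD10", "J45.0", "2009-01-01", np.nan),
            ("P1", "hospital", "ICD10", "J45.1", "2010-01-01", np.nan),
        ])
        m = map_code_groups(ev, self.MAP, min_count=2, participants=pp)
        for col in m.values.columns:
            v = m.values[col]
            assert int((v == 1).sum() + (v == 0).sum() + v.isna().sum()) == len(pp)


class TestEvaluateComposite:
    CODE_SETS = {
        "copd_icd": COPD,
        "copd_rx": CodeSet("copd_rx", (CodeSetMember("CUSTOM", "RX_COPD", "exact"),)),
    }

    def _definition(self):
        return phenotypes.PhenotypeDefinition(
            phenotype_id="X", kind="binary",
            case_rule=AnyOf((Predicate("copd_icd", "hospital", 1),
                             Predicate("copd_rx", "prescription", 2))),
        )

    def test_two_prescriptions_make_a_case(self):
        pp = _participants(1)
        ev = _events([
            ("P1", "prescription", "CUSTOM", "RX_COPD", "2010-01-01", np.nan),
            ("P1", "prescription", "CUSTOM", "RX_COPD", "2010-06-01", np.nan),
        ])
        col = evaluate_composite(self._definition(), ev, pp, self.CODE_SETS)
        assert col["P1"] == 1.0

    def test_single_prescription_is_control(self):
        pp = _participants(1)
        ev = _events([("P1", "prescription", "CUSTOM", "RX_COPD", "2010-01-01", np.nan)])
        col = evaluate_composite(self._definition(), ev, pp, self.CODE_SETS)
        assert col["P1"] == 0.0

    def test_unknown_code_set_reference_fatal(self):
        d = phenotypes.PhenotypeDefinition(
            phenotype_id="X", kind="binary", case_rule=Predicate("nonexistent"))
        with pytest.raises(core.PhewasError, match="nonexistent"):
            evaluate_composite(d, _events([("P1", "hospital", "ICD10", "J44", "2010-01-01", np.nan)]),
                               _participants(1), self.CODE_SETS)

    def test_sex_restriction_masks_opposite_sex(self):
        pp = _participants(3, sexes=["female", "male", "unknown"])
        ev = _events([(p, "hospital", "ICD10", "J44.1", "2010-01-01", np.nan)
                      for p in ("P1", "P2", "P3")])
        d = phenotypes.PhenotypeDefinition(
            phenotype_id="X", kind="binary", case_rule=Predicate("copd_icd"),
            sex_restriction="female_only")
        col = evaluate_composite(d, ev, pp, self.CODE_SETS)
        assert col["P1"] == 1.0 and np.isnan(col["P2"]) and np.isnan(col["P3"])

    def test_truth_table_matches_brute_force_boolean_oracle(self):
        # 8 participants = all subsets of predicates {x, y, z};
        # rule ALL(x, y) with NOT(z) as control exclusion
        sets = {c: CodeSet(c, (CodeSetMember("CUSTOM", c.upper(), "exact"),))
                for c in "xyz"}
        rows = []
        flags = {}
        for i in range(8):
            eid = f"P{i+1}"
            has = {c: bool(i >> j & 1) for j, c in enumerate("xyz")}
            flags[eid] = has
            for c, present in has.items():
                if present:
                    rows.append((eid, "hospital", "CUSTOM", c.upper(), "2010-01-01", np.nan))
        pp = _participants(8)
        d = phenotypes.PhenotypeDefinition(
            phenotype_id="T", kind="binary",
            case_rule=AllOf((Predicate("x"), Predicate("y"))),
            control_exclusion_rule=NotRule(Predicate("z")),
        )
        col = evaluate_composite(d, _events(rows), pp, sets)
        for eid, has in flags.items():
            case = has["x"] and has["y"]
            if case:
                assert col[eid] == 1.0
            elif not has["z"]:           # exclusion NOT(z) true -> missing
                assert np.isnan(col[eid])
            else:
                assert col[eid] == 0.0

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_random_rules_match_boolean_oracle(self, data):
        """Composite evaluation equals brute-force boolean logic on
        all-boolean fixtures (<=10 participants, <=4 predicates)."""
        preds = "abcd"
        sets = {c: CodeSet(c, (CodeSetMember("CUSTOM", c.upper(), "exact"),))
                for c in preds}

        def rule_strategy(depth):
            leaf = st.sampled_from([Predicate(c) for c in preds])
            if depth == 0:
                return leaf
            sub = rule_strategy(depth - 1)
            return st.one_of(
                leaf,
                st.lists(sub, min_size=1, max_size=3).map(lambda l: AnyOf(tuple(l))),
                st.lists(sub, min_size=1, max_size=3).map(lambda l: AllOf(tuple(l))),
                sub.map(NotRule),
            )

        def brute(rule, has):
            if isinstance(rule, Predicate):
                return has[rule.code_set]
            if isinstance(rule, AnyOf):
                return any(brute(c, has) for c in rule.children)
            if isinstance(rule, AllOf):
                return all(brute(c, has) for c in rule.children)
            return not brute(rule.child, has)

        n = data.draw(st.integers(1, 10))
        case_rule = data.draw(st.one_of(
            rule_strategy(1).filter(lambda r: not isinstance(r, NotRule)),
        ))
        excl_rule = data.draw(st.none() | rule_strategy(1))
        rows, flags = [], {}
        for i in range(n):
            eid = f"P{i+1}"
            has = {c: data.draw(st.booleans()) for c in preds}
            flags[eid] = has
            for c, present in has.items():
                if present:
                    rows.append((eid, "hospital", "CUSTOM", c.upper(), "2010-01-01", np.nan))
        d = phenotypes.PhenotypeDefinition(
            phenotype_id="T", kind="binary", case_rule=case_rule,
            control_exclusion_rule=excl_rule)
        ev = _events(rows) if rows else _events(
            [("P1", "hospital", "CUSTOM", "NONE", "2010-01-01", np.nan)])
        col = evaluate_composite(d, ev, _participants(n), sets)
        for eid, has in flags.items():
            case = brute(case_rule, has)
            if case:
                assert col[eid] == 1.0
            elif excl_rule is not None and brute(excl_rule, has):
                assert np.isnan(col[eid])
            else:
                assert col[eid] == 0.0


SODIUM = CodeSet("sodium", (CodeSetMember("CUSTOM", "NA_BLOOD", "exact"),))


class TestExtractQuantitative:
    def _ev(self, values_dates):
        return _events([("P1", "primary_care", "CUSTOM", "NA_BLOOD", d, v)
                        for d, v in values_dates])

    def test_mean_aggregation(self):
        ev = self._ev([("2010-01-01", 138.0), ("2011-01-01", 140.0), ("2012-01-01", 142.0)])
        spec = QuantTraitSpec("sodium", "mean", 1)
        col = extract_quantitative(ev, spec, _participants(1), {"sodium": SODIUM})
        assert col["P1"] == 140.0

    def test_plausible_range_drops_outliers(self):
        ev = self._ev([("2010-01-01", 140.0), ("2011-01-01", 9999.0)])
        spec = QuantTraitSpec("sodium", "mean", 1, plausible_range=(100.0, 200.0))
        col = extract_quantitative(ev, spec, _participants(1), {"sodium": SODIUM})
        assert col["P1"] == 140.0

    def test_min_measurements_not_met_is_missing(self):
        ev = self._ev([("2010-01-01", 140.0)])
        spec = QuantTraitSpec("sodium", "mean", 2)
        col = extract_quantitative(ev, spec, _participants(1), {"sodium": SODIUM})
        assert np.isnan(col["P1"])

    def test_first_last_with_same_day_ties_averaged(self):
        ev = self._ev([("2010-01-01", 100.0), ("2010-01-01", 102.0), ("2012-01-01", 130.0)])
        first = extract_quantitative(ev, QuantTraitSpec("sodium", "first", 1),
                                     _participants(1), {"sodium": SODIUM})
        last = extract_quantitative(ev, QuantTraitSpec("sodium", "last", 1),
                                    _participants(1), {"sodium": SODIUM})
        assert first["P1"] == 101.0 and last["P1"] == 130.0


class TestTrajectorySlope:
    def _ev(self, pairs):  # (date, value)
        return _events([("P1", "primary_care", "CUSTOM", "NA_BLOOD", d, v) for d, v in pairs])

    def test_collinear_points_give_exact_slope(self):
        ev = self._ev([("2000-01-01", 1.0), ("2001-01-01", 2.0), ("2002-01-01", 3.0)])
        col = trajectory_slope(ev, SODIUM, 3, _participants(1))
        # one unit per year up to leap-day rounding in the age axis
        assert col["P1"] == pytest.approx(1.0, abs=2e-3)

    def test_constant_values_give_zero_slope(self):
        ev = self._ev([("2000-01-01", 5.0), ("2001-01-01", 5.0), ("2002-01-01", 5.0)])
        assert trajectory_slope(ev, SODIUM, 3, _participants(1))["P1"] == 0.0

    def test_matches_closed_form_ols(self):
        rng = np.random.default_rng(3)
        dates = pd.date_range("2000-01-01", periods=10, freq="181D")
        vals = 0.3 * np.arange(10) + rng.normal(0, 1, 10)
        ev = self._ev([(d.strftime("%Y-%m-%d"), v) for d, v in zip(dates, vals)])
        col = trajectory_slope(ev, SODIUM, 3, _participants(1))
        birth = pd.Timestamp("1950-01-01")
        x = np.array([(d - birth).days / 365.25 for d in dates])
        expected = np.sum((x - x.mean()) * (vals - vals.mean())) / np.sum((x - x.mean()) ** 2)
        assert col["P1"] == pytest.approx(expected, abs=1e-10)

    def test_too_few_measurements_missing(self):
        ev = self._ev([("2000-01-01", 1.0), ("2001-01-01", 2.0)])
        assert np.isnan(trajectory_slope(ev, SODIUM, 3, _participants(1))["P1"])


RX = CodeSet("rx", (CodeSetMember("CUSTOM", "RX", "exact"),))
LDL = CodeSet("ldl", (CodeSetMember("CUSTOM", "LDL", "exact"),))


class TestDrugResponse:
    def test_delta_of_window_means(self):
        ev = _events([
            ("P1", "prescription", "CUSTOM", "RX", "2010-06-01", np.nan),
            ("P1", "primary_care", "CUSTOM", "LDL", "2010-01-01", 10.0),
            ("P1", "primary_care", "CUSTOM", "LDL", "2010-03-01", 10.0),
            ("P1", "primary_care", "CUSTOM", "LDL", "2010-09-01", 8.0),
        ])
        col = drug_response(ev, RX, LDL, 365, (30, 365), _participants(1))
        assert col["P1"] == pytest.approx(-2.0)

    def test_no_prescription_missing(self):
        ev = _events([("P1", "primary_care", "CUSTOM", "LDL", "2010-01-01", 10.0)])
        assert np.isnan(drug_response(ev, RX, LDL, 365, (30, 365), _participants(1))["P1"])

    def test_measure_on_index_date_in_neither_window(self):
        ev = _events([
            ("P1", "prescription", "CUSTOM", "RX", "2010-06-01", np.nan),
            ("P1", "primary_care", "CUSTOM", "LDL", "2010-06-01", 99.0),
            ("P1", "primary_care", "CUSTOM", "LDL", "2010-01-01", 10.0),
            ("P1", "primary_care", "CUSTOM", "LDL", "2010-09-01", 8.0),
        ])
        col = drug_response(ev, RX, LDL, 365, (30, 365), _participants(1))
        assert col["P1"] == pytest.approx(-2.0)  # the 99 on the index date is ignored


class TestProgression:
    def _setup(self):
        pp = pd.DataFrame({
            "eid": ["P1", "P2"],
            "sex": ["female", "male"],
            "birth_date": pd.to_datetime(["1960-01-01", "1960-01-01"]),
        })
        ev = _events([
            ("P1", "hospital", "ICD10", "J44.1", "2012-05-05", np.nan),
            ("P1", "hospital", "ICD10", "J44.9", "2010-01-01", np.nan),
            ("P1", "hospital", "ICD10", "J44.9", "2009-06-30", np.nan),
        ])
        binary = pd.Series([1.0, 0.0], index=pd.Index(["P1", "P2"], name="eid"))
        return pp, ev, binary

    def test_age_at_earliest_qualifying_event(self):
        pp, ev, binary = self._setup()
        col = age_of_onset(binary, [(COPD, None)], ev, pp)
        expected = (pd.Timestamp("2009-06-30") - pd.Timestamp("1960-01-01")).days / 365.25
        assert col["P1"] == pytest.approx(expected, abs=1e-12)
        assert np.isnan(col["P2"])  # control is missing

    def test_fifty_year_interval(self):
        pp = _participants(1)
        pp["birth_date"] = pd.to_datetime(["1960-01-01"])
        ev = _events([("P1", "hospital", "ICD10", "J44.1", "2010-01-01", np.nan)])
        binary = pd.Series([1.0], index=pd.Index(["P1"], name="eid"))
        col = age_of_onset(binary, [(COPD, None)], ev, pp)
        assert 49.989 <= col["P1"] <= 50.009

    def test_event_count_post_onset_distinct_dates(self):
        pp, ev, binary = self._setup()
        exac = CodeSet("exac", (CodeSetMember("ICD10", "J44.1", "exact"),))
        col = event_count(binary, exac, [(COPD, None)], ev, pp)
        assert col["P1"] == 1.0          # only 2012-05-05 matches J44.1
        assert np.isnan(col["P2"])

    def test_qualifying_events_only_before_onset_count_zero(self):
        pp = _participants(1)
        ev = _events([
            ("P1", "hospital", "ICD10", "J44.9", "2010-01-01", np.nan),
            ("P1", "hospital", "ICD10", "J44.1", "2005-01-01", np.nan),
        ])
        binary = pd.Series([1.0], index=pd.Index(["P1"], name="eid"))
        onset_set = CodeSet("onset", (CodeSetMember("ICD10", "J44.9", "exact"),))
        exac = CodeSet("exac", (CodeSetMember("ICD10", "J44.1", "exact"),))
        assert event_count(binary, exac, [(onset_set, None)], ev, pp)["P1"] == 0.0


def _quant_matrix(arrays, ids=None):
    cols = {f"T{i+1}": a for i, a in enumerate(arrays)}
    idx = pd.Index(ids or [f"P{i+1}" for i in range(len(arrays[0]))], name="eid")
    values = pd.DataFrame(cols, index=idx, dtype=float)
    meta = [PhenotypeColumn(c, c, "quantitative") for c in values.columns]
    return PhenotypeMatrix(values, meta)


class TestCollapseCorrelated:
    def test_perfect_correlation_collapses_to_one(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=100)
        m = _quant_matrix([a, 2 * a, rng.normal(size=100)])
        reduced, report = collapse_correlated(m, 0.9)
        assert set(reduced.values.columns) == {"T1", "T3"}
        assert report.iloc[0].tolist() == ["T2", "T1"]

    def test_uncorrelated_matrix_unchanged(self):
        rng = np.random.default_rng(1)
        m = _quant_matrix([rng.normal(size=200) for _ in range(4)])
        reduced, report = collapse_correlated(m, 0.9)
        assert list(reduced.values.columns) == ["T1", "T2", "T3", "T4"]
        assert report.empty

    def test_curated_representative_honoured_and_validated(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=100)
        m = _quant_matrix([a, 2 * a + rng.normal(0, 0.01, 100)])
        reduced, _ = collapse_correlated(m, 0.9, curated_representatives={"T1": "T2"})
        assert list(reduced.values.columns) == ["T2"]
        with pytest.raises(core.PhewasError, match="component"):
            collapse_correlated(m, 0.9, curated_representatives={"T1": "T9"})

    def test_sparse_overlap_pairs_treated_as_uncorrelated(self):
        a = np.r_[np.arange(20.0), np.full(80, np.nan)]
        b = np.r_[np.full(80, np.nan), np.arange(20.0)]
        m = _quant_matrix([a, b])
        reduced, _ = collapse_correlated(m, 0.9, min_shared=30)
        assert list(reduced.values.columns) == ["T1", "T2"]


class TestStratifyBySex:
    def test_partition_and_unknown_sex(self):
        pp = _participants(6, sexes=["female"] * 3 + ["male"] * 2 + ["unknown"])
        m = _quant_matrix([np.ones(6)])
        m.meta[0] = PhenotypeColumn("T1", "T1", "binary")
        out = stratify_by_sex(m, pp)
        f, ma = out.values["T1_female"], out.values["T1_male"]
        assert int(f.notna().sum()) == 3 and int(ma.notna().sum()) == 2
        assert np.isnan(f["P6"]) and np.isnan(ma["P6"])
        known = int(m.values["T1"][pp.set_index("eid")["sex"] != "unknown"].notna().sum())
        assert int(f.notna().sum() + ma.notna().sum()) == known


class TestBuildMatrix:
    def test_golden_fixture_matches_hand_enumeration(self, golden_inputs, golden_dir):
        participants, events, defs, code_sets, code_map = golden_inputs
        matrix, log = build_phenotype_matrix(
            defs, code_sets, code_map, events, participants,
            BuildOptions(code_group_min_count=2))
        expected = pd.read_csv(golden_dir / "expected_pheno.tsv", sep="\t",
                               na_values=["NA"], keep_default_na=False,
                               dtype={"eid": str}).set_index("eid").astype(float)
        pd.testing.assert_frame_equal(matrix.values, expected,
                                      check_exact=False, rtol=1e-9)

    def test_only_code_groups_when_no_definitions(self, golden_inputs):
        participants, events, _, _, code_map = golden_inputs
        matrix, _ = build_phenotype_matrix([], {}, code_map, events, participants)
        assert list(matrix.values.columns) == ["CG_COPD", "CG_ASTHMA"]

    def test_rerun_is_deterministic_and_row_order_invariant(self, golden_inputs):
        participants, events, defs, code_sets, code_map = golden_inputs
        opts = BuildOptions(code_group_min_count=2)
        m1, _ = build_phenotype_matrix(defs, code_sets, code_map, events, participants, opts)
        shuffled = EventTable(events.data.sample(frac=1, random_state=5).reset_index(drop=True))
        m2, _ = build_phenotype_matrix(defs, code_sets, code_map, shuffled, participants, opts)
        pd.testing.assert_frame_equal(m1.values, m2.values)

    def test_duplicate_phenotype_id_fatal(self, golden_inputs):
        participants, events, defs, code_sets, code_map = golden_inputs
        with pytest.raises(core.ValidationError, match="duplicate"):
            build_phenotype_matrix(defs + [defs[0]], code_sets, code_map,
                                   events, participants)
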