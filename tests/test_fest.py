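import math

import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests

from festflow.fest import (
    FestConfig,
    FestConfigError,
    bh_adjust,
    call_antigen_specific,
    call_triplicate_mode,
    fisher_expansion_test,
    well_presence_fraction,
)
from .conftest import make_table


def hypergeom_upper_tail(a, n1, b, n2):
    """Independent enumeration oracle: P(X >= a) for X hypergeometric with
    population n1+n2, draws n1, successes a+b."""
    K = a + b
    total = 0.0
    for k in range(a, min(n1, K) + 1):
        total += (math.comb(n1, k) * math.comb(n2, K - k)) / math.comb(n1 + n2, K)
    return min(total, 1.0)


class TestFisherExpansionTest:
    def test_empty_clone_is_not_expanded(self):
        p, _ = fisher_expansion_test(0, 100, 0, 100)
        assert p == 1.0

    def test_matches_enumeration_with_zero_reference(self):
        p, orr = fisher_expansion_test(10, 100, 0, 100)
        assert p == pytest.approx(hypergeom_upper_tail(10, 100, 0, 100), abs=1e-12)
        assert orr == pytest.approx((10.5 * 100.5) / (90.5 * 0.5))

    def test_symmetric_table_p_at_least_half(self):
        p, _ = fisher_expansion_test(5, 1000, 5, 1000)
        assert p >= 0.5

    @pytest.mark.parametrize("a,n1,b,n2", [
        (3, 20, 1, 30), (7, 15, 7, 15), (12, 40, 2, 25), (0, 10, 5, 10),
    ])
    def test_matches_enumeration(self, a, n1, b, n2):
        p, _ = fisher_expansion_test(a, n1, b, n2)
        assert p == pytest.approx(hypergeom_upper_tail(a, n1, b, n2), abs=1e-12)

    def test_monotone_in_clone_reads(self):
        # fixed margins: moving a read from reference to condition clone
        ps = [fisher_expansion_test(a, 50, 20 - a, 50)[0] for a in range(21)]
        assert all(p1 >= p2 - 1e-12 for p1, p2 in zip(ps, ps[1:]))

    def test_zero_totals_rejected(self):
        with pytest.raises(ValueError):
            fisher_expansion_test(0, 0, 1, 10)


class TestBhAdjust:
    def test_all_ones(self):
        assert bh_adjust([1, 1, 1]).tolist() == [1, 1, 1]

    def test_hand_computed_step_up(self):
        # p*(m/i) = (.04,.04,.04,.04) after the step-up minimum
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]).tolist() == pytest.approx(
            [0.04, 0.04, 0.04, 0.04])

    def test_single_value_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_matches_statsmodels(self, rng):
        p = rng.uniform(size=40)
        expected = multipletests(p, method="fdr_bh")[1]
        assert bh_adjust(p) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestWellPresenceFraction:
    def test_one_of_ten_wells_passes_at_threshold(self):
        rows = [("CASSIRSSYEQYF", 3, "w1")]
        rows += [("CASSBACKGRDF", 5, f"w{i}") for i in range(1, 11)]
        table = make_table("c", rows)
        assert table.n_wells == 10
        frac = well_presence_fraction("CASSIRSSYEQYF", table)
        assert frac == pytest.approx(0.10)
        assert frac >= FestConfig().min_well_fraction  # "at least" is inclusive

    def test_absent_clone_is_zero(self):
        table = make_table("c", [("CASSBACKGRDF", 5, "w1")])
        assert well_presence_fraction("CASSIRSSYEQYF", table) == 0.0

    def test_single_well_present_is_one(self):
        table = make_table("c", [("CASSIRSSYEQYF", 5, "w1")])
        assert well_presence_fraction("CASSIRSSYEQYF", table) == 1.0


class TestCallAntigenSpecific:
    def test_expanded_clone_called_others_not(self, two_clone_tables):
        cond, ctrl = two_clone_tables
        calls = call_antigen_specific([cond], ctrl, FestConfig(read_floor=30))
        by_clone = calls.set_index("cdr3_aa")
        assert bool(by_clone.loc["CASSEXPANDAF", "verdict"])
        assert not bool(by_clone.loc["CASSBACKGRDF", "verdict"])

    def test_odds_ratio_exactly_five_fails_criterion(self):
        # OR = (50*100)/(100*10) = 5.0 exactly; strict ">5" must fail
        cond = make_table("pepX", [("CASSIRSSYEQYF", 50, "w1"),
                                   ("CASSBACKGRDF", 100, "w1")])
        ctrl = make_table("ctrl", [("CASSIRSSYEQYF", 10, "w1"),
                                   ("CASSBACKGRDF", 100, "w1")])
        calls = call_antigen_specific([cond], ctrl, FestConfig(read_floor=30))
        row = calls.set_index("cdr3_aa").loc["CASSIRSSYEQYF"]
        assert row["odds_ratio"] == pytest.approx(5.0)
        assert not row["crit_or"]
        assert not row["verdict"]

    def test_criterion2_requires_expansion_vs_all_other_conditions(self, two_clone_tables):
        cond, ctrl = two_clone_tables
        # second condition where the clone is just as frequent -> crit 2 fails
        other = cond.copy()
        other.condition_id = "pepY"
        calls = call_antigen_specific([cond, other], ctrl, FestConfig(read_floor=30))
        row = calls.set_index(["cdr3_aa", "condition_id"]).loc[("CASSEXPANDAF", "pepX")]
        assert row["crit_control"] and not row["crit_others"]
        assert not row["verdict"]

    def test_same_mutation_group_exempt_from_criterion2(self, two_clone_tables):
        cond, ctrl = two_clone_tables
        other = cond.copy()
        other.condition_id = "pepY"
        cfg = FestConfig(read_floor=30,
                         mutation_groups={"pepX": "KRAS_G12V", "pepY": "KRAS_G12V"})
        calls = call_antigen_specific([cond, other], ctrl, cfg)
        row = calls.set_index(["cdr3_aa", "condition_id"]).loc[("CASSEXPANDAF", "pepX")]
        assert bool(row["verdict"])

    def test_read_floor_gates_eligibility(self, two_clone_tables):
        cond, ctrl = two_clone_tables
        calls = call_antigen_specific([cond], ctrl, FestConfig(read_floor=1000))
        assert "CASSEXPANDAF" not in set(calls["cdr3_aa"])

    def test_verdicts_invariant_to_condition_order(self, two_clone_tables):
        cond, ctrl = two_clone_tables
        other = make_table("pepY", [("CASSOTHERGYF", 400, "w1"),
                                    ("CASSBACKGRDF", 4600, "w1")])
        cfg = FestConfig(read_floor=30)
        c1 = call_antigen_specific([cond, other], ctrl, cfg)
        c2 = call_antigen_specific([other, cond], ctrl, cfg)
        assert c1.equals(c2)

    def test_missing_control_is_configuration_error(self, two_clone_tables):
        cond, _ = two_clone_tables
        with pytest.raises(FestConfigError):
            call_antigen_specific([cond], None, FestConfig())


def _triplicate_tables(sig_wells):
    """Condition with the clone expanded in the listed wells of w1..w3."""
    rows = []
    for w in ("w1", "w2", "w3"):
        reads = 400 if w in sig_wells else 5
        rows.append(("CASSEXPANDAF", reads, w))
        rows.append(("CASSBACKGRDF", 5000 - reads, w))
    return make_table("pepX", rows)


class TestTriplicateMode:
    ctrl_rows = [("CASSEXPANDAF", 5, "w1"), ("CASSBACKGRDF", 9995, "w1")]

    def test_two_of_three_replicates_suffice(self):
        ctrl = make_table("ctrl", self.ctrl_rows)
        calls = call_triplicate_mode(
            [_triplicate_tables({"w1", "w2"})], ctrl,
            FestConfig(triplicate_mode=True, read_floor=30))
        row = calls.set_index("cdr3_aa").loc["CASSEXPANDAF"]
        assert row["n_replicates_significant"] == 2
        assert bool(row["verdict"])

    def test_one_of_three_fails(self):
        ctrl = make_table("ctrl", self.ctrl_rows)
        calls = call_triplicate_mode(
            [_triplicate_tables({"w1"})], ctrl,
            FestConfig(triplicate_mode=True, read_floor=30))
        assert not calls.set_index("cdr3_aa").loc["CASSEXPANDAF", "verdict"]

    def test_expansion_in_two_conditions_disqualifies_both(self):
        ctrl = make_table("ctrl", self.ctrl_rows)
        t1 = _triplicate_tables({"w1", "w2", "w3"})
        t2 = _triplicate_tables({"w1", "w2", "w3"})
        t2.condition_id = "pepY"
        calls = call_triplicate_mode(
            [t1, t2], ctrl, FestConfig(triplicate_mode=True, read_floor=30))
        clone = calls[calls["cdr3_aa"] == "CASSEXPANDAF"]
        assert not clone["verdict"].any()
        assert clone["significant_elsewhere"].all()

    def test_wrong_replicate_count_is_error(self):
        ctrl = make_table("ctrl", self.ctrl_rows)
        bad = make_table("pepX", [("CASSEXPANDAF", 400, "w1"),
                                  ("CASSBACKGRDF", 4600, "w1")])
        with pytest.raises(FestConfigError, match="3 replicate wells"):
            call_triplicate_mode([bad], ctrl, FestConfig(triplicate_mode=True))
        # override flag permits it
        call_triplicate_mode([bad], ctrl, FestConfig(triplicate_mode=True, read_floor=30),
                             allow_non_triplicate=True)
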