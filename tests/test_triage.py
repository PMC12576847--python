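"""Picker rejection rules, winner picking and the head-to-head selection rule."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from modeltriage import (
    IncompleteMetricsError,
    InputError,
    NoAcceptableModelError,
    RefinementMetrics,
    filter_candidates,
    pick_winner,
    read_metrics_table,
    select_input_model,
    sigma_rfree,
    significant_rfree_change,
    write_metrics_table,
)


def metrics(model_id="m", r_work=0.20, r_free=0.24, n_test=1000, free_ll=-1000.0,
            bond_rmsz=0.5, angle_rmsz=0.5, **kw):
    return RefinementMetrics(
        model_id=model_id, r_work=r_work, r_free=r_free, n_test=n_test,
        free_ll=free_ll, bond_rmsz=bond_rmsz, angle_rmsz=angle_rmsz, **kw,
    )


class TestSigmaRfree:
    @pytest.mark.parametrize("r_free,n_test,expected", [(0.25, 625, 0.01), (0.30, 900, 0.01)])
    def test_closed_form(self, r_free, n_test, expected):
        assert sigma_rfree(r_free, n_test) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(InputError):
            sigma_rfree(0.25, 0)
        with pytest.raises(InputError):
            sigma_rfree(1.2, 100)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(r=st.floats(0.05, 0.5), n=st.integers(1, 10**6))
    def test_monotone(self, r, n):
        assert sigma_rfree(r, n + 1) < sigma_rfree(r, n)
        assert sigma_rfree(min(r * 1.1, 0.99), n) > sigma_rfree(r, n)


class TestFilterCandidates:
    def test_rmsz_rejection_and_boundary(self):
        bad = metrics("bad", bond_rmsz=1.2)
        boundary = metrics("edge", bond_rmsz=1.0, angle_rmsz=0.8, r_work=0.20, r_free=0.22)
        survivors, rejected = filter_candidates([bad, boundary])
        assert [s.model_id for s in survivors] == ["edge"]  # strict inequality
        assert rejected == [("bad", "rmsz")]

    def test_overfit_ratio_and_gap(self):
        ratio = metrics("ratio", r_work=0.20, r_free=0.30)  # ratio 1.5
        gap = metrics("gap", r_work=0.25, r_free=0.32)  # ratio 1.28 but gap 0.07
        survivors, rejected = filter_candidates([ratio, gap])
        assert survivors == []
        assert rejected == [("ratio", "overfit"), ("gap", "overfit")]

    def test_incomplete_metrics_rejected_not_fatal(self):
        incomplete = RefinementMetrics(model_id="partial", r_free=0.25)
        survivors, rejected = filter_candidates([incomplete, metrics("ok")])
        assert [s.model_id for s in survivors] == ["ok"]
        assert rejected == [("partial", "incomplete_metrics")]

    def test_partition_is_exact(self):
        cands = [metrics(f"m{i}", bond_rmsz=0.3 * i) for i in range(1, 8)]
        survivors, rejected = filter_candidates(cands)
        ids = {s.model_id for s in survivors} | {r[0] for r in rejected}
        assert ids == {c.model_id for c in cands}
        assert len(survivors) + len(rejected) == len(cands)

    def test_empty_input_errors(self):
        with pytest.raises(InputError):
            filter_candidates([])


class TestPickWinner:
    def test_lowest_rfree_survivor_wins(self):
        decision = pick_winner([metrics("a", r_free=0.27), metrics("b", r_free=0.25)])
        assert decision.chosen == "b"
        survivors, _ = filter_candidates([metrics("b", r_free=0.25)])
        assert survivors  # the winner always passes the filter

    def test_all_rejected_raises(self):
        cands = [metrics(f"m{i}", bond_rmsz=1.5) for i in range(3)]
        with pytest.raises(NoAcceptableModelError, match="no acceptable model"):
            pick_winner(cands)

    def test_tie_breaks_by_rwork_then_id(self):
        a = metrics("a", r_free=0.25, r_work=0.23)
        b = metrics("b", r_free=0.25, r_work=0.22)
        assert pick_winner([a, b]).chosen == "b"
        c = metrics("c", r_free=0.25, r_work=0.22)
        assert pick_winner([b, c]).chosen == "b"

    def test_shortlist_restriction_by_rfree(self):
        # the ten lowest-Rfree candidates all have bad geometry; a good
        # candidate outside the shortlist must NOT be picked
        bad = [metrics(f"bad{i}", r_free=0.20 + 0.001 * i, bond_rmsz=1.5) for i in range(10)]
        good = metrics("good", r_free=0.35, r_work=0.31)
        with pytest.raises(NoAcceptableModelError):
            pick_winner(bad + [good], top_n_by_rfree=10)
        assert pick_winner(bad + [good], top_n_by_rfree=11).chosen == "good"


class TestSelectInputModel:
    def test_both_conditions_select_original(self):
        orig = metrics("orig", r_free=0.240, n_test=625, free_ll=-990.0)
        chal = metrics("foldit", r_free=0.260, free_ll=-1000.0)
        decision = select_input_model(orig, chal)
        assert decision.chosen == "orig"
        assert all(r["met"] for r in decision.reasons if "met" in r)

    def test_equal_rfree_keeps_challenger(self):
        orig = metrics("orig", r_free=0.25, free_ll=-990.0)
        chal = metrics("foldit", r_free=0.25, free_ll=-1000.0)
        assert select_input_model(orig, chal).chosen == "foldit"

    def test_insufficient_likelihood_margin_keeps_challenger(self):
        orig = metrics("orig", r_free=0.20, free_ll=-994.0)  # margin 6.0 < 6.7
        chal = metrics("foldit", r_free=0.30, free_ll=-1000.0)
        assert select_input_model(orig, chal).chosen == "foldit"

    @pytest.mark.parametrize(
        "delta_ll,rfree_margin_sigma,expect_original",
        [(10.0, 2.0, True), (10.0, 0.5, False), (3.0, 2.0, False), (3.0, 0.5, False)],
    )
    def test_full_condition_table(self, delta_ll, rfree_margin_sigma, expect_original):
        """Only the cell where both conditions hold selects the original."""
        n_test = 625
        orig_rfree = 0.25
        sigma = orig_rfree / math.sqrt(n_test)
        orig = metrics("orig", r_free=orig_rfree, n_test=n_test, free_ll=-1000.0 + delta_ll)
        chal = metrics("foldit", r_free=orig_rfree + rfree_margin_sigma * sigma, free_ll=-1000.0)
        decision = select_input_model(orig, chal)
        assert (decision.chosen == "orig") is expect_original
        assert decision.reasons  # machine-readable trail always present

    def test_missing_fields_error(self):
        orig = RefinementMetrics(model_id="orig", r_free=0.25, n_test=100)
        chal = metrics("foldit")
        with pytest.raises(IncompleteMetricsError):
            select_input_model(orig, chal)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        delta=st.floats(-20, 20),
        bump=st.floats(0.1, 30),
        margin=st.floats(-0.05, 0.05),
    )
    def test_monotone_in_likelihood_advantage(self, delta, bump, margin):
        """Raising the original's likelihood advantage never flips original->challenger."""
        orig = metrics("orig", r_free=0.25, n_test=2500, free_ll=-1000.0 + delta)
        chal = metrics("foldit", r_free=min(max(0.25 + margin, 0.01), 0.99), free_ll=-1000.0)
        first = select_input_model(orig, chal).chosen
        boosted = metrics("orig", r_free=0.25, n_test=2500, free_ll=-1000.0 + delta + bump)
        second = select_input_model(boosted, chal).chosen
        if first == "orig":
            assert second == "orig"

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(delta=st.floats(-20, 20), margin=st.floats(-0.05, 0.05), drop=st.floats(0.001, 0.05))
    def test_monotone_in_challenger_rfree(self, delta, margin, drop):
        """Lowering the challenger's Rfree never flips challenger->original."""
        orig = metrics("orig", r_free=0.25, n_test=2500, free_ll=-1000.0 + delta)
        rf = min(max(0.25 + margin, 0.06), 0.99)
        chal = metrics("foldit", r_free=rf, free_ll=-1000.0)
        first = select_input_model(orig, chal).chosen
        better = metrics("foldit", r_free=max(rf - drop, 0.01), free_ll=-1000.0)
        second = select_input_model(orig, better).chosen
        if first == "foldit":
            assert second == "foldit"


class TestSignificantChange:
    def test_threshold_behaviour(self):
        a = metrics("a", r_free=0.25, n_test=625)  # sigma = 0.01
        assert not significant_rfree_change(a, metrics("b", r_free=0.25))
        assert significant_rfree_change(a, metrics("b", r_free=0.27))  # 2 sigma
        assert not significant_rfree_change(a, metrics("b", r_free=0.255))  # 0.5 sigma

    def test_missing_n_test_errors(self):
        a = RefinementMetrics(model_id="a", r_free=0.25)
        with pytest.raises(IncompleteMetricsError):
            significant_rfree_change(a, metrics("b"))


def test_metrics_table_roundtrip(tmp_path):
    records = [metrics(f"m{i}", molprobity_score=2.0 + i) for i in range(4)]
    path = tmp_path / "metrics.csv"
    write_metrics_table(records, path)
    again = read_metrics_table(path)
    assert [m.model_id for m in again] == [m.model_id for m in records]
    assert again[2].molprobity_score == pytest.approx(4.0)
    bad = tmp_path / "bad.csv"
    bad.write_text("name,r_free\nx,0.25\n")
    with pytest.raises(InputError, match="model_id"):
        read_metrics_table(bad)


def test_metrics_validation():
    with pytest.raises(InputError):
        RefinementMetrics(model_id="x", r_free=1.5)
    with pytest.raises(InputError):
        RefinementMetrics(model_id="x", n_test=0)
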