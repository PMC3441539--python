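"""Unit tests for the domain types and the three reaction-class updates."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nhejsim import (
    ContractError,
    EndStatus,
    FragmentDistribution,
    SimParams,
    apply_join,
    apply_recruitment,
    apply_release,
    build_initial_state,
    simulate,
    site_capacity,
)

from conftest import bind_all

F, B, X = EndStatus.FREE, EndStatus.BOUND, EndStatus.BLOCKED


class TestSimParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"k_f": -1.0},
            {"k_r": -0.5},
            {"V": 0.0},
            {"n_E": 0},
            {"L_min": 50, "L_c": 42},
            {"L_min": 0},
            {"t_max": -1.0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimParams(**kwargs)

    def test_derived_propensities(self):
        p = SimParams(k_f=2.0, n_E=3, k_j=5.0, V=4.0)
        assert p.recruit_propensity == pytest.approx(1.5)
        assert p.join_propensity == pytest.approx(1.25)


class TestSiteCapacity:
    @pytest.mark.parametrize(
        "length,expected",
        [(19, 0), (20, 1), (41, 1), (42, 2), (1, 0), (10000, 2)],
    )
    def test_thresholds(self, length, expected, params):
        assert site_capacity(length, params) == expected

    @pytest.mark.parametrize("bad", [0, -5, 3.5, "30", True])
    def test_invalid_length_rejected(self, bad, params):
        with pytest.raises(ValueError):
            site_capacity(bad, params)


class TestRecruitment:
    def test_free_end_becomes_bound(self, two_long, params):
        state = build_initial_state(two_long, params)
        fid = next(iter(state.fragments))
        apply_recruitment(state, fid, 0)
        assert state.fragments[fid].ends == [B, F]
        assert state.event_counts["RECRUIT"] == 1

    def test_single_site_fragment(self, two_short, params):
        state = build_initial_state(two_short, params)
        fid = next(iter(state.fragments))
        apply_recruitment(state, fid, 0)
        assert state.fragments[fid].ends == [B]

    def test_recruit_on_bound_end_is_contract_violation(self, two_short, params):
        state = build_initial_state(two_short, params)
        fid = next(iter(state.fragments))
        apply_recruitment(state, fid, 0)
        with pytest.raises(ContractError):
            apply_recruitment(state, fid, 0)


class TestJoin:
    def test_short_short_blocks_product_with_one_R_token(self, two_short, params):
        state = bind_all(build_initial_state(two_short, params))
        ids = list(state.fragments)
        apply_join(state, ids[0], 0, ids[1], 0, params)
        (frag,) = state.fragments.values()
        assert frag.length == 60
        assert frag.ends == [X, X]  # 60 >= L_c: capacity 2, both blocked
        (token,) = state.residues.values()
        assert token.kind == "R"
        assert token.blocked_ends == (0, 1)

    def test_short_short_below_critical_keeps_one_tracked_end(self, params):
        # 20 + 20 = 40 < L_c = 42: the product is still a one-site fragment
        dist = FragmentDistribution.from_lengths([20, 20])
        state = bind_all(build_initial_state(dist, params))
        ids = list(state.fragments)
        apply_join(state, ids[0], 0, ids[1], 0, params)
        (frag,) = state.fragments.values()
        assert frag.length == 40 and frag.ends == [X]
        (token,) = state.residues.values()
        assert token.kind == "R" and token.blocked_ends == (0,)

    def test_short_long_blocks_short_side_only(self, short_long, params):
        state = build_initial_state(short_long, params)
        short_id = next(i for i, f in state.fragments.items() if f.length == 30)
        long_id = next(i for i, f in state.fragments.items() if f.length == 100)
        apply_recruitment(state, short_id, 0)
        apply_recruitment(state, long_id, 0)
        apply_join(state, short_id, 0, long_id, 0, params)
        (frag,) = state.fragments.values()
        assert frag.length == 130
        assert frag.ends == [X, F]  # short side blocked, long side stays free
        (token,) = state.residues.values()
        assert token.kind == "r" and token.blocked_ends == (0,)

    def test_long_long_leaves_no_residue_and_inherits_ends(self, two_long, params):
        state = build_initial_state(two_long, params)
        ids = list(state.fragments)
        apply_recruitment(state, ids[0], 0)
        apply_recruitment(state, ids[1], 0)
        apply_recruitment(state, ids[1], 1)
        apply_join(state, ids[0], 0, ids[1], 0, params)
        (frag,) = state.fragments.values()
        assert frag.length == 200
        assert frag.ends == [F, B]  # non-joining statuses carry over
        assert not state.residues

    def test_surviving_r_token_repoints_to_product(self, params):
        # short+long then the product's free long-side end joins another long:
        # the r token must survive onto the final fragment
        dist = FragmentDistribution.from_lengths([30, 100, 100])
        state = build_initial_state(dist, params)
        by_len = sorted(state.fragments.values(), key=lambda f: (f.length, f.id))
        short, long1, long2 = by_len
        apply_recruitment(state, short.id, 0)
        apply_recruitment(state, long1.id, 0)
        apply_join(state, short.id, 0, long1.id, 0, params)
        mid = next(f for f in state.fragments.values() if f.length == 130)
        apply_recruitment(state, mid.id, 1)
        apply_recruitment(state, long2.id, 0)
        apply_join(state, mid.id, 1, long2.id, 0, params)
        (final,) = state.fragments.values()
        assert final.length == 230
        (token,) = state.residues.values()
        assert token.fragment_id == final.id
        assert final.ends[token.blocked_ends[0]] is X

    def test_self_join_rejected(self, two_long, params):
        state = bind_all(build_initial_state(two_long, params))
        fid = next(iter(state.fragments))
        with pytest.raises(ValueError):
            apply_join(state, fid, 0, fid, 1, params)

    def test_join_on_free_end_is_contract_violation(self, two_short, params):
        state = build_initial_state(two_short, params)
        ids = list(state.fragments)
        with pytest.raises(ContractError):
            apply_join(state, ids[0], 0, ids[1], 0, params)


class TestRelease:
    def test_release_R_frees_both_ends(self, two_short, params):
        state = bind_all(build_initial_state(two_short, params))
        ids = list(state.fragments)
        apply_join(state, ids[0], 0, ids[1], 0, params)
        (token_id,) = state.residues
        apply_release(state, token_id, params)
        (frag,) = state.fragments.values()
        assert frag.ends == [F, F]
        assert not state.residues
        assert state.event_counts["RELEASE"] == 1

    def test_release_on_subcritical_product_frees_single_end(self, params):
        dist = FragmentDistribution.from_lengths([20, 20])
        state = bind_all(build_initial_state(dist, params))
        ids = list(state.fragments)
        apply_join(state, ids[0], 0, ids[1], 0, params)
        (token_id,) = state.residues
        apply_release(state, token_id, params)
        (frag,) = state.fragments.values()
        assert frag.ends == [F]  # 40 bp: still only one binding end

    def test_release_unknown_token_is_contract_violation(self, two_short, params):
        state = build_initial_state(two_short, params)
        with pytest.raises(ContractError):
            apply_release(state, 99, params)


class TestInvariants:
    @given(
        lengths=st.lists(st.integers(min_value=20, max_value=300), min_size=2, max_size=6),
        seed=st.integers(min_value=0, max_value=2**20),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_conservation_and_join_count_on_full_runs(self, lengths, seed):
        """Total bp conserved and join events == M0 - 1 on completed runs."""
        params = SimParams()
        dist = FragmentDistribution.from_lengths(lengths)
        traj = simulate(dist, params, seed)
        assert traj.status == "completed"
        assert traj.final_state.total_length == dist.total_length
        assert traj.join_count == dist.m0 - 1
        # fragment-count column equals M0 minus cumulative joins
        joins = 0
        for _, kind, count in traj.events:
            joins += kind == "JOIN"
            assert count == traj.m0_total - joins

    def test_all_long_runs_never_create_residues(self, params):
        dist = FragmentDistribution.from_lengths([100, 150, 200, 250])
        for seed in range(10):
            traj = simulate(dist, params, seed)
            assert traj.release_count == 0
            assert not traj.final_state.residues

    def test_capacity_zero_fragments_never_change(self):
        params = SimParams(include_irreparable=True)
        dist = FragmentDistribution.from_lengths([10, 15, 100, 100, 100])
        traj = simulate(dist, params, 5)
        assert traj.status == "completed"
        irr = [f for f in traj.final_state.fragments.values() if not f.countable]
        assert sorted(f.length for f in irr) == [10, 15]

    def test_blocked_ends_and_tokens_are_in_bijection(self, params):
        dist = FragmentDistribution.from_lengths([25, 30, 35, 100])
        for seed in range(5):
            state = build_initial_state(dist, params)
            rng = np.random.default_rng(seed)
            from nhejsim.gillespie import direct_method_step, execute_channel

            for _ in range(12):
                if state.countable_count <= 1:
                    break
                _, ch = direct_method_step(state, params, rng)
                execute_channel(state, ch, params)
                blocked = {
                    (f.id, e)
                    for f in state.fragments.values()
                    for e, s in enumerate(f.ends)
                    if s is EndStatus.BLOCKED
                }
                from_tokens = {
                    (t.fragment_id, e)
                    for t in state.residues.values()
                    for e in t.blocked_ends
                }
                assert blocked == from_tokens
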