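"""Simulator core: initialization, move classification, rates, stepping."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from condensates import (
    ASK3,
    EMPTY,
    OBSTACLE,
    KmcRandom,
    LatticeConfig,
    LatticeState,
    RateModel,
    classify_move,
    count_contacts,
    expand_grid,
    initialize,
    make_lattice_fixture,
    rate_for,
    run,
    step,
)
from condensates.lattice import _advance


class TestConfig:
    def test_capacity_error(self):
        with pytest.raises(ValueError, match="exceed"):
            LatticeConfig(width=3, height=3, n_ask3=5, n_obstacles=5)

    @pytest.mark.parametrize(
        "field,value",
        [("k1", 1.5), ("k5", -0.1), ("A", 0.0), ("dE_over_theta", -1.0), ("width", 0)],
    )
    def test_invalid_parameters(self, field, value):
        with pytest.raises(ValueError):
            LatticeConfig(**{field: value})


class TestInitialize:
    def test_full_lattice_forced(self):
        cfg = LatticeConfig(width=2, height=2, n_ask3=4, n_obstacles=0)
        state = initialize(cfg, KmcRandom(0))
        assert (state.occupancy() == ASK3).all()

    def test_default_counts(self):
        state = initialize(LatticeConfig(), KmcRandom(3))
        occ = state.occupancy()
        assert (occ == ASK3).sum() == 500
        assert (occ == OBSTACLE).sum() == 1500
        state.validate()

    def test_deterministic_under_seed(self):
        cfg = LatticeConfig(width=30, height=30, n_ask3=40, n_obstacles=60)
        assert initialize(cfg, KmcRandom(5)) == initialize(cfg, KmcRandom(5))

    def test_uniform_placement(self):
        # each square equally likely: chi-square over many initializations
        cfg = LatticeConfig(width=5, height=5, n_ask3=5, n_obstacles=5)
        counts = np.zeros((5, 5))
        n_draws = 400
        for s in range(n_draws):
            counts += initialize(cfg, KmcRandom(s)).occupancy() > 0
        expected = n_draws * 10 / 25
        chi2 = ((counts - expected) ** 2 / expected).sum()
        assert chi2 < 60  # 24 dof, p ~ 1e-4 cutoff


class TestContacts:
    def test_isolated_unit(self):
        state = make_lattice_fixture(9, 9, ask3=[(4, 4)])
        assert count_contacts(state, (4, 4)) == 0

    def test_plus_shape_center_saturated(self):
        plus = [(4, 4), (3, 4), (5, 4), (4, 3), (4, 5)]
        state = make_lattice_fixture(9, 9, ask3=plus)
        assert count_contacts(state, (4, 4)) == 4

    def test_end_of_three_run(self):
        state = make_lattice_fixture(9, 9, ask3=[(2, 4), (3, 4), (4, 4)])
        assert count_contacts(state, (2, 4)) == 1

    def test_obstacles_do_not_count(self):
        state = make_lattice_fixture(9, 9, ask3=[(4, 4)], obstacles=[(3, 4), (5, 4)])
        assert count_contacts(state, (4, 4)) == 0

    def test_out_of_bounds_raises(self, small_state):
        with pytest.raises(IndexError):
            count_contacts(small_state, (99, 0))


class TestClassifyMove:
    def test_free_move(self):
        state = make_lattice_fixture(9, 9, ask3=[(4, 4)])
        p = classify_move(state, 0, (5, 4))
        assert p.move_class == "ask3_free" and p.n_lost == 0

    def test_penalized_move_counts_lost_contacts(self):
        # mover at (3,4) touches two units; destination (3,3) touches none
        state = make_lattice_fixture(9, 9, ask3=[(3, 4), (2, 4), (4, 4)])
        p = classify_move(state, 0, (3, 3))
        assert p.move_class == "ask3_penalized" and p.n_lost == 2

    def test_gaining_contacts_is_free(self):
        # moving from 1 contact to a square adjacent to 2 others
        state = make_lattice_fixture(
            9, 9, ask3=[(2, 4), (3, 4), (5, 4), (5, 3)]
        )
        p = classify_move(state, 0, (2, 3))  # away from everything
        assert p.move_class == "ask3_penalized" and p.n_lost == 1
        # sliding (3,4) -> (4,4): loses contact with (2,4), gains (5,4): net 0
        p2 = classify_move(state, 1, (4, 4))
        assert p2.move_class == "ask3_free" and p2.n_lost == 0

    def test_out_of_bounds_reflects(self):
        state = make_lattice_fixture(3, 3, ask3=[(0, 1)])
        assert classify_move(state, 0, (-1, 1)).move_class == "reflect_out_of_bounds"

    def test_occupied_destination(self):
        state = make_lattice_fixture(9, 9, ask3=[(4, 4), (5, 4)], obstacles=[(3, 4)])
        assert classify_move(state, 0, (3, 4)).move_class == "reflect_occupied"
        assert classify_move(state, 0, (5, 4)).move_class == "ask3_exchange"
        # obstacle bumping into an ASK3 unit reflects
        assert classify_move(state, 2, (4, 4)).move_class == "reflect_occupied"

    def test_obstacle_free(self):
        state = make_lattice_fixture(9, 9, obstacles=[(4, 4)])
        assert classify_move(state, 0, (4, 5)).move_class == "obstacle_free"

    def test_non_neighbour_rejected(self, small_state):
        x, y = small_state.xs[0], small_state.ys[0]
        with pytest.raises(ValueError):
            classify_move(small_state, 0, (x + 2, y))


class TestRates:
    def test_k3_at_zero_lost_is_A(self, default_model):
        assert default_model.k3(0) == 1.0

    def test_k3_closed_form(self, default_model):
        assert default_model.k3(2) == pytest.approx(math.exp(-2))

    def test_k3_strictly_decreasing(self):
        model = RateModel(dE_over_theta=0.7)
        ks = [model.k3(n) for n in range(5)]
        assert all(a > b for a, b in zip(ks, ks[1:]))

    @pytest.mark.parametrize(
        "move_class,n_lost,expected",
        [
            ("ask3_free", 0, 1.0),
            ("obstacle_free", 0, 0.01),
            ("ask3_penalized", 2, math.exp(-2)),
            ("ask3_exchange", 0, 0.0),
            ("reflect_out_of_bounds", 0, 0.0),
            ("reflect_occupied", 0, 0.0),
        ],
    )
    def test_rate_for(self, default_model, move_class, n_lost, expected):
        from condensates import MoveProposal

        p = MoveProposal(0, (1, 1), (2, 1), move_class, n_lost)
        assert rate_for(default_model, p) == pytest.approx(expected)


class TestStep:
    def test_free_unit_always_moves_when_in_bounds(self, default_model):
        # interior unit on a 5x5 grid: all 4 proposals are free, k1 = 1
        moved = 0
        rng = KmcRandom(2)
        state = make_lattice_fixture(5, 5, ask3=[(2, 2)])
        for _ in range(200):
            before = (state.xs[0], state.ys[0])
            step(state, default_model, rng)
            after = (state.xs[0], state.ys[0])
            if after != before:
                moved += 1
            # re-centre to keep every proposal in bounds
            state = make_lattice_fixture(5, 5, ask3=[(2, 2)])
        assert moved == 200

    def test_single_square_grid_never_moves(self, default_model):
        state = make_lattice_fixture(1, 1, ask3=[(0, 0)])
        rng = KmcRandom(0)
        for _ in range(50):
            step(state, default_model, rng)
        assert (state.xs[0], state.ys[0]) == (0, 0)
        assert state.step == 50

    def test_single_molecule_matches_uniform_proposal_enumeration(
        self, default_model
    ):
        # one free unit in the interior: each of the 4 destinations is
        # proposed uniformly and always accepted, so over many one-step
        # trials the empirical move distribution must be uniform over the
        # von Neumann neighbours (binomial 4 sigma).
        from collections import Counter

        rng = KmcRandom(9)
        tally = Counter()
        n = 4000
        for _ in range(n):
            state = make_lattice_fixture(7, 7, ask3=[(3, 3)])
            step(state, default_model, rng)
            tally[(state.xs[0] - 3, state.ys[0] - 3)] += 1
        assert set(tally) == {(1, 0), (-1, 0), (0, 1), (0, -1)}
        sigma = math.sqrt(n * 0.25 * 0.75)
        for moves in tally.values():
            assert abs(moves - n / 4) < 4 * sigma

    def test_obstacle_acceptance_fraction(self, default_model):
        # lone obstacle in the interior: every in-bounds proposal is
        # obstacle_free, accepted with k5 = 0.01
        rng = KmcRandom(17)
        n, accepted = 120_000, 0
        state = make_lattice_fixture(9, 9, obstacles=[(4, 4)])
        for _ in range(n):
            step(state, default_model, rng)
            if (state.xs[0], state.ys[0]) != (4, 4):
                accepted += 1
            state = make_lattice_fixture(9, 9, obstacles=[(4, 4)])
        p = accepted / n
        sigma = math.sqrt(0.01 * 0.99 / n)
        assert abs(p - 0.01) < 3 * sigma

    def test_step_counter_increments(self, small_state, default_model):
        rng = KmcRandom(1)
        step(small_state, default_model, rng)
        assert small_state.step == 1


class TestRunTrajectory:
    def test_zero_steps_only_initial_snapshot(self, small_state, default_model):
        traj = run(small_state, default_model, 0, KmcRandom(0))
        assert len(traj) == 1 and traj[0].step == 0

    def test_counts_conserved_and_consistent(self, default_model):
        cfg = LatticeConfig(width=40, height=40, n_ask3=80, n_obstacles=160, seed=2)
        rng = KmcRandom(cfg.seed)
        state = initialize(cfg, rng)
        traj = run(state, default_model, 50_000, rng, record_every=10_000)
        for snap in traj:
            assert snap.n_ask3 == 80 and snap.n_obstacles == 160
            snap.validate()
        assert traj[-1].step == 50_000

    def test_fixed_seed_bit_identical(self, default_model):
        cfg = LatticeConfig(width=25, height=25, n_ask3=50, n_obstacles=100, seed=4)

        def trajectory():
            rng = KmcRandom(cfg.seed)
            state = initialize(cfg, rng)
            return run(state, default_model, 20_000, rng, record_every=5_000)

        for a, b in zip(trajectory(), trajectory()):
            assert a == b

    def test_advance_equals_repeated_step(self, default_model):
        cfg = LatticeConfig(width=15, height=15, n_ask3=30, n_obstacles=40, seed=6)
        s1 = initialize(cfg, KmcRandom(cfg.seed))
        s2 = s1.copy()
        rng1, rng2 = KmcRandom(42), KmcRandom(42)
        # burn the init stream equally (initialize above consumed s1's)
        _advance(s1, default_model, rng1, 5_000)
        for _ in range(5_000):
            step(s2, default_model, rng2)
        assert s1 == s2

    def test_penalized_acceptance_matches_exponential(self, default_model):
        # dense ASK3-only lattice: bin accepted/proposed by n_lost and
        # compare with exp(-n_lost) (the rejection-sampling check)
        cfg = LatticeConfig(width=30, height=30, n_ask3=300, n_obstacles=0, seed=8)
        rng = KmcRandom(cfg.seed)
        state = initialize(cfg, rng)
        proposed = np.zeros(5)
        accepted = np.zeros(5)
        for _ in range(60_000):
            i = rng.target(state.n_molecules)
            d = rng.direction()
            from condensates.lattice import _DX, _DY

            x, y = state.xs[i], state.ys[i]
            p = classify_move(state, i, (x + _DX[d], y + _DY[d]))
            if p.move_class in ("ask3_free", "ask3_penalized"):
                k = rate_for(default_model, p)
                ok = rng.accept(k)
                if p.n_lost < 5:
                    proposed[p.n_lost] += 1
                    accepted[p.n_lost] += ok
                if ok:
                    nx, ny = p.destination
                    state._grid[y][x] = EMPTY
                    state._grid[ny][nx] = ASK3
                    state.xs[i], state.ys[i] = nx, ny
        for n_lost in range(4):
            if proposed[n_lost] < 50:
                continue
            expect = math.exp(-n_lost)
            frac = accepted[n_lost] / proposed[n_lost]
            sigma = math.sqrt(expect * (1 - expect) / proposed[n_lost]) + 1e-9
            assert abs(frac - expect) < 4 * sigma + 1e-9


class TestExpandGrid:
    def test_expansion_preserves_molecules(self):
        cfg = LatticeConfig(width=55, height=55, seed=1)
        state = initialize(cfg, KmcRandom(1))
        big = expand_grid(state, 120, 120)
        assert big.width == 120 and big.height == 120
        assert big.n_ask3 == 500 and big.n_obstacles == 1500
        assert max(big.xs) < 55 and max(big.ys) < 55
        big.validate()

    def test_identity_expansion(self, small_state):
        same = expand_grid(small_state, small_state.width, small_state.height)
        assert same == small_state

    def test_shrink_rejected(self, small_state):
        with pytest.raises(ValueError, match="shrink"):
            expand_grid(small_state, small_state.width - 1, small_state.height)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 10_000),
    w=st.integers(2, 12),
    h=st.integers(2, 12),
    frac=st.floats(0.1, 0.9),
)
def test_invariants_hold_after_stepping(seed, w, h, frac):
    """Single occupancy and count conservation after every step on small
    random lattices (exhaustive check)."""
    capacity = w * h
    n_ask3 = max(1, int(capacity * frac * 0.6))
    n_obs = int(capacity * frac * 0.4)
    cfg = LatticeConfig(width=w, height=h, n_ask3=n_ask3, n_obstacles=n_obs, seed=seed)
    rng = KmcRandom(seed)
    state = initialize(cfg, rng)
    model = RateModel.from_config(cfg)
    for _ in range(200):
        step(state, model, rng)
        state.validate()
    assert state.n_ask3 == n_ask3 and state.n_obstacles == n_obs
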