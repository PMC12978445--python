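import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ideorice.sensitivity import (
    OUTPUT_CHANNELS,
    ElementaryEffectSet,
    ParameterSpace,
    RSIMatrix,
    build_trajectory,
    default_space,
    elementary_effects,
    replicate_screening,
    rsi,
    screen_once,
    select_targets,
)


def linear_model(coeffs):
    def run(x):
        y = float(np.dot(coeffs, x))
        return {c: y for c in OUTPUT_CHANNELS}
    return run


def check_trajectory_invariants(traj, space):
    k = space.k
    assert traj.points.shape == (k + 1, k)
    touched = [j for j, _ in traj.moves]
    assert sorted(touched) == list(range(k))
    for i, (j, step) in enumerate(traj.moves):
        diff = traj.points[i + 1] - traj.points[i]
        assert diff[j] == pytest.approx(step)
        assert abs(step) == pytest.approx(space.delta[j])
        others = np.delete(diff, j)
        assert np.all(others == 0.0)
    assert np.all(traj.points >= space.lower - 1e-12)
    assert np.all(traj.points <= space.upper + 1e-12)


class TestBuildTrajectory:
    def test_structure_k2(self, rng):
        space = ParameterSpace(("a", "b"), [0, 0], [1, 1], delta=[0.5, 0.5])
        traj = build_trajectory(space, rng)
        assert traj.points.shape == (3, 2)
        check_trajectory_invariants(traj, space)

    def test_k11_gives_12_evaluations(self, space11, rng):
        traj = build_trajectory(space11, rng)
        assert traj.n_evaluations == 12

    def test_reflection_at_upper_bound(self, rng):
        # delta equals the full range: every step from anywhere must reflect
        space = ParameterSpace(("a",), [0.0], [1.0], delta=[1.0])
        for _ in range(20):
            traj = build_trajectory(space, rng)
            check_trajectory_invariants(traj, space)

    def test_invalid_delta_rejected(self):
        with pytest.raises(ValueError):
            ParameterSpace(("a",), [0.0], [1.0], delta=[2.0])

    @given(seed=st.integers(0, 2**31), k=st.integers(1, 11))
    @settings(max_examples=250, deadline=None)
    def test_invariants_random_spaces(self, seed, k):
        rng = np.random.default_rng(seed)
        lower = rng.uniform(-10, 10, k)
        upper = lower + rng.uniform(0.1, 100, k)
        delta = rng.uniform(0.05, 1.0, k) * (upper - lower)
        space = ParameterSpace(tuple(f"p{i}" for i in range(k)), lower, upper, delta)
        traj = build_trajectory(space, np.random.default_rng(seed + 1))
        check_trajectory_invariants(traj, space)


class TestElementaryEffects:
    def test_constant_model(self, rng):
        space = ParameterSpace(("a", "b"), [0, 0], [1, 1], delta=[0.5, 0.5])
        traj = build_trajectory(space, rng)
        outputs = [{c: 7.0 for c in OUTPUT_CHANNELS} for _ in traj.points]
        eff = elementary_effects(traj, outputs, space.names)
        for c in OUTPUT_CHANNELS:
            assert np.all(eff.raw[c] == 0.0)

    def test_linear_model_closed_form(self, rng):
        space = ParameterSpace(("a", "b"), [0, 0], [1, 1], delta=[0.5, 0.5])
        model = linear_model([3.0, 1.0])
        traj = build_trajectory(space, rng)
        outputs = [model(p) for p in traj.points]
        eff = elementary_effects(traj, outputs, space.names)
        assert np.abs(eff.raw["yield"][0]) == pytest.approx([1.5, 0.5])

    def test_normalized_effects_recover_slopes(self, rng):
        space = ParameterSpace(("a", "b"), [0, 0], [1, 1], delta=[0.5, 0.25])
        model = linear_model([3.0, 1.0])
        traj = build_trajectory(space, rng)
        eff = elementary_effects(traj, [model(p) for p in traj.points], space.names)
        assert np.abs(eff.normalized["yield"][0]) == pytest.approx([3.0, 1.0])

    def test_order_invariance_additive_model(self):
        # brute force: for an additive model the per-coefficient |effect| is
        # identical whatever the move order
        space = ParameterSpace(("a", "b"), [0, 0], [1, 1], delta=[0.5, 0.5])
        model = linear_model([2.0, 5.0])
        base = np.array([0.25, 0.25])
        results = []
        for order in itertools.permutations(range(2)):
            points = [base.copy()]
            moves = []
            cur = base.copy()
            for j in order:
                cur = cur.copy()
                cur[j] += 0.5
                points.append(cur)
                moves.append((j, 0.5))
            from ideorice.sensitivity import MorrisTrajectory

            traj = MorrisTrajectory(np.array(points), tuple(moves), base)
            eff = elementary_effects(traj, [model(p) for p in points], space.names)
            results.append(np.abs(eff.raw["yield"][0]))
        assert np.allclose(results[0], results[1])

    def test_output_count_mismatch(self, rng):
        space = ParameterSpace(("a", "b"), [0, 0], [1, 1], delta=[0.5, 0.5])
        traj = build_trajectory(space, rng)
        with pytest.raises(ValueError):
            elementary_effects(traj, [{}], space.names)


class TestRSI:
    def _effects(self, per_coeff):
        k = len(per_coeff)
        n = len(per_coeff[0])
        raw = np.array(per_coeff, dtype=float).T  # (n, k)
        return ElementaryEffectSet(
            names=tuple(f"p{i}" for i in range(k)),
            channels=("yield",),
            raw={"yield": raw},
            normalized={"yield": raw},
        )

    def test_arithmetic_example(self):
        # one coefficient with |effects| {2,4,8}, pooled max 8 -> (14/3)/8
        eff = self._effects([[2, 4, 8], [1, 1, 1]])
        got = rsi(eff, "yield")
        assert got[0] == pytest.approx((14 / 3) / 8)

    def test_all_zero_effects(self):
        eff = self._effects([[0, 0], [0, 0]])
        assert np.all(rsi(eff, "yield") == 0.0)

    def test_upper_endpoint(self):
        eff = self._effects([[8, 8, 8], [2, 1, 3]])
        got = rsi(eff, "yield")
        assert got[0] == pytest.approx(1.0)
        assert np.all(got <= 1.0)

    def test_sign_ignored(self):
        eff = self._effects([[-2, 4, -8], [1, -1, 1]])
        assert rsi(eff, "yield")[0] == pytest.approx((14 / 3) / 8)


class TestReplicateScreening:
    def test_linear_ranking_matches_slopes(self, space11):
        slopes = np.array([11, 3, 7, 1, 9, 5, 2, 8, 4, 10, 6], dtype=float)
        # unit cube so all deltas are equal and RSI ordering == |slope| ordering
        space = ParameterSpace(space11.names, np.zeros(11), np.ones(11))
        matrix = replicate_screening(space, linear_model(slopes), r=4, reps=5, seed=0)
        expected = np.argsort(-slopes)
        for rep in matrix.replicates:
            got = np.argsort(-rep[:, 0])
            assert np.array_equal(got, expected)

    def test_all_rsi_in_unit_interval(self, space11):
        slopes = np.arange(1.0, 12.0)
        space = ParameterSpace(space11.names, np.zeros(11), np.ones(11))
        matrix = replicate_screening(space, linear_model(slopes), r=4, reps=5, seed=1)
        assert np.all(matrix.replicates >= 0.0)
        assert np.all(matrix.replicates <= 1.0 + 1e-12)
        lo, hi = matrix.ci_bounds()
        assert np.all(lo >= 0.0) and np.all(hi <= 1.0)

    def test_deterministic_under_seed(self, space11):
        space = ParameterSpace(space11.names, np.zeros(11), np.ones(11))
        model = linear_model(np.arange(1.0, 12.0))
        a = replicate_screening(space, model, r=3, reps=3, seed=42)
        b = replicate_screening(space, model, r=3, reps=3, seed=42)
        assert np.array_equal(a.mean, b.mean)
        assert np.array_equal(a.replicates, b.replicates)

    def test_reps_below_two_rejected(self, space11):
        with pytest.raises(ValueError):
            replicate_screening(space11, linear_model(np.ones(11)), r=2, reps=1)

    def test_ci_halfwidth_shrinks_with_reps(self):
        # quadratic response: per-replicate RSI varies with the random bases
        names = tuple(f"p{i}" for i in range(5))
        space = ParameterSpace(names, np.zeros(5), np.ones(5))
        coeffs = np.array([5.0, 4.0, 3.0, 2.0, 1.0])

        def model(x):
            y = float(np.dot(coeffs, np.asarray(x) ** 2))
            return {c: y for c in OUTPUT_CHANNELS}

        small = replicate_screening(space, model, r=4, reps=10, seed=5)
        large = replicate_screening(space, model, r=4, reps=20, seed=5)
        assert large.ci95.mean() < small.ci95.mean()


class TestSelectTargets:
    def _matrix(self, names, maxima):
        k = len(names)
        mean = np.array(maxima, dtype=float)[:, None]
        return RSIMatrix(
            names=tuple(names), channels=("yield",),
            mean=mean, sd=np.zeros((k, 1)), ci95=np.zeros((k, 1)), reps=2,
        )

    def test_near_zero_rows_excluded(self):
        names = ("P1", "TCLDP", "TCLDF", "G3")
        matrix = self._matrix(names, [0.9, 0.01, 0.0, 0.5])
        assert select_targets(matrix) == ["P1", "G3"]

    def test_tie_break_by_declared_order(self):
        names = ("a", "b", "c")
        matrix = self._matrix(names, [0.5, 0.5, 0.5])
        assert select_targets(matrix, top_n=2) == ["a", "b"]

    def test_singleton_under_threshold_policy(self):
        matrix = self._matrix(("a", "b", "c"), [0.0, 0.6, 0.0])
        assert select_targets(matrix) == ["b"]

    def test_top_n_cap(self):
        names = tuple(f"p{i}" for i in range(11))
        matrix = self._matrix(names, np.linspace(1.0, 0.1, 11))
        assert len(select_targets(matrix, top_n=8)) == 8


def test_screen_once_accumulates_r_effects(space11, rng):
    space = ParameterSpace(space11.names, np.zeros(11), np.ones(11))
    eff = screen_once(space, linear_model(np.arange(1.0, 12.0)), r=5, rng=rng)
    assert eff.r == 5
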