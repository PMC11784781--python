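import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eagledrp.geo import (
    ArchiveMember,
    GEOConfig,
    ZeroAttackVector,
    archive_insert,
    attack_vector,
    crowding_distances,
    cruise_destination,
    dominates,
    geo_minimize,
    mogeo_minimize,
    roulette_select,
    sparsity_scores,
    step_vector,
    transition_coefficients,
)


class _StubRng:
    """Deterministic stand-in feeding scripted choice/random values."""

    def __init__(self, choice_value, randoms):
        self._choice = choice_value
        self._randoms = list(randoms)

    def choice(self, options, **kw):
        return self._choice

    def random(self, size=None):
        out = np.array(self._randoms[: size if size else 1], dtype=float)
        return out if size else out[0]


def test_attack_vector_subtraction_and_identity():
    A = attack_vector(np.array([1.0, 1.0]), np.array([3.0, 4.0]))
    np.testing.assert_array_equal(A, [2.0, 3.0])
    np.testing.assert_array_equal(A + [1.0, 1.0], [3.0, 4.0])
    np.testing.assert_array_equal(
        attack_vector(np.array([2.0]), np.array([2.0])), [0.0]
    )


def test_cruise_hand_solution_2d():
    """A = [1, 0], eagle at origin, free coordinate 0.7: cruise = [0, 0.7]."""
    cruise = cruise_destination(
        np.array([1.0, 0.0]), np.zeros(2), _StubRng(0, [0.5, 0.7])
    )
    np.testing.assert_allclose(cruise, [0.0, 0.7])
    assert abs(np.dot([1.0, 0.0], cruise)) < 1e-12


def test_cruise_hand_solution_3d_sums_to_zero():
    """A = [1,1,1] through the origin: pivot solves to −(0.2+0.3) = −0.5."""
    cruise = cruise_destination(
        np.array([1.0, 1.0, 1.0]), np.zeros(3), _StubRng(0, [0.9, 0.2, 0.3])
    )
    assert cruise[0] == pytest.approx(-0.5)
    assert cruise.sum() == pytest.approx(0.0)


def test_cruise_orthogonality_random_pairs():
    rng = np.random.default_rng(0)
    for _ in range(1000):
        dim = int(rng.integers(2, 8))
        attack = rng.standard_normal(dim)
        eagle = rng.uniform(-5, 5, dim)
        cruise = cruise_destination(attack, eagle, rng)
        bound = 1e-9 * np.linalg.norm(attack) * np.linalg.norm(cruise)
        assert abs(attack @ cruise) <= max(bound, 1e-15)


def test_cruise_zero_attack_signals_at_prey():
    with pytest.raises(ZeroAttackVector):
        cruise_destination(np.zeros(3), np.ones(3), np.random.default_rng(0))


def test_step_vector_norm_and_degenerate_cases():
    rng = np.random.default_rng(1)
    for _ in range(1000):
        a = rng.standard_normal(4)
        c = rng.standard_normal(4)
        pa, pc = rng.uniform(0, 2, 2)
        step = step_vector(a, c, pa, pc, rng)
        assert np.linalg.norm(step) <= pa + pc + 1e-12
    np.testing.assert_array_equal(
        step_vector(np.zeros(3), np.zeros(3), 1.0, 1.0, rng), np.zeros(3)
    )


def test_transition_coefficients_linear_schedule():
    cfg = GEOConfig(pop_size=2, max_iter=10, pa0=2.0, paT=0.0, pc0=1.0, pcT=0.5,
                    lower=np.zeros(1), upper=np.ones(1))
    assert transition_coefficients(0, cfg) == (2.0, 1.0)
    assert transition_coefficients(10, cfg) == (0.0, 0.5)
    pa, pc = transition_coefficients(5, cfg)
    assert pa == pytest.approx(1.0)
    assert pc == pytest.approx(0.75)


def test_geo_converges_on_1d_quadratic():
    cfg = GEOConfig(pop_size=20, max_iter=100, lower=np.array([0.0]),
                    upper=np.array([5.0]), seed=0)
    pos, fit, hist = geo_minimize(lambda x: float((x[0] - 2) ** 2), cfg)
    assert abs(pos[0] - 2) < 0.05


def test_geo_history_non_increasing_and_bounds_respected():
    seen = []

    def sphere(x):
        seen.append(x.copy())
        return float(np.sum(x**2))

    cfg = GEOConfig(pop_size=10, max_iter=50, lower=-np.ones(3), upper=np.ones(3),
                    seed=1)
    _, _, hist = geo_minimize(sphere, cfg)
    assert all(b <= a for a, b in zip(hist, hist[1:]))
    allpos = np.array(seen)
    assert (allpos >= -1).all() and (allpos <= 1).all()


def test_geo_non_finite_objective_raises():
    cfg = GEOConfig(pop_size=4, max_iter=5, lower=np.zeros(1), upper=np.ones(1),
                    seed=0)
    with pytest.raises(ValueError, match="non-finite"):
        geo_minimize(lambda x: float("nan"), cfg)


def test_dominance_relations():
    assert dominates([1, 1], [2, 2])
    assert not dominates([1, 2], [2, 1])
    assert not dominates([2, 1], [1, 2])
    assert not dominates([1, 1], [1, 1])


@given(
    st.lists(st.floats(min_value=-10, max_value=10), min_size=2, max_size=2),
    st.lists(st.floats(min_value=-10, max_value=10), min_size=2, max_size=2),
)
@settings(max_examples=100, deadline=None, derandomize=True)
def test_dominance_antisymmetric(fa, fb):
    assert not (dominates(fa, fb) and dominates(fb, fa))


def test_crowding_second_difference_values():
    # equally spaced: the second difference vanishes in the middle
    c = crowding_distances(np.array([[0.0], [0.5], [1.0]]))
    assert c[1] == pytest.approx(0.0)
    # uneven spacing: ((1 − 0.2) − (0.2 − 0)) / 1 = 0.6
    c = crowding_distances(np.array([[0.0], [0.2], [1.0]]))
    assert c[1] == pytest.approx(0.6)
    assert c[0] == 0.0 and c[2] == 0.0  # boundary members


def test_crowding_degenerate_all_identical():
    c = crowding_distances(np.full((4, 2), 3.0))
    np.testing.assert_array_equal(c, 0.0)


def test_sparsity_scores_clipping():
    np.testing.assert_allclose(
        sparsity_scores(np.array([0.0, 1.0, 0.6, -2.0, 5.0])),
        [1.0, 0.0, 0.4, 1.0, 0.0],
    )


def test_roulette_select_degenerate_and_frequency():
    rng = np.random.default_rng(0)
    assert all(
        roulette_select(np.array([1.0, 0.0, 0.0]), rng) == 0 for _ in range(20)
    )
    draws = [roulette_select(np.array([1.0, 1.0]), rng) for _ in range(10000)]
    freq = np.mean(draws)
    assert abs(freq - 0.5) <= 3 * np.sqrt(0.25 / 10000)
    zero_draws = {roulette_select(np.zeros(3), rng) for _ in range(200)}
    assert zero_draws == {0, 1, 2}  # uniform fallback reaches every index
    with pytest.raises(ValueError):
        roulette_select(np.array([-1.0, 1.0]), rng)


def _member(pos, obj):
    return ArchiveMember(position=np.atleast_1d(np.asarray(pos, dtype=float)),
                         objectives=np.asarray(obj, dtype=float))


def test_archive_insert_rules():
    rng = np.random.default_rng(0)
    archive = [_member(0, [1.0, 1.0])]
    # dominated candidate rejected
    out = archive_insert(archive, _member(1, [2.0, 2.0]), 10, rng)
    assert len(out) == 1 and out[0].objectives.tolist() == [1.0, 1.0]
    # dominating candidate removes both incumbents
    archive = [_member(0, [2.0, 3.0]), _member(1, [3.0, 2.0])]
    out = archive_insert(archive, _member(2, [1.0, 1.0]), 10, rng)
    assert len(out) == 1 and out[0].objectives.tolist() == [1.0, 1.0]


def test_archive_capacity_eliminates_one_and_keeps_candidate():
    rng = np.random.default_rng(1)
    archive = []
    for i in range(10):  # a 10-member non-dominated front at capacity
        archive = archive_insert(
            archive, _member(i, [i / 10, 1 - i / 10]), 10, rng
        )
    assert len(archive) == 10
    cand = _member(99, [0.55, 0.41])
    out = archive_insert(archive, cand, 10, rng)
    assert len(out) == 10
    assert any(m.position[0] == 99 for m in out)
    # mutual non-dominance preserved
    for a in out:
        for b in out:
            if a is not b:
                assert not dominates(a.objectives, b.objectives)


def test_mogeo_recovers_convex_pareto_set():
    wins = 0
    for seed in range(5):
        cfg = GEOConfig(pop_size=40, max_iter=200, lower=np.array([-5.0]),
                        upper=np.array([5.0]), seed=seed)
        archive = mogeo_minimize(
            lambda x: np.array([x[0] ** 2, (x[0] - 2) ** 2]), cfg, capacity=25
        )
        xs = np.array([m.position[0] for m in archive])
        nondom = all(
            not dominates(a.objectives, b.objectives)
            for a in archive
            for b in archive
            if a is not b
        )
        wins += nondom and xs.min() >= -0.1 and xs.max() <= 2.1
    assert wins >= 4


def test_mogeo_archive_objectives_distinct():
    cfg = GEOConfig(pop_size=20, max_iter=50, lower=np.array([-5.0]),
                    upper=np.array([5.0]), seed=0)
    archive = mogeo_minimize(
        lambda x: np.array([x[0] ** 2, (x[0] - 2) ** 2]), cfg, capacity=15
    )
    for i, a in enumerate(archive):
        for b in archive[i + 1:]:
            assert (
                np.abs(a.objectives - b.objectives).max() > 1e-9
                or np.abs(a.position - b.position).max() > 0
            )


def test_geo_config_validation():
    with pytest.raises(ValueError):
        GEOConfig(pop_size=1, lower=np.zeros(1), upper=np.ones(1))
    with pytest.raises(ValueError):
        GEOConfig(lower=np.ones(2), upper=np.zeros(2))
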