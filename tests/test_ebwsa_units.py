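import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from wolfselect.ebwsa import (
    EBWSAConfig,
    MemoryBuffer,
    attract_move,
    binarize,
    compute_gamma,
    compute_sigma,
    enforce_weight_bounds,
    escape_move,
    minkowski_distance,
    prey_move,
    update_weights,
)


class _FixedRng:
    """Stub generator whose uniform() returns a constant (for closed-form moves)."""

    def __init__(self, value):
        self.value = value

    def uniform(self, low=0.0, high=1.0, size=None):
        if size is None:
            return self.value
        return np.full(size, self.value)


class TestBinarize:
    @pytest.mark.parametrize("x,bit", [
        (0.7, 1), (-0.3, 0), (0.49, 0), (0.5, 1),
        (-0.5, 0), (1.49, 1), (1.0, 1),
    ])
    def test_boundary_grid(self, x, bit):
        assert binarize(np.array([x]))[0] == bit

    def test_clip_then_binarize_out_of_range(self):
        clipped = np.clip(np.array([2.7]), -0.5, 1.5 - 1e-9)
        assert binarize(clipped)[0] == 1

    @given(hnp.arrays(float, 20, elements=st.floats(-0.5, 1.5 - 1e-9)))
    @settings(derandomize=True, max_examples=50)
    def test_output_is_binary_and_matches_band(self, x):
        b = binarize(x)
        assert set(np.unique(b)) <= {0, 1}
        np.testing.assert_array_equal(b == 1, (x >= 0.5) & (x < 1.5))


class TestMinkowski:
    def test_euclidean_345(self):
        assert minkowski_distance([0, 0], [3, 4], 2) == pytest.approx(5.0)

    def test_manhattan(self):
        assert minkowski_distance([0, 0], [1, 2], 1) == pytest.approx(3.0)

    def test_matches_brute_force_sum(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=50), rng.normal(size=50)
        brute = (np.sum(np.abs(a - b) ** 2)) ** 0.5
        assert minkowski_distance(a, b, 2) == pytest.approx(brute, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            minkowski_distance([0, 1], [0, 1, 2], 2)


class TestMoves:
    def test_attraction_closed_form_one_dim(self):
        # d=1 => new x = 0 + 1*exp(-1)*(1-0)*1 = e^-1
        new = attract_move(np.array([0.0]), np.array([1.0]), beta0=1.0,
                           weight_factor=1.0, order=2, rng=None,
                           jitter_scale=0.0)
        assert new[0] == pytest.approx(np.exp(-1.0), abs=1e-9)

    def test_attraction_zero_weight_freezes(self):
        new = attract_move(np.array([0.2]), np.array([1.0]), 1.0, 0.0, 2,
                           None, jitter_scale=0.0)
        assert new[0] == pytest.approx(0.2)

    def test_attraction_to_self_is_identity(self):
        x = np.array([0.3, 0.9])
        new = attract_move(x, x, 1.0, 1.0, 2, None, jitter_scale=0.0)
        np.testing.assert_allclose(new, x)

    def test_prey_closed_form(self):
        new = prey_move(np.array([0.2]), step_size=0.1, weight_factor=1.0,
                        rng=_FixedRng(1.0))
        assert new[0] == pytest.approx(0.3)

    def test_prey_zero_step(self):
        x = np.array([0.4, -0.2])
        new = prey_move(x, step_size=1e-300, weight_factor=1.0,
                        rng=_FixedRng(1.0))
        np.testing.assert_allclose(new, x)

    def test_escape_clears_minimum_length_over_many_draws(self):
        """Monte-Carlo: every escape displacement exceeds the visual radius.

        With unit step scaling from the box center the applied step is
        target - pos, so no clipping occurs and the rejection-sampled
        minimum-length constraint is observable directly.
        """
        radius = 0.5
        pos = np.full(5, 0.5)
        for seed in range(1000):
            new = escape_move(pos, step_size=1.0, weight_factor=1.0,
                              radius=radius, order=2,
                              rng=np.random.default_rng(seed))
            assert minkowski_distance(new, pos, 2) > radius

    def test_escape_fallback_takes_largest_seen_displacement(self):
        """An unsatisfiable radius still yields the largest candidate jump."""
        pos = np.full(3, 0.5)
        new = escape_move(pos, step_size=0.01, weight_factor=1.0,
                          radius=100.0, order=2,
                          rng=np.random.default_rng(0), max_tries=20)
        assert 0 < minkowski_distance(new, pos, 2) < 100.0

    def test_moves_respect_bounds(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            pos = rng.uniform(-0.5, 1.5, size=8)
            for new in (
                prey_move(pos, 5.0, 3.0, rng),
                escape_move(pos, 5.0, 3.0, 1.0, 2, rng),
            ):
                assert (new >= -0.5).all() and (new < 1.5).all()


class TestWeightEconomy:
    def test_gamma_hand_sum(self):
        w = np.full(5, 0.2)
        improved = np.array([False, False, False, True, True])
        assert compute_gamma(w, improved) == pytest.approx(0.4)
        assert compute_gamma(w, np.zeros(5, bool)) == 0.0
        assert compute_gamma(w, np.ones(5, bool)) == pytest.approx(1.0)

    @pytest.mark.parametrize("gamma,expected", [
        (0.5, 0.0),
        (0.25, 0.5 * np.log(3.0)),
        (0.8, 0.5 * np.log(0.25)),
        (0.0, 0.0),
        (1.0, 0.0),
    ])
    def test_sigma_values(self, gamma, expected):
        assert compute_sigma(gamma) == pytest.approx(expected, abs=1e-6)

    def test_sigma_sign_law_and_monotonicity(self):
        grid = np.arange(0.1, 0.95, 0.1)
        sigmas = [compute_sigma(g) for g in grid]
        for g, s in zip(grid, sigmas):
            assert (s > 0) == (g < 0.5)
            if abs(g - 0.5) < 1e-12:
                assert s == 0.0
        assert all(b < a for a, b in zip(sigmas, sigmas[1:]))

    def test_update_weights_exact_algebra(self):
        w = np.full(5, 0.2)
        improved = np.array([False, False, False, True, True])
        sigma = compute_sigma(compute_gamma(w, improved))  # 0.5*ln 1.5
        new = update_weights(w, improved, sigma)
        np.testing.assert_allclose(new[3:], 0.25, atol=1e-12)
        np.testing.assert_allclose(new[:3], 1.0 / 6.0, atol=1e-12)

    def test_update_weights_zero_sigma_is_identity(self):
        w = np.array([0.5, 0.3, 0.2])
        new = update_weights(w, np.array([True, False, True]), 0.0)
        np.testing.assert_allclose(new, w)

    @given(
        weights=hnp.arrays(float, 6, elements=st.floats(0.01, 1.0)),
        improved=hnp.arrays(bool, 6),
    )
    @settings(derandomize=True, max_examples=100)
    def test_update_preserves_unit_sum_and_sign_law(self, weights, improved):
        w = weights / weights.sum()
        gamma = compute_gamma(w, improved)
        sigma = compute_sigma(gamma)
        new = update_weights(w, improved, sigma)
        assert new.sum() == pytest.approx(1.0, abs=1e-12)
        if 0.0 < gamma < 0.5:
            # harsh environment: improvers' pre-normalization weights grow
            assert np.all(w[improved] * np.exp(sigma) > w[improved])
        elif 0.5 < gamma < 1.0:
            assert np.all(w[improved] * np.exp(sigma) < w[improved])


class TestEnforceWeightBounds:
    def test_underweight_wolf_reborn_at_uniform_share(self):
        w = np.full(10, 0.1)
        w[3] = 0.0009  # < 1/(100*10)
        w = w / w.sum() * 1.0  # keep it below threshold after scaling
        w[3] = 0.0009
        new, reborn = enforce_weight_bounds(w, np.random.default_rng(0),
                                            renormalize=False)
        assert reborn == [3]
        assert new[3] == pytest.approx(0.1)

    def test_overweight_wolf_shrunk_by_uniform_draw(self):
        rng = np.random.default_rng(5)
        w = np.array([0.6, 0.2, 0.2])
        new, reborn = enforce_weight_bounds(w, rng)
        assert reborn == []
        assert new[0] < 0.6 / (new.sum() / 1.0) + 1e-12
        assert new.sum() == pytest.approx(1.0, abs=1e-12)

    def test_in_band_weights_untouched(self):
        w = np.array([0.4, 0.35, 0.25])
        new, reborn = enforce_weight_bounds(w, np.random.default_rng(0))
        assert reborn == []
        np.testing.assert_allclose(new, w, atol=1e-12)


class TestMemoryBuffer:
    def test_empty_accepts_anything(self):
        mem = MemoryBuffer(5)
        assert np.array([1, 0, 1]) not in mem

    def test_membership_after_record(self):
        mem = MemoryBuffer(5)
        v = np.array([1, 0, 1], dtype=np.int8)
        mem.record(v)
        assert v in mem
        assert np.array([0, 0, 1]) not in mem

    def test_fifo_eviction_with_forget_count(self):
        """capacity 5, forget 2, 6 distinct inserts -> size 4, 2 oldest gone."""
        mem = MemoryBuffer(5, forget_count=2)
        vecs = [np.array([int(b) for b in f"{i:03b}"]) for i in range(6)]
        for v in vecs:
            mem.record(v)
        assert len(mem) == 4
        assert vecs[0] not in mem and vecs[1] not in mem
        for v in vecs[2:]:
            assert v in mem

    def test_duplicates_not_double_stored(self):
        mem = MemoryBuffer(5)
        v = np.array([1, 1, 0])
        mem.record(v)
        mem.record(v)
        assert len(mem) == 1

    def test_zero_capacity_disables_memory(self):
        mem = MemoryBuffer(0)
        mem.record(np.array([1, 0]))
        assert len(mem) == 0
        assert np.array([1, 0]) not in mem


def test_config_validation():
    with pytest.raises(ValueError):
        EBWSAConfig(pop_size=1).validate()
    with pytest.raises(ValueError):
        EBWSAConfig(escape_threshold=1.5).validate()
    with pytest.raises(ValueError):
        EBWSAConfig(lower_bound=2.0, upper_bound=1.0).validate()
    cfg = EBWSAConfig()
    cfg.validate()
    assert cfg.resolved_radius(100) == pytest.approx(2.0)
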