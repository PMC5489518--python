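import numpy as np
import pytest

from wolfselect.data import Dataset
from wolfselect.fitness import FitnessEvaluator, exhaustive_search, final_evaluate
from wolfselect.synth import SynthSpec, generate


def _mask(p, ones):
    m = np.zeros(p, dtype=np.int8)
    m[list(ones)] = 1
    return m


def test_all_zero_mask_scores_zero_without_training(easy_synth):
    ds, _ = easy_synth
    ev = FitnessEvaluator(ds)
    assert ev.evaluate_mask(np.zeros(ds.n_features)) == 0.0
    assert ev.n_trainings == 0


def test_cache_returns_identical_score_and_trains_once(easy_synth):
    ds, truth = easy_synth
    ev = FitnessEvaluator(ds, elm_seed=1, split_seed=1)
    mask = _mask(ds.n_features, truth)
    first = ev.evaluate_mask(mask)
    trained = ev.n_trainings
    second = ev.evaluate_mask(mask)
    assert second == first  # bit-identical
    assert ev.n_trainings == trained
    assert ev.n_cache_hits == 1


def test_mask_length_mismatch(easy_synth):
    ds, _ = easy_synth
    ev = FitnessEvaluator(ds)
    with pytest.raises(ValueError, match="mask length"):
        ev.evaluate_mask(np.ones(ds.n_features + 1))


def test_informative_mask_beats_noise_mask_across_split_seeds():
    spec = SynthSpec(n_samples=200, n_features=20, n_informative=5,
                     effect_size=3.0, n_redundant=0, seed=7)
    ds, truth = generate(spec)
    noise = [j for j in range(20) if j not in truth][:5]
    wins = 0
    for split_seed in range(10):
        ev = FitnessEvaluator(ds, elm_seed=0, split_seed=split_seed)
        wins += ev.evaluate_mask(_mask(20, truth)) >= ev.evaluate_mask(
            _mask(20, noise))
    assert wins >= 9


def test_changing_elm_seed_keeps_cache_keys():
    spec = SynthSpec(n_samples=80, n_features=10, n_informative=3,
                     effect_size=2.0, n_redundant=0, seed=3)
    ds, _ = generate(spec)
    ev_a = FitnessEvaluator(ds, elm_seed=0, split_seed=5)
    ev_b = FitnessEvaluator(ds, elm_seed=99, split_seed=5)
    masks = [_mask(10, [0, 1]), _mask(10, [4, 7, 9]), _mask(10, range(10))]
    for m in masks:
        ev_a.evaluate_mask(m)
        ev_b.evaluate_mask(m)
    assert set(ev_a.cache) == set(ev_b.cache)


def test_holdout_scheme_is_deterministic(easy_synth):
    ds, truth = easy_synth
    mask = _mask(ds.n_features, truth)
    s1 = FitnessEvaluator(ds, scheme="holdout", split_seed=2).evaluate_mask(mask)
    s2 = FitnessEvaluator(ds, scheme="holdout", split_seed=2).evaluate_mask(mask)
    assert s1 == s2


def test_exhaustive_search_finds_true_optimum_by_enumeration():
    spec = SynthSpec(n_samples=60, n_features=4, n_informative=2,
                     effect_size=3.0, n_redundant=0, seed=13)
    ds, _ = generate(spec)
    ev = FitnessEvaluator(ds, elm_seed=1, split_seed=1)
    best_mask, best_fit = exhaustive_search(ev)
    # brute-force re-check against the cached table
    assert best_fit == max(ev.cache.values())
    assert ev.evaluate_mask(best_mask) == best_fit


class TestFinalEvaluate:
    def test_chance_level_on_identical_clouds(self):
        spec = SynthSpec(n_samples=100, n_features=20, n_informative=5,
                         effect_size=0.0, n_redundant=0, seed=17)
        ds, _ = generate(spec)
        report = final_evaluate(ds, np.ones(20), folds=5, repeats=5, seed=0)
        mean, sd = report["accuracy"]
        assert abs(mean - 0.5) <= max(3 * sd, 0.15)

    def test_separable_data_scores_perfectly(self):
        spec = SynthSpec(n_samples=60, n_features=5, n_informative=3,
                         effect_size=8.0, noise_sd=0.5, n_redundant=0, seed=19)
        ds, truth = generate(spec)
        report = final_evaluate(ds, _mask(5, truth), folds=5, repeats=2, seed=1)
        assert report["accuracy"][0] == 1.0
        assert report["kappa"][0] == 1.0

    def test_repeat_determinism(self, easy_synth):
        ds, truth = easy_synth
        mask = _mask(ds.n_features, truth)
        r1 = final_evaluate(ds, mask, folds=5, repeats=2, seed=4)
        r2 = final_evaluate(ds, mask, folds=5, repeats=2, seed=4)
        assert r1 == r2

    def test_empty_mask_rejected(self, easy_synth):
        ds, _ = easy_synth
        with pytest.raises(ValueError, match="empty"):
            final_evaluate(ds, np.zeros(ds.n_features))

    def test_folds_reduced_with_warning(self):
        X = np.vstack([np.random.default_rng(0).normal(size=(8, 3)),
                       np.random.default_rng(1).normal(3.0, 1.0, size=(3, 3))])
        ds = Dataset(X, np.array([0] * 8 + [1] * 3), ["a", "b", "c"])
        with pytest.warns(UserWarning, match="reducing folds"):
            final_evaluate(ds, np.ones(3), folds=10, repeats=1, seed=0)


def test_search_fitness_tracks_final_evaluation(easy_synth):
    """Inner 3-fold fitness and the 10-fold report agree within 0.15."""
    ds, truth = easy_synth
    ev = FitnessEvaluator(ds, elm_seed=3, split_seed=3)
    rng = np.random.default_rng(0)
    close = 0
    diffs = []
    for _ in range(10):
        mask = (rng.random(ds.n_features) < 0.5).astype(np.int8)
        if not mask.any():
            mask[0] = 1
        search = ev.evaluate_mask(mask)
        final = final_evaluate(ds, mask, folds=10, repeats=1, seed=1)
        diff = abs(search - final["accuracy"][0])
        diffs.append(diff)
        close += diff <= 0.15
    assert close >= 8
    assert np.mean(diffs) <= 0.15
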