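"""Quality-scorer data generation, checkpoint scoring and selection."""

import numpy as np
import pytest

from fbdenoise import make_phantom
from fbdenoise.qnet import (EnsembleScorer, ScoreTrajectory, intensity_ladder,
                            make_qnet_training_set,
                            make_restoration_training_set, score_trajectory,
                            select_best, train_checkpoint_scorer, train_qnet)


@pytest.fixture(scope="module")
def bases():
    return [make_phantom(32, 32, kind, seed=i)
            for i, kind in enumerate(("blobs", "cells", "stripes", "blobs"))]


def test_training_set_count_and_structure(bases):
    samples = make_qnet_training_set(bases, n_levels=5, seed=0)
    assert len(samples) == 4 * 4 * 5  # bases x (3 noise + blur) x levels
    kinds = {s.noise_kind for s in samples}
    assert kinds == {"gaussian", "poisson", "salt_pepper", "blur"}
    noise_only = make_qnet_training_set(
        bases, kinds=("gaussian", "poisson", "salt_pepper"), n_levels=5, seed=0)
    assert len(noise_only) == 4 * 3 * 5


def test_pseudo_scores_strictly_decrease_within_series(bases):
    samples = make_qnet_training_set(bases, n_levels=6, seed=1)
    series = {}
    for s in samples:
        series.setdefault((s.base_id, s.noise_kind), []).append(
            (s.intensity_rank, s.pseudo_score))
    for vals in series.values():
        vals.sort()
        scores = [v[1] for v in vals]
        assert all(a > b for a, b in zip(scores, scores[1:]))
        assert scores[0] == 100.0 and scores[-1] == 0.0


def test_degradation_ladders_worsen_with_rank(bases):
    """Higher rank means visibly more corruption for every noise kind."""
    samples = make_qnet_training_set(bases[:1], n_levels=6, seed=2)
    base = bases[0]
    for kind in ("gaussian", "poisson", "salt_pepper"):
        sub = sorted((s for s in samples if s.noise_kind == kind),
                     key=lambda s: s.intensity_rank)
        errs = [np.abs(s.image - base).mean() for s in sub]
        assert errs[-1] > errs[0]
        assert errs[-1] > 2 * errs[1]


def test_training_set_validation(bases):
    with pytest.raises(ValueError):
        make_qnet_training_set([], seed=0)
    with pytest.raises(ValueError):
        make_qnet_training_set(bases, n_levels=2, seed=0)


def test_untrained_qnet_returns_finite_scores(bases):
    samples = make_qnet_training_set(bases[:2], n_levels=3, seed=3)
    scorer = train_qnet(samples, epochs=0, seed=0)
    assert np.isfinite(scorer(bases[0]))


def test_train_qnet_needs_multiple_series(bases):
    samples = make_qnet_training_set(bases[:1], kinds=("gaussian",),
                                     n_levels=3, seed=4)
    with pytest.raises(ValueError):
        train_qnet(samples, epochs=0, seed=0)


def test_train_qnet_deterministic_under_seed(bases):
    samples = make_qnet_training_set(bases[:2], kinds=("gaussian",),
                                     n_levels=3, seed=5)
    a = train_qnet(samples, epochs=1, seed=7)
    b = train_qnet(samples, epochs=1, seed=7)
    probe = bases[2]
    assert a(probe) == b(probe)


def test_score_trajectory_contract(bases):
    scorer = train_qnet(make_qnet_training_set(bases[:2], kinds=("gaussian",),
                                               n_levels=3, seed=6),
                        epochs=0, seed=0)
    imgs = [bases[0], bases[1], bases[2]]
    st = score_trajectory(scorer, imgs, [100, 200, 300])
    assert len(st.scores) == 3
    rev = score_trajectory(scorer, imgs[::-1], [100, 200, 300])
    assert rev.scores == st.scores[::-1]
    with pytest.raises(ValueError):
        score_trajectory(scorer, [], [])
    with pytest.raises(ValueError):
        score_trajectory(scorer, imgs, [100, 200])


def test_score_trajectory_rejects_nonincreasing_iterations():
    with pytest.raises(ValueError):
        ScoreTrajectory(iterations=[100, 100], scores=[1.0, 2.0])


def test_select_best_argmax_and_tiebreak():
    assert select_best(ScoreTrajectory([100, 200, 300], [10, 50, 30])) == 1
    assert select_best(ScoreTrajectory([1, 2, 3], [5.0, 5.0, 5.0])) == 0
    assert select_best(ScoreTrajectory([1, 2], [1.0, 1.0 + 1e-12])) in (0, 1)


def test_select_best_hand_computed_moving_average():
    # smoothed([1,2,9,2,1], w=3) = [1.5, 4, 4.333, 4, 1.5] -> index 2
    traj = ScoreTrajectory([10, 20, 30, 40, 50], [1, 2, 9, 2, 1])
    assert select_best(traj, smoothing_window=3) == 2
    assert select_best(traj, smoothing_window=1) == 2
    with pytest.raises(ValueError):
        select_best(traj, smoothing_window=2)


def test_restoration_manifold_grid_structure(bases):
    samples = make_restoration_training_set(bases[:2], seed=0)
    assert len(samples) == 2 * 4 * 5  # bases x blur levels x noise levels
    series = {}
    for s in samples:
        series.setdefault((s.base_id, s.noise_kind), []).append(
            (s.intensity_rank, s.pseudo_score))
    # within each blur level, scores strictly decrease with noise rank
    for vals in series.values():
        vals.sort()
        scores = [v[1] for v in vals]
        assert all(a > b for a, b in zip(scores, scores[1:]))
    # ceilings fall with blur rank: the clean image scores highest overall
    tops = {k[1]: max(v[1] for v in vals) for k, vals in series.items()}
    assert tops["blurred_level_0"] == 100.0
    assert tops["blurred_level_3"] < tops["blurred_level_0"]


def test_ensemble_scorer_is_member_mean(bases):
    a = train_qnet(make_qnet_training_set(bases[:2], kinds=("gaussian",),
                                          n_levels=3, seed=0), epochs=0, seed=0)
    b = train_qnet(make_qnet_training_set(bases[:2], kinds=("gaussian",),
                                          n_levels=3, seed=0), epochs=0, seed=99)
    ens = EnsembleScorer([a, b])
    img = bases[0]
    assert ens(img) == pytest.approx((a(img) + b(img)) / 2, rel=1e-9)
    with pytest.raises(ValueError):
        EnsembleScorer([])


def test_checkpoint_scorer_recipe_builds_ensemble(bases):
    scorer = train_checkpoint_scorer(bases[:2], seed=0, epochs=0, n_members=2)
    assert len(scorer.members) == 2
    assert np.isfinite(scorer(bases[2]))


def test_intensity_ladders_are_geometric_and_ordered():
    g = intensity_ladder("gaussian", 5)
    assert np.allclose(np.diff(np.log(g)), np.log(g[1] / g[0]))
    lam = intensity_ladder("poisson", 5)
    assert lam[0] > lam[-1]  # photons fall as degradation rises
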