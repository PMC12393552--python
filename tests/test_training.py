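import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seq2track import (
    TrainingConfig,
    build_model,
    evaluate,
    lr_at,
    pearson,
    poisson_nll,
    train,
)
from seq2track.data import TrackDataset
from seq2track.errors import (
    ConfigurationError,
    DegenerateMetricError,
    EvaluationError,
    ShapeError,
)
from seq2track.training import AdamW, poisson_nll_grad


class TestPoissonNLL:
    @pytest.mark.parametrize("lam,y,expected", [
        ([1.0], [0.0], 1.0),                 # ln 1 = 0
        ([1.0], [5.0], 1.0),                 # y·ln λ vanishes at λ=1
        ([2.0], [2.0], 2.0 - 2.0 * math.log(2.0)),
    ])
    def test_closed_form_scalars(self, lam, y, expected):
        assert poisson_nll(np.array(lam), np.array(y)) == pytest.approx(expected, abs=1e-9)

    def test_mean_reduction_over_elements(self):
        lam = np.array([[1.0, 2.0], [3.0, 4.0]])
        y = np.array([[0.0, 2.0], [3.0, 1.0]])
        expected = np.mean(lam - y * np.log(lam))
        assert poisson_nll(lam, y) == pytest.approx(expected, rel=1e-12)

    def test_minimized_at_rate_equal_to_target(self):
        """d/dλ (λ − y ln λ) = 0 at λ = y: scan a grid around the target."""
        y = np.array([3.0])
        grid = np.linspace(0.5, 8.0, 200)
        losses = [poisson_nll(np.array([g]), y) for g in grid]
        assert grid[int(np.argmin(losses))] == pytest.approx(3.0, abs=0.05)

    def test_gradient_matches_finite_difference(self):
        rng = np.random.default_rng(0)
        lam = rng.uniform(0.5, 4.0, size=(5, 3))
        y = rng.poisson(2.0, size=(5, 3)).astype(float)
        g = poisson_nll_grad(lam, y)
        eps = 1e-7
        for idx in [(0, 0), (2, 1), (4, 2)]:
            lp = lam.copy(); lp[idx] += eps
            lm = lam.copy(); lm[idx] -= eps
            fd = (poisson_nll(lp, y) - poisson_nll(lm, y)) / (2 * eps)
            assert g[idx] == pytest.approx(fd, rel=1e-5)

    def test_contract_violations(self):
        with pytest.raises(ShapeError):
            poisson_nll(np.ones((2, 2)), np.ones((2, 3)))
        with pytest.raises(ValueError, match="positive"):
            poisson_nll(np.array([0.0]), np.array([1.0]))


class TestPearson:
    def test_worked_example(self):
        assert pearson([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8, abs=1e-12)

    def test_perfect_and_anti_correlation(self):
        x = np.arange(10.0)
        assert pearson(x, x) == pytest.approx(1.0)
        assert pearson(x, -x + 3.0) == pytest.approx(-1.0)

    def test_matches_independent_implementation(self):
        from scipy import stats
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=100), rng.normal(size=100)
        assert pearson(x, y) == pytest.approx(stats.pearsonr(x, y)[0], abs=1e-12)

    @settings(max_examples=40, deadline=None)
    @given(a=st.floats(0.1, 50), b=st.floats(-100, 100))
    def test_invariant_under_positive_affine_transform(self, a, b):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=30), rng.normal(size=30)
        assert pearson(a * x + b, y) == pytest.approx(pearson(x, y), abs=1e-8)
        assert pearson(-a * x + b, y) == pytest.approx(-pearson(x, y), abs=1e-8)

    def test_constant_input_is_degenerate(self):
        with pytest.raises(DegenerateMetricError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestSchedule:
    def _cfg(self):
        return TrainingConfig(epochs=10, peak_lr=3e-5, warmup_epochs=1)

    def test_triangle_endpoints_and_peak(self):
        cfg = self._cfg()
        assert lr_at(0, 100, cfg) == 0.0
        assert lr_at(100, 100, cfg) == pytest.approx(3e-5)
        assert lr_at(1000, 100, cfg) == 0.0

    def test_midpoint_of_decay(self):
        # (1000 - 550) / 900 × 3e-5
        assert lr_at(550, 100, self._cfg()) == pytest.approx(1.5e-5)

    def test_linearity_within_segments(self):
        cfg = self._cfg()
        assert lr_at(50, 100, cfg) == pytest.approx(1.5e-5)      # mid-warmup
        for s in range(101, 1000):
            step = lr_at(s + 1, 100, cfg) - lr_at(s, 100, cfg)
            assert step == pytest.approx(-3e-5 / 900, rel=1e-9)
            if s > 900:
                break

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            lr_at(1001, 100, self._cfg())


def _constant_predictor_dataset(model, arch, n=3, seed=0):
    """Dataset whose targets equal the (fixed) model predictions."""
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 4, size=(n, arch.sequence_length)).astype(np.uint8)
    import pandas as pd
    from seq2track.data import codes_to_one_hot
    targets = np.stack([model.forward_one(codes_to_one_hot(c)) for c in codes])
    tracks = pd.DataFrame({"name": [f"t{i}" for i in range(arch.num_tracks)],
                           "assay": ["synthetic"] * arch.num_tracks,
                           "species": ["synthetic"] * arch.num_tracks})
    return TrackDataset(seq_codes=codes, targets=targets, tracks=tracks,
                        bin_size=arch.bin_size)


class TestEvaluate:
    def test_perfect_predictions_score_one(self, tiny_model, tiny_arch):
        ds = _constant_predictor_dataset(tiny_model, tiny_arch)
        report = evaluate(tiny_model, ds)
        assert report.per_track == pytest.approx([1.0] * tiny_arch.num_tracks)
        assert report.average == pytest.approx(1.0)

    def test_track_subset(self, tiny_model, tiny_arch, tiny_dataset):
        report = evaluate(tiny_model, tiny_dataset, tracks=[1])
        assert report.track_indices == [1]
        assert report.average == report.per_track[0]

    def test_pooled_convention(self, tiny_model, tiny_arch):
        """Construct two examples where per-example correlations and the
        pooled correlation disagree; the report must use the pooled value."""
        ds = _constant_predictor_dataset(tiny_model, tiny_arch, n=2, seed=1)
        # shift example 2's targets: within-example correlation stays 1,
        # pooled correlation drops below 1
        ds.targets[1] += 50.0
        report = evaluate(tiny_model, ds, tracks=[0])
        preds = np.concatenate([tiny_model.forward_one(ds.one_hot(i))[:, 0]
                                for i in range(2)])
        targs = np.concatenate([ds.targets[i, :, 0] for i in range(2)])
        pooled = pearson(preds, targs)
        assert report.per_track[0] == pytest.approx(pooled)
        per_example = np.mean([pearson(tiny_model.forward_one(ds.one_hot(i))[:, 0],
                                       ds.targets[i, :, 0]) for i in range(2)])
        assert abs(pooled - per_example) > 1e-3  # the conventions do disagree

    def test_constant_track_skipped_with_warning(self, tiny_model, tiny_arch, caplog):
        ds = _constant_predictor_dataset(tiny_model, tiny_arch)
        ds.targets[:, :, 1] = 7.0
        with caplog.at_level("WARNING"):
            report = evaluate(tiny_model, ds)
        assert report.skipped_tracks == [1]
        assert math.isnan(report.per_track[1])
        valid = [v for i, v in enumerate(report.per_track) if i != 1]
        assert report.average == pytest.approx(np.mean(valid))

    def test_all_constant_is_an_error(self, tiny_model, tiny_arch):
        ds = _constant_predictor_dataset(tiny_model, tiny_arch)
        ds.targets[:] = 1.0
        with pytest.raises(EvaluationError):
            evaluate(tiny_model, ds)


class TestTrain:
    def test_zero_epochs_is_a_no_op(self, tiny_arch, tiny_dataset):
        from seq2track import param_checksum
        m = build_model(tiny_arch, seed=0)
        before = param_checksum(m)
        m, history = train(m, tiny_dataset, TrainingConfig(epochs=0))
        assert len(history) == 0
        assert param_checksum(m) == before

    def test_history_length_and_lr_bookkeeping(self, tiny_arch, tiny_dataset):
        m = build_model(tiny_arch, seed=0)
        cfg = TrainingConfig(epochs=3, warmup_epochs=1, peak_lr=1e-3)
        m, history = train(m, tiny_dataset, cfg)
        assert len(history) == 3
        steps = len(tiny_dataset)
        for e, rec in enumerate(history.records):
            assert rec.lr_end == pytest.approx(lr_at((e + 1) * steps, steps, cfg))

    def test_loss_trajectory_is_reproducible(self, tiny_arch, tiny_dataset):
        losses = []
        for _ in range(2):
            m = build_model(tiny_arch, seed=3)
            _, h = train(m, tiny_dataset,
                         TrainingConfig(epochs=2, peak_lr=1e-3, shuffle_seed=5))
            losses.append([r.mean_loss for r in h.records])
        assert losses[0] == losses[1]

    def test_loss_descends_on_synthetic_task(self, tiny_arch, tiny_dataset):
        wins = 0
        for seed in range(3):
            m = build_model(tiny_arch, seed=seed)
            _, h = train(m, tiny_dataset,
                         TrainingConfig(epochs=4, peak_lr=3e-3, shuffle_seed=seed))
            if h.records[-1].mean_loss <= h.records[0].mean_loss:
                wins += 1
        assert wins >= 2  # descent on the majority of seeds

    def test_single_track_mode_touches_only_selected_track_loss(self, tiny_arch, tiny_dataset):
        cfg = TrainingConfig(epochs=1, peak_lr=1e-3, warmup_epochs=0,
                             mode="single_track", track_index=1)
        m = build_model(tiny_arch, seed=0)
        m, h = train(m, tiny_dataset, cfg)
        assert len(h) == 1

    def test_single_track_requires_valid_index(self, tiny_arch, tiny_dataset):
        cfg = TrainingConfig(epochs=1, warmup_epochs=0, mode="single_track",
                             track_index=99)
        with pytest.raises(ConfigurationError, match="track_index"):
            train(build_model(tiny_arch, seed=0), tiny_dataset, cfg)

    def test_shrinking_noise_improves_correlation(self, tiny_model, tiny_arch):
        """Targets = predictions + zero-mean noise of shrinking amplitude:
        the pooled correlation must trend to 1."""
        base = _constant_predictor_dataset(tiny_model, tiny_arch, n=4, seed=2)
        rng = np.random.default_rng(0)
        # noise scaled per track so every track sees the same relative level
        noise = rng.normal(size=base.targets.shape) * base.targets.std(axis=(0, 1))
        scores = []
        for amp in (2.0, 0.5, 0.05):
            ds = TrackDataset(seq_codes=base.seq_codes,
                              targets=np.clip(base.targets + amp * noise, 0, None),
                              tracks=base.tracks, bin_size=base.bin_size)
            scores.append(evaluate(tiny_model, ds).average)
        assert scores[0] < scores[1] < scores[2]
        assert scores[2] > 0.99


class TestAdamW:
    def test_weight_decay_is_decoupled(self):
        from seq2track.nn import Param
        p = Param("w", np.array([1.0]))
        opt = AdamW([p], weight_decay=0.1)
        p.grad[...] = 0.0
        opt.step(lr=0.5)
        # zero gradient: only the decay term moves the weight
        assert p.value[0] == pytest.approx(1.0 - 0.5 * 0.1 * 1.0)

    def test_frozen_parameters_do_not_move(self):
        from seq2track.nn import Param
        p = Param("w", np.array([1.0]), trainable=False)
        opt = AdamW([p], weight_decay=0.1)
        p.grad[...] = 5.0
        opt.step(lr=0.5)
        assert p.value[0] == 1.0
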