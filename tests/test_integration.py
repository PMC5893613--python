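import math

import numpy as np
import pytest

from vscable import (
    ReceptiveField,
    SynthRFSpec,
    WeightVector,
    difference_index,
    filtering_sweep,
    ln_filter,
    ln_threshold,
    make_branchlet_rfs,
    make_ground_truth_axon,
    normalize,
    predict_axonal_rf,
    shuffle_test,
    uniform_integration,
    weighted_integration,
)


def field(vectors, ids=None, label="f"):
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    n = len(vectors)
    if ids is None:
        ids = np.arange(1, n + 1)
    return ReceptiveField(
        location_ids=ids,
        azimuth_deg=np.zeros(n),
        elevation_deg=np.zeros(n),
        vectors=vectors,
        source_label=label,
    )


class TestAveraging:
    def test_single_field_is_identity(self, branchlet_rfs):
        out = uniform_integration(branchlet_rfs[:1])
        np.testing.assert_allclose(
            out.vectors, branchlet_rfs[0].sorted_by_id().vectors
        )

    def test_opposed_fields_cancel(self):
        u = field([[1, 0], [0, 2]])
        w = field([[-1, 0], [0, -2]])
        out = uniform_integration([u, w])
        np.testing.assert_allclose(out.vectors, 0.0, atol=1e-15)

    def test_equal_weights_reduce_to_uniform(self, branchlet_rfs):
        uni = uniform_integration(branchlet_rfs)
        wtd = weighted_integration(branchlet_rfs, np.full(len(branchlet_rfs), 3.7))
        np.testing.assert_allclose(wtd.vectors, uni.vectors, atol=1e-12)

    def test_degenerate_weight_selects_one_field(self, branchlet_rfs):
        out = weighted_integration(branchlet_rfs[:2], [1.0, 0.0])
        np.testing.assert_allclose(
            out.vectors, branchlet_rfs[0].sorted_by_id().vectors
        )

    def test_hand_worked_convex_combination(self):
        u = field([[2, 0]], ids=[1])
        w = field([[0, 2]], ids=[1])
        out = weighted_integration([u, w], [1.0, 3.0])
        np.testing.assert_allclose(out.vectors, [[0.5, 1.5]])

    def test_weight_scale_invariance(self, branchlet_rfs):
        w = np.linspace(1, 3, len(branchlet_rfs))
        a = weighted_integration(branchlet_rfs, w)
        b = weighted_integration(branchlet_rfs, 17.3 * w)
        np.testing.assert_allclose(a.vectors, b.vectors, atol=1e-14)

    def test_missing_weight_for_field_rejected(self, branchlet_rfs):
        wv = WeightVector.from_mapping({99: 1.0})
        with pytest.raises(ValueError, match="no weight"):
            weighted_integration(branchlet_rfs[:2], wv)

    def test_mismatched_grids_rejected(self, branchlet_rfs):
        odd = field(np.ones((5, 2)), ids=[101, 102, 103, 104, 105])
        with pytest.raises(ValueError, match="different location grid"):
            uniform_integration([branchlet_rfs[0], odd])


class TestLNFilter:
    def test_delta_zero_is_identity(self, branchlet_rfs):
        rf = branchlet_rfs[0]
        assert ln_filter(rf, 0.0) is rf

    def test_worked_example_1_to_50_delta_98(self):
        """Magnitudes 1..50 with δ = 98: Θ = 49, only the 50 survives."""
        mags = np.arange(1.0, 51.0)
        rf = field(np.column_stack([mags, np.zeros(50)]))
        assert ln_threshold(rf.magnitudes(), 98.0) == 49.0
        out = ln_filter(rf, 98.0)
        survivors = np.flatnonzero(out.magnitudes() > 0)
        assert survivors.tolist() == [49]
        assert out.vectors[49, 0] == 50.0  # untouched, bit-exact

    def test_nearest_rank_convention(self):
        mags = np.arange(1.0, 51.0)
        assert ln_threshold(mags, 90.0) == 45.0  # ceil(0.9*50)=45th value
        rf = field(np.column_stack([mags, np.zeros(50)]))
        assert int(np.sum(ln_filter(rf, 90.0).magnitudes() > 0)) == 5

    def test_tied_magnitudes_remove_everything(self):
        rf = field(np.tile([0.6, 0.8], (10, 1)))
        out = ln_filter(rf, 10.0)
        assert np.all(out.magnitudes() == 0.0)

    @pytest.mark.parametrize("delta", [-1.0, 100.0, 120.0])
    def test_delta_out_of_range(self, branchlet_rfs, delta):
        with pytest.raises(ValueError, match="delta"):
            ln_filter(branchlet_rfs[0], delta)


class TestPredictAxonalRF:
    def test_delta_zero_equal_weights_is_normalized_uniform(self, branchlet_rfs):
        pred = predict_axonal_rf(branchlet_rfs, None, 0.0)
        expected = normalize(uniform_integration(branchlet_rfs))
        np.testing.assert_allclose(pred.vectors, expected.vectors, atol=1e-14)

    def test_output_is_normalized(self, branchlet_rfs):
        w = np.linspace(1, 3, len(branchlet_rfs))
        for delta in (0.0, 50.0, 90.0):
            pred = predict_axonal_rf(branchlet_rfs, w, delta)
            assert pred.magnitudes().max() == pytest.approx(1.0, abs=1e-12)

    def test_forward_model_self_consistency(self, branchlet_rfs):
        """Noiseless ground truth is recovered exactly by prediction with the
        generating weights and δ."""
        w = np.linspace(1.0, 3.0, len(branchlet_rfs))
        truth = make_ground_truth_axon(branchlet_rfs, w, delta=90.0, noise_sd=0.0)
        pred = predict_axonal_rf(branchlet_rfs, w, 90.0)
        assert difference_index(pred, truth) < 1e-9

    def test_all_filtered_is_an_error(self):
        rf = field(np.tile([1.0, 0.0], (10, 1)))
        with pytest.raises(ValueError, match="filtered out every branchlet"):
            predict_axonal_rf([rf], [1.0], 50.0)

    def test_fully_zeroed_branchlet_drops_out(self, branchlet_rfs):
        flat = field(np.tile([0.0, 1.0], (50, 1)),
                     ids=branchlet_rfs[0].sorted_by_id().location_ids)
        pred_with = predict_axonal_rf(list(branchlet_rfs) + [flat],
                                      np.ones(len(branchlet_rfs) + 1), 50.0)
        pred_without = predict_axonal_rf(branchlet_rfs,
                                         np.ones(len(branchlet_rfs)), 50.0)
        # the tied flat field is entirely removed by the filter, so its
        # weight must not dilute the average
        np.testing.assert_allclose(pred_with.vectors, pred_without.vectors, atol=1e-14)


class TestShuffleTest:
    def test_same_seed_reproduces_report(self, branchlet_rfs):
        w = np.linspace(1, 3, len(branchlet_rfs))
        t = make_ground_truth_axon(branchlet_rfs, w, 90.0, 0.05, seed=4)
        a = shuffle_test(branchlet_rfs, w, t, 90.0, 200, seed=11)
        b = shuffle_test(branchlet_rfs, w, t, 90.0, 200, seed=11)
        np.testing.assert_array_equal(a.null_dis, b.null_dis)
        assert a.true_di == b.true_di

    def test_equal_weights_degenerate_null(self, branchlet_rfs):
        w = np.ones(len(branchlet_rfs))
        t = make_ground_truth_axon(branchlet_rfs, w, 0.0, 0.05, seed=4)
        rep = shuffle_test(branchlet_rfs, w, t, 0.0, 100, seed=1)
        assert rep.degenerate
        assert rep.null_sd == 0.0
        assert math.isnan(rep.z_score)
        assert np.all(rep.null_dis == rep.true_di)

    def test_too_few_shuffles_rejected(self, branchlet_rfs):
        w = np.ones(len(branchlet_rfs))
        t = make_ground_truth_axon(branchlet_rfs, w, 0.0, 0.0)
        with pytest.raises(ValueError, match="at least 100"):
            shuffle_test(branchlet_rfs, w, t, 0.0, 10, seed=1)

    def test_true_weighting_beats_nearly_all_shuffles(self, branchlet_rfs):
        """With weights spanning a factor of 3, the generating weighting's DI
        is lower than >= 97% of permuted weightings'."""
        rng = np.random.default_rng(5)
        w = rng.uniform(1.0, 3.0, len(branchlet_rfs))
        t = make_ground_truth_axon(branchlet_rfs, w, 90.0, 0.05, seed=6)
        rep = shuffle_test(branchlet_rfs, w, t, 90.0, 1000, seed=7)
        assert np.mean(rep.null_dis >= rep.true_di) >= 0.97

    def test_z_is_standard_normal_under_exchangeable_weights(self):
        """When the target was generated with a permuted copy of the same
        weights, the true weighting has no advantage and its z-score should
        scatter around zero across replicates."""
        rfs = make_branchlet_rfs(SynthRFSpec(n_branchlets=10, seed=0))
        w = np.linspace(1.0, 3.0, 10)
        master = np.random.default_rng(12)
        zs = []
        for _ in range(200):
            wp = w[master.permutation(10)]
            t = make_ground_truth_axon(
                rfs, wp, 0.0, 0.05, seed=int(master.integers(2**31))
            )
            rep = shuffle_test(rfs, w, t, 0.0, 100,
                               seed=int(master.integers(2**31)))
            zs.append(rep.z_score)
        assert abs(np.mean(zs)) < 0.2

    def test_report_json(self, tmp_path, branchlet_rfs):
        w = np.linspace(1, 3, len(branchlet_rfs))
        t = make_ground_truth_axon(branchlet_rfs, w, 0.0, 0.05, seed=4)
        rep = shuffle_test(branchlet_rfs, w, t, 0.0, 100, seed=2)
        out = tmp_path / "rep.json"
        rep.to_json(out)
        import json

        d = json.loads(out.read_text())
        assert d["n_shuffles"] == 100
        assert d["seed"] == 2
        assert d["z_score"] == pytest.approx(rep.z_score)


class TestFilteringSweep:
    def test_single_point_grid(self, branchlet_rfs):
        w = np.linspace(1, 3, len(branchlet_rfs))
        t = make_ground_truth_axon(branchlet_rfs, w, 0.0, 0.05, seed=4)
        table, best = filtering_sweep(branchlet_rfs, w, t, [0.0])
        assert len(table) == 1
        assert best == 0.0
        only = difference_index(predict_axonal_rf(branchlet_rfs, w, 0.0), normalize(t))
        assert table["di"].iloc[0] == pytest.approx(only)

    def test_recovers_generating_percentile(self, branchlet_rfs):
        w = np.linspace(1.0, 3.0, len(branchlet_rfs))
        t = make_ground_truth_axon(branchlet_rfs, w, delta=90.0, noise_sd=0.05, seed=8)
        grid = [float(d) for d in range(0, 100, 2)]
        _, best = filtering_sweep(branchlet_rfs, w, t, grid)
        assert abs(best - 90.0) <= 2.0

    def test_noisier_targets_have_larger_di(self, branchlet_rfs):
        """Expected DI grows monotonically with the target's vector noise."""
        w = np.linspace(1.0, 3.0, len(branchlet_rfs))
        clean = predict_axonal_rf(branchlet_rfs, w, 0.0)
        means = []
        for sd in (0.02, 0.05, 0.1):
            dis = [
                difference_index(
                    clean,
                    make_ground_truth_axon(branchlet_rfs, w, 0.0, sd, seed=k),
                )
                for k in range(200)
            ]
            means.append(np.mean(dis))
        assert means[0] < means[1] < means[2]
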