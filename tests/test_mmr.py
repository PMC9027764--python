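import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from mmrlink.mmr import (
    LabelEvoked,
    MMRMatrix,
    average_labels,
    compute_mmr,
    compute_mmr_matrix,
    log_mmr,
    roi_window_mean,
    select_preceding_standards,
    vertex_mmr,
    window_to_samples,
)
from mmrlink.synthetic import generate_oddball_sequence


def make_evoked(data, subject="s0", condition="standard", t0=-0.1, fs=100.0):
    return LabelEvoked(
        subject_id=subject, condition=condition, data=np.asarray(data, float),
        time_start=t0, sample_rate=fs,
    )


class TestComputeMMR:
    def test_identical_conditions_zero(self, rng):
        data = rng.normal(size=(4, 6, 3))
        std = make_evoked(data)
        dev = make_evoked(data.copy(), condition="deviant")
        assert np.array_equal(compute_mmr(std, dev), np.zeros((4, 6)))

    def test_unit_and_orthogonal_difference(self):
        std = make_evoked(np.zeros((2, 3, 3)))
        diff = np.zeros((2, 3, 3))
        diff[0, :, 0] = 1.0            # (1, 0, 0) everywhere on label 0
        diff[1, :, 0] = diff[1, :, 1] = 1.0  # (1, 1, 0) on label 1
        dev = make_evoked(diff, condition="deviant")
        out = compute_mmr(std, dev)
        assert np.allclose(out[0], 1.0)
        assert np.allclose(out[1], math.sqrt(2.0))

    def test_brute_force_oracle(self, rng):
        std = make_evoked(rng.normal(size=(5, 4, 3)))
        dev = make_evoked(rng.normal(size=(5, 4, 3)), condition="deviant")
        out = compute_mmr(std, dev)
        for l in range(5):
            for t in range(4):
                acc = 0.0
                for c in range(3):
                    acc += (dev.data[l, t, c] - std.data[l, t, c]) ** 2
                assert out[l, t] == pytest.approx(math.sqrt(acc), abs=1e-12)

    def test_alignment_errors_name_first_mismatch(self, rng):
        std = make_evoked(rng.normal(size=(3, 4, 3)))
        dev = make_evoked(rng.normal(size=(3, 4, 3)), condition="deviant")
        dev.label_names = ["label_000", "other", "label_002"]
        with pytest.raises(ValueError, match="index 1"):
            compute_mmr(std, dev)
        dev2 = make_evoked(rng.normal(size=(3, 5, 3)), condition="deviant")
        with pytest.raises(ValueError, match="shape"):
            compute_mmr(std, dev2)

    def test_rotation_invariance(self, rng):
        std = make_evoked(rng.normal(size=(4, 6, 3)))
        dev = make_evoked(rng.normal(size=(4, 6, 3)), condition="deviant")
        R = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        std_rot = make_evoked(std.data @ R.T)
        dev_rot = make_evoked(dev.data @ R.T, condition="deviant")
        assert np.allclose(
            compute_mmr(std, dev), compute_mmr(std_rot, dev_rot), atol=1e-12
        )

    def test_triangle_inequality(self, rng):
        std = make_evoked(rng.normal(size=(4, 6, 3)))
        dev = make_evoked(rng.normal(size=(4, 6, 3)), condition="deviant")
        bound = np.linalg.norm(std.data, axis=2) + np.linalg.norm(dev.data, axis=2)
        assert np.all(compute_mmr(std, dev) <= bound + 1e-12)

    def test_scaling_linearity(self, rng):
        std = make_evoked(np.zeros((4, 6, 3)))
        diff = rng.normal(size=(4, 6, 3))
        out1 = compute_mmr(std, make_evoked(diff, condition="deviant"))
        out2 = compute_mmr(std, make_evoked(-2.5 * diff, condition="deviant"))
        assert np.allclose(out2, 2.5 * out1)


class TestAverageLabels:
    def test_one_vertex_per_label_identity(self, rng):
        data = rng.normal(size=(3, 5, 3))
        out = average_labels(data, np.array([0, 1, 2]), ["a", "b", "c"])
        assert np.array_equal(out, data)

    def test_opposite_vectors_cancel(self):
        data = np.stack([np.ones((4, 3)), -np.ones((4, 3))])
        out = average_labels(data, np.array([0, 0]), ["a"])
        assert np.array_equal(out, np.zeros((1, 4, 3)))

    def test_groupby_oracle(self, rng):
        data = rng.normal(size=(12, 4, 3))
        label_map = rng.integers(0, 3, size=12)
        while len(set(label_map)) < 3:
            label_map = rng.integers(0, 3, size=12)
        out = average_labels(data, label_map, ["a", "b", "c"])
        # independent group-by mean via pandas
        flat = pd.DataFrame(
            {
                "label": np.repeat(label_map, 12),
                "cell": np.tile(np.arange(12), 12),
                "value": data.reshape(12, -1).ravel(),
            }
        )
        expected = (
            flat.groupby(["label", "cell"])["value"].mean().unstack().to_numpy()
        ).reshape(3, 4, 3)
        assert np.allclose(out, expected, atol=1e-12)

    def test_empty_label_raises(self, rng):
        with pytest.raises(ValueError, match="no vertices"):
            average_labels(rng.normal(size=(2, 3, 3)), np.array([0, 0]), ["a", "b"])


class TestVertexMMR:
    def test_magnitude_before_averaging(self, rng):
        # oracle: per-vertex norms averaged by a hand-rolled group-by
        std = rng.normal(size=(8, 5, 3))
        dev = rng.normal(size=(8, 5, 3))
        label_map = np.array([0, 0, 1, 1, 1, 2, 2, 2])
        out = vertex_mmr(std, dev, label_map, ["a", "b", "c"])
        for lab in range(3):
            members = np.flatnonzero(label_map == lab)
            for t in range(5):
                norms = [
                    math.sqrt(sum((dev[v, t, c] - std[v, t, c]) ** 2 for c in range(3)))
                    for v in members
                ]
                assert out[lab, t] == pytest.approx(np.mean(norms), abs=1e-12)

    def test_differs_from_average_then_norm_under_cancellation(self):
        # two opposite difference vectors: vector averaging cancels to 0,
        # magnitude-first averaging does not
        std = np.zeros((2, 1, 3))
        dev = np.zeros((2, 1, 3))
        dev[0, 0, 0], dev[1, 0, 0] = 1.0, -1.0
        out = vertex_mmr(std, dev, np.array([0, 0]), ["a"])
        assert out[0, 0] == pytest.approx(1.0)
        averaged = average_labels(dev - std, np.array([0, 0]), ["a"])
        assert np.linalg.norm(averaged[0, 0]) == pytest.approx(0.0)


class TestWindowing:
    def make_matrix(self, data, t0=-0.1, fs=100.0):
        data = np.asarray(data, float)
        return MMRMatrix(
            data=data,
            subject_ids=[f"s{i}" for i in range(data.shape[0])],
            label_names=[f"label_{i:03d}" for i in range(data.shape[1])],
            time_start=t0,
            sample_rate=fs,
        )

    def test_constant_map(self):
        mat = self.make_matrix(np.full((2, 3, 50), 1.7))
        out = roi_window_mean(mat, ["label_000", "label_002"], (0.0, 0.2))
        assert np.allclose(out, 1.7)

    def test_two_sample_window(self):
        # [0.2, 0.4) on a 10 Hz grid covers samples 2 and 3, values {2, 4}
        data = np.zeros((1, 1, 10))
        data[0, 0, 2], data[0, 0, 3] = 2.0, 4.0
        mat = self.make_matrix(data, t0=0.0, fs=10.0)
        assert roi_window_mean(mat, ["label_000"], (0.2, 0.4))[0] == pytest.approx(3.0)

    def test_left_closed_right_open(self):
        lo, hi = window_to_samples(0.0, 10.0, 10, (0.2, 0.5))
        assert (lo, hi) == (2, 5)

    def test_two_step_mean_oracle(self, rng):
        data = rng.uniform(1, 2, size=(4, 6, 30))
        mat = self.make_matrix(data, t0=-0.1, fs=100.0)
        roi = ["label_001", "label_004"]
        window = (0.05, 0.15)
        out = roi_window_mean(mat, roi, window)
        lo, hi = window_to_samples(-0.1, 100.0, 30, window)
        expected = data[:, [1, 4], lo:hi].reshape(4, -1).mean(axis=1)
        assert np.allclose(out, expected, atol=1e-12)

    def test_empty_window_raises(self):
        mat = self.make_matrix(np.ones((1, 2, 10)), t0=0.0, fs=10.0)
        with pytest.raises(ValueError, match="no samples"):
            roi_window_mean(mat, ["label_000"], (0.21, 0.29))

    def test_unknown_roi_label(self):
        mat = self.make_matrix(np.ones((1, 2, 10)), t0=0.0, fs=10.0)
        with pytest.raises(ValueError, match="nope"):
            roi_window_mean(mat, ["nope"], (0.0, 0.5))


class TestLogMMR:
    def test_unit_values(self):
        assert log_mmr(1.0) == pytest.approx(0.0)
        assert log_mmr(math.e) == pytest.approx(1.0)

    def test_matches_library_log(self, rng):
        x = rng.uniform(0.1, 10.0, size=50)
        assert np.allclose(log_mmr(x), np.log(x))

    def test_floor_raises_and_clamp(self):
        with pytest.raises(ValueError, match="floor"):
            log_mmr(0.0)
        assert log_mmr(0.0, clamp=True) == pytest.approx(math.log(1e-12))


class TestPrecedingStandards:
    def test_by_definition(self):
        labels = ["standard", "standard", "deviant", "standard", "standard", "deviant"]
        assert select_preceding_standards(labels).tolist() == [1, 4]

    def test_all_standard_empty(self):
        assert select_preceding_standards(["standard"] * 4).size == 0

    def test_generated_sequence_property_scan(self):
        seq = generate_oddball_sequence(600, 150, 2, 800.0, 50.0, seed=21)
        idx = select_preceding_standards(seq.trial_labels)
        assert idx.size == 150
        for i in idx:
            assert seq.trial_labels[i] == "standard"
            assert seq.trial_labels[i + 1] == "deviant"

    def test_leading_deviant_raises(self):
        with pytest.raises(ValueError, match="position 0"):
            select_preceding_standards(["deviant", "standard"])


class TestMatrixStacking:
    def test_mismatched_label_order_rejected(self, rng):
        a = (make_evoked(rng.normal(size=(2, 3, 3)), subject="a"),
             make_evoked(rng.normal(size=(2, 3, 3)), subject="a", condition="deviant"))
        b_std = make_evoked(rng.normal(size=(2, 3, 3)), subject="b")
        b_std.label_names = ["x", "y"]
        b_dev = make_evoked(rng.normal(size=(2, 3, 3)), subject="b", condition="deviant")
        b_dev.label_names = ["x", "y"]
        with pytest.raises(ValueError, match="ordering"):
            compute_mmr_matrix([a, (b_std, b_dev)])
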