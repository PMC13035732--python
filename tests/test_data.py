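"""Core containers, normalization and the two metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from fairnmf import (
    Factorization,
    GroupedMatrix,
    compute_metrics,
    normalize_features,
    objective_f,
    read_grouped_csv,
    relative_error,
    relative_loss,
    write_metric_table,
)
from fairnmf.synthetic import gen_dataset1, write_csv


class TestGroupedMatrix:
    def test_partition_and_order(self):
        X = np.arange(12, dtype=float).reshape(6, 2) + 1
        G = GroupedMatrix(X, np.array(["b", "a", "b", "a", "b", "c"]))
        # group order follows first appearance, not lexicographic
        assert list(G.groups) == ["b", "a", "c"]
        all_idx = np.concatenate(G.group_indices)
        assert sorted(all_idx) == list(range(6))
        assert G.group_sizes.sum() == G.m == 6
        np.testing.assert_array_equal(G.block(2), X[[5]])

    def test_rejects_negative_and_zero_norm_group(self):
        with pytest.raises(ValueError, match="non-negative"):
            GroupedMatrix(np.array([[1.0, -0.5]]), np.array(["a"]))
        X = np.array([[1.0, 2.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match="zero Frobenius norm"):
            GroupedMatrix(X, np.array(["a", "b"]))

    def test_factorization_shape_check(self):
        with pytest.raises(ValueError, match="rank mismatch"):
            Factorization(np.ones((3, 2)), np.ones((3, 4)))


class TestNormalizeFeatures:
    def test_unit_norm_column(self):
        out = normalize_features(np.array([[3.0], [4.0]]))
        np.testing.assert_allclose(out[:, 0], [0.6, 0.8])

    def test_zero_column_unchanged(self):
        X = np.array([[1.0, 0.0], [1.0, 0.0]])
        out = normalize_features(X)
        np.testing.assert_array_equal(out[:, 1], 0.0)
        np.testing.assert_allclose(np.linalg.norm(out[:, 0]), 1.0)

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            normalize_features(np.array([[-1.0]]))

    @settings(max_examples=25, derandomize=True)
    @given(
        arrays(
            float,
            (20, 5),
            elements=st.floats(0, 10, allow_nan=False),
        )
    )
    def test_idempotent_and_unit_norms(self, X):
        once = normalize_features(X)
        norms = np.linalg.norm(once, axis=0)
        zero_cols = np.linalg.norm(X, axis=0) == 0
        assert np.all(np.abs(norms[~zero_cols] - 1.0) < 1e-12)
        assert np.all(norms[zero_cols] == 0.0)
        np.testing.assert_allclose(normalize_features(once), once, atol=1e-12)


class TestMetrics:
    def test_relative_error_examples(self):
        # exact reconstruction
        W = np.array([[1.0], [2.0]])
        H = np.array([[3.0, 4.0]])
        assert relative_error(W @ H, W, H) == 0.0
        # zero reconstruction of (3,4) gives ratio 1
        assert relative_error(np.array([[3.0, 4.0]]), np.zeros((1, 1)), np.zeros((1, 2))) == 1.0
        # hand-computed 4/5
        X = np.array([[3.0, 4.0]])
        assert relative_error(X, np.array([[1.0]]), np.array([[3.0, 0.0]])) == pytest.approx(0.8)

    def test_relative_error_zero_norm_raises(self):
        with pytest.raises(ZeroDivisionError):
            relative_error(np.zeros((2, 2)), np.zeros((2, 1)), np.zeros((1, 2)))

    def test_relative_loss_examples(self):
        X = np.array([[3.0, 4.0]])
        W = np.array([[1.0]])
        H = np.array([[3.0, 0.0]])  # achieved error 4, ||X|| = 5
        assert relative_loss(X, W, H, 4.0) == pytest.approx(0.0)
        assert relative_loss(X, W, H, 0.0) == pytest.approx(relative_error(X, W, H))
        # achieved error 2, E = 3, norm 5 -> -0.2 (negative loss is legal)
        X2 = np.array([[3.0, 4.0]])
        H2 = np.array([[3.0, 2.0]])  # residual (0, 2) -> error 2
        assert relative_loss(X2, np.array([[1.0]]), H2, 3.0) == pytest.approx(-0.2)

    def test_objective_f_max_and_tiebreak(self, rng):
        X = rng.uniform(0.1, 1.0, size=(9, 4))
        G = GroupedMatrix(X, np.repeat(["a", "b", "c"], 3))
        F = Factorization(rng.uniform(size=(9, 2)), rng.uniform(size=(2, 4)))
        errs = np.array(
            [np.linalg.norm(G.block(l) - F.W[G.group_indices[l]] @ F.H) for l in range(3)]
        )
        norms = G.group_norms
        # choose E so losses are (0.2, 0.5, 0.1)
        target = np.array([0.2, 0.5, 0.1])
        E = errs - target * norms
        m = compute_metrics(G, F, E)
        np.testing.assert_allclose(m.relative_losses, target, atol=1e-12)
        assert m.f == pytest.approx(0.5)
        assert m.worst_group == 1
        assert objective_f(G, F, E) == pytest.approx(0.5)
        # exact tie -> lowest index
        E_tie = errs - np.array([0.3, 0.3, 0.1]) * norms
        assert compute_metrics(G, F, E_tie).worst_group == 0

    def test_objective_single_group(self, rng):
        X = rng.uniform(0.1, 1.0, size=(5, 3))
        G = GroupedMatrix(X, np.zeros(5))
        F = Factorization(rng.uniform(size=(5, 2)), rng.uniform(size=(2, 3)))
        m = compute_metrics(G, F, [0.0])
        assert m.f == pytest.approx(m.relative_losses[0])

    def test_f_equals_bruteforce_max(self, rng):
        for _ in range(20):
            X = rng.uniform(0.05, 1.0, size=(12, 5))
            G = GroupedMatrix(X, rng.integers(0, 3, size=12))
            F = Factorization(rng.uniform(size=(12, 2)), rng.uniform(size=(2, 5)))
            E = rng.uniform(0, 1, size=G.L)
            m = compute_metrics(G, F, E)
            brute = max(
                relative_loss(G.block(l), F.W[G.group_indices[l]], F.H, E[l])
                for l in range(G.L)
            )
            assert m.f == pytest.approx(brute, abs=1e-14)


class TestIO:
    def test_csv_roundtrip(self, tmp_path):
        G = gen_dataset1(3)
        p = write_csv(G, tmp_path / "d1.csv")
        G2 = read_grouped_csv(p, "group")
        np.testing.assert_allclose(G2.X, G.X)
        assert list(G2.groups) == [str(g) for g in G.groups]

    def test_reader_rejects_non_numeric(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("f1,f2,group\n1.0,oops,a\n")
        with pytest.raises(ValueError, match="non-numeric"):
            read_grouped_csv(p, "group")

    def test_reader_missing_group_col(self, tmp_path):
        p = tmp_path / "x.csv"
        p.write_text("f1,f2\n1,2\n")
        with pytest.raises(ValueError, match="group column"):
            read_grouped_csv(p, "nope")

    def test_metric_writer_formats(self, tmp_path, rng, small_grouped):
        F = Factorization(rng.uniform(size=(40, 2)), rng.uniform(size=(2, 8)))
        m = compute_metrics(small_grouped, F, np.zeros(2))
        written = write_metric_table(m.to_frame(rank=2, trial=0), tmp_path / "metrics")
        assert {p.suffix for p in written} == {".csv", ".json"}
        assert all(p.exists() for p in written)
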