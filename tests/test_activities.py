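"""Activity inference, normalization, differential calls, correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy

from imodkit import (
    ActivityTable,
    activity_correlation,
    average_replicates,
    cluster_activities,
    differential_calls,
    infer_activities,
    normalize_to_reference,
)
from imodkit.exceptions import (
    ConfigurationError,
    IdentifierError,
    UndefinedCorrelationError,
)
from tests.conftest import expr


def random_structure(n_genes=80, k=4, n_samples=12, seed=0):
    rng = np.random.default_rng(seed)
    M = rng.laplace(0, 1, (n_genes, k))
    M /= np.linalg.norm(M, axis=0)
    M_df = pd.DataFrame(M, index=[f"g{i}" for i in range(n_genes)],
                        columns=[f"IC_{j + 1}" for j in range(k)])
    A = rng.normal(0, 4, (k, n_samples))
    A_df = pd.DataFrame(A, index=M_df.columns,
                        columns=[f"s{j}" for j in range(n_samples)])
    return M_df, A_df


class TestInferActivities:
    def test_exact_recovery_for_full_rank_structure(self):
        M, A = random_structure()
        x = expr(M.to_numpy() @ A.to_numpy(), genes=list(M.index),
                 samples=list(A.columns))
        inferred = infer_activities(M, x)
        np.testing.assert_allclose(inferred.data.to_numpy(), A.to_numpy(),
                                   atol=1e-8)

    def test_zero_input_gives_zero_activities(self):
        M, A = random_structure()
        x = expr(np.zeros((80, 3)), genes=list(M.index))
        inferred = infer_activities(M, x)
        np.testing.assert_allclose(inferred.data.to_numpy(), 0.0)

    def test_residual_orthogonal_to_structure_columns(self):
        rng = np.random.default_rng(1)
        M, A = random_structure(seed=1)
        noisy = M.to_numpy() @ A.to_numpy() + rng.normal(0, 0.5, (80, 12))
        x = expr(noisy, genes=list(M.index), samples=list(A.columns))
        inferred = infer_activities(M, x)
        resid = noisy - M.to_numpy() @ inferred.data.to_numpy()
        np.testing.assert_allclose(M.to_numpy().T @ resid, 0.0, atol=1e-8)

    def test_rank_deficient_structure_warns_minimum_norm(self):
        M, A = random_structure(k=3)
        M["IC_3"] = M["IC_1"]  # duplicate column -> rank deficient
        x = expr(np.random.default_rng(2).normal(size=(80, 4)),
                 genes=list(M.index))
        with pytest.warns(UserWarning, match="rank-deficient"):
            infer_activities(M, x)

    def test_gene_alignment_by_intersection(self):
        M, A = random_structure()
        x_full = expr(M.to_numpy() @ A.to_numpy(), genes=list(M.index),
                      samples=list(A.columns))
        shuffled = x_full.data.sample(frac=1, random_state=0)
        x = expr(shuffled.to_numpy(), genes=list(shuffled.index),
                 samples=list(shuffled.columns))
        inferred = infer_activities(M, x)
        np.testing.assert_allclose(inferred.data.to_numpy(), A.to_numpy(),
                                   atol=1e-8)


class TestNormalizeToReference:
    @staticmethod
    def _table():
        return ActivityTable(
            pd.DataFrame([[1.0, 6.0, 3.0], [-2.0, 0.0, 4.0]],
                         index=["a", "b"], columns=["r", "s1", "s2"])
        )

    def test_reference_column_becomes_zero(self):
        out = normalize_to_reference(self._table(), "r")
        np.testing.assert_allclose(out.data["r"], 0.0, atol=1e-9)
        assert out.normalization == "reference_relative"

    def test_idempotent(self):
        once = normalize_to_reference(self._table(), "r")
        twice = normalize_to_reference(once, "r")
        pd.testing.assert_frame_equal(once.data, twice.data)

    def test_differences_between_samples_preserved(self):
        t = self._table()
        out = normalize_to_reference(t, "r")
        before = t.data["s2"] - t.data["s1"]
        after = out.data["s2"] - out.data["s1"]
        pd.testing.assert_series_equal(before, after)

    def test_unknown_reference_raises(self):
        with pytest.raises(IdentifierError):
            normalize_to_reference(self._table(), "nope")


class TestDifferentialCalls:
    @staticmethod
    def _table():
        return ActivityTable(
            pd.DataFrame(
                {"a": [0.0, 0.0, 0.0, 0.0], "b": [6.0, -6.0, 5.0, 0.0]},
                index=["im1", "im2", "im3", "im4"],
            )
        )

    def test_threshold_semantics_strict(self):
        calls = {c.imodulon_id: c.call
                 for c in differential_calls(self._table(), "a", "b")}
        assert calls == {"im1": "U", "im2": "D", "im3": "-", "im4": "-"}

    def test_antisymmetric_under_sample_swap(self):
        fwd = differential_calls(self._table(), "a", "b")
        rev = differential_calls(self._table(), "b", "a")
        flip = {"U": "D", "D": "U", "-": "-"}
        for f, r in zip(fwd, rev):
            assert r.call == flip[f.call]
            assert r.delta_activity == -f.delta_activity

    def test_identical_samples_raise(self):
        with pytest.raises(ConfigurationError):
            differential_calls(self._table(), "a", "a")


class TestActivityCorrelation:
    @staticmethod
    def _table(seed=0, n=36):
        rng = np.random.default_rng(seed)
        return ActivityTable(
            pd.DataFrame(rng.normal(size=(2, n)), index=["u", "v"])
        )

    def test_self_correlation_is_one(self):
        t = self._table()
        r, p = activity_correlation(t, ("u", "u"))
        assert r == pytest.approx(1.0)

    def test_negation_gives_minus_one(self):
        t = self._table()
        t.data.loc["v"] = -t.data.loc["u"]
        r, p = activity_correlation(t, ("u", "v"))
        assert r == pytest.approx(-1.0)
        assert p < 1e-30

    def test_null_p_values_approximately_uniform(self):
        rng = np.random.default_rng(7)
        ps = []
        for _ in range(1000):
            t = ActivityTable(pd.DataFrame(rng.normal(size=(2, 36)),
                                           index=["u", "v"]))
            ps.append(activity_correlation(t, ("u", "v"))[1])
        from scipy.stats import kstest

        assert kstest(ps, "uniform").statistic < 0.05

    def test_matches_permutation_oracle(self):
        rng = np.random.default_rng(11)
        u = rng.normal(size=12)
        v = 0.8 * u + rng.normal(0, 0.8, 12)
        t = ActivityTable(pd.DataFrame([u, v], index=["u", "v"]))
        r, p = activity_correlation(t, ("u", "v"))
        n_perm, hits = 10_000, 0
        for _ in range(n_perm):
            rp = np.corrcoef(u, rng.permutation(v))[0, 1]
            hits += abs(rp) >= abs(r)
        p_perm = (hits + 1) / (n_perm + 1)
        assert p == pytest.approx(p_perm, abs=3 * np.sqrt(p_perm / n_perm) + 5e-4)

    def test_small_subset_and_zero_variance_raise(self):
        t = self._table()
        with pytest.raises(ConfigurationError):
            activity_correlation(t, ("u", "v"), t.sample_ids[:2])
        t.data.loc["v"] = 1.0
        with pytest.raises(UndefinedCorrelationError):
            activity_correlation(t, ("u", "v"))


class TestClusterActivities:
    def test_identical_rows_merge_first_at_zero_height(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=10)
        rows = np.vstack([base, rng.normal(size=10), base + 0.0,
                          rng.normal(size=10)])
        t = ActivityTable(pd.DataFrame(rows, index=["a", "b", "a2", "c"]))
        order, Z = cluster_activities(t)
        first = {int(Z[0, 0]), int(Z[0, 1])}
        assert first == {0, 2}
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_opposite_trajectory_groups_separate_at_two_clusters(self):
        t_vals = np.linspace(0, 24, 12)
        up = 5 / (1 + np.exp(-(t_vals - 8) / 2))
        rng = np.random.default_rng(1)
        rows, ids = [], []
        for i in range(3):
            rows.append(up + rng.normal(0, 0.1, 12))
            ids.append(f"up{i}")
        for i in range(3):
            rows.append(-up + rng.normal(0, 0.1, 12))
            ids.append(f"down{i}")
        t = ActivityTable(pd.DataFrame(rows, index=ids))
        order, Z = cluster_activities(t)
        labels = hierarchy.fcluster(Z, 2, criterion="maxclust")
        up_labels = set(labels[:3])
        down_labels = set(labels[3:])
        assert len(up_labels) == len(down_labels) == 1
        assert up_labels != down_labels

    def test_single_row_raises(self):
        t = ActivityTable(pd.DataFrame([[1.0, 2.0]], index=["only"]))
        with pytest.raises(ValueError):
            cluster_activities(t)

    def test_constant_row_warns_with_fallback(self):
        rows = np.vstack([np.ones(8), np.arange(8.0), np.arange(8.0) * 2])
        t = ActivityTable(pd.DataFrame(rows, index=["flat", "a", "b"]))
        with pytest.warns(UserWarning, match="constant"):
            order, Z = cluster_activities(t)
        assert len(order) == 3


def test_average_replicates_means_within_groups():
    meta = pd.DataFrame({
        "sample_id": ["s1", "s2", "s3"],
        "condition": ["c", "c", "c"],
        "time_h": [3.0, 3.0, 6.0],
        "replicate": [1, 2, 1],
    })
    t = ActivityTable(pd.DataFrame([[1.0, 3.0, 10.0]], index=["im"],
                                   columns=["s1", "s2", "s3"]))
    avg = average_replicates(t, meta)
    assert avg.data.loc["im", "c_t3"] == pytest.approx(2.0)
    assert avg.data.loc["im", "c_t6"] == pytest.approx(10.0)


from hypothesis import given, settings, strategies as st


@settings(derandomize=True, max_examples=200)
@given(
    deltas=st.lists(
        st.floats(-50, 50, allow_nan=False, allow_infinity=False),
        min_size=1, max_size=8,
    ),
    threshold=st.floats(0.1, 20),
)
def test_differential_call_invariant_holds_for_any_deltas(deltas, threshold):
    """call = U iff delta > t, D iff delta < -t, '-' otherwise; antisymmetric."""
    table = ActivityTable(
        pd.DataFrame({"a": [0.0] * len(deltas), "b": deltas},
                     index=[f"im{i}" for i in range(len(deltas))])
    )
    fwd = differential_calls(table, "a", "b", threshold=threshold)
    rev = differential_calls(table, "b", "a", threshold=threshold)
    flip = {"U": "D", "D": "U", "-": "-"}
    for c, r, d in zip(fwd, rev, deltas):
        expected = "U" if d > threshold else ("D" if d < -threshold else "-")
        assert c.call == expected
        assert r.call == flip[c.call]
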