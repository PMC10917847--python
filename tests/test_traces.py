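import numpy as np
import pandas as pd
import pytest

from adexmf.sweep import generate_grid
from adexmf.traces import (
    DEPOLARIZED_REGION,
    HYPERPOLARIZED_REGION,
    build_traces,
    class_distribution,
    cluster_traces,
)


def synthetic_table(n_values=3, feature=None, parox=None, seed=0):
    """Sweep-shaped table with synthesized feature values."""
    ranges = {
        "S": (0.0, 0.4),
        "E_L_i": (-80.0, -66.0),
        "E_L_e": (-78.0, -62.0),
        "T": (5.0, 40.0),
        "b_e": (0.0, 120.0),
    }
    grid = generate_grid(ranges, n_values=n_values)
    df = grid.as_dataframe()
    rng = np.random.default_rng(seed)
    if feature is None:
        df["mean_FC"] = rng.uniform(0, 1, len(df))
    else:
        df["mean_FC"] = feature(df)
    df["corrFCSC"] = rng.uniform(-0.2, 0.8, len(df))
    df["is_paroxysmal"] = False if parox is None else parox(df)
    df["status"] = "ok"
    return df


class TestBuildTraces:
    def test_trace_count_identity(self):
        df = synthetic_table(n_values=4)
        traces = build_traces(df, "mean_FC")
        assert len(traces) == len(df) // 4

    def test_default_grid_trace_count(self):
        # full 16-value grid: 675,840 / 16 = 42,240 traces
        grid = generate_grid(n_values=16)
        df = grid.as_dataframe()
        df["mean_FC"] = 0.0
        df["is_paroxysmal"] = False
        df["status"] = "ok"
        traces = build_traces(df, "mean_FC")
        assert len(traces) == 42_240

    def test_single_paroxysmal_record_invalidates_one_trace(self):
        df = synthetic_table(n_values=3)
        df.loc[7, "is_paroxysmal"] = True
        traces = build_traces(df, "mean_FC")
        invalid = [t for t in traces if not t.valid]
        assert len(invalid) == 1

    def test_incomplete_table_raises(self):
        df = synthetic_table(n_values=3)
        with pytest.raises(ValueError, match="incomplete"):
            build_traces(df.drop(index=[0]), "mean_FC")

    def test_unknown_feature(self):
        df = synthetic_table(n_values=2)
        with pytest.raises(ValueError, match="unknown feature"):
            build_traces(df, "nope")

    def test_trace_values_ordered_by_b_e(self):
        df = synthetic_table(n_values=3, feature=lambda d: d["b_e"] / 120.0)
        traces = build_traces(df, "mean_FC")
        for t in traces:
            assert np.all(np.diff(t.values) > 0)


class TestClusterTraces:
    def test_identical_traces_single_occupied_cluster(self):
        df = synthetic_table(n_values=3, feature=lambda d: 0.42)
        traces = build_traces(df, "mean_FC")
        model = cluster_traces(traces, k=4, seed=0)
        assert model.inertia == pytest.approx(0.0, abs=1e-12)
        occupied = {lab for lab in model.labels.values()}
        assert len(occupied) == 1
        lab = occupied.pop()
        assert np.allclose(model.centroids[lab], 0.42)

    def test_two_planted_families_recovered(self):
        rng = np.random.default_rng(1)
        n_be = 8
        flat = 0.1 + rng.normal(0, 0.003, (200, n_be))
        rising = np.linspace(0.1, 0.9, n_be) + rng.normal(0, 0.003, (200, n_be))
        from adexmf.traces import FeatureTrace

        traces = [
            FeatureTrace(key=(0, 0, 0, float(i)), b_e_values=np.arange(n_be),
                         values=v, valid=True)
            for i, v in enumerate(np.vstack([flat, rising]))
        ]
        model = cluster_traces(traces, k=2, seed=0)
        labels = np.array([model.labels[t.key] for t in traces])
        true = np.array([0] * 200 + [1] * 200)
        agreement = max((labels == true).mean(), (labels != true).mean())
        assert agreement == 1.0

    def test_six_centroids_of_trace_length(self):
        df = synthetic_table(n_values=4)
        traces = build_traces(df, "mean_FC")
        model = cluster_traces(traces, k=6, seed=1)
        assert model.centroids.shape == (6, 4)

    def test_deterministic_for_fixed_seed(self):
        df = synthetic_table(n_values=3)
        traces = build_traces(df, "mean_FC")
        a = cluster_traces(traces, k=3, seed=5)
        b = cluster_traces(traces, k=3, seed=5)
        assert a.labels == b.labels
        assert np.array_equal(a.centroids, b.centroids)

    def test_canonical_ordering_by_first_value(self):
        df = synthetic_table(n_values=3)
        traces = build_traces(df, "mean_FC")
        model = cluster_traces(traces, k=4, seed=2)
        assert np.all(np.diff(model.centroids[:, 0]) >= 0)

    def test_too_few_valid_traces(self):
        df = synthetic_table(n_values=2, parox=lambda d: True)
        traces = build_traces(df, "mean_FC")
        with pytest.raises(ValueError):
            cluster_traces(traces, k=3)


class TestClassDistribution:
    def _models(self, parox=None):
        df = synthetic_table(n_values=3, parox=parox)
        traces_fc = build_traces(df, "mean_FC")
        traces_cc = build_traces(df, "corrFCSC")
        return (
            cluster_traces(traces_fc, k=3, seed=0),
            cluster_traces(traces_cc, k=3, seed=0),
        )

    def test_fractions_sum_to_one(self):
        ma, mb = self._models()
        joint, cmap = class_distribution(ma, mb)
        assert joint.sum() == pytest.approx(1.0, abs=1e-12)
        assert (joint >= 0).all()
        assert len(cmap) == len(ma.labels)

    def test_single_trace_single_cell(self):
        from adexmf.traces import FeatureTrace, TraceClassModel

        key = (0.1, -70.0, -65.0, 19.0)
        ma = TraceClassModel(k=2, centroids=np.zeros((2, 3)), labels={key: 1},
                             inertia=0.0, seed=0)
        mb = TraceClassModel(k=2, centroids=np.zeros((2, 3)), labels={key: 0},
                             inertia=0.0, seed=0)
        joint, cmap = class_distribution(ma, mb)
        assert joint[1, 0] == 1.0
        assert joint.sum() == 1.0

    def test_independent_labels_approximate_product(self):
        from adexmf.traces import TraceClassModel

        rng = np.random.default_rng(3)
        keys = [(float(i), 0.0, 0.0, 0.0) for i in range(20000)]
        la = {key: int(rng.integers(0, 3)) for key in keys}
        lb = {key: int(rng.integers(0, 3)) for key in keys}
        ma = TraceClassModel(k=3, centroids=np.zeros((3, 2)), labels=la, inertia=0, seed=0)
        mb = TraceClassModel(k=3, centroids=np.zeros((3, 2)), labels=lb, inertia=0, seed=0)
        joint, _ = class_distribution(ma, mb)
        assert np.allclose(joint, 1 / 9, atol=0.01)

    def test_empty_region_filter(self):
        ma, mb = self._models()
        joint, cmap = class_distribution(ma, mb, region_filter=lambda key: False)
        assert joint.sum() == 0.0
        assert cmap.empty

    def test_region_filters(self):
        ma, mb = self._models()
        _, dep = class_distribution(ma, mb, region_filter=DEPOLARIZED_REGION)
        _, hyp = class_distribution(ma, mb, region_filter=HYPERPOLARIZED_REGION)
        if not dep.empty:
            assert dep["E_L_e"].between(-65, -60).all()
        if not hyp.empty:
            assert hyp["E_L_e"].between(-80, -75).all()

    def test_mismatched_trace_sets(self):
        from adexmf.traces import TraceClassModel

        ma = TraceClassModel(k=2, centroids=np.zeros((2, 2)),
                             labels={(0.0, 0.0, 0.0, 0.0): 0}, inertia=0, seed=0)
        mb = TraceClassModel(k=2, centroids=np.zeros((2, 2)),
                             labels={(1.0, 0.0, 0.0, 0.0): 0}, inertia=0, seed=0)
        with pytest.raises(ValueError):
            class_distribution(ma, mb)
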