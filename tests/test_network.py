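"""Functional graph estimation: partial correlations, lags, strong edges."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from funcgroups._utils import DegenerateInputError
from funcgroups.network import (
    ConditioningSet,
    FunctionalGraph,
    FunctionalGraphEstimator,
    build_functional_graph,
    functional_group,
    functional_lag,
    functional_weight,
    pairwise_functional_lags,
    pairwise_functional_weights,
    trial_partial_correlation,
)


def residual_correlation_oracle(cond: ConditioningSet) -> float:
    """Independent oracle: correlate the residuals of x and y after
    regressing each on the three conditioning series (with intercept)."""
    z = np.column_stack([np.ones_like(cond.mean_x), cond.mean_x, cond.mean_y, cond.pop])
    rx = cond.x - z @ np.linalg.lstsq(z, cond.x, rcond=None)[0]
    ry = cond.y - z @ np.linalg.lstsq(z, cond.y, rcond=None)[0]
    return float(np.corrcoef(rx, ry)[0, 1])


def random_conditioning_set(rng, t=200, coupled=0.9):
    c1, c2, c3 = rng.normal(size=(3, t))
    x = 0.5 * c1 - 0.3 * c2 + rng.normal(size=t)
    y = coupled * x + 0.4 * c3 + rng.normal(size=t)
    return ConditioningSet(x=x, y=y, mean_x=c1, mean_y=c2, pop=c3)


class TestTrialPartialCorrelation:
    def test_matches_residual_regression_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            cond = random_conditioning_set(rng, t=3000)
            assert abs(trial_partial_correlation(cond)
                       - residual_correlation_oracle(cond)) < 1e-8

    def test_independent_series_near_zero(self):
        rng = np.random.default_rng(1)
        cond = random_conditioning_set(rng, t=3000, coupled=0.0)
        cond.y = rng.normal(size=3000)  # fully independent of everything
        assert abs(trial_partial_correlation(cond)) < 0.1

    def test_symmetric_in_x_y(self):
        rng = np.random.default_rng(2)
        cond = random_conditioning_set(rng)
        swapped = ConditioningSet(x=cond.y, y=cond.x, mean_x=cond.mean_y,
                                  mean_y=cond.mean_x, pop=cond.pop)
        # Eq-1 is symmetric; numerically identical up to inversion rounding
        assert trial_partial_correlation(cond) == pytest.approx(
            trial_partial_correlation(swapped), abs=1e-12
        )

    def test_short_series_rejected(self):
        cond = ConditioningSet(*(np.arange(5.0) for _ in range(5)))
        with pytest.raises(DegenerateInputError):
            trial_partial_correlation(cond)

    def test_zero_variance_rejected(self):
        rng = np.random.default_rng(3)
        cond = random_conditioning_set(rng)
        cond.pop = np.zeros_like(cond.pop)
        with pytest.raises(DegenerateInputError):
            trial_partial_correlation(cond)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_bounded_in_minus_one_one(self, seed):
        cond = random_conditioning_set(np.random.default_rng(seed), t=40)
        assert -1.0 <= trial_partial_correlation(cond) <= 1.0


class TestFunctionalWeight:
    def test_mean_over_blocks(self, small_ds):
        from funcgroups.network import _conditioning_set

        aligned = small_ds.aligned_blocks()
        per_block = [
            trial_partial_correlation(_conditioning_set(aligned, b, 2, 5))
            for b in range(aligned.shape[0])
        ]
        assert functional_weight(small_ds, 2, 5) == pytest.approx(np.mean(per_block))

    def test_symmetry(self, small_ds):
        assert functional_weight(small_ds, 1, 4) == functional_weight(small_ds, 4, 1)

    def test_vectorized_matches_scalar(self, small_ds):
        w = pairwise_functional_weights(small_ds)
        for x in range(4):
            for y in range(x + 1, 5):
                assert w[x, y] == pytest.approx(functional_weight(small_ds, x, y), abs=1e-12)

    def test_null_simulation_centered_on_zero(self, null_sim):
        w = pairwise_functional_weights(null_sim.dataset)
        iu, ju = np.triu_indices(null_sim.dataset.n_neurons, k=1)
        vals = w[iu, ju]
        assert abs(vals.mean()) < 0.05
        # at T >= 5,000 frames spurious strong weights are rare
        assert np.mean(np.abs(vals) > 0.3) < 0.01


class TestFunctionalLag:
    def _shifted_dataset(self, shift=2):
        """Two neurons whose block-mean traces are exact shifted copies."""
        from funcgroups.dataset import FluorescenceDataset

        rng = np.random.default_rng(0)
        tb = 120
        base = np.convolve(rng.normal(size=tb + 10), np.ones(5) / 5, mode="same")
        a = base[5 : 5 + tb]
        b = np.roll(base, shift)[5 : 5 + tb]
        traces = np.tile(np.stack([a, b, rng.normal(size=tb)]), 2)
        return FluorescenceDataset(
            traces=traces,
            frame_rate_hz=30.0,
            labels=np.zeros(2 * tb, dtype=int),
            running_speed=np.zeros(2 * tb),
            block_index=np.repeat([0, 1], tb),
        )

    def test_exact_shift_recovered(self):
        ds = self._shifted_dataset(shift=2)
        assert functional_lag(ds, 0, 1, max_lag=5) == 2
        assert functional_lag(ds, 1, 0, max_lag=5) == -2

    def test_identical_traces_lag_zero(self):
        ds = self._shifted_dataset(shift=0)
        assert functional_lag(ds, 0, 1, max_lag=5) == 0

    def test_matches_exhaustive_scan(self, small_ds):
        m = small_ds.aligned_blocks().mean(axis=0)

        def brute(x, y, max_lag):
            best, best_lag = -np.inf, None
            for lag in range(-max_lag, max_lag + 1):
                if lag >= 0:
                    a, b = m[x][: len(m[x]) - lag or None], m[y][lag:]
                else:
                    a, b = m[x][-lag:], m[y][: len(m[y]) + lag]
                c = np.corrcoef(a, b)[0, 1]
                better = c > best + 1e-12
                tie = abs(c - best) <= 1e-12 and (
                    abs(lag) < abs(best_lag) or (abs(lag) == abs(best_lag) and lag > 0)
                )
                if better or tie:
                    best, best_lag = max(c, best), lag
            return best_lag

        lags = pairwise_functional_lags(small_ds, max_lag=8)
        for x in range(6):
            for y in range(x + 1, 7):
                expected = brute(x, y, 8)
                assert functional_lag(small_ds, x, y, max_lag=8) == expected
                assert lags[x, y] == expected

    def test_constant_trace_rejected(self):
        ds = self._shifted_dataset()
        ds.traces[0] = 1.0
        with pytest.raises(DegenerateInputError):
            functional_lag(ds, 0, 1, max_lag=3)

    def test_tie_prefers_small_then_positive_lag(self):
        # period-2 traces: the correlogram is identical at every even lag
        from funcgroups.dataset import FluorescenceDataset

        tb = 64
        a = np.tile([1.0, -1.0], tb // 2)
        b = np.tile([1.0, -1.0], tb // 2)
        traces = np.tile(np.stack([a, b, np.sin(np.arange(tb))]), 2)
        ds = FluorescenceDataset(
            traces=traces, frame_rate_hz=30.0,
            labels=np.zeros(2 * tb, dtype=int),
            running_speed=np.zeros(2 * tb),
            block_index=np.repeat([0, 1], tb),
        )
        assert functional_lag(ds, 0, 1, max_lag=4) == 0  # ties at -4,-2,0,2,4
        c = np.tile([1.0, -1.0], tb // 2) * -1  # anti-phase: ties at odd lags
        ds.traces[2] = np.tile(c, 2)
        assert functional_lag(ds, 0, 2, max_lag=4) == 1  # +1 preferred over -1


class TestGraph:
    def test_edge_count(self, small_graph):
        n = small_graph.n_neurons
        assert small_graph.n_edges == n * (n - 1) // 2 == 190

    def test_strong_mask_matches_sort_oracle(self, small_graph):
        w = np.abs(small_graph.edges["weight"].to_numpy())
        thr = np.percentile(w, 75)
        assert small_graph.edges["is_strong"].sum() == (w >= thr).sum()
        assert small_graph.strong_threshold() == pytest.approx(thr)

    def test_too_few_neurons_rejected(self, small_ds):
        from funcgroups.dataset import FluorescenceDataset

        tiny = FluorescenceDataset(
            traces=small_ds.traces[:2], frame_rate_hz=30.0,
            labels=small_ds.labels, running_speed=small_ds.running_speed,
            block_index=small_ds.block_index,
        )
        with pytest.raises(ValueError):
            build_functional_graph(tiny)

    def test_functional_groups_from_crafted_edges(self):
        edges = pd.DataFrame(
            {
                "neuron_a": [0, 0, 1],
                "neuron_b": [1, 2, 2],
                "weight": [0.5, -0.2, 0.4],
                "lag": [1, 0, 1],
                "direction": ["a->b", "bidirectional", "b->a"],
                "is_strong": [True, False, True],
            }
        )
        g = FunctionalGraph(n_neurons=3, edges=edges)
        assert functional_group(g, 1) == {0, 2}  # 0->1 directed, 2->1 via b->a
        assert functional_group(g, 0) == {2}  # only the bidirectional edge
        assert functional_group(g, 2) == {0}  # bidirectional counts both ways
        sizes = g.group_sizes()
        assert sizes.tolist() == [1, 2, 1]

    def test_incoming_matrix_respects_direction(self):
        edges = pd.DataFrame(
            {
                "neuron_a": [0], "neuron_b": [1], "weight": [0.7],
                "lag": [1], "direction": ["a->b"], "is_strong": [True],
            }
        )
        g = FunctionalGraph(n_neurons=3, edges=edges)
        w1 = g.weight_matrix(1)
        assert w1[1, 0] == 0.7 and w1[0, 1] == 0.0

    def test_tsv_roundtrip(self, small_graph, tmp_path):
        path = tmp_path / "graph.tsv"
        small_graph.to_tsv(path)
        loaded = FunctionalGraph.from_tsv(path, n_neurons=small_graph.n_neurons)
        pd.testing.assert_frame_equal(
            loaded.edges, small_graph.edges, check_dtype=False
        )

    def test_estimator_wrapper(self, small_ds, small_graph):
        est = FunctionalGraphEstimator(max_lag=8).fit(small_ds)
        assert est.n_neurons_ == small_ds.n_neurons
        pd.testing.assert_frame_equal(est.graph_.edges, small_graph.edges)

    def test_planted_direction_recovery_on_small_sim(self, small_sim, small_graph):
        # directions of planted lagged edges mostly recovered even at toy scale
        c = small_sim.coupling
        lags = pairwise_functional_lags(small_sim.dataset, max_lag=8)
        m1 = c.lag == 1
        if m1.sum() >= 3:
            assert np.mean(lags[c.source[m1], c.target[m1]] > 0) > 0.5
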