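"""Encoding models: splits, stimulus/running terms, fits, MSE comparisons."""
import numpy as np
import pandas as pd
import pytest

from funcgroups._utils import EmptySubsetError
from funcgroups.dataset import GREY
from funcgroups.encoding import (
    LinearEncoder,
    evaluate_mse,
    infer_tuned,
    percent_change_mse,
    run_block_averaged_comparison,
    run_model_suite,
    running_term,
    split_frames,
    stimulus_term_average_response,
    stimulus_term_block_averaged,
    subset_mask,
)


class TestSplitFrames:
    def test_block_split_70_30(self, small_ds):
        # 6 blocks at 0.7 -> 4 earliest blocks train (round(4.2))
        train, test = split_frames(small_ds, 0.7, "block")
        train_blocks = set(small_ds.block_index[train])
        assert train_blocks == {0, 1, 2}.union({3})
        assert set(small_ds.block_index[test]) == {4, 5}

    def test_partition(self, small_ds):
        train, test = split_frames(small_ds, 0.5, "presentation")
        assert len(np.intersect1d(train, test)) == 0
        assert len(train) + len(test) == small_ds.n_frames

    def test_equal_presentations_per_label_at_50_50(self, small_ds):
        train, _ = split_frames(small_ds, 0.5, "presentation")
        in_train = np.zeros(small_ds.n_frames, bool)
        in_train[train] = True
        counts = {}
        for p in small_ds.presentations():
            counts.setdefault(p.label, []).append(in_train[p.start : p.stop].all())
        for label, flags in counts.items():
            assert sum(flags) == len(flags) // 2

    def test_seeded_split_reproducible(self, small_ds):
        a = split_frames(small_ds, 0.7, "block", seed=3)
        b = split_frames(small_ds, 0.7, "block", seed=3)
        assert np.array_equal(a[0], b[0])
        c = split_frames(small_ds, 0.7, "block", seed=4)
        assert not np.array_equal(a[0], c[0])

    @pytest.mark.parametrize("ratio", [0.0, 1.0, -0.1])
    def test_invalid_ratio(self, small_ds, ratio):
        with pytest.raises(ValueError):
            split_frames(small_ds, ratio, "block")


class TestStimulusTerms:
    def test_average_response_is_plugin_mean(self, small_ds):
        train, _ = split_frames(small_ds, 0.7, "block")
        s = stimulus_term_average_response(small_ds, 3, train, tuned=True)
        lab = small_ds.labels
        for code in range(1, 13):
            expected = small_ds.traces[3, train][lab[train] == code].mean()
            vals = np.unique(s[lab == code])
            assert vals == pytest.approx(expected)
        assert np.all(s[lab == GREY] == 0.0)

    def test_untuned_constant_is_mean_of_direction_means(self, small_ds):
        train, _ = split_frames(small_ds, 0.7, "block")
        s = stimulus_term_average_response(small_ds, 3, train, tuned=False)
        lab = small_ds.labels
        per_dir = [
            small_ds.traces[3, train][lab[train] == c].mean() for c in range(1, 13)
        ]
        grating_vals = np.unique(s[lab != GREY])
        assert len(grating_vals) == 1
        assert grating_vals[0] == pytest.approx(np.mean(per_dir))

    def test_block_averaged_matches_groupby_oracle(self, small_ds):
        train, _ = split_frames(small_ds, 0.5, "presentation")
        s = stimulus_term_block_averaged(small_ds, 2, train)
        in_train = np.zeros(small_ds.n_frames, bool)
        in_train[train] = True
        pres = [p for p in small_ds.presentations() if in_train[p.start : p.stop].all()]
        by_label = {}
        for p in pres:
            by_label.setdefault(p.label, []).append(p)
        for label, group in by_label.items():
            stacked = np.stack(
                [small_ds.traces[2, p.start : p.stop] for p in group]
            )
            mean = stacked.mean(axis=0)
            for p in group:
                assert np.allclose(s[p.start : p.stop], mean)
        assert np.isnan(s[small_ds.labels == GREY]).all()

    def test_two_identical_presentations_average_to_either(self):
        from funcgroups.dataset import FluorescenceDataset

        rng = np.random.default_rng(0)
        block = np.r_[np.zeros(4, int), np.full(6, 3), np.zeros(4, int), np.full(6, 5)]
        labels = np.tile(block, 2)
        tb = len(block)
        one_block = rng.normal(size=(3, tb))
        ds = FluorescenceDataset(
            traces=np.tile(one_block, 2), frame_rate_hz=30.0, labels=labels,
            running_speed=np.zeros(2 * tb), block_index=np.repeat([0, 1], tb),
        )
        s = stimulus_term_block_averaged(ds, 0, np.arange(2 * tb))
        m = ds.labels == 3
        assert np.allclose(s[m], ds.traces[0, m])


class TestRunningTerm:
    def test_rotary_is_recorded_speed(self, small_ds):
        v = running_term(small_ds, "rotary")
        assert np.array_equal(v, small_ds.running_speed)
        assert np.all(v[small_ds.running_speed == 0] == 0)

    def test_population_average_excludes_target(self, small_ds):
        v = running_term(small_ds, "population_average", excluded_neuron=2)
        oracle = np.delete(small_ds.traces, 2, axis=0).mean(axis=0)
        assert np.allclose(v, oracle)

    def test_population_average_of_equal_traces(self):
        from funcgroups.dataset import FluorescenceDataset

        base = np.sin(np.linspace(0, 6, 50))
        ds = FluorescenceDataset(
            traces=np.tile(base, (4, 1)), frame_rate_hz=30.0,
            labels=np.zeros(50, int), running_speed=np.zeros(50),
            block_index=np.zeros(50, int),
        )
        assert np.allclose(running_term(ds, "population_average", 1), base)


class TestLinearEncoder:
    def test_exact_single_feature_fit(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(100, 3))
        y = x[:, 1].copy()
        enc = LinearEncoder().fit(x, y)
        assert enc.coef_ == pytest.approx([0.0, 1.0, 0.0], abs=1e-10)
        assert enc.intercept_ == pytest.approx(0.0, abs=1e-10)
        assert np.mean((enc.predict(x) - y) ** 2) < 1e-20

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            k = rng.integers(1, 8)
            x = rng.normal(size=(200, k))
            y = rng.normal(size=200)
            enc = LinearEncoder().fit(x, y)
            a = np.column_stack([np.ones(200), x])
            beta = np.linalg.solve(a.T @ a, a.T @ y)
            assert np.allclose(np.r_[enc.intercept_, enc.coef_], beta, atol=1e-8)

    def test_known_coefficients_recovered(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(500, 2))
        y = 2.0 * x[:, 0] - 3.0 * x[:, 1] + 5.0
        enc = LinearEncoder().fit(x, y)
        assert enc.coef_ == pytest.approx([2.0, -3.0], abs=1e-10)
        assert enc.intercept_ == pytest.approx(5.0, abs=1e-10)

    def test_nonneg_boundary_case(self):
        rng = np.random.default_rng(3)
        f = np.abs(rng.normal(size=(120, 1)))
        y = -f[:, 0]
        enc = LinearEncoder(nonneg=True).fit(f, y)
        assert enc.coef_[0] == pytest.approx(0.0, abs=1e-9)
        assert enc.intercept_ == pytest.approx(y.mean(), abs=1e-6)

    def test_nonneg_matches_unconstrained_when_truth_positive(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(300, 3))
        y = x @ [1.0, 2.0, 0.5] + 0.3 + 0.01 * rng.normal(size=300)
        a = LinearEncoder(nonneg=True).fit(x, y)
        b = LinearEncoder().fit(x, y)
        assert np.allclose(a.coef_, b.coef_, atol=1e-6)

    def test_reciprocal_link_generate_and_recover(self):
        rng = np.random.default_rng(5)
        x = np.abs(rng.normal(size=(400, 2))) + 0.5
        beta = np.array([1.0, 0.5, 0.8])
        eta = beta[0] + x @ beta[1:]
        y = 1.0 / eta
        enc = LinearEncoder(link="reciprocal").fit(x, y)
        assert enc.converged_
        assert np.allclose(np.r_[enc.intercept_, enc.coef_], beta, atol=1e-6)
        assert np.allclose(enc.predict(x), y, atol=1e-6)

    def test_cube_link_generate_and_recover(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(400, 2))
        beta = np.array([0.2, 1.5, -0.7])
        y = np.cbrt(beta[0] + x @ beta[1:])
        enc = LinearEncoder(link="cube").fit(x, y)
        assert np.allclose(np.r_[enc.intercept_, enc.coef_], beta, atol=1e-6)

    def test_cube_link_constant_response(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(100, 1))
        y = np.full(100, 2.0)
        enc = LinearEncoder(link="cube").fit(x, y)
        assert np.allclose(enc.predict(x), 2.0, atol=1e-6)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            LinearEncoder().fit(np.zeros((5, 3)), np.zeros(5))


class TestEvaluation:
    def test_perfect_predictions_zero(self, small_ds):
        y = small_ds.traces[0]
        assert evaluate_mse(y, y.copy(), np.arange(len(y))) == 0.0

    def test_zero_prediction_gives_variance(self, small_ds):
        y = small_ds.traces[0]
        frames = np.arange(len(y))
        got = evaluate_mse(y, np.zeros_like(y), frames)
        assert got == pytest.approx(np.mean(y**2))  # z-scored: variance

    def test_matches_direct_loop(self, small_ds):
        rng = np.random.default_rng(0)
        y = small_ds.traces[1]
        pred = y + rng.normal(size=len(y))
        frames = rng.choice(len(y), 200, replace=False)
        oracle = np.mean([(y[t] - pred[t]) ** 2 for t in frames])
        assert evaluate_mse(y, pred, frames) == pytest.approx(oracle)

    def test_empty_subset_signals(self, small_ds):
        y = small_ds.traces[0]
        with pytest.raises(EmptySubsetError):
            evaluate_mse(y, y, np.array([], dtype=int))

    def test_subset_masks(self, small_ds):
        assert subset_mask(small_ds, "all").all()
        assert np.array_equal(
            subset_mask(small_ds, "stimulus_only"), small_ds.labels != GREY
        )
        assert np.array_equal(
            subset_mask(small_ds, "running_only"), small_ds.running_speed > 0
        )
        fs = subset_mask(small_ds, "first_second_after_onset")
        k = int(np.ceil(small_ds.frame_rate_hz))
        pres = small_ds.presentations()
        assert fs.sum() == sum(min(k, p.stop - p.start) for p in pres)

    @pytest.mark.parametrize(
        "restricted,unrestricted,expected",
        [(0.05, 0.04, 25.0), (0.04, 0.04, 0.0), (0.03, 0.04, -25.0)],
    )
    def test_percent_change(self, restricted, unrestricted, expected):
        assert percent_change_mse(restricted, unrestricted) == pytest.approx(expected)

    def test_percent_change_undefined_for_zero_baseline(self):
        with pytest.raises(ValueError):
            percent_change_mse(0.1, 0.0)


class TestModelSuite:
    def test_unrestricted_is_zero_change(self, small_ds, small_graph):
        comp = run_model_suite(small_ds, small_graph, variants=("unrestricted",))
        r = comp.results
        assert (r.loc[r["variant"] == "unrestricted", "pct_change"] == 0.0).all()

    def test_nesting_enforced_on_every_run(self, small_ds, small_graph):
        # _check_nesting raises on violation; a clean run is the assertion
        comp = run_model_suite(
            small_ds, small_graph,
            variants=("unrestricted", "stim_restricted", "coupling_restricted", "lm0"),
        )
        assert set(comp.results["variant"]) == {
            "unrestricted", "stim_restricted", "coupling_restricted", "lm0"
        }

    def test_coupling_beats_stimulus_on_coupled_sim(self, small_ds, small_graph):
        comp = run_model_suite(
            small_ds, small_graph,
            variants=("unrestricted", "coupling_restricted", "stim_restricted"),
        )
        assert (comp.median_pct_change("coupling_restricted")
                > comp.median_pct_change("stim_restricted"))

    def test_relabeling_invariance(self, small_ds, small_graph):
        perm = np.random.default_rng(0).permutation(small_ds.n_neurons)
        from funcgroups.dataset import FluorescenceDataset
        from funcgroups.network import FunctionalGraph

        inv = np.argsort(perm)
        ds2 = FluorescenceDataset(
            traces=small_ds.traces[perm], frame_rate_hz=small_ds.frame_rate_hz,
            labels=small_ds.labels, running_speed=small_ds.running_speed,
            block_index=small_ds.block_index, tuned=small_ds.tuned[perm],
        )
        e = small_graph.edges.copy()
        a, b = inv[e["neuron_a"]], inv[e["neuron_b"]]
        flip = a > b
        e["neuron_a"], e["neuron_b"] = np.minimum(a, b), np.maximum(a, b)
        d = e["direction"].to_numpy().copy()
        was_fwd = flip & (d == "a->b")
        was_rev = flip & (d == "b->a")
        d[was_fwd], d[was_rev] = "b->a", "a->b"
        e["direction"] = d
        g2 = FunctionalGraph(small_ds.n_neurons, e, small_graph.lag_filter,
                             small_graph.max_lag)
        comp1 = run_model_suite(small_ds, small_graph,
                                variants=("unrestricted", "coupling_restricted"))
        comp2 = run_model_suite(ds2, g2,
                                variants=("unrestricted", "coupling_restricted"))
        r1 = comp1.results.query("variant == 'coupling_restricted'")
        r2 = comp2.results.query("variant == 'coupling_restricted'")
        v1 = r1.set_index("neuron")["pct_change"]
        v2 = r2.set_index("neuron")["pct_change"]
        for old in range(small_ds.n_neurons):
            assert v1[old] == pytest.approx(v2[inv[old]], abs=1e-6)

    def test_block_averaged_comparison(self, small_ds, small_graph):
        res = run_block_averaged_comparison(small_ds, small_graph)
        assert set(res["variant"]) == {"stim_restricted", "coupling_restricted"}
        med = res.groupby("variant")["pct_change"].median()
        assert med["coupling_restricted"] > 0  # coupling drives this sim


def test_infer_tuned_finds_tuned_neurons(small_sim):
    ds = small_sim.dataset
    train, _ = split_frames(ds, 0.7, "block")
    tuned = infer_tuned(ds, train)
    truth = small_sim.tuning.tuned
    strong = truth & (small_sim.tuning.stim_gain > 0.3)
    if strong.any():
        assert tuned[strong].mean() > 0.5
    assert tuned[~truth].mean() < 0.5
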