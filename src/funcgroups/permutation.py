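"""Graph permutation stress tests for the coupled encoding model.

Two null schemes act on the pooled *strong* edges (top quartile of |weight|):

- **weights**: a uniformly random permutation of the (weight, lag) pairs over
  the strong edges, keeping the source-target pairs fixed — topology
  preserved, weights scrambled.  Bidirectionality travels with the permuted
  lag.
- **edges**: a uniformly random permutation of the strong edges' terminal
  neurons, keeping each (weight, lag) attached to its source — functional
  group memberships change, per-source weight multisets are preserved.

Without refitting, the original unrestricted-LM coefficients are applied to
the permuted coupling features and the change in *training* MSE is recorded
(refitting would let the coefficients absorb the shuffle).  With refitting,
coefficients are refit on the training split and *test* MSE is compared.
Each permutation draws from a counter-based seed stream so any single
permutation is reproducible in isolation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .encoding import VARIANTS, ModelComparison, _lagged_coupling
from .network import FunctionalGraph

logger = logging.getLogger(__name__)

__all__ = [
    "PermutationResult",
    "permute_strong_weights",
    "permute_strong_edges",
    "permutation_mse_change",
]

_MAX_REDRAWS = 1000


def _permuted_graph_weights(graph: FunctionalGraph, perm: np.ndarray) -> FunctionalGraph:
    """Apply an explicit permutation to the strong edges' (weight, lag) pairs."""
    edges = graph.edges.copy()
    idx = edges.index[edges["is_strong"]].to_numpy()
    w = edges.loc[idx, "weight"].to_numpy()
    l = edges.loc[idx, "lag"].to_numpy()
    d = edges.loc[idx, "direction"].to_numpy()
    new_w, new_l = w[perm], l[perm]
    # bidirectionality follows the permuted lag; directed edges keep their
    # stored source->target orientation when they receive a nonzero lag
    fallback = np.where(d == "bidirectional", "a->b", d)
    new_d = np.where(new_l == 0, "bidirectional", fallback)
    edges.loc[idx, "weight"] = new_w
    edges.loc[idx, "lag"] = new_l
    edges.loc[idx, "direction"] = new_d
    return FunctionalGraph(graph.n_neurons, edges, graph.lag_filter, graph.max_lag)


def permute_strong_weights(graph: FunctionalGraph, seed: int) -> FunctionalGraph:
    """Topology-preserving shuffle of the strong (weight, lag) pairs."""
    k = int(graph.edges["is_strong"].sum())
    if k < 2:
        logger.warning("fewer than 2 strong edges; weight permutation is a no-op")
        return graph
    perm = np.random.default_rng(seed).permutation(k)
    return _permuted_graph_weights(graph, perm)


def _permuted_graph_edges(graph: FunctionalGraph, new_tgt: np.ndarray) -> FunctionalGraph:
    """Reassign the strong edges' terminal neurons to ``new_tgt``.

    Because the estimated functional graph carries an edge for *every*
    pair, a permuted strong edge necessarily lands on a pair already
    holding a weak edge; that weak edge is superseded (dropped for this
    permuted graph).  Two strong edges landing on the same directed slot
    simply stack — the incoming-weight matrices accumulate contributions —
    which preserves the strong-edge count and every per-source strong
    weight multiset.
    """
    edges = graph.edges.copy()
    strong = graph.strong_edges()
    src = strong["source"].to_numpy()
    if (src == new_tgt).any():
        raise ValueError("self-edges must be repaired before reassignment")
    pair_a = np.minimum(src, new_tgt)
    pair_b = np.maximum(src, new_tgt)
    new_pairs = set(zip(pair_a.tolist(), pair_b.tolist()))
    idx = strong["edge_index"].to_numpy()
    lag = edges.loc[idx, "lag"].to_numpy()
    direction = np.where(lag == 0, "bidirectional",
                         np.where(src < new_tgt, "a->b", "b->a"))
    edges.loc[idx, "neuron_a"] = pair_a
    edges.loc[idx, "neuron_b"] = pair_b
    edges.loc[idx, "direction"] = direction
    weak = edges[~edges["is_strong"]]
    collide = [
        i for i, a, b in zip(weak.index, weak["neuron_a"], weak["neuron_b"])
        if (a, b) in new_pairs
    ]
    if collide:
        edges = edges.drop(index=collide)
    return FunctionalGraph(graph.n_neurons, edges, graph.lag_filter, graph.max_lag)


def permute_strong_edges(graph: FunctionalGraph, seed: int) -> FunctionalGraph:
    """Topology-changing shuffle of the strong edges' terminal neurons.

    Weights and lags stay attached to their source neuron.  A uniformly
    random permutation of the target list is drawn; assignments that would
    create a self-edge are repaired by swapping targets with another
    randomly chosen strong edge (bounded rounds, logged), since full
    rejection sampling is infeasible when strong edges outnumber neurons.
    """
    k = int(graph.edges["is_strong"].sum())
    if k < 2:
        logger.warning("fewer than 2 strong edges; edge permutation is a no-op")
        return graph
    rng = np.random.default_rng(seed)
    strong = graph.strong_edges()
    src = strong["source"].to_numpy()
    new_tgt = strong["target"].to_numpy()[rng.permutation(k)]
    for round_ in range(_MAX_REDRAWS):
        bad = np.flatnonzero(src == new_tgt)
        if len(bad) == 0:
            if round_:
                logger.debug("self-edges repaired in %d swap rounds", round_)
            break
        for i in bad:
            j = int(rng.integers(k))
            new_tgt[i], new_tgt[j] = new_tgt[j], new_tgt[i]
    else:
        raise RuntimeError(f"self-edges persisted after {_MAX_REDRAWS} repair rounds")
    return _permuted_graph_edges(graph, new_tgt)


@dataclass
class PermutationResult:
    """Per-permutation, per-neuron percent change in MSE plus summaries.

    Without refit the matrix holds training-MSE changes and the headline
    summary is the median (across permutations) of the per-permutation
    median (across neurons), with the IQR of those medians.  With refit it
    holds test-MSE changes and the summary is the grand median / IQR pooled
    over all neurons and permutations.
    """

    scheme: str
    refit: bool
    n_permutations: int
    pct_change: np.ndarray  # (n_permutations, n_neurons)
    seed: int

    def per_permutation_medians(self) -> np.ndarray:
        out = np.full(self.pct_change.shape[0], np.nan)
        ok = np.isfinite(self.pct_change).any(axis=1)
        if ok.any():
            out[ok] = np.nanmedian(self.pct_change[ok], axis=1)
        return out

    def summary(self) -> dict:
        def iqr(x):
            x = np.asarray(x)
            if x.size == 0:
                return float("nan")
            q1, q3 = np.nanpercentile(x, [25, 75])
            return float(q3 - q1)

        out = {"scheme": self.scheme, "refit": self.refit,
               "n_permutations": self.n_permutations}
        if self.refit:
            flat = self.pct_change[np.isfinite(self.pct_change)]
            out["grand_median"] = float(np.median(flat))
            out["grand_iqr"] = iqr(flat)
        else:
            med = self.per_permutation_medians()
            out["median_of_medians"] = float(np.median(med))
            out["iqr_of_medians"] = iqr(med)
        return out

    def to_json(self) -> dict:
        d = self.summary()
        d["seed"] = self.seed
        d["pct_change"] = self.pct_change.tolist()
        return d


def _coupling_features(graph, traces, block_index):
    c0, _ = _lagged_coupling(graph.weight_matrix(0), traces, 0, block_index)
    c1, valid1 = _lagged_coupling(graph.weight_matrix(1), traces, 1, block_index)
    if 0 not in graph.lag_filter:
        c0 = np.zeros_like(c0)
    if 1 not in graph.lag_filter:
        c1 = np.zeros_like(c1)
    return c0, c1, valid1


def permutation_mse_change(
    comparison: ModelComparison,
    scheme: str = "weights",
    n_permutations: int | None = None,
    refit: bool = False,
    seed: int = 0,
) -> PermutationResult:
    """Distribution of per-neuron % MSE change under a permutation scheme.

    `comparison` must hold fitted unrestricted models (terms c0, c1, stim,
    run).  Defaults to 1000 permutations without refit and 100 with refit.
    """
    if scheme not in ("weights", "edges"):
        raise ValueError("scheme must be 'weights' or 'edges'")
    if n_permutations is None:
        n_permutations = 100 if refit else 1000
    if n_permutations < 1:
        raise ValueError("n_permutations must be positive")
    assert VARIANTS["unrestricted"].terms == ("c0", "c1", "stim", "run")
    ds, graph, feats = comparison.dataset, comparison.graph, comparison.features
    models = comparison.models["unrestricted"]
    traces = ds.traces
    n, t = traces.shape
    fitted = sorted(models)
    ic = np.array([models[i].intercept_ for i in fitted])
    coef = np.array([models[i].coef_ for i in fitted])  # (n_fit, 4)

    train = np.zeros(t, dtype=bool)
    train[comparison.train_frames] = True
    test = np.zeros(t, dtype=bool)
    test[comparison.test_frames] = True

    def predictions(c0, c1):
        return (ic[:, None]
                + coef[:, 0:1] * c0[fitted]
                + coef[:, 1:2] * c1[fitted]
                + coef[:, 2:3] * feats.stim[fitted]
                + coef[:, 3:4] * feats.run[None, :])

    c0_orig, c1_orig, valid1 = _coupling_features(graph, traces, ds.block_index)
    rows_train = train & valid1
    rows_test = test & valid1
    pred0 = predictions(c0_orig, c1_orig)
    base_train = np.mean((traces[fitted][:, rows_train] - pred0[:, rows_train]) ** 2, axis=1)
    base_test = np.mean((traces[fitted][:, rows_test] - pred0[:, rows_test]) ** 2, axis=1)

    permute = permute_strong_weights if scheme == "weights" else permute_strong_edges
    pct = np.full((n_permutations, n), np.nan)
    for p in range(n_permutations):
        perm_seed = np.random.default_rng([seed, p]).integers(2**31 - 1)
        try:
            pg = permute(graph, int(perm_seed))
        except RuntimeError as err:
            logger.warning("permutation %d failed: %s", p, err)
            continue
        c0p, c1p, _ = _coupling_features(pg, traces, ds.block_index)
        if refit:
            for row, i in enumerate(fitted):
                x = np.column_stack(
                    [c0p[i], c1p[i], feats.stim[i], feats.run]
                )
                a = np.column_stack([np.ones(rows_train.sum()), x[rows_train]])
                beta, *_ = np.linalg.lstsq(a, traces[i, rows_train], rcond=None)
                resid = traces[i, rows_test] - (beta[0] + x[rows_test] @ beta[1:])
                pct[p, i] = 100.0 * (np.mean(resid**2) - base_test[row]) / base_test[row]
        else:
            predp = predictions(c0p, c1p)
            msep = np.mean(
                (traces[fitted][:, rows_train] - predp[:, rows_train]) ** 2, axis=1
            )
            pct[p, fitted] = 100.0 * (msep - base_train) / base_train
    return PermutationResult(
        scheme=scheme, refit=refit, n_permutations=n_permutations,
        pct_change=pct, seed=seed,
    )
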