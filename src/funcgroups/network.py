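"""Functional coupling graph from trial-wise partial correlations.

The *functional weight* between neurons x and y is the across-trial mean of
a trial-specific partial correlation: within each block, the correlation
between the two trial traces after conditioning on (i) each neuron's
leave-one-out trial-mean trace (stimulus-locked component) and (ii) the
within-trial population mean excluding the pair (running / global state).
With Omega the 5x5 correlation matrix of those series (x and y first),

    rho_xy = -(Omega^-1)_xy / sqrt((Omega^-1)_xx (Omega^-1)_yy)

The *functional lag* is the argmax over integer lags of the cross-correlogram
of the two neurons' block-mean traces; its sign orients the edge (positive:
y follows x, edge x->y) and lag 0 marks a bidirectional edge.  Per neuron,
incoming weights at each lag form the coupling feature vectors used by the
encoding models; "strong" edges are the pooled top quartile of |weight|.

Two implementations are provided: a scalar per-pair path
(:func:`trial_partial_correlation`, :func:`functional_weight`,
:func:`functional_lag`) that follows the definitions directly, and a
vectorized all-pairs path used by :func:`build_functional_graph`; the two are
cross-checked in the test suite.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._utils import DegenerateInputError
from .dataset import FluorescenceDataset

logger = logging.getLogger(__name__)

__all__ = [
    "ConditioningSet",
    "FunctionalGraph",
    "FunctionalGraphEstimator",
    "trial_partial_correlation",
    "functional_weight",
    "functional_lag",
    "build_functional_graph",
    "functional_group",
    "pairwise_functional_weights",
    "pairwise_functional_lags",
]

_RIDGE = 1e-8
_COND_MAX = 1e12


# ---------------------------------------------------------------------------
# scalar path
# ---------------------------------------------------------------------------
@dataclass
class ConditioningSet:
    """The five equal-length series entering the trial partial correlation.

    Index order in Omega: trial trace of x, trial trace of y, leave-one-out
    trial-mean of x, leave-one-out trial-mean of y, within-trial population
    mean excluding x and y.
    """

    x: np.ndarray
    y: np.ndarray
    mean_x: np.ndarray
    mean_y: np.ndarray
    pop: np.ndarray

    def series(self) -> np.ndarray:
        s = np.stack([self.x, self.y, self.mean_x, self.mean_y, self.pop])
        if s.ndim != 2:
            raise ValueError("all five series must be equal-length 1-D arrays")
        return s

    def omega(self) -> np.ndarray:
        return np.corrcoef(self.series())


def trial_partial_correlation(cond: ConditioningSet) -> float:
    """Partial correlation of x and y given the three conditioning series.

    Computed from the precision matrix of the 5x5 correlation matrix of the
    series.  A ridge of 1e-8 is added when Omega is ill-conditioned
    (condition number > 1e12); if Omega is still numerically singular the
    value 0 is returned with a logged degeneracy flag.

    Raises
    ------
    DegenerateInputError
        If any series is shorter than 10 frames or has zero variance.
    """
    s = cond.series()
    if s.shape[1] < 10:
        raise DegenerateInputError("conditioning series must have length >= 10")
    if (s.std(axis=1) < 1e-14).any():
        raise DegenerateInputError("conditioning series with zero variance")
    omega = np.corrcoef(s)
    if np.linalg.cond(omega) > _COND_MAX:
        omega = omega + _RIDGE * np.eye(5)
    try:
        prec = np.linalg.inv(omega)
    except np.linalg.LinAlgError:
        logger.warning("singular Omega after ridge; returning 0")
        return 0.0
    denom = prec[0, 0] * prec[1, 1]
    if not np.isfinite(denom) or denom <= 0:
        logger.warning("degenerate precision matrix; returning 0")
        return 0.0
    rho = -prec[0, 1] / np.sqrt(denom)
    return float(np.clip(rho, -1.0, 1.0))


def _conditioning_set(aligned: np.ndarray, block: int, x: int, y: int) -> ConditioningSet:
    """Build the five series for pair (x, y) within one block.

    `aligned` is the (n_blocks, n_neurons, frames_per_block) array of traces
    aligned by within-block frame position.
    """
    b_count, n, _ = aligned.shape
    loo = (aligned.sum(axis=0) - aligned[block]) / (b_count - 1)
    pop = (aligned[block].sum(axis=0) - aligned[block, x] - aligned[block, y]) / (n - 2)
    return ConditioningSet(
        x=aligned[block, x],
        y=aligned[block, y],
        mean_x=loo[x],
        mean_y=loo[y],
        pop=pop,
    )


def functional_weight(dataset: FluorescenceDataset, x: int, y: int) -> float:
    """Across-block mean of the trial partial correlation for pair (x, y).

    Blocks whose conditioning series are degenerate are excluded from the
    mean; if every block is degenerate the weight is 0 (flagged in the log).
    """
    x, y = (x, y) if x < y else (y, x)  # canonical order: symmetry is exact
    aligned = dataset.aligned_blocks()
    if aligned.shape[0] < 2:
        raise ValueError("functional weights need at least 2 blocks")
    vals = []
    for b in range(aligned.shape[0]):
        try:
            vals.append(trial_partial_correlation(_conditioning_set(aligned, b, x, y)))
        except DegenerateInputError:
            logger.warning("degenerate block %d for pair (%d, %d); excluded", b, x, y)
    if not vals:
        logger.warning("all blocks degenerate for pair (%d, %d); weight set to 0", x, y)
        return 0.0
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# vectorized all-pairs weights
# ---------------------------------------------------------------------------
def pairwise_functional_weights(dataset: FluorescenceDataset) -> np.ndarray:
    """All-pairs functional weights as a symmetric (N, N) matrix (diag 0).

    Algebraically identical to averaging :func:`trial_partial_correlation`
    over blocks for every pair, but built from per-block Gram matrices so the
    5x5 correlation matrices of all pairs are assembled and inverted in a
    single batch per block.
    """
    aligned = dataset.aligned_blocks()
    b_count, n, tb = aligned.shape
    if b_count < 2:
        raise ValueError("functional weights need at least 2 blocks")
    if n < 3:
        raise ValueError("population mean excluding the pair needs N >= 3")
    iu, ju = np.triu_indices(n, k=1)
    p = len(iu)
    total = aligned.sum(axis=0)
    rho_sum = np.zeros(p)
    rho_cnt = np.zeros(p, dtype=int)
    eye5 = np.eye(5)
    for b in range(b_count):
        xc = aligned[b] - aligned[b].mean(axis=1, keepdims=True)
        m = (total - aligned[b]) / (b_count - 1)
        mc = m - m.mean(axis=1, keepdims=True)
        sc = xc.sum(axis=0)
        g_xx = xc @ xc.T
        g_xm = xc @ mc.T  # g_xm[i, j] = x_i . m_j
        g_mm = mc @ mc.T
        g_xs = xc @ sc
        g_ms = mc @ sc
        g_ss = float(sc @ sc)
        nm2 = n - 2
        cov = np.empty((p, 5, 5))
        dxx = np.diag(g_xx)
        dxm = np.diag(g_xm)
        dmm = np.diag(g_mm)
        cov[:, 0, 0] = dxx[iu]
        cov[:, 1, 1] = dxx[ju]
        cov[:, 2, 2] = dmm[iu]
        cov[:, 3, 3] = dmm[ju]
        cov[:, 0, 1] = g_xx[iu, ju]
        cov[:, 0, 2] = dxm[iu]
        cov[:, 0, 3] = g_xm[iu, ju]
        cov[:, 1, 2] = g_xm[ju, iu]
        cov[:, 1, 3] = dxm[ju]
        cov[:, 2, 3] = g_mm[iu, ju]
        cov[:, 0, 4] = (g_xs[iu] - dxx[iu] - g_xx[iu, ju]) / nm2
        cov[:, 1, 4] = (g_xs[ju] - g_xx[iu, ju] - dxx[ju]) / nm2
        cov[:, 2, 4] = (g_ms[iu] - dxm[iu] - g_xm[ju, iu]) / nm2
        cov[:, 3, 4] = (g_ms[ju] - g_xm[iu, ju] - dxm[ju]) / nm2
        cov[:, 4, 4] = (
            g_ss - 2 * (g_xs[iu] + g_xs[ju]) + dxx[iu] + dxx[ju] + 2 * g_xx[iu, ju]
        ) / nm2**2
        il, jl = np.tril_indices(5, k=-1)
        cov[:, il, jl] = cov[:, jl, il]
        var = np.diagonal(cov, axis1=1, axis2=2)
        ok = (var > 1e-14 * tb).all(axis=1)
        d = np.sqrt(np.where(var > 0, var, 1.0))
        omega = cov / (d[:, :, None] * d[:, None, :])
        with np.errstate(all="ignore"):
            conds = np.linalg.cond(omega)
        bad = ~np.isfinite(conds) | (conds > _COND_MAX)
        if bad.any():
            omega[bad] += _RIDGE * eye5
        try:
            prec = np.linalg.inv(omega[ok])
        except np.linalg.LinAlgError:  # isolate failures pair by pair
            prec = np.empty((ok.sum(), 5, 5))
            for idx, om in enumerate(omega[ok]):
                try:
                    prec[idx] = np.linalg.inv(om)
                except np.linalg.LinAlgError:
                    prec[idx] = np.nan
        denom = prec[:, 0, 0] * prec[:, 1, 1]
        with np.errstate(all="ignore"):
            rho = np.clip(-prec[:, 0, 1] / np.sqrt(denom), -1.0, 1.0)
        good = np.isfinite(rho) & (denom > 0)
        idx_ok = np.flatnonzero(ok)[good]
        rho_sum[idx_ok] += rho[good]
        rho_cnt[idx_ok] += 1
    weights = np.zeros(p)
    has = rho_cnt > 0
    weights[has] = rho_sum[has] / rho_cnt[has]
    if (~has).any():
        logger.warning("%d pairs degenerate in every block; weights set to 0", (~has).sum())
    w = np.zeros((n, n))
    w[iu, ju] = weights
    w[ju, iu] = weights
    return w


# ---------------------------------------------------------------------------
# functional lags
# ---------------------------------------------------------------------------
def _block_mean_traces(dataset: FluorescenceDataset) -> np.ndarray:
    return dataset.aligned_blocks().mean(axis=0)


def _lagged_correlation(a: np.ndarray, b: np.ndarray, lag: int) -> float:
    """Pearson correlation of a(t) with b(t + lag) on the overlap."""
    if lag >= 0:
        sa, sb = a[: len(a) - lag or None], b[lag:]
    else:
        sa, sb = a[-lag:], b[: len(b) + lag]
    sa = sa - sa.mean()
    sb = sb - sb.mean()
    denom = np.sqrt((sa @ sa) * (sb @ sb))
    if denom < 1e-14:
        return np.nan
    return float((sa @ sb) / denom)


def _preference_order(max_lag: int) -> list[int]:
    """Tie-break order: smallest |lag| first, positive before negative."""
    order = [0]
    for l in range(1, max_lag + 1):
        order.extend([l, -l])
    return order


def functional_lag(
    dataset: FluorescenceDataset, x: int, y: int, max_lag: int = 17
) -> int:
    """Signed lag maximizing the cross-correlogram of the block-mean traces.

    Positive means y follows x (edge x -> y), negative means x follows y,
    zero marks a bidirectional edge.  Ties go to the smallest |lag|, then to
    the positive lag.
    """
    m = _block_mean_traces(dataset)
    if m[x].std() < 1e-14 or m[y].std() < 1e-14:
        raise DegenerateInputError("constant block-mean trace")
    order = _preference_order(max_lag)
    vals = np.array([_lagged_correlation(m[x], m[y], l) for l in order])
    finite = np.isfinite(vals)
    if not finite.any():
        raise DegenerateInputError("no finite lagged correlations")
    best = np.nanmax(vals)
    return order[int(np.argmax(vals >= best - 1e-12))]


def pairwise_functional_lags(
    dataset: FluorescenceDataset, max_lag: int = 17
) -> np.ndarray:
    """All-pairs signed functional lags, (N, N) antisymmetric matrix.

    Entry [x, y] is the signed lag of pair (x, y) under the same convention
    and tie rules as :func:`functional_lag`.
    """
    m = _block_mean_traces(dataset)
    n, tb = m.shape
    if max_lag >= tb - 1:
        raise ValueError("max_lag too large for block length")
    corr = {}
    for l in range(max_lag + 1):
        a = m[:, : tb - l or None]
        b = m[:, l:]
        ac = a - a.mean(axis=1, keepdims=True)
        bc = b - b.mean(axis=1, keepdims=True)
        sa = np.sqrt((ac * ac).sum(axis=1))
        sb = np.sqrt((bc * bc).sum(axis=1))
        sa[sa < 1e-14] = np.inf
        sb[sb < 1e-14] = np.inf
        corr[l] = (ac / sa[:, None]) @ (bc / sb[:, None]).T
    order = _preference_order(max_lag)
    iu, ju = np.triu_indices(n, k=1)
    stack = np.empty((len(order), len(iu)))
    for k, l in enumerate(order):
        c = corr[abs(l)]
        stack[k] = c[iu, ju] if l >= 0 else c[ju, iu]
    best = stack.max(axis=0)
    first = np.argmax(stack >= best - 1e-12, axis=0)
    lags = np.array(order)[first]
    out = np.zeros((n, n), dtype=int)
    out[iu, ju] = lags
    out[ju, iu] = -lags
    return out


# ---------------------------------------------------------------------------
# graph container
# ---------------------------------------------------------------------------
_EDGE_COLUMNS = ["neuron_a", "neuron_b", "weight", "lag", "direction", "is_strong"]


@dataclass
class FunctionalGraph:
    """One functional edge per unordered neuron pair.

    Edges are rows of a DataFrame with columns neuron_a < neuron_b, weight
    (mean trial partial correlation), lag (nonnegative frames), direction
    ('a->b', 'b->a' or 'bidirectional'; bidirectional iff lag == 0) and
    is_strong (pooled top quartile of |weight|, inclusive of ties at the
    75th-percentile magnitude).
    """

    n_neurons: int
    edges: pd.DataFrame
    lag_filter: tuple[int, ...] = (0, 1)
    max_lag: int = 17

    def __post_init__(self):
        self.edges = self.edges.reset_index(drop=True)
        bid = self.edges["direction"] == "bidirectional"
        if not (bid == (self.edges["lag"] == 0)).all():
            raise ValueError("bidirectional edges must be exactly the lag-0 edges")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def strong_threshold(self) -> float:
        return float(np.percentile(np.abs(self.edges["weight"]), 75))

    # -- incoming-weight matrices (Eq-3-style assembly) --------------------
    def _incoming(self, rows: pd.DataFrame) -> np.ndarray:
        """(N, N) matrix W with W[i, k] = weight of edge k -> i."""
        w = np.zeros((self.n_neurons, self.n_neurons))
        a = rows["neuron_a"].to_numpy()
        b = rows["neuron_b"].to_numpy()
        wt = rows["weight"].to_numpy()
        d = rows["direction"].to_numpy()
        fwd = d != "b->a"  # a->b or bidirectional: incoming to b from a
        rev = d != "a->b"  # b->a or bidirectional: incoming to a from b
        # accumulate: estimated graphs have one edge per pair, but permuted
        # graphs may land several strong edges on one directed slot
        np.add.at(w, (b[fwd], a[fwd]), wt[fwd])
        np.add.at(w, (a[rev], b[rev]), wt[rev])
        return w

    def weight_matrix(self, lag: int) -> np.ndarray:
        """Incoming-weight matrix restricted to edges at the given lag.

        Bidirectional (lag 0) edges contribute to both endpoints.
        """
        return self._incoming(self.edges[self.edges["lag"] == lag])

    def sign_matrix(self, sign: int) -> np.ndarray:
        """Incoming weights of the given sign across all lags, treated lag 0."""
        rows = self.edges[np.sign(self.edges["weight"]) == sign]
        return self._incoming(rows)

    # -- strong edges -------------------------------------------------------
    def strong_edges(self) -> pd.DataFrame:
        """Directed enumeration {(source, target, weight, lag)} of strong edges.

        Bidirectional edges appear once, oriented neuron_a -> neuron_b, and
        keep a bidirectional marker; permutation schemes act on this list.
        """
        rows = self.edges[self.edges["is_strong"]]
        src = np.where(rows["direction"] == "b->a", rows["neuron_b"], rows["neuron_a"])
        tgt = np.where(rows["direction"] == "b->a", rows["neuron_a"], rows["neuron_b"])
        return pd.DataFrame(
            {
                "source": src,
                "target": tgt,
                "weight": rows["weight"].to_numpy(),
                "lag": rows["lag"].to_numpy(),
                "edge_index": rows.index.to_numpy(),
            }
        )

    def functional_group(self, target: int) -> set[int]:
        """Sources of all edges directed toward `target` (bidirectional count)."""
        if not 0 <= target < self.n_neurons:
            raise ValueError("target out of range")
        e = self.edges
        inc_from_a = e[(e["neuron_b"] == target) & (e["direction"] != "b->a")]
        inc_from_b = e[(e["neuron_a"] == target) & (e["direction"] != "a->b")]
        return set(inc_from_a["neuron_a"]) | set(inc_from_b["neuron_b"])

    def group_sizes(self) -> np.ndarray:
        w0 = np.zeros((self.n_neurons, self.n_neurons), dtype=bool)
        for lag in sorted(self.edges["lag"].unique()):
            w0 |= self.weight_matrix(int(lag)) != 0
        return w0.sum(axis=1)

    # -- IO -----------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        self.edges[_EDGE_COLUMNS].to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls, path: str | Path, n_neurons: int | None = None,
        lag_filter: tuple[int, ...] = (0, 1), max_lag: int = 17,
    ) -> "FunctionalGraph":
        edges = pd.read_csv(path, sep="\t")
        if n_neurons is None:
            n_neurons = int(max(edges["neuron_a"].max(), edges["neuron_b"].max())) + 1
        return cls(n_neurons=n_neurons, edges=edges, lag_filter=lag_filter, max_lag=max_lag)


def build_functional_graph(
    dataset: FluorescenceDataset,
    max_lag: int = 17,
    lag_filter: tuple[int, ...] = (0, 1),
) -> FunctionalGraph:
    """Estimate the full functional graph of a dataset.

    One edge per unordered pair: weight from the across-trial mean partial
    correlation, lag and direction from the cross-correlogram of block-mean
    traces, strong mask from the pooled top quartile of |weight|.
    """
    n = dataset.n_neurons
    if n < 3:
        raise ValueError("need N >= 3 (population mean excluding the pair)")
    w = pairwise_functional_weights(dataset)
    lags = pairwise_functional_lags(dataset, max_lag=max_lag)
    iu, ju = np.triu_indices(n, k=1)
    signed = lags[iu, ju]
    direction = np.where(signed > 0, "a->b", np.where(signed < 0, "b->a", "bidirectional"))
    weights = w[iu, ju]
    thr = np.percentile(np.abs(weights), 75)
    edges = pd.DataFrame(
        {
            "neuron_a": iu,
            "neuron_b": ju,
            "weight": weights,
            "lag": np.abs(signed),
            "direction": direction,
            "is_strong": np.abs(weights) >= thr,
        }
    )
    return FunctionalGraph(
        n_neurons=n, edges=edges, lag_filter=tuple(lag_filter), max_lag=max_lag
    )


def functional_group(graph: FunctionalGraph, target: int) -> set[int]:
    """Module-level alias for :meth:`FunctionalGraph.functional_group`."""
    return graph.functional_group(target)


class FunctionalGraphEstimator(BaseEstimator):
    """Estimator-style wrapper around :func:`build_functional_graph`.

    Parameters
    ----------
    max_lag : int
        Cross-correlogram scan range in frames (default 17, ~510 ms at 33 Hz).
    lag_filter : tuple of int
        Coupling lags admitted into the encoding-model feature vectors.
    """

    def __init__(self, max_lag: int = 17, lag_filter: tuple[int, ...] = (0, 1)):
        self.max_lag = max_lag
        self.lag_filter = lag_filter

    def fit(self, dataset: FluorescenceDataset, y=None):
        self.graph_ = build_functional_graph(
            dataset, max_lag=self.max_lag, lag_filter=tuple(self.lag_filter)
        )
        self.n_neurons_ = self.graph_.n_neurons
        return self
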