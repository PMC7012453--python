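"""Coupled linear encoding models and the restricted-model ladder.

Each neuron's normalized fluorescence r_i(t) is modeled as a linear
combination of *data-derived* features: the coupling features
W_i0' r(t) and W_i1' r(t-1) (incoming functional weights applied to the
observed population activity; the weights are measured, not fitted), a
stimulus term s(t) and a running term v(t).  The unrestricted model

    r_i(t) = c + b0 * W_i0'r(t) + b1 * W_i1'r(t-1) + Psi*s(t) + Gamma*v(t) + e_t

has 5 free parameters, fitted by least squares on a training split.
Restricted variants drop one term (stimulus-, run-, coupling-restricted),
keep a single coupling lag (LM0 / LM1), or keep a single coupling sign
(LM+ / LM-, all lags treated as lag 0); controls refit with all lags up to
the cross-correlogram maximum, with nonnegative coefficients, or under
reciprocal / cube GLM links.  Each variant's importance is read off the
percent change in test-set MSE relative to the unrestricted model.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import lsq_linear
from statsmodels.genmod.families import links as sm_links
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from ._utils import EmptySubsetError
from .dataset import GREY, N_CONDITIONS, FluorescenceDataset
from .network import FunctionalGraph

logger = logging.getLogger(__name__)

__all__ = [
    "LinearEncoder",
    "EncodingFeatures",
    "ModelComparison",
    "split_frames",
    "infer_tuned",
    "stimulus_term_average_response",
    "stimulus_term_block_averaged",
    "running_term",
    "build_features",
    "subset_mask",
    "evaluate_mse",
    "percent_change_mse",
    "run_model_suite",
    "run_block_averaged_comparison",
    "VARIANTS",
]


# ---------------------------------------------------------------------------
# fitting machinery
# ---------------------------------------------------------------------------
class LinearEncoder(BaseEstimator, RegressorMixin):
    """Least-squares linear encoder with optional sign constraint or GLM link.

    Parameters
    ----------
    nonneg : bool
        Constrain all term coefficients to be >= 0 (the intercept stays
        free: it models baseline fluorescence).
    link : {'identity', 'reciprocal', 'cube'}
        identity: ordinary least squares.  reciprocal: Gaussian GLM with
        1/y = X beta.  cube: Gaussian GLM with y^3 = X beta.  GLM fits use
        iteratively reweighted least squares (statsmodels).
    reciprocal_eps : float
        Floor applied to the linear predictor before inverting under the
        reciprocal link, keeping predictions finite.

    Attributes
    ----------
    coef_ : ndarray of shape (n_features,)
    intercept_ : float
    converged_ : bool
        False if the IRLS fit diverged; coefficients then come from a
        linearized fallback (OLS of g(y) on X) and predictions remain usable.
    rank_ : int
        Rank of the design; a rank-deficient identity fit returns the
        minimum-norm solution (logged).
    """

    def __init__(self, nonneg: bool = False, link: str = "identity",
                 max_iter: int = 100, reciprocal_eps: float = 1e-6):
        self.nonneg = nonneg
        self.link = link
        self.max_iter = max_iter
        self.reciprocal_eps = reciprocal_eps

    # -- link helpers ------------------------------------------------------
    def _invert_link(self, eta: np.ndarray) -> np.ndarray:
        if self.link == "identity":
            return eta
        if self.link == "reciprocal":
            return 1.0 / np.maximum(eta, self.reciprocal_eps)
        if self.link == "cube":
            return np.cbrt(eta)
        raise ValueError(f"unknown link {self.link!r}")

    def _apply_link(self, y: np.ndarray) -> np.ndarray:
        if self.link == "reciprocal":
            return 1.0 / np.where(np.abs(y) < self.reciprocal_eps,
                                  np.sign(y) * self.reciprocal_eps + (y == 0) * self.reciprocal_eps,
                                  y)
        if self.link == "cube":
            return y**3
        return y

    def fit(self, X, y):
        X = check_array(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if len(y) != X.shape[0]:
            raise ValueError("X and y disagree on sample count")
        if X.shape[0] < 2 * (X.shape[1] + 1):
            raise ValueError("need at least 2x more training frames than parameters")
        self.n_features_in_ = X.shape[1]
        self.converged_ = True
        if self.link == "identity" and not self.nonneg:
            a = np.column_stack([np.ones(len(y)), X])
            beta, _, rank, _ = np.linalg.lstsq(a, y, rcond=None)
            self.rank_ = int(rank)
            if rank < a.shape[1]:
                # common benign case: a zero column (no incoming edges at a
                # lag, or a running term that never leaves zero in training)
                logger.debug("rank-deficient design (%d < %d); minimum-norm solution",
                             rank, a.shape[1])
        elif self.link == "identity":
            a = np.column_stack([np.ones(len(y)), X])
            lb = np.r_[-np.inf, np.zeros(X.shape[1])]
            res = lsq_linear(a, y, bounds=(lb, np.full(a.shape[1], np.inf)))
            beta = res.x
            self.rank_ = int(np.linalg.matrix_rank(a))
        else:
            beta = self._fit_glm(X, y)
            self.rank_ = int(np.linalg.matrix_rank(X)) + 1
        self.intercept_ = float(beta[0])
        self.coef_ = np.asarray(beta[1:], dtype=float)
        return self

    def _fit_glm(self, X: np.ndarray, y: np.ndarray) -> np.ndarray:
        import statsmodels.api as sm

        link = (_ReciprocalLink(self.reciprocal_eps) if self.link == "reciprocal"
                else _CubeLink())
        a = sm.add_constant(X, has_constant="add")
        try:
            import warnings

            with np.errstate(all="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore")
                family = sm.families.Gaussian(link=link, check_link=False)
                res = sm.GLM(y, a, family=family).fit(maxiter=self.max_iter)
            params = np.asarray(res.params, dtype=float)
            # a perfect (zero-deviance) fit trips the separation check and
            # clears the convergence flag; the parameters are still exact
            ok = getattr(res, "converged", True) or res.deviance <= 1e-10 * len(y)
            if np.isfinite(params).all() and ok:
                return params
            raise RuntimeError("IRLS did not converge")
        except Exception as err:  # noqa: BLE001 - divergence path is expected
            logger.warning("GLM (%s link) did not converge (%s); linearized fallback",
                           self.link, err)
            self.converged_ = False
            z = self._apply_link(y)
            a = np.column_stack([np.ones(len(y)), X])
            beta, *_ = np.linalg.lstsq(a, z, rcond=None)
            return beta

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X, dtype=float, ensure_all_finite=False)
        eta = self.intercept_ + X @ self.coef_
        return self._invert_link(eta)


class _ReciprocalLink(sm_links.Link):
    """Gaussian-GLM reciprocal link 1/mu with a floored inverse."""

    def __init__(self, eps: float = 1e-6):
        self.eps = eps

    def __call__(self, mu):
        return 1.0 / np.maximum(np.asarray(mu, float), self.eps)

    def inverse(self, z):
        return 1.0 / np.maximum(np.asarray(z, float), self.eps)

    def deriv(self, mu):
        mu = np.maximum(np.asarray(mu, float), self.eps)
        return -1.0 / mu**2

    def inverse_deriv(self, z):
        z = np.maximum(np.asarray(z, float), self.eps)
        return -1.0 / z**2

    def deriv2(self, mu):
        mu = np.maximum(np.asarray(mu, float), self.eps)
        return 2.0 / mu**3


class _CubeLink(sm_links.Link):
    """Gaussian-GLM cube link mu^3, with a sign-safe cube-root inverse."""

    _eps = 1e-8

    def __call__(self, mu):
        return np.asarray(mu, float) ** 3

    def inverse(self, z):
        return np.cbrt(np.asarray(z, float))

    def deriv(self, mu):
        mu = np.asarray(mu, float)
        return 3.0 * np.maximum(mu**2, self._eps)

    def inverse_deriv(self, z):
        z = np.asarray(z, float)
        return 1.0 / (3.0 * np.maximum(np.abs(z) ** (2.0 / 3.0), self._eps))

    def deriv2(self, mu):
        return 6.0 * np.asarray(mu, float)


# ---------------------------------------------------------------------------
# splits and terms
# ---------------------------------------------------------------------------
def split_frames(
    dataset: FluorescenceDataset,
    ratio: float = 0.7,
    granularity: str = "block",
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Partition frames into disjoint, exhaustive train/test sets.

    granularity 'block': whole blocks; round(ratio * n_blocks) train blocks,
    earliest blocks first unless a seed requests a random block order.
    granularity 'presentation': each grating presentation (with its
    preceding grey interval) is one unit; units are allocated per stimulus
    label so a 50/50 split puts equal presentation counts of every label in
    each half.  No presentation straddles the boundary.
    """
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    t = dataset.n_frames
    if granularity == "block":
        b = dataset.n_blocks
        n_train = int(round(ratio * b))
        if n_train < 1 or n_train >= b:
            raise ValueError(f"ratio {ratio} leaves an empty split with {b} blocks")
        order = np.arange(b)
        if seed is not None:
            order = np.random.default_rng(seed).permutation(b)
        train_blocks = set(order[:n_train].tolist())
        train_mask = np.isin(dataset.block_index, list(train_blocks))
    elif granularity == "presentation":
        pres = dataset.presentations()
        if len(pres) < 2:
            raise ValueError("too few presentations to split")
        unit_of_frame = np.empty(t, dtype=int)
        # frames belong to the unit of the next presentation start
        starts = np.array([p.start for p in pres])
        stops = np.array([p.stop for p in pres])
        unit_of_frame[:] = np.searchsorted(stops, np.arange(t), side="right")
        unit_of_frame[unit_of_frame == len(pres)] = len(pres) - 1
        train_units: set[int] = set()
        labels = np.array([p.label for p in pres])
        rng = np.random.default_rng(seed) if seed is not None else None
        for lab in np.unique(labels):
            idx = np.flatnonzero(labels == lab)
            n_train = int(round(ratio * len(idx)))
            n_train = min(max(n_train, 1), len(idx) - 1)
            if rng is not None:
                chosen = rng.choice(idx, size=n_train, replace=False)
            elif abs(ratio - 0.5) < 1e-9:
                chosen = idx[::2][:n_train]  # alternate presentations
            else:
                chosen = idx[:n_train]
            train_units.update(int(u) for u in chosen)
        train_mask = np.isin(unit_of_frame, list(train_units))
    else:
        raise ValueError("granularity must be 'block' or 'presentation'")
    frames = np.arange(t)
    return frames[train_mask], frames[~train_mask]


def infer_tuned(
    dataset: FluorescenceDataset, train_frames: np.ndarray, alpha: float = 0.01
) -> np.ndarray:
    """Surrogate tuning test: one-way ANOVA of per-presentation mean
    responses across the 12 directions on the training split."""
    train = np.zeros(dataset.n_frames, dtype=bool)
    train[train_frames] = True
    groups: list[list[np.ndarray]] = [[] for _ in range(N_CONDITIONS)]
    for p in dataset.presentations():
        sel = train[p.start : p.stop]
        if sel.any():
            groups[p.label].append(
                dataset.traces[:, p.start : p.stop][:, sel].mean(axis=1)
            )
    samples = [np.stack(g, axis=1) for g in groups[1:] if len(g) >= 2]
    if len(samples) < 2:
        raise ValueError("not enough presentations per direction for tuning test")
    tuned = np.zeros(dataset.n_neurons, dtype=bool)
    for i in range(dataset.n_neurons):
        _, pval = stats.f_oneway(*[s[i] for s in samples])
        tuned[i] = np.isfinite(pval) and pval < alpha
    return tuned


def _stim_table(
    dataset: FluorescenceDataset, train_frames: np.ndarray, tuned: np.ndarray
) -> np.ndarray:
    """(N, 13) average-response stimulus values per condition; grey = 0.

    Tuned neurons get their per-direction training mean; untuned neurons a
    single constant, the mean of the 12 per-direction means.  A direction
    absent from training falls back to the untuned constant (logged).
    """
    n = dataset.n_neurons
    table = np.zeros((n, N_CONDITIONS))
    lab = dataset.labels[train_frames]
    tr = dataset.traces[:, train_frames]
    per_dir = np.full((n, 12), np.nan)
    for c in range(1, N_CONDITIONS):
        sel = lab == c
        if sel.any():
            per_dir[:, c - 1] = tr[:, sel].mean(axis=1)
    missing = np.isnan(per_dir[0])
    if missing.any():
        logger.warning("directions %s absent from training; untuned fallback",
                       [30 * (i + 1) for i in np.flatnonzero(missing)])
    untuned_const = np.nanmean(per_dir, axis=1)
    filled = np.where(np.isnan(per_dir), untuned_const[:, None], per_dir)
    table[:, 1:] = np.where(tuned[:, None], filled, untuned_const[:, None])
    return table


def stimulus_term_average_response(
    dataset: FluorescenceDataset,
    neuron: int,
    train_frames: np.ndarray,
    tuned: bool,
) -> np.ndarray:
    """Per-frame average-response stimulus term s(t) for one neuron."""
    flags = np.zeros(dataset.n_neurons, dtype=bool)
    flags[neuron] = tuned
    table = _stim_table(dataset, train_frames, flags)
    return table[neuron, dataset.labels]


def stimulus_term_block_averaged(
    dataset: FluorescenceDataset, neuron: int, frames: np.ndarray
) -> np.ndarray:
    """Block-averaged-trace stimulus term on the grating frames of a split.

    s(t) is the mean, over the split's presentations of the same label, of
    the neuron's fluorescence at the same within-presentation frame offset;
    presentations of unequal length are truncated to the shortest (logged).
    Grey frames and frames outside the split are NaN (excluded from both
    fitting and evaluation under this stimulus model).
    """
    return _block_averaged_terms(dataset, frames)[neuron]


def _block_averaged_terms(dataset: FluorescenceDataset, frames: np.ndarray) -> np.ndarray:
    in_split = np.zeros(dataset.n_frames, dtype=bool)
    in_split[frames] = True
    out = np.full((dataset.n_neurons, dataset.n_frames), np.nan)
    pres = [p for p in dataset.presentations() if in_split[p.start : p.stop].all()]
    for lab in sorted({p.label for p in pres}):
        group = [p for p in pres if p.label == lab]
        lengths = [p.stop - p.start for p in group]
        lmin = min(lengths)
        if len(set(lengths)) > 1:
            logger.warning("unequal presentation lengths for label %d; truncating", lab)
        mean = np.mean(
            [dataset.traces[:, p.start : p.start + lmin] for p in group], axis=0
        )
        for p in group:
            out[:, p.start : p.start + lmin] = mean
    return out


def running_term(
    dataset: FluorescenceDataset,
    model: str = "rotary",
    excluded_neuron: int | None = None,
) -> np.ndarray:
    """Running regressor: the rotary-encoder speed, or the time-varying
    average population response (target neuron excluded)."""
    if model == "rotary":
        return dataset.running_speed.copy()
    if model == "population_average":
        s = dataset.traces.sum(axis=0)
        if excluded_neuron is None:
            return s / dataset.n_neurons
        return (s - dataset.traces[excluded_neuron]) / (dataset.n_neurons - 1)
    raise ValueError("model must be 'rotary' or 'population_average'")


# ---------------------------------------------------------------------------
# feature assembly
# ---------------------------------------------------------------------------
@dataclass
class EncodingFeatures:
    """Per-neuron, per-frame scalar regressors shared by every LM variant."""

    coupling0: np.ndarray  # (N, T): W_i0' r(t)
    coupling1: np.ndarray  # (N, T): W_i1' r(t-1); NaN where undefined
    coupling_pos: np.ndarray  # (N, T): all-lag positive weights at lag 0
    coupling_neg: np.ndarray
    all_lag: dict[int, np.ndarray]  # lag -> (N, T) lagged coupling feature
    stim: np.ndarray  # (N, T) average-response stimulus term
    stim_table: np.ndarray  # (N, 13) condition values behind `stim`
    run: np.ndarray  # (T,) rotary running term
    poprun: np.ndarray  # (N, T) population-average running term (self excluded)
    valid_lag1: np.ndarray  # (T,) frames where the lag-1 feature exists
    valid_all_lag: np.ndarray
    tuned: np.ndarray

    def design(self, variant: str, neuron: int) -> np.ndarray:
        """(T, k) design matrix of the variant's terms for one neuron."""
        cols = []
        for term in VARIANTS[variant].terms:
            if term == "c0":
                cols.append(self.coupling0[neuron])
            elif term == "c1":
                cols.append(self.coupling1[neuron])
            elif term == "cp":
                cols.append(self.coupling_pos[neuron])
            elif term == "cn":
                cols.append(self.coupling_neg[neuron])
            elif term == "stim":
                cols.append(self.stim[neuron])
            elif term == "run":
                cols.append(self.run)
            elif term == "poprun":
                cols.append(self.poprun[neuron])
            elif term.startswith("al"):
                lag = int(term[2:])
                if lag in self.all_lag:  # graphs built with smaller max_lag
                    cols.append(self.all_lag[lag][neuron])
            else:
                raise KeyError(term)
        return np.column_stack(cols)

    def valid_mask(self, variant: str) -> np.ndarray:
        terms = VARIANTS[variant].terms
        if any(t.startswith("al") for t in terms):
            return self.valid_all_lag
        if "c1" in terms:
            return self.valid_lag1
        return np.ones_like(self.valid_lag1)


def _lagged_coupling(
    w: np.ndarray, traces: np.ndarray, lag: int, block_index: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Coupling feature W r(t-lag) and its validity mask (no block crossing)."""
    n, t = traces.shape
    if lag == 0:
        return w @ traces, np.ones(t, dtype=bool)
    shifted = np.zeros_like(traces)
    shifted[:, lag:] = traces[:, :-lag]
    valid = np.zeros(t, dtype=bool)
    valid[lag:] = block_index[lag:] == block_index[:-lag]
    feat = w @ shifted
    feat[:, ~valid] = np.nan
    return feat, valid


def build_features(
    dataset: FluorescenceDataset,
    graph: FunctionalGraph,
    train_frames: np.ndarray,
    tuned: np.ndarray | None = None,
    with_all_lag: bool = False,
) -> EncodingFeatures:
    """Assemble every regressor the model ladder needs.

    The stimulus term uses training-split means only (plug-in on test
    frames); coupling features are linear functionals of the observed
    population activity with measured weights, so they need no fitting.
    """
    if tuned is None:
        tuned = dataset.tuned
    if tuned is None:
        tuned = infer_tuned(dataset, train_frames)
    traces, blocks = dataset.traces, dataset.block_index
    c0, _ = _lagged_coupling(graph.weight_matrix(0), traces, 0, blocks)
    c1, valid1 = _lagged_coupling(graph.weight_matrix(1), traces, 1, blocks)
    if 0 not in graph.lag_filter:
        c0 = np.zeros_like(c0)
    if 1 not in graph.lag_filter:
        c1 = np.zeros_like(c1)
    all_lag: dict[int, np.ndarray] = {}
    valid_all = valid1.copy()
    if with_all_lag:
        for lag in range(graph.max_lag + 1):
            w = graph.weight_matrix(lag)
            feat, valid = _lagged_coupling(w, traces, lag, blocks)
            all_lag[lag] = feat
            valid_all &= valid
    table = _stim_table(dataset, train_frames, tuned)
    popsum = traces.sum(axis=0)
    return EncodingFeatures(
        coupling0=c0,
        coupling1=c1,
        coupling_pos=graph.sign_matrix(1) @ traces,
        coupling_neg=graph.sign_matrix(-1) @ traces,
        all_lag=all_lag,
        stim=table[:, dataset.labels],
        stim_table=table,
        run=dataset.running_speed.copy(),
        poprun=(popsum[None, :] - traces) / (dataset.n_neurons - 1),
        valid_lag1=valid1,
        valid_all_lag=valid_all,
        tuned=np.asarray(tuned, bool),
    )


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------
def subset_mask(
    dataset: FluorescenceDataset, subset: str = "all", run_threshold: float = 0.0
) -> np.ndarray:
    """Frame mask for an evaluation subset.

    'running_only' keeps frames with v(t) > run_threshold (default strictly
    positive); 'first_second_after_onset' keeps the first ceil(frame rate)
    frames of each grating presentation.
    """
    t = dataset.n_frames
    if subset == "all":
        return np.ones(t, dtype=bool)
    if subset == "stimulus_only":
        return dataset.grating_mask()
    if subset == "running_only":
        return dataset.running_speed > run_threshold
    if subset == "first_second_after_onset":
        k = int(np.ceil(dataset.frame_rate_hz))
        mask = np.zeros(t, dtype=bool)
        for p in dataset.presentations():
            mask[p.start : min(p.start + k, p.stop)] = True
        return mask
    raise ValueError(f"unknown subset {subset!r}")


def evaluate_mse(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    frames: np.ndarray,
    mask: np.ndarray | None = None,
) -> float:
    """Mean squared prediction error over frames (optionally intersected
    with a subset mask).  An empty selection raises EmptySubsetError."""
    sel = np.zeros(len(y_true), dtype=bool)
    sel[frames] = True
    if mask is not None:
        sel &= mask
    sel &= np.isfinite(y_pred)
    if not sel.any():
        raise EmptySubsetError("no frames in evaluation subset")
    d = y_true[sel] - y_pred[sel]
    return float(np.mean(d * d))


def percent_change_mse(restricted_mse: float, unrestricted_mse: float) -> float:
    """100 * (restricted - unrestricted) / unrestricted."""
    if not unrestricted_mse > 0:
        raise ValueError("undefined comparison: unrestricted MSE must be > 0")
    return 100.0 * (restricted_mse - unrestricted_mse) / unrestricted_mse


# ---------------------------------------------------------------------------
# the model ladder
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class _Variant:
    terms: tuple[str, ...]
    nonneg: bool = False
    link: str = "identity"
    baseline: str = "unrestricted"
    nested_in_unrestricted: bool = False


_ALL_LAG_TERMS = tuple(f"al{l}" for l in range(18))

VARIANTS: dict[str, _Variant] = {
    "unrestricted": _Variant(("c0", "c1", "stim", "run"), nested_in_unrestricted=True),
    "stim_restricted": _Variant(("c0", "c1", "run"), nested_in_unrestricted=True),
    "run_restricted": _Variant(("c0", "c1", "stim"), nested_in_unrestricted=True),
    "coupling_restricted": _Variant(("stim", "run"), nested_in_unrestricted=True),
    "lm0": _Variant(("c0", "stim", "run"), nested_in_unrestricted=True),
    "lm1": _Variant(("c1", "stim", "run"), nested_in_unrestricted=True),
    "lm_plus": _Variant(("cp", "stim", "run")),
    "lm_minus": _Variant(("cn", "stim", "run")),
    "all_lag": _Variant(_ALL_LAG_TERMS + ("stim", "run")),
    "nonneg": _Variant(("c0", "c1", "stim", "run"), nonneg=True),
    "nonneg_run_restricted": _Variant(("c0", "c1", "stim"), nonneg=True, baseline="nonneg"),
    "reciprocal": _Variant(("c0", "c1", "stim", "run"), link="reciprocal"),
    "cube": _Variant(("c0", "c1", "stim", "run"), link="cube"),
    "poprun": _Variant(("c0", "c1", "stim", "poprun")),
    "poprun_run_restricted": _Variant(("c0", "c1", "stim"), baseline="poprun"),
}

CORE_VARIANTS = (
    "unrestricted", "stim_restricted", "run_restricted", "coupling_restricted",
    "lm0", "lm1", "lm_plus", "lm_minus",
)

SUBSETS = ("all", "stimulus_only", "running_only", "first_second_after_onset")


@dataclass
class ModelComparison:
    """Fitted ladder with per-neuron, per-variant test MSE and % changes."""

    results: pd.DataFrame
    train_frames: np.ndarray
    test_frames: np.ndarray
    models: dict[str, dict[int, LinearEncoder]]
    features: EncodingFeatures
    dataset: FluorescenceDataset = field(repr=False)
    graph: FunctionalGraph = field(repr=False)

    def summary(self) -> pd.DataFrame:
        """Population median and IQR of the percent change, per variant x subset."""
        def iqr(x):
            q1, q3 = np.nanpercentile(x, [25, 75])
            return q3 - q1

        g = self.results.groupby(["variant", "subset"])["pct_change"]
        out = g.agg(median="median", iqr=iqr, n="count").reset_index()
        return out

    def median_pct_change(self, variant: str, subset: str = "all") -> float:
        r = self.results
        sel = (r["variant"] == variant) & (r["subset"] == subset)
        return float(r.loc[sel, "pct_change"].median())


def _fit_variant(
    features: EncodingFeatures,
    responses: np.ndarray,
    variant: str,
    train_frames: np.ndarray,
    neurons: np.ndarray,
) -> tuple[dict[int, LinearEncoder], np.ndarray]:
    spec = VARIANTS[variant]
    n, t = responses.shape
    preds = np.full((n, t), np.nan)
    models: dict[int, LinearEncoder] = {}
    valid = features.valid_mask(variant)
    fit_rows = np.zeros(t, dtype=bool)
    fit_rows[train_frames] = True
    fit_rows &= valid
    for i in neurons:
        x = features.design(variant, i)
        enc = LinearEncoder(nonneg=spec.nonneg, link=spec.link)
        try:
            enc.fit(x[fit_rows], responses[i, fit_rows])
        except Exception as err:  # noqa: BLE001 - recorded, not dropped silently
            logger.warning("variant %s neuron %d failed to fit: %s", variant, i, err)
            continue
        models[i] = enc
        preds[i, valid] = enc.predict(x[valid])
    return models, preds


def run_model_suite(
    dataset: FluorescenceDataset,
    graph: FunctionalGraph,
    variants: tuple[str, ...] | str = CORE_VARIANTS,
    split: tuple[float, str] = (0.7, "block"),
    seed: int | None = None,
    subsets: tuple[str, ...] = ("all",),
    run_threshold: float = 0.0,
) -> ModelComparison:
    """Fit the requested LM variants per neuron and tabulate test-set MSE.

    Every variant is fitted on the same training split and evaluated on the
    same test split; percent changes are taken against the variant's
    baseline model (the unrestricted LM unless noted) evaluated on the same
    frames.  The least-squares nesting property (adding a term never raises
    training MSE) is checked on every run for the nested identity variants.
    """
    if variants == "all":
        variants = tuple(VARIANTS)
    variants = tuple(variants)
    needed = set(variants) | {VARIANTS[v].baseline for v in variants}
    ordered = [v for v in VARIANTS if v in needed]
    train_frames, test_frames = split_frames(dataset, *split, seed=seed)
    features = build_features(
        dataset, graph, train_frames,
        with_all_lag=any("al0" in VARIANTS[v].terms for v in ordered),
    )
    responses = dataset.traces
    neurons = np.arange(dataset.n_neurons)
    models: dict[str, dict[int, LinearEncoder]] = {}
    preds: dict[str, np.ndarray] = {}
    for v in ordered:
        models[v], preds[v] = _fit_variant(features, responses, v, train_frames, neurons)

    _check_nesting(features, responses, models, train_frames)

    masks = {s: subset_mask(dataset, s, run_threshold) for s in subsets}
    rows = []
    for v in variants:
        base = VARIANTS[v].baseline
        valid = features.valid_mask(v) & features.valid_mask(base)
        eval_frames = test_frames[valid[test_frames]]
        for s in subsets:
            if not masks[s][eval_frames].any():
                logger.warning("variant %s: subset %r empty on test frames", v, s)
                rows.extend((i, v, s, np.nan, np.nan, np.nan, base) for i in neurons)
                continue
            for i in neurons:
                if i not in models[v] or i not in models[base]:
                    rows.append((i, v, s, np.nan, np.nan, np.nan, base))
                    continue
                try:
                    mse = evaluate_mse(responses[i], preds[v][i], eval_frames, masks[s])
                    bmse = evaluate_mse(responses[i], preds[base][i], eval_frames, masks[s])
                    pct = percent_change_mse(mse, bmse) if v != base else 0.0
                except (EmptySubsetError, ValueError) as err:
                    logger.warning("neuron %d variant %s subset %s: %s", i, v, s, err)
                    mse = bmse = pct = np.nan
                rows.append((i, v, s, mse, bmse, pct, base))
    results = pd.DataFrame(
        rows,
        columns=["neuron", "variant", "subset", "test_mse", "baseline_mse",
                 "pct_change", "baseline"],
    )
    return ModelComparison(
        results=results,
        train_frames=train_frames,
        test_frames=test_frames,
        models=models,
        features=features,
        dataset=dataset,
        graph=graph,
    )


def _check_nesting(features, responses, models, train_frames) -> None:
    """Unconstrained LS: adding a term can never raise training MSE."""
    if "unrestricted" not in models:
        return
    valid = features.valid_mask("unrestricted")
    rows = np.zeros(responses.shape[1], dtype=bool)
    rows[train_frames] = True
    rows &= valid
    for v, spec in VARIANTS.items():
        if v == "unrestricted" or not spec.nested_in_unrestricted or v not in models:
            continue
        for i, enc in models[v].items():
            if i not in models["unrestricted"]:
                continue
            xr = features.design(v, i)[rows]
            xu = features.design("unrestricted", i)[rows]
            y = responses[i, rows]
            mse_r = float(np.mean((y - enc.predict(xr)) ** 2))
            mse_u = float(np.mean((y - models["unrestricted"][i].predict(xu)) ** 2))
            if mse_u > mse_r + 1e-9 + 1e-9 * mse_r:
                raise RuntimeError(
                    f"nesting violated: unrestricted train MSE {mse_u} > "
                    f"{v} train MSE {mse_r} for neuron {i}"
                )


def run_block_averaged_comparison(
    dataset: FluorescenceDataset,
    graph: FunctionalGraph,
    seed: int | None = None,
) -> pd.DataFrame:
    """Stimulus- and coupling-restricted comparison under the block-averaged
    stimulus model.

    Uses a 50/50 presentation-granularity split so training and testing
    averages pool equal presentation counts; the stimulus regressor is the
    split-specific block-averaged trace; grey frames are excluded from both
    fitting and evaluation.  Returns per-neuron percent changes in test MSE
    on stimulus frames for the stimulus- and coupling-restricted models
    relative to the unrestricted model.
    """
    train_frames, test_frames = split_frames(dataset, 0.5, "presentation", seed=seed)
    stim_train = _block_averaged_terms(dataset, train_frames)
    stim_test = _block_averaged_terms(dataset, test_frames)
    traces, blocks = dataset.traces, dataset.block_index
    c0, _ = _lagged_coupling(graph.weight_matrix(0), traces, 0, blocks)
    c1, valid1 = _lagged_coupling(graph.weight_matrix(1), traces, 1, blocks)
    run = dataset.running_speed

    def designs(stim):
        return {
            "unrestricted": lambda i: np.column_stack([c0[i], c1[i], stim[i], run]),
            "stim_restricted": lambda i: np.column_stack([c0[i], c1[i], run]),
            "coupling_restricted": lambda i: np.column_stack([stim[i], run]),
        }

    d_train, d_test = designs(stim_train), designs(stim_test)
    rows = []
    for i in range(dataset.n_neurons):
        fit_ok = valid1 & np.isfinite(stim_train[i])
        fit_rows = np.zeros(dataset.n_frames, dtype=bool)
        fit_rows[train_frames] = True
        fit_rows &= fit_ok
        ev = np.zeros(dataset.n_frames, dtype=bool)
        ev[test_frames] = True
        ev &= valid1 & np.isfinite(stim_test[i])
        mses = {}
        for v in d_train:
            enc = LinearEncoder().fit(d_train[v](i)[fit_rows], traces[i, fit_rows])
            pred = enc.predict(d_test[v](i)[ev])
            mses[v] = float(np.mean((traces[i, ev] - pred) ** 2))
        for v in ("stim_restricted", "coupling_restricted"):
            rows.append((i, v, mses[v], mses["unrestricted"],
                         percent_change_mse(mses[v], mses["unrestricted"])))
    return pd.DataFrame(
        rows, columns=["neuron", "variant", "test_mse", "baseline_mse", "pct_change"]
    )
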