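"""Bayesian MAP decoding of the stimulus from population activity.

Both decoders put a uniform prior over the 13 conditions (grey + 12
directions) and decode each frame by maximum a posteriori under a Gaussian
likelihood:

- **coupled**: the condition-s mean at frame t is the unrestricted-LM
  prediction with the stimulus term evaluated at candidate s while coupling
  and running terms use the observed data at t; the covariance is the full
  per-condition covariance of the training traces (shrunk toward its
  diagonal for invertibility).
- **uncoupled**: the condition-s mean is the per-neuron stimulus-dependent
  average response and the covariance is diagonal, so the likelihood
  factorizes over neurons (conditional independence).

Decoder quality is summarized by overall accuracy, a row-normalized
confusion matrix (percent of each true condition's frames decoded as each
label), and the plug-in mutual information of the empirical joint of true
and decoded labels, in bits.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.covariance import LedoitWolf
from sklearn.utils.validation import check_is_fitted

from .dataset import N_CONDITIONS, FluorescenceDataset
from .encoding import ModelComparison

logger = logging.getLogger(__name__)

__all__ = [
    "GaussianMAPDecoder",
    "DecoderModel",
    "DecodingResult",
    "fit_coupled_decoder",
    "fit_uncoupled_decoder",
    "decode_map",
    "confusion_and_accuracy",
    "mutual_information",
]

_VAR_FLOOR = 1e-8
_DIAG_LOADING = 1e-8


class GaussianMAPDecoder(BaseEstimator, ClassifierMixin):
    """MAP classifier under per-class Gaussian likelihoods.

    Parameters
    ----------
    covariance : {'full', 'diag'}
        Full per-class covariance (shrunk toward its diagonal with a
        Ledoit-Wolf-style data-driven intensity, plus a small diagonal
        loading) or per-class per-feature variances.
    shrinkage : float or None
        Override the data-driven shrinkage intensity with a fixed value in
        [0, 1]; None (default) estimates it per class.  0 disables
        shrinkage (the diagonal loading is always applied).
    classes : sequence of int, optional
        Required label alphabet; fitting raises if any is absent from y.

    Attributes
    ----------
    classes_ : ndarray
    means_ : ndarray (n_classes, n_features)
    covariances_ : ndarray (n_classes, n_features, n_features) for 'full'
    variances_ : ndarray (n_classes, n_features) for 'diag'
    log_prior_ : ndarray (n_classes,) — uniform prior.

    Ties in the posterior break toward the lowest class index (grey first,
    then ascending direction).
    """

    def __init__(self, covariance: str = "full", shrinkage: float | None = None,
                 classes: tuple[int, ...] | None = None):
        self.covariance = covariance
        self.shrinkage = shrinkage
        self.classes = classes

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        present = np.unique(y)
        if self.classes is not None:
            missing = sorted(set(self.classes) - set(present.tolist()))
            if missing:
                raise ValueError(f"unseen conditions in training data: {missing}")
            self.classes_ = np.asarray(sorted(self.classes))
        else:
            self.classes_ = present
        k, d = len(self.classes_), X.shape[1]
        self.means_ = np.empty((k, d))
        self.log_prior_ = np.full(k, -np.log(k))
        if self.covariance == "full":
            self.covariances_ = np.empty((k, d, d))
            self._chol_ = []
            for idx, c in enumerate(self.classes_):
                xc = X[y == c]
                self.means_[idx] = xc.mean(axis=0)
                self.covariances_[idx] = _shrunk_covariance(xc, self.shrinkage)
                self._chol_.append(np.linalg.cholesky(self.covariances_[idx]))
        elif self.covariance == "diag":
            self.variances_ = np.empty((k, d))
            for idx, c in enumerate(self.classes_):
                xc = X[y == c]
                self.means_[idx] = xc.mean(axis=0)
                v = xc.var(axis=0, ddof=1)
                floored = v < _VAR_FLOOR
                if floored.any():
                    logger.warning("class %s: %d zero-variance cells floored",
                                   c, int(floored.sum()))
                self.variances_[idx] = np.maximum(v, _VAR_FLOOR)
        else:
            raise ValueError("covariance must be 'full' or 'diag'")
        return self

    def _class_log_likelihood(self, X: np.ndarray, idx: int,
                              means: np.ndarray | None = None) -> np.ndarray:
        """Per-frame Gaussian log density under class idx.

        `means` optionally overrides the class mean with a per-frame mean
        matrix of shape (n_frames, n_features) — the coupled decoder's
        time-varying LM mean rule.
        """
        mu = self.means_[idx][None, :] if means is None else means
        resid = X - mu
        if self.covariance == "full":
            chol = self._chol_[idx]
            w = solve_triangular(chol, resid.T, lower=True).T
            logdet = 2.0 * np.sum(np.log(np.diag(chol)))
            quad = np.sum(w * w, axis=1)
        else:
            v = self.variances_[idx]
            logdet = float(np.sum(np.log(v)))
            quad = np.sum(resid * resid / v[None, :], axis=1)
        d = X.shape[1]
        return -0.5 * (quad + logdet + d * np.log(2.0 * np.pi))

    def log_posterior(self, X, means: np.ndarray | None = None) -> np.ndarray:
        """(n_frames, n_classes) unnormalized log posterior.

        `means`, if given, has shape (n_classes, n_frames, n_features).
        """
        check_is_fitted(self, "means_")
        X = np.asarray(X, dtype=float)
        out = np.empty((X.shape[0], len(self.classes_)))
        for idx in range(len(self.classes_)):
            m = None if means is None else means[idx]
            out[:, idx] = self._class_log_likelihood(X, idx, m) + self.log_prior_[idx]
        return out

    def predict(self, X, means: np.ndarray | None = None) -> np.ndarray:
        lp = self.log_posterior(X, means)
        # argmax takes the first maximum: lowest class index wins ties
        labels = self.classes_[np.argmax(lp, axis=1)]
        bad = ~np.isfinite(lp).any(axis=1)
        if bad.any():
            logger.warning("%d frames with non-finite log-posterior flagged", bad.sum())
            labels = labels.copy()
            labels[bad] = -1
        return labels


def _shrunk_covariance(x: np.ndarray, shrinkage: float | None) -> np.ndarray:
    """Sample covariance shrunk toward its diagonal, plus diagonal loading.

    The intensity is the Ledoit-Wolf estimate (data-driven) unless a fixed
    value is given; the target is diag(S) rather than sklearn's scaled
    identity, preserving per-neuron variances.
    """
    s = np.cov(x, rowvar=False)
    s = np.atleast_2d(s)
    if shrinkage is None:
        if x.shape[0] <= x.shape[1]:
            logger.warning("fewer frames (%d) than neurons (%d); shrinkage forced high",
                           x.shape[0], x.shape[1])
        lam = float(LedoitWolf(assume_centered=False).fit(x).shrinkage_)
    else:
        lam = float(shrinkage)
    out = (1.0 - lam) * s + lam * np.diag(np.diag(s))
    out[np.diag_indices_from(out)] += _DIAG_LOADING
    # guard: loading up until Cholesky succeeds (extreme collinearity)
    loading = _DIAG_LOADING
    for _ in range(12):
        try:
            np.linalg.cholesky(out)
            return out
        except np.linalg.LinAlgError:
            loading *= 10.0
            out[np.diag_indices_from(out)] += loading
    raise np.linalg.LinAlgError("covariance could not be conditioned")


# ---------------------------------------------------------------------------
# the two decoders
# ---------------------------------------------------------------------------
@dataclass
class DecoderModel:
    """A fitted decoder: the Gaussian MAP core plus its mean rule."""

    variant: str  # 'coupled' | 'uncoupled'
    core: GaussianMAPDecoder
    dataset: FluorescenceDataset = field(repr=False)
    _mean_fn: object = field(default=None, repr=False)

    def decode(self, frames: np.ndarray) -> np.ndarray:
        x = self.dataset.traces[:, frames].T
        means = None
        if self._mean_fn is not None:
            means = self._mean_fn(frames)
        return self.core.predict(x, means=means)


def fit_coupled_decoder(
    dataset: FluorescenceDataset,
    comparison: ModelComparison,
    train_frames: np.ndarray | None = None,
    shrinkage: float | None = None,
) -> DecoderModel:
    """Coupled Bayesian decoder built on the fitted unrestricted LMs.

    The condition-s mean at frame t substitutes the candidate stimulus value
    into the LM stimulus term while the coupling and running terms use the
    observed activity and speed at t; grey uses a stimulus term of 0.  The
    per-condition covariance is the (shrunk) covariance of the training
    traces during that condition's frames.
    """
    if train_frames is None:
        train_frames = comparison.train_frames
    feats = comparison.features
    models = comparison.models["unrestricted"]
    n, t = dataset.traces.shape
    if len(models) < n:
        raise ValueError("coupled decoder needs an unrestricted LM for every neuron")
    ic = np.array([models[i].intercept_ for i in range(n)])
    coef = np.array([models[i].coef_ for i in range(n)])  # (n, 4): c0 c1 stim run
    # stimulus-independent part of the LM prediction, per neuron and frame
    base = (ic[:, None]
            + coef[:, 0:1] * feats.coupling0
            + coef[:, 1:2] * np.nan_to_num(feats.coupling1)
            + coef[:, 3:4] * feats.run[None, :])
    psi = coef[:, 2]
    stim_table = feats.stim_table  # (n, 13); grey column is 0

    classes = tuple(range(N_CONDITIONS))
    core = GaussianMAPDecoder(covariance="full", shrinkage=shrinkage, classes=classes)
    core.fit(dataset.traces[:, train_frames].T, dataset.labels[train_frames])

    def mean_fn(frames: np.ndarray) -> np.ndarray:
        b = base[:, frames].T  # (T, N)
        return np.stack([b + (psi * stim_table[:, c])[None, :] for c in classes])

    return DecoderModel(variant="coupled", core=core, dataset=dataset, _mean_fn=mean_fn)


def fit_uncoupled_decoder(
    dataset: FluorescenceDataset, train_frames: np.ndarray
) -> DecoderModel:
    """Uncoupled decoder: per-neuron condition means, diagonal covariance."""
    core = GaussianMAPDecoder(covariance="diag", classes=tuple(range(N_CONDITIONS)))
    core.fit(dataset.traces[:, train_frames].T, dataset.labels[train_frames])
    return DecoderModel(variant="uncoupled", core=core, dataset=dataset)


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------
@dataclass
class DecodingResult:
    """Decoded labels with confusion, accuracy and mutual information."""

    decoded: np.ndarray
    true: np.ndarray
    frames: np.ndarray
    confusion: np.ndarray  # (13, 13) row percent; NaN rows for absent conditions
    accuracy: float  # percent
    mutual_information: float  # bits
    joint: np.ndarray  # empirical P(s, s_hat)

    def to_json(self) -> dict:
        return {
            "accuracy_pct": self.accuracy,
            "mutual_information_bits": self.mutual_information,
            "confusion_pct": self.confusion.tolist(),
            "decoded": self.decoded.tolist(),
            "frames": self.frames.tolist(),
        }


def decode_map(
    decoder: DecoderModel,
    dataset: FluorescenceDataset | None = None,
    frames: np.ndarray | str = "all",
) -> DecodingResult:
    """MAP-decode a frame set (default: every frame, training and test).

    Frames whose log-posterior is non-finite are flagged and excluded from
    the confusion / accuracy / information summaries.
    """
    if dataset is None:
        dataset = decoder.dataset
    if isinstance(frames, str):
        if frames != "all":
            raise ValueError("frames must be an index array or 'all'")
        frames = np.arange(dataset.n_frames)
    frames = np.asarray(frames, dtype=int)
    decoded = decoder.decode(frames)
    true = dataset.labels[frames]
    ok = decoded >= 0
    conf, acc = confusion_and_accuracy(true[ok], decoded[ok])
    mi, joint = mutual_information(true[ok], decoded[ok], return_joint=True)
    return DecodingResult(
        decoded=decoded, true=true, frames=frames,
        confusion=conf, accuracy=acc, mutual_information=mi, joint=joint,
    )


def confusion_and_accuracy(
    true_labels: np.ndarray, decoded_labels: np.ndarray
) -> tuple[np.ndarray, float]:
    """Row-normalized percent confusion over the 13 conditions, and overall
    percent accuracy.  Rows of conditions absent from the true labels are
    NaN (undefined)."""
    true_labels = np.asarray(true_labels)
    decoded_labels = np.asarray(decoded_labels)
    if len(true_labels) != len(decoded_labels):
        raise ValueError("label sequences differ in length")
    counts = np.zeros((N_CONDITIONS, N_CONDITIONS))
    for s in range(N_CONDITIONS):
        sel = true_labels == s
        if sel.any():
            counts[s] = np.bincount(decoded_labels[sel], minlength=N_CONDITIONS)[
                :N_CONDITIONS
            ]
    row_sums = counts.sum(axis=1)
    conf = np.full_like(counts, np.nan)
    present = row_sums > 0
    conf[present] = 100.0 * counts[present] / row_sums[present, None]
    accuracy = 100.0 * float(np.mean(decoded_labels == true_labels))
    return conf, accuracy


def mutual_information(
    true_labels: np.ndarray,
    decoded_labels: np.ndarray,
    return_joint: bool = False,
):
    """Plug-in mutual information of true and decoded labels, in bits.

    I = sum_{s, s_hat} P(s, s_hat) log2( P(s, s_hat) / (P(s) P(s_hat)) )
    evaluated on the empirical joint, with 0*log0 := 0.
    """
    true_labels = np.asarray(true_labels)
    decoded_labels = np.asarray(decoded_labels)
    if len(true_labels) == 0:
        raise ValueError("empty label sequences")
    joint = np.zeros((N_CONDITIONS, N_CONDITIONS))
    np.add.at(joint, (true_labels, decoded_labels), 1.0)
    joint /= joint.sum()
    ps = joint.sum(axis=1)
    pd_ = joint.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = joint / (ps[:, None] * pd_[None, :])
        terms = np.where(joint > 0, joint * np.log2(ratio), 0.0)
    mi = float(terms.sum())
    if return_joint:
        return mi, joint
    return mi
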