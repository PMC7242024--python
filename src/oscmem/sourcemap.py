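"""LCMV beamforming and informative-activity mapping.

A linearly constrained minimum-variance (LCMV) filter for grid point m with
lead field l_m and (regularized) sensor covariance C is

    w_m = (l_m^T C^-1 l_m)^-1 l_m^T C^-1,

which has unit gain at its own source (w_m^T l_m = 1).  Classifier weights
w are made interpretable by the activation-pattern transform

    a = Sigma w / (w^T Sigma w),

and "informative activity" at (source m, time t) is |w_m . a_t|: where in
the source grid the decodable signal originates.  Significance of the map
is assessed by re-running the classifier chain under shuffled trial labels
and z-scoring the observed map against the permutation distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthgen import EpochSet, ForwardModel
from .decode import fit_lda


@dataclass
class SpatialFilterSet:
    filters: np.ndarray          # (n_sources, n_channels)
    lam: float                   # regularization, fraction of mean eigenvalue
    cov: np.ndarray              # regularized covariance actually inverted


@dataclass
class InformativeActivityMap:
    z: np.ndarray                # (n_sources, n_times)
    raw: np.ndarray              # absolute informative activity, >= 0
    n_permutations: int
    n_degenerate: int = 0        # cells with zero permutation SD (NaN in z)


def epoch_covariance(epochs: EpochSet) -> np.ndarray:
    """Channel covariance pooled over trials and samples (per-channel means
    removed), the covariance of 'the entire epoch'."""
    x = epochs.data.transpose(1, 0, 2).reshape(epochs.n_channels, -1)
    x = x - x.mean(axis=1, keepdims=True)
    return (x @ x.T) / (x.shape[1] - 1)


def lcmv_filters(fwd: ForwardModel, cov: np.ndarray,
                 lam: float = 0.05) -> SpatialFilterSet:
    """Unit-gain LCMV filters for every grid point.

    ``lam`` scales the diagonal loading as a fraction of the mean
    eigenvalue of ``cov``.
    """
    cov = np.asarray(cov, dtype=float)
    if cov.shape[0] != cov.shape[1] or not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError("covariance must be symmetric")
    if lam < 0:
        raise ValueError("lam must be >= 0")
    d = cov.shape[0]
    c_reg = cov + lam * (np.trace(cov) / d) * np.eye(d)
    try:
        c_inv = np.linalg.inv(c_reg)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "covariance is singular; increase lam") from err
    L = fwd.leadfield
    A = L @ c_inv                         # (n_sources, n_channels)
    denom = np.einsum("sc,sc->s", A, L)
    if np.any(denom <= 0):
        raise np.linalg.LinAlgError("covariance is not positive definite")
    return SpatialFilterSet(filters=A / denom[:, None], lam=lam, cov=c_reg)


def haufe_pattern(w: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Activation pattern a = Sigma w / (w^T Sigma w) of extraction
    weights ``w`` under data covariance ``cov``."""
    w = np.asarray(w, dtype=float)
    cov = np.asarray(cov, dtype=float)
    sw = cov @ w
    denom = float(w @ sw)
    if denom <= 0:
        raise ValueError("w^T Sigma w must be positive")
    return sw / denom


def informative_activity(weights: np.ndarray, cov: np.ndarray,
                         filters: SpatialFilterSet,
                         normalize: bool = False) -> np.ndarray:
    """Raw informative-activity map, (n_sources, n_times), from per-time
    classifier weights (n_times, n_channels): |W . a_t| per source.

    With ``normalize=True`` each activation pattern is scaled to unit norm
    before projection.  The activation-pattern transform is homogeneous of
    degree -1 in the weights (w -> c w maps a -> a/c), so under label
    permutation the near-zero discriminants produce inflated patterns;
    unit-norm patterns make observed and permuted maps comparable, which is
    what the permutation z-scoring needs.
    """
    weights = np.atleast_2d(np.asarray(weights, dtype=float))
    if weights.shape[1] != filters.filters.shape[1]:
        raise ValueError("channel dimension mismatch")
    patterns = np.stack([haufe_pattern(w, cov) for w in weights], axis=1)
    if normalize:
        patterns = patterns / np.linalg.norm(patterns, axis=0, keepdims=True)
    return np.abs(filters.filters @ patterns)     # (n_sources, n_times)


def _fit_weights(X: np.ndarray, labels: np.ndarray, shrinkage) -> np.ndarray:
    """No-CV LDA weights per time point; X is (trials, channels, times)."""
    n_times = X.shape[2]
    w = np.empty((n_times, X.shape[1]))
    for ti in range(n_times):
        w[ti] = fit_lda(X[:, :, ti], labels, shrinkage=shrinkage).weights
    return w


def permutation_zscore(X: np.ndarray, labels: np.ndarray, cov: np.ndarray,
                       filters: SpatialFilterSet, n_perm: int = 500,
                       seed: int | None = None, shrinkage="auto",
                       collapse: bool = False) -> InformativeActivityMap:
    """z-scored informative activity: the classifier + source projection
    chain is re-run ``n_perm`` times with shuffled labels and the observed
    map is z-transformed with the permutation mean and SD per cell.

    ``X`` is (trials, channels, times) restricted to the decoding window.
    With ``collapse=True`` maps are averaged over the time axis *before*
    z-scoring (permuted classifiers are nearly independent across time, so
    collapsing sharpens the null), yielding one z per source.  Cells with
    zero permutation SD become NaN and are counted.
    """
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    labels = np.asarray(labels).astype(bool)

    def one_map(lab):
        m = informative_activity(_fit_weights(X, lab, shrinkage), cov,
                                 filters, normalize=True)
        return m.mean(axis=1, keepdims=True) if collapse else m

    obs = one_map(labels)
    rng = np.random.default_rng(seed)
    mean = np.zeros_like(obs)
    m2 = np.zeros_like(obs)
    for k in range(n_perm):
        pm = one_map(rng.permutation(labels))
        delta = pm - mean
        mean += delta / (k + 1)
        m2 += delta * (pm - mean)
    sd = np.sqrt(m2 / (n_perm - 1))
    degenerate = sd == 0
    z = np.full_like(obs, np.nan)
    np.divide(obs - mean, sd, out=z, where=~degenerate)
    n_bad = int(degenerate.sum())
    if n_bad:
        import warnings
        warnings.warn(f"{n_bad} map cells had zero permutation SD",
                      RuntimeWarning, stacklevel=2)
    return InformativeActivityMap(z=z, raw=obs, n_permutations=n_perm,
                                  n_degenerate=n_bad)


def virtual_sensor(epochs: EpochSet, filters: SpatialFilterSet,
                   source_index: int) -> np.ndarray:
    """Single-trial source time course w_m^T x(trial, t) for one grid
    point; (n_trials, n_samples)."""
    n_sources = filters.filters.shape[0]
    if not 0 <= source_index < n_sources:
        raise IndexError("source index out of range")
    w = filters.filters[source_index]
    return np.einsum("c,nck->nk", w, epochs.data)
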