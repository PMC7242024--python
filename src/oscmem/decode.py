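"""LDA decoding of probe-in-set vs. out-of-set trials.

Implements shrinkage-regularized linear discriminant analysis, rank-based
AUC, per-timepoint ("temporal") decoding with repeated stratified
cross-validation, time generalization (train at every time point on all
trials, test everywhere, score per trial group), the memory-strength proxy
(mean AUC over a train x test sub-block), and band-filtered decoding.

The discriminant is w = S^-1 (mu1 - mu0) with the pooled within-class
covariance shrunk toward a scaled identity,
S = (1 - lambda) S_emp + lambda * trace(S_emp)/d * I; lambda defaults to
the Ledoit-Wolf analytic estimate.  AUC uses the rank (Mann-Whitney)
definition with ties counted 1/2, so flipping all labels maps every AUC
exactly to 1 - AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import RepeatedStratifiedKFold

from .synthgen import EpochSet
from .sigproc import bandlimit, resample_epochs

DECODE_SFREQ = 100.0                      # decoding runs at 100 Hz
PROBE_TRAIN_WINDOW = (0.4, 0.7)           # s after probe, classifier training
PRE_DISTRACTOR_TEST = 0.5                 # s before distractor, test window


# ---------------------------------------------------------------------------
# shrinkage LDA
# ---------------------------------------------------------------------------

@dataclass
class DecoderModel:
    weights: np.ndarray
    bias: float
    shrinkage: float
    train_time: float | tuple | None = None

    def score(self, X: np.ndarray) -> np.ndarray:
        """Discriminant value; higher means more likely class 1."""
        return X @ self.weights + self.bias


def _ledoit_wolf_shrinkage(Xc: np.ndarray) -> float:
    """Analytic Ledoit-Wolf shrinkage intensity for centered data ``Xc``
    (rows are observations), target = trace(S)/d * I."""
    n, d = Xc.shape
    if n == 1:
        return 1.0
    X2 = Xc ** 2
    emp_trace = X2.sum(axis=0) / n
    mu = emp_trace.sum() / d
    delta_ = float(np.sum((Xc.T @ Xc) ** 2)) / n ** 2
    beta_ = float(np.sum(X2.T @ X2))
    beta = (beta_ / n - delta_) / (d * n)
    delta = (delta_ - 2.0 * mu * emp_trace.sum() + d * mu ** 2) / d
    if delta == 0:
        return 0.0
    beta = min(beta, delta)
    return 0.0 if beta <= 0 else float(beta / delta)


def fit_lda(X: np.ndarray, y: np.ndarray, shrinkage="auto",
            train_time=None) -> DecoderModel:
    """Fit a binary shrinkage-LDA; ``y`` holds the two class labels."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite features")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("need exactly two classes in y")
    m0 = (y == classes[0])
    if m0.sum() < 2 or (~m0).sum() < 2:
        raise ValueError("need at least 2 trials per class")
    mu0 = X[m0].mean(axis=0)
    mu1 = X[~m0].mean(axis=0)
    Xc = X.copy()
    Xc[m0] -= mu0
    Xc[~m0] -= mu1
    n, d = Xc.shape
    S = (Xc.T @ Xc) / n
    lam = _ledoit_wolf_shrinkage(Xc) if shrinkage == "auto" else float(shrinkage)
    if not 0.0 <= lam <= 1.0:
        raise ValueError("shrinkage must lie in [0, 1]")
    target = np.trace(S) / d
    S_hat = (1.0 - lam) * S + lam * target * np.eye(d)
    w = np.linalg.solve(S_hat, mu1 - mu0)
    b = -0.5 * float(w @ (mu0 + mu1))
    return DecoderModel(weights=w, bias=b, shrinkage=lam,
                        train_time=train_time)


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC: P(score_1 > score_0) with ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n0 * n1))


def auc_map(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Rank-based AUC over the leading (trial) axis of a score array;
    returns an array of the trailing shape."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores, axis=0)
    u = ranks[labels].sum(axis=0) - n1 * (n1 + 1) / 2.0
    return u / (n0 * n1)


# ---------------------------------------------------------------------------
# cross-validated temporal decoding
# ---------------------------------------------------------------------------

@dataclass
class CVSpec:
    n_folds: int = 5
    n_repeats: int = 5
    stratified: bool = True
    seed: int = 0

    def folds(self, y: np.ndarray) -> list:
        if not self.stratified:
            raise NotImplementedError("only stratified CV is supported")
        rskf = RepeatedStratifiedKFold(n_splits=self.n_folds,
                                       n_repeats=self.n_repeats,
                                       random_state=self.seed)
        return list(rskf.split(np.zeros(len(y)), y))


@dataclass
class TemporalDecodingResult:
    times: np.ndarray           # s (epoch time base)
    auc: np.ndarray             # (n_times,) mean over folds x repeats
    fold_auc: np.ndarray        # (n_splits, n_times)
    full_weights: np.ndarray | None = None    # (n_times, n_channels), no CV
    full_shrinkage: np.ndarray | None = None

    def mean_auc(self, window: tuple[float, float]) -> float:
        m = (self.times >= window[0] - 1e-9) & (self.times <= window[1] + 1e-9)
        return float(self.auc[m].mean())


def _prepare(epochs: EpochSet, decode_sfreq: float | None) -> EpochSet:
    if decode_sfreq is not None and epochs.sfreq > decode_sfreq:
        return resample_epochs(epochs, decode_sfreq)
    return epochs


def temporal_decoding(epochs: EpochSet, labels: np.ndarray,
                      window: tuple[float, float], cv: CVSpec | None = None,
                      shrinkage="auto", decode_sfreq: float | None = DECODE_SFREQ,
                      fit_full: bool = False) -> TemporalDecodingResult:
    """Independent classifier per time sample inside ``window`` (epoch time);
    AUC averaged across folds and repeats."""
    cv = cv or CVSpec()
    labels = np.asarray(labels).astype(bool)
    if len(labels) < cv.n_folds:
        raise ValueError("fewer trials than folds")
    ep = _prepare(epochs, decode_sfreq)
    mask = ep.time_mask(window)
    times = ep.times[mask]
    X = ep.data[:, :, mask]                 # (trials, channels, n_times)
    n_times = times.size
    splits = cv.folds(labels)
    fold_auc = np.empty((len(splits), n_times))
    for si, (tr, te) in enumerate(splits):
        for ti in range(n_times):
            model = fit_lda(X[tr, :, ti], labels[tr], shrinkage=shrinkage)
            fold_auc[si, ti] = auc(model.score(X[te, :, ti]), labels[te])
    full_w = full_lam = None
    if fit_full:
        full_w = np.empty((n_times, ep.n_channels))
        full_lam = np.empty(n_times)
        for ti in range(n_times):
            m = fit_lda(X[:, :, ti], labels, shrinkage=shrinkage,
                        train_time=float(times[ti]))
            full_w[ti] = m.weights
            full_lam[ti] = m.shrinkage
    return TemporalDecodingResult(times=times, auc=fold_auc.mean(axis=0),
                                  fold_auc=fold_auc, full_weights=full_w,
                                  full_shrinkage=full_lam)


# ---------------------------------------------------------------------------
# time generalization and the memory-strength proxy
# ---------------------------------------------------------------------------

@dataclass
class TimeGenResult:
    train_times: np.ndarray
    test_times: np.ndarray
    auc: np.ndarray             # (n_train, n_test); < 0.5 is meaningful
    group: str = "all"
    trained_on: str = "all trials, no cross-validation"


def time_generalization(epochs: EpochSet, labels: np.ndarray,
                        train_window: tuple[float, float],
                        test_window: tuple[float, float],
                        groups: dict | None = None, shrinkage="auto",
                        decode_sfreq: float | None = DECODE_SFREQ,
                        train_mask: np.ndarray | None = None
                        ) -> dict[str, TimeGenResult]:
    """One classifier per train time, fitted on all trials (pooled over
    groups) without cross-validation, scored at every test time; AUC is then
    computed within each group separately.

    ``train_mask`` optionally restricts the training pool (sensitivity
    analysis); scoring still covers all trials of each group.
    """
    labels = np.asarray(labels).astype(bool)
    ep = _prepare(epochs, decode_sfreq)
    tr_mask = ep.time_mask(train_window)
    te_mask = ep.time_mask(test_window)
    train_times = ep.times[tr_mask]
    test_times = ep.times[te_mask]
    Xtr = ep.data[:, :, tr_mask]
    Xte = ep.data[:, :, te_mask]
    pool = np.ones(len(labels), dtype=bool) if train_mask is None \
        else np.asarray(train_mask, dtype=bool)
    if groups is None:
        groups = {"all": np.ones(len(labels), dtype=bool)}
    for name, g in groups.items():
        g = np.asarray(g, dtype=bool)
        if labels[g].all() or not labels[g].any():
            raise ValueError(f"group {name!r} contains a single class")

    n_tr, n_te = train_times.size, test_times.size
    scores = np.empty((len(labels), n_tr, n_te))
    for ti in range(n_tr):
        model = fit_lda(Xtr[pool][:, :, ti], labels[pool],
                        shrinkage=shrinkage, train_time=float(train_times[ti]))
        scores[:, ti, :] = np.einsum("nck,c->nk", Xte, model.weights) + model.bias
    out = {}
    for name, g in groups.items():
        g = np.asarray(g, dtype=bool)
        mat = auc_map(scores[g], labels[g])
        out[name] = TimeGenResult(train_times=train_times,
                                  test_times=test_times, auc=mat, group=name)
    return out


def memory_strength(tg: TimeGenResult,
                    train_window: tuple[float, float],
                    test_window: tuple[float, float]) -> float:
    """Strength of memorized information: mean AUC over the rectangular
    (train x test) sub-block of a time-generalization matrix."""
    trm = (tg.train_times >= train_window[0] - 1e-9) & \
          (tg.train_times <= train_window[1] + 1e-9)
    tem = (tg.test_times >= test_window[0] - 1e-9) & \
          (tg.test_times <= test_window[1] + 1e-9)
    block = tg.auc[np.ix_(trm, tem)]
    if block.size == 0:
        raise ValueError("empty train x test sub-block")
    if np.any(np.isnan(block)):
        raise ValueError("NaN inside the strength sub-block")
    return float(block.mean())


# ---------------------------------------------------------------------------
# band-filtered decoding
# ---------------------------------------------------------------------------

@dataclass
class BandDecodingSpec:
    name: str
    band: tuple[float, float]    # Hz
    transform: str = "real"      # real | analytic_amplitude


DEFAULT_BAND_SPECS = (
    BandDecodingSpec("broadband", (1.0, 30.0), "real"),
    BandDecodingSpec("theta", (1.0, 7.0), "real"),
    BandDecodingSpec("alpha", (9.0, 17.0), "real"),
    BandDecodingSpec("beta", (18.0, 24.0), "real"),
    BandDecodingSpec("broadband_env", (1.0, 30.0), "analytic_amplitude"),
    BandDecodingSpec("theta_env", (1.0, 7.0), "analytic_amplitude"),
)


def band_filtered_decoding(epochs: EpochSet, labels: np.ndarray,
                           window: tuple[float, float],
                           specs=DEFAULT_BAND_SPECS, cv: CVSpec | None = None,
                           shrinkage="auto",
                           decode_sfreq: float | None = DECODE_SFREQ
                           ) -> dict[str, TemporalDecodingResult]:
    """Temporal decoding after band-limiting (and optionally replacing the
    signal by its analytic amplitude), one result per spec."""
    out = {}
    for spec in specs:
        limited = bandlimit(epochs, spec.band, transform=spec.transform)
        out[spec.name] = temporal_decoding(limited, labels, window, cv=cv,
                                           shrinkage=shrinkage,
                                           decode_sfreq=decode_sfreq)
    return out
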