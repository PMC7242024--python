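"""Inferential statistics: t-tests, Cohen's d, critical t values, Pearson
correlation, 2x2 repeated-measures ANOVA, and cluster-based permutation
tests for 1-D, 2-D and graph-connected statistic maps.

The cluster test follows the standard nonparametric recipe for
within-subject contrasts: cell-wise paired/one-sample t statistics are
thresholded at the two-sided critical t (alpha = 0.05 by default), the
supra-threshold cells are grouped into connected clusters separately for
positive and negative signs, each cluster's mass is the sum of its t
values, and the null distribution is the maximal absolute cluster mass
under random sign flips of the per-subject difference maps.  Reported p
values include the observed statistic: p = (1 + #{null >= obs}) / (1 + n).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy import stats as sps
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components


# ---------------------------------------------------------------------------
# elementary tests
# ---------------------------------------------------------------------------

def _t_pvalue(t: float, df: int, sided: str) -> float:
    if sided == "two":
        return float(2.0 * sps.t.sf(abs(t), df))
    if sided == "greater":
        return float(sps.t.sf(t, df))
    if sided == "less":
        return float(sps.t.cdf(t, df))
    raise ValueError(f"unknown sidedness {sided!r}")


def one_sample_t(x, mu: float = 0.0, sided: str = "two"):
    """t, df, p of a one-sample t-test of ``x`` against ``mu``."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two observations")
    d = x - mu
    sd = d.std(ddof=1)
    if sd == 0:
        if np.allclose(d, 0):
            return 0.0, x.size - 1, 1.0 if sided == "two" else 0.5
        raise ValueError("zero variance with nonzero mean")
    t = float(d.mean() / (sd / np.sqrt(x.size)))
    df = x.size - 1
    return t, df, _t_pvalue(t, df, sided)


def paired_t(x, y, sided: str = "two"):
    """Paired t-test; ``sided='less'``/``'greater'`` refer to mean(x - y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    return one_sample_t(x - y, 0.0, sided)


def cohens_d(x, y=None, paired: bool = True) -> float:
    """Paired Cohen's d: mean of differences over their SD."""
    x = np.asarray(x, dtype=float)
    d = x if y is None else x - np.asarray(y, dtype=float)
    if not paired:
        raise NotImplementedError("only the paired/one-sample d is provided")
    sd = d.std(ddof=1)
    if sd == 0:
        if np.allclose(d, d.mean()) and d.mean() == 0:
            return 0.0
        raise ValueError("zero standard deviation")
    return float(d.mean() / sd)


def critical_t(df: int, alpha: float = 0.05, sided: str = "two") -> float:
    """Student-t quantile used as a cluster-forming / reporting threshold."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    q = 1.0 - alpha / 2.0 if sided == "two" else 1.0 - alpha
    return float(sps.t.ppf(q, df))


def pearson(x, y):
    """Product-moment correlation with a two-sided p (t transform, df=n-2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length samples with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# 2x2 repeated-measures ANOVA
# ---------------------------------------------------------------------------

@dataclass
class RmAnovaResult:
    f_a: float
    p_a: float
    f_b: float
    p_b: float
    f_ab: float
    p_ab: float
    df: tuple[int, int]
    factors: tuple[str, str] = ("A", "B")

    def as_dict(self) -> dict:
        a, b = self.factors
        return {a: {"F": self.f_a, "p": self.p_a, "df": list(self.df)},
                b: {"F": self.f_b, "p": self.p_b, "df": list(self.df)},
                f"{a}*{b}": {"F": self.f_ab, "p": self.p_ab,
                             "df": list(self.df)}}


def rm_anova_2x2(values: np.ndarray, factors=("A", "B")) -> RmAnovaResult:
    """Two-way fully within-subject ANOVA for a 2x2 design.

    ``values`` is (n_subjects, 2, 2) indexed as [subject, level of A, level
    of B].  With a single df per effect, each F equals the squared paired t
    of the corresponding within-subject contrast.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 3 or v.shape[1:] != (2, 2):
        raise ValueError("values must be (n_subjects, 2, 2)")
    if np.any(np.isnan(v)):
        raise ValueError("missing cells")
    n = v.shape[0]
    if n < 2:
        raise ValueError("need at least two subjects")
    # within-subject contrasts (each averaged over the other factor)
    con_a = v[:, 1, :].mean(axis=1) - v[:, 0, :].mean(axis=1)
    con_b = v[:, :, 1].mean(axis=1) - v[:, :, 0].mean(axis=1)
    con_ab = (v[:, 1, 1] - v[:, 1, 0]) - (v[:, 0, 1] - v[:, 0, 0])

    def f_of(con):
        # with 1 numerator df, F is exactly the squared paired t; contrast
        # scaling cancels out of the ratio
        sd = con.std(ddof=1)
        if sd == 0:
            return 0.0, 1.0
        t = con.mean() / (sd / np.sqrt(n))
        f = float(t ** 2)
        return f, float(sps.f.sf(f, 1, n - 1))

    f_a, p_a = f_of(con_a)
    f_b, p_b = f_of(con_b)
    f_ab, p_ab = f_of(con_ab)
    return RmAnovaResult(f_a=f_a, p_a=p_a, f_b=f_b, p_b=p_b, f_ab=f_ab,
                         p_ab=p_ab, df=(1, n - 1), factors=tuple(factors))


# ---------------------------------------------------------------------------
# cluster-based permutation test
# ---------------------------------------------------------------------------

@dataclass
class Cluster:
    cells: np.ndarray            # flat indices into the statistic map
    mass: float                  # sum of t values (signed)
    p: float


@dataclass
class ClusterTestResult:
    stat_map: np.ndarray         # t per cell, original shape
    threshold: float             # cluster-forming critical t (two-sided)
    clusters: list = field(default_factory=list)
    mask: np.ndarray | None = None   # cells in clusters with p <= alpha_out
    n_permutations: int = 0

    @property
    def min_p(self) -> float:
        return min((c.p for c in self.clusters), default=1.0)

    def significant(self, alpha: float = 0.05) -> list:
        return [c for c in self.clusters if c.p <= alpha]


def _t_map(data: np.ndarray, sumsq: np.ndarray, signs: np.ndarray
           ) -> np.ndarray:
    """Vectorized one-sample t over cells for sign-flipped subject maps.

    ``data`` is (n_subjects, n_cells); ``signs`` is (n_perm, n_subjects).
    Sign flips leave per-cell sums of squares unchanged, which makes the
    permutation t cheap: only the mean changes.
    """
    n = data.shape[0]
    mean = signs @ data / n
    var = (sumsq - n * mean ** 2) / (n - 1)
    var = np.maximum(var, 1e-300)
    return mean / np.sqrt(var / n)


def _label_lattice(supra: np.ndarray, shape: tuple) -> list[np.ndarray]:
    """Connected components of a boolean lattice map (1-D two-neighbor,
    2-D four-connectivity, ...); returns lists of flat indices."""
    structure = ndimage.generate_binary_structure(len(shape), 1)
    lab, n = ndimage.label(supra.reshape(shape), structure=structure)
    lab = lab.ravel()
    return [np.flatnonzero(lab == k) for k in range(1, n + 1)]


def _label_graph(supra: np.ndarray, adjacency: csr_matrix) -> list[np.ndarray]:
    idx = np.flatnonzero(supra)
    if idx.size == 0:
        return []
    sub = adjacency[idx][:, idx]
    n, lab = connected_components(sub, directed=False)
    return [idx[lab == k] for k in range(n)]


def _clusters_of(tmap: np.ndarray, thr: float, shape, adjacency
                 ) -> list[tuple[np.ndarray, float]]:
    out = []
    for sign in (1.0, -1.0):
        supra = sign * tmap > thr
        comps = (_label_graph(supra, adjacency) if adjacency is not None
                 else _label_lattice(supra, shape))
        out.extend((cells, float(tmap[cells].sum())) for cells in comps)
    return out


def cluster_permutation(data: np.ndarray, y: np.ndarray | None = None,
                        adjacency: csr_matrix | np.ndarray | None = None,
                        n_perm: int = 5000, seed: int | None = None,
                        alpha_cf: float = 0.05, alpha_out: float = 0.05,
                        block: int = 200) -> ClusterTestResult:
    """Cluster-mass permutation test of subject maps against zero.

    ``data`` is (n_subjects, ...) — 1-D, 2-D or flat maps.  For a paired
    contrast pass ``y`` with the same shape; the test then runs on the
    difference maps.  ``adjacency`` (sparse or dense boolean, cells x cells)
    overrides lattice connectivity, e.g. for a source grid.
    """
    x = np.asarray(data, dtype=float)
    if y is not None:
        x = x - np.asarray(y, dtype=float)
    if x.ndim < 2:
        raise ValueError("data must be (n_subjects, cells...)")
    n_subj = x.shape[0]
    if n_subj < 2:
        raise ValueError("need at least two subjects")
    shape = x.shape[1:]
    flat = x.reshape(n_subj, -1)
    n_cells = flat.shape[1]
    if adjacency is not None:
        adjacency = csr_matrix(adjacency)
        if adjacency.shape != (n_cells, n_cells):
            raise ValueError("adjacency does not match the number of cells")
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")

    thr = critical_t(n_subj - 1, alpha_cf, "two")
    sumsq = (flat ** 2).sum(axis=0)
    obs_t = _t_map(flat, sumsq, np.ones((1, n_subj)))[0]
    obs_clusters = _clusters_of(obs_t, thr, shape, adjacency)

    rng = np.random.default_rng(seed)
    null = np.zeros(n_perm)
    done = 0
    while done < n_perm:
        k = min(block, n_perm - done)
        signs = rng.choice([-1.0, 1.0], size=(k, n_subj))
        tmaps = _t_map(flat, sumsq, signs)
        for i in range(k):
            masses = [abs(m) for _, m in
                      _clusters_of(tmaps[i], thr, shape, adjacency)]
            null[done + i] = max(masses, default=0.0)
        done += k

    clusters = []
    for cells, mass in obs_clusters:
        p = float((1 + np.sum(null >= abs(mass))) / (1 + n_perm))
        clusters.append(Cluster(cells=cells, mass=mass, p=p))
    clusters.sort(key=lambda c: c.p)
    mask = np.zeros(n_cells, dtype=bool)
    for c in clusters:
        if c.p <= alpha_out:
            mask[c.cells] = True
    return ClusterTestResult(stat_map=obs_t.reshape(shape), threshold=thr,
                             clusters=clusters, mask=mask.reshape(shape),
                             n_permutations=n_perm)
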