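"""Treatment-difference tests and CAP ordination with LOO classification.

Three statistical layers used to evaluate dose-structured bioassay
endpoints:

* Kruskal-Wallis rank tests with Dunn post-hoc comparisons (Holm
  adjusted) summarised as a compact letter display;
* Spearman rank correlation of each endpoint against the applied dose
  (reported as rho, rho^2 and signed rho^2);
* canonical analysis of principal coordinates (CAP, Anderson & Willis):
  a metric ordination (PCoA) of the between-sample distance matrix
  followed by canonical discriminant analysis on the first m axes, with
  leave-one-out (LOO) allocation of every sample to its nearest group
  centroid in canonical space and a permutation test of the canonical
  trace statistic.  m defaults to the value maximising LOO allocation
  success (smallest m on ties).

Held-out samples are projected onto axes computed *without* them (true
LOO); axes and discriminant space are refitted for every held-out
sample.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.linalg import eigh
from scipy.spatial.distance import cdist, pdist, squareform

__all__ = [
    "CapResult",
    "kruskal_wallis_letters",
    "spearman_dose",
    "cap",
]

_EIG_TOL = 1e-9


# ---------------------------------------------------------------------------
# Kruskal-Wallis with compact letter display


@dataclass
class KruskalResult:
    H: float
    p: float
    letters: dict
    pairwise_p: dict = field(default_factory=dict)
    alpha: float = 0.05


def _dunn_pairwise(values: np.ndarray, groups: np.ndarray,
                   labels: list) -> dict:
    """Two-sided Dunn rank-sum z tests for all group pairs (unadjusted p).

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j))
    with the tie correction T = sum(t^3 - t) / (12 (N - 1)).
    """
    n = values.size
    ranks = stats.rankdata(values)
    _, counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term
    mean_ranks = {g: ranks[groups == g].mean() for g in labels}
    sizes = {g: int((groups == g).sum()) for g in labels}
    out = {}
    for a, b in itertools.combinations(labels, 2):
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        if se == 0:
            out[(a, b)] = 1.0
            continue
        z = (mean_ranks[a] - mean_ranks[b]) / se
        out[(a, b)] = float(2.0 * stats.norm.sf(abs(z)))
    return out


def _holm(pvals: dict) -> dict:
    items = sorted(pvals.items(), key=lambda kv: kv[1])
    m = len(items)
    adj, running = {}, 0.0
    for rank, (pair, p) in enumerate(items):
        running = max(running, min(1.0, (m - rank) * p))
        adj[pair] = running
    return adj


def _compact_letters(labels: list, different: set) -> dict:
    """Letter display: groups not in ``different`` pairs share a letter.

    Letters are the maximal cliques of the not-significantly-different
    graph, ordered by first group occurrence.  Feasible by subset
    enumeration for the handful of treatment groups of a bioassay.
    """
    idx = {g: i for i, g in enumerate(labels)}
    k = len(labels)

    def compatible(subset):
        return all(
            (labels[a], labels[b]) not in different
            and (labels[b], labels[a]) not in different
            for a, b in itertools.combinations(subset, 2)
        )

    cliques = []
    for size in range(k, 0, -1):
        for subset in itertools.combinations(range(k), size):
            if compatible(subset) and not any(
                set(subset) <= set(c) for c in cliques
            ):
                cliques.append(subset)
    cliques.sort(key=lambda c: min(c))
    letters = {g: "" for g in labels}
    for letter_i, clique in enumerate(cliques):
        ch = chr(ord("a") + letter_i)
        for i in clique:
            letters[labels[i]] += ch
    return {g: "".join(sorted(s)) for g, s in letters.items()}


def kruskal_wallis_letters(values, groups, alpha: float = 0.05) -> KruskalResult:
    """Kruskal-Wallis H test with a Dunn/Holm compact letter display.

    When the global test is significant at ``alpha``, pairwise Dunn
    tests with Holm adjustment define which groups differ; groups not
    significantly different share a letter.  Otherwise all groups share
    one letter.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(dict.fromkeys(groups.tolist()))
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    samples = [values[groups == g] for g in labels]
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs at least two observations")
    if np.ptp(values) == 0:
        return KruskalResult(H=0.0, p=1.0,
                             letters={g: "a" for g in labels}, alpha=alpha)
    h, p = stats.kruskal(*samples)
    if p >= alpha:
        return KruskalResult(H=float(h), p=float(p),
                             letters={g: "a" for g in labels}, alpha=alpha)
    raw = _dunn_pairwise(values, groups, labels)
    adj = _holm(raw)
    different = {pair for pair, q in adj.items() if q < alpha}
    letters = _compact_letters(labels, different)
    return KruskalResult(H=float(h), p=float(p), letters=letters,
                         pairwise_p=adj, alpha=alpha)


# ---------------------------------------------------------------------------
# Spearman dose-response correlation


@dataclass
class SpearmanResult:
    rho: float
    rho2: float
    signed_rho2: float
    p: float
    undefined: bool = False


def spearman_dose(values, doses) -> SpearmanResult:
    """Spearman rank correlation of an endpoint against the applied dose.

    Reports rho, rho^2 and the signed rho^2 (the sign of rho carried
    onto rho^2, a convention common in dose-response screening tables).
    Constant input yields an undefined result with a flag.
    """
    values = np.asarray(values, dtype=float)
    doses = np.asarray(doses, dtype=float)
    if values.size != doses.size or values.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(values) == 0 or np.ptp(doses) == 0:
        return SpearmanResult(float("nan"), float("nan"), float("nan"),
                              float("nan"), undefined=True)
    rho, p = stats.spearmanr(values, doses)
    return SpearmanResult(rho=float(rho), rho2=float(rho**2),
                          signed_rho2=float(np.sign(rho) * rho**2),
                          p=float(p))


# ---------------------------------------------------------------------------
# CAP: canonical analysis of principal coordinates


@dataclass
class CapResult:
    """CAP ordination, LOO classification and permutation test summary."""

    eigenvalues: np.ndarray          # PCoA eigenvalues (descending, positive)
    m: int                           # number of PCoA axes used
    m_rule: str
    scores: np.ndarray               # n x m PCoA axis scores (full data)
    canonical_scores: np.ndarray     # n x (g-1) canonical variates
    group_labels: list               # group order of the confusion matrix
    confusion: np.ndarray            # LOO confusion matrix, rows = true group
    accuracy: float                  # overall correct classification, percent
    trace_stat: float
    p_permutation: float
    n_permutations: int
    seed: int
    loo_by_m: dict = field(default_factory=dict)
    ridge_used: bool = False
    n_negative_eigenvalues: int = 0


def _gower_center(d2: np.ndarray) -> np.ndarray:
    n = d2.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    return -0.5 * j @ d2 @ j


def _pcoa(d2: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Eigendecomposition of the Gower-centred matrix.

    Returns positive eigenvalues (descending), the matching orthonormal
    eigenvectors, and the count of meaningfully negative eigenvalues.
    """
    g = _gower_center(d2)
    evals, evecs = eigh((g + g.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    scale = max(abs(evals[0]), 1.0)
    n_neg = int(np.sum(evals < -_EIG_TOL * scale))
    keep = evals > _EIG_TOL * scale
    return evals[keep], evecs[:, keep], n_neg


def _project_new(d2_new: np.ndarray, g_diag: np.ndarray,
                 evecs: np.ndarray, evals: np.ndarray) -> np.ndarray:
    """Project a held-out sample onto existing PCoA axes (Gower add-a-point).

    h_i = -0.5 * ((d2_i - G_ii) - mean_j(d2_j - G_jj)); axis scores are
    h @ q_k / sqrt(lambda_k).
    """
    raw = d2_new - g_diag
    h = -0.5 * (raw - raw.mean())
    return (h @ evecs) / np.sqrt(evals)


class _Cda:
    """Canonical discriminant analysis with nearest-centroid allocation."""

    def __init__(self, scores: np.ndarray, groups: np.ndarray, labels: list):
        self.labels = labels
        self.mean = scores.mean(axis=0)
        x = scores - self.mean
        n, m = x.shape
        mu = {g: x[groups == g].mean(axis=0) for g in labels}
        b = np.zeros((m, m))
        w = np.zeros((m, m))
        for g in labels:
            xg = x[groups == g]
            d = mu[g][None, :]
            b += len(xg) * (d.T @ d)
            r = xg - mu[g]
            w += r.T @ r
        self.ridge_used = False
        try:
            evals, vecs = eigh(b, w)
        except np.linalg.LinAlgError:
            w = w + np.eye(m) * (np.trace(w) / m + 1e-8) * 1e-6
            evals, vecs = eigh(b, w)
            self.ridge_used = True
        if not np.all(np.isfinite(evals)):
            w = w + np.eye(m) * (np.trace(w) / m + 1e-8) * 1e-6
            evals, vecs = eigh(b, w)
            self.ridge_used = True
        order = np.argsort(evals)[::-1]
        n_axes = min(len(labels) - 1, m)
        self.axes = vecs[:, order[:n_axes]]  # W-normalised: V'WV = I
        self.centroids = {g: (mu[g]) @ self.axes for g in labels}

    def transform(self, scores: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(scores) - self.mean) @ self.axes

    def allocate(self, scores: np.ndarray):
        u = self.transform(scores)
        cents = np.array([self.centroids[g] for g in self.labels])
        d = cdist(u, cents)
        return [self.labels[i] for i in np.argmin(d, axis=1)]


def _trace_stat(evecs_m: np.ndarray, groups: np.ndarray, labels: list) -> float:
    """Anderson-Willis canonical trace: tr(Q_m' H Q_m).

    Q_m are the orthonormal PCoA axes, H the hat matrix of the group
    indicator design; equals the sum of squared canonical correlations.
    """
    x = np.zeros((len(groups), len(labels)))
    for j, g in enumerate(labels):
        x[groups == g, j] = 1.0
    hq = x @ np.linalg.solve(x.T @ x, x.T @ evecs_m)
    return float(np.sum(evecs_m * hq))


def _loo_accuracy(d2: np.ndarray, groups: np.ndarray, labels: list,
                  m: int) -> tuple[np.ndarray, bool]:
    """Leave-one-out confusion matrix with axes refit per held-out sample."""
    n = d2.shape[0]
    gidx = {g: i for i, g in enumerate(labels)}
    confusion = np.zeros((len(labels), len(labels)), dtype=int)
    ridge = False
    for i in range(n):
        keep = np.arange(n) != i
        evals, evecs, _ = _pcoa(d2[np.ix_(keep, keep)])
        m_i = min(m, len(evals))
        g_train = _gower_center(d2[np.ix_(keep, keep)])
        scores = evecs[:, :m_i] * np.sqrt(evals[:m_i])
        cda = _Cda(scores, groups[keep], labels)
        ridge |= cda.ridge_used
        new = _project_new(d2[i, keep], np.diag(g_train),
                           evecs[:, :m_i], evals[:m_i])
        pred = cda.allocate(new)[0]
        confusion[gidx[groups[i]], gidx[pred]] += 1
    return confusion, ridge


def cap(
    features,
    groups,
    distance: str = "euclidean",
    m_rule: str = "max_loo",
    m: int | None = None,
    n_perm: int = 9999,
    seed: int = 0,
) -> CapResult:
    """Canonical analysis of principal coordinates with LOO classification.

    Parameters
    ----------
    features : array-like, n_samples x n_features
        Multivariate observations (e.g. raw Kautsky fluorescence samples
        or fatty-acid relative abundances).
    groups : array-like
        Group (treatment) label per sample.
    distance : str
        Any metric accepted by :func:`scipy.spatial.distance.pdist`;
        Euclidean by default.
    m_rule : {"max_loo", "fixed"}
        How many PCoA axes feed the discriminant analysis: maximise the
        LOO allocation success over m (smallest m on ties; the Primer
        heuristic), or use the ``m`` argument as given.
    n_perm : int
        Label permutations for the canonical-trace test.
    seed : int
        RNG seed for the permutation test (always recorded).
    """
    x = np.asarray(features, dtype=float)
    groups = np.asarray(groups)
    if x.ndim != 2:
        raise ValueError("features must be 2-D (samples x features)")
    labels = list(dict.fromkeys(groups.tolist()))
    n, g = x.shape[0], len(labels)
    if g < 2:
        raise ValueError("need at least two groups")
    if n < g + 1:
        raise ValueError("need at least one more sample than groups")
    if m_rule not in ("max_loo", "fixed"):
        raise ValueError("m_rule must be 'max_loo' or 'fixed'")
    if m_rule == "fixed" and (m is None or m < 1):
        raise ValueError("m_rule='fixed' requires a positive m")

    d2 = squareform(pdist(x, metric=distance)) ** 2
    evals, evecs, n_neg = _pcoa(d2)
    if n_neg:
        warnings.warn(f"{n_neg} negative PCoA eigenvalues excluded")
    m_max = max(1, min(len(evals), n - g))

    loo_by_m: dict[int, float] = {}
    ridge = False
    if m_rule == "max_loo":
        best_m, best_conf, best_acc = 1, None, -1.0
        for m_try in range(1, m_max + 1):
            conf, r = _loo_accuracy(d2, groups, labels, m_try)
            ridge |= r
            acc = float(np.trace(conf)) / n * 100.0
            loo_by_m[m_try] = acc
            if acc > best_acc:
                best_m, best_conf, best_acc = m_try, conf, acc
        m_used, confusion = best_m, best_conf
    else:
        m_used = min(m, m_max)
        confusion, ridge = _loo_accuracy(d2, groups, labels, m_used)
        loo_by_m[m_used] = float(np.trace(confusion)) / n * 100.0

    accuracy = float(np.trace(confusion)) / n * 100.0

    scores_full = evecs[:, :m_used] * np.sqrt(evals[:m_used])
    cda_full = _Cda(scores_full, groups, labels)
    canonical = cda_full.transform(scores_full)

    q_m = evecs[:, :m_used]
    obs = _trace_stat(q_m, groups, labels)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _trace_stat(q_m, groups[perm], labels) >= obs - 1e-12:
            exceed += 1
    p_perm = (1 + exceed) / (n_perm + 1)

    return CapResult(
        eigenvalues=evals,
        m=m_used,
        m_rule=m_rule,
        scores=scores_full,
        canonical_scores=canonical,
        group_labels=labels,
        confusion=confusion,
        accuracy=accuracy,
        trace_stat=obs,
        p_permutation=float(p_perm),
        n_permutations=n_perm,
        seed=seed,
        loo_by_m=loo_by_m,
        ridge_used=ridge or cda_full.ridge_used,
        n_negative_eigenvalues=n_neg,
    )
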