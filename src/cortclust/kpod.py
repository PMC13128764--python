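"""k-POD clustering of partially observed matrices.

k-POD is a k-means variant for data with missing entries.  It alternates
(a) completing each missing cell with the corresponding coordinate of the
centroid its row is currently assigned to, and (b) ordinary Lloyd updates
(nearest-centroid assignment, centroid recomputation) on the completed
matrix.  Each full sweep is a majorization-minimization step, so the
completed-data within-cluster sum of squares (WCSS) never increases.

Cluster quality is summarized by the fit-integrity statistic

    fit = 1 - WCSS / TSS,

where TSS is the total sum of squares around the grand mean.  Both sums
are taken over *observed* cells only (with column means and per-cluster
centroid coordinates recomputed from observed cells), so that imputed
values cannot inflate the reported fit; completed-cell accounting is
available behind ``fit_on="imputed"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import kmeans_plusplus
from sklearn.metrics import adjusted_rand_score

logger = logging.getLogger(__name__)

__all__ = [
    "DataMatrix",
    "FitIntegrity",
    "ClusteringResult",
    "ElbowReport",
    "ConvergenceDiagnosis",
    "KPOD",
    "kpod_fit",
    "fit_integrity",
    "elbow_select",
    "diagnose_convergence",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class DataMatrix:
    """n-patients x T-timepoints cortisol matrix with missing cells as NaN.

    Every row must carry at least one observed value; rows with none are
    rejected here and must be dropped (and logged) by the caller.
    """

    values: np.ndarray
    row_ids: Sequence = None
    col_hours: np.ndarray = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, t = self.values.shape
        if self.row_ids is None:
            self.row_ids = list(range(n))
        if self.col_hours is None:
            self.col_hours = np.arange(1, t + 1, dtype=float) * 6.0
        self.col_hours = np.asarray(self.col_hours, dtype=float)
        if len(self.row_ids) != n or len(self.col_hours) != t:
            raise ValueError("row_ids/col_hours do not match matrix shape")
        if not self.mask.any(axis=1).all():
            bad = [self.row_ids[i] for i in np.flatnonzero(~self.mask.any(axis=1))]
            raise ValueError(f"rows with no observed cells: {bad}")

    @property
    def mask(self) -> np.ndarray:
        """Boolean observation mask (True = observed)."""
        return ~np.isnan(self.values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class FitIntegrity:
    tss: float
    wcss: float
    fit: float
    degenerate: bool = False


@dataclass
class ClusteringResult:
    """One clustering solution with its diagnostics."""

    K: int
    assignments: np.ndarray
    centroids: np.ndarray
    overall_mean: np.ndarray
    wcss: float
    tss: float
    fit: float
    n_iter: int
    converged: bool
    restart_agreement: float
    seed: int | None

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.assignments, minlength=self.K)


@dataclass
class ElbowReport:
    k_grid: np.ndarray
    fit_curve: np.ndarray
    selected_k: int | None
    selection_rule: str
    results: dict = field(default_factory=dict, repr=False)


@dataclass(frozen=True)
class ConvergenceDiagnosis:
    converged: bool
    reason: str | None
    restart_agreement: float
    min_cluster_size_seen: int


# ---------------------------------------------------------------------------
# helpers


def _coerce(X) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(X, DataMatrix):
        return X.values.copy(), X.mask.copy()
    values = np.asarray(X, dtype=float)
    if values.ndim != 2:
        raise ValueError("X must be a 2-D matrix")
    mask = ~np.isnan(values)
    if not mask.any(axis=1).all():
        raise ValueError("every row needs at least one observed cell")
    return values.copy(), mask

def _observed_col_means(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    counts = mask.sum(axis=0)
    sums = np.where(mask, values, 0.0).sum(axis=0)
    out = np.divide(sums, counts, out=np.zeros_like(sums), where=counts > 0)
    if (counts == 0).any():
        # a fully missing column carries no information; park it at the grand mean
        out[counts == 0] = values[mask].mean()
    return out


def fit_integrity(X, assignments, *, on: str = "observed") -> FitIntegrity:
    """TSS, WCSS and fit = 1 - WCSS/TSS over observed cells.

    The grand mean and the per-cluster centroids are recomputed as
    observed-cell column means, so the statistic never depends on imputed
    values.  ``on="imputed"`` treats every cell of `X` as observed (useful
    only on completed matrices).  A zero TSS (all observed values equal)
    is degenerate: fit is defined as 1 and flagged.
    """
    values, mask = _coerce(X)
    if on == "imputed":
        mask = np.ones_like(mask)
    elif on != "observed":
        raise ValueError("on must be 'observed' or 'imputed'")
    labels = np.asarray(assignments)
    if labels.shape[0] != values.shape[0]:
        raise ValueError("assignments must cover every row")
    mu = _observed_col_means(values, mask)
    resid = np.where(mask, values - mu, 0.0)
    tss = float((resid**2).sum())
    wcss = 0.0
    for k in np.unique(labels):
        rows = labels == k
        mu_k = _observed_col_means(values[rows], mask[rows])
        r = np.where(mask[rows], values[rows] - mu_k, 0.0)
        wcss += float((r**2).sum())
    if tss <= 0.0:
        return FitIntegrity(tss=tss, wcss=wcss, fit=1.0, degenerate=True)
    fit = 1.0 - wcss / tss
    # guard tiny negative round-off
    fit = min(1.0, max(0.0, fit))
    return FitIntegrity(tss=tss, wcss=wcss, fit=fit, degenerate=False)


# ---------------------------------------------------------------------------
# the alternating completion / Lloyd loop


def _update_centers(Xc: np.ndarray, labels: np.ndarray, K: int) -> np.ndarray:
    sums = np.zeros((K, Xc.shape[1]))
    np.add.at(sums, labels, Xc)
    counts = np.bincount(labels, minlength=K).astype(float)
    return sums / counts[:, None]


def _repair_empty(Xc, centers, labels, K) -> tuple[np.ndarray, int]:
    """Re-seed empty clusters at the point farthest from its centroid.

    The farthest point is force-assigned to the empty cluster (ties on
    duplicate coordinates would otherwise leave it empty again); donors
    reduced to singletons are repaired in subsequent passes, capped to
    guarantee termination."""
    n_reseeds = 0
    labels = labels.copy()
    for _ in range(K + 1):
        present = np.bincount(labels, minlength=K)
        empties = np.flatnonzero(present == 0)
        if empties.size == 0:
            break
        resid = ((Xc - centers[labels]) ** 2).sum(axis=1)
        # a singleton donor would just create a new empty cluster
        resid[np.isin(labels, np.flatnonzero(present == 1))] = -np.inf
        for k in empties:
            far = int(np.argmax(resid))
            centers[k] = Xc[far]
            labels[far] = k
            resid[far] = -np.inf
            n_reseeds += 1
            logger.info("empty cluster %d re-seeded at row %d", k, far)
    return labels, n_reseeds


def _kpod_single(values, mask, centers, max_iter, tol):
    K = centers.shape[0]
    centers = centers.copy()
    # initial completion: assign each row to its nearest center over the
    # row's *observed* coordinates, then fill missing cells from that
    # center.  A column-mean fill would park heavily missing rows at the
    # grand mean and can lock them into the wrong basin before the first
    # sweep; the observed-coordinate assignment uses only real data.
    Xz = np.where(mask, values, 0.0)
    d0 = ((Xz[:, None, :] - centers[None, :, :]) ** 2 * mask[:, None, :]).sum(axis=2)
    labels0 = d0.argmin(axis=1)
    Xc = values.copy()
    Xc[~mask] = centers[labels0][~mask]
    history: list[float] = []
    labels_prev = None
    obj_prev = np.inf
    converged = False
    n_reseeds = 0
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        labels = cdist(Xc, centers, "sqeuclidean").argmin(axis=1)
        if (np.bincount(labels, minlength=K) == 0).any():
            labels, r = _repair_empty(Xc, centers, labels, K)
            n_reseeds += r
        Xc[~mask] = centers[labels][~mask]          # completion (majorization)
        centers = _update_centers(Xc, labels, K)    # Lloyd step (minimization)
        obj = float(((Xc - centers[labels]) ** 2).sum())
        history.append(obj)
        if labels_prev is not None and np.array_equal(labels, labels_prev):
            converged = True
            break
        if obj_prev - obj < tol:
            converged = True
            break
        labels_prev, obj_prev = labels, obj
    # final refill so completed cells sit exactly on their centroid coordinate
    Xc[~mask] = centers[labels][~mask]
    return labels, centers, Xc, history, n_iter, converged, n_reseeds


@dataclass
class _SingleFit:
    labels: np.ndarray
    centers: np.ndarray
    completed: np.ndarray
    history: list
    n_iter: int
    converged: bool
    n_reseeds: int
    fit: float


def _fit_kpod(values, mask, K, n_init, max_iter, tol, seed, fit_on="observed",
              extra_inits=()):
    n, _ = values.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n:
        raise ValueError(f"K={K} exceeds the number of rows ({n})")
    X0 = values.copy()
    col_fill = np.broadcast_to(_observed_col_means(values, mask), values.shape)
    X0[~mask] = col_fill[~mask]

    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(n_init)
    inits = [np.asarray(c, dtype=float) for c in extra_inits]
    for cs in child_seeds:
        centers, _ = kmeans_plusplus(
            X0, K, random_state=np.random.RandomState(int(cs) % (2**31))
        )
        inits.append(centers)

    runs: list[_SingleFit] = []
    for centers in inits:
        labels, cen, Xc, hist, it, conv, resee = _kpod_single(
            values, mask, centers, max_iter, tol
        )
        X_eval = Xc if fit_on == "imputed" else values
        fi = fit_integrity(X_eval, labels, on=fit_on)
        runs.append(_SingleFit(labels, cen, Xc, hist, it, conv, resee, fi.fit))
    best = max(range(len(runs)), key=lambda i: (runs[i].fit, -i))
    return runs, best


# ---------------------------------------------------------------------------
# estimator


class KPOD(ClusterMixin, BaseEstimator):
    """k-means clustering robust to missing data (k-POD).

    Parameters
    ----------
    n_clusters : int, default=3
        Number of clusters K.
    n_init : int, default=25
        Number of k-means++ restarts; the restart with the best
        fit-integrity wins.
    max_iter : int, default=200
        Maximum alternating completion/Lloyd sweeps per restart.
    tol : float, default=1e-6
        Stop a restart when the completed-data WCSS decreases by less
        than this (assignment stability also stops it).
    fit_on : {"observed", "imputed"}, default="observed"
        Whether ``wcss_``/``tss_``/``fit_`` are accounted over observed
        cells only or over the completed matrix.
    random_state : int or None
        Seed for the restart initializations.

    Attributes
    ----------
    labels_ : (n,) cluster index per row.
    cluster_centers_ : (K, T) completed-data centroids of the best restart.
    completed_data_ : (n, T) matrix with missing cells set to their
        assigned centroid's coordinates.
    wcss_, tss_, fit_ : fit-integrity accounting (see ``fit_on``).
    inertia_ : completed-data WCSS of the best restart.
    objective_history_ : per-sweep completed-data WCSS of the best restart.
    n_iter_, converged_ : inner-loop diagnostics of the best restart.
    restart_labels_ : final labelings of every restart.
    restart_agreement_ : mean pairwise adjusted Rand index across restarts.
    n_reseeds_ : empty-cluster repairs performed in the best restart.
    """

    def __init__(self, n_clusters: int = 3, *, n_init: int = 25,
                 max_iter: int = 200, tol: float = 1e-6,
                 fit_on: str = "observed", random_state: int | None = None):
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.max_iter = max_iter
        self.tol = tol
        self.fit_on = fit_on
        self.random_state = random_state

    def fit(self, X, y=None):
        values, mask = _coerce(X)
        runs, best = _fit_kpod(
            values, mask, self.n_clusters, self.n_init, self.max_iter,
            self.tol, self.random_state, fit_on=self.fit_on,
        )
        b = runs[best]
        self.n_features_in_ = values.shape[1]
        self.labels_ = b.labels
        self.cluster_centers_ = b.centers
        self.completed_data_ = b.completed
        self.objective_history_ = list(b.history)
        self.inertia_ = b.history[-1] if b.history else 0.0
        self.n_iter_ = b.n_iter
        self.n_reseeds_ = b.n_reseeds
        self.converged_ = bool(
            b.converged and (np.bincount(b.labels, minlength=self.n_clusters) > 0).all()
        )
        X_eval = b.completed if self.fit_on == "imputed" else values
        fi = fit_integrity(X_eval, b.labels, on=self.fit_on)
        self.wcss_, self.tss_, self.fit_ = fi.wcss, fi.tss, fi.fit
        self.fit_degenerate_ = fi.degenerate
        self.restart_labels_ = [r.labels for r in runs]
        self.restart_fits_ = np.array([r.fit for r in runs])
        self.restart_agreement_ = _pairwise_agreement(self.restart_labels_)
        self.overall_mean_ = _observed_col_means(values, mask)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    def predict(self, X):
        """Assign rows to the nearest centroid over their observed coordinates."""
        values, mask = _coerce(X)
        out = np.empty(values.shape[0], dtype=int)
        for i in range(values.shape[0]):
            m = mask[i]
            d = ((self.cluster_centers_[:, m] - values[i, m]) ** 2).sum(axis=1)
            out[i] = int(np.argmin(d))
        return out

    def result(self, seed: int | None = None) -> ClusteringResult:
        """Bundle the fitted state into a :class:`ClusteringResult`."""
        return ClusteringResult(
            K=self.n_clusters,
            assignments=self.labels_,
            centroids=self.cluster_centers_,
            overall_mean=self.overall_mean_,
            wcss=self.wcss_,
            tss=self.tss_,
            fit=self.fit_,
            n_iter=self.n_iter_,
            converged=self.converged_,
            restart_agreement=self.restart_agreement_,
            seed=self.random_state if seed is None else seed,
        )


def _pairwise_agreement(labelings: Sequence[np.ndarray]) -> float:
    if len(labelings) < 2:
        return 1.0
    scores = [
        adjusted_rand_score(a, b) for a, b in combinations(labelings, 2)
    ]
    return float(np.mean(scores))


def kpod_fit(X, K: int, n_restarts: int = 25, max_iter: int = 200,
             tol: float = 1e-6, seed: int | None = None) -> ClusteringResult:
    """Functional wrapper around :class:`KPOD`."""
    est = KPOD(n_clusters=K, n_init=n_restarts, max_iter=max_iter,
               tol=tol, random_state=seed).fit(X)
    return est.result()


# ---------------------------------------------------------------------------
# elbow selection


def elbow_select(X, k_grid=tuple(range(1, 7)), n_restarts: int = 25,
                 seed: int | None = None, max_iter: int = 200,
                 tol: float = 1e-6) -> ElbowReport:
    """Fit-integrity curve over a K grid and elbow-based K choice.

    The elbow is automated as the interior K maximizing the curve's
    curvature (2 f_K - f_{K-1} - f_{K+1}) — the point where the marginal
    gain of one more cluster drops the most — with ties broken toward
    smaller K.  Two refinements over the naive rule: (i) if some K
    already attains the curve's maximum fit (within 1e-9), the smallest
    such K is returned (a zero-spread plateau needs no curvature); and
    (ii) the K=1 point is excluded from the curvature computation
    whenever enough candidates remain, because fit(1) = 0 identically,
    so the 1->2 jump measures the overall scale of the data rather than
    cluster structure and would otherwise absorb the elbow for any
    structured input.  The full curve is reported so a human can inspect
    it or override the choice.  Each K's restarts include a warm start
    from the previous K's solution plus its farthest point, which keeps
    the best-restart curve non-decreasing in K.
    """
    values, mask = _coerce(X)
    k_grid = np.asarray(sorted(int(k) for k in k_grid))
    if k_grid[0] < 1:
        raise ValueError("k_grid entries must be >= 1")
    fits = []
    results = {}
    prev_best: _SingleFit | None = None
    for K in k_grid:
        extra = []
        if prev_best is not None and prev_best.centers.shape[0] == K - 1:
            resid = ((prev_best.completed - prev_best.centers[prev_best.labels]) ** 2).sum(axis=1)
            far = prev_best.completed[int(np.argmax(resid))]
            extra.append(np.vstack([prev_best.centers, far]))
        runs, best = _fit_kpod(values, mask, int(K), n_restarts, max_iter,
                               tol, seed, extra_inits=extra)
        prev_best = runs[best]
        fits.append(runs[best].fit)
        results[int(K)] = runs[best]
    fits = np.asarray(fits)
    if len(k_grid) < 3:
        return ElbowReport(k_grid, fits, None, "curve_only", results)
    at_max = np.flatnonzero(fits >= fits.max() - 1e-9)
    if at_max[0] < len(k_grid) - 1:
        return ElbowReport(k_grid, fits, int(k_grid[at_max[0]]),
                           "smallest_k_at_max_fit", results)
    start = 1 if (k_grid[0] == 1 and len(k_grid) >= 4) else 0
    kk, ff = k_grid[start:], fits[start:]
    curvature = 2 * ff[1:-1] - ff[:-2] - ff[2:]
    sel = int(kk[1 + int(np.argmax(curvature))])  # argmax keeps first tie => smaller K
    return ElbowReport(k_grid, fits, sel, "max_curvature", results)


# ---------------------------------------------------------------------------
# convergence diagnostics


def diagnose_convergence(results, min_cluster_size: int = 3,
                         agreement_threshold: float = 0.45,
                         n_clusters: int | None = None) -> ConvergenceDiagnosis:
    """Declare a clustering non-converged when restarts disagree or clusters
    are too small for the sample size.

    ``results`` is a list of :class:`ClusteringResult` or of raw label
    arrays (e.g. ``KPOD.restart_labels_``).  Failure modes, checked in
    order: ``insufficient_sample`` (n < K * min_cluster_size),
    ``small_cluster`` (any cluster of the first/best result below
    ``min_cluster_size``), ``unstable_restarts`` (mean pairwise adjusted
    Rand index across the restart partitions below
    ``agreement_threshold``).  The adjusted index is used because the
    plain Rand index saturates near 1 regardless of structure; the 0.45
    default separates the stable three-cluster regime from homogeneous
    small-sample cohorts, where restarts land on essentially arbitrary
    partitions (see the methods note for the calibration).
    """
    if len(results) < 2:
        raise ValueError("need at least two restarts to diagnose")
    labelings = [
        np.asarray(r.assignments if isinstance(r, ClusteringResult) else r)
        for r in results
    ]
    if n_clusters is None:
        if isinstance(results[0], ClusteringResult):
            n_clusters = results[0].K
        else:
            n_clusters = int(max(l.max() for l in labelings)) + 1
    n = labelings[0].shape[0]
    sizes = np.bincount(labelings[0], minlength=n_clusters)
    agreement = _pairwise_agreement(labelings)
    if n < n_clusters * min_cluster_size:
        return ConvergenceDiagnosis(False, "insufficient_sample", agreement, int(sizes.min()))
    if sizes.min() < min_cluster_size:
        return ConvergenceDiagnosis(False, "small_cluster", agreement, int(sizes.min()))
    if agreement < agreement_threshold:
        return ConvergenceDiagnosis(False, "unstable_restarts", agreement, int(sizes.min()))
    return ConvergenceDiagnosis(True, None, agreement, int(sizes.min()))
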