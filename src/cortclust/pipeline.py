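"""End-to-end trajectory phenotyping procedure.

Raw 6-hourly cortisol measurements are binned to the grid, values after
replacement-steroid administration are discarded, and patients are
clustered twice: a first k-POD pass over the full follow-up matrix, a
per-timepoint one-way ANOVA across the pass-1 clusters, and a second
pass restricted to the continuous early window over which the clusters
separate significantly.  Trajectory features (initial 6 h cortisol,
nadir, descent velocity between 6 h and 18 h) are derived per patient
after censoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .cohort import Cohort, CortisolTrajectory, FULL_GRID
from .kpod import (
    KPOD, ClusteringResult, DataMatrix, ElbowReport, diagnose_convergence,
    elbow_select,
)
from .stats import TestResult, apply_alpha_policy

logger = logging.getLogger(__name__)

__all__ = [
    "TrajectoryFeatures",
    "WindowSelection",
    "TimepointTest",
    "NonConvergenceError",
    "bin_to_grid",
    "censor_after_steroids",
    "derive_features",
    "compare_timepoints",
    "select_window",
    "two_pass_cluster",
    "add_trajectory_features",
    "TwoPassTrajectoryClusterer",
]


@dataclass(frozen=True)
class TrajectoryFeatures:
    """Scalar summaries of one censored trajectory (NaN = underivable)."""

    initial_cortisol: float      # cortisol at 6 h, mcg/dL
    nadir_cortisol: float        # min observed value in the window, mcg/dL
    descent_velocity: float      # (c(6h) - c(18h)) / 12, mcg/dL/h; >0 = decline


@dataclass
class WindowSelection:
    """Contiguous grid run of significant cluster separation."""

    timepoints: np.ndarray
    per_timepoint_p: np.ndarray
    rule: str
    adjusted_alpha: float = np.nan

    @property
    def empty(self) -> bool:
        return len(self.timepoints) == 0


@dataclass
class TimepointTest:
    hour: float
    p_value: float
    statistic: float
    group_means: tuple
    group_sds: tuple
    group_ns: tuple
    skipped: bool = False
    note: str = ""

    def as_test_result(self) -> TestResult:
        return TestResult(
            variable=f"cortisol_{self.hour:g}h", test_kind="anova",
            statistic=self.statistic, p_value=self.p_value,
            group_summaries=[{"mean": m, "sd": s, "n": n} for m, s, n in
                             zip(self.group_means, self.group_sds, self.group_ns)],
            n_per_group=self.group_ns, degenerate=self.skipped, note=self.note,
        )


class NonConvergenceError(RuntimeError):
    """Pass-1 clustering judged unstable for this sample."""

    def __init__(self, diagnosis):
        self.diagnosis = diagnosis
        super().__init__(f"clustering failed to converge: {diagnosis.reason} "
                         f"(restart agreement {diagnosis.restart_agreement:.3f})")


# ---------------------------------------------------------------------------
# binning / censoring / features


def bin_to_grid(times, values, grid=FULL_GRID, patient_id: str = "p0",
                half_width: float = 3.0) -> CortisolTrajectory:
    """Assign raw measurements to the nearest grid point within
    [t - half_width, t + half_width); multiple hits are averaged and
    unmatched measurements dropped with a log line."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if (times < 0).any():
        raise ValueError("measurement times must be non-negative hours post-op")
    grid = np.asarray(grid, dtype=float)
    sums = np.zeros(grid.size)
    counts = np.zeros(grid.size, dtype=int)
    dropped = 0
    lower_edges = grid - half_width
    for t, v in zip(times, values):
        # half-open bins [g - hw, g + hw): a boundary time belongs upward
        j = int(np.searchsorted(lower_edges, t, side="right")) - 1
        if j >= 0 and lower_edges[j] <= t < grid[j] + half_width:
            sums[j] += v
            counts[j] += 1
        else:
            dropped += 1
    if dropped:
        logger.info("patient %s: dropped %d measurements outside the grid",
                    patient_id, dropped)
    out = np.full(grid.size, np.nan)
    obs = counts > 0
    out[obs] = sums[obs] / counts[obs]
    return CortisolTrajectory(patient_id, out, obs, None, tuple(grid))


def censor_after_steroids(trajectory: CortisolTrajectory,
                          steroid_time: float | None) -> CortisolTrajectory:
    """Discard every value strictly after replacement steroids started."""
    if steroid_time is None:
        return trajectory
    grid = np.asarray(trajectory.grid)
    mask = trajectory.observed_mask & (grid <= steroid_time)
    return CortisolTrajectory(trajectory.patient_id, trajectory.values, mask,
                              steroid_time, trajectory.grid)


def derive_features(trajectory: CortisolTrajectory,
                    window: tuple = (6.0, 36.0)) -> TrajectoryFeatures:
    """Initial cortisol (6 h), nadir over the window, and the 6-18 h
    descent velocity; each NaN when its inputs are unobserved."""
    grid = np.asarray(trajectory.grid)
    vals = trajectory.values
    obs = trajectory.observed_mask
    in_window = (grid >= window[0]) & (grid <= window[1]) & obs
    nadir = float(np.min(vals[in_window])) if in_window.any() else np.nan

    def at(hour):
        idx = np.flatnonzero((grid == hour) & obs)
        return float(vals[idx[0]]) if idx.size else np.nan

    c6, c18 = at(6.0), at(18.0)
    velocity = (c6 - c18) / 12.0 if not (np.isnan(c6) or np.isnan(c18)) else np.nan
    return TrajectoryFeatures(c6, nadir, velocity)


def add_trajectory_features(covariates: pd.DataFrame, trajectories,
                            window: tuple = (6.0, 36.0)) -> pd.DataFrame:
    """Join derived trajectory features onto the covariate table."""
    feats = [derive_features(t, window) for t in trajectories]
    out = covariates.copy()
    out["initial_cortisol"] = [f.initial_cortisol for f in feats]
    out["nadir_cortisol"] = [f.nadir_cortisol for f in feats]
    out["descent_velocity"] = [f.descent_velocity for f in feats]
    return out


# ---------------------------------------------------------------------------
# per-timepoint comparison and window selection


def compare_timepoints(matrix: DataMatrix, assignments) -> list[TimepointTest]:
    """One-way ANOVA on the observed values at each grid point, grouped by
    cluster; group moments are reported alongside each p-value.

    A timepoint with fewer than two groups holding >= 2 observations is
    skipped and flagged; a timepoint where every observed value is equal
    is degenerate (p = 1)."""
    labels = np.asarray(assignments)
    values, mask = matrix.values, matrix.mask
    tests = []
    for j, hour in enumerate(np.asarray(matrix.col_hours, dtype=float)):
        groups, means, sds, ns = [], [], [], []
        for g in np.unique(labels):
            v = values[(labels == g) & mask[:, j], j]
            means.append(float(v.mean()) if v.size else np.nan)
            sds.append(float(v.std(ddof=1)) if v.size > 1 else np.nan)
            ns.append(int(v.size))
            if v.size >= 2:
                groups.append(v)
        if len(groups) < 2:
            tests.append(TimepointTest(hour, np.nan, np.nan, tuple(means),
                                       tuple(sds), tuple(ns), skipped=True,
                                       note="fewer than two groups with n >= 2"))
            continue
        allv = np.concatenate(groups)
        if np.ptp(allv) == 0.0:
            tests.append(TimepointTest(hour, 1.0, 0.0, tuple(means),
                                       tuple(sds), tuple(ns),
                                       note="all observed values identical"))
            continue
        from .stats import oneway_anova
        r = oneway_anova(groups)
        tests.append(TimepointTest(hour, r.p_value, r.statistic, tuple(means),
                                   tuple(sds), tuple(ns), note=r.note))
    return tests


def select_window(tests, alpha_policy: str = "bh", q: float = 0.05) -> WindowSelection:
    """Maximal run of consecutive significant grid points starting at the
    earliest significant one (skipped timepoints break the run)."""
    hours = np.array([t.hour for t in tests])
    p = np.array([t.p_value for t in tests])
    flags, alpha = apply_alpha_policy(p, policy=alpha_policy, q=q)
    sig = np.flatnonzero(flags)
    if sig.size == 0:
        return WindowSelection(hours[:0], p, "earliest_significant_run", alpha)
    start = int(sig[0])
    end = start
    while end + 1 < len(tests) and flags[end + 1]:
        end += 1
    return WindowSelection(hours[start:end + 1], p,
                           "earliest_significant_run", alpha)


# ---------------------------------------------------------------------------
# two-pass clustering


class TwoPassTrajectoryClusterer(BaseEstimator):
    """Two-pass k-POD phenotyping of incomplete cortisol trajectories.

    Pass 1 clusters the full follow-up matrix (K elbow-selected unless
    fixed); per-timepoint ANOVAs across the pass-1 clusters define the
    continuous window of significant separation; pass 2 re-runs k-POD
    at the same K restricted to the window's columns.

    Parameters
    ----------
    k : "auto" or int
        Elbow-selected K over ``k_grid``, or a fixed K.
    k_grid : iterable of int
        Candidate K values for the elbow.
    alpha_policy : "bh" | "bonferroni" | "fixed:<x>"
        Significance rule for the per-timepoint tests.
    q : float
        FDR level (or family alpha) fed to the policy.
    n_init, max_iter, tol, random_state
        Passed to the underlying k-POD fits; both passes share
        ``random_state`` so identical column sets give identical fits.
    check_convergence : bool
        When True (default), raise :class:`NonConvergenceError` if the
        pass-1 restarts are unstable or clusters degenerate — the small
        homogeneous non-remission group exercises this path.
    """

    def __init__(self, k="auto", *, k_grid=tuple(range(1, 7)),
                 alpha_policy: str = "bh", q: float = 0.05, n_init: int = 25,
                 max_iter: int = 200, tol: float = 1e-6,
                 min_cluster_size: int = 3, agreement_threshold: float = 0.45,
                 check_convergence: bool = True,
                 random_state: int | None = None):
        self.k = k
        self.k_grid = k_grid
        self.alpha_policy = alpha_policy
        self.q = q
        self.n_init = n_init
        self.max_iter = max_iter
        self.tol = tol
        self.min_cluster_size = min_cluster_size
        self.agreement_threshold = agreement_threshold
        self.check_convergence = check_convergence
        self.random_state = random_state

    def fit(self, X, y=None):
        matrix = X if isinstance(X, DataMatrix) else DataMatrix(np.asarray(X, dtype=float))

        if self.k == "auto":
            self.elbow_report_ = elbow_select(
                matrix, k_grid=self.k_grid, n_restarts=self.n_init,
                seed=self.random_state, max_iter=self.max_iter, tol=self.tol)
            K = self.elbow_report_.selected_k
            if K is None:
                raise ValueError("k_grid too short for elbow selection; pass k explicitly")
        else:
            self.elbow_report_ = None
            K = int(self.k)

        pass1 = KPOD(n_clusters=K, n_init=self.n_init, max_iter=self.max_iter,
                     tol=self.tol, random_state=self.random_state).fit(matrix)
        self.pass1_ = pass1.result()
        self.diagnosis_ = diagnose_convergence(
            pass1.restart_labels_, min_cluster_size=self.min_cluster_size,
            agreement_threshold=self.agreement_threshold, n_clusters=K)
        if self.check_convergence and not self.diagnosis_.converged:
            raise NonConvergenceError(self.diagnosis_)

        self.timepoint_tests_ = compare_timepoints(matrix, pass1.labels_)
        self.window_ = select_window(self.timepoint_tests_,
                                     alpha_policy=self.alpha_policy, q=self.q)

        if self.window_.empty:
            logger.info("no significant separation at any timepoint; pass 2 skipped")
            self.pass2_ = None
            self.labels_ = pass1.labels_
            return self

        cols = np.isin(np.asarray(matrix.col_hours, dtype=float), self.window_.timepoints)
        sub_values = matrix.values[:, cols]
        keep = ~np.isnan(sub_values).all(axis=1)
        if not keep.all():
            logger.info("pass 2: %d patients have no observed value inside the "
                        "window and keep label -1", int((~keep).sum()))
        sub = DataMatrix(sub_values[keep],
                         row_ids=[matrix.row_ids[i] for i in np.flatnonzero(keep)],
                         col_hours=np.asarray(matrix.col_hours)[cols])
        pass2 = KPOD(n_clusters=K, n_init=self.n_init, max_iter=self.max_iter,
                     tol=self.tol, random_state=self.random_state).fit(sub)
        self.pass2_ = pass2.result()
        labels = np.full(matrix.shape[0], -1, dtype=int)
        labels[keep] = pass2.labels_
        self.labels_ = labels
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def two_pass_cluster(cohort_or_matrix, k_grid=tuple(range(1, 7)),
                     alpha_policy: str = "bh", seed: int | None = None,
                     k="auto", q: float = 0.05, n_restarts: int = 25) -> dict:
    """Functional wrapper: returns {"pass1", "window", "pass2", "labels",
    "elbow", "timepoint_tests", "diagnosis"}."""
    matrix = (cohort_or_matrix.to_matrix()
              if isinstance(cohort_or_matrix, Cohort) else cohort_or_matrix)
    est = TwoPassTrajectoryClusterer(
        k=k, k_grid=k_grid, alpha_policy=alpha_policy, q=q,
        n_init=n_restarts, random_state=seed).fit(matrix)
    return {
        "pass1": est.pass1_,
        "window": est.window_,
        "pass2": est.pass2_,
        "labels": est.labels_,
        "elbow": est.elbow_report_,
        "timepoint_tests": est.timepoint_tests_,
        "diagnosis": est.diagnosis_,
    }
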