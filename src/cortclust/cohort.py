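"""Synthetic postoperative cortisol cohorts.

Real patient-level data for this analysis are not publicly deposited, so
every downstream stage is exercised on synthetic cohorts that reproduce
the published statistical structure: a three-component trajectory
mixture for the remission group (per-timepoint means/SDs of clusters A,
B, C on the 6-36 h grid, mixing counts 23/15/39 of n=77), a single
non-remission profile (n=17), monotone steroid-replacement censoring,
sporadic missingness, and covariates drawn from the published marginal
summaries.

Each trajectory is drawn as

    y_it = m_t + f * s_t * z_i + sqrt(1 - f^2) * s_t * e_it

with z_i, e_it standard normal, so the marginal mean/SD at timepoint t
are exactly (m_t, s_t) while the shared patient intercept z_i (fraction
``f`` of the SD) gives curves realistic within-patient smoothness.
Draws are floored at a small positive cortisol value.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .kpod import DataMatrix

__all__ = [
    "REMISSION_GRID",
    "FULL_GRID",
    "ClusterProfile",
    "GeneratorConfig",
    "CortisolTrajectory",
    "Cohort",
    "make_default_profiles",
    "generate_trajectory",
    "generate_cohort",
    "default_remission_config",
    "default_nonremission_config",
]

#: 6-hourly sampling grid covered by the published cluster profiles (hours).
REMISSION_GRID = (6.0, 12.0, 18.0, 24.0, 30.0, 36.0)
#: full 6-hourly follow-up grid out to 96 h.
FULL_GRID = tuple(float(h) for h in range(6, 97, 6))

# published per-timepoint mean (SD) cortisol in mcg/dL on the 6-36 h grid
_REMISSION_TABLE = {
    "A": ([25.5, 31.5, 32.1, 12.7, 4.7, 2.7],
          [8.6, 10.7, 11.4, 5.4, 1.9, 1.4], 23),
    "B": ([61.2, 56.6, 34.7, 21.5, 17.1, 11.9],
          [15.4, 23.7, 19.2, 11.9, 10.2, 8.4], 15),
    "C": ([25.5, 10.6, 4.6, 3.5, 3.4, 3.6],
          [14.7, 7.3, 3.5, 3.3, 2.3, 2.7], 39),
}
_NONREMISSION_TABLE = {
    "NR": ([54.0, 26.9, 24.7, 22.8, 18.4, 16.6],
           [25.2, 15.2, 20.4, 11.0, 15.8, 11.8], 17),
}

# marginal covariate summaries by group: (mean, sd) for continuous,
# proportion for flags
_COVARIATE_MARGINALS = {
    "remission": {
        "male": 32 / 77, "age": (45.1, 15.2), "length_of_stay": (3.2, 1.5),
        "ki67": (0.1, 0.1), "max_diameter_cm": (1.0, 0.7),
        "tumor_volume_cm3": (1.1, 2.4), "knosp_grade": (1.2, 1.3),
        "macroadenoma": 22 / 77, "apoplexy": 5 / 77, "crooke_hyaline": 9 / 77,
        "piecemeal_resection": 36 / 77, "iop_csf_leak": 10 / 77,
        "postop_complication": 11 / 77, "postop_csf_leak": 2 / 77,
        "remission": True,
    },
    "non_remission": {
        "male": 8 / 17, "age": (43.1, 13.3), "length_of_stay": (3.4, 2.0),
        "ki67": (0.0, 0.0), "max_diameter_cm": (1.1, 0.8),
        "tumor_volume_cm3": (1.7, 2.9), "knosp_grade": (1.7, 1.5),
        "macroadenoma": 8 / 17, "apoplexy": 3 / 17, "crooke_hyaline": 1 / 17,
        "piecemeal_resection": 7 / 17, "iop_csf_leak": 2 / 17,
        "postop_complication": 3 / 17, "postop_csf_leak": 2 / 17,
        "remission": False,
    },
}


@dataclass(frozen=True)
class ClusterProfile:
    """Per-timepoint marginal moments of one trajectory cluster."""

    label: str
    mean_curve: tuple
    sd_curve: tuple
    mixing_weight: float

    def __post_init__(self):
        object.__setattr__(self, "mean_curve", tuple(float(v) for v in self.mean_curve))
        object.__setattr__(self, "sd_curve", tuple(float(v) for v in self.sd_curve))
        if len(self.mean_curve) != len(self.sd_curve):
            raise ValueError("mean_curve and sd_curve must have equal length")
        if any(s < 0 for s in self.sd_curve):
            raise ValueError("SDs must be non-negative")
        if not 0.0 <= self.mixing_weight <= 1.0:
            raise ValueError("mixing_weight must be in [0, 1]")


def make_default_profiles(group: str) -> list[ClusterProfile]:
    """Published cluster profiles: three remission clusters or the single
    non-remission profile, with mixing weights from the printed counts."""
    if group == "remission":
        table = _REMISSION_TABLE
    elif group == "non_remission":
        table = _NONREMISSION_TABLE
    else:
        raise ValueError(f"unknown group {group!r}; use 'remission' or 'non_remission'")
    total = sum(n for _, _, n in table.values())
    return [
        ClusterProfile(label, tuple(means), tuple(sds), n / total)
        for label, (means, sds, n) in table.items()
    ]


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic cohort generator."""

    n_patients: int = 77
    profiles: tuple = None
    grid: tuple = REMISSION_GRID
    patient_effect_sd_fraction: float = 0.5
    #: per-6h-interval probability of starting replacement steroids;
    #: 1 - 0.5**(1/5) leaves ~half of patients uncensored at 36 h.
    censor_hazard: float = 0.129
    sporadic_missing_rate: float = 0.05
    truncation_floor: float | None = 0.1
    covariate_group: str = "remission"
    fixed_counts: tuple | None = None
    seed: int = 0

    def __post_init__(self):
        if self.profiles is None:
            object.__setattr__(
                self, "profiles", tuple(make_default_profiles(self.covariate_group))
            )
        else:
            object.__setattr__(self, "profiles", tuple(self.profiles))
        if self.n_patients < len(self.profiles):
            raise ValueError("n_patients must be >= the number of profiles")
        if not 0.0 <= self.censor_hazard <= 1.0:
            raise ValueError("censor_hazard must be in [0, 1]")
        if not 0.0 <= self.sporadic_missing_rate <= 1.0:
            raise ValueError("sporadic_missing_rate must be in [0, 1]")
        if self.truncation_floor is not None and self.truncation_floor <= 0:
            raise ValueError("truncation_floor must be positive (or None to disable)")
        g = np.asarray(self.grid, dtype=float)
        if (np.diff(g) <= 0).any():
            raise ValueError("grid must be strictly increasing")
        w = sum(p.mixing_weight for p in self.profiles)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"mixing weights sum to {w}, expected 1")
        for p in self.profiles:
            if len(p.mean_curve) != len(self.grid):
                raise ValueError("profile curves must match the grid length")
        if self.fixed_counts is not None:
            if len(self.fixed_counts) != len(self.profiles):
                raise ValueError("fixed_counts must match the number of profiles")
            if sum(self.fixed_counts) != self.n_patients:
                raise ValueError("fixed_counts must sum to n_patients")


def default_remission_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """Study-condition remission cohort: n=77, clusters A/B/C at 23/15/39."""
    base = dict(n_patients=77, covariate_group="remission",
                fixed_counts=(23, 15, 39), seed=seed)
    base.update(overrides)
    return GeneratorConfig(**base)


def default_nonremission_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """Study-condition non-remission cohort: n=17, one homogeneous profile."""
    base = dict(n_patients=17, covariate_group="non_remission",
                fixed_counts=(17,), seed=seed)
    base.update(overrides)
    return GeneratorConfig(**base)


@dataclass
class CortisolTrajectory:
    """One patient's cortisol series on the 6-hourly grid (NaN = missing)."""

    patient_id: str
    values: np.ndarray
    observed_mask: np.ndarray
    steroid_time: float | None
    grid: tuple = REMISSION_GRID

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
        self.values = np.where(self.observed_mask, self.values, np.nan)


@dataclass
class Cohort:
    """Trajectories + covariates (+ ground-truth labels for synthetic data)."""

    trajectories: list
    covariates: pd.DataFrame
    true_labels: np.ndarray | None = None
    grid: tuple = REMISSION_GRID

    def __post_init__(self):
        if len(self.covariates) != len(self.trajectories):
            raise ValueError("one covariate record per trajectory required")

    def __len__(self) -> int:
        return len(self.trajectories)

    def to_matrix(self, drop_empty: bool = True) -> DataMatrix:
        """Stack trajectories into a DataMatrix; rows with no observed
        value are dropped with a log line (they cannot be clustered)."""
        values = np.vstack([t.values for t in self.trajectories])
        ids = [t.patient_id for t in self.trajectories]
        keep = ~np.isnan(values).all(axis=1)
        if drop_empty and not keep.all():
            import logging
            logging.getLogger(__name__).info(
                "dropping %d patients with no observed cortisol values",
                (~keep).sum(),
            )
            values = values[keep]
            ids = [i for i, k in zip(ids, keep) if k]
        return DataMatrix(values, row_ids=ids, col_hours=np.asarray(self.grid))

    def to_measurements_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.trajectories:
            for h, v, obs in zip(t.grid, t.values, t.observed_mask):
                if obs:
                    rows.append((t.patient_id, h, v))
        return pd.DataFrame(rows, columns=["patient_id", "hours_postop", "cortisol_mcg_dl"])

    def write(self, out_dir) -> dict:
        """Write measurements/covariates(/labels) CSVs; missing cells are
        simply absent rows, never sentinel numbers."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        m = out / "measurements.csv"
        self.to_measurements_frame().to_csv(m, index=False)
        paths["measurements"] = m
        c = out / "covariates.csv"
        self.covariates.to_csv(c, index=False)
        paths["covariates"] = c
        if self.true_labels is not None:
            l = out / "true_labels.csv"
            pd.DataFrame({
                "patient_id": [t.patient_id for t in self.trajectories],
                "true_label": self.true_labels,
            }).to_csv(l, index=False)
            paths["true_labels"] = l
        return paths


# ---------------------------------------------------------------------------
# generation


def generate_trajectory(profile: ClusterProfile, config: GeneratorConfig,
                        rng: np.random.Generator,
                        patient_id: str = "p0") -> CortisolTrajectory:
    """Draw one trajectory from a cluster profile.

    Marginal moments match the profile exactly (before flooring); the
    patient-level intercept carries ``patient_effect_sd_fraction`` of
    each timepoint's SD.  Monotone steroid censoring and sporadic
    missingness are applied after the values are drawn.
    """
    f = config.patient_effect_sd_fraction
    if not 0.0 <= f <= 1.0:
        raise ValueError(
            "patient_effect_sd_fraction must be in [0, 1]; larger values "
            "would require a negative residual variance"
        )
    grid = np.asarray(config.grid, dtype=float)
    means = np.asarray(profile.mean_curve)
    sds = np.asarray(profile.sd_curve)
    T = grid.size
    z = rng.standard_normal()
    eps = rng.standard_normal(T)
    values = means + f * sds * z + np.sqrt(1.0 - f * f) * sds * eps
    if config.truncation_floor is not None:
        values = np.maximum(values, config.truncation_floor)

    # monotone censoring: steroids may start in any inter-measurement interval
    steroid_time = None
    u = rng.random(T - 1)
    hit = np.flatnonzero(u < config.censor_hazard)
    if hit.size:
        j = int(hit[0])
        steroid_time = float(0.5 * (grid[j] + grid[j + 1]))
    mask = np.ones(T, dtype=bool)
    if steroid_time is not None:
        mask &= grid <= steroid_time
    # sporadic missingness, independent of censoring
    mask &= rng.random(T) >= config.sporadic_missing_rate
    return CortisolTrajectory(patient_id, values, mask, steroid_time, tuple(grid))


def _draw_covariates(rng: np.random.Generator, n: int, group: str) -> pd.DataFrame:
    m = _COVARIATE_MARGINALS[group]
    def norm(key, lo=None, hi=None):
        mu, sd = m[key]
        x = rng.normal(mu, sd, n)
        return np.clip(x, lo, hi)
    df = pd.DataFrame({
        "male": rng.random(n) < m["male"],
        "age": norm("age", 18, None).round(1),
        "length_of_stay": norm("length_of_stay", 1, None).round(1),
        "ki67": norm("ki67", 0, None).round(2),
        "max_diameter_cm": norm("max_diameter_cm", 0.1, None).round(2),
        "tumor_volume_cm3": norm("tumor_volume_cm3", 0.0, None).round(2),
        "knosp_grade": np.rint(norm("knosp_grade", 0, 4)).astype(int),
        "macroadenoma": rng.random(n) < m["macroadenoma"],
        "apoplexy": rng.random(n) < m["apoplexy"],
        "crooke_hyaline": rng.random(n) < m["crooke_hyaline"],
        "piecemeal_resection": rng.random(n) < m["piecemeal_resection"],
        "iop_csf_leak": rng.random(n) < m["iop_csf_leak"],
        "postop_complication": rng.random(n) < m["postop_complication"],
        "postop_csf_leak": rng.random(n) < m["postop_csf_leak"],
        "remission": bool(m["remission"]),
    })
    return df


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Generate a full synthetic cohort, deterministic given ``config.seed``.

    Labels come from ``fixed_counts`` when set (the study-condition
    cohorts fix them to the printed cluster sizes), otherwise they are
    multinomial draws from the mixing weights.
    """
    rng = np.random.default_rng(config.seed)
    P = len(config.profiles)
    if config.fixed_counts is not None:
        labels = np.repeat(np.arange(P), config.fixed_counts)
    else:
        weights = np.array([p.mixing_weight for p in config.profiles])
        labels = rng.choice(P, size=config.n_patients, p=weights)
    rng.shuffle(labels)
    trajectories = []
    for i, lab in enumerate(labels):
        pid = f"pt{i:03d}"
        trajectories.append(
            generate_trajectory(config.profiles[lab], config, rng, patient_id=pid)
        )
    covariates = _draw_covariates(rng, config.n_patients, config.covariate_group)
    covariates.insert(0, "patient_id", [t.patient_id for t in trajectories])
    return Cohort(trajectories, covariates,
                  true_labels=np.asarray(labels), grid=tuple(config.grid))
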