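"""Synthetic longitudinal cortical-thickness cohorts with known ground truth.

The generator emulates an accelerated-longitudinal design: two cohorts
with different follow-up schedules (one with up to two waves about 2.8
years apart, one with up to three waves about 1.4 years apart) jointly
spanning ages 8.5-14.5, with a scanner upgrade before the second
cohort's final wave. Regional thickness follows

    thickness(s, r, a) = mu_r + d_s + b_sex*sex + b_coh*cohort
                         + b_scan*scanner + slope_r*(a - age_min)
                         + lambda_r(a) * f_{s,w} + eps

where ``d_s`` is a global per-participant offset, ``slope_r`` a
region-specific linear thinning rate (mm/year, negative), and
``lambda_r(a) * f`` an age-varying common-factor term: per scan one
global factor and one factor per module, each standard normal, loaded
through a Gaussian bump in age centred at ``factor_loading_peak_age``.
The bump makes between-region covariance peak at that age; regions in
designated "hub" modules carry larger loadings (hence higher degree in
thresholded networks), and thinning slopes are drawn correlated with the
loadings at correlation ``thinning_degree_coupling`` (< 0), planting a
negative association between thinning rate and late-age degree.

Every random choice flows from a single seed, so a configuration
regenerates bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidConfigError

ID_COLUMNS = ("participant_id", "scan_id", "age", "sex", "cohort", "scanner")


# ---------------------------------------------------------------------------
# parcellation
# ---------------------------------------------------------------------------


@dataclass
class Parcellation:
    """Synthetic cortical parcellation on two unit hemispheres.

    Regions are points on a unit sphere (one sphere per hemisphere);
    distances are great-circle lengths, and module labels (1..n_modules)
    are spatially contiguous nearest-centroid patches shared across
    hemispheres, standing in for a 7-way functional community
    assignment.
    """

    region_ids: list
    hemisphere: np.ndarray  # "L"/"R" per region
    coords: np.ndarray  # (n, 3) unit vectors
    modules: np.ndarray  # (n,) int labels in 1..n_modules
    distance: dict  # hemisphere -> (n_h, n_h) great-circle matrix

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def n_modules(self) -> int:
        return int(self.modules.max())

    def hemi_indices(self, hemisphere: str) -> np.ndarray:
        return np.flatnonzero(self.hemisphere == hemisphere)

    def hemi_region_ids(self, hemisphere: str) -> list:
        idx = self.hemi_indices(hemisphere)
        return [self.region_ids[i] for i in idx]


def _random_unit_points(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _great_circle(points: np.ndarray) -> np.ndarray:
    dots = np.clip(points @ points.T, -1.0, 1.0)
    d = np.arccos(dots)
    np.fill_diagonal(d, 0.0)
    return d


def generate_parcellation(
    n_regions: int = 60, n_modules: int = 7, seed: int = 0
) -> Parcellation:
    """Random spherical parcellation split evenly across hemispheres.

    Module labels are assigned per hemisphere to the nearest of
    ``n_modules`` random centroids (same labels on both hemispheres);
    centroids are redrawn until every module has at least one region
    overall.
    """
    if n_regions % 2 != 0:
        raise InvalidConfigError("n_regions must be even (split across hemispheres)")
    if n_regions < 2 * n_modules:
        raise InvalidConfigError("n_regions must be >= 2 * n_modules")
    rng = np.random.default_rng(seed)
    n_h = n_regions // 2
    hemisphere = np.array(["L"] * n_h + ["R"] * n_h)
    width = len(str(n_h))
    region_ids = [f"L{i + 1:0{width}d}" for i in range(n_h)] + [
        f"R{i + 1:0{width}d}" for i in range(n_h)
    ]
    coords = np.vstack(
        [_random_unit_points(rng, n_h), _random_unit_points(rng, n_h)]
    )
    for _attempt in range(1000):
        modules = np.empty(n_regions, dtype=int)
        for hemi, sl in (("L", slice(0, n_h)), ("R", slice(n_h, n_regions))):
            centroids = _random_unit_points(rng, n_modules)
            dots = coords[sl] @ centroids.T
            modules[sl] = np.argmax(dots, axis=1) + 1
        if len(np.unique(modules)) == n_modules:
            break
    else:  # pragma: no cover - vanishingly unlikely at valid sizes
        raise InvalidConfigError("could not place all modules; too few regions")
    distance = {
        "L": _great_circle(coords[:n_h]),
        "R": _great_circle(coords[n_h:]),
    }
    return Parcellation(region_ids, hemisphere, coords, modules, distance)


# ---------------------------------------------------------------------------
# cohort / scan generation
# ---------------------------------------------------------------------------


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort and generative model.

    The demographic defaults mirror the emulated study: 192 participants
    contributing about 366 scans between ages 8.5 and 14.5; cohort 0
    ("slow", up to 2 waves, mean gap 2.763 y) and cohort 1 ("fast", up
    to 3 waves, mean gap 1.432 y); the scanner flag switches on at the
    fast cohort's third wave.
    """

    n_participants: int = 192
    target_scans: int = 366
    age_min: float = 8.5
    age_max: float = 14.5
    cohort1_fraction: float = 90 / 192  # fraction in the fast (3-wave) cohort
    interwave_gap_means: tuple = (2.763, 1.432)  # (cohort 0, cohort 1), years
    interwave_gap_sds: tuple = (0.243, 0.222)
    waves_per_cohort: tuple = (2, 3)
    baseline_age_ranges: tuple = ((8.5, 10.7), (9.5, 11.4))
    scanner_upgrade_wave: int = 3  # fast-cohort wave index at which scanner flips

    n_regions: int = 60
    n_modules: int = 7

    baseline_thickness_mean: float = 2.7  # mm
    region_mu_sd: float = 0.15  # mm, spread of regional baselines
    sex_effect: float = 0.03  # mm offsets of the covariates
    cohort_effect: float = 0.04
    scanner_effect: float = 0.05

    thinning_slope_mean: float = -0.045  # mm/year
    thinning_slope_sd: float = 0.015
    thinning_degree_coupling: float = -0.7  # corr(slope, loading), unitless

    factor_loading_peak_age: float = 11.5  # years
    factor_loading_width: float = 1.1  # years
    loading_base: float = 0.15  # mm, typical factor loading at the peak
    loading_jitter: float = 0.2  # regional loadings vary by +/- this fraction
    hub_modules: tuple = (1, 2)
    hub_loading_boost: float = 0.7  # hub-module loadings scaled by (1 + boost)
    global_factor_weight: float = 0.6
    module_factor_weight: float = 0.8
    peak_age_by_sex: Optional[tuple] = None  # (male, female) peaks; overrides default

    subject_sd: float = 0.03  # mm, global per-participant offset
    noise_sd: float = 0.12  # mm, scan-and-region noise

    seed: int = 0

    def validate(self) -> None:
        for name in ("interwave_gap_sds", "subject_sd", "noise_sd", "region_mu_sd",
                     "thinning_slope_sd", "loading_base", "factor_loading_width"):
            val = getattr(self, name)
            vals = val if isinstance(val, tuple) else (val,)
            if any(v < 0 for v in vals):
                raise InvalidConfigError(f"{name} must be non-negative")
        if self.factor_loading_width == 0:
            raise InvalidConfigError("factor_loading_width must be positive")
        if not -1.0 <= self.thinning_degree_coupling <= 1.0:
            raise InvalidConfigError("thinning_degree_coupling must be in [-1, 1]")
        if not 0.0 <= self.cohort1_fraction <= 1.0:
            raise InvalidConfigError("cohort1_fraction must be a proportion")
        if self.age_max <= self.age_min:
            raise InvalidConfigError("age_max must exceed age_min")
        n0 = self.n_participants - round(self.n_participants * self.cohort1_fraction)
        n1 = self.n_participants - n0
        max_scans = n0 * self.waves_per_cohort[0] + n1 * self.waves_per_cohort[1]
        if not self.n_participants <= self.target_scans <= max_scans:
            raise InvalidConfigError(
                f"target_scans={self.target_scans} infeasible for "
                f"{self.n_participants} participants with waves {self.waves_per_cohort}"
            )


@dataclass
class GroundTruth:
    """What the generator planted, for downstream recovery checks."""

    mu: np.ndarray  # per-region baseline thickness (mm)
    slope: np.ndarray  # per-region thinning rate (mm/year)
    loading: np.ndarray  # per-region peak factor loading (mm)
    modules: np.ndarray
    hub_modules: tuple
    peak_age: float
    peak_age_by_sex: Optional[tuple]
    width: float
    thinning_degree_coupling: float

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        return d


def _follow_up_probability(cfg: SyntheticConfig, n0: int, n1: int) -> float:
    """Per-wave retention solving E[total scans] = target_scans.

    Attendance is sequential: a participant attends wave k+1 with
    probability q given attendance at wave k, up to the cohort maximum,
    so E[total] = n + q*n + q^2*n1 for 2-/3-wave cohorts.
    """
    n = n0 + n1
    a, b, c = float(n1), float(n), float(n - cfg.target_scans)
    if a == 0:
        return -c / b
    disc = b * b - 4 * a * c
    q = (-b + math.sqrt(disc)) / (2 * a)
    return min(max(q, 0.0), 1.0)


def _truncated_gap(rng, mean, sd) -> float:
    if sd == 0:
        return mean
    lo, hi = (max(mean - 3 * sd, 1e-3) - mean) / sd, 3.0
    return float(stats.truncnorm.rvs(lo, hi, loc=mean, scale=sd, random_state=rng))


def generate_dataset(
    config: SyntheticConfig, parcellation: Parcellation
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a longitudinal scan table and its ground truth.

    Returns a tidy table with one row per scan (identifiers, age, binary
    sex / cohort / scanner covariates, one thickness column per region)
    and the :class:`GroundTruth` describing the planted structure.
    """
    config.validate()
    if parcellation.n_regions != config.n_regions:
        raise InvalidConfigError(
            f"parcellation has {parcellation.n_regions} regions, "
            f"config expects {config.n_regions}"
        )
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    n1 = round(n * config.cohort1_fraction)
    n0 = n - n1

    cohort = np.array([0] * n0 + [1] * n1)
    sex = np.zeros(n, dtype=int)
    sex[rng.permutation(n)[: n // 2]] = 1

    # wave attendance: redraw until the scan total is within 5% of target
    q = _follow_up_probability(config, n0, n1)
    max_waves = np.where(cohort == 0, config.waves_per_cohort[0],
                         config.waves_per_cohort[1])
    tol = 0.05 * config.target_scans
    for _ in range(200):
        attend = np.ones(n, dtype=int)
        for p in range(n):
            for _w in range(1, max_waves[p]):
                if rng.random() < q:
                    attend[p] += 1
                else:
                    break
        if abs(int(attend.sum()) - config.target_scans) <= tol:
            break

    # ground truth maps
    P = config.n_regions
    mu = config.baseline_thickness_mean + rng.normal(0, config.region_mu_sd, P)
    is_hub = np.isin(parcellation.modules, config.hub_modules)
    loading = (
        config.loading_base
        * (1.0 + config.hub_loading_boost * is_hub)
        * rng.uniform(1 - config.loading_jitter, 1 + config.loading_jitter, P)
    )
    if loading.std() > 0:
        load_z = (loading - loading.mean()) / loading.std()
    else:
        load_z = np.zeros(P)
    rho = config.thinning_degree_coupling
    slope_noise = rng.normal(size=P)
    slope = config.thinning_slope_mean + config.thinning_slope_sd * (
        rho * load_z + math.sqrt(max(0.0, 1 - rho**2)) * slope_noise
    )

    d_subject = rng.normal(0, config.subject_sd, n)

    rows = []
    thickness = []
    mods = parcellation.modules
    module_ids = np.unique(mods)
    w_g, w_m = config.global_factor_weight, config.module_factor_weight
    pid_width = len(str(n))
    for p in range(n):
        pid = f"P{p + 1:0{pid_width}d}"
        lo, hi = config.baseline_age_ranges[cohort[p]]
        age = rng.uniform(lo, hi)
        gmean = config.interwave_gap_means[cohort[p]]
        gsd = config.interwave_gap_sds[cohort[p]]
        if config.peak_age_by_sex is not None:
            peak = config.peak_age_by_sex[sex[p]]
        else:
            peak = config.factor_loading_peak_age
        gaps = [_truncated_gap(rng, gmean, gsd) for _ in range(attend[p] - 1)]
        # keep the schedule inside the age range: shrink this participant's
        # gaps proportionally if the last wave would overshoot
        if gaps and age + sum(gaps) > config.age_max:
            gaps = [g * (config.age_max - age) / sum(gaps) for g in gaps]
        ages_p = [age] + list(age + np.cumsum(gaps))
        for w in range(1, attend[p] + 1):
            age = ages_p[w - 1]
            scanner = int(
                cohort[p] == 1 and w >= config.scanner_upgrade_wave
            )
            bump = math.exp(-((age - peak) ** 2) / (2 * config.factor_loading_width**2))
            g = rng.normal()
            h = rng.normal(size=len(module_ids))
            factor = w_g * g + w_m * h[np.searchsorted(module_ids, mods)]
            eps = rng.normal(0, config.noise_sd, P)
            th = (
                mu
                + d_subject[p]
                + config.sex_effect * sex[p]
                + config.cohort_effect * cohort[p]
                + config.scanner_effect * scanner
                + slope * (age - config.age_min)
                + loading * bump * factor
                + eps
            )
            rows.append(
                {
                    "participant_id": pid,
                    "scan_id": f"{pid}_w{w}",
                    "age": float(age),
                    "sex": int(sex[p]),
                    "cohort": int(cohort[p]),
                    "scanner": scanner,
                }
            )
            thickness.append(th)

    table = pd.DataFrame(rows)
    thick = pd.DataFrame(np.asarray(thickness), columns=parcellation.region_ids)
    table = pd.concat([table, thick], axis=1)
    truth = GroundTruth(
        mu=mu,
        slope=slope,
        loading=loading,
        modules=mods.copy(),
        hub_modules=tuple(config.hub_modules),
        peak_age=config.factor_loading_peak_age,
        peak_age_by_sex=config.peak_age_by_sex,
        width=config.factor_loading_width,
        thinning_degree_coupling=rho,
    )
    return table, truth


def null_coupling_config(**overrides) -> SyntheticConfig:
    """Generator variant with no planted regional structure.

    Testing that the thinning-degree association test does *not* reject
    when nothing is planted requires more than switching the coupling
    off. Two emergent channels otherwise tie the slope map to the degree
    map even at zero coupling: (i) heterogeneous thinning rates act as a
    common age factor inside wide late-age bins, so steeper-thinning
    regions genuinely covary more and gain degree; and (ii) the common
    factors enter both the networks and the slope fits, so slope
    estimation errors align with loading-driven degree. The sharp null
    therefore uses homogeneous thinning rates and no factor loadings,
    with a slightly larger global subject offset so that baseline
    correlations keep the thresholded network (and hence the degree map)
    non-degenerate.
    """
    base = dict(
        thinning_degree_coupling=0.0,
        thinning_slope_sd=0.0,
        loading_base=0.0,
        subject_sd=0.07,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


def region_columns(scan_table: pd.DataFrame) -> list:
    """Thickness column names of a scan table (everything non-identifier)."""
    return [c for c in scan_table.columns if c not in ID_COLUMNS]
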