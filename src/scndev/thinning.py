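"""Cortical thinning rates and spatially-constrained map association tests.

Per-region thinning rates are the age fixed effects of Gaussian linear
mixed models (fixed: sex, cohort, scanner, age; random: participant
intercept; REML). Their spatial correlation with standardized degree is
tested against surrogate maps that preserve the empirical map's value
distribution and spatial autocorrelation: each surrogate permutes the
map, smooths it over k nearest neighbours with inverse-distance
weights, picks the k whose binned variogram best matches the empirical
one, and rank-remaps the result onto the original values. The
non-parametric p-value is the (add-one) proportion of surrogates whose
correlation magnitude reaches the empirical one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import InvalidConfigError, InvalidInputError
from .synthetic import Parcellation, region_columns

THINNING_COVARIATES = ("sex", "cohort", "scanner")


# ---------------------------------------------------------------------------
# mixed-model thinning rates
# ---------------------------------------------------------------------------


def fit_thinning_rates(
    scan_table: pd.DataFrame,
    covariates: Sequence[str] = THINNING_COVARIATES,
) -> pd.DataFrame:
    """Per-region random-intercept mixed-model slopes of thickness on age.

    Returns a DataFrame indexed by region with columns ``beta_age``
    (mm/year), the covariate fixed effects, ``intercept``,
    ``random_intercept_sd``, ``residual_sd`` and ``method`` ("mixed", or
    "ols" when the mixed fit fails to converge and an ordinary
    least-squares fallback is used).
    """
    missing = [c for c in covariates if c not in scan_table.columns]
    if missing:
        raise InvalidInputError(f"covariates not in table: {missing}")
    regions = region_columns(scan_table)
    n = len(scan_table)
    X = np.column_stack(
        [np.ones(n)]
        + [scan_table[c].to_numpy(dtype=float) for c in covariates]
        + [scan_table["age"].to_numpy(dtype=float)]
    )
    groups = scan_table["participant_id"].to_numpy()
    age_col = X.shape[1] - 1

    rows = []
    for region in regions:
        y = scan_table[region].to_numpy(dtype=float)
        params = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.MixedLM(y, X, groups=groups).fit(reml=True)
                if np.all(np.isfinite(res.fe_params)):
                    params = res
            except (np.linalg.LinAlgError, ValueError):
                params = None
        if params is not None:
            fe = params.fe_params
            re_sd = float(np.sqrt(max(float(np.asarray(params.cov_re)[0, 0]), 0.0)))
            resid_sd = float(np.sqrt(max(params.scale, 0.0)))
            method = "mixed"
        else:
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            fe = beta
            resid = y - X @ beta
            re_sd = float("nan")
            resid_sd = float(np.sqrt(np.mean(resid**2)))
            method = "ols"
        row = {
            "region": region,
            "intercept": float(fe[0]),
            "beta_age": float(fe[age_col]),
            "random_intercept_sd": re_sd,
            "residual_sd": resid_sd,
            "method": method,
        }
        for j, c in enumerate(covariates, start=1):
            row[f"beta_{c}"] = float(fe[j])
        rows.append(row)
    return pd.DataFrame(rows).set_index("region")


# ---------------------------------------------------------------------------
# variogram-matched surrogate maps
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SurrogateSpec:
    """Surrogate-ensemble parameters."""

    n_surr: int = 1000
    kernel_grid: tuple = (3, 5, 10, 20)
    n_distance_bins: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.n_surr < 1:
            raise InvalidConfigError("n_surr must be >= 1")
        if not self.kernel_grid:
            raise InvalidConfigError("kernel_grid must be non-empty")
        if self.n_distance_bins < 2:
            raise InvalidConfigError("need at least 2 distance bins")


@dataclass
class SurrogateEnsemble:
    """Autocorrelation-preserving randomizations of one regional map."""

    maps: np.ndarray  # (n_surr, n_regions)
    source: np.ndarray
    chosen_k: np.ndarray  # kernel size selected per surrogate
    spec: SurrogateSpec


def binned_variogram(
    values: np.ndarray, distance: np.ndarray, bin_edges: np.ndarray
) -> np.ndarray:
    """Mean semivariance 0.5*(x_i - x_j)^2 per distance bin."""
    iu = np.triu_indices(len(values), k=1)
    d = distance[iu]
    v = 0.5 * (values[iu[0]] - values[iu[1]]) ** 2
    idx = np.clip(np.digitize(d, bin_edges[1:-1]), 0, len(bin_edges) - 2)
    out = np.zeros(len(bin_edges) - 1)
    for b in range(len(out)):
        mask = idx == b
        out[b] = v[mask].mean() if mask.any() else 0.0
    return out


def _equal_count_edges(distance: np.ndarray, n_bins: int) -> np.ndarray:
    iu = np.triu_indices(distance.shape[0], k=1)
    return np.quantile(distance[iu], np.linspace(0, 1, n_bins + 1))


def build_surrogates(
    source_map: np.ndarray, distance: np.ndarray, spec: SurrogateSpec
) -> SurrogateEnsemble:
    """Generate variogram-matched surrogate maps for one hemisphere.

    Each surrogate: random permutation -> inverse-distance k-NN
    smoothing for every k in the kernel grid -> rank-remap onto the
    source value multiset -> keep the k whose binned variogram has the
    smallest squared error against the source map's. Every surrogate
    therefore has exactly the source's value distribution.
    """
    x = np.asarray(source_map, dtype=float)
    n = len(x)
    if distance.shape != (n, n):
        raise InvalidInputError(
            f"distance matrix {distance.shape} does not match map length {n}"
        )
    rng = np.random.default_rng(spec.seed)
    if np.ptp(x) == 0:
        warnings.warn("constant map; surrogates equal the source", stacklevel=2)
        return SurrogateEnsemble(
            maps=np.tile(x, (spec.n_surr, 1)),
            source=x.copy(),
            chosen_k=np.zeros(spec.n_surr, dtype=int),
            spec=spec,
        )

    edges = _equal_count_edges(distance, spec.n_distance_bins)
    target_vario = binned_variogram(x, distance, edges)
    sorted_vals = np.sort(x)
    ks = [min(int(k), n - 1) for k in spec.kernel_grid]
    # k nearest neighbours (self excluded) and inverse-distance weights
    order = np.argsort(distance + np.eye(n) * (distance.max() + 1), axis=1)
    neighbours = {k: order[:, :k] for k in ks}
    weights = {}
    for k in ks:
        d = np.take_along_axis(distance, neighbours[k], axis=1)
        w = 1.0 / np.clip(d, 1e-12, None)
        weights[k] = w / w.sum(axis=1, keepdims=True)

    perms = np.array([rng.permutation(x) for _ in range(spec.n_surr)])
    candidates = {}
    for k in ks:
        smoothed = np.einsum("snk,nk->sn", perms[:, neighbours[k]], weights[k])
        ranks = np.argsort(np.argsort(smoothed, axis=1), axis=1)
        candidates[k] = sorted_vals[ranks]

    maps = np.empty_like(perms)
    chosen = np.empty(spec.n_surr, dtype=int)
    iu = np.triu_indices(n, k=1)
    d_iu = distance[iu]
    bin_idx = np.clip(np.digitize(d_iu, edges[1:-1]), 0, spec.n_distance_bins - 1)
    counts = np.bincount(bin_idx, minlength=spec.n_distance_bins)
    counts = np.where(counts == 0, 1, counts)
    for s in range(spec.n_surr):
        best_sse, best_k = np.inf, ks[0]
        for k in ks:
            vals = candidates[k][s]
            v = 0.5 * (vals[iu[0]] - vals[iu[1]]) ** 2
            vario = np.bincount(bin_idx, weights=v, minlength=spec.n_distance_bins) / counts
            sse = float(np.sum((vario - target_vario) ** 2))
            if sse < best_sse:
                best_sse, best_k = sse, k
        maps[s] = candidates[best_k][s]
        chosen[s] = best_k
    return SurrogateEnsemble(maps=maps, source=x.copy(), chosen_k=chosen, spec=spec)


# ---------------------------------------------------------------------------
# map-to-map correlation test
# ---------------------------------------------------------------------------


@dataclass
class MapCorrelationTest:
    """Correlation between two regional maps with a surrogate null p-value."""

    hemisphere: str
    r_empirical: float
    p_nonparametric: float
    direction: str  # "two-sided-magnitude" or "one-sided-signed"
    n_surrogates: int
    degenerate: bool = False  # a map had zero variance; test undefined


def surrogate_correlation_test(
    map_a: np.ndarray,
    map_b: np.ndarray,
    ensemble_for_a: SurrogateEnsemble,
    hemisphere: str = "",
    alternative: str = "two-sided-magnitude",
) -> MapCorrelationTest:
    """Test corr(map_a, map_b) against the surrogate null for map_a.

    p = (#{surrogates with |corr| >= |r_emp|} + 1) / (n_surr + 1) under
    the default magnitude alternative; the signed one-sided option
    counts surrogates with corr at least as extreme in the empirical
    direction.
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if len(a) != len(b):
        raise InvalidInputError("maps must have equal length")
    if ensemble_for_a.maps.shape[1] != len(a):
        raise InvalidInputError("ensemble was built for a different map size")
    n_surr = ensemble_for_a.maps.shape[0]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("zero-variance map; correlation undefined", stacklevel=2)
        return MapCorrelationTest(
            hemisphere=hemisphere,
            r_empirical=float("nan"),
            p_nonparametric=float("nan"),
            direction=alternative,
            n_surrogates=n_surr,
            degenerate=True,
        )
    r_emp = float(stats.pearsonr(a, b)[0])
    bc = b - b.mean()
    S = ensemble_for_a.maps - ensemble_for_a.maps.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(S, axis=1) * np.linalg.norm(bc)
    with np.errstate(divide="ignore", invalid="ignore"):
        r_surr = np.where(denom > 0, S @ bc / denom, 0.0)
    if alternative == "two-sided-magnitude":
        exceed = np.abs(r_surr) >= abs(r_emp)
    elif alternative == "one-sided-signed":
        exceed = r_surr <= r_emp if r_emp < 0 else r_surr >= r_emp
    else:
        raise InvalidConfigError(f"unknown alternative '{alternative}'")
    p = (int(exceed.sum()) + 1) / (n_surr + 1)
    return MapCorrelationTest(
        hemisphere=hemisphere,
        r_empirical=r_emp,
        p_nonparametric=float(p),
        direction=alternative,
        n_surrogates=n_surr,
    )


def thinning_degree_association(
    thinning_model: pd.DataFrame,
    z_degree: pd.Series,
    parcellation: Parcellation,
    spec: SurrogateSpec,
    alternative: str = "two-sided-magnitude",
) -> dict:
    """Per-hemisphere surrogate test of thinning rate vs standardized degree.

    ``z_degree`` is a region-indexed Series (one bin's standardized
    degree); the surrogate ensemble is built on the thinning map of each
    hemisphere using that hemisphere's distance matrix.
    """
    results = {}
    for hemi in ("L", "R"):
        rids = parcellation.hemi_region_ids(hemi)
        missing = [r for r in rids if r not in thinning_model.index or r not in z_degree.index]
        if missing:
            raise InvalidInputError(f"regions missing from inputs: {missing[:5]}")
        beta = thinning_model.loc[rids, "beta_age"].to_numpy()
        z = z_degree.loc[rids].to_numpy(dtype=float)
        if np.ptp(z) == 0 or np.ptp(beta) == 0:
            warnings.warn(
                f"degenerate map in hemisphere {hemi}; returning flagged null",
                stacklevel=2,
            )
            results[hemi] = MapCorrelationTest(
                hemisphere=hemi,
                r_empirical=float("nan"),
                p_nonparametric=float("nan"),
                direction=alternative,
                n_surrogates=spec.n_surr,
                degenerate=True,
            )
            continue
        ensemble = build_surrogates(beta, parcellation.distance[hemi], spec)
        results[hemi] = surrogate_correlation_test(
            beta, z, ensemble, hemisphere=hemi, alternative=alternative
        )
    return results
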