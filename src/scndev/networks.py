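"""Per-bin covariance networks: residualization, correlation, thresholding.

Thickness is first residualized region-wise for nuisance covariates
(sex, cohort, scanner) across the full sample; internally studentized
residuals (raw residual / (sigma_hat * sqrt(1 - leverage))) are the
values entering every network. Within an age-bin the network is the
Pearson correlation matrix across regions over that bin's scans. Edges
are then thresholded by bootstrap consistency: participants are
resampled with replacement, the network re-estimated, and an edge kept
only if its correlation is consistently positive across bootstraps after
Benjamini-Hochberg control over all region pairs; surviving edges are
binarized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import InvalidConfigError, InvalidInputError
from .synthetic import region_columns
from .windows import AgeBin

DEFAULT_COVARIATES = ("sex", "cohort", "scanner")


@dataclass
class CovarianceNetwork:
    """One age-bin's network: correlations and (optionally) a retained mask."""

    r: np.ndarray  # region x region Pearson correlations
    retained: Optional[np.ndarray]  # binary mask (None when unthresholded)
    bin_median_age: float
    n_subjects: int
    region_ids: list
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_regions(self) -> int:
        return self.r.shape[0]

    @property
    def thresholded(self) -> bool:
        return self.retained is not None


@dataclass(frozen=True)
class BootstrapSpec:
    """Bootstrap-thresholding parameters."""

    B: int = 1000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.B < 1:
            raise InvalidConfigError(f"B must be >= 1, got {self.B}")
        if not 0.0 < self.alpha < 1.0:
            raise InvalidConfigError(f"alpha must be in (0, 1), got {self.alpha}")


def residualize(
    scan_table: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Replace thickness by internally studentized OLS residuals.

    Each region is regressed on an intercept plus the covariates across
    all scans; residuals are standardized as
    ``resid / (sigma_hat * sqrt(1 - h))`` with ``sigma_hat^2 = RSS/(n-p)``
    and ``h`` the leverage. Constant covariates are dropped with a
    warning; aliased (collinear) columns are dropped likewise. A region
    fit perfectly by the covariates returns all-zero residuals.
    """
    missing = [c for c in covariates if c not in scan_table.columns]
    if missing:
        raise InvalidInputError(f"covariates not in table: {missing}")
    regions = region_columns(scan_table)
    n = len(scan_table)

    cols = [np.ones(n)]
    names = ["intercept"]
    for c in covariates:
        v = scan_table[c].to_numpy(dtype=float)
        if np.ptp(v) == 0:
            warnings.warn(f"covariate '{c}' is constant; dropped", stacklevel=2)
            continue
        cols.append(v)
        names.append(c)
    X = np.column_stack(cols)
    # drop aliased columns so the design has full column rank
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        keep = [0]
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, keep + [j]]) > len(keep):
                keep.append(j)
        dropped = [names[j] for j in range(X.shape[1]) if j not in keep]
        warnings.warn(f"aliased covariates dropped: {dropped}", stacklevel=2)
        X = X[:, keep]
    p = X.shape[1]
    if n <= p:
        raise InvalidInputError(f"need more scans ({n}) than parameters ({p})")

    Q, _ = np.linalg.qr(X)
    h = np.sum(Q**2, axis=1)
    Y = scan_table[regions].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    rss = np.sum(resid**2, axis=0)
    sigma = np.sqrt(rss / (n - p))
    # a region fit perfectly by the covariates (sigma ~ 0 relative to its
    # scale) gets all-zero residuals rather than 0/0 noise
    scale = np.maximum(np.sqrt(np.mean(Y**2, axis=0)), 1.0)
    perfect = sigma <= 1e-10 * scale
    denom = np.sqrt(np.clip(1.0 - h, 1e-12, None))[:, None] * sigma[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        std_resid = np.where(perfect[None, :], 0.0, resid / denom)
    out = scan_table.copy()
    out[regions] = std_resid
    return out


def _bin_values(residual_table: pd.DataFrame, bin_: AgeBin) -> np.ndarray:
    regions = region_columns(residual_table)
    sub = residual_table.set_index("scan_id").loc[list(bin_.scan_ids), regions]
    return sub.to_numpy(dtype=float)


def _corr_with_guard(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlations with zero-variance regions mapped to r = 0."""
    sd = X.std(axis=0)
    degenerate = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.corrcoef(X, rowvar=False)
    r = np.where(np.isfinite(r), r, 0.0)
    if degenerate.any():
        r[degenerate, :] = 0.0
        r[:, degenerate] = 0.0
    np.fill_diagonal(r, 1.0)
    return r, degenerate


def correlation_matrix(
    residual_table: pd.DataFrame, bin_: AgeBin
) -> CovarianceNetwork:
    """Unthresholded Pearson correlation network for one age-bin."""
    if bin_.n < 3:
        raise InvalidInputError("bin must contain at least 3 participants")
    X = _bin_values(residual_table, bin_)
    r, degenerate = _corr_with_guard(X)
    diagnostics = {}
    if degenerate.any():
        diagnostics["zero_variance_regions"] = int(degenerate.sum())
    return CovarianceNetwork(
        r=r,
        retained=None,
        bin_median_age=bin_.median_age,
        n_subjects=bin_.n,
        region_ids=region_columns(residual_table),
        diagnostics=diagnostics,
    )


def mean_correlation(network: CovarianceNetwork, mode: str = "positive") -> float:
    """Mean off-diagonal correlation of an unthresholded network.

    ``mode="positive"`` (default) averages strictly positive
    upper-triangle entries; ``mode="all"`` averages all of them.
    """
    if network.thresholded:
        raise InvalidInputError("mean_correlation expects an unthresholded network")
    iu = np.triu_indices(network.n_regions, k=1)
    vals = network.r[iu]
    if mode == "all":
        return float(vals.mean()) if vals.size else 0.0
    if mode != "positive":
        raise InvalidConfigError(f"unknown mode '{mode}'")
    pos = vals[vals > 0]
    if pos.size == 0:
        warnings.warn("no positive correlations; returning 0", stacklevel=2)
        return 0.0
    return float(pos.mean())


def bootstrap_threshold(
    residual_table: pd.DataFrame, bin_: AgeBin, spec: BootstrapSpec
) -> CovarianceNetwork:
    """Bootstrap-thresholded, binarized network for one age-bin.

    For each edge the bootstrap p-value is ``(#{b: r_b <= 0} + 1)/(B+1)``
    over ``B`` resamples of the bin's participants (with replacement,
    same size). Benjamini-Hochberg is applied across all region pairs at
    level ``alpha``; surviving edges with a positive point-estimate
    correlation are set to 1, everything else to 0. Diagnostics record
    the fraction of BH survivors whose point estimate was negative
    (discarded by the positivity guard).
    """
    if bin_.n < 3:
        raise InvalidInputError("bin must contain at least 3 participants")
    X = _bin_values(residual_table, bin_)
    r_point, _ = _corr_with_guard(X)
    n, P = X.shape
    rng = np.random.default_rng(spec.seed)
    iu = np.triu_indices(P, k=1)
    neg_counts = np.zeros(len(iu[0]), dtype=int)
    for _b in range(spec.B):
        idx = rng.integers(0, n, n)
        rb, _ = _corr_with_guard(X[idx])
        neg_counts += rb[iu] <= 0
    pvals = (neg_counts + 1) / (spec.B + 1)
    reject, p_adj, *_ = multipletests(pvals, alpha=spec.alpha, method="fdr_bh")
    point = r_point[iu]
    survivors = reject
    n_neg_survivors = int(np.sum(survivors & (point <= 0)))
    keep = survivors & (point > 0)
    retained = np.zeros((P, P), dtype=int)
    retained[iu[0][keep], iu[1][keep]] = 1
    retained += retained.T
    diagnostics = {
        "negative_survivor_fraction": (
            n_neg_survivors / survivors.sum() if survivors.sum() else 0.0
        ),
        "n_edges_retained": int(keep.sum()),
    }
    return CovarianceNetwork(
        r=r_point,
        retained=retained,
        bin_median_age=bin_.median_age,
        n_subjects=n,
        region_ids=region_columns(residual_table),
        diagnostics=diagnostics,
    )
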