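"""Trajectory model selection for per-bin metrics.

Each metric series (value vs bin median age) is fit with three nested
Gaussian models by maximum likelihood: a constant ("null"), a line in
age ("linear"), and a "smooth" model — a natural cubic spline of age
with knots at the minimum, median and maximum bin age, i.e. two basis
functions beyond the intercept, matching the maximum flexibility of a
penalized smooth with basis dimension 3. The more complex model is
selected only when its AIC undercuts every lower-order model by at
least 3. Smooth-term p-values (F-test vs the null model) can be FDR
corrected across regions or modules, and a finding is reported only
when detected in more than half of the sliding-window configurations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InvalidConfigError, InvalidInputError

MODELS = ("null", "linear", "smooth")
DELTA_AIC = 3.0


def natural_spline_term(x: np.ndarray, knots: Sequence[float]) -> np.ndarray:
    """The single nonlinear basis function of a 3-knot natural cubic spline.

    Truncated-power construction: with knots k1 < k2 < k3,
    ``N(x) = d1(x) - d2(x)`` where
    ``dj(x) = ((x - kj)_+^3 - (x - k3)_+^3) / (k3 - kj)``.
    Together with the intercept and the linear term this spans the full
    natural cubic spline space on three knots.
    """
    k1, k2, k3 = knots
    if not k1 < k2 < k3:
        raise InvalidInputError("knots must be strictly increasing")

    def d(kj):
        return (np.clip(x - kj, 0, None) ** 3 - np.clip(x - k3, 0, None) ** 3) / (
            k3 - kj
        )

    return d(k1) - d(k2)


def _gaussian_ml(X: np.ndarray, y: np.ndarray):
    """OLS fit; returns (beta, rss, loglik) under the Gaussian ML variance."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    n = len(y)
    sigma2 = max(rss / n, 1e-300)
    loglik = -0.5 * n * (math.log(2 * math.pi * sigma2) + 1)
    return beta, rss, loglik


def _aic(loglik: float, n_mean_params: int) -> float:
    # the ML error variance counts as one estimated parameter
    return -2.0 * loglik + 2.0 * (n_mean_params + 1)


@dataclass
class TrajectoryFit:
    """Model comparison for one metric series."""

    metric_id: str
    config_id: str
    aic: dict  # model -> AIC (+inf when the model could not be fit)
    loglik: dict
    selected: str
    smooth_p: float
    fitted_values: dict  # model -> fitted values at the observed ages
    coef: dict  # model -> coefficient vector
    knots: Optional[tuple]
    peak_age: Optional[float]  # argmax of the smooth fit (when selected)
    peak_interior: bool
    net_change: float  # fitted value at max age minus at min age, selected model

    @property
    def direction(self) -> str:
        if self.selected == "null" or self.net_change == 0:
            return "flat"
        return "increase" if self.net_change > 0 else "decrease"


def select_with_rule(
    aic_null: float, aic_linear: float, aic_smooth: float, delta: float = DELTA_AIC
) -> str:
    """Step-up AIC selection: a model wins only by beating *all* lower-order
    models by at least ``delta`` AIC points."""
    if aic_smooth <= aic_linear - delta and aic_smooth <= aic_null - delta:
        return "smooth"
    if aic_linear <= aic_null - delta:
        return "linear"
    return "null"


def fit_trajectory(
    ages: Sequence[float],
    values: Sequence[float],
    metric_id: str = "",
    config_id: str = "",
    delta: float = DELTA_AIC,
    peak_grid: int = 501,
) -> TrajectoryFit:
    """Fit null/linear/smooth models to one metric series and select.

    Requires at least 4 points for the smooth model (otherwise only
    null/linear are attempted and the smooth AIC is +inf). The smooth
    peak age is the argmax of the fitted spline on a dense age grid.
    """
    x = np.asarray(ages, dtype=float)
    y = np.asarray(values, dtype=float)
    ok = np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(y)
    if n < 2:
        raise InvalidInputError("need at least 2 finite points")
    if np.ptp(x) == 0:
        raise InvalidInputError("ages are constant; no trajectory to fit")

    designs = {"null": np.ones((n, 1)), "linear": np.column_stack([np.ones(n), x])}
    knots = None
    k1, k2, k3 = float(x.min()), float(np.median(x)), float(x.max())
    if n >= 4 and k1 < k2 < k3:
        knots = (k1, k2, k3)
        designs["smooth"] = np.column_stack(
            [np.ones(n), x, natural_spline_term(x, knots)]
        )

    aic, loglik, fitted, coef, rss = {}, {}, {}, {}, {}
    for name in MODELS:
        X = designs.get(name)
        if X is None or n <= X.shape[1]:
            aic[name] = math.inf
            loglik[name] = -math.inf
            continue
        b, r, ll = _gaussian_ml(X, y)
        coef[name] = b
        rss[name] = r
        loglik[name] = ll
        aic[name] = _aic(ll, X.shape[1])
        fitted[name] = X @ b

    selected = select_with_rule(aic["null"], aic["linear"], aic["smooth"], delta)

    # F-test of the two spline terms against the null (constant) model
    smooth_p = float("nan")
    if "smooth" in rss and n > 3:
        num = (rss["null"] - rss["smooth"]) / 2
        den = rss["smooth"] / (n - 3)
        if den > 0:
            smooth_p = float(stats.f.sf(num / den, 2, n - 3))
        else:
            smooth_p = 0.0

    peak_age = None
    peak_interior = False
    if selected == "smooth":
        grid = np.linspace(x.min(), x.max(), peak_grid)
        Xg = np.column_stack(
            [np.ones(peak_grid), grid, natural_spline_term(grid, knots)]
        )
        yg = Xg @ coef["smooth"]
        j = int(np.argmax(yg))
        peak_age = float(grid[j])
        peak_interior = 0 < j < peak_grid - 1

    sel_fit = fitted.get(selected)
    if sel_fit is None:
        net_change = 0.0
    else:
        net_change = float(sel_fit[np.argmax(x)] - sel_fit[np.argmin(x)])

    return TrajectoryFit(
        metric_id=metric_id,
        config_id=config_id,
        aic=aic,
        loglik=loglik,
        selected=selected,
        smooth_p=smooth_p,
        fitted_values=fitted,
        coef=coef,
        knots=knots,
        peak_age=peak_age,
        peak_interior=peak_interior,
        net_change=net_change,
    )


def fdr_correct(p_values: Sequence[float], alpha: float = 0.05):
    """Benjamini-Hochberg step-up. Returns (reject flags, adjusted p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise InvalidInputError("empty p-value vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InvalidInputError("p-values must lie in [0, 1]")
    reject, p_adj, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject, p_adj


@dataclass
class ConsensusReport:
    """Whether a finding recurs in more than ``fraction`` of configurations."""

    finding_id: tuple
    n_configs_detected: int
    n_configs_total: int
    reported: bool


def consensus(
    detected_by_config: Sequence[bool], finding_id=("",), fraction: float = 0.5
) -> ConsensusReport:
    """Report a finding iff detected in strictly more than ``fraction``
    of the window configurations (e.g. 5 of 9 counts, 4 of 9 does not)."""
    flags = list(detected_by_config)
    if not flags:
        raise InvalidInputError("no configurations supplied")
    n_det = sum(bool(f) for f in flags)
    return ConsensusReport(
        finding_id=tuple(finding_id),
        n_configs_detected=n_det,
        n_configs_total=len(flags),
        reported=n_det / len(flags) > fraction,
    )


def consensus_findings(
    fits_by_config: dict, fraction: float = 0.5, match: str = "model_direction"
) -> ConsensusReport:
    """Consensus over per-configuration :class:`TrajectoryFit` objects.

    A "finding" is matched across configurations as the modal
    (selected model, direction) pair (``match="model_direction"``) or
    just the selected model (``match="model"``); configurations whose
    fit matches the modal finding count as detections.
    """
    if not fits_by_config:
        raise InvalidInputError("no configurations supplied")
    keys = []
    for fit in fits_by_config.values():
        keys.append(
            (fit.selected, fit.direction) if match == "model_direction" else (fit.selected,)
        )
    vals, counts = np.unique([str(k) for k in keys], return_counts=True)
    modal = keys[[str(k) for k in keys].index(vals[np.argmax(counts)])]
    flags = [k == modal for k in keys]
    metric = next(iter(fits_by_config.values())).metric_id
    return consensus(flags, finding_id=(metric, *modal), fraction=fraction)
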