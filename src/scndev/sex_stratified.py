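"""Sex-stratified networks and sex-interaction trajectory comparison.

The core pipeline is re-run inside each sex: residualization uses only
cohort and scanner (sex is constant within a stratum), bins are rebuilt
from the stratum's own age-sorted scan pool at the full bin size, and
networks/metrics are computed with the same machinery. Global
trajectories are compared between sexes with a shared-smooth model
(one spline of age plus a sex offset) against a by-sex model (separate
splines per sex), selected under the same AIC-margin rule. Modular
densities are normalized by each stratum's own global density and are
reported descriptively only, never tested across sexes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import graph_metrics as gm
from ._utils import derive_seed
from .errors import InvalidInputError
from .networks import BootstrapSpec, bootstrap_threshold, residualize
from .trajectories import DELTA_AIC, _aic, _gaussian_ml, natural_spline_term
from .windows import WindowConfig, build_bins

STRATIFIED_COVARIATES = ("cohort", "scanner")


@dataclass
class SexStratifiedRun:
    """Outputs of the network pipeline inside one sex stratum."""

    sex: int
    config: WindowConfig
    bins: list
    networks: list
    metrics: pd.DataFrame
    global_density_by_bin: pd.DataFrame  # columns: median_age, value
    skipped: bool = False


def stratified_pipeline(
    scan_table: pd.DataFrame,
    sex: int,
    window_config: WindowConfig,
    spec: BootstrapSpec,
    modules: Optional[np.ndarray] = None,
) -> SexStratifiedRun:
    """Run residualize -> bins -> threshold -> metrics within one sex.

    A stratum smaller than the bin size cannot form a single window; the
    configuration is then skipped with a warning and an empty, flagged
    result is returned.
    """
    stratum = scan_table[scan_table["sex"] == sex].reset_index(drop=True)
    if len(stratum) < window_config.bin_size:
        warnings.warn(
            f"stratum sex={sex} has {len(stratum)} scans < bin_size "
            f"{window_config.bin_size}; configuration skipped",
            stacklevel=2,
        )
        return SexStratifiedRun(
            sex=sex,
            config=window_config,
            bins=[],
            networks=[],
            metrics=pd.DataFrame(),
            global_density_by_bin=pd.DataFrame(columns=["median_age", "value"]),
            skipped=True,
        )
    resid = residualize(stratum, covariates=STRATIFIED_COVARIATES)
    bins = build_bins(resid, window_config)
    networks = []
    metric_frames = []
    density_rows = []
    region_ids = None
    for b in bins:
        net = bootstrap_threshold(
            resid,
            b,
            BootstrapSpec(
                B=spec.B,
                alpha=spec.alpha,
                seed=derive_seed(spec.seed, window_config.config_id, b.index),
            ),
        )
        networks.append(net)
        region_ids = net.region_ids
        density_rows.append(
            {"median_age": b.median_age, "value": gm.global_density(net.retained)}
        )
        if modules is not None:
            metric_frames.append(
                gm.metrics_frame(
                    net.retained,
                    modules,
                    region_ids,
                    b.index,
                    b.median_age,
                    window_config.config_id,
                )
            )
    metrics = pd.concat(metric_frames, ignore_index=True) if metric_frames else pd.DataFrame()
    return SexStratifiedRun(
        sex=sex,
        config=window_config,
        bins=bins,
        networks=networks,
        metrics=metrics,
        global_density_by_bin=pd.DataFrame(density_rows),
    )


@dataclass
class SexComparisonFit:
    """Shared-smooth vs by-sex-smooth comparison for one global metric."""

    aic_smooth_shared: float
    aic_smooth_by_sex: float
    loglik_shared: float
    loglik_by_sex: float
    selected: str  # "shared" | "by_sex"


def sex_interaction_fit(
    series_female: pd.DataFrame,
    series_male: pd.DataFrame,
    delta: float = DELTA_AIC,
) -> SexComparisonFit:
    """Compare a shared smooth of age (plus sex offset) to separate smooths.

    Both models are Gaussian ML fits to the pooled (age, value) points
    of the two strata; knots sit at the pooled min/median/max age. The
    by-sex model is selected only when its AIC is at least ``delta``
    below the shared model's.
    """
    for name, s in (("female", series_female), ("male", series_male)):
        if s is None or len(s) == 0:
            raise InvalidInputError(f"{name} series is empty")
    x = np.concatenate(
        [series_female["median_age"].to_numpy(), series_male["median_age"].to_numpy()]
    )
    y = np.concatenate(
        [series_female["value"].to_numpy(), series_male["value"].to_numpy()]
    )
    sex = np.concatenate(
        [np.ones(len(series_female)), np.zeros(len(series_male))]
    )
    k1, k2, k3 = float(x.min()), float(np.median(x)), float(x.max())
    if not k1 < k2 < k3:
        raise InvalidInputError("degenerate pooled age distribution")
    spline = np.column_stack([x, natural_spline_term(x, (k1, k2, k3))])
    X_shared = np.column_stack([np.ones(len(x)), sex, spline])
    X_by_sex = np.column_stack(
        [np.ones(len(x)), sex, spline, spline * sex[:, None]]
    )
    _, _, ll_shared = _gaussian_ml(X_shared, y)
    _, _, ll_by_sex = _gaussian_ml(X_by_sex, y)
    aic_shared = _aic(ll_shared, X_shared.shape[1])
    aic_by_sex = _aic(ll_by_sex, X_by_sex.shape[1])
    selected = "by_sex" if aic_by_sex <= aic_shared - delta else "shared"
    return SexComparisonFit(
        aic_smooth_shared=aic_shared,
        aic_smooth_by_sex=aic_by_sex,
        loglik_shared=ll_shared,
        loglik_by_sex=ll_by_sex,
        selected=selected,
    )
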