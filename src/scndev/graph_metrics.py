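"""Graph metrics of binarized covariance networks.

Deliberately restricted to density- and degree-based measures: the
bootstrap thresholding yields networks of varying density, which would
confound comparisons of higher-order metrics across bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, InvalidInputError


def _check_adjacency(adj: np.ndarray) -> np.ndarray:
    adj = np.asarray(adj)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise InvalidInputError("adjacency must be square")
    if adj.shape[0] < 2:
        raise InvalidInputError("network must have at least 2 nodes")
    if not np.array_equal(adj, adj.T):
        raise InvalidInputError("adjacency must be symmetric")
    if not np.isin(adj, (0, 1)).all():
        raise InvalidInputError("adjacency must be binary")
    if np.diagonal(adj).any():
        raise InvalidInputError("adjacency must have a zero diagonal")
    return adj


def global_density(adj: np.ndarray) -> float:
    """Fraction of all possible region pairs that are connected."""
    adj = _check_adjacency(adj)
    P = adj.shape[0]
    return float(adj.sum() / (P * (P - 1)))


def degree(adj: np.ndarray) -> np.ndarray:
    """Connections per region."""
    return _check_adjacency(adj).sum(axis=1)


def standardized_degree(adj: np.ndarray) -> np.ndarray:
    """Degree in SD units within the network (sample SD, n-1 denominator).

    A regular graph (constant degree) returns all zeros with a warning,
    so tiny degenerate networks yield "no hubs" rather than an error.
    """
    k = degree(adj)
    sd = k.std(ddof=1)
    if sd == 0:
        warnings.warn("constant degree; standardized degree set to 0", stacklevel=2)
        return np.zeros(len(k))
    return (k - k.mean()) / sd


@dataclass
class HubSet:
    """Regions with standardized degree > threshold in >= min_bins bins."""

    is_hub: np.ndarray
    n_bins_as_hub: np.ndarray
    threshold: float
    min_bins: int


def identify_hubs(
    z_degree_by_bin: np.ndarray, threshold: float = 1.0, min_bins: int = 2
) -> HubSet:
    """Classify hubs from a (bins x regions) standardized-degree array.

    A region is a hub when its standardized degree strictly exceeds
    ``threshold`` in at least ``min_bins`` bins.
    """
    z = np.asarray(z_degree_by_bin, dtype=float)
    if z.ndim != 2:
        raise InvalidInputError("expected a (bins x regions) array")
    if min_bins > z.shape[0]:
        raise InvalidConfigError(
            f"min_bins={min_bins} exceeds the {z.shape[0]} available bins"
        )
    counts = (z > threshold).sum(axis=0)
    return HubSet(
        is_hub=counts >= min_bins,
        n_bins_as_hub=counts,
        threshold=threshold,
        min_bins=min_bins,
    )


@dataclass
class ModularDensity:
    """Intra-/inter-modular densities, optionally normalized by global density."""

    intra: dict  # module -> density
    inter: dict  # (module_a, module_b), a < b -> density
    normalized: bool
    global_density_used: float


def modular_density(
    adj: np.ndarray, modules: Sequence[int], normalize: bool = True
) -> ModularDensity:
    """Within- and between-module edge densities.

    Raw intra-density of module m is (edges within m) / C(n_m, 2); raw
    inter-density of modules (a, b) is (edges between) / (n_a * n_b).
    With ``normalize`` the values are divided by the network's global
    density; a zero global density (or a singleton module) yields NaN so
    downstream fits can skip the value.
    """
    adj = _check_adjacency(adj)
    modules = np.asarray(modules)
    if len(modules) != adj.shape[0]:
        raise InvalidInputError("one module label per region required")
    gd = global_density(adj)
    labels = np.unique(modules)
    scale = np.nan if (normalize and gd == 0) else (gd if normalize else 1.0)

    intra = {}
    for m in labels:
        idx = np.flatnonzero(modules == m)
        n_m = len(idx)
        if n_m < 2:
            intra[int(m)] = float("nan")
            continue
        edges = adj[np.ix_(idx, idx)].sum() / 2
        raw = edges / (n_m * (n_m - 1) / 2)
        intra[int(m)] = float(raw / scale) if normalize else float(raw)
    inter = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            ia = np.flatnonzero(modules == a)
            ib = np.flatnonzero(modules == b)
            raw = adj[np.ix_(ia, ib)].sum() / (len(ia) * len(ib))
            inter[(int(a), int(b))] = float(raw / scale) if normalize else float(raw)
    return ModularDensity(
        intra=intra, inter=inter, normalized=normalize, global_density_used=gd
    )


def metrics_frame(
    adj: np.ndarray,
    modules: Sequence[int],
    region_ids: Sequence[str],
    bin_index: int,
    median_age: float,
    config_id: str,
) -> pd.DataFrame:
    """Tidy table of all metrics of one network.

    One row per (metric, target): global density, per-region degree and
    standardized degree, and normalized intra-/inter-modular densities.
    """
    rows = [
        {
            "config_id": config_id,
            "bin_index": bin_index,
            "median_age": median_age,
            "metric": "global_density",
            "target": "global",
            "value": global_density(adj),
        }
    ]
    k = degree(adj)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        z = standardized_degree(adj)
    for rid, kk, zz in zip(region_ids, k, z):
        rows.append(
            {
                "config_id": config_id,
                "bin_index": bin_index,
                "median_age": median_age,
                "metric": "degree",
                "target": rid,
                "value": float(kk),
            }
        )
        rows.append(
            {
                "config_id": config_id,
                "bin_index": bin_index,
                "median_age": median_age,
                "metric": "z_degree",
                "target": rid,
                "value": float(zz),
            }
        )
    md = modular_density(adj, modules, normalize=True)
    for m, v in md.intra.items():
        rows.append(
            {
                "config_id": config_id,
                "bin_index": bin_index,
                "median_age": median_age,
                "metric": "norm_intra",
                "target": f"M{m}",
                "value": v,
            }
        )
    for (a, b), v in md.inter.items():
        rows.append(
            {
                "config_id": config_id,
                "bin_index": bin_index,
                "median_age": median_age,
                "metric": "norm_inter",
                "target": f"M{a}-M{b}",
                "value": v,
            }
        )
    return pd.DataFrame(rows)
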