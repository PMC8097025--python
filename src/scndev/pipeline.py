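"""End-to-end orchestration: simulate -> windows -> networks -> metrics ->
trajectories -> thinning -> sex, with deterministic seeding and a hashed
output manifest.

Every randomized stage derives its seed from the run's root seed plus a
stage/configuration/bin tag, so reruns with the same configuration and
root seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import graph_metrics as gm
from . import io as scnio
from ._utils import derive_seed
from .errors import InvalidConfigError
from .networks import (
    BootstrapSpec,
    bootstrap_threshold,
    mean_correlation,
    residualize,
)
from .sex_stratified import sex_interaction_fit, stratified_pipeline
from .synthetic import (
    Parcellation,
    SyntheticConfig,
    generate_dataset,
    generate_parcellation,
)
from .thinning import SurrogateSpec, fit_thinning_rates, thinning_degree_association
from .trajectories import consensus_findings, fdr_correct, fit_trajectory
from .windows import (
    DEFAULT_BIN_SIZES,
    DEFAULT_STEP_FRACTIONS,
    WindowConfig,
    bins_to_frame,
    build_bins,
    enumerate_configs,
)

_BLOCK_KEYS = {
    "simulate": None,  # validated against SyntheticConfig fields
    "input": {"scan_table", "parcellation_dir"},
    "window": {"bin_sizes", "step_fractions"},
    "bootstrap": {"B", "alpha"},
    "trajectory": {"delta_aic", "consensus_fraction", "fdr_alpha"},
    "surrogate": {"n_surr", "kernel_grid", "n_distance_bins"},
    "hub": {"threshold", "min_bins"},
    "root_seed": None,
    "out_dir": None,
}


@dataclass
class RunConfig:
    """Validated run configuration with the study's default settings."""

    simulate: Optional[dict] = field(default_factory=dict)
    scan_table: Optional[str] = None
    parcellation_dir: Optional[str] = None
    bin_sizes: tuple = DEFAULT_BIN_SIZES
    step_fractions: tuple = DEFAULT_STEP_FRACTIONS
    bootstrap_B: int = 1000
    bootstrap_alpha: float = 0.05
    delta_aic: float = 3.0
    consensus_fraction: float = 0.5
    fdr_alpha: float = 0.05
    n_surr: int = 1000
    kernel_grid: tuple = (3, 5, 10, 20)
    n_distance_bins: int = 10
    hub_threshold: float = 1.0
    hub_min_bins: int = 2
    root_seed: int = 0
    out_dir: str = "scn_out"

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - set(_BLOCK_KEYS)
        if unknown:
            raise InvalidConfigError(f"unknown configuration keys: {sorted(unknown)}")
        kw: dict = {}
        sim = raw.get("simulate")
        if sim is not None:
            valid = {f.name for f in dataclasses.fields(SyntheticConfig)}
            bad = set(sim) - valid
            if bad:
                raise InvalidConfigError(f"unknown simulate keys: {sorted(bad)}")
            kw["simulate"] = dict(sim)
        for block, keys in _BLOCK_KEYS.items():
            if keys is None or block not in raw:
                continue
            sub = raw[block]
            bad = set(sub) - keys
            if bad:
                raise InvalidConfigError(
                    f"unknown keys in '{block}' block: {sorted(bad)}"
                )
            if block == "input":
                kw.update({k: sub[k] for k in sub})
            elif block == "window":
                if "bin_sizes" in sub:
                    kw["bin_sizes"] = tuple(sub["bin_sizes"])
                if "step_fractions" in sub:
                    kw["step_fractions"] = tuple(sub["step_fractions"])
            elif block == "bootstrap":
                if "B" in sub:
                    kw["bootstrap_B"] = int(sub["B"])
                if "alpha" in sub:
                    kw["bootstrap_alpha"] = float(sub["alpha"])
            elif block == "trajectory":
                kw.update({k: float(sub[k]) for k in sub})
            elif block == "surrogate":
                if "n_surr" in sub:
                    kw["n_surr"] = int(sub["n_surr"])
                if "kernel_grid" in sub:
                    kw["kernel_grid"] = tuple(sub["kernel_grid"])
                if "n_distance_bins" in sub:
                    kw["n_distance_bins"] = int(sub["n_distance_bins"])
            elif block == "hub":
                if "threshold" in sub:
                    kw["hub_threshold"] = float(sub["threshold"])
                if "min_bins" in sub:
                    kw["hub_min_bins"] = int(sub["min_bins"])
        if "root_seed" in raw:
            kw["root_seed"] = int(raw["root_seed"])
        if "out_dir" in raw:
            kw["out_dir"] = str(raw["out_dir"])
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)


def load_or_simulate(cfg: RunConfig):
    """Return (scan_table, parcellation, ground_truth_or_None)."""
    if cfg.scan_table is not None:
        if cfg.parcellation_dir is None:
            raise InvalidConfigError("scan_table given without parcellation_dir")
        parc = scnio.read_parcellation(cfg.parcellation_dir)
        table = scnio.read_scan_table(cfg.scan_table, parc)
        return table, parc, None
    sim = dict(cfg.simulate or {})
    sim.setdefault("seed", derive_seed(cfg.root_seed, "simulate"))
    scfg = SyntheticConfig(**sim)
    parc = generate_parcellation(
        scfg.n_regions, scfg.n_modules, seed=derive_seed(cfg.root_seed, "parcellation")
    )
    table, truth = generate_dataset(scfg, parc)
    return table, parc, truth


def threshold_config(
    resid: pd.DataFrame, config: WindowConfig, cfg: RunConfig
) -> tuple[list, list]:
    """Bins and bootstrap-thresholded networks for one window configuration."""
    bins = build_bins(resid, config)
    nets = [
        bootstrap_threshold(
            resid,
            b,
            BootstrapSpec(
                B=cfg.bootstrap_B,
                alpha=cfg.bootstrap_alpha,
                seed=derive_seed(cfg.root_seed, "boot", config.config_id, b.index),
            ),
        )
        for b in bins
    ]
    return bins, nets


def global_series(bins, nets) -> pd.DataFrame:
    """Per-bin global density and positive mean correlation."""
    return pd.DataFrame(
        {
            "median_age": [b.median_age for b in bins],
            "global_density": [gm.global_density(n.retained) for n in nets],
            "mean_correlation": [mean_correlation(
                dataclasses.replace(n, retained=None)) for n in nets],
        }
    )


def reference_config(configs: list) -> WindowConfig:
    """The presentation configuration: the median of the enumerated list."""
    return configs[len(configs) // 2]


def run_all(cfg: RunConfig) -> dict:
    """Execute every stage for every window configuration; write outputs
    and a manifest of content hashes to ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    table, parc, truth = load_or_simulate(cfg)
    p = out / "scan_table.csv"
    scnio.write_scan_table(table, p)
    written.append(p)
    written.extend(scnio.write_parcellation(parc, out))
    if truth is not None:
        p = out / "ground_truth.json"
        scnio.write_ground_truth(truth, p)
        written.append(p)

    resid = residualize(table)
    configs = enumerate_configs(cfg.bin_sizes, cfg.step_fractions)
    modules = parc.modules

    all_metrics = []
    series_by_config: dict = {}
    z_by_config: dict = {}
    nets_by_config: dict = {}
    bins_by_config: dict = {}
    for wc in configs:
        bins, nets = threshold_config(resid, wc, cfg)
        bins_by_config[wc.config_id] = bins
        nets_by_config[wc.config_id] = nets
        manifest_df = bins_to_frame(bins, wc)
        p = out / f"bins_{wc.config_id}.csv"
        manifest_df.to_csv(p, index=False, float_format="%.12g")
        written.append(p)
        frames = [
            gm.metrics_frame(
                n.retained, modules, n.region_ids, b.index, b.median_age, wc.config_id
            )
            for b, n in zip(bins, nets)
        ]
        metrics = pd.concat(frames, ignore_index=True)
        all_metrics.append(metrics)
        series_by_config[wc.config_id] = global_series(bins, nets)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            z_by_config[wc.config_id] = np.array(
                [gm.standardized_degree(n.retained) for n in nets]
            )
    metrics_all = pd.concat(all_metrics, ignore_index=True)
    p = out / "metrics.csv"
    metrics_all.to_csv(p, index=False, float_format="%.12g")
    written.append(p)

    # trajectories: global metrics per configuration + consensus
    fit_rows = []
    global_fits = {m: {} for m in ("global_density", "mean_correlation")}
    for wc in configs:
        s = series_by_config[wc.config_id]
        for metric in ("global_density", "mean_correlation"):
            fit = fit_trajectory(
                s["median_age"], s[metric], metric_id=metric,
                config_id=wc.config_id, delta=cfg.delta_aic,
            )
            global_fits[metric][wc.config_id] = fit
            fit_rows.append(_fit_row(fit))
    # nodal: hub regions per configuration, FDR over smooth p-values
    region_ids = nets_by_config[configs[0].config_id][0].region_ids
    for wc in configs:
        z = z_by_config[wc.config_id]
        hubs = gm.identify_hubs(z, cfg.hub_threshold, cfg.hub_min_bins)
        ages = [b.median_age for b in bins_by_config[wc.config_id]]
        nodal_fits = []
        for j in np.flatnonzero(hubs.is_hub):
            fit = fit_trajectory(
                ages, z[:, j], metric_id=f"z_degree[{region_ids[j]}]",
                config_id=wc.config_id, delta=cfg.delta_aic,
            )
            nodal_fits.append(fit)
        _append_fdr_rows(fit_rows, nodal_fits, cfg.fdr_alpha)
        # modular densities
        mod_metrics = metrics_all[
            (metrics_all["config_id"] == wc.config_id)
            & metrics_all["metric"].isin(["norm_intra", "norm_inter"])
        ]
        mod_fits = []
        for target, sub in mod_metrics.groupby("target"):
            sub = sub.sort_values("bin_index")
            vals = sub["value"].to_numpy()
            if np.isfinite(vals).sum() < 4:
                continue
            fit = fit_trajectory(
                sub["median_age"], vals,
                metric_id=f"{sub['metric'].iloc[0]}[{target}]",
                config_id=wc.config_id, delta=cfg.delta_aic,
            )
            mod_fits.append(fit)
        _append_fdr_rows(fit_rows, mod_fits, cfg.fdr_alpha)
    fits_df = pd.DataFrame(fit_rows)
    p = out / "trajectory_fits.csv"
    fits_df.to_csv(p, index=False, float_format="%.12g")
    written.append(p)

    cons_rows = []
    for metric, fits in global_fits.items():
        rep = consensus_findings(fits, fraction=cfg.consensus_fraction)
        cons_rows.append(
            {
                "finding_id": "|".join(str(x) for x in rep.finding_id),
                "n_configs_detected": rep.n_configs_detected,
                "n_configs_total": rep.n_configs_total,
                "reported": rep.reported,
            }
        )
    cons_df = pd.DataFrame(cons_rows)
    p = out / "consensus.csv"
    cons_df.to_csv(p, index=False)
    written.append(p)

    # thinning-degree association, oldest bin of every configuration
    rates = fit_thinning_rates(table)
    p = out / "thinning_rates.csv"
    rates.to_csv(p, float_format="%.12g")
    written.append(p)
    surr_spec_base = dict(
        n_surr=cfg.n_surr,
        kernel_grid=cfg.kernel_grid,
        n_distance_bins=cfg.n_distance_bins,
    )
    thin_rows = []
    for wc in configs:
        nets = nets_by_config[wc.config_id]
        for which, idx in (("oldest", -1), ("youngest", 0)):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                z = gm.standardized_degree(nets[idx].retained)
            zs = pd.Series(z, index=region_ids)
            spec = SurrogateSpec(
                seed=derive_seed(cfg.root_seed, "surr", wc.config_id, which),
                **surr_spec_base,
            )
            res = thinning_degree_association(rates, zs, parc, spec)
            for hemi, t in res.items():
                thin_rows.append(
                    {
                        "config_id": wc.config_id,
                        "bin": which,
                        "hemisphere": hemi,
                        "r": t.r_empirical,
                        "p": t.p_nonparametric,
                        "degenerate": t.degenerate,
                    }
                )
    thin_df = pd.DataFrame(thin_rows)
    p = out / "thinning_association.csv"
    thin_df.to_csv(p, index=False, float_format="%.12g")
    written.append(p)

    # sex-stratified global density + interaction comparison (reference config)
    ref = reference_config(configs)
    sex_rows = []
    runs = {}
    for sex in (0, 1):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            run = stratified_pipeline(
                table,
                sex,
                ref,
                BootstrapSpec(
                    B=cfg.bootstrap_B,
                    alpha=cfg.bootstrap_alpha,
                    seed=derive_seed(cfg.root_seed, "sex", sex),
                ),
                modules=modules,
            )
        runs[sex] = run
        for _, row in run.global_density_by_bin.iterrows():
            sex_rows.append(
                {
                    "config_id": ref.config_id,
                    "sex": sex,
                    "median_age": row["median_age"],
                    "global_density": row["value"],
                }
            )
    sex_df = pd.DataFrame(sex_rows)
    sex_result = {}
    if not runs[0].skipped and not runs[1].skipped:
        comp = sex_interaction_fit(
            runs[1].global_density_by_bin.rename(columns={"value": "value"}),
            runs[0].global_density_by_bin.rename(columns={"value": "value"}),
            delta=cfg.delta_aic,
        )
        sex_result = {
            "aic_smooth_shared": comp.aic_smooth_shared,
            "aic_smooth_by_sex": comp.aic_smooth_by_sex,
            "selected": comp.selected,
        }
    p = out / "sex_density.csv"
    sex_df.to_csv(p, index=False, float_format="%.12g")
    written.append(p)
    p = out / "sex_comparison.json"
    p.write_text(json.dumps(sex_result, indent=1, sort_keys=True))
    written.append(p)

    params = {
        "root_seed": cfg.root_seed,
        "bin_sizes": list(cfg.bin_sizes),
        "step_fractions": list(cfg.step_fractions),
        "bootstrap_B": cfg.bootstrap_B,
        "bootstrap_alpha": cfg.bootstrap_alpha,
        "delta_aic": cfg.delta_aic,
        "consensus_fraction": cfg.consensus_fraction,
        "n_surr": cfg.n_surr,
        "hub_threshold": cfg.hub_threshold,
        "hub_min_bins": cfg.hub_min_bins,
    }
    manifest = scnio.write_manifest(written, out / "manifest.json", params=params)
    return manifest


def _fit_row(fit) -> dict:
    return {
        "metric_id": fit.metric_id,
        "config_id": fit.config_id,
        "aic_null": fit.aic["null"],
        "aic_linear": fit.aic["linear"],
        "aic_smooth": fit.aic["smooth"],
        "selected": fit.selected,
        "smooth_p": fit.smooth_p,
        "adjusted_p": np.nan,
        "peak_age": fit.peak_age if fit.peak_age is not None else np.nan,
        "net_change": fit.net_change,
    }


def _append_fdr_rows(fit_rows: list, fits: list, alpha: float) -> None:
    """Append fit rows for a batch, FDR-adjusting the smooth p-values."""
    if not fits:
        return
    ps = np.array([f.smooth_p for f in fits])
    ok = np.isfinite(ps)
    adj = np.full(len(fits), np.nan)
    if ok.any():
        _, adj_ok = fdr_correct(ps[ok], alpha=alpha)
        adj[ok] = adj_ok
    for f, a in zip(fits, adj):
        row = _fit_row(f)
        row["adjusted_p"] = a
        fit_rows.append(row)
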