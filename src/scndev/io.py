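"""Reading and writing the pipeline's plain-text formats.

Scan tables travel as tidy CSV (one row per scan, thickness columns
named by region id); parcellations as JSON (coords, hemispheres,
modules) plus per-hemisphere distance CSVs; correlation matrices as
square CSV; thresholded networks as edge lists (and optionally
GraphML); ground truth and diagnostics as JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Union

import networkx as nx
import numpy as np
import pandas as pd

from .errors import DimensionError, SchemaError
from .networks import CovarianceNetwork
from .synthetic import ID_COLUMNS, GroundTruth, Parcellation, region_columns

PathLike = Union[str, Path]


def write_scan_table(scan_table: pd.DataFrame, path: PathLike) -> None:
    scan_table.to_csv(path, index=False, float_format="%.12g")


def read_scan_table(path: PathLike, parcellation: Parcellation | None = None) -> pd.DataFrame:
    """Read and validate a scan table CSV.

    Checks required columns, uniqueness of (participant_id, scan_id),
    numeric thickness without missing values, and (when a parcellation
    is given) that the region columns match it.
    """
    df = pd.read_csv(path)
    missing = [c for c in ID_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"scan table missing required columns: {missing}")
    if df.duplicated(["participant_id", "scan_id"]).any():
        raise SchemaError("duplicate (participant_id, scan_id) rows")
    regions = region_columns(df)
    if not regions:
        raise SchemaError("scan table has no thickness columns")
    thick = df[regions]
    bad = thick.apply(lambda c: pd.to_numeric(c, errors="coerce")).isna()
    if bad.any().any():
        row = int(np.argwhere(bad.to_numpy())[0][0])
        raise SchemaError(f"non-numeric or missing thickness at row {row}")
    if parcellation is not None and list(regions) != list(parcellation.region_ids):
        raise DimensionError(
            f"table has {len(regions)} region columns, parcellation has "
            f"{parcellation.n_regions}; names must match in order"
        )
    return df


def write_parcellation(parc: Parcellation, out_dir: PathLike) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "region_ids": list(parc.region_ids),
        "hemisphere": parc.hemisphere.tolist(),
        "coords": parc.coords.tolist(),
        "modules": parc.modules.tolist(),
    }
    paths = [out / "parcellation.json"]
    paths[0].write_text(json.dumps(meta, indent=1))
    for hemi, mat in parc.distance.items():
        p = out / f"distance_{hemi}.csv"
        ids = parc.hemi_region_ids(hemi)
        pd.DataFrame(mat, index=ids, columns=ids).to_csv(p, float_format="%.12g")
        paths.append(p)
    return paths


def read_parcellation(in_dir: PathLike) -> Parcellation:
    in_dir = Path(in_dir)
    meta = json.loads((in_dir / "parcellation.json").read_text())
    parc = Parcellation(
        region_ids=list(meta["region_ids"]),
        hemisphere=np.array(meta["hemisphere"]),
        coords=np.array(meta["coords"], dtype=float),
        modules=np.array(meta["modules"], dtype=int),
        distance={},
    )
    for hemi in np.unique(parc.hemisphere):
        df = pd.read_csv(in_dir / f"distance_{hemi}.csv", index_col=0)
        parc.distance[str(hemi)] = df.to_numpy(dtype=float)
    return parc


def write_ground_truth(truth: GroundTruth, path: PathLike) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=1))


def write_matrix(matrix: np.ndarray, region_ids, path: PathLike) -> None:
    pd.DataFrame(matrix, index=region_ids, columns=region_ids).to_csv(
        path, float_format="%.12g"
    )


def write_edge_list(network: CovarianceNetwork, path: PathLike) -> None:
    iu = np.triu_indices(network.n_regions, k=1)
    mask = network.retained[iu] > 0
    pd.DataFrame(
        {
            "region_a": [network.region_ids[i] for i in iu[0][mask]],
            "region_b": [network.region_ids[j] for j in iu[1][mask]],
        }
    ).to_csv(path, index=False)


def write_graphml(network: CovarianceNetwork, path: PathLike) -> None:
    g = nx.Graph()
    g.add_nodes_from(network.region_ids)
    iu = np.triu_indices(network.n_regions, k=1)
    for i, j in zip(*iu):
        if network.retained[i, j]:
            g.add_edge(
                network.region_ids[i],
                network.region_ids[j],
                r=float(network.r[i, j]),
            )
    nx.write_graphml(g, path)


def file_sha256(path: PathLike) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(paths: list, out_path: PathLike, params: dict | None = None) -> dict:
    """Manifest JSON listing every output file with its content hash."""
    manifest = {
        "params": params or {},
        "files": {
            str(Path(p).name): file_sha256(p) for p in sorted(paths, key=str)
        },
    }
    Path(out_path).write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
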