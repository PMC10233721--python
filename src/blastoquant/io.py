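"""Readers and writers for the formats shared by all pipeline stages.

Tables are UTF-8 CSV, expression matrices Matrix Market (genes × cells, with
``genes.tsv``/``cells.tsv`` sidecars), image stacks TIFF with a JSON sidecar
recording channel names and axis convention, thresholds and run configs JSON.
All writers round-trip: ``read(write(x)) == x`` for every table/matrix type.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile
from scipy import sparse
from scipy.io import mmread, mmwrite

from .classify import MarkerThreshold
from .imaging import VoxelStack


class SchemaError(ValueError):
    """A file parsed but its contents violate the expected schema."""


# -- cell tables ------------------------------------------------------------

def write_cells_csv(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, index=False)


def read_cells_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"cell_id", "embryo_id", "stage", "volume", "compartment", "manual_exclude"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"cell table {path} lacks columns {sorted(missing)}")
    df["manual_exclude"] = df["manual_exclude"].astype(bool)
    return df


# -- thresholds -------------------------------------------------------------

def write_thresholds_json(thresholds: Mapping[str, MarkerThreshold], path: str | Path) -> None:
    payload = {marker: th.to_dict() for marker, th in thresholds.items()}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_thresholds_json(path: str | Path) -> dict[str, MarkerThreshold]:
    payload = json.loads(Path(path).read_text())
    return {marker: MarkerThreshold.from_dict(d) for marker, d in payload.items()}


# -- expression matrices ----------------------------------------------------

def write_expression_mtx(matrix: pd.DataFrame, outdir: str | Path) -> None:
    """Write a genes×cells matrix as matrix.mtx + genes.tsv + cells.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mmwrite(str(outdir / "matrix.mtx"), sparse.csr_matrix(matrix.to_numpy()))
    pd.Series(matrix.index).to_csv(outdir / "genes.tsv", sep="\t", index=False, header=False)
    pd.Series(matrix.columns).to_csv(outdir / "cells.tsv", sep="\t", index=False, header=False)


def read_expression_mtx(indir: str | Path) -> pd.DataFrame:
    indir = Path(indir)
    mat = np.asarray(mmread(str(indir / "matrix.mtx")).todense())
    genes = pd.read_csv(indir / "genes.tsv", sep="\t", header=None)[0].astype(str).tolist() \
        if (indir / "genes.tsv").stat().st_size else []
    cells = pd.read_csv(indir / "cells.tsv", sep="\t", header=None)[0].astype(str).tolist() \
        if (indir / "cells.tsv").stat().st_size else []
    if len(genes) != mat.shape[0]:
        raise SchemaError(
            f"genes.tsv lists {len(genes)} genes but matrix.mtx has {mat.shape[0]} rows"
        )
    if len(cells) != mat.shape[1]:
        raise SchemaError(
            f"cells.tsv lists {len(cells)} cells but matrix.mtx has {mat.shape[1]} columns"
        )
    return pd.DataFrame(mat, index=pd.Index(genes, name="gene"),
                        columns=pd.Index(cells, name="cell"))


def write_expression_csv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path)


def read_expression_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


# -- pseudotime and gene lists ----------------------------------------------

def write_pseudotime_csv(values: pd.Series, path: str | Path) -> None:
    values.rename("pseudotime").rename_axis("cell").to_csv(path)


def read_pseudotime_csv(path: str | Path) -> pd.Series:
    df = pd.read_csv(path)
    if df.shape[1] != 2:
        raise SchemaError(f"pseudotime file {path} must have two columns (cell, value)")
    return pd.Series(df.iloc[:, 1].to_numpy(dtype=float),
                     index=df.iloc[:, 0].astype(str), name="pseudotime")


def read_gene_list(path: str | Path) -> list[str]:
    lines = Path(path).read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip()]


def write_gene_list(genes: list[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(genes) + "\n")


# -- image stacks -----------------------------------------------------------

def write_stack_tiff(stack: VoxelStack, path: str | Path) -> None:
    """Write a stack as channel-first TIFF with a JSON sidecar (<path>.json)."""
    path = Path(path)
    tifffile.imwrite(path, stack.data, photometric="minisblack")
    sidecar = {
        "axes": "CZYX",
        "channels": list(stack.channels),
        "bit_depth": stack.bit_depth,
        "voxel_size": list(stack.voxel_size) if stack.voxel_size else None,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2) + "\n"
    )


def read_stack_tiff(path: str | Path) -> VoxelStack:
    path = Path(path)
    data = tifffile.imread(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        channels = meta["channels"]
        voxel_size = tuple(meta["voxel_size"]) if meta.get("voxel_size") else None
        bit_depth = meta.get("bit_depth")
    else:
        channels = [f"ch{i}" for i in range(data.shape[0])]
        voxel_size, bit_depth = None, None
    if data.ndim == 3:
        data = data[None]
    return VoxelStack(channels=channels, data=data, bit_depth=bit_depth,
                      voxel_size=voxel_size)


def write_mask_tiff(mask: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(path, np.asarray(mask, dtype=np.int32), photometric="minisblack")


def read_mask_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(path).astype(np.int32)


# -- provenance -------------------------------------------------------------

def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_run_config(config: Mapping, outdir: str | Path, name: str = "run_config.json") -> Path:
    """Write the resolved run configuration next to the outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / name
    path.write_text(json.dumps(dict(config), indent=2, sort_keys=True, default=str) + "\n")
    return path
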