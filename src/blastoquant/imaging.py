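"""Per-nucleus fluorescence quantification from 3D stacks and label masks.

A :class:`VoxelStack` holds a multi-channel ``(channel, z, y, x)`` intensity
grid.  Given a matching 3D integer label mask (0 = background), per-nucleus
volume, mean intensity and integrated density are measured per channel, the
same summaries a confocal quantification workflow exports.  Trophectoderm
nuclei are excluded by an explicit label list, mirroring manual curation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from skimage.measure import regionprops_table

from .simulate import CELL_TABLE_COLUMNS


@dataclass
class VoxelStack:
    """Multi-channel 3D intensity grid.

    ``data`` has shape ``(n_channels, z, y, x)`` aligned with ``channels``;
    intensities must be nonnegative.  ``voxel_size`` is an optional physical
    (z, y, x) voxel edge length used to report volumes in physical units.
    """

    channels: list[str]
    data: np.ndarray
    bit_depth: Optional[int] = None
    voxel_size: Optional[tuple[float, float, float]] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"data must be 4D (channel, z, y, x), got ndim={self.data.ndim}")
        if self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"{len(self.channels)} channel names for {self.data.shape[0]} channel planes"
            )
        if self.data.size and self.data.min() < 0:
            raise ValueError("intensities must be nonnegative")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channels.index(name)]


def rescale_to_8bit(stack: VoxelStack) -> VoxelStack:
    """Linearly rescale each channel to the 8-bit range [0, 255].

    Per channel, ``x -> (x - min) / (max - min) * 255`` with round-half-to-even
    rounding; a constant channel maps to all zeros.  The input stack is left
    unmodified.
    """
    out = np.empty_like(stack.data, dtype=np.uint8)
    for ci in range(stack.data.shape[0]):
        chan = stack.data[ci].astype(float)
        lo, hi = chan.min(), chan.max()
        if hi == lo:
            out[ci] = 0
        else:
            out[ci] = np.rint((chan - lo) / (hi - lo) * 255.0).astype(np.uint8)
    return VoxelStack(channels=list(stack.channels), data=out, bit_depth=8,
                      voxel_size=stack.voxel_size)


def measure_nuclei(
    stack: VoxelStack,
    mask: np.ndarray,
    stage: str,
    embryo_id: str,
) -> pd.DataFrame:
    """Measure volume, mean intensity and integrated density per nucleus.

    One row per nonzero label in ``mask``, ordered by label, with columns
    ``<marker>_mean`` and ``<marker>_intdens`` per channel where integrated
    density = mean × volume (voxel units).  When the stack carries a
    ``voxel_size``, a ``volume_physical`` column is added.  An empty mask
    yields an empty table.
    """
    mask = np.asarray(mask)
    if mask.shape != stack.spatial_shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match stack spatial shape {stack.spatial_shape}"
        )
    if not np.issubdtype(mask.dtype, np.integer):
        raise ValueError("mask must be an integer label grid")
    if mask.size and mask.min() < 0:
        raise ValueError("labels must be nonnegative (0 = background)")

    columns = CELL_TABLE_COLUMNS + [
        f"{m}_{s}" for m in stack.channels for s in ("mean", "intdens")
    ]
    if stack.voxel_size is not None:
        columns = columns + ["volume_physical"]
    if not np.any(mask):
        return pd.DataFrame(columns=columns)

    base = regionprops_table(mask, properties=("label", "area"))
    table = pd.DataFrame({"cell_id": base["label"].astype(int),
                          "volume": base["area"].astype(int)})
    for name in stack.channels:
        props = regionprops_table(mask, intensity_image=stack.channel(name),
                                  properties=("label", "intensity_mean"))
        means = pd.Series(props["intensity_mean"], index=props["label"].astype(int))
        table[f"{name}_mean"] = table["cell_id"].map(means)
        table[f"{name}_intdens"] = table[f"{name}_mean"] * table["volume"]
    table.insert(1, "embryo_id", embryo_id)
    table.insert(2, "stage", stage)
    table.insert(4, "compartment", "ICM")
    table.insert(5, "manual_exclude", False)
    if stack.voxel_size is not None:
        table["volume_physical"] = table["volume"] * float(np.prod(stack.voxel_size))
    return table.sort_values("cell_id").reset_index(drop=True)[columns]


def flag_compartment(records: pd.DataFrame, te_labels: Sequence[int]) -> pd.DataFrame:
    """Flag the listed labels as trophectoderm and exclude them from the ICM.

    Returns a copy with ``compartment="TE"`` and ``manual_exclude=True`` for
    every label in ``te_labels``; all other records are ICM.  An unknown label
    raises a ``ValueError`` naming it.
    """
    records = records.copy()
    present = set(records["cell_id"].tolist())
    for lab in te_labels:
        if lab not in present:
            raise ValueError(f"label {lab} not present in the record table")
    te = records["cell_id"].isin(set(te_labels))
    records.loc[:, "compartment"] = np.where(te, "TE", "ICM")
    records.loc[:, "manual_exclude"] = te
    return records
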