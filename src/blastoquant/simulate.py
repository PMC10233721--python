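"""Synthetic data generators with known ground truth.

Two domains are emulated:

* **image domain** — multi-channel 3D confocal-like voxel stacks of ICM nuclei
  with an integer label mask, where each nucleus draws its voxel intensities
  from a lineage-conditional log-normal (``gen_embryo_stack``), plus an
  image-free shortcut that draws per-nucleus intensities directly
  (``gen_intensity_table``);
* **expression domain** — a genes×cells count matrix along a single-branch
  trajectory where each gene switches on (or off) as a noisy sigmoid of
  pseudotime at a design-specified midpoint (``gen_expression``).

Every generator is a pure function of (parameters, seed).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .presets import (
    GeneSpec,
    StagePreset,
    SyntheticTruth,
    TrajectoryDesign,
)

CELL_TABLE_COLUMNS = ["cell_id", "embryo_id", "stage", "volume", "compartment", "manual_exclude"]


class PlacementError(RuntimeError):
    """Raised when non-overlapping nucleus placement fails (density too high)."""


def _draw_lineages(preset: StagePreset, rng: np.random.Generator, n: int) -> np.ndarray:
    lineages = np.array(preset.lineages, dtype=object)
    probs = np.array([preset.lineage_fractions[l] for l in lineages], dtype=float)
    return rng.choice(lineages, size=n, p=probs / probs.sum())


def _mean_volume_voxels(rng: np.random.Generator, n: int) -> np.ndarray:
    # nuclear volumes ~ log-normal around 300 voxels, mild spread
    return np.maximum(1, np.round(rng.lognormal(np.log(300.0), 0.2, size=n))).astype(int)


def gen_intensity_table(preset: StagePreset, seed: int) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw a per-nucleus intensity table without rendering voxels.

    Per-cell mean intensities come from the same lineage-conditional
    log-normal model as :func:`gen_embryo_stack`; integrated density is
    mean × volume.  Returns a cell table (one row per nucleus) and the
    ground-truth lineage labels.
    """
    rng = np.random.default_rng(seed)
    markers = preset.markers
    rows: list[dict] = []
    truth_labels: dict[int, str] = {}
    cell_id = 1
    for e in range(1, preset.n_embryos + 1):
        embryo_id = f"{preset.stage_name}_E{e}"
        lineages = _draw_lineages(preset, rng, preset.n_cells_icm)
        volumes = _mean_volume_voxels(rng, preset.n_cells_icm)
        for lin, vol in zip(lineages, volumes):
            row = {
                "cell_id": cell_id,
                "embryo_id": embryo_id,
                "stage": preset.stage_name,
                "volume": int(vol),
                "compartment": "ICM",
                "manual_exclude": False,
            }
            for marker in markers:
                p = preset.intensity_params[(lin, marker)]
                mean = float(rng.lognormal(p.mu, p.sigma)) if p.sigma > 0 else p.mode_location
                row[f"{marker}_mean"] = mean
                row[f"{marker}_intdens"] = mean * vol
            rows.append(row)
            truth_labels[cell_id] = str(lin)
            cell_id += 1
    columns = CELL_TABLE_COLUMNS + [f"{m}_{s}" for m in markers for s in ("mean", "intdens")]
    table = pd.DataFrame(rows, columns=columns)
    lineage = pd.Series(truth_labels, name="lineage", dtype=object)
    lineage.index.name = "cell_id"
    return table, SyntheticTruth(seed=seed, lineage=lineage)


def _place_centres(
    rng: np.random.Generator,
    n: int,
    shape: tuple[int, int, int],
    radii: np.ndarray,
    max_tries_per_cell: int = 2000,
) -> np.ndarray:
    """Rejection-sample non-overlapping ellipsoid centres inside the grid."""
    centres = np.empty((n, 3), dtype=float)
    placed = 0
    tries = 0
    budget = max_tries_per_cell * max(n, 1)
    while placed < n:
        if tries >= budget:
            raise PlacementError(
                f"could not place {n} non-overlapping nuclei in a grid of shape "
                f"{shape} after {budget} attempts; nucleus density too high"
            )
        tries += 1
        cand = np.array(
            [rng.uniform(radii[k] + 1, shape[k] - radii[k] - 1) for k in range(3)]
        )
        # conservative clearance: centre distance at least the sum of max radii
        if placed:
            d = np.linalg.norm(centres[:placed] - cand, axis=1)
            if np.any(d < 2.0 * radii.max() + 1.0):
                continue
        centres[placed] = cand
        placed += 1
    return centres


def gen_embryo_stack(
    preset: StagePreset,
    seed: int,
    radii: tuple[float, float, float] = (2.5, 3.5, 3.5),
    background: tuple[float, float] = (2.0, 0.5),
) -> tuple[np.ndarray, np.ndarray, SyntheticTruth]:
    """Render one embryo's ICM as a multi-channel 3D stack plus label mask.

    Nuclei are axis-aligned ellipsoids of half-axes ``radii`` (z, y, x) with
    small per-nucleus jitter, placed without overlap.  Voxels inside nucleus
    ``l`` in each marker channel are i.i.d. log-normal with that nucleus's
    lineage-conditional parameters; background voxels are a low Gaussian noise
    floor (clipped at zero), ``background=(mean, sd)``.

    Returns ``(stack, mask, truth)`` with ``stack`` of shape
    ``(n_channels, z, y, x)`` (float32, channel order ``preset.markers``) and
    ``mask`` an int32 label grid (0 = background, labels 1..n).
    """
    rng = np.random.default_rng(seed)
    n = preset.n_cells_icm
    markers = preset.markers
    radii_arr = np.asarray(radii, dtype=float)

    # size the grid for ~6% occupancy so rejection placement terminates fast
    cell_vol = 4.0 / 3.0 * np.pi * np.prod(radii_arr + 1.0)
    side = int(np.ceil((max(n, 1) * cell_vol / 0.06) ** (1.0 / 3.0)))
    side = max(side, int(2 * (radii_arr.max() + 2)) + 1)
    shape = (side, side, side)

    mask = np.zeros(shape, dtype=np.int32)
    bg_mean, bg_sd = background
    if bg_sd > 0:
        stack = np.clip(
            rng.normal(bg_mean, bg_sd, size=(len(markers), *shape)), 0, None
        ).astype(np.float32)
    else:
        stack = np.full((len(markers), *shape), float(bg_mean), dtype=np.float32)

    lineages = _draw_lineages(preset, rng, n)
    centres = _place_centres(rng, n, shape, radii_arr + 1.0)
    truth_labels: dict[int, str] = {}
    zz, yy, xx = np.indices(shape, sparse=True)
    for label, (lin, centre) in enumerate(zip(lineages, centres), start=1):
        jitter = rng.uniform(0.9, 1.1, size=3)
        r = radii_arr * jitter
        inside = (
            ((zz - centre[0]) / r[0]) ** 2
            + ((yy - centre[1]) / r[1]) ** 2
            + ((xx - centre[2]) / r[2]) ** 2
        ) <= 1.0
        mask[inside] = label
        nvox = int(inside.sum())
        for ci, marker in enumerate(markers):
            p = preset.intensity_params[(lin, marker)]
            if p.sigma > 0:
                vals = rng.lognormal(p.mu, p.sigma, size=nvox)
            else:
                vals = np.full(nvox, p.mode_location)
            stack[ci][inside] = vals
        truth_labels[label] = str(lin)

    lineage = pd.Series(truth_labels, name="lineage", dtype=object)
    lineage.index.name = "cell_id"
    return stack, mask, SyntheticTruth(seed=seed, lineage=lineage)


def sigmoid_mean(gene: GeneSpec, t: np.ndarray) -> np.ndarray:
    """Noise-free expected expression of ``gene`` at pseudotime ``t``."""
    t = np.asarray(t, dtype=float)
    z = gene.slope * (t - gene.midpoint)
    if gene.direction == "down":
        z = -z
    return gene.baseline + gene.amplitude / (1.0 + np.exp(-z))


def _sample_pseudotime(design: TrajectoryDesign, rng: np.random.Generator) -> np.ndarray:
    dist = design.pseudotime_distribution
    if dist == "uniform":
        return rng.uniform(0.0, 1.0, size=design.n_cells)
    if isinstance(dist, tuple) and dist[0] == "beta":
        _, a, b = dist
        return rng.beta(a, b, size=design.n_cells)
    raise ValueError(f"unknown pseudotime distribution {dist!r}")


def gen_expression(design: TrajectoryDesign) -> tuple[pd.DataFrame, pd.Series, SyntheticTruth]:
    """Simulate a genes×cells expression matrix along a single branch.

    Cells receive pseudotimes from the design's density on [0, 1]; each
    gene's expected value is its sigmoid mean, optionally rescaled by one
    global constant so the average per-cell total matches
    ``design.library_size`` (midpoints are invariant to this).  Noise is then
    applied per the design's noise model; counts are nonnegative.

    Returns ``(matrix, pseudotime, truth)``; ``truth`` records the pseudotime
    and every gene's true midpoint.
    """
    rng = np.random.default_rng(design.seed)
    t = np.sort(_sample_pseudotime(design, rng))
    cells = [f"cell_{i:04d}" for i in range(design.n_cells)]
    genes = design.gene_names

    mu = np.vstack([sigmoid_mean(g, t) for g in design.genes]) if genes else np.zeros((0, design.n_cells))
    if design.library_size is not None and design.n_cells > 0 and genes:
        factor = design.library_size / float(mu.sum(axis=0).mean())
        mu = mu * factor

    kind = design.noise_model[0]
    if kind == "none":
        values = mu
    elif kind == "negative_binomial":
        dispersion = design.noise_model[1]
        size = 1.0 / dispersion
        p = size / (size + mu)
        values = rng.negative_binomial(size, p).astype(float)
    else:  # lognormal, mean-preserving multiplicative noise
        sigma = design.noise_model[1]
        noise = rng.lognormal(-0.5 * sigma**2, sigma, size=mu.shape)
        values = mu * noise

    matrix = pd.DataFrame(values, index=pd.Index(genes, name="gene"),
                          columns=pd.Index(cells, name="cell"))
    pseudotime = pd.Series(t, index=matrix.columns, name="pseudotime")
    truth = SyntheticTruth(seed=design.seed, pseudotime=pseudotime,
                           midpoints=design.true_midpoints)
    return matrix, pseudotime, truth
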