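"""Domain types and default presets for the synthetic embryo and trajectory generators.

Stage presets encode the lineage composition of the human blastocyst inner
cell mass (ICM) at four developmental timepoints (D5, early D6, late D6, D7),
with per-(marker, lineage) log-normal nuclear-intensity parameters.  Trajectory
designs encode a single-branch differentiation trajectory along which genes
switch on as noisy sigmoids at staggered midpoints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import pandas as pd

STAGES = ("D5", "early_D6", "late_D6", "D7")

EPIBLAST = "epiblast"
HYPOBLAST = "hypoblast"
CO_EXPRESSING = "co_expressing"
NEGATIVE = "negative"

#: classes a classifier can emit; presets never generate ``negative`` cells
LINEAGES = (EPIBLAST, HYPOBLAST, CO_EXPRESSING, NEGATIVE)


@dataclass(frozen=True)
class LogNormalParams:
    """Parameters of a log-normal intensity distribution.

    ``mu`` and ``sigma`` are the mean and SD of the underlying normal in log
    space, i.e. intensities are ``exp(N(mu, sigma^2))``.  ``sigma == 0`` gives
    a constant intensity ``exp(mu)``.
    """

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")

    @property
    def mode_location(self) -> float:
        return math.exp(self.mu)


# Default low/high intensity modes (arbitrary units).  The low mode sits near
# 20 a.u. and the high mode near 180 a.u.; the modes are far more than four
# pooled SDs apart, so a two-component mixture separates them cleanly.
LOW_MODE = LogNormalParams(mu=math.log(20.0), sigma=0.25)
HIGH_MODE = LogNormalParams(mu=math.log(180.0), sigma=0.15)

#: which mode each lineage occupies for the two canonical nuclear markers
_MARKER_STATE = {
    (EPIBLAST, "OCT4"): HIGH_MODE,
    (EPIBLAST, "SOX17"): LOW_MODE,
    (HYPOBLAST, "OCT4"): LOW_MODE,
    (HYPOBLAST, "SOX17"): HIGH_MODE,
    (CO_EXPRESSING, "OCT4"): HIGH_MODE,
    (CO_EXPRESSING, "SOX17"): HIGH_MODE,
}


@dataclass(frozen=True)
class StagePreset:
    """Generator preset for one blastocyst stage.

    ``lineage_fractions`` must sum to one; ``intensity_params`` holds one
    log-normal per (marker, lineage) pair and must cover every lineage in
    ``lineage_fractions`` for every marker it references.
    ``n_cells_icm`` is the ICM cell count per embryo.
    """

    stage_name: str
    lineage_fractions: dict[str, float]
    n_cells_icm: int
    n_embryos: int
    intensity_params: dict[tuple[str, str], LogNormalParams]

    def __post_init__(self) -> None:
        if self.stage_name not in STAGES:
            raise ValueError(f"unknown stage {self.stage_name!r}; expected one of {STAGES}")
        total = sum(self.lineage_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"lineage fractions sum to {total}, not 1")
        for frac in self.lineage_fractions.values():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"lineage fraction {frac} outside [0, 1]")
        if self.n_cells_icm < 0 or self.n_embryos < 0:
            raise ValueError("cell and embryo counts must be nonnegative")
        for marker in self.markers:
            for lineage in self.lineage_fractions:
                if (lineage, marker) not in self.intensity_params:
                    raise ValueError(
                        f"marker {marker!r} lacks intensity parameters for lineage {lineage!r}"
                    )

    @property
    def markers(self) -> tuple[str, ...]:
        return tuple(sorted({m for (_, m) in self.intensity_params}))

    @property
    def lineages(self) -> tuple[str, ...]:
        return tuple(self.lineage_fractions)

    def with_size(self, n_cells_icm: int | None = None, n_embryos: int | None = None) -> "StagePreset":
        """Copy of this preset with overridden cohort size."""
        kwargs = {}
        if n_cells_icm is not None:
            kwargs["n_cells_icm"] = n_cells_icm
        if n_embryos is not None:
            kwargs["n_embryos"] = n_embryos
        return replace(self, **kwargs)


def _preset(stage: str, fractions: dict[str, float], n_cells: int) -> StagePreset:
    params = {
        (lin, marker): _MARKER_STATE[(lin, marker)]
        for lin in fractions
        for marker in ("OCT4", "SOX17")
    }
    return StagePreset(
        stage_name=stage,
        lineage_fractions=fractions,
        n_cells_icm=n_cells,
        n_embryos=5,
        intensity_params=params,
    )


# Stage-wise ICM lineage compositions observed by immunofluorescence for
# OCT4 (epiblast) and SOX17 (hypoblast).  "epiblast" at D5/early D6 means
# OCT4-positive-only cells; co_expressing cells carry both markers.
# Per-embryo ICM cell counts are package choices of realistic magnitude.
DEFAULT_PRESETS: dict[str, StagePreset] = {
    "D5": _preset("D5", {EPIBLAST: 0.64, CO_EXPRESSING: 0.36}, 40),
    "early_D6": _preset("early_D6", {EPIBLAST: 0.54, CO_EXPRESSING: 0.46}, 50),
    "late_D6": _preset("late_D6", {EPIBLAST: 0.38, CO_EXPRESSING: 0.44, HYPOBLAST: 0.18}, 60),
    "D7": _preset("D7", {EPIBLAST: 0.27, CO_EXPRESSING: 0.10, HYPOBLAST: 0.63}, 80),
}


@dataclass(frozen=True)
class GeneSpec:
    """One gene on the synthetic trajectory.

    The noise-free mean at pseudotime ``t`` is
    ``baseline + amplitude / (1 + exp(-slope * (t - midpoint)))`` for
    ``direction == "up"`` and the mirrored decreasing curve for ``"down"``.
    """

    name: str
    midpoint: float
    slope: float = 12.0
    baseline: float = 0.2
    amplitude: float = 4.0
    direction: str = "up"

    def __post_init__(self) -> None:
        if not 0.0 <= self.midpoint <= 1.0:
            raise ValueError(f"midpoint {self.midpoint} outside [0, 1]")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")
        if self.slope <= 0:
            raise ValueError("slope must be > 0")
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got {self.direction!r}")


#: canonical 16-gene hypoblast activation panel, in activation order
HYPOBLAST_PANEL = (
    "PDGFRA", "BMP2", "OTX2", "LGALS2", "VIL1", "SOX17", "FOXA2", "SALL1",
    "GATA4", "COL4A1", "RSPO3", "FRZB", "IGF1", "FLRT3", "CPN1", "SYT13",
)


@dataclass(frozen=True)
class TrajectoryDesign:
    """Design of a synthetic single-branch expression trajectory.

    noise_model is one of ``("none",)``, ``("negative_binomial", dispersion)``
    or ``("lognormal", sigma)``.  ``pseudotime_distribution`` is ``"uniform"``
    or ``("beta", a, b)``.  When ``library_size`` is set, all gene means are
    multiplied by one constant so that the expected per-cell total matches it;
    the scaling preserves every midpoint.  ``library_size=None`` leaves means
    in raw baseline/amplitude units.
    """

    n_cells: int
    genes: tuple[GeneSpec, ...]
    noise_model: tuple = ("negative_binomial", 0.1)
    pseudotime_distribution: object = "uniform"
    library_size: Optional[float] = 10_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be nonnegative")
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            raise ValueError("gene names must be unique")
        kind = self.noise_model[0]
        if kind == "negative_binomial":
            if len(self.noise_model) != 2 or self.noise_model[1] <= 0:
                raise ValueError("negative_binomial noise requires dispersion > 0")
        elif kind == "lognormal":
            if len(self.noise_model) != 2 or self.noise_model[1] <= 0:
                raise ValueError("lognormal noise requires sigma > 0")
        elif kind != "none":
            raise ValueError(f"unknown noise model {kind!r}")
        if self.library_size is not None and self.library_size <= 0:
            raise ValueError("library_size must be positive or None")

    @property
    def gene_names(self) -> list[str]:
        return [g.name for g in self.genes]

    @property
    def true_midpoints(self) -> pd.Series:
        return pd.Series({g.name: g.midpoint for g in self.genes}, name="true_midpoint")


def default_trajectory_design(
    n_cells: int = 600,
    noise_model: tuple = ("negative_binomial", 0.1),
    seed: int = 0,
    t_lo: float = 0.1,
    t_hi: float = 0.9,
) -> TrajectoryDesign:
    """16 activation-panel genes with midpoints equally spaced on [t_lo, t_hi]."""
    n = len(HYPOBLAST_PANEL)
    step = (t_hi - t_lo) / (n - 1)
    genes = tuple(
        GeneSpec(name=name, midpoint=t_lo + i * step) for i, name in enumerate(HYPOBLAST_PANEL)
    )
    return TrajectoryDesign(n_cells=n_cells, genes=genes, noise_model=noise_model, seed=seed)


@dataclass
class SyntheticTruth:
    """Generator-side ground truth for a synthetic dataset.

    Fields not applicable to a given generator are None: intensity-domain
    outputs carry ``lineage`` (per cell), expression-domain outputs carry
    ``pseudotime`` (per cell) and ``midpoints`` (per gene).
    """

    seed: int
    lineage: Optional[pd.Series] = None
    pseudotime: Optional[pd.Series] = None
    midpoints: Optional[pd.Series] = None

    def lineage_fractions(self) -> pd.Series:
        if self.lineage is None:
            raise ValueError("this truth object carries no lineage labels")
        if len(self.lineage) == 0:
            return pd.Series(dtype=float)
        return self.lineage.value_counts(normalize=True)
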