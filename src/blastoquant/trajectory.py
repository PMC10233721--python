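"""Gene-activation ordering along a differentiation branch.

The pipeline mirrors the hypoblast-branch analysis: (1) a per-cell branch
pseudotime on [0, 1], either imported from an upstream trajectory tool or
computed here as a seeded mutual-kNN graph geodesic from a root cell;
(2) kNN smoothing, replacing each cell's expression by the unweighted mean
over the cell and its k most similar cells (k = 30 by default, similarity
measured in a structure-gene feature space); (3) a four-parameter logistic
least-squares fit per gene,

    y(t) = b + A / (1 + exp(-s · (t - t0)))

(and the mirrored decreasing form), whose midpoint ``t0`` — the pseudotime at
which the curve reaches half its amplitude above baseline — is the gene's
activation tipping point; (4) ordering the genes by ascending ``t0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.sparse.csgraph import connected_components, dijkstra
from sklearn.neighbors import NearestNeighbors, kneighbors_graph


@dataclass(frozen=True)
class SmoothingParams:
    """Neighbourhood definition for smoothing and the kNN graph.

    ``structure_genes`` restricts the similarity feature space to a gene
    subset (e.g. an externally derived highly-structured gene list); ``None``
    uses all genes.  ``metric`` is ``euclidean_on_log`` (Euclidean distance on
    the log-normalised matrix) or ``pearson_distance`` (1 − Pearson
    correlation between cell profiles).
    """

    k_neighbors: int = 30
    structure_genes: Optional[tuple[str, ...]] = None
    metric: str = "euclidean_on_log"

    def __post_init__(self) -> None:
        if self.k_neighbors < 0:
            raise ValueError("k_neighbors must be >= 0")
        if self.metric not in ("euclidean_on_log", "pearson_distance"):
            raise ValueError(f"unknown metric {self.metric!r}")


def lognormalize(matrix: pd.DataFrame, already_normalized: bool = False) -> pd.DataFrame:
    """Library-size normalise counts to the median library, then log1p.

    ``already_normalized`` passes the matrix through untouched (for upstream
    embeddings whose values are already on a comparable scale).  Matrix is
    genes×cells.
    """
    if already_normalized:
        return matrix
    libs = matrix.sum(axis=0)
    target = float(np.median(libs[libs > 0])) if (libs > 0).any() else 1.0
    scaled = matrix.div(libs.replace(0, np.nan), axis=1).fillna(0.0) * target
    return np.log1p(scaled)


def _feature_matrix(matrix: pd.DataFrame, params: SmoothingParams) -> np.ndarray:
    """Cells×features array used for similarity searches."""
    if params.structure_genes is not None:
        missing = [g for g in params.structure_genes if g not in matrix.index]
        if missing:
            raise ValueError(f"structure genes absent from matrix: {missing[:5]}")
        matrix = matrix.loc[list(params.structure_genes)]
    return matrix.to_numpy().T


_SK_METRIC = {"euclidean_on_log": "euclidean", "pearson_distance": "correlation"}


def _neighbor_indices(features: np.ndarray, k: int, metric: str) -> np.ndarray:
    """(n_cells, k+1) index array: each row is the cell itself plus its k NN."""
    n = features.shape[0]
    if k >= n:
        raise ValueError(f"k_neighbors={k} must be < n_cells={n}")
    nn = NearestNeighbors(n_neighbors=min(k + 2, n), metric=_SK_METRIC[metric])
    nn.fit(features)
    _, idx = nn.kneighbors(features)
    rows = np.empty((n, k + 1), dtype=int)
    for i in range(n):
        others = [j for j in idx[i] if j != i][:k]
        rows[i] = [i] + others
    return rows


def smooth_expression(
    matrix: pd.DataFrame,
    params: SmoothingParams = SmoothingParams(),
    feature_space: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Replace each cell's expression by the mean over {cell} ∪ its k NN.

    Neighbours are found in structure-gene space — on ``feature_space`` when
    given (e.g. the log1p matrix, keeping the smoothed values on their
    original scale), otherwise on ``matrix`` itself.  The average is
    unweighted over k + 1 cells and the cell itself is always included.
    ``k_neighbors = 0`` is the identity.
    """
    if params.k_neighbors == 0:
        return matrix.copy()
    if feature_space is not None and list(feature_space.columns) != list(matrix.columns):
        raise ValueError("feature_space must cover the same cells in the same order")
    features = _feature_matrix(feature_space if feature_space is not None else matrix, params)
    rows = _neighbor_indices(features, params.k_neighbors, params.metric)
    values = matrix.to_numpy()
    smoothed = values[:, rows].mean(axis=2)  # genes × cells × (k+1) -> mean
    out = pd.DataFrame(smoothed, index=matrix.index, columns=matrix.columns)
    out.attrs["smoothed"] = True
    return out


@dataclass
class Pseudotime:
    """Per-cell branch pseudotime on [0, 1].

    ``values`` is indexed by cell; the root has pseudotime 0 and the farthest
    cell 1.  ``source`` records whether the vector was computed from the
    mutual-kNN geodesic or imported from an external file/vector.
    """

    values: pd.Series
    root: Optional[str]
    source: str

    def __post_init__(self) -> None:
        v = self.values
        if len(v) and (v.min() < -1e-12 or v.max() > 1 + 1e-12):
            raise ValueError("pseudotime must lie in [0, 1]")


def scale_pseudotime(values: pd.Series) -> pd.Series:
    """Min-max scale an external pseudotime vector to [0, 1]."""
    v = values.astype(float)
    lo, hi = v.min(), v.max()
    if hi == lo:
        raise ValueError("pseudotime vector has zero range")
    return (v - lo) / (hi - lo)


def external_pseudotime(values: pd.Series) -> Pseudotime:
    """Wrap an imported pseudotime vector (min-max scaled, otherwise untouched)."""
    scaled = scale_pseudotime(values)
    root = str(scaled.idxmin())
    return Pseudotime(values=scaled, root=root, source="external_file")


def compute_pseudotime(
    matrix: pd.DataFrame,
    params: SmoothingParams,
    root_cell: str,
    branch_cells: Optional[Sequence[str]] = None,
) -> Pseudotime:
    """Graph-geodesic pseudotime from a root cell over the mutual-kNN graph.

    The graph keeps an edge between two cells only when each lies among the
    other's k nearest neighbours in structure-gene space (edge weight =
    distance); pseudotime is the shortest-path distance from ``root_cell``,
    min-max scaled to [0, 1].  A disconnected branch graph is an error naming
    the number of components.
    """
    if branch_cells is not None:
        missing = [c for c in branch_cells if c not in matrix.columns]
        if missing:
            raise ValueError(f"branch cells absent from matrix: {missing[:5]}")
        matrix = matrix[list(branch_cells)]
    if root_cell not in matrix.columns:
        raise ValueError(f"root cell {root_cell!r} is not in the branch")
    features = _feature_matrix(matrix, params)
    n = features.shape[0]
    k = min(params.k_neighbors, n - 1)
    if k < 1:
        raise ValueError("need k_neighbors >= 1 and at least 2 cells")
    graph = kneighbors_graph(features, n_neighbors=k, mode="distance",
                             metric=_SK_METRIC[params.metric])
    # duplicate cells have distance 0; floor keeps those edges in the sparse graph
    graph.data = np.maximum(graph.data, 1e-12)
    mutual = graph.minimum(graph.T)  # keeps only reciprocated edges
    n_comp, _ = connected_components(mutual, directed=False)
    if n_comp > 1:
        raise ValueError(
            f"mutual-kNN graph is disconnected ({n_comp} components); "
            "increase k_neighbors or restrict the branch"
        )
    root_idx = matrix.columns.get_loc(root_cell)
    dist = dijkstra(mutual, directed=False, indices=root_idx)
    values = pd.Series(dist, index=matrix.columns, name="pseudotime")
    return Pseudotime(values=scale_pseudotime(values), root=root_cell,
                      source="internal_geodesic")


# ---------------------------------------------------------------------------
# logistic activation-curve fitting


@dataclass
class LogisticFit:
    """Fitted activation curve for one gene.

    ``midpoint`` (t0) is the pseudotime at which the curve crosses
    ``baseline + amplitude/2`` — the tipping point between inactive and
    active.  ``extrapolated`` flags midpoints outside the observed [0, 1]
    pseudotime range; ``converged=False`` fits are excluded from ordering by
    default.
    """

    gene: str
    baseline: float
    amplitude: float
    midpoint: float
    slope: float
    direction: str
    rss: float
    converged: bool
    extrapolated: bool = field(init=False)

    def __post_init__(self) -> None:
        self.extrapolated = not (0.0 <= self.midpoint <= 1.0)

    def predict(self, t: np.ndarray) -> np.ndarray:
        z = self.slope * (np.asarray(t, dtype=float) - self.midpoint)
        if self.direction == "down":
            z = -z
        return self.baseline + self.amplitude / (1.0 + np.exp(-z))

    def to_dict(self) -> dict:
        return {
            "gene": self.gene, "baseline": self.baseline, "amplitude": self.amplitude,
            "midpoint": self.midpoint, "slope": self.slope, "direction": self.direction,
            "rss": self.rss, "converged": self.converged, "extrapolated": self.extrapolated,
        }


_MAX_SLOPE = 500.0


def _model_up(t, b, A, s, t0):
    return b + A / (1.0 + np.exp(-np.clip(s * (t - t0), -700, 700)))


def _model_down(t, b, A, s, t0):
    return b + A / (1.0 + np.exp(np.clip(s * (t - t0), -700, 700)))


def _half_crossing(t: np.ndarray, y: np.ndarray) -> float:
    half = y.min() + 0.5 * (y.max() - y.min())
    order = np.argsort(t)
    return float(t[order][np.argmin(np.abs(y[order] - half))])


def fit_logistic(
    y: np.ndarray | pd.Series,
    t: np.ndarray | pd.Series,
    gene: str = "",
    n_starts: int = 8,
    seed: int = 0,
) -> LogisticFit:
    """Least-squares logistic fit of one gene's (smoothed) expression vs pseudotime.

    Both the increasing and the mirrored decreasing sigmoid are fitted with
    multi-start initialisation (baseline = min, amplitude = range, midpoint at
    the half-range crossing, slope jittered around 10; slope bounded in
    (0, 500]); the direction with the lower residual sum of squares wins.
    Non-convergence across all starts returns ``converged=False``.
    """
    y = np.asarray(y, dtype=float).ravel()
    t = np.asarray(t, dtype=float).ravel()
    if y.size != t.size:
        raise ValueError("y and t must have equal length")
    if y.size < 8:
        raise ValueError(f"need at least 8 cells, got {y.size}")
    if np.ptp(t) == 0:
        raise ValueError("pseudotime spans a zero range")

    rng = np.random.default_rng(seed)
    b0, A0 = float(y.min()), float(max(np.ptp(y), 1e-12))
    t0_init = _half_crossing(t, y)
    starts = [(b0, A0, 10.0, t0_init)]
    for _ in range(n_starts - 1):
        starts.append((
            b0,
            A0,
            float(np.exp(rng.uniform(np.log(2.0), np.log(100.0)))),
            float(np.clip(t0_init + rng.uniform(-0.25, 0.25), -0.5, 1.5)),
        ))

    bounds = ([-np.inf, 0.0, 1e-9, -1.0], [np.inf, np.inf, _MAX_SLOPE, 2.0])
    best = None
    for direction, model in (("up", _model_up), ("down", _model_down)):
        for p0 in starts:
            p0 = (p0[0], p0[1], min(p0[2], _MAX_SLOPE), p0[3])
            try:
                popt, _ = curve_fit(
                    model, t, y, p0=p0, bounds=bounds, maxfev=5000,
                    xtol=1e-12, ftol=1e-12, gtol=1e-12,
                )
            except (RuntimeError, ValueError):
                continue
            rss = float(np.sum((model(t, *popt) - y) ** 2))
            if best is None or rss < best[0]:
                best = (rss, direction, popt)

    if best is None:
        return LogisticFit(gene=gene, baseline=b0, amplitude=A0, midpoint=t0_init,
                           slope=10.0, direction="up", rss=float(np.sum((y - y.mean()) ** 2)),
                           converged=False)
    rss, direction, (b, A, s, t0) = best
    return LogisticFit(gene=gene, baseline=float(b), amplitude=float(A),
                       midpoint=float(t0), slope=float(s), direction=direction,
                       rss=rss, converged=True)


def fit_all_genes(
    matrix: pd.DataFrame,
    pseudotime: Pseudotime | pd.Series,
    genes: Optional[Iterable[str]] = None,
    seed: int = 0,
) -> list[LogisticFit]:
    """Fit a logistic activation curve for each requested gene."""
    t = pseudotime.values if isinstance(pseudotime, Pseudotime) else pseudotime
    t = t.reindex(matrix.columns)
    if t.isna().any():
        raise ValueError("pseudotime missing for some cells in the matrix")
    gene_list = list(genes) if genes is not None else list(matrix.index)
    missing = [g for g in gene_list if g not in matrix.index]
    if missing:
        raise ValueError(f"genes absent from matrix: {missing[:5]}")
    return [
        fit_logistic(matrix.loc[g], t, gene=g, seed=seed) for g in gene_list
    ]


@dataclass
class ActivationOrder:
    """Genes ordered by ascending activation midpoint.

    ``table`` holds the ordered, eligible fits (converged and matching the
    direction filter; ties on the midpoint broken by gene name);
    ``excluded`` lists genes dropped by convergence or direction, with the
    reason.  Extrapolated midpoints sort to the ends of the order and stay
    flagged.
    """

    table: pd.DataFrame
    excluded: pd.DataFrame

    @property
    def genes(self) -> list[str]:
        return self.table["gene"].tolist()


def activation_order_pipeline(
    counts: pd.DataFrame,
    pseudotime: Pseudotime,
    params: SmoothingParams = SmoothingParams(),
    genes: Optional[Iterable[str]] = None,
    raw_counts: bool = True,
    seed: int = 0,
    direction_filter: Optional[str] = "up",
) -> tuple[list[LogisticFit], "ActivationOrder"]:
    """Smooth, fit and order in one call — the default expression-arm pipeline.

    For raw counts, neighbours are found on the log1p matrix (variance
    stabilised) while smoothing and curve fitting stay on the linear count
    scale, where a sigmoid mean remains a sigmoid; pre-normalised input is
    smoothed and fitted as supplied.
    """
    feature_space = np.log1p(counts) if raw_counts else None
    smoothed = smooth_expression(counts, params, feature_space=feature_space)
    fits = fit_all_genes(smoothed, pseudotime, genes=genes, seed=seed)
    return fits, order_genes(fits, direction_filter=direction_filter)


def order_genes(
    fits: Sequence[LogisticFit], direction_filter: Optional[str] = "up"
) -> ActivationOrder:
    """Sort converged, direction-matching fits by ascending midpoint."""
    eligible, excluded = [], []
    for f in fits:
        if not f.converged:
            excluded.append((f.gene, "not_converged"))
        elif direction_filter is not None and f.direction != direction_filter:
            excluded.append((f.gene, f"direction_{f.direction}"))
        else:
            eligible.append(f)
    if not eligible:
        raise ValueError("no converged fits pass the direction filter")
    eligible.sort(key=lambda f: (f.midpoint, f.gene))
    table = pd.DataFrame([f.to_dict() for f in eligible])
    table.insert(0, "rank", np.arange(1, len(eligible) + 1))
    excluded_df = pd.DataFrame(excluded, columns=["gene", "reason"])
    return ActivationOrder(table=table, excluded=excluded_df)
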