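"""Bimodal intensity thresholding and ICM lineage classification.

At D7 the ICM has resolved into epiblast and hypoblast with mutually
exclusive marker expression, so the pooled per-nucleus intensity histogram of
an epiblast marker (OCT4) or a hypoblast marker (SOX17) is bimodal: a
negative and a positive normal component.  A two-component Gaussian mixture
is fitted to the anchor-stage (D7) intensities and the point between the two
components — by default the density intersection, the Bayes boundary —
becomes the positivity threshold.  That D7-anchored cut is then applied
unchanged to earlier stages to split cells into epiblast (epi+ hypo−),
hypoblast (epi− hypo+), co-expressing (both +, the "undefined ICM"
population) and negative (both −) classes, and the class proportions are
summarised per embryo and per stage.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

from .presets import CO_EXPRESSING, EPIBLAST, HYPOBLAST, LINEAGES, NEGATIVE


class NotBimodalError(ValueError):
    """The intensity distribution does not separate into two components.

    Raised when the fitted component means nearly coincide; such a
    marker/stage cannot anchor a positivity threshold.
    """


THRESHOLD_METHODS = ("density_intersection", "posterior_half", "midpoint")


@dataclass(frozen=True)
class MarkerThreshold:
    """Fitted two-component mixture and derived positivity cut for one marker.

    Component 1 is the low (negative) mode, component 2 the high (positive)
    mode; ``mu1 < threshold < mu2`` always holds.
    """

    marker: str
    w1: float
    mu1: float
    sigma1: float
    w2: float
    mu2: float
    sigma2: float
    threshold: float
    anchor_stage: str
    method: str

    def __post_init__(self) -> None:
        if not (self.mu1 < self.threshold < self.mu2):
            raise ValueError(
                f"threshold {self.threshold} does not lie between component means "
                f"({self.mu1}, {self.mu2})"
            )
        if abs(self.w1 + self.w2 - 1.0) > 1e-9:
            raise ValueError("component weights must sum to 1")
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValueError("component SDs must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "MarkerThreshold":
        return cls(**d)


def mixture_intersection(
    w1: float, mu1: float, sigma1: float, w2: float, mu2: float, sigma2: float
) -> float:
    """Root of ``w1·N(x; mu1, sigma1) = w2·N(x; mu2, sigma2)`` in (mu1, mu2).

    This is the valley between the two modes of a well-separated mixture and
    equals the point where the component posterior crosses 0.5.
    """
    if mu1 >= mu2:
        raise ValueError("requires mu1 < mu2")

    def diff(x: float) -> float:
        return (np.log(w1) + norm.logpdf(x, mu1, sigma1)) - (
            np.log(w2) + norm.logpdf(x, mu2, sigma2)
        )

    lo, hi = mu1, mu2
    f_lo, f_hi = diff(lo), diff(hi)
    if f_lo <= 0 or f_hi >= 0:
        raise NotBimodalError(
            "mixture densities do not cross between the component means"
        )
    return float(brentq(diff, lo, hi, xtol=1e-12))


def fit_bimodal_threshold(
    intensities: np.ndarray | pd.Series,
    marker: str = "",
    anchor_stage: str = "",
    method: str = "density_intersection",
    log_scale: bool = False,
    min_separation: float = 0.5,
    random_state: int = 0,
) -> MarkerThreshold:
    """Fit a two-component Gaussian mixture and derive the positivity cut.

    The mixture is fitted by maximum likelihood with multi-start EM
    (10 restarts, seeded).  ``method`` selects how the cut is derived:
    ``density_intersection`` (default) solves ``w1·N1(x) = w2·N2(x)`` in
    ``(mu1, mu2)``; ``posterior_half`` finds where the high-component
    posterior crosses 0.5 (identical root for two components, computed on the
    posterior for transparency); ``midpoint`` is ``(mu1 + mu2) / 2``.  With
    ``log_scale`` the mixture is fitted on log intensities and the cut mapped
    back through ``exp``.

    Raises :class:`NotBimodalError` when the fitted means are closer than
    ``min_separation`` pooled SDs — such a distribution cannot anchor a
    threshold.
    """
    x = np.asarray(intensities, dtype=float).ravel()
    if x.size < 20:
        raise ValueError(f"need at least 20 observations, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("intensities must be finite")
    if np.any(x < 0):
        raise ValueError("intensities must be nonnegative")
    if method not in THRESHOLD_METHODS:
        raise ValueError(f"method must be one of {THRESHOLD_METHODS}, got {method!r}")
    if log_scale:
        if np.any(x <= 0):
            raise ValueError("log-scale fitting requires strictly positive intensities")
        x = np.log(x)

    gm = GaussianMixture(
        n_components=2, covariance_type="full", n_init=10,
        tol=1e-8, max_iter=500, random_state=random_state,
    ).fit(x.reshape(-1, 1))
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    order = np.argsort(means)
    (mu1, mu2), (s1, s2), (w1, w2) = means[order], sds[order], weights[order]

    pooled_sd = float(np.sqrt(w1 * s1**2 + w2 * s2**2))
    if mu2 - mu1 < min_separation * pooled_sd:
        raise NotBimodalError(
            f"fitted component means {mu1:.4g} and {mu2:.4g} are separated by less "
            f"than {min_separation} pooled SDs; marker {marker!r} at stage "
            f"{anchor_stage!r} cannot anchor a threshold"
        )

    if method == "midpoint":
        cut = 0.5 * (mu1 + mu2)
    elif method == "density_intersection":
        try:
            cut = mixture_intersection(w1, mu1, s1, w2, mu2, s2)
        except NotBimodalError as exc:
            raise NotBimodalError(
                f"{exc}; marker {marker!r} at stage {anchor_stage!r} cannot "
                "anchor a threshold"
            ) from exc
    else:  # posterior_half

        def post2(x0: float) -> float:
            log_r = (np.log(w1) + norm.logpdf(x0, mu1, s1)) - (
                np.log(w2) + norm.logpdf(x0, mu2, s2)
            )
            return 1.0 / (1.0 + np.exp(log_r)) - 0.5

        cut = float(brentq(post2, mu1, mu2, xtol=1e-12))

    if log_scale:
        mu1, mu2, cut = np.exp(mu1), np.exp(mu2), np.exp(cut)
        # report SDs on the intensity scale via the delta method
        s1, s2 = s1 * mu1, s2 * mu2
    return MarkerThreshold(
        marker=marker, w1=float(w1), mu1=float(mu1), sigma1=float(s1),
        w2=float(w2), mu2=float(mu2), sigma2=float(s2),
        threshold=float(cut), anchor_stage=anchor_stage, method=method,
    )


def _icm_records(records: pd.DataFrame) -> pd.DataFrame:
    return records[(records["compartment"] == "ICM") & (~records["manual_exclude"])]


def _intensity_column(marker: str, feature: str) -> str:
    if feature not in ("mean", "intdens"):
        raise ValueError(f"feature must be 'mean' or 'intdens', got {feature!r}")
    return f"{marker}_{feature}"


def classify_cells(
    records: pd.DataFrame,
    thresholds: Mapping[str, MarkerThreshold],
    rule: tuple[str, str] = ("OCT4", "SOX17"),
    feature: str = "mean",
) -> pd.DataFrame:
    """Assign each ICM cell a lineage from its marker positivity quadrant.

    ``rule = (epiblast_marker, hypoblast_marker)``.  Positivity is strict
    (intensity > threshold; a cell exactly at the cut is negative for that
    marker).  Quadrants map to lineages as (+,−)→epiblast, (−,+)→hypoblast,
    (+,+)→co_expressing, (−,−)→negative.  Only ICM, non-excluded records are
    classified.
    """
    epi_marker, hypo_marker = rule
    for marker in rule:
        if marker not in thresholds:
            raise ValueError(f"no threshold provided for marker {marker!r}")
        col = _intensity_column(marker, feature)
        if col not in records.columns:
            raise ValueError(f"record table lacks column {col!r}")
    icm = _icm_records(records)
    epi_pos = icm[_intensity_column(epi_marker, feature)].to_numpy() > thresholds[epi_marker].threshold
    hypo_pos = icm[_intensity_column(hypo_marker, feature)].to_numpy() > thresholds[hypo_marker].threshold
    lineage = np.select(
        [epi_pos & ~hypo_pos, ~epi_pos & hypo_pos, epi_pos & hypo_pos],
        [EPIBLAST, HYPOBLAST, CO_EXPRESSING],
        default=NEGATIVE,
    )
    calls = icm[["cell_id", "embryo_id", "stage"]].copy()
    calls[f"{epi_marker}_positive"] = epi_pos
    calls[f"{hypo_marker}_positive"] = hypo_pos
    calls["lineage"] = lineage
    return calls.reset_index(drop=True)


def apply_anchor_thresholds(
    records: pd.DataFrame,
    rule: tuple[str, str] = ("OCT4", "SOX17"),
    anchor_stage: str = "D7",
    method: str = "density_intersection",
    feature: str = "mean",
    log_scale: bool = False,
    random_state: int = 0,
) -> tuple[pd.DataFrame, dict[str, MarkerThreshold]]:
    """Fit thresholds once on the anchor stage, then classify every stage.

    Thresholds are fitted on the pooled anchor-stage ICM intensities and
    applied unchanged to all stages present in ``records``.  Returns the
    classification table for all stages and the fitted thresholds.
    """
    if anchor_stage not in set(records["stage"]):
        raise ValueError(f"anchor stage {anchor_stage!r} absent from records")
    anchor = _icm_records(records[records["stage"] == anchor_stage])
    thresholds = {
        marker: fit_bimodal_threshold(
            anchor[_intensity_column(marker, feature)],
            marker=marker, anchor_stage=anchor_stage, method=method,
            log_scale=log_scale, random_state=random_state,
        )
        for marker in rule
    }
    calls = classify_cells(records, thresholds, rule=rule, feature=feature)
    return calls, thresholds


@dataclass
class StageSummary:
    """Lineage proportions per embryo and their unweighted across-embryo mean.

    ``per_embryo`` has one row per (stage, embryo) with one percentage column
    per lineage class (summing to 100) and the embryo's cell count;
    ``across`` averages the per-embryo percentages within each stage.
    """

    per_embryo: pd.DataFrame
    across: pd.DataFrame


def stage_proportions(calls: pd.DataFrame, group_by: str = "embryo_id") -> StageSummary:
    """Summarise lineage percentages per embryo and average across embryos."""
    if calls.empty:
        raise ValueError("no classified cells to summarise")
    counts = (
        calls.groupby(["stage", group_by])["lineage"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=list(LINEAGES), fill_value=0)
    )
    n_cells = counts.sum(axis=1)
    per_embryo = counts.div(n_cells, axis=0) * 100.0
    per_embryo["n_cells"] = n_cells
    per_embryo = per_embryo.reset_index()

    pct_cols = list(LINEAGES)
    across = per_embryo.groupby("stage")[pct_cols].mean()
    across["n_embryos"] = per_embryo.groupby("stage").size()
    across["n_cells"] = per_embryo.groupby("stage")["n_cells"].sum()
    return StageSummary(per_embryo=per_embryo, across=across.reset_index())


def coexpression_map(
    records: pd.DataFrame,
    marker_x: str,
    marker_y: str,
    thresholds: Mapping[str, MarkerThreshold],
    feature: str = "mean",
) -> pd.DataFrame:
    """Long-format per-cell co-expression table for scatter/violin plots.

    One row per ICM cell with both markers' intensities and strict-threshold
    positivity flags; empty input yields an empty table.
    """
    cols_out = ["cell_id", "embryo_id", "stage", "x_intensity", "y_intensity",
                "x_positive", "y_positive"]
    icm = _icm_records(records)
    if icm.empty:
        return pd.DataFrame(columns=cols_out)
    out = icm[["cell_id", "embryo_id", "stage"]].copy()
    out["x_intensity"] = icm[_intensity_column(marker_x, feature)].to_numpy()
    out["y_intensity"] = icm[_intensity_column(marker_y, feature)].to_numpy()
    out["x_positive"] = out["x_intensity"] > thresholds[marker_x].threshold
    out["y_positive"] = out["y_intensity"] > thresholds[marker_y].threshold
    return out.reset_index(drop=True)[cols_out]
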