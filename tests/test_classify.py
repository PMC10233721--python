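"""Bimodal thresholding and lineage classification behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from blastoquant.classify import (
    MarkerThreshold,
    NotBimodalError,
    apply_anchor_thresholds,
    classify_cells,
    coexpression_map,
    fit_bimodal_threshold,
    mixture_intersection,
    stage_proportions,
)
from blastoquant.presets import DEFAULT_PRESETS
from blastoquant.simulate import gen_intensity_table
from conftest import true_intersection_grid


def _make_thresholds(oct4=50.0, sox17=50.0):
    def th(marker, cut):
        return MarkerThreshold(marker=marker, w1=0.5, mu1=cut - 30, sigma1=5.0,
                               w2=0.5, mu2=cut + 30, sigma2=5.0, threshold=cut,
                               anchor_stage="D7", method="midpoint")
    return {"OCT4": th("OCT4", oct4), "SOX17": th("SOX17", sox17)}


def _records(oct4_vals, sox17_vals, stage="D7", embryo="E1"):
    n = len(oct4_vals)
    return pd.DataFrame({
        "cell_id": range(1, n + 1), "embryo_id": embryo, "stage": stage,
        "volume": 100, "compartment": "ICM", "manual_exclude": False,
        "OCT4_mean": oct4_vals, "OCT4_intdens": np.asarray(oct4_vals) * 100,
        "SOX17_mean": sox17_vals, "SOX17_intdens": np.asarray(sox17_vals) * 100,
    })


class TestMixtureIntersection:
    def test_symmetric_components_intersect_at_mid_mean(self):
        assert mixture_intersection(0.5, 10, 7.0, 0.5, 100, 7.0) == pytest.approx(55.0)

    def test_matches_grid_oracle_for_unequal_components(self):
        args = (0.4, 30.0, 15.0, 0.6, 180.0, 20.0)
        assert mixture_intersection(*args) == pytest.approx(
            true_intersection_grid(*args), abs=1e-3)


class TestFitBimodalThreshold:
    def test_recovers_true_density_intersection_from_sample(self, known_mixture_sample):
        x, p = known_mixture_sample
        th = fit_bimodal_threshold(x, marker="OCT4", anchor_stage="D7")
        oracle = true_intersection_grid(**p)
        assert abs(th.threshold - oracle) / oracle < 0.05

    def test_fitted_means_bracket_generator_modes(self, d7_cohort):
        table, _ = d7_cohort
        preset = DEFAULT_PRESETS["D7"]
        low = preset.intensity_params[("hypoblast", "OCT4")].mode_location
        high = preset.intensity_params[("epiblast", "OCT4")].mode_location
        th = fit_bimodal_threshold(table["OCT4_mean"], marker="OCT4")
        assert th.mu1 < low * 1.5 and th.mu2 > high * 0.7
        assert low < th.threshold < high

    def test_methods_coincide_for_symmetric_mixture(self):
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(30, 8, 2000), rng.normal(150, 8, 2000)])
        x = np.clip(x, 0, None)
        cuts = {m: fit_bimodal_threshold(x, method=m).threshold
                for m in ("density_intersection", "posterior_half", "midpoint")}
        assert cuts["density_intersection"] == pytest.approx(cuts["midpoint"], rel=0.02)
        assert cuts["posterior_half"] == pytest.approx(cuts["density_intersection"], abs=1e-6)

    def test_log_scale_threshold_lands_between_modes(self, d7_cohort):
        table, _ = d7_cohort
        th = fit_bimodal_threshold(table["SOX17_mean"], marker="SOX17", log_scale=True)
        assert 20 < th.threshold < 180

    def test_unimodal_sample_raises_not_bimodal(self):
        rng = np.random.default_rng(0)
        with pytest.raises(NotBimodalError, match="cannot anchor"):
            fit_bimodal_threshold(rng.normal(100, 5, 500), marker="OCT4")

    @pytest.mark.parametrize("bad", [np.ones(5), np.array([1.0, np.nan] * 20),
                                     -np.ones(30)])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            fit_bimodal_threshold(bad)

    @pytest.mark.parametrize("seed", range(6))
    def test_threshold_always_brackets_component_means(self, seed):
        """mu1 < threshold < mu2 over randomly drawn well-separated mixtures."""
        rng = np.random.default_rng(seed)
        mu1, gap = rng.uniform(10, 60), rng.uniform(80, 250)
        s1, s2 = rng.uniform(3, 12, 2)
        w = rng.uniform(0.2, 0.8)
        n1 = int(1000 * w)
        x = np.clip(np.concatenate([rng.normal(mu1, s1, n1),
                                    rng.normal(mu1 + gap, s2, 1000 - n1)]), 0, None)
        th = fit_bimodal_threshold(x, method="density_intersection")
        assert th.mu1 < th.threshold < th.mu2


class TestClassifyCells:
    @pytest.mark.parametrize("oct4,sox17,expected", [
        (80.0, 20.0, "epiblast"),
        (20.0, 80.0, "hypoblast"),
        (80.0, 80.0, "co_expressing"),
        (20.0, 20.0, "negative"),
    ])
    def test_quadrant_rule(self, oct4, sox17, expected):
        calls = classify_cells(_records([oct4], [sox17]), _make_thresholds())
        assert calls["lineage"].tolist() == [expected]

    def test_cell_exactly_at_both_thresholds_is_negative(self):
        calls = classify_cells(_records([50.0], [50.0]), _make_thresholds(50.0, 50.0))
        assert calls["lineage"].tolist() == ["negative"]

    def test_te_and_excluded_records_are_dropped(self):
        rec = _records([80.0, 80.0], [20.0, 20.0])
        rec.loc[1, "compartment"] = "TE"
        rec.loc[1, "manual_exclude"] = True
        calls = classify_cells(rec, _make_thresholds())
        assert calls["cell_id"].tolist() == [1]

    def test_missing_marker_column_is_schema_error(self):
        rec = _records([80.0], [20.0]).drop(columns=["SOX17_mean"])
        with pytest.raises(ValueError, match="SOX17_mean"):
            classify_cells(rec, _make_thresholds())

    def test_every_cell_gets_exactly_one_lineage(self, d7_cohort):
        table, _ = d7_cohort
        calls, _ = apply_anchor_thresholds(table, anchor_stage="D7")
        assert len(calls) == len(table)
        assert calls["lineage"].isin(
            ["epiblast", "hypoblast", "co_expressing", "negative"]).all()

    def test_misclassification_below_generator_overlap_mass(self, d7_cohort):
        """Confusion vs truth stays below the lineage-conditional overlap integral."""
        table, truth = d7_cohort
        calls, thresholds = apply_anchor_thresholds(table, anchor_stage="D7")
        predicted = calls.set_index("cell_id")["lineage"]
        err_rate = (predicted != truth.lineage.reindex(predicted.index)).mean()
        # per-marker overlap mass at the fitted cut, from the true log-normal modes
        preset = DEFAULT_PRESETS["D7"]
        overlap = 0.0
        for marker in ("OCT4", "SOX17"):
            cut = np.log(thresholds[marker].threshold)
            low = preset.intensity_params[("hypoblast" if marker == "OCT4" else "epiblast", marker)]
            high = preset.intensity_params[("epiblast" if marker == "OCT4" else "hypoblast", marker)]
            overlap += norm.sf(cut, low.mu, low.sigma) + norm.cdf(cut, high.mu, high.sigma)
        assert err_rate <= max(overlap, 1e-3)

    def test_raising_threshold_never_increases_positive_count(self, d7_cohort):
        table, _ = d7_cohort
        counts = []
        for cut in (40.0, 60.0, 90.0, 140.0):
            calls = classify_cells(table, _make_thresholds(oct4=cut, sox17=50.0))
            counts.append(int(calls["OCT4_positive"].sum()))
        assert counts == sorted(counts, reverse=True)


class TestAnchoring:
    def test_anchor_stage_absent_raises(self, d7_cohort):
        table, _ = d7_cohort
        with pytest.raises(ValueError, match="anchor"):
            apply_anchor_thresholds(table, anchor_stage="D5")

    def test_self_anchoring_equals_direct_classification(self, d7_cohort):
        table, _ = d7_cohort
        calls, thresholds = apply_anchor_thresholds(table, anchor_stage="D7")
        direct = classify_cells(table, thresholds)
        pd.testing.assert_frame_equal(calls, direct)

    def test_earlier_stage_uses_d7_derived_cuts(self, d7_cohort):
        d7_table, _ = d7_cohort
        d5_table, _ = gen_intensity_table(
            DEFAULT_PRESETS["D5"].with_size(n_cells_icm=100, n_embryos=2), seed=30)
        d5_table["cell_id"] += 10_000
        combined = pd.concat([d7_table, d5_table], ignore_index=True)
        calls, thresholds = apply_anchor_thresholds(combined, anchor_stage="D7")
        assert all(t.anchor_stage == "D7" for t in thresholds.values())
        d7_only, thresholds_alone = apply_anchor_thresholds(d7_table, anchor_stage="D7")
        assert thresholds["OCT4"].threshold == thresholds_alone["OCT4"].threshold
        d5_calls = calls[calls["stage"] == "D5"]
        pd.testing.assert_frame_equal(
            d5_calls.reset_index(drop=True),
            classify_cells(d5_table, thresholds_alone).reset_index(drop=True),
        )


class TestStageProportions:
    def test_single_embryo_arithmetic(self):
        calls = pd.DataFrame({
            "cell_id": range(100), "embryo_id": "E1", "stage": "D7",
            "lineage": ["epiblast"] * 10 + ["hypoblast"] * 20 + ["co_expressing"] * 70,
        })
        s = stage_proportions(calls)
        row = s.across.set_index("stage").loc["D7"]
        assert (row["epiblast"], row["hypoblast"], row["co_expressing"]) == (10.0, 20.0, 70.0)

    def test_identical_embryos_mean_equals_either(self):
        one = pd.DataFrame({"cell_id": range(10), "embryo_id": "E1", "stage": "D7",
                            "lineage": ["epiblast"] * 4 + ["hypoblast"] * 6})
        two = one.assign(embryo_id="E2", cell_id=range(10, 20))
        s = stage_proportions(pd.concat([one, two], ignore_index=True))
        row = s.across.set_index("stage").loc["D7"]
        assert row["epiblast"] == pytest.approx(40.0)
        assert row["hypoblast"] == pytest.approx(60.0)

    def test_per_embryo_percentages_sum_to_100(self, d7_cohort):
        table, _ = d7_cohort
        calls, _ = apply_anchor_thresholds(table, anchor_stage="D7")
        s = stage_proportions(calls)
        lineages = ["epiblast", "hypoblast", "co_expressing", "negative"]
        np.testing.assert_allclose(s.per_embryo[lineages].sum(axis=1), 100.0, atol=1e-6)

    def test_empty_calls_raise(self):
        with pytest.raises(ValueError):
            stage_proportions(pd.DataFrame(columns=["stage", "embryo_id", "lineage"]))


class TestCoexpressionMap:
    def test_empty_input_gives_empty_table(self):
        out = coexpression_map(_records([], []), "OCT4", "SOX17", _make_thresholds())
        assert out.empty

    def test_all_cells_below_both_thresholds_all_negative(self):
        out = coexpression_map(_records([10.0, 20.0], [10.0, 5.0]),
                               "OCT4", "SOX17", _make_thresholds())
        assert not out["x_positive"].any() and not out["y_positive"].any()

    def test_late_d6_occupies_three_truth_quadrants(self):
        preset = DEFAULT_PRESETS["late_D6"].with_size(n_cells_icm=300, n_embryos=2)
        table, truth = gen_intensity_table(preset, seed=17)
        thresholds = _make_thresholds(oct4=60.0, sox17=60.0)
        out = coexpression_map(table, "OCT4", "SOX17", thresholds).set_index("cell_id")
        quadrant = np.select(
            [out["x_positive"] & ~out["y_positive"],
             ~out["x_positive"] & out["y_positive"],
             out["x_positive"] & out["y_positive"]],
            ["epiblast", "hypoblast", "co_expressing"], default="negative")
        assert set(quadrant) == {"epiblast", "hypoblast", "co_expressing"}
        agreement = (pd.Series(quadrant, index=out.index) == truth.lineage).mean()
        assert agreement > 0.99


@settings(max_examples=25, derandomize=True, deadline=None)
@given(st.lists(st.sampled_from(["epiblast", "hypoblast", "co_expressing", "negative"]),
                min_size=1, max_size=60),
       st.integers(min_value=1, max_value=4))
def test_partition_counts_conserved_for_arbitrary_lineage_vectors(labels, n_embryos):
    """Summaries conserve cell counts and partition every cell exactly once."""
    calls = pd.DataFrame({
        "cell_id": range(len(labels)),
        "embryo_id": [f"E{i % n_embryos}" for i in range(len(labels))],
        "stage": "D7", "lineage": labels,
    })
    s = stage_proportions(calls)
    assert int(s.across["n_cells"].sum()) == len(labels)
    np.testing.assert_allclose(
        s.per_embryo[["epiblast", "hypoblast", "co_expressing", "negative"]].sum(axis=1),
        100.0)
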