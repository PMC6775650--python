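"""Depth labeling, depth sweep and the zero-false-negative threshold."""

import numpy as np
import pandas as pd
import pytest

from drscascade import study_procedures as sp
from drscascade import synthetic_data as sd
from drscascade.errors import CalibrationError, DataError, EvaluationError

from conftest import noise_free_config


def location(true_class="tumor", depth=0.0, extent=2.0, **overrides):
    fields = dict(
        location_id="L0",
        patient_id="P0",
        true_class=true_class,
        tumor_depth_mm=depth if true_class == "tumor" else None,
        tumor_extent_mm=extent if true_class == "tumor" else None,
        surgeon_class="tumor",
        surgeon_certain=True,
        replicate_spectra=[],
    )
    fields.update(overrides)
    return sd.MeasurementLocation(**fields)


class TestDepthLabel:
    def test_surface_tumor_is_tumor(self):
        assert sp.depth_label(location(depth=0.0, extent=2.0)) == "tumor"

    def test_tumor_beyond_max_depth_is_non_tumor(self):
        assert sp.depth_label(location(depth=2.0)) == "non_tumor"

    def test_small_extent_within_depth_is_excluded(self):
        assert sp.depth_label(location(depth=1.0, extent=0.3)) == "excluded"

    def test_non_tumor_location_is_non_tumor(self):
        assert sp.depth_label(location(true_class="wall")) == "non_tumor"

    def test_missing_depth_raises(self):
        loc = location()
        loc.tumor_depth_mm = None  # annotation lost downstream of construction
        with pytest.raises(DataError):
            sp.depth_label(loc)

    def test_labels_partition_tumor_locations(self, rng):
        rule = sp.DepthRule(max_depth_mm=1.5, min_extent_mm=0.5)
        for _ in range(200):
            loc = location(
                depth=float(rng.uniform(0, 5)), extent=float(rng.uniform(0.05, 6))
            )
            label = sp.depth_label(loc, rule)
            assert label in {"tumor", "non_tumor", "excluded"}
            # exactly one branch applies
            within = loc.tumor_depth_mm <= rule.max_depth_mm
            small = loc.tumor_extent_mm < rule.min_extent_mm
            expected = "excluded" if within and small else "tumor" if within else "non_tumor"
            assert label == expected


class TestZeroFnThreshold:
    def test_fixed_example(self):
        # tumor scores {0.9, 0.8}, healthy {0.7, 0.95}: threshold in (0.7, 0.8),
        # every tumor called, one healthy (0.95) above threshold.
        cal = sp.zero_fn_threshold([0.9, 0.8, 0.7, 0.95], [True, True, False, False])
        assert 0.7 < cal.tumor_threshold < 0.8
        assert cal.fn == 0 and cal.fp == 1

    def test_separable_scores_give_zero_fp(self):
        cal = sp.zero_fn_threshold([0.9, 0.8, 0.1, 0.2], [True, True, False, False])
        assert cal.fn == 0 and cal.fp == 0

    def test_healthy_tied_with_minimum_tumor_counts_as_fp(self):
        cal = sp.zero_fn_threshold([0.8, 0.8, 0.2], [True, False, False])
        assert cal.fn == 0 and cal.fp == 1

    def test_no_tumor_locations_rejected(self):
        with pytest.raises(CalibrationError):
            sp.zero_fn_threshold([0.5, 0.6], [False, False])

    def test_guarantee_and_minimality_against_brute_force(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 30))
            scores = np.round(rng.normal(size=n), 3)  # ties likely
            truths = rng.integers(0, 2, size=n) == 1
            if not truths.any():
                truths[0] = True
            cal = sp.zero_fn_threshold(scores, truths)
            calls = scores > cal.tumor_threshold
            assert not (truths & ~calls).any()  # FN = 0 always
            # brute force: minimal FP over all thresholds with FN = 0
            candidates = np.concatenate([[scores.min() - 1.0], np.unique(scores)])
            best_fp = min(
                int((~truths & (scores > t)).sum())
                for t in candidates
                if not (truths & ~(scores > t)).any()
            )
            assert cal.fp == best_fp

    def test_lowering_threshold_is_monotone_in_sensitivity_and_specificity(self, rng):
        scores = rng.normal(size=50)
        truths = rng.integers(0, 2, size=50) == 1
        thresholds = np.sort(rng.normal(size=8))
        prev_sens, prev_spec = None, None
        for t in thresholds[::-1]:  # decreasing threshold
            calls = scores > t
            sens = (calls & truths).sum() / truths.sum()
            spec = (~calls & ~truths).sum() / (~truths).sum()
            if prev_sens is not None:
                assert sens >= prev_sens - 1e-12
                assert spec <= prev_spec + 1e-12
            prev_sens, prev_spec = sens, spec


class TestEvaluateUncertain:
    def make_frame(self, n_healthy_fp, n_healthy, surgeon_fp):
        truth = [False] * n_healthy + [True, True]
        clf_scores = (
            [1.0] * n_healthy_fp + [-1.0] * (n_healthy - n_healthy_fp) + [1.0, 1.0]
        )
        surgeon = (
            ["tumor"] * surgeon_fp
            + ["healthy"] * (n_healthy - surgeon_fp)
            + ["tumor", "tumor"]
        )
        return pd.DataFrame(
            {"truth_tumor": truth, "tumor_score": clf_scores, "surgeon_class": surgeon}
        )

    def test_published_style_counts_reproduce_rates(self):
        frame = self.make_frame(n_healthy_fp=13, n_healthy=52, surgeon_fp=36)
        cal = sp.ThresholdCalibration(tumor_threshold=0.0, n_calibration=10, fn=0, fp=0)
        out = sp.evaluate_uncertain(frame, cal)
        assert out.surgeon_fp_rate == pytest.approx(36 / 52)
        assert out.classifier_fp_rate == pytest.approx(13 / 52)
        assert (out.classifier.tp, out.classifier.fn) == (2, 0)
        assert (out.surgeon.tn, out.surgeon.fp) == (16, 36)

    def test_perfect_classifier_has_zero_fp_rate(self):
        frame = self.make_frame(n_healthy_fp=0, n_healthy=10, surgeon_fp=5)
        cal = sp.ThresholdCalibration(tumor_threshold=0.0, n_calibration=5, fn=0, fp=0)
        out = sp.evaluate_uncertain(frame, cal)
        assert out.classifier_fp_rate == 0.0 and out.classifier.fn == 0

    def test_empty_subset_rejected(self):
        cal = sp.ThresholdCalibration(tumor_threshold=0.0, n_calibration=5, fn=0, fp=0)
        with pytest.raises(EvaluationError):
            sp.evaluate_uncertain(pd.DataFrame(columns=["truth_tumor"]), cal)


class TestDepthSweep:
    def test_all_surface_tumors_make_bins_identical(self):
        config = noise_free_config(
            n_patients=4,
            tumor_depth_distribution=sd.DepthDistribution(surface_mass=1.0),
            inconclusive_fraction=0.0,
        )
        dataset = sd.simulate_dataset(config)
        table = sp.depth_sweep(dataset, depths=[0.0, 1.5, 4.0], k=3, repeats=1, seed=2)
        assert table["n_tumor_locations"].nunique() == 1
        assert table["mcc_mean"].nunique() == 1

    def test_same_seed_reproduces_table(self, small_dataset):
        a = sp.depth_sweep(small_dataset, depths=[1.5, 4.0], k=3, repeats=1, seed=5)
        b = sp.depth_sweep(small_dataset, depths=[1.5, 4.0], k=3, repeats=1, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_bin_flagged_not_skipped(self):
        config = noise_free_config(
            n_patients=3,
            tumor_depth_distribution=sd.DepthDistribution(
                surface_mass=0.0, exp_scale_mm=0.5, max_depth_mm=1.0
            ),
            inconclusive_fraction=0.0,
        )
        dataset = sd.simulate_dataset(config)
        # shift every tumor deeper than the first bin
        for loc in dataset.locations:
            if loc.true_class == "tumor":
                loc.tumor_depth_mm = 3.0
        table = sp.depth_sweep(dataset, depths=[0.0, 4.0], k=3, repeats=1, seed=1)
        first = table.iloc[0]
        assert first["empty"] and np.isnan(first["mcc_mean"])
        assert len(table) == 2


class TestEndToEnd:
    def test_zero_fn_holds_on_calibration_subset(self, small_dataset, small_pipeline):
        result = sp.compare_to_surgeon(small_dataset, pipeline=small_pipeline)
        certain = result.certain_locations
        calls = certain["tumor_score"] > result.calibration.tumor_threshold
        assert not (certain["truth_tumor"] & ~calls).any()
        assert result.calibration.fn == 0

    def test_classifier_beats_surgeon_fp_rate_on_majority_of_seeds(self):
        """With a surgeon over-calling tumor at 0.69 on uncertain locations,
        the calibrated classifier should show the lower false-positive rate
        in most replicate studies."""
        wins = 0
        n_seeds = 20
        for seed in range(n_seeds):
            config = sd.SimConfig(n_patients=16, seed=300 + seed)
            dataset = sd.simulate_dataset(config)
            result = sp.compare_to_surgeon(dataset, k=5, repeats=1, seed=seed)
            wins += (
                result.comparison.classifier_fp_rate < result.comparison.surgeon_fp_rate
            )
        assert wins > n_seeds / 2
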