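"""Monte Carlo cohort simulator: reproducibility and convergence."""

import math

import numpy as np
import pandas as pd
import pytest

from ctdnalim.abundance import expected_copies_per_draw
from ctdnalim.detection import DetectionParams
from ctdnalim.geometry import burden_from_diameter
from ctdnalim.simulate import CohortConfig, SizeDistribution, simulate_cohort, summarize

POINT_27 = SizeDistribution("point", {"value": 27.0})


def _se(p: float, n: int) -> float:
    return math.sqrt(p * (1 - p) / n)


class TestSizeDistribution:
    def test_invalid_parameters_rejected_before_sampling(self):
        with pytest.raises(ValueError):
            SizeDistribution("lognormal", {"mu": 1.0, "sigma": 0.0})
        with pytest.raises(ValueError):
            SizeDistribution("uniform", {"lo": 5.0, "hi": 2.0})
        with pytest.raises(ValueError):
            SizeDistribution("gamma", {"k": 1.0})

    def test_point_mass(self):
        rng = np.random.default_rng(0)
        assert (POINT_27.sample(rng, 5) == 27.0).all()

    def test_uniform_support(self):
        rng = np.random.default_rng(0)
        x = SizeDistribution("uniform", {"lo": 2.0, "hi": 10.0}).sample(rng, 1000)
        assert x.min() >= 2.0 and x.max() <= 10.0


class TestSimulateCohort:
    def test_seed_reproducibility(self):
        cfg = CohortConfig(n=5000, prevalence=0.01, size_distribution=POINT_27, seed=11)
        rec1, c1 = simulate_cohort(cfg)
        rec2, c2 = simulate_cohort(cfg)
        pd.testing.assert_frame_equal(rec1, rec2)
        assert (c1.tp, c1.fn, c1.fp, c1.tn) == (c2.tp, c2.fn, c2.fp, c2.tn)

    def test_no_cancer_cohort(self):
        cfg = CohortConfig(
            n=50_000, prevalence=0.0, size_distribution=POINT_27, seed=3
        )
        _, counts = simulate_cohort(cfg)
        assert counts.tp == 0 and counts.fn == 0
        fp_rate = counts.fp / 50_000
        assert abs(fp_rate - 0.01) < 3 * _se(0.01, 50_000)

    def test_sampling_layer_matches_poisson_tail(self):
        """With coverage and positivity off, sensitivity is the Poisson tail."""
        cfg = CohortConfig(
            n=40_000,
            prevalence=0.1,
            size_distribution=POINT_27,
            seed=5,
            panel_coverage_prob=1.0,
            positivity_prob=1.0,
            false_positive_prob=0.0,
        )
        _, counts = simulate_cohort(cfg)
        lam = float(expected_copies_per_draw(burden_from_diameter(27.0).mass_mg))
        p = 1 - math.exp(-lam)  # independent closed form
        n_cancer = counts.tp + counts.fn
        assert abs(counts.tp / n_cancer - p) < 3 * _se(p, n_cancer)

    def test_all_layers_multiply(self):
        """Joint positive rate among cancers is Poisson tail x coverage x positivity."""
        cfg = CohortConfig(
            n=60_000,
            prevalence=0.2,
            size_distribution=POINT_27,
            seed=9,
            panel_coverage_prob=0.8,
            positivity_prob=0.5,
            false_positive_prob=0.0,
        )
        records, counts = simulate_cohort(cfg)
        lam = float(expected_copies_per_draw(burden_from_diameter(27.0).mass_mg))
        p = (1 - math.exp(-lam)) * 0.8 * 0.5
        n_cancer = counts.tp + counts.fn
        assert abs(counts.tp / n_cancer - p) < 3 * _se(p, n_cancer)
        # per-record structure: a positive cancer passed every layer
        pos = records[records.screen_positive & records.has_cancer]
        assert (pos.sampled_copies >= 1).all()
        assert pos.covered_by_panel.all() and pos.assay_positive.all()

    def test_healthy_individuals_have_no_tumor_signal(self):
        cfg = CohortConfig(n=2000, prevalence=0.5, size_distribution=POINT_27, seed=2)
        records, _ = simulate_cohort(cfg)
        healthy = records[~records.has_cancer]
        assert (healthy.tumor_diameter_mm == 0).all()
        assert (healthy.sampled_copies == 0).all()

    def test_detection_threshold_respected(self):
        det = DetectionParams(min_copies=3)
        cfg = CohortConfig(
            n=20_000, prevalence=0.3, size_distribution=POINT_27, seed=4,
            panel_coverage_prob=1.0, positivity_prob=1.0, false_positive_prob=0.0,
        )
        records, _ = simulate_cohort(cfg, det=det)
        pos = records[records.screen_positive]
        assert (pos.sampled_copies >= 3).all()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n=0, prevalence=0.1, size_distribution=POINT_27, seed=1)
        with pytest.raises(ValueError):
            CohortConfig(n=10, prevalence=1.5, size_distribution=POINT_27, seed=1)


class TestSummarize:
    def test_hand_built_records_exact_counts(self):
        records = pd.DataFrame(
            {
                "id": [0, 1, 2, 3],
                "has_cancer": [True, True, False, False],
                "tumor_diameter_mm": [20.0, 5.0, 0.0, 0.0],
                "screen_positive": [True, False, True, False],
            }
        )
        counts = summarize(records)
        assert (counts.tp, counts.fn, counts.fp, counts.tn) == (1, 1, 1, 1)
        assert counts.ppv == pytest.approx(0.5)

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            summarize(pd.DataFrame(columns=["has_cancer", "screen_positive"]))

    def test_binned_sensitivity_increases_with_size(self):
        cfg = CohortConfig(
            n=40_000,
            prevalence=0.5,
            size_distribution=SizeDistribution("uniform", {"lo": 5.0, "hi": 35.0}),
            seed=8,
            panel_coverage_prob=1.0,
            positivity_prob=1.0,
            false_positive_prob=0.0,
        )
        records, _ = simulate_cohort(cfg)
        counts, per_bin = summarize(records, diameter_bins=[5, 15, 25, 35])
        assert counts.total == 40_000
        sens = per_bin["sensitivity"].to_numpy()
        assert (np.diff(sens) > 0).all()
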