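import numpy as np
import pytest

from spikecube.classifier import KNNParams
from spikecube.desnn import FeatureVector, Strategy
from spikecube.hrv import (
    RRSeries,
    baevsky_si,
    cohort_hrv,
    fuse,
    fuse_dataset,
    hrv_params,
    hrv_subset_search,
    segment,
)
from spikecube.synth import SynthSpec, generate


class TestSegmentation:
    def test_full_window_is_identity(self):
        rr = RRSeries(np.full(20, 1000.0))
        out = segment(rr, 0.0, 60.0)
        np.testing.assert_array_equal(out.intervals, rr.intervals)

    def test_constant_series_ten_second_window(self):
        rr = RRSeries(np.full(30, 1000.0))
        assert segment(rr, 0.0, 10.0).intervals.size == 10

    def test_boundary_interval_assigned_by_starting_peak(self):
        # peaks at 0, 0.8, 1.6 s; the interval starting at 0.8 belongs to a
        # window starting at 0.8 even though it ends outside it
        rr = RRSeries(np.array([800.0, 800.0]))
        out = segment(rr, 0.8, 0.5)
        assert out.intervals.tolist() == [800.0]

    def test_empty_window_rejected(self):
        rr = RRSeries(np.full(5, 1000.0))
        with pytest.raises(ValueError):
            segment(rr, 100.0, 10.0)


class TestHRVParams:
    def test_constant_series(self):
        p = hrv_params(RRSeries(np.array([800.0, 800, 800, 800])), 30.0)
        assert p.RMSSD == 0.0
        assert p.SDNN == 0.0
        assert p.meanHR == pytest.approx(75.0)

    def test_hand_computed_oracle(self):
        # diffs 10, −20, 15 → RMSSD = sqrt((100+400+225)/3); SDNN from the
        # sample variance of the four intervals
        p = hrv_params(RRSeries(np.array([800.0, 810, 790, 805])), 30.0)
        assert p.RMSSD == pytest.approx(np.sqrt(725.0 / 3.0))
        assert p.SDNN == pytest.approx(np.sqrt(218.75 / 3.0))

    def test_scale_equivariance(self):
        x = np.array([820.0, 760, 910, 850, 835])
        a = hrv_params(RRSeries(x), 30.0)
        b = hrv_params(RRSeries(2 * x), 30.0)
        assert b.RMSSD == pytest.approx(2 * a.RMSSD)
        assert b.SDNN == pytest.approx(2 * a.SDNN)

    def test_shift_invariance(self):
        x = np.array([820.0, 760, 910, 850, 835])
        a = hrv_params(RRSeries(x), 30.0)
        b = hrv_params(RRSeries(x + 100.0), 30.0)
        assert b.RMSSD == pytest.approx(a.RMSSD)
        assert b.SDNN == pytest.approx(a.SDNN)

    def test_ten_second_segment_rmssd_only(self):
        p = hrv_params(RRSeries(np.array([800.0, 810, 790, 805])), 10.0)
        assert p.RMSSD > 0
        assert np.isnan(p.SDNN) and np.isnan(p.SI) and np.isnan(p.meanHR)

    def test_too_few_intervals_rejected(self):
        with pytest.raises(ValueError):
            hrv_params(RRSeries(np.array([800.0, 810])), 30.0)

    def test_nonpositive_interval_rejected(self):
        with pytest.raises(ValueError):
            RRSeries(np.array([800.0, -5.0]))

    def test_si_increases_as_variability_shrinks(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, 300)
        sis = [
            baevsky_si(850.0 + sd * base)
            for sd in (80.0, 40.0, 20.0, 10.0)
        ]
        assert all(a < b for a, b in zip(sis, sis[1:]))

    def test_si_degenerate_series_infinite(self):
        assert baevsky_si(np.full(10, 800.0)) == np.inf

    def test_outlier_flagging(self):
        rr = RRSeries(np.array([800.0, 250.0, 2500.0, 900.0]))
        assert rr.flag_outliers().tolist() == [False, True, True, False]


class TestCohort:
    def test_composites_are_cohort_zscores(self):
        ds = generate(SynthSpec(n_per_class=8, seed=0))
        tab = cohort_hrv([segment(ds.rr(i), 0.0, 120.0) for i in range(16)], 120.0)
        assert abs(tab["PNS"].mean()) < 1e-9
        assert abs(tab["SNS"].mean()) < 1e-9


class TestFusion:
    def fv(self, n=4):
        return FeatureVector(np.arange(n, dtype=float), [f"f{i}" for i in range(n)],
                             Strategy.ALL32_IO, label=0)

    def test_empty_subset_identity(self):
        fv = self.fv()
        assert fuse(fv, {}) is fv

    def test_appends_named_features(self):
        out = fuse(self.fv(32 - 30), {"SNS": 1.2, "SI": 8.0})
        assert len(out.values) == 4
        assert out.feature_names[-2:] == ["SI", "SNS"]

    def test_name_collision_rejected(self):
        with pytest.raises(ValueError):
            fuse(self.fv(), {"f0": 1.0})

    def test_z_normalization_against_training_stats(self):
        out = fuse(self.fv(), {"SNS": 3.0}, stats={"SNS": (1.0, 2.0)})
        assert out.values[-1] == pytest.approx(1.0)

    def test_fused_dataset_classifies_hrv_only_signal(self):
        # EEG block is pure noise; all class signal lives in one HRV column
        rng = np.random.default_rng(1)
        n = 24
        y = [0] * (n // 2) + [1] * (n // 2)
        fvs = [
            FeatureVector(rng.normal(size=6), [f"f{i}" for i in range(6)],
                          Strategy.ALL32_IO, label=l)
            for l in y
        ]
        import pandas as pd

        tab = pd.DataFrame({"SNS": np.array(y) * 3.0 + rng.normal(0, 0.3, n)})
        fused = fuse_dataset(fvs, tab, ["SNS"])
        from spikecube.classifier import loocv

        X_eeg = np.stack([f.values for f in fvs])
        X_fused = np.stack([f.values for f in fused])
        p = KNNParams(k=3, feature_weighting="snr")
        assert loocv(X_fused, y, p).accuracy > loocv(X_eeg, y, p).accuracy
        assert loocv(X_fused, y, p).accuracy >= 90.0


class TestSubsetSearch:
    def test_row_count_is_subset_count(self):
        ds = generate(SynthSpec(n_per_class=6, seed=2))
        tab = cohort_hrv([segment(ds.rr(i), 0.0, 120.0) for i in range(12)], 120.0)
        _, _, table = hrv_subset_search(tab, ds.labels)
        p = 6  # PNS, SNS, SI, SDNN, RMSSD, meanHR
        assert len(table) == 2**p - 1

    def test_single_field_space(self):
        ds = generate(SynthSpec(n_per_class=6, seed=2))
        tab = cohort_hrv([segment(ds.rr(i), 0.0, 120.0) for i in range(12)], 120.0)
        best, _, table = hrv_subset_search(tab, ds.labels, fields=["RMSSD"])
        assert best == ["RMSSD"] and len(table) == 1

    def test_planted_sympathetic_analogue_recovered(self):
        # cohorts with no autonomic class difference; a shift planted only in
        # the SNS composite must be found by the exhaustive search
        wins = 0
        for seed in range(10):
            ds = generate(SynthSpec(seed=seed, rr_mean_shift=0.0, rr_var_shift=1.0))
            tab = cohort_hrv(
                [segment(ds.rr(i), 0.0, 120.0) for i in range(ds.n_subjects)], 120.0
            )
            y = np.array(ds.labels)
            tab.loc[y == 1, "SNS"] += 1.5
            best, _, _ = hrv_subset_search(tab, ds.labels)
            wins += "SNS" in best
        assert wins >= 9
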