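"""Generator behaviour: determinism, target statistics, artifact plumbing."""
import numpy as np
import pytest

from hrvaf import synthetic as syn
from hrvaf._errors import ConfigurationError
from hrvaf.types import RRSegment


def quiet_sr(**kw):
    base = dict(mean_rr_mu=800.0, mean_rr_sigma=0.0, resp_amplitude=0.0,
                noise_sd=0.0, noise_sd_spread=0.0, vlf_amplitude=0.0,
                ectopy_rate=0.0)
    base.update(kw)
    return syn.SRParams(**base)


class TestSRSeries:
    def test_degenerate_no_noise_is_constant(self):
        rec = syn.generate_sr_series(quiet_sr(), 60.0, np.random.default_rng(0))
        assert np.allclose(rec.rr_ms, 800.0)
        assert set(rec.rhythm_label) == {"SR"}
        # constant series: zero successive differences, hence pRR50 = 0
        from hrvaf.features import compute_features
        seg = RRSegment("p", "d", 0, "SR", rec.rr_ms, np.ones(len(rec) - 1, bool))
        assert compute_features(seg).pRR50 == 0.0

    def test_minimal_prefix_covers_duration(self):
        rec = syn.generate_sr_series(syn.SRParams(), 120.0, np.random.default_rng(3))
        assert rec.rr_ms.sum() >= 120_000.0
        assert rec.rr_ms[:-1].sum() < 120_000.0

    def test_determinism_same_seed(self):
        a = syn.generate_sr_series(syn.SRParams(), 300.0, np.random.default_rng(5))
        b = syn.generate_sr_series(syn.SRParams(), 300.0, np.random.default_rng(5))
        np.testing.assert_array_equal(a.rr_ms, b.rr_ms)

    def test_lag1_autocorrelation_matches_model(self):
        """Empirical lag-1 autocorrelation tracks the AR(1)+sinusoid value."""
        params = syn.SRParams(noise_sd_spread=0.0, vlf_amplitude_spread=0.0,
                              mean_rr_sigma=0.0, ectopy_rate=0.0)
        devs = []
        for p in range(10):
            rng = np.random.default_rng(100 + p)
            rec = syn.generate_sr_series(params, 600.0, rng)
            x = rec.rr_ms
            implied = syn.implied_sr_lag1_corr(
                rec.meta["mean_rr"], rec.meta["noise_sd"], rec.meta["ar1"],
                rec.meta["resp_amplitude"], rec.meta["resp_frequency"],
                rec.meta["vlf_amplitude"], rec.meta["vlf_frequency"])
            emp = np.corrcoef(x[:-1], x[1:])[0, 1]
            devs.append(abs(emp - implied))
        assert np.median(devs) < 0.1

    def test_invalid_duration_rejected(self):
        with pytest.raises(ConfigurationError):
            syn.generate_sr_series(syn.SRParams(), -1.0, np.random.default_rng(0))


class TestAFSeries:
    def test_cv_close_to_target(self):
        params = syn.AFParams(mean_rr_mu=650.0, mean_rr_sigma=0.0,
                              dispersion_cv=0.20, dispersion_cv_spread=0.0,
                              lag1_corr=0.0)
        rec = syn.generate_af_series(params, 600.0, np.random.default_rng(11))
        cv = rec.rr_ms.std(ddof=1) / rec.rr_ms.mean()
        assert 0.16 <= cv <= 0.24

    def test_zero_dispersion_limit_has_no_variability(self):
        params = syn.AFParams(mean_rr_mu=650.0, mean_rr_sigma=0.0,
                              dispersion_cv=0.0, dispersion_cv_spread=0.0)
        rec = syn.generate_af_series(params, 60.0, np.random.default_rng(1))
        assert np.allclose(rec.rr_ms, 650.0)  # pRR50 -> 0 in this limit

    def test_af_prr50_exceeds_sr(self):
        """Median pRR50 is far higher in default AF cohorts than SR ones."""
        from hrvaf.features import compute_features

        def median_prr(gen, params):
            vals = []
            for p in range(10):
                rec = gen(params, 120.0, np.random.default_rng(300 + p))
                seg = RRSegment("p", "d", 0, rec.rhythm_label[0], rec.rr_ms,
                                np.ones(len(rec) - 1, bool))
                vals.append(compute_features(seg).pRR50)
            return np.median(vals)

        assert median_prr(syn.generate_af_series, syn.AFParams()) \
            > median_prr(syn.generate_sr_series, syn.SRParams())

    def test_durations_stay_in_physiological_band(self):
        rec = syn.generate_af_series(syn.AFParams(dispersion_cv=0.4), 600.0,
                                     np.random.default_rng(2))
        assert rec.rr_ms.min() >= 240.0 and rec.rr_ms.max() <= 3000.0


class TestArtifacts:
    def test_rate_zero_returns_unchanged(self):
        rec = syn.generate_sr_series(quiet_sr(), 60.0, np.random.default_rng(0))
        assert syn.inject_artifacts(rec, 0.0, np.random.default_rng(1)) is rec

    def test_rate_one_marks_everything(self):
        rec = syn.generate_sr_series(quiet_sr(), 4.0, np.random.default_rng(0))
        rec.rr_ms = rec.rr_ms[:5]
        rec.beat_label = rec.beat_label[:5]
        rec.rhythm_label = rec.rhythm_label[:5]
        out = syn.inject_artifacts(rec, 1.0, np.random.default_rng(1))
        assert list(out.beat_label) == ["artifact"] * 5
        assert np.all((out.rr_ms < 240) | (out.rr_ms > 3000))

    def test_injection_count_binomial(self):
        params = quiet_sr(mean_rr_mu=600.0)
        rec = syn.generate_sr_series(params, 6000.0, np.random.default_rng(0))
        rec.rr_ms = rec.rr_ms[:10_000]
        rec.beat_label = rec.beat_label[:10_000]
        rec.rhythm_label = rec.rhythm_label[:10_000]
        out = syn.inject_artifacts(rec, 0.02, np.random.default_rng(42))
        count = int(np.sum(out.beat_label == "artifact"))
        assert abs(count - 200) <= 3 * np.sqrt(200)


class TestCohort:
    def test_cohort_determinism(self):
        cfg = syn.GeneratorConfig(n_patients_per_class=4, recording_duration=120.0, seed=9)
        recs1, man1 = syn.generate_cohort(cfg)
        recs2, man2 = syn.generate_cohort(cfg)
        assert man1.equals(man2)
        for a, b in zip(recs1, recs2):
            np.testing.assert_array_equal(a.rr_ms, b.rr_ms)
            np.testing.assert_array_equal(a.rhythm_label, b.rhythm_label)

    def test_artifacts_only_source_of_out_of_band_durations(self, small_cohort):
        for rec in small_cohort["recordings"]:
            out_of_band = (rec.rr_ms < 240) | (rec.rr_ms > 3000)
            assert np.all(rec.beat_label[out_of_band] == "artifact")

    def test_prr50_separates_better_than_mean_rr(self, small_cohort):
        """Class histogram overlap of pRR50 < overlap of mean RR."""
        table = small_cohort["table"]

        def overlap(col):
            af = table.loc[table.rhythm_class == "AF", col]
            sr = table.loc[table.rhythm_class == "SR", col]
            lo = max(af.min(), sr.min())
            hi = min(af.max(), sr.max())
            both = ((table[col] >= lo) & (table[col] <= hi)).mean()
            return both

        from hrvaf.ranking import feature_auc
        auc_p, _ = feature_auc(table, "pRR50")
        auc_m, _ = feature_auc(table, "meanRR")
        assert auc_p > auc_m  # smaller overlap <=> larger separability

    def test_invalid_config_rejected(self):
        cfg = syn.GeneratorConfig(artifact_rate=1.5)
        with pytest.raises(ConfigurationError):
            cfg.validate()

    def test_roundtrip_text_io(self, tmp_path):
        cfg = syn.GeneratorConfig(n_patients_per_class=2, recording_duration=90.0, seed=3)
        recs, man = syn.generate_cohort(cfg)
        syn.write_cohort(recs, man, tmp_path / "cohort", cfg)
        recs2, man2 = syn.read_cohort(tmp_path / "cohort")
        assert len(recs2) == len(recs)
        got = {r.patient_id: r for r in recs2}
        for r in recs:
            np.testing.assert_allclose(got[r.patient_id].rr_ms, r.rr_ms)
            np.testing.assert_array_equal(got[r.patient_id].rhythm_label, r.rhythm_label)


class TestFilterFixtures:
    def test_documented_counts(self):
        from hrvaf.preprocessing import segment_recording

        for fx in syn.make_filter_fixtures():
            segs, qc = segment_recording(fx.recording)
            assert len(segs) == fx.expected_segments, fx.note
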