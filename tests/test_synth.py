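import numpy as np
import pytest

from windfa import (CohortSpec, HurstProfile, dfa, generate_cohort,
                    generate_fgn, generate_modulated_signal, sliding_alpha)
from windfa.synth import _fgn_autocovariance


class TestGenerateFgn:
    def test_h_half_is_white(self):
        x = generate_fgn(0.5, 65536, seed=0).samples
        rho1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert abs(rho1) < 3 / np.sqrt(x.size)

    def test_autocovariance_matches_closed_form(self):
        H, N = 0.75, 65536
        x = generate_fgn(H, N, seed=1).samples
        gamma = _fgn_autocovariance(H, np.arange(11))
        for k in range(1, 11):
            sample_cov = np.mean(x[:-k] * x[k:])
            # Monte-Carlo SD of the lag covariance estimate, ~3 sigma band
            mc_sd = 3.0 / np.sqrt(N - k)
            assert abs(sample_cov - gamma[k]) < 3 * mc_sd

    def test_unit_second_moment(self):
        # note: the mean-subtracted sample variance is biased low by
        # N**(2H-2) under long-range dependence, so test E[x^2] instead
        for H in (0.3, 0.6, 0.9):
            moments = [np.mean(generate_fgn(H, 32768, seed=s).samples ** 2)
                       for s in range(5)]
            assert np.mean(moments) == pytest.approx(1.0, rel=0.05)

    def test_alpha_equals_h(self):
        fit = dfa(generate_fgn(0.75, 65536, seed=3))
        assert fit.alpha == pytest.approx(0.75, abs=0.05)

    def test_reproducible(self):
        a = generate_fgn(0.7, 1024, seed=9).samples
        b = generate_fgn(0.7, 1024, seed=9).samples
        assert np.array_equal(a, b)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            generate_fgn(1.2, 100)
        with pytest.raises(ValueError):
            generate_fgn(0.5, 1)


class TestHurstProfile:
    def test_non_contiguous_rejected(self):
        with pytest.raises(ValueError, match="contiguous"):
            HurstProfile(segments=((0, 1, 0.5), (2, 3, 0.6)))

    def test_h_outside_range_rejected(self):
        with pytest.raises(ValueError):
            HurstProfile(segments=((0, 1, 1.5),))

    def test_crossfade_too_long_rejected(self):
        with pytest.raises(ValueError, match="crossfade"):
            HurstProfile(segments=((0, 1, 0.5), (1, 2, 0.8)), crossfade_s=1.5)


class TestModulatedSignal:
    def test_flat_profile_statistics_match_plain_fgn(self):
        # windowed-alpha distributions indistinguishable (KS over 20 seeds)
        from scipy import stats as sstats
        alphas_mod, alphas_fgn = [], []
        for seed in range(20):
            prof = HurstProfile(segments=((0.0, 12.0, 0.5),))
            mod = generate_modulated_signal(prof, 250, seed=seed).samples
            fgn = generate_fgn(0.5, mod.size, seed=seed + 100).samples
            alphas_mod.extend(sliding_alpha(mod, 500, 500).alphas)
            alphas_fgn.extend(sliding_alpha(fgn, 500, 500).alphas)
        p = sstats.ks_2samp(alphas_mod, alphas_fgn).pvalue
        assert p > 0.01

    def test_bump_recovered_by_sliding_dfa(self):
        prof = HurstProfile(segments=((0, 4, 0.5), (4, 7, 0.9), (7, 11, 0.5)))
        trajs = []
        for seed in range(10):
            sig = generate_modulated_signal(prof, 250, seed=seed)
            trajs.append(sliding_alpha(sig.samples, 500, 25, sampling_rate=250).alphas)
        mean_alpha = np.mean(trajs, axis=0)
        times = sliding_alpha(np.zeros(int(11 * 250)), 500, 25, sampling_rate=250).times
        peak_t = times[np.argmax(mean_alpha)]
        assert 4.0 < peak_t < 7.0

    def test_two_bumps_two_local_maxima(self):
        prof = HurstProfile(segments=((0, 3, 0.5), (3, 5.5, 0.85), (5.5, 8, 0.5),
                                      (8, 10.5, 0.85), (10.5, 14, 0.5)))
        trajs = []
        for seed in range(12):
            sig = generate_modulated_signal(prof, 250, seed=seed)
            trajs.append(sliding_alpha(sig.samples, 500, 50, sampling_rate=250).alphas)
        m = np.mean(trajs, axis=0)
        # smooth lightly, then count strict interior local maxima above baseline
        kernel = np.ones(3) / 3
        ms = np.convolve(m, kernel, mode="valid")
        peaks = [i for i in range(1, ms.size - 1)
                 if ms[i] > ms[i - 1] and ms[i] > ms[i + 1] and ms[i] > 0.6]
        assert len(peaks) >= 2

    def test_variance_close_to_unit(self):
        prof = HurstProfile(segments=((0, 5, 0.5), (5, 8, 0.9), (8, 12, 0.5)))
        sig = generate_modulated_signal(prof, 250, seed=4).samples
        assert sig.var() == pytest.approx(1.0, rel=0.1)

    def test_reproducible(self):
        prof = HurstProfile(segments=((0, 5, 0.6),))
        a = generate_modulated_signal(prof, 250, seed=1).samples
        b = generate_modulated_signal(prof, 250, seed=1).samples
        assert np.array_equal(a, b)


class TestGenerateCohort:
    def test_default_counts(self):
        spec = CohortSpec(channels=("C4",), seed=5)   # default 10 subjects, 30/hand
        cohort = generate_cohort(spec)
        assert len(cohort.recordings) == 20
        for sid, ev in cohort.events.items():
            assert (ev["hand"] == "LH").sum() == 30
            assert (ev["hand"] == "RH").sum() == 30
            assert ev.loc[ev["hand"] == "LH", "keep"].sum() == 15
            assert ev.loc[ev["hand"] == "RH", "keep"].sum() == 15
            assert set(ev.loc[ev["hand"] == "LH", "cue_duration_s"]) == {0.3}
            assert set(ev.loc[ev["hand"] == "RH", "cue_duration_s"]) == {0.75}

    def test_reproducible_bit_identical(self, small_cohort):
        spec, cohort = small_cohort
        again = generate_cohort(spec)
        for sid in cohort.recordings:
            assert np.array_equal(cohort.recordings[sid].data,
                                  again.recordings[sid].data)
            assert cohort.events[sid].equals(again.events[sid])
        assert cohort.manifest == again.manifest

    def test_channel_rms_normalized(self, small_cohort):
        spec, cohort = small_cohort
        rec = next(iter(cohort.recordings.values()))
        rms = rec.data.std(axis=0)
        assert np.allclose(rms, spec.signal_rms_uv, rtol=0.05)

    def test_manifest_records_truth(self, small_cohort):
        spec, cohort = small_cohort
        man = cohort.manifest
        assert man["seed"] == spec.seed
        assert len(man["subjects"]) == 2 * spec.n_subjects
        for entry in man["subjects"]:
            assert 0.3 <= entry["baseline_hurst"] <= 0.8
            assert set(entry["slopes"]) == {"LH:clench", "RH:clench",
                                            "LH:unclench", "RH:unclench"}

    def test_infeasible_targets_clipped_with_warning(self):
        spec = CohortSpec(n_subjects=1, trials_per_hand=1, keep_per_hand=1,
                          channels=("C4",), baseline_hurst=0.9,
                          slope_targets={("elderly", h, s): 0.3
                                         for h in ("LH", "RH")
                                         for s in ("clench", "unclench")} | {
                                        ("young", h, s): 0.3
                                         for h in ("LH", "RH")
                                         for s in ("clench", "unclench")},
                          seed=0)
        with pytest.warns(UserWarning, match="clipped"):
            cohort = generate_cohort(spec)
        assert cohort.manifest["clipped"] is True

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(keep_per_hand=40, trials_per_hand=30)
        with pytest.raises(ValueError):
            CohortSpec(channels=("C4", "C4"))
        with pytest.raises(ValueError):
            CohortSpec(baseline_hurst=1.2)
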