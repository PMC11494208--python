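"""Cosine tuning fits, circular deltas, bootstrap change detection, maps."""

import numpy as np
import pandas as pd
import pytest

from mindful.tuning import (
    TuningFit,
    TuningMap,
    TuningSamples,
    bootstrap_delta_significance,
    build_tuning_map,
    cluster_feature_order,
    correlate_kld_with_similarity,
    delta_tuning,
    extract_tuning_samples,
    fit_cosine,
    session_tuning_fits,
    tuning_similarity,
)


def make_samples(md, pd_deg, n_trials=40, bins_per_trial=50, noise=0.0,
                 seed=0, b0=0.0):
    """Cosine-tuned samples over 8 directions with optional Gaussian noise."""
    rng = np.random.default_rng(seed)
    dirs = np.tile(np.arange(0, 360, 45.0), n_trials // 8 + 1)[:n_trials]
    theta = np.repeat(dirs, bins_per_trial)
    trial_id = np.repeat(np.arange(n_trials), bins_per_trial)
    y = b0 + md * np.cos(np.radians(theta - pd_deg))
    if noise:
        y = y + rng.normal(0, noise, y.shape)
    return TuningSamples(theta_deg=theta, y=y, trial_id=trial_id,
                         feature_id=0, session_day=0)


class TestCosineFit:
    @pytest.mark.parametrize(
        "md, pd_deg",
        [(1.0, 0.0), (2.0, 90.0), (0.7, 215.0)],
    )
    def test_noiseless_exact_recovery(self, md, pd_deg):
        fit = fit_cosine(make_samples(md, pd_deg))
        assert fit.md == pytest.approx(md, abs=1e-10)
        assert fit.pd_deg == pytest.approx(pd_deg, abs=1e-8)
        assert fit.b0 == pytest.approx(0.0, abs=1e-10)
        assert fit.p_value < 1e-10
        assert fit.significant

    def test_noisy_recovery_within_tolerance(self):
        """Planted (md, pd) recovered within 20% / 10 deg at 40 trials."""
        fit = fit_cosine(make_samples(0.5, 130.0, noise=1.0, seed=1))
        assert fit.md == pytest.approx(0.5, rel=0.2)
        assert abs(((fit.pd_deg - 130.0 + 180) % 360) - 180) < 10.0

    def test_untuned_feature_not_significant(self):
        samples = make_samples(0.0, 0.0, noise=1.0, seed=2)
        fit = fit_cosine(samples)
        assert fit.p_value > 0.05

    def test_rank_deficient_design_rejected(self):
        s = make_samples(1.0, 0.0)
        s.theta_deg[:] = 90.0
        with pytest.raises(ValueError, match="distinct"):
            fit_cosine(s)


class TestDeltaTuning:
    def mk(self, md, pd_deg):
        return TuningFit(b0=0, b1=md * np.cos(np.radians(pd_deg)),
                         b2=md * np.sin(np.radians(pd_deg)), md=md,
                         pd_deg=pd_deg, f_stat=100.0, p_value=0.0, n_obs=100)

    @pytest.mark.parametrize(
        "pd_now, pd_ref, expected",
        [(350.0, 10.0, 20.0), (10.0, 190.0, 180.0), (90.0, 45.0, 45.0)],
    )
    def test_circular_pd_difference(self, pd_now, pd_ref, expected):
        _, dpd = delta_tuning(self.mk(1.0, pd_now), self.mk(1.0, pd_ref))
        assert dpd == pytest.approx(expected)

    def test_md_difference_signed(self):
        dmd, _ = delta_tuning(self.mk(0.8, 0.0), self.mk(1.0, 0.0))
        assert dmd == pytest.approx(-0.2)

    def test_self_delta_is_zero(self):
        f = self.mk(1.3, 77.0)
        assert delta_tuning(f, f) == (0.0, 0.0)


class TestBootstrap:
    def test_matched_sessions_not_significant(self):
        a = make_samples(0.6, 45.0, noise=1.0, seed=3)
        b = make_samples(0.6, 45.0, noise=1.0, seed=4)
        res = bootstrap_delta_significance(a, b, B=1000, rng=0)
        assert not res.significant_pd
        assert res.ci_pd[0] <= 0.0 <= res.ci_pd[1]

    def test_planted_rotation_detected(self):
        a = make_samples(0.6, 45.0, noise=1.0, seed=5)
        b = make_samples(0.6, 105.0, noise=1.0, seed=6)
        res = bootstrap_delta_significance(a, b, B=1000, rng=1)
        assert res.significant_pd
        assert res.significant_change

    def test_ci_endpoints_ordered(self):
        a = make_samples(0.5, 10.0, noise=1.0, seed=7)
        b = make_samples(0.8, 350.0, noise=1.0, seed=8)
        res = bootstrap_delta_significance(a, b, B=200, rng=2)
        assert res.ci_md[0] <= res.ci_md[1]
        assert res.ci_pd[0] <= res.ci_pd[1]


class TestExtraction:
    def test_observation_count_and_outlier_exclusion(self, small_session):
        sess = small_session.copy()
        z = np.asarray(sess.features, dtype=float)
        base = extract_tuning_samples(sess, z)
        # flag the longest trial as outlier; its bins must disappear
        spans = [(t.end_bin - t.start_bin, i) for i, t in enumerate(sess.trials)]
        _, idx = max(spans)
        from dataclasses import replace
        sess.trials[idx] = replace(sess.trials[idx], outlier=True)
        cut = extract_tuning_samples(sess, z)
        assert len(cut[0].y) < len(base[0].y)
        assert idx not in np.unique(cut[0].trial_id)

    def test_fifty_bins_per_full_trial(self, small_session):
        samples = extract_tuning_samples(small_session, small_session.features)
        counts = np.bincount(samples[0].trial_id)
        full = [
            t for t in small_session.trials
            if t.end_bin - t.go_cue_bin >= 58  # 160 ms offset + 1 s window
        ]
        for i, t in enumerate(small_session.trials):
            if t in full and counts[i]:
                assert counts[i] == 50


class TestMapsAndClustering:
    def fits_frame(self, sig_flags, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "feature_id": np.arange(len(sig_flags)),
                "b0": rng.normal(0, 0.1, len(sig_flags)),
                "b1": rng.normal(0, 1, len(sig_flags)),
                "b2": rng.normal(0, 1, len(sig_flags)),
                "md": np.ones(len(sig_flags)),
                "pd": np.zeros(len(sig_flags)),
                "f": np.ones(len(sig_flags)),
                "p": np.where(sig_flags, 0.01, 0.5),
                "significant": sig_flags,
                "n_obs": 400,
                "session_day": 0,
            }
        )

    def test_map_keeps_only_significant_features(self):
        tmap = build_tuning_map(self.fits_frame([True, False, True, True, False]))
        assert tmap.params.shape == (3, 3)
        np.testing.assert_array_equal(tmap.feature_ids, [0, 2, 3])

    def test_similarity_self_and_sign_flip(self):
        tmap = build_tuning_map(self.fits_frame([True] * 6, seed=1))
        assert tuning_similarity(tmap, tmap) == pytest.approx(1.0)
        flipped = TuningMap(
            session_day=1, feature_ids=tmap.feature_ids, params=-tmap.params
        )
        assert tuning_similarity(tmap, flipped) == pytest.approx(-1.0)

    def test_similarity_missing_below_two_shared(self):
        a = build_tuning_map(self.fits_frame([True, False, False]))
        b = build_tuning_map(self.fits_frame([False, False, True]))
        assert np.isnan(tuning_similarity(a, b))

    def test_cluster_groups_planted_profiles(self):
        rng = np.random.default_rng(3)
        S, F = 6, 10
        profile_a = np.linspace(0, 1, S)[:, None]
        profile_b = np.linspace(0, -1, S)[:, None]
        cols = {}
        for f in range(F):
            base = profile_a if f % 2 == 0 else profile_b
            cols[f] = base[:, 0] + rng.normal(0, 0.05, S)
        dmd = pd.DataFrame(cols)
        dpd = pd.DataFrame({f: rng.normal(0, 0.05, S) for f in range(F)})
        order = cluster_feature_order(dmd, dpd)
        assert sorted(order) == list(range(F))  # a bijection
        parity = [o % 2 for o in order]
        # planted even/odd clusters come out contiguous
        assert parity[:5] == [parity[0]] * 5 and parity[5:] == [parity[5]] * 5

    def test_single_feature_identity_order(self):
        dmd = pd.DataFrame({0: [0.1, 0.2]})
        dpd = pd.DataFrame({0: [1.0, 2.0]})
        np.testing.assert_array_equal(cluster_feature_order(dmd, dpd), [0])

    def test_kld_similarity_correlation_trivial(self):
        rng = np.random.default_rng(4)
        m = np.abs(rng.normal(0, 1, (5, 5)))
        kld = pd.DataFrame(m)
        sim = pd.DataFrame(-m)
        r, _ = correlate_kld_with_similarity(kld, sim)
        assert r == pytest.approx(-1.0)


class TestSessionFits:
    def test_simulated_population_widely_tuned(self, drifting_study,
                                               drifting_zscores):
        sessions, _, _ = drifting_study
        fits = session_tuning_fits(sessions[0], drifting_zscores[0])
        assert len(fits) == sessions[0].n_channels
        assert fits["significant"].mean() > 0.8

    def test_day0_pd_recovery_against_ground_truth(self, population,
                                                   drifting_study,
                                                   drifting_zscores):
        """Fitted PDs on the undrifted day match the generator's PDs."""
        sessions, _, _ = drifting_study
        fits = session_tuning_fits(sessions[0], drifting_zscores[0])
        sig = fits[fits["significant"]]
        err = ((sig["pd"].to_numpy() - population.pd_deg[sig["feature_id"]]
                + 180) % 360) - 180
        assert np.median(np.abs(err)) < 10.0
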