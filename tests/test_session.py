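"""Session data model: serialization round trips, invariants, outlier rules."""

import numpy as np
import pytest

from mindful.session import (
    BinnedSession,
    SessionFormatError,
    SessionIntegrityError,
    TrialRecord,
    flag_outlier_trials,
    read_session,
    write_session,
)


def make_session(T=200, C=4, n_trials=4, seed=0, drop_fracs=None):
    rng = np.random.default_rng(seed)
    span = T // n_trials
    trials = []
    for i in range(n_trials):
        s = i * span
        trials.append(
            TrialRecord(
                start_bin=s,
                go_cue_bin=s,
                end_bin=s + span - 2,  # leave a gap between trials
                target=rng.uniform(-0.4, 0.4, 2),
                success=bool(i % 2),
                packet_drop_frac=(drop_fracs or [0.0] * n_trials)[i],
            )
        )
    return BinnedSession(
        session_day=0,
        features=rng.normal(0, 1, (T, C)),
        decoded_velocity=rng.normal(0, 0.1, (T, 2)),
        cursor_pos=rng.uniform(-0.5, 0.5, (T, 2)),
        target_pos=rng.uniform(-0.5, 0.5, (T, 2)),
        block_id=np.repeat([0, 1], [T // 2, T - T // 2]),
        trials=trials,
    )


class TestRoundTrip:
    @pytest.mark.parametrize("fmt", ["csv", "parquet"])
    def test_write_read_identity(self, tmp_path, fmt):
        sess = make_session(seed=1)
        write_session(sess, tmp_path / "s0", fmt=fmt)
        back = read_session(tmp_path / "s0")
        np.testing.assert_array_equal(back.features, sess.features)
        np.testing.assert_array_equal(back.decoded_velocity, sess.decoded_velocity)
        np.testing.assert_array_equal(back.cursor_pos, sess.cursor_pos)
        np.testing.assert_array_equal(back.target_pos, sess.target_pos)
        np.testing.assert_array_equal(back.block_id, sess.block_id)
        assert back.session_day == sess.session_day
        assert back.bin_width == sess.bin_width
        assert len(back.trials) == len(sess.trials)
        for a, b in zip(back.trials, sess.trials):
            assert (a.start_bin, a.go_cue_bin, a.end_bin) == (
                b.start_bin, b.go_cue_bin, b.end_bin)
            np.testing.assert_array_equal(a.target, b.target)
            assert a.success == b.success
            assert a.packet_drop_frac == b.packet_drop_frac

    def test_empty_trial_list(self, tmp_path):
        sess = make_session()
        sess.trials = []
        write_session(sess, tmp_path / "s")
        assert read_session(tmp_path / "s").trials == []

    def test_two_block_boundaries_preserved(self, tmp_path):
        sess = make_session()
        write_session(sess, tmp_path / "s")
        back = read_session(tmp_path / "s")
        np.testing.assert_array_equal(back.block_starts(), sess.block_starts())

    def test_simulator_output_round_trips(self, tmp_path, small_session):
        write_session(small_session, tmp_path / "sim")
        back = read_session(tmp_path / "sim")
        back.validate()
        np.testing.assert_array_equal(back.features, small_session.features)


class TestInvariants:
    def test_length_mismatch_rejected(self):
        sess = make_session()
        with pytest.raises(SessionIntegrityError, match="decoded_velocity"):
            BinnedSession(
                session_day=0,
                features=sess.features,
                decoded_velocity=sess.decoded_velocity[:-1],
                cursor_pos=sess.cursor_pos,
                target_pos=sess.target_pos,
                block_id=sess.block_id,
            )

    def test_overlapping_trials_rejected(self):
        sess = make_session()
        bad = [
            TrialRecord(0, 0, 50, np.zeros(2), True),
            TrialRecord(40, 40, 90, np.zeros(2), True),
        ]
        with pytest.raises(SessionIntegrityError, match="overlaps"):
            BinnedSession(
                session_day=0,
                features=sess.features,
                decoded_velocity=sess.decoded_velocity,
                cursor_pos=sess.cursor_pos,
                target_pos=sess.target_pos,
                block_id=sess.block_id,
                trials=bad,
            )

    def test_trial_span_ordering_enforced(self):
        with pytest.raises(SessionIntegrityError):
            TrialRecord(start_bin=10, go_cue_bin=5, end_bin=20, target=np.zeros(2),
                        success=True)

    def test_missing_meta_is_format_error(self, tmp_path):
        (tmp_path / "empty").mkdir()
        with pytest.raises(SessionFormatError, match="meta.json"):
            read_session(tmp_path / "empty")

    def test_missing_column_named_in_error(self, tmp_path):
        sess = make_session()
        write_session(sess, tmp_path / "s")
        bins = (tmp_path / "s" / "bins.csv").read_text().splitlines()
        header = bins[0].replace("vx_hat", "vx_renamed")
        (tmp_path / "s" / "bins.csv").write_text("\n".join([header] + bins[1:]))
        with pytest.raises(SessionFormatError, match="vx_hat"):
            read_session(tmp_path / "s")


class TestOutlierFlagging:
    def test_packet_drop_above_threshold_flagged(self):
        sess = make_session(drop_fracs=[0.0, 0.06, 0.0, 0.0])
        n = flag_outlier_trials(sess)
        assert n == 1
        assert [t.outlier for t in sess.trials] == [False, True, False, False]

    def test_clean_gaussian_session_has_no_outliers(self):
        # with 8-SD threshold, N(0,1) features at T=10^4 essentially never trip
        sess = make_session(T=10_000, C=8, n_trials=8, seed=42)
        assert flag_outlier_trials(sess) == 0

    def test_injected_spike_flags_exactly_that_trial(self):
        sess = make_session(seed=5)
        mu = sess.features[:, 2].mean()
        sd = sess.features[:, 2].std()
        spike_bin = sess.trials[2].start_bin + 3
        sess.features[spike_bin, 2] = mu + 10 * sd
        flag_outlier_trials(sess)
        assert [t.outlier for t in sess.trials] == [False, False, True, False]

    def test_idempotent_and_monotone_in_amp_sd(self):
        sess = make_session(T=2000, C=6, n_trials=8, seed=9)
        n1 = flag_outlier_trials(sess, amp_sd=3.0)
        flagged_tight = [t.outlier for t in sess.trials]
        n2 = flag_outlier_trials(sess, amp_sd=3.0)
        assert n1 == n2 and [t.outlier for t in sess.trials] == flagged_tight
        flag_outlier_trials(sess, amp_sd=8.0)
        flagged_loose = [t.outlier for t in sess.trials]
        # lower threshold flags a superset
        assert all(l or not t for l, t in zip(flagged_tight, flagged_loose))

    def test_zero_variance_channel_skipped(self):
        sess = make_session()
        sess.features[:, 0] = 1.5
        assert flag_outlier_trials(sess) == 0
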