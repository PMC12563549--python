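"""HRF, motion censoring, LS-S design construction and fitting."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from icnet.glm import (build_lss_designs, censor, double_gamma_hrf, fit_lss,
                       hrf_regressor, hrf_regressor_matrix)

TR = 1.56


def make_events(onsets, phase="encoding", duration=6.0, run=0):
    """Minimal encoding event table: only trial events (plus run/phase)."""
    rows = []
    for k, on in enumerate(onsets):
        rows.append(dict(onset=on, duration=duration, trial_type="encoding",
                         trial=k, context="spatial", response_time=np.nan,
                         correct=True, run=run, phase=phase))
    return pd.DataFrame(rows)


class TestHrf:
    def test_shape_of_kernel(self):
        h = double_gamma_hrf(0.1)
        t = np.arange(h.size) * 0.1
        assert h[0] == 0.0
        assert h.max() == pytest.approx(1.0)
        assert 4.0 < t[np.argmax(h)] < 6.0
        # one sign change: positive lobe then undershoot
        signs = np.sign(h[np.abs(h) > 1e-12])
        changes = np.count_nonzero(np.diff(signs))
        assert changes == 1

    def test_bad_args(self):
        with pytest.raises(ValueError):
            double_gamma_hrf(0.0)
        with pytest.raises(ValueError):
            double_gamma_hrf(0.1, length=10)
        with pytest.raises(ValueError):
            double_gamma_hrf(50.0, length=32)

    def test_regressor_support(self):
        # a 6 s boxcar convolved with the HRF stays up for > 6 s
        col = hrf_regressor([10.0], [6.0], n_vols=60, tr=TR)
        assert col[:6].sum() == pytest.approx(0.0, abs=1e-12)
        dur_above = (col > 1e-3).sum() * TR
        assert dur_above >= 6.0


class TestCensor:
    def test_quiet_run(self):
        ev = make_events([10, 30, 50])
        rep = censor(np.full(60, 0.1), ev, TR)
        assert rep.censored_volumes.size == 0
        assert not rep.run_excluded and rep.usable
        assert rep.excluded_trials == {}

    def test_run_exclusion_fraction(self):
        ev = make_events([10.0])
        fd = np.full(100, 0.1)
        fd[:25] = 1.0   # 25% > 20%
        rep = censor(fd, ev, TR)
        assert rep.run_excluded
        fd2 = np.full(100, 0.1)
        fd2[:20] = 1.0  # exactly 20% is not "more than 20%"
        assert not censor(fd2, ev, TR).run_excluded

    def test_absolute_motion_exclusion(self):
        ev = make_events([10.0])
        rep = censor(np.full(40, 0.1), ev, TR, abs_motion=1.3)
        assert rep.abs_motion_excluded and not rep.usable

    def test_spike_excludes_only_affected_trial(self):
        ev = make_events([10.0, 60.0, 110.0])
        fd = np.full(120, 0.1)
        spike_vol = int(round(12.0 / TR))  # 2 s after trial 0 onset
        fd[spike_vol] = 1.0
        rep = censor(fd, ev, TR)
        assert list(rep.excluded_trials) == [0]
        assert not rep.run_excluded

    def test_window_includes_hrf_rise(self):
        # spike 4 s after trial offset still contaminates the response
        ev = make_events([10.0])
        fd = np.full(60, 0.1)
        fd[int(round(20.0 / TR))] = 1.0   # t=20 s < 10+6+6
        assert 0 in censor(fd, ev, TR).excluded_trials

    def test_negative_fd_rejected(self):
        with pytest.raises(ValueError):
            censor(np.array([-0.1, 0.2]), make_events([1.0]), TR)


class TestDesigns:
    def test_one_design_per_trial(self, tiny_encoding_session):
        rd = tiny_encoding_session["runs"][0]
        designs = build_lss_designs(rd.events, "encoding",
                                    rd.data.shape[0], rd.tr)
        n_trials = (rd.events["trial_type"] == "encoding").sum()
        assert len(designs) == n_trials
        for d in designs:
            assert d.names.count("trial_of_interest") == 1
            assert not np.any(np.all(d.matrix == 0, axis=0))

    def test_designs_differ_only_in_trial_partition(self, tiny_encoding_session):
        rd = tiny_encoding_session["runs"][0]
        designs = build_lss_designs(rd.events, "encoding",
                                    rd.data.shape[0], rd.tr)
        d0, d1 = designs[0], designs[1]
        # columns 0+1 (trial + others) sum to the same total regressor
        assert np.allclose(d0.matrix[:, 0] + d0.matrix[:, 1],
                           d1.matrix[:, 0] + d1.matrix[:, 1], atol=1e-12)
        assert np.allclose(d0.matrix[:, 2:], d1.matrix[:, 2:], atol=1e-12)

    def test_missing_rt_flagged_with_nominal_duration(self):
        ev = make_events([10.0, 60.0])
        ev.loc[ev["trial"] == 1, "duration"] = np.nan
        designs = build_lss_designs(ev, "encoding", 80, TR)
        assert designs[1].flags == ["missing_rt"]
        assert designs[0].flags == []

    def test_retrieval_uses_source_period(self, tiny_study):
        from icnet.synthetic import generate_events

        ev = generate_events(tiny_study, 0, "pre")["retrieval"][0]
        designs = build_lss_designs(ev, "retrieval", 200, TR)
        n_src = (ev["trial_type"] == "source_retrieval").sum()
        assert len(designs) == n_src
        assert "item_retrieval" in designs[0].names
        assert "iti" not in designs[0].names   # implicit baseline at retrieval


class TestFitLss:
    def test_noiseless_signal_from_design_recovers_exactly(self, rng):
        # TR-aligned, widely spaced onsets: identical regressor shapes
        ev = make_events([(6 + 32 * k) * TR for k in range(4)])
        n_vols = 140
        designs = build_lss_designs(ev, "encoding", n_vols, TR)
        amps = rng.normal(size=(4, 20))
        cols = hrf_regressor_matrix(ev["onset"], ev["duration"], n_vols, TR)
        Y = cols @ amps
        fit = fit_lss(Y, designs)
        assert np.abs(fit.betas - amps).max() < 1e-8

    def test_lss_equals_full_model_for_isolated_trials(self, rng):
        # TR-aligned, widely spaced equal-duration trials, no nuisance events
        ev = make_events([(6 + 32 * k) * TR for k in range(4)])
        n_vols = 160
        designs = build_lss_designs(ev, "encoding", n_vols, TR)
        amps = rng.normal(size=(4, 10))
        cols = hrf_regressor_matrix(ev["onset"], ev["duration"], n_vols, TR)
        Y = cols @ amps
        fit = fit_lss(Y, designs)
        full = np.column_stack([cols, np.ones(n_vols)])
        beta_full, *_ = np.linalg.lstsq(full, Y, rcond=None)
        assert np.abs(fit.betas - beta_full[:4]).max() < 1e-8

    def test_white_noise_tmaps_follow_student_t(self, rng):
        ev = make_events([10.0, 60.0, 110.0, 160.0])
        n_vols = 140
        designs = build_lss_designs(ev, "encoding", n_vols, TR)
        Y = rng.normal(size=(n_vols, 5000))
        fit = fit_lss(Y, designs)
        dof = n_vols - designs[0].matrix.shape[1]
        ks = sps.kstest(fit.tmaps[0], sps.t(df=dof).cdf)
        assert ks.pvalue > 0.01

    def test_noise_halves_t(self, rng):
        ev = make_events([10.0, 60.0, 110.0, 160.0])
        n_vols = 140
        designs = build_lss_designs(ev, "encoding", n_vols, TR)
        cols = hrf_regressor_matrix(ev["onset"], ev["duration"], n_vols, TR)
        amps = np.ones((4, 2000))
        t_by_sd = {}
        for sd in (1.0, 2.0):
            Y = cols @ amps + rng.normal(0, sd, size=(n_vols, 2000))
            t_by_sd[sd] = np.abs(fit_lss(Y, designs).tmaps).mean()
        assert t_by_sd[1.0] / t_by_sd[2.0] == pytest.approx(2.0, rel=0.1)

    def test_rank_deficient_design_named(self):
        ev = make_events([10.0, 60.0])
        designs = build_lss_designs(ev, "encoding", 80, TR,
                                    motion=np.ones((80, 1)))
        # motion column identical to the intercept -> collinear
        with pytest.raises(np.linalg.LinAlgError, match="intercept|motion"):
            fit_lss(np.zeros((80, 3)), designs, check_rank=True)
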