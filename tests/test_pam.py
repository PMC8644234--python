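"""Saturation-pulse quenching analysis and state-transition kinetics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import granafit as gf
from granafit.exceptions import DegenerateError, DomainError, ProtocolError
from granafit.synth import NoiseSpec


class TestPsiiYields:
    def test_closed_reaction_centres(self):
        r = gf.psii_yields(F=0.5, FMp=0.5, F0=0.2, FM=1.0)
        assert r.YII == 0.0
        assert r.NPQ == pytest.approx(1.0)
        assert r.qP == pytest.approx(0.0)

    def test_dark_adapted_identity(self):
        # FM' = FM makes F0' = F0, so F = F0 gives YII = FV/FM, qP = 1
        F0 = 0.164
        r = gf.psii_yields(F=F0, FMp=1.0, F0=F0, FM=1.0)
        assert r.F0p == pytest.approx(F0, rel=1e-12)
        assert r.YII == pytest.approx(0.836)
        assert r.NPQ == 0.0
        assert r.qP == pytest.approx(1.0)

    def test_hand_computed_mid_induction_case(self):
        r = gf.psii_yields(F=0.5, FMp=0.8, F0=0.2, FM=1.0)
        assert r.F0p == pytest.approx(0.2 / (0.8 + 0.25))  # 0.19048
        assert r.qP == pytest.approx(0.3 / (0.8 - 0.2 / 1.05))  # 0.49219
        assert r.YII == pytest.approx(0.375)
        assert r.NPQ == pytest.approx(0.25)
        assert r.one_minus_qP == pytest.approx(1 - r.qP)

    def test_f_above_fmp_clamps_qp_and_flags(self):
        with pytest.warns(UserWarning):
            r = gf.psii_yields(F=0.9, FMp=0.8, F0=0.2, FM=1.0)
        assert r.qP == 0.0 and r.flagged

    @given(F=st.floats(0.21, 0.99), FMp=st.floats(0.3, 1.0))
    def test_qp_boundaries_iff_f_at_extremes(self, F, FMp):
        r = gf.psii_yields(F=min(F, FMp), FMp=FMp, F0=0.2, FM=1.0)
        if min(F, FMp) == FMp:
            assert r.qP == pytest.approx(0.0, abs=1e-12)
        else:
            assert 0.0 <= r.qP <= 1.0 + 1e-9


class TestP700Yields:
    def test_fully_donor_limited_steady_state(self):
        r = gf.p700_yields(P=1.0, Pm=1.0, Pmp=1.0)
        assert (r.YND, r.YNA, r.YI) == (1.0, 0.0, 0.0)

    def test_dark_acceptor_limited_onset(self):
        r = gf.p700_yields(P=0.0, Pm=1.0, Pmp=0.0)
        assert (r.YND, r.YNA, r.YI) == (0.0, 1.0, 0.0)

    def test_mixed_case_arithmetic(self):
        r = gf.p700_yields(P=0.2, Pm=1.0, Pmp=0.9)
        assert r.YND == pytest.approx(0.2)
        assert r.YNA == pytest.approx(0.1)
        assert r.YI == pytest.approx(0.7)

    def test_failed_pulse_flags_and_zeroes_yi(self):
        with pytest.warns(UserWarning):
            r = gf.p700_yields(P=0.5, Pm=1.0, Pmp=0.4)
        assert r.YI == 0.0 and r.flagged
        assert r.YI + r.YND + r.YNA == 1.0

    @given(P=st.floats(0.0, 1.0), Pmp=st.floats(0.0, 1.0))
    def test_yields_sum_to_one_exactly(self, P, Pmp):
        if Pmp < P:
            with pytest.warns(UserWarning):
                r = gf.p700_yields(P=P, Pm=1.0, Pmp=Pmp)
        else:
            r = gf.p700_yields(P=P, Pm=1.0, Pmp=Pmp)
        assert r.YI + r.YND + r.YNA == pytest.approx(1.0, abs=1e-15)


class TestEtr:
    def test_reference_value(self):
        assert gf.etr(0.5, 800.0) == pytest.approx(168.0)

    def test_zero_yield(self):
        assert gf.etr(0.0, 800.0) == 0.0

    @given(Y=st.floats(0.0, 0.5), par=st.floats(0.0, 2000.0))
    def test_linearity(self, Y, par):
        assert gf.etr(2 * Y, par) == pytest.approx(2 * gf.etr(Y, par), abs=1e-9)

    def test_negative_inputs_rejected(self):
        with pytest.raises(DomainError):
            gf.etr(-0.1, 800.0)
        with pytest.raises(DomainError):
            gf.etr(0.5, -1.0)


class TestAnalyzeProtocol:
    def test_no_quenching_protocol_reports_dark_values(self):
        traj = {"YII": [(0.0, 0.8), (960.0, 0.8)], "NPQ": [(0.0, 0.0), (960.0, 0.0)],
                "YND": [(0.0, 0.2), (960.0, 0.2)], "YNA": [(0.0, 0.3), (960.0, 0.3)]}
        fluor, p700, ann = gf.synth.gen_pam_protocol(traj, dark_ref={"F0": 0.2, "FM": 1.0})
        recs = gf.analyze_protocol(fluor, p700, ann, {"F0": 0.2, "FM": 1.0, "Pm": 1.0})
        for r in recs:
            assert r.NPQ == pytest.approx(0.0, abs=1e-12)
            assert r.YII == pytest.approx(0.8, abs=1e-12)

    def test_cef_zero_when_etri_equals_etrii(self):
        # YI = 1 - YND - YNA = 0.5 = YII at every pulse
        traj = {"YII": [(0.0, 0.5), (960.0, 0.5)], "NPQ": [(0.0, 0.5), (960.0, 0.5)],
                "YND": [(0.0, 0.2), (960.0, 0.2)], "YNA": [(0.0, 0.3), (960.0, 0.3)]}
        fluor, p700, ann = gf.synth.gen_pam_protocol(traj)
        recs = gf.analyze_protocol(fluor, p700, ann, {"F0": 0.2, "FM": 1.0, "Pm": 1.0})
        for r in recs:
            assert r.CEF == pytest.approx(0.0, abs=1e-9)

    def test_gain_invariance_of_yields(self, pam_trajectories):
        fluor, p700, ann = gf.synth.gen_pam_protocol(pam_trajectories)
        dark = {"F0": 0.2, "FM": 1.0, "Pm": 1.0}
        recs1 = gf.analyze_protocol(fluor, p700, ann, dark)
        gain = 7.3
        fluor2 = gf.SampledTrace(fluor.t, fluor.y * gain, channel="fluorescence")
        dark2 = {"F0": 0.2 * gain, "FM": 1.0 * gain, "Pm": 1.0}
        recs2 = gf.analyze_protocol(fluor2, p700, ann, dark2)
        for r1, r2 in zip(recs1, recs2):
            assert r2.NPQ == pytest.approx(r1.NPQ, rel=1e-12)
            assert r2.YII == pytest.approx(r1.YII, rel=1e-12)
            assert r2.qP == pytest.approx(r1.qP, rel=1e-12)

    def test_npq_monotone_when_trajectory_monotone(self, pam_trajectories):
        fluor, p700, ann = gf.synth.gen_pam_protocol(pam_trajectories)
        recs = gf.analyze_protocol(fluor, p700, ann, {"F0": 0.2, "FM": 1.0, "Pm": 1.0})
        npq = [r.NPQ for r in recs]
        assert all(a <= b + 1e-12 for a, b in zip(npq, npq[1:]))

    def test_records_frame_has_one_row_per_pulse(self, pam_trajectories):
        fluor, p700, ann = gf.synth.gen_pam_protocol(pam_trajectories)
        recs = gf.analyze_protocol(fluor, p700, ann, {"F0": 0.2, "FM": 1.0, "Pm": 1.0})
        frame = gf.records_to_frame(recs)
        assert frame.shape[0] == 16
        assert list(frame.columns) == list(gf.QuenchRecord.FIELDS)

    def test_no_pulses_is_a_protocol_error(self):
        t = np.linspace(0, 10, 100)
        tr = gf.SampledTrace(t, np.full(100, 0.3))
        ann = gf.ProtocolAnnotation(events=[(0.0, "actinic_on"), (10.0, "actinic_off")])
        with pytest.raises(ProtocolError):
            gf.analyze_protocol(tr, None, ann, {"F0": 0.2, "FM": 1.0})


class TestStateTransition:
    def test_noiseless_protocol_recovers_parameters(self):
        trace, ann = gf.synth.gen_state_transition(0.117, 124.0)
        res = gf.state_transition(trace, ann)
        assert res.qT == pytest.approx(0.117, rel=1e-6)
        assert res.t_half_s == pytest.approx(124.0, rel=1e-3)
        assert not res.used_fallback

    def test_recovery_within_5pct_under_noise(self):
        qts, t_halves = [], []
        for seed in range(10):
            trace, ann = gf.synth.gen_state_transition(
                0.117, 124.0, noise=NoiseSpec("gaussian_rel", 0.02, seed))
            res = gf.state_transition(trace, ann)
            qts.append(res.qT)
            t_halves.append(res.t_half_s)
        assert np.mean(qts) == pytest.approx(0.117, rel=0.05)
        assert np.mean(t_halves) == pytest.approx(124.0, rel=0.05)

    def test_equal_pulse_maxima_give_zero_qt(self):
        trace, ann = gf.synth.gen_state_transition(0.0, 60.0)
        res = gf.state_transition(trace, ann)
        assert res.qT == pytest.approx(0.0, abs=1e-9)

    def test_flat_post_fr_off_signal_is_degenerate(self):
        t = np.arange(0.0, 400.0, 0.5)
        y = np.full_like(t, 0.4)
        y[(t >= 30.0) & (t <= 30.8)] = 1.0
        y[(t >= 380.0) & (t <= 380.8)] = 1.0
        ann = gf.ProtocolAnnotation(
            events=[(0.0, "fr_on"), (30.0, "sat_pulse_on"), (30.8, "sat_pulse_off"),
                    (60.0, "fr_off"), (380.0, "sat_pulse_on"), (380.8, "sat_pulse_off")])
        with pytest.raises(DegenerateError):
            gf.state_transition(gf.SampledTrace(t, y), ann)

    def test_missing_fr_off_is_a_protocol_error(self):
        trace, ann = gf.synth.gen_state_transition(0.1, 60.0)
        stripped = gf.ProtocolAnnotation(
            events=[e for e in ann.events if e[1] not in ("fr_on", "fr_off")],
            par=ann.par)
        with pytest.raises(ProtocolError):
            gf.state_transition(trace, stripped)
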