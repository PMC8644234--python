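"""I/O, record validation and protocol-event detection."""

import numpy as np
import pytest

import granafit as gf
from granafit.exceptions import FormatError, ValidationError
from granafit.synth import NoiseSpec


class TestReadTrace:
    def test_microsecond_csv_converted_to_seconds(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("t_us,F\n50,0.2\n100,0.25\n300,0.4\n2000,0.8\n")
        tr = gf.read_trace(p, dialect="generic_csv")
        np.testing.assert_allclose(tr.t, [5e-5, 1e-4, 3e-4, 2e-3])
        np.testing.assert_allclose(tr.y, [0.2, 0.25, 0.4, 0.8])

    def test_duplicated_time_row_rejected(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("t_s,F\n0.1,0.2\n0.2,0.3\n0.2,0.3\n0.4,0.5\n")
        with pytest.raises(ValidationError):
            gf.read_trace(p)

    def test_garbage_line_names_line_number(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("t_s,F\n0.1,0.2\n0.2,oops\n0.3,0.4\n0.4,0.5\n")
        with pytest.raises(FormatError, match="line 3"):
            gf.read_trace(p)

    @pytest.mark.parametrize("dialect", ["generic_csv", "dualpam_export", "pea_export"])
    def test_write_read_round_trip_bit_exact(self, tmp_path, dialect):
        rng = np.random.default_rng(7)
        t = np.sort(rng.uniform(1e-5, 5.0, 50))
        tr = gf.SampledTrace(t, rng.uniform(0.1, 1.0, 50))
        back = gf.read_trace(gf.write_trace(tr, tmp_path / "x.csv", dialect), dialect)
        # serialised at 17 significant digits: doubles survive exactly
        assert np.array_equal(back.y, tr.y)
        np.testing.assert_allclose(back.t, tr.t, rtol=1e-15)

    def test_dualpam_channel_selection(self, tmp_path):
        p = tmp_path / "dual.txt"
        p.write_text("Time;Fluo;P700;Junk\n0.0;0.2;0.9;7\n0.1;0.3;0.8;7\n"
                     "0.2;0.4;0.7;7\n0.3;0.5;0.6;7\n")
        fl = gf.read_trace(p, dialect="dualpam_export", channel="fluorescence")
        p7 = gf.read_trace(p, dialect="dualpam_export", channel="p700")
        assert fl.channel == "fluorescence" and fl.y[0] == 0.2
        assert p7.channel == "p700" and p7.y[0] == 0.9


class TestRecordInvariants:
    def test_short_trace_rejected(self):
        with pytest.raises(ValidationError):
            gf.SampledTrace([0.0, 1.0, 2.0], [1, 2, 3])

    def test_non_finite_signal_rejected(self):
        with pytest.raises(ValidationError):
            gf.SampledTrace([0, 1, 2, 3], [1.0, np.nan, 2.0, 3.0])

    def test_unmatched_pulse_on_rejected(self):
        with pytest.raises(ValidationError):
            gf.ProtocolAnnotation(events=[(1.0, "sat_pulse_on")])

    def test_zero_duration_pulse_rejected(self):
        with pytest.raises(ValidationError):
            gf.ProtocolAnnotation(events=[(1.0, "sat_pulse_on"), (1.0, "sat_pulse_off")])

    def test_annotation_json_round_trip(self, tmp_path):
        ann = gf.ProtocolAnnotation(
            events=[(0.0, "actinic_on"), (5.0, "sat_pulse_on"),
                    (5.3, "sat_pulse_off"), (10.0, "actinic_off")], par=800.0)
        back = gf.read_annotation(gf.write_annotation(ann, tmp_path / "a.json"))
        assert back.events == ann.events and back.par == ann.par


class TestDetectPulses:
    def test_recovers_all_pulses_with_onset_accuracy(self, pam_trajectories):
        fluor, _, ann = gf.synth.gen_pam_protocol(pam_trajectories)
        det = gf.detect_pulses(fluor, min_rise=0.2, min_sep=1.0)
        truth = ann.pairs("sat_pulse_on")
        got = det.pairs("sat_pulse_on")
        assert len(got) == len(truth) == 16
        dt = np.median(np.diff(fluor.t))
        for (t_true, _), (t_det, _) in zip(truth, got):
            assert abs(t_det - t_true) <= dt + 1e-9

    def test_count_recovered_under_noise_snr20(self):
        """50 seeded trials at SNR 20 all recover the true pulse count."""
        traj = {"YII": [(0.0, 0.7), (240.0, 0.5)], "NPQ": [(0.0, 0.0), (240.0, 1.0)],
                "YND": [(0.0, 0.0), (240.0, 0.6)], "YNA": [(0.0, 0.8), (240.0, 0.1)]}
        times = (5.0, 40.0, 80.0, 130.0, 180.0, 230.0)
        for seed in range(50):
            fluor, _, _ = gf.synth.gen_pam_protocol(
                traj, pulse_times=times, duration_s=240.0,
                noise=NoiseSpec("gaussian_rel", 0.05, seed))
            det = gf.detect_pulses(fluor, min_rise=0.2, min_sep=1.0)
            assert len(det.pairs("sat_pulse_on")) == len(times), f"seed {seed}"

    def test_flat_trace_yields_empty_annotation(self):
        tr = gf.SampledTrace(np.linspace(0, 10, 500), np.full(500, 0.4))
        assert gf.detect_pulses(tr).events == []

    def test_close_pulses_keep_earlier(self):
        t = np.arange(0, 20, 0.01)
        y = np.full_like(t, 0.3)
        y[(t >= 5.0) & (t <= 5.3)] = 1.0
        y[(t >= 5.6) & (t <= 5.9)] = 1.0
        det = gf.detect_pulses(gf.SampledTrace(t, y), min_rise=0.5, min_sep=1.0)
        pairs = det.pairs("sat_pulse_on")
        assert len(pairs) == 1
        assert abs(pairs[0][0] - 5.0) < 0.02


class TestPointsMasksSpectra:
    def test_points_tsv_pixel_scaling(self, tmp_path):
        p = tmp_path / "pts.tsv"
        p.write_text("x_px\ty_px\tangle_deg\n10\t0\t45\n0\t10\t45\n5\t5\t45\n"
                     "1\t2\t45\n3\t4\t45\n6\t7\t45\n")
        ps = gf.read_points(p, pixel_size_A=2.18)
        np.testing.assert_allclose(ps.points[0], [21.8, 0.0])
        np.testing.assert_allclose(ps.orientations[0],
                                   [np.cos(np.pi / 4), np.sin(np.pi / 4)])

    def test_points_round_trip(self, tmp_path):
        ps = gf.synth.gen_lattice_points(244, 170, 80, 4, 4, jitter_A=2.0, seed=3,
                                         diag_angle_deg=50.0)
        back = gf.read_points(gf.write_points(ps, tmp_path / "p.tsv"),
                              pixel_size_A=ps.pixel_size_A)
        np.testing.assert_allclose(back.points, ps.points, rtol=1e-12, atol=1e-9)

    @pytest.mark.parametrize("suffix", [".png", ".tif"])
    def test_mask_round_trip(self, tmp_path, suffix):
        mask = gf.synth.gen_array_mask(0.4, shape=(64, 64), seed=2)
        back = gf.read_mask(gf.write_mask(mask, tmp_path / f"m{suffix}"))
        assert np.array_equal(back.data, mask.data)

    def test_all_zero_mask_gives_zero_fraction(self, tmp_path):
        mask = gf.BinaryMask(np.zeros((32, 32), dtype=bool))
        back = gf.read_mask(gf.write_mask(mask, tmp_path / "z.png"))
        assert gf.area_fraction([back]).per_micrograph == [0.0]

    def test_spectrum_round_trip(self, tmp_path):
        sp = gf.synth.gen_cd_spectrum({"cd685": 0.8, "cd505": 0.4})
        back = gf.read_spectrum(gf.write_spectrum(sp, tmp_path / "cd.csv"))
        assert np.array_equal(back.signal, sp.signal)
        np.testing.assert_allclose(back.wavelength_nm, sp.wavelength_nm, rtol=1e-15)
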