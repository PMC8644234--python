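"""Ground-truth generators for every input class the analyses consume.

No instrument or microscope output ships with the package, so each analysis
has a paired generator whose parameters are the quantities the analysis is
supposed to recover: landmark values for OJIP transients, a rate constant
for DCMU induction, phase amplitudes/time constants for flash decays, yield
trajectories for saturation-pulse protocols, (qT, t1/2) for state
transitions, a unit cell for lattice point sets, a target area fraction for
crystal masks and band amplitudes for CD spectra. The PAM generator is the
exact algebraic inverse of the quenching formulas, so forward-analysis of
its noiseless output is an identity — the strongest available oracle.

All generators are bitwise deterministic for a fixed :class:`NoiseSpec`
seed. The default noise model is multiplicative Gaussian with sigma = 2%,
a realistic leaf-level trace quality; it is a parameter, not a constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.ndimage import gaussian_filter

from .exceptions import DomainError
from .flash_decay import DecayFit, decay_model
from .traces import (BinaryMask, PointSet2D, ProtocolAnnotation, SampledTrace,
                     Spectrum)

__all__ = [
    "NoiseSpec",
    "gen_ojip",
    "gen_dcmu_induction",
    "gen_decay",
    "gen_pam_protocol",
    "gen_state_transition",
    "gen_lattice_points",
    "gen_array_mask",
    "gen_cd_spectrum",
]


@dataclass
class NoiseSpec:
    """Reproducible noise: kind in {gaussian_rel, gaussian_abs, none}."""

    kind: str = "gaussian_rel"
    sigma: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("gaussian_rel", "gaussian_abs", "none"):
            raise DomainError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise DomainError("noise sigma must be >= 0")

    @classmethod
    def none(cls) -> "NoiseSpec":
        return cls(kind="none", sigma=0.0, seed=0)

    def apply(self, y: np.ndarray) -> np.ndarray:
        if self.kind == "none" or self.sigma == 0:
            return y.copy()
        rng = np.random.default_rng(self.seed)
        noise = rng.standard_normal(len(y))
        if self.kind == "gaussian_rel":
            return y * (1.0 + self.sigma * noise)
        return y + self.sigma * noise


def _loggrid(t0: float, t1: float, n: int) -> np.ndarray:
    return np.logspace(np.log10(t0), np.log10(t1), n)


# ---------------------------------------------------------------------------
# fluorescence induction
# ---------------------------------------------------------------------------

def gen_ojip(
    landmarks: dict,
    n_points: int = 300,
    t_range_s: tuple = (50e-6, 5.0),
    noise: NoiseSpec | None = None,
    t_peak_s: float = 0.3,
) -> SampledTrace:
    """Monotone O-J-I-P transient through prescribed landmark anchors.

    ``landmarks`` maps {F0, F300, FJ, FI, FM} to signal values anchored at
    50 us, 300 us, 2 ms, 30 ms and the peak time. The curve is a monotone
    cubic (PCHIP) in log10-time — landmark fidelity, not mechanism, is what
    downstream tests need. Sampling is log-uniform; noise is applied last.
    """
    noise = noise or NoiseSpec.none()
    F0, F300, FJ = landmarks["F0"], landmarks["F300"], landmarks["FJ"]
    FI, FM = landmarks["FI"], landmarks["FM"]
    if not (0 < F0 < F300 < FJ <= FI <= FM):
        raise DomainError(
            f"landmarks must satisfy 0 < F0 < F300 < FJ <= FI <= FM, got {landmarks}"
        )
    if t_range_s[0] > 50e-6 or t_range_s[1] < t_peak_s:
        raise DomainError("t_range must cover 50 us to the peak time")
    anchor_t = np.array([50e-6, 300e-6, 2e-3, 30e-3, t_peak_s, t_range_s[1]])
    anchor_f = np.array([F0, F300, FJ, FI, FM, FM])
    interp = PchipInterpolator(np.log10(anchor_t), anchor_f)
    t = _loggrid(t_range_s[0], t_range_s[1], n_points)
    y = interp(np.log10(t))
    return SampledTrace(t, noise.apply(y), channel="fluorescence",
                        meta={"generator": "gen_ojip"})


def gen_dcmu_induction(
    k: float,
    n_points: int = 300,
    duration_s: float = 0.45,
    noise: NoiseSpec | None = None,
    F0: float = 0.2,
    FM: float = 1.0,
    t_start_s: float = 1e-6,
) -> SampledTrace:
    """DCMU-blocked induction F(t) = F0 + (FM-F0)(1 - e^(-kt)) on a log grid.

    With electron transport blocked the relative variable fluorescence is a
    single exponential whose complementary area is exactly 1/k, giving a
    closed-form oracle for the cross-section analysis.
    """
    noise = noise or NoiseSpec.none()
    if k <= 0:
        raise DomainError("rate constant k must be positive")
    if FM <= F0:
        raise DomainError("need FM > F0")
    t = _loggrid(t_start_s, duration_s, n_points)
    y = F0 + (FM - F0) * (1.0 - np.exp(-k * t))
    return SampledTrace(t, noise.apply(y), channel="fluorescence",
                        meta={"generator": "gen_dcmu_induction", "k": str(k),
                              "F0": str(F0), "FM": str(FM)})


# ---------------------------------------------------------------------------
# flash decay
# ---------------------------------------------------------------------------

def gen_decay(
    params: DecayFit | dict,
    t_range_s: tuple = (15e-6, 50.0),
    n_points: int = 300,
    noise: NoiseSpec | None = None,
) -> SampledTrace:
    """Flash-decay trace from prescribed (A0, A1..A3, T1..T3)."""
    noise = noise or NoiseSpec.none()
    if isinstance(params, DecayFit):
        p = [params.A0, params.A1, params.A2, params.A3,
             params.T1, params.T2, params.T3]
    else:
        p = [params[k] for k in ("A0", "A1", "A2", "A3", "T1", "T2", "T3")]
    t = _loggrid(t_range_s[0], t_range_s[1], n_points)
    y = decay_model(t, *p)
    return SampledTrace(t, noise.apply(y), channel="fluorescence",
                        meta={"generator": "gen_decay"})


# ---------------------------------------------------------------------------
# saturation-pulse protocols
# ---------------------------------------------------------------------------

DEFAULT_PULSE_TIMES = (5.0, 20.0, 40.0, 60.0, 90.0, 120.0, 180.0, 240.0,
                       300.0, 360.0, 480.0, 600.0, 720.0, 840.0, 900.0, 950.0)


def _traj(knots, t: float) -> float:
    """Piecewise-linear trajectory through (time, value) knots."""
    ts = [k[0] for k in knots]
    vs = [k[1] for k in knots]
    return float(np.interp(t, ts, vs))


def gen_pam_protocol(
    traj: dict,
    dark_ref: dict | None = None,
    pulse_times: tuple = DEFAULT_PULSE_TIMES,
    par: float = 800.0,
    pulse_dur_s: float = 0.3,
    dt_s: float = 0.02,
    duration_s: float = 960.0,
    noise: NoiseSpec | None = None,
) -> tuple[SampledTrace, SampledTrace, ProtocolAnnotation]:
    """Fluorescence + P700 protocol traces from prescribed yield trajectories.

    ``traj`` holds piecewise-linear knot lists for ``YII``, ``NPQ``, ``YND``
    and ``YNA`` (each a list of (t_s, value)). The generator inverts the
    analysis algebra: FM'(t) = FM/(1+NPQ(t)), F(t) = FM'(t)(1-YII(t)),
    P(t) = YND(t) Pm and Pm'(t) = Pm(1-YNA(t)); 300-ms pulse plateaus are
    inserted at ``pulse_times``. Trajectory values are frozen at the pulse
    onset over the pre-pulse 150 ms and the pulse itself, so the forward
    analysis of a noiseless protocol returns the prescribed values exactly.

    The defaults mirror a dark-to-light induction experiment: 16 saturating
    pulses during 16 min of 800 umol photons m^-2 s^-1 actinic light.
    """
    noise = noise or NoiseSpec.none()
    dark = {"F0": 0.2, "FM": 1.0, "Pm": 1.0}
    if dark_ref:
        dark.update(dark_ref)
    FM, Pm = float(dark["FM"]), float(dark["Pm"])
    for name in ("YII", "NPQ", "YND", "YNA"):
        if name not in traj:
            raise DomainError(f"trajectory {name!r} missing")
    for t_k in {t for t, _ in traj["YND"]} | {t for t, _ in traj["YNA"]}:
        if _traj(traj["YND"], t_k) + _traj(traj["YNA"], t_k) > 1.0 + 1e-12:
            raise DomainError(f"YND + YNA > 1 at t = {t_k}")

    pulse_times = tuple(sorted(pulse_times))
    t = np.arange(0.0, duration_s + dt_s / 2, dt_s)
    f = np.empty_like(t)
    p = np.empty_like(t)
    for i, ti in enumerate(t):
        # freeze trajectories at the pulse onset around each pulse
        t_eval, in_pulse = ti, False
        for tp in pulse_times:
            if tp - 0.15 <= ti <= tp + pulse_dur_s:
                t_eval = tp
                in_pulse = ti >= tp
                break
        yii = _traj(traj["YII"], t_eval)
        npq = _traj(traj["NPQ"], t_eval)
        ynd = _traj(traj["YND"], t_eval)
        yna = _traj(traj["YNA"], t_eval)
        if ynd + yna > 1.0 + 1e-12:
            raise DomainError(f"YND + YNA > 1 at t = {t_eval}")
        fmp = FM / (1.0 + npq)
        if in_pulse:
            f[i] = fmp
            p[i] = Pm * (1.0 - yna)  # Pm' plateau
        else:
            f[i] = fmp * (1.0 - yii)
            p[i] = ynd * Pm

    events = [(0.0, "actinic_on")]
    for tp in pulse_times:
        events.append((tp, "sat_pulse_on"))
        events.append((tp + pulse_dur_s, "sat_pulse_off"))
    events.append((duration_s, "actinic_off"))
    events.sort(key=lambda e: e[0])
    ann = ProtocolAnnotation(events=events, par=par)

    n_f = noise
    n_p = NoiseSpec(noise.kind, noise.sigma, noise.seed + 1) \
        if noise.kind != "none" else noise
    fluor = SampledTrace(t, n_f.apply(f), channel="fluorescence",
                         meta={"generator": "gen_pam_protocol"})
    p700 = SampledTrace(t, n_p.apply(p), channel="p700",
                        meta={"generator": "gen_pam_protocol"})
    return fluor, p700, ann


# ---------------------------------------------------------------------------
# state transitions
# ---------------------------------------------------------------------------

def gen_state_transition(
    qT: float,
    t_half_s: float,
    levels: dict | None = None,
    noise: NoiseSpec | None = None,
    dt_s: float = 0.05,
    fr_off_s: float = 60.0,
    pulse_dur_s: float = 0.8,
    decay_span_halves: float = 6.0,
) -> tuple[SampledTrace, ProtocolAnnotation]:
    """Fluorescence trace of a State I -> State II transition protocol.

    Far-red light keeps the leaf in State I (steady level F1, saturating
    pulse to FM'); switching it off triggers an exponential fluorescence
    decay with half-time ``t_half_s`` toward the State-II level F2, after
    which a second pulse reads FM'' = FM'(1 - qT). The decay is recorded
    for ``decay_span_halves`` half-times (at least 5 min).
    """
    noise = noise or NoiseSpec.none()
    if not 0 <= qT < 1:
        raise DomainError("qT must lie in [0, 1)")
    if t_half_s <= 0:
        raise DomainError("t_half must be positive")
    lv = {"F1": 0.48, "F2": 0.40, "FM1": 1.0}
    if levels:
        lv.update(levels)
    F1, F2, FM1 = lv["F1"], lv["F2"], lv["FM1"]
    FM2 = FM1 * (1.0 - qT)
    tau = t_half_s / np.log(2.0)
    t_pulse1 = fr_off_s / 2.0
    decay_len = max(300.0, decay_span_halves * t_half_s)
    t_pulse2 = fr_off_s + decay_len
    t_end = t_pulse2 + pulse_dur_s + 5.0

    t = np.arange(0.0, t_end, dt_s)
    y = np.empty_like(t)
    for i, ti in enumerate(t):
        if t_pulse1 <= ti <= t_pulse1 + pulse_dur_s:
            y[i] = FM1
        elif t_pulse2 <= ti <= t_pulse2 + pulse_dur_s:
            y[i] = FM2
        elif ti < fr_off_s:
            y[i] = F1
        elif ti < t_pulse2:
            y[i] = F2 + (F1 - F2) * np.exp(-(ti - fr_off_s) / tau)
        else:
            y[i] = F2
    ann = ProtocolAnnotation(
        events=[(0.0, "fr_on"),
                (t_pulse1, "sat_pulse_on"), (t_pulse1 + pulse_dur_s, "sat_pulse_off"),
                (fr_off_s, "fr_off"),
                (t_pulse2, "sat_pulse_on"), (t_pulse2 + pulse_dur_s, "sat_pulse_off")],
        par=13.0,
    )
    trace = SampledTrace(t, noise.apply(y), channel="fluorescence",
                         meta={"generator": "gen_state_transition"})
    return trace, ann


# ---------------------------------------------------------------------------
# lattices, masks, CD spectra
# ---------------------------------------------------------------------------

def gen_lattice_points(
    a_A: float,
    b_A: float,
    alpha_deg: float,
    n_rows: int = 8,
    n_cols: int = 8,
    jitter_A: float = 0.0,
    occupancy: float = 1.0,
    rotation_deg: float = 0.0,
    seed: int = 0,
    diag_angle_deg: float | None = None,
) -> PointSet2D:
    """Jittered, partially occupied 2D lattice with a prescribed unit cell.

    Points are n1*a + n2*b with a = (a_A, 0) and b = b_A (cos alpha,
    sin alpha), rigidly rotated by ``rotation_deg``, Gaussian-jittered with
    sd ``jitter_A`` and kept with probability ``occupancy``. When
    ``diag_angle_deg`` is given, each point carries a supercomplex-diagonal
    orientation at that angle from the a vector.
    """
    if a_A <= 0 or b_A <= 0:
        raise DomainError("cell lengths must be positive")
    if not 0 < occupancy <= 1:
        raise DomainError("occupancy must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    al = np.deg2rad(alpha_deg)
    va = np.array([a_A, 0.0])
    vb = np.array([b_A * np.cos(al), b_A * np.sin(al)])
    ii, jj = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    pts = ii.reshape(-1, 1) * va + jj.reshape(-1, 1) * vb
    keep = rng.random(len(pts)) < occupancy
    pts = pts[keep]
    if len(pts) < 6:
        raise DomainError(f"only {len(pts)} points survive occupancy {occupancy}")
    if jitter_A > 0:
        pts = pts + jitter_A * rng.standard_normal(pts.shape)
    rot = np.deg2rad(rotation_deg)
    R = np.array([[np.cos(rot), -np.sin(rot)], [np.sin(rot), np.cos(rot)]])
    pts = pts @ R.T
    ori = None
    if diag_angle_deg is not None:
        ang = rot + np.deg2rad(diag_angle_deg)  # a vector is at `rot` after rotation
        ori = np.tile([np.cos(ang), np.sin(ang)], (len(pts), 1))
    return PointSet2D(pts, orientations=ori, pixel_size_A=1.0)


def gen_array_mask(
    fraction: float,
    shape: tuple = (256, 256),
    blob_scale: float = 12.0,
    seed: int = 0,
    pixel_size_A: float = 10.0,
) -> BinaryMask:
    """Blobby binary mask whose crystalline-pixel fraction hits ``fraction``
    up to pixel quantisation (smoothed Gaussian field thresholded at the
    matching quantile)."""
    if not 0 <= fraction <= 1:
        raise DomainError("fraction must lie in [0, 1]")
    if fraction == 0:
        return BinaryMask(np.zeros(shape, dtype=bool), pixel_size_A)
    if fraction == 1:
        return BinaryMask(np.ones(shape, dtype=bool), pixel_size_A)
    rng = np.random.default_rng(seed)
    field = gaussian_filter(rng.standard_normal(shape), blob_scale)
    thresh = np.quantile(field, 1.0 - fraction)
    return BinaryMask(field > thresh, pixel_size_A)


def _gauss(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


def gen_cd_spectrum(
    band_amps: dict,
    wl_range_nm: tuple = (400.0, 750.0),
    step_nm: float = 0.5,
    noise: NoiseSpec | None = None,
) -> Spectrum:
    """CD spectrum with prescribed psi-band anchor differences.

    ``band_amps`` gives the target cd685 = CD(685)-CD(750) and cd505 =
    CD(505)-CD(620). The spectrum is a sum of Gaussian bands at 685, 505
    and a fixed negative 673 band; the two free amplitudes are solved from
    a 2x2 linear system so the anchor differences match the request exactly
    (before noise).
    """
    noise = noise or NoiseSpec.none()
    cd685 = float(band_amps["cd685"])
    cd505 = float(band_amps["cd505"])
    wl = np.arange(wl_range_nm[0], wl_range_nm[1] + step_nm / 2, step_nm)
    g685 = _gauss(wl, 685.0, 8.0)
    g505 = _gauss(wl, 505.0, 12.0)
    g673 = _gauss(wl, 673.0, 6.0)
    fixed = -0.4 * abs(cd685) * g673  # the (-)673 grana-stacking band

    def anchor_diff(y, band, base):
        return (np.interp(band, wl, y) - np.interp(base, wl, y))

    M = np.array([
        [anchor_diff(g685, 685, 750), anchor_diff(g505, 685, 750)],
        [anchor_diff(g685, 505, 620), anchor_diff(g505, 505, 620)],
    ])
    rhs = np.array([
        cd685 - anchor_diff(fixed, 685, 750),
        cd505 - anchor_diff(fixed, 505, 620),
    ])
    amp685, amp505 = np.linalg.solve(M, rhs)
    y = amp685 * g685 + amp505 * g505 + fixed
    return Spectrum(wl, noise.apply(y))
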