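"""Saturation-pulse quenching analysis for PSII and P700, and state transitions.

Quenching analysis follows the standard saturation-pulse bookkeeping: during
actinic illumination each 300-ms saturating pulse yields the pre-pulse steady
fluorescence F and the pulse maximum FM', which together with the
dark-adapted F0 and FM give

    Y(II) = (FM' - F)/FM'          effective PSII yield
    NPQ   = (FM - FM')/FM'         non-photochemical quenching
    F0'   = F0 / (FV/FM + F0/FM')  light-adapted minimal fluorescence
                                   (Oxborough-Baker estimate; a measured
                                   F0' may be supplied instead)
    qP    = (FM' - F)/(FM' - F0')  photochemical quenching coefficient

P700 yields use the Klughammer-Schreiber convention against the dark-adapted
maximal oxidation Pm and the pulse maximum Pm':

    Y(ND) = P/Pm,  Y(NA) = (Pm - Pm')/Pm,  Y(I) = (Pm' - P)/Pm

so Y(I) + Y(ND) + Y(NA) = 1 identically. Electron-transport rates are
ETR = PAR x Y x absorptance x photosystem fraction (defaults 0.84 and 0.5),
and cyclic electron flow around PSI is estimated as CEF = ETR-I - ETR-II.

State-transition kinetics: qT = (FM' - FM'')/FM' compares the State-I and
State-II pulse maxima, and the transition half-time comes from a
single-exponential fit to the fluorescence decay after far-red light is
switched off (half-amplitude crossing as a flagged fallback).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit

import pandas as pd

from .exceptions import DegenerateError, DomainError, ProtocolError
from .traces import ProtocolAnnotation, SampledTrace

__all__ = [
    "QuenchRecord",
    "StateTransitionResult",
    "psii_yields",
    "p700_yields",
    "etr",
    "analyze_protocol",
    "state_transition",
    "StateTransitionModel",
    "records_to_frame",
]


@dataclass
class QuenchRecord:
    """Per-pulse PSII/PSI yields and transport rates."""

    t_s: float = float("nan")
    F: float = float("nan")
    FMp: float = float("nan")
    F0p: float = float("nan")
    YII: float = float("nan")
    NPQ: float = float("nan")
    qP: float = float("nan")
    one_minus_qP: float = float("nan")
    ETRII: Optional[float] = None
    P: Optional[float] = None
    Pm: Optional[float] = None
    Pmp: Optional[float] = None
    YI: Optional[float] = None
    YND: Optional[float] = None
    YNA: Optional[float] = None
    ETRI: Optional[float] = None
    CEF: Optional[float] = None
    flagged: bool = False

    FIELDS = ("t_s", "F", "FMp", "F0p", "YII", "NPQ", "qP", "one_minus_qP",
              "ETRII", "P", "Pm", "Pmp", "YI", "YND", "YNA", "ETRI", "CEF",
              "flagged")

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.FIELDS}


def psii_yields(F: float, FMp: float, F0: float, FM: float) -> QuenchRecord:
    """PSII quenching parameters from one saturating pulse.

    F0' is estimated as F0 / (FV/FM + F0/FM'); when FM' = FM this reduces
    to F0' = F0 (dark-adapted identity). F above FM' clamps qP to 0 and
    flags the record instead of raising.
    """
    if not (FM > F0 > 0):
        raise DomainError(f"need FM > F0 > 0, got F0={F0!r}, FM={FM!r}")
    if FMp <= 0:
        raise DomainError(f"FM' must be positive, got {FMp!r}")
    fvfm = (FM - F0) / FM
    f0p = F0 / (fvfm + F0 / FMp)
    if FMp <= f0p:
        raise DomainError(
            f"quench collapse: FM'={FMp:.4g} <= F0'={f0p:.4g}; qP undefined"
        )
    yii = (FMp - F) / FMp
    npq = (FM - FMp) / FMp
    qp = (FMp - F) / (FMp - f0p)
    flagged = False
    if F > FMp:
        warnings.warn("F exceeds FM'; clamping qP to 0", stacklevel=2)
        qp = 0.0
        flagged = True
    return QuenchRecord(F=F, FMp=FMp, F0p=f0p, YII=yii, NPQ=npq,
                        qP=qp, one_minus_qP=1.0 - qp, flagged=flagged)


def p700_yields(P: float, Pm: float, Pmp: float) -> QuenchRecord:
    """PSI yields Y(I), Y(ND), Y(NA) from the P700 signal around one pulse.

    If the pulse fails to oxidise beyond the steady state (Pm' < P) the
    record is flagged and Y(I) set to 0 (Pm' treated as P), preserving
    Y(I) + Y(ND) + Y(NA) = 1.
    """
    if Pm <= 0:
        raise DomainError(f"Pm must be positive, got {Pm!r}")
    if not (0 <= P <= Pm) or not (0 <= Pmp <= Pm):
        raise DomainError(f"need 0 <= P, Pm' <= Pm; got P={P!r}, Pm'={Pmp!r}, Pm={Pm!r}")
    flagged = False
    if Pmp < P:
        warnings.warn("Pm' < P: pulse failed to oxidise P700 further; Y(I)=0",
                      stacklevel=2)
        Pmp = P
        flagged = True
    ynd = P / Pm
    yna = (Pm - Pmp) / Pm
    yi = 1.0 - ynd - yna
    return QuenchRecord(P=P, Pm=Pm, Pmp=Pmp, YI=yi, YND=ynd, YNA=yna, flagged=flagged)


def etr(Y: float, par: float, absorptance: float = 0.84,
        ps_fraction: float = 0.5) -> float:
    """Electron-transport rate PAR x Y x absorptance x photosystem fraction.

    The defaults are the conventional leaf absorptance of PAR (0.84) and the
    fraction of absorbed light reaching one photosystem (0.5); both are
    parameters, not constants.
    """
    if not 0 <= Y <= 1:
        raise DomainError(f"yield must lie in [0, 1], got {Y!r}")
    if par < 0 or absorptance < 0 or ps_fraction < 0:
        raise DomainError("ETR inputs must be non-negative")
    return par * Y * absorptance * ps_fraction


def analyze_protocol(
    fluor: SampledTrace,
    p700: Optional[SampledTrace],
    ann: ProtocolAnnotation,
    dark_ref: dict,
    par: Optional[float] = None,
    pre_window_s: float = 0.1,
    absorptance: float = 0.84,
    ps_fraction: float = 0.5,
) -> list[QuenchRecord]:
    """Quenching analysis of a full saturation-pulse induction protocol.

    For each annotated pulse: F (and P) is the median of the 100 ms
    preceding the pulse onset, FM' (and Pm') the maximum within the pulse
    window. ``dark_ref`` supplies the dark-adapted ``F0``, ``FM`` and (for
    P700) ``Pm``. Pulses with fewer than 3 samples are skipped with a
    warning rather than failing the whole protocol.
    """
    F0, FM = float(dark_ref["F0"]), float(dark_ref["FM"])
    Pm = float(dark_ref["Pm"]) if (p700 is not None and "Pm" in dark_ref) else None
    if par is None:
        par = ann.par
    pulses = ann.pairs("sat_pulse_on")
    if not pulses:
        raise ProtocolError("annotation contains no saturating pulses")
    records: list[QuenchRecord] = []
    for t_on, t_off in pulses:
        in_pulse = fluor.window(t_on, t_off)
        pre = fluor.window(t_on - pre_window_s, t_on * (1 - 1e-12))
        if in_pulse.sum() < 3 or pre.sum() < 1:
            warnings.warn(f"pulse at t={t_on:.3g}s has too few samples; skipped",
                          stacklevel=2)
            continue
        F = float(np.median(fluor.y[pre]))
        FMp = float(np.max(fluor.y[in_pulse]))
        rec = psii_yields(F, FMp, F0, FM)
        rec.t_s = t_on
        if par is not None:
            rec.ETRII = etr(min(max(rec.YII, 0.0), 1.0), par, absorptance, ps_fraction)
        if p700 is not None and Pm is not None:
            ppre = p700.window(t_on - pre_window_s, t_on * (1 - 1e-12))
            pin = p700.window(t_on, t_off)
            if pin.sum() >= 3 and ppre.sum() >= 1:
                P = float(np.median(p700.y[ppre]))
                Pmp = float(np.max(p700.y[pin]))
                psi = p700_yields(min(max(P, 0.0), Pm), Pm, min(Pmp, Pm))
                rec.P, rec.Pm, rec.Pmp = psi.P, psi.Pm, psi.Pmp
                rec.YI, rec.YND, rec.YNA = psi.YI, psi.YND, psi.YNA
                rec.flagged = rec.flagged or psi.flagged
                if par is not None:
                    rec.ETRI = etr(min(max(rec.YI, 0.0), 1.0), par,
                                   absorptance, ps_fraction)
                    rec.CEF = rec.ETRI - rec.ETRII
        records.append(rec)
    return records


def records_to_frame(records: list[QuenchRecord]) -> pd.DataFrame:
    """One row per pulse, columns exactly the QuenchRecord fields."""
    return pd.DataFrame([r.as_dict() for r in records], columns=QuenchRecord.FIELDS)


# ---------------------------------------------------------------------------
# state transitions
# ---------------------------------------------------------------------------

@dataclass
class StateTransitionResult:
    """Amplitude (qT) and kinetics (t1/2) of a State I -> State II transition."""

    FMp_state1: float
    FMpp_state2: float
    qT: float = None
    t_half_s: float = float("nan")
    fit_rss: float = float("nan")
    tau_s: float = float("nan")
    used_fallback: bool = False
    t_half_fallback_s: Optional[float] = None

    def __post_init__(self):
        if self.qT is None:
            self.qT = (self.FMp_state1 - self.FMpp_state2) / self.FMp_state1

    def summary(self) -> str:
        return (
            "State I -> State II transition\n"
            f"  FM' (State I)   {self.FMp_state1:.6g}\n"
            f"  FM'' (State II) {self.FMpp_state2:.6g}\n"
            f"  qT              {self.qT:.4f}\n"
            f"  t1/2            {self.t_half_s:.4g} s"
            + ("  [half-crossing fallback]" if self.used_fallback else "")
        )


class StateTransitionModel:
    """Single-exponential model of the post-far-red fluorescence decay.

    Needs an annotation with an ``fr_off`` event, one saturating pulse
    before it (FM' in State I) and one after the decay (FM'' in State II).
    ``fit`` estimates F(t) = F_end + (F_start - F_end) exp(-(t-t0)/tau) on
    the decay segment and reports t1/2 = tau ln 2; when the fit fails the
    half-amplitude crossing is interpolated instead and the result flagged.
    """

    def __init__(self, fluor: SampledTrace, ann: ProtocolAnnotation,
                 pulse_stat: str = "upper_half_mean", settle_s: float = 0.0):
        fr_offs = ann.times("fr_off")
        if not fr_offs:
            raise ProtocolError("annotation has no fr_off event")
        self.t_fr_off = fr_offs[-1]
        pulses = ann.pairs("sat_pulse_on")
        before = [p for p in pulses if p[1] <= self.t_fr_off]
        after = [p for p in pulses if p[0] > self.t_fr_off]
        if not before or not after:
            raise ProtocolError("need one saturating pulse before fr_off and one after")
        self.pulse1 = before[-1]
        self.pulse2 = after[0]
        self.fluor = fluor
        self.pulse_stat = pulse_stat
        self.settle_s = settle_s

    def _pulse_level(self, pair) -> float:
        sel = self.fluor.window(*pair)
        if sel.sum() < 1:
            raise ProtocolError(f"no samples in pulse window {pair}")
        y = self.fluor.y[sel]
        if self.pulse_stat == "max" or y.size < 4:
            return float(np.max(y))
        med = np.median(y)
        return float(np.mean(y[y >= med]))  # robust plateau level

    def fit(self) -> StateTransitionResult:
        fm1 = self._pulse_level(self.pulse1)
        fm2 = self._pulse_level(self.pulse2)
        seg = self.fluor.window(self.t_fr_off + self.settle_s,
                                self.pulse2[0] * (1 - 1e-12))
        t = self.fluor.t[seg] - self.t_fr_off
        y = self.fluor.y[seg]
        if len(t) < 5:
            raise ProtocolError("fewer than 5 samples in the post-fr_off decay")
        if t[-1] - t[0] <= 0 or np.ptp(y) < 1e-6 * max(abs(float(np.max(y))), 1e-300):
            raise DegenerateError("no fluorescence decay after fr_off")

        f_start0, f_end0 = float(y[0]), float(np.mean(y[-max(3, len(y) // 10):]))
        tau0 = max((t[-1] - t[0]) / 3.0, 1e-6)

        def model(tt, f_end, amp, tau):
            return f_end + amp * np.exp(-tt / tau)

        used_fallback = False
        tau = rss = float("nan")
        try:
            popt, _ = curve_fit(
                model, t, y, p0=[f_end0, f_start0 - f_end0, tau0],
                maxfev=10000,
            )
            f_end, amp, tau = popt
            rss = float(np.sum((model(t, *popt) - y) ** 2))
            if not np.isfinite(tau) or tau <= 0 or amp <= 0:
                raise RuntimeError("non-physical exponential fit")
            t_half = float(tau * math.log(2))
        except RuntimeError:
            used_fallback = True
            t_half = self._half_crossing(t, y, f_start0, f_end0)

        t_half_fb = None
        if not used_fallback:
            # cross-check; report both when they disagree by >10%
            try:
                fb = self._half_crossing(t, y, f_start0, f_end0)
                if abs(fb - t_half) > 0.1 * t_half:
                    t_half_fb = fb
            except DegenerateError:
                pass

        return StateTransitionResult(
            FMp_state1=fm1, FMpp_state2=fm2, t_half_s=t_half,
            fit_rss=rss, tau_s=float(tau), used_fallback=used_fallback,
            t_half_fallback_s=t_half_fb,
        )

    @staticmethod
    def _half_crossing(t, y, f_start, f_end) -> float:
        target = 0.5 * (f_start + f_end)
        below = np.nonzero(y <= target)[0]
        if len(below) == 0:
            raise DegenerateError("decay never crosses its half amplitude")
        i = below[0]
        if i == 0:
            return float(t[0])
        # linear interpolation of the crossing
        t0, t1, y0, y1 = t[i - 1], t[i], y[i - 1], y[i]
        return float(t0 + (target - y0) * (t1 - t0) / (y1 - y0))


def state_transition(fluor: SampledTrace, ann: ProtocolAnnotation,
                     **kw) -> StateTransitionResult:
    """Functional wrapper around :class:`StateTransitionModel`."""
    return StateTransitionModel(fluor, ann, **kw).fit()
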