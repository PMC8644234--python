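"""Fast chlorophyll-fluorescence induction (O-J-I-P) analysis.

A dark-adapted leaf under strong light shows a multiphasic fluorescence
rise with inflections O (50 us), J (2 ms), I (30 ms) and P (the peak, FM).
From the landmark values this module derives the classical JIP-test
quantities:

* ``FV/FM = (FM - F0)/FM`` — maximum quantum yield of PSII photochemistry,
* ``VJ = (FJ - F0)/(FM - F0)`` — relative variable fluorescence at J,
* ``M0 = 4 (F300us - F50us)/(FM - F0)`` — initial slope of the O-J rise
  (per ms), with the 50 us value standing in for F0,
* ``TR0/RC = M0/VJ`` — maximal trapping flux per reaction centre, an
  effective-antenna-size statistic.

For DCMU-blocked induction curves the complementary area between the
double-normalised curve V(t) and its saturation plateau estimates the
functional absorption cross-section of PSII: CA = 1/(sigma I), so at fixed
incident intensity sigma ~ 1/CA (reported in relative units, s^-1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import trapezoid
from scipy.ndimage import median_filter, uniform_filter1d

from .exceptions import CoverageError, DegenerateError, DomainError, NonSaturatedError
from .traces import SampledTrace

__all__ = [
    "OJIPFeatures",
    "CrossSectionResult",
    "extract_ojip",
    "fv_fm",
    "relative_variable_fluorescence",
    "complementary_area",
    "LANDMARK_TIMES",
]

#: canonical landmark times (seconds)
LANDMARK_TIMES = {"F0": 50e-6, "F300": 300e-6, "FJ": 2e-3, "FI": 30e-3}


@dataclass
class OJIPFeatures:
    """Fluorescence landmarks of one O-J-I-P transient plus JIP-test derivatives."""

    F0: float  # at 50 us (O level)
    F300: float  # at 300 us
    FJ: float  # at 2 ms (J step)
    FI: float  # at 30 ms (I step)
    FM: float  # peak (P level)
    FV: float = None  # FM - F0
    FvFm: float = None
    VJ: float = None
    M0: float = None
    TR0_RC: float = None

    def __post_init__(self):
        if self.FV is None:
            self.FV = self.FM - self.F0
        if self.FvFm is None:
            self.FvFm = self.FV / self.FM
        if self.VJ is None:
            self.VJ = (self.FJ - self.F0) / (self.FM - self.F0)
        if self.M0 is None:
            self.M0 = 4.0 * (self.F300 - self.F0) / (self.FM - self.F0)
        if self.TR0_RC is None:
            self.TR0_RC = self.M0 / self.VJ

    def as_dict(self) -> dict:
        return {
            "F0": self.F0, "F300": self.F300, "FJ": self.FJ, "FI": self.FI,
            "FM": self.FM, "FV": self.FV, "FvFm": self.FvFm, "VJ": self.VJ,
            "M0": self.M0, "TR0_RC": self.TR0_RC,
        }

    def summary(self) -> str:
        d = self.as_dict()
        rows = "\n".join(f"{k:>8s}  {v: .6g}" for k, v in d.items())
        return "O-J-I-P transient features\n" + rows


@dataclass
class CrossSectionResult:
    """Complementary area of a DCMU induction curve and the derived cross-section."""

    CA: float  # seconds, on the double-normalised curve
    sigma_rel: float  # 1/CA, relative cross-section at the given intensity
    plateau: float  # V level used as the saturation reference

    def summary(self) -> str:
        return (
            "DCMU complementary-area cross-section\n"
            f"      CA  {self.CA:.6g} s\n"
            f"   sigma  {self.sigma_rel:.6g} s^-1 (relative)\n"
            f" plateau  {self.plateau:.6g}"
        )


def _smooth(y: np.ndarray, kernel: int = 5) -> np.ndarray:
    return median_filter(y, size=kernel, mode="nearest")


def _landmark(t: np.ndarray, y: np.ndarray, t_target: float, rel_tol: float = 0.02) -> float:
    """Signal at ``t_target``: nearest sample if within +-2% of the target
    time, otherwise linear interpolation in (log10 t, F)."""
    i = int(np.argmin(np.abs(t - t_target)))
    if abs(t[i] - t_target) <= rel_tol * t_target:
        return float(y[i])
    if not (t[0] <= t_target <= t[-1]):
        raise CoverageError(
            f"trace [{t[0]:.3g}, {t[-1]:.3g}] s does not cover landmark at {t_target:.3g} s"
        )
    return float(np.interp(np.log10(t_target), np.log10(t), y))


def extract_ojip(trace: SampledTrace) -> OJIPFeatures:
    """Extract O-J-I-P landmarks and JIP-test derivatives from a fast transient.

    Landmarks are read by log-time interpolation at 50 us, 300 us, 2 ms and
    30 ms; FM is the maximum of a 5-point median-filtered (spike rejection)
    and then 5-point boxcar-averaged (plateau-noise suppression) trace, so
    neither a single spiky sample nor the running maximum of noise sets the
    P level.
    """
    t, y = trace.t, trace.y
    if np.any(t <= 0):
        raise DomainError("OJIP landmarks need positive times (log-time interpolation)")
    vals = {name: _landmark(t, y, tt) for name, tt in LANDMARK_TIMES.items()}
    FM = float(np.max(uniform_filter1d(_smooth(y), size=5, mode="nearest")))
    if FM <= vals["F0"]:
        raise DegenerateError(f"degenerate transient: FM={FM:.4g} <= F0={vals['F0']:.4g}")
    return OJIPFeatures(FM=FM, **vals)


def fv_fm(F0: float, FM: float) -> float:
    """Maximum quantum yield of PSII photochemistry, (FM - F0)/FM."""
    if FM <= 0:
        raise DomainError(f"FM must be positive, got {FM!r}")
    if F0 > FM:
        warnings.warn("F0 > FM: FV/FM is negative (invalid transient)", stacklevel=2)
    return (FM - F0) / FM


def relative_variable_fluorescence(trace: SampledTrace, F0: float, FM: float) -> SampledTrace:
    """Double-normalise F(t) to V(t) = (F(t) - F0)/(FM - F0)."""
    if FM <= F0:
        raise DomainError(f"FM={FM!r} must exceed F0={F0!r}")
    v = (trace.y - F0) / (FM - F0)
    return SampledTrace(trace.t.copy(), v, channel=trace.channel,
                        meta={**trace.meta, "normalized": "relative_variable"})


def complementary_area(
    vtrace: SampledTrace,
    plateau_mode: str = "max",
    reach_tol: float = 0.01,
    tail_frac: float = 0.2,
) -> CrossSectionResult:
    """Complementary area of a double-normalised DCMU induction curve.

    The plateau is either exactly 1 (``plateau_mode="one"``) or, with the
    default ``"max"``, the mean of V over the final ``tail_frac`` of the
    record — an estimate that is robust when the curve does not quite reach
    the FM used for normalisation and, unlike a running maximum, is not
    biased upward by noise. CA is the trapezoidal integral of (plateau - V)
    over the whole trace and sigma_rel = 1/CA. If the median-smoothed V
    never climbs within ``reach_tol`` of the plateau the curve is not
    saturated and an error is raised.
    """
    t, v = vtrace.t, vtrace.y
    if plateau_mode not in ("one", "max"):
        raise DomainError(f"unknown plateau_mode {plateau_mode!r}")
    if plateau_mode == "one":
        plateau = 1.0
    else:
        tail = t >= t[-1] - tail_frac * (t[-1] - t[0])
        plateau = float(np.mean(v[tail]))
    if plateau <= 0:
        raise DegenerateError("plateau is not positive; V(t) is not an induction curve")
    if float(np.max(_smooth(v))) < plateau * (1.0 - reach_tol):
        raise NonSaturatedError(
            f"V(t) never reaches the plateau {plateau:.4g} within {reach_tol:.0%} "
            f"(last V = {v[-1]:.4g})"
        )
    ca = float(trapezoid(plateau - v, t))
    if ca <= 0:
        raise DomainError("complementary area is zero (V at plateau from the start); "
                          "sigma is undefined")
    return CrossSectionResult(CA=ca, sigma_rel=1.0 / ca, plateau=plateau)
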