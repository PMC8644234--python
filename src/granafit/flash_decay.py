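"""Deconvolution of flash-induced variable-fluorescence decay.

After a single-turnover saturating flash, variable fluorescence decays as
QA- is reoxidised. The decay spans ~15 us to ~50 s and is described by two
exponential phases and one hyperbolic phase:

    FV(t) = A0 + A1 exp(-t/T1) + A2 exp(-t/T2) + A3 / (1 + t/T3)

The fast exponential (hundreds of us) reports QA- -> QB/QB- electron
transfer; the middle phase (tens of ms) QA- reoxidation in centres with an
empty QB pocket; the slow hyperbolic phase (seconds) S2(QA QB)- charge
recombination; A0 is the non-decaying component within the record.

The fit is a bounded trust-region least squares (analytic Jacobian) in the
style of a statsmodels model: build :class:`FlashDecayModel` from a trace,
call :meth:`~FlashDecayModel.fit`, get a :class:`DecayFit` results object.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .exceptions import CoverageError, DegenerateError, FitError, ValidationError
from .traces import SampledTrace

__all__ = ["DecayFit", "FlashDecayModel", "fit_decay", "initial_guess", "decay_model"]

#: decade windows used to seed the three time constants (seconds)
GUESS_WINDOWS = ((15e-6, 5e-3), (5e-3, 1.0), (1.0, 50.0))

PARAM_NAMES = ("A0", "A1", "A2", "A3", "T1", "T2", "T3")


def decay_model(t: np.ndarray, A0, A1, A2, A3, T1, T2, T3) -> np.ndarray:
    """Two exponentials plus a hyperbola: the flash-decay model."""
    t = np.asarray(t, dtype=float)
    return A0 + A1 * np.exp(-t / T1) + A2 * np.exp(-t / T2) + A3 / (1.0 + t / T3)


def _jacobian(t, A0, A1, A2, A3, T1, T2, T3) -> np.ndarray:
    e1 = np.exp(-t / T1)
    e2 = np.exp(-t / T2)
    h = 1.0 / (1.0 + t / T3)
    cols = [
        np.ones_like(t),
        e1,
        e2,
        h,
        A1 * e1 * t / T1**2,
        A2 * e2 * t / T2**2,
        A3 * h**2 * t / T3**2,
    ]
    return np.column_stack(cols)


@dataclass
class DecayFit:
    """Fitted parameters, phase fractions and diagnostics of a flash decay.

    Phases are relabelled after fitting so T1 < T2 for the two exponentials;
    the hyperbolic phase always carries index 3. Fractions are amplitudes
    over A1+A2+A3 (A0 excluded), summing to 1 exactly.
    """

    A0: float
    A1: float
    A2: float
    A3: float
    T1: float
    T2: float
    T3: float
    rss: float = float("nan")
    converged: bool = True
    n_iter: int = 0
    f1: float = field(default=None)
    f2: float = field(default=None)
    f3: float = field(default=None)

    def __post_init__(self):
        for name in ("T1", "T2", "T3"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("A1", "A2", "A3"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        total = self.A1 + self.A2 + self.A3
        if self.f1 is None:
            if total > 0:
                self.f1 = self.A1 / total
                self.f2 = self.A2 / total
                self.f3 = 1.0 - self.f1 - self.f2
            else:
                self.f1 = self.f2 = self.f3 = float("nan")
        if self.T2 >= self.T3:
            warnings.warn(
                "hyperbolic time constant T3 does not exceed T2; "
                "phase assignment may be ambiguous", stacklevel=3,
            )
        if self.converged and not np.isfinite(self.rss):
            self.converged = False

    # -- results-object conveniences -------------------------------------
    @property
    def params(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES])

    @property
    def fv0(self) -> float:
        """Model value at t = 0: A0 + A1 + A2 + A3."""
        return self.A0 + self.A1 + self.A2 + self.A3

    def predict(self, t) -> np.ndarray:
        return decay_model(np.asarray(t, dtype=float), *self.params)

    def as_dict(self) -> dict:
        d = {n: float(getattr(self, n)) for n in PARAM_NAMES}
        d.update(f1=self.f1, f2=self.f2, f3=self.f3, rss=self.rss,
                 converged=self.converged, n_iter=self.n_iter)
        return d

    def summary(self) -> str:
        lines = [
            "Flash-induced variable-fluorescence decay fit",
            "  FV(t) = A0 + A1 e^(-t/T1) + A2 e^(-t/T2) + A3/(1 + t/T3)",
            f"  {'phase':<10}{'tau':>12}{'amplitude':>12}{'fraction':>10}",
            f"  {'fast':<10}{self.T1:>12.4g}{self.A1:>12.4g}{self.f1:>10.3f}",
            f"  {'middle':<10}{self.T2:>12.4g}{self.A2:>12.4g}{self.f2:>10.3f}",
            f"  {'slow(hyp)':<10}{self.T3:>12.4g}{self.A3:>12.4g}{self.f3:>10.3f}",
            f"  A0 = {self.A0:.4g}   rss = {self.rss:.4g}   "
            f"converged = {self.converged} (nfev {self.n_iter})",
        ]
        return "\n".join(lines)


def initial_guess(trace: SampledTrace) -> DecayFit:
    """Seed the optimiser from the signal drop in three fixed decade windows.

    T1-T3 start at the geometric centres of [15 us, 5 ms], [5 ms, 1 s] and
    [1 s, 50 s]; amplitudes from the signal drop within each window; A0 from
    the trace minimum.
    """
    t, y = trace.t, trace.y
    amps, taus = [], []
    ymax = float(np.max(np.abs(y)))
    for lo, hi in GUESS_WINDOWS:
        sel = (t >= lo) & (t <= hi)
        if not np.any(sel):
            raise CoverageError(f"no samples in guess window [{lo:.3g}, {hi:.3g}] s")
        drop = float(y[sel][0] - y[sel][-1])
        amps.append(max(drop, 1e-3 * ymax))
        taus.append(float(np.sqrt(lo * hi)))
    a0 = float(np.min(y))
    return DecayFit(A0=a0, A1=amps[0], A2=amps[1], A3=amps[2],
                    T1=taus[0], T2=taus[1], T3=taus[2], rss=float("nan"))


class FlashDecayModel:
    """Least-squares model for the 7-parameter flash-decay deconvolution.

    Parameters
    ----------
    trace
        variable fluorescence FV(t) = F(t) - F0, baseline already
        subtracted, spanning at least three decades in time.
    weights
        ``"log_density"`` (default) weights each point inversely to the
        local sampling density in log-time, so a microsecond decade sampled
        densely does not dominate the seconds decades; ``"uniform"``
        weights all points equally.
    """

    #: physical bounds of the protocol window
    T_BOUNDS = (1e-5, 100.0)

    def __init__(self, trace: SampledTrace, weights: str = "log_density"):
        if len(trace) < 10:
            raise DegenerateError("flash-decay fit needs at least 10 samples")
        if np.allclose(trace.y, 0.0):
            raise DegenerateError("all-zero variable fluorescence")
        if weights not in ("uniform", "log_density"):
            raise ValidationError(f"unknown weighting {weights!r}")
        if np.any(trace.t <= 0):
            raise ValidationError("flash-decay times must be positive")
        self.trace = trace
        self.weights = weights
        if weights == "log_density":
            d = np.gradient(np.log(trace.t))
            self._w = np.sqrt(d / np.mean(d))
        else:
            self._w = np.ones_like(trace.t)

    # -- internals --------------------------------------------------------
    def _bounds(self):
        ymax = float(np.max(self.trace.y))
        lo = np.array([-0.1 * ymax, 0.0, 0.0, 0.0,
                       self.T_BOUNDS[0], self.T_BOUNDS[0], self.T_BOUNDS[0]])
        hi = np.array([0.5 * ymax, 2 * ymax, 2 * ymax, 2 * ymax,
                       self.T_BOUNDS[1], self.T_BOUNDS[1], self.T_BOUNDS[1]])
        return lo, hi

    def _solve(self, x0, lo, hi, max_nfev):
        t, y, w = self.trace.t, self.trace.y, self._w

        def resid(p):
            return (decay_model(t, *p) - y) * w

        def jac(p):
            return _jacobian(t, *p) * w[:, None]

        return least_squares(
            resid, x0, jac=jac, bounds=(lo, hi), method="trf",
            x_scale="jac", xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=max_nfev,
        )

    def fit(self, init: DecayFit | None = None, max_nfev: int = 500,
            restart_seed: int = 0) -> DecayFit:
        """Fit the decay; one jittered restart if the iteration cap is hit."""
        if init is None:
            init = initial_guess(self.trace)
        lo, hi = self._bounds()
        x0 = np.clip(init.params, lo + 1e-12, hi - 1e-12)
        res = self._solve(x0, lo, hi, max_nfev)
        n_iter = res.nfev
        if res.status == 0:  # hit the cap: restart once from perturbed init
            rng = np.random.default_rng(restart_seed)
            x1 = np.clip(x0 * (1.0 + 0.2 * rng.standard_normal(len(x0))),
                         lo + 1e-12, hi - 1e-12)
            res2 = self._solve(x1, lo, hi, max_nfev)
            n_iter += res2.nfev
            if res2.cost <= res.cost:
                res = res2
        if not np.all(np.isfinite(res.x)):
            raise FitError(f"optimizer returned non-finite parameters: {res.x}")

        A0, A1, A2, A3, T1, T2, T3 = res.x
        if T2 < T1:  # canonical order of the permutation-symmetric exponentials
            A1, A2, T1, T2 = A2, A1, T2, T1
        raw = decay_model(self.trace.t, A0, A1, A2, A3, T1, T2, T3) - self.trace.y
        return DecayFit(
            A0=A0, A1=A1, A2=A2, A3=A3, T1=T1, T2=T2, T3=T3,
            rss=float(np.sum(raw**2)),
            converged=bool(res.status != 0),
            n_iter=int(n_iter),
        )


def fit_decay(trace: SampledTrace, init: DecayFit | None = None,
              weights: str = "log_density") -> DecayFit:
    """Functional wrapper around :class:`FlashDecayModel`."""
    return FlashDecayModel(trace, weights=weights).fit(init=init)
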