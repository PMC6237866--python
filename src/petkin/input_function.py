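"""Blood-data modelling: tri-exponential plasma fit, Hill parent-fraction fit,
and the metabolite-corrected arterial input function their product defines.

The measured total-plasma curve is fitted to a linear-rise/tri-exponential
model (peak pinned at the maximal sample, rise as a straight line through
zero — exponential sums cannot represent the rise). The parent fraction is
fitted to a Hill curve under box bounds. The corrected input is
plasma_fit(t) * parent_fraction(t).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .core import TimeActivityCurve
from .errors import ContractError, FitFailureError, InsufficientDataError
from .synthetic import AifParams, HillParams


def fit_plasma_triexp(samples: TimeActivityCurve, n_starts: int = 5,
                      seed: int = 0, weighted: bool = False) -> tuple[AifParams, float]:
    """Least-squares fit of the plasma model; returns (params, residual RMS).

    Variable projection: for candidate decay rates the amplitudes are solved
    by non-negative least squares, and the rates are optimized by seeded
    multi-start Nelder-Mead in log space. ``weighted`` divides residuals by
    max(sample, peak/100) for relative weighting.
    """
    t = samples.times
    y = samples.activity
    if len(t) < 8:
        raise InsufficientDataError("plasma fit needs at least 8 samples")
    if np.max(y) <= 0:
        raise FitFailureError("plasma samples are non-positive everywhere")
    i_peak = int(np.argmax(y))
    tp = float(t[i_peak])
    if tp <= 0:
        raise ContractError("peak sample must occur at t > 0")
    tt = t[i_peak:] - tp
    yy = y[i_peak:]
    if len(tt) < 4:
        raise InsufficientDataError("too few post-peak samples for a 3-exponential fit")
    w = 1.0 / np.maximum(yy, np.max(y) / 100.0) if weighted else np.ones_like(yy)

    def residual_for(log_rates):
        rates = np.exp(log_rates)
        E = np.exp(-np.outer(tt, rates)) * w[:, None]
        amps, _ = optimize.nnls(E, yy * w)
        res = E @ amps - yy * w
        return float(res @ res), amps, rates

    rng = np.random.default_rng(seed)
    base = np.log([3.0, 0.3, 0.03])
    best = None
    for k in range(n_starts):
        start = base if k == 0 else base + rng.normal(0.0, 0.7, size=3)
        sol = optimize.minimize(lambda lr: residual_for(lr)[0], start,
                                method="Nelder-Mead",
                                options={"xatol": 1e-7, "fatol": 1e-12,
                                         "maxiter": 4000})
        if best is None or sol.fun < best.fun:
            best = sol
    sse, amps, rates = residual_for(best.x)
    order = np.argsort(-rates)
    rates, amps = rates[order], amps[order]
    # decay rates must be distinct for the closed-form machinery downstream
    for i in range(1, 3):
        if abs(rates[i] - rates[i - 1]) < 1e-9:
            rates[i] = rates[i - 1] * (1.0 - 1e-6) - 1e-9
    params = AifParams(peak_time=tp, amplitudes=tuple(amps),
                       decay_rates=tuple(rates))
    rms = float(np.sqrt(np.mean((params(t) - y) ** 2)))
    return params, rms


def fit_parent_hill(times, fractions) -> tuple[HillParams, float]:
    """Bounded least-squares Hill fit of parent-fraction samples."""
    times = np.asarray(times, dtype=float)
    fractions = np.asarray(fractions, dtype=float)
    if np.any((fractions < 0) | (fractions > 1)):
        raise ContractError("parent fractions must lie in [0, 1]")
    if not np.any(times >= 5.0):
        raise ContractError("need at least one parent-fraction sample at t >= 5 min")

    def model(t, a, b, c):
        tb = np.power(np.clip(t, 0.0, None), b)
        return 1.0 - a * tb / (tb + c)

    best = None
    for p0 in ((0.5, 1.0, 7.0), (0.9, 2.0, 50.0), (0.0, 1.0, 10.0)):
        try:
            popt, _ = optimize.curve_fit(
                model, times, fractions, p0=p0,
                bounds=([0.0, 1e-3, 1e-3], [1.0, 10.0, 1e4]), maxfev=20000)
        except RuntimeError:
            continue
        sse = float(np.sum((model(times, *popt) - fractions) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None:
        raise FitFailureError("Hill fit failed to converge from every start")
    popt = best[1]
    params = HillParams(a=float(popt[0]), b=float(popt[1]), c=float(popt[2]))
    rms = float(np.sqrt(np.mean((params(times) - fractions) ** 2)))
    return params, rms


@dataclass
class ArterialInputModel:
    """Fitted plasma + metabolite model yielding the corrected input."""

    aif_fit: AifParams
    hill_fit: HillParams
    plasma_rms: float = 0.0
    hill_rms: float = 0.0
    t_max: float = 60.0          # last fitted sample time, for extrapolation warnings
    route: str = "venous"

    def __call__(self, t) -> np.ndarray:
        return self.aif_fit(t) * self.hill_fit(np.clip(t, 0.0, None))

    def cum_integral(self, t, dt: float = 0.01) -> np.ndarray:
        """Running integral of the corrected input on a fine uniform grid."""
        t = np.asarray(t, dtype=float)
        grid = np.arange(0.0, float(np.max(t)) + dt, dt)
        from scipy.integrate import cumulative_trapezoid
        cum = cumulative_trapezoid(self(grid), grid, initial=0.0)
        return np.interp(t, grid, cum)

    def to_dict(self) -> dict:
        return {
            "aif_fit": {"peak_time": self.aif_fit.peak_time,
                        "amplitudes": list(self.aif_fit.amplitudes),
                        "decay_rates": list(self.aif_fit.decay_rates)},
            "hill_fit": {"a": self.hill_fit.a, "b": self.hill_fit.b,
                         "c": self.hill_fit.c},
            "plasma_rms": self.plasma_rms, "hill_rms": self.hill_rms,
            "t_max": self.t_max, "route": self.route,
        }

    @classmethod
    def from_dict(cls, d) -> "ArterialInputModel":
        return cls(AifParams(d["aif_fit"]["peak_time"],
                             tuple(d["aif_fit"]["amplitudes"]),
                             tuple(d["aif_fit"]["decay_rates"])),
                   HillParams(**d["hill_fit"]),
                   d.get("plasma_rms", 0.0), d.get("hill_rms", 0.0),
                   d.get("t_max", 60.0), d.get("route", "venous"))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "ArterialInputModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_input_model(plasma: TimeActivityCurve, parent_times, parent_fractions,
                    seed: int = 0, route: str = "venous") -> ArterialInputModel:
    """Fit both blood models and assemble the corrected-input object."""
    aif, prms = fit_plasma_triexp(plasma, seed=seed)
    hill, hrms = fit_parent_hill(parent_times, parent_fractions)
    return ArterialInputModel(aif, hill, prms, hrms,
                              t_max=float(plasma.times[-1]), route=route)


def corrected_input(model: ArterialInputModel, times) -> TimeActivityCurve:
    """Metabolite-corrected plasma curve at the requested times."""
    times = np.asarray(times, dtype=float)
    if np.any(times > model.t_max + 1e-9):
        warnings.warn("corrected_input evaluated beyond the fitted span; "
                      "extrapolating the plasma and Hill models")
    return TimeActivityCurve(times, model(times), label="plasma_corrected",
                             model=model)
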