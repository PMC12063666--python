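"""Fluorescence-lifetime fitting and FRET efficiency.

Photon-arrival histograms from time-correlated single-photon counting
are fitted on the tail of the decay (past the peak, so no instrument
response modelling is needed) with a mono- or bi-exponential model plus
a constant background, using Poisson-weighted nonlinear least squares.
FRET efficiency follows from donor lifetimes as E = 1 - tau_DA / tau_D,
where tau_DA is the donor lifetime in the presence of the acceptor (the
tension-sensor pair) and tau_D the lifetime of the donor alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize

from .synth import DecayHistogram

__all__ = [
    "LifetimeFit",
    "FretResult",
    "FitError",
    "fit_decay_tail",
    "fret_efficiency",
    "cohort_fret",
]


class FitError(RuntimeError):
    """Decay fit failed to converge."""


@dataclass(frozen=True)
class LifetimeFit:
    model: str  # "mono" | "bi"
    lifetimes: tuple[float, ...]  # ns, sorted ascending for bi
    amplitudes: tuple[float, ...]
    background: float
    tau_avg: float  # ns
    tail_start: float  # ns
    reduced_residual: float
    at_bounds: bool = False


@dataclass(frozen=True)
class FretResult:
    E: float
    tau_DA: float
    tau_D: float


def _mono(t, a, tau, c):
    return a * np.exp(-t / tau) + c


def _bi(t, a1, tau1, a2, tau2, c):
    return a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2) + c


def default_tail_start(hist: DecayHistogram, offset_bins: int = 2) -> float:
    """Tail begins a couple of bins past the histogram maximum."""
    i = int(np.argmax(hist.counts)) + offset_bins
    i = min(i, len(hist.bin_centers) - 1)
    return float(hist.bin_centers[i])


def fit_decay_tail(
    hist: DecayHistogram,
    model: str = "mono",
    tail_start: float | None = None,
    intensity_weighted: bool = False,
) -> LifetimeFit:
    """Fit the decay tail with an exponential model plus flat background.

    Residuals are weighted by 1/sqrt(max(counts, 1)) (Poisson). The
    average lifetime ``tau_avg`` is amplitude-weighted
    (sum a_i tau_i / sum a_i) by default; set ``intensity_weighted`` for
    the photon-weighted mean (sum a_i tau_i^2 / sum a_i tau_i).
    """
    if model not in ("mono", "bi"):
        raise ValueError("model must be 'mono' or 'bi'")
    if tail_start is None:
        tail_start = default_tail_start(hist)
    t = np.asarray(hist.bin_centers, dtype=float)
    y = np.asarray(hist.counts, dtype=float)
    sel = t >= tail_start
    t, y = t[sel], y[sel]
    if len(t) < 20:
        raise ValueError("need at least 20 bins after tail_start")
    if y.sum() < 1e3:
        raise ValueError("need at least 1e3 photons in the tail")
    t0 = t[0]
    ts = t - t0  # fit in shifted time for conditioning
    sigma = np.sqrt(np.maximum(y, 1.0))

    # initial lifetime from a log-linear fit of the upper tail
    pos = y > 0
    slope, _ = np.polyfit(ts[pos], np.log(y[pos] + 1e-9), 1)
    tau0 = -1.0 / slope if slope < 0 else (ts[-1] - ts[0]) / 3.0
    tau0 = float(np.clip(tau0, 1e-3, 10 * (ts[-1] + 1e-9)))
    a0 = float(max(y[0], 1.0))

    tau_hi = 50.0 * max(tau0, 1.0)
    func = _mono if model == "mono" else _bi
    if model == "mono":
        p0 = [a0, tau0, 0.0]
        bounds = ([0.0, 1e-4, -np.inf], [np.inf, tau_hi, np.inf])
    else:
        p0 = [0.6 * a0, 0.5 * tau0, 0.4 * a0, 1.5 * tau0, 0.0]
        bounds = (
            [0.0, 1e-4, 0.0, 1e-4, -np.inf],
            [np.inf, tau_hi, np.inf, tau_hi, np.inf],
        )
    try:
        popt, _ = optimize.curve_fit(
            func, ts, y, p0=p0, sigma=sigma, bounds=bounds, maxfev=20000
        )
        # second pass with model-based Poisson weights: removes the bias
        # of weighting by the observed counts in sparse tail bins
        sigma2 = np.sqrt(np.maximum(func(ts, *popt), 1.0))
        popt, _ = optimize.curve_fit(
            func, ts, y, p0=popt, sigma=sigma2, bounds=bounds, maxfev=20000
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"decay fit did not converge: {exc}") from exc
    fitted = func(ts, *popt)
    if model == "mono":
        a, tau, c = popt
        amps = (float(a),)
        taus = (float(tau),)
        c = float(c)
    else:
        a1, tau1, a2, tau2, c = popt
        pairs = sorted([(float(tau1), float(a1)), (float(tau2), float(a2))])
        taus = tuple(p[0] for p in pairs)
        amps = tuple(p[1] for p in pairs)
        c = float(c)

    at_bounds = any(
        math.isclose(tau, b, rel_tol=1e-6)
        for tau in taus
        for b in (1e-4, tau_hi)
    )
    # amplitudes refer to t = tail_start; rescale to t = 0 convention
    amps0 = tuple(a * math.exp(t0 / tau) for a, tau in zip(amps, taus))
    if intensity_weighted:
        tau_avg = sum(a * tau**2 for a, tau in zip(amps0, taus)) / sum(
            a * tau for a, tau in zip(amps0, taus)
        )
    else:
        tau_avg = sum(a * tau for a, tau in zip(amps0, taus)) / sum(amps0)
    red = float(np.mean(((y - fitted) / sigma) ** 2))
    return LifetimeFit(
        model=model,
        lifetimes=taus,
        amplitudes=amps0,
        background=c,
        tau_avg=float(tau_avg),
        tail_start=float(tail_start),
        reduced_residual=red,
        at_bounds=at_bounds,
    )


def fret_efficiency(tau_DA: float, tau_D: float) -> FretResult:
    """FRET efficiency E = 1 - tau_DA / tau_D."""
    if tau_D <= 0:
        raise ValueError("tau_D must be positive")
    return FretResult(E=1.0 - tau_DA / tau_D, tau_DA=tau_DA, tau_D=tau_D)


def cohort_fret(
    sensor_fits: Sequence[LifetimeFit],
    donor_only_fits: Sequence[LifetimeFit],
) -> dict:
    """Per-sensor FRET efficiencies against the donor-cohort median.

    tau_D is the median tau_avg of the donor-only cohort (the convention
    used for calibrated lifetime references); each sensor's tau_avg is
    converted to an efficiency against that value.
    """
    if not donor_only_fits:
        raise ValueError("empty donor cohort")
    tau_D = float(np.median([f.tau_avg for f in donor_only_fits]))
    results = [fret_efficiency(f.tau_avg, tau_D) for f in sensor_fits]
    es = np.array([r.E for r in results])
    summary = {
        "tau_D": tau_D,
        "efficiencies": results,
        "median_E": float(np.median(es)) if len(es) else math.nan,
        "iqr_E": (
            float(np.percentile(es, 75) - np.percentile(es, 25))
            if len(es)
            else math.nan
        ),
        "n": len(es),
    }
    return summary
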