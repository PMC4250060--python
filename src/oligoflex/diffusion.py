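"""Internal diffusion coefficients of collective variables.

Within the harmonic approximation the motion of a protein along a
collective variable xi behaves like diffusion in a quadratic well, and
the diffusion coefficient is D = <d xi^2> / tau_xi: the stationary
variance of the CV divided by its decorrelation time.  tau_xi comes
from a single-exponential fit to the normalized autocorrelation
function, which for a quasi-harmonic CV decays exponentially after a
short transient.  An initial stretch of the series (default 10 ns) is
discarded as equilibration before anything is estimated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .collective_variables import CVSeries

__all__ = [
    "DiffusionEstimate",
    "CorrelationTimeFit",
    "autocorrelation",
    "fit_correlation_time",
    "diffusion_coefficient",
]


def _skip_series(series: CVSeries, skip_ns: float) -> np.ndarray:
    keep = series.times >= skip_ns * 1000.0
    return series.values[keep]


def autocorrelation(
    series: CVSeries, skip_ns: float = 10.0, max_lag_fraction: float = 0.1
) -> np.ndarray:
    """Mean-removed, variance-normalized ACF of a CV series.

    Computed by FFT up to a lag of ``max_lag_fraction`` of the series
    length (long lags are noise-dominated); ACF(0) = 1 exactly.  The
    first ``skip_ns`` of the series is excluded as transient.
    """
    x = _skip_series(series, skip_ns)
    n = x.size
    if n < 10:
        raise ValueError("series too short after transient skip")
    x = x - x.mean()
    var = float(np.dot(x, x) / n)
    if var <= 0:
        raise ValueError("constant CV series: autocorrelation undefined")
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n] / n
    max_lag = max(int(np.floor(max_lag_fraction * n)), 2)
    return acov[: max_lag + 1] / acov[0]


@dataclass
class CorrelationTimeFit:
    """Exponential fit of the ACF: rho(lag) = exp(-lag/tau)."""

    tau: float  # in frames of the ACF's sampling interval
    residual_rms: float
    n_lags_fit: int
    ok: bool = True
    message: str = ""


def fit_correlation_time(
    acf: np.ndarray,
    transient_lags: int = 0,
    floor: float = np.exp(-2.0),
    poor_fit_rms: float = 0.1,
) -> CorrelationTimeFit:
    """Single-exponential least-squares fit of the ACF decay.

    The fit window starts after ``transient_lags`` and stops where the
    ACF first drops below e^-2 (beyond that the tail is noise).  No
    additive offset is fitted; the residual RMS is reported and fits
    with RMS above ``poor_fit_rms`` (e.g. oscillating ACFs) are flagged
    ``ok=False``.  tau is in units of the lag spacing.
    """
    acf = np.asarray(acf, dtype=float)
    below = np.flatnonzero(acf < floor)
    if below.size:
        end = int(below[0])
    elif float(acf.min()) > 0.9:
        raise ValueError("ACF never decays within the available lags")
    else:
        end = acf.size  # decays, but not below e^-2 in the window: fit what exists
    end = max(end, transient_lags + 3)
    if end > acf.size:
        raise ValueError("ACF window too short after the transient")
    lags = np.arange(transient_lags, end, dtype=float)
    y = acf[transient_lags:end]

    def model(t, tau):
        return np.exp(-t / tau)

    # log-linear start value from the last fitted point
    tau0 = max(-lags[-1] / np.log(max(y[-1], 1e-6)), 1.0)
    popt, _ = curve_fit(model, lags, y, p0=(tau0,), bounds=((1e-9,), (np.inf,)), maxfev=10000)
    tau = float(popt[0])
    rms = float(np.sqrt(np.mean((model(lags, tau) - y) ** 2)))
    ok = rms <= poor_fit_rms
    msg = "" if ok else f"poor exponential fit (residual rms {rms:.3g})"
    return CorrelationTimeFit(tau, rms, int(end - transient_lags), ok, msg)


@dataclass
class DiffusionEstimate:
    """D = <d xi^2> / tau_xi for one collective variable."""

    cv_name: str
    variance: float  # CV-units^2, after transient skip
    tau_ps: float  # decorrelation time, ps
    skip_ns: float
    fit: CorrelationTimeFit
    units: str = ""

    def __post_init__(self) -> None:
        if self.variance < 0 or not self.tau_ps > 0:
            raise ValueError("variance must be >= 0 and tau > 0")

    @property
    def tau_ns(self) -> float:
        return self.tau_ps / 1000.0

    @property
    def diffusion_per_ps(self) -> float:
        return self.variance / self.tau_ps

    @property
    def diffusion_per_ns(self) -> float:
        return self.variance / self.tau_ns

    def as_dict(self) -> dict:
        return {
            "cv": self.cv_name,
            "variance": self.variance,
            "tau_ns": self.tau_ns,
            "D_per_ns": self.diffusion_per_ns,
            "skip_ns": self.skip_ns,
            "fit_residual_rms": self.fit.residual_rms,
            "fit_ok": self.fit.ok,
        }


def diffusion_coefficient(
    series: CVSeries, skip_ns: float = 10.0, transient_lags: int = 0
) -> DiffusionEstimate:
    """Estimate D for a CV series: variance over fitted decorrelation time."""
    x = _skip_series(series, skip_ns)
    if x.size < 10:
        raise ValueError("series too short after transient skip")
    var = float(x.var())
    acf = autocorrelation(series, skip_ns)
    fit = fit_correlation_time(acf, transient_lags=transient_lags)
    dt = float(series.times[1] - series.times[0]) if series.times.size > 1 else 1.0
    return DiffusionEstimate(
        series.name, var, fit.tau * dt, skip_ns, fit, units=series.units
    )
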