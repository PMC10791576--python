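"""Kinetic model fitting.

Models:

* single exponential rise ``y = baseline + amplitude*(1 - exp(-rate*t))`` or
  decay ``y = baseline + amplitude*exp(-rate*t)`` (direction auto-detected),
  the per-trace fit for quench-flow product formation and real-time
  association/dissociation measurements;
* hyperbolic concentration dependence ``k_obs = k_pol*c / (K_d,app + c)``,
  giving the maximum incorporation rate and apparent dissociation constant;
* the specificity constant ``k_pol / K_d,app`` with first-order error
  propagation;
* pseudo-first-order association, per-concentration exponential rates
  regressed through the origin to give ``k_on``;
* a dissociation upper bound for traces with no measurable decay.

Uncertainties on the exponential rate come from seeded residual-resampling
bootstrap; hyperbolic-fit standard errors from the curve_fit covariance.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .simulate.traces import KineticTrace

logger = logging.getLogger(__name__)

__all__ = [
    "ExpFit",
    "HyperbolicFit",
    "SpecificityConstant",
    "AssociationFit",
    "DissociationResult",
    "fit_single_exponential",
    "fit_hyperbola",
    "specificity_constant",
    "fit_association",
    "dissociation_bound",
]


@dataclass(frozen=True)
class ExpFit:
    rate: float
    amplitude: float
    baseline: float
    kind: str  # "rise" | "decay" | "flat"
    rmse: float
    rate_ci: tuple[float, float]
    n_boot: int

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("fitted rate must be >= 0")
        lo, hi = self.rate_ci
        if not (lo <= self.rate <= hi):
            raise ValueError("CI must contain the point estimate")


@dataclass(frozen=True)
class HyperbolicFit:
    k_pol: float
    kd_app: float
    k_pol_stderr: float
    kd_app_stderr: float
    rmse: float


@dataclass(frozen=True)
class SpecificityConstant:
    value: float  # k_pol / kd_app
    stderr: float


@dataclass(frozen=True)
class AssociationFit:
    k_on: float
    concs: tuple[float, ...]
    k_obs: tuple[float, ...]


@dataclass(frozen=True)
class DissociationResult:
    k_off: float
    rate_ci: tuple[float, float]
    measurable: bool
    upper_bound: float  # meaningful when not measurable


def _rise(t, baseline, amplitude, rate):
    return baseline + amplitude * (1.0 - np.exp(-rate * t))


def _decay(t, baseline, amplitude, rate):
    return baseline + amplitude * np.exp(-rate * t)


def _coerce_trace(trace) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(trace, KineticTrace):
        return trace.time, trace.signal
    t, y = trace
    return np.asarray(t, dtype=float), np.asarray(y, dtype=float)


def _init_rate(t: np.ndarray, y: np.ndarray, rising: bool) -> float:
    """Log-linearized rate estimate from the early part of the trace."""
    span = t[-1] - t[0]
    if rising:
        plateau = np.mean(y[-max(2, len(y) // 5):])
        lo = np.min(y)
        denom = plateau - lo
        if denom <= 0:
            return 1.0 / max(span, 1e-12)
        frac = np.clip((y - lo) / denom, 1e-6, 1 - 1e-6)
        z = -np.log1p(-frac)
    else:
        base = np.min(y)
        top = y[0] - base
        if top <= 0:
            return 1.0 / max(span, 1e-12)
        frac = np.clip((y - base) / top, 1e-6, 1.0)
        z = -np.log(frac)
    # z ~ rate * t on the early rise/fall
    m = min(len(t), max(4, len(t) // 3))
    tt, zz = t[:m], z[:m]
    denom = float(np.dot(tt, tt))
    rate = float(np.dot(tt, zz) / denom) if denom > 0 else 1.0 / max(span, 1e-12)
    return rate if rate > 0 else 1.0 / max(span, 1e-12)


def fit_single_exponential(
    trace,
    n_boot: int = 200,
    seed: int = 0,
    direction: str | None = None,
) -> ExpFit:
    """Least-squares single-exponential fit with multi-start initialization
    and a residual-resampling bootstrap CI on the rate.

    ``trace`` is a KineticTrace or a (time, signal) pair.  Direction is
    detected from the trend unless given ('rise' or 'decay').  A flat trace
    returns rate 0 with a wide CI.
    """
    t, y = _coerce_trace(trace)
    if len(t) < 5:
        raise ValueError("need at least 5 points")
    if not np.all(np.diff(t) > 0):
        raise ValueError("times must be strictly increasing")

    scale = float(np.ptp(y))
    if scale == 0.0 or scale < 1e-12 * max(1.0, abs(float(np.mean(y)))):
        span = t[-1] - t[0]
        return ExpFit(rate=0.0, amplitude=0.0, baseline=float(np.mean(y)),
                      kind="flat", rmse=0.0, rate_ci=(0.0, 10.0 / span), n_boot=0)

    if direction is None:
        head = np.mean(y[: max(2, len(y) // 5)])
        tail = np.mean(y[-max(2, len(y) // 5):])
        rising = tail > head
    else:
        rising = direction == "rise"
    model = _rise if rising else _decay

    r0 = _init_rate(t, y, rising)
    if rising:
        p0_base = (float(np.min(y)), float(np.max(y) - np.min(y)), r0)
    else:
        p0_base = (float(np.min(y)), float(y[0] - np.min(y)), r0)
    bounds = ([-np.inf, 0.0, 0.0], [np.inf, np.inf, np.inf])

    def _try_fit(tt, yy, p0):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(model, tt, yy, p0=p0, bounds=bounds,
                                maxfev=20000, xtol=1e-10, ftol=1e-10)
        return popt

    best = None
    diagnostics = []
    for jitter in (1.0, 0.2, 0.5, 2.0, 5.0):
        p0 = (p0_base[0], p0_base[1], max(r0 * jitter, 1e-12))
        try:
            popt = _try_fit(t, y, p0)
        except (RuntimeError, ValueError) as exc:
            diagnostics.append(f"start rate={p0[2]:.3g}: {exc}")
            continue
        sse = float(np.sum((model(t, *popt) - y) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None:
        raise RuntimeError(
            "single-exponential fit failed from all starts:\n" + "\n".join(diagnostics)
        )
    sse, popt = best
    baseline, amplitude, rate = (float(v) for v in popt)
    resid = y - model(t, *popt)
    rmse = float(np.sqrt(np.mean(resid**2)))

    # flat-trace degenerate fit: rate indistinguishable from 0 on this window
    if rate * (t[-1] - t[0]) < 1e-6:
        span = t[-1] - t[0]
        return ExpFit(rate=0.0, amplitude=amplitude, baseline=baseline, kind="flat",
                      rmse=rmse, rate_ci=(0.0, 10.0 / span), n_boot=0)

    rng = np.random.default_rng(seed)
    fitted = model(t, *popt)
    boot_rates = []
    for _ in range(n_boot):
        yb = fitted + rng.choice(resid, size=len(resid), replace=True)
        try:
            pb = _try_fit(t, yb, popt)
            boot_rates.append(pb[2])
        except (RuntimeError, ValueError):
            continue
    if len(boot_rates) >= max(10, n_boot // 2):
        lo, hi = np.percentile(boot_rates, [2.5, 97.5])
        ci = (min(float(lo), rate), max(float(hi), rate))
    else:
        ci = (0.0, rate * 10.0)
    return ExpFit(rate=rate, amplitude=amplitude, baseline=baseline,
                  kind="rise" if rising else "decay", rmse=rmse,
                  rate_ci=ci, n_boot=len(boot_rates))


def fit_hyperbola(
    concs: Sequence[float],
    rates: Sequence[float],
    rate_stderrs: Sequence[float] | None = None,
) -> HyperbolicFit:
    """Fit k_obs = k_pol * c / (K_d,app + c), optionally inverse-variance
    weighted when per-rate standard errors are supplied."""
    c = np.asarray(concs, dtype=float)
    k = np.asarray(rates, dtype=float)
    if c.shape != k.shape or c.ndim != 1:
        raise ValueError("concs and rates must be equal-length 1-D arrays")
    if len(c) < 2:
        raise ValueError("need at least 2 concentrations")
    if np.any(c <= 0):
        raise ValueError("concentrations must be > 0")
    if len(c) < 4:
        logger.warning("fewer than 4 concentrations; hyperbolic fit may be fragile")

    def model(cc, k_pol, kd):
        return k_pol * cc / (kd + cc)

    kmax = float(np.max(k))
    half = kmax / 2.0
    kd0 = float(c[np.argmin(np.abs(k - half))]) if kmax > 0 else float(np.median(c))
    sigma = np.asarray(rate_stderrs, dtype=float) if rate_stderrs is not None else None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        popt, pcov = curve_fit(
            model, c, k, p0=(kmax * 1.2 if kmax > 0 else 1.0, max(kd0, 1e-12)),
            sigma=sigma, absolute_sigma=sigma is not None,
            bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=20000,
        )
    k_pol, kd = (float(v) for v in popt)
    perr = np.sqrt(np.diag(pcov))
    rmse = float(np.sqrt(np.mean((model(c, *popt) - k) ** 2)))
    if kd < np.min(c) / 10 or kd > np.max(c) * 10:
        logger.warning(
            "hyperbolic parameters weakly identified: K_d,app=%.3g outside the "
            "sampled concentration range [%.3g, %.3g]", kd, c.min(), c.max(),
        )
    return HyperbolicFit(k_pol=k_pol, kd_app=kd,
                         k_pol_stderr=float(perr[0]), kd_app_stderr=float(perr[1]),
                         rmse=rmse)


def specificity_constant(fit: HyperbolicFit) -> SpecificityConstant:
    """k_pol / K_d,app with first-order (independent-error) propagation."""
    if fit.k_pol <= 0 or fit.kd_app <= 0:
        raise ValueError("fit parameters must be positive")
    value = fit.k_pol / fit.kd_app
    rel = np.sqrt(
        (fit.k_pol_stderr / fit.k_pol) ** 2 + (fit.kd_app_stderr / fit.kd_app) ** 2
    )
    return SpecificityConstant(value=float(value), stderr=float(value * rel))


def fit_association(
    traces: Sequence[tuple],
    n_boot: int = 0,
    seed: int = 0,
) -> AssociationFit:
    """Fit k_on from per-concentration association traces.

    ``traces`` is a sequence of (concentration, trace) pairs or of
    KineticTrace objects carrying their concentration.  Per-trace exponential
    rates are regressed linearly through the origin against concentration.
    """
    pairs = []
    for item in traces:
        if isinstance(item, KineticTrace):
            if item.concentration is None:
                raise ValueError("trace has no concentration attached")
            pairs.append((float(item.concentration), item))
        else:
            conc, tr = item
            pairs.append((float(conc), tr))
    if not pairs:
        raise ValueError("no traces supplied")
    concs, k_obs = [], []
    for i, (conc, tr) in enumerate(pairs):
        fit = fit_single_exponential(tr, n_boot=n_boot, seed=seed + i, direction="rise")
        concs.append(conc)
        k_obs.append(fit.rate)
    c = np.asarray(concs)
    k = np.asarray(k_obs)
    if len(c) == 1:
        logger.warning("single concentration: k_on taken as k_obs / c")
        k_on = float(k[0] / c[0])
    else:
        k_on = float(np.dot(c, k) / np.dot(c, c))
    if k_on <= 0:
        raise ValueError(f"non-positive association slope ({k_on:.3g})")
    return AssociationFit(k_on=k_on, concs=tuple(concs), k_obs=tuple(k_obs))


def dissociation_bound(
    trace,
    window: float = 60.0,
    min_detectable_fraction: float = 0.01,
    n_boot: int = 200,
    seed: int = 0,
) -> DissociationResult:
    """Fit a decay rate; when indistinguishable from zero, report the upper
    bound implied by not observing a detectable signal drop over ``window``.

    The detectable drop is max(3 x residual noise, ``min_detectable_fraction``)
    of the starting signal.
    """
    t, y = _coerce_trace(trace)
    if t[-1] - t[0] < window:
        raise ValueError(
            f"trace spans {t[-1] - t[0]:.3g} s but a {window:.3g} s window was requested"
        )
    fit = fit_single_exponential((t, y), n_boot=n_boot, seed=seed, direction="decay")
    # fitted signal at the start and end of the observed window
    s_start = fit.baseline + fit.amplitude * np.exp(-fit.rate * t[0])
    s_end = fit.baseline + fit.amplitude * np.exp(-fit.rate * (t[0] + window))
    if s_start <= 0:
        s_start = max(float(np.mean(y)), 1e-12)
    frac = max(min_detectable_fraction, 3.0 * fit.rmse / s_start)
    frac = min(frac, 0.999)
    bound = float(-np.log(1.0 - frac) / window)
    # measurable decay: the fitted drop over the observed window is itself
    # detectable and the rate CI excludes the detection bound
    drop = (s_start - s_end) / s_start
    measurable = fit.kind != "flat" and drop >= frac and fit.rate_ci[0] > bound
    return DissociationResult(
        k_off=fit.rate, rate_ci=fit.rate_ci, measurable=measurable,
        upper_bound=bound if not measurable else fit.rate,
    )
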