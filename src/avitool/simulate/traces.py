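"""Binding/incorporation kinetics trace simulators.

Three regimes are modelled:

* pseudo-first-order association of a reporting substrate to polonies,
  ``S(t) = s_max * (1 - exp(-k_on * c * t))``;
* dissociation during wash/imaging, ``S(t) = s0 * exp(-k_off * t)`` —
  ``k_off = 0`` is the multivalent (avidite) regime of persistent signal,
  large ``k_off`` the monovalent fast-off regime;
* quench-flow nucleotide incorporation, product fraction
  ``F(t) = 1 - exp(-k_obs t)`` with ``k_obs = k_pol * c / (K_d,app + c)``.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "KineticTrace",
    "KineticTraceSet",
    "simulate_association_trace",
    "simulate_dissociation_trace",
    "simulate_quench_flow",
]


@dataclass(frozen=True)
class KineticTrace:
    """A single (time, signal) series with its condition metadata."""

    time: np.ndarray
    signal: np.ndarray
    concentration: float | None = None  # molar-scale units, label only
    condition: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "signal", s)
        if t.ndim != 1 or t.shape != s.shape:
            raise ValueError("time and signal must be 1-D arrays of equal length")
        if len(t) >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(s)):
            raise ValueError("signals must be finite")


@dataclass(frozen=True)
class KineticTraceSet:
    traces: tuple[KineticTrace, ...]
    kind: str  # "association" | "dissociation" | "quench_flow"

    def __iter__(self):
        return iter(self.traces)

    def __len__(self) -> int:
        return len(self.traces)


def _grid(t_grid: Sequence[float]) -> np.ndarray:
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or len(t) < 2:
        raise ValueError("t_grid must be a 1-D array with >= 2 points")
    if not np.all(np.diff(t) > 0):
        raise ValueError("t_grid must be strictly increasing")
    return t


def simulate_association_trace(
    k_on: float,
    conc: float,
    t_grid: Sequence[float],
    s_max: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> KineticTraceSet:
    """Pseudo-first-order binding rise with ``k_obs = k_on * conc``."""
    if k_on <= 0 or conc <= 0:
        raise ValueError("k_on and conc must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    t = _grid(t_grid)
    rng = np.random.default_rng(seed)
    s = s_max * (1.0 - np.exp(-k_on * conc * t))
    if noise_sd > 0:
        s = s + rng.normal(0.0, noise_sd, size=t.shape)
    trace = KineticTrace(time=t, signal=s, concentration=conc, condition="association")
    return KineticTraceSet(traces=(trace,), kind="association")


def simulate_dissociation_trace(
    k_off: float,
    t_grid: Sequence[float],
    s0: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> KineticTraceSet:
    """Exponential signal decay; ``k_off = 0`` gives avidite-like persistence."""
    if k_off < 0:
        raise ValueError("k_off must be >= 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    t = _grid(t_grid)
    rng = np.random.default_rng(seed)
    s = s0 * np.exp(-k_off * t)
    if noise_sd > 0:
        s = s + rng.normal(0.0, noise_sd, size=t.shape)
    condition = "avidite" if k_off == 0 else "monovalent"
    trace = KineticTrace(time=t, signal=s, condition=condition)
    return KineticTraceSet(traces=(trace,), kind="dissociation")


def simulate_quench_flow(
    k_pol: float,
    kd_app: float,
    concs: Sequence[float],
    t_grid: Sequence[float] | None = None,
    noise_frac: float = 0.0,
    seed: int = 0,
    points_per_trace: int = 25,
) -> KineticTraceSet:
    """Quench-flow product-formation time series across substrate concentrations.

    Per concentration ``c``, the product fraction follows a single exponential
    with ``k_obs = k_pol * c / (kd_app + c)``.  Noise is multiplicative
    Gaussian with fractional standard deviation ``noise_frac``.  If ``t_grid``
    is None, each trace gets its own grid covering ~6 characteristic times of
    its expected rate.
    """
    if k_pol <= 0 or kd_app <= 0:
        raise ValueError("k_pol and kd_app must be > 0")
    concs = np.asarray(concs, dtype=float)
    if concs.ndim != 1 or len(concs) == 0 or np.any(concs <= 0):
        raise ValueError("concs must be positive")
    if noise_frac < 0:
        raise ValueError("noise_frac must be >= 0")
    rng = np.random.default_rng(seed)
    traces = []
    for c in concs:
        k_obs = k_pol * c / (kd_app + c)
        if t_grid is None:
            t = np.linspace(0.0, 6.0 / k_obs, points_per_trace)[1:]
        else:
            t = _grid(t_grid)
        f = 1.0 - np.exp(-k_obs * t)
        if noise_frac > 0:
            f = f * (1.0 + rng.normal(0.0, noise_frac, size=t.shape))
        traces.append(
            KineticTrace(time=t, signal=f, concentration=float(c), condition="quench_flow")
        )
    return KineticTraceSet(traces=tuple(traces), kind="quench_flow")
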