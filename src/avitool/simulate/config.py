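"""Simulator configuration."""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = ["SimConfig", "DEFAULT_CROSSTALK"]

# Mild spectral bleed-through between neighbouring dye channels; rows are
# observed channels, columns are pure (dye) channels, diagonally dominant and
# comfortably invertible.
DEFAULT_CROSSTALK = np.array(
    [
        [0.88, 0.07, 0.02, 0.01],
        [0.08, 0.86, 0.06, 0.02],
        [0.02, 0.05, 0.87, 0.08],
        [0.02, 0.02, 0.05, 0.89],
    ]
)


@dataclass
class SimConfig:
    """Knobs of the polony intensity simulator.

    Attributes
    ----------
    n_polonies, read_length
        Number of polonies and imaging cycles.
    p_lag, p_lead
        Per-cycle phasing (no advance) and prephasing (double advance)
        probabilities; run-level scalars.
    crosstalk
        4x4 spectral mixing matrix applied to pure channel signals.
    brightness_cv
        Coefficient of variation of per-polony brightness (lognormal,
        mean 1).
    noise_sd
        Additive Gaussian noise standard deviation on observed intensities.
    signal_decay_per_cycle
        Multiplicative per-cycle intensity decay factor in (0, 1].
    seed
        RNG seed; every stochastic draw derives from it.
    """

    n_polonies: int = 1000
    read_length: int = 150
    p_lag: float = 0.005
    p_lead: float = 0.002
    crosstalk: np.ndarray = field(default_factory=lambda: DEFAULT_CROSSTALK.copy())
    brightness_cv: float = 0.15
    noise_sd: float = 0.02
    signal_decay_per_cycle: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.crosstalk = np.asarray(self.crosstalk, dtype=float)
        if self.n_polonies < 1:
            raise ValueError("n_polonies must be >= 1")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if not (0.0 <= self.p_lag < 1.0 and 0.0 <= self.p_lead < 1.0):
            raise ValueError("p_lag and p_lead must be in [0, 1)")
        if self.p_lag + self.p_lead >= 1.0:
            raise ValueError("p_lag + p_lead must be < 1")
        if self.crosstalk.shape != (4, 4):
            raise ValueError("crosstalk must be a 4x4 matrix")
        if abs(np.linalg.det(self.crosstalk)) < 1e-12:
            raise ValueError("crosstalk matrix is singular")
        if self.brightness_cv < 0:
            raise ValueError("brightness_cv must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0.0 < self.signal_decay_per_cycle <= 1.0):
            raise ValueError("signal_decay_per_cycle must be in (0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["crosstalk"] = self.crosstalk.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown SimConfig keys: {sorted(unknown)}")
        return cls(**d)
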