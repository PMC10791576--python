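"""Primary-analysis base calling.

The pipeline inverts the two instrument distortions of the pure per-channel
signal — spectral cross-talk between dye channels and phasing/prephasing
blur across cycles — then normalizes channels onto a common scale and calls
the base with the highest normalized intensity in each cycle.

Cross-talk is removed by solving the 4x4 mixing system per polony per cycle.
Phasing is removed by solving, per polony per channel, the cycles x cycles
linear system given by the explicit strand-state distribution matrix of the
trinomial advance model; in the noiseless case this is the exact inverse of
the simulator's forward model (up to truncation when templates extend past
the last cycle).  The run-level lag/lead probabilities are estimated by a
grid search maximizing the mean clarity of the corrected signal.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .simulate.intensities import IntensityTensor
from .simulate.phasing import phasing_state_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "CrosstalkMatrix",
    "PhasingEstimate",
    "CorrectedIntensities",
    "BaseCallResult",
    "correct_crosstalk",
    "estimate_phasing",
    "correct_phasing",
    "normalize",
    "call_bases",
    "run_pipeline",
    "default_phasing_grid",
]

COND_WARN_THRESHOLD = 1e3


@dataclass(frozen=True)
class CrosstalkMatrix:
    """4x4 spectral mixing matrix (observed = matrix . pure)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.shape != (4, 4):
            raise ValueError("crosstalk matrix must be 4x4")
        cond = self.condition_number
        if not np.isfinite(cond) or abs(np.linalg.det(m)) < 1e-12:
            raise ValueError(f"crosstalk matrix is singular (condition number {cond:.3g})")
        if cond > COND_WARN_THRESHOLD:
            logger.warning("crosstalk matrix poorly conditioned (cond=%.3g)", cond)

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix))


@dataclass(frozen=True)
class PhasingEstimate:
    p_lag: float
    p_lead: float
    objective: float = float("nan")

    def __post_init__(self) -> None:
        if self.p_lag < 0 or self.p_lead < 0 or self.p_lag + self.p_lead >= 1:
            raise ValueError("invalid phasing estimate")

    @property
    def phasing_sum(self) -> float:
        return self.p_lag + self.p_lead


@dataclass(frozen=True)
class CorrectedIntensities:
    """Intensities after (some of) cross-talk inversion, phasing deconvolution
    and normalization; ``stages`` records provenance."""

    values: np.ndarray  # (n_polonies, cycles, 4)
    stages: tuple[str, ...] = ()

    @property
    def n_polonies(self) -> int:
        return self.values.shape[0]

    @property
    def cycles(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class BaseCallResult:
    calls: np.ndarray      # (n_polonies, cycles) uint8 channel indices
    tie_flags: np.ndarray  # (n_polonies, cycles) bool

    def to_strings(self) -> list[str]:
        lut = np.frombuffer("ACGT".encode(), dtype=np.uint8)
        return [bytes(lut[row]).decode("ascii") for row in self.calls]


def correct_crosstalk(raw: IntensityTensor, m: CrosstalkMatrix | np.ndarray) -> IntensityTensor:
    """Invert spectral mixing: solve m . x = y per polony per cycle.

    Negative components are clamped to zero after the solve (the linear
    algebra stays exact; clamping is cosmetic for downstream stages).
    """
    if not isinstance(m, CrosstalkMatrix):
        m = CrosstalkMatrix(matrix=m)
    y = raw.values.reshape(-1, 4).T  # (4, n*T)
    x = np.linalg.solve(m.matrix, y).T.reshape(raw.values.shape)
    n_clamped = int((x < 0).sum())
    if n_clamped:
        logger.info("crosstalk inversion clamped %d negative components", n_clamped)
    np.clip(x, 0.0, None, out=x)
    return IntensityTensor(values=x, channel_order=raw.channel_order)


def default_phasing_grid(p_max: float = 0.02, step: float = 5e-4) -> np.ndarray:
    return np.arange(0.0, p_max + step / 2, step)


def _clarity_mean(values: np.ndarray) -> float:
    """Mean (A+1)/(B+1) over calls.

    A is the highest channel value; B is the second-highest *magnitude*, so
    that over-deconvolution (which drives off-channels negative) lowers the
    score instead of being rewarded by clipping.
    """
    a = values.max(axis=-1)
    mag = np.abs(values)
    part = np.partition(mag, 2, axis=-1)
    b = np.minimum(part[..., 2], a)  # second-highest magnitude, at most A
    return float(np.mean((a + 1.0) / (b + 1.0)))


def estimate_phasing(
    tensor: IntensityTensor,
    grid: np.ndarray | None = None,
    max_polonies: int = 100,
) -> PhasingEstimate:
    """Grid search for (p_lag, p_lead) maximizing post-correction clarity.

    Deterministic given the tensor and grid: the polony subsample is taken at
    evenly spaced indices, and grid ties resolve to the first (smallest
    lag, then lead) candidate.
    """
    if tensor.cycles < 2:
        raise ValueError("need at least 2 cycles to estimate phasing")
    if grid is None:
        grid = default_phasing_grid()
    grid = np.asarray(grid, dtype=float)
    n = tensor.n_polonies
    idx = np.linspace(0, n - 1, min(max_polonies, n)).astype(int)
    sub = tensor.values[np.unique(idx)]
    scale = np.median(sub.max(axis=-1))
    if scale <= 0:
        raise ValueError("degenerate intensity tensor (no signal)")
    sub = sub / scale
    T = tensor.cycles
    # per-(polony, channel) signal-over-cycles vectors as columns
    y = sub.transpose(1, 0, 2).reshape(T, -1)

    best = (-np.inf, 0.0, 0.0)
    for p_lag in grid:
        for p_lead in grid:
            if p_lag + p_lead >= 1.0:
                continue
            if p_lag == 0.0 and p_lead == 0.0:
                x = y
            else:
                P = phasing_state_matrix(p_lag, p_lead, T, n_positions=T).matrix
                x = np.linalg.solve(P, y)
            vals = x.reshape(T, sub.shape[0], 4).transpose(1, 0, 2)
            score = _clarity_mean(vals)
            if score > best[0] + 1e-12:
                best = (score, float(p_lag), float(p_lead))
    return PhasingEstimate(p_lag=best[1], p_lead=best[2], objective=best[0])


def correct_phasing(
    tensor: IntensityTensor,
    est: PhasingEstimate,
    cond_threshold: float = 1e8,
    ridge: float = 1e-6,
) -> IntensityTensor:
    """Deconvolve phasing blur by solving the truncated state-matrix system.

    Falls back to a ridge-regularized solve when the truncated system is
    ill-conditioned (logged).
    """
    T = tensor.cycles
    if est.p_lag == 0.0 and est.p_lead == 0.0:
        return IntensityTensor(values=tensor.values.copy(), channel_order=tensor.channel_order)
    P = phasing_state_matrix(est.p_lag, est.p_lead, T, n_positions=T).matrix
    y = tensor.values.transpose(1, 0, 2).reshape(T, -1)
    cond = np.linalg.cond(P)
    if cond > cond_threshold:
        lam = ridge * np.trace(P.T @ P) / T
        logger.warning(
            "phasing system ill-conditioned (cond=%.3g); ridge solve with lambda=%.3g",
            cond, lam,
        )
        x = np.linalg.solve(P.T @ P + lam * np.eye(T), P.T @ y)
    else:
        x = np.linalg.solve(P, y)
    values = x.reshape(T, tensor.n_polonies, 4).transpose(1, 0, 2)
    return IntensityTensor(values=values, channel_order=tensor.channel_order)


def normalize(
    tensor: IntensityTensor,
    low_pct: float = 5.0,
    high_pct: float = 95.0,
) -> CorrectedIntensities:
    """Per channel per cycle, map the low percentile of all values to 0 and
    the high percentile of on-state values (where the channel is the
    per-polony maximum) to 1.

    The affine map is invariant to per-channel scaling of the input.
    """
    v = tensor.values
    n, T, C = v.shape
    out = np.empty_like(v, dtype=float)
    argmax = v.argmax(axis=-1)  # (n, T)
    for t in range(T):
        for c in range(C):
            col = v[:, t, c]
            uniq = np.unique(col)
            if len(uniq) < 2:
                raise ValueError(
                    f"cannot normalize: channel {c} at cycle {t} has fewer than "
                    "2 distinct values"
                )
            lo = np.percentile(col, low_pct)
            on = col[argmax[:, t] == c]
            hi = np.percentile(on, high_pct) if len(on) else np.percentile(col, high_pct)
            if hi - lo <= 0:
                raise ValueError(
                    f"cannot normalize: degenerate percentile range in channel {c} "
                    f"at cycle {t}"
                )
            out[:, t, c] = (col - lo) / (hi - lo)
    return CorrectedIntensities(values=out, stages=("normalized",))


def call_bases(ci: CorrectedIntensities, tie_tol: float = 1e-8) -> BaseCallResult:
    """Argmax base call per polony per cycle; ties (top two within
    ``tie_tol``) resolve to the lowest channel index and are flagged."""
    v = ci.values
    if not np.all(np.isfinite(v)):
        raise ValueError("corrected intensities contain non-finite values")
    calls = v.argmax(axis=-1).astype(np.uint8)
    part = np.partition(v, 2, axis=-1)
    ties = (part[..., 3] - part[..., 2]) <= tie_tol
    return BaseCallResult(calls=calls, tie_flags=ties)


def run_pipeline(
    raw: IntensityTensor,
    m: CrosstalkMatrix | np.ndarray,
    grid: np.ndarray | None = None,
    phasing: PhasingEstimate | None = None,
) -> tuple[BaseCallResult, CorrectedIntensities, PhasingEstimate]:
    """correct_crosstalk -> estimate/correct phasing -> normalize -> call."""
    ct = correct_crosstalk(raw, m)
    est = phasing if phasing is not None else estimate_phasing(ct, grid=grid)
    logger.info("phasing estimate: lag=%.4g lead=%.4g", est.p_lag, est.p_lead)
    ph = correct_phasing(ct, est)
    ci = normalize(ph)
    ci = CorrectedIntensities(
        values=ci.values, stages=("crosstalk", "phasing", "normalized")
    )
    result = call_bases(ci)
    logger.info(
        "called %d polonies x %d cycles (%d tie-flagged calls)",
        result.calls.shape[0], result.calls.shape[1], int(result.tie_flags.sum()),
    )
    return result, ci, est
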