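"""Empirical phred quality tables.

Quality scores follow the standard definition Q = -10*log10(p) with p the
probability that a base call is wrong, encoded phred+33 in FASTQ.  Q is
predicted per call from four predictors of call confidence:

1. maximum normalized intensity of the polony across channels;
2. clarity, (A+1)/(B+1) with A and B the highest and second-highest channel
   intensities;
3. the run-level sum of phasing and prephasing estimates;
4. cohort clarity: per cycle, the median clarity of the 10% lowest-maximum-
   intensity polonies (a field-level difficulty indicator shared by all
   polonies of the cycle).

The table is trained on calls with known truth: predictor space is cut into
equal-frequency bins, the per-bin empirical error rate is smoothed with
(errors+1)/(total+2) pseudocounts, sparse bins are pooled with neighbours
along the clarity axis, rates are made monotone non-increasing in clarity by
weighted isotonic regression, and Q is capped (default 45).
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .basecall import CorrectedIntensities, PhasingEstimate

logger = logging.getLogger(__name__)

__all__ = [
    "Predictors",
    "QualityTable",
    "CalibrationTable",
    "compute_predictors",
    "train_quality_table",
    "assign_quality",
    "assess_calibration",
    "summarize_q_fractions",
    "q_to_error_prob",
    "error_prob_to_q",
    "encode_phred33",
    "decode_phred33",
]

PREDICTOR_NAMES = ("max_intensity", "clarity", "phasing_sum", "cohort_clarity")
DEFAULT_BINS = (8, 12, 4, 4)
Q_FLOOR = 2


def q_to_error_prob(q: float | np.ndarray) -> float | np.ndarray:
    return 10.0 ** (-np.asarray(q, dtype=float) / 10.0)


def error_prob_to_q(p: float | np.ndarray) -> float | np.ndarray:
    return -10.0 * np.log10(np.asarray(p, dtype=float))


def encode_phred33(q: np.ndarray | list[int]) -> str:
    q = np.asarray(q, dtype=int)
    if q.min() < 0 or q.max() > 93:
        raise ValueError("phred+33 requires Q in [0, 93]")
    return bytes((q + 33).astype(np.uint8)).decode("ascii")


def decode_phred33(s: str) -> np.ndarray:
    arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8).astype(int) - 33
    if arr.min() < 0:
        raise ValueError("quality string contains characters below '!'")
    return arr


@dataclass(frozen=True)
class Predictors:
    """Per-call predictor arrays, all shaped (n_polonies, cycles)."""

    max_intensity: np.ndarray
    clarity: np.ndarray
    phasing_sum: np.ndarray
    cohort_clarity: np.ndarray

    def stacked(self) -> np.ndarray:
        """(n_calls, 4) matrix in PREDICTOR_NAMES order, row-major by read."""
        return np.stack(
            [
                self.max_intensity.ravel(),
                self.clarity.ravel(),
                self.phasing_sum.ravel(),
                self.cohort_clarity.ravel(),
            ],
            axis=1,
        )

    @property
    def shape(self) -> tuple[int, int]:
        return self.max_intensity.shape


def compute_predictors(
    ci: CorrectedIntensities, est: PhasingEstimate, cohort_fraction: float = 0.10
) -> Predictors:
    """Compute the four per-call quality predictors from normalized
    intensities and the run-level phasing estimate."""
    v = ci.values
    n, T, _ = v.shape
    part = np.partition(v, 2, axis=-1)
    a = part[..., 3]
    b = part[..., 2]
    clarity = (a + 1.0) / (b + 1.0)
    max_intensity = a

    k = max(1, int(np.ceil(cohort_fraction * n)))
    cohort = np.empty(T)
    for t in range(T):
        lowest = np.argpartition(max_intensity[:, t], k - 1)[:k]
        cohort[t] = np.median(clarity[lowest, t])
    return Predictors(
        max_intensity=max_intensity,
        clarity=clarity,
        phasing_sum=np.full((n, T), est.phasing_sum),
        cohort_clarity=np.broadcast_to(cohort, (n, T)).copy(),
    )


def _quantile_edges(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Interior bin edges from equal-frequency quantiles (duplicates dropped)."""
    qs = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.unique(qs)


def _pava_nonincreasing(rates: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted pool-adjacent-violators for a non-increasing fit."""
    # fit non-decreasing on the reversed sequence
    r = rates[::-1].astype(float)
    w = weights[::-1].astype(float)
    vals: list[float] = []
    wts: list[float] = []
    counts: list[int] = []
    for ri, wi in zip(r, w):
        vals.append(ri)
        wts.append(wi)
        counts.append(1)
        while len(vals) > 1 and vals[-2] > vals[-1]:
            v2 = (vals[-2] * wts[-2] + vals[-1] * wts[-1]) / (wts[-2] + wts[-1])
            w2 = wts[-2] + wts[-1]
            c2 = counts[-2] + counts[-1]
            vals[-2:] = [v2]
            wts[-2:] = [w2]
            counts[-2:] = [c2]
    out = np.concatenate([np.full(c, v) for v, c in zip(vals, counts)])
    return out[::-1]


@dataclass
class QualityTable:
    """Binned predictor space -> empirical phred Q, with observation counts."""

    edges: list[np.ndarray]          # interior edges per predictor
    errors: np.ndarray               # per-bin raw error counts
    totals: np.ndarray               # per-bin raw call counts
    rates: np.ndarray                # smoothed (pooled, isotonic) error rates
    q: np.ndarray                    # integer Q per bin, in [Q_FLOOR, q_cap]
    q_cap: int = 45
    pseudo_errors: float = 1.0
    pseudo_total: float = 2.0

    CLARITY_AXIS = 1

    @property
    def shape(self) -> tuple[int, ...]:
        return self.totals.shape

    def bin_indices(self, predictors: Predictors | np.ndarray) -> tuple[np.ndarray, ...]:
        x = predictors.stacked() if isinstance(predictors, Predictors) else np.asarray(predictors)
        idx = []
        for d in range(4):
            i = np.digitize(x[:, d], self.edges[d])
            idx.append(np.clip(i, 0, self.shape[d] - 1))
        return tuple(idx)

    def to_dict(self) -> dict:
        return {
            "format_version": 1,
            "predictors": list(PREDICTOR_NAMES),
            "edges": [e.tolist() for e in self.edges],
            "errors": self.errors.tolist(),
            "totals": self.totals.tolist(),
            "rates": self.rates.tolist(),
            "q": self.q.tolist(),
            "q_cap": self.q_cap,
            "pseudo_errors": self.pseudo_errors,
            "pseudo_total": self.pseudo_total,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "QualityTable":
        return cls(
            edges=[np.asarray(e, dtype=float) for e in d["edges"]],
            errors=np.asarray(d["errors"]),
            totals=np.asarray(d["totals"]),
            rates=np.asarray(d["rates"]),
            q=np.asarray(d["q"]),
            q_cap=int(d["q_cap"]),
            pseudo_errors=float(d["pseudo_errors"]),
            pseudo_total=float(d["pseudo_total"]),
        )

    @classmethod
    def load(cls, path: str | Path) -> "QualityTable":
        return cls.from_dict(json.loads(Path(path).read_text()))


def train_quality_table(
    predictors: Predictors | np.ndarray,
    truth_errors: np.ndarray,
    bins_per_predictor: tuple[int, int, int, int] = DEFAULT_BINS,
    min_bin_count: int = 200,
    q_cap: int = 45,
) -> QualityTable:
    """Train an empirical quality table from calls with known truth labels.

    ``truth_errors`` is a boolean array (1 = miscall) aligned 1:1 with the
    predictor vectors.
    """
    x = predictors.stacked() if isinstance(predictors, Predictors) else np.asarray(predictors)
    err = np.asarray(truth_errors, dtype=bool).ravel()
    if x.ndim != 2 or x.shape[1] != 4:
        raise ValueError("predictors must stack to an (n_calls, 4) matrix")
    if len(err) != x.shape[0]:
        raise ValueError(
            f"{len(err)} truth labels for {x.shape[0]} predictor vectors"
        )
    if x.shape[0] == 0:
        raise ValueError("empty training set")

    edges = [_quantile_edges(x[:, d], nb) for d, nb in enumerate(bins_per_predictor)]
    shape = tuple(len(e) + 1 for e in edges)
    idx = tuple(
        np.clip(np.digitize(x[:, d], edges[d]), 0, shape[d] - 1) for d in range(4)
    )
    flat = np.ravel_multi_index(idx, shape)
    size = int(np.prod(shape))
    totals = np.bincount(flat, minlength=size).reshape(shape)
    errors = np.bincount(flat, weights=err.astype(float), minlength=size).reshape(shape)

    # pool sparse bins with adjacent bins along the clarity axis, then smooth
    nb_cl = shape[QualityTable.CLARITY_AXIS]
    ax = QualityTable.CLARITY_AXIS
    err_m = np.moveaxis(errors, ax, -1).reshape(-1, nb_cl)
    tot_m = np.moveaxis(totals, ax, -1).reshape(-1, nb_cl)
    rates = np.empty_like(err_m, dtype=float)
    for row in range(err_m.shape[0]):
        e_row, t_row = err_m[row], tot_m[row]
        pooled_e, pooled_t = _pool_sparse(e_row, t_row, min_bin_count)
        r = (pooled_e + 1.0) / (pooled_t + 2.0)
        rates[row] = _pava_nonincreasing(r, pooled_t + 2.0)
    rates = np.moveaxis(rates.reshape(np.moveaxis(totals, ax, -1).shape), -1, ax)

    q_real = -10.0 * np.log10(rates)
    q = np.clip(np.round(q_real), Q_FLOOR, q_cap).astype(int)
    return QualityTable(
        edges=edges, errors=errors, totals=totals, rates=rates, q=q, q_cap=q_cap
    )


def _pool_sparse(
    errors: np.ndarray, totals: np.ndarray, min_count: int
) -> tuple[np.ndarray, np.ndarray]:
    """Pool adjacent clarity bins until each pooled group has >= min_count
    observations (or the whole axis is one group); members share the pooled
    counts."""
    n = len(totals)
    groups: list[list[int]] = []
    current: list[int] = []
    acc = 0.0
    for i in range(n):
        current.append(i)
        acc += totals[i]
        if acc >= min_count:
            groups.append(current)
            current, acc = [], 0.0
    if current:
        if groups:
            groups[-1].extend(current)
        else:
            groups.append(current)
    out_e = np.empty(n)
    out_t = np.empty(n)
    for g in groups:
        ge = errors[g].sum()
        gt = totals[g].sum()
        out_e[g] = ge
        out_t[g] = gt
    return out_e, out_t


def assign_quality(
    predictors: Predictors | np.ndarray, table: QualityTable
) -> np.ndarray:
    """Look up integer Q per call; out-of-range predictor values clamp to
    edge bins.  Returns an array shaped like the per-call predictor layout
    ((n_polonies, cycles) for Predictors input, (n_calls,) otherwise)."""
    idx = table.bin_indices(predictors)
    q = table.q[idx]
    n_empty = int((table.totals[idx] == 0).sum())
    if n_empty:
        logger.info("%d calls fell in empty bins; pooled-rate Q used", n_empty)
    if isinstance(predictors, Predictors):
        return q.reshape(predictors.shape)
    return q


def reads_to_fastq_quality(q: np.ndarray) -> list[str]:
    """Phred+33 quality strings, one per polony (row)."""
    return [encode_phred33(row) for row in np.atleast_2d(q)]


@dataclass(frozen=True)
class CalibrationTable:
    """Predicted-vs-observed Q, the diagonal-plot substrate."""

    table: pd.DataFrame  # columns: predicted_q, observed_q, n, errors

    def max_abs_deviation(self, min_n: int = 0) -> float:
        t = self.table[self.table["n"] >= min_n]
        return float((t["predicted_q"] - t["observed_q"]).abs().max())


def assess_calibration(
    assigned_q: np.ndarray,
    truth_errors: np.ndarray,
    min_count: int = 100,
) -> CalibrationTable:
    """Group calls by predicted Q and compare with the mismatch-derived
    observed Q.  Zero-error groups report the resolution-limited lower bound
    -10*log10(1/(n+1)).  Groups under ``min_count`` calls are dropped."""
    q = np.asarray(assigned_q).ravel()
    err = np.asarray(truth_errors, dtype=bool).ravel()
    if len(q) != len(err):
        raise ValueError("assigned_q and truth_errors must align 1:1")
    rows = []
    for qv in np.unique(q):
        sel = q == qv
        n = int(sel.sum())
        if n < min_count:
            continue
        e = int(err[sel].sum())
        p = e / n if e > 0 else 1.0 / (n + 1)
        rows.append((int(qv), float(-10.0 * np.log10(p)), n, e))
    return CalibrationTable(
        table=pd.DataFrame(rows, columns=["predicted_q", "observed_q", "n", "errors"])
    )


def summarize_q_fractions(
    assigned_q: np.ndarray, thresholds: tuple[int, ...] = (30, 40)
) -> dict[int, float]:
    """Fraction of calls with Q strictly above each threshold."""
    q = np.asarray(assigned_q).ravel()
    if len(q) == 0:
        raise ValueError("no calls")
    return {thr: float((q > thr).mean()) for thr in thresholds}
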