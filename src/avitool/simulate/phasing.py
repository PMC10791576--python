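"""Phasing / prephasing forward model.

Within a polony, individual strands can fail to advance during a sequencing
cycle ("phasing", lag) or advance twice ("prephasing", lead).  Over cycles
this spreads a polony's signal across neighbouring template positions.  The
model here is a per-cycle trinomial step: each strand independently advances
0 positions with probability ``p_lag``, 2 with probability ``p_lead`` and 1
otherwise.  The induced distribution over templating positions is what the
base caller later deconvolves.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["StateDistribution", "phasing_state_matrix", "simulate_strand_positions"]


@dataclass(frozen=True)
class StateDistribution:
    """Cycle x template-position distribution of strand states.

    ``matrix[t, j]`` is the fraction of strands whose templating position at
    imaging cycle ``t`` is ``j``.  Row 0 is unit mass at position 0; the
    support of row ``t`` lies in ``[0, 2t]``.
    """

    p_lag: float
    p_lead: float
    matrix: np.ndarray  # (cycles, n_positions)

    @property
    def cycles(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_positions(self) -> int:
        return self.matrix.shape[1]


def _validate_probs(p_lag: float, p_lead: float) -> None:
    if not (0.0 <= p_lag < 1.0):
        raise ValueError(f"p_lag must be in [0, 1), got {p_lag}")
    if not (0.0 <= p_lead < 1.0):
        raise ValueError(f"p_lead must be in [0, 1), got {p_lead}")
    if p_lag + p_lead >= 1.0:
        raise ValueError(f"p_lag + p_lead must be < 1, got {p_lag + p_lead}")


def phasing_state_matrix(
    p_lag: float,
    p_lead: float,
    cycles: int,
    n_positions: int | None = None,
) -> StateDistribution:
    """Forward recursion of the trinomial strand-advance model.

    Parameters
    ----------
    p_lag, p_lead
        Per-cycle probabilities of advancing 0 or 2 template positions.
    cycles
        Number of imaging cycles (rows).
    n_positions
        Number of template positions (columns).  Defaults to ``2*cycles - 1``,
        wide enough that no probability mass is truncated and every row sums
        to 1.  A narrower matrix (e.g. ``cycles`` columns, used by the base
        caller's deconvolution) silently drops the tail mass that leads push
        beyond the last column.
    """
    _validate_probs(p_lag, p_lead)
    if cycles < 1:
        raise ValueError("cycles must be >= 1")
    if n_positions is None:
        n_positions = 2 * cycles - 1
    p1 = 1.0 - p_lag - p_lead
    P = np.zeros((cycles, n_positions))
    P[0, 0] = 1.0
    for t in range(1, cycles):
        prev = P[t - 1]
        row = p_lag * prev.copy()
        row[1:] += p1 * prev[:-1]
        if n_positions >= 2:
            row[2:] += p_lead * prev[:-2]
        P[t] = row
    return StateDistribution(p_lag=p_lag, p_lead=p_lead, matrix=P)


def simulate_strand_positions(
    p_lag: float,
    p_lead: float,
    cycles: int,
    n_strands: int,
    seed: int,
) -> np.ndarray:
    """Monte-Carlo strand walk: the independent oracle for the recursion.

    Returns an ``(cycles, n_strands)`` integer array of templating positions.
    """
    _validate_probs(p_lag, p_lead)
    rng = np.random.default_rng(seed)
    pos = np.zeros(n_strands, dtype=np.int64)
    out = np.empty((cycles, n_strands), dtype=np.int64)
    out[0] = pos
    for t in range(1, cycles):
        u = rng.random(n_strands)
        step = np.ones(n_strands, dtype=np.int64)
        step[u < p_lag] = 0
        step[u >= 1.0 - p_lead] = 2
        pos = pos + step
        out[t] = pos
    return out
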