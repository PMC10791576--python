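"""Alignment-based error characterization.

Two procedures are implemented:

* Homopolymer three-segment analysis: each aligned read overlapping a
  homopolymer run is oriented 5'->3' (sequencing order) and split into the
  segment preceding the homopolymer, the segment overlapping it, and the
  segment following it.  Substitution rates are compared between the pre and
  post segments, and all reads are stacked into a per-offset error matrix
  (offset 0 = the first templated base after the homopolymer's 3' end in
  read orientation).

* k-mer context mismatch analysis: for k in {1, 2, 3}, every window of k
  consecutive aligned reference positions fully covered by aligned,
  non-clipped, non-indel, non-masked read bases is an instance of its
  reference k-mer (reverse-complemented to read orientation for
  reverse-strand reads by default); the fraction of instances containing at
  least one mismatch is tabulated per context.

N-calls, soft-clipped bases and indel columns never contribute to any
numerator or denominator; known variant sites can be masked out entirely.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import pysam

from .io import read_bed

logger = logging.getLogger(__name__)

__all__ = [
    "HomopolymerInterval",
    "SegmentedRead",
    "FilterStats",
    "HomopolymerSummary",
    "KmerMismatchTable",
    "load_homopolymer_bed",
    "filter_reads",
    "segment_read",
    "homopolymer_error_summary",
    "SiteMask",
    "mask_known_sites",
    "MaskedReference",
    "kmer_mismatch_table",
    "compare_platforms",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class HomopolymerInterval:
    """A homopolymer run, slop-trimmed, 0-based half-open."""

    contig: str
    start: int
    end: int
    base: str | None = None
    name: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SegmentedRead:
    """An aligned read split into pre / overlap / post homopolymer segments.

    Counts are aligned (matched-column) bases and substitution mismatches per
    segment, in read 5'->3' orientation; boundaries are read coordinates
    (0-based, half-open ranges) in the same orientation.
    """

    read_id: str
    strand: str  # "+" | "-"
    pre_range: tuple[int, int]
    overlap_range: tuple[int, int]
    post_range: tuple[int, int]
    pre_aligned: int = 0
    pre_mismatch: int = 0
    overlap_aligned: int = 0
    overlap_mismatch: int = 0
    post_aligned: int = 0
    post_mismatch: int = 0
    # read-oriented offset -> (aligned, mismatch)
    offsets: dict[int, tuple[int, int]] = field(default_factory=dict)

    @property
    def total_aligned(self) -> int:
        return self.pre_aligned + self.overlap_aligned + self.post_aligned


@dataclass
class FilterStats:
    kept: int = 0
    secondary: int = 0
    supplementary: int = 0
    unmapped: int = 0
    mapq_zero: int = 0


def load_homopolymer_bed(
    path: str | Path,
    slop: int = 5,
    reference: dict[str, str] | None = None,
    min_length: int = 1,
) -> list[HomopolymerInterval]:
    """Load homopolymer intervals from a slopped BED file.

    ``slop`` bases are trimmed from each interval end to recover the exact
    run coordinates.  When a reference is supplied, each trimmed interval is
    validated to be a single-base run and annotated with its base.
    """
    if slop < 0:
        raise ValueError("slop must be >= 0")
    intervals = []
    for contig, start, end, name in read_bed(path):
        t_start, t_end = start + slop, end - slop
        if t_end <= t_start:
            logger.warning(
                "rejecting BED row %s:%d-%d (%s): empty after trimming slop %d",
                contig, start, end, name, slop,
            )
            continue
        base = None
        if reference is not None:
            if contig not in reference:
                raise KeyError(f"BED contig {contig!r} not in reference")
            run = reference[contig][t_start:t_end].upper()
            if len(set(run)) != 1:
                raise ValueError(
                    f"trimmed interval {contig}:{t_start}-{t_end} is not a "
                    f"single-base run: {run[:20]!r}..."
                )
            base = run[0]
        if t_end - t_start < min_length:
            continue
        intervals.append(
            HomopolymerInterval(contig=contig, start=t_start, end=t_end, base=base, name=name)
        )
    return intervals


def filter_reads(
    alignments: Iterable[pysam.AlignedSegment],
    stats: FilterStats | None = None,
) -> Iterator[pysam.AlignedSegment]:
    """Drop secondary, supplementary, unmapped and MAPQ-0 records."""
    for rec in alignments:
        if rec.is_unmapped:
            if stats:
                stats.unmapped += 1
            continue
        if rec.is_secondary:
            if stats:
                stats.secondary += 1
            continue
        if rec.is_supplementary:
            if stats:
                stats.supplementary += 1
            continue
        if rec.mapping_quality == 0:
            if stats:
                stats.mapq_zero += 1
            continue
        if stats:
            stats.kept += 1
        yield rec


def _aligned_columns(
    read: pysam.AlignedSegment,
    reference: dict[str, str],
    mask: "SiteMask | None" = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Matched columns of a read vs the reference.

    Returns (query_positions, reference_positions, is_mismatch) for columns
    where both query and reference positions exist (no indels, no clips),
    the query base is not N, the reference base is not N, and the reference
    position is not masked.
    """
    contig = read.reference_name
    if contig not in reference:
        raise KeyError(f"alignment contig {contig!r} not in reference")
    ref_seq = reference[contig]
    qseq = read.query_sequence
    if qseq is None:
        raise ValueError(f"read {read.query_name} has no sequence")
    pairs = read.get_aligned_pairs(matches_only=True)
    if not pairs:
        return (np.empty(0, int), np.empty(0, int), np.empty(0, bool))
    qpos = np.fromiter((p[0] for p in pairs), dtype=np.int64, count=len(pairs))
    rpos = np.fromiter((p[1] for p in pairs), dtype=np.int64, count=len(pairs))
    qarr = np.frombuffer(qseq.upper().encode("ascii"), dtype=np.uint8)
    rarr = np.frombuffer(ref_seq.encode("ascii"), dtype=np.uint8)
    qb = qarr[qpos]
    rb = rarr[rpos]
    keep = (qb != ord("N")) & (rb != ord("N"))
    if mask is not None:
        keep &= ~mask.is_masked(contig, rpos)
    qpos, rpos, qb, rb = qpos[keep], rpos[keep], qb[keep], rb[keep]
    return qpos, rpos, qb != rb


def segment_read(
    read: pysam.AlignedSegment,
    interval: HomopolymerInterval,
    reference: dict[str, str],
    mask: "SiteMask | None" = None,
    min_flank: int = 5,
) -> SegmentedRead | None:
    """Split one aligned read around a homopolymer and count mismatches.

    Segment membership uses the reference projection of each aligned column;
    reads are oriented 5'->3' so that for reverse-strand alignments the
    genomic right side of the homopolymer is the *pre* segment.  Returns None
    (read discarded) when the pre or post segment has fewer than
    ``min_flank`` aligned bases.
    """
    qpos, rpos, mm = _aligned_columns(read, reference, mask)
    if len(qpos) == 0:
        return None
    is_rev = read.is_reverse
    read_len = read.infer_read_length() or (max(qpos) + 1)
    # read coordinate in sequencing (5'->3') orientation
    cyc = (read_len - 1 - qpos) if is_rev else qpos

    before_g = rpos < interval.start    # genomic left of the run
    within = (rpos >= interval.start) & (rpos < interval.end)
    after_g = rpos >= interval.end      # genomic right of the run
    if is_rev:
        pre_sel, post_sel = after_g, before_g
    else:
        pre_sel, post_sel = before_g, after_g

    pre_n, post_n, ov_n = int(pre_sel.sum()), int(post_sel.sum()), int(within.sum())
    if ov_n == 0:
        return None
    if pre_n < min_flank or post_n < min_flank:
        return None

    def _range(sel: np.ndarray) -> tuple[int, int]:
        if not sel.any():
            return (0, 0)
        c = cyc[sel]
        return (int(c.min()), int(c.max()) + 1)

    # read-oriented offsets: 0 = first base after the run's 3' end
    offsets = np.empty(len(rpos), dtype=np.int64)
    if is_rev:
        offsets[after_g] = interval.end - 1 - rpos[after_g]   # negative, pre side
        offsets[within] = 0  # placeholder, excluded below
        offsets[before_g] = interval.start - 1 - rpos[before_g]  # >= 0, post side
    else:
        offsets[before_g] = rpos[before_g] - interval.start   # negative
        offsets[within] = 0
        offsets[after_g] = rpos[after_g] - interval.end       # >= 0
    offset_counts: dict[int, tuple[int, int]] = {}
    flank = pre_sel | post_sel
    for off, m in zip(offsets[flank], mm[flank]):
        a, e = offset_counts.get(int(off), (0, 0))
        offset_counts[int(off)] = (a + 1, e + int(m))

    return SegmentedRead(
        read_id=read.query_name,
        strand="-" if is_rev else "+",
        pre_range=_range(pre_sel),
        overlap_range=_range(within),
        post_range=_range(post_sel),
        pre_aligned=pre_n,
        pre_mismatch=int(mm[pre_sel].sum()),
        overlap_aligned=ov_n,
        overlap_mismatch=int(mm[within].sum()),
        post_aligned=post_n,
        post_mismatch=int(mm[post_sel].sum()),
        offsets=offset_counts,
    )


@dataclass
class HomopolymerSummary:
    """Aggregated pre/overlap/post mismatch rates and the per-offset matrix."""

    pre_aligned: int
    pre_mismatch: int
    overlap_aligned: int
    overlap_mismatch: int
    post_aligned: int
    post_mismatch: int
    offset_matrix: pd.DataFrame      # columns: offset, aligned, mismatch, error_rate
    per_interval: pd.DataFrame       # one row per interval with pre/post rates + diff
    n_reads_used: int
    n_reads_discarded: int
    filter_stats: FilterStats

    @property
    def pre_rate(self) -> float:
        return self.pre_mismatch / self.pre_aligned if self.pre_aligned else float("nan")

    @property
    def post_rate(self) -> float:
        return self.post_mismatch / self.post_aligned if self.post_aligned else float("nan")

    @property
    def overlap_rate(self) -> float:
        return (
            self.overlap_mismatch / self.overlap_aligned
            if self.overlap_aligned
            else float("nan")
        )


def homopolymer_error_summary(
    alignments: Iterable[pysam.AlignedSegment] | str | Path,
    intervals: Sequence[HomopolymerInterval],
    reference: dict[str, str],
    mask: "SiteMask | None" = None,
    min_flank: int = 5,
) -> HomopolymerSummary:
    """Aggregate three-segment analysis over all read x interval pairs.

    A read overlapping several homopolymers contributes once per interval.
    """
    if isinstance(alignments, (str, Path)):
        af = pysam.AlignmentFile(str(alignments), check_sq=False)
        alignments = af.fetch(until_eof=True)
    by_contig: dict[str, list[HomopolymerInterval]] = {}
    for iv in intervals:
        by_contig.setdefault(iv.contig, []).append(iv)

    stats = FilterStats()
    totals = {k: 0 for k in ("pre_a", "pre_m", "ov_a", "ov_m", "post_a", "post_m")}
    offset_counts: dict[int, list[int]] = {}
    per_interval: dict[int, list[int]] = {}
    interval_index = {id(iv): i for i, iv in enumerate(intervals)}
    used = discarded = 0

    for read in filter_reads(alignments, stats):
        ivs = by_contig.get(read.reference_name)
        if not ivs:
            continue
        rs, re = read.reference_start, read.reference_end
        for iv in ivs:
            if not (rs < iv.end and re > iv.start):
                continue
            seg = segment_read(read, iv, reference, mask=mask, min_flank=min_flank)
            if seg is None:
                discarded += 1
                continue
            used += 1
            totals["pre_a"] += seg.pre_aligned
            totals["pre_m"] += seg.pre_mismatch
            totals["ov_a"] += seg.overlap_aligned
            totals["ov_m"] += seg.overlap_mismatch
            totals["post_a"] += seg.post_aligned
            totals["post_m"] += seg.post_mismatch
            for off, (a, m) in seg.offsets.items():
                acc = offset_counts.setdefault(off, [0, 0])
                acc[0] += a
                acc[1] += m
            acc = per_interval.setdefault(interval_index[id(iv)], [0, 0, 0, 0])
            acc[0] += seg.pre_aligned
            acc[1] += seg.pre_mismatch
            acc[2] += seg.post_aligned
            acc[3] += seg.post_mismatch

    if used == 0:
        logger.warning("no qualifying reads overlapped any homopolymer interval")

    off_rows = []
    for off in sorted(offset_counts):
        a, m = offset_counts[off]
        off_rows.append((off, a, m, m / a if a else np.nan))
    offset_df = pd.DataFrame(off_rows, columns=["offset", "aligned", "mismatch", "error_rate"])

    iv_rows = []
    for idx in sorted(per_interval):
        iv = intervals[idx]
        pa, pm, qa, qm = per_interval[idx]
        pre_r = pm / pa if pa else np.nan
        post_r = qm / qa if qa else np.nan
        iv_rows.append(
            (iv.contig, iv.start, iv.end, iv.base, iv.length, pa, pm, qa, qm,
             pre_r, post_r, post_r - pre_r)
        )
    iv_df = pd.DataFrame(
        iv_rows,
        columns=[
            "contig", "start", "end", "base", "length",
            "pre_aligned", "pre_mismatch", "post_aligned", "post_mismatch",
            "pre_rate", "post_rate", "rate_diff",
        ],
    )

    return HomopolymerSummary(
        pre_aligned=totals["pre_a"],
        pre_mismatch=totals["pre_m"],
        overlap_aligned=totals["ov_a"],
        overlap_mismatch=totals["ov_m"],
        post_aligned=totals["post_a"],
        post_mismatch=totals["post_m"],
        offset_matrix=offset_df,
        per_interval=iv_df,
        n_reads_used=used,
        n_reads_discarded=discarded,
        filter_stats=stats,
    )


# -- known-variant masking ---------------------------------------------------


class SiteMask:
    """Per-contig boolean arrays of reference positions excluded from counting."""

    def __init__(self, reference: dict[str, str]):
        self._mask = {c: np.zeros(len(s), dtype=bool) for c, s in reference.items()}

    def add(self, contig: str, start: int, end: int) -> None:
        if contig not in self._mask:
            raise KeyError(f"mask contig {contig!r} not in reference")
        arr = self._mask[contig]
        if start < 0 or end > len(arr):
            raise ValueError(
                f"mask interval {contig}:{start}-{end} out of reference bounds (len {len(arr)})"
            )
        arr[start:end] = True

    def is_masked(self, contig: str, positions: np.ndarray) -> np.ndarray:
        arr = self._mask.get(contig)
        if arr is None:
            return np.zeros(len(positions), dtype=bool)
        return arr[positions]

    @property
    def n_masked(self) -> int:
        return int(sum(a.sum() for a in self._mask.values()))

    @classmethod
    def from_bed(cls, reference: dict[str, str], path: str | Path) -> "SiteMask":
        mask = cls(reference)
        for contig, start, end, _ in read_bed(path):
            mask.add(contig, start, end)
        return mask

    @classmethod
    def from_vcf(cls, reference: dict[str, str], path: str | Path) -> "SiteMask":
        mask = cls(reference)
        with pysam.VariantFile(str(path)) as vf:
            for rec in vf:
                mask.add(rec.chrom, rec.start, rec.start + len(rec.ref))
        return mask


@dataclass(frozen=True)
class MaskedReference:
    """A reference plus the sites excluded from all mismatch counting."""

    sequences: dict[str, str]
    mask: SiteMask


def mask_known_sites(
    reference: dict[str, str],
    sites: str | Path | Sequence[tuple[str, int, int]] | None,
) -> MaskedReference:
    """Build a variant-masked reference from a BED/VCF path or interval list."""
    if sites is None:
        return MaskedReference(sequences=reference, mask=SiteMask(reference))
    if isinstance(sites, (str, Path)):
        p = str(sites)
        if p.endswith((".vcf", ".vcf.gz", ".bcf")):
            mask = SiteMask.from_vcf(reference, p)
        else:
            mask = SiteMask.from_bed(reference, p)
    else:
        mask = SiteMask(reference)
        for contig, start, end in sites:
            mask.add(contig, start, end)
    return MaskedReference(sequences=reference, mask=mask)


# -- k-mer context analysis --------------------------------------------------


@dataclass
class KmerMismatchTable:
    """Per-context instance counts and mismatch percentages for one k."""

    k: int
    table: pd.DataFrame  # columns: kmer, instances, mismatching, pct

    def pct(self, kmer: str) -> float:
        row = self.table.loc[self.table["kmer"] == kmer]
        return float(row["pct"].iloc[0])


def _all_kmers(k: int) -> list[str]:
    return ["".join(p) for p in itertools.product("ACGT", repeat=k)]


def kmer_mismatch_table(
    alignments: Iterable[pysam.AlignedSegment] | str | Path,
    reference: dict[str, str] | MaskedReference,
    k: int,
    mask: SiteMask | None = None,
    read_oriented: bool = True,
    sample_fraction: float | None = None,
    seed: int = 0,
) -> KmerMismatchTable:
    """Tabulate the fraction of k-mer instances containing >= 1 mismatch.

    An instance is a window of k consecutive reference positions fully
    covered by matched (non-clip, non-indel, non-N, non-masked) read bases,
    keyed by the reference k-mer — reverse-complemented into read orientation
    for reverse-strand reads unless ``read_oriented`` is False.
    """
    if k not in (1, 2, 3):
        raise ValueError(f"k must be 1, 2 or 3, got {k}")
    if isinstance(reference, MaskedReference):
        mask = reference.mask if mask is None else mask
        reference = reference.sequences
    if isinstance(alignments, (str, Path)):
        af = pysam.AlignmentFile(str(alignments), check_sq=False)
        alignments = af.fetch(until_eof=True)
    rng = np.random.default_rng(seed)

    kmers = _all_kmers(k)
    kmer_index = {m: i for i, m in enumerate(kmers)}
    instances = np.zeros(4**k, dtype=np.int64)
    mismatching = np.zeros(4**k, dtype=np.int64)

    for read in filter_reads(alignments):
        if sample_fraction is not None and rng.random() >= sample_fraction:
            continue
        qpos, rpos, mm = _aligned_columns(read, reference, mask)
        if len(rpos) < k:
            continue
        ref_seq = reference[read.reference_name]
        # maximal runs of columns consecutive in both read and reference
        brk = np.flatnonzero((np.diff(rpos) != 1) | (np.diff(qpos) != 1)) + 1
        starts = np.concatenate(([0], brk))
        ends = np.concatenate((brk, [len(rpos)]))
        for s, e in zip(starts, ends):
            if e - s < k:
                continue
            run_r = rpos[s:e]
            run_mm = mm[s:e]
            # windows of k consecutive positions
            if k == 1:
                win_mm = run_mm
                win_start = run_r
            else:
                win_mm = run_mm[: 1 - k].copy()
                for d in range(1, k):
                    win_mm |= run_mm[d : len(run_mm) - (k - 1) + d]
                win_start = run_r[: 1 - k]
            for r0, bad in zip(win_start, win_mm):
                mer = ref_seq[r0 : r0 + k]
                if read.is_reverse and read_oriented:
                    mer = revcomp(mer)
                idx = kmer_index.get(mer)
                if idx is None:  # ambiguity codes in reference
                    continue
                instances[idx] += 1
                mismatching[idx] += int(bad)

    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(instances > 0, 100.0 * mismatching / np.maximum(instances, 1), np.nan)
    df = pd.DataFrame(
        {"kmer": kmers, "instances": instances, "mismatching": mismatching, "pct": pct}
    )
    return KmerMismatchTable(k=k, table=df)


def compare_platforms(tables: Sequence[KmerMismatchTable]) -> dict:
    """Count contexts where the first table has strictly lowest mismatch pct.

    Returns {"k": k, "wins": n, "ties": n, "losses": n, "total": 4^k}.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 tables to compare")
    k = tables[0].k
    base = tables[0].table.set_index("kmer")["pct"]
    others = []
    for t in tables[1:]:
        if t.k != k or list(t.table["kmer"]) != list(tables[0].table["kmer"]):
            raise ValueError("tables cover different k-mer sets")
        others.append(t.table.set_index("kmer")["pct"])
    other_min = pd.concat(others, axis=1).min(axis=1)
    wins = int((base < other_min).sum())
    ties = int((base == other_min).sum())
    losses = int((base > other_min).sum())
    return {"k": k, "wins": wins, "ties": ties, "losses": losses, "total": 4**k}
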