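"""Ground-truthed alignment fixtures for the error profilers.

Builds a synthetic reference carrying specified homopolymer runs, a slopped
BED of their coordinates, and coordinate-sorted SAM alignments tiled across
the runs with substitution errors injected at independent per-base rates
before and after each homopolymer (in read 5'->3' orientation).  This
emulates the elevated post-homopolymer substitution regime seen on some
sequencing chemistries, and the flat regime (pre_error == post_error) of
avidity chemistry.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam

from ..io import write_bed, write_fasta
from ..profiles import HomopolymerInterval
from .templates import BASES

__all__ = ["ProfilingFixture", "generate_profiling_fixture", "generate_uniform_error_fixture"]


@dataclass
class ProfilingFixture:
    reference: dict[str, str]
    intervals: list[HomopolymerInterval]   # slop-trimmed run coordinates
    bed_rows: list[tuple[str, int, int, str]]  # slopped, as written to BED
    fasta_path: Path | None
    bed_path: Path | None
    sam_path: Path | None
    n_reads: int
    snp_positions: dict[int, str] = field(default_factory=dict)  # ref pos -> alt base
    # injection bookkeeping (read-oriented), excluding SNP positions
    injected: dict[str, int] = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, length: int) -> list[str]:
    return [BASES[i] for i in rng.integers(0, 4, size=length)]


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in BASES if b != base]
    return choices[int(rng.integers(0, 3))]


def generate_profiling_fixture(
    seed: int,
    ref_length: int = 4000,
    homopolymer_spec: Sequence[tuple[str, int, int]] = (("A", 15, 1000),),
    pre_error: float = 0.0,
    post_error: float = 0.0,
    n_reads: int = 200,
    read_length: int = 150,
    out_dir: str | Path | None = None,
    contig: str = "sim1",
    slop: int = 5,
    reverse_fraction: float = 0.0,
    snp_positions: Sequence[int] = (),
    include_decoys: bool = True,
    min_flank: int = 6,
) -> ProfilingFixture:
    """Generate (FASTA reference, slopped BED, sorted SAM) with known truth.

    ``homopolymer_spec`` lists (base, run_length, ref_start) runs; runs (with
    their slop margins) must not overlap.  Every templated read fully spans
    one run with at least ``min_flank`` bases on each side; substitution
    errors are drawn per base at ``pre_error`` before the run and
    ``post_error`` after it, in read orientation.  Reads at ``snp_positions``
    always carry a fixed alternate base (a planted known variant).
    """
    if not (0.0 <= pre_error < 1.0 and 0.0 <= post_error < 1.0):
        raise ValueError("error probabilities must be in [0, 1)")
    rng = np.random.default_rng(seed)
    ref = _random_seq(rng, ref_length)

    spec = sorted(homopolymer_spec, key=lambda s: s[2])
    intervals: list[HomopolymerInterval] = []
    bed_rows: list[tuple[str, int, int, str]] = []
    prev_end = -1
    for i, (base, length, pos) in enumerate(spec):
        if base not in BASES:
            raise ValueError(f"homopolymer base {base!r} not in {BASES}")
        if pos - slop < 1 or pos + length + slop > ref_length - 1:
            raise ValueError(f"homopolymer at {pos} (+slop {slop}) does not fit in reference")
        if pos - slop <= prev_end:
            raise ValueError(f"homopolymer specs overlap near position {pos}")
        prev_end = pos + length + slop
        ref[pos : pos + length] = base * length
        # guarantee the run is exactly the stated length
        if ref[pos - 1] == base:
            ref[pos - 1] = _other_base(rng, base)
        if ref[pos + length] == base:
            ref[pos + length] = _other_base(rng, base)
        intervals.append(
            HomopolymerInterval(contig=contig, start=pos, end=pos + length, base=base,
                                name=f"hp{i}")
        )
        bed_rows.append((contig, pos - slop, pos + length + slop, f"hp{i}"))

    snp_alts: dict[int, str] = {}
    for p in snp_positions:
        if not (0 <= p < ref_length):
            raise ValueError(f"SNP position {p} out of reference bounds")
        snp_alts[int(p)] = _other_base(rng, ref[p])
    ref_str = "".join(ref)

    injected = {"pre_bases": 0, "pre_errors": 0, "post_bases": 0, "post_errors": 0}
    records = []
    for i in range(n_reads):
        iv = intervals[i % len(intervals)]
        lo = max(iv.end + min_flank - read_length, 0)
        hi = min(iv.start - min_flank, ref_length - read_length)
        if lo > hi:
            raise ValueError(
                f"read_length {read_length} too short to span homopolymer of length "
                f"{iv.length} with {min_flank}-base flanks"
            )
        start = int(rng.integers(lo, hi + 1))
        is_rev = bool(rng.random() < reverse_fraction)
        seq = list(ref_str[start : start + read_length])
        for j in range(read_length):
            p = start + j
            if p in snp_alts:
                seq[j] = snp_alts[p]
                continue
            if iv.start <= p < iv.end:
                continue
            pre_side = (p < iv.start) != is_rev  # XOR: genomic-right is pre for reverse reads
            rate = pre_error if pre_side else post_error
            key = "pre" if pre_side else "post"
            injected[f"{key}_bases"] += 1
            if rate > 0 and rng.random() < rate:
                seq[j] = _other_base(rng, seq[j])
                injected[f"{key}_errors"] += 1
        records.append(
            dict(name=f"read{i}", flag=16 if is_rev else 0, pos=start,
                 mapq=60, cigar=f"{read_length}M", seq="".join(seq))
        )

    if include_decoys:
        iv = intervals[0]
        start = max(0, iv.start - min_flank - 20)
        seq = ref_str[start : start + read_length]
        records.append(dict(name="decoy_secondary", flag=256, pos=start, mapq=60,
                            cigar=f"{read_length}M", seq=seq))
        records.append(dict(name="decoy_supplementary", flag=2048, pos=start, mapq=60,
                            cigar=f"{read_length}M", seq=seq))
        records.append(dict(name="decoy_mapq0", flag=0, pos=start, mapq=0,
                            cigar=f"{read_length}M", seq=seq))
        records.append(dict(name="decoy_unmapped", flag=4, pos=0, mapq=0,
                            cigar="*", seq=seq))

    records.sort(key=lambda r: (r["pos"], r["name"]))

    fasta_path = bed_path = sam_path = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        fasta_path = out_dir / "reference.fasta"
        bed_path = out_dir / "homopolymers_slop.bed"
        sam_path = out_dir / "alignments.sam"
        write_fasta({contig: ref_str}, fasta_path)
        write_bed(bed_rows, bed_path)
        header = pysam.AlignmentHeader.from_dict(
            {
                "HD": {"VN": "1.6", "SO": "coordinate"},
                "SQ": [{"SN": contig, "LN": ref_length}],
            }
        )
        with pysam.AlignmentFile(str(sam_path), "wh", header=header) as out:
            for r in records:
                a = pysam.AlignedSegment(header)
                a.query_name = r["name"]
                a.flag = r["flag"]
                a.query_sequence = r["seq"]
                a.query_qualities = pysam.qualitystring_to_array("I" * len(r["seq"]))
                if r["flag"] & 4:
                    a.reference_id = -1
                    a.reference_start = -1
                else:
                    a.reference_id = 0
                    a.reference_start = r["pos"]
                    a.cigarstring = r["cigar"]
                a.mapping_quality = r["mapq"]
                out.write(a)

    return ProfilingFixture(
        reference={contig: ref_str},
        intervals=intervals,
        bed_rows=bed_rows,
        fasta_path=fasta_path,
        bed_path=bed_path,
        sam_path=sam_path,
        n_reads=n_reads,
        snp_positions=snp_alts,
        injected=injected,
    )


def generate_uniform_error_fixture(
    seed: int,
    ref_length: int = 2000,
    n_reads: int = 300,
    read_length: int = 100,
    error_rate: float = 0.01,
    out_dir: str | Path | None = None,
    contig: str = "sim1",
) -> ProfilingFixture:
    """Reads tiled over a random reference with uniform per-base substitutions.

    Companion fixture for the k-mer analysis: under a uniform per-base error
    rate ``e``, the expected fraction of k-mer instances containing at least
    one mismatch is ``1 - (1 - e)**k``.
    """
    if not (0.0 <= error_rate < 1.0):
        raise ValueError("error_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    ref_str = "".join(_random_seq(rng, ref_length))
    records = []
    n_err = 0
    for i in range(n_reads):
        start = int(rng.integers(0, ref_length - read_length + 1))
        seq = list(ref_str[start : start + read_length])
        err = rng.random(read_length) < error_rate
        for j in np.flatnonzero(err):
            seq[j] = _other_base(rng, seq[j])
        n_err += int(err.sum())
        records.append(dict(name=f"read{i}", flag=0, pos=start, mapq=60,
                            cigar=f"{read_length}M", seq="".join(seq)))
    records.sort(key=lambda r: (r["pos"], r["name"]))

    fasta_path = sam_path = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        fasta_path = out_dir / "reference.fasta"
        sam_path = out_dir / "alignments.sam"
        write_fasta({contig: ref_str}, fasta_path)
        header = pysam.AlignmentHeader.from_dict(
            {"HD": {"VN": "1.6", "SO": "coordinate"},
             "SQ": [{"SN": contig, "LN": ref_length}]}
        )
        with pysam.AlignmentFile(str(sam_path), "wh", header=header) as out:
            for r in records:
                a = pysam.AlignedSegment(header)
                a.query_name = r["name"]
                a.flag = r["flag"]
                a.query_sequence = r["seq"]
                a.query_qualities = pysam.qualitystring_to_array("I" * len(r["seq"]))
                a.reference_id = 0
                a.reference_start = r["pos"]
                a.cigarstring = r["cigar"]
                a.mapping_quality = r["mapq"]
                out.write(a)

    return ProfilingFixture(
        reference={contig: ref_str},
        intervals=[],
        bed_rows=[],
        fasta_path=fasta_path,
        bed_path=None,
        sam_path=sam_path,
        n_reads=n_reads,
        injected={"errors": n_err, "bases": n_reads * read_length},
    )
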