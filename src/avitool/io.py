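"""Format readers/writers shared across the toolkit.

All internal coordinates are 0-based half-open.  FASTQ and BED are written by
hand so that round-trips are byte-identical; FASTA parsing goes through
Bio.SeqIO and SAM/BAM through pysam.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np
import pysam
from Bio import SeqIO

from .simulate.intensities import IntensityTensor
from .simulate.traces import KineticTrace, KineticTraceSet

__all__ = [
    "FastqRecord",
    "read_fastq",
    "write_fastq",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_traces",
    "write_traces",
    "save_intensities",
    "load_intensities",
    "read_alignments",
    "RunSummary",
]


class FastqRecord(NamedTuple):
    name: str
    sequence: str
    quality: str  # phred+33


def read_fastq(path: str | Path) -> list[FastqRecord]:
    records = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) % 4 != 0:
        raise ValueError(f"{path}: FASTQ line count {len(lines)} not a multiple of 4")
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = lines[i : i + 4]
        rec_idx = i // 4
        if not head.startswith("@"):
            raise ValueError(f"{path}: record {rec_idx}: header does not start with '@'")
        if not plus.startswith("+"):
            raise ValueError(f"{path}: record {rec_idx}: separator line missing '+'")
        if len(seq) != len(qual):
            raise ValueError(
                f"{path}: record {rec_idx}: sequence length {len(seq)} != "
                f"quality length {len(qual)}"
            )
        records.append(FastqRecord(name=head[1:], sequence=seq, quality=qual))
    return records


def write_fastq(records: Iterable[FastqRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if len(rec.sequence) != len(rec.quality):
                raise ValueError(f"record {rec.name}: sequence/quality length mismatch")
            fh.write(f"@{rec.name}\n{rec.sequence}\n+\n{rec.quality}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read BED rows as (contig, start, end, name); 0-based half-open."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{ln + 1}: BED row has fewer than 3 columns")
            contig, start, end = fields[0], int(fields[1]), int(fields[2])
            if end < start:
                raise ValueError(f"{path}:{ln + 1}: end < start")
            name = fields[3] if len(fields) > 3 else ""
            rows.append((contig, start, end, name))
    return rows


def write_bed(rows: Iterable[Sequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


# -- kinetic trace tables -------------------------------------------------

_TRACE_HEADER = "time\tsignal\tconcentration\tcondition"


def write_traces(traces: KineticTraceSet | Iterable[KineticTrace], path: str | Path) -> None:
    """Write traces as a TSV: time, signal, concentration, condition."""
    items = traces.traces if isinstance(traces, KineticTraceSet) else tuple(traces)
    with open(path, "w") as fh:
        fh.write(_TRACE_HEADER + "\n")
        for tr in items:
            conc = "" if tr.concentration is None else repr(float(tr.concentration))
            for t, s in zip(tr.time, tr.signal):
                fh.write(f"{float(t)!r}\t{float(s)!r}\t{conc}\t{tr.condition}\n")


def read_traces(path: str | Path) -> list[KineticTrace]:
    """Read a trace TSV back into traces, grouped by (concentration, condition)."""
    groups: dict[tuple, list[tuple[float, float]]] = {}
    order: list[tuple] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        cols = header.split("\t")
        if cols[:2] != ["time", "signal"]:
            raise ValueError(f"{path}: expected 'time<TAB>signal...' header, got {header!r}")
        for ln, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            t, s = float(fields[0]), float(fields[1])
            conc = float(fields[2]) if len(fields) > 2 and fields[2] != "" else None
            cond = fields[3] if len(fields) > 3 else ""
            key = (conc, cond)
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append((t, s))
    traces = []
    for conc, cond in order:
        pts = groups[(conc, cond)]
        times = np.array([p[0] for p in pts])
        sigs = np.array([p[1] for p in pts])
        traces.append(KineticTrace(time=times, signal=sigs, concentration=conc, condition=cond))
    return traces


# -- intensity container --------------------------------------------------


def save_intensities(
    path: str | Path,
    tensor: IntensityTensor,
    truth: np.ndarray | None = None,
    config: dict | None = None,
) -> None:
    """Save an intensity tensor (NPZ) with a JSON sidecar of config + seed."""
    path = Path(path)
    npz_path = path if path.suffix == ".npz" else Path(str(path) + ".npz")
    arrays = {"values": tensor.values}
    if truth is not None:
        arrays["truth"] = truth
    np.savez_compressed(npz_path, **arrays)
    sidecar = {
        "channel_order": tensor.channel_order,
        "shape": list(tensor.values.shape),
        "config": config or {},
    }
    npz_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def load_intensities(path: str | Path) -> tuple[IntensityTensor, np.ndarray | None, dict]:
    path = Path(path)
    with np.load(path) as data:
        values = data["values"]
        truth = data["truth"] if "truth" in data else None
    sidecar_path = path.with_suffix(".json")
    sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    tensor = IntensityTensor(values=values, channel_order=sidecar.get("channel_order", "ACGT"))
    return tensor, truth, sidecar.get("config", {})


# -- alignments ------------------------------------------------------------


def read_alignments(
    path: str | Path,
    regions: Sequence[tuple[str, int, int]] | None = None,
) -> Iterator[pysam.AlignedSegment]:
    """Iterate alignment records, optionally restricted to regions.

    Regions are (contig, start, end), 0-based half-open.  Indexed BAM files
    use random access; plain SAM streams the file and filters by overlap.
    Records overlapping several regions are yielded once.
    """
    path = str(path)
    af = pysam.AlignmentFile(path, check_sq=False)
    if regions is None:
        yield from af.fetch(until_eof=True)
        af.close()
        return
    has_index = False
    try:
        has_index = af.check_index()
    except (AttributeError, ValueError, OSError):
        has_index = False
    if has_index:
        seen: set[tuple] = set()
        for contig, start, end in regions:
            for rec in af.fetch(contig, start, end):
                key = (rec.query_name, rec.flag, rec.reference_start)
                if key not in seen:
                    seen.add(key)
                    yield rec
    else:
        by_contig: dict[str, list[tuple[int, int]]] = {}
        for contig, start, end in regions:
            by_contig.setdefault(contig, []).append((start, end))
        for rec in af.fetch(until_eof=True):
            if rec.is_unmapped or rec.reference_name not in by_contig:
                continue
            rs, re = rec.reference_start, rec.reference_end
            if any(rs < end and re > start for start, end in by_contig[rec.reference_name]):
                yield rec
    af.close()


# -- run summary ------------------------------------------------------------


@dataclass
class RunSummary:
    """Machine-readable per-invocation summary."""

    tool: str
    version: str
    config: dict = field(default_factory=dict)
    counters: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str) + "\n")
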