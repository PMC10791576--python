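"""Independent brute-force per-base alignment walker used as a counting oracle.

Parses SAM text directly (no pysam) and walks CIGAR operations one base at a
time, so it shares no code path with the package's profilers.
"""
from __future__ import annotations

import re

CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def parse_sam(path):
    """Yield dicts for non-header SAM lines."""
    with open(path) as fh:
        for line in fh:
            if line.startswith("@"):
                continue
            f = line.rstrip("\n").split("\t")
            yield {
                "qname": f[0],
                "flag": int(f[1]),
                "rname": f[2],
                "pos": int(f[3]) - 1,  # to 0-based
                "mapq": int(f[4]),
                "cigar": f[5],
                "seq": f[9],
            }


def keep(rec):
    flag = rec["flag"]
    return not (flag & 0x4 or flag & 0x100 or flag & 0x800) and rec["mapq"] > 0


def walk_columns(rec, ref):
    """Yield (qpos, rpos, qbase, rbase) for every aligned (M/=/X) column."""
    q = 0
    r = rec["pos"]
    seq = rec["seq"]
    contig = ref[rec["rname"]]
    for n_str, op in CIGAR_RE.findall(rec["cigar"]):
        n = int(n_str)
        if op in "M=X":
            for _ in range(n):
                yield q, r, seq[q].upper(), contig[r].upper()
                q += 1
                r += 1
        elif op in "IS":
            q += n
        elif op in "DN":
            r += n
        # H and P consume nothing


def segment_counts(rec, ref, hp_start, hp_end, masked=frozenset()):
    """Per-segment (aligned, mismatch) counts in read 5'->3' orientation."""
    rev = bool(rec["flag"] & 0x10)
    counts = {"pre": [0, 0], "overlap": [0, 0], "post": [0, 0]}
    for _, rpos, qb, rb in walk_columns(rec, ref):
        if qb == "N" or rb == "N" or rpos in masked:
            continue
        if rpos < hp_start:
            seg = "post" if rev else "pre"
        elif rpos < hp_end:
            seg = "overlap"
        else:
            seg = "pre" if rev else "post"
        counts[seg][0] += 1
        counts[seg][1] += int(qb != rb)
    return counts


def kmer_counts(records, ref, k, read_oriented=True, masked=frozenset()):
    """Instance / mismatching counts per reference k-mer context."""
    out = {}
    for rec in records:
        if not keep(rec):
            continue
        cols = [
            (q, r, qb, rb)
            for q, r, qb, rb in walk_columns(rec, ref)
            if qb != "N" and rb != "N" and r not in masked
        ]
        rev = bool(rec["flag"] & 0x10)
        for i in range(len(cols) - k + 1):
            window = cols[i : i + k]
            if any(
                window[j + 1][0] != window[j][0] + 1 or window[j + 1][1] != window[j][1] + 1
                for j in range(k - 1)
            ):
                continue
            mer = "".join(c[3] for c in window)
            if rev and read_oriented:
                mer = "".join(COMP[b] for b in reversed(mer))
            bad = any(c[2] != c[3] for c in window)
            inst, mm = out.get(mer, (0, 0))
            out[mer] = (inst + 1, mm + int(bad))
    return out
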