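"""Template (polony concatemer identity) generation."""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

BASES = "ACGT"
BASE_TO_INDEX = {b: i for i, b in enumerate(BASES)}

__all__ = ["TemplateSet", "generate_templates", "BASES", "BASE_TO_INDEX", "encode_bases"]


@dataclass(frozen=True)
class TemplateSet:
    """The true base sequence underlying each polony."""

    sequences: tuple[str, ...]
    origin: str  # "random" | "reference"

    def __len__(self) -> int:
        return len(self.sequences)


def encode_bases(seq: str) -> np.ndarray:
    """Encode an ACGT string as uint8 channel indices (A,C,G,T -> 0..3)."""
    lut = np.full(256, 255, dtype=np.uint8)
    for b, i in BASE_TO_INDEX.items():
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    arr = lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        bad = seq[int(np.argmax(arr == 255))]
        raise ValueError(f"non-ACGT base {bad!r} in sequence")
    return arr


def generate_templates(
    n: int,
    length: int,
    seed: int,
    reference: str | Sequence[str] | None = None,
) -> TemplateSet:
    """Draw ``n`` templates of ``length`` bases.

    Without a reference, bases are uniform i.i.d.  With a reference (one
    string or several contigs), templates are random substrings of contigs
    long enough to contain them.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    if reference is None:
        idx = rng.integers(0, 4, size=(n, length))
        seqs = tuple("".join(BASES[j] for j in row) for row in idx)
        return TemplateSet(sequences=seqs, origin="random")
    contigs = [reference] if isinstance(reference, str) else list(reference)
    usable = [c for c in contigs if len(c) >= length]
    if not usable:
        raise ValueError(
            f"no reference contig is at least {length} bases long "
            f"(max available {max((len(c) for c in contigs), default=0)})"
        )
    seqs = []
    for _ in range(n):
        c = usable[int(rng.integers(0, len(usable)))]
        start = int(rng.integers(0, len(c) - length + 1))
        sub = c[start : start + length].upper()
        encode_bases(sub)  # validates alphabet
        seqs.append(sub)
    return TemplateSet(sequences=tuple(seqs), origin="reference")
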