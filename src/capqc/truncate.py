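"""Ligation-junction detection and 3' truncation of chimeric reads.

Reads are scanned 5'→3' for any of the library's ligation-junction
sequences.  A read containing a junction is chimeric: its 3' part comes
from the second fragment of a ligation product and would prevent the read
from mapping.  The read is therefore truncated at the junction.  By
default the retained prefix keeps the reconstructed end of the first
fragment (``flank5 + overhang`` for fill-in protocols, ``flank5``
otherwise) — that sequence is genomic for the first digest's locus and
maximises mappable length; ``keep_remnant=False`` cuts at the junction
start instead.

Pairs where either truncated mate falls below ``min_length`` are dropped
entirely (both mates), since such reads cannot be mapped reliably.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterator

import pysam

from .enzymes import Junction

__all__ = [
    "TruncationResult",
    "TruncationCounters",
    "truncate_read",
    "process_fastq_pair",
    "read_fastq",
    "write_fastq",
    "DEFAULT_MIN_LENGTH",
]

#: Shortest truncated read still considered reliably mappable.
DEFAULT_MIN_LENGTH = 20


@dataclass(frozen=True)
class TruncationResult:
    sequence: str
    quality: str
    was_truncated: bool

    @property
    def retained_length(self) -> int:
        return len(self.sequence)


@dataclass
class TruncationCounters:
    total_pairs: int = 0
    pairs_removed_short: int = 0
    reads_truncated_forward: int = 0
    reads_truncated_reverse: int = 0

    def to_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def truncate_read(
    seq: str,
    qual: str,
    junctions: list[Junction],
    keep_remnant: bool = True,
) -> TruncationResult:
    """Truncate ``seq``/``qual`` at the leftmost junction occurrence.

    With ``keep_remnant`` the retained prefix length is
    ``j + cut_offset + overhang_length`` (fill-in) or ``j + cut_offset``
    (plain), where ``j`` is the junction start; without it, ``j``.
    If several junctions start at the same leftmost position the one
    retaining the fewest bases wins.  A read without any junction is
    returned unchanged.
    """
    if len(seq) != len(qual):
        raise ValueError("sequence and quality strings differ in length")
    best: tuple[int, int] | None = None  # (junction start, retained length)
    for j in junctions:
        i = seq.find(j.sequence)
        if i == -1:
            continue
        keep = i + (j.keep_length if keep_remnant else 0)
        if best is None or (i, keep) < best:
            best = (i, keep)
    if best is None:
        best = _partial_junction_at_end(seq, junctions, keep_remnant)
    if best is None:
        return TruncationResult(seq, qual, False)
    keep = best[1]
    return TruncationResult(seq[:keep], qual[:keep], True)


def _partial_junction_at_end(
    seq: str, junctions: list[Junction], keep_remnant: bool
) -> tuple[int, int] | None:
    """Detect a junction straddling the read's 3' end.

    A fill-in junction whose prefix extends past the upstream fragment's
    reconstructed end (``flank5 + overhang``) is not genomic sequence, so
    a read ending inside one would fail to map even though no complete
    junction is present.  If a proper junction prefix longer than the
    retained remnant is a suffix of the read, the read is truncated there.
    Plain (no-fill-in) junction prefixes coincide with genomic restriction
    sites and are left alone.
    """
    best: tuple[int, int] | None = None
    for j in junctions:
        if not j.fill_in:
            continue
        for ell in range(len(j.sequence) - 1, j.keep_length, -1):
            if seq.endswith(j.sequence[:ell]):
                start = len(seq) - ell
                keep = start + (j.keep_length if keep_remnant else 0)
                if best is None or (start, keep) < best:
                    best = (start, keep)
                break
    return best


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield ``(name, sequence, quality)`` from a (gzip-aware) FASTQ file."""
    with pysam.FastxFile(str(path)) as fh:
        for rec in fh:
            yield rec.name, rec.sequence, rec.quality


def _open_out(path: str | Path) -> IO[str]:
    if str(path).endswith(".gz"):
        return gzip.open(path, "wt")
    return open(path, "w")


def write_fastq(records: list[tuple[str, str, str]], path: str | Path) -> None:
    with _open_out(path) as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def process_fastq_pair(
    fastq1: str | Path,
    fastq2: str | Path,
    junctions: list[Junction],
    out1: str | Path,
    out2: str | Path,
    min_length: int = DEFAULT_MIN_LENGTH,
    keep_remnant: bool = True,
) -> TruncationCounters:
    """Truncate both mates of every pair; drop pairs rendered too short.

    The two FASTQ streams must be order-synchronized with matching
    identifiers (a trailing ``/1`` / ``/2`` mate suffix is tolerated).
    Output preserves identifiers and order; counters record totals,
    dropped pairs and per-side truncations.
    """
    counters = TruncationCounters()
    kept1: list[tuple[str, str, str]] = []
    kept2: list[tuple[str, str, str]] = []
    it1, it2 = read_fastq(fastq1), read_fastq(fastq2)
    while True:
        r1 = next(it1, None)
        r2 = next(it2, None)
        if r1 is None and r2 is None:
            break
        if r1 is None or r2 is None:
            raise ValueError("FASTQ streams have different numbers of records")
        if _core_name(r1[0]) != _core_name(r2[0]):
            raise ValueError(
                f"read identifier mismatch at pair {counters.total_pairs + 1}: "
                f"{r1[0]!r} vs {r2[0]!r}"
            )
        counters.total_pairs += 1
        t1 = truncate_read(r1[1], r1[2], junctions, keep_remnant)
        t2 = truncate_read(r2[1], r2[2], junctions, keep_remnant)
        counters.reads_truncated_forward += t1.was_truncated
        counters.reads_truncated_reverse += t2.was_truncated
        if t1.retained_length < min_length or t2.retained_length < min_length:
            counters.pairs_removed_short += 1
            continue
        kept1.append((r1[0], t1.sequence, t1.quality))
        kept2.append((r2[0], t2.sequence, t2.quality))
    write_fastq(kept1, out1)
    write_fastq(kept2, out2)
    return counters


def _core_name(name: str) -> str:
    if len(name) > 2 and name[-2] == "/" and name[-1] in "12":
        return name[:-2]
    return name
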