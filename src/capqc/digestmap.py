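"""In-silico genome digestion into a digest map.

The digest map is the coordinate system of the whole pipeline: the genome
partitioned per chromosome into the disjoint intervals between consecutive
restriction cut sites.  Coordinates are 1-based inclusive everywhere a user
sees them (digest file, reports), matching SAM convention.  A cut at
inter-base coordinate ``c`` assigns base ``c`` to the left digest and base
``c + 1`` to the right digest.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio import SeqIO

from .enzymes import RestrictionEnzyme, find_sites

__all__ = [
    "Digest",
    "DigestMap",
    "digest_genome",
    "annotate_targets",
    "read_digest_file",
    "write_digest_file",
    "DIGEST_FILE_HEADER",
]

logger = logging.getLogger(__name__)

DIGEST_FILE_HEADER = "chrom\tstart\tend\tindex\tlength\tgc\ttarget"


@dataclass(frozen=True)
class Digest:
    """A restriction digest: one interval of the genome partition.

    ``start``/``end`` are 1-based inclusive; ``index`` is the 1-based
    ordinal of the digest within its chromosome; ``gc_fraction`` is the
    G+C fraction of the digest sequence with ``N`` excluded from both
    numerator and denominator (0 for an all-N digest).
    """

    chrom: str
    start: int
    end: int
    index: int
    gc_fraction: float
    is_target: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"digest {self.chrom}:{self.start}-{self.end}: start > end")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError(
                f"digest {self.chrom}:{self.start}-{self.end}: "
                f"gc_fraction {self.gc_fraction} outside [0, 1]"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class DigestMap:
    """Per-chromosome ordered digests with O(log n) position lookup.

    Digests within a chromosome must be sorted, non-overlapping and
    contiguous: the first starts at 1, each next digest starts one base
    after its predecessor ends.  The chromosome length is implied by the
    last digest's end.
    """

    def __init__(
        self,
        digests: Iterable[Digest],
        enzymes: tuple[str, ...] = (),
        genome_id: str = "",
    ) -> None:
        self.enzymes = tuple(enzymes)
        self.genome_id = genome_id
        self._by_chrom: dict[str, list[Digest]] = {}
        for d in digests:
            self._by_chrom.setdefault(d.chrom, []).append(d)
        self._starts: dict[str, list[int]] = {}
        for chrom, ds in self._by_chrom.items():
            self._validate_partition(chrom, ds)
            self._starts[chrom] = [d.start for d in ds]

    @staticmethod
    def _validate_partition(chrom: str, ds: list[Digest]) -> None:
        if ds[0].start != 1:
            raise ValueError(f"{chrom}: first digest starts at {ds[0].start}, not 1")
        for i, (a, b) in enumerate(zip(ds, ds[1:]), start=1):
            if b.start != a.end + 1:
                raise ValueError(
                    f"{chrom}: digest {i + 1} starts at {b.start} but "
                    f"digest {i} ends at {a.end} (must be contiguous)"
                )
        for i, d in enumerate(ds, start=1):
            if d.index != i:
                raise ValueError(f"{chrom}: digest ordinal {d.index} != position {i}")

    @property
    def chromosomes(self) -> list[str]:
        return list(self._by_chrom)

    def chromosome_length(self, chrom: str) -> int:
        return self._by_chrom[chrom][-1].end

    def digests(self, chrom: str | None = None) -> Iterator[Digest]:
        chroms = [chrom] if chrom is not None else self.chromosomes
        for c in chroms:
            yield from self._by_chrom[c]

    def n_digests(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return len(self._by_chrom[chrom])
        return sum(len(ds) for ds in self._by_chrom.values())

    def lookup(self, chrom: str, pos: int) -> Digest:
        """The unique digest with ``start <= pos <= end`` (1-based)."""
        try:
            ds = self._by_chrom[chrom]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} not in digest map") from None
        if not 1 <= pos <= ds[-1].end:
            raise ValueError(
                f"position {chrom}:{pos} outside chromosome bounds "
                f"[1, {ds[-1].end}]"
            )
        i = bisect.bisect_right(self._starts[chrom], pos) - 1
        return ds[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DigestMap):
            return NotImplemented
        return self._by_chrom == other._by_chrom

    def __len__(self) -> int:
        return self.n_digests()

    def __repr__(self) -> str:
        return (
            f"DigestMap({self.n_digests()} digests on "
            f"{len(self.chromosomes)} chromosomes, enzymes={self.enzymes})"
        )

    def _replace_digests(self, digests: Iterable[Digest]) -> "DigestMap":
        return DigestMap(digests, enzymes=self.enzymes, genome_id=self.genome_id)


def _gc_fraction(seq: str) -> float:
    gc = seq.count("G") + seq.count("C") + seq.count("g") + seq.count("c")
    n = seq.count("N") + seq.count("n")
    denom = len(seq) - n
    return gc / denom if denom else 0.0


def _read_fasta(source: str | Path | IO[str]) -> list[tuple[str, str]]:
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(source, "fasta")]
    if not records:
        raise ValueError("FASTA source contains no sequences")
    names = [name for name, _ in records]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate sequence names in FASTA: {dupes}")
    return records


def digest_genome(
    genome: str | Path | IO[str] | list[tuple[str, str]],
    enzymes: list[RestrictionEnzyme] | tuple[RestrictionEnzyme, ...],
    genome_id: str = "",
) -> DigestMap:
    """Digest a genome FASTA (or ``[(name, seq), ...]``) with one or more enzymes.

    Cut coordinates from all enzymes are merged and deduplicated per
    chromosome; cuts falling exactly on a chromosome boundary are ignored
    (they would create zero-length digests).
    """
    if not enzymes:
        raise ValueError("at least one enzyme is required")
    if isinstance(genome, list):
        records = genome
        if not records:
            raise ValueError("genome contains no sequences")
        names = [name for name, _ in records]
        if len(set(names)) != len(names):
            raise ValueError("duplicate sequence names in genome")
    else:
        records = _read_fasta(genome)
    digests: list[Digest] = []
    for chrom, seq in records:
        cuts: set[int] = set()
        for enz in enzymes:
            cuts.update(find_sites(seq, enz))
        cuts.discard(0)
        cuts.discard(len(seq))
        bounds = [0, *sorted(cuts), len(seq)]
        for idx, (a, b) in enumerate(zip(bounds, bounds[1:]), start=1):
            digests.append(
                Digest(
                    chrom=chrom,
                    start=a + 1,
                    end=b,
                    index=idx,
                    gc_fraction=_gc_fraction(seq[a:b]),
                )
            )
    return DigestMap(digests, enzymes=tuple(e.name for e in enzymes), genome_id=genome_id)


def _parse_bed(source: str | Path | IO[str]) -> list[tuple[str, int, int]]:
    """Minimal BED3 reader: 0-based half-open intervals."""
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        lines = Path(source).read_text().splitlines()
    intervals = []
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"BED line {lineno}: fewer than 3 columns")
        intervals.append((fields[0], int(fields[1]), int(fields[2])))
    return intervals


def annotate_targets(
    dmap: DigestMap, targets: str | Path | IO[str] | list[tuple[str, int, int]]
) -> DigestMap:
    """Flag every digest overlapping a target interval by at least 1 bp.

    ``targets`` is a BED source (0-based half-open) or a list of
    ``(chrom, bed_start, bed_end)``.  Intervals on chromosomes absent
    from the map are skipped with a warning.  Returns a new map; flags
    not set by any interval are cleared.
    """
    intervals = targets if isinstance(targets, list) else _parse_bed(targets)
    flagged: set[tuple[str, int]] = set()
    skipped = 0
    for chrom, bed_start, bed_end in intervals:
        if chrom not in dmap._by_chrom:
            skipped += 1
            logger.warning("target interval on unknown chromosome %r skipped", chrom)
            continue
        start1, end1 = bed_start + 1, bed_end  # to 1-based inclusive
        if end1 < start1 or end1 < 1 or start1 > dmap.chromosome_length(chrom):
            continue
        lo = max(start1, 1)
        hi = min(end1, dmap.chromosome_length(chrom))
        d = dmap.lookup(chrom, lo)
        while True:
            flagged.add((chrom, d.index))
            if d.end >= hi:
                break
            d = dmap.lookup(chrom, d.end + 1)
    if skipped:
        logger.warning("%d target interval(s) skipped (unknown chromosome)", skipped)
    return dmap._replace_digests(
        replace(d, is_target=(d.chrom, d.index) in flagged) for d in dmap.digests()
    )


def write_digest_file(dmap: DigestMap, path: str | Path) -> None:
    """Write the tab-separated digest file (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write(DIGEST_FILE_HEADER + "\n")
        for d in dmap.digests():
            fh.write(
                f"{d.chrom}\t{d.start}\t{d.end}\t{d.index}\t{d.length}\t"
                f"{d.gc_fraction!r}\t{int(d.is_target)}\n"
            )


def read_digest_file(path: str | Path) -> DigestMap:
    """Read a digest file back; the partition invariant is re-validated."""
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] != DIGEST_FILE_HEADER:
        raise ValueError(f"{path}: missing or malformed digest file header")
    digests = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != 7:
            raise ValueError(f"{path}, line {lineno}: expected 7 columns, got {len(fields)}")
        try:
            d = Digest(
                chrom=fields[0],
                start=int(fields[1]),
                end=int(fields[2]),
                index=int(fields[3]),
                gc_fraction=float(fields[5]),
                is_target=bool(int(fields[6])),
            )
        except ValueError as exc:
            raise ValueError(f"{path}, line {lineno}: {exc}") from None
        if d.length != int(fields[4]):
            raise ValueError(
                f"{path}, line {lineno}: length column {fields[4]} "
                f"inconsistent with coordinates"
            )
        digests.append(d)
    return DigestMap(digests)
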