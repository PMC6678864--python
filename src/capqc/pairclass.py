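"""Re-pairing, size computation and artefact classification of read pairs.

Hi-C mates are mapped independently as single-end reads, so the first
step re-joins the two alignment streams by read name ("re-pairing").
Each surviving pair is then classified by relative orientation, digest
membership and three sizes:

``lu``
    un-ligated fragment size — for inward cis pairs the inclusive span
    between the two 5' ends; for outward pairs the gap between them.
``lr``
    ligation-fragment size — the sum of the two digest-end segments, a
    segment being the distance from a read's 5' end to the next
    restriction site in its 3' direction.
``ls``
    self-ligated digest size — ``lu + lr`` for outward cis pairs; for a
    pair wholly inside one digest this equals the digest length.

The decision tree: trans pairs are chimeric by construction; inward or
outward pairs on a single digest are un-ligated or self-ligated
respectively; inward pairs with small ``lu`` and outward pairs with small
``ls`` are artefacts even across digest boundaries; same-strand pairs on
one digest are "strange internal"; all remaining (chimeric) pairs are
size-filtered on ``lr`` into too-short / too-long / valid.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pysam

from .digestmap import Digest, DigestMap

__all__ = [
    "Strand",
    "MappedRead",
    "ReadPair",
    "Orientation",
    "Category",
    "Thresholds",
    "RePairCounters",
    "re_pair",
    "orientation",
    "segment_size",
    "fragment_size_lr",
    "unligated_size_lu",
    "selfligation_size_ls",
    "classify",
    "deduplicate",
    "is_dangling",
    "classify_pairs",
    "ClassificationCounters",
    "write_valid_sam",
]


class Orientation(str, enum.Enum):
    INWARD = "inward"
    OUTWARD = "outward"
    LEFT = "left"
    RIGHT = "right"


class Category(str, enum.Enum):
    UNLIGATED = "unligated"
    SELF_LIGATED = "self_ligated"
    STRANGE_INTERNAL = "strange_internal"
    CHIMERIC_TOO_SHORT = "chimeric_too_short"
    CHIMERIC_TOO_LONG = "chimeric_too_long"
    VALID = "valid"


@dataclass(frozen=True)
class MappedRead:
    """One independently mapped mate.

    ``five_prime`` is the 1-based genomic coordinate of the read's 5'
    base: the leftmost aligned base on the forward strand, the rightmost
    on the reverse strand.
    """

    name: str
    chrom: str | None
    five_prime: int
    strand: str  # '+' or '-'
    mapq: int = 60
    is_unmapped: bool = False
    is_multimapped: bool = False

    @property
    def is_usable(self) -> bool:
        return not (self.is_unmapped or self.is_multimapped)


@dataclass
class ReadPair:
    """A re-paired forward-file / reverse-file read with classification state."""

    fwd: MappedRead
    rev: MappedRead
    category: Category | None = None
    is_cis: bool | None = None
    dangling: bool = False
    lu: int | None = None
    lr: int | None = None
    ls: int | None = None

    @property
    def name(self) -> str:
        return self.fwd.name

    @property
    def is_trans(self) -> bool | None:
        return None if self.is_cis is None else not self.is_cis


@dataclass(frozen=True)
class Thresholds:
    """Size thresholds of the classification tree (bp).

    Un-ligated fragments and self-ligating digests are bounded by the
    shearing-size range ("a few hundred" bp) and typical digest sizes
    ("a few thousand" bp) respectively; the valid range brackets the
    sonication size selection.  All values are configurable — only their
    orders of magnitude are dictated by the chemistry.
    """

    max_unligated_size: int = 1000
    max_selfligation_size: int = 3000
    valid_size_min: int = 50
    valid_size_max: int = 1000
    min_mapq: int = 30

    def __post_init__(self) -> None:
        if not (
            self.max_unligated_size > 0
            and self.max_selfligation_size > 0
            and 0 < self.valid_size_min < self.valid_size_max
        ):
            raise ValueError(f"invalid thresholds: {self}")


DEFAULT_THRESHOLDS = Thresholds()


# ---------------------------------------------------------------------------
# re-pairing

@dataclass
class RePairCounters:
    total_pairs: int = 0
    unmapped_pairs: int = 0
    multimapped_pairs: int = 0

    def to_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def _read_groups(path: str | Path) -> Iterator[list[pysam.AlignedSegment]]:
    """Group consecutive same-name records of a single-end SAM/BAM."""
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        group: list[pysam.AlignedSegment] = []
        for rec in fh:
            if group and rec.query_name != group[0].query_name:
                yield group
                group = []
            group.append(rec)
        if group:
            yield group


def _mate_from_group(
    group: list[pysam.AlignedSegment], min_mapq: int
) -> tuple[MappedRead, pysam.AlignedSegment | None]:
    primary = next((r for r in group if not r.is_secondary and not r.is_supplementary), group[0])
    name = primary.query_name
    if primary.is_unmapped:
        return MappedRead(name, None, 0, "+", 0, is_unmapped=True), None
    multi = len(group) > 1 or primary.mapping_quality < min_mapq
    strand = "-" if primary.is_reverse else "+"
    five_prime = primary.reference_end if primary.is_reverse else primary.reference_start + 1
    read = MappedRead(
        name,
        primary.reference_name,
        five_prime,
        strand,
        primary.mapping_quality,
        is_multimapped=multi,
    )
    return read, primary


def re_pair(
    sam_fwd: str | Path,
    sam_rev: str | Path,
    min_mapq: int = DEFAULT_THRESHOLDS.min_mapq,
    keep_segments: bool = False,
) -> tuple[list[ReadPair], RePairCounters, list[tuple]]:
    """Re-join two order-synchronized single-end alignment streams.

    Pairs with an unmapped mate, or a mate that is multimapped
    (secondary/supplementary records present, or MAPQ below
    ``min_mapq``), are counted and excluded from the returned list.
    Returns ``(pairs, counters, segments)`` where ``segments`` holds the
    primary pysam records of each usable pair when ``keep_segments`` (for
    writing the valid-pair SAM later).
    """
    counters = RePairCounters()
    pairs: list[ReadPair] = []
    segments: list[tuple] = []
    gen_fwd, gen_rev = _read_groups(sam_fwd), _read_groups(sam_rev)
    while True:
        g1 = next(gen_fwd, None)
        g2 = next(gen_rev, None)
        if g1 is None and g2 is None:
            break
        if g1 is None or g2 is None:
            lone = (g1 or g2)[0].query_name
            raise ValueError(f"read {lone!r} present in only one alignment stream")
        if g1[0].query_name != g2[0].query_name:
            raise ValueError(
                f"alignment streams out of sync: {g1[0].query_name!r} vs "
                f"{g2[0].query_name!r} (name-sort or order-synchronize them)"
            )
        counters.total_pairs += 1
        r1, seg1 = _mate_from_group(g1, min_mapq)
        r2, seg2 = _mate_from_group(g2, min_mapq)
        if r1.is_unmapped or r2.is_unmapped:
            counters.unmapped_pairs += 1
            continue
        if r1.is_multimapped or r2.is_multimapped:
            counters.multimapped_pairs += 1
            continue
        pairs.append(ReadPair(r1, r2))
        if keep_segments:
            segments.append((seg1, seg2))
    return pairs, counters, segments


# ---------------------------------------------------------------------------
# orientation and sizes

def orientation(pair: ReadPair) -> Orientation:
    """Relative orientation of a same-chromosome pair.

    Opposite strands: inward when the forward-strand mate's 5' end is
    leftmost (ties break to inward), outward otherwise.  Same strand:
    right (both forward) or left (both reverse).
    """
    a, b = pair.fwd, pair.rev
    if a.chrom != b.chrom:
        raise ValueError(f"pair {pair.name!r} is trans; orientation undefined")
    if a.strand == b.strand:
        return Orientation.RIGHT if a.strand == "+" else Orientation.LEFT
    plus = a if a.strand == "+" else b
    minus = b if a.strand == "+" else a
    return Orientation.INWARD if plus.five_prime <= minus.five_prime else Orientation.OUTWARD


def segment_size(read: MappedRead, dmap: DigestMap) -> int:
    """Distance from a read's 5' end to the next restriction site 3' of it.

    Digest boundaries stand in for restriction sites: a forward read on
    digest (s, e) has segment ``e - five_prime + 1``; a reverse read,
    ``five_prime - s + 1``.
    """
    d = dmap.lookup(read.chrom, read.five_prime)
    if read.strand == "+":
        return d.end - read.five_prime + 1
    return read.five_prime - d.start + 1


def fragment_size_lr(pair: ReadPair, dmap: DigestMap) -> int:
    """Ligation-fragment size: the sum of the two digest-end segments."""
    return segment_size(pair.fwd, dmap) + segment_size(pair.rev, dmap)


def unligated_size_lu(pair: ReadPair) -> int:
    """Un-ligated size (inward) or un-ligated gap (outward) of a cis pair."""
    ori = orientation(pair)
    lo = min(pair.fwd.five_prime, pair.rev.five_prime)
    hi = max(pair.fwd.five_prime, pair.rev.five_prime)
    if ori is Orientation.INWARD:
        return hi - lo + 1
    if ori is Orientation.OUTWARD:
        return hi - lo - 1
    raise ValueError(f"lu undefined for {ori.value} pair {pair.name!r}")


def selfligation_size_ls(pair: ReadPair, dmap: DigestMap) -> int:
    """Self-ligated digest size of an outward cis pair: ``lu + lr``."""
    if orientation(pair) is not Orientation.OUTWARD:
        raise ValueError(f"ls only defined for outward pairs ({pair.name!r})")
    return unligated_size_lu(pair) + fragment_size_lr(pair, dmap)


# ---------------------------------------------------------------------------
# classification

def classify(
    pair: ReadPair,
    dmap: DigestMap,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> Category:
    """Assign exactly one category to a mapped, deduplicated pair.

    Sets ``pair.category``, ``pair.is_cis`` and whichever of
    ``lu``/``lr``/``ls`` are defined, then returns the category.
    """
    a, b = pair.fwd, pair.rev
    if not (a.is_usable and b.is_usable):
        raise ValueError(f"pair {pair.name!r} did not pass mapping filters")
    pair.is_cis = a.chrom == b.chrom
    pair.lr = fragment_size_lr(pair, dmap)

    if not pair.is_cis:
        return _size_filter(pair, thresholds)

    ori = orientation(pair)
    da = dmap.lookup(a.chrom, a.five_prime)
    db = dmap.lookup(b.chrom, b.five_prime)
    same_digest = da.index == db.index

    if ori in (Orientation.INWARD, Orientation.OUTWARD):
        pair.lu = unligated_size_lu(pair)
        if ori is Orientation.OUTWARD:
            pair.ls = pair.lu + pair.lr
        if same_digest:
            pair.category = (
                Category.UNLIGATED if ori is Orientation.INWARD else Category.SELF_LIGATED
            )
            return pair.category
        if ori is Orientation.INWARD and pair.lu <= thresholds.max_unligated_size:
            pair.category = Category.UNLIGATED
            return pair.category
        if ori is Orientation.OUTWARD and pair.ls <= thresholds.max_selfligation_size:
            pair.category = Category.SELF_LIGATED
            return pair.category
        return _size_filter(pair, thresholds)

    # same strand: chimeric unless confined to a single digest
    if same_digest:
        pair.category = Category.STRANGE_INTERNAL
        return pair.category
    return _size_filter(pair, thresholds)


def _size_filter(pair: ReadPair, thresholds: Thresholds) -> Category:
    if pair.lr < thresholds.valid_size_min:
        pair.category = Category.CHIMERIC_TOO_SHORT
    elif pair.lr > thresholds.valid_size_max:
        pair.category = Category.CHIMERIC_TOO_LONG
    else:
        pair.category = Category.VALID
    return pair.category


def _dedup_key(pair: ReadPair) -> tuple:
    k1 = (pair.fwd.chrom, pair.fwd.five_prime, pair.fwd.strand)
    k2 = (pair.rev.chrom, pair.rev.five_prime, pair.rev.strand)
    return (k1, k2) if k1 <= k2 else (k2, k1)


def deduplicate(pairs: Iterable[ReadPair]) -> tuple[list[ReadPair], int]:
    """Remove coordinate duplicates, keeping the first-seen pair.

    The key is the canonically ordered pair of (chrom, 5' position,
    strand) tuples, so mates swapped between the two input files still
    collide.
    """
    seen: set[tuple] = set()
    kept: list[ReadPair] = []
    dupes = 0
    for p in pairs:
        k = _dedup_key(p)
        if k in seen:
            dupes += 1
        else:
            seen.add(k)
            kept.append(p)
    return kept, dupes


def is_dangling(pair: ReadPair, dmap: DigestMap) -> bool:
    """True iff either mate's 5' end coincides with a restriction site.

    Forward reads are compared against their digest's start, reverse
    reads against its end.  Dangling pairs are counted but never removed:
    they may stem from incomplete ligation.
    """
    for read in (pair.fwd, pair.rev):
        d = dmap.lookup(read.chrom, read.five_prime)
        boundary = d.start if read.strand == "+" else d.end
        if read.five_prime == boundary:
            return True
    return False


# ---------------------------------------------------------------------------
# batch driver

@dataclass
class ClassificationCounters:
    """Tallies over deduplicated pairs (the Table-style category block)."""

    duplicated: int = 0
    remaining_pairs: int = 0
    dangling_pairs: int = 0
    unligated: int = 0
    self_ligated: int = 0
    strange_internal: int = 0
    chimeric: int = 0
    chimeric_too_short: int = 0
    chimeric_too_long: int = 0
    valid: int = 0
    cis: int = 0
    trans: int = 0

    def to_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


_CHIMERIC = (Category.VALID, Category.CHIMERIC_TOO_SHORT, Category.CHIMERIC_TOO_LONG)


def classify_pairs(
    pairs: Iterable[ReadPair],
    dmap: DigestMap,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> tuple[list[ReadPair], ClassificationCounters]:
    """Deduplicate, classify and tally a stream of mapped pairs.

    Returns the deduplicated pairs (each with ``category`` set) and the
    counters.  "Chimeric" counts all pairs reaching the size filter —
    valid plus too-short/too-long — and splits them into cis and trans.
    """
    deduped, dupes = deduplicate(pairs)
    counters = ClassificationCounters(duplicated=dupes, remaining_pairs=len(deduped))
    for p in deduped:
        p.dangling = is_dangling(p, dmap)
        counters.dangling_pairs += p.dangling
        cat = classify(p, dmap, thresholds)
        if cat is Category.UNLIGATED:
            counters.unligated += 1
        elif cat is Category.SELF_LIGATED:
            counters.self_ligated += 1
        elif cat is Category.STRANGE_INTERNAL:
            counters.strange_internal += 1
        else:
            counters.chimeric += 1
            if p.is_cis:
                counters.cis += 1
            else:
                counters.trans += 1
            if cat is Category.CHIMERIC_TOO_SHORT:
                counters.chimeric_too_short += 1
            elif cat is Category.CHIMERIC_TOO_LONG:
                counters.chimeric_too_long += 1
            else:
                counters.valid += 1
    return deduped, counters


def write_valid_sam(
    pairs: list[ReadPair],
    segments: list[tuple],
    dmap: DigestMap,
    path: str | Path,
) -> int:
    """Write valid pairs as a paired-end SAM with mate flags set.

    ``segments`` must be the pysam records returned by :func:`re_pair`
    with ``keep_segments=True``, parallel to the *pre-deduplication* pair
    stream; pairs lacking a segment record (e.g. constructed in memory)
    are skipped.  Returns the number of pairs written.
    """
    by_name = {}
    for seg1, seg2 in segments:
        if seg1 is not None:
            by_name[seg1.query_name] = (seg1, seg2)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [
                {"SN": c, "LN": dmap.chromosome_length(c)} for c in dmap.chromosomes
            ],
        }
    )
    written = 0
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for p in pairs:
            if p.category is not Category.VALID or p.name not in by_name:
                continue
            seg1, seg2 = by_name[p.name]
            for mine, mate, first in ((seg1, seg2, True), (seg2, seg1, False)):
                rec = pysam.AlignedSegment(header)
                rec.query_name = mine.query_name
                rec.query_sequence = mine.query_sequence
                rec.query_qualities = mine.query_qualities
                rec.reference_name = mine.reference_name
                rec.reference_start = mine.reference_start
                rec.mapping_quality = mine.mapping_quality
                rec.cigarstring = mine.cigarstring
                rec.is_paired = True
                rec.is_proper_pair = True
                rec.is_read1 = first
                rec.is_read2 = not first
                rec.is_reverse = mine.is_reverse
                rec.mate_is_reverse = mate.is_reverse
                rec.next_reference_name = mate.reference_name
                rec.next_reference_start = mate.reference_start
                out.write(rec)
            written += 1
    return written
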