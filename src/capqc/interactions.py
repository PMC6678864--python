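"""Aggregation of valid pairs into digest-pair interaction counts.

An interaction is a canonically ordered pair of digests together with the
number of valid read pairs supporting it.  Interactions supported by more
than one pair ("non-singletons") feed the NSI quality metric: random
cross-ligations rarely hit the same digest pair twice, so a singleton
excess signals cross-ligation noise.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .digestmap import Digest, DigestMap
from .pairclass import Category, ReadPair

__all__ = [
    "TargetStatus",
    "Interaction",
    "count_interactions",
    "nonsingleton_stats",
    "target_pair_count",
    "write_interactions",
    "read_interactions",
    "INTERACTION_FILE_HEADER",
]

INTERACTION_FILE_HEADER = (
    "chromA\tstartA\tendA\tchromB\tstartB\tendB\tcount\ttargetStatus"
)


class TargetStatus(str, enum.Enum):
    NEITHER = "neither"
    ONE = "one"
    BOTH = "both"


@dataclass(frozen=True)
class Interaction:
    digest_a: Digest
    digest_b: Digest
    count: int
    target_status: TargetStatus

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("interaction count must be >= 1")


def _canonical(d1: Digest, d2: Digest) -> tuple[Digest, Digest]:
    if (d1.chrom, d1.start) <= (d2.chrom, d2.start):
        return d1, d2
    return d2, d1


def _status(a: Digest, b: Digest) -> TargetStatus:
    n = int(a.is_target) + int(b.is_target)
    return (TargetStatus.NEITHER, TargetStatus.ONE, TargetStatus.BOTH)[n]


def count_interactions(
    pairs: Iterable[ReadPair], dmap: DigestMap
) -> list[Interaction]:
    """Tally valid pairs per canonical digest pair.

    Pairs not classified valid are rejected (self pairs never reach this
    stage).  The result is sorted by coordinates, so it is independent of
    read input order.  The sum of counts equals the number of valid pairs.
    """
    tallies: dict[tuple, int] = {}
    digests: dict[tuple, tuple[Digest, Digest]] = {}
    for p in pairs:
        if p.category is not Category.VALID:
            raise ValueError(
                f"pair {p.name!r} has category {p.category}; only valid "
                "pairs are counted as interactions"
            )
        da = dmap.lookup(p.fwd.chrom, p.fwd.five_prime)
        db = dmap.lookup(p.rev.chrom, p.rev.five_prime)
        da, db = _canonical(da, db)
        key = (da.chrom, da.start, db.chrom, db.start)
        tallies[key] = tallies.get(key, 0) + 1
        digests[key] = (da, db)
    return [
        Interaction(*digests[key], count=tallies[key], target_status=_status(*digests[key]))
        for key in sorted(tallies)
    ]


def nonsingleton_stats(interactions: Iterable[Interaction]) -> tuple[int, int]:
    """``(non-singleton read-pair count, singleton interaction count)``.

    The first element — the total read pairs in interactions supported by
    more than one pair — is the NSI numerator.
    """
    nonsingleton_pairs = 0
    singletons = 0
    for ia in interactions:
        if ia.count > 1:
            nonsingleton_pairs += ia.count
        else:
            singletons += 1
    return nonsingleton_pairs, singletons


def target_pair_count(interactions: Iterable[Interaction]) -> int:
    """Read pairs with at least one end on a target-enriched digest."""
    return sum(
        ia.count for ia in interactions if ia.target_status is not TargetStatus.NEITHER
    )


def write_interactions(interactions: list[Interaction], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(INTERACTION_FILE_HEADER + "\n")
        for ia in interactions:
            a, b = ia.digest_a, ia.digest_b
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}\t"
                f"{ia.count}\t{ia.target_status.value}\n"
            )


def read_interactions(path: str | Path) -> list[tuple]:
    """Read an interaction file back as plain tuples (coordinates, count, status)."""
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] != INTERACTION_FILE_HEADER:
        raise ValueError(f"{path}: missing or malformed interaction file header")
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        f = line.split("\t")
        if len(f) != 8:
            raise ValueError(f"{path}, line {lineno}: expected 8 columns")
        rows.append(
            (f[0], int(f[1]), int(f[2]), f[3], int(f[4]), int(f[5]), int(f[6]),
             TargetStatus(f[7]))
        )
    return rows
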