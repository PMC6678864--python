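"""Synthetic Hi-C / Capture-C library simulator with truth labels.

The simulator emulates the wet-lab protocol on a random genome: it digests
the genome in silico, assembles sonication-sized fragments of each ligation
category, and sequences their outermost ends as an error-free paired-end
library.  Every emitted pair carries a truth record (generating category,
source digests, junction offsets within the reads, dangling flags), so
each pipeline stage can be scored against ground truth.

Fragment construction mirrors the chemistry:

* valid ligation (cis or trans): the filled-in (or plain) junction joins
  the 3' end segment of one digest to the 5' end segment of another;
* self-ligation: the two ends of a single digest joined through a
  junction (the sheared circle);
* un-ligated: a contiguous piece of a single digest, optionally starting
  or ending exactly at a restriction site (a dangling end).

Random cross-ligation products are sequence-identical to valid ligations
and are therefore not generated separately.  Reads are error-free: the
simulator exercises classification logic, not mapping robustness.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pysam

from .digestmap import Digest, DigestMap, digest_genome
from .enzymes import (
    BUILTIN_ENZYMES,
    RestrictionEnzyme,
    revcomp,
)

__all__ = [
    "SimConfig",
    "TruthRecord",
    "Fragment",
    "simulate_genome",
    "simulate_fragments",
    "fragments_to_reads",
    "simulate_library",
    "toy_exact_mapper",
    "write_fasta",
    "read_truth_table",
    "write_truth_table",
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a synthetic library.

    Defaults model a small HindIII fill-in Hi-C experiment: two 400 kb
    chromosomes at GC 0.5 (≈100 digests each at the six-cutter mean of
    4096 bp), 100 bp reads, sonication sizes uniform in [150, 500] bp,
    and 10^4 fragments per category.  ``min_interaction_distance`` keeps
    interacting digest pairs far beyond any self-ligation threshold, and
    ``end_margin`` keeps both digest-end segments of a fragment long
    enough that a truncated read always stays mappable.
    """

    chromosome_lengths: tuple[int, ...] = (400_000, 400_000)
    gc_content: float = 0.5
    enzyme: str = "HindIII"
    fill_in: bool = True
    n_valid_cis: int = 10_000
    n_valid_trans: int = 10_000
    n_self_ligated: int = 10_000
    n_unligated: int = 10_000
    shear_dist: str = "uniform"  # "uniform" or "normal"
    shear_min: int = 150
    shear_max: int = 500
    shear_mean: float = 300.0
    shear_sd: float = 60.0
    read_length: int = 100
    min_interaction_distance: int = 10_000
    dangling_fraction: float = 0.5
    end_margin: int = 30
    duplicate_extra: int = 0
    seed: int = 1

    def __post_init__(self) -> None:
        if self.read_length > self.shear_min:
            raise ValueError("read_length must not exceed the minimum shearing size")
        if self.shear_dist not in ("uniform", "normal"):
            raise ValueError(f"unknown shearing distribution {self.shear_dist!r}")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content outside [0, 1]")

    @property
    def enzyme_obj(self) -> RestrictionEnzyme:
        return BUILTIN_ENZYMES[self.enzyme]


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one emitted read pair."""

    name: str
    category: str  # valid_cis | valid_trans | self_ligated | unligated
    chrom_a: str
    digest_a: int
    chrom_b: str
    digest_b: int
    junction_r1: int  # 0-based junction start within R1, -1 if absent
    junction_r2: int
    dangling: bool
    is_duplicate: bool


@dataclass(frozen=True)
class Fragment:
    sequence: str
    truth: TruthRecord


_BASES = np.array(list("ATGC"))


def simulate_genome(config: SimConfig, rng: np.random.Generator) -> list[tuple[str, str]]:
    """Random i.i.d. genome with the configured GC content."""
    gc = config.gc_content
    probs = [(1 - gc) / 2, (1 - gc) / 2, gc / 2, gc / 2]
    genome = []
    for i, length in enumerate(config.chromosome_lengths, start=1):
        seq = "".join(rng.choice(_BASES, size=length, p=probs))
        genome.append((f"chr{i}", seq))
    return genome


def write_fasta(genome: list[tuple[str, str]], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _shear_size(config: SimConfig, rng: np.random.Generator) -> int:
    if config.shear_dist == "uniform":
        return int(rng.integers(config.shear_min, config.shear_max + 1))
    s = int(round(rng.normal(config.shear_mean, config.shear_sd)))
    return max(config.shear_min, min(config.shear_max, s))


def _eligible(dmap: DigestMap, min_len: int) -> dict[str, list[Digest]]:
    """Interior digests (both boundaries are cut sites) of sufficient length."""
    out: dict[str, list[Digest]] = {}
    for chrom in dmap.chromosomes:
        ds = list(dmap.digests(chrom))
        out[chrom] = [d for d in ds[1:-1] if d.length >= min_len]
    return out


def simulate_fragments(
    dmap: DigestMap,
    genome: list[tuple[str, str]],
    config: SimConfig,
    rng: np.random.Generator,
) -> list[Fragment]:
    """Assemble labelled fragments of every category.

    Digests whose requested segment sizes cannot be accommodated are never
    drawn (eligibility is filtered up front); if a chromosome offers no
    eligible digest a ``ValueError`` explains which category failed.
    """
    seqs = dict(genome)
    enz = config.enzyme_obj
    insert = enz.overhang if config.fill_in else ""
    junction_len = len(enz.recognition) + (len(enz.overhang) if config.fill_in else 0)
    margin = config.end_margin
    eligible = _eligible(dmap, config.shear_max + 1)
    all_eligible = [d for ds in eligible.values() for d in ds]
    if not all_eligible:
        raise ValueError("no eligible digests: genome too short or digests too small")

    fragments: list[Fragment] = []
    counter = 0

    def next_name(category: str) -> str:
        nonlocal counter
        counter += 1
        return f"sim{counter:07d}"

    def pick(digests: list[Digest]) -> Digest:
        return digests[int(rng.integers(len(digests)))]

    def chimeric_fragment(da: Digest, db: Digest, category: str) -> Fragment:
        s = _shear_size(config, rng)
        inner = s - len(insert)
        s1 = int(rng.integers(margin, inner - margin + 1))
        s2 = inner - s1
        left = seqs[da.chrom][da.end - s1 : da.end]
        right = seqs[db.chrom][db.start - 1 : db.start - 1 + s2]
        frag = left + insert + right
        j0 = s1 - enz.cut_offset  # junction start within the fragment
        jr1 = j0 if 0 <= j0 and j0 + junction_len <= config.read_length else -1
        tail_start = len(frag) - config.read_length
        jr2_frag_ok = j0 >= tail_start and j0 + junction_len <= len(frag)
        jr2 = (len(frag) - (j0 + junction_len)) if jr2_frag_ok else -1
        truth = TruthRecord(
            next_name(category), category,
            da.chrom, da.index, db.chrom, db.index,
            jr1, jr2, dangling=False, is_duplicate=False,
        )
        return Fragment(frag, truth)

    # valid cis: two digests on one chromosome, far apart
    made = 0
    while made < config.n_valid_cis:
        chrom = dmap.chromosomes[int(rng.integers(len(dmap.chromosomes)))]
        cands = eligible[chrom]
        if len(cands) < 2:
            raise ValueError(f"{chrom}: not enough eligible digests for valid_cis")
        da, db = pick(cands), pick(cands)
        if da.start > db.start:
            da, db = db, da
        if db.start - da.end < config.min_interaction_distance:
            continue
        fragments.append(chimeric_fragment(da, db, "valid_cis"))
        made += 1

    # valid trans: digests on different chromosomes
    if config.n_valid_trans and len(dmap.chromosomes) < 2:
        raise ValueError("valid_trans fragments need at least two chromosomes")
    made = 0
    while made < config.n_valid_trans:
        ca, cb = rng.choice(len(dmap.chromosomes), size=2, replace=False)
        da = pick(eligible[dmap.chromosomes[ca]])
        db = pick(eligible[dmap.chromosomes[cb]])
        fragments.append(chimeric_fragment(da, db, "valid_trans"))
        made += 1

    # self-ligated: both ends of one digest joined through a junction
    for _ in range(config.n_self_ligated):
        d = pick(all_eligible)
        s = _shear_size(config, rng)
        inner = s - len(insert)
        s1 = int(rng.integers(margin, inner - margin + 1))
        s2 = inner - s1
        frag = (
            seqs[d.chrom][d.end - s1 : d.end]
            + insert
            + seqs[d.chrom][d.start - 1 : d.start - 1 + s2]
        )
        j0 = s1 - enz.cut_offset
        jr1 = j0 if j0 + junction_len <= config.read_length else -1
        tail_start = len(frag) - config.read_length
        jr2 = (len(frag) - (j0 + junction_len)) if j0 >= tail_start else -1
        truth = TruthRecord(
            next_name("self_ligated"), "self_ligated",
            d.chrom, d.index, d.chrom, d.index,
            jr1, jr2, dangling=False, is_duplicate=False,
        )
        fragments.append(Fragment(frag, truth))

    # un-ligated: contiguous slice of one digest, possibly at a boundary
    for _ in range(config.n_unligated):
        d = pick(all_eligible)
        s = _shear_size(config, rng)
        if rng.random() < config.dangling_fraction:
            offset = 0 if rng.random() < 0.5 else d.length - s
        else:
            offset = int(rng.integers(0, d.length - s + 1))
        start0 = d.start - 1 + offset
        frag = seqs[d.chrom][start0 : start0 + s]
        dangling = offset == 0 or offset + s == d.length
        truth = TruthRecord(
            next_name("unligated"), "unligated",
            d.chrom, d.index, d.chrom, d.index,
            -1, -1, dangling=dangling, is_duplicate=False,
        )
        fragments.append(Fragment(frag, truth))

    # duplicates: re-emit already-generated fragments
    for _ in range(config.duplicate_extra):
        src = fragments[int(rng.integers(len(fragments)))]
        truth = dataclasses.replace(
            src.truth, name=next_name("dup"), is_duplicate=True
        )
        fragments.append(Fragment(src.sequence, truth))

    return fragments


def fragments_to_reads(
    fragments: list[Fragment],
    read_length: int,
    rng: np.random.Generator | None = None,
) -> tuple[list[tuple[str, str, str]], list[tuple[str, str, str]], list[TruthRecord]]:
    """Sequence the two outermost ends of every fragment.

    R1 is the fragment's first ``read_length`` bases, R2 the reverse
    complement of its last ``read_length`` bases (overlapping when the
    fragment is shorter than twice the read length).  When an ``rng`` is
    given, each fragment is flipped to the opposite strand with
    probability 0.5 before sequencing — a sheared molecule has no
    preferred orientation — which swaps the junction offsets accordingly.
    Qualities are uniform maximum.
    """
    r1s, r2s, truths = [], [], []
    for frag in fragments:
        seq, truth = frag.sequence, frag.truth
        if rng is not None and rng.random() < 0.5:
            seq = revcomp(seq)
            truth = dataclasses.replace(
                truth,
                chrom_a=truth.chrom_b, digest_a=truth.digest_b,
                chrom_b=truth.chrom_a, digest_b=truth.digest_a,
                junction_r1=truth.junction_r2, junction_r2=truth.junction_r1,
            )
        r1 = seq[:read_length]
        r2 = revcomp(seq[-read_length:])
        r1s.append((truth.name, r1, "I" * len(r1)))
        r2s.append((truth.name, r2, "I" * len(r2)))
        truths.append(truth)
    return r1s, r2s, truths


def simulate_library(
    config: SimConfig,
) -> tuple[
    list[tuple[str, str]],
    DigestMap,
    list[tuple[str, str, str]],
    list[tuple[str, str, str]],
    list[TruthRecord],
]:
    """Genome → digest map → fragments → reads, all from one seed."""
    rng = np.random.default_rng(config.seed)
    genome = simulate_genome(config, rng)
    dmap = digest_genome(genome, [config.enzyme_obj], genome_id=f"sim(seed={config.seed})")
    frags = simulate_fragments(dmap, genome, config, rng)
    r1, r2, truth = fragments_to_reads(frags, config.read_length, rng)
    return genome, dmap, r1, r2, truth


# ---------------------------------------------------------------------------
# truth table io

_TRUTH_HEADER = (
    "name\tcategory\tchromA\tdigestA\tchromB\tdigestB\t"
    "junctionR1\tjunctionR2\tdangling\tduplicate"
)


def write_truth_table(truths: list[TruthRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_TRUTH_HEADER + "\n")
        for t in truths:
            fh.write(
                f"{t.name}\t{t.category}\t{t.chrom_a}\t{t.digest_a}\t"
                f"{t.chrom_b}\t{t.digest_b}\t{t.junction_r1}\t{t.junction_r2}\t"
                f"{int(t.dangling)}\t{int(t.is_duplicate)}\n"
            )


def read_truth_table(path: str | Path) -> list[TruthRecord]:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] != _TRUTH_HEADER:
        raise ValueError(f"{path}: malformed truth table header")
    out = []
    for line in lines[1:]:
        f = line.split("\t")
        out.append(
            TruthRecord(
                f[0], f[1], f[2], int(f[3]), f[4], int(f[5]),
                int(f[6]), int(f[7]), bool(int(f[8])), bool(int(f[9])),
            )
        )
    return out


# ---------------------------------------------------------------------------
# toy exact-match mapper

class ToyMapper:
    """Exact-substring single-end mapper for fixtures.

    Indexes every genomic k-mer; a read maps wherever the full read (or
    its reverse complement) occurs verbatim.  Unique hits become mapped
    records, multiple hits a primary plus secondary records (MAPQ 0), no
    hit an unmapped record.  Deterministic: hits are ordered by
    (chromosome order, position, strand).
    """

    def __init__(self, genome: list[tuple[str, str]], k: int = 20) -> None:
        self.genome = genome
        self.k = k
        self.index: dict[str, list[tuple[int, int]]] = {}
        for ci, (_, seq) in enumerate(genome):
            for p in range(len(seq) - k + 1):
                self.index.setdefault(seq[p : p + k], []).append((ci, p))

    def _hits(self, read: str) -> list[tuple[int, int, bool]]:
        """All exact occurrences as ``(chrom index, 0-based pos, is_reverse)``."""
        hits = []
        for query, rev in ((read, False), (revcomp(read), True)):
            if len(query) >= self.k:
                for ci, p in self.index.get(query[: self.k], ()):
                    if self.genome[ci][1].startswith(query, p):
                        hits.append((ci, p, rev))
            else:  # short query: direct scan (rare; only sub-k reads)
                for ci, (_, seq) in enumerate(self.genome):
                    i = seq.find(query)
                    while i != -1:
                        hits.append((ci, i, rev))
                        i = seq.find(query, i + 1)
        return sorted(hits)

    def map_reads(
        self, reads: list[tuple[str, str, str]], out_sam: str | Path
    ) -> None:
        header = pysam.AlignmentHeader.from_dict(
            {
                "HD": {"VN": "1.6", "SO": "unsorted"},
                "SQ": [{"SN": name, "LN": len(seq)} for name, seq in self.genome],
            }
        )
        with pysam.AlignmentFile(str(out_sam), "w", header=header) as out:
            for name, seq, qual in reads:
                hits = self._hits(seq)
                if not hits:
                    rec = pysam.AlignedSegment(header)
                    rec.query_name = name
                    rec.query_sequence = seq
                    rec.query_qualities = pysam.qualitystring_to_array(qual)
                    rec.is_unmapped = True
                    out.write(rec)
                    continue
                mapq = 60 if len(hits) == 1 else 0
                for rank, (ci, pos, rev) in enumerate(hits):
                    rec = pysam.AlignedSegment(header)
                    rec.query_name = name
                    rec.query_sequence = revcomp(seq) if rev else seq
                    rec.query_qualities = pysam.qualitystring_to_array(
                        qual[::-1] if rev else qual
                    )
                    rec.reference_id = ci
                    rec.reference_start = pos
                    rec.cigarstring = f"{len(seq)}M"
                    rec.mapping_quality = mapq
                    rec.is_reverse = rev
                    rec.is_secondary = rank > 0
                    out.write(rec)


def toy_exact_mapper(
    reads: list[tuple[str, str, str]] | str | Path,
    genome: list[tuple[str, str]],
    out_sam: str | Path,
    k: int = 20,
) -> None:
    """Map a FASTQ file or in-memory reads against ``genome``; write SAM."""
    if not isinstance(reads, list):
        from .truncate import read_fastq

        reads = list(read_fastq(reads))
    ToyMapper(genome, k=k).map_reads(reads, out_sam)
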