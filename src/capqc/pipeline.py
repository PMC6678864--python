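"""End-to-end composition of the pre-processing stages.

``run_pipeline`` chains truncation → mapping → re-pairing → deduplication
→ classification → interaction counting → QC report, writing each stage's
output files plus a JSON counter sidecar.  Running stages individually
(via the CLI subcommands or the stage functions) produces byte-identical
outputs: every stage is a pure function of its inputs and the seed.

Alignment is an external concern: pass pre-mapped single-end SAM/BAM
streams from a real aligner (bowtie2 in single-end mode), or let the
bundled exact-match toy mapper handle synthetic fixtures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from . import truncate as trunc_mod
from .digestmap import DigestMap, annotate_targets, digest_genome, write_digest_file
from .enzymes import RestrictionEnzyme, junction_specs
from .interactions import (
    count_interactions,
    nonsingleton_stats,
    target_pair_count,
    write_interactions,
)
from .metrics import QCReport, render_report_json, render_report_text
from .pairclass import Thresholds, classify_pairs, re_pair, write_valid_sam
from .simulate import toy_exact_mapper

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    report: QCReport
    digest_map: DigestMap
    n_interactions: int
    outdir: Path


def run_pipeline(
    genome: list[tuple[str, str]] | str | Path,
    fastq1: str | Path,
    fastq2: str | Path,
    enzymes: list[RestrictionEnzyme],
    outdir: str | Path,
    fill_in: bool = True,
    thresholds: Thresholds = Thresholds(),
    min_length: int = trunc_mod.DEFAULT_MIN_LENGTH,
    keep_remnant: bool = True,
    targets: str | Path | list | None = None,
    sam_fwd: str | Path | None = None,
    sam_rev: str | Path | None = None,
    digest_map: DigestMap | None = None,
) -> PipelineResult:
    """Run the full pipeline; returns the QC report and writes all outputs.

    When ``sam_fwd``/``sam_rev`` are given they must be single-end
    alignments of the *truncated* reads this call produces (external
    aligner workflow); otherwise the toy exact mapper maps the truncated
    reads against ``genome``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if digest_map is None:
        digest_map = digest_genome(genome, enzymes)
    if targets is not None:
        digest_map = annotate_targets(digest_map, targets)
    write_digest_file(digest_map, outdir / "digests.tsv")

    # 1. truncation
    junctions = junction_specs(enzymes, fill_in)
    t1, t2 = outdir / "truncated_R1.fastq", outdir / "truncated_R2.fastq"
    tcounters = trunc_mod.process_fastq_pair(
        fastq1, fastq2, junctions, t1, t2,
        min_length=min_length, keep_remnant=keep_remnant,
    )
    (outdir / "truncation.json").write_text(
        json.dumps(tcounters.to_dict(), indent=2, sort_keys=True) + "\n"
    )

    # 2. mapping (external or toy)
    if sam_fwd is None or sam_rev is None:
        if isinstance(genome, (str, Path)):
            from Bio import SeqIO

            genome = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(genome, "fasta")]
        sam_fwd, sam_rev = outdir / "mapped_R1.sam", outdir / "mapped_R2.sam"
        toy_exact_mapper(t1, genome, sam_fwd)
        toy_exact_mapper(t2, genome, sam_rev)

    # 3. re-pairing, deduplication, classification
    pairs, rcounters, segments = re_pair(
        sam_fwd, sam_rev, min_mapq=thresholds.min_mapq, keep_segments=True
    )
    deduped, ccounters = classify_pairs(pairs, digest_map, thresholds)
    write_valid_sam(deduped, segments, digest_map, outdir / "valid_pairs.sam")

    # 4. interactions
    from .pairclass import Category

    valid_pairs = [p for p in deduped if p.category is Category.VALID]
    ias = count_interactions(valid_pairs, digest_map)
    write_interactions(ias, outdir / "interactions.tsv")
    nonsingleton_pairs, _ = nonsingleton_stats(ias)

    # 5. report
    report = QCReport(
        total_raw_pairs=tcounters.total_pairs,
        removed_by_truncation=tcounters.pairs_removed_short,
        unmapped_multimapped=rcounters.unmapped_pairs + rcounters.multimapped_pairs,
        duplicated=ccounters.duplicated,
        remaining_pairs=ccounters.remaining_pairs,
        dangling_pairs=ccounters.dangling_pairs,
        unligated=ccounters.unligated,
        self_ligated=ccounters.self_ligated,
        strange_internal=ccounters.strange_internal,
        chimeric=ccounters.chimeric,
        chimeric_too_short=ccounters.chimeric_too_short,
        chimeric_too_long=ccounters.chimeric_too_long,
        valid=ccounters.valid,
        cis=ccounters.cis,
        trans=ccounters.trans,
        nonsingleton_pairs=nonsingleton_pairs,
        target_pairs=target_pair_count(ias),
        has_targets=targets is not None,
    )
    report.validate()
    (outdir / "qc_report.json").write_text(render_report_json(report))
    (outdir / "qc_report.txt").write_text(render_report_text(report))
    return PipelineResult(report, digest_map, len(ias), outdir)
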