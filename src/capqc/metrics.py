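"""Quality metrics and QC report rendering.

All metrics are pure functions of pipeline counters: the same counter set
always renders byte-identical reports.  Percentages and ratios are
rounded half-up to two decimals, matching the way such QC tables are
customarily printed.

Global metrics
--------------
YCP
    yield of chimeric pairs — chimeric pairs as a percentage of raw input
    pairs; the overall efficiency of the protocol.
cis:trans ratio
    cis over trans chimeric pairs; a low ratio indicates a high degree of
    random cross-ligation.
NSI
    non-singleton index — read pairs belonging to interactions with more
    than one supporting pair, as a percentage of chimeric pairs.
TEC
    target enrichment coefficient — chimeric pairs with at least one read
    on a target-enriched digest, as a percentage of chimeric pairs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Optional

from .digestmap import DigestMap
from .pairclass import ReadPair

__all__ = [
    "QCReport",
    "pct",
    "ratio2",
    "ycp",
    "cis_trans_ratio",
    "nsi",
    "yield_nonsingleton",
    "tec",
    "trans_by_chromosome",
    "render_report_text",
    "render_report_json",
    "report_from_json",
]


def _round2(x: Decimal) -> float:
    return float(x.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def pct(numerator: int, denominator: int) -> float:
    """``100 * numerator / denominator`` rounded half-up to 2 decimals (0 if empty)."""
    if denominator == 0:
        return 0.0
    return _round2(Decimal(100 * numerator) / Decimal(denominator))


def ratio2(numerator: int, denominator: int) -> Optional[float]:
    """``numerator / denominator`` to 2 decimals; ``None`` (NA) when denominator is 0."""
    if denominator == 0:
        return None
    return _round2(Decimal(numerator) / Decimal(denominator))


def ycp(chimeric: int, total_raw: int) -> float:
    """Yield of chimeric pairs: chimeric as % of raw input read pairs."""
    return pct(chimeric, total_raw)


def cis_trans_ratio(cis: int, trans: int) -> Optional[float]:
    """cis / trans ratio of chimeric pairs; NA (None) when trans is 0."""
    return ratio2(cis, trans)


def nsi(nonsingleton_pairs: int, chimeric: int) -> float:
    """Non-singleton index: non-singleton pairs as % of chimeric pairs."""
    return pct(nonsingleton_pairs, chimeric)


def yield_nonsingleton(nonsingleton_pairs: int, total_raw: int) -> float:
    """Non-singleton pairs as % of raw input read pairs."""
    return pct(nonsingleton_pairs, total_raw)


def tec(target_pairs: int, chimeric: int) -> float:
    """Target enrichment coefficient: % of chimeric pairs touching a target digest."""
    return pct(target_pairs, chimeric)


@dataclass
class QCReport:
    """All pipeline counters plus the derived global metrics.

    Invariants (checked by :meth:`validate`): the remaining pairs equal
    raw input minus truncation/mapping/duplication losses; the four
    categories partition the remaining pairs; cis + trans = chimeric.
    """

    total_raw_pairs: int = 0
    removed_by_truncation: int = 0
    unmapped_multimapped: int = 0
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
    nonsingleton_pairs: int = 0
    target_pairs: int = 0
    has_targets: bool = False

    def validate(self) -> None:
        expected_remaining = (
            self.total_raw_pairs
            - self.removed_by_truncation
            - self.unmapped_multimapped
            - self.duplicated
        )
        if self.remaining_pairs != expected_remaining:
            raise ValueError(
                f"remaining_pairs {self.remaining_pairs} != "
                f"total - losses {expected_remaining}"
            )
        cats = self.unligated + self.self_ligated + self.strange_internal + self.chimeric
        if cats != self.remaining_pairs:
            raise ValueError(
                f"categories sum to {cats}, not remaining_pairs {self.remaining_pairs}"
            )
        if self.cis + self.trans != self.chimeric:
            raise ValueError(
                f"cis {self.cis} + trans {self.trans} != chimeric {self.chimeric}"
            )

    # derived metrics -------------------------------------------------
    @property
    def ycp(self) -> float:
        return ycp(self.chimeric, self.total_raw_pairs)

    @property
    def ycp_valid(self) -> float:
        """YCP with only size-valid chimeric pairs in the numerator."""
        return ycp(self.valid, self.total_raw_pairs)

    @property
    def cis_trans_ratio(self) -> Optional[float]:
        return cis_trans_ratio(self.cis, self.trans)

    @property
    def nsi(self) -> float:
        return nsi(self.nonsingleton_pairs, self.chimeric)

    @property
    def yield_nonsingleton(self) -> float:
        return yield_nonsingleton(self.nonsingleton_pairs, self.total_raw_pairs)

    @property
    def tec(self) -> Optional[float]:
        if not self.has_targets:
            return None
        return tec(self.target_pairs, self.chimeric)


def trans_by_chromosome(
    pairs: Iterable[ReadPair], dmap: DigestMap
) -> list[tuple[str, int, float]]:
    """Per-chromosome trans fraction vs. digest count.

    For every chromosome: the number of digests, and the fraction of
    chimeric pairs touching the chromosome that are trans.  Small
    chromosomes are expected to show larger trans fractions (roughly
    linear in digest count), so deviations flag cross-ligation problems.
    Sorted by digest count.
    """
    touch: dict[str, int] = {c: 0 for c in dmap.chromosomes}
    trans: dict[str, int] = {c: 0 for c in dmap.chromosomes}
    for p in pairs:
        if p.is_cis is None:
            continue
        chroms = {p.fwd.chrom, p.rev.chrom}
        for c in chroms:
            touch[c] += 1
            if not p.is_cis:
                trans[c] += 1
    table = [
        (c, dmap.n_digests(c), (trans[c] / touch[c]) if touch[c] else 0.0)
        for c in dmap.chromosomes
    ]
    return sorted(table, key=lambda row: (row[1], row[0]))


def plot_trans_by_chromosome(table: list[tuple[str, int, float]], path) -> None:
    """Scatter of per-chromosome trans fraction vs. digest count (needs matplotlib).

    On a healthy library the points fall on a roughly linear trend with
    the largest chromosomes showing the smallest trans fractions.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    xs = [n for _, n, _ in table]
    ys = [f for _, _, f in table]
    ax.scatter(xs, ys)
    for chrom, n, f in table:
        ax.annotate(chrom, (n, f), fontsize=7, xytext=(2, 2), textcoords="offset points")
    ax.set_xlabel("restriction digests per chromosome")
    ax.set_ylabel("trans fraction of chimeric pairs")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


# ---------------------------------------------------------------------------
# rendering

def _fmt_ratio(x: Optional[float]) -> str:
    return "n/a" if x is None else f"{x:.2f}"


def render_report_text(report: QCReport) -> str:
    """Human-readable summary mirroring the standard QC table layout."""
    r = report
    lines = [
        "Truncation, Mapping and Deduplication",
        f"  Total raw read pairs    {r.total_raw_pairs:>15,}",
        f"  Removed by truncation   {r.removed_by_truncation:>15,}  "
        f"{pct(r.removed_by_truncation, r.total_raw_pairs):.2f}%",
        f"  Unmapped/multimapped    {r.unmapped_multimapped:>15,}  "
        f"{pct(r.unmapped_multimapped, r.total_raw_pairs):.2f}%",
        f"  Duplicated              {r.duplicated:>15,}  "
        f"{pct(r.duplicated, r.total_raw_pairs):.2f}%",
        f"  Remaining pairs         {r.remaining_pairs:>15,}  "
        f"{pct(r.remaining_pairs, r.total_raw_pairs):.2f}%",
        f"  Dangling ends           {r.dangling_pairs:>15,}  "
        f"{pct(r.dangling_pairs, r.total_raw_pairs):.2f}%",
        "Categorization of re-paired read pairs",
        f"  Un-ligated              {r.unligated:>15,}  "
        f"{pct(r.unligated, r.remaining_pairs):.2f}%",
        f"  Self-ligated            {r.self_ligated:>15,}  "
        f"{pct(r.self_ligated, r.remaining_pairs):.2f}%",
        f"  Strange internal        {r.strange_internal:>15,}  "
        f"{pct(r.strange_internal, r.remaining_pairs):.2f}%",
        f"  Chimeric                {r.chimeric:>15,}  "
        f"{pct(r.chimeric, r.remaining_pairs):.2f}%",
        "Analysis of chimeric read pairs",
        f"  Trans                   {r.trans:>15,}  {pct(r.trans, r.chimeric):.2f}%",
        f"  Cis                     {r.cis:>15,}  {pct(r.cis, r.chimeric):.2f}%",
        f"  Too short (< min size)  {r.chimeric_too_short:>15,}",
        f"  Too long (> max size)   {r.chimeric_too_long:>15,}",
        f"  Valid                   {r.valid:>15,}",
        f"  Non-singleton pairs     {r.nonsingleton_pairs:>15,}  {r.nsi:.2f}%",
        "Global quality metrics",
        f"  Yield of chimeric pairs (YCP)   {r.ycp:.2f}%",
        f"  YCP (size-valid only)           {r.ycp_valid:.2f}%",
        f"  cis:trans ratio                 {_fmt_ratio(r.cis_trans_ratio)}",
        f"  Yield of non-singleton pairs    {r.yield_nonsingleton:.2f}%",
        f"  Target enrichment (TEC)         "
        + ("n/a" if r.tec is None else f"{r.tec:.2f}%"),
    ]
    return "\n".join(lines) + "\n"


def render_report_json(report: QCReport) -> str:
    """Machine-readable report; counters plus derived metrics, round-trips."""
    payload = {
        "counters": asdict(report),
        "metrics": {
            "ycp": report.ycp,
            "ycp_valid": report.ycp_valid,
            "cis_trans_ratio": report.cis_trans_ratio,
            "nsi": report.nsi,
            "yield_nonsingleton": report.yield_nonsingleton,
            "tec": report.tec,
        },
    }
    return json.dumps(payload, indent=2, sort_keys=True) + "\n"


def report_from_json(text: str) -> QCReport:
    payload = json.loads(text)
    return QCReport(**payload["counters"])
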