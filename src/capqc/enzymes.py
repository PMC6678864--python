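"""Restriction-enzyme model and ligation-junction construction.

A restriction enzyme is described by its palindromic recognition sequence
and the 0-based offset of the top-strand cut within that sequence.  Only
5'-overhang and blunt cutters are supported (``cut_offset`` at most half
the site length); this covers the enzymes used in practice for Hi-C and
Capture-C (HindIII, DpnII, MboI, ...).

Cutting a palindromic site at ``cut_offset`` splits it into three parts::

    recognition = flank5 + overhang + flank3

with ``flank5`` and ``flank3`` of equal length ``cut_offset``.  After
digestion, the upstream fragment ends with ``flank5`` and the downstream
fragment begins with ``overhang + flank3``.  Blunt re-ligation of
filled-in sticky ends therefore creates the sequence

    flank5 + overhang + overhang + flank3

(two consecutive copies of the overhang; ``AAGCTAGCTT`` for HindIII),
whereas re-annealing without fill-in restores the plain recognition site.
These junction sequences are what the truncation stage searches for.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "RestrictionEnzyme",
    "BUILTIN_ENZYMES",
    "get_enzyme",
    "parse_enzyme_spec",
    "fill_in_junction",
    "plain_junction",
    "junction_set",
    "find_sites",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A palindromic restriction enzyme with a 5' overhang or blunt cut.

    Parameters
    ----------
    name
        Enzyme name, e.g. ``"HindIII"``.
    recognition
        Recognition sequence over {A,C,G,T}; must equal its own reverse
        complement.
    cut_offset
        0-based position of the top-strand cut within ``recognition``.
        Must satisfy ``0 <= cut_offset <= len(recognition) / 2``; values
        above the midpoint would describe a 3' overhang, which is not
        supported.
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        rec = self.recognition.upper()
        object.__setattr__(self, "recognition", rec)
        if not rec:
            raise ValueError(f"{self.name}: empty recognition sequence")
        if set(rec) - set("ACGT"):
            raise ValueError(
                f"{self.name}: recognition sequence {rec!r} contains "
                "characters outside A/C/G/T (IUPAC ambiguity codes are "
                "not supported)"
            )
        if revcomp(rec) != rec:
            raise ValueError(
                f"{self.name}: recognition sequence {rec!r} is not "
                "palindromic; only palindromic enzymes are supported"
            )
        if not 0 <= self.cut_offset <= len(rec) / 2:
            raise ValueError(
                f"{self.name}: cut offset {self.cut_offset} outside "
                f"[0, {len(rec) / 2:g}]; 3'-overhang enzymes are not "
                "supported"
            )

    @property
    def overhang(self) -> str:
        """Single-stranded 5' overhang left by the cut (may be empty)."""
        return self.recognition[self.cut_offset : len(self.recognition) - self.cut_offset]

    @property
    def flank5(self) -> str:
        """Part of the site upstream of the top-strand cut."""
        return self.recognition[: self.cut_offset]

    @property
    def flank3(self) -> str:
        """Part of the site downstream of the bottom-strand cut."""
        return self.recognition[len(self.recognition) - self.cut_offset :]

    @property
    def is_blunt(self) -> bool:
        return not self.overhang


#: Enzymes shipped with the package; others can be declared in config.
BUILTIN_ENZYMES: dict[str, RestrictionEnzyme] = {
    "HindIII": RestrictionEnzyme("HindIII", "AAGCTT", 1),
    "DpnII": RestrictionEnzyme("DpnII", "GATC", 0),
}


def get_enzyme(name: str) -> RestrictionEnzyme:
    """Look up a built-in enzyme by (case-insensitive) name."""
    for key, enz in BUILTIN_ENZYMES.items():
        if key.lower() == name.lower():
            return enz
    raise KeyError(
        f"unknown enzyme {name!r}; built-ins are "
        f"{sorted(BUILTIN_ENZYMES)} — declare others as NAME:SITE:OFFSET"
    )


def parse_enzyme_spec(spec: str) -> RestrictionEnzyme:
    """Parse ``NAME:SITE:OFFSET`` (or a bare built-in name) into an enzyme."""
    if ":" not in spec:
        return get_enzyme(spec)
    parts = spec.split(":")
    if len(parts) != 3:
        raise ValueError(f"enzyme spec {spec!r} is not NAME:SITE:OFFSET")
    name, site, offset = parts
    return RestrictionEnzyme(name, site, int(offset))


def fill_in_junction(enzyme: RestrictionEnzyme) -> str:
    """Ligation-junction sequence after biotin fill-in (Hi-C, CHC).

    The filled-in, blunt-ligated junction carries two consecutive copies
    of the overhang: ``flank5 + overhang + overhang + flank3``.  For a
    blunt cutter this degenerates to the plain recognition site.

    >>> fill_in_junction(BUILTIN_ENZYMES["HindIII"])
    'AAGCTAGCTT'
    """
    return enzyme.flank5 + enzyme.overhang + enzyme.overhang + enzyme.flank3


def plain_junction(enzyme: RestrictionEnzyme) -> str:
    """Ligation-junction sequence without fill-in (Capture-C).

    Sticky ends re-anneal directly, so the junction is indistinguishable
    from a plain recognition site.
    """
    return enzyme.recognition


@dataclass(frozen=True)
class Junction:
    """A junction sequence with the retention bookkeeping truncation needs.

    ``keep_fill_in`` / ``keep_plain`` give, relative to the junction start
    within a read, how many bases belong to the upstream fragment's
    reconstructed end (``flank5 + overhang`` after fill-in, ``flank5``
    otherwise).
    """

    sequence: str
    cut_offset: int
    overhang_length: int
    fill_in: bool

    @property
    def keep_length(self) -> int:
        """Bases of the junction retained with the upstream fragment."""
        if self.fill_in:
            return self.cut_offset + self.overhang_length
        return self.cut_offset


def junction_set(
    enzymes: list[RestrictionEnzyme] | tuple[RestrictionEnzyme, ...],
    fill_in: bool,
) -> set[str]:
    """All junction sequences to search for during truncation.

    With fill-in, every ordered pair of enzymes (A, B) can form a hybrid
    junction ``flank5_A + overhang_A + overhang_B + flank3_B`` (the blunt
    ligation of A's filled upstream end with B's filled downstream end).
    Without fill-in only the plain recognition sites occur.
    """
    return {j.sequence for j in junction_specs(enzymes, fill_in)}


def junction_specs(
    enzymes: list[RestrictionEnzyme] | tuple[RestrictionEnzyme, ...],
    fill_in: bool,
) -> list[Junction]:
    """Like :func:`junction_set` but keeping per-junction retention info.

    When distinct enzyme pairs yield the same sequence, the spec with the
    smallest retained length wins (conservative, deterministic).
    """
    if not enzymes:
        raise ValueError("at least one enzyme is required")
    specs: dict[str, Junction] = {}
    if fill_in:
        for a in enzymes:
            for b in enzymes:
                seq = a.flank5 + a.overhang + b.overhang + b.flank3
                j = Junction(seq, a.cut_offset, len(a.overhang), True)
                if seq not in specs or j.keep_length < specs[seq].keep_length:
                    specs[seq] = j
    else:
        for a in enzymes:
            seq = a.recognition
            j = Junction(seq, a.cut_offset, len(a.overhang), False)
            if seq not in specs or j.keep_length < specs[seq].keep_length:
                specs[seq] = j
    return sorted(specs.values(), key=lambda j: j.sequence)


def find_sites(sequence: str, enzyme: RestrictionEnzyme) -> list[int]:
    """0-based inter-base cut coordinates in ``sequence`` for ``enzyme``.

    A cut coordinate ``c`` means the enzyme cuts between base ``c-1`` and
    base ``c`` (0-based), i.e. ``c = site_index + cut_offset`` for every
    occurrence of the recognition sequence.  Overlapping occurrences all
    count; ``N`` never matches.
    """
    seq = sequence.upper()
    rec = enzyme.recognition
    cuts: list[int] = []
    i = seq.find(rec)
    while i != -1:
        cuts.append(i + enzyme.cut_offset)
        i = seq.find(rec, i + 1)
    return cuts
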