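"""Orientation, fragment sizes and artefact classification of read pairs.

Classifies hand-built pairs on a small digest map and prints the sizes
(lu, lr, ls) the decisions rest on.
"""

from capqc.digestmap import Digest, DigestMap
from capqc.pairclass import MappedRead, ReadPair, Thresholds, classify, orientation

# one chromosome, digests (1,1000) (1001,2000) (2001,8000) (8001,20000)
dmap = DigestMap(
    Digest("chr1", s, e, i, 0.5)
    for i, (s, e) in enumerate([(1, 1000), (1001, 2000), (2001, 8000), (8001, 20000)], 1)
)
thresholds = Thresholds()  # un-ligated <= 1000, self-ligated <= 3000, valid lr in [50, 1000]

cases = {
    "inward, same digest": ReadPair(
        MappedRead("a", "chr1", 1100, "+"), MappedRead("a", "chr1", 1900, "-")),
    "outward, same digest": ReadPair(
        MappedRead("b", "chr1", 1900, "+"), MappedRead("b", "chr1", 1100, "-")),
    "inward, distant digests": ReadPair(
        MappedRead("c", "chr1", 1800, "+"), MappedRead("c", "chr1", 8400, "-")),
    "same strand, same digest": ReadPair(
        MappedRead("d", "chr1", 1100, "+"), MappedRead("d", "chr1", 1900, "+")),
}

for label, pair in cases.items():
    cat = classify(pair, dmap, thresholds)
    print(f"{label:28s} -> {cat.value:16s} "
          f"(orientation={orientation(pair).value}, lu={pair.lu}, "
          f"lr={pair.lr}, ls={pair.ls})")
# Inward pairs confined to one digest never saw a ligation: un-ligated.
# Outward pairs on one digest come from a circularized digest: self-ligated.
# Distant inward pairs with a valid ligation size are the Hi-C signal.
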