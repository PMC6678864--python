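"""Restriction enzymes, ligation junctions and in-silico digestion.

Builds the junction sequences searched for during read truncation and
digests a toy chromosome into its restriction digests.
"""

from capqc import BUILTIN_ENZYMES, digest_genome, fill_in_junction, plain_junction

hindiii = BUILTIN_ENZYMES["HindIII"]
dpnii = BUILTIN_ENZYMES["DpnII"]

print("HindIII site:", hindiii.recognition, "overhang:", hindiii.overhang)
print("Hi-C / CHC junction (biotin fill-in):", fill_in_junction(hindiii))
print("Capture-C junction (no fill-in, DpnII):", plain_junction(dpnii))
# The fill-in junction carries two consecutive overhang copies, so it is
# longer and more specific than the plain site - fewer chance matches
# means fewer reads lost to truncation.

dmap = digest_genome([("toy", "ACGAAGCTTGGAAGCTTAC")], [hindiii])
print("\ndigest map of ACGAAGCTTGGAAGCTTAC (HindIII cuts A^AGCTT):")
for d in dmap.digests():
    print(f"  digest {d.index}: {d.chrom}:{d.start}-{d.end}  "
          f"len={d.length}  GC={d.gc_fraction:.2f}")
# Each digest is the interval between two cuts; digest boundaries are the
# coordinate system for all downstream artefact classification.
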