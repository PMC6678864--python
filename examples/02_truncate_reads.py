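"""Junction truncation of chimeric reads.

A read sequenced across a ligation junction carries sequence from two
genomic loci and cannot be mapped as-is; it is cut back to the first
fragment's reconstructed end.
"""

from capqc.enzymes import BUILTIN_ENZYMES, junction_specs
from capqc.truncate import truncate_read

junctions = junction_specs([BUILTIN_ENZYMES["HindIII"]], fill_in=True)

chimeric = "TTTTAAGCTAGCTTGGGG"  # junction AAGCTAGCTT starts at index 4
res = truncate_read(chimeric, "I" * len(chimeric), junctions)
print(f"chimeric read : {chimeric}")
print(f"truncated to  : {res.sequence}  ({res.retained_length} bp, "
      f"truncated={res.was_truncated})")
# The retained 3' end "AAGCT" (flank + overhang) is genomic sequence of
# the first digest, so the truncated read still maps to its true origin.

genomic = "ACGTACGTACGTACGTAC"
res = truncate_read(genomic, "I" * len(genomic), junctions)
print(f"\ngenomic read  : {genomic}")
print(f"unchanged     : {res.sequence}  (truncated={res.was_truncated})")
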