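"""Load a raw Y-STR table and apply the standard locus conventions.

Builds a small CSV in a temp directory, then: derives the DYS389b repeat
block from the composite DYS389II reading, orders the duplicated DYS385
alleles (shorter one to DYS385a), and excludes records with missing or
intermediate alleles.
"""

import tempfile
from pathlib import Path

from ystr_founder import derive_dys389b, filter_discrete, normalize_dys385, read_table

RAW = """sample_id,population,DYS19,DYS385a,DYS385b,DYS389I,DYS389II,DYS390
a1,Harbor,14,14,11,13,29,23
a2,Harbor,15,11,14,12,28,24
a3,Harbor,14,12,15,13,30,23.2
a4,Uplands,14,13,13,13,29,
"""

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "raw.csv"
    path.write_text(RAW)
    ds = read_table(path)

ds = derive_dys389b(ds)     # DYS389b = DYS389II - DYS389I, composite dropped
ds = normalize_dys385(ds)   # shorter allele -> DYS385a
ds, report = filter_discrete(ds)

print("retained records:", ds.n, "of 4")
print("loci:", ", ".join(ds.locus_names))
print("exclusions:")
print(report.to_string(index=False))
# a3 carries an intermediate allele (23.2) and a4 a missing value: both
# excluded, never rounded or imputed.  a1's DYS385 pair (14, 11) is
# reordered to (11, 14); everyone's DYS389b is the distal block (e.g. 16
# for 29 - 13).
print("a1 haplotype:", dict(zip(ds.locus_names, ds.haplotypes()[0])))
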