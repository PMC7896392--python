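"""Infer an adapter sequence from the unmapped parts of reads.

Reads whose fragment is shorter than the read length run into the adapter;
its 10-mers dominate the unmapped read tails and seed-and-extend recovers
the sequence without any catalogue.
"""

import numpy as np

from readsmith.adapters import collect_unmapped_kmers, infer_adapter
from readsmith.records import ReadRecord

TRUSEQ = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"

rng = np.random.default_rng(1)
reads = []
for i in range(500):
    stem = "".join("ACGT"[j] for j in rng.integers(0, 4, size=30))
    reads.append(ReadRecord(
        segment=0, name=f"r{i}", bases=stem + TRUSEQ + "A" * 10,
        qualities=[30] * (30 + len(TRUSEQ) + 10),
        mapped=True, fragment_length=30,
    ))

table = collect_unmapped_kmers(reads)
inferred = infer_adapter(table, segment=0)
print(f"reads considered: {table.considered[0]}")
print(f"planted : {TRUSEQ}")
print(f"inferred: {inferred}")
print("exact match" if inferred == TRUSEQ else "differs (poly-A rule)")
# the inferred sequence should equal the planted TruSeq adapter; a trailing
# A, if the adapter ends in one, is absorbed by the poly-A trimming rule
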