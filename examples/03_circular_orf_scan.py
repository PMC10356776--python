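"""Six-frame ORF detection on a circular genome with an origin-wrapping gene.

Many small viral genomes are circular; reading frames continue across the
origin, so a gene can start near the end of the sequence and finish at the
beginning. The scanner reports such ORFs once, flagged ``wraps_origin``.
"""

import numpy as np

from orfdiv.io_formats import GenomeRecord
from orfdiv.orf_model import find_orfs, orf_sequence, translate

rng = np.random.default_rng(2)
background = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
# plant a 120 nt gene whose last 30 nt wrap past the origin
gene = "ATG" + "GCT" * 37 + "TAA"
seq = gene[30:] + background[:280] + "TAG" + gene[:30]
genome = GenomeRecord(id="circle", sequence=seq, circular=True)

orfs = find_orfs(genome, min_orf_nt=90)
print(f"{len(orfs)} ORFs of >= 90 nt on the {len(genome)} nt circle")
for orf in orfs:
    mark = " (wraps origin)" if orf.wraps_origin else ""
    print(f"  {orf.id}: {orf.start}-{orf.end} {orf.strand} "
          f"frame {orf.frame}, {orf.length_nt} nt{mark}")
    if orf.wraps_origin:
        protein = translate(orf_sequence(orf, genome))
        print(f"    translation: {protein[:20]}...{protein[-5:]}")
print()
print("The wrapping ORF's coordinates run start > end: its footprint covers")
print("the end of the forward strand and continues through position 0.")
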