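"""Amplicon-referenced CDF: select tiling probes covered by PCR products.

Instead of a gene annotation, step 4 of the filtering pipeline can use
PCR amplicon sequences located in the genome by exact search.  Probes
from either strand falling inside an amplicon interval form that
amplicon's probeset — the construction used to compare a tiling design
against a PCR-spotted array.  Amplicons absent from the genome, or
found at more than one locus, are skipped with a warning.
"""

import numpy as np

from tilede import GenomeSequence, ProbeRecord, build_cdf_from_amplicons, revcomp
from tilede.cdf import BuildLog

rng = np.random.default_rng(4)
seq = "".join(rng.choice(list("ACGT"), 6_000))
genome = GenomeSequence(["chrI"], {"chrI": seq})

# a 25-mer tiling of the first 2 kb, both strands, 20 nt step
probes = []
for s in range(0, 1_976, 20):
    probes.append(ProbeRecord(f"t{s}+", s, 0, seq[s : s + 25]))
    probes.append(ProbeRecord(f"t{s}-", s, 1, revcomp(seq[s : s + 25])))

amplicons = {
    "ampA": seq[100:450],          # clean single-locus amplicon
    "ampB": seq[900:1300],         # clean single-locus amplicon
    "ampC": "ACGT" * 80,           # not present in the genome
}
log = BuildLog()
probesets, counts = build_cdf_from_amplicons(probes, genome, amplicons, log=log)

for ps in probesets:
    strands = {m.strand for m in ps.members}
    print(f"{ps.probeset_id}: {len(ps.members)} probes from strands {sorted(strands)}")
print("skipped amplicons:", log.skipped_amplicons)
print("step counts:", dict(counts.as_rows()))
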