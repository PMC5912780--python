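"""Compute the three per-gene chromatin features on tiny hand-made data."""

from crispr_chromatin import (
    atac_coefficient,
    gc_content,
    methylation_coefficient,
    promoter_score,
)
from crispr_chromatin.genomic_io import GenomicInterval, Peak, ProbeRecord
from crispr_chromatin.tss_units import TranscriptionalUnit

# ATAC: one peak of signal 4.2 covering 500 of the 2,000 nt TSS region
unit = TranscriptionalUnit("g1", (5000,), 5000,
                           GenomicInterval("chr1", 4000, 6000), 2000)
peak = Peak(GenomicInterval("chr1", 4500, 5000), signal_value=4.2)
print(f"ATAC coefficient: {atac_coefficient(unit, [peak])}")
# 4.2 * 500 / 2000 = 1.05 -- signal weighted by overlap, per region length

# methylation: peaks cover 500 of 1,000 exonic bases
exons = [GenomicInterval("chr1", 0, 1000)]
meth = [Peak(GenomicInterval("chr1", 0, 250), signal_value=1.0),
        Peak(GenomicInterval("chr1", 500, 750), signal_value=1.0)]
print(f"methylation coefficient: {methylation_coefficient(exons, meth)}")
# 0.5 -- the covered fraction of the gene's nonredundant exon footprint

# promoter score: per-array sums of log2 probe intensities, averaged
probes = [ProbeRecord("g1", "p1", "array1", 4.0),   # log2 = 2
          ProbeRecord("g1", "p2", "array1", 4.0),   # array1 sum = 4
          ProbeRecord("g1", "p1", "array2", 64.0)]  # array2 sum = 6
print(f"promoter score: {promoter_score(probes)}")
# (4 + 6) / 2 = 5.0

print(f"guide GC%: {gc_content('GCGCGCGCGCATATATATAT')}")
# 50.0 -- ten of twenty protospacer bases are G or C
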