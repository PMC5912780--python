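"""Pool, cluster and flank transcription start sites.

TSSs within 500 nt of each other count as one transcriptional unit; each
unit is scored over a +/-1,000 nt window around the cluster midpoint.
"""

from crispr_chromatin import GeneModel, Transcript, build_units, extract_tss
from crispr_chromatin.genomic_io import GenomicInterval


def tx(tid, strand, exons):
    return Transcript(tid, strand, tuple(
        GenomicInterval("chr1", s, e, strand) for s, e in exons))


# three alternative promoters: two within 500 nt, one 5 kb downstream
gene = GeneModel("myod1-like", (
    tx("t1", "+", [(10_000, 10_400), (11_000, 11_500)]),
    tx("t2", "+", [(10_300, 10_400), (11_000, 11_500)]),
    tx("t3", "+", [(15_500, 16_000)]),
))

print("pooled TSSs:", extract_tss(gene))

for unit in build_units([gene]):
    print(f"unit members={unit.member_tss} representative={unit.representative_tss} "
          f"region={unit.region.start}-{unit.region.end}")

# Expected: TSSs 10000 and 10300 merge (gap 300 <= 500) into one unit with
# representative 10150; TSS 15500 stands alone.  Each scoring region spans
# exactly 2,000 nt around its representative.
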