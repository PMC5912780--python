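"""Transcriptional-unit construction.

TSSs of all transcripts of a gene are pooled, deduplicated, and clustered
by single-linkage chaining: any two consecutive positions at most
``cluster_gap`` apart (default 500 nt) fall in the same transcriptional
unit.  Each unit is represented by the midpoint of its span and scored over
a symmetric flanking region of ±``flank`` nt (default 1,000, i.e. a
2,000 nt region).  Clipping at contig boundaries shrinks the physical
region but never the nominal length used as the coefficient denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .genomic_io import GeneModel, GenomicInterval

DEFAULT_CLUSTER_GAP = 500
DEFAULT_FLANK = 1000


@dataclass(frozen=True)
class TranscriptionalUnit:
    gene_id: str
    member_tss: tuple[int, ...]
    representative_tss: int
    region: GenomicInterval
    nominal_length: int

    def __post_init__(self) -> None:
        if not (min(self.member_tss) <= self.representative_tss <= max(self.member_tss)):
            raise ValueError("representative TSS outside member span")


def extract_tss(gene: GeneModel) -> list[int]:
    """Pool one TSS per transcript, deduplicated and sorted.

    The TSS is the first transcribed base: the minimum exon start on '+',
    the maximum exon end minus one on '-'.  Unstranded transcripts are an
    error because the TSS cannot be oriented.
    """
    positions = set()
    for t in gene.transcripts:
        if t.strand == "+":
            positions.add(min(e.start for e in t.exons))
        elif t.strand == "-":
            positions.add(max(e.end for e in t.exons) - 1)
        else:
            raise ValueError(
                f"transcript {t.transcript_id} of {gene.gene_id} has no strand; "
                "cannot orient TSS"
            )
    return sorted(positions)


def cluster_tss(
    positions: Sequence[int], cluster_gap: int = DEFAULT_CLUSTER_GAP
) -> list[tuple[tuple[int, ...], int]]:
    """Single-linkage chain sorted TSS positions into clusters.

    Consecutive positions with difference <= ``cluster_gap`` join the same
    cluster.  Returns ``(members, representative)`` pairs where the
    representative is ``floor((min + max) / 2)`` of the cluster span; a
    singleton's representative is the position itself.
    """
    if not positions:
        return []
    pos = list(positions)
    if any(b < a for a, b in zip(pos, pos[1:])):
        raise ValueError("positions must be sorted ascending")
    clusters: list[tuple[tuple[int, ...], int]] = []
    current = [pos[0]]
    for p in pos[1:]:
        if p - current[-1] <= cluster_gap:
            current.append(p)
        else:
            clusters.append((tuple(current), (current[0] + current[-1]) // 2))
            current = [p]
    clusters.append((tuple(current), (current[0] + current[-1]) // 2))
    return clusters


def build_units(
    genes: Iterable[GeneModel],
    cluster_gap: int = DEFAULT_CLUSTER_GAP,
    flank: int = DEFAULT_FLANK,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[TranscriptionalUnit]:
    """Build one scoring unit per TSS cluster per gene.

    The region is ``[rep - flank, rep + flank)``, clipped at 0 and (when
    ``chrom_sizes`` is given) at the contig end; ``nominal_length`` stays
    ``2 * flank`` regardless of clipping so the coefficient denominator is
    constant across genes.
    """
    units: list[TranscriptionalUnit] = []
    for gene in genes:
        chrom = gene.chrom
        for members, rep in cluster_tss(extract_tss(gene), cluster_gap):
            start = max(0, rep - flank)
            end = rep + flank
            if chrom_sizes is not None and chrom in chrom_sizes:
                end = min(end, chrom_sizes[chrom])
            units.append(
                TranscriptionalUnit(
                    gene_id=gene.gene_id,
                    member_tss=members,
                    representative_tss=rep,
                    region=GenomicInterval(chrom, start, end),
                    nominal_length=2 * flank,
                )
            )
    return units


def units_to_bed(units: Iterable[TranscriptionalUnit]) -> str:
    """Render units as BED6 (name = gene_id, score = member count)."""
    lines = []
    for u in sorted(units, key=lambda u: (u.region.chrom, u.region.start)):
        lines.append(
            f"{u.region.chrom}\t{u.region.start}\t{u.region.end}\t"
            f"{u.gene_id}\t{len(u.member_tss)}\t.\n"
        )
    return "".join(lines)
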