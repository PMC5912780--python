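"""Per-gene chromatin feature scores.

Three features are computed per gene:

* **ATAC coefficient** — over each ±1 kb TSS-unit region, the sum of
  (peak signalValue × overlap in bp) divided by the nominal region length
  (2,000 nt); multi-unit genes average their unit coefficients so every
  gene ends up with a single value.
* **Methylation coefficient** — the fraction of the gene's nonredundant
  exonic footprint covered by methylation peaks (peaks are merged first, so
  the value is a true coverage fraction in [0, 1]).  A signal-weighted
  variant is available via ``weight="signal"``.
* **Promoter score** — per hybridisation array, the sum of log2 median
  probe intensities over the gene's promoter probes; scores are averaged
  across arrays.

Plus the guide GC content in percent.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .genomic_io import GeneModel, GenomicInterval, Peak, ProbeRecord, ValidationError
from .tss_units import TranscriptionalUnit

logger = logging.getLogger(__name__)


class PeakIndex:
    """Per-chromosome interval tree over peaks for O(log n) overlap queries."""

    def __init__(self, peaks: Iterable[Peak]):
        by_chrom: dict[str, list[Peak]] = defaultdict(list)
        for p in peaks:
            by_chrom[p.interval.chrom].append(p)
        self._trees = {
            chrom: IntervalTree.from_tuples(
                (p.interval.start, p.interval.end, p) for p in ps
            )
            for chrom, ps in by_chrom.items()
        }

    def overlapping(self, region: GenomicInterval) -> list[Peak]:
        tree = self._trees.get(region.chrom)
        if tree is None:
            return []
        return sorted(
            (iv.data for iv in tree.overlap(region.start, region.end)),
            key=lambda p: (p.interval.start, p.interval.end),
        )


def _as_index(peaks) -> PeakIndex:
    return peaks if isinstance(peaks, PeakIndex) else PeakIndex(peaks)


def atac_coefficient(unit: TranscriptionalUnit, peaks) -> float:
    """Signal-weighted overlap of ATAC peaks with one TSS-unit region.

    Returns ``sum(signal * overlap_bp) / nominal_length``; 0.0 when nothing
    overlaps.  ``peaks`` may be a :class:`PeakIndex` or any peak iterable.
    """
    index = _as_index(peaks)
    total = 0.0
    for p in index.overlapping(unit.region):
        total += p.signal_value * p.interval.overlap_bp(unit.region)
    return total / unit.nominal_length


def gene_atac_coefficient(units: Sequence[TranscriptionalUnit], peaks) -> float | None:
    """Mean of per-unit ATAC coefficients; None for a gene without units."""
    if not units:
        logger.warning("gene has no transcriptional units; ATAC coefficient missing")
        return None
    index = _as_index(peaks)
    return sum(atac_coefficient(u, index) for u in units) / len(units)


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of (start, end) half-open intervals as maximal disjoint runs."""
    srt = sorted(intervals)
    merged: list[list[int]] = []
    for s, e in srt:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def merged_exons(gene: GeneModel) -> list[GenomicInterval]:
    """All transcripts' exons merged into maximal disjoint intervals."""
    chrom = gene.chrom
    runs = merge_intervals(
        (e.start, e.end) for t in gene.transcripts for e in t.exons
    )
    return [GenomicInterval(chrom, s, e) for s, e in runs]


def _overlap_disjoint(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> int:
    """Total overlap bp between two sorted disjoint interval lists."""
    i = j = 0
    total = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            total += e - s
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return total


def methylation_coefficient(
    exons: Sequence[GenomicInterval],
    peaks: Iterable[Peak],
    weight: str = "coverage",
) -> float | None:
    """Peak overlap with a gene's merged exons, normalised by exon length.

    ``weight="coverage"`` (default) counts each exonic base at most once —
    the peak footprint is merged first — so the value is a coverage
    fraction in [0, 1].  ``weight="signal"`` sums signalValue × overlap
    instead (unbounded; kept for the alternative reading of the summation).
    """
    if not exons:
        return None
    total_exon = sum(e.length() for e in exons)
    if total_exon == 0:
        return None
    chrom = exons[0].chrom
    exon_runs = [(e.start, e.end) for e in exons]
    same_chrom = [p for p in peaks if p.interval.chrom == chrom]
    if weight == "coverage":
        peak_runs = merge_intervals((p.interval.start, p.interval.end) for p in same_chrom)
        return _overlap_disjoint(exon_runs, peak_runs) / total_exon
    if weight == "signal":
        total = 0.0
        for p in same_chrom:
            for e in exons:
                total += p.signal_value * e.overlap_bp(p.interval)
        return total / total_exon
    raise ValueError(f"unknown weight mode {weight!r}")


def promoter_score(probes: Sequence[ProbeRecord]) -> float | None:
    """Mean over arrays of the per-array sum of log2 median intensities."""
    if not probes:
        return None
    per_array: dict[str, float] = defaultdict(float)
    for p in probes:
        per_array[p.array_id] += math.log2(p.median_intensity)
    return sum(per_array.values()) / len(per_array)


def gc_content(guide_sequence: str) -> float:
    """GC percent of a 20-nt protospacer (PAM excluded)."""
    seq = guide_sequence.upper()
    if len(seq) != 20:
        raise ValidationError(f"guide must be 20 nt, got {len(seq)}")
    if set(seq) - set("ACGT"):
        raise ValidationError(f"guide contains non-ACGT characters: {guide_sequence!r}")
    return 100.0 * (seq.count("G") + seq.count("C")) / 20.0
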