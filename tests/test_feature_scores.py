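"""Chromatin feature scores against hand values and a per-base oracle."""

import numpy as np
import pytest

from crispr_chromatin.feature_scores import (
    PeakIndex,
    atac_coefficient,
    gc_content,
    gene_atac_coefficient,
    merged_exons,
    methylation_coefficient,
    promoter_score,
)
from crispr_chromatin.genomic_io import (
    GeneModel,
    GenomicInterval,
    Peak,
    ProbeRecord,
    Transcript,
    ValidationError,
)
from crispr_chromatin.tss_units import TranscriptionalUnit

from conftest import make_peak


def unit(start, end, chrom="chr1", nominal=2000):
    rep = (start + end) // 2
    return TranscriptionalUnit("g", (rep,), rep,
                               GenomicInterval(chrom, start, end), nominal)


def brute_force_atac(u, peaks):
    """Per-base oracle: overlap measured by counting covered positions."""
    total = 0.0
    region = set(range(u.region.start, u.region.end))
    for p in peaks:
        if p.interval.chrom != u.region.chrom:
            continue
        overlap = len(region & set(range(p.interval.start, p.interval.end)))
        total += p.signal_value * overlap
    return total / u.nominal_length


def brute_force_meth(exons, peaks):
    """Per-base oracle: fraction of exonic positions under >=1 peak."""
    exonic = set()
    for e in exons:
        exonic |= set(range(e.start, e.end))
    covered = set()
    for p in peaks:
        if p.interval.chrom == exons[0].chrom:
            covered |= set(range(p.interval.start, p.interval.end))
    return len(exonic & covered) / len(exonic)


class TestAtacCoefficient:
    def test_no_overlap_is_zero(self):
        u = unit(4000, 6000)
        assert atac_coefficient(u, [make_peak("chr1", 100, 200, 5.0)]) == 0.0

    def test_full_coverage_returns_signal(self):
        u = unit(4000, 6000)
        assert atac_coefficient(u, [make_peak("chr1", 3000, 7000, 3.7)]) == 3.7

    def test_hand_value(self):
        u = unit(4000, 6000)
        peak = make_peak("chr1", 4500, 5000, 4.2)
        assert atac_coefficient(u, [peak]) == pytest.approx(4.2 * 500 / 2000)

    def test_other_chromosome_ignored(self):
        u = unit(4000, 6000)
        assert atac_coefficient(u, [make_peak("chr2", 4000, 6000, 9.0)]) == 0.0

    def test_linear_in_signal(self, rng):
        u = unit(10_000, 12_000)
        peaks = [make_peak("chr1", int(s), int(s) + int(w), float(v))
                 for s, w, v in zip(rng.integers(9000, 13_000, 10),
                                    rng.integers(50, 800, 10),
                                    rng.uniform(0.1, 5, 10))]
        base = atac_coefficient(u, peaks)
        scaled = [Peak(p.interval, p.name, p.score, p.signal_value * 3.5)
                  for p in peaks]
        assert atac_coefficient(u, scaled) == pytest.approx(3.5 * base, rel=1e-12)

    def test_translation_invariance(self, rng):
        shift = 12_345
        u1 = unit(4000, 6000)
        peaks1 = [make_peak("chr1", 4100, 4800, 2.0), make_peak("chr1", 5500, 6400, 1.5)]
        u2 = unit(4000 + shift, 6000 + shift)
        peaks2 = [make_peak("chr1", p.interval.start + shift,
                            p.interval.end + shift, p.signal_value) for p in peaks1]
        assert atac_coefficient(u1, peaks1) == atac_coefficient(u2, peaks2)

    def test_irrelevant_peak_changes_nothing(self):
        u = unit(4000, 6000)
        peaks = [make_peak("chr1", 4500, 5000, 4.2)]
        with_extra = peaks + [make_peak("chr1", 9000, 9500, 100.0)]
        assert atac_coefficient(u, peaks) == atac_coefficient(u, with_extra)

    def test_agrees_with_per_base_oracle(self, rng):
        for _ in range(100):
            n_peaks = int(rng.integers(0, 21))
            start = int(rng.integers(0, 90_000))
            u = unit(start, start + int(rng.integers(100, 5000)))
            peaks = [
                make_peak("chr1", int(s), int(s) + int(w), float(v))
                for s, w, v in zip(
                    rng.integers(0, 100_000, n_peaks),
                    rng.integers(1, 3000, n_peaks),
                    rng.uniform(0, 10, n_peaks),
                )
            ]
            assert atac_coefficient(u, peaks) == brute_force_atac(u, peaks)


class TestGeneAtacCoefficient:
    def test_mean_of_units(self):
        u1, u2 = unit(0, 2000), unit(10_000, 12_000)
        peaks = [make_peak("chr1", 0, 2000, 1.0), make_peak("chr1", 10_000, 12_000, 3.0)]
        assert gene_atac_coefficient([u1, u2], peaks) == pytest.approx(2.0)

    def test_missing_for_no_units(self, caplog):
        with caplog.at_level("WARNING"):
            assert gene_atac_coefficient([], []) is None
        assert caplog.records

    def test_accepts_prebuilt_index(self):
        u = unit(4000, 6000)
        index = PeakIndex([make_peak("chr1", 4500, 5000, 4.2)])
        assert gene_atac_coefficient([u], index) == pytest.approx(1.05)


class TestMergedExons:
    def _gene(self, *tx_exons):
        txs = tuple(
            Transcript(f"t{i}", "+",
                       tuple(GenomicInterval("chr1", s, e, "+") for s, e in exons))
            for i, exons in enumerate(tx_exons)
        )
        return GeneModel("g", txs)

    def test_overlapping_exons_merged(self):
        g = self._gene([(100, 200)], [(150, 250)])
        merged = merged_exons(g)
        assert [(m.start, m.end) for m in merged] == [(100, 250)]
        assert sum(m.length() for m in merged) == 150

    def test_single_exon_identity(self):
        g = self._gene([(0, 100)])
        assert [(m.start, m.end) for m in merged_exons(g)] == [(0, 100)]

    def test_total_matches_per_base_bitmap(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 20))
            starts = rng.integers(0, 5000, n)
            # a transcript's exons must be disjoint, so use one tx per exon
            exons = [[(int(s), int(s) + int(w))]
                     for s, w in zip(starts, rng.integers(1, 400, n))]
            g = self._gene(*exons)
            covered = set()
            for ex in exons:
                covered |= set(range(*ex[0]))
            assert sum(m.length() for m in merged_exons(g)) == len(covered)


class TestMethylationCoefficient:
    def test_no_overlap_is_zero(self):
        exons = [GenomicInterval("chr1", 0, 1000)]
        assert methylation_coefficient(exons, [make_peak("chr1", 5000, 6000)]) == 0.0

    def test_exact_tiling_is_one(self):
        exons = [GenomicInterval("chr1", 0, 500), GenomicInterval("chr1", 600, 1000)]
        peaks = [make_peak("chr1", 0, 500), make_peak("chr1", 600, 1000)]
        assert methylation_coefficient(exons, peaks) == 1.0

    def test_hand_value(self):
        exons = [GenomicInterval("chr1", 0, 1000)]
        peaks = [make_peak("chr1", 0, 250), make_peak("chr1", 500, 750)]
        assert methylation_coefficient(exons, peaks) == pytest.approx(0.5)

    def test_overlapping_peaks_capped_at_one(self):
        exons = [GenomicInterval("chr1", 0, 1000)]
        peaks = [make_peak("chr1", 0, 800), make_peak("chr1", 200, 1000)]
        assert methylation_coefficient(exons, peaks) == 1.0

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(50):
            exons = [GenomicInterval("chr1", 0, int(rng.integers(100, 2000)))]
            n = int(rng.integers(0, 15))
            peaks = [make_peak("chr1", int(s), int(s) + int(w))
                     for s, w in zip(rng.integers(0, 3000, n),
                                     rng.integers(1, 1500, n))]
            c = methylation_coefficient(exons, peaks)
            assert 0.0 <= c <= 1.0

    def test_signal_weight_mode_unbounded(self):
        exons = [GenomicInterval("chr1", 0, 100)]
        peaks = [make_peak("chr1", 0, 100, signal=5.0)]
        assert methylation_coefficient(exons, peaks, weight="signal") == pytest.approx(5.0)

    def test_missing_for_empty_exons(self):
        assert methylation_coefficient([], []) is None

    def test_agrees_with_per_base_oracle(self, rng):
        for _ in range(100):
            n_exon = int(rng.integers(1, 6))
            starts = sorted(rng.integers(0, 80_000, n_exon).tolist())
            exon_runs = []
            cursor = 0
            for s in starts:
                s = max(s, cursor)
                w = int(rng.integers(50, 600))
                exon_runs.append((s, s + w))
                cursor = s + w + 10
            exons = [GenomicInterval("chr1", s, e) for s, e in exon_runs]
            n_peak = int(rng.integers(0, 21))
            peaks = [make_peak("chr1", int(s), int(s) + int(w))
                     for s, w in zip(rng.integers(0, 100_000, n_peak),
                                     rng.integers(1, 2000, n_peak))]
            got = methylation_coefficient(exons, peaks)
            want = brute_force_meth(exons, peaks)
            assert got == want


class TestPromoterScore:
    def test_single_probe_log2(self):
        probes = [ProbeRecord("g", "p1", "a1", 8.0)]
        assert promoter_score(probes) == pytest.approx(3.0)

    def test_mean_over_arrays(self):
        probes = [
            ProbeRecord("g", "p1", "a1", 4.0),   # log2 = 2
            ProbeRecord("g", "p2", "a1", 4.0),   # per-array sum = 4
            ProbeRecord("g", "p1", "a2", 64.0),  # per-array sum = 6
        ]
        assert promoter_score(probes) == pytest.approx(5.0)

    def test_unit_intensities_give_zero(self):
        probes = [ProbeRecord("g", f"p{i}", "a1", 1.0) for i in range(5)]
        assert promoter_score(probes) == 0.0

    def test_missing_for_no_probes(self):
        assert promoter_score([]) is None


class TestGcContent:
    @pytest.mark.parametrize("seq,expected", [
        ("G" * 20, 100.0),
        ("AT" * 10, 0.0),
        ("GCGCGCGCGCATATATATAT", 50.0),
    ])
    def test_known_values(self, seq, expected):
        assert gc_content(seq) == expected

    def test_lowercase_normalized(self):
        assert gc_content("gcgcgcgcgcatatatatat") == 50.0

    def test_wrong_length_rejected(self):
        with pytest.raises(ValidationError):
            gc_content("ACGT")

    def test_non_acgt_rejected(self):
        with pytest.raises(ValidationError):
            gc_content("NCGTACGTACGTACGTACGT")
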