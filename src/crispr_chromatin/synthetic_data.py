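"""Seeded generator of complete synthetic mutagenesis studies.

A single latent per-gene "openness" (standard normal) drives every output:

* promoter ATAC peaks whose signalValue is ``exp(a * openness + eps)``;
* methylation peaks covering a logistic(-b * openness + eps') fraction of
  each gene's exonic footprint (closed chromatin is more methylated);
* stage-wise RPKM, lognormal with a log-mean increasing in openness and a
  stage trajectory that rises from the oblong-sphere stage onward more
  steeply for open genes (so the maternal-to-zygotic increase tracks
  openness);
* promoter microarray probes with lognormal median intensities;
* per-guide mutagenesis efficiencies coupled to openness through a
  Gaussian copula at a chosen Spearman rho: the Pearson coupling is
  ``r = 2 sin(pi * rho_s / 6)``, the value whose bivariate-normal Spearman
  correlation equals the planted rho, so the pipeline's estimate is
  directly comparable to the planted value.

Everything is a pure function of :class:`SimulationConfig` (including the
seed), so identical configs produce byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr

from .genomic_io import (
    STAGES,
    EfficiencyRecord,
    ExpressionRecord,
    GeneModel,
    GenomicInterval,
    Peak,
    ProbeRecord,
    Transcript,
    write_peaks,
)
from .feature_scores import merged_exons

#: guide efficiencies below this percent count as non-functional in vivo
FUNCTIONAL_THRESHOLD = 10.0


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror the regime of the real accessibility analysis: 263
    genes with mutagenesis data and a planted Spearman rho of 0.18 between
    openness and efficiency.  ``multi_tss_fraction`` of 0.16 matches the
    share of genes with more than one annotated transcript in a typical
    fish annotation.
    """

    n_genes: int = 263
    n_chromosomes: int = 5
    multi_tss_fraction: float = 0.16
    planted_rho: float = 0.18
    noise_sd: float = 0.1
    peak_density: float = 0.05  # background peaks per kb
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    chrom_length: int | None = None  # fixed contig length; None = auto-size
    atac_slope: float = 1.0     # a: log-signal per openness SD
    meth_slope: float = 1.0     # b: logit-coverage per openness SD
    expr_slope: float = 1.0     # c: log-RPKM per openness SD
    guide_noise_sd: float = 2.0  # percentage points around the gene value
    guides_per_gene: tuple[int, int] = (1, 4)

    def __post_init__(self) -> None:
        if self.n_genes < 10:
            raise ValueError("n_genes must be >= 10")
        if not (-1.0 < self.planted_rho < 1.0):
            raise ValueError("|planted_rho| must be < 1")
        if not (0.0 <= self.multi_tss_fraction <= 1.0):
            raise ValueError("multi_tss_fraction must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class SimulatedStudy:
    """A full study bundle plus the latent truth used to generate it."""

    config: SimulationConfig
    genes: list[GeneModel]
    chrom_sizes: dict[str, int]
    latent: pd.DataFrame  # gene_id, openness, efficiency (percent)
    atac_peaks: list[Peak]
    meth_peaks: list[Peak]
    expression: list[ExpressionRecord]
    probes: list[ProbeRecord]
    efficiency: list[EfficiencyRecord]


# stage trajectory: baseline log-RPKM and openness weight per stage.  The
# weight step between oblong-sphere and 50%-epiboly makes the zygotic rise
# steeper for open genes.
_STAGE_MU = {
    "64-cell": 0.0, "oblong-sphere": 0.1, "50%-epiboly": 0.5, "15-somite": 0.8,
    "36hpf": 1.0, "48hpf": 1.0, "60hpf": 0.9, "72hpf": 0.8,
}
_STAGE_WEIGHT = {
    "64-cell": 0.5, "oblong-sphere": 0.6, "50%-epiboly": 1.0, "15-somite": 1.1,
    "36hpf": 1.1, "48hpf": 1.0, "60hpf": 1.0, "72hpf": 0.9,
}


def simulate_genome(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[list[GeneModel], dict[str, int]]:
    """Place non-overlapping multi-transcript genes on the contigs."""
    genes: list[GeneModel] = []
    cursors = {f"chr{i + 1}": 2000 for i in range(config.n_chromosomes)}
    chrom_names = sorted(cursors)
    for gi in range(config.n_genes):
        chrom = chrom_names[gi % config.n_chromosomes]
        gene_id = f"gene{gi + 1:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_tx = 1
        if rng.random() < config.multi_tss_fraction:
            n_tx = int(rng.integers(2, 5))
        base_start = cursors[chrom]
        # base transcript exon chain
        n_exons = int(rng.integers(2, 9))
        exon_lens = rng.integers(100, 501, size=n_exons)
        intron_lens = rng.integers(100, 2001, size=n_exons - 1)
        starts = [base_start]
        for k in range(1, n_exons):
            starts.append(starts[-1] + int(exon_lens[k - 1]) + int(intron_lens[k - 1]))
        base_exons = [
            (s, s + int(l)) for s, l in zip(starts, exon_lens)
        ]
        offsets = [0] + [int(rng.integers(50, 5001)) for _ in range(n_tx - 1)]
        transcripts = []
        max_end = 0
        for ti, off in enumerate(offsets):
            exons = tuple(
                GenomicInterval(chrom, s + off, e + off, strand)
                for s, e in base_exons
            )
            max_end = max(max_end, exons[-1].end)
            transcripts.append(Transcript(f"{gene_id}.t{ti + 1}", strand, exons))
        genes.append(GeneModel(gene_id, tuple(transcripts)))
        cursors[chrom] = max_end + int(rng.integers(3000, 10001))
        if config.chrom_length is not None and cursors[chrom] > config.chrom_length:
            raise ValueError(
                f"cannot place gene {gene_id} on {chrom} without overlap; "
                "increase chrom_length or n_chromosomes"
            )
    if config.chrom_length is not None:
        sizes = {c: config.chrom_length for c in chrom_names}
    else:
        sizes = {c: cursors[c] + 2000 for c in chrom_names}
    return genes, sizes


def simulate_chromatin(
    genes: Sequence[GeneModel],
    chrom_sizes: dict[str, int],
    openness: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[list[Peak], list[Peak]]:
    """ATAC promoter + background peaks, and exon methylation peaks."""
    from .tss_units import cluster_tss, extract_tss  # avoid an import cycle

    # one accessibility peak per promoter: TSSs within one transcriptional
    # unit share a single peak centred on the cluster representative
    atac: list[Peak] = []
    eps = rng.normal(0.0, config.noise_sd, size=len(genes))
    for i, gene in enumerate(genes):
        signal = float(np.exp(config.atac_slope * openness[i] + eps[i]))
        for j, (_, rep) in enumerate(cluster_tss(extract_tss(gene))):
            width = int(np.clip(rng.normal(800, 150), 300, 1500))
            start = max(0, rep - width // 2)
            end = min(chrom_sizes[gene.chrom], start + width)
            atac.append(
                Peak(GenomicInterval(gene.chrom, start, end),
                     name=f"atac_{gene.gene_id}_{j}", score=0, signal_value=signal)
            )
    # openness-independent background peaks (pure dilution)
    total_kb = sum(chrom_sizes.values()) / 1000.0
    n_bg = int(rng.poisson(config.peak_density * total_kb))
    chrom_names = sorted(chrom_sizes)
    probs = np.array([chrom_sizes[c] for c in chrom_names], dtype=float)
    probs /= probs.sum()
    for k in range(n_bg):
        chrom = chrom_names[int(rng.choice(len(chrom_names), p=probs))]
        width = int(rng.integers(200, 1001))
        start = int(rng.integers(0, max(1, chrom_sizes[chrom] - width)))
        # background signal well below promoter-peak scale, as in real calls
        atac.append(
            Peak(GenomicInterval(chrom, start, start + width),
                 name=f"atac_bg_{k}", score=0,
                 signal_value=float(rng.lognormal(-1.5, 0.5)))
        )

    meth: list[Peak] = []
    eps2 = rng.normal(0.0, config.noise_sd, size=len(genes))
    for i, gene in enumerate(genes):
        frac = float(expit(-config.meth_slope * openness[i] + eps2[i]))
        exons = merged_exons(gene)
        total = sum(e.length() for e in exons)
        budget = int(round(frac * total))
        for e in exons:
            if budget <= 0:
                break
            covered = min(budget, e.length())
            meth.append(
                Peak(GenomicInterval(e.chrom, e.start, e.start + covered),
                     name=f"meth_{gene.gene_id}_{len(meth)}", score=0,
                     signal_value=1.0)
            )
            budget -= covered
    return atac, meth


def simulate_efficiency(
    gene_ids: Sequence[str],
    openness: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[list[EfficiencyRecord], np.ndarray]:
    """Gaussian-copula efficiencies plus per-guide records."""
    rho_s = config.planted_rho
    r = 2.0 * np.sin(np.pi * rho_s / 6.0)
    eta = rng.normal(size=len(gene_ids))
    z_eff = r * openness + np.sqrt(1.0 - r * r) * eta
    gene_eff = 100.0 * ndtr(z_eff)
    records: list[EfficiencyRecord] = []
    bases = np.array(list("ACGT"))
    lo, hi = config.guides_per_gene
    for i, gid in enumerate(gene_ids):
        n_guides = int(rng.integers(lo, hi + 1))
        for _ in range(n_guides):
            eff = float(np.clip(gene_eff[i] + rng.normal(0.0, config.guide_noise_sd),
                                0.0, 100.0))
            seq = "".join(bases[rng.integers(0, 4, size=20)])
            records.append(
                EfficiencyRecord(gid, seq, eff, functional=eff >= FUNCTIONAL_THRESHOLD)
            )
    return records, gene_eff


def simulate_expression(
    gene_ids: Sequence[str],
    openness: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[ExpressionRecord]:
    records: list[ExpressionRecord] = []
    for i, gid in enumerate(gene_ids):
        for stage in config.stages:
            log_rpkm = (
                _STAGE_MU[stage]
                + config.expr_slope * _STAGE_WEIGHT[stage] * openness[i]
                + rng.normal(0.0, config.noise_sd)
            )
            records.append(ExpressionRecord(gid, stage, float(np.exp(log_rpkm))))
    return records


def simulate_probes(
    gene_ids: Sequence[str],
    openness: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    n_arrays: int = 2,
) -> list[ProbeRecord]:
    records: list[ProbeRecord] = []
    for i, gid in enumerate(gene_ids):
        n_probes = int(rng.integers(3, 11))
        for a in range(n_arrays):
            for p in range(n_probes):
                intensity = float(
                    np.exp(np.log(100.0) + openness[i] + rng.normal(0.0, 0.2))
                )
                records.append(ProbeRecord(gid, f"{gid}_p{p + 1}", f"array{a + 1}",
                                           intensity))
    return records


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate the complete bundle from one seed."""
    rng = np.random.default_rng(config.seed)
    genes, chrom_sizes = simulate_genome(config, rng)
    gene_ids = [g.gene_id for g in genes]
    openness = rng.normal(size=len(genes))
    atac, meth = simulate_chromatin(genes, chrom_sizes, openness, config, rng)
    eff_records, gene_eff = simulate_efficiency(gene_ids, openness, config, rng)
    expression = simulate_expression(gene_ids, openness, config, rng)
    probes = simulate_probes(gene_ids, openness, config, rng)
    latent = pd.DataFrame(
        {"gene_id": gene_ids, "openness": openness, "efficiency": gene_eff}
    )
    return SimulatedStudy(config, genes, chrom_sizes, latent, atac, meth,
                          expression, probes, eff_records)


# ---------------------------------------------------------------------------
# file output


def _write_gff3(genes: Sequence[GeneModel], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            span_start = min(e.start for t in g.transcripts for e in t.exons)
            span_end = max(e.end for t in g.transcripts for e in t.exons)
            strand = g.transcripts[0].strand
            fh.write(
                f"{g.chrom}\tsim\tgene\t{span_start + 1}\t{span_end}\t.\t{strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for t in g.transcripts:
                t_start = min(e.start for e in t.exons)
                t_end = max(e.end for e in t.exons)
                fh.write(
                    f"{g.chrom}\tsim\tmRNA\t{t_start + 1}\t{t_end}\t.\t{t.strand}\t.\t"
                    f"ID={t.transcript_id};Parent={g.gene_id}\n"
                )
                for k, e in enumerate(t.exons):
                    fh.write(
                        f"{g.chrom}\tsim\texon\t{e.start + 1}\t{e.end}\t.\t{t.strand}\t.\t"
                        f"ID={t.transcript_id}.e{k + 1};Parent={t.transcript_id}\n"
                    )


def write_study(study: SimulatedStudy, out_dir: str | Path) -> dict[str, Path]:
    """Write the bundle as plain-text files; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotation": out / "genome.gff3",
        "chrom_sizes": out / "chrom_sizes.tsv",
        "atac": out / "atac.broadPeak",
        "methylation": out / "meth.broadPeak",
        "expression": out / "expression.tsv",
        "probes": out / "probes.tsv",
        "efficiency": out / "efficiency.tsv",
        "latent": out / "latent_truth.tsv",
    }
    _write_gff3(study.genes, paths["annotation"])
    with open(paths["chrom_sizes"], "w") as fh:
        for chrom in sorted(study.chrom_sizes):
            fh.write(f"{chrom}\t{study.chrom_sizes[chrom]}\n")
    write_peaks(study.atac_peaks, paths["atac"])
    write_peaks(study.meth_peaks, paths["methylation"])
    with open(paths["expression"], "w") as fh:
        fh.write("gene_id\tstage\trpkm\n")
        for r in study.expression:
            fh.write(f"{r.gene_id}\t{r.stage}\t{r.rpkm:.6g}\n")
    with open(paths["probes"], "w") as fh:
        fh.write("gene_id\tprobe_id\tarray_id\tmedian_intensity\n")
        for r in study.probes:
            fh.write(f"{r.gene_id}\t{r.probe_id}\t{r.array_id}\t{r.median_intensity:.6g}\n")
    with open(paths["efficiency"], "w") as fh:
        fh.write("gene_id\tguide_sequence\tefficiency\tfunctional\n")
        for r in study.efficiency:
            fh.write(
                f"{r.gene_id}\t{r.guide_sequence}\t{r.efficiency:.6g}\t"
                f"{'true' if r.functional else 'false'}\n"
            )
    with open(paths["latent"], "w") as fh:
        fh.write("gene_id\topenness\tefficiency\n")
        for _, row in study.latent.iterrows():
            fh.write(f"{row.gene_id}\t{row.openness:.6g}\t{row.efficiency:.6g}\n")
    return paths
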