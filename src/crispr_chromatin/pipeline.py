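"""End-to-end orchestration: inputs -> units -> scores -> associations.

Two entry points:

* :func:`analyze_study` works on in-memory objects (annotation, peak
  lists, record lists) and returns the joined per-gene feature table plus
  the association results and contingency tests.  Tests and simulations go
  through this path.
* :func:`run_pipeline` is the file-based wrapper: it reads the standard
  formats, calls :func:`analyze_study`, and writes the feature table,
  association TSV, contingency report and a JSON manifest recording
  parameters, input checksums and the complete-case n of every analysis.
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genomic_io import (
    STAGES,
    EfficiencyRecord,
    ExpressionRecord,
    GeneModel,
    Peak,
    ProbeRecord,
    read_alias_map,
    read_gene_annotation,
    read_peaks,
    read_table,
    write_association,
    write_feature_table,
)
from .tss_units import DEFAULT_CLUSTER_GAP, DEFAULT_FLANK, build_units
from .feature_scores import (
    PeakIndex,
    gc_content,
    gene_atac_coefficient,
    merged_exons,
    methylation_coefficient,
    promoter_score,
)
from .association import (
    AssociationResult,
    ContingencyTable2x2,
    aggregate_efficiency,
    classify_expression,
    correlate_all,
    fisher_exact,
    mann_whitney,
    mzt_change,
)

logger = logging.getLogger(__name__)


class EmptyJoinError(RuntimeError):
    """Features and efficiency share no gene identifiers."""


@dataclass
class RunConfig:
    """Validated input paths and parameters for one pipeline run."""

    annotation: Path
    atac: Path | None = None
    methylation: Path | None = None
    expression: Path | None = None
    probes: Path | None = None
    efficiency: Path | None = None
    alias_map: Path | None = None
    out_dir: Path = Path("results")
    annotation_format: str = "gff3"
    chrom_sizes: Path | None = None
    cluster_gap: int = DEFAULT_CLUSTER_GAP
    flank: int = DEFAULT_FLANK
    low_rpkm: float = 0.5
    alpha: float = 0.05
    aggregation: str = "mean"
    meth_weight: str = "coverage"
    stages: tuple[str, ...] = STAGES
    seed: int = 0

    def validate(self) -> None:
        for name in ("annotation", "atac", "methylation", "expression",
                     "probes", "efficiency", "alias_map", "chrom_sizes"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")
        if self.cluster_gap < 0 or self.flank <= 0:
            raise ValueError("cluster_gap must be >= 0 and flank > 0")
        if self.aggregation not in {"mean", "median"}:
            raise ValueError(f"unknown aggregation {self.aggregation!r}")
        if self.meth_weight not in {"coverage", "signal"}:
            raise ValueError(f"unknown meth_weight {self.meth_weight!r}")


def build_feature_table(
    genes: Sequence[GeneModel],
    atac_peaks: Sequence[Peak] | None = None,
    meth_peaks: Sequence[Peak] | None = None,
    expression: Sequence[ExpressionRecord] | None = None,
    probes: Sequence[ProbeRecord] | None = None,
    efficiency: Sequence[EfficiencyRecord] | None = None,
    cluster_gap: int = DEFAULT_CLUSTER_GAP,
    flank: int = DEFAULT_FLANK,
    chrom_sizes: Mapping[str, int] | None = None,
    aggregation: str = "mean",
    meth_weight: str = "coverage",
) -> pd.DataFrame:
    """Join every per-gene feature into one table keyed by gene_id."""
    table = pd.DataFrame({"gene_id": [g.gene_id for g in genes]})

    if atac_peaks is not None:
        units = build_units(genes, cluster_gap, flank, chrom_sizes)
        by_gene: dict[str, list] = defaultdict(list)
        for u in units:
            by_gene[u.gene_id].append(u)
        index = PeakIndex(atac_peaks)
        table["atac_coefficient"] = [
            gene_atac_coefficient(by_gene.get(g.gene_id, []), index) for g in genes
        ]

    if meth_peaks is not None:
        meth_by_chrom: dict[str, list[Peak]] = defaultdict(list)
        for p in meth_peaks:
            meth_by_chrom[p.interval.chrom].append(p)
        table["methylation_coefficient"] = [
            methylation_coefficient(
                merged_exons(g), meth_by_chrom.get(g.chrom, []), weight=meth_weight
            )
            for g in genes
        ]

    if probes is not None:
        probes_by_gene: dict[str, list[ProbeRecord]] = defaultdict(list)
        for r in probes:
            probes_by_gene[r.gene_id].append(r)
        table["promoter_score"] = [
            promoter_score(probes_by_gene.get(g.gene_id, [])) for g in genes
        ]

    if expression is not None:
        expr = pd.DataFrame(
            [(r.gene_id, r.stage, r.rpkm) for r in expression],
            columns=["gene_id", "stage", "rpkm"],
        )
        wide = expr.pivot_table(index="gene_id", columns="stage", values="rpkm",
                                aggfunc="mean")
        wide.columns = [f"rpkm_{c}" for c in wide.columns]
        ordered = [f"rpkm_{s}" for s in STAGES if f"rpkm_{s}" in wide.columns]
        table = table.merge(wide[ordered].reset_index(), on="gene_id", how="left")

    if efficiency is not None:
        eff_map = aggregate_efficiency(efficiency, method=aggregation)
        table["efficiency"] = [eff_map.get(g.gene_id, np.nan) for g in genes]
        gc_by_gene: dict[str, list[float]] = defaultdict(list)
        for r in efficiency:
            gc_by_gene[r.gene_id].append(gc_content(r.guide_sequence))
        table["gc_percent"] = [
            float(np.mean(gc_by_gene[g.gene_id])) if g.gene_id in gc_by_gene else np.nan
            for g in genes
        ]
    return table


def contingency_tests(
    features: pd.DataFrame,
    efficiency: Sequence[EfficiencyRecord],
    low_rpkm: float = 0.5,
    alpha: float = 0.05,
) -> list[AssociationResult]:
    """Expression-category 2x2 tests comparing mutagenesis-resistant vs
    permissive genes, plus the guide GC-content comparison.

    A gene is *permissive* if any of its guides showed in-vivo activity,
    *resistant* otherwise.  Test 1: low expression (RPKM below threshold at
    every stage of the oblong-sphere..15-somite window) vs expressed.
    Test 2: RPKM increase across the maternal-to-zygotic transition
    (oblong-sphere -> 50%-epiboly) vs no increase.
    """
    permissive_genes = {r.gene_id for r in efficiency if r.functional}
    observed_genes = {r.gene_id for r in efficiency}
    results: list[AssociationResult] = []

    counts_low = {("resistant", "low"): 0, ("resistant", "expressed"): 0,
                  ("permissive", "low"): 0, ("permissive", "expressed"): 0}
    counts_mzt = {("resistant", "increased"): 0, ("resistant", "not_increased"): 0,
                  ("permissive", "increased"): 0, ("permissive", "not_increased"): 0}
    stage_cols = {s: f"rpkm_{s}" for s in STAGES}
    for _, row in features.iterrows():
        gid = row["gene_id"]
        if gid not in observed_genes:
            continue
        group = "permissive" if gid in permissive_genes else "resistant"
        rpkm = {
            s: row[c] for s, c in stage_cols.items()
            if c in features.columns and not pd.isna(row[c])
        }
        try:
            cat = classify_expression(rpkm, low_threshold=low_rpkm)
            counts_low[(group, cat)] += 1
        except KeyError:
            logger.warning("gene %s lacks a window stage; excluded from Fig-3a test", gid)
        if "oblong-sphere" in rpkm and "50%-epiboly" in rpkm:
            counts_mzt[(group, mzt_change(rpkm["oblong-sphere"], rpkm["50%-epiboly"]))] += 1

    for label, counts, cats in (
        ("low_expression_vs_mutability", counts_low, ("low", "expressed")),
        ("mzt_increase_vs_mutability", counts_mzt, ("increased", "not_increased")),
    ):
        table = ContingencyTable2x2(
            counts[("resistant", cats[0])], counts[("resistant", cats[1])],
            counts[("permissive", cats[0])], counts[("permissive", cats[1])],
        )
        results.append(fisher_exact(table, feature_name=label,
                                    stage="early-development", alpha=alpha))

    gc_functional = [gc_content(r.guide_sequence) for r in efficiency if r.functional]
    gc_nonfunctional = [gc_content(r.guide_sequence) for r in efficiency
                        if not r.functional]
    if gc_functional and gc_nonfunctional:
        results.append(
            mann_whitney(gc_functional, gc_nonfunctional,
                         feature_name="gc_content_functional_vs_not",
                         stage="guides", alpha=alpha)
        )
    else:
        logger.warning("one GC group empty; Mann-Whitney comparison skipped")
    return results


def analyze_study(
    genes: Sequence[GeneModel],
    atac_peaks=None,
    meth_peaks=None,
    expression=None,
    probes=None,
    efficiency=None,
    config: RunConfig | None = None,
    chrom_sizes: Mapping[str, int] | None = None,
) -> tuple[pd.DataFrame, list[AssociationResult], list[AssociationResult]]:
    """Score, join and correlate one study; returns (features, correlations,
    contingency results)."""
    cfg = config or RunConfig(annotation=Path("."))
    features = build_feature_table(
        genes, atac_peaks, meth_peaks, expression, probes, efficiency,
        cluster_gap=cfg.cluster_gap, flank=cfg.flank, chrom_sizes=chrom_sizes,
        aggregation=cfg.aggregation, meth_weight=cfg.meth_weight,
    )
    correlations: list[AssociationResult] = []
    contingency: list[AssociationResult] = []
    if efficiency is not None and "efficiency" in features.columns:
        if features["efficiency"].notna().sum() == 0:
            raise EmptyJoinError(
                "no gene_id shared between the feature table's 'gene_id' column "
                "and the efficiency table's 'gene_id' column"
            )
        correlations = correlate_all(features, stages=cfg.stages, alpha=cfg.alpha)
        if expression is not None:
            contingency = contingency_tests(features, efficiency,
                                            low_rpkm=cfg.low_rpkm, alpha=cfg.alpha)
    return features, correlations, contingency


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _apply_alias(records, alias: Mapping[str, str]):
    from dataclasses import replace

    return [replace(r, gene_id=alias.get(r.gene_id, r.gene_id)) for r in records]


def run_pipeline(config: RunConfig) -> dict:
    """File-based end-to-end run; writes outputs + manifest, returns manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    genes = read_gene_annotation(config.annotation, config.annotation_format)
    chrom_sizes = None
    if config.chrom_sizes is not None:
        cs = pd.read_csv(config.chrom_sizes, sep="\t", header=None,
                         names=["chrom", "size"])
        chrom_sizes = dict(zip(cs["chrom"], cs["size"]))
    alias = read_alias_map(config.alias_map) if config.alias_map else {}

    atac = read_peaks(config.atac) if config.atac else None
    meth = read_peaks(config.methylation) if config.methylation else None
    expression = read_table(config.expression, "expression") if config.expression else None
    probes = read_table(config.probes, "probes") if config.probes else None
    efficiency = read_table(config.efficiency, "efficiency") if config.efficiency else None
    if alias:
        if expression:
            expression = _apply_alias(expression, alias)
        if probes:
            probes = _apply_alias(probes, alias)
        if efficiency:
            efficiency = _apply_alias(efficiency, alias)

    known_chroms = {g.chrom for g in genes}
    for name, peaks in (("atac", atac), ("methylation", meth)):
        if peaks:
            n_unknown = sum(1 for p in peaks if p.interval.chrom not in known_chroms)
            if n_unknown:
                logger.info("%s: %d peak(s) on chromosomes absent from the "
                            "annotation (retained, never overlap)", name, n_unknown)

    features, correlations, contingency = analyze_study(
        genes, atac, meth, expression, probes, efficiency,
        config=config, chrom_sizes=chrom_sizes,
    )

    write_feature_table(features, out / "features.tsv")
    write_association(correlations, out / "associations.tsv")
    write_association(contingency, out / "contingency.tsv")

    from . import __version__

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "cluster_gap": config.cluster_gap, "flank": config.flank,
            "low_rpkm": config.low_rpkm, "alpha": config.alpha,
            "aggregation": config.aggregation, "meth_weight": config.meth_weight,
            "stages": list(config.stages),
        },
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(Path(p))}
            for name, p in (
                ("annotation", config.annotation), ("atac", config.atac),
                ("methylation", config.methylation), ("expression", config.expression),
                ("probes", config.probes), ("efficiency", config.efficiency),
            )
            if p is not None
        },
        "n_genes_annotated": len(genes),
        "analyses": [
            {"feature": r.feature_name, "stage": r.stage_or_timepoint,
             "statistic": r.statistic_name, "n": r.n}
            for r in correlations + contingency
        ],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
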