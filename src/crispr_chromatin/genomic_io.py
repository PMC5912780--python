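"""Standard-format I/O with explicit coordinate conventions.

All genomic coordinates inside the package are 0-based half-open
(``[start, end)``), the BED convention.  GFF3/GTF, which are 1-based
inclusive, are converted at the parsing boundary and nowhere else, so
overlap arithmetic downstream never has to think about conventions.

Readers return plain frozen dataclasses; tabular data passes through
pandas.  Writers emit deterministic, gene-sorted TSV with floats rendered
to 6 significant digits, so two writes of the same table are
byte-identical.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd

logger = logging.getLogger(__name__)

#: Developmental stages of the expression table, in chronological order.
STAGES = (
    "64-cell",
    "oblong-sphere",
    "50%-epiboly",
    "15-somite",
    "36hpf",
    "48hpf",
    "60hpf",
    "72hpf",
)

VALID_STRANDS = {"+", "-", "."}


class FormatError(ValueError):
    """A record that cannot be parsed under the declared format."""


class ValidationError(ValueError):
    """A parsed record that violates a domain-type invariant."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval.

    ``start`` is inclusive and ``end`` exclusive; zero-length intervals are
    rejected because nothing in the pipeline can meaningfully overlap them.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"negative start {self.start} on {self.chrom}")
        if self.start >= self.end:
            raise ValidationError(
                f"empty interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Number of bases shared with ``other`` (0 on different chroms)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True, order=True)
class Peak:
    """One broadPeak record: a scored interval with a signal value."""

    interval: GenomicInterval
    name: str = "."
    score: int = 0
    signal_value: float = 0.0
    p_value: float = -1.0  # broadPeak col 8; parsed but unused downstream
    q_value: float = -1.0  # broadPeak col 9; parsed but unused downstream

    def __post_init__(self) -> None:
        if self.signal_value < 0:
            raise ValidationError(f"negative signalValue {self.signal_value}")


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    strand: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValidationError(f"transcript {self.transcript_id} has no exons")
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")
        srt = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(srt, srt[1:]):
            if a.end > b.start:
                raise ValidationError(
                    f"overlapping exons in transcript {self.transcript_id}: "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )
        object.__setattr__(self, "exons", tuple(srt))


@dataclass(frozen=True)
class GeneModel:
    """A gene with one or more transcripts, all on one chromosome."""

    gene_id: str
    transcripts: tuple[Transcript, ...]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValidationError(f"gene {self.gene_id} has no transcripts")
        chroms = {e.chrom for t in self.transcripts for e in t.exons}
        if len(chroms) != 1:
            raise ValidationError(
                f"gene {self.gene_id} spans multiple chromosomes: {sorted(chroms)}"
            )

    @property
    def chrom(self) -> str:
        return self.transcripts[0].exons[0].chrom


@dataclass(frozen=True)
class EfficiencyRecord:
    gene_id: str
    guide_sequence: str
    efficiency: float | None  # percent, may be missing
    functional: bool

    def __post_init__(self) -> None:
        seq = self.guide_sequence.upper()
        if len(seq) != 20 or set(seq) - set("ACGT"):
            raise ValidationError(
                f"guide for {self.gene_id} is not a 20-mer over ACGT: {self.guide_sequence!r}"
            )
        object.__setattr__(self, "guide_sequence", seq)
        if self.efficiency is not None and not (0.0 <= self.efficiency <= 100.0):
            raise ValidationError(
                f"efficiency {self.efficiency} for {self.gene_id} outside [0, 100]"
            )


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    stage: str
    rpkm: float

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage {self.stage!r} for {self.gene_id}")
        if self.rpkm < 0:
            raise ValidationError(f"negative RPKM {self.rpkm} for {self.gene_id}")


@dataclass(frozen=True)
class ProbeRecord:
    gene_id: str
    probe_id: str
    array_id: str
    median_intensity: float

    def __post_init__(self) -> None:
        if not self.median_intensity > 0:
            raise ValidationError(
                f"probe {self.probe_id} median_intensity {self.median_intensity} "
                "must be positive (log undefined otherwise)"
            )


# ---------------------------------------------------------------------------
# annotation


def read_gene_annotation(path: str | Path, format: str = "gff3") -> list[GeneModel]:
    """Parse a GFF3/GTF annotation into :class:`GeneModel` objects.

    Coordinates are converted from the format's 1-based inclusive convention
    to the internal 0-based half-open one.  Genes without any exon are
    dropped with a warning; exons whose parent transcript cannot be resolved
    are logged and skipped.
    """
    path = Path(path)
    if format not in {"gff3", "gtf"}:
        raise ValueError(f"unknown annotation format {format!r}")
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=(format == "gtf"),
            disable_infer_transcripts=(format == "gtf"),
        )
    except Exception as exc:  # gffutils raises assorted types on bad input
        raise FormatError(f"cannot parse {path} as {format}: {exc}") from exc

    transcript_types = {"mRNA", "transcript"}
    genes: list[GeneModel] = []
    n_orphans = 0
    # exons whose Parent chain does not reach a transcript
    known_tx = {f.id for t in transcript_types for f in db.features_of_type(t)}
    for exon in db.features_of_type("exon"):
        parents = exon.attributes.get("Parent") or exon.attributes.get("transcript_id")
        if not parents or not any(p in known_tx for p in parents):
            n_orphans += 1
    if n_orphans:
        logger.warning("%d orphan exon(s) skipped (no parent transcript)", n_orphans)

    for g in db.features_of_type("gene"):
        transcripts: list[Transcript] = []
        for ttype in transcript_types:
            for t in db.children(g, featuretype=ttype):
                exons = tuple(
                    GenomicInterval(e.seqid, e.start - 1, e.end, t.strand or ".")
                    for e in db.children(t, featuretype="exon")
                )
                if exons:
                    transcripts.append(Transcript(t.id, t.strand or ".", exons))
        if not transcripts:
            logger.warning("gene %s has no exons; dropped", g.id)
            continue
        genes.append(GeneModel(g.id, tuple(transcripts)))
    return genes


# ---------------------------------------------------------------------------
# peaks


def read_peaks(path: str | Path) -> list[Peak]:
    """Read a broadPeak (BED6+3) file, sorted by (chrom, start, end).

    Only columns 1-7 are required; signalValue is column 7.  Coordinates are
    already 0-based half-open in BED and are kept as-is.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split()
            if len(cols) < 7:
                raise FormatError(
                    f"{path}:{lineno}: expected >=7 broadPeak columns, got {len(cols)}"
                )
            try:
                chrom = cols[0]
                start, end = int(cols[1]), int(cols[2])
                name = cols[3]
                score = int(float(cols[4]))
                strand = cols[5] if cols[5] in VALID_STRANDS else "."
                signal = float(cols[6])
                pval = float(cols[7]) if len(cols) > 7 else -1.0
                qval = float(cols[8]) if len(cols) > 8 else -1.0
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if start < 0:
                raise FormatError(f"{path}:{lineno}: negative start {start}")
            try:
                peaks.append(
                    Peak(GenomicInterval(chrom, start, end, strand), name, score,
                         signal, pval, qval)
                )
            except ValidationError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))
    return peaks


def write_peaks(peaks: Iterable[Peak], path: str | Path) -> None:
    """Write peaks as broadPeak, sorted, deterministically formatted."""
    rows = sorted(peaks, key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))
    with open(path, "w") as fh:
        for p in rows:
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name}\t{p.score}\t{iv.strand}"
                f"\t{_fmt(p.signal_value)}\t{_fmt(p.p_value)}\t{_fmt(p.q_value)}\n"
            )


# ---------------------------------------------------------------------------
# tables

_TABLE_SCHEMAS = {
    "efficiency": ["gene_id", "guide_sequence", "efficiency", "functional"],
    "expression": ["gene_id", "stage", "rpkm"],
    "probes": ["gene_id", "probe_id", "array_id", "median_intensity"],
}


def read_table(path: str | Path, schema: str):
    """Read a typed TSV table.

    ``schema`` is one of ``efficiency``, ``expression``, ``probes``.  Rows
    violating the record invariants raise :class:`ValidationError` with the
    offending row number.
    """
    if schema not in _TABLE_SCHEMAS:
        raise ValueError(f"unknown table schema {schema!r}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _TABLE_SCHEMAS[schema] if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")

    records = []
    for idx, row in df.iterrows():
        rowno = idx + 2  # 1-based, after header
        try:
            if schema == "efficiency":
                eff = row["efficiency"]
                eff = None if pd.isna(eff) or eff == "" else float(eff)
                func = str(row["functional"]).strip().lower() in {"1", "true", "yes"}
                records.append(
                    EfficiencyRecord(row["gene_id"], row["guide_sequence"], eff, func)
                )
            elif schema == "expression":
                records.append(
                    ExpressionRecord(row["gene_id"], row["stage"], float(row["rpkm"]))
                )
            else:
                records.append(
                    ProbeRecord(row["gene_id"], row["probe_id"], row["array_id"],
                                float(row["median_intensity"]))
                )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path} row {rowno}: {exc}") from exc
    return records


def _fmt(x) -> str:
    """Render a float to 6 significant digits, stable across writes."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return ""
    if isinstance(x, float) and math.isinf(x):
        return "inf" if x > 0 else "-inf"
    if isinstance(x, (int,)) or (isinstance(x, float) and x == int(x) and abs(x) < 1e15):
        return str(int(x))
    return f"{x:.6g}"


def write_feature_table(features: pd.DataFrame, path: str | Path) -> None:
    """Write the per-gene feature table as deterministic TSV.

    Rows are sorted by gene_id and the column order is fixed; floats use
    6 significant digits, so identical tables yield byte-identical files.
    """
    df = features.sort_values("gene_id").reset_index(drop=True)
    cols = ["gene_id"] + [c for c in df.columns if c != "gene_id"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for _, row in df.iterrows():
            vals = []
            for c in cols:
                v = row[c]
                vals.append(str(v) if isinstance(v, str) else _fmt(v))
            fh.write("\t".join(vals) + "\n")


def write_association(results: Sequence, path: str | Path) -> None:
    """Write association results (feature, stage, statistic, n, p, flag)."""
    with open(path, "w") as fh:
        fh.write("feature\tstage_or_timepoint\tstatistic_name\tstatistic\tn\tp_value\tsignificant\n")
        for r in results:
            fh.write(
                f"{r.feature_name}\t{r.stage_or_timepoint}\t{r.statistic_name}\t"
                f"{_fmt(r.statistic)}\t{r.n}\t{_fmt(r.p_value)}\t"
                f"{'*' if r.significant else ''}\n"
            )


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Re-read a table written by :func:`write_feature_table`."""
    return pd.read_csv(path, sep="\t")


def read_alias_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (alias -> gene_id) used to translate external symbols."""
    df = pd.read_csv(path, sep="\t", header=None, names=["alias", "gene_id"], dtype=str)
    return dict(zip(df["alias"], df["gene_id"]))
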