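"""Gene structure: exons, derived introns, and fast boundary lookup.

All internal coordinates are 1-based inclusive (VCF-compatible): the first
intronic base downstream of an exon is at ``exon.end + 1`` and sits at splice
offset +1.  BED input (0-based half-open) is converted at parse time.
Chromosome names are normalized by stripping a leading ``chr`` prefix so that
mixed VCF/annotation dialects match deterministically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from intervaltree import IntervalTree

log = logging.getLogger(__name__)


class AnnotationError(ValueError):
    """Raised for unparseable or inconsistent gene annotations."""


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix (case-insensitive)."""
    return chrom[3:] if chrom[:3].lower() == "chr" else chrom


@dataclass(frozen=True)
class ExonInterval:
    """One exon, 1-based inclusive, with its rank in transcript orientation."""

    chrom: str
    start: int
    end: int
    strand: str
    transcript_id: str
    exon_rank: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise AnnotationError(
                f"exon start > end ({self.start} > {self.end}) in {self.transcript_id}"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"bad strand {self.strand!r} in {self.transcript_id}")
        if self.exon_rank < 1:
            raise AnnotationError(f"exon_rank < 1 in {self.transcript_id}")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class TranscriptModel:
    """A transcript as an ordered exon chain plus the introns derived from it.

    ``exons`` and ``introns`` are in genomic order; introns fill exactly the
    gaps between consecutive exons, so a transcript with *k* exons carries
    *k − 1* introns (fewer if exons are directly adjacent).
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[ExonInterval]
    introns: list[tuple[int, int]] = field(default_factory=list)

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end


def derive_introns(t: TranscriptModel) -> list[tuple[int, int]]:
    """Intervals ``[exon_i.end+1, exon_{i+1}.start-1]`` between consecutive exons.

    Single-exon transcripts yield ``[]``; directly adjacent exons (gap 0)
    yield no intron and log a warning.
    """
    introns: list[tuple[int, int]] = []
    for a, b in zip(t.exons, t.exons[1:]):
        if b.start <= a.end:
            raise AnnotationError(
                f"overlapping exons in transcript {t.transcript_id}: "
                f"[{a.start},{a.end}] vs [{b.start},{b.end}]"
            )
        if b.start == a.end + 1:
            log.warning(
                "transcript %s: adjacent exons at %d|%d yield no intron",
                t.transcript_id, a.end, b.start,
            )
            continue
        introns.append((a.end + 1, b.start - 1))
    return introns


@dataclass
class GenomeAnnotation:
    """All transcripts plus per-chromosome interval indexes for lookup.

    ``W`` is the flanking-window half-width in bp: the intronic bases within
    W of either splice site of an exon form the flanking region profiled
    downstream (default 200).
    """

    transcripts: dict[str, TranscriptModel]
    W: int = 200
    # per-chromosome interval trees; data = (transcript_id,) for exons and
    # (start, end, strand, transcript_id) for introns
    _exon_index: dict[str, IntervalTree] = field(default_factory=dict, repr=False)
    _intron_index: dict[str, IntervalTree] = field(default_factory=dict, repr=False)
    _warned_chroms: set[str] = field(default_factory=set, repr=False)

    def __post_init__(self) -> None:
        if self.W < 1:
            raise AnnotationError("W must be >= 1")
        if not self._exon_index:
            self._build_index()

    def _build_index(self) -> None:
        for t in self.transcripts.values():
            c = t.chrom
            etree = self._exon_index.setdefault(c, IntervalTree())
            itree = self._intron_index.setdefault(c, IntervalTree())
            for e in t.exons:
                etree.addi(e.start, e.end + 1, t.transcript_id)
            for s, e in t.introns:
                itree.addi(s, e + 1, (s, e, t.strand, t.transcript_id))

    def exons_at(self, chrom: str, pos: int) -> list[str]:
        """transcript_ids with an exon covering ``pos`` (sorted)."""
        tree = self._exon_index.get(normalize_chrom(chrom))
        if tree is None:
            return []
        return sorted(iv.data for iv in tree.at(pos))

    def introns_at(self, chrom: str, pos: int) -> list[tuple[int, int, str, str]]:
        """(start, end, strand, transcript_id) of introns covering ``pos``."""
        tree = self._intron_index.get(normalize_chrom(chrom))
        if tree is None:
            return []
        return sorted((iv.data for iv in tree.at(pos)), key=lambda x: x[3])

    def has_chrom(self, chrom: str) -> bool:
        return normalize_chrom(chrom) in self._exon_index

    def gene_of(self, transcript_id: str) -> str:
        return self.transcripts[transcript_id].gene_id


# ---------------------------------------------------------------------------
# parsing


def _build_transcript(
    transcript_id: str, gene_id: str, exons: list[tuple[str, int, int, str]]
) -> TranscriptModel:
    """Assemble a TranscriptModel from raw (chrom, start, end, strand) exons."""
    exons = sorted(exons, key=lambda x: x[1])
    chrom = exons[0][0]
    strand = exons[0][3]
    n = len(exons)
    models = []
    for i, (c, s, e, st) in enumerate(exons):
        if c != chrom or st != strand:
            raise AnnotationError(
                f"transcript {transcript_id} spans chromosomes or strands"
            )
        rank = i + 1 if strand == "+" else n - i
        models.append(ExonInterval(chrom, s, e, strand, transcript_id, rank))
    t = TranscriptModel(transcript_id, gene_id, chrom, strand, models)
    t.introns = derive_introns(t)
    return t


def _parse_gff_like(path: str | Path, gtf: bool) -> dict[str, TranscriptModel]:
    import gffutils

    # pre-scan so parse failures name the offending line
    with open(path) as fh:
        n_data = 0
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            if len(line.rstrip("\n").split("\t")) < 8:
                raise AnnotationError(f"unparseable annotation line {lineno}: {line!r}")
            n_data += 1
    if n_data == 0:
        raise AnnotationError("no transcripts in annotation")

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    # transcript -> gene mapping from transcript-level features where present
    tx2gene: dict[str, str] = {}
    for ftype in ("transcript", "mRNA"):
        for f in db.features_of_type(ftype):
            gid = f.attributes.get("gene_id", f.attributes.get("Parent", [f.id]))[0]
            tx2gene[f.id] = gid

    grouped: dict[str, list[tuple[str, int, int, str]]] = {}
    genes: dict[str, str] = {}
    for f in db.features_of_type("exon"):
        if gtf:
            tid = f.attributes["transcript_id"][0]
        else:
            tid = f.attributes.get("transcript_id", f.attributes.get("Parent"))
            if tid is None:
                raise AnnotationError(f"exon without Parent/transcript_id at {f.start}")
            tid = tid[0]
        gid = f.attributes.get("gene_id", [None])[0] or tx2gene.get(tid, tid)
        chrom = normalize_chrom(f.seqid)
        grouped.setdefault(tid, []).append((chrom, f.start, f.end, f.strand))
        genes[tid] = gid

    if not grouped:
        raise AnnotationError("no transcripts in annotation")
    return {
        tid: _build_transcript(tid, genes[tid], exons)
        for tid, exons in grouped.items()
    }


def _parse_bed12(path: str | Path) -> dict[str, TranscriptModel]:
    transcripts: dict[str, TranscriptModel] = {}
    with open(path) as fh:
        n_data = 0
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 12:
                raise AnnotationError(f"unparseable annotation line {lineno}: {line!r}")
            n_data += 1
            chrom = normalize_chrom(fields[0])
            chrom_start = int(fields[1])
            name, strand = fields[3], fields[5]
            block_sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            block_starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            # BED is 0-based half-open: 1-based inclusive exon is
            # [chromStart+blockStart+1, chromStart+blockStart+blockSize]
            exons = [
                (chrom, chrom_start + bs + 1, chrom_start + bs + sz, strand)
                for bs, sz in zip(block_starts, block_sizes)
            ]
            gene = name.rsplit(".", 1)[0] if "." in name else name
            transcripts[name] = _build_transcript(name, gene, exons)
    if not transcripts:
        raise AnnotationError("no transcripts in annotation")
    return transcripts


def load_annotation(
    path: str | Path, format: str | None = None, W: int = 200
) -> GenomeAnnotation:
    """Read a gene annotation (GFF3, GTF, or BED12) and derive introns.

    Parameters
    ----------
    path:
        Annotation file.
    format:
        ``gff3``, ``gtf`` or ``bed12``; inferred from the file suffix when
        omitted.
    W:
        Flanking window half-width in bp (default 200).
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower().lstrip(".")
        format = {"gff": "gff3", "gff3": "gff3", "gtf": "gtf", "bed": "bed12",
                  "bed12": "bed12"}.get(suffix)
        if format is None:
            raise AnnotationError(f"cannot infer annotation format from {path.name}")
    if format in ("gff3", "gtf"):
        transcripts = _parse_gff_like(path, gtf=(format == "gtf"))
    elif format == "bed12":
        transcripts = _parse_bed12(path)
    else:
        raise AnnotationError(f"unknown annotation format {format!r}")
    return GenomeAnnotation(transcripts=transcripts, W=W)


# ---------------------------------------------------------------------------
# writers


def write_intron_table(ann: GenomeAnnotation, path: str | Path) -> None:
    """Tab-separated intron table (chrom, start, end, strand, transcript_id,
    intron_rank) for debugging."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tstrand\ttranscript_id\tintron_rank\n")
        for t in sorted(ann.transcripts.values(), key=lambda t: t.transcript_id):
            n = len(t.introns)
            for i, (s, e) in enumerate(t.introns):
                rank = i + 1 if t.strand == "+" else n - i
                fh.write(f"{t.chrom}\t{s}\t{e}\t{t.strand}\t{t.transcript_id}\t{rank}\n")


def write_bed12(ann: GenomeAnnotation, path: str | Path) -> None:
    """Write transcripts as BED12 (0-based half-open), one line each."""
    with open(path, "w") as fh:
        for t in sorted(ann.transcripts.values(), key=lambda t: t.transcript_id):
            chrom_start = t.start - 1
            sizes = ",".join(str(len(e)) for e in t.exons)
            starts = ",".join(str(e.start - 1 - chrom_start) for e in t.exons)
            fh.write(
                f"{t.chrom}\t{chrom_start}\t{t.end}\t{t.transcript_id}\t0\t"
                f"{t.strand}\t{chrom_start}\t{t.end}\t0\t{len(t.exons)}\t"
                f"{sizes}\t{starts}\n"
            )


def write_gff3(ann: GenomeAnnotation, path: str | Path) -> None:
    """Write transcripts and exons as GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in sorted(ann.transcripts.values(), key=lambda t: t.transcript_id):
            fh.write(
                f"{t.chrom}\tintronflank\ttranscript\t{t.start}\t{t.end}\t.\t"
                f"{t.strand}\t.\tID={t.transcript_id};gene_id={t.gene_id}\n"
            )
            for i, e in enumerate(t.exons, 1):
                fh.write(
                    f"{t.chrom}\tintronflank\texon\t{e.start}\t{e.end}\t.\t"
                    f"{t.strand}\t.\tID={t.transcript_id}.exon{i};"
                    f"Parent={t.transcript_id};gene_id={t.gene_id}\n"
                )


def iter_introns(ann: GenomeAnnotation) -> Iterator[tuple[str, int, int, str, str]]:
    """Yield (chrom, start, end, strand, transcript_id) over all introns."""
    for t in ann.transcripts.values():
        for s, e in t.introns:
            yield t.chrom, s, e, t.strand, t.transcript_id
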