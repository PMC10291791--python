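"""Assign variants to splice-site offset buckets and aggregate positional profiles.

Positions inside introns within W bases of a splice site form the flanking
region.  Offsets count from 1 at the first intronic base: +d moving into the
intron from the donor (5' splice) site, -d moving upstream from the acceptor
(3' splice) site, both in transcript orientation.  Donor-side +d and
acceptor-side -d collapse into the symmetric bucket d; the side is retained
so profiles can be split by splice site.

Precedence: exonic anywhere beats intronic everywhere (variant partitions
must be disjoint); among flanking candidates the minimal offset wins, then
donor over acceptor at an exact midpoint, then the lexicographically smallest
transcript id.  Each intronic base is assigned to its nearer boundary only,
so short introns are never double-counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Optional

import numpy as np
import pandas as pd

from .gene_model import GenomeAnnotation, normalize_chrom
from .qc_filters import deleterious_filter
from .variant_io import UniqueVariant

log = logging.getLogger(__name__)

REGIONS = ("exonic", "intronic_flanking", "deep_intronic", "intergenic")


@dataclass(frozen=True)
class PositionAssignment:
    region: str
    d: Optional[int] = None      # offset bucket, 1..W, flanking only
    side: Optional[str] = None   # donor | acceptor, flanking only
    transcript_id: Optional[str] = None

    def __post_init__(self) -> None:
        assert self.region in REGIONS
        assert (self.d is not None) == (self.region == "intronic_flanking")
        assert (self.side is None) or self.side in ("donor", "acceptor")


def _offsets(pos: int, start: int, end: int, strand: str) -> tuple[int, int]:
    """(donor_offset, acceptor_offset) of pos inside intron [start, end]."""
    left = pos - start + 1   # distance from genomic-left intron edge
    right = end - pos + 1    # distance from genomic-right intron edge
    return (left, right) if strand == "+" else (right, left)


def classify_position(
    chrom: str, pos: int, ann: GenomeAnnotation
) -> PositionAssignment:
    """Region class and, for flanking positions, the offset bucket and side."""
    chrom = normalize_chrom(chrom)
    if not ann.has_chrom(chrom):
        if chrom not in ann._warned_chroms:
            ann._warned_chroms.add(chrom)
            log.warning("chromosome %s absent from annotation; "
                        "variants there count as intergenic", chrom)
        return PositionAssignment("intergenic")

    exon_hits = ann.exons_at(chrom, pos)
    if exon_hits:
        return PositionAssignment("exonic", transcript_id=exon_hits[0])

    intron_hits = ann.introns_at(chrom, pos)
    best: Optional[tuple[int, int, str, str]] = None  # (d, side_rank, tid); donor<acceptor
    for start, end, strand, tid in intron_hits:
        dd, da = _offsets(pos, start, end, strand)
        d, side_rank = (dd, 0) if dd <= da else (da, 1)
        if d > ann.W:
            continue
        cand = (d, side_rank, tid)
        if best is None or cand < best:
            best = cand
    if best is not None:
        d, side_rank, tid = best
        return PositionAssignment(
            "intronic_flanking", d=d,
            side="donor" if side_rank == 0 else "acceptor",
            transcript_id=tid,
        )
    if intron_hits:
        return PositionAssignment("deep_intronic",
                                  transcript_id=intron_hits[0][3])
    return PositionAssignment("intergenic")


# ---------------------------------------------------------------------------
# aggregation


@dataclass
class PositionProfile:
    """Per-bucket tallies over unique variants plus partition totals.

    ``per_bucket`` is indexed by d in 1..W with columns raw_count,
    pass_count, false_count, fp, mean_depth, deleterious_count,
    raw_donor, raw_acceptor.  fp and mean_depth are NaN where undefined
    (no raw variants / no depth), never 0.

    ``totals`` maps each partition (total, exonic, intronic,
    intronic_flanking, deep_intronic, intergenic) to raw/pass/deleterious
    counts and distinct-gene counts.
    """

    per_bucket: pd.DataFrame
    totals: dict[str, dict[str, int]]
    W: int

    def bucket(self, d: int) -> pd.Series:
        return self.per_bucket.loc[d]


def assign_all(
    uniques: Iterable[UniqueVariant], ann: GenomeAnnotation
) -> list[tuple[UniqueVariant, PositionAssignment]]:
    return [(u, classify_position(u.chrom, u.pos, ann)) for u in uniques]


def build_profile(
    uniques: Iterable[UniqueVariant],
    ann: GenomeAnnotation,
    W: Optional[int] = None,
    deleterious: Callable[[UniqueVariant], bool] = deleterious_filter,
) -> PositionProfile:
    """Aggregate unique variants into a positional profile.

    ``deleterious`` is the cascade predicate, evaluated only on pass
    variants (so the deleterious set is a subset of the pass set by
    construction).
    """
    W = ann.W if W is None else W
    if W <= 0:
        raise ValueError("W must be positive")
    if W != ann.W:
        raise ValueError(f"profile W={W} disagrees with annotation W={ann.W}")

    idx = np.arange(1, W + 1)
    raw = np.zeros(W, dtype=int)
    passed = np.zeros(W, dtype=int)
    dele = np.zeros(W, dtype=int)
    raw_donor = np.zeros(W, dtype=int)
    raw_acceptor = np.zeros(W, dtype=int)
    dp_sum = np.zeros(W, dtype=float)
    dp_n = np.zeros(W, dtype=int)

    totals = {
        part: {"raw": 0, "pass": 0, "deleterious": 0}
        for part in ("total",) + REGIONS + ("intronic",)
    }
    genes: dict[tuple[str, str], set] = {}

    def _tally(part: str, status: str, gene: Optional[str]) -> None:
        totals[part][status] += 1
        if gene is not None:
            genes.setdefault((part, status), set()).add(gene)

    for u, a in assign_all(uniques, ann):
        gene = ann.gene_of(a.transcript_id) if a.transcript_id else None
        is_pass = u.any_pass
        is_del = bool(is_pass and deleterious(u))
        parts = ["total", a.region]
        if a.region in ("intronic_flanking", "deep_intronic"):
            parts.append("intronic")
        for part in parts:
            _tally(part, "raw", gene)
            if is_pass:
                _tally(part, "pass", gene)
            if is_del:
                _tally(part, "deleterious", gene)
        if a.region == "intronic_flanking":
            i = a.d - 1
            raw[i] += 1
            (raw_donor if a.side == "donor" else raw_acceptor)[i] += 1
            if is_pass:
                passed[i] += 1
            if is_del:
                dele[i] += 1
            if u.mean_dp is not None:
                dp_sum[i] += u.mean_dp
                dp_n[i] += 1

    with np.errstate(invalid="ignore", divide="ignore"):
        fp = np.where(raw > 0, (raw - passed) / np.where(raw > 0, raw, 1), np.nan)
        mean_depth = np.where(dp_n > 0, dp_sum / np.where(dp_n > 0, dp_n, 1), np.nan)

    per_bucket = pd.DataFrame(
        {
            "raw_count": raw,
            "pass_count": passed,
            "false_count": raw - passed,
            "fp": fp,
            "mean_depth": mean_depth,
            "deleterious_count": dele,
            "raw_donor": raw_donor,
            "raw_acceptor": raw_acceptor,
        },
        index=pd.Index(idx, name="position"),
    )

    totals_out = {
        part: {
            "raw": totals[part]["raw"],
            "pass": totals[part]["pass"],
            "deleterious": totals[part]["deleterious"],
            "genes_raw": len(genes.get((part, "raw"), ())),
            "genes_pass": len(genes.get((part, "pass"), ())),
            "genes_deleterious": len(genes.get((part, "deleterious"), ())),
        }
        for part in totals
    }
    return PositionProfile(per_bucket=per_bucket, totals=totals_out, W=W)


def gene_counts(
    uniques: Iterable[UniqueVariant],
    ann: GenomeAnnotation,
    partition: str = "intronic_flanking",
    status: str = "raw",
    deleterious: Callable[[UniqueVariant], bool] = deleterious_filter,
) -> int:
    """Distinct genes contributing >= 1 variant to a partition.

    ``partition`` is a region class or ``intronic`` (flanking + deep);
    ``status`` is raw, pass, or deleterious.  Gene identity comes from the
    transcript that resolved the position assignment.
    """
    if status not in ("raw", "pass", "deleterious"):
        raise ValueError(f"unknown status {status!r}")
    seen: set[str] = set()
    for u, a in assign_all(uniques, ann):
        in_part = (a.region == partition) or (
            partition == "intronic"
            and a.region in ("intronic_flanking", "deep_intronic")
        ) or partition == "total"
        if not in_part or a.transcript_id is None:
            continue
        if status == "pass" and not u.any_pass:
            continue
        if status == "deleterious" and not (u.any_pass and deleterious(u)):
            continue
        seen.add(ann.gene_of(a.transcript_id))
    return len(seen)


# ---------------------------------------------------------------------------
# table writers (profile table layouts: raw / FP+depth / pass / deleterious)


def write_profile_tables(profile: PositionProfile, outdir) -> list[str]:
    """Write the four positional TSV tables; returns the paths written.

    raw_counts.tsv:          position, raw_count
    fp_profile.tsv:          position, raw_count, pass_count, false_count,
                             fp, mean_depth
    pass_counts.tsv:         position, pass_count
    deleterious_counts.tsv:  position, deleterious_count
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pb = profile.per_bucket
    spec = {
        "raw_counts.tsv": ["raw_count"],
        "fp_profile.tsv": ["raw_count", "pass_count", "false_count", "fp",
                           "mean_depth"],
        "pass_counts.tsv": ["pass_count"],
        "deleterious_counts.tsv": ["deleterious_count"],
    }
    written = []
    for name, cols in spec.items():
        path = outdir / name
        pb[cols].to_csv(path, sep="\t", float_format="%.6g", na_rep="NA")
        written.append(str(path))
    return written
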