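"""Parse annotated VCFs into variant records and deduplicate across samples.

A cohort is read one single-sample VCF at a time; every record carries the
QC metrics the hard filter consumes (QD, FS, MQ, MQRankSum, ReadPosRankSum,
DP, DV) and the annotation scores the deleterious cascade consumes
(population max allele frequency, clinical significance, CADD, SPIDEX
dpsi z-score, dbscSNV).  Missing tags become missing fields, never zeros.

Across samples, a variant seen in several exomes counts once: deduplication
keys on (chrom, pos, ref, alt) and aggregates per-sample observations into a
:class:`UniqueVariant`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Literal, Optional

log = logging.getLogger(__name__)

VClass = Literal["SNV", "INDEL"]


@dataclass(frozen=True)
class QCMetrics:
    """Per-record quality annotations; any field may be missing (None).

    DV is the variant-supporting read depth; when the VCF carries no DV tag
    it is taken from the alt entry of FORMAT/AD.
    """

    qd: Optional[float] = None
    fs: Optional[float] = None
    mq: Optional[float] = None
    mq_rank_sum: Optional[float] = None
    read_pos_rank_sum: Optional[float] = None
    dp: Optional[float] = None
    dv: Optional[float] = None

    def __post_init__(self) -> None:
        if self.dp is not None and self.dp < 0:
            raise ValueError("DP < 0")
        if self.dv is not None and self.dv < 0:
            raise ValueError("DV < 0")
        if self.dp is not None and self.dv is not None and self.dv > self.dp:
            raise ValueError("DV > DP")


@dataclass(frozen=True)
class AnnotationScores:
    """Deleteriousness annotations; any field may be missing (None)."""

    af_popmax: Optional[float] = None
    clinsig: Optional[str] = None
    cadd: Optional[float] = None
    dpsi_zscore: Optional[float] = None
    dbscsnv: Optional[float] = None

    def __post_init__(self) -> None:
        if self.af_popmax is not None and not (0.0 <= self.af_popmax <= 1.0):
            raise ValueError(f"af_popmax outside [0,1]: {self.af_popmax}")
        if self.dbscsnv is not None and not (0.0 <= self.dbscsnv <= 1.0):
            raise ValueError(f"dbscsnv outside [0,1]: {self.dbscsnv}")


@dataclass(frozen=True)
class VariantRecord:
    """One called variant in one sample."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    vclass: VClass
    qc: QCMetrics = field(default_factory=QCMetrics)
    ann: AnnotationScores = field(default_factory=AnnotationScores)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def classify_vclass(ref: str, alt: str) -> VClass:
    """SNV iff both alleles are single bases; anything else is an indel."""
    return "SNV" if len(ref) == 1 and len(alt) == 1 else "INDEL"


@dataclass
class UniqueVariant:
    """A cross-sample-deduplicated variant.

    ``any_pass`` follows the configured aggregation policy (default: pass in
    at least one carrier sample).  ``ann`` is the per-site annotation
    collapsed over observations: the most deleterious score where scores
    disagree, first non-missing frequency/clinical label otherwise.
    """

    key: tuple[str, int, str, str]
    observations: list[VariantRecord]
    any_pass: bool = False

    def __post_init__(self) -> None:
        if not self.observations:
            raise ValueError("UniqueVariant with no observations")
        if any(o.key != self.key for o in self.observations):
            raise ValueError("observation key mismatch")

    @property
    def chrom(self) -> str:
        return self.key[0]

    @property
    def pos(self) -> int:
        return self.key[1]

    @property
    def vclass(self) -> VClass:
        return self.observations[0].vclass

    @property
    def n_samples(self) -> int:
        return len({o.sample_id for o in self.observations})

    @property
    def mean_dp(self) -> Optional[float]:
        dps = [o.qc.dp for o in self.observations if o.qc.dp is not None]
        return sum(dps) / len(dps) if dps else None

    @property
    def ann(self) -> AnnotationScores:
        obs = self.observations
        return AnnotationScores(
            af_popmax=next((o.ann.af_popmax for o in obs if o.ann.af_popmax is not None), None),
            clinsig=next((o.ann.clinsig for o in obs if o.ann.clinsig is not None), None),
            cadd=_max_or_none(o.ann.cadd for o in obs),
            dpsi_zscore=_max_or_none(o.ann.dpsi_zscore for o in obs),
            dbscsnv=_max_or_none(o.ann.dbscsnv for o in obs),
        )


def _max_or_none(values: Iterable[Optional[float]]) -> Optional[float]:
    present = [v for v in values if v is not None]
    return max(present) if present else None


# ---------------------------------------------------------------------------
# field map


@dataclass
class FieldMap:
    """Mapping of VCF tags onto QCMetrics / AnnotationScores fields.

    ``info`` maps internal QC field names to INFO tags; ``dv_from_ad``
    falls back to FORMAT/AD[alt] for DV when no DV tag is mapped or present.
    ``scores`` maps annotation fields to INFO tags; ``dbscsnv`` may list
    several tags whose maximum is taken (the two dbscSNV ensemble scores).
    """

    info: dict[str, str] = field(default_factory=lambda: {
        "qd": "QD",
        "fs": "FS",
        "mq": "MQ",
        "mq_rank_sum": "MQRankSum",
        "read_pos_rank_sum": "ReadPosRankSum",
        "dp": "DP",
    })
    dv_tag: Optional[str] = None
    dv_from_ad: bool = True
    scores: dict[str, object] = field(default_factory=lambda: {
        "af_popmax": "AF_POPMAX",
        "clinsig": "CLNSIG",
        "cadd": "CADD",
        "dpsi_zscore": "DPSI_ZSCORE",
        "dbscsnv": ["DBSCSNV_ADA", "DBSCSNV_RF"],
    })

    @classmethod
    def from_dict(cls, d: dict) -> "FieldMap":
        fm = cls()
        fm.info.update(d.get("info", {}))
        fm.scores.update(d.get("scores", {}))
        fm.dv_tag = d.get("dv_tag", fm.dv_tag)
        fm.dv_from_ad = d.get("dv_from_ad", fm.dv_from_ad)
        return fm


def _pick_allele(value, ai: int):
    """Per-allele tags (comma-separated / Number=A) matched by allele index."""
    if isinstance(value, (tuple, list)):
        return value[ai] if ai < len(value) else None
    return value


def _as_float(value) -> Optional[float]:
    if value is None:
        return None
    try:
        v = float(value)
    except (TypeError, ValueError):
        return None
    if math.isnan(v):
        return None
    # htslib stores INFO floats as float32; rounding off the representation
    # error keeps threshold comparisons at printed values (e.g. 0.6) exact
    return round(v, 6)


def read_vcf(
    path: str | Path,
    sample_id: Optional[str] = None,
    field_map: Optional[FieldMap] = None,
) -> Iterator[VariantRecord]:
    """Stream VariantRecords from a (plain or bgzipped) VCF.

    Multi-allelic sites are split into one record per alt allele before
    field extraction; per-allele INFO values are matched by allele index.
    ``sample_id`` defaults to the VCF's sample name (or the file stem for a
    sites-only VCF).
    """
    from cyvcf2 import VCF

    fm = field_map or FieldMap()
    vcf = VCF(str(path))
    if sample_id is None:
        sample_id = vcf.samples[0] if vcf.samples else Path(path).stem

    header_info = {
        h.info().get("ID")
        for h in vcf.header_iter()
        if h.type == "INFO"
    }
    wanted = list(fm.info.values()) + [
        t for v in fm.scores.values() for t in (v if isinstance(v, list) else [v])
    ]
    if fm.dv_tag:
        wanted.append(fm.dv_tag)
    for tag in wanted:
        if tag not in header_info:
            log.warning("%s: tag %s not declared in header; treated as missing",
                        path, tag)

    for v in vcf:
        for ai, alt in enumerate(v.ALT):
            qc_vals: dict[str, Optional[float]] = {}
            for fname, tag in fm.info.items():
                qc_vals[fname] = _as_float(_pick_allele(v.INFO.get(tag), ai))
            dv = None
            if fm.dv_tag is not None:
                dv = _as_float(_pick_allele(v.INFO.get(fm.dv_tag), ai))
            if dv is None and fm.dv_from_ad and vcf.samples:
                ad = v.format("AD")
                if ad is not None:
                    raw = ad[0][ai + 1] if ad.shape[1] > ai + 1 else None
                    dv = _as_float(raw) if raw is not None and raw >= 0 else None
            if dv is not None and qc_vals.get("dp") is not None:
                dv = min(dv, qc_vals["dp"])  # caller-side clamp for odd VCFs

            sc: dict[str, object] = {}
            for fname, tag in fm.scores.items():
                if fname == "clinsig":
                    raw = v.INFO.get(tag)
                    sc[fname] = str(raw) if raw is not None else None
                    continue
                tags = tag if isinstance(tag, list) else [tag]
                vals = [_as_float(_pick_allele(v.INFO.get(t), ai)) for t in tags]
                vals = [x for x in vals if x is not None]
                sc[fname] = max(vals) if vals else None

            yield VariantRecord(
                sample_id=sample_id,
                chrom=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alt=alt,
                vclass=classify_vclass(v.REF, alt),
                qc=QCMetrics(dv=dv, **qc_vals),
                ann=AnnotationScores(**sc),
            )


def read_cohort(
    paths: Iterable[str | Path], field_map: Optional[FieldMap] = None
) -> list[VariantRecord]:
    """Read several single-sample VCFs into one record list."""
    records: list[VariantRecord] = []
    for p in paths:
        records.extend(read_vcf(p, field_map=field_map))
    return records


# ---------------------------------------------------------------------------
# deduplication ("counted as 1")


def dedup_unique(
    records: Iterable[VariantRecord],
    pass_policy: str = "any",
    thresholds=None,
    missing_fails: bool = False,
) -> list[UniqueVariant]:
    """Collapse records to one UniqueVariant per (chrom, pos, ref, alt).

    A variant detected in multiple samples is counted once.  Pass status
    under disagreeing observations follows ``pass_policy``:

    - ``any`` (default): passes the hard filter in >= 1 sample;
    - ``majority``: passes in more than half of its observations;
    - ``all``: passes in every observation.
    """
    from .qc_filters import hard_filter

    if pass_policy not in ("any", "majority", "all"):
        raise ValueError(f"unknown pass_policy {pass_policy!r}")

    grouped: dict[tuple, list[VariantRecord]] = {}
    for r in records:
        grouped.setdefault(r.key, []).append(r)

    uniques = []
    for key in sorted(grouped):
        obs = grouped[key]
        verdicts = [
            hard_filter(o, thresholds=thresholds, missing_fails=missing_fails).passed
            for o in obs
        ]
        if pass_policy == "any":
            passed = any(verdicts)
        elif pass_policy == "all":
            passed = all(verdicts)
        else:
            passed = sum(verdicts) * 2 > len(verdicts)
        uniques.append(UniqueVariant(key=key, observations=obs, any_pass=passed))
    return uniques
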