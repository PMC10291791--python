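"""Hard-filter (pass/false) and deleterious-filter cascades as pure predicates.

The hard filter reimplements GATK-style site filtration with separate SNV
and indel branches:

- SNV fails when  QD < 2.0 or FS > 60.0 or MQ < 40.0 or MQRankSum < -12.5
  or ReadPosRankSum < -8.0 or DP < 20 or DV < 8;
- INDEL fails when QD < 2.0 or FS > 200.0 or ReadPosRankSum < -20.0
  or DP < 20 or DV < 8.

A missing metric never triggers a violation by default (rank-sum
annotations are legitimately absent at hom-alt sites); ``missing_fails``
switches to the conservative alternative.

The deleterious cascade keeps a pass variant when it is rare
(af_popmax < 0.05 or unknown), not labelled Benign/Likely_benign, and its
in-silico scores clear CADD > 10, SPIDEX dpsi z >= 2, dbscSNV > 0.6.  dbscSNV
is only defined near canonical splice sites, so by default the conjunction is
evaluated over the scores actually present (at least one required); a strict
three-way AND is available via ``score_policy="strict"``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

from .variant_io import UniqueVariant, VariantRecord


@dataclass(frozen=True)
class FilterVerdict:
    passed: bool
    failed_criteria: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        assert self.passed == (len(self.failed_criteria) == 0)


@dataclass(frozen=True)
class HardFilterThresholds:
    """Hard-filter cutoffs; defaults are the conventional exome values."""

    snv_qd_min: float = 2.0
    snv_fs_max: float = 60.0
    snv_mq_min: float = 40.0
    snv_mqranksum_min: float = -12.5
    snv_readposranksum_min: float = -8.0
    indel_qd_min: float = 2.0
    indel_fs_max: float = 200.0
    indel_readposranksum_min: float = -20.0
    dp_min: float = 20.0
    dv_min: float = 8.0


@dataclass(frozen=True)
class DeleteriousThresholds:
    af_popmax_max: float = 0.05
    cadd_min_exclusive: float = 10.0
    dpsi_zscore_min: float = 2.0
    dbscsnv_min_exclusive: float = 0.6
    benign_labels: tuple[str, ...] = ("benign", "likely_benign")


DEFAULT_HARD = HardFilterThresholds()
DEFAULT_DELETERIOUS = DeleteriousThresholds()


def _violates(value: Optional[float], ok, missing_fails: bool) -> bool:
    if value is None:
        return missing_fails
    return not ok(value)


def hard_filter(
    v: VariantRecord,
    thresholds: Optional[HardFilterThresholds] = None,
    missing_fails: bool = False,
) -> FilterVerdict:
    """Classify one record as pass or false; pure in the record's metrics."""
    th = thresholds or DEFAULT_HARD
    q = v.qc
    failed: list[str] = []
    if v.vclass == "SNV":
        checks = [
            ("QD", q.qd, lambda x: x >= th.snv_qd_min),
            ("FS", q.fs, lambda x: x <= th.snv_fs_max),
            ("MQ", q.mq, lambda x: x >= th.snv_mq_min),
            ("MQRankSum", q.mq_rank_sum, lambda x: x >= th.snv_mqranksum_min),
            ("ReadPosRankSum", q.read_pos_rank_sum,
             lambda x: x >= th.snv_readposranksum_min),
            ("DP", q.dp, lambda x: x >= th.dp_min),
            ("DV", q.dv, lambda x: x >= th.dv_min),
        ]
    else:
        checks = [
            ("QD", q.qd, lambda x: x >= th.indel_qd_min),
            ("FS", q.fs, lambda x: x <= th.indel_fs_max),
            ("ReadPosRankSum", q.read_pos_rank_sum,
             lambda x: x >= th.indel_readposranksum_min),
            ("DP", q.dp, lambda x: x >= th.dp_min),
            ("DV", q.dv, lambda x: x >= th.dv_min),
        ]
    for name, value, ok in checks:
        if _violates(value, ok, missing_fails):
            failed.append(name)
    return FilterVerdict(passed=not failed, failed_criteria=tuple(failed))


_LABEL_SPLIT = re.compile(r"[,/|;]")


def is_benign_label(clinsig: Optional[str],
                    benign_labels=DEFAULT_DELETERIOUS.benign_labels) -> bool:
    """Case-insensitive token match on comma/slash/pipe-joined labels."""
    if clinsig is None:
        return False
    tokens = {t.strip().lower().replace(" ", "_")
              for t in _LABEL_SPLIT.split(clinsig)}
    return bool(tokens & set(benign_labels))


def deleterious_filter(
    u: UniqueVariant,
    thresholds: Optional[DeleteriousThresholds] = None,
    score_policy: str = "present",
    signed_dpsi: bool = True,
) -> bool:
    """True iff a pass variant survives the deleteriousness cascade.

    Applied per unique variant on its collapsed (most deleterious)
    annotation.  Never true for a variant that failed QC, so the deleterious
    set is a subset of the pass set on any input.

    ``signed_dpsi=False`` compares |dpsi z| instead of the signed value.
    """
    if score_policy not in ("present", "strict"):
        raise ValueError(f"unknown score_policy {score_policy!r}")
    th = thresholds or DEFAULT_DELETERIOUS
    if not u.any_pass:
        return False
    ann = u.ann

    # (1) population frequency: unknown is treated as rare
    if ann.af_popmax is not None and ann.af_popmax >= th.af_popmax_max:
        return False
    # (2) clinical significance: must not be Benign/Likely_benign
    if is_benign_label(ann.clinsig, th.benign_labels):
        return False
    # (3) in-silico scores
    dpsi = ann.dpsi_zscore
    if dpsi is not None and not signed_dpsi:
        dpsi = abs(dpsi)
    score_checks = [
        (ann.cadd, lambda x: x > th.cadd_min_exclusive),
        (dpsi, lambda x: x >= th.dpsi_zscore_min),
        (ann.dbscsnv, lambda x: x > th.dbscsnv_min_exclusive),
    ]
    if score_policy == "strict":
        return all(v is not None and ok(v) for v, ok in score_checks)
    present = [(v, ok) for v, ok in score_checks if v is not None]
    if not present:
        return False
    return all(ok(v) for v, ok in present)
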