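"""Offset classification (vs a brute-force oracle) and profile aggregation."""

import numpy as np
import pytest

from intronflank.position_profile import (build_profile, classify_position,
                                          gene_counts)
from intronflank.variant_io import (AnnotationScores, QCMetrics,
                                    UniqueVariant, VariantRecord)
from conftest import make_annotation


# ---------------------------------------------------------------------------
# independent brute-force oracle: scan every exon and intron of every
# transcript, compute all boundary distances, apply the documented
# precedence rules (written from scratch, no shared code path)


def oracle_classify(chrom, pos, ann):
    chrom = chrom[3:] if chrom.lower().startswith("chr") else chrom
    exon_hits, flank_cands, intron_hits = [], [], []
    for tid in sorted(ann.transcripts):
        t = ann.transcripts[tid]
        if t.chrom != chrom:
            continue
        for e in t.exons:
            if e.start <= pos <= e.end:
                exon_hits.append(tid)
        for s, e in t.introns:
            if s <= pos <= e:
                intron_hits.append(tid)
                if t.strand == "+":
                    dd, da = pos - s + 1, e - pos + 1
                else:
                    dd, da = e - pos + 1, pos - s + 1
                if dd <= da:
                    d, side = dd, "donor"
                else:
                    d, side = da, "acceptor"
                if d <= ann.W:
                    flank_cands.append((d, 0 if side == "donor" else 1, tid))
    if exon_hits:
        return ("exonic", None, None, min(exon_hits))
    if flank_cands:
        d, srank, tid = min(flank_cands)
        return ("intronic_flanking", d,
                "donor" if srank == 0 else "acceptor", tid)
    if intron_hits:
        return ("deep_intronic", None, None, min(intron_hits))
    return ("intergenic", None, None, None)


def as_tuple(a):
    return (a.region, a.d, a.side, a.transcript_id)


@pytest.mark.parametrize("pos,expected", [
    (1109, ("intronic_flanking", 9, "donor", "tx1")),
    (1500, ("intronic_flanking", 1, "acceptor", "tx1")),
    (1301, ("intronic_flanking", 200, "acceptor", "tx1")),  # donor dist 201
    (1050, ("exonic", None, None, "tx1")),
    (1600, ("exonic", None, None, "tx1")),
    (5000, ("intergenic", None, None, None)),
])
def test_classify_plus_strand(two_exon_plus, pos, expected):
    assert as_tuple(classify_position("1", pos, two_exon_plus)) == expected


def test_classify_minus_strand_donor_is_genomically_right(two_exon_minus):
    # the exon at [1501,1600] is transcriptionally upstream on -strand
    a = classify_position("1", 1492, two_exon_minus)
    assert (a.region, a.d, a.side) == ("intronic_flanking", 9, "donor")
    b = classify_position("1", 1109, two_exon_minus)
    assert (b.region, b.d, b.side) == ("intronic_flanking", 9, "acceptor")


def test_midpoint_tie_resolves_to_donor():
    # odd-length intron [1101,1501]: pos 1301 is 201 from both boundaries
    ann = make_annotation(
        [("t", "g", "+", [("1", 1001, 1100), ("1", 1502, 1600)])], W=250
    )
    a = classify_position("1", 1301, ann)
    assert (a.d, a.side) == (201, "donor")


def test_exonic_precedence_across_transcripts():
    ann = make_annotation([
        ("a", "g1", "+", [("1", 1001, 1100), ("1", 1501, 1600)]),
        ("b", "g2", "+", [("1", 900, 1200)]),  # exon covers a's intron start
    ])
    assert classify_position("1", 1105, ann).region == "exonic"


def test_minimal_d_wins_across_transcripts_then_lexicographic():
    ann = make_annotation([
        ("z", "g1", "+", [("1", 1001, 1100), ("1", 1501, 1600)]),
        ("a", "g2", "+", [("1", 1001, 1110), ("1", 1501, 1600)]),
    ])
    hit = classify_position("1", 1111, ann)
    assert (hit.d, hit.transcript_id) == (1, "a")  # d=1 in a beats d=11 in z
    tie = classify_position("1", 1490, ann)        # acceptor d=11 in both
    assert (tie.d, tie.transcript_id) == (11, "a")


def test_unknown_chromosome_counts_intergenic(two_exon_plus):
    assert classify_position("99", 1000, two_exon_plus).region == "intergenic"


def test_deep_intronic_beyond_w():
    ann = make_annotation(
        [("t", "g", "+", [("1", 1000, 1100), ("1", 2000, 2100)])], W=200
    )
    # intron [1101,1999], length 899 > 2W=400: middle is deep
    assert classify_position("1", 1550, ann).region == "deep_intronic"


def test_classify_matches_oracle_on_random_instances(small_cohort):
    ann = small_cohort["ann"]
    rng = np.random.default_rng(11)
    chroms = sorted({t.chrom for t in ann.transcripts.values()})
    spans = {c: max(t.end for t in ann.transcripts.values() if t.chrom == c)
             for c in chroms}
    for _ in range(2000):
        c = chroms[rng.integers(len(chroms))]
        pos = int(rng.integers(1, spans[c] + 500))
        assert as_tuple(classify_position(c, pos, ann)) == \
            oracle_classify(c, pos, ann)


# ---------------------------------------------------------------------------
# aggregation


def _uniq(pos, any_pass=True, dp=50.0, chrom="1", **ann):
    r = VariantRecord("S", chrom, pos, "A", "G", "SNV",
                      qc=QCMetrics(dp=dp, dv=min(dp, 20.0)),
                      ann=AnnotationScores(**ann))
    return UniqueVariant(key=r.key, observations=[r], any_pass=any_pass)


def test_profile_hand_count(two_exon_plus):
    # three uniques in bucket 9, one failing QC
    uniques = [
        _uniq(1109),                        # donor d=9, pass
        _uniq(1501 - 9),                    # acceptor d=9, pass
        _uniq(1109, any_pass=False),        # same bucket, false
    ]
    prof = build_profile(uniques, two_exon_plus)
    row = prof.bucket(9)
    assert row["raw_count"] == 3 and row["pass_count"] == 2
    assert row["false_count"] == 1
    assert row["fp"] == pytest.approx(1 / 3)
    assert row["raw_donor"] == 2 and row["raw_acceptor"] == 1


def test_empty_bucket_fp_is_missing_not_zero(two_exon_plus):
    prof = build_profile([_uniq(1109)], two_exon_plus)
    assert np.isnan(prof.bucket(37)["fp"])
    assert prof.bucket(37)["raw_count"] == 0


def test_deleterious_spike_single_bucket(two_exon_plus):
    u = _uniq(1101 + 4, cadd=20.0)  # d=5 donor, deleterious
    prof = build_profile([u], two_exon_plus)
    dels = prof.per_bucket["deleterious_count"]
    assert dels.loc[5] == 1 and dels.drop(5).sum() == 0


def test_mean_depth_averages_unique_mean_dp(two_exon_plus):
    prof = build_profile([_uniq(1109, dp=10.0), _uniq(1492, dp=30.0)],
                         two_exon_plus)
    assert prof.bucket(9).mean_depth == 20.0


def test_w_zero_fatal(two_exon_plus):
    with pytest.raises(ValueError):
        build_profile([], two_exon_plus, W=0)


def test_gene_counts_partitions():
    ann = make_annotation([
        ("t1", "gA", "+", [("1", 1001, 1100), ("1", 1501, 1600)]),
        ("t2", "gB", "+", [("2", 1001, 1100), ("2", 1501, 1600)]),
        ("t3", "gC", "+", [("3", 1001, 1100), ("3", 1501, 1600)]),
    ])
    uniques = [
        _uniq(1109, chrom="1"), _uniq(1110, chrom="1"),   # gA, both pass
        _uniq(1109, chrom="2"),                           # gB pass
        _uniq(1109, chrom="3", any_pass=False),           # gC false only
    ]
    assert gene_counts(uniques, ann, "intronic_flanking", "raw") == 3
    assert gene_counts(uniques, ann, "intronic_flanking", "pass") == 2
    assert gene_counts([], ann, "intronic_flanking", "raw") == 0
    assert gene_counts([_uniq(1109, chrom="1"),
                        _uniq(1110, chrom="1")], ann,
                       "intronic_flanking", "raw") == 1


def test_partition_conservation_on_cohort(small_cohort):
    prof = build_profile(small_cohort["uniques"], small_cohort["ann"])
    t = prof.totals
    assert t["total"]["raw"] == sum(
        t[r]["raw"] for r in ("exonic", "intronic_flanking", "deep_intronic",
                              "intergenic"))
    assert t["intronic"]["raw"] == (t["intronic_flanking"]["raw"]
                                    + t["deep_intronic"]["raw"])
    pb = prof.per_bucket
    assert (pb["raw_count"] == pb["pass_count"] + pb["false_count"]).all()
    assert pb["raw_count"].sum() == t["intronic_flanking"]["raw"]
    assert (pb["deleterious_count"] <= pb["pass_count"]).all()
    fp = pb["fp"].dropna()
    assert ((fp >= 0) & (fp <= 1)).all()
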