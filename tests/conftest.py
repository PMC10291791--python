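"""Shared fixtures: toy gene models, a hand-labelled VCF covering every
filter criterion, and a small synthetic cohort."""

from __future__ import annotations

from pathlib import Path

import pytest

from intronflank.gene_model import GenomeAnnotation, _build_transcript


def make_annotation(transcript_specs, W=200) -> GenomeAnnotation:
    """transcript_specs: list of (tid, gene, strand, [(chrom,start,end),...])."""
    transcripts = {}
    for tid, gene, strand, exons in transcript_specs:
        transcripts[tid] = _build_transcript(
            tid, gene, [(c, s, e, strand) for c, s, e in exons]
        )
    return GenomeAnnotation(transcripts=transcripts, W=W)


@pytest.fixture
def two_exon_plus() -> GenomeAnnotation:
    """+strand transcript with exons [1001,1100], [1501,1600]."""
    return make_annotation(
        [("tx1", "gene1", "+", [("1", 1001, 1100), ("1", 1501, 1600)])]
    )


@pytest.fixture
def two_exon_minus() -> GenomeAnnotation:
    """-strand transcript with the same genomic exons."""
    return make_annotation(
        [("txm", "genem", "-", [("1", 1001, 1100), ("1", 1501, 1600)])]
    )


# ---------------------------------------------------------------------------
# hand-labelled VCF fixture: 50 records covering every hard-filter criterion
# of both branches and every deleterious criterion, with expected labels
# computed by hand.  Tuple layout:
#   (ref, alt, info_dict, expect_pass, expect_failed, expect_deleterious)
# expect_deleterious is the cascade verdict assuming the record passes QC
# (None for records built to fail QC).

NOMINAL = dict(QD=20.0, FS=10.0, MQ=60.0, MQRankSum=0.0,
               ReadPosRankSum=0.0, DP=100, AD=(50, 50))

def _r(ref="A", alt="G", over=None, drop=(), passed=True, failed=(),
       deleterious=False):
    info = dict(NOMINAL)
    info.update(over or {})
    for k in drop:
        info.pop(k, None)
    return (ref, alt, info, passed, set(failed), deleterious)


HAND_RECORDS = [
    # --- SNV branch: each criterion individually, plus boundary values ---
    _r(over={"QD": 1.5}, passed=False, failed={"QD"}),
    _r(over={"QD": 2.0}),                                    # boundary: not < 2
    _r(over={"FS": 61.0}, passed=False, failed={"FS"}),
    _r(over={"FS": 60.0}),                                   # not > 60
    _r(over={"MQ": 39.9}, passed=False, failed={"MQ"}),
    _r(over={"MQ": 40.0}),
    _r(over={"MQRankSum": -13.0}, passed=False, failed={"MQRankSum"}),
    _r(over={"MQRankSum": -12.5}),
    _r(over={"ReadPosRankSum": -8.5}, passed=False, failed={"ReadPosRankSum"}),
    _r(over={"ReadPosRankSum": -8.0}),
    _r(over={"DP": 19, "AD": (11, 8)}, passed=False, failed={"DP"}),
    _r(over={"DP": 20, "AD": (12, 8)}),
    _r(over={"AD": (93, 7)}, passed=False, failed={"DV"}),
    _r(over={"AD": (92, 8)}),
    _r(over={"QD": 1.0, "DP": 5, "AD": (3, 2)}, passed=False,
       failed={"QD", "DP", "DV"}),
    _r(),                                                    # all nominal
    # missing metrics never trigger a violation
    _r(drop=("MQRankSum", "ReadPosRankSum")),
    _r(drop=("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum")),
    # --- INDEL branch ---
    _r(alt="AT", over={"QD": 1.5}, passed=False, failed={"QD"}),
    _r(alt="AT", over={"FS": 100.0}),            # 100 passes the indel branch
    _r(over={"FS": 100.0}, passed=False, failed={"FS"}),  # ... but fails SNV
    _r(alt="AT", over={"FS": 201.0}, passed=False, failed={"FS"}),
    _r(alt="AT", over={"FS": 200.0}),
    _r(alt="AT", over={"ReadPosRankSum": -15.0}),  # passes indel (-20 cutoff)
    _r(over={"ReadPosRankSum": -15.0}, passed=False,
       failed={"ReadPosRankSum"}),                 # ... but fails SNV
    _r(alt="AT", over={"ReadPosRankSum": -20.5}, passed=False,
       failed={"ReadPosRankSum"}),
    _r(alt="AT", over={"DP": 19, "AD": (11, 8)}, passed=False, failed={"DP"}),
    _r(alt="AT", over={"AD": (93, 7)}, passed=False, failed={"DV"}),
    _r(alt="AT", over={"MQ": 10.0}),   # MQ is not an indel criterion
    _r(ref="ATT", alt="A"),            # deletion, nominal -> pass
    # --- deleterious cascade (all QC-nominal so any_pass holds) ---
    _r(over={"AF_POPMAX": 0.01, "CADD": 15.0, "DPSI_ZSCORE": 2.5,
             "DBSCSNV_ADA": 0.9}, deleterious=True),
    _r(over={"CLNSIG": "Benign", "CADD": 35.0, "DPSI_ZSCORE": 5.0,
             "DBSCSNV_ADA": 0.99}, deleterious=False),
    _r(over={"CLNSIG": "Likely_benign", "CADD": 35.0}, deleterious=False),
    _r(over={"CLNSIG": "Benign/Likely_benign", "CADD": 35.0},
       deleterious=False),
    _r(over={"CLNSIG": "Pathogenic", "CADD": 15.0}, deleterious=True),
    _r(over={"AF_POPMAX": 0.2, "CADD": 15.0, "DPSI_ZSCORE": 3.0},
       deleterious=False),
    _r(over={"AF_POPMAX": 0.05, "CADD": 15.0}, deleterious=False),  # not < .05
    _r(over={"AF_POPMAX": 0.049, "CADD": 15.0}, deleterious=True),
    _r(over={"CADD": 15.0}, deleterious=True),    # only CADD present, passes
    _r(over={"DPSI_ZSCORE": 2.0}, deleterious=True),   # >= 2 inclusive
    _r(over={"DPSI_ZSCORE": 1.9}, deleterious=False),
    _r(over={"CADD": 10.0}, deleterious=False),        # > 10 strict
    _r(over={"CADD": 10.1}, deleterious=True),
    _r(over={"DBSCSNV_ADA": 0.6}, deleterious=False),  # > 0.6 strict
    _r(over={"DBSCSNV_ADA": 0.61}, deleterious=True),
    _r(over={"DBSCSNV_ADA": 0.3, "DBSCSNV_RF": 0.7},
       deleterious=True),                          # max of the two ensembles
    _r(deleterious=False),                         # no scores present at all
    _r(over={"CADD": 15.0, "DPSI_ZSCORE": -1.0}, deleterious=False),
    _r(over={"CADD": 15.0, "DPSI_ZSCORE": 2.1, "DBSCSNV_ADA": 0.5},
       deleterious=False),                         # one present score fails
    _r(over={"CADD": 9.0}, deleterious=False),
]
assert len(HAND_RECORDS) == 50

_INFO_KEYS = ["QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum", "DP",
              "AF_POPMAX", "CLNSIG", "CADD", "DPSI_ZSCORE",
              "DBSCSNV_ADA", "DBSCSNV_RF"]


def write_hand_vcf(path: Path, sample: str = "T01") -> None:
    lines = ["##fileformat=VCFv4.2", "##contig=<ID=1,length=100000000>"]
    for k in _INFO_KEYS:
        typ = ("Integer" if k == "DP"
               else "String" if k == "CLNSIG" else "Float")
        lines.append(f'##INFO=<ID={k},Number=1,Type={typ},Description="x">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="x">')
    lines.append('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="x">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + sample)
    for i, (ref, alt, info, *_rest) in enumerate(HAND_RECORDS):
        pairs = [f"{k}={info[k]}" for k in _INFO_KEYS if k in info and k != "DP"]
        pairs.insert(0, f"DP={info['DP']}")
        ad = info.get("AD", (50, 50))
        lines.append(
            f"1\t{1000 + i * 10}\tr{i}\t{ref}\t{alt}\t100\t.\t"
            f"{';'.join(pairs)}\tGT:AD\t0/1:{ad[0]},{ad[1]}"
        )
    path.write_text("\n".join(lines) + "\n")


@pytest.fixture
def hand_vcf(tmp_path) -> Path:
    p = tmp_path / "hand.vcf"
    write_hand_vcf(p)
    return p


# ---------------------------------------------------------------------------
# small synthetic cohort shared by structural tests (session-scoped for speed)


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    from intronflank.synthetic_data import (SyntheticConfig,
                                            generate_annotation,
                                            generate_cohort)
    from intronflank.variant_io import dedup_unique, read_cohort

    outdir = tmp_path_factory.mktemp("small_cohort")
    cfg = SyntheticConfig(seed=7, n_samples=6, n_genes=60)
    ann = generate_annotation(cfg, gff3_path=outdir / "ann.gff3")
    res = generate_cohort(cfg, ann, outdir)
    records = read_cohort(res["vcfs"])
    uniques = dedup_unique(records)
    return {"cfg": cfg, "ann": ann, "outdir": outdir, "records": records,
            "uniques": uniques, **res}
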