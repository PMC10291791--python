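"""Synthetic exome cohorts with position-structured intronic variation.

The generator emulates the positional statistics a clinical exome cohort
shows around splice sites, so the whole pipeline can be exercised and scored
against a known truth with no external data:

- per-offset variant intensity with a minimum at +/-2 (the most conserved
  splice-dinucleotide position), a sharp maximum at +/-9, a gentle decay out
  to ~150 and a steeper fall beyond;
- sequencing depth that plateaus near the exon (capture probes tile exons)
  and decays logistically with distance, down to an off-target floor;
- QC failure generated *through* depth — each observation fails with a
  probability logistic in its drawn read depth — so the false-proportion
  curve is S-shaped in offset and inversely related to depth by
  construction, not by fiat;
- deleterious-annotation enrichment spiking at +/-5 (a known pathogenic
  hot-spot offset).

Everything is deterministic under the configured seed; cohorts are written
as one VCF 4.2 file per sample plus a GFF3 annotation and a per-offset
truth table (the acceptance surface for parameter recovery).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from .gene_model import GenomeAnnotation, TranscriptModel, _build_transcript, write_gff3

log = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


class ConfigError(ValueError):
    pass


@dataclass
class SyntheticConfig:
    """Cohort-generation parameters; defaults are the desk-scale study
    conditions (20 samples, 500 genes, W = 200)."""

    seed: int = 0
    n_samples: int = 20
    n_genes: int = 500
    exons_per_gene: tuple[int, int] = (3, 7)
    exon_len: tuple[int, int] = (80, 250)
    intron_len: tuple[int, int] = (450, 1500)   # >= 2W+1 so buckets never overlap
    W: int = 200
    n_chroms: int = 10

    # per-offset intensity: lam(d) = lam_scale * r(d) expected variants per
    # available base; r is the piecewise relative profile below
    lam_scale: float = 0.06
    r_d1: float = 0.55           # +/-1: elevated relative to +/-2
    r_d2: float = 0.10           # +/-2: global minimum within d <= 150
    r_rise_start: float = 0.35   # at d = 3
    r_rise_end: float = 0.70     # at d_peak - 1
    r_peak: float = 1.0          # at d_peak
    d_peak: int = 9
    r_post_peak: float = 0.74    # at d_peak + 1
    r_knee: float = 0.60         # at d_knee
    d_knee: int = 149
    r_end: float = 0.08          # at W; tail counts dip below the +/-2 count

    # depth model: mean DP = floor + (plateau - floor) * sigmoid((mid - d)/slope)
    depth_plateau: float = 120.0
    depth_floor: float = 8.0
    depth_mid: float = 50.0
    depth_slope: float = 45.0
    depth_dispersion: float = 5.0    # gamma-Poisson (negative binomial) size
    exon_depth: float = 130.0

    # QC-failure model: P(fail) = base + (1-base) * sigmoid((mid - DP)/slope)
    fail_base: float = 0.05
    fail_dp_mid: float = 22.0
    fail_dp_slope: float = 5.0

    # deleterious-annotation enrichment
    del_base_p: float = 0.04
    del_spike_d: int = 5
    del_spike_mult: float = 10.0

    # cohort structure
    carrier_q: float = 0.09     # per-sample carriage probability per variant
    indel_frac: float = 0.10
    exonic_rate: float = 0.04   # variants per exonic base
    deep_rate: float = 0.002    # variants per deep-intronic base
    alt_frac: float = 0.45      # mean variant-supporting read fraction

    def validate(self) -> None:
        errs = []
        if self.n_samples < 1:
            errs.append("n_samples must be >= 1")
        if self.n_genes < 1:
            errs.append("n_genes must be >= 1")
        for name in ("exons_per_gene", "exon_len", "intron_len"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                errs.append(f"{name} range invalid: {(lo, hi)}")
        if self.intron_len[0] < 3:
            errs.append("minimum intron length must be >= 3")
        if self.W < 1:
            errs.append("W must be >= 1")
        if not (self.r_d2 < self.r_d1 < self.r_peak):
            errs.append("intensity profile requires r_d2 < r_d1 < r_peak")
        if self.lam_scale <= 0:
            errs.append("lam_scale must be positive")
        if not (0 < self.depth_floor < self.depth_plateau):
            errs.append("depth model requires 0 < floor < plateau")
        for p in ("fail_base", "carrier_q", "indel_frac", "del_base_p",
                  "alt_frac"):
            if not (0 <= getattr(self, p) <= 1):
                errs.append(f"{p} must be in [0,1]")
        if errs:
            raise ConfigError("; ".join(errs))

    @property
    def del_spike_p(self) -> float:
        return min(0.95, self.del_base_p * self.del_spike_mult)


# ---------------------------------------------------------------------------
# designed curves (the truth the pipeline is scored against)


def rel_intensity(cfg: SyntheticConfig, d: np.ndarray) -> np.ndarray:
    """Relative per-base variant intensity r(d), piecewise in the offset."""
    d = np.asarray(d, dtype=float)
    dp = min(cfg.d_peak, cfg.W)
    dk = min(cfg.d_knee, cfg.W)
    r = np.empty_like(d)

    def seg(x, x0, x1, y0, y1):
        if x1 == x0:
            return np.full_like(x, y1)
        return y0 + (y1 - y0) * (x - x0) / (x1 - x0)

    r = np.where(d <= dk, seg(d, dp + 1, dk, cfg.r_post_peak, cfg.r_knee),
                 seg(d, dk + 1, cfg.W, cfg.r_knee * 0.97, cfg.r_end))
    rise = seg(d, 3, dp - 1, cfg.r_rise_start, cfg.r_rise_end)
    r = np.where(d <= dp - 1, rise, r)
    r = np.where(d == dp, cfg.r_peak, r)
    r = np.where(d == 2, cfg.r_d2, r)
    r = np.where(d == 1, cfg.r_d1, r)
    return np.clip(r, 0.01, None)


def depth_mean(cfg: SyntheticConfig, d: np.ndarray) -> np.ndarray:
    """Designed mean read depth at offset d (monotone non-increasing)."""
    d = np.asarray(d, dtype=float)
    return cfg.depth_floor + (cfg.depth_plateau - cfg.depth_floor) * expit(
        (cfg.depth_mid - d) / cfg.depth_slope
    )


def designed_fp(cfg: SyntheticConfig, d: np.ndarray) -> np.ndarray:
    """Designed per-observation QC-failure probability at the mean depth.

    The empirical unique-variant FP sits below this (a unique variant is
    false only when *every* carrier observation fails) but is a monotone
    transform of it, which is what the rank-based recovery checks use.
    """
    mu = depth_mean(cfg, d)
    return cfg.fail_base + (1 - cfg.fail_base) * expit(
        (cfg.fail_dp_mid - mu) / cfg.fail_dp_slope
    )


def designed_del_fraction(cfg: SyntheticConfig, d: np.ndarray) -> np.ndarray:
    d = np.asarray(d)
    return np.where(d == cfg.del_spike_d, cfg.del_spike_p, cfg.del_base_p)


def truth_table(cfg: SyntheticConfig,
                ann: Optional[GenomeAnnotation] = None) -> pd.DataFrame:
    """Per-offset design table: intensity, expected count, depth, FP,
    deleterious fraction."""
    cfg.validate()
    d = np.arange(1, cfg.W + 1)
    if ann is not None:
        n_introns = sum(len(t.introns) for t in ann.transcripts.values())
    else:
        lo, hi = cfg.exons_per_gene
        n_introns = int(cfg.n_genes * ((lo + hi) / 2 - 1))
    n_bases = 2 * n_introns  # one donor-side and one acceptor-side base per intron
    lam = cfg.lam_scale * rel_intensity(cfg, d)
    return pd.DataFrame({
        "position": d,
        "rel_intensity": rel_intensity(cfg, d),
        "lam": lam,
        "n_bases": n_bases,
        "expected_count": lam * n_bases,
        "depth_mean": depth_mean(cfg, d),
        "designed_fp": designed_fp(cfg, d),
        "designed_del_fraction": designed_del_fraction(cfg, d),
    }).set_index("position")


# ---------------------------------------------------------------------------
# annotation generation


def generate_annotation(
    cfg: SyntheticConfig, gff3_path: Optional[str | Path] = None
) -> GenomeAnnotation:
    """Deterministically generate gene structures; optionally write GFF3.

    Genes are laid out without overlap across ``n_chroms`` chromosomes on
    alternating random strands; the written GFF3 round-trips through
    :func:`intronflank.gene_model.load_annotation`.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 11]))
    cursors = {str(c + 1): 10_000 for c in range(cfg.n_chroms)}
    transcripts: dict[str, TranscriptModel] = {}
    for g in range(cfg.n_genes):
        chrom = str(1 + g % cfg.n_chroms)
        gene_id = f"G{g:04d}"
        tid = f"{gene_id}.t1"
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
        ex_lens = rng.integers(cfg.exon_len[0], cfg.exon_len[1] + 1, n_ex)
        in_lens = rng.integers(cfg.intron_len[0], cfg.intron_len[1] + 1,
                               max(n_ex - 1, 0))
        start = cursors[chrom] + int(rng.integers(2_000, 8_000))
        exons = []
        pos = start
        for i in range(n_ex):
            exons.append((chrom, pos, pos + int(ex_lens[i]) - 1, strand))
            pos = exons[-1][2] + 1
            if i < n_ex - 1:
                pos += int(in_lens[i])
        cursors[chrom] = exons[-1][2]
        transcripts[tid] = _build_transcript(tid, gene_id, exons)
    ann = GenomeAnnotation(transcripts=transcripts, W=cfg.W)
    if gff3_path is not None:
        Path(gff3_path).parent.mkdir(parents=True, exist_ok=True)
        write_gff3(ann, gff3_path)
    return ann


# ---------------------------------------------------------------------------
# cohort generation


def _intron_arrays(ann: GenomeAnnotation):
    rows = []
    for tid in sorted(ann.transcripts):
        t = ann.transcripts[tid]
        for s, e in t.introns:
            rows.append((t.chrom, s, e, 1 if t.strand == "+" else -1))
    if not rows:
        return (np.array([], dtype=object), np.array([], int),
                np.array([], int), np.array([], int))
    chrom, start, end, strand = zip(*rows)
    return (np.array(chrom, dtype=object), np.array(start, int),
            np.array(end, int), np.array(strand, int))


def _exon_arrays(ann: GenomeAnnotation):
    rows = []
    for tid in sorted(ann.transcripts):
        t = ann.transcripts[tid]
        for e in t.exons:
            rows.append((t.chrom, e.start, e.end))
    chrom, start, end = zip(*rows)
    return np.array(chrom, dtype=object), np.array(start, int), np.array(end, int)


@dataclass
class _Variants:
    """Flat per-variant truth arrays used internally by the generator."""

    chrom: np.ndarray
    pos: np.ndarray
    d: np.ndarray          # offset bucket; 0 for non-flanking
    region: np.ndarray     # 0 flanking, 1 exonic, 2 deep intronic
    ref: list
    alt: list
    is_del: np.ndarray
    mu_depth: np.ndarray


def _draw_sites(cfg: SyntheticConfig, ann: GenomeAnnotation,
                rng: np.random.Generator) -> _Variants:
    ichrom, istart, iend, istrand = _intron_arrays(ann)
    n_introns = len(istart)

    chroms, positions, ds, regions = [], [], [], []

    # flanking sites, bucket by bucket: two candidate bases per intron
    # (donor-side and acceptor-side), sampled without replacement so sites
    # are unique by construction
    for d in range(1, cfg.W + 1):
        lam = cfg.lam_scale * float(rel_intensity(cfg, np.array([d]))[0])
        n_slots = 2 * n_introns
        if n_slots == 0:
            break
        n = min(int(rng.poisson(lam * n_slots)), n_slots)
        if n == 0:
            continue
        slots = rng.choice(n_slots, size=n, replace=False)
        k = slots // 2
        donor_side = (slots % 2) == 0
        plus = istrand[k] == 1
        # donor offset counts from the transcriptional 5' end of the intron
        left = istart[k] + d - 1
        right = iend[k] - d + 1
        pos = np.where(donor_side == plus, left, right)
        chroms.append(ichrom[k])
        positions.append(pos)
        ds.append(np.full(n, d))
        regions.append(np.zeros(n, int))

    # exonic sites
    echrom, estart, eend = _exon_arrays(ann)
    elen = eend - estart + 1
    n_ex = int(rng.poisson(cfg.exonic_rate * elen.sum()))
    if n_ex:
        k = rng.choice(len(elen), size=n_ex, p=elen / elen.sum())
        pos = estart[k] + rng.integers(0, elen[k])
        chroms.append(echrom[k])
        positions.append(pos)
        ds.append(np.zeros(n_ex, int))
        regions.append(np.ones(n_ex, int))

    # deep-intronic sites (beyond W of both splice sites)
    deep_len = np.maximum(iend - istart + 1 - 2 * cfg.W, 0)
    if deep_len.sum() > 0:
        n_dp = int(rng.poisson(cfg.deep_rate * deep_len.sum()))
        if n_dp:
            k = rng.choice(len(deep_len), size=n_dp,
                           p=deep_len / deep_len.sum())
            pos = istart[k] + cfg.W + rng.integers(0, deep_len[k])
            chroms.append(ichrom[k])
            positions.append(pos)
            ds.append(np.zeros(n_dp, int))
            regions.append(np.full(n_dp, 2))

    chrom = np.concatenate(chroms) if chroms else np.array([], dtype=object)
    pos = np.concatenate(positions).astype(int) if chroms else np.array([], int)
    d_arr = np.concatenate(ds).astype(int) if chroms else np.array([], int)
    region = np.concatenate(regions).astype(int) if chroms else np.array([], int)

    # exonic/deep sampling is with replacement: drop duplicate sites
    key = np.char.add(np.char.add(chrom.astype(str), ":"), pos.astype(str))
    _, keep = np.unique(key, return_index=True)
    keep = np.sort(keep)
    chrom, pos, d_arr, region = chrom[keep], pos[keep], d_arr[keep], region[keep]
    n = len(pos)

    # alleles
    ref_i = rng.integers(0, 4, n)
    alt_i = (ref_i + rng.integers(1, 4, n)) % 4
    ins_i = rng.integers(0, 4, n)
    is_indel = rng.random(n) < cfg.indel_frac
    ref = list(_BASES[ref_i])
    alt = [
        (_BASES[ref_i[i]] + _BASES[ins_i[i]]) if is_indel[i] else _BASES[alt_i[i]]
        for i in range(n)
    ]

    # deleterious designation (flanking spike at del_spike_d)
    p_del = np.where(region == 0,
                     designed_del_fraction(cfg, d_arr), cfg.del_base_p * 0.5)
    is_del = rng.random(n) < p_del

    mu = np.where(region == 1, cfg.exon_depth,
                  np.where(region == 2, cfg.depth_floor,
                           depth_mean(cfg, d_arr)))
    return _Variants(chrom, pos, d_arr, region, ref, alt, is_del, mu)


def _draw_scores(cfg: SyntheticConfig, v: _Variants, rng: np.random.Generator):
    """Site-level annotation scores: deleterious-designated sites clear the
    cascade, all other sites are blocked by frequency, a benign label, or
    uniformly low scores."""
    n = len(v.pos)
    af = np.full(n, np.nan)
    cadd = np.full(n, np.nan)
    dpsi = np.full(n, np.nan)
    dbsc = np.full(n, np.nan)
    clinsig = np.array([None] * n, dtype=object)

    dmask = v.is_del
    nd = int(dmask.sum())
    if nd:
        present = rng.random((nd, 3)) < 0.8
        none = ~present.any(axis=1)
        present[none, 0] = True  # at least one in-silico score present
        cadd[dmask] = np.where(present[:, 0], rng.uniform(10.5, 40, nd), np.nan)
        dpsi[dmask] = np.where(present[:, 1], rng.uniform(2.0, 6.0, nd), np.nan)
        dbsc[dmask] = np.where(present[:, 2], rng.uniform(0.65, 0.99, nd), np.nan)
        af_known = rng.random(nd) < 0.5
        af[dmask] = np.where(af_known, rng.uniform(0.0, 0.045, nd), np.nan)
        cl = rng.random(nd) < 0.2
        cs = np.array([None] * nd, dtype=object)
        cs[cl] = "Uncertain_significance"
        clinsig[dmask] = cs

    nmask = ~dmask
    nn = int(nmask.sum())
    if nn:
        present = rng.random((nn, 3)) < 0.7
        cadd[nmask] = np.where(present[:, 0], rng.uniform(0.5, 9.5, nn), np.nan)
        dpsi[nmask] = np.where(present[:, 1], rng.uniform(-3.0, 1.8, nn), np.nan)
        dbsc[nmask] = np.where(present[:, 2], rng.uniform(0.0, 0.55, nn), np.nan)
        mode = rng.choice(3, size=nn, p=[0.25, 0.15, 0.60])
        af[nmask] = np.where(mode == 0, rng.uniform(0.06, 0.6, nn), np.nan)
        cs = np.array([None] * nn, dtype=object)
        benign = rng.random(nn) < 0.5
        cs[mode == 1] = "Benign"
        cs[(mode == 1) & benign] = "Likely_benign"
        clinsig[nmask] = cs
    return af, clinsig, cadd, dpsi, dbsc


def generate_cohort(
    cfg: SyntheticConfig, ann: GenomeAnnotation, outdir: str | Path
) -> dict:
    """Write one VCF per sample plus the per-offset truth table.

    Returns ``{"vcfs": [paths], "truth": path, "n_variants": int}``.
    Deterministic under ``cfg.seed``.
    """
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 23]))

    v = _draw_sites(cfg, ann, rng)
    af, clinsig, cadd, dpsi, dbsc = _draw_scores(cfg, v, rng)
    n = len(v.pos)

    # carriage: each sample carries each variant independently; every
    # variant gets at least one carrier (it was called in someone)
    carriers = rng.random((n, cfg.n_samples)) < cfg.carrier_q
    empty = ~carriers.any(axis=1)
    carriers[empty, rng.integers(0, cfg.n_samples, int(empty.sum()))] = True
    ovar, osmp = np.nonzero(carriers)
    m = len(ovar)

    # observation-level depth (gamma-Poisson) and QC metrics
    k = cfg.depth_dispersion
    lam = rng.gamma(k, v.mu_depth[ovar] / k)
    dp = rng.poisson(lam)
    dv = rng.binomial(dp, cfg.alt_frac)
    p_bad = cfg.fail_base + (1 - cfg.fail_base) * expit(
        (cfg.fail_dp_mid - dp) / cfg.fail_dp_slope
    )
    bad = rng.random(m) < p_bad
    qd = np.clip(rng.normal(18, 4, m), 2.5, 35)
    fs = np.clip(rng.exponential(5, m), 0.0, 50.0)
    mq = np.clip(rng.normal(59, 1.5, m), 41, 70)
    mqrs = np.clip(rng.normal(0, 1, m), -6, 6)
    rprs = np.clip(rng.normal(0, 1, m), -6, 6)
    mqrs_missing = rng.random(m) < 0.15
    rprs_missing = rng.random(m) < 0.15
    mode = rng.integers(0, 3, m)
    inj_qd = bad & (mode == 0)
    inj_fs = bad & (mode == 1)
    inj_rp = bad & (mode == 2)
    qd[inj_qd] = rng.uniform(0.1, 1.9, int(inj_qd.sum()))
    fs[inj_fs] = rng.uniform(210, 400, int(inj_fs.sum()))
    rprs[inj_rp] = rng.uniform(-30, -21, int(inj_rp.sum()))
    rprs_missing[inj_rp] = False

    sample_names = [f"S{i + 1:02d}" for i in range(cfg.n_samples)]
    contigs = sorted({str(c) for c in v.chrom}, key=_chrom_key)

    def info_str(oi: int) -> str:
        vi = ovar[oi]
        parts = [f"QD={qd[oi]:.4g}", f"FS={fs[oi]:.4g}", f"MQ={mq[oi]:.4g}"]
        if not mqrs_missing[oi]:
            parts.append(f"MQRankSum={mqrs[oi]:.4g}")
        if not rprs_missing[oi]:
            parts.append(f"ReadPosRankSum={rprs[oi]:.4g}")
        parts.append(f"DP={dp[oi]}")
        if not np.isnan(af[vi]):
            parts.append(f"AF_POPMAX={af[vi]:.5g}")
        if clinsig[vi] is not None:
            parts.append(f"CLNSIG={clinsig[vi]}")
        if not np.isnan(cadd[vi]):
            parts.append(f"CADD={cadd[vi]:.4g}")
        if not np.isnan(dpsi[vi]):
            parts.append(f"DPSI_ZSCORE={dpsi[vi]:.4g}")
        if not np.isnan(dbsc[vi]):
            parts.append(f"DBSCSNV_ADA={dbsc[vi]:.4g}")
            parts.append(f"DBSCSNV_RF={dbsc[vi]:.4g}")
        return ";".join(parts)

    vcf_paths = []
    for si, name in enumerate(sample_names):
        idx = np.nonzero(osmp == si)[0]
        order = sorted(
            idx,
            key=lambda oi: (_chrom_key(str(v.chrom[ovar[oi]])),
                            int(v.pos[ovar[oi]]), v.ref[ovar[oi]],
                            v.alt[ovar[oi]]),
        )
        path = outdir / f"{name}.vcf"
        with open(path, "w") as fh:
            fh.write(_vcf_header(contigs, name))
            for oi in order:
                vi = ovar[oi]
                rd = int(dp[oi] - dv[oi])
                fh.write(
                    f"{v.chrom[vi]}\t{v.pos[vi]}\t.\t{v.ref[vi]}\t{v.alt[vi]}"
                    f"\t100\t.\t{info_str(oi)}\tGT:AD:DP"
                    f"\t0/1:{rd},{int(dv[oi])}:{dp[oi]}\n"
                )
        vcf_paths.append(str(path))

    truth_path = outdir / "truth.tsv"
    truth_table(cfg, ann).to_csv(truth_path, sep="\t", float_format="%.6g")
    return {"vcfs": vcf_paths, "truth": str(truth_path), "n_variants": n}


def _chrom_key(c: str):
    return (0, int(c)) if c.isdigit() else (1, c)


def _vcf_header(contigs: list[str], sample: str) -> str:
    lines = ["##fileformat=VCFv4.2", "##source=intronflank-simulate"]
    for c in contigs:
        lines.append(f"##contig=<ID={c},length=500000000>")
    defs = [
        ("QD", "1", "Float", "Variant quality by depth"),
        ("FS", "1", "Float", "Fisher strand bias (phred)"),
        ("MQ", "1", "Float", "RMS mapping quality"),
        ("MQRankSum", "1", "Float", "Mapping quality rank-sum z"),
        ("ReadPosRankSum", "1", "Float", "Read position rank-sum z"),
        ("DP", "1", "Integer", "Read depth at site"),
        ("AF_POPMAX", "1", "Float", "Population max allele frequency"),
        ("CLNSIG", "1", "String", "Clinical significance"),
        ("CADD", "1", "Float", "CADD phred score"),
        ("DPSI_ZSCORE", "1", "Float", "SPIDEX dpsi z-score"),
        ("DBSCSNV_ADA", "1", "Float", "dbscSNV ada score"),
        ("DBSCSNV_RF", "1", "Float", "dbscSNV rf score"),
    ]
    for tag, num, typ, desc in defs:
        lines.append(
            f'##INFO=<ID={tag},Number={num},Type={typ},Description="{desc}">'
        )
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Allelic depths">')
    lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample
    )
    return "\n".join(lines) + "\n"
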