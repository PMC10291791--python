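# intronflank

Positional profiling of intronic variants flanking exons in whole-exome
sequencing (WES) callsets.

WES capture kits target exons, but reads spill into the surrounding introns,
so conventional exome callsets contain large numbers of intronic variants —
some of them clinically decisive splice-region variants, many of them
artifacts of thinning coverage. `intronflank` characterises that trade-off
positionally. For every called variant it computes the offset *d* from the
nearest splice site (+*d* into the intron from the donor site, −*d* from the
acceptor site, collapsed into the symmetric bucket *d* ∈ 1..*W*, default
*W* = 200 bp), and then builds per-position profiles over the cohort:

- **raw counts** — unique variants per offset (a variant seen in several
  samples is counted once);
- **pass counts** — variants surviving a GATK-style hard filter
  (SNV: `QD < 2.0 ∨ FS > 60.0 ∨ MQ < 40.0 ∨ MQRankSum < −12.5 ∨
  ReadPosRankSum < −8.0 ∨ DP < 20 ∨ DV < 8`;
  indel: `QD < 2.0 ∨ FS > 200.0 ∨ ReadPosRankSum < −20.0 ∨ DP < 20 ∨ DV < 8`);
- **FP** — the false proportion (failing / raw) per offset, alongside mean
  read depth, which decays with distance from the exon and drives the
  S-shaped FP curve;
- **deleterious counts** — pass variants that are rare
  (`AF_POPMAX < 0.05` or unknown), not labelled Benign/Likely_benign, and
  whose in-silico scores clear `CADD > 10`, `SPIDEX dpsi z ≥ 2`,
  `dbscSNV > 0.6` (evaluated over the scores present, since dbscSNV exists
  only near canonical splice sites).

Positional differences are tested with paired t-tests on per-sample counts,
Fisher's exact tests on pooled pass/false tables, Benjamini–Hochberg
adjustment, and a noncentral-*t* power computation for planning cohort
sizes. A synthetic cohort generator produces annotation + multi-sample VCFs
with a known truth table, so the entire pipeline is testable offline.

Intended users: bioinformaticians analysing clinical WES cohorts who want to
know how far from the exon a variant call can be trusted, and where the
splice-region deleterious burden concentrates.

## Worked example

Simulate a small cohort (4 samples, 60 genes), profile it, and test it:

```bash
intronflank simulate --out demo/sim --seed 1 --n-samples 4 --n-genes 60
intronflank profile --annotation demo/sim/annotation.gff3 \
    $(for f in demo/sim/S*.vcf; do echo --vcf $f; done) --out demo/prof
intronflank stats --profile-dir demo/prof --out demo/stats \
    --buckets 1,2,5,9,50,150
intronflank report --profile-dir demo/prof --out demo/figs
```

`profile` prints the partition totals (excerpt):

```
"total":             { "raw": 5493, "pass": 3984, "deleterious": 141, ... }
"exonic":            { "raw": 1906, "pass": 1797, ... }
"intronic_flanking": { "raw": 3354, "pass": 2181, "deleterious": 94, ... }
```

Every variant falls in exactly one partition and raw = pass + false
everywhere. `demo/prof/fp_profile.tsv` holds the per-offset table:

```
position  raw_count  pass_count  false_count  fp         mean_depth
1         19         18          1            0.0526316  83.8684
2         3          3           0            0          92.6667
9         29         28          1            0.0344828  100.345
149       16         1           15           0.9375     15.125
```

Near the exon (offsets 1–9) depth is high and almost everything passes; by
offset ~150 depth has fallen to ~15× and >90% of calls fail QC — the
S-shaped FP curve inverse to depth. `stats` writes pairwise p-value matrices
and the flanking-vs-exonic comparison:

```
"flanking_vs_exonic": { "t_p": 2.17e-4, "fisher_p": 7.32e-155,
                        "mean_fp_flanking": 0.352, "mean_fp_exonic": 0.057 }
```

i.e. the false proportion in the flanking introns (35.2%) far exceeds the
exonic one (5.7%), by the paired per-sample t-test and the pooled Fisher
reading alike.

For cohort planning, the power module reports that a two-tailed paired
t-test at a medium standardized effect (dz = 0.5) needs

```python
>>> from intronflank import power_sample_size
>>> power_sample_size("paired_t", effect_size=0.5, alpha=0.05, power=0.95)
54
```

samples for 95% power.

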