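# Methods

## Offset model

All coordinates are 1-based inclusive (VCF convention); BED12 input is
converted at parse time and `chr` prefixes are stripped for matching.
Introns are derived as the exact gaps between consecutive exons of a
transcript, so for every transcript the exons and introns tile its span
contiguously.

For a position inside an intron of length L on the + strand, the donor
offset is `pos − intron_start + 1` and the acceptor offset
`intron_end − pos + 1`; on the − strand the two are swapped (the donor site
of a −strand intron is its genomically right edge). A position is
*flanking* when its smaller offset d ≤ W (default W = 200). Donor +d and
acceptor −d collapse into the symmetric bucket d, matching how splice-region
positions are conventionally reported; the side is kept internally
(`raw_donor` / `raw_acceptor` columns) for by-side inspection.

Precedence rules, applied in order and deterministic by construction:

1. exonic in any transcript beats everything (the exonic/intronic partition
   must be disjoint, and an exonic variant cannot drive a splice-offset
   count);
2. among flanking candidates across transcripts, minimal d wins; at an
   exact donor/acceptor midpoint (odd-length introns) the donor side wins;
   remaining ties go to the lexicographically smallest transcript id;
3. otherwise deep-intronic if inside any intron, else intergenic.
   Chromosomes absent from the annotation are reported intergenic with one
   warning per chromosome.

Each base of a short intron (< 2W) is assigned to its nearer boundary only,
so buckets never double-count. Position assignment is per transcript with
minimal-d resolution rather than per collapsed gene model; with overlapping
transcripts a variant therefore takes the smallest defensible offset.

## Filters

The hard filter is a pure predicate over a record's QC metrics with separate
SNV and indel branches (thresholds in `HardFilterThresholds`, every value
overridable). A missing metric never triggers a violation by default: rank-sum
annotations are legitimately absent at homozygous-alt sites, and failing on
missingness would discard most real records (`missing_fails=True` gives the
conservative behaviour). `DV`, the variant-supporting depth, is taken from
`FORMAT/AD[alt]` when no dedicated tag exists. INFO floats are stored as
float32 by htslib; parsed values are rounded to 6 decimals so comparisons at
printed thresholds (e.g. `dbscSNV > 0.6`) behave as written.

Deduplication keys on (chrom, pos, ref, alt): a variant observed in many
samples counts once. Its pass status aggregates per-observation verdicts
under a configurable policy — `any` (default; pass in ≥ 1 sample),
`majority`, or `all`. Indels are keyed and positioned by their VCF anchor
base. Multi-allelic sites are split per alt allele before extraction, with
`Number=A` tags matched by allele index.

The deleterious cascade runs per unique variant on its collapsed
annotation (most deleterious score across observations, first non-missing
frequency/label): rare (`af_popmax < 0.05`, with unknown frequency treated
as rare, since novel variants have no database entry), not
Benign/Likely_benign (case-insensitive token match over comma/slash/pipe
joined labels), and in-silico scores clearing `CADD > 10`,
`dpsi z ≥ 2` (signed as printed; `signed_dpsi=False` compares |z|),
`dbscSNV > 0.6`. The conjunction is evaluated over the scores *present*,
requiring at least one: dbscSNV is defined only near canonical splice
sites, so a strict three-way AND would make deleterious calls beyond the
first few bases impossible; the strict policy remains available as a
config switch. Deleteriousness is only ever evaluated on pass variants, so
the deleterious set is a subset of the pass set on any input.

## Statistics

- Per-sample count comparisons between offset buckets: two-sided paired
  t-test on the n_samples × W count matrix (Welch unpaired optional).
- Per-offset FP comparisons: two-sided Fisher's exact test on the pooled
  2×2 [[pass_i, false_i], [pass_j, false_j]] table, two-sidedness by
  summing the probabilities of tables no more likely than observed.
- Flanking-vs-exonic FP: paired t-test on per-sample false proportions,
  with the pooled-count Fisher reading reported alongside, since either
  reading of "difference in FP" is defensible.
- Zero-variance differences and empty cells yield a missing p (NaN), never
  a silent 0 or 1.
- Benjamini–Hochberg step-up over the upper triangle is reported next to
  raw p-values: the pairwise design performs thousands of tests, and raw
  0.05/0.01 masks alone would be anticonservative.
- Power: paired-t power is computed from the noncentral t distribution with
  noncentrality dz·√n and n−1 df; `power_sample_size` binary-searches the
  smallest n reaching the target (dz = 0.5, α = 0.05, power = 0.95,
  two-tailed → n = 54; power = 0.80 → n = 34).

## Synthetic cohort generator

The generator emulates the positional structure of a clinical WES cohort;
its defaults are the desk-scale study conditions (20 samples, 500 genes of
3–7 exons, introns 450–1500 bp so buckets never overlap, W = 200).

- **Intensity.** Expected unique variants per available base,
  λ(d) = `lam_scale` · r(d), with r piecewise: elevated at ±1 (0.55),
  global minimum within 150 at ±2 (0.10; the splice dinucleotide is the
  most conserved position), linear rise to a sharp peak of 1.0 at ±9,
  gentle decay to 0.60 at ±149, then a steeper fall to 0.08 at ±200 so the
  last offsets dip below the ±2 count. Each intron contributes exactly two
  bases per bucket (donor- and acceptor-side), sampled without replacement
  so sites are unique by construction.
- **Depth.** Mean DP = floor + (plateau − floor)·σ((mid − d)/slope) with
  plateau 120×, floor 8×, midpoint 50 bp, slope 45 bp — capture probes tile
  exons, so depth plateaus near the splice site and decays into the
  intron. Per-observation DP is gamma-Poisson (negative binomial,
  dispersion 5) around the positional mean; exonic sites sit at 130×.
- **QC failure through depth, not position.** Each observation fails with
  probability base + (1 − base)·σ((22 − DP)/5) (base 0.05), implemented by
  corrupting one metric (low QD, extreme FS, or extreme ReadPosRankSum —
  each failing both filter branches); very low DP additionally fails the
  DP/DV criteria naturally. The S-shaped FP-vs-offset curve and its inverse
  relation to depth are therefore emergent consequences of coverage decay —
  encoding the causal reading that false intronic calls in WES stem mainly
  from low coverage — not hand-painted per position.
- **Deleterious enrichment.** Each flanking site is designated deleterious
  with probability 0.04, ×10 at ±5 (a known pathogenic hot-spot offset);
  designated sites draw passing scores (with realistic missingness, ≥ 1
  in-silico score present), other sites are blocked by a common frequency,
  a benign label, or uniformly sub-threshold scores.
- **Cohort structure.** Each sample carries each variant independently with
  probability 0.09 (≈ 1.8 carriers/variant at n = 20), conditioned on ≥ 1
  carrier. One plain VCF 4.2 per sample is written with every default
  field-map tag declared; `truth.tsv` records the designed λ(d), depth,
  per-observation failure probability and deleterious fraction per offset.

Everything is drawn from `numpy.random.default_rng` seeded from the single
config seed (separate fixed streams for annotation and cohort), so outputs
are byte-identical across runs.

What the generator does **not** emulate: linkage and site-frequency
structure, per-gene variant-rate heterogeneity, sequence-context error
modes, multi-allelic sites, real gene names or score databases, the small
empirical FP bump at ±1/±2 (our FP is purely depth-mediated and hence
monotone in offset), and BAM-level depth (profile depth is the DP of the
variant records themselves, since the pipeline consumes VCFs only). Passing
recovery tests on synthetic cohorts therefore demonstrates correctness of
the positional accounting and filter plumbing under known structure, not
fidelity to any particular real cohort.

## Numerical and design notes

- Empirical unique-variant FP lies below the designed per-observation
  failure probability (a unique variant is false only when every carrier
  observation fails); it is a monotone transform of it, so the recovery
  checks compare ranks (Spearman), not magnitudes.
- FP and mean depth are reported missing (NA), never 0, for empty buckets.
- Recovery testing runs the full pipeline on 20 independently seeded
  default-scale cohorts (≈ 45–50k unique variants each, ≈ 2 minutes total)
  and asserts each structural property in ≥ 95% of seeds: pass-count argmax
  at 9, pass-count argmin within 150 at 2, FP-vs-design Spearman ρ ≥ 0.9,
  depth-vs-FP Spearman ρ ≤ −0.8, deleterious argmax at 5.
- The classifier is verified against an independently written brute-force
  boundary scanner on > 10⁴ random positions (mixed strands, short introns,
  off-annotation positions); Fisher p-values against exhaustive
  hypergeometric enumeration on all 2×2 tables with total ≤ 30.
- Open choices resolved here (and configurable where stated): any-pass
  aggregation across samples; per-unique-variant deleterious evaluation;
  signed dpsi comparison; present-scores conjunction; donor on midpoint
  ties; minimal-d across transcripts; exonic precedence. Each is the
  behaviour a disjoint-partition, reproducibility-first design forces or
  the least-surprising convention where several were defensible.

## Known limitations

- Depth is VCF-derived; positions with no called variants contribute no
  depth estimate (no BAM re-pileup).
- The t-test treats per-sample counts as approximately normal; at very low
  counts per bucket a paired nonparametric test would be preferable.
- The pairwise t/Fisher split (t for counts, Fisher for proportions) is one
  reasonable mapping of "test positional differences"; both matrices are
  emitted so either reading can be inspected.
- Annotation parsing is geometry-only (no UTR/CDS distinction, no
  canonical-transcript selection); the pipeline is annotation-agnostic.
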