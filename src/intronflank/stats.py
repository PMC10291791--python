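"""Positional hypothesis tests, multiple-testing adjustment, and power.

Count comparisons between offset buckets use a paired t-test on per-sample
counts (Welch's unpaired variant available); false-proportion comparisons
between buckets use Fisher's exact test on the pooled 2x2 pass/false table.
The flanking-vs-exonic false-proportion comparison reports both routes.

Raw p-values are reported at the conventional 0.05 / 0.01 thresholds;
Benjamini-Hochberg adjusted values are reported alongside because the
pairwise design performs thousands of tests.

Zero-variance and empty-cell cases yield a missing p (NaN), never a silent
0 or 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .gene_model import GenomeAnnotation
from .position_profile import PositionProfile, classify_position
from .variant_io import VariantRecord

log = logging.getLogger(__name__)


@dataclass
class PairwiseTestMatrix:
    """Symmetric W x W p-value matrix (diagonal NaN) plus BH adjustment."""

    test_name: str
    p: pd.DataFrame
    p_adj: pd.DataFrame


# ---------------------------------------------------------------------------
# per-sample count matrix


def build_sample_counts(
    records: Iterable[VariantRecord],
    ann: GenomeAnnotation,
    pass_only: bool = False,
    thresholds=None,
    missing_fails: bool = False,
) -> pd.DataFrame:
    """Per-sample, per-bucket variant counts (n_samples x W).

    Counts records (not deduplicated variants): each sample's own calls at
    each flanking offset, the quantity the paired t-test compares.
    """
    from .qc_filters import hard_filter

    W = ann.W
    counts: dict[str, np.ndarray] = {}
    for r in records:
        if pass_only and not hard_filter(
            r, thresholds=thresholds, missing_fails=missing_fails
        ).passed:
            continue
        a = classify_position(r.chrom, r.pos, ann)
        if a.region != "intronic_flanking":
            continue
        row = counts.setdefault(r.sample_id, np.zeros(W, dtype=int))
        row[a.d - 1] += 1
    df = pd.DataFrame.from_dict(counts, orient="index",
                                columns=pd.RangeIndex(1, W + 1, name="position"))
    return df.sort_index()


def per_sample_fp(
    records: Iterable[VariantRecord],
    ann: GenomeAnnotation,
    thresholds=None,
    missing_fails: bool = False,
) -> pd.DataFrame:
    """Per-sample false proportions in the flanking and exonic partitions.

    Returns a DataFrame indexed by sample with columns
    (fp_flanking, fp_exonic, raw/false counts for both partitions).
    """
    from .qc_filters import hard_filter

    acc: dict[str, np.ndarray] = {}  # [raw_fl, false_fl, raw_ex, false_ex]
    for r in records:
        region = classify_position(r.chrom, r.pos, ann).region
        if region not in ("intronic_flanking", "exonic"):
            continue
        row = acc.setdefault(r.sample_id, np.zeros(4, dtype=int))
        failed = not hard_filter(
            r, thresholds=thresholds, missing_fails=missing_fails
        ).passed
        if region == "intronic_flanking":
            row[0] += 1
            row[1] += failed
        else:
            row[2] += 1
            row[3] += failed
    df = pd.DataFrame.from_dict(
        acc, orient="index",
        columns=["raw_flanking", "false_flanking", "raw_exonic", "false_exonic"],
    ).sort_index()
    with np.errstate(invalid="ignore"):
        df["fp_flanking"] = df["false_flanking"] / df["raw_flanking"]
        df["fp_exonic"] = df["false_exonic"] / df["raw_exonic"]
    return df


# ---------------------------------------------------------------------------
# tests


def pairwise_count_ttest(
    m: pd.DataFrame, i: int, j: int, paired: bool = True
) -> float:
    """Two-sided t-test p on per-sample counts at buckets i vs j.

    Paired across samples by default; Welch unpaired otherwise.  Returns
    NaN (with a warning) when the differences have zero variance.
    """
    if i == j:
        raise ValueError("i and j must differ")
    if len(m) < 2:
        raise ValueError("need >= 2 samples for a t-test")
    x = m[i].to_numpy(dtype=float)
    y = m[j].to_numpy(dtype=float)
    if paired:
        diff = x - y
        if np.allclose(diff.std(ddof=1), 0.0):
            log.warning("zero variance of differences for buckets %d vs %d", i, j)
            return float("nan")
        return float(sps.ttest_rel(x, y).pvalue)
    if np.allclose(x.std(ddof=1), 0.0) and np.allclose(y.std(ddof=1), 0.0):
        log.warning("zero variance in both groups for buckets %d vs %d", i, j)
        return float("nan")
    return float(sps.ttest_ind(x, y, equal_var=False).pvalue)


def pairwise_fp_fisher(profile: PositionProfile, i: int, j: int) -> float:
    """Two-sided Fisher's exact p on [[pass_i, false_i], [pass_j, false_j]].

    Two-sidedness sums the probabilities of all tables no more likely than
    the observed one.  Missing (NaN) when either bucket has no raw variants.
    """
    bi, bj = profile.bucket(i), profile.bucket(j)
    if bi["raw_count"] == 0 or bj["raw_count"] == 0:
        return float("nan")
    table = [
        [int(bi["pass_count"]), int(bi["false_count"])],
        [int(bj["pass_count"]), int(bj["false_count"])],
    ]
    return float(sps.fisher_exact(table, alternative="two-sided")[1])


@dataclass(frozen=True)
class FlankingExonicResult:
    t_p: float
    fisher_p: Optional[float]
    mean_fp_flanking: float
    mean_fp_exonic: float


def flanking_vs_exonic_fp_test(
    per_sample_fp_flanking: np.ndarray,
    per_sample_fp_exonic: np.ndarray,
    pooled_table: Optional[list[list[int]]] = None,
) -> FlankingExonicResult:
    """Paired t-test on per-sample false proportions, flanking vs exonic.

    ``pooled_table`` — optional [[pass_fl, false_fl], [pass_ex, false_ex]]
    cohort-pooled counts — adds the Fisher's-exact reading of the same
    comparison.
    """
    x = np.asarray(per_sample_fp_flanking, dtype=float)
    y = np.asarray(per_sample_fp_exonic, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("FP vectors must be 1-D and equal length")
    if len(x) < 2:
        raise ValueError("need >= 2 samples")
    diff = x - y
    if np.allclose(diff.std(ddof=1), 0.0):
        log.warning("zero variance of FP differences; t-test p is missing")
        t_p = float("nan")
    else:
        t_p = float(sps.ttest_rel(x, y).pvalue)
    fisher_p = None
    if pooled_table is not None:
        fisher_p = float(sps.fisher_exact(pooled_table, "two-sided")[1])
    return FlankingExonicResult(
        t_p=t_p, fisher_p=fisher_p,
        mean_fp_flanking=float(np.nanmean(x)),
        mean_fp_exonic=float(np.nanmean(y)),
    )


# ---------------------------------------------------------------------------
# multiple testing


def bh_adjust_vector(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up; NaNs pass through untouched."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[mask] = res
    return out


def bh_adjust(p: pd.DataFrame) -> pd.DataFrame:
    """BH over the upper triangle of a symmetric p-value matrix."""
    arr = p.to_numpy(dtype=float)
    n = arr.shape[0]
    iu = np.triu_indices(n, k=1)
    adj_flat = bh_adjust_vector(arr[iu])
    out = np.full_like(arr, np.nan)
    out[iu] = adj_flat
    out[(iu[1], iu[0])] = adj_flat
    return pd.DataFrame(out, index=p.index, columns=p.columns)


def pairwise_matrix(
    profile_or_counts,
    test: str,
    buckets: Optional[Iterable[int]] = None,
    paired: bool = True,
) -> PairwiseTestMatrix:
    """All-pairs p-value matrix over offset buckets.

    ``test`` is ``t_test`` (per-sample count matrix input) or
    ``fisher_exact`` (PositionProfile input).
    """
    if test == "t_test":
        m: pd.DataFrame = profile_or_counts
        idx = list(buckets) if buckets is not None else list(m.columns)
        getp = lambda i, j: pairwise_count_ttest(m, i, j, paired=paired)
    elif test == "fisher_exact":
        prof: PositionProfile = profile_or_counts
        idx = list(buckets) if buckets is not None else list(range(1, prof.W + 1))
        getp = lambda i, j: pairwise_fp_fisher(prof, i, j)
    else:
        raise ValueError(f"unknown test {test!r}")
    n = len(idx)
    arr = np.full((n, n), np.nan)
    for a in range(n):
        for b in range(a + 1, n):
            arr[a, b] = arr[b, a] = getp(idx[a], idx[b])
    p = pd.DataFrame(arr, index=idx, columns=idx)
    return PairwiseTestMatrix(test_name=test, p=p, p_adj=bh_adjust(p))


def matrix_to_long(mat: PairwiseTestMatrix) -> pd.DataFrame:
    """Long-format (i, j, test, p, p_adj) over the upper triangle."""
    idx = list(mat.p.index)
    rows = []
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            rows.append((idx[a], idx[b], mat.test_name,
                         mat.p.iat[a, b], mat.p_adj.iat[a, b]))
    return pd.DataFrame(rows, columns=["i", "j", "test", "p", "p_adj"])


# ---------------------------------------------------------------------------
# power / sample size


def paired_t_power(n: int, effect_size: float, alpha: float = 0.05,
                   tails: int = 2) -> float:
    """Power of the paired t-test at n pairs via the noncentral t.

    Noncentrality is dz * sqrt(n) on n - 1 degrees of freedom.
    """
    if n < 2:
        return 0.0
    df = n - 1
    delta = effect_size * np.sqrt(n)
    if tails == 2:
        tcrit = sps.t.ppf(1 - alpha / 2, df)
        return float(1 - sps.nct.cdf(tcrit, df, delta)
                     + sps.nct.cdf(-tcrit, df, delta))
    tcrit = sps.t.ppf(1 - alpha, df)
    return float(1 - sps.nct.cdf(tcrit, df, delta))


def power_sample_size(
    test: str = "paired_t",
    effect_size: float = 0.5,
    alpha: float = 0.05,
    power: float = 0.95,
    tails: int = 2,
    max_n: int = 1_000_000,
) -> int:
    """Smallest n whose paired t-test power reaches the target.

    With the conventional medium standardized effect dz = 0.5 at alpha 0.05
    and target power 0.95 (two-tailed) this returns 54 samples.
    """
    if test != "paired_t":
        raise ValueError(f"unsupported test {test!r}")
    if not (0 < alpha < 1) or not (0 < power < 1) or effect_size <= 0:
        raise ValueError("require 0<alpha<1, 0<power<1, effect_size>0")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    lo, hi = 2, 2
    while paired_t_power(hi, effect_size, alpha, tails) < power:
        if hi >= max_n:
            raise ValueError(f"power {power} unattainable within n <= {max_n}")
        lo, hi = hi, min(hi * 2, max_n)
    # power is monotone non-decreasing in n over the search range
    while lo < hi:
        mid = (lo + hi) // 2
        if paired_t_power(mid, effect_size, alpha, tails) >= power:
            hi = mid
        else:
            lo = mid + 1
    return hi
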