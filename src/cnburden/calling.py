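"""Read-depth copy-number calling over fixed 500-kb bins.

Pipeline per sample: median-relative log2 normalization of bin counts,
penalized least-squares changepoint segmentation per chromosome, fixed
log2-ratio thresholds for loss/neutral/gain calls with merging of adjacent
same-call segments, and a mean-segment-SD quality score.

The segmenter minimizes total within-segment sum of squares plus a penalty
per additional segment by exact dynamic programming (optimal partitioning),
so for the breakpoint cardinality it returns, no other breakpoint placement
of the same cardinality achieves a lower residual sum of squares.  The
default penalty is ``2 * log(n_usable_bins) * sigma^2`` with ``sigma``
estimated robustly from the median absolute difference of adjacent bins.
No GC or mappability correction is applied: counts are assumed unbiased or
pre-corrected upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeBins

LOSS_CUT_DEFAULT = -0.15
GAIN_CUT_DEFAULT = 0.15

SEGMENT_COLUMNS = ["chrom", "start", "end", "first_bin", "last_bin", "n_bins",
                   "mean_log2", "call"]


@dataclass
class BinProfile:
    """Per-bin normalized copy-ratio profile of one sample."""

    sample_id: str
    counts: np.ndarray      # raw read counts (float; NaN where missing)
    log2: np.ndarray        # log2(count / sample median); NaN where unusable
    usable: np.ndarray      # bool: autosomal, present in input
    bins: GenomeBins


@dataclass
class SegmentProfile:
    """Called segments of one sample.

    ``segments`` columns: chrom, start, end (bp, half-open), first_bin,
    last_bin (inclusive global bin indices), n_bins, mean_log2, call in
    {-1, 0, +1}.  Segments are contiguous within each chromosome and jointly
    cover every usable autosomal bin.  ``center`` is the estimated log2
    level of copy-neutral DNA that the calling thresholds were applied
    around (see :func:`call_segments`).
    """

    sample_id: str
    segments: pd.DataFrame
    qc_mean_segment_sd: float = field(default=np.nan)
    center: float = 0.0


def normalize_bins(counts: np.ndarray, bins: GenomeBins, sample_id: str = "sample",
                   pseudocount: float = 0.5, min_usable: int = 100) -> BinProfile:
    """Median-relative log2 ratios over usable autosomal bins.

    Zero-count bins are floored at ``pseudocount`` before the log.  Bins with
    missing counts (NaN) and non-autosomal bins are masked out of all
    downstream statistics.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (bins.n_bins,):
        raise ValueError(f"expected {bins.n_bins} counts, got {counts.shape}")
    usable = bins.autosomal & ~np.isnan(counts)
    if np.count_nonzero(usable) < min_usable:
        raise ValueError(f"sample {sample_id}: only {np.count_nonzero(usable)} usable "
                         f"autosomal bins (< {min_usable})")
    median = float(np.median(counts[usable]))
    if median <= 0:
        raise ValueError(f"sample {sample_id}: non-positive median read count")
    log2 = np.full(bins.n_bins, np.nan)
    log2[usable] = np.log2(np.maximum(counts[usable], pseudocount) / median)
    return BinProfile(sample_id=sample_id, counts=counts, log2=log2,
                      usable=usable, bins=bins)


def _optimal_partition(x: np.ndarray, penalty: float) -> list[int]:
    """Exact penalized changepoint placement on one chromosome.

    Returns breakpoint positions ``b`` (split between x[b-1] and x[b]) that
    minimize sum of within-segment RSS + penalty per additional segment.
    A split is therefore accepted only where it reduces RSS by more than the
    penalty.  Ties resolve toward fewer/longer segments.
    """
    n = len(x)
    if n < 2:
        return []
    cs = np.concatenate(([0.0], np.cumsum(x)))
    ss = np.concatenate(([0.0], np.cumsum(x * x)))
    F = np.empty(n + 1)
    F[0] = -penalty
    prev = np.zeros(n + 1, dtype=np.int64)
    for t in range(1, n + 1):
        s = np.arange(t)
        seglen = t - s
        cost = (ss[t] - ss[s]) - (cs[t] - cs[s]) ** 2 / seglen
        total = F[:t] + cost + penalty
        i = int(np.argmin(total))   # ties -> smallest s -> longer last segment
        F[t] = total[i]
        prev[t] = i
    breaks = []
    t = n
    while t > 0:
        if prev[t] > 0:
            breaks.append(int(prev[t]))
        t = prev[t]
    return sorted(breaks)


def robust_noise_variance(profile: BinProfile) -> float:
    """Bin-level noise variance from the median absolute difference of
    adjacent usable bins (Gaussian-consistent scaling), pooled genome-wide."""
    diffs = []
    for chrom in profile.bins.chroms:
        sl = profile.bins.chrom_slice(chrom)
        x = profile.log2[sl][profile.usable[sl]]
        if len(x) >= 2:
            diffs.append(np.abs(np.diff(x)))
    if not diffs:
        return 0.0
    mad = float(np.median(np.concatenate(diffs)))
    sigma = mad / (0.6744897501960817 * np.sqrt(2.0))
    return sigma ** 2


def default_penalty(profile: BinProfile, n: int | None = None) -> float:
    """BIC-type penalty 2 * log(n) * robust noise variance.

    ``n`` defaults to the genome-wide usable bin count; pass the
    chromosome's bin count for the per-chromosome penalty used by
    :func:`segment_bins` (chromosomes are segmented independently, so the
    candidate-breakpoint multiplicity the penalty guards against is the
    chromosome's, not the genome's).
    """
    if n is None:
        n = int(np.count_nonzero(profile.usable))
    return max(2.0 * np.log(max(n, 2)) * robust_noise_variance(profile), 1e-10)


def segment_bins(profile: BinProfile, penalty: float | None = None) -> pd.DataFrame:
    """Segment each chromosome independently; returns the raw segment table.

    Masked bins are skipped: a segment covers a run of consecutive *usable*
    bins and its genomic extent runs from the start of its first usable bin
    to the end of its last.  Chromosomes with < 2 usable bins yield a single
    segment.  With ``penalty=None`` each chromosome uses the per-chromosome
    default penalty; an explicit float applies to every chromosome.
    """
    sigma2 = robust_noise_variance(profile) if penalty is None else None
    bdf = profile.bins.df
    rows = []
    for chrom in profile.bins.chroms:
        sl = profile.bins.chrom_slice(chrom)
        idx = np.flatnonzero(profile.usable[sl]) + sl.start
        if idx.size == 0:
            continue
        x = profile.log2[idx]
        beta = penalty if penalty is not None else \
            max(2.0 * np.log(max(idx.size, 2)) * sigma2, 1e-10)
        breaks = _optimal_partition(x, beta) if idx.size >= 2 else []
        edges = [0, *breaks, idx.size]
        for lo, hi in zip(edges[:-1], edges[1:]):
            seg_bins = idx[lo:hi]
            rows.append({
                "chrom": chrom,
                "start": int(bdf["start"].iloc[seg_bins[0]]),
                "end": int(bdf["end"].iloc[seg_bins[-1]]),
                "first_bin": int(seg_bins[0]), "last_bin": int(seg_bins[-1]),
                "n_bins": int(hi - lo),
                "mean_log2": float(np.mean(x[lo:hi])),
                "call": 0,
            })
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    return float(v[np.searchsorted(cum, 0.5 * cum[-1])])


def call_segments(segments: pd.DataFrame, loss_cut: float = LOSS_CUT_DEFAULT,
                  gain_cut: float = GAIN_CUT_DEFAULT, center: float | None = None,
                  sample_id: str = "sample") -> SegmentProfile:
    """Threshold segment means into calls and merge same-call neighbours.

    Thresholds are applied to ``mean_log2 - center``, where ``center``
    (default: the bin-count-weighted median of segment means) estimates the
    log2 level of copy-neutral DNA.  The log of overdispersed counts is
    left-skewed, so after median normalization neutral segments have a mean
    log2 slightly below zero; re-centering on the neutral mode removes that
    bias from the calls, as mixture-model callers do implicitly.  Pass
    ``center=0.0`` to threshold raw means.

    Boundary convention: a centered mean exactly at a cut is called altered
    (``<= loss_cut`` -> -1, ``>= gain_cut`` -> +1).  Adjacent same-call
    segments within a chromosome are merged, with the merged mean recomputed
    as the bin-count-weighted mean.
    """
    if not (loss_cut < 0 < gain_cut):
        raise ValueError("need loss_cut < 0 < gain_cut")
    seg = segments.copy()
    if center is None:
        center = _weighted_median(seg["mean_log2"].to_numpy(float),
                                  seg["n_bins"].to_numpy(float))
    centered = seg["mean_log2"] - center
    seg["call"] = np.select([centered <= loss_cut, centered >= gain_cut],
                            [-1, 1], default=0)
    merged_rows = []
    for chrom, sub in seg.groupby("chrom", sort=False):
        sub = sub.sort_values("first_bin")
        current = None
        for row in sub.to_dict("records"):
            if current is not None and row["call"] == current["call"]:
                tot = current["n_bins"] + row["n_bins"]
                current["mean_log2"] = (current["mean_log2"] * current["n_bins"]
                                        + row["mean_log2"] * row["n_bins"]) / tot
                current["n_bins"] = tot
                current["end"] = row["end"]
                current["last_bin"] = row["last_bin"]
            else:
                if current is not None:
                    merged_rows.append(current)
                current = dict(row)
        if current is not None:
            merged_rows.append(current)
    return SegmentProfile(sample_id=sample_id,
                          segments=pd.DataFrame(merged_rows, columns=SEGMENT_COLUMNS),
                          center=float(center))


def qc_profile(profile: BinProfile, segments: pd.DataFrame) -> float:
    """Mean segment SD: per-segment sample SD of bin residuals, averaged
    with equal weight per segment.  Single-bin segments contribute 0."""
    sds = []
    for row in segments.itertuples():
        x = profile.log2[row.first_bin:row.last_bin + 1]
        x = x[~np.isnan(x)]
        sds.append(float(np.std(x - row.mean_log2, ddof=1)) if len(x) >= 2 else 0.0)
    return float(np.mean(sds)) if sds else np.nan


def call_sample(counts: np.ndarray, bins: GenomeBins, sample_id: str = "sample",
                penalty: float | None = None, loss_cut: float = LOSS_CUT_DEFAULT,
                gain_cut: float = GAIN_CUT_DEFAULT, pseudocount: float = 0.5) -> SegmentProfile:
    """Convenience: normalize -> segment -> call -> QC for one sample."""
    profile = normalize_bins(counts, bins, sample_id=sample_id, pseudocount=pseudocount)
    raw = segment_bins(profile, penalty=penalty)
    called = call_segments(raw, loss_cut=loss_cut, gain_cut=gain_cut, sample_id=sample_id)
    called.qc_mean_segment_sd = qc_profile(profile, called.segments)
    return called
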