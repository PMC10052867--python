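"""Enrichment peak calling against an IgG null, set comparison, Hi-C check.

Candidate regions (non-overlapping bins of a configurable width,
default 200 bp) are tested with an exact one-sided binomial test of
their flagged-call count k out of adenine-call count n against the
null probability p0 = the genome-wide methylation ratio of an
IgG/no-antibody control. P-values are Benjamini-Hochberg corrected
across all tested regions; adjacent significant bins are merged, and a
merged region is a peak when adj-p < 0.01 (strict) and its width
exceeds 50 bp (strict).

Peak sets are compared by any-bp overlap (Venn counts) plus a two-
sided rank-sum test of reference signal between overlapping and
non-overlapping reference peaks. The Hi-C proximity comparison asks
whether regions that physically contact a peak-bound locus (interaction
ends +/-2.5 kb) carry more methylation than randomly sampled background
regions free of interactions and peaks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom, mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .errors import DataQualityWarning, InsufficientDataError
from .io import GenomicBin

logger = logging.getLogger(__name__)

NULL_CLAMP = 1e-6


def estimate_null(igg_molecules, cutoff: float) -> float:
    """Genome-wide flagged/total call ratio of the control sample.

    Pools counts over all control molecules (a ratio of pooled counts,
    not a mean of per-molecule ratios) and clamps the result to
    [1e-6, 1 - 1e-6] so the binomial null is never degenerate.
    """
    flagged = 0
    total = 0
    for m in igg_molecules:
        meth = m.meth if m.meth is not None else (m.prob > cutoff)
        flagged += int(np.sum(meth))
        total += len(meth)
    if total == 0:
        raise InsufficientDataError("control sample has no calls")
    p = flagged / total
    if p <= 0 or p >= 1:
        warnings.warn(
            f"degenerate control methylation ratio {p}; clamped",
            DataQualityWarning,
            stacklevel=2,
        )
    return float(min(max(p, NULL_CLAMP), 1 - NULL_CLAMP))


def binomial_region_test(meth_count: int, a_count: int, null_p: float) -> float:
    """Exact upper-tail binomial p-value P(X >= k | Binomial(n, p0))."""
    k, n = int(meth_count), int(a_count)
    if n < 1:
        raise ValueError("a_count must be >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"meth_count must be in [0, a_count], got k={k}, n={n}")
    if not 0 < null_p < 1:
        raise ValueError("null_p must be in (0, 1)")
    return float(binom.sf(k - 1, n, null_p))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class PeakCallResult:
    """Pre-merge per-bin table and the merged peak set."""

    table: pd.DataFrame  # chrom,start,end,meth_count,a_count,p_value,adj_p,significant
    peaks: pd.DataFrame  # merged: chrom,start,end,meth_count,a_count,adj_p,width,passes
    null_p: float
    alpha: float
    min_width: int

    @property
    def passing(self) -> pd.DataFrame:
        return self.peaks[self.peaks["passes"]]


def call_peaks(
    track: pd.DataFrame,
    null_p: float,
    alpha: float = 0.01,
    min_width: int = 50,
    merge: bool = True,
) -> PeakCallResult:
    """Binomial peak calling over a count track.

    ``track`` must carry chrom/start/end/meth_count/a_count (as from
    :func:`modfoot.track.ratio_track` on non-overlapping bins). Bins
    with no adenine call are not tested. BH correction runs across all
    tested bins; adjacent significant bins (touching or overlapping on
    the same chromosome) are merged before the strict width > min_width
    filter. With ``merge=False`` each significant bin stands alone.
    """
    tested = track[track["a_count"] > 0].copy()
    if tested.empty:
        empty = tested.assign(p_value=[], adj_p=[], significant=[])
        peaks = pd.DataFrame(
            columns=["chrom", "start", "end", "meth_count", "a_count", "adj_p", "width", "passes"]
        )
        return PeakCallResult(empty, peaks, null_p, alpha, min_width)
    tested["p_value"] = binom.sf(
        tested["meth_count"].to_numpy() - 1, tested["a_count"].to_numpy(), null_p
    )
    tested["adj_p"] = bh_adjust(tested["p_value"].to_numpy())
    tested["significant"] = tested["adj_p"] < alpha

    sig = tested[tested["significant"]].sort_values(["chrom", "start"])
    rows = []
    if not sig.empty:
        groups = [[sig.iloc[0]]]
        for _, row in sig.iloc[1:].iterrows():
            prev = groups[-1][-1]
            if merge and row["chrom"] == prev["chrom"] and row["start"] <= prev["end"]:
                groups[-1].append(row)
            else:
                groups.append([row])
        for grp in groups:
            start = int(grp[0]["start"])
            end = int(max(r["end"] for r in grp))
            rows.append(
                {
                    "chrom": grp[0]["chrom"],
                    "start": start,
                    "end": end,
                    "meth_count": int(sum(r["meth_count"] for r in grp)),
                    "a_count": int(sum(r["a_count"] for r in grp)),
                    "adj_p": float(min(r["adj_p"] for r in grp)),
                    "width": end - start,
                }
            )
    peaks = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "meth_count", "a_count", "adj_p", "width"]
    )
    peaks["passes"] = (peaks["adj_p"] < alpha) & (peaks["width"] > min_width)
    return PeakCallResult(tested, peaks, null_p, alpha, min_width)


def peaks_to_bed(result: PeakCallResult, path) -> None:
    """Write passing peaks as narrowPeak-like BED6+4 (signal = -log10 adj-p)."""
    with open(path, "w", encoding="utf-8") as fh:
        for i, row in enumerate(result.passing.itertuples(index=False), start=1):
            score = -np.log10(max(row.adj_p, 1e-300))
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\tpeak_{i}\t"
                f"{min(1000, int(10 * score))}\t.\t{score:.4f}\t-1\t-1\t-1\n"
            )


def _bins_frame(bins) -> pd.DataFrame:
    if isinstance(bins, pd.DataFrame):
        return bins[["chrom", "start", "end"]].reset_index(drop=True)
    rows = [(b.chrom, b.start, b.end) for b in bins]
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _overlap_mask(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Boolean per query row: any-bp overlap with any subject interval."""
    mask = np.zeros(len(query), dtype=bool)
    by_chrom = {c: g for c, g in subject.groupby("chrom", sort=False)}
    for chrom, idx in query.groupby("chrom", sort=False).indices.items():
        if chrom not in by_chrom:
            continue
        sub = by_chrom[chrom].sort_values("start")
        s_starts = sub["start"].to_numpy()
        # running max of ends handles nested intervals
        s_maxend = np.maximum.accumulate(sub["end"].to_numpy())
        q_starts = query["start"].to_numpy()[idx]
        q_ends = query["end"].to_numpy()[idx]
        # candidate: last subject starting before the query end
        pos = np.searchsorted(s_starts, q_ends, side="left") - 1
        ok = pos >= 0
        hit = np.zeros(len(idx), dtype=bool)
        hit[ok] = s_maxend[pos[ok]] > q_starts[ok]
        mask[idx] = hit
    return mask


@dataclass
class OverlapResult:
    """Venn counts of two peak sets plus the non-overlap signal test."""

    n_a: int
    n_b: int
    a_with_overlap: int
    b_with_overlap: int
    a_only: int
    b_only: int
    wilcoxon_stat: float = float("nan")
    wilcoxon_p: float = float("nan")
    test_skipped: bool = True

    def venn(self) -> dict:
        return {"a_only": self.a_only, "b_only": self.b_only,
                "a_overlap": self.a_with_overlap, "b_overlap": self.b_with_overlap}


def peak_overlap(peaks_a, peaks_b, track_b_values=None) -> OverlapResult:
    """Any-bp overlap counts between two peak sets in one coordinate system.

    ``track_b_values`` (one signal value per B peak, in order) enables
    the two-sided rank-sum comparison of overlapping vs non-overlapping
    B peaks; the test is skipped (flagged) when either group is empty.
    """
    a = _bins_frame(peaks_a)
    b = _bins_frame(peaks_b)
    if a.empty or b.empty:
        return OverlapResult(len(a), len(b), 0, 0, len(a), len(b))
    a_hit = _overlap_mask(a, b)
    b_hit = _overlap_mask(b, a)
    res = OverlapResult(
        n_a=len(a),
        n_b=len(b),
        a_with_overlap=int(a_hit.sum()),
        b_with_overlap=int(b_hit.sum()),
        a_only=int((~a_hit).sum()),
        b_only=int((~b_hit).sum()),
    )
    if track_b_values is not None:
        values = np.asarray(track_b_values, dtype=float)
        if len(values) != len(b):
            raise ValueError("track_b_values must align with peaks_b")
        g1 = values[b_hit]
        g2 = values[~b_hit]
        if len(g1) and len(g2):
            stat, p = mannwhitneyu(g1, g2, alternative="two-sided")
            res.wilcoxon_stat, res.wilcoxon_p, res.test_skipped = float(stat), float(p), False
    return res


@dataclass
class HicProximityResult:
    """Mean methylation of contact-proximate vs background regions."""

    proximate_means: np.ndarray
    background_means: np.ndarray
    stat: float
    p_value: float
    attrition: dict = field(default_factory=dict)


def _region_mean_ratio(track: pd.DataFrame, chrom: str, start: int, end: int) -> float:
    sel = (track["chrom"] == chrom) & (track["start"] < end) & (track["end"] > start)
    vals = track.loc[sel, "ratio"].to_numpy(dtype=float)
    vals = vals[np.isfinite(vals)]
    return float(vals.mean()) if len(vals) else float("nan")


def hic_proximity_compare(
    pairs: pd.DataFrame,
    peaks,
    track: pd.DataFrame,
    flank: int = 2500,
    bg_width: int = 5000,
    n_background: int = 100,
    seed: int = 0,
) -> HicProximityResult:
    """Compare methylation at contact partners of peak-bound loci vs background.

    Each interaction end is expanded to +/-``flank``; pairs with exactly
    one end overlapping a peak define a proximate region around the
    other end. Background regions of ``bg_width`` are sampled (seeded)
    away from every pair flank and every peak. Mean per-region track
    ratios are compared two-sided by rank sum.
    """
    peaks_df = _bins_frame(peaks)
    rng = np.random.default_rng(seed)
    attrition = {"n_pairs": len(pairs), "both_ends": 0, "no_end": 0, "one_end": 0,
                 "undefined_signal": 0}
    end_regions = []
    proximate = []
    for chrom, pos1, pos2 in pairs[["chrom", "pos1", "pos2"]].itertuples(index=False):
        r1 = (chrom, max(0, int(pos1) - flank), int(pos1) + flank)
        r2 = (chrom, max(0, int(pos2) - flank), int(pos2) + flank)
        end_regions.extend([r1, r2])
        ends = pd.DataFrame([r1, r2], columns=["chrom", "start", "end"])
        hits = _overlap_mask(ends, peaks_df) if not peaks_df.empty else np.zeros(2, bool)
        if hits.sum() == 2:
            attrition["both_ends"] += 1
        elif hits.sum() == 0:
            attrition["no_end"] += 1
        else:
            attrition["one_end"] += 1
            proximate.append(r2 if hits[0] else r1)
    if not proximate:
        raise InsufficientDataError(
            f"no interaction pair has exactly one peak-bound end; attrition: {attrition}"
        )
    prox_means = np.array(
        [_region_mean_ratio(track, *r) for r in proximate], dtype=float
    )
    attrition["undefined_signal"] = int(np.sum(~np.isfinite(prox_means)))
    prox_means = prox_means[np.isfinite(prox_means)]
    if len(prox_means) == 0:
        raise InsufficientDataError("no proximate region has defined track signal")

    exclude = pd.DataFrame(end_regions, columns=["chrom", "start", "end"])
    exclude = pd.concat([exclude, peaks_df], ignore_index=True)
    extents = track.groupby("chrom")["end"].max()
    bg_means = []
    max_tries = n_background * 50
    tries = 0
    while len(bg_means) < n_background and tries < max_tries:
        tries += 1
        chrom = str(rng.choice(extents.index.to_numpy()))
        limit = int(extents[chrom]) - bg_width
        if limit <= 0:
            continue
        start = int(rng.integers(0, limit))
        cand = pd.DataFrame([(chrom, start, start + bg_width)],
                            columns=["chrom", "start", "end"])
        if _overlap_mask(cand, exclude)[0]:
            continue
        v = _region_mean_ratio(track, chrom, start, start + bg_width)
        if np.isfinite(v):
            bg_means.append(v)
    if len(bg_means) < 3:
        raise InsufficientDataError(
            f"could only place {len(bg_means)} background region(s); "
            "relax exclusions or shrink bg_width"
        )
    bg_means = np.asarray(bg_means)
    stat, p = mannwhitneyu(prox_means, bg_means, alternative="two-sided")
    return HicProximityResult(
        proximate_means=prox_means,
        background_means=bg_means,
        stat=float(stat),
        p_value=float(p),
        attrition=attrition,
    )


__all__ = [
    "estimate_null",
    "binomial_region_test",
    "bh_adjust",
    "PeakCallResult",
    "call_peaks",
    "peaks_to_bed",
    "OverlapResult",
    "peak_overlap",
    "HicProximityResult",
    "hic_proximity_compare",
]
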