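"""Binned methylation-ratio tracks, normalization, meta-profiles.

The bulk readout of a methyltransferase-footprinting run is the
methylation ratio per genomic bin: flagged m6A calls divided by all
adenine calls from every read covering the bin (default 50-bp bins
sliding by 5 bp). Bins with no adenine call are *undefined* (NaN), a
distinct state from ratio 0 — a coverage gap must not read as
biological absence.

Count tracks are normalized to counts-per-``scale`` (Nm_i = C_i /
sum(C) * scale, default 1e6). Meta-profiles average the ratio in offset
bins around a set of centers (e.g. peak centers +/-1000 bp, motif
centers +/-500 bp in 100-bp bins), mirroring offsets for minus-strand
centers. Replicate concordance is the Pearson correlation of
log2(ratio + pseudocount) over bins defined in both replicates.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .errors import InsufficientDataError
from .io import GenomicBin

logger = logging.getLogger(__name__)


def make_bins(chrom_sizes, width: int = 50, step: int | None = 5) -> pd.DataFrame:
    """Tile chromosomes with sliding bins from position 0.

    ``step == width`` gives a disjoint tiling; ``step > width`` (gaps)
    is unsupported. Trailing bins are clipped to the chromosome end and
    kept with their true width; a chromosome shorter than one bin width
    yields the single bin [0, length).
    """
    if step is None:
        step = width
    if width < 1:
        raise ValueError("width must be >= 1")
    if not 1 <= step <= width:
        raise ValueError("step must satisfy 1 <= step <= width (gaps unsupported)")
    frames = []
    for chrom, length in chrom_sizes.items():
        length = int(length)
        if length < 1:
            raise ValueError(f"chromosome {chrom} has non-positive length {length}")
        if length <= width:
            starts = np.array([0], dtype=np.int64)
        else:
            starts = np.arange(0, length, step, dtype=np.int64)
        ends = np.minimum(starts + width, length)
        frames.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(frames, ignore_index=True)


def tile_region(chrom: str, start: int, end: int, width: int) -> pd.DataFrame:
    """Non-sliding bins tiling [start, end); trailing partial kept."""
    if end <= start:
        raise ValueError("region end must exceed start")
    starts = np.arange(start, end, width, dtype=np.int64)
    ends = np.minimum(starts + width, end)
    return pd.DataFrame({"chrom": chrom, "start": starts, "end": ends})


def _pooled_calls(molecules, strand: str | None):
    """Per-chromosome sorted call positions with flags and cumulative sums."""
    by_chrom: dict[str, list] = {}
    for m in molecules:
        if m.meth is None:
            raise ValueError(
                f"molecule {m.read_id} has no methylated flags; run binarize_calls first"
            )
        sel = slice(None) if strand is None else (m.strand == strand)
        pos = m.pos[sel]
        meth = m.meth[sel]
        if len(pos):
            by_chrom.setdefault(m.chrom, []).append((pos, meth))
    out = {}
    for chrom, chunks in by_chrom.items():
        pos = np.concatenate([c[0] for c in chunks])
        meth = np.concatenate([c[1] for c in chunks])
        order = np.argsort(pos, kind="stable")
        pos = pos[order]
        cum = np.concatenate(([0], np.cumsum(meth[order])))
        out[chrom] = (pos, cum)
    return out


def ratio_track(molecules, bins: pd.DataFrame, strand: str | None = None) -> pd.DataFrame:
    """Per-bin pooled methylation ratio over all covering reads.

    Returns the bin frame with ``meth_count``, ``a_count`` and
    ``ratio`` columns; ``ratio`` is NaN where ``a_count`` is 0. Strands
    are pooled by default; pass ``strand='+'``/``'-'`` for a per-strand
    track.
    """
    pooled = _pooled_calls(molecules, strand)
    meth_count = np.zeros(len(bins), dtype=np.int64)
    a_count = np.zeros(len(bins), dtype=np.int64)
    for chrom, idx in bins.groupby("chrom", sort=False).indices.items():
        if chrom not in pooled:
            continue
        pos, cum = pooled[chrom]
        starts = bins["start"].to_numpy()[idx]
        ends = bins["end"].to_numpy()[idx]
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="left")
        a_count[idx] = hi - lo
        meth_count[idx] = cum[hi] - cum[lo]
    out = bins.copy()
    out["meth_count"] = meth_count
    out["a_count"] = a_count
    with np.errstate(invalid="ignore", divide="ignore"):
        out["ratio"] = np.where(a_count > 0, meth_count / np.maximum(a_count, 1), np.nan)
    return out


def normalize_track(counts, scale: float = 1e6) -> np.ndarray:
    """Counts-per-``scale`` normalization: C_i / sum(C) * scale.

    The output sums to ``scale`` exactly (up to floating rounding) and
    is invariant to rescaling the input counts by a constant.
    """
    c = np.asarray(counts, dtype=float)
    if scale <= 0:
        raise ValueError("scale must be positive")
    total = c.sum()
    if total <= 0:
        raise ValueError("cannot normalize an all-zero count track")
    return c / total * scale


def _center_frame(centers) -> pd.DataFrame:
    if isinstance(centers, pd.DataFrame):
        df = centers.copy()
        if "pos" not in df.columns:
            df["pos"] = (df["start"] + df["end"]) // 2
        if "strand" not in df.columns:
            df["strand"] = "+"
        return df[["chrom", "pos", "strand"]]
    rows = []
    for c in centers:
        if isinstance(c, GenomicBin):
            rows.append((c.chrom, (c.start + c.end) // 2, c.strand or "+"))
        else:
            chrom, pos = c[0], c[1]
            strand = c[2] if len(c) > 2 and c[2] else "+"
            rows.append((chrom, int(pos), strand))
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand"])


def center_profile(
    molecules,
    centers,
    flank: int = 1000,
    bin_width: int = 100,
    step: int | None = None,
) -> pd.DataFrame:
    """Meta-profile: mean methylation ratio per offset bin around centers.

    For each center, the ratio is computed in windows
    [center + offset, center + offset + bin_width) for offsets from
    ``-flank`` up to ``flank - bin_width`` in steps of ``step``
    (default: non-overlapping, ``step = bin_width``). Minus-strand
    centers have their offsets mirrored so that negative offsets always
    mean "upstream". Each profile point is the mean of the defined
    per-center ratios; ``n_centers`` counts the contributors.
    """
    if step is None:
        step = bin_width
    if flank % step != 0:
        raise ValueError("flank must be a multiple of step")
    cdf = _center_frame(centers)
    if cdf.empty:
        raise ValueError("centers must be nonempty")
    pooled = _pooled_calls(molecules, strand=None)
    offsets = np.arange(-flank, flank - bin_width + 1, step, dtype=np.int64)
    sums = np.zeros(len(offsets))
    counts = np.zeros(len(offsets), dtype=np.int64)
    for chrom, pos, strand in cdf.itertuples(index=False):
        if chrom not in pooled:
            continue
        call_pos, cum = pooled[chrom]
        if strand == "-":
            starts = pos - offsets - bin_width
        else:
            starts = pos + offsets
        ends = starts + bin_width
        lo = np.searchsorted(call_pos, np.maximum(starts, 0), side="left")
        hi = np.searchsorted(call_pos, np.maximum(ends, 0), side="left")
        a = hi - lo
        meth = cum[hi] - cum[lo]
        defined = a > 0
        sums[defined] += meth[defined] / a[defined]
        counts[defined] += 1
    if not counts.any():
        logger.warning("no center has any covered offset bin; profile is all-undefined")
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame({"offset": offsets, "mean_ratio": mean, "n_centers": counts})


def replicate_correlation(
    track_a: pd.DataFrame,
    track_b: pd.DataFrame,
    pseudocount: float = 1e-3,
) -> float:
    """Pearson r of log2(ratio + pseudocount) between two replicate tracks.

    Both tracks must be on the same bin grid; bins where either ratio
    is undefined are dropped (count logged). Fewer than 3 shared
    defined bins is an error.
    """
    key = ["chrom", "start", "end"]
    merged = track_a[key + ["ratio"]].merge(
        track_b[key + ["ratio"]], on=key, suffixes=("_a", "_b")
    )
    if len(merged) != len(track_a) or len(merged) != len(track_b):
        raise ValueError("replicate tracks are not on the same bin grid")
    defined = merged["ratio_a"].notna() & merged["ratio_b"].notna()
    n_dropped = int((~defined).sum())
    if n_dropped:
        logger.info("dropped %d bin(s) undefined in either replicate", n_dropped)
    sub = merged[defined]
    if len(sub) < 3:
        raise InsufficientDataError(
            f"only {len(sub)} shared defined bin(s); need at least 3 for a correlation"
        )
    a = np.log2(sub["ratio_a"].to_numpy() + pseudocount)
    b = np.log2(sub["ratio_b"].to_numpy() + pseudocount)
    return float(pearsonr(a, b).statistic)


__all__ = [
    "make_bins",
    "tile_region",
    "ratio_track",
    "normalize_track",
    "center_profile",
    "replicate_correlation",
]
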