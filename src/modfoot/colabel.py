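"""Co-labeling coefficient (CC) analysis of single-molecule methylation.

Two genomic windows are *co-labeled* on a fiber when they carry similar
amounts of methylation on that same molecule. For per-window flagged
call counts A_i, A_j of one molecule the local coefficient is

    cc(A_i, A_j) = 0.5 - |A_i - A_j| / (A_i + A_j)

which is 0.5 when the windows are identically labeled (both nonzero),
-0.5 when exactly one is unlabeled, and symmetric / scale-invariant in
between. Across molecules spanning both windows the matrix entry is
the mean of the per-molecule coefficients; molecules with A_i = A_j = 0
are excluded from that pair (mutual absence is no evidence of
co-labeling — the single most consequential convention in this module).
A distance-dependent variant multiplies each entry by
(|L_i - L_j| / n + 1), amplifying long-range values of either sign
(n = region length, L = window start positions).

The promoter-upstream scan computes, per gene, the CC row between a
promoter anchor window and each window of the 2-kb upstream span,
keeps the top quartile of genes by row variance, clusters the retained
rows hierarchically, and reports contiguous high-CC runs as candidate
cis-regulators.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataQualityWarning, InsufficientDataError
from .io import GenomicBin, Molecule
from .single_molecule import (
    DEFAULT_SM_CUTOFF,
    METHYLATED_BIN_MIN_SITES,
    METHYLATED_BIN_RATIO,
    hierarchical_labels,
)

logger = logging.getLogger(__name__)


@dataclass
class WindowVector:
    """Per-window flagged-call counts of one molecule over a region."""

    read_id: str
    region: GenomicBin
    w: int
    starts: np.ndarray  # window genomic start positions (L)
    A: np.ndarray  # flagged (methylated) call count per window
    defined: np.ndarray  # windows where the molecule has >= 1 adenine call


@dataclass
class CCMatrix:
    """Symmetric co-labeling matrix over fixed-width windows of a region.

    ``cc`` is NaN where support (number of contributing spanning
    molecules) is below the minimum; ``aggregate`` is the sum of the
    defined entries over the full double index (the region-level
    aggregate score).
    """

    region: GenomicBin
    w: int
    n: int  # region length
    starts: np.ndarray  # L: window start positions
    cc: np.ndarray
    support: np.ndarray
    aggregate: float
    distance_weighted: bool = False

    def to_frame(self) -> pd.DataFrame:
        """Long-format (i, j, L_i, L_j, cc, support) over defined entries."""
        i, j = np.nonzero(~np.isnan(self.cc))
        return pd.DataFrame(
            {
                "i": i,
                "j": j,
                "L_i": self.starts[i],
                "L_j": self.starts[j],
                "cc": self.cc[i, j],
                "support": self.support[i, j],
            }
        )


def cc_pair(a_i: float, a_j: float) -> float:
    """Local co-labeling coefficient 0.5 - |Ai - Aj| / (Ai + Aj).

    Bounded in [-0.5, 0.5]; 0.5 iff Ai == Aj > 0; -0.5 iff exactly one
    count is zero. Ai = Aj = 0 carries no information and returns the
    excluded-pair sentinel NaN.
    """
    if a_i < 0 or a_j < 0:
        raise ValueError("window counts must be non-negative")
    if a_i == 0 and a_j == 0:
        return float("nan")
    return 0.5 - abs(a_i - a_j) / (a_i + a_j)


def window_vector(
    molecule: Molecule,
    region: GenomicBin,
    w: int = 50,
    cutoff: float | None = DEFAULT_SM_CUTOFF,
    binary: bool = False,
) -> WindowVector:
    """Count this molecule's methylated calls per full w-bp window.

    Windows tile the region from its start; a trailing remainder
    shorter than ``w`` is ignored. A window with no adenine call from
    this molecule is masked undefined. With ``binary=True`` the counts
    are collapsed to the methylated-bin rule (ratio > 0.5 and >= 2
    sites -> 1, else 0).
    """
    meth = molecule.meth
    if meth is None:
        if cutoff is None:
            raise ValueError("molecule has no flags; pass cutoff to binarize on the fly")
        meth = molecule.prob > cutoff
    n_win = region.width // w
    if n_win < 1:
        raise ValueError("region shorter than one window")
    starts = region.start + np.arange(n_win, dtype=np.int64) * w
    ends = starts + w
    if molecule.chrom != region.chrom:
        raise ValueError(f"molecule {molecule.read_id} is not on {region.chrom}")
    lo = np.searchsorted(molecule.pos, starts, side="left")
    hi = np.searchsorted(molecule.pos, ends, side="left")
    a_calls = hi - lo
    cum = np.concatenate(([0], np.cumsum(meth)))
    counts = cum[hi] - cum[lo]
    defined = a_calls > 0
    if binary:
        with np.errstate(invalid="ignore"):
            ratio = np.where(defined, counts / np.maximum(a_calls, 1), np.nan)
        counts = (
            defined & (ratio > METHYLATED_BIN_RATIO) & (counts >= METHYLATED_BIN_MIN_SITES)
        ).astype(np.int64)
    return WindowVector(
        read_id=molecule.read_id,
        region=region,
        w=w,
        starts=starts,
        A=counts.astype(np.int64),
        defined=defined,
    )


def _window_matrix(molecules, region, w, cutoff, binary):
    """Stack per-molecule window vectors into (A, defined) arrays."""
    vecs = []
    for m in molecules:
        if m.chrom != region.chrom or m.end <= region.start or m.start >= region.end:
            continue
        vecs.append(window_vector(m, region, w=w, cutoff=cutoff, binary=binary))
    if not vecs:
        n_win = region.width // w
        starts = region.start + np.arange(n_win, dtype=np.int64) * w
        return starts, np.zeros((0, n_win), dtype=np.int64), np.zeros((0, n_win), dtype=bool)
    starts = vecs[0].starts
    A = np.stack([v.A for v in vecs])
    defined = np.stack([v.defined for v in vecs])
    return starts, A, defined


def cc_matrix(
    molecules,
    region: GenomicBin,
    w: int = 50,
    min_reads: int = 1,
    cutoff: float | None = DEFAULT_SM_CUTOFF,
    binary: bool = False,
) -> CCMatrix:
    """Mean per-molecule co-labeling coefficient for every window pair.

    Entry (i, j) averages cc_pair(A_k[i], A_k[j]) over molecules k
    covering both windows (both defined), excluding molecules with
    A_k[i] = A_k[j] = 0; its support is the number of contributors, and
    entries with support below ``min_reads`` are NaN. The aggregate
    scalar sums the defined entries over the full double index.
    """
    if region.width < 2 * w:
        raise ValueError("region must span at least two windows")
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    starts, A, defined = _window_matrix(molecules, region, w, cutoff, binary)
    n_win = len(starts)
    cc = np.full((n_win, n_win), np.nan)
    support = np.zeros((n_win, n_win), dtype=np.int64)
    Af = A.astype(float)
    for i in range(n_win):
        ai = Af[:, i : i + 1]  # (n_mol, 1)
        contrib = defined[:, i : i + 1] & defined & ~((A[:, i : i + 1] == 0) & (A == 0))
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = 0.5 - np.abs(ai - Af) / (ai + Af)
        vals = np.where(contrib, vals, np.nan)
        cnt = contrib.sum(axis=0)
        support[i] = cnt
        ok = cnt >= min_reads
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            means = np.nanmean(vals, axis=0)
        cc[i, ok] = means[ok]
    if not np.any(support >= min_reads):
        warnings.warn(
            "no window pair reaches the minimum read support; empty matrix",
            DataQualityWarning,
            stacklevel=2,
        )
    aggregate = float(np.nansum(cc)) if np.any(~np.isnan(cc)) else 0.0
    return CCMatrix(
        region=region,
        w=w,
        n=region.width,
        starts=starts,
        cc=cc,
        support=support,
        aggregate=aggregate,
    )


def cc_distance_weighted(matrix: CCMatrix) -> CCMatrix:
    """Distance-dependent variant: entry * (|L_i - L_j| / n + 1).

    The factor lies in [1, 2), so plain values in [-0.5, 0.5] map into
    (-1, 1); signs are preserved and distant pairs are amplified.
    """
    L = matrix.starts.astype(float)
    factor = np.abs(L[:, None] - L[None, :]) / matrix.n + 1.0
    cc = matrix.cc * factor
    aggregate = float(np.nansum(cc)) if np.any(~np.isnan(cc)) else 0.0
    return CCMatrix(
        region=matrix.region,
        w=matrix.w,
        n=matrix.n,
        starts=matrix.starts,
        cc=cc,
        support=matrix.support.copy(),
        aggregate=aggregate,
        distance_weighted=True,
    )


@dataclass
class UpstreamScanResult:
    """Per-gene promoter-anchored upstream CC profiles and selections.

    ``profiles`` rows are genes; columns ``up{d}`` give the CC between
    the promoter anchor window and the window ``d`` bp further
    upstream (d = w, 2w, ...). ``selected`` is the top variance
    quartile, with cluster labels in ``clusters``; ``candidates`` maps
    each selected gene to contiguous high-CC runs as
    (upstream_start_bp, upstream_end_bp) offsets.
    """

    profiles: pd.DataFrame
    variance: pd.Series
    selected: list
    clusters: pd.Series
    candidates: dict


def upstream_cc_scan(
    molecules,
    promoters,
    span: int = 2000,
    w: int = 50,
    cutoff: float | None = DEFAULT_SM_CUTOFF,
    n_clusters: int = 2,
    seed: int = 0,
    high_cc: float = 0.25,
    binary: bool = False,
) -> UpstreamScanResult:
    """Scan the 2-kb span upstream of each promoter for co-labeled windows.

    The anchor is the w-bp window at the promoter's upstream (TSS-
    proximal) edge; the scan covers ``span`` bp further upstream in
    w-bp windows, strand-aware. Genes are ranked by the variance of
    their CC row; the upper quartile is retained and clustered with the
    same hierarchical settings as the gene-heterogeneity clustering.
    """
    del seed  # clustering is deterministic; kept for interface stability
    items = promoters.items() if hasattr(promoters, "items") else promoters
    n_up = span // w
    profiles = {}
    for gene_id, prom in items:
        strand = prom.strand or "+"
        if strand == "+":
            scan_start = prom.start - span
            region = GenomicBin(prom.chrom, scan_start, prom.start + w, strand=strand)
            anchor = n_up  # last window = promoter edge
            upstream_idx = np.arange(n_up - 1, -1, -1)  # nearest first
        else:
            region = GenomicBin(prom.chrom, prom.end - w, prom.end + span, strand=strand)
            anchor = 0
            upstream_idx = np.arange(1, n_up + 1)
        if region.start < 0:
            logger.info("gene %s upstream span exceeds the chromosome start; skipped", gene_id)
            continue
        mat = cc_matrix(molecules, region, w=w, min_reads=1, cutoff=cutoff, binary=binary)
        profiles[gene_id] = mat.cc[anchor, upstream_idx]
    if not profiles:
        raise InsufficientDataError("no promoter has a valid upstream scan region")
    cols = [f"up{(i + 1) * w}" for i in range(n_up)]
    df = pd.DataFrame.from_dict(profiles, orient="index", columns=cols)
    df.index.name = "gene_id"
    if df.notna().sum().sum() == 0:
        raise InsufficientDataError("no gene has spanning molecule coverage upstream")

    variance = df.var(axis=1, skipna=True).fillna(-np.inf)
    # descending variance, ties broken by gene id: selection is
    # invariant to input order
    order = variance.loc[sorted(variance.index, key=lambda g: (-variance[g], str(g)))]
    n_keep = max(1, int(np.ceil(len(order) / 4)))
    selected = list(order.index[:n_keep])

    clusters = pd.Series(1, index=pd.Index(selected, name="gene_id"), dtype=np.int64)
    if len(selected) >= 2 and n_clusters >= 2:
        sub = df.loc[selected].fillna(0.0).to_numpy()
        k = min(n_clusters, len(selected))
        clusters = pd.Series(
            hierarchical_labels(sub, k), index=pd.Index(selected, name="gene_id")
        )

    candidates = {}
    for gene_id in selected:
        row = df.loc[gene_id].to_numpy(dtype=float)
        hot = np.where(np.isnan(row), False, row >= high_cc)
        runs = []
        start = None
        for i, flag in enumerate(np.append(hot, False)):
            if flag and start is None:
                start = i
            elif not flag and start is not None:
                runs.append((start * w + w, (i + 1) * w))  # bp offsets upstream
                start = None
        candidates[gene_id] = runs
    return UpstreamScanResult(
        profiles=df,
        variance=variance.replace(-np.inf, np.nan),
        selected=selected,
        clusters=clusters,
        candidates=candidates,
    )


__all__ = [
    "WindowVector",
    "CCMatrix",
    "UpstreamScanResult",
    "cc_pair",
    "window_vector",
    "cc_matrix",
    "cc_distance_weighted",
    "upstream_cc_scan",
]
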