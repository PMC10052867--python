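"""Single-molecule chromatin-state classification and heterogeneity.

Each sequenced fiber is scored on non-sliding 50-bp bins using only its
own calls. A bin is *methylated* when its per-molecule methylation
ratio is strictly greater than 0.5 AND it carries at least 2 flagged
sites (one stray high-probability call is never enough). The fraction
of defined bins that are methylated — the methylation bin density —
classifies the molecule:

* light  : density < 25%
* medium : 25% <= density <= 75%
* heavy  : density > 75%

Bins with no adenine call are undefined and excluded from the density
denominator by default (``strict=True`` counts them as unmethylated
instead, for sensitivity analysis).

Per-gene heterogeneity rows collect the sorted per-molecule densities
over a promoter region (2 kb upstream of the TSS), quantile-resampled
to a fixed length so genes with unequal molecule counts are comparable,
and are grouped by deterministic agglomerative clustering (Euclidean,
average linkage). Cluster-level mean expression (TPM) annotates the
clusters when an expression table is supplied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .errors import InsufficientDataError, ValidationError
from .io import GenomicBin, Molecule

logger = logging.getLogger(__name__)

LIGHT = "light"
MEDIUM = "medium"
HEAVY = "heavy"
UNCLASSIFIED = "unclassified"

DEFAULT_BIN_WIDTH = 50
DEFAULT_SM_CUTOFF = 0.80  # high-confidence single-molecule binarization
METHYLATED_BIN_MIN_SITES = 2
METHYLATED_BIN_RATIO = 0.5


@dataclass
class MoleculeStateRecord:
    """Per-molecule binned methylation summary over a region."""

    read_id: str
    region: GenomicBin
    bin_starts: np.ndarray
    bin_ratios: np.ndarray  # NaN where the molecule has no call in the bin
    n_sites: np.ndarray  # flagged calls per bin
    methylated: np.ndarray  # boolean bin flags
    bin_density: float  # NaN when no bin is defined
    state: str | None = None


def molecule_bins(
    molecule: Molecule,
    region: GenomicBin,
    bin_width: int = DEFAULT_BIN_WIDTH,
    cutoff: float | None = None,
    strict: bool = False,
) -> MoleculeStateRecord:
    """Bin one molecule's calls over ``region`` and flag methylated bins.

    Bins tile the region non-overlapping from its start. Ratios use
    this molecule's calls only. A bin is methylated iff ratio > 0.5 and
    it has >= 2 flagged sites. ``cutoff`` binarizes on the fly when the
    molecule carries no flags yet. With ``strict=True`` undefined bins
    inside the molecule's overlap span count as unmethylated.
    """
    if molecule.chrom != region.chrom:
        raise ValidationError(
            f"molecule {molecule.read_id} on {molecule.chrom} does not overlap {region.chrom}"
        )
    ov_start = max(molecule.start, region.start)
    ov_end = min(molecule.end, region.end)
    if ov_end - ov_start < 1:
        raise ValidationError(
            f"molecule {molecule.read_id} does not overlap region "
            f"{region.chrom}:{region.start}-{region.end}"
        )
    meth = molecule.meth
    if meth is None:
        if cutoff is None:
            raise ValueError("molecule has no flags; pass cutoff to binarize on the fly")
        meth = molecule.prob > cutoff

    starts = np.arange(region.start, region.end, bin_width, dtype=np.int64)
    ends = np.minimum(starts + bin_width, region.end)
    lo = np.searchsorted(molecule.pos, starts, side="left")
    hi = np.searchsorted(molecule.pos, ends, side="left")
    a = hi - lo
    cum = np.concatenate(([0], np.cumsum(meth)))
    k = cum[hi] - cum[lo]
    with np.errstate(invalid="ignore"):
        ratios = np.where(a > 0, k / np.maximum(a, 1), np.nan)
    flags = (a > 0) & (ratios > METHYLATED_BIN_RATIO) & (k >= METHYLATED_BIN_MIN_SITES)

    if strict:
        in_span = (starts < ov_end) & (ends > ov_start)
        denom = int(in_span.sum())
    else:
        denom = int((a > 0).sum())
    density = float(flags.sum() / denom) if denom else float("nan")
    return MoleculeStateRecord(
        read_id=molecule.read_id,
        region=region,
        bin_starts=starts,
        bin_ratios=ratios,
        n_sites=k,
        methylated=flags,
        bin_density=density,
    )


def classify_state(bin_density: float) -> str:
    """Map a methylation bin density to light/medium/heavy.

    The boundaries 0.25 and 0.75 belong to medium (heavy and light are
    strict inequalities). An undefined density (NaN) returns the
    ``unclassified`` sentinel, never a default state.
    """
    if bin_density is None or np.isnan(bin_density):
        return UNCLASSIFIED
    if not 0.0 <= bin_density <= 1.0:
        raise ValueError(f"bin density must be in [0, 1], got {bin_density}")
    if bin_density < 0.25:
        return LIGHT
    if bin_density > 0.75:
        return HEAVY
    return MEDIUM


def classify_molecules(
    molecules,
    region: GenomicBin,
    bin_width: int = DEFAULT_BIN_WIDTH,
    cutoff: float | None = None,
    strict: bool = False,
) -> pd.DataFrame:
    """State table for all molecules overlapping ``region``.

    Returns a DataFrame (read_id, bin_density, state); molecules not
    overlapping the region by at least one bin are skipped.
    """
    rows = []
    for m in molecules:
        try:
            rec = molecule_bins(m, region, bin_width=bin_width, cutoff=cutoff, strict=strict)
        except ValidationError:
            continue
        rec.state = classify_state(rec.bin_density)
        rows.append((rec.read_id, rec.bin_density, rec.state))
    return pd.DataFrame(rows, columns=["read_id", "bin_density", "state"])


def resample_sorted(values, length: int) -> np.ndarray:
    """Sort ascending and linearly interpolate to a fixed-length quantile grid.

    Endpoints are preserved (the first output equals the minimum, the
    last the maximum); a single value yields a constant row. The result
    is nondecreasing and invariant to the input order.
    """
    v = np.sort(np.asarray(values, dtype=float))
    if len(v) == 0:
        raise ValueError("cannot resample an empty density list")
    if len(v) == 1:
        return np.full(length, v[0])
    grid = np.linspace(0.0, 1.0, length)
    return np.interp(grid, np.linspace(0.0, 1.0, len(v)), v)


def gene_heterogeneity_matrix(
    molecules,
    promoters,
    resample_len: int = 50,
    bin_width: int = DEFAULT_BIN_WIDTH,
    cutoff: float | None = None,
    min_molecules: int = 1,
    strict: bool = False,
) -> pd.DataFrame:
    """Per-gene sorted-density rows over promoter regions.

    ``promoters`` maps gene_id -> GenomicBin (typically the 2 kb
    upstream of the TSS). Per gene, the defined molecule densities are
    sorted ascending and quantile-resampled to ``resample_len``
    columns ``q0..q{L-1}``; ``n_molecules`` records the contributing
    count. Genes with fewer than ``min_molecules`` defined molecules
    are dropped and logged; no gene passing coverage is an error.
    """
    items = promoters.items() if hasattr(promoters, "items") else promoters
    rows = {}
    n_mol = {}
    dropped = []
    for gene_id, region in items:
        table = classify_molecules(
            molecules, region, bin_width=bin_width, cutoff=cutoff, strict=strict
        )
        dens = table["bin_density"].dropna().to_numpy()
        if len(dens) < min_molecules:
            dropped.append(gene_id)
            continue
        rows[gene_id] = resample_sorted(dens, resample_len)
        n_mol[gene_id] = len(dens)
    if dropped:
        logger.info("dropped %d gene(s) below %d covering molecule(s): %s",
                    len(dropped), min_molecules, ", ".join(map(str, dropped[:10])))
    if not rows:
        raise InsufficientDataError("no gene passes the molecule-coverage requirement")
    df = pd.DataFrame.from_dict(rows, orient="index", columns=[f"q{i}" for i in range(resample_len)])
    df.index.name = "gene_id"
    df["n_molecules"] = pd.Series(n_mol)
    return df


def hierarchical_labels(matrix: np.ndarray, n_clusters: int, method: str = "average",
                        metric: str = "euclidean") -> np.ndarray:
    """Deterministic agglomerative clustering, labels relabelled by first occurrence."""
    z = linkage(pdist(matrix, metric=metric), method=method)
    raw = fcluster(z, t=n_clusters, criterion="maxclust")
    relabel: dict[int, int] = {}
    labels = np.empty(len(raw), dtype=np.int64)
    for i, r in enumerate(raw):
        labels[i] = relabel.setdefault(int(r), len(relabel) + 1)
    return labels


def cluster_genes(
    rows: pd.DataFrame,
    n_clusters: int,
    expression: pd.DataFrame | None = None,
    seed: int = 0,
    method: str = "average",
    metric: str = "euclidean",
):
    """Cluster heterogeneity rows; annotate clusters with mean expression.

    Returns ``(rows_with_cluster_id, cluster_summary)``. Clustering is
    agglomerative (``metric``/``method``, defaults Euclidean/average)
    on the resampled quantile columns and fully deterministic — the
    ``seed`` argument is accepted for interface stability only.
    ``expression`` is a DataFrame (gene_id, tpm); genes absent from it
    are excluded from the cluster means, with counts reported in the
    summary.
    """
    del seed  # deterministic; kept for a stable call signature
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    if len(rows) < n_clusters:
        raise InsufficientDataError(
            f"need at least {n_clusters} gene rows to form {n_clusters} clusters"
        )
    qcols = [c for c in rows.columns if c.startswith("q")]
    labels = hierarchical_labels(rows[qcols].to_numpy(), n_clusters, method, metric)
    out = rows.copy()
    out["cluster_id"] = labels

    tpm = None
    if expression is not None:
        tpm = expression.set_index("gene_id")["tpm"]
    summary_rows = []
    for cid, grp in out.groupby("cluster_id", sort=True):
        rec = {"cluster_id": cid, "n_genes": len(grp)}
        if tpm is not None:
            covered = grp.index.intersection(tpm.index)
            rec["n_with_expression"] = len(covered)
            rec["mean_tpm"] = float(tpm.loc[covered].mean()) if len(covered) else float("nan")
        summary_rows.append(rec)
    summary = pd.DataFrame(summary_rows).set_index("cluster_id")
    if tpm is not None:
        n_missing = len(out.index.difference(tpm.index))
        if n_missing:
            logger.info("%d gene(s) missing from the expression table", n_missing)
    return out, summary


__all__ = [
    "LIGHT",
    "MEDIUM",
    "HEAVY",
    "UNCLASSIFIED",
    "MoleculeStateRecord",
    "molecule_bins",
    "classify_state",
    "classify_molecules",
    "resample_sorted",
    "gene_heterogeneity_matrix",
    "hierarchical_labels",
    "cluster_genes",
]
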