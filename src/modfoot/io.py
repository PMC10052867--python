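"""Genomic data model and on-disk formats.

The atomic input of the pipeline is a per-read modified-base call: one
(read, chromosome, strand, position, probability) record per adenine, as
emitted by a nanopore modified-base caller. Calls are grouped into
:class:`Molecule` objects — single sequenced DNA fibers — which every
downstream module consumes. Coordinates are 0-based half-open
throughout, matching BED.

On-disk dialects:

* per-read call table — TSV with header columns ``read_id``, ``chrom``,
  ``strand``, ``pos``, ``mod_prob`` (extra columns ignored);
* BED3/BED6 for intervals (peaks, promoters, motif centers);
* bedGraph (4 columns, values written with 6 decimal places).

All text is UTF-8 and tab-separated; ``.gz`` paths are read and written
transparently.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataQualityWarning, FormatError, ValidationError

logger = logging.getLogger(__name__)

MODCALL_COLUMNS = ("read_id", "chrom", "strand", "pos", "mod_prob")
STRANDS = ("+", "-")


@dataclass
class ModCall:
    """One per-read, per-adenine modification-probability record."""

    read_id: str
    chrom: str
    pos: int
    strand: str
    prob: float

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValidationError(f"strand must be one of {STRANDS}, got {self.strand!r}")
        if not 0.0 <= self.prob <= 1.0:
            raise ValidationError(f"prob must be in [0, 1], got {self.prob}")
        if self.pos < 0:
            raise ValidationError(f"pos must be >= 0, got {self.pos}")


@dataclass
class Molecule:
    """One sequenced DNA fiber: ordered calls with a genomic span.

    Call data are stored as parallel numpy arrays sorted by position
    (ties broken by strand); ``meth`` is filled by
    :func:`modfoot.threshold.binarize_calls` and is ``None`` until then.
    """

    read_id: str
    chrom: str
    pos: np.ndarray
    strand: np.ndarray
    prob: np.ndarray
    meth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.strand = np.asarray(self.strand, dtype="U1")
        self.prob = np.asarray(self.prob, dtype=np.float64)
        if not (len(self.pos) == len(self.strand) == len(self.prob)):
            raise ValidationError("pos, strand and prob must have equal lengths")
        if len(self.pos) == 0:
            raise ValidationError("a molecule must carry at least one call")
        order = np.lexsort((self.strand, self.pos))
        self.pos = self.pos[order]
        self.strand = self.strand[order]
        self.prob = self.prob[order]
        if self.meth is not None:
            self.meth = np.asarray(self.meth, dtype=bool)[order]
        for s in STRANDS:
            sel = self.strand == s
            if np.any(np.diff(self.pos[sel]) == 0):
                raise ValidationError(
                    f"duplicate call positions on strand {s} in read {self.read_id}"
                )
        if np.any(self.prob < 0) or np.any(self.prob > 1):
            raise ValidationError(f"probabilities outside [0, 1] in read {self.read_id}")

    @property
    def start(self) -> int:
        return int(self.pos[0])

    @property
    def end(self) -> int:
        """End of the half-open span: max call position + 1."""
        return int(self.pos[-1]) + 1

    @property
    def n_calls(self) -> int:
        return len(self.pos)

    @property
    def calls(self) -> list[ModCall]:
        return [
            ModCall(self.read_id, self.chrom, int(p), str(s), float(q))
            for p, s, q in zip(self.pos, self.strand, self.prob)
        ]


@dataclass
class GenomicBin:
    """A 0-based half-open genomic interval, optionally named/stranded."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(
                f"interval end must exceed start, got {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class ExpressionRecord:
    """Per-gene expression level (mean TPM across replicates)."""

    gene_id: str
    tpm: float

    def __post_init__(self) -> None:
        if self.tpm < 0:
            raise ValidationError(f"tpm must be >= 0, got {self.tpm} for {self.gene_id}")


def _read_table(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype={"read_id": str, "chrom": str})
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=list(MODCALL_COLUMNS))


def read_modcall_table(path, min_prob_filter: float | None = None) -> list[Molecule]:
    """Read a per-read call TSV into a list of molecules.

    Rows are grouped by ``read_id`` (split per chromosome should a read
    map to several, with a warning); calls are sorted by position.
    Duplicate (read_id, pos, strand) rows keep the first occurrence and
    warn. ``min_prob_filter`` drops rows with ``mod_prob`` below the
    threshold; the number dropped is logged.
    """
    df = _read_table(path)
    missing = [c for c in MODCALL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"call table {path} is missing required column(s): {', '.join(missing)}")
    if df.empty:
        return []

    # line numbers: header is line 1, first data row line 2
    lines = df.index.to_numpy() + 2
    prob = pd.to_numeric(df["mod_prob"], errors="coerce")
    bad = ~np.isfinite(prob)
    if bad.any():
        raise ValidationError("mod_prob is not a number", line=int(lines[bad.to_numpy()][0]))
    out_of_range = (prob < 0) | (prob > 1)
    if out_of_range.any():
        i = int(np.flatnonzero(out_of_range.to_numpy())[0])
        raise ValidationError(
            f"mod_prob {prob.iloc[i]} outside [0, 1]", line=int(lines[i])
        )
    pos = pd.to_numeric(df["pos"], errors="coerce")
    if (~np.isfinite(pos)).any() or np.any(pos.to_numpy() % 1 != 0):
        i = int(np.flatnonzero((~np.isfinite(pos) | (pos % 1 != 0)).to_numpy())[0])
        raise ValidationError("pos is not an integer", line=int(lines[i]))
    if (pos < 0).any():
        i = int(np.flatnonzero((pos < 0).to_numpy())[0])
        raise ValidationError("pos is negative", line=int(lines[i]))
    bad_strand = ~df["strand"].isin(STRANDS)
    if bad_strand.any():
        i = int(np.flatnonzero(bad_strand.to_numpy())[0])
        raise ValidationError(
            f"strand {df['strand'].iloc[i]!r} not in {STRANDS}", line=int(lines[i])
        )

    df = df.assign(pos=pos.astype(np.int64), mod_prob=prob.astype(np.float64))

    dup = df.duplicated(subset=["read_id", "pos", "strand"])
    if dup.any():
        warnings.warn(
            f"{int(dup.sum())} duplicate (read_id, pos, strand) row(s) in {path}; keeping first",
            DataQualityWarning,
            stacklevel=2,
        )
        df = df[~dup]

    if min_prob_filter is not None:
        keep = df["mod_prob"] >= min_prob_filter
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("filtered %d call(s) below mod_prob %g", n_drop, min_prob_filter)
        df = df[keep]
    if df.empty:
        return []

    molecules: list[Molecule] = []
    multi_chrom = 0
    for read_id, grp in df.groupby("read_id", sort=False):
        chroms = grp["chrom"].unique()
        if len(chroms) > 1:
            multi_chrom += 1
        for chrom in chroms:
            sub = grp[grp["chrom"] == chrom]
            molecules.append(
                Molecule(
                    read_id=str(read_id),
                    chrom=str(chrom),
                    pos=sub["pos"].to_numpy(),
                    strand=sub["strand"].to_numpy(),
                    prob=sub["mod_prob"].to_numpy(),
                )
            )
    if multi_chrom:
        warnings.warn(
            f"{multi_chrom} read(s) mapped to multiple chromosomes; split per chromosome",
            DataQualityWarning,
            stacklevel=2,
        )
    return molecules


def write_modcall_table(molecules, path) -> None:
    """Write molecules back to the 5-column per-read call TSV dialect."""
    frames = [
        pd.DataFrame(
            {
                "read_id": m.read_id,
                "chrom": m.chrom,
                "strand": m.strand,
                "pos": m.pos,
                "mod_prob": m.prob,
            }
        )
        for m in molecules
    ]
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=list(MODCALL_COLUMNS))
    )
    df = df[list(MODCALL_COLUMNS)]
    df.to_csv(path, sep="\t", index=False)


def read_bed(path) -> list[GenomicBin]:
    """Read BED3/BED6 intervals (0-based half-open), validating end > start.

    ``track``/``browser``/``#`` lines are skipped; name ``.`` maps to
    ``None`` and so does a missing score or strand.
    """
    bins: list[GenomicBin] = []
    opener = _opener(path)
    with opener(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"BED line {lineno} in {path} has fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValidationError(f"non-integer BED coordinate: {exc}", line=lineno) from exc
            if end <= start:
                raise ValidationError(
                    f"BED interval end <= start ({chrom}:{start}-{end})", line=lineno
                )
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] != ".":
                score = float(fields[4])
            strand = fields[5] if len(fields) > 5 and fields[5] in STRANDS else None
            bins.append(GenomicBin(chrom, start, end, name=name, score=score, strand=strand))
    return bins


def write_bed(bins, path) -> None:
    """Write intervals as BED (3 to 6 columns depending on populated fields)."""
    opener = _opener(path)
    with opener(path, "wt", encoding="utf-8") as fh:
        for b in bins:
            fields = [b.chrom, str(b.start), str(b.end)]
            if b.name is not None or b.score is not None or b.strand is not None:
                fields.append(b.name if b.name is not None else ".")
                fields.append(f"{b.score:g}" if b.score is not None else ".")
                fields.append(b.strand if b.strand is not None else ".")
            fh.write("\t".join(fields) + "\n")


def write_bedgraph(track, path, value_col: str = "value", allow_overlap: bool = False) -> None:
    """Write a 4-column bedGraph.

    ``track`` is either a DataFrame with columns ``chrom``, ``start``,
    ``end`` and ``value_col``, or an iterable of ``(GenomicBin, value)``
    pairs. NaN values are skipped (their count is logged). Overlapping
    (sliding) bins require ``allow_overlap=True`` and are written as
    stepped records as-is.
    """
    df = _track_frame(track, value_col)
    if not allow_overlap:
        for _, grp in df.groupby("chrom", sort=False):
            g = grp.sort_values("start")
            if np.any(g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]):
                raise ValidationError(
                    "overlapping bins; pass allow_overlap=True to write sliding bins"
                )
    values = df[value_col].to_numpy(dtype=float)
    nan = ~np.isfinite(values)
    if nan.any():
        logger.info("skipped %d bin(s) with undefined value in bedGraph output", int(nan.sum()))
    df = df[~nan]
    opener = _opener(path)
    with opener(path, "wt", encoding="utf-8") as fh:
        for chrom, start, end, value in df[["chrom", "start", "end", value_col]].itertuples(
            index=False
        ):
            fh.write(f"{chrom}\t{int(start)}\t{int(end)}\t{value:.6f}\n")


def read_bedgraph(path) -> pd.DataFrame:
    """Read a bedGraph into a DataFrame (chrom, start, end, value)."""
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str},
            comment="#",
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["chrom", "start", "end", "value"])
    return df


def read_expression_table(path) -> pd.DataFrame:
    """Read a per-gene expression TSV with columns ``gene_id`` and ``tpm``."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    for col in ("gene_id", "tpm"):
        if col not in df.columns:
            raise FormatError(f"expression table {path} is missing column {col}")
    if (df["tpm"] < 0).any():
        i = int(np.flatnonzero((df["tpm"] < 0).to_numpy())[0])
        raise ValidationError(f"negative TPM for {df['gene_id'].iloc[i]}", line=i + 2)
    return df[["gene_id", "tpm"]]


def read_pair_table(path) -> pd.DataFrame:
    """Read an interaction-pair TSV with columns ``chrom``, ``pos1``, ``pos2``."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in ("chrom", "pos1", "pos2"):
        if col not in df.columns:
            raise FormatError(f"pair table {path} is missing column {col}")
    return df[["chrom", "pos1", "pos2"]]


def total_call_count(molecules) -> int:
    return int(sum(m.n_calls for m in molecules))


def _track_frame(track, value_col: str) -> pd.DataFrame:
    if isinstance(track, pd.DataFrame):
        for col in ("chrom", "start", "end", value_col):
            if col not in track.columns:
                raise FormatError(f"track frame is missing column {col}")
        return track
    rows = [(b.chrom, b.start, b.end, v) for b, v in track]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", value_col])


def _opener(path):
    import gzip

    return gzip.open if str(path).endswith(".gz") else open
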