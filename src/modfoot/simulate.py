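"""Synthetic references, molecules, and per-call probabilities with truth.

The generator emulates the data produced by antibody-tethered adenine
methyltransferase footprinting read out on a nanopore: single-strand
molecules whose covered adenines each receive a modification
probability drawn from a two-component emission — a sharp component
near zero for unmodified adenines and a broad high component for truly
modified ones. Four labeling modes cover the analysis surface:

* ``footprint`` — adenines inside truth footprint intervals are
  modified at ``p_fg``, elsewhere at ``p_bg`` (protein-of-interest
  labeling vs background);
* ``dam_motif`` — only GATC-motif adenines are modifiable, each at
  ``motif_efficiency`` (Dam-treated control DNA);
* ``state_mixture`` — each molecule draws a target methylated-bin
  density from ``state_densities`` (weights ``state_weights``); the
  matching number of molecule-local 50-bp bins is planted methylated,
  all their adenines truly modified, background bins at ``p_bg``;
* ``correlated_windows`` — fixed genome windows toggle on/off per
  molecule; designated window pairs share a latent with copy
  probability ``p_shared``, on-windows label at ``p_fg``, off at
  ``p_bg``.

Every call's true modified flag (and per-molecule / per-pair latents)
is recorded in a :class:`TruthTable`. All randomness flows from the
single config seed; identical configs give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
import warnings

import numpy as np
import pandas as pd
import yaml

from .errors import DataQualityWarning, ValidationError
from .io import Molecule, write_modcall_table

MODES = ("footprint", "dam_motif", "state_mixture", "correlated_windows")
BASES = np.array(["A", "C", "G", "T"])


@dataclass
class SimConfig:
    """Generator settings; defaults are the package's declared study conditions."""

    genome_length: int = 100_000
    base_composition: tuple = (0.25, 0.25, 0.25, 0.25)  # A, C, G, T
    chrom: str = "chrSim"
    mode: str = "footprint"
    footprints: tuple = ()
    p_fg: float = 0.6
    p_bg: float = 0.05
    emission_low: tuple = (0.15, 0.08)  # unmodified: sharp near zero
    emission_high: tuple = (0.80, 0.12)  # modified: broad, high
    noiseless: bool = False  # emission collapses to exact 0/1
    read_length_mean: float = 2000.0  # log-normal median
    read_length_sigma: float = 0.35
    fixed_read_length: int | None = None
    depth: float = 20.0
    n_molecules: int | None = None  # overrides depth when set
    strands: tuple = ("+", "-")
    motif_efficiency: float = 0.85
    state_densities: tuple = (0.05, 0.5, 0.95)
    state_weights: tuple = (1 / 3, 1 / 3, 1 / 3)
    state_bin_width: int = 50
    state_mod_prob: float = 1.0  # adenines of a planted methylated bin
    window_size: int = 50
    window_pairs: tuple = ()
    p_shared: float = 0.9
    p_window_on: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValidationError(f"mode must be one of {MODES}, got {self.mode!r}")
        comp = np.asarray(self.base_composition, dtype=float)
        if len(comp) != 4 or np.any(comp < 0) or abs(comp.sum() - 1) > 1e-9:
            raise ValidationError("base_composition must be 4 non-negative values summing to 1")
        for name in ("p_fg", "p_bg", "motif_efficiency", "p_shared", "p_window_on",
                     "state_mod_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        fp = sorted(tuple(map(int, f)) for f in self.footprints)
        for (s, e) in fp:
            if not (0 <= s < e <= self.genome_length):
                raise ValidationError(f"footprint ({s}, {e}) outside [0, {self.genome_length})")
        for (s1, e1), (s2, e2) in zip(fp, fp[1:]):
            if s2 < e1:
                raise ValidationError("footprints must be non-overlapping")
        self.footprints = tuple(fp)
        if self.genome_length < 1:
            raise ValidationError("genome_length must be >= 1")
        dens = np.asarray(self.state_densities, dtype=float)
        if np.any(dens < 0) or np.any(dens > 1):
            raise ValidationError("state_densities must lie in [0, 1]")
        w = np.asarray(self.state_weights, dtype=float)
        if len(w) != len(dens) or np.any(w < 0) or abs(w.sum() - 1) > 1e-9:
            raise ValidationError("state_weights must match state_densities and sum to 1")


@dataclass
class Reference:
    """Simulated sequence plus adenine and GATC-motif position indexes."""

    sequence: str
    a_plus: np.ndarray  # A positions (adenines on the + strand)
    a_minus: np.ndarray  # T positions (adenines on the - strand)
    gatc_plus: np.ndarray  # motif adenines on + (GATC offset + 1)
    gatc_minus: np.ndarray  # motif adenines on - (GATC offset + 2)

    def adenines(self, strand: str) -> np.ndarray:
        return self.a_plus if strand == "+" else self.a_minus

    def motif_adenines(self, strand: str) -> np.ndarray:
        return self.gatc_plus if strand == "+" else self.gatc_minus


@dataclass
class TruthTable:
    """Ground truth for every emitted call plus per-mode latents."""

    calls: pd.DataFrame  # read_id, chrom, pos, strand, modified
    footprints: tuple = ()
    # state_mixture: read_id, start, end, n_bins, target_density, planted_density
    molecule_states: pd.DataFrame | None = None
    window_latents: pd.DataFrame | None = None  # correlated_windows mode


def simulate_reference(config: SimConfig) -> Reference:
    """Seeded random sequence with adenine and GATC indexes for both strands."""
    comp = np.asarray(config.base_composition, dtype=float)
    if comp[0] + comp[3] == 0:
        raise ValidationError("base composition has no A or T: nothing to label")
    rng = np.random.default_rng(config.seed)
    seq_arr = rng.choice(BASES, size=config.genome_length, p=comp)
    seq = "".join(seq_arr)
    a_plus = np.flatnonzero(seq_arr == "A")
    a_minus = np.flatnonzero(seq_arr == "T")
    motif_starts = np.array(
        [i for i in range(config.genome_length - 3) if seq[i : i + 4] == "GATC"],
        dtype=np.int64,
    )
    return Reference(
        sequence=seq,
        a_plus=a_plus,
        a_minus=a_minus,
        gatc_plus=motif_starts + 1,
        gatc_minus=motif_starts + 2,
    )


def _emission(rng, modified: np.ndarray, config: SimConfig) -> np.ndarray:
    if config.noiseless:
        return modified.astype(float)
    lo_m, lo_s = config.emission_low
    hi_m, hi_s = config.emission_high
    probs = np.where(
        modified,
        rng.normal(hi_m, hi_s, size=len(modified)),
        rng.normal(lo_m, lo_s, size=len(modified)),
    )
    return np.clip(probs, 0.0, 1.0)


def _footprint_truth(rng, pos, config):
    p = np.full(len(pos), config.p_bg)
    for s, e in config.footprints:
        p[(pos >= s) & (pos < e)] = config.p_fg
    return rng.random(len(pos)) < p


def _dam_truth(rng, pos, motif_pos, config):
    in_motif = np.isin(pos, motif_pos)
    modified = np.zeros(len(pos), dtype=bool)
    modified[in_motif] = rng.random(int(in_motif.sum())) < config.motif_efficiency
    return modified


def _state_truth(rng, pos, start, end, config):
    """Plant round(d * n_bins) methylated molecule-local bins."""
    width = config.state_bin_width
    n_bins = int(np.ceil((end - start) / width))
    d = float(rng.choice(config.state_densities, p=config.state_weights))
    n_meth = int(round(d * n_bins))
    meth_bins = rng.choice(n_bins, size=n_meth, replace=False) if n_meth else np.array([], int)
    in_meth = np.isin((pos - start) // width, meth_bins)
    p = np.where(in_meth, config.state_mod_prob, config.p_bg)
    modified = rng.random(len(pos)) < p
    planted = n_meth / n_bins if n_bins else float("nan")
    return modified, d, planted, n_bins


def _correlated_truth(rng, pos, config):
    """Window on/off latents with shared pairs; returns per-call truth + latents."""
    w = config.window_size
    n_win = int(np.ceil(config.genome_length / w))
    on = rng.random(n_win) < config.p_window_on
    latents = []
    for idx, (i, j) in enumerate(config.window_pairs):
        if rng.random() < config.p_shared:
            on[j] = on[i]
        # else window j keeps its independent draw
        latents.append((idx, int(i), int(j), bool(on[i]), bool(on[j])))
    p = np.where(on[pos // w], config.p_fg, config.p_bg)
    modified = rng.random(len(pos)) < p
    return modified, latents


def simulate_molecules(config: SimConfig, reference: Reference | None = None):
    """Generate molecules plus their :class:`TruthTable`.

    Molecules get seeded random strands, start positions and log-normal
    lengths (median ``read_length_mean``); each covered adenine of the
    molecule's strand becomes one call. The number of molecules is
    ``n_molecules`` if set, else ``depth * genome_length /
    read_length_mean``.
    """
    if reference is None:
        reference = simulate_reference(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    if config.n_molecules is not None:
        n_mol = int(config.n_molecules)
    else:
        n_mol = int(round(config.depth * config.genome_length / config.read_length_mean))
    if n_mol == 0:
        warnings.warn("zero molecules requested; empty simulation", DataQualityWarning,
                      stacklevel=2)
        return [], TruthTable(calls=_empty_calls(), footprints=config.footprints)

    molecules: list[Molecule] = []
    truth_chunks = []
    state_rows = []
    latent_rows = []
    for k in range(n_mol):
        strand = str(rng.choice(np.asarray(config.strands)))
        if config.fixed_read_length is not None:
            length = int(config.fixed_read_length)
        else:
            length = int(round(rng.lognormal(np.log(config.read_length_mean),
                                             config.read_length_sigma)))
        length = int(np.clip(length, 1, config.genome_length))
        start = int(rng.integers(0, config.genome_length - length + 1))
        end = start + length
        adenines = reference.adenines(strand)
        lo, hi = np.searchsorted(adenines, [start, end])
        pos = adenines[lo:hi]
        if len(pos) == 0:
            continue
        read_id = f"read_{k:06d}"

        if config.mode == "footprint":
            modified = _footprint_truth(rng, pos, config)
        elif config.mode == "dam_motif":
            modified = _dam_truth(rng, pos, reference.motif_adenines(strand), config)
        elif config.mode == "state_mixture":
            modified, target_d, planted_d, n_bins = _state_truth(rng, pos, start, end, config)
            state_rows.append((read_id, start, end, n_bins, target_d, planted_d))
        else:  # correlated_windows
            modified, latents = _correlated_truth(rng, pos, config)
            latent_rows.extend((read_id, *lat) for lat in latents)

        probs = _emission(rng, modified, config)
        molecules.append(
            Molecule(
                read_id=read_id,
                chrom=config.chrom,
                pos=pos,
                strand=np.full(len(pos), strand, dtype="U1"),
                prob=probs,
            )
        )
        truth_chunks.append(
            pd.DataFrame(
                {
                    "read_id": read_id,
                    "chrom": config.chrom,
                    "pos": pos,
                    "strand": strand,
                    "modified": modified,
                }
            )
        )

    calls = pd.concat(truth_chunks, ignore_index=True) if truth_chunks else _empty_calls()
    truth = TruthTable(calls=calls, footprints=config.footprints)
    if state_rows:
        truth.molecule_states = pd.DataFrame(
            state_rows,
            columns=["read_id", "start", "end", "n_bins", "target_density", "planted_density"],
        )
    if latent_rows:
        truth.window_latents = pd.DataFrame(
            latent_rows, columns=["read_id", "pair_index", "i", "j", "on_i", "on_j"]
        )
    return molecules, truth


def _empty_calls() -> pd.DataFrame:
    return pd.DataFrame(columns=["read_id", "chrom", "pos", "strand", "modified"])


def write_calls(molecules, path) -> None:
    """Write simulated calls in the per-read call TSV dialect."""
    write_modcall_table(molecules, path)


def write_truth(truth: TruthTable, path) -> None:
    """Write the per-call truth sidecar TSV keyed by (read_id, pos, strand)."""
    truth.calls.to_csv(path, sep="\t", index=False)


def load_config(path) -> SimConfig:
    """Load a SimConfig from a flat key: value YAML document."""
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    for key in ("base_composition", "footprints", "strands", "state_densities",
                "state_weights", "window_pairs", "emission_low", "emission_high"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(
                tuple(v) if isinstance(v, list) else v for v in data[key]
            )
    return SimConfig(**data)


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """A copy of the config with a different seed (all else identical)."""
    return replace(config, seed=seed)


__all__ = [
    "SimConfig",
    "Reference",
    "TruthTable",
    "simulate_reference",
    "simulate_molecules",
    "write_calls",
    "write_truth",
    "load_config",
    "with_seed",
]
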