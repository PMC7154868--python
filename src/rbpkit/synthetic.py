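"""Synthetic inputs for the whole pipeline.

Generates random RNA read pools, concentration-dependent pulldown libraries
under an explicit saturating (Langmuir) binding model, two-channel array
signal tables with planted enrichment, and paired pellet/supernatant blot
tables — all seeded and fully reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .sequtils import decode_matrix, encode_matrix, normalize_rna, rolling_kmer_codes

logger = logging.getLogger(__name__)

#: concentration (nM) at which c * affinity = affinity in the Langmuir weight
REFERENCE_CONCENTRATION_NM = 100.0


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class BindingModel:
    """K-mer affinity table plus a background affinity for motif-free reads.

    Affinities are dimensionless and relative; reads containing several motif
    occurrences combine them with ``combine_rule`` ("max" or "sum").
    """

    motif_affinities: dict[str, float]
    background_affinity: float = 1.0
    combine_rule: str = "max"

    def __post_init__(self) -> None:
        if not self.motif_affinities:
            raise ConfigurationError("motif_affinities must be non-empty")
        if self.combine_rule not in ("max", "sum"):
            raise ConfigurationError(f"unknown combine_rule {self.combine_rule!r}")
        normalized = {normalize_rna(k): float(a) for k, a in self.motif_affinities.items()}
        object.__setattr__(self, "motif_affinities", normalized)
        lengths = {len(k) for k in normalized}
        if len(lengths) != 1:
            raise ConfigurationError(f"motif k-mers must share one length, got {sorted(lengths)}")
        if any(a <= 0 for a in normalized.values()) or self.background_affinity <= 0:
            raise ConfigurationError("all affinities must be strictly positive")
        if self.background_affinity > min(normalized.values()):
            raise ConfigurationError("background_affinity must not exceed the smallest motif affinity")

    @property
    def k(self) -> int:
        return len(next(iter(self.motif_affinities)))

    def _delta_lookup(self) -> np.ndarray:
        """Affinity excess over background per k-mer index (0 for non-motif)."""
        from .sequtils import kmer_to_index

        delta = np.zeros(4**self.k)
        for kmer, aff in self.motif_affinities.items():
            delta[kmer_to_index(kmer)] = aff
        return delta

    def read_affinities(self, codes: np.ndarray) -> np.ndarray:
        """Combined affinity of each read in an (n, L) code matrix."""
        lookup = self._delta_lookup()
        windows = lookup[rolling_kmer_codes(codes, self.k)]
        if self.combine_rule == "max":
            combined = windows.max(axis=1)
        else:
            combined = windows.sum(axis=1)
        return np.where(combined > 0, combined, self.background_affinity)

    def read_affinity(self, read: str) -> float:
        codes = encode_matrix([normalize_rna(read)])
        return float(self.read_affinities(codes)[0])


def graded_binding_model(
    kmer: str,
    top_affinity: float = 1.0,
    min_affinity: float = 0.02,
    background_affinity: float = 0.01,
    n_variants: int = 60,
    max_mismatches: int = 2,
) -> BindingModel:
    """A binding model with a graded affinity spectrum around one k-mer.

    The planted k-mer gets ``top_affinity``; its nearest mismatch variants
    (lexicographic order, up to ``n_variants`` total) get geometrically
    decreasing affinities down to ``min_affinity``. A graded spectrum is
    what makes k-mer rankings comparable across protein concentrations:
    with a single high-affinity k-mer the remaining top ranks are pure
    sampling noise.
    """
    from .genome import kmer_derivatives

    kmer = normalize_rna(kmer)
    variants = [kmer] + [v for v in kmer_derivatives(kmer, max_mismatches) if v != kmer]
    if len(variants) < n_variants:
        raise ConfigurationError(
            f"only {len(variants)} variants within {max_mismatches} mismatches; "
            f"cannot grade {n_variants} affinities"
        )
    affinities = np.geomspace(top_affinity, min_affinity, n_variants)
    return BindingModel(
        motif_affinities={v: float(a) for v, a in zip(variants[:n_variants], affinities)},
        background_affinity=background_affinity,
    )


@dataclass(frozen=True)
class SelectionConfig:
    protein_concentrations: tuple[float, ...] = (0.0, 100.0, 1000.0)
    rna_concentration: float = 0.5  # µM; recorded for provenance
    read_length: int = 40
    n_input_reads: int = 100_000
    n_pulldown_reads: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "protein_concentrations", tuple(float(c) for c in self.protein_concentrations))
        if self.read_length <= 0 or self.n_input_reads <= 0 or self.n_pulldown_reads <= 0:
            raise ConfigurationError("read_length and read counts must be positive")
        if any(c < 0 for c in self.protein_concentrations):
            raise ConfigurationError("protein concentrations must be non-negative")
        if 0.0 not in self.protein_concentrations:
            raise ConfigurationError("the zero-protein control concentration is required")

    def validate_model(self, model: BindingModel) -> None:
        if model.k > self.read_length:
            raise ConfigurationError(
                f"read_length {self.read_length} shorter than motif length {model.k}"
            )


@dataclass
class ReadPool:
    """An ordered pool of equal-length RNA reads, stored as a code matrix."""

    label: str
    codes: np.ndarray
    provenance: SelectionConfig | None = None
    _reads: list[str] | None = field(default=None, repr=False)

    @classmethod
    def from_strings(cls, label: str, reads: list[str], provenance: SelectionConfig | None = None) -> "ReadPool":
        if not reads:
            raise ValueError("read pool must be non-empty")
        normalized = [normalize_rna(r) for r in reads]
        lengths = {len(r) for r in normalized}
        if len(lengths) != 1:
            raise ValueError(f"reads must share one length, got {sorted(lengths)}")
        return cls(label=label, codes=encode_matrix(normalized), provenance=provenance)

    @property
    def reads(self) -> list[str]:
        if self._reads is None:
            self._reads = decode_matrix(self.codes, rna=True)
        return self._reads

    @property
    def read_length(self) -> int:
        return int(self.codes.shape[1])

    def __len__(self) -> int:
        return int(self.codes.shape[0])


def generate_input_pool(config: SelectionConfig) -> ReadPool:
    """Uniform i.i.d. random RNA reads (the unselected input pool)."""
    rng = np.random.default_rng(config.seed)
    codes = rng.integers(0, 4, size=(config.n_input_reads, config.read_length), dtype=np.uint8)
    return ReadPool(label="input", codes=codes, provenance=config)


def read_binding_probability(read: str, model: BindingModel, conc: float) -> float:
    """Langmuir occupancy of one read: p = x / (1 + x), x = (conc/100 nM) * affinity."""
    if conc < 0:
        raise ValueError("concentration must be >= 0")
    if conc == 0:
        return 0.0
    x = (conc / REFERENCE_CONCENTRATION_NM) * model.read_affinity(read)
    return x / (1.0 + x)


def _binding_probabilities(codes: np.ndarray, model: BindingModel, conc: float) -> np.ndarray:
    if conc == 0:
        return np.zeros(codes.shape[0])
    x = (conc / REFERENCE_CONCENTRATION_NM) * model.read_affinities(codes)
    return x / (1.0 + x)


def simulate_selection(
    input_pool: ReadPool,
    model: BindingModel,
    conc: float,
    n_out: int,
    seed: int,
) -> ReadPool:
    """Sample a pulldown library from the input pool.

    Reads are drawn with replacement, weighted by their binding probability.
    At zero protein every read has weight 0, which is interpreted as uniform
    nonspecific background carryover.
    """
    if len(input_pool) == 0:
        raise ValueError("input pool is empty")
    if n_out <= 0:
        raise ConfigurationError("n_out must be positive")
    rng = np.random.default_rng(seed)
    n = len(input_pool)
    if conc == 0:
        idx = rng.integers(0, n, size=n_out)
    else:
        weights = _binding_probabilities(input_pool.codes, model, conc)
        total = weights.sum()
        if total <= 0:
            raise RuntimeError("all selection weights are zero; cannot sample pulldown")
        idx = rng.choice(n, size=n_out, replace=True, p=weights / total)
    label = f"{conc:g}nM"
    return ReadPool(label=label, codes=input_pool.codes[idx], provenance=input_pool.provenance)


def run_rbns(config: SelectionConfig, model: BindingModel) -> dict[str, ReadPool]:
    """Generate the input pool and one pulldown per configured concentration."""
    config.validate_model(model)
    pools = {"input": generate_input_pool(config)}
    for i, conc in enumerate(config.protein_concentrations):
        pool = simulate_selection(
            pools["input"], model, conc, config.n_pulldown_reads, seed=config.seed + 1 + i
        )
        pools[pool.label] = pool
    return pools


# ---------------------------------------------------------------------------
# FASTQ / FASTA I/O (RNA dialect by default; --dna maps U<->T)
# ---------------------------------------------------------------------------

def _records(pool: ReadPool, dna: bool) -> list[SeqRecord]:
    reads = decode_matrix(pool.codes, rna=not dna)
    out = []
    for i, seq in enumerate(reads):
        rec = SeqRecord(Seq(seq), id=f"read_{i}", description="")
        rec.letter_annotations["phred_quality"] = [40] * len(seq)
        out.append(rec)
    return out


def write_fastq(pool: ReadPool, path, dna: bool = False) -> None:
    SeqIO.write(_records(pool, dna), str(path), "fastq")


def write_fasta(pool: ReadPool, path, dna: bool = False) -> None:
    SeqIO.write(_records(pool, dna), str(path), "fasta")


def read_pool(path, fmt: str | None = None, label: str | None = None) -> ReadPool:
    """Read a FASTQ/FASTA file back into a ReadPool (T mapped to U)."""
    path = Path(path)
    if fmt is None:
        fmt = "fastq" if path.suffix.lower() in (".fastq", ".fq") else "fasta"
    reads = [str(rec.seq) for rec in SeqIO.parse(str(path), fmt)]
    if not reads:
        raise ValueError(f"no reads in {path}")
    return ReadPool.from_strings(label if label is not None else path.stem, reads)


# ---------------------------------------------------------------------------
# Array and blot signal tables
# ---------------------------------------------------------------------------

ARRAY_COLUMNS = ["probe_id", "start", "end", "feature", "is_rrna", "replicate", "F635", "F532"]
BLOT_COLUMNS = ["target", "genotype", "fraction_label", "signal", "volume_fraction"]


def simulate_array_table(
    genome_length: int,
    probes: list[tuple[str, int, int, str, bool]],
    planted_regions: list[tuple[int, int]],
    enrichment_factors: list[float],
    n_replicates: int = 3,
    noise_sd: float = 0.2,
    seed: int = 0,
    baseline_log_mean: float = np.log(1000.0),
    baseline_log_sd: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-channel array tables for a wt IP and a matched control IP.

    probes: (probe_id, start, end, feature, is_rrna) tiles of the genome.
    A probe overlapping a planted region gets that region's enrichment
    factor on F635 in the wt table; the control table has all factors 1.
    Returns (wt_table, control_table).
    """
    if len(planted_regions) != len(enrichment_factors):
        raise ValueError("planted_regions and enrichment_factors must be parallel")
    if any(f < 1 for f in enrichment_factors):
        raise ValueError("enrichment factors must be >= 1")
    rng = np.random.default_rng(seed)
    factor_of = {}
    for probe_id, start, end, _feature, _is_rrna in probes:
        if not (0 <= start < end <= genome_length):
            raise ValueError(f"probe {probe_id} [{start},{end}) outside genome [0,{genome_length})")
        factor = 1.0
        for (rs, re), f in zip(planted_regions, enrichment_factors):
            if start < re and rs < end:
                factor = max(factor, f)
        factor_of[probe_id] = factor

    def _one(genotype_factors: dict[str, float]) -> pd.DataFrame:
        rows = []
        for probe_id, start, end, feature, is_rrna in probes:
            for rep in range(1, n_replicates + 1):
                f532 = rng.lognormal(baseline_log_mean, baseline_log_sd)
                noise = rng.lognormal(0.0, noise_sd) if noise_sd > 0 else 1.0
                f635 = f532 * genotype_factors[probe_id] * noise
                rows.append((probe_id, start, end, feature, is_rrna, rep, f635, f532))
        return pd.DataFrame(rows, columns=ARRAY_COLUMNS)

    wt = _one(factor_of)
    control = _one({p: 1.0 for p in factor_of})
    return wt, control


def simulate_blot_table(
    targets: list[str],
    true_bound_fractions: list[float],
    total_signals: list[float],
    background: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired pellet/supernatant dot-blot signals with a null-mutant control.

    Per target, wt pellet = total * fraction and wt supernatant =
    total * (1 - fraction); control rows are generated with fraction 0.
    ``background`` is the scale of additive exponential background noise.
    """
    if not (len(targets) == len(true_bound_fractions) == len(total_signals)):
        raise ValueError("targets, fractions and totals must be parallel")
    if any(not 0 <= f <= 1 for f in true_bound_fractions):
        raise ValueError("bound fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    def _noise() -> float:
        return float(rng.exponential(background)) if background > 0 else 0.0

    rows = []
    for target, frac, total in zip(targets, true_bound_fractions, total_signals):
        for genotype, f in (("wt", frac), ("control", 0.0)):
            rows.append((target, genotype, "P", total * f + _noise(), 1.0))
            rows.append((target, genotype, "S", total * (1.0 - f) + _noise(), 1.0))
    return pd.DataFrame(rows, columns=BLOT_COLUMNS)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Config file (YAML/JSON via yaml superset)
# ---------------------------------------------------------------------------

def load_config(path) -> tuple[SelectionConfig, BindingModel]:
    """Load a simulation config holding a SelectionConfig and a BindingModel."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    try:
        model = BindingModel(**data["binding_model"])
        config = SelectionConfig(**{
            **data.get("selection", {}),
            "protein_concentrations": tuple(
                data.get("selection", {}).get("protein_concentrations", (0.0, 100.0, 1000.0))
            ),
        })
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"invalid simulation config {path}: {exc}") from exc
    config.validate_model(model)
    return config, model
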