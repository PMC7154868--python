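"""Consensus motif assembly from significant k-mers.

The top-enrichment k-mer seeds the alignment; every further significant
k-mer is shifted against the seed within a small offset window, kept if it
overlaps enough with few mismatches, and contributes its excess enrichment
(R - 1) as weight to a position frequency matrix.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sequtils import RNA_ALPHABET, normalize_rna

logger = logging.getLogger(__name__)

DEFAULT_MAX_OFFSET = 2
DEFAULT_MISMATCH_MAX = 1
DEFAULT_TRIM_FRACTION = 0.75

WEIGHTING_CHOICES = ("excess", "ratio", "uniform")


@dataclass
class AlignedKmer:
    kmer: str
    offset: int
    weight: float
    mismatches: int
    accepted: bool


@dataclass
class PositionFrequencyMatrix:
    """Column-stochastic motif model; columns ordered 5'->3', rows A,C,G,U."""

    matrix: np.ndarray  # (n_columns, 4)
    support: np.ndarray  # total weight per column before normalization

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.support = np.asarray(self.support, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4 or self.matrix.shape[0] < 1:
            raise ValueError("matrix must be (n_columns >= 1, 4)")
        sums = self.matrix.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("every column must sum to 1")

    def __len__(self) -> int:
        return int(self.matrix.shape[0])

    @classmethod
    def from_kmer(cls, kmer: str) -> "PositionFrequencyMatrix":
        kmer = normalize_rna(kmer)
        mat = np.zeros((len(kmer), 4))
        for i, base in enumerate(kmer):
            mat[i, RNA_ALPHABET.index(base)] = 1.0
        return cls(matrix=mat, support=np.ones(len(kmer)))


def _align_to_seed(seed: str, kmer: str, max_offset: int) -> tuple[int, int, int]:
    """Best offset of ``kmer`` against ``seed``: returns (offset, overlap, mismatches).

    Maximizes matching overlap positions; ties prefer small |offset|, then
    the more negative offset. Deterministic.
    """
    k = len(seed)
    best = None
    for offset in sorted(range(-max_offset, max_offset + 1), key=lambda o: (abs(o), o)):
        lo = max(0, offset)
        hi = min(k, k + offset)
        overlap = hi - lo
        if overlap <= 0:
            continue
        matches = sum(1 for j in range(lo, hi) if seed[j] == kmer[j - offset])
        if best is None or matches > best[0]:
            best = (matches, offset, overlap)
    matches, offset, overlap = best
    return offset, overlap, overlap - matches


def assemble_motif(
    significant: list[tuple[str, float]],
    max_offset: int = DEFAULT_MAX_OFFSET,
    mismatch_max: int = DEFAULT_MISMATCH_MAX,
    min_overlap: int | None = None,
    weighting: str = "excess",
    trim_fraction: float = DEFAULT_TRIM_FRACTION,
) -> tuple[PositionFrequencyMatrix, list[AlignedKmer]]:
    """Build a PFM from (kmer, R) pairs ordered by R descending.

    The first entry after deterministic re-sorting (R descending, ties
    lexicographic) seeds the alignment at offset 0. ``weighting`` selects
    the per-k-mer weight: "excess" (R - 1, the default), "ratio" (R) or
    "uniform" (1). The seed-spanning columns are always kept; flanking
    columns are trimmed unless their support reaches ``trim_fraction`` of
    the maximum column support.
    """
    if not significant:
        raise ValueError("no significant k-mers to assemble")
    if weighting not in WEIGHTING_CHOICES:
        raise ValueError(f"weighting must be one of {WEIGHTING_CHOICES}")
    entries = sorted(
        ((normalize_rna(km), float(r)) for km, r in significant),
        key=lambda e: (-e[1], e[0]),
    )
    if any(r <= 1.0 for _, r in entries):
        raise ValueError("all significant k-mers must have R > 1")
    k = len(entries[0][0])
    if any(len(km) != k for km, _ in entries):
        raise ValueError("all k-mers must share one length")
    if min_overlap is None:
        min_overlap = k - 2

    def _weight(r: float) -> float:
        return {"excess": r - 1.0, "ratio": r, "uniform": 1.0}[weighting]

    seed = entries[0][0]
    # coordinate system: seed occupies columns max_offset .. max_offset + k - 1
    width = k + 2 * max_offset
    counts = np.zeros((width, 4))
    aligned: list[AlignedKmer] = []

    for i, (kmer, r) in enumerate(entries):
        if i == 0:
            offset, mismatches, accepted = 0, 0, True
        else:
            offset, overlap, mismatches = _align_to_seed(seed, kmer, max_offset)
            accepted = overlap >= min_overlap and mismatches <= mismatch_max
        w = _weight(r)
        aligned.append(AlignedKmer(kmer, offset, w, mismatches, accepted))
        if accepted:
            for j, base in enumerate(kmer):
                counts[max_offset + offset + j, RNA_ALPHABET.index(base)] += w

    n_accepted = sum(a.accepted for a in aligned)
    if n_accepted == 1 and len(aligned) > 1:
        logger.warning("assemble_motif: all %d non-seed k-mers discarded; matrix is the seed profile", len(aligned) - 1)

    support = counts.sum(axis=1)
    threshold = trim_fraction * support.max()
    keep = (support >= threshold) & (support > 0)
    # the seed anchors the motif: its columns are never trimmed, flanking
    # columns must clear the support threshold
    keep[max_offset : max_offset + k] = True
    lo = int(np.argmax(keep))
    hi = width - int(np.argmax(keep[::-1]))
    counts, support = counts[lo:hi], support[lo:hi]
    matrix = counts / support[:, None]
    return PositionFrequencyMatrix(matrix=matrix, support=support), aligned


def consensus_string(pfm: PositionFrequencyMatrix) -> str:
    """Per-column argmax base; ties resolve alphabetically (A < C < G < U)."""
    return "".join(RNA_ALPHABET[i] for i in np.argmax(pfm.matrix, axis=1))


def aligned_to_frame(aligned: list[AlignedKmer]) -> pd.DataFrame:
    return pd.DataFrame(
        [(a.kmer, a.offset, a.weight, a.mismatches, a.accepted) for a in aligned],
        columns=["kmer", "offset", "weight", "mismatches", "accepted"],
    )


# ---------------------------------------------------------------------------
# MEME minimal format
# ---------------------------------------------------------------------------

def write_meme(pfm: PositionFrequencyMatrix, path, name: str | None = None) -> None:
    """Write a MEME minimal motif file with an ACGU alphabet."""
    if name is None:
        name = consensus_string(pfm)
    lines = [
        "MEME version 4",
        "",
        "ALPHABET= ACGU",
        "",
        "Background letter frequencies",
        "A 0.25 C 0.25 G 0.25 U 0.25",
        "",
        f"MOTIF {name}",
        f"letter-probability matrix: alength= 4 w= {len(pfm)} nsites= 1 E= 0",
    ]
    for row in pfm.matrix:
        lines.append(" " + " ".join(f"{v:.6f}" for v in row))
    lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def read_meme(path) -> tuple[str, PositionFrequencyMatrix]:
    """Parse the first motif of a MEME minimal file written by write_meme."""
    with open(path) as fh:
        text = fh.read()
    m = re.search(r"^MOTIF\s+(\S+)", text, re.MULTILINE)
    if m is None:
        raise ValueError(f"no MOTIF block in {path}")
    name = m.group(1)
    header = re.search(r"letter-probability matrix:[^\n]*w=\s*(\d+)[^\n]*\n", text)
    if header is None:
        raise ValueError(f"no letter-probability matrix in {path}")
    width = int(header.group(1))
    rows = []
    for line in text[header.end():].splitlines():
        line = line.strip()
        if not line:
            if len(rows) >= width:
                break
            continue
        rows.append([float(v) for v in line.split()])
        if len(rows) == width:
            break
    matrix = np.array(rows)
    if matrix.shape != (width, 4):
        raise ValueError(f"matrix shape {matrix.shape} does not match declared width {width}")
    return name, PositionFrequencyMatrix(matrix=matrix, support=matrix.sum(axis=1))
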