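"""K-mer counting and enrichment statistics for selected vs. input read libraries.

The central quantity is the per-k-mer enrichment R: the frequency of the
k-mer among all overlapping windows of a selected (pulldown) library divided
by its frequency in the matched input library. R values are standardized to
z-scores across all 4**k k-mers of one library pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
from scipy import stats

from .sequtils import all_kmers, encode_matrix, kmer_to_index, rolling_kmer_codes

if TYPE_CHECKING:
    from .synthetic import ReadPool

logger = logging.getLogger(__name__)

DEFAULT_KS = (6, 7, 8, 9)
DEFAULT_PSEUDOCOUNT = 1.0
DEFAULT_ZMIN = 3.0


class DegenerateDistributionError(ValueError):
    """All R values identical; z-scores are undefined."""


@dataclass
class KmerCountTable:
    """Counts of all 4**k k-mers in one read library.

    ``counts`` is indexed by the lexicographic ACGU rank of the k-mer
    (see :func:`rbpkit.sequtils.kmer_to_index`); zeros are kept so the
    table always covers the full k-mer space.
    """

    k: int
    counts: np.ndarray
    total_positions: int
    library_label: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.counts.shape != (4**self.k,):
            raise ValueError(f"counts must have length 4**{self.k}")
        if int(self.counts.sum()) != self.total_positions:
            raise ValueError("counts do not sum to total_positions")

    def __getitem__(self, kmer: str) -> int:
        return int(self.counts[kmer_to_index(kmer)])

    def frequencies(self, pseudocount: float = 0.0) -> np.ndarray:
        denom = self.total_positions + pseudocount * len(self.counts)
        return (self.counts + pseudocount) / denom

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"kmer": all_kmers(self.k), "count": self.counts})


@dataclass
class EnrichmentTable:
    """Per-k-mer R values (and optionally z-scores) for one sample/input pair."""

    k: int
    counts_sample: np.ndarray
    counts_input: np.ndarray
    f_sample: np.ndarray
    f_input: np.ndarray
    R: np.ndarray
    sample_label: str = ""
    input_label: str = ""
    pseudocount: float = 0.0
    z: np.ndarray | None = None
    finite_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.finite_mask is None:
            self.finite_mask = np.isfinite(self.R)

    @property
    def kmers(self) -> list[str]:
        return all_kmers(self.k)

    def value(self, kmer: str, column: str = "R") -> float:
        arr = getattr(self, column)
        if arr is None:
            raise ValueError(f"column {column!r} not computed")
        return float(arr[kmer_to_index(kmer)])

    def to_frame(self, sort: bool = True) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "kmer": self.kmers,
                "count_sample": self.counts_sample,
                "count_input": self.counts_input,
                "f_sample": self.f_sample,
                "f_input": self.f_input,
                "R": self.R,
            }
        )
        if self.z is not None:
            df["z"] = self.z
        if sort:
            df = df.sort_values(["R", "kmer"], ascending=[False, True], kind="mergesort")
            df = df.reset_index(drop=True)
        return df


def _codes_of(pool: "ReadPool | list[str]") -> np.ndarray | list[str]:
    codes = getattr(pool, "codes", None)
    if codes is not None:
        return codes
    reads = getattr(pool, "reads", pool)
    return list(reads)


def count_kmers(pool: "ReadPool | list[str]", k: int, label: str | None = None) -> KmerCountTable:
    """Count every overlapping k-mer occurrence, read by read.

    Reads shorter than k are skipped with a logged warning; reads are never
    concatenated, so no window spans a read boundary.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    source = _codes_of(pool)
    if label is None:
        label = getattr(pool, "label", "")
    counts = np.zeros(4**k, dtype=np.int64)
    if isinstance(source, np.ndarray):
        if source.shape[1] < k:
            raise ValueError(f"all reads shorter than k={k}")
        windows = rolling_kmer_codes(source, k)
        counts += np.bincount(windows.ravel(), minlength=4**k)
    else:
        by_length: dict[int, list[str]] = {}
        skipped = 0
        for read in source:
            if len(read) < k:
                skipped += 1
                continue
            by_length.setdefault(len(read), []).append(read)
        if skipped:
            logger.warning("count_kmers: skipped %d reads shorter than k=%d", skipped, k)
        if not by_length:
            raise ValueError(f"no reads of length >= k={k}")
        for length, reads in by_length.items():
            windows = rolling_kmer_codes(encode_matrix(reads, length), k)
            counts += np.bincount(windows.ravel(), minlength=4**k)
    return KmerCountTable(k=k, counts=counts, total_positions=int(counts.sum()), library_label=label)


def compute_enrichment(
    sample: KmerCountTable,
    input_table: KmerCountTable,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> EnrichmentTable:
    """R = f_sample / f_input with a symmetric per-cell pseudocount.

    With pseudocount 0, k-mers absent from the input get a non-finite R and
    are excluded from downstream z computation via ``finite_mask``.
    """
    if sample.k != input_table.k:
        raise ValueError(f"k mismatch: sample k={sample.k}, input k={input_table.k}")
    if sample.total_positions <= 0 or input_table.total_positions <= 0:
        raise ValueError("both libraries must contain at least one k-mer position")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    f_sample = sample.frequencies(pseudocount)
    f_input = input_table.frequencies(pseudocount)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = f_sample / f_input
    n_bad = int((~np.isfinite(r)).sum())
    if n_bad:
        logger.warning(
            "compute_enrichment: %d k-mers with zero input count and pseudocount 0; "
            "R flagged non-finite and excluded from z-scores",
            n_bad,
        )
    return EnrichmentTable(
        k=sample.k,
        counts_sample=sample.counts,
        counts_input=input_table.counts,
        f_sample=f_sample,
        f_input=f_input,
        R=r,
        sample_label=sample.library_label,
        input_label=input_table.library_label,
        pseudocount=pseudocount,
    )


def compute_zscores(table: EnrichmentTable, log_space: bool = False) -> EnrichmentTable:
    """Standardize R over all finite k-mers: z = (R - mean) / population sd.

    ``log_space`` standardizes log(R) instead; the default works on raw R.
    """
    mask = table.finite_mask
    values = table.R[mask]
    if log_space:
        values = np.log(values)
    if values.size < 2:
        raise ValueError("need at least 2 finite R values to compute z-scores")
    mean = values.mean()
    sd = values.std()  # population sd (ddof=0)
    if sd == 0:
        raise DegenerateDistributionError("all R values identical; z undefined")
    z = np.full_like(table.R, np.nan)
    z[mask] = (values - mean) / sd
    table.z = z
    return table


def select_significant(table: EnrichmentTable, z_min: float = DEFAULT_ZMIN) -> list[str]:
    """K-mers with z >= z_min, sorted by R descending, ties lexicographic."""
    if table.z is None:
        raise ValueError("z-scores not computed; call compute_zscores first")
    idx = np.flatnonzero(table.finite_mask & (table.z >= z_min))
    kmers = np.array(table.kmers, dtype=object)[idx]
    order = sorted(range(len(idx)), key=lambda i: (-table.R[idx[i]], kmers[i]))
    return [str(kmers[i]) for i in order]


def concentration_report(
    tables: dict[float, EnrichmentTable], top_n: int = 50
) -> dict:
    """Compare enrichment across protein concentrations.

    Reports the maximal R per concentration, the concentration achieving the
    overall maximum, and the Spearman rank correlation of the top-``top_n``
    k-mers (ranked in the lower concentration of each pair) between every
    pair of concentrations.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 concentrations to compare")
    ks = {t.k for t in tables.values()}
    if len(ks) != 1:
        raise ValueError(f"tables mix k values: {sorted(ks)}")
    concs = sorted(tables)
    max_r = {c: float(np.nanmax(tables[c].R)) for c in concs}
    best = max(max_r, key=lambda c: max_r[c])
    correlations = {}
    for i, lo in enumerate(concs):
        for hi in concs[i + 1 :]:
            r_lo, r_hi = tables[lo].R, tables[hi].R
            top = np.argsort(-r_lo, kind="stable")[:top_n]
            rho = stats.spearmanr(r_lo[top], r_hi[top]).statistic
            correlations[(lo, hi)] = float(rho)
    return {"max_R": max_r, "best_concentration": best, "spearman_top": correlations}


def enrichment_to_tsv(table: EnrichmentTable, path) -> None:
    table.to_frame(sort=True).to_csv(path, sep="\t", index=False, float_format="%.6g")
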