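"""Strand-aware motif scanning of genome sequences and per-feature hit counts.

Coordinates are 0-based half-open internally and in BED output; GFF3 input
(1-based inclusive) is converted on load. Circular sequences are scanned
across the origin via a junction pad of k - 1 bases, with wrapped hits
reported modulo the sequence length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations, product

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO

from .motif import PositionFrequencyMatrix
from .sequtils import DNA_ALPHABET, encode, normalize_dna, reverse_complement

logger = logging.getLogger(__name__)


@dataclass
class GenomeSequence:
    id: str
    sequence: str
    circular: bool = False

    def __post_init__(self) -> None:
        self.sequence = normalize_dna(self.sequence)
        if not self.sequence:
            raise ValueError("genome sequence must be non-empty")

    def __len__(self) -> int:
        return len(self.sequence)

    @classmethod
    def from_fasta(cls, path, circular: bool = False) -> list["GenomeSequence"]:
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no sequences in {path}")
        return [cls(id=r.id, sequence=str(r.seq), circular=circular) for r in records]


@dataclass(frozen=True)
class MotifHit:
    seq_id: str
    start: int  # 0-based inclusive, always in [0, genome length)
    end: int  # exclusive; < start only for circular wrap-around hits
    strand: str
    matched: str  # sequence read on the hit strand
    source_kmer: str  # query as provided (RNA dialect preserved)
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


@dataclass
class FeatureAnnotation:
    feature_id: str
    seq_id: str
    start: int  # 0-based half-open after load
    end: int
    strand: str
    type: str = "CDS"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"feature {self.feature_id}: start must be < end")
        if self.strand not in "+-":
            raise ValueError(f"feature {self.feature_id}: strand must be + or -")


def load_gff(path) -> list[FeatureAnnotation]:
    """Load GFF3 features, converting 1-based inclusive to 0-based half-open."""
    db = gffutils.create_db(str(path), dbfn=":memory:", keep_order=True, merge_strategy="create_unique")
    features = []
    for f in db.all_features():
        name = f.attributes.get("Name", f.attributes.get("ID", [f.id]))[0]
        features.append(
            FeatureAnnotation(
                feature_id=name,
                seq_id=f.seqid,
                start=f.start - 1,
                end=f.end,
                strand=f.strand,
                type=f.featuretype,
            )
        )
    return features


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, pos = [], haystack.find(needle)
    while pos != -1:
        hits.append(pos)
        pos = haystack.find(needle, pos + 1)  # overlapping hits allowed
    return hits


def scan_kmers(genome: GenomeSequence, queries: list[str]) -> list[MotifHit]:
    """Exact occurrences of each query on both strands.

    Plus-strand matches of the query and matches of its reverse complement
    (reported with strand "-") are both returned; ``matched`` always reads
    in the hit's own strand, so it equals the query up to the U/T dialect.
    """
    if not queries:
        raise ValueError("query set must be non-empty")
    dna_queries = [normalize_dna(q) for q in queries]
    lengths = {len(q) for q in dna_queries}
    if len(lengths) != 1:
        raise ValueError(f"queries must share one length, got {sorted(lengths)}")
    k = lengths.pop()
    n = len(genome)
    subject = genome.sequence + (genome.sequence[: k - 1] if genome.circular and k > 1 else "")
    hits = []
    for query, source in zip(dna_queries, queries):
        for strand, needle in (("+", query), ("-", reverse_complement(query))):
            for pos in _find_all(subject, needle):
                if pos >= n:  # duplicate of a wrapped start already covered
                    continue
                end = pos + k if pos + k <= n else (pos + k) % n
                hits.append(
                    MotifHit(
                        seq_id=genome.id,
                        start=pos,
                        end=end,
                        strand=strand,
                        matched=query,
                        source_kmer=source,
                    )
                )
    hits.sort(key=lambda h: (h.seq_id, h.start, h.strand))
    return hits


def kmer_derivatives(kmer: str, max_mismatches: int = 1) -> list[str]:
    """All sequences within ``max_mismatches`` substitutions of ``kmer``."""
    kmer_dna = normalize_dna(kmer)
    rna = "U" in kmer.upper()
    out = {kmer_dna}
    for m in range(1, max_mismatches + 1):
        for positions in combinations(range(len(kmer_dna)), m):
            for subs in product(DNA_ALPHABET, repeat=m):
                if any(kmer_dna[p] == s for p, s in zip(positions, subs)):
                    continue
                var = list(kmer_dna)
                for p, s in zip(positions, subs):
                    var[p] = s
                out.add("".join(var))
    variants = sorted(out)
    if rna:
        variants = [v.replace("T", "U") for v in variants]
    return variants


def hits_in_feature(
    hits: list[MotifHit], feature: FeatureAnnotation, sense_only: bool = False
) -> tuple[int, list[MotifHit]]:
    """Hits fully contained in the feature; sense_only keeps strand-matched hits."""
    subset = [
        h
        for h in hits
        if h.seq_id == feature.seq_id
        and h.end > h.start  # wrapped hits are never contained in a linear feature
        and h.start >= feature.start
        and h.end <= feature.end
        and (not sense_only or h.strand == feature.strand)
    ]
    return len(subset), subset


def scan_pfm(
    genome: GenomeSequence,
    pfm: PositionFrequencyMatrix,
    score_min: float,
    pseudocount: float = 0.0,
) -> list[MotifHit]:
    """Log-odds (bits, vs uniform background) PFM scan of both strands."""
    if pseudocount == 0.0 and (pfm.matrix == 0).any():
        raise ValueError("PFM contains zero frequencies; a pseudocount is required for scoring")
    probs = pfm.matrix + pseudocount
    probs /= probs.sum(axis=1, keepdims=True)
    logodds = np.log2(probs / 0.25)  # (w, 4), rows A,C,G,U == A,C,G,T codes
    w = len(pfm)
    n = len(genome)
    subject = genome.sequence + (genome.sequence[: w - 1] if genome.circular and w > 1 else "")
    codes = encode(subject)
    if codes.size < w:
        return []
    n_windows = codes.size - w + 1
    fwd = np.zeros(n_windows)
    rev = np.zeros(n_windows)
    logodds_rc = logodds[::-1, ::-1]  # score of the revcomp window
    for j in range(w):
        col = codes[j : j + n_windows]
        fwd += logodds[j][col]
        rev += logodds_rc[j][col]
    hits = []
    consensus = "".join(DNA_ALPHABET[i] for i in np.argmax(pfm.matrix, axis=1))
    for strand, scores in (("+", fwd), ("-", rev)):
        for pos in np.flatnonzero(scores >= score_min):
            pos = int(pos)
            if pos >= n:
                continue
            window = subject[pos : pos + w]
            hits.append(
                MotifHit(
                    seq_id=genome.id,
                    start=pos,
                    end=pos + w if pos + w <= n else (pos + w) % n,
                    strand=strand,
                    matched=window if strand == "+" else reverse_complement(window),
                    source_kmer=consensus,
                    score=float(scores[pos]),
                )
            )
    hits.sort(key=lambda h: (h.seq_id, h.start, h.strand))
    return hits


# ---------------------------------------------------------------------------
# BED6 I/O
# ---------------------------------------------------------------------------

def write_bed(hits: list[MotifHit], path) -> None:
    rows = [(h.seq_id, h.start, h.end, h.source_kmer, f"{h.score:g}", h.strand) for h in hits]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def read_bed(path) -> list[MotifHit]:
    df = pd.read_csv(path, sep="\t", header=None, names=["seq_id", "start", "end", "name", "score", "strand"])
    return [
        MotifHit(
            seq_id=str(r.seq_id),
            start=int(r.start),
            end=int(r.end),
            strand=str(r.strand),
            matched=str(r["name"]),
            source_kmer=str(r["name"]),
            score=float(r.score),
        )
        for _, r in df.iterrows()
    ]
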