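"""Pairwise local-alignment kernel: scores, bit scores, E-values, coverage.

This is the computational substrate shared by homolog search, greedy
clustering, and neighborhood homology grouping.  Alignments are optimal
Smith-Waterman local alignments with affine gaps under BLOSUM62 (gap open 11,
gap extend 1, the protein-BLAST defaults the field's identity/coverage
thresholds were calibrated against).  Raw scores are converted to bits with
fixed gapped Karlin-Altschul constants, and E-values use the bit-score closed
form  E = m * n * 2**(-bits), which is equivalent by definition of bits to
K * m * n * exp(-lambda * S).

Conventions that matter downstream (and are easy to get subtly wrong):

* percent identity is matches / alignment columns, counting gap columns —
  the protein-BLAST convention used by the 30%/50%/70%/90% gates;
* coverage of a sequence is the aligned span divided by its full length;
* residue ``X`` scores 0 against everything;
* alignment coordinates are 1-based inclusive residue positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices

from .datastore import ProteinSeq, VALID_RESIDUES

__all__ = [
    "AlignParams",
    "Hit",
    "local_align",
    "self_score",
    "score_ratio",
    "evalue",
    "KmerIndex",
    "batch_search",
    "HIT_COLUMNS",
]

# Gapped Karlin-Altschul parameters for BLOSUM62 with gap open 11 / extend 1.
_DEFAULT_LAMBDA = 0.267
_DEFAULT_K = 0.041


@dataclass(frozen=True)
class AlignParams:
    """Scoring scheme plus the statistical constants for E-values.

    ``gap_open``/``gap_extend`` follow the NCBI convention: a gap of length L
    costs ``gap_open + L * gap_extend``.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    lambda_: float = _DEFAULT_LAMBDA
    k: float = _DEFAULT_K

    def __post_init__(self) -> None:
        if self.lambda_ <= 0 or self.k <= 0:
            raise ValueError("Karlin-Altschul parameters must be positive")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")

    def bits(self, raw_score: float) -> float:
        """Convert a raw alignment score to bits."""
        return (self.lambda_ * raw_score - math.log(self.k)) / math.log(2.0)


@dataclass
class Hit:
    """One query->subject alignment with the quantities the filters consume."""

    query_id: str
    subject_id: str
    raw_score: float
    bit_score: float
    e_value: float
    pct_identity: float
    query_cov: float
    subject_cov: float
    qstart: int
    qend: int
    sstart: int
    send: int
    n_columns: int = 0
    n_mismatches: int = 0
    n_gaps: int = 0
    subject_genome_id: str | None = None
    rank: int = 0


HIT_COLUMNS = [
    "query_id", "subject_id", "pct_identity", "length", "mismatches", "gaps",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    "query_cov", "subject_cov",
]


@lru_cache(maxsize=8)
def _aligner(matrix_name: str, gap_open: float, gap_extend: float) -> PairwiseAligner:
    matrix = substitution_matrices.load(matrix_name).copy()
    if "X" in matrix.alphabet:  # X is ambiguity, not similarity signal
        i = matrix.alphabet.index("X")
        matrix[i, :] = 0.0
        matrix[:, i] = 0.0
    aligner = PairwiseAligner(mode="local", substitution_matrix=matrix,
                              open_gap_score=-(gap_open + gap_extend),
                              extend_gap_score=-gap_extend)
    return aligner


def _check_sequence(seq: str, label: str) -> None:
    bad = set(seq) - VALID_RESIDUES
    if bad:
        raise ValueError(f"{label}: residues outside 20 aa + X: {sorted(bad)}")
    if not seq:
        raise ValueError(f"{label}: empty sequence")


def raw_local_score(a: str, b: str, params: AlignParams = AlignParams()) -> float:
    """Optimal local alignment raw score (score only — no traceback)."""
    return _aligner(params.matrix_name, params.gap_open, params.gap_extend).score(a, b)


def local_align(
    a: ProteinSeq, b: ProteinSeq, params: AlignParams = AlignParams(),
    db_len: int | None = None,
) -> Hit | None:
    """Optimal Smith-Waterman local alignment of ``a`` (query) vs ``b``.

    Returns ``None`` when no positive-scoring local alignment exists.
    ``db_len`` is the effective database residue count used for the E-value;
    it defaults to the subject length (single-pair statistics).
    """
    _check_sequence(a.sequence, a.protein_id)
    _check_sequence(b.sequence, b.protein_id)
    aligner = _aligner(params.matrix_name, params.gap_open, params.gap_extend)
    raw = aligner.score(a.sequence, b.sequence)
    if raw <= 0:
        return None
    aln = aligner.align(a.sequence, b.sequence)[0]
    qblocks, sblocks = aln.aligned
    qstart, qend = int(qblocks[0][0]) + 1, int(qblocks[-1][1])
    sstart, send = int(sblocks[0][0]) + 1, int(sblocks[-1][1])
    counts = aln.counts()
    identities = counts.identities
    mismatches = counts.mismatches
    gaps = counts.internal_gaps
    columns = identities + mismatches + gaps
    bit = params.bits(raw)
    n = db_len if db_len is not None else b.length
    return Hit(
        query_id=a.protein_id, subject_id=b.protein_id,
        raw_score=raw, bit_score=bit,
        e_value=evalue(bit, a.length, n),
        pct_identity=100.0 * identities / columns,
        query_cov=100.0 * (qend - qstart + 1) / a.length,
        subject_cov=100.0 * (send - sstart + 1) / b.length,
        qstart=qstart, qend=qend, sstart=sstart, send=send,
        n_columns=columns, n_mismatches=mismatches, n_gaps=gaps,
    )


def self_score(a: ProteinSeq, params: AlignParams = AlignParams()) -> float:
    """Bit score of a protein aligned to itself (the maximum attainable)."""
    _check_sequence(a.sequence, a.protein_id)
    return params.bits(raw_local_score(a.sequence, a.sequence, params))


def score_ratio(hit_bit_score: float, query_self_score: float) -> float:
    """Bit score of a hit divided by the query's self-alignment bit score."""
    if query_self_score <= 0:
        raise ValueError("query self score must be positive")
    return hit_bit_score / query_self_score


def evalue(bit_score: float, query_len: int, db_len: int) -> float:
    """E = m * n * 2**(-bits); monotone decreasing in the bit score."""
    if query_len <= 0 or db_len <= 0:
        raise ValueError("sequence/database lengths must be positive")
    return float(query_len) * float(db_len) * 2.0 ** (-bit_score)


class KmerIndex:
    """Exact shared-word prefilter over a protein set.

    A subject is a candidate for a query if they share at least
    ``min_shared`` distinct k-mers.  With k=4 and one shared word (the
    defaults used for searching) recall on real homologs (>=70% identity) is
    effectively complete; clustering uses a stricter setting for speed, with
    ``verify_clusters`` as the correctness backstop.
    """

    def __init__(self, proteins: Mapping[str, ProteinSeq], k: int = 4):
        self.k = k
        self.proteins = dict(proteins)
        self._index: dict[str, list[str]] = {}
        for pid in sorted(self.proteins):
            seq = self.proteins[pid].sequence
            for word in {seq[i:i + k] for i in range(len(seq) - k + 1)}:
                self._index.setdefault(word, []).append(pid)

    def candidates(self, query_seq: str, min_shared: int = 1) -> list[str]:
        """Subject ids sharing >= ``min_shared`` distinct words with the query.

        Queries shorter than k fall back to the full protein set (exhaustive
        alignment) so short peptides never silently return nothing.
        """
        if len(query_seq) < self.k:
            return sorted(self.proteins)
        words = {query_seq[i:i + self.k] for i in range(len(query_seq) - self.k + 1)}
        counts: dict[str, int] = {}
        for w in words:
            for pid in self._index.get(w, ()):
                counts[pid] = counts.get(pid, 0) + 1
        return sorted(pid for pid, c in counts.items() if c >= min_shared)


def sort_hits(hits: list[Hit]) -> list[Hit]:
    """Deterministic hit order: bit desc, E asc, subject id, genome id."""
    hits = sorted(hits, key=lambda h: (-h.bit_score, h.e_value, h.subject_id,
                                       h.subject_genome_id or ""))
    for i, h in enumerate(hits, 1):
        h.rank = i
    return hits


def batch_search(
    query: ProteinSeq,
    index: KmerIndex,
    params: AlignParams = AlignParams(),
    db_len: int | None = None,
    e_max: float | None = None,
    min_shared: int = 1,
) -> list[Hit]:
    """Search a query against an indexed protein set.

    Candidates from the k-mer prefilter are scored (score-only pass); only
    candidates that can pass ``e_max`` get a full traceback.  The result is
    identical to exhaustive all-pairs ``local_align`` + sort for every subject
    the prefilter admits.  Hits are sorted bit-score desc / E asc / subject id
    and ranked 1..N.
    """
    _check_sequence(query.sequence, query.protein_id)
    if db_len is None:
        db_len = sum(p.length for p in index.proteins.values())
    hits: list[Hit] = []
    for pid in index.candidates(query.sequence, min_shared=min_shared):
        subject = index.proteins[pid]
        raw = raw_local_score(query.sequence, subject.sequence, params)
        if raw <= 0:
            continue
        if e_max is not None and evalue(params.bits(raw), query.length, db_len) > e_max:
            continue
        hit = local_align(query, subject, params, db_len=db_len)
        if hit is not None:
            hits.append(hit)
    return sort_hits(hits)


def hits_to_rows(hits: Iterable[Hit]) -> list[dict]:
    """Tabular (12-column + coverages) representation of a hit list."""
    return [{
        "query_id": h.query_id, "subject_id": h.subject_id,
        "pct_identity": round(h.pct_identity, 2), "length": h.n_columns,
        "mismatches": h.n_mismatches, "gaps": h.n_gaps,
        "qstart": h.qstart, "qend": h.qend, "sstart": h.sstart, "send": h.send,
        "evalue": h.e_value, "bitscore": round(h.bit_score, 1),
        "query_cov": round(h.query_cov, 2), "subject_cov": round(h.subject_cov, 2),
    } for h in hits]
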