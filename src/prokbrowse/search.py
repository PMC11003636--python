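"""Homolog search against a comparative database.

Two search paths share one scoring scale (the align-module kernel):

* :func:`search_direct` — prefilter + optimal local alignment against every
  distinct protein, filtered at E <= 1e-3, truncated to one hit list of at
  most #genomes entries.
* :func:`search_clustered` — the accelerated path for redundant order-level
  databases: search cluster *representatives* first, expand the hit
  representatives to their full cluster membership (capped at
  max(#genomes, 200) candidates), then re-align the query to every candidate.

Hits are classified post hoc: every hit is a homolog; *potential orthologs*
additionally have >= 30% identity and >= 50% query coverage; *good homologs*
have a bit score >= 30% of the query's self-alignment score; and the
high-coverage ortholog class further requires >= 90% coverage of both
sequences.

The module also carries the length -> engine-sensitivity schedule and the
split-align-merge workflow contract for an optional external prefilter+align
engine (the engine itself is not bundled; without a handle the adapter raises
rather than silently falling back).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Callable, Mapping, Protocol, Sequence

from .align import AlignParams, Hit, KmerIndex, batch_search, evalue, local_align, sort_hits
from .datastore import Database, ProteinSeq

__all__ = [
    "SearchConfig",
    "search_direct",
    "search_clustered",
    "classify_hit",
    "sensitivity_for_length",
    "parallel_engine_search",
    "split_candidates",
    "merge_sorted_parts",
    "EngineUnavailableError",
]


@dataclass(frozen=True)
class SearchConfig:
    """Thresholds for searching and hit classification."""

    e_max: float = 1e-3          # homolog cutoff used everywhere
    e_strict: float = 1e-5       # stricter cutoff used by the evaluation harness
    max_hits: int | None = None  # None -> number of genomes in the target db
    candidate_cap: int | None = None  # None -> max(#genomes, 200)
    ortho_min_identity: float = 30.0
    ortho_min_query_cov: float = 50.0
    good_ratio_min: float = 0.30
    high_cov_both: float = 90.0

    def __post_init__(self) -> None:
        for name in ("e_max", "e_strict", "ortho_min_identity",
                     "ortho_min_query_cov", "good_ratio_min", "high_cov_both"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def resolved_max_hits(self, db: Database) -> int:
        return self.max_hits if self.max_hits is not None else db.n_genomes

    def resolved_candidate_cap(self, db: Database) -> int:
        cap = (self.candidate_cap if self.candidate_cap is not None
               else max(db.n_genomes, 200))
        if cap < 200:
            raise ValueError("candidate cap must be >= 200")
        return cap


def _db_index(db: Database) -> KmerIndex:
    index = getattr(db, "_kmer_index", None)
    if index is None or index.proteins.keys() != db.proteins.keys():
        index = KmerIndex(db.proteins)
        db._kmer_index = index
    return index


def _expand_to_genomes(hits: Sequence[Hit], db: Database) -> list[Hit]:
    """One hit per (subject protein, genome containing it)."""
    out = []
    for h in hits:
        for genome_id in db.genomes_of_protein(h.subject_id):
            out.append(dataclasses.replace(h, subject_genome_id=genome_id))
    return out


def _finalize(hits: list[Hit], db: Database, cfg: SearchConfig) -> list[Hit]:
    hits = sort_hits(_expand_to_genomes(hits, db))
    hits = hits[: cfg.resolved_max_hits(db)]
    for i, h in enumerate(hits, 1):
        h.rank = i
    return hits


def search_direct(
    query: ProteinSeq,
    db: Database,
    cfg: SearchConfig = SearchConfig(),
    params: AlignParams = AlignParams(),
) -> list[Hit]:
    """Search every distinct protein in ``db``; E <= ``cfg.e_max``; one ranked
    list truncated to at most #genomes (genome-expanded) entries."""
    protein_hits = batch_search(query, _db_index(db), params,
                                db_len=db.total_residues, e_max=cfg.e_max)
    return _finalize(protein_hits, db, cfg)


def search_clustered(
    query: ProteinSeq,
    db: Database,
    cfg: SearchConfig = SearchConfig(),
    params: AlignParams = AlignParams(),
) -> list[Hit]:
    """Two-stage clustered search: representatives, expand, re-align.

    Stage 1 searches only cluster representatives; stage 2 expands each hit
    representative to its full cluster membership, keeping candidates in
    stage-1 score order (members in cluster order) up to the candidate cap;
    stage 3 re-aligns the query to every candidate with the same kernel and
    E-value scale as :func:`search_direct`, so the two paths are directly
    comparable.
    """
    if db.clusters is None:
        raise ValueError("database has no cluster table; run `prokbrowse cluster` first")
    rep_index = getattr(db, "_rep_index", None)
    rep_ids = {cl.rep_id for cl in db.clusters}
    if rep_index is None or rep_index.proteins.keys() != rep_ids:
        rep_index = KmerIndex({r: db.proteins[r] for r in rep_ids})
        db._rep_index = rep_index
    db_len = db.total_residues  # same statistical scale as the direct search
    stage1 = batch_search(query, rep_index, params, db_len=db_len, e_max=cfg.e_max)

    members_of = {cl.rep_id: list(cl.member_ids) for cl in db.clusters}
    cap = cfg.resolved_candidate_cap(db)
    candidates: list[str] = []
    seen: set[str] = set()
    for rep_hit in stage1:  # stage-1 score order keeps the strongest families
        for member in members_of[rep_hit.subject_id]:
            if member not in seen:
                seen.add(member)
                candidates.append(member)
    candidates = candidates[:cap]

    hits = []
    for pid in candidates:
        hit = local_align(query, db.proteins[pid], params, db_len=db_len)
        if hit is not None and hit.e_value <= cfg.e_max:
            hits.append(hit)
    return _finalize(hits, db, cfg)


def classify_hit(
    hit: Hit, query_self_score: float, cfg: SearchConfig = SearchConfig(),
) -> frozenset[str]:
    """Labels for a hit that already passed the E-value gate.

    Thresholds are inclusive ("at least"): identity 30 / query coverage 50
    for potential orthologs, bit-score ratio 0.30 for good homologs, both
    coverages 90 on top of that for high-coverage orthologs.
    """
    labels = {"homolog"}
    if (hit.pct_identity >= cfg.ortho_min_identity
            and hit.query_cov >= cfg.ortho_min_query_cov):
        labels.add("potential_ortholog")
    ratio = hit.bit_score / query_self_score
    if ratio >= cfg.good_ratio_min:
        labels.add("good_homolog")
        if hit.query_cov >= cfg.high_cov_both and hit.subject_cov >= cfg.high_cov_both:
            labels.add("high_coverage_ortholog")
    return frozenset(labels)


def sensitivity_for_length(query_len: int) -> float:
    """Engine sensitivity setting as a function of query length (residues).

    Shorter queries get more sensitive settings because their miss rate is
    otherwise much higher; the breakpoints are 150/250/350/650 residues.
    """
    if query_len < 1:
        raise ValueError("query length must be >= 1")
    if query_len <= 150:
        return 7.5
    if query_len <= 250:
        return 7.0
    if query_len <= 350:
        return 6.25
    if query_len <= 650:
        return 6.0
    return 5.7


# ---------------------------------------------------------------------------
# optional external-engine adapter (split-align-merge workflow)


class EngineUnavailableError(RuntimeError):
    """Raised when the external prefilter+align engine is not configured."""


class ExternalEngine(Protocol):
    """Minimal contract for an external prefilter+align engine."""

    def prefilter(self, query: ProteinSeq, max_candidates: int,
                  sensitivity: float) -> list[str]: ...

    def align(self, query: ProteinSeq, candidate_ids: Sequence[str]) -> list[Hit]: ...


def split_candidates(candidates: Sequence, n_parts: int) -> list[list]:
    """Split a candidate list into ``n_parts`` contiguous, near-equal parts.

    Concatenating the parts reproduces the input exactly; empty trailing
    parts appear when there are fewer candidates than parts.
    """
    if n_parts < 1:
        raise ValueError("n_parts must be >= 1")
    n = len(candidates)
    base, extra = divmod(n, n_parts)
    parts, pos = [], 0
    for i in range(n_parts):
        size = base + (1 if i < extra else 0)
        parts.append(list(candidates[pos:pos + size]))
        pos += size
    return parts


def merge_sorted_parts(parts: Sequence[Sequence[Hit]]) -> list[Hit]:
    """Merge per-part hit lists into one globally sorted, ranked list."""
    merged: list[Hit] = [h for part in parts for h in part]
    return sort_hits(merged)


def parallel_engine_search(
    query: ProteinSeq,
    db: Database,
    engine: ExternalEngine | None,
    n_parts: int = 10,
    cfg: SearchConfig = SearchConfig(),
) -> list[Hit]:
    """Split-align-merge workflow around an external engine.

    The engine's prefilter candidate list is split into ``n_parts`` contiguous
    parts which are aligned independently (concurrently, when the engine
    supports it); the merged result is sorted identically to a single-run
    ordering and truncated to #genomes entries.  The engine is invoked with
    max-candidates = 8 * #genomes and the sensitivity from
    :func:`sensitivity_for_length`.  Without an engine this raises — there is
    no silent fallback to the internal kernel.
    """
    if engine is None:
        raise EngineUnavailableError(
            "no external engine configured; use search_direct/search_clustered")
    candidates = engine.prefilter(query, max_candidates=8 * db.n_genomes,
                                  sensitivity=sensitivity_for_length(query.length))
    parts = split_candidates(candidates, n_parts)
    aligned = [engine.align(query, part) for part in parts]
    merged = merge_sorted_parts(aligned)
    merged = [h for h in merged if h.e_value <= cfg.e_max]
    merged = merged[: db.n_genomes]
    for i, h in enumerate(merged, 1):
        h.rank = i
    return merged
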