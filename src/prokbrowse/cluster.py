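"""Greedy incremental protein clustering (70% identity, 90% coverage both ways).

Order-level databases keep up to 10 genomes per species and therefore carry
many near-identical sequences.  Clustering them CD-HIT-style — proteins
processed longest first, each joining the first existing cluster whose
*representative* it matches at >= 70% identity with the alignment covering
>= 90% of both sequences, else founding a new cluster — compresses the search
space severalfold and is what the two-stage clustered search expands from.

One deliberate divergence from CD-HIT: percent identity here is the alignment
module's convention (matches over alignment columns, gaps included), not
CD-HIT's matches-over-shorter-sequence.  The thresholds are applied uniformly
with that one definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .align import AlignParams, Hit, local_align
from .datastore import ProteinSeq

__all__ = ["Cluster", "greedy_cluster", "verify_clusters", "clusters_frame"]


@dataclass
class Cluster:
    """A representative (the longest member, always first) plus its members."""

    rep_id: str
    member_ids: list[str]
    #: member -> (pct identity vs rep, coverage of member, coverage of rep)
    member_stats: dict[str, tuple[float, float, float]]


def _member_stats(hit: Hit) -> tuple[float, float, float]:
    # query = member, subject = representative
    return (hit.pct_identity, hit.query_cov, hit.subject_cov)


def _matches(hit: Hit | None, min_identity: float, min_cov_both: float) -> bool:
    return (hit is not None and hit.pct_identity >= min_identity
            and hit.query_cov >= min_cov_both and hit.subject_cov >= min_cov_both)


def greedy_cluster(
    proteins: Mapping[str, ProteinSeq],
    min_identity: float = 70.0,
    min_cov_both: float = 90.0,
    params: AlignParams = AlignParams(),
    prefilter_k: int = 5,
    prefilter_min_shared: int = 2,
) -> list[Cluster]:
    """Cluster ``proteins`` greedily; deterministic for a given input set.

    Proteins are processed in length-descending order (ties broken by id) and
    assigned first-fit in cluster-creation order.  Candidate clusters are
    prescreened by shared k-mers with the representative before the full
    alignment; :func:`verify_clusters` is the correctness backstop for the
    membership contract.
    """
    if not 0 < min_identity <= 100 or not 0 < min_cov_both <= 100:
        raise ValueError("thresholds must be in (0, 100]")
    order = sorted(proteins, key=lambda pid: (-proteins[pid].length, pid))
    clusters: list[Cluster] = []
    # incremental k-mer index over representatives: word -> cluster indices
    word_index: dict[str, list[int]] = {}

    for pid in order:
        seq = proteins[pid].sequence
        words = {seq[i:i + prefilter_k] for i in range(len(seq) - prefilter_k + 1)}
        if words:
            counts: dict[int, int] = {}
            for w in words:
                for ci in word_index.get(w, ()):
                    counts[ci] = counts.get(ci, 0) + 1
            candidate_ids = sorted(ci for ci, c in counts.items()
                                   if c >= prefilter_min_shared)
        else:  # shorter than k: no prefilter possible, check every cluster
            candidate_ids = list(range(len(clusters)))
        placed = False
        for ci in candidate_ids:  # first fit, creation order
            rep = proteins[clusters[ci].rep_id]
            hit = local_align(proteins[pid], rep, params)
            if _matches(hit, min_identity, min_cov_both):
                clusters[ci].member_ids.append(pid)
                clusters[ci].member_stats[pid] = _member_stats(hit)
                placed = True
                break
        if not placed:
            ci = len(clusters)
            clusters.append(Cluster(rep_id=pid, member_ids=[pid],
                                    member_stats={pid: (100.0, 100.0, 100.0)}))
            for w in words:
                word_index.setdefault(w, []).append(ci)
    return clusters


def verify_clusters(
    clusters: Sequence[Cluster],
    proteins: Mapping[str, ProteinSeq],
    min_identity: float = 70.0,
    min_cov_both: float = 90.0,
    params: AlignParams = AlignParams(),
) -> list[dict]:
    """Re-align every member to its representative; report contract violations.

    The returned list is empty exactly when the clustering satisfies the
    membership contract (identity and both-way coverage thresholds, rep at
    least as long as each member) and forms a partition of ``proteins``.
    """
    violations: list[dict] = []
    seen: dict[str, str] = {}
    for cl in clusters:
        for m in cl.member_ids:
            if m not in proteins:
                raise KeyError(f"cluster member {m} not in protein set")
            if m in seen:
                violations.append({"member": m, "rep": cl.rep_id,
                                   "problem": f"also in cluster {seen[m]}"})
            seen[m] = cl.rep_id
            if proteins[m].length > proteins[cl.rep_id].length:
                violations.append({"member": m, "rep": cl.rep_id,
                                   "problem": "member longer than representative"})
            if m == cl.rep_id:
                continue
            hit = local_align(proteins[m], proteins[cl.rep_id], params)
            if not _matches(hit, min_identity, min_cov_both):
                violations.append({
                    "member": m, "rep": cl.rep_id,
                    "problem": "below identity/coverage thresholds",
                    "identity": None if hit is None else hit.pct_identity,
                    "cov_member": None if hit is None else hit.query_cov,
                    "cov_rep": None if hit is None else hit.subject_cov,
                })
    for pid in proteins:
        if pid not in seen:
            violations.append({"member": pid, "rep": None,
                               "problem": "not in any cluster"})
    return violations


def clusters_frame(clusters: Sequence[Cluster]) -> pd.DataFrame:
    """Cluster table: rep_id, member_id, identity, cov_member, cov_rep."""
    rows = []
    for cl in clusters:
        for m in cl.member_ids:
            ident, cm, cr = cl.member_stats[m]
            rows.append({"rep_id": cl.rep_id, "member_id": m,
                         "identity": round(ident, 2),
                         "cov_member": round(cm, 2), "cov_rep": round(cr, 2)})
    return pd.DataFrame(rows, columns=["rep_id", "member_id", "identity",
                                       "cov_member", "cov_rep"])
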