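"""Sensitivity evaluation: rank-binned miss rates of one search method
against a reference method.

The reference universe is the reference method's hits with E below a strict
cutoff (1e-5) and rank at most half the genome count (hits further down are
unlikely to be orthologs), optionally restricted to potential orthologs
(>= 30% identity, >= 50% query coverage) or additionally to score ratio
>= 0.3.  A reference hit is *missed* when its (query, subject protein) pair
is absent from the test method's results — scores are never compared, since
different engines use different score scales.  Misses are binned by reference
rank in windows of 50 ranks by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .align import Hit
from .datastore import Database
from .search import SearchConfig

__all__ = ["MissRateCurve", "miss_rate_by_rank", "benchmark_queries"]


@dataclass
class MissRateCurve:
    bin_width: int
    #: per bin: (rank_lo, rank_hi, n_reference_hits, n_missed, miss_rate)
    bins: list[tuple[int, int, int, int, float]]
    n_reference: int
    n_missed: int
    subset: str

    @property
    def overall(self) -> float:
        return self.n_missed / self.n_reference if self.n_reference else 0.0


def _in_subset(hit: Hit, subset: str, self_score: float | None,
               cfg: SearchConfig) -> bool:
    if subset == "all":
        return True
    ortho = (hit.pct_identity >= cfg.ortho_min_identity
             and hit.query_cov >= cfg.ortho_min_query_cov)
    if subset == "ortholog":
        return ortho
    if subset == "ortholog_scoreratio":
        if self_score is None:
            raise ValueError("score-ratio subset needs query self scores")
        return ortho and hit.bit_score / self_score >= cfg.good_ratio_min
    raise ValueError(f"unknown subset {subset!r}")


def miss_rate_by_rank(
    reference: Mapping[str, Sequence[Hit]],
    test: Mapping[str, Sequence[Hit]],
    rank_cap: int,
    e_cap: float = 1e-5,
    bin_width: int = 50,
    subset: str = "all",
    self_scores: Mapping[str, float] | None = None,
    cfg: SearchConfig = SearchConfig(),
) -> MissRateCurve:
    """Miss-rate curve of ``test`` against ``reference``, binned by rank.

    Both mappings are query id -> ranked hit list.  ``rank_cap`` is usually
    #genomes / 2.  The reference hit at rank r lands in bin floor((r-1)/bin);
    per-bin and overall rates are fractions of reference hits whose
    (query, subject) pair the test method did not return at all.
    """
    if rank_cap < 1:
        raise ValueError("rank_cap must be >= 1")
    n_bins = (rank_cap + bin_width - 1) // bin_width
    n_ref = np.zeros(n_bins, dtype=int)
    n_miss = np.zeros(n_bins, dtype=int)
    for query_id, ref_hits in reference.items():
        found = {(h.query_id, h.subject_id) for h in test.get(query_id, ())}
        self_score = self_scores.get(query_id) if self_scores else None
        for h in ref_hits:
            if h.e_value > e_cap or h.rank > rank_cap:
                continue
            if not _in_subset(h, subset, self_score, cfg):
                continue
            b = (h.rank - 1) // bin_width
            n_ref[b] += 1
            if (h.query_id, h.subject_id) not in found:
                n_miss[b] += 1
    bins = []
    for b in range(n_bins):
        lo, hi = b * bin_width + 1, min((b + 1) * bin_width, rank_cap)
        rate = n_miss[b] / n_ref[b] if n_ref[b] else 0.0
        bins.append((lo, hi, int(n_ref[b]), int(n_miss[b]), float(rate)))
    return MissRateCurve(bin_width=bin_width, bins=bins,
                         n_reference=int(n_ref.sum()),
                         n_missed=int(n_miss.sum()), subset=subset)


def benchmark_queries(db: Database, n: int = 1000, seed: int = 0) -> list[str]:
    """Uniform seeded sample (without replacement) of protein ids from ``db``."""
    if not db.proteins:
        raise ValueError("database has no proteins")
    ids = sorted(db.proteins)
    rng = np.random.default_rng(seed)
    if n >= len(ids):
        return ids
    picked = rng.choice(len(ids), size=n, replace=False)
    return [ids[i] for i in sorted(picked)]
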