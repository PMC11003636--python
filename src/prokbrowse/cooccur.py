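"""Co-occurrence (phylogenetic profiling) of two proteins' homologs.

For every genome with a homolog of either query, the per-genome point is the
pair of best bit-score ratios (a missing side is marked absent — rendered in
the gray band below zero).  Genomes where the two homologs are encoded close
by (within 5 kb, same strand) or where one protein is the best hit for both
queries (a fusion) are flagged.

The headline statistic asks whether the two presence/absence patterns
co-occur more than chance: a single rank threshold k, shared by both hit
lists, defines "present" as best-hit rank <= k; for every candidate k the
2x2 contingency table over *all* database genomes is scored with a one-sided
(enrichment) Fisher exact test, the best k is the one minimizing P, and the
minimum P is Bonferroni-multiplied by the number of candidate thresholds
scanned.  Candidates are exactly the ranks where either list gains a genome
— the table is constant between them, so the scan is exhaustive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom

from .align import Hit
from .datastore import Database, Gene
from .search import SearchConfig

__all__ = ["GenomePair", "ThresholdScan", "genome_pairs", "is_nearby",
           "optimal_threshold", "cooccur_summary", "render_scatter_svg"]

ABSENT = None  # marker for "no homolog of this query in the genome"


@dataclass
class GenomePair:
    genome_id: str
    ratio_a: float | None   # best score ratio, or None if absent
    ratio_b: float | None
    nearby: bool
    fused: bool
    lineage: tuple[str, ...]


@dataclass
class ThresholdScan:
    candidate_ranks: list[int]
    tables: list[tuple[int, int, int, int]]  # (n11, n10, n01, n00) per k
    p_values: list[float]
    bonferroni_factor: int
    k_star: int | None
    p_min: float
    p_corrected: float


def _best_hit_per_genome(hits: Sequence[Hit]) -> dict[str, Hit]:
    """Best (lowest-rank) hit for each genome; hit lists are rank-sorted."""
    best: dict[str, Hit] = {}
    for h in sorted(hits, key=lambda h: h.rank):
        best.setdefault(h.subject_genome_id, h)
    return best


def is_nearby(gene_a: Gene, gene_b: Gene, max_dist: int = 5000) -> bool:
    """Same genome, contig, and strand, nearest ends within ``max_dist`` bp.

    Overlapping genes count as distance 0; the bound is inclusive.
    """
    if (gene_a.genome_id, gene_a.contig_id) != (gene_b.genome_id, gene_b.contig_id):
        return False
    if gene_a.strand != gene_b.strand:
        return False
    first, second = sorted((gene_a, gene_b), key=lambda g: g.start)
    gap = max(0, second.start - first.end - 1)
    return gap <= max_dist


def _min_gap_nearby(genes_a: Sequence[Gene], genes_b: Sequence[Gene],
                    max_dist: int) -> bool:
    return any(is_nearby(ga, gb, max_dist)
               for ga in genes_a for gb in genes_b if ga.gene_id != gb.gene_id)


def genome_pairs(
    hits_a: Sequence[Hit],
    hits_b: Sequence[Hit],
    db: Database,
    self_score_a: float,
    self_score_b: float,
    max_dist: int = 5000,
) -> list[GenomePair]:
    """One entry per genome with >= 1 hit of either query.

    ``fused`` means the same subject protein is the best hit for both
    queries; ``nearby`` means some homolog gene of A and some homolog gene of
    B sit within ``max_dist`` bp on one strand of one contig.
    """
    for h in list(hits_a) + list(hits_b):
        if h.subject_genome_id not in db.genomes:
            raise ValueError(f"hit genome {h.subject_genome_id} not in database")
    best_a = _best_hit_per_genome(hits_a)
    best_b = _best_hit_per_genome(hits_b)
    genes_a: dict[str, list[Gene]] = {}
    genes_b: dict[str, list[Gene]] = {}
    for h in hits_a:
        genes_a.setdefault(h.subject_genome_id, []).extend(
            db.genes[g] for g in db.genes_of_protein(h.subject_id)
            if db.genes[g].genome_id == h.subject_genome_id)
    for h in hits_b:
        genes_b.setdefault(h.subject_genome_id, []).extend(
            db.genes[g] for g in db.genes_of_protein(h.subject_id)
            if db.genes[g].genome_id == h.subject_genome_id)

    out = []
    for genome_id in sorted(set(best_a) | set(best_b)):
        ha, hb = best_a.get(genome_id), best_b.get(genome_id)
        fused = (ha is not None and hb is not None
                 and ha.subject_id == hb.subject_id)
        nearby = (ha is not None and hb is not None and not fused
                  and _min_gap_nearby(genes_a.get(genome_id, ()),
                                      genes_b.get(genome_id, ()), max_dist))
        out.append(GenomePair(
            genome_id=genome_id,
            ratio_a=None if ha is None else ha.bit_score / self_score_a,
            ratio_b=None if hb is None else hb.bit_score / self_score_b,
            nearby=nearby, fused=fused,
            lineage=tuple(db.genomes[genome_id].taxonomy),
        ))
    return out


def fisher_one_sided(n11: int, n10: int, n01: int, n00: int) -> float:
    """One-sided (enrichment) Fisher exact P for a 2x2 table.

    P(X >= n11) where X is hypergeometric: N genomes, n11+n10 carrying A,
    n11+n01 draws (genomes carrying B).
    """
    n = n11 + n10 + n01 + n00
    return float(hypergeom.sf(n11 - 1, n, n11 + n10, n11 + n01))


def optimal_threshold(
    hits_a: Sequence[Hit],
    hits_b: Sequence[Hit],
    db: Database,
) -> ThresholdScan:
    """Scan shared rank thresholds; minimize the one-sided Fisher P.

    A genome is "present for A" at threshold k iff its best A-hit has rank
    <= k (likewise B).  The contingency universe is every genome in the
    database, including genomes with no homolog of either protein.  Ties in
    P go to the smallest k; the corrected P multiplies the minimum by the
    number of candidate thresholds (capped at 1).
    """
    n_genomes = db.n_genomes
    best_a = {g: h.rank for g, h in _best_hit_per_genome(hits_a).items()}
    best_b = {g: h.rank for g, h in _best_hit_per_genome(hits_b).items()}
    if not best_a or not best_b:
        return ThresholdScan([], [], [], 0, None, 1.0, 1.0)
    candidates = sorted({r for r in (*best_a.values(), *best_b.values())
                         if r <= n_genomes})
    tables, pvals = [], []
    ranks_a = np.array([best_a.get(g, n_genomes + 1) for g in sorted(db.genomes)])
    ranks_b = np.array([best_b.get(g, n_genomes + 1) for g in sorted(db.genomes)])
    for k in candidates:
        a_in = ranks_a <= k
        b_in = ranks_b <= k
        n11 = int(np.sum(a_in & b_in))
        n10 = int(np.sum(a_in & ~b_in))
        n01 = int(np.sum(~a_in & b_in))
        n00 = n_genomes - n11 - n10 - n01
        tables.append((n11, n10, n01, n00))
        pvals.append(fisher_one_sided(n11, n10, n01, n00))
    i_star = int(np.argmin(pvals))  # argmin takes the first = smallest k on ties
    p_min = pvals[i_star]
    return ThresholdScan(
        candidate_ranks=candidates, tables=tables, p_values=pvals,
        bonferroni_factor=len(candidates), k_star=candidates[i_star],
        p_min=p_min, p_corrected=min(1.0, p_min * len(candidates)),
    )


def cooccur_summary(
    hits_a: Sequence[Hit],
    hits_b: Sequence[Hit],
    db: Database,
    self_score_a: float,
    self_score_b: float,
    cfg: SearchConfig = SearchConfig(),
    taxa_level: str = "genus",
    max_dist: int = 5000,
) -> dict:
    """Co-occurrence counts (all and good homologs) plus taxa tables.

    Returns a dict with ``counts_all`` / ``counts_good`` (both, a_only,
    b_only, neither over all db genomes), the taxa at ``taxa_level``
    containing both homologs, and the subset containing them in proximity.
    """
    pairs = genome_pairs(hits_a, hits_b, db, self_score_a, self_score_b, max_dist)

    def counts(min_ratio: float | None) -> dict[str, int]:
        both = a_only = b_only = 0
        for p in pairs:
            a = p.ratio_a is not None and (min_ratio is None or p.ratio_a >= min_ratio)
            b = p.ratio_b is not None and (min_ratio is None or p.ratio_b >= min_ratio)
            both += a and b
            a_only += a and not b
            b_only += b and not a
        return {"both": both, "a_only": a_only, "b_only": b_only,
                "neither": db.n_genomes - both - a_only - b_only}

    taxa_both = sorted({db.genomes[p.genome_id].taxonomy.rank(taxa_level)
                        for p in pairs
                        if p.ratio_a is not None and p.ratio_b is not None})
    taxa_near = sorted({db.genomes[p.genome_id].taxonomy.rank(taxa_level)
                        for p in pairs if p.nearby or p.fused})
    return {
        "counts_all": counts(None),
        "counts_good": counts(cfg.good_ratio_min),
        "taxa_both": taxa_both,
        "taxa_nearby": taxa_near,
        "pairs": pairs,
    }


def render_scatter_svg(pairs: Sequence[GenomePair], path: str,
                       size: int = 360) -> None:
    """Presence/absence scatter: green = nearby, blue = fused, black other;
    genomes missing one side sit in the gray band below zero on that axis."""
    margin, band = 40, 28
    plot = size - margin - band

    def coord(r: float | None, axis: str) -> float:
        if r is None:
            return (margin + band / 2) if axis == "y" else (margin - band / 2)
        if axis == "x":
            return margin + band + r * (plot - 10)
        return size - margin - band - r * (plot - 10)

    parts = [f'<svg xmlns="http://www.w3.org/2000/svg" width="{size}" height="{size}">',
             f'<rect x="{margin}" y="{size - margin - band}" width="{size - margin}"'
             f' height="{band}" fill="#eeeeee"/>',
             f'<rect x="{margin - band}" y="0" width="{band}"'
             f' height="{size - margin}" fill="#eeeeee"/>']
    for p in pairs:
        color = "#1f4da0" if p.fused else "#2ca02c" if p.nearby else "#000000"
        cx = coord(p.ratio_a, "x") if p.ratio_a is not None else margin - band / 2
        cy = coord(p.ratio_b, "y") if p.ratio_b is not None else size - margin - band / 2
        parts.append(f'<circle cx="{cx:.1f}" cy="{cy:.1f}" r="3" fill="{color}"'
                     ' fill-opacity="0.7"/>')
    parts.append("</svg>")
    with open(path, "w") as fh:
        fh.write("\n".join(parts) + "\n")
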