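"""Taxonomic prevalence of a protein's homologs.

Aggregates a hit list at a chosen taxonomy rank: for each taxon, how many of
its genomes are in the database, how many have a (filtered) hit, and the
"max ratio" — the best bit-score ratio among the taxon's hits, a quick gauge
of how close the closest homolog in that taxon is.  Filters mirror the hit
classes: all homologs, potential orthologs (>= 30% identity, >= 50% query
coverage), or good homologs (score ratio >= 0.3).
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .align import Hit
from .datastore import Database, RANKS
from .search import SearchConfig, classify_hit

__all__ = ["profile", "export_homolog_table", "FILTERS"]

FILTERS = ("all", "potential_ortholog", "good_homolog")


def _filtered(hits: Sequence[Hit], flt: str, query_self_score: float,
              cfg: SearchConfig) -> list[Hit]:
    if flt == "all":
        return list(hits)
    if flt not in FILTERS:
        raise ValueError(f"unknown filter {flt!r}; choose from {FILTERS}")
    return [h for h in hits if flt in classify_hit(h, query_self_score, cfg)]


def profile(
    hits: Sequence[Hit],
    db: Database,
    level: str = "phylum",
    flt: str = "all",
    query_self_score: float | None = None,
    cfg: SearchConfig = SearchConfig(),
    include_empty: bool = True,
) -> pd.DataFrame:
    """Prevalence table at ``level``: one row per taxon with >= 1 genome in db.

    A genome counts once however many hits it has.  Rows are sorted by the
    number of genomes with a hit (descending), then by label.  Taxa without
    hits are kept (with zero counts and missing max_ratio) unless
    ``include_empty`` is false.
    """
    if level not in RANKS:
        raise ValueError(f"unknown taxonomy level {level!r}")
    if flt != "all" and query_self_score is None:
        raise ValueError("filtered profiles need the query self score")
    kept = _filtered(hits, flt, query_self_score or 1.0, cfg)

    in_db: dict[tuple, set[str]] = {}
    for aid, rec in db.genomes.items():
        in_db.setdefault(rec.taxonomy.lineage(level), set()).add(aid)
    with_hit: dict[tuple, set[str]] = {}
    best: dict[tuple, float] = {}
    for h in kept:
        lineage = db.genomes[h.subject_genome_id].taxonomy.lineage(level)
        with_hit.setdefault(lineage, set()).add(h.subject_genome_id)
        if query_self_score is not None:
            ratio = h.bit_score / query_self_score
            best[lineage] = max(best.get(lineage, 0.0), ratio)

    rows = []
    for lineage, genomes in in_db.items():
        n_with = len(with_hit.get(lineage, ()))
        if n_with == 0 and not include_empty:
            continue
        rows.append({
            "level": level, "taxon": lineage[-1], "lineage": ";".join(lineage),
            "n_genomes_in_db": len(genomes), "n_genomes_with_hit": n_with,
            "fraction": n_with / len(genomes),
            "max_ratio": best.get(lineage, float("nan")),
        })
    rows.sort(key=lambda r: (-r["n_genomes_with_hit"], r["taxon"]))
    return pd.DataFrame(rows, columns=["level", "taxon", "lineage",
                                       "n_genomes_in_db", "n_genomes_with_hit",
                                       "fraction", "max_ratio"])


def export_homolog_table(
    hits: Sequence[Hit],
    db: Database,
    query_self_score: float | None = None,
) -> pd.DataFrame:
    """One row per hit, in rank order, with the genome's full lineage."""
    rows = []
    for h in hits:
        tax = db.genomes[h.subject_genome_id].taxonomy
        rows.append({
            "rank": h.rank, "subject_id": h.subject_id,
            "genome_id": h.subject_genome_id,
            **{r: tax[i] for i, r in enumerate(RANKS)},
            "bitscore": h.bit_score, "evalue": h.e_value,
            "pct_identity": h.pct_identity, "query_cov": h.query_cov,
            "subject_cov": h.subject_cov,
            "score_ratio": (h.bit_score / query_self_score
                            if query_self_score else float("nan")),
        })
    return pd.DataFrame(rows, columns=["rank", "subject_id", "genome_id",
                                       *RANKS, "bitscore", "evalue",
                                       "pct_identity", "query_cov",
                                       "subject_cov", "score_ratio"])
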