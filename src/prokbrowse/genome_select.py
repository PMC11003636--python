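"""Genome quality gate and representative selection.

Only high-quality assemblies enter a database, so that the *absence* of a
homolog is informative: CheckM completeness >= 90%, contamination <= 5%, not
chimeric (GUNC), MIMAG high-quality draft for non-isolates, and at least half
of the genes protein coding.  Within each genus (main database) or species
(order databases, up to 10 genomes each) representatives are chosen by a
fixed preference order; a final lexicographic tiebreak on assembly id makes
selection a pure, order-independent function of the metadata.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

from .datastore import GenomeRecord

__all__ = ["passes_quality", "selection_key", "pick_representatives"]


def passes_quality(g: GenomeRecord) -> tuple[bool, str | None]:
    """Apply the quality gate; on failure the reason names the first failing rule.

    Rules, in order: completeness >= 90; contamination <= 5; not chimeric;
    isolate or MIMAG high-quality draft; has genes; >= half the genes protein
    coding.
    """
    if g.completeness < 90:
        return False, "completeness"
    if g.contamination > 5:
        return False, "contamination"
    if g.is_chimeric:
        return False, "chimeric"
    if not g.is_isolate and not g.mimag_high_quality:
        return False, "MIMAG"
    if g.n_genes <= 0:
        return False, "no_genes"
    if g.n_protein_coding / g.n_genes < 0.5:
        return False, "coding_fraction"
    return True, None


def selection_key(g: GenomeRecord) -> tuple:
    """Sort key realizing the representative preference order (best first).

    Preferences, in sequence: in RefSeq; type species of the genus; GTDB
    species representative; lower quality score 2*contamination -
    completeness; on the important-strains list; longer largest scaffold;
    finally assembly id (lexicographic) to make the order total.
    """
    return (
        not g.in_refseq,
        not g.is_type_species,
        not g.is_species_representative,
        2.0 * g.contamination - g.completeness,
        not g.in_important_strains,
        -g.largest_scaffold_bp,
        g.assembly_id,
    )


def pick_representatives(
    genomes: Iterable[GenomeRecord],
    group_rank: str = "genus",
    max_per_group: int = 1,
) -> dict[tuple[str, ...], list[GenomeRecord]]:
    """Top ``max_per_group`` genomes per taxon at ``group_rank``, in key order.

    Groups are keyed by the full lineage down to ``group_rank`` so that label
    collisions across higher taxa never merge groups.  All inputs are assumed
    to have passed :func:`passes_quality`.
    """
    if max_per_group < 1:
        raise ValueError("max_per_group must be >= 1")
    if group_rank not in ("genus", "species"):
        raise ValueError(f"group_rank must be genus or species, not {group_rank!r}")
    groups: dict[tuple[str, ...], list[GenomeRecord]] = {}
    for g in genomes:
        groups.setdefault(g.taxonomy.lineage(group_rank), []).append(g)
    return {
        key: sorted(members, key=selection_key)[:max_per_group]
        for key, members in sorted(groups.items())
    }
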