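"""Gene-neighborhood view: extraction, homology grouping, styling, trees.

For each top homolog of a query, the view shows the genes flanking it on its
contig, oriented so the homolog points rightward.  Visible proteins are
grouped by mutual homology (alignments covering at least 50% of both
sequences, single linkage) and each multi-member group gets one of 33 styles
(11 colors x 3 hatch states); the query's own group is white and singleton
groups are neutral gray.  Same-species rows whose anchor proteins share a
cluster are collapsed to one row.  Rows can be ordered by a neighbor-joining
guide tree built from query-region-restricted identities, midpoint rooted,
with splits rotated so the best homolog comes first.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .align import AlignParams, Hit, local_align
from .datastore import Database, Gene, ProteinSeq

__all__ = [
    "PlacedGene", "NeighborhoodRow", "extract_neighborhood",
    "group_by_homology", "assign_styles", "collapse_by_species",
    "gene_spacing", "build_guide_tree", "sample_homologs",
    "tree_to_newick", "render_svg", "N_COLORS", "N_HATCHES",
]

N_COLORS = 11
N_HATCHES = 3  # none, hatch1, hatch2


@dataclass(frozen=True)
class PlacedGene:
    """A gene in display coordinates: signed bp offsets from the anchor start."""

    gene: Gene
    start_off: int
    end_off: int
    strand: str  # display strand; the anchor is always '+'


@dataclass
class NeighborhoodRow:
    anchor_gene_id: str
    genes: list[PlacedGene]
    anchor_hit: Hit | None = None
    collapsed_genome_ids: list[str] = field(default_factory=list)
    taxon_label: str = ""


def extract_neighborhood(
    anchor_gene_id: str,
    db: Database,
    window_bp: int = 10_000,
    anchor_hit: Hit | None = None,
    taxon_level: str = "species",
) -> NeighborhoodRow:
    """Genes overlapping the +-``window_bp`` window around the anchor.

    The window is clipped at contig ends.  If the anchor is on the minus
    strand all coordinates are mirrored, so the anchor sits at offset 0
    pointing right and its genomic upstream appears to its right.
    """
    if anchor_gene_id not in db.genes:
        raise KeyError(f"anchor gene {anchor_gene_id!r} not in database")
    anchor = db.genes[anchor_gene_id]
    contig_len = db.contigs.get((anchor.genome_id, anchor.contig_id))
    lo = max(1, anchor.start - window_bp)
    hi = anchor.end + window_bp
    if contig_len is not None:
        hi = min(hi, contig_len)
    placed = []
    for gene in db.genes_on_contig(anchor.genome_id, anchor.contig_id):
        if gene.end < lo or gene.start > hi:
            continue
        if anchor.strand == "+":
            start_off, end_off = gene.start - anchor.start, gene.end - anchor.start
            strand = gene.strand
        else:
            start_off, end_off = anchor.end - gene.end, anchor.end - gene.start
            strand = "+" if gene.strand == "-" else "-"
        placed.append(PlacedGene(gene, start_off, end_off, strand))
    placed.sort(key=lambda p: (p.start_off, p.end_off, p.gene.gene_id))
    record = db.genomes[anchor.genome_id]
    return NeighborhoodRow(
        anchor_gene_id=anchor_gene_id, genes=placed, anchor_hit=anchor_hit,
        collapsed_genome_ids=[anchor.genome_id],
        taxon_label=record.taxonomy.rank(taxon_level),
    )


def group_by_homology(
    visible: Mapping[str, ProteinSeq],
    params: AlignParams = AlignParams(),
    min_cov_both: float = 50.0,
) -> dict[str, int]:
    """Single-linkage homology groups over the visible proteins.

    All-vs-all local alignment; a pair is linked when the alignment covers at
    least ``min_cov_both`` percent of *both* sequences.  Links are applied in
    bit-score-descending order (ties broken by protein ids), which makes the
    grouping independent of input order; connected components are the groups.
    Group indices are assigned by each component's smallest member id.
    """
    if not visible:
        raise ValueError("need at least one visible protein")
    ids = sorted(visible)
    links = []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            hit = local_align(visible[a], visible[b], params)
            if (hit is not None and hit.query_cov >= min_cov_both
                    and hit.subject_cov >= min_cov_both):
                links.append((-hit.bit_score, a, b))
    parent = {pid: pid for pid in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for _score, a, b in sorted(links):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    roots = sorted({find(pid) for pid in ids})
    group_index = {root: i for i, root in enumerate(roots)}
    return {pid: group_index[find(pid)] for pid in ids}


def assign_styles(
    group_of: Mapping[str, int],
    query_group: int,
) -> dict[int, tuple]:
    """Map each homology group to a display style.

    The query group is white.  Multi-member groups, in descending size then
    first-appearance (smallest member id) order, receive styles from the
    fixed sequence of 11 colors x 3 hatch states (33 distinct styles, then
    cyclic reuse).  Singleton groups are neutral gray and consume no style.
    """
    members: dict[int, list[str]] = {}
    for pid in sorted(group_of):
        members.setdefault(group_of[pid], []).append(pid)
    if query_group not in members:
        raise ValueError(f"query group {query_group} has no members")
    styles: dict[int, tuple] = {query_group: ("white",)}
    informative = sorted(
        (g for g, ms in members.items() if g != query_group and len(ms) > 1),
        key=lambda g: (-len(members[g]), min(members[g])))
    for i, g in enumerate(informative):
        styles[g] = (i % N_COLORS, (i // N_COLORS) % N_HATCHES)
    for g in members:
        if g not in styles:
            styles[g] = ("gray",)
    return styles


def collapse_by_species(
    hits: Sequence[Hit],
    db: Database,
) -> list[tuple[Hit, list[str]]]:
    """Merge hits from the same species whose subjects share a cluster.

    Returns ``(best_hit, merged_genome_ids)`` pairs in rank order of the best
    member.  Hits differing in species or in cluster never merge.  Without a
    cluster table, collapsing is disabled (one row per hit) with a warning.
    """
    if db.clusters is None:
        import warnings
        warnings.warn("no cluster table; species collapsing disabled")
        return [(h, [h.subject_genome_id]) for h in hits]
    rep_of = db.cluster_of_protein()
    rows: dict[tuple, tuple[Hit, list[str]]] = {}
    for hit in hits:
        species = db.genomes[hit.subject_genome_id].taxonomy.lineage("species")
        key = (species, rep_of[hit.subject_id])
        if key not in rows:
            rows[key] = (hit, [hit.subject_genome_id])
        else:
            best, genomes = rows[key]
            if hit.subject_genome_id not in genomes:
                genomes.append(hit.subject_genome_id)
    return sorted(rows.values(), key=lambda r: r[0].rank)


def gene_spacing(g1: Gene, g2: Gene) -> int:
    """Nucleotides between two genes on one contig; negative means overlap.

    ``g1`` must be upstream of ``g2`` by start coordinate.  Abutting genes
    (end 100, start 101) have spacing 0; spacing -n means n bp of overlap.
    """
    if (g1.genome_id, g1.contig_id) != (g2.genome_id, g2.contig_id):
        raise ValueError("genes are on different contigs")
    if g1.start > g2.start:
        raise ValueError("g1 must be upstream of g2")
    return g2.start - g1.end - 1


def _restricted_to_query(hit: Hit, subject: ProteinSeq) -> str:
    """The part of the subject sequence that aligns to the query."""
    return subject.sequence[hit.sstart - 1: hit.send]


def build_guide_tree(
    sequences: Mapping[str, str],
    bit_scores: Mapping[str, float],
    params: AlignParams = AlignParams(),
) -> TreeNode:
    """Neighbor-joining guide tree over homolog sequences, midpoint rooted.

    ``sequences`` should already be restricted to the query-similar region of
    each homolog (see :func:`_restricted_to_query`).  Distances are
    1 - fractional identity of the pairwise local alignment (distance 1 for
    unalignable pairs).  After midpoint rooting, the children of every
    internal node are ordered by their best member bit score (descending), so
    the first leaf is the best homolog.
    """
    ids = sorted(sequences)
    if len(ids) == 0:
        raise ValueError("no sequences")
    if len(ids) == 1:
        return TreeNode(name=ids[0], length=0.0)
    dist = np.zeros((len(ids), len(ids)))
    prots = {i: ProteinSeq("Pquery" + format(k, "03d"), sequences[i])
             for k, i in enumerate(ids)}
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            hit = local_align(prots[ids[i]], prots[ids[j]], params)
            d = 1.0 if hit is None else 1.0 - (hit.pct_identity / 100.0)
            dist[i, j] = dist[j, i] = d
    if len(ids) == 2:
        half = dist[0, 1] / 2.0
        tree = TreeNode(children=[TreeNode(name=ids[0], length=half),
                                  TreeNode(name=ids[1], length=half)])
    else:
        tree = nj(DistanceMatrix(dist, ids=ids), neg_as_zero=True)
        tree = tree.root_at_midpoint()

    def best_bit(node: TreeNode) -> float:
        if node.is_tip():
            return bit_scores.get(node.name, 0.0)
        return max(best_bit(c) for c in node.children)

    for node in tree.postorder(include_self=True):
        if not node.is_tip() and node.children:
            node.children.sort(key=lambda c: (-best_bit(c), min(t.name for t in c.tips(include_self=True))))
    return tree


def sample_homologs(
    hits: Sequence[Hit],
    mode: str = "top",
    n_max: int = 200,
    seed: int = 0,
    query_self_score: float | None = None,
    good_ratio_min: float = 0.30,
) -> list[Hit]:
    """Pick up to ``n_max`` homologs to display.

    ``top`` takes the first ``n_max`` by rank; ``random_all`` samples
    uniformly without replacement from all hits; ``random_good`` samples from
    hits with bit-score ratio >= ``good_ratio_min`` (requires
    ``query_self_score``).  Samples are seeded and returned in rank order.
    """
    if mode == "top":
        eligible = list(hits)[:n_max]
        return eligible
    if mode == "random_all":
        eligible = list(hits)
    elif mode == "random_good":
        if query_self_score is None:
            raise ValueError("random_good mode needs query_self_score")
        eligible = [h for h in hits
                    if h.bit_score / query_self_score >= good_ratio_min]
    else:
        raise ValueError(f"unknown sampling mode {mode!r}")
    rng = np.random.default_rng(seed)
    if len(eligible) > n_max:
        idx = sorted(rng.choice(len(eligible), size=n_max, replace=False))
        eligible = [eligible[i] for i in idx]
    return sorted(eligible, key=lambda h: h.rank)


def tree_to_newick(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


# ---------------------------------------------------------------------------
# SVG rendering

_PALETTE = ["#a6cee3", "#1f78b4", "#b2df8a", "#33a02c", "#fb9a99", "#e31a1c",
            "#fdbf6f", "#ff7f00", "#cab2d6", "#6a3d9a", "#b15928"]


def _style_fill(style: tuple) -> tuple[str, str | None]:
    if style[0] == "white":
        return "#ffffff", None
    if style[0] == "gray":
        return "#d9d9d9", None
    color = _PALETTE[style[0]]
    hatch = None if style[1] == 0 else f"hatch{style[1]}"
    return color, hatch


def render_svg(
    rows: Sequence[NeighborhoodRow],
    group_of: Mapping[str, int],
    styles: Mapping[int, tuple],
    path: str,
    bp_per_px: float = 20.0,
    row_height: int = 34,
) -> None:
    """Write the neighborhood figure: one row per homolog, arrows per gene.

    Genes are arrows colored by homology group; the anchor carries a blue bar
    marking the extent of homology to the query (from the anchor hit's
    subject coordinates); the taxon label sits at the right edge.
    """
    min_off = min((g.start_off for r in rows for g in r.genes), default=0)
    max_off = max((g.end_off for r in rows for g in r.genes), default=1)
    width = int((max_off - min_off) / bp_per_px) + 170
    height = row_height * len(rows) + 10
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}">',
        '<defs>'
        '<pattern id="hatch1" width="5" height="5" patternTransform="rotate(45)"'
        ' patternUnits="userSpaceOnUse"><line x1="0" y1="0" x2="0" y2="5"'
        ' stroke="#000000" stroke-width="1"/></pattern>'
        '<pattern id="hatch2" width="5" height="5" patternUnits="userSpaceOnUse">'
        '<circle cx="2" cy="2" r="1" fill="#000000"/></pattern>'
        '</defs>']
    x = lambda off: (off - min_off) / bp_per_px + 5
    for ri, row in enumerate(rows):
        y = ri * row_height + 6
        for placed in row.genes:
            x0, x1 = x(placed.start_off), x(placed.end_off)
            fill, hatch = _style_fill(styles[group_of[placed.gene.protein_id]]
                                      if placed.gene.protein_id in group_of
                                      else ("gray",))
            head = min(6.0, x1 - x0)
            if placed.strand == "+":
                pts = f"{x0},{y} {x1 - head},{y} {x1},{y + 8} {x1 - head},{y + 16} {x0},{y + 16}"
            else:
                pts = f"{x1},{y} {x0 + head},{y} {x0},{y + 8} {x0 + head},{y + 16} {x1},{y + 16}"
            parts.append(f'<polygon points="{pts}" fill="{fill}" stroke="#333333"'
                         ' stroke-width="0.8"/>')
            if hatch:
                parts.append(f'<polygon points="{pts}" fill="url(#{hatch})"'
                             ' stroke="none"/>')
            if (placed.gene.gene_id == row.anchor_gene_id
                    and row.anchor_hit is not None):
                b0 = x(placed.start_off + 3 * (row.anchor_hit.sstart - 1))
                b1 = x(placed.start_off + 3 * row.anchor_hit.send)
                parts.append(f'<rect x="{b0}" y="{y + 6}" width="{max(b1 - b0, 1)}"'
                             f' height="4" fill="#1f4da0"/>')
        label = row.taxon_label
        if len(row.collapsed_genome_ids) > 1:
            label += f" (x{len(row.collapsed_genome_ids)})"
        parts.append(f'<text x="{width - 160}" y="{y + 12}" font-size="11"'
                     f' font-family="sans-serif">{label}</text>')
    parts.append("</svg>")
    with open(path, "w") as fh:
        fh.write("\n".join(parts) + "\n")
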