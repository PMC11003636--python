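"""Neighborhood extraction, homology grouping, styles, collapsing, trees."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from prokbrowse.align import local_align
from prokbrowse.cluster import greedy_cluster
from prokbrowse.datastore import Database, Gene
from prokbrowse.neighborhood import (N_COLORS, N_HATCHES, assign_styles,
                                     build_guide_tree, collapse_by_species,
                                     extract_neighborhood, gene_spacing,
                                     group_by_homology, render_svg,
                                     sample_homologs, tree_to_newick)

from conftest import bare_database, make_hit, mutate, prot, random_protein


def _toy_db(genes, contig_len=100_000) -> Database:
    """genes: (gene_id, start, end, strand) on genome G1 / contig_1."""
    db = bare_database(["G1"])
    for gid, start, end, strand in genes:
        db.genes[gid] = Gene(gid, "G1", "contig_1", start, end, strand,
                             is_protein_coding=False)
    db.contigs[("G1", "contig_1")] = contig_len
    db.invalidate()
    return db


class TestExtractNeighborhood:
    def test_window_selects_overlapping_genes(self):
        db = _toy_db([("a", 1000, 1900, "+"), ("b", 5000, 5900, "+"),
                      ("c", 40_000, 40_900, "+")])
        row = extract_neighborhood("b", db, window_bp=10_000)
        assert [p.gene.gene_id for p in row.genes] == ["a", "b", "c"][:2]
        assert row.genes[1].start_off == 0

    def test_contig_edge_clips_without_error(self):
        db = _toy_db([("a", 50, 500, "+")], contig_len=600)
        row = extract_neighborhood("a", db, window_bp=10_000)
        assert [p.gene.gene_id for p in row.genes] == ["a"]

    def test_window_zero_keeps_only_overlappers(self):
        db = _toy_db([("a", 1000, 2000, "+"), ("b", 1500, 2500, "+"),
                      ("c", 3000, 3500, "+")])
        row = extract_neighborhood("a", db, window_bp=0)
        assert [p.gene.gene_id for p in row.genes] == ["a", "b"]

    def test_minus_anchor_mirrors_coordinates(self):
        # neighbor upstream in genome coordinates appears to the right
        db = _toy_db([("up", 1000, 1900, "+"), ("anchor", 3000, 3900, "-")])
        row = extract_neighborhood("anchor", db, window_bp=5000)
        offsets = {p.gene.gene_id: p for p in row.genes}
        assert offsets["anchor"].start_off == 0
        assert offsets["anchor"].strand == "+"
        assert offsets["up"].start_off > 0       # flipped to the right
        assert offsets["up"].strand == "-"

    def test_mirrored_genome_renders_identically(self):
        # mirror all coordinates on the contig; re-extraction is identical
        L = 10_000
        genes = [("a", 1000, 1600, "+"), ("anchor", 2000, 2900, "+"),
                 ("b", 3200, 4100, "-")]
        db1 = _toy_db(genes, contig_len=L)
        mirrored = [(gid, L + 1 - end, L + 1 - start,
                     "+" if strand == "-" else "-")
                    for gid, start, end, strand in genes]
        db2 = _toy_db(mirrored, contig_len=L)
        r1 = extract_neighborhood("anchor", db1, window_bp=5000)
        r2 = extract_neighborhood("anchor", db2, window_bp=5000)
        p1 = [(p.gene.gene_id, p.start_off, p.end_off, p.strand) for p in r1.genes]
        p2 = [(p.gene.gene_id, p.start_off, p.end_off, p.strand) for p in r2.genes]
        assert p1 == p2

    def test_missing_anchor_errors(self):
        with pytest.raises(KeyError):
            extract_neighborhood("nope", _toy_db([]))


class TestGroupByHomology:
    def test_identical_proteins_one_group(self):
        rng = np.random.default_rng(0)
        seq = random_protein(rng, 80)
        groups = group_by_homology({"a": prot(seq, "a"), "b": prot(seq, "b")})
        assert groups["a"] == groups["b"]

    def test_low_mutual_coverage_splits(self):
        rng = np.random.default_rng(1)
        core = random_protein(rng, 40)
        # 40-residue shared core in a 100-residue protein: 40% coverage
        a = prot(core + random_protein(rng, 60), "a")
        b = prot(random_protein(rng, 60) + core, "b")
        groups = group_by_homology({"a": a, "b": b})
        assert groups["a"] != groups["b"]

    def test_single_linkage_chain_matches_components_oracle(self):
        rng = np.random.default_rng(2)
        left, right = random_protein(rng, 60), random_protein(rng, 60)
        a = prot(left + random_protein(rng, 10), "a")
        b = prot(left + right, "b")        # bridges a and c
        c = prot(random_protein(rng, 10) + right, "c")
        prots = {"a": a, "b": b, "c": c}
        groups = group_by_homology(prots)
        assert groups["a"] == groups["b"] == groups["c"]
        # oracle: connected components over the 50%-both-coverage link graph
        import networkx as nx
        g = nx.Graph()
        g.add_nodes_from(prots)
        for x, y in itertools.combinations(sorted(prots), 2):
            h = local_align(prots[x], prots[y])
            if h and h.query_cov >= 50 and h.subject_cov >= 50:
                g.add_edge(x, y)
        comps = {n: i for i, comp in enumerate(sorted(nx.connected_components(g),
                                                      key=min)) for n in comp}
        relabel = {}
        for pid in sorted(prots):
            relabel.setdefault(groups[pid], comps[pid])
            assert relabel[groups[pid]] == comps[pid]

    def test_order_independence(self):
        rng = np.random.default_rng(3)
        root = random_protein(rng, 90)
        prots = {f"p{i}": prot(mutate(root, 5, rng), f"p{i}") for i in range(6)}
        g1 = group_by_homology(prots)
        g2 = group_by_homology(dict(reversed(list(prots.items()))))
        assert g1 == g2


class TestAssignStyles:
    def _groups(self, sizes, query_group=0):
        """Build a group_of mapping with the given group sizes."""
        group_of = {}
        n = 0
        for g, size in enumerate(sizes):
            for _ in range(size):
                group_of[f"p{n:03d}"] = g
                n += 1
        return group_of

    def test_query_group_is_white(self):
        styles = assign_styles(self._groups([2, 3, 3]), query_group=0)
        assert styles[0] == ("white",)
        assert styles[1] != styles[2]

    def test_singletons_are_gray_and_consume_no_style(self):
        styles = assign_styles(self._groups([1, 1, 4]), query_group=0)
        assert styles[1] == ("gray",)
        assert styles[2] == (0, 0)  # first style despite group 1 existing

    def test_capacity_is_33_distinct_styles(self):
        sizes = [1] + [2] * 40
        styles = assign_styles(self._groups(sizes), query_group=0)
        distinct = {styles[g] for g in range(1, 34)}
        assert len(distinct) == N_COLORS * N_HATCHES == 33
        # style 34 reuses style 1 (cyclic)
        assert styles[34] == styles[1]

    def test_larger_groups_styled_first(self):
        group_of = self._groups([1, 2, 5, 3], query_group=0)
        styles = assign_styles(group_of, query_group=0)
        assert styles[2] == (0, 0)   # size 5
        assert styles[3] == (1, 0)   # size 3
        assert styles[1] == (2, 0)   # size 2


class TestCollapseBySpecies:
    def _db_with_clusters(self):
        lineages = [("d__B", "p__P", "c__C", "o__O", "f__F", "g__G", sp)
                    for sp in ("s__X", "s__X", "s__Y")]
        db = bare_database(["G1", "G2", "G3"], lineages)
        from prokbrowse.cluster import Cluster
        db.clusters = [
            Cluster("pA", ["pA", "pB"], {"pA": (100, 100, 100),
                                         "pB": (95, 95, 95)}),
            Cluster("pC", ["pC"], {"pC": (100, 100, 100)}),
        ]
        return db

    def test_same_species_same_cluster_merge(self):
        db = self._db_with_clusters()
        hits = [make_hit(subject_id="pA", genome_id="G1", rank=1),
                make_hit(subject_id="pB", genome_id="G2", rank=2)]
        rows = collapse_by_species(hits, db)
        assert len(rows) == 1
        best, genomes = rows[0]
        assert best.rank == 1 and set(genomes) == {"G1", "G2"}

    def test_different_cluster_never_merges(self):
        db = self._db_with_clusters()
        hits = [make_hit(subject_id="pA", genome_id="G1", rank=1),
                make_hit(subject_id="pC", genome_id="G2", rank=2)]
        assert len(collapse_by_species(hits, db)) == 2

    def test_different_species_never_merges(self):
        db = self._db_with_clusters()
        hits = [make_hit(subject_id="pA", genome_id="G1", rank=1),
                make_hit(subject_id="pB", genome_id="G3", rank=2)]
        assert len(collapse_by_species(hits, db)) == 2

    def test_no_cluster_table_disables_with_warning(self):
        db = bare_database(["G1"])
        hits = [make_hit(genome_id="G1")]
        with pytest.warns(UserWarning, match="cluster"):
            rows = collapse_by_species(hits, db)
        assert len(rows) == 1


class TestGeneSpacing:
    def _gene(self, gid, start, end, contig="c1"):
        return Gene(gid, "G1", contig, start, end, "+", False)

    def test_abutting_is_zero(self):
        assert gene_spacing(self._gene("a", 1, 100), self._gene("b", 101, 200)) == 0

    def test_gap_arithmetic(self):
        assert gene_spacing(self._gene("a", 1, 100), self._gene("b", 121, 200)) == 20

    def test_overlap_is_negative(self):
        assert gene_spacing(self._gene("a", 1, 100), self._gene("b", 91, 200)) == -10

    def test_different_contigs_error(self):
        with pytest.raises(ValueError):
            gene_spacing(self._gene("a", 1, 100),
                         self._gene("b", 121, 200, contig="c2"))


class TestGuideTree:
    def test_two_leaves_rooted_at_midpoint(self):
        rng = np.random.default_rng(0)
        a = random_protein(rng, 80)
        b = mutate(a, 16, rng)  # d = 0.2
        tree = build_guide_tree({"a": a, "b": b}, {"a": 100.0, "b": 60.0})
        dists = {t.name: tree.distance(t) for t in tree.tips()}
        assert dists["a"] == pytest.approx(dists["b"])

    def test_midpoint_minimizes_max_root_leaf_distance(self):
        # oracle: max root-to-leaf distance == half the tree diameter
        for seed in range(50):
            rng = np.random.default_rng(100 + seed)
            root = random_protein(rng, 90)
            n = int(rng.integers(4, 8))
            seqs = {f"L{i}": mutate(root, int(rng.integers(4, 36)), rng)
                    for i in range(n)}
            bits = {k: float(rng.integers(50, 300)) for k in seqs}
            tree = build_guide_tree(seqs, bits)
            tips = list(tree.tips())
            maxdist = max(tree.distance(t) for t in tips)
            diameter = max(t1.distance(t2) for t1 in tips for t2 in tips)
            assert maxdist == pytest.approx(diameter / 2, abs=1e-9)

    def test_best_homolog_is_first_leaf(self):
        rng = np.random.default_rng(5)
        root = random_protein(rng, 90)
        seqs = {f"L{i}": mutate(root, 5 * (i + 1), rng) for i in range(5)}
        bits = {f"L{i}": 300.0 - 10 * i for i in range(5)}
        tree = build_guide_tree(seqs, bits)
        first_leaf = next(iter(tree.tips())).name
        assert first_leaf == "L0"

    def test_leaf_set_matches_input(self):
        rng = np.random.default_rng(6)
        root = random_protein(rng, 70)
        seqs = {f"L{i}": mutate(root, 8, rng) for i in range(4)}
        tree = build_guide_tree(seqs, {k: 1.0 for k in seqs})
        assert {t.name for t in tree.tips()} == set(seqs)
        assert tree_to_newick(tree).endswith(";")


class TestSampleHomologs:
    def _hits(self, n=500):
        return [make_hit(subject_id=f"s{i:03d}", genome_id=f"G{i:03d}",
                         rank=i + 1, bit_score=500.0 - i) for i in range(n)]

    def test_top_mode_takes_first_200(self):
        sample = sample_homologs(self._hits(), mode="top", n_max=200)
        assert [h.rank for h in sample] == list(range(1, 201))

    def test_small_eligible_set_returned_whole(self):
        hits = self._hits(20)
        assert len(sample_homologs(hits, mode="random_all", n_max=200, seed=1)) == 20

    def test_seeded_sampling_is_reproducible(self):
        hits = self._hits()
        s1 = sample_homologs(hits, mode="random_all", n_max=50, seed=7)
        s2 = sample_homologs(hits, mode="random_all", n_max=50, seed=7)
        s3 = sample_homologs(hits, mode="random_all", n_max=50, seed=8)
        assert [h.rank for h in s1] == [h.rank for h in s2]
        assert [h.rank for h in s1] != [h.rank for h in s3]

    def test_random_good_filters_by_ratio(self):
        hits = self._hits(100)  # bits 500..401, self score 1000: ratio 0.5..0.4
        sample = sample_homologs(hits, mode="random_good", n_max=200, seed=0,
                                 query_self_score=1500.0)
        # ratio >= 0.3 iff bit >= 450 (ranks 1..51)
        assert all(h.bit_score >= 450 for h in sample)
        assert len(sample) == 51

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            sample_homologs([], mode="bogus")


def test_svg_renders_rows(tmp_path, small_db):
    db = small_db
    coding = [g for g in db.genes.values() if g.is_protein_coding][:1]
    row = extract_neighborhood(coding[0].gene_id, db)
    visible = {p.gene.protein_id: db.proteins[p.gene.protein_id]
               for p in row.genes if p.gene.protein_id}
    group_of = group_by_homology(visible)
    styles = assign_styles(group_of, group_of[coding[0].protein_id])
    out = tmp_path / "view.svg"
    render_svg([row], group_of, styles, str(out))
    text = out.read_text()
    assert text.startswith("<svg") and "polygon" in text
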