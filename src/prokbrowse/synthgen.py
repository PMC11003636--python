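"""Seeded generator of synthetic taxonomies, protein families, and genomes.

The generator emulates the structure that the comparative-database machinery
exploits in real data: a GTDB-style ranked taxonomy, protein families that
diverge with taxonomic distance (substitution-only by default, so identity
ground truth is exact), redundant genomes within species, operons (families
placed adjacently on one strand with small gaps), and an implanted pair of
co-occurring families with a known joint-presence pattern.  Everything is
driven by one seeded NumPy generator and emits plain-text FASTA / GFF3 /
metadata-TSV files plus a machine-readable ground truth, so every other
module can be tested without downloading anything.

Sequence evolution proceeds down the taxonomy: family root -> phylum ->
genus -> species -> genome, substituting an exact fraction of positions at
each step (substituted residues always differ).  Two genomes of one species
therefore differ by about twice the per-genome divergence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .datastore import RANKS

__all__ = ["SimConfig", "ImplantSpec", "GroundTruth", "SimResult",
           "evolve_family", "simulate_genomes"]

AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class ImplantSpec:
    """Joint-presence pattern for one implanted co-occurring family pair."""

    n_both: int = 30
    n_a_only: int = 0
    n_b_only: int = 0
    n_neither: int = 30
    #: fraction of joint-presence genomes where the pair is adjacent,
    #: same strand, within 5 kb (the proximity the co-occurrence view flags)
    proximity_fraction: float = 0.9
    #: implant families evolve this much slower than background families —
    #: functionally coupled genes are conserved, and it keeps every carrier
    #: genome's copy detectable so presence/absence matches the ground truth
    divergence_scale: float = 0.3


@dataclass(frozen=True)
class SimConfig:
    """Shape and rates of a simulated genome collection.

    The defaults describe the order-level benchmark condition: 8 genera x
    3 species x 8 genomes (192 genomes, one taxonomic order), ~150 protein
    families, and within-species pairwise divergence of about 4% (<= 5%), the
    redundancy regime the clustered search is designed for.
    """

    seed: int = 0
    n_phyla: int = 1
    genera_per_phylum: int = 8
    species_per_genus: int = 3
    genomes_per_species: int = 8
    n_families: int = 150
    #: probability a family is present in a genus at all
    family_presence_prob: float = 0.7
    #: probability each genome retains a family present in its genus
    genome_retention_prob: float = 0.95
    # expected substituted fraction on the branch entering each level
    # chosen so adjacent levels land on opposite sides of the field's
    # thresholds: within-species pairs ~96% identity, within-genus ~86%
    # (above the 70% clustering gate), cross-genus ~54% (well below it but
    # still an unambiguous homolog), cross-phylum near the detection floor
    phylum_divergence: float = 0.22
    genus_divergence: float = 0.16
    species_divergence: float = 0.05
    genome_divergence: float = 0.02
    length_range: tuple[int, int] = (90, 180)   # family protein lengths, aa
    operons: tuple[tuple[int, ...], ...] = ((0, 1, 2), (3, 4))
    operon_gap_range: tuple[int, int] = (20, 200)       # bp, within operons
    intergenic_gap_range: tuple[int, int] = (50, 400)   # bp, between blocks
    max_contigs: int = 2
    n_noncoding_per_genome: int = 2
    implant: ImplantSpec | None = None
    #: quality rule -> fraction of genomes made to fail it (disjoint sets)
    fail_fractions: Mapping[str, float] = field(default_factory=dict)

    @property
    def n_genomes(self) -> int:
        return (self.n_phyla * self.genera_per_phylum
                * self.species_per_genus * self.genomes_per_species)

    @classmethod
    def small(cls, seed: int = 0, **kw) -> "SimConfig":
        """A desk-scale fixture: 2 phyla x 2 genera x 1 species x 2 genomes."""
        defaults = dict(seed=seed, n_phyla=2, genera_per_phylum=2,
                        species_per_genus=1, genomes_per_species=2,
                        n_families=12, family_presence_prob=0.9,
                        operons=((0, 1, 2),))
        defaults.update(kw)
        return cls(**defaults)

    @classmethod
    def cooccur_benchmark(cls, seed: int = 0, **kw) -> "SimConfig":
        """60 genomes with an implanted pair jointly present in 30, absent in 30."""
        defaults = dict(seed=seed, n_phyla=2, genera_per_phylum=5,
                        species_per_genus=2, genomes_per_species=3,
                        n_families=15, implant=ImplantSpec())
        defaults.update(kw)
        return cls(**defaults)


@dataclass
class GroundTruth:
    """What the generator actually did, keyed for test assertions."""

    #: genome -> sorted family indices present (implant families included)
    presence: dict[str, list[int]]
    #: gene id -> family index (coding genes only)
    family_of_gene: dict[str, int]
    #: genome -> 7-rank lineage
    taxonomy: dict[str, list[str]]
    #: genome -> quality rule it was made to fail
    quality_fail: dict[str, str]
    #: implant bookkeeping (family indices and genome lists), or None
    implant: dict | None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        d["family_of_gene"] = {k: int(v) for k, v in d["family_of_gene"].items()}
        return cls(**d)

    def species_protein_groups(self) -> dict[tuple, list[str]]:
        """(family, species lineage) -> gene ids; each group should co-cluster."""
        groups: dict[tuple, list[str]] = {}
        for gene_id, fam in sorted(self.family_of_gene.items()):
            genome = gene_id.rsplit("_", 1)[0]
            groups.setdefault((fam, tuple(self.taxonomy[genome])), []).append(gene_id)
        return groups


@dataclass
class SimResult:
    out_dir: Path
    fasta_paths: list[Path]
    gff_paths: list[Path]
    metadata_path: Path
    ground_truth: GroundTruth


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(AA[rng.integers(0, 20, size=length)])


def _mutate(seq: str, fraction: float, rng: np.random.Generator) -> str:
    """Substitute exactly round(fraction * len) distinct positions.

    The replacement residue always differs from the original, so realized
    identity to the input is exactly 1 - fraction (to rounding).
    """
    if not 0 <= fraction < 1:
        raise ValueError(f"divergence fraction must be in [0, 1): {fraction}")
    n_sub = int(round(fraction * len(seq)))
    if n_sub == 0:
        return seq
    positions = rng.choice(len(seq), size=n_sub, replace=False)
    chars = list(seq)
    for pos in positions:
        options = AA[AA != chars[pos]]
        chars[pos] = options[rng.integers(0, len(options))]
    return "".join(chars)


def evolve_family(
    root_sequence: str,
    n_copies: int,
    divergence_fractions: float | Sequence[float],
    seed: int,
) -> list[str]:
    """Derive ``n_copies`` sequences from a root at given divergences.

    ``divergence_fractions`` is a scalar (applied to every copy) or one value
    per copy; each copy's realized identity to the root is exactly
    1 - its divergence (to rounding).
    """
    rng = np.random.default_rng(seed)
    if np.isscalar(divergence_fractions):
        fractions = [float(divergence_fractions)] * n_copies
    else:
        fractions = [float(f) for f in divergence_fractions]
        if len(fractions) != n_copies:
            raise ValueError("need one divergence per copy")
    return [_mutate(root_sequence, f, rng) for f in fractions]


def _lineage(p: int, g: int, s: int) -> tuple[str, ...]:
    return (
        "d__Bacteria",
        f"p__Phy{p + 1:02d}",
        f"c__Cls{p + 1:02d}",
        f"o__Ord{p + 1:02d}",
        f"f__Fam{p + 1:02d}",
        f"g__Gen{p + 1:02d}.{g + 1:02d}",
        f"s__Sp{p + 1:02d}.{g + 1:02d}.{s + 1:02d}",
    )


def simulate_genomes(cfg: SimConfig, out_dir: str | Path) -> SimResult:
    """Generate genomes per ``cfg`` and write FASTA/GFF3/metadata/ground truth.

    Output is byte-identical for a fixed config (one seeded generator, sorted
    iteration everywhere).  Files: ``<assembly>.faa`` + ``<assembly>.gff`` per
    genome, ``metadata.tsv``, ``ground_truth.json``.
    """
    if cfg.n_genomes == 0 or cfg.n_families == 0:
        raise ValueError("config describes an empty collection")
    rng = np.random.default_rng(cfg.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # ---- taxonomy and genome ids ------------------------------------------
    genome_keys: list[tuple[int, int, int, int]] = []  # (phylum, genus, species, idx)
    for p in range(cfg.n_phyla):
        for g in range(cfg.genera_per_phylum):
            for s in range(cfg.species_per_genus):
                for i in range(cfg.genomes_per_species):
                    genome_keys.append((p, g, s, i))
    assembly_ids = [f"G{i + 1:05d}" for i in range(len(genome_keys))]
    lineage_of = {aid: _lineage(p, g, s)
                  for aid, (p, g, s, _i) in zip(assembly_ids, genome_keys)}

    # ---- family presence ---------------------------------------------------
    n_fam_total = cfg.n_families + (2 if cfg.implant else 0)
    fam_a, fam_b = cfg.n_families, cfg.n_families + 1  # implant family indices
    genus_presence: dict[tuple[int, int, int], bool] = {}
    for fam in range(cfg.n_families):
        for p in range(cfg.n_phyla):
            for g in range(cfg.genera_per_phylum):
                genus_presence[(fam, p, g)] = rng.random() < cfg.family_presence_prob
    presence: dict[str, set[int]] = {aid: set() for aid in assembly_ids}
    for aid, (p, g, s, i) in zip(assembly_ids, genome_keys):
        for fam in range(cfg.n_families):
            if genus_presence[(fam, p, g)] and rng.random() < cfg.genome_retention_prob:
                presence[aid].add(fam)
        if not presence[aid]:  # a genome with zero genes breaks the layout
            presence[aid].add(0)

    # ---- implanted co-occurring pair --------------------------------------
    implant_truth = None
    proximal: set[str] = set()
    if cfg.implant:
        sp = cfg.implant
        total = sp.n_both + sp.n_a_only + sp.n_b_only + sp.n_neither
        if total > len(assembly_ids):
            raise ValueError("implant spec covers more genomes than exist")
        shuffled = [assembly_ids[j] for j in rng.permutation(len(assembly_ids))]
        both = sorted(shuffled[: sp.n_both])
        a_only = sorted(shuffled[sp.n_both: sp.n_both + sp.n_a_only])
        b_only = sorted(shuffled[sp.n_both + sp.n_a_only:
                                 sp.n_both + sp.n_a_only + sp.n_b_only])
        neither = sorted(shuffled[sp.n_both + sp.n_a_only + sp.n_b_only: total])
        for aid in both:
            presence[aid] |= {fam_a, fam_b}
        for aid in a_only:
            presence[aid].add(fam_a)
        for aid in b_only:
            presence[aid].add(fam_b)
        n_prox = int(round(sp.proximity_fraction * len(both)))
        proximal = set(both[:n_prox])
        implant_truth = {"family_a": fam_a, "family_b": fam_b, "both": both,
                         "a_only": a_only, "b_only": b_only, "neither": neither,
                         "proximal": sorted(proximal)}

    # ---- sequences: root -> phylum -> genus -> species -> genome ----------
    lengths = rng.integers(cfg.length_range[0], cfg.length_range[1] + 1,
                           size=n_fam_total)
    roots = [_random_protein(rng, int(L)) for L in lengths]

    def _scale(fam: int) -> float:
        if cfg.implant and fam >= cfg.n_families:
            return cfg.implant.divergence_scale
        return 1.0

    phylum_seq = {(f, p): _mutate(roots[f], _scale(f) * cfg.phylum_divergence, rng)
                  for f in range(n_fam_total) for p in range(cfg.n_phyla)}
    genus_seq = {(f, p, g): _mutate(phylum_seq[(f, p)],
                                    _scale(f) * cfg.genus_divergence, rng)
                 for f in range(n_fam_total) for p in range(cfg.n_phyla)
                 for g in range(cfg.genera_per_phylum)}
    species_seq = {(f, p, g, s): _mutate(genus_seq[(f, p, g)],
                                         _scale(f) * cfg.species_divergence, rng)
                   for f in range(n_fam_total) for p in range(cfg.n_phyla)
                   for g in range(cfg.genera_per_phylum)
                   for s in range(cfg.species_per_genus)}

    # ---- per-genome gene layout -------------------------------------------
    fasta_paths, gff_paths = [], []
    metadata_rows: list[dict] = []
    family_of_gene: dict[str, int] = {}
    gap = lambda lo_hi: int(rng.integers(lo_hi[0], lo_hi[1] + 1))

    # quality-failure designations (disjoint)
    quality_fail: dict[str, str] = {}
    if cfg.fail_fractions:
        shuffled = [assembly_ids[j] for j in rng.permutation(len(assembly_ids))]
        pos = 0
        for rule in sorted(cfg.fail_fractions):
            count = int(round(cfg.fail_fractions[rule] * len(assembly_ids)))
            for aid in shuffled[pos: pos + count]:
                quality_fail[aid] = rule
            pos += count

    for aid, (p, g, s, _i) in zip(assembly_ids, genome_keys):
        fams = sorted(presence[aid])
        genome_seqs = {
            f: _mutate(species_seq[(f, p, g, s)],
                       _scale(f) * cfg.genome_divergence, rng)
            for f in fams}

        # blocks: operons (>=2 members present) then singles; implant pair
        # becomes its own same-strand block in designated proximal genomes,
        # and is forced onto opposite strands otherwise so the proximity
        # ground truth is unambiguous.
        blocked: set[int] = set()
        blocks: list[tuple[list[int], str | None]] = []
        if cfg.implant and fam_a in fams and fam_b in fams:
            if aid in proximal:
                blocks.append(([fam_a, fam_b], None))
            else:
                blocks.append(([fam_a], "+"))
                blocks.append(([fam_b], "-"))
            blocked |= {fam_a, fam_b}
        for operon in cfg.operons:
            members = [f for f in operon if f in fams and f not in blocked]
            if len(members) >= 2:
                blocks.append((members, None))
                blocked |= set(members)
        for f in fams:
            if f not in blocked:
                blocks.append(([f], None))
        for _ in range(cfg.n_noncoding_per_genome):
            blocks.append(([-1], None))  # -1 marks a non-coding tRNA gene

        blocks = [blocks[j] for j in rng.permutation(len(blocks))]
        n_contigs = int(rng.integers(1, cfg.max_contigs + 1))
        contig_of_block = rng.integers(0, n_contigs, size=len(blocks))

        genes = []  # (contig, start, end, strand, family)
        contig_len: dict[str, int] = {}
        for ci in range(n_contigs):
            contig = f"contig_{ci + 1}"
            pos = 0
            for bi, (members, forced_strand) in enumerate(blocks):
                if contig_of_block[bi] != ci:
                    continue
                strand = forced_strand or ("+" if rng.random() < 0.5 else "-")
                for j, fam in enumerate(members):
                    pos += gap(cfg.intergenic_gap_range if j == 0
                               else cfg.operon_gap_range)
                    nt_len = 75 if fam == -1 else 3 * (len(genome_seqs[fam]) + 1)
                    start, end = pos + 1, pos + nt_len
                    genes.append((contig, start, end, strand, fam))
                    pos = end
            contig_len[contig] = pos + gap(cfg.intergenic_gap_range)

        genes.sort(key=lambda t: (t[0], t[1]))
        gff_lines = ["##gff-version 3"]
        for contig in sorted(contig_len):
            gff_lines.append(f"##sequence-region {contig} 1 {contig_len[contig]}")
        fasta_records = []
        n_coding = 0
        for j, (contig, start, end, strand, fam) in enumerate(genes, 1):
            gene_id = f"{aid}_{j:04d}"
            if fam >= 0:
                n_coding += 1
                family_of_gene[gene_id] = fam
                fasta_records.append((gene_id, genome_seqs[fam]))
                ftype, product = "CDS", f"family {fam} protein"
            else:
                ftype, product = "tRNA", "tRNA"
            gff_lines.append("\t".join([
                contig, "synthgen", ftype, str(start), str(end), ".", strand,
                "0" if ftype == "CDS" else ".",
                f"ID={gene_id};product={product};locus_tag={gene_id}"]))

        fasta_path = out / f"{aid}.faa"
        with open(fasta_path, "w") as fh:
            for gene_id, seq in fasta_records:
                fh.write(f">{gene_id}\n{seq}\n")
        gff_path = out / f"{aid}.gff"
        gff_path.write_text("\n".join(gff_lines) + "\n")
        fasta_paths.append(fasta_path)
        gff_paths.append(gff_path)

        # ---- metadata (quality fields; failures injected per designation) --
        row = {
            "assembly_id": aid,
            **dict(zip(RANKS, lineage_of[aid])),
            "is_isolate": rng.random() < 0.8,
            "completeness": round(float(rng.uniform(92, 99.9)), 2),
            "contamination": round(float(rng.uniform(0, 4)), 2),
            "is_chimeric": False,
            "mimag_high_quality": True,
            "in_refseq": rng.random() < 0.7,
            "is_type_species": rng.random() < 0.1,
            "is_species_representative": rng.random() < 0.3,
            "in_important_strains": rng.random() < 0.1,
            "largest_scaffold_bp": max(contig_len.values()),
            "n_genes": len(genes),
            "n_protein_coding": n_coding,
        }
        rule = quality_fail.get(aid)
        if rule == "completeness":
            row["completeness"] = round(float(rng.uniform(50, 89.9)), 2)
        elif rule == "contamination":
            row["contamination"] = round(float(rng.uniform(5.1, 15)), 2)
        elif rule == "chimeric":
            row["is_chimeric"] = True
        elif rule == "MIMAG":
            row["is_isolate"] = False
            row["mimag_high_quality"] = False
        elif rule == "coding_fraction":
            row["n_protein_coding"] = int(0.4 * row["n_genes"])
        elif rule is not None:
            raise ValueError(f"unknown quality rule {rule!r} in fail_fractions")
        metadata_rows.append(row)

    metadata_path = out / "metadata.tsv"
    header = list(metadata_rows[0])
    with open(metadata_path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in metadata_rows:
            fh.write("\t".join(str(row[c]) for c in header) + "\n")

    truth = GroundTruth(
        presence={aid: sorted(p_) for aid, p_ in sorted(presence.items())},
        family_of_gene=family_of_gene,
        taxonomy={aid: list(lineage_of[aid]) for aid in assembly_ids},
        quality_fail=quality_fail,
        implant=implant_truth,
    )
    truth.to_json(out / "ground_truth.json")
    return SimResult(out_dir=out, fasta_paths=fasta_paths, gff_paths=gff_paths,
                     metadata_path=metadata_path, ground_truth=truth)
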