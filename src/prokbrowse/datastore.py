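"""Genome/gene/protein data model and persistence.

A :class:`Database` holds annotated genomes (assemblies with a 7-rank GTDB-style
taxonomy and quality metadata), their genes (1-based inclusive coordinates, as
in GFF3), and a *deduplicated* protein table: one :class:`ProteinSeq` record per
distinct amino-acid sequence, shared by every gene that encodes exactly that
sequence.  Deduplication is what makes a "main" database of thousands of
genomes searchable at interactive speed, and the protein count of a database is
therefore the number of distinct sequences, not the number of coding genes.

Databases are persisted to a single SQLite file and can be exported as TSV
tables for interchange.
"""

from __future__ import annotations

import hashlib
import sqlite3
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "RANKS",
    "Taxonomy",
    "GenomeRecord",
    "Gene",
    "ProteinSeq",
    "Database",
    "LoadError",
    "load_genomes",
    "dedupe_proteins",
    "save_database",
    "load_database",
]

#: The seven GTDB taxonomy ranks, most to least inclusive.
RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

SCHEMA_VERSION = 1

#: Amino-acid alphabet accepted throughout: the 20 standard residues plus X.
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: Non-coding feature types retained for neighborhood display.
NONCODING_TYPES = frozenset({"rRNA", "tRNA", "tmRNA", "ncRNA", "pseudogene"})

METADATA_COLUMNS = [
    "assembly_id", "domain", "phylum", "class", "order", "family", "genus",
    "species", "is_isolate", "completeness", "contamination", "is_chimeric",
    "mimag_high_quality", "in_refseq", "is_type_species",
    "is_species_representative", "in_important_strains",
    "largest_scaffold_bp", "n_genes", "n_protein_coding",
]


class LoadError(ValueError):
    """Raised when input files are inconsistent or malformed."""


class Taxonomy(NamedTuple):
    domain: str
    phylum: str
    class_: str
    order: str
    family: str
    genus: str
    species: str

    def rank(self, level: str) -> str:
        """Label at ``level`` (one of :data:`RANKS`)."""
        return self[RANKS.index(level)]

    def lineage(self, level: str) -> tuple[str, ...]:
        """Lineage prefix down to and including ``level``."""
        return tuple(self[: RANKS.index(level) + 1])


@dataclass(frozen=True)
class GenomeRecord:
    """One assembly plus the quality/selection metadata the genome gate reads."""

    assembly_id: str
    taxonomy: Taxonomy
    is_isolate: bool
    completeness: float
    contamination: float
    is_chimeric: bool
    mimag_high_quality: bool
    in_refseq: bool
    is_type_species: bool
    is_species_representative: bool
    in_important_strains: bool
    largest_scaffold_bp: int
    n_genes: int
    n_protein_coding: int

    def __post_init__(self) -> None:
        if not 0 <= self.completeness <= 100:
            raise ValueError(f"completeness out of [0,100]: {self.completeness}")
        if not 0 <= self.contamination <= 100:
            raise ValueError(f"contamination out of [0,100]: {self.contamination}")
        if self.n_protein_coding > self.n_genes:
            raise ValueError("n_protein_coding exceeds n_genes")
        if any(not label for label in self.taxonomy):
            raise ValueError(f"{self.assembly_id}: empty taxonomy rank")


@dataclass(frozen=True)
class Gene:
    """A gene row: 1-based inclusive, stranded coordinates on one contig."""

    gene_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    is_protein_coding: bool
    protein_id: str | None = None
    annotation: str = ""
    locus_tag: str | None = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValueError(f"{self.gene_id}: bad coordinates {self.start}..{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        if self.is_protein_coding != (self.protein_id is not None):
            raise ValueError(f"{self.gene_id}: protein_id present iff protein coding")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ProteinSeq:
    """One distinct amino-acid sequence; ``protein_id`` is a content hash."""

    protein_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty protein sequence")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise ValueError(f"invalid residues {sorted(bad)} in {self.protein_id}")

    @property
    def length(self) -> int:
        return len(self.sequence)


def protein_id_for(sequence: str) -> str:
    """Deterministic content-derived protein identifier."""
    return "P" + hashlib.sha1(sequence.encode()).hexdigest()[:16]


@dataclass
class Database:
    """In-memory comparative database: genomes, genes, deduplicated proteins."""

    name: str = "db"
    genomes: dict[str, GenomeRecord] = field(default_factory=dict)
    genes: dict[str, Gene] = field(default_factory=dict)
    proteins: dict[str, ProteinSeq] = field(default_factory=dict)
    #: (genome_id, contig_id) -> contig length in bp (None if unknown)
    contigs: dict[tuple[str, str], int | None] = field(default_factory=dict)
    #: optional cluster table (list of cluster.Cluster), set by the cluster step
    clusters: list | None = None

    # -- derived indices (built lazily, invalidated on mutation) -------------
    def __post_init__(self) -> None:
        self._indices = None

    def invalidate(self) -> None:
        self._indices = None

    def _build_indices(self):
        genes_of_protein: dict[str, list[str]] = {}
        genes_by_genome: dict[str, list[str]] = {g: [] for g in self.genomes}
        for gid in sorted(self.genes):
            gene = self.genes[gid]
            genes_by_genome.setdefault(gene.genome_id, []).append(gid)
            if gene.protein_id is not None:
                genes_of_protein.setdefault(gene.protein_id, []).append(gid)
        genomes_of_protein = {
            pid: sorted({self.genes[g].genome_id for g in gids})
            for pid, gids in genes_of_protein.items()
        }
        self._indices = (genes_of_protein, genes_by_genome, genomes_of_protein)

    @property
    def n_genomes(self) -> int:
        return len(self.genomes)

    @property
    def total_residues(self) -> int:
        """Total residues across distinct proteins (the search-space size)."""
        return sum(p.length for p in self.proteins.values())

    def genes_of_protein(self, protein_id: str) -> list[str]:
        if self._indices is None:
            self._build_indices()
        return self._indices[0].get(protein_id, [])

    def genes_in_genome(self, genome_id: str) -> list[str]:
        if self._indices is None:
            self._build_indices()
        return self._indices[1].get(genome_id, [])

    def genomes_of_protein(self, protein_id: str) -> list[str]:
        if self._indices is None:
            self._build_indices()
        return self._indices[2].get(protein_id, [])

    def genes_on_contig(self, genome_id: str, contig_id: str) -> list[Gene]:
        """Genes on one contig sorted by start coordinate."""
        out = [self.genes[g] for g in self.genes_in_genome(genome_id)
               if self.genes[g].contig_id == contig_id]
        return sorted(out, key=lambda g: (g.start, g.end, g.gene_id))

    def cluster_of_protein(self) -> dict[str, str]:
        """member protein_id -> representative protein_id (requires clusters)."""
        if self.clusters is None:
            raise ValueError("database has no cluster table; run clustering first")
        mapping: dict[str, str] = {}
        for cl in self.clusters:
            for m in cl.member_ids:
                mapping[m] = cl.rep_id
        return mapping

    # -- validation & export -------------------------------------------------
    def validate(self) -> None:
        for gene in self.genes.values():
            if gene.genome_id not in self.genomes:
                raise LoadError(f"gene {gene.gene_id}: unknown genome {gene.genome_id}")
            if gene.protein_id is not None and gene.protein_id not in self.proteins:
                raise LoadError(f"gene {gene.gene_id}: unknown protein {gene.protein_id}")
        referenced = {g.protein_id for g in self.genes.values() if g.protein_id}
        orphans = set(self.proteins) - referenced
        if orphans:
            raise LoadError(f"{len(orphans)} proteins referenced by no gene")

    def genomes_frame(self) -> pd.DataFrame:
        rows = []
        for aid in sorted(self.genomes):
            g = self.genomes[aid]
            rows.append({
                "assembly_id": aid,
                **{r: g.taxonomy[i] for i, r in enumerate(RANKS)},
                "is_isolate": g.is_isolate, "completeness": g.completeness,
                "contamination": g.contamination, "is_chimeric": g.is_chimeric,
                "mimag_high_quality": g.mimag_high_quality, "in_refseq": g.in_refseq,
                "is_type_species": g.is_type_species,
                "is_species_representative": g.is_species_representative,
                "in_important_strains": g.in_important_strains,
                "largest_scaffold_bp": g.largest_scaffold_bp,
                "n_genes": g.n_genes, "n_protein_coding": g.n_protein_coding,
            })
        return pd.DataFrame(rows, columns=METADATA_COLUMNS)

    def genes_frame(self) -> pd.DataFrame:
        rows = [{
            "gene_id": g.gene_id, "genome_id": g.genome_id, "contig_id": g.contig_id,
            "start": g.start, "end": g.end, "strand": g.strand,
            "is_protein_coding": g.is_protein_coding,
            "protein_id": g.protein_id or "", "annotation": g.annotation,
            "locus_tag": g.locus_tag or "",
        } for _, g in sorted(self.genes.items())]
        return pd.DataFrame(rows, columns=["gene_id", "genome_id", "contig_id",
                                           "start", "end", "strand",
                                           "is_protein_coding", "protein_id",
                                           "annotation", "locus_tag"])

    def proteins_frame(self) -> pd.DataFrame:
        rows = [{"protein_id": pid, "length": p.length, "sequence": p.sequence}
                for pid, p in sorted(self.proteins.items())]
        return pd.DataFrame(rows, columns=["protein_id", "length", "sequence"])

    def export_tsv(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.genomes_frame().to_csv(out / "genomes.tsv", sep="\t", index=False)
        self.genes_frame().to_csv(out / "genes.tsv", sep="\t", index=False)
        self.proteins_frame().to_csv(out / "proteins.tsv", sep="\t", index=False)

    def equals(self, other: "Database") -> bool:
        return (self.genomes == other.genomes and self.genes == other.genes
                and self.proteins == other.proteins and self.contigs == other.contigs)


# ---------------------------------------------------------------------------
# parsing


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in ("1", "true", "t", "yes"):
        return True
    if s in ("0", "false", "f", "no"):
        return False
    raise LoadError(f"cannot parse boolean value {value!r}")


def read_metadata(path: str | Path) -> dict[str, GenomeRecord]:
    """Read the UTF-8 metadata TSV into :class:`GenomeRecord` objects.

    Unknown columns are ignored (a warning is printed); missing required
    columns are a hard error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise LoadError(f"{path}: missing metadata columns {missing}")
    extra = [c for c in df.columns if c not in METADATA_COLUMNS]
    if extra:
        import warnings
        warnings.warn(f"{path}: ignoring unknown metadata columns {extra}")
    records: dict[str, GenomeRecord] = {}
    for _, row in df.iterrows():
        aid = row["assembly_id"]
        records[aid] = GenomeRecord(
            assembly_id=aid,
            taxonomy=Taxonomy(*[row[r] for r in RANKS]),
            is_isolate=_parse_bool(row["is_isolate"]),
            completeness=float(row["completeness"]),
            contamination=float(row["contamination"]),
            is_chimeric=_parse_bool(row["is_chimeric"]),
            mimag_high_quality=_parse_bool(row["mimag_high_quality"]),
            in_refseq=_parse_bool(row["in_refseq"]),
            is_type_species=_parse_bool(row["is_type_species"]),
            is_species_representative=_parse_bool(row["is_species_representative"]),
            in_important_strains=_parse_bool(row["in_important_strains"]),
            largest_scaffold_bp=int(row["largest_scaffold_bp"]),
            n_genes=int(row["n_genes"]),
            n_protein_coding=int(row["n_protein_coding"]),
        )
    return records


def _parse_gff_attributes(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def parse_gff3(path: str | Path, genome_id: str):
    """Parse one GFF3 file.

    Returns ``(rows, contig_lengths)`` where rows are dicts with gene fields
    (protein_id unresolved).  Coordinates are kept 1-based inclusive as in the
    file.  Malformed lines raise :class:`LoadError` naming file and line.
    """
    rows = []
    contig_lengths: dict[str, int | None] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    contig_lengths[parts[1]] = int(parts[3])
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise LoadError(f"{path}:{lineno}: expected 9 tab-separated columns")
            contig, _src, ftype, start, end, _score, strand, _frame, attrs = fields
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise LoadError(f"{path}:{lineno}: non-integer coordinates") from None
            if strand not in ("+", "-"):
                raise LoadError(f"{path}:{lineno}: bad strand {strand!r}")
            if ftype == "region":
                contig_lengths.setdefault(contig, end_i)
                continue
            if ftype != "CDS" and ftype not in NONCODING_TYPES:
                continue  # skip 'gene' wrappers and other feature types
            attr = _parse_gff_attributes(attrs)
            gene_id = attr.get("ID")
            if not gene_id:
                raise LoadError(f"{path}:{lineno}: feature without ID attribute")
            contig_lengths.setdefault(contig, None)
            rows.append({
                "gene_id": gene_id, "genome_id": genome_id, "contig_id": contig,
                "start": start_i, "end": end_i, "strand": strand,
                "is_protein_coding": ftype == "CDS",
                "annotation": attr.get("product", ""),
                "locus_tag": attr.get("locus_tag"),
            })
    return rows, contig_lengths


def dedupe_proteins(
    sequences_by_gene: Mapping[str, str],
) -> tuple[dict[str, ProteinSeq], dict[str, str]]:
    """Collapse exact-duplicate sequences to one record per distinct sequence.

    Returns ``(proteins, gene_to_protein)``.  Protein identifiers are content
    hashes, so the mapping is deterministic across runs and input orders.
    """
    proteins: dict[str, ProteinSeq] = {}
    mapping: dict[str, str] = {}
    for gene_id in sorted(sequences_by_gene):
        seq = sequences_by_gene[gene_id]
        if not seq:
            raise LoadError(f"gene {gene_id}: empty protein sequence")
        pid = protein_id_for(seq)
        if pid not in proteins:
            proteins[pid] = ProteinSeq(pid, seq)
        elif proteins[pid].sequence != seq:  # pragma: no cover - hash collision
            raise LoadError(f"protein id collision on {pid}")
        mapping[gene_id] = pid
    return proteins, mapping


def load_genomes(
    fasta_paths: Sequence[str | Path],
    gff_paths: Sequence[str | Path],
    metadata_path: str | Path,
    name: str = "db",
    order: str | None = None,
) -> Database:
    """Build a :class:`Database` from protein FASTAs, GFF3s, and metadata.

    FASTA and GFF files are matched by filename stem, which is the assembly id
    and must have a row in the metadata table.  FASTA record ids are gene ids.
    ``order`` restricts the database to assemblies of one taxonomic order
    (an order-level sub-database).
    """
    fasta_by_stem = {Path(p).stem: Path(p) for p in fasta_paths}
    gff_by_stem = {Path(p).stem: Path(p) for p in gff_paths}
    if set(fasta_by_stem) != set(gff_by_stem):
        raise LoadError(
            f"FASTA/GFF assembly sets differ: {sorted(set(fasta_by_stem) ^ set(gff_by_stem))}")
    metadata = read_metadata(metadata_path)
    db = Database(name=name)
    for stem in sorted(fasta_by_stem):
        if stem not in metadata:
            raise LoadError(f"no metadata row for assembly {stem!r}")
        record = metadata[stem]
        if order is not None and record.taxonomy.order != order:
            continue
        db.genomes[stem] = record
        gene_rows, contig_lengths = parse_gff3(gff_by_stem[stem], stem)
        for contig, length in contig_lengths.items():
            db.contigs[(stem, contig)] = length
        with open(fasta_by_stem[stem]) as fh:
            seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}
        coding = {}
        for row in gene_rows:
            if row["is_protein_coding"]:
                if row["gene_id"] not in seqs:
                    raise LoadError(
                        f"CDS gene {row['gene_id']} has no protein FASTA entry in {fasta_by_stem[stem]}")
                coding[row["gene_id"]] = seqs[row["gene_id"]]
        proteins, mapping = dedupe_proteins(coding)
        for pid, prot in proteins.items():
            db.proteins.setdefault(pid, prot)
        for row in gene_rows:
            gid = row.pop("gene_id")
            if gid in db.genes:
                raise LoadError(f"duplicate gene id {gid}")
            db.genes[gid] = Gene(gene_id=gid, protein_id=mapping.get(gid), **row)
    db.validate()
    db.invalidate()
    return db


# ---------------------------------------------------------------------------
# persistence (single-file SQLite)

_TABLES = """
CREATE TABLE meta (key TEXT PRIMARY KEY, value TEXT);
CREATE TABLE genomes (
    assembly_id TEXT PRIMARY KEY, domain TEXT, phylum TEXT, class TEXT,
    "order" TEXT, family TEXT, genus TEXT, species TEXT,
    is_isolate INTEGER, completeness REAL, contamination REAL,
    is_chimeric INTEGER, mimag_high_quality INTEGER, in_refseq INTEGER,
    is_type_species INTEGER, is_species_representative INTEGER,
    in_important_strains INTEGER, largest_scaffold_bp INTEGER,
    n_genes INTEGER, n_protein_coding INTEGER);
CREATE TABLE genes (
    gene_id TEXT PRIMARY KEY, genome_id TEXT, contig_id TEXT,
    start INTEGER, end INTEGER, strand TEXT, is_protein_coding INTEGER,
    protein_id TEXT, annotation TEXT, locus_tag TEXT);
CREATE TABLE proteins (protein_id TEXT PRIMARY KEY, sequence TEXT);
CREATE TABLE contigs (genome_id TEXT, contig_id TEXT, length INTEGER,
    PRIMARY KEY (genome_id, contig_id));
CREATE TABLE clusters (rep_id TEXT, member_id TEXT, identity REAL,
    cov_member REAL, cov_rep REAL, member_order INTEGER);
"""


def save_database(db: Database, path: str | Path) -> None:
    """Persist ``db`` losslessly to a single SQLite file (overwrites)."""
    path = Path(path)
    if path.exists():
        path.unlink()
    con = sqlite3.connect(path)
    try:
        con.executescript(_TABLES)
        con.execute("INSERT INTO meta VALUES ('schema_version', ?)", (str(SCHEMA_VERSION),))
        con.execute("INSERT INTO meta VALUES ('name', ?)", (db.name,))
        for aid in sorted(db.genomes):
            g = db.genomes[aid]
            con.execute(
                "INSERT INTO genomes VALUES (" + ",".join("?" * 20) + ")",
                (aid, *g.taxonomy, int(g.is_isolate), g.completeness,
                 g.contamination, int(g.is_chimeric), int(g.mimag_high_quality),
                 int(g.in_refseq), int(g.is_type_species),
                 int(g.is_species_representative), int(g.in_important_strains),
                 g.largest_scaffold_bp, g.n_genes, g.n_protein_coding))
        for gid in sorted(db.genes):
            g = db.genes[gid]
            con.execute("INSERT INTO genes VALUES (?,?,?,?,?,?,?,?,?,?)",
                        (gid, g.genome_id, g.contig_id, g.start, g.end, g.strand,
                         int(g.is_protein_coding), g.protein_id, g.annotation,
                         g.locus_tag))
        for pid in sorted(db.proteins):
            con.execute("INSERT INTO proteins VALUES (?,?)", (pid, db.proteins[pid].sequence))
        for (gid, cid) in sorted(db.contigs):
            con.execute("INSERT INTO contigs VALUES (?,?,?)", (gid, cid, db.contigs[(gid, cid)]))
        if db.clusters is not None:
            for cl in db.clusters:
                for i, m in enumerate(cl.member_ids):
                    ident, cm, cr = cl.member_stats[m]
                    con.execute("INSERT INTO clusters VALUES (?,?,?,?,?,?)",
                                (cl.rep_id, m, ident, cm, cr, i))
        con.commit()
    finally:
        con.close()


def load_database(path: str | Path) -> Database:
    """Load a database written by :func:`save_database`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    con = sqlite3.connect(path)
    try:
        version = dict(con.execute("SELECT key, value FROM meta"))
        if int(version.get("schema_version", -1)) != SCHEMA_VERSION:
            raise LoadError(
                f"{path}: on-disk schema version {version.get('schema_version')} "
                f"!= supported {SCHEMA_VERSION}")
        db = Database(name=version.get("name", "db"))
        for row in con.execute("SELECT * FROM genomes ORDER BY assembly_id"):
            (aid, *tax, iso, comp, cont, chim, mimag, refseq, typesp, sprep,
             imp, scaf, ng, npc) = row
            db.genomes[aid] = GenomeRecord(
                aid, Taxonomy(*tax), bool(iso), comp, cont, bool(chim),
                bool(mimag), bool(refseq), bool(typesp), bool(sprep), bool(imp),
                scaf, ng, npc)
        for row in con.execute("SELECT * FROM genes ORDER BY gene_id"):
            gid, genome, contig, start, end, strand, coding, pid, ann, lt = row
            db.genes[gid] = Gene(gid, genome, contig, start, end, strand,
                                 bool(coding), pid, ann, lt)
        for pid, seq in con.execute("SELECT * FROM proteins ORDER BY protein_id"):
            db.proteins[pid] = ProteinSeq(pid, seq)
        for gid, cid, length in con.execute("SELECT * FROM contigs"):
            db.contigs[(gid, cid)] = length
        cluster_rows = list(con.execute(
            "SELECT rep_id, member_id, identity, cov_member, cov_rep, member_order "
            "FROM clusters ORDER BY rep_id, member_order"))
        if cluster_rows:
            from .cluster import Cluster
            by_rep: dict[str, list] = {}
            for rep, member, ident, cm, cr, _i in cluster_rows:
                by_rep.setdefault(rep, []).append((member, ident, cm, cr))
            db.clusters = [
                Cluster(rep_id=rep,
                        member_ids=[m for m, *_ in members],
                        member_stats={m: (i_, cm, cr) for m, i_, cm, cr in members})
                for rep, members in sorted(by_rep.items())
            ]
        db.invalidate()
        return db
    finally:
        con.close()
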