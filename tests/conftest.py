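"""Shared fixtures: small synthetic databases and hit-construction helpers."""

from __future__ import annotations

import numpy as np
import pytest

from prokbrowse.align import Hit
from prokbrowse.datastore import (Database, Gene, GenomeRecord, ProteinSeq,
                                  Taxonomy, load_genomes, protein_id_for)
from prokbrowse.synthgen import SimConfig, simulate_genomes

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(AA[i] for i in rng.integers(0, 20, size=length))


def mutate(seq: str, n_sub: int, rng: np.random.Generator) -> str:
    """Substitute exactly n_sub positions (replacement always differs)."""
    chars = list(seq)
    for pos in rng.choice(len(seq), size=n_sub, replace=False):
        options = [a for a in AA if a != chars[pos]]
        chars[pos] = options[rng.integers(0, len(options))]
    return "".join(chars)


def prot(seq: str, pid: str | None = None) -> ProteinSeq:
    return ProteinSeq(pid or protein_id_for(seq), seq)


def make_hit(query_id="q", subject_id="s", genome_id="G1", rank=1,
             bit_score=100.0, e_value=1e-10, pct_identity=50.0,
             query_cov=80.0, subject_cov=80.0, qstart=1, qend=50,
             sstart=1, send=50) -> Hit:
    return Hit(query_id=query_id, subject_id=subject_id, raw_score=0.0,
               bit_score=bit_score, e_value=e_value, pct_identity=pct_identity,
               query_cov=query_cov, subject_cov=subject_cov, qstart=qstart,
               qend=qend, sstart=sstart, send=send,
               subject_genome_id=genome_id, rank=rank)


def make_genome(aid: str, lineage=None, **kw) -> GenomeRecord:
    lineage = lineage or ("d__B", "p__P1", "c__C1", "o__O1", "f__F1",
                          "g__G1", f"s__{aid}")
    defaults = dict(is_isolate=True, completeness=98.0, contamination=1.0,
                    is_chimeric=False, mimag_high_quality=True, in_refseq=True,
                    is_type_species=False, is_species_representative=False,
                    in_important_strains=False, largest_scaffold_bp=1_000_000,
                    n_genes=100, n_protein_coding=95)
    defaults.update(kw)
    return GenomeRecord(assembly_id=aid, taxonomy=Taxonomy(*lineage), **defaults)


def bare_database(genome_ids, lineages=None) -> Database:
    """A database of genomes only (no genes/proteins) for statistics tests."""
    db = Database(name="bare")
    for i, aid in enumerate(genome_ids):
        lineage = lineages[i] if lineages else None
        db.genomes[aid] = make_genome(aid, lineage)
    return db


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    out = tmp_path_factory.mktemp("smallsim")
    return simulate_genomes(SimConfig.small(seed=11), out)


@pytest.fixture(scope="session")
def small_db(small_sim):
    return load_genomes(small_sim.fasta_paths, small_sim.gff_paths,
                        small_sim.metadata_path, name="small")
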