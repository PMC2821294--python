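"""Data model and I/O for annotated genomes.

A :class:`Genome` is a set of replicons, each carrying an ordered list of
protein-coding :class:`GeneFeature` records with 1-based inclusive
coordinates (GFF3 convention).  Only protein-coding features matter here:
the downstream analyses are about gene neighborhoods and protein families,
not nucleotide sequence.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


class ParseError(ValueError):
    """Malformed input file."""


class DatasetError(ValueError):
    """Inputs are individually well-formed but mutually inconsistent."""


@dataclass(frozen=True)
class GeneFeature:
    """A protein-coding gene on a replicon.

    Coordinates are 1-based inclusive; ``strand`` is ``'+'`` or ``'-'``.
    """

    gene_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    protein_seq: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"{self.gene_id}: invalid coordinates {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.protein_seq:
            raise ValueError(f"{self.gene_id}: empty protein sequence")
        bad = set(self.protein_seq) - PROTEIN_ALPHABET
        if bad:
            raise ValueError(
                f"{self.gene_id}: residues outside alphabet: {sorted(bad)}"
            )


@dataclass
class Replicon:
    replicon_id: str
    length: int
    circular: bool = False
    genes: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.end, g.gene_id))
        for g in self.genes:
            if g.end > self.length:
                raise ValueError(
                    f"{g.gene_id} ends at {g.end} beyond replicon "
                    f"{self.replicon_id} length {self.length}"
                )


@dataclass
class Genome:
    genome_id: str
    taxon_label: str
    replicons: list[Replicon]

    def __post_init__(self) -> None:
        if not self.replicons:
            raise ValueError(f"{self.genome_id}: genome needs at least one replicon")

    @property
    def genes(self) -> list[GeneFeature]:
        """All genes, replicon by replicon, in positional order."""
        return [g for rep in self.replicons for g in rep.genes]

    def gene(self, gene_id: str) -> GeneFeature:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


def _locate_bad_gff_line(path: str) -> int | None:
    """Best-effort scan for the first structurally bad GFF3 body line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                return lineno
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError:
                return lineno
            if start < 1 or end < start:
                return lineno
    return None


def parse_genome(
    gff3_path: str,
    fasta_path: str,
    genome_id: str | None = None,
    taxon_label: str | None = None,
    circular: bool = False,
    max_id_mismatch: float = 0.2,
) -> Genome:
    """Parse a GFF3 + protein-FASTA pair into a :class:`Genome`.

    CDS features (falling back to ``gene`` features when a file carries no
    CDS) are matched to FASTA records by their ``ID`` attribute.  Features
    without a protein sequence are dropped with a warning; if the dropped
    fraction exceeds ``max_id_mismatch`` the inputs are considered to be
    from different annotations and a :class:`DatasetError` is raised.
    """
    try:
        db = gffutils.create_db(
            gff3_path, ":memory:", merge_strategy="create_unique", force=True
        )
    except Exception as exc:  # gffutils raises bare ValueError etc.
        if "No lines parsed" in str(exc):
            raise ParseError(f"{gff3_path}: no features") from exc
        lineno = _locate_bad_gff_line(gff3_path)
        where = f" at line {lineno}" if lineno is not None else ""
        raise ParseError(f"malformed GFF3 in {gff3_path}{where}: {exc}") from exc

    feats = list(db.features_of_type("CDS"))
    if not feats:
        feats = list(db.features_of_type("gene"))
    if not feats:
        raise ParseError(f"{gff3_path}: no features")

    proteins = {rec.id: str(rec.seq) for rec in SeqIO.parse(fasta_path, "fasta")}

    seq_regions: dict[str, int] = {}
    for directive in db.directives:
        parts = directive.split()
        if parts and parts[0] == "sequence-region" and len(parts) >= 4:
            seq_regions[parts[1]] = int(parts[3])

    by_replicon: dict[str, list[GeneFeature]] = {}
    n_dropped = 0
    for feat in feats:
        fid = feat.attributes.get("ID", [feat.id])[0]
        seq = proteins.get(fid)
        if seq is None:
            n_dropped += 1
            logger.warning("%s: no protein sequence for %s; dropped", gff3_path, fid)
            continue
        gene = GeneFeature(
            gene_id=fid,
            replicon_id=feat.seqid,
            start=feat.start,
            end=feat.end,
            strand=feat.strand if feat.strand in ("+", "-") else "+",
            protein_seq=seq,
        )
        by_replicon.setdefault(feat.seqid, []).append(gene)

    if n_dropped / len(feats) > max_id_mismatch:
        raise DatasetError(
            f"{gff3_path} vs {fasta_path}: {n_dropped}/{len(feats)} features "
            f"lack protein sequences (ID mismatch above {max_id_mismatch:.0%})"
        )

    replicons = []
    for rep_id, genes in sorted(by_replicon.items()):
        length = seq_regions.get(rep_id) or max(g.end for g in genes)
        replicons.append(
            Replicon(replicon_id=rep_id, length=length, circular=circular, genes=genes)
        )
    gid = genome_id or os.path.splitext(os.path.basename(gff3_path))[0]
    return Genome(genome_id=gid, taxon_label=taxon_label or gid, replicons=replicons)


def write_genome(genome: Genome, gff3_path: str, fasta_path: str) -> None:
    """Write a Genome back to GFF3 + protein FASTA (round-trip safe)."""
    with open(gff3_path, "w") as gff:
        gff.write("##gff-version 3\n")
        for rep in genome.replicons:
            gff.write(f"##sequence-region {rep.replicon_id} 1 {rep.length}\n")
        for rep in genome.replicons:
            for g in rep.genes:
                gff.write(
                    f"{rep.replicon_id}\tefpmod\tCDS\t{g.start}\t{g.end}\t.\t"
                    f"{g.strand}\t0\tID={g.gene_id}\n"
                )
    records = [
        SeqRecord(Seq(g.protein_seq), id=g.gene_id, description="")
        for rep in genome.replicons
        for g in rep.genes
    ]
    SeqIO.write(records, fasta_path, "fasta")


def gene_order_index(genome: Genome) -> dict[str, tuple[str, int]]:
    """Map gene_id -> (replicon_id, ordinal), ordinals 0..n-1 per replicon."""
    index: dict[str, tuple[str, int]] = {}
    for rep in genome.replicons:
        for pos, g in enumerate(rep.genes):
            if g.gene_id in index:
                raise ValueError(f"duplicate gene_id {g.gene_id!r} in {genome.genome_id}")
            index[g.gene_id] = (rep.replicon_id, pos)
    return index


def genome_summary_tsv(genomes: list[Genome], path: str) -> None:
    """Per-replicon gene counts, one row per replicon."""
    with open(path, "w") as fh:
        fh.write("genome_id\treplicon\tn_genes\n")
        for genome in genomes:
            for rep in genome.replicons:
                fh.write(f"{genome.genome_id}\t{rep.replicon_id}\t{len(rep.genes)}\n")
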