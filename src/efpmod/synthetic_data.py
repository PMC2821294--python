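"""Synthetic genomes and alignments with known ground truth.

The generator emulates the structure of the real dataset the analysis was
designed for: a panel of annotated bacterial genomes in which every
genome carries ``efp``, a configurable fraction carries the ``yjeA``/
``yjeK`` pair, the pair-carrying genomes split into the three arrangement
categories (three-gene operon / pairwise cluster / no clustering) in set
proportions, and the residue at the EF-P anchor position correlates with
pair presence.  Defaults reproduce the reported study conditions: 725
genomes, 200 with both genes (plus 2 yjeA-only genomes, the two known
symbiont exceptions), a 31/60/9 arrangement mix, 97% Lys at the anchor in
the with-pair stratum and a 70/24.1/3.4/2.2/0.3 Lys/Arg/Met/Asn/Gln mix
without it.

Every genome gets its own RNG stream derived from (seed, genome index),
so any subset of genomes is reproducible in isolation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .genome_model import GeneFeature, Genome, Replicon, write_genome
from .phylo import AA_ORDER, JTT_FREQS, ProteinAlignment, jtt_transition
from .references import (
    EFP_ANCHOR_POSITION,
    mutate_jtt,
    reference_families,
)

CATEGORIES = ("three_gene_operon", "pairwise_cluster", "no_cluster")
PAIR_CHOICES = ("efp_yjeA", "efp_yjeK", "yjeA_yjeK")

# residue mixes at the EF-P anchor position (paper-reported conditions)
DEFAULT_RESIDUE_MIX_WITH = {"K": 0.97, "A": 0.015, "H": 0.015}
DEFAULT_RESIDUE_MIX_WITHOUT = {"K": 0.70, "R": 0.241, "M": 0.034, "N": 0.022, "Q": 0.003}


@dataclass
class SimulationConfig:
    n_genomes: int = 725
    p_both: float = 200 / 725
    p_onlyA: float = 2 / 725        # yjeA without yjeK: the two symbiont cases
    p_onlyB: float = 0.0
    clustering_mix: tuple[float, float, float] = (0.31, 0.60, 0.09)
    residue_mix_with: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RESIDUE_MIX_WITH)
    )
    residue_mix_without: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RESIDUE_MIX_WITHOUT)
    )
    p_lam: float = 0.25             # chance a genome carries an ablA/ablB cluster
    mutation_distance: float = 0.3  # JTT distance of planted genes from references
    decoy_range: tuple[int, int] = (20, 60)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 1:
            raise ValueError("n_genomes must be >= 1")
        if self.p_both + self.p_onlyA + self.p_onlyB > 1 + 1e-9:
            raise ValueError("presence probabilities exceed 1")
        for name, mix in (
            ("clustering_mix", self.clustering_mix),
            ("residue_mix_with", tuple(self.residue_mix_with.values())),
            ("residue_mix_without", tuple(self.residue_mix_without.values())),
        ):
            if abs(sum(mix) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")

    @property
    def p_neither(self) -> float:
        return 1.0 - self.p_both - self.p_onlyA - self.p_onlyB


@dataclass
class SimulationResult:
    genomes: list[Genome]
    truth: pd.DataFrame  # one row per genome, planted ground truth

    def write_files(self, outdir: str) -> dict[str, tuple[str, str]]:
        """Write GFF3+FASTA per genome; returns genome_id -> (gff, faa)."""
        os.makedirs(outdir, exist_ok=True)
        paths = {}
        for genome in self.genomes:
            gff = os.path.join(outdir, f"{genome.genome_id}.gff3")
            faa = os.path.join(outdir, f"{genome.genome_id}.faa")
            write_genome(genome, gff, faa)
            paths[genome.genome_id] = (gff, faa)
        return paths

    def write_family_table(self, path: str) -> None:
        """Per-genome family table in the accession-or-blank dialect."""
        with open(path, "w") as fh:
            fh.write("genome_id\ttaxon\tefp\tyjeA\tyjeK\tablA\tablB\tclustering\n")
            for _, row in self.truth.iterrows():
                if row.category == "three_gene_operon":
                    annotation = "operon"
                elif row.category == "pairwise_cluster":
                    annotation = f"pair:{row.pair}"
                elif row.category == "no_cluster":
                    annotation = "none"
                else:
                    annotation = ""
                fh.write(
                    f"{row.genome_id}\t{row.genome_id}\t{row.efp_acc}\t"
                    f"{row.yjeA_acc}\t{row.yjeK_acc}\t{row.ablA_acc}\t"
                    f"{row.ablB_acc}\t{annotation}\n"
                )

    def efp_sequences(self, with_pair: bool) -> list[tuple[str, str]]:
        """(genome_id, EF-P protein) for the chosen stratum — the dialect
        of the published EF-P sequence lists."""
        rows = self.truth[self.truth.has_pair == with_pair]
        wanted = set(rows.genome_id)
        out = []
        for genome in self.genomes:
            if genome.genome_id not in wanted:
                continue
            acc = self.truth.set_index("genome_id").loc[genome.genome_id, "efp_acc"]
            out.append((genome.genome_id, genome.gene(acc).protein_seq))
        return out

    def write_efp_fasta(self, path: str, with_pair: bool) -> None:
        with open(path, "w") as fh:
            for gid, seq in self.efp_sequences(with_pair):
                fh.write(f">{gid}_efp\n{seq}\n")


def _draw_residue(rng: np.random.Generator, mix: dict[str, float]) -> str:
    residues = sorted(mix)
    probs = np.array([mix[r] for r in residues])
    return residues[rng.choice(len(residues), p=probs / probs.sum())]


def _planted_gene(
    family: str, rng: np.random.Generator, distance: float, anchor_residue: str | None
) -> str:
    """A family member: the family's first reference evolved by ``distance``
    substitutions/site; EF-P keeps its motif window intact except for the
    planted anchor residue."""
    _, ancestor = reference_families()[family][0]
    if family == "efp":
        frozen = set(range(EFP_ANCHOR_POSITION - 5, EFP_ANCHOR_POSITION + 4))
        seq = mutate_jtt(ancestor, distance, rng, frozen=frozen)
        if anchor_residue is not None:
            seq = seq[: EFP_ANCHOR_POSITION - 1] + anchor_residue + seq[EFP_ANCHOR_POSITION:]
        return seq
    return mutate_jtt(ancestor, distance, rng)


def _decoy(rng: np.random.Generator) -> str:
    """Shuffled residues of a random reference — same composition, no
    recognizable homology."""
    families = sorted(reference_families())
    fam = families[rng.integers(len(families))]
    _, seq = reference_families()[fam][rng.integers(len(reference_families()[fam]))]
    arr = np.array(list(seq))
    rng.shuffle(arr)
    return "".join(arr)


# assembly plan: blocks of planted genes separated by >= SAFE_PAD decoys so
# that unplanted pairs never fall within the clustering threshold
SAFE_PAD = 6


def _simulate_one(
    genome_index: int, config: SimulationConfig
) -> tuple[Genome, dict]:
    rng = np.random.default_rng([config.seed, genome_index])
    genome_id = f"G{genome_index:04d}"

    u = rng.random()
    if u < config.p_both:
        presence = "both"
    elif u < config.p_both + config.p_onlyA:
        presence = "onlyA"
    elif u < config.p_both + config.p_onlyA + config.p_onlyB:
        presence = "onlyB"
    else:
        presence = "neither"
    has_pair = presence == "both"

    if has_pair:
        category = CATEGORIES[rng.choice(3, p=np.array(config.clustering_mix))]
        pair = PAIR_CHOICES[rng.integers(3)] if category == "pairwise_cluster" else ""
        anchor_residue = _draw_residue(rng, config.residue_mix_with)
    else:
        category, pair = "incomplete", ""
        anchor_residue = _draw_residue(rng, config.residue_mix_without)
    has_lam = rng.random() < config.p_lam

    # ---- blocks of (family | None for decoy, same_strand) ----------------
    blocks: list[tuple[list[str | None], bool]] = []
    if has_pair and category == "three_gene_operon":
        triple = ["efp", "yjeA", "yjeK"]
        rng.shuffle(triple)
        blocks.append((triple, True))
    elif has_pair and category == "pairwise_cluster":
        members = {"efp_yjeA": ("efp", "yjeA"), "efp_yjeK": ("efp", "yjeK"),
                   "yjeA_yjeK": ("yjeA", "yjeK")}[pair]
        inner: list[str | None] = [members[0]]
        inner += [None] * int(rng.integers(0, 3))   # 0-2 intervening decoys
        inner.append(members[1])
        blocks.append((inner, False))
        third = ({"efp", "yjeA", "yjeK"} - set(members)).pop()
        blocks.append(([third], False))
    else:
        blocks.append((["efp"], False))
        if presence in ("both", "onlyA"):
            blocks.append((["yjeA"], False))
        if presence in ("both", "onlyB"):
            blocks.append((["yjeK"], False))
    if has_lam:
        blocks.append((["ablA", "ablB"], False))
    order = rng.permutation(len(blocks))
    blocks = [blocks[i] for i in order]

    n_inner_decoys = sum(1 for members, _ in blocks for m in members if m is None)
    min_decoys = SAFE_PAD * (len(blocks) - 1) + n_inner_decoys
    lo, hi = config.decoy_range
    n_decoys = int(rng.integers(max(lo, min_decoys), max(hi, min_decoys) + 1))

    # distribute decoys: SAFE_PAD between blocks, the rest over all pads
    n_pads = len(blocks) + 1
    pads = [0] + [SAFE_PAD] * (len(blocks) - 1) + [0]
    spare = n_decoys - n_inner_decoys - sum(pads)
    for _ in range(spare):
        pads[rng.integers(n_pads)] += 1

    # ---- lay out genes along one replicon ---------------------------------
    layout: list[tuple[str | None, str, bool]] = []  # family, strand, in_operon_block

    def pad(k: int) -> None:
        for _ in range(k):
            layout.append((None, "+-"[rng.integers(2)], False))

    pad(pads[0])
    for b, (members, same_strand) in enumerate(blocks):
        strand = "+-"[rng.integers(2)]
        for m in members:
            layout.append((m, strand if same_strand else "+-"[rng.integers(2)], same_strand))
        pad(pads[b + 1])

    genes: list[GeneFeature] = []
    accessions: dict[str, str] = {}
    pos = 1
    for k, (family, strand, in_operon) in enumerate(layout):
        if family is None:
            seq = _decoy(rng)
        else:
            seq = _planted_gene(
                family, rng, config.mutation_distance,
                anchor_residue if family == "efp" else None,
            )
        gap = int(rng.integers(20, 81)) if in_operon and genes else int(rng.integers(150, 401))
        start = pos + gap
        end = start + 3 * len(seq) + 2
        gene_id = f"{genome_id}_g{k:04d}"
        genes.append(
            GeneFeature(
                gene_id=gene_id, replicon_id="chr", start=start, end=end,
                strand=strand, protein_seq=seq,
            )
        )
        if family is not None:
            accessions[family] = gene_id
        pos = end
    replicon = Replicon(replicon_id="chr", length=pos + 200, circular=False, genes=genes)
    genome = Genome(genome_id=genome_id, taxon_label=genome_id, replicons=[replicon])

    truth_row = {
        "genome_id": genome_id,
        "has_yjeA": presence in ("both", "onlyA"),
        "has_yjeK": presence in ("both", "onlyB"),
        "has_pair": has_pair,
        "has_lam": has_lam,
        "category": category,
        "pair": pair,
        "anchor_residue": anchor_residue,
        "efp_acc": accessions.get("efp", ""),
        "yjeA_acc": accessions.get("yjeA", ""),
        "yjeK_acc": accessions.get("yjeK", ""),
        "ablA_acc": accessions.get("ablA", ""),
        "ablB_acc": accessions.get("ablB", ""),
    }
    return genome, truth_row


def simulate_genomes(config: SimulationConfig) -> SimulationResult:
    """Simulate the full genome panel with its ground-truth table."""
    genomes, rows = [], []
    for idx in range(config.n_genomes):
        genome, row = _simulate_one(idx, config)
        genomes.append(genome)
        rows.append(row)
    return SimulationResult(genomes=genomes, truth=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Protein-family evolution along a known tree
# ---------------------------------------------------------------------------

def evolve_alignment(
    tree: dendropy.Tree, region_length: int, seed: int
) -> ProteinAlignment:
    """Evolve a gapless protein alignment along ``tree`` under JTT.

    The root state is drawn from the stationary frequencies; each branch
    applies the normalized JTT transition matrix for its length.  Leaf
    taxon labels become alignment taxa.  Deterministic given seed.
    """
    if region_length <= 0:
        raise ValueError("region_length must be positive")
    rng = np.random.default_rng(seed)
    states: dict[int, np.ndarray] = {}
    root = tree.seed_node
    states[id(root)] = rng.choice(20, size=region_length, p=JTT_FREQS)
    taxa, rows = [], []
    for node in tree.preorder_node_iter():
        if node is root:
            parent_state = states[id(root)]
        else:
            parent_state = states[id(node.parent_node)]
            t = node.edge.length or 0.0
            if t == 0:
                child = parent_state.copy()
            else:
                P = jtt_transition(t)
                cdf = np.cumsum(P, axis=1)
                u = rng.random(region_length)
                child = np.array(
                    [np.searchsorted(cdf[a], x) for a, x in zip(parent_state, u)]
                )
                np.clip(child, 0, 19, out=child)
            states[id(node)] = child
        if node.is_leaf():
            seq = "".join(AA_ORDER[i] for i in states[id(node)])
            taxa.append(node.taxon.label)
            rows.append(seq)
    return ProteinAlignment(taxa=taxa, rows=rows)


def two_clade_tree(
    n_per_clade: int = 12,
    intra: float = 0.15,
    split: float = 1.0,
    labels: tuple[str, str] = ("yjeK", "ablA"),
) -> tuple[dendropy.Tree, dict[str, str]]:
    """A balanced two-clade tree (the LAM-vs-YjeK scenario): two star-like
    clades of ``n_per_clade`` leaves with terminal branches ``intra``,
    joined by an internal edge of length ``split``.  Returns the tree and
    taxon -> clade labels."""
    names = [f"{labels[0]}_{i}" for i in range(n_per_clade)] + [
        f"{labels[1]}_{i}" for i in range(n_per_clade)
    ]
    tns = dendropy.TaxonNamespace(names)
    tree = dendropy.Tree(taxon_namespace=tns)
    clade_roots = []
    for c, label in enumerate(labels):
        node = dendropy.Node()
        for i in range(n_per_clade):
            leaf = dendropy.Node(taxon=tns.get_taxon(f"{label}_{i}"))
            node.add_child(leaf)
            leaf.edge.length = intra
        clade_roots.append(node)
    tree.seed_node.add_child(clade_roots[0])
    clade_roots[0].edge.length = split / 2
    tree.seed_node.add_child(clade_roots[1])
    clade_roots[1].edge.length = split / 2
    clade_of = {name: name.rsplit("_", 1)[0] for name in names}
    return tree, clade_of
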