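"""Physical clustering of efp/yjeA/yjeK and per-genome arrangement classes.

"Physical clustering" means two genes sit on the same replicon with at
most ``max_intervening`` genes between them (wrapping across the origin
on circular replicons).  An operon additionally requires co-orientation,
strict consecutiveness, and short intergenic gaps.  Each genome carrying
all three families falls in exactly one category — three-gene operon,
pairwise cluster, or no clustering — mirroring the mutually exclusive
arrangement percentages reported for genomes with both yjeA and yjeK.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome_model import GeneFeature, Genome, gene_order_index
from .homology import FamilyAssignment

CORE_FAMILIES = ("efp", "yjeA", "yjeK")
PAIR_NAMES = {
    frozenset({"efp", "yjeA"}): "efp_yjeA",
    frozenset({"efp", "yjeK"}): "efp_yjeK",
    frozenset({"yjeA", "yjeK"}): "yjeA_yjeK",
}


@dataclass(frozen=True)
class NeighborhoodConfig:
    max_intervening: int = 5
    operon_max_gap: int = 100      # bp between consecutive same-strand genes
    context_window: int = 5        # genes on each side for context labels

    def __post_init__(self) -> None:
        if min(self.max_intervening, self.operon_max_gap, self.context_window) < 0:
            raise ValueError("neighborhood parameters must be >= 0")


@dataclass(frozen=True)
class ClusterClass:
    genome_id: str
    category: str                  # three_gene_operon | pairwise_cluster | no_cluster | incomplete
    pair: str | None = None        # set iff category == pairwise_cluster
    supporting_genes: tuple[str, ...] = ()
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if (self.pair is not None) != (self.category == "pairwise_cluster"):
            raise ValueError("pair must be set iff category is pairwise_cluster")


def _replicon_of(genome: Genome, gene: GeneFeature):
    for rep in genome.replicons:
        if rep.replicon_id == gene.replicon_id:
            return rep
    raise ValueError(f"gene {gene.gene_id} not on any replicon of {genome.genome_id}")


def intervening_genes(
    gene_a: GeneFeature, gene_b: GeneFeature, genome: Genome
) -> int | None:
    """Number of genes strictly between the two, or None if on different
    replicons.  On circular replicons the shorter way around counts."""
    if gene_a.replicon_id != gene_b.replicon_id:
        return None
    index = gene_order_index(genome)
    try:
        _, pos_a = index[gene_a.gene_id]
        _, pos_b = index[gene_b.gene_id]
    except KeyError as exc:
        raise ValueError(f"gene {exc} not in genome {genome.genome_id}") from exc
    rep = _replicon_of(genome, gene_a)
    direct = abs(pos_a - pos_b) - 1
    if rep.circular:
        around = len(rep.genes) - abs(pos_a - pos_b) - 1
        return min(direct, around)
    return direct


def are_clustered(
    gene_a: GeneFeature,
    gene_b: GeneFeature,
    genome: Genome,
    config: NeighborhoodConfig = NeighborhoodConfig(),
) -> bool:
    between = intervening_genes(gene_a, gene_b, genome)
    return between is not None and between <= config.max_intervening


def is_operon(
    genes: list[GeneFeature],
    genome: Genome,
    config: NeighborhoodConfig = NeighborhoodConfig(),
) -> bool:
    """True iff the genes are consecutive, co-oriented, and tightly spaced
    on one replicon (order within the list does not matter)."""
    if len(genes) < 2:
        raise ValueError("operon test needs >= 2 genes")
    if len({g.replicon_id for g in genes}) != 1:
        return False
    if len({g.strand for g in genes}) != 1:
        return False
    index = gene_order_index(genome)
    for g in genes:
        if g.gene_id not in index:
            raise ValueError(f"gene {g.gene_id} not in genome {genome.genome_id}")
    ordered = sorted(genes, key=lambda g: index[g.gene_id][1])
    positions = [index[g.gene_id][1] for g in ordered]
    if positions != list(range(positions[0], positions[0] + len(genes))):
        return False  # intervening genes present
    for left, right in zip(ordered, ordered[1:]):
        if right.start - left.end - 1 > config.operon_max_gap:
            return False
    return True


def _family_genes(
    genome: Genome, assignments: list[FamilyAssignment]
) -> dict[str, list[GeneFeature]]:
    by_id = {g.gene_id: g for g in genome.genes}
    out: dict[str, list[GeneFeature]] = {}
    for a in assignments:
        if a.family != "none" and a.gene_id in by_id:
            out.setdefault(a.family, []).append(by_id[a.gene_id])
    return out


def classify_clustering(
    genome: Genome,
    assignments: list[FamilyAssignment],
    config: NeighborhoodConfig = NeighborhoodConfig(),
) -> ClusterClass:
    """Arrangement category of the genome's efp/yjeA/yjeK genes.

    Precedence is operon > pairwise > none; with paralogs, any passing
    combination of copies suffices and the best pair (fewest intervening
    genes, ties by pair name) is reported.  Genomes lacking a core family
    are ``incomplete``.  When two distinct pairs cluster separately the
    result carries a ``multi-pair`` flag.
    """
    fam_genes = _family_genes(genome, assignments)
    missing = [f for f in CORE_FAMILIES if not fam_genes.get(f)]
    if missing:
        return ClusterClass(
            genome_id=genome.genome_id,
            category="incomplete",
            flags=("missing:" + ",".join(missing),),
        )

    for efp in fam_genes["efp"]:
        for yjea in fam_genes["yjeA"]:
            for yjek in fam_genes["yjeK"]:
                if is_operon([efp, yjea, yjek], genome, config):
                    return ClusterClass(
                        genome_id=genome.genome_id,
                        category="three_gene_operon",
                        supporting_genes=(efp.gene_id, yjea.gene_id, yjek.gene_id),
                    )

    pair_hits = {}
    for fam_pair, pair_name in sorted(PAIR_NAMES.items(), key=lambda kv: kv[1]):
        fam_a, fam_b = sorted(fam_pair)
        best = None
        for ga in fam_genes[fam_a]:
            for gb in fam_genes[fam_b]:
                between = intervening_genes(ga, gb, genome)
                if between is not None and between <= config.max_intervening:
                    if best is None or between < best[0]:
                        best = (between, ga.gene_id, gb.gene_id)
        if best is not None:
            pair_hits[pair_name] = best
    if pair_hits:
        winner = min(pair_hits.items(), key=lambda kv: (kv[1][0], kv[0]))
        name, (_, ga, gb) = winner
        flags = ("multi-pair",) if len(pair_hits) > 1 else ()
        return ClusterClass(
            genome_id=genome.genome_id,
            category="pairwise_cluster",
            pair=name,
            supporting_genes=(ga, gb),
            flags=flags,
        )
    return ClusterClass(genome_id=genome.genome_id, category="no_cluster")


def neighborhood_context(
    gene: GeneFeature,
    genome: Genome,
    assignments: list[FamilyAssignment],
    config: NeighborhoodConfig = NeighborhoodConfig(),
) -> set[str]:
    """Family labels (excluding the gene itself and 'none') within
    ``context_window`` genes on either side, same replicon.  Linear
    replicons truncate at the edge; circular ones wrap."""
    index = gene_order_index(genome)
    if gene.gene_id not in index:
        raise ValueError(f"gene {gene.gene_id} not in genome {genome.genome_id}")
    rep = _replicon_of(genome, gene)
    _, pos = index[gene.gene_id]
    n = len(rep.genes)
    offsets = range(-config.context_window, config.context_window + 1)
    neighbor_ids = set()
    for off in offsets:
        if off == 0:
            continue
        k = pos + off
        if rep.circular:
            k %= n
        elif not 0 <= k < n:
            continue
        neighbor_ids.add(rep.genes[k].gene_id)
    families = {
        a.family
        for a in assignments
        if a.gene_id in neighbor_ids and a.family != "none"
    }
    return families


def all_contexts(
    genome: Genome,
    assignments: list[FamilyAssignment],
    config: NeighborhoodConfig = NeighborhoodConfig(),
) -> dict[str, set[str]]:
    """Neighborhood context for every gene with a family label."""
    by_id = {g.gene_id: g for g in genome.genes}
    return {
        a.gene_id: neighborhood_context(by_id[a.gene_id], genome, assignments, config)
        for a in assignments
        if a.family != "none" and a.gene_id in by_id
    }


def write_clusters_tsv(
    path: str, classes: list[ClusterClass], config: NeighborhoodConfig
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "genome_id\tcategory\tpair\tsupporting_genes\tflags\t"
            "max_intervening\toperon_max_gap\n"
        )
        for c in classes:
            fh.write(
                f"{c.genome_id}\t{c.category}\t{c.pair or ''}\t"
                f"{','.join(c.supporting_genes)}\t{','.join(c.flags)}\t"
                f"{config.max_intervening}\t{config.operon_max_gap}\n"
            )
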