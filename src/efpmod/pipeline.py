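"""End-to-end orchestration: assignments -> clustering -> profiles ->
conservation -> (optional) phylogenetics, with a machine-readable summary.

Every stage writes its TSV into the output directory as it completes, so
a failing stage leaves the earlier outputs behind, and each stage is
independently re-runnable through the CLI.
"""

from __future__ import annotations

import glob
import json
import logging
import os
from dataclasses import dataclass, field

from . import conservation, homology, neighborhood, profiles, phylo
from .conservation import AnchorConfig
from .genome_model import Genome, parse_genome
from .homology import FamilyAssignment
from .neighborhood import NeighborhoodConfig
from .references import reference_families

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    genome_dir: str | None = None          # directory of <id>.gff3 + <id>.faa pairs
    family_table: str | None = None        # or a precomputed per-genome table
    reference_paths: dict[str, str] | None = None  # family -> FASTA; default: built-ins
    alignment_path: str | None = None      # aligned FASTA for the tree stage
    region: slice | None = None            # column slice of the conserved region
    neighborhood: NeighborhoodConfig = field(default_factory=NeighborhoodConfig)
    anchor: AnchorConfig = field(default_factory=AnchorConfig)
    n_reps: int = 1000
    seed: int = 0
    outdir: str = "efpmod_out"
    min_score: float = homology.DEFAULT_MIN_SCORE

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.genome_dir is None and self.family_table is None:
            raise ValueError("need either genome_dir or family_table")


def load_genomes(genome_dir: str) -> list[Genome]:
    genomes = []
    for gff in sorted(glob.glob(os.path.join(genome_dir, "*.gff3"))):
        faa = gff[: -len(".gff3")] + ".faa"
        if not os.path.exists(faa):
            raise FileNotFoundError(f"missing protein FASTA for {gff}")
        genomes.append(parse_genome(gff, faa))
    if not genomes:
        raise FileNotFoundError(f"no *.gff3 genomes under {genome_dir}")
    return genomes


def assign_stage(
    genomes: list[Genome], config: PipelineConfig
) -> dict[str, list[FamilyAssignment]]:
    """Family assignment with context-based yjeK/ablA disambiguation."""
    if config.reference_paths:
        from .references import read_reference_fastas

        refs = read_reference_fastas(config.reference_paths)
    else:
        refs = reference_families()
    out = {}
    for genome in genomes:
        raw = homology.assign_families(genome, refs, min_score=config.min_score)
        contexts = neighborhood.all_contexts(genome, raw, config.neighborhood)
        out[genome.genome_id] = homology.disambiguate_yjek_lam(raw, contexts)
        logger.info("assigned %s", genome.genome_id)
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the machine-readable summary (also written
    to ``summary.json`` in the output directory)."""
    os.makedirs(config.outdir, exist_ok=True)
    summary: dict = {"parameters": {
        "max_intervening": config.neighborhood.max_intervening,
        "operon_max_gap": config.neighborhood.operon_max_gap,
        "context_window": config.neighborhood.context_window,
        "motif": config.anchor.motif,
        "window": config.anchor.window,
        "n_reps": config.n_reps,
        "seed": config.seed,
    }}

    genomes: list[Genome] = []
    if config.genome_dir is not None:
        stage = "parse"
        try:
            genomes = load_genomes(config.genome_dir)
        except Exception as exc:
            raise PipelineError(stage, exc) from exc

        stage = "assign"
        try:
            assignments = assign_stage(genomes, config)
            homology.write_assignments_tsv(
                os.path.join(config.outdir, "assignments.tsv"), assignments
            )
        except Exception as exc:
            raise PipelineError(stage, exc) from exc

        stage = "neighborhood"
        try:
            classes = [
                neighborhood.classify_clustering(
                    g, assignments[g.genome_id], config.neighborhood
                )
                for g in genomes
            ]
            neighborhood.write_clusters_tsv(
                os.path.join(config.outdir, "clusters.tsv"), classes, config.neighborhood
            )
        except Exception as exc:
            raise PipelineError(stage, exc) from exc

        stage = "profile"
        try:
            profile = profiles.build_profile(assignments)
        except Exception as exc:
            raise PipelineError(stage, exc) from exc
    else:
        stage = "profile"
        try:
            profile, classes = profiles.read_family_table(config.family_table)
        except Exception as exc:
            raise PipelineError(stage, exc) from exc
        assignments = None

    try:
        profile.to_tsv(os.path.join(config.outdir, "profile.tsv"))
        summaries = {}
        for fam_a, fam_b in [("yjeA", "yjeK"), ("efp", "yjeA"), ("efp", "yjeK")]:
            summaries[(fam_a, fam_b)] = profiles.cooccurrence(profile, fam_a, fam_b)
        profiles.write_cooccurrence_tsv(
            os.path.join(config.outdir, "cooccurrence.tsv"), summaries
        )
        pair_summary = summaries[("yjeA", "yjeK")]
        with_both = profile.with_both("yjeA", "yjeK")
        breakdown = profiles.clustering_breakdown(classes, restrict_to=with_both)
        summary["cooccurrence"] = {
            "n_total": pair_summary.n_total,
            "n_both": pair_summary.n_both,
            "fraction_both": pair_summary.fraction_both,
        }
        summary["clustering_breakdown"] = breakdown
    except Exception as exc:
        raise PipelineError("profile", exc) from exc

    if assignments is not None:
        stage = "conserve"
        try:
            summary["conservation"] = {}
            by_id = {g.genome_id: g for g in genomes}
            pair_set = set(with_both)
            for label, wanted in (
                ("with_pair", pair_set),
                ("without_pair", set(profile.genomes) - pair_set),
            ):
                seqs, gids = [], []
                for gid in sorted(wanted):
                    for a in assignments[gid]:
                        if a.family == "efp":
                            seqs.append(by_id[gid].gene(a.gene_id).protein_seq)
                            gids.append(gid)
                if not seqs:
                    summary["conservation"][label] = {"n": 0}
                    continue
                dist = conservation.residue_distribution(
                    seqs, config.anchor, genome_ids=gids
                )
                conservation.write_residue_tsv(
                    os.path.join(config.outdir, f"residues_{label}.tsv"), dist, label
                )
                windows = conservation.anchored_windows(seqs, config.anchor)
                if windows:
                    columns = conservation.logo_heights(windows)
                    conservation.write_logo_tsv(
                        os.path.join(config.outdir, f"logo_{label}.tsv"), columns
                    )
                summary["conservation"][label] = {
                    "n": dist.n_anchored,
                    "percent_lys": dist.percentages.get("K", 0.0),
                    "percentages": dist.percentages,
                }
        except Exception as exc:
            raise PipelineError(stage, exc) from exc

    if config.alignment_path is not None:
        stage = "tree"
        try:
            aln = phylo.ProteinAlignment.read_fasta(config.alignment_path, region=config.region)
            D = phylo.jtt_distance_matrix(aln)
            D.to_tsv(os.path.join(config.outdir, "distances.tsv"))
            tree = phylo.nj_tree(D)
            reps = phylo.bootstrap_trees(aln, config.n_reps, config.seed)
            tree = phylo.consensus_support(tree, reps)
            phylo.write_newick(tree, os.path.join(config.outdir, "tree.nwk"))
            supports = sorted(
                (node.support for node in tree.preorder_node_iter()
                 if getattr(node, "support", None) is not None),
                reverse=True,
            )
            summary["tree"] = {"n_taxa": aln.n_taxa, "n_reps": config.n_reps,
                               "supports": supports[:10]}
        except Exception as exc:
            raise PipelineError(stage, exc) from exc

    with open(os.path.join(config.outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary


def report(summary: dict) -> str:
    """Human-readable report; every number carries its denominator."""
    lines = ["EF-P modification-pathway comparative-genomics report", ""]
    params = summary.get("parameters", {})
    if params:
        lines.append("parameters: " + ", ".join(f"{k}={v}" for k, v in params.items()))
        lines.append("")
    co = summary.get("cooccurrence")
    if co:
        lines.append(
            f"genomes with both yjeA and yjeK: {co['n_both']}/{co['n_total']} "
            f"({100 * co['fraction_both']:.1f}%)"
        )
    breakdown = summary.get("clustering_breakdown")
    if breakdown:
        lines.append("arrangement among with-both genomes:")
        for category, pct in breakdown.items():
            lines.append(f"  {category}: {pct:.1f}%")
    cons = summary.get("conservation", {})
    for label, stats in cons.items():
        if stats.get("n", 0) == 0:
            lines.append(f"anchored EF-P residues ({label}): n=0")
            continue
        lines.append(
            f"anchored EF-P residues ({label}, n={stats['n']}): "
            + ", ".join(f"{r}={p:.1f}%" for r, p in stats["percentages"].items())
        )
    tree = summary.get("tree")
    if tree:
        lines.append(
            f"NJ tree on {tree['n_taxa']} taxa, {tree['n_reps']} bootstrap "
            f"replicates; top supports: {tree['supports']}"
        )
    return "\n".join(lines) + "\n"
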