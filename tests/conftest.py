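import numpy as np
import pytest

from efpmod.genome_model import GeneFeature, Genome, Replicon
from efpmod.homology import FamilyAssignment
from efpmod.references import reference_families
from efpmod.synthetic_data import SimulationConfig, simulate_genomes


def make_genome(
    spec: list[tuple],
    genome_id: str = "G",
    replicon_id: str = "chr",
    circular: bool = False,
    length: int | None = None,
) -> Genome:
    """Compact genome builder: spec rows are (gene_id, start, end, strand)
    with an optional fifth element giving the protein sequence."""
    genes = [
        GeneFeature(
            gene_id=row[0], replicon_id=replicon_id, start=row[1], end=row[2],
            strand=row[3], protein_seq=row[4] if len(row) > 4 else "MKT" * 20,
        )
        for row in spec
    ]
    rep_len = length or max(g.end for g in genes) + 500
    rep = Replicon(replicon_id=replicon_id, length=rep_len, circular=circular, genes=genes)
    return Genome(genome_id=genome_id, taxon_label=genome_id, replicons=[rep])


def assign(genome: Genome, families: dict[str, str]) -> list[FamilyAssignment]:
    """Truth-style assignments: gene_id -> family for the listed genes,
    'none' for the rest."""
    return [
        FamilyAssignment(
            gene_id=g.gene_id,
            family=families.get(g.gene_id, "none"),
            evidence=None,
            reference_id=None,
        )
        for g in genome.genes
    ]


@pytest.fixture(scope="session")
def refs():
    return reference_families()


@pytest.fixture(scope="session")
def small_sim():
    """A 60-genome simulated panel shared across tests (read-only)."""
    return simulate_genomes(SimulationConfig(n_genomes=60, seed=11))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
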