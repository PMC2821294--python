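"""Phyletic profiles and co-occurrence / clustering summary statistics.

Presence is genome-level: a family is present when the genome carries at
least one assigned copy.  The headline numbers of the analysis live here:
the fraction of genomes possessing both yjeA and yjeK, and the
operon / pairwise / none arrangement breakdown within that subset.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .homology import FAMILIES, FamilyAssignment
from .neighborhood import ClusterClass


@dataclass
class PhyleticProfile:
    """Genomes x families boolean presence matrix (pandas-backed)."""

    table: pd.DataFrame  # index: genome_id, columns: family labels, bool

    @property
    def genomes(self) -> list[str]:
        return list(self.table.index)

    @property
    def families(self) -> list[str]:
        return list(self.table.columns)

    def present(self, genome_id: str, family: str) -> bool:
        return bool(self.table.loc[genome_id, family])

    def with_both(self, fam_a: str, fam_b: str) -> list[str]:
        mask = self.table[fam_a] & self.table[fam_b]
        return list(self.table.index[mask])

    def to_tsv(self, path: str) -> None:
        out = self.table.astype(int)
        out.index.name = "genome_id"
        out.to_csv(path, sep="\t")


@dataclass(frozen=True)
class CooccurrenceSummary:
    n_total: int
    n_both: int
    n_onlyA: int
    n_onlyB: int
    n_neither: int

    @property
    def fraction_both(self) -> float:
        return self.n_both / self.n_total


def build_profile(
    assignments: dict[str, list[FamilyAssignment]],
    families: tuple[str, ...] = FAMILIES,
) -> PhyleticProfile:
    """Presence/absence profile from per-genome family assignments."""
    if not assignments:
        raise ValueError("empty dataset")
    if len(set(assignments)) != len(assignments):
        raise ValueError("duplicate genome_id")
    rows = {}
    for genome_id, genome_assignments in assignments.items():
        present = {a.family for a in genome_assignments if a.family != "none"}
        rows[genome_id] = {fam: fam in present for fam in families}
    table = pd.DataFrame.from_dict(rows, orient="index", columns=list(families))
    return PhyleticProfile(table=table.astype(bool))


def cooccurrence(
    profile: PhyleticProfile, fam_a: str, fam_b: str
) -> CooccurrenceSummary:
    for fam in (fam_a, fam_b):
        if fam not in profile.families:
            raise ValueError(f"unknown family {fam!r}")
    a = profile.table[fam_a]
    b = profile.table[fam_b]
    return CooccurrenceSummary(
        n_total=len(profile.genomes),
        n_both=int((a & b).sum()),
        n_onlyA=int((a & ~b).sum()),
        n_onlyB=int((~a & b).sum()),
        n_neither=int((~a & ~b).sum()),
    )


def clustering_breakdown(
    classes: list[ClusterClass], restrict_to: list[str] | None = None
) -> dict[str, float]:
    """Percentage of each arrangement category among ``restrict_to``
    genomes (typically those with both yjeA and yjeK); the three
    categories sum to 100."""
    if restrict_to is not None:
        restrict = set(restrict_to)
        classes = [c for c in classes if c.genome_id in restrict]
    classes = [c for c in classes if c.category != "incomplete"]
    if not classes:
        raise ValueError("empty restricted set")
    n = len(classes)
    counts = {"three_gene_operon": 0, "pairwise_cluster": 0, "no_cluster": 0}
    for c in classes:
        counts[c.category] += 1
    return {cat: 100.0 * k / n for cat, k in counts.items()}


# ---------------------------------------------------------------------------
# Per-genome family table ("Table S1 dialect"): one row per genome, one
# column per family holding an accession (presence) or blank (absence),
# plus a clustering-annotation column.
# ---------------------------------------------------------------------------

def read_family_table(
    path: str,
    genome_col: str = "genome_id",
    family_cols: dict[str, str] | None = None,
    clustering_col: str = "clustering",
) -> tuple[PhyleticProfile, list[ClusterClass]]:
    """Read a per-genome family table into a profile + cluster classes.

    ``family_cols`` maps family label -> column name (defaults to the
    family names themselves); a non-blank cell means presence.  The
    clustering column uses ``operon``, ``pair:<pair_name>``, ``none`` or
    blank (for genomes lacking a family).
    """
    family_cols = family_cols or {f: f for f in FAMILIES}
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if df[genome_col].duplicated().any():
        raise ValueError("duplicate genome_id in family table")
    presence = pd.DataFrame(
        {fam: df[col].str.strip() != "" for fam, col in family_cols.items()}
    )
    presence.index = df[genome_col]
    profile = PhyleticProfile(table=presence.astype(bool))

    classes = []
    for _, row in df.iterrows():
        annotation = row.get(clustering_col, "").strip()
        genome_id = row[genome_col]
        if annotation == "operon":
            classes.append(ClusterClass(genome_id=genome_id, category="three_gene_operon"))
        elif annotation.startswith("pair:"):
            classes.append(
                ClusterClass(
                    genome_id=genome_id,
                    category="pairwise_cluster",
                    pair=annotation.split(":", 1)[1],
                )
            )
        elif annotation == "none":
            classes.append(ClusterClass(genome_id=genome_id, category="no_cluster"))
        else:
            classes.append(ClusterClass(genome_id=genome_id, category="incomplete"))
    return profile, classes


def write_cooccurrence_tsv(
    path: str, summaries: dict[tuple[str, str], CooccurrenceSummary]
) -> None:
    with open(path, "w") as fh:
        fh.write("family_a\tfamily_b\tn_total\tn_both\tn_onlyA\tn_onlyB\t"
                 "n_neither\tfraction_both\n")
        for (fa, fb), s in summaries.items():
            fh.write(
                f"{fa}\t{fb}\t{s.n_total}\t{s.n_both}\t{s.n_onlyA}\t{s.n_onlyB}\t"
                f"{s.n_neither}\t{s.fraction_both:.4f}\n"
            )
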