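"""Synthetic reference protein families for the five tracked gene families.

These are *synthetic* stand-ins for curated reference sequences: each
family is a fixed, seeded draw from the JTT stationary distribution (the
EF-P family additionally carries the PGKG motif with the focal lysine at
position 34, matching the conserved motif around E. coli EF-P Lys34), and
per-family reference copies are divergent descendants of the family
ancestor under the JTT process.  yjeK and ablA descend from a *common*
lysine-2,3-aminomutase (LAM) ancestor at a distance that leaves them
roughly 30% identical, so sequence similarity alone cannot separate them
— genomic context has to, exactly the situation the pipeline is built to
resolve.

Family lengths mimic the real proteins: EF-P ~188 aa; YjeA a truncated
class-II LysRS catalytic core; YjeK a LAM lacking the C-terminal
multimerization domain; ablA a full-length LAM; ablB a
beta-lysine acetyltransferase.
"""

from __future__ import annotations

import numpy as np

from .phylo import AA_ORDER, JTT_FREQS, jtt_transition

EFP_MOTIF = "PGKG"
EFP_MOTIF_START = 32          # 1-based position of the P; K lands at 34
EFP_ANCHOR_POSITION = 34      # 1-based position of the focal lysine

FAMILY_LENGTHS = {
    "efp": 188,
    "yjeA": 325,
    "yjeK": 342,
    "ablA": 416,
    "ablB": 276,
}

_REFERENCE_SEED = 20100113    # fixed: reference sets must never drift


def _stationary_protein(rng: np.random.Generator, length: int) -> str:
    idx = rng.choice(20, size=length, p=JTT_FREQS)
    return "".join(AA_ORDER[i] for i in idx)


def mutate_jtt(
    seq: str, distance: float, rng: np.random.Generator, frozen: set[int] = frozenset()
) -> str:
    """Evolve ``seq`` for ``distance`` substitutions/site under JTT.

    ``frozen`` holds 0-based positions that must not change (used to keep
    the EF-P motif context intact).
    """
    P = jtt_transition(distance)
    out = []
    for pos, ch in enumerate(seq):
        i = AA_ORDER.index(ch)
        if pos in frozen:
            out.append(ch)
        else:
            out.append(AA_ORDER[rng.choice(20, p=P[i])])
    return "".join(out)


def _build() -> dict[str, list[tuple[str, str]]]:
    rng = np.random.default_rng(_REFERENCE_SEED)
    refs: dict[str, list[tuple[str, str]]] = {}

    def family_from_ancestor(name: str, ancestor: str, frozen: set[int]) -> None:
        copies = []
        for k in range(2):
            copies.append(
                (f"{name}_ref{k + 1}", mutate_jtt(ancestor, 0.15, rng, frozen))
            )
        refs[name] = copies

    # EF-P: stationary draw with the PGKG motif planted at 32-35 and the
    # whole 9-aa window around position 34 held fixed across references.
    efp = list(_stationary_protein(rng, FAMILY_LENGTHS["efp"]))
    efp[EFP_MOTIF_START - 1 : EFP_MOTIF_START - 1 + 4] = EFP_MOTIF
    efp = "".join(efp)
    efp_frozen = set(range(EFP_ANCHOR_POSITION - 5, EFP_ANCHOR_POSITION + 4))
    family_from_ancestor("efp", efp, efp_frozen)

    family_from_ancestor("yjeA", _stationary_protein(rng, FAMILY_LENGTHS["yjeA"]), set())

    # yjeK / ablA: common LAM ancestor, deep split (~0.5 subs/site each
    # side leaves the subfamilies ~30-35% identical, the identity reported
    # between true aminomutase homologs); ablA keeps a C-terminal domain.
    lam_core = _stationary_protein(rng, FAMILY_LENGTHS["yjeK"])
    yjek_anc = mutate_jtt(lam_core, 0.5, rng)
    abla_anc = mutate_jtt(lam_core, 0.5, rng) + _stationary_protein(
        rng, FAMILY_LENGTHS["ablA"] - FAMILY_LENGTHS["yjeK"]
    )
    family_from_ancestor("yjeK", yjek_anc, set())
    family_from_ancestor("ablA", abla_anc, set())

    family_from_ancestor("ablB", _stationary_protein(rng, FAMILY_LENGTHS["ablB"]), set())
    return refs


_CACHE: dict[str, list[tuple[str, str]]] | None = None


def reference_families() -> dict[str, list[tuple[str, str]]]:
    """family -> list of (reference_id, protein sequence)."""
    global _CACHE
    if _CACHE is None:
        _CACHE = _build()
    return _CACHE


def write_reference_fastas(outdir: str) -> dict[str, str]:
    """One multi-FASTA per family; returns family -> path."""
    import os

    paths = {}
    for family, seqs in reference_families().items():
        path = os.path.join(outdir, f"{family}.faa")
        with open(path, "w") as fh:
            for rid, seq in seqs:
                fh.write(f">{rid}\n{seq}\n")
        paths[family] = path
    return paths


def read_reference_fastas(paths: dict[str, str]) -> dict[str, list[tuple[str, str]]]:
    from Bio import SeqIO

    refs = {}
    for family, path in paths.items():
        refs[family] = [
            (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fasta")
        ]
    return refs
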