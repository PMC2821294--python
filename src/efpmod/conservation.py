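"""Motif-anchored conservation of the EF-P focal lysine (Lys34).

Rather than building a full multiple alignment, each EF-P sequence is
anchored on the conserved PGKG motif: the position homologous to E. coli
Lys34 is the third motif position.  Sequences where the exact motif is
absent (the focal residue is replaced by Arg/Met/Asn/Gln in many
organisms without the yjeA/yjeK pair) are anchored by a degenerate match
in which the focal position is free and the flanking motif positions are
scored with BLOSUM62 above a floor.  Residue distributions at the anchor
and WebLogo-style per-column information content (with the standard
small-sample correction) are computed from the anchored windows.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass

from Bio.Align import substitution_matrices

logger = logging.getLogger(__name__)

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


@dataclass(frozen=True)
class AnchorConfig:
    motif: str = "PGKG"
    window: int = 9                  # logo width, centered on the anchor
    anchor_offset: int = 3           # 1-based position of the focal residue in the motif
    degenerate_floor: float = 12.0   # min BLOSUM62 flank score for a fallback hit

    def __post_init__(self) -> None:
        if not 1 <= self.anchor_offset <= len(self.motif):
            raise ValueError("anchor_offset must index into the motif")
        if self.window % 2 != 1:
            raise ValueError("window must be odd")


@dataclass
class LogoColumn:
    frequencies: dict[str, float]
    n: int
    information: float               # bits, small-sample corrected


def anchor_position(seq: str, config: AnchorConfig = AnchorConfig()) -> int | None:
    """1-based index of the focal residue, or None when unanchorable.

    The leftmost exact motif occurrence wins; failing that, the leftmost
    best degenerate window (focal position free, flanks scored by
    BLOSUM62 against the motif) with flank score >= the floor.
    """
    seq = seq.upper()
    motif = config.motif.upper()
    if len(seq) < len(motif):
        return None
    hit = seq.find(motif)
    if hit != -1:
        return hit + config.anchor_offset

    best_score, best_pos = None, None
    for start in range(len(seq) - len(motif) + 1):
        score = 0.0
        for k, motif_res in enumerate(motif):
            if k == config.anchor_offset - 1:
                continue
            res = seq[start + k]
            try:
                score += _BLOSUM62[motif_res, res]
            except (KeyError, IndexError):
                score += 0.0
        if score >= config.degenerate_floor and (best_score is None or score > best_score):
            best_score, best_pos = score, start  # strict > keeps leftmost on ties
    if best_pos is None:
        return None
    return best_pos + config.anchor_offset


@dataclass
class ResidueDistribution:
    percentages: dict[str, float]     # residue -> percent of anchored observations
    n_anchored: int
    n_excluded: int
    mode: str = "per_sequence"


def residue_distribution(
    seqs: list[str],
    config: AnchorConfig = AnchorConfig(),
    genome_ids: list[str] | None = None,
    mode: str = "per_sequence",
) -> ResidueDistribution:
    """Distribution of the anchored residue across sequences.

    ``per_sequence``: every anchorable sequence is one observation
    (paralogs count separately).  ``per_genome`` (requires genome_ids):
    one observation per genome — lysine if any copy carries it, else the
    genome's most common anchored residue (alphabetical tie-break).
    """
    if not seqs:
        raise ValueError("need at least one sequence")
    if mode == "per_genome" and genome_ids is None:
        raise ValueError("per_genome mode requires genome_ids")

    anchored: list[tuple[str | None, str]] = []
    n_excluded = 0
    for idx, seq in enumerate(seqs):
        pos = anchor_position(seq, config)
        if pos is None or pos > len(seq):
            n_excluded += 1
            logger.info("sequence %d not anchorable; excluded", idx)
            continue
        gid = genome_ids[idx] if genome_ids is not None else None
        anchored.append((gid, seq[pos - 1].upper()))
    if not anchored:
        raise ValueError("no sequence could be anchored")

    if mode == "per_sequence":
        observations = [res for _, res in anchored]
    elif mode == "per_genome":
        by_genome: dict[str, list[str]] = {}
        for gid, res in anchored:
            by_genome.setdefault(gid, []).append(res)
        observations = []
        for residues in by_genome.values():
            if "K" in residues:
                observations.append("K")
            else:
                counts = Counter(residues)
                top = max(counts.values())
                observations.append(sorted(r for r, c in counts.items() if c == top)[0])
    else:
        raise ValueError(f"unknown mode {mode!r}")

    n = len(observations)
    counts = Counter(observations)
    percentages = {res: 100.0 * c / n for res, c in sorted(counts.items())}
    return ResidueDistribution(
        percentages=percentages, n_anchored=n, n_excluded=n_excluded, mode=mode
    )


def anchored_windows(
    seqs: list[str], config: AnchorConfig = AnchorConfig()
) -> list[str]:
    """Fixed-width windows centered on the anchor; sequences that cannot
    be anchored or whose window runs off either end are excluded."""
    half = config.window // 2
    rows = []
    for seq in seqs:
        pos = anchor_position(seq, config)
        if pos is None:
            continue
        start = pos - 1 - half
        end = pos + half
        if start < 0 or end > len(seq):
            continue
        rows.append(seq[start:end].upper())
    return rows


LOG2_20 = math.log2(20)


def logo_heights(rows: list[str]) -> list[LogoColumn]:
    """Per-column information content in bits, WebLogo style.

    R = log2(20) - (H + e_n) with Shannon entropy H in bits and the
    small-sample correction e_n = 19 / (2 ln2 n); clamped at 0.
    """
    if not rows:
        raise ValueError("no rows")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("rows must be equal length")
    n = len(rows)
    e_n = 19.0 / (2.0 * math.log(2) * n)
    columns = []
    for j in range(width):
        counts = Counter(r[j] for r in rows)
        freqs = {res: c / n for res, c in sorted(counts.items())}
        entropy = -sum(f * math.log2(f) for f in freqs.values() if f > 0)
        info = max(0.0, LOG2_20 - (entropy + e_n))
        columns.append(LogoColumn(frequencies=freqs, n=n, information=info))
    return columns


def write_residue_tsv(path: str, dist: ResidueDistribution, label: str) -> None:
    with open(path, "w") as fh:
        fh.write("set\tresidue\tpercent\tn_anchored\tn_excluded\tmode\n")
        for res, pct in dist.percentages.items():
            fh.write(
                f"{label}\t{res}\t{pct:.4f}\t{dist.n_anchored}\t"
                f"{dist.n_excluded}\t{dist.mode}\n"
            )


def write_logo_tsv(path: str, columns: list[LogoColumn]) -> None:
    with open(path, "w") as fh:
        fh.write("column\tresidue\tfrequency\tbits\n")
        for j, col in enumerate(columns, start=1):
            for res, freq in col.frequencies.items():
                fh.write(f"{j}\t{res}\t{freq:.6f}\t{col.information:.4f}\n")
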