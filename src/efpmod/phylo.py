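"""JTT distances, neighbor-joining, bootstrap, and subfamily splitting.

The model is the Jones-Taylor-Thornton (JTT) empirical amino-acid
replacement process, used as a reversible continuous-time Markov chain
whose rate matrix is normalized to one expected substitution per site per
unit branch length.  Pairwise distances are maximum-likelihood estimates
under that chain; trees are built by neighbor-joining (Saitou-Nei
agglomeration with the Studier-Keppler Q criterion); branch reliability
comes from column bootstrap with bipartition counting.

Amino-acid order throughout is ARNDCQEGHILKMFPSTWYV.  Gaps (``-``) and
``X`` are treated as missing data: columns where either member of a pair
is missing are excluded from that pair's distance (pairwise deletion).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar

logger = logging.getLogger(__name__)

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

# JTT exchangeabilities: lower triangle, row by row, in AA_ORDER
# (Jones, Taylor & Thornton 1992, the matrix distributed with Protdist/PAML).
_JTT_LOWER = [
    58,
    54, 45,
    81, 16, 528,
    56, 113, 34, 10,
    57, 310, 86, 49, 9,
    105, 29, 58, 767, 5, 323,
    179, 137, 81, 130, 59, 26, 119,
    27, 328, 391, 112, 69, 597, 26, 23,
    36, 22, 47, 11, 17, 9, 12, 6, 16,
    30, 38, 12, 7, 23, 72, 9, 6, 56, 229,
    35, 646, 263, 26, 7, 292, 181, 27, 45, 21, 14,
    54, 44, 30, 15, 31, 43, 18, 14, 33, 479, 388, 65,
    15, 5, 10, 4, 78, 4, 5, 5, 40, 89, 248, 4, 43,
    194, 74, 15, 15, 14, 164, 18, 24, 115, 10, 102, 21, 16, 17,
    378, 101, 503, 59, 223, 53, 30, 201, 73, 40, 59, 47, 29, 92, 285,
    475, 64, 232, 38, 42, 51, 32, 33, 46, 245, 25, 103, 226, 12, 118, 477,
    9, 126, 8, 4, 115, 18, 10, 55, 8, 9, 52, 10, 24, 53, 6, 35, 12,
    11, 20, 70, 46, 209, 24, 7, 8, 573, 32, 24, 8, 18, 536, 10, 63, 21, 71,
    298, 17, 16, 31, 62, 20, 45, 47, 11, 961, 180, 14, 323, 62, 23, 38, 112, 25, 16,
]

JTT_FREQS = np.array([
    0.076747923252076758, 0.051690948309051694, 0.042644957355042652,
    0.051543948456051550, 0.019802980197019805, 0.040751959248040752,
    0.061829938170061841, 0.073151926848073159, 0.022943977056022944,
    0.053760946239053767, 0.091903908096091905, 0.058675941324058678,
    0.023825976174023829, 0.040125959874040135, 0.050900949099050907,
    0.068764931235068771, 0.058564941435058568, 0.014260985739014262,
    0.032101967898032102, 0.066004933995066004,
])


def _jtt_exchangeability_matrix() -> np.ndarray:
    S = np.zeros((20, 20))
    k = 0
    for i in range(1, 20):
        for j in range(i):
            S[i, j] = S[j, i] = _JTT_LOWER[k]
            k += 1
    assert k == 190
    return S


def _jtt_rate_matrix() -> np.ndarray:
    """Reversible rate matrix Q, normalized to 1 expected sub/site/unit t."""
    S = _jtt_exchangeability_matrix()
    Q = S * JTT_FREQS[None, :]
    np.fill_diagonal(Q, 0.0)
    Q[np.diag_indices(20)] = -Q.sum(axis=1)
    mu = -(JTT_FREQS * np.diag(Q)).sum()
    return Q / mu


@lru_cache(maxsize=1)
def _jtt_eigen() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Symmetric eigendecomposition of Q for fast matrix exponentials.

    Reversibility means B = D^{1/2} Q D^{-1/2} is symmetric (D = diag(pi)),
    so P(t) = D^{-1/2} V exp(L t) V' D^{1/2} with B = V L V'.
    """
    Q = _jtt_rate_matrix()
    sq = np.sqrt(JTT_FREQS)
    B = (sq[:, None] * Q) / sq[None, :]
    B = (B + B.T) / 2.0  # symmetrize away rounding noise
    eigvals, eigvecs = np.linalg.eigh(B)
    left = eigvecs.T * sq[None, :]          # V' D^{1/2}
    right = eigvecs / sq[:, None]           # D^{-1/2} V
    return eigvals, right, left


def jtt_transition(t: float) -> np.ndarray:
    """Transition matrix P(t) of the normalized JTT chain; rows sum to 1."""
    if t < 0:
        raise ValueError(f"branch length must be >= 0, got {t}")
    eigvals, right, left = _jtt_eigen()
    P = (right * np.exp(eigvals * t)[None, :]) @ left
    np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=1, keepdims=True)
    return P


def _transition_batch(ts: np.ndarray) -> np.ndarray:
    """P(t) for a vector of t, shape (len(ts), 20, 20)."""
    eigvals, right, left = _jtt_eigen()
    expd = np.exp(np.outer(ts, eigvals))            # (T, 20)
    P = np.einsum("ik,tk,kj->tij", right, expd, left)
    np.clip(P, 1e-300, None, out=P)
    P /= P.sum(axis=2, keepdims=True)
    return P


# ---------------------------------------------------------------------------
# Alignments and distances
# ---------------------------------------------------------------------------

@dataclass
class ProteinAlignment:
    """Equal-length gapped protein sequences with unique taxon labels."""

    taxa: list[str]
    rows: list[str]
    region: slice | None = None

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa and rows differ in count")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"unequal row lengths: {sorted(lengths)}")
        if self.region is not None:
            self.rows = [r[self.region] for r in self.rows]
            self.region = None

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def codes(self) -> np.ndarray:
        """Integer matrix (n_taxa, n_columns); -1 for gap/X/unknown."""
        out = np.full((self.n_taxa, self.n_columns), -1, dtype=np.int16)
        for i, row in enumerate(self.rows):
            for j, ch in enumerate(row):
                out[i, j] = AA_INDEX.get(ch, -1)
        return out

    @classmethod
    def read_fasta(cls, path: str, region: slice | None = None) -> "ProteinAlignment":
        from Bio import SeqIO

        taxa, rows = [], []
        for rec in SeqIO.parse(path, "fasta"):
            taxa.append(rec.id)
            rows.append(str(rec.seq).upper())
        return cls(taxa=taxa, rows=rows, region=region)


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray
    saturated: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be non-negative")

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("taxon\t" + "\t".join(self.taxa) + "\n")
            for i, t in enumerate(self.taxa):
                fh.write(t + "\t" + "\t".join(f"{x:.6f}" for x in self.d[i]) + "\n")


_T_MIN, _T_MAX = 1e-6, 10.0


def _pair_counts(codes_a: np.ndarray, codes_b: np.ndarray) -> np.ndarray:
    """Flat 400-vector of residue-pair counts over pairwise-complete columns."""
    valid = (codes_a >= 0) & (codes_b >= 0)
    if not valid.any():
        raise ValueError("no shared non-gap columns between the two rows")
    flat = codes_a[valid].astype(np.int64) * 20 + codes_b[valid]
    return np.bincount(flat, minlength=400).astype(float)


def _pair_loglik(t: float, counts: np.ndarray, log_prior: np.ndarray) -> float:
    P = jtt_transition(t)
    return float(counts @ (log_prior + np.log(np.clip(P, 1e-300, None))).ravel())


_LOG_PRIOR = np.log(JTT_FREQS)[:, None]  # log pi(a), broadcast over b


def jtt_distance(row_a: str, row_b: str, xatol: float = 1e-6) -> float:
    """ML distance between two gapped rows under the JTT chain.

    Maximizes sum over pairwise-complete columns of log(pi(a) P_t(a,b)) by
    bounded 1-D optimization on [1e-6, 10].  Identical rows give ~0; an
    optimum pinned at the upper bound is logged as saturated.
    """
    if len(row_a) != len(row_b):
        raise ValueError("rows must be equal length")
    codes = ProteinAlignment(taxa=["a", "b"], rows=[row_a.upper(), row_b.upper()]).codes()
    counts = _pair_counts(codes[0], codes[1])
    res = minimize_scalar(
        lambda t: -_pair_loglik(t, counts, _LOG_PRIOR),
        bounds=(_T_MIN, _T_MAX),
        method="bounded",
        options={"xatol": xatol},
    )
    t_hat = float(res.x)
    if t_hat > _T_MAX - 1e-3:
        logger.warning("pairwise distance saturated (t ~ %.3f)", t_hat)
    return t_hat


_COARSE_GRID = np.geomspace(_T_MIN, _T_MAX, 160)


def jtt_distance_matrix(aln: ProteinAlignment, xatol: float = 1e-6) -> DistanceMatrix:
    """All-pairs ML JTT distances, coarse-grid bracketing + bounded refine."""
    if aln.n_columns == 0:
        raise ValueError("alignment of width 0")
    codes = aln.codes()
    n = aln.n_taxa
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    counts = np.stack([_pair_counts(codes[i], codes[j]) for i, j in pairs])
    d = _distances_from_counts(counts, xatol)
    D = np.zeros((n, n))
    saturated = set()
    for (i, j), t_hat in zip(pairs, d):
        D[i, j] = D[j, i] = t_hat
        if t_hat > _T_MAX - 1e-3:
            saturated.add((aln.taxa[i], aln.taxa[j]))
    return DistanceMatrix(taxa=list(aln.taxa), d=D, saturated=saturated)


@lru_cache(maxsize=1)
def _coarse_logP() -> np.ndarray:
    P = _transition_batch(_COARSE_GRID)
    return (np.log(P) + _LOG_PRIOR[None, :, :]).reshape(len(_COARSE_GRID), 400)


def _distances_from_counts(counts: np.ndarray, xatol: float) -> np.ndarray:
    ll = counts @ _coarse_logP().T          # (n_pairs, n_grid)
    best = np.argmax(ll, axis=1)
    out = np.empty(len(counts))
    for k, b in enumerate(best):
        lo = _COARSE_GRID[max(b - 1, 0)]
        hi = _COARSE_GRID[min(b + 1, len(_COARSE_GRID) - 1)]
        if lo == hi:
            out[k] = lo
            continue
        res = minimize_scalar(
            lambda t: -_pair_loglik(t, counts[k], _LOG_PRIOR),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": xatol},
        )
        out[k] = res.x
    return out


# ---------------------------------------------------------------------------
# Neighbor-joining
# ---------------------------------------------------------------------------

def nj_tree(D: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor-joining with the Studier-Keppler Q criterion.

    Ties on Q go to the lowest (i, j) index pair; negative branch lengths
    are clamped to 0 (original value logged).  Returns an unrooted tree
    (trifurcating seed node) with branch lengths in substitutions/site.
    """
    n = len(D.taxa)
    if n < 2:
        raise ValueError("need at least 2 taxa")

    taxon_ns = dendropy.TaxonNamespace(D.taxa)
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    nodes = []
    for label in D.taxa:
        node = dendropy.Node(taxon=taxon_ns.get_taxon(label))
        nodes.append(node)
    dist = D.d.copy()

    def clamp(value: float) -> float:
        if value < 0:
            logger.debug("negative NJ branch length %.6g clamped to 0", value)
            return 0.0
        return value

    active = list(range(len(nodes)))
    while len(active) > 3:
        m = len(active)
        sub = dist[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index pair among minima: argmin of flattened array scans in
        # row-major order, which is exactly (lowest i, then lowest j)
        flat = int(np.argmin(q))
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        vi = 0.5 * sub[ai, aj] + (r[ai] - r[aj]) / (2 * (m - 2))
        vj = sub[ai, aj] - vi
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = clamp(vi)
        nodes[j].edge.length = clamp(vj)
        # distances from the new node to every other active node
        new_row = np.zeros(dist.shape[0] + 1)
        for ak in active:
            if ak in (i, j):
                continue
            new_row[ak] = 0.5 * (dist[i, ak] + dist[j, ak] - dist[i, j])
        dist = np.pad(dist, ((0, 1), (0, 1)))
        dist[-1, :-1] = new_row[:-1]
        dist[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]

    seed = dendropy.Node()
    if len(active) == 3:
        i, j, k = active
        dij, dik, djk = dist[i, j], dist[i, k], dist[j, k]
        for idx, bl in (
            (i, (dij + dik - djk) / 2),
            (j, (dij + djk - dik) / 2),
            (k, (dik + djk - dij) / 2),
        ):
            seed.add_child(nodes[idx])
            nodes[idx].edge.length = clamp(bl)
    else:  # exactly 2
        i, j = active
        seed.add_child(nodes[i])
        seed.add_child(nodes[j])
        nodes[i].edge.length = clamp(dist[i, j] / 2)
        nodes[j].edge.length = clamp(dist[i, j] / 2)

    tree.seed_node = seed
    tree.is_rooted = False
    return tree


def patristic_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Leaf-to-leaf path lengths on the tree, in taxon-label order."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted([t.label for t in tree.taxon_namespace])
    lookup = {t.label: t for t in tree.taxon_namespace}
    n = len(taxa)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pdm.patristic_distance(lookup[taxa[i]], lookup[taxa[j]])
    return DistanceMatrix(taxa=taxa, d=D)


# ---------------------------------------------------------------------------
# Bootstrap and consensus
# ---------------------------------------------------------------------------

def bootstrap_trees(
    aln: ProteinAlignment, n_reps: int, seed: int, xatol: float = 1e-6
) -> list[dendropy.Tree]:
    """Column-bootstrap NJ trees: resample columns with replacement, then
    JTT distances + NJ per replicate.  Deterministic given seed."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if aln.n_columns == 0:
        raise ValueError("alignment of width 0")
    rng = np.random.default_rng(seed)
    codes = aln.codes()
    n, L = codes.shape
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    # per-pair per-column flat codes; -1 marks pairwise-incomplete columns
    pair_codes = np.full((len(pairs), L), -1, dtype=np.int64)
    for k, (i, j) in enumerate(pairs):
        valid = (codes[i] >= 0) & (codes[j] >= 0)
        pair_codes[k, valid] = codes[i, valid] * 20 + codes[j, valid]

    trees = []
    for _ in range(n_reps):
        weights = np.bincount(rng.integers(0, L, size=L), minlength=L).astype(float)
        counts = np.zeros((len(pairs), 400))
        for k in range(len(pairs)):
            valid = pair_codes[k] >= 0
            if not valid.any() or weights[valid].sum() == 0:
                raise ValueError("bootstrap replicate lost all shared columns")
            counts[k] = np.bincount(
                pair_codes[k][valid], weights=weights[valid], minlength=400
            )
        d = _distances_from_counts(counts, xatol)
        D = np.zeros((n, n))
        for (i, j), t_hat in zip(pairs, d):
            D[i, j] = D[j, i] = t_hat
        trees.append(nj_tree(DistanceMatrix(taxa=list(aln.taxa), d=D)))
    return trees


def _bipartitions(tree: dendropy.Tree) -> dict[frozenset, dendropy.Node]:
    """Internal-edge bipartitions keyed by the smaller taxon-label side."""
    all_taxa = frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())
    out = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        other = all_taxa - side
        if len(side) < 2 or len(other) < 2:
            continue  # trivial split
        key = min(side, other, key=lambda s: (len(s), sorted(s)))
        out[key] = node
    return out


def consensus_support(
    main: dendropy.Tree, reps: list[dendropy.Tree]
) -> dendropy.Tree:
    """Annotate each internal edge of ``main`` with the count of replicate
    trees containing the same bipartition (stored as ``node.label`` and
    ``node.support``)."""
    main_taxa = frozenset(l.taxon.label for l in main.leaf_node_iter())
    for rep in reps:
        rep_taxa = frozenset(l.taxon.label for l in rep.leaf_node_iter())
        if rep_taxa != main_taxa:
            raise ValueError("taxon-set mismatch between main tree and replicates")
    rep_counts: dict[frozenset, int] = {}
    for rep in reps:
        for key in _bipartitions(rep):
            rep_counts[key] = rep_counts.get(key, 0) + 1
    for key, node in _bipartitions(main).items():
        node.support = rep_counts.get(key, 0)
        node.label = str(node.support)
    return main


def majority_rule_consensus(reps: list[dendropy.Tree]) -> dendropy.Tree:
    """Majority-rule consensus topology of the replicates."""
    tns = reps[0].taxon_namespace
    tl = dendropy.TreeList(taxon_namespace=tns)
    for rep in reps:
        tl.append(dendropy.Tree(rep, taxon_namespace=tns))
    return tl.consensus(min_freq=0.5)


def robinson_foulds(a: dendropy.Tree, b: dendropy.Tree) -> int:
    """Unweighted RF distance (symmetric difference of bipartitions)."""
    ka, kb = set(_bipartitions(a)), set(_bipartitions(b))
    return len(ka ^ kb)


# ---------------------------------------------------------------------------
# Subfamily splitting by genomic context
# ---------------------------------------------------------------------------

@dataclass
class SubfamilyPartition:
    members: list[str]
    dominant_context: str | None  # None when every member context is empty
    min_support: int | None       # support on subtending edge, if annotated
    conflicts: list[str] = field(default_factory=list)


def split_subfamilies(
    tree: dendropy.Tree, context_labels: dict[str, set[str]]
) -> list[SubfamilyPartition]:
    """Partition the tree into maximal clades of agreeing genomic context.

    Walks from the seed node down; a subtree whose members' non-empty
    context sets all agree on a single label becomes one partition
    (empty-context members ride along).  Subtrees with mixed contexts are
    descended into.  When two or more partitions share a dominant context,
    only the largest is kept as the subfamily; smaller ones are reported
    as conflicting placements.
    """
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label not in context_labels:
            raise ValueError(f"taxon {leaf.taxon.label!r} has no context entry")

    # clades of an unrooted tree depend on the rooting; midpoint rooting
    # puts the root on the deepest split, making both subfamilies proper
    # subtrees.  Supports are carried over by bipartition identity.
    all_taxa = frozenset(l.taxon.label for l in tree.leaf_node_iter())

    def bipartition_key(side: frozenset) -> frozenset:
        other = all_taxa - side
        return min(side, other, key=lambda s: (len(s), sorted(s)))

    support_map = {
        key: getattr(node, "support", None)
        for key, node in _bipartitions(tree).items()
    }
    work = dendropy.Tree(tree)
    if len(all_taxa) > 2:
        try:
            work.reroot_at_midpoint(update_bipartitions=False)
        except (AssertionError, ValueError):  # degenerate branch lengths
            pass

    def node_support(node) -> int | None:
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if len(side) < 2 or len(all_taxa - side) < 2:
            return None
        return support_map.get(bipartition_key(side))

    partitions: list[SubfamilyPartition] = []

    def leaf_labels(node) -> list[str]:
        return [l.taxon.label for l in node.leaf_iter()]

    def label_counts(members: list[str]) -> dict[str, int]:
        counts: dict[str, int] = {}
        for m in members:
            for lab in context_labels[m]:
                counts[lab] = counts.get(lab, 0) + 1
        return counts

    def clean_partitions(node) -> list[SubfamilyPartition]:
        """Maximal single-context subtrees below (and including) node."""
        members = leaf_labels(node)
        counts = label_counts(members)
        if len(counts) <= 1:
            ctx = next(iter(counts)) if counts else None
            return [
                SubfamilyPartition(
                    members=sorted(members),
                    dominant_context=ctx,
                    min_support=node_support(node),
                )
            ]
        out = []
        for child in node.child_nodes():
            out.extend(clean_partitions(child))
        return out

    def walk(node) -> None:
        members = leaf_labels(node)
        counts = label_counts(members)
        if len(counts) <= 1:
            partitions.extend(clean_partitions(node))
            return
        # mixed subtree with exactly one odd taxon out: absorb it into the
        # surrounding clade as a conflicting placement (subtrees holding
        # several outliers keep recursing, so scattered outliers are each
        # resolved at the deepest subtree that isolates them)
        majority = max(sorted(counts), key=lambda lab: counts[lab])
        minority_parts = [
            p
            for p in clean_partitions(node)
            if p.dominant_context not in (None, majority)
        ]
        minority_n = sum(len(p.members) for p in minority_parts)
        if minority_n == 1 and counts[majority] >= 2:
            partitions.append(
                SubfamilyPartition(
                    members=sorted(members),
                    dominant_context=majority,
                    min_support=node_support(node),
                    conflicts=sorted(m for p in minority_parts for m in p.members),
                )
            )
            return
        for child in node.child_nodes():
            walk(child)

    walk(work.seed_node)

    # one subfamily per context: the tree is unrooted, so a clade may
    # surface as several sibling subtrees around the seed trifurcation —
    # same-context partitions are merged into a single subfamily
    by_context: dict[str, list[SubfamilyPartition]] = {}
    for part in partitions:
        if part.dominant_context is not None:
            by_context.setdefault(part.dominant_context, []).append(part)
    keep: list[SubfamilyPartition] = []
    unlabeled = [p for p in partitions if p.dominant_context is None]
    for context, parts in sorted(by_context.items()):
        supports = [p.min_support for p in parts if p.min_support is not None]
        keep.append(
            SubfamilyPartition(
                members=sorted({m for p in parts for m in p.members}),
                dominant_context=context,
                min_support=min(supports) if supports else None,
                conflicts=sorted({m for p in parts for m in p.conflicts}),
            )
        )
    # empty-context stragglers that were not absorbed form one unassigned pool
    if unlabeled:
        pool = sorted(m for p in unlabeled for m in p.members)
        keep.append(
            SubfamilyPartition(members=pool, dominant_context=None, min_support=None)
        )
    return keep


def write_newick(tree: dendropy.Tree, path: str) -> None:
    tree.write(path=path, schema="newick", suppress_rooting=True)
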