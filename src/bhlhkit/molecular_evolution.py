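"""Codon-level substitution statistics and distance-based phylogenetics.

This module covers the molecular-evolution layer of the toolkit:

* global protein alignment (affine gaps) and back-translation to a codon
  alignment;
* Nei–Gojobori (1986) counting of synonymous/nonsynonymous sites and
  differences with Jukes–Cantor correction, yielding Ka, Ks and Ka/Ks;
* protein distance matrices with partial-deletion gap handling
  (p-distance or Poisson-corrected);
* neighbor-joining tree construction with column-bootstrap support;
* clade assignment by cutting internal edges (or around anchor genes) and
  Ks-based inference of post-speciation lineage expansions in tandem
  transcription-factor clusters.

Under Nei–Gojobori counting, each codon contributes synonymous site
fractions obtained by enumerating all nine single-nucleotide changes
(changes creating a stop codon count as nonsynonymous), and the observed
differences between a codon pair are averaged with equal weight over all
minimal mutational pathways that avoid stop codons.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data import CodonTable

from .errors import InputError

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Genetic code tables
# ---------------------------------------------------------------------------

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
SENSE_CODONS: tuple[str, ...] = tuple(sorted(_STANDARD_TABLE.forward_table))
STOP_CODONS: frozenset[str] = frozenset(_STANDARD_TABLE.stop_codons)
AA_OF: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
NUCLEOTIDES = "ACGT"

GAP_CODON = "---"


def translate_codons(codons: Iterable[str]) -> str:
    """Translate an iterable of sense codons to an amino-acid string."""
    try:
        return "".join(AA_OF[c] for c in codons)
    except KeyError as exc:  # stop or malformed codon
        raise InputError(f"cannot translate codon {exc.args[0]!r}") from exc


# ---------------------------------------------------------------------------
# NG86 site and pathway counting
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def synonymous_site_fraction(codon: str) -> float:
    """Number of synonymous sites in ``codon`` (0..3).

    Each of the three positions contributes (number of synonymous
    single-nucleotide changes)/3; mutations to stop codons are counted as
    nonsynonymous.
    """
    if codon not in AA_OF:
        raise InputError(f"not a sense codon: {codon!r}")
    aa = AA_OF[codon]
    s = 0.0
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if AA_OF.get(alt) == aa:
                s += 1.0 / 3.0
    return s


@lru_cache(maxsize=None)
def pathway_difference_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two sense codons.

    Averaged with equal weight over every ordering of the differing
    positions whose intermediate codons are all sense codons.  If every
    pathway passes through a stop codon (a rare corner), all pathways are
    used and steps touching a stop are counted as nonsynonymous.
    """
    for c in (codon_a, codon_b):
        if c not in AA_OF:
            raise InputError(f"not a sense codon: {c!r}")
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return (0.0, 0.0)

    def walk(order: tuple[int, ...], allow_stops: bool) -> tuple[float, float] | None:
        sd = nd = 0.0
        cur = codon_a
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS and not allow_stops:
                return None
            if AA_OF.get(cur) is not None and AA_OF.get(nxt) == AA_OF.get(cur):
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        return sd, nd

    orders = list(itertools.permutations(diff_positions))
    counted = [w for w in (walk(o, False) for o in orders) if w is not None]
    if not counted:
        counted = [walk(o, True) for o in orders]  # type: ignore[misc]
    sd = sum(c[0] for c in counted) / len(counted)
    nd = sum(c[1] for c in counted) / len(counted)
    return sd, nd


@dataclass(frozen=True)
class SubstitutionRates:
    """NG86 counts and Jukes–Cantor-corrected rates for one codon-aligned pair."""

    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ks: float
    Ka: float
    ratio: float | None
    saturated: bool
    n_codons: int
    method: str = "NG86"


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        return math.nan
    if p <= 0.0:
        return 0.0
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


@dataclass(frozen=True)
class CodonAlignment:
    """Pairwise codon alignment: per-position codon or the 3-nt gap ``---``."""

    codons_a: tuple[str, ...]
    codons_b: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.codons_a) != len(self.codons_b):
            raise InputError("codon alignment rows have different lengths")
        for row in (self.codons_a, self.codons_b):
            for c in row:
                if c != GAP_CODON and c not in AA_OF:
                    raise InputError(f"alignment contains non-sense codon {c!r}")
        for ca, cb in zip(self.codons_a, self.codons_b):
            if ca == GAP_CODON and cb == GAP_CODON:
                raise InputError("codon alignment contains a gap-gap column")

    def ungapped_columns(self) -> list[tuple[str, str]]:
        return [
            (ca, cb)
            for ca, cb in zip(self.codons_a, self.codons_b)
            if ca != GAP_CODON and cb != GAP_CODON
        ]


def compute_ng86(aln: CodonAlignment) -> SubstitutionRates:
    """Nei–Gojobori (1986) Ka/Ks for a pairwise codon alignment.

    Site counts are averaged over the two sequences; differences are
    averaged over minimal stop-free mutational pathways; proportions are
    Jukes–Cantor corrected.  ``pS >= 3/4`` or ``pN >= 3/4`` flags
    saturation and leaves the corrected value undefined (NaN).
    """
    columns = aln.ungapped_columns()
    if not columns:
        raise InputError("codon alignment has no ungapped columns")
    s_a = s_b = 0.0
    sd = nd = 0.0
    for ca, cb in columns:
        s_a += synonymous_site_fraction(ca)
        s_b += synonymous_site_fraction(cb)
        d_s, d_n = pathway_difference_counts(ca, cb)
        sd += d_s
        nd += d_n
    n_codons = len(columns)
    S = (s_a + s_b) / 2.0
    N = 3.0 * n_codons - S
    pS = sd / S if S > 0 else 0.0
    pN = nd / N if N > 0 else 0.0
    saturated = pS >= 0.75 or pN >= 0.75
    Ks = _jukes_cantor(pS)
    Ka = _jukes_cantor(pN)
    ratio: float | None = None
    if not saturated and Ks > 0 and not math.isnan(Ka):
        ratio = Ka / Ks
    return SubstitutionRates(
        S=S, N=N, Sd=sd, Nd=nd, pS=pS, pN=pN, Ks=Ks, Ka=Ka,
        ratio=ratio, saturated=saturated, n_codons=n_codons,
    )


# ---------------------------------------------------------------------------
# Protein alignment and back-translation
# ---------------------------------------------------------------------------

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class PairwiseAlignment:
    """Two gapped amino-acid strings of equal length plus the alignment score."""

    a_aligned: str
    b_aligned: str
    score: float

    def __post_init__(self) -> None:
        if len(self.a_aligned) != len(self.b_aligned):
            raise InputError("aligned strings differ in length")
        for x, y in zip(self.a_aligned, self.b_aligned):
            if x == "-" and y == "-":
                raise InputError("alignment contains a gap-gap column")


def align_proteins_global(
    a: str,
    b: str,
    *,
    matrix: str = "BLOSUM62",
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
) -> PairwiseAlignment:
    """Optimal global (Needleman–Wunsch–Gotoh) alignment with affine gaps.

    Deterministic: the first optimal alignment reported by the aligner is
    returned, which is stable for fixed inputs and parameters.
    """
    for name, seq in (("a", a), ("b", b)):
        if not seq:
            raise InputError(f"sequence {name} is empty")
        bad = set(seq) - PROTEIN_ALPHABET
        if bad:
            raise InputError(f"sequence {name} contains invalid residues {sorted(bad)}")
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    result = aligner.align(a, b)
    best = result[0]
    return PairwiseAlignment(str(best[0]), str(best[1]), float(best.score))


def backtranslate_codon_alignment(
    protein_aln: PairwiseAlignment,
    cds_a: Sequence[str] | str,
    cds_b: Sequence[str] | str,
    *,
    a_id: str = "a",
    b_id: str = "b",
) -> CodonAlignment:
    """Expand a protein alignment to codons using the two source CDSs.

    Each amino-acid column becomes the source codon or a 3-nt gap.  The
    CDSs must translate exactly to the ungapped proteins; a mismatch
    raises an error naming the offending sequence and codon position.
    """
    def to_codons(cds: Sequence[str] | str, name: str) -> list[str]:
        if isinstance(cds, str):
            if len(cds) % 3:
                raise InputError(f"CDS of {name} has length not divisible by 3")
            return [cds[i : i + 3] for i in range(0, len(cds), 3)]
        return list(cds)

    rows = []
    for name, gapped, cds in ((a_id, protein_aln.a_aligned, cds_a), (b_id, protein_aln.b_aligned, cds_b)):
        codons = to_codons(cds, name)
        protein = gapped.replace("-", "")
        if len(codons) != len(protein):
            raise InputError(
                f"{name}: CDS has {len(codons)} codons but protein has {len(protein)} residues"
            )
        for i, (codon, aa) in enumerate(zip(codons, protein)):
            if AA_OF.get(codon) != aa:
                raise InputError(
                    f"{name}: codon {i} ({codon}) does not translate to residue {aa!r}"
                )
        it = iter(codons)
        rows.append(tuple(next(it) if ch != "-" else GAP_CODON for ch in gapped))
    return CodonAlignment(rows[0], rows[1])


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    matrix: np.ndarray  # symmetric, zero diagonal; np.inf for incomparable pairs
    method: str
    partial_deletion_coverage: float

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.labels), len(self.labels)):
            raise InputError("distance matrix shape does not match labels")
        if not np.allclose(m, m.T, equal_nan=True):
            raise InputError("distance matrix is not symmetric")

    @property
    def flagged_pairs(self) -> list[tuple[str, str]]:
        out = []
        for i, j in zip(*np.where(~np.isfinite(self.matrix))):
            if i < j:
                out.append((self.labels[i], self.labels[j]))
        return out


def protein_distance_matrix(
    alignment: Mapping[str, str],
    *,
    method: str = "poisson",
    partial_deletion_coverage: float = 0.8,
) -> DistanceMatrix:
    """Pairwise distances from a protein multiple alignment.

    Columns with non-gap coverage below ``partial_deletion_coverage`` are
    removed first (partial deletion).  ``method`` is ``"p"`` for raw
    p-distance or ``"poisson"`` for the Poisson correction -ln(1-p).
    Pairs with no comparable columns are flagged with an infinite
    distance.
    """
    if method not in ("p", "poisson"):
        raise InputError(f"unknown distance method {method!r}")
    labels = tuple(alignment)
    if len(labels) < 3:
        raise InputError("distance matrix requires at least 3 sequences")
    rows = [alignment[l] for l in labels]
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows):
        raise InputError("alignment rows have unequal lengths")
    arr = np.array([list(r) for r in rows])
    coverage = (arr != "-").mean(axis=0)
    keep = coverage >= partial_deletion_coverage
    arr = arr[:, keep]
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = (arr[i] != "-") & (arr[j] != "-")
            total = int(both.sum())
            if total == 0:
                d[i, j] = d[j, i] = np.inf
                continue
            p = float((arr[i][both] != arr[j][both]).sum()) / total
            if method == "p":
                dist = p
            else:
                dist = np.inf if p >= 1.0 else -math.log1p(-p)
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(labels, d, method, partial_deletion_coverage)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


@dataclass
class PhyloTree:
    """Unrooted tree as an adjacency map with branch lengths.

    Nodes are integers; leaves carry labels.  Negative NJ branch
    estimates are clamped to zero and recorded in ``clamped_edges``.
    """

    adjacency: dict[int, dict[int, float]]
    leaf_labels: dict[int, str]
    clamped_edges: list[tuple[int, int]] = field(default_factory=list)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.leaf_labels[n] for n in sorted(self.leaf_labels))

    def _node_of(self, label: str) -> int:
        for node, lab in self.leaf_labels.items():
            if lab == label:
                return node
        raise InputError(f"no leaf labelled {label!r}")

    def leaf_distance(self, a: str, b: str) -> float:
        """Path-length distance between two leaves."""
        start, goal = self._node_of(a), self._node_of(b)
        stack = [(start, -1, 0.0)]
        while stack:
            node, prev, dist = stack.pop()
            if node == goal:
                return dist
            for nbr, length in self.adjacency[node].items():
                if nbr != prev:
                    stack.append((nbr, node, dist + length))
        raise InputError("tree is disconnected")

    def leaf_distance_matrix(self) -> DistanceMatrix:
        labels = self.labels
        n = len(labels)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = self.leaf_distance(labels[i], labels[j])
        return DistanceMatrix(labels, d, "tree-path", 0.0)

    def internal_edges(self) -> list[tuple[int, int]]:
        out = []
        for u, nbrs in self.adjacency.items():
            for v in nbrs:
                if u < v and u not in self.leaf_labels and v not in self.leaf_labels:
                    out.append((u, v))
        return out

    def edge_bipartition(self, u: int, v: int) -> frozenset[str]:
        """Canonical bipartition for an edge: the leaf side not containing
        the alphabetically first leaf."""
        side = set()
        stack = [(v, u)]
        while stack:
            node, prev = stack.pop()
            if node in self.leaf_labels:
                side.add(self.leaf_labels[node])
            for nbr in self.adjacency[node]:
                if nbr != prev:
                    stack.append((nbr, node))
        first = min(self.labels)
        if first in side:
            side = set(self.labels) - side
        return frozenset(side)

    def bipartitions(self) -> dict[frozenset[str], tuple[int, int]]:
        """Non-trivial bipartitions (internal edges only)."""
        out = {}
        for u, v in self.internal_edges():
            out[self.edge_bipartition(u, v)] = (u, v)
        return out

    def newick(self, support: Mapping[frozenset[str], float] | None = None) -> str:
        """Newick string, rooted for writing at the highest-degree node."""
        root = max(self.adjacency, key=lambda n: (len(self.adjacency[n]), -n))

        def render(node: int, prev: int) -> str:
            if node in self.leaf_labels:
                return self.leaf_labels[node]
            parts = [
                f"{render(nbr, node)}:{length:.6f}"
                for nbr, length in sorted(self.adjacency[node].items())
                if nbr != prev
            ]
            label = ""
            if support is not None and prev >= 0:
                bip = self.edge_bipartition(prev, node)
                if bip in support:
                    label = f"{support[bip]:.2f}"
            return "(" + ",".join(parts) + ")" + label

        return render(root, -1) + ";"


def build_nj_tree(d: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining on the Q-criterion.

    Ties in Q are broken by the lexicographically smallest (label, label)
    pair, where an internal node carries the smallest leaf label beneath
    it.  Negative branch-length estimates are clamped to zero and
    flagged.
    """
    n = len(d.labels)
    if n < 3:
        raise InputError("neighbor joining requires at least 3 taxa")
    if not np.all(np.isfinite(d.matrix)):
        raise InputError("distance matrix contains non-finite entries")
    adjacency: dict[int, dict[int, float]] = {i: {} for i in range(n)}
    leaf_labels = dict(enumerate(d.labels))
    clamped: list[tuple[int, int]] = []
    active = list(range(n))
    node_label = {i: d.labels[i] for i in range(n)}
    dist = {
        (i, j): float(d.matrix[i, j])
        for i in range(n)
        for j in range(n)
        if i != j
    }
    next_node = n

    def get(i: int, j: int) -> float:
        return dist[(i, j)]

    def add_edge(u: int, v: int, length: float) -> None:
        if length < 0:
            clamped.append((u, v))
            length = 0.0
        adjacency.setdefault(u, {})[v] = length
        adjacency.setdefault(v, {})[u] = length

    while len(active) > 3:
        m = len(active)
        r = {i: sum(get(i, j) for j in active if j != i) for i in active}
        best = None
        for ii, i in enumerate(active):
            for j in active[ii + 1 :]:
                q = (m - 2) * get(i, j) - r[i] - r[j]
                key = (q, tuple(sorted((node_label[i], node_label[j]))))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best  # type: ignore[misc]
        dij = get(i, j)
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        u = next_node
        next_node += 1
        add_edge(u, i, li)
        add_edge(u, j, lj)
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (get(i, k) + get(j, k) - dij)
            dist[(u, k)] = dist[(k, u)] = duk
        active = [k for k in active if k not in (i, j)] + [u]
        node_label[u] = min(node_label[i], node_label[j])

    i, j, k = active
    u = next_node
    add_edge(u, i, 0.5 * (get(i, j) + get(i, k) - get(j, k)))
    add_edge(u, j, 0.5 * (get(i, j) + get(j, k) - get(i, k)))
    add_edge(u, k, 0.5 * (get(i, k) + get(j, k) - get(i, j)))
    return PhyloTree(adjacency, leaf_labels, clamped)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------


def bootstrap_support(
    alignment: Mapping[str, str],
    tree_builder: Callable[[Mapping[str, str]], PhyloTree] | None = None,
    n_reps: int = 1000,
    seed: int = 0,
    *,
    distance_method: str = "poisson",
    partial_deletion_coverage: float = 0.8,
) -> dict[frozenset[str], float]:
    """Column-bootstrap support for each internal edge of the NJ tree.

    Columns are resampled with replacement ``n_reps`` times; support for a
    bipartition of the reference tree is the fraction of replicate trees
    containing it.  Fully seed-deterministic.
    """
    if n_reps < 0:
        raise InputError("n_reps must be >= 0")

    def default_builder(aln: Mapping[str, str]) -> PhyloTree:
        d = protein_distance_matrix(
            aln,
            method=distance_method,
            partial_deletion_coverage=partial_deletion_coverage,
        )
        m = d.matrix.copy()
        if not np.all(np.isfinite(m)):  # keep replicates usable
            finite_max = np.nanmax(m[np.isfinite(m)]) if np.isfinite(m).any() else 1.0
            m[~np.isfinite(m)] = 2.0 * max(finite_max, 1.0)
            d = DistanceMatrix(d.labels, m, d.method, d.partial_deletion_coverage)
        return build_nj_tree(d)

    builder = tree_builder or default_builder
    reference = builder(alignment)
    target_bips = set(reference.bipartitions())
    if n_reps == 0:
        return {}
    labels = list(alignment)
    ncol = len(alignment[labels[0]])
    rng = np.random.default_rng(seed)
    counts = {bip: 0 for bip in target_bips}
    rows = {l: alignment[l] for l in labels}
    for _ in range(n_reps):
        cols = rng.integers(0, ncol, size=ncol)
        resampled = {l: "".join(rows[l][c] for c in cols) for l in labels}
        rep_bips = set(builder(resampled).bipartitions())
        for bip in target_bips & rep_bips:
            counts[bip] += 1
    return {bip: counts[bip] / n_reps for bip in target_bips}


# ---------------------------------------------------------------------------
# Clade assignment
# ---------------------------------------------------------------------------

_ROMAN = [
    (50, "L"), (40, "XL"), (10, "X"), (9, "IX"),
    (5, "V"), (4, "IV"), (1, "I"),
]


def roman(n: int) -> str:
    out = []
    for value, sym in _ROMAN:
        while n >= value:
            out.append(sym)
            n -= value
    return "".join(out)


@dataclass(frozen=True)
class CladeAssignment:
    assignment: dict[str, str]  # leaf label -> clade label
    k: int
    cut_edges: tuple[frozenset[str], ...]

    def members(self, clade: str) -> list[str]:
        return sorted(l for l, c in self.assignment.items() if c == clade)

    @property
    def clades(self) -> list[str]:
        return sorted(set(self.assignment.values()))


def assign_clades(
    tree: PhyloTree,
    k: int,
    anchor_genes: Mapping[str, Sequence[str]] | None = None,
) -> CladeAssignment:
    """Partition the leaves into ``k`` clades.

    Without anchors, the tree's leaf metric is cut at its k-1 deepest
    splits by single-linkage agglomeration: the closest leaf groups are
    merged (ties broken by the lexicographically smallest label pair)
    until k groups remain, so the surviving boundaries are the deepest
    divergences of the tree.  Groups are labelled I..k in order of their
    alphabetically first leaf.  With anchors (clade label -> anchor
    leaves), every leaf joins the clade of its nearest anchor by path
    length; the resulting regions must be connected and separate all
    anchor groups, otherwise the conflicting anchors are reported.
    """
    labels = tree.labels
    if k > len(labels):
        raise InputError(f"k={k} exceeds leaf count {len(labels)}")
    if k < 1:
        raise InputError("k must be >= 1")

    if anchor_genes is None:
        pairs = sorted(
            (
                (tree.leaf_distance(a, b), a, b)
                for a, b in itertools.combinations(labels, 2)
            ),
            key=lambda t: (t[0], t[1], t[2]),
        )
        parent = {l: l for l in labels}

        def find(x: str) -> str:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        n_groups = len(labels)
        for _, a, b in pairs:
            if n_groups <= k:
                break
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
                n_groups -= 1
        grouped: dict[str, list[str]] = {}
        for leaf in labels:
            grouped.setdefault(find(leaf), []).append(leaf)
        groups = sorted((sorted(g) for g in grouped.values()), key=lambda g: g[0])
        assignment = {}
        for idx, group in enumerate(groups, start=1):
            for leaf in group:
                assignment[leaf] = roman(idx)
        return CladeAssignment(
            assignment, len(groups), tuple(frozenset(g) for g in groups)
        )

    # Anchor-guided: Voronoi partition by path distance to anchors.
    leaf_node = {lab: node for node, lab in tree.leaf_labels.items()}
    anchor_of: dict[str, str] = {}
    for clade, genes in anchor_genes.items():
        for g in genes:
            if g not in leaf_node:
                raise InputError(f"anchor {g!r} is not a leaf of the tree")
            if g in anchor_of and anchor_of[g] != clade:
                raise InputError(
                    f"anchor conflict: leaf {g!r} anchors both {anchor_of[g]} and {clade}"
                )
            anchor_of[g] = clade
    assignment = {}
    for leaf in labels:
        best: tuple[float, str] | None = None
        for clade in sorted(anchor_genes):
            dmin = min(tree.leaf_distance(leaf, g) for g in anchor_genes[clade])
            if best is None or (dmin, clade) < best:
                best = (dmin, clade)
        assignment[leaf] = best[1]  # type: ignore[index]
    # Verify each clade's leaves form a connected subtree.
    for clade in sorted(anchor_genes):
        members = {l for l, c in assignment.items() if c == clade}
        if members and not _leaves_connected(tree, members):
            raise InputError(
                f"anchors for clade {clade} do not separate cleanly; "
                f"members {sorted(members)} are not a connected subtree"
            )
    return CladeAssignment(assignment, len(set(assignment.values())), ())


def _leaf_components(tree: PhyloTree, cut_edges: set[tuple[int, int]]) -> list[list[str]]:
    seen: set[int] = set()
    groups: list[list[str]] = []
    for start in tree.adjacency:
        if start in seen:
            continue
        comp_leaves: list[str] = []
        stack = [start]
        seen.add(start)
        while stack:
            node = stack.pop()
            if node in tree.leaf_labels:
                comp_leaves.append(tree.leaf_labels[node])
            for nbr in tree.adjacency[node]:
                if (node, nbr) in cut_edges or nbr in seen:
                    continue
                seen.add(nbr)
                stack.append(nbr)
        if comp_leaves:
            groups.append(sorted(comp_leaves))
    return groups


def _leaves_connected(tree: PhyloTree, members: set[str]) -> bool:
    """True if the minimal subtree spanning ``members`` contains no leaf
    outside ``members`` assigned elsewhere — approximated by checking the
    Steiner tree's leaves."""
    nodes = {node for node, lab in tree.leaf_labels.items() if lab in members}
    if len(nodes) <= 1:
        return True
    # Steiner tree of the member leaves: union of pairwise paths.
    first = next(iter(nodes))
    steiner: set[int] = set()
    for target in nodes:
        path = _path(tree, first, target)
        steiner.update(path)
    for node in steiner:
        if node in tree.leaf_labels and tree.leaf_labels[node] not in members:
            return False
    return True


def _path(tree: PhyloTree, a: int, b: int) -> list[int]:
    parent = {a: -1}
    stack = [a]
    while stack:
        node = stack.pop()
        if node == b:
            break
        for nbr in tree.adjacency[node]:
            if nbr not in parent:
                parent[nbr] = node
                stack.append(nbr)
    path = [b]
    while parent[path[-1]] != -1:
        path.append(parent[path[-1]])
    return path


# ---------------------------------------------------------------------------
# Lineage-expansion inference
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpansionCall:
    species: str
    clade: str
    genes: tuple[str, ...]
    verdict: str  # "expansion" | "ancestral" | "loss"
    intra_ks_max: float | None
    inter_ks_min: float | None
    recent: bool
    recent_dup_threshold: float


def infer_lineage_expansion(
    genes_by_species: Mapping[str, Sequence[str]],
    ks_table: Mapping[frozenset[str], float | None],
    clades: CladeAssignment,
    *,
    recent_dup_threshold: float = 0.32,
    species_universe: Sequence[str] | None = None,
) -> list[ExpansionCall]:
    """Call post-speciation expansions inside a clustered gene family.

    Within each clade, a species' gene set is a post-speciation
    expansion iff its maximum intra-species Ks is smaller than the
    minimum inter-species Ks from that species to other clade members;
    clades with no member in a species yield a loss call.  Saturated or
    missing Ks values (``None``) are skipped with a warning.  The
    ``recent`` flag marks intra-species duplications whose Ks falls
    below ``recent_dup_threshold``.
    """
    species_of = {
        g: sp for sp, genes in genes_by_species.items() for g in genes
    }
    universe = list(species_universe or sorted(genes_by_species))
    calls: list[ExpansionCall] = []

    def ks(a: str, b: str) -> float | None:
        value = ks_table.get(frozenset((a, b)))
        if value is None or (isinstance(value, float) and math.isnan(value)):
            logger.warning("Ks unavailable or saturated for pair (%s, %s); skipped", a, b)
            return None
        return value

    for clade in clades.clades:
        members = [g for g in clades.members(clade) if g in species_of]
        if not members:
            continue
        for sp in universe:
            own = tuple(g for g in members if species_of[g] == sp)
            others = [g for g in members if species_of[g] != sp]
            if not own:
                calls.append(
                    ExpansionCall(sp, clade, (), "loss", None, None, False,
                                  recent_dup_threshold)
                )
                continue
            intra = [
                v for a, b in itertools.combinations(own, 2)
                if (v := ks(a, b)) is not None
            ]
            inter = [
                v for a in own for b in others
                if (v := ks(a, b)) is not None
            ]
            intra_max = max(intra) if intra else None
            inter_min = min(inter) if inter else None
            if len(own) >= 2 and intra_max is not None:
                if inter_min is not None:
                    verdict = "expansion" if intra_max < inter_min else "ancestral"
                else:
                    verdict = (
                        "expansion" if intra_max < recent_dup_threshold else "ancestral"
                    )
            else:
                verdict = "ancestral"
            recent = intra_max is not None and intra_max < recent_dup_threshold
            calls.append(
                ExpansionCall(sp, clade, own, verdict, intra_max, inter_min,
                              recent, recent_dup_threshold)
            )
    return calls


def copy_number_table(calls: Iterable[ExpansionCall]):
    """Species x clade copy-number table from expansion calls."""
    import pandas as pd

    records = {}
    for call in calls:
        records.setdefault(call.species, {})[call.clade] = len(call.genes)
    frame = pd.DataFrame.from_dict(records, orient="index").fillna(0).astype(int)
    return frame.sort_index().reindex(sorted(frame.columns), axis=1)
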