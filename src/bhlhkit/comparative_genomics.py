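"""Synteny-based comparative genomics: collinear blocks, orthologs,
paralogs and tandem duplicates.

Collinear blocks are maximal-score chains of homology anchors with
strictly monotone gene ranks on both sides (increasing, or decreasing on
the second side for inverted blocks), found per chromosome pair by
dynamic programming with a per-rank gap penalty.  Inter-genomic blocks
yield ortholog pairs, whose connected components become ortholog groups
(OGs); intra-genomic blocks yield paralog pairs; tandem clusters are
connected runs of same-chromosome homologs within a small rank gap.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

from .errors import InputError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Loci and anchors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneLocus:
    gene_id: str
    species: str
    chromosome: str
    rank: int  # order along the chromosome
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise InputError(f"{self.gene_id}: start >= end")


@dataclass(frozen=True)
class AnchorPair:
    """A homology anchor between two genes (canonically ordered)."""

    gene_a: str
    gene_b: str
    similarity: float = 1.0
    kind: str = "inter"  # "inter" or "intra"

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise InputError(f"anchor pairs a gene with itself: {self.gene_a}")
        if self.gene_a > self.gene_b:
            a, b = self.gene_b, self.gene_a
            object.__setattr__(self, "gene_a", a)
            object.__setattr__(self, "gene_b", b)


def natural_chromosome_key(chromosome: str) -> tuple:
    """Natural sort key: chr2 < chr10; unplaced scaffolds sort after."""
    match = re.match(r"^(chr|Chr|chromosome)?_?0*(\d+)$", chromosome)
    if match:
        return (0, int(match.group(2)), chromosome)
    return (1, 0, chromosome)


# ---------------------------------------------------------------------------
# Collinear block chaining
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CollinearBlock:
    block_id: str
    anchors: tuple[tuple[str, str], ...]  # ordered along the a-side
    side_a: tuple[str, str]  # (species, chromosome)
    side_b: tuple[str, str]
    orientation: str  # "same" or "inverted"
    score: float
    size: int

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(g for pair in self.anchors for g in pair)


@dataclass(frozen=True)
class ChainingParams:
    min_block_size: int = 5
    max_gap_ranks: int = 25
    gap_penalty: float = 0.05
    match_score: float = 1.0


def _orient_anchor(anchor: AnchorPair, loci: Mapping[str, GeneLocus]):
    for gene in (anchor.gene_a, anchor.gene_b):
        if gene not in loci:
            raise InputError(f"anchor references unknown locus {gene!r}")
    la, lb = loci[anchor.gene_a], loci[anchor.gene_b]
    ka = (la.species, natural_chromosome_key(la.chromosome), la.rank)
    kb = (lb.species, natural_chromosome_key(lb.chromosome), lb.rank)
    if kb < ka:
        la, lb = lb, la
    return la, lb


def _chain_group(
    anchors: list[tuple[int, int, str, str]],
    orientation: str,
    params: ChainingParams,
) -> tuple[list[tuple[int, int, str, str]], float] | None:
    """Best chain (max score; ties -> smaller starting a-rank) for one
    orientation.  Anchor tuples are (rank_a, rank_b, gene_a, gene_b)."""
    sign = 1 if orientation == "same" else -1
    items = sorted(anchors, key=lambda t: (t[0], sign * t[1]))
    n = len(items)
    if n == 0:
        return None
    # DP over anchors sorted by a-rank.
    score = [params.match_score] * n
    start = [(items[i][0], items[i][1]) for i in range(n)]
    parent = [-1] * n
    for i in range(n):
        ra_i, rb_i = items[i][0], items[i][1]
        for j in range(i):
            ra_j, rb_j = items[j][0], items[j][1]
            if ra_j >= ra_i:
                continue
            if sign * rb_j >= sign * rb_i:
                continue
            gap_a = ra_i - ra_j - 1
            gap_b = abs(rb_i - rb_j) - 1
            if gap_a > params.max_gap_ranks or gap_b > params.max_gap_ranks:
                continue
            cand = score[j] + params.match_score - params.gap_penalty * (gap_a + gap_b)
            key = (cand, -start[j][0], -start[j][1])
            if (score[i], -start[i][0], -start[i][1]) < key:
                score[i] = cand
                start[i] = start[j]
                parent[i] = j
    best = max(range(n), key=lambda i: (score[i], -start[i][0], -start[i][1], -items[i][0]))
    chain = []
    i = best
    while i != -1:
        chain.append(items[i])
        i = parent[i]
    chain.reverse()
    return chain, score[best]


def chain_collinear_blocks(
    anchors: Iterable[AnchorPair],
    loci: Mapping[str, GeneLocus],
    params: ChainingParams | None = None,
) -> list[CollinearBlock]:
    """Chain anchors into collinear blocks by sparse dynamic programming.

    Within each (chromosome pair, orientation) the maximal-score chain is
    extracted repeatedly (each anchor joins at most one block); chains
    below ``min_block_size`` are discarded at the end.
    """
    params = params or ChainingParams()
    groups: dict[tuple, list[tuple[int, int, str, str]]] = {}
    for anchor in anchors:
        la, lb = _orient_anchor(anchor, loci)
        key = (la.species, la.chromosome, lb.species, lb.chromosome)
        groups.setdefault(key, []).append((la.rank, lb.rank, la.gene_id, lb.gene_id))
    blocks: list[CollinearBlock] = []
    counter = itertools.count(1)
    for key in sorted(groups):
        sp_a, chrom_a, sp_b, chrom_b = key
        remaining = sorted(set(groups[key]))
        while remaining:
            candidates = []
            for orientation in ("same", "inverted"):
                result = _chain_group(remaining, orientation, params)
                if result is not None:
                    chain, chain_score = result
                    candidates.append((chain_score, orientation == "same", chain, orientation))
            if not candidates:
                break
            chain_score, _, chain, orientation = max(
                candidates, key=lambda c: (c[0], c[1], -c[2][0][0])
            )
            for item in chain:
                remaining.remove(item)
            if len(chain) >= params.min_block_size:
                blocks.append(
                    CollinearBlock(
                        block_id=f"B{next(counter):04d}",
                        anchors=tuple((g_a, g_b) for _, _, g_a, g_b in chain),
                        side_a=(sp_a, chrom_a),
                        side_b=(sp_b, chrom_b),
                        orientation=orientation,
                        score=chain_score,
                        size=len(chain),
                    )
                )
    return blocks


def best_chain_score(
    anchors: Iterable[AnchorPair],
    loci: Mapping[str, GeneLocus],
    params: ChainingParams | None = None,
) -> float:
    """Maximal chain score over all chromosome pairs and orientations.

    Convenience entry point for verifying the chaining DP; a single
    anchor scores ``match_score``.
    """
    params = params or ChainingParams()
    probe = replace(params, min_block_size=1)
    blocks = chain_collinear_blocks(anchors, loci, probe)
    if not blocks:
        return 0.0
    return max(b.score for b in blocks)


# ---------------------------------------------------------------------------
# Orthologs and paralogs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OrthologGroup:
    og_id: str
    members: frozenset[str]
    species_count: int


def derive_ortholog_pairs(
    blocks: Iterable[CollinearBlock],
    family_genes: frozenset[str] | set[str],
    loci: Mapping[str, GeneLocus],
) -> list[tuple[str, str]]:
    """Family anchors inside inter-genomic blocks, as ordered pairs."""
    pairs = set()
    for block in blocks:
        if block.side_a[0] == block.side_b[0]:
            continue  # intra-genomic block: not orthology evidence
        for g_a, g_b in block.anchors:
            if g_a in family_genes and g_b in family_genes:
                if loci[g_a].species == loci[g_b].species:
                    continue
                pairs.add(tuple(sorted((g_a, g_b))))
    return sorted(pairs)


def find_paralog_pairs(
    blocks: Iterable[CollinearBlock],
    family_genes: frozenset[str] | set[str],
    loci: Mapping[str, GeneLocus],
) -> list[tuple[str, str]]:
    """Family anchors inside intra-genomic blocks (self-pairs excluded)."""
    pairs = set()
    for block in blocks:
        if block.side_a[0] != block.side_b[0]:
            continue
        for g_a, g_b in block.anchors:
            if g_a == g_b:
                continue
            if g_a in family_genes and g_b in family_genes:
                pairs.add(tuple(sorted((g_a, g_b))))
    return sorted(pairs)


def merge_ortholog_groups(
    pairs: Iterable[tuple[str, str]],
    all_family_genes: Iterable[str],
    loci: Mapping[str, GeneLocus],
    intra_pairs: Iterable[tuple[str, str]] = (),
) -> list[OrthologGroup]:
    """Connected components of the ortholog-pair graph as OGs.

    Family genes in no cross-species pair form species-specific OGs,
    merged with same-species unplaced homologs exactly when linked by the
    supplied intra-species pairs.  IDs are zero-padded and ordered by
    descending species count, then by the genomic coordinates of the
    first member.
    """
    parent: dict[str, str] = {g: g for g in all_family_genes}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    cross_linked: set[str] = set()
    for a, b in pairs:
        if a not in parent or b not in parent:
            raise InputError(f"pair ({a}, {b}) references non-family gene")
        union(a, b)
        cross_linked.update((a, b))
    for a, b in intra_pairs:
        if a in parent and b in parent:
            union(a, b)
    components: dict[str, set[str]] = {}
    for g in parent:
        components.setdefault(find(g), set()).add(g)

    def coord_key(genes: set[str]) -> tuple:
        return min(
            (loci[g].species, natural_chromosome_key(loci[g].chromosome), loci[g].start)
            for g in genes
        )

    ordered = sorted(
        components.values(),
        key=lambda genes: (
            -len({loci[g].species for g in genes}),
            coord_key(genes),
        ),
    )
    groups = []
    for idx, genes in enumerate(ordered, start=1):
        groups.append(
            OrthologGroup(
                og_id=f"OG{idx:03d}",
                members=frozenset(genes),
                species_count=len({loci[g].species for g in genes}),
            )
        )
    return groups


# ---------------------------------------------------------------------------
# Tandem clusters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TandemCluster:
    cluster_id: str  # T1, T2, ... per species in coordinate order
    species: str
    members: tuple[str, ...]  # ordered by rank
    chromosome: str


def detect_tandem_clusters(
    loci: Mapping[str, GeneLocus],
    homology: Iterable[AnchorPair | tuple[str, str]],
    max_gap: int = 1,
) -> list[TandemCluster]:
    """Tandem-duplicate clusters from intra-species homology.

    Two genes belong together when homologous, on the same chromosome,
    and within ``max_gap`` intervening genes (rank distance <=
    max_gap + 1); clusters are the connected components of that relation,
    named T1, T2, ... per species in genomic-coordinate order.
    """
    edges = []
    for item in homology:
        a, b = (item.gene_a, item.gene_b) if isinstance(item, AnchorPair) else item
        la, lb = loci.get(a), loci.get(b)
        if la is None or lb is None:
            raise InputError(f"homology pair ({a}, {b}) references unknown locus")
        if la.species != lb.species:
            raise InputError(f"homology pair ({a}, {b}) spans species")
        if la.chromosome != lb.chromosome:
            continue
        if abs(la.rank - lb.rank) <= max_gap + 1:
            edges.append((a, b))
    parent = {}
    for a, b in edges:
        parent.setdefault(a, a)
        parent.setdefault(b, b)

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    components: dict[str, set[str]] = {}
    for g in parent:
        components.setdefault(find(g), set()).add(g)
    clusters_by_species: dict[str, list[tuple]] = {}
    for genes in components.values():
        if len(genes) < 2:
            continue
        members = tuple(sorted(genes, key=lambda g: loci[g].rank))
        first = loci[members[0]]
        clusters_by_species.setdefault(first.species, []).append(
            (natural_chromosome_key(first.chromosome), first.start, members, first.chromosome)
        )
    out: list[TandemCluster] = []
    for species in sorted(clusters_by_species):
        ordered = sorted(clusters_by_species[species])
        for idx, (_, _, members, chromosome) in enumerate(ordered, start=1):
            out.append(TandemCluster(f"T{idx}", species, members, chromosome))
    return out
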