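"""Collinear chaining, ortholog/paralog derivation, OG merging and
tandem-cluster detection, each against an independent brute-force oracle."""

import itertools

import numpy as np
import pytest

from bhlhkit.errors import InputError
from bhlhkit.comparative_genomics import (
    AnchorPair,
    ChainingParams,
    GeneLocus,
    best_chain_score,
    chain_collinear_blocks,
    derive_ortholog_pairs,
    detect_tandem_clusters,
    find_paralog_pairs,
    merge_ortholog_groups,
    natural_chromosome_key,
)

# ---------------------------------------------------------------------------
# Helpers and oracles
# ---------------------------------------------------------------------------


def make_instance(pairs, species=("A", "B")):
    """Anchors between chrA of species A and chrB of species B at the
    given (rank_a, rank_b) pairs."""
    loci = {}
    anchors = []
    for ra, rb in pairs:
        ga, gb = f"A{ra:03d}", f"B{rb:03d}"
        loci.setdefault(ga, GeneLocus(ga, species[0], "chrA", ra, ra * 100 + 1, ra * 100 + 50))
        loci.setdefault(gb, GeneLocus(gb, species[1], "chrB", rb, rb * 100 + 1, rb * 100 + 50))
        anchors.append(AnchorPair(ga, gb))
    return anchors, loci


def oracle_best_chain(pairs, params: ChainingParams):
    """Exhaustive maximum over all rank-monotone anchor subsets."""
    best = 0.0
    items = sorted(set(pairs))
    n = len(items)
    for mask in range(1, 1 << n):
        subset = sorted(
            (items[i] for i in range(n) if mask >> i & 1), key=lambda t: t[0]
        )
        for sign in (1, -1):
            ok = True
            score = params.match_score
            for (ra0, rb0), (ra1, rb1) in zip(subset, subset[1:]):
                gap_a = ra1 - ra0 - 1
                gap_b = sign * (rb1 - rb0) - 1
                if ra1 <= ra0 or sign * (rb1 - rb0) <= 0:
                    ok = False
                    break
                if gap_a > params.max_gap_ranks or gap_b > params.max_gap_ranks:
                    ok = False
                    break
                score += params.match_score - params.gap_penalty * (gap_a + gap_b)
            if ok:
                best = max(best, score)
    return best


def oracle_components(pairs, genes):
    """Transitive closure by repeated boolean-matrix squaring."""
    index = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    adj = np.eye(n, dtype=bool)
    for a, b in pairs:
        adj[index[a], index[b]] = adj[index[b], index[a]] = True
    while True:
        closure = adj @ adj
        if (closure == adj).all():
            break
        adj = closure
    comps = set()
    for i in range(n):
        comps.add(frozenset(genes[j] for j in range(n) if adj[i, j]))
    return comps


# ---------------------------------------------------------------------------
# Chaining
# ---------------------------------------------------------------------------


def test_perfect_five_anchor_chain_forms_one_block():
    anchors, loci = make_instance([(i, i) for i in range(5)])
    blocks = chain_collinear_blocks(anchors, loci)
    assert len(blocks) == 1
    assert blocks[0].size == 5
    assert blocks[0].score == pytest.approx(5.0)
    assert blocks[0].orientation == "same"


def test_four_anchors_fall_below_size_cutoff():
    anchors, loci = make_instance([(i, i) for i in range(4)])
    assert chain_collinear_blocks(anchors, loci) == []


def test_inverted_blocks_are_chained():
    anchors, loci = make_instance([(i, 10 - i) for i in range(6)])
    blocks = chain_collinear_blocks(anchors, loci)
    assert len(blocks) == 1
    assert blocks[0].orientation == "inverted"


def test_gap_limit_splits_chains():
    params = ChainingParams(min_block_size=2, max_gap_ranks=3)
    anchors, loci = make_instance([(0, 0), (1, 1), (10, 10), (11, 11)])
    blocks = chain_collinear_blocks(anchors, loci, params)
    assert sorted(b.size for b in blocks) == [2, 2]


def test_unknown_locus_is_an_error():
    anchors, _ = make_instance([(0, 0)])
    with pytest.raises(InputError, match="unknown locus"):
        chain_collinear_blocks(anchors, {})


def test_chain_scores_match_bruteforce_on_small_instances():
    rng = np.random.default_rng(7)
    params = ChainingParams(min_block_size=1, max_gap_ranks=4, gap_penalty=0.05)
    for _ in range(60):
        n = int(rng.integers(1, 11))
        pairs = {
            (int(rng.integers(0, 12)), int(rng.integers(0, 12))) for _ in range(n)
        }
        anchors, loci = make_instance(sorted(pairs))
        assert best_chain_score(anchors, loci, params) == pytest.approx(
            oracle_best_chain(pairs, params)
        )


def test_emitted_blocks_are_rank_monotone(default_bundle):
    loci = default_bundle.loci
    blocks = chain_collinear_blocks(default_bundle.anchor_pairs, loci)
    assert blocks
    for block in blocks:
        ranks_a = [loci[a].rank for a, _ in block.anchors]
        ranks_b = [loci[b].rank for _, b in block.anchors]
        assert ranks_a == sorted(ranks_a) and len(set(ranks_a)) == len(ranks_a)
        if block.orientation == "same":
            assert ranks_b == sorted(ranks_b) and len(set(ranks_b)) == len(ranks_b)
        else:
            assert ranks_b == sorted(ranks_b, reverse=True)
        assert block.size >= 5


# ---------------------------------------------------------------------------
# Ortholog pairs and groups
# ---------------------------------------------------------------------------


def test_ortholog_pairs_filter_to_family_members():
    anchors, loci = make_instance([(i, i) for i in range(5)])
    blocks = chain_collinear_blocks(anchors, loci)
    family = {"A002", "B002"}
    pairs = derive_ortholog_pairs(blocks, family, loci)
    assert pairs == [("A002", "B002")]
    assert derive_ortholog_pairs(blocks, set(), loci) == []


def test_family_anchor_outside_blocks_is_excluded():
    anchors, loci = make_instance([(i, i) for i in range(5)] + [(40, 2)])
    blocks = chain_collinear_blocks(anchors, loci)
    family = {"A040", "B002"}
    assert derive_ortholog_pairs(blocks, family, loci) == []


def test_component_merging_and_species_specific_groups():
    loci = {
        g: GeneLocus(g, g[0], "chr1", i, i * 10 + 1, i * 10 + 5)
        for i, g in enumerate(["Xa", "Yb", "Zc", "Xd", "Ye", "Xf"])
    }
    pairs = [("Xa", "Yb"), ("Yb", "Zc"), ("Xd", "Ye")]
    groups = merge_ortholog_groups(pairs, loci.keys(), loci)
    partitions = {g.members for g in groups}
    assert frozenset({"Xa", "Yb", "Zc"}) in partitions
    assert frozenset({"Xd", "Ye"}) in partitions
    assert frozenset({"Xf"}) in partitions  # unpaired gene: species-specific
    assert groups[0].og_id == "OG001" and groups[0].species_count == 3
    assert sum(len(g.members) for g in groups) == len(loci)


def test_components_match_closure_oracle():
    rng = np.random.default_rng(8)
    for _ in range(30):
        genes = [f"S{i%4}g{i:02d}" for i in range(int(rng.integers(3, 21)))]
        n_pairs = int(rng.integers(0, 15))
        pairs = [
            tuple(sorted(rng.choice(genes, 2, replace=False)))
            for _ in range(n_pairs)
        ]
        loci = {
            g: GeneLocus(g, g[:2], "chr1", i, i * 10 + 1, i * 10 + 5)
            for i, g in enumerate(genes)
        }
        groups = merge_ortholog_groups(pairs, genes, loci)
        assert {g.members for g in groups} == oracle_components(pairs, genes)


def test_paralog_pairs_within_species():
    # intra-genomic block: both sides in the same species
    loci = {}
    anchors = []
    for i in range(6):
        g1, g2 = f"Xg{i:02d}", f"Xh{i:02d}"
        loci[g1] = GeneLocus(g1, "X", "chr1", i, i * 100 + 1, i * 100 + 50)
        loci[g2] = GeneLocus(g2, "X", "chr2", i, i * 100 + 1, i * 100 + 50)
        anchors.append(AnchorPair(g1, g2, kind="intra"))
    blocks = chain_collinear_blocks(anchors, loci)
    family = set(loci)
    pairs = find_paralog_pairs(blocks, family, loci)
    assert len(pairs) == 6
    assert all(a[0] == b[0] == "X" for a, b in pairs)
    assert derive_ortholog_pairs(blocks, family, loci) == []


def test_self_anchor_rejected():
    with pytest.raises(InputError):
        AnchorPair("g1", "g1")


def test_wgd_sibling_pairs_recovered_from_simulated_bundle(default_bundle):
    """Every polyploidy sibling pair retained on a chained duplicated
    segment appears among the paralog pairs."""
    blocks = chain_collinear_blocks(default_bundle.anchor_pairs, default_bundle.loci)
    family = frozenset(default_bundle.loci)
    pairs = find_paralog_pairs(blocks, family, default_bundle.loci)
    truth = default_bundle.ground_truth
    # sibling pairs: same species, same family prefix, different OG lineage.
    # Tandem arrays share a lineage, so a monotone chain can carry only a
    # subset of the cross anchors: require at least one recovered pair per
    # sibling-lineage pair, and the exact pair when both lineages are
    # single-copy in that species.
    in_blocks = {g for b in blocks if b.side_a[0] == b.side_b[0] for g in b.genes}
    lineage = truth.og_membership
    by_group: dict[tuple, set[tuple[str, str]]] = {}
    copies: dict[tuple, int] = {}
    for g, lin in lineage.items():
        copies[(g[:3], lin)] = copies.get((g[:3], lin), 0) + 1
    for a, b in itertools.combinations(sorted(lineage), 2):
        same_species = a[:3] == b[:3]
        same_family = lineage[a][:4] == lineage[b][:4]
        if same_species and same_family and lineage[a] != lineage[b]:
            if a in in_blocks and b in in_blocks:
                key = (a[:3], *sorted((lineage[a], lineage[b])))
                by_group.setdefault(key, set()).add((a, b))
    assert by_group  # the planted duplicated segment is chained
    recovered = set(pairs)
    for (species, lin_a, lin_b), group in by_group.items():
        assert group & recovered, (species, lin_a, lin_b)
        if copies[(species, lin_a)] == 1 and copies[(species, lin_b)] == 1:
            assert group <= recovered


# ---------------------------------------------------------------------------
# Tandem clusters
# ---------------------------------------------------------------------------


def _tandem_loci(ranks, species="X", chrom="chr1"):
    return {
        f"g{r}": GeneLocus(f"g{r}", species, chrom, r, r * 10 + 1, r * 10 + 9)
        for r in ranks
    }


def test_adjacent_homologs_form_one_cluster():
    loci = _tandem_loci([5, 6, 7])
    pairs = [("g5", "g6"), ("g6", "g7"), ("g5", "g7")]
    clusters = detect_tandem_clusters(loci, pairs, max_gap=1)
    assert len(clusters) == 1
    assert clusters[0].members == ("g5", "g6", "g7")
    assert clusters[0].cluster_id == "T1"


def test_distance_cutoff_blocks_clustering():
    loci = _tandem_loci([5, 9])
    assert detect_tandem_clusters(loci, [("g5", "g9")], max_gap=1) == []


def test_cluster_naming_follows_coordinates():
    loci = {**_tandem_loci([50, 51]), **_tandem_loci([2, 3], chrom="chr2")}
    clusters = detect_tandem_clusters(
        loci, [("g50", "g51"), ("g2", "g3")], max_gap=1
    )
    assert [c.cluster_id for c in clusters] == ["T1", "T2"]
    assert clusters[0].chromosome == "chr1"  # chr1:501 precedes chr2:21


def test_tandem_clusters_match_pairwise_check_oracle():
    rng = np.random.default_rng(9)
    for _ in range(30):
        n = int(rng.integers(2, 31))
        ranks = sorted(rng.choice(200, n, replace=False))
        loci = _tandem_loci([int(r) for r in ranks])
        genes = sorted(loci)
        families = {g: int(rng.integers(0, 5)) for g in genes}
        homology = [
            (a, b)
            for a, b in itertools.combinations(genes, 2)
            if families[a] == families[b]
        ]
        max_gap = int(rng.integers(0, 3))
        clusters = detect_tandem_clusters(loci, homology, max_gap=max_gap)
        # oracle: exhaustive pairwise relation + DFS components
        edges = {
            (a, b)
            for a, b in homology
            if abs(loci[a].rank - loci[b].rank) <= max_gap + 1
        }
        comps, seen = [], set()
        for g in genes:
            if g in seen:
                continue
            stack, comp = [g], set()
            while stack:
                x = stack.pop()
                if x in comp:
                    continue
                comp.add(x)
                for a, b in edges:
                    if a == x and b not in comp:
                        stack.append(b)
                    elif b == x and a not in comp:
                        stack.append(a)
            seen |= comp
            if len(comp) > 1:
                comps.append(frozenset(comp))
        assert {frozenset(c.members) for c in clusters} == set(comps)


def test_natural_chromosome_ordering():
    names = ["chr10", "chr2", "scaffold_7", "chr1"]
    assert sorted(names, key=natural_chromosome_key) == [
        "chr1", "chr2", "chr10", "scaffold_7",
    ]
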