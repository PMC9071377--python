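"""Molecular-evolution layer: NG86 counting, alignment, distances, NJ,
bootstrap, clades and expansion calls."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bhlhkit.errors import InputError
from bhlhkit.molecular_evolution import (
    AA_OF,
    SENSE_CODONS,
    STOP_CODONS,
    CodonAlignment,
    DistanceMatrix,
    align_proteins_global,
    assign_clades,
    backtranslate_codon_alignment,
    bootstrap_support,
    build_nj_tree,
    compute_ng86,
    infer_lineage_expansion,
    pathway_difference_counts,
    protein_distance_matrix,
    synonymous_site_fraction,
)

# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def oracle_site_fraction(codon):
    """Enumerate all nine single-nucleotide changes directly."""
    syn = 0
    for pos, nt in itertools.product(range(3), "ACGT"):
        if nt == codon[pos]:
            continue
        alt = codon[:pos] + nt + codon[pos + 1 :]
        if AA_OF.get(alt) == AA_OF[codon]:
            syn += 1
    return syn / 3.0


def oracle_pathways(c1, c2):
    """Enumerate full mutational pathways as explicit codon walks."""
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return (0.0, 0.0)

    def paths(order):
        walk, cur = [], c1
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            walk.append((cur, nxt))
            cur = nxt
        return walk

    all_walks = [paths(order) for order in itertools.permutations(diffs)]
    valid = [
        w for w in all_walks
        if all(b not in STOP_CODONS for _, b in w[:-1])
    ]
    chosen = valid or all_walks
    sd = nd = 0.0
    for walk in chosen:
        for a, b in walk:
            if AA_OF.get(a) is not None and AA_OF.get(a) == AA_OF.get(b):
                sd += 1
            else:
                nd += 1
    return sd / len(chosen), nd / len(chosen)


def oracle_alignment_score(a, b, matrix, gap_open, gap_extend):
    """Exhaustive recursion over all global alignments with affine gaps."""
    best = [-math.inf]

    def go(i, j, score, state):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            go(i + 1, j + 1, score + matrix[a[i], b[j]], "m")
        if i < len(a):
            cost = gap_extend if state == "a" else gap_open
            go(i + 1, j, score + cost, "a")
        if j < len(b):
            cost = gap_extend if state == "b" else gap_open
            go(i, j + 1, score + cost, "b")

    go(0, 0, 0.0, "m")
    return best[0]


# ---------------------------------------------------------------------------
# NG86
# ---------------------------------------------------------------------------


def test_single_codon_site_fractions():
    # TTT: of the 9 single-nucleotide changes only TTT->TTC is synonymous
    assert synonymous_site_fraction("TTT") == pytest.approx(1 / 3)
    # Trp has a single codon: no synonymous changes at all
    assert synonymous_site_fraction("TGG") == 0.0
    for codon in ("ATG", "CTT", "CGA", "GGG"):
        assert synonymous_site_fraction(codon) == pytest.approx(
            oracle_site_fraction(codon)
        )


def test_pathway_counts_match_oracle_on_sample():
    rng = np.random.default_rng(0)
    codons = list(SENSE_CODONS)
    for _ in range(300):
        c1, c2 = rng.choice(codons, 2)
        sd, nd = pathway_difference_counts(c1, c2)
        osd, ond = oracle_pathways(c1, c2)
        assert sd == pytest.approx(osd, abs=1e-12)
        assert nd == pytest.approx(ond, abs=1e-12)
        n_diff = sum(x != y for x, y in zip(c1, c2))
        assert sd + nd == pytest.approx(n_diff, abs=1e-9)


def test_identical_sequences_have_zero_rates():
    aln = CodonAlignment(("ATG", "GGC", "TTT"), ("ATG", "GGC", "TTT"))
    rates = compute_ng86(aln)
    assert rates.Sd == rates.Nd == 0.0
    assert rates.Ka == rates.Ks == 0.0
    assert rates.ratio is None  # Ks == 0 leaves the ratio undefined


def test_ng86_symmetry_and_site_sum():
    rng = np.random.default_rng(1)
    codons = [c for c in SENSE_CODONS]
    for _ in range(20):
        row_a = tuple(rng.choice(codons, 30))
        row_b = tuple(rng.choice(codons, 30))
        fwd = compute_ng86(CodonAlignment(row_a, row_b))
        rev = compute_ng86(CodonAlignment(row_b, row_a))
        assert fwd.S == rev.S and fwd.N == rev.N
        assert fwd.Sd == rev.Sd and fwd.Nd == rev.Nd
        assert fwd.S + fwd.N == pytest.approx(3 * 30, abs=1e-9)


def test_gapped_columns_are_excluded():
    aln = CodonAlignment(("ATG", "---", "TTT"), ("ATG", "GGC", "TTC"))
    rates = compute_ng86(aln)
    assert rates.n_codons == 2
    assert rates.S + rates.N == pytest.approx(6.0)


def test_empty_overlap_is_an_error():
    with pytest.raises(InputError):
        compute_ng86(CodonAlignment(("ATG", "---"), ("---", "GGC")))


# ---------------------------------------------------------------------------
# Protein alignment and back-translation
# ---------------------------------------------------------------------------


def test_identical_proteins_align_gapless():
    aln = align_proteins_global("MKV", "MKV")
    assert aln.a_aligned == aln.b_aligned == "MKV"
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    assert aln.score == pytest.approx(sum(blosum[c, c] for c in "MKV"))


def test_alignment_score_matches_exhaustive_enumeration():
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    rng = np.random.default_rng(2)
    alphabet = list("ACDE")
    for _ in range(40):
        a = "".join(rng.choice(alphabet, rng.integers(1, 6)))
        b = "".join(rng.choice(alphabet, rng.integers(1, 6)))
        aln = align_proteins_global(a, b, gap_open=-5.0, gap_extend=-1.0)
        expected = oracle_alignment_score(a, b, blosum, -5.0, -1.0)
        assert aln.score == pytest.approx(expected)


def test_backtranslation_verbatim_and_gap_expansion():
    aln = align_proteins_global("MKV", "MKV")
    codon_aln = backtranslate_codon_alignment(aln, "ATGAAAGTT", "ATGAAGGTC")
    assert codon_aln.codons_a == ("ATG", "AAA", "GTT")
    assert codon_aln.codons_b == ("ATG", "AAG", "GTC")

    from bhlhkit.molecular_evolution import PairwiseAlignment

    gapped = PairwiseAlignment("MK-V", "MKLV", 0.0)
    codon_aln = backtranslate_codon_alignment(gapped, "ATGAAAGTT", "ATGAAGCTGGTC")
    assert codon_aln.codons_a[2] == "---"


def test_backtranslation_mismatch_names_position():
    from bhlhkit.molecular_evolution import PairwiseAlignment

    aln = PairwiseAlignment("MKVLF", "MKVLF", 0.0)
    bad_cds = "ATGAAAGTTCTGGGG"  # codon 4 codes G, not F
    with pytest.raises(InputError, match=r"codon 4"):
        backtranslate_codon_alignment(aln, bad_cds, "ATGAAAGTTCTGTTT", a_id="geneA")


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------


def test_p_distance_and_partial_deletion():
    aln = {
        "a": "AAAAAAAAAA",
        "b": "AACCAAAAAA",  # 2 mismatches over 10 columns
        "c": "AAAAAAAAAA",
    }
    d = protein_distance_matrix(aln, method="p", partial_deletion_coverage=0.8)
    i, j = d.labels.index("a"), d.labels.index("b")
    assert d.matrix[i, j] == pytest.approx(0.2)
    assert d.matrix[d.labels.index("a"), d.labels.index("c")] == 0.0

    # a column gapped in 3 of 10 rows has coverage 0.7 < 0.8 and is removed
    rows = {f"s{k}": "AB" for k in range(7)}
    rows.update({f"g{k}": "-B" for k in range(3)})
    d = protein_distance_matrix(rows, method="p", partial_deletion_coverage=0.8)
    assert np.all(d.matrix == 0.0)  # only the invariant column survives


def test_poisson_correction_and_incomparable_pairs():
    aln = {"a": "AAAA", "b": "CCCC", "c": "AAAA"}
    d = protein_distance_matrix(aln, method="poisson", partial_deletion_coverage=0.0)
    assert not np.isfinite(d.matrix[0, 1])  # p = 1 -> infinite, flagged
    assert ("a", "b") in d.flagged_pairs


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


def _random_additive_tree(n_leaves, rng):
    """Random unrooted binary tree; returns its leaf distance matrix."""
    labels = [f"t{i:02d}" for i in range(n_leaves)]
    nodes = list(range(n_leaves))
    adjacency = {i: {} for i in range(n_leaves)}
    nxt = n_leaves
    while len(nodes) > 2:
        i, j = rng.choice(len(nodes), 2, replace=False)
        a, b = nodes[int(i)], nodes[int(j)]
        u = nxt
        nxt += 1
        adjacency[u] = {}
        for x in (a, b):
            w = float(rng.uniform(0.1, 2.0))
            adjacency[u][x] = w
            adjacency[x][u] = w
        nodes = [x for x in nodes if x not in (a, b)] + [u]
    w = float(rng.uniform(0.1, 2.0))
    adjacency[nodes[0]][nodes[1]] = w
    adjacency[nodes[1]][nodes[0]] = w

    def dist(a, b):
        stack = [(a, -1, 0.0)]
        while stack:
            node, prev, acc = stack.pop()
            if node == b:
                return acc
            for nbr, length in adjacency[node].items():
                if nbr != prev:
                    stack.append((nbr, node, acc + length))
        raise AssertionError

    m = np.zeros((n_leaves, n_leaves))
    for i in range(n_leaves):
        for j in range(i + 1, n_leaves):
            m[i, j] = m[j, i] = dist(i, j)
    return DistanceMatrix(tuple(labels), m, "additive", 0.0)


def test_three_taxon_closed_form():
    m = np.array([[0.0, 2.0, 4.0], [2.0, 0.0, 4.0], [4.0, 4.0, 0.0]])
    tree = build_nj_tree(DistanceMatrix(("A", "B", "C"), m, "p", 0.0))
    # closed form: a = (dAB + dAC - dBC) / 2, etc.
    assert tree.leaf_distance("A", "B") == pytest.approx(2.0)
    node_a = tree._node_of("A")
    (hub, length_a), = tree.adjacency[node_a].items()
    assert length_a == pytest.approx(1.0)
    assert tree.adjacency[tree._node_of("C")][hub] == pytest.approx(3.0)


def test_four_taxon_additive_recovery():
    # tree ((A,B),(C,D)) with branches 1,2 | 3 | 4,5
    m = np.array([
        [0, 3, 8, 9],
        [3, 0, 9, 10],
        [8, 9, 0, 9],
        [9, 10, 9, 0],
    ], dtype=float)
    tree = build_nj_tree(DistanceMatrix(("A", "B", "C", "D"), m, "p", 0.0))
    for (i, a), (j, b) in itertools.combinations(enumerate("ABCD"), 2):
        assert tree.leaf_distance(a, b) == pytest.approx(m[i, j], abs=1e-9)
    assert frozenset({"C", "D"}) in tree.bipartitions() or \
        frozenset({"A", "B"}) in tree.bipartitions()


def test_random_additive_matrices_recovered():
    rng = np.random.default_rng(3)
    for _ in range(20):
        n = int(rng.integers(4, 13))
        d = _random_additive_tree(n, rng)
        tree = build_nj_tree(d)
        rebuilt = tree.leaf_distance_matrix()
        assert rebuilt.labels == d.labels
        assert np.max(np.abs(rebuilt.matrix - d.matrix)) < 1e-9


def test_star_matrix_yields_zero_internal_branches():
    n = 5
    m = np.ones((n, n)) - np.eye(n)
    tree = build_nj_tree(DistanceMatrix(tuple("ABCDE"), m, "p", 0.0))
    for u, v in tree.internal_edges():
        assert tree.adjacency[u][v] == pytest.approx(0.0, abs=1e-9)


def test_nj_agrees_with_skbio_on_random_matrix():
    skbio = pytest.importorskip("skbio")
    rng = np.random.default_rng(4)
    d = _random_additive_tree(8, rng)
    ours = build_nj_tree(d)
    sk_dm = skbio.DistanceMatrix(d.matrix, ids=list(d.labels))
    sk_tree = skbio.tree.nj(sk_dm)
    sk_bips = set()
    for node in sk_tree.non_tips():
        side = frozenset(t.name for t in node.tips())
        if min(d.labels) in side:
            side = frozenset(d.labels) - side
        if 1 < len(side) < len(d.labels) - 1:
            sk_bips.add(side)
    our_bips = {b for b in ours.bipartitions() if 1 < len(b) < len(d.labels) - 1}
    assert our_bips == sk_bips


def test_asymmetric_matrix_rejected():
    m = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], dtype=float)
    with pytest.raises(InputError):
        DistanceMatrix(("a", "b", "c"), m, "p", 0.0)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------


def test_bootstrap_invariant_alignment_gives_full_support():
    aln = {"a": "AAAA", "b": "AAAC", "c": "CCCA", "d": "CCCC"}
    aln = {k: v * 5 for k, v in aln.items()}
    support = bootstrap_support(aln, n_reps=50, seed=0, distance_method="p")
    assert support
    assert all(0.0 <= s <= 1.0 for s in support.values())
    again = bootstrap_support(aln, n_reps=50, seed=0, distance_method="p")
    assert support == again  # seed determinism
    assert bootstrap_support(aln, n_reps=0, seed=0) == {}


# ---------------------------------------------------------------------------
# Clades and expansions
# ---------------------------------------------------------------------------


def test_each_leaf_its_own_clade_at_k_equals_n():
    rng = np.random.default_rng(5)
    d = _random_additive_tree(6, rng)
    tree = build_nj_tree(d)
    clades = assign_clades(tree, 6)
    assert clades.k == 6
    assert len(set(clades.assignment.values())) == 6


def test_two_clades_cut_at_longest_internal_edge():
    # caterpillar with one very long internal edge between {A,B,C} and {D,E,F}
    m = np.zeros((6, 6))
    group = {"A": 0, "B": 0, "C": 0, "D": 1, "E": 1, "F": 1}
    labels = tuple("ABCDEF")
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i != j:
                m[i, j] = 1.0 if group[a] == group[b] else 10.0
    tree = build_nj_tree(DistanceMatrix(labels, m, "p", 0.0))
    clades = assign_clades(tree, 2)
    sides = {frozenset(clades.members(c)) for c in clades.clades}
    assert sides == {frozenset("ABC"), frozenset("DEF")}


def test_anchor_conflict_is_reported():
    rng = np.random.default_rng(6)
    tree = build_nj_tree(_random_additive_tree(5, rng))
    with pytest.raises(InputError, match="anchor conflict"):
        assign_clades(tree, 2, {"I": ["t00"], "II": ["t00"]})


def test_expansion_rule_application():
    from bhlhkit.molecular_evolution import CladeAssignment

    clades = CladeAssignment({"m1": "I", "m2": "I", "x1": "I"}, 1, ())
    ks = {
        frozenset(("m1", "m2")): 0.10,
        frozenset(("m1", "x1")): 0.40,
        frozenset(("m2", "x1")): 0.45,
    }
    calls = infer_lineage_expansion(
        {"melon": ["m1", "m2"], "other": ["x1"], "absent": []},
        ks, clades, species_universe=["melon", "other", "absent"],
    )
    by_species = {c.species: c for c in calls}
    assert by_species["melon"].verdict == "expansion"
    assert by_species["melon"].recent  # 0.10 < 0.32
    assert by_species["other"].verdict == "ancestral"
    assert by_species["absent"].verdict == "loss"
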