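"""Multi-species pangenome simulator with full ground truth.

The simulator emulates the comparative setting of a small transcription-
factor gene family evolving across a clade of diploid genomes that share
an ancient whole-genome tetraploidization (default 90 MYA) and may carry
lineage-specific WGDs: ancestral genes are laid out on two chromosomes,
duplicated segmentally at the shared polyploidy with a configurable
retention fraction, and then evolved down a dated species tree with
per-branch codon substitution (proposal process with omega-scaled
acceptance of nonsynonymous changes), gene losses and tandem
duplications whose children stay adjacent to their parents.

Each gene carries a planted bHLH-like domain drawn from the packaged
consensus with rule-controlled binding-category residues and an intron
layout realizing a chosen canonical pattern; the basic region of the
domain is held fixed during evolution (modelling its strong purifying
constraint), so planted binding categories and intron patterns are
exactly recoverable.  A designated regulator cluster mirrors the tandem
cucurbitacin-regulator architecture: a three-copy cluster born after the
shared tetraploidy, its two-copy paralogous cluster on the duplicated
segment, one root-predominant gene per species in the paralogous cluster
(the *Brp* analog), and an optional recent post-speciation expansion in
one designated lineage.

Output is a :class:`PangenomeBundle` (per-species proteins, CDS, gene
models, loci, homology anchors, FPKM matrix) plus a :class:`GroundTruth`
with ortholog groups, tandem clusters, per-gene labels and the event
log, and can be written to standard flat formats with
:func:`emit_files`.
"""

from __future__ import annotations

import copy
import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .comparative_genomics import AnchorPair, GeneLocus
from .domain_analysis import (
    BindingCategory,
    GeneModel,
    IntronPatternCode,
    DEFAULT_PATTERN_TABLE,
    default_profile,
)
from .molecular_evolution import AA_OF, STOP_CODONS, SENSE_CODONS, translate_codons
from . import synthetic_seed_profile as seed_profile

logger = logging.getLogger(__name__)

TISSUES_DEFAULT = ("root", "stem", "leaf", "fruit")

# ---------------------------------------------------------------------------
# Codon sequences and evolution
# ---------------------------------------------------------------------------

_CODONS_BY_AA: dict[str, tuple[str, ...]] = {}
for _codon, _aa in AA_OF.items():
    _CODONS_BY_AA.setdefault(_aa, tuple())
_CODONS_BY_AA = {
    aa: tuple(sorted(c for c, a in AA_OF.items() if a == aa)) for aa in set(AA_OF.values())
}

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_NUCS = "ACGT"


@dataclass(frozen=True)
class CodonSequence:
    """An ordered list of sense codons for one gene."""

    codons: tuple[str, ...]
    gene_id: str = ""

    def __post_init__(self) -> None:
        if not self.codons:
            raise InputError("codon sequence is empty")
        for c in self.codons:
            if c in STOP_CODONS:
                raise InputError(f"{self.gene_id or 'sequence'}: internal stop codon {c}")
            if c not in AA_OF:
                raise InputError(f"{self.gene_id or 'sequence'}: invalid codon {c!r}")

    def __len__(self) -> int:
        return len(self.codons)

    @property
    def nucleotides(self) -> str:
        return "".join(self.codons)

    @property
    def protein(self) -> str:
        return translate_codons(self.codons)


def random_codon_sequence(n_codons: int, seed: int | np.random.Generator, gene_id: str = "") -> CodonSequence:
    """Uniform random sense codons (no stops)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    codons = tuple(SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n_codons))
    return CodonSequence(codons, gene_id)


def evolve_codon_sequence(
    ancestor: CodonSequence,
    branch_length: float,
    omega: float,
    seed: int | None = None,
    *,
    kappa: float = 1.0,
    frozen_codons: frozenset[int] | set[int] = frozenset(),
    rng: np.random.Generator | None = None,
) -> CodonSequence:
    """Evolve a codon sequence along a branch.

    Point mutations are proposed at rate ``branch_length`` per
    nucleotide site with an HKY-like transition bias ``kappa`` (the
    default 1.0 makes proposals uniform), then accepted with probability
    1 for synonymous and ``omega`` for nonsynonymous changes (for
    ``omega > 1`` the roles invert), so the realized dN/dS equals
    ``omega``.  Proposals creating stop codons are rejected and redrawn
    among the remaining target nucleotides; codons listed in
    ``frozen_codons`` never change (used to model absolutely constrained
    motifs).  Seed-deterministic.
    """
    if branch_length < 0:
        raise InputError("branch_length must be >= 0")
    if omega < 0:
        raise InputError("omega must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    codons = list(ancestor.codons)
    n_sites = 3 * len(codons)
    n_proposals = int(rng.poisson(branch_length * n_sites))
    p_syn = 1.0 if omega <= 1.0 else 1.0 / omega
    p_nonsyn = min(1.0, omega)
    for _ in range(n_proposals):
        site = int(rng.integers(0, n_sites))
        ci, offset = divmod(site, 3)
        if ci in frozen_codons:
            continue
        codon = codons[ci]
        old = codon[offset]
        alts = []
        weights = []
        for nt in _NUCS:
            if nt == old:
                continue
            candidate = codon[:offset] + nt + codon[offset + 1 :]
            if candidate in STOP_CODONS:
                continue  # rejected and redrawn among the rest
            alts.append(candidate)
            weights.append(kappa if _TRANSITION[old] == nt else 1.0)
        if not alts:
            continue
        probs = np.asarray(weights) / sum(weights)
        new_codon = alts[int(rng.choice(len(alts), p=probs))]
        synonymous = AA_OF[new_codon] == AA_OF[codon]
        accept_p = p_syn if synonymous else p_nonsyn
        if accept_p >= 1.0 or rng.random() < accept_p:
            codons[ci] = new_codon
    return CodonSequence(tuple(codons), ancestor.gene_id)


# ---------------------------------------------------------------------------
# Species tree
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    name: str
    time: float  # MYA; 0 at the tips
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return [leaf for child in self.children for leaf in child.leaves()]

    def branches(self) -> list[tuple["TreeNode", "TreeNode"]]:
        out = []
        for child in self.children:
            out.append((self, child))
            out.extend(child.branches())
        return out


@dataclass(frozen=True)
class WgdEvent:
    branch: str  # name of the child node of the branch carrying the event
    time: float  # MYA
    retention_fraction: float


@dataclass
class SpeciesTreeSpec:
    root: TreeNode
    wgd_events: list[WgdEvent] = field(default_factory=list)
    shared_polyploidy_time: float = 90.0

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(leaf.name for leaf in self.root.leaves())

    def validate(self) -> None:
        names = set()
        for node in self._walk(self.root):
            if node.name in names:
                raise ConfigurationError(f"tree: duplicate node name {node.name!r}")
            names.add(node.name)
        for parent, child in self.root.branches():
            if not child.time < parent.time:
                raise ConfigurationError(
                    f"tree: time does not decrease from {parent.name} "
                    f"({parent.time}) to {child.name} ({child.time})"
                )
        if self.shared_polyploidy_time <= self.root.time:
            raise ConfigurationError(
                "shared_polyploidy_time must predate the root divergence"
            )
        branch_names = {child.name for _, child in self.root.branches()}
        for event in self.wgd_events:
            if event.branch not in branch_names:
                raise ConfigurationError(f"wgd_events: unknown branch {event.branch!r}")
            if not 0.0 < event.retention_fraction <= 1.0:
                raise ConfigurationError(
                    f"wgd_events: retention_fraction {event.retention_fraction} "
                    "outside (0, 1]"
                )

    @staticmethod
    def _walk(node: TreeNode):
        yield node
        for child in node.children:
            yield from SpeciesTreeSpec._walk(child)


def default_species_tree(n_species: int = 3) -> SpeciesTreeSpec:
    """Dated default topologies for 3 or 7 taxa.

    The 7-taxon tree mirrors a cucurbit-like clade (two close sister
    species, successively deeper outgroups, a recent WGD on one deep
    lineage); divergence times are configurable defaults, not estimates.
    """
    if n_species == 3:
        root = TreeNode("N1", 18.0, [
            TreeNode("N2", 10.0, [TreeNode("Csa", 0.0), TreeNode("Cme", 0.0)]),
            TreeNode("Cla", 0.0),
        ])
        return SpeciesTreeSpec(root)
    if n_species == 7:
        n2 = TreeNode("N6", 10.0, [TreeNode("Csa", 0.0), TreeNode("Cme", 0.0)])
        n3 = TreeNode("N5", 18.0, [n2, TreeNode("Cla", 0.0)])
        n4 = TreeNode("N4", 22.0, [n3, TreeNode("Lsi", 0.0)])
        n5 = TreeNode("N3", 26.0, [n4, TreeNode("Bhi", 0.0)])
        n6 = TreeNode("N2", 30.0, [n5, TreeNode("Cma", 0.0)])
        root = TreeNode("N1", 40.0, [n6, TreeNode("Mch", 0.0)])
        return SpeciesTreeSpec(root, wgd_events=[WgdEvent("Cma", 3.0, 0.5)])
    raise ConfigurationError(f"no default tree for n_species={n_species}")


# ---------------------------------------------------------------------------
# Simulation configuration
# ---------------------------------------------------------------------------

DEFAULT_BINDING_MIX: dict[BindingCategory, float] = {
    BindingCategory.GBOX: 0.50,
    BindingCategory.NON_BINDING: 0.28,
    BindingCategory.EBOX_NON_GBOX: 0.13,
    BindingCategory.NON_EBOX: 0.09,
}

DEFAULT_INTRON_MIX: dict[IntronPatternCode, float] = {
    IntronPatternCode.IX: 0.40,
    IntronPatternCode.I: 0.25,
    IntronPatternCode.XI: 0.15,
    IntronPatternCode.II: 0.04,
    IntronPatternCode.III: 0.03,
    IntronPatternCode.IV: 0.03,
    IntronPatternCode.V: 0.02,
    IntronPatternCode.VI: 0.02,
    IntronPatternCode.VII: 0.02,
    IntronPatternCode.VIII: 0.02,
    IntronPatternCode.X: 0.01,
    IntronPatternCode.O: 0.01,
}

# Residue substitutions (profile column -> residue) that realize each
# binding category on the packaged consensus domain.
_CATEGORY_EDITS: dict[BindingCategory, tuple[tuple[int, str], ...]] = {
    BindingCategory.GBOX: (),
    BindingCategory.EBOX_NON_GBOX: ((3, "A"),),
    BindingCategory.NON_EBOX: ((10, "N"),),
    BindingCategory.NON_BINDING: ((1, "S"), (4, "T"), (5, "A"), (7, "S"), (8, "T")),
}

# Occupied canonical positions (and presence of a non-canonical intron)
# realizing each intron pattern; inverse of the pattern lookup table,
# with O realized by an untabulated signature.
PATTERN_REALIZATIONS: dict[IntronPatternCode, tuple[tuple[int, ...], bool]] = {
    **{
        code: (tuple(sorted(sig)), noncanon)
        for (sig, noncanon), code in DEFAULT_PATTERN_TABLE.items()
    },
    IntronPatternCode.O: ((1, 3), True),
}

_NONCANONICAL_OFFSET = 61  # nt inside the domain, far from all canonical sites


@dataclass
class TissueProfileSpec:
    tissues: tuple[str, ...] = TISSUES_DEFAULT
    bias_fold: float = 6.0
    noise_sigma_log2: float = 0.3
    base_log2_mean: float = 3.0
    base_log2_sd: float = 1.0


@dataclass
class SimulationConfig:
    tree: SpeciesTreeSpec = field(default_factory=default_species_tree)
    n_ancestral_genes: int = 24
    tandem_rate: float = 0.03  # expected tandem duplications per gene per branch
    loss_rate: float = 0.03  # per-gene per-branch loss probability
    codon_length: int = 110
    omega_by_branch: float | Mapping[str, float] = 0.2
    mutation_rate: float = 0.006  # proposed substitutions / site / MY
    binding_category_mix: Mapping[BindingCategory, float] = field(
        default_factory=lambda: dict(DEFAULT_BINDING_MIX)
    )
    intron_pattern_mix: Mapping[IntronPatternCode, float] = field(
        default_factory=lambda: dict(DEFAULT_INTRON_MIX)
    )
    tissue_profiles: TissueProfileSpec = field(default_factory=TissueProfileSpec)
    seed: int = 0
    shared_retention: float = 0.4  # retention fraction of the shared polyploidy
    plant_regulator_cluster: bool = True
    regulator_cluster_copies: int = 3  # copies in the main (Bt-like) cluster
    regulator_cluster_time: float = 50.0  # MYA of the cluster expansion
    paralog_cluster_time: float = 70.0  # MYA of the paralogous-cluster duplication
    plant_recent_expansion: bool = True
    recent_expansion_taxon: str | None = None  # default: second taxon
    recent_expansion_copies: int = 2
    recent_expansion_time: float = 2.0

    def validate(self) -> None:
        self.tree.validate()
        for name in ("tandem_rate", "loss_rate", "mutation_rate"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.n_ancestral_genes < 0:
            raise ConfigurationError("n_ancestral_genes must be >= 0")
        if self.codon_length < 75:
            raise ConfigurationError("codon_length must be >= 75 (domain + flanks)")
        if not 0.0 <= self.shared_retention <= 1.0:
            raise ConfigurationError("shared_retention must lie in [0, 1]")
        for label, mix in (
            ("binding_category_mix", self.binding_category_mix),
            ("intron_pattern_mix", self.intron_pattern_mix),
        ):
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(f"{label} sums to {total}, not 1")
            if any(v < 0 for v in mix.values()):
                raise ConfigurationError(f"{label} contains a negative proportion")
        if self.plant_regulator_cluster and self.n_ancestral_genes < 8:
            raise ConfigurationError(
                "n_ancestral_genes must be >= 8 to plant the regulator cluster"
            )

    def omega_for(self, branch: str) -> float:
        if isinstance(self.omega_by_branch, Mapping):
            return float(self.omega_by_branch.get(branch, 0.2))
        return float(self.omega_by_branch)


def default_config(seed: int = 42, n_species: int = 3, **overrides) -> SimulationConfig:
    config = SimulationConfig(tree=default_species_tree(n_species), seed=seed)
    for key, value in overrides.items():
        if not hasattr(config, key):
            raise ConfigurationError(f"unknown configuration field {key!r}")
        setattr(config, key, value)
    return config


# ---------------------------------------------------------------------------
# Ground truth containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DuplicationEvent:
    kind: str  # "wgd" | "tandem"
    time: float
    branch: str  # child-node name, or "ancestral" for pre-root events
    parent: str  # lineage label of the parent copy
    child: str  # lineage label (wgd) or parent lineage (tandem children share it)


@dataclass(frozen=True)
class LossEvent:
    branch: str
    lineage: str


@dataclass
class GroundTruth:
    og_membership: dict[str, str]  # gene id -> OG label
    tdg_clusters: list[tuple[str, ...]]  # ordered member tuples
    binding_category: dict[str, BindingCategory]
    intron_pattern: dict[str, IntronPatternCode]
    branch_omega: dict[str, float]
    duplication_events: list[DuplicationEvent]
    loss_events: list[LossEvent]
    brp_genes: tuple[str, ...]  # the planted root-predominant paralog-cluster genes
    bt_og: str | None  # OG label of the main regulator cluster
    brp_og: str | None  # OG label of its paralogous cluster
    n_root_genes: int  # genes in the post-polyploidy root genome

    def og_partition(self) -> set[frozenset[str]]:
        groups: dict[str, set[str]] = {}
        for gene, og in self.og_membership.items():
            groups.setdefault(og, set()).add(gene)
        return {frozenset(v) for v in groups.values()}


@dataclass
class PangenomeBundle:
    species: tuple[str, ...]
    proteins: dict[str, dict[str, str]]
    cds: dict[str, dict[str, str]]
    gene_models: dict[str, dict[str, GeneModel]]
    loci: dict[str, GeneLocus]
    anchor_pairs: list[AnchorPair]
    fpkm: pd.DataFrame
    ground_truth: GroundTruth
    config: SimulationConfig

    def all_genes(self, species: str) -> list[str]:
        return sorted(self.proteins[species])


# ---------------------------------------------------------------------------
# Internal simulated-gene representation
# ---------------------------------------------------------------------------


@dataclass
class _SimGene:
    family: int  # pre-polyploidy ancestral gene
    lineage: str  # post-polyploidy locus label = ground-truth OG
    codons: list[str]
    domain_start: int  # codon offset of the domain
    intron_offsets: tuple[int, ...]  # CDS-nucleotide intron positions
    category: BindingCategory
    pattern: IntronPatternCode
    tissue: str
    protected: bool = False
    tag: str = ""  # "", "bt", "brp", "brp_sib"

    def clone(self) -> "_SimGene":
        twin = copy.copy(self)
        twin.codons = list(self.codons)
        return twin

    @property
    def frozen_codons(self) -> frozenset[int]:
        # The basic region of the domain is under absolute constraint.
        b0, b1 = seed_profile.REGION_SPEC["basic"]
        return frozenset(range(self.domain_start + b0, self.domain_start + b1))


def _codons_for_protein(protein: str, rng: np.random.Generator) -> list[str]:
    return [
        _CODONS_BY_AA[aa][int(rng.integers(0, len(_CODONS_BY_AA[aa])))]
        for aa in protein
    ]


def _build_ancestral_gene(
    family: int,
    config: SimulationConfig,
    rng: np.random.Generator,
    category: BindingCategory,
    pattern: IntronPatternCode,
) -> _SimGene:
    consensus = list(default_profile().consensus)
    for col, residue in _CATEGORY_EDITS[category]:
        consensus[col] = residue
    domain = "".join(consensus)
    n_flank_total = config.codon_length - len(domain)
    n_left = int(rng.integers(8, n_flank_total - 8))
    left = random_codon_sequence(n_left, rng).codons
    right = random_codon_sequence(n_flank_total - n_left, rng).codons
    domain_codons = _codons_for_protein(domain, rng)
    codons = list(left) + domain_codons + list(right)
    positions, noncanonical = PATTERN_REALIZATIONS[pattern]
    domain_nt = 3 * n_left
    offsets = [domain_nt + seed_profile.CANONICAL_INTRON_OFFSETS[p - 1] for p in positions]
    if noncanonical:
        offsets.append(domain_nt + _NONCANONICAL_OFFSET)
    if rng.random() < 0.5 and n_left >= 4:  # occasional intron outside the domain
        offsets.append(3 * (n_left // 2))
    return _SimGene(
        family=family,
        lineage=f"L{family:03d}a",
        codons=codons,
        domain_start=n_left,
        intron_offsets=tuple(sorted(set(offsets))),
        category=category,
        pattern=pattern,
        tissue="",
    )


# ---------------------------------------------------------------------------
# Main simulation
# ---------------------------------------------------------------------------


def simulate_pangenome(config: SimulationConfig) -> PangenomeBundle:
    """Simulate a pangenome bundle with full ground truth (seed-deterministic)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    tree = config.tree
    root_time = tree.root.time
    t_poly = tree.shared_polyploidy_time

    categories = sorted(config.binding_category_mix, key=lambda c: c.name)
    cat_p = np.array([config.binding_category_mix[c] for c in categories])
    patterns = sorted(config.intron_pattern_mix, key=lambda c: c.name)
    pat_p = np.array([config.intron_pattern_mix[c] for c in patterns])

    events: list[DuplicationEvent] = []
    losses: list[LossEvent] = []

    # --- ancestral genes on two chromosomes -------------------------------
    genes: list[_SimGene] = []
    for fam in range(config.n_ancestral_genes):
        category = categories[int(rng.choice(len(categories), p=cat_p))]
        pattern = patterns[int(rng.choice(len(patterns), p=pat_p))]
        genes.append(_build_ancestral_gene(fam, config, rng, category, pattern))
    chrom_of = rng.integers(0, 2, size=len(genes))
    chromosomes: dict[str, list[_SimGene]] = {"chr1": [], "chr2": []}
    order = rng.permutation(len(genes))
    for idx in order:
        chromosomes["chr1" if chrom_of[idx] == 0 else "chr2"].append(genes[idx])

    regulator_family = None
    if config.plant_regulator_cluster:
        # The regulator sits mid-chromosome so its duplicated segment has
        # enough flanking anchors to form a collinear block.
        host = "chr1" if len(chromosomes["chr1"]) >= len(chromosomes["chr2"]) else "chr2"
        pos = len(chromosomes[host]) // 2
        regulator_gene = chromosomes[host][pos]
        regulator_family = regulator_gene.family
        regulator_gene.protected = True
        regulator_gene.tag = "bt"
        regulator_gene.category = BindingCategory.GBOX
        # rebuild with GBOX residues and a uniform pattern for the cluster
        rebuilt = _build_ancestral_gene(
            regulator_family, config, rng, BindingCategory.GBOX, IntronPatternCode.I
        )
        regulator_gene.codons = rebuilt.codons
        regulator_gene.domain_start = rebuilt.domain_start
        regulator_gene.intron_offsets = rebuilt.intron_offsets
        regulator_gene.pattern = rebuilt.pattern
        forced_neighbors = [
            chromosomes[host][i]
            for i in range(max(0, pos - 2), min(len(chromosomes[host]), pos + 3))
        ]
    else:
        forced_neighbors = []
    forced_families = {g.family for g in forced_neighbors}

    # --- shared polyploidy ------------------------------------------------
    retained: dict[str, list[_SimGene]] = {"chr1": [], "chr2": []}
    for chrom in ("chr1", "chr2"):
        for gene in chromosomes[chrom]:
            keep = gene.family in forced_families or rng.random() < config.shared_retention
            if keep:
                twin = gene.clone()
                twin.lineage = f"L{gene.family:03d}b"
                twin.protected = gene.family == regulator_family
                if twin.tag == "bt":
                    twin.tag = "brp_parent"
                retained[chrom].append(twin)
                events.append(DuplicationEvent(
                    "wgd", t_poly, "ancestral", gene.lineage, twin.lineage
                ))
    # the duplicate of each chromosome is appended to the other one
    chromosomes["chr1"] = chromosomes["chr1"] + retained["chr2"]
    chromosomes["chr2"] = chromosomes["chr2"] + retained["chr1"]

    # --- evolve from the polyploidy to the root, planting clusters --------
    def expand_cluster(
        gene: _SimGene, n_copies: int, t_event: float, t_stop: float, tag: str
    ) -> list[_SimGene]:
        """Evolve to t_event, split into n_copies, evolve each to t_stop."""
        _evolve(gene, t_poly, t_event, "ancestral")
        copies = []
        for k in range(n_copies):
            twin = gene.clone() if k else gene
            if k:
                twin.tag = tag
                events.append(DuplicationEvent(
                    "tandem", t_event, "ancestral", gene.lineage, gene.lineage
                ))
            copies.append(twin)
        for twin in copies:
            _evolve(twin, t_event, t_stop, "ancestral")
        return copies

    def _evolve(gene: _SimGene, t_from: float, t_to: float, branch: str) -> None:
        span = t_from - t_to
        if span <= 0:
            return
        evolved = evolve_codon_sequence(
            CodonSequence(tuple(gene.codons)),
            branch_length=span * config.mutation_rate,
            omega=config.omega_for(branch),
            frozen_codons=gene.frozen_codons,
            rng=rng,
        )
        gene.codons = list(evolved.codons)

    root_genome: dict[str, list[_SimGene]] = {"chr1": [], "chr2": []}
    for chrom in ("chr1", "chr2"):
        for gene in chromosomes[chrom]:
            if config.plant_regulator_cluster and gene.tag == "bt":
                copies = expand_cluster(
                    gene, config.regulator_cluster_copies,
                    min(config.regulator_cluster_time, t_poly - 1e-9),
                    root_time, "bt",
                )
                for c in copies:
                    c.tag = "bt"
                    c.protected = True
                root_genome[chrom].extend(copies)
            elif config.plant_regulator_cluster and gene.tag == "brp_parent":
                copies = expand_cluster(
                    gene, 2,
                    min(config.paralog_cluster_time, t_poly - 1e-9),
                    root_time, "brp_sib",
                )
                copies[0].tag = "brp"
                copies[1].tag = "brp_sib"
                for c in copies:
                    c.protected = True
                root_genome[chrom].extend(copies)
            else:
                _evolve(gene, t_poly, root_time, "ancestral")
                root_genome[chrom].append(gene)

    n_root_genes = sum(len(v) for v in root_genome.values())

    # --- tissue assignment (inherited through descent) --------------------
    tissues = config.tissue_profiles.tissues
    for chrom in ("chr1", "chr2"):
        for gene in root_genome[chrom]:
            if gene.tag == "brp":
                gene.tissue = "root"
            elif gene.tag in ("brp_sib", "bt"):
                gene.tissue = "fruit" if "fruit" in tissues else tissues[-1]
            else:
                gene.tissue = str(tissues[int(rng.integers(0, len(tissues)))])

    # --- descend the species tree -----------------------------------------
    taxa = tree.taxa
    recent_taxon = config.recent_expansion_taxon or (taxa[1] if len(taxa) > 1 else taxa[0])
    wgd_by_branch: dict[str, list[WgdEvent]] = {}
    for event in tree.wgd_events:
        wgd_by_branch.setdefault(event.branch, []).append(event)
    leaf_genomes: dict[str, dict[str, list[_SimGene]]] = {}

    def descend(node: TreeNode, genome: dict[str, list[_SimGene]]) -> None:
        if node.is_leaf:
            leaf_genomes[node.name] = genome
            return
        for child in node.children:
            branch = child.name
            child_genome: dict[str, list[_SimGene]] = {}
            for chrom, gene_list in genome.items():
                child_genome[chrom] = [g.clone() for g in gene_list]
            # losses
            for chrom in list(child_genome):
                survivors = []
                for gene in child_genome[chrom]:
                    if not gene.protected and rng.random() < config.loss_rate:
                        losses.append(LossEvent(branch, gene.lineage))
                    else:
                        survivors.append(gene)
                child_genome[chrom] = survivors
            # lineage-specific WGD: retained copies appended to the other chromosome
            for event in wgd_by_branch.get(branch, ()):
                chrom_names = sorted(child_genome)
                appended: dict[str, list[_SimGene]] = {c: [] for c in chrom_names}
                for chrom in chrom_names:
                    other = chrom_names[(chrom_names.index(chrom) + 1) % len(chrom_names)]
                    for gene in child_genome[chrom]:
                        if rng.random() < event.retention_fraction:
                            twin = gene.clone()
                            twin.lineage = f"{gene.lineage}.{branch}w"
                            twin.protected = False
                            twin.tag = ""
                            appended[other].append(twin)
                            events.append(DuplicationEvent(
                                "wgd", event.time, branch, gene.lineage, twin.lineage
                            ))
                for chrom in chrom_names:
                    child_genome[chrom].extend(appended[chrom])
            # tandem duplications (children adjacent to parents) + branch evolution
            for chrom in list(child_genome):
                new_list: list[_SimGene] = []
                for gene in child_genome[chrom]:
                    event_times = sorted(
                        (
                            float(rng.uniform(child.time, node.time))
                            for _ in range(int(rng.poisson(config.tandem_rate)))
                        ),
                        reverse=True,
                    )
                    if (
                        config.plant_regulator_cluster
                        and config.plant_recent_expansion
                        and branch == recent_taxon
                        and gene.tag == "bt"
                        and gene is next(
                            (g for g in child_genome[chrom] if g.tag == "bt"), None
                        )
                    ):
                        extra = [config.recent_expansion_time] * (
                            config.recent_expansion_copies
                        )
                        event_times = sorted(event_times + extra, reverse=True)
                    cohort = [gene]
                    t_cursor = node.time
                    for t_event in event_times:
                        t_event = min(t_event, t_cursor)
                        for g in cohort:
                            _evolve(g, t_cursor, t_event, branch)
                        twin = gene.clone()
                        cohort.append(twin)
                        events.append(DuplicationEvent(
                            "tandem", t_event, branch, gene.lineage, gene.lineage
                        ))
                        t_cursor = t_event
                    for g in cohort:
                        _evolve(g, t_cursor, child.time, branch)
                    new_list.extend(cohort)
                child_genome[chrom] = new_list
            descend(child, child_genome)

    descend(tree.root, root_genome)

    # --- finalize per-species records -------------------------------------
    proteins: dict[str, dict[str, str]] = {}
    cds: dict[str, dict[str, str]] = {}
    gene_models: dict[str, dict[str, GeneModel]] = {}
    loci: dict[str, GeneLocus] = {}
    binding_truth: dict[str, BindingCategory] = {}
    pattern_truth: dict[str, IntronPatternCode] = {}
    og_truth: dict[str, str] = {}
    tdg_clusters: list[tuple[str, ...]] = []
    brp_genes: list[str] = []
    fpkm_rows: dict[str, dict[str, float]] = {}
    bt_og = brp_og = None
    spacing = 5000
    intron_length = 200

    for species in taxa:
        genome = leaf_genomes[species]
        proteins[species] = {}
        cds[species] = {}
        gene_models[species] = {}
        counter = itertools.count(1)
        for chrom in sorted(genome):
            run: list[tuple[str, _SimGene]] = []
            for rank, gene in enumerate(genome[chrom]):
                gene_id = f"{species}g{next(counter):03d}"
                seq = CodonSequence(tuple(gene.codons), gene_id)
                start = 1000 + rank * spacing
                n_introns = len(gene.intron_offsets)
                end = start + 3 * len(seq) + intron_length * n_introns
                loci[gene_id] = GeneLocus(gene_id, species, chrom, rank, start, end, "+")
                proteins[species][gene_id] = seq.protein
                cds[species][gene_id] = seq.nucleotides
                gene_models[species][gene_id] = _gene_model(
                    gene_id, chrom, start, seq, gene.intron_offsets, intron_length
                )
                binding_truth[gene_id] = gene.category
                pattern_truth[gene_id] = gene.pattern
                og_truth[gene_id] = gene.lineage
                if gene.tag == "brp":
                    brp_genes.append(gene_id)
                    brp_og = gene.lineage
                if gene.tag == "bt":
                    bt_og = gene.lineage
                fpkm_rows[gene_id] = _expression_row(gene, config.tissue_profiles, rng)
                # tandem-run bookkeeping (same family, adjacent ranks)
                if run and run[-1][1].family != gene.family:
                    if len(run) >= 2:
                        tdg_clusters.append(tuple(g for g, _ in run))
                    run = []
                run.append((gene_id, gene))
            if len(run) >= 2:
                tdg_clusters.append(tuple(g for g, _ in run))

    anchors = _anchor_pairs(taxa, leaf_genomes, proteins, loci)
    fpkm = pd.DataFrame.from_dict(fpkm_rows, orient="index").sort_index()
    if not fpkm.empty:
        fpkm = fpkm[list(config.tissue_profiles.tissues)]

    truth = GroundTruth(
        og_membership=og_truth,
        tdg_clusters=tdg_clusters,
        binding_category=binding_truth,
        intron_pattern=pattern_truth,
        branch_omega={
            child.name: config.omega_for(child.name)
            for _, child in tree.root.branches()
        },
        duplication_events=events,
        loss_events=losses,
        brp_genes=tuple(sorted(brp_genes)),
        bt_og=bt_og,
        brp_og=brp_og,
        n_root_genes=n_root_genes,
    )
    bundle = PangenomeBundle(
        species=taxa,
        proteins=proteins,
        cds=cds,
        gene_models=gene_models,
        loci=loci,
        anchor_pairs=anchors,
        fpkm=fpkm,
        ground_truth=truth,
        config=config,
    )
    _check_bundle(bundle)
    return bundle


def _gene_model(
    gene_id: str,
    chrom: str,
    start: int,
    seq: CodonSequence,
    intron_offsets: tuple[int, ...],
    intron_length: int,
) -> GeneModel:
    cds_len = 3 * len(seq)
    boundaries = [0, *intron_offsets, cds_len]
    exons = []
    cursor = start
    for lo, hi in zip(boundaries, boundaries[1:]):
        exons.append((cursor, cursor + (hi - lo)))
        cursor += (hi - lo) + intron_length
    return GeneModel(
        gene_id=gene_id,
        chromosome=chrom,
        strand="+",
        exons=tuple(exons),
        cds_segments=tuple(exons),
    )


def _expression_row(
    gene: _SimGene, spec: TissueProfileSpec, rng: np.random.Generator
) -> dict[str, float]:
    base = 2.0 ** rng.normal(spec.base_log2_mean, spec.base_log2_sd)
    row = {}
    for tissue in spec.tissues:
        mean = base * (spec.bias_fold if tissue == gene.tissue else 1.0)
        row[tissue] = float(mean * 2.0 ** rng.normal(0.0, spec.noise_sigma_log2))
    return row


def _anchor_pairs(
    taxa: Sequence[str],
    leaf_genomes: Mapping[str, Mapping[str, list[_SimGene]]],
    proteins: Mapping[str, Mapping[str, str]],
    loci: Mapping[str, GeneLocus],
) -> list[AnchorPair]:
    """Homology anchors: inter-genomic within a lineage (orthologs and
    their tandem descendants), intra-genomic within a family (tandem and
    polyploidy siblings).  This emulates a similarity-thresholded anchor
    list in which cross-species out-paralogs fall below the cutoff."""
    by_lineage: dict[str, list[str]] = {}
    by_family: dict[tuple[str, int], list[str]] = {}
    info: dict[str, tuple[str, str]] = {}
    for species in taxa:
        counter = itertools.count(1)
        for chrom in sorted(leaf_genomes[species]):
            for gene in leaf_genomes[species][chrom]:
                gene_id = f"{species}g{next(counter):03d}"
                info[gene_id] = (species, gene.lineage)
                by_lineage.setdefault(gene.lineage, []).append(gene_id)
                by_family.setdefault((species, gene.family), []).append(gene_id)

    def identity(a: str, b: str) -> float:
        pa = proteins[loci[a].species][a]
        pb = proteins[loci[b].species][b]
        n = min(len(pa), len(pb))
        same = sum(1 for x, y in zip(pa, pb) if x == y)
        return round(same / n, 4) if n else 0.0

    anchors: list[AnchorPair] = []
    seen: set[tuple[str, str]] = set()
    for lineage in sorted(by_lineage):
        members = by_lineage[lineage]
        for a, b in itertools.combinations(members, 2):
            if info[a][0] == info[b][0]:
                continue
            key = tuple(sorted((a, b)))
            if key not in seen:
                seen.add(key)
                anchors.append(AnchorPair(key[0], key[1], identity(a, b), "inter"))
    for (species, _), members in sorted(by_family.items()):
        for a, b in itertools.combinations(members, 2):
            key = tuple(sorted((a, b)))
            if key not in seen:
                seen.add(key)
                anchors.append(AnchorPair(key[0], key[1], identity(a, b), "intra"))
    return anchors


def _check_bundle(bundle: PangenomeBundle) -> None:
    from Bio.Seq import Seq

    truth = bundle.ground_truth
    for species in bundle.species:
        for gene_id, cds_seq in bundle.cds[species].items():
            protein = str(Seq(cds_seq).translate())
            if protein != bundle.proteins[species][gene_id]:
                raise InputError(f"bundle inconsistency: {gene_id} CDS/protein mismatch")
            if gene_id not in truth.og_membership:
                raise InputError(f"bundle inconsistency: {gene_id} missing from OGs")
    lineage_of = truth.og_membership
    fam_of = {g: og.split(".")[0][:4] for g, og in lineage_of.items()}
    for anchor in bundle.anchor_pairs:
        if fam_of[anchor.gene_a] != fam_of[anchor.gene_b]:
            raise InputError("anchor joins genes from different families")


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FileManifest:
    files: tuple[tuple[str, int], ...]  # (relative path, record count)

    def count(self, name: str) -> int:
        for path, n in self.files:
            if path == name:
                return n
        raise KeyError(name)


def emit_files(bundle: PangenomeBundle, out_dir: str | Path) -> FileManifest:
    """Write the bundle to flat files (FASTA, GFF3, TSV) and return a manifest."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise InputError(f"output directory {out} is not writable: {exc}") from exc
    manifest: list[tuple[str, int]] = []

    for species in bundle.species:
        prot_path = out / f"{species}.protein.fasta"
        _write_fasta(prot_path, bundle.proteins[species])
        manifest.append((prot_path.name, len(bundle.proteins[species])))
        cds_path = out / f"{species}.cds.fasta"
        _write_fasta(cds_path, bundle.cds[species])
        manifest.append((cds_path.name, len(bundle.cds[species])))
        gff_path = out / f"{species}.gff3"
        n = _write_gff3(gff_path, bundle, species)
        manifest.append((gff_path.name, n))

    anchors_path = out / "anchors.tsv"
    with anchors_path.open("w") as fh:
        fh.write("gene_a\tgene_b\tsimilarity\ttype\n")
        for a in bundle.anchor_pairs:
            fh.write(f"{a.gene_a}\t{a.gene_b}\t{a.similarity}\t{a.kind}\n")
    manifest.append((anchors_path.name, len(bundle.anchor_pairs)))

    fpkm_path = out / "fpkm.tsv"
    frame = bundle.fpkm.copy()
    frame.index.name = "gene"
    frame.to_csv(fpkm_path, sep="\t")
    manifest.append((fpkm_path.name, len(frame)))

    truth = bundle.ground_truth
    truth_dir = out / "ground_truth"
    truth_dir.mkdir(exist_ok=True)

    def write_table(name: str, header: list[str], rows: list[list]) -> None:
        path = truth_dir / name
        with path.open("w") as fh:
            fh.write("\t".join(header) + "\n")
            for row in rows:
                fh.write("\t".join(str(x) for x in row) + "\n")
        manifest.append((f"ground_truth/{name}", len(rows)))

    write_table("og.tsv", ["gene", "og"], [[g, og] for g, og in sorted(truth.og_membership.items())])
    write_table("tandem.tsv", ["cluster_index", "members"],
                [[i, ",".join(m)] for i, m in enumerate(truth.tdg_clusters, 1)])
    write_table("binding.tsv", ["gene", "category"],
                [[g, c.value] for g, c in sorted(truth.binding_category.items())])
    write_table("intron.tsv", ["gene", "pattern"],
                [[g, p.value] for g, p in sorted(truth.intron_pattern.items())])
    write_table("brp.tsv", ["gene"], [[g] for g in truth.brp_genes])
    write_table("omega.tsv", ["branch", "omega"],
                [[b, w] for b, w in sorted(truth.branch_omega.items())])
    return FileManifest(tuple(manifest))


def _write_fasta(path: Path, records: Mapping[str, str]) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    SeqIO.write(
        (SeqRecord(Seq(seq), id=gene, description="") for gene, seq in sorted(records.items())),
        str(path),
        "fasta",
    )


def _write_gff3(path: Path, bundle: PangenomeBundle, species: str) -> int:
    models = bundle.gene_models[species]
    n_genes = 0
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        ordered = sorted(
            models.values(), key=lambda m: (m.chromosome, m.exons[0][0])
        )
        for model in ordered:
            n_genes += 1
            g_start = model.exons[0][0] + 1  # to 1-based inclusive
            g_end = model.exons[-1][1]
            gid = model.gene_id
            fh.write(
                f"{model.chromosome}\tbhlhkit_sim\tgene\t{g_start}\t{g_end}\t.\t"
                f"{model.strand}\t.\tID=gene:{gid}\n"
            )
            fh.write(
                f"{model.chromosome}\tbhlhkit_sim\tmRNA\t{g_start}\t{g_end}\t.\t"
                f"{model.strand}\t.\tID=mrna:{gid}.t1;Parent=gene:{gid}\n"
            )
            for k, (s, e) in enumerate(model.exons, 1):
                fh.write(
                    f"{model.chromosome}\tbhlhkit_sim\texon\t{s + 1}\t{e}\t.\t"
                    f"{model.strand}\t.\tID=exon:{gid}.t1.{k};Parent=mrna:{gid}.t1\n"
                )
            for (s, e), phase in zip(model.cds_segments, model.phases):
                fh.write(
                    f"{model.chromosome}\tbhlhkit_sim\tCDS\t{s + 1}\t{e}\t.\t"
                    f"{model.strand}\t{phase}\tID=cds:{gid}.t1;Parent=mrna:{gid}.t1\n"
                )
    return n_genes
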