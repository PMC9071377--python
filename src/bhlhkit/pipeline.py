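"""End-to-end orchestration: load genomes, locate and classify domains,
run synteny/orthology/tandem analysis, Ka/Ks, cluster phylogenetics and
expression calls, and assemble a report.

The pipeline consumes per-species protein/CDS FASTA and GFF3 files, a
homology-anchor TSV (inter- and intra-genomic) and an FPKM matrix, and
produces coordinate-ordered gene names (e.g. ``CsabHLH001``), per-gene
binding categories and intron patterns, collinear blocks, ortholog
groups, paralog pairs with substitution rates, tandem clusters with Ks,
a neighbor-joining tree of the detected regulator cluster with clade
assignment and lineage-expansion calls, tissue-predominance calls, and
the root-predominant paralog-cluster candidates (*Brp* analogs).
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import BhlhkitError, ConfigurationError, InputError
from .comparative_genomics import (
    AnchorPair,
    ChainingParams,
    CollinearBlock,
    GeneLocus,
    OrthologGroup,
    TandemCluster,
    chain_collinear_blocks,
    derive_ortholog_pairs,
    detect_tandem_clusters,
    find_paralog_pairs,
    merge_ortholog_groups,
    natural_chromosome_key,
)
from .domain_analysis import (
    BindingCategory,
    BindingRuleSet,
    DomainAnnotation,
    DomainProfile,
    GeneModel,
    ProteinRecord,
    classify_binding,
    count_basic_residues,
    default_profile,
    find_bhlh_domain,
    map_introns_to_domain,
    partition_regions,
    type_intron_pattern,
)
from .expression_profiles import (
    ExpressionMatrix,
    PredominanceCall,
    call_tissue_predominance,
    log_transform_matrix,
)
from .molecular_evolution import (
    CladeAssignment,
    ExpansionCall,
    SubstitutionRates,
    align_proteins_global,
    assign_clades,
    backtranslate_codon_alignment,
    bootstrap_support,
    build_nj_tree,
    compute_ng86,
    copy_number_table,
    infer_lineage_expansion,
    protein_distance_matrix,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Gene-model loading
# ---------------------------------------------------------------------------


def load_gene_models(
    gff3_path: str | Path,
    protein_fasta: str | Path,
    cds_fasta: str | Path,
    species: str,
) -> tuple[dict[str, GeneLocus], dict[str, GeneModel], dict[str, str], dict[str, str]]:
    """Load loci, gene models and sequences for one species.

    GFF3 1-based inclusive coordinates are converted to 0-based
    half-open; for each gene the representative transcript is the one
    with the longest CDS; genes whose CDS length is not divisible by 3
    are excluded with a warning.  Returns (loci, models, proteins, cds).
    """
    proteins = {rec.id: str(rec.seq).rstrip("*") for rec in SeqIO.parse(str(protein_fasta), "fasta")}
    cds = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(cds_fasta), "fasta")}
    db = gffutils.create_db(
        str(gff3_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models: dict[str, GeneModel] = {}
    loci: dict[str, GeneLocus] = {}
    raw: list[tuple[str, str, int, int, str]] = []
    for gene in db.features_of_type("gene"):
        gene_id = gene.id.split(":", 1)[-1]
        transcripts = list(db.children(gene, featuretype="mRNA"))
        best = None
        for mrna in transcripts or [gene]:
            segs = sorted(
                (c.start - 1, c.end) for c in db.children(mrna, featuretype="CDS")
            )
            if segs and (best is None or sum(e - s for s, e in segs) > best[1]):
                best = (mrna, sum(e - s for s, e in segs), segs)
        if best is None:
            logger.warning("%s: gene %s has no CDS; skipped", species, gene_id)
            continue
        mrna, cds_len, segs = best
        if cds_len % 3:
            logger.warning(
                "%s: gene %s CDS length %d not divisible by 3; excluded",
                species, gene_id, cds_len,
            )
            continue
        exons = sorted((e.start - 1, e.end) for e in db.children(mrna, featuretype="exon"))
        if not exons:
            exons = segs
        if gene.strand == "-":
            exons = exons[::-1]
            segs = segs[::-1]
        models[gene_id] = GeneModel(
            gene_id=gene_id,
            chromosome=gene.seqid,
            strand=gene.strand,
            exons=tuple(exons),
            cds_segments=tuple(segs),
        )
        raw.append((gene_id, gene.seqid, gene.start - 1, gene.end, gene.strand))
    by_chrom: dict[str, list[tuple]] = {}
    for item in raw:
        by_chrom.setdefault(item[1], []).append(item)
    for chrom, items in by_chrom.items():
        for rank, (gene_id, _, start, end, strand) in enumerate(
            sorted(items, key=lambda t: t[2])
        ):
            loci[gene_id] = GeneLocus(gene_id, species, chrom, rank, start, end, strand)
    return loci, models, proteins, cds


def load_bundle_dir(directory: str | Path) -> dict:
    """Discover the per-species files of an emitted bundle directory."""
    directory = Path(directory)
    species_files: dict[str, dict[str, str]] = {}
    for prot in sorted(directory.glob("*.protein.fasta")):
        sp = prot.name.removesuffix(".protein.fasta")
        species_files[sp] = {
            "protein_fasta": str(prot),
            "cds_fasta": str(directory / f"{sp}.cds.fasta"),
            "gff3": str(directory / f"{sp}.gff3"),
        }
    return {
        "species_files": species_files,
        "anchors_tsv": str(directory / "anchors.tsv"),
        "fpkm_tsv": str(directory / "fpkm.tsv"),
    }


# ---------------------------------------------------------------------------
# Gene naming and summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneName:
    prefix: str
    index: int
    family_tag: str = "bHLH"

    def __str__(self) -> str:
        return f"{self.prefix}{self.family_tag}{self.index:03d}"


def name_genes(
    loci: Mapping[str, GeneLocus], prefix: str
) -> dict[str, GeneName]:
    """Coordinate-ordered family names, e.g. CsabHLH001.

    Loci are sorted by (natural chromosome order, start); duplicate
    coordinates fall back to the input gene id with a warning.
    """
    items = sorted(
        loci.values(),
        key=lambda l: (natural_chromosome_key(l.chromosome), l.start, l.gene_id),
    )
    seen = set()
    names = {}
    for index, locus in enumerate(items, start=1):
        key = (locus.chromosome, locus.start)
        if key in seen:
            logger.warning(
                "duplicate coordinates at %s:%d; ordering falls back to gene id",
                locus.chromosome, locus.start,
            )
        seen.add(key)
        names[locus.gene_id] = GeneName(prefix, index)
    return names


def summarize_categories(gene_table: pd.DataFrame) -> pd.DataFrame:
    """Per-species percentages over the four binding categories (to 0.1%)."""
    if "species" not in gene_table or "category" not in gene_table:
        raise InputError("gene table must have 'species' and 'category' columns")
    rows = {}
    order = [c.value for c in BindingCategory]
    for species, sub in gene_table.groupby("species"):
        counts = sub["category"].value_counts()
        total = int(counts.sum())
        rows[species] = {
            cat: round(100.0 * counts.get(cat, 0) / total, 1) if total else 0.0
            for cat in order
        }
    return pd.DataFrame.from_dict(rows, orient="index")[order].sort_index()


def flag_brp_candidates(
    paralog_cluster_genes: Iterable[str],
    clades: CladeAssignment | None,
    predominance_calls: Sequence[PredominanceCall],
    target_tissue: str = "root",
    clade_label: str | None = None,
    species_of: Mapping[str, str] | None = None,
) -> tuple[list[str], str | None]:
    """Root-expressed candidates in the paralogous regulator cluster.

    Candidates are the cluster genes that are tissue-predominant in the
    target tissue and (when a clade assignment is available) lie in the
    designated clade — by default the clade holding most of the
    predominant cluster genes.  Cluster genes without an expression
    record are skipped with a warning; deviations from one candidate per
    species are warned about.
    """
    cluster = set(paralog_cluster_genes)
    verdicts = {c.gene: c.verdict for c in predominance_calls if c.tissue == target_tissue}
    predominant = set()
    for gene in sorted(cluster):
        if gene not in verdicts:
            logger.warning("cluster gene %s has no expression record; skipped", gene)
            continue
        if verdicts[gene]:
            predominant.add(gene)
    if clades is None:
        return sorted(predominant), None
    if clade_label is None:
        in_clades = [clades.assignment.get(g) for g in predominant]
        in_clades = [c for c in in_clades if c is not None]
        if not in_clades:
            logger.warning("no %s-predominant gene in the paralogous cluster", target_tissue)
            return [], None
        clade_label = max(sorted(set(in_clades)), key=in_clades.count)
    candidates = sorted(
        g for g in predominant if clades.assignment.get(g) == clade_label
    )
    if species_of:
        per_species: dict[str, int] = {}
        for g in candidates:
            per_species[species_of[g]] = per_species.get(species_of[g], 0) + 1
        for sp, n in sorted(per_species.items()):
            if n != 1:
                logger.warning("species %s has %d candidates (expected 1)", sp, n)
    return candidates, clade_label


# ---------------------------------------------------------------------------
# Configuration and report containers
# ---------------------------------------------------------------------------


@dataclass
class AnalysisConfig:
    species_files: dict[str, dict[str, str]]  # species -> {gff3, protein_fasta, cds_fasta}
    anchors_tsv: str
    fpkm_tsv: str | None = None
    outdir: str | None = None
    seed: int = 0
    family_tag: str = "bHLH"
    chaining: ChainingParams = field(default_factory=ChainingParams)
    binding_rules: BindingRuleSet = field(default_factory=BindingRuleSet)
    max_tandem_gap: int = 1
    intron_tolerance: int = 6
    fold_threshold: float = 2.0
    min_expression: float = 1.0
    target_tissue: str = "root"
    bootstrap_reps: int = 100
    distance_method: str = "poisson"
    partial_deletion_coverage: float = 0.8
    clade_count: int = 5
    recent_ks_threshold: float = 0.32

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        data = json.loads(Path(path).read_text())
        chaining = ChainingParams(**data.pop("chaining", {}))
        data.pop("binding_rules", None)
        config = cls(chaining=chaining, **data)
        return config

    def validate(self) -> None:
        for sp, files in self.species_files.items():
            for key in ("gff3", "protein_fasta", "cds_fasta"):
                if key not in files:
                    raise ConfigurationError(f"species {sp}: missing {key}")
                if not Path(files[key]).exists():
                    raise ConfigurationError(f"species {sp}: {files[key]} does not exist")
        if not Path(self.anchors_tsv).exists():
            raise ConfigurationError(f"anchors_tsv {self.anchors_tsv} does not exist")
        if self.fpkm_tsv is not None and not Path(self.fpkm_tsv).exists():
            raise ConfigurationError(f"fpkm_tsv {self.fpkm_tsv} does not exist")


@dataclass
class ClusterReport:
    bt_og: str | None = None
    paralog_og: str | None = None
    tree_newick: str | None = None
    bootstrap: dict | None = None
    clades: CladeAssignment | None = None
    ancestral_copy_number: int | None = None
    expansion_calls: list[ExpansionCall] = field(default_factory=list)
    copy_numbers: pd.DataFrame | None = None
    designated_clade: str | None = None


@dataclass
class ReportBundle:
    gene_table: pd.DataFrame
    category_percentages: pd.DataFrame
    ortholog_groups: list[OrthologGroup]
    blocks: list[CollinearBlock]
    paralog_rates: pd.DataFrame
    tandem_clusters: list[TandemCluster]
    tandem_rates: pd.DataFrame
    cluster: ClusterReport
    predominance: list[PredominanceCall]
    brp_candidates: list[str]
    names: dict[str, str]

    def og_partition(self) -> set[frozenset[str]]:
        return {og.members for og in self.ortholog_groups}

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.gene_table.to_csv(out / "gene_table.tsv", sep="\t", index=False)
        self.category_percentages.to_csv(out / "category_percentages.tsv", sep="\t")
        with (out / "ortholog_groups.tsv").open("w") as fh:
            fh.write("og_id\tspecies_count\tmembers\n")
            for og in self.ortholog_groups:
                fh.write(f"{og.og_id}\t{og.species_count}\t{','.join(sorted(og.members))}\n")
        with (out / "blocks.tsv").open("w") as fh:
            fh.write("block_id\tside_a\tside_b\torientation\tscore\tsize\tanchors\n")
            for b in self.blocks:
                anchors = ";".join(f"{x}|{y}" for x, y in b.anchors)
                fh.write(
                    f"{b.block_id}\t{':'.join(b.side_a)}\t{':'.join(b.side_b)}\t"
                    f"{b.orientation}\t{b.score:.4f}\t{b.size}\t{anchors}\n"
                )
        self.paralog_rates.to_csv(out / "paralog_kaks.tsv", sep="\t", index=False)
        self.tandem_rates.to_csv(out / "tandem_kaks.tsv", sep="\t", index=False)
        with (out / "tandem_clusters.tsv").open("w") as fh:
            fh.write("species\tcluster_id\tchromosome\tmembers\n")
            for c in self.tandem_clusters:
                fh.write(f"{c.species}\t{c.cluster_id}\t{c.chromosome}\t{','.join(c.members)}\n")
        if self.cluster.tree_newick:
            (out / "cluster_tree.nwk").write_text(self.cluster.tree_newick + "\n")
        if self.cluster.clades is not None:
            with (out / "clades.tsv").open("w") as fh:
                fh.write("gene\tclade\n")
                for gene, clade in sorted(self.cluster.clades.assignment.items()):
                    fh.write(f"{gene}\t{clade}\n")
        if self.cluster.expansion_calls:
            rows = []
            for call in self.cluster.expansion_calls:
                rows.append({
                    "species": call.species, "clade": call.clade,
                    "genes": ",".join(call.genes), "verdict": call.verdict,
                    "intra_ks_max": call.intra_ks_max, "inter_ks_min": call.inter_ks_min,
                    "recent": call.recent,
                })
            pd.DataFrame(rows).to_csv(out / "expansion_calls.tsv", sep="\t", index=False)
        with (out / "predominance.tsv").open("w") as fh:
            fh.write("gene\ttissue\tmax_fpkm\tsecond_fpkm\tverdict\n")
            for call in self.predominance:
                fh.write(
                    f"{call.gene}\t{call.tissue}\t{call.max_value:.4f}\t"
                    f"{call.second_value:.4f}\t{call.verdict}\n"
                )
        (out / "brp_candidates.tsv").write_text(
            "gene\n" + "".join(f"{g}\n" for g in self.brp_candidates)
        )


def star_codon_msa(
    genes: Sequence[str],
    proteins: Mapping[str, str],
    cds: Mapping[str, str],
) -> dict[str, str]:
    """Reference-anchored nucleotide MSA of closely related genes.

    Every gene is aligned pairwise to the alphabetically first gene and
    its codons are projected onto the reference coordinates (insertions
    relative to the reference are dropped).  Exact for indel-free gene
    sets; an approximation elsewhere.  Rows are nucleotide strings of
    length 3 x len(reference protein) with '-' gaps.
    """
    ordered = sorted(genes)
    reference = ordered[0]
    ref_len = len(proteins[reference])
    msa: dict[str, str] = {}
    for gene in ordered:
        if gene == reference:
            msa[gene] = cds[gene][: 3 * ref_len]
            continue
        aln = align_proteins_global(proteins[reference], proteins[gene])
        codon_aln = backtranslate_codon_alignment(
            aln, cds[reference], cds[gene], a_id=reference, b_id=gene
        )
        row = [
            cb
            for ca, cb in zip(codon_aln.codons_a, codon_aln.codons_b)
            if ca != "---"
        ]
        msa[gene] = "".join(row)
    return msa


# ---------------------------------------------------------------------------
# Ka/Ks helper
# ---------------------------------------------------------------------------


def pairwise_rates(
    gene_a: str,
    gene_b: str,
    proteins: Mapping[str, str],
    cds: Mapping[str, str],
) -> SubstitutionRates:
    """Align two proteins, back-translate, and compute NG86 rates."""
    aln = align_proteins_global(proteins[gene_a], proteins[gene_b])
    codon_aln = backtranslate_codon_alignment(
        aln, cds[gene_a], cds[gene_b], a_id=gene_a, b_id=gene_b
    )
    return compute_ng86(codon_aln)


def _rates_frame(
    pairs: Iterable[tuple[str, str]],
    proteins: Mapping[str, str],
    cds: Mapping[str, str],
    species_of: Mapping[str, str],
) -> pd.DataFrame:
    rows = []
    for a, b in pairs:
        rates = pairwise_rates(a, b, proteins, cds)
        rows.append({
            "gene_a": a, "gene_b": b, "species": species_of.get(a, ""),
            "S": rates.S, "N": rates.N, "Sd": rates.Sd, "Nd": rates.Nd,
            "Ka": rates.Ka, "Ks": rates.Ks,
            "ratio": rates.ratio if rates.ratio is not None else float("nan"),
            "saturated": rates.saturated,
        })
    columns = ["gene_a", "gene_b", "species", "S", "N", "Sd", "Nd", "Ka", "Ks",
               "ratio", "saturated"]
    return pd.DataFrame(rows, columns=columns)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


def run_full_analysis(config: AnalysisConfig) -> ReportBundle:
    """Execute the full analysis and return (and optionally write) the report."""

    def stage(name: str):
        logger.info("stage: %s", name)
        return name

    current = stage("load")
    try:
        config.validate()
        profile = default_profile()
        loci: dict[str, GeneLocus] = {}
        models: dict[str, GeneModel] = {}
        proteins: dict[str, str] = {}
        cds: dict[str, str] = {}
        species_of: dict[str, str] = {}
        per_species_loci: dict[str, dict[str, GeneLocus]] = {}
        for sp in sorted(config.species_files):
            files = config.species_files[sp]
            sp_loci, sp_models, sp_prot, sp_cds = load_gene_models(
                files["gff3"], files["protein_fasta"], files["cds_fasta"], sp
            )
            logger.info("loaded %s: %d genes", sp, len(sp_loci))
            per_species_loci[sp] = sp_loci
            loci.update(sp_loci)
            models.update(sp_models)
            proteins.update(sp_prot)
            cds.update(sp_cds)
            species_of.update({g: sp for g in sp_loci})

        current = stage("name")
        names: dict[str, str] = {}
        for sp in sorted(per_species_loci):
            names.update({
                g: str(n) for g, n in name_genes(per_species_loci[sp], sp).items()
            })

        current = stage("domain")
        annotations: dict[str, DomainAnnotation] = {}
        rows = []
        for gene_id in sorted(loci):
            record = ProteinRecord(gene_id, species_of[gene_id], proteins[gene_id])
            annotation = find_bhlh_domain(record, profile)
            row = {
                "species": species_of[gene_id], "gene": gene_id,
                "name": names.get(gene_id, ""),
                "chromosome": loci[gene_id].chromosome, "start": loci[gene_id].start,
                "domain_start": None, "domain_end": None, "score": None,
                "basic_count": None, "category": None, "pattern": None,
                **{f"region_{r}": None for r in profile.region_spec},
            }
            if annotation is not None:
                annotations[gene_id] = annotation
                category = classify_binding(annotation, profile, config.binding_rules)
                regions = partition_regions(annotation, profile)
                events = map_introns_to_domain(
                    models[gene_id], annotation, cds[gene_id]
                ) if gene_id in models else []
                pattern = type_intron_pattern(events, tolerance=config.intron_tolerance)
                row.update({
                    "domain_start": annotation.start, "domain_end": annotation.end,
                    "score": round(annotation.score, 2),
                    "basic_count": count_basic_residues(annotation, profile, config.binding_rules),
                    "category": category.value, "pattern": pattern.value,
                    **{
                        f"region_{r}": "" if span is None else f"{span[0]}-{span[1]}"
                        for r, span in regions.items()
                    },
                })
            rows.append(row)
        gene_table = pd.DataFrame(rows)
        family_genes = frozenset(annotations)
        logger.info("domains located in %d/%d genes", len(family_genes), len(loci))

        current = stage("classify-summary")
        categorized = gene_table.dropna(subset=["category"])
        percentages = summarize_categories(categorized) if not categorized.empty \
            else pd.DataFrame()

        current = stage("synteny")
        anchors_df = pd.read_csv(config.anchors_tsv, sep="\t")
        anchors = [
            AnchorPair(r.gene_a, r.gene_b, float(r.similarity), str(r.type))
            for r in anchors_df.itertuples()
            if r.gene_a in loci and r.gene_b in loci
        ]
        blocks = chain_collinear_blocks(anchors, loci, config.chaining)
        logger.info("chained %d collinear blocks from %d anchors", len(blocks), len(anchors))

        current = stage("orthology")
        ortho_pairs = derive_ortholog_pairs(blocks, family_genes, loci)
        paralog_pairs = find_paralog_pairs(blocks, family_genes, loci)
        intra_anchors = [a for a in anchors if a.kind == "intra"]
        tandem = detect_tandem_clusters(loci, intra_anchors, config.max_tandem_gap)
        tandem = [
            TandemCluster(c.cluster_id, c.species,
                          tuple(g for g in c.members if g in family_genes), c.chromosome)
            for c in tandem
        ]
        tandem = [c for c in tandem if len(c.members) >= 2]
        tandem_copair = [
            pair
            for cluster in tandem
            for pair in itertools.combinations(cluster.members, 2)
        ]
        ogs = merge_ortholog_groups(ortho_pairs, family_genes, loci, tandem_copair)
        logger.info(
            "%d ortholog pairs -> %d OGs; %d paralog pairs; %d tandem clusters",
            len(ortho_pairs), len(ogs), len(paralog_pairs), len(tandem),
        )

        current = stage("kaks")
        paralog_rates = _rates_frame(paralog_pairs, proteins, cds, species_of)
        tandem_rates = _rates_frame(tandem_copair, proteins, cds, species_of)

        current = stage("cluster-evolution")
        cluster = _cluster_evolution(
            config, ogs, tandem, paralog_pairs, annotations, profile,
            proteins, cds, species_of,
        )

        current = stage("expression")
        predominance: list[PredominanceCall] = []
        brp_candidates: list[str] = []
        if config.fpkm_tsv is not None:
            fpkm = pd.read_csv(config.fpkm_tsv, sep="\t", index_col=0)
            matrix = log_transform_matrix(ExpressionMatrix(fpkm))
            predominance = call_tissue_predominance(
                matrix, config.target_tissue,
                fold_threshold=config.fold_threshold,
                min_expression=config.min_expression,
            )
            if cluster.paralog_og is not None:
                paralog_members = next(
                    og.members for og in ogs if og.og_id == cluster.paralog_og
                )
                brp_candidates, designated = flag_brp_candidates(
                    paralog_members, cluster.clades, predominance,
                    target_tissue=config.target_tissue, species_of=species_of,
                )
                cluster.designated_clade = designated

        current = stage("report")
        report = ReportBundle(
            gene_table=gene_table,
            category_percentages=percentages,
            ortholog_groups=ogs,
            blocks=blocks,
            paralog_rates=paralog_rates,
            tandem_clusters=tandem,
            tandem_rates=tandem_rates,
            cluster=cluster,
            predominance=predominance,
            brp_candidates=brp_candidates,
            names=names,
        )
        if config.outdir:
            report.write(config.outdir)
        return report
    except BhlhkitError as exc:
        raise BhlhkitError(f"stage '{current}' failed: {exc}") from exc


def _cluster_evolution(
    config: AnalysisConfig,
    ogs: Sequence[OrthologGroup],
    tandem: Sequence[TandemCluster],
    paralog_pairs: Sequence[tuple[str, str]],
    annotations: Mapping[str, DomainAnnotation],
    profile: DomainProfile,
    proteins: Mapping[str, str],
    cds: Mapping[str, str],
    species_of: Mapping[str, str],
) -> ClusterReport:
    """Identify the tandem regulator cluster OG and its paralogous OG,
    build the cluster NJ tree, assign clades, and call expansions."""
    report = ClusterReport()
    og_of = {g: og.og_id for og in ogs for g in og.members}
    members_of = {og.og_id: og.members for og in ogs}
    clusters_by_og: dict[str, set[str]] = {}
    for cluster in tandem:
        og_ids = {og_of.get(g) for g in cluster.members}
        og_ids.discard(None)
        if len(og_ids) == 1:
            clusters_by_og.setdefault(og_ids.pop(), set()).add(cluster.species)
    if not clusters_by_og:
        logger.info("no tandem-bearing OG; cluster evolution skipped")
        return report
    bt_og = max(
        sorted(clusters_by_og),
        key=lambda og: (len(clusters_by_og[og]), len(members_of[og])),
    )
    report.bt_og = bt_og
    partner_counts: dict[str, int] = {}
    for a, b in paralog_pairs:
        oa, ob = og_of.get(a), og_of.get(b)
        if oa == bt_og and ob not in (None, bt_og):
            partner_counts[ob] = partner_counts.get(ob, 0) + 1
        elif ob == bt_og and oa not in (None, bt_og):
            partner_counts[oa] = partner_counts.get(oa, 0) + 1
    if partner_counts:
        report.paralog_og = max(sorted(partner_counts), key=partner_counts.get)
    cluster_genes = sorted(
        members_of[bt_og]
        | (members_of[report.paralog_og] if report.paralog_og else set())
    )
    cluster_genes = [g for g in cluster_genes if g in annotations]
    if len(cluster_genes) < 3:
        logger.info("cluster has <3 genes with domains; tree skipped")
        return report
    # Close paralogs/orthologs: use the full CDS (reference-anchored codon
    # MSA) rather than the short domain alignment — far more informative
    # columns for resolving clades within the cluster.
    msa = star_codon_msa(cluster_genes, proteins, cds)
    distance = protein_distance_matrix(
        msa, method=config.distance_method,
        partial_deletion_coverage=config.partial_deletion_coverage,
    )
    matrix = distance.matrix.copy()
    if not np.all(np.isfinite(matrix)):
        finite = matrix[np.isfinite(matrix)]
        cap = 2.0 * (finite.max() if finite.size else 1.0)
        matrix[~np.isfinite(matrix)] = cap
        distance = type(distance)(distance.labels, matrix, distance.method,
                                  distance.partial_deletion_coverage)
    tree = build_nj_tree(distance)
    support = bootstrap_support(
        msa, n_reps=config.bootstrap_reps, seed=config.seed,
        distance_method=config.distance_method,
        partial_deletion_coverage=config.partial_deletion_coverage,
    )
    report.tree_newick = tree.newick(support)
    report.bootstrap = {tuple(sorted(k)): v for k, v in support.items()}
    k = min(config.clade_count, len(cluster_genes))
    clades = assign_clades(tree, k)
    report.clades = clades
    bt_members = members_of[bt_og]
    report.ancestral_copy_number = len({
        clades.assignment[g] for g in bt_members if g in clades.assignment
    })
    ks_table: dict[frozenset[str], float | None] = {}
    for a, b in itertools.combinations(cluster_genes, 2):
        rates = pairwise_rates(a, b, proteins, cds)
        ks_table[frozenset((a, b))] = None if rates.saturated else rates.Ks
    genes_by_species: dict[str, list[str]] = {}
    for g in cluster_genes:
        genes_by_species.setdefault(species_of[g], []).append(g)
    calls = infer_lineage_expansion(
        genes_by_species, ks_table, clades,
        recent_dup_threshold=config.recent_ks_threshold,
        species_universe=sorted({species_of[g] for g in species_of}),
    )
    report.expansion_calls = calls
    report.copy_numbers = copy_number_table(calls)
    return report


# ---------------------------------------------------------------------------
# Ground-truth evaluation (used by tests and the acceptance script)
# ---------------------------------------------------------------------------


def evaluate_against_truth(report: ReportBundle, truth) -> dict[str, float]:
    """Recovery metrics of a pipeline report against simulator ground truth."""
    truth_ogs = truth.og_partition()
    found_ogs = report.og_partition()
    og_hits = sum(1 for og in truth_ogs if og in found_ogs)
    truth_clusters = {frozenset(c) for c in truth.tdg_clusters}
    found_clusters = {frozenset(c.members) for c in report.tandem_clusters}
    tandem_hits = sum(1 for c in truth_clusters if c in found_clusters)
    table = report.gene_table.set_index("gene")
    binding_ok = pattern_ok = n_genes = 0
    for gene, category in truth.binding_category.items():
        n_genes += 1
        if gene in table.index:
            if table.loc[gene, "category"] == category.value:
                binding_ok += 1
            if table.loc[gene, "pattern"] == truth.intron_pattern[gene].value:
                pattern_ok += 1
    brp_truth = set(truth.brp_genes)
    brp_found = set(report.brp_candidates)
    return {
        "n_true_ogs": len(truth_ogs),
        "og_recovery_pct": 100.0 * og_hits / len(truth_ogs) if truth_ogs else 100.0,
        "n_true_tandem_clusters": len(truth_clusters),
        "tandem_recovery_pct": (
            100.0 * tandem_hits / len(truth_clusters) if truth_clusters else 100.0
        ),
        "false_tandem_clusters": len(found_clusters - truth_clusters),
        "n_genes": n_genes,
        "binding_recovery_pct": 100.0 * binding_ok / n_genes if n_genes else 100.0,
        "intron_recovery_pct": 100.0 * pattern_ok / n_genes if n_genes else 100.0,
        "brp_true_positives": len(brp_truth & brp_found),
        "brp_false_positives": len(brp_found - brp_truth),
        "brp_false_negatives": len(brp_truth - brp_found),
        "brp_exact": float(brp_truth == brp_found),
    }
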