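"""End-to-end orchestration of the comparative regulon-reconstruction workflow.

Stages run strictly in order: parse genomes -> TF ortholog detection -> TF
tree -> mixture motifs -> operon prediction -> promoter scoring -> operon
splitting -> rescan -> regulated gene set -> reciprocal-best-hit cliques ->
bootstrapped ancestral reconstruction -> reports.  A run with identical
configuration and seed reproduces identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import ancestral_recon, genome_model, motif_model, orthologs, promoter_scoring, reporting
from .errors import ConfigurationError, PipelineError
from .genome_model import Genome, Operon
from .motif_model import SiteCollection
from .promoter_scoring import best_site_of
from .search import AlignmentSearchBackend, SearchBackend
from . import tf_phylogeny
from .tf_phylogeny import TFInstance

logger = logging.getLogger(__name__)

PROMOTER_UPSTREAM = 250
PROMOTER_DOWNSTREAM = 50
MIN_BACKGROUND_WINDOWS = 100


@dataclass(frozen=True)
class ReferenceConfig:
    instance_id: str
    protein: str
    sites: tuple[str, ...]
    species_id: Optional[str] = None  # set when the reference is also a target


@dataclass(frozen=True)
class SpeciesConfig:
    species_id: str
    genome_files: tuple[str, ...]


@dataclass(frozen=True)
class Parameters:
    sites_per_promoter: int = 1
    posterior_cutoff: float = 0.5
    evalue_ortholog: float = orthologs.ORTHOLOG_EVALUE_CUTOFF
    evalue_tf: float = tf_phylogeny.TF_EVALUE_CUTOFF
    bootstrap_replicates: int = ancestral_recon.DEFAULT_N_REPLICATES
    rng_seed: int = 0
    prior_mode: str = "auto"  # auto | site-count | information-content
    pseudocount: float = motif_model.DEFAULT_PSEUDOCOUNT
    threshold_multiplier: float = 1.0
    reference_regulon_size: Optional[int] = None
    reference_n_operons: Optional[int] = None  # informative only


@dataclass(frozen=True)
class RunConfig:
    tf_instances: tuple[ReferenceConfig, ...]
    species: tuple[SpeciesConfig, ...]
    parameters: Parameters = field(default_factory=Parameters)

    def __post_init__(self):
        refs_with_sites = [r for r in self.tf_instances if len(r.sites) >= 2]
        if not refs_with_sites:
            raise ConfigurationError(
                "at least one reference TF instance with >= 2 aligned sites is required"
            )
        if not self.species:
            raise ConfigurationError("at least one target species is required")
        for sp in self.species:
            for f in sp.genome_files:
                if not Path(f).exists():
                    raise ConfigurationError(f"{sp.species_id}: genome file not found: {f}")
        mode = self.parameters.prior_mode
        if mode not in ("auto", "site-count", "information-content"):
            raise ConfigurationError(f"unknown prior_mode {mode!r}")

    @property
    def references(self) -> list[ReferenceConfig]:
        return [r for r in self.tf_instances if len(r.sites) >= 2]


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a JSON run configuration."""
    raw = json.loads(Path(path).read_text(encoding="utf-8"))
    try:
        refs = tuple(
            ReferenceConfig(
                instance_id=t["id"],
                protein=t.get("protein", ""),
                sites=tuple(t.get("sites", [])),
                species_id=t.get("species_id"),
            )
            for t in raw["tf_instances"]
        )
        species = tuple(
            SpeciesConfig(s["species_id"], tuple(s["genome_files"])) for s in raw["species"]
        )
    except KeyError as exc:
        raise ConfigurationError(f"missing required config key: {exc}")
    params = Parameters(**raw.get("parameters", {}))
    return RunConfig(tf_instances=refs, species=species, parameters=params)


@dataclass
class SpeciesResult:
    genome: Genome
    operons: list[Operon]
    posteriors: dict[str, "promoter_scoring.RegulationPosterior"]  # operon_id -> posterior
    gene_info: dict[str, tuple[str, float]]  # locus -> (operon_id, p_regulated)
    site_rows: list[list]
    pssm: "motif_model.PSSM"
    mixture: "motif_model.PSWM"


@dataclass
class PipelineResult:
    species_results: dict[str, SpeciesResult]
    tree: Optional[object]
    groups: list[orthologs.OrthologGroup]
    ancestral: list[ancestral_recon.AncestralReport]
    matrix: Optional[reporting.RegulonMatrix]
    manifest: dict[str, str]


def _promoter_sequence(genome: Genome, interval: tuple[str, int, int]) -> str:
    contig, start, end = interval
    return genome.contig(contig).sequence[start:end]


def _gene_upstream_window(genome: Genome, gene) -> str:
    """Untruncated [-250, +50] window around a gene's translation start."""
    seq = genome.contig(gene.contig).sequence
    if gene.strand == "+":
        return seq[max(0, gene.start - PROMOTER_UPSTREAM): gene.start + PROMOTER_DOWNSTREAM]
    return seq[max(0, gene.end - PROMOTER_DOWNSTREAM): gene.end + PROMOTER_UPSTREAM]


def _score_species(
    species_id: str,
    genome: Genome,
    mixture: motif_model.PSWM,
    params: Parameters,
) -> SpeciesResult:
    """Operon prediction, promoter scoring, splitting and rescan for one species."""
    bg = genome.mononucleotide_frequencies
    pssm = motif_model.pswm_to_pssm(mixture, bg)

    threshold = genome_model.adaptive_operon_threshold(genome) * params.threshold_multiplier
    operons = genome_model.predict_operons(genome, threshold)

    def regions_of(ops: list[Operon]) -> dict[str, tuple[str, int, int]]:
        return {
            op.operon_id: genome_model.promoter_interval(
                op, genome, PROMOTER_UPSTREAM, PROMOTER_DOWNSTREAM
            )
            for op in ops
        }

    regions = regions_of(operons)
    region_seqs = [_promoter_sequence(genome, iv) for iv in regions.values()]
    n_windows = sum(max(0, len(s) - pssm.width + 1) for s in region_seqs)
    bg_regions = list(region_seqs)
    if n_windows < MIN_BACKGROUND_WINDOWS:
        logger.warning("%s: only %d promoter windows; widening background fit to "
                       "whole contigs", species_id, n_windows)
        bg_regions += [c.sequence for c in genome.contigs]
    bg_model = promoter_scoring.fit_background_model(pssm, bg_regions)
    motif_stats = promoter_scoring.fit_motif_model(pssm, mixture)

    avg_promoter = genome_model.average_divergent_intergenic_distance(genome)
    alpha = promoter_scoring.alpha_prior(params.sites_per_promoter, int(round(avg_promoter)))
    ic = motif_model.information_content(mixture, bg)
    if params.prior_mode == "site-count" or (
        params.prior_mode == "auto" and params.reference_regulon_size is not None
    ):
        if params.reference_regulon_size is None:
            raise ConfigurationError("prior_mode=site-count needs reference_regulon_size")
        p_r = promoter_scoring.estimate_prior_from_sites(
            params.reference_regulon_size, len(operons)
        )
    else:
        p_r = promoter_scoring.estimate_prior_from_ic(ic, max(n_windows, 1), len(operons))
    priors = promoter_scoring.PriorConfig(alpha=alpha, p_regulation=p_r)

    def score_operons(ops, regs):
        scans, posts = {}, {}
        for op in ops:
            seq = _promoter_sequence(genome, regs[op.operon_id])
            scan = promoter_scoring.scan_promoter(pssm, seq, op.operon_id, regs[op.operon_id][1:])
            scans[op.operon_id] = scan
            posts[op.operon_id] = promoter_scoring.posterior_probability(
                scan, bg_model, motif_stats, priors
            )
        return scans, posts

    scans, posteriors = score_operons(operons, regions)

    # splitting: single-strand scores over the untruncated window of each gene
    split_thr = genome_model.split_score_threshold(pssm, bg, ic)
    per_gene_best = {}
    for gene in genome.genes:
        window = _gene_upstream_window(genome, gene)
        fwd = promoter_scoring.score_windows_single_strand(pssm, window)
        rev = promoter_scoring.score_windows_single_strand(
            pssm, promoter_scoring.reverse_complement(window)
        )
        best = -np.inf
        for arr in (fwd, rev):
            finite = arr[~np.isnan(arr)] if arr.size else arr
            if finite.size:
                best = max(best, float(finite.max()))
        per_gene_best[gene.locus_tag] = best
    split_ops = genome_model.split_operons_on_sites(operons, per_gene_best, split_thr, species_id)

    # rescan only promoters whose first gene is new; recycle otherwise
    old_by_first = {op.first_gene.locus_tag: op.operon_id for op in operons}
    final_regions = regions_of(split_ops)
    final_scans, final_posts = {}, {}
    for op in split_ops:
        prev_id = old_by_first.get(op.first_gene.locus_tag)
        if prev_id is not None:
            final_scans[op.operon_id] = scans[prev_id]
            final_posts[op.operon_id] = promoter_scoring.RegulationPosterior(
                op.operon_id, posteriors[prev_id].p_regulated, None
            )
        else:
            scan = promoter_scoring.scan_promoter(
                pssm,
                _promoter_sequence(genome, final_regions[op.operon_id]),
                op.operon_id,
                final_regions[op.operon_id][1:],
            )
            final_scans[op.operon_id] = scan
            final_posts[op.operon_id] = promoter_scoring.posterior_probability(
                scan, bg_model, motif_stats, priors
            )

    gene_info, site_rows = {}, []
    for op in split_ops:
        p = final_posts[op.operon_id].p_regulated
        for gene in op.genes:
            gene_info[gene.locus_tag] = (op.operon_id, p)
        site = best_site_of(final_scans[op.operon_id], pssm.width)
        if site is not None:
            _contig, rstart, _rend = final_regions[op.operon_id]
            g = op.first_gene
            left = rstart + site.position
            if g.strand == "+":
                rel = left - g.start
            else:
                rel = g.end - left - pssm.width
            site_rows.append([
                species_id, op.operon_id, g.locus_tag, rel, site.strand,
                site.sequence, f"{site.score:.4f}", f"{p:.6f}",
            ])
    return SpeciesResult(
        genome=genome,
        operons=split_ops,
        posteriors=final_posts,
        gene_info=gene_info,
        site_rows=site_rows,
        pssm=pssm,
        mixture=mixture,
    )


def run_pipeline(
    config: RunConfig,
    out_dir: str | Path,
    figures: bool = False,
    search_backend: SearchBackend | None = None,
) -> PipelineResult:
    params = config.parameters
    backend = search_backend or AlignmentSearchBackend()
    out_dir = Path(out_dir)

    # --- stage 1: parse genomes --------------------------------------------
    genomes: dict[str, Genome] = {}
    for sp in config.species:
        records = []
        for f in sp.genome_files:
            from Bio import SeqIO

            records.extend(SeqIO.parse(f, "genbank"))
        genomes[sp.species_id] = genome_model.parse_genome(records, sp.species_id)
        logger.info("parsed %s: %d contigs, %d genes", sp.species_id,
                    len(genomes[sp.species_id].contigs), len(genomes[sp.species_id].genes))

    # --- stage 2: TF ortholog detection ------------------------------------
    reference_db = {r.instance_id: r.protein for r in config.references if r.protein}
    if not reference_db:
        raise ConfigurationError("no reference TF instance carries a protein sequence")
    tf_by_species: dict[str, TFInstance] = {}
    for species_id, genome in genomes.items():
        found = None
        for ref in config.references:
            if not ref.protein:
                continue
            ref_tf = TFInstance(ref.instance_id, ref.species_id or ref.instance_id,
                                ref.protein, "reference")
            found = tf_phylogeny.find_tf_ortholog(
                ref_tf, genome, backend, params.evalue_tf, reference_db
            )
            if found is not None:
                break
        if found is None:
            logger.warning("%s: no TF ortholog found; species dropped", species_id)
        else:
            tf_by_species[species_id] = found
    if not tf_by_species:
        raise PipelineError("tf_ortholog", "no target species retains a TF ortholog")
    kept_species = [sp.species_id for sp in config.species if sp.species_id in tf_by_species]

    # --- stage 3: TF tree ---------------------------------------------------
    # one leaf per retained target species; extra leaves for references whose
    # species is not a target
    leaf_seqs: dict[str, str] = {s: tf_by_species[s].protein for s in kept_species}
    ref_leaf: dict[str, str] = {}
    for ref in config.references:
        if ref.species_id in leaf_seqs:
            ref_leaf[ref.instance_id] = ref.species_id
        else:
            leaf_name = ref.instance_id
            leaf_seqs[leaf_name] = ref.protein
            ref_leaf[ref.instance_id] = leaf_name
    tree = None
    leaf_names = sorted(leaf_seqs)
    if len(leaf_names) >= 2:
        n = len(leaf_names)
        mat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = tf_phylogeny.pairwise_distance(leaf_seqs[leaf_names[i]],
                                                   leaf_seqs[leaf_names[j]])
                mat[i, j] = mat[j, i] = d
        tree = tf_phylogeny.build_nj_tree(leaf_names, mat)
    else:
        logger.warning("single TF instance: no tree; comparative stages skipped")

    # --- stage 4: mixture motifs; stages 5-8 per species --------------------
    species_results: dict[str, SpeciesResult] = {}
    for species_id in kept_species:
        genome = genomes[species_id]
        bg = genome.mononucleotide_frequencies
        ref_pswms = {
            r.instance_id: motif_model.build_pswm(
                SiteCollection(r.instance_id, tuple(r.sites)), params.pseudocount, bg
            )
            for r in config.references
        }
        if tree is not None:
            patristic = tf_phylogeny.patristic_distances(tree, species_id)
            distances = {r.instance_id: patristic[ref_leaf[r.instance_id]]
                         for r in config.references}
        else:
            distances = {r.instance_id: 0.0 for r in config.references}
        weights = motif_model.mixture_weights(distances, target_species_id=species_id)
        mixture = motif_model.build_mixture_pswm(ref_pswms, weights)
        species_results[species_id] = _score_species(species_id, genome, mixture, params)
        logger.info("%s: %d operons after splitting", species_id,
                    len(species_results[species_id].operons))

    # --- stage 9: regulated gene set ----------------------------------------
    eligible = orthologs.regulated_gene_set(
        {
            s: [(locus, op, p) for locus, (op, p) in r.gene_info.items()]
            for s, r in species_results.items()
        },
        params.posterior_cutoff,
    )

    # --- stage 10: RBH graph and cliques ------------------------------------
    groups: list[orthologs.OrthologGroup] = []
    comparative = len(kept_species) >= 2
    if not comparative:
        logger.warning("fewer than 2 species: comparative stages skipped")
    else:
        proteomes = {
            s: {
                g.locus_tag: g.protein
                for g in species_results[s].genome.genes
                if g.protein and g.locus_tag in eligible[s]
            }
            for s in kept_species
        }
        edges = []
        for i, a in enumerate(kept_species):
            for b in kept_species[i + 1:]:
                edges.extend(
                    orthologs.reciprocal_best_hits(
                        a, proteomes[a], b, proteomes[b], backend, params.evalue_ortholog
                    )
                )
        graph = orthologs.build_rbh_graph(edges)
        groups = orthologs.detect_ortholog_groups(graph)
        groups = orthologs.attach_posteriors(
            groups, {s: r.gene_info for s, r in species_results.items()}
        )

    # --- stage 11: bootstrapped ancestral reconstruction --------------------
    ancestral_reports: list[ancestral_recon.AncestralReport] = []
    if comparative and tree is not None and groups:
        all_leaves = [t.name for t in tree.tips()]
        for gi, group in enumerate(groups):
            leaf_posteriors = {
                leaf: group.posteriors.get(leaf) if leaf in group.members else None
                for leaf in all_leaves
            }
            seed = int(np.random.SeedSequence([params.rng_seed, gi]).generate_state(1)[0]
                       % (2 ** 31))
            ancestral_reports.append(
                ancestral_recon.bootstrap_ancestral_regulation(
                    tree, group.group_id, leaf_posteriors,
                    params.bootstrap_replicates, seed,
                )
            )

    # --- stage 12: reports ---------------------------------------------------
    matrix = reporting.build_regulon_matrix(groups, kept_species)
    site_rows = [row for s in kept_species for row in species_results[s].site_rows]
    operon_rows = []
    for s in kept_species:
        r = species_results[s]
        for op in r.operons:
            iv = genome_model.promoter_interval(op, r.genome, PROMOTER_UPSTREAM,
                                                PROMOTER_DOWNSTREAM)
            operon_rows.append([
                s, op.operon_id, op.strand, ";".join(g.locus_tag for g in op.genes),
                iv[0], iv[1], iv[2], f"{r.posteriors[op.operon_id].p_regulated:.6f}",
            ])
    manifest = reporting.write_reports(
        matrix,
        site_rows,
        operon_rows,
        {s: species_results[s].mixture for s in kept_species},
        ancestral_reports,
        out_dir,
        tree_newick=tf_phylogeny.to_newick(tree) if tree is not None else "",
        figures=figures,
    )
    return PipelineResult(species_results, tree, groups, ancestral_reports, matrix, manifest)
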