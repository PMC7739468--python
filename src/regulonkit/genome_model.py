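"""Annotated genomes, directons, and intergenic-distance operon prediction.

Operons are predicted in two tiers.  First, adjacent same-strand genes within
a directon (a maximal run of same-strand genes with no intervening
opposite-strand gene) are merged when their intergenic distance falls below a
genome-adaptive threshold: the mean intergenic distance over all
within-directon adjacent pairs of that genome.  Coding density varies widely
across bacteria, so a fixed threshold transfers poorly between genomes.
Second, predicted operons are split at any internal gene whose upstream region
carries a binding site scoring above a threshold chosen so that the negative
log2 of the single-strand false-positive rate equals the motif's information
content; this rescues regulation evidence buried by over-merged operons.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from Bio import SeqIO

from .errors import InputError
from .motif_model import PSSM, _check_background
from .promoter_scoring import DEFAULT_PROMOTER_LENGTH

logger = logging.getLogger(__name__)

#: Operon-distance fallback (bp) for genomes with no within-directon pairs.
FALLBACK_OPERON_THRESHOLD = 50.0
#: Discretization step (bits) for the exact PSSM score distribution DP.
FPR_BIN_WIDTH = 0.01

_CODING_KINDS = ("CDS",)
_RNA_KINDS = ("tRNA", "rRNA", "ncRNA", "tmRNA")


@dataclass(frozen=True)
class Gene:
    locus_tag: str
    contig: str
    start: int  # 0-based, half-open
    end: int
    strand: str  # '+' or '-'
    product: str = ""
    protein: Optional[str] = None  # None for RNA genes / pseudogenes
    kind: str = "CDS"

    def __post_init__(self):
        if not self.start < self.end:
            raise InputError(f"{self.locus_tag}: start must be < end")
        if self.strand not in "+-":
            raise InputError(f"{self.locus_tag}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Contig:
    accession: str
    sequence: str
    genes: tuple[Gene, ...]  # sorted by start


@dataclass(frozen=True)
class Genome:
    species_id: str
    contigs: tuple[Contig, ...]
    mononucleotide_frequencies: np.ndarray

    @property
    def genes(self) -> list[Gene]:
        return [g for c in self.contigs for g in c.genes]

    def contig(self, accession: str) -> Contig:
        for c in self.contigs:
            if c.accession == accession:
                return c
        raise InputError(f"unknown contig {accession}")


@dataclass(frozen=True)
class Directon:
    """Maximal run of adjacent same-strand genes on one contig."""

    genes: tuple[Gene, ...]  # in coordinate order

    @property
    def strand(self) -> str:
        return self.genes[0].strand

    @property
    def contig(self) -> str:
        return self.genes[0].contig


@dataclass(frozen=True)
class Operon:
    operon_id: str
    genes: tuple[Gene, ...]  # transcription order; genes[0] owns the promoter
    promoter_region: Optional[tuple[str, int, int]] = None  # (contig, start, end)

    @property
    def strand(self) -> str:
        return self.genes[0].strand

    @property
    def first_gene(self) -> Gene:
        return self.genes[0]


def parse_genome(records, species_id: str) -> Genome:
    """Build a Genome from parsed GenBank records (or a path to a flat file).

    CDS features lacking a /translation qualifier are translated with the
    bacterial code (table 11).  Features extending beyond the contig are
    skipped with a warning.
    """
    if isinstance(records, (str, bytes)) or hasattr(records, "read"):
        records = list(SeqIO.parse(records, "genbank"))
    else:
        records = list(records)
    if not records:
        raise InputError(f"{species_id}: no GenBank records")
    contigs = []
    counts = np.zeros(4)
    for rec in records:
        try:
            seq = str(rec.seq).upper()
        except Exception as exc:  # undefined sequence (CONTIG-only record)
            raise InputError(f"{species_id}/{rec.id}: record has no sequence ({exc})")
        if not seq:
            raise InputError(f"{species_id}/{rec.id}: record has empty sequence")
        for i, b in enumerate("ACGT"):
            counts[i] += seq.count(b)
        genes = []
        for feat in rec.features:
            if feat.type not in _CODING_KINDS + _RNA_KINDS:
                continue
            start, end = int(feat.location.start), int(feat.location.end)
            if end > len(seq) or start < 0:
                logger.warning(
                    "%s/%s: feature %s beyond contig bounds, skipped", species_id, rec.id, feat
                )
                continue
            strand = "+" if feat.location.strand != -1 else "-"
            locus = feat.qualifiers.get("locus_tag", [f"{rec.id}_{start}"])[0]
            product = feat.qualifiers.get("product", [""])[0]
            protein = None
            if feat.type == "CDS" and "pseudo" not in feat.qualifiers:
                translations = feat.qualifiers.get("translation")
                if translations:
                    protein = translations[0]
                else:
                    dna = feat.extract(rec.seq)
                    protein = str(dna.translate(table=11)).rstrip("*")
            genes.append(Gene(locus, rec.id, start, end, strand, product, protein, feat.type))
        genes.sort(key=lambda g: (g.start, g.end, g.locus_tag))
        contigs.append(Contig(rec.id, seq, tuple(genes)))
    total = counts.sum()
    freqs = counts / total if total else np.full(4, 0.25)
    return Genome(species_id, tuple(contigs), freqs)


def find_directons(genome: Genome) -> list[Directon]:
    """Partition each contig's genes into maximal same-strand runs."""
    directons = []
    for contig in genome.contigs:
        run: list[Gene] = []
        for gene in contig.genes:
            if run and gene.strand != run[-1].strand:
                directons.append(Directon(tuple(run)))
                run = []
            run.append(gene)
        if run:
            directons.append(Directon(tuple(run)))
    return directons


def intergenic_distance(upstream: Gene, downstream: Gene) -> int:
    """start(downstream) - end(upstream); negative when genes overlap."""
    return downstream.start - upstream.end


def adaptive_operon_threshold(genome: Genome) -> float:
    """Mean intergenic distance over all within-directon adjacent gene pairs."""
    distances = []
    for d in find_directons(genome):
        for a, b in zip(d.genes, d.genes[1:]):
            distances.append(intergenic_distance(a, b))
    if not distances:
        logger.warning(
            "%s: no within-directon gene pairs; falling back to %.0f bp",
            genome.species_id, FALLBACK_OPERON_THRESHOLD,
        )
        return FALLBACK_OPERON_THRESHOLD
    return float(np.mean(distances))


def _number_operons(species_id: str, gene_groups: list[list[Gene]]) -> list[Operon]:
    """Assign deterministic ids by (contig, leftmost coordinate)."""
    gene_groups = sorted(gene_groups, key=lambda gs: (gs[0].contig, min(g.start for g in gs)))
    operons = []
    for i, genes in enumerate(gene_groups, start=1):
        if genes[0].strand == "-":
            genes = sorted(genes, key=lambda g: -g.start)  # transcription order
        else:
            genes = sorted(genes, key=lambda g: g.start)
        operons.append(Operon(f"{species_id}_op{i:04d}", tuple(genes)))
    return operons


def predict_operons(genome: Genome, threshold: float) -> list[Operon]:
    """Split each directon between genes whose intergenic distance exceeds the threshold.

    Pairs at exactly the threshold stay together (strict > splits).
    """
    groups: list[list[Gene]] = []
    for d in find_directons(genome):
        current = [d.genes[0]]
        for a, b in zip(d.genes, d.genes[1:]):
            if intergenic_distance(a, b) > threshold:
                groups.append(current)
                current = [b]
            else:
                current.append(b)
        groups.append(current)
    return _number_operons(genome.species_id, groups)


def promoter_interval(operon: Operon, genome: Genome,
                      upstream: int = 250, downstream: int = 50) -> tuple[str, int, int]:
    """Genomic interval of the operon's promoter: [-250, +50] around the first
    gene's translation start, truncated at the neighboring gene and contig edge."""
    g = operon.first_gene
    contig = genome.contig(g.contig)
    genes = contig.genes
    if g.strand == "+":
        start = max(0, g.start - upstream)
        for other in genes:
            if other.locus_tag != g.locus_tag and other.end <= g.start:
                start = max(start, other.end)
        end = min(len(contig.sequence), g.start + downstream)
    else:
        end = min(len(contig.sequence), g.end + upstream)
        for other in reversed(genes):
            if other.locus_tag != g.locus_tag and other.start >= g.end:
                end = min(end, other.start)
        start = max(0, g.end - downstream)
    return (g.contig, start, end)


def pssm_score_distribution(pssm: PSSM, background: np.ndarray,
                            bin_width: float = FPR_BIN_WIDTH) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of single-strand PSSM scores of i.i.d. background k-mers.

    Scores are discretized to multiples of ``bin_width`` and the distribution
    is built by dynamic programming (one convolution per motif column).
    Returns (scores, probabilities) over the support.
    """
    bg = _check_background(background)
    if not np.all(np.isfinite(pssm.scores)):
        raise InputError("PSSM has -inf scores; use a positive pseudocount")
    offsets = np.rint(pssm.scores / bin_width).astype(np.int64)  # (w, 4)
    lo = int(offsets.min(axis=1).sum())
    hi = int(offsets.max(axis=1).sum())
    dist = np.zeros(hi - lo + 1)
    # start at offset 0 relative to the running minimum
    cur_lo = 0
    dist[0] = 1.0
    cur_len = 1
    for j in range(pssm.width):
        col = offsets[j]
        cmin, cmax = int(col.min()), int(col.max())
        new_lo = cur_lo + cmin
        new_len = cur_len + (cmax - cmin)
        new = np.zeros(new_len)
        for b in range(4):
            if bg[b] == 0:
                continue
            shift = int(col[b]) - cmin
            new[shift:shift + cur_len] += bg[b] * dist[:cur_len]
        dist = new
        cur_lo, cur_len = new_lo, new_len
    scores = (np.arange(cur_lo, cur_lo + cur_len)) * bin_width
    return scores, dist


def split_score_threshold(pssm: PSSM, background: np.ndarray, ic: float,
                          bin_width: float = FPR_BIN_WIDTH) -> float:
    """Smallest score t with -log2(FPR(t)) >= IC, i.e. FPR(t) <= 2^(-IC).

    FPR(t) = P(single-strand score >= t) for a background k-mer, from the
    exact discretized score distribution.  If no attainable score reaches the
    target FPR (weak motif), the maximum attainable score is returned with a
    warning.
    """
    if ic <= 0:
        raise InputError("information content must be positive")
    scores, dist = pssm_score_distribution(pssm, background, bin_width)
    target = 2.0 ** (-ic)
    # survival function: FPR at score[i] = sum of dist[i:]
    sf = np.cumsum(dist[::-1])[::-1]
    ok = np.flatnonzero(sf <= target)
    if ok.size == 0:
        warnings.warn(
            "motif too weak: no score reaches the IC-matched FPR; "
            "returning the maximum attainable score"
        )
        return float(scores[-1])
    return float(scores[ok[0]])


def split_operons_on_sites(
    operons: list[Operon],
    per_gene_best_scores: dict[str, float],
    split_threshold: float,
    species_id: str | None = None,
) -> list[Operon]:
    """Split operons at internal genes with a high-scoring upstream site.

    Every non-first gene whose upstream region holds a single-strand score at
    or above the threshold becomes the first gene of a new operon.  Idempotent:
    first genes are never tested, so re-splitting changes nothing.  Operon ids
    are reassigned deterministically by genomic position.
    """
    if species_id is None and operons:
        species_id = operons[0].operon_id.rsplit("_op", 1)[0]
    groups: list[list[Gene]] = []
    for op in operons:
        current = [op.genes[0]]
        for gene in op.genes[1:]:
            score = per_gene_best_scores.get(gene.locus_tag, -np.inf)
            if score >= split_threshold:
                groups.append(current)
                current = [gene]
            else:
                current.append(gene)
        groups.append(current)
    return _number_operons(species_id or "genome", groups)


def average_divergent_intergenic_distance(genome: Genome) -> float:
    """Average promoter length proxy: mean intergenic distance between the
    first genes of adjacent opposing (divergently transcribed) directons;
    falls back to 250 bp when a genome has none."""
    directons = find_directons(genome)
    gaps = []
    for a, b in zip(directons, directons[1:]):
        if a.contig != b.contig:
            continue
        if a.strand == "-" and b.strand == "+":
            gap = b.genes[0].start - a.genes[-1].end
            if gap > 0:
                gaps.append(gap)
    if not gaps:
        return float(DEFAULT_PROMOTER_LENGTH)
    return float(np.mean(gaps))
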