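"""Synthetic multi-species genomes with planted regulatory structure.

The generator emits minimal but valid GenBank records — so the production
parser is exercised, never bypassed — for a clade of bacterial species that
share gene content and gene order.  Every species carries the same operon
layout; a chosen fraction of operons is regulated, and each regulated operon
receives one binding site sampled from a known planting PSWM in the
intergenic region upstream of its first gene.  Protein sequences diverge per
species from family ancestors, and each species' TF diverges from the
reference TF by a controlled amount, so ortholog detection, tree building and
ancestral reconstruction all have a known ground truth.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .errors import ConfigurationError
from .motif_model import ALPHABET, PSWM
from .promoter_scoring import reverse_complement

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# codons per amino acid under the bacterial code (table 11), fixed order
_CODONS: dict[str, list[str]] = {}
for _c1 in "TCAG":
    for _c2 in "TCAG":
        for _c3 in "TCAG":
            _codon = _c1 + _c2 + _c3
            _aa = str(Seq(_codon).translate(table=11))
            if _aa != "*":
                _CODONS.setdefault(_aa, []).append(_codon)


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic clade."""

    rng_seed: int
    n_species: int = 4
    n_genes: int = 60  # gene families per genome, incl. the TF gene
    operon_size_probs: tuple[float, ...] = (0.4, 0.3, 0.2, 0.1)  # sizes 1..k
    within_operon_gap: tuple[float, float] = (15.0, 5.0)  # mean, sd (bp)
    between_operon_gap: tuple[float, float] = (150.0, 40.0)
    motif_width: int = 16
    motif_dominant_prob: float = 0.9
    fraction_regulated: float = 0.3
    site_temperature: float = 1.0
    n_reference_sites: int = 20
    protein_length_range: tuple[int, int] = (90, 140)
    family_divergence: float = 0.08  # per-residue substitution prob per species
    tf_divergences: tuple[float, ...] | None = None  # per species; default 0.08*i
    tf_protein_length: int = 200

    def __post_init__(self):
        if self.rng_seed is None:
            raise ConfigurationError("rng_seed is mandatory")
        if self.n_species < 1 or self.n_genes < 2:
            raise ConfigurationError("need >= 1 species and >= 2 gene families")
        if abs(sum(self.operon_size_probs) - 1.0) > 1e-9:
            raise ConfigurationError("operon size probabilities must sum to 1")
        if not 0 <= self.fraction_regulated <= 1:
            raise ConfigurationError("fraction_regulated must be in [0,1]")
        if self.motif_width + 20 > 250:
            raise ConfigurationError("site width exceeds the promoter window")
        if self.between_operon_gap[0] < self.motif_width + 20:
            raise ConfigurationError(
                "between-operon gaps too short to hold a planted site"
            )

    @property
    def species_ids(self) -> list[str]:
        return [f"SP{i + 1}" for i in range(self.n_species)]

    def tf_divergence(self, species_index: int) -> float:
        if self.tf_divergences is not None:
            return self.tf_divergences[species_index]
        return 0.08 * species_index


@dataclass
class Fixture:
    spec: FixtureSpec
    records: dict[str, SeqRecord]  # species -> single-contig record
    planting_pswm: PSWM
    reference_sites: list[str]
    tf_proteins: dict[str, str]  # species -> TF protein
    truth_operons: pd.DataFrame  # species, operon_index, locus_tags, strand, regulated
    truth_sites: pd.DataFrame  # species, operon_index, first_locus, offset, sequence
    truth_gaps: pd.DataFrame  # species, kind, distance
    families: pd.DataFrame  # family x species -> locus_tag

    def genbank_text(self, species_id: str) -> str:
        buf = io.StringIO()
        SeqIO.write([self.records[species_id]], buf, "genbank")
        return buf.getvalue()

    def run_config(self, genome_paths: dict[str, str]) -> dict:
        """JSON-serializable pipeline configuration for this fixture."""
        n_operons = self.truth_operons[
            self.truth_operons.species == self.spec.species_ids[0]
        ].shape[0]
        n_regulated = int(
            self.truth_operons[
                self.truth_operons.species == self.spec.species_ids[0]
            ].regulated.sum()
        )
        ref_species = self.spec.species_ids[0]
        return {
            "tf_instances": [
                {
                    "id": f"TF_{ref_species}",
                    "species_id": ref_species,
                    "protein": self.tf_proteins[ref_species],
                    "sites": list(self.reference_sites),
                }
            ],
            "species": [
                {"species_id": s, "genome_files": [genome_paths[s]]}
                for s in self.spec.species_ids
            ],
            "parameters": {
                "rng_seed": self.spec.rng_seed,
                "reference_regulon_size": max(n_regulated, 1),
                "reference_n_operons": n_operons,
            },
        }


def sample_site(pswm: PSWM, rng: np.random.Generator, temperature: float = 1.0) -> str:
    """Draw one site from the PSWM, column-independently; temperature < 1
    sharpens the per-column distributions."""
    cols = pswm.columns ** (1.0 / temperature)
    cols = cols / cols.sum(axis=1, keepdims=True)
    return "".join(ALPHABET[rng.choice(4, p=col)] for col in cols)


def sample_functional_site(
    pswm: PSWM, rng: np.random.Generator, temperature: float = 1.0, min_z: float = -1.0
) -> str:
    """Draw a site conditioned on being functional.

    Binding sites observed in vivo are under selection: a sequence scoring far
    below the motif's typical range would not be bound.  Draws are rejected
    until the site's score is within ``min_z`` SD of the motif-model mean, i.e.
    planted sites come from the upper ~84%% of the motif's score distribution
    (its functional range) rather than its non-functional tail.
    """
    from .promoter_scoring import fit_motif_model
    from .motif_model import BASE_INDEX, pswm_to_pssm

    pssm = pswm_to_pssm(pswm)
    stats = fit_motif_model(pssm, pswm)
    floor = stats.mu_M + min_z * stats.sigma_M
    site = sample_site(pswm, rng, temperature)
    for _ in range(200):
        score = sum(pssm.scores[j, BASE_INDEX[b]] for j, b in enumerate(site))
        if score >= floor:
            break
        site = sample_site(pswm, rng, temperature)
    return site


def _informative_pswm(spec: FixtureSpec, rng: np.random.Generator) -> PSWM:
    p_dom = spec.motif_dominant_prob
    p_off = (1.0 - p_dom) / 3.0
    cols = np.full((spec.motif_width, 4), p_off)
    for j in range(spec.motif_width):
        cols[j, rng.integers(4)] = p_dom
    return PSWM(columns=cols, effective_site_count=float(spec.n_reference_sites))


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))


def _mutate_protein(protein: str, rate: float, rng: np.random.Generator) -> str:
    out = []
    for aa in protein:
        if rng.random() < rate:
            choices = AMINO_ACIDS.replace(aa, "")
            out.append(choices[rng.integers(len(choices))])
        else:
            out.append(aa)
    return "".join(out)


def _back_translate(protein: str, rng: np.random.Generator) -> str:
    codons = [_CODONS[aa][rng.integers(len(_CODONS[aa]))] for aa in protein]
    return "".join(codons) + "TAA"


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(ALPHABET[i] for i in rng.integers(0, 4, size=length))


def _draw_gap(mean_sd: tuple[float, float], rng: np.random.Generator, floor: int) -> int:
    mean, sd = mean_sd
    return int(max(floor, round(rng.normal(mean, sd))))


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Build the clade: shared operon layout, per-species sequences, planted
    sites, and full truth tables.  Byte-identical for identical seeds."""
    rng = np.random.default_rng(spec.rng_seed)
    pswm = _informative_pswm(spec, rng)
    reference_sites = [
        sample_functional_site(pswm, rng, spec.site_temperature)
        for _ in range(spec.n_reference_sites)
    ]

    # --- shared structure: operon layout over gene families -----------------
    sizes = []
    remaining = spec.n_genes
    k = len(spec.operon_size_probs)
    while remaining > 0:
        size = int(rng.choice(np.arange(1, k + 1), p=spec.operon_size_probs))
        sizes.append(min(size, remaining))
        remaining -= sizes[-1]
    n_operons = len(sizes)
    strands = [str(rng.choice(["+", "-"])) for _ in range(n_operons)]
    # Divergently transcribed adjacent operons ('-' then '+') share one
    # bidirectional promoter gap; regulation is assigned per promoter unit so
    # a planted site never sits in an unregulated promoter's scan window.
    units: list[tuple[int, ...]] = []
    i = 0
    while i < n_operons:
        if i + 1 < n_operons and strands[i] == "-" and strands[i + 1] == "+":
            units.append((i, i + 1))
            i += 2
        else:
            units.append((i,))
            i += 1
    target = int(round(spec.fraction_regulated * n_operons))
    regulated: set[int] = set()
    regulated_units: list[tuple[int, ...]] = []
    for ui in rng.permutation(len(units)):
        if len(regulated) >= target:
            break
        unit = units[int(ui)]
        regulated_units.append(unit)
        regulated.update(unit)
    regulated_units.sort()

    # --- family ancestors (family 0 is the TF) ------------------------------
    lo, hi = spec.protein_length_range
    ancestors = [_random_protein(rng, spec.tf_protein_length)] + [
        _random_protein(rng, int(rng.integers(lo, hi + 1))) for _ in range(spec.n_genes - 1)
    ]
    family_versions: dict[str, list[str]] = {}
    tf_proteins: dict[str, str] = {}
    for si, species in enumerate(spec.species_ids):
        tf_rate = spec.tf_divergence(si)
        versions = [_mutate_protein(ancestors[0], tf_rate, rng)]
        for anc in ancestors[1:]:
            versions.append(_mutate_protein(anc, spec.family_divergence, rng))
        family_versions[species] = versions
        tf_proteins[species] = versions[0]

    # --- per-species genome assembly ----------------------------------------
    records: dict[str, SeqRecord] = {}
    operon_rows, site_rows, gap_rows, family_rows = [], [], [], []
    for species in spec.species_ids:
        seq_parts: list[str] = []
        pos = 0

        def emit(s: str):
            nonlocal pos
            seq_parts.append(s)
            pos += len(s)

        emit(_random_dna(rng, 300))
        genes = []  # (locus, start, end, strand, protein, family)
        op_extent: dict[int, tuple[int, int]] = {}  # operon -> (min start, max end)
        op_first: dict[int, str] = {}
        family_idx = 0
        prev_strand = None
        for oi, (size, strand) in enumerate(zip(sizes, strands)):
            if oi > 0:
                kind = (
                    "between_operon_same_directon"
                    if strand == prev_strand
                    else "between_directon"
                )
                gap = _draw_gap(spec.between_operon_gap, rng, spec.motif_width + 20)
                gap_rows.append([species, kind, gap])
                emit(_random_dna(rng, gap))
            members = []
            op_start = pos
            for gi in range(size):
                if gi > 0:
                    gap = _draw_gap(spec.within_operon_gap, rng, 1)
                    gap_rows.append([species, "within_operon", gap])
                    emit(_random_dna(rng, gap))
                family = family_idx
                family_idx += 1
                protein = family_versions[species][family]
                dna = _back_translate(protein, rng)
                if strand == "-":
                    dna = reverse_complement(dna)
                locus = f"{species}_G{family:03d}"
                start = pos
                emit(dna)
                genes.append((locus, start, pos, strand, protein, family))
                members.append(locus)
            op_extent[oi] = (op_start, pos)
            if strand == "-":
                members = members[::-1]  # transcription order
            op_first[oi] = members[0]
            operon_rows.append(
                [species, oi, ";".join(members), strand, oi in regulated, members[0]]
            )
            prev_strand = strand
        emit(_random_dna(rng, 300))
        sequence = list("".join(seq_parts))
        contig_len = len(sequence)

        # --- plant one site per regulated promoter unit ----------------------
        occupied: list[tuple[int, int]] = []
        w = spec.motif_width
        for unit in regulated_units:
            if len(unit) == 2:
                # shared bidirectional promoter: the gap between the two operons
                gap_lo = op_extent[unit[0]][1]
                gap_hi = op_extent[unit[1]][0]
                lo_left, hi_left = gap_lo, gap_hi - w
                anchor_oi = unit[1]
                gstrand = "+"
                anchor_start = gap_hi  # '+' operon's first-gene start
            else:
                oi = unit[0]
                gstrand = strands[oi]
                if gstrand == "+":
                    anchor_start = op_extent[oi][0]
                    space = anchor_start - max(
                        [e for _s, e in op_extent.values() if e <= anchor_start], default=0
                    )
                    lo_left = anchor_start - min(250, space)
                    hi_left = anchor_start - w
                else:
                    anchor_start = op_extent[oi][1]  # '-' translation start edge
                    nxt = min(
                        [s for s, _e in op_extent.values() if s >= anchor_start],
                        default=contig_len,
                    )
                    space = nxt - anchor_start
                    lo_left = anchor_start
                    hi_left = anchor_start + min(250, space) - w
                anchor_oi = oi
            if lo_left > hi_left:
                raise ConfigurationError(
                    f"{species} operon(s) {unit}: intergenic space cannot hold a "
                    f"{w}-bp site"
                )
            for _attempt in range(50):
                left = int(rng.integers(lo_left, hi_left + 1))
                if all(left + w <= a or left >= b for a, b in occupied):
                    break
            occupied.append((left, left + w))
            site = sample_functional_site(pswm, rng, spec.site_temperature)
            planted = site if gstrand == "+" else reverse_complement(site)
            sequence[left:left + w] = list(planted)
            offset = (left - anchor_start) if gstrand == "+" else (anchor_start - left - w)
            site_rows.append(
                [species, ";".join(str(o) for o in unit), op_first[anchor_oi],
                 offset, site, left]
            )

        seq = "".join(sequence)
        features = []
        for locus, start, end, strand, protein, family in genes:
            features.append(
                SeqFeature(
                    SimpleLocation(start, end, 1 if strand == "+" else -1),
                    type="CDS",
                    qualifiers={
                        "locus_tag": [locus],
                        "product": [f"family F{family:03d} protein"],
                        "translation": [protein],
                        "transl_table": ["11"],
                    },
                )
            )
            family_rows.append([family, species, locus])
        record = SeqRecord(
            Seq(seq),
            id=f"{species}CTG1",
            name=f"{species}CTG1",
            description=f"synthetic genome of {species}",
            annotations={"molecule_type": "DNA", "date": "01-JAN-2000",
                         "topology": "linear", "data_file_division": "BCT"},
            features=features,
        )
        records[species] = record

    truth_operons = pd.DataFrame(
        operon_rows,
        columns=["species", "operon_index", "locus_tags", "strand", "regulated", "first_locus"],
    )
    truth_sites = pd.DataFrame(
        site_rows,
        columns=["species", "operon_index", "first_locus", "offset", "site", "contig_position"],
    )
    truth_gaps = pd.DataFrame(gap_rows, columns=["species", "kind", "distance"])
    families = pd.DataFrame(family_rows, columns=["family", "species", "locus_tag"])
    return Fixture(
        spec=spec,
        records=records,
        planting_pswm=pswm,
        reference_sites=reference_sites,
        tf_proteins=tf_proteins,
        truth_operons=truth_operons,
        truth_sites=truth_sites,
        truth_gaps=truth_gaps,
        families=families,
    )


def write_fixture(fixture: Fixture, out_dir: Path) -> dict:
    """Write genomes (GenBank), truth CSVs and a ready pipeline config; returns
    the config dict (also stored as config.json)."""
    import json

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for species in fixture.spec.species_ids:
        p = out_dir / f"{species}.gbk"
        p.write_text(fixture.genbank_text(species), encoding="utf-8")
        paths[species] = str(p)
    fixture.truth_operons.to_csv(out_dir / "truth_operons.csv", index=False)
    fixture.truth_sites.to_csv(out_dir / "truth_sites.csv", index=False)
    fixture.truth_gaps.to_csv(out_dir / "truth_gaps.csv", index=False)
    fixture.families.to_csv(out_dir / "truth_families.csv", index=False)
    config = fixture.run_config(paths)
    (out_dir / "config.json").write_text(json.dumps(config, indent=2), encoding="utf-8")
    return config
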