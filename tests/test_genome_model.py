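import io
import itertools

import numpy as np
import pytest
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from regulonkit.genome_model import (
    adaptive_operon_threshold,
    average_divergent_intergenic_distance,
    find_directons,
    parse_genome,
    predict_operons,
    promoter_interval,
    pssm_score_distribution,
    split_operons_on_sites,
    split_score_threshold,
)
from regulonkit.motif_model import BASE_INDEX, PSWM, build_pswm, SiteCollection, pswm_to_pssm
from regulonkit.promoter_scoring import reverse_complement

from conftest import make_genome

UNIFORM = np.full(4, 0.25)


def genbank_record(seq, features, name="TESTCTG1"):
    rec = SeqRecord(Seq(seq), id=name, name=name, description="test",
                    annotations={"molecule_type": "DNA", "date": "01-JAN-2000"})
    rec.features = features
    return rec


def cds(start, end, strand, locus, translation=None):
    quals = {"locus_tag": [locus]}
    if translation:
        quals["translation"] = [translation]
    return SeqFeature(SimpleLocation(start, end, strand), type="CDS", qualifiers=quals)


class TestParseGenome:
    def test_five_cds_in_coordinate_order(self):
        rng = np.random.default_rng(0)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=2000))
        feats = [cds(i * 300, i * 300 + 90, 1, f"g{i}", "M" * 29) for i in (3, 1, 0, 4, 2)]
        genome = parse_genome([genbank_record(seq, feats)], "SPT")
        assert [g.locus_tag for g in genome.genes] == ["g0", "g1", "g2", "g3", "g4"]

    def test_minus_strand_cds_translated_from_reverse_complement(self):
        protein = "MKLV"
        dna = "ATGAAACTGGTT" + "TAA"
        seq = "GGGG" + reverse_complement(dna) + "GGGG"
        feats = [cds(4, 4 + len(dna), -1, "gneg")]
        genome = parse_genome([genbank_record(seq, feats)], "SPT")
        assert genome.genes[0].protein == protein

    def test_two_contig_draft_keeps_directons_separate(self):
        recs = [
            genbank_record("A" * 500, [cds(10, 100, 1, "a1", "M"), cds(150, 300, 1, "a2", "M")],
                           "CTGA"),
            genbank_record("C" * 500, [cds(20, 120, 1, "b1", "M")], "CTGB"),
        ]
        genome = parse_genome(recs, "SPT")
        directons = find_directons(genome)
        assert sorted(len(d.genes) for d in directons) == [1, 2]
        assert all(len({g.contig for g in d.genes}) == 1 for d in directons)

    def test_genbank_roundtrip_through_flat_file(self):
        rng = np.random.default_rng(1)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=600))
        feats = [cds(50, 200, 1, "x1", "M" * 49), cds(250, 400, -1, "x2", "M" * 49)]
        buf = io.StringIO()
        SeqIO.write([genbank_record(seq, feats)], buf, "genbank")
        buf.seek(0)
        genome = parse_genome(buf, "SPT")
        assert [g.locus_tag for g in genome.genes] == ["x1", "x2"]
        assert genome.mononucleotide_frequencies.sum() == pytest.approx(1.0)


class TestDirectons:
    def test_strand_pattern_splits(self):
        genes = [(f"g{i}", 100 * i, 100 * i + 50, s)
                 for i, s in enumerate("++--+")]
        genome = make_genome(genes)
        assert [len(d.genes) for d in find_directons(genome)] == [2, 2, 1]

    def test_single_strand_single_directon(self):
        genome = make_genome([(f"g{i}", 100 * i, 100 * i + 50, "+") for i in range(5)])
        assert len(find_directons(genome)) == 1

    def test_alternating_strands_all_singletons(self):
        genome = make_genome([(f"g{i}", 100 * i, 100 * i + 50, "+-"[i % 2])
                              for i in range(6)])
        assert all(len(d.genes) == 1 for d in find_directons(genome))


class TestAdaptiveThreshold:
    def test_mean_of_gaps(self):
        # gaps 10, 20, 30 within one directon
        coords = [(0, 100), (110, 200), (220, 300), (330, 400)]
        genome = make_genome([(f"g{i}", s, e, "+") for i, (s, e) in enumerate(coords)])
        assert adaptive_operon_threshold(genome) == pytest.approx(20.0)

    def test_overlapping_pair_counts_negative(self):
        coords = [(0, 100), (96, 200), (204, 300)]  # gaps -4, +4
        genome = make_genome([(f"g{i}", s, e, "+") for i, (s, e) in enumerate(coords)])
        assert adaptive_operon_threshold(genome) == pytest.approx(0.0)

    def test_fallback_when_no_pairs(self):
        genome = make_genome([("g0", 0, 100, "+"), ("g1", 200, 300, "-")])
        assert adaptive_operon_threshold(genome) == 50.0


def brute_force_operons(genome, threshold):
    """Independent splitter: walk sorted genes, breaking on strand/contig
    switches and on gaps strictly above the threshold."""
    blocks = []
    for contig in genome.contigs:
        current = []
        for gene in contig.genes:
            if current and (
                gene.strand != current[-1].strand
                or gene.start - current[-1].end > threshold
            ):
                blocks.append(current)
                current = []
            current.append(gene)
        if current:
            blocks.append(current)
    return sorted(
        tuple(sorted(g.locus_tag for g in b)) for b in blocks
    )


class TestPredictOperons:
    def test_gap_pattern_splits_into_pairs(self):
        coords = [(0, 100), (105, 200), (700, 800), (805, 900)]
        genome = make_genome([(f"g{i}", s, e, "+") for i, (s, e) in enumerate(coords)])
        ops = predict_operons(genome, 50)
        assert sorted(len(o.genes) for o in ops) == [2, 2]

    def test_exact_threshold_keeps_pair_together(self):
        genome = make_genome([("g0", 0, 100, "+"), ("g1", 150, 250, "+")])
        assert len(predict_operons(genome, 50)) == 1
        assert len(predict_operons(genome, 49)) == 2

    def test_minus_strand_operon_in_transcription_order(self):
        genome = make_genome([("g0", 0, 100, "-"), ("g1", 110, 200, "-")])
        (op,) = predict_operons(genome, 50)
        assert [g.locus_tag for g in op.genes] == ["g1", "g0"]

    def test_matches_brute_force_on_random_gene_layouts(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            pos, genes = 0, []
            for i in range(int(rng.integers(3, 25))):
                pos += int(rng.integers(-20, 300))
                start = max(pos, 0)
                end = start + int(rng.integers(50, 400))
                genes.append((f"g{i:02d}", start, end, rng.choice(["+", "-"])))
                pos = end
            genome = make_genome(genes)
            threshold = float(rng.integers(0, 200))
            ops = predict_operons(genome, threshold)
            got = sorted(tuple(sorted(g.locus_tag for g in o.genes)) for o in ops)
            assert got == brute_force_operons(genome, threshold)
            # partition invariant
            all_loci = [g.locus_tag for o in ops for g in o.genes]
            assert sorted(all_loci) == sorted(g[0] for g in genes)


def enumerate_fpr(pssm, background, threshold, bin_width=0.01):
    """Exhaustive k-mer oracle with the same score discretization as the DP."""
    offsets = np.rint(pssm.scores / bin_width) * bin_width
    total = 0.0
    for kmer in itertools.product(range(4), repeat=pssm.width):
        s = sum(offsets[j, b] for j, b in enumerate(kmer))
        if s >= threshold - 1e-9:
            total += np.prod([background[b] for b in kmer])
    return total


class TestSplitScoreThreshold:
    def test_distribution_matches_enumeration(self):
        rng = np.random.default_rng(12)
        sites = tuple("".join("ACGT"[i] for i in rng.integers(0, 4, size=4))
                      for _ in range(8))
        pswm = build_pswm(SiteCollection("t", sites), 0.5, UNIFORM)
        pssm = pswm_to_pssm(pswm, UNIFORM)
        scores, probs = pssm_score_distribution(pssm, UNIFORM)
        assert probs.sum() == pytest.approx(1.0)
        # compare survival function with enumeration at every support point
        for t in scores[:: max(1, len(scores) // 20)]:
            sf = probs[scores >= t - 1e-9].sum()
            assert sf == pytest.approx(enumerate_fpr(pssm, UNIFORM, t), abs=1e-12)

    def test_threshold_satisfies_ic_rule(self, informative_pswm):
        pssm = pswm_to_pssm(informative_pswm, UNIFORM)
        from regulonkit.motif_model import information_content

        ic = information_content(informative_pswm, UNIFORM)
        t = split_score_threshold(pssm, UNIFORM, ic)
        assert enumerate_fpr(pssm, UNIFORM, t) <= 2.0 ** (-ic) + 1e-12

    def test_weak_motif_warns_and_returns_max(self):
        pswm = PSWM(np.full((4, 4), 0.25), 5.0)
        pssm = pswm_to_pssm(pswm, UNIFORM)
        with pytest.warns(UserWarning):
            t = split_score_threshold(pssm, UNIFORM, 10.0)
        assert t == pytest.approx(0.0, abs=1e-9)


class TestSplitOperons:
    def build(self):
        coords = [(0, 300), (310, 600), (610, 900), (910, 1200)]
        genome = make_genome([(f"g{i}", s, e, "+") for i, (s, e) in enumerate(coords)])
        (op,) = predict_operons(genome, 500)
        assert len(op.genes) == 4
        return genome, [op]

    def test_no_qualifying_gene_is_identity(self):
        _, ops = self.build()
        out = split_operons_on_sites(ops, {}, 10.0)
        assert [tuple(g.locus_tag for g in o.genes) for o in out] == [
            tuple(g.locus_tag for g in o.genes) for o in ops
        ]

    def test_split_at_third_gene(self):
        _, ops = self.build()
        out = split_operons_on_sites(ops, {"g2": 12.0}, 10.0)
        assert [len(o.genes) for o in out] == [2, 2]
        assert out[1].genes[0].locus_tag == "g2"

    def test_multiple_splits_and_idempotence(self):
        _, ops = self.build()
        out = split_operons_on_sites(ops, {"g1": 12.0, "g3": 12.0}, 10.0)
        assert [len(o.genes) for o in out] == [1, 2, 1]
        again = split_operons_on_sites(out, {"g1": 12.0, "g3": 12.0}, 10.0)
        assert [tuple(g.locus_tag for g in o.genes) for o in again] == [
            tuple(g.locus_tag for g in o.genes) for o in out
        ]

    def test_score_below_threshold_does_not_split(self):
        _, ops = self.build()
        out = split_operons_on_sites(ops, {"g2": 9.99}, 10.0)
        assert len(out) == 1


class TestPromoterInterval:
    def test_plus_strand_truncated_by_upstream_gene(self):
        genome = make_genome([("up", 0, 400, "+"), ("g", 500, 900, "+")], contig_len=1200)
        ops = predict_operons(genome, 99)  # gap 100 > 99: separate operons
        target = [o for o in ops if o.first_gene.locus_tag == "g"][0]
        contig, start, end = promoter_interval(target, genome)
        assert (start, end) == (400, 550)

    def test_minus_strand_window_extends_downstream_in_genome_coords(self):
        genome = make_genome([("g", 500, 900, "-"), ("down", 1300, 1500, "+")],
                             contig_len=1700)
        ops = predict_operons(genome, 50)
        target = [o for o in ops if o.first_gene.locus_tag == "g"][0]
        contig, start, end = promoter_interval(target, genome)
        assert (start, end) == (850, 1150)

    def test_contig_edge_truncation(self):
        genome = make_genome([("g", 30, 200, "+")], contig_len=300)
        (op,) = predict_operons(genome, 50)
        _, start, end = promoter_interval(op, genome)
        assert start == 0 and end == 80


def test_divergent_intergenic_average():
    genes = [("a", 0, 100, "-"), ("b", 300, 400, "+"),
             ("c", 500, 600, "-"), ("d", 700, 800, "+")]
    genome = make_genome(genes)
    # divergent gaps: 300-100=200 and 700-600=100
    assert average_divergent_intergenic_distance(genome) == pytest.approx(150.0)
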