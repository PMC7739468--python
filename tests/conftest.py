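import numpy as np
import pytest

from regulonkit.genome_model import Contig, Gene, Genome
from regulonkit.motif_model import PSWM, SiteCollection, build_pswm


@pytest.fixture
def uniform_bg():
    return np.full(4, 0.25)


def make_genome(gene_spec, species_id="SPX", contig_len=None, seq=None):
    """Build a Genome directly from (locus, start, end, strand[, protein]) tuples.

    One contig; sequence is deterministic filler unless given.
    """
    genes = []
    for item in gene_spec:
        locus, start, end, strand = item[:4]
        protein = item[4] if len(item) > 4 else "M" + "A" * 20
        genes.append(Gene(locus, f"{species_id}C1", start, end, strand, "", protein))
    length = contig_len or (max((g.end for g in genes), default=0) + 100)
    if seq is None:
        rng = np.random.default_rng(0)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
    contig = Contig(f"{species_id}C1", seq, tuple(sorted(genes, key=lambda g: g.start)))
    return Genome(species_id, (contig,), np.full(4, 0.25))


@pytest.fixture
def informative_pswm():
    """Sharp 6-column motif with consensus ACGTAC."""
    cols = []
    for base in "ACGTAC":
        col = np.full(4, 0.04)
        col["ACGT".index(base)] = 0.88
        cols.append(col)
    return PSWM(columns=np.array(cols), effective_site_count=20.0)


@pytest.fixture
def two_site_collection():
    return SiteCollection("tfA", ("ACGTAC", "ACGTAC", "ACGAAC", "TCGTAC"))


def random_pswm(rng, width, n_sites=10, pseudocount=0.5, background=None):
    bg = background if background is not None else np.full(4, 0.25)
    sites = tuple(
        "".join("ACGT"[i] for i in rng.integers(0, 4, size=width)) for _ in range(n_sites)
    )
    return build_pswm(SiteCollection("rnd", sites), pseudocount, bg)


def random_background(rng):
    v = rng.dirichlet(np.full(4, 5.0))
    return v / v.sum()
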