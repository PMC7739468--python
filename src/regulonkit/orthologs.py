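"""Ortholog groups across target species as cliques of reciprocal best hits.

Only genes sitting in an operon whose posterior probability of regulation
exceeds a user cutoff in at least one species enter the search; that keeps the
all-vs-all step proportional to the putative regulon, not the genomes.
Reciprocal best hits for every species pair form an undirected graph whose
maximal cliques are the candidate ortholog groups; genes are committed to
groups greedily by decreasing clique size with deterministic tie-breaking.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
import networkx as nx

from .errors import PipelineError
from .search import SearchBackend, best_hit

logger = logging.getLogger(__name__)

#: Default e-value cutoff for ortholog detection.
ORTHOLOG_EVALUE_CUTOFF = 1e-10

#: A vertex is a (species_id, locus_tag) pair.
Vertex = tuple[str, str]


@dataclass(frozen=True)
class OrthologGroup:
    group_id: str
    members: dict[str, str]  # species_id -> locus_tag (at most one per species)
    posteriors: dict[str, float] = field(default_factory=dict)  # species -> p_regulated
    operon_ids: dict[str, str] = field(default_factory=dict)

    @property
    def average_posterior(self) -> float:
        vals = [self.posteriors[s] for s in self.members if s in self.posteriors]
        return sum(vals) / len(vals) if vals else 0.0


def regulated_gene_set(
    species_results: dict[str, list[tuple[str, str, float]]],
    probability_cutoff: float,
) -> dict[str, set[str]]:
    """Genes eligible for ortholog search, per species.

    ``species_results`` maps species -> [(locus_tag, operon_id, p_regulated)].
    A gene qualifies when its operon posterior is strictly above the cutoff.
    """
    out: dict[str, set[str]] = {}
    for species, rows in species_results.items():
        out[species] = {locus for locus, _op, p in rows if p > probability_cutoff}
    return out


def reciprocal_best_hits(
    species_a: str,
    genes_a: dict[str, str],
    species_b: str,
    genes_b: dict[str, str],
    search_backend: SearchBackend,
    evalue_cutoff: float = ORTHOLOG_EVALUE_CUTOFF,
) -> list[tuple[Vertex, Vertex, float]]:
    """Edges (one per mutual best-hit pair) between two species' gene sets.

    Best hits maximize score; exact ties resolve to the lexicographically
    smaller locus tag, making the edge set deterministic.
    """
    if not genes_a or not genes_b:
        return []
    try:
        best_ab = {
            a: best_hit(search_backend.search(a, seq, genes_b), evalue_cutoff)
            for a, seq in genes_a.items()
        }
        best_ba = {
            b: best_hit(search_backend.search(b, seq, genes_a), evalue_cutoff)
            for b, seq in genes_b.items()
        }
    except Exception as exc:
        raise PipelineError("reciprocal_best_hits", f"{species_a} vs {species_b}: {exc}")
    edges = []
    for a, hit in sorted(best_ab.items()):
        if hit is None:
            continue
        back = best_ba.get(hit.subject_id)
        if back is not None and back.subject_id == a:
            edges.append(((species_a, a), (species_b, hit.subject_id), hit.score))
    return edges


def build_rbh_graph(edges: list[tuple[Vertex, Vertex, float]]) -> nx.Graph:
    graph = nx.Graph()
    for u, v, score in edges:
        if u[0] == v[0]:
            raise PipelineError("build_rbh_graph", f"intra-species edge {u}-{v}")
        graph.add_edge(u, v, score=score)
    return graph


def greedy_clique_partition(graph: nx.Graph, cliques: list[list[Vertex]]) -> list[list[Vertex]]:
    """Commit vertices to cliques greedily by decreasing size.

    Ties break by larger total edge score, then lexicographic member ids.
    A clique containing an already-committed vertex is skipped; leftover
    vertices become singletons.
    """

    def total_score(members: list[Vertex]) -> float:
        return sum(
            graph[u][v]["score"]
            for u, v in itertools.combinations(members, 2)
            if graph.has_edge(u, v)
        )

    ranked = sorted(
        (sorted(c) for c in cliques),
        key=lambda c: (-len(c), -total_score(c), c),
    )
    assigned: set[Vertex] = set()
    groups: list[list[Vertex]] = []
    for clique in ranked:
        if any(v in assigned for v in clique):
            continue
        groups.append(clique)
        assigned.update(clique)
    for v in sorted(set(graph.nodes) - assigned):
        groups.append([v])
    return groups


def detect_ortholog_groups(graph: nx.Graph) -> list[OrthologGroup]:
    """Ortholog groups = maximal cliques of the RBH graph, greedily assigned."""
    if graph.number_of_nodes() == 0:
        return []
    cliques = list(nx.find_cliques(graph))
    member_lists = greedy_clique_partition(graph, cliques)
    # deterministic ids: larger groups first, then lexicographic members
    member_lists.sort(key=lambda ms: (-len(ms), ms))
    groups = []
    for i, members in enumerate(member_lists, start=1):
        by_species = {species: locus for species, locus in sorted(members)}
        if len(by_species) != len(members):
            # a clique can never hold two genes of one species (no intra-species
            # edges => they would not be adjacent), but guard anyway
            raise PipelineError("detect_ortholog_groups", f"species collision in {members}")
        groups.append(OrthologGroup(group_id=f"og{i:04d}", members=by_species))
    return groups


def attach_posteriors(
    groups: list[OrthologGroup],
    species_results: dict[str, dict[str, tuple[str, float]]],
) -> list[OrthologGroup]:
    """Return groups annotated with per-species operon ids and posteriors.

    ``species_results`` maps species -> locus_tag -> (operon_id, p_regulated).
    """
    out = []
    for g in groups:
        posteriors, operon_ids = {}, {}
        for species, locus in g.members.items():
            info = species_results.get(species, {}).get(locus)
            if info is not None:
                operon_ids[species], posteriors[species] = info
        out.append(OrthologGroup(g.group_id, dict(g.members), posteriors, operon_ids))
    return out
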