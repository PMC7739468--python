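"""Phylogeny of the reference and target TF instances.

The TF tree serves two purposes downstream: its patristic distances weight
the reference motifs when building each target species' mixture PSWM, and its
topology carries the ancestral reconstruction of regulation states.  Distances
come from pairwise global protein alignments (BLOSUM62, affine gaps) with a
Poisson correction; the tree is built by neighbor joining and midpoint-rooted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .errors import InputError
from .genome_model import Genome
from .search import AlignmentSearchBackend, SearchBackend, best_hit

logger = logging.getLogger(__name__)

#: Distance assigned to pairs with no alignable overlap.
MAX_DISTANCE = 3.0
#: p-distances are capped here before Poisson correction.
_MAX_P = 1.0 - np.exp(-MAX_DISTANCE)

#: Default e-value cutoff for TF ortholog detection.
TF_EVALUE_CUTOFF = 1e-30


@dataclass(frozen=True)
class TFInstance:
    """One transcription factor protein: a reference (with known sites) or a
    target-genome ortholog."""

    instance_id: str
    species_id: str
    protein: str
    role: str  # 'reference' or 'target'

    def __post_init__(self):
        if not self.protein:
            raise InputError(f"{self.instance_id}: empty protein sequence")
        if self.role not in ("reference", "target"):
            raise InputError(f"{self.instance_id}: role must be reference|target")


def find_tf_ortholog(
    reference_tf: TFInstance,
    genome: Genome,
    search_backend: SearchBackend | None = None,
    evalue_cutoff: float = TF_EVALUE_CUTOFF,
    reference_db: dict[str, str] | None = None,
) -> Optional[TFInstance]:
    """Reciprocal best hit of a reference TF in a target genome, or None.

    The forward best significant hit in the target proteome must, searched
    back against the reference TF set, return the original reference.
    Species without a TF ortholog are dropped from the analysis upstream.
    """
    backend = search_backend or AlignmentSearchBackend()
    proteome = {g.locus_tag: g.protein for g in genome.genes if g.protein}
    if not proteome:
        return None
    fwd = best_hit(backend.search(reference_tf.instance_id, reference_tf.protein, proteome),
                   evalue_cutoff)
    if fwd is None:
        logger.warning("%s: no TF ortholog of %s above cutoff %.1e",
                       genome.species_id, reference_tf.instance_id, evalue_cutoff)
        return None
    refs = reference_db or {reference_tf.instance_id: reference_tf.protein}
    back = best_hit(backend.search(fwd.subject_id, proteome[fwd.subject_id], refs),
                    evalue_cutoff)
    if back is None or back.subject_id != reference_tf.instance_id:
        logger.warning("%s: hit %s fails reciprocality against %s",
                       genome.species_id, fwd.subject_id, reference_tf.instance_id)
        return None
    return TFInstance(
        instance_id=f"{genome.species_id}:{fwd.subject_id}",
        species_id=genome.species_id,
        protein=proteome[fwd.subject_id],
        role="target",
    )


_distance_aligner = None


def _get_distance_aligner() -> Align.PairwiseAligner:
    global _distance_aligner
    if _distance_aligner is None:
        aligner = Align.PairwiseAligner()
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -10
        aligner.extend_gap_score = -0.5
        aligner.mode = "global"
        _distance_aligner = aligner
    return _distance_aligner


def pairwise_distance(a: str, b: str) -> float:
    """Poisson-corrected distance d = -ln(1 - p) from global-alignment p-distance.

    Arguments are canonicalized by lexicographic order before aligning so the
    result is exactly symmetric; d(a, a) = 0.
    """
    if not a or not b:
        raise InputError("empty protein sequence")
    a, b = a.upper().replace("*", ""), b.upper().replace("*", "")
    if a == b:
        return 0.0
    if b < a:
        a, b = b, a
    aln = _get_distance_aligner().align(a, b)[0]
    counts = aln.counts()
    aligned = counts.identities + counts.mismatches
    if aligned == 0:
        return MAX_DISTANCE
    p = counts.mismatches / aligned
    p = min(p, _MAX_P)
    return float(-np.log(1.0 - p))


def _canonicalize(tree: TreeNode) -> TreeNode:
    """Sort children by smallest descendant leaf name and name internal nodes
    N1..Nk in postorder, so node ids are stable across runs."""

    def min_leaf(node: TreeNode) -> str:
        if node.is_tip():
            return node.name
        return min(min_leaf(c) for c in node.children)

    for node in tree.postorder():
        if not node.is_tip():
            node.children.sort(key=min_leaf)
    counter = 1
    for node in tree.postorder():
        if not node.is_tip():
            node.name = f"N{counter}"
            counter += 1
    return tree


def build_nj_tree(ids: list[str], matrix: np.ndarray) -> TreeNode:
    """Neighbor-joining tree from a symmetric distance matrix, negative branch
    lengths clamped to zero, midpoint-rooted, deterministically labeled."""
    matrix = np.asarray(matrix, dtype=float)
    n = len(ids)
    if n < 2:
        raise InputError("need at least 2 taxa to build a tree")
    if matrix.shape != (n, n) or not np.allclose(matrix, matrix.T) or np.any(np.diag(matrix) != 0):
        raise InputError("distance matrix must be symmetric with a zero diagonal")
    order = sorted(range(n), key=lambda i: ids[i])
    ids = [ids[i] for i in order]
    matrix = matrix[np.ix_(order, order)]
    if n == 2:
        half = matrix[0, 1] / 2.0
        tree = TreeNode(children=[TreeNode(name=ids[0], length=half),
                                  TreeNode(name=ids[1], length=half)])
        return _canonicalize(tree)
    dm = DistanceMatrix(matrix, ids)
    tree = nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    tree = tree.root_at_midpoint()
    for node in tree.traverse():
        if node.length is None and not node.is_root():
            node.length = 0.0
    return _canonicalize(tree)


def patristic_distances(tree: TreeNode, target_leaf: str) -> dict[str, float]:
    """Sum of branch lengths from one leaf to every leaf of the tree."""
    try:
        target = next(t for t in tree.tips() if t.name == target_leaf)
    except StopIteration:
        raise InputError(f"unknown leaf {target_leaf!r}")
    out = {}
    for tip in tree.tips():
        out[tip.name] = 0.0 if tip is target else float(target.distance(tip))
    return out


def to_newick(tree: TreeNode) -> str:
    return str(tree).strip()


def from_newick(newick: str) -> TreeNode:
    import io

    return TreeNode.read(io.StringIO(newick))
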