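"""Pluggable sequence-similarity search backend.

A backend maps a protein query against a protein database and returns ranked
hits with a raw alignment score and a significance (e-value).  The bundled
backend performs exhaustive Smith-Waterman alignment of the query against
every database sequence (BLOSUM62, affine gaps matching blastp defaults) and
converts scores to e-values with the gapped Karlin-Altschul statistics, so the
whole pipeline runs without external binaries.  A production deployment can
drop in any object satisfying the same contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

# gapped Karlin-Altschul parameters for BLOSUM62, gap open 11 / extend 1
_LAMBDA = 0.267
_K = 0.041


@dataclass(frozen=True)
class Hit:
    subject_id: str
    score: float
    evalue: float


class SearchBackend(Protocol):
    def search(self, query_id: str, query_seq: str, database: dict[str, str]) -> list[Hit]:
        """Ranked hits (best first) of the query against the database."""
        ...


def _hit_sort_key(h: Hit):
    # best score first; deterministic lexicographic tie-break
    return (-h.score, h.subject_id)


class AlignmentSearchBackend:
    """Exhaustive pairwise local alignment over the database."""

    def __init__(self, max_evalue: float = 10.0):
        self.max_evalue = max_evalue
        aligner = Align.PairwiseAligner()
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11
        aligner.extend_gap_score = -1
        aligner.mode = "local"
        self._aligner = aligner

    def _evalue(self, score: float, m: int, n: int) -> float:
        return float(_K * m * n * np.exp(-_LAMBDA * score))

    def search(self, query_id: str, query_seq: str, database: dict[str, str]) -> list[Hit]:
        hits = []
        q = query_seq.replace("*", "").upper()
        if not q:
            return []
        for subject_id, subject_seq in database.items():
            s = (subject_seq or "").replace("*", "").upper()
            if not s:
                continue
            score = float(self._aligner.score(q, s))
            ev = self._evalue(score, len(q), len(s))
            if ev <= self.max_evalue:
                hits.append(Hit(subject_id, score, ev))
        hits.sort(key=_hit_sort_key)
        return hits


def best_hit(hits: list[Hit], evalue_cutoff: float) -> Hit | None:
    """Top significant hit; ties already broken by (score, lexicographic id)."""
    for h in hits:
        if h.evalue <= evalue_cutoff:
            return h
    return None
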