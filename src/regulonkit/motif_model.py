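"""Position weight matrices for TF-binding motifs and their cross-species transfer.

A transcription factor's binding specificity is summarized by an aligned
collection of equal-width binding sites.  Column-wise base frequencies give a
position-specific weight matrix (PSWM); its log-odds transform against a genome
background composition gives the scoring matrix (PSSM, in bits) used for
promoter scanning.  When binding-site collections exist for several reference
TF instances, the motif transferred to a target species is a convex mixture of
the reference PSWMs, weighted by phylogenetic proximity of the target's TF to
each reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError, ConfigurationError, InputError

ALPHABET = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
#: Uniform mononucleotide background, the default when no genome is attached.
UNIFORM_BACKGROUND = np.full(4, 0.25)

#: Total pseudocount added per column, distributed by background composition.
DEFAULT_PSEUDOCOUNT = 0.5


def _check_background(background: np.ndarray) -> np.ndarray:
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or np.any(bg < 0) or abs(bg.sum() - 1.0) > 1e-9:
        raise InputError(f"background must be a length-4 probability vector, got {background}")
    return bg


@dataclass(frozen=True)
class SiteCollection:
    """Aligned binding sites reported for one reference TF instance."""

    tf_instance_id: str
    sites: tuple[str, ...]

    def __post_init__(self):
        sites = tuple(s.upper() for s in self.sites)
        object.__setattr__(self, "sites", sites)
        if len(sites) < 2:
            raise InputError(f"{self.tf_instance_id}: need at least 2 aligned sites, got {len(sites)}")
        widths = {len(s) for s in sites}
        if len(widths) != 1:
            raise AlignmentError(
                f"{self.tf_instance_id}: sites are ragged (widths {sorted(widths)}); align them first"
            )
        bad = set("".join(sites)) - set(ALPHABET)
        if bad:
            raise InputError(f"{self.tf_instance_id}: non-ACGT characters in sites: {sorted(bad)}")

    @property
    def width(self) -> int:
        return len(self.sites[0])


@dataclass(frozen=True)
class PSWM:
    """Per-position base probabilities of a motif.

    ``columns`` has shape (width, 4) in A,C,G,T order; every row sums to 1.
    ``effective_site_count`` tracks how many (possibly fractional, for
    mixtures) sites inform the matrix.
    """

    columns: np.ndarray
    effective_site_count: float

    def __post_init__(self):
        cols = np.asarray(self.columns, dtype=float)
        object.__setattr__(self, "columns", cols)
        if cols.ndim != 2 or cols.shape[1] != 4:
            raise InputError(f"PSWM columns must have shape (width, 4), got {cols.shape}")
        if np.any(cols < 0) or np.any(np.abs(cols.sum(axis=1) - 1.0) > 1e-9):
            raise InputError("PSWM columns must each sum to 1 with non-negative entries")
        if self.effective_site_count <= 0:
            raise InputError("effective_site_count must be positive")

    @property
    def width(self) -> int:
        return self.columns.shape[0]


@dataclass(frozen=True)
class PSSM:
    """Log-odds scoring matrix in bits: score[j, b] = log2(pswm[j, b] / background[b])."""

    scores: np.ndarray
    background: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "scores", np.asarray(self.scores, dtype=float))
        object.__setattr__(self, "background", _check_background(self.background))

    @property
    def width(self) -> int:
        return self.scores.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.scores.max(axis=1).sum())


@dataclass(frozen=True)
class MixtureWeights:
    """Normalized contribution of each reference TF instance to a target motif."""

    target_species_id: str
    weights: dict[str, float]

    def __post_init__(self):
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9 or any(w < 0 for w in self.weights.values()):
            raise InputError("mixture weights must be non-negative and sum to 1")


def build_pswm(
    sites: SiteCollection,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    background: np.ndarray = UNIFORM_BACKGROUND,
) -> PSWM:
    """Column base frequencies with a background-distributed pseudocount.

    frequency[j, b] = (count[j, b] + pseudocount * background[b]) / (n_sites + pseudocount)
    """
    if pseudocount < 0:
        raise InputError("pseudocount must be non-negative")
    bg = _check_background(background)
    n = len(sites.sites)
    counts = np.zeros((sites.width, 4))
    for site in sites.sites:
        for j, base in enumerate(site):
            counts[j, BASE_INDEX[base]] += 1
    freqs = (counts + pseudocount * bg) / (n + pseudocount)
    return PSWM(columns=freqs, effective_site_count=float(n))


def pswm_to_pssm(pswm: PSWM, background: np.ndarray = UNIFORM_BACKGROUND) -> PSSM:
    """Log2 odds of the motif versus the background composition, in bits."""
    bg = _check_background(background)
    with np.errstate(divide="ignore"):
        scores = np.log2(pswm.columns / bg)
    return PSSM(scores=scores, background=bg)


def information_content(pswm: PSWM, background: np.ndarray = UNIFORM_BACKGROUND) -> float:
    """Kullback-Leibler divergence of the motif from the background, in bits.

    IC = sum_j sum_b f_jb * log2(f_jb / bg_b), with 0 * log(0) taken as 0.
    """
    bg = _check_background(background)
    f = pswm.columns
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(f > 0, f * np.log2(f / bg), 0.0)
    return float(terms.sum())


def mixture_weights(
    distances: dict[str, float],
    epsilon: float = 0.01,
    target_species_id: str = "",
) -> MixtureWeights:
    """Inverse-patristic-distance weights for combining reference motifs.

    weight_r is proportional to 1 / (d_r + epsilon); the epsilon floor keeps a
    target that coincides with a reference (d = 0) dominant without silencing
    the other references.
    """
    finite = {r: d for r, d in distances.items() if np.isfinite(d)}
    if not finite:
        raise ConfigurationError("no reference with a finite distance to the target")
    if any(d < 0 for d in finite.values()):
        raise InputError("patristic distances must be non-negative")
    raw = {r: 1.0 / (d + epsilon) for r, d in finite.items()}
    total = sum(raw.values())
    return MixtureWeights(
        target_species_id=target_species_id,
        weights={r: w / total for r, w in raw.items()},
    )


def build_mixture_pswm(reference_pswms: dict[str, PSWM], weights: MixtureWeights) -> PSWM:
    """Convex combination of compatible (same-width) reference PSWMs."""
    missing = set(weights.weights) - set(reference_pswms)
    if missing:
        raise ConfigurationError(f"weights refer to unknown references: {sorted(missing)}")
    used = [(reference_pswms[r], w) for r, w in sorted(weights.weights.items())]
    widths = {p.width for p, _ in used}
    if len(widths) != 1:
        raise AlignmentError(
            f"reference PSWMs have incompatible widths {sorted(widths)}; pre-align the motifs"
        )
    cols = sum(w * p.columns for p, w in used)
    # Renormalize away float round-off so downstream invariants hold exactly.
    cols = cols / cols.sum(axis=1, keepdims=True)
    esc = sum(w * p.effective_site_count for p, w in used)
    return PSWM(columns=cols, effective_site_count=float(esc))


def format_jaspar_counts(tf_id: str, pswm: PSWM) -> str:
    """JASPAR-style 4-row export of the PSWM scaled by its effective site count."""
    counts = pswm.columns * pswm.effective_site_count
    lines = [f">{tf_id}"]
    for i, base in enumerate(ALPHABET):
        row = " ".join(f"{c:8.3f}" for c in counts[:, i])
        lines.append(f"{base} [{row} ]")
    return "\n".join(lines) + "\n"
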