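"""Bayesian posterior probability of regulation for promoter regions.

Each promoter window is scored on both strands and the two strand scores are
combined as log2(2^f + 2^r).  Scores in an unregulated promoter follow a
genome-wide background normal B ~ N(mu_G, sigma_G^2); in a regulated promoter
they follow the two-component mixture R ~ alpha*N(mu_M, sigma_M^2) +
(1-alpha)*N(mu_G, sigma_G^2), where the motif component N(mu_M, sigma_M^2) is
the score distribution of true sites and the mixing parameter alpha is the
prior probability that any one window of a regulated promoter is a functional
site.  The posterior for an operon's promoter, given its window scores D, is

    P(R|D) = P(D|R) P(R) / (P(D|R) P(R) + P(D|B) P(B))

with window scores treated as independent.  All likelihoods are evaluated in
log space; underflow is impossible by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import norm

from .errors import InputError, ModelError
from .motif_model import BASE_INDEX, PSSM, PSWM

#: Fallback average promoter length (bp) when a genome yields no divergent pairs.
DEFAULT_PROMOTER_LENGTH = 250

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class BackgroundModel:
    """Normal model of combined-strand PSSM scores in promoters genome-wide."""

    mu_G: float
    sigma_G: float

    def __post_init__(self):
        if not self.sigma_G > 0:
            raise ModelError(f"sigma_G must be positive, got {self.sigma_G}")


@dataclass(frozen=True)
class MotifScoreModel:
    """Normal model of single-strand PSSM scores of true binding sites."""

    mu_M: float
    sigma_M: float

    def __post_init__(self):
        if not self.sigma_M > 0:
            raise ModelError(f"sigma_M must be positive, got {self.sigma_M}")


@dataclass(frozen=True)
class PriorConfig:
    """Priors of the regulation model: mixing parameter alpha and P(R)."""

    alpha: float
    p_regulation: float

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise InputError(f"alpha must be in (0,1), got {self.alpha}")
        if not 0 <= self.p_regulation <= 1:
            raise InputError(f"P(R) must be in [0,1], got {self.p_regulation}")

    @property
    def p_background(self) -> float:
        return 1.0 - self.p_regulation


@dataclass(frozen=True)
class BestSite:
    """Maximum-scoring window of a scanned promoter region."""

    position: int  # window start, 0-based within the scanned region
    strand: str  # '+' or '-'
    sequence: str  # site sequence, read 5'->3' on its strand
    score: float  # single-strand PSSM score on that strand, bits


@dataclass(frozen=True)
class PromoterScoreVector:
    """Combined-strand scores for every unambiguous window of one promoter."""

    operon_id: str
    scores: np.ndarray  # combined scores, ambiguous windows dropped
    region: tuple[int, int]  # genomic interval scanned (half-open)
    positions: np.ndarray = None  # window starts within the region
    forward: np.ndarray = None  # single-strand forward scores
    reverse: np.ndarray = None  # single-strand reverse scores
    sequence: str = ""


@dataclass(frozen=True)
class RegulationPosterior:
    operon_id: str
    p_regulated: float
    best_site: Optional[BestSite]


def combine_strand_scores(score_forward: float, score_reverse: float) -> float:
    """Combine the two strand scores of a window: log2(2^f + 2^r).

    Commutative, >= max(f, r), and equal to x+1 when f = r = x; -inf
    (impossible window) on one strand is absorbing.
    """
    return float(np.logaddexp2(score_forward, score_reverse))


def encode_sequence(seq: str) -> np.ndarray:
    """Map ACGT to 0..3; any other character (N, gap) to -1."""
    out = np.full(len(seq), -1, dtype=np.int64)
    for i, c in enumerate(seq.upper()):
        out[i] = BASE_INDEX.get(c, -1)
    return out


def score_windows_single_strand(pssm: PSSM, seq: str) -> np.ndarray:
    """Forward-strand PSSM score of every window; NaN where a window has non-ACGT."""
    w = pssm.width
    enc = encode_sequence(seq)
    n = len(enc) - w + 1
    if n <= 0:
        return np.empty(0)
    idx = np.arange(n)[:, None] + np.arange(w)[None, :]
    wins = enc[idx]
    valid = (wins >= 0).all(axis=1)
    scores = np.full(n, np.nan)
    if valid.any():
        v = wins[valid]
        scores[valid] = pssm.scores[np.arange(w)[None, :], v].sum(axis=1)
    return scores


def scan_promoter(pssm: PSSM, region_sequence: str, operon_id: str = "",
                  region: tuple[int, int] | None = None) -> PromoterScoreVector:
    """Score every window of a promoter region on both strands and combine.

    The reverse score of a window is the forward score of its reverse
    complement, so combined scores are reported in forward-strand coordinates.
    Windows containing ambiguous bases are skipped (draft genomes have gaps).
    """
    seq = region_sequence.upper()
    w = pssm.width
    if region is None:
        region = (0, len(seq))
    fwd = score_windows_single_strand(pssm, seq)
    rev_all = score_windows_single_strand(pssm, reverse_complement(seq))
    # window i on the reverse complement corresponds to forward window n-1-i
    rev = rev_all[::-1] if rev_all.size else rev_all
    valid = ~(np.isnan(fwd) | np.isnan(rev))
    combined = np.logaddexp2(fwd[valid], rev[valid])
    return PromoterScoreVector(
        operon_id=operon_id,
        scores=combined,
        region=region,
        positions=np.flatnonzero(valid),
        forward=fwd[valid],
        reverse=rev[valid],
        sequence=seq,
    )


def best_site_of(vector: PromoterScoreVector, width: int) -> Optional[BestSite]:
    """Best single-strand site in a scanned region (strand with the higher score)."""
    if vector.scores.size == 0:
        return None
    i = int(np.argmax(vector.scores))
    pos = int(vector.positions[i])
    window = vector.sequence[pos:pos + width]
    if vector.forward[i] >= vector.reverse[i]:
        return BestSite(pos, "+", window, float(vector.forward[i]))
    return BestSite(pos, "-", reverse_complement(window), float(vector.reverse[i]))


def fit_background_model(pssm: PSSM, all_promoter_regions: list[str]) -> BackgroundModel:
    """Sample mean/SD of combined scores over all promoter windows genome-wide."""
    chunks = []
    for region in all_promoter_regions:
        v = scan_promoter(pssm, region)
        if v.scores.size:
            chunks.append(v.scores)
    if not chunks:
        raise ModelError("no scannable promoter windows to fit the background model")
    scores = np.concatenate(chunks)
    if scores.size < 2:
        raise ModelError("need at least 2 windows to fit the background model")
    mu = float(scores.mean())
    sigma = float(scores.std(ddof=1))
    if sigma == 0:
        raise ModelError("degenerate background: all windows score identically")
    return BackgroundModel(mu_G=mu, sigma_G=sigma)


def fit_motif_model(pssm: PSSM, pswm: PSWM) -> MotifScoreModel:
    """Analytic single-strand score statistics of a site drawn from the PSWM.

    Under column independence, mu_M = sum_j sum_b f_jb * score_jb and
    sigma_M^2 = sum_j (E[score_j^2] - E[score_j]^2).
    """
    f = pswm.columns
    s = pssm.scores
    # guard 0 * (-inf) for zero-probability bases under zero pseudocount
    fs = np.where(f > 0, f * np.where(np.isfinite(s), s, 0.0), 0.0)
    fs2 = np.where(f > 0, f * np.where(np.isfinite(s), s * s, 0.0), 0.0)
    col_mean = fs.sum(axis=1)
    col_var = fs2.sum(axis=1) - col_mean ** 2
    var = float(np.clip(col_var, 0.0, None).sum())
    if var == 0:
        # deterministic motif (all columns fixed): tiny positive SD keeps the
        # normal density defined
        var = 1e-12
    return MotifScoreModel(mu_M=float(col_mean.sum()), sigma_M=float(np.sqrt(var)))


def alpha_prior(sites_per_promoter: int, avg_promoter_length: int) -> float:
    """Prior probability that a window of a regulated promoter is a functional site.

    For a TF binding one site per regulated promoter and an average promoter
    of 250 bp, alpha = 1/250 = 0.004: the regulated-promoter mixture still
    draws from the background 99.6% of the time.
    """
    if sites_per_promoter <= 0:
        raise InputError("sites_per_promoter must be positive")
    if avg_promoter_length <= 0:
        raise InputError("avg_promoter_length must be positive")
    return float(np.clip(sites_per_promoter / avg_promoter_length, 1e-9, 1 - 1e-6))


def estimate_prior_from_sites(n_known_regulated_promoters: int, n_operons: int) -> float:
    """P(R) = known regulated promoters in a reference genome / total operons."""
    if n_operons <= 0:
        raise InputError("n_operons must be positive")
    if n_known_regulated_promoters <= 0:
        raise InputError("a TF with no known targets cannot seed the prior")
    return float(np.clip(n_known_regulated_promoters / n_operons, 1e-9, 1 - 1e-6))


def estimate_prior_from_ic(ic: float, n_scannable_positions: int, n_operons: int) -> float:
    """P(R) from the motif's information content.

    The expected number of sites at the motif's intrinsic false-positive rate
    is m = n_scannable_positions * 2^(-IC); P(R) = min(m / n_operons, 1-1e-6).
    """
    if ic <= 0:
        raise InputError("information content must be positive")
    if n_operons <= 0:
        raise InputError("n_operons must be positive")
    m = n_scannable_positions * 2.0 ** (-ic)
    return float(min(m / n_operons, 1 - 1e-6))


def posterior_probability(
    scores: PromoterScoreVector,
    bg: BackgroundModel,
    mm: MotifScoreModel,
    priors: PriorConfig,
) -> RegulationPosterior:
    """Posterior probability that the promoter's operon is regulated.

    log P(D|R) = sum_i logaddexp(log alpha + logN(s_i; mu_M, sigma_M),
                                 log(1-alpha) + logN(s_i; mu_G, sigma_G))
    log P(D|B) = sum_i logN(s_i; mu_G, sigma_G)
    and the posterior is formed from the log odds, so no product underflows.
    An empty scan (region shorter than the motif) falls back to the prior.
    """
    s = np.asarray(scores.scores, dtype=float)
    if np.isnan(s).any():
        raise InputError("NaN in promoter scores")
    if s.size == 0:
        return RegulationPosterior(scores.operon_id, priors.p_regulation, None)
    if priors.p_regulation == 1.0:
        return RegulationPosterior(scores.operon_id, 1.0, None)
    if priors.p_regulation == 0.0:
        return RegulationPosterior(scores.operon_id, 0.0, None)
    log_bg = norm.logpdf(s, bg.mu_G, bg.sigma_G)
    log_m = norm.logpdf(s, mm.mu_M, mm.sigma_M)
    la, l1a = np.log(priors.alpha), np.log1p(-priors.alpha)
    log_r = np.logaddexp(la + log_m, l1a + log_bg)
    log_odds = (log_r.sum() + np.log(priors.p_regulation)) - (
        log_bg.sum() + np.log(priors.p_background)
    )
    # p = 1 / (1 + exp(-log_odds)), computed stably
    p = float(np.exp(-np.logaddexp(0.0, -log_odds)))
    return RegulationPosterior(scores.operon_id, p, None)
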