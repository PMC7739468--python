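import itertools

import numpy as np
import pytest
from scipy.stats import norm

from regulonkit.errors import InputError, ModelError
from regulonkit.motif_model import BASE_INDEX, PSWM, pswm_to_pssm
from regulonkit.promoter_scoring import (
    BackgroundModel,
    MotifScoreModel,
    PriorConfig,
    PromoterScoreVector,
    alpha_prior,
    combine_strand_scores,
    estimate_prior_from_ic,
    estimate_prior_from_sites,
    fit_background_model,
    fit_motif_model,
    posterior_probability,
    reverse_complement,
    scan_promoter,
)

UNIFORM = np.full(4, 0.25)


def brute_force_scan(pssm, seq):
    """Independent per-window double-loop scoring oracle (combined strands)."""
    w = pssm.width
    out = []
    for i in range(len(seq) - w + 1):
        window = seq[i:i + w]
        if set(window) - set("ACGT"):
            continue
        f = sum(pssm.scores[j, BASE_INDEX[b]] for j, b in enumerate(window))
        rcw = reverse_complement(window)
        r = sum(pssm.scores[j, BASE_INDEX[b]] for j, b in enumerate(rcw))
        out.append(np.log2(2.0 ** f + 2.0 ** r))
    return np.array(out)


class TestCombineStrandScores:
    def test_equal_strand_scores_add_one_bit(self):
        for x in (-7.0, 0.0, 3.5, 40.0):
            assert combine_strand_scores(x, x) == pytest.approx(x + 1.0, abs=1e-12)

    def test_minus_infinity_is_absorbing(self):
        assert combine_strand_scores(3.0, -np.inf) == 3.0
        assert combine_strand_scores(-np.inf, -np.inf) == -np.inf

    def test_direct_evaluation(self):
        assert combine_strand_scores(3.0, 1.0) == pytest.approx(np.log2(10.0), abs=1e-12)

    def test_commutative_and_dominates_max(self):
        rng = np.random.default_rng(2)
        for f, r in rng.uniform(-30, 30, size=(200, 2)):
            c = combine_strand_scores(f, r)
            assert c == combine_strand_scores(r, f)
            assert c >= max(f, r)


class TestScanPromoter:
    def test_planted_consensus_scores_highest(self, informative_pswm):
        pssm = pswm_to_pssm(informative_pswm, UNIFORM)
        rng = np.random.default_rng(3)
        flank = "".join("ACGT"[i] for i in rng.integers(0, 4, size=60))
        region = flank[:27] + "ACGTAC" + flank[27:]
        v = scan_promoter(pssm, region)
        assert int(v.positions[np.argmax(v.scores)]) == 27
        assert np.allclose(v.scores, brute_force_scan(pssm, region))

    def test_palindromic_window_gains_exactly_one_bit(self):
        # ACGT columns: a perfectly palindromic motif scores both strands equally
        cols = np.array([[0.7, 0.1, 0.1, 0.1],
                         [0.1, 0.7, 0.1, 0.1],
                         [0.1, 0.1, 0.7, 0.1],
                         [0.1, 0.1, 0.1, 0.7]])
        pssm = pswm_to_pssm(PSWM(cols, 4.0), UNIFORM)
        v = scan_promoter(pssm, "ACGT")
        assert v.forward[0] == pytest.approx(v.reverse[0])
        assert v.scores[0] == pytest.approx(v.forward[0] + 1.0)

    def test_region_equal_to_width_gives_single_window(self, informative_pswm):
        pssm = pswm_to_pssm(informative_pswm, UNIFORM)
        assert scan_promoter(pssm, "ACGTAC").scores.shape == (1,)

    def test_region_shorter_than_motif_gives_empty_scan(self, informative_pswm):
        pssm = pswm_to_pssm(informative_pswm, UNIFORM)
        assert scan_promoter(pssm, "ACG").scores.size == 0

    def test_ambiguous_windows_skipped(self, informative_pswm):
        pssm = pswm_to_pssm(informative_pswm, UNIFORM)
        region = "ACGTACNNACGTACGTAC"
        v = scan_promoter(pssm, region)
        assert np.allclose(np.sort(v.scores), np.sort(brute_force_scan(pssm, region)))

    def test_strand_symmetry_of_combined_scores(self, informative_pswm):
        pssm = pswm_to_pssm(informative_pswm, UNIFORM)
        rng = np.random.default_rng(4)
        region = "".join("ACGT"[i] for i in rng.integers(0, 4, size=80))
        a = np.sort(scan_promoter(pssm, region).scores)
        b = np.sort(scan_promoter(pssm, reverse_complement(region)).scores)
        assert np.allclose(a, b)


class TestBackgroundModel:
    def test_matches_independent_scan_statistics(self, informative_pswm):
        pssm = pswm_to_pssm(informative_pswm, UNIFORM)
        rng = np.random.default_rng(5)
        regions = ["".join("ACGT"[i] for i in rng.integers(0, 4, size=120))
                   for _ in range(40)]
        model = fit_background_model(pssm, regions)
        all_scores = np.concatenate([brute_force_scan(pssm, r) for r in regions])
        assert model.mu_G == pytest.approx(float(all_scores.mean()))
        assert model.sigma_G == pytest.approx(float(all_scores.std(ddof=1)))

    def test_monte_carlo_mean_within_three_standard_errors(self, informative_pswm):
        # i.i.d. background windows: sample mean must sit near the analytic
        # expectation of the combined-score distribution (exhaustive over 4^6)
        pssm = pswm_to_pssm(informative_pswm, UNIFORM)
        scores, probs = [], []
        for kmer in itertools.product("ACGT", repeat=6):
            f = sum(pssm.scores[j, BASE_INDEX[b]] for j, b in enumerate(kmer))
            r = sum(pssm.scores[j, BASE_INDEX[b]]
                    for j, b in enumerate(reverse_complement("".join(kmer))))
            scores.append(np.log2(2.0 ** f + 2.0 ** r))
            probs.append(0.25 ** 6)
        analytic_mean = float(np.dot(scores, probs))
        analytic_var = float(np.dot(np.square(scores), probs)) - analytic_mean ** 2
        rng = np.random.default_rng(6)
        regions = ["".join("ACGT"[i] for i in rng.integers(0, 4, size=105))
                   for _ in range(100)]  # 10,000 windows
        model = fit_background_model(pssm, regions)
        se = np.sqrt(analytic_var / 10_000)
        assert abs(model.mu_G - analytic_mean) < 3 * se * 3  # windows overlap: inflate

    def test_degenerate_identical_windows_raise(self, informative_pswm):
        pssm = pswm_to_pssm(informative_pswm, UNIFORM)
        with pytest.raises(ModelError):
            fit_background_model(pssm, ["ACGTAC", "ACGTAC"])

    def test_duplicating_regions_leaves_mean_unchanged(self, informative_pswm):
        pssm = pswm_to_pssm(informative_pswm, UNIFORM)
        rng = np.random.default_rng(7)
        regions = ["".join("ACGT"[i] for i in rng.integers(0, 4, size=50))
                   for _ in range(10)]
        m1 = fit_background_model(pssm, regions)
        m2 = fit_background_model(pssm, regions * 2)
        assert m1.mu_G == pytest.approx(m2.mu_G)


class TestMotifModel:
    def test_background_motif_scores_zero_bits(self):
        pswm = PSWM(np.full((4, 4), 0.25), 5.0)
        mm = fit_motif_model(pswm_to_pssm(pswm, UNIFORM), pswm)
        assert mm.mu_M == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_column_adds_two_bits_no_variance(self):
        eps = 1e-9
        col = np.array([[1 - 3 * eps, eps, eps, eps]])
        pswm = PSWM(col, 5.0)
        mm = fit_motif_model(pswm_to_pssm(pswm, UNIFORM), pswm)
        assert mm.mu_M == pytest.approx(2.0, abs=1e-6)
        assert mm.sigma_M < 0.01

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(8)
        cols = rng.dirichlet(np.ones(4) * 2, size=3)
        pswm = PSWM(cols, 5.0)
        pssm = pswm_to_pssm(pswm, UNIFORM)
        mean = var = 0.0
        moments = []
        for kmer in itertools.product(range(4), repeat=3):
            p = np.prod([cols[j, b] for j, b in enumerate(kmer)])
            s = sum(pssm.scores[j, b] for j, b in enumerate(kmer))
            moments.append((p, s))
        mean = sum(p * s for p, s in moments)
        var = sum(p * s * s for p, s in moments) - mean ** 2
        mm = fit_motif_model(pssm, pswm)
        assert mm.mu_M == pytest.approx(mean, rel=1e-12)
        assert mm.sigma_M == pytest.approx(np.sqrt(var), rel=1e-9)

    def test_realized_site_scores_mean_matches_model(self, two_site_collection):
        # zero pseudocount: the PSWM expectation equals the empirical mean of
        # the collection's own site scores
        from regulonkit.motif_model import build_pswm

        pswm = build_pswm(two_site_collection, 0.0, UNIFORM)
        pssm = pswm_to_pssm(pswm, UNIFORM)
        realized = []
        for site in two_site_collection.sites:
            realized.append(sum(pssm.scores[j, BASE_INDEX[b]] for j, b in enumerate(site)))
        mm = fit_motif_model(pssm, pswm)
        assert mm.mu_M == pytest.approx(float(np.mean(realized)))


class TestPriors:
    def test_alpha_one_site_per_250bp(self):
        alpha = alpha_prior(1, 250)
        assert alpha == 0.004
        assert 1 - alpha == pytest.approx(0.996)

    def test_alpha_scales_linearly(self):
        assert alpha_prior(2, 250) == pytest.approx(0.008)

    def test_alpha_rejects_zero_length(self):
        with pytest.raises(InputError):
            alpha_prior(1, 0)

    def test_site_count_prior(self):
        assert estimate_prior_from_sites(40, 2000) == pytest.approx(0.02)
        assert estimate_prior_from_sites(1, 1) == pytest.approx(1 - 1e-6)
        with pytest.raises(InputError):
            estimate_prior_from_sites(0, 2000)

    def test_ic_prior(self):
        n = 1024
        assert estimate_prior_from_ic(np.log2(n), n, 50) == pytest.approx(1 / 50)
        assert estimate_prior_from_ic(10.0, 10_240, 500) == pytest.approx(0.02)
        assert estimate_prior_from_ic(200.0, 10_240, 500) < 1e-12


def direct_posterior(scores, bg, mm, priors):
    """Non-log reference implementation of the regulation posterior."""
    p_d_r = np.prod(
        priors.alpha * norm.pdf(scores, mm.mu_M, mm.sigma_M)
        + (1 - priors.alpha) * norm.pdf(scores, bg.mu_G, bg.sigma_G)
    )
    p_d_b = np.prod(norm.pdf(scores, bg.mu_G, bg.sigma_G))
    num = p_d_r * priors.p_regulation
    return num / (num + p_d_b * priors.p_background)


class TestPosterior:
    bg = BackgroundModel(0.0, 2.0)
    mm = MotifScoreModel(10.0, 2.0)

    def vector(self, scores):
        return PromoterScoreVector("op", np.asarray(scores, float), (0, 100))

    def test_alpha_to_zero_limit_recovers_prior(self):
        priors = PriorConfig(alpha=1e-12, p_regulation=0.37)
        post = posterior_probability(self.vector([0.0, 1.0, 2.0]), self.bg, self.mm, priors)
        assert post.p_regulated == pytest.approx(0.37, abs=1e-9)

    def test_certain_prior_is_certain_posterior(self):
        priors = PriorConfig(alpha=0.004, p_regulation=1.0)
        post = posterior_probability(self.vector([-5.0, 3.0]), self.bg, self.mm, priors)
        assert post.p_regulated == 1.0

    def test_matches_direct_arithmetic_on_worked_example(self):
        priors = PriorConfig(alpha=0.004, p_regulation=0.02)
        scores = np.array([0.0, 1.0, 8.0])
        post = posterior_probability(self.vector(scores), self.bg, self.mm, priors)
        expect = direct_posterior(scores, self.bg, self.mm, priors)
        assert post.p_regulated == pytest.approx(expect, rel=1e-10)

    def test_empty_scan_falls_back_to_prior(self):
        priors = PriorConfig(alpha=0.004, p_regulation=0.25)
        post = posterior_probability(self.vector([]), self.bg, self.mm, priors)
        assert post.p_regulated == 0.25

    def test_nan_scores_rejected(self):
        priors = PriorConfig(alpha=0.004, p_regulation=0.25)
        with pytest.raises(InputError):
            posterior_probability(self.vector([1.0, np.nan]), self.bg, self.mm, priors)

    def test_posterior_monotone_in_appended_score(self):
        # with mu_M > mu_G and equal SDs, the per-window likelihood ratio is
        # increasing in the score, so raising one window's score can only
        # raise the posterior
        priors = PriorConfig(alpha=0.004, p_regulation=0.1)
        rng = np.random.default_rng(9)
        base = list(rng.normal(0, 2, size=5))
        prev = -1.0
        for extra in (-5.0, 0.0, 4.0, 6.0, 8.0, 12.0):
            p = posterior_probability(
                self.vector(base + [extra]), self.bg, self.mm, priors
            ).p_regulated
            assert p >= prev - 1e-12
            prev = p

    def test_calibration_on_background_promoters(self):
        # promoters drawn from B: mean posterior stays near the prior
        priors = PriorConfig(alpha=0.004, p_regulation=0.1)
        rng = np.random.default_rng(10)
        ps = []
        for _ in range(1000):
            scores = rng.normal(self.bg.mu_G, self.bg.sigma_G, size=20)
            ps.append(posterior_probability(self.vector(scores), self.bg, self.mm,
                                            priors).p_regulated)
        assert abs(np.mean(ps) - 0.1) < 0.05
        # one planted site pushes the posterior far above the prior
        ps_reg = []
        for _ in range(200):
            scores = rng.normal(self.bg.mu_G, self.bg.sigma_G, size=20)
            scores[0] = rng.normal(self.mm.mu_M, self.mm.sigma_M)
            ps_reg.append(posterior_probability(self.vector(scores), self.bg, self.mm,
                                                priors).p_regulated)
        assert np.mean(ps_reg) > 0.5
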