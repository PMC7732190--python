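"""Likelihood engine: pruning vs enumeration, closed forms, optimization."""

import numpy as np
import pytest

import lbasim as lb
from lbasim.inference import (
    PruningEngine,
    estimate_alpha,
    log_likelihood,
    optimize_branch_lengths,
    pmsf_model,
    pmsf_profiles,
)
from lbasim.models import (
    ExchangeabilityMatrix,
    FrequencyProfile,
    GammaRates,
    ProfileMixture,
    SiteModel,
    discrete_gamma,
)
from lbasim.simulate import simulate_alignment
from oracles import brute_force_site_loglik


def _random_mixture(rng, k):
    comps = tuple(FrequencyProfile(rng.dirichlet(np.full(20, 0.5)))
                  for _ in range(k))
    w = rng.dirichlet(np.ones(k))
    return ProfileMixture(comps, w)


class TestPruningOracle:
    def test_two_leaf_closed_form(self):
        t = lb.parse_newick("(A:0.25,B:0.25);")
        model = SiteModel(ExchangeabilityMatrix.poisson(),
                          GammaRates.constant(), "single",
                          profile=FrequencyProfile.uniform())
        aln = lb.Alignment.from_sequences({"A": "A", "B": "A"})
        res = log_likelihood(t, aln, model)
        closed = np.log((1 / 20) * (1 / 20 + (19 / 20) * np.exp(-(20 / 19) * 0.5)))
        assert res.total == pytest.approx(closed, abs=1e-12)

    def test_all_gap_site_contributes_zero(self):
        t = lb.parse_newick("((A:0.2,B:0.3):0.1,(C:0.1,D:0.4):0.2);")
        model = SiteModel.lg_g(alpha=0.9)
        aln = lb.Alignment.from_sequences(
            {"A": "R-", "B": "R-", "C": "W-", "D": "W-"})
        res = log_likelihood(t, aln, model)
        assert res.per_site[1] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("newick,ex,k_comp,k_rates,seqs", [
        ("((A:0.3,B:0.7):0.15,(C:0.4,D:0.2):0.05);", "lg", 2, 3,
         {"A": "ARN", "B": "RRW", "C": "A-N", "D": "CRV"}),
        ("((A:0.5,B:0.1):0.2,C:0.3,D:0.6);", "poisson", 3, 2,
         {"A": "WY", "B": "-C", "C": "GH", "D": "IL"}),
        ("(((A:0.2,B:0.4):0.1,C:0.8):0.05,D:0.3,E:0.9);", "lg", 1, 2,
         {"A": "KM", "B": "FP", "C": "ST", "D": "K-", "E": "MV"}),
        ("((A:1.5,B:0.01):0.3,(C:0.2,D:2.0):0.1);", "poisson", 2, 1,
         {"A": "DD", "B": "EE", "C": "DD", "D": "EE"}),
    ])
    def test_matches_enumeration(self, newick, ex, k_comp, k_rates, seqs):
        rng = np.random.default_rng(abs(hash((newick, ex))) % 2**31)
        tree = lb.parse_newick(newick)
        exm = (ExchangeabilityMatrix.lg() if ex == "lg"
               else ExchangeabilityMatrix.poisson())
        gamma = (GammaRates.constant() if k_rates == 1
                 else discrete_gamma(0.7, k_rates))
        if k_comp == 1:
            model = SiteModel(exm, gamma, "single",
                              profile=FrequencyProfile(
                                  rng.dirichlet(np.ones(20))))
        else:
            model = SiteModel(exm, gamma, "mixture",
                              mixture=_random_mixture(rng, k_comp))
        aln = lb.Alignment.from_sequences(seqs)
        res = log_likelihood(tree, aln, model)
        oracle = brute_force_site_loglik(tree, aln, model)
        assert np.abs(res.per_site - oracle).max() < 1e-8

    def test_total_is_sum_of_sites(self):
        t = lb.parse_newick("((A:0.2,B:0.3):0.1,(C:0.1,D:0.4):0.2);")
        aln = lb.Alignment.from_sequences(
            {"A": "ARNDW", "B": "RRWKY", "C": "AANNV", "D": "CRVWL"})
        res = log_likelihood(t, aln, SiteModel.lg_g(alpha=0.5))
        assert res.total == pytest.approx(res.per_site.sum(), abs=1e-6)

    def test_rerooting_invariance(self, het_model):
        aln = lb.Alignment.from_sequences(
            {"A": "ARND", "B": "RRWC", "C": "AANN", "D": "CRVW"})
        t1 = lb.parse_newick("((A:0.3,B:0.7):0.2,C:0.4,D:0.2);")
        t2 = lb.parse_newick("((A:0.3,B:0.7):0.05,(C:0.4,D:0.2):0.15);")
        t3 = lb.parse_newick("((B:0.7,(C:0.4,D:0.2):0.2):0.1,A:0.2);")
        r1 = log_likelihood(t1, aln, het_model).total
        for t in (t2, t3):
            assert log_likelihood(t, aln, het_model).total == pytest.approx(
                r1, abs=1e-8)

    def test_taxon_mismatch_rejected(self):
        t = lb.parse_newick("((A:0.2,B:0.3):0.1,(C:0.1,D:0.4):0.2);")
        aln = lb.Alignment.from_sequences(
            {"A": "A", "B": "R", "C": "N", "E": "D"})
        with pytest.raises(Exception, match="differ"):
            log_likelihood(t, aln, SiteModel.lg_g())

    def test_per_site_mode_equals_single_when_profiles_identical(self):
        t = lb.parse_newick("((A:0.2,B:0.3):0.1,(C:0.1,D:0.4):0.2);")
        aln = lb.Alignment.from_sequences(
            {"A": "ARND", "B": "RRWC", "C": "AANN", "D": "CRVW"})
        prof = FrequencyProfile.lg()
        single = SiteModel.homogeneous(profile=prof, alpha=0.8)
        per_site = SiteModel.per_site(
            np.tile(prof.probabilities, (4, 1)), alpha=0.8)
        assert log_likelihood(t, aln, per_site).total == pytest.approx(
            log_likelihood(t, aln, single).total, abs=1e-8)


class TestOptimizeBranchLengths:
    def test_identical_sequences_hit_lower_bound(self):
        t = lb.parse_newick("(A:0.5,B:0.5);")
        aln = lb.Alignment.from_sequences({"A": "ARNDW" * 10,
                                           "B": "ARNDW" * 10})
        fitted, res = optimize_branch_lengths(t, aln, SiteModel.lg_g(),
                                              xatol=1e-7)
        total = sum(n.length for n in fitted.postorder()
                    if n is not fitted.root)
        # each branch is driven to the lower bound, resolved to xatol
        assert total <= 2 * (1e-8 + 1e-6)
        assert res.converged

    def test_loglik_never_decreases(self, hom_model):
        rng = np.random.default_rng(5)
        t = lb.parse_newick(
            "((A:0.4,B:0.15):0.08,(C:0.3,D:0.1):0.05,F:0.6);")
        aln, _ = simulate_alignment(t, hom_model, 300, seed=13)
        for n in t.postorder():  # distort the start badly
            if n is not t.root:
                n.length = float(rng.uniform(0.001, 3.0))
        before = log_likelihood(t, aln, hom_model).total
        for cycles in (1, 3):
            fitted, res = optimize_branch_lengths(
                t, aln, hom_model, max_cycles=cycles)
            assert res.total >= before - 1e-9

    def test_recovers_generating_lengths(self, hom_model):
        true = lb.parse_newick(
            "((A:0.4,B:0.15):0.08,(C:0.3,(D:0.1,E:0.25):0.12):0.05,F:0.6);")
        aln, _ = simulate_alignment(true, hom_model, 8000, seed=17)
        fitted, res = optimize_branch_lengths(true, aln, hom_model, tol=1e-4)
        td = {n.name: n.length for n in true.postorder() if n.is_leaf}
        fd = {n.name: n.length for n in fitted.postorder() if n.is_leaf}
        rel = [abs(fd[k] - td[k]) / td[k] for k in td]
        assert np.mean(rel) < 0.10
        assert res.converged

    def test_nonconvergence_flagged_not_raised(self, hom_model):
        t = lb.parse_newick(
            "((A:0.4,B:0.15):0.08,(C:0.3,D:0.1):0.05,F:0.6);")
        aln, _ = simulate_alignment(t, hom_model, 500, seed=19)
        for n in t.postorder():
            if n is not t.root:
                n.length = 2.0
        _, res = optimize_branch_lengths(t, aln, hom_model,
                                         tol=1e-12, max_cycles=1)
        assert not res.converged


@pytest.fixture(scope="module")
def eight_taxon_tree():
    return lb.parse_newick(
        "(((A:0.2,B:0.3):0.1,(C:0.25,D:0.15):0.1):0.05,"
        "((E:0.2,F:0.3):0.1,G:0.4):0.05,H:0.5);")


class TestEstimateAlpha:

    def test_recovers_generating_shape(self, eight_taxon_tree):
        gen = SiteModel.lg_g(alpha=0.8)
        aln, _ = simulate_alignment(eight_taxon_tree, gen, 10000, seed=23)
        alpha = estimate_alpha(eight_taxon_tree, aln, gen)
        assert 0.6 <= alpha <= 1.0

    def test_rate_homogeneous_pushes_to_upper_bound(self, eight_taxon_tree):
        gen = SiteModel.homogeneous(alpha=None)  # constant rates
        aln, _ = simulate_alignment(eight_taxon_tree, gen, 3000, seed=29)
        alpha = estimate_alpha(eight_taxon_tree, aln, SiteModel.lg_g(),
                               bounds=(0.05, 10.0))
        assert alpha > 9.0

    def test_fitted_alpha_improves_loglik(self, eight_taxon_tree):
        gen = SiteModel.lg_g(alpha=0.5)
        aln, _ = simulate_alignment(eight_taxon_tree, gen, 2000, seed=31)
        start = SiteModel.lg_g(alpha=3.0)
        alpha = estimate_alpha(eight_taxon_tree, aln, start)
        ll_start = log_likelihood(eight_taxon_tree, aln, start).total
        ll_fit = log_likelihood(eight_taxon_tree, aln,
                                start.with_alpha(alpha)).total
        assert ll_fit >= ll_start


class TestPMSF:
    def test_single_component_returns_that_profile(self):
        t = lb.parse_newick("((A:0.2,B:0.3):0.1,(C:0.1,D:0.4):0.2);")
        aln = lb.Alignment.from_sequences(
            {"A": "ARND", "B": "RRWC", "C": "AANN", "D": "CRVW"})
        mix = ProfileMixture((FrequencyProfile.lg(),), np.ones(1))
        profs = pmsf_profiles(aln, t, mix)
        assert np.allclose(profs, FrequencyProfile.lg().probabilities)

    def test_degenerate_posterior_selects_only_live_component(self):
        # component 1 puts ~all mass on A/R, component 2 on W/Y; a site of
        # all W can only come from component 2
        p1 = np.full(20, 1e-8)
        p1[0] = p1[1] = 0.5 - 9e-8
        p2 = np.full(20, 1e-8)
        p2[17] = p2[18] = 0.5 - 9e-8
        mix = ProfileMixture((FrequencyProfile(p1 / p1.sum()),
                              FrequencyProfile(p2 / p2.sum())),
                             np.array([0.5, 0.5]))
        t = lb.parse_newick("((A:0.1,B:0.1):0.05,(C:0.1,D:0.1):0.05);")
        aln = lb.Alignment.from_sequences(
            {"A": "W", "B": "W", "C": "W", "D": "W"})
        profs = pmsf_profiles(aln, t, mix)
        assert np.abs(profs[0] - mix.components[1].probabilities).max() < 1e-6

    def test_posteriors_match_direct_bayes(self):
        """Component posteriors agree with per-component likelihood Bayes."""
        rng = np.random.default_rng(37)
        mix = _random_mixture(rng, 3)
        gamma = discrete_gamma(0.9, 4)
        ex = ExchangeabilityMatrix.lg()
        t = lb.parse_newick("((A:0.3,B:0.7):0.15,(C:0.4,D:0.2):0.05);")
        aln = lb.Alignment.from_sequences(
            {"A": "ARNDW", "B": "RRWKY", "C": "AANNV", "D": "CRVWL"})
        profs = pmsf_profiles(aln, t, mix, ex, gamma)

        # direct Bayes: likelihood of each site under each single component
        comp_ll = []
        for comp in mix.components:
            m = SiteModel(ex, gamma, "single", profile=comp)
            comp_ll.append(log_likelihood(t, aln, m).per_site)
        comp_ll = np.array(comp_ll)
        post = np.asarray(mix.weights)[:, None] * np.exp(comp_ll)
        post /= post.sum(axis=0)
        expected = post.T @ mix.profile_matrix()
        expected /= expected.sum(axis=1, keepdims=True)
        assert np.abs(profs - expected).max() < 1e-10

    def test_pmsf_model_outputs_are_simplex(self, het_model):
        t = lb.backbone_preset("farris-default")
        aln, _ = simulate_alignment(t, het_model, 200, seed=41)
        model = pmsf_model(aln, t, het_model.mixture,
                           het_model.exchangeabilities, het_model.gamma)
        sp = model.site_profiles
        assert sp.shape == (200, 20)
        assert np.allclose(sp.sum(axis=1), 1.0, atol=1e-9)
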