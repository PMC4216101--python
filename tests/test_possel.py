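"""GY94 rate matrices, pruning likelihood and site-model machinery."""

import numpy as np
import pytest
from scipy import stats

from codonscan.seq_io import CodingAlignment, STANDARD_CODE
from codonscan.phylo import TreeNode, from_newick
from codonscan import possel
from codonscan.possel import (
    CodonModelParams,
    SiteModelFit,
    alignment_loglik,
    f3x4_frequencies,
    gy94_rate_matrix,
    lrt_m8_m8a,
    neb_sites,
    transition_probabilities,
)

CODONS = STANDARD_CODE.sense_codons
N = len(CODONS)


@pytest.fixture(scope="module")
def random_pi():
    rng = np.random.default_rng(1)
    pi = rng.dirichlet(np.ones(N))
    return pi


class TestRateMatrix:
    def test_rows_sum_to_zero(self, random_pi):
        Q = gy94_rate_matrix(2.0, 0.5, random_pi)
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)

    def test_mean_rate_is_one(self, random_pi):
        Q = gy94_rate_matrix(2.0, 0.5, random_pi)
        assert -np.dot(random_pi, np.diag(Q)) == pytest.approx(1.0)

    def test_detailed_balance(self, random_pi):
        Q = gy94_rate_matrix(3.0, 0.7, random_pi)
        flux = random_pi[:, None] * Q
        assert np.allclose(flux, flux.T, atol=1e-12)

    def test_omega_zero_kills_nonsynonymous_rates(self, random_pi):
        Q = gy94_rate_matrix(2.0, 0.0, random_pi, normalize=False)
        for i in range(N):
            for j in range(N):
                if i == j or Q[i, j] == 0:
                    continue
                assert STANDARD_CODE.table[CODONS[i]] == STANDARD_CODE.table[
                    CODONS[j]
                ]

    def test_multistep_exchanges_zero(self, random_pi):
        Q = gy94_rate_matrix(2.0, 0.5, random_pi)
        for i, j in [(0, 5), (10, 40)]:
            diffs = sum(x != y for x, y in zip(CODONS[i], CODONS[j]))
            if diffs > 1:
                assert Q[i, j] == 0.0


class TestTransitionProbabilities:
    def test_t_zero_is_identity(self, random_pi):
        Q = gy94_rate_matrix(2.0, 0.5, random_pi)
        P = transition_probabilities(Q, 0.0, random_pi)
        assert np.allclose(P, np.eye(N), atol=1e-12)

    @pytest.mark.parametrize("t", [0.01, 0.3, 2.0])
    def test_rows_stochastic(self, random_pi, t):
        Q = gy94_rate_matrix(2.0, 0.5, random_pi)
        P = transition_probabilities(Q, t, random_pi)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
        assert (P >= 0).all()

    def test_stationarity(self, random_pi):
        Q = gy94_rate_matrix(2.0, 0.5, random_pi)
        P = transition_probabilities(Q, 0.7, random_pi)
        assert np.allclose(random_pi @ P, random_pi, atol=1e-10)

    def test_negative_time_rejected(self, random_pi):
        Q = gy94_rate_matrix(2.0, 0.5, random_pi)
        with pytest.raises(ValueError):
            transition_probabilities(Q, -0.1, random_pi)


def _two_taxon_tree(t1: float, t2: float) -> TreeNode:
    root = TreeNode()
    root.children = [
        TreeNode(name="a", length=t1),
        TreeNode(name="b", length=t2),
    ]
    return root


class TestAlignmentLoglik:
    def test_zero_branches_identical_codons(self, random_pi):
        aln = CodingAlignment(
            taxa=["a", "b"], sequences={"a": "ATG", "b": "ATG"}, reference="a"
        )
        params = CodonModelParams(
            kappa=2.0, omega_classes=[0.5], class_weights=[1.0], pi=random_pi
        )
        lnL = alignment_loglik(aln, _two_taxon_tree(0.0, 0.0), params)
        c = list(CODONS).index("ATG")
        assert lnL == pytest.approx(np.log(random_pi[c]))

    def test_matches_brute_force_sum(self, random_pi):
        """Pruning equals the direct 61-term sum over root states."""
        aln = CodingAlignment(
            taxa=["a", "b"],
            sequences={"a": "ATGAAA", "b": "AAATTT"},
            reference="a",
        )
        params = CodonModelParams(
            kappa=2.3, omega_classes=[0.4], class_weights=[1.0], pi=random_pi
        )
        t1, t2 = 0.17, 0.42
        lnL = alignment_loglik(aln, _two_taxon_tree(t1, t2), params)
        Q = gy94_rate_matrix(2.3, 0.4, random_pi)
        P1 = transition_probabilities(Q, t1, random_pi)
        P2 = transition_probabilities(Q, t2, random_pi)
        expected = 0.0
        idx = {c: i for i, c in enumerate(CODONS)}
        for ca, cb in [("ATG", "AAA"), ("AAA", "TTT")]:
            expected += np.log(
                sum(
                    random_pi[i] * P1[i, idx[ca]] * P2[i, idx[cb]]
                    for i in range(N)
                )
            )
        assert lnL == pytest.approx(expected, abs=1e-8)

    def test_gap_codon_is_missing_data(self, random_pi):
        params = CodonModelParams(
            kappa=2.0, omega_classes=[0.5], class_weights=[1.0], pi=random_pi
        )
        tree = _two_taxon_tree(0.2, 0.3)
        aln_gap = CodingAlignment(
            taxa=["a", "b"], sequences={"a": "ATG---", "b": "AAATTT"},
            reference="a",
        )
        # site 2 reduces to the marginal over taxon b's codon, which equals
        # pi_TTT by stationarity, so lnL = lnL(site1) + log(pi_TTT)
        aln_one = CodingAlignment(
            taxa=["a", "b"], sequences={"a": "ATG", "b": "AAA"}, reference="a"
        )
        idx = list(CODONS).index("TTT")
        expected = alignment_loglik(aln_one, tree, params) + np.log(random_pi[idx])
        assert alignment_loglik(aln_gap, tree, params) == pytest.approx(
            expected, abs=1e-10
        )

    def test_reroot_invariance(self, random_pi):
        """The reversible model's likelihood is invariant to root placement."""
        params = CodonModelParams(
            kappa=2.0, omega_classes=[0.3], class_weights=[1.0], pi=random_pi
        )
        seqs = {"a": "ATGAAA", "b": "AAATTT", "c": "ATGTTT", "d": "CCCAAA"}
        aln = CodingAlignment(taxa=list(seqs), sequences=seqs, reference="a")
        t1 = from_newick("((a:0.1,b:0.2):0.05,(c:0.3,d:0.1):0.07);")
        # same unrooted tree, root slid onto the central edge's other end
        t2 = from_newick("((a:0.1,b:0.2):0.12,(c:0.3,d:0.1):0.0);")
        assert alignment_loglik(aln, t1, params) == pytest.approx(
            alignment_loglik(aln, t2, params), abs=1e-8
        )

    def test_mixture_is_weighted_average_of_class_likelihoods(self, random_pi):
        seqs = {"a": "ATGAAA", "b": "AAATTT"}
        aln = CodingAlignment(taxa=list(seqs), sequences=seqs, reference="a")
        tree = _two_taxon_tree(0.2, 0.3)
        # a mixture with equal classes at the same omega equals the point model
        point = CodonModelParams(
            kappa=2.0, omega_classes=[0.5], class_weights=[1.0], pi=random_pi
        )
        mix = CodonModelParams(
            kappa=2.0, omega_classes=[0.5, 0.5], class_weights=[0.5, 0.5],
            pi=random_pi,
        )
        assert alignment_loglik(aln, tree, mix) == pytest.approx(
            alignment_loglik(aln, tree, point), abs=1e-10
        )


class TestLRT:
    def _dummy_fit(self, model, lnL):
        params = CodonModelParams(
            kappa=2.0,
            omega_classes=[0.5, 1.0],
            class_weights=[0.9, 0.1],
            pi=np.full(N, 1.0 / N),
        )
        return SiteModelFit(model=model, params=params, lnL=lnL, tree=TreeNode())

    def test_mixture_quantile(self):
        fit8 = self._dummy_fit("M8", -1000.0 + 2.71 / 2)
        fit8a = self._dummy_fit("M8a", -1000.0)
        stat, p = lrt_m8_m8a(fit8, fit8a)
        assert stat == pytest.approx(2.71)
        assert p == pytest.approx(0.5 * stats.chi2.sf(2.71, 1), rel=1e-6)
        assert p == pytest.approx(0.05, abs=0.002)

    def test_equal_likelihood_boundary(self):
        stat, p = lrt_m8_m8a(
            self._dummy_fit("M8", -500.0), self._dummy_fit("M8a", -500.0)
        )
        assert stat == 0.0 and p == 1.0

    def test_negative_statistic_clamped(self):
        stat, p = lrt_m8_m8a(
            self._dummy_fit("M8", -500.5), self._dummy_fit("M8a", -500.0)
        )
        assert stat == 0.0 and p == 1.0

    def test_model_mismatch_rejected(self):
        with pytest.raises(ValueError):
            lrt_m8_m8a(self._dummy_fit("M8a", -1.0), self._dummy_fit("M8", -1.0))


class TestNEB:
    def _fit_with_posteriors(self, aln, params):
        engine = possel._PruningEngine(aln, _two_taxon_tree(0.2, 0.3), params.code)
        lnL, class_ll = engine.mixture_loglik(params)
        return SiteModelFit(
            model="M8", params=params, lnL=lnL, tree=TreeNode(),
            site_class_loglik=class_ll,
        )

    def test_class_posteriors_sum_to_one(self, random_pi):
        seqs = {"a": "ATGAAATTTCCC", "b": "AAAAAATTTGGG"}
        aln = CodingAlignment(taxa=list(seqs), sequences=seqs, reference="a")
        params = CodonModelParams(
            kappa=2.0, omega_classes=[0.1, 1.0, 4.0],
            class_weights=[0.6, 0.3, 0.1], pi=random_pi,
        )
        fit = self._fit_with_posteriors(aln, params)
        post = fit.site_posteriors
        assert np.allclose(post.sum(axis=0), 1.0, atol=1e-12)

    def test_site_order_permutation_equivariance(self, random_pi):
        params = CodonModelParams(
            kappa=2.0, omega_classes=[0.1, 4.0], class_weights=[0.8, 0.2],
            pi=random_pi,
        )
        seqs = {"a": "ATGAAATTTCCC", "b": "AAAAAATTTGGG"}
        aln = CodingAlignment(taxa=list(seqs), sequences=seqs, reference="a")
        perm = [2, 0, 3, 1]
        seqs_p = {
            t: "".join(s[3 * i : 3 * i + 3] for i in perm)
            for t, s in seqs.items()
        }
        aln_p = CodingAlignment(taxa=list(seqs_p), sequences=seqs_p, reference="a")
        post = self._fit_with_posteriors(aln, params).site_posteriors
        post_p = self._fit_with_posteriors(aln_p, params).site_posteriors
        assert np.allclose(post[:, perm], post_p, atol=1e-12)

    def test_identical_alignment_no_selected_sites(self, random_pi):
        seqs = {"a": "ATGAAA", "b": "ATGAAA"}
        aln = CodingAlignment(taxa=list(seqs), sequences=seqs, reference="a")
        params = CodonModelParams(
            kappa=2.0, omega_classes=[0.1, 4.0], class_weights=[0.95, 0.05],
            pi=random_pi,
        )
        fit = self._fit_with_posteriors(aln, params)
        assert neb_sites(fit, threshold=0.95) == []

    def test_m8a_fit_returns_no_sites(self, random_pi):
        params = CodonModelParams(
            kappa=2.0, omega_classes=[0.1, 1.0], class_weights=[0.9, 0.1],
            pi=random_pi,
        )
        fit = SiteModelFit(model="M8a", params=params, lnL=-1.0, tree=TreeNode())
        assert neb_sites(fit) == []


class TestF3x4:
    def test_sums_to_one_and_positive(self):
        seqs = {"a": "ATGAAATTT", "b": "ATGAAGTTC"}
        aln = CodingAlignment(taxa=list(seqs), sequences=seqs, reference="a")
        pi = f3x4_frequencies(aln)
        assert pi.sum() == pytest.approx(1.0)
        assert (pi > 0).all()
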