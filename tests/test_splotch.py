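import math
from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm, poisson

from shmseq import core_io, fixtures, splotch


class TestSizeFactors:
    def test_direct_arithmetic(self):
        s = splotch.compute_size_factors(np.array([100.0, 200.0, 300.0]))
        assert np.allclose(s, [0.5, 1.0, 1.5])

    def test_identical_totals_give_unit_factors(self):
        assert np.allclose(splotch.compute_size_factors(np.array([7.0] * 4)), 1.0)

    def test_single_spot(self):
        assert splotch.compute_size_factors(np.array([42.0])) == [1.0]

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            splotch.compute_size_factors(np.zeros(3))


def _toy_layout(coords):
    spots = [core_io.Spot(f"s{i}", _bc(i), x, y)
             for i, (x, y) in enumerate(coords)]
    return core_io.ArrayLayout(spots=spots, reserved_positions=set())


def _bc(i):
    digits = []
    for _ in range(18):
        digits.append("ACGT"[i % 4])
        i //= 4
    return "".join(digits)


class TestBuildAdjacency:
    def test_two_adjacent_spots(self):
        lay = _toy_layout([(2, 2), (2, 3)])
        W, K = splotch.build_adjacency(lay, lay.barcodes)
        assert np.array_equal(W, [[0, 1], [1, 0]])
        assert np.array_equal(np.diag(K), [1, 1])

    def test_3x3_block_neighbor_counts(self):
        coords = [(x, y) for x in (2, 3, 4) for y in (2, 3, 4)]
        lay = _toy_layout(coords)
        W, K = splotch.build_adjacency(lay, lay.barcodes)
        k = np.diag(K)
        center = coords.index((3, 3))
        corner = coords.index((2, 2))
        assert k[center] == 4
        assert k[corner] == 2

    def test_isolated_spot_allowed(self):
        lay = _toy_layout([(2, 2), (10, 10)])
        W, K = splotch.build_adjacency(lay, lay.barcodes)
        assert np.diag(K).tolist() == [0, 0]


class TestZipLogpmf:
    def test_reduces_to_poisson_at_theta_zero(self):
        lp = splotch.zip_logpmf(np.array([0]), np.array([1.0]), 0.0)
        assert np.isclose(lp[0], -1.0)
        y = np.arange(6)
        lp = splotch.zip_logpmf(y, np.full(6, 2.5), 0.0)
        assert np.allclose(lp, poisson.logpmf(y, 2.5))

    def test_zero_branch_closed_form(self):
        lp = splotch.zip_logpmf(np.array([0]), np.array([2.0]), 0.5)
        assert np.isclose(lp[0], math.log(0.5 + 0.5 * math.exp(-2.0)))
        assert np.isclose(math.exp(lp[0]), 0.56767, atol=1e-5)

    def test_theta_one_forbids_positive_counts(self):
        lp = splotch.zip_logpmf(np.array([3]), np.array([2.0]), 1.0)
        assert lp[0] == -np.inf

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            splotch.zip_logpmf(np.array([-1]), np.array([1.0]), 0.0)

    @pytest.mark.parametrize("rate,theta", [(0.5, 0.0), (2.0, 0.3),
                                            (10.0, 0.8)])
    def test_normalizes_over_support(self, rate, theta):
        y = np.arange(1001)
        total = np.exp(splotch.zip_logpmf(y, np.full(1001, rate), theta)).sum()
        assert np.isclose(total, 1.0, atol=1e-12)


class TestCarPrecision:
    def test_2x2_arithmetic(self):
        K = np.diag([1.0, 1.0])
        W = np.array([[0.0, 1.0], [1.0, 0.0]])
        Q = splotch.car_precision(K, W, alpha=0.5, tau=1.0)
        assert np.allclose(Q, [[1.0, -0.5], [-0.5, 1.0]])
        assert np.isclose(np.linalg.det(Q), 0.75)

    def test_alpha_to_zero_limit_is_independent_spots(self):
        K = np.diag([2.0, 3.0, 1.0])
        W = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        Q = splotch.car_precision(K, W, alpha=1e-12, tau=2.0)
        assert np.allclose(Q, 2.0 * K, atol=1e-9)

    @pytest.mark.parametrize("alpha", [0.05, 0.5, 0.95, 0.999])
    def test_positive_definite_on_grid(self, alpha):
        coords = [(x, y) for x in range(2, 7) for y in range(2, 7)]
        lay = _toy_layout(coords)
        W, K = splotch.build_adjacency(lay, lay.barcodes)
        Q = splotch.car_precision(K, W, alpha=alpha, tau=1.3)
        assert np.linalg.eigvalsh(Q).min() > 0

    def test_asymmetric_adjacency_rejected(self):
        with pytest.raises(ValueError):
            splotch.car_precision(np.eye(2), np.array([[0, 1], [0, 0]]),
                                  0.5, 1.0)


def _two_condition_input(layout, n_spots=75, seed=3, n_genes=1, theta=0.1,
                         beta_fn=None):
    sections = [("s0", "SPF", "a0"), ("s1", "SPF", "a1"),
                ("s2", "GF", "b0"), ("s3", "GF", "b1")]
    ann = fixtures.make_annotations(layout, mrois=("BASE", "MID", "PE"),
                                    sections=sections,
                                    max_spots_per_section=n_spots, seed=seed)
    taxa = [f"t{i}" for i in range(n_genes)]
    beta = {}
    for _, cond, animal in sections:
        for m in ("BASE", "MID", "PE"):
            if beta_fn is None:
                val = np.full(n_genes, 0.5)
            else:
                val = beta_fn(cond, m, n_genes)
            beta[(cond, animal, m)] = val
    params = fixtures.SpatialModelParams(
        taxa=taxa, beta=beta, theta=np.full(n_genes, theta),
        alpha=0.8, tau=10.0, sigma=0.25,
    )
    tissue = fixtures.make_spatial_dataset(
        layout, ann, params, seed=seed,
        size_factors={s: np.full(n_spots, 1.5) for s, _, _ in sections})
    inp = splotch.build_splotch_input(tissue.counts, ann, layout,
                                      size_factors=tissue.size_factors)
    return inp, params


class TestPosterior:
    def test_gradient_matches_finite_differences(self, layout):
        inp, _ = _two_condition_input(layout, n_spots=40)
        post = splotch._Posterior(inp, inp.counts[0])
        rng = np.random.default_rng(0)
        q = post.initial(rng)
        _, g = post.logp_grad(q)
        idxs = list(rng.integers(0, post.dim, size=25))
        idxs += [post.i_usige, post.i_t, post.i_a, post.i_v, post.i_usig2]
        for idx in idxs:
            e = 1e-5
            qp, qm = q.copy(), q.copy()
            qp[idx] += e
            qm[idx] -= e
            num = (post.logp_grad(qp)[0] - post.logp_grad(qm)[0]) / (2 * e)
            assert abs(num - g[idx]) <= 1e-4 * max(1.0, abs(num) + abs(g[idx]))

    def test_one_level_model_without_animal_replication(self, layout):
        ann = fixtures.make_annotations(layout, mrois=("BASE", "PE"),
                                        sections=(("s0", "ASF", "a0"),),
                                        max_spots_per_section=40, seed=0)
        beta = {("ASF", "a0", m): np.array([0.5]) for m in ("BASE", "PE")}
        params = fixtures.SpatialModelParams(taxa=["t0"], beta=beta,
                                             theta=np.array([0.0]))
        tissue = fixtures.make_spatial_dataset(layout, ann, params, seed=0)
        inp = splotch.build_splotch_input(tissue.counts, ann, layout)
        assert not inp.two_level
        fit = splotch.fit(inp, "t0", chains=2, iterations=100, warmup=50,
                          seed=0)
        assert fit.beta_l2 is None


class TestFit:
    def test_fixed_seed_is_bitwise_reproducible(self, layout):
        inp, _ = _two_condition_input(layout, n_spots=30)
        a = splotch.fit(inp, "t0", chains=2, iterations=80, warmup=40, seed=11)
        b = splotch.fit(inp, "t0", chains=2, iterations=80, warmup=40, seed=11)
        assert np.array_equal(a.beta_l1, b.beta_l1)
        assert np.array_equal(a.psi, b.psi)

    def test_theta_recovered_near_zero_without_zeros(self, layout):
        # large rates, no dropout: almost no zeros in the data
        inp, _ = _two_condition_input(
            layout, n_spots=50, theta=0.0,
            beta_fn=lambda c, m, n: np.full(n, 2.5))
        assert (inp.counts[0] == 0).mean() < 0.02
        fit = splotch.fit(inp, "t0", seed=1)
        assert np.quantile(fit.theta, 0.9) < 0.1

    def test_rate_draws_positive_and_shaped(self, layout):
        inp, _ = _two_condition_input(layout, n_spots=30)
        fit = splotch.fit(inp, "t0", chains=2, iterations=80, warmup=40,
                          seed=2)
        lam = fit.rate()
        assert lam.shape == (fit.n_draws, inp.n_spots)
        assert (lam > 0).all()

    def test_poisson_glm_limit_matches_stratified_means(self, layout):
        # psi and eps variance driven to ~0, theta = 0: the model reduces to
        # a Poisson GLM whose exp(beta) is the MROI-stratified mean of y/s
        mrois = ("BASE", "MID", "PE")
        ann = fixtures.make_annotations(layout, mrois=mrois,
                                        sections=(("s0", "SPF", "a0"),),
                                        max_spots_per_section=500, seed=5)
        truth = {"BASE": math.log(3.0), "MID": math.log(1.2),
                 "PE": math.log(6.0)}
        beta = {("SPF", "a0", m): np.array([truth[m]]) for m in mrois}
        params = fixtures.SpatialModelParams(
            taxa=["t0"], beta=beta, theta=np.array([0.0]),
            alpha=0.5, tau=1e8, sigma=0.0,
        )
        tissue = fixtures.make_spatial_dataset(layout, ann, params, seed=6)
        inp = splotch.build_splotch_input(tissue.counts, ann, layout)
        fit = splotch.fit(inp, "t0", seed=3)
        y = inp.counts[0]
        for m, mroi in enumerate(inp.mrois):
            sel = inp.spot_mroi == m
            stratified = (y[sel] / inp.size_factors[sel]).mean()
            post_mean = np.exp(fit.beta_l1[:, 0, m]).mean()
            assert abs(post_mean - stratified) / stratified < 0.05


def _fake_fit(delta_mean, delta_sd, n=400):
    """A minimal fit whose (A - B) level-1 contrast has exact mean and sd."""
    rng = np.random.default_rng(0)
    z = rng.standard_normal(n)
    z = (z - z.mean()) / z.std(ddof=1)
    draws = delta_mean + delta_sd * z
    beta = np.zeros((n, 1, 2))
    beta[:, 0, 0] = draws
    inp = SimpleNamespace(l1_groups=["SPF"], mrois=["A", "B"])
    return SimpleNamespace(taxon="t", input=inp, beta_l1=beta)


class TestSavageDickey:
    def test_closed_form_normal_ratio(self):
        fit = _fake_fit(1.0, 0.5)
        res = splotch.savage_dickey_bf(fit, ("SPF", "A"), ("SPF", "B"))
        prior = 1.0 / math.sqrt(16.0 * math.pi)
        post = norm.pdf(0.0, loc=1.0, scale=0.5)
        assert abs(res.bf - prior / post) < 1e-6
        assert abs(res.bf - 1.30621) < 1e-4
        assert abs(res.log10_bf - 0.11602) < 1e-4
        assert res.direction == 1

    def test_bf_is_one_when_posterior_equals_prior(self):
        fit = _fake_fit(0.0, math.sqrt(8.0))
        res = splotch.savage_dickey_bf(fit, ("SPF", "A"), ("SPF", "B"))
        assert abs(res.bf - 1.0) < 1e-6

    def test_far_posterior_is_de_positive(self):
        fit = _fake_fit(3.0, 0.3)
        res = splotch.savage_dickey_bf(fit, ("SPF", "A"), ("SPF", "B"))
        assert res.log10_bf > 0.5 and res.direction == 1

    def test_zero_sd_reports_infinity(self):
        fit = _fake_fit(1.0, 0.0)
        res = splotch.savage_dickey_bf(fit, ("SPF", "A"), ("SPF", "B"))
        assert math.isinf(res.bf) and res.infinite

    def test_kde_density_option(self):
        fit = _fake_fit(1.0, 0.5)
        res = splotch.savage_dickey_bf(fit, ("SPF", "A"), ("SPF", "B"),
                                       method="kde")
        assert 0.5 < res.bf < 3.0  # same order as the normal approximation

    def test_identical_cells_rejected(self):
        fit = _fake_fit(1.0, 0.5)
        with pytest.raises(ValueError):
            splotch.savage_dickey_bf(fit, ("SPF", "A"), ("SPF", "A"))


class TestCallDe:
    def test_negative_direction_never_flagged(self):
        res = splotch.savage_dickey_bf(_fake_fit(-3.0, 0.3),
                                       ("SPF", "A"), ("SPF", "B"))
        table = splotch.call_de([res])
        assert not table.iloc[0]["significant"]

    def test_threshold_is_strict(self):
        res = splotch.savage_dickey_bf(_fake_fit(1.0, 0.5),
                                       ("SPF", "A"), ("SPF", "B"))
        res.log10_bf = 0.5
        table = splotch.call_de([res])
        assert not table.iloc[0]["significant"]

    def test_strong_positive_flagged(self):
        res = splotch.savage_dickey_bf(_fake_fit(3.0, 0.3),
                                       ("SPF", "A"), ("SPF", "B"))
        assert splotch.call_de([res]).iloc[0]["significant"]


class TestDetectTaxa:
    @staticmethod
    def _tables(spf_mean, share):
        spf = pd.DataFrame({"R1": [spf_mean], "R2": [0.1]}, index=["tx"])
        gf = pd.DataFrame({"R1": [2.0], "R2": [1.0]}, index=["tx"])
        counts = pd.DataFrame(
            {"R1": [share * 1000], "R2": [(1 - share) * 1000]}, index=["tx"])
        return spf, gf, counts

    def test_detected_when_above_gf_and_share(self):
        spf, gf, counts = self._tables(spf_mean=5.0, share=0.10)
        assert splotch.detect_taxa(spf, gf, counts) == [("tx", "R1")]

    def test_small_share_blocks_detection(self):
        spf, gf, counts = self._tables(spf_mean=5.0, share=0.01)
        assert splotch.detect_taxa(spf, gf, counts) == []

    def test_below_gf_max_not_detected(self):
        spf, gf, counts = self._tables(spf_mean=1.0, share=0.10)
        assert splotch.detect_taxa(spf, gf, counts) == []

    def test_taxon_absent_from_gf_uses_zero(self):
        spf = pd.DataFrame({"R1": [0.5]}, index=["only_spf"])
        gf = pd.DataFrame({"R1": [2.0]}, index=["other"])
        counts = pd.DataFrame({"R1": [100]}, index=["only_spf"])
        assert splotch.detect_taxa(spf, gf, counts) == [("only_spf", "R1")]
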