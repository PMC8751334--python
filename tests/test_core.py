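import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phiclust.config import RunConfig
from phiclust.core import (
    correct_singular_values,
    estimate_uncertainty,
    gamma_from_theta,
    phi_cell,
    phi_gene,
    phi_mult,
    phiclust_from_matrix,
    regress_confounders,
    theta_additive,
    theta_multiplicative,
    variance_driving_genes,
)
from phiclust.core import _components_from_svd
from phiclust.rmt import mp_model, scaled_svd
from phiclust.simulate import PlantedSpec, planted_rank_one

C_DEFAULT = 201 / 350


class TestThetaGammaMaps:
    @pytest.mark.parametrize("c", [0.05, 0.25, 0.5743, 0.9, 1.0])
    def test_round_trip_identity_grid(self, c):
        thetas = np.geomspace(c**0.25 * 1.01, 50.0, 40)
        for t in thetas:
            assert theta_additive(gamma_from_theta(t, c), c) == pytest.approx(t, abs=1e-10, rel=1e-10)

    def test_forward_example_theta_two(self):
        # theta = 2 at c = 201/350: gamma^2 = (5 * (4 + c)) / 4
        gamma = np.sqrt(5 * (4 + C_DEFAULT) / 4)
        assert gamma == pytest.approx(2.391204, abs=1e-6)
        assert theta_additive(gamma, C_DEFAULT) == pytest.approx(2.0, abs=1e-9)

    def test_bulk_gamma_rejected(self):
        with pytest.raises(ValueError, match="bulk"):
            theta_additive(1.0, 0.5)

    def test_edge_limit_approaches_bbp_threshold(self):
        c = 0.4
        gamma = (1 + np.sqrt(c)) * (1 + 1e-9)
        assert theta_additive(gamma, c) == pytest.approx(c**0.25, abs=1e-3)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        theta=st.floats(min_value=1.2, max_value=40.0),
        c=st.floats(min_value=0.05, max_value=1.0),
    )
    def test_round_trip_property(self, theta, c):
        if theta <= c**0.25 * 1.01:
            theta = c**0.25 * 1.05
        assert theta_additive(gamma_from_theta(theta, c), c) == pytest.approx(theta, rel=1e-9)


class TestPhiFormulas:
    @pytest.mark.parametrize("c", [0.1, 0.5, 1.0])
    def test_algebraic_zero_at_detection_threshold(self, c):
        assert phi_cell(c**0.25, c) == pytest.approx(0.0, abs=1e-12)
        assert phi_gene(c**0.25, c) == pytest.approx(0.0, abs=1e-12)

    def test_limits_to_one_for_strong_signal(self):
        assert phi_cell(1e4, 0.5) == pytest.approx(1.0, abs=1e-6)
        assert phi_gene(1e4, 0.5) == pytest.approx(1.0, abs=1e-6)

    def test_reference_values_at_theta_two(self):
        assert phi_cell(2.0, C_DEFAULT) == pytest.approx(0.8431, abs=1e-4)
        assert phi_gene(2.0, C_DEFAULT) == pytest.approx(0.7713, abs=1e-4)

    def test_sub_threshold_returns_zero(self):
        assert phi_cell(0.1, 0.5) == 0.0
        assert phi_gene(0.1, 0.5) == 0.0

    @pytest.mark.parametrize("c", [0.1, 0.5743, 1.0])
    def test_monotone_increasing_in_theta(self, c):
        thetas = np.linspace(c**0.25 * 1.01, 20, 200)
        pc = [phi_cell(t, c) for t in thetas]
        pg = [phi_gene(t, c) for t in thetas]
        assert np.all(np.diff(pc) > 0)
        assert np.all(np.diff(pg) > 0)


class TestMultiplicative:
    def test_printed_example_square_case(self):
        # c = 1, lambda = 9: theta = 2 / (7 - sqrt(45)), phi = 0.4271
        theta = theta_multiplicative(9.0, 1.0)
        assert theta == pytest.approx(2 / (7 - np.sqrt(45)), rel=1e-12)
        assert theta == pytest.approx(6.8541, abs=1e-4)
        assert phi_mult(theta, 1.0) == pytest.approx(0.4271, abs=1e-4)

    def test_zero_at_threshold(self):
        assert phi_mult(np.sqrt(0.3), 0.3) == 0.0

    def test_edge_rejected(self):
        c = 0.5
        with pytest.raises(ValueError, match="bulk"):
            theta_multiplicative((1 + np.sqrt(c)) ** 2, c)

    def test_theta_approaches_lambda_for_strong_signal(self):
        assert theta_multiplicative(1e4, 0.5) == pytest.approx(1e4, rel=0.01)

    def test_saturates_below_one(self):
        c = 0.5
        assert phi_mult(1e6, c) == pytest.approx(1 / (c + 1), rel=1e-4)


class TestConfounderRegression:
    def _svd(self, seed=0):
        ds = planted_rank_one(PlantedSpec(theta=5.0, seed=seed))
        return scaled_svd(ds.matrix)

    def test_self_covariate_gives_r2_one(self):
        svd = self._svd()
        cov = pd.DataFrame({"self": svd.V[:, 0]})
        out = regress_confounders(svd, cov, [0])
        assert out[0][0] == pytest.approx(1.0, abs=1e-10)

    def test_independent_covariate_near_zero(self):
        rng = np.random.default_rng(0)
        vals = []
        for s in range(10):
            svd = self._svd(seed=s)
            cov = pd.DataFrame({"junk": rng.standard_normal(svd.n_cells)})
            vals.append(regress_confounders(svd, cov, [0])[0][0])
        assert abs(np.mean(vals)) < 0.02

    def test_no_covariates_identity(self):
        svd = self._svd()
        out = regress_confounders(svd, None, [0, 1])
        assert out == {0: (0.0, {}), 1: (0.0, {})}

    def test_constant_covariate_dropped_with_warning(self):
        svd = self._svd()
        cov = pd.DataFrame({"const": np.ones(svd.n_cells)})
        with pytest.warns(UserWarning, match="constant"):
            out = regress_confounders(svd, cov, [0])
        assert out[0][0] == 0.0

    def test_per_covariate_breakdown_bounded_by_joint(self):
        svd = self._svd()
        rng = np.random.default_rng(1)
        v = svd.V[:, 0]
        cov = pd.DataFrame({
            "half_signal": v + rng.standard_normal(v.size),
            "junk": rng.standard_normal(v.size),
        })
        adj, per = regress_confounders(svd, cov, [0])[0]
        assert 0 < per["half_signal"] < 1
        assert per["junk"] < 0.05
        assert adj >= per["half_signal"] - 0.05


class TestCorrection:
    def test_identity_and_full_removal(self):
        assert correct_singular_values(2.0, 0.0) == 2.0
        assert correct_singular_values(2.0, 1.0) == 0.0

    def test_hand_arithmetic(self):
        assert correct_singular_values(2.0, 0.36) == pytest.approx(1.6)

    def test_invalid_r2_rejected(self):
        with pytest.raises(ValueError):
            correct_singular_values(2.0, 1.5)


class TestPipeline:
    def test_planted_matches_closed_form(self):
        phis = []
        for s in range(10):
            ds = planted_rank_one(PlantedSpec(theta=5.0, seed=s))
            phis.append(phiclust_from_matrix(ds.matrix, config=RunConfig(seed=s)).phiclust)
        assert np.mean(phis) == pytest.approx(phi_cell(5.0, C_DEFAULT), abs=0.02)

    def test_phiclust_permutation_invariant(self):
        ds = planted_rank_one(PlantedSpec(theta=5.0, seed=3))
        rng = np.random.default_rng(0)
        perm = ds.matrix[np.ix_(rng.permutation(350), rng.permutation(201))]
        a = phiclust_from_matrix(ds.matrix, config=RunConfig(seed=1)).phiclust
        b = phiclust_from_matrix(perm, config=RunConfig(seed=1)).phiclust
        assert a == pytest.approx(b, abs=1e-10)

    def test_result_fields_consistent(self):
        ds = planted_rank_one(PlantedSpec(theta=5.0, seed=0))
        r = phiclust_from_matrix(ds.matrix, config=RunConfig(seed=0))
        assert 0 <= r.phiclust < 1
        assert r.n_genes == 350 and r.n_cells == 201
        assert len(r.components) == 1
        comp = r.components[0]
        assert comp.gamma_corrected <= comp.gamma
        assert comp.theta > r.c**0.25

    def test_covariate_equal_to_signal_zeroes_phiclust(self):
        ds = planted_rank_one(PlantedSpec(theta=5.0, seed=0))
        cov = pd.DataFrame({"signal": ds.true_cell_vector})
        r = phiclust_from_matrix(ds.matrix, covariates=cov, config=RunConfig(seed=0))
        assert r.phiclust == 0.0


class TestUncertainty:
    def _fitted(self, seed=0):
        ds = planted_rank_one(PlantedSpec(theta=5.0, seed=seed))
        svd = scaled_svd(ds.matrix)
        mp = mp_model(350, 201, 0.01)
        cfg = RunConfig(seed=seed, n_boot=50)
        return svd, _components_from_svd(svd, mp, cfg), cfg

    def test_zero_components_zero_spread(self):
        svd, _, cfg = self._fitted()
        assert estimate_uncertainty(svd, [], cfg) == (0.0, 0.0)

    def test_deterministic_under_seed(self):
        svd, comps, cfg = self._fitted()
        assert estimate_uncertainty(svd, comps, cfg) == estimate_uncertainty(svd, comps, cfg)

    def test_point_estimate_within_resampled_spread(self):
        ok = 0
        for s in range(5):
            svd, comps, cfg = self._fitted(seed=s)
            point = max(c.phi for c in comps)
            sp, sm = estimate_uncertainty(svd, comps, cfg)
            # resampling around the approximated signal should bracket
            # the point estimate within a few sigma
            ok += (sp + sm) > 0 and (sp < 0.05 and sm < 0.05)
        assert ok >= 4


class TestVarianceDrivingGenes:
    def test_planted_support_recovered(self):
        hits = []
        for s in range(10):
            ds = planted_rank_one(PlantedSpec(theta=5.0, seed=s))
            svd = scaled_svd(ds.matrix)
            genes = [f"g{i}" for i in range(350)]
            tab = variance_driving_genes(svd, genes, 0, [0], top_n=20)
            # orient by the recovered component's overall sign (the SVD
            # sign convention is internal, not tied to the planted truth)
            align = np.sign(float(svd.U[:, 0] @ ds.true_gene_vector))
            pos = tab[align * tab["sign"] > 0]["gene_id"]
            # planted positive support is genes 0..199
            hits.append(np.mean([int(g[1:]) < 200 for g in pos]))
        assert np.mean(hits) >= 0.9

    def test_top_n_zero_empty(self):
        ds = planted_rank_one(PlantedSpec(theta=5.0, seed=0))
        svd = scaled_svd(ds.matrix)
        tab = variance_driving_genes(svd, [f"g{i}" for i in range(350)], 0, [0], top_n=0)
        assert tab.empty

    def test_bulk_component_rejected(self):
        ds = planted_rank_one(PlantedSpec(theta=5.0, seed=0))
        svd = scaled_svd(ds.matrix)
        with pytest.raises(ValueError, match="not significant"):
            variance_driving_genes(svd, [f"g{i}" for i in range(350)], 5, [0])
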