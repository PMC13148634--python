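import numpy as np
import pytest

from quadjrf.errors import TreeError
from quadjrf.phylo_comparative import (
    ancestral_correlation,
    ancestral_states,
    brownian_covariance,
    internal_state_values,
    pgls_fit,
    phylo_from_string,
    read_newick,
    simulate_brownian,
)
from quadjrf.synthetic_data import pure_birth_tree

# Five-tip ultrametric fixture used for the frozen external cross-checks.
FIXTURE_NEWICK = "(((A:1.0,B:1.0):0.5,(C:0.75,D:0.75):0.75):0.5,E:2.0);"
FIXTURE_X = {"A": 0.2, "B": 0.5, "C": -0.3, "D": 0.8, "E": 0.1}
FIXTURE_Y = {"A": 0.35, "B": 0.9, "C": -0.45, "D": 1.2, "E": 0.4}

# Reference values computed independently with R: nlme::gls with a Brownian
# correlation structure (REML) and phytools::fastAnc on the same fixture.
R_GLS = {
    "slope": 1.507477122238,
    "intercept": 0.118153411205,
    "slope_se": 0.092799108073,
    "intercept_se": 0.074585723987,
    "t": 16.244521672064,
    "p": 0.000507524129,
}
R_FASTANC_X = [0.233980582524, 0.267475728155, 0.308737864078, 0.255825242718]
R_FASTANC_Y = [0.470873786408, 0.488592233010, 0.556796116505, 0.412864077670]
R_ANC_CORR = 0.764079136889


class TestReadNewick:
    def test_two_tips(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("(A:1,B:1);")
        ph = read_newick(p)
        assert ph.n_tips == 2
        assert max(ph.depths().values()) == pytest.approx(1.0)

    def test_nesting(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("((A:1,B:1):1,C:2);")
        ph = read_newick(p)
        assert sorted(ph.tip_labels) == ["A", "B", "C"]
        depths = {n.taxon.label: d for n, d in ph.depths().items() if n.is_leaf()}
        assert depths == {"A": 2.0, "B": 2.0, "C": 2.0}

    def test_malformed_rejected(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("((A:1,B:1;")
        with pytest.raises(TreeError):
            read_newick(p)

    def test_missing_branch_length_named(self):
        with pytest.raises(TreeError, match="B"):
            phylo_from_string("(A:1,B);")


class TestBrownianCovariance:
    def test_star_tree_is_scaled_identity(self):
        ph = phylo_from_string("(A:2.5,B:2.5,C:2.5,D:2.5);")
        C = brownian_covariance(ph, order=["A", "B", "C", "D"])
        assert np.allclose(C, 2.5 * np.eye(4))

    def test_hand_path_lengths(self):
        ph = phylo_from_string("((A:1,B:1):1,C:2);")
        C = brownian_covariance(ph, order=["A", "B", "C"])
        assert C[0, 0] == pytest.approx(2.0)  # var(A)
        assert C[0, 1] == pytest.approx(1.0)  # cov(A,B)
        assert C[0, 2] == pytest.approx(0.0)  # cov(A,C)

    @pytest.mark.parametrize("seed", range(3))
    def test_positive_semidefinite_on_random_trees(self, seed):
        ph = pure_birth_tree(12, seed=seed)
        C = brownian_covariance(ph)
        eig = np.linalg.eigvalsh(C)
        assert eig.min() > -1e-12


class TestPGLSFit:
    def test_identity_covariance_reduces_to_ols(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(20)
        y = 1.5 * x + rng.standard_normal(20)
        fit = pgls_fit(x, y, np.eye(20))
        slope_ols, intercept_ols = np.polyfit(x, y, 1)
        assert fit.slope == pytest.approx(slope_ols, rel=1e-12)
        assert fit.intercept == pytest.approx(intercept_ols, rel=1e-12)

    def test_exact_linear_data(self):
        ph = pure_birth_tree(8, seed=4)
        C = brownian_covariance(ph)
        x = np.linspace(-1, 1, 8)
        fit = pgls_fit(x, 2.0 * x, C)
        assert fit.slope == pytest.approx(2.0, abs=1e-9)
        assert fit.sigma2 == pytest.approx(0.0, abs=1e-18)

    def test_matches_r_gls_brownian(self):
        ph = phylo_from_string(FIXTURE_NEWICK)
        labels = ["A", "B", "C", "D", "E"]
        C = brownian_covariance(ph, order=labels)
        fit = pgls_fit(
            [FIXTURE_X[t] for t in labels], [FIXTURE_Y[t] for t in labels], C
        )
        assert fit.slope == pytest.approx(R_GLS["slope"], rel=1e-9)
        assert fit.intercept == pytest.approx(R_GLS["intercept"], rel=1e-9)
        assert fit.slope_se == pytest.approx(R_GLS["slope_se"], rel=1e-9)
        assert fit.intercept_se == pytest.approx(R_GLS["intercept_se"], rel=1e-9)
        assert fit.t_slope == pytest.approx(R_GLS["t"], rel=1e-9)
        assert fit.p_slope == pytest.approx(R_GLS["p"], rel=1e-6)
        assert fit.df == 3

    def test_scale_and_shift_equivariance(self):
        ph = pure_birth_tree(10, seed=6)
        C = brownian_covariance(ph)
        rng = np.random.default_rng(1)
        x = rng.standard_normal(10)
        y = rng.standard_normal(10)
        base = pgls_fit(x, y, C)
        scaled = pgls_fit(x, 3.0 * y, C)
        shifted = pgls_fit(x, y + 5.0, C)
        assert scaled.slope == pytest.approx(3.0 * base.slope, rel=1e-9)
        assert shifted.slope == pytest.approx(base.slope, rel=1e-9)
        assert shifted.intercept == pytest.approx(base.intercept + 5.0, rel=1e-9)

    def test_singular_covariance_raises_with_hint(self):
        C = np.ones((4, 4))
        with pytest.raises(np.linalg.LinAlgError, match="ridge"):
            pgls_fit([0, 1, 2, 3], [0, 1, 2, 3], C)


class TestAncestralStates:
    def test_two_tip_root_is_mean(self):
        ph = phylo_from_string("(A:1,B:1);")
        states = ancestral_states(ph, {"A": 2.0, "B": 6.0})
        root = internal_state_values(ph, states)
        assert root[0] == pytest.approx(4.0)

    def test_star_tree_root_is_mean(self):
        ph = phylo_from_string("(A:1,B:1,C:1,D:1);")
        states = ancestral_states(ph, {"A": 1.0, "B": 2.0, "C": 3.0, "D": 6.0})
        assert internal_state_values(ph, states)[0] == pytest.approx(3.0)

    def test_constant_tips_constant_everywhere(self):
        ph = pure_birth_tree(9, seed=2)
        states = ancestral_states(ph, {t: 0.7 for t in ph.tip_labels})
        assert np.allclose(list(states.values()), 0.7)

    def test_matches_phytools_fastanc(self):
        ph = phylo_from_string(FIXTURE_NEWICK)
        sx = ancestral_states(ph, FIXTURE_X)
        sy = ancestral_states(ph, FIXTURE_Y)
        assert np.allclose(internal_state_values(ph, sx), R_FASTANC_X, atol=1e-9)
        assert np.allclose(internal_state_values(ph, sy), R_FASTANC_Y, atol=1e-9)

    def test_missing_tip_listed(self):
        ph = phylo_from_string("(A:1,B:1);")
        with pytest.raises(TreeError, match="B"):
            ancestral_states(ph, {"A": 1.0})


class TestAncestralCorrelation:
    def test_identical_lists(self):
        x = [0.1, 0.4, 0.9, 0.2]
        assert ancestral_correlation(x, x) == pytest.approx(1.0)

    def test_negated_lists(self):
        x = np.array([0.1, 0.4, 0.9, 0.2])
        assert ancestral_correlation(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_four_points(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 1.0, 4.0, 3.0])
        expected = np.cov(x, y)[0, 1] / (x.std(ddof=1) * y.std(ddof=1))
        assert ancestral_correlation(x, y) == pytest.approx(expected)

    def test_matches_r_on_fixture(self):
        ph = phylo_from_string(FIXTURE_NEWICK)
        ix = internal_state_values(ph, ancestral_states(ph, FIXTURE_X))
        iy = internal_state_values(ph, ancestral_states(ph, FIXTURE_Y))
        assert ancestral_correlation(ix, iy) == pytest.approx(R_ANC_CORR, rel=1e-9)

    def test_zero_variance_flagged_nan(self):
        assert np.isnan(ancestral_correlation([1.0, 1.0, 1.0], [0.1, 0.2, 0.3]))


class TestSimulateBrownian:
    def test_deterministic_and_tipwise(self):
        ph = pure_birth_tree(7, seed=0)
        a = simulate_brownian(ph, rate=1.0, seed=3)
        b = simulate_brownian(ph, rate=1.0, seed=3)
        assert a == b
        assert set(a) == set(ph.tip_labels)

    def test_zero_rate_keeps_root_value(self):
        ph = pure_birth_tree(5, seed=1)
        vals = simulate_brownian(ph, rate=0.0, seed=0, root_value=0.42)
        assert np.allclose(list(vals.values()), 0.42)

    def test_bounds_respected(self):
        ph = pure_birth_tree(20, seed=5)
        vals = simulate_brownian(ph, rate=5.0, seed=2, root_value=0.5, bounds=(0, 1))
        arr = np.array(list(vals.values()))
        assert np.all((arr >= 0) & (arr <= 1))
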