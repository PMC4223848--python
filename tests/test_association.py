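import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cokappa import (
    InvalidInputError,
    NeighborConfig,
    RatingDataset,
    UndefinedStatisticError,
    association_matrix,
    build_table,
    clq,
    clq_max,
    dichotomize,
    find_nearest_neighbors,
    kappa_exact,
    kappa_from_clq,
    null_se,
    overall_kappa,
    p_value,
    permutation_null,
    significance_stars,
)
from cokappa.contingency import CategoryScheme
from cokappa.simulate import SimulationConfig, generate, null_confusion

import pandas as pd


class TestClq:
    def test_observed_over_expected(self, make_table):
        # margins p1=0.34, p2=0.12 with o_12 = 5.1% -> CLQ 1.275
        cells = np.array([[0.289, 0.051], [0.051, 0.069]])
        cells = np.pad(cells, ((0, 1), (0, 1)))
        cells[2, 2] = 1 - cells.sum()
        table = make_table(cells)
        assert clq(table, 1, 2) == pytest.approx(0.051 / (0.34 * 0.12))

    def test_chance_level_is_one(self, make_table):
        p = np.array([0.2, 0.5, 0.3])
        table = make_table(np.outer(p, p))
        for a in (1, 2, 3):
            for b in (1, 2, 3):
                assert clq(table, a, b) == pytest.approx(1.0)

    def test_zero_observed_gives_zero(self, make_table):
        table = make_table([[0.5, 0.0], [0.2, 0.3]])
        assert clq(table, 1, 2) == 0.0

    def test_zero_margin_is_undefined(self, make_table):
        table = make_table([[0.5, 0.5, 0], [0.0, 0.0, 0], [0, 0, 0]], codes=(1, 2, 3))
        with pytest.raises(UndefinedStatisticError):
            clq(table, 2, 1)


class TestClqMax:
    def test_equal_halves(self):
        assert clq_max(0.5, 0.5) == pytest.approx(2.0)

    def test_cross_category_back_calculation(self):
        """CLQ_max(0.34, 0.12) ~ 5.637 normalizes CLQ 1.3 to ~6.5% kappa."""
        cmax = clq_max(0.34, 0.12)
        assert cmax == pytest.approx(0.46 / (2 * 0.34 * 0.12), rel=1e-12)
        assert cmax == pytest.approx(5.637, abs=5e-4)
        assert (1.3 - 1) / (cmax - 1) * 100 == pytest.approx(6.6, abs=0.2)

    def test_same_category_back_calculation(self):
        cmax = clq_max(0.12, 0.12, same_category=True)
        assert cmax == pytest.approx(1 / 0.12)
        assert round((2.5 - 1) / (cmax - 1) * 100) == 20

    def test_constraint_and_degenerate(self):
        with pytest.raises(InvalidInputError):
            clq_max(0.7, 0.6)
        with pytest.raises(UndefinedStatisticError):
            clq_max(0.0, 0.5)
        with pytest.raises(UndefinedStatisticError):
            clq_max(1.0, 1.0, same_category=True)


class TestKappaExact:
    def test_direct_arithmetic(self, make_table):
        # 2x2, P_O = 0.62, both margins 0.46/0.54 -> P_E = 0.5032
        table = make_table([[0.27, 0.19], [0.19, 0.35]])
        k = kappa_exact(table, 1, 1)
        assert k == pytest.approx((0.62 - 0.5032) / (1 - 0.5032), abs=1e-12)
        assert k == pytest.approx(0.2351, abs=5e-5)

    def test_identity_table_is_one(self, make_table):
        table = make_table(np.diag([0.2, 0.5, 0.3]))
        for a in (1, 2, 3):
            assert kappa_exact(table, a, a) == pytest.approx(1.0)

    def test_independence_table_is_zero(self, make_table):
        p = np.array([0.1, 0.4, 0.5])
        table = make_table(np.outer(p, p))
        for a in (1, 2, 3):
            for b in (1, 2, 3):
                assert kappa_exact(table, a, b) == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_margin_undefined(self, make_table):
        table = make_table([[1.0, 0.0], [0.0, 0.0]])
        with pytest.raises(UndefinedStatisticError):
            kappa_exact(table, 1, 1)

    def test_equals_overall_kappa_of_dichotomized_table(self, make_symmetric_table, rng):
        for _ in range(25):
            table = make_symmetric_table(c=int(rng.integers(2, 6)))
            for a in table.scheme.codes:
                d = dichotomize(table, a, a)
                assert kappa_exact(table, a, a) == pytest.approx(
                    overall_kappa(d), abs=1e-12
                )


class TestKappaFromClq:
    def test_published_value_normalization(self):
        assert 100 * kappa_from_clq(1.3, 0.34, 0.12) == pytest.approx(6.6, abs=0.2)

    def test_chance_clq_gives_zero(self):
        assert kappa_from_clq(1.0, 0.3, 0.2) == 0.0

    def test_max_clq_gives_one(self):
        cmax = clq_max(0.25, 0.4)
        assert kappa_from_clq(cmax, 0.25, 0.4) == pytest.approx(1.0)

    def test_algebraic_form(self):
        pa, pb, c = 0.31, 0.22, 1.7
        expected = 2 * pa * pb * (c - 1) / (pa + pb - 2 * pa * pb)
        assert kappa_from_clq(c, pa, pb) == pytest.approx(expected, rel=1e-12)

    @settings(derandomize=True, max_examples=200)
    @given(
        c=st.floats(0.0, 12.0),
        pa=st.floats(0.01, 0.6),
        pb=st.floats(0.01, 0.39),
    )
    def test_sign_coherence(self, c, pa, pb):
        """CLQ > 1 <=> kappa > 0; CLQ < 1 <=> kappa < 0."""
        k = kappa_from_clq(c, pa, pb)
        assert np.sign(k) == np.sign(c - 1.0)

    def test_matches_exact_kappa_under_equal_margins(self, make_symmetric_table):
        for _ in range(50):
            table = make_symmetric_table()
            p = table.index_margins
            for a in table.scheme.codes:
                for b in table.scheme.codes:
                    pa, pb = p[a - 1], p[b - 1]
                    approx = kappa_from_clq(clq(table, a, b), pa, pb, same_category=a == b)
                    assert approx == pytest.approx(kappa_exact(table, a, b), abs=1e-9)


class TestNullSe:
    def test_symmetric_closed_form(self, make_table):
        """Symmetric 0.5 margins: SE0 = 1/sqrt(n)."""
        table = make_table([[0.25, 0.25], [0.25, 0.25]], n_sets=100)
        assert null_se(table, 1, 1) == pytest.approx(0.1, abs=1e-12)

    def test_inverse_sqrt_n_scaling(self, make_table):
        cells = [[0.2, 0.15], [0.25, 0.4]]
        se_n = null_se(make_table(cells, n_sets=500), 1, 1)
        se_2n = null_se(make_table(cells, n_sets=1000), 1, 1)
        assert se_n / se_2n == pytest.approx(np.sqrt(2.0), rel=1e-12)

    def test_agrees_with_direct_formula(self, make_table):
        table = make_table([[0.1, 0.3], [0.2, 0.4]], n_sets=250)
        r = np.array([0.4, 0.6])
        s = np.array([0.3, 0.7])
        pe = r @ s
        num = pe + pe**2 - np.sum(r * s * (r + s))
        assert null_se(table, 1, 1) == pytest.approx(np.sqrt(num / (250 * (1 - pe) ** 2)))


class TestInference:
    def test_zero_kappa_p_is_one(self):
        assert p_value(0.0, 0.1) == pytest.approx(1.0)
        assert significance_stars(1.0) == ""

    def test_normal_quantile_boundary(self):
        assert p_value(1.959964 * 0.05, 0.05) == pytest.approx(0.05, abs=1e-4)
        assert significance_stars(0.0499) == "*"
        assert significance_stars(0.05) == ""

    @pytest.mark.parametrize(
        "p,stars", [(0.0005, "***"), (0.005, "**"), (0.03, "*"), (0.2, "")]
    )
    def test_star_bands(self, p, stars):
        assert significance_stars(p) == stars

    def test_invalid_se(self):
        with pytest.raises(InvalidInputError):
            p_value(0.5, 0.0)


class TestAssociationMatrix:
    def test_symmetric_table_symmetric_clq(self, make_symmetric_table):
        m = association_matrix(make_symmetric_table())
        for a in m.scheme_codes:
            for b in m.scheme_codes:
                assert m.get(a, b).clq == pytest.approx(m.get(b, a).clq, abs=1e-12)
        assert m.max_asymmetry == pytest.approx(0.0, abs=1e-12)

    def test_identity_table_pattern(self, make_table):
        m = association_matrix(make_table(np.diag([0.2, 0.45, 0.35])))
        for a in (1, 2, 3):
            assert m.get(a, a).kappa_exact == pytest.approx(1.0)
            for b in (1, 2, 3):
                if a != b:
                    assert m.get(a, b).kappa_exact < 0

    def test_cells_match_scalar_recomputation(self, make_table, rng):
        table = make_table(rng.dirichlet(np.ones(9)).reshape(3, 3))
        m = association_matrix(table)
        p = table.index_margins
        for a in (1, 2, 3):
            for b in (1, 2, 3):
                r = m.get(a, b)
                assert r.clq == pytest.approx(clq(table, a, b), abs=1e-14)
                assert r.kappa_exact == pytest.approx(kappa_exact(table, a, b), abs=1e-14)
                assert r.clq_max == pytest.approx(
                    clq_max(p[a - 1], p[b - 1], same_category=a == b)
                )
                assert r.se_null == pytest.approx(null_se(table, a, b))

    def test_zero_margin_flagged_not_zero(self, make_table):
        table = make_table([[0.5, 0.5, 0], [0.2, 0.3, 0], [0, 0, 0]], codes=(1, 2, 3))
        r = association_matrix(table).get(3, 3)
        assert np.isnan(r.clq) and np.isnan(r.clq_max)
        assert not r.defined


@pytest.fixture(scope="module")
def small_world():
    cfg = SimulationConfig(
        n_raters=300,
        domain_size=1500.0,
        confusion=null_confusion((0.3, 0.4, 0.3)),
        latent_probs=(0.3, 0.4, 0.3),
        p_indefinite=0.0,
        p_missing=0.0,
        seed=42,
    )
    data = generate(cfg)
    sets = find_nearest_neighbors(data, NeighborConfig(max_radius=1e6)).sets
    return data, sets


class TestPermutationNull:
    def test_fixed_seed_reproducibility(self, small_world):
        data, sets = small_world
        a = permutation_null(data, sets, "rating", 2, 2, n_perm=50, seed=9)
        b = permutation_null(data, sets, "rating", 2, 2, n_perm=50, seed=9)
        np.testing.assert_array_equal(a.clq, b.clq)
        np.testing.assert_array_equal(a.kappa, b.kappa)
        c = permutation_null(data, sets, "rating", 2, 2, n_perm=50, seed=10)
        assert not np.array_equal(a.kappa, c.kappa)

    def test_null_centering(self, small_world):
        data, sets = small_world
        null = permutation_null(data, sets, "rating", 2, 2, n_perm=400, seed=5)
        assert np.nanmean(null.clq) == pytest.approx(1.0, abs=3 * np.nanstd(null.clq) / 20 + 0.01)
        assert np.nanmean(null.kappa) == pytest.approx(0.0, abs=3 * np.nanstd(null.kappa) / 20 + 0.005)

    def test_matches_rebuild_from_permuted_dataset(self, small_world):
        """Each permutation equals rebuilding the table on permuted ratings."""
        data, sets = small_world
        null = permutation_null(data, sets, "rating", 1, 2, n_perm=3, seed=77)
        rng = np.random.default_rng(77)
        values = data.rating_values("rating")
        scheme = CategoryScheme(codes=(1, 2, 3))
        for t in range(3):
            permuted = values[rng.permutation(data.n)]
            shuffled = RatingDataset(
                ids=data.ids, coords=data.coords, ratings=pd.DataFrame({"rating": permuted})
            )
            table = build_table(sets, shuffled, "rating", scheme)
            assert null.clq[t] == pytest.approx(clq(table, 1, 2), abs=1e-12)
            assert null.kappa[t] == pytest.approx(kappa_exact(table, 1, 2), abs=1e-12)
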