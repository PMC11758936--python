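"""Edge-wise GLM/LMM, suprathreshold components, permutation FWE."""

import warnings

import numpy as np
import pytest
from scipy import stats

from msnets import (
    ConnMatrix,
    DesignError,
    DesignMatrix,
    devectorize_edges,
    edgewise_glm,
    edgewise_lmm,
    fit_scalar_lmm,
    nbs_glm,
    nbs_lmm,
    suprathreshold_components,
    vectorize_edges,
)
from msnets.netstats import EdgeIndex, _LongData, _PreparedY, _reml_eval


def sym_matrix(rng, n=5):
    v = rng.random((n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0)
    return v


def complete_index(n_nodes, n_edges=None):
    r, c = np.triu_indices(n_nodes, k=1)
    if n_edges is not None:
        r, c = r[:n_edges], c[:n_edges]
    return EdgeIndex(r, c, n_nodes)


class TestVectorize:
    def test_full_mask_length(self, rng):
        m = ConnMatrix(sym_matrix(rng, 4), np.arange(4), "similarity")
        vec, idx = vectorize_edges(m)
        assert len(vec) == 6

    def test_round_trip_identity(self, rng):
        v = sym_matrix(rng, 6)
        vec, idx = vectorize_edges(v)
        np.testing.assert_allclose(devectorize_edges(vec, idx), v)

    def test_masked_entries_restored_as_zero(self, rng):
        v = sym_matrix(rng, 5)
        mask = np.zeros_like(v, dtype=bool)
        mask[0, 1] = mask[1, 0] = mask[2, 3] = mask[3, 2] = True
        vec, idx = vectorize_edges(v, mask)
        back = devectorize_edges(vec, idx)
        assert back[0, 1] == v[0, 1] and back[2, 3] == v[2, 3]
        assert back[0, 2] == 0

    def test_asymmetric_rejected(self, rng):
        with pytest.raises(ValueError):
            vectorize_edges(rng.random((4, 4)))


class TestEdgewiseGLM:
    def test_simple_regression_closed_form(self, rng):
        n = 40
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        design = DesignMatrix(np.column_stack([np.ones(n), x]), [0.0, 1.0])
        t, p = edgewise_glm(y[:, None], design)
        r = np.corrcoef(x, y)[0, 1]
        df = n - 2
        assert t[0] == pytest.approx(r * np.sqrt(df / (1 - r ** 2)))
        assert p[0] == pytest.approx(2 * stats.t.sf(abs(t[0]), df))

    def test_constant_interest_is_design_error(self):
        n = 20
        design = DesignMatrix(np.column_stack([np.ones(n), np.ones(n)]), [0.0, 1.0])
        with pytest.raises(DesignError):
            edgewise_glm(np.random.default_rng(0).normal(size=(n, 3)), design)

    def test_null_pvalues_uniform(self, rng):
        n = 50
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
        design = DesignMatrix(X, [0.0, 1.0, 0.0])
        Y = rng.normal(size=(n, 1000))
        _, p = edgewise_glm(Y, design)
        assert stats.kstest(p, "uniform").pvalue > 0.01


class TestComponents:
    def _brute_components(self, edges):
        """Exhaustive union-find oracle over an edge list."""
        parent = {}

        def find(x):
            parent.setdefault(x, x)
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a, b in edges:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
        groups = {}
        for a, b in edges:
            groups.setdefault(find(a), set()).add((a, b))
        return sorted([frozenset(g) for g in groups.values()], key=len)

    def test_no_suprathreshold_edges(self):
        idx = complete_index(4)
        comps = suprathreshold_components(np.ones(6), np.ones(6), 0.01, idx)
        assert comps == []

    def test_chain_forms_single_component(self):
        idx = EdgeIndex(np.array([0, 1]), np.array([1, 2]), 3)
        comps = suprathreshold_components(np.array([3.0, 3.0]), np.array([0.001, 0.001]),
                                          0.01, idx)
        assert len(comps) == 1 and comps[0].n_edges == 2
        assert comps[0].stat_sum == pytest.approx(6.0)

    def test_matches_union_find_oracle(self, rng):
        for _ in range(30):
            idx = complete_index(8)
            t = rng.normal(size=idx.n_edges) + 1.0      # keep one sign
            p = rng.random(idx.n_edges)
            comps = suprathreshold_components(np.abs(t), p, 0.3, idx, sign="both")
            sel = [(int(idx.rows[e]), int(idx.cols[e]))
                   for e in np.flatnonzero(p < 0.3)]
            oracle = self._brute_components(sel)
            got = sorted([frozenset((int(a), int(b)) for a, b in c.node_pairs)
                          for c in comps], key=len)
            assert got == oracle

    def test_sign_split_separates_directions(self):
        idx = EdgeIndex(np.array([0, 1]), np.array([1, 2]), 3)
        comps = suprathreshold_components(np.array([3.0, -3.0]), np.array([0.001, 0.001]),
                                          0.01, idx, sign="split")
        assert len(comps) == 2 and {c.sign for c in comps} == {1, -1}


class TestNBSGLM:
    def _data(self, rng, n=40, edges=30, effect=0.0):
        x = rng.normal(size=n)
        Z = rng.normal(size=(n, 2))
        Y = rng.normal(size=(n, edges))
        Y[:, :5] += effect * x[:, None]
        X = np.column_stack([np.ones(n), x, Z])
        return Y, DesignMatrix(X, [0, 1.0, 0, 0])

    def test_pfwe_respects_add_one_bound(self, rng):
        Y, design = self._data(rng, effect=1.0)
        res = nbs_glm(Y, design, complete_index(10, 30), n_perm=49, seed=1)
        for c in res.components:
            assert 1 / 50 <= c.p_fwe <= 1.0

    def test_zero_nuisance_columns_equal_no_nuisance(self, rng):
        Y, design = self._data(rng)
        n = len(Y)
        with_zeros = DesignMatrix(
            np.column_stack([design.X[:, :2], np.zeros((n, 2))]), [0, 1.0, 0, 0])
        plain = DesignMatrix(design.X[:, :2], [0, 1.0])
        idx = complete_index(10, 30)
        a = nbs_glm(Y, with_zeros, idx, n_perm=30, seed=5)
        b = nbs_glm(Y, plain, idx, n_perm=30, seed=5)
        np.testing.assert_array_equal(a.null_max, b.null_max)
        assert [c.stat_sum for c in a.components] == [c.stat_sum for c in b.components]

    def test_more_permutations_keep_observed_components(self, rng):
        Y, design = self._data(rng, effect=0.8)
        idx = complete_index(10, 30)
        a = nbs_glm(Y, design, idx, n_perm=20, seed=2)
        b = nbs_glm(Y, design, idx, n_perm=40, seed=2)
        assert [tuple(c.edge_indices) for c in a.components] == \
               [tuple(c.edge_indices) for c in b.components]

    def test_invalid_n_perm(self, rng):
        Y, design = self._data(rng)
        with pytest.raises(ValueError):
            nbs_glm(Y, design, complete_index(10, 30), n_perm=0)


class TestEdgewiseLMM:
    def _long(self, rng, n_subj=40, slope=0.1, noise=0.05, edges=5,
              re_int=0.5, re_slope=0.05):
        subj = np.repeat(np.arange(n_subj), 4)
        tv = np.tile(np.arange(4.0), n_subj)
        bi = rng.normal(0, re_int, (n_subj, edges))
        bs = rng.normal(0, re_slope, (n_subj, edges))
        Y = bi[subj] + (slope + bs[subj]) * tv[:, None] + rng.normal(0, noise, (len(subj), edges))
        return Y, subj, tv

    def test_agrees_with_statsmodels_reml(self, rng):
        from statsmodels.regression.mixed_linear_model import MixedLM

        Y, subj, tv = self._long(rng)
        res = edgewise_lmm(Y, subj, tv)
        X = np.column_stack([np.ones(len(subj)), tv])
        data = _LongData(subj, tv, None)
        for e in range(Y.shape[1]):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sm_fit = MixedLM(Y[:, e], X, groups=subj, exog_re=X).fit(reml=True)
            # compare only when both optimizers reached the same optimum
            cov = np.asarray(sm_fit.cov_re) / sm_fit.scale
            L = np.linalg.cholesky(cov + 1e-10 * np.eye(2))
            th_sm = np.array([np.log(L[0, 0]), np.log(L[1, 1]), L[1, 0]])
            prep = _PreparedY(data, Y[data.order][:, e:e + 1])
            crit_sm = _reml_eval(th_sm, data, prep, True)[0][0]
            crit_us = _reml_eval(res.theta[e], data, prep, True)[0][0]
            assert crit_us <= crit_sm + 1e-3
            if abs(crit_us - crit_sm) < 1e-3:
                assert res.B[e] == pytest.approx(sm_fit.params[1], rel=1e-3)
                assert res.SE[e] == pytest.approx(sm_fit.bse[1], rel=2e-2)

    def test_slope_recovery(self, rng):
        Y, subj, tv = self._long(rng, edges=10)
        res = edgewise_lmm(Y, subj, tv)
        assert abs(res.B.mean() - 0.1) < 0.01

    def test_zero_random_variance_matches_pooled_ols(self, rng):
        Y, subj, tv = self._long(rng, edges=3, re_int=0.0, re_slope=0.0, noise=0.3)
        res = edgewise_lmm(Y, subj, tv)
        X = np.column_stack([np.ones(len(subj)), tv])
        beta = np.linalg.lstsq(X, Y, rcond=None)[0]
        np.testing.assert_allclose(res.B, beta[1], rtol=0.05, atol=5e-3)

    def test_single_visit_everywhere_rejected(self, rng):
        with pytest.raises(ValueError):
            edgewise_lmm(rng.normal(size=(5, 2)), np.arange(5), np.zeros(5))


class TestNBSLMM:
    def test_invalid_n_perm(self, rng):
        subj = np.repeat(np.arange(5), 2)
        tv = np.tile([0.0, 1.0], 5)
        with pytest.raises(ValueError):
            nbs_lmm(rng.normal(size=(10, 3)), subj, tv, complete_index(3), n_perm=0)

    def test_planted_progressive_component_detected(self, rng):
        n_subj, edges = 40, 21
        subj = np.repeat(np.arange(n_subj), 3)
        tv = np.tile(np.arange(3.0), n_subj)
        Y = rng.normal(0, 0.2, (len(subj), edges)) \
            + rng.normal(0, 0.3, (n_subj, edges))[subj]
        Y[:, :5] += 0.25 * tv[:, None]          # strong common slope on 5 edges
        idx = complete_index(7)                 # C(7,2)=21; first 5 edges share node 0
        res = nbs_lmm(Y, subj, tv, idx, n_perm=50, seed=9)
        assert res.components
        top = res.components[0]
        assert top.p_fwe < 0.05
        assert set(map(tuple, top.node_pairs)) >= {(0, k) for k in range(1, 6)}

    def test_null_family_wise_error_controlled(self):
        n_subj, reps = 20, 20
        subj = np.repeat(np.arange(n_subj), 3)
        tv = np.tile(np.arange(3.0), n_subj)
        fwe = 0
        for k in range(reps):
            r = np.random.default_rng(300 + k)
            Y = r.normal(0, 0.3, (len(subj), 10)) + r.normal(0, 0.3, (n_subj, 10))[subj]
            res = nbs_lmm(Y, subj, tv, complete_index(5), n_perm=40, seed=k)
            fwe += any(c.p_fwe < 0.05 for c in res.components)
        assert fwe <= 4          # nominal 5%: expect ~1 of 20


class TestScalarLMM:
    def test_two_noiseless_points_give_exact_slope(self):
        subj = np.repeat(np.arange(6), 2)
        tv = np.tile([0.0, 2.0], 6)
        y = 1.0 + 0.3 * tv + subj * 0.1
        fit = fit_scalar_lmm(y, tv, subj)
        assert fit.B["time"] == pytest.approx(0.3, abs=1e-6)

    def test_flat_trajectories_give_null_slope(self, rng):
        # Wald p uses the normal approximation, so mild inflation over the
        # nominal 5% is expected at this subject count
        n = 40
        subj = np.repeat(np.arange(n), 3)
        tv = np.tile(np.arange(3.0), n)
        hits, bs = 0, []
        for k in range(40):
            r = np.random.default_rng(k)
            y = r.normal(0, 1, n)[subj] + r.normal(0, 0.5, len(subj))
            fit = fit_scalar_lmm(y, tv, subj)
            hits += fit.p["time"] < 0.05
            bs.append(fit.B["time"])
        assert hits <= 6
        assert abs(np.mean(bs)) < 0.02

    def test_recovers_generator_scale_slope(self, rng):
        n = 60
        subj = np.repeat(np.arange(n), 4)
        tv = np.tile(np.arange(4.0), n)
        y = rng.normal(0, 1.0, n)[subj] + (0.084 + rng.normal(0, 0.1, n)[subj]) * tv \
            + rng.normal(0, 0.3, len(subj))
        fit = fit_scalar_lmm(y, tv, subj)
        assert fit.B["time"] - 1.96 * fit.SE["time"] < 0.084 < fit.B["time"] + 1.96 * fit.SE["time"]
        assert fit.var_residual > 0


def test_edgewise_lmm_null_type_one_rate(rng):
    """Zero-slope null: the fraction of edges with p < 0.05 stays near the
    nominal level (mild inflation from the normal approximation allowed)."""
    n_subj, edges = 50, 300
    subj = np.repeat(np.arange(n_subj), 3)
    tv = np.tile(np.arange(3.0), n_subj)
    Y = rng.normal(0, 0.3, (n_subj, edges))[subj] + rng.normal(0, 0.3, (len(subj), edges))
    res = edgewise_lmm(Y, subj, tv)
    rate = float((res.p < 0.05).mean())
    assert 0.01 <= rate <= 0.10
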