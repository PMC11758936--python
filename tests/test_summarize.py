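"""Clinical derivations, z-summaries, correlations, group tests, coupling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from msnets import (
    ConnMatrix,
    DomainError,
    annualized_change,
    bpf_z,
    cdp_label,
    chi_square_2x2,
    component_zscore_summary,
    coupling,
    coupling_by_duration,
    edge_reference_stats,
    group_compare,
    invert_sdmt,
    partial_spearman,
    spearman,
    welch_t_from_summary,
    welch_t_test,
)


class TestCDP:
    @pytest.mark.parametrize("b, f, expect", [
        (5.5, 6.5, True),      # +1.0 at the low-baseline threshold
        (6.0, 6.5, True),      # +0.5 suffices above baseline 5.5
        (3.0, 3.5, False),     # +0.5 below threshold at low baseline
        (2.0, 2.5, False),
        (4.0, 3.0, False),     # improvement
        (2.0, 3.0, True),
        (5.5, 6.0, False),     # +0.5 not enough at baseline <= 5.5
    ])
    def test_rule(self, b, f, expect):
        assert cdp_label(b, f) is expect

    @pytest.mark.parametrize("b, f", [(2.3, 3.0), (-1.0, 0.0), (3.0, 10.5)])
    def test_off_grid_rejected(self, b, f):
        with pytest.raises(DomainError):
            cdp_label(b, f)


class TestBPFZ:
    def _hc(self, rng, n=40):
        age = rng.uniform(20, 70, n)
        sex = rng.integers(0, 2, n)
        icv = rng.normal(1.45e6, 1e5, n)
        bpf = 0.85 - 0.0012 * (age - 40) - 0.005 * (1 - sex) + rng.normal(0, 0.01, n)
        return pd.DataFrame({"brain_volume": bpf * icv, "icv": icv,
                             "age": age, "sex": sex})

    def test_hc_sample_z_has_unit_moments(self, rng):
        hc = self._hc(rng)
        z = bpf_z(hc.brain_volume, hc.icv, hc.age, hc.sex, hc)
        assert np.mean(z) == pytest.approx(0.0, abs=1e-10)
        assert np.std(z, ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_atrophic_patients_negative(self, rng):
        hc = self._hc(rng)
        age = rng.uniform(20, 70, 30)
        sex = rng.integers(0, 2, 30)
        icv = rng.normal(1.45e6, 1e5, 30)
        bpf = 0.85 - 0.0012 * (age - 40) - 0.005 * (1 - sex) - 0.04 + rng.normal(0, 0.01, 30)
        z = bpf_z(bpf * icv, icv, age, sex, hc)
        assert np.mean(z) < -1.0

    def test_zero_icv_rejected(self, rng):
        hc = self._hc(rng)
        with pytest.raises(DomainError):
            bpf_z(1.2e6, 0.0, 40.0, 1, hc)

    def test_small_reference_rejected(self, rng):
        with pytest.raises(ValueError):
            bpf_z(1.2e6, 1.5e6, 40.0, 1, self._hc(rng, n=5))


class TestZSummary:
    def test_subject_at_reference_mean_is_zero(self, rng):
        ref_mean = rng.random((5, 5))
        ref_sd = np.ones((5, 5))
        assert component_zscore_summary(ref_mean, ref_mean, ref_sd, [(0, 1), (2, 3)]) == 0.0

    def test_absolute_values_do_not_cancel(self):
        ref_mean = np.zeros((3, 3))
        ref_sd = np.ones((3, 3))
        vals = np.zeros((3, 3))
        vals[0, 1] = vals[1, 0] = 2.0
        vals[0, 2] = vals[2, 0] = -2.0
        assert component_zscore_summary(vals, ref_mean, ref_sd, [(0, 1), (0, 2)]) == 2.0

    def test_matches_edge_loop(self, rng):
        n = 6
        refs = [np.triu(rng.random((n, n)), 1) for _ in range(8)]
        refs = [r + r.T for r in refs]
        mean, sd = edge_reference_stats(refs)
        subj = refs[0] * 0.7 + 0.1
        edges = [(0, 1), (1, 3), (2, 5)]
        expect = np.mean([abs((subj[i, j] - mean[i, j]) / sd[i, j]) for i, j in edges])
        assert component_zscore_summary(subj, mean, sd, edges) == pytest.approx(expect)

    def test_translation_scale_equivariance(self, rng):
        n = 5
        mats = [rng.random((n, n)) for _ in range(10)]
        mats = [(m + m.T) / 2 for m in mats]
        mean, sd = edge_reference_stats(mats)
        subj = mats[0] * 0.5 + 0.2
        edges = [(0, 2), (1, 4)]
        a = component_zscore_summary(subj, mean, sd, edges)
        b = component_zscore_summary(3 * subj + 1, 3 * mean + 1, 3 * sd, edges)
        assert a == pytest.approx(b)

    def test_zero_sd_edges_excluded_with_warning(self):
        mean = np.zeros((3, 3))
        sd = np.ones((3, 3))
        sd[0, 1] = sd[1, 0] = 0.0
        vals = np.full((3, 3), 1.0)
        with pytest.warns(UserWarning):
            out = component_zscore_summary(vals, mean, sd, [(0, 1), (0, 2)])
        assert out == 1.0


class TestChangeAndCorrelation:
    def test_annualized_change(self):
        assert annualized_change(2.0, 3.0, 2.0) == 0.5
        assert annualized_change(1.0, 1.0, 5.0) == 0.0
        with pytest.raises(DomainError):
            annualized_change(1.0, 2.0, 0.0)

    def test_monotone_pair_perfect_rank_correlation(self, rng):
        x = rng.normal(size=30)
        rho, _ = spearman(x, np.exp(x))
        assert rho == pytest.approx(1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman(np.ones(10), np.arange(10))

    def test_partial_spearman_removes_confound(self, rng):
        n = 500
        z = rng.normal(size=n)
        x = z + rng.normal(scale=0.5, size=n)
        y = z + rng.normal(scale=0.5, size=n)
        rho_raw, _ = spearman(x, y)
        rho_partial, _ = partial_spearman(x, y, z)
        assert rho_raw > 0.5
        assert abs(rho_partial) < 0.1

    def test_null_pvalues_roughly_uniform(self):
        ps = []
        for k in range(200):
            r = np.random.default_rng(k)
            ps.append(spearman(r.normal(size=25), r.normal(size=25))[1])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


def _conn(vals, kind="similarity", ids=None, mask=None, systems=None):
    ids = np.arange(vals.shape[0]) if ids is None else ids
    return ConnMatrix(vals, ids, kind, system_labels=systems, structural_mask=mask)


class TestCoupling:
    def _pair_sets(self, rng, n_sub=8, n_nodes=12, identical=False):
        discs, sims = [], []
        for _ in range(n_sub):
            d = rng.random((n_nodes, n_nodes)) * 0.5
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0)
            s = d.copy() if identical else (lambda m: (m + m.T) / 2)(rng.random((n_nodes, n_nodes)))
            np.fill_diagonal(s, 0)
            s = np.clip(s, 0.01, 1.0)
            np.fill_diagonal(s, 0)
            discs.append(_conn(d, "disconnection"))
            sims.append(_conn(s, "similarity"))
        return discs, sims

    def test_identical_profiles_node_coupling_one(self, rng):
        discs, sims = self._pair_sets(rng, identical=True)
        rhos = coupling(discs, sims, level="node")
        np.testing.assert_allclose(rhos, 1.0)

    def test_independent_matrices_weak_coupling(self, rng):
        discs, sims = self._pair_sets(rng, n_sub=30, n_nodes=100)
        rhos = coupling(discs, sims, level="node")
        assert np.nanmean(np.abs(rhos)) < 0.1

    def test_exclude_zero_drops_masked_and_zero_edges(self, rng):
        n = 6
        d = np.zeros((n, n))
        d[0, 1] = d[1, 0] = 0.4
        d[2, 3] = d[3, 2] = 0.2
        mask = d > 0
        mask[4, 5] = mask[5, 4] = True           # structurally connected, zero value
        s = rng.random((n, n))
        s = (s + s.T) / 2
        np.fill_diagonal(s, 0)
        disc = _conn(d, "disconnection", mask=mask)
        sim = _conn(np.clip(s, 0.01, 1), "similarity")
        # only edges (0,1) and (2,3) survive: too few for a correlation
        with pytest.raises(ValueError):
            coupling([disc], [sim], level="edge", exclude_zero_disconnection=True)

    def test_subcortical_rows_dropped(self, rng):
        n = 8
        systems = np.array(["VIS"] * 6 + ["SUBC"] * 2)
        d = rng.random((n, n)) * 0.5
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        disc = _conn(d, "disconnection", systems=systems)
        s6 = rng.random((6, 6))
        s6 = np.clip((s6 + s6.T) / 2, 0.01, 1)
        np.fill_diagonal(s6, 0)
        sim = _conn(s6, "similarity", ids=np.arange(6))
        rhos = coupling([disc] * 5, [sim] * 5, level="node")
        assert len(rhos) == 6

    def test_duration_split_tie_goes_to_shorter(self, rng):
        discs, sims = self._pair_sets(rng, n_sub=11)
        dd = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 5.0])   # median 5, tied subject
        out = coupling_by_duration(discs, sims, dd, level="global")
        assert out["median"] == 5.0
        assert out["n_shorter"] == 6 and out["n_longer"] == 5  # ties join "shorter"
        assert out["shorter"] is not None and out["longer"] is not None


class TestGroupCompare:
    def test_equal_groups_null(self):
        t = welch_t_from_summary(5.0, 1.0, 30, 5.0, 1.0, 30)
        assert t.statistic == 0.0 and t.p == pytest.approx(1.0)

    def test_published_style_age_row_rounds_to_002(self):
        t = welch_t_from_summary(42.4, 15.7, 55, 37.2, 10.6, 461)
        assert round(t.p, 2) == 0.02

    def test_summary_equals_raw_when_moments_match(self, rng):
        a = rng.normal(size=40)
        a = (a - a.mean()) / a.std(ddof=1) * 2.0 + 10.0     # exact moments
        b = rng.normal(size=60)
        b = (b - b.mean()) / b.std(ddof=1) * 3.0 + 9.0
        t_raw = welch_t_test(a, b)
        t_sum = welch_t_from_summary(10.0, 2.0, 40, 9.0, 3.0, 60)
        assert t_raw.statistic == pytest.approx(t_sum.statistic)
        assert t_raw.p == pytest.approx(t_sum.p)

    def test_chi_square_sex_table(self):
        t = chi_square_2x2([[25, 30], [324, 137]])
        assert t.p < 0.001

    def test_dispatch(self):
        assert group_compare(42.4, 15.7, 55, 37.2, 10.6, 461).kind == "welch"
        assert group_compare([[10, 20], [20, 10]]).kind == "chi2"
        with pytest.raises(ValueError):
            welch_t_from_summary(1, 1, 1, 2, 1, 10)


class TestInvertSDMT:
    def test_sign_flip_and_involution(self):
        assert invert_sdmt(-1.1) == 1.1
        assert invert_sdmt(0.0) == 0.0
        x = np.array([-0.5, 0.3, 2.0])
        np.testing.assert_array_equal(invert_sdmt(invert_sdmt(x)), x)
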