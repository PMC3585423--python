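"""Normalization, dispersion, exact test, BH and t-test against oracles."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from scipy.special import betainc

from mirsat import (
    bh_adjust,
    estimate_common_dispersion,
    exact_nb_pvalue,
    group_t_test,
    median_ratio_size_factors,
    nb_exact_test,
    tmm_factors,
)


def random_table(n_genes=50, n_samples=4, seed=0, lam=200):
    rng = np.random.default_rng(seed)
    counts = rng.poisson(lam, size=(n_genes, n_samples)) + 1
    return pd.DataFrame(counts, index=[f"g{i}" for i in range(n_genes)],
                        columns=[f"s{j}" for j in range(n_samples)])


def tmm_oracle(counts, sample, reference, trim_m=0.30, trim_a=0.05):
    """Brute-force weighted trimmed mean of M-values, coded independently."""
    lib = counts.sum(axis=0)
    yj, yr = counts[sample].to_numpy().astype(float), counts[reference].to_numpy().astype(float)
    nj, nr = float(lib[sample]), float(lib[reference])
    ok = (yj > 0) & (yr > 0)
    yj, yr = yj[ok], yr[ok]
    m = np.log2((yj / nj) / (yr / nr))
    a = 0.5 * np.log2((yj / nj) * (yr / nr))
    keep = np.ones(m.size, bool)
    order_m = np.argsort(m, kind="stable")
    cut = int(np.floor(m.size * trim_m))
    drop = np.concatenate([order_m[:cut], order_m[m.size - cut:]])
    keep[drop] = False
    order_a = np.argsort(a, kind="stable")
    cut_a = int(np.floor(a.size * trim_a))
    drop_a = np.concatenate([order_a[:cut_a], order_a[a.size - cut_a:]])
    keep[drop_a] = False
    w = 1.0 / ((nj - yj) / (nj * yj) + (nr - yr) / (nr * yr))
    return 2.0 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))


class TestTMM:
    def test_identical_libraries_give_unit_factors(self):
        t = random_table(seed=1)
        t["s1"] = t["s0"]
        f = tmm_factors(t[["s0", "s1"]])
        assert np.allclose(f, 1.0)

    def test_depth_doubling_is_absorbed(self):
        t = random_table(n_samples=2, seed=2)
        t["s1"] = 2 * t["s0"]
        assert np.allclose(tmm_factors(t), 1.0)

    def test_single_inflated_gene_matches_independent_oracle(self):
        t = random_table(n_samples=2, seed=3)
        t.loc["g0", "s1"] *= 100
        f = tmm_factors(t, reference="s0")
        raw = tmm_oracle(t, "s1", "s0")
        expected = pd.Series({"s0": 1.0, "s1": raw})
        expected /= np.exp(np.log(expected).mean())
        assert f["s1"] == pytest.approx(expected["s1"], rel=1e-9)
        assert f["s1"] < f["s0"]  # inflated gene pulls the factor down

    def test_random_table_matches_oracle_for_every_sample(self):
        t = random_table(n_genes=50, n_samples=5, seed=4)
        f = tmm_factors(t, reference="s2")
        raw = pd.Series({s: 1.0 if s == "s2" else tmm_oracle(t, s, "s2")
                         for s in t.columns})
        raw /= np.exp(np.log(raw).mean())
        assert np.allclose(f, raw.reindex(f.index))

    def test_geometric_mean_is_one(self):
        f = tmm_factors(random_table(seed=5, n_samples=6))
        assert np.exp(np.log(f).mean()) == pytest.approx(1.0)

    def test_too_sparse_table_fails(self):
        t = pd.DataFrame({"s0": [5, 0, 0], "s1": [0, 7, 0]})
        with pytest.raises(ValueError):
            tmm_factors(t)


class TestMedianRatio:
    def test_single_sample_unit_factor(self):
        t = random_table(n_samples=1, seed=6)
        assert median_ratio_size_factors(t)["s0"] == 1.0

    def test_doubled_library_doubles_the_factor(self):
        t = random_table(n_samples=2, seed=7)
        t["s1"] = 2 * t["s0"]
        f = median_ratio_size_factors(t)
        assert f["s1"] / f["s0"] == pytest.approx(2.0)

    def test_matches_brute_force_oracle(self):
        t = random_table(n_genes=50, n_samples=4, seed=8)
        f = median_ratio_size_factors(t)
        sub = t[(t > 0).all(axis=1)].to_numpy().astype(float)
        geo = np.exp(np.mean(np.log(sub), axis=1))
        for j, s in enumerate(t.columns):
            assert f[s] == pytest.approx(np.median(sub[:, j] / geo), rel=1e-9)

    def test_all_zero_rows_everywhere_fails(self):
        t = pd.DataFrame({"s0": [5, 0], "s1": [0, 3]})
        with pytest.raises(ValueError):
            median_ratio_size_factors(t)


class TestDispersion:
    def test_constant_counts_give_zero(self):
        t = pd.DataFrame({"a1": [10, 20], "a2": [10, 20], "b1": [10, 20], "b2": [10, 20]})
        phi = estimate_common_dispersion(t, ["A", "A", "B", "B"], normalization="none")
        assert phi == 0.0

    def test_poisson_data_estimates_near_zero(self):
        rng = np.random.default_rng(9)
        t = pd.DataFrame(rng.poisson(100, size=(800, 8)),
                         columns=[f"s{j}" for j in range(8)])
        phi = estimate_common_dispersion(t, ["A"] * 4 + ["B"] * 4, normalization="none")
        assert abs(phi) < 0.01

    def test_recovers_injected_dispersion(self):
        """NB data with phi=0.2: pooled moment estimate lands within 0.05."""
        truth = 0.2
        estimates = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            mu = rng.lognormal(5, 1, size=500)
            lam = mu[:, None] * rng.gamma(1 / truth, truth, size=(500, 18))
            t = pd.DataFrame(rng.poisson(lam), columns=[f"s{j}" for j in range(18)])
            estimates.append(estimate_common_dispersion(
                t, ["A"] * 9 + ["B"] * 9, normalization="none"))
        assert np.mean(estimates) == pytest.approx(truth, abs=0.05)

    def test_unreplicated_design_fails(self):
        t = pd.DataFrame({"a": [1, 2], "b": [3, 4]})
        with pytest.raises(ValueError, match="unidentifiable"):
            estimate_common_dispersion(t, ["A", "B"], normalization="none")


class TestExactTest:
    def test_no_evidence_gives_p_one(self):
        t = pd.DataFrame({"a1": [10], "a2": [12], "b1": [12], "b2": [10]})
        out = nb_exact_test(t, ["A", "A", "B", "B"], dispersion=0.0, normalization="none")
        assert out.p_value.iloc[0] == pytest.approx(1.0)

    def test_group_swap_negates_log2fc_keeps_p(self):
        t = random_table(n_genes=30, n_samples=6, seed=10)
        g1 = ["A", "A", "A", "B", "B", "B"]
        g2 = ["B", "B", "B", "A", "A", "A"]
        out1 = nb_exact_test(t, g1, dispersion=0.1, normalization="none")
        out2 = nb_exact_test(t, g2, dispersion=0.1, normalization="none")
        assert np.allclose(out1.p_value, out2.p_value)
        assert np.allclose(out1.log2_fc, -out2.log2_fc)

    def test_poisson_case_matches_binomial_enumeration(self):
        """phi=0, 10 vs 0 in single libraries: enumerate Binomial(10, 1/2)."""
        p = exact_nb_pvalue(10, 0, 1, 1, 0.0)
        pmf = np.array([scipy.stats.binom.pmf(s, 10, 0.5) for s in range(11)])
        oracle = pmf[pmf <= pmf[10] + 1e-15].sum()
        assert p == pytest.approx(oracle)
        assert p == pytest.approx(2 / 1024)

    def test_nb_conditional_matches_direct_enumeration(self):
        """phi>0 conditional pmf equals normalized products of NB pmfs."""
        phi, na, nb_, t = 0.25, 3, 4, 40
        mu = 7.3  # arbitrary: the conditional law must not depend on it
        pa = scipy.stats.nbinom.pmf(np.arange(t + 1), na / phi,
                                    (na / phi) / (na / phi + na * mu))
        pb = scipy.stats.nbinom.pmf(t - np.arange(t + 1), nb_ / phi,
                                    (nb_ / phi) / (nb_ / phi + nb_ * mu))
        joint = pa * pb
        joint /= joint.sum()
        for s_obs in (0, 13, 40):
            oracle = joint[joint <= joint[s_obs] + 1e-15].sum()
            assert exact_nb_pvalue(s_obs, t - s_obs, na, nb_, phi) == pytest.approx(
                oracle, rel=1e-8)

    def test_non_integer_counts_rejected(self):
        t = pd.DataFrame({"a1": [1.5], "a2": [2.0], "b1": [2.0], "b2": [1.0]})
        with pytest.raises(ValueError, match="integer"):
            nb_exact_test(t, ["A", "A", "B", "B"], dispersion=0.0, normalization="none")


class TestBH:
    def test_single_pvalue_identity(self):
        assert bh_adjust([0.02])[0] == pytest.approx(0.02)

    def test_hand_stepup_example(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, 0.04)

    def test_all_ones(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_order_preserved_and_matches_manual_stepup(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(size=25)
        adj = bh_adjust(p)
        order = np.argsort(p)
        manual = np.empty_like(p)
        m = p.size
        running = 1.0
        for rank in range(m, 0, -1):
            idx = order[rank - 1]
            running = min(running, p[idx] * m / rank)
            manual[idx] = running
        assert np.allclose(adj, manual)
        assert (adj >= p - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestGroupTTest:
    def test_identical_groups(self):
        t, _, p = group_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_clear_separation(self):
        _, _, p = group_t_test([0, 0, 0, 0], [10, 10, 10, 10.0001])
        assert p < 1e-6

    def test_zero_variance_equal_means_convention(self):
        t, _, p = group_t_test([5.0, 5.0], [5.0, 5.0])
        assert (t, p) == (0.0, 1.0)

    @pytest.mark.parametrize("variant", ["welch", "pooled"])
    def test_textbook_case_matches_closed_form(self, variant):
        a = np.array([19.8, 21.2, 20.4, 18.9, 22.0, 20.7])
        b = np.array([17.1, 18.6, 16.9, 19.0, 18.2])
        t, df, p = group_t_test(a, b, variant=variant)
        va, vb = a.var(ddof=1), b.var(ddof=1)
        na, nb_ = a.size, b.size
        if variant == "pooled":
            sp2 = ((na - 1) * va + (nb_ - 1) * vb) / (na + nb_ - 2)
            t_oracle = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb_))
            df_oracle = na + nb_ - 2
        else:
            se2 = va / na + vb / nb_
            t_oracle = (a.mean() - b.mean()) / np.sqrt(se2)
            df_oracle = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb_) ** 2 / (nb_ - 1))
        p_oracle = betainc(df_oracle / 2, 0.5, df_oracle / (df_oracle + t_oracle ** 2))
        assert t == pytest.approx(t_oracle)
        assert df == pytest.approx(df_oracle)
        assert p == pytest.approx(p_oracle)

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            group_t_test([1.0], [2.0, 3.0])
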