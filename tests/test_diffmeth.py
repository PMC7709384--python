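import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import xlogy

from retrometh.diffmeth import (HYPO, HYPER, NONE, adjust_q, call_dmcs,
                                call_dmrs, dmc_chromosome_summary, dmc_test,
                                lrt_statistics, dmc_test_all)
from retrometh.methcall import CONTROL, EXPOSED, GroupDesign

from conftest import make_counts_matrix


def pooled_g_statistic(m_ctrl, t_ctrl, m_expo, t_expo):
    """Independent oracle: G = 2 * sum O*ln(O/E) on the pooled 2x2 table."""
    obs = np.array([[m_ctrl, t_ctrl - m_ctrl], [m_expo, t_expo - m_expo]],
                   dtype=float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    exp = row * col / obs.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = xlogy(obs, obs / exp)
    return 2.0 * np.nansum(terms)


class TestDmcTest:
    def setup_method(self):
        self.mask = np.array([False, False, True, True])  # 2v2

    def test_example_matches_pooled_g(self):
        # control (45/50, 45/50), exposed (25/50, 25/50)
        m = np.array([45, 45, 25, 25])
        t = np.array([50, 50, 50, 50])
        stat, p, diff = dmc_test(m, t, self.mask)
        assert diff == pytest.approx(-40.0)
        g = pooled_g_statistic(90, 100, 50, 100)
        assert stat == pytest.approx(g, abs=1e-9)
        assert p == pytest.approx(stats.chi2.sf(g, 1))

    def test_identical_proportions_null(self):
        stat, p, diff = dmc_test(np.array([5, 5, 5, 5]),
                                 np.array([10, 10, 10, 10]), self.mask)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)
        assert diff == pytest.approx(0.0)

    def test_boundary_proportions(self):
        stat, p, diff = dmc_test(np.array([10, 10, 0, 0]),
                                 np.array([10, 10, 10, 10]), self.mask)
        assert diff == pytest.approx(-100.0)
        assert np.isfinite(stat) and p < 1e-6

    def test_zero_coverage_rejected(self):
        with pytest.raises(ValueError):
            dmc_test(np.array([1, 1, 0, 1]), np.array([10, 10, 0, 10]),
                     self.mask)

    def test_lrt_equals_g_on_random_configurations(self):
        # per-site identity between the per-sample-likelihood LRT and the
        # pooled-table G statistic, on unbalanced random counts
        rng = np.random.default_rng(42)
        mask = np.array([False] * 5 + [True] * 5)
        tot = rng.integers(10, 101, (300, 10))
        meth = rng.binomial(tot, rng.uniform(0.05, 0.95, (300, 1)))
        stat, _, _ = lrt_statistics(meth, tot, mask)
        for i in range(300):
            g = pooled_g_statistic(meth[i, :5].sum(), tot[i, :5].sum(),
                                   meth[i, 5:].sum(), tot[i, 5:].sum())
            assert stat[i] == pytest.approx(g, abs=1e-6)

    def test_matches_statsmodels_logistic_deviance(self):
        # cross-check against an iteratively fitted binomial GLM
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        mask = np.array([False] * 5 + [True] * 5)
        x = sm.add_constant(mask.astype(float))
        for _ in range(25):
            tot = rng.integers(10, 80, 10)
            meth = rng.binomial(tot, rng.uniform(0.1, 0.9))
            endog = np.column_stack([meth, tot - meth])
            alt = sm.GLM(endog, x, family=sm.families.Binomial()).fit()
            null = sm.GLM(endog, np.ones((10, 1)),
                          family=sm.families.Binomial()).fit()
            lrt = 2 * (alt.llf - null.llf)
            stat, _, _ = dmc_test(meth, tot, mask)
            assert stat == pytest.approx(lrt, abs=1e-6)

    def test_label_swap_flips_sign_and_calls(self, matrix):
        dmc = call_dmcs(dmc_test_all(matrix))
        exposed = matrix.design.group_mask(EXPOSED)
        stat, p, diff = lrt_statistics(matrix.n_meth, matrix.n_total, ~exposed)
        assert np.allclose(diff, -dmc["meth_diff"].to_numpy())
        swapped = dmc.copy()
        swapped["meth_diff"] = diff
        swapped["q"] = adjust_q(p)
        swapped = call_dmcs(swapped)
        mapping = {HYPO: HYPER, HYPER: HYPO, NONE: NONE}
        assert list(swapped["call"]) == [mapping[c] for c in dmc["call"]]


class TestAdjustQ:
    def test_hand_computed_bh(self):
        # q_i = min_{j>=i} p_j * m / j
        q = adjust_q(np.array([0.01, 0.02, 0.03]))
        assert q == pytest.approx([0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert adjust_q(np.ones(5)) == pytest.approx(np.ones(5))

    def test_single_p(self):
        assert adjust_q(np.array([0.2])) == pytest.approx([0.2])

    def test_monotone_in_sorted_p(self):
        rng = np.random.default_rng(0)
        p = np.sort(rng.uniform(size=50))
        q = adjust_q(p)
        assert (np.diff(q) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_q(np.array([0.5, 1.5]))


class TestCallDmcs:
    @pytest.mark.parametrize("q,diff,expected", [
        (0.01, -10.0, HYPO),    # both boundaries inclusive
        (0.01, 10.0, HYPER),
        (0.011, -50.0, NONE),   # q fails
        (0.001, 9.9, NONE),     # diff fails
    ])
    def test_thresholds(self, q, diff, expected):
        df = pd.DataFrame({"q": [q], "meth_diff": [diff]})
        assert call_dmcs(df)["call"].iloc[0] == expected


class TestCallDmrs:
    def _matrix_and_dmcs(self, design, positions, ctrl_p, expo_p, cov=30):
        n = len(positions)
        tot = np.full((n, 10), cov)
        meth = np.zeros((n, 10), dtype=int)
        meth[:, :5] = np.round(np.asarray(ctrl_p)[:, None] * cov).astype(int)
        meth[:, 5:] = np.round(np.asarray(expo_p)[:, None] * cov).astype(int)
        m = make_counts_matrix(design, [("chr1", p) for p in positions],
                               meth, tot)
        dmc = call_dmcs(dmc_test_all(m))
        return m, dmc

    def test_chained_hypo_region_detected(self, design_5v5):
        # 4 CpGs within 80 bp, diffs about -15/-20/-12/-14 points at 30x
        ctrl = np.array([0.80, 0.85, 0.78, 0.82])
        expo = ctrl - np.array([0.15, 0.20, 0.12, 0.14])
        m, dmc = self._matrix_and_dmcs(design_5v5, [100, 150, 200, 260],
                                       ctrl, expo)
        dmrs = call_dmrs(m, dmc)
        assert len(dmrs) == 1
        row = dmrs.iloc[0]
        assert row["n_cpg"] == 4 and row["call"] == HYPO
        assert row["n_dmc"] >= 1
        assert (row["start"], row["end"]) == (99, 260)

    def test_two_cpg_chain_never_a_region(self, design_5v5):
        m, dmc = self._matrix_and_dmcs(design_5v5, [100, 150],
                                       [0.9, 0.9], [0.4, 0.4])
        assert len(call_dmrs(m, dmc)) == 0

    def test_region_diff_exactly_minus_10_rejected(self, design_5v5):
        # strict > 10 filter: engineered pooled region diff of exactly -10
        ctrl = np.array([0.80, 0.80, 0.80])
        expo = np.array([0.70, 0.70, 0.70])
        m, dmc = self._matrix_and_dmcs(design_5v5, [100, 150, 200],
                                       ctrl, expo, cov=30)
        region_diff = 100 * (m.n_meth[:, 5:].sum() / m.n_total[:, 5:].sum()
                             - m.n_meth[:, :5].sum() / m.n_total[:, :5].sum())
        assert region_diff == pytest.approx(-10.0)
        dmc.loc[0, "call"] = HYPO  # ensure the DMC requirement is met
        assert len(call_dmrs(m, dmc)) == 0

    def test_gap_breaks_chain(self, design_5v5):
        m, dmc = self._matrix_and_dmcs(
            design_5v5, [100, 150, 200, 500, 550, 600],
            [0.9] * 6, [0.4] * 6)
        dmrs = call_dmrs(m, dmc, max_gap=100)
        assert len(dmrs) == 2
        assert dmrs["n_cpg"].tolist() == [3, 3]

    def test_every_dmr_contains_dmc_and_min_cpgs(self, matrix, dmc_table):
        dmrs = call_dmrs(matrix, dmc_table)
        assert len(dmrs) > 0
        assert (dmrs["n_cpg"] >= 3).all()
        assert (dmrs["n_dmc"] >= 1).all()
        assert (dmrs["meth_diff"].abs() > 10).all()


class TestChromosomeSummary:
    def test_counts_and_percentages(self, design_5v5):
        m = make_counts_matrix(
            design_5v5,
            [("chr1", p) for p in range(100, 1100, 10)],
            np.full((100, 10), 5), np.full((100, 10), 10))
        dmc = dmc_test_all(m)
        dmc["call"] = NONE
        dmc.loc[:4, "call"] = HYPO
        out = dmc_chromosome_summary(dmc, m)
        row = out.iloc[0]
        assert row["n_hypo"] == 5 and row["pct_hypo"] == pytest.approx(5.0)
        assert row["n_hyper"] == 0 and row["pct_hyper"] == 0.0

    def test_seeded_chromosome_has_highest_hypo_fraction(self):
        # effects confined to IAP 5'LTRs with proviruses only on the chrY
        # analog: that chromosome must show the top hypoDMC percentage
        from retrometh.methcall import unite_sites
        from retrometh.synthetic import (DEFAULT_FEATURES, EffectSpec,
                                         SynthConfig, generate_genome,
                                         simulate_counts)

        features = {c: dict(f) for c, f in DEFAULT_FEATURES.items()}
        for c in ("chr1", "chr2", "chrX"):
            features[c]["IAPE_provirus"] = 0
        cfg = SynthConfig(
            seed=9, features=features,
            effects=(EffectSpec(("IAPE:5LTR:U3", "IAPE:5LTR:R"), 30.0),))
        genome = generate_genome(cfg)
        samples, _ = simulate_counts(genome, cfg)
        m = unite_sites(samples, cfg.design(), 10)
        out = dmc_chromosome_summary(call_dmcs(dmc_test_all(m)), m)
        out = out.set_index("chrom")
        assert out["pct_hypo"].idxmax() == "chrY"
        assert out.drop("chrY")["pct_hypo"].max() < out.loc["chrY", "pct_hypo"]
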