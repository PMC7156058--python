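"""Railway regression statistics, Fisher combination and Bonferroni."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from splicerail import (
    bonferroni,
    fisher_combine,
    probe_regression,
    railway_table,
    signed_score,
)
from splicerail.railway import SCORE_CAP, railway_plot
from splicerail import SyntheticConfig, build_probe_table, generate_dataset


class TestProbeRegression:
    def test_five_point_hand_ols_oracle(self):
        mal = np.array([100.0, 300.0, 500.0, 800.0, 1200.0])
        y = np.array([7.1, 6.8, 6.2, 5.9, 5.1])
        slope, p = probe_regression(y, mal)
        # normal-equations + t-distribution reference
        n = 5
        xc = mal - mal.mean()
        beta = (xc @ (y - y.mean())) / (xc @ xc)
        resid = (y - y.mean()) - beta * xc
        se = np.sqrt((resid @ resid) / (n - 2) / (xc @ xc))
        t = beta / se
        p_ref = 2 * stats.t.sf(abs(t), n - 2)
        assert slope == pytest.approx(beta, rel=1e-12)
        assert p == pytest.approx(p_ref, rel=1e-12)

    def test_agrees_with_scipy_linregress(self, rng):
        mal = rng.uniform(100, 1300, 12)
        y = rng.normal(7, 1, 12)
        slope, p = probe_regression(y, mal)
        ref = stats.linregress(mal, y)
        assert slope == pytest.approx(ref.slope, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_perfect_linear_fit_gives_p_zero(self):
        mal = np.array([100.0, 400.0, 700.0, 1000.0])
        slope, p = probe_regression(2e-3 * mal + 5.0, mal)
        assert slope == pytest.approx(2e-3)
        assert p == 0.0

    def test_constant_intensities_degenerate_convention(self):
        mal = np.array([100.0, 400.0, 700.0])
        slope, p = probe_regression(np.full(3, 6.0), mal)
        assert (slope, p) == (0.0, 1.0)

    def test_constant_mal_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            probe_regression(np.array([1.0, 2.0, 3.0]), np.full(3, 500.0))

    def test_null_pvalues_approximately_uniform(self):
        rng = np.random.default_rng(5)
        mal = rng.uniform(100, 1300, 20)
        pvals = [
            probe_regression(rng.normal(size=20), mal)[1] for _ in range(400)
        ]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_pvalue_agrees_with_permutation_test(self):
        """Parametric t-test p within 2 permutation SEs of a brute-force null."""
        rng = np.random.default_rng(6)
        mal = rng.uniform(100, 1300, 10)
        y = 0.0015 * mal + rng.normal(0, 0.8, 10)
        slope, p_param = probe_regression(y, mal)
        n_perm = 10_000
        xc = mal - mal.mean()
        obs = abs((xc @ (y - y.mean())) / (xc @ xc))
        count = 0
        for _ in range(n_perm):
            yp = rng.permutation(y)
            b = abs((xc @ (yp - yp.mean())) / (xc @ xc))
            count += b >= obs
        p_perm = (1 + count) / (n_perm + 1)
        se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(p_param - p_perm) < 2 * se + 0.005


class TestSignedScore:
    def test_positive_slope_nominal_threshold(self):
        assert signed_score(1.2, 0.05) == pytest.approx(1.30103, abs=1e-5)

    def test_negative_slope_sign_rule(self):
        assert signed_score(-0.8, 0.05) == pytest.approx(-1.30103, abs=1e-5)

    def test_p_one_scores_zero(self):
        assert signed_score(0.5, 1.0) == 0.0
        assert signed_score(0.0, 1.0) == 0.0

    def test_p_zero_capped(self):
        assert signed_score(2.0, 0.0) == SCORE_CAP
        assert signed_score(-2.0, 0.0, cap=100.0) == -100.0

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            signed_score(1.0, 1.5)
        with pytest.raises(ValueError):
            signed_score(1.0, -0.1)


class TestFisherCombine:
    def test_all_ones_combine_to_one(self):
        assert fisher_combine([1.0, 1.0, 1.0]) == pytest.approx(1.0)

    def test_single_p_is_identity(self):
        for p in (0.5, 0.01, 0.9):
            assert fisher_combine([p]) == pytest.approx(p, rel=1e-12)

    def test_pair_of_0_05_chi_square_oracle(self):
        x = -2 * (np.log(0.05) + np.log(0.05))
        expected = stats.chi2.sf(x, 4)
        combined = fisher_combine([0.05, 0.05])
        assert combined == pytest.approx(expected, rel=1e-12)
        assert combined == pytest.approx(0.0175, abs=5e-4)

    def test_agrees_with_scipy_combine_pvalues(self, rng):
        p = rng.uniform(0.001, 1.0, 6)
        expected = stats.combine_pvalues(p, method="fisher").pvalue
        assert fisher_combine(p) == pytest.approx(expected, rel=1e-12)

    def test_permutation_invariant_and_monotone(self):
        p = [0.2, 0.8, 0.05]
        assert fisher_combine(p) == pytest.approx(fisher_combine(p[::-1]))
        lowered = [0.2, 0.8, 0.01]
        assert fisher_combine(lowered) < fisher_combine(p)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            fisher_combine([])
        with pytest.raises(ValueError):
            fisher_combine([0.0, 0.5])


class TestBonferroni:
    def test_worked_example_huex_multiplicity(self):
        corrected = bonferroni(4.19e-10, int(1.4e6))
        assert corrected == pytest.approx(5.88e-4, rel=0.01)

    def test_identity_multiplicity(self):
        assert bonferroni(0.5, 1) == 0.5

    def test_capped_at_one(self):
        assert bonferroni(0.1, 100) == 1.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            bonferroni(0.5, 0)
        with pytest.raises(ValueError):
            bonferroni(1.5, 10)


@pytest.fixture(scope="module")
def railway_dataset():
    """A dataset whose biomarker probesets carry strong directional effects."""
    cfg = SyntheticConfig(
        seed=31, effect_beta=3.0, noise_sd=0.3, frac_unaffected_probes=0.0,
    )
    ds = generate_dataset(cfg)
    table, _ = build_probe_table(ds.raw_intensities, ds.annotation)
    mal = ds.cohort.set_index("participant_id")["mal"]
    return ds, table, mal


class TestRailwayTable:
    def test_rows_ordered_by_position_with_thresholds(self, railway_dataset):
        ds, table, mal = railway_dataset
        gene = ds.biomarker_genes[0]
        frame, thresholds = railway_table(table[table["gene_name"] == gene], mal)
        n = ds.config.probesets_per_gene * ds.config.probes_per_probeset
        assert len(frame) == n
        assert (np.diff(frame["position"]) >= 0).all()
        assert thresholds.nominal == 0.05
        assert thresholds.corrected == pytest.approx(0.05 / n)

    def test_twenty_probe_corrected_threshold(self, railway_dataset):
        _, table, mal = railway_dataset
        subset = table.head(20).copy()
        subset["gene_name"] = "ONEGENE"
        _, thresholds = railway_table(subset, mal)
        assert thresholds.corrected == pytest.approx(0.0025)

    def test_negative_effect_probeset_dominates_splice_out(self, railway_dataset):
        ds, table, mal = railway_dataset
        beta = ds.probe_effects
        # pick a biomarker gene containing a negative-effect probeset
        gene = next(
            g for g in ds.biomarker_genes
            if (beta[ds.annotation["gene_name"] == g] < 0).any()
        )
        frame, thresholds = railway_table(table[table["gene_name"] == gene], mal)
        frame = frame.set_index("probe_id")
        neg_probes = beta[(ds.annotation["gene_name"] == gene) & (beta < 0)].index
        assert (frame.loc[list(neg_probes), "signed_score"]
                < -thresholds.corrected_score).all()

    def test_all_null_gene_rarely_exceeds_corrected_threshold(self):
        rng = np.random.default_rng(32)
        exceed = 0
        n_rep = 60
        for _ in range(n_rep):
            mal = pd.Series(
                rng.uniform(100, 1300, 20),
                index=[f"patient_{i}" for i in range(20)],
            )
            frame = pd.DataFrame(
                rng.normal(7, 1, size=(8, 20)),
                columns=mal.index,
            )
            frame.insert(0, "gene_name", "NULLGENE")
            frame.insert(1, "probeset_id", ["ps1"] * 4 + ["ps2"] * 4)
            frame.insert(2, "genecode_left", np.arange(8) * 30 + 1)
            frame.index = [f"probe{i}" for i in range(8)]
            rows, thresholds = railway_table(frame, mal)
            exceed += (rows["signed_score"].abs() > thresholds.corrected_score).any()
        assert exceed / n_rep <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_no_shared_participants_rejected(self, railway_dataset):
        ds, table, _ = railway_dataset
        gene = ds.biomarker_genes[0]
        foreign = pd.Series([500.0, 700.0], index=["x1", "x2"])
        with pytest.raises(ValueError, match="participants"):
            railway_table(table[table["gene_name"] == gene], foreign)

    def test_plot_renders(self, railway_dataset, tmp_path):
        import matplotlib

        matplotlib.use("Agg")
        ds, table, mal = railway_dataset
        gene = ds.biomarker_genes[0]
        frame, thresholds = railway_table(table[table["gene_name"] == gene], mal)
        ax = railway_plot(frame, thresholds, title=gene)
        ax.figure.savefig(tmp_path / "railway.png", dpi=40)
        assert (tmp_path / "railway.png").exists()
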