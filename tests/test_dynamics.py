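"""Single-cell QC, normalization, trajectory calls, controls, and the
GAM-adjusted CV noise metric."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from estro.dynamics import (
    CVNoiseModel,
    ExpressionTimecourse,
    adjusted_cv,
    assign_noise_levels,
    assign_trajectories,
    call_differential,
    classify_mean_levels,
    compare_covariate,
    compute_qc,
    filter_cells,
    filter_genes,
    gene_mean_cv,
    mean_bins,
    normalize,
    read_counts_mtx,
    select_controls,
)
from estro.simulate import SimulationConfig, generate_expression, write_counts


def make_tc(counts, timepoints):
    counts = np.asarray(counts)
    meta = pd.DataFrame(
        {"timepoint": timepoints},
        index=[f"c{i}" for i in range(counts.shape[0])],
    )
    genes = pd.Index([f"g{j}" for j in range(counts.shape[1])], name="gene_id")
    return ExpressionTimecourse(counts=counts, cell_meta=meta, gene_ids=genes)


class TestQcAndFilters:
    def test_bounds_inclusive_mito_strict(self):
        # three cells: at the bounds, inside, and at the mito threshold
        counts = np.array([[8500, 0], [20000, 0], [9300, 700]])
        tc = make_tc(counts, [0.0, 0.0, 0.0])
        tc.gene_ids = pd.Index(["gene", "MT-ND1"], name="gene_id")
        tc = compute_qc(tc)
        kept = filter_cells(
            tc, min_counts=8500, max_counts=35000, max_pct_mito=7.0
        )
        assert list(kept.cell_meta.index) == ["c0", "c1"]  # c2 has 7.0% mito

    def test_no_thresholds_is_identity(self):
        tc = compute_qc(make_tc(np.ones((4, 3), dtype=int), [0.0] * 4))
        assert len(filter_cells(tc).cell_meta) == 4

    def test_all_removed_errors(self):
        tc = compute_qc(make_tc(np.ones((2, 2), dtype=int), [0.0, 0.0]))
        with pytest.raises(ValueError, match="every cell"):
            filter_cells(tc, min_counts=10)


class TestNormalize:
    def test_log1p_formula(self):
        tc = make_tc([[1, 9999]], [0.0])
        norm = normalize(tc, scale=10_000).normalized
        assert norm[0, 0] == pytest.approx(np.log(2.0))

    def test_scale_invariance_per_cell(self):
        base = make_tc([[3, 7, 0]], [0.0])
        doubled = make_tc([[6, 14, 0]], [0.0])
        assert np.allclose(
            normalize(base).normalized, normalize(doubled).normalized
        )

    def test_zero_count_cell_errors(self):
        with pytest.raises(ValueError, match="zero total"):
            normalize(make_tc([[0, 0]], [0.0]))

    def test_all_zero_gene_stays_zero(self):
        norm = normalize(make_tc([[5, 0], [3, 0]], [0.0, 2.0])).normalized
        assert (norm[:, 1] == 0).all()


class TestFilterGenes:
    def test_per_timepoint_rule(self):
        # gene 1 is well expressed at 0 h but silent at 2 h
        counts = np.array([[50, 50, 1], [50, 50, 1], [50, 0, 1], [50, 0, 1]])
        tc = normalize(make_tc(counts, [0.0, 0.0, 2.0, 2.0]))
        kept = filter_genes(tc, min_mean=0.01)
        assert list(kept.gene_ids) == ["g0", "g2"]

    def test_pooled_variant_keeps_it(self):
        counts = np.array([[50, 50, 1], [50, 50, 1], [50, 0, 1], [50, 0, 1]])
        tc = normalize(make_tc(counts, [0.0, 0.0, 2.0, 2.0]))
        kept = filter_genes(tc, min_mean=0.01, per_timepoint=False)
        assert "g1" in kept.gene_ids

    def test_zero_cutoff_removes_only_silent_genes(self):
        counts = np.array([[5, 0, 1], [3, 0, 1]])
        tc = normalize(make_tc(counts, [0.0, 0.0]))
        assert list(filter_genes(tc, min_mean=0.0).gene_ids) == ["g0", "g2"]


class TestCallDifferential:
    def test_identical_samples(self):
        counts = np.tile([[4, 7]], (10, 1))
        tc = normalize(make_tc(counts, [0.0] * 5 + [2.0] * 5))
        de = call_differential(tc, 2.0)
        assert (de["p"] == 1.0).all()
        assert (de["direction"] == 0.0).all()

    def test_planted_shift_detected(self, rng):
        base = rng.poisson(5.0, size=(1000, 1))
        shifted = rng.poisson(10.0, size=(500, 1))
        counts = np.hstack([
            np.vstack([base[:500], shifted]),
            rng.poisson(20.0, size=(1000, 1)),  # stable reference gene
        ])
        tc = normalize(make_tc(counts, [0.0] * 500 + [2.0] * 500))
        de = call_differential(tc, 2.0)
        assert de.loc["g0", "p"] < 1e-6
        assert de.loc["g0", "direction"] > 0

    def test_matches_permutation_oracle(self, rng):
        for trial in range(20):
            a = rng.normal(0, 1, 12)
            b = rng.normal(0.5, 1, 10)
            counts = np.vstack([a[:, None], b[:, None]])
            # embed into a tc with an extra constant-ish gene for normalization
            counts = np.hstack([np.exp(counts), np.full((22, 1), 50.0)])
            tc = make_tc(np.round(counts * 10).astype(int), [0.0] * 12 + [2.0] * 10)
            tc = normalize(tc)
            p_pkg = call_differential(tc, 2.0).loc["g0", "p"]
            x = tc.normalized[:12, 0]
            y = tc.normalized[12:, 0]
            obs = abs(stats.mannwhitneyu(x, y).statistic - len(x) * len(y) / 2)
            pooled = np.concatenate([x, y])
            perm_rng = np.random.default_rng(trial)
            hits = 0
            n_perm = 600
            for _ in range(n_perm):
                perm_rng.shuffle(pooled)
                u = stats.mannwhitneyu(pooled[:12], pooled[12:]).statistic
                hits += abs(u - len(x) * len(y) / 2) >= obs - 1e-9
            p_perm = hits / n_perm
            assert abs(p_pkg - p_perm) < 4 * np.sqrt(p_perm * (1 - p_perm) / n_perm) + 0.05


class TestAssignTrajectories:
    def _de(self, p, direction):
        return pd.DataFrame(
            {"p": p, "direction": direction}, index=["g0", "g1", "g2"]
        )

    def test_classification_rules(self):
        de = {
            2.0: self._de([0.001, 0.2, 0.9], [1, -1, 1]),
            4.0: self._de([0.5, 0.001, 0.8], [1, -1, -1]),
            8.0: self._de([0.5, 0.9, 0.7], [1, 1, 1]),
        }
        out = assign_trajectories(de, correction="none")
        assert out.loc["g0", "trajectory"] == "EarlyUp"
        assert out.loc["g1", "trajectory"] == "LateDown"
        assert out.loc["g2", "trajectory"] == "Unlabeled"

    def test_first_significant_timepoint_sets_late_direction(self):
        de = {
            2.0: self._de([0.9, 0.9, 0.9], [1, 1, 1]),
            4.0: self._de([0.001, 0.9, 0.9], [1, 1, 1]),
            8.0: self._de([0.001, 0.001, 0.9], [-1, -1, 1]),
        }
        out = assign_trajectories(de, correction="none")
        assert out.loc["g0", "trajectory"] == "LateUp"  # 4 h direction wins
        assert out.loc["g1", "trajectory"] == "LateDown"


class TestControlsAndLevels:
    def test_stratified_controls_match_bins(self, rng):
        means = pd.Series(
            np.sort(rng.lognormal(0, 1, 400)), index=[f"g{i:03d}" for i in range(400)]
        )
        labels = pd.Series("Unlabeled", index=means.index, dtype=object)
        regulated = means.index[::7]
        labels[regulated] = "EarlyUp"
        controls = select_controls(labels, means, seed=1)
        assert len(controls) == len(regulated)
        assert set(controls).isdisjoint(regulated)
        bins = mean_bins(means)
        assert (
            bins.loc[list(controls)].value_counts().sort_index()
            == bins.loc[regulated].value_counts().sort_index()
        ).all()

    def test_control_means_distributionally_matched(self, rng):
        means = pd.Series(
            rng.lognormal(0, 1, 4000), index=[f"g{i:04d}" for i in range(4000)]
        )
        labels = pd.Series("Unlabeled", index=means.index, dtype=object)
        # regulated genes biased toward high means, as in real data
        high = means.nlargest(2000).index
        labels[high[::2]] = "EarlyUp"
        controls = select_controls(labels, means, seed=2)
        ks = stats.ks_2samp(means[list(controls)], means[labels == "EarlyUp"])
        assert ks.pvalue > 0.1

    def test_exhausted_bin_errors(self):
        means = pd.Series(np.arange(20, dtype=float), index=[f"g{i:02d}" for i in range(20)])
        labels = pd.Series("EarlyUp", index=means.index, dtype=object)
        labels.iloc[:2] = "Unlabeled"
        with pytest.raises(ValueError, match="bin"):
            select_controls(labels, means, n_bins=2, seed=0)

    def test_mean_levels_20_60_20(self):
        means = pd.Series(
            np.arange(10, dtype=float), index=[f"g{i}" for i in range(10)]
        )
        levels = classify_mean_levels(means)
        assert (levels.value_counts() == pd.Series({"Mid": 6, "Low": 2, "High": 2})).all()

    def test_rank_invariance(self, rng):
        means = pd.Series(rng.lognormal(0, 1, 50), index=[f"g{i:02d}" for i in range(50)])
        a = classify_mean_levels(means)
        b = classify_mean_levels(np.log(means) * 3 + 7)
        assert (a == b).all()

    def test_degenerate_means_error(self):
        means = pd.Series(np.ones(10), index=[f"g{i}" for i in range(10)])
        with pytest.raises(ValueError, match="identical"):
            classify_mean_levels(means)


class TestAdjustedCV:
    def test_gene_on_fitted_curve_has_zero_adjustment(self, rng):
        means = np.sort(rng.lognormal(0, 1, 200))
        cvs = 1.0 / np.sqrt(means) + rng.normal(0, 0.05, 200)
        cvs = np.clip(cvs, 0.01, None)
        model = CVNoiseModel().fit(means, cvs)
        # a new gene placed exactly on the fitted curve
        on_curve_cv = 2.0 ** model.fitted_log2_[50] - 1.0
        adj = model.transform(means[[50]], [on_curve_cv])
        assert adj[0] == pytest.approx(0.0, abs=1e-9)

    def test_constant_shift_leaves_residuals_unchanged(self, rng):
        means = np.sort(rng.lognormal(0, 1, 300))
        cvs = 1.0 / np.sqrt(means) + rng.normal(0, 0.05, 300)
        cvs = np.clip(cvs, 0.01, None)
        r1 = CVNoiseModel().fit_transform(means, cvs)
        # shift y = log2(cv+1) by a constant -> same residuals
        shifted = 2.0 ** (np.log2(cvs + 1.0) + 0.7) - 1.0
        r2 = CVNoiseModel().fit_transform(means, shifted)
        assert np.allclose(
            np.log2(r1 + 1.0), np.log2(r2 + 1.0), atol=1e-6
        )

    def test_removes_mean_dependence_on_nb_data(self, rng):
        # study conditions: 500 cells, 20/60/20 dispersion classes
        n = 3000
        means = rng.lognormal(np.log(0.5), 1.0, n)
        phi = rng.choice([0.1, 0.5, 2.5], n, p=[0.2, 0.6, 0.2])
        x = rng.negative_binomial(1.0 / phi, 1.0 / (1.0 + means * phi), (500, n))
        norm = np.log1p(1e4 * x / x.sum(axis=1, keepdims=True))
        gm = norm.mean(axis=0)
        keep = gm > 0.01
        cv = norm.std(axis=0, ddof=1)[keep] / gm[keep]
        adj = CVNoiseModel().fit_transform(gm[keep], cv)
        rho = stats.spearmanr(adj, gm[keep]).statistic
        assert abs(rho) < 0.1

    def test_too_few_genes_error(self):
        with pytest.raises(ValueError, match=">= 30"):
            CVNoiseModel().fit(np.arange(10.0) + 1, np.ones(10))


class TestAssignNoiseLevels:
    def test_quantile_counts_per_bin(self, rng):
        n = 1000
        table = pd.DataFrame(
            {
                "mean": rng.lognormal(0, 1, n),
                "adjusted_cv": rng.normal(0, 1, n),
            },
            index=[f"g{i:04d}" for i in range(n)],
        )
        out = assign_noise_levels(table)
        for b, sub in out.groupby("mean_bin"):
            counts = sub["noise_level"].value_counts()
            assert counts["High"] == 20
            assert counts["Low"] == 20
            assert counts["Mid"] == 60

    def test_small_bin_errors(self, rng):
        table = pd.DataFrame(
            {"mean": np.arange(12.0), "adjusted_cv": np.arange(12.0)},
            index=[f"g{i}" for i in range(12)],
        )
        with pytest.raises(ValueError, match="< 5"):
            assign_noise_levels(table, n_bins=10)


class TestCompareCovariate:
    def _setup(self, rng, shift=0.0, n=300):
        control = rng.normal(10, 2, n)
        group = rng.normal(10 + shift * 2, 2, n)
        cov = pd.Series(
            np.concatenate([group, control]),
            index=[f"g{i:04d}" for i in range(2 * n)],
        )
        labels = pd.Series(
            ["EarlyDown"] * n + ["Control"] * n, index=cov.index
        )
        return labels, cov

    def test_identical_groups(self, rng):
        labels, cov = self._setup(rng, shift=0.0)
        p, shift = compare_covariate(labels, cov, "EarlyDown", "Control")
        assert p > 0.01
        assert abs(shift) < 0.25

    def test_exact_one_sd_shift(self):
        control = pd.Series(np.arange(100, dtype=float))
        sd = control.std(ddof=1)
        cov = pd.Series(
            np.concatenate([control + sd, control]),
            index=[f"g{i:03d}" for i in range(200)],
        )
        labels = pd.Series(["G"] * 100 + ["C"] * 100, index=cov.index)
        _, shift = compare_covariate(labels, cov, "G", "C")
        assert shift == pytest.approx(1.0)

    def test_planted_negative_shift_recovered(self, rng):
        labels, cov = self._setup(rng, shift=-0.5)
        p, shift = compare_covariate(labels, cov, "EarlyDown", "Control")
        assert p < 0.01
        assert shift == pytest.approx(-0.5, abs=0.1)

    def test_missing_covariate_errors(self, rng):
        labels, cov = self._setup(rng)
        cov[labels == "EarlyDown"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            compare_covariate(labels, cov, "EarlyDown", "Control")


class TestMtxRoundtrip:
    def test_write_read_counts(self, tmp_path, small_genes, small_truth, small_config):
        tc = generate_expression(small_genes, small_truth, small_config, seed=9)
        write_counts(
            tc, tmp_path / "m.mtx", tmp_path / "cells.tsv", tmp_path / "genes.tsv"
        )
        back = read_counts_mtx(
            tmp_path / "m.mtx", tmp_path / "cells.tsv", tmp_path / "genes.tsv"
        )
        assert np.array_equal(back.counts, tc.counts)
        assert list(back.gene_ids) == list(tc.gene_ids)
        assert (back.cell_meta["timepoint"] == tc.cell_meta["timepoint"]).all()
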