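"""Tier-2 screen: detection filter, normalisation, moderation, FDR, congruence."""

import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import chemoscreen as cs
from chemoscreen.paired import quantile_normalize


def _expr(values, probes=None, samples=None, detection=None, scale="log2"):
    n, m = np.asarray(values).shape
    probes = probes or [f"p{i}" for i in range(n)]
    samples = samples or [f"s{j}" for j in range(m)]
    df = pd.DataFrame(values, index=probes, columns=samples)
    det = (
        pd.DataFrame(detection, index=probes, columns=samples)
        if detection is not None
        else None
    )
    return cs.ExpressionMatrix(df, det, scale=scale)


class TestDetectionFilter:
    def test_undetected_probe_dropped(self):
        expr = _expr([[5.0, 5.0]], detection=[[0.5, 0.5]])
        out = cs.detection_filter(expr, 0.01)
        assert out.n_probes == 0

    def test_single_detected_sample_retains(self):
        expr = _expr([[5.0, 5.0]], detection=[[0.5, 0.001]])
        out = cs.detection_filter(expr, 0.01)
        assert out.probe_ids == ["p0"]

    def test_planted_detectable_count_recovered(self):
        # plant a known number of detectable probes in a larger grid
        rng = np.random.default_rng(77)
        n_probes, n_det = 2000, 887
        detection = rng.uniform(0.02, 1.0, (n_probes, 6))
        detectable = rng.choice(n_probes, n_det, replace=False)
        detection[detectable, rng.integers(0, 6, n_det)] = 1e-4
        expr = _expr(rng.normal(8, 1, (n_probes, 6)), detection=detection)
        out = cs.detection_filter(expr, 0.01)
        assert out.n_probes == n_det

    def test_missing_grid_is_config_error(self):
        with pytest.raises(cs.ContractError):
            cs.detection_filter(_expr([[1.0, 2.0]]), 0.01)


class TestQuantileNormalize:
    def test_identical_columns_unchanged_after_log2(self):
        col = np.array([[4.0], [16.0], [1.0]])
        expr = _expr(np.hstack([col, col]), scale="raw")
        out = cs.normalize_log_quantile(expr)
        assert np.allclose(out.values.to_numpy(), np.log2(np.hstack([col, col])))
        assert out.scale == "log2"

    def test_permuted_columns_identical_sorted(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(1, 100, 50)
        expr = _expr(np.column_stack([a, rng.permutation(a)]), scale="raw")
        out = cs.normalize_log_quantile(expr).values.to_numpy()
        assert np.allclose(np.sort(out[:, 0]), np.sort(out[:, 1]))

    def test_column_means_equalised(self):
        rng = np.random.default_rng(4)
        values = rng.lognormal(3, 1, (500, 8))
        out = cs.normalize_log_quantile(_expr(values, scale="raw")).values.to_numpy()
        means = out.mean(axis=0)
        assert np.ptp(means) < 1e-12

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(ValueError):
            cs.normalize_log_quantile(_expr([[1.0, 0.0]], scale="raw"))

    def test_quantile_normalize_preserves_ranks_per_column(self):
        rng = np.random.default_rng(5)
        values = rng.normal(0, 1, (100, 4))
        out = quantile_normalize(values)
        for j in range(4):
            assert np.array_equal(np.argsort(out[:, j]), np.argsort(values[:, j]))


class TestEstimateModeration:
    def test_equal_variances_give_infinite_prior(self):
        params = cs.estimate_moderation(np.full(100, 4.0), 8)
        assert math.isinf(params.prior_df)
        assert params.prior_var == pytest.approx(4.0)

    def test_hyperparameter_recovery(self):
        # s^2 ~ s0^2 * F(d, d0) with d0 = 4, s0^2 = 1
        rng = np.random.default_rng(11)
        d, d0 = 8, 4.0
        v = (rng.chisquare(d, 5000) / d) / (rng.chisquare(d0, 5000) / d0)
        params = cs.estimate_moderation(v, d)
        assert 2.0 <= params.prior_df <= 8.0
        assert 0.8 <= params.prior_var <= 1.25

    def test_matches_limma_fitFDist(self, tmp_path):
        """Independent R oracle: limma's scaled-F moment fit on the same data."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        rng = np.random.default_rng(5)
        d = 6
        v = (rng.chisquare(d, 300) / d) * (0.5 + rng.gamma(2.0, 0.5, 300))
        vfile = tmp_path / "vars.txt"
        np.savetxt(vfile, v)
        script = (
            "suppressMessages(library(limma));"
            f"v <- scan('{vfile}', quiet=TRUE);"
            "f <- limma::fitFDist(v, df1=6);"
            "cat(f$scale, f$df2)"
        )
        res = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=120
        )
        if res.returncode != 0:
            pytest.skip(f"limma oracle failed to run: {res.stderr[:200]}")
        scale, df2 = map(float, res.stdout.split())
        params = cs.estimate_moderation(v, d)
        assert params.prior_var == pytest.approx(scale, rel=1e-4)
        assert params.prior_df == pytest.approx(df2, rel=1e-4)

    def test_too_few_probes(self):
        with pytest.raises(cs.ContractError):
            cs.estimate_moderation(np.array([1.0, 2.0]), 4)

    def test_all_zero_variances(self):
        with pytest.raises(ValueError):
            cs.estimate_moderation(np.zeros(100), 4)


def _single_pair_design(reps=3):
    sens = [f"S{r}" for r in range(reps)]
    res = [f"R{r}" for r in range(reps)]
    return cs.PairedDesign([cs.PairRecord("PAIR1", sens, res)]), sens + res


class TestModeratedPairTest:
    def test_prior_df_zero_equals_ordinary_pooled_t(self):
        rng = np.random.default_rng(21)
        design, samples = _single_pair_design(4)
        values = rng.normal(8, 1, (60, 8))
        expr = _expr(values, samples=samples)
        params = cs.ModerationParams(prior_df=0.0, prior_var=1.0)
        records = cs.moderated_pair_test(expr, design, params)
        t_ref, p_ref = stats.ttest_ind(values[:, :4].T, values[:, 4:].T, equal_var=True)
        got_t = np.array([r.pair_stats["PAIR1"].moderated_t for r in records])
        got_p = np.array([r.pair_stats["PAIR1"].raw_p for r in records])
        assert np.allclose(got_t, t_ref, atol=1e-10)
        assert np.allclose(got_p, p_ref, atol=1e-10)

    def test_planted_fold_change_recovered(self):
        planted = [cs.PlantedFoldChange("TARGET", 1.0)]
        expr, design, pmap = cs.gen_paired_experiment(
            cs.PairedSpec(n_probes=500, planted=planted, noise_sd=0.25, seed=14)
        )
        records = cs.moderated_pair_test(expr, design, probe_gene_map=pmap)
        rec = next(r for r in records if r.gene_symbol == "TARGET")
        for ps in rec.pair_stats.values():
            assert 1.6 <= ps.fold_change <= 2.5

    def test_flat_probe_has_unit_fold_change(self):
        design, samples = _single_pair_design(3)
        values = np.vstack([np.full(6, 7.0), np.random.default_rng(1).normal(8, 1, (99, 6))])
        expr = _expr(values, samples=samples)
        records = cs.moderated_pair_test(expr, design)
        cs.attach_fdr(records)
        assert records[0].pair_stats["PAIR1"].fold_change == pytest.approx(1.0)
        cs.congruence_filter(records)
        assert records[0].direction == "none"

    def test_moderated_variance_is_convex_combination(self):
        rng = np.random.default_rng(2)
        s2 = rng.chisquare(4, 200) / 4
        params = cs.ModerationParams(prior_df=4.0, prior_var=1.0)
        v = cs.moderated_variance(s2, 6.0, params)
        lo = np.minimum(s2, params.prior_var)
        hi = np.maximum(s2, params.prior_var)
        assert np.all(v >= lo - 1e-12) and np.all(v <= hi + 1e-12)

    def test_moderated_t_approaches_ordinary_t_with_replicates(self):
        # shrinkage washes out as residual df grows
        rng = np.random.default_rng(31)
        max_diffs = []
        for reps in (3, 6, 12):
            design, samples = _single_pair_design(reps)
            values = rng.normal(8, 1, (200, 2 * reps))
            expr = _expr(values, samples=samples)
            records = cs.moderated_pair_test(
                expr, design, cs.ModerationParams(prior_df=4.0, prior_var=1.0)
            )
            t_mod = np.array([r.pair_stats["PAIR1"].moderated_t for r in records])
            t_ref, _ = stats.ttest_ind(
                values[:, :reps].T, values[:, reps:].T, equal_var=True
            )
            max_diffs.append(np.max(np.abs(t_mod - t_ref)))
        assert max_diffs[0] > max_diffs[1] > max_diffs[2]

    def test_single_replicate_group_rejected(self):
        design = cs.PairedDesign([cs.PairRecord("P", ["a"], ["b", "c"])])
        expr = _expr(np.zeros((60, 3)), samples=["a", "b", "c"])
        with pytest.raises(ValueError, match="replicates"):
            cs.moderated_pair_test(expr, design, cs.ModerationParams(1.0, 1.0))


def brute_force_bh(p):
    """Double-loop BH step-up q-values, straight from the definition."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [None] * m
    for pos, i in enumerate(order, start=1):
        q[i] = min(
            min(m * p[j] / (rank + 1) for rank, j in enumerate(order) if rank + 1 >= pos),
            1.0,
        )
    return q


class TestBhFdr:
    def test_hand_computed_example(self):
        q = cs.bh_fdr(np.array([0.01, 0.02, 0.03]))
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_single_p(self):
        assert cs.bh_fdr(np.array([0.2]))[0] == pytest.approx(0.2)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(41)
        p = rng.uniform(size=1000)
        q = cs.bh_fdr(p)
        assert np.array_equal(q, np.array(brute_force_bh(list(p))))

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(43)
        p = rng.uniform(size=500)
        q = cs.bh_fdr(p)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(q, q_sm, atol=1e-12)

    def test_monotone_in_sorted_order(self):
        rng = np.random.default_rng(44)
        p = rng.uniform(size=300)
        q = cs.bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cs.bh_fdr(np.array([0.0, 0.5]))


class TestCongruenceFilter:
    def _record(self, fc_by_pair, raw_p=1e-4, q=1e-3, gene="G"):
        pair_stats = {
            name: cs.PairStats(fc, math.log2(fc), 5.0, raw_p)
            for name, fc in fc_by_pair.items()
        }
        rec = cs.DifferentialRecord("p", gene, pair_stats, combined_p=raw_p)
        rec.fdr_q = q
        return rec

    def test_directional_incongruence_fails(self):
        rec = self._record({"A": 2.0, "B": 0.4})
        sens, res = cs.congruence_filter([rec])
        assert not rec.congruent and sens == set() and res == set()

    def test_threshold_edge_fails(self):
        rec = self._record({"A": 1.4, "B": 2.0})
        cs.congruence_filter([rec], fc_min=1.5)
        assert not rec.congruent
        # exactly at the threshold also fails (exclusive rule)
        rec2 = self._record({"A": 1.5, "B": 2.0})
        cs.congruence_filter([rec2], fc_min=1.5)
        assert not rec2.congruent

    def test_passing_probe_assigned_by_direction(self):
        up = self._record({"A": 2.0, "B": 1.8}, gene="UPGENE")
        down = self._record({"A": 0.4, "B": 0.5}, gene="DOWNGENE")
        sens, res = cs.congruence_filter([up, down])
        assert sens == {"UPGENE"} and res == {"DOWNGENE"}
        assert up.direction == "higher_in_sensitive"

    def test_planted_signature_recovered_exactly(self):
        # mirrors the paired-screen scale: 20 sensitivity + 38 resistance genes
        planted = [cs.PlantedFoldChange(f"SENS{i:02d}", 1.2) for i in range(20)] + [
            cs.PlantedFoldChange(f"RES{i:02d}", -1.2) for i in range(38)
        ]
        expr, design, pmap = cs.gen_paired_experiment(
            cs.PairedSpec(n_probes=5100, planted=planted, seed=99, absent_fraction=0.0)
        )
        records = cs.moderated_pair_test(expr, design, probe_gene_map=pmap)
        cs.attach_fdr(records)
        sens, res = cs.congruence_filter(records)
        assert sens == {p.gene for p in planted[:20]}
        assert res == {p.gene for p in planted[20:]}
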