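"""TMT quantitation: QC, transforms, normalization, and the moderated test.

The moderated t machinery is checked along two independent routes: a plain
scripted-arithmetic oracle (group means, pooled variances, shrinkage by hand)
and the reference empirical-Bayes implementation in the R limma package,
driven through Rscript on a small fixture.
"""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from matrisopy import simulate, tmt


def _two_group_exp(values, stage_a="larva", stage_b="adult"):
    """Build a normalized-scale experiment from an array with the first half
    of columns in stage A, the rest in stage B."""
    values = np.asarray(values, float)
    m, n = values.shape
    half = n // 2
    sample_ids = [f"s{j}" for j in range(n)]
    samples = pd.DataFrame({
        "life_stage": [stage_a] * half + [stage_b] * (n - half),
        "replicate": [str(j % half + 1) for j in range(n)],
        "batch": ["1"] * n,
    }, index=sample_ids)
    proteins = pd.DataFrame({
        "unique_peptides": np.full(m, 5), "contaminant": np.zeros(m, bool)},
        index=[f"P{i}" for i in range(m)])
    matrix = pd.DataFrame(values, index=proteins.index, columns=sample_ids)
    return tmt.TMTExperiment(matrix, proteins, samples, scale="normalized")


class TestQCFilter:
    def test_counting_with_planted_contaminants(self):
        bundle = simulate.generate_tmt(
            m_proteins=100, contaminant_rate=0.0, single_peptide_rate=0.0,
            seed=0)
        exp = bundle.experiment
        exp.proteins.iloc[:10, exp.proteins.columns.get_loc("contaminant")] = True
        exp.proteins.iloc[10:15, exp.proteins.columns.get_loc(
            "unique_peptides")] = 1
        out = tmt.qc_filter(exp)
        assert out.n_proteins == 85
        assert out.log["qc_removed_contaminant"] == 10
        assert out.log["qc_removed_low_peptides"] == 5

    def test_contaminant_flag_dominates_peptide_count(self):
        bundle = simulate.generate_tmt(m_proteins=20, contaminant_rate=0.0,
                                       single_peptide_rate=0.0, seed=1)
        exp = bundle.experiment
        exp.proteins.iloc[0] = [10, True]  # many peptides, still contaminant
        out = tmt.qc_filter(exp)
        assert exp.proteins.index[0] not in out.matrix.index


class TestLog2:
    def test_exact_values(self):
        exp = _two_group_exp([[8.0, 1.0, 4.0, 2.0]])
        exp.scale = "raw"
        out = tmt.log2_transform(exp)
        assert out.matrix.to_numpy().tolist() == [[3.0, 0.0, 2.0, 1.0]]
        assert out.scale == "log2"

    def test_zeros_become_missing(self):
        exp = _two_group_exp([[8.0, 0.0, 4.0, 2.0]])
        exp.scale = "raw"
        out = tmt.log2_transform(exp)
        assert np.isnan(out.matrix.iloc[0, 1])
        assert out.log["zeros_set_missing"] == 1

    def test_negative_intensity_rejected(self):
        exp = _two_group_exp([[8.0, -1.0, 4.0, 2.0]])
        exp.scale = "raw"
        with pytest.raises(ValueError, match="negative"):
            tmt.log2_transform(exp)

    def test_round_trip_recovers_exponent(self):
        rng = np.random.default_rng(0)
        x = rng.normal(20, 2, size=(40, 6))
        exp = _two_group_exp(2.0 ** x)
        exp.scale = "raw"
        out = tmt.log2_transform(exp)
        np.testing.assert_allclose(out.matrix.to_numpy(), x, rtol=1e-12)


class TestBatchRemoval:
    def _exp_with_batches(self, values, batch):
        exp = _two_group_exp(values)
        exp.samples["batch"] = batch
        exp.scale = "log2"
        return exp

    def test_constructed_additive_offset_removed(self):
        # signal follows the model exactly: protein baseline + stage effect
        rng = np.random.default_rng(3)
        baseline = rng.normal(20, 1, size=(30, 1))
        stage_effect = np.repeat(rng.normal(0, 1, size=(30, 2)), 4, axis=1)
        signal = baseline + stage_effect
        delta = 1.7
        batch = ["1", "1", "2", "2", "1", "1", "2", "2"]
        corrupted = signal + np.where(np.array(batch) == "2", delta, 0.0)
        exp = self._exp_with_batches(corrupted, batch)
        out = tmt.remove_batch_effects(exp)
        np.testing.assert_allclose(out.matrix.to_numpy(), signal, atol=1e-8)

    def test_single_batch_is_identity(self):
        rng = np.random.default_rng(4)
        exp = self._exp_with_batches(rng.normal(size=(10, 4)),
                                     ["1", "1", "1", "1"])
        out = tmt.remove_batch_effects(exp)
        np.testing.assert_array_equal(out.matrix.to_numpy(),
                                      exp.matrix.to_numpy())

    def test_residualization_idempotent(self):
        """Refitting after correction gives batch coefficients ~ 0."""
        rng = np.random.default_rng(5)
        batch = ["1", "2", "1", "2", "1", "2"]
        exp = self._exp_with_batches(rng.normal(size=(20, 6)), batch)
        once = tmt.remove_batch_effects(exp)
        twice = tmt.remove_batch_effects(once)
        np.testing.assert_allclose(twice.matrix.to_numpy(),
                                   once.matrix.to_numpy(), atol=1e-8)

    def test_confounded_design_rejected(self):
        rng = np.random.default_rng(6)
        # batch == stage: perfectly confounded
        exp = self._exp_with_batches(rng.normal(size=(10, 4)),
                                     ["1", "1", "2", "2"])
        with pytest.raises(ValueError, match="confounded"):
            tmt.remove_batch_effects(exp)


class TestNormalize:
    def test_median_center_aligns_constant_shift(self):
        rng = np.random.default_rng(7)
        base = rng.normal(20, 1, size=(50, 1))
        values = np.hstack([base, base + 3.0, base - 1.5, base + 0.2])
        exp = _two_group_exp(values)
        exp.scale = "log2"
        out = tmt.vs_normalize(exp, "median_center")
        medians = np.median(out.matrix.to_numpy(), axis=0)
        np.testing.assert_allclose(medians, medians[0], atol=1e-12)
        # shift-only columns become identical after calibration
        np.testing.assert_allclose(out.matrix.iloc[:, 0], out.matrix.iloc[:, 1],
                                   atol=1e-10)

    def test_affine_arsinh_identical_samples_equal_columns(self):
        rng = np.random.default_rng(8)
        col = rng.lognormal(10, 1, size=(60, 1))
        exp = _two_group_exp(np.hstack([col, col, col, col]))
        exp.scale = "raw"
        out = tmt.vs_normalize(exp, "affine_arsinh")
        arr = out.matrix.to_numpy()
        assert np.max(np.abs(arr - arr[:, [0]])) < 1e-6
        assert out.scale == "normalized"

    def test_affine_arsinh_strictly_increasing(self):
        rng = np.random.default_rng(9)
        # shared per-protein abundance structure, multiplicative noise
        base = rng.lognormal(10, 1, size=(80, 1))
        values = base * rng.lognormal(0, 0.2, size=(80, 4))
        exp = _two_group_exp(values)
        exp.scale = "raw"
        out = tmt.vs_normalize(exp, "affine_arsinh")
        for j in range(4):
            order = np.argsort(values[:, j])
            transformed = out.matrix.to_numpy()[order, j]
            assert np.all(np.diff(transformed) > 0)


class TestEBFit:
    def test_parameter_recovery_from_scaled_f_model(self):
        d0_true, s0_true, m, df = 4.0, 0.05, 2000, 9
        rng = np.random.default_rng(123)
        s0_g = d0_true * s0_true / rng.chisquare(d0_true, size=m)
        s2 = s0_g * rng.chisquare(df, size=m) / df
        eb = tmt.fit_eb_parameters([(v, df) for v in s2])
        assert abs(eb.d0 - d0_true) / d0_true < 0.15
        assert abs(eb.s0_sq - s0_true) / s0_true < 0.15

    def test_identical_variances_give_infinite_d0(self):
        eb = tmt.fit_eb_parameters([(0.2, 5)] * 20)
        assert np.isinf(eb.d0)
        assert eb.s0_sq == pytest.approx(0.2, rel=1e-6)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(10)
        pairs = [(v, 6) for v in rng.chisquare(6, size=50) / 6 * 0.1]
        eb1 = tmt.fit_eb_parameters(pairs)
        eb2 = tmt.fit_eb_parameters(list(reversed(pairs)))
        assert eb1.d0 == pytest.approx(eb2.d0, rel=1e-9)
        assert eb1.s0_sq == pytest.approx(eb2.s0_sq, rel=1e-9)

    def test_too_few_proteins_rejected(self):
        with pytest.raises(ValueError, match=">= 10"):
            tmt.fit_eb_parameters([(0.1, 5)] * 9)

    def test_trigamma_inverse_inverts(self):
        from scipy.special import polygamma
        for x in (0.1, 1.0, 7.3, 50.0):
            y = float(polygamma(1, x))
            assert tmt.trigamma_inverse(y) == pytest.approx(x, rel=1e-8)


class TestModeratedT:
    def test_identical_groups_are_null(self):
        values = np.tile(np.array([[3.0, 5.0, 7.0]]), (1, 2))  # A == B
        exp = _two_group_exp(np.vstack([values] * 12))
        table = tmt.moderated_ttest(exp, ("larva", "adult"), blocks=())
        assert np.allclose(table["log2_fc"], 0.0)
        assert np.allclose(table["moderated_t"], 0.0)
        assert np.allclose(table["p"], 1.0)

    def test_d0_zero_matches_ordinary_t(self):
        rng = np.random.default_rng(11)
        values = rng.normal(size=(25, 8))
        exp = _two_group_exp(values)
        eb = tmt.EBParameters(d0=0.0, s0_sq=1.0)
        table = tmt.moderated_ttest(exp, ("larva", "adult"), blocks=(), eb=eb)
        t_ref, p_ref = stats.ttest_ind(values[:, :4], values[:, 4:], axis=1)
        np.testing.assert_allclose(table["moderated_t"], t_ref, atol=1e-10)
        np.testing.assert_allclose(table["p"], p_ref, atol=1e-10)

    def test_brute_force_arithmetic_oracle(self):
        """4x6 two-group fit with fixed prior vs scripted arithmetic."""
        values = np.array([
            [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            [0.5, 0.4, 0.6, 2.0, 2.2, 1.8],
            [10., 10., 10., 10., 10., 10.],
            [3.0, 1.0, 2.0, 9.0, 7.0, 8.0],
        ])
        d0, s0 = 3.0, 0.1
        exp = _two_group_exp(values)
        table = tmt.moderated_ttest(
            exp, ("larva", "adult"), blocks=(),
            eb=tmt.EBParameters(d0=d0, s0_sq=s0))
        a, b = values[:, :3], values[:, 3:]
        fc = a.mean(axis=1) - b.mean(axis=1)
        s2 = (((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
              + ((b - b.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)) / 4.0
        post = (d0 * s0 + 4.0 * s2) / (d0 + 4.0)
        t_ref = fc / np.sqrt(post * (1 / 3 + 1 / 3))
        p_ref = 2.0 * stats.t.sf(np.abs(t_ref), d0 + 4.0)
        np.testing.assert_allclose(table["log2_fc"], fc, atol=1e-10)
        np.testing.assert_allclose(table["moderated_t"], t_ref, atol=1e-10)
        np.testing.assert_allclose(table["p"], p_ref, atol=1e-10)

    def test_shrinkage_brackets_variances(self, tmt_bundle):
        exp = tmt.vs_normalize(tmt.log2_transform(
            tmt.qc_filter(tmt_bundle.experiment)), "median_center")
        model = tmt.DifferentialAbundanceModel(exp, blocks=("batch",))
        res = model.fit()
        table = res.frame(("primary_polyp", "larva"))
        lo = np.minimum(table["s2"], res.eb.s0_sq)
        hi = np.maximum(table["s2"], res.eb.s0_sq)
        assert ((lo - 1e-12 <= table["posterior_s2"])
                & (table["posterior_s2"] <= hi + 1e-12)).all()

    def test_infinite_d0_uses_pooled_variance_and_normal_tail(self):
        rng = np.random.default_rng(12)
        values = rng.normal(size=(15, 8))
        exp = _two_group_exp(values)
        eb = tmt.EBParameters(d0=np.inf, s0_sq=0.5)
        table = tmt.moderated_ttest(exp, ("larva", "adult"), blocks=(), eb=eb)
        fc = values[:, :4].mean(axis=1) - values[:, 4:].mean(axis=1)
        t_ref = fc / np.sqrt(0.5 * 0.5)
        np.testing.assert_allclose(table["moderated_t"], t_ref, atol=1e-10)
        np.testing.assert_allclose(
            table["p"], 2 * stats.norm.sf(np.abs(t_ref)), atol=1e-12)

    def test_deterministic_rerun_bit_identical(self, tmt_bundle):
        exp = tmt.vs_normalize(tmt.log2_transform(
            tmt.qc_filter(tmt_bundle.experiment)), "median_center")
        t1 = tmt.moderated_ttest(exp, ("adult", "larva"))
        t2 = tmt.moderated_ttest(exp, ("adult", "larva"))
        pd.testing.assert_frame_equal(t1, t2)


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="Rscript not available")
class TestLimmaCrossCheck:
    def test_moderated_statistics_match_limma(self, tmp_path):
        """Dual-route check: our EB fit + shrinkage against limma's
        lmFit/eBayes on the same small matrix."""
        rng = np.random.default_rng(77)
        m = 60
        values = rng.normal(0.0, 0.4, size=(m, 6))
        values[:10, 3:] += 1.5
        exp = _two_group_exp(values)
        ours = tmt.moderated_ttest(exp, ("larva", "adult"), blocks=())

        data_path = tmp_path / "mat.tsv"
        pd.DataFrame(values).to_csv(data_path, sep="\t", index=False,
                                    header=False)
        out_path = tmp_path / "limma_out.tsv"
        script = tmp_path / "run_limma.R"
        script.write_text(f"""
suppressMessages(library(limma))
y <- as.matrix(read.delim("{data_path}", header=FALSE))
group <- factor(c("A","A","A","B","B","B"), levels=c("A","B"))
design <- model.matrix(~0+group)
fit <- lmFit(y, design)
ct <- makeContrasts(groupA-groupB, levels=design)
fit2 <- eBayes(contrasts.fit(fit, ct))
out <- data.frame(t=fit2$t[,1], p=fit2$p.value[,1],
                  d0=fit2$df.prior, s0=fit2$s2.prior)
write.table(out, "{out_path}", sep="\\t", row.names=FALSE)
""")
        subprocess.run(["Rscript", str(script)], check=True,
                       capture_output=True)
        ref = pd.read_csv(out_path, sep="\t")
        np.testing.assert_allclose(ours["moderated_t"], ref["t"], rtol=1e-5)
        np.testing.assert_allclose(ours["p"], ref["p"], rtol=1e-5)


class TestBenjaminiHochberg:
    def test_hand_enumerated_step_up(self):
        np.testing.assert_allclose(
            tmt.benjamini_hochberg([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_ones_stay_one(self):
        assert tmt.benjamini_hochberg([1.0, 1.0, 1.0]).tolist() == [1, 1, 1]

    def test_single_p_unchanged(self):
        assert tmt.benjamini_hochberg([0.2]).tolist() == [0.2]

    def test_out_of_domain_rejected(self):
        with pytest.raises(ValueError):
            tmt.benjamini_hochberg([0.1, 0.0])
        with pytest.raises(ValueError):
            tmt.benjamini_hochberg([1.2])

    def test_monotone_in_ranked_p(self):
        rng = np.random.default_rng(13)
        p = rng.uniform(1e-6, 1, size=200)
        fdr = tmt.benjamini_hochberg(p)
        order = np.argsort(p)
        assert np.all(np.diff(fdr[order]) >= -1e-15)

    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0),
                    min_size=1, max_size=40))
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_equals_hand_written_step_up(self, p):
        """Property: BH equals an independent step-up implementation."""
        m = len(p)
        order = sorted(range(m), key=lambda i: p[i])
        adjusted = [0.0] * m
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            adjusted[i] = running
        np.testing.assert_allclose(tmt.benjamini_hochberg(p), adjusted,
                                   rtol=1e-12)


class TestCallHits:
    def _frame(self, fc, fdr):
        return pd.DataFrame({"log2_fc": fc, "fdr": fdr})

    def test_boundary_fold_change_inclusive(self):
        out = tmt.call_hits(self._frame([1.0], [0.01]))
        assert out["hit"].tolist() == [True]

    def test_fdr_boundary_strict(self):
        out = tmt.call_hits(self._frame([2.5, 2.5], [0.06, 0.05]))
        assert out["hit"].tolist() == [False, False]

    def test_hit_counts_monotone_in_thresholds(self):
        rng = np.random.default_rng(14)
        frame = self._frame(rng.normal(0, 2, 300),
                            rng.uniform(1e-4, 1, 300))
        n = [tmt.call_hits(frame, fc, 0.05)["hit"].sum()
             for fc in (1.5, 2.0, 3.0, 4.0)]
        assert n == sorted(n, reverse=True)
        n2 = [tmt.call_hits(frame, 2.0, q)["hit"].sum()
              for q in (0.1, 0.05, 0.01)]
        assert n2 == sorted(n2, reverse=True)


class TestStageMedians:
    def test_odd_sample_median(self):
        exp = _two_group_exp(np.array([[1.0, 3.0, 100.0, 5.0, 5.0, 5.0]]))
        exp.samples["life_stage"] = ["larva"] * 3 + ["adult"] * 3
        out = tmt.stage_medians(exp)
        assert out.loc["P0", "larva"] == 3.0

    def test_single_sample_per_stage_is_identity(self):
        values = np.array([[1.0, 2.0], [5.0, 7.0]])
        exp = _two_group_exp(values)
        out = tmt.stage_medians(exp)
        np.testing.assert_array_equal(out.to_numpy(), values)

    def test_matches_independent_recomputation(self, tmt_bundle):
        exp = tmt.vs_normalize(tmt.log2_transform(
            tmt.qc_filter(tmt_bundle.experiment)), "median_center")
        out = tmt.stage_medians(exp)
        for stage in ("larva", "primary_polyp", "adult"):
            cols = exp.samples.index[exp.samples["life_stage"] == stage]
            ref = np.median(exp.matrix[cols].to_numpy(), axis=1)
            np.testing.assert_allclose(out[stage], ref, atol=0)

    def test_empty_stage_rejected(self):
        exp = _two_group_exp(np.ones((3, 4)))
        with pytest.raises(ValueError, match="no samples"):
            tmt.stage_medians(exp, stages=["larva", "adult", "ghost"])
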