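"""Harmonization, model reduction, and the summary-statistic gene Z-score."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from transtwas.expr_model import PredictionModel, SnpCovariance
from transtwas.gene_assoc import (gene_zscore, harmonize, reduce_model,
                                  run_study_genescan)


def make_model(rsids, weights, eff="G", ref="A", cv_r2=0.5):
    effs = [eff] * len(rsids) if isinstance(eff, str) else eff
    refs = [ref] * len(rsids) if isinstance(ref, str) else ref
    return PredictionModel("gene1", pd.DataFrame({
        "rsid": rsids, "ref_allele": refs, "eff_allele": effs,
        "weight": weights}), cv_r2=cv_r2)


def make_summary(rows):
    df = pd.DataFrame(rows, columns=["SNP", "A1", "A2", "FREQ1", "BETA", "SE"])
    df["CHR"] = "1"
    df["POS"] = np.arange(1, len(df) + 1)
    df["P"] = 0.5
    df["N_CASES"] = 100
    df["N_CONTROLS"] = 100
    return df


class TestHarmonize:
    def test_matching_alleles_unchanged(self):
        model = make_model(["s1"], [1.0])
        summ = make_summary([("s1", "G", "A", 0.3, 0.25, 0.1)])
        rec = harmonize(summ, model).records
        assert rec["beta"].iloc[0] == 0.25
        assert rec["freq"].iloc[0] == 0.3

    def test_swapped_alleles_negate_beta_and_mirror_freq(self):
        model = make_model(["s1"], [1.0])
        summ = make_summary([("s1", "A", "G", 0.3, 0.25, 0.1)])
        rec = harmonize(summ, model).records
        assert rec["beta"].iloc[0] == -0.25
        assert rec["freq"].iloc[0] == pytest.approx(0.7)

    def test_ambiguous_kept_with_flag_by_default(self):
        model = make_model(["s1"], [1.0], eff="T", ref="A")
        summ = make_summary([("s1", "T", "A", 0.3, 0.2, 0.1)])
        harm = harmonize(summ, model)
        assert harm.records["ambiguous"].iloc[0]
        assert not harm.dropped

    def test_ambiguous_dropped_on_option_and_logged(self):
        model = make_model(["s1"], [1.0], eff="T", ref="A")
        summ = make_summary([("s1", "T", "A", 0.3, 0.2, 0.1)])
        harm = harmonize(summ, model, drop_ambiguous=True)
        assert harm.records.empty
        assert harm.dropped == {"s1": "strand_ambiguous"}

    def test_incompatible_alleles_dropped_with_reason(self):
        model = make_model(["s1"], [1.0])
        summ = make_summary([("s1", "C", "T", 0.3, 0.2, 0.1)])
        harm = harmonize(summ, model)
        assert harm.records.empty
        assert "allele_mismatch" in harm.dropped["s1"]

    def test_absent_snp_logged(self):
        model = make_model(["s1", "s2"], [1.0, 1.0])
        summ = make_summary([("s1", "G", "A", 0.3, 0.2, 0.1)])
        harm = harmonize(summ, model)
        assert harm.dropped == {"s2": "absent_from_summary"}


class TestReduceModel:
    def cov6(self):
        mat = 0.2 * np.ones((6, 6)) + 0.8 * np.eye(6)
        return SnpCovariance("gene1", [f"s{i}" for i in range(6)], mat)

    def test_six_to_five_snps(self):
        model = make_model([f"s{i}" for i in range(6)], np.ones(6))
        red, cov = reduce_model(model, self.cov6(),
                                [f"s{i}" for i in range(5)])
        assert red.n_snps == 5
        assert cov.matrix.shape == (5, 5)

    def test_identity_when_all_available(self):
        model = make_model([f"s{i}" for i in range(6)], np.ones(6))
        red, cov = reduce_model(model, self.cov6(), model.snps["rsid"])
        pd.testing.assert_frame_equal(red.snps, model.snps)
        np.testing.assert_allclose(cov.matrix, self.cov6().matrix)

    def test_empty_reduction_gives_missing_record(self):
        model = make_model([f"s{i}" for i in range(6)], np.ones(6))
        red, cov = reduce_model(model, self.cov6(), [])
        assoc = gene_zscore(red, cov, pd.DataFrame(columns=["rsid", "z"]),
                            n_model_snps=6)
        assert assoc.missing
        assert assoc.n_snps_used == 0
        assert assoc.n_model_snps == 6


class TestGeneZscore:
    def aligned(self, rsids, zs):
        return pd.DataFrame({"rsid": rsids, "z": zs,
                             "beta": np.asarray(zs) * 0.1,
                             "se": [0.1] * len(rsids)})

    def test_single_snp_scale_cancellation(self):
        cov = SnpCovariance("gene1", ["s1"], np.array([[0.37]]))
        for w in (0.4, -0.4):
            model = make_model(["s1"], [w])
            assoc = gene_zscore(model, cov, self.aligned(["s1"], [2.5]))
            assert assoc.zscore == pytest.approx(np.sign(w) * 2.5)

    def test_hand_computed_two_snp_case(self):
        model = make_model(["s1", "s2"], [1.0, 1.0])
        cov = SnpCovariance("gene1", ["s1", "s2"],
                            np.array([[1.0, 0.5], [0.5, 1.0]]))
        assoc = gene_zscore(model, cov, self.aligned(["s1", "s2"], [2.0, 3.0]))
        assert assoc.sigma_g == pytest.approx(np.sqrt(3.0))
        assert assoc.zscore == pytest.approx(5.0 / np.sqrt(3.0), abs=1e-3)
        assert assoc.zscore == pytest.approx(2.887, abs=1e-3)

    def test_null_betas_give_zero_z(self):
        model = make_model(["s1", "s2"], [1.0, -2.0])
        cov = SnpCovariance("gene1", ["s1", "s2"],
                            np.array([[1.0, 0.2], [0.2, 1.0]]))
        assoc = gene_zscore(model, cov, self.aligned(["s1", "s2"], [0.0, 0.0]))
        assert assoc.zscore == 0.0
        assert assoc.pvalue == 1.0

    def test_degenerate_covariance_missing(self):
        model = make_model(["s1"], [1.0])
        cov = SnpCovariance("gene1", ["s1"], np.array([[0.0]]))
        assoc = gene_zscore(model, cov, self.aligned(["s1"], [2.0]))
        assert assoc.missing

    @settings(deadline=None, derandomize=True)
    @given(c=st.floats(0.01, 100.0))
    def test_weight_scale_invariance(self, c):
        cov = SnpCovariance("gene1", ["s1", "s2"],
                            np.array([[1.0, 0.3], [0.3, 2.0]]))
        aligned = self.aligned(["s1", "s2"], [1.5, -0.7])
        z1 = gene_zscore(make_model(["s1", "s2"], [0.2, -1.1]),
                         cov, aligned).zscore
        z2 = gene_zscore(make_model(["s1", "s2"], [0.2 * c, -1.1 * c]),
                         cov, aligned).zscore
        assert z2 == pytest.approx(z1, rel=1e-9)

    def test_snp_order_invariance(self):
        cov = SnpCovariance("gene1", ["s1", "s2", "s3"],
                            np.array([[1.0, 0.3, 0.1], [0.3, 2.0, 0.2],
                                      [0.1, 0.2, 1.5]]))
        aligned = self.aligned(["s1", "s2", "s3"], [1.0, -2.0, 0.5])
        z1 = gene_zscore(make_model(["s1", "s2", "s3"], [0.5, 1.0, -0.3]),
                         cov, aligned).zscore
        perm_model = make_model(["s3", "s1", "s2"], [-0.3, 0.5, 1.0])
        z2 = gene_zscore(perm_model, cov, aligned).zscore
        assert z2 == pytest.approx(z1, rel=1e-12)

    def test_allele_flip_invariance_through_harmonization(self):
        model = make_model(["s1", "s2"], [0.8, -0.5])
        cov = SnpCovariance("gene1", ["s1", "s2"],
                            np.array([[1.0, 0.4], [0.4, 1.0]]))
        straight = make_summary([("s1", "G", "A", 0.3, 0.2, 0.1),
                                 ("s2", "G", "A", 0.6, -0.1, 0.05)])
        flipped = make_summary([("s1", "A", "G", 0.7, -0.2, 0.1),
                                ("s2", "G", "A", 0.6, -0.1, 0.05)])
        z1 = gene_zscore(model, cov, harmonize(straight, model).records).zscore
        z2 = gene_zscore(model, cov, harmonize(flipped, model).records).zscore
        assert z2 == pytest.approx(z1, rel=1e-12)


class TestRunStudyGenescan:
    def test_empty_model_db(self):
        summ = make_summary([("s1", "G", "A", 0.3, 0.2, 0.1)])
        out = run_study_genescan(summ, {}, {}, study="s")
        assert out.empty

    def test_monomorphic_in_study_reduces_model(self):
        model = make_model(["s1", "s2"], [1.0, 1.0])
        cov = SnpCovariance("gene1", ["s1", "s2"],
                            np.array([[1.0, 0.2], [0.2, 1.0]]))
        summ = make_summary([("s1", "G", "A", 0.5, 0.2, 0.1),
                             ("s2", "G", "A", 0.0, np.nan, np.nan)])
        log = {}
        out = run_study_genescan(summ, {"gene1": model}, {"gene1": cov},
                                 study="s", reduction_log=log)
        assert out["n_snps_used"].iloc[0] == 1
        assert out["n_model_snps"].iloc[0] == 2
        assert "s2" in log["gene1"]

    def test_untestable_model_skipped_as_missing(self):
        model = make_model(["s1"], [1.0], cv_r2=0.0)
        cov = SnpCovariance("gene1", ["s1"], np.array([[1.0]]))
        summ = make_summary([("s1", "G", "A", 0.5, 0.2, 0.1)])
        out = run_study_genescan(summ, {"gene1": model}, {"gene1": cov})
        assert np.isnan(out["zscore"].iloc[0])
        assert out["n_snps_used"].iloc[0] == 0
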