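"""Cross-study combination: effective N, weighted Z, IVW, Cochran's Q.

The reproduction suite checks every printed meta cell of the packaged
published tables against recombination of the per-study cells.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import er_negative_neff, overall_neff
from transtwas.metacombine import (cochran_q, combine_z, effective_n,
                                   ivw_meta_snp, meta_z_genes, se_from_ci)


class TestEffectiveN:
    def test_balanced_design(self):
        assert effective_n(500, 500) == pytest.approx(1000.0)

    @pytest.mark.parametrize("cases,controls,expected", [
        (988, 2745, 2906.0),    # African-American ER-negative subset
        (1998, 3263, 4956.8),   # European ER-negative cohort
    ])
    def test_case_control_counts(self, cases, controls, expected):
        assert effective_n(cases, controls) == pytest.approx(expected, abs=0.1)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            effective_n(0, 100)


class TestCombineZ:
    def test_single_study_identity(self):
        assert combine_z([2.5], [1000.0]) == pytest.approx(2.5)

    def test_missing_studies_omitted(self):
        z = combine_z([2.0, np.nan, 1.0], [100.0, 900.0, 100.0])
        assert z == pytest.approx((np.sqrt(100) * 2 + np.sqrt(100) * 1)
                                  / np.sqrt(200))

    @settings(deadline=None, derandomize=True)
    @given(c=st.floats(0.1, 100.0))
    def test_neff_scale_invariance(self, c):
        z = [1.2, -0.4, 2.0]
        n = [500.0, 800.0, 300.0]
        assert combine_z(z, [c * x for x in n]) == \
            pytest.approx(combine_z(z, n), rel=1e-9)

    def test_study_order_invariance(self):
        z = [1.2, -0.4, 2.0]
        n = [500.0, 800.0, 300.0]
        assert combine_z(z[::-1], n[::-1]) == pytest.approx(combine_z(z, n))


class TestSeFromCi:
    def test_reconstruction_from_printed_ci(self):
        assert se_from_ci(1.29, 1.12, 1.50) == pytest.approx(0.0745, abs=1e-4)

    def test_log_symmetric_ci(self):
        se = se_from_ci(1.00, 0.80, 1.25)
        assert se == pytest.approx(0.1139, abs=1e-4)
        assert np.log(1.00) == pytest.approx(
            (np.log(0.80) + np.log(1.25)) / 2, abs=1e-12)

    def test_degenerate_ci(self):
        assert se_from_ci(1.0, 1.1, 1.1) == 0.0

    def test_nonpositive_bounds_rejected(self):
        with pytest.raises(ValueError):
            se_from_ci(1.0, 0.0, 1.2)


class TestIvwMeta:
    def test_replication_limit(self):
        res = ivw_meta_snp([0.3] * 4, [0.1] * 4)
        assert res.beta == pytest.approx(0.3)
        assert res.se == pytest.approx(0.1 / 2)

    def test_se_never_exceeds_smallest_input(self):
        res = ivw_meta_snp([0.1, 0.5, -0.2], [0.05, 0.2, 0.4])
        assert res.se <= 0.05

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ivw_meta_snp([], [])

    def test_ci_is_exp_of_beta_pm_1_96_se(self):
        res = ivw_meta_snp([0.2, 0.1], [0.1, 0.2])
        assert res.ci_low == pytest.approx(np.exp(res.beta - 1.96 * res.se))
        assert res.ci_high == pytest.approx(np.exp(res.beta + 1.96 * res.se))


class TestCochranQ:
    def test_identical_effects(self):
        q, p = cochran_q([0.2, 0.2, 0.2], [0.1, 0.2, 0.1])
        assert q == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_two_study_case(self):
        q, p = cochran_q([0.0, 3.0], [1.0, 1.0])
        assert q == pytest.approx(4.5)

    def test_single_study_missing(self):
        q, p = cochran_q([0.2], [0.1])
        assert np.isnan(q) and np.isnan(p)


class TestPublishedReproduction:
    """Every printed meta cell follows from the per-study cells."""

    def _neff(self, published, phenotype):
        return (er_negative_neff(published) if phenotype == "er_negative"
                else overall_neff(published))

    @pytest.mark.parametrize("phenotype", ["overall", "er_negative"])
    def test_gene_meta_z_all_rows(self, published, phenotype):
        table = (published.gene_scan_er_negative
                 if phenotype == "er_negative"
                 else published.gene_scan_overall)
        neff = self._neff(published, phenotype)
        per_study = table[table["study"] != "meta"]
        meta = meta_z_genes(per_study, neff).set_index("gene")
        printed = table[table["study"] == "meta"]
        for _, row in printed.iterrows():
            assert meta.at[row["gene"], "zscore"] == \
                pytest.approx(row["zscore"], abs=0.005), row["gene"]

    @pytest.mark.parametrize("phenotype", ["overall", "er_negative"])
    def test_snp_meta_rows(self, published, phenotype):
        # inputs are two-decimal printed ORs/CIs, so the recombined meta
        # drifts by up to ~0.03 for the wide-CI rows; 0.035 bounds the
        # rounding propagation while still pinning every cell
        table = published.snp_discovery
        table = table[table["phenotype"] == phenotype]
        for snp, grp in table.groupby("snp"):
            per = grp[grp["study"] != "meta"]
            printed = grp[grp["study"] == "meta"].iloc[0]
            betas = np.log(per["or_point"].to_numpy())
            ses = [se_from_ci(o, lo, hi) for o, lo, hi in
                   zip(per["or_point"], per["ci_low"], per["ci_high"])]
            res = ivw_meta_snp(betas, ses, snp=snp)
            assert res.or_point == pytest.approx(printed["or_point"], abs=0.035)
            assert res.ci_low == pytest.approx(printed["ci_low"], abs=0.035)
            assert res.ci_high == pytest.approx(printed["ci_high"], abs=0.035)

    def test_no_heterogeneity_across_studies(self, published):
        table = published.snp_discovery
        for (snp, phen), grp in table.groupby(["snp", "phenotype"]):
            per = grp[grp["study"] != "meta"]
            betas = np.log(per["or_point"].to_numpy())
            ses = [se_from_ci(o, lo, hi) for o, lo, hi in
                   zip(per["or_point"], per["ci_low"], per["ci_high"])]
            _, p_het = cochran_q(betas, ses)
            assert p_het > 0.05, (snp, phen)

    def test_replication_phase_discovery_rows_follow_from_per_study(
            self, published):
        # the ER-negative discovery rows of the replication table re-combine
        # the per-study cells with the European cohort excluded
        disc = published.snp_discovery
        disc = disc[(disc["phenotype"] == "er_negative")
                    & (disc["study"] != "meta") & (disc["study"] != "BPC3")]
        rep = published.snp_replication
        rep = rep[(rep["phase"] == "U4C") & (rep["phenotype"] == "er_negative")]
        for _, printed in rep.iterrows():
            per = disc[disc["snp"] == printed["snp"]]
            betas = np.log(per["or_point"].to_numpy())
            ses = [se_from_ci(o, lo, hi) for o, lo, hi in
                   zip(per["or_point"], per["ci_low"], per["ci_high"])]
            res = ivw_meta_snp(betas, ses)
            assert res.or_point == pytest.approx(printed["or_point"],
                                                 abs=0.01), printed["snp"]
            assert res.ci_low == pytest.approx(printed["ci_low"], abs=0.01)
            assert res.ci_high == pytest.approx(printed["ci_high"], abs=0.01)


class TestMetaZGenesTable:
    def test_missing_value_record_when_no_contributions(self):
        table = pd.DataFrame({"gene": ["g"], "study": ["s1"],
                              "zscore": [np.nan], "pvalue": [np.nan]})
        out = meta_z_genes(table, {"s1": 1000.0})
        assert out["n_studies"].iloc[0] == 0
        assert np.isnan(out["zscore"].iloc[0])
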