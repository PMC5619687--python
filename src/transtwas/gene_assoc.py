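"""Summary-statistic gene-level association.

The core statistic combines, for one gene g, the GWAS per-SNP Wald
z-scores z_l = beta_l / se_l of the SNPs in its expression predictor:

    Z_g = sum_l w_lg * (sigma_l / sigma_g) * (beta_l / se_l)

where w_lg is the eQTL weight of SNP l, sigma_l = sqrt(Gamma_ll) is the
SNP's dosage standard deviation in the reference panel, and
sigma_g = sqrt(w' Gamma w) is the standard deviation of the gene's
predicted expression under the reference LD covariance Gamma. A positive
Z_g means higher predicted expression associates with higher disease risk.
p = 2*Phi(-|Z_g|).

Before scoring, GWAS summaries are harmonized to the model's effect-allele
orientation (swapped alleles negate beta and mirror the frequency), and
the model is reduced to the SNPs actually usable in the study: SNPs that
are absent, monomorphic/below the MAF filter, or allele-incompatible are
dropped and the covariance restricted to the survivors — so a predictor
whose sixth SNP is monomorphic in one cohort is scored there on five.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._io import write_tsv
from .expr_model import PredictionModel, SnpCovariance

__all__ = [
    "GeneAssociation",
    "HarmonizedSummary",
    "harmonize",
    "reduce_model",
    "gene_zscore",
    "run_study_genescan",
    "write_gene_assoc",
]

AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class GeneAssociation:
    """Per-study gene-level result."""

    gene_id: str
    study: str
    zscore: float
    pvalue: float
    n_model_snps: int
    n_snps_used: int
    sigma_g: float = float("nan")

    @property
    def missing(self) -> bool:
        return not np.isfinite(self.zscore)


@dataclass
class HarmonizedSummary:
    """Model SNPs aligned to the study summary, plus per-SNP drop reasons."""

    records: pd.DataFrame  # rsid, beta, se, z, freq, ambiguous
    dropped: dict[str, str]


def harmonize(summary: pd.DataFrame, model: PredictionModel,
              drop_ambiguous: bool = False) -> HarmonizedSummary:
    """Align study summary rows to the model's effect-allele orientation.

    Matching alleles keep beta; swapped alleles negate beta and replace the
    effect-allele frequency f by 1-f. Strand-ambiguous (A/T, C/G) SNPs are
    kept with a flag by default and dropped when ``drop_ambiguous`` is set.
    Allele pairs that neither match nor swap are dropped with a reason.
    """
    stats = summary.set_index("SNP")
    rows, dropped = [], {}
    for _, mrow in model.snps.iterrows():
        rsid = mrow["rsid"]
        if rsid not in stats.index:
            dropped[rsid] = "absent_from_summary"
            continue
        srow = stats.loc[rsid]
        a1, a2 = str(srow["A1"]), str(srow["A2"])
        eff, ref = str(mrow["eff_allele"]), str(mrow["ref_allele"])
        ambiguous = (a1, a2) in AMBIGUOUS_PAIRS
        if ambiguous and drop_ambiguous:
            dropped[rsid] = "strand_ambiguous"
            continue
        if (a1, a2) == (eff, ref):
            sign = 1.0
            freq = float(srow["FREQ1"])
        elif (a1, a2) == (ref, eff):
            sign = -1.0
            freq = 1.0 - float(srow["FREQ1"])
        else:
            dropped[rsid] = f"allele_mismatch:{a1}/{a2}_vs_{eff}/{ref}"
            continue
        beta, se = srow["BETA"], srow["SE"]
        if not (np.isfinite(beta) and np.isfinite(se) and se > 0):
            dropped[rsid] = "missing_estimate"
            continue
        rows.append({"rsid": rsid, "beta": sign * float(beta),
                     "se": float(se), "z": sign * float(beta) / float(se),
                     "freq": freq, "ambiguous": ambiguous})
    records = pd.DataFrame(rows, columns=["rsid", "beta", "se", "z",
                                          "freq", "ambiguous"])
    return HarmonizedSummary(records=records, dropped=dropped)


def reduce_model(model: PredictionModel, covariance: SnpCovariance,
                 available_ids) -> tuple[PredictionModel, SnpCovariance]:
    """Restrict a model and its covariance to the SNPs usable in a study."""
    available = set(available_ids)
    keep = model.snps["rsid"].isin(available)
    snps = model.snps[keep].reset_index(drop=True)
    reduced = PredictionModel(gene_id=model.gene_id, snps=snps,
                              mixing=model.mixing, penalty=model.penalty,
                              cv_r2=model.cv_r2)
    return reduced, covariance.subset(snps["rsid"].tolist())


def gene_zscore(model: PredictionModel, covariance: SnpCovariance,
                aligned: pd.DataFrame, study: str = "",
                n_model_snps: int | None = None) -> GeneAssociation:
    """Score one gene from weights, reference covariance, and per-SNP z."""
    n_model = model.n_snps if n_model_snps is None else n_model_snps
    if model.n_snps == 0:
        return GeneAssociation(model.gene_id, study, np.nan, np.nan,
                               n_model, 0)
    order = model.snps["rsid"].tolist()
    if covariance.snp_ids != order:
        covariance = covariance.subset(order)
    z = aligned.set_index("rsid").loc[order, "z"].to_numpy(dtype=float)
    w = model.weights()
    gamma = covariance.matrix
    var_g = float(w @ gamma @ w)
    if var_g <= 0:
        return GeneAssociation(model.gene_id, study, np.nan, np.nan,
                               n_model, 0)
    sigma_g = np.sqrt(var_g)
    sigma_l = np.sqrt(np.diag(gamma))
    zg = float(np.sum(w * sigma_l * z) / sigma_g)
    p = float(2.0 * norm.sf(abs(zg)))
    return GeneAssociation(model.gene_id, study, zg, max(p, np.finfo(float).tiny),
                           n_model, model.n_snps, sigma_g)


def run_study_genescan(summary: pd.DataFrame,
                       models: dict[str, PredictionModel],
                       covariances: dict[str, SnpCovariance],
                       study: str = "study",
                       maf_threshold: float = 0.05,
                       drop_ambiguous: bool = False,
                       reduction_log: dict | None = None) -> pd.DataFrame:
    """Harmonize, reduce, and score every gene against one study's summary.

    Genes whose model loses all SNPs (or was untestable to begin with)
    yield missing-value rows with ``n_snps_used`` = 0; rows are ordered by
    gene id. ``reduction_log`` (optional dict) collects per-gene drop
    reasons.
    """
    results = []
    for gene in sorted(models):
        model = models[gene]
        if not model.testable:
            if reduction_log is not None:
                reduction_log[gene] = {"*": "untestable_model"}
            results.append({"gene": gene, "study": study, "zscore": np.nan,
                            "pvalue": np.nan, "n_model_snps": model.n_snps,
                            "n_snps_used": 0})
            continue
        cov = covariances[gene]
        harm = harmonize(summary, model, drop_ambiguous=drop_ambiguous)
        rec = harm.records
        usable = rec.loc[np.minimum(rec["freq"], 1 - rec["freq"]) > maf_threshold,
                         "rsid"]
        for rsid in rec.loc[~rec["rsid"].isin(usable), "rsid"]:
            harm.dropped[rsid] = "monomorphic_or_low_maf_in_study"
        if reduction_log is not None and harm.dropped:
            reduction_log[gene] = dict(harm.dropped)
        reduced, red_cov = reduce_model(model, cov, usable)
        assoc = gene_zscore(reduced, red_cov,
                            rec[rec["rsid"].isin(usable)], study=study,
                            n_model_snps=model.n_snps)
        results.append({"gene": assoc.gene_id, "study": study,
                        "zscore": assoc.zscore, "pvalue": assoc.pvalue,
                        "n_model_snps": assoc.n_model_snps,
                        "n_snps_used": assoc.n_snps_used})
    return pd.DataFrame(results, columns=["gene", "study", "zscore", "pvalue",
                                          "n_model_snps", "n_snps_used"])


def write_gene_assoc(table: pd.DataFrame, path, provenance=None) -> None:
    write_tsv(table, path, provenance)
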