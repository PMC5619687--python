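"""Cross-study combination of gene- and SNP-level results.

Gene level: sample-size-weighted Z meta-analysis,

    Z_meta = sum_k sqrt(Neff_k) Z_k / sqrt(sum_k Neff_k),

with the case-control effective sample size Neff = 4/(1/Ncases+1/Nctrls)
as the weight. Studies in which a gene could not be scored (no usable
model SNPs) are omitted from both sums — a predictor monomorphic in one
cohort simply contributes nothing from that cohort.

SNP level: fixed-effect inverse-variance meta-analysis of per-study log
odds ratios with Cochran's Q heterogeneity (chi-square, K-1 df). Printed
odds-ratio tables carry only OR and 95% CI, so ``se_from_ci`` reconstructs
the log-scale standard error as (ln hi - ln lo) / (2 * 1.96); 1.96 (not a
higher-precision normal quantile) is used throughout CI arithmetic to
match printed confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from ._io import write_tsv

__all__ = [
    "MetaGeneResult",
    "MetaSnpResult",
    "effective_n",
    "combine_z",
    "meta_z_genes",
    "se_from_ci",
    "ivw_meta_snp",
    "cochran_q",
]

Z95 = 1.96  # CI multiplier matching printed confidence-interval arithmetic


@dataclass
class MetaGeneResult:
    gene_id: str
    zscore: float
    pvalue: float
    contributions: list[tuple[str, float, float]] = field(default_factory=list)
    # (study, Z_k, Neff_k) for each contributing study


@dataclass
class MetaSnpResult:
    snp: str
    beta: float
    se: float
    or_point: float
    ci_low: float
    ci_high: float
    pvalue: float
    q: float = float("nan")
    p_het: float = float("nan")
    n_studies: int = 0


def effective_n(n_cases: int, n_controls: int) -> float:
    """Case-control effective sample size 4/(1/Ncases + 1/Nctrls)."""
    if n_cases < 1 or n_controls < 1:
        raise ValueError("counts must be >= 1")
    return 4.0 / (1.0 / n_cases + 1.0 / n_controls)


def combine_z(zscores, neffs) -> float:
    """Sample-size-weighted Z combination over contributing studies."""
    z = np.asarray(zscores, dtype=float)
    n = np.asarray(neffs, dtype=float)
    keep = np.isfinite(z)
    z, n = z[keep], n[keep]
    if z.size == 0:
        return float("nan")
    return float(np.sum(np.sqrt(n) * z) / np.sqrt(np.sum(n)))


def meta_z_genes(gene_table: pd.DataFrame,
                 neff_by_study: dict[str, float]) -> pd.DataFrame:
    """Combine a long per-study gene table (gene, study, zscore, pvalue).

    Studies with a missing Z for a gene are omitted from that gene's
    combination; genes with no finite contribution yield NA rows. Returns
    one row per gene: gene, zscore, pvalue, n_studies, studies.
    """
    rows = []
    for gene, grp in gene_table.groupby("gene", sort=True):
        grp = grp[np.isfinite(grp["zscore"].to_numpy(dtype=float))]
        grp = grp[grp["study"].isin(neff_by_study)]
        if grp.empty:
            rows.append({"gene": gene, "zscore": np.nan, "pvalue": np.nan,
                         "n_studies": 0, "studies": ""})
            continue
        neffs = [neff_by_study[s] for s in grp["study"]]
        zmeta = combine_z(grp["zscore"], neffs)
        rows.append({"gene": gene, "zscore": zmeta,
                     "pvalue": float(2.0 * norm.sf(abs(zmeta))),
                     "n_studies": len(grp),
                     "studies": ",".join(sorted(grp["study"]))})
    return pd.DataFrame(rows, columns=["gene", "zscore", "pvalue",
                                       "n_studies", "studies"])


def se_from_ci(or_point: float, ci_low: float, ci_high: float) -> float:
    """Log-scale standard error reconstructed from a printed 95% CI."""
    if ci_low <= 0 or ci_high <= 0:
        raise ValueError("CI bounds must be positive")
    if ci_low > ci_high:
        raise ValueError("ci_low must not exceed ci_high")
    del or_point  # the point estimate does not enter the reconstruction
    return float((np.log(ci_high) - np.log(ci_low)) / (2.0 * Z95))


def ivw_meta_snp(betas, ses, snp: str = "") -> MetaSnpResult:
    """Fixed-effect inverse-variance combination of per-study log ORs."""
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size == 0:
        raise ValueError("no studies to combine")
    if (s <= 0).any():
        raise ValueError("all standard errors must be positive")
    w = 1.0 / s**2
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    q, p_het = cochran_q(b, s) if b.size >= 2 else (float("nan"), float("nan"))
    return MetaSnpResult(
        snp=snp, beta=beta, se=se,
        or_point=float(np.exp(beta)),
        ci_low=float(np.exp(beta - Z95 * se)),
        ci_high=float(np.exp(beta + Z95 * se)),
        pvalue=float(2.0 * norm.sf(abs(beta / se))),
        q=q, p_het=p_het, n_studies=int(b.size))


def cochran_q(betas, ses) -> tuple[float, float]:
    """Cochran's Q against the fixed-effect combination; chi2 p, K-1 df."""
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size < 2:
        return (float("nan"), float("nan"))
    w = 1.0 / s**2
    beta_meta = np.sum(w * b) / np.sum(w)
    q = float(np.sum(w * (b - beta_meta) ** 2))
    return (q, float(chi2.sf(q, df=b.size - 1)))


def write_meta_genes(table: pd.DataFrame, path, provenance=None) -> None:
    write_tsv(table, path, provenance)


def write_meta_snps(results: list[MetaSnpResult], path, provenance=None) -> None:
    rows = [{"SNP": r.snp, "BETA": r.beta, "SE": r.se, "OR": r.or_point,
             "CI_LOW": r.ci_low, "CI_HIGH": r.ci_high, "P": r.pvalue,
             "Q": r.q, "P_HET": r.p_het, "N_STUDIES": r.n_studies}
            for r in results]
    write_tsv(pd.DataFrame(rows), path, provenance)
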