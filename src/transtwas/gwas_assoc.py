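"""Per-study SNP-level association scan.

MAF filtering (MAF strictly > threshold on min(f, 1-f)), genotype PCA for
population-structure covariates, additive-model logistic regression per
SNP, and emission of a METAL-style summary-statistics table — the
inter-stage currency consumed by the gene-level scan and the SNP-level
meta-analysis.

Per-SNP fits use maximum likelihood (Newton/IRLS, log-likelihood tolerance
1e-8, at most 50 iterations). Separation or non-convergence yields a
missing-value record rather than an exception, so one pathological SNP
cannot abort a study scan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from ._io import read_tsv, write_tsv
from .synthdata import SimulatedCohort

__all__ = [
    "PcResult",
    "maf_filter",
    "compute_pcs",
    "fit_snp_logistic",
    "run_study_gwas",
    "write_summary_stats",
    "read_summary_stats",
    "SUMMARY_COLUMNS",
]

SUMMARY_COLUMNS = ["SNP", "CHR", "POS", "A1", "A2", "FREQ1", "BETA", "SE",
                   "P", "N_CASES", "N_CONTROLS"]


@dataclass
class PcResult:
    """Leading principal axes of the standardized dosage matrix."""

    coords: pd.DataFrame     # samples x k, columns PC1..PCk
    eigenvalues: np.ndarray  # non-increasing, variance units


def maf_filter(variants: pd.DataFrame, threshold: float = 0.05,
               freq_col: str = "freq") -> list[str]:
    """Variant ids whose minor allele frequency is strictly above threshold."""
    freqs = variants[freq_col].to_numpy(dtype=float)
    if ((freqs < 0) | (freqs > 1)).any():
        raise ValueError("frequencies must lie in [0, 1]")
    # round before the strict comparison so that e.g. f=0.95 yields a MAF
    # of exactly 0.05 rather than 0.05 + 4e-17
    maf = np.round(np.minimum(freqs, 1.0 - freqs), 12)
    return variants.loc[maf > threshold, "id"].tolist()


def compute_pcs(dosages: pd.DataFrame, k: int) -> PcResult:
    """PCA of the centred, variance-standardized dosage matrix.

    Constant columns are dropped before the decomposition; smartPCA-style
    LD pruning and outlier removal are deliberately not reproduced — the
    eigenvectors serve only as structure covariates.
    """
    x = dosages.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("no variable sites: all dosage columns are constant")
    x = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    rank = min(x.shape)
    if k > rank:
        raise ValueError(f"k={k} exceeds attainable rank {rank}")
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    eigvals = (s ** 2) / (x.shape[0] - 1)
    coords = pd.DataFrame(u[:, :k] * s[:k], index=dosages.index,
                          columns=[f"PC{i + 1}" for i in range(k)])
    return PcResult(coords=coords, eigenvalues=eigvals[:k])


def fit_snp_logistic(dosage, phenotype, covariates=None
                     ) -> tuple[float, float, float]:
    """Additive-model logistic regression for one SNP.

    Returns (beta, se, p): the per-allele log odds ratio, its Wald standard
    error, and the two-sided normal p-value 2*Phi(-|beta/se|). Returns
    (nan, nan, nan) on separation or non-convergence.
    """
    y = np.asarray(phenotype, dtype=float)
    g = np.asarray(dosage, dtype=float)
    cols = [np.ones_like(g), g]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        # constant columns are collinear with the intercept; drop them
        cols.extend(col for col in cov.T if col.std() > 0)
    design = np.column_stack(cols)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, design).fit(method="newton", maxiter=50,
                                          tol=1e-8, disp=False)
        if not res.mle_retvals.get("converged", False):
            return (np.nan, np.nan, np.nan)
        beta = float(res.params[1])
        se = float(res.bse[1])
    except Exception:
        return (np.nan, np.nan, np.nan)
    if not np.isfinite(beta) or not np.isfinite(se) or se <= 0 or se > 50:
        return (np.nan, np.nan, np.nan)
    p = float(2.0 * norm.sf(abs(beta / se)))
    return (beta, se, max(p, np.finfo(float).tiny))


def run_study_gwas(cohort: SimulatedCohort, n_pcs: int = 4,
                   maf_threshold: float = 0.05,
                   covariate_cols: tuple[str, ...] = ("age",)
                   ) -> pd.DataFrame:
    """Full SNP scan of one cohort: MAF filter, PCs, per-SNP logistic fits.

    Emits a METAL-style summary table sorted by (CHR, POS); effect allele
    A1 is the dosage-counted (alt) allele, FREQ1 its sample frequency.
    """
    freqs = cohort.dosages.mean(axis=0) / 2.0
    table = cohort.variants.copy()
    table = table.set_index("id")
    table["obs_freq"] = freqs
    table = table.reset_index()
    keep = maf_filter(table, maf_threshold, freq_col="obs_freq")
    if not keep:
        raise ValueError(f"{cohort.name}: no variants pass the MAF filter")

    pcs = compute_pcs(cohort.dosages[keep], n_pcs)
    cov = pcs.coords
    for col in covariate_cols:
        if col in cohort.covariates:
            cov = pd.concat([cov, cohort.covariates[col]], axis=1)
    cov_arr = cov.to_numpy(dtype=float)
    y = cohort.phenotype.to_numpy(dtype=float)

    meta = table.set_index("id")
    rows = []
    for snp in keep:
        beta, se, p = fit_snp_logistic(cohort.dosages[snp].to_numpy(),
                                       y, cov_arr)
        rows.append({
            "SNP": snp,
            "CHR": meta.at[snp, "chrom"],
            "POS": int(meta.at[snp, "pos"]),
            "A1": meta.at[snp, "alt"],
            "A2": meta.at[snp, "ref"],
            "FREQ1": float(freqs[snp]),
            "BETA": beta, "SE": se, "P": p,
            "N_CASES": cohort.n_cases, "N_CONTROLS": cohort.n_controls,
        })
    out = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    return out.sort_values(["CHR", "POS", "SNP"], kind="mergesort",
                           ignore_index=True)


def write_summary_stats(summary: pd.DataFrame, path, provenance=None) -> None:
    write_tsv(summary[SUMMARY_COLUMNS], path, provenance)


def read_summary_stats(path) -> pd.DataFrame:
    """Read a METAL-style summary table (also accepts pre-computed releases)."""
    df = read_tsv(path, dtype={"CHR": str, "A1": str, "A2": str})
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing summary columns {missing}")
    return df[SUMMARY_COLUMNS]
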