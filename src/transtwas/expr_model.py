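"""Elastic-net cis-eQTL expression prediction models and SNP covariance.

Per gene, expression is regressed on cis dosages (within a window of the
TSS, MAF > 0.05) with an elastic net whose mixing parameter defaults to
0.5 — halfway between ridge and lasso — and whose penalty is chosen by
k-fold cross-validation minimizing mean squared error. The nonzero-weight
SNPs form the prediction model; the sample covariance (denominator n-1) of
those SNPs' dosages in the reference panel supplies the LD information the
summary-statistic gene test needs.

Models whose cross-validated R^2 is at or below a floor (default 0.01)
are flagged untestable and skipped downstream, mirroring the restriction
of a genome-wide scan to genes with usable predictors.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold

from ._io import read_tsv, write_tsv
from .synthdata import SimulatedPanel

__all__ = [
    "PredictionModel",
    "SnpCovariance",
    "train_elastic_net",
    "build_covariance",
    "write_model_db",
    "read_model_db",
    "WEAK_R2_FLOOR",
]

WEAK_R2_FLOOR = 0.01


@dataclass
class PredictionModel:
    """Trained per-gene expression predictor (nonzero weights only)."""

    gene_id: str
    snps: pd.DataFrame  # rsid, ref_allele, eff_allele, weight
    mixing: float = 0.5
    penalty: float = float("nan")
    cv_r2: float = 0.0

    def __post_init__(self):
        if self.snps["rsid"].duplicated().any():
            raise ValueError(f"{self.gene_id}: duplicate SNPs in model")

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def testable(self) -> bool:
        return self.n_snps > 0 and self.cv_r2 > WEAK_R2_FLOOR

    def weights(self) -> np.ndarray:
        return self.snps["weight"].to_numpy(dtype=float)


@dataclass
class SnpCovariance:
    """Reference LD: dosage covariance of a model's SNPs, in model order."""

    gene_id: str
    snp_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        g = np.asarray(self.matrix, dtype=float)
        if g.shape != (len(self.snp_ids), len(self.snp_ids)):
            raise ValueError("covariance shape does not match SNP list")
        if not np.allclose(g, g.T, atol=1e-8):
            raise ValueError(f"{self.gene_id}: covariance not symmetric")
        if len(self.snp_ids) and np.linalg.eigvalsh(g).min() < -1e-8:
            raise ValueError(f"{self.gene_id}: covariance not PSD")
        self.matrix = g

    def subset(self, snp_ids: list[str]) -> "SnpCovariance":
        idx = [self.snp_ids.index(s) for s in snp_ids]
        return SnpCovariance(self.gene_id, list(snp_ids),
                             self.matrix[np.ix_(idx, idx)])


def train_elastic_net(panel: SimulatedPanel, gene_id: str, tss: int,
                      chrom: str, cis_window: int = 1_000_000,
                      mixing: float = 0.5, folds: int = 10,
                      seed: int = 0, maf_threshold: float = 0.05,
                      penalty: float | None = None) -> PredictionModel:
    """Fit one gene's cis elastic-net expression predictor.

    Candidate SNPs are panel variants on ``chrom`` within ``cis_window`` bp
    of the TSS passing MAF > ``maf_threshold`` in the panel. The penalty is
    selected on a 100-point log-scale grid by ``folds``-fold CV (seeded
    shuffle, so the fit is deterministic given ``seed``); the reported
    cross-validated R^2 is 1 - CV-MSE / Var(y), clipped at 0. Passing an
    explicit ``penalty`` skips the grid search and fits at that penalty
    (CV is still used to estimate R^2).
    """
    if gene_id not in panel.expression.columns:
        raise KeyError(f"gene {gene_id} not in panel expression")
    variants = panel.variants
    obs_freq = panel.dosages.mean(axis=0) / 2.0
    in_cis = ((variants["chrom"].astype(str) == str(chrom))
              & (variants["pos"] >= tss - cis_window)
              & (variants["pos"] <= tss + cis_window))
    cand = variants.loc[in_cis, "id"]
    maf_ok = cand.map(lambda s: min(obs_freq[s], 1 - obs_freq[s]) > maf_threshold)
    cand = cand[maf_ok].tolist()
    if not cand:
        return PredictionModel(gene_id=gene_id, mixing=mixing, cv_r2=0.0,
                               snps=_empty_weights())

    x = panel.dosages[cand].to_numpy(dtype=float)
    y = panel.expression[gene_id].to_numpy(dtype=float)
    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    if penalty is None:
        fit = ElasticNetCV(l1_ratio=mixing, alphas=100, cv=cv,
                           max_iter=5000, tol=1e-6)
        fit.fit(x, y)
        cv_mse = fit.mse_path_[np.argmin(fit.mse_path_.mean(axis=1))].mean()
        chosen = float(fit.alpha_)
    else:
        fit = ElasticNet(alpha=penalty, l1_ratio=mixing, max_iter=5000,
                         tol=1e-6)
        fit.fit(x, y)
        sse, n_held = 0.0, 0
        for train_idx, test_idx in cv.split(x):
            held = ElasticNet(alpha=penalty, l1_ratio=mixing, max_iter=5000,
                              tol=1e-6).fit(x[train_idx], y[train_idx])
            resid = y[test_idx] - held.predict(x[test_idx])
            sse += float(resid @ resid)
            n_held += test_idx.size
        cv_mse = sse / n_held
        chosen = float(penalty)
    cv_r2 = max(0.0, 1.0 - cv_mse / y.var())

    nz = np.flatnonzero(fit.coef_)
    vmeta = variants.set_index("id")
    snps = pd.DataFrame({
        "rsid": [cand[i] for i in nz],
        "ref_allele": [vmeta.at[cand[i], "ref"] for i in nz],
        "eff_allele": [vmeta.at[cand[i], "alt"] for i in nz],
        "weight": fit.coef_[nz],
    })
    return PredictionModel(gene_id=gene_id, snps=snps, mixing=mixing,
                           penalty=chosen, cv_r2=float(cv_r2))


def _empty_weights() -> pd.DataFrame:
    return pd.DataFrame(columns=["rsid", "ref_allele", "eff_allele", "weight"])


def build_covariance(dosages: pd.DataFrame,
                     model: PredictionModel) -> SnpCovariance:
    """Sample covariance (n-1 denominator) of the model SNPs' dosages."""
    missing = [s for s in model.snps["rsid"] if s not in dosages.columns]
    if missing:
        raise KeyError(f"{model.gene_id}: model SNPs absent from panel: "
                       f"{missing}")
    ids = model.snps["rsid"].tolist()
    x = dosages[ids].to_numpy(dtype=float)
    if len(ids) == 0:
        mat = np.zeros((0, 0))
    else:
        mat = np.atleast_2d(np.cov(x, rowvar=False, ddof=1))
    return SnpCovariance(gene_id=model.gene_id, snp_ids=ids, matrix=mat)


def write_model_db(path, models: dict[str, PredictionModel],
                   covariances: dict[str, SnpCovariance],
                   provenance=None) -> None:
    """Persist weights and covariances as two TSVs under a directory.

    ``weights.tsv``: gene, rsid, ref_allele, eff_allele, weight, cv_r2,
    mixing. ``covariances.tsv``: long format GENE RSID1 RSID2 VALUE with
    (gene, snp_i <= snp_j) rows in sorted order.
    """
    os.makedirs(path, exist_ok=True)
    wrows, crows = [], []
    for gene in sorted(models):
        model = models[gene]
        for _, r in model.snps.iterrows():
            wrows.append({"gene": gene, "rsid": r["rsid"],
                          "ref_allele": r["ref_allele"],
                          "eff_allele": r["eff_allele"],
                          "weight": r["weight"], "cv_r2": model.cv_r2,
                          "mixing": model.mixing})
        cov = covariances.get(gene)
        if cov is None:
            continue
        for i, si in enumerate(cov.snp_ids):
            for j in range(i, len(cov.snp_ids)):
                crows.append({"GENE": gene, "RSID1": si,
                              "RSID2": cov.snp_ids[j],
                              "VALUE": cov.matrix[i, j]})
    write_tsv(pd.DataFrame(
        wrows, columns=["gene", "rsid", "ref_allele", "eff_allele",
                        "weight", "cv_r2", "mixing"]),
        os.path.join(path, "weights.tsv"), provenance)
    write_tsv(pd.DataFrame(crows, columns=["GENE", "RSID1", "RSID2", "VALUE"]),
              os.path.join(path, "covariances.tsv"), provenance)


def read_model_db(path) -> tuple[dict[str, PredictionModel],
                                 dict[str, SnpCovariance]]:
    """Load a model db directory written by :func:`write_model_db`."""
    wpath = os.path.join(path, "weights.tsv")
    cpath = os.path.join(path, "covariances.tsv")
    weights = read_tsv(wpath)
    for lineno, (_, row) in enumerate(weights.iterrows(), start=2):
        if pd.isna(row["weight"]) or not isinstance(row["rsid"], str):
            raise ValueError(f"{wpath}:{lineno}: malformed weight row")
    models: dict[str, PredictionModel] = {}
    for gene, grp in weights.groupby("gene", sort=True):
        models[gene] = PredictionModel(
            gene_id=gene,
            snps=grp[["rsid", "ref_allele", "eff_allele", "weight"]]
            .reset_index(drop=True),
            mixing=float(grp["mixing"].iloc[0]),
            cv_r2=float(grp["cv_r2"].iloc[0]))

    covs: dict[str, SnpCovariance] = {}
    ctable = read_tsv(cpath)
    for gene, grp in ctable.groupby("GENE", sort=True):
        if gene not in models:
            continue
        ids = models[gene].snps["rsid"].tolist()
        index = {s: i for i, s in enumerate(ids)}
        mat = np.zeros((len(ids), len(ids)))
        for lineno, (_, row) in enumerate(grp.iterrows(), start=2):
            try:
                i, j = index[row["RSID1"]], index[row["RSID2"]]
            except KeyError as err:
                raise ValueError(
                    f"{cpath}: covariance names unknown SNP {err} "
                    f"for gene {gene}") from err
            mat[i, j] = mat[j, i] = float(row["VALUE"])
        covs[gene] = SnpCovariance(gene_id=gene, snp_ids=ids, matrix=mat)
    return models, covs
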