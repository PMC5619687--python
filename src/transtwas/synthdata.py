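"""Synthetic multi-ancestry GWAS and reference-transcriptome data.

The generator emulates the data layout of a summary-statistic TWAS of
case-control GWAS cohorts drawn from diverged ancestry groups:

* a reference panel of unrelated individuals with genotype dosages and gene
  expression containing cis-eQTLs (the role played by a whole-blood
  eQTL reference of ~900 RNA-seq samples);
* several case-control cohorts whose allele frequencies diverge from the
  shared ancestral frequencies following the Balding-Nichols model
  (cohort frequency ~ Beta with mean p and variance p(1-p)*Fst);
* a liability model in which disease risk depends on each gene's
  genetically regulated expression (GReX), not on total expression, so the
  generative effect gamma is exactly the estimand of a predicted-expression
  association test.

Linkage disequilibrium is produced by thresholding a latent first-order
autoregressive Gaussian per gene block: corr(latent_i, latent_j) =
rho^|i-j|, giving tunable LD for covariance tests. All randomness flows
from one explicit integer seed through numpy Generators; same seed, same
output, byte for byte.

Published summary tables from a trans-ethnic breast-cancer TWAS of five
GWAS datasets (per-study gene Z-scores, SNP odds ratios with confidence
intervals, and cohort case/control counts) ship as packaged TSV fixtures
and are exposed through :func:`load_published_tables` for regression tests
of the meta-analysis arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from ._io import read_tsv, write_tsv

__all__ = [
    "AncestrySpec",
    "CohortSpec",
    "GeneArchitecture",
    "SimulatedPanel",
    "SimulatedCohort",
    "InvalidArchitectureError",
    "SamplingBudgetExceededError",
    "build_variant_table",
    "standard_architectures",
    "simulate_reference_panel",
    "simulate_cohort",
    "load_published_tables",
    "PublishedTables",
]

#: population prevalence targeted by the liability-model intercept
PREVALENCE = 0.10
#: rejection-sampling budget, as a multiple of the requested cohort size
SAMPLING_BUDGET_FACTOR = 100


class InvalidArchitectureError(ValueError):
    """A gene architecture is internally inconsistent (e.g. h2>0, no eQTLs)."""


class SamplingBudgetExceededError(RuntimeError):
    """Case/control rejection sampling could not fill the cohort in budget."""


@dataclass(frozen=True)
class AncestrySpec:
    """An ancestry group: Fst divergence from the ancestral population."""

    label: str
    fst: float = 0.0
    pc_shift: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.fst < 1.0):
            raise ValueError(f"fst must be in [0, 1), got {self.fst}")


@dataclass(frozen=True)
class CohortSpec:
    """A case-control GWAS cohort to simulate."""

    name: str
    ancestry: AncestrySpec
    n_cases: int
    n_controls: int
    monomorphic_snps: tuple[str, ...] = ()

    def __post_init__(self):
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("n_cases and n_controls must be >= 1")


@dataclass(frozen=True)
class GeneArchitecture:
    """Generative truth for one gene.

    ``causal_eqtls`` lists (variant id, per-allele effect on expression);
    ``h2_cis`` is the fraction of expression variance explained by cis
    genotype; ``gamma`` is the log-odds effect on disease per standard
    deviation of genetically regulated expression.
    """

    gene_id: str
    chrom: str
    tss: int
    gene_end: int
    causal_eqtls: tuple[tuple[str, float], ...] = ()
    h2_cis: float = 0.0
    gamma: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.h2_cis <= 1.0):
            raise ValueError(f"h2_cis must be in [0, 1], got {self.h2_cis}")
        if self.h2_cis > 0 and not self.causal_eqtls:
            raise InvalidArchitectureError(
                f"{self.gene_id}: h2_cis > 0 requires at least one causal eQTL"
            )


@dataclass
class SimulatedPanel:
    """Reference panel: dosages, variant table, and expression matrix."""

    dosages: pd.DataFrame      # samples x variants, values in [0, 2]
    variants: pd.DataFrame     # id, chrom, pos, ref, alt, freq, block
    expression: pd.DataFrame   # samples x genes

    def write(self, outdir, provenance=None):
        write_tsv(self.dosages.reset_index(names="sample"),
                  f"{outdir}/panel_dosage.tsv", provenance)
        write_tsv(self.variants, f"{outdir}/panel_variants.tsv", provenance)
        write_tsv(self.expression.reset_index(names="sample"),
                  f"{outdir}/panel_expression.tsv", provenance)


@dataclass
class SimulatedCohort:
    """One case-control cohort: dosages, variants, phenotype, covariates."""

    name: str
    dosages: pd.DataFrame
    variants: pd.DataFrame
    phenotype: pd.Series       # 0 control / 1 case, indexed like dosages
    covariates: pd.DataFrame

    @property
    def n_cases(self) -> int:
        return int(self.phenotype.sum())

    @property
    def n_controls(self) -> int:
        return int((1 - self.phenotype).sum())

    def write(self, outdir, provenance=None):
        write_tsv(self.dosages.reset_index(names="sample"),
                  f"{outdir}/{self.name}_dosage.tsv", provenance)
        write_tsv(self.variants, f"{outdir}/{self.name}_variants.tsv", provenance)
        pheno = self.covariates.copy()
        pheno.insert(0, "phenotype", self.phenotype)
        write_tsv(pheno.reset_index(names="sample"),
                  f"{outdir}/{self.name}_phenotype.tsv", provenance)


def build_variant_table(architectures, snps_per_gene: int = 6,
                        spacing: int = 5000, seed: int = 0) -> pd.DataFrame:
    """Lay out a cis variant grid around each gene's TSS.

    Each gene gets its own LD block of ``snps_per_gene`` variants spaced
    ``spacing`` bp apart and centred on the TSS, with ancestral allele
    frequencies drawn Uniform(0.1, 0.9). Variant ids are
    ``{gene_id}_v{j}`` so architectures can name causal eQTLs up front.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for block, arch in enumerate(architectures):
        start = arch.tss - spacing * (snps_per_gene // 2)
        for j in range(snps_per_gene):
            rows.append({
                "id": f"{arch.gene_id}_v{j}",
                "chrom": arch.chrom,
                "pos": start + j * spacing,
                "ref": "A",
                "alt": "G",
                "freq": rng.uniform(0.1, 0.9),
                "block": block,
            })
    table = pd.DataFrame(rows)
    if table["id"].duplicated().any():
        raise ValueError("duplicate variant ids across architectures")
    return table


def standard_architectures(n_genes: int, snps_per_gene: int = 6,
                           h2_cis: float = 0.3, gamma=0.0,
                           causal_index: int | None = None,
                           effect: float = 1.0,
                           chrom: str = "1",
                           gene_span: int = 20_000,
                           gene_gap: int = 2_000_000) -> list[GeneArchitecture]:
    """A regular grid of single-eQTL genes, spaced far apart on one chromosome.

    ``gamma`` may be a scalar or a sequence of per-gene values. Genes with
    ``h2_cis == 0`` carry no causal eQTL (pure-noise expression).
    """
    if causal_index is None:
        causal_index = snps_per_gene // 2
    gammas = np.broadcast_to(np.asarray(gamma, dtype=float), (n_genes,))
    archs = []
    for i in range(n_genes):
        gene_id = f"g{i:04d}"
        tss = 1_000_000 + i * gene_gap
        eqtls = () if h2_cis == 0 else ((f"{gene_id}_v{causal_index}", effect),)
        archs.append(GeneArchitecture(
            gene_id=gene_id, chrom=chrom, tss=tss, gene_end=tss + gene_span,
            causal_eqtls=eqtls, h2_cis=h2_cis, gamma=float(gammas[i])))
    return archs


def _ar1_latent(n: int, blocks: np.ndarray, rho: float,
                rng: np.random.Generator) -> np.ndarray:
    """Latent Gaussians with AR(1) correlation rho within each block."""
    m = blocks.size
    eps = rng.standard_normal((n, m))
    if rho == 0.0:
        return eps
    z = eps.copy()
    carry = np.sqrt(1.0 - rho * rho)
    for j in range(1, m):
        if blocks[j] == blocks[j - 1]:
            z[:, j] = rho * z[:, j - 1] + carry * eps[:, j]
    return z


def _draw_dosages(freqs: np.ndarray, blocks: np.ndarray, rho: float,
                  n: int, rng: np.random.Generator) -> np.ndarray:
    """Diploid dosages in {0,1,2} from two thresholded latent haplotypes."""
    thresh = norm.ppf(np.clip(freqs, 0.0, 1.0))
    dos = np.zeros((n, freqs.size))
    for _hap in range(2):
        dos += (_ar1_latent(n, blocks, rho, rng) < thresh)
    return dos


def _grex_matrix(dosages: pd.DataFrame, architectures,
                 weights_truth: dict[str, list[tuple[str, float]]]) -> pd.DataFrame:
    """Genetically regulated expression per gene: sum of effect * centred dosage."""
    cols = {}
    for arch in architectures:
        eqtls = weights_truth.get(arch.gene_id, [])
        g = np.zeros(len(dosages))
        for snp, effect in eqtls:
            vec = dosages[snp].to_numpy(dtype=float)
            g += effect * (vec - vec.mean())
        cols[arch.gene_id] = g
    return pd.DataFrame(cols, index=dosages.index)


def simulate_reference_panel(n_samples: int, architectures,
                             ld_block_rho: float = 0.0, seed: int = 0,
                             snps_per_gene: int = 6, spacing: int = 5000,
                             variants: pd.DataFrame | None = None) -> SimulatedPanel:
    """Simulate the eQTL reference panel: dosages plus expression.

    Expression of each gene is the sum of its causal-eQTL contributions plus
    Gaussian noise scaled so that the genetic fraction of expression
    variance equals ``h2_cis``; ``h2_cis == 0`` genes are pure noise.
    """
    if n_samples < 30:
        raise ValueError("n_samples must be >= 30")
    if not (0.0 <= ld_block_rho < 1.0):
        raise ValueError("ld_block_rho must be in [0, 1)")
    rng = np.random.default_rng(seed)
    if variants is None:
        variants = build_variant_table(architectures, snps_per_gene, spacing,
                                       seed=rng.integers(2**31))
    known = set(variants["id"])
    for arch in architectures:
        for snp, _ in arch.causal_eqtls:
            if snp not in known:
                raise InvalidArchitectureError(
                    f"{arch.gene_id}: causal eQTL {snp} not in variant table")

    dos = _draw_dosages(variants["freq"].to_numpy(),
                        variants["block"].to_numpy(), ld_block_rho,
                        n_samples, rng)
    samples = [f"ref_s{i}" for i in range(n_samples)]
    dosages = pd.DataFrame(dos, index=samples, columns=variants["id"].tolist())

    truth = {a.gene_id: list(a.causal_eqtls) for a in architectures}
    grex = _grex_matrix(dosages, architectures, truth)
    expr = {}
    for arch in architectures:
        g = grex[arch.gene_id].to_numpy()
        var_g = g.var()
        if arch.h2_cis == 0.0 or var_g == 0.0:
            expr[arch.gene_id] = rng.standard_normal(n_samples)
        else:
            noise_sd = np.sqrt(var_g * (1.0 - arch.h2_cis) / arch.h2_cis)
            expr[arch.gene_id] = g + noise_sd * rng.standard_normal(n_samples)
    expression = pd.DataFrame(expr, index=samples)
    return SimulatedPanel(dosages=dosages, variants=variants,
                          expression=expression)


def _cohort_frequencies(ancestral: np.ndarray, fst: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Balding-Nichols draw: Beta with mean p and variance p(1-p)*Fst."""
    if fst == 0.0:
        return ancestral.copy()
    scale = (1.0 - fst) / fst
    freqs = rng.beta(ancestral * scale, (1.0 - ancestral) * scale)
    # keep cohorts polymorphic unless monomorphism is requested explicitly
    return np.clip(freqs, 0.005, 0.995)


def simulate_cohort(spec: CohortSpec, architectures,
                    variants: pd.DataFrame,
                    weights_truth: dict[str, list[tuple[str, float]]] | None = None,
                    ld_block_rho: float = 0.0, seed: int = 0,
                    prevalence: float = PREVALENCE) -> SimulatedCohort:
    """Simulate one case-control cohort under the GReX liability model.

    Risk follows logit P(case) = intercept + sum_g gamma_g * standardized
    GReX_g + ancestry pc_shift, with the intercept calibrated to the target
    population prevalence. Exactly ``spec.n_cases`` cases and
    ``spec.n_controls`` controls are collected by rejection sampling with a
    budget of 100x the requested cohort size.
    """
    rng = np.random.default_rng(seed)
    if weights_truth is None:
        weights_truth = {a.gene_id: list(a.causal_eqtls) for a in architectures}

    freqs = _cohort_frequencies(variants["freq"].to_numpy(dtype=float),
                                spec.ancestry.fst, rng)
    mono = set(spec.monomorphic_snps)
    if mono:
        is_mono = variants["id"].isin(mono).to_numpy()
        freqs = np.where(is_mono, 0.0, freqs)
    cohort_variants = variants.copy()
    cohort_variants["freq"] = freqs

    blocks = variants["block"].to_numpy()
    var_ids = variants["id"].tolist()
    causal = [a for a in architectures if a.gamma != 0.0 or weights_truth.get(a.gene_id)]
    gammas = np.array([a.gamma for a in causal])

    def draw_batch(size):
        dos = _draw_dosages(freqs, blocks, ld_block_rho, size, rng)
        return pd.DataFrame(dos, columns=var_ids)

    # calibrate GReX standardization on a throwaway batch
    calib = draw_batch(2000)
    grex_c = _grex_matrix(calib, causal, weights_truth)
    mu = grex_c.mean().to_numpy()
    sd = grex_c.std(ddof=0).to_numpy()
    sd[sd == 0.0] = 1.0
    intercept = logit(prevalence)

    n_target = spec.n_cases + spec.n_controls
    budget = SAMPLING_BUDGET_FACTOR * n_target
    drawn = 0
    cases = pd.DataFrame(columns=var_ids)
    controls = pd.DataFrame(columns=var_ids)
    while len(cases) < spec.n_cases or len(controls) < spec.n_controls:
        if drawn >= budget:
            raise SamplingBudgetExceededError(
                f"{spec.name}: could not collect {spec.n_cases} cases / "
                f"{spec.n_controls} controls within {budget} draws")
        size = min(max(n_target, 1000), budget - drawn)
        batch = draw_batch(size)
        drawn += size
        grex = (_grex_matrix(batch, causal, weights_truth).to_numpy() - mu) / sd
        eta = intercept + grex @ gammas + spec.ancestry.pc_shift
        y = rng.random(size) < expit(eta)
        new_cases = batch[y].head(spec.n_cases - len(cases))
        new_controls = batch[~y].head(spec.n_controls - len(controls))
        cases = new_cases if cases.empty else pd.concat([cases, new_cases])
        controls = (new_controls if controls.empty
                    else pd.concat([controls, new_controls]))
    dosages = pd.concat([cases, controls], ignore_index=True)
    samples = [f"{spec.name}_s{i}" for i in range(n_target)]
    dosages.index = samples
    phenotype = pd.Series([1] * spec.n_cases + [0] * spec.n_controls,
                          index=samples, name="phenotype")
    covariates = pd.DataFrame({
        "age": np.round(rng.normal(50.0, 8.0, n_target), 1),
        "ancestry_score": spec.ancestry.pc_shift + rng.normal(0.0, 0.5, n_target),
    }, index=samples)
    return SimulatedCohort(name=spec.name, dosages=dosages,
                           variants=cohort_variants, phenotype=phenotype,
                           covariates=covariates)


def read_panel(outdir) -> SimulatedPanel:
    """Load a panel previously written by :meth:`SimulatedPanel.write`."""
    dosages = read_tsv(f"{outdir}/panel_dosage.tsv").set_index("sample")
    variants = read_tsv(f"{outdir}/panel_variants.tsv", dtype={"chrom": str})
    expression = read_tsv(f"{outdir}/panel_expression.tsv").set_index("sample")
    return SimulatedPanel(dosages=dosages, variants=variants,
                          expression=expression)


def read_cohort(outdir, name: str) -> SimulatedCohort:
    """Load a cohort previously written by :meth:`SimulatedCohort.write`."""
    dosages = read_tsv(f"{outdir}/{name}_dosage.tsv").set_index("sample")
    variants = read_tsv(f"{outdir}/{name}_variants.tsv", dtype={"chrom": str})
    pheno = read_tsv(f"{outdir}/{name}_phenotype.tsv").set_index("sample")
    return SimulatedCohort(name=name, dosages=dosages, variants=variants,
                           phenotype=pheno["phenotype"],
                           covariates=pheno.drop(columns=["phenotype"]))


def write_truth(architectures, path, provenance=None) -> None:
    """Persist the generative gene-level truth (gamma, h2_cis) as TSV."""
    rows = [{"gene": a.gene_id, "chrom": a.chrom, "tss": a.tss,
             "gene_end": a.gene_end, "gamma": a.gamma, "h2_cis": a.h2_cis}
            for a in architectures]
    write_tsv(pd.DataFrame(rows), path, provenance)


@dataclass
class PublishedTables:
    """Published trans-ethnic breast-cancer TWAS summary tables.

    ``gene_scan_*``: per-study and meta gene-level Z/P (plus FDR on meta
    rows) for the top genes of the overall and ER-negative scans.
    ``snp_discovery``: per-study odds ratios with 95% CIs for the six SNPs
    predicting TP53INP2 expression, including the printed meta rows.
    ``snp_replication``: discovery-phase vs external-consortium odds ratios
    for the same SNPs. ``study_counts``: case/control counts per cohort and
    phenotype.
    """

    gene_scan_overall: pd.DataFrame
    gene_scan_er_negative: pd.DataFrame
    snp_discovery: pd.DataFrame
    snp_replication: pd.DataFrame
    study_counts: pd.DataFrame

    def gene_z(self, gene: str, phenotype: str, study: str) -> float:
        table = (self.gene_scan_er_negative if phenotype == "er_negative"
                 else self.gene_scan_overall)
        row = table[(table["gene"] == gene) & (table["study"] == study)]
        if row.empty:
            raise KeyError(f"no fixture row for {gene}/{phenotype}/{study}")
        return float(row["zscore"].iloc[0])

    def counts(self, study: str, phenotype: str) -> tuple[int, int]:
        t = self.study_counts
        row = t[(t["study"] == study) & (t["phenotype"] == phenotype)]
        if row.empty:
            raise KeyError(f"no counts for {study}/{phenotype}")
        return int(row["n_cases"].iloc[0]), int(row["n_controls"].iloc[0])


def load_published_tables() -> PublishedTables:
    """Load the packaged published summary tables."""
    root = resources.files("transtwas") / "fixtures"
    def rd(name):
        with resources.as_file(root / name) as path:
            return read_tsv(path, dtype={"chrom": str})
    return PublishedTables(
        gene_scan_overall=rd("gene_scan_overall.tsv"),
        gene_scan_er_negative=rd("gene_scan_er_negative.tsv"),
        snp_discovery=rd("snp_assoc_discovery.tsv"),
        snp_replication=rd("snp_assoc_replication.tsv"),
        study_counts=rd("study_counts.tsv"),
    )
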