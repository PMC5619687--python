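"""End-to-end orchestration of the expression-based association pipeline.

Stages: simulate (optional) -> per-study SNP GWAS -> train (or load)
expression models -> per-study gene scan -> cross-study meta-analysis ->
post-processing (FDR, QQ coordinates, locus enrichment). Every output TSV
carries a provenance header (config hash, seed, package version) and the
whole run is deterministic given the seed: identical config + seed
reproduces identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__
from ._io import read_tsv, write_tsv
from . import gwas_assoc, gene_assoc, metacombine, posthoc, synthdata
from .expr_model import build_covariance, read_model_db, train_elastic_net, write_model_db
from .gwas_assoc import run_study_gwas, write_summary_stats
from .synthdata import (AncestrySpec, CohortSpec, simulate_cohort,
                        simulate_reference_panel, standard_architectures)

log = logging.getLogger("transtwas")

__all__ = ["PipelineConfig", "run_pipeline", "validate_formats",
           "parse_config"]


@dataclass
class PipelineConfig:
    """Scalar knobs of the analysis plus simulation sizes for demo runs."""

    outdir: str = "transtwas_out"
    seed: int = 0
    phenotype: str = "overall"         # overall | er_negative (label only)
    maf_threshold: float = 0.05
    n_pcs: int = 4
    cis_window: int = 1_000_000
    mixing: float = 0.5
    cv_folds: int = 10
    locus_window: int = 250_000
    alpha: float = 0.05
    # simulation block
    n_panel: int = 900
    n_genes: int = 100
    snps_per_gene: int = 6
    ld_rho: float = 0.3
    h2_cis: float = 0.3
    n_causal_genes: int = 5
    gamma: float = 0.3
    cohort_size: int = 2000
    n_cohorts: int = 2
    fst: float = 0.05

    def __post_init__(self):
        if not (0 <= self.maf_threshold < 0.5):
            raise ValueError("maf_threshold must be in [0, 0.5)")
        if not (0 <= self.mixing <= 1):
            raise ValueError("mixing must be in [0, 1]")
        if self.alpha <= 0 or self.alpha >= 1:
            raise ValueError("alpha must be in (0, 1)")

    def hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("outdir")  # paths do not affect the analysis
        payload = json.dumps(payload, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def provenance(self) -> dict:
        return {"config_hash": self.hash(), "seed": self.seed,
                "transtwas_version": __version__}


def parse_config(path) -> PipelineConfig:
    """Read a plain key=value config file; unknown keys are an error."""
    fields = {f.name: f.type for f in dataclasses.fields(PipelineConfig)}
    values = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value")
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key not in fields:
                raise ValueError(f"{path}:{lineno}: unknown option {key!r}")
            hint = str(fields[key])
            if "int" in hint:
                values[key] = int(raw)
            elif "float" in hint:
                values[key] = float(raw)
            else:
                values[key] = raw
    return PipelineConfig(**values)


def _demo_cohort_specs(config: PipelineConfig) -> list[CohortSpec]:
    half = config.cohort_size // 2
    specs = []
    for i in range(config.n_cohorts):
        ancestry = AncestrySpec(label=f"pop{i}", fst=config.fst * i,
                                pc_shift=0.2 * i)
        specs.append(CohortSpec(name=f"cohort{i}", ancestry=ancestry,
                                n_cases=half,
                                n_controls=config.cohort_size - half))
    return specs


def run_pipeline(config: PipelineConfig, architectures=None,
                 cohort_specs=None, model_db: str | None = None) -> dict:
    """Run the full analysis; returns a bundle of in-memory results.

    With no ``architectures``/``cohort_specs`` a demo simulation is set up
    from the config's simulation block (the first ``n_causal_genes`` genes
    carry alternating-sign gamma, the rest are null).
    """
    started = time.time()
    prov = config.provenance()
    out = config.outdir
    os.makedirs(out, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    if architectures is None:
        gammas = np.zeros(config.n_genes)
        signs = np.resize([1.0, -1.0], config.n_causal_genes)
        gammas[:config.n_causal_genes] = signs * config.gamma
        architectures = standard_architectures(
            config.n_genes, snps_per_gene=config.snps_per_gene,
            h2_cis=config.h2_cis, gamma=gammas)
    if cohort_specs is None:
        cohort_specs = _demo_cohort_specs(config)

    log.info("simulate: panel n=%d, %d genes", config.n_panel,
             len(architectures))
    panel = simulate_reference_panel(
        config.n_panel, architectures, ld_block_rho=config.ld_rho,
        seed=int(rng.integers(2**31)))
    panel.write(out, prov)
    synthdata.write_truth(architectures, f"{out}/truth.tsv", prov)

    if model_db is not None:
        models, covariances = read_model_db(model_db)
    else:
        log.info("train: elastic net (mixing=%.2f) for %d genes",
                 config.mixing, len(architectures))
        models, covariances = {}, {}
        train_seed = int(rng.integers(2**31))
        for arch in architectures:
            model = train_elastic_net(
                panel, arch.gene_id, tss=arch.tss, chrom=arch.chrom,
                cis_window=config.cis_window, mixing=config.mixing,
                folds=config.cv_folds, seed=train_seed,
                maf_threshold=config.maf_threshold)
            models[arch.gene_id] = model
            covariances[arch.gene_id] = build_covariance(panel.dosages, model)
        write_model_db(f"{out}/model_db", models, covariances, prov)

    gene_tables, neff = [], {}
    for spec in cohort_specs:
        t0 = time.time()
        cohort = simulate_cohort(spec, architectures, panel.variants,
                                 ld_block_rho=config.ld_rho,
                                 seed=int(rng.integers(2**31)))
        cohort.write(out, prov)
        summary = run_study_gwas(cohort, n_pcs=config.n_pcs,
                                 maf_threshold=config.maf_threshold)
        write_summary_stats(summary, f"{out}/{spec.name}_summary.tsv", prov)
        reduction: dict = {}
        scan = gene_assoc.run_study_genescan(
            summary, models, covariances, study=spec.name,
            maf_threshold=config.maf_threshold, reduction_log=reduction)
        gene_assoc.write_gene_assoc(scan, f"{out}/{spec.name}_genes.tsv", prov)
        for gene, reasons in reduction.items():
            log.debug("reduce %s/%s: %s", spec.name, gene, reasons)
        gene_tables.append(scan)
        neff[spec.name] = metacombine.effective_n(spec.n_cases,
                                                  spec.n_controls)
        log.info("study %s: %d SNPs, %d genes, %.1fs", spec.name,
                 len(summary), len(scan), time.time() - t0)

    long_table = pd.concat(gene_tables, ignore_index=True)
    meta = metacombine.meta_z_genes(long_table, neff)
    metacombine.write_meta_genes(meta, f"{out}/meta_genes.tsv", prov)

    tested = meta[np.isfinite(meta["pvalue"].to_numpy(dtype=float))].copy()
    m = len(tested)
    report = {}
    if m:
        tested["fdr"] = posthoc.bh_adjust(tested["pvalue"].to_numpy(), m)
        write_tsv(tested, f"{out}/meta_genes_fdr.tsv", prov)
        qq = posthoc.qq_points(tested["pvalue"].to_numpy())
        posthoc.write_qq(qq, f"{out}/qq.tsv", prov)
        report["bonferroni"] = posthoc.bonferroni_threshold(m, config.alpha)

        # demo locus catalogue: index variants at the causal genes' TSS
        causal = [a for a in architectures if a.gamma != 0.0]
        if causal:
            catalog = posthoc.LocusCatalog(
                loci=pd.DataFrame({
                    "locus_id": [f"locus_{a.gene_id}" for a in causal],
                    "chrom": [a.chrom for a in causal],
                    "pos": [a.tss for a in causal]}),
                window=config.locus_window)
            bodies = pd.DataFrame({
                "gene": [a.gene_id for a in architectures],
                "chrom": [a.chrom for a in architectures],
                "start": [a.tss for a in architectures],
                "end": [a.gene_end for a in architectures]})
            near = posthoc.classify_proximity(bodies, catalog)
            sig = tested.set_index("gene")["pvalue"] < config.alpha
            sig = bodies["gene"].map(sig).fillna(False).to_numpy(dtype=bool)
            near = near.to_numpy(dtype=bool)
            a_ = int((near & sig).sum()); b_ = int((near & ~sig).sum())
            c_ = int((~near & sig).sum()); d_ = int((~near & ~sig).sum())
            try:
                enrich = posthoc.enrichment_chi2(a_, b_, c_, d_)
                posthoc.write_enrichment(enrich, f"{out}/enrichment.tsv", prov)
                report["enrichment_p"] = enrich.pvalue
            except ValueError:
                log.info("enrichment skipped: degenerate 2x2 margin")

    log.info("pipeline done in %.1fs", time.time() - started)
    return {"panel": panel, "models": models, "covariances": covariances,
            "gene_tables": gene_tables, "meta_genes": meta, "neff": neff,
            "report": report, "provenance": prov}


_FORMATS = {
    "summary": gwas_assoc.SUMMARY_COLUMNS,
    "weights": ["gene", "rsid", "ref_allele", "eff_allele", "weight",
                "cv_r2", "mixing"],
    "covariance": ["GENE", "RSID1", "RSID2", "VALUE"],
    "gene_assoc": ["gene", "study", "zscore", "pvalue", "n_model_snps",
                   "n_snps_used"],
    "locus": ["locus_id", "chrom", "pos"],
}

_VALID_ALLELES = set("ACGT")


def validate_formats(path, format_name: str) -> list[dict]:
    """Schema/content checks for the pipeline's tabular formats.

    Returns a machine-readable list of {level, row, message} records;
    an empty list means the file is well formed. Missing BETA/SE values
    are warnings (rows retained as missing); duplicate variant ids and
    schema violations are errors.
    """
    if format_name not in _FORMATS:
        raise ValueError(f"unknown format {format_name!r}; expected one of "
                         f"{sorted(_FORMATS)}")
    issues: list[dict] = []
    df = read_tsv(path)
    expected = _FORMATS[format_name]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        return [{"level": "error", "row": 0,
                 "message": f"missing columns {missing}"}]
    if format_name == "summary":
        dup = df["SNP"][df["SNP"].duplicated()]
        for idx in dup.index:
            issues.append({"level": "error", "row": int(idx),
                           "message": f"duplicated variant id {df['SNP'][idx]}"})
        for idx, row in df.iterrows():
            if not (set(str(row["A1"])) <= _VALID_ALLELES
                    and set(str(row["A2"])) <= _VALID_ALLELES):
                issues.append({"level": "error", "row": int(idx),
                               "message": f"bad alleles {row['A1']}/{row['A2']}"})
            if row["POS"] <= 0:
                issues.append({"level": "error", "row": int(idx),
                               "message": "non-positive coordinate"})
            if pd.isna(row["BETA"]) or pd.isna(row["SE"]):
                issues.append({"level": "warning", "row": int(idx),
                               "message": "missing estimate; row kept as NA"})
            elif not (0 <= row["FREQ1"] <= 1):
                issues.append({"level": "error", "row": int(idx),
                               "message": "frequency outside [0, 1]"})
    elif format_name == "locus":
        for idx, row in df.iterrows():
            if row["pos"] <= 0:
                issues.append({"level": "error", "row": int(idx),
                               "message": "non-positive coordinate"})
    elif format_name == "weights":
        dup = df.duplicated(subset=["gene", "rsid"])
        for idx in df.index[dup]:
            issues.append({"level": "error", "row": int(idx),
                           "message": "duplicated (gene, rsid)"})
    return issues
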