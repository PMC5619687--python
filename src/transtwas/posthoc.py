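"""Multiple testing, QQ diagnostics, and known-locus enrichment.

Bonferroni threshold alpha/m; Benjamini-Hochberg step-up FDR adjustment
that can evaluate a truncated top-k list against the full genome-wide test
count m (valid when the unlisted p-values are all larger than the listed
ones, as for a published top-genes table); gene-to-locus proximity using
gene-body distance with an inclusive window; Pearson chi-square enrichment
on the resulting 2x2 table without continuity correction; and QQ plot
coordinates on the -log10 scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from ._io import write_tsv

__all__ = [
    "LocusCatalog",
    "EnrichmentTable",
    "bonferroni_threshold",
    "bh_adjust",
    "classify_proximity",
    "enrichment_chi2",
    "qq_points",
]


@dataclass
class LocusCatalog:
    """Index-variant positions of known susceptibility loci."""

    loci: pd.DataFrame  # locus_id, chrom, pos (1-based)
    window: int = 250_000

    def __post_init__(self):
        if self.window < 0:
            raise ValueError("window must be >= 0")
        if (self.loci["pos"] <= 0).any():
            raise ValueError("locus positions must be positive")

    @classmethod
    def from_tsv(cls, path, window: int = 250_000) -> "LocusCatalog":
        from ._io import read_tsv
        df = read_tsv(path, dtype={"chrom": str})
        return cls(loci=df[["locus_id", "chrom", "pos"]], window=window)


@dataclass
class EnrichmentTable:
    """2x2 near-locus x significance table with its chi-square test."""

    a: int  # near locus, significant
    b: int  # near locus, not significant
    c: int  # far, significant
    d: int  # far, not significant
    prop_near: float
    prop_far: float
    chi2_stat: float
    pvalue: float


def bonferroni_threshold(m: int, alpha: float = 0.05) -> float:
    """Family-wise per-test threshold alpha/m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def bh_adjust(pvalues, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values against m total tests.

    ``m`` may exceed the list length to adjust a top-k list against a
    genome-wide test count (the unlisted p-values are assumed larger).
    Returns values in the input order, clipped at 1 and monotone in rank.
    """
    p = np.asarray(pvalues, dtype=float)
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError(f"m={m} smaller than number of p-values {p.size}")
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty_like(adjusted)
    out[order] = adjusted
    return out


def classify_proximity(genes: pd.DataFrame, catalog: LocusCatalog
                       ) -> pd.Series:
    """Flag each gene as near (True) / far (False) from any known locus.

    A gene is near iff the distance between its body interval
    [start, end] and an index variant on the same chromosome is <= window
    (inclusive; zero if the variant falls inside the gene body).
    """
    flags = []
    loci_by_chrom = {str(c): g["pos"].to_numpy()
                     for c, g in catalog.loci.groupby("chrom")}
    for _, row in genes.iterrows():
        pos = loci_by_chrom.get(str(row["chrom"]))
        if pos is None:
            flags.append(False)
            continue
        start, end = row["start"], row["end"]
        dist = np.where(pos < start, start - pos,
                        np.where(pos > end, pos - end, 0))
        flags.append(bool((dist <= catalog.window).any()))
    return pd.Series(flags, index=genes.index, name="near_locus")


def enrichment_chi2(a: int, b: int, c: int, d: int) -> EnrichmentTable:
    """Pearson chi-square (no continuity correction) on the 2x2 table."""
    for count in (a, b, c, d):
        if count < 0:
            raise ValueError("counts must be >= 0")
    n = a + b + c + d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(mg == 0 for mg in margins):
        raise ValueError("both margins of the 2x2 table must be positive")
    stat = n * (a * d - b * c) ** 2 / np.prod(margins, dtype=float)
    return EnrichmentTable(
        a=a, b=b, c=c, d=d,
        prop_near=a / (a + b), prop_far=c / (c + d),
        chi2_stat=float(stat), pvalue=float(chi2.sf(stat, df=1)))


def qq_points(pvalues) -> pd.DataFrame:
    """Expected vs observed -log10(p) quantiles for a QQ plot."""
    p = np.asarray(pvalues, dtype=float)
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    n = p.size
    observed = -np.log10(np.sort(p))  # largest -log10 first, matching expected
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    return pd.DataFrame({"expected": expected, "observed": observed})


def write_qq(points: pd.DataFrame, path, provenance=None) -> None:
    write_tsv(points, path, provenance)


def write_enrichment(table: EnrichmentTable, path, provenance=None) -> None:
    write_tsv(pd.DataFrame([{
        "near_significant": table.a, "near_total": table.a + table.b,
        "far_significant": table.c, "far_total": table.c + table.d,
        "prop_near": table.prop_near, "prop_far": table.prop_far,
        "chi2": table.chi2_stat, "pvalue": table.pvalue,
    }]), path, provenance)
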