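"""Per-gene sequencing-coverage fractions and gene exclusion filters.

A coding base counts as sufficiently covered when tumor depth >= 14 and
matched-normal depth >= 8 (the thresholds used by the TCGA exome pipelines);
a gene's coverage fraction in one sample is the covered share of its coding
bases (longest transcript, plus 25 bp flanks when depth arrays include
them). Cohort-level medians of these fractions feed two places downstream:
genes with median coverage below 50% are excluded outright, and the mutated
patient fraction of every kept gene is divided by its median coverage so
that poorly covered genes are not mistaken for conserved ones.

The primary input is a precomputed long-format TSV of per-sample per-gene
fractions; :func:`coverage_fraction` implements the per-base depth rule for
callers that do have depth arrays.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataFormatError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DepthThresholds:
    """Sufficient-coverage rule: minimum depths and flank width in bp."""

    tumor_min: int = 14
    normal_min: int = 8
    flank: int = 25

    def __post_init__(self):
        if self.tumor_min <= 0 or self.normal_min <= 0 or self.flank <= 0:
            raise ConfigError("depth thresholds and flank must be strictly positive")


@dataclass
class GeneCoverage:
    """Per-sample coverage fractions for one gene, plus the cohort median."""

    gene_symbol: str
    per_sample_fraction: dict[str, float]
    median_fraction: float = field(default=float("nan"))

    def __post_init__(self):
        for sample, frac in self.per_sample_fraction.items():
            if not (0.0 <= frac <= 1.0):
                raise DataFormatError(
                    f"coverage fraction {frac} for {self.gene_symbol}/{sample} outside [0, 1]"
                )
        if np.isnan(self.median_fraction) and self.per_sample_fraction:
            self.median_fraction = float(np.median(list(self.per_sample_fraction.values())))


def coverage_fraction(
    tumor_depths: np.ndarray,
    normal_depths: np.ndarray,
    thresholds: DepthThresholds | None = None,
) -> float:
    """Fraction of bases with tumor depth >= tumor_min and normal depth >= normal_min.

    Both arrays must span the same region (coding bases plus flanks),
    one entry per base.
    """
    thresholds = thresholds or DepthThresholds()
    tumor = np.asarray(tumor_depths)
    normal = np.asarray(normal_depths)
    if tumor.shape != normal.shape:
        raise DataFormatError(
            f"tumor and normal depth arrays differ in length ({tumor.size} vs {normal.size})"
        )
    if tumor.size == 0:
        raise DataFormatError("empty region: no bases to assess coverage on")
    ok = (tumor >= thresholds.tumor_min) & (normal >= thresholds.normal_min)
    return float(ok.mean())


def median_coverage(gc: GeneCoverage, cohort_samples: Iterable[str]) -> float:
    """Median coverage fraction of a gene over the cohort's samples.

    Samples missing from the gene's coverage map are logged and skipped;
    an even count uses the mean of the two central values (numpy median).
    """
    cohort = list(cohort_samples)
    present = [s for s in cohort if s in gc.per_sample_fraction]
    n_missing = len(cohort) - len(present)
    if n_missing:
        logger.warning(
            "median_coverage(%s): %d of %d cohort samples have no coverage value; skipped",
            gc.gene_symbol,
            n_missing,
            len(cohort),
        )
    if not present:
        raise DataFormatError(
            f"no coverage values for gene {gc.gene_symbol} overlap the cohort samples"
        )
    return float(np.median([gc.per_sample_fraction[s] for s in present]))


@dataclass(frozen=True)
class FilterThresholds:
    """Gene-exclusion cutoffs. Genes strictly below either cutoff are dropped;
    values exactly at the boundary are kept."""

    min_median_cov: float = 0.5
    min_expression_log2: float = 2.0


def read_coverage_tsv(path: str | Path) -> pd.DataFrame:
    """Read a long-format coverage table: gene_symbol, sample_id, fraction."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_symbol": str, "sample_id": str})
    missing = {"gene_symbol", "sample_id", "fraction"} - set(df.columns)
    if missing:
        raise DataFormatError(f"coverage TSV missing column(s): {', '.join(sorted(missing))}")
    bad = ~df["fraction"].between(0.0, 1.0)
    if bad.any():
        raise DataFormatError(f"coverage TSV has {int(bad.sum())} fraction(s) outside [0, 1]")
    return df


def read_annotation_tsv(path: str | Path) -> pd.DataFrame:
    """Read the gene annotation table: gene_symbol, coding_length, annotation_error."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_symbol": str})
    missing = {"gene_symbol", "coding_length"} - set(df.columns)
    if missing:
        raise DataFormatError(f"annotation TSV missing column(s): {', '.join(sorted(missing))}")
    if "annotation_error" not in df.columns:
        df["annotation_error"] = False
    df["annotation_error"] = df["annotation_error"].astype(bool)
    if (df["coding_length"] <= 0).any():
        raise DataFormatError("annotation TSV has non-positive coding_length values")
    return df


def read_expression_tsv(path: str | Path, aggregator: str = "median") -> pd.Series:
    """Read per-gene expression (log2 counts) as a Series indexed by gene.

    Accepts either a two-column table (gene_symbol, expression_log2) or a
    wide per-sample matrix, which is summarized per gene with `aggregator`
    ("median" or "mean").
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_symbol": str})
    if "gene_symbol" not in df.columns:
        raise DataFormatError("expression TSV missing column: gene_symbol")
    df = df.set_index("gene_symbol")
    if "expression_log2" in df.columns:
        return df["expression_log2"].astype(float)
    if df.shape[1] == 0:
        raise DataFormatError("expression TSV has no expression columns")
    if aggregator == "median":
        return df.median(axis=1)
    if aggregator == "mean":
        return df.mean(axis=1)
    raise ConfigError(f"unknown expression aggregator {aggregator!r}")


def cohort_median_coverage(
    coverage: pd.DataFrame, cohort_samples: Iterable[str]
) -> pd.Series:
    """Per-gene median coverage fraction over the given cohort samples."""
    cohort = set(cohort_samples)
    sub = coverage[coverage["sample_id"].isin(cohort)]
    if sub.empty:
        raise DataFormatError("no coverage rows overlap the cohort samples")
    return sub.groupby("gene_symbol")["fraction"].median()


REASON_COVERAGE = "coverage"
REASON_EXPRESSION = "expression"
REASON_ANNOTATION = "annotation_error"


def filter_genes(
    annotations: pd.DataFrame,
    median_cov: Mapping[str, float] | pd.Series,
    expression: Mapping[str, float] | pd.Series,
    thresholds: FilterThresholds | None = None,
) -> tuple[set[str], pd.DataFrame]:
    """Apply the gene exclusion filters; return (kept genes, exclusion report).

    A gene is kept when median coverage >= min_median_cov AND expression
    >= min_expression_log2 AND it carries no annotation-error flag. The
    report lists every excluded gene with all reasons that apply
    ("coverage", "expression", "annotation_error", comma-joined). Genes with
    no coverage value at all are treated as median 0 (logged).
    """
    thresholds = thresholds or FilterThresholds()
    median_cov = pd.Series(dict(median_cov)) if not isinstance(median_cov, pd.Series) else median_cov
    expression = pd.Series(dict(expression)) if not isinstance(expression, pd.Series) else expression

    kept: set[str] = set()
    rows = []
    n_no_cov = 0
    for row in annotations.itertuples(index=False):
        gene = row.gene_symbol
        m = float(median_cov.get(gene, np.nan))
        if np.isnan(m):
            n_no_cov += 1
            m = 0.0
        e = float(expression.get(gene, np.nan))
        if np.isnan(e):
            e = -np.inf  # unmeasured expression cannot clear the floor
        reasons = []
        if m < thresholds.min_median_cov:
            reasons.append(REASON_COVERAGE)
        if e < thresholds.min_expression_log2:
            reasons.append(REASON_EXPRESSION)
        if bool(row.annotation_error):
            reasons.append(REASON_ANNOTATION)
        if reasons:
            rows.append({"gene_symbol": gene, "reasons": ",".join(reasons), "median_coverage": m, "expression_log2": e})
        else:
            kept.add(gene)
    if n_no_cov:
        logger.warning("filter_genes: %d genes had no coverage value; treated as median 0", n_no_cov)
    report = pd.DataFrame(rows, columns=["gene_symbol", "reasons", "median_coverage", "expression_log2"])
    logger.info("filter_genes: kept %d of %d genes", len(kept), len(annotations))
    return kept, report
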