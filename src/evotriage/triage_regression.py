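"""The selection statistic: size-adjusted standardized residuals.

For each gene in a cohort we compute the fraction of patients carrying at
least one protein-altering mutation, divide it by the gene's median coverage
fraction (so under-sequenced genes are not mistaken for conserved ones), and
regress the square root of this corrected fraction on the square root of
coding length. Under a neutral per-base mutation process with small
per-gene hit probability p ~ rate x length, sqrt(p) is close to linear in
sqrt(length) and the square-root transform stabilizes the binomial variance
of the observed fraction, so neutral genes scatter homoscedastically around
the line. Each gene's standardized residual (SR) — its vertical distance
from the line divided by the residual scale — is the selection score:
SR <= -1 flags conservation (negative selection), SR >= +1 flags
over-mutation (positive selection / drivers), with |SR| >= 1.65 and
|SR| >= 2.0 as the suggestive and significant tiers (two-sided normal
p = 0.1 and 0.05).

The fit is OLS by default; a Huber M-estimator ("huber") is available so
heavily over-mutated drivers do not drag the background line upward.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataFormatError, EvoTriageError
from .maf_io import MutationRecord, VariantClassPolicy, is_protein_altering

logger = logging.getLogger(__name__)

LABEL_CONSERVED = "conserved"
LABEL_BACKGROUND = "background"
LABEL_OVER_MUTATED = "over_mutated"

TIER_NONE = "none"
TIER_SUGGESTIVE = "suggestive"
TIER_SIGNIFICANT = "significant"


@dataclass(frozen=True)
class Thresholds:
    """SR cutoffs: |SR| >= flag labels a gene, the tiers add significance."""

    flag: float = 1.0
    suggestive: float = 1.65
    significant: float = 2.0

    def __post_init__(self):
        if not (0 < self.flag <= self.suggestive <= self.significant):
            raise ConfigError("thresholds must satisfy 0 < flag <= suggestive <= significant")


@dataclass(frozen=True)
class TriageModel:
    """Fitted background-mutation line y = intercept + slope * x."""

    intercept: float
    slope: float
    residual_scale: float
    n_genes: int
    estimator: str = "ols"

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)


def mutation_fractions(
    records: Iterable[MutationRecord],
    cohort_patients: Sequence[str],
    policy: VariantClassPolicy | None = None,
) -> pd.DataFrame:
    """Per-gene mutated-patient counts and fractions for one cohort.

    A patient counts at most once per gene no matter how many qualifying
    mutations it carries. Returns a DataFrame indexed by gene_symbol with
    columns n_mutated and f; genes never mutated in the cohort are absent
    (callers fill 0).
    """
    cohort = set(cohort_patients)
    if not cohort:
        raise DataFormatError("mutation_fractions: empty cohort")
    policy = policy or VariantClassPolicy()
    pairs = {
        (r.gene_symbol, r.patient_id)
        for r in records
        if r.patient_id in cohort and is_protein_altering(r, policy)
    }
    counts: dict[str, int] = {}
    for gene, _ in pairs:
        counts[gene] = counts.get(gene, 0) + 1
    df = pd.DataFrame(
        {"n_mutated": pd.Series(counts, dtype=int)}
    ).rename_axis("gene_symbol")
    df["f"] = df["n_mutated"] / len(cohort)
    return df.sort_index()


def mutation_fraction(
    records: Iterable[MutationRecord],
    cohort_patients: Sequence[str],
    gene: str,
    policy: VariantClassPolicy | None = None,
) -> tuple[int, float]:
    """(number of mutated patients, fraction) for a single gene."""
    df = mutation_fractions(records, cohort_patients, policy)
    if gene in df.index:
        return int(df.loc[gene, "n_mutated"]), float(df.loc[gene, "f"])
    return 0, 0.0


def corrected_fraction(f: float, median_cov: float) -> float:
    """Coverage-corrected mutated fraction c = f / m. Not capped at 1."""
    if median_cov <= 0:
        raise DataFormatError(
            f"median coverage {median_cov} is not positive; the gene should have been filtered"
        )
    return f / median_cov


def fit_triage(
    x: Sequence[float],
    y: Sequence[float],
    estimator: str = "ols",
) -> TriageModel:
    """Fit the background line y ~ x on (sqrt length, sqrt corrected fraction).

    estimator "ols" uses least squares with residual scale
    sqrt(RSS / (n - 2)); "huber" uses a Huber M-estimator (tuning constant
    1.345) with its robust MAD-based scale.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DataFormatError("x and y must have the same length")
    n = x.size
    if n < 3:
        raise DataFormatError(f"fit_triage needs at least 3 genes, got {n}")
    if np.ptp(x) == 0:
        raise DataFormatError("all gene sizes identical: regression on size is degenerate")

    if estimator == "ols":
        design = np.column_stack([np.ones(n), x])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        intercept, slope = float(coef[0]), float(coef[1])
        rss = float(np.sum((y - design @ coef) ** 2))
        scale = float(np.sqrt(rss / (n - 2)))
    elif estimator == "huber":
        import statsmodels.api as sm

        design = sm.add_constant(x)
        fit = sm.RLM(y, design, M=sm.robust.norms.HuberT(t=1.345)).fit()
        intercept, slope = float(fit.params[0]), float(fit.params[1])
        scale = float(fit.scale)
    else:
        raise ConfigError(f"unknown estimator {estimator!r}; use 'ols' or 'huber'")
    return TriageModel(intercept=intercept, slope=slope, residual_scale=scale, n_genes=n, estimator=estimator)


def standardized_residuals(
    model: TriageModel,
    x: Sequence[float],
    y: Sequence[float],
    studentized: bool = False,
) -> np.ndarray:
    """SR per gene: (y - fitted) / residual_scale.

    With studentized=True each residual is additionally divided by
    sqrt(1 - leverage) (internal studentization; OLS leverages).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    # an exactly-collinear input leaves only rounding noise in the RSS;
    # treat that as a zero scale too
    if model.residual_scale <= 1e-12:
        raise EvoTriageError(
            "residual scale is zero (perfect fit); the input is degenerate — "
            "standardized residuals are undefined"
        )
    resid = y - model.predict(x)
    sr = resid / model.residual_scale
    if studentized:
        n = x.size
        xbar = x.mean()
        sxx = float(np.sum((x - xbar) ** 2))
        leverage = 1.0 / n + (x - xbar) ** 2 / sxx
        sr = sr / np.sqrt(1.0 - leverage)
    return sr


def classify(sr: float, thresholds: Thresholds | None = None) -> tuple[str, str, float]:
    """Label a gene from its SR: (label, tier, two-sided normal p).

    The p-value mirrors the normal reference used for the tier cutoffs
    (|SR| >= 1.65 ~ p 0.1, |SR| >= 2.0 ~ p 0.05); no multiple-testing
    correction is applied.
    """
    thresholds = thresholds or Thresholds()
    a = abs(sr)
    if a >= thresholds.flag:
        label = LABEL_CONSERVED if sr < 0 else LABEL_OVER_MUTATED
    else:
        label = LABEL_BACKGROUND
    if a >= thresholds.significant:
        tier = TIER_SIGNIFICANT
    elif a >= thresholds.suggestive:
        tier = TIER_SUGGESTIVE
    else:
        tier = TIER_NONE
    p = float(2.0 * stats.norm.sf(a))
    return label, tier, p


def frequently_mutated(scores: pd.DataFrame, cutoff: float = 0.10) -> set[str]:
    """Genes with raw mutated fraction strictly greater than the cutoff."""
    if scores.empty:
        return set()
    return set(scores.index[scores["f"] > cutoff])


def score_cohort(
    records: Iterable[MutationRecord],
    cohort_patients: Sequence[str],
    coding_length: Mapping[str, float] | pd.Series,
    median_cov: Mapping[str, float] | pd.Series,
    kept_genes: Iterable[str],
    policy: VariantClassPolicy | None = None,
    thresholds: Thresholds | None = None,
    estimator: str = "ols",
    studentized: bool = False,
) -> tuple[pd.DataFrame, TriageModel]:
    """Run the full per-cohort scoring: fractions -> correction -> fit -> SR.

    Genes in `kept_genes` (the post-filter set) are scored even when never
    mutated (f = 0 enters the fit as sqrt(0)). Returns a DataFrame indexed
    by gene_symbol with columns n_mutated, cohort_size, f, m, c, sr, label,
    tier, p_two_sided (plus coding_length), and the fitted model.
    """
    thresholds = thresholds or Thresholds()
    coding_length = pd.Series(dict(coding_length)) if not isinstance(coding_length, pd.Series) else coding_length
    median_cov = pd.Series(dict(median_cov)) if not isinstance(median_cov, pd.Series) else median_cov
    genes = sorted(kept_genes)
    if not genes:
        raise DataFormatError("score_cohort: no genes survive the filters")
    missing_len = [g for g in genes if g not in coding_length.index]
    if missing_len:
        raise DataFormatError(f"score_cohort: {len(missing_len)} kept genes lack coding_length (e.g. {missing_len[:3]})")

    frac = mutation_fractions(records, cohort_patients, policy)
    n_cohort = len(set(cohort_patients))

    df = pd.DataFrame(index=pd.Index(genes, name="gene_symbol"))
    df["coding_length"] = coding_length.reindex(genes).astype(float)
    df["n_mutated"] = frac["n_mutated"].reindex(genes).fillna(0).astype(int)
    df["cohort_size"] = n_cohort
    df["f"] = df["n_mutated"] / n_cohort
    df["m"] = median_cov.reindex(genes).astype(float)
    df["c"] = [corrected_fraction(f, m) for f, m in zip(df["f"], df["m"])]

    x = np.sqrt(df["coding_length"].to_numpy())
    y = np.sqrt(df["c"].to_numpy())
    model = fit_triage(x, y, estimator=estimator)
    df["sr"] = standardized_residuals(model, x, y, studentized=studentized)

    labels, tiers, ps = zip(*(classify(s, thresholds) for s in df["sr"]))
    df["label"] = labels
    df["tier"] = tiers
    df["p_two_sided"] = ps
    return df, model


def write_scores(scores: pd.DataFrame, path) -> None:
    """Write a cohort score table as TSV with stable float formatting."""
    scores.reset_index().to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_scores(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"gene_symbol": str}).set_index("gene_symbol")
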