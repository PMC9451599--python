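"""Seeded synthetic tumor cohorts with planted selection.

The generator emulates the statistical structure the pipeline is built for:
a gene universe with log-normally distributed coding lengths, patient-level
Bernoulli mutation events whose per-gene probability follows a neutral
per-base rate scaled by a selection multiplier (1 = neutral, < 1 conserved,
> 1 positively selected), near-1 coverage fractions with planted
low-coverage genes, and expression values with planted low-expression
genes. Optional driver planting writes hotspot protein changes (KRAS G12
class, BRAF V600 class, EGFR L858 class and exon-19 in-frame deletions)
into chosen patients so cohort stratification can be tested against a truth
table.

A patient mutates gene g with probability 1 - (1 - rate * multiplier)^length
— the chance that at least one of the gene's coding bases is hit. All
randomness derives from a single root seed via independent child streams,
so a fixed seed yields byte-identical output files, and raising one gene's
multiplier (same seed) can only add mutation events, never remove them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .coverage_model import FilterThresholds, cohort_median_coverage, filter_genes, read_annotation_tsv
from .maf_io import records_from_dataframe
from .triage_regression import Thresholds, score_cohort

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Real coding lengths (bp, longest transcript) for the stratification genes.
DRIVER_GENE_LENGTHS = {"KRAS": 570, "EGFR": 3633, "BRAF": 2301}

# Hotspot protein changes planted per driver label. EGFR additionally plants
# exon-19 in-frame deletions (see _plant_drivers).
DRIVER_HOTSPOTS = {
    "KRAS": ["p.G12D", "p.G12C", "p.G12V", "p.G13D", "p.Q61H", "p.A146T"],
    "BRAF": ["p.V600E", "p.N581S", "p.G469A", "p.G466V", "p.D594G"],
    "EGFR": ["p.L858R", "p.S768I", "p.L861Q", "p.G719A", "p.T790M"],
}
EGFR_EXON19_DEL = "p.E746_A750del"


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe a mid-sized exome cohort: 200 patients, 2,000 genes
    with log-normal coding lengths (median 1.5 kb, sigma 0.6 — spanning
    roughly 0.4-6 kb like human coding genes), and a neutral per-base hit
    rate calibrated so a median-length gene carries a protein-altering
    mutation in ~3% of patients, the background scale seen in
    exome-sequenced lung adenocarcinoma.
    """

    n_patients: int = 200
    n_genes: int = 2000
    length_median_bp: float = 1500.0
    length_sigma: float = 0.6
    #: neutral probability that one coding base is hit in one patient;
    #: default makes a 1500 bp neutral gene mutate in 3% of patients.
    per_base_rate: float = 1.0 - (1.0 - 0.03) ** (1.0 / 1500.0)
    #: explicit per-gene multiplier overrides (gene symbol -> multiplier)
    selection_multipliers: Mapping[str, float] = field(default_factory=dict)
    #: planted conserved genes: placed among the longest-quartile genes
    n_planted_conserved: int = 0
    conserved_multiplier: float = 0.0
    #: planted positively selected genes, also on longest-quartile genes
    n_planted_hyper: int = 0
    hyper_multiplier: float = 5.0
    #: planted gene-filter victims (placed on neutral genes)
    n_low_coverage: int = 0
    n_low_expression: int = 0
    #: coverage fraction per gene/sample is 1 - Beta(a, b): mean ~0.95
    coverage_beta_a: float = 2.0
    coverage_beta_b: float = 40.0
    low_coverage_range: tuple[float, float] = (0.10, 0.45)
    expression_mean: float = 7.0
    expression_sd: float = 2.0
    low_expression_range: tuple[float, float] = (0.5, 1.9)
    #: patients planted with driver hotspot mutations (adds KRAS/EGFR/BRAF
    #: genes to the universe); n_multi_driver patients get two rule genes
    #: and must end up excluded.
    n_mkras: int = 0
    n_megfr: int = 0
    n_mbraf: int = 0
    n_multi_driver: int = 0
    #: Poisson rate of Silent decoy mutations per patient (ignored downstream)
    silent_decoys_per_patient: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.per_base_rate <= 1.0):
            raise ConfigError(f"per_base_rate {self.per_base_rate} outside [0, 1]")
        for gene, mult in self.selection_multipliers.items():
            if mult < 0:
                raise ConfigError(f"selection multiplier for {gene} is negative")
            if self.per_base_rate * mult > 1.0:
                raise ConfigError(
                    f"per-base rate x multiplier exceeds 1 for {gene}; not a probability"
                )
        for name in ("n_patients", "n_genes"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        n_drivers = self.n_mkras + self.n_megfr + self.n_mbraf + 2 * self.n_multi_driver
        if n_drivers > self.n_patients:
            raise ConfigError("more planted driver patients than patients")


@dataclass
class SyntheticCohort:
    """Generated tables plus the truth they were generated from."""

    config: SyntheticCohortConfig
    maf: pd.DataFrame
    coverage: pd.DataFrame
    expression: pd.DataFrame
    annotation: pd.DataFrame
    gene_truth: pd.DataFrame
    patient_truth: pd.DataFrame
    patients: list[str]
    samples: list[str]

    def records(self):
        return records_from_dataframe(self.maf)

    def panels(self) -> dict[str, list[str]]:
        """A demo panel config: planted genes plus a neutral background slice."""
        truth = self.gene_truth
        panels = {}
        conserved = list(truth.loc[truth["planted_conserved"], "gene_symbol"])
        hyper = list(truth.loc[truth["planted_hyper"], "gene_symbol"])
        neutral = list(
            truth.loc[
                (truth["multiplier"] == 1.0)
                & ~truth["planted_low_coverage"]
                & ~truth["planted_low_expression"],
                "gene_symbol",
            ][:10]
        )
        if conserved:
            panels["Planted Conserved"] = conserved
        if hyper:
            panels["Planted Hypermutated"] = hyper
        if neutral:
            panels["Background Sample"] = neutral
        return panels

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write all tables; returns the path of each artifact."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "maf": outdir / "mutations.maf",
            "coverage": outdir / "coverage.tsv",
            "expression": outdir / "expression.tsv",
            "annotation": outdir / "annotation.tsv",
            "gene_truth": outdir / "gene_truth.tsv",
            "patient_truth": outdir / "patient_truth.tsv",
            "panels": outdir / "panels.yaml",
        }
        self.maf.to_csv(paths["maf"], sep="\t", index=False)
        self.coverage.to_csv(paths["coverage"], sep="\t", index=False, float_format="%.6f")
        self.expression.to_csv(paths["expression"], sep="\t", index=False, float_format="%.6f")
        self.annotation.to_csv(paths["annotation"], sep="\t", index=False)
        self.gene_truth.to_csv(paths["gene_truth"], sep="\t", index=False, float_format="%.6f")
        self.patient_truth.to_csv(paths["patient_truth"], sep="\t", index=False)
        with open(paths["panels"], "w") as fh:
            yaml.safe_dump(self.panels(), fh, sort_keys=False)
        return paths


def _gene_probabilities(lengths: np.ndarray, multipliers: np.ndarray, rate: float) -> np.ndarray:
    per_base = np.clip(rate * multipliers, 0.0, 1.0)
    return 1.0 - np.power(1.0 - per_base, lengths)


def _random_substitution(rng: np.random.Generator, lo: int, hi: int) -> str:
    pos = int(rng.integers(lo, hi + 1))
    ref, alt = rng.choice(list(AMINO_ACIDS), size=2, replace=False)
    return f"p.{ref}{pos}{alt}"


def generate_cohort(
    config: SyntheticCohortConfig, outdir: str | Path | None = None
) -> SyntheticCohort:
    """Generate one synthetic cohort; optionally write its files to `outdir`."""
    ss = np.random.SeedSequence(config.seed)
    (ss_universe, ss_mut, ss_cov, ss_expr, ss_driver, ss_decoy) = ss.spawn(6)
    rng_universe = np.random.default_rng(ss_universe)
    rng_mut = np.random.default_rng(ss_mut)
    rng_cov = np.random.default_rng(ss_cov)
    rng_expr = np.random.default_rng(ss_expr)
    rng_driver = np.random.default_rng(ss_driver)
    rng_decoy = np.random.default_rng(ss_decoy)

    # --- gene universe -----------------------------------------------------
    width = max(4, len(str(config.n_genes)))
    genes = [f"GS{i:0{width}d}" for i in range(1, config.n_genes + 1)]
    lengths = np.maximum(
        30,
        np.round(
            rng_universe.lognormal(np.log(config.length_median_bp), config.length_sigma, config.n_genes)
        ),
    ).astype(int)

    plant_drivers = (config.n_mkras + config.n_megfr + config.n_mbraf + config.n_multi_driver) > 0
    driver_genes = list(DRIVER_GENE_LENGTHS) if plant_drivers else []
    if driver_genes:
        genes = genes + driver_genes
        lengths = np.concatenate([lengths, [DRIVER_GENE_LENGTHS[g] for g in driver_genes]])

    n_total = len(genes)
    multipliers = np.ones(n_total)

    # planted selection lives on the longest-quartile synthetic genes so the
    # expected neutral signal is large enough to fall away from
    long_cut = np.quantile(lengths[: config.n_genes], 0.75)
    long_idx = np.flatnonzero(lengths[: config.n_genes] >= long_cut)
    n_planted = config.n_planted_conserved + config.n_planted_hyper
    if n_planted > len(long_idx):
        raise ConfigError("not enough longest-quartile genes for the requested plants")
    planted = rng_universe.choice(long_idx, size=n_planted, replace=False)
    conserved_idx = planted[: config.n_planted_conserved]
    hyper_idx = planted[config.n_planted_conserved :]
    multipliers[conserved_idx] = config.conserved_multiplier
    multipliers[hyper_idx] = config.hyper_multiplier

    # filter victims go on neutral, unplanted genes
    neutral_pool = np.setdiff1d(np.arange(config.n_genes), planted)
    n_victims = config.n_low_coverage + config.n_low_expression
    if n_victims > len(neutral_pool):
        raise ConfigError("not enough neutral genes for low-coverage/low-expression plants")
    victims = rng_universe.choice(neutral_pool, size=n_victims, replace=False)
    low_cov_idx = set(victims[: config.n_low_coverage].tolist())
    low_expr_idx = set(victims[config.n_low_coverage :].tolist())

    for gene, mult in config.selection_multipliers.items():
        if gene not in genes:
            raise ConfigError(f"selection multiplier references unknown gene {gene}")
        multipliers[genes.index(gene)] = mult

    # --- patients ----------------------------------------------------------
    patients = [f"TCGA-SY-{i:04d}" for i in range(1, config.n_patients + 1)]
    samples = [p + "-01A-11D-0001-08" for p in patients]
    sample_of = dict(zip(patients, samples))

    # --- mutation events ---------------------------------------------------
    probs = _gene_probabilities(lengths.astype(float), multipliers, config.per_base_rate)
    # one uniform per (patient, gene): a higher multiplier only raises p, so
    # under a fixed seed it can only add events (monotone coupling)
    u = rng_mut.random((config.n_patients, n_total))
    mutated = u < probs[None, :]

    # classification/HGVSp details are drawn per event from a separate stream
    # keyed only by event order; driver rule genes get background changes well
    # away from hotspot residues so planted cohort truth stays exact
    rows: list[dict] = []
    class_choices = np.array(["Missense_Mutation", "Nonsense_Mutation", "Splice_Site"])
    class_p = np.array([0.85, 0.10, 0.05])
    for pi, gi in np.argwhere(mutated):
        gene = genes[gi]
        if gene in DRIVER_GENE_LENGTHS:
            classification = "Missense_Mutation"
            hgvsp = _random_substitution(rng_mut, 1000, 1200)
        else:
            classification = str(rng_mut.choice(class_choices, p=class_p))
            max_res = max(int(lengths[gi]) // 3, 2)
            hgvsp = "" if classification == "Splice_Site" else _random_substitution(rng_mut, 1, max_res)
        rows.append(
            {
                "Hugo_Symbol": gene,
                "Tumor_Sample_Barcode": sample_of[patients[pi]],
                "Variant_Classification": classification,
                "HGVSp_Short": hgvsp,
                "Variant_Type": "SNP",
                "Exon_Number": "",
            }
        )

    # --- planted drivers ---------------------------------------------------
    patient_label = {p: "WT" for p in patients}
    if plant_drivers:
        n_driver_patients = config.n_mkras + config.n_megfr + config.n_mbraf + config.n_multi_driver
        chosen = rng_driver.choice(config.n_patients, size=n_driver_patients, replace=False)
        cursor = 0

        def plant(gene: str, patient: str):
            if gene == "EGFR" and rng_driver.random() < 0.4:
                rows.append(
                    {
                        "Hugo_Symbol": "EGFR",
                        "Tumor_Sample_Barcode": sample_of[patient],
                        "Variant_Classification": "In_Frame_Del",
                        "HGVSp_Short": EGFR_EXON19_DEL,
                        "Variant_Type": "DEL",
                        "Exon_Number": "19",
                    }
                )
            else:
                rows.append(
                    {
                        "Hugo_Symbol": gene,
                        "Tumor_Sample_Barcode": sample_of[patient],
                        "Variant_Classification": "Missense_Mutation",
                        "HGVSp_Short": str(rng_driver.choice(DRIVER_HOTSPOTS[gene])),
                        "Variant_Type": "SNP",
                        "Exon_Number": "",
                    }
                )

        for label, gene, count in (
            ("mKRAS", "KRAS", config.n_mkras),
            ("mEGFR", "EGFR", config.n_megfr),
            ("mBRAF", "BRAF", config.n_mbraf),
        ):
            for _ in range(count):
                patient = patients[chosen[cursor]]
                cursor += 1
                plant(gene, patient)
                patient_label[patient] = label
        for _ in range(config.n_multi_driver):
            patient = patients[chosen[cursor]]
            cursor += 1
            gene_a, gene_b = rng_driver.choice(list(DRIVER_HOTSPOTS), size=2, replace=False)
            plant(str(gene_a), patient)
            plant(str(gene_b), patient)
            patient_label[patient] = "excluded"

    # --- silent decoys (must be ignored by protein-altering filters) -------
    if config.silent_decoys_per_patient > 0:
        n_decoys = rng_decoy.poisson(config.silent_decoys_per_patient, config.n_patients)
        for pi, k in enumerate(n_decoys):
            for _ in range(k):
                gi = int(rng_decoy.integers(0, config.n_genes))
                pos = int(rng_decoy.integers(1, max(int(lengths[gi]) // 3, 2) + 1))
                ref = str(rng_decoy.choice(list(AMINO_ACIDS)))
                rows.append(
                    {
                        "Hugo_Symbol": genes[gi],
                        "Tumor_Sample_Barcode": sample_of[patients[pi]],
                        "Variant_Classification": "Silent",
                        "HGVSp_Short": f"p.{ref}{pos}{ref}",
                        "Variant_Type": "SNP",
                        "Exon_Number": "",
                    }
                )

    maf = pd.DataFrame(
        rows,
        columns=[
            "Hugo_Symbol",
            "Tumor_Sample_Barcode",
            "Variant_Classification",
            "HGVSp_Short",
            "Variant_Type",
            "Exon_Number",
        ],
    )
    maf = maf.sort_values(["Tumor_Sample_Barcode", "Hugo_Symbol", "HGVSp_Short"], kind="mergesort").reset_index(
        drop=True
    )

    # --- coverage ----------------------------------------------------------
    frac = 1.0 - rng_cov.beta(config.coverage_beta_a, config.coverage_beta_b, (n_total, config.n_patients))
    lo, hi = config.low_coverage_range
    for gi in low_cov_idx:
        frac[gi, :] = rng_cov.uniform(lo, hi, config.n_patients)
    coverage = pd.DataFrame(
        {
            "gene_symbol": np.repeat(genes, config.n_patients),
            "sample_id": np.tile(samples, n_total),
            "fraction": np.round(frac.ravel(), 6),
        }
    )

    # --- expression ----------------------------------------------------------
    expr = rng_expr.normal(config.expression_mean, config.expression_sd, n_total)
    elo, ehi = config.low_expression_range
    for gi in low_expr_idx:
        expr[gi] = rng_expr.uniform(elo, ehi)
    expression = pd.DataFrame({"gene_symbol": genes, "expression_log2": np.round(expr, 6)})

    annotation = pd.DataFrame(
        {"gene_symbol": genes, "coding_length": lengths, "annotation_error": False}
    )

    gene_truth = pd.DataFrame(
        {
            "gene_symbol": genes,
            "coding_length": lengths,
            "multiplier": multipliers,
            "mutation_prob": np.round(probs, 8),
            "planted_conserved": [i in set(conserved_idx.tolist()) for i in range(n_total)],
            "planted_hyper": [i in set(hyper_idx.tolist()) for i in range(n_total)],
            "planted_low_coverage": [i in low_cov_idx for i in range(n_total)],
            "planted_low_expression": [i in low_expr_idx for i in range(n_total)],
        }
    )
    patient_truth = pd.DataFrame(
        {"patient_id": patients, "true_label": [patient_label[p] for p in patients]}
    )

    cohort = SyntheticCohort(
        config=config,
        maf=maf,
        coverage=coverage,
        expression=expression,
        annotation=annotation,
        gene_truth=gene_truth,
        patient_truth=patient_truth,
        patients=patients,
        samples=samples,
    )
    if outdir is not None:
        cohort.write(outdir)
    return cohort


def recovery_experiment(
    config: SyntheticCohortConfig,
    estimator: str = "ols",
    suggestive_sr: float = 1.65,
    significant_sr: float = 2.0,
) -> dict:
    """Generate a cohort, run the full scoring pipeline, compare to truth.

    Returns sensitivity (fraction of planted strongly conserved genes —
    multiplier <= 0.1 and length in the top quartile — scoring
    SR <= -suggestive_sr), false_flag_rate (fraction of neutral kept genes
    with |SR| >= significant_sr), rank_agreement (Spearman correlation
    between multiplier and SR over planted genes), top_sr_is_planted_driver
    (whether the maximum-SR gene is a planted positively selected gene), and
    the score table itself. Undefined metrics are None.
    """
    cohort = generate_cohort(config)
    records = cohort.records()
    truth = cohort.gene_truth.set_index("gene_symbol")

    median_cov = cohort_median_coverage(cohort.coverage, cohort.samples)
    expression = cohort.expression.set_index("gene_symbol")["expression_log2"]
    kept, report = filter_genes(cohort.annotation, median_cov, expression)

    scores, model = score_cohort(
        records,
        cohort.patients,
        coding_length=cohort.annotation.set_index("gene_symbol")["coding_length"],
        median_cov=median_cov,
        kept_genes=kept,
        estimator=estimator,
    )

    kept_truth = truth.loc[scores.index]
    long_cut = float(np.quantile(truth["coding_length"], 0.75))

    target = kept_truth[(kept_truth["multiplier"] <= 0.1) & (kept_truth["coding_length"] >= long_cut)]
    if len(target):
        sensitivity = float((scores.loc[target.index, "sr"] <= -suggestive_sr).mean())
    else:
        sensitivity = None

    neutral = kept_truth[
        (kept_truth["multiplier"] == 1.0)
        & ~kept_truth["planted_low_coverage"]
        & ~kept_truth["planted_low_expression"]
    ]
    false_flag_rate = (
        float((scores.loc[neutral.index, "sr"].abs() >= significant_sr).mean()) if len(neutral) else None
    )

    planted = kept_truth[kept_truth["multiplier"] != 1.0]
    if len(planted) >= 2 and planted["multiplier"].nunique() >= 2:
        from scipy import stats as _st

        rho = _st.spearmanr(planted["multiplier"], scores.loc[planted.index, "sr"]).statistic
        rank_agreement = float(rho)
    else:
        rank_agreement = None

    positive_truth = set(truth.index[truth["planted_hyper"]])
    if positive_truth:
        top_gene = scores["sr"].idxmax()
        top_sr_is_planted_driver = bool(top_gene in positive_truth)
    else:
        top_sr_is_planted_driver = None

    return {
        "sensitivity": sensitivity,
        "false_flag_rate": false_flag_rate,
        "rank_agreement": rank_agreement,
        "top_sr_is_planted_driver": top_sr_is_planted_driver,
        "mean_sr": float(scores["sr"].mean()),
        "n_kept_genes": int(len(scores)),
        "scores": scores,
        "model": model,
        "exclusion_report": report,
        "truth": cohort.gene_truth,
    }
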