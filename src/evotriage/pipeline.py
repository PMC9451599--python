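"""End-to-end orchestration: MAF -> cohorts -> filters -> scores -> reports.

`run_pipeline` wires the stages together from a single RunConfig, writes
every intermediate table so any stage can be audited, and records a run
manifest (input checksums, configuration, library versions, per-stage
counts). Outputs are deterministic for identical inputs and configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .errors import ConfigError, DataFormatError
from . import __version__
from .coverage_model import (
    FilterThresholds,
    cohort_median_coverage,
    filter_genes,
    read_annotation_tsv,
    read_coverage_tsv,
    read_expression_tsv,
)
from .driver_cohorts import (
    DEFAULT_DRIVER_RULES,
    assign_cohorts,
    cohort_patients,
    load_driver_rules,
    write_assignments,
)
from .gene_panels import cross_cohort_overlap, load_panels, panel_report
from .maf_io import one_sample_per_patient, patient_barcode, read_maf
from .triage_regression import Thresholds, frequently_mutated, score_cohort, write_scores

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths, thresholds and choices for one pipeline run."""

    maf: Path
    coverage: Path
    expression: Path
    annotation: Path
    out_dir: Path
    panels: Path | None = None
    driver_rules: Path | None = None
    cohorts: list[str] | None = None  # None = every label except "excluded"
    estimator: str = "ols"
    studentized: bool = False
    thresholds: Thresholds = field(default_factory=Thresholds)
    filters: FilterThresholds = field(default_factory=FilterThresholds)
    panel_cutoff: float = 1.65
    min_cohort_size: int = 10
    make_plots: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        required = ["maf", "coverage", "expression", "annotation", "out_dir"]
        missing = [k for k in required if k not in raw]
        if missing:
            raise ConfigError(f"run config missing key(s): {', '.join(missing)}")
        sr = raw.get("sr", {})
        filt = raw.get("filters", {})
        cfg = cls(
            maf=Path(raw["maf"]),
            coverage=Path(raw["coverage"]),
            expression=Path(raw["expression"]),
            annotation=Path(raw["annotation"]),
            out_dir=Path(raw["out_dir"]),
            panels=Path(raw["panels"]) if raw.get("panels") else None,
            driver_rules=Path(raw["driver_rules"]) if raw.get("driver_rules") else None,
            cohorts=list(raw["cohorts"]) if raw.get("cohorts") else None,
            estimator=raw.get("estimator", "ols"),
            studentized=bool(raw.get("studentized", False)),
            thresholds=Thresholds(
                flag=float(sr.get("flag", 1.0)),
                suggestive=float(sr.get("suggestive", 1.65)),
                significant=float(sr.get("significant", 2.0)),
            ),
            filters=FilterThresholds(
                min_median_cov=float(filt.get("min_median_cov", 0.5)),
                min_expression_log2=float(filt.get("min_expression_log2", 2.0)),
            ),
            panel_cutoff=float(raw.get("panel_cutoff", 1.65)),
            min_cohort_size=int(raw.get("min_cohort_size", 10)),
            make_plots=bool(raw.get("make_plots", True)),
        )
        for name in ("maf", "coverage", "expression", "annotation"):
            p = getattr(cfg, name)
            if not Path(p).exists():
                raise ConfigError(f"configured {name} path does not exist: {p}")
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns the manifest dict (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "tool": "evotriage",
        "version": __version__,
        "inputs": {
            name: {"path": str(getattr(config, name)), "sha256": _sha256(Path(getattr(config, name)))}
            for name in ("maf", "coverage", "expression", "annotation")
        },
        "library_versions": _library_versions(),
        "stages": {},
    }

    # stage: MAF ingestion
    records = read_maf(config.maf)
    records = one_sample_per_patient(records)
    manifest["stages"]["maf"] = {
        "n_records": len(records),
        "n_patients": len({r.patient_id for r in records}),
    }

    # stage: cohort assignment
    rules = load_driver_rules(config.driver_rules) if config.driver_rules else list(DEFAULT_DRIVER_RULES)
    assignments = assign_cohorts(records, rules)
    write_assignments(assignments, out / "cohort_assignments.tsv")
    label_counts: dict[str, int] = {}
    for a in assignments:
        label_counts[a.label] = label_counts.get(a.label, 0) + 1
    manifest["stages"]["cohorts"] = label_counts

    # stage: shared tables
    coverage = read_coverage_tsv(config.coverage)
    expression = read_expression_tsv(config.expression)
    annotation = read_annotation_tsv(config.annotation)
    coverage["patient_id"] = coverage["sample_id"].map(patient_barcode)
    coding_length = annotation.set_index("gene_symbol")["coding_length"]

    labels = config.cohorts
    if labels is None:
        labels = [
            lab
            for lab, n in sorted(label_counts.items())
            if lab != "excluded" and n >= config.min_cohort_size
        ]
    if not labels:
        raise DataFormatError("no cohort meets the minimum size; nothing to score")

    score_tables: dict[str, pd.DataFrame] = {}
    reports: dict[str, dict[str, pd.DataFrame]] = {}
    panels = load_panels(config.panels) if config.panels else None

    for label in labels:
        patients = cohort_patients(assignments, label)
        if not patients:
            raise DataFormatError(f"cohort {label!r} has no patients")
        cohort_cov = coverage[coverage["patient_id"].isin(set(patients))]
        if cohort_cov.empty:
            raise DataFormatError(f"cohort {label!r}: no coverage rows for its samples")
        median_cov = cohort_cov.groupby("gene_symbol")["fraction"].median()
        kept, excl = filter_genes(annotation, median_cov, expression, config.filters)
        excl.to_csv(out / f"excluded_genes_{label}.tsv", sep="\t", index=False, float_format="%.10g")

        scores, model = score_cohort(
            records,
            patients,
            coding_length=coding_length,
            median_cov=median_cov,
            kept_genes=kept,
            thresholds=config.thresholds,
            estimator=config.estimator,
            studentized=config.studentized,
        )
        write_scores(scores, out / f"scores_{label}.tsv")
        score_tables[label] = scores
        manifest["stages"][f"triage_{label}"] = {
            "cohort_size": len(patients),
            "n_genes_kept": int(len(scores)),
            "n_genes_excluded": int(len(excl)),
            "n_conserved_significant": int(((scores["sr"] <= -config.thresholds.significant)).sum()),
            "n_over_mutated_significant": int(((scores["sr"] >= config.thresholds.significant)).sum()),
            "n_frequently_mutated": len(frequently_mutated(scores)),
            "model": {
                "intercept": model.intercept,
                "slope": model.slope,
                "residual_scale": model.residual_scale,
                "estimator": model.estimator,
            },
        }

        if panels:
            cons = panel_report(scores, panels, "conserved", -config.panel_cutoff)
            over = panel_report(scores, panels, "over_mutated", config.panel_cutoff)
            cons.to_csv(out / f"panel_conserved_{label}.tsv", sep="\t", index=False, float_format="%.10g")
            over.to_csv(out / f"panel_over_mutated_{label}.tsv", sep="\t", index=False, float_format="%.10g")
            reports[label] = {"conserved": cons, "over_mutated": over}

        if config.make_plots:
            from .plots import sr_vs_expression

            sr_vs_expression(
                scores,
                expression,
                out / f"sr_vs_expression_{label}.png",
                title=f"{label} (n={len(patients)})",
                flag=config.thresholds.flag,
            )

    if panels and len(reports) >= 2:
        (a, b) = list(reports)[:2]
        overlap = {
            "cohorts": [a, b],
            "conserved_overlap": sorted(cross_cohort_overlap(reports[a]["conserved"], reports[b]["conserved"])),
            "over_mutated_overlap": sorted(
                cross_cohort_overlap(reports[a]["over_mutated"], reports[b]["over_mutated"])
            ),
        }
        with open(out / "panel_overlap.json", "w") as fh:
            json.dump(overlap, fh, indent=2)
        manifest["stages"]["panel_overlap"] = overlap

    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    logger.info("pipeline complete: %s", out)
    return manifest


def _library_versions() -> dict[str, str]:
    import numpy, pandas, scipy, statsmodels

    return {
        "numpy": numpy.__version__,
        "pandas": pandas.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
    }
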