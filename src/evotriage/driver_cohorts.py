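"""Cohort stratification by driver hotspot mutations.

Patients are assigned to a driver-defined cohort (e.g. mKRAS, mEGFR, mBRAF)
when they carry a recurrent activating mutation in exactly one of the rule
genes, to WT when they carry none, and are excluded when they match rules
for more than one gene. Hotspot matching uses the reference residue and
position parsed from the HGVSp protein change ("G12" matches p.G12D and
p.G12C alike, but not the synonymous p.G12G); indel rules match by exon
number, with a protein-residue window as fallback when the MAF lacks exon
annotation.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .errors import ConfigError
from .hgvs import parse_protein_change
from .maf_io import MutationRecord

logger = logging.getLogger(__name__)

WT_LABEL = "WT"
EXCLUDED_LABEL = "excluded"

_SITE_RE = re.compile(r"^([A-Z])(\d+)$")


@dataclass(frozen=True)
class DriverRule:
    """Hotspot definition for one driver gene.

    residue_sites holds (reference residue, position) pairs such as
    ("G", 12); any non-synonymous substitution at such a site matches.
    indel_exon_range marks an inclusive exon interval in which any indel
    matches (e.g. EGFR exons 18-21); indel_residue_range is the fallback
    window on protein positions used when the record has no exon number.
    """

    gene_symbol: str
    residue_sites: frozenset[tuple[str, int]] = frozenset()
    indel_exon_range: tuple[int, int] | None = None
    indel_residue_range: tuple[int, int] | None = None

    def __post_init__(self):
        if not self.residue_sites and self.indel_exon_range is None:
            raise ConfigError(
                f"driver rule for {self.gene_symbol} has neither residue sites nor an indel exon range"
            )
        for _, pos in self.residue_sites:
            if pos <= 0:
                raise ConfigError(f"driver rule for {self.gene_symbol}: non-positive residue position {pos}")

    @property
    def label(self) -> str:
        return f"m{self.gene_symbol.upper()}"


def parse_site(site: str) -> tuple[str, int]:
    """Parse a hotspot site string like 'G12' into ('G', 12)."""
    m = _SITE_RE.match(site.strip())
    if not m:
        raise ConfigError(f"cannot parse hotspot site {site!r}; expected e.g. 'G12'")
    return m.group(1), int(m.group(2))


#: Lung-adenocarcinoma stratification rules: recurrent activating mutations
#: in KRAS, BRAF and EGFR, plus EGFR indels in exons 18-21 (protein-residue
#: fallback window 688-875 when the MAF carries no exon number).
DEFAULT_DRIVER_RULES = (
    DriverRule("KRAS", frozenset(parse_site(s) for s in ["G12", "G13", "Q61", "A146"])),
    DriverRule(
        "BRAF",
        frozenset(parse_site(s) for s in ["V600", "N581", "G464", "G466", "G469", "G596", "D594"]),
    ),
    DriverRule(
        "EGFR",
        frozenset(parse_site(s) for s in ["L858", "S768", "L861", "G719", "T790"]),
        indel_exon_range=(18, 21),
        indel_residue_range=(688, 875),
    ),
)


def load_driver_rules(path: str | Path) -> list[DriverRule]:
    """Load driver rules from YAML: gene -> {sites: [...], indel_exons: [lo, hi]}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not raw:
        raise ConfigError(f"driver-rule file {path} is empty")
    rules = []
    for gene, spec in raw.items():
        spec = spec or {}
        sites = frozenset(parse_site(s) for s in spec.get("sites", []))
        exons = spec.get("indel_exons")
        residues = spec.get("indel_residues")
        rules.append(
            DriverRule(
                gene_symbol=str(gene),
                residue_sites=sites,
                indel_exon_range=tuple(exons) if exons else None,
                indel_residue_range=tuple(residues) if residues else None,
            )
        )
    return rules


@dataclass(frozen=True)
class CohortAssignment:
    """A patient's cohort label with the rule genes it matched."""

    patient_id: str
    label: str
    matched_rules: tuple[str, ...] = ()


def match_rule(record: MutationRecord, rule: DriverRule) -> bool:
    """True iff this variant satisfies the rule for its gene.

    A match is either (a) a non-synonymous substitution whose reference
    residue and position are a listed hotspot, or (b) an indel falling in the
    rule's exon range (protein-residue fallback window when the exon number
    is missing).
    """
    if record.gene_symbol.upper() != rule.gene_symbol.upper():
        return False

    parsed = parse_protein_change(record.protein_change) if record.protein_change else None
    if record.protein_change and parsed is None:
        logger.warning(
            "unparseable protein change %r on rule gene %s (%s); treated as non-match",
            record.protein_change,
            rule.gene_symbol,
            record.sample_id,
        )

    if parsed and parsed.is_substitution and not parsed.is_synonymous:
        if (parsed.ref, parsed.position) in rule.residue_sites:
            return True

    if record.is_indel and rule.indel_exon_range is not None:
        lo, hi = rule.indel_exon_range
        if record.exon_number is not None:
            return lo <= record.exon_number <= hi
        if rule.indel_residue_range is not None and parsed is not None:
            rlo, rhi = rule.indel_residue_range
            return rlo <= parsed.position <= rhi
    return False


def assign_cohorts(
    records: Sequence[MutationRecord],
    rules: Sequence[DriverRule] = DEFAULT_DRIVER_RULES,
    patients: Iterable[str] | None = None,
) -> list[CohortAssignment]:
    """Assign every patient a cohort label: m<GENE>, WT, or excluded.

    `records` must already be one sample per patient. `patients` may extend
    the universe beyond patients that have mutations (patients absent from
    the MAF are WT by definition). Matching exactly one rule gene yields that
    gene's cohort; more than one yields "excluded"; none yields "WT".
    """
    if not rules:
        raise ConfigError("assign_cohorts requires at least one driver rule")

    all_patients = set(patients) if patients is not None else set()
    all_patients.update(r.patient_id for r in records)

    matched: dict[str, set[str]] = {p: set() for p in all_patients}
    for record in records:
        for rule in rules:
            if match_rule(record, rule):
                matched[record.patient_id].add(rule.gene_symbol.upper())

    label_of = {rule.gene_symbol.upper(): rule.label for rule in rules}
    assignments = []
    for patient in sorted(all_patients):
        genes = tuple(sorted(matched[patient]))
        if len(genes) == 0:
            label = WT_LABEL
        elif len(genes) == 1:
            label = label_of[genes[0]]
        else:
            label = EXCLUDED_LABEL
        assignments.append(CohortAssignment(patient_id=patient, label=label, matched_rules=genes))

    counts: dict[str, int] = {}
    for a in assignments:
        counts[a.label] = counts.get(a.label, 0) + 1
    logger.info("cohort assignment counts: %s", dict(sorted(counts.items())))
    return assignments


def cohort_patients(assignments: Sequence[CohortAssignment], label: str) -> list[str]:
    """Patient ids carrying a given cohort label, sorted."""
    return sorted(a.patient_id for a in assignments if a.label == label)


def write_assignments(assignments: Sequence[CohortAssignment], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "patient_id": [a.patient_id for a in assignments],
            "label": [a.label for a in assignments],
            "matched_rules": [",".join(a.matched_rules) for a in assignments],
        }
    ).to_csv(path, sep="\t", index=False)


def read_assignments(path: str | Path) -> list[CohortAssignment]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        CohortAssignment(
            patient_id=row["patient_id"],
            label=row["label"],
            matched_rules=tuple(g for g in row["matched_rules"].split(",") if g),
        )
        for _, row in df.iterrows()
    ]
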