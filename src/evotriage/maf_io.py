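"""Reading and reducing TCGA MC3-dialect MAF files.

A MAF (Mutation Annotation Format) file is a tab-separated table of somatic
variant calls, one row per call, with a controlled vocabulary in
``Variant_Classification``. This module parses such files into
:class:`MutationRecord` values, decides which classifications are
protein-altering, and reduces multi-sample patients to one tumor sample each.
Columns are addressed by name; unknown extra columns are ignored, so the
full 100+ column MC3 file and minimal test fixtures parse identically.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import DataFormatError
from .hgvs import parse_protein_change

logger = logging.getLogger(__name__)

MANDATORY_COLUMNS = ("Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification")

#: MAF classification codes for indel-type events.
INDEL_CLASSES = frozenset(
    {"Frame_Shift_Del", "Frame_Shift_Ins", "In_Frame_Del", "In_Frame_Ins"}
)

#: Default protein-altering classes: nonsynonymous, truncating, and
#: canonical splice-site events. Silent and UTR/flank classes are excluded.
DEFAULT_PROTEIN_ALTERING = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Splice_Site",
        "Translation_Start_Site",
    }
)


@dataclass(frozen=True)
class VariantClassPolicy:
    """Which MAF ``Variant_Classification`` values count as protein-altering."""

    protein_altering_classes: frozenset[str] = DEFAULT_PROTEIN_ALTERING

    @classmethod
    def from_config(cls, classes: Iterable[str]) -> "VariantClassPolicy":
        return cls(protein_altering_classes=frozenset(classes))


@dataclass(frozen=True)
class MutationRecord:
    """One somatic variant call, reduced to the fields the pipeline uses."""

    patient_id: str           # TCGA patient barcode (first 12 chars of sample)
    sample_id: str            # full tumor sample barcode
    gene_symbol: str          # Hugo symbol
    variant_classification: str
    protein_change: str = ""  # HGVSp short form, e.g. "p.G12D"; "" if absent
    protein_position: int | None = None
    is_indel: bool = False
    exon_number: int | None = None


def patient_barcode(sample_barcode: str) -> str:
    """TCGA patient barcode: the first 12 characters (project-TSS-participant)."""
    return sample_barcode[:12]


_EXON_RE = re.compile(r"^\s*(\d+)\s*(?:/\s*\d+\s*)?$")


def _parse_exon(value) -> int | None:
    """MC3 exon fields look like '19' or '19/28'; anything else is None."""
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    m = _EXON_RE.match(str(value))
    return int(m.group(1)) if m else None


def _row_to_record(row: dict) -> MutationRecord:
    sample = str(row["Tumor_Sample_Barcode"])
    classification = str(row["Variant_Classification"])
    hgvsp = row.get("HGVSp_Short") or row.get("HGVSp") or ""
    if pd.isna(hgvsp):
        hgvsp = ""
    hgvsp = str(hgvsp).strip()
    if hgvsp in {".", "NA"}:
        hgvsp = ""
    parsed = parse_protein_change(hgvsp) if hgvsp else None
    variant_type = str(row.get("Variant_Type") or "").upper()
    is_indel = variant_type in {"INS", "DEL"} or classification in INDEL_CLASSES
    return MutationRecord(
        patient_id=patient_barcode(sample),
        sample_id=sample,
        gene_symbol=str(row["Hugo_Symbol"]),
        variant_classification=classification,
        protein_change=hgvsp,
        protein_position=parsed.position if parsed else None,
        is_indel=is_indel,
        exon_number=_parse_exon(row.get("Exon_Number")),
    )


def records_from_dataframe(maf: pd.DataFrame) -> list[MutationRecord]:
    """Convert an in-memory MAF-dialect DataFrame into MutationRecords.

    Rows with a missing/blank gene symbol are dropped (count logged).
    """
    missing = [c for c in MANDATORY_COLUMNS if c not in maf.columns]
    if missing:
        raise DataFormatError(f"MAF is missing mandatory column(s): {', '.join(missing)}")
    symbols = maf["Hugo_Symbol"]
    bad = symbols.isna() | (symbols.astype(str).str.strip() == "")
    n_bad = int(bad.sum())
    if n_bad:
        logger.warning("dropped %d MAF rows with missing gene symbol", n_bad)
        maf = maf.loc[~bad]
    return [_row_to_record(row) for row in maf.to_dict("records")]


def read_maf(path: str | Path, policy: VariantClassPolicy | None = None) -> list[MutationRecord]:
    """Read a MAF file (plain or gzip) into MutationRecords.

    `policy` is accepted for interface symmetry with downstream filters; the
    reader itself keeps all classifications so silent variants remain
    available to callers that need them.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"MAF file not found: {path}")
    try:
        maf = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            dtype=str,
            compression="infer",
            keep_default_na=False,
            na_values=[""],
            low_memory=False,
        )
    except (OSError, gzip.BadGzipFile) as exc:
        raise IOError(f"could not read MAF file {path}: {exc}") from exc
    except pd.errors.ParserError as exc:
        raise DataFormatError(f"malformed MAF file {path}: {exc}") from exc
    return records_from_dataframe(maf)


def write_maf(records: Sequence[MutationRecord], path: str | Path) -> None:
    """Write records back to a minimal MAF-dialect TSV (lossless round-trip)."""
    rows = []
    for r in records:
        rows.append(
            {
                "Hugo_Symbol": r.gene_symbol,
                "Tumor_Sample_Barcode": r.sample_id,
                "Variant_Classification": r.variant_classification,
                "HGVSp_Short": r.protein_change,
                "Variant_Type": "DEL" if r.is_indel else "SNP",
                "Exon_Number": "" if r.exon_number is None else str(r.exon_number),
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "Hugo_Symbol",
            "Tumor_Sample_Barcode",
            "Variant_Classification",
            "HGVSp_Short",
            "Variant_Type",
            "Exon_Number",
        ],
    ).to_csv(path, sep="\t", index=False)


def is_protein_altering(record: MutationRecord, policy: VariantClassPolicy | None = None) -> bool:
    """True iff the record's classification is in the protein-altering set."""
    policy = policy or VariantClassPolicy()
    return record.variant_classification in policy.protein_altering_classes


def _sample_sort_key(sample_id: str) -> tuple[int, str]:
    # TCGA sample-type code is characters 14-15 of the barcode ("01" = primary
    # tumor). Prefer primary tumor, then the lexicographically smallest barcode.
    sample_type = sample_id[13:15] if len(sample_id) >= 15 else ""
    return (0 if sample_type == "01" else 1, sample_id)


def one_sample_per_patient(records: Sequence[MutationRecord]) -> list[MutationRecord]:
    """Retain exactly one tumor sample per patient.

    When a patient has several samples, the primary-tumor sample (type code
    "01") with the lexicographically smallest barcode wins. Deterministic by
    construction.
    """
    samples_by_patient: dict[str, set[str]] = {}
    for r in records:
        samples_by_patient.setdefault(r.patient_id, set()).add(r.sample_id)
    chosen = {
        patient: min(samples, key=_sample_sort_key)
        for patient, samples in samples_by_patient.items()
    }
    kept = [r for r in records if r.sample_id == chosen[r.patient_id]]
    n_dropped_samples = sum(len(s) - 1 for s in samples_by_patient.values())
    if n_dropped_samples:
        logger.info(
            "one_sample_per_patient: kept %d samples, dropped %d extra samples (%d records removed)",
            len(chosen),
            n_dropped_samples,
            len(records) - len(kept),
        )
    return kept
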