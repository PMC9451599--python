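import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from evotriage.maf_io import MutationRecord, patient_barcode
from evotriage.hgvs import protein_position

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

INDEL_CLASSES = {"Frame_Shift_Del", "Frame_Shift_Ins", "In_Frame_Del", "In_Frame_Ins"}


def make_record(
    gene: str,
    sample: str = "TCGA-AA-0001-01A-11D-0001-08",
    classification: str = "Missense_Mutation",
    hgvsp: str = "",
    exon: int | None = None,
) -> MutationRecord:
    """Build a MutationRecord the way the MAF reader would."""
    return MutationRecord(
        patient_id=patient_barcode(sample),
        sample_id=sample,
        gene_symbol=gene,
        variant_classification=classification,
        protein_change=hgvsp,
        protein_position=protein_position(hgvsp),
        is_indel=classification in INDEL_CLASSES,
        exon_number=exon,
    )


def sample_for(patient_num: int) -> str:
    return f"TCGA-AA-{patient_num:04d}-01A-11D-0001-08"


@pytest.fixture
def tiny_maf(tmp_path):
    """A 3-row MAF fixture covering missense, silent and frameshift rows."""
    path = tmp_path / "tiny.maf"
    rows = [
        "Hugo_Symbol\tTumor_Sample_Barcode\tVariant_Classification\tHGVSp_Short\tVariant_Type\tExon_Number",
        "TP53\tTCGA-05-4244-01A-01D-1105-08\tMissense_Mutation\tp.R175H\tSNP\t5/11",
        "KRAS\tTCGA-05-4244-01A-01D-1105-08\tSilent\tp.G13G\tSNP\t2/5",
        "STK11\tTCGA-05-4250-01A-01D-1105-08\tFrame_Shift_Del\tp.T286Lfs*97\tDEL\t6/10",
    ]
    path.write_text("\n".join(rows) + "\n")
    return path


def ols_oracle(x, y):
    """Independent simple-regression oracle: explicit normal equations,
    residual scale sqrt(RSS/(n-2)), SR = residual / scale."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    # solve [[n, sx], [sx, sxx]] @ [a, b] = [sy, sxy] by Cramer's rule
    det = n * sxx - sx * sx
    intercept = (sy * sxx - sx * sxy) / det
    slope = (n * sxy - sx * sy) / det
    resid = y - (intercept + slope * x)
    scale = np.sqrt((resid**2).sum() / (n - 2))
    return intercept, slope, scale, resid / scale
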