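"""Readers/writers for the pipeline's plain-TSV dialects.

Two input families are supported:

* LFQ protein-group matrices (proteins x samples, log2 intensities, missing
  values as empty fields or ``NA``) with a companion sample sheet
  (sample_id, cell_line, subtype, bio_rep, tech_rep).
* Patient expression cohorts: a gene x patient mRNA z-score matrix plus a
  clinical table.  Clinical column names and event codings follow the
  cBioPortal export dialect and are normalised through documented mapping
  tables (e.g. ``OS_STATUS`` of ``1:DECEASED`` -> event).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LfqMatrix",
    "ExpressionCohort",
    "read_lfq",
    "write_lfq",
    "read_cohort",
    "write_cohort",
    "split_protein_id",
    "file_digest",
]

FLOAT_FORMAT = "%.10g"

SUBTYPES_CELL = ("basal", "luminal", "control")
PAM50_LEVELS = ("Basal", "LumA", "LumB", "Her2", "Normal")

#: Accepted clinical column aliases (upper-cased before lookup).
CLINICAL_ALIASES = {
    "patient_id": ("PATIENT_ID", "CASE_ID", "SAMPLE_ID"),
    "pam50": ("PAM50", "PAM50_SUBTYPE", "SUBTYPE", "CLAUDIN_SUBTYPE"),
    "os_months": ("OS_MONTHS", "OVERALL_SURVIVAL_MONTHS"),
    "os_status": ("OS_STATUS", "OVERALL_SURVIVAL_STATUS"),
    "drfs_months": ("DRFS_MONTHS", "DRFS_TIME_MONTHS"),
    "drfs_status": ("DRFS_STATUS", "DRFS_EVENT"),
    "er": ("ER", "ER_STATUS", "ER_STATUS_BY_IHC"),
    "pr": ("PR", "PR_STATUS", "PR_STATUS_BY_IHC"),
    "her2": ("HER2", "HER2_STATUS", "IHC_HER2"),
}

#: Event-status value -> boolean event indicator.
EVENT_CODES = {
    "DECEASED": True, "1:DECEASED": True, "DEAD": True,
    "LIVING": False, "0:LIVING": False, "ALIVE": False,
    "RECURRED": True, "1:RECURRED": True, "EVENT": True,
    "DISEASEFREE": False, "0:DISEASEFREE": False,
    "1": True, "0": False, "TRUE": True, "FALSE": False,
    "1.0": True, "0.0": False,
}

#: PAM50 label spelling variants.
PAM50_ALIASES = {
    "BASAL": "Basal", "BASAL-LIKE": "Basal", "BASALLIKE": "Basal",
    "LUMA": "LumA", "LUMINAL A": "LumA", "LUMINAL_A": "LumA",
    "LUMB": "LumB", "LUMINAL B": "LumB", "LUMINAL_B": "LumB",
    "HER2": "Her2", "HER2-ENRICHED": "Her2", "HER2_ENRICHED": "Her2",
    "HER2+": "Her2",
    "NORMAL": "Normal", "NORMAL-LIKE": "Normal", "NORMAL_LIKE": "Normal",
}


@dataclass
class LfqMatrix:
    """Log2 LFQ intensity matrix with replicate/subtype annotations.

    ``values``: DataFrame proteins x samples (NaN = not quantified).
    ``samples``: DataFrame indexed by sample_id with columns
    cell_line, subtype, bio_rep, tech_rep.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self):
        self.validate()

    def validate(self):
        if not self.values.index.is_unique:
            raise ValueError("protein ids are not unique")
        missing = [c for c in self.values.columns if c not in self.samples.index]
        if missing:
            raise ValueError(f"samples missing from sample sheet: {missing}")
        bad = set(self.samples["subtype"]) - set(SUBTYPES_CELL)
        if bad:
            raise ValueError(f"unknown cell-line subtype labels: {sorted(bad)}")
        counts = self.samples.loc[list(self.values.columns)].groupby("cell_line").size()
        if (counts < 2).any():
            low = counts[counts < 2].index.tolist()
            raise ValueError(f"cell lines with <2 replicate columns: {low}")
        vals = self.values.to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise ValueError("non-finite intensities present")

    @property
    def cell_lines(self) -> list[str]:
        seen = dict.fromkeys(self.samples.loc[list(self.values.columns), "cell_line"])
        return list(seen)

    def columns_of(self, cell_line: str) -> list[str]:
        sub = self.samples.loc[list(self.values.columns)]
        return list(sub.index[sub["cell_line"] == cell_line])

    def subtype_of(self, cell_line: str) -> str:
        rows = self.samples[self.samples["cell_line"] == cell_line]
        return str(rows["subtype"].iloc[0])

    def lines_of_subtype(self, subtype: str) -> list[str]:
        return [cl for cl in self.cell_lines if self.subtype_of(cl) == subtype]


@dataclass
class ExpressionCohort:
    """Gene x patient z-score matrix plus PAM50 and survival annotations.

    Patients lacking survival data are kept in ``z``/``clinical`` but
    flagged (``has_survival``) and excluded from survival operations.
    """

    name: str
    z: pd.DataFrame
    clinical: pd.DataFrame  # index patient_id: pam50, time_months, event
    endpoint: str = "OS"

    def __post_init__(self):
        if self.endpoint not in ("OS", "DRFS"):
            raise ValueError(f"unknown endpoint {self.endpoint!r}")
        missing = [p for p in self.z.columns if p not in self.clinical.index]
        if missing:
            raise ValueError(f"patients missing from clinical table: {missing[:5]}...")
        self.clinical = self.clinical.loc[list(self.z.columns)]
        if self.clinical["pam50"].isna().any():
            raise ValueError("PAM50 label missing for some patients")
        t = self.clinical["time_months"]
        if (t.dropna() < 0).any():
            raise ValueError("negative survival times")

    @property
    def has_survival(self) -> pd.Series:
        return self.clinical["time_months"].notna() & self.clinical["event"].notna()

    def patients_in_scope(self, pam50_scope) -> list[str]:
        """Patients of the given PAM50 subtype(s) that carry survival data."""
        scope = {pam50_scope} if isinstance(pam50_scope, str) else set(pam50_scope)
        keep = self.clinical["pam50"].isin(scope) & self.has_survival
        return list(self.clinical.index[keep])


def split_protein_id(protein_id: str) -> tuple[str, str]:
    """Split ``ACCESSION|GENE`` into its parts; a bare id maps to itself."""
    if "|" in protein_id:
        acc, gene = protein_id.split("|", 1)
        return acc, gene
    return protein_id, protein_id


# ---------------------------------------------------------------------- I/O

def read_lfq(matrix_path, samples_path) -> LfqMatrix:
    values = pd.read_csv(matrix_path, sep="\t", index_col=0, na_values=["NA", ""])
    values = values.astype(float)
    samples = pd.read_csv(samples_path, sep="\t", index_col="sample_id", dtype={"sample_id": str})
    samples.index = samples.index.astype(str)
    values.columns = values.columns.astype(str)
    return LfqMatrix(values=values, samples=samples)


def write_lfq(matrix: LfqMatrix, matrix_path, samples_path) -> None:
    matrix.values.to_csv(matrix_path, sep="\t", index_label="protein_id",
                         float_format=FLOAT_FORMAT, na_rep="NA")
    matrix.samples.to_csv(samples_path, sep="\t", index_label="sample_id")


def _find_column(columns, key):
    upper = {c.upper(): c for c in columns}
    for alias in CLINICAL_ALIASES[key]:
        if alias in upper:
            return upper[alias]
    return None


def normalize_clinical(raw: pd.DataFrame, endpoint: str = "OS") -> pd.DataFrame:
    """Map a cBioPortal-dialect clinical table onto the internal schema.

    Returns a DataFrame indexed by patient_id with columns
    ``pam50``, ``time_months``, ``event`` (the requested endpoint).
    """
    pid_col = _find_column(raw.columns, "patient_id")
    if pid_col is None:
        raise ValueError(f"no patient id column among {list(raw.columns)}")
    pam_col = _find_column(raw.columns, "pam50")
    if pam_col is None:
        raise ValueError("no PAM50 subtype column found")
    key = endpoint.lower()
    t_col = _find_column(raw.columns, f"{key}_months")
    s_col = _find_column(raw.columns, f"{key}_status")
    if t_col is None or s_col is None:
        raise ValueError(f"no {endpoint} time/status columns found")

    pam = raw[pam_col].astype(str).str.strip()
    pam = pam.map(lambda v: PAM50_ALIASES.get(v.upper(), v))
    bad = set(pam) - set(PAM50_LEVELS)
    if bad:
        raise ValueError(f"unrecognised PAM50 labels: {sorted(bad)}")

    def decode(v):
        if pd.isna(v):
            return np.nan
        s = str(v).strip().upper()
        if s in EVENT_CODES:
            return EVENT_CODES[s]
        raise ValueError(f"unrecognised event status {v!r}")

    out = pd.DataFrame(
        {
            "pam50": pam.to_numpy(),
            "time_months": pd.to_numeric(raw[t_col], errors="coerce").to_numpy(),
            "event": [decode(v) for v in raw[s_col]],
        },
        index=raw[pid_col].astype(str),
    )
    out.index.name = "patient_id"
    return out


def read_cohort(expr_path, clinical_path, name: str, endpoint: str = "OS") -> ExpressionCohort:
    z = pd.read_csv(expr_path, sep="\t", index_col=0, na_values=["NA", ""]).astype(float)
    z.columns = z.columns.astype(str)
    raw = pd.read_csv(clinical_path, sep="\t")
    clinical = normalize_clinical(raw, endpoint=endpoint)
    clinical = clinical.loc[[p for p in z.columns if p in clinical.index]]
    keep = [p for p in z.columns if p in clinical.index]
    return ExpressionCohort(name=name, z=z[keep], clinical=clinical, endpoint=endpoint)


def write_cohort(cohort: ExpressionCohort, expr_path, clinical_path) -> None:
    cohort.z.to_csv(expr_path, sep="\t", index_label="gene_id",
                    float_format=FLOAT_FORMAT, na_rep="NA")
    status_col = f"{cohort.endpoint}_STATUS"
    months_col = f"{cohort.endpoint}_MONTHS"
    if cohort.endpoint == "OS":
        status = cohort.clinical["event"].map({True: "DECEASED", False: "LIVING"})
    else:
        status = cohort.clinical["event"].map({True: "1", False: "0"})
    out = pd.DataFrame(
        {
            "PATIENT_ID": cohort.clinical.index,
            "PAM50": cohort.clinical["pam50"].to_numpy(),
            months_col: cohort.clinical["time_months"].to_numpy(),
            status_col: status.to_numpy(),
        }
    )
    out.to_csv(clinical_path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def file_digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
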