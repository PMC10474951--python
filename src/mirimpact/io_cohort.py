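"""Cohort assembly: mutation tables, count matrices, clinical data, mutation contexts.

A *mutation context* is the binary division of one cancer cohort's patients
into mutant vs wild-type with respect to one gene's nonsilent mutation
status.  A gene counts as mutated in a patient if the patient carries at
least one nonsilent mutation anywhere in the gene body.  Contexts are kept
only when both the mutant and the wild-type class exceed a minimum fraction
(default 5%) of the cohort, and each context is assigned to one of ten
discrete mutation-frequency categories {0.05, 0.10, ..., 0.50} that index a
shared permutation null distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The discrete mutation-frequency grid indexing permutation nulls.
CATEGORY_GRID: np.ndarray = np.round(np.arange(1, 11) * 0.05, 2)

#: Consequence tokens treated as nonsilent (protein-altering) by default.
#: Covers the standard MAF Variant_Classification vocabulary plus plain
#: lower-case synonyms for minimal three-column inputs.
DEFAULT_NONSILENT = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Splice_Site",
        "Nonstop_Mutation",
        "Translation_Start_Site",
        "missense",
        "nonsense",
        "frameshift_indel",
        "in_frame_indel",
        "splice_site",
        "nonstop",
        "translation_start",
    }
)

MAF_COLUMNS = {
    "Tumor_Sample_Barcode": "patient_id",
    "Hugo_Symbol": "gene",
    "Chromosome": "chrom",
    "Start_Position": "pos",
    "Reference_Allele": "ref",
    "Tumor_Seq_Allele2": "alt",
    "Variant_Classification": "consequence",
}


@dataclass(frozen=True)
class MutationRecord:
    """One somatic variant call: patient, gene, locus, alleles, consequence."""

    patient_id: str
    gene: str
    chrom: str = "."
    pos: int = 1
    ref: str = "N"
    alt: str = "A"
    consequence: str = "missense"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1 (1-based), got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt alleles must differ, got {self.ref!r}")
        if not self.consequence:
            raise ValueError("consequence must be a non-empty token")


@dataclass
class Cohort:
    """One cancer type's patients with their feature counts and clinical data.

    Parameters
    ----------
    cancer_type : str
        Cohort label (e.g. a TCGA study abbreviation).
    counts : pandas.DataFrame
        Raw feature-by-patient count matrix, non-negative integers.
    clinical : pandas.DataFrame or None
        Indexed by patient ID with columns ``os_time``, ``os_event``,
        ``dss_time``, ``dss_event`` (times in days; events in {0, 1};
        missing values allowed).
    """

    cancer_type: str
    counts: pd.DataFrame
    clinical: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if self.clinical is not None:
            extra = set(self.clinical.index) - set(self.counts.columns)
            if extra:
                logger.warning(
                    "%d clinical rows have no count column and are dropped", len(extra)
                )
                self.clinical = self.clinical.drop(index=sorted(extra))

    @property
    def patients(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_patients(self) -> int:
        return self.counts.shape[1]

    @property
    def features(self) -> list[str]:
        return list(self.counts.index)


@dataclass
class MutationContext:
    """Binary mutant/wild-type labelling of a cohort's patients for one gene."""

    cancer_type: str
    gene: str
    labels: np.ndarray  # boolean, True = mutant, aligned to cohort.patients
    f: float
    f_effective: float = field(init=False)
    category: float = field(init=False)
    rounding: str = "nearest"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=bool)
        if not 0.05 < self.f < 0.95:
            raise ValueError(
                f"mutation frequency {self.f:.4f} outside the admissible (0.05, 0.95) band"
            )
        self.f_effective = min(self.f, 1.0 - self.f)
        self.category = map_frequency_category(self.f, rounding=self.rounding)

    @property
    def n_mutant(self) -> int:
        return int(self.labels.sum())


def map_frequency_category(f: float, rounding: str = "nearest") -> float:
    """Map a mutation frequency to its discrete null-distribution category.

    The grid covers the minority-class fraction ``f_eff = min(f, 1-f)`` in
    {0.05, ..., 0.50}; permutation nulls are symmetric in the class labels,
    so only the minority fraction matters.

    Parameters
    ----------
    f : float
        Mutation frequency, strictly inside (0.05, 0.95).
    rounding : {"nearest", "ceil"}
        ``nearest`` picks the closest grid value (exact midpoints round
        down); ``ceil`` picks the smallest grid value >= f_eff.
    """
    if not 0.05 < f < 0.95:
        raise ValueError(f"frequency {f} outside (0.05, 0.95)")
    f_eff = min(f, 1.0 - f)
    if rounding == "nearest":
        # argmin returns the first (lowest) grid point on exact ties
        return float(CATEGORY_GRID[np.argmin(np.abs(CATEGORY_GRID - f_eff))])
    if rounding == "ceil":
        idx = int(np.searchsorted(CATEGORY_GRID, f_eff - 1e-12, side="left"))
        return float(CATEGORY_GRID[min(idx, len(CATEGORY_GRID) - 1)])
    raise ValueError(f"unknown rounding mode {rounding!r}")


def aggregate_mutations(
    records: Iterable[MutationRecord],
    patients: Sequence[str],
    nonsilent_classes: Iterable[str] = DEFAULT_NONSILENT,
) -> pd.DataFrame:
    """Aggregate variant calls to a gene-by-patient binary mutation matrix.

    A gene is mutated in a patient iff at least one record for that
    (gene, patient) pair carries a nonsilent consequence; silent records and
    duplicate calls do not change the entry.  Records for patients outside
    ``patients`` are dropped with a logged count (patients absent from the
    mutation table are wild-type everywhere, the usual convention for
    consortium call sets where absence of a call means no mutation).
    """
    patients = list(patients)
    if not patients:
        raise ValueError("patients must be non-empty")
    nonsilent = set(nonsilent_classes)
    if not nonsilent:
        raise ValueError("nonsilent_classes must be non-empty")

    patient_idx = {p: i for i, p in enumerate(patients)}
    gene_rows: dict[str, np.ndarray] = {}
    n_dropped = 0
    for rec in records:
        if rec.consequence not in nonsilent:
            continue
        j = patient_idx.get(rec.patient_id)
        if j is None:
            n_dropped += 1
            continue
        row = gene_rows.get(rec.gene)
        if row is None:
            row = gene_rows[rec.gene] = np.zeros(len(patients), dtype=np.int8)
        row[j] = 1
    if n_dropped:
        logger.warning("dropped %d mutation records with unknown patient IDs", n_dropped)
    if not gene_rows:
        return pd.DataFrame(
            np.zeros((0, len(patients)), dtype=np.int8), columns=patients
        )
    genes = sorted(gene_rows)
    return pd.DataFrame(
        np.vstack([gene_rows[g] for g in genes]), index=genes, columns=patients
    )


def build_contexts(
    mutmatrix: pd.DataFrame,
    cohort: Cohort,
    min_freq: float = 0.05,
    rounding: str = "nearest",
) -> list[MutationContext]:
    """Build the frequency-filtered mutation contexts of a cohort.

    One context per gene whose mutation frequency f satisfies
    ``min_freq < f < 1 - min_freq`` among the cohort's count-matrix
    patients.  Patients present in counts but absent from the mutation
    matrix are treated as wild-type (logged).
    """
    if not 0 < min_freq < 0.5:
        raise ValueError("min_freq must lie in (0, 0.5)")
    patients = cohort.patients
    shared = [p for p in patients if p in mutmatrix.columns]
    if mutmatrix.shape[0] and not shared:
        raise ValueError(
            "no overlap between mutation-table patients and count-matrix patients"
        )
    missing = len(patients) - len(shared)
    if missing:
        logger.info(
            "%d count-matrix patients absent from the mutation table; treated as wild-type",
            missing,
        )
    aligned = mutmatrix.reindex(columns=patients, fill_value=0)
    contexts: list[MutationContext] = []
    n = len(patients)
    for gene, row in aligned.iterrows():
        labels = row.to_numpy() > 0
        f = labels.sum() / n
        if not min_freq < f < 1.0 - min_freq:
            continue
        contexts.append(
            MutationContext(
                cancer_type=cohort.cancer_type,
                gene=str(gene),
                labels=labels,
                f=float(f),
                rounding=rounding,
            )
        )
    return contexts


# ---------------------------------------------------------------------------
# File readers (plain TSV dialects)
# ---------------------------------------------------------------------------

def read_mutations(path) -> list[MutationRecord]:
    """Read a mutation table: MAF-compatible headers or a minimal 3-column
    (patient, gene, consequence) dialect."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if set(MAF_COLUMNS) <= set(df.columns):
        df = df.rename(columns=MAF_COLUMNS)
    elif {"patient", "gene", "consequence"} <= set(df.columns):
        df = df.rename(columns={"patient": "patient_id"})
        df["chrom"] = df.get("chrom", ".")
        df["pos"] = df.get("pos", 1)
        df["ref"] = df.get("ref", "N")
        df["alt"] = df.get("alt", "A")
    else:
        raise ValueError(
            f"{path}: expected MAF headers {sorted(MAF_COLUMNS)} or "
            "minimal columns (patient, gene, consequence)"
        )
    return [
        MutationRecord(
            patient_id=r.patient_id,
            gene=r.gene,
            chrom=str(r.chrom),
            pos=int(r.pos),
            ref=str(r.ref),
            alt=str(r.alt),
            consequence=str(r.consequence),
        )
        for r in df.itertuples(index=False)
    ]


def read_counts(path) -> pd.DataFrame:
    """Read a feature-by-patient raw count TSV (first column = feature ID)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if not np.issubdtype(df.values.dtype, np.number):
        raise ValueError(f"{path}: count matrix must be numeric")
    if (df.values < 0).any():
        raise ValueError(f"{path}: counts must be non-negative")
    return df.astype(np.int64)


CLINICAL_COLUMNS = ["os_time", "os_event", "dss_time", "dss_event"]


def read_clinical(path) -> pd.DataFrame:
    """Read a clinical TSV (patient, os_time, os_event, dss_time, dss_event)."""
    df = pd.read_csv(path, sep="\t")
    if "patient" not in df.columns:
        raise ValueError(f"{path}: clinical table needs a 'patient' column")
    df = df.set_index("patient")
    for col in CLINICAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return df[CLINICAL_COLUMNS].astype(float)


def load_cohort(
    counts_path, clinical_path=None, cancer_type: str = "COHORT"
) -> Cohort:
    """Assemble a :class:`Cohort` from count and (optional) clinical TSVs."""
    counts = read_counts(counts_path)
    clinical = read_clinical(clinical_path) if clinical_path is not None else None
    return Cohort(cancer_type=cancer_type, counts=counts, clinical=clinical)
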