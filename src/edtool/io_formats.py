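"""Readers/writers for the tabular and sequence formats the pipeline touches.

MAF (tab-separated, MC3-style column names), coding-sequence FASTA, GMT gene
sets, and the TSV tables describing cell-line panels. Cohort assembly and
filtering also live here.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class ImpactClass(str, Enum):
    """Functional consequence of a somatic mutation."""

    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    SPLICE_SITE = "splice_site"
    FRAMESHIFT_INDEL = "frameshift_indel"
    INFRAME_INDEL = "inframe_indel"
    OTHER = "other"


#: Classes counted as "non-silent" when defining mutation contexts and TMB.
NON_SILENT_CLASSES = frozenset(
    {
        ImpactClass.MISSENSE.value,
        ImpactClass.NONSENSE.value,
        ImpactClass.SPLICE_SITE.value,
        ImpactClass.FRAMESHIFT_INDEL.value,
        ImpactClass.INFRAME_INDEL.value,
    }
)

INDEL_CLASSES = frozenset(
    {ImpactClass.FRAMESHIFT_INDEL.value, ImpactClass.INFRAME_INDEL.value}
)

TRUNCATING_CLASSES = frozenset(
    {ImpactClass.NONSENSE.value, ImpactClass.SPLICE_SITE.value}
)

#: Default mapping of MAF ``Variant_Classification`` values to internal classes.
DEFAULT_CLASS_MAP: dict[str, str] = {
    "Missense_Mutation": ImpactClass.MISSENSE.value,
    "Nonsense_Mutation": ImpactClass.NONSENSE.value,
    "Splice_Site": ImpactClass.SPLICE_SITE.value,
    "Silent": ImpactClass.SYNONYMOUS.value,
    "Frame_Shift_Ins": ImpactClass.FRAMESHIFT_INDEL.value,
    "Frame_Shift_Del": ImpactClass.FRAMESHIFT_INDEL.value,
    "In_Frame_Ins": ImpactClass.INFRAME_INDEL.value,
    "In_Frame_Del": ImpactClass.INFRAME_INDEL.value,
}

#: Inverse map used when emitting MAF files (one representative per class).
CLASS_TO_MAF: dict[str, str] = {
    ImpactClass.MISSENSE.value: "Missense_Mutation",
    ImpactClass.NONSENSE.value: "Nonsense_Mutation",
    ImpactClass.SPLICE_SITE.value: "Splice_Site",
    ImpactClass.SYNONYMOUS.value: "Silent",
    ImpactClass.FRAMESHIFT_INDEL.value: "Frame_Shift_Del",
    ImpactClass.INFRAME_INDEL.value: "In_Frame_Del",
    ImpactClass.OTHER.value: "3'UTR",
}

RECORD_COLUMNS = [
    "sample_id",
    "gene",
    "impact_class",
    "ref_allele",
    "alt_allele",
    "t_alt_count",
    "t_ref_count",
    "tumor_type",
    "position",
]


class FormatError(ValueError):
    """Raised when an input file violates the expected layout."""


class GeneModelError(ValueError):
    """Raised when a CDS fails gene-model validation."""


class EmptyCohortError(ValueError):
    """Raised when a cohort filter removes every sample."""


@dataclass
class MutationRecord:
    """One somatic mutation call."""

    sample_id: str
    gene: str
    impact_class: str
    ref_allele: str = ""
    alt_allele: str = ""
    t_alt_count: int = 0
    t_ref_count: int = 0
    tumor_type: str = ""
    position: int | None = None

    def __post_init__(self) -> None:
        self.impact_class = ImpactClass(self.impact_class).value
        if self.t_alt_count < 0 or self.t_ref_count < 0:
            raise ValueError("read counts must be non-negative")


@dataclass
class ParseReport:
    """Bookkeeping from a MAF parse."""

    n_records: int = 0
    n_unmapped: int = 0
    unmapped_values: Counter = field(default_factory=Counter)
    n_skipped_zero_depth: int = 0


class Cohort:
    """A mutation table plus a sample roster.

    ``records`` is a DataFrame with :data:`RECORD_COLUMNS`; ``samples`` is a
    DataFrame with at least ``sample_id`` and ``tumor_type`` columns. Samples
    may carry zero mutations (they enter via an explicit roster).
    """

    def __init__(
        self,
        records: pd.DataFrame,
        samples: pd.DataFrame,
        parse_report: ParseReport | None = None,
    ) -> None:
        records = records.copy()
        for col in RECORD_COLUMNS:
            if col not in records.columns:
                records[col] = "" if col not in ("t_alt_count", "t_ref_count", "position") else 0
        self.records = records[RECORD_COLUMNS].reset_index(drop=True)
        samples = samples.copy()
        if "tumor_type" not in samples.columns:
            samples["tumor_type"] = ""
        if "subtype" not in samples.columns:
            samples["subtype"] = ""
        self.samples = samples[["sample_id", "tumor_type", "subtype"]].reset_index(drop=True)
        self.parse_report = parse_report or ParseReport(n_records=len(self.records))
        self.validate()

    # -- construction -----------------------------------------------------
    @classmethod
    def from_records(
        cls,
        records: Iterable[MutationRecord],
        roster: Sequence[str] | pd.DataFrame | None = None,
        tumor_types: Mapping[str, str] | None = None,
    ) -> "Cohort":
        rows = [vars(r) for r in records]
        rec_df = pd.DataFrame(rows, columns=RECORD_COLUMNS)
        if roster is None:
            sample_ids = sorted(rec_df["sample_id"].unique())
            samples = pd.DataFrame({"sample_id": sample_ids})
        elif isinstance(roster, pd.DataFrame):
            samples = roster
        else:
            samples = pd.DataFrame({"sample_id": list(roster)})
        if tumor_types is not None:
            samples = samples.copy()
            samples["tumor_type"] = samples["sample_id"].map(tumor_types).fillna("")
        elif "tumor_type" not in samples.columns and not rec_df.empty:
            tt = rec_df.groupby("sample_id")["tumor_type"].first()
            samples = samples.copy()
            samples["tumor_type"] = samples["sample_id"].map(tt).fillna("")
        return cls(rec_df, samples)

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        if self.samples.empty:
            raise EmptyCohortError("cohort roster is empty")
        if self.samples["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in roster")
        roster = set(self.samples["sample_id"])
        if not self.records.empty:
            missing = set(self.records["sample_id"]) - roster
            if missing:
                raise ValueError(
                    f"{len(missing)} record sample_ids missing from roster, e.g. "
                    f"{sorted(missing)[:3]}"
                )

    @property
    def N(self) -> int:
        """Total number of genomes (roster size)."""
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return self.samples["sample_id"].tolist()

    def subset(self, sample_ids: Iterable[str]) -> "Cohort":
        keep = set(sample_ids)
        samples = self.samples[self.samples["sample_id"].isin(keep)]
        if samples.empty:
            raise EmptyCohortError("subset removed all samples")
        records = self.records[self.records["sample_id"].isin(keep)]
        return Cohort(records, samples)

    def non_silent(self) -> pd.DataFrame:
        return self.records[self.records["impact_class"].isin(NON_SILENT_CLASSES)]

    def __repr__(self) -> str:  # pragma: no cover
        return f"Cohort(N={self.N}, records={len(self.records)})"


# ---------------------------------------------------------------------------
# MAF
# ---------------------------------------------------------------------------

_REQUIRED_MAF_COLUMNS = ("Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification")


def read_maf(
    path: str | Path,
    class_map: Mapping[str, str] | None = None,
    sample_list: Sequence[str] | None = None,
    tumor_type_map: Mapping[str, str] | None = None,
) -> Cohort:
    """Read a MAF file into a :class:`Cohort`.

    Parameters
    ----------
    path
        Tab-separated file with at least ``Hugo_Symbol``,
        ``Tumor_Sample_Barcode`` and ``Variant_Classification`` columns.
    class_map
        Override for the ``Variant_Classification`` → impact-class mapping;
        values absent from the map fall through to ``other``.
    sample_list
        Explicit roster. Without it the roster is the distinct barcodes seen
        in the file (zero-mutation samples cannot be represented).
    tumor_type_map
        Optional ``sample_id → tumor_type`` manifest.
    """
    cmap = dict(DEFAULT_CLASS_MAP if class_map is None else class_map)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_MAF_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"MAF {path} missing required column(s): {missing}")

    report = ParseReport(n_records=len(df))
    mapped = df["Variant_Classification"].map(cmap)
    unmapped = mapped.isna()
    report.n_unmapped = int(unmapped.sum())
    report.unmapped_values = Counter(df.loc[unmapped, "Variant_Classification"])
    mapped = mapped.fillna(ImpactClass.OTHER.value)

    def _int_col(name: str) -> pd.Series:
        if name in df.columns:
            return pd.to_numeric(df[name], errors="coerce").fillna(0).astype(int)
        return pd.Series(np.zeros(len(df), dtype=int))

    tumor_type = df["tumor_type"] if "tumor_type" in df.columns else pd.Series([""] * len(df))
    position = (
        pd.to_numeric(df["Start_Position"], errors="coerce")
        if "Start_Position" in df.columns
        else pd.Series([np.nan] * len(df))
    )
    records = pd.DataFrame(
        {
            "sample_id": df["Tumor_Sample_Barcode"],
            "gene": df["Hugo_Symbol"],
            "impact_class": mapped,
            "ref_allele": df.get("Reference_Allele", pd.Series([""] * len(df))),
            "alt_allele": df.get("Tumor_Seq_Allele2", pd.Series([""] * len(df))),
            "t_alt_count": _int_col("t_alt_count"),
            "t_ref_count": _int_col("t_ref_count"),
            "tumor_type": tumor_type,
            "position": position,
        }
    )

    if sample_list is not None:
        roster_ids = list(sample_list)
        extra = set(records["sample_id"]) - set(roster_ids)
        if extra:
            raise FormatError(
                f"MAF contains {len(extra)} barcodes absent from the supplied sample list"
            )
    else:
        roster_ids = sorted(records["sample_id"].unique())
    samples = pd.DataFrame({"sample_id": roster_ids})
    if tumor_type_map is not None:
        samples["tumor_type"] = samples["sample_id"].map(tumor_type_map).fillna("")
    else:
        tt = records.groupby("sample_id")["tumor_type"].first() if len(records) else {}
        samples["tumor_type"] = samples["sample_id"].map(tt).fillna("")
    logger.info("read_maf: %d records, %d samples from %s", len(records), len(samples), path)
    return Cohort(records, samples, parse_report=report)


def write_maf(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort back out as a minimal MC3-style MAF."""
    rec = cohort.records
    out = pd.DataFrame(
        {
            "Hugo_Symbol": rec["gene"],
            "Tumor_Sample_Barcode": rec["sample_id"],
            "Variant_Classification": rec["impact_class"].map(CLASS_TO_MAF),
            "Reference_Allele": rec["ref_allele"],
            "Tumor_Seq_Allele2": rec["alt_allele"],
            "t_alt_count": rec["t_alt_count"],
            "t_ref_count": rec["t_ref_count"],
            "tumor_type": rec["tumor_type"],
            "Start_Position": rec["position"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Cohort filtering
# ---------------------------------------------------------------------------


def filter_cohort(
    cohort: Cohort,
    tumor_types: Iterable[str] | None = None,
    subtype: Callable[[pd.Series], bool] | None = None,
    min_cases: int | None = None,
) -> Cohort:
    """Restrict a cohort by tumor type, subtype predicate and cohort size.

    ``min_cases`` drops whole tumor types whose case count falls below the
    threshold (applied after the tumor-type/subtype restriction).
    """
    samples = cohort.samples
    n_before = len(samples)
    if tumor_types is not None:
        wanted = set(tumor_types)
        samples = samples[samples["tumor_type"].isin(wanted)]
    if subtype is not None:
        keep_mask = samples.apply(subtype, axis=1)
        samples = samples[keep_mask.astype(bool)]
    if min_cases is not None:
        counts = samples["tumor_type"].value_counts()
        big = set(counts[counts >= min_cases].index)
        samples = samples[samples["tumor_type"].isin(big)]
    if samples.empty:
        raise EmptyCohortError("filter removed all samples")
    keep = set(samples["sample_id"])
    records = cohort.records[cohort.records["sample_id"].isin(keep)]
    logger.info("filter_cohort: %d -> %d samples", n_before, len(samples))
    return Cohort(records, samples)


# ---------------------------------------------------------------------------
# FASTA / GMT / panel tables
# ---------------------------------------------------------------------------


def read_cds_fasta(path: str | Path):
    """Read coding sequences into GeneModel objects keyed by gene symbol."""
    from Bio import SeqIO

    from .dnds_core import GeneModel

    models: dict[str, "GeneModel"] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            models[rec.id] = GeneModel(gene=rec.id, cds=str(rec.seq).upper())
        except ValueError as exc:
            raise GeneModelError(f"gene {rec.id}: {exc}") from exc
    return models


def write_cds_fasta(models: Mapping[str, object], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in models:
            fh.write(f">{name}\n{models[name].cds}\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file: ``name<TAB>description<TAB>gene...`` per line."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"GMT line {lineno}: expected name, description, genes")
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sets:
            genes = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\tna\t{genes}\n")


def read_panel_tables(
    mutation_path: str | Path,
    viability_path: str | Path | None = None,
    ic50_path: str | Path | None = None,
    tumor_type_path: str | Path | None = None,
):
    """Assemble a cell-line panel from its TSV components.

    The mutation matrix is cell line × gene (0/1); viability is cell line ×
    knockout gene; the IC50 table has columns ``cell_line``, ``drug``,
    ``target_gene``, ``ic50``.
    """
    from .dependency_pharm import CellLinePanel

    mutations = pd.read_csv(mutation_path, sep="\t", index_col=0)
    viability = (
        pd.read_csv(viability_path, sep="\t", index_col=0) if viability_path else None
    )
    ic50 = pd.read_csv(ic50_path, sep="\t") if ic50_path else None
    tumor_type = None
    if tumor_type_path:
        tt = pd.read_csv(tumor_type_path, sep="\t", index_col=0)
        tumor_type = tt.iloc[:, 0]
    return CellLinePanel(
        mutation_matrix=mutations, viability=viability, ic50=ic50, tumor_type=tumor_type
    )


def write_results(table: pd.DataFrame, path: str | Path) -> None:
    """Write a results table as TSV (no index)."""
    table.to_csv(path, sep="\t", index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
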