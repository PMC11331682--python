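"""Per-gene, per-class somatic dN/dS estimation.

The estimator enumerates every possible single-nucleotide substitution in a
coding sequence, classifies it by its effect on the protein, fits a
synonymous-calibrated substitution-rate model (uniform, 12 base-change
categories, or 96/192 trinucleotide categories), and reports
observed/expected ratios (omega) for missense and truncating mutations plus
a length-normalised indel rate ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import (
    Cohort,
    ImpactClass,
    INDEL_CLASSES,
    TRUNCATING_CLASSES,
)

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.int64)  # A<->T, C<->G

# class codes inside opportunity tables
CLS_SYN, CLS_MIS, CLS_NON, CLS_SPL = 0, 1, 2, 3
CLASS_NAMES = ("synonymous", "missense", "nonsense", "splice_site")

GRANULARITIES = ("uniform", "base12", "trinuc96", "trinuc192")
_N_CATEGORIES = {"uniform": 1, "base12": 12, "trinuc96": 96, "trinuc192": 192}

STOP_CODONS = {"TAA", "TAG", "TGA"}
START_CODON = "ATG"


def _codon_aa_table() -> np.ndarray:
    """Amino-acid code (0..20, 20 = stop) for each of the 64 codon integers."""
    from Bio.Data.CodonTable import standard_dna_table

    aa_codes = np.empty(64, dtype=np.int64)
    for i0 in range(4):
        for i1 in range(4):
            for i2 in range(4):
                codon = BASES[i0] + BASES[i1] + BASES[i2]
                idx = i0 * 16 + i1 * 4 + i2
                if codon in standard_dna_table.stop_codons:
                    aa_codes[idx] = 20
                else:
                    aa_codes[idx] = ord(standard_dna_table.forward_table[codon]) - 65
    return aa_codes


_AA_TABLE = _codon_aa_table()
_STOP_CODE = 20

# rank of alt base among the three bases != ref (for category indexing)
_ALT_RANK = np.full((4, 4), -1, dtype=np.int64)
for _r in range(4):
    _rank = 0
    for _a in range(4):
        if _a != _r:
            _ALT_RANK[_r, _a] = _rank
            _rank += 1


class EstimationError(ValueError):
    """Raised when a rate model cannot be fitted from the available data."""


@dataclass
class GeneModel:
    """A coding sequence plus its splice-site opportunity.

    The CDS must start with ATG, end with a stop codon, contain no internal
    stop, and use only A/C/G/T.
    """

    gene: str
    cds: str
    splice_opportunity: float = 0.0

    def __post_init__(self) -> None:
        cds = self.cds.upper()
        if set(cds) - set(BASES):
            raise ValueError(f"CDS contains non-ACGT characters: {set(cds) - set(BASES)}")
        if len(cds) % 3 != 0:
            raise ValueError(f"CDS length {len(cds)} not divisible by 3")
        if len(cds) < 6:
            raise ValueError("CDS must contain at least a start and a stop codon")
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        if codons[0] != START_CODON:
            raise ValueError(f"CDS does not start with {START_CODON}")
        if codons[-1] not in STOP_CODONS:
            raise ValueError("CDS does not end with a stop codon")
        if any(c in STOP_CODONS for c in codons[:-1]):
            raise ValueError("internal stop codon")
        if self.splice_opportunity < 0:
            raise ValueError("splice_opportunity must be non-negative")
        self.cds = cds

    @property
    def length(self) -> int:
        return len(self.cds)

    @property
    def n_codons(self) -> int:
        return len(self.cds) // 3


def encode_sequence(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int64)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    if (out < 0).any():
        raise ValueError("sequence contains non-ACGT characters")
    return out


@dataclass
class OpportunityTable:
    """Every possible single-nucleotide substitution of a gene, pre-classified.

    ``site_pos``/``site_alt``/``site_class``/``site_category`` are parallel
    arrays of length 3 × CDS length (positions are 1-based CDS coordinates).
    ``counts`` is (n_categories × 4) with class columns ordered as
    :data:`CLASS_NAMES`; splice opportunity (3 per splice position) is carried
    in category 0 of the splice column.
    """

    gene: str
    granularity: str
    cds_length: int
    site_pos: np.ndarray
    site_alt: np.ndarray
    site_class: np.ndarray
    site_category: np.ndarray
    counts: np.ndarray
    splice_opportunity: float = 0.0
    _cat_lookup: np.ndarray = field(default=None, repr=False)

    @property
    def n_categories(self) -> int:
        return _N_CATEGORIES[self.granularity]

    def class_opportunity(self, cls: int) -> np.ndarray:
        """Opportunity per category for one class column."""
        return self.counts[:, cls]

    def category_of(self, pos1: np.ndarray, alt_idx: np.ndarray) -> np.ndarray:
        """Map 1-based CDS positions + alt base indices to rate categories."""
        key = (np.asarray(pos1, dtype=np.int64) - 1) * 4 + np.asarray(alt_idx, dtype=np.int64)
        return self._cat_lookup[key]


def _site_categories(
    seq: np.ndarray, pos3: np.ndarray, ref3: np.ndarray, alt3: np.ndarray, granularity: str
) -> np.ndarray:
    if granularity == "uniform":
        return np.zeros(pos3.shape, dtype=np.int64)
    rank = _ALT_RANK[ref3, alt3]
    if granularity == "base12":
        return ref3 * 3 + rank
    # trinucleotide context; CDS termini are padded with A
    left = np.where(pos3 > 0, seq[np.maximum(pos3 - 1, 0)], 0)
    right = np.where(pos3 < len(seq) - 1, seq[np.minimum(pos3 + 1, len(seq) - 1)], 0)
    if granularity == "trinuc192":
        return ((left * 4 + ref3) * 4 + right) * 3 + rank
    if granularity == "trinuc96":
        purine = (ref3 == 0) | (ref3 == 2)  # A or G: collapse to reverse strand
        l2 = np.where(purine, _COMPLEMENT[right], left)
        r2 = np.where(purine, _COMPLEMENT[left], right)
        ref2 = np.where(purine, _COMPLEMENT[ref3], ref3)
        alt2 = np.where(purine, _COMPLEMENT[alt3], alt3)
        pyr = np.where(ref2 == 1, 0, 1)  # C -> 0, T -> 1
        return ((l2 * 2 + pyr) * 4 + r2) * 3 + _ALT_RANK[ref2, alt2]
    raise ValueError(f"unknown granularity {granularity!r}")


def build_opportunity_table(gene: GeneModel, granularity: str = "uniform") -> OpportunityTable:
    """Classify all 3L possible substitutions of a gene's CDS.

    Each substitution is classified by translating the mutated codon:
    same amino acid → synonymous, stop gain → nonsense, otherwise missense
    (changes within or away from the terminal stop codon that do not preserve
    the stop are counted as missense). Deterministic.
    """
    if granularity not in GRANULARITIES:
        raise ValueError(f"granularity must be one of {GRANULARITIES}")
    seq = encode_sequence(gene.cds)
    L = len(seq)
    pos = np.arange(L)
    codon_start = (pos // 3) * 3
    codon_int = seq[codon_start] * 16 + seq[codon_start + 1] * 4 + seq[codon_start + 2]
    mult = np.array([16, 4, 1])[pos % 3]

    alt_choices = np.array([[b for b in range(4) if b != r] for r in range(4)])
    alts = alt_choices[seq]  # (L, 3)
    pos3 = np.repeat(pos, 3)
    ref3 = np.repeat(seq, 3)
    alt3 = alts.ravel()
    mut_codon = np.repeat(codon_int, 3) + (alt3 - ref3) * np.repeat(mult, 3)

    aa_ref = _AA_TABLE[np.repeat(codon_int, 3)]
    aa_mut = _AA_TABLE[mut_codon]
    cls = np.where(
        aa_mut == aa_ref, CLS_SYN, np.where(aa_mut == _STOP_CODE, CLS_NON, CLS_MIS)
    ).astype(np.int64)

    cat = _site_categories(seq, pos3, ref3, alt3, granularity)
    n_cat = _N_CATEGORIES[granularity]
    counts = np.zeros((n_cat, 4), dtype=np.float64)
    np.add.at(counts, (cat, cls), 1.0)
    counts[0, CLS_SPL] += 3.0 * gene.splice_opportunity

    lookup = np.full(L * 4, -1, dtype=np.int64)
    lookup[pos3 * 4 + alt3] = cat
    return OpportunityTable(
        gene=gene.gene,
        granularity=granularity,
        cds_length=L,
        site_pos=pos3 + 1,
        site_alt=alt3,
        site_class=cls,
        site_category=cat,
        counts=counts,
        splice_opportunity=gene.splice_opportunity,
        _cat_lookup=lookup,
    )


def build_opportunity_tables(
    genes: Mapping[str, GeneModel], granularity: str = "uniform"
) -> dict[str, OpportunityTable]:
    return {name: build_opportunity_table(genes[name], granularity) for name in genes}


@dataclass
class SubstitutionModel:
    """Per-category mutation rate per opportunity unit per sample.

    Fitted from synonymous mutations only; categories with zero opportunity
    carry NaN and must never be multiplied by a non-zero opportunity.
    """

    granularity: str
    rates: np.ndarray
    total_exposure: int
    syn_opportunity: np.ndarray
    n_syn_mutations: int

    @property
    def mean_rate(self) -> float:
        """Opportunity-weighted average per-site rate (used for splice classes)."""
        mask = self.syn_opportunity > 0
        return float(
            np.sum(self.rates[mask] * self.syn_opportunity[mask])
            / np.sum(self.syn_opportunity[mask])
        )


def _syn_category_counts(
    cohort: Cohort, tables: Mapping[str, OpportunityTable], granularity: str
) -> np.ndarray:
    n_cat = _N_CATEGORIES[granularity]
    out = np.zeros(n_cat, dtype=np.float64)
    rec = cohort.records
    syn = rec[rec["impact_class"] == ImpactClass.SYNONYMOUS.value]
    if granularity == "uniform":
        out[0] = float(len(syn[syn["gene"].isin(tables.keys())]))
        return out
    for gene, sub in syn.groupby("gene"):
        table = tables.get(gene)
        if table is None:
            continue
        pos = pd.to_numeric(sub["position"], errors="coerce")
        alt = sub["alt_allele"].map(_BASE_INDEX)
        ok = pos.notna() & alt.notna()
        if not ok.all():
            raise EstimationError(
                f"gene {gene}: {int((~ok).sum())} synonymous records lack position/alt "
                "needed for category-resolved rate fitting; use granularity='uniform'"
            )
        cats = table.category_of(pos[ok].to_numpy(np.int64), alt[ok].to_numpy(np.int64))
        if (cats < 0).any():
            raise EstimationError(f"gene {gene}: records at positions without a site entry")
        np.add.at(out, cats, 1.0)
    return out


def fit_substitution_model(
    cohort: Cohort,
    tables: Mapping[str, OpportunityTable],
    granularity: str = "uniform",
) -> SubstitutionModel:
    """ML rates: synonymous count / (synonymous opportunity × sample count)."""
    if granularity not in GRANULARITIES:
        raise ValueError(f"granularity must be one of {GRANULARITIES}")
    for t in tables.values():
        if t.granularity != granularity:
            raise ValueError("opportunity table granularity does not match the model")
    syn_counts = _syn_category_counts(cohort, tables, granularity)
    total_syn = int(syn_counts.sum())
    if total_syn == 0:
        raise EstimationError(
            "no synonymous mutations in the cohort subset; pool more samples or "
            "use a coarser granularity"
        )
    syn_opp = np.sum([t.counts[:, CLS_SYN] for t in tables.values()], axis=0)
    rates = np.full_like(syn_opp, np.nan, dtype=np.float64)
    mask = syn_opp > 0
    rates[mask] = syn_counts[mask] / (syn_opp[mask] * cohort.N)
    return SubstitutionModel(
        granularity=granularity,
        rates=rates,
        total_exposure=cohort.N,
        syn_opportunity=syn_opp,
        n_syn_mutations=total_syn,
    )


@dataclass
class DndsEstimate:
    """Observed/expected ratio for one gene × impact class."""

    gene: str
    impact_class: str  # missense | truncating | indel | synonymous
    n_obs: float
    n_exp: float
    omega: float
    subset_size: int
    defined: bool = True
    ci: tuple[float, float] | None = None


def _poisson_ci(n_obs: float, n_exp: float, alpha: float = 0.05) -> tuple[float, float]:
    if n_exp <= 0:
        return (np.nan, np.nan)
    lo = stats.chi2.ppf(alpha / 2, 2 * n_obs) / 2 if n_obs > 0 else 0.0
    hi = stats.chi2.ppf(1 - alpha / 2, 2 * (n_obs + 1)) / 2
    return (lo / n_exp, hi / n_exp)


def expected_count(
    table: OpportunityTable, model: SubstitutionModel, cls_columns: Sequence[int], subset_size: int
) -> float:
    """Expected neutral mutation count for one or more class columns."""
    opp = table.counts[:, list(cls_columns)].sum(axis=1)
    mask = (opp > 0) & np.isfinite(model.rates)
    n_exp = subset_size * float(np.sum(model.rates[mask] * opp[mask]))
    # splice opportunity rides in category 0 of the splice column; if that
    # category has no fitted rate, fall back to the panel-average rate
    if CLS_SPL in cls_columns and not np.isfinite(model.rates[0]) and table.splice_opportunity:
        n_exp += subset_size * model.mean_rate * 3.0 * table.splice_opportunity
    return n_exp


_CLASS_COLUMNS = {"missense": (CLS_MIS,), "truncating": (CLS_NON, CLS_SPL)}
_OBS_CLASSES = {
    "missense": {ImpactClass.MISSENSE.value},
    "truncating": set(TRUNCATING_CLASSES),
}


def dnds(
    cohort_subset: Cohort,
    gene: str,
    model: SubstitutionModel,
    table: OpportunityTable,
    classes: Iterable[str] = ("missense", "truncating"),
    pseudocount: float = 0.0,
) -> dict[str, DndsEstimate]:
    """dN/dS per impact class for one gene on one cohort subset.

    omega = n_obs / n_exp with n_exp from the synonymous-calibrated rate
    model. A zero numerator yields omega = 0; a zero n_exp is flagged
    (``defined=False``) rather than silently reported.
    """
    rec = cohort_subset.records
    grec = rec[rec["gene"] == gene]
    out: dict[str, DndsEstimate] = {}
    for cls_name in classes:
        n_obs = float((grec["impact_class"].isin(_OBS_CLASSES[cls_name])).sum())
        n_exp = expected_count(table, model, _CLASS_COLUMNS[cls_name], cohort_subset.N)
        num, den = n_obs + pseudocount, n_exp + pseudocount
        if den <= 0:
            out[cls_name] = DndsEstimate(
                gene, cls_name, n_obs, n_exp, np.nan, cohort_subset.N, defined=False
            )
            continue
        out[cls_name] = DndsEstimate(
            gene,
            cls_name,
            n_obs,
            n_exp,
            num / den,
            cohort_subset.N,
            ci=_poisson_ci(n_obs, n_exp),
        )
    return out


def dnds_indel(
    cohort_subset: Cohort,
    gene: str,
    background_genes: Iterable[str],
    cds_lengths: Mapping[str, int],
    pseudocount: float = 0.0,
) -> DndsEstimate:
    """Length-normalised indel rate of a gene over the pooled background rate.

    Frameshift and in-frame indels are pooled. The background panel must not
    contain the tested gene.
    """
    background_genes = [g for g in background_genes if g != gene]
    if not background_genes:
        raise ValueError("background panel is empty")
    rec = cohort_subset.records
    ind = rec[rec["impact_class"].isin(INDEL_CLASSES)]
    n_gene = float((ind["gene"] == gene).sum())
    n_bg = float(ind["gene"].isin(background_genes).sum())
    L_gene = float(cds_lengths[gene])
    L_bg = float(sum(cds_lengths[g] for g in background_genes))
    bg_rate = n_bg / L_bg
    n_exp = bg_rate * L_gene
    num, den = n_gene + pseudocount, n_exp + pseudocount
    if den <= 0:
        return DndsEstimate(gene, "indel", n_gene, n_exp, np.nan, cohort_subset.N, defined=False)
    return DndsEstimate(gene, "indel", n_gene, n_exp, num / den, cohort_subset.N)


def select_driver_genes(
    cohort: Cohort,
    tables: Mapping[str, OpportunityTable],
    model: SubstitutionModel,
    q_threshold: float = 0.1,
) -> pd.DataFrame:
    """Genes under global positive selection at FDR ``q_threshold``.

    One-sided Poisson test of pooled non-silent substitution counts (missense
    + nonsense + splice) against their neutral expectation, Benjamini-
    Hochberg corrected across genes.
    """
    from statsmodels.stats.multitest import multipletests

    rec = cohort.records
    nonsilent = {ImpactClass.MISSENSE.value} | set(TRUNCATING_CLASSES)
    rows = []
    for gene in sorted(tables):
        table = tables[gene]
        grec = rec[rec["gene"] == gene]
        n_obs = int(grec["impact_class"].isin(nonsilent).sum())
        n_exp = expected_count(table, model, (CLS_MIS, CLS_NON, CLS_SPL), cohort.N)
        p = stats.poisson.sf(n_obs - 1, n_exp) if n_exp > 0 else 1.0
        rows.append({"gene": gene, "n_obs": n_obs, "n_exp": n_exp, "p": p})
    df = pd.DataFrame(rows)
    if df.empty:
        return df.assign(q=[], selected=[])
    df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    df["selected"] = df["q"] < q_threshold
    return df
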