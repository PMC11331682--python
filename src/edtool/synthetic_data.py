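"""Synthetic cohorts and cell-line panels with known ground truth.

The cohort generator is a two-stage process per sample: context-gene
mutation status is drawn first (realised as an actual non-silent mutation
record), then every (gene, class) mutation count is Poisson with mean
burden × opportunity × rate × omega_eff, where omega_eff picks up a
2**cdns_true factor for a pair's partner class in context-positive genomes.
Synonymous mutations always use omega = 1, so the programmed cdns_true is
the estimand of the cdNS pipeline by construction. Every mutation receives
a concrete site consistent with its class and read counts from a
clonal/subclonal Beta-binomial VAF model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dnds_core import (
    BASES,
    CLS_MIS,
    CLS_NON,
    CLS_SYN,
    GeneModel,
    build_opportunity_table,
)
from .io_formats import CLASS_TO_MAF, Cohort, ImpactClass

_NONSTOP_CODONS = [
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in {"TAA", "TAG", "TGA"}
]


@dataclass
class EdPairSpec:
    """One programmed evolutionary-dependency pair."""

    gene_a: str
    gene_b: str
    impact_class: str = "missense"  # missense | truncating | indel
    cdns_true: float = 0.0
    context_prevalence: float = 0.2

    def __post_init__(self) -> None:
        if not (0.0 < self.context_prevalence < 1.0):
            raise ValueError("context_prevalence must be in (0, 1)")
        if not np.isfinite(self.cdns_true):
            raise ValueError("cdns_true must be finite")


@dataclass
class VafModel:
    """Read-depth and allele-fraction model."""

    depth_mean: float = 80.0
    clonal: tuple[float, float] = (30.0, 30.0)  # Beta(a, b), mean 0.5
    subclonal: tuple[float, float] = (4.0, 36.0)  # mean 0.1


@dataclass
class PanelPairSpec:
    """Programmed effect sizes for one cell-line gene pair."""

    context_gene: str
    target_gene: str
    drug: str | None = None
    dependency_effect: float = 0.0
    ic50_effect: float = 0.0
    noise_sd: float = 0.1
    context_freq: float = 0.5
    baseline_viability: float = -1.0
    baseline_ic50: float = 1.0


@dataclass
class PanelSpec:
    n_cell_lines: int = 40
    pairs: list[PanelPairSpec] = field(default_factory=list)
    tumor_type: str = "TT1"


@dataclass
class SimulationConfig:
    """Full description of a synthetic cohort (and optional panel)."""

    seed: int = 0
    n_samples: int = 1000
    tumor_types: Mapping[str, float] = field(default_factory=lambda: {"TT1": 1.0})
    n_genes: int = 50
    length_codons: int = 300
    mutation_rate: float = 3e-4  # per site per sample (synonymous scale)
    burden_sigma: float = 0.5  # lognormal sigma of the per-sample multiplier
    hypermutator_fraction: float = 0.0
    hypermutator_factor: float = 20.0
    omega_missense: Mapping[str, float] = field(default_factory=dict)
    omega_truncating: Mapping[str, float] = field(default_factory=dict)
    omega_indel: Mapping[str, float] = field(default_factory=dict)
    indel_rate_per_kb: float = 0.02  # per sample per kb of CDS
    ed_pairs: list[EdPairSpec] = field(default_factory=list)
    subclonal_genes: set[str] = field(default_factory=set)
    vaf: VafModel = field(default_factory=VafModel)
    panel: PanelSpec | None = None

    def __post_init__(self) -> None:
        if self.mutation_rate < 0 or self.indel_rate_per_kb < 0:
            raise ValueError("rates must be non-negative")
        partners = {p.gene_b for p in self.ed_pairs}
        contexts = {p.gene_a for p in self.ed_pairs}
        clash = partners & contexts
        if clash:
            raise ValueError(
                f"genes cannot be both context and partner in programmed pairs: {sorted(clash)}"
            )


@dataclass
class SimulatedCohort:
    cohort: Cohort
    maf: pd.DataFrame
    genes: dict[str, GeneModel]
    gene_truth: pd.DataFrame
    pair_truth: pd.DataFrame
    context_status: pd.DataFrame  # sample × context gene (bool)


def simulate_cds(
    n_genes: int,
    length_codons: int,
    seed: int | np.random.Generator = 0,
    prefix: str = "G",
) -> dict[str, GeneModel]:
    """Random single-exon coding sequences: ATG + non-stop codons + TAA."""
    if length_codons < 10:
        raise ValueError("length_codons must be >= 10")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    genes: dict[str, GeneModel] = {}
    width = max(3, len(str(n_genes)))
    for i in range(n_genes):
        body = rng.choice(_NONSTOP_CODONS, size=length_codons - 2)
        cds = "ATG" + "".join(body) + "TAA"
        name = f"{prefix}{i + 1:0{width}d}"
        genes[name] = GeneModel(gene=name, cds=cds)
    return genes


def _class_sites(table) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    out = {}
    for cls in (CLS_SYN, CLS_MIS, CLS_NON):
        sel = table.site_class == cls
        out[cls] = (table.site_pos[sel], table.site_alt[sel])
    return out


def _draw_read_counts(
    n: int, vaf: VafModel, subclonal: bool, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    depth = np.maximum(rng.poisson(vaf.depth_mean, size=n), 1)
    a, b = vaf.subclonal if subclonal else vaf.clonal
    p = rng.beta(a, b, size=n)
    alt = np.clip(rng.binomial(depth, p), 1, depth)
    return alt, depth - alt


def simulate_cohort(
    config: SimulationConfig, genes: Mapping[str, GeneModel] | None = None
) -> SimulatedCohort:
    """Generate a cohort realising the configured selection structure.

    Deterministic given ``config.seed`` (byte-identical MAF output).
    Context genes carry their non-silent signal exclusively through the
    Bernoulli context draw (one missense record per positive genome), so the
    realised context split equals the programmed one; their synonymous
    mutations follow the neutral background like any other gene.
    """
    rng = np.random.default_rng(config.seed)
    if genes is None:
        genes = simulate_cds(config.n_genes, config.length_codons, rng)
    genes = dict(genes)
    tables = {g: build_opportunity_table(genes[g], "uniform") for g in genes}

    n = config.n_samples
    sample_ids = np.array([f"S{i + 1:05d}" for i in range(n)])
    tt_names = sorted(config.tumor_types)
    tt_probs = np.array([config.tumor_types[t] for t in tt_names], dtype=float)
    tt_probs = tt_probs / tt_probs.sum()
    tumor_type = rng.choice(tt_names, size=n, p=tt_probs)

    burden = rng.lognormal(mean=-config.burden_sigma**2 / 2, sigma=config.burden_sigma, size=n)
    is_hyper = rng.random(n) < config.hypermutator_fraction
    burden = np.where(is_hyper, burden * config.hypermutator_factor, burden)

    # stage 1: context-gene mutation status
    context_genes = []
    context_status: dict[str, np.ndarray] = {}
    for pair in config.ed_pairs:
        if pair.gene_a not in context_status:
            context_status[pair.gene_a] = rng.random(n) < pair.context_prevalence
            context_genes.append(pair.gene_a)
    pairs_by_partner: dict[tuple[str, str], EdPairSpec] = {
        (p.gene_b, p.impact_class): p for p in config.ed_pairs
    }

    cols: dict[str, list] = {k: [] for k in (
        "sample_id", "gene", "impact_class", "ref_allele", "alt_allele",
        "t_alt_count", "t_ref_count", "position",
    )}

    def _emit(
        gene: str,
        impact: str,
        counts: np.ndarray,
        pos: np.ndarray,
        ref: list[str],
        alt: list[str],
    ) -> None:
        total = int(counts.sum())
        if total == 0:
            return
        sidx = np.repeat(np.arange(n), counts)
        alt_c, ref_c = _draw_read_counts(
            total, config.vaf, gene in config.subclonal_genes, rng
        )
        cols["sample_id"].append(sample_ids[sidx])
        cols["gene"].append(np.full(total, gene))
        cols["impact_class"].append(np.full(total, impact))
        cols["ref_allele"].append(np.asarray(ref, dtype=object))
        cols["alt_allele"].append(np.asarray(alt, dtype=object))
        cols["t_alt_count"].append(alt_c)
        cols["t_ref_count"].append(ref_c)
        cols["position"].append(pos)

    def _substitution_records(gene: str, impact: str, cls: int, counts: np.ndarray) -> None:
        total = int(counts.sum())
        if total == 0:
            return
        pos_arr, alt_arr = sites[cls]
        if len(pos_arr) == 0:
            raise ValueError(f"gene {gene} has no opportunity for class {impact}")
        pick = rng.integers(0, len(pos_arr), size=total)
        pos = pos_arr[pick]
        ref = [genes[gene].cds[p - 1] for p in pos]
        alt = [BASES[a] for a in alt_arr[pick]]
        _emit(gene, impact, counts, pos, ref, alt)

    def _omega_eff(gene: str, impact: str, base: float) -> np.ndarray:
        om = np.full(n, base, dtype=float)
        pair = pairs_by_partner.get((gene, impact))
        if pair is not None:
            om = np.where(
                context_status[pair.gene_a], base * 2.0**pair.cdns_true, base
            )
        return om

    for gene in sorted(genes):
        table = tables[gene]
        sites = _class_sites(table)
        opp = table.counts.sum(axis=0)  # per class, uniform granularity
        lam_syn = burden * config.mutation_rate * opp[CLS_SYN]
        _substitution_records(
            gene, ImpactClass.SYNONYMOUS.value, CLS_SYN, rng.poisson(lam_syn)
        )

        if gene in context_status:
            counts_mis = context_status[gene].astype(np.int64)
            _substitution_records(gene, ImpactClass.MISSENSE.value, CLS_MIS, counts_mis)
            continue  # context genes: no other non-silent classes

        om_mis = _omega_eff(gene, "missense", config.omega_missense.get(gene, 1.0))
        lam_mis = burden * config.mutation_rate * opp[CLS_MIS] * om_mis
        _substitution_records(
            gene, ImpactClass.MISSENSE.value, CLS_MIS, rng.poisson(lam_mis)
        )

        om_non = _omega_eff(gene, "truncating", config.omega_truncating.get(gene, 1.0))
        lam_non = burden * config.mutation_rate * opp[CLS_NON] * om_non
        _substitution_records(
            gene, ImpactClass.NONSENSE.value, CLS_NON, rng.poisson(lam_non)
        )

        om_ind = _omega_eff(gene, "indel", config.omega_indel.get(gene, 1.0))
        lam_ind = burden * config.indel_rate_per_kb * (table.cds_length / 1000.0) * om_ind
        counts_ind = rng.poisson(lam_ind)
        total = int(counts_ind.sum())
        if total:
            pos = rng.integers(1, table.cds_length + 1, size=total)
            ref = [genes[gene].cds[p - 1] for p in pos]
            alt = ["-"] * total
            _emit(gene, ImpactClass.FRAMESHIFT_INDEL.value, counts_ind, pos, ref, alt)

    records = pd.DataFrame(
        {k: np.concatenate(v) if v else np.array([], dtype=object) for k, v in cols.items()}
    )
    if not records.empty:
        records["t_alt_count"] = records["t_alt_count"].astype(int)
        records["t_ref_count"] = records["t_ref_count"].astype(int)
        records["position"] = records["position"].astype(int)
        tt_map = dict(zip(sample_ids, tumor_type))
        records["tumor_type"] = records["sample_id"].map(tt_map)
        records = records.sort_values(
            ["sample_id", "gene", "position"], kind="mergesort"
        ).reset_index(drop=True)

    samples = pd.DataFrame({"sample_id": sample_ids, "tumor_type": tumor_type})
    samples["subtype"] = np.where(is_hyper, "hypermutator", "")
    cohort = Cohort(records, samples)

    maf = pd.DataFrame(
        {
            "Hugo_Symbol": records["gene"],
            "Tumor_Sample_Barcode": records["sample_id"],
            "Variant_Classification": records["impact_class"].map(CLASS_TO_MAF),
            "Reference_Allele": records["ref_allele"],
            "Tumor_Seq_Allele2": records["alt_allele"],
            "t_alt_count": records["t_alt_count"],
            "t_ref_count": records["t_ref_count"],
            "Start_Position": records["position"],
            "tumor_type": records["tumor_type"],
        }
    )

    gene_truth = pd.DataFrame(
        {
            "gene": sorted(genes),
            "cds_length": [genes[g].length for g in sorted(genes)],
            "omega_missense": [config.omega_missense.get(g, 1.0) for g in sorted(genes)],
            "omega_truncating": [config.omega_truncating.get(g, 1.0) for g in sorted(genes)],
            "omega_indel": [config.omega_indel.get(g, 1.0) for g in sorted(genes)],
            "is_context": [g in context_status for g in sorted(genes)],
            "clonality": [
                "subclonal" if g in config.subclonal_genes else "clonal" for g in sorted(genes)
            ],
        }
    )
    pair_truth = pd.DataFrame(
        [
            {
                "gene_a": p.gene_a,
                "gene_b": p.gene_b,
                "impact_class": p.impact_class,
                "cdns_true": p.cdns_true,
                "context_prevalence": p.context_prevalence,
                "n_context_pos": int(context_status[p.gene_a].sum()),
            }
            for p in config.ed_pairs
        ],
        columns=[
            "gene_a", "gene_b", "impact_class", "cdns_true",
            "context_prevalence", "n_context_pos",
        ],
    )
    ctx_df = pd.DataFrame(
        {g: context_status[g] for g in context_genes}, index=sample_ids
    )
    return SimulatedCohort(cohort, maf, genes, gene_truth, pair_truth, ctx_df)


def simulate_panel(
    spec: PanelSpec, seed: int | np.random.Generator = 0
) -> tuple["CellLinePanel", pd.DataFrame]:
    """Cell-line panel with programmed dependency/IC50 effect sizes.

    Each pair's target gene is mutated in every line; the context gene is
    mutated in a Bernoulli(context_freq) subset. Viability and IC50 are
    baseline + effect × context_indicator + Normal(0, noise_sd).
    """
    from .dependency_pharm import CellLinePanel

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = spec.n_cell_lines
    lines = [f"CL{i + 1:04d}" for i in range(n)]
    targets = [p.target_gene for p in spec.pairs]
    if len(set(targets)) != len(targets):
        raise ValueError("target genes must be unique across panel pairs")

    mut = pd.DataFrame(0, index=lines, columns=sorted({g for p in spec.pairs for g in (p.context_gene, p.target_gene)}))
    via = pd.DataFrame(np.nan, index=lines, columns=targets)
    ic50_rows = []
    truth_rows = []
    ctx_cache: dict[str, np.ndarray] = {}
    for p in spec.pairs:
        mut[p.target_gene] = 1
        if p.context_gene not in ctx_cache:
            ctx_cache[p.context_gene] = (rng.random(n) < p.context_freq).astype(int)
            mut[p.context_gene] = ctx_cache[p.context_gene]
        ctx = ctx_cache[p.context_gene]
        via[p.target_gene] = (
            p.baseline_viability
            + p.dependency_effect * ctx
            + rng.normal(0.0, p.noise_sd, size=n)
        )
        drug = p.drug or f"inh_{p.target_gene}"
        ic50 = (
            p.baseline_ic50 + p.ic50_effect * ctx + rng.normal(0.0, p.noise_sd, size=n)
        )
        for line, value in zip(lines, ic50):
            ic50_rows.append(
                {"cell_line": line, "drug": drug, "target_gene": p.target_gene, "ic50": value}
            )
        truth_rows.append(
            {
                "context_gene": p.context_gene,
                "target_gene": p.target_gene,
                "drug": drug,
                "dependency_effect": p.dependency_effect,
                "ic50_effect": p.ic50_effect,
                "noise_sd": p.noise_sd,
                "n_context_pos": int(ctx.sum()),
            }
        )
    panel = CellLinePanel(
        mutation_matrix=mut,
        viability=via,
        ic50=pd.DataFrame(ic50_rows),
        tumor_type=pd.Series(spec.tumor_type, index=lines),
    )
    return panel, pd.DataFrame(truth_rows)
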