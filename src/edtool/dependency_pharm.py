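"""Effect sizes linking gene-pair dependency calls to cell-line screens.

Knockout-viability and IC50 differentials between context-mutant and
context-wild-type cell lines, their rescuing/compromising labels, the
fourfold categorisation against SYN/ANT calls, and oncogene/TSG annotation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CellLinePanel:
    """Cell-line mutation/dependency/IC50 tables.

    ``mutation_matrix``: cell line × gene 0/1; ``viability``: cell line ×
    knockout gene score (lower = less viable); ``ic50``: rows of
    (cell_line, drug, target_gene, ic50); ``tumor_type``: per cell line.
    """

    mutation_matrix: pd.DataFrame
    viability: pd.DataFrame | None = None
    ic50: pd.DataFrame | None = None
    tumor_type: pd.Series | None = None
    ic50_natural_log: bool = True

    def __post_init__(self) -> None:
        lines = set(self.mutation_matrix.index)
        if self.viability is not None:
            extra = set(self.viability.index) - lines
            if extra:
                raise ValueError(f"viability rows missing from mutation matrix: {sorted(extra)[:3]}")
        if self.ic50 is not None:
            required = {"cell_line", "drug", "target_gene", "ic50"}
            if not required <= set(self.ic50.columns):
                raise ValueError(f"ic50 table must have columns {sorted(required)}")
            extra = set(self.ic50["cell_line"]) - lines
            if extra:
                raise ValueError(f"ic50 cell lines missing from mutation matrix: {sorted(extra)[:3]}")

    def mutated(self, gene: str) -> pd.Series:
        if gene not in self.mutation_matrix.columns:
            return pd.Series(False, index=self.mutation_matrix.index)
        return self.mutation_matrix[gene].astype(bool)


@dataclass
class EffectSizeResult:
    """Viability or IC50 differential of context+ vs context− cell lines."""

    gene_a: str  # context gene
    gene_b: str  # knockout gene or drug target
    modality: str  # dependency | drug
    effect: float
    n_pos: int
    n_neg: int
    label: str  # rescuing | compromising | tie
    drug: str | None = None
    p_value: float | None = None
    category: str | None = None  # Res-SYN | Res-ANT | Com-SYN | Com-ANT


def _label(effect: float) -> str:
    if effect > 0:
        return "rescuing"
    if effect < 0:
        return "compromising"
    return "tie"


def _group_effect(
    pos: np.ndarray, neg: np.ndarray, min_group: int = 2
) -> tuple[float, float] | None:
    if len(pos) < min_group or len(neg) < min_group:
        return None
    effect = float(np.median(pos) - np.median(neg))
    if np.std(pos) == 0 and np.std(neg) == 0:
        p = float("nan")  # degenerate groups: no spread to test against
    else:
        p = float(stats.ttest_ind(pos, neg, equal_var=False)[1])
    return effect, p


def dependency_effect_size(
    panel: CellLinePanel,
    knockout_gene: str,
    context_gene: str,
    min_group: int = 2,
) -> EffectSizeResult | None:
    """Median knockout-viability difference, context+ minus context−.

    Restricted to cell lines mutated in the knockout gene that have a
    viability score for it. Returns None (omitted) when either group has
    fewer than ``min_group`` lines.
    """
    if panel.viability is None or knockout_gene not in panel.viability.columns:
        return None
    via = panel.viability[knockout_gene].dropna()
    mutated = panel.mutated(knockout_gene)
    lines = via.index[mutated.reindex(via.index, fill_value=False)]
    ctx = panel.mutated(context_gene).reindex(lines, fill_value=False)
    pos = via.loc[lines[ctx]].to_numpy(float)
    neg = via.loc[lines[~ctx]].to_numpy(float)
    res = _group_effect(pos, neg, min_group)
    if res is None:
        return None
    effect, p = res
    return EffectSizeResult(
        gene_a=context_gene,
        gene_b=knockout_gene,
        modality="dependency",
        effect=effect,
        n_pos=len(pos),
        n_neg=len(neg),
        label=_label(effect),
        p_value=p,
    )


def drug_effect_size(
    panel: CellLinePanel,
    drug: str,
    target_gene: str,
    context_gene: str,
    tumor_type: str | None = None,
    min_group: int = 2,
) -> EffectSizeResult | None:
    """Median IC50 difference, context+ minus context−.

    Restricted to (optionally tumor-type-matched) cell lines mutated in the
    drug's target gene with an IC50 for the drug. Positive effect = the
    context mutation confers resistance.
    """
    if panel.ic50 is None:
        return None
    tab = panel.ic50
    tab = tab[(tab["drug"] == drug) & (tab["target_gene"] == target_gene)]
    if tumor_type is not None and panel.tumor_type is not None:
        keep = panel.tumor_type[panel.tumor_type == tumor_type].index
        tab = tab[tab["cell_line"].isin(set(keep))]
    mutated = panel.mutated(target_gene)
    tab = tab[tab["cell_line"].map(mutated).fillna(False).astype(bool)]
    if tab.empty:
        return None
    ctx = tab["cell_line"].map(panel.mutated(context_gene)).astype(bool)
    pos = tab.loc[ctx, "ic50"].to_numpy(float)
    neg = tab.loc[~ctx, "ic50"].to_numpy(float)
    res = _group_effect(pos, neg, min_group)
    if res is None:
        return None
    effect, p = res
    return EffectSizeResult(
        gene_a=context_gene,
        gene_b=target_gene,
        modality="drug",
        effect=effect,
        n_pos=len(pos),
        n_neg=len(neg),
        label=_label(effect),
        drug=drug,
        p_value=p,
    )


def _category(effect: float, cdns: float) -> str | None:
    if effect == 0 or not (math.isfinite(effect) and math.isfinite(cdns)):
        return None
    eff = "Res" if effect > 0 else "Com"
    ed = "SYN" if cdns > 0 else "ANT"
    return f"{eff}-{ed}"


@dataclass
class CategorizeResult:
    table: pd.DataFrame  # per-pair: gene_a, gene_b, effect, cdns, category
    pearson_r: float
    pearson_p: float


def categorize(
    effects: Sequence[EffectSizeResult],
    cdns_results: pd.DataFrame,
) -> CategorizeResult:
    """Join effect sizes with cdNS scores into the fourfold categories.

    Pairs appearing in several screens are averaged first. ``cdns_results``
    needs ``gene_a``, ``gene_b`` and ``cdns`` columns. Also reports the
    Pearson correlation between effect size and cdNS.
    """
    if not effects:
        return CategorizeResult(pd.DataFrame(), float("nan"), float("nan"))
    eff = pd.DataFrame(
        [
            {"gene_a": e.gene_a, "gene_b": e.gene_b, "effect": e.effect}
            for e in effects
        ]
    )
    eff = eff.groupby(["gene_a", "gene_b"], as_index=False)["effect"].mean()
    merged = eff.merge(
        cdns_results[["gene_a", "gene_b", "cdns"]].drop_duplicates(["gene_a", "gene_b"]),
        on=["gene_a", "gene_b"],
        how="inner",
    )
    if merged.empty:
        return CategorizeResult(merged, float("nan"), float("nan"))
    merged["category"] = [
        _category(e, c) for e, c in zip(merged["effect"], merged["cdns"])
    ]
    ok = merged[["effect", "cdns"]].apply(pd.to_numeric).dropna()
    if len(ok) >= 3:
        r, p = stats.pearsonr(ok["effect"], ok["cdns"])
    else:
        r, p = float("nan"), float("nan")
    return CategorizeResult(merged, float(r), float(p))


OG_TSG_VALUES = ("OG", "TSG", "both", "unknown")


def annotate_og_tsg(
    pairs: pd.DataFrame,
    annotation: Mapping[str, str],
) -> pd.DataFrame:
    """Contingency counts of pair categories × oncogene/TSG composition.

    ``pairs`` needs ``gene_a``, ``gene_b`` and ``category`` columns.
    Pair composition is unordered: (OG, TSG) and (TSG, OG) both count as
    OG-TSG; any unannotated gene puts the pair in the ``unknown`` bucket.
    """

    def _pair_kind(a: str, b: str) -> str:
        ka = annotation.get(a, "unknown")
        kb = annotation.get(b, "unknown")
        if ka not in OG_TSG_VALUES or kb not in OG_TSG_VALUES:
            raise ValueError(f"annotation values must be in {OG_TSG_VALUES}")
        if "unknown" in (ka, kb):
            return "unknown"
        kinds = {ka, kb}
        if kinds == {"OG"} or kinds == {"OG", "both"}:
            return "OG-OG"
        if kinds == {"TSG"} or kinds == {"TSG", "both"}:
            return "TSG-TSG"
        if kinds == {"both"}:
            return "OG-TSG"
        return "OG-TSG"

    rows = []
    for r in pairs.itertuples():
        if r.category is None or (isinstance(r.category, float) and math.isnan(r.category)):
            continue
        rows.append({"category": r.category, "pair_kind": _pair_kind(r.gene_a, r.gene_b)})
    if not rows:
        return pd.DataFrame(columns=["category", "pair_kind", "count"])
    df = pd.DataFrame(rows)
    return df.groupby(["category", "pair_kind"]).size().reset_index(name="count")
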