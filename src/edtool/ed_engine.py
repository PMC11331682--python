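"""Context-stratified dN/dS and the cdNS score for gene pairs.

A cohort is split into genomes with and without non-silent mutations in a
context gene (gene A). The partner gene's (gene B) dN/dS is estimated in
both arms, each with its own synonymous calibration, and combined as
cdNS = log2(omega_plus / omega_minus). Significance comes from label
permutation (and from a sample-size-corrected one-sided Fisher test for
pan-cancer antagonistic pairs); pairs are then filtered into SYN/ANT calls.

The permutation engine is fully vectorised: per-sample count vectors are
precomputed once, so each permutation is a single matrix product.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dnds_core import (
    CLS_MIS,
    CLS_NON,
    CLS_SPL,
    CLS_SYN,
    OpportunityTable,
    _N_CATEGORIES,
)
from .io_formats import (
    Cohort,
    ImpactClass,
    INDEL_CLASSES,
    NON_SILENT_CLASSES,
    TRUNCATING_CLASSES,
)

logger = logging.getLogger(__name__)

IMPACT_CLASS_SETS: dict[str, frozenset[str]] = {
    "missense": frozenset({ImpactClass.MISSENSE.value}),
    "truncating": frozenset(TRUNCATING_CLASSES),
    "indel": frozenset(INDEL_CLASSES),
}
_SUBSTITUTION_COLUMNS = {"missense": (CLS_MIS,), "truncating": (CLS_NON, CLS_SPL)}


@dataclass
class MutationContext:
    """Partition of a roster by non-silent mutation status of a context gene."""

    context_gene: str
    positive_samples: set[str]
    negative_samples: set[str]

    @property
    def n_pos(self) -> int:
        return len(self.positive_samples)

    @property
    def n_neg(self) -> int:
        return len(self.negative_samples)


def split_by_context(
    cohort: Cohort,
    gene_a: str,
    non_silent_classes: Iterable[str] = NON_SILENT_CLASSES,
) -> MutationContext:
    """Split the roster into context-positive/-negative genomes for gene A."""
    rec = cohort.records
    hit = rec[(rec["gene"] == gene_a) & rec["impact_class"].isin(set(non_silent_classes))]
    positive = set(hit["sample_id"])
    roster = set(cohort.sample_ids)
    positive &= roster
    if not positive:
        logger.warning("split_by_context: %s has no non-silent mutations", gene_a)
    return MutationContext(gene_a, positive, roster - positive)


def cdns_score(dnds_plus: float, dnds_minus: float) -> float:
    """log2 ratio of the two context-stratified dN/dS values.

    Returns NaN when either input is zero or not finite (undefined score).
    """
    if dnds_plus is None or dnds_minus is None:
        return float("nan")
    if not (math.isfinite(dnds_plus) and math.isfinite(dnds_minus)):
        return float("nan")
    if dnds_plus <= 0 or dnds_minus <= 0:
        return float("nan")
    return math.log2(dnds_plus / dnds_minus)


# ---------------------------------------------------------------------------
# Vectorised evaluator
# ---------------------------------------------------------------------------


class CdnsEvaluator:
    """Precomputed per-sample count vectors for fast context-stratified dN/dS.

    For substitution classes, omega on a subset with indicator ``m`` is

        omega = (b . m) / sum_c (S . m)_c * opp_B[c] / syn_opp[c]

    where ``b`` is the per-sample gene-B class count, ``S`` the per-sample
    panel synonymous counts per rate category and ``syn_opp`` the panel
    synonymous opportunity — i.e. each subset gets its own synonymous
    calibration (subset-size factors cancel). For indels the expected count
    is the pooled background indel count scaled by CDS-length share.
    """

    def __init__(
        self,
        cohort: Cohort,
        tables: Mapping[str, OpportunityTable],
        granularity: str = "uniform",
        indel_background_exclude: Iterable[str] = (),
        non_silent_classes: Iterable[str] = NON_SILENT_CLASSES,
    ) -> None:
        self.cohort = cohort
        self.tables = dict(tables)
        self.granularity = granularity
        self.non_silent_classes = frozenset(non_silent_classes)
        self.sample_ids = cohort.sample_ids
        self.n = len(self.sample_ids)
        self._sample_index = {s: i for i, s in enumerate(self.sample_ids)}
        self._indel_exclude = set(indel_background_exclude)
        n_cat = _N_CATEGORIES[granularity]

        rec = cohort.records
        self._rec_sample_idx = rec["sample_id"].map(self._sample_index).to_numpy(np.int64)

        # per-sample synonymous counts per category over the gene panel
        self.S = np.zeros((self.n, n_cat), dtype=np.float64)
        syn = rec[
            (rec["impact_class"] == ImpactClass.SYNONYMOUS.value) & rec["gene"].isin(self.tables)
        ]
        if granularity == "uniform":
            idx = syn["sample_id"].map(self._sample_index).to_numpy(np.int64)
            np.add.at(self.S, (idx, np.zeros(len(idx), dtype=np.int64)), 1.0)
        else:
            from .dnds_core import _BASE_INDEX

            for gene, sub in syn.groupby("gene"):
                table = self.tables[gene]
                pos = pd.to_numeric(sub["position"], errors="coerce")
                alt = sub["alt_allele"].map(_BASE_INDEX)
                ok = (pos.notna() & alt.notna()).to_numpy()
                if not ok.all():
                    raise ValueError(
                        f"gene {gene}: synonymous records lack position/alt for "
                        f"granularity {granularity!r}"
                    )
                cats = table.category_of(pos.to_numpy(np.int64), alt.to_numpy(np.int64))
                idx = sub["sample_id"].map(self._sample_index).to_numpy(np.int64)
                np.add.at(self.S, (idx, cats), 1.0)
        self.syn_opp = np.sum([t.counts[:, CLS_SYN] for t in self.tables.values()], axis=0)

        self._b_cache: dict[tuple[str, str], np.ndarray] = {}
        self._bg_cache: dict[str, tuple[np.ndarray, float]] = {}
        self._ctx_cache: dict[str, np.ndarray] = {}

    # -- per-sample vectors ------------------------------------------------
    def gene_class_counts(self, gene: str, impact_class: str) -> np.ndarray:
        key = (gene, impact_class)
        if key not in self._b_cache:
            rec = self.cohort.records
            sel = (rec["gene"] == gene) & rec["impact_class"].isin(
                IMPACT_CLASS_SETS[impact_class]
            )
            b = np.zeros(self.n, dtype=np.float64)
            idx = self._rec_sample_idx[sel.to_numpy()]
            np.add.at(b, idx, 1.0)
            self._b_cache[key] = b
        return self._b_cache[key]

    def indel_background(self, gene_b: str) -> tuple[np.ndarray, float]:
        """Pooled background indel counts per sample and the length ratio L_B/L_bg."""
        if gene_b not in self._bg_cache:
            bg_genes = [
                g for g in self.tables if g != gene_b and g not in self._indel_exclude
            ]
            if not bg_genes:
                raise ValueError("indel background panel is empty")
            rec = self.cohort.records
            sel = rec["impact_class"].isin(INDEL_CLASSES) & rec["gene"].isin(bg_genes)
            bg = np.zeros(self.n, dtype=np.float64)
            np.add.at(bg, self._rec_sample_idx[sel.to_numpy()], 1.0)
            L_b = float(self.tables[gene_b].cds_length)
            L_bg = float(sum(self.tables[g].cds_length for g in bg_genes))
            self._bg_cache[gene_b] = (bg, L_b / L_bg)
        return self._bg_cache[gene_b]

    def context_mask(self, gene_a: str) -> np.ndarray:
        if gene_a not in self._ctx_cache:
            ctx = split_by_context(self.cohort, gene_a, self.non_silent_classes)
            mask = np.zeros(self.n, dtype=bool)
            for s in ctx.positive_samples:
                mask[self._sample_index[s]] = True
            self._ctx_cache[gene_a] = mask
        return self._ctx_cache[gene_a]

    def _weights(self, gene_b: str, impact_class: str) -> np.ndarray:
        """opp_B[c] / syn_opp[c] with zero-opportunity categories dropped."""
        table = self.tables[gene_b]
        opp = table.counts[:, list(_SUBSTITUTION_COLUMNS[impact_class])].sum(axis=1)
        w = np.zeros_like(opp)
        mask = self.syn_opp > 0
        w[mask] = opp[mask] / self.syn_opp[mask]
        return w

    # -- omega / cdns ------------------------------------------------------
    def omega(self, mask: np.ndarray, gene_b: str, impact_class: str) -> float:
        """dN/dS (or indel ratio) of gene B on the masked subset; NaN if undefined."""
        b = self.gene_class_counts(gene_b, impact_class)
        n_obs = float(b[mask].sum())
        if impact_class == "indel":
            bg, ratio = self.indel_background(gene_b)
            n_exp = float(bg[mask].sum()) * ratio
        else:
            w = self._weights(gene_b, impact_class)
            n_exp = float(self.S[mask].sum(axis=0) @ w)
        if n_exp <= 0:
            return float("nan")
        return n_obs / n_exp

    def pair_cdns(self, gene_a: str, gene_b: str, impact_class: str) -> dict:
        mask = self.context_mask(gene_a)
        omega_plus = self.omega(mask, gene_b, impact_class)
        omega_minus = self.omega(~mask, gene_b, impact_class)
        b = self.gene_class_counts(gene_b, impact_class)
        return {
            "dnds_plus": omega_plus,
            "dnds_minus": omega_minus,
            "cdns": cdns_score(omega_plus, omega_minus),
            "n_mut_plus": int(b[mask].sum()),
            "n_mut_minus": int(b[~mask].sum()),
            "n_pos": int(mask.sum()),
            "n_neg": int((~mask).sum()),
        }

    def permuted_cdns(
        self,
        gene_b: str,
        impact_class: str,
        n_pos: int,
        n_perm: int,
        rng: np.random.Generator,
    ) -> np.ndarray:
        """cdNS for ``n_perm`` random context+ label sets of size ``n_pos``.

        Undefined permutation scores come back as NaN.
        """
        b = self.gene_class_counts(gene_b, impact_class)
        if impact_class == "indel":
            bg, ratio = self.indel_background(gene_b)
            D = np.column_stack([b, bg])
        else:
            w = self._weights(gene_b, impact_class)
            D = np.column_stack([b, self.S @ w])
        order = np.argsort(rng.random((n_perm, self.n)), axis=1)
        M = np.zeros((n_perm, self.n), dtype=np.float64)
        np.put_along_axis(M, order[:, :n_pos], 1.0, axis=1)
        plus = M @ D
        totals = D.sum(axis=0)
        minus = totals[None, :] - plus
        if impact_class == "indel":
            e_plus = plus[:, 1] * ratio
            e_minus = minus[:, 1] * ratio
        else:
            e_plus = plus[:, 1]
            e_minus = minus[:, 1]
        with np.errstate(divide="ignore", invalid="ignore"):
            om_p = np.where(e_plus > 0, plus[:, 0] / e_plus, np.nan)
            om_m = np.where(e_minus > 0, minus[:, 0] / e_minus, np.nan)
            out = np.where((om_p > 0) & (om_m > 0), np.log2(om_p / om_m), np.nan)
        return out


# ---------------------------------------------------------------------------
# Permutation test
# ---------------------------------------------------------------------------


@dataclass
class PermutationResult:
    p: float
    observed_cdns: float
    null_cdns: np.ndarray
    n_undefined: int
    direction: int  # +1 tested upper tail, -1 lower tail


def permutation_p(
    observed: float,
    null_cdns: np.ndarray,
    n_perm: int,
    alternative: str = "directional",
) -> tuple[float, int, int]:
    """Add-one permutation p. Undefined (NaN) permutation scores count as
    non-exceeding.

    ``alternative``:
      - ``directional`` (default): one-sided in the direction of the observed
        sign — rejects at roughly twice the nominal rate under the null;
      - ``greater``: frequency with which permuted scores are >= the observed
        score (uniform under the null);
      - ``less``: lower-tail analogue;
      - ``two_sided``: twice the smaller tail, capped at 1.
    """
    finite = null_cdns[np.isfinite(null_cdns)]
    n_undef = len(null_cdns) - len(finite)
    upper = (1.0 + int(np.sum(finite >= observed))) / (n_perm + 1.0)
    lower = (1.0 + int(np.sum(finite <= observed))) / (n_perm + 1.0)
    direction = 1 if observed >= 0 else -1
    if alternative == "directional":
        p = upper if direction > 0 else lower
    elif alternative == "greater":
        p = upper
    elif alternative == "less":
        p = lower
    elif alternative == "two_sided":
        p = min(1.0, 2.0 * min(upper, lower))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return p, direction, n_undef


def permutation_test(
    cohort: Cohort,
    gene_a: str,
    gene_b: str,
    impact_class: str,
    n_perm: int = 1000,
    seed: int | None = None,
    *,
    tables: Mapping[str, OpportunityTable],
    granularity: str = "uniform",
    evaluator: CdnsEvaluator | None = None,
    rng: np.random.Generator | None = None,
    alternative: str = "directional",
) -> PermutationResult:
    """Shuffle context labels (fixed context+ size) and recompute cdNS.

    With the default alternative,
    p = (1 + #{permuted cdNS at least as extreme, same direction}) / (n_perm + 1).
    Deterministic given ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    ev = evaluator or CdnsEvaluator(cohort, tables, granularity)
    obs = ev.pair_cdns(gene_a, gene_b, impact_class)
    if not math.isfinite(obs["cdns"]):
        raise ValueError(
            f"observed cdNS for ({gene_a}, {gene_b}, {impact_class}) is undefined"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    null = ev.permuted_cdns(gene_b, impact_class, obs["n_pos"], n_perm, rng)
    p, direction, n_undef = permutation_p(obs["cdns"], null, n_perm, alternative)
    return PermutationResult(p, obs["cdns"], null, n_undef, direction)


# ---------------------------------------------------------------------------
# Sample-size correction + Fisher test for pan-cancer ANT pairs
# ---------------------------------------------------------------------------


@dataclass
class SigmoidParams:
    """Logistic curve for the sample-size correction factor w.

    ``w = 1 / (1 + exp(-slope * (f - midpoint)))`` with f the
    context-positive fraction. ``force_w`` overrides the curve entirely
    (``force_w=1`` disables the correction).
    """

    midpoint: float = 0.05
    slope: float = 50.0
    force_w: float | None = None


@dataclass
class CorrectionParams:
    w: float
    n_pos: int
    n_neg: int
    corrected_n: float

    def __post_init__(self) -> None:
        if not (0.0 < self.w <= 1.0):
            raise ValueError("w must be in (0, 1]")


def sample_size_correction(
    n_pos: int, n_neg: int, params: SigmoidParams | None = None
) -> CorrectionParams:
    """Shrink the mutation-negative genome count by a logistic factor w."""
    if n_pos < 0 or n_neg < 0:
        raise ValueError("group sizes must be non-negative")
    if n_pos + n_neg == 0:
        raise ValueError("empty cohort")
    params = params or SigmoidParams()
    if params.force_w is not None:
        w = params.force_w
    else:
        f = n_pos / (n_pos + n_neg)
        w = 1.0 / (1.0 + math.exp(-params.slope * (f - params.midpoint)))
    return CorrectionParams(w=w, n_pos=n_pos, n_neg=n_neg, corrected_n=n_pos + w * n_neg)


def fisher_ant_from_counts(
    n_pos_mut: int, n_pos: int, n_neg_mut: int, n_neg: int, w: float = 1.0
) -> float:
    """One-sided Fisher P for depletion of double mutants on the w-corrected table.

    The context-negative row is rescaled by w and rounded; the observed
    double-positive cell is untouched. Returns NaN when a margin is zero.
    """
    a = n_pos_mut
    b = n_pos - n_pos_mut
    c = int(round(w * n_neg_mut))
    d = int(round(w * (n_neg - n_neg_mut)))
    table = np.array([[a, b], [c, d]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return float("nan")
    return float(stats.fisher_exact(table, alternative="less")[1])


def fisher_ant_test(
    cohort: Cohort,
    gene_a: str,
    gene_b: str,
    correction: CorrectionParams | None = None,
    impact_class: str | None = None,
    sigmoid: SigmoidParams | None = None,
) -> float:
    """Corrected Fisher test of context status vs gene-B mutation status.

    Gene B counts as mutated in a genome when it carries a mutation of
    ``impact_class`` (or any non-silent mutation when ``impact_class`` is
    None).
    """
    ctx = split_by_context(cohort, gene_a)
    rec = cohort.records
    classes = (
        IMPACT_CLASS_SETS[impact_class] if impact_class is not None else NON_SILENT_CLASSES
    )
    b_samples = set(
        rec[(rec["gene"] == gene_b) & rec["impact_class"].isin(classes)]["sample_id"]
    )
    n_pos_mut = len(ctx.positive_samples & b_samples)
    n_neg_mut = len(ctx.negative_samples & b_samples)
    if correction is None:
        correction = sample_size_correction(ctx.n_pos, ctx.n_neg, sigmoid)
    return fisher_ant_from_counts(
        n_pos_mut, ctx.n_pos, n_neg_mut, ctx.n_neg, correction.w
    )


# ---------------------------------------------------------------------------
# Pair calling
# ---------------------------------------------------------------------------


@dataclass
class PairThresholds:
    """Filters applied when calling SYN/ANT pairs."""

    p_value: float = 0.01
    min_mut_syn: int = 3
    min_mut_ant: int = 1
    ratio_hi: float = 3.0
    ratio_lo: float = 0.3


@dataclass
class CdnsResult:
    """One (context gene, partner gene, impact class) evaluation."""

    gene_a: str
    gene_b: str
    impact_class: str
    dnds_plus: float
    dnds_minus: float
    cdns: float
    ed_ratio: float
    n_mut_plus: int
    n_mut_minus: int
    p_perm: float
    p_fisher: float | None
    call: str  # SYN | ANT | not_significant | undefined
    n_pos: int = 0
    n_neg: int = 0
    reason: str = ""


RESULT_COLUMNS = [
    "gene_a",
    "gene_b",
    "impact_class",
    "dnds_plus",
    "dnds_minus",
    "cdns",
    "ed_ratio",
    "n_mut_plus",
    "n_mut_minus",
    "p_perm",
    "p_fisher",
    "call",
    "n_pos",
    "n_neg",
    "reason",
]


def results_to_frame(results: Sequence[CdnsResult]) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in results], columns=RESULT_COLUMNS)
    for col in ("dnds_plus", "dnds_minus", "cdns", "ed_ratio", "p_perm", "p_fisher"):
        df[col] = pd.to_numeric(df[col])
    return df


def _apply_filters(r: CdnsResult, mode: str, th: PairThresholds) -> str:
    if not math.isfinite(r.cdns):
        return "undefined"
    is_syn = r.cdns > 0
    p = r.p_perm
    if mode == "pancancer" and not is_syn:
        p = r.p_fisher if r.p_fisher is not None else float("nan")
    if not (math.isfinite(p) and p < th.p_value):
        return "not_significant"
    min_mut = th.min_mut_syn if is_syn else th.min_mut_ant
    if r.n_mut_plus < min_mut:
        return "not_significant"
    if not (r.ed_ratio > th.ratio_hi or r.ed_ratio < th.ratio_lo):
        return "not_significant"
    return "SYN" if is_syn else "ANT"


def call_pairs(
    cohort: Cohort,
    tables: Mapping[str, OpportunityTable],
    context_genes: Sequence[str],
    partner_genes: Sequence[str],
    mode: str = "pancancer",
    impact_classes: Sequence[str] = ("missense", "truncating", "indel"),
    n_perm: int = 1000,
    seed: int = 0,
    thresholds: PairThresholds | None = None,
    granularity: str = "uniform",
    sigmoid: SigmoidParams | None = None,
    evaluator: CdnsEvaluator | None = None,
) -> pd.DataFrame:
    """Evaluate all ordered (context, partner) pairs × impact classes.

    Significance uses the permutation test, except pan-cancer ANT pairs
    which use the sample-size-corrected Fisher test. Retained pairs must
    pass the minimum-mutation filter (SYN >= min_mut_syn, ANT >= min_mut_ant
    gene-B mutations in the context+ arm) and the ED-ratio filter
    (ratio > ratio_hi or < ratio_lo).
    """
    if mode not in ("pancancer", "tumor_type"):
        raise ValueError("mode must be 'pancancer' or 'tumor_type'")
    th = thresholds or PairThresholds()
    ev = evaluator or CdnsEvaluator(
        cohort, tables, granularity, indel_background_exclude=set(context_genes)
    )
    rng = np.random.default_rng(seed)
    results: list[CdnsResult] = []
    for gene_a in context_genes:
        mask = ev.context_mask(gene_a)
        n_pos = int(mask.sum())
        n_neg = ev.n - n_pos
        for gene_b in partner_genes:
            if gene_b == gene_a:
                continue
            for impact_class in impact_classes:
                obs = ev.pair_cdns(gene_a, gene_b, impact_class)
                cdns = obs["cdns"]
                ratio = (
                    obs["dnds_plus"] / obs["dnds_minus"]
                    if obs["dnds_minus"] and math.isfinite(obs["dnds_minus"]) and obs["dnds_minus"] > 0
                    else float("nan")
                )
                p_perm = float("nan")
                n_undef = 0
                if math.isfinite(cdns) and n_pos > 0 and n_neg > 0:
                    null = ev.permuted_cdns(gene_b, impact_class, n_pos, n_perm, rng)
                    p_perm, _, n_undef = permutation_p(cdns, null, n_perm)
                p_fisher = None
                if mode == "pancancer" and (not math.isfinite(cdns) or cdns < 0):
                    rec = cohort.records
                    classes = IMPACT_CLASS_SETS[impact_class]
                    sel = (rec["gene"] == gene_b) & rec["impact_class"].isin(classes)
                    b_mask = np.zeros(ev.n, dtype=bool)
                    b_mask[ev._rec_sample_idx[sel.to_numpy()]] = True
                    corr = sample_size_correction(n_pos, n_neg, sigmoid)
                    p_fisher = fisher_ant_from_counts(
                        int((b_mask & mask).sum()), n_pos,
                        int((b_mask & ~mask).sum()), n_neg, corr.w,
                    )
                r = CdnsResult(
                    gene_a=gene_a,
                    gene_b=gene_b,
                    impact_class=impact_class,
                    dnds_plus=obs["dnds_plus"],
                    dnds_minus=obs["dnds_minus"],
                    cdns=cdns,
                    ed_ratio=ratio,
                    n_mut_plus=obs["n_mut_plus"],
                    n_mut_minus=obs["n_mut_minus"],
                    p_perm=p_perm,
                    p_fisher=p_fisher,
                    call="",
                    n_pos=n_pos,
                    n_neg=n_neg,
                )
                r.call = _apply_filters(r, mode, th)
                if r.call == "undefined":
                    r.reason = "omega zero or undefined in one arm"
                results.append(r)
    return results_to_frame(results)


def subsample_stability(
    cohort: Cohort,
    tables: Mapping[str, OpportunityTable],
    gene_a: str,
    gene_b: str,
    impact_class: str,
    sizes: Sequence[int],
    reps: int = 100,
    seed: int = 0,
    granularity: str = "uniform",
) -> pd.DataFrame:
    """Subsample context+ genomes and recompute cdNS against the full context−.

    Returns one row per (size, rep) with the recomputed dnds_plus, cdNS and
    the gene-B mutation count inside the subsample.
    """
    ev = CdnsEvaluator(cohort, tables, granularity, indel_background_exclude={gene_a})
    mask = ev.context_mask(gene_a)
    pos_idx = np.flatnonzero(mask)
    if max(sizes) > len(pos_idx):
        raise ValueError(
            f"requested subsample size {max(sizes)} exceeds the {len(pos_idx)} "
            "available context+ genomes"
        )
    omega_minus = ev.omega(~mask, gene_b, impact_class)
    b = ev.gene_class_counts(gene_b, impact_class)
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        for rep in range(reps):
            sub = rng.choice(pos_idx, size=size, replace=False)
            m = np.zeros(ev.n, dtype=bool)
            m[sub] = True
            om_p = ev.omega(m, gene_b, impact_class)
            rows.append(
                {
                    "size": size,
                    "rep": rep,
                    "dnds_plus": om_p,
                    "dnds_minus": omega_minus,
                    "cdns": cdns_score(om_p, omega_minus),
                    "n_mut_plus": int(b[m].sum()),
                }
            )
    return pd.DataFrame(rows)
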