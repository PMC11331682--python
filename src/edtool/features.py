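"""Mutation-level features of called gene pairs: ΔVAF, ΔTMB, pathway z-scores.

ΔVAF contrasts the clonality (variant allele frequency) of the partner gene
against the context gene; ΔTMB contrasts the mutation burden of double-mutant
genomes against singleton-mutant genomes. Both come with gene-shuffled
permutation baselines. Pathway concordance counts gene-set co-membership and
z-normalises it against size-preserving random gene sets.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import Cohort, MutationRecord, NON_SILENT_CLASSES

logger = logging.getLogger(__name__)


def compute_vaf(record: MutationRecord) -> float:
    """alt / (alt + ref); NaN at zero depth (record should then be skipped)."""
    depth = record.t_alt_count + record.t_ref_count
    if depth <= 0:
        return float("nan")
    return record.t_alt_count / depth


def _vaf_series(cohort: Cohort, gene: str) -> np.ndarray:
    cached = getattr(cohort, "_vaf_cache", None)
    if cached is None:
        cached = {}
        for g, sub in cohort.non_silent().groupby("gene"):
            depth = sub["t_alt_count"].to_numpy(float) + sub["t_ref_count"].to_numpy(float)
            ok = depth > 0
            n_skipped = int((~ok).sum())
            if n_skipped:
                logger.debug("gene %s: %d zero-depth records skipped for VAF", g, n_skipped)
            cached[g] = sub["t_alt_count"].to_numpy(float)[ok] / depth[ok]
        cohort._vaf_cache = cached
    return cached.get(gene, np.empty(0))


def delta_vaf(pair: tuple[str, str], cohort: Cohort) -> float:
    """median VAF(gene B non-silent mutations) − median VAF(gene A).

    NaN when either gene has no VAF-evaluable mutation.
    """
    gene_a, gene_b = pair[0], pair[1]
    vaf_a = _vaf_series(cohort, gene_a)
    vaf_b = _vaf_series(cohort, gene_b)
    if len(vaf_a) == 0 or len(vaf_b) == 0:
        return float("nan")
    return float(np.median(vaf_b) - np.median(vaf_a))


def _tmb_per_sample(cohort: Cohort) -> pd.Series:
    # cached: cohorts are treated as immutable once built
    cached = getattr(cohort, "_tmb_cache", None)
    if cached is None:
        ns = cohort.non_silent()
        counts = ns.groupby("sample_id").size()
        cached = counts.reindex(cohort.sample_ids, fill_value=0)
        cohort._tmb_cache = cached
    return cached


def _mutated_samples(cohort: Cohort, gene: str) -> set[str]:
    cached = getattr(cohort, "_mutated_cache", None)
    if cached is None:
        ns = cohort.non_silent()
        cached = {g: set(sub["sample_id"]) for g, sub in ns.groupby("gene")}
        cohort._mutated_cache = cached
    return cached.get(gene, set())


@dataclass
class DeltaTmb:
    log10: float
    raw: float
    n_double: int
    n_single: int


def delta_tmb(pair: tuple[str, str], cohort: Cohort, summary: str = "median") -> DeltaTmb:
    """Burden contrast: genomes mutated in both genes vs in exactly one.

    Reported both as log10(median TMB double) − log10(median TMB single)
    and as the raw difference of the group summaries.
    """
    gene_a, gene_b = pair[0], pair[1]
    in_a = _mutated_samples(cohort, gene_a)
    in_b = _mutated_samples(cohort, gene_b)
    double = in_a & in_b
    single = (in_a | in_b) - double
    tmb = _tmb_per_sample(cohort)
    agg = np.median if summary == "median" else np.mean
    if not double or not single:
        return DeltaTmb(float("nan"), float("nan"), len(double), len(single))
    t_double = float(agg(tmb.loc[sorted(double)].to_numpy(float)))
    t_single = float(agg(tmb.loc[sorted(single)].to_numpy(float)))
    log10 = (
        math.log10(t_double) - math.log10(t_single)
        if t_double > 0 and t_single > 0
        else float("nan")
    )
    return DeltaTmb(log10, t_double - t_single, len(double), len(single))


@dataclass
class BaselineResult:
    """Gene-shuffled null for a pair statistic plus group-vs-null t-tests."""

    statistic: str
    observed: pd.DataFrame  # columns: gene_a, gene_b, call, value
    null_values: np.ndarray
    t_syn: float
    p_syn: float
    t_ant: float
    p_ant: float


def _pair_statistic(statistic: str, pair: tuple[str, str], cohort: Cohort) -> float:
    if statistic == "delta_vaf":
        return delta_vaf(pair, cohort)
    if statistic == "delta_tmb":
        return delta_tmb(pair, cohort).log10
    raise ValueError("statistic must be 'delta_vaf' or 'delta_tmb'")


def permuted_baseline(
    pairs: pd.DataFrame,
    cohort: Cohort,
    statistic: str = "delta_vaf",
    n_perm: int = 100,
    seed: int = 0,
) -> BaselineResult:
    """Shuffle genes across the pair list and recompute the statistic.

    ``pairs`` needs ``gene_a``, ``gene_b`` and ``call`` columns. The shuffle
    preserves the gene multiset and list length; self-pairs are redrawn.
    Observed SYN and ANT groups are each compared to the pooled null with a
    two-sample t-test.
    """
    if len(pairs) < 2:
        raise ValueError("need at least two pairs to permute")
    rng = np.random.default_rng(seed)
    observed = pairs.copy()
    observed["value"] = [
        _pair_statistic(statistic, (r.gene_a, r.gene_b), cohort)
        for r in pairs.itertuples()
    ]

    genes = list(pairs["gene_a"]) + list(pairs["gene_b"])
    n_pairs = len(pairs)
    null_vals: list[float] = []
    for _ in range(n_perm):
        for _attempt in range(100):
            perm = rng.permutation(genes)
            pa, pb = perm[:n_pairs], perm[n_pairs:]
            if (pa != pb).all():
                break
        else:  # give up on avoiding self-pairs; drop them instead
            keep = pa != pb
            pa, pb = pa[keep], pb[keep]
        for a, b in zip(pa, pb):
            null_vals.append(_pair_statistic(statistic, (a, b), cohort))
    null = np.asarray(null_vals, dtype=float)
    null_finite = null[np.isfinite(null)]

    def _test(group: str) -> tuple[float, float]:
        vals = observed.loc[observed["call"] == group, "value"].to_numpy(float)
        vals = vals[np.isfinite(vals)]
        if len(vals) < 2 or len(null_finite) < 2:
            return float("nan"), float("nan")
        if np.std(vals) == 0 and np.std(null_finite) == 0:
            return float("nan"), float("nan")
        with warnings.catch_warnings():
            # constant groups trigger a scipy precision warning; the Welch
            # statistic is still well-defined there
            warnings.simplefilter("ignore", RuntimeWarning)
            t, p = stats.ttest_ind(vals, null_finite, equal_var=False)
        return float(t), float(p)

    t_syn, p_syn = _test("SYN")
    t_ant, p_ant = _test("ANT")
    return BaselineResult(statistic, observed, null, t_syn, p_syn, t_ant, p_ant)


def pathway_concordance(
    pair: tuple[str, str],
    gene_sets: Mapping[str, Iterable[str]],
    n_perm: int = 1000,
    seed: int = 0,
    universe: Sequence[str] | None = None,
) -> float:
    """z-score for how often both genes co-occur across gene sets.

    The null reassigns genes uniformly from the universe while preserving
    each set's size. NaN when the permutation spread is zero.
    """
    gene_a, gene_b = pair[0], pair[1]
    sets = {name: set(g) for name, g in gene_sets.items()}
    if universe is None:
        universe = sorted(set().union(*sets.values()))
    universe = list(universe)
    if gene_a not in universe or gene_b not in universe:
        raise ValueError("both genes must be in the gene-set universe")
    obs = sum(1 for s in sets.values() if gene_a in s and gene_b in s)

    rng = np.random.default_rng(seed)
    sizes = [min(len(s), len(universe)) for s in sets.values()]
    null = np.empty(n_perm, dtype=float)
    uni = np.asarray(universe, dtype=object)
    for i in range(n_perm):
        count = 0
        for size in sizes:
            members = uni[rng.choice(len(uni), size=size, replace=False)]
            if gene_a in members and gene_b in members:
                count += 1
        null[i] = count
    sd = float(null.std(ddof=0))
    if sd == 0:
        return float("nan")
    return (obs - float(null.mean())) / sd


def pair_features(
    pairs: pd.DataFrame,
    cohort: Cohort,
    gene_sets: Mapping[str, Iterable[str]] | None = None,
    n_perm_pathway: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-pair ΔVAF, ΔTMB (and pathway z when gene sets are given)."""
    rows = []
    for r in pairs.itertuples():
        pair = (r.gene_a, r.gene_b)
        dt = delta_tmb(pair, cohort)
        row = {
            "gene_a": r.gene_a,
            "gene_b": r.gene_b,
            "call": getattr(r, "call", ""),
            "delta_vaf": delta_vaf(pair, cohort),
            "delta_tmb_log10": dt.log10,
            "delta_tmb_raw": dt.raw,
        }
        if gene_sets is not None:
            try:
                row["pathway_z"] = pathway_concordance(
                    pair, gene_sets, n_perm=n_perm_pathway, seed=seed
                )
            except ValueError:
                row["pathway_z"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
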