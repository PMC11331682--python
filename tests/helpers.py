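"""Independent oracles used to cross-check the engine implementations.

Everything here is deliberately naive (string slicing, direct enumeration,
exhaustive summation) and shares no code path with the package internals.
"""

from __future__ import annotations

import itertools
import math

from Bio.Seq import Seq

BASES = "ACGT"


def brute_force_site_classes(cds: str) -> list[tuple[int, str, str]]:
    """Classify all 3L substitutions by translating full mutated codons.

    Returns (1-based position, alt base, class) with class in
    {synonymous, missense, nonsense}; stop-preserving changes in the terminal
    stop codon are synonymous, stop-losing ones missense.
    """
    out = []
    for i in range(len(cds)):
        codon_start = (i // 3) * 3
        codon = cds[codon_start : codon_start + 3]
        aa_ref = str(Seq(codon).translate())
        for alt in BASES:
            if alt == cds[i]:
                continue
            mut = codon[: i - codon_start] + alt + codon[i - codon_start + 1 :]
            aa_mut = str(Seq(mut).translate())
            if aa_mut == aa_ref:
                cls = "synonymous"
            elif aa_mut == "*":
                cls = "nonsense"
            else:
                cls = "missense"
            out.append((i + 1, alt, cls))
    return out


def brute_force_opportunity(cds: str) -> dict[str, int]:
    counts = {"synonymous": 0, "missense": 0, "nonsense": 0}
    for _, _, cls in brute_force_site_classes(cds):
        counts[cls] += 1
    return counts


def closed_form_dnds(n_nonsyn: float, opp_nonsyn: float, n_syn: float, opp_syn: float) -> float:
    """(n_N / L_N) / (n_S / L_S)."""
    return (n_nonsyn / opp_nonsyn) / (n_syn / opp_syn)


def hypergeom_depletion_p(a: int, b: int, c: int, d: int) -> float:
    """P(X <= a) for X ~ Hypergeom: direct summation over the lower tail."""
    n_total = a + b + c + d
    col1 = a + c  # total mutated
    row1 = a + b  # context positive
    denom = math.comb(n_total, row1)
    p = 0.0
    for x in range(0, a + 1):
        if x > col1 or row1 - x > n_total - col1:
            continue
        p += math.comb(col1, x) * math.comb(n_total - col1, row1 - x) / denom
    return p


def exhaustive_permutation_p(values_b, values_e, n_pos: int, observed: float) -> float:
    """Exact one-sided label-shuffle p over all context+ assignments.

    ``values_b``/``values_e`` are per-sample gene-B class counts and
    per-sample calibration counts (synonymous totals already weighted, or
    background indels scaled). cdNS per assignment is
    log2((B+/E+)/(B-/E-)); undefined assignments count as non-exceeding.
    """
    n = len(values_b)
    tot_b = sum(values_b)
    tot_e = sum(values_e)
    count = 0
    total = 0
    direction = 1 if observed >= 0 else -1
    for subset in itertools.combinations(range(n), n_pos):
        total += 1
        bp = sum(values_b[i] for i in subset)
        ep = sum(values_e[i] for i in subset)
        bm, em = tot_b - bp, tot_e - ep
        if ep <= 0 or em <= 0 or bp <= 0 or bm <= 0:
            continue
        score = math.log2((bp / ep) / (bm / em))
        if direction > 0 and score >= observed:
            count += 1
        elif direction < 0 and score <= observed:
            count += 1
    return count / total
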