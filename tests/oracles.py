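"""Independent brute-force oracles used by the tests.

These deliberately re-implement counting and statistics with the simplest
possible code paths (explicit Python loops, direct formulas) so they stay
independent of the vectorised implementations they check.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd


def brute_force_mature_counts(alignments: pd.DataFrame, annotations, window: int = 4):
    """O(reads × matures) re-scan of the end-window counting rule.

    Each primary plus-strand read goes to the in-window mature minimising
    |Δ5′| + |Δ3′|, ties to the lexicographically smallest mature_id.
    Returns (counts Series, n_unassigned_window, n_unassigned_reference).
    """
    counts = {m.mature_id: 0 for m in annotations}
    known = {m.precursor_id for m in annotations}
    un_window = 0
    un_ref = 0
    for row in alignments.itertuples(index=False):
        if not row.is_primary or row.strand != "+":
            continue
        if row.precursor_id not in known:
            un_ref += 1
            continue
        candidates = []
        for m in annotations:
            if m.precursor_id != row.precursor_id:
                continue
            d5 = abs(row.aln_start - m.start)
            d3 = abs(row.aln_end - m.end)
            if d5 <= window and d3 <= window:
                candidates.append((d5 + d3, m.mature_id))
        if candidates:
            counts[min(candidates)[1]] += 1
        else:
            un_window += 1
    out = pd.Series(counts, name="count")
    out.index.name = "mature_id"
    return out, un_window, un_ref


def rank_correlation(x, y) -> float:
    """Spearman rho as Pearson correlation of midranks, computed directly."""

    def midranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(len(v), dtype=float)
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = midranks(x), midranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / math.sqrt((rx**2).sum() * (ry**2).sum()))


def brute_force_ks_D(a, b) -> float:
    """sup |F_a − F_b| by scanning every observed value as a threshold."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    best = 0.0
    for t in np.concatenate([a, b]):
        fa = (a <= t).mean()
        fb = (b <= t).mean()
        best = max(best, abs(fa - fb))
    return best


def asymptotic_ks_pvalue(d: float, n1: int, n2: int) -> float:
    """Two-sample asymptotic KS p-value from the Kolmogorov distribution."""
    en = math.sqrt(n1 * n2 / (n1 + n2))
    x = en * d
    # Kolmogorov survival function, truncated series
    return float(min(1.0, 2.0 * sum((-1) ** (k - 1) * math.exp(-2.0 * (k * x) ** 2)
                                    for k in range(1, 101))))


def direct_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios recomputed gene-by-gene with explicit loops.

    At even reference counts the two middle ratios are interpolated
    geometrically (the DESeq2 convention: median taken on the log scale).
    """
    ref = {}
    for gene, row in counts.iterrows():
        vals = row.to_numpy(dtype=float)
        if (vals > 0).all():
            ref[gene] = math.exp(sum(math.log(v) for v in vals) / len(vals))
    if not ref:
        raise ValueError("no all-nonzero gene")
    factors = {}
    for sample in counts.columns:
        ratios = sorted(counts.loc[g, sample] / r for g, r in ref.items())
        k = len(ratios)
        factors[sample] = (
            ratios[k // 2]
            if k % 2
            else math.sqrt(ratios[k // 2 - 1] * ratios[k // 2])
        )
    return pd.Series(factors, name="size_factor")
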