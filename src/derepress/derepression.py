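"""Per-family target de-repression scoring.

The central statistic standardises the mean log2-fold change of a miRNA
family's predicted targets against the rest of the transcriptome:

    Z = (Sm − µ) · m^(1/2) / ∂

where Sm is the mean log2FC over the m expressed predicted targets of the
family and µ, ∂ are the mean and standard deviation of the background
log2FC values.  Under no de-repression, Sm is approximately normal with
mean µ and SD ∂/√m, so Z ~ N(0, 1); a positive Z means the family's targets
are preferentially upregulated — de-repressed — relative to background.

The same target/background split feeds a two-sample Kolmogorov–Smirnov
comparison of the empirical log2FC distributions (the cumulative-distribution
panels that accompany the bubble plot).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError

logger = logging.getLogger(__name__)

DEFAULT_M_MIN = 10

#: fixed column order of the per-family output table
RECORD_COLUMNS = [
    "family_id", "m", "Sm", "mu", "sd", "z",
    "abundance_log10", "ks_D", "ks_p", "ks_p_bh", "status",
]


@dataclass(frozen=True)
class BackgroundStats:
    """Mean, SD (sample SD, n−1) and size of the background log2FC set."""

    mu: float
    sd: float
    n_background: int


@dataclass(frozen=True)
class CdfComparison:
    """Empirical CDFs of target vs background log2FCs and their KS test."""

    target_curve: pd.DataFrame      # columns: x, F
    background_curve: pd.DataFrame  # columns: x, F
    ks_D: float
    ks_p: float
    #: +1 if the targets' CDF is right-shifted (de-repression), −1 if
    #: left-shifted, 0 if the two signed sup-differences tie
    shift_sign: int


def _expressed(fc: pd.DataFrame) -> pd.DataFrame:
    if "expressed" in fc.columns:
        fc = fc[fc["expressed"]]
    if not np.isfinite(fc["log2fc"].to_numpy(dtype=float)).all():
        raise InputError("non-finite log2fc among expressed genes")
    return fc


def background_stats(fc: pd.DataFrame, exclude: set[str] | frozenset[str] = frozenset()) -> BackgroundStats:
    """µ and ∂ over expressed genes outside ``exclude``.

    Raises ``InputError`` for an empty (< 2 genes) or degenerate (∂ = 0)
    background.
    """
    expressed = _expressed(fc)
    bg = expressed.loc[~expressed.index.isin(exclude), "log2fc"].to_numpy(dtype=float)
    if bg.size < 2:
        raise InputError("empty background: fewer than 2 expressed genes outside the target set")
    sd = float(bg.std(ddof=1))
    if sd == 0.0:
        raise InputError("degenerate background: all background log2fc values identical")
    return BackgroundStats(mu=float(bg.mean()), sd=sd, n_background=int(bg.size))


def family_zscore(
    fc: pd.DataFrame, targets: set[str], bg: BackgroundStats
) -> tuple[float, int, float]:
    """(Sm, m, z) for one target set against precomputed background stats.

    Sm is the mean log2FC over the expressed members of ``targets``;
    z = (Sm − µ)·√m/∂.
    """
    expressed = _expressed(fc)
    vals = expressed.loc[expressed.index.isin(targets), "log2fc"].to_numpy(dtype=float)
    m = int(vals.size)
    if m == 0:
        raise InputError("no expressed genes in the target set")
    sm = float(vals.mean())
    z = (sm - bg.mu) * np.sqrt(m) / bg.sd
    return sm, m, float(z)


def cdf_compare(
    fc: pd.DataFrame,
    targets: set[str],
    background: set[str] | None = None,
) -> CdfComparison:
    """Empirical CDFs of target vs background log2FCs plus the KS test.

    ``background`` defaults to all expressed genes outside ``targets``.
    D is the sup-difference of the two empirical CDFs; the p-value is from
    the two-sided two-sample Kolmogorov–Smirnov test, exact when the smaller
    set has ≤ 25 genes and asymptotic otherwise.
    """
    expressed = _expressed(fc)
    tvals = expressed.loc[expressed.index.isin(targets), "log2fc"].to_numpy(dtype=float)
    if background is None:
        bvals = expressed.loc[~expressed.index.isin(targets), "log2fc"].to_numpy(dtype=float)
    else:
        bvals = expressed.loc[expressed.index.isin(background), "log2fc"].to_numpy(dtype=float)
    if tvals.size < 2:
        raise InputError("target set has fewer than 2 expressed genes")
    if bvals.size < 2:
        raise InputError("background set has fewer than 2 expressed genes")

    method = "exact" if min(tvals.size, bvals.size) <= 25 else "asymp"
    ks = stats.ks_2samp(tvals, bvals, alternative="two-sided", method=method)

    ts = np.sort(tvals)
    bs = np.sort(bvals)
    grid = np.concatenate([ts, bs])
    grid.sort(kind="mergesort")
    ft = np.searchsorted(ts, grid, side="right") / ts.size
    fb = np.searchsorted(bs, grid, side="right") / bs.size
    d_signed = ft - fb
    d_plus = float(d_signed.max())   # targets left-shifted where F_t > F_b
    d_minus = float((-d_signed).max())
    sign = 0 if d_plus == d_minus else (1 if d_minus > d_plus else -1)

    return CdfComparison(
        target_curve=pd.DataFrame({"x": ts, "F": np.arange(1, ts.size + 1) / ts.size}),
        background_curve=pd.DataFrame({"x": bs, "F": np.arange(1, bs.size + 1) / bs.size}),
        ks_D=float(ks.statistic),
        ks_p=float(ks.pvalue),
        shift_sign=sign,
    )


def derepression_table(
    fc: pd.DataFrame,
    target_map: dict[str, list[str] | set[str]],
    abundance: pd.Series | None = None,
    m_min: int = DEFAULT_M_MIN,
    per_family_background: bool = True,
    compute_ks: bool = True,
) -> pd.DataFrame:
    """Score every miRNA family's target de-repression.

    For each family, the background is the expressed transcriptome minus
    that family's own predicted targets (targets of *other* families stay in
    the background; with ``per_family_background=False`` the global expressed
    set is used instead, own targets included).  Families with fewer than
    ``m_min`` expressed targets are reported with status ``too_few_targets``
    rather than scored; families without a defined abundance are scored but
    flagged ``abundance_undefined`` and excluded from the bubble table.

    Returns one row per family in the fixed column order
    ``family_id, m, Sm, mu, sd, z, abundance_log10, ks_D, ks_p, ks_p_bh, status``.
    ``ks_p_bh`` is the Benjamini–Hochberg adjustment across scored families
    (an addition for reuse; the statistic itself involves no multiple-testing
    correction).
    """
    expressed = _expressed(fc)
    values = expressed["log2fc"].to_numpy(dtype=float)
    index = expressed.index
    n_expressed = values.size
    if n_expressed < 2:
        raise InputError("empty background: fewer than 2 expressed genes")

    global_bg = None
    if not per_family_background:
        global_bg = background_stats(fc, exclude=frozenset())

    rows = []
    for fam in sorted(target_map):
        targets = target_map[fam]
        pos = index.get_indexer(sorted(set(targets)))
        pos = pos[pos >= 0]
        m = int(pos.size)
        a_f = float(abundance.get(fam, np.nan)) if abundance is not None else np.nan
        row = {
            "family_id": fam, "m": m, "Sm": np.nan, "mu": np.nan, "sd": np.nan,
            "z": np.nan, "abundance_log10": a_f, "ks_D": np.nan, "ks_p": np.nan,
            "ks_p_bh": np.nan, "status": "ok",
        }
        if m < m_min:
            row["status"] = "too_few_targets"
            rows.append(row)
            continue

        tvals = values[pos]
        if per_family_background:
            mask = np.ones(n_expressed, dtype=bool)
            mask[pos] = False
            bvals = values[mask]
            if bvals.size < 2:
                raise InputError(f"empty background for family {fam!r}")
            mu = float(bvals.mean())
            sd = float(bvals.std(ddof=1))
            if sd == 0.0:
                raise InputError(f"degenerate background for family {fam!r}")
        else:
            mu, sd = global_bg.mu, global_bg.sd
            bvals = values

        sm = float(tvals.mean())
        row["Sm"] = sm
        row["mu"] = mu
        row["sd"] = sd
        row["z"] = float((sm - mu) * np.sqrt(m) / sd)

        if compute_ks:
            method = "exact" if min(tvals.size, bvals.size) <= 25 else "asymp"
            ks = stats.ks_2samp(tvals, bvals, alternative="two-sided", method=method)
            row["ks_D"] = float(ks.statistic)
            row["ks_p"] = float(ks.pvalue)

        if abundance is not None and not np.isfinite(a_f):
            row["status"] = "abundance_undefined"
        rows.append(row)

    table = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    scored = table["ks_p"].notna()
    if scored.any():
        table.loc[scored, "ks_p_bh"] = multipletests(
            table.loc[scored, "ks_p"].to_numpy(), method="fdr_bh"
        )[1]
    return table


def assemble_bubble_table(records: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready bubble table: family_id, z, abundance_log10, m.

    Keeps scored families with a defined abundance, sorted by abundance
    descending (ties by family_id); z goes on the y-axis, abundance on the
    x-axis, and bubble area is proportional to m.  Rows flagged
    ``abundance_undefined`` or unscored are excluded (with a log notice).
    """
    valid = records[(records["status"] == "ok") & records["abundance_log10"].notna()]
    dropped = len(records) - len(valid)
    if dropped:
        logger.info("bubble table: excluded %d unscored/abundance-undefined families", dropped)
    out = (
        valid[["family_id", "z", "abundance_log10", "m"]]
        .sort_values(
            ["abundance_log10", "family_id"], ascending=[False, True], kind="mergesort"
        )
        .reset_index(drop=True)
    )
    return out
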