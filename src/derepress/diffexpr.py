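"""Per-gene log2-fold changes from a count matrix.

The de-repression statistic consumes only per-gene log2-fold changes, so
this stage is deliberately simple: median-of-ratios size-factor
normalisation (the DESeq-style estimator) followed by a pseudocount
log-ratio of condition means, plus an expression filter.  A fully fitted
differential-expression table computed externally (e.g. by DESeq2) can be
ingested verbatim instead and is the preferred input for real data.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError

DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_MIN_MEAN = 10.0


def median_ratio_normalize(counts: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Median-of-ratios size factors and the normalised matrix.

    For each sample s, the reported size factor is the median over reference
    genes of count_gs / geomean_g, where geomean_g is the geometric mean of
    gene g across samples and reference genes are those with nonzero counts
    in every sample (the DESeq convention, median taken on the log scale).

    The normalised matrix applies the same composition correction to
    CPM-scaled samples, so normalised values are in scale-free
    counts-per-million-like units: multiplying any one sample's counts by a
    positive constant leaves the normalised matrix (and everything downstream
    of it) unchanged.  Plain counts/size-factor normalisation does not have
    this property — its geometric-mean reference absorbs part of the scale.
    """
    if (counts.to_numpy() < 0).any():
        raise InputError("counts must be non-negative")
    totals = counts.sum(axis=0).astype(float)
    if (totals <= 0).any():
        raise InputError("zero-total sample: cannot normalise")
    cpm = counts * 1e6 / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        logc = np.log(cpm.to_numpy(dtype=float))
        log_geomean = logc.mean(axis=1)
    usable = np.isfinite(log_geomean)
    if not usable.any():
        raise InputError(
            "no gene has nonzero counts in all samples; median-of-ratios is undefined "
            "(consider a pseudo-reference fallback or pre-filtering)"
        )
    # median of log-ratios, then exp — at even reference counts this
    # interpolates geometrically, matching DESeq2
    log_ratios = logc[usable] - log_geomean[usable, None]
    cpm_factors = np.exp(np.median(log_ratios, axis=0))
    normalized = cpm / cpm_factors

    # classic raw-count size factors: f_s = f~_s * T_s / geomean(T)
    log_t = np.log(totals.to_numpy())
    size_factors = pd.Series(
        cpm_factors * np.exp(log_t - log_t.mean()),
        index=counts.columns,
        name="size_factor",
    )
    return size_factors, normalized


def estimate_log2fc(
    normalized: pd.DataFrame,
    conditions: pd.Series,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    control_label: str = "control",
    treatment_label: str = "treatment",
) -> pd.DataFrame:
    """Pseudocount log-ratio of condition means (treatment vs control).

    log2fc = log2((mean_trt + pc) / (mean_ctl + pc)); ``mean_expr`` is the
    mean normalised count over *all* samples and feeds the expression filter.
    """
    if (normalized.to_numpy() < 0).any():
        raise InputError("normalized counts must be non-negative")
    conditions = conditions.reindex(normalized.columns)
    if conditions.isna().any():
        missing = list(normalized.columns[conditions.isna()])
        raise InputError(f"samples with no condition label: {missing}")
    ctl = normalized.loc[:, conditions == control_label]
    trt = normalized.loc[:, conditions == treatment_label]
    if ctl.shape[1] < 1 or trt.shape[1] < 1:
        raise InputError("both conditions need at least one sample")
    if pseudocount < 0:
        raise InputError("pseudocount must be >= 0")
    mean_ctl = ctl.mean(axis=1)
    mean_trt = trt.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2((mean_trt + pseudocount) / (mean_ctl + pseudocount))
    out = pd.DataFrame(
        {"log2fc": log2fc, "mean_expr": normalized.mean(axis=1)}, index=normalized.index
    )
    out.index.name = "gene_id"
    return out


def filter_expressed(fc: pd.DataFrame, min_mean: float = DEFAULT_MIN_MEAN) -> pd.DataFrame:
    """Mark genes with mean normalised expression >= ``min_mean`` as expressed.

    Downstream stages (background statistics, target sets, CDFs) see only
    expressed genes.
    """
    out = fc.copy()
    out["expressed"] = out["mean_expr"] >= min_mean
    return out


def fold_changes_from_counts(
    counts: pd.DataFrame,
    conditions: pd.Series,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    min_mean: float = DEFAULT_MIN_MEAN,
) -> pd.DataFrame:
    """Convenience: normalise, estimate log2FCs, and set the expressed flag."""
    _, normalized = median_ratio_normalize(counts)
    fc = estimate_log2fc(normalized, conditions, pseudocount=pseudocount)
    return filter_expressed(fc, min_mean=min_mean)


def read_external_lfc(path: str | Path, min_mean: float | None = None) -> pd.DataFrame:
    """Ingest an externally computed fold-change table verbatim.

    Expects a TSV with columns ``gene_id``, ``log2fc``, ``mean_expr`` and
    optionally ``expressed``; no re-normalisation is applied.  If
    ``expressed`` is absent it is derived from ``mean_expr`` (using
    ``min_mean``, default 10).
    """
    fc = pd.read_csv(path, sep="\t")
    required = {"gene_id", "log2fc", "mean_expr"}
    if not required.issubset(fc.columns):
        raise InputError(f"external fold-change table needs columns {sorted(required)}")
    fc = fc.set_index("gene_id")
    if "expressed" not in fc.columns:
        fc = filter_expressed(fc, min_mean=DEFAULT_MIN_MEAN if min_mean is None else min_mean)
    return fc
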