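"""The de-repression z-score and the target-vs-background CDF comparison."""

import numpy as np
import pandas as pd
import pytest
from oracles import asymptotic_ks_pvalue, brute_force_ks_D, rank_correlation

from derepress import (
    InputError,
    assemble_bubble_table,
    background_stats,
    cdf_compare,
    derepression_table,
    family_zscore,
)


def _fc(values, expressed=None, prefix="g"):
    idx = pd.Index([f"{prefix}{i}" for i in range(len(values))], name="gene_id")
    return pd.DataFrame(
        {
            "log2fc": values,
            "mean_expr": 100.0,
            "expressed": True if expressed is None else expressed,
        },
        index=idx,
    )


def test_background_stats_arithmetic(toy_fc):
    bg = background_stats(toy_fc, exclude={"t0", "t1", "t2", "t3"})
    assert bg.mu == 0.0
    assert bg.sd == 1.0
    assert bg.n_background == 3


def test_background_stats_degenerate_and_empty():
    with pytest.raises(InputError, match="degenerate"):
        background_stats(_fc([0.5, 0.5, 0.5]))
    with pytest.raises(InputError, match="empty background"):
        background_stats(_fc([0.1, 0.2, 0.3]), exclude={"g0", "g1"})


def test_background_stats_match_direct_recomputation():
    rng = np.random.default_rng(5)
    vals = rng.normal(0.1, 0.7, 500)
    fc = _fc(vals)
    exclude = {f"g{i}" for i in range(100)}
    bg = background_stats(fc, exclude=exclude)
    kept = vals[100:]
    assert bg.mu == pytest.approx(kept.mean(), abs=1e-12)
    assert bg.sd == pytest.approx(kept.std(ddof=1), abs=1e-12)


def test_family_zscore_worked_example(toy_fc):
    """Four targets at log2fc = 1 against mu=0, sd=1 background: z = sqrt(4) * 1 = 2."""
    bg = background_stats(toy_fc, exclude={"t0", "t1", "t2", "t3"})
    sm, m, z = family_zscore(toy_fc, {"t0", "t1", "t2", "t3"}, bg)
    assert (sm, m) == (1.0, 4)
    assert z == 2.0


def test_zscore_zero_when_targets_match_background(toy_fc):
    bg = background_stats(toy_fc, exclude={"t0"})
    fc = toy_fc.copy()
    fc.loc["t0", "log2fc"] = bg.mu
    _, _, z = family_zscore(fc, {"t0"}, bg)
    assert z == 0.0


def test_zscore_magnitude_monotone_in_m():
    """Fixed Sm, mu, sd: |z| grows like sqrt(m)."""
    vals = list(np.linspace(-1, 1, 50))
    zs = []
    for m in (4, 9, 16, 25):
        fc = _fc(vals + [0.5] * m, prefix="b")
        targets = {f"b{i}" for i in range(50, 50 + m)}
        bg = background_stats(fc, exclude=targets)
        zs.append(abs(family_zscore(fc, targets, bg)[2]))
    assert zs == sorted(zs)
    assert zs[0] < zs[-1]


def test_derepression_table_exactness_and_statuses():
    rng = np.random.default_rng(17)
    fc = _fc(rng.normal(0, 0.5, 400))
    tmap = {
        "famA": [f"g{i}" for i in range(40)],
        "famB": [f"g{i}" for i in range(40, 80)],
        "famSmall": ["g0", "g1"],
    }
    abundance = pd.Series({"famA": 3.0, "famB": np.nan, "famSmall": 2.0})
    rec = derepression_table(fc, tmap, abundance=abundance, m_min=10).set_index("family_id")

    assert rec.loc["famSmall", "status"] == "too_few_targets"
    assert rec.loc["famB", "status"] == "abundance_undefined"
    assert rec.loc["famA", "status"] == "ok"
    for fam in ("famA", "famB"):
        row = rec.loc[fam]
        # z identity holds to machine precision
        assert row["z"] == (row["Sm"] - row["mu"]) * np.sqrt(row["m"]) / row["sd"]
        # per-family background excludes exactly that family's targets
        kept = fc.drop(index=tmap[fam])["log2fc"]
        assert row["mu"] == pytest.approx(kept.mean(), abs=1e-12)
        assert row["sd"] == pytest.approx(kept.std(ddof=1), abs=1e-12)


def test_bubble_table_sorting_and_exclusion():
    rec = pd.DataFrame(
        {
            "family_id": ["f1", "f2", "f3", "f4"],
            "m": [20, 30, 40, 50],
            "Sm": [0.1] * 4,
            "mu": [0.0] * 4,
            "sd": [1.0] * 4,
            "z": [1.0, 2.0, 3.0, 4.0],
            "abundance_log10": [1.0, 3.0, np.nan, 2.0],
            "ks_D": [0.1] * 4,
            "ks_p": [0.5] * 4,
            "ks_p_bh": [0.5] * 4,
            "status": ["ok", "ok", "abundance_undefined", "too_few_targets"],
        }
    )
    bubble = assemble_bubble_table(rec)
    assert bubble["family_id"].tolist() == ["f2", "f1"]
    assert bubble["abundance_log10"].tolist() == [3.0, 1.0]
    assert assemble_bubble_table(rec.iloc[:0]).empty


def test_cdf_identical_sets_D_zero():
    fc = _fc([0.0, 0.5, -0.5, 1.0, 0.0, 0.5, -0.5, 1.0])
    comp = cdf_compare(fc, {f"g{i}" for i in range(4)})
    assert comp.ks_D == 0.0
    assert comp.shift_sign == 0


def test_cdf_disjoint_supports_D_one():
    fc = _fc([5.0, 6.0, 7.0, -1.0, -2.0, 0.0])
    comp = cdf_compare(fc, {"g0", "g1", "g2"})
    assert comp.ks_D == 1.0
    assert comp.shift_sign == 1  # targets entirely right-shifted


def test_cdf_curves_are_valid_ecdfs():
    rng = np.random.default_rng(2)
    fc = _fc(rng.normal(0, 1, 100))
    comp = cdf_compare(fc, {f"g{i}" for i in range(30)})
    for curve in (comp.target_curve, comp.background_curve):
        assert curve["F"].iloc[-1] == 1.0
        assert (curve["F"].diff().dropna() >= 0).all()
        assert (curve["x"].diff().dropna() >= 0).all()


def test_cdf_shift_matches_independent_ks_computation():
    """0.3-shifted targets, n = 500 each: D and p agree with the brute-force
    sup-difference and the Kolmogorov-distribution p-value."""
    rng = np.random.default_rng(3)
    bg_vals = rng.normal(0, 1, 500)
    t_vals = rng.normal(0, 1, 500) + 0.3
    fc = _fc(list(t_vals) + list(bg_vals))
    targets = {f"g{i}" for i in range(500)}
    comp = cdf_compare(fc, targets)
    assert comp.ks_D == pytest.approx(brute_force_ks_D(t_vals, bg_vals), abs=1e-12)
    # scipy's asymptotic mode carries a finite-sample correction; the classical
    # Kolmogorov series agrees to within ~15% at n = 500
    assert comp.ks_p == pytest.approx(asymptotic_ks_pvalue(comp.ks_D, 500, 500), rel=0.3)
    assert comp.shift_sign == 1
    # shifting the other way flips the direction
    fc_neg = _fc(list(t_vals - 0.6) + list(bg_vals))
    assert cdf_compare(fc_neg, targets).shift_sign == -1


def test_cdf_undersized_sets_error():
    fc = _fc([0.0, 1.0, 2.0])
    with pytest.raises(InputError, match="target"):
        cdf_compare(fc, {"g0"})
    with pytest.raises(InputError, match="background"):
        cdf_compare(fc, {"g0", "g1"})


def test_small_sets_use_exact_ks():
    rng = np.random.default_rng(4)
    fc = _fc(list(rng.normal(0, 1, 20)) + list(rng.normal(0, 1, 300)))
    targets = {f"g{i}" for i in range(20)}
    comp = cdf_compare(fc, targets)
    from scipy import stats

    t = fc.loc[sorted(targets), "log2fc"].to_numpy()
    b = fc.drop(index=sorted(targets))["log2fc"].to_numpy()
    exact = stats.ks_2samp(t, b, method="exact")
    assert comp.ks_p == pytest.approx(exact.pvalue, abs=1e-12)


def test_bubble_rank_correlation_matches_oracle(small_dataset):
    """Spearman of (z, abundance) computed two independent ways agrees."""
    from scipy import stats

    from derepress import fold_changes_from_counts

    ds = small_dataset
    fc = fold_changes_from_counts(ds.counts, ds.conditions)
    rec = derepression_table(
        fc, ds.target_map, abundance=ds.ground_truth.abundance_log10, compute_ks=False
    )
    bubble = assemble_bubble_table(rec)
    rho_scipy = float(stats.spearmanr(bubble["z"], bubble["abundance_log10"]).statistic)
    rho_oracle = rank_correlation(bubble["z"], bubble["abundance_log10"])
    assert rho_scipy == pytest.approx(rho_oracle, abs=1e-12)


def test_global_background_mode():
    rng = np.random.default_rng(9)
    fc = _fc(rng.normal(0, 0.5, 200))
    tmap = {"f": [f"g{i}" for i in range(50)]}
    rec = derepression_table(fc, tmap, per_family_background=False).iloc[0]
    assert rec["mu"] == pytest.approx(fc["log2fc"].mean(), abs=1e-12)
    assert rec["sd"] == pytest.approx(fc["log2fc"].std(ddof=1), abs=1e-12)
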