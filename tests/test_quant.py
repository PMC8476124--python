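"""End-window counting rule, GFF3 ingestion, family aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from oracles import brute_force_mature_counts, rank_correlation

from derepress import (
    AlignmentRecord,
    InputError,
    MatureAnnotation,
    SimulationConfig,
    aggregate_families,
    compare_mirna_abundance,
    count_mature,
    match_read,
    read_alignments,
    read_annotation,
)
from derepress.simulate import (
    generate_annotation,
    simulate_small_rna_alignments,
    write_gff3,
    write_sam,
)

MIXED_JITTER = {0: 0.6, -2: 0.15, 2: 0.15, -6: 0.05, 6: 0.05}

MATURE = MatureAnnotation("miR-x-5p", "pre-x", 10, 31)


def _aln(start, end, strand="+", primary=True, precursor="pre-x"):
    return AlignmentRecord("r1", precursor, start, end, strand, primary)


@pytest.mark.parametrize(
    "aln, expected",
    [
        (_aln(10, 31), True),                # exact ends
        (_aln(15, 31), False),               # 5' offset 5 exceeds the window
        (_aln(6, 35), True),                 # offsets -4/+4: bounds are inclusive
        (_aln(10, 36), False),               # conjunction: 3' end out, 5' exact
        (_aln(14, 27), True),                # offsets +4/-4
        (_aln(10, 31, strand="-"), False),   # antisense never counted
        (_aln(10, 31, primary=False), False),  # secondary never counted
    ],
)
def test_match_read_end_window_rule(aln, expected):
    assert match_read(aln, MATURE, window=4) is expected


@settings(max_examples=200, derandomize=True, deadline=None)
@given(
    d5=st.integers(-9, 9),
    d3=st.integers(-9, 9),
    window=st.integers(0, 6),
)
def test_match_read_is_exactly_the_two_end_window_predicate(d5, d3, window):
    """Counted iff BOTH end offsets are within the window, bounds inclusive."""
    aln = _aln(MATURE.start + d5, MATURE.end + d3)
    assert match_read(aln, MATURE, window=window) == (
        abs(d5) <= window and abs(d3) <= window
    )


def test_match_read_cross_precursor_is_caller_bug():
    with pytest.raises(ValueError):
        match_read(_aln(10, 31, precursor="pre-y"), MATURE)


def test_read_annotation_roundtrips_generator_output(tmp_path):
    cfg = SimulationConfig(n_families=8, rng_seed=4)
    ann = generate_annotation(cfg)
    path = tmp_path / "m.gff3"
    write_gff3(ann, path)
    records = read_annotation(path, families=ann.families)
    assert sorted(
        (r.mature_id, r.precursor_id, r.start, r.end, r.family_id) for r in records
    ) == sorted(
        (m.mature_id, m.precursor_id, m.start, m.end, m.family_id) for m in ann.matures
    )


def test_read_annotation_empty_and_errors(tmp_path):
    empty = tmp_path / "empty.gff3"
    empty.write_text("##gff-version 3\n")
    assert read_annotation(empty) == []

    no_derives = tmp_path / "nd.gff3"
    no_derives.write_text(
        "##gff-version 3\n"
        "p1\tsrc\tmiRNA_primary_transcript\t1\t80\t.\t+\t.\tID=p1\n"
        "p1\tsrc\tmiRNA\t10\t31\t.\t+\t.\tID=m1\n"
    )
    with pytest.raises(InputError, match="m1"):
        read_annotation(no_derives)

    bad_ref = tmp_path / "br.gff3"
    bad_ref.write_text(
        "##gff-version 3\n"
        "p1\tsrc\tmiRNA_primary_transcript\t1\t80\t.\t+\t.\tID=p1\n"
        "p1\tsrc\tmiRNA\t10\t31\t.\t+\t.\tID=m1;Derives_from=pX\n"
    )
    with pytest.raises(InputError, match="pX"):
        read_annotation(bad_ref)

    dupe = tmp_path / "dupe.gff3"
    dupe.write_text(
        "##gff-version 3\n"
        "p1\tsrc\tmiRNA_primary_transcript\t1\t80\t.\t+\t.\tID=p1\n"
        "p1\tsrc\tmiRNA\t10\t31\t.\t+\t.\tID=m1;Derives_from=p1\n"
        "p1\tsrc\tmiRNA\t40\t61\t.\t+\t.\tID=m1;Derives_from=p1\n"
    )
    with pytest.raises(InputError, match="duplicate"):
        read_annotation(dupe)


def test_count_mature_zero_alignments():
    empty = pd.DataFrame(
        columns=["read_id", "precursor_id", "aln_start", "aln_end", "strand", "is_primary"]
    )
    counts, qc = count_mature(empty, [MATURE])
    assert (counts == 0).all()
    assert qc["n_primary_plus"] == 0


def test_counts_equal_totals_without_jitter(tmp_path):
    """Point-mass jitter at 0: SAM-roundtripped counts equal read totals."""
    cfg = SimulationConfig(
        n_families=5, end_jitter_probs={0: 1.0}, reads_per_mirna_scale=20.0, rng_seed=11
    )
    ann = generate_annotation(cfg)
    aln, truth = simulate_small_rna_alignments(ann, cfg)
    sam = tmp_path / "x.sam"
    write_sam(aln, ann.precursors, sam)
    counts, qc = count_mature(read_alignments(sam), ann.matures)
    pd.testing.assert_series_equal(counts, truth, check_names=False)
    assert qc["assigned"] == len(aln)


@pytest.mark.parametrize("seed", [7, 19, 33])
def test_counts_equal_brute_force_oracle(tmp_path, seed):
    """Vectorised counting equals the O(reads x matures) matcher exactly."""
    cfg = SimulationConfig(
        n_families=6, end_jitter_probs=MIXED_JITTER,
        reads_per_mirna_scale=40.0, rng_seed=seed,
    )
    ann = generate_annotation(cfg)
    aln, truth = simulate_small_rna_alignments(ann, cfg)
    sam = tmp_path / f"s{seed}.sam"
    write_sam(aln, ann.precursors, sam)
    loaded = read_alignments(sam)
    counts, qc = count_mature(loaded, ann.matures)
    oracle, un_window, un_ref = brute_force_mature_counts(loaded, ann.matures)
    pd.testing.assert_series_equal(counts.sort_index(), oracle.sort_index())
    # conservation: nothing silently dropped
    assert qc["assigned"] + qc["unassigned_window"] + qc["unassigned_reference"] == qc[
        "n_primary_plus"
    ]
    assert (qc["unassigned_window"], qc["unassigned_reference"]) == (un_window, un_ref)
    # ground truth is a per-mature property; totals agree when no annotations overlap
    assert counts.sum() == truth.sum()


def test_unknown_precursor_tallied_not_dropped():
    aln = pd.DataFrame(
        {
            "read_id": ["a", "b"],
            "precursor_id": ["pre-x", "pre-unknown"],
            "aln_start": [10, 10],
            "aln_end": [31, 31],
            "strand": ["+", "+"],
            "is_primary": [True, True],
        }
    )
    counts, qc = count_mature(aln, [MATURE])
    assert counts["miR-x-5p"] == 1
    assert qc["unassigned_reference"] == 1
    assert qc["assigned"] + qc["unassigned_window"] + qc["unassigned_reference"] == 2


def test_counts_monotone_in_window():
    cfg = SimulationConfig(
        n_families=4, end_jitter_probs=MIXED_JITTER, reads_per_mirna_scale=40.0, rng_seed=2
    )
    ann = generate_annotation(cfg)
    aln, _ = simulate_small_rna_alignments(ann, cfg)
    totals = [count_mature(aln, ann.matures, window=w)[0].sum() for w in range(0, 7)]
    assert totals == sorted(totals)


def test_tie_break_closest_then_lexicographic():
    # two overlapping matures; the read is equidistant from both
    m_a = MatureAnnotation("miR-a", "p", 10, 31)
    m_b = MatureAnnotation("miR-b", "p", 12, 33)
    aln = pd.DataFrame(
        {
            "read_id": ["r"],
            "precursor_id": ["p"],
            "aln_start": [11],
            "aln_end": [32],
            "strand": ["+"],
            "is_primary": [True],
        }
    )
    counts, _ = count_mature(aln, [m_b, m_a])
    assert counts["miR-a"] == 1 and counts["miR-b"] == 0
    # closer annotation wins when distances differ
    aln2 = aln.assign(aln_start=[12], aln_end=[33])
    counts2, _ = count_mature(aln2, [m_b, m_a])
    assert counts2["miR-b"] == 1 and counts2["miR-a"] == 0


def test_aggregate_families_sums_and_log10():
    families = pd.DataFrame(
        {
            "family_id": ["f1", "f1", "f2", "f3"],
            "member_mirna": ["a", "b", "c", "d"],
        }
    )
    counts = pd.Series({"a": 100, "b": 50, "c": 1, "d": 0})
    table = aggregate_families(counts, families)
    assert table.loc["f1", "family_count"] == 150
    assert table.loc["f1", "abundance_log10"] == pytest.approx(np.log10(150))
    assert table.loc["f2", "abundance_log10"] == 0.0
    assert not table.loc["f3", "abundance_defined"]
    assert np.isnan(table.loc["f3", "abundance_log10"])


def test_aggregate_families_orphan_mature_errors():
    families = pd.DataFrame({"family_id": ["f1"], "member_mirna": ["a"]})
    with pytest.raises(InputError, match="orphan|no family"):
        aggregate_families(pd.Series({"a": 1, "zzz": 2}), families)


def test_compare_abundance_identity_and_scaling():
    counts = pd.Series({"a": 100, "b": 10, "c": 1000, "d": 0})
    table, rho = compare_mirna_abundance(counts, counts)
    assert np.allclose(table["log2_ratio"], 0.0)
    assert rho == pytest.approx(1.0)
    # library-size scaling changes nothing after CPM normalisation
    table2, rho2 = compare_mirna_abundance(counts, 2 * counts)
    assert np.allclose(table2["log2_ratio"], 0.0)
    assert np.allclose(table2["cpm_a"], table2["cpm_b"])
    assert rho2 == pytest.approx(1.0)


def test_compare_abundance_zero_library_errors():
    counts = pd.Series({"a": 1, "b": 2})
    with pytest.raises(InputError):
        compare_mirna_abundance(counts, pd.Series({"a": 0, "b": 0}))


def test_compare_abundance_spearman_matches_rank_oracle():
    rng = np.random.default_rng(8)
    idx = [f"m{i}" for i in range(60)]
    a = pd.Series(rng.poisson(rng.lognormal(3, 1, 60)), index=idx)
    b = pd.Series(rng.poisson(rng.lognormal(3, 1, 60)), index=idx)
    _, rho = compare_mirna_abundance(a, b)
    expected = rank_correlation(
        (a / a.sum()).to_numpy(), (b / b.sum()).to_numpy()
    )
    assert rho == pytest.approx(expected, abs=1e-12)
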