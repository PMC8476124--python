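"""Mature-miRNA quantification from precursor-space small-RNA alignments.

Small-RNA reads aligned to pre-miRNA hairpin sequences are counted toward an
annotated mature miRNA when *both* alignment ends fall within a fixed window
(default ±4 nt) of the annotated mature 5′ and 3′ ends.  The window absorbs
templated isomiR end-heterogeneity while excluding degradation fragments,
which typically violate at least one end.  Counts of miRNAs sharing a seed
(nt 2–8) are summed per family, and family abundance is the log10 of that
sum — the x-axis of the de-repression bubble plot.

Only primary, plus-strand alignments are counted: the reference is a
sense-strand precursor index, so antisense or secondary hits would
double-count or misassign reads.  Alignment ends are aligned-segment ends in
precursor coordinates (soft-clipped bases excluded).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from gffutils.iterators import DataIterator
from scipy import stats

from .errors import InputError

logger = logging.getLogger(__name__)

DEFAULT_END_WINDOW = 4

ALIGNMENT_COLUMNS = ["read_id", "precursor_id", "aln_start", "aln_end", "strand", "is_primary"]


@dataclass(frozen=True)
class MatureAnnotation:
    """A mature miRNA annotated on its precursor hairpin.

    Coordinates are 1-based inclusive positions on the precursor sequence.
    """

    mature_id: str
    precursor_id: str
    start: int
    end: int
    family_id: str | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise InputError(
                f"mature {self.mature_id!r}: invalid coordinates {self.start}..{self.end}"
            )


@dataclass(frozen=True)
class AlignmentRecord:
    """A single read alignment in precursor space (1-based inclusive ends)."""

    read_id: str
    precursor_id: str
    aln_start: int
    aln_end: int
    strand: str = "+"
    is_primary: bool = True

    def __post_init__(self) -> None:
        if self.aln_start > self.aln_end:
            raise InputError(f"alignment {self.read_id!r}: start > end")


# ---------------------------------------------------------------------------
# annotation ingestion
# ---------------------------------------------------------------------------

def read_annotation(
    gff3_path: str | Path,
    families: pd.DataFrame | None = None,
) -> list[MatureAnnotation]:
    """Read mature miRNA annotations from a miRBase-dialect GFF3 file.

    Every ``miRNA`` feature becomes one :class:`MatureAnnotation`; its
    ``Derives_from`` attribute must resolve to a ``miRNA_primary_transcript``
    feature (the precursor).  Coordinates are preserved 1-based inclusive.

    Parameters
    ----------
    gff3_path:
        Path to the GFF3 file.
    families:
        Optional family table with columns ``family_id`` and ``member_mirna``;
        when given, each mature's ``family_id`` is filled from it.

    Raises
    ------
    InputError
        If a ``miRNA`` feature lacks ``Derives_from``, the referenced
        precursor does not exist, or a mature ID occurs more than once.
    """
    gff3_path = Path(gff3_path)
    precursor_ids: set[str] = set()
    raw: list[tuple[str, str | None, int, int]] = []
    for feat in DataIterator(str(gff3_path)):
        ftype = feat.featuretype
        attrs = feat.attributes
        if ftype == "miRNA_primary_transcript":
            precursor_ids.add(attrs["ID"][0])
        elif ftype == "miRNA":
            mid = attrs["ID"][0]
            derives = attrs["Derives_from"][0] if "Derives_from" in attrs else None
            if derives is None:
                raise InputError(f"miRNA feature {mid!r} has no Derives_from attribute")
            raw.append((mid, derives, feat.start, feat.end))

    seen: set[str] = set()
    dupes = sorted({mid for mid, *_ in raw if (mid in seen) or seen.add(mid)})
    if dupes:
        raise InputError(f"duplicate mature miRNA IDs in {gff3_path.name}: {dupes}")

    fam_of: dict[str, str] = {}
    if families is not None:
        fam_of = dict(zip(families["member_mirna"], families["family_id"]))

    records = []
    for mid, derives, start, end in raw:
        if derives not in precursor_ids:
            raise InputError(
                f"miRNA feature {mid!r}: Derives_from={derives!r} does not match any "
                "miRNA_primary_transcript feature"
            )
        records.append(
            MatureAnnotation(
                mature_id=mid,
                precursor_id=derives,
                start=start,
                end=end,
                family_id=fam_of.get(mid),
            )
        )
    return records


# ---------------------------------------------------------------------------
# SAM ingestion
# ---------------------------------------------------------------------------

def read_alignments(sam_path: str | Path) -> pd.DataFrame:
    """Load precursor-space alignments from SAM/BAM into a table.

    Returns a DataFrame with columns ``read_id``, ``precursor_id``,
    ``aln_start``, ``aln_end`` (1-based inclusive, soft clips excluded),
    ``strand`` and ``is_primary``.  Unmapped records are skipped.
    """
    rows = {c: [] for c in ALIGNMENT_COLUMNS}
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            rows["read_id"].append(aln.query_name)
            rows["precursor_id"].append(aln.reference_name)
            # reference_start is 0-based; reference_end is 0-based exclusive,
            # i.e. exactly the 1-based inclusive end.
            rows["aln_start"].append(aln.reference_start + 1)
            rows["aln_end"].append(aln.reference_end)
            rows["strand"].append("-" if aln.is_reverse else "+")
            rows["is_primary"].append(not (aln.is_secondary or aln.is_supplementary))
    return pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS)


# ---------------------------------------------------------------------------
# the end-window counting rule
# ---------------------------------------------------------------------------

def match_read(
    aln: AlignmentRecord,
    mature: MatureAnnotation,
    window: int = DEFAULT_END_WINDOW,
) -> bool:
    """Decide whether one alignment counts toward one mature miRNA.

    True iff the alignment is primary, on the plus strand, and *both* its 5′
    and 3′ ends lie within ``window`` nt (inclusive) of the annotated mature
    ends.  The two-end conjunction is deliberate: a read matching only one
    end is more likely a degradation fragment than an isomiR.
    """
    if aln.precursor_id != mature.precursor_id:
        raise ValueError(
            f"match_read called across precursors ({aln.precursor_id!r} vs "
            f"{mature.precursor_id!r}); this is a caller bug"
        )
    return (
        aln.is_primary
        and aln.strand == "+"
        and abs(aln.aln_start - mature.start) <= window
        and abs(aln.aln_end - mature.end) <= window
    )


def count_mature(
    alignments: pd.DataFrame,
    annotations: list[MatureAnnotation],
    window: int = DEFAULT_END_WINDOW,
) -> tuple[pd.Series, dict]:
    """Count reads per mature miRNA with the end-window rule.

    Each primary, plus-strand alignment contributes at most one count.  A
    read compatible with several matures (possible only for overlapping
    annotations) is assigned to the mature minimising |Δ5′| + |Δ3′|, ties
    broken by lexicographically smallest ``mature_id``.  Reads referencing a
    precursor absent from the annotation are tallied as
    ``unassigned_reference``; in-reference reads matching no mature as
    ``unassigned_window``.  Nothing is silently dropped:

        assigned + unassigned_window + unassigned_reference
            == number of primary plus-strand alignments.

    Returns
    -------
    (counts, qc):
        ``counts`` is a Series indexed by every annotated ``mature_id``;
        ``qc`` is a dict of tallies.
    """
    if not annotations:
        raise InputError("count_mature requires at least one mature annotation")
    if window < 0:
        raise InputError("window must be non-negative")

    mature_ids = [m.mature_id for m in annotations]
    counts = np.zeros(len(annotations), dtype=np.int64)

    # per-precursor mature index, columns sorted by mature_id for the tie rule
    by_prec: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for prec in {m.precursor_id for m in annotations}:
        members = sorted(
            (i for i, m in enumerate(annotations) if m.precursor_id == prec),
            key=lambda i: annotations[i].mature_id,
        )
        by_prec[prec] = (
            np.array([annotations[i].start for i in members]),
            np.array([annotations[i].end for i in members]),
            np.array(members),
        )

    qc = {
        "n_alignments": int(len(alignments)),
        "n_primary_plus": 0,
        "assigned": 0,
        "unassigned_window": 0,
        "unassigned_reference": 0,
        "n_secondary_or_supplementary": 0,
        "n_minus_strand": 0,
    }

    if len(alignments):
        qc["n_secondary_or_supplementary"] = int((~alignments["is_primary"]).sum())
        primary = alignments[alignments["is_primary"]]
        qc["n_minus_strand"] = int((primary["strand"] == "-").sum())
        usable = primary[primary["strand"] == "+"]
        qc["n_primary_plus"] = int(len(usable))

        for prec, grp in usable.groupby("precursor_id", sort=False):
            if prec not in by_prec:
                qc["unassigned_reference"] += len(grp)
                continue
            mstart, mend, midx = by_prec[prec]
            d5 = np.abs(grp["aln_start"].to_numpy()[:, None] - mstart[None, :])
            d3 = np.abs(grp["aln_end"].to_numpy()[:, None] - mend[None, :])
            ok = (d5 <= window) & (d3 <= window)
            score = np.where(ok, d5 + d3, np.iinfo(np.int64).max)
            any_ok = ok.any(axis=1)
            # argmin returns the first minimum; columns are mature_id-sorted,
            # so ties resolve to the lexicographically smallest mature
            chosen = midx[np.argmin(score[any_ok], axis=1)]
            np.add.at(counts, chosen, 1)
            qc["assigned"] += int(any_ok.sum())
            qc["unassigned_window"] += int((~any_ok).sum())

    return pd.Series(counts, index=pd.Index(mature_ids, name="mature_id"), name="count"), qc


# ---------------------------------------------------------------------------
# family aggregation
# ---------------------------------------------------------------------------

def aggregate_families(
    mature_counts: pd.Series,
    families: pd.DataFrame,
) -> pd.DataFrame:
    """Sum mature counts per seed family and compute family abundance.

    ``families`` maps members to families (columns ``family_id``,
    ``member_mirna``).  Family abundance a_f = log10(family count); it is
    undefined for zero-count families, which are flagged
    (``abundance_defined = False``) and excluded from downstream
    abundance-dependent reporting.

    Raises
    ------
    InputError
        If any counted mature has no family assignment.
    """
    fam_of = dict(zip(families["member_mirna"], families["family_id"]))
    orphans = sorted(set(mature_counts.index) - set(fam_of))
    if orphans:
        raise InputError(f"matures with counts but no family assignment: {orphans}")

    fam = mature_counts.groupby(mature_counts.index.map(fam_of)).sum()
    # families with members but no counted mature still get a (zero) row
    fam = fam.reindex(sorted(set(families["family_id"])), fill_value=0)
    fam.index.name = "family_id"
    out = pd.DataFrame({"family_count": fam.astype(np.int64)})
    with np.errstate(divide="ignore"):
        out["abundance_log10"] = np.where(
            out["family_count"] > 0, np.log10(out["family_count"]), np.nan
        )
    out["abundance_defined"] = out["family_count"] > 0
    return out


# ---------------------------------------------------------------------------
# library comparison (abundance scatter)
# ---------------------------------------------------------------------------

def compare_mirna_abundance(
    counts_a: pd.Series,
    counts_b: pd.Series,
    pseudocount_cpm: float = 0.5,
) -> tuple[pd.DataFrame, float]:
    """Pair two small-RNA libraries per mature miRNA for a scatter comparison.

    Counts are normalised to counts-per-million (CPM) within each library;
    the log-ratio uses a small CPM pseudocount so zero-count miRNAs stay
    finite.  Returns the per-mature table (``cpm_a``, ``cpm_b``,
    ``log2_ratio``) and the Spearman correlation between the two libraries.
    """
    if not counts_a.index.equals(counts_b.index):
        raise InputError("compare_mirna_abundance requires the same mature universe")
    tot_a, tot_b = float(counts_a.sum()), float(counts_b.sum())
    if tot_a <= 0 or tot_b <= 0:
        raise InputError("zero-total library: cannot normalise to CPM")
    cpm_a = counts_a / tot_a * 1e6
    cpm_b = counts_b / tot_b * 1e6
    table = pd.DataFrame(
        {
            "cpm_a": cpm_a,
            "cpm_b": cpm_b,
            "log2_ratio": np.log2((cpm_a + pseudocount_cpm) / (cpm_b + pseudocount_cpm)),
        }
    )
    rho = float(stats.spearmanr(cpm_a.to_numpy(), cpm_b.to_numpy()).statistic)
    return table, rho
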