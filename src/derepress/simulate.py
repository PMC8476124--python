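"""Synthetic data emulating a miRISC-inhibition (T6B-style) experiment.

The generator produces every input the pipeline consumes, with the
statistical structure the analysis assumes:

* pre-miRNA hairpin sequences, each carrying one or two annotated mature
  miRNAs, partitioned into seed families (FASTA + miRBase-dialect GFF3 +
  family table);
* small-RNA read alignments in precursor space whose 5′/3′ ends jitter
  around the annotated mature ends (isomiR-like end heterogeneity), for two
  libraries with identical expected miRNA abundance — blocking miRISC
  assembly de-represses targets without changing miRNA levels;
* a TargetScan-style family → predicted-target map;
* a gene × sample negative-binomial count matrix in two conditions, where
  predicted targets are de-repressed in the treatment condition with a
  log2 effect proportional to the family's log10 small-RNA abundance
  (the monotone abundance–effect trend the analysis is built to detect).

Ground truth (per-family effect δ_f, per-gene assignments, true abundances)
is retained so recovery can be scored exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .errors import InputError
from .quant import MatureAnnotation, aggregate_families

#: default 5′/3′ end-offset distribution (nt); support deliberately extends
#: beyond the ±4 counting window so window exclusion is exercised
DEFAULT_END_JITTER = {
    0: 0.55,
    -1: 0.10,
    1: 0.10,
    -2: 0.06,
    2: 0.06,
    -3: 0.02,
    3: 0.02,
    -4: 0.015,
    4: 0.015,
    -5: 0.02,
    5: 0.02,
    -6: 0.01,
    6: 0.01,
}

SMALL_RNA_LIBRARY_LABELS = ("control", "treatment")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the simulated experiment.

    Defaults describe a bulk mouse-tissue-scale experiment: ~12k expressed
    genes, a few dozen conserved miRNA families with several hundred
    predicted targets each, three replicates per condition, and miRNA
    abundances spanning several orders of magnitude.
    """

    n_genes: int = 12000
    n_families: int = 40
    targets_per_family: int = 400
    #: "random" draws each family's targets independently (genes may be
    #: targeted by several families, as in TargetScan); "disjoint" tiles
    #: families over distinct genes, leaving the remainder as pure background
    target_assignment: str = "random"
    mean_family_size: float = 2.0
    n_samples_per_condition: int = 3
    baseline_mean_log10_range: tuple[float, float] = (0.5, 3.5)
    nb_dispersion: float = 0.1
    #: δ_max — log2 de-repression of targets of the most abundant family
    max_effect_log2: float = 0.5
    #: median expected reads per mature miRNA
    reads_per_mirna_scale: float = 100.0
    #: sd (log10) of per-mature expected abundance
    abundance_sigma_log10: float = 1.0
    end_jitter_probs: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_END_JITTER))
    n_small_rna_libraries: int = 2
    mature_length_range: tuple[int, int] = (20, 23)
    precursor_length_range: tuple[int, int] = (75, 100)
    #: distance of the 5′ mature start / 3′ mature end from the hairpin ends
    end_margin_range: tuple[int, int] = (8, 12)
    p_second_mature: float = 0.5
    #: NB means are capped here to stay overflow-safe for extreme baselines
    mean_cap: float = 1e9
    rng_seed: int = 0

    def validate(self) -> None:
        for name in ("n_genes", "n_families", "targets_per_family", "n_samples_per_condition"):
            if getattr(self, name) < 1:
                raise InputError(f"{name} must be >= 1")
        if self.nb_dispersion <= 0:
            raise InputError("nb_dispersion must be > 0")
        if self.reads_per_mirna_scale <= 0:
            raise InputError("reads_per_mirna_scale must be > 0")
        if self.target_assignment not in ("random", "disjoint"):
            raise InputError("target_assignment must be 'random' or 'disjoint'")
        if self.targets_per_family > self.n_genes:
            raise InputError("targets_per_family exceeds the gene universe")
        if (
            self.target_assignment == "disjoint"
            and self.n_families * self.targets_per_family > self.n_genes
        ):
            raise InputError("disjoint target assignment needs n_families*targets_per_family <= n_genes")
        if not self.end_jitter_probs:
            raise InputError("end_jitter_probs must be non-empty")
        if any(p < 0 for p in self.end_jitter_probs.values()):
            raise InputError("end_jitter_probs must be non-negative")
        if abs(sum(self.end_jitter_probs.values()) - 1.0) > 1e-9:
            raise InputError("end_jitter_probs must sum to 1")
        max_off = max(abs(o) for o in self.end_jitter_probs)
        if max_off >= min(self.end_margin_range):
            raise InputError(
                "end jitter offsets must stay inside the precursor: "
                f"max |offset| {max_off} >= min end margin {min(self.end_margin_range)}"
            )
        if self.mature_length_range[0] < 1 or self.mature_length_range[0] > self.mature_length_range[1]:
            raise InputError("invalid mature_length_range")
        if self.mature_length_range[1] > self.precursor_length_range[0]:
            raise InputError("mature length exceeds the shortest precursor")
        if self.p_second_mature > 0 and self.precursor_length_range[0] < 2 * (
            self.mature_length_range[1] + max(self.end_margin_range)
        ):
            raise InputError(
                "precursors too short to hold two non-overlapping mature arms; "
                "increase precursor_length_range or set p_second_mature=0"
            )

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "end_jitter_probs" in d:
            d["end_jitter_probs"] = {int(k): float(v) for k, v in d["end_jitter_probs"].items()}
        for key in ("baseline_mean_log10_range", "mature_length_range",
                    "precursor_length_range", "end_margin_range"):
            if key in d:
                d[key] = tuple(d[key])
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise InputError(f"unknown simulation config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["end_jitter_probs"] = {str(k): v for k, v in self.end_jitter_probs.items()}
        return d


@dataclass(frozen=True)
class Annotation:
    """Precursor sequences, mature annotations and the family table."""

    precursors: dict[str, str]
    matures: list[MatureAnnotation]
    families: pd.DataFrame  # family_id, seed, member_mirna


@dataclass(frozen=True)
class GroundTruth:
    """What the simulator actually did, for recovery scoring.

    ``delta_family`` is δ_f = δ_max · a_f / max_g(a_g), with a_f the log10
    total within-window small-RNA count of the family (δ_f = 0 for families
    whose abundance is undefined); ``delta_gene`` is the per-gene applied
    effect (max over targeting families); ``abundance_log10`` the true a_f.
    """

    delta_family: pd.Series
    delta_gene: pd.Series
    abundance_log10: pd.Series
    target_map: dict[str, list[str]]


@dataclass(frozen=True)
class SimulatedDataset:
    config: SimulationConfig
    annotation: Annotation
    alignments: dict[str, pd.DataFrame]
    true_mature_counts: dict[str, pd.Series]
    target_map: dict[str, list[str]]
    ground_truth: GroundTruth
    counts: pd.DataFrame
    conditions: pd.Series


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def generate_annotation(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> Annotation:
    """Generate precursor hairpins with 1–2 mature arms, partitioned into families.

    Every mature is fully contained in its precursor with enough margin that
    end-jittered reads never leave the reference; every mature belongs to
    exactly one family and each family has at least one member.  Identical
    config + seed gives byte-identical output.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)

    n_target = max(config.n_families, int(round(config.n_families * config.mean_family_size)))
    alphabet = np.array(list("ACGT"))
    lo_len, hi_len = config.precursor_length_range
    lo_m, hi_m = config.mature_length_range
    lo_e, hi_e = config.end_margin_range

    precursors: dict[str, str] = {}
    matures: list[MatureAnnotation] = []
    k = 0
    while len(matures) < n_target:
        pid = f"sim-mir-{k:04d}"
        length = int(rng.integers(lo_len, hi_len + 1))
        seq = "".join(rng.choice(alphabet, size=length))
        start5 = int(rng.integers(lo_e, hi_e + 1))
        len5 = int(rng.integers(lo_m, hi_m + 1))
        matures.append(MatureAnnotation(f"sim-miR-{k:04d}-5p", pid, start5, start5 + len5 - 1))
        if rng.random() < config.p_second_mature and len(matures) < n_target:
            margin3 = int(rng.integers(lo_e, hi_e + 1))
            len3 = int(rng.integers(lo_m, hi_m + 1))
            end3 = length - margin3
            matures.append(MatureAnnotation(f"sim-miR-{k:04d}-3p", pid, end3 - len3 + 1, end3))
        precursors[pid] = seq
        k += 1

    # partition matures into families: first one member per family, then the rest
    order = rng.permutation(len(matures))
    fam_idx = np.empty(len(matures), dtype=np.int64)
    fam_idx[order[: config.n_families]] = np.arange(config.n_families)
    if len(matures) > config.n_families:
        fam_idx[order[config.n_families:]] = rng.integers(
            0, config.n_families, size=len(matures) - config.n_families
        )
    fam_ids = [f"miR-fam-{i:03d}" for i in range(config.n_families)]

    matures = [
        dataclasses.replace(m, family_id=fam_ids[fam_idx[i]]) for i, m in enumerate(matures)
    ]

    # seed string: nt 2..8 of the family's first member
    seed_of: dict[str, str] = {}
    rows = []
    for m in matures:
        mseq = precursors[m.precursor_id][m.start - 1 : m.end]
        seed_of.setdefault(m.family_id, mseq[1:8])
        rows.append((m.family_id, seed_of[m.family_id], m.mature_id))
    families = (
        pd.DataFrame(rows, columns=["family_id", "seed", "member_mirna"])
        .sort_values(["family_id", "member_mirna"], kind="mergesort")
        .reset_index(drop=True)
    )
    return Annotation(precursors=precursors, matures=matures, families=families)


# ---------------------------------------------------------------------------
# small-RNA reads
# ---------------------------------------------------------------------------

def draw_mature_expression(
    annotation: Annotation, config: SimulationConfig, rng: np.random.Generator
) -> pd.Series:
    """Per-mature expected read counts, lognormal over several orders of magnitude."""
    lam = config.reads_per_mirna_scale * np.power(
        10.0, rng.normal(0.0, config.abundance_sigma_log10, size=len(annotation.matures))
    )
    return pd.Series(lam, index=[m.mature_id for m in annotation.matures], name="expected_reads")


def simulate_small_rna_alignments(
    annotation: Annotation,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    expression: pd.Series | None = None,
    library_id: str = "lib",
    window: int = 4,
) -> tuple[pd.DataFrame, pd.Series]:
    """Emit precursor-space small-RNA alignments with jittered ends.

    Each read's 5′ and 3′ ends are the annotated mature ends plus offsets
    drawn independently from ``end_jitter_probs``.  The returned ground-truth
    Series counts, per mature, the reads with both |offsets| ≤ ``window`` —
    exactly what an end-window quantifier should recover.

    Reads are primary and on the precursor sense strand (miRNA biogenesis
    produces sense-strand products; the aligner index is sense-strand).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    if expression is None:
        expression = draw_mature_expression(annotation, config, rng)

    offsets = np.array(sorted(config.end_jitter_probs), dtype=np.int64)
    probs = np.array([config.end_jitter_probs[o] for o in offsets], dtype=float)
    probs = probs / probs.sum()

    frames = []
    truth = {}
    read_no = 0
    for m in annotation.matures:
        n = int(rng.poisson(expression[m.mature_id]))
        d5 = rng.choice(offsets, size=n, p=probs)
        d3 = rng.choice(offsets, size=n, p=probs)
        truth[m.mature_id] = int(((np.abs(d5) <= window) & (np.abs(d3) <= window)).sum())
        frames.append(
            pd.DataFrame(
                {
                    "read_id": [f"{library_id}-read-{read_no + i:08d}" for i in range(n)],
                    "precursor_id": m.precursor_id,
                    "aln_start": m.start + d5,
                    "aln_end": m.end + d3,
                    "strand": "+",
                    "is_primary": True,
                }
            )
        )
        read_no += n
    alignments = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["read_id", "precursor_id", "aln_start", "aln_end", "strand", "is_primary"]
    )
    truth_s = pd.Series(truth, name="true_count").reindex(
        [m.mature_id for m in annotation.matures]
    )
    truth_s.index.name = "mature_id"
    return alignments, truth_s


# ---------------------------------------------------------------------------
# targets, ground truth, counts
# ---------------------------------------------------------------------------

def gene_universe(config: SimulationConfig) -> list[str]:
    return [f"gene_{i:05d}" for i in range(config.n_genes)]


def generate_target_map(
    config: SimulationConfig, rng: np.random.Generator
) -> dict[str, list[str]]:
    """TargetScan-style family → predicted-target map over the gene universe."""
    genes = np.array(gene_universe(config))
    fam_ids = [f"miR-fam-{i:03d}" for i in range(config.n_families)]
    tmap: dict[str, list[str]] = {}
    if config.target_assignment == "disjoint":
        perm = rng.permutation(config.n_genes)
        for i, fam in enumerate(fam_ids):
            sel = perm[i * config.targets_per_family : (i + 1) * config.targets_per_family]
            tmap[fam] = sorted(genes[sel])
    else:
        for fam in fam_ids:
            sel = rng.choice(config.n_genes, size=config.targets_per_family, replace=False)
            tmap[fam] = sorted(genes[sel])
    return tmap


def build_ground_truth(
    annotation: Annotation,
    true_mature_counts: pd.Series,
    target_map: dict[str, list[str]],
    config: SimulationConfig,
) -> GroundTruth:
    """Derive per-family effects δ_f = δ_max · a_f / max(a) from true counts.

    a_f is the log10 family-summed within-window read count; families with
    zero counts have undefined abundance and δ_f = 0.  The per-gene applied
    effect is the maximum δ_f over families predicting that gene.
    """
    fam_table = aggregate_families(true_mature_counts, annotation.families)
    abundance = fam_table["abundance_log10"]
    a = abundance.to_numpy(dtype=float)
    amax = np.nanmax(a) if np.isfinite(a).any() else np.nan
    if not np.isfinite(amax) or amax <= 0:
        delta = pd.Series(0.0, index=abundance.index)
    else:
        delta = pd.Series(
            np.where(np.isfinite(a), np.clip(a, 0.0, None) / amax, 0.0) * config.max_effect_log2,
            index=abundance.index,
        )
    delta.name = "delta_log2"

    genes = gene_universe(config)
    dg = pd.Series(0.0, index=pd.Index(genes, name="gene_id"), name="delta_log2")
    for fam, targets in target_map.items():
        d = float(delta.get(fam, 0.0))
        if d > 0:
            sel = dg.loc[targets]
            dg.loc[targets] = np.maximum(sel.to_numpy(), d)
    return GroundTruth(
        delta_family=delta,
        delta_gene=dg,
        abundance_log10=abundance,
        target_map={k: list(v) for k, v in target_map.items()},
    )


def simulate_counts(
    ground_truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Negative-binomial gene × sample counts with target de-repression.

    mean(gene, sample) = baseline_gene · 2^(δ_gene · I[sample in treatment]);
    variance = mean + dispersion · mean².  Means are capped at ``mean_cap``
    so extreme baselines stay overflow-safe.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    genes = list(ground_truth.delta_gene.index)
    lo, hi = config.baseline_mean_log10_range
    baseline = np.power(10.0, rng.uniform(lo, hi, size=len(genes)))
    delta = ground_truth.delta_gene.to_numpy(dtype=float)

    mu_ctl = np.minimum(baseline, config.mean_cap)
    mu_trt = np.minimum(baseline * np.power(2.0, delta), config.mean_cap)
    r = 1.0 / config.nb_dispersion

    cols = {}
    conditions = {}
    for i in range(config.n_samples_per_condition):
        name = f"ctl_{i + 1}"
        cols[name] = rng.negative_binomial(r, r / (r + mu_ctl))
        conditions[name] = "control"
    for i in range(config.n_samples_per_condition):
        name = f"t6b_{i + 1}"
        cols[name] = rng.negative_binomial(r, r / (r + mu_trt))
        conditions[name] = "treatment"
    counts = pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))
    cond = pd.Series(conditions, name="condition")
    cond.index.name = "sample"
    return counts, cond


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the whole generator with one seeded RNG stream.

    Small-RNA libraries share per-mature expected abundance (miRISC
    inhibition leaves miRNA levels unchanged); ground-truth family abundance
    — and hence δ_f — comes from the control library.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    annotation = generate_annotation(config, rng)
    expression = draw_mature_expression(annotation, config, rng)

    labels = list(SMALL_RNA_LIBRARY_LABELS[: max(1, config.n_small_rna_libraries)])
    alignments: dict[str, pd.DataFrame] = {}
    truths: dict[str, pd.Series] = {}
    for label in labels:
        aln, truth = simulate_small_rna_alignments(
            annotation, config, rng, expression=expression, library_id=label
        )
        alignments[label] = aln
        truths[label] = truth

    target_map = generate_target_map(config, rng)
    ground_truth = build_ground_truth(annotation, truths[labels[0]], target_map, config)
    counts, conditions = simulate_counts(ground_truth, config, rng)
    return SimulatedDataset(
        config=config,
        annotation=annotation,
        alignments=alignments,
        true_mature_counts=truths,
        target_map=target_map,
        ground_truth=ground_truth,
        counts=counts,
        conditions=conditions,
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_fasta(precursors: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for pid, seq in precursors.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(annotation: Annotation, path: str | Path) -> None:
    """miRBase-dialect GFF3: precursors as miRNA_primary_transcript, matures
    as miRNA features with Derives_from, 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for pid, seq in annotation.precursors.items():
            fh.write(
                f"{pid}\tderepress-sim\tmiRNA_primary_transcript\t1\t{len(seq)}\t.\t+\t.\t"
                f"ID={pid};Name={pid}\n"
            )
            for m in annotation.matures:
                if m.precursor_id != pid:
                    continue
                fh.write(
                    f"{pid}\tderepress-sim\tmiRNA\t{m.start}\t{m.end}\t.\t+\t.\t"
                    f"ID={m.mature_id};Name={m.mature_id};Derives_from={pid}\n"
                )


def write_sam(
    alignments: pd.DataFrame, precursors: dict[str, str], path: str | Path
) -> None:
    """Write alignments as a valid SAM file with @SQ headers for every precursor."""
    refs = list(precursors)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": pid, "LN": len(precursors[pid])} for pid in refs],
    }
    ref_idx = {pid: i for i, pid in enumerate(refs)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        hdr = out.header
        for row in alignments.itertuples(index=False):
            a = pysam.AlignedSegment(hdr)
            a.query_name = row.read_id
            a.flag = (0 if row.strand == "+" else 16) | (0 if row.is_primary else 256)
            a.reference_id = ref_idx[row.precursor_id]
            a.reference_start = int(row.aln_start) - 1
            a.mapping_quality = 255
            length = int(row.aln_end) - int(row.aln_start) + 1
            a.cigartuples = [(0, length)]
            a.query_sequence = precursors[row.precursor_id][
                int(row.aln_start) - 1 : int(row.aln_end)
            ]
            out.write(a)


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write every pipeline input (and the ground truth) under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["fasta"] = outdir / "precursors.fa"
    write_fasta(ds.annotation.precursors, paths["fasta"])

    paths["gff3"] = outdir / "matures.gff3"
    write_gff3(ds.annotation, paths["gff3"])

    for label, aln in ds.alignments.items():
        p = outdir / f"smallrna_{label}.sam"
        write_sam(aln, ds.annotation.precursors, p)
        paths[f"sam_{label}"] = p

    paths["families"] = outdir / "families.tsv"
    ds.annotation.families.to_csv(paths["families"], sep="\t", index=False)

    paths["targets"] = outdir / "targets.tsv"
    with open(paths["targets"], "w") as fh:
        fh.write("family_id\tgene_id\n")
        for fam in sorted(ds.target_map):
            for gene in ds.target_map[fam]:
                fh.write(f"{fam}\t{gene}\n")

    paths["counts"] = outdir / "counts.tsv"
    ds.counts.to_csv(paths["counts"], sep="\t")

    paths["conditions"] = outdir / "conditions.tsv"
    ds.conditions.to_frame().to_csv(paths["conditions"], sep="\t")

    paths["ground_truth"] = outdir / "ground_truth.json"
    with open(paths["ground_truth"], "w") as fh:
        json.dump(
            {
                "max_effect_log2": ds.config.max_effect_log2,
                "delta_per_family": {k: float(v) for k, v in ds.ground_truth.delta_family.items()},
                "abundance_log10": {
                    k: (None if not np.isfinite(v) else float(v))
                    for k, v in ds.ground_truth.abundance_log10.items()
                },
                "true_mature_counts": {
                    label: {k: int(v) for k, v in s.items()}
                    for label, s in ds.true_mature_counts.items()
                },
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    return paths
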