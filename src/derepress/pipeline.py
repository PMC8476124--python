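"""End-to-end orchestration: simulate → quant → diffexpr → derepress.

A run is configured by a single (YAML-backed) dict; every run writes its
resolved configuration, input digests, per-stage row counts and seed into a
manifest, and identical config + seed reproduces byte-identical analysis
tables.  On a stage failure the manifest is written with ``valid: false``
and the failing stage named, then the error propagates.
"""

from __future__ import annotations

import copy
import datetime
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, diffexpr, io, quant, simulate
from .derepression import assemble_bubble_table, cdf_compare, derepression_table
from .errors import InputError

logger = logging.getLogger("derepress")

DEFAULT_CONFIG: dict = {
    "simulate": {},  # SimulationConfig overrides; stage skipped if "inputs" given
    "inputs": None,  # {gff3, sam: {label: path}, families, targets, counts, conditions, external_lfc}
    "quant": {"window": 4, "abundance_library": "control"},
    "diffexpr": {"pseudocount": 0.5, "min_mean": 10.0},
    "derepress": {
        "m_min": 10,
        "per_family_background": True,
        "compute_ks": True,
        "n_cdf_families": 3,
    },
}


def load_config(path: str | Path | None) -> dict:
    config = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(config.get(key), dict):
                config[key].update(val)
            else:
                config[key] = val
    return config


def _stage(name: str, msg: str) -> None:
    logger.info("[%s] %s", name, msg)


def run_pipeline(config: dict, outdir: str | Path, seed: int | None = None) -> Path:
    """Run every stage, writing all outputs plus a manifest under ``outdir``.

    Returns the output directory.  ``seed`` overrides the simulation seed in
    the config.  Analysis tables are deterministic given (config, seed).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "derepress-seq",
        "version": __version__,
        "started": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "seed": seed,
        "valid": False,
        "row_counts": {},
        "input_digests": {},
    }
    stage = "setup"
    try:
        inputs = config.get("inputs")
        sim_dir = outdir / "inputs"

        if inputs is None:
            stage = "simulate"
            sim_conf = dict(config.get("simulate") or {})
            if seed is not None:
                sim_conf["rng_seed"] = int(seed)
            sim_config = simulate.SimulationConfig.from_dict(sim_conf)
            _stage(stage, f"simulating dataset (seed={sim_config.rng_seed})")
            ds = simulate.simulate_dataset(sim_config)
            paths = simulate.write_dataset(ds, sim_dir)
            inputs = {
                "gff3": str(paths["gff3"]),
                "families": str(paths["families"]),
                "targets": str(paths["targets"]),
                "counts": str(paths["counts"]),
                "conditions": str(paths["conditions"]),
                "sam": {
                    label: str(paths[f"sam_{label}"])
                    for label in ds.alignments
                },
            }
            manifest["simulated"] = True
        else:
            manifest["simulated"] = False

        for key, val in sorted(inputs.items()):
            if isinstance(val, dict):
                for label, p in sorted(val.items()):
                    manifest["input_digests"][f"{key}:{label}"] = io.sha256_of(p)
            elif val is not None and Path(str(val)).is_file():
                manifest["input_digests"][key] = io.sha256_of(val)

        # ------------------------------------------------------------- quant
        stage = "quant"
        qconf = config["quant"]
        families = io.read_families(inputs["families"])
        annotations = quant.read_annotation(inputs["gff3"], families=families)
        mature_counts: dict[str, pd.Series] = {}
        qc_all: dict[str, dict] = {}
        for label, sam_path in sorted(inputs.get("sam", {}).items()):
            _stage(stage, f"counting {label} library ({sam_path})")
            aln = quant.read_alignments(sam_path)
            counts_m, qc = quant.count_mature(aln, annotations, window=qconf["window"])
            mature_counts[label] = counts_m
            qc_all[label] = qc
            counts_m.rename("count").to_frame().to_csv(
                outdir / f"mature_counts_{label}.tsv", sep="\t"
            )
            manifest["row_counts"][f"mature_counts_{label}"] = int(len(counts_m))
        io.write_json(qc_all, outdir / "quant_qc.json")

        ab_label = qconf.get("abundance_library", "control")
        if ab_label not in mature_counts:
            ab_label = sorted(mature_counts)[0]
        abundance_table = quant.aggregate_families(mature_counts[ab_label], families)
        abundance_table.to_csv(outdir / "family_abundance.tsv", sep="\t")
        manifest["row_counts"]["family_abundance"] = int(len(abundance_table))

        if len(mature_counts) >= 2:
            labels = sorted(mature_counts)
            pair, rho = quant.compare_mirna_abundance(
                mature_counts[labels[0]], mature_counts[labels[1]]
            )
            pair.to_csv(outdir / "abundance_comparison.tsv", sep="\t")
            io.write_json(
                {"libraries": labels[:2], "spearman_rho": rho},
                outdir / "abundance_comparison.json",
            )

        # ---------------------------------------------------------- diffexpr
        stage = "diffexpr"
        dconf = config["diffexpr"]
        if inputs.get("external_lfc"):
            _stage(stage, f"ingesting external fold changes ({inputs['external_lfc']})")
            fc = diffexpr.read_external_lfc(inputs["external_lfc"], min_mean=dconf["min_mean"])
            manifest["lfc_source"] = "external"
        else:
            _stage(stage, "median-of-ratios normalisation + pseudocount log2FC")
            counts = io.read_counts(inputs["counts"])
            conditions = io.read_conditions(inputs["conditions"])
            fc = diffexpr.fold_changes_from_counts(
                counts, conditions,
                pseudocount=dconf["pseudocount"], min_mean=dconf["min_mean"],
            )
            manifest["lfc_source"] = "median_ratio_pseudocount"
        fc.to_csv(outdir / "fold_changes.tsv", sep="\t")
        manifest["row_counts"]["fold_changes"] = int(len(fc))
        manifest["row_counts"]["expressed_genes"] = int(fc["expressed"].sum())

        # --------------------------------------------------------- derepress
        stage = "derepress"
        rconf = config["derepress"]
        target_map = io.read_targets(inputs["targets"])
        universe = set(fc.index)
        missing_targets = {
            fam: len([g for g in genes if g not in universe])
            for fam, genes in target_map.items()
        }
        n_missing = int(sum(missing_targets.values()))
        if n_missing:
            _stage(stage, f"{n_missing} predicted-target genes absent from the fold-change table")

        abundance = abundance_table["abundance_log10"]
        records = derepression_table(
            fc, target_map, abundance=abundance,
            m_min=rconf["m_min"],
            per_family_background=rconf["per_family_background"],
            compute_ks=rconf["compute_ks"],
        )
        records.to_csv(outdir / "derepression.tsv", sep="\t", index=False)
        manifest["row_counts"]["derepression"] = int(len(records))
        manifest["row_counts"]["families_scored"] = int((records["status"] == "ok").sum())

        bubble = assemble_bubble_table(records)
        bubble.to_csv(outdir / "bubble_table.tsv", sep="\t", index=False)
        manifest["row_counts"]["bubble_table"] = int(len(bubble))

        # CDF curves for the most de-repressed families
        scored = records[records["status"] == "ok"].copy()
        scored["absz"] = scored["z"].abs()
        top = scored.sort_values(["absz", "family_id"], ascending=[False, True]).head(
            int(rconf["n_cdf_families"])
        )
        expressed = fc[fc["expressed"]]
        for fam in top["family_id"]:
            comp = cdf_compare(expressed, set(target_map[fam]))
            curve = pd.concat(
                [
                    comp.target_curve.assign(set="targets"),
                    comp.background_curve.assign(set="background"),
                ],
                ignore_index=True,
            )
            curve.to_csv(outdir / f"cdf_{fam}.tsv", sep="\t", index=False)

        summary = {
            "config": _jsonable(config),
            "seed": seed,
            "missing_targets": n_missing,
            "families_total": int(len(records)),
            "families_scored": int((records["status"] == "ok").sum()),
            "cdf_families": list(top["family_id"]),
        }
        io.write_json(summary, outdir / "summary.json")

        manifest["valid"] = True
    except Exception as err:
        manifest["failed_stage"] = stage
        manifest["error"] = str(err)
        manifest["finished"] = datetime.datetime.now(datetime.timezone.utc).isoformat()
        io.write_json(_jsonable(manifest), outdir / "manifest.json")
        raise
    manifest["config"] = _jsonable(config)
    manifest["finished"] = datetime.datetime.now(datetime.timezone.utc).isoformat()
    io.write_json(_jsonable(manifest), outdir / "manifest.json")
    _stage("done", f"outputs in {outdir}")
    return outdir


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj


#: analysis tables whose bytes must be identical across reruns with the same
#: config + seed (the manifest itself carries timestamps and is excluded)
ANALYSIS_TABLE_GLOBS = [
    "mature_counts_*.tsv",
    "family_abundance.tsv",
    "abundance_comparison.tsv",
    "fold_changes.tsv",
    "derepression.tsv",
    "bubble_table.tsv",
    "cdf_*.tsv",
]


def analysis_tables(outdir: str | Path) -> list[Path]:
    outdir = Path(outdir)
    found: list[Path] = []
    for pattern in ANALYSIS_TABLE_GLOBS:
        found.extend(sorted(outdir.glob(pattern)))
    return found


def save_config(config: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_jsonable(config), fh, sort_keys=True)
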