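"""End-to-end orchestration of the epigenomic and pathology arms.

``run_generation`` executes, for one generation: window counting (or
count simulation), normalization, common-dispersion estimation, the
exact NB test, DMR calling with the threshold grid, the permutation
null, DMR-restricted PCA, and annotation; it writes tables plus a
deterministic JSON summary.  ``run_overlap`` computes the cross-
generation Venn and ``run_pathology`` the cohort statistics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import annotation as ann
from . import pathology as pth
from .difftest import estimate_common_dispersion, normalize, test_windows
from .dmr import DmrConfig, DmrSet, call_dmrs, classify_multiple_window, threshold_table
from .permutation import dmr_pca, permutation_null
from .synthetic import (
    CohortSimConfig,
    CountSimConfig,
    SimGenome,
    generate_gene_annotation,
    generate_genome,
    simulate_cohort,
    simulate_window_counts,
    write_genes_bed,
)
from .windows import GenomeWindows, bin_reads, filter_windows

log = logging.getLogger("dmrpipe")

__all__ = ["run_generation", "run_overlap", "run_pathology", "load_config"]


def load_config(path: str | Path) -> dict:
    import yaml

    with open(path) as fh:
        return yaml.safe_load(fh)


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def write_json(payload: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(payload), fh, indent=2, sort_keys=True)
        fh.write("\n")


def _simulate_inputs(cfg: dict, seed: int, generation: str):
    genome_cfg = dict(cfg.get("genome", {}))
    chrom_lengths = genome_cfg.pop(
        "chrom_lengths", {f"chr{i + 1}": 1_000_000 for i in range(5)}
    )
    genome = generate_genome(chrom_lengths, seed=seed, **genome_cfg)
    genes_cfg = cfg.get("genes", {})
    genes = generate_gene_annotation(
        genome, n_genes=int(genes_cfg.get("n_genes", 40)), seed=seed + 1
    )
    counts_cfg = dict(cfg.get("counts", {}))
    counts_cfg.setdefault("seed", seed + 2)
    counts_cfg["generation"] = generation
    if "dmr_span_windows" in counts_cfg:
        counts_cfg["dmr_span_windows"] = tuple(counts_cfg["dmr_span_windows"])
    sim_cfg = CountSimConfig(**counts_cfg)
    matrix, truth = simulate_window_counts(genome, sim_cfg)
    return genome, genes, matrix, truth


def run_generation(
    config: dict,
    generation: str = "F3",
    out_dir: str | Path | None = None,
) -> dict:
    """Run the epigenomic arm for one generation; returns the summary.

    ``config`` carries optional sections ``simulate`` (genome / genes /
    counts generators), ``reads`` (sample -> BED/SAM path plus
    ``groups`` and ``chrom_lengths`` for a file-based run), ``dmr``,
    ``permutation`` and ``annotation``; every stage's parameters and
    seeds end up in the summary.
    """
    seed = int(config.get("seed", 0))
    out = Path(out_dir or config.get("output_dir", "dmrpipe_out")) / generation
    out.mkdir(parents=True, exist_ok=True)

    genes = None
    genome: SimGenome | None = None
    truth = None
    if "reads" in config:
        rcfg = config["reads"]
        gw = GenomeWindows(
            int(config.get("window_size", 100)),
            tuple(rcfg["chrom_lengths"]),
            tuple(rcfg["chrom_lengths"].values()),
        )
        matrix = bin_reads(rcfg["files"], rcfg["groups"], gw, generation=generation)
    else:
        genome, genes, matrix, truth = _simulate_inputs(
            config.get("simulate", {}), seed, generation
        )
        genome.write_fasta(out / "genome.fa")
        write_genes_bed(genes, out / "genes.bed")
        truth.regions.to_csv(out / "truth_regions.tsv", sep="\t", index=False)
    log.info("generation %s: %d windows x %d samples", generation,
             matrix.n_windows, matrix.n_samples)
    matrix.write_tsv(out / "window_counts.tsv")

    min_total = int(config.get("min_total", 10))
    filtered = filter_windows(matrix, min_total)
    factors = normalize(filtered, config.get("normalization", "total"))
    disp_cfg = config.get("dispersion", "auto")
    if disp_cfg == "auto":
        phi = estimate_common_dispersion(filtered, factors).phi
    else:
        phi = float(disp_cfg)
    log.info("dispersion phi = %.4g", phi)

    results = test_windows(filtered, factors, phi=phi)
    results.to_csv(out / "window_tests.tsv", sep="\t", index=False)

    dmr_cfg = DmrConfig(**{
        k: (tuple(v) if k == "threshold_grid" else v)
        for k, v in config.get("dmr", {}).items()
    })
    dmr_set = call_dmrs(results, matrix.windows, dmr_cfg, name=generation)
    dmr_set.write_tsv(out / "dmrs.tsv")
    dmr_set.write_bed(out / "dmrs.bed")
    total, multiple, hist = classify_multiple_window(dmr_set)
    tt = threshold_table(results, matrix.windows, dmr_cfg)
    tt.to_csv(out / "threshold_table.tsv", sep="\t", index=False)

    perm_cfg = config.get("permutation", {})
    perm = None
    if perm_cfg.get("enabled", True):
        perm = permutation_null(
            filtered,
            dmr_cfg,
            factors,
            scheme=perm_cfg.get("scheme", "auto"),
            max_perms=int(perm_cfg.get("max_perms", 200)),
            seed=seed + 10,
            reestimate_dispersion=bool(perm_cfg.get("reestimate_dispersion", True)),
        )
        perm.to_frame().to_csv(out / "permutation_null.tsv", sep="\t", index=False)

    pca_summary = None
    if len(dmr_set) >= 1:
        try:
            pca = dmr_pca(filtered, dmr_set, factors)
            pca.to_frame().to_csv(out / "pca_scores.tsv", sep="\t", index=False)
            pca_summary = {
                "explained_variance_ratio": list(pca.explained_variance_ratio),
            }
        except ValueError as exc:
            log.warning("PCA skipped: %s", exc)

    annot_cfg = config.get("annotation", {})
    annot_summary = None
    if genome is not None and len(dmr_set) > 0:
        annot = ann.cpg_annotate(
            dmr_set, genome, desert_threshold=float(annot_cfg.get("desert_threshold", 10.0))
        )
        annot.to_csv(out / "dmr_annotation.tsv", sep="\t", index=False)
        assoc, frac = ann.associate_genes(
            dmr_set, genes, max_dist=int(annot_cfg.get("max_dist", 10_000))
        )
        assoc.to_csv(out / "gene_associations.tsv", sep="\t", index=False)
        clusters = ann.detect_clusters(
            dmr_set,
            cluster_gap=int(annot_cfg.get("cluster_gap", 2_000_000)),
            min_size=int(annot_cfg.get("min_size", 3)),
        )
        annot_summary = {
            "mean_cpg_density_per_100bp": float(
                annot["cpg_density_per_100bp"].mean()
            ),
            "fraction_cpg_desert": float(annot["cpg_desert"].mean()),
            "fraction_gene_associated": frac,
            "n_clusters": int(len(set(clusters[clusters >= 0]))),
        }

    summary: dict[str, Any] = {
        "generation": generation,
        "seed": seed,
        "n_windows": matrix.n_windows,
        "n_windows_tested": filtered.n_windows,
        "n_samples": matrix.n_samples,
        "min_total": min_total,
        "normalization": factors.method,
        "phi": phi,
        "dmr_config": asdict(dmr_cfg),
        "n_dmrs": total,
        "n_multiple_window_dmrs": multiple,
        "sig_window_histogram": hist,
        "threshold_table": tt.to_dict(orient="records"),
    }
    if truth is not None:
        summary["truth"] = {
            "n_regions": int(len(truth.regions)),
            "recall": truth_recall(dmr_set, truth.regions),
        }
    if perm is not None:
        summary["permutation"] = {
            "scheme": perm.scheme,
            "n_labelings": perm.n_labelings,
            "n_permutations": perm.n_permutations,
            "observed_count": perm.observed_count,
            "max_null_count": int(perm.null_counts.max()) if perm.n_permutations else None,
            "empirical_p": perm.empirical_p,
        }
    if pca_summary is not None:
        summary["pca"] = pca_summary
    if annot_summary is not None:
        summary["annotation"] = annot_summary
    write_json(summary, out / "summary.json")
    return summary


def truth_recall(dmr_set: DmrSet, truth_regions: pd.DataFrame) -> float:
    """Fraction of truth regions overlapped (>= 1 bp) by a called DMR."""
    if len(truth_regions) == 0:
        return float("nan")
    hit = 0
    for _, r in truth_regions.iterrows():
        for d in dmr_set:
            if d.chrom == r["chrom"] and d.start < r["end"] and r["start"] < d.end:
                hit += 1
                break
    return hit / len(truth_regions)


def run_overlap(named_sets: dict[str, DmrSet], out_path: str | Path | None = None) -> dict:
    """Cross-generation DMR overlap (Venn cells)."""
    if len(named_sets) < 2:
        raise ValueError("need at least 2 DMR sets")
    res = ann.overlap_sets(named_sets)
    payload = {
        "sets": {k: len(v) for k, v in named_sets.items()},
        "cells": res.cells,
        "union_size": res.union_size,
    }
    if out_path is not None:
        write_json(payload, out_path)
    return payload


def run_pathology(
    observations: pd.DataFrame,
    measures: pd.DataFrame,
    adipocytes: pd.DataFrame,
    breeding: pd.DataFrame,
    out_dir: str | Path | None = None,
    control_lineage: str = "control",
    sd_mult: float = 1.5,
) -> dict:
    """Pathology arm for one generation: disease calls, frequencies,
    obesity, fertility and disease burden, with group statistics."""
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # tissue disease calls and Fisher comparisons, per sex
    all_calls = []
    tissue_stats: dict[str, dict] = {}
    for sex, obs_sex in observations.groupby("sex"):
        calls = pth.call_diseases(obs_sex, control_lineage)
        calls["sex"] = sex
        all_calls.append(calls)
        for tissue, g in calls.groupby("tissue"):
            by_lin = {
                lin: (int(gg["diseased"].sum()), len(gg))
                for lin, gg in g.groupby("lineage")
            }
            entry: dict[str, Any] = {}
            for lin, (aff, tot) in by_lin.items():
                entry[f"{lin}_affected"] = aff
                entry[f"{lin}_total"] = tot
                entry[f"{lin}_frequency"] = aff / tot
            if control_lineage in by_lin:
                c_aff, c_tot = by_lin[control_lineage]
                for lin, (aff, tot) in by_lin.items():
                    if lin != control_lineage:
                        entry["fisher_p"] = pth.frequency_test(
                            aff, tot, c_aff, c_tot
                        ).p_value
            tissue_stats[f"{sex}:{tissue}"] = entry
    calls = pd.concat(all_calls, ignore_index=True)
    if out is not None:
        calls.to_csv(out / "disease_calls.tsv", sep="\t", index=False)

    # obesity per sex against control stats
    adi_metric = {
        aid: pth.adipocyte_metric(
            [g2["area_um2"].to_numpy() for _, g2 in g.groupby("image")], top_n=20
        )
        for aid, g in adipocytes.groupby("animal_id")
    }
    meas = measures.copy()
    meas["bmi"] = [
        pth.bmi(w, l) for w, l in zip(meas["weight_g"], meas["length_cm"])
    ]
    meas["adipocyte_area"] = meas["animal_id"].map(adi_metric)
    obesity_stats: dict[str, dict] = {}
    phenotypes = []
    for sex, g in meas.groupby("sex"):
        ctl = g[g["lineage"] == control_lineage]
        control_stats = {
            m: (float(ctl[m].mean()), float(ctl[m].std(ddof=1)))
            for m in ("bmi", "adipocyte_area", "adiposity_score")
        }
        pheno = g.apply(
            lambda row: pth.obesity_classify(
                {m: row[m] for m in ("bmi", "adipocyte_area", "adiposity_score")},
                control_stats,
                sd_mult=sd_mult,
            ),
            axis=1,
        )
        dfp = pd.DataFrame(
            {"animal_id": g["animal_id"], "sex": sex, "lineage": g["lineage"],
             "phenotype": pheno}
        )
        phenotypes.append(dfp)
        by_lin = {
            lin: (int((gg["phenotype"] == "obese").sum()), len(gg))
            for lin, gg in dfp.groupby("lineage")
        }
        entry = {}
        for lin, (ob, tot) in by_lin.items():
            entry[f"{lin}_obese"] = ob
            entry[f"{lin}_total"] = tot
            entry[f"{lin}_frequency"] = ob / tot
        if control_lineage in by_lin and len(by_lin) > 1:
            c_ob, c_tot = by_lin[control_lineage]
            for lin, (ob, tot) in by_lin.items():
                if lin != control_lineage:
                    entry["fisher_p"] = pth.frequency_test(ob, tot, c_ob, c_tot).p_value
        obesity_stats[sex] = entry
    phenotype_df = pd.concat(phenotypes, ignore_index=True)
    if out is not None:
        phenotype_df.to_csv(out / "obesity_phenotypes.tsv", sep="\t", index=False)

    # continuous measures (t-tests)
    continuous: dict[str, dict] = {}
    for sex, g in meas.groupby("sex"):
        for col in ("puberty_age_days", "weaning_weight_g"):
            groups = {lin: gg[col].to_numpy() for lin, gg in g.groupby("lineage")}
            if control_lineage not in groups or len(groups) < 2:
                continue
            for lin, vals in groups.items():
                if lin == control_lineage:
                    continue
                cmp_ = pth.continuous_test(vals, groups[control_lineage])
                continuous[f"{sex}:{col}"] = {
                    "t": cmp_.statistic,
                    "p": cmp_.p_value,
                    f"{lin}_mean": float(np.mean(vals)),
                    f"{control_lineage}_mean": float(np.mean(groups[control_lineage])),
                }

    # fertility and parturition abnormalities
    fert = pth.fertility_rate(breeding).to_dict()
    parturition: dict[str, dict] = {}
    by_lin_breed = {
        lin: (int(g["n_abnormal_parturitions"].sum()), int(g["n_pregnancies"].sum()))
        for lin, g in breeding.groupby("lineage")
    }
    if control_lineage in by_lin_breed:
        c_ab, c_pr = by_lin_breed[control_lineage]
        for lin, (ab, pr) in by_lin_breed.items():
            entry = {"abnormal": ab, "pregnancies": pr,
                     "frequency": ab / pr if pr else float("nan")}
            if lin != control_lineage and pr and c_pr:
                entry["fisher_p"] = pth.frequency_test(ab, pr, c_ab, c_pr).p_value
            parturition[lin] = entry

    # disease burden: tissue calls plus obesity flags
    burden_input = calls[["animal_id", "lineage", "tissue", "diseased"]].copy()
    ob_rows = phenotype_df.rename(columns={"phenotype": "diseased"}).copy()
    ob_rows["diseased"] = ob_rows["diseased"] == "obese"
    ob_rows["tissue"] = "obesity"
    burden_input = pd.concat(
        [burden_input, ob_rows[["animal_id", "lineage", "tissue", "diseased"]]],
        ignore_index=True,
    )
    burden = pth.disease_burden(burden_input, control_lineage)

    report = {
        "tissues": tissue_stats,
        "obesity": obesity_stats,
        "continuous": continuous,
        "fertility_rate": fert,
        "parturition": parturition,
        "disease_burden": burden.to_dict(orient="records"),
    }
    if out is not None:
        write_json(report, out / "pathology_report.json")
    return report


def run_all(config: dict, out_dir: str | Path | None = None) -> dict:
    """Full study: per-generation epigenomic arm, overlap, pathology arm."""
    out = Path(out_dir or config.get("output_dir", "dmrpipe_out"))
    out.mkdir(parents=True, exist_ok=True)
    generations = config.get("generations", ["F1", "F2", "F3"])
    seed = int(config.get("seed", 0))
    summaries = {}
    dmr_sets: dict[str, DmrSet] = {}
    for i, gen in enumerate(generations):
        gcfg = dict(config)
        gcfg["seed"] = seed + 100 * i
        summary = run_generation(gcfg, generation=gen, out_dir=out)
        summaries[gen] = summary
        dmrs = pd.read_csv(out / gen / "dmrs.tsv", sep="\t")
        from .dmr import Dmr  # local import to rebuild sets from disk

        dmr_sets[gen] = DmrSet(
            dmrs=[
                Dmr(
                    chrom=r["chrom"], start=int(r["start"]), end=int(r["end"]),
                    seed_windows=(0,), n_significant_windows=int(r["n_significant_windows"]),
                    min_p=float(r["min_p"]), min_q=float(r["min_q"]),
                    max_abs_log2_fc=float(r["max_abs_log2_fc"]),
                )
                for _, r in dmrs.iterrows()
            ],
            config=DmrConfig(),
            name=gen,
        )
    overlap = None
    if len(dmr_sets) >= 2:
        overlap = run_overlap(dmr_sets, out / "overlap.json")

    pathology = None
    if config.get("pathology", {}).get("enabled", True):
        pcfg = dict(config.get("pathology", {}).get("cohort", {}))
        pcfg.setdefault("seed", seed + 999)
        obs, meas, adi, breed, _truth = simulate_cohort(CohortSimConfig(**pcfg))
        pathology = run_pathology(obs, meas, adi, breed, out / "pathology")

    full = {"generations": summaries, "overlap": overlap, "pathology": pathology}
    write_json(full, out / "run_all_summary.json")
    return full
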