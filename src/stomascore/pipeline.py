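"""Pipeline stages over a study directory.

Each stage reads its inputs from a study directory, writes its outputs back
into it (atomically, via temp-file rename) and returns the paths it wrote.
Stages check for their upstream artefacts before doing any work and raise
``MissingArtifactError`` naming the missing file. ``run_stage`` dispatches by
stage name; the ``report`` stage aggregates every stage output plus a manifest
with the config snapshot, seeds and input checksums.

All thresholds default to the standard values used throughout this kind of
analysis: DP > 22, FS < 0.2, |ReadPosRankSum| < 2, mac 3, site missingness
15%, sample missingness 50%, control tolerance 2.5% with 1,000 draws, 100 bp
Tajima windows, 500 km pairing radius, alpha 0.01, 100 permutations and 100
modern subsamples.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from . import climate as climate_mod
from . import genesets, geopair, popgen, score as score_mod, synth, variants

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "filter",
    "constraint-scan",
    "adaptation-scan",
    "pair",
    "climate",
    "score",
    "temporal-test",
    "report",
)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "synth": {},
    "filters": {
        "min_mac": 3,
        "mac_mode": "carriers",
        "max_site_missing": 0.15,
        "max_sample_missing": 0.5,
        "dp_min": 22.0,
        "fs_max": 0.2,
        "rprs_abs_max": 2.0,
    },
    "controls": {"tol": 0.025, "n_sets": 1000},
    "tajima_window_bp": 100,
    "pairing": {"max_km": 500.0, "order_policy": "sample_id"},
    "climate": {"alpha": 0.01, "period": 12},
    "score": {"n_perm": 100, "n_subsamples": 100, "permutation_mode": "shuffle"},
    "kmeans": {"k_min": 2, "k_max": 15},
}


class MissingArtifactError(FileNotFoundError):
    pass


def merge_config(overrides: dict | None) -> dict:
    cfg = copy.deepcopy(DEFAULT_CONFIG)

    def merge(dst, src):
        for k, v in src.items():
            if isinstance(v, dict) and isinstance(dst.get(k), dict):
                merge(dst[k], v)
            else:
                dst[k] = v

    if overrides:
        merge(cfg, overrides)
    return cfg


def _require(outdir: Path, *names: str) -> None:
    for name in names:
        if not (outdir / name).exists():
            raise MissingArtifactError(
                f"stage input {name!r} not found in {outdir}; run the upstream stage first"
            )


def _write_json(obj, path: Path) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    with os.fdopen(fd, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_jsonable)
    os.replace(tmp, path)


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    os.close(fd)
    df.to_csv(tmp, sep="\t", index=False)
    os.replace(tmp, path)


# ---------------------------------------------------------------------------
# shared loaders


def load_filtered(outdir: Path):
    _require(outdir, "filtered.vcf", "genes.gff3", "focus_genes.tsv")
    ds = variants.read_vcf(str(outdir / "filtered.vcf"))
    genes = genesets.read_gff3(str(outdir / "genes.gff3"))
    focus = list(pd.read_csv(outdir / "focus_genes.tsv", sep="\t")["gene_id"])
    assignments = genesets.assign_snps_to_genes(ds, genes)
    return ds, genes, focus, assignments


def load_samples(outdir: Path) -> pd.DataFrame:
    _require(outdir, "samples.tsv")
    df = pd.read_csv(outdir / "samples.tsv", sep="\t")
    if "region_tags" in df.columns:
        df["region_tags"] = df["region_tags"].fillna("")
    return df


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config: dict, outdir: Path) -> dict:
    synth_kwargs = dict(config.get("synth", {}))
    synth_kwargs.setdefault("seed", config["seed"])
    for key in ("hist_years", "mod_years", "lat_range", "lon_range", "gene_length_range",
                "climate_years"):
        if key in synth_kwargs and isinstance(synth_kwargs[key], list):
            synth_kwargs[key] = tuple(synth_kwargs[key])
    cfg = synth.SynthConfig(**synth_kwargs)
    study = synth.generate_study(cfg)
    paths = synth.write_study(study, str(outdir))
    logger.info("simulate: wrote %d sites, %d samples", study.dataset.n_sites, len(study.samples))
    return paths


def stage_filter(config: dict, outdir: Path) -> dict:
    _require(outdir, "variants.vcf", "genes.gff3")
    ds = variants.read_vcf(str(outdir / "variants.vcf"))
    fcfg = variants.FilterConfig(**config["filters"])
    ds_q, log_q = variants.apply_site_quality(ds, fcfg)
    ds_f, log_f = variants.filter_dataset(ds_q, fcfg)
    variants.write_vcf(ds_f, str(outdir / "filtered.vcf"))

    genes = genesets.read_gff3(str(outdir / "genes.gff3"))
    assignments = genesets.assign_snps_to_genes(ds_f, genes)
    sites = ds_f.sites[["chrom", "pos", "ref", "alt"]].copy()
    cls = assignments.drop_duplicates("site_index").set_index("site_index")["effect_class"]
    sites["effect_class"] = [cls.get(i, "OTHER") for i in range(len(sites))]
    _write_tsv(sites, outdir / "site_classes.tsv")
    _write_json({"quality": log_q, "filters": log_f}, outdir / "filter_log.json")
    return {"filtered": str(outdir / "filtered.vcf")}


def _epoch_split(ds, samples: pd.DataFrame):
    meta = samples.set_index("sample_id")
    idx = {"historical": [], "modern": []}
    for i, s in enumerate(ds.samples):
        if s in meta.index:
            idx[meta.loc[s, "epoch"]].append(i)
    return {ep: ds.take_samples(ix) for ep, ix in idx.items() if ix}


def _group_tests(gene_stats: pd.DataFrame, draws: pd.DataFrame, focus: list[str], columns):
    """Group empirical tests and per-gene decile flags for the given stat columns."""
    stats_by_gene = gene_stats.set_index("gene_id")
    results = {}
    flags = {}
    for col, tail in columns.items():
        focus_vals = stats_by_gene.loc[focus, col].to_numpy(dtype=float)
        focus_mean = float(np.nanmean(focus_vals))
        control_vals = stats_by_gene[col].reindex(draws["control_gene"]).to_numpy(dtype=float)
        dd = draws.assign(value=control_vals)
        control_means = dd.groupby("draw_id")["value"].mean().to_numpy()
        test = genesets.empirical_group_test(focus_mean, control_means, tail)
        results[col] = {
            "focus_mean": focus_mean,
            "control_mean": float(np.nanmean(control_means)),
            "tail": tail,
            "p_empirical": test.p_empirical,
        }
        per_gene = {}
        for gid, grp in dd.groupby("focus_gene"):
            per_gene[gid] = genesets.per_gene_decile_flag(
                float(stats_by_gene.loc[gid, col]), grp["value"].to_numpy()
            )
        flags[col] = per_gene
    return results, flags


def stage_constraint_scan(config: dict, outdir: Path) -> dict:
    """Diversity constraint screen: pi, theta_W, SNPs/bp and functional-class
    proportions of the focus genes against length-matched control draws."""
    ds, genes, focus, assignments = load_filtered(outdir)
    samples = load_samples(outdir)
    lengths = genesets.gene_lengths(genes)
    draws = genesets.draw_length_matched_controls(
        focus,
        lengths,
        tol=config["controls"]["tol"],
        n_sets=config["controls"]["n_sets"],
        seed=config["seed"] + 11,
    )
    _write_tsv(draws, outdir / "control_draws.tsv")

    report = {}
    for epoch, sub in _epoch_split(ds, samples).items():
        sub_assign = assignments  # site indices unchanged by sample subsetting
        gene_stats = popgen.gene_pop_stats(sub, sub_assign, genes)
        # SNP-class proportions per gene (functional share)
        cc = variants.class_counts(sub_assign, gene_ids=list(genes))
        cc = cc[cc["gene_id"] != "__set__"]
        merged = gene_stats.merge(
            cc[["gene_id", "prop_NONSYN", "prop_LOF"]], on="gene_id", how="left"
        )
        _write_tsv(merged, outdir / f"gene_stats_{epoch}.tsv")
        tests, flags = _group_tests(
            merged,
            draws,
            focus,
            {
                "pi_per_bp": "lower",
                "pi_max_site": "lower",
                "theta_w_per_bp": "lower",
                "snps_per_bp": "lower",
                "prop_NONSYN": "lower",
                "prop_LOF": "lower",
            },
        )
        report[epoch] = {"group_tests": tests, "per_gene_flags": flags}
    _write_json(report, outdir / "constraint_scan.json")
    return {"constraint_scan": str(outdir / "constraint_scan.json")}


def stage_adaptation_scan(config: dict, outdir: Path) -> dict:
    """Adaptation screen: windowed Tajima's D per gene and WC84 F_ST under the
    epoch scheme and a k-means climate scheme, against control draws."""
    _require(outdir, "control_draws.tsv")
    ds, genes, focus, assignments = load_filtered(outdir)
    samples = load_samples(outdir)
    draws = pd.read_csv(outdir / "control_draws.tsv", sep="\t")
    meta = samples.set_index("sample_id")
    window_bp = config["tajima_window_bp"]

    pop_schemes: dict[str, np.ndarray] = {
        "epoch": np.array([meta.loc[s, "epoch"] for s in ds.samples])
    }
    climate_path = outdir / "climate.tsv"
    if climate_path.exists():
        clim = pd.read_csv(climate_path, sep="\t")
        feats = (
            clim.pivot_table(
                index="location_id", columns="variable", values="value", aggfunc=["mean", "std"]
            )
        )
        feats.columns = ["_".join(c) for c in feats.columns]
        feats = feats.reindex(ds.samples).dropna()
        if len(feats) > 3:
            k_max = min(config["kmeans"]["k_max"], len(feats) - 1)
            assign = popgen.kmeans_populations(
                feats,
                k_range=range(config["kmeans"]["k_min"], k_max + 1),
                seed=config["seed"] + 13,
            )
            labels = assign.labels.reindex(ds.samples)
            if not labels.isna().any():
                pop_schemes["climate_kmeans"] = labels.to_numpy()

    report = {}
    for epoch, sub in _epoch_split(ds, samples).items():
        windows = popgen.tajima_d_windows(
            sub.sites["pos"].to_numpy(), sub.dosages, sub.sites["chrom"].to_numpy(), window_bp
        )
        _write_tsv(windows, outdir / f"tajima_windows_{epoch}.tsv")
        gene_stats = popgen.gene_pop_stats(sub, assignments, genes, windows=windows,
                                           window_bp=window_bp)
        tests, flags = _group_tests(gene_stats, draws, focus, {"tajima_d_mean": "two"})
        report[epoch] = {"group_tests": tests, "per_gene_flags": flags}

    fst_stats = popgen.gene_pop_stats(ds, assignments, genes, pop_schemes=pop_schemes)
    fst_cols = {c: "upper" for c in fst_stats.columns if c.startswith("fst_")}
    tests, flags = _group_tests(fst_stats, draws, focus, fst_cols)
    _write_tsv(fst_stats, outdir / "gene_fst.tsv")
    report["fst"] = {"group_tests": tests, "per_gene_flags": flags}
    _write_json(report, outdir / "adaptation_scan.json")
    return {"adaptation_scan": str(outdir / "adaptation_scan.json")}


def stage_pair(config: dict, outdir: Path) -> dict:
    samples = load_samples(outdir)
    rules = config.get("pairing", {}).get("exclusion_rules") or []
    pairs = geopair.pair_samples(
        samples,
        max_km=config["pairing"]["max_km"],
        order_policy=config["pairing"]["order_policy"],
        seed=config["seed"] + 17,
        exclusion_rules=rules,
    )
    _write_tsv(pairs, outdir / "pairs.tsv")
    return {"pairs": str(outdir / "pairs.tsv")}


def stage_climate(config: dict, outdir: Path) -> dict:
    _require(outdir, "climate.tsv", "pairs.tsv")
    clim = pd.read_csv(outdir / "climate.tsv", sep="\t")
    trends = climate_mod.climate_trends(
        clim, alpha=config["climate"]["alpha"], period=config["climate"]["period"]
    )
    _write_tsv(trends, outdir / "climate_trends.tsv")
    pairs = pd.read_csv(outdir / "pairs.tsv", sep="\t").fillna({"excluded_reason": ""})
    kept = pairs[pairs["kept"]].copy()
    samples = load_samples(outdir)
    loc = pd.Series(samples["sample_id"].to_numpy(), index=samples["sample_id"])
    for var in ("ppt", "tmax"):
        kept[f"climate_class_{var}"] = climate_mod.classify_pairs(kept, trends, loc, var)
    _write_tsv(kept, outdir / "pairs_classified.tsv")
    return {"trends": str(outdir / "climate_trends.tsv")}


def stage_score(config: dict, outdir: Path) -> dict:
    _require(outdir, "gene_effects.tsv")
    ds, genes, focus, assignments = load_filtered(outdir)
    samples = load_samples(outdir)
    effects = score_mod.load_gene_effects(str(outdir / "gene_effects.tsv"))
    indicators = score_mod.functional_indicator_matrix(ds, assignments, effects["gene_id"])
    scores = score_mod.density_scores(indicators, effects.set_index("gene_id")["effect"])
    meta = samples.set_index("sample_id")
    out = pd.DataFrame(
        {
            "sample_id": scores.index,
            "epoch": [meta.loc[s, "epoch"] if s in meta.index else "" for s in scores.index],
            "score": scores.to_numpy(),
        }
    )
    _write_tsv(out, outdir / "scores.tsv")
    indicators.reset_index(names="sample_id").to_csv(
        outdir / "indicators.tsv", sep="\t", index=False
    )
    return {"scores": str(outdir / "scores.tsv")}


def stage_temporal_test(config: dict, outdir: Path) -> dict:
    _require(outdir, "scores.tsv", "pairs.tsv", "indicators.tsv", "gene_effects.tsv")
    scores_df = pd.read_csv(outdir / "scores.tsv", sep="\t")
    scores = scores_df.set_index("sample_id")["score"]
    pairs_path = outdir / "pairs_classified.tsv"
    classified = pairs_path.exists()
    pairs = pd.read_csv(pairs_path if classified else outdir / "pairs.tsv", sep="\t")
    if "kept" in pairs.columns:
        pairs = pairs[pairs["kept"]]
    effects = score_mod.load_gene_effects(str(outdir / "gene_effects.tsv"))
    indicators = pd.read_csv(outdir / "indicators.tsv", sep="\t").set_index("sample_id")
    samples = load_samples(outdir)

    delta = score_mod.delta_and_wilcoxon(pairs, scores)
    perm = score_mod.permute_effect_labels(
        indicators,
        effects.set_index("gene_id")["effect"],
        pairs,
        n_perm=config["score"]["n_perm"],
        seed=config["seed"] + 19,
        mode=config["score"]["permutation_mode"],
    )
    report = {
        "n_pairs": delta.n_pairs,
        "mean_delta": delta.mean_delta,
        "wilcoxon_p": delta.wilcoxon_p,
        "wilcoxon_statistic": delta.wilcoxon_statistic,
        "permutation": {
            "observed_mean_delta": perm.observed_mean_delta,
            "rank": perm.rank,
            "n_perm": perm.n_perm,
            "null_mean": float(perm.null_means.mean()),
        },
        "fisher": {},
        "fisher_table_orientation": "rows: in group / out; cols: delta<0 / delta>=0",
    }
    deltas_out = delta.deltas.copy()
    if classified and "climate_class_ppt" in pairs.columns:
        cls = pairs.set_index(["hist_id", "mod_id"])["climate_class_ppt"]
        deltas_out["climate_class_ppt"] = [
            cls.get((h, m), "unmatched")
            for h, m in zip(deltas_out["hist_id"], deltas_out["mod_id"])
        ]
        matched = deltas_out[
            deltas_out["climate_class_ppt"].isin(["matching_increase", "matching_decrease"])
        ]
        for group in ("matching_increase", "matching_decrease"):
            if (matched["climate_class_ppt"] == group).any():
                res = score_mod.fisher_decrease_odds(
                    matched["delta"].to_numpy(),
                    (matched["climate_class_ppt"] == group).to_numpy(),
                )
                report["fisher"][group] = res
        try:
            report["delta_vs_ppt_direction"] = score_mod.delta_vs_climate_regression(
                matched["delta"].to_numpy(), matched["climate_class_ppt"]
            )
        except ValueError as exc:
            report["delta_vs_ppt_direction"] = {"error": str(exc)}
    _write_tsv(deltas_out, outdir / "deltas.tsv")

    report["latitude"] = score_mod.latitude_correlation(
        scores,
        samples,
        n_subsamples=config["score"]["n_subsamples"],
        seed=config["seed"] + 23,
    )
    # trim the bulky per-subsample list to summaries for the JSON report
    subs = report["latitude"].pop("modern_subsamples")
    report["latitude"]["modern_r_values"] = [s["r"] for s in subs]
    _write_json(report, outdir / "temporal_test.json")
    return {"temporal_test": str(outdir / "temporal_test.json")}


def stage_report(config: dict, outdir: Path) -> dict:
    manifest = {
        "config": config,
        "seed": config["seed"],
        "stages": list(STAGES),
        "input_checksums": {},
        "outputs": {},
    }
    for name in ("variants.vcf", "genes.gff3", "gene_effects.tsv", "samples.tsv", "climate.tsv"):
        p = outdir / name
        if p.exists():
            manifest["input_checksums"][name] = hashlib.sha256(p.read_bytes()).hexdigest()
    report = {"manifest": manifest}
    for name in ("filter_log", "constraint_scan", "adaptation_scan", "temporal_test"):
        p = outdir / f"{name}.json"
        if p.exists():
            with open(p) as fh:
                report[name] = json.load(fh)
            manifest["outputs"][name] = p.name
    _write_json(manifest, outdir / "manifest.json")
    _write_json(report, outdir / "report.json")
    return {"report": str(outdir / "report.json")}


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "filter": stage_filter,
    "constraint-scan": stage_constraint_scan,
    "adaptation-scan": stage_adaptation_scan,
    "pair": stage_pair,
    "climate": stage_climate,
    "score": stage_score,
    "temporal-test": stage_temporal_test,
    "report": stage_report,
}


def run_stage(name: str, config: dict | None, outdir: str) -> dict:
    """Run one named stage against a study directory; returns output paths."""
    if name not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {name!r}; choose from {STAGES}")
    cfg = merge_config(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("stage %s: outdir=%s seed=%s", name, out, cfg["seed"])
    return _STAGE_FUNCS[name](cfg, out)


def run_all(config: dict | None, outdir: str) -> dict:
    """Run the full pipeline in order; returns the merged output-path map."""
    paths = {}
    for name in STAGES:
        paths.update(run_stage(name, config, outdir))
    return paths
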