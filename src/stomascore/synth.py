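"""Synthetic study generator.

Emulates the inputs of a herbarium-plus-contemporary resequencing study of a
selfing annual: effect-annotated biallelic SNPs (VCF with SnpEff-style ANN
entries), gene models (GFF3), a gene-to-density-effect table, sample metadata
with collection years and coordinates, and monthly climate series per sample
location with seasonal cycles and linear trends.

Built-in structure, all controllable through :class:`SynthConfig`:

* a latitudinal cline in functional-allele frequency within effect genes
  (log-odds slope ``cline_beta`` per degree), oriented so the density score
  increases with latitude;
* an epoch shift (``shift_delta`` logits) in functional-allele frequency,
  signed per gene effect so that the default scenario is a coordinated
  stomatal-density *decrease* in the modern epoch (set to 0 for null cohorts);
* per-location climate trends drawn from configurable slope distributions,
  recorded as ground truth for recovery tests.

Sites are independent by design: no linkage, no coalescent history.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genesets import GeneModel
from .variants import MISSING, VariantDataset, write_vcf

logger = logging.getLogger(__name__)


@dataclass
class SynthConfig:
    """Study conditions for the synthetic generator.

    Defaults are the package's fixed desk-scale study: 60 historical and 120
    modern samples in a European bounding box, 43 focus genes of which 24
    carry a density effect (14 increase, 10 decrease), a background pool of
    400 genes guaranteeing length-matched controls, and 60 years of monthly
    climate per location.
    """

    seed: int = 0
    n_hist: int = 60
    n_mod: int = 120
    hist_years: tuple[int, int] = (1817, 2002)
    mod_years: tuple[int, int] = (1992, 2012)
    lat_range: tuple[float, float] = (35.0, 65.0)
    lon_range: tuple[float, float] = (-10.0, 30.0)

    n_focus_genes: int = 43
    n_effect_genes: int = 24
    n_increase: int = 14  # e_g = +1
    n_decrease: int = 10  # e_g = -1
    pool_size: int = 400
    gene_length_range: tuple[int, int] = (800, 4000)
    snp_rate: float = 0.004  # SNPs per bp of gene span
    class_mixture: dict = field(
        default_factory=lambda: {
            "missense": 0.28,
            "synonymous": 0.30,
            "intron": 0.20,
            "5_prime_UTR": 0.07,
            "3_prime_UTR": 0.05,
            "stop_gained": 0.03,
            "frameshift": 0.02,
            "splice_region": 0.05,
        }
    )

    base_freq_functional: float = 0.10
    base_freq_other: float = 0.15
    cline_beta: float = 0.04  # logits per degree latitude, on effect genes
    shift_delta: float = 0.5  # logits, epoch shift oriented to density decrease
    shift_scope: str = "all"  # or "ppt_increase": shift only east-half samples
    het_rate: float = 0.0  # selfing species: homozygous by default
    missing_rate: float = 0.02
    metric_fail_fraction: float = 0.05

    climate_years: tuple[int, int] = (1958, 2017)
    ppt_mean: float = 60.0
    ppt_amplitude: float = 40.0
    # precipitation change is spatially coherent: a west-east gradient in the
    # per-location slope (mm/year at the box edges) plus local noise, so that
    # geographically close samples experience the same trend direction
    ppt_slope_gradient: float = 0.30
    ppt_slope_sd: float = 0.05  # mm / year, local deviation
    ppt_noise_sd: float = 8.0
    tmax_mean: float = 15.0
    tmax_amplitude: float = 8.0
    tmax_slope_mean: float = 0.02  # degC / year
    tmax_slope_sd: float = 0.02
    tmax_noise_sd: float = 1.2
    ar1_phi: float = 0.3

    def __post_init__(self) -> None:
        if self.n_increase + self.n_decrease != self.n_effect_genes:
            raise ValueError("n_increase + n_decrease must equal n_effect_genes")
        if self.n_effect_genes > self.n_focus_genes:
            raise ValueError("n_effect_genes cannot exceed n_focus_genes")


FUNCTIONAL_TERMS = {"missense", "stop_gained", "frameshift"}


@dataclass
class StudyData:
    samples: pd.DataFrame
    genes: dict[str, GeneModel]
    focus_genes: list[str]
    effects: pd.DataFrame
    dataset: VariantDataset
    climate: pd.DataFrame | None
    truth: dict


def generate_cohort(cfg: SynthConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Sample metadata: ids, epoch, collection year, coordinates.

    Coordinates are uniform in the bounding box and years uniform in the
    epoch ranges; deterministic under the config seed.
    """
    if cfg.n_hist < 1 or cfg.n_mod < 1:
        raise ValueError("both epochs need at least one sample")
    rng = rng or np.random.default_rng(cfg.seed)
    rows = []
    for epoch, n, years, prefix in (
        ("historical", cfg.n_hist, cfg.hist_years, "H"),
        ("modern", cfg.n_mod, cfg.mod_years, "M"),
    ):
        lat = rng.uniform(*cfg.lat_range, size=n)
        lon = rng.uniform(*cfg.lon_range, size=n)
        yr = rng.integers(years[0], years[1] + 1, size=n)
        for i in range(n):
            rows.append(
                {
                    "sample_id": f"{prefix}{i + 1:04d}",
                    "epoch": epoch,
                    "year": int(yr[i]),
                    "lat": float(lat[i]),
                    "lon": float(lon[i]),
                    "region_tags": "",
                }
            )
    return pd.DataFrame(rows)


def generate_gene_models(
    cfg: SynthConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, GeneModel], list[str]]:
    """Focus and pool gene models laid out over five chromosomes.

    For every focus gene at least three pool genes are created within +/-2%
    of its length, so length-matched control draws (+/-2.5%) never fail.
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    lengths = []
    ids = []
    focus = [f"FG{i + 1:03d}" for i in range(cfg.n_focus_genes)]
    focus_len = rng.integers(*cfg.gene_length_range, size=cfg.n_focus_genes)
    ids.extend(focus)
    lengths.extend(int(x) for x in focus_len)
    k = 0
    for L in focus_len:
        for _ in range(3):
            k += 1
            ids.append(f"BG{k:04d}")
            lengths.append(int(L * rng.uniform(0.98, 1.02)))
    while k < cfg.pool_size:
        k += 1
        ids.append(f"BG{k:04d}")
        lengths.append(int(rng.integers(*cfg.gene_length_range)))

    order = rng.permutation(len(ids))
    genes: dict[str, GeneModel] = {}
    chrom_cursor = {f"Chr{c}": 1000 for c in range(1, 6)}
    for j in order:
        gid, L = ids[j], lengths[j]
        chrom = f"Chr{(j % 5) + 1}"
        start = chrom_cursor[chrom]
        end = start + L - 1
        chrom_cursor[chrom] = end + 500
        transcripts = [f"{gid}.1"]
        if rng.random() < 0.5:
            transcripts.append(f"{gid}.2")
        genes[gid] = GeneModel(gid, chrom, start, end, "+", transcripts)
    return genes, focus


def generate_effects(
    cfg: SynthConfig, focus: list[str], rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Assign +1/-1/0 density effects to the focus genes (seeded)."""
    rng = rng or np.random.default_rng(cfg.seed + 2)
    chosen = rng.choice(len(focus), size=cfg.n_effect_genes, replace=False)
    effects = np.zeros(len(focus), dtype=int)
    effects[chosen[: cfg.n_increase]] = 1
    effects[chosen[cfg.n_increase :]] = -1
    return pd.DataFrame(
        {"gene_id": focus, "effect": effects, "note": "synthetic knock-out phenotype"}
    )


def _logit(p: float) -> float:
    return float(np.log(p / (1 - p)))


def _lon_norm(cfg: SynthConfig, lon: np.ndarray) -> np.ndarray:
    """Longitude scaled to [-1, 1] across the bounding box."""
    lo, hi = cfg.lon_range
    return (2 * (np.asarray(lon) - lo) / (hi - lo)) - 1.0


def generate_genotypes(
    cfg: SynthConfig,
    samples: pd.DataFrame,
    genes: dict[str, GeneModel],
    effects: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> VariantDataset:
    """Annotated biallelic SNPs with a cline and an epoch shift in effect genes.

    Per-SNP carrier frequency is logistic in latitude and epoch: for a
    functional SNP in a gene with effect e_g,

        logit p = logit(base) + cline_beta * (lat - lat_mid) * e_g
                  - shift_delta * e_g * 1[modern],

    so with ``shift_delta > 0`` modern samples lose functional alleles in
    "+1" genes and gain them in "-1" genes — a coordinated density decrease.
    Other SNPs have a flat carrier frequency. Genotypes are homozygous
    (dosage 0/2) unless ``het_rate`` > 0; a small fraction of calls is
    missing.
    """
    rng = rng or np.random.default_rng(cfg.seed + 3)
    eff = effects.set_index("gene_id")["effect"]
    lat = samples["lat"].to_numpy()
    lat_mid = float(np.mean(cfg.lat_range))
    is_mod = (samples["epoch"] == "modern").to_numpy()
    if cfg.shift_scope == "all":
        shifted = np.ones(len(samples))
    elif cfg.shift_scope == "ppt_increase":
        shifted = (_lon_norm(cfg, samples["lon"].to_numpy()) > 0).astype(float)
    else:
        raise ValueError(f"unknown shift_scope {cfg.shift_scope!r}")

    terms = list(cfg.class_mixture.keys())
    probs = np.array(list(cfg.class_mixture.values()), dtype=float)
    probs = probs / probs.sum()

    bases = "ACGT"
    site_rows = []
    dosage_rows = []
    order = sorted(genes.values(), key=lambda g: (g.chrom, g.start))
    for g in order:
        n_snps = rng.poisson(cfg.snp_rate * g.length)
        if n_snps == 0:
            continue
        n_snps = min(n_snps, g.length)
        positions = np.sort(rng.choice(np.arange(g.start, g.end + 1), size=n_snps, replace=False))
        snp_terms = rng.choice(terms, size=n_snps, p=probs)
        e_g = int(eff.get(g.gene_id, 0))
        for pos, term in zip(positions, snp_terms):
            functional = term in FUNCTIONAL_TERMS
            if functional and e_g != 0:
                logit_p = (
                    _logit(cfg.base_freq_functional)
                    + cfg.cline_beta * (lat - lat_mid) * e_g
                    - cfg.shift_delta * e_g * is_mod * shifted
                )
                p = 1 / (1 + np.exp(-logit_p))
            else:
                base = cfg.base_freq_functional if functional else cfg.base_freq_other
                p = np.full(len(samples), base)
            carrier = rng.random(len(samples)) < p
            het = rng.random(len(samples)) < cfg.het_rate
            dosage = np.where(carrier, np.where(het, 1, 2), 0).astype(np.int8)
            miss = rng.random(len(samples)) < cfg.missing_rate
            dosage[miss] = MISSING

            ref, alt = rng.choice(list(bases), size=2, replace=False)
            fail = rng.random() < cfg.metric_fail_fraction
            dp = float(round(rng.normal(60, 8))) if not fail else float(rng.integers(5, 21))
            fs = float(rng.uniform(0, 0.15)) if not fail else float(rng.uniform(0.3, 1.0))
            rprs = float(np.clip(rng.normal(0, 0.7), -1.9, 1.9))
            ann = [(f"{g.gene_id}.1", [term])]
            if len(g.transcripts) > 1 and rng.random() < 0.5:
                ann.append((f"{g.gene_id}.2", [term]))
            site_rows.append(
                {
                    "chrom": g.chrom,
                    "pos": int(pos),
                    "ref": ref,
                    "alt": alt,
                    "DP": dp,
                    "FS": fs,
                    "ReadPosRankSum": rprs,
                    "ann": ann,
                }
            )
            dosage_rows.append(dosage)

    sites = pd.DataFrame(
        site_rows, columns=["chrom", "pos", "ref", "alt", "DP", "FS", "ReadPosRankSum", "ann"]
    )
    dosages = (
        np.vstack(dosage_rows)
        if dosage_rows
        else np.empty((0, len(samples)), dtype=np.int8)
    )
    ds = VariantDataset(sites, dosages, list(samples["sample_id"]))
    # keep genome order stable: sort by chrom, pos
    order_idx = np.lexsort((sites["pos"].to_numpy(), sites["chrom"].to_numpy()))
    return ds.take_sites(order_idx)


def generate_climate(
    cfg: SynthConfig, locations: pd.DataFrame, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, dict]:
    """Monthly ppt and tmax series per location with known linear trends.

    value = mean + amplitude * sin(2 pi month / 12) + slope * (year - y0)
            + AR(1) noise. Precipitation slopes follow a west-east gradient
    plus local noise (spatially coherent change); tmax slopes are drawn
    i.i.d. per location. All slopes are returned as ground truth.
    """
    rng = rng or np.random.default_rng(cfg.seed + 4)
    y0, y1 = cfg.climate_years
    years = np.arange(y0, y1 + 1)
    months = np.arange(1, 13)
    n_months = len(years) * 12
    yy = np.repeat(years, 12)
    mm = np.tile(months, len(years))
    season = np.sin(2 * np.pi * mm / 12.0)
    frames = []
    truth_slopes: dict[str, dict[str, float]] = {}
    lon_norm = dict(zip(locations["sample_id"], _lon_norm(cfg, locations["lon"].to_numpy())))
    for loc in locations["sample_id"]:
        slopes = {
            "ppt": float(
                cfg.ppt_slope_gradient * lon_norm[loc] + rng.normal(0.0, cfg.ppt_slope_sd)
            ),
            "tmax": float(rng.normal(cfg.tmax_slope_mean, cfg.tmax_slope_sd)),
        }
        truth_slopes[loc] = slopes
        for var, mean, amp, noise_sd in (
            ("ppt", cfg.ppt_mean, cfg.ppt_amplitude, cfg.ppt_noise_sd),
            ("tmax", cfg.tmax_mean, cfg.tmax_amplitude, cfg.tmax_noise_sd),
        ):
            eps = rng.normal(0, noise_sd, size=n_months)
            noise = np.empty(n_months)
            noise[0] = eps[0]
            for t in range(1, n_months):
                noise[t] = cfg.ar1_phi * noise[t - 1] + eps[t]
            vals = mean + amp * season + slopes[var] * (yy - y0) + noise
            if var == "ppt":
                vals = np.clip(vals, 0, None)
            frames.append(
                pd.DataFrame(
                    {
                        "location_id": loc,
                        "variable": var,
                        "year": yy,
                        "month": mm,
                        "value": vals,
                    }
                )
            )
    climate = pd.concat(frames, ignore_index=True)
    return climate, truth_slopes


def generate_study(cfg: SynthConfig, with_climate: bool = True) -> StudyData:
    """Generate a full synthetic study (in memory)."""
    samples = generate_cohort(cfg)
    genes, focus = generate_gene_models(cfg)
    effects = generate_effects(cfg, focus)
    ds = generate_genotypes(cfg, samples, genes, effects)
    climate, truth_slopes = (None, {})
    if with_climate:
        climate, truth_slopes = generate_climate(cfg, samples)
    truth = {
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(cfg).items()},
        "climate_slopes": truth_slopes,
        "effects": dict(zip(effects["gene_id"], (int(e) for e in effects["effect"]))),
    }
    return StudyData(samples, genes, focus, effects, ds, climate, truth)


def write_gff3(genes: dict[str, GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes.values(), key=lambda g: (g.chrom, g.start)):
            fh.write(
                f"{g.chrom}\tsynth\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            for tid in g.transcripts:
                fh.write(
                    f"{g.chrom}\tsynth\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                    f"ID={tid};Parent={g.gene_id}\n"
                )


def write_study(study: StudyData, outdir: str) -> dict[str, str]:
    """Write every study artefact (VCF, GFF3, TSVs, truth JSON) to a directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": str(out / "variants.vcf"),
        "gff3": str(out / "genes.gff3"),
        "effects": str(out / "gene_effects.tsv"),
        "samples": str(out / "samples.tsv"),
        "focus": str(out / "focus_genes.tsv"),
        "truth": str(out / "truth.json"),
    }
    write_vcf(study.dataset, paths["vcf"])
    write_gff3(study.genes, paths["gff3"])
    study.effects.to_csv(paths["effects"], sep="\t", index=False)
    study.samples.to_csv(paths["samples"], sep="\t", index=False)
    pd.DataFrame({"gene_id": study.focus_genes}).to_csv(paths["focus"], sep="\t", index=False)
    if study.climate is not None:
        paths["climate"] = str(out / "climate.tsv")
        study.climate.to_csv(paths["climate"], sep="\t", index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(study.truth, fh, indent=1)
    return paths
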