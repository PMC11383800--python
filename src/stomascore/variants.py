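"""Effect-annotated variant handling.

Reads biallelic SNPs from VCF files carrying SnpEff-style ``ANN`` INFO
entries, classifies predicted effects into six categories (loss-of-function,
non-synonymous, synonymous, UTR, intron, other), applies site-quality,
missingness and minor-allele-carrier filters, and intersects two datasets to
their shared sites.

Genotypes are held as per-sample allele dosages (0, 1, 2; -1 for missing) in
a sites-by-samples integer matrix. Phased and unphased calls are treated
identically; half-missing diploid calls count as missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1


class EffectClass(str, Enum):
    """Mutually exclusive effect category of a SNP on one transcript."""

    LOF = "LOF"
    NONSYN = "NONSYN"
    SYN = "SYN"
    UTR = "UTR"
    INTRON = "INTRON"
    OTHER = "OTHER"


#: SnpEff terms per class, after stripping the "_variant" suffix.
LOF_TERMS = frozenset(
    {
        "disruptive_inframe_deletion",
        "disruptive_inframe_insertion",
        "inframe_deletion",
        "inframe_insertion",
        "frameshift",
        "start_lost",
        "stop_lost",
        "stop_gained",
    }
)
NONSYN_TERMS = frozenset({"missense"})
SYN_TERMS = frozenset({"synonymous"})
UTR_TERMS = frozenset(
    {
        "5_prime_UTR_premature_start_codon_gain",
        "3_prime_UTR",
        "5_prime_UTR",
    }
)
INTRON_TERMS = frozenset({"intron"})
OTHER_TERMS = frozenset(
    {
        "none",
        "splice_region",
        "splice_donor",
        "splice_acceptor",
        "stop_retained",
        "non_coding_transcript_exon",
        "upstream_gene",
        "downstream_gene",
        "intergenic_region",
        "intragenic",
    }
)

KNOWN_TERMS = LOF_TERMS | NONSYN_TERMS | SYN_TERMS | UTR_TERMS | INTRON_TERMS | OTHER_TERMS

_warned_terms: set[str] = set()


def normalize_term(term: str) -> str:
    """Strip SnpEff's ``_variant`` suffix so both dialects map identically."""
    term = term.strip()
    if term.endswith("_variant"):
        term = term[: -len("_variant")]
    return term


def classify_effect(terms: Iterable[str]) -> EffectClass:
    """Classify a list of SnpEff annotation terms into one effect class.

    Priority order is LOF > NONSYN > SYN > UTR > INTRON > OTHER, so the most
    severe predicted consequence wins when a transcript carries several terms.
    Unknown terms fall through to OTHER with a logged warning.
    """
    normalized = [normalize_term(t) for t in terms if t.strip()]
    for t in normalized:
        if t not in KNOWN_TERMS and t not in _warned_terms:
            _warned_terms.add(t)
            logger.warning("unknown annotation term %r classified as OTHER", t)
    tset = set(normalized)
    if tset & LOF_TERMS:
        return EffectClass.LOF
    if tset & NONSYN_TERMS:
        return EffectClass.NONSYN
    if tset & SYN_TERMS:
        return EffectClass.SYN
    if tset & UTR_TERMS:
        return EffectClass.UTR
    if tset & INTRON_TERMS:
        return EffectClass.INTRON
    return EffectClass.OTHER


@dataclass
class FilterConfig:
    """Thresholds for site-quality and genotype-level filtering.

    Defaults follow standard practice for joint herbarium/contemporary SNP
    panels: combined depth DP > 22, strand-bias FS < 0.2, |ReadPosRankSum| < 2,
    minor-allele carrier count >= 3, site missingness <= 15%, sample
    missingness <= 50%.
    """

    min_mac: int = 3
    mac_mode: str = "carriers"  # "carriers" (samples with dosage>=1) or "alleles"
    max_site_missing: float = 0.15
    max_sample_missing: float = 0.5
    dp_min: float = 22.0
    fs_max: float = 0.2
    rprs_abs_max: float = 2.0
    missing_metric_passes: bool = False

    def __post_init__(self) -> None:
        for name in ("max_site_missing", "max_sample_missing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.min_mac < 0:
            raise ValueError("min_mac must be non-negative")
        if self.mac_mode not in ("carriers", "alleles"):
            raise ValueError("mac_mode must be 'carriers' or 'alleles'")


@dataclass
class VariantDataset:
    """Biallelic SNP table plus a dosage matrix.

    ``sites`` has one row per SNP with columns chrom, pos, ref, alt, DP, FS,
    ReadPosRankSum and ``ann`` (list of ``(feature_id, [terms])`` tuples).
    ``dosages`` is an int8 array of shape (n_sites, n_samples) with values in
    {0, 1, 2, -1}.
    """

    sites: pd.DataFrame
    dosages: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        if self.dosages.shape != (len(self.sites), len(self.samples)):
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def site_keys(self) -> pd.Series:
        s = self.sites
        return (
            s["chrom"].astype(str)
            + ":"
            + s["pos"].astype(str)
            + ":"
            + s["ref"]
            + ":"
            + s["alt"]
        )

    def take_sites(self, index: np.ndarray | Sequence[int]) -> "VariantDataset":
        index = np.asarray(index)
        return VariantDataset(
            self.sites.iloc[index].reset_index(drop=True),
            self.dosages[index],
            list(self.samples),
        )

    def take_samples(self, index: np.ndarray | Sequence[int]) -> "VariantDataset":
        index = np.asarray(index)
        return VariantDataset(
            self.sites.copy(),
            self.dosages[:, index],
            [self.samples[i] for i in index],
        )


def parse_ann_field(ann: str) -> list[tuple[str, list[str]]]:
    """Parse a SnpEff ``ANN`` INFO value into (feature_id, terms) entries.

    Entries are comma-separated; fields within an entry pipe-delimited with
    the annotation terms in field 2 joined by '&' and the transcript
    (feature) id in field 7.
    """
    entries = []
    for part in ann.split(","):
        fields = part.split("|")
        if len(fields) < 7:
            continue
        terms = [t for t in fields[1].split("&") if t]
        feature_id = fields[6]
        entries.append((feature_id, terms))
    return entries


def read_vcf(path: str) -> VariantDataset:
    """Load biallelic SNPs from a VCF file.

    Multi-allelic records and indels are dropped (not decomposed), matching a
    biallelic-SNP-only calling strategy. INFO metrics DP, FS and
    ReadPosRankSum are carried through (NaN when absent).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows = []
    dosage_rows = []
    n_dropped_multi = 0
    n_dropped_indel = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_dropped_multi += 1
            continue
        alt = rec.ALT[0]
        if len(rec.REF) != 1 or len(alt) != 1 or alt not in "ACGT":
            n_dropped_indel += 1
            continue
        ann_raw = rec.INFO.get("ANN")
        ann = parse_ann_field(ann_raw) if ann_raw else []
        # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        g = rec.gt_types.astype(np.int8)
        g[g == 3] = MISSING
        rows.append(
            {
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "ref": rec.REF,
                "alt": alt,
                "DP": _info_float(rec, "DP"),
                "FS": _info_float(rec, "FS"),
                "ReadPosRankSum": _info_float(rec, "ReadPosRankSum"),
                "ann": ann,
            }
        )
        dosage_rows.append(g)
    vcf.close()
    if n_dropped_multi or n_dropped_indel:
        logger.info(
            "read_vcf: dropped %d multi-allelic and %d non-SNP records",
            n_dropped_multi,
            n_dropped_indel,
        )
    sites = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "DP", "FS", "ReadPosRankSum", "ann"]
    )
    dosages = (
        np.vstack(dosage_rows) if dosage_rows else np.empty((0, len(samples)), dtype=np.int8)
    )
    return VariantDataset(sites, dosages, samples)


def _info_float(rec, key: str) -> float:
    v = rec.INFO.get(key)
    if v is None:
        return float("nan")
    try:
        return float(v)
    except (TypeError, ValueError):
        return float("nan")


def write_vcf(ds: VariantDataset, path: str) -> None:
    """Write a dataset back out as minimal uncompressed VCF v4.2 text."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(ds.sites["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Combined depth">\n')
        fh.write('##INFO=<ID=FS,Number=1,Type=Float,Description="Strand bias (phred)">\n')
        fh.write(
            '##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,'
            'Description="Read position rank sum">\n'
        )
        fh.write(
            '##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(ds.samples) + "\n")
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for i, row in enumerate(ds.sites.itertuples(index=False)):
            info_parts = []
            for key in ("DP", "FS", "ReadPosRankSum"):
                v = getattr(row, key)
                if v == v:  # not NaN
                    info_parts.append(f"{key}={int(round(v)) if key == 'DP' else f'{v:g}'}")
            if row.ann:
                ann_str = ",".join(
                    f"{ds.sites.at[i, 'alt']}|{'&'.join(terms)}|MODIFIER|||transcript|{fid}|protein_coding|||||||||"
                    for fid, terms in row.ann
                )
                info_parts.append(f"ANN={ann_str}")
            info = ";".join(info_parts) if info_parts else "."
            gts = "\t".join(gt_map[int(d)] for d in ds.dosages[i])
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t{info}\tGT\t{gts}\n"
            )


def site_quality_pass(metrics: dict | pd.Series, cfg: FilterConfig) -> bool:
    """Strict-inequality site-quality predicate on DP, FS and ReadPosRankSum.

    Missing metrics fail by default (``cfg.missing_metric_passes`` flips this).
    """
    dp = metrics.get("DP", float("nan"))
    fs = metrics.get("FS", float("nan"))
    rprs = metrics.get("ReadPosRankSum", float("nan"))
    checks = [
        (dp, lambda v: v > cfg.dp_min),
        (fs, lambda v: v < cfg.fs_max),
        (rprs, lambda v: -cfg.rprs_abs_max < v < cfg.rprs_abs_max),
    ]
    for value, ok in checks:
        if value != value:  # NaN
            if not cfg.missing_metric_passes:
                return False
            continue
        if not ok(value):
            return False
    return True


def apply_site_quality(ds: VariantDataset, cfg: FilterConfig) -> tuple[VariantDataset, dict]:
    """Drop sites failing the DP/FS/ReadPosRankSum predicate."""
    keep = np.array(
        [site_quality_pass(ds.sites.iloc[i], cfg) for i in range(ds.n_sites)], dtype=bool
    )
    log = {"step": "site_quality", "n_in": ds.n_sites, "n_removed": int((~keep).sum())}
    return ds.take_sites(np.flatnonzero(keep)), log


def _site_missing_fraction(dosages: np.ndarray) -> np.ndarray:
    if dosages.shape[1] == 0:
        return np.ones(dosages.shape[0])
    return (dosages == MISSING).mean(axis=1)


def _carrier_counts(dosages: np.ndarray, mode: str) -> np.ndarray:
    if mode == "carriers":
        return (dosages >= 1).sum(axis=1)
    return np.where(dosages == MISSING, 0, dosages).sum(axis=1)


def filter_dataset(ds: VariantDataset, cfg: FilterConfig) -> tuple[VariantDataset, dict]:
    """Apply sample-missingness, mac and site-missingness filters.

    Order within one pass: drop samples whose missing-genotype fraction
    exceeds ``max_sample_missing``, then drop sites whose missing fraction
    (on the reduced sample set) exceeds ``max_site_missing`` or whose
    alternative-allele carrier count falls below ``min_mac``. Because
    removing sites can in principle push a remaining sample back over its
    missingness threshold, the pass is iterated to a fixed point, which makes
    the whole operation idempotent. The returned log records the counts
    removed at each step of each pass.
    """
    steps = []
    current = ds
    for iteration in range(1, 100):
        sample_missing = (
            (current.dosages == MISSING).mean(axis=0)
            if current.n_sites
            else np.zeros(current.n_samples)
        )
        keep_samples = np.flatnonzero(sample_missing <= cfg.max_sample_missing)
        n_samples_removed = current.n_samples - len(keep_samples)
        reduced = current.take_samples(keep_samples) if n_samples_removed else current

        site_missing = _site_missing_fraction(reduced.dosages)
        mac = _carrier_counts(reduced.dosages, cfg.mac_mode)
        keep_sites = (site_missing <= cfg.max_site_missing) & (mac >= cfg.min_mac)
        n_sites_removed = int((~keep_sites).sum())
        reduced = reduced.take_sites(np.flatnonzero(keep_sites))

        steps.append(
            {
                "pass": iteration,
                "samples_removed": int(n_samples_removed),
                "sites_removed": n_sites_removed,
            }
        )
        current = reduced
        if n_samples_removed == 0 and n_sites_removed == 0:
            break

    log = {
        "step": "filter_dataset",
        "config": {k: v for k, v in asdict(cfg).items()},
        "passes": steps,
        "n_sites_out": current.n_sites,
        "n_samples_out": current.n_samples,
        "empty_result": current.n_sites == 0 or current.n_samples == 0,
    }
    if log["empty_result"]:
        logger.warning("filter_dataset produced an empty collection")
    return current, log


def intersect_shared_sites(
    a: VariantDataset, b: VariantDataset
) -> tuple[VariantDataset, VariantDataset, dict]:
    """Restrict both datasets to sites matching on (chrom, pos, ref, alt).

    Allele-swapped sites (ref/alt exchanged between the datasets) are treated
    as non-matching, excluded from both outputs and counted in the log.
    """
    keys_a = a.site_keys()
    keys_b = b.site_keys()
    shared = set(keys_a) & set(keys_b)

    def swapped_key(key: str) -> str:
        chrom, pos, ref, alt = key.rsplit(":", 3)
        return f"{chrom}:{pos}:{alt}:{ref}"

    n_swapped = sum(1 for k in keys_a if k not in shared and swapped_key(k) in set(keys_b))
    if n_swapped:
        logger.warning("intersect_shared_sites: %d allele-swapped sites excluded", n_swapped)

    idx_a = np.flatnonzero(keys_a.isin(shared).to_numpy())
    idx_b = np.flatnonzero(keys_b.isin(shared).to_numpy())
    log = {
        "step": "intersect",
        "n_shared": len(shared),
        "n_allele_swapped_excluded": n_swapped,
    }
    return a.take_sites(idx_a), b.take_sites(idx_b), log


def class_counts(
    site_classes: pd.DataFrame, gene_ids: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-gene and per-set counts and proportions of each effect class.

    ``site_classes`` needs columns ``gene_id`` and ``effect_class`` (one row
    per SNP-gene assignment). Returns one row per gene plus a ``__set__``
    total row; proportion columns sum to 1 within each row that has SNPs.
    """
    classes = [c.value for c in EffectClass]
    if gene_ids is None:
        gene_ids = sorted(site_classes["gene_id"].unique())
    rows = []
    grouped = site_classes.groupby("gene_id")["effect_class"]
    for gid in gene_ids:
        counts = {c: 0 for c in classes}
        if gid in grouped.groups:
            vc = grouped.get_group(gid).value_counts()
            for c, n in vc.items():
                counts[str(c)] = int(n)
        total = sum(counts.values())
        if total == 0:
            logger.info("class_counts: gene %s has zero SNPs", gid)
        row = {"gene_id": gid, "n_snps": total}
        row.update({f"n_{c}": counts[c] for c in classes})
        row.update(
            {f"prop_{c}": (counts[c] / total if total else 0.0) for c in classes}
        )
        rows.append(row)
    set_counts = {c: sum(r[f"n_{c}"] for r in rows) for c in classes}
    set_total = sum(set_counts.values())
    set_row = {"gene_id": "__set__", "n_snps": set_total}
    set_row.update({f"n_{c}": set_counts[c] for c in classes})
    set_row.update(
        {f"prop_{c}": (set_counts[c] / set_total if set_total else 0.0) for c in classes}
    )
    rows.append(set_row)
    return pd.DataFrame(rows)
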