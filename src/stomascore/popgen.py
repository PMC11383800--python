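"""Diversity and differentiation statistics.

Per-site nucleotide diversity pi, per-gene pi summaries, Watterson's theta,
windowed Tajima's D (Tajima 1989) and the Weir & Cockerham (1984) F_ST
estimator from diploid dosages, plus k-means population construction with
silhouette-selected k.

All estimators count allele copies from diploid dosages (n = 2 x called
samples). For fully homozygous (selfing) data this matches the haploid
computation up to the n/(n-1) sampling factor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variants import MISSING

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# nucleotide diversity


def site_pi(dosages: np.ndarray) -> float:
    """Per-site nucleotide diversity: c_ref * c_alt / C(n, 2) over called alleles."""
    d = np.asarray(dosages)
    called = d[d != MISSING]
    n = 2 * len(called)
    if n < 2:
        return float("nan")
    c_alt = int(called.sum())
    c_ref = n - c_alt
    return c_ref * c_alt / (n * (n - 1) / 2)


def sites_pi(dosages: np.ndarray) -> np.ndarray:
    """Vectorised ``site_pi`` over a (sites x samples) dosage matrix."""
    d = np.asarray(dosages)
    called = d != MISSING
    n = 2 * called.sum(axis=1)
    c_alt = np.where(called, d, 0).sum(axis=1)
    c_ref = n - c_alt
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = np.where(n >= 2, c_ref * c_alt / (n * (n - 1) / 2.0), np.nan)
    return pi


def gene_pi_summary(site_pis, gene_length: int) -> tuple[float, float]:
    """Return (max per-site pi, summed pi / gene length).

    Positions without a SNP are invariant and contribute 0 to the sum; a gene
    without SNPs returns (0, 0).
    """
    vals = np.asarray(site_pis, dtype=float)
    vals = vals[~np.isnan(vals)]
    if len(vals) == 0:
        return 0.0, 0.0
    return float(vals.max()), float(vals.sum() / gene_length)


def harmonic(n: int) -> float:
    return float(np.sum(1.0 / np.arange(1, n)))


def watterson_theta(S: int, n: int, L: int) -> float:
    """Watterson's estimator per bp: S / (a1 * L), a1 the (n-1)-th harmonic number."""
    if n < 2:
        raise ValueError("watterson_theta requires n >= 2 sequences")
    if L < 1:
        raise ValueError("watterson_theta requires L >= 1")
    return S / (harmonic(n) * L)


# ---------------------------------------------------------------------------
# Tajima's D


def tajima_constants(n: int) -> dict[str, float]:
    """The a1..e2 constants of Tajima (1989) for n sequences."""
    a1 = harmonic(n)
    a2 = float(np.sum(1.0 / np.arange(1, n) ** 2))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajima_d(site_pis, n: int) -> float:
    """Tajima's D from per-site pi values of the segregating sites and n sequences."""
    if n < 4:
        logger.warning("tajima_d: n=%d < 4, variance terms unstable; returning NaN", n)
        return float("nan")
    pis = np.asarray(site_pis, dtype=float)
    pis = pis[~np.isnan(pis)]
    pis = pis[pis > 0]
    S = len(pis)
    if S == 0:
        return float("nan")
    k = tajima_constants(n)
    pi_sum = float(pis.sum())
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    if var <= 0:
        return float("nan")
    return (pi_sum - S / k["a1"]) / np.sqrt(var)


def tajima_d_windows(
    positions: np.ndarray,
    dosages: np.ndarray,
    chroms: np.ndarray,
    window_bp: int = 100,
) -> pd.DataFrame:
    """Non-overlapping windowed Tajima's D anchored at coordinate 1.

    A window covering positions ``[w*window_bp + 1, (w+1)*window_bp]`` gets a
    D value from the segregating sites it contains; windows without
    segregating sites are absent from the output. n is taken as 2 x the
    number of samples. The output uses 0-based half-open window spans
    (BED-like convention, for the windows file only).
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    positions = np.asarray(positions)
    chroms = np.asarray(chroms)
    n = 2 * dosages.shape[1]
    pis = sites_pi(dosages)
    window_idx = (positions - 1) // window_bp
    rows = []
    df = pd.DataFrame({"chrom": chroms, "widx": window_idx, "pi": pis})
    for (chrom, widx), grp in df.groupby(["chrom", "widx"], sort=True):
        d = tajima_d(grp["pi"].to_numpy(), n)
        seg = int((grp["pi"].to_numpy() > 0).sum())
        rows.append(
            {
                "chrom": chrom,
                "start0": int(widx) * window_bp,
                "end": (int(widx) + 1) * window_bp,
                "n_snps": seg,
                "D": d,
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "start0", "end", "n_snps", "D"])


def gene_tajima_mean(
    windows: pd.DataFrame, snp_chroms, snp_positions, window_bp: int = 100
) -> float:
    """Mean window D over a gene's SNPs (each SNP inherits its window's D)."""
    lookup = {
        (row.chrom, row.start0 // window_bp): row.D for row in windows.itertuples()
    }
    values = [
        lookup.get((c, (p - 1) // window_bp), float("nan"))
        for c, p in zip(np.asarray(snp_chroms), np.asarray(snp_positions))
    ]
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if len(arr) == 0:
        return float("nan")
    return float(arr.mean())


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) F_ST


def wc_fst_components(dosages: np.ndarray, pops: np.ndarray) -> tuple[float, float, float]:
    """WC84 variance components (a, b, c) for one biallelic site.

    a: among populations, b: among individuals within populations, c: within
    individuals. Computed from diploid genotype counts; missing dosages are
    excluded per population.
    """
    dosages = np.asarray(dosages)
    pops = np.asarray(pops)
    labels = [p for p in pd.unique(pops)]
    n_i, p_i, h_i = [], [], []
    for lab in labels:
        d = dosages[pops == lab]
        d = d[d != MISSING]
        if len(d) == 0:
            continue
        n_i.append(len(d))
        p_i.append(d.sum() / (2 * len(d)))
        h_i.append(np.mean(d == 1))
    r = len(n_i)
    if r < 2:
        raise ValueError("wc_fst requires >= 2 populations with called genotypes")
    n_i = np.asarray(n_i, dtype=float)
    p_i = np.asarray(p_i)
    h_i = np.asarray(h_i)
    n_bar = n_i.mean()
    if n_bar <= 1:
        return float("nan"), float("nan"), float("nan")
    n_c = (n_i.sum() - (n_i**2).sum() / n_i.sum()) / (r - 1)
    p_bar = (n_i * p_i).sum() / n_i.sum()
    s2 = (n_i * (p_i - p_bar) ** 2).sum() / ((r - 1) * n_bar)
    h_bar = (n_i * h_i).sum() / n_i.sum()

    if n_c == 0 or n_bar == 1:
        return float("nan"), float("nan"), float("nan")
    a = (n_bar / n_c) * (
        s2 - (1 / (n_bar - 1)) * (p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - h_bar / 4)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
    )
    c = h_bar / 2
    return float(a), float(b), float(c)


def wc_fst(dosages: np.ndarray, pops: np.ndarray) -> float:
    """Per-SNP WC84 F_ST = a / (a + b + c); NaN when the denominator is 0.

    Negative estimates are retained (the estimator is unbiased around 0 for
    undifferentiated populations).
    """
    a, b, c = wc_fst_components(dosages, pops)
    denom = a + b + c
    if not np.isfinite(denom) or denom == 0:
        return float("nan")
    return a / denom


def fst_per_site(dosage_matrix: np.ndarray, pops: np.ndarray) -> np.ndarray:
    return np.array([wc_fst(row, pops) for row in np.asarray(dosage_matrix)])


def gene_fst_mean(fst_values) -> float:
    """Gene-level F_ST as the mean of per-SNP ratio estimates."""
    arr = np.asarray(fst_values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if len(arr) == 0:
        return float("nan")
    return float(arr.mean())


# ---------------------------------------------------------------------------
# population construction


@dataclass
class PopulationAssignment:
    scheme: str
    labels: pd.Series  # sample -> population id
    k: int
    silhouette_by_k: dict[int, float] = field(default_factory=dict)


def kmeans_populations(
    features: pd.DataFrame,
    k_range=range(2, 16),
    seed: int | None = None,
    scheme: str = "climate",
) -> PopulationAssignment:
    """Cluster samples into populations by k-means with silhouette-selected k.

    Features are standardised to zero mean / unit variance; for each k in
    ``k_range`` (skipping k >= n_samples) a clustering is run and the mean
    silhouette computed; the final labels come from a single k-means run at
    the argmax k under ``seed``.
    """
    from sklearn.cluster import KMeans
    from sklearn.metrics import silhouette_score
    from sklearn.preprocessing import StandardScaler

    X = StandardScaler().fit_transform(features.to_numpy(dtype=float))
    n = X.shape[0]
    scores: dict[int, float] = {}
    for k in k_range:
        if k >= n:
            logger.info("kmeans_populations: skipping k=%d (only %d samples)", k, n)
            continue
        km = KMeans(n_clusters=k, n_init=1, random_state=seed)
        lab = km.fit_predict(X)
        if len(np.unique(lab)) < 2:
            continue
        scores[k] = float(silhouette_score(X, lab))
    if not scores:
        raise ValueError("no feasible k in k_range")
    best_k = max(scores, key=lambda k: (scores[k], -k))
    final = KMeans(n_clusters=best_k, n_init=1, random_state=seed).fit_predict(X)
    labels = pd.Series(final, index=features.index, name="population")
    return PopulationAssignment(scheme=scheme, labels=labels, k=best_k, silhouette_by_k=scores)


# ---------------------------------------------------------------------------
# per-gene bundle


def gene_pop_stats(
    ds,
    assignments: pd.DataFrame,
    genes,
    windows: pd.DataFrame | None = None,
    pop_schemes: dict[str, np.ndarray] | None = None,
    window_bp: int = 100,
) -> pd.DataFrame:
    """Per-gene statistic bundle: SNP count, SNPs/bp, pi, theta_W, D, F_ST.

    ``assignments`` is the (site_index, gene_id, effect_class) table from
    ``assign_snps_to_genes``; ``pop_schemes`` maps a scheme name to an array
    of per-sample population labels.
    """
    pis = sites_pi(ds.dosages)
    n_seq = 2 * ds.n_samples
    positions = ds.sites["pos"].to_numpy()
    chroms = ds.sites["chrom"].to_numpy()
    fst_cache: dict[str, np.ndarray] = {}
    if pop_schemes:
        for scheme, labels in pop_schemes.items():
            fst_cache[scheme] = fst_per_site(ds.dosages, np.asarray(labels))

    rows = []
    by_gene = assignments.groupby("gene_id")["site_index"]
    for gid, g in genes.items():
        idx = by_gene.get_group(gid).to_numpy() if gid in by_gene.groups else np.array([], int)
        gene_pis = pis[idx]
        seg = int(np.nansum(gene_pis > 0))
        pi_max, pi_bp = gene_pi_summary(gene_pis, g.length)
        theta = watterson_theta(seg, n_seq, g.length) if n_seq >= 2 else float("nan")
        d_mean = (
            gene_tajima_mean(windows, chroms[idx], positions[idx], window_bp)
            if windows is not None and len(idx)
            else float("nan")
        )
        row = {
            "gene_id": gid,
            "length": g.length,
            "snp_count": len(idx),
            "snps_per_bp": len(idx) / g.length,
            "pi_max_site": pi_max,
            "pi_per_bp": pi_bp,
            "theta_w_per_bp": theta,
            "tajima_d_mean": d_mean,
        }
        for scheme, values in fst_cache.items():
            row[f"fst_{scheme}"] = gene_fst_mean(values[idx]) if len(idx) else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
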