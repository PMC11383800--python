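"""The functional stomatal density score and its inference.

The score summarises, per sample, protein-altering variation in genes whose
knock-out is known to change abaxial stomatal density. Each such gene g has an
effect e_g of +1 (loss increases density) or -1 (loss decreases density). A
sample scores

    score = sum_g e_g * I_g,

where the indicator I_g is 1 iff the sample carries at least one alternative
allele at any putatively functional SNP (loss-of-function or non-synonymous)
assigned to gene g, counting a single functional SNP per gene. Scores are
relative to the reference accession (all-reference carries score 0).

Inference around the score: per-pair deltas (modern minus matched historical)
with a Wilcoxon signed-rank test, a permutation null that shuffles effect
labels across the effect genes, Fisher's exact odds of density decrease under
climate splits, and latitude correlations with modern subsampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .variants import EffectClass, MISSING, VariantDataset

logger = logging.getLogger(__name__)

FUNCTIONAL_CLASSES = frozenset({EffectClass.LOF.value, EffectClass.NONSYN.value})


def load_gene_effects(path: str) -> pd.DataFrame:
    """Read the gene -> density-effect table (TSV: gene_id, effect, note)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if not {"gene_id", "effect"} <= set(df.columns):
        raise ValueError("gene-effect table needs columns gene_id, effect")
    if not df["effect"].isin([-1, 0, 1]).all():
        raise ValueError("gene effects must be in {-1, 0, +1}")
    return df


def functional_indicator_matrix(
    ds: VariantDataset,
    assignments: pd.DataFrame,
    gene_ids,
    dosage_weighted: bool = False,
) -> pd.DataFrame:
    """Per-sample, per-gene functional-carriage indicators.

    Entry (s, g) is 1 iff sample s carries >= 1 alternative allele (dosage
    >= 1) at any functional SNP assigned to gene g; missing genotypes never
    count as carriage. With ``dosage_weighted`` the entry is the maximum
    dosage instead (heterozygote 1, homozygote 2).
    """
    func = assignments[assignments["effect_class"].isin(FUNCTIONAL_CLASSES)]
    mat = pd.DataFrame(0, index=list(ds.samples), columns=list(gene_ids), dtype=int)
    for gid, grp in func.groupby("gene_id"):
        if gid not in mat.columns:
            continue
        idx = grp["site_index"].to_numpy()
        d = ds.dosages[idx]
        carried = np.where(d == MISSING, 0, d)
        mat[gid] = carried.max(axis=0) if dosage_weighted else (carried >= 1).any(axis=0).astype(int)
    return mat


def density_scores(indicators: pd.DataFrame, effects: pd.Series) -> pd.Series:
    """Sum of effect-signed indicators over the nonzero-effect genes."""
    eff = effects[effects != 0]
    common = [g for g in eff.index if g in indicators.columns]
    scores = indicators[common].to_numpy() @ eff[common].to_numpy()
    return pd.Series(scores.astype(int), index=indicators.index, name="score")


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank with exact small-sample tail


def _exact_signed_rank_p(deltas: np.ndarray) -> tuple[float, float]:
    """Exact two-sided signed-rank p by enumeration over sign assignments.

    Zeros must already be dropped. Mid-ranks (possibly half-integer) are
    doubled to integers and the distribution of W+ built by dynamic
    programming over all 2^n assignments. Two-sided p = min(1, 2 * min(
    P(W+ <= w), P(W+ >= w))), the convention of exact signed-rank tables.
    """
    n = len(deltas)
    ranks = stats.rankdata(np.abs(deltas))  # mid-ranks for ties
    dranks = np.round(2 * ranks).astype(int)
    w_plus = int(np.round(2 * ranks[deltas > 0].sum()))
    total = dranks.sum()
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for dr in dranks:
        shifted = np.zeros_like(counts)
        shifted[dr:] = counts[: total + 1 - dr]
        counts = counts + shifted
    counts /= 2.0**n
    p_le = counts[: w_plus + 1].sum()
    p_ge = counts[w_plus:].sum()
    return float(ranks[deltas > 0].sum()), float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(deltas, exact_max_n: int = 25) -> dict:
    """Two-sided Wilcoxon signed-rank test of deltas against zero.

    Zero deltas are dropped; ties get mid-ranks. Up to ``exact_max_n``
    nonzero deltas the exact enumeration distribution is used, above that the
    normal approximation with continuity and tie correction. All deltas zero
    (or empty input) leaves p undefined (NaN).
    """
    d = np.asarray(deltas, dtype=float)
    d = d[d != 0]
    if len(d) == 0:
        return {"statistic": float("nan"), "p": float("nan"), "n_nonzero": 0, "method": "undefined"}
    if len(d) <= exact_max_n:
        w, p = _exact_signed_rank_p(d)
        return {"statistic": w, "p": p, "n_nonzero": len(d), "method": "exact"}
    res = stats.wilcoxon(d, zero_method="wilcox", correction=True, method="approx")
    return {
        "statistic": float(res.statistic),
        "p": float(res.pvalue),
        "n_nonzero": len(d),
        "method": "normal_approx",
    }


@dataclass
class DeltaResult:
    deltas: pd.DataFrame  # hist_id, mod_id, delta
    mean_delta: float
    wilcoxon_p: float
    wilcoxon_statistic: float
    n_pairs: int


def delta_and_wilcoxon(pairs: pd.DataFrame, scores: pd.Series) -> DeltaResult:
    """Per-pair delta = score(modern) - score(historical), mean and signed-rank p."""
    kept = pairs[pairs["kept"]] if "kept" in pairs.columns else pairs
    if kept.empty:
        raise ValueError("no kept pairs to compute deltas on")
    missing = [
        s
        for s in pd.concat([kept["hist_id"], kept["mod_id"]])
        if s not in scores.index
    ]
    if missing:
        raise ValueError(f"pairs reference unscored samples, e.g. {missing[:3]}")
    deltas = (
        scores[kept["mod_id"]].to_numpy() - scores[kept["hist_id"]].to_numpy()
    ).astype(float)
    w = wilcoxon_signed_rank(deltas)
    table = pd.DataFrame(
        {"hist_id": kept["hist_id"].to_numpy(), "mod_id": kept["mod_id"].to_numpy(), "delta": deltas}
    )
    return DeltaResult(
        deltas=table,
        mean_delta=float(np.mean(deltas)),
        wilcoxon_p=w["p"],
        wilcoxon_statistic=w["statistic"],
        n_pairs=len(deltas),
    )


# ---------------------------------------------------------------------------
# permutation null over effect labels


@dataclass
class PermutationResult:
    observed_mean_delta: float
    null_means: np.ndarray
    rank: int  # count of null means <= observed
    n_perm: int


def permute_effect_labels(
    indicators: pd.DataFrame,
    effects: pd.Series,
    pairs: pd.DataFrame,
    n_perm: int = 100,
    seed: int | None = None,
    mode: str = "shuffle",
) -> PermutationResult:
    """Null distribution of the mean delta under permuted gene-effect labels.

    ``mode='shuffle'`` (default) permutes the observed labels across the
    nonzero-effect genes, preserving the +1/-1 composition exactly;
    ``mode='redraw'`` draws each nonzero gene's sign independently with the
    observed +1 proportion. Zero-effect genes are never touched. Scores for
    every sample are recomputed per permutation; reproducible under ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    eff = effects[effects != 0]
    if len(eff) < 2:
        raise ValueError("permutation requires >= 2 nonzero-effect genes")
    kept = pairs[pairs["kept"]] if "kept" in pairs.columns else pairs
    genes = [g for g in eff.index if g in indicators.columns]
    ind = indicators[genes]
    # mean delta is linear in the effect vector: precompute per-gene mean
    # indicator differences over pairs, then each permutation is a dot product
    diff = (
        ind.loc[kept["mod_id"]].to_numpy() - ind.loc[kept["hist_id"]].to_numpy()
    ).mean(axis=0)
    e = eff[genes].to_numpy(dtype=float)
    observed = float(diff @ e)

    rng = np.random.default_rng(seed)
    null_means = np.empty(n_perm)
    p_plus = float(np.mean(e > 0))
    for i in range(n_perm):
        if mode == "shuffle":
            perm = rng.permutation(e)
        elif mode == "redraw":
            perm = np.where(rng.random(len(e)) < p_plus, 1.0, -1.0)
        else:
            raise ValueError(f"unknown permutation mode {mode!r}")
        null_means[i] = diff @ perm
    rank = int(np.sum(null_means <= observed))
    return PermutationResult(observed, null_means, rank, n_perm)


# ---------------------------------------------------------------------------
# Fisher's exact odds of density decrease


def fisher_odds(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 table.

    Returns the conditional maximum-likelihood odds ratio (the R
    ``fisher.test`` convention) and the exact two-sided p. A zero margin
    leaves the OR undefined (NaN) with p = 1.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("fisher_odds expects a non-negative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return float("nan"), 1.0
    res = stats.contingency.odds_ratio(t, kind="conditional")
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return float(res.statistic), float(p)


def fisher_decrease_odds(deltas: np.ndarray, in_group: np.ndarray) -> dict:
    """Odds of a density-score decrease (delta < 0) inside vs outside a group.

    Table orientation (printed in reports): rows = in group / not in group,
    columns = delta < 0 / delta >= 0, so OR > 1 always means more decreases
    in the named group.
    """
    deltas = np.asarray(deltas, dtype=float)
    in_group = np.asarray(in_group, dtype=bool)
    table = [
        [int(((deltas < 0) & in_group).sum()), int(((deltas >= 0) & in_group).sum())],
        [int(((deltas < 0) & ~in_group).sum()), int(((deltas >= 0) & ~in_group).sum())],
    ]
    odds, p = fisher_odds(table)
    return {"table": table, "odds_ratio": odds, "p": p}


# ---------------------------------------------------------------------------
# latitude (and generic trait) correlations


def score_latitude_correlation(scores: pd.Series, lats: pd.Series) -> dict:
    """One-sided (positive) Pearson test of score vs latitude.

    The regression intercept is re-expressed at the set's median latitude to
    avoid extrapolating to latitude zero.
    """
    common = scores.index.intersection(lats.index)
    if len(common) < 3:
        raise ValueError("latitude correlation requires >= 3 samples")
    x = lats[common].to_numpy(dtype=float)
    y = scores[common].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        return {"r": float("nan"), "p": float("nan"), "n": len(common)}
    r, p = stats.pearsonr(x, y, alternative="greater")
    fit = stats.linregress(x, y)
    med = float(np.median(x))
    return {
        "r": float(r),
        "p": float(p),
        "n": int(len(common)),
        "slope": float(fit.slope),
        "intercept_at_median_latitude": float(fit.slope * med + fit.intercept),
        "median_latitude": med,
    }


def latitude_correlation(
    scores: pd.Series,
    samples: pd.DataFrame,
    n_subsamples: int = 100,
    seed: int | None = None,
) -> dict:
    """Latitude correlations: whole historical set, subsampled modern set.

    The modern set is subsampled ``n_subsamples`` times without replacement
    down to the historical size (mirroring unequal cohort sizes), each
    subsample tested separately; the summary reports the mean r and the
    per-subsample tables.
    """
    meta = samples.set_index("sample_id")
    hist_ids = meta.index[(meta["epoch"] == "historical") & meta.index.isin(scores.index)]
    mod_ids = meta.index[(meta["epoch"] == "modern") & meta.index.isin(scores.index)]
    result: dict = {}
    result["historical"] = score_latitude_correlation(
        scores[hist_ids], meta.loc[hist_ids, "lat"]
    )
    rng = np.random.default_rng(seed)
    k = min(len(hist_ids), len(mod_ids))
    subs = []
    for _ in range(n_subsamples):
        pick = rng.choice(np.asarray(mod_ids), size=k, replace=False)
        subs.append(score_latitude_correlation(scores[pick], meta.loc[pick, "lat"]))
    rs = np.array([s["r"] for s in subs], dtype=float)
    ps = np.array([s["p"] for s in subs], dtype=float)
    result["modern_subsamples"] = subs
    result["modern_mean_r"] = float(np.nanmean(rs))
    result["modern_mean_p"] = float(np.nanmean(ps))
    result["n_subsamples"] = n_subsamples
    return result


def trait_correlation(scores: pd.Series, trait: pd.Series) -> dict:
    """One-sided (positive) Pearson test of the score against any trait vector."""
    common = scores.index.intersection(trait.index)
    if len(common) < 3:
        raise ValueError("trait correlation requires >= 3 samples")
    x = trait[common].to_numpy(dtype=float)
    y = scores[common].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        return {"r": float("nan"), "p": float("nan"), "n": len(common)}
    r, p = stats.pearsonr(x, y, alternative="greater")
    return {"r": float(r), "p": float(p), "n": int(len(common))}


# ---------------------------------------------------------------------------
# delta ~ climate-directionality regression


def delta_vs_climate_regression(deltas: np.ndarray, classes) -> dict:
    """OLS of per-pair delta on the precipitation-direction factor.

    Only 'matching_increase' and 'matching_decrease' pairs enter. The model
    uses treatment coding with an intercept; per-level p-values (each level's
    mean against zero) come from the no-intercept parameterisation of the
    same fit, plus the whole-model F-test p.
    """
    import statsmodels.formula.api as smf

    df = pd.DataFrame({"delta": np.asarray(deltas, float), "direction": list(classes)})
    df = df[df["direction"].isin(["matching_increase", "matching_decrease"])]
    for level in ("matching_increase", "matching_decrease"):
        n = int((df["direction"] == level).sum())
        if n < 2:
            raise ValueError(f"level {level!r} has {n} pairs; need >= 2")
    fit = smf.ols("delta ~ C(direction)", data=df).fit()
    fit_levels = smf.ols("delta ~ 0 + C(direction)", data=df).fit()
    coef = {
        "intercept": float(fit.params.iloc[0]),
        "direction_coef": float(fit.params.iloc[1]),
        "direction_p": float(fit.pvalues.iloc[1]),
        "p_model": float(fit.f_pvalue),
        "per_level": {
            name.split("[")[-1].rstrip("]"): {
                "mean": float(fit_levels.params[name]),
                "p": float(fit_levels.pvalues[name]),
            }
            for name in fit_levels.params.index
        },
        "n": int(len(df)),
    }
    return coef
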