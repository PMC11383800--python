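"""Functional density score and the inference built on it."""

import numpy as np
import pandas as pd
import pytest

from stomascore import genesets, geopair, score as sc
from stomascore.score import (
    delta_and_wilcoxon,
    delta_vs_climate_regression,
    density_scores,
    fisher_decrease_odds,
    fisher_odds,
    functional_indicator_matrix,
    latitude_correlation,
    permute_effect_labels,
    score_latitude_correlation,
    wilcoxon_signed_rank,
)
from conftest import make_dataset
import oracles


def _assignments(rows):
    return pd.DataFrame(rows, columns=["site_index", "gene_id", "effect_class"])


class TestIndicator:
    def test_all_reference_sample_scores_zero(self):
        ds = make_dataset([[0, 2]])
        a = _assignments([(0, "G", "NONSYN")])
        ind = functional_indicator_matrix(ds, a, ["G"])
        assert ind.loc["S0", "G"] == 0 and ind.loc["S1", "G"] == 1

    def test_multiple_functional_snps_count_once(self):
        ds = make_dataset([[2], [2], [2], [2], [2]])
        a = _assignments([(i, "G", "LOF") for i in range(5)])
        ind = functional_indicator_matrix(ds, a, ["G"])
        assert ind.loc["S0", "G"] == 1

    def test_synonymous_alt_not_counted(self):
        ds = make_dataset([[2]])
        a = _assignments([(0, "G", "SYN")])
        assert functional_indicator_matrix(ds, a, ["G"]).loc["S0", "G"] == 0

    def test_missing_genotype_is_not_carriage(self):
        ds = make_dataset([[-1]])
        a = _assignments([(0, "G", "LOF")])
        assert functional_indicator_matrix(ds, a, ["G"]).loc["S0", "G"] == 0

    def test_dosage_weighted_mode(self):
        ds = make_dataset([[1], [2]])
        a = _assignments([(0, "G", "LOF"), (1, "H", "LOF")])
        ind = functional_indicator_matrix(ds, a, ["G", "H"], dosage_weighted=True)
        assert ind.loc["S0", "G"] == 1 and ind.loc["S0", "H"] == 2


class TestDensityScore:
    def test_sum_of_signed_indicators(self):
        ind = pd.DataFrame(
            {"a": [1], "b": [1], "c": [1], "d": [1], "z": [1]}, index=["s"]
        )
        eff = pd.Series({"a": 1, "b": 1, "c": 1, "d": -1, "z": 0})
        assert density_scores(ind, eff)["s"] == 2  # 3 - 1, zero-effect ignored

    def test_no_functional_alleles_zero(self):
        ind = pd.DataFrame({"a": [0], "b": [0]}, index=["s"])
        eff = pd.Series({"a": 1, "b": -1})
        assert density_scores(ind, eff)["s"] == 0

    def test_matches_per_gene_enumeration(self, study):
        a = genesets.assign_snps_to_genes(study.dataset, study.genes)
        ind = functional_indicator_matrix(study.dataset, a, study.effects["gene_id"])
        eff = study.effects.set_index("gene_id")["effect"]
        scores = density_scores(ind, eff)
        func = a[a["effect_class"].isin(["LOF", "NONSYN"])]
        for si, sample in enumerate(study.dataset.samples[:10]):
            total = 0
            for gid, e in eff[eff != 0].items():
                rows = func[func["gene_id"] == gid]["site_index"].to_numpy()
                carries = any(study.dataset.dosages[r, si] >= 1 for r in rows)
                total += e * int(carries)
            assert scores[sample] == total

    def test_global_label_flip_negates_scores(self, study):
        a = genesets.assign_snps_to_genes(study.dataset, study.genes)
        ind = functional_indicator_matrix(study.dataset, a, study.effects["gene_id"])
        eff = study.effects.set_index("gene_id")["effect"]
        assert density_scores(ind, -eff).equals(-density_scores(ind, eff))


class TestWilcoxon:
    def test_exact_matches_full_enumeration(self):
        deltas = [-2, -1, -1, -1, 1]
        res = wilcoxon_signed_rank(deltas)
        assert res["method"] == "exact"
        assert res["p"] == pytest.approx(oracles.wilcoxon_exact_oracle(deltas), abs=1e-12)

    def test_random_small_samples_match_enumeration(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            d = rng.integers(-3, 4, size=rng.integers(4, 10))
            d = d[d != 0]
            if len(d) == 0:
                continue
            res = wilcoxon_signed_rank(d)
            assert res["p"] == pytest.approx(oracles.wilcoxon_exact_oracle(d), abs=1e-12)

    def test_all_zero_deltas_undefined(self):
        res = wilcoxon_signed_rank([0, 0, 0])
        assert np.isnan(res["p"]) and res["method"] == "undefined"

    def test_symmetric_deltas_p_near_one(self):
        res = wilcoxon_signed_rank([1, -1, 1, -1, 1, -1])
        assert res["p"] == pytest.approx(1.0)

    def test_large_sample_uses_normal_approximation(self):
        rng = np.random.default_rng(2)
        d = rng.normal(-0.5, 1, size=60)
        res = wilcoxon_signed_rank(d)
        assert res["method"] == "normal_approx"
        assert 0 <= res["p"] <= 1


def test_delta_and_wilcoxon(study):
    from stomascore.genesets import assign_snps_to_genes

    a = assign_snps_to_genes(study.dataset, study.genes)
    ind = functional_indicator_matrix(study.dataset, a, study.effects["gene_id"])
    scores = density_scores(ind, study.effects.set_index("gene_id")["effect"])
    pairs = geopair.pair_samples(study.samples)
    res = delta_and_wilcoxon(pairs, scores)
    assert res.n_pairs == int(pairs["kept"].sum())
    expected = scores[pairs[pairs["kept"]]["mod_id"]].to_numpy() - scores[
        pairs[pairs["kept"]]["hist_id"]
    ].to_numpy()
    assert res.mean_delta == pytest.approx(expected.mean())


class TestFisher:
    def test_symmetric_table(self):
        odds, p = fisher_odds([[1, 1], [1, 1]])
        assert odds == pytest.approx(1.0) and p == pytest.approx(1.0)

    def test_zero_cell_infinite_odds(self):
        odds, p = fisher_odds([[5, 0], [3, 4]])
        assert odds == float("inf")
        _, p_oracle = oracles.fisher_exact_oracle([[5, 0], [3, 4]])
        assert p == pytest.approx(p_oracle, abs=1e-12)

    def test_matches_enumeration_oracle(self):
        table = [[10, 5], [5, 10]]
        odds, p = fisher_odds(table)
        odds_o, p_o = oracles.fisher_exact_oracle(table)
        assert p == pytest.approx(p_o, abs=1e-10)
        assert odds == pytest.approx(odds_o, rel=1e-5)

    def test_zero_margin(self):
        odds, p = fisher_odds([[0, 0], [3, 4]])
        assert np.isnan(odds) and p == 1.0

    def test_decrease_odds_orientation(self):
        # decreases concentrated in the group -> OR > 1
        deltas = np.array([-1, -1, -1, 1, 1, 1])
        in_group = np.array([True, True, True, False, False, False])
        res = fisher_decrease_odds(deltas, in_group)
        assert res["odds_ratio"] > 1 or res["odds_ratio"] == float("inf")
        assert res["table"][0][0] == 3


class TestPermutation:
    def test_composition_preserved_and_identity(self, study):
        a = genesets.assign_snps_to_genes(study.dataset, study.genes)
        ind = functional_indicator_matrix(study.dataset, a, study.effects["gene_id"])
        eff = study.effects.set_index("gene_id")["effect"]
        pairs = geopair.pair_samples(study.samples)
        res = permute_effect_labels(ind, eff, pairs, n_perm=50, seed=4)
        # observed equals a direct recomputation
        scores = density_scores(ind, eff)
        direct = delta_and_wilcoxon(pairs, scores).mean_delta
        assert res.observed_mean_delta == pytest.approx(direct)
        assert res.n_perm == 50 and 0 <= res.rank <= 50

    def test_reproducible_under_seed(self, study):
        a = genesets.assign_snps_to_genes(study.dataset, study.genes)
        ind = functional_indicator_matrix(study.dataset, a, study.effects["gene_id"])
        eff = study.effects.set_index("gene_id")["effect"]
        pairs = geopair.pair_samples(study.samples)
        r1 = permute_effect_labels(ind, eff, pairs, n_perm=20, seed=7)
        r2 = permute_effect_labels(ind, eff, pairs, n_perm=20, seed=7)
        assert np.array_equal(r1.null_means, r2.null_means)

    def test_requires_permutations_and_effect_genes(self, study):
        ind = pd.DataFrame({"a": [1, 0]}, index=["h", "m"])
        pairs = pd.DataFrame({"hist_id": ["h"], "mod_id": ["m"], "kept": [True]})
        with pytest.raises(ValueError):
            permute_effect_labels(ind, pd.Series({"a": 1}), pairs, n_perm=0, seed=0)
        with pytest.raises(ValueError):
            permute_effect_labels(ind, pd.Series({"a": 1}), pairs, n_perm=10, seed=0)


class TestLatitude:
    def test_score_equal_latitude_r_one(self):
        lats = pd.Series([40.0, 45.0, 50.0, 55.0], index=list("abcd"))
        res = score_latitude_correlation(lats.copy(), lats)
        assert res["r"] == pytest.approx(1.0)
        # intercept re-expressed at the median latitude equals the fit there
        assert res["intercept_at_median_latitude"] == pytest.approx(res["median_latitude"])

    def test_two_samples_rejected(self):
        s = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError):
            score_latitude_correlation(s, s)

    def test_subsampling_sizes(self, study):
        rng = np.random.default_rng(0)
        scores = pd.Series(
            rng.integers(-3, 4, len(study.samples)),
            index=study.samples["sample_id"],
        )
        res = latitude_correlation(scores, study.samples, n_subsamples=10, seed=1)
        n_hist = (study.samples["epoch"] == "historical").sum()
        assert all(s["n"] == n_hist for s in res["modern_subsamples"])
        # scores independent of latitude: mean r near zero
        assert abs(res["modern_mean_r"]) < 0.3


class TestDeltaRegression:
    def test_equal_deltas_zero_coefficient(self):
        deltas = [1.0] * 6
        classes = ["matching_increase"] * 3 + ["matching_decrease"] * 3
        out = delta_vs_climate_regression(deltas, classes)
        assert out["direction_coef"] == pytest.approx(0.0, abs=1e-12)

    def test_exact_group_means_recovered(self):
        deltas = [-1, -1, -1, 1, 1, 1]
        classes = ["matching_increase"] * 3 + ["matching_decrease"] * 3
        out = delta_vs_climate_regression(deltas, classes)
        assert out["per_level"]["matching_increase"]["mean"] == pytest.approx(-1.0)
        assert out["per_level"]["matching_decrease"]["mean"] == pytest.approx(1.0)
        assert abs(out["direction_coef"]) == pytest.approx(2.0)

    def test_sparse_level_rejected(self):
        with pytest.raises(ValueError, match="matching_decrease"):
            delta_vs_climate_regression(
                [1, 2, 3], ["matching_increase", "matching_increase", "matching_decrease"]
            )

    def test_coverage_on_simulated_groups(self):
        """The direction coefficient's CI covers the true group difference in
        most replicates."""
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(3)
        hits = 0
        n_rep = 60
        for _ in range(n_rep):
            d_inc = rng.normal(-1, 1, 20)
            d_dec = rng.normal(1, 1, 20)
            deltas = np.concatenate([d_inc, d_dec])
            classes = ["matching_increase"] * 20 + ["matching_decrease"] * 20
            out = delta_vs_climate_regression(deltas, classes)
            # 95% CI of the increase-vs-decrease difference; true value is -2
            # (baseline level is matching_decrease under alphabetical coding)
            fit = smf.ols(
                "delta ~ C(direction)",
                data=pd.DataFrame({"delta": deltas, "direction": classes}),
            ).fit()
            lo, hi = fit.conf_int().iloc[1]
            assert out["direction_coef"] == pytest.approx(fit.params.iloc[1])
            if lo <= -2.0 <= hi:
                hits += 1
        assert hits >= 50  # ~95% nominal coverage over 60 replicates
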