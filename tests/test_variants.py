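"""Effect classification, site filters, intersection and class counting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from stomascore import variants
from stomascore.variants import (
    EffectClass,
    FilterConfig,
    classify_effect,
    class_counts,
    filter_dataset,
    intersect_shared_sites,
    site_quality_pass,
)
from conftest import make_dataset

VOCAB = sorted(variants.KNOWN_TERMS)


@pytest.mark.parametrize(
    "terms,expected",
    [
        (["stop_gained"], EffectClass.LOF),
        (["frameshift_variant"], EffectClass.LOF),
        (["missense"], EffectClass.NONSYN),
        (["missense_variant"], EffectClass.NONSYN),
        (["missense", "synonymous"], EffectClass.NONSYN),
        (["synonymous_variant"], EffectClass.SYN),
        (["5_prime_UTR_premature_start_codon_gain_variant"], EffectClass.UTR),
        (["intron_variant"], EffectClass.INTRON),
        (["intron", "missense"], EffectClass.NONSYN),
        (["splice_region"], EffectClass.OTHER),
        (["upstream_gene_variant"], EffectClass.OTHER),
        ([], EffectClass.OTHER),
        (["made_up_term_xyz"], EffectClass.OTHER),
        (["stop_gained", "missense", "intron"], EffectClass.LOF),
    ],
)
def test_classify_effect(terms, expected):
    assert classify_effect(terms) is expected


@given(st.lists(st.sampled_from(VOCAB), max_size=6))
@settings(deadline=None)
def test_classify_effect_total_and_prioritised(terms):
    """Every vocabulary subset maps to exactly one class, respecting severity."""
    cls = classify_effect(terms)
    assert isinstance(cls, EffectClass)
    tset = set(terms)
    if tset & variants.LOF_TERMS:
        assert cls is EffectClass.LOF
    elif tset & variants.NONSYN_TERMS:
        assert cls is EffectClass.NONSYN
    elif tset & variants.SYN_TERMS:
        assert cls is EffectClass.SYN


@pytest.mark.parametrize(
    "metrics,expected",
    [
        ({"DP": 30.0, "FS": 0.1, "ReadPosRankSum": 0.5}, True),
        ({"DP": 22.0, "FS": 0.1, "ReadPosRankSum": 0.5}, False),  # strict boundary
        ({"DP": 30.0, "FS": 0.2, "ReadPosRankSum": 0.0}, False),
        ({"DP": 30.0, "FS": 0.1, "ReadPosRankSum": -2.0}, False),  # open interval
        ({"DP": 30.0, "FS": 0.1, "ReadPosRankSum": 1.99}, True),
        ({"DP": float("nan"), "FS": 0.1, "ReadPosRankSum": 0.0}, False),
    ],
)
def test_site_quality_pass(metrics, expected):
    assert site_quality_pass(metrics, FilterConfig()) is expected


def test_missing_metric_configurable():
    m = {"DP": float("nan"), "FS": 0.1, "ReadPosRankSum": 0.0}
    assert site_quality_pass(m, FilterConfig(missing_metric_passes=True)) is True


class TestFilterDataset:
    def test_mac_filter_removes_rare_carriers(self):
        # site 0: 2 carriers; site 1: 3 carriers
        ds = make_dataset([[2, 2, 0, 0, 0], [2, 2, 2, 0, 0]])
        out, log = filter_dataset(ds, FilterConfig(min_mac=3, max_site_missing=1.0))
        assert out.n_sites == 1 and out.sites.iloc[0]["pos"] == 2

    def test_mac_allele_mode(self):
        # 2 carriers but 4 allele copies
        ds = make_dataset([[2, 2, 0, 0, 0]])
        out_c, _ = filter_dataset(ds, FilterConfig(min_mac=3, max_site_missing=1.0))
        out_a, _ = filter_dataset(
            ds, FilterConfig(min_mac=3, mac_mode="alleles", max_site_missing=1.0)
        )
        assert out_c.n_sites == 0 and out_a.n_sites == 1

    def test_clean_site_retained(self):
        ds = make_dataset([[2, 2, 2, 2, 2]])
        out, _ = filter_dataset(ds, FilterConfig())
        assert out.n_sites == 1

    def test_sample_removed_then_sites_recomputed(self):
        """A 60%-missing sample is dropped first; site missingness is then
        re-evaluated on the reduced matrix (direct enumeration oracle)."""
        M = variants.MISSING
        dosages = np.array(
            [
                [M, 2, 2, 2, 0],
                [M, 2, 2, 0, 0],
                [M, 2, 2, 2, 2],
                [2, 2, 2, 0, 2],
                [0, 2, 2, 2, 2],
            ],
            dtype=np.int8,
        )
        # sample 0 misses 3/5 = 60% > 50%
        cfg = FilterConfig(min_mac=2, max_site_missing=0.1, max_sample_missing=0.5)
        ds = make_dataset(dosages)
        out, log = filter_dataset(ds, cfg)
        assert out.samples == ["S1", "S2", "S3", "S4"]
        # on the reduced matrix every site is fully called -> all pass
        assert out.n_sites == 5
        # oracle: recompute missingness by enumeration on the reduced matrix
        reduced = dosages[:, 1:]
        assert ((reduced == M).mean(axis=1) <= 0.1).all()

    def test_empty_result_flagged(self):
        ds = make_dataset([[2, 0, 0, 0, 0]])
        out, log = filter_dataset(ds, FilterConfig(min_mac=3))
        assert out.n_sites == 0 and log["empty_result"]

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=25)
    def test_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        dosages = rng.choice(
            [0, 1, 2, variants.MISSING], size=(12, 8), p=[0.4, 0.1, 0.3, 0.2]
        ).astype(np.int8)
        cfg = FilterConfig(min_mac=2, max_site_missing=0.3, max_sample_missing=0.4)
        once, _ = filter_dataset(make_dataset(dosages), cfg)
        twice, _ = filter_dataset(once, cfg)
        assert twice.n_sites == once.n_sites
        assert twice.samples == once.samples
        assert np.array_equal(twice.dosages, once.dosages)


class TestIntersect:
    def _ds(self, keys):
        ds = make_dataset(np.zeros((len(keys), 2)), positions=[k[1] for k in keys])
        ds.sites["chrom"] = [k[0] for k in keys]
        ds.sites["ref"] = [k[2] for k in keys]
        ds.sites["alt"] = [k[3] for k in keys]
        return ds

    def test_site_absent_from_one_excluded_from_both(self):
        a = self._ds([("1", 100, "A", "T"), ("1", 200, "C", "G")])
        b = self._ds([("1", 100, "A", "T")])
        oa, ob, log = intersect_shared_sites(a, b)
        assert list(oa.sites["pos"]) == [100] and list(ob.sites["pos"]) == [100]

    def test_identity(self):
        a = self._ds([("1", 100, "A", "T"), ("2", 5, "C", "G")])
        oa, ob, _ = intersect_shared_sites(a, a)
        assert oa.sites[["chrom", "pos", "ref", "alt"]].equals(
            a.sites[["chrom", "pos", "ref", "alt"]]
        )

    def test_allele_swapped_excluded(self):
        a = self._ds([("1", 100, "A", "T")])
        b = self._ds([("1", 100, "T", "A")])
        oa, ob, log = intersect_shared_sites(a, b)
        assert oa.n_sites == 0 and ob.n_sites == 0
        assert log["n_allele_swapped_excluded"] == 1

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=20)
    def test_outputs_symmetric_in_site_keys(self, seed):
        rng = np.random.default_rng(seed)
        pool = [("1", int(p), r, a) for p in range(1, 30)
                for r, a in [("A", "T"), ("T", "A"), ("C", "G")]]
        ka = [pool[i] for i in rng.choice(len(pool), 10, replace=False)]
        kb = [pool[i] for i in rng.choice(len(pool), 10, replace=False)]
        oa, ob, _ = intersect_shared_sites(self._ds(ka), self._ds(kb))
        assert oa.n_sites == ob.n_sites
        assert set(oa.site_keys()) == set(ob.site_keys())


def test_class_counts_matches_enumeration():
    rng = np.random.default_rng(3)
    classes = [c.value for c in EffectClass]
    table = pd.DataFrame(
        {
            "site_index": range(40),
            "gene_id": rng.choice(["g1", "g2", "g3"], 40),
            "effect_class": rng.choice(classes, 40),
        }
    )
    out = class_counts(table).set_index("gene_id")
    for gid in ["g1", "g2", "g3"]:
        sub = table[table["gene_id"] == gid]
        for c in classes:
            assert out.loc[gid, f"n_{c}"] == (sub["effect_class"] == c).sum()
        props = [out.loc[gid, f"prop_{c}"] for c in classes]
        assert np.isclose(sum(props), 1.0)
    assert out.loc["__set__", "n_snps"] == 40


def test_class_counts_empty_gene_zeroed():
    table = pd.DataFrame({"site_index": [0], "gene_id": ["g1"], "effect_class": ["SYN"]})
    out = class_counts(table, gene_ids=["g1", "empty"]).set_index("gene_id")
    assert out.loc["empty", "n_snps"] == 0
    assert out.loc["empty", "prop_SYN"] == 0.0


def test_vcf_round_trip(study, tmp_path):
    """A generated study VCF re-reads into the identical dataset."""
    path = tmp_path / "rt.vcf"
    variants.write_vcf(study.dataset, str(path))
    back = variants.read_vcf(str(path))
    assert back.samples == study.dataset.samples
    assert np.array_equal(back.dosages, study.dataset.dosages)
    pd.testing.assert_frame_equal(
        back.sites[["chrom", "pos", "ref", "alt"]],
        study.dataset.sites[["chrom", "pos", "ref", "alt"]],
    )
    # ANN entries survive the round trip
    assert [a for a in back.sites["ann"]] == [a for a in study.dataset.sites["ann"]]
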