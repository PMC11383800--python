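# Methods

`stomascore` reconstructs a cellular phenotype — leaf stomatal density — from
genotypes alone, for cohorts where the phenotype itself was never measured
(e.g. herbarium specimens). It combines five pieces: effect-annotated variant
handling, per-gene population-genetic screens against length-matched control
genes, geodesic historical–modern sample pairing, climate-trend
classification, and a cumulative ±1 *functional stomatal density score* with
permutation and counterfactual inference. This note documents the models,
conventions and numerical choices; it states nothing the tests or the
acceptance script do not themselves compute.

## The functional density score

For each gene *g* with a known knock-out effect on abaxial stomatal density,
let *e_g* = +1 (loss increases density) or −1 (loss decreases density). A
sample's score is

    score = Σ_g e_g · I_g,

where *I_g* = 1 iff the sample carries ≥ 1 alternative allele at any
putatively functional SNP (loss-of-function or missense class) assigned to
*g* — one functional SNP per gene, however many it carries. The score is
relative to the reference accession: an all-reference sample scores 0.
Heterozygous carriage (dosage 1) counts as carriage; the species modelled is
selfing, so heterozygotes are rare, and a dosage-weighted mode exists for
outcrossing data. The per-pair temporal statistic is
`delta = score(modern) − score(historical)` over geographically matched
pairs.

Inference:

* **Wilcoxon signed-rank** of deltas against zero, two-sided. Zero deltas are
  dropped, ties get mid-ranks. Up to 25 nonzero deltas the exact distribution
  is computed by dynamic programming over doubled mid-ranks (scipy's exact
  method refuses ties); above that, the normal approximation with continuity
  and tie correction. Two-sided p = min(1, 2·min(P(W⁺≤w), P(W⁺≥w))).
* **Effect-label permutation**: the ±1 labels are shuffled across the
  nonzero-effect genes (composition preserved, 14 "+1" / 10 "−1" by default;
  an independent-redraw mode exists), every sample rescored and the mean
  delta recomputed; the observed mean's rank is the count of null means ≤
  observed. Because the mean delta is linear in the effect vector, each
  permutation reduces to a dot product with precomputed per-gene mean
  indicator differences.
* **Fisher's exact test** on (in climate group vs not) × (delta < 0 vs ≥ 0).
  The odds ratio is the conditional MLE (the R `fisher.test` convention,
  via `scipy.stats.contingency.odds_ratio`), the p exact two-sided. The
  table orientation is fixed and printed: OR > 1 always means more score
  decreases in the named group.
* **Latitude correlation**: one-sided Pearson with the positive alternative
  (the working hypothesis is higher scores at higher latitude); the larger
  modern cohort is subsampled without replacement to the historical size,
  100 times by default, and the regression intercept re-expressed at the
  set's median latitude to avoid extrapolation.
* **delta ~ precipitation direction**: OLS with treatment coding on pairs
  from significantly changed locations only; per-level means and p-values
  come from the equivalent no-intercept parameterisation, the model p from
  the F-test.

## Variant handling

Input is VCF with SnpEff-style `ANN` entries. Only biallelic SNPs are kept
(multi-allelic records dropped, not decomposed; indels dropped). Effect terms
are normalised by stripping `_variant` and classified with priority
LOF > NONSYN > SYN > UTR > INTRON > OTHER, so a transcript carrying several
terms gets the most severe class; "intron" is claimed by INTRON, the more
specific class, rather than OTHER. Unknown terms log a warning and fall to
OTHER.

Site quality is a strict-inequality predicate: DP > 22, FS < 0.2,
−2 < ReadPosRankSum < 2 by default; a missing metric fails the site
(configurable). Genotype filters run sample-missingness first (> 50%
dropped), then site missingness (> 15%) and minor-allele carriers (< 3
carrier samples dropped; an allele-copy mode exists). Because removing sites
can in principle push a sample back over its missingness threshold, the pass
iterates to a fixed point — this makes filtering idempotent, which the suite
asserts. Dataset intersection matches sites on (chrom, pos, ref, alt);
allele-swapped sites are excluded and logged.

## Control genes and empirical tests

Per-gene statistics scale with gene length, so the focus set is compared with
control genes drawn uniformly among background genes within ±2.5% of each
focus gene's genomic span (end − start + 1; summed exon length is not used,
matching assignment by genomic overlap). Default 1,000 draws; all focus genes
are excluded from eligibility, and within a draw two focus genes of similar
length may draw the same control (a no-duplicates mode exists). Empirical
group P is the fraction of control-draw means at least as extreme as the
focus mean, ties counted as extreme and no +1 continuity term — a focus value
beyond every control is reported as exactly 0. Per-gene outliers are flagged
when the gene statistic falls at or below the 10th (or at or above the 90th)
percentile of its own control distribution, percentiles by linear
interpolation.

## Population-genetic statistics

All estimators count allele copies from diploid dosages (n = 2 × called
samples). Per-site π = c_ref·c_alt / C(n,2); gene summaries report both the
maximum per-site π and Σπ / gene length (SNP-free positions are invariant).
Watterson's θ/bp = S / (a₁·L). Tajima's D follows the 1989 constants, in
non-overlapping 100-bp windows anchored at coordinate 1; windows without
segregating sites are missing, and n < 4 sequences is refused (variance
terms unstable). A gene's D is the SNP-weighted mean of its windows' D.
F_ST is Weir & Cockerham (1984): variance components a, b, c from diploid
genotype counts, per-SNP ratio a/(a+b+c), gene value the mean of per-SNP
ratios (not ratio-of-sums), negative estimates retained for unbiasedness.
Every estimator is checked to 1e-10 against an independent brute-force
oracle (pair enumeration for π, harmonic loops for θ and the D constants, a
nested allele-level ANOVA for F_ST).

Population schemes: the epoch scheme (historical vs modern) reuses the same
estimator; climate or life-history schemes are built by k-means on
standardised features with k selected by mean silhouette over k = 2..15 and
final labels from a single run at the argmax k under the recorded seed.

## Pairing and climate

Distances are Vincenty inverse solutions on WGS84 (checked against frozen
reference values from an independent geodesic implementation). For nearly
antipodal points, where Vincenty's iteration does not converge, Lambert's
approximation on reduced latitudes is used and flagged — metre-level error at
continental scales, within ~0.1% near the antipode; irrelevant in practice
for ≤ 500 km pairs.

Pairing is greedy and sequential: historical samples in ascending-id order
(by-year and seeded-random policies available; the order changes greedy
outcomes, so the report records the policy), each taking the nearest
remaining modern sample, which is then consumed. Selected pairs are dropped
(with reasons) when beyond 500 km, when the year gap is not positive, or when
a declarative exclusion rule fires (cross-tag pairs such as island–mainland;
sample exclusions by tag or by longitude bound). No global bipartite
optimisation is attempted — the procedure is deliberately the sequential one.

Climate series are monthly ppt (mm) and tmax (°C) per location. Annualising:
tmax takes each year's hottest month; ppt is decomposed additively with
period 12 (centred moving-average trend, endpoints dropped rather than
padded) and the trend component averaged within years — a monthly mode
exists. Direction comes from the OLS slope over years, significance from a
two-sided Spearman correlation (the slope, not the test, carries the sign),
BH-adjusted across locations *within* each variable (the variables are
analysed separately downstream), significant at adjusted p < 0.01. A pair
matches when both locations show the same significant direction; everything
else — no change, one-sided, opposing — is unmatched.

## The synthetic study

The generator emulates the study inputs at desk scale with fixed default
conditions: 60 historical (years 1817–2002) and 120 modern (1992–2012)
samples uniform over a European bounding box (35–65°N, −10–30°E); 43 focus
genes (spans 0.8–4 kb) of which 24 carry effects (14 "+1", 10 "−1"); a
400-gene background pool constructed so every focus gene has length-matched
controls; ~4 SNPs/kb with a realistic SnpEff term mixture; fully homozygous
genotypes (selfing) with 2% missingness and 5% of sites failing quality
metrics.

Functional-allele carrier frequency in an effect gene is logistic:
logit p = logit(0.10) + 0.04·(lat − 50)·e_g − 0.5·e_g·1[modern] (base
frequency 0.10 keeps indicators unsaturated; other SNPs sit at 0.15). The
cline term makes the score rise with latitude; the 0.5-logit epoch shift is
signed per effect so its default direction is a coordinated density
*decrease* — set `shift_delta=0` (and `cline_beta=0`) for null cohorts, or
`shift_scope="ppt_increase"` to confine the shift to samples in the
increased-precipitation region. Monthly climate is
mean + amplitude·sin(2πm/12) + slope·(year−1958) + AR(1) noise, with
precipitation slopes following a west–east gradient (±0.30 mm/yr at the box
edges, local sd 0.05) so that nearby pair members share a trend direction, as
real regional change does; tmax slopes are i.i.d. N(0.02, 0.02²) °C/yr.
Ground-truth slopes and effects are always written next to the data.

What the generator does **not** emulate: linkage (sites are independent),
coalescent history, ascertainment differences between historical and modern
calling, spatial clustering of collections, or any correlation between gene
function and SNP class mixture beyond the lower functional base frequency.
Passing tests therefore demonstrate that the estimators and the inference
chain are correct and calibrated under the stated generative model — not that
the biological conclusions transfer to any particular real dataset.

## Problem sizes and reproducibility

The default study (60 + 120 samples, ~440 genes, ~7,000 SNPs, 180 climate
locations × 60 years) runs end to end in well under a minute; the test
suite's calibration checks use 200 null cohorts and 2 × 50 recovery
replicates at the same study conditions. All randomness flows through
`numpy.random.default_rng` seeds derived from one master seed; identical
configs and seeds produce byte-identical reports, which the suite asserts.

## Known limitations

* Tajima windows assume near-complete genotype calls within a window (n is
  taken as 2 × samples); heavy missingness would bias the variance terms.
* The mac filter's default counts carrier samples, not allele copies — the
  two differ for heterozygous calls.
* The exact signed-rank enumeration is O(n · Σranks) and switched off above
  25 nonzero deltas in favour of the corrected normal approximation.
* Greedy pairing is order-dependent by construction; only the default
  ascending-id policy is deterministic without a seed.
* The empirical-P convention (no continuity term) can return exactly 0,
  which should be read as "below 1/n_draws", not as a literal zero.
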