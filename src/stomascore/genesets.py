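"""Gene models, SNP-to-gene assignment and length-matched control resampling.

Per-gene statistics are strongly driven by gene length (longer genes carry
more SNPs), so focus genes are compared against control genes drawn uniformly
from the background genome within a +/-2.5% length window of each focus gene.
Group-level and per-gene empirical tests against those control draws live
here too.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variants import EffectClass, VariantDataset, classify_effect

logger = logging.getLogger(__name__)


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    transcripts: list[str]  # ordered isoform ids, e.g. ["G1.1", "G1.2"]

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def read_gff3(path: str) -> dict[str, GeneModel]:
    """Load gene models (with ordered isoform ids) from a GFF3 file."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: dict[str, GeneModel] = {}
    for g in db.features_of_type("gene"):
        transcripts = [
            t.id for t in db.children(g, featuretype=("mRNA", "transcript"), order_by="start")
        ]
        # isoform ids sort naturally as <gene>.<k>
        transcripts.sort()
        genes[g.id] = GeneModel(
            gene_id=g.id,
            chrom=g.seqid,
            start=g.start,
            end=g.end,
            strand=g.strand,
            transcripts=transcripts,
        )
    return genes


def gene_lengths(genes: dict[str, GeneModel]) -> pd.Series:
    return pd.Series({gid: g.length for gid, g in genes.items()}, name="length")


def assign_snps_to_genes(
    ds: VariantDataset,
    genes: dict[str, GeneModel],
    n_isoforms: int = 2,
) -> pd.DataFrame:
    """Assign SNPs to genes through their annotated transcripts.

    A SNP belongs to a gene iff one of its ANN entries names one of the
    gene's first ``n_isoforms`` splice isoforms. The effect class is assessed
    on the first isoform (falling back to the earliest annotated isoform
    within the allowed set when the first carries no entry). ANN entries
    naming transcripts of unknown genes are left unassigned and logged.

    Returns a DataFrame with one row per (SNP, gene) assignment:
    ``site_index, gene_id, effect_class``.
    """
    transcript_to_gene: dict[str, tuple[str, int]] = {}
    for gid, g in genes.items():
        for rank, tid in enumerate(g.transcripts[:n_isoforms]):
            transcript_to_gene[tid] = (gid, rank)

    rows = []
    n_unknown = 0
    for i, ann in enumerate(ds.sites["ann"]):
        per_gene: dict[str, dict[int, list[str]]] = {}
        for feature_id, terms in ann:
            hit = transcript_to_gene.get(feature_id)
            if hit is None:
                n_unknown += 1
                continue
            gid, rank = hit
            per_gene.setdefault(gid, {})[rank] = terms
        for gid, by_rank in per_gene.items():
            first_rank = min(by_rank)
            rows.append(
                {
                    "site_index": i,
                    "gene_id": gid,
                    "effect_class": classify_effect(by_rank[first_rank]).value,
                }
            )
    if n_unknown:
        logger.info(
            "assign_snps_to_genes: %d ANN entries named transcripts outside the "
            "first %d isoforms of known genes",
            n_unknown,
            n_isoforms,
        )
    return pd.DataFrame(rows, columns=["site_index", "gene_id", "effect_class"])


def draw_length_matched_controls(
    focus: list[str],
    pool_lengths: pd.Series,
    tol: float = 0.025,
    n_sets: int = 1000,
    seed: int | None = None,
    exclude: list[str] | None = None,
    allow_duplicates: bool = True,
) -> pd.DataFrame:
    """Draw ``n_sets`` control gene lists length-matched to the focus set.

    For every focus gene, one control gene is drawn uniformly among pool
    genes whose genomic length lies within ``+/-tol`` of the focus gene's
    length. By default all focus genes are excluded from eligibility and
    two focus genes of similar length may draw the same control within a
    draw (``allow_duplicates=False`` redraws within-draw repeats).

    Raises ``ValueError`` naming the first focus gene with an empty eligible
    set. Reproducible under ``seed``.
    """
    if exclude is None:
        exclude = list(focus)
    exclude_set = set(exclude)
    rng = np.random.default_rng(seed)

    pool = pool_lengths.drop(index=[g for g in exclude_set if g in pool_lengths.index])
    pool_ids = pool.index.to_numpy()
    pool_len = pool.to_numpy(dtype=float)

    eligible: dict[str, np.ndarray] = {}
    for gid in focus:
        if gid not in pool_lengths.index:
            raise ValueError(f"focus gene {gid} has no length in the pool table")
        L = float(pool_lengths[gid])
        mask = np.abs(pool_len - L) <= tol * L
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            raise ValueError(
                f"focus gene {gid} (length {L:.0f}) has no eligible control "
                f"within +/-{tol:.1%}"
            )
        eligible[gid] = idx

    rows = []
    for draw_id in range(n_sets):
        chosen: list[str] = []
        used: set[str] = set()
        for gid in focus:
            idx = eligible[gid]
            if allow_duplicates:
                pick = pool_ids[rng.choice(idx)]
            else:
                avail = [j for j in idx if pool_ids[j] not in used]
                if not avail:
                    raise ValueError(
                        f"draw {draw_id}: no duplicate-free control left for {gid}"
                    )
                pick = pool_ids[rng.choice(avail)]
                used.add(pick)
            chosen.append(pick)
        rows.extend(
            {"draw_id": draw_id, "focus_gene": f, "control_gene": c}
            for f, c in zip(focus, chosen)
        )
    return pd.DataFrame(rows, columns=["draw_id", "focus_gene", "control_gene"])


@dataclass
class EmpiricalTestResult:
    focus_stat: float
    control_stats: np.ndarray
    tail: str
    p_empirical: float

    @property
    def n_draws(self) -> int:
        return len(self.control_stats)


def empirical_group_test(
    focus_stat: float, control_stats, tail: str
) -> EmpiricalTestResult:
    """Empirical P of the focus-group statistic against control-draw statistics.

    ``p = (# control stats at least as extreme as the focus, in the tail
    direction) / (# draws)`` with ties counted as "as extreme" and no +1
    continuity term, so a focus value beyond every control yields an exact 0.
    ``tail='two'`` doubles the smaller one-sided fraction (capped at 1).
    """
    controls = np.asarray(control_stats, dtype=float)
    controls = controls[~np.isnan(controls)]
    if len(controls) == 0:
        raise ValueError("empirical_group_test requires at least one control statistic")
    if tail == "lower":
        p = float(np.mean(controls <= focus_stat))
    elif tail == "upper":
        p = float(np.mean(controls >= focus_stat))
    elif tail == "two":
        p_low = float(np.mean(controls <= focus_stat))
        p_high = float(np.mean(controls >= focus_stat))
        p = min(1.0, 2.0 * min(p_low, p_high))
    else:
        raise ValueError(f"tail must be 'lower', 'upper' or 'two', got {tail!r}")
    return EmpiricalTestResult(float(focus_stat), controls, tail, p)


def per_gene_decile_flag(gene_stat: float, control_stats) -> str:
    """Flag a gene as a 'low'/'high' outlier against its own controls.

    'low' if the gene statistic is at or below the 10th percentile of the
    control distribution, 'high' at or above the 90th, else 'none'.
    Percentiles use linear interpolation between order statistics.
    """
    controls = np.asarray(control_stats, dtype=float)
    controls = controls[~np.isnan(controls)]
    if len(controls) == 0 or np.isnan(gene_stat):
        return "none"
    if len(controls) < 10:
        logger.warning(
            "per_gene_decile_flag: only %d controls; flag is noisy", len(controls)
        )
    q10, q90 = np.percentile(controls, [10, 90])
    if gene_stat <= q10:
        return "low"
    if gene_stat >= q90:
        return "high"
    return "none"
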