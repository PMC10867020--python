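"""Preranked GSEA engine and LSC/blast cluster classification.

The enrichment statistic is the weighted Kolmogorov-Smirnov running sum:
walking down a ranking of genes by log2 fold change, the sum rises by
|score| / sum(|score| over set genes) at each set gene ("hit") and falls by
1 / (N - N_hit) at each non-set gene; the enrichment score (ES) is the
extremum of largest magnitude. Significance comes from a gene-permutation
null: random same-size gene sets drawn from the ranking's universe. The
normalised score NES divides ES by the mean magnitude of same-sign null
scores, and the nominal p-value is the +1-corrected fraction of same-sign
null scores at least as extreme.

Single-cell clusters are classified by running this statistic with each
cluster's marker genes as the set against a bulk blast-minus-LSC ranking:
positive NES reads blast-like, negative LSC-like, and clusters failing the
|NES| and adjusted-p thresholds remain intermediate ("LSC/Blast").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .bulk_signatures import ExpressionTable, GeneSignature

__all__ = [
    "EnrichmentResult",
    "make_ranking",
    "build_bulk_ranking",
    "bulk_log2fc_ranking",
    "preranked_gsea",
    "classify_clusters",
    "de_fold_change",
]


@dataclass
class EnrichmentResult:
    """Result of a single preranked GSEA run."""

    set_name: str
    es: float
    nes: float
    p_nominal: float
    n_perm: int
    seed: int
    n_hits: int
    p_adj: float | None = None


def make_ranking(scores: pd.Series) -> pd.Series:
    """Sort a gene -> score series descending; ties break lexicographically.

    Raises on duplicate genes or non-finite scores.
    """
    if scores.index.duplicated().any():
        raise ValueError("ranking contains duplicate genes")
    if not np.isfinite(scores.to_numpy(dtype=float)).all():
        raise ValueError("ranking scores must be finite")
    df = scores.rename("score").rename_axis("gene").reset_index()
    df = df.sort_values(["score", "gene"], ascending=[False, True])
    return pd.Series(df["score"].to_numpy(), index=df["gene"])


def build_bulk_ranking(
    lsc_sig: GeneSignature, blast_sig: GeneSignature
) -> pd.Series:
    """Blast-minus-LSC ranking from the two bulk signatures.

    Blast-signature genes enter with their (positive) log2fc, LSC-signature
    genes with the negated one, so positive scores mean blast-high.
    """
    overlap = set(lsc_sig.genes) & set(blast_sig.genes)
    if overlap:
        raise ValueError(f"signatures overlap: {sorted(overlap)[:5]}")
    scores = pd.concat(
        [
            blast_sig.log2fc.reindex(blast_sig.genes),
            -lsc_sig.log2fc.reindex(lsc_sig.genes),
        ]
    )
    return make_ranking(scores)


def bulk_log2fc_ranking(
    table: ExpressionTable, group_a: str = "Blast", group_b: str = "LSC"
) -> pd.Series:
    """Rank all genes by normalized bulk log2FC of group_a minus group_b.

    With the defaults the ranking is blast-minus-LSC over the whole table,
    the orientation where positive NES reads blast-like.
    """
    from .bulk_signatures import normalize_bulk

    norm = table if table.log2 else normalize_bulk(table, log2=True)
    return make_ranking(norm.group_mean(group_a) - norm.group_mean(group_b))


def _running_sum(scores: np.ndarray, hit: np.ndarray, weight: float) -> np.ndarray:
    """Running-sum path over one ranking for one hit-indicator vector."""
    n = scores.size
    n_hit = int(hit.sum())
    w = np.abs(scores) ** weight
    denom = w[hit].sum()
    if denom == 0:
        # all hit scores are zero: fall back to unweighted hit steps
        steps = np.where(hit, 1.0 / n_hit, -1.0 / (n - n_hit))
    else:
        steps = np.where(hit, w / denom, -1.0 / (n - n_hit))
    return np.cumsum(steps)


def _es_from_path(path: np.ndarray) -> float:
    return float(path[np.argmax(np.abs(path))])


def preranked_gsea(
    ranking: pd.Series,
    gene_set,
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
) -> EnrichmentResult:
    """Weighted-KS preranked gene set enrichment with a gene-permutation null.

    ``ranking`` is a gene -> log2FC series (use :func:`make_ranking` to fix
    the sort and tie order). ``gene_set`` is any iterable of gene ids; genes
    absent from the ranking are ignored. The null draws ``n_perm`` uniform
    random same-size gene sets from the ranking's universe (seeded).
    """
    ranking = make_ranking(ranking)
    genes = ranking.index.to_numpy()
    scores = ranking.to_numpy(dtype=float)
    n = genes.size
    members = list(getattr(gene_set, "genes", gene_set))
    in_set = np.isin(genes, members)
    n_hit = int(in_set.sum())
    if n_hit == 0:
        raise ValueError("gene set shares no genes with the ranking")
    if n_hit == n:
        raise ValueError("gene set equals the entire ranking; ES undefined")

    es = _es_from_path(_running_sum(scores, in_set, weight))

    rng = np.random.default_rng(seed)
    # vectorized null: n_perm random hit-indicator rows of n_hit genes each
    keys = rng.random((n_perm, n))
    idx = np.argpartition(keys, n_hit - 1, axis=1)[:, :n_hit]
    hits = np.zeros((n_perm, n), dtype=bool)
    hits[np.arange(n_perm)[:, None], idx] = True

    w = np.abs(scores) ** weight
    hit_w = np.where(hits, w, 0.0)
    denom = hit_w.sum(axis=1, keepdims=True)
    miss = -1.0 / (n - n_hit)
    safe = np.where(denom == 0, 1.0, denom)
    steps = np.where(hits, hit_w / safe, miss)
    zero_rows = (denom.ravel() == 0)
    if zero_rows.any():
        steps[zero_rows] = np.where(hits[zero_rows], 1.0 / n_hit, miss)
    paths = np.cumsum(steps, axis=1)
    arg = np.argmax(np.abs(paths), axis=1)
    null_es = paths[np.arange(n_perm), arg]

    same_sign = null_es >= 0 if es >= 0 else null_es < 0
    n_same = int(same_sign.sum())
    if n_same > 0:
        nes = es / np.mean(np.abs(null_es[same_sign]))
        p = (1 + int((np.abs(null_es[same_sign]) >= abs(es)).sum())) / (1 + n_same)
    else:  # no same-sign permutation scores; scale by the overall null
        nes = es / np.mean(np.abs(null_es))
        p = 1.0 / (1 + n_perm)
    return EnrichmentResult(
        set_name=getattr(gene_set, "name", "set"),
        es=es,
        nes=float(nes),
        p_nominal=float(p),
        n_perm=n_perm,
        seed=seed,
        n_hits=n_hit,
    )


def classify_clusters(
    profiles: list,
    lsc_sig: GeneSignature,
    blast_sig: GeneSignature,
    nes_min: float = 1.0,
    padj_max: float = 0.05,
    ranking: pd.Series | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> list:
    """Classify cluster profiles as LSC, Blast or intermediate (LSC/Blast).

    Each cluster's marker genes form the gene set; the ranking is
    blast-minus-LSC (built from the two bulk signatures unless supplied), so
    NES > ``nes_min`` with BH-adjusted p < ``padj_max`` (adjusted across
    clusters) reads Blast, NES < -``nes_min`` reads LSC, anything else stays
    "LSC/Blast". Profiles are annotated in place (``cls.class_`` and
    ``cls.enrichment``) and returned.
    """
    if not profiles:
        raise ValueError("no cluster profiles to classify")
    if ranking is None:
        ranking = build_bulk_ranking(lsc_sig, blast_sig)
    ranking = make_ranking(ranking)
    results = []
    for prof in profiles:
        marker_genes = [g for g in prof.marker_genes() if g in ranking.index]
        if not marker_genes:
            raise ValueError(
                f"cluster {prof.cluster_id}: no marker gene present in ranking"
            )
        res = preranked_gsea(ranking, marker_genes, n_perm=n_perm, seed=seed)
        res.set_name = str(prof.cluster_id)
        results.append(res)
    padj = multipletests([r.p_nominal for r in results], method="fdr_bh")[1]
    for prof, res, pa in zip(profiles, results, padj):
        res.p_adj = float(pa)
        if res.nes > nes_min and pa < padj_max:
            prof.class_ = "Blast"
        elif res.nes < -nes_min and pa < padj_max:
            prof.class_ = "LSC"
        else:
            prof.class_ = "LSC/Blast"
        prof.enrichment = res
    return profiles


def de_fold_change(
    table: ExpressionTable,
    group_a: str,
    group_b: str,
    fold: float = 2.0,
    min_count: int = 50,
    test: str | None = "t",
    padj_max: float = 0.1,
) -> tuple[list[str], list[str]]:
    """Fold-change differential expression on a counts table.

    Genes with fewer than ``min_count`` counts in every sample are dropped;
    counts are CPM-normalized per sample; a gene is up (a over b) when the
    group-mean ratio is at least ``fold``, down symmetrically. When both
    groups have replicates (>= 2 samples) and ``test`` is not None, a
    two-sample t-test on log2(CPM+1) with BH-adjusted p < ``padj_max`` is
    additionally required ("t" pooled-variance, "welch" unequal-variance);
    without replicates the fold rule alone applies. Returns (up, down) gene
    lists, each sorted.
    """
    from scipy import stats

    for g in (group_a, group_b):
        if g not in set(table.sample_groups):
            raise ValueError(f"group {g!r} missing from table")
    counts = table.values
    keep = (counts >= min_count).any(axis=1)
    counts = counts.loc[keep]
    cpm = counts / counts.sum(axis=0) * 1e6

    cols_a = table.sample_groups.index[table.sample_groups == group_a]
    cols_b = table.sample_groups.index[table.sample_groups == group_b]
    mean_a = cpm[cols_a].mean(axis=1).to_numpy()
    mean_b = cpm[cols_b].mean(axis=1).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        up = mean_a >= fold * mean_b
        down = mean_b >= fold * mean_a
    up &= mean_a > 0
    down &= mean_b > 0

    has_reps = len(cols_a) >= 2 and len(cols_b) >= 2
    if test is not None and has_reps:
        log_a = np.log2(cpm[cols_a].to_numpy() + 1.0)
        log_b = np.log2(cpm[cols_b].to_numpy() + 1.0)
        res = stats.ttest_ind(
            log_a, log_b, axis=1, equal_var=(test != "welch")
        )
        pvals = np.nan_to_num(res.pvalue, nan=1.0)
        padj = multipletests(pvals, method="fdr_bh")[1]
        sig = padj < padj_max
        up &= sig
        down &= sig

    genes = cpm.index.to_numpy()
    return sorted(genes[up]), sorted(genes[down])
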