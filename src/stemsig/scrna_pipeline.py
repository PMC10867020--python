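"""Single-cell RNA-seq pipeline: QC, normalization, cell-cycle scoring,
cluster detection, marker genes, contamination filtering and Z-summaries.

The cell container is an :class:`anndata.AnnData` with raw UMIs kept in
``layers["counts"]`` and normalized values in ``X``. The processing order is
QC -> log-normalize -> cell-cycle score -> regress/scale/cluster -> marker
detection -> contamination filter, mirroring a standard droplet-scRNA-seq
workflow for sorted leukemic samples.

Cell-cycle phase is assigned by the binned-control module score: the score
of a gene program is the mean normalized expression of its genes minus the
mean of control genes drawn from the same average-expression bins, so a
positive score means the program is expressed above its expression-matched
background. Clustering regresses out S/G2M scores per gene (ordinary least
squares), z-scales residuals (clipped at +-10), and runs modularity-based
community detection (Leiden, RBConfiguration) on a shared-nearest-neighbour
graph built from PCA space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests

from .bulk_signatures import GeneSignature

__all__ = [
    "ClusterProfile",
    "qc_filter",
    "log_normalize",
    "score_cell_cycle",
    "regress_scale_cluster",
    "find_cluster_markers",
    "filter_contaminant_clusters",
    "phase_subset_markers",
    "cluster_signature_zscore",
    "module_score",
    "order_clusters_by_signature",
    "center_by_patient",
]


@dataclass
class ClusterProfile:
    """Per-cluster summary: markers, mean expression, class and order."""

    cluster_id: str
    markers: pd.DataFrame  # gene, log2fc, p, p_adj
    mean_expression: pd.Series
    n_cells: int
    class_: str | None = None
    order_index: int | None = None
    enrichment: object | None = None

    def marker_genes(self) -> list[str]:
        return list(self.markers["gene"])


def _counts(adata: AnnData) -> sparse.csr_matrix:
    if "counts" in adata.layers:
        return sparse.csr_matrix(adata.layers["counts"])
    return sparse.csr_matrix(adata.X)


def _dense(x) -> np.ndarray:
    return x.toarray() if sparse.issparse(x) else np.asarray(x)


def qc_filter(
    adata: AnnData,
    min_genes: int = 200,
    max_genes: int = 5000,
    max_mito: float = 0.15,
) -> AnnData:
    """Remove low-quality cells.

    Retains cells with detected (nonzero) genes in [min_genes, max_genes]
    inclusive and mitochondrial UMI fraction <= max_mito, the standard
    droplet QC gate (cells below 200 genes are empty-ish droplets, above
    5000 likely doublets, mito-rich cells dying). Mito genes come from
    ``var["mito"]`` or, failing that, an "MT-" name prefix.
    """
    counts = _counts(adata)
    n_detected = np.asarray((counts > 0).sum(axis=1)).ravel()
    if "mito" in adata.var:
        mito_mask = adata.var["mito"].to_numpy(dtype=bool)
    else:
        mito_mask = adata.var_names.str.startswith("MT-").to_numpy()
    total = np.asarray(counts.sum(axis=1)).ravel()
    mito = np.asarray(counts[:, mito_mask].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito / total, 1.0)

    keep = (n_detected >= min_genes) & (n_detected <= max_genes) & (
        mito_frac <= max_mito
    )
    if not keep.any():
        raise ValueError("QC removed every cell")
    out = adata[keep].copy()
    out.obs["n_genes"] = n_detected[keep]
    out.obs["mito_fraction"] = mito_frac[keep]
    out.uns["qc"] = {
        "n_input": int(adata.n_obs),
        "n_removed_genes": int(
            ((n_detected < min_genes) | (n_detected > max_genes)).sum()
        ),
        "n_removed_mito": int((mito_frac > max_mito).sum()),
        "n_kept": int(keep.sum()),
    }
    return out


def log_normalize(adata: AnnData, scale: float = 1e4) -> AnnData:
    """Library-size normalize and log transform: x -> ln(1 + scale*x/total)."""
    counts = _counts(adata)
    totals = np.asarray(counts.sum(axis=1)).ravel()
    if (totals == 0).any():
        bad = adata.obs_names[totals == 0]
        raise ValueError(f"cells with zero total UMIs: {list(bad[:5])}")
    out = adata.copy()
    norm = counts.multiply(scale / totals[:, None]).tocsr()
    norm.data = np.log1p(norm.data)
    out.X = norm
    out.layers["counts"] = counts
    out.obs["total_umis"] = totals
    return out


def module_score(
    adata: AnnData,
    genes: list[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Binned-control module score per cell.

    mean(normalized expression of program genes) minus mean over a control
    set drawn per program gene from the same average-expression bin
    (equal-frequency bins over all genes; ``n_ctrl`` draws per gene, union
    of draws as the control set). Program genes absent from the matrix are
    dropped with a warning.
    """
    present = [g for g in genes if g in adata.var_names]
    dropped = set(genes) - set(present)
    if dropped:
        warnings.warn(f"{len(dropped)} program genes absent from matrix")
    if not present:
        raise ValueError("no program gene present in the matrix")
    rng = np.random.default_rng(seed)
    X = _dense(adata.X)
    avg = X.mean(axis=0)
    order = np.argsort(avg, kind="stable")
    bin_of = np.empty(adata.n_vars, dtype=int)
    # equal-frequency bins over the sorted average expression
    bin_of[order] = np.floor(
        np.arange(adata.n_vars) * n_bins / adata.n_vars
    ).astype(int)
    gene_idx = adata.var_names.get_indexer(present)

    ctrl: set[int] = set()
    for gi in gene_idx:
        pool = np.flatnonzero(bin_of == bin_of[gi])
        take = rng.choice(pool, size=min(n_ctrl, pool.size), replace=False)
        ctrl.update(int(t) for t in take)
    ctrl_idx = np.array(sorted(ctrl))
    return X[:, gene_idx].mean(axis=1) - X[:, ctrl_idx].mean(axis=1)


def score_cell_cycle(
    adata: AnnData,
    s_genes: GeneSignature | list[str],
    g2m_genes: GeneSignature | list[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> AnnData:
    """Score S and G2M programs per cell and call the phase.

    Phase is S when the S score is the larger positive score (ties go to S),
    G2M when the G2M score is, and G1 when neither score is positive.
    """
    s_list = list(getattr(s_genes, "genes", s_genes))
    g2m_list = list(getattr(g2m_genes, "genes", g2m_genes))
    out = adata.copy()
    out.obs["S_score"] = module_score(adata, s_list, n_bins, n_ctrl, seed)
    out.obs["G2M_score"] = module_score(adata, g2m_list, n_bins, n_ctrl, seed + 1)
    s = out.obs["S_score"].to_numpy()
    g = out.obs["G2M_score"].to_numpy()
    phase = np.where(
        (s <= 0) & (g <= 0), "G1", np.where(s >= g, "S", "G2M")
    )
    out.obs["phase"] = pd.Categorical(phase, categories=["G1", "S", "G2M"])
    return out


def _snn_graph(pcs: np.ndarray, n_neighbors: int, prune: float = 1 / 15):
    """Shared-nearest-neighbour graph: Jaccard overlap of kNN sets."""
    from sklearn.neighbors import NearestNeighbors
    import igraph as ig

    nn = NearestNeighbors(n_neighbors=n_neighbors, algorithm="brute")
    nn.fit(pcs)
    knn = nn.kneighbors(return_distance=False)
    n = pcs.shape[0]
    # neighbor sets include the cell itself
    sets = np.hstack([np.arange(n)[:, None], knn])
    indicator = sparse.csr_matrix(
        (
            np.ones(sets.size, dtype=np.float64),
            (np.repeat(np.arange(n), sets.shape[1]), sets.ravel()),
        ),
        shape=(n, n),
    )
    shared = indicator @ indicator.T
    shared = shared.tocoo()
    k = sets.shape[1]
    jac = shared.data / (2 * k - shared.data)
    keep = (jac >= prune) & (shared.row < shared.col)
    edges = list(zip(shared.row[keep].tolist(), shared.col[keep].tolist()))
    g = ig.Graph(n=n, edges=edges)
    g.es["weight"] = jac[keep].tolist()
    return g


def regress_scale_cluster(
    adata: AnnData,
    resolution: float = 0.8,
    n_pcs: int = 30,
    n_neighbors: int = 20,
    seed: int = 0,
    clip: float = 10.0,
) -> AnnData:
    """Regress out cell-cycle scores, scale, and cluster.

    Per gene, normalized values are replaced by residuals of an OLS fit on
    (intercept, S score, G2M score); residuals are z-scaled per gene and
    clipped at +-``clip``; PCA reduces to ``n_pcs`` components; Leiden
    community detection (RBConfiguration modularity) at ``resolution`` runs
    on the shared-nearest-neighbour graph. Cluster ids are renumbered by
    size, largest first, as strings "0", "1", ...
    """
    import leidenalg
    from sklearn.decomposition import PCA

    if adata.n_obs <= n_pcs:
        raise ValueError(f"need more than n_pcs={n_pcs} cells, got {adata.n_obs}")
    for col in ("S_score", "G2M_score"):
        if col not in adata.obs:
            raise ValueError("cell-cycle scores missing; run score_cell_cycle")
    out = adata.copy()
    X = _dense(out.X).astype(np.float64)
    design = np.column_stack(
        [
            np.ones(out.n_obs),
            out.obs["S_score"].to_numpy(),
            out.obs["G2M_score"].to_numpy(),
        ]
    )
    beta, *_ = np.linalg.lstsq(design, X, rcond=None)
    resid = X - design @ beta
    sd = resid.std(axis=0, ddof=1)
    # genes fully explained by the covariates would amplify numerical noise
    near_zero = sd <= 1e-8 * np.maximum(X.std(axis=0), 1e-12)
    sd[near_zero] = 1.0
    scaled = np.clip((resid - resid.mean(axis=0)) / sd, -clip, clip)
    scaled[:, near_zero] = 0.0
    out.layers["scaled"] = scaled

    pca = PCA(n_components=n_pcs, svd_solver="full")
    pcs = pca.fit_transform(scaled)
    out.obsm["X_pca"] = pcs

    graph = _snn_graph(pcs, n_neighbors=n_neighbors)
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
    )
    labels = np.asarray(part.membership)
    sizes = pd.Series(labels).value_counts()
    remap = {old: str(new) for new, old in enumerate(sizes.index)}
    out.obs["cluster"] = pd.Categorical([remap[l] for l in labels])
    out.uns["clustering"] = {
        "resolution": resolution,
        "n_pcs": n_pcs,
        "n_neighbors": n_neighbors,
        "seed": seed,
    }
    return out


def _rank_markers(
    X: np.ndarray,
    in_group: np.ndarray,
    genes: np.ndarray,
    min_log2fc: float,
    max_padj: float,
    positive_only: bool,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Rank-sum marker test of one group against the rest."""
    a = X[in_group]
    b = X[~in_group]
    res = stats.mannwhitneyu(a, b, axis=0, alternative="two-sided")
    pvals = np.nan_to_num(res.pvalue, nan=1.0)
    padj = multipletests(pvals, method="fdr_bh")[1]
    # fold change on the de-logged scale, Seurat-style pseudocounted means
    mean_a = np.expm1(a).mean(axis=0)
    mean_b = np.expm1(b).mean(axis=0)
    log2fc = np.log2(mean_a + pseudocount) - np.log2(mean_b + pseudocount)
    if positive_only:
        keep = (log2fc >= min_log2fc) & (padj < max_padj)
    else:
        keep = (np.abs(log2fc) >= min_log2fc) & (padj < max_padj)
    df = pd.DataFrame(
        {"gene": genes[keep], "log2fc": log2fc[keep], "p": pvals[keep],
         "p_adj": padj[keep]}
    )
    return df.sort_values("log2fc", ascending=False).reset_index(drop=True)


def find_cluster_markers(
    adata: AnnData,
    min_log2fc: float = 0.25,
    max_padj: float = 0.1,
    positive_only: bool = False,
    groupby: str = "cluster",
    pseudocount: float = 1.0,
) -> list[ClusterProfile]:
    """Marker genes per cluster: rank-sum test of the cluster versus rest.

    Keeps genes with average log2 fold change of at least ``min_log2fc``
    (absolute value unless ``positive_only``) and BH-adjusted p below
    ``max_padj``. Clusters of a single cell are skipped with a warning.
    Use ``min_log2fc=0.5, positive_only=True`` for the integrated LSC/blast
    marker list variant.
    """
    if groupby not in adata.obs:
        raise ValueError(f"obs column {groupby!r} missing; cluster first")
    X = _dense(adata.X)
    genes = adata.var_names.to_numpy()
    profiles = []
    for cid in _group_order(adata.obs[groupby]):
        in_group = (adata.obs[groupby] == cid).to_numpy()
        if in_group.sum() < 2:
            warnings.warn(f"cluster {cid}: fewer than 2 cells, skipped")
            continue
        markers = _rank_markers(
            X, in_group, genes, min_log2fc, max_padj, positive_only, pseudocount
        )
        profiles.append(
            ClusterProfile(
                cluster_id=str(cid),
                markers=markers,
                mean_expression=pd.Series(
                    X[in_group].mean(axis=0), index=adata.var_names
                ),
                n_cells=int(in_group.sum()),
            )
        )
    return profiles


def _group_order(series: pd.Series) -> list:
    if isinstance(series.dtype, pd.CategoricalDtype):
        return [c for c in series.cat.categories if (series == c).any()]
    return sorted(series.unique())


def filter_contaminant_clusters(
    adata: AnnData, gene: str = "RUNX1T1", min_cells: int = 4
) -> AnnData:
    """Drop clusters with fewer than ``min_cells`` cells expressing ``gene``.

    Clusters of leukemic cells should express the fusion transcript; a
    cluster nearly devoid of it is contaminating healthy material.
    """
    if gene not in adata.var_names:
        raise ValueError(f"gene {gene!r} absent from matrix")
    if "cluster" not in adata.obs:
        raise ValueError("clusters not assigned")
    counts = _counts(adata)
    gi = adata.var_names.get_loc(gene)
    expressing = np.asarray((counts[:, gi] > 0).todense()).ravel()
    keep_cells = np.ones(adata.n_obs, dtype=bool)
    removed = []
    for cid in _group_order(adata.obs["cluster"]):
        in_c = (adata.obs["cluster"] == cid).to_numpy()
        if int(expressing[in_c].sum()) < min_cells:
            keep_cells &= ~in_c
            removed.append(str(cid))
    out = adata[keep_cells].copy()
    out.uns["contamination_filter"] = {
        "gene": gene, "min_cells": min_cells, "removed_clusters": removed
    }
    if isinstance(out.obs["cluster"].dtype, pd.CategoricalDtype):
        out.obs["cluster"] = out.obs["cluster"].cat.remove_unused_categories()
    return out


def phase_subset_markers(
    adata: AnnData,
    exclude_phases: set[str] = frozenset({"S", "G2M"}),
    grouping: str = "class",
    min_log2fc: float = 0.25,
    max_padj: float = 0.1,
    positive_only: bool = False,
) -> list[ClusterProfile]:
    """Marker detection restricted to cells outside the excluded phases.

    Used to find genes differential specifically among G0/G1 cells, grouped
    by the LSC/Blast class labels rather than cluster ids.
    """
    if "phase" not in adata.obs:
        raise ValueError("phases not assigned; run score_cell_cycle")
    keep = ~adata.obs["phase"].isin(list(exclude_phases)).to_numpy()
    if not keep.any():
        raise ValueError("excluding those phases leaves no cells")
    sub = adata[keep].copy()
    if isinstance(sub.obs[grouping].dtype, pd.CategoricalDtype):
        sub.obs[grouping] = sub.obs[grouping].cat.remove_unused_categories()
    return find_cluster_markers(
        sub, min_log2fc=min_log2fc, max_padj=max_padj,
        positive_only=positive_only, groupby=grouping,
    )


def order_clusters_by_signature(
    adata: AnnData,
    blast_sig: GeneSignature | list[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> list[str]:
    """Cluster ordering along the LSC-to-blast axis.

    Clusters are ordered by ascending mean Blast-signature module score, so
    the most LSC-like cluster (lowest blast score) comes first — a
    deterministic stand-in for trajectory pseudotime rooted at the earliest
    LSC population.
    """
    genes = list(getattr(blast_sig, "genes", blast_sig))
    score = module_score(adata, genes, n_bins, n_ctrl, seed)
    means = (
        pd.Series(score, index=adata.obs.index)
        .groupby(adata.obs["cluster"], observed=True)
        .mean()
    )
    return [str(c) for c in means.sort_values().index]


def cluster_signature_zscore(
    adata: AnnData,
    sig: GeneSignature | list[str],
    ordering: list[str] | None = None,
) -> pd.DataFrame:
    """Genes x clusters Z-score matrix of per-cluster mean expression.

    Each signature gene's per-cluster mean (normalized values) is z-scored
    across clusters with the sample standard deviation (ddof=1); constant
    rows map to 0. Columns follow ``ordering`` (default: cluster id order);
    rows are grouped by the cluster where the gene's Z peaks and sorted
    highest-to-lowest within each group, the display convention of the
    subtype-specific heatmap.
    """
    genes = list(getattr(sig, "genes", sig))
    present = [g for g in genes if g in adata.var_names]
    if len(present) < len(genes):
        warnings.warn(f"{len(genes) - len(present)} signature genes absent")
    if not present:
        raise ValueError("no signature gene present in matrix")
    if "cluster" not in adata.obs:
        raise ValueError("clusters not assigned")
    X = _dense(adata.X)
    idx = adata.var_names.get_indexer(present)
    df = pd.DataFrame(X[:, idx], columns=present, index=adata.obs.index)
    means = df.groupby(adata.obs["cluster"], observed=True).mean().T  # genes x clusters
    if ordering is not None:
        means = means[[c for c in ordering if c in means.columns]]
    mu = means.mean(axis=1)
    sd = means.std(axis=1, ddof=1)
    z = means.sub(mu, axis=0).div(sd.replace(0, np.nan), axis=0).fillna(0.0)
    peak = z.to_numpy().argmax(axis=1)
    peak_val = z.to_numpy().max(axis=1)
    order = np.lexsort((-peak_val, peak))
    return z.iloc[order]


def center_by_patient(adata: AnnData, patient_key: str = "patient") -> AnnData:
    """Per-patient gene-mean centering before joint analysis.

    A deliberately simple batch-alignment step: subtract each patient's
    per-gene mean from that patient's cells so patient-level offsets do not
    dominate the joint PCA. Flagged in ``uns`` so downstream output records
    that centering (not anchor-based integration) was applied.
    """
    out = adata.copy()
    X = _dense(out.X).astype(np.float64)
    for pat in out.obs[patient_key].unique():
        mask = (out.obs[patient_key] == pat).to_numpy()
        X[mask] -= X[mask].mean(axis=0)
    out.X = X
    out.uns["integration"] = {"method": "per-patient mean centering"}
    return out
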