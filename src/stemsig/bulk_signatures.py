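"""Bulk RNA-seq signature derivation for sorted LSC/blast populations.

Implements the bulk side of the LSC-vs-blast analysis: upper-quartile
normalization of FPKM tables, derivation of LSC- and blast-specific gene
signatures from sorted-population expression, and the all-versus-each
subtype-specific gene rule used to define t(8;21)-specific genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionTable",
    "GeneSignature",
    "normalize_bulk",
    "derive_lsc_blast_signature",
    "derive_subtype_specific_genes",
]


@dataclass
class ExpressionTable:
    """Genes x samples expression matrix with per-sample group labels.

    values
        DataFrame indexed by gene id, one column per sample. Non-negative
        FPKM (or counts) on the linear scale unless ``log2`` is True.
    sample_groups
        Series mapping sample -> group label (e.g. "LSC", "Blast", "t821").
    protein_coding
        Optional boolean Series per gene; genes absent default to True.
    log2
        Whether ``values`` are log2-transformed.
    """

    values: pd.DataFrame
    sample_groups: pd.Series
    protein_coding: pd.Series | None = None
    log2: bool = False

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dups[:5])}")
        missing = [s for s in self.values.columns if s not in self.sample_groups.index]
        if missing:
            raise ValueError(f"samples without group label: {missing}")
        self.sample_groups = self.sample_groups.loc[self.values.columns]

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def groups(self) -> list[str]:
        return list(pd.unique(self.sample_groups))

    def group_mean(self, group: str) -> pd.Series:
        cols = self.sample_groups.index[self.sample_groups == group]
        if len(cols) == 0:
            raise ValueError(f"group {group!r} not present")
        return self.values[cols].mean(axis=1)

    def coding_mask(self) -> pd.Series:
        if self.protein_coding is None:
            return pd.Series(True, index=self.genes)
        return self.protein_coding.reindex(self.genes, fill_value=True).astype(bool)


@dataclass
class GeneSignature:
    """A named, directed gene set with per-gene log2 fold-changes."""

    name: str
    genes: list[str]
    log2fc: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("signature genes must be unique")
        if len(self.log2fc) and not np.isfinite(self.log2fc.to_numpy()).all():
            raise ValueError("log2fc must be finite")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)

    def to_frame(self) -> pd.DataFrame:
        fc = self.log2fc.reindex(self.genes)
        return pd.DataFrame({"gene": self.genes, "log2fc": fc.to_numpy()})


def upper_quartiles(values: pd.DataFrame) -> pd.Series:
    """75th percentile of the positive values of each sample (column)."""
    uq = {}
    for s in values.columns:
        col = values[s].to_numpy(dtype=float)
        pos = col[col > 0]
        if pos.size == 0:
            raise ValueError(f"sample {s!r} has all-zero values; cannot normalize")
        uq[s] = float(np.percentile(pos, 75))
    return pd.Series(uq)


def normalize_bulk(
    table: ExpressionTable, pseudocount: float = 1.0, log2: bool = True
) -> ExpressionTable:
    """Upper-quartile normalize an FPKM table, then optionally log2 transform.

    Each sample is scaled so that its upper quartile (75th percentile over
    genes with value > 0) equals the geometric mean of all samples' upper
    quartiles; values then become log2(x + pseudocount) unless ``log2`` is
    False, in which case the scaled linear values are returned (used by the
    subtype-specific derivation, which applies its fold rule on the linear
    scale).
    """
    if table.log2:
        raise ValueError("table is already log2-transformed")
    uq = upper_quartiles(table.values)
    target = float(np.exp(np.mean(np.log(uq.to_numpy()))))
    scaled = table.values * (target / uq)
    if log2:
        scaled = np.log2(scaled + pseudocount)
    return replace(table, values=scaled, log2=log2)


def derive_lsc_blast_signature(
    table: ExpressionTable,
    fpkm_floor: float = 1.0,
    fc_threshold: float = 1.0,
    lsc_group: str = "LSC",
    blast_group: str = "Blast",
    pseudocount: float = 1.0,
) -> tuple[GeneSignature, GeneSignature]:
    """Derive LSC-specific and blast-specific gene signatures.

    From a raw FPKM table of sorted LSC and blast samples: keep
    protein-coding genes whose raw mean FPKM exceeds ``fpkm_floor`` in either
    population; upper-quartile normalize and log2 transform; assign each
    retained gene to the population with the higher normalized mean whenever
    the linear fold-change between the two population means exceeds
    ``fc_threshold`` (default 1.0: any difference; pass 2.0 for a stricter
    two-fold rule). Returns ``(lsc_signature, blast_signature)``; the LSC
    signature records LSC-minus-blast log2 fold changes (positive) and the
    blast signature blast-minus-LSC (positive).
    """
    for g in (lsc_group, blast_group):
        if g not in set(table.sample_groups):
            raise ValueError(f"required group {g!r} missing from table")
    raw_lsc = table.group_mean(lsc_group)
    raw_blast = table.group_mean(blast_group)
    expressed = (raw_lsc > fpkm_floor) | (raw_blast > fpkm_floor)
    keep = expressed & table.coding_mask()

    # the fold rule applies to the linear ratio of normalized group means
    # (a pseudocounted log scale would not absorb per-sample scaling exactly)
    norm = normalize_bulk(table, pseudocount=pseudocount, log2=False)
    mean_lsc = norm.group_mean(lsc_group)[keep]
    mean_blast = norm.group_mean(blast_group)[keep]
    tiny = np.finfo(float).tiny
    log2fc_blast = np.log2(np.maximum(mean_blast, tiny) / np.maximum(mean_lsc, tiny))
    log2fc_blast = log2fc_blast.clip(-1000, 1000)
    log2_thr = np.log2(fc_threshold)

    lsc_mask = -log2fc_blast > log2_thr
    blast_mask = log2fc_blast > log2_thr
    lsc_genes = sorted(log2fc_blast.index[lsc_mask])
    blast_genes = sorted(log2fc_blast.index[blast_mask])
    lsc_sig = GeneSignature("LSC", lsc_genes, (-log2fc_blast[lsc_genes]))
    blast_sig = GeneSignature("Blast", blast_genes, log2fc_blast[blast_genes])
    return lsc_sig, blast_sig


def derive_subtype_specific_genes(
    table: ExpressionTable, target_group: str, fold: float = 2.0
) -> GeneSignature:
    """Genes specific to one subtype versus each of the others.

    A gene qualifies when the target group's mean is at least ``fold`` times
    the mean of EVERY other group individually (all-versus-each, not versus
    the pooled mean); the comparison is inclusive (>=) on the linear scale.
    Recorded log2fc is target mean over the strongest competing group's mean.
    """
    groups = table.groups()
    if target_group not in groups:
        raise ValueError(f"target group {target_group!r} not present")
    others = [g for g in groups if g != target_group]
    if not others:
        raise ValueError("need at least two sample groups")
    if table.log2:
        raise ValueError("subtype rule applies to linear-scale values")

    target = table.group_mean(target_group).to_numpy(dtype=float)
    other_means = np.column_stack(
        [table.group_mean(g).to_numpy(dtype=float) for g in others]
    )
    max_other = other_means.max(axis=1)
    qualifies = target >= fold * max_other
    # genes silent everywhere trivially satisfy 0 >= fold*0; exclude them
    qualifies &= target > 0
    genes = sorted(table.genes[qualifies])
    with np.errstate(divide="ignore"):
        fc = np.log2(target / np.maximum(max_other, np.finfo(float).tiny))
    fc_series = pd.Series(fc, index=table.genes)[genes]
    fc_series = fc_series.clip(upper=np.log2(np.finfo(float).max))
    return GeneSignature(f"{target_group}-specific", genes, fc_series)
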