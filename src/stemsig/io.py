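"""Readers/writers for the plain-text formats the package exchanges.

Matrix Market + barcodes/features TSV for UMI matrices, FASTA for synthetic
genomes, BED/bedGraph via :mod:`stemsig.chromatin`, two-column TSV for gene
signatures, JSON for ground truth and config echoes.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import io as scio
from scipy import sparse

from .bulk_signatures import GeneSignature
from .chromatin import PeakCollection, write_bedgraph
from .synthetic_data import PeakLandscape

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_sc_mtx",
    "read_sc_mtx",
    "write_signature",
    "read_signature",
    "write_landscape",
]


def write_fasta(genome: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    """Load a small FASTA fully into memory (pyfaidx handles random access
    for large genomes; synthetic fixtures fit comfortably in RAM)."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_sc_mtx(adata: AnnData, outdir) -> None:
    """10x-style triplet: matrix.mtx (genes x cells), features/barcodes TSV,
    plus the cell metadata and ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts = adata.layers.get("counts", adata.X)
    scio.mmwrite(outdir / "matrix.mtx", sparse.csr_matrix(counts).T.astype(int))
    adata.var_names.to_series().to_csv(
        outdir / "features.tsv", sep="\t", header=False, index=False
    )
    adata.obs_names.to_series().to_csv(
        outdir / "barcodes.tsv", sep="\t", header=False, index=False
    )
    adata.obs.to_csv(outdir / "cell_meta.tsv", sep="\t")
    if "sim" in adata.uns:
        (outdir / "ground_truth.json").write_text(
            json.dumps(adata.uns["sim"], indent=2)
        )


def read_sc_mtx(indir) -> AnnData:
    indir = Path(indir)
    mat = scio.mmread(indir / "matrix.mtx").tocsr().T.astype(np.float64)
    features = pd.read_csv(indir / "features.tsv", sep="\t", header=None)[0]
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0]
    var = pd.DataFrame(index=pd.Index(features, name="gene"))
    var["mito"] = var.index.str.startswith("MT-")
    obs = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    meta_path = indir / "cell_meta.tsv"
    if meta_path.exists():
        obs = pd.read_csv(meta_path, sep="\t", index_col=0)
    adata = AnnData(X=sparse.csr_matrix(mat), obs=obs, var=var)
    adata.layers["counts"] = adata.X.copy()
    gt = indir / "ground_truth.json"
    if gt.exists():
        adata.uns["sim"] = json.loads(gt.read_text())
    return adata


def write_signature(sig: GeneSignature, path) -> None:
    sig.to_frame().to_csv(path, sep="\t", index=False)


def read_signature(path, name: str | None = None) -> GeneSignature:
    df = pd.read_csv(path, sep="\t")
    fc = pd.Series(df["log2fc"].to_numpy(), index=df["gene"])
    return GeneSignature(name or Path(path).stem, list(df["gene"]), fc)


def write_landscape(landscape: PeakLandscape, outdir) -> None:
    """Serialize a synthetic peak landscape: FASTA genome, per-set BED,
    per-sample bedGraph, ground-truth CSV/JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(landscape.genome, outdir / "genome.fa")
    for name, df in landscape.peak_sets.items():
        PeakCollection(df, source=name).to_bed(outdir / f"peaks_{name}.bed")
    for sample, cov in landscape.coverage.items():
        write_bedgraph(cov, outdir / f"coverage_{sample}.bedGraph")
    landscape.motif_insertions.to_csv(outdir / "motif_insertions.csv", index=False)
    landscape.intensity.to_csv(outdir / "intensity.csv")
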