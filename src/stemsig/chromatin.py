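"""Open-chromatin and binding analysis over peak unions.

Coordinates are BED-style 0-based half-open throughout. A peak union is the
bookended merge of all peaks called in any compared sample; tag densities
are quantified in fixed windows centred on union summits, CPM-normalized
against each sample's genome-wide tag total and log2(CPM + 0.1) transformed
for fold-change calls. Differential sites are a simple symmetric fold rule
(>= 2-fold by default) on the log2CPM matrix.

Coverage tracks are held in memory as per-chromosome per-bp arrays
(bedGraph in/out); at the scale this package targets that is both exact and
fast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "PeakCollection",
    "TagMatrix",
    "read_bedgraph",
    "write_bedgraph",
    "coverage_total",
    "merge_peak_union",
    "quantify_windows",
    "differential_sites",
    "ranked_density_matrix",
    "normalized_average_profile",
    "profile_fold_changes",
    "binding_correlation",
    "assign_peaks_to_genes",
]

Coverage = dict[str, np.ndarray]  # chrom -> per-bp tag density


@dataclass
class PeakCollection:
    """Sorted genomic intervals with summits (0-based half-open)."""

    df: pd.DataFrame  # columns: chrom, start, end, summit, score, name
    source: str = ""

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end"}
        if not required <= set(self.df.columns):
            raise ValueError(f"peak table needs columns {sorted(required)}")
        df = self.df.copy()
        if "summit" not in df.columns:
            df["summit"] = (df["start"] + df["end"]) // 2
        if "score" not in df.columns:
            df["score"] = 0.0
        if "name" not in df.columns:
            df["name"] = [f"peak{i}" for i in range(len(df))]
        bad = df.index[(df["start"] >= df["end"])]
        if len(bad):
            raise ValueError(f"start >= end at rows {list(bad[:5])}")
        bad = df.index[(df["summit"] < df["start"]) | (df["summit"] >= df["end"])]
        if len(bad):
            raise ValueError(f"summit outside interval at rows {list(bad[:5])}")
        self.df = df.sort_values(["chrom", "start"], kind="stable").reset_index(
            drop=True
        )

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_bed(cls, path, source: str = "") -> "PeakCollection":
        """BED6(+summit) reader: optional column 7 is an absolute summit."""
        rows = []
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("track", "#", "browser")):
                    continue
                f = line.split("\t")
                try:
                    row = {
                        "chrom": f[0],
                        "start": int(f[1]),
                        "end": int(f[2]),
                        "name": f[3] if len(f) > 3 else f"peak{ln}",
                        "score": float(f[4]) if len(f) > 4 else 0.0,
                    }
                    if len(f) > 6:
                        row["summit"] = int(f[6])
                except (ValueError, IndexError) as e:
                    raise ValueError(f"{path}: malformed BED at line {ln}: {e}")
                rows.append(row)
        return cls(pd.DataFrame(rows), source=source or str(path))

    @classmethod
    def from_narrowpeak(cls, path, source: str = "") -> "PeakCollection":
        """narrowPeak reader; column 10 is the summit offset (-1 -> midpoint)."""
        rows = []
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("track", "#")):
                    continue
                f = line.split("\t")
                try:
                    start, end = int(f[1]), int(f[2])
                    offset = int(f[9]) if len(f) > 9 else -1
                    summit = start + offset if offset >= 0 else (start + end) // 2
                    rows.append(
                        {
                            "chrom": f[0],
                            "start": start,
                            "end": end,
                            "name": f[3] if len(f) > 3 else f"peak{ln}",
                            "score": float(f[6]) if len(f) > 6 else 0.0,
                            "summit": summit,
                        }
                    )
                except (ValueError, IndexError) as e:
                    raise ValueError(
                        f"{path}: malformed narrowPeak at line {ln}: {e}"
                    )
        return cls(pd.DataFrame(rows), source=source or str(path))

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for _, r in self.df.iterrows():
                fh.write(
                    f"{r['chrom']}\t{r['start']}\t{r['end']}\t{r['name']}\t"
                    f"{r['score']}\t.\t{r['summit']}\n"
                )


@dataclass
class TagMatrix:
    """Peaks x samples tag densities with an explicit normalization state."""

    values: pd.DataFrame  # index: peak name
    state: str  # raw | CPM | log2CPM
    half_width: int
    totals: pd.Series  # per-sample genome-wide tag totals
    peaks: PeakCollection | None = None

    def to_cpm(self) -> "TagMatrix":
        if self.state != "raw":
            raise ValueError(f"expected raw state, got {self.state}")
        cpm = self.values / self.totals * 1e6
        return replace(self, values=cpm, state="CPM")

    def to_log2cpm(self, pseudocount: float = 0.1) -> "TagMatrix":
        cpm = self if self.state == "CPM" else self.to_cpm()
        return replace(cpm, values=np.log2(cpm.values + pseudocount), state="log2CPM")


# ---------------------------------------------------------------------------
# coverage I/O


def read_bedgraph(path, chrom_sizes: dict[str, int] | None = None) -> Coverage:
    """Load a bedGraph into per-chromosome per-bp arrays."""
    df = pd.read_csv(
        path, sep="\t", comment="t", header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": int, "end": int, "value": float},
    )
    sizes = dict(chrom_sizes or {})
    for chrom, sub in df.groupby("chrom"):
        sizes.setdefault(chrom, int(sub["end"].max()))
    cov = {c: np.zeros(n) for c, n in sizes.items()}
    for chrom, sub in df.groupby("chrom"):
        arr = cov[chrom]
        for s, e, v in sub[["start", "end", "value"]].itertuples(index=False):
            arr[s:e] = v
    return cov


def write_bedgraph(cov: Coverage, path) -> None:
    """Run-length encode per-bp arrays back to bedGraph (zeros omitted)."""
    with open(path, "w") as fh:
        for chrom in sorted(cov):
            arr = np.asarray(cov[chrom])
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [arr.size]])
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def coverage_total(cov: Coverage) -> float:
    """Genome-wide tag total: sum of per-bp coverage."""
    return float(sum(np.asarray(a).sum() for a in cov.values()))


# ---------------------------------------------------------------------------
# peak union and quantification


def merge_peak_union(collections: list[PeakCollection]) -> PeakCollection:
    """Bookended merge of all input peaks into a disjoint union.

    Overlapping or directly adjacent intervals merge; the union interval's
    summit is the summit of the highest-scoring contributing peak (leftmost
    on ties).
    """
    frames = [c.df for c in collections if len(c)]
    if not frames:
        raise ValueError("no peaks to merge")
    allp = pd.concat(frames, ignore_index=True).sort_values(
        ["chrom", "start"], kind="stable"
    )
    out_rows = []
    cur = None
    for r in allp.itertuples(index=False):
        if cur is not None and r.chrom == cur["chrom"] and r.start <= cur["end"]:
            cur["end"] = max(cur["end"], r.end)
            # ties keep the first (leftmost) contributing peak's summit
            if r.score > cur["score"]:
                cur["score"], cur["summit"] = r.score, r.summit
        else:
            if cur is not None:
                out_rows.append(cur)
            cur = {
                "chrom": r.chrom, "start": r.start, "end": r.end,
                "summit": r.summit, "score": r.score,
            }
    if cur is not None:
        out_rows.append(cur)
    df = pd.DataFrame(out_rows)
    df["name"] = [f"union{i:05d}" for i in range(len(df))]
    return PeakCollection(df, source="union")


def _window_mean(cov: Coverage, chrom: str, summit: int, half_width: int) -> float:
    arr = cov.get(chrom)
    if arr is None:
        warnings.warn(f"no coverage for chromosome {chrom}")
        return 0.0
    lo, hi = summit - half_width, summit + half_width
    if lo < 0 or hi > arr.size:
        warnings.warn(f"window [{lo},{hi}) clipped on {chrom}")
        lo, hi = max(lo, 0), min(hi, arr.size)
    if hi <= lo:
        return 0.0
    return float(arr[lo:hi].mean())


def quantify_windows(
    union: PeakCollection,
    coverages: dict[str, Coverage],
    half_width: int = 200,
) -> TagMatrix:
    """Mean per-bp tag density in a window centred on each union summit.

    The default half-width of 200 gives the 400-bp summit window. CPM
    normalization (via :meth:`TagMatrix.to_cpm`) divides by each sample's
    genome-wide tag total.
    """
    values = {}
    for sample, cov in coverages.items():
        values[sample] = [
            _window_mean(cov, r.chrom, int(r.summit), half_width)
            for r in union.df.itertuples(index=False)
        ]
    df = pd.DataFrame(values, index=pd.Index(union.df["name"], name="peak"))
    totals = pd.Series({s: coverage_total(c) for s, c in coverages.items()})
    return TagMatrix(df, state="raw", half_width=half_width, totals=totals,
                     peaks=union)


def differential_sites(
    tm: TagMatrix, sample_a: str, sample_b: str, fold: float = 2.0
) -> tuple[PeakCollection, PeakCollection]:
    """Peaks at least ``fold`` different between two samples (log2CPM scale).

    Returns (a_specific, b_specific): a-specific peaks satisfy
    log2CPM(a) - log2CPM(b) >= log2(fold), b-specific symmetrically.
    """
    if tm.state != "log2CPM":
        raise ValueError("differential_sites expects a log2CPM TagMatrix")
    for s in (sample_a, sample_b):
        if s not in tm.values.columns:
            raise ValueError(f"unknown sample {s!r}")
    if tm.peaks is None:
        raise ValueError("TagMatrix lacks its peak collection")
    diff = tm.values[sample_a] - tm.values[sample_b]
    thr = np.log2(fold)
    names = tm.peaks.df["name"]
    a_mask = names.map(dict(zip(diff.index, diff >= thr))).fillna(False)
    b_mask = names.map(dict(zip(diff.index, diff <= -thr))).fillna(False)
    a_df = tm.peaks.df[a_mask.to_numpy(dtype=bool)].reset_index(drop=True)
    b_df = tm.peaks.df[b_mask.to_numpy(dtype=bool)].reset_index(drop=True)
    mk = lambda df, src: PeakCollection(df, source=src) if len(df) else \
        PeakCollection(pd.DataFrame(columns=tm.peaks.df.columns).astype(
            tm.peaks.df.dtypes), source=src)
    return mk(a_df, f"{sample_a}-specific"), mk(b_df, f"{sample_b}-specific")


# ---------------------------------------------------------------------------
# profiles and density matrices


def _binned_profile(
    cov: Coverage, chrom: str, center: int, half_width: int, bin_size: int
) -> np.ndarray:
    n_bins = 2 * half_width // bin_size
    arr = cov.get(chrom)
    out = np.zeros(n_bins)
    if arr is None:
        return out
    for b in range(n_bins):
        lo = center - half_width + b * bin_size
        hi = lo + bin_size
        lo_c, hi_c = max(lo, 0), min(hi, arr.size)
        if hi_c > lo_c:
            out[b] = arr[lo_c:hi_c].sum() / (hi - lo)
    return out


def ranked_density_matrix(
    coverages: dict[str, Coverage],
    peaks: PeakCollection,
    sample_a: str,
    sample_b: str,
    half_width: int = 1000,
    bin_size: int = 10,
) -> dict[str, pd.DataFrame]:
    """Per-sample peaks x bins density matrices, rows ranked by A:B fold.

    Rows are sorted by descending fold change of the average tag count
    between ``sample_a`` and ``sample_b`` in the +-``half_width`` window
    (ties fall back to genomic order); the same row order applies to every
    sample so all matrices plot along one axis.
    """
    if (2 * half_width) % bin_size:
        raise ValueError("bin size must divide the window")
    means = {}
    for s in (sample_a, sample_b):
        means[s] = np.array(
            [
                _window_mean(coverages[s], r.chrom, int(r.summit), half_width)
                for r in peaks.df.itertuples(index=False)
            ]
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(
            means[sample_b] > 0,
            means[sample_a] / means[sample_b],
            np.where(means[sample_a] > 0, np.inf, 1.0),
        )
    order = np.lexsort((np.arange(len(fc)), -fc))
    names = peaks.df["name"].to_numpy()[order]
    out = {}
    for sample, cov in coverages.items():
        rows = [
            _binned_profile(
                cov, peaks.df["chrom"].iat[i], int(peaks.df["summit"].iat[i]),
                half_width, bin_size,
            )
            for i in order
        ]
        offsets = np.arange(-half_width, half_width, bin_size)
        out[sample] = pd.DataFrame(rows, index=names, columns=offsets)
    return out


def normalized_average_profile(
    coverages: dict[str, Coverage],
    sites: PeakCollection,
    half_width: int = 1000,
    bin_size: int = 10,
) -> tuple[dict[str, pd.DataFrame], pd.Series]:
    """Average coverage profile around sites, with equalizing scale factors.

    For every sample, the profile is the mean binned coverage over all sites
    as a function of offset from the summit. The per-sample peak height is
    the central (summit) bin of that profile; scale factors bring every
    sample's height to the common mean height, so scaled profiles are
    directly comparable. Returns ({sample: raw and scaled profile}, factors).
    """
    if len(sites) == 0:
        raise ValueError("empty site set")
    profiles = {}
    heights = {}
    for sample, cov in coverages.items():
        rows = np.array(
            [
                _binned_profile(cov, r.chrom, int(r.summit), half_width, bin_size)
                for r in sites.df.itertuples(index=False)
            ]
        )
        prof = rows.mean(axis=0)
        offsets = np.arange(-half_width, half_width, bin_size)
        center = len(prof) // 2
        heights[sample] = prof[center]
        profiles[sample] = pd.DataFrame({"offset": offsets, "raw": prof})
    mean_height = float(np.mean(list(heights.values())))
    factors = pd.Series(
        {
            s: (mean_height / h if h > 0 else 1.0)
            for s, h in heights.items()
        }
    )
    for sample in profiles:
        profiles[sample]["scaled"] = profiles[sample]["raw"] * factors[sample]
    return profiles, factors


def profile_fold_changes(
    coverages: dict[str, Coverage],
    site_sets: dict[str, PeakCollection],
    sample_a: str,
    sample_b: str,
    half_width: int = 1000,
    bin_size: int = 10,
) -> pd.Series:
    """log2 fold change of the normalized average peak height, per site set.

    The heatmap statistic comparing a factor's binding with versus without a
    perturbation at LSC- and blast-specific site sets: for each site set the
    average profile height (central bin) of ``sample_a`` over ``sample_b``.
    """
    out = {}
    for name, sites in site_sets.items():
        _, factors = normalized_average_profile(
            {s: coverages[s] for s in (sample_a, sample_b)},
            sites, half_width, bin_size,
        )
        # factors are inversely proportional to heights
        out[name] = float(np.log2(factors[sample_b] / factors[sample_a]))
    return pd.Series(out, name=f"log2({sample_a}/{sample_b})")


def binding_correlation(
    tm: TagMatrix,
) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise Spearman correlation of tag counts plus a display order.

    Hierarchical clustering (complete linkage, Euclidean distance on the
    correlation rows) gives the heatmap leaf order. Samples with constant
    tag counts yield undefined (NaN) correlations and are excluded from the
    clustering order computation.
    """
    if tm.values.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    if tm.values.shape[0] < 3:
        raise ValueError("need at least 3 peaks")
    corr = tm.values.corr(method="spearman")
    const = tm.values.std(axis=0) == 0
    corr.loc[const, :] = np.nan
    corr.loc[:, const] = np.nan
    np.fill_diagonal(corr.values, 1.0)
    ok = corr.index[~const]
    if len(ok) > 2:
        link = hierarchy.linkage(
            pdist(corr.loc[ok, ok].to_numpy()), method="complete"
        )
        order = [ok[i] for i in hierarchy.leaves_list(link)]
    else:
        order = list(ok)
    order += [s for s in corr.index if s not in order]
    return corr, [str(s) for s in order]


# ---------------------------------------------------------------------------
# peak -> gene assignment


def assign_peaks_to_genes(
    peaks: PeakCollection,
    tss: pd.DataFrame,
    hic_map: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assign each peak to a gene, preferring promoter-capture Hi-C links.

    ``tss`` needs columns (gene, chrom, tss); ``hic_map`` (chrom, start,
    end, gene) maps interacting fragments to promoters. A peak whose summit
    falls inside a mapped fragment takes that fragment's gene even when
    another TSS is nearer (the chromatin loop identifies the true target);
    otherwise the nearest TSS by absolute summit distance wins, ties going
    to the lexicographically smaller gene id. Peaks on chromosomes absent
    from the TSS table come back unassigned and flagged.
    """
    rows = []
    for r in peaks.df.itertuples(index=False):
        summit = int(r.summit)
        gene, source, dist = None, None, np.nan
        if hic_map is not None and len(hic_map):
            frag = hic_map[
                (hic_map["chrom"] == r.chrom)
                & (hic_map["start"] <= summit)
                & (summit < hic_map["end"])
            ]
            if len(frag):
                centers = (frag["start"] + frag["end"]) / 2
                frag = frag.assign(_d=(centers - summit).abs())
                frag = frag.sort_values(["_d", "gene"], kind="stable")
                gene, source = frag["gene"].iloc[0], "hic"
                dist = 0.0
        if gene is None:
            cand = tss[tss["chrom"] == r.chrom]
            if len(cand) == 0:
                rows.append(
                    {"peak": r.name, "gene": None, "source": "unassigned",
                     "distance": np.nan}
                )
                continue
            d = (cand["tss"] - summit).abs()
            cand = cand.assign(_d=d).sort_values(["_d", "gene"], kind="stable")
            gene, source, dist = (
                cand["gene"].iloc[0], "nearest_tss", float(cand["_d"].iloc[0])
            )
        rows.append({"peak": r.name, "gene": gene, "source": source,
                     "distance": dist})
    return pd.DataFrame(rows)
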