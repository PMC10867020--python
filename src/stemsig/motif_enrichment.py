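"""PWM motif scanning and the peak-set motif enrichment score.

A motif is a position-probability matrix with a log-odds hit threshold.
Scanning scores every position of a window centred on each peak summit on
both strands against a background base distribution; positions at or above
the threshold are hits.

The enrichment score for motif i in peak set j is

    S_ij = (n_ij / m_j) / (sum_j n_ij / sum_j m_j)

where n_ij is the number of peaks in set j containing at least one hit of
motif i and m_j the number of peaks in set j: the motif's hit frequency in
a set relative to its pooled frequency across all compared sets. By
construction the m-weighted mean of S_ij over sets is exactly 1 for every
motif with any hits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .chromatin import PeakCollection

__all__ = [
    "MotifModel",
    "MotifHit",
    "read_motifs",
    "write_motifs",
    "consensus_pwm",
    "scan_pwm",
    "count_hit_peaks",
    "motif_enrichment_score",
    "motif_spacing_profile",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class MotifModel:
    """Position-probability matrix with a log-odds hit threshold (bits)."""

    name: str
    matrix: np.ndarray  # L x 4, columns A,C,G,T; rows sum to 1
    threshold: float
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("matrix must be L x 4 (A,C,G,T)")
        if self.matrix.shape[0] < 4:
            raise ValueError("motif length must be >= 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("matrix rows must sum to 1")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def log_odds(self, floor: float = 1e-3) -> np.ndarray:
        """log2 odds versus background, probabilities floored to avoid -inf."""
        p = np.maximum(self.matrix, floor)
        return np.log2(p / self.background)

    def max_score(self, floor: float = 1e-3) -> float:
        return float(self.log_odds(floor).max(axis=1).sum())

    def revcomp(self) -> "MotifModel":
        return MotifModel(
            self.name, self.matrix[::-1, ::-1], self.threshold,
            self.background[::-1],
        )


@dataclass
class MotifHit:
    peak: str
    offset: int  # match start relative to the peak summit
    strand: str
    score: float
    position: int  # absolute genomic start of the match


def consensus_pwm(
    name: str, consensus: str, p_match: float = 0.997, threshold: float | None = None
) -> MotifModel:
    """Near-deterministic PWM from a consensus string.

    Handy for fixtures: with the default threshold (90% of the maximal
    attainable score) only near-exact instances pass.
    """
    L = len(consensus)
    mat = np.full((L, 4), (1 - p_match) / 3)
    for i, b in enumerate(consensus):
        mat[i, _BASE_INDEX[b]] = p_match
    m = MotifModel(name, mat, 0.0)
    m.threshold = 0.9 * m.max_score() if threshold is None else threshold
    return m


def read_motifs(path) -> list[MotifModel]:
    """Read motifs from Homer-style text: '>name consensus threshold' headers
    followed by one A/C/G/T probability row per motif position."""
    motifs, name, thr, rows = [], None, None, []
    def flush():
        if name is not None:
            motifs.append(MotifModel(name, np.array(rows), thr))
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                fields = line[1:].split()
                name = fields[0]
                thr = float(fields[2]) if len(fields) > 2 else None
                if thr is None:
                    raise ValueError(
                        f"motif {name}: no threshold supplied in motif file"
                    )
                rows = []
            else:
                rows.append([float(x) for x in line.split()])
    flush()
    return motifs


def write_motifs(motifs: list[MotifModel], path) -> None:
    with open(path, "w") as fh:
        for m in motifs:
            consensus = "".join("ACGT"[i] for i in m.matrix.argmax(axis=1))
            fh.write(f">{m.name}\t{consensus}\t{m.threshold:g}\n")
            for row in m.matrix:
                fh.write("\t".join(f"{v:.6f}" for v in row) + "\n")


def _encode(seq: str) -> np.ndarray:
    """Sequence -> integer codes; anything outside ACGT becomes 4 (N)."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    codes = np.full(arr.size, 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        codes[arr == ord(base)] = idx
    return codes


def _scan_scores(codes: np.ndarray, lom: np.ndarray) -> np.ndarray:
    """Log-odds score at every start position; windows touching N score -inf."""
    L = lom.shape[0]
    n_pos = codes.size - L + 1
    if n_pos <= 0:
        return np.empty(0)
    # pad the score table with a -inf row for N
    table = np.vstack([lom.T, np.full((1, L), -np.inf)]).T  # (L, 5)
    idx = np.lib.stride_tricks.sliding_window_view(codes, L)
    return table[np.arange(L), idx].sum(axis=1)


def scan_pwm(
    genome: dict[str, str],
    peaks: PeakCollection,
    motif: MotifModel,
    window: int | None = 200,
    floor: float = 1e-3,
) -> list[MotifHit]:
    """Scan peak windows for motif hits on both strands.

    ``window`` bp centred on each summit (None scans the whole peak). A hit
    is any start position whose log-odds score is >= the motif threshold;
    minus-strand hits are reported at the genomic start of the matched
    segment with strand "-". Windows running past a contig end are clipped
    with a warning.
    """
    lom = motif.log_odds(floor)
    lom_rc = motif.revcomp().log_odds(floor)
    hits: list[MotifHit] = []
    for r in peaks.df.itertuples(index=False):
        seq = genome[r.chrom]
        if window is None:
            lo, hi = int(r.start), int(r.end)
        else:
            lo = int(r.summit) - window // 2
            hi = int(r.summit) + (window - window // 2)
        if lo < 0 or hi > len(seq):
            warnings.warn(f"peak {r.name}: window clipped at contig edge")
            lo, hi = max(lo, 0), min(hi, len(seq))
        codes = _encode(seq[lo:hi])
        for strand, mat in (("+", lom), ("-", lom_rc)):
            scores = _scan_scores(codes, mat)
            for pos in np.flatnonzero(scores >= motif.threshold):
                hits.append(
                    MotifHit(
                        peak=str(r.name),
                        offset=int(lo + pos - r.summit),
                        strand=strand,
                        score=float(scores[pos]),
                        position=int(lo + pos),
                    )
                )
    return hits


def count_hit_peaks(hits: list[MotifHit]) -> int:
    """Number of distinct peaks containing at least one hit."""
    return len({h.peak for h in hits})


def motif_enrichment_score(
    n: pd.DataFrame,
    m: pd.Series,
    multiplicity: bool = False,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-set motif enrichment scores S_ij plus a display clustering order.

    ``n`` is motifs x peak-sets counts of hit-bearing peaks (or total hits
    if the table was built in ``multiplicity`` mode — the formula is
    agnostic, the flag is recorded for provenance only); ``m`` gives each
    set's peak total. Motifs with zero hits everywhere come back as NaN rows
    and are excluded from the clustering order.
    """
    if (m <= 0).any():
        bad = list(m.index[m <= 0])
        raise ValueError(f"peak sets with zero peaks: {bad}")
    n = n[m.index]
    if not multiplicity and (n.to_numpy() > m.to_numpy()).any():
        raise ValueError("n_ij exceeds m_j; counts are not per-peak containment")
    total_n = n.sum(axis=1)
    total_m = float(m.sum())
    # evaluate as (n * total_m) / (m * total_n): integer-valued products stay
    # exact in floating point, so rational scores like 3/2 come out exact
    with np.errstate(divide="ignore", invalid="ignore"):
        s = (n * total_m).div(m, axis=1).div(total_n, axis=0)
    s[total_n == 0] = np.nan
    defined = s.index[total_n > 0]
    if len(defined) > 2:
        link = hierarchy.linkage(
            pdist(s.loc[defined].to_numpy()), method="complete"
        )
        order = [str(defined[i]) for i in hierarchy.leaves_list(link)]
    else:
        order = [str(i) for i in defined]
    return s, order


def motif_spacing_profile(
    anchors: list[MotifHit],
    partners: list[MotifHit],
    half_width: int = 1000,
    bin_size: int = 10,
    smooth: bool = False,
    smooth_frac: float = 0.2,
) -> pd.DataFrame:
    """Binned frequency of partner-motif positions relative to anchors.

    For every anchor hit, partner hits within +-``half_width`` are binned by
    signed offset; frequencies are counts per anchor. Optional loess
    smoothing adds a display column; the raw bins are always emitted.
    """
    if not anchors:
        raise ValueError("no anchor hits")
    if (2 * half_width) % bin_size:
        raise ValueError("bin size must divide the window")
    n_bins = 2 * half_width // bin_size
    edges = np.arange(-half_width, half_width + bin_size, bin_size)
    counts = np.zeros(n_bins)
    partner_pos = np.array([p.position for p in partners], dtype=float)
    for a in anchors:
        rel = partner_pos - a.position
        sel = (rel >= -half_width) & (rel < half_width)
        if sel.any():
            which = ((rel[sel] + half_width) // bin_size).astype(int)
            np.add.at(counts, which, 1.0)
    freq = counts / len(anchors)
    out = pd.DataFrame({"offset": edges[:-1], "frequency": freq})
    if smooth:
        from statsmodels.nonparametric.smoothers_lowess import lowess
        sm = lowess(freq, edges[:-1], frac=smooth_frac, return_sorted=False)
        out["smoothed"] = sm
    return out
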