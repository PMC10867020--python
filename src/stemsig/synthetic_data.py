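"""Synthetic fixtures emulating the statistical structure of the study inputs.

Every downstream stage of the package (bulk signatures, the single-cell
pipeline, chromatin accessibility, motif enrichment, CyTOF statistics) is
exercised on data produced here, so nothing needs downloading. The generator
emulates:

* bulk FPKM panels with planted group-specific genes at a configured fold,
* 10x-style UMI count matrices over an LSC population, a blast population
  and a transition population carrying a mixture of both marker programs,
  with planted cell-cycle programs and controlled mitochondrial fractions,
* a random genome with peak sets into which motif instances are inserted at
  controlled per-set rates, plus per-sample coverage with known per-peak
  intensities (hence known fold-changes),
* CyTOF-like ion-count tables with planted population shifts.

Ground truth (which genes/peaks/cells carry which planted effect) is always
recorded alongside the data. A single seeded generator stream drives each
generator call, so a seed fully determines every output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse

from .bulk_signatures import ExpressionTable

__all__ = [
    "PopulationSpec",
    "BulkGroupSpec",
    "SimConfig",
    "PeakLandscape",
    "gen_bulk_expression",
    "gen_sc_counts",
    "gen_peak_landscape",
    "gen_cytof_table",
]

PHASES = ("G1", "S", "G2M")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PopulationSpec:
    """One simulated cell population with its planted marker program."""

    name: str
    marker_indices: list[int]
    marker_log2_effect: float = 2.0
    # fraction of cells in G1 / S / G2M
    cycle_fractions: tuple[float, float, float] = (0.70, 0.20, 0.10)

    def validate(self) -> None:
        if abs(sum(self.cycle_fractions) - 1.0) > 1e-9:
            raise ValueError(
                f"population {self.name!r}: cycle_fractions must sum to 1"
            )
        if self.marker_indices and self.marker_log2_effect < 0:
            raise ValueError("marker effects must be non-negative")


@dataclass
class BulkGroupSpec:
    """One bulk sample group with planted group-specific genes."""

    name: str
    n_samples: int
    specific_indices: list[int] = field(default_factory=list)
    log2_effect: float = 2.0


def _default_populations() -> list[PopulationSpec]:
    # Quiescence gradient: LSCs mostly G0/G1, blasts actively cycling.
    lsc = PopulationSpec("LSC", list(range(0, 100)), 2.0, (0.71, 0.19, 0.10))
    trans = PopulationSpec(
        "Transition",
        list(range(50, 100)) + list(range(100, 150)),
        2.0,
        (0.57, 0.28, 0.15),
    )
    blast = PopulationSpec("Blast", list(range(100, 200)), 2.0, (0.43, 0.37, 0.20))
    return [lsc, trans, blast]


def _default_bulk_groups() -> list[BulkGroupSpec]:
    return [
        BulkGroupSpec("LSC", 3, list(range(0, 100)), 2.0),
        BulkGroupSpec("Blast", 3, list(range(100, 200)), 2.0),
    ]


@dataclass
class SimConfig:
    """Configuration for all synthetic generators.

    The defaults are the package's study conditions: 2,000 genes; three cell
    populations (LSC, transition, blast) of 500 cells each with 100 planted
    markers per pole at log2 effect 2 (the transition carries half of each
    pole's markers); cell-cycle fractions reflecting quiescent LSCs versus
    cycling blasts; a planted S and G2M program; mitochondrial fractions
    drawn from [0.01, 0.10] over a 10-gene MT- block; two peak sets of 100
    non-overlapping peaks on a 140-kb genome; and a two-group bulk panel
    planting the same marker genes.
    """

    seed: int = 0
    # --- expression ---
    n_genes: int = 2000
    n_cells_per_population: int = 500
    populations: list[PopulationSpec] = field(default_factory=_default_populations)
    s_gene_indices: list[int] = field(default_factory=lambda: list(range(300, 340)))
    g2m_gene_indices: list[int] = field(default_factory=lambda: list(range(340, 380)))
    cycle_log2_effect: float = 2.0
    mito_fraction_range: tuple[float, float] = (0.01, 0.10)
    n_mito_genes: int = 10
    nb_dispersion: float = 0.4
    mean_library_size: float = 6000.0
    contaminant_gene: str = "RUNX1T1"
    # --- bulk ---
    bulk_groups: list[BulkGroupSpec] = field(default_factory=_default_bulk_groups)
    bulk_noise_sigma: float = 0.0
    # --- chromatin ---
    genome_length: int = 140_000
    n_peaks_per_set: dict[str, int] = field(
        default_factory=lambda: {"A": 100, "B": 100}
    )
    peak_width: int = 200
    motif_consensus: dict[str, str] = field(
        default_factory=lambda: {"GATA_like": "AGATAAGATAAG"}
    )
    motif_insertion_rates: dict[tuple[str, str], float] = field(
        default_factory=lambda: {("GATA_like", "A"): 0.30, ("GATA_like", "B"): 0.10}
    )
    suppress_chance_hits: bool = True
    coverage_samples: tuple[str, ...] = ("condA", "condB")
    # per (sample, set) flat coverage intensity over the 400-bp summit window
    coverage_intensity: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("condA", "A"): 12.0,
            ("condA", "B"): 4.0,
            ("condB", "A"): 4.0,
            ("condB", "B"): 12.0,
        }
    )
    # --- cytof ---
    cytof_markers: tuple[str, ...] = (
        "CD34", "CD38", "CD117", "Ki67", "pJUN", "pJNK", "CD45", "CD11b",
    )
    cytof_populations: tuple[str, ...] = ("LSC", "Blast")
    cytof_cells_per_population: int = 500
    cytof_shifts: dict[tuple[str, str], float] = field(
        default_factory=lambda: {("Ki67", "Blast"): 1.0, ("CD38", "Blast"): 1.5}
    )
    cytof_sigma: float = 1.0

    def validate(self) -> None:
        for pop in self.populations:
            pop.validate()
        for rate in self.motif_insertion_rates.values():
            if not 0.0 <= rate <= 1.0:
                raise ValueError("motif insertion rates must lie in [0, 1]")
        lo, hi = self.mito_fraction_range
        if not (0.0 <= lo <= hi < 1.0):
            raise ValueError("mito_fraction_range must satisfy 0 <= lo <= hi < 1")
        seen: set[int] = set()
        for grp in self.bulk_groups:
            overlap = seen & set(grp.specific_indices)
            if overlap:
                raise ValueError(
                    f"planted bulk gene sets overlap (gene indices {sorted(overlap)[:5]})"
                )
            seen |= set(grp.specific_indices)
        for idx in seen:
            if not 0 <= idx < self.n_genes:
                raise ValueError("planted gene index out of range")

    def gene_names(self) -> list[str]:
        names = [f"GENE{i:04d}" for i in range(self.n_genes)]
        for k in range(self.n_mito_genes):
            names[self.n_genes - self.n_mito_genes + k] = f"MT-G{k}"
        # the contamination-filter target gene; keep it outside planted blocks
        names[self.n_genes - self.n_mito_genes - 1] = self.contaminant_gene
        return names

    def mito_indices(self) -> list[int]:
        return list(range(self.n_genes - self.n_mito_genes, self.n_genes))

    def to_json(self) -> str:
        d = asdict(self)
        d["motif_insertion_rates"] = {
            f"{m}|{s}": r for (m, s), r in self.motif_insertion_rates.items()
        }
        d["coverage_intensity"] = {
            f"{a}|{b}": v for (a, b), v in self.coverage_intensity.items()
        }
        d["cytof_shifts"] = {f"{m}|{p}": v for (m, p), v in self.cytof_shifts.items()}
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimConfig":
        d = json.loads(text)
        d["populations"] = [PopulationSpec(**p) for p in d.get("populations", [])]
        for p in d["populations"]:
            p.cycle_fractions = tuple(p.cycle_fractions)
        d["bulk_groups"] = [BulkGroupSpec(**g) for g in d.get("bulk_groups", [])]
        for key in ("motif_insertion_rates", "coverage_intensity", "cytof_shifts"):
            if key in d:
                d[key] = {tuple(k.split("|")): v for k, v in d[key].items()}
        for key in ("mito_fraction_range", "coverage_samples", "cytof_markers",
                    "cytof_populations"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# bulk expression


def gen_bulk_expression(cfg: SimConfig) -> tuple[ExpressionTable, dict[str, list[str]]]:
    """Simulate a bulk FPKM panel with planted group-specific genes.

    Baseline FPKM per gene is log-normal and shared across all samples;
    each group's planted genes are multiplied by ``2**log2_effect`` in that
    group only. Planted genes are assigned top-quartile baseline expression,
    so upper-quartile normalization is unaffected by the planting and, with
    ``bulk_noise_sigma == 0``, non-planted genes are exactly equal across
    groups. Returns the table plus ground truth (group -> planted gene names).
    """
    cfg.validate()
    if len(cfg.bulk_groups) < 2:
        raise ValueError("need at least 2 bulk sample groups")
    rng = np.random.default_rng(cfg.seed)
    names = cfg.gene_names()
    base = rng.lognormal(mean=1.0, sigma=1.2, size=cfg.n_genes)

    # Move planted genes into the top quartile of baseline expression by
    # swapping values with the highest-expressed non-planted genes.
    planted_all = [i for g in cfg.bulk_groups for i in g.specific_indices]
    if planted_all:
        q75 = np.percentile(base[base > 0], 75)
        order = np.argsort(base)[::-1]
        donors = [i for i in order if i not in set(planted_all)]
        for k, gi in enumerate(planted_all):
            if base[gi] <= q75:
                di = donors[k]
                base[gi], base[di] = base[di], base[gi]

    columns, groups = {}, {}
    for grp in cfg.bulk_groups:
        mean = base.copy()
        mean[grp.specific_indices] *= 2.0 ** grp.log2_effect
        for r in range(grp.n_samples):
            sample = f"{grp.name}_{r+1}"
            noise = (
                rng.lognormal(mean=0.0, sigma=cfg.bulk_noise_sigma, size=cfg.n_genes)
                if cfg.bulk_noise_sigma > 0
                else 1.0
            )
            columns[sample] = mean * noise
            groups[sample] = grp.name

    values = pd.DataFrame(columns, index=pd.Index(names, name="gene"))
    table = ExpressionTable(
        values=values,
        sample_groups=pd.Series(groups),
        protein_coding=pd.Series(True, index=values.index),
    )
    truth = {
        g.name: [names[i] for i in g.specific_indices] for g in cfg.bulk_groups
    }
    return table, truth


# ---------------------------------------------------------------------------
# single-cell counts


def gen_sc_counts(cfg: SimConfig) -> AnnData:
    """Simulate a UMI count matrix over the configured cell populations.

    Counts are negative-binomial with per-gene means: a shared log-normal
    baseline, population marker genes up-shifted by ``2**marker_log2_effect``,
    planted S / G2M programs up-shifted in cells simulated in those phases,
    and a mitochondrial gene block tuned so each cell's expected mito UMI
    fraction equals a draw from ``mito_fraction_range``. Ground-truth
    population and phase labels live in ``obs``; planted gene lists and the
    config echo in ``uns``.
    """
    cfg.validate()
    if cfg.n_cells_per_population <= 0:
        raise ValueError("n_cells_per_population must be positive (empty matrix)")
    pop_names = [p.name for p in cfg.populations]
    if not {"LSC", "Blast"} <= set(pop_names):
        raise ValueError("populations must include 'LSC' and 'Blast'")
    rng = np.random.default_rng(cfg.seed)
    names = cfg.gene_names()
    n_cells = cfg.n_cells_per_population * len(cfg.populations)
    mito_idx = np.array(cfg.mito_indices())
    nonmito = np.setdiff1d(np.arange(cfg.n_genes), mito_idx)

    rel = rng.lognormal(mean=0.0, sigma=1.0, size=cfg.n_genes)
    rel[mito_idx] = np.mean(rel[nonmito])  # rebalanced per cell below

    rows, pops, phases, mito_targets = [], [], [], []
    for pop in cfg.populations:
        pop_rel = rel.copy()
        pop_rel[pop.marker_indices] *= 2.0 ** pop.marker_log2_effect
        n = cfg.n_cells_per_population
        phase_draw = rng.choice(3, size=n, p=list(pop.cycle_fractions))
        lib = rng.lognormal(
            mean=np.log(cfg.mean_library_size), sigma=0.25, size=n
        )
        mito_f = rng.uniform(*cfg.mito_fraction_range, size=n)
        for c in range(n):
            mu = pop_rel.copy()
            if phase_draw[c] == 1:
                mu[cfg.s_gene_indices] = mu[cfg.s_gene_indices] * 2.0 ** cfg.cycle_log2_effect
            elif phase_draw[c] == 2:
                mu[cfg.g2m_gene_indices] = mu[cfg.g2m_gene_indices] * 2.0 ** cfg.cycle_log2_effect
            # split the cell's library between mito and non-mito blocks
            f = mito_f[c]
            mu[mito_idx] = mu[mito_idx] / mu[mito_idx].sum() * f
            mu[nonmito] = mu[nonmito] / mu[nonmito].sum() * (1.0 - f)
            rows.append(mu * lib[c])
            phases.append(PHASES[phase_draw[c]])
            mito_targets.append(f)
        pops.extend([pop.name] * n)

    mu_matrix = np.asarray(rows)
    if cfg.nb_dispersion > 0:
        r = 1.0 / cfg.nb_dispersion
        p = r / (r + mu_matrix)
        counts = rng.negative_binomial(r, p)
    else:
        counts = rng.poisson(mu_matrix)
    # the mito block carries a planted QC fraction; Poisson keeps the
    # realized fraction tight around its per-cell target
    counts[:, mito_idx] = rng.poisson(mu_matrix[:, mito_idx])

    obs = pd.DataFrame(
        {
            "population": pops,
            "phase_true": phases,
            "mito_fraction_target": mito_targets,
            "patient": "sim1",
            "sorted_label": [
                p if p in ("LSC", "Blast") else "unknown" for p in pops
            ],
        },
        index=pd.Index([f"CELL{i:05d}" for i in range(n_cells)], name="barcode"),
    )
    var = pd.DataFrame(
        {"mito": [n.startswith("MT-") for n in names]},
        index=pd.Index(names, name="gene"),
    )
    adata = AnnData(
        X=sparse.csr_matrix(counts.astype(np.float64)), obs=obs, var=var
    )
    adata.layers["counts"] = adata.X.copy()
    adata.uns["sim"] = {
        "seed": cfg.seed,
        "markers": {
            p.name: [names[i] for i in p.marker_indices] for p in cfg.populations
        },
        "s_genes": [names[i] for i in cfg.s_gene_indices],
        "g2m_genes": [names[i] for i in cfg.g2m_gene_indices],
        "config": cfg.to_json(),
    }
    return adata


# ---------------------------------------------------------------------------
# peak landscape


@dataclass
class PeakLandscape:
    """Synthetic genome + peak sets + coverage with recorded ground truth."""

    genome: dict[str, str]
    peak_sets: dict[str, pd.DataFrame]  # columns chrom,start,end,summit,score,name
    coverage: dict[str, dict[str, np.ndarray]]  # sample -> chrom -> per-bp array
    motif_insertions: pd.DataFrame  # motif,set,peak,start,strand
    intensity: pd.DataFrame  # peaks x samples configured window intensity


def _find_exact(seq: str, pattern: str) -> list[int]:
    out, start = [], 0
    while True:
        i = seq.find(pattern, start)
        if i < 0:
            return out
        out.append(i)
        start = i + 1


def gen_peak_landscape(cfg: SimConfig) -> PeakLandscape:
    """Simulate a genome, peak sets with inserted motifs, and coverage.

    Peaks are non-overlapping 200-bp intervals laid out on a uniform grid
    (so their 400-bp quantification windows never overlap), alternating
    between sets. For each (motif, set) insertion rate, exactly
    ``round(rate * n_peaks)`` peaks receive one verbatim motif instance at a
    uniformly chosen offset and strand. With ``suppress_chance_hits`` the
    background sequence is then mutated wherever the exact consensus occurs
    away from a planted position, making planted counts exact. Coverage is
    flat at the configured intensity over each peak's 400-bp summit window.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    for motif, cons in cfg.motif_consensus.items():
        if set(cons) - set("ACGT"):
            raise ValueError(f"motif {motif!r}: consensus must be over ACGT")
        if len(cons) > cfg.peak_width:
            raise ValueError(f"motif {motif!r} longer than peak width")

    chrom = "chr1"
    genome = rng.choice(list("ACGT"), size=cfg.genome_length)

    set_names = list(cfg.n_peaks_per_set)
    total_peaks = sum(cfg.n_peaks_per_set.values())
    spacing = cfg.genome_length // (total_peaks + 1)
    if spacing < cfg.peak_width + 400:
        raise ValueError("genome too short for requested peak count")
    peak_sets: dict[str, list[dict]] = {s: [] for s in set_names}
    # interleave sets deterministically across the genome (round-robin)
    remaining = {s: cfg.n_peaks_per_set[s] for s in set_names}
    slots: list[str] = []
    while any(remaining.values()):
        for s in set_names:
            if remaining[s] > 0:
                slots.append(s)
                remaining[s] -= 1
    for k, set_name in enumerate(slots):
        start = (k + 1) * spacing - cfg.peak_width // 2
        peak_sets[set_name].append(
            {
                "chrom": chrom,
                "start": start,
                "end": start + cfg.peak_width,
                "summit": start + cfg.peak_width // 2,
                "score": 100.0,
                "name": f"{set_name}_peak{len(peak_sets[set_name]):03d}",
            }
        )

    insertions = []
    for (motif, set_name), rate in sorted(cfg.motif_insertion_rates.items()):
        cons = cfg.motif_consensus[motif]
        peaks = peak_sets[set_name]
        n_insert = int(round(rate * len(peaks)))
        chosen = rng.choice(len(peaks), size=n_insert, replace=False)
        for pi in sorted(chosen):
            pk = peaks[pi]
            off = int(rng.integers(0, cfg.peak_width - len(cons) + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            inst = cons if strand == "+" else revcomp(cons)
            pos = pk["start"] + off
            genome[pos : pos + len(cons)] = list(inst)
            insertions.append(
                {
                    "motif": motif,
                    "set": set_name,
                    "peak": pk["name"],
                    "start": pos,
                    "strand": strand,
                }
            )

    seq = "".join(genome)
    if cfg.suppress_chance_hits and insertions:
        planted_spans = {
            r["start"] + k
            for r in insertions
            for k in range(len(cfg.motif_consensus[r["motif"]]))
        }
        changed = True
        while changed:
            changed = False
            for motif, cons in cfg.motif_consensus.items():
                for pat in {cons, revcomp(cons)}:
                    for pos in _find_exact(seq, pat):
                        span = set(range(pos, pos + len(pat)))
                        if span & planted_spans:
                            continue
                        # break the chance occurrence by rotating one base
                        i = pos + len(pat) // 2
                        old = seq[i]
                        new = "ACGT"[("ACGT".index(old) + 1) % 4]
                        seq = seq[:i] + new + seq[i + 1 :]
                        changed = True

    peak_frames = {
        s: pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)
        for s, rows in peak_sets.items()
    }

    coverage: dict[str, dict[str, np.ndarray]] = {}
    all_peaks = pd.concat(
        [df.assign(set=s) for s, df in peak_frames.items()], ignore_index=True
    )
    intensity = pd.DataFrame(
        index=pd.Index(all_peaks["name"], name="peak"),
        columns=list(cfg.coverage_samples),
        dtype=float,
    )
    for sample in cfg.coverage_samples:
        cov = np.zeros(cfg.genome_length)
        for _, pk in all_peaks.iterrows():
            inten = cfg.coverage_intensity.get((sample, pk["set"]), 0.0)
            lo = int(pk["summit"]) - 200
            hi = int(pk["summit"]) + 200
            cov[max(lo, 0) : min(hi, cfg.genome_length)] = inten
            intensity.loc[pk["name"], sample] = inten
        coverage[sample] = {chrom: cov}

    return PeakLandscape(
        genome={chrom: seq},
        peak_sets=peak_frames,
        coverage=coverage,
        motif_insertions=pd.DataFrame(
            insertions, columns=["motif", "set", "peak", "start", "strand"]
        ),
        intensity=intensity,
    )


# ---------------------------------------------------------------------------
# CyTOF


def gen_cytof_table(cfg: SimConfig) -> tuple[pd.DataFrame, dict[str, float]]:
    """Simulate a CyTOF-like ion-count table with planted population shifts.

    Ion counts are log-normal per marker (base-2 parameterization); the
    configured shifts add ``shift`` to the log2 mean of a marker in one
    population. Returns a long table (cells x markers + 'population',
    'patient') and the ground-truth shifts keyed "marker|population".
    """
    cfg.validate()
    if len(cfg.cytof_populations) < 2:
        raise ValueError("need at least 2 CyTOF populations")
    rng = np.random.default_rng(cfg.seed)
    # base log2 mean ion counts in the hundreds range, so the +1 display
    # pseudocount downstream is negligible
    base = {m: rng.uniform(6.0, 10.0) for m in cfg.cytof_markers}
    frames = []
    for pop in cfg.cytof_populations:
        n = cfg.cytof_cells_per_population
        cols = {}
        for m in cfg.cytof_markers:
            mu = base[m] + cfg.cytof_shifts.get((m, pop), 0.0)
            cols[m] = 2.0 ** rng.normal(mu, cfg.cytof_sigma, size=n)
        df = pd.DataFrame(cols)
        df["population"] = pop
        df["patient"] = "sim1"
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    truth = {f"{m}|{p}": v for (m, p), v in cfg.cytof_shifts.items()}
    return table, truth
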