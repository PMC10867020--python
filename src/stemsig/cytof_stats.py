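"""Population-level mass-cytometry statistics.

Ion counts are log2(x + 1) transformed; populations are compared per marker
by the difference of mean log2 counts and a two-sided two-sample t-test,
with significance reported as display bands: n.s. for p > 1e-3, * for
p <= 1e-3, ** for p <= 1e-5, *** for p <= 1e-10 (cutpoints inclusive on the
small side).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "IonTable",
    "significance_band",
    "transform_and_summarize",
    "compare_populations",
    "population_fold_heatmap",
]

BAND_CUTS = ((1e-10, "***"), (1e-5, "**"), (1e-3, "*"))


@dataclass
class IonTable:
    """Cells x markers ion counts with population and patient labels."""

    counts: pd.DataFrame
    population: pd.Series
    patient: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("ion counts must be non-negative")
        if len(self.population) != len(self.counts):
            raise ValueError("population labels must match cell count")

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, population_col: str = "population",
        patient_col: str = "patient",
    ) -> "IonTable":
        meta = [c for c in (population_col, patient_col) if c in df.columns]
        counts = df.drop(columns=meta)
        return cls(
            counts=counts,
            population=df[population_col],
            patient=df[patient_col] if patient_col in df.columns else None,
        )

    @property
    def markers(self) -> pd.Index:
        return self.counts.columns

    def subset(self, population: str) -> pd.DataFrame:
        mask = (self.population == population).to_numpy()
        if not mask.any():
            raise ValueError(f"population {population!r} is empty")
        return self.counts[mask]


def significance_band(p: float) -> str:
    for cut, band in BAND_CUTS:
        if p <= cut:
            return band
    return "n.s."


def transform_and_summarize(table: IonTable) -> pd.DataFrame:
    """Per-population marker means on the log2(x+1) and raw scales.

    Returns a long-format frame (population, marker, mean_log2, mean_raw,
    log2_mean_raw); the transformed mean feeds the fold-difference
    statistics, the log2 of the raw mean the "log2 mean ion count" heatmap.
    """
    pops = pd.unique(table.population)
    if len(pops) == 0:
        raise ValueError("no populations")
    rows = []
    for pop in pops:
        sub = table.subset(pop)
        log2 = np.log2(sub + 1.0)
        for marker in table.markers:
            raw_mean = float(sub[marker].mean())
            rows.append(
                {
                    "population": pop,
                    "marker": marker,
                    "mean_log2": float(log2[marker].mean()),
                    "mean_raw": raw_mean,
                    "log2_mean_raw": float(np.log2(raw_mean + 1.0)),
                }
            )
    return pd.DataFrame(rows)


def compare_populations(
    table: IonTable, pop_a: str, pop_b: str, equal_var: bool = True
) -> pd.DataFrame:
    """Per-marker log2 fold difference (a - b) with t-test p and band.

    Means and the two-sided t-test are computed on log2(x+1) counts;
    ``equal_var`` selects pooled-variance Student (default) versus Welch.
    Zero-variance markers with equal means report p = 1 (n.s.).
    """
    a = np.log2(table.subset(pop_a) + 1.0)
    b = np.log2(table.subset(pop_b) + 1.0)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both populations need at least 2 cells")
    rows = []
    for marker in table.markers:
        x, y = a[marker].to_numpy(), b[marker].to_numpy()
        diff = float(x.mean() - y.mean())
        res = stats.ttest_ind(x, y, equal_var=equal_var)
        p = float(res.pvalue)
        if np.isnan(p):
            p = 1.0 if np.isclose(x.mean(), y.mean()) else 0.0
        rows.append(
            {
                "marker": marker,
                "log2_fold": diff,
                "p": p,
                "band": significance_band(p),
            }
        )
    return pd.DataFrame(rows)


def population_fold_heatmap(
    table: IonTable, pop_a: str, pop_b: str, equal_var: bool = True
) -> pd.DataFrame:
    """Heatmap-ready comparison table indexed by marker."""
    pops = set(pd.unique(table.population))
    if len(pops) < 2:
        raise ValueError("fold heatmap needs at least 2 populations")
    cmp = compare_populations(table, pop_a, pop_b, equal_var=equal_var)
    return cmp.set_index("marker")
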