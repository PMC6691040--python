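"""Gene retention/loss statistics and the geometric model of fractionation.

After polyploidy, duplicated genes are removed in events that delete runs of
consecutive genes.  Run lengths are read off the homology table as maximal
stretches of empty group-1 cells strictly between two filled cells of the
same collinear block (gaps at block boundaries reflect rearrangement, not
removal, and are excluded).  If each gene in a run stops the event with
probability p, run lengths follow a geometric distribution
``P(K = k) = p (1-p)^(k-1)``; the parameter is estimated both by nonlinear
least squares on the event-count histogram and by the closed-form MLE
``p = total events / total removed genes`` (the reciprocal mean run length).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .alignment_table import EMPTY, HomologyTable, _count_fragments

__all__ = [
    "RunLengthHistogram",
    "GeometricFit",
    "retention_by_chromosome",
    "removal_runs",
    "fit_geometric",
    "small_event_share",
]

#: histogram bins beyond this run length are pooled before regression
REGRESSION_K_CAP = 50


@dataclass
class RunLengthHistogram:
    """Counts of gene-removal events by run length k (genes per event)."""

    species: str
    counts: dict[int, int] = field(default_factory=dict)

    @classmethod
    def from_runs(cls, species: str, runs) -> "RunLengthHistogram":
        h = cls(species)
        for k in runs:
            if k < 1:
                raise ValueError(f"run length must be >= 1, got {k}")
            h.counts[int(k)] = h.counts.get(int(k), 0) + 1
        return h

    @property
    def total_events(self) -> int:
        return sum(self.counts.values())

    @property
    def total_removed_genes(self) -> int:
        return sum(k * c for k, c in self.counts.items())

    @property
    def mean_run_length(self) -> float:
        ev = self.total_events
        return self.total_removed_genes / ev if ev else float("nan")


@dataclass
class GeometricFit:
    p_regression: float
    p_mle: float
    r_squared: float
    sse: float
    rmse: float
    f_statistic: float
    p_value: float  # P(F <= observed) under the no-relation null; near 1 accepts the fit


def retention_by_chromosome(table: HomologyTable) -> pd.DataFrame:
    """Per reference-chromosome x species retention (fragments, genes, percent),
    with a totals row per species.  Percentages are to 2 decimals."""
    rows = []
    spans = table.chromosome_rows()
    for sp in table.species:
        col = table.cells[(1, sp)]
        for chrom, lo, hi in spans:
            n_chrom = hi - lo + 1
            filled = sum(1 for r in range(lo, hi + 1) if col[r] != EMPTY)
            rows.append(
                {
                    "species": sp,
                    "chromosome": chrom,
                    "reference_genes": n_chrom,
                    "fragments": _count_fragments(table, sp, (lo, hi)),
                    "collinear_genes": filled,
                    "percent": round(100.0 * filled / n_chrom, 2),
                }
            )
        filled = table.filled(1, sp)
        rows.append(
            {
                "species": sp,
                "chromosome": "Total",
                "reference_genes": table.n_rows,
                "fragments": _count_fragments(table, sp),
                "collinear_genes": filled,
                "percent": round(100.0 * filled / table.n_rows, 2) if table.n_rows else 0.0,
            }
        )
    return pd.DataFrame(rows)


def removal_runs(table: HomologyTable, species: str) -> RunLengthHistogram:
    """Extract removal-event run lengths for one species from the table.

    A run is a maximal stretch of empty group-1 cells strictly between two
    filled cells backed by the same block, within one reference chromosome.
    """
    if species not in table.species:
        raise ValueError(f"species {species!r} not in table ({table.species})")
    col = table.cells[(1, species)]
    bcol = table.block_ids[(1, species)]
    runs: list[int] = []
    for _, lo, hi in table.chromosome_rows():
        prev_row = None
        prev_block = None
        for r in range(lo, hi + 1):
            if col[r] == EMPTY:
                continue
            if prev_row is not None and bcol[r] == prev_block:
                gap = r - prev_row - 1
                if gap >= 1:
                    runs.append(gap)
            prev_row, prev_block = r, bcol[r]
    return RunLengthHistogram.from_runs(species, runs)


def fit_geometric(histogram: RunLengthHistogram) -> GeometricFit:
    """Fit ``count(k) = E * p * (1-p)^(k-1)`` to the event histogram.

    E is the total event count; p is fitted by nonlinear least squares over
    the observed k (tail bins beyond :data:`REGRESSION_K_CAP` pooled at the
    cap).  Goodness of fit is summarised by R^2, SSE, RMSE and a regression
    F statistic (regression mean square over residual mean square, df
    ``(1, K-2)`` for K distinct bins); the reported p-value is ``P(F <=
    observed)``, so values near 1 accept the geometric model.  The MLE
    ``p = events / removed genes`` uses the unpooled data.
    """
    if histogram.total_events == 0:
        raise ValueError("empty histogram")
    if histogram.total_events < 30:
        warnings.warn(
            f"only {histogram.total_events} removal events; geometric fit is unstable",
            stacklevel=2,
        )
    p_mle = histogram.total_events / histogram.total_removed_genes

    pooled: dict[int, int] = {}
    for k, c in histogram.counts.items():
        pooled[min(k, REGRESSION_K_CAP)] = pooled.get(min(k, REGRESSION_K_CAP), 0) + c
    ks = np.array(sorted(pooled), dtype=float)
    counts = np.array([pooled[int(k)] for k in ks], dtype=float)
    E = float(counts.sum())

    if len(ks) < 2:
        return GeometricFit(
            p_regression=float("nan"), p_mle=p_mle, r_squared=float("nan"),
            sse=float("nan"), rmse=float("nan"), f_statistic=float("nan"),
            p_value=float("nan"),
        )

    def model(k, p):
        return E * p * np.power(1.0 - p, k - 1.0)

    (p_hat,), _ = optimize.curve_fit(
        model, ks, counts, p0=[min(p_mle, 0.99)], bounds=(1e-9, 1.0)
    )
    resid = counts - model(ks, p_hat)
    sse = float(np.sum(resid**2))
    sst = float(np.sum((counts - counts.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    K = len(ks)
    rmse = float(np.sqrt(sse / max(K - 1, 1)))
    if K > 2 and sse > 0:
        ms_reg = (sst - sse) / 1.0
        ms_res = sse / (K - 2)
        f_stat = ms_reg / ms_res
        p_val = float(stats.f.cdf(f_stat, 1, K - 2))
    else:
        f_stat = float("inf") if sse == 0 else float("nan")
        p_val = 1.0 if sse == 0 else float("nan")
    return GeometricFit(
        p_regression=float(p_hat), p_mle=p_mle, r_squared=r2, sse=sse,
        rmse=rmse, f_statistic=float(f_stat), p_value=p_val,
    )


def small_event_share(
    histogram: RunLengthHistogram, k_max: int = 2
) -> tuple[float, float]:
    """Share of events with k <= k_max, and of removed genes they account for."""
    if histogram.total_events == 0:
        raise ValueError("empty histogram")
    small_events = sum(c for k, c in histogram.counts.items() if k <= k_max)
    small_genes = sum(k * c for k, c in histogram.counts.items() if k <= k_max)
    return (
        small_events / histogram.total_events,
        small_genes / histogram.total_removed_genes,
    )
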