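"""Mutation-vs-selection diagnostics: ENc-plot, PR2 summary, neutrality plot.

The three classic plots read as follows: genes on the expected ENc curve
(and PR2 points at the (0.5, 0.5) centre, and a GC12-on-GC3 slope near 1)
indicate mutation-driven usage; genes below the curve, displaced PR2
points and a slope near 0 indicate selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from cpcub.codon_stats import GeneCUBRecord

__all__ = [
    "EncPlotRecord",
    "NeutralityFit",
    "enc_plot_table",
    "neutrality_regression",
    "interpret_diagnostics",
]


@dataclass(frozen=True)
class EncPlotRecord:
    gene_id: str
    gc3s: float
    enc: float
    enc_expected: float
    #: relative deviation (expected - observed) / expected; positive = below curve
    deviation: float


@dataclass(frozen=True)
class NeutralityFit:
    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    n_genes: int
    pool_label: str

    @property
    def abs_slope(self) -> float:
        return abs(self.slope)


def enc_plot_table(records: Sequence[GeneCUBRecord]) -> list[EncPlotRecord]:
    """One row per gene with defined ENc and GC3s; undefined rows dropped."""
    if not records:
        raise ValueError("no gene records supplied")
    rows = []
    for r in records:
        if math.isnan(r.enc) or math.isnan(r.gc3s) or math.isnan(r.enc_expected):
            continue
        if r.enc_expected <= 0:
            continue
        rows.append(
            EncPlotRecord(
                gene_id=r.gene_id,
                gc3s=r.gc3s,
                enc=r.enc,
                enc_expected=r.enc_expected,
                deviation=(r.enc_expected - r.enc) / r.enc_expected,
            )
        )
    return rows


def neutrality_regression(
    records: Sequence[GeneCUBRecord], pool_label: str = "all"
) -> NeutralityFit:
    """OLS of GC12 on GC3, with Pearson r and its two-sided t-test p-value."""
    pts = [
        (r.gc3, r.gc12)
        for r in records
        if not (math.isnan(r.gc3) or math.isnan(r.gc12))
    ]
    if len(pts) < 3:
        raise ValueError(f"need >= 3 genes for a neutrality fit, got {len(pts)}")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in GC3; regression undefined")
    fit = stats.linregress(x, y)
    return NeutralityFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        pearson_r=float(fit.rvalue),
        p_value=float(fit.pvalue),
        n_genes=len(pts),
        pool_label=pool_label,
    )


def interpret_diagnostics(
    fit: NeutralityFit,
    enc_rows: Sequence[EncPlotRecord],
    pr2_points: Sequence[tuple[float, float]],
    slope_selection: float = 0.3,
    slope_mutation: float = 0.7,
) -> dict:
    """Heuristic labelling of the three diagnostics.

    Slope thresholds are conveniences, not published rules; they are
    echoed in the output so readers can see what was applied.
    """
    a = fit.abs_slope
    if a < slope_selection:
        label = "selection-dominant"
    elif a > slope_mutation:
        label = "mutation-dominant"
    else:
        label = "mixed"
    frac_below = (
        sum(1 for r in enc_rows if r.enc < r.enc_expected) / len(enc_rows)
        if enc_rows
        else math.nan
    )
    pts = [(x, y) for x, y in pr2_points if not (math.isnan(x) or math.isnan(y))]
    if pts:
        dx = float(np.mean([x - 0.5 for x, _ in pts]))
        dy = float(np.mean([y - 0.5 for _, y in pts]))
    else:
        dx = dy = math.nan
    return {
        "pool_label": fit.pool_label,
        "slope": fit.slope,
        "abs_slope": a,
        "pearson_r": fit.pearson_r,
        "p_value": fit.p_value,
        "n_genes": fit.n_genes,
        "label": label,
        "label_thresholds": {
            "selection_lt": slope_selection,
            "mutation_gt": slope_mutation,
            "heuristic": True,
        },
        "frac_genes_below_enc_curve": frac_below,
        "pr2_mean_displacement": (dx, dy),
    }


def enc_plot_frame(rows: Sequence[EncPlotRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])
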