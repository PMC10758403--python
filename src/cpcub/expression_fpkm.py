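"""FPKM from gene-level fragment counts and cross-taxon comparison.

Alignment and feature counting are upstream; this module ingests a
genes x samples count table plus gene lengths, normalises to FPKM
(fragments per kilobase per million mapped fragments) and compares mean
expression of genes of interest across taxa / habitat groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["CountMatrix", "fpkm", "cross_taxa_expression"]


@dataclass
class CountMatrix:
    """Gene x sample fragment counts with per-gene lengths (nt).

    ``library_sizes`` defaults to column sums of the counted genes; an
    explicit vector may be larger (unassigned fragments) but never
    smaller.
    """

    counts: pd.DataFrame
    gene_lengths: pd.Series
    library_sizes: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(float)
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = self.counts.index.difference(self.gene_lengths.index)
        if len(missing):
            raise ValueError(f"lengths missing for genes: {list(missing)[:5]}")
        self.gene_lengths = self.gene_lengths.loc[self.counts.index].astype(float)
        if (self.gene_lengths <= 0).any():
            raise ValueError("gene lengths must be positive")
        col_sums = self.counts.sum(axis=0)
        if self.library_sizes is None:
            self.library_sizes = col_sums
        else:
            self.library_sizes = self.library_sizes.loc[self.counts.columns].astype(float)
            if (self.library_sizes + 1e-9 < col_sums).any():
                raise ValueError("library sizes smaller than column sums")

    @classmethod
    def from_tsv(
        cls,
        counts_path: str | Path,
        lengths_path: str | Path,
        library_sizes_path: str | Path | None = None,
    ) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        lengths = pd.read_csv(lengths_path, sep="\t", index_col=0).iloc[:, 0]
        libs = None
        if library_sizes_path is not None:
            libs = pd.read_csv(library_sizes_path, sep="\t", index_col=0).iloc[:, 0]
        return cls(counts=counts, gene_lengths=lengths, library_sizes=libs)


def fpkm(matrix: CountMatrix) -> pd.DataFrame:
    """FPKM[g, s] = counts[g, s] * 1e9 / (library_sizes[s] * gene_lengths[g])."""
    libs = matrix.library_sizes
    if (libs <= 0).any():
        raise ValueError("zero library size")
    scale = np.outer(1.0 / matrix.gene_lengths.values, 1.0 / libs.values) * 1e9
    return pd.DataFrame(
        matrix.counts.values * scale,
        index=matrix.counts.index,
        columns=matrix.counts.columns,
    )


def cross_taxa_expression(
    fpkm_by_taxon: Mapping[str, pd.DataFrame],
    genes: Sequence[str],
    habitat_groups: Mapping[str, str] | None = None,
    replicate_policy: str = "mean",
) -> pd.DataFrame:
    """Per-gene mean FPKM per taxon, rank order, and a direction label.

    The direction label names the habitat group whose mean-of-taxon-means
    is higher ("tie" when equal); genes absent from any taxon are flagged
    and excluded from ranking. Replicates are aggregated by mean
    (default) or median.
    """
    if replicate_policy not in ("mean", "median"):
        raise ValueError(f"unknown replicate policy {replicate_policy!r}")
    agg = np.mean if replicate_policy == "mean" else np.median
    taxa = list(fpkm_by_taxon)
    rows = []
    for gene in genes:
        means: dict[str, float] = {}
        missing = [t for t in taxa if gene not in fpkm_by_taxon[t].index]
        for t in taxa:
            if t in missing:
                means[t] = np.nan
            else:
                means[t] = float(agg(fpkm_by_taxon[t].loc[gene].values))
        row: dict = {"gene": gene, "missing_in": ",".join(missing)}
        row.update({f"mean_{t}": means[t] for t in taxa})
        if missing:
            row["rank_order"] = ""
            row["direction"] = "missing"
        else:
            ranked = sorted(taxa, key=lambda t: (-means[t], t))
            row["rank_order"] = ">".join(ranked)
            row["direction"] = _direction(means, habitat_groups)
        rows.append(row)
    return pd.DataFrame(rows)


def _direction(
    means: Mapping[str, float], habitat_groups: Mapping[str, str] | None
) -> str:
    if not habitat_groups:
        top = max(means.values())
        leaders = sorted(t for t, v in means.items() if v == top)
        return "tie" if len(leaders) > 1 else leaders[0]
    group_means: dict[str, list[float]] = {}
    for taxon, value in means.items():
        group = habitat_groups.get(taxon, taxon)
        group_means.setdefault(group, []).append(value)
    avg = {g: float(np.mean(v)) for g, v in group_means.items()}
    top = max(avg.values())
    leaders = sorted(g for g, v in avg.items() if v == top)
    return "tie" if len(leaders) > 1 else leaders[0]
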