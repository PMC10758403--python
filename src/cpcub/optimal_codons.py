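"""Optimal-codon calling from high/low-expression gene extremes.

Genes are ranked by a bias proxy (CAI by default, optionally ENc or
their intersection); the top and bottom ``fraction`` (default 5%) form
the putative high- and low-expression sets. A codon is called optimal
when its RSCU rises by more than ``delta`` from the low to the high set
and its anchor RSCU exceeds 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from cpcub.codon_stats import CodonCountTable, GeneCUBRecord, rscu
from cpcub.sequence_io import DEFAULT_CODE, GeneticCode

__all__ = [
    "OptimalCodonCall",
    "select_extreme_genes",
    "call_optimal",
    "shared_optimal",
    "overrepresented",
    "calls_frame",
]


@dataclass(frozen=True)
class OptimalCodonCall:
    codon: str
    amino_acid: str
    rscu_high: float
    rscu_low: float
    delta_rscu: float
    rscu_all: float
    is_optimal: bool
    taxon: str = ""


def select_extreme_genes(
    records: Sequence[GeneCUBRecord],
    metric: str = "cai",
    fraction: float = 0.05,
) -> tuple[list[str], list[str]]:
    """Return (high-expression gene ids, low-expression gene ids).

    k = ceil(fraction * n), so even tiny gene sets yield one gene per
    extreme. Ties are broken by gene_id so the choice is deterministic.
    ``metric="cai"`` ranks by CAI (high CAI = high expression);
    ``"enc"`` ranks by ENc (low ENc = high bias = high expression);
    ``"both"`` intersects the two and errors if either intersection is
    empty.
    """
    if metric not in ("cai", "enc", "both"):
        raise ValueError(f"unknown metric {metric!r}")
    if not 0.0 < fraction < 0.5:
        raise ValueError(f"fraction must be in (0, 0.5), got {fraction}")
    n = len(records)
    if n < 2:
        raise ValueError("need at least 2 genes")
    k = math.ceil(fraction * n)
    if 2 * k > n:
        raise ValueError(f"high/low sets overlap: n={n}, k={k}")

    def extremes(key, reverse_high: bool) -> tuple[list[str], list[str]]:
        ranked = sorted(records, key=lambda r: (key(r), r.gene_id))
        ids = [r.gene_id for r in ranked]
        if reverse_high:
            return ids[-k:], ids[:k]
        return ids[:k], ids[-k:]

    if metric == "cai":
        high, low = extremes(lambda r: r.cai, reverse_high=True)
    elif metric == "enc":
        high, low = extremes(lambda r: r.enc, reverse_high=False)
    else:
        cai_high, cai_low = extremes(lambda r: r.cai, reverse_high=True)
        enc_high, enc_low = extremes(lambda r: r.enc, reverse_high=False)
        high = sorted(set(cai_high) & set(enc_high))
        low = sorted(set(cai_low) & set(enc_low))
        if not high or not low:
            raise ValueError("CAI and ENc extremes do not intersect; use metric='cai'")
    return high, low


def call_optimal(
    high: CodonCountTable,
    low: CodonCountTable,
    all_genes: CodonCountTable,
    delta: float = 0.08,
    code: GeneticCode = DEFAULT_CODE,
    anchor: str = "high",
    taxon: str = "",
) -> list[OptimalCodonCall]:
    """One call per sense codon in a family observed in both extreme sets.

    ``anchor`` selects which RSCU the ">1" condition applies to:
    ``"high"`` (default) uses the high-expression set, ``"all"`` the
    whole-gene-set RSCU. Singleton families never produce calls.
    """
    if anchor not in ("high", "all"):
        raise ValueError(f"unknown anchor {anchor!r}")
    if high.total == 0 or low.total == 0:
        raise ValueError("empty high or low codon table")
    r_high = rscu(high, code)
    r_low = rscu(low, code)
    r_all = rscu(all_genes, code)
    calls = []
    for aa, fam in sorted(code.families().items()):
        if len(fam) == 1:
            continue
        for codon in fam:
            rh, rl = r_high[codon], r_low[codon]
            if math.isnan(rh) or math.isnan(rl):
                continue
            d = rh - rl
            ref = rh if anchor == "high" else r_all[codon]
            calls.append(
                OptimalCodonCall(
                    codon=codon,
                    amino_acid=aa,
                    rscu_high=rh,
                    rscu_low=rl,
                    delta_rscu=d,
                    rscu_all=r_all[codon],
                    is_optimal=bool(d > delta and not math.isnan(ref) and ref > 1.0),
                    taxon=taxon,
                )
            )
    return calls


def shared_optimal(
    calls_by_taxon: Mapping[str, Sequence[OptimalCodonCall]],
    groups: Mapping[str, str] | None = None,
) -> dict:
    """Intersection and per-taxon differences of optimal-codon sets.

    ``groups`` maps taxon -> habitat-group label; for each group the
    codons shared by all its members but absent from every other taxon
    are reported (the "habitat-specific" sets).
    """
    if len(calls_by_taxon) < 2:
        raise ValueError("need at least 2 taxa")
    sets = {
        taxon: {c.codon for c in calls if c.is_optimal}
        for taxon, calls in calls_by_taxon.items()
    }
    shared = set.intersection(*sets.values())
    specific = {t: s - set.union(*(v for u, v in sets.items() if u != t)) for t, s in sets.items()}
    out = {
        "per_taxon": sets,
        "shared": shared,
        "taxon_specific": specific,
    }
    if groups:
        group_sets: dict[str, set[str]] = {}
        for group in sorted(set(groups.values())):
            members = [t for t, g in groups.items() if g == group]
            others = [t for t in sets if t not in members]
            inside = set.intersection(*(sets[t] for t in members)) if members else set()
            outside = set.union(*(sets[t] for t in others)) if others else set()
            group_sets[group] = inside - outside
        out["group_specific"] = group_sets
    return out


def overrepresented(rscu_table: Mapping[str, float], threshold: float = 1.6) -> set[str]:
    """Codons with defined RSCU strictly greater than ``threshold``."""
    return {
        c for c, v in rscu_table.items() if not math.isnan(v) and v > threshold
    }


def calls_frame(calls: Sequence[OptimalCodonCall]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in calls])
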