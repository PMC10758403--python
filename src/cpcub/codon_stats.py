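"""Per-gene and pooled codon-usage statistics.

Implements the standard codon-usage-bias toolbox over 64-codon count
tables: base composition by codon position (GC, GC1/GC2/GC3, GC3s),
relative synonymous codon usage (RSCU), Wright's effective number of
codons (ENc) with its expected-value curve, the codon adaptation index
(CAI, Sharp & Li construction) and parity-rule-2 (PR2) coordinates.

Conventions:

- Stop codons are tallied separately and excluded from all 61-codon
  analyses; codons containing ambiguity characters are skipped entirely.
- RSCU of singleton families (Met, Trp under table 11) is 1.0.
- ENc is clamped to [20, 61]; a missing 3-fold mean is imputed as the
  mean of the 2- and 4-fold means (CodonW convention); otherwise a gene
  with insufficient data gets NaN.
- CAI floors relative adaptiveness at ``w_floor`` (default 0.01) so one
  unused reference codon cannot zero out a gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from cpcub.sequence_io import BASES, DEFAULT_CODE, CodingSequence, GeneticCode

__all__ = [
    "CodonCountTable",
    "CompositionProfile",
    "GeneCUBRecord",
    "count_codons",
    "pool_counts",
    "composition",
    "rscu",
    "enc",
    "enc_expected",
    "cai",
    "relative_adaptiveness",
    "pr2_coordinates",
    "build_gene_records",
    "records_frame",
]

_ACGT = set(BASES)


@dataclass
class CodonCountTable:
    """Counts over the 64 codons for one gene or a pooled gene set."""

    counts: dict[str, int]
    source: str = ""
    taxon: str = ""
    stop_counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def get(self, codon: str) -> int:
        return self.counts.get(codon, 0)

    def scaled(self, factor: int) -> "CodonCountTable":
        return CodonCountTable(
            counts={c: n * factor for c, n in self.counts.items()},
            source=self.source,
            taxon=self.taxon,
            stop_counts={c: n * factor for c, n in self.stop_counts.items()},
        )


def count_codons(
    cds: CodingSequence, code: GeneticCode = DEFAULT_CODE
) -> CodonCountTable:
    """Count complete, unambiguous codons; stops go to a separate tally."""
    counts: dict[str, int] = {}
    stop_counts: dict[str, int] = {}
    stops = code.stop_codons
    for codon in cds.codons():
        if set(codon) - _ACGT:
            continue
        if codon in stops:
            stop_counts[codon] = stop_counts.get(codon, 0) + 1
        else:
            counts[codon] = counts.get(codon, 0) + 1
    return CodonCountTable(
        counts=counts, source=cds.gene_id, taxon=cds.taxon, stop_counts=stop_counts
    )


def pool_counts(tables: Iterable[CodonCountTable], label: str = "pool") -> CodonCountTable:
    """Sum codon counts over tables into one pooled table."""
    counts: dict[str, int] = {}
    stop_counts: dict[str, int] = {}
    taxon = ""
    for t in tables:
        taxon = taxon or t.taxon
        for c, n in t.counts.items():
            counts[c] = counts.get(c, 0) + n
        for c, n in t.stop_counts.items():
            stop_counts[c] = stop_counts.get(c, 0) + n
    return CodonCountTable(counts=counts, source=label, taxon=taxon, stop_counts=stop_counts)


@dataclass
class CompositionProfile:
    """Base fractions overall and per codon position, plus GC summaries.

    ``gc3s`` is computed only over codons whose amino acid is neither a
    singleton (Met, Trp) nor STOP; it is NaN when no codon is eligible.
    """

    base_fractions: dict[str, float]
    position_fractions: tuple[dict[str, float], dict[str, float], dict[str, float]]
    gc_total: float
    gc1: float
    gc2: float
    gc3: float
    gc3s: float
    a3: int
    t3: int
    g3: int
    c3: int

    @property
    def gc12(self) -> float:
        return (self.gc1 + self.gc2) / 2.0


def composition(
    table: CodonCountTable, code: GeneticCode = DEFAULT_CODE
) -> CompositionProfile:
    if table.total == 0:
        raise ValueError(f"empty codon table for {table.source!r}")
    pos_counts = [dict.fromkeys(BASES, 0) for _ in range(3)]
    for codon, n in table.counts.items():
        for i, base in enumerate(codon):
            pos_counts[i][base] += n
    totals = [sum(pc.values()) for pc in pos_counts]
    pos_fracs = tuple(
        {b: pc[b] / t for b in BASES} for pc, t in zip(pos_counts, totals)
    )
    overall = {
        b: sum(pc[b] for pc in pos_counts) / sum(totals) for b in BASES
    }
    gc = [pf["G"] + pf["C"] for pf in pos_fracs]

    singles = {aa for aa, fam in code.families().items() if len(fam) == 1}
    eligible = 0
    gc3s_hits = 0
    for codon, n in table.counts.items():
        if code.translate(codon) in singles:
            continue
        eligible += n
        if codon[2] in "GC":
            gc3s_hits += n
    gc3s = gc3s_hits / eligible if eligible else math.nan

    return CompositionProfile(
        base_fractions=overall,
        position_fractions=pos_fracs,  # type: ignore[arg-type]
        gc_total=overall["G"] + overall["C"],
        gc1=gc[0],
        gc2=gc[1],
        gc3=gc[2],
        gc3s=gc3s,
        a3=pos_counts[2]["A"],
        t3=pos_counts[2]["T"],
        g3=pos_counts[2]["G"],
        c3=pos_counts[2]["C"],
    )


def rscu(
    table: CodonCountTable, code: GeneticCode = DEFAULT_CODE
) -> dict[str, float]:
    """RSCU_ij = X_ij / ((1/k_i) * sum_j X_ij) per synonymous family.

    Families with zero total get NaN; singleton families report 1.0
    (the no-preference convention) when observed, NaN when absent.
    """
    out: dict[str, float] = {}
    for aa, fam in code.families().items():
        fam_total = sum(table.get(c) for c in fam)
        if fam_total == 0:
            for c in fam:
                out[c] = math.nan
            continue
        if len(fam) == 1:
            out[fam[0]] = 1.0
            continue
        expected = fam_total / len(fam)
        for c in fam:
            out[c] = table.get(c) / expected
    return out


def _family_homozygosity(counts: Sequence[int]) -> float | None:
    """Wright's F-hat for one synonymous family; None if n < 2."""
    n = sum(counts)
    if n < 2:
        return None
    p2 = sum((c / n) ** 2 for c in counts)
    return (n * p2 - 1.0) / (n - 1.0)


def enc(table: CodonCountTable, code: GeneticCode = DEFAULT_CODE) -> float:
    """Wright's effective number of codons, NaN when inestimable.

    Mean F-hat is taken per family size over families with n >= 2; a
    missing 3-fold mean is imputed as (F2+F4)/2; any other missing or
    non-positive mean leaves ENc undefined. Result clamped to [20, 61].
    """
    families = code.families()
    by_size: dict[int, list[float]] = {}
    n_single = 0
    sizes_present: dict[int, int] = {}
    for aa, fam in families.items():
        k = len(fam)
        if k == 1:
            n_single += 1
            continue
        sizes_present[k] = sizes_present.get(k, 0) + 1
        f_hat = _family_homozygosity([table.get(c) for c in fam])
        if f_hat is not None:
            by_size.setdefault(k, []).append(f_hat)

    means = {k: float(np.mean(v)) for k, v in by_size.items() if v}
    # impute a missing/zero 3-fold mean from the flanking sizes (CodonW rule)
    if 3 in sizes_present and means.get(3, 0.0) <= 0.0:
        if means.get(2, 0.0) > 0.0 and means.get(4, 0.0) > 0.0:
            means[3] = (means[2] + means[4]) / 2.0
        else:
            return math.nan

    value = float(n_single)
    for k, n_fam in sorted(sizes_present.items()):
        mean_f = means.get(k, 0.0)
        if mean_f <= 0.0:
            return math.nan
        value += n_fam / mean_f
    return float(min(max(value, 20.0), 61.0))


def enc_expected(gc3s: float) -> float:
    """Expected ENc under pure GC3s-driven mutation pressure.

    ``2 + s + 29 / (s**2 + (1-s)**2)``; note the formula is *not*
    symmetric about s=0.5 because of the linear term.
    """
    if not 0.0 <= gc3s <= 1.0:
        raise ValueError(f"gc3s must be in [0,1], got {gc3s}")
    s = gc3s
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) * (1.0 - s))


def relative_adaptiveness(
    reference_rscu: Mapping[str, float], code: GeneticCode = DEFAULT_CODE
) -> dict[str, float]:
    """w_j = RSCU_ref(j) / max RSCU within j's synonymous family."""
    w: dict[str, float] = {}
    for aa, fam in code.families().items():
        vals = [reference_rscu.get(c, math.nan) for c in fam]
        if all(math.isnan(v) for v in vals):
            continue
        fam_max = max(v for v in vals if not math.isnan(v))
        if fam_max <= 0:
            continue
        for c, v in zip(fam, vals):
            if not math.isnan(v):
                w[c] = v / fam_max
    return w


def cai(
    table: CodonCountTable,
    reference_rscu: Mapping[str, float],
    code: GeneticCode = DEFAULT_CODE,
    w_floor: float = 0.01,
) -> float:
    """Codon adaptation index: geometric mean of relative adaptiveness.

    Computed in the log domain over all counted codons in non-singleton
    families; w values below ``w_floor`` are floored to it.
    """
    w = relative_adaptiveness(reference_rscu, code)
    singles = {aa for aa, fam in code.families().items() if len(fam) == 1}
    log_sum = 0.0
    n = 0
    for codon, count in table.counts.items():
        if code.translate(codon) in singles:
            continue
        wj = w.get(codon)
        if wj is None:
            raise ValueError(
                f"reference RSCU undefined for codon {codon} in {table.source!r}"
            )
        log_sum += count * math.log(max(wj, w_floor))
        n += count
    if n == 0:
        raise ValueError(f"no eligible codons for CAI in {table.source!r}")
    return math.exp(log_sum / n)


def pr2_coordinates(
    table: CodonCountTable,
    code: GeneticCode = DEFAULT_CODE,
    family_scope: str = "all",
) -> tuple[float, float]:
    """PR2 point ``(G3/(G3+C3), A3/(A3+T3))`` over third-position bases.

    ``family_scope`` is ``"all"`` (every sense codon) or ``"fourfold"``
    (codons in 4-fold degenerate families only). Zero denominators give
    NaN for the affected coordinate.
    """
    if family_scope not in ("all", "fourfold"):
        raise ValueError(f"unknown family_scope {family_scope!r}")
    tallies = dict.fromkeys(BASES, 0)
    for codon, n in table.counts.items():
        if family_scope == "fourfold" and code.family_size(codon) != 4:
            continue
        tallies[codon[2]] += n
    at = tallies["A"] + tallies["T"]
    gc = tallies["G"] + tallies["C"]
    y = tallies["A"] / at if at else math.nan
    x = tallies["G"] / gc if gc else math.nan
    return x, y


@dataclass
class GeneCUBRecord:
    """Per-gene codon-usage statistics bundle."""

    gene_id: str
    taxon: str
    category: str
    length_codons: int
    composition: CompositionProfile
    enc: float
    enc_expected: float
    cai: float
    pr2_x: float
    pr2_y: float

    @property
    def gc12(self) -> float:
        return self.composition.gc12

    @property
    def gc3(self) -> float:
        return self.composition.gc3

    @property
    def gc3s(self) -> float:
        return self.composition.gc3s


def build_gene_records(
    cds_list: Sequence[CodingSequence],
    code: GeneticCode = DEFAULT_CODE,
    reference_rscu: Mapping[str, float] | None = None,
    pr2_scope: str = "all",
) -> list[GeneCUBRecord]:
    """Assemble per-gene records; the CAI reference defaults to the pooled
    usage of all supplied genes (genome-wide conformity)."""
    tables = [count_codons(c, code) for c in cds_list]
    if reference_rscu is None:
        reference_rscu = rscu(pool_counts(tables), code)
    records = []
    for cds_item, table in zip(cds_list, tables):
        prof = composition(table, code)
        enc_val = enc(table, code)
        exp_val = enc_expected(prof.gc3s) if not math.isnan(prof.gc3s) else math.nan
        x, y = pr2_coordinates(table, code, pr2_scope)
        records.append(
            GeneCUBRecord(
                gene_id=cds_item.gene_id,
                taxon=cds_item.taxon,
                category=cds_item.category,
                length_codons=table.total,
                composition=prof,
                enc=enc_val,
                enc_expected=exp_val,
                cai=cai(table, reference_rscu, code),
                pr2_x=x,
                pr2_y=y,
            )
        )
    return records


def records_frame(records: Sequence[GeneCUBRecord]) -> pd.DataFrame:
    """Flatten records into the standard per-gene output table."""
    rows = []
    for r in records:
        rows.append(
            {
                "gene_id": r.gene_id,
                "taxon": r.taxon,
                "category": r.category,
                "length_codons": r.length_codons,
                "gc_total": r.composition.gc_total,
                "gc1": r.composition.gc1,
                "gc2": r.composition.gc2,
                "gc3": r.composition.gc3,
                "gc12": r.gc12,
                "gc3s": r.gc3s,
                "enc": r.enc,
                "enc_expected": r.enc_expected,
                "cai": r.cai,
                "pr2_x": r.pr2_x,
                "pr2_y": r.pr2_y,
            }
        )
    return pd.DataFrame(rows)
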