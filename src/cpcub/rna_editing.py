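"""C-to-U RNA-edit effect classification and editing/RSCU association.

Edit-site prediction is upstream; this module consumes site lists
(taxon, gene, 1-based CDS position, C reference), maps each site onto
its codon, reports the amino-acid change and the hydrophobicity-class
transition, and tests whether editing prefers high-RSCU codons via a
within-gene permutation test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from cpcub.codon_stats import count_codons
from cpcub.sequence_io import DEFAULT_CODE, CodingSequence, GeneticCode

__all__ = [
    "EditSite",
    "EditEffect",
    "DEFAULT_AA_CLASSES",
    "classify_edit",
    "summarize_edits",
    "rscu_editing_association",
    "read_edit_sites_tsv",
    "effects_frame",
]

#: Hydrophobicity-class table. Class membership for Gly/Pro varies across
#: published tables; this assignment is a config default, not a constant
#: of nature, and every report should echo the table it used.
DEFAULT_AA_CLASSES: dict[str, str] = {
    **{aa: "hydrophobic" for aa in "AVLIPFMWG"},
    **{aa: "neutral" for aa in "STCYNQ"},
    **{aa: "basic" for aa in "KRH"},
    **{aa: "acidic" for aa in "DE"},
}


@dataclass(frozen=True)
class EditSite:
    taxon: str
    gene_id: str
    cds_position: int  # 1-based nt index within the CDS
    ref_base: str = "C"
    edited_base: str = "T"


@dataclass(frozen=True)
class EditEffect:
    site: EditSite
    codon_index: int  # 1-based codon number
    codon_position: int  # 1 | 2 | 3
    ref_codon: str
    edited_codon: str
    ref_aa: str
    edited_aa: str
    synonymous: bool
    class_transition: tuple[str, str]


def classify_edit(
    site: EditSite,
    cds: CodingSequence,
    classes: Mapping[str, str] | None = None,
    code: GeneticCode = DEFAULT_CODE,
) -> EditEffect:
    """Map one C->U site onto its codon and classify the consequence."""
    if classes is None:
        classes = DEFAULT_AA_CLASSES
    pos = site.cds_position
    if not 1 <= pos <= len(cds.sequence):
        raise ValueError(
            f"{cds.gene_id}: edit position {pos} outside CDS of {len(cds.sequence)} nt"
        )
    found = cds.sequence[pos - 1]
    if found != site.ref_base:
        raise ValueError(
            f"{cds.gene_id} position {pos}: expected {site.ref_base}, found {found}"
        )
    codon_index = (pos - 1) // 3 + 1
    codon_position = (pos - 1) % 3 + 1
    start = (codon_index - 1) * 3
    ref_codon = cds.sequence[start : start + 3]
    edited_codon = (
        ref_codon[: codon_position - 1]
        + site.edited_base
        + ref_codon[codon_position:]
    )
    ref_aa = code.translate(ref_codon)
    edited_aa = code.translate(edited_codon)

    def cls(aa: str) -> str:
        return "stop" if aa == "*" else classes[aa]

    return EditEffect(
        site=site,
        codon_index=codon_index,
        codon_position=codon_position,
        ref_codon=ref_codon,
        edited_codon=edited_codon,
        ref_aa=ref_aa,
        edited_aa=edited_aa,
        synonymous=ref_aa == edited_aa,
        class_transition=(cls(ref_aa), cls(edited_aa)),
    )


def summarize_edits(effects: Sequence[EditEffect]) -> dict:
    """Counts and percentages by codon position and class transition."""
    n = len(effects)
    by_position = {p: 0 for p in (1, 2, 3)}
    by_transition: dict[tuple[str, str], int] = {}
    n_synonymous = 0
    for e in effects:
        by_position[e.codon_position] += 1
        by_transition[e.class_transition] = by_transition.get(e.class_transition, 0) + 1
        n_synonymous += e.synonymous
    pct = (lambda c: 100.0 * c / n) if n else (lambda c: 0.0)
    return {
        "n_sites": n,
        "n_synonymous": n_synonymous,
        "by_position": {p: (c, pct(c)) for p, c in by_position.items()},
        "by_transition": {
            t: (c, pct(c)) for t, c in sorted(by_transition.items())
        },
    }


def rscu_editing_association(
    effects: Sequence[EditEffect],
    rscu_table: Mapping[str, float],
    cds_by_gene: Mapping[str, CodingSequence],
    code: GeneticCode = DEFAULT_CODE,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> dict:
    """Do edits sit in codons with higher RSCU than chance?

    Observed statistic: mean RSCU of the edited reference codons.
    Null: each edit is reassigned to a uniformly random sense codon of
    the same gene (labels permuted within genes), ``n_permutations``
    times. One-sided p = P(null mean >= observed), add-one corrected.
    """
    if not effects:
        raise ValueError("no edit effects supplied")
    observed_vals = [rscu_table[e.ref_codon] for e in effects]
    if any(math.isnan(v) for v in observed_vals):
        raise ValueError("RSCU undefined for an edited reference codon")
    observed = float(np.mean(observed_vals))

    background = [
        v
        for codon, v in rscu_table.items()
        if not math.isnan(v) and code.translate(codon) != "*"
    ]
    background_mean = float(np.mean(background))

    out = {
        "n_edits": len(effects),
        "observed_mean_rscu": observed,
        "background_mean_rscu": background_mean,
        "mean_difference": observed - background_mean,
        "n_permutations": n_permutations,
        "p_value": math.nan,
        "p_defined": False,
    }
    if len(effects) < 2:
        return out  # degenerate n: report emitted, p flagged undefined

    rng = np.random.default_rng(seed)
    gene_codon_rscu: dict[str, np.ndarray] = {}
    for e in effects:
        gid = e.site.gene_id
        if gid not in gene_codon_rscu:
            table = count_codons(cds_by_gene[gid], code)
            vals = []
            for codon, count in table.counts.items():
                v = rscu_table.get(codon, math.nan)
                if not math.isnan(v):
                    vals.extend([v] * count)
            gene_codon_rscu[gid] = np.array(vals)
    draws = np.empty((n_permutations, len(effects)))
    for j, e in enumerate(effects):
        pool = gene_codon_rscu[e.site.gene_id]
        draws[:, j] = rng.choice(pool, size=n_permutations, replace=True)
    null_means = draws.mean(axis=1)
    p = (1 + int(np.sum(null_means >= observed))) / (n_permutations + 1)
    out["p_value"] = float(p)
    out["p_defined"] = True
    return out


def read_edit_sites_tsv(path: str | Path) -> list[EditSite]:
    """Load sites from a TSV with columns taxon, gene_id, cds_position, ref, alt."""
    df = pd.read_csv(path, sep="\t")
    return [
        EditSite(
            taxon=str(row["taxon"]),
            gene_id=str(row["gene_id"]),
            cds_position=int(row["cds_position"]),
            ref_base=str(row["ref"]).upper().replace("U", "T"),
            edited_base=str(row["alt"]).upper().replace("U", "T"),
        )
        for _, row in df.iterrows()
    ]


def effects_frame(effects: Sequence[EditEffect]) -> pd.DataFrame:
    rows = []
    for e in effects:
        rows.append(
            {
                "taxon": e.site.taxon,
                "gene_id": e.site.gene_id,
                "cds_position": e.site.cds_position,
                "codon_index": e.codon_index,
                "codon_position": e.codon_position,
                "ref_codon": e.ref_codon,
                "edited_codon": e.edited_codon,
                "ref_aa": e.ref_aa,
                "edited_aa": e.edited_aa,
                "synonymous": e.synonymous,
                "class_from": e.class_transition[0],
                "class_to": e.class_transition[1],
            }
        )
    return pd.DataFrame(rows)
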