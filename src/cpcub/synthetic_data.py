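"""Ground-truth fixture generators for every pipeline stage.

Two generative regimes for CDS sets mirror the mutation/selection
dichotomy the diagnostics are meant to detect:

- *mutation-driven*: every codon position of a gene shares one GC
  pressure drawn per gene, so GC12 tracks GC3 and genes sit on the
  expected ENc curve;
- *selection-driven*: the amino-acid sequence is drawn first and the
  synonymous codon is chosen with probability proportional to
  ``exp(beta * 1[preferred])``, decoupling third-position usage from
  positions 1-2 and pushing genes below the curve.

Additional generators plant C->U edit sites with a requested
position/class-transition mix and negative-binomial count matrices with
known fold changes. Every generator records its planted truth in a
manifest sufficient to recompute expectations without regenerating the
sequences, and derives its randomness from a named substream of one
integer seed so adding a generator never perturbs existing fixtures.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqIO import write as seqio_write
from Bio.SeqRecord import SeqRecord

from cpcub.rna_editing import DEFAULT_AA_CLASSES, EditSite, classify_edit
from cpcub.sequence_io import BASES, DEFAULT_CODE, CodingSequence, GeneticCode

__all__ = [
    "GeneratorManifest",
    "generate_mutation_driven",
    "generate_selection_driven",
    "default_preferred_codons",
    "generate_edit_sites",
    "generate_counts",
    "write_fasta",
    "write_genbank",
    "write_edit_sites_tsv",
]


@dataclass
class GeneratorManifest:
    """Planted ground truth, recorded as flat key/value pairs."""

    seed: int
    regime: str
    entries: dict[str, object] = field(default_factory=dict)

    def __getitem__(self, key: str) -> object:
        return self.entries[key]

    def write(self, path: str | Path) -> None:
        lines = [f"seed\t{self.seed}", f"regime\t{self.regime}"]
        for key in sorted(self.entries):
            lines.append(f"{key}\t{self.entries[key]}")
        Path(path).write_text("\n".join(lines) + "\n")


def _rng(seed: int, stream: str) -> np.random.Generator:
    # named substream: independent of any other generator's draws
    return np.random.default_rng([seed, zlib.crc32(stream.encode())])


def _pick_length(rng: np.random.Generator, length_range: tuple[int, int]) -> int:
    lo, hi = length_range
    if lo > hi or lo < 9:
        raise ValueError(f"degenerate length range {length_range}")
    lo3, hi3 = -(-lo // 3), hi // 3
    return 3 * int(rng.integers(lo3, hi3 + 1))


def generate_mutation_driven(
    n_genes: int,
    length_range: tuple[int, int] = (300, 1500),
    gc_pressure_range: tuple[float, float] = (0.2, 0.8),
    seed: int = 0,
    taxon: str = "synthMutation",
    code: GeneticCode = DEFAULT_CODE,
) -> tuple[list[CodingSequence], GeneratorManifest]:
    """CDS set where all three codon positions share one GC pressure per gene.

    Per gene a pressure ``g`` is drawn uniformly from the range; bases
    are i.i.d. with P(G)=P(C)=g/2 and P(A)=P(T)=(1-g)/2. Stop codons are
    resampled in frame; ATG is prepended and TAA appended.
    """
    g_lo, g_hi = gc_pressure_range
    if not (0.0 <= g_lo <= g_hi <= 1.0):
        raise ValueError(f"degenerate GC pressure range {gc_pressure_range}")
    rng = _rng(seed, f"mutation:{taxon}")
    stops = np.array(sorted(code.stop_codons))
    base_arr = np.array(list(BASES))
    genes: list[CodingSequence] = []
    manifest = GeneratorManifest(seed=seed, regime="mutation")
    for i in range(n_genes):
        g = float(rng.uniform(g_lo, g_hi))
        body_codons = (_pick_length(rng, length_range)) // 3
        probs = np.array([(1 - g) / 2, g / 2, g / 2, (1 - g) / 2])
        mat = base_arr[rng.choice(4, size=(body_codons, 3), p=probs)]
        cod = np.char.add(np.char.add(mat[:, 0], mat[:, 1]), mat[:, 2])
        bad = np.isin(cod, stops)
        while bad.any():  # resample stop codons in frame
            redraw = base_arr[rng.choice(4, size=(int(bad.sum()), 3), p=probs)]
            cod[bad] = np.char.add(np.char.add(redraw[:, 0], redraw[:, 1]), redraw[:, 2])
            bad = np.isin(cod, stops)
        codons = list(cod)
        gene_id = f"{taxon}_g{i:03d}"
        genes.append(
            CodingSequence(
                gene_id=gene_id,
                taxon=taxon,
                sequence="ATG" + "".join(codons) + "TAA",
                category="other",
            )
        )
        manifest.entries[f"gene.{gene_id}.gc_pressure"] = g
        manifest.entries[f"gene.{gene_id}.length_nt"] = 3 * body_codons + 6
    return genes, manifest


def default_preferred_codons(code: GeneticCode = DEFAULT_CODE) -> dict[str, str]:
    """One preferred codon per multi-codon family, A/T-ending when possible
    (mimics the A/U-ending bias typical of chloroplast genes)."""
    preferred = {}
    for aa, fam in sorted(code.families().items()):
        if len(fam) == 1:
            continue
        for suffix in ("A", "T", "G", "C"):
            ending = [c for c in fam if c.endswith(suffix)]
            if ending:
                preferred[aa] = sorted(ending)[0]
                break
    return preferred


def generate_selection_driven(
    n_genes: int,
    length_range: tuple[int, int] = (300, 1500),
    preferred: Mapping[str, str] | None = None,
    bias_range: tuple[float, float] = (0.5, 3.0),
    seed: int = 0,
    taxon: str = "synthSelection",
    code: GeneticCode = DEFAULT_CODE,
) -> tuple[list[CodingSequence], GeneratorManifest]:
    """CDS set with third-position usage decoupled from positions 1-2.

    The amino-acid sequence is drawn uniformly over the 20 amino acids;
    per gene a bias strength ``beta`` is drawn from ``bias_range`` and
    each synonymous codon is chosen with probability proportional to
    ``exp(beta)`` for the family's preferred codon and 1 otherwise.
    """
    if preferred is None:
        preferred = default_preferred_codons(code)
    families = code.families()
    for aa, codon in preferred.items():
        if codon not in families.get(aa, ()):
            raise ValueError(f"preferred codon {codon} is not synonymous for {aa}")
    rng = _rng(seed, f"selection:{taxon}")
    aas = sorted(families)
    genes: list[CodingSequence] = []
    manifest = GeneratorManifest(seed=seed, regime="selection")
    manifest.entries["preferred"] = ",".join(
        f"{aa}:{c}" for aa, c in sorted(preferred.items())
    )
    b_lo, b_hi = bias_range
    for i in range(n_genes):
        beta = float(rng.uniform(b_lo, b_hi))
        n_codons = _pick_length(rng, length_range) // 3
        aa_idx = rng.choice(len(aas), size=n_codons)
        codons = np.empty(n_codons, dtype=object)
        for ai, aa in enumerate(aas):
            mask = aa_idx == ai
            k = int(mask.sum())
            if k == 0:
                continue
            fam = families[aa]
            weights = np.array(
                [np.exp(beta) if c == preferred.get(aa) else 1.0 for c in fam]
            )
            picks = rng.choice(len(fam), size=k, p=weights / weights.sum())
            codons[mask] = np.array(fam, dtype=object)[picks]
        codons = list(codons)
        gene_id = f"{taxon}_g{i:03d}"
        genes.append(
            CodingSequence(
                gene_id=gene_id,
                taxon=taxon,
                sequence="ATG" + "".join(codons) + "TAA",
                category="other",
            )
        )
        manifest.entries[f"gene.{gene_id}.beta"] = beta
        manifest.entries[f"gene.{gene_id}.length_nt"] = 3 * n_codons + 6
    return genes, manifest


def generate_edit_sites(
    cds_list: Sequence[CodingSequence],
    n_sites: int | None = None,
    mix: Sequence[tuple[int | None, str | None, str | None, int]] | None = None,
    seed: int = 0,
    classes: Mapping[str, str] | None = None,
    code: GeneticCode = DEFAULT_CODE,
) -> tuple[list[EditSite], GeneratorManifest]:
    """Plant C->U edit sites with a known effect profile.

    ``mix`` is a list of ``(codon_position, from_class, to_class, count)``
    buckets (None matches anything); alternatively ``n_sites`` picks
    sites uniformly at random over all editable C positions. The manifest
    records the expected classification of every planted site. Raises if
    a bucket cannot be filled from the available C positions.
    """
    if classes is None:
        classes = DEFAULT_AA_CLASSES
    if (n_sites is None) == (mix is None):
        raise ValueError("specify exactly one of n_sites or mix")
    rng = _rng(seed, "edit_sites")
    by_gene = {c.gene_id: c for c in cds_list}

    candidates = []  # (site, effect) over every editable C in a sense codon
    for cds in cds_list:
        n_codons = len(cds.sequence) // 3
        for pos in range(1, len(cds.sequence) + 1):
            if cds.sequence[pos - 1] != "C":
                continue
            if (pos - 1) // 3 + 1 == n_codons:  # skip the stop codon
                continue
            site = EditSite(taxon=cds.taxon, gene_id=cds.gene_id, cds_position=pos)
            effect = classify_edit(site, cds, classes, code)
            if "stop" in effect.class_transition:
                continue
            candidates.append((site, effect))

    chosen: list[tuple[EditSite, object]] = []
    if n_sites is not None:
        if n_sites > len(candidates):
            raise ValueError(
                f"requested {n_sites} sites but only {len(candidates)} editable"
            )
        idx = rng.choice(len(candidates), size=n_sites, replace=False)
        chosen = [candidates[int(i)] for i in idx]
    else:
        used: set[int] = set()
        for codon_position, from_cls, to_cls, count in mix:  # type: ignore[union-attr]
            pool = [
                i
                for i, (_, eff) in enumerate(candidates)
                if i not in used
                and (codon_position is None or eff.codon_position == codon_position)
                and (from_cls is None or eff.class_transition[0] == from_cls)
                and (to_cls is None or eff.class_transition[1] == to_cls)
            ]
            if len(pool) < count:
                raise ValueError(
                    f"infeasible mix: need {count} sites at position="
                    f"{codon_position} {from_cls}->{to_cls}, have {len(pool)}"
                )
            picked = rng.choice(pool, size=count, replace=False)
            used.update(int(i) for i in picked)
            chosen.extend(candidates[int(i)] for i in picked)

    manifest = GeneratorManifest(seed=seed, regime="edit_sites")
    sites = []
    for site, effect in chosen:
        sites.append(site)
        key = f"site.{site.gene_id}.{site.cds_position}"
        manifest.entries[f"{key}.codon_position"] = effect.codon_position
        manifest.entries[f"{key}.transition"] = "->".join(effect.class_transition)
        manifest.entries[f"{key}.aa_change"] = f"{effect.ref_aa}>{effect.edited_aa}"
    assert all(by_gene[s.gene_id].sequence[s.cds_position - 1] == "C" for s in sites)
    return sites, manifest


def generate_counts(
    gene_ids: Sequence[str],
    taxa: Sequence[str],
    gene_lengths: Mapping[str, int],
    fold_plan: Mapping[str, Mapping[str, float]] | None = None,
    base_mean: float = 200.0,
    dispersion: float = 0.1,
    n_replicates: int = 3,
    seed: int = 0,
):
    """Negative-binomial count matrices per taxon with planted fold changes.

    ``fold_plan[taxon][gene]`` multiplies the base mean (default 1x).
    Dispersion 0 degenerates to deterministic rounded means. Returns
    ``(matrices_by_taxon, manifest)`` where each matrix is a
    :class:`cpcub.expression_fpkm.CountMatrix`.
    """
    from cpcub.expression_fpkm import CountMatrix

    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    fold_plan = fold_plan or {}
    manifest = GeneratorManifest(seed=seed, regime="counts")
    lengths = pd.Series({g: float(gene_lengths[g]) for g in gene_ids})
    matrices = {}
    for taxon in taxa:
        rng = _rng(seed, f"counts:{taxon}")
        data = np.empty((len(gene_ids), n_replicates))
        for gi, gene in enumerate(gene_ids):
            fold = float(fold_plan.get(taxon, {}).get(gene, 1.0))
            mu = base_mean * fold * lengths[gene] / 1000.0
            if fold != 1.0:
                manifest.entries[f"fold.{taxon}.{gene}"] = fold
            if dispersion == 0:
                data[gi, :] = round(mu)
            else:
                r = 1.0 / dispersion
                p = r / (r + mu)
                data[gi, :] = rng.negative_binomial(r, p, size=n_replicates)
        counts = pd.DataFrame(
            data.astype(int),
            index=list(gene_ids),
            columns=[f"{taxon}_rep{j + 1}" for j in range(n_replicates)],
        )
        matrices[taxon] = CountMatrix(counts=counts, gene_lengths=lengths)
    return matrices, manifest


def write_fasta(cds_list: Sequence[CodingSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for cds in cds_list:
            fh.write(f">{cds.gene_id} taxon={cds.taxon}\n")
            for i in range(0, len(cds.sequence), 70):
                fh.write(cds.sequence[i : i + 70] + "\n")


def write_genbank(
    cds_list: Sequence[CodingSequence],
    path: str | Path,
    accession: str = "SYN000001",
    spacer: int = 30,
) -> None:
    """Write a single synthetic 'genome' record carrying one CDS feature
    per gene.

    To exercise location parsing, every third gene is placed on the
    minus strand (complement location) and every fifth as a two-segment
    join; the extracted CDS set must round-trip to the FASTA twin.
    """
    genome_parts: list[str] = []
    features: list[SeqFeature] = []
    offset = 0

    def pad(n: int) -> str:
        return "N" * n

    for i, cds in enumerate(cds_list):
        genome_parts.append(pad(spacer))
        offset += spacer
        seq = cds.sequence
        if i % 5 == 4 and len(seq) >= 12:
            cut = (len(seq) // 2) // 3 * 3
            part1, part2 = seq[:cut], seq[cut:]
            loc1 = SimpleLocation(offset, offset + len(part1), strand=1)
            genome_parts.append(part1 + pad(10) + part2)
            loc2 = SimpleLocation(
                offset + len(part1) + 10, offset + len(seq) + 10, strand=1
            )
            features.append(
                SeqFeature(
                    CompoundLocation([loc1, loc2]),
                    type="CDS",
                    qualifiers={"gene": [cds.gene_id]},
                )
            )
            offset += len(seq) + 10
        elif i % 3 == 2:
            rc = str(Seq(seq).reverse_complement())
            genome_parts.append(rc)
            features.append(
                SeqFeature(
                    SimpleLocation(offset, offset + len(seq), strand=-1),
                    type="CDS",
                    qualifiers={"gene": [cds.gene_id]},
                )
            )
            offset += len(seq)
        else:
            genome_parts.append(seq)
            features.append(
                SeqFeature(
                    SimpleLocation(offset, offset + len(seq), strand=1),
                    type="CDS",
                    qualifiers={"gene": [cds.gene_id]},
                )
            )
            offset += len(seq)

    record = SeqRecord(
        Seq("".join(genome_parts)),
        id=accession,
        name=accession,
        description="synthetic fixture genome",
        features=features,
        annotations={"molecule_type": "DNA"},
    )
    seqio_write([record], str(path), "genbank")


def write_edit_sites_tsv(sites: Sequence[EditSite], path: str | Path) -> None:
    lines = ["taxon\tgene_id\tcds_position\tref\talt"]
    lines += [
        f"{s.taxon}\t{s.gene_id}\t{s.cds_position}\t{s.ref_base}\t{s.edited_base}"
        for s in sites
    ]
    Path(path).write_text("\n".join(lines) + "\n")
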