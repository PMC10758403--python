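"""Reading, validation, filtering and functional classification of CDS.

Sequences come in from multi-record FASTA (one CDS per record) or from
GenBank flat files (CDS features extracted, honouring join/complement
locations). Validation enforces the usual coding-sequence invariants:
length divisible by three, minimum length, a recognised start codon and
no internal stop codon under the configured genetic code. Rejections are
data, not errors: they are returned alongside the kept records so they
can be written to a rejection log.
"""

from __future__ import annotations

import fnmatch
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable

__all__ = [
    "BASES",
    "IUPAC_NT",
    "GeneticCode",
    "CodingSequence",
    "CategoryRules",
    "Rejection",
    "read_cds_fasta",
    "read_cds_genbank",
    "validate_and_filter",
    "classify_gene",
    "write_rejection_log",
]

BASES = "ACGT"
#: IUPAC nucleotide one-letter codes accepted on input (ambiguity included).
IUPAC_NT = frozenset("ACGTRYSWKMBDHVN")


@dataclass(frozen=True)
class GeneticCode:
    """A complete codon->amino-acid map plus start codons.

    Built from an NCBI translation table; default is table 11
    (bacterial/archaeal/plant plastid). Stops are encoded as ``"*"``.
    """

    table_id: int
    codon_to_aa: dict[str, str]
    start_codons: frozenset[str]

    @classmethod
    def from_ncbi_table(cls, table_id: int = 11) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[table_id]
        mapping = dict(table.forward_table)
        for stop in table.stop_codons:
            mapping[stop] = "*"
        if len(mapping) != 64:
            raise ValueError(f"translation table {table_id} does not cover 64 codons")
        return cls(
            table_id=table_id,
            codon_to_aa=mapping,
            start_codons=frozenset(table.start_codons),
        )

    def __post_init__(self) -> None:
        if len(self.codon_to_aa) != 64:
            raise ValueError("codon_to_aa must have exactly 64 entries")

    @property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(c for c, aa in self.codon_to_aa.items() if aa == "*")

    @property
    def sense_codons(self) -> frozenset[str]:
        return frozenset(c for c, aa in self.codon_to_aa.items() if aa != "*")

    def families(self) -> dict[str, tuple[str, ...]]:
        """Synonymous families: amino acid -> sorted tuple of sense codons."""
        fam: dict[str, list[str]] = {}
        for codon, aa in self.codon_to_aa.items():
            if aa == "*":
                continue
            fam.setdefault(aa, []).append(codon)
        return {aa: tuple(sorted(cs)) for aa, cs in fam.items()}

    def family_size(self, codon: str) -> int:
        aa = self.codon_to_aa[codon]
        if aa == "*":
            return 0
        return sum(1 for a in self.codon_to_aa.values() if a == aa)

    def translate(self, codon: str) -> str:
        return self.codon_to_aa[codon]


#: Default genetic code used throughout (plastid = NCBI table 11).
DEFAULT_CODE = GeneticCode.from_ncbi_table(11)

#: Default start-codon set for filtering (stricter than table 11's full set).
DEFAULT_START_CODONS = frozenset({"ATG", "GTG"})

CATEGORIES = ("photosynthesis", "transcription_translation", "other")


@dataclass(frozen=True)
class CodingSequence:
    """One validated protein-coding sequence."""

    gene_id: str
    taxon: str
    sequence: str
    category: str = "other"

    def __len__(self) -> int:
        return len(self.sequence)

    def codons(self) -> list[str]:
        seq = self.sequence
        return [seq[i : i + 3] for i in range(0, len(seq) - len(seq) % 3, 3)]


@dataclass
class CategoryRules:
    """Ordered gene-name glob patterns mapping to functional categories.

    First match wins; names missing every pattern get ``default``.
    """

    rules: list[tuple[str, str]] = field(default_factory=list)
    default: str = "other"

    @classmethod
    def defaults(cls) -> "CategoryRules":
        photo = ["psa*", "psb*", "pet*", "ndh*", "rbcL", "atp*"]
        transl = ["rpo*", "rps*", "rpl*", "infA"]
        rules = [(p, "photosynthesis") for p in photo]
        rules += [(p, "transcription_translation") for p in transl]
        return cls(rules=rules, default="other")

    @classmethod
    def from_tsv(cls, path: str | Path, default: str = "other") -> "CategoryRules":
        rules = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            pattern, category = line.split("\t")[:2]
            rules.append((pattern, category))
        return cls(rules=rules, default=default)


def classify_gene(gene_id: str, rules: CategoryRules | None = None) -> str:
    """Assign a functional category to a gene name (first matching rule wins)."""
    if rules is None:
        rules = CategoryRules.defaults()
    for pattern, category in rules.rules:
        if fnmatch.fnmatchcase(gene_id, pattern):
            return category
    return rules.default


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_cds_fasta(path: str | Path, taxon: str = "") -> list[tuple[str, str]]:
    """Read raw (gene_id, sequence) pairs from a multi-record FASTA file.

    IDs are the first whitespace-delimited header token; sequences are
    upper-cased with U normalised to T. Non-IUPAC characters raise with
    the offending record named.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pairs: list[tuple[str, str]] = []
    for record in SeqIO.parse(str(path), "fasta"):
        seq = _normalize(str(record.seq))
        bad = set(seq) - IUPAC_NT
        if bad:
            raise ValueError(
                f"record {record.id!r}: non-IUPAC characters {sorted(bad)}"
            )
        pairs.append((record.id, seq))
    if not pairs:
        raise ValueError(f"no FASTA records in {path}")
    return pairs


def read_cds_genbank(path: str | Path) -> list[tuple[str, str]]:
    """Extract CDS features from a GenBank flat file.

    Locations are honoured via Biopython's extraction (join/complement
    included; multi-segment CDS concatenated in feature order). gene_id
    comes from the ``gene`` qualifier, falling back to ``locus_tag``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pairs: list[tuple[str, str]] = []
    for record in SeqIO.parse(str(path), "genbank"):
        if len(record.seq) == 0:
            raise ValueError(f"record {record.id!r} has no sequence")
        for feature in record.features:
            if feature.type != "CDS":
                continue
            quals = feature.qualifiers
            gene_id = (quals.get("gene") or quals.get("locus_tag") or ["?"])[0]
            try:
                seq = str(feature.extract(record.seq))
            except Exception as exc:  # unresolvable location
                raise ValueError(f"CDS {gene_id!r}: cannot resolve location: {exc}")
            pairs.append((gene_id, _normalize(seq)))
    return pairs


@dataclass(frozen=True)
class Rejection:
    gene_id: str
    taxon: str
    rule_failed: str


def _internal_stop_index(seq: str, code: GeneticCode) -> int | None:
    """Index (0-based, codon units) of the first internal stop, if any."""
    stops = code.stop_codons
    n_codons = len(seq) // 3
    for i in range(n_codons - 1):
        codon = seq[3 * i : 3 * i + 3]
        if codon in stops:
            return i
    return None


def validate_and_filter(
    raw_pairs: Iterable[tuple[str, str]],
    taxon: str = "",
    code: GeneticCode = DEFAULT_CODE,
    min_length: int = 300,
    start_codons: frozenset[str] | None = None,
    dedupe: bool = True,
    rules: CategoryRules | None = None,
) -> tuple[list[CodingSequence], list[Rejection]]:
    """Keep sequences passing all CDS invariants; log one rule per rejection.

    Checks, in order: length divisible by 3, minimum length, recognised
    start codon, no internal stop codon. With ``dedupe`` on, records with
    identical (gene_id, sequence) -- e.g. inverted-repeat duplicates --
    are kept once. Codons containing ambiguity characters never reject a
    gene; they are excluded downstream at counting time.
    """
    if start_codons is None:
        start_codons = DEFAULT_START_CODONS
    if rules is None:
        rules = CategoryRules.defaults()
    kept: list[CodingSequence] = []
    rejections: list[Rejection] = []
    seen: set[tuple[str, str]] = set()
    for gene_id, seq in raw_pairs:
        seq = _normalize(seq)
        if dedupe:
            key = (gene_id, seq)
            if key in seen:
                continue
            seen.add(key)
        if len(seq) % 3 != 0:
            rejections.append(Rejection(gene_id, taxon, "length_not_multiple_of_3"))
            continue
        if len(seq) < min_length:
            rejections.append(Rejection(gene_id, taxon, f"length_lt_{min_length}"))
            continue
        if seq[:3] not in start_codons:
            rejections.append(Rejection(gene_id, taxon, f"start_codon_{seq[:3]}"))
            continue
        stop_at = _internal_stop_index(seq, code)
        if stop_at is not None:
            rejections.append(
                Rejection(gene_id, taxon, f"internal_stop_codon_{stop_at + 1}")
            )
            continue
        kept.append(
            CodingSequence(
                gene_id=gene_id,
                taxon=taxon,
                sequence=seq,
                category=classify_gene(gene_id, rules),
            )
        )
    return kept, rejections


def write_rejection_log(rejections: Sequence[Rejection], path: str | Path) -> None:
    lines = ["gene_id\ttaxon\trule_failed"]
    lines += [f"{r.gene_id}\t{r.taxon}\t{r.rule_failed}" for r in rejections]
    Path(path).write_text("\n".join(lines) + "\n")
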