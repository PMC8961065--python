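"""Reading CDS sets and the five-rule quality filter.

Chloroplast CDS sets arrive either as multi-FASTA (one record per CDS) or as
GenBank flat files whose CDS features must be spliced and strand-corrected.
Before any codon-usage statistic is computed, sequences pass a quality filter:

1. composed only of A, C, G, T;
2. length a multiple of three;
3. starts with ATG;
4. ends with TAA, TAG or TGA;
5. no internal in-frame stop codon;
6. length >= 300 nt.

Each rejected sequence is charged to the first failing rule (rules checked in
the order above), so the :class:`FilterReport` tallies are deterministic.
Ambiguity codes (N, R, ...) fail rule 1 rather than being repaired; RNA input
should be pre-converted with :func:`rna_to_dna`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from Bio import SeqIO

from .genetic_code import GeneticCode


@dataclass
class CodingSequence:
    """One CDS record: identifier, optional gene name, species tag, sequence."""

    id: str
    seq: str
    gene_name: str = ""
    species: str = ""

    def __len__(self) -> int:
        return len(self.seq)


#: Filter rule identifiers, in checking order.
RULE_ALPHABET = "alphabet"
RULE_MULT3 = "length_mod3"
RULE_START = "start_codon"
RULE_STOP = "terminal_stop"
RULE_INTERNAL_STOP = "internal_stop"
RULE_MIN_LENGTH = "min_length"
FILTER_RULES = (
    RULE_ALPHABET,
    RULE_MULT3,
    RULE_START,
    RULE_STOP,
    RULE_INTERNAL_STOP,
    RULE_MIN_LENGTH,
)

_DNA = frozenset("ACGT")


@dataclass
class FilterReport:
    """Per-rule rejection accounting for one filtering pass."""

    n_input: int = 0
    n_retained: int = 0
    rejected_by_rule: dict = field(default_factory=dict)
    rejected_ids: list = field(default_factory=list)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("id\trule_failed\n")
            for ident, rule in self.rejected_ids:
                fh.write(f"{ident}\t{rule}\n")


def rna_to_dna(seq: str) -> str:
    """Convert an RNA string to its DNA spelling (U -> T, uppercased)."""
    return seq.upper().replace("U", "T")


def _unique_ids(ids: list[str]) -> list[str]:
    seen: dict[str, int] = {}
    out = []
    for ident in ids:
        if ident in seen:
            seen[ident] += 1
            out.append(f"{ident}_{seen[ident]}")
        else:
            seen[ident] = 1
            out.append(ident)
    return out


def read_cds_fasta(path, species: str = "") -> list[CodingSequence]:
    """Read an (unfiltered) CDS set from a multi-FASTA file.

    The header token before the first whitespace becomes the record id;
    duplicate ids are disambiguated with an ordinal suffix.  Sequences are
    uppercased on read; filtering decides the fate of ambiguity codes.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        warnings.warn(f"{path}: no FASTA records found", stacklevel=2)
    ids = _unique_ids([r.id for r in records])
    return [
        CodingSequence(id=ident, seq=str(r.seq).upper(), species=species)
        for ident, r in zip(ids, records)
    ]


def read_genbank_cds(path, species: str | None = None) -> list[CodingSequence]:
    """Extract CDS features from a GenBank flat file.

    join/complement locations are resolved to the spliced, strand-corrected
    nucleotide sequence; the ``gene`` (or ``locus_tag``) qualifier is captured
    as ``gene_name``.  Malformed features are skipped with a warning.
    """
    out: list[CodingSequence] = []
    for rec in SeqIO.parse(str(path), "genbank"):
        sp = species or rec.annotations.get("organism", "") or rec.id
        for i, feat in enumerate(f for f in rec.features if f.type == "CDS"):
            quals = feat.qualifiers
            gene = (quals.get("gene") or quals.get("locus_tag") or [""])[0]
            ident = (quals.get("protein_id") or [f"{rec.id}_cds{i + 1}"])[0]
            try:
                seq = str(feat.extract(rec.seq)).upper()
            except Exception as exc:  # malformed location
                warnings.warn(f"{ident}: skipping CDS feature ({exc})", stacklevel=2)
                continue
            out.append(CodingSequence(id=ident, seq=seq, gene_name=gene, species=sp))
    ids = _unique_ids([r.id for r in out])
    for r, ident in zip(out, ids):
        r.id = ident
    return out


def dedupe_by_gene_name(records: list[CodingSequence]) -> list[CodingSequence]:
    """Keep the first CDS per gene name (inverted-repeat duplicates collapse).

    Records without a gene name are always kept.  Off by default in the
    pipeline; raw feature counts match published per-genome CDS tallies.
    """
    seen: set[str] = set()
    out = []
    for r in records:
        if r.gene_name and r.gene_name in seen:
            continue
        if r.gene_name:
            seen.add(r.gene_name)
        out.append(r)
    return out


def _first_failing_rule(seq: str, stops: frozenset, min_length: int) -> str | None:
    if not set(seq) <= _DNA:
        return RULE_ALPHABET
    if len(seq) == 0 or len(seq) % 3 != 0:
        return RULE_MULT3
    if not seq.startswith("ATG"):
        return RULE_START
    if seq[-3:] not in stops:
        return RULE_STOP
    for i in range(0, len(seq) - 3, 3):
        if seq[i : i + 3] in stops:
            return RULE_INTERNAL_STOP
    if len(seq) < min_length:
        return RULE_MIN_LENGTH
    return None


def filter_cds(
    records: list[CodingSequence],
    min_length: int = 300,
    code: GeneticCode | None = None,
) -> tuple[list[CodingSequence], FilterReport]:
    """Apply the five-rule CDS quality filter (plus the length floor).

    Returns the retained records (order preserved) and a
    :class:`FilterReport` charging each rejection to its first failing rule.
    Filtering is total (never raises) and idempotent.
    """
    stops = frozenset((code or GeneticCode()).stop_codons)
    report = FilterReport(n_input=len(records))
    report.rejected_by_rule = {r: 0 for r in FILTER_RULES}
    retained = []
    for rec in records:
        rule = _first_failing_rule(rec.seq, stops, min_length)
        if rule is None:
            retained.append(rec)
        else:
            report.rejected_by_rule[rule] += 1
            report.rejected_ids.append((rec.id, rule))
    report.n_retained = len(retained)
    return retained, report


def write_cds_fasta(records: list[CodingSequence], path, width: int = 70) -> None:
    """Write CDS records as wrapped multi-FASTA."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")
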