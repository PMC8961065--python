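"""Genetic-code structure and codon counting.

Every downstream codon-usage statistic (RSCU, RFSC, ENc, SCUO, MILC, the
59-dimensional clustering space) is defined relative to the synonymous-family
structure of a genetic code: which codons encode the same amino acid and how
large each family is.  :class:`GeneticCode` exposes that structure for any
NCBI translation table (default: the standard code, table 1, whose degeneracy
structure is identical to the plastid/bacterial table 11 for these purposes).
Ser, Leu and Arg are kept as single six-fold families, the CodonW convention.

:class:`CodonCounts` is the shared 64-slot occurrence table, at gene or
genome scope.
"""

from __future__ import annotations

import warnings
from collections import OrderedDict
from dataclasses import dataclass, field

from Bio.Data import CodonTable

#: Base order used throughout (classical codon-table order).
BASES = "TCAG"

#: All 64 codons, TCAG-major order.
CODONS = tuple(a + b + c for a in BASES for b in BASES for c in BASES)

#: Symbol used for stop codons in ``codon_to_aa``.
STOP = "*"

#: Family label under which stop codons enter the high-frequency screen.
TER = "TER"


class GeneticCode:
    """Codon -> amino-acid map plus synonymous-family metadata.

    Parameters
    ----------
    table_id : int
        NCBI translation table identifier (1 = standard, 11 = bacterial/plastid).
    codon_to_aa : dict, optional
        Explicit 64-entry codon -> amino-acid map (``"*"`` marks stops).  When
        given, ``table_id`` is kept only as a label.

    Attributes
    ----------
    codon_to_aa : dict
        All 64 codons mapped to one-letter amino acids or ``"*"``.
    families : dict
        Amino acid -> ordered tuple of synonymous codons (stops excluded).
    degeneracy : dict
        Amino acid -> family size ``n_i``.
    stop_codons : tuple
        The stop codons of the table.
    sense_codons : tuple
        The non-stop codons (61 under the standard code).
    synonymous_codons : tuple
        Sense codons in families with ``n_i >= 2`` — the 59-codon space used
        for preferred-codon screening and RSCU-profile clustering under the
        standard code (ATG, TGG and the three stops removed).
    """

    def __init__(self, table_id: int = 1, codon_to_aa: dict | None = None):
        if codon_to_aa is None:
            tbl = CodonTable.unambiguous_dna_by_id[table_id]
            codon_to_aa = {}
            for codon in CODONS:
                if codon in tbl.stop_codons:
                    codon_to_aa[codon] = STOP
                else:
                    codon_to_aa[codon] = tbl.forward_table[codon]
        else:
            codon_to_aa = {c: codon_to_aa[c] for c in CODONS}
        self.table_id = table_id
        self.codon_to_aa = codon_to_aa
        self.stop_codons = tuple(c for c in CODONS if codon_to_aa[c] == STOP)
        fams: "OrderedDict[str, list[str]]" = OrderedDict()
        for codon in CODONS:
            aa = codon_to_aa[codon]
            if aa == STOP:
                continue
            fams.setdefault(aa, []).append(codon)
        self.families = {aa: tuple(cs) for aa, cs in fams.items()}
        self.degeneracy = {aa: len(cs) for aa, cs in self.families.items()}
        self.sense_codons = tuple(c for c in CODONS if codon_to_aa[c] != STOP)
        self.synonymous_codons = tuple(
            c for c in self.sense_codons if self.degeneracy[codon_to_aa[c]] >= 2
        )

    @classmethod
    def from_file(cls, path) -> "GeneticCode":
        """Load a code from a plain-text two-column ``codon<TAB>aa`` file.

        Lines starting with ``#`` are ignored; all 64 codons must be present.
        Stop codons are marked with ``*``.
        """
        mapping: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                codon, aa = line.split()[:2]
                mapping[codon.upper().replace("U", "T")] = aa
        missing = set(CODONS) - set(mapping)
        if missing:
            raise ValueError(f"genetic-code file is missing {len(missing)} codons")
        return cls(table_id=0, codon_to_aa=mapping)

    def degeneracy_classes(self) -> dict[int, int]:
        """Map family size k -> number of amino acids with that degeneracy."""
        out: dict[int, int] = {}
        for aa, n in self.degeneracy.items():
            out[n] = out.get(n, 0) + 1
        return out

    def __repr__(self) -> str:  # pragma: no cover
        return f"GeneticCode(table_id={self.table_id}, n_families={len(self.families)})"


@dataclass
class CodonCounts:
    """64-slot codon occurrence table.

    ``counts`` always carries all 64 codons (zeros included); ``L`` is the
    total number of tallied codons, the x_i. of the RSCU/RFSC formulas.
    """

    scope: str
    counts: dict[str, int] = field(default_factory=dict)
    L: int = 0

    def __post_init__(self):
        full = {c: 0 for c in CODONS}
        full.update({k: int(v) for k, v in self.counts.items()})
        self.counts = full
        self.L = int(sum(full.values()))


def count_codons(cds, include_stop: bool = False, code: GeneticCode | None = None) -> CodonCounts:
    """Tally non-overlapping frame-0 codons of a filtered CDS.

    With ``include_stop=False`` (the convention for family-based indices) a
    terminal stop codon is excluded from both the counts and ``L``.
    """
    code = code or GeneticCode()
    seq = cds.seq if hasattr(cds, "seq") else str(cds)
    ident = getattr(cds, "id", "seq")
    if len(seq) % 3 != 0:
        raise ValueError(f"{ident}: length {len(seq)} is not a multiple of 3")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if not include_stop and codons and codons[-1] in code.stop_codons:
        codons = codons[:-1]
    tally: dict[str, int] = {}
    for c in codons:
        tally[c] = tally.get(c, 0) + 1
    return CodonCounts(scope=ident, counts=tally)


def aggregate_counts(genes: list[CodonCounts], scope: str = "genome") -> CodonCounts:
    """Element-wise sum of per-gene count tables into a genome-scope table."""
    scopes = [g.scope for g in genes]
    if len(set(scopes)) != len(scopes):
        raise ValueError("aggregate_counts requires distinct gene scopes")
    if not genes:
        return CodonCounts(scope=scope)
    total = {c: 0 for c in CODONS}
    for g in genes:
        for c, x in g.counts.items():
            total[c] += x
    return CodonCounts(scope=scope, counts=total)
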