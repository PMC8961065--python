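"""Positional GC content and silent third-position base composition.

GC1/GC2/GC3 are the G+C fractions at the three codon positions; GC = their
mean and GC12 the mean of the first two (the neutrality-plot ordinate).
GC3s and the T3s/C3s/A3s/G3s fractions are restricted to *silent-capable*
third positions: codons whose amino-acid family has degeneracy >= 2 (Met,
Trp and stops excluded).  By default the terminal stop codon is included in
the whole-CDS GC tallies (switchable), while GC3s always ignores stops.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .genetic_code import GeneticCode


@dataclass
class PositionalComposition:
    """Per-gene (or pooled per-genome) positional composition fractions."""

    gc1: float
    gc2: float
    gc3: float
    gc: float
    gc12: float
    gc3s: float
    t3s: float
    c3s: float
    a3s: float
    g3s: float
    n_codons: int = 0


def _codons_of(seq: str):
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def _tally(seqs, code: GeneticCode, include_stop: bool):
    """Pooled position tallies over a list of sequences."""
    gc_pos = [0, 0, 0]
    n_codons = 0
    silent = {"T": 0, "C": 0, "A": 0, "G": 0}
    stops = set(code.stop_codons)
    for seq in seqs:
        if len(seq) == 0 or len(seq) % 3 != 0:
            raise ValueError("positional composition requires a filtered CDS")
        codons = _codons_of(seq)
        if not include_stop and codons[-1] in stops:
            codons = codons[:-1]
        for codon in codons:
            n_codons += 1
            for k in range(3):
                if codon[k] in "GC":
                    gc_pos[k] += 1
            aa = code.codon_to_aa.get(codon)
            if aa is not None and aa != "*" and code.degeneracy.get(aa, 0) >= 2:
                silent[codon[2]] += 1
    return gc_pos, n_codons, silent


def _from_tallies(gc_pos, n_codons, silent) -> PositionalComposition:
    if n_codons == 0:
        raise ValueError("zero-length input")
    gc1, gc2, gc3 = (g / n_codons for g in gc_pos)
    n_silent = sum(silent.values())
    if n_silent:
        t3s, c3s, a3s, g3s = (silent[b] / n_silent for b in "TCAG")
        gc3s = c3s + g3s
    else:
        t3s = c3s = a3s = g3s = gc3s = math.nan
    return PositionalComposition(
        gc1=gc1,
        gc2=gc2,
        gc3=gc3,
        gc=(gc1 + gc2 + gc3) / 3,
        gc12=(gc1 + gc2) / 2,
        gc3s=gc3s,
        t3s=t3s,
        c3s=c3s,
        a3s=a3s,
        g3s=g3s,
        n_codons=n_codons,
    )


def positional_gc(cds, code: GeneticCode | None = None, include_stop: bool = True) -> PositionalComposition:
    """Positional GC metrics of one filtered CDS.

    ``include_stop`` controls whether the terminal stop codon enters the
    GC1/GC2/GC3 tallies (whole-CDS convention by default); GC3s and the *3s
    fractions are always computed over silent-capable third positions only.
    """
    code = code or GeneticCode()
    seq = cds.seq if hasattr(cds, "seq") else str(cds)
    return _from_tallies(*_tally([seq], code, include_stop))


def genome_composition(
    genes,
    code: GeneticCode | None = None,
    include_stop: bool = True,
    mode: str = "pooled",
) -> PositionalComposition:
    """Genome-level composition over a list of CDS records.

    ``mode="pooled"`` (default) pools position tallies across genes, which is
    exactly the composition of the concatenated sequence — i.e. codon-count
    weighted.  ``mode="mean"`` returns the unweighted mean of per-gene
    fractions, provided for sensitivity checks.
    """
    code = code or GeneticCode()
    if not genes:
        raise ValueError("genome_composition requires at least one gene")
    seqs = [g.seq if hasattr(g, "seq") else str(g) for g in genes]
    if mode == "pooled":
        return _from_tallies(*_tally(seqs, code, include_stop))
    if mode != "mean":
        raise ValueError(f"unknown mode {mode!r}")
    comps = [positional_gc(s, code, include_stop) for s in seqs]

    def m(attr):
        vals = [getattr(c, attr) for c in comps if not math.isnan(getattr(c, attr))]
        return sum(vals) / len(vals) if vals else math.nan

    return PositionalComposition(
        gc1=m("gc1"),
        gc2=m("gc2"),
        gc3=m("gc3"),
        gc=m("gc"),
        gc12=m("gc12"),
        gc3s=m("gc3s"),
        t3s=m("t3s"),
        c3s=m("c3s"),
        a3s=m("a3s"),
        g3s=m("g3s"),
        n_codons=sum(c.n_codons for c in comps),
    )
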