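"""RSCU, RFSC and the preferred / high-frequency codon screens.

For codon j of amino acid i with family size n_i and observed count x_ij:

    RSCU_ij = x_ij / ((1/n_i) * sum_j x_ij)      (1 = no bias)
    RFSC_ij = x_ij / sum_j x_ij                  (family share, sums to 1)

so RSCU = RFSC * n_i.  A codon is *preferred* when RSCU > 1 (evaluated over
the 59-codon space: single-codon families and stops excluded).  A codon is
*high-frequency* (HF) when RFSC > 0.60 or RFSC > 1.5 * (1/n_i), i.e. more
than 1.5 times the uniform within-family expectation; stop codons take part
in the HF screen as a three-codon TER family.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .genetic_code import TER, CodonCounts, GeneticCode


def codon_index_table(
    counts: CodonCounts,
    code: GeneticCode | None = None,
    include_ter: bool = False,
) -> pd.DataFrame:
    """Per-codon RSCU/RFSC table for one gene or genome.

    Returns a DataFrame indexed by codon with columns ``amino_acid``,
    ``family_size``, ``count``, ``rscu``, ``rfsc``.  Families with zero total
    count get NaN in both index columns.  With ``include_ter=True`` the stop
    codons are appended as a TER family (the counts must then have been
    tallied with the terminal stop included for the row to be meaningful).
    """
    code = code or GeneticCode()
    rows = []
    families = dict(code.families)
    if include_ter:
        families[TER] = code.stop_codons
    for aa, codons in families.items():
        n_i = len(codons)
        total = sum(counts.counts[c] for c in codons)
        for c in codons:
            x = counts.counts[c]
            if total > 0:
                rfsc = x / total
                rscu = rfsc * n_i
            else:
                rfsc = rscu = math.nan
            rows.append((c, aa, n_i, x, rscu, rfsc))
    df = pd.DataFrame(
        rows, columns=["codon", "amino_acid", "family_size", "count", "rscu", "rfsc"]
    ).set_index("codon")
    return df


def rscu(counts: CodonCounts, code: GeneticCode | None = None) -> pd.DataFrame:
    """RSCU table (plus RFSC) for the sense-codon families."""
    return codon_index_table(counts, code)


def rfsc(counts: CodonCounts, code: GeneticCode | None = None) -> pd.DataFrame:
    """RFSC table (plus RSCU) for the sense-codon families."""
    return codon_index_table(counts, code)


def preferred_codons(table: pd.DataFrame) -> frozenset:
    """Codons with RSCU strictly > 1, restricted to the 59-codon space."""
    mask = (
        (table["amino_acid"] != TER)
        & (table["family_size"] >= 2)
        & (table["rscu"] > 1)
    )
    return frozenset(table.index[mask])


def high_frequency_codons(table: pd.DataFrame) -> frozenset:
    """HF screen: RFSC > 0.60 or RFSC > 1.5x the uniform family expectation.

    Single-codon families are excluded (their RFSC is trivially 1); a TER
    family present in the table participates like any other family.
    """
    multi = table[table["family_size"] >= 2]
    hf = (multi["rfsc"] > 0.60) | (multi["rfsc"] > 1.5 / multi["family_size"])
    return frozenset(multi.index[hf.fillna(False)])


def ends_in_at(codon: str) -> bool:
    """True when the codon's third base is A or T (== A/U on the RNA alphabet)."""
    return codon[2] in "AT"


def rscu_vector(counts: CodonCounts, code: GeneticCode | None = None) -> pd.Series:
    """The 59-dimensional RSCU profile used for clustering and heatmaps.

    Unobserved families yield NaN entries; consumers decide the imputation
    (the distance matrix imputes 0 with a warning).
    """
    code = code or GeneticCode()
    table = codon_index_table(counts, code)
    return table.loc[list(code.synonymous_codons), "rscu"]


def rscu_matrix(
    genomes: dict[str, CodonCounts], code: GeneticCode | None = None
) -> pd.DataFrame:
    """Species x 59-codon RSCU matrix from genome-aggregate counts."""
    code = code or GeneticCode()
    return pd.DataFrame(
        {name: rscu_vector(c, code) for name, c in genomes.items()}
    ).T.loc[list(genomes)]
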