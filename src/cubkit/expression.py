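"""Entropy- and divergence-based expression proxies: SCUO and MILC.

SCUO (synonymous codon usage order) is a normalized Shannon-entropy deficit.
For amino acid i with family size n_i >= 2 and observed family count x_i > 0:

    H_i = -sum_j p_ij log p_ij,   p_ij = x_ij / x_i
    O_i = (log n_i - H_i) / log n_i
    SCUO = sum_i (x_i / sum_i x_i) * O_i

SCUO is 0 under uniform synonymous usage and 1 when every observed family
uses a single codon; the log base cancels in O_i.

MILC (measure independent of length and composition) compares a gene's
within-family codon frequencies f against a reference distribution g:

    M_a = 2 * sum_j x_aj * ln(f_aj / g_aj)
    MILC = (sum_a M_a) / L  -  c,   c = (sum_a (n_a - 1)) / L

summed over amino acids observed in the gene; L is the gene's codon count
(stops excluded).  Natural log throughout.  A gene matching the reference
exactly scores -c; long reference-sampled genes score near 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .genetic_code import CodonCounts, GeneticCode


@dataclass
class ScuoResult:
    scope: str
    scuo: float
    o_by_aa: dict = field(default_factory=dict)
    weight_by_aa: dict = field(default_factory=dict)


@dataclass
class MilcResult:
    scope: str
    milc: float
    m_by_aa: dict = field(default_factory=dict)
    correction: float = 0.0
    L: int = 0
    reference_id: str = ""
    flags: list = field(default_factory=list)


def scuo(counts: CodonCounts, code: GeneticCode | None = None) -> ScuoResult:
    """SCUO of one gene or genome (stops and single-codon families excluded)."""
    code = code or GeneticCode()
    o_by_aa: dict[str, float] = {}
    weight: dict[str, float] = {}
    total = 0
    for aa, codons in code.families.items():
        n_i = len(codons)
        if n_i < 2:
            continue
        xs = np.array([counts.counts[c] for c in codons], dtype=float)
        x_i = xs.sum()
        if x_i == 0:
            continue
        p = xs[xs > 0] / x_i
        h = -float(np.sum(p * np.log(p)))
        o_by_aa[aa] = (math.log(n_i) - h) / math.log(n_i)
        weight[aa] = x_i
        total += x_i
    if total == 0:
        warnings.warn(f"{counts.scope}: no multi-codon family observed; SCUO undefined",
                      stacklevel=2)
        return ScuoResult(scope=counts.scope, scuo=math.nan)
    weight = {aa: w / total for aa, w in weight.items()}
    value = sum(weight[aa] * o_by_aa[aa] for aa in o_by_aa)
    return ScuoResult(scope=counts.scope, scuo=value, o_by_aa=o_by_aa, weight_by_aa=weight)


def milc(
    counts: CodonCounts,
    reference: CodonCounts,
    code: GeneticCode | None = None,
) -> MilcResult:
    """MILC of a gene against a reference codon-usage distribution.

    ``reference`` is typically the genome-aggregate counts (stops excluded).
    Reference families observed in the gene but with zero reference counts on
    a used codon get 0.5 added to every reference codon of that family, and
    the result is flagged.
    """
    code = code or GeneticCode()
    m_by_aa: dict[str, float] = {}
    flags: list[str] = []
    L = 0
    deg_sum = 0
    for aa, codons in code.families.items():
        n_i = len(codons)
        xs = np.array([counts.counts[c] for c in codons], dtype=float)
        x_i = xs.sum()
        if x_i == 0:
            continue
        L += int(x_i)
        deg_sum += n_i - 1
        gs = np.array([reference.counts[c] for c in codons], dtype=float)
        if np.any((xs > 0) & (gs == 0)):
            gs = gs + 0.5
            flags.append(f"pseudo_frequency:{aa}")
        g_i = gs.sum()
        if g_i == 0:  # family absent from the reference altogether
            gs = gs + 0.5
            g_i = gs.sum()
            flags.append(f"pseudo_frequency:{aa}")
        f = xs / x_i
        g = gs / g_i
        used = xs > 0
        m_by_aa[aa] = 2.0 * float(np.sum(xs[used] * np.log(f[used] / g[used])))
    if L == 0:
        raise ValueError(f"{counts.scope}: empty gene (L = 0)")
    c = deg_sum / L
    value = sum(m_by_aa.values()) / L - c
    return MilcResult(scope=counts.scope, milc=value, m_by_aa=m_by_aa,
                      correction=c, L=L, reference_id=reference.scope, flags=flags)


def correlate_scuo_milc(scuos, milcs) -> tuple[float, float]:
    """Pearson correlation (r, two-tailed p) between paired SCUO and MILC values.

    Accepts raw floats or the result dataclasses; NaN pairs are dropped.
    """
    x = np.array([s.scuo if hasattr(s, "scuo") else float(s) for s in scuos])
    y = np.array([m.milc if hasattr(m, "milc") else float(m) for m in milcs])
    if x.shape != y.shape:
        raise ValueError("SCUO and MILC vectors must be paired")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("correlation requires at least 3 paired genes")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero variance; SCUO-MILC correlation undefined", stacklevel=2)
        return math.nan, math.nan
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
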