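"""Mutation-vs-selection diagnostics: ENc, PR2 bias and the neutrality plot.

Observed ENc follows Wright's homozygosity estimator: within each amino-acid
family with n > 1 observed codons,

    F_hat = (n * sum_j p_j**2 - 1) / (n - 1),

F_hat values are averaged within each degeneracy class k (2, 3, 4, 6 under
the standard code) and

    ENc = 2 + N2/F2 + N3/F3 + N4/F4 + N6/F6,

where N_k is the number of amino acids in class k (9, 1, 5, 3), giving the
familiar range ~20 (one codon per amino acid) to 61 (uniform usage).  The
expected ENc under mutation pressure alone is a function of S = GC3s:

    ENc* = 2 + S + 29 / (S**2 + (1 - S)**2).

PR2 coordinates are G3/(G3+C3) vs A3/(A3+T3) over four-fold degenerate
families; (0.5, 0.5) means no bias between complementary strands.  The
neutrality plot regresses per-gene GC12 on GC3: a slope near 1 indicates
mutation pressure dominates, near 0 natural selection.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .composition import PositionalComposition
from .genetic_code import CodonCounts, GeneticCode


@dataclass
class EncResult:
    scope: str
    enc: float
    f_bar_by_class: dict = field(default_factory=dict)
    n_missing_classes: int = 0
    flags: list = field(default_factory=list)


@dataclass
class PR2Point:
    scope: str
    x: float  # G3 / (G3 + C3)
    y: float  # A3 / (A3 + T3)
    family_mode: str = "fourfold"


@dataclass
class NeutralityFit:
    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    n_genes: int
    gc12_range: tuple
    gc3_range: tuple


def enc_observed(counts: CodonCounts, code: GeneticCode | None = None) -> EncResult:
    """Observed effective number of codons for one gene or genome.

    Missing-class fallback: a class with no estimable mean homozygosity uses
    (F2+F4)/2 for the three-fold class when both neighbours exist, otherwise
    the mean of the available class means.  The result is clamped to [2, 61].
    """
    code = code or GeneticCode()
    class_sizes = sorted(k for k in code.degeneracy_classes() if k >= 2)
    n_aa_by_class = {k: v for k, v in code.degeneracy_classes().items() if k >= 2}
    fhat: dict[int, list[float]] = {k: [] for k in class_sizes}
    flags: list[str] = []
    for aa, codons in code.families.items():
        n_i = len(codons)
        if n_i < 2:
            continue
        xs = np.array([counts.counts[c] for c in codons], dtype=float)
        n = xs.sum()
        if n <= 1:
            continue
        p = xs / n
        f = (n * float(p @ p) - 1.0) / (n - 1.0)
        fhat[n_i].append(f)

    f_bar: dict[int, float] = {}
    for k in class_sizes:
        if fhat[k]:
            m = float(np.mean(fhat[k]))
            if m > 1e-12:
                f_bar[k] = m

    if not f_bar:
        warnings.warn(f"{counts.scope}: no estimable synonymous family for ENc", stacklevel=2)
        return EncResult(scope=counts.scope, enc=math.nan,
                         n_missing_classes=len(class_sizes), flags=["no_families"])

    n_missing = 0
    filled = dict(f_bar)
    for k in class_sizes:
        if k in filled:
            continue
        n_missing += 1
        if k == 3 and 2 in f_bar and 4 in f_bar:
            filled[k] = (f_bar[2] + f_bar[4]) / 2.0
            flags.append("class3_interpolated")
        else:
            filled[k] = float(np.mean(list(f_bar.values())))
            flags.append(f"class{k}_imputed")

    enc = 2.0 + sum(n_aa_by_class[k] / filled[k] for k in class_sizes)
    upper = 2.0 + sum(n_aa_by_class[k] * k for k in class_sizes)  # 61 for the standard code
    if enc > upper:
        enc = upper
        flags.append("clamped_high")
    if enc < 2.0:
        enc = 2.0
        flags.append("clamped_low")
    return EncResult(scope=counts.scope, enc=enc, f_bar_by_class=filled,
                     n_missing_classes=n_missing, flags=flags)


def enc_expected(gc3s):
    """Expected ENc under mutation pressure alone, as a function of S = GC3s."""
    s = np.asarray(gc3s, dtype=float)
    if np.any((s < 0) | (s > 1)):
        raise ValueError("gc3s must lie in [0, 1]")
    out = 2.0 + s + 29.0 / (s**2 + (1.0 - s) ** 2)
    return float(out) if out.ndim == 0 else out


def pr2_point(
    counts: CodonCounts,
    code: GeneticCode | None = None,
    family_mode: str = "fourfold",
) -> PR2Point:
    """PR2-bias coordinates from third-position tallies.

    ``family_mode="fourfold"`` (default) restricts to codons of four-fold
    degenerate families; ``"all"`` uses every tallied codon.  A zero
    denominator yields a NaN coordinate.
    """
    code = code or GeneticCode()
    if family_mode not in ("fourfold", "all"):
        raise ValueError(f"unknown family_mode {family_mode!r}")
    tally = {b: 0 for b in "TCAG"}
    for codon, x in counts.counts.items():
        if x == 0:
            continue
        if family_mode == "fourfold":
            aa = code.codon_to_aa[codon]
            if aa == "*" or code.degeneracy.get(aa) != 4:
                continue
        tally[codon[2]] += x
    gc = tally["G"] + tally["C"]
    at = tally["A"] + tally["T"]
    x = tally["G"] / gc if gc > 0 else math.nan
    y = tally["A"] / at if at > 0 else math.nan
    return PR2Point(scope=counts.scope, x=x, y=y, family_mode=family_mode)


def neutrality_fit(genes: list[PositionalComposition]) -> NeutralityFit:
    """OLS regression of per-gene GC12 on GC3 with Pearson r and two-tailed p."""
    pairs = [
        (g.gc3, g.gc12)
        for g in genes
        if not (math.isnan(g.gc3) or math.isnan(g.gc12))
    ]
    if len(pairs) < 3:
        raise ValueError("neutrality_fit requires at least 3 genes")
    gc3 = np.array([p[0] for p in pairs])
    gc12 = np.array([p[1] for p in pairs])
    if np.ptp(gc3) == 0:
        warnings.warn("zero variance in GC3; neutrality slope undefined", stacklevel=2)
        return NeutralityFit(math.nan, math.nan, math.nan, math.nan, len(pairs),
                             (float(gc12.min()), float(gc12.max())),
                             (float(gc3.min()), float(gc3.max())))
    res = stats.linregress(gc3, gc12)
    return NeutralityFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        p_value=float(res.pvalue),
        n_genes=len(pairs),
        gc12_range=(float(gc12.min()), float(gc12.max())),
        gc3_range=(float(gc3.min()), float(gc3.max())),
    )
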