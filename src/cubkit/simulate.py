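"""Chloroplast-like synthetic CDS sets with controlled codon bias.

The generator emulates the input regime of a plastome codon-usage study:
~45–60 genes per genome, lengths >= 300 nt and multiples of 3, ATG start,
canonical stop, overall GC in the high-30s (%), an A/T-ending codon
preference of tunable strength, and a per-gene GC3 gradient that can carry a
prescribed neutrality (GC12 ~ GC3) slope.

Mechanics per gene:

* amino acids are drawn i.i.d. from a composition vector (default: a
  plant-plastome-like composition);
* within each synonymous family, codons follow a softmax-tilted
  distribution: a designated A/T-ending codon is up-weighted by
  ``exp(bias_theta)`` and G/C-ending codons by ``exp(w)``, where the tilt
  ``w`` is solved by bisection so the gene's expected GC3 matches its
  target;
* when a neutrality triple ``(slope, intercept, noise_sd)`` is given, each
  gene also receives a GC12 target ``slope * gc3 + intercept + noise`` met
  by exponentially tilting the amino-acid composition;
* the first codon is ATG, the last a stop drawn uniformly from
  {TAA, TAG, TGA}.

All randomness flows through one seeded ``numpy`` generator; a fixed seed
reproduces the FASTA byte for byte.  The ground-truth record keeps the exact
per-gene sampling distributions so estimators can be checked against the
distributions that actually generated the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .composition import positional_gc
from .genetic_code import GeneticCode
from .io import CodingSequence

#: Plant-plastome-like amino-acid composition (normalized at use).
DEFAULT_AA_COMPOSITION = {
    "L": 0.105, "I": 0.086, "S": 0.082, "F": 0.065, "K": 0.060,
    "G": 0.060, "E": 0.055, "T": 0.053, "R": 0.048, "A": 0.050,
    "N": 0.046, "V": 0.050, "D": 0.040, "P": 0.040, "Q": 0.035,
    "Y": 0.034, "H": 0.023, "C": 0.012, "M": 0.028, "W": 0.019,
}

_TILT_BOUND = 25.0


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic genome.

    ``gc3_targets`` may be a ``(slope, intercept, noise_sd)`` triple (per-gene
    GC3 drawn uniformly from ``gc3_range`` with GC12 following the neutrality
    line), an explicit per-gene sequence of GC3 targets, or ``None`` for no
    composition targeting (pure ``bias_theta`` tilt, uniform families at 0).
    """

    n_genes: int = 57
    length_range: tuple = (100, 500)  # codons, start and stop included
    aa_composition: dict | None = None
    bias_theta: float = 0.7
    gc3_targets: object = (0.1, 0.34, 0.02)
    gc3_range: tuple = (0.15, 0.45)
    seed: int = 0
    species: str = "synthetic"
    table_id: int = 1


@dataclass
class GeneTruth:
    gene_id: str
    length_codons: int
    target_gc3: float
    expected_gc3: float
    realized_gc3: float
    target_gc12: float
    expected_gc12: float
    realized_gc12: float
    tilt_w: float
    tilt_u: float
    aa_probs: dict
    family_dists: dict  # aa -> {codon: probability}
    flags: list = field(default_factory=list)


@dataclass
class GroundTruth:
    config: SimulationConfig
    genes: list = field(default_factory=list)

    def to_tsv(self, path) -> None:
        import json

        with open(path, "w") as fh:
            fh.write(
                "gene\tL_codons\ttarget_gc3\texpected_gc3\trealized_gc3\t"
                "target_gc12\trealized_gc12\ttilt_w\ttilt_u\tflags\tfamily_dists\n"
            )
            for g in self.genes:
                dists = json.dumps(
                    {aa: {c: round(p, 6) for c, p in d.items()} for aa, d in g.family_dists.items()}
                )
                fh.write(
                    f"{g.gene_id}\t{g.length_codons}\t{g.target_gc3:.4f}\t"
                    f"{g.expected_gc3:.4f}\t{g.realized_gc3:.4f}\t{g.target_gc12:.4f}\t"
                    f"{g.realized_gc12:.4f}\t{g.tilt_w:.4f}\t{g.tilt_u:.4f}\t"
                    f"{';'.join(g.flags)}\t{dists}\n"
                )


class _CodeGeometry:
    """Per-family codon arrays used by the tilt solvers and the sampler."""

    def __init__(self, code: GeneticCode, theta: float):
        self.code = code
        self.aas = list(code.families)
        self.codons = {aa: np.array(code.families[aa]) for aa in self.aas}
        self.gc_end = {
            aa: np.array([c[2] in "GC" for c in code.families[aa]], dtype=float)
            for aa in self.aas
        }
        self.gc12_codon = {
            aa: np.array(
                [((c[0] in "GC") + (c[1] in "GC")) / 2.0 for c in code.families[aa]]
            )
            for aa in self.aas
        }
        self.base_weight = {}
        for aa in self.aas:
            fam = code.families[aa]
            designated = next(
                (c for c in fam if c[2] == "T"), next((c for c in fam if c[2] == "A"), fam[0])
            )
            self.base_weight[aa] = np.array(
                [math.exp(theta) if c == designated else 1.0 for c in fam]
            )

    def family_dists(self, w: float) -> dict:
        out = {}
        for aa in self.aas:
            weights = self.base_weight[aa] * np.exp(w * self.gc_end[aa])
            out[aa] = weights / weights.sum()
        return out

    def expected_gc3(self, comp: np.ndarray, dists: dict) -> float:
        return float(
            sum(comp[i] * float(dists[aa] @ self.gc_end[aa]) for i, aa in enumerate(self.aas))
        )

    def gc12_by_aa(self, dists: dict) -> np.ndarray:
        return np.array([float(dists[aa] @ self.gc12_codon[aa]) for aa in self.aas])


def _bisect(fn, target, lo=-_TILT_BOUND, hi=_TILT_BOUND, tol=1e-4, iters=80):
    """Solve fn(x) = target for a monotone increasing fn; clamp at the bounds.

    Returns (x, achieved, clamped_flag).
    """
    f_lo, f_hi = fn(lo), fn(hi)
    if target <= f_lo:
        return lo, f_lo, target < f_lo - 1e-9
    if target >= f_hi:
        return hi, f_hi, target > f_hi + 1e-9
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        f_mid = fn(mid)
        if abs(f_mid - target) < tol:
            return mid, f_mid, False
        if f_mid < target:
            lo = mid
        else:
            hi = mid
    mid = 0.5 * (lo + hi)
    return mid, fn(mid), False


def _solve_gene_distributions(geom: _CodeGeometry, comp0: np.ndarray,
                              target_gc3, target_gc12):
    """Alternate bisections on the GC3 tilt w and the GC12 composition tilt u."""
    flags: list[str] = []
    w = u = 0.0
    comp = comp0.copy()
    if target_gc3 is None:
        return 0.0, 0.0, comp, geom.family_dists(0.0), flags
    for _ in range(3):
        w, achieved3, clamped3 = _bisect(
            lambda x: geom.expected_gc3(comp, geom.family_dists(x)), target_gc3
        )
        dists = geom.family_dists(w)
        if target_gc12 is None:
            break
        gc12 = geom.gc12_by_aa(dists)

        def comp_of(x):
            wts = comp0 * np.exp(x * gc12)
            return wts / wts.sum()

        u, achieved12, clamped12 = _bisect(lambda x: float(comp_of(x) @ gc12), target_gc12)
        comp = comp_of(u)
    dists = geom.family_dists(w)
    if clamped3:
        flags.append("gc3_target_clamped")
    if target_gc12 is not None and clamped12:
        flags.append("gc12_target_clamped")
    return w, u, comp, dists, flags


def _draw_targets(config: SimulationConfig, rng) -> list:
    """Per-gene (gc3_target, gc12_target) pairs, or (None, None) pairs."""
    t = config.gc3_targets
    if t is None:
        return [(None, None)] * config.n_genes
    if isinstance(t, tuple) and len(t) == 3 and all(np.isscalar(v) for v in t):
        slope, intercept, noise_sd = t
        lo, hi = config.gc3_range
        out = []
        for _ in range(config.n_genes):
            x = float(rng.uniform(lo, hi))
            y = float(np.clip(slope * x + intercept + rng.normal(0.0, noise_sd), 0.02, 0.98))
            out.append((x, y))
        return out
    targets = list(t)
    if len(targets) != config.n_genes:
        raise ValueError("per-gene gc3_targets must have length n_genes")
    return [(float(x), None) for x in targets]


def _sample_gene(geom: _CodeGeometry, comp: np.ndarray, dists: dict,
                 n_internal: int, rng) -> str:
    aa_idx = rng.choice(len(geom.aas), size=n_internal, p=comp)
    codons = np.empty(n_internal, dtype=object)
    for i, aa in enumerate(geom.aas):
        where = np.nonzero(aa_idx == i)[0]
        if where.size:
            codons[where] = rng.choice(geom.codons[aa], size=where.size, p=dists[aa])
    stop = rng.choice(np.array(geom.code.stop_codons))
    return "ATG" + "".join(codons.tolist()) + str(stop)


def generate_cds_set(config: SimulationConfig) -> tuple[list, GroundTruth]:
    """Generate one synthetic genome: CDS records plus the ground truth."""
    code = GeneticCode(config.table_id)
    geom = _CodeGeometry(code, config.bias_theta)
    comp_map = config.aa_composition or DEFAULT_AA_COMPOSITION
    comp0 = np.array([comp_map.get(aa, 0.0) for aa in geom.aas], dtype=float)
    if comp0.sum() <= 0:
        raise ValueError("aa_composition has no mass on this code's amino acids")
    comp0 = comp0 / comp0.sum()

    rng = np.random.default_rng(config.seed)
    lo, hi = config.length_range
    if lo < 100:
        raise ValueError("length_range minimum must be >= 100 codons (300 nt)")
    targets = _draw_targets(config, rng)

    records: list[CodingSequence] = []
    truth = GroundTruth(config=config)
    for g, (t_gc3, t_gc12) in enumerate(targets, start=1):
        L = int(rng.integers(lo, hi + 1))
        w, u, comp, dists, flags = _solve_gene_distributions(geom, comp0, t_gc3, t_gc12)
        seq = _sample_gene(geom, comp, dists, L - 2, rng)
        gene_id = f"{config.species}_g{g:03d}"
        records.append(CodingSequence(id=gene_id, seq=seq, species=config.species))
        pc = positional_gc(seq, code, include_stop=True)
        truth.genes.append(
            GeneTruth(
                gene_id=gene_id,
                length_codons=L,
                target_gc3=math.nan if t_gc3 is None else t_gc3,
                expected_gc3=geom.expected_gc3(comp, dists),
                realized_gc3=pc.gc3,
                target_gc12=math.nan if t_gc12 is None else t_gc12,
                expected_gc12=float(comp @ geom.gc12_by_aa(dists)),
                realized_gc12=pc.gc12,
                tilt_w=w,
                tilt_u=u,
                aa_probs={aa: float(p) for aa, p in zip(geom.aas, comp)},
                family_dists={
                    aa: {c: float(p) for c, p in zip(code.families[aa], dists[aa])}
                    for aa in geom.aas
                },
                flags=flags,
            )
        )
    return records, truth


def generate_reference_genome_pair(
    config: SimulationConfig, divergence: float
) -> tuple[tuple[list, GroundTruth], tuple[list, GroundTruth]]:
    """Generate two genomes whose within-family codon distributions differ by
    a controlled amount.

    The second genome reuses the first genome's per-gene amino-acid
    compositions and gene lengths, but each within-family distribution is
    interpolated toward the uniform distribution by ``divergence`` in [0, 1]
    (0 = identical usage, 1 = fully uniform families).
    """
    if not 0.0 <= divergence <= 1.0:
        raise ValueError("divergence must lie in [0, 1]")
    code = GeneticCode(config.table_id)
    geom = _CodeGeometry(code, config.bias_theta)
    set_a, truth_a = generate_cds_set(config)

    rng = np.random.default_rng([int(config.seed), 104729])
    species_b = config.species + "_div"
    records_b: list[CodingSequence] = []
    truth_b = GroundTruth(config=replace(config, species=species_b))
    for g, gt in enumerate(truth_a.genes, start=1):
        comp = np.array([gt.aa_probs[aa] for aa in geom.aas])
        dists = {}
        for aa in geom.aas:
            p = np.array([gt.family_dists[aa][c] for c in code.families[aa]])
            uniform = np.full(len(p), 1.0 / len(p))
            dists[aa] = (1.0 - divergence) * p + divergence * uniform
        seq = _sample_gene(geom, comp, dists, gt.length_codons - 2, rng)
        gene_id = f"{species_b}_g{g:03d}"
        records_b.append(CodingSequence(id=gene_id, seq=seq, species=species_b))
        pc = positional_gc(seq, code, include_stop=True)
        truth_b.genes.append(
            replace(
                gt,
                gene_id=gene_id,
                realized_gc3=pc.gc3,
                realized_gc12=pc.gc12,
                family_dists={
                    aa: {c: float(p) for c, p in zip(code.families[aa], dists[aa])}
                    for aa in geom.aas
                },
            )
        )
    return (set_a, truth_a), (records_b, truth_b)
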