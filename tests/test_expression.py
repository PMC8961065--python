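"""SCUO and MILC expression proxies and their correlation."""

import math

import numpy as np
import pytest

from cubkit import CodonCounts, correlate_scuo_milc, milc, scuo

from conftest import random_counts, uniform_usage_counts


def test_scuo_zero_under_uniform_usage(code):
    res = scuo(uniform_usage_counts(code), code)
    assert res.scuo == pytest.approx(0.0, abs=1e-12)
    assert all(o == pytest.approx(0.0, abs=1e-12) for o in res.o_by_aa.values())


def test_scuo_one_under_single_codon_usage(code):
    res = scuo(CodonCounts("toy", {"TTT": 4}), code)
    assert res.scuo == pytest.approx(1.0)
    # every multi-codon family used with a single codon each
    res2 = scuo(CodonCounts("toy2", {"TTT": 4, "CAA": 2, "GGG": 7, "CTA": 1}), code)
    assert res2.scuo == pytest.approx(1.0)


def test_scuo_hand_entropy(code):
    # Phe (3,1): H = -(0.75 ln 0.75 + 0.25 ln 0.25), O = (ln2 - H)/ln2
    res = scuo(CodonCounts("toy", {"TTT": 3, "TTC": 1}), code)
    h = -(0.75 * math.log(0.75) + 0.25 * math.log(0.25))
    assert res.scuo == pytest.approx((math.log(2) - h) / math.log(2))


def test_scuo_is_base_invariant(rng, code):
    """Recompute O_i with log2 instead of ln: the normalized deficit matches."""
    counts = random_counts(rng, code, low=0, high=30)
    res = scuo(counts, code)
    total = 0.0
    weight = 0.0
    for aa, codons in code.families.items():
        if len(codons) < 2:
            continue
        xs = np.array([counts.counts[c] for c in codons], dtype=float)
        if xs.sum() == 0:
            continue
        p = xs[xs > 0] / xs.sum()
        h2 = -np.sum(p * np.log2(p))
        total += xs.sum() * (math.log2(len(codons)) - h2) / math.log2(len(codons))
        weight += xs.sum()
    assert res.scuo == pytest.approx(total / weight, abs=1e-12)


def test_scuo_invariant_to_within_family_scaling(code):
    a = scuo(CodonCounts("a", {"TTT": 3, "TTC": 1, "GGA": 2, "GGC": 2}), code)
    b = scuo(CodonCounts("b", {"TTT": 30, "TTC": 10, "GGA": 2, "GGC": 2}), code)
    assert a.o_by_aa["F"] == pytest.approx(b.o_by_aa["F"], abs=1e-12)


def test_scuo_missing_when_no_multicodon_family(code):
    with pytest.warns(UserWarning):
        res = scuo(CodonCounts("m", {"ATG": 5, "TGG": 2}), code)
    assert math.isnan(res.scuo)


def test_milc_zero_divergence_equals_minus_correction(code):
    gene = CodonCounts("g", {"TTT": 6, "TTC": 2, "GGA": 4, "GGC": 4})
    ref = CodonCounts("ref", {"TTT": 3, "TTC": 1, "GGA": 10, "GGC": 10})
    res = milc(gene, ref, code)
    # family frequencies match the reference exactly -> sum M_a = 0
    assert sum(res.m_by_aa.values()) == pytest.approx(0.0, abs=1e-12)
    # c = ((2-1) + (4-1)) / 16
    assert res.correction == pytest.approx(4 / 16)
    assert res.milc == pytest.approx(-4 / 16)


def test_milc_one_family_hand_value(code):
    gene = CodonCounts("g", {"TTT": 3, "TTC": 1})
    ref = CodonCounts("ref", {"TTT": 1, "TTC": 1})
    res = milc(gene, ref, code)
    m = 2 * (3 * math.log(1.5) + 1 * math.log(0.5))
    assert res.milc == pytest.approx(m / 4 - 1 / 4)
    assert res.L == 4


def test_milc_zero_reference_cell_uses_pseudo_frequency(code):
    gene = CodonCounts("g", {"TTT": 2, "TTC": 2})
    ref = CodonCounts("ref", {"TTT": 10})  # TTC unseen in reference
    res = milc(gene, ref, code)
    assert res.flags == ["pseudo_frequency:F"]
    assert math.isfinite(res.milc)


def test_milc_empty_gene_rejected(code):
    with pytest.raises(ValueError):
        milc(CodonCounts("g", {}), CodonCounts("r", {"TTT": 1}), code)


def test_milc_shrinks_for_reference_sampled_genes(rng, code):
    """Genes drawn from the reference distribution drift toward MILC = 0 as L grows."""
    ref = random_counts(rng, code, low=5, high=60)
    codons = list(code.sense_codons)
    p = np.array([ref.counts[c] for c in codons], dtype=float)
    p /= p.sum()
    mean_abs = {}
    for L in (100, 1000, 10000):
        vals = []
        for s in range(20):
            draw = rng.multinomial(L, p)
            gene = CodonCounts(f"L{L}_{s}", dict(zip(codons, draw)))
            vals.append(milc(gene, ref, code).milc)
        mean_abs[L] = float(np.mean(np.abs(vals)))
    assert mean_abs[10000] < mean_abs[1000] < mean_abs[100]
    assert mean_abs[10000] < 0.02


def test_correlation_perfect_and_oracle(rng):
    scuos = np.linspace(0.1, 0.4, 10)
    r, p = correlate_scuo_milc(scuos, 2.0 * scuos + 0.05)
    assert r == pytest.approx(1.0)
    x = rng.uniform(0, 1, 30)
    y = 0.4 * x + rng.normal(0, 0.1, 30)
    r, p = correlate_scuo_milc(x, y)
    cov = np.cov(x, y, ddof=1)[0, 1]
    oracle = cov / (np.std(x, ddof=1) * np.std(y, ddof=1))
    assert r == pytest.approx(oracle, abs=1e-12)
    # affine invariance and symmetry
    r2, _ = correlate_scuo_milc(3 * x + 1, y)
    r3, _ = correlate_scuo_milc(y, x)
    assert r2 == pytest.approx(r, abs=1e-12)
    assert r3 == pytest.approx(r, abs=1e-12)


def test_correlation_degenerate_inputs():
    with pytest.raises(ValueError):
        correlate_scuo_milc([0.1, 0.2], [0.3, 0.4])
    with pytest.warns(UserWarning):
        r, p = correlate_scuo_milc([0.2, 0.2, 0.2], [0.1, 0.5, 0.9])
    assert math.isnan(r)
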