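"""ENc (observed and expected), PR2 coordinates and the neutrality fit."""

import math

import numpy as np
import pytest

from cubkit import (
    CodonCounts,
    SimulationConfig,
    enc_expected,
    enc_observed,
    generate_cds_set,
    neutrality_fit,
    positional_gc,
    pr2_point,
)
from cubkit.composition import PositionalComposition

from conftest import uniform_usage_counts


def test_enc_expected_reference_points():
    assert enc_expected(0.5) == pytest.approx(60.5)
    assert enc_expected(0.0) == pytest.approx(31.0)
    assert enc_expected(1.0) == pytest.approx(32.0)


def test_enc_expected_symmetry_identity():
    # f(S) - f(1-S) = 2S - 1 exactly (the rational term is symmetric)
    s = np.linspace(0, 1, 101)
    np.testing.assert_allclose(enc_expected(s) - enc_expected(1 - s), 2 * s - 1,
                               atol=1e-12)


def test_enc_expected_maximized_near_half():
    # the linear +S term shifts the true maximum marginally right of 0.5
    s = np.linspace(0, 1, 2001)
    vals = enc_expected(s)
    assert s[np.argmax(vals)] == pytest.approx(0.5, abs=5e-3)
    assert vals.max() == pytest.approx(60.5, abs=0.01)


def test_enc_expected_rejects_out_of_range():
    with pytest.raises(ValueError):
        enc_expected(1.2)


def test_enc_uniform_large_counts_near_61(code):
    res = enc_observed(uniform_usage_counts(code, per_codon=170), code)  # ~10^4 codons
    assert res.enc == pytest.approx(61.0, abs=0.5)
    assert res.n_missing_classes == 0


def test_enc_single_codon_families_hand_value(code):
    # three 2-fold families, one codon each: every F-hat = 1, all classes
    # fall back to F-bar = 1, so ENc = 2 + 9 + 1 + 5 + 3 = 20
    counts = CodonCounts("toy", {"TTT": 10, "CAT": 10, "AAA": 10})
    res = enc_observed(counts, code)
    assert res.enc == pytest.approx(20.0)
    assert res.f_bar_by_class == pytest.approx({2: 1.0, 3: 1.0, 4: 1.0, 6: 1.0})
    assert res.n_missing_classes == 3


def test_enc_clamped_into_range(rng, code):
    for _ in range(20):
        counts = CodonCounts(
            "r", {c: int(rng.integers(0, 6)) for c in code.sense_codons})
        res = enc_observed(counts, code)
        if not math.isnan(res.enc):
            assert 2.0 <= res.enc <= 61.0


def test_enc_decreases_with_bias_strength(code):
    """Stronger within-family tilt must lower ENc in expectation (paired seeds)."""
    deltas = []
    for seed in range(20):
        encs = {}
        for theta in (0.0, 1.5):
            cfg = SimulationConfig(n_genes=1, length_range=(400, 400),
                                   bias_theta=theta, gc3_targets=None, seed=seed)
            (recs, _) = generate_cds_set(cfg)
            from cubkit import count_codons
            encs[theta] = enc_observed(count_codons(recs[0], code=code), code).enc
        deltas.append(encs[0.0] - encs[1.5])
    assert np.mean(deltas) > 0
    assert sum(d > 0 for d in deltas) >= 17  # near-uniformly across seeds


def test_pr2_center_and_hand_values(code):
    # Ala third positions equal: (0.5, 0.5)
    even = CodonCounts("c", {"GCA": 1, "GCC": 1, "GCG": 1, "GCT": 1})
    pt = pr2_point(even, code)
    assert (pt.x, pt.y) == (0.5, 0.5)
    # tallies A3=1, T3=3, G3=3, C3=1 -> (0.75, 0.25)
    skew = CodonCounts("s", {"GCA": 1, "GCT": 3, "GCG": 3, "GCC": 1})
    pt = pr2_point(skew, code)
    assert pt.x == pytest.approx(0.75)
    assert pt.y == pytest.approx(0.25)


def test_pr2_fourfold_mode_ignores_other_families(code):
    counts = CodonCounts("g", {"GCA": 2, "GCT": 2, "TTT": 50, "AAA": 50})
    four = pr2_point(counts, code, family_mode="fourfold")
    assert four.y == pytest.approx(0.5)  # Phe/Lys codons excluded
    allpt = pr2_point(counts, code, family_mode="all")
    assert allpt.y == pytest.approx(52 / 104)


def test_pr2_zero_denominator_is_missing(code):
    counts = CodonCounts("g", {"GCA": 3, "GCT": 1})  # no G3/C3 in 4-fold codons
    pt = pr2_point(counts, code)
    assert math.isnan(pt.x)
    assert pt.y == pytest.approx(0.75)


def _comp(gc12, gc3):
    return PositionalComposition(gc1=gc12, gc2=gc12, gc3=gc3, gc=(2 * gc12 + gc3) / 3,
                                 gc12=gc12, gc3s=gc3, t3s=0.25, c3s=0.25,
                                 a3s=0.25, g3s=0.25, n_codons=100)


def test_neutrality_perfect_line():
    genes = [_comp(0.4 * x + 0.2, x) for x in np.linspace(0.1, 0.6, 12)]
    fit = neutrality_fit(genes)
    assert fit.slope == pytest.approx(0.4, abs=1e-12)
    assert fit.intercept == pytest.approx(0.2, abs=1e-12)
    assert fit.pearson_r == pytest.approx(1.0)
    assert fit.n_genes == 12


def test_neutrality_matches_closed_form_ols(rng):
    x = rng.uniform(0.1, 0.6, size=40)
    y = 0.25 * x + 0.3 + rng.normal(0, 0.02, size=40)
    fit = neutrality_fit([_comp(yi, xi) for xi, yi in zip(x, y)])
    slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
    intercept = y.mean() - slope * x.mean()
    assert fit.slope == pytest.approx(slope, abs=1e-12)
    assert fit.intercept == pytest.approx(intercept, abs=1e-12)
    r = np.corrcoef(x, y)[0, 1]
    assert fit.pearson_r == pytest.approx(r, abs=1e-12)
    assert abs(fit.pearson_r) <= 1
    assert np.sign(fit.slope) == np.sign(fit.pearson_r)


def test_neutrality_requires_variance_and_enough_genes():
    with pytest.raises(ValueError):
        neutrality_fit([_comp(0.4, 0.3)] * 2)
    with pytest.warns(UserWarning):
        fit = neutrality_fit([_comp(v, 0.3) for v in (0.35, 0.4, 0.45)])
    assert math.isnan(fit.slope)
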