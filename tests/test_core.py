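"""Unit and property tests for the closed-form population quantities."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crossld.core import (
    HAP_DOSE_M,
    HAP_DOSE_N,
    AlleleFreqPair,
    InfeasibleLDError,
    LineHapFreqs,
    MonomorphicLocusError,
    crossbred_allele_freq,
    crossbred_genotype_freqs,
    crossbred_r2_from_moments,
    crossbred_true_ld,
    d_bounds,
    dosage_moments,
    hap_freqs_from_params,
    inbreeding_coefficient,
    inbreeding_coefficient_printed,
    line_ld,
)
from conftest import random_hap_freqs

# ---------------------------------------------------------------------------
# independent oracles


def brute_force_moments(hA, hB):
    """Dosage moments by enumeration over the 16-cell pair distribution."""
    out = dict(E_Mg=0.0, E_Ng=0.0, E_Mg2=0.0, E_Ng2=0.0, E_MgNg=0.0)
    for i, j in itertools.product(range(4), repeat=2):
        p = hA.as_array()[i] * hB.as_array()[j]
        mg = HAP_DOSE_M[i] + HAP_DOSE_M[j]
        ng = HAP_DOSE_N[i] + HAP_DOSE_N[j]
        out["E_Mg"] += p * mg
        out["E_Ng"] += p * ng
        out["E_Mg2"] += p * mg * mg
        out["E_Ng2"] += p * ng * ng
        out["E_MgNg"] += p * mg * ng
    return out


def brute_force_dosage_r2(hA, hB):
    """Exact dosage correlation squared from the joint pair distribution."""
    m = brute_force_moments(hA, hB)
    var_m = m["E_Mg2"] - m["E_Mg"] ** 2
    var_n = m["E_Ng2"] - m["E_Ng"] ** 2
    cov = m["E_MgNg"] - m["E_Mg"] * m["E_Ng"]
    return cov**2 / (var_m * var_n)


# ---------------------------------------------------------------------------
# crossbred allele frequency and inbreeding


def test_crossbred_allele_freq_example():
    assert crossbred_allele_freq(AlleleFreqPair(0.05, 0.09)) == pytest.approx(0.07)


@pytest.mark.parametrize("p", [0.0, 0.3, 1.0])
def test_crossbred_allele_freq_identical_lines(p):
    assert crossbred_allele_freq(AlleleFreqPair(p, p)) == p


def test_crossbred_allele_freq_boundary():
    assert crossbred_allele_freq(AlleleFreqPair(0.0, 1.0)) == 0.5


def test_inbreeding_zero_when_equal():
    assert inbreeding_coefficient(AlleleFreqPair(0.3, 0.3)) == 0.0


@pytest.mark.parametrize(
    "pA,pB",
    [(0.05, 0.09), (0.25, 0.29)],
)
def test_inbreeding_defining_relation_oracle(pA, pB):
    # oracle: f solves pA*pB = p^2 + p(1-p) f directly
    p = (pA + pB) / 2
    expected = (pA * pB - p * p) / (p * (1 - p))
    assert inbreeding_coefficient(AlleleFreqPair(pA, pB)) == pytest.approx(
        expected, abs=1e-15
    )


def test_inbreeding_derived_values():
    # frozen values hand-computed from the defining relation
    assert inbreeding_coefficient(AlleleFreqPair(0.05, 0.09)) == pytest.approx(
        -0.006144393, abs=1e-9
    )
    assert inbreeding_coefficient(AlleleFreqPair(0.25, 0.29)) == pytest.approx(
        -0.002029427, abs=1e-9
    )


def test_inbreeding_monomorphic_error():
    with pytest.raises(MonomorphicLocusError):
        inbreeding_coefficient(AlleleFreqPair(0.0, 0.0))
    with pytest.raises(MonomorphicLocusError):
        inbreeding_coefficient(AlleleFreqPair(1.0, 1.0))


def test_inbreeding_sign_property(rng):
    for _ in range(500):
        pA, pB = rng.uniform(0.01, 0.99, size=2)
        f = inbreeding_coefficient(AlleleFreqPair(pA, pB))
        assert f <= 0.0
        assert (f == 0.0) == (pA == pB)


def test_printed_variant_reproduces_published_rounding():
    fM = inbreeding_coefficient_printed(AlleleFreqPair(0.05, 0.09))
    fN = inbreeding_coefficient_printed(AlleleFreqPair(0.25, 0.29))
    assert f"{fM:.2g}" == "-0.0056"
    assert f"{fN:.2g}" == "-0.0015"
    assert inbreeding_coefficient_printed(AlleleFreqPair(0.3, 0.3)) == 0.0


def test_printed_variant_differs_from_derivation_form():
    pair = AlleleFreqPair(0.05, 0.09)
    assert inbreeding_coefficient_printed(pair) != pytest.approx(
        inbreeding_coefficient(pair), abs=1e-6
    )


def test_f_equality_only_in_degenerate_configs(rng):
    # random continuous frequency quadruples should never give f_M == f_N
    # unless the loci have equal line-frequency pairs (a measure-zero event
    # otherwise)
    hits = 0
    for _ in range(2000):
        pAM, pBM, pAN, pBN = rng.uniform(0.01, 0.99, size=4)
        fM = inbreeding_coefficient(AlleleFreqPair(pAM, pBM))
        fN = inbreeding_coefficient(AlleleFreqPair(pAN, pBN))
        if abs(fM - fN) < 1e-12:
            hits += 1
    assert hits == 0
    # trivial equality when both loci share the line frequencies
    assert inbreeding_coefficient(
        AlleleFreqPair(0.2, 0.4)
    ) == inbreeding_coefficient(AlleleFreqPair(0.2, 0.4))


# ---------------------------------------------------------------------------
# D bounds and haplotype construction


@pytest.mark.parametrize(
    "pM,pN,expected",
    [
        (0.5, 0.5, (-0.25, 0.25)),
        (0.05, 0.05, (-0.0025, 0.0475)),
        (0.45, 0.45, (-0.2025, 0.2475)),
    ],
)
def test_d_bounds_examples(pM, pN, expected):
    dmin, dmax = d_bounds(pM, pN)
    assert dmin == pytest.approx(expected[0], abs=1e-15)
    assert dmax == pytest.approx(expected[1], abs=1e-15)
    assert dmin <= 0.0 <= dmax


def test_d_bounds_monomorphic():
    with pytest.raises(MonomorphicLocusError):
        d_bounds(0.0, 0.5)


def test_hap_freqs_perfect_coupling():
    h = hap_freqs_from_params(0.5, 0.5, 1.0, "+")
    assert h.as_array() == pytest.approx([0.5, 0.0, 0.0, 0.5], abs=1e-15)


def test_hap_freqs_equilibrium():
    h = hap_freqs_from_params(0.5, 0.5, 0.0, "+")
    assert h.as_array() == pytest.approx([0.25] * 4, abs=1e-15)


def test_hap_freqs_derived_f11():
    h = hap_freqs_from_params(0.45, 0.45, 0.2, "+")
    assert h.f11 == pytest.approx(0.2025 + math.sqrt(0.2) * 0.2475, abs=1e-12)


def test_hap_freqs_infeasible_names_maximum():
    with pytest.raises(InfeasibleLDError) as excinfo:
        hap_freqs_from_params(0.05, 0.45, 0.8, "+")
    max_r2 = excinfo.value.max_r2
    assert 0.0 < max_r2 < 0.8
    # just-feasible value constructs fine
    hap_freqs_from_params(0.05, 0.45, max_r2 * 0.999, "+")


def test_hap_freqs_round_trip(rng):
    for _ in range(300):
        pM, pN = rng.uniform(0.05, 0.95, size=2)
        sign = rng.choice([1, -1])
        dmin, dmax = d_bounds(pM, pN)
        limit = dmax if sign > 0 else -dmin
        max_r2 = limit**2 / (pM * (1 - pM) * pN * (1 - pN))
        r2 = rng.uniform(0, max_r2)
        h = hap_freqs_from_params(pM, pN, r2, sign)
        ld = line_ld(h)
        assert h.pM == pytest.approx(pM, abs=1e-12)
        assert h.pN == pytest.approx(pN, abs=1e-12)
        assert ld.r2 == pytest.approx(r2, abs=1e-12)
        if r2 > 0:
            assert math.copysign(1, ld.D) == sign


# ---------------------------------------------------------------------------
# within-line and crossbred LD


def test_line_ld_equilibrium():
    ld = line_ld(LineHapFreqs(0.25, 0.25, 0.25, 0.25))
    assert (ld.D, ld.r2, ld.Dprime) == (0.0, 0.0, 0.0)


def test_line_ld_perfect():
    ld = line_ld(LineHapFreqs(0.5, 0.0, 0.0, 0.5))
    assert ld.D == pytest.approx(0.25)
    assert ld.r2 == pytest.approx(1.0)
    assert ld.Dprime == pytest.approx(1.0)


def test_line_ld_hand_example():
    ld = line_ld(LineHapFreqs(0.4, 0.1, 0.1, 0.4))
    assert ld.D == pytest.approx(0.15, abs=1e-15)
    assert ld.r2 == pytest.approx(0.36, abs=1e-12)


def test_line_ld_monomorphic_flag():
    ld = line_ld(LineHapFreqs(0.5, 0.5, 0.0, 0.0))  # locus M fixed at 0
    assert not ld.defined


def test_line_ld_invariants(rng):
    for _ in range(300):
        ld = line_ld(random_hap_freqs(rng))
        assert 0.0 <= ld.r2 <= 1.0 + 1e-12
        assert abs(ld.Dprime) <= 1.0 + 1e-12
        assert (ld.r2 == 0.0) == (ld.D == 0.0)


def test_crossbred_identical_lines_reduces_to_line_ld(rng):
    for _ in range(50):
        h = random_hap_freqs(rng)
        a = line_ld(h)
        b = crossbred_true_ld(h, h)
        assert b.r2 == pytest.approx(a.r2, abs=1e-12)
        assert b.D == pytest.approx(a.D, abs=1e-15)


def test_crossbred_covariances_cancel():
    hA = LineHapFreqs(0.4, 0.1, 0.1, 0.4)  # D = +0.15
    hB = LineHapFreqs(0.1, 0.4, 0.4, 0.1)  # D = -0.15, same variances
    ld = crossbred_true_ld(hA, hB)
    assert ld.r2 == pytest.approx(0.0, abs=1e-15)
    assert ld.D == pytest.approx(0.0, abs=1e-15)


def test_crossbred_vs_exact_dosage_correlation_oracle():
    hA = hap_freqs_from_params(0.05, 0.05, 0.2, "+")
    hB = hap_freqs_from_params(0.45, 0.45, 0.2, "+")
    expected = brute_force_dosage_r2(hA, hB)
    assert crossbred_true_ld(hA, hB).r2 == pytest.approx(expected, abs=1e-14)
    m = dosage_moments(hA, hB)
    assert crossbred_r2_from_moments(m).r2 == pytest.approx(expected, abs=1e-14)


def test_crossbred_undefined_when_both_lines_fixed():
    hA = LineHapFreqs(1.0, 0.0, 0.0, 0.0)
    assert not crossbred_true_ld(hA, hA).defined


# ---------------------------------------------------------------------------
# genotype-frequency table and dosage moments


def test_genotype_freqs_uniform():
    h = LineHapFreqs(0.25, 0.25, 0.25, 0.25)
    table = crossbred_genotype_freqs(h, h)
    assert table == pytest.approx(np.full((4, 4), 0.0625))


def test_genotype_freqs_cell_is_product(rng):
    hA, hB = random_hap_freqs(rng), random_hap_freqs(rng)
    table = crossbred_genotype_freqs(hA, hB)
    # cell (11, 00) = f11(A) * f00(B)
    assert table[3, 0] == pytest.approx(hA.f11 * hB.f00, abs=1e-15)


def test_genotype_freqs_is_distribution_with_correct_margins(rng):
    for _ in range(100):
        hA, hB = random_hap_freqs(rng), random_hap_freqs(rng)
        table = crossbred_genotype_freqs(hA, hB)
        assert np.all(table >= 0)
        assert table.sum() == pytest.approx(1.0, abs=1e-12)
        assert table.sum(axis=1) == pytest.approx(hA.as_array(), abs=1e-12)
        assert table.sum(axis=0) == pytest.approx(hB.as_array(), abs=1e-12)


def test_dosage_moments_perfect_ld_example():
    h = LineHapFreqs(0.5, 0.0, 0.0, 0.5)
    m = dosage_moments(h, h)
    assert m.E_Mg == pytest.approx(1.0)
    assert m.E_Mg2 == pytest.approx(1.5)
    assert m.E_MgNg == pytest.approx(1.5)
    # cross-check against the enumeration oracle
    bf = brute_force_moments(h, h)
    assert m.E_MgNg == pytest.approx(bf["E_MgNg"], abs=1e-14)


def test_dosage_moments_linearity(rng):
    hA, hB = random_hap_freqs(rng), random_hap_freqs(rng)
    m = dosage_moments(hA, hB)
    assert m.E_Mg == pytest.approx(hA.pM + hB.pM, abs=1e-14)
    assert m.E_Ng == pytest.approx(hA.pN + hB.pN, abs=1e-14)


def test_dosage_moments_equilibrium_independence():
    h = LineHapFreqs(0.25, 0.25, 0.25, 0.25)
    m = dosage_moments(h, h)
    assert m.E_MgNg == pytest.approx(1.0, abs=1e-15)
    assert m.E_MgNg == pytest.approx(m.E_Mg * m.E_Ng, abs=1e-15)


def test_dosage_moments_match_brute_force(random_hap_pairs):
    for hA, hB in random_hap_pairs(200, seed=5):
        m = dosage_moments(hA, hB)
        bf = brute_force_moments(hA, hB)
        for name in bf:
            assert getattr(m, name) == pytest.approx(bf[name], abs=1e-14)
        assert m.var_M >= -1e-14
        assert m.var_N >= -1e-14


# ---------------------------------------------------------------------------
# the central equivalence


def test_equivalence_theorem_random_pairs(random_hap_pairs):
    for hA, hB in random_hap_pairs(1000, seed=99):
        via_hap = crossbred_true_ld(hA, hB)
        via_geno = crossbred_r2_from_moments(dosage_moments(hA, hB))
        if not via_hap.defined:
            assert not via_geno.defined
            continue
        assert via_geno.r2 == pytest.approx(via_hap.r2, abs=1e-12)
        # D from the two routes is identical too (shared numerator)
        assert via_geno.D == pytest.approx(via_hap.D, abs=1e-12)
        assert via_geno.Dprime == pytest.approx(via_hap.Dprime, abs=1e-12)


@settings(max_examples=200, deadline=None)
@given(
    raw=st.lists(st.floats(0.001, 1.0), min_size=8, max_size=8),
)
def test_equivalence_theorem_hypothesis(raw):
    a = np.array(raw[:4]) / sum(raw[:4])
    b = np.array(raw[4:]) / sum(raw[4:])
    hA, hB = LineHapFreqs(*a), LineHapFreqs(*b)
    via_hap = crossbred_true_ld(hA, hB)
    via_geno = crossbred_r2_from_moments(dosage_moments(hA, hB))
    assert via_hap.defined == via_geno.defined
    if via_hap.defined:
        assert via_geno.r2 == pytest.approx(via_hap.r2, abs=1e-12)
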