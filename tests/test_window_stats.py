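"""Diversity/differentiation statistics against brute-force oracles.

The oracles are independent of the implementation: pi via exhaustive
pairwise allele comparison, Tajima's D via a from-scratch evaluation of the
published constant formulas, and F_ST via a literal transcription of the
Weir-Cockerham component algebra evaluated site by site.
"""

import itertools

import numpy as np
import pytest

from campina import (
    GenotypeMatrix,
    PopulationMap,
    TajimaConstants,
    ValidationError,
    dxy_window,
    pi_window,
    tajimas_d,
    weir_cockerham_fst,
    windowed_scan,
)
from conftest import make_site


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------


def brute_pi(allele_lists, denominator):
    """Mean pairwise difference over all allele pairs, summed over sites."""
    total = 0.0
    for alleles in allele_lists:
        pairs = list(itertools.combinations(alleles, 2))
        total += sum(a != b for a, b in pairs) / len(pairs)
    return total / denominator


def brute_wc_site(g1, g2):
    """Direct Weir-Cockerham (1984) a, b, c for one site, two populations
    of diploids given as dosage lists (no missing data)."""
    r = 2
    n = [len(g1), len(g2)]
    p = [sum(g1) / (2 * n[0]), sum(g2) / (2 * n[1])]
    h = [sum(1 for g in g1 if g == 1) / n[0], sum(1 for g in g2 if g == 1) / n[1]]
    nbar = sum(n) / r
    nc = (r * nbar - sum(x * x for x in n) / (r * nbar)) / (r - 1)
    pbar = sum(n[i] * p[i] for i in range(r)) / (r * nbar)
    s2 = sum(n[i] * (p[i] - pbar) ** 2 for i in range(r)) / ((r - 1) * nbar)
    hbar = sum(n[i] * h[i] for i in range(r)) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    return a, b, c


def genotypes_to_alleles(dosages):
    """Diploid dosages -> list of 0/1 allele copies (missing dropped)."""
    out = []
    for d in dosages:
        if d >= 0:
            out.extend([1] * d + [0] * (2 - d))
    return out


def two_pop_matrix(sites_a, sites_b, positions=None):
    """Build matrix + popmap from parallel per-site dosage lists."""
    nA, nB = len(sites_a[0]), len(sites_b[0])
    samples = [f"a{i}" for i in range(nA)] + [f"b{i}" for i in range(nB)]
    positions = positions or [10 * (i + 1) for i in range(len(sites_a))]
    sites = [
        make_site("chr1", pos, list(ga) + list(gb))
        for pos, ga, gb in zip(positions, sites_a, sites_b)
    ]
    matrix = GenotypeMatrix(samples=samples, sites=sites)
    popmap = PopulationMap(
        assignment={s: ("A" if s.startswith("a") else "B") for s in samples}
    )
    return matrix, popmap


class TestPi:
    def test_monomorphic_window_is_zero(self, toy_popmap):
        assert (
            pi_window([], "A", toy_popmap, 10000, ["a1", "a2", "a3", "b1", "b2", "b3"])
            == 0.0
        )

    def test_single_site_n4_k2(self):
        matrix, popmap = two_pop_matrix([[1, 1]], [[0, 0]])
        got = pi_window(matrix.sites, "A", popmap, 10, matrix.samples)
        assert got == pytest.approx((2 * 2 * 2) / (4 * 3) / 10, abs=1e-12)
        # brute-force over the 6 allele pairs
        oracle = brute_pi([genotypes_to_alleles([1, 1])], 10)
        assert got == pytest.approx(oracle, abs=1e-12)

    def test_two_singleton_sites(self):
        matrix, popmap = two_pop_matrix([[1, 0], [0, 1]], [[0, 0], [0, 0]])
        got = pi_window(matrix.sites, "A", popmap, 100, matrix.samples)
        assert got == pytest.approx(0.01, abs=1e-12)

    def test_random_matrix_matches_pairwise_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n_sites = int(rng.integers(1, 8))
            dosA = rng.integers(0, 3, size=(n_sites, 4)).tolist()
            matrix, popmap = two_pop_matrix(dosA, [[0, 0]] * n_sites)
            got = pi_window(matrix.sites, "A", popmap, 50, matrix.samples)
            oracle = brute_pi([genotypes_to_alleles(d) for d in dosA], 50)
            assert got == pytest.approx(oracle, abs=1e-12)


class TestTajimasD:
    def test_no_segregating_sites_undefined(self):
        matrix, popmap = two_pop_matrix([[2, 2, 2]], [[0, 0, 0]])
        assert tajimas_d(matrix.sites, "A", popmap, matrix.samples) is None

    def test_constants_against_independent_formulas(self):
        # recompute every constant from its published definition
        for n in (4, 10, 24):
            c = TajimaConstants.for_n(n)
            a1 = sum(1 / i for i in range(1, n))
            a2 = sum(1 / i**2 for i in range(1, n))
            b1 = (n + 1) / (3 * (n - 1))
            b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
            c1 = b1 - 1 / a1
            c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
            assert c.a1 == pytest.approx(a1, rel=1e-14)
            assert c.a2 == pytest.approx(a2, rel=1e-14)
            assert c.e1 == pytest.approx(c1 / a1, rel=1e-14)
            assert c.e2 == pytest.approx(c2 / (a1**2 + a2), rel=1e-14)
        assert TajimaConstants.for_n(10).a1 == pytest.approx(2.828968, abs=1e-6)

    def test_value_matches_independent_evaluation(self):
        rng = np.random.default_rng(3)
        dosA = rng.integers(0, 3, size=(5, 5)).tolist()
        matrix, popmap = two_pop_matrix(dosA, [[0, 0]] * 5)
        got = tajimas_d(matrix.sites, "A", popmap, matrix.samples)
        n = 10
        ks = [sum(d) for d in dosA]
        seg = [k for k in ks if 0 < k < n]
        S = len(seg)
        pi_sum = sum(2 * k * (n - k) / (n * (n - 1)) for k in seg)
        a1 = sum(1 / i for i in range(1, n))
        c = TajimaConstants.for_n(n)
        expected = (pi_sum - S / a1) / np.sqrt(c.e1 * S + c.e2 * S * (S - 1))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_sites_with_missing_genotypes_excluded(self):
        # one fully-called segregating site + one site with a missing call
        matrix, popmap = two_pop_matrix(
            [[1, 0, 1], [-1, 1, 1]], [[0, 0, 0], [0, 0, 0]]
        )
        got = tajimas_d(matrix.sites, "A", popmap, matrix.samples)
        only_full, popmap2 = two_pop_matrix([[1, 0, 1]], [[0, 0, 0]])
        expected = tajimas_d(only_full.sites, "A", popmap2, only_full.samples)
        assert got == pytest.approx(expected, abs=1e-12)


class TestWeirCockerhamFst:
    def test_fixed_difference_is_one(self):
        matrix, popmap = two_pop_matrix([[2, 2]], [[0, 0]])
        *_, fst = weir_cockerham_fst(matrix.sites, "A", "B", popmap, matrix.samples)
        assert fst == pytest.approx(1.0, abs=1e-12)

    def test_identical_populations_nonpositive(self):
        matrix, popmap = two_pop_matrix(
            [[1, 0, 2], [0, 1, 1]], [[1, 0, 2], [0, 1, 1]]
        )
        *_, fst = weir_cockerham_fst(matrix.sites, "A", "B", popmap, matrix.samples)
        assert fst is not None and fst <= 0.0

    def test_components_match_direct_evaluation(self):
        rng = np.random.default_rng(11)
        dosA = rng.integers(0, 3, size=(5, 3)).tolist()
        dosB = rng.integers(0, 3, size=(5, 3)).tolist()
        matrix, popmap = two_pop_matrix(dosA, dosB)
        a, b, c, fst = weir_cockerham_fst(
            matrix.sites, "A", "B", popmap, matrix.samples
        )
        oa, ob, oc = zip(*(brute_wc_site(ga, gb) for ga, gb in zip(dosA, dosB)))
        np.testing.assert_allclose(a, oa, atol=1e-12)
        np.testing.assert_allclose(b, ob, atol=1e-12)
        np.testing.assert_allclose(c, oc, atol=1e-12)
        assert fst == pytest.approx(sum(oa) / (sum(oa) + sum(ob) + sum(oc)), abs=1e-12)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(5)
        dosA = rng.integers(0, 3, size=(6, 3)).tolist()
        dosB = rng.integers(0, 3, size=(6, 3)).tolist()
        matrix, popmap = two_pop_matrix(dosA, dosB)
        *_, f1 = weir_cockerham_fst(matrix.sites, "A", "B", popmap, matrix.samples)
        *_, f2 = weir_cockerham_fst(matrix.sites, "B", "A", popmap, matrix.samples)
        assert f1 == pytest.approx(f2, abs=1e-12)
        assert f1 <= 1.0

    def test_same_population_rejected(self, toy_matrix, toy_popmap):
        with pytest.raises(ValidationError):
            weir_cockerham_fst(toy_matrix.sites, "A", "A", toy_popmap, toy_matrix.samples)


class TestDxy:
    def test_fixed_difference(self):
        matrix, popmap = two_pop_matrix([[2, 2]], [[0, 0]])
        assert dxy_window(matrix.sites, "A", "B", popmap, 1, matrix.samples) == 1.0

    def test_identical_monomorphic_zero(self):
        matrix, popmap = two_pop_matrix([[0, 0]], [[0, 0]])
        assert dxy_window(matrix.sites, "A", "B", popmap, 10, matrix.samples) == 0.0

    def test_half_half(self):
        matrix, popmap = two_pop_matrix([[1, 1]], [[1, 1]])
        got = dxy_window(matrix.sites, "A", "B", popmap, 10, matrix.samples)
        assert got == pytest.approx(0.05, abs=1e-12)

    def test_self_comparison_rejected(self, toy_matrix, toy_popmap):
        with pytest.raises(ValidationError):
            dxy_window(toy_matrix.sites, "A", "A", toy_popmap, 10, toy_matrix.samples)


class TestWindowedScan:
    def test_composition_matches_components(self, toy_matrix, toy_popmap):
        df = windowed_scan(
            toy_matrix, toy_popmap, 1000, ["A", "B"], [("A", "B")]
        )
        assert len(df) == 3  # sites span 100..2100
        row = df.iloc[0]
        win_sites = [s for s in toy_matrix.sites if s.pos <= 1000]
        assert row["pi_A"] == pytest.approx(
            pi_window(win_sites, "A", toy_popmap, 1000, toy_matrix.samples)
        )
        *_, fst = weir_cockerham_fst(
            win_sites, "A", "B", toy_popmap, toy_matrix.samples
        )
        assert row["fst_A_B"] == pytest.approx(fst)
        assert list(df["start"]) == sorted(df["start"])

    def test_empty_matrix(self, toy_popmap):
        m = GenotypeMatrix(samples=["a1", "b1"], sites=[])
        df = windowed_scan(m, toy_popmap, 1000, ["A"])
        assert df.empty
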