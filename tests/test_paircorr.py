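import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pepcoord import (
    build_histogram,
    coordination,
    coordination_delta,
    cumulative_coordination,
    cumulative_profile,
    first_shell_peak,
    make_chain,
    make_ideal_gas,
    make_variant,
    pdf_from_histogram,
    rdf_from_pdf,
    SyntheticSpec,
)
from pepcoord.errors import (
    DuplicateAtomError,
    EmptySelectionError,
    GridMismatchError,
)
from pepcoord.paircorr import PairHistogram, canonical_selector, parse_selector

from conftest import pair_structure, random_structure


def brute_force_cumulative(s, r_edges_upper):
    """Independent oracle: n(0, r) = 2 * #(pairs with distance < r) / N."""
    from scipy.spatial.distance import pdist

    d = pdist(s.coords)
    return np.array([2.0 * np.sum(d < r) / s.n_atoms for r in r_edges_upper])


class TestSelectors:
    def test_parse(self):
        assert parse_selector("total") is None
        assert parse_selector("N-C") == ("C", "N")
        assert canonical_selector("n-c") == "C-N"
        with pytest.raises(ValueError):
            parse_selector("C/N")


class TestHistogram:
    def test_single_pair_bin(self):
        s = pair_structure(1.5)
        h = build_histogram(s, "total", 0.1)
        assert h.counts.sum() == 1
        assert h.counts[15] == 1  # bin [1.5, 1.6)

    def test_half_open_convention(self):
        # a distance exactly on a bin edge belongs to the upper bin
        s = pair_structure(1.2)
        h = build_histogram(s, "total", 0.1, r_max=2.0)
        assert h.counts[12] == 1
        assert h.counts[11] == 0

    def test_pair_count_50_atoms(self, rng):
        s = random_structure(rng, 50)
        h = build_histogram(s, "total", 0.1)
        assert h.counts.sum() == 50 * 49 // 2

    def test_too_few_atoms(self):
        s = random_structure(np.random.default_rng(0), 5, elements=("C",))
        with pytest.raises(EmptySelectionError):
            build_histogram(s, "N-N")

    def test_duplicate_atoms_named(self):
        s = random_structure(np.random.default_rng(0), 3)
        s.coords[1] = s.coords[0]
        with pytest.raises(DuplicateAtomError, match="res"):
            build_histogram(s)

    def test_partials_sum_to_total(self, chain9):
        total = build_histogram(chain9, "total", 0.1, r_max=25.0)
        partials = np.zeros_like(total.counts)
        species = sorted(set(chain9.elements))
        for i, a in enumerate(species):
            for b in species[i:]:
                try:
                    h = build_histogram(chain9, f"{a}-{b}", 0.1, r_max=25.0)
                except EmptySelectionError:
                    continue
                partials = partials + h.counts
        np.testing.assert_array_equal(partials, total.counts)


class TestPdfRdf:
    def test_empty_bin_gives_zero(self, chain9):
        h = build_histogram(chain9, "total", 0.1, r_max=25.0)
        g = pdf_from_histogram(h)
        empty = h.counts == 0
        assert np.all(g.values[empty] == 0.0)
        assert np.all(g.values >= 0.0)

    def test_partial_pdfs_sum_to_total(self, chain9):
        total = pdf_from_histogram(build_histogram(chain9, "total", 0.1, r_max=25.0))
        acc = np.zeros_like(total.values)
        species = sorted(set(chain9.elements))
        for i, a in enumerate(species):
            for b in species[i:]:
                try:
                    h = build_histogram(chain9, f"{a}-{b}", 0.1, r_max=25.0)
                except EmptySelectionError:
                    continue
                acc = acc + pdf_from_histogram(h).values
        np.testing.assert_allclose(acc, total.values, rtol=1e-9)

    def test_rdf_closed_form(self, chain9):
        # R * dr == 2 * counts / N, exactly cancelling the r^2 prefactors
        h = build_histogram(chain9, "total", 0.1, r_max=25.0)
        rdf = rdf_from_pdf(pdf_from_histogram(h))
        np.testing.assert_allclose(
            rdf.values * h.bin_size, 2.0 * h.counts / h.n_atoms, rtol=1e-9
        )

    def test_rdf_requires_pdf(self, chain9):
        h = build_histogram(chain9)
        rdf = rdf_from_pdf(pdf_from_histogram(h))
        with pytest.raises(ValueError):
            rdf_from_pdf(rdf)

    def test_ideal_gas_g_near_one(self):
        means = []
        for seed in range(10):
            gas = make_ideal_gas(5000, 40.0, seed=seed)
            g = pdf_from_histogram(build_histogram(gas, "total", 0.1, r_max=3.0))
            means.append(g.values[g.r_grid > 1.0].mean())
        assert 0.9 <= np.mean(means) <= 1.1


class TestCoordination:
    def test_full_range_is_n_minus_1(self, chain9):
        prof = cumulative_coordination(chain9)
        assert prof.n_cum[-1] == pytest.approx(chain9.n_atoms - 1, rel=1e-12)

    def test_two_atoms_window(self):
        s = pair_structure(2.35)
        rdf = rdf_from_pdf(pdf_from_histogram(build_histogram(s, "total", 0.1, r_max=5.0)))
        assert coordination(rdf, 2.0, 3.0) == pytest.approx(1.0)
        assert coordination(rdf, 0.0, 2.0) == 0.0
        assert coordination(rdf, 3.0, 5.0) == 0.0

    def test_window_outside_grid(self, chain9):
        rdf = rdf_from_pdf(pdf_from_histogram(build_histogram(chain9, "total", 0.1, r_max=5.0)))
        with pytest.raises(ValueError):
            coordination(rdf, 0.0, 50.0)

    def test_profile_non_decreasing(self, chain9):
        prof = cumulative_coordination(chain9)
        assert np.min(np.diff(prof.n_cum)) >= 0.0

    def test_empty_histogram_all_zero(self):
        h = PairHistogram(0.1, np.zeros(50, dtype=int), "total", 10, 0.01)
        prof = cumulative_profile(rdf_from_pdf(pdf_from_histogram(h)))
        assert np.all(prof.n_cum == 0.0)

    def test_oracle_equivalence_random(self, rng):
        for n in (10, 57, 200):
            s = random_structure(rng, n)
            prof = cumulative_coordination(s, bin_size=0.1)
            upper_edges = prof.r_grid + prof.bin_size / 2.0
            expected = brute_force_cumulative(s, upper_edges)
            np.testing.assert_allclose(prof.n_cum, expected, rtol=1e-9, atol=1e-12)

    @settings(max_examples=20, deadline=None)
    @given(n=st.integers(4, 60), seed=st.integers(0, 2**31 - 1))
    def test_oracle_equivalence_property(self, n, seed):
        s = random_structure(np.random.default_rng(seed), n)
        prof = cumulative_coordination(s, bin_size=0.25)
        expected = brute_force_cumulative(s, prof.r_grid + prof.bin_size / 2.0)
        np.testing.assert_allclose(prof.n_cum, expected, rtol=1e-9, atol=1e-12)


class TestDelta:
    def test_self_delta_zero(self, chain9):
        p = cumulative_coordination(chain9)
        d = coordination_delta(p, p)
        assert np.all(d.delta == 0.0)

    def test_dilation_sign(self, chain9):
        v = make_variant(chain9, 1.05)
        r_max = 40.0
        pv = cumulative_coordination(v, r_max=r_max)
        pi = cumulative_coordination(chain9, r_max=r_max)
        d = coordination_delta(pv, pi)
        assert np.all(d.delta <= 1e-12)

    @settings(max_examples=15, deadline=None)
    @given(f=st.floats(1.0, 1.5), seed=st.integers(0, 10_000))
    def test_scale_monotonicity_property(self, f, seed):
        s = random_structure(np.random.default_rng(seed), 40)
        v = make_variant(s, f)
        r_max = 40.0
        dv = coordination_delta(
            cumulative_coordination(v, r_max=r_max),
            cumulative_coordination(s, r_max=r_max),
        )
        assert np.all(dv.delta <= 1e-12)

    def test_grid_mismatch(self, chain9):
        p1 = cumulative_coordination(chain9, r_max=10.0)
        p2 = cumulative_coordination(chain9, r_max=20.0)
        with pytest.raises(GridMismatchError):
            coordination_delta(p1, p2)


class TestBinRobustnessAndPeaks:
    def test_halving_bin_size(self, chain9):
        r = 7.0
        n1 = cumulative_coordination(chain9, bin_size=0.1, r_max=25.0)
        n2 = cumulative_coordination(chain9, bin_size=0.05, r_max=25.0)
        i1 = np.searchsorted(n1.r_grid + 0.05, r) - 1
        i2 = np.searchsorted(n2.r_grid + 0.025, r) - 1
        a, b = n1.n_cum[i1], n2.n_cum[i2]
        assert abs(a - b) / a < 0.01

    def test_first_shell_peaks(self):
        for seed in (0, 7, 23):
            s = make_chain(SyntheticSpec(n_residues=9, seed=seed))
            cc = first_shell_peak(pdf_from_histogram(build_histogram(s, "C-C")))
            cn = first_shell_peak(pdf_from_histogram(build_histogram(s, "C-N")))
            assert cc == 1.5
            assert cn == 1.3
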