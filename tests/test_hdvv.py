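"""HDvV tetramer model: Clebsch-Gordan coupling, coupled-basis
diagonalization, Griffith closed form, spin expectations."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spincluster.hdvv import (
    DEFAULT_TOPOLOGY,
    CoupledState,
    ExchangeParameters,
    build_hdvv_hamiltonian,
    build_product_basis,
    clebsch_gordan,
    coupled_basis_unitary,
    coupled_state_vector,
    griffith_energies,
    griffith_energy,
    spin_expectations,
    total_spin_squared,
)

S52 = (Fraction(5, 2),) * 4
PARAMS = ExchangeParameters(32.0, 55.5, "cm-1")


class TestClebschGordan:
    def test_two_spin_singlet(self):
        assert clebsch_gordan(Fraction(1, 2), Fraction(1, 2),
                              Fraction(1, 2), Fraction(-1, 2), 0, 0) == \
            pytest.approx(1 / math.sqrt(2))

    @pytest.mark.parametrize("j", [Fraction(1, 2), 1, Fraction(5, 2), 4])
    def test_stretched_antialigned(self, j):
        """<j m j -m|0 0> = (-1)^(j-m) / sqrt(2j+1)."""
        for two_m in range(-int(2 * j), int(2 * j) + 1, 2):
            m = Fraction(two_m, 2)
            expected = (-1) ** int(j - m) / math.sqrt(2 * j + 1)
            assert clebsch_gordan(j, m, j, -m, 0, 0) == pytest.approx(expected)

    def test_selection_rules_return_zero(self):
        assert clebsch_gordan(1, 0, 1, 1, 2, 0) == 0.0  # M != m1+m2
        assert clebsch_gordan(1, 0, 1, 0, 3, 0) == 0.0  # triangle violated

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            clebsch_gordan(0.3, 0.3, 1, 0, 1, 0.3)
        with pytest.raises(ValueError):
            clebsch_gordan(1, 2, 1, 0, 2, 2)  # |m1| > j1

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(tj1=st.integers(0, 6), tj2=st.integers(0, 6))
    def test_unitarity_of_coupling(self, tj1, tj2):
        """For fixed (j1, j2), the CG matrix from |m1 m2> to |J M> is
        orthogonal: rows indexed by m-splits, columns by (J, M)."""
        j1, j2 = Fraction(tj1, 2), Fraction(tj2, 2)
        splits = [
            (Fraction(a, 2), Fraction(b, 2))
            for a in range(-tj1, tj1 + 1, 2)
            for b in range(-tj2, tj2 + 1, 2)
        ]
        jm = [
            (Fraction(tJ, 2), Fraction(tM, 2))
            for tJ in range(abs(tj1 - tj2), tj1 + tj2 + 1, 2)
            for tM in range(-tJ, tJ + 1, 2)
        ]
        mat = np.array([
            [clebsch_gordan(j1, m1, j2, m2, J, M) for (J, M) in jm]
            for (m1, m2) in splits
        ])
        assert mat.shape[0] == mat.shape[1]
        assert np.allclose(mat @ mat.T, np.eye(len(splits)), atol=1e-12)

    def test_against_sympy_oracle(self):
        sympy = pytest.importorskip("sympy")
        from sympy.physics.quantum.cg import CG

        rng = np.random.default_rng(42)
        checked = 0
        while checked < 40:
            tj1, tj2 = rng.integers(0, 6, size=2)
            tJ = rng.integers(abs(tj1 - tj2), tj1 + tj2 + 1)
            if (tj1 + tj2 + tJ) % 2:
                continue
            tm1 = rng.integers(-tj1, tj1 + 1)
            tm2 = rng.integers(-tj2, tj2 + 1)
            if (tj1 - tm1) % 2 or (tj2 - tm2) % 2 or abs(tm1 + tm2) > tJ:
                continue
            args = [sympy.Rational(t, 2) for t in (tj1, tm1, tj2, tm2, tJ, tm1 + tm2)]
            ref = float(CG(*args).doit())
            mine = clebsch_gordan(*(Fraction(t, 2) for t in (tj1, tm1, tj2, tm2, tJ, tm1 + tm2)))
            assert mine == pytest.approx(ref, abs=1e-12)
            checked += 1


class TestProductBasis:
    @pytest.mark.parametrize(
        "spins, size",
        [(S52, 1296), ((Fraction(1, 2),) * 4, 16), ((Fraction(3, 2),) * 4, 256)],
    )
    def test_sizes(self, spins, size):
        assert len(build_product_basis(spins)) == size

    def test_lexicographic_from_top(self):
        basis = build_product_basis((Fraction(1, 2),) * 4)
        assert basis[0].m == (Fraction(1, 2),) * 4
        assert basis[-1].m == (Fraction(-1, 2),) * 4


class TestHamiltonian:
    def test_uniform_coupling_closed_form_spin_half(self):
        """J_2B = J_4B = J: E = (J/2)[S(S+1) - 4 s(s+1)] for total spin S."""
        spins = (Fraction(1, 2),) * 4
        params = ExchangeParameters(3.0, 3.0, "cm-1")
        H = build_hdvv_hamiltonian(spins, params)
        evals = np.sort(np.linalg.eigvalsh(H))
        expected = sorted(
            1.5 * (S * (S + 1) - 3.0)
            for S, mult in ((0, 2), (1, 9), (2, 5))
            for _ in range(mult)
        )
        assert np.allclose(evals, expected, atol=1e-12)

    def test_commutes_with_total_spin(self):
        spins = (Fraction(3, 2),) * 4
        H = build_hdvv_hamiltonian(spins, ExchangeParameters(1.0, 2.0, "cm-1"))
        S2 = total_spin_squared(spins)
        assert np.max(np.abs(H @ S2 - S2 @ H)) < 1e-10
        # Sz is diagonal in the product basis; H preserves each Sz block
        ms = [sum(p.m) for p in build_product_basis(spins)]
        for a, b in itertools.product(range(len(ms)), repeat=2):
            if ms[a] != ms[b]:
                assert H[a, b] == 0.0

    def test_singlet_multiplicity_is_six(self, fe4_spins):
        evals = np.linalg.eigvalsh(total_spin_squared(fe4_spins))
        assert int(np.sum(np.abs(evals) < 1e-8)) == 6

    def test_traceless(self, fe4_spins):
        H = build_hdvv_hamiltonian(fe4_spins, PARAMS)
        assert abs(np.trace(H)) < 1e-8

    def test_bad_topology_rejected(self, fe4_spins):
        with pytest.raises(ValueError):
            build_hdvv_hamiltonian(fe4_spins, PARAMS, {"AB": "2B"})
        bad = dict(DEFAULT_TOPOLOGY)
        bad["AC"] = "2B"
        with pytest.raises(ValueError):
            build_hdvv_hamiltonian(fe4_spins, PARAMS, bad)


class TestCoupledBasis:
    def test_unitary(self, fe4_unitary):
        U, labels = fe4_unitary
        assert len(labels) == 1296
        assert np.max(np.abs(U.T @ U - np.eye(1296))) < 1e-12

    def test_diagonalizes_hdvv(self, fe4_spins, fe4_unitary):
        U, labels = fe4_unitary
        H = build_hdvv_hamiltonian(fe4_spins, PARAMS)
        D = U.T @ H @ U
        off = D - np.diag(np.diag(D))
        assert np.max(np.abs(off)) < 1e-10 * max(abs(PARAMS.j2b), abs(PARAMS.j4b))

    def test_alternative_scheme_only_block_diagonal(self, fe4_spins):
        """The (AC)(BD) pairing does not diagonalize H: blocks remain."""
        U, labels = coupled_basis_unitary(fe4_spins, scheme=((0, 2), (1, 3)))
        H = build_hdvv_hamiltonian(fe4_spins, PARAMS)
        D = U.T @ H @ U
        off = np.abs(D - np.diag(np.diag(D)))
        assert np.max(off) > 1.0  # genuinely non-diagonal
        # but H still block-diagonalizes over (S_tot, S_tot^z)
        for a in range(0, 1296, 97):
            for b in range(a + 1, min(a + 40, 1296)):
                la, lb = labels[a], labels[b]
                if (la.S_tot, la.S_tot_z) != (lb.S_tot, lb.S_tot_z):
                    assert off[a, b] < 1e-10

    def test_triangle_rule_enforced_on_labels(self):
        with pytest.raises(ValueError):
            CoupledState(5, 5, 11, 0)
        with pytest.raises(ValueError):
            CoupledState(2, 2, 1, 3)


class TestGriffith:
    @pytest.mark.parametrize("two_s", [1, 2, 3, 5])
    def test_matches_diagonalization_on_grid(self, two_s):
        """Griffith's closed form reproduces the coupled-basis diagonal of H
        on a 5x5 grid of (J_2B, J_4B), for s up to 5/2."""
        s = Fraction(two_s, 2)
        spins = (s,) * 4
        U, labels = coupled_basis_unitary(spins)
        from spincluster.hdvv import pair_coupling_operator

        A = pair_coupling_operator(spins, 0, 1) + pair_coupling_operator(spins, 2, 3)
        B = sum(pair_coupling_operator(spins, i, j)
                for i, j in ((0, 2), (0, 3), (1, 2), (1, 3)))
        At, Bt = U.T @ A @ U, U.T @ B @ U
        for j2b in np.linspace(-50, 100, 5):
            for j4b in np.linspace(-50, 100, 5):
                params = ExchangeParameters(j2b, j4b, "cm-1")
                D = j2b * At + j4b * Bt
                off = D - np.diag(np.diag(D))
                assert np.max(np.abs(off)) < 1e-9 * (1 + max(abs(j2b), abs(j4b)))
                for k, st_ in enumerate(labels):
                    e = griffith_energy(s, st_.S_AB, st_.S_CD, st_.S_tot, params)
                    assert D[k, k] == pytest.approx(e, abs=1e-8)

    def test_singlet_ladder_spacings(self):
        """Singlet energies relative to |(5,5),0,0> follow
        (J_4B - J_2B) x {0, 10, 18, 24, 28, 30}."""
        params = ExchangeParameters(30.0, 47.0, "cm-1")  # J4B - J2B = 17
        ref = griffith_energy(Fraction(5, 2), 5, 5, 0, params)
        spacings = [
            (griffith_energy(Fraction(5, 2), k, k, 0, params) - ref) / 17.0
            for k in (5, 4, 3, 2, 1, 0)
        ]
        assert spacings == pytest.approx([0, 10, 18, 24, 28, 30])

    def test_smax_gap_is_55_j4b(self):
        params = ExchangeParameters(11.0, 7.0, "cm-1")
        gap = griffith_energy(Fraction(5, 2), 5, 5, 10, params) \
            - griffith_energy(Fraction(5, 2), 5, 5, 0, params)
        assert gap == pytest.approx(55 * 7.0)

    def test_equal_couplings_give_sixfold_degenerate_singlets(self):
        params = ExchangeParameters(40.0, 40.0, "cm-1")
        energies = {
            round(griffith_energy(Fraction(5, 2), k, k, 0, params), 9)
            for k in range(6)
        }
        assert len(energies) == 1

    def test_ladder_sorted_and_grounded(self):
        ladder = griffith_energies(Fraction(5, 2), PARAMS)
        assert ladder.entries[0].energy == 0.0
        energies = [e.energy for e in ladder.entries]
        assert energies == sorted(energies)

    def test_level_degeneracy_in_product_basis(self):
        """Each Griffith level appears (2 S_tot + 1) x (number of channels
        sharing the energy) times in the product-basis spectrum."""
        s = Fraction(3, 2)
        params = ExchangeParameters(13.0, 29.0, "cm-1")
        H = build_hdvv_hamiltonian((s,) * 4, params)
        evals = np.linalg.eigvalsh(H)
        from collections import Counter

        expected = Counter()
        for S_AB in range(4):
            for S_CD in range(4):
                for S_tot in range(abs(S_AB - S_CD), S_AB + S_CD + 1):
                    e = round(griffith_energy(s, S_AB, S_CD, S_tot, params), 6)
                    expected[e] += 2 * S_tot + 1
        observed = Counter(round(e, 6) for e in evals)
        assert observed == expected

    def test_invariance_under_site_relabeling(self, fe4_spins):
        """Swapping the two-bond pair (AB <-> CD) or permuting the four-bond
        edges leaves the spectrum unchanged."""
        H1 = build_hdvv_hamiltonian(fe4_spins, PARAMS)
        swapped = {"CD": "2B", "AB": "2B", "AC": "4B", "AD": "4B", "BC": "4B", "BD": "4B"}
        H2 = build_hdvv_hamiltonian(fe4_spins, PARAMS, swapped)
        assert np.allclose(
            np.sort(np.linalg.eigvalsh(H1)), np.sort(np.linalg.eigvalsh(H2)), atol=1e-8
        )


class TestSpinExpectations:
    def test_highest_channel(self, fe4_spins):
        vals = spin_expectations(CoupledState(5, 5, 0, 0), fe4_spins)
        assert vals == pytest.approx((8.75, 30.0, 8.75))

    def test_lowest_channel(self, fe4_spins):
        vals = spin_expectations(CoupledState(0, 0, 0, 0), fe4_spins)
        assert vals == pytest.approx((8.75, 0.0, 8.75), abs=1e-10)

    @pytest.mark.parametrize("sd, mid", [(4, 20.0), (3, 12.0), (2, 6.0), (1, 2.0)])
    def test_intermediate_channels(self, fe4_spins, sd, mid):
        vals = spin_expectations(CoupledState(sd, sd, 0, 0), fe4_spins)
        assert vals[1] == pytest.approx(mid)
        assert vals[0] == pytest.approx(8.75)

    def test_unnormalized_rejected(self, fe4_spins):
        vec = 2.0 * coupled_state_vector(fe4_spins, CoupledState(5, 5, 0, 0))
        with pytest.raises(ValueError):
            spin_expectations(vec, fe4_spins)
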