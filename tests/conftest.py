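"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's CSF machinery: they work in
the full 2^n spin-product basis using bit arithmetic, so that spectra and
spin-purity checks are computed by a route independent of the genealogical
expansion they validate.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

import numpy as np
import pytest

from spincluster.combinatorics import SiteSpec
from spincluster.csf import full_csf_basis
from spincluster.exchange import ExchangeCouplingMatrix, build_exchange_hamiltonian

# ---------------------------------------------------------------------------
# Brute-force oracles (product basis, bit arithmetic)
# ---------------------------------------------------------------------------


def brute_exchange_hamiltonian(jmat: np.ndarray) -> np.ndarray:
    """H = sum_{i<j} J_ij S_i.S_j over all 2^n spin-product states.

    Bit b of the state index = 1 means orbital b is spin-up.
    """
    n = jmat.shape[0]
    dim = 1 << n
    H = np.zeros((dim, dim))
    for state in range(dim):
        for i in range(n):
            si = 0.5 if (state >> i) & 1 else -0.5
            for j in range(i + 1, n):
                if jmat[i, j] == 0.0:
                    continue
                sj = 0.5 if (state >> j) & 1 else -0.5
                H[state, state] += jmat[i, j] * si * sj
                if si != sj:  # transverse part swaps the two spins
                    flipped = state ^ (1 << i) ^ (1 << j)
                    H[flipped, state] += 0.5 * jmat[i, j]
    return H


def brute_total_s2(n: int) -> np.ndarray:
    """Total S^2 = 3n/4 + 2 sum_{i<j} S_i.S_j over all 2^n product states."""
    twos = 2.0 * (np.ones((n, n)) - np.eye(n))
    return brute_exchange_hamiltonian(twos) + 0.75 * n * np.eye(1 << n)


def sector_eigenvalues(jmat: np.ndarray, S: Fraction) -> np.ndarray:
    """Eigenvalues of the exchange Hamiltonian within one total-spin sector.

    Diagonalizes H + c S^2 in the full product space for a shift c large
    enough to separate the spin sectors, then collects the eigenvalues whose
    S^2 offset matches S(S+1).
    """
    n = jmat.shape[0]
    c = 100.0 * (1.0 + np.abs(jmat).sum())
    A = brute_exchange_hamiltonian(jmat) + c * brute_total_s2(n)
    evals = np.linalg.eigvalsh(A)
    target = c * float(S * (S + 1))
    span = np.abs(jmat).sum() + 1.0
    sel = np.sort(evals[(evals > target - span) & (evals < target + span)] - target)
    mult = int(2 * S) + 1  # each sector level carries its Sz degeneracy
    assert len(sel) % mult == 0
    return sel[::mult]


def brute_paths_count(n_o: int, S: Fraction, forbidden=frozenset()) -> int:
    """Count +-1/2 step sequences with non-negative partial sums ending at S,
    avoiding forbidden (k, S) nodes, by explicit enumeration."""
    two_S = int(2 * S)
    count = 0
    for steps in itertools.product((1, -1), repeat=n_o):
        running, ok = 0, True
        for k, s in enumerate(steps, start=1):
            running += s
            if running < 0 or (k, Fraction(running, 2)) in forbidden:
                ok = False
                break
        if ok and running == two_S:
            count += 1
    return count


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture(scope="session")
def n4_sites():
    """Four s=3/2 sites (the 12-orbital nitrogen-tetramer-like model)."""
    return [SiteSpec(lbl, Fraction(3, 2)) for lbl in "ABCD"]


@pytest.fixture(scope="session")
def n4_couplings():
    """Site-symmetric couplings: uniform ferromagnetic intra-site constant,
    one inter-site constant per bond class (two-bond 0.8, four-bond 1.0)."""
    inter = {(0, 1): 0.8, (2, 3): 0.8, (0, 2): 1.0, (0, 3): 1.0, (1, 2): 1.0, (1, 3): 1.0}
    return ExchangeCouplingMatrix.site_symmetric((3, 3, 3, 3), -10.0, inter)


@pytest.fixture(scope="session")
def n4_basis():
    return full_csf_basis(12, 0)


@pytest.fixture(scope="session")
def n4_hamiltonian(n4_couplings, n4_basis):
    return build_exchange_hamiltonian(n4_couplings, n4_basis)


@pytest.fixture(scope="session")
def fe4_spins():
    return (Fraction(5, 2),) * 4


@pytest.fixture(scope="session")
def fe4_unitary(fe4_spins):
    from spincluster.hdvv import coupled_basis_unitary

    return coupled_basis_unitary(fe4_spins)
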