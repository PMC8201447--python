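"""Exchange-only Hamiltonians in the genealogical CSF basis.

The model Hamiltonian is H = sum_{i<j} J_ij S_i . S_j over orbital-level
spin-1/2 operators, with J > 0 antiferromagnetic.  Matrices are built by
expanding each CSF into sigma-strings at a fixed projection and conjugating
the product-basis Hamiltonian; the genealogical CSFs are orthonormal, so the
result is the exact representation in the spin-adapted basis.

Also provided: orbital reorderings (atom-separated vs interleaved), sparsity
and block/sign-coherence profiling against the Hund-allowed sub-block, and a
deterministic imaginary-time projector that targets the lowest state coupled
to a chosen initial CSF (the deterministic analogue of starting a projective
eigensolver from a single configuration).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import sparse

from .csf import GenealogicalCSF, determinant_expansion_matrix, sz_determinants
from .util import as_half_integer

__all__ = [
    "ExchangeCouplingMatrix",
    "OrbitalOrdering",
    "BlockProfile",
    "ProjectionResult",
    "build_exchange_hamiltonian",
    "apply_ordering",
    "block_profile",
    "imaginary_time_project",
]

#: magnitudes below this are treated as structural zeros
ZERO_THRESHOLD = 1e-12


@dataclass(frozen=True)
class ExchangeCouplingMatrix:
    """Symmetric orbital-pair exchange couplings J_ij with zero diagonal.

    ``site_sizes`` optionally partitions the orbitals into contiguous site
    blocks (atom-separated ordering), which classifies every pair as
    intra-site or inter-site.
    """

    j: np.ndarray
    site_sizes: tuple[int, ...] | None = None

    def __post_init__(self):
        j = np.asarray(self.j, dtype=float)
        object.__setattr__(self, "j", j)
        if j.ndim != 2 or j.shape[0] != j.shape[1]:
            raise ValueError("J must be a square matrix")
        if not np.allclose(j, j.T, atol=ZERO_THRESHOLD):
            raise ValueError("J must be symmetric")
        if np.any(np.abs(np.diag(j)) > ZERO_THRESHOLD):
            raise ValueError("J must have zero diagonal")
        if self.site_sizes is not None:
            sizes = tuple(int(s) for s in self.site_sizes)
            object.__setattr__(self, "site_sizes", sizes)
            if sum(sizes) != j.shape[0]:
                raise ValueError("site_sizes must sum to the orbital count")

    @property
    def n_orbitals(self) -> int:
        return self.j.shape[0]

    def site_of(self, i: int) -> int:
        if self.site_sizes is None:
            raise ValueError("no site partition attached")
        acc = 0
        for t, s in enumerate(self.site_sizes):
            acc += s
            if i < acc:
                return t
        raise IndexError(i)

    def pair_class(self, i: int, j: int) -> str:
        return "intra" if self.site_of(i) == self.site_of(j) else "inter"

    @classmethod
    def site_symmetric(cls, site_sizes, j_intra: float, j_inter) -> "ExchangeCouplingMatrix":
        """Uniform couplings per class: a single ferromagnetic intra-site
        constant (j_intra < 0, the Hund stabilization) and one inter-site
        constant per site pair (``j_inter`` scalar or {(t,u): J} mapping)."""
        sizes = tuple(int(s) for s in site_sizes)
        n = sum(sizes)
        starts = np.cumsum((0,) + sizes)
        site = np.empty(n, dtype=int)
        for t, (a, b) in enumerate(zip(starts[:-1], starts[1:])):
            site[a:b] = t
        j = np.zeros((n, n))
        for i in range(n):
            for k in range(i + 1, n):
                ti, tk = site[i], site[k]
                if ti == tk:
                    v = j_intra
                elif np.isscalar(j_inter):
                    v = j_inter
                else:
                    v = j_inter.get((ti, tk), j_inter.get((tk, ti)))
                    if v is None:
                        raise KeyError(f"no inter-site coupling for site pair ({ti},{tk})")
                j[i, k] = j[k, i] = v
        return cls(j, sizes)

    @classmethod
    def random(cls, n_orbitals: int, rng: np.random.Generator,
               scale: float = 1.0) -> "ExchangeCouplingMatrix":
        """Seeded random symmetric couplings (fixture generator)."""
        a = rng.uniform(-scale, scale, size=(n_orbitals, n_orbitals))
        j = np.triu(a, 1)
        j = j + j.T
        return cls(j)


@dataclass(frozen=True)
class OrbitalOrdering:
    """Bijective permutation of orbital indices with a scheme tag.

    ``permutation[a]`` is the old index of the orbital placed at new
    position a.
    """

    permutation: tuple[int, ...]
    scheme: str = "custom"

    def __post_init__(self):
        p = tuple(int(i) for i in self.permutation)
        object.__setattr__(self, "permutation", p)
        if sorted(p) != list(range(len(p))):
            raise ValueError("permutation must be a bijection of 0..n-1")

    @classmethod
    def atom_separated(cls, site_sizes) -> "OrbitalOrdering":
        n = sum(site_sizes)
        return cls(tuple(range(n)), "atom_separated")

    @classmethod
    def interleaved(cls, site_sizes) -> "OrbitalOrdering":
        """Round-robin over sites: A1 B1 C1 D1 A2 B2 ... (relative to
        atom-separated input order)."""
        sizes = tuple(int(s) for s in site_sizes)
        starts = [0]
        for s in sizes[:-1]:
            starts.append(starts[-1] + s)
        perm = []
        for j in range(max(sizes)):
            for t, s in enumerate(sizes):
                if j < s:
                    perm.append(starts[t] + j)
        return cls(tuple(perm), "interleaved")


def apply_ordering(J: ExchangeCouplingMatrix, ordering: OrbitalOrdering):
    """Reindex the couplings under an orbital permutation and regenerate the
    CSF basis in the new cumulative coupling order.

    Returns ``(J_permuted, basis_factory)`` where ``basis_factory(S)`` yields
    the genealogical basis for the permuted orbital list.  Spectra of the
    exchange Hamiltonian are invariant under any ordering; sparsity is not.
    """
    p = ordering.permutation
    if len(p) != J.n_orbitals:
        raise ValueError("permutation length must equal the orbital count")
    jp = J.j[np.ix_(p, p)]
    sizes = J.site_sizes if ordering.scheme == "atom_separated" else None
    from .csf import full_csf_basis

    return ExchangeCouplingMatrix(jp, sizes), lambda S: full_csf_basis(len(p), S)


def _product_basis_hamiltonian(J: ExchangeCouplingMatrix, dets) -> sparse.csr_array:
    """H = sum_{i<j} J_ij S_i.S_j over sigma-strings of one Sz sector."""
    j = J.j
    n = J.n_orbitals
    index = {d: i for i, d in enumerate(dets)}
    pairs = [(a, b) for a in range(n) for b in range(a + 1, n)
             if abs(j[a, b]) > ZERO_THRESHOLD]
    rows, cols, vals = [], [], []
    sig = np.array(dets, dtype=float) / 2.0  # projections +-1/2
    diag = 0.5 * np.einsum("di,ij,dj->d", sig, j, sig)
    for d_idx, det in enumerate(dets):
        rows.append(d_idx)
        cols.append(d_idx)
        vals.append(diag[d_idx])
        for a, b in pairs:
            if det[a] == det[b]:
                continue
            flipped = list(det)
            flipped[a], flipped[b] = det[b], det[a]
            f_idx = index[tuple(flipped)]
            rows.append(d_idx)
            cols.append(f_idx)
            vals.append(0.5 * j[a, b])
    H = sparse.csr_array((vals, (rows, cols)), shape=(len(dets), len(dets)))
    return H


def build_exchange_hamiltonian(J: ExchangeCouplingMatrix,
                               basis: list[GenealogicalCSF],
                               Sz=None) -> sparse.csr_array:
    """Matrix of H = sum_{i<j} J_ij S_i.S_j in a genealogical CSF basis.

    The basis must span one (n_o, S) sector.  Each CSF is expanded into
    sigma-strings at projection ``Sz`` (default: Sz = S) and the product-basis
    Hamiltonian is conjugated; entries below ``ZERO_THRESHOLD`` are dropped.
    """
    if not basis:
        raise ValueError("empty basis")
    n_o = basis[0].n_orbitals
    if n_o != J.n_orbitals:
        raise ValueError(f"basis has {n_o} orbitals but J has {J.n_orbitals}")
    S = basis[0].spin
    if any(c.spin != S or c.n_orbitals != n_o for c in basis):
        raise ValueError("basis must span a single (n_o, S) sector")
    Sz = S if Sz is None else as_half_integer(Sz, "Sz")
    dets = sz_determinants(n_o, Sz)
    C, _ = determinant_expansion_matrix(basis, Sz, dets)
    Hdet = _product_basis_hamiltonian(J, dets)
    H = (C.T @ (Hdet @ C)).tocoo()
    mask = np.abs(H.data) > ZERO_THRESHOLD
    H = sparse.csr_array(
        (H.data[mask], (H.coords[0][mask], H.coords[1][mask])),
        shape=H.shape,
    )
    return H


@dataclass(frozen=True)
class BlockProfile:
    """Sparsity/block summary of a CSF-basis Hamiltonian.

    ``cross_block_max`` is the largest coupling magnitude between the
    Hund-allowed sub-block and its complement; ``sign_coherent`` says whether
    all off-diagonal elements inside the Hund block share one sign.
    """

    nnz: int
    cross_block_max: float
    sign_coherent: bool


def block_profile(H, hund_index_set) -> BlockProfile:
    """Profile the coupling between the Hund sub-block and its complement."""
    H = sparse.coo_array(H)
    dim = H.shape[0]
    hund = set(int(i) for i in hund_index_set)
    if not hund <= set(range(dim)):
        raise ValueError("hund_index_set must be a subset of basis indices")
    nnz = 0
    cross = 0.0
    signs: set[int] = set()
    for r, c, v in zip(H.coords[0], H.coords[1], H.data):
        if abs(v) <= ZERO_THRESHOLD:
            continue
        nnz += 1
        rin, cin = r in hund, c in hund
        if rin != cin:
            cross = max(cross, abs(v))
        elif rin and r != c:
            signs.add(1 if v > 0 else -1)
    return BlockProfile(nnz, cross, len(signs) <= 1)


@dataclass(frozen=True)
class ProjectionResult:
    energy: float
    vector: np.ndarray
    iterations: int
    converged: bool
    residual: float


def imaginary_time_project(H, initial_csf_index: int, tau: float | None = None,
                           tol: float = 1e-10, max_iter: int = 20000) -> ProjectionResult:
    """Deterministic imaginary-time projection x <- (1 - tau (H - E)) x.

    Starting from a single CSF, repeated application of the propagator damps
    every eigencomponent above the lowest eigenvalue that the initial state
    couples to; because the energy shift E is updated to the running Rayleigh
    quotient, the iteration converges to that state-specific energy rather
    than necessarily the global ground state.  The default time step is
    0.9 * 2/(lambda_max - lambda_min) from Gershgorin bounds.
    """
    H = sparse.csr_array(H)
    dim = H.shape[0]
    if not (0 <= initial_csf_index < dim):
        raise IndexError("initial CSF index out of range")
    if tau is None:
        diag = H.diagonal()
        radii = np.abs(H).sum(axis=1) - np.abs(diag)
        lo = float(np.min(diag - radii))
        hi = float(np.max(diag + radii))
        tau = 0.9 * 2.0 / (hi - lo) if hi > lo else 1.0
    elif tau <= 0:
        raise ValueError("tau must be positive")
    x = np.zeros(dim)
    x[initial_csf_index] = 1.0
    energy = float(H.diagonal()[initial_csf_index])
    for it in range(1, max_iter + 1):
        hx = H @ x
        energy = float(x @ hx)
        r = hx - energy * x
        res = float(np.linalg.norm(r))
        if res < tol:
            return ProjectionResult(energy, x, it, True, res)
        x = x - tau * r
        x /= np.linalg.norm(x)
    return ProjectionResult(energy, x, max_iter, False, res)
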