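"""The four-site Heisenberg-Dirac-van Vleck (HDvV) model.

H = J_2B (S_A.S_B + S_C.S_D) + J_4B (S_A.S_C + S_A.S_D + S_B.S_C + S_B.S_D)

for four local spins on a distorted tetrahedron with two coupling classes:
the two symmetry-equivalent bonds (class "2B", the AB and CD edges) and the
four remaining bonds (class "4B").  J > 0 is antiferromagnetic.  The module
builds the Hamiltonian in the uncoupled product basis |S_A^z S_B^z S_C^z
S_D^z> via the ladder-operator expansion, constructs the Clebsch-Gordan
unitary to the coupled basis |(S_AB S_CD) S_tot S_tot^z> in which H is
diagonal, evaluates Griffith's closed-form eigenvalues

    E = J_2B/2 [S_AB(S_AB+1) + S_CD(S_CD+1) - 4 s(s+1)]
      + J_4B/2 [S_tot(S_tot+1) - S_AB(S_AB+1) - S_CD(S_CD+1)],

and computes partial-spin expectation values.

Clebsch-Gordan coefficients use Racah's algebraic sum with exact rational
arithmetic (floats only at the final square root), Condon-Shortley phases.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from math import factorial

import numpy as np

from .util import as_half_integer, couple, spin_range, twice

__all__ = [
    "ProductState",
    "CoupledState",
    "ExchangeParameters",
    "SpinLadder",
    "LadderEntry",
    "TETRAHEDRON_EDGES",
    "DEFAULT_TOPOLOGY",
    "clebsch_gordan",
    "build_product_basis",
    "build_hdvv_hamiltonian",
    "pair_coupling_operator",
    "total_spin_squared",
    "coupled_basis_unitary",
    "coupled_state_vector",
    "griffith_energy",
    "griffith_energies",
    "spin_expectations",
]

SITE_LABELS = ("A", "B", "C", "D")
TETRAHEDRON_EDGES = ("AB", "CD", "AC", "AD", "BC", "BD")
#: the distorted-cubane assignment: two symmetry-equivalent bonds AB, CD
DEFAULT_TOPOLOGY = {"AB": "2B", "CD": "2B", "AC": "4B", "AD": "4B", "BC": "4B", "BD": "4B"}

VALID_UNITS = ("cm-1", "meV")


@dataclass(frozen=True)
class ProductState:
    """Uncoupled basis label |S_A^z S_B^z S_C^z S_D^z>."""

    m: tuple[Fraction, ...]


@dataclass(frozen=True)
class CoupledState:
    """Coupled basis label |(S_AB S_CD) S_tot S_tot^z>."""

    S_AB: Fraction
    S_CD: Fraction
    S_tot: Fraction
    S_tot_z: Fraction

    def __post_init__(self):
        for name in ("S_AB", "S_CD", "S_tot", "S_tot_z"):
            object.__setattr__(self, name, as_half_integer(getattr(self, name), name))
        if self.S_tot not in couple(self.S_AB, self.S_CD):
            raise ValueError(
                f"triangle rule violated: |{self.S_AB}-{self.S_CD}| <= S_tot <= "
                f"{self.S_AB + self.S_CD} required, got S_tot={self.S_tot}"
            )
        if abs(self.S_tot_z) > self.S_tot:
            raise ValueError("|S_tot^z| must not exceed S_tot")

    def label(self) -> str:
        def fmt(x: Fraction) -> str:
            return str(x.numerator) if x.denominator == 1 else f"{x.numerator}/{x.denominator}"

        return (f"|({fmt(self.S_AB)}, {fmt(self.S_CD)}), "
                f"{fmt(self.S_tot)}, {fmt(self.S_tot_z)}>")


@dataclass(frozen=True)
class ExchangeParameters:
    """The two exchange constants of the distorted tetrahedron."""

    j2b: float
    j4b: float
    unit: str

    def __post_init__(self):
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unit must be one of {VALID_UNITS}, got {self.unit!r}")
        if not (math.isfinite(self.j2b) and math.isfinite(self.j4b)):
            raise ValueError("exchange constants must be finite")


@dataclass(frozen=True)
class LadderEntry:
    state: CoupledState
    energy: float  # relative to the ladder's ground entry


@dataclass(frozen=True)
class SpinLadder:
    """Channel-labelled energies relative to the ground entry, ascending."""

    entries: tuple[LadderEntry, ...]
    unit: str

    def __post_init__(self):
        if self.entries and abs(self.entries[0].energy) > 1e-12:
            raise ValueError("ground entry must sit at zero")
        energies = [e.energy for e in self.entries]
        if energies != sorted(energies):
            raise ValueError("ladder must be sorted ascending")

    def energy_of(self, state: CoupledState) -> float:
        for e in self.entries:
            if e.state == state:
                return e.energy
        raise KeyError(state.label())


# ---------------------------------------------------------------------------
# Clebsch-Gordan coefficients (Racah's closed form, exact rationals)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _cg_twice(tj1: int, tm1: int, tj2: int, tm2: int, tJ: int, tM: int) -> float:
    if tm1 + tm2 != tM:
        return 0.0
    if tJ < abs(tj1 - tj2) or tJ > tj1 + tj2 or (tj1 + tj2 + tJ) % 2:
        return 0.0
    if abs(tM) > tJ:
        return 0.0
    # all factorial arguments below are guaranteed integral
    def f(tx: int) -> int:
        if tx % 2 or tx < 0:
            raise ValueError("non-integral or negative factorial argument")
        return factorial(tx // 2)

    pre = Fraction(
        (tJ + 1)
        * f(tJ + tj1 - tj2) * f(tJ - tj1 + tj2) * f(tj1 + tj2 - tJ)
        * f(tJ + tM) * f(tJ - tM)
        * f(tj1 - tm1) * f(tj1 + tm1) * f(tj2 - tm2) * f(tj2 + tm2),
        f(tj1 + tj2 + tJ + 2),
    )
    k_min = max(0, (tj2 - tJ - tm1) // 2, (tj1 + tm2 - tJ) // 2)
    k_max = min((tj1 + tj2 - tJ) // 2, (tj1 - tm1) // 2, (tj2 + tm2) // 2)
    total = Fraction(0)
    for k in range(k_min, k_max + 1):
        tk = 2 * k
        den = (
            factorial(k)
            * f(tj1 + tj2 - tJ - tk) * f(tj1 - tm1 - tk) * f(tj2 + tm2 - tk)
            * f(tJ - tj2 + tm1 + tk) * f(tJ - tj1 - tm2 + tk)
        )
        total += Fraction((-1) ** k, den)
    if total == 0:
        return 0.0
    sign = 1.0 if total > 0 else -1.0
    return sign * math.sqrt(float(pre * total * total))


def clebsch_gordan(j1, m1, j2, m2, J, M) -> float:
    """Clebsch-Gordan coefficient <j1 m1 j2 m2 | J M> (Condon-Shortley).

    Returns 0 when the triangle rule or M = m1 + m2 fails; raises for
    non-half-integer inputs or |m| > j.
    """
    vals = {}
    for name, x in (("j1", j1), ("m1", m1), ("j2", j2), ("m2", m2), ("J", J), ("M", M)):
        vals[name] = as_half_integer(x, name)
    for j, m in (("j1", "m1"), ("j2", "m2"), ("J", "M")):
        if vals[j] < 0:
            raise ValueError(f"{j} must be non-negative")
        if abs(vals[m]) > vals[j] or (vals[j] - vals[m]).denominator != 1:
            raise ValueError(f"|{m}| <= {j} with integral {j}-{m} required")
    return _cg_twice(*(twice(vals[n]) for n in ("j1", "m1", "j2", "m2", "J", "M")))


# ---------------------------------------------------------------------------
# Product basis and Hamiltonian
# ---------------------------------------------------------------------------

def _check_spins(spins) -> tuple[Fraction, ...]:
    spins = tuple(as_half_integer(s, "site spin") for s in spins)
    if len(spins) != 4:
        raise ValueError("the tetramer model needs exactly four site spins")
    if any(s < Fraction(1, 2) for s in spins):
        raise ValueError("site spins must be >= 1/2")
    return spins


def _m_values(s: Fraction) -> list[Fraction]:
    return list(reversed(spin_range(-s, s)))  # +s down to -s


def build_product_basis(spins) -> list[ProductState]:
    """Uncoupled basis, lexicographic with m running from +s downward."""
    spins = _check_spins(spins)
    return [ProductState(m) for m in itertools.product(*(_m_values(s) for s in spins))]


def _single_site_matrices(s: Fraction):
    """(Sz, S+, S-) for one spin-s site, basis m = +s .. -s."""
    d = twice(s) + 1
    ms = _m_values(s)
    sz = np.diag([float(m) for m in ms])
    sp = np.zeros((d, d))
    for k in range(1, d):  # raise m of column state k (m = ms[k]) to ms[k-1]
        m = ms[k]
        sp[k - 1, k] = math.sqrt(float(s * (s + 1) - m * (m + 1)))
    return sz, sp, sp.T


def _kron_chain(mats) -> np.ndarray:
    out = mats[0]
    for m in mats[1:]:
        out = np.kron(out, m)
    return out


def pair_coupling_operator(spins, i: int, j: int) -> np.ndarray:
    """S_i . S_j in the product basis (dense)."""
    spins = _check_spins(spins)
    dims = [twice(s) + 1 for s in spins]
    ops = [_single_site_matrices(s) for s in spins]
    out = np.zeros((int(np.prod(dims)),) * 2)
    for a, b, w in ((0, 0, 1.0), (1, 2, 0.5), (2, 1, 0.5)):  # SzSz + (S+S- + S-S+)/2
        mats = []
        for t in range(4):
            if t == i:
                mats.append(ops[t][a])
            elif t == j:
                mats.append(ops[t][b])
            else:
                mats.append(np.eye(dims[t]))
        out += w * _kron_chain(mats)
    return out


def _validate_topology(topology) -> dict[str, str]:
    topo = {}
    for edge, cls in topology.items():
        key = "".join(sorted(edge))
        if key not in TETRAHEDRON_EDGES and key[::-1] not in TETRAHEDRON_EDGES:
            raise ValueError(f"unknown tetrahedron edge {edge!r}")
        key = key if key in TETRAHEDRON_EDGES else key[::-1]
        if cls not in ("2B", "4B"):
            raise ValueError(f"bond class must be '2B' or '4B', got {cls!r}")
        if key in topo:
            raise ValueError(f"edge {key} assigned twice")
        topo[key] = cls
    missing = set(TETRAHEDRON_EDGES) - set(topo)
    if missing:
        raise ValueError(f"edges without a bond class: {sorted(missing)}")
    if sorted(topo.values()).count("2B") != 2:
        raise ValueError("exactly two edges must belong to class 2B")
    return topo


def build_hdvv_hamiltonian(spins, params: ExchangeParameters,
                           topology=DEFAULT_TOPOLOGY) -> np.ndarray:
    """HDvV Hamiltonian in the product basis (dense, in ``params.unit``)."""
    spins = _check_spins(spins)
    topo = _validate_topology(topology)
    jval = {"2B": params.j2b, "4B": params.j4b}
    dim = int(np.prod([twice(s) + 1 for s in spins]))
    H = np.zeros((dim, dim))
    for edge, cls in topo.items():
        i, j = SITE_LABELS.index(edge[0]), SITE_LABELS.index(edge[1])
        H += jval[cls] * pair_coupling_operator(spins, i, j)
    return H


def total_spin_squared(spins) -> np.ndarray:
    """S_tot^2 in the product basis."""
    spins = _check_spins(spins)
    dim = int(np.prod([twice(s) + 1 for s in spins]))
    out = sum(float(s * (s + 1)) for s in spins) * np.eye(dim)
    for i in range(4):
        for j in range(i + 1, 4):
            out += 2.0 * pair_coupling_operator(spins, i, j)
    return out


# ---------------------------------------------------------------------------
# Coupled basis
# ---------------------------------------------------------------------------

def _coupled_labels(spins, scheme) -> list[CoupledState]:
    (p, q), (r, t) = scheme
    labels = []
    for S_pq in couple(spins[p], spins[q]):
        for S_rt in couple(spins[r], spins[t]):
            for S in couple(S_pq, S_rt):
                for M in reversed(spin_range(-S, S)):
                    labels.append(CoupledState(S_pq, S_rt, S, M))
    return labels


def coupled_state_vector(spins, state: CoupledState,
                         scheme=((0, 1), (2, 3))) -> np.ndarray:
    """Product-basis vector of one coupled state via Clebsch-Gordan sums."""
    spins = _check_spins(spins)
    (p, q), (r, t) = scheme
    dims = [twice(s) + 1 for s in spins]
    strides = [int(np.prod(dims[k + 1:])) for k in range(4)]

    def idx_of(site: int, m: Fraction) -> int:
        return int(spins[site] - m)

    vec = np.zeros(int(np.prod(dims)))
    S_pq, S_rt, S, M = state.S_AB, state.S_CD, state.S_tot, state.S_tot_z
    for m_pq in spin_range(-S_pq, S_pq):
        m_rt = M - m_pq
        if abs(m_rt) > S_rt:
            continue
        c_outer = clebsch_gordan(S_pq, m_pq, S_rt, m_rt, S, M)
        if c_outer == 0.0:
            continue
        for m_p in spin_range(-spins[p], spins[p]):
            m_q = m_pq - m_p
            if abs(m_q) > spins[q]:
                continue
            c1 = clebsch_gordan(spins[p], m_p, spins[q], m_q, S_pq, m_pq)
            if c1 == 0.0:
                continue
            for m_r in spin_range(-spins[r], spins[r]):
                m_t = m_rt - m_r
                if abs(m_t) > spins[t]:
                    continue
                c2 = clebsch_gordan(spins[r], m_r, spins[t], m_t, S_rt, m_rt)
                if c2 == 0.0:
                    continue
                m_site = {p: m_p, q: m_q, r: m_r, t: m_t}
                flat = sum(strides[k] * idx_of(k, m_site[k]) for k in range(4))
                vec[flat] += c_outer * c1 * c2
    return vec


def coupled_basis_unitary(spins, scheme=((0, 1), (2, 3))):
    """Unitary U from the product to the coupled basis.

    Columns are coupled states ordered by (S_pair1, S_pair2, S_tot) ascending
    with S_tot^z descending; ``scheme`` pairs site indices, default (AB)(CD).
    Returns ``(U, labels)`` with U[:, k] the product-basis vector of
    ``labels[k]``; U is real orthogonal.  In the (AB)(CD) scheme U^T H U is
    diagonal for the HDvV tetramer; other pairings give only a block-diagonal
    form.
    """
    spins = _check_spins(spins)
    labels = _coupled_labels(spins, scheme)
    dim = int(np.prod([twice(s) + 1 for s in spins]))
    if len(labels) != dim:
        raise AssertionError("coupled basis must be complete")
    U = np.empty((dim, dim))
    for k, st in enumerate(labels):
        U[:, k] = coupled_state_vector(spins, st, scheme)
    return U, labels


# ---------------------------------------------------------------------------
# Griffith closed form
# ---------------------------------------------------------------------------

def griffith_energy(s, S_AB, S_CD, S_tot, params: ExchangeParameters) -> float:
    """Closed-form HDvV eigenvalue of |(S_AB S_CD) S_tot S_tot^z>."""
    s = as_half_integer(s, "s")
    x = float(as_half_integer(S_AB) * (as_half_integer(S_AB) + 1))
    y = float(as_half_integer(S_CD) * (as_half_integer(S_CD) + 1))
    st = float(as_half_integer(S_tot) * (as_half_integer(S_tot) + 1))
    return (params.j2b / 2.0) * (x + y - 4.0 * float(s * (s + 1))) \
        + (params.j4b / 2.0) * (st - x - y)


def griffith_energies(s, params: ExchangeParameters) -> SpinLadder:
    """Full spin ladder over all (S_AB, S_CD, S_tot), relative to the ground
    level, sorted ascending (S_tot^z = 0 representatives)."""
    s = as_half_integer(s, "s")
    items = []
    for S_AB in spin_range(0, 2 * s):
        for S_CD in spin_range(0, 2 * s):
            for S_tot in couple(S_AB, S_CD):
                e = griffith_energy(s, S_AB, S_CD, S_tot, params)
                items.append((e, CoupledState(S_AB, S_CD, S_tot, 0)))
    items.sort(key=lambda t: (t[0], t[1].S_AB, t[1].S_CD, t[1].S_tot))
    e0 = items[0][0]
    entries = tuple(LadderEntry(st, e - e0) for e, st in items)
    return SpinLadder(entries, params.unit)


# ---------------------------------------------------------------------------
# Spin expectation values
# ---------------------------------------------------------------------------

def spin_expectations(state, spins) -> tuple[float, float, float]:
    """(<S_A^2>, <(S_A+S_B)^2>, <(S_A+S_B+S_C)^2>) of a normalized state.

    ``state`` is either a product-basis vector or a :class:`CoupledState`
    (converted via its Clebsch-Gordan expansion).
    """
    spins = _check_spins(spins)
    if isinstance(state, CoupledState):
        vec = coupled_state_vector(spins, state)
    else:
        vec = np.asarray(state, dtype=float)
    norm = np.linalg.norm(vec)
    if abs(norm - 1.0) > 1e-8:
        raise ValueError(f"state must be normalized, |norm - 1| = {abs(norm - 1.0):.2e}")
    dim = vec.size
    out = []
    for last in (0, 1, 2):
        op = sum(float(spins[i] * (spins[i] + 1)) for i in range(last + 1)) * np.eye(dim)
        for i in range(last + 1):
            for j in range(i + 1, last + 1):
                op += 2.0 * pair_coupling_operator(spins, i, j)
        out.append(float(vec @ op @ vec))
    return tuple(out)
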