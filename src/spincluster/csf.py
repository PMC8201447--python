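"""Genealogically coupled configuration state functions (CSFs).

A CSF over ``n_o`` singly occupied orbitals is encoded as a path on the
branching diagram: a sequence of spin increments of +-1/2, one per orbital,
whose partial sums (the cumulative spins) stay non-negative.  Each path is an
eigenfunction of every cumulative spin-squared operator, in particular of the
total S^2 with eigenvalue S(S+1) where S is the final cumulative spin.

The expansion of a CSF in spin-orbital product states (Slater determinants of
the fixed orbital set) is a product of elementary Clebsch-Gordan factors for
coupling one spin-1/2 at a time; :func:`csf_to_determinants` evaluates it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import sparse

from .util import as_half_integer, twice

__all__ = [
    "GenealogicalCSF",
    "csf_to_determinants",
    "full_csf_basis",
    "sz_determinants",
    "determinant_expansion_matrix",
]


@dataclass(frozen=True)
class GenealogicalCSF:
    """A spin-coupling path: one +-1/2 step per singly occupied orbital.

    Parameters
    ----------
    steps:
        Tuple of +1/-1 entries, each meaning a spin increment of +1/2 or
        -1/2 (in units of hbar) for the corresponding orbital.
    """

    steps: tuple[int, ...]

    def __post_init__(self):
        if not self.steps:
            raise ValueError("a CSF needs at least one orbital")
        if any(s not in (1, -1) for s in self.steps):
            raise ValueError("steps must be +-1 (meaning spin increments of +-1/2)")
        running = 0
        for k, s in enumerate(self.steps, start=1):
            running += s
            if running < 0:
                raise ValueError(f"negative cumulative spin after orbital {k}")

    @classmethod
    def from_spins(cls, increments) -> "GenealogicalCSF":
        """Build from +-1/2 increments (Fractions, floats or +-1 ints)."""
        steps = []
        for x in increments:
            f = as_half_integer(x, "step")
            if abs(f) == Fraction(1, 2):
                steps.append(1 if f > 0 else -1)
            elif abs(f) == 1:
                steps.append(int(f))
            else:
                raise ValueError(f"step must be +-1/2, got {x!r}")
        return cls(tuple(steps))

    @property
    def n_orbitals(self) -> int:
        return len(self.steps)

    @property
    def cumulative_spins(self) -> tuple[Fraction, ...]:
        out, running = [], 0
        for s in self.steps:
            running += s
            out.append(Fraction(running, 2))
        return tuple(out)

    @property
    def spin(self) -> Fraction:
        """Total spin S (final cumulative value)."""
        return Fraction(sum(self.steps), 2)

    def cumulative_at(self, k: int) -> Fraction:
        """Cumulative spin after the first k orbitals (k=0 gives 0)."""
        return Fraction(sum(self.steps[:k]), 2)

    def __repr__(self):  # compact: u/d per orbital
        return "CSF[" + "".join("u" if s > 0 else "d" for s in self.steps) + "]"


def _step_coefficient(two_S_prev: int, two_M_prev: int, step: int, sigma: int) -> float:
    """Elementary genealogical CG factor <S' M'; 1/2 sigma/2 | S M>.

    ``step`` is +-1 (S = S' +- 1/2), ``sigma`` is +-1 (the new orbital's spin
    projection +-1/2).  Condon-Shortley phases.
    """
    two_S = two_S_prev + step
    two_M = two_M_prev + sigma
    if abs(two_M) > two_S:
        return 0.0
    if step == 1:
        if sigma == 1:
            num, den = two_S + two_M, 2 * two_S
        else:
            num, den = two_S - two_M, 2 * two_S
        return math.sqrt(num / den)
    if sigma == 1:
        return -math.sqrt((two_S - two_M + 2) / (2 * two_S + 4))
    return math.sqrt((two_S + two_M + 2) / (2 * two_S + 4))


def csf_to_determinants(csf: GenealogicalCSF, Sz) -> dict[tuple[int, ...], float]:
    """Expand a CSF into spin-orbital occupation strings at projection Sz.

    Returns a mapping from sigma-strings (tuples of +-1, one per orbital,
    meaning spin up/down) to real coefficients.  The squared coefficients sum
    to one and the resulting vector is a total-S^2 eigenvector with eigenvalue
    S(S+1).
    """
    two_Sz = twice(as_half_integer(Sz, "Sz"))
    two_S = 2 * csf.spin
    if abs(two_Sz) > two_S:
        raise ValueError(f"|Sz|={abs(Fraction(two_Sz, 2))} exceeds S={csf.spin}")
    n = csf.n_orbitals
    # cumulative 2S along the path, prefixed with 0
    two_S_path = [0]
    for s in csf.steps:
        two_S_path.append(two_S_path[-1] + s)

    states: dict[tuple[int, ...], float] = {(): 1.0}
    for k, step in enumerate(csf.steps):
        remaining = n - k - 1
        nxt: dict[tuple[int, ...], float] = {}
        for prefix, coeff in states.items():
            two_M_prev = sum(prefix)
            for sigma in (1, -1):
                two_M = two_M_prev + sigma
                if abs(two_M) > two_S_path[k + 1]:
                    continue
                if abs(two_Sz - two_M) > remaining:
                    continue  # cannot reach the target projection
                c = _step_coefficient(two_S_path[k], two_M_prev, step, sigma)
                if c == 0.0:
                    continue
                nxt[prefix + (sigma,)] = nxt.get(prefix + (sigma,), 0.0) + coeff * c
        states = nxt
    return {det: c for det, c in states.items() if c != 0.0}


def full_csf_basis(n_o: int, S) -> list[GenealogicalCSF]:
    """All genealogical CSFs of an ``n_o``-orbital spin system with total spin S.

    Deterministic order: depth-first with the +1/2 step explored first.  The
    count equals the van Vleck-Sherman dimension.
    """
    two_S = twice(as_half_integer(S, "S"))
    if two_S < 0 or two_S > n_o or (n_o - two_S) % 2:
        return []
    out: list[GenealogicalCSF] = []
    path: list[int] = []

    def rec(k: int, running: int):
        if k == n_o:
            if running == two_S:
                out.append(GenealogicalCSF(tuple(path)))
            return
        for step in (1, -1):
            nxt = running + step
            if nxt < 0 or abs(two_S - nxt) > n_o - k - 1:
                continue
            path.append(step)
            rec(k + 1, nxt)
            path.pop()

    rec(0, 0)
    return out


def sz_determinants(n_o: int, Sz) -> list[tuple[int, ...]]:
    """All sigma-strings of n_o spins with total projection Sz (lexicographic,
    spin-up first)."""
    two_Sz = twice(as_half_integer(Sz, "Sz"))
    if (n_o - two_Sz) % 2 or abs(two_Sz) > n_o:
        return []
    n_up = (n_o + two_Sz) // 2
    import itertools

    dets = []
    for ups in itertools.combinations(range(n_o), n_up):
        det = [-1] * n_o
        for i in ups:
            det[i] = 1
        dets.append(tuple(det))
    dets.sort(reverse=True)
    return dets


def determinant_expansion_matrix(basis: list[GenealogicalCSF], Sz,
                                 dets: list[tuple[int, ...]] | None = None):
    """Sparse matrix C with C[d, mu] = coefficient of determinant d in CSF mu.

    Columns are orthonormal (distinct genealogical paths are orthogonal).
    Returns ``(C, dets)``.
    """
    if dets is None:
        dets = sz_determinants(basis[0].n_orbitals, Sz)
    index = {d: i for i, d in enumerate(dets)}
    rows, cols, vals = [], [], []
    for mu, csf in enumerate(basis):
        for det, c in csf_to_determinants(csf, Sz).items():
            rows.append(index[det])
            cols.append(mu)
            vals.append(c)
    C = sparse.csr_array(
        (np.asarray(vals), (np.asarray(rows), np.asarray(cols))),
        shape=(len(dets), len(basis)),
    )
    return C, dets
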