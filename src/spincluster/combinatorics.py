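"""Spin-coupling combinatorics for exchange-coupled open-shell clusters.

Provides the Weyl-Paldus dimension of a CAS(N e, n o) spin sector, the van
Vleck-Sherman count of spin-exchange configurations (all orbitals singly
occupied), genealogical branching diagrams with optional forbidden nodes, and
the enumeration of Hund-allowed coupling paths for a cluster of high-spin
magnetic sites in atom-separated orbital ordering.

All counts use exact integer arithmetic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache
from math import comb

from .csf import GenealogicalCSF
from .util import as_half_integer, couple, twice

__all__ = [
    "SiteSpec",
    "BranchingNode",
    "BranchingDiagram",
    "CouplingChannel",
    "NonHundPathError",
    "weyl_paldus_dim",
    "vanvleck_sherman_count",
    "build_branching_diagram",
    "enumerate_hund_paths",
    "hund_allowed_nodes",
    "classify_channel",
]


@dataclass(frozen=True)
class SiteSpec:
    """A high-spin magnetic site: one unpaired electron per orbital."""

    label: str
    local_spin: Fraction

    def __post_init__(self):
        object.__setattr__(self, "local_spin", as_half_integer(self.local_spin, "local_spin"))
        if self.local_spin <= 0:
            raise ValueError("local_spin must be positive")

    @property
    def n_orbitals(self) -> int:
        return twice(self.local_spin)


@dataclass(frozen=True)
class BranchingNode:
    """Node (k, S) of a branching diagram with its path count."""

    k: int
    S: Fraction
    weight: int


@dataclass
class BranchingDiagram:
    """Genealogical branching diagram: node weights count left-to-right paths.

    ``weights[(k, 2S)]`` is the number of paths from the origin to node
    (k, S) that avoid every forbidden node; nodes not stored have weight 0.
    """

    n_o: int
    S_target: Fraction
    forbidden: frozenset[tuple[int, Fraction]] = field(default_factory=frozenset)
    weights: dict[tuple[int, int], int] = field(default_factory=dict)

    def weight(self, k: int, S) -> int:
        return self.weights.get((k, twice(S)), 0)

    def node(self, k: int, S) -> BranchingNode:
        S = as_half_integer(S)
        return BranchingNode(k, S, self.weight(k, S))

    @property
    def terminal_weight(self) -> int:
        return self.weight(self.n_o, self.S_target)


def weyl_paldus_dim(N: int, n: int, S) -> int:
    """Weyl-Paldus dimension of the CAS(N e, n o) space with total spin S.

    f(N, n, S) = (2S+1)/(n+1) * C(n+1, N/2 - S) * C(n+1, N/2 + S + 1),
    evaluated exactly in integer arithmetic.
    """
    two_S = twice(as_half_integer(S, "S"))
    if two_S < 0:
        raise ValueError("S must be non-negative")
    if N < 0 or n < 0 or N > 2 * n:
        raise ValueError(f"need 0 <= N <= 2n, got N={N}, n={n}")
    if two_S > N:
        raise ValueError(f"S={Fraction(two_S, 2)} exceeds N/2 for N={N}")
    if (N - two_S) % 2:
        raise ValueError(f"N={N} and 2S={two_S} must have equal parity")
    a = (N - two_S) // 2
    b = (N + two_S) // 2 + 1
    return (two_S + 1) * comb(n + 1, a) * comb(n + 1, b) // (n + 1)


def vanvleck_sherman_count(n_o: int, S) -> int:
    """van Vleck-Sherman count of spin-exchange CSFs.

    g(n_o, S) = C(n_o, n_o/2 - S) - C(n_o, n_o/2 - S - 1): the number of
    spin couplings of n_o singly occupied orbitals to total spin S.  Equals
    weyl_paldus_dim(n_o, n_o, S) restricted to singly occupied configurations.
    """
    two_S = twice(as_half_integer(S, "S"))
    if two_S < 0:
        raise ValueError("S must be non-negative")
    if n_o < 1:
        raise ValueError("n_o must be >= 1")
    if two_S > n_o or (n_o - two_S) % 2:
        raise ValueError(f"2S={two_S} must not exceed n_o={n_o} and match its parity")
    a = (n_o - two_S) // 2
    return comb(n_o, a) - (comb(n_o, a - 1) if a >= 1 else 0)


def build_branching_diagram(n_o: int, S_target, forbidden_nodes=None) -> BranchingDiagram:
    """Branching diagram with forward path counts, honouring forbidden nodes.

    ``forbidden_nodes`` is an iterable of (k, S) pairs whose weight is forced
    to zero (and therefore propagates: no path may pass through them).  With
    no forbidden nodes the terminal weight at (n_o, S_target) equals the van
    Vleck-Sherman count.
    """
    if n_o < 1:
        raise ValueError("n_o must be >= 1")
    S_target = as_half_integer(S_target, "S_target")
    forbidden = frozenset(
        (k, as_half_integer(S)) for k, S in (forbidden_nodes or ())
    )
    fkeys = {(k, twice(S)) for k, S in forbidden}
    weights: dict[tuple[int, int], int] = {(0, 0): 1}
    for k in range(1, n_o + 1):
        for two_S in range(k % 2, k + 1, 2):
            if (k, two_S) in fkeys:
                continue
            w = weights.get((k - 1, two_S - 1), 0) + weights.get((k - 1, two_S + 1), 0)
            if w:
                weights[(k, two_S)] = w
    return BranchingDiagram(n_o, S_target, forbidden, weights)


@dataclass(frozen=True)
class CouplingChannel:
    """Channel label of a Hund-allowed path of a four-site cluster.

    ``pair_spins`` holds (S_AB, S_CD); for a singlet tetramer S_CD = S_AB is
    fixed by angular-momentum conservation, otherwise S_CD is undetermined by
    the cumulative path and left as None.  ``channel_tag`` is the intermediate
    pair spin k of the Gamma(k) x Gamma(k) channel.
    """

    pair_spins: tuple[Fraction, Fraction | None]
    cumulative: tuple[tuple[str, Fraction], ...] = ()
    channel_tag: Fraction | None = None

    def cumulative_spin(self, label: str) -> Fraction:
        return dict(self.cumulative)[label]


class NonHundPathError(ValueError):
    """Raised when a coupling path violates the Hund (maximal-site-spin) rule."""


def _coupled_totals(start: Fraction, spins) -> set[Fraction]:
    totals = {start}
    for s in spins:
        totals = {t for a in totals for t in couple(a, s)}
    return totals


def hund_allowed_nodes(sites, S_total) -> dict[int, set[Fraction]]:
    """Allowed cumulative spins at each diagram column for Hund-only coupling.

    A node (k, S), with k falling j orbitals into site t, is Hund-allowed iff
    (a) S is reachable by coupling sites 1..t-1 at their maximal local spins
    with the partial site t at its maximal partial spin j/2, and (b) the
    target S_total is reachable from S by coupling the rest of site t at
    maximal spin with the remaining sites at maximal spin.  Paths through the
    complementary (non-Hund) nodes have vanishing weight in the Hund sector.
    """
    return _hund_allowed_nodes_cached(tuple(sites), as_half_integer(S_total, "S_total"))


@lru_cache(maxsize=256)
def _hund_allowed_nodes_cached(sites: tuple[SiteSpec, ...],
                               S_total: Fraction) -> dict[int, set[Fraction]]:
    allowed: dict[int, set[Fraction]] = {0: {Fraction(0)}}
    spins = [site.local_spin for site in sites]
    k = 0
    for t, site in enumerate(sites):
        n_t = site.n_orbitals
        for j in range(1, n_t + 1):
            k += 1
            forward = _coupled_totals(Fraction(0), spins[:t] + [Fraction(j, 2)])
            rest = [Fraction(n_t - j, 2)] + spins[t + 1:]
            allowed[k] = {
                S for S in forward if S_total in _coupled_totals(S, rest)
            }
    return allowed


def enumerate_hund_paths(sites: list[SiteSpec], S_total) -> list[GenealogicalCSF]:
    """Hund-allowed genealogical paths of a cluster in atom-separated ordering.

    Enumerates the spin-coupling paths that keep every site at its maximal
    local spin (the non-gray paths of the cluster branching diagram); returns
    the empty list when S_total is unreachable.
    """
    if not sites:
        raise ValueError("sites must be nonempty")
    S_total = as_half_integer(S_total, "S_total")
    allowed = hund_allowed_nodes(sites, S_total)
    n_o = sum(site.n_orbitals for site in sites)
    out: list[GenealogicalCSF] = []
    path: list[int] = []

    def rec(k: int, two_S: int):
        if k == n_o:
            if two_S == twice(S_total):
                out.append(GenealogicalCSF(tuple(path)))
            return
        ok = allowed[k + 1]
        for step in (1, -1):
            nxt = two_S + step
            if nxt < 0 or Fraction(nxt, 2) not in ok:
                continue
            path.append(step)
            rec(k + 1, nxt)
            path.pop()

    rec(0, 0)
    return out


def classify_channel(path: GenealogicalCSF, sites: list[SiteSpec]) -> CouplingChannel:
    """Channel of a Hund-allowed path, read off at the site-block boundaries.

    Raises :class:`NonHundPathError` for a path that passes through a
    non-Hund node (the channel is undefined there).
    """
    S_total = path.spin
    allowed = hund_allowed_nodes(sites, S_total)
    running = 0
    for k, step in enumerate(path.steps, start=1):
        running += step
        if Fraction(running, 2) not in allowed[k]:
            raise NonHundPathError(
                f"path visits non-Hund node (k={k}, S={Fraction(running, 2)})"
            )
    boundaries = list(itertools.accumulate(site.n_orbitals for site in sites))
    labels = []
    acc = ""
    for site, b in zip(sites, boundaries):
        acc += site.label
        labels.append((f"S_{acc}", path.cumulative_at(b)))
    cumulative = tuple(labels[:-1])  # the final boundary is just S_total
    if len(sites) == 4:
        S_AB = path.cumulative_at(boundaries[1])
        S_CD = S_AB if S_total == 0 else None
        return CouplingChannel((S_AB, S_CD), cumulative, channel_tag=S_AB)
    S_12 = path.cumulative_at(boundaries[min(1, len(boundaries) - 1)])
    return CouplingChannel((S_12, None), cumulative, channel_tag=S_12)
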