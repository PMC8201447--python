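"""Extraction of (J_2B, J_4B) from state-energy gaps and ladder prediction.

The HDvV tetramer's singlet manifold spans the channels S_AB = S_CD = 0..2s;
its total width is |J_4B - J_2B| * 2s(2s+1) and the maximal-spin state
|(2s,2s), 4s, 0> sits 2s(4s+1) * J_4B above the |(2s,2s), 0, 0> singlet.
Three states - the two extreme singlets and the maximal-spin state - therefore
determine both exchange constants exactly: the singlet width fixes
|J_4B - J_2B| (the sign follows from which channel is the ground state) and
the maximal-spin gap fixes J_4B.  For s = 5/2 the two coefficients are the
familiar 30 and 55.

Energies can be supplied in meV or cm^-1; conversion uses the CODATA value
1 cm^-1 = 0.1239841984 meV.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

from .hdvv import (
    CoupledState,
    ExchangeParameters,
    LadderEntry,
    SpinLadder,
    VALID_UNITS,
    griffith_energy,
)
from .util import as_half_integer, spin_range

__all__ = [
    "StateEnergyInput",
    "extract_couplings",
    "predict_ladder",
    "convert_units",
    "CM1_IN_MEV",
]

#: hc * 1 cm^-1 expressed in meV (CODATA)
CM1_IN_MEV = 0.1239841984


def convert_units(value: float, from_unit: str, to_unit: str) -> float:
    """Convert an energy between cm^-1 and meV (exact inverse round trip)."""
    for u in (from_unit, to_unit):
        if u not in VALID_UNITS:
            raise ValueError(f"unknown unit {u!r}; expected one of {VALID_UNITS}")
    if from_unit == to_unit:
        return value
    if from_unit == "cm-1":
        return value * CM1_IN_MEV
    return value / CM1_IN_MEV


@dataclass(frozen=True)
class StateEnergyInput:
    """The three-state mapping input.

    gap_singlet:
        E(highest singlet) - E(lowest singlet), the width of the singlet
        manifold.
    gap_smax:
        E(maximal-spin state) - E(ground singlet).
    ground_channel:
        S_AB of the ground singlet: 2s when J_4B > J_2B (pair spins aligned
        along the two-bond class), 0 when J_4B < J_2B.
    """

    gap_singlet: float
    gap_smax: float
    ground_channel: Fraction
    unit: str

    def __post_init__(self):
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unit must be one of {VALID_UNITS}")
        if self.gap_singlet < 0 or self.gap_smax < 0:
            raise ValueError("gaps must be non-negative")
        object.__setattr__(self, "ground_channel",
                           as_half_integer(self.ground_channel, "ground_channel"))


def _coefficients(s: Fraction) -> tuple[float, float]:
    """(singlet-width, maximal-spin) coefficients: 2s(2s+1) and 2s(4s+1)."""
    width = float(2 * s * (2 * s + 1))
    smax = float(2 * s * (4 * s + 1))
    return width, smax


def extract_couplings(inp: StateEnergyInput, s,
                      unit_out: str = "cm-1") -> ExchangeParameters:
    """Solve the three-state mapping for (J_2B, J_4B).

    For s = 5/2: |J_4B - J_2B| = gap_singlet / 30 with the sign set by the
    ground channel, and 55 J_4B = gap_smax minus the singlet width when the
    ground channel is 0 (the maximal-spin state lives in the (2s, 2s)
    channel).  A ferromagnetic (negative) constant is allowed but unexpected
    for these clusters.
    """
    s = as_half_integer(s, "s")
    if inp.ground_channel not in (Fraction(0), 2 * s):
        raise ValueError(f"ground_channel must be 0 or {2 * s}")
    width_coeff, smax_coeff = _coefficients(s)
    if inp.ground_channel == 2 * s:
        diff = inp.gap_singlet / width_coeff          # J_4B - J_2B > 0
        j4b = inp.gap_smax / smax_coeff
    else:
        diff = -inp.gap_singlet / width_coeff
        j4b = (inp.gap_smax - inp.gap_singlet) / smax_coeff
    j2b = j4b - diff
    return ExchangeParameters(
        convert_units(j2b, inp.unit, unit_out),
        convert_units(j4b, inp.unit, unit_out),
        unit_out,
    )


def predict_ladder(params: ExchangeParameters, s, ground_channel) -> SpinLadder:
    """Singlet ladder plus the maximal-spin state, in meV.

    The ladder is re-zeroed on the ground channel's singlet; in the
    antiferromagnetic regime expected for these clusters that state is the
    lowest of the predicted set.  Should a ferromagnetic parameter choice
    push another state below it, the zero falls on the actual minimum so the
    ladder stays a non-negative ascending sequence.
    """
    s = as_half_integer(s, "s")
    ground_channel = as_half_integer(ground_channel, "ground_channel")
    if ground_channel not in (Fraction(0), 2 * s):
        raise ValueError(f"ground_channel must be 0 or {2 * s}")
    states = [CoupledState(S_d, S_d, 0, 0) for S_d in spin_range(0, 2 * s)]
    states.append(CoupledState(2 * s, 2 * s, 4 * s, 0))
    e0 = griffith_energy(s, ground_channel, ground_channel, 0, params)
    items = []
    for st in states:
        e = griffith_energy(s, st.S_AB, st.S_CD, st.S_tot, params) - e0
        items.append((convert_units(e, params.unit, "meV"), st))
    floor = min(e for e, _ in items)
    if floor < 0.0:
        items = [(e - floor, st) for e, st in items]
    items.sort(key=lambda t: (t[0], t[1].S_AB))
    return SpinLadder(tuple(LadderEntry(st, e) for e, st in items), "meV")
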