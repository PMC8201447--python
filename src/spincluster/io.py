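"""File output: Matrix Market export and TSV reports.

Energies are written with six significant digits; state labels follow the
|(S_AB, S_CD), S_tot, S_tot^z> convention.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from scipy import io as spio
from scipy import sparse

from .exchange import BlockProfile
from .hdvv import SpinLadder

__all__ = [
    "export_sparse",
    "read_sparse",
    "write_ladder_tsv",
    "write_counts_tsv",
    "write_block_profile_tsv",
]


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def export_sparse(H, path) -> Path:
    """Write a symmetric sparse Hamiltonian in Matrix Market coordinate
    format (general symmetry field, deterministic entry order)."""
    path = Path(path)
    coo = sparse.coo_array(H)
    order = np.lexsort((coo.coords[0], coo.coords[1]))  # column-major, as mmwrite
    coo = sparse.coo_array(
        (coo.data[order], (coo.coords[0][order], coo.coords[1][order])),
        shape=coo.shape,
    )
    spio.mmwrite(path, coo, symmetry="general")
    return path


def read_sparse(path) -> sparse.csr_array:
    return sparse.csr_array(spio.mmread(Path(path)))


def write_ladder_tsv(ladder: SpinLadder, path, input_energies=None) -> Path:
    """TSV report of a spin ladder: state, model energy, optional input
    energy, unit."""
    path = Path(path)
    lines = ["state\tE_model\tE_input\tunit"]
    for entry in ladder.entries:
        e_in = ""
        if input_energies is not None:
            v = input_energies.get(entry.state)
            e_in = _fmt(v) if v is not None else ""
        lines.append(f"{entry.state.label()}\t{_fmt(entry.energy)}\t{e_in}\t{ladder.unit}")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_counts_tsv(rows: list[tuple[str, int]], path) -> Path:
    """TSV of labelled exact counts."""
    path = Path(path)
    lines = ["quantity\tcount"] + [f"{label}\t{count}" for label, count in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


def write_block_profile_tsv(profile: BlockProfile, path) -> Path:
    path = Path(path)
    lines = [
        "metric\tvalue",
        f"nnz\t{profile.nnz}",
        f"cross_block_max\t{_fmt(profile.cross_block_max)}",
        f"sign_coherent\t{str(profile.sign_coherent).lower()}",
    ]
    path.write_text("\n".join(lines) + "\n")
    return path
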