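"""Plain-text structure and trajectory I/O: XYZ, extended XYZ, PDB.

Extended-XYZ comment lines carry ``Lattice="ax ay az bx by bz cx cy cz"``
for periodic frames, which is enough to round-trip the orthorhombic cells
the rest of the package produces.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable

import numpy as np

from .datamodel import Atom, AtomSet, BondSet, Cell, Configuration
from .errors import ValidationError


def write_xyz(config: Configuration, path, comment: str = "") -> None:
    """Write a single-frame XYZ file (element + Cartesian Angstrom)."""
    if config.cell.periodic and not comment:
        L = config.cell
        comment = (f'Lattice="{L.a} 0.0 0.0 0.0 {L.b} 0.0 0.0 0.0 {L.c}" '
                   'Properties=species:S:1:pos:R:3')
    lines = [str(config.n_atoms), comment]
    for el, (x, y, z) in zip(config.elements, config.coordinates):
        lines.append(f"{el} {x:.10f} {y:.10f} {z:.10f}")
    Path(path).write_text("\n".join(lines) + "\n")


_LATTICE_RE = re.compile(r'Lattice="([^"]+)"')


def _parse_frame(lines: list[str], start: int) -> tuple[Configuration, int]:
    n = int(lines[start].split()[0])
    comment = lines[start + 1]
    m = _LATTICE_RE.search(comment)
    cell = Cell()
    if m:
        vals = np.array([float(v) for v in m.group(1).split()]).reshape(3, 3)
        cell = Cell(vals[0, 0], vals[1, 1], vals[2, 2], periodic=True)
    atoms, coords = AtomSet(), []
    for line in lines[start + 2 : start + 2 + n]:
        parts = line.split()
        atoms.append(Atom(parts[0]))
        coords.append([float(v) for v in parts[1:4]])
    return Configuration(atoms, BondSet(), np.array(coords), cell), start + 2 + n


def read_xyz(path) -> Configuration:
    """Read the first frame of an (extended) XYZ file."""
    lines = Path(path).read_text().splitlines()
    config, _ = _parse_frame(lines, 0)
    return config


def read_xyz_frames(path) -> list[Configuration]:
    """Read every frame of a multi-frame (extended) XYZ file."""
    lines = Path(path).read_text().splitlines()
    frames, pos = [], 0
    while pos < len(lines) and lines[pos].strip():
        frame, pos = _parse_frame(lines, pos)
        frames.append(frame)
    return frames


def write_xyz_frames(frames: Iterable[Configuration], path) -> None:
    """Write a multi-frame extended-XYZ trajectory file."""
    chunks = []
    for config in frames:
        comment = ""
        if config.cell.periodic:
            L = config.cell
            comment = (f'Lattice="{L.a} 0.0 0.0 0.0 {L.b} 0.0 0.0 0.0 {L.c}" '
                       'Properties=species:S:1:pos:R:3')
        body = "\n".join(
            f"{el} {x:.10f} {y:.10f} {z:.10f}"
            for el, (x, y, z) in zip(config.elements, config.coordinates)
        )
        chunks.append(f"{config.n_atoms}\n{comment}\n{body}")
    Path(path).write_text("\n".join(chunks) + "\n")


def write_pdb(config: Configuration, path, molecule_ids: list[int] | None = None) -> None:
    """Write a PDB file (HETATM records; CRYST1 when periodic).

    ``molecule_ids`` assigns a residue number per atom; by default all atoms
    share residue 1.
    """
    if config.n_atoms > 99999:
        raise ValidationError("PDB format supports at most 99999 atoms")
    lines = []
    if config.cell.periodic:
        c = config.cell
        lines.append(
            f"CRYST1{c.a:9.3f}{c.b:9.3f}{c.c:9.3f}"
            f"{c.alpha:7.2f}{c.beta:7.2f}{c.gamma:7.2f} P 1           1"
        )
    if molecule_ids is None:
        molecule_ids = [1] * config.n_atoms
    for idx, (atom, (x, y, z)) in enumerate(zip(config.atom_set, config.coordinates), 1):
        el = atom.element
        name = (atom.name or f"{el}{idx % 100}")[:4]
        res = molecule_ids[idx - 1] % 10000
        lines.append(
            f"HETATM{idx:5d} {name:<4s} MOL  {res:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {el:>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
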