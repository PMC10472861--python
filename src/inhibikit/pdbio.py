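"""PDB reading and writing for receptors, pose sets, and trajectories.

Reading goes through Biopython's PDB parser.  Writing uses a small
fixed-width formatter because multi-model pose files need a per-model
energy remark (``REMARK VINA RESULT:`` dialect) that the stock writer
cannot emit; round-tripping through the Biopython reader is covered by
tests.  Only the coordinate records matter here — no topology, occupancy
or B-factor semantics are interpreted.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser

from .structures import Atom, Pose, Trajectory

__all__ = [
    "read_structure",
    "read_poses",
    "read_trajectory",
    "write_structure",
    "write_poses",
    "write_trajectory",
]

_ENERGY_REMARK = re.compile(r"^REMARK\s+(?:VINA\s+RESULT|ENERGY):\s*(-?\d+\.?\d*)")


def _guess_element(bio_atom) -> str:
    el = (bio_atom.element or "").strip()
    if el:
        return el.capitalize() if len(el) > 1 else el.upper()
    name = bio_atom.get_name().strip()
    return name[0].upper()


def _atoms_from_model(model) -> tuple[Atom, ...]:
    atoms = []
    for chain in model:
        for residue in chain:
            for a in residue:
                atoms.append(
                    Atom(
                        serial=a.get_serial_number() or len(atoms) + 1,
                        name=a.get_name(),
                        element=_guess_element(a),
                        res_name=residue.get_resname().strip(),
                        res_seq=residue.get_id()[1],
                        chain=chain.get_id(),
                        x=float(a.coord[0]),
                        y=float(a.coord[1]),
                        z=float(a.coord[2]),
                    )
                )
    return tuple(atoms)


def _parse(path):
    parser = PDBParser(QUIET=True)
    return parser.get_structure(Path(path).stem, str(path))


def read_structure(path) -> tuple[Atom, ...]:
    """Atoms of the first model of a PDB file."""
    structure = _parse(path)
    model = next(iter(structure))
    return _atoms_from_model(model)


def _model_energies(path) -> list[float | None]:
    """Per-model energies scanned from REMARK lines between MODEL records."""
    energies: list[float | None] = []
    current: float | None = None
    seen_model = False
    with open(path) as fh:
        for line in fh:
            if line.startswith("MODEL"):
                if seen_model:
                    energies.append(current)
                seen_model = True
                current = None
            else:
                m = _ENERGY_REMARK.match(line)
                if m:
                    current = float(m.group(1))
    if seen_model:
        energies.append(current)
    return energies


def read_poses(path, compound_id: str | None = None) -> list[Pose]:
    """Docked poses from a multi-model PDB with per-model energy remarks."""
    structure = _parse(path)
    energies = _model_energies(path)
    poses = []
    for i, model in enumerate(structure):
        energy = energies[i] if i < len(energies) and energies[i] is not None else np.nan
        if not np.isfinite(energy):
            warnings.warn(f"model {i + 1} in {path} has no energy remark; skipped", stacklevel=2)
            continue
        poses.append(
            Pose(
                compound_id=compound_id or Path(path).stem,
                atoms=_atoms_from_model(model),
                energy=energy,
                run_id=i,
            )
        )
    return poses


def read_trajectory(path, dt_ps: float = 100.0) -> Trajectory:
    """A multi-model PDB as an ordered frame stack over a fixed roster."""
    structure = _parse(path)
    models = list(structure)
    if len(models) < 2:
        raise ValueError(f"{path} has {len(models)} model(s); a trajectory needs >= 2")
    roster = _atoms_from_model(models[0])
    coords = np.empty((len(models), len(roster), 3))
    for i, model in enumerate(models):
        atoms = _atoms_from_model(model)
        if len(atoms) != len(roster):
            raise ValueError(f"frame {i + 1} atom count differs from frame 1")
        coords[i] = [[a.x, a.y, a.z] for a in atoms]
    return Trajectory(atoms=roster, coords=coords, dt_ps=dt_ps)


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def _format_atom_line(a: Atom, serial: int) -> str:
    record = "HETATM" if a.res_name in ("LIG", "UNL", "HOH", "CU") or a.is_metal else "ATOM  "
    name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
    return (
        f"{record}{serial:>5d} {name:<4.4s} {a.res_name:<3.3s} {a.chain:1.1s}"
        f"{a.res_seq:>4d}    {a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {a.element.upper():>2.2s}"
    )


def write_structure(path, atoms) -> None:
    lines = [_format_atom_line(a, i + 1) for i, a in enumerate(atoms)]
    Path(path).write_text("\n".join(lines) + "\nEND\n")


def write_poses(path, poses) -> None:
    """Multi-model PDB with a Vina-style energy remark inside each model."""
    lines = []
    for i, pose in enumerate(poses):
        lines.append(f"MODEL {i + 1:>8d}")
        lines.append(f"REMARK VINA RESULT: {pose.energy:10.3f}")
        lines.extend(_format_atom_line(a, j + 1) for j, a in enumerate(pose.atoms))
        lines.append("ENDMDL")
    Path(path).write_text("\n".join(lines) + "\nEND\n")


def write_trajectory(path, traj: Trajectory) -> None:
    lines = []
    for f in range(traj.n_frames):
        lines.append(f"MODEL {f + 1:>8d}")
        for j, a in enumerate(traj.atoms):
            lines.append(_format_atom_line(a.moved_to(traj.coords[f, j]), j + 1))
        lines.append("ENDMDL")
    Path(path).write_text("\n".join(lines) + "\nEND\n")
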