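"""Lightweight structural containers shared by the docking and MD modules.

An :class:`Atom` is a plain record (no topology); structures are tuples of
atoms; a :class:`Pose` is one docked ligand conformation with its score; a
:class:`Trajectory` is a frame stack over a fixed atom roster.  Coordinate
geometry helpers (angles, rigid transforms) live here too.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._elements import METAL_ELEMENTS, atomic_weight

__all__ = [
    "Atom",
    "Pose",
    "Trajectory",
    "RingGroup",
    "coords_array",
    "dha_angle",
    "apply_rigid",
    "random_rotation",
]


@dataclass(frozen=True)
class Atom:
    serial: int
    name: str
    element: str
    res_name: str
    res_seq: int
    chain: str
    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.x, self.y, self.z]).all():
            raise ValueError(f"atom {self.serial} has non-finite coordinates")

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])

    @property
    def is_metal(self) -> bool:
        return self.element.upper() in METAL_ELEMENTS

    @property
    def mass(self) -> float:
        return atomic_weight(self.element)

    def moved_to(self, xyz) -> "Atom":
        x, y, z = map(float, xyz)
        return replace(self, x=x, y=y, z=z)


def coords_array(atoms) -> np.ndarray:
    """(N, 3) coordinate array of an atom sequence."""
    return np.array([[a.x, a.y, a.z] for a in atoms], dtype=float)


@dataclass(frozen=True)
class Pose:
    """One docked conformation of a compound with its docking score."""

    compound_id: str
    atoms: tuple[Atom, ...]
    energy: float  # kcal/mol
    run_id: int = 0

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("a pose needs at least one atom")
        if not np.isfinite(self.energy):
            raise ValueError("pose energy must be finite")


@dataclass(frozen=True)
class RingGroup:
    """A labelled ligand ring (atom indices into the trajectory roster)."""

    label: str
    indices: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.indices:
            raise ValueError(f"ring group {self.label!r} is empty")


@dataclass(frozen=True)
class Trajectory:
    """Ordered coordinate frames over a fixed atom roster."""

    atoms: tuple[Atom, ...]
    coords: np.ndarray  # (n_frames, n_atoms, 3)
    dt_ps: float = 100.0

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if coords.shape[1] != len(self.atoms):
            raise ValueError("frame atom count does not match the roster")
        if self.dt_ps <= 0:
            raise ValueError("dt must be positive")
        object.__setattr__(self, "coords", coords)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def times_ns(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt_ps / 1000.0

    def select(self, predicate) -> np.ndarray:
        """Indices of roster atoms for which predicate(atom) is true."""
        return np.array([i for i, a in enumerate(self.atoms) if predicate(a)], dtype=int)


def dha_angle(donor_xyz, hydrogen_xyz, acceptor_xyz) -> float:
    """Donor-hydrogen-acceptor angle in degrees (vertex at the hydrogen)."""
    d = np.asarray(donor_xyz, float) - np.asarray(hydrogen_xyz, float)
    a = np.asarray(acceptor_xyz, float) - np.asarray(hydrogen_xyz, float)
    cosang = np.dot(d, a) / (np.linalg.norm(d) * np.linalg.norm(a))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def apply_rigid(atoms, rotation: np.ndarray, translation) -> tuple[Atom, ...]:
    """Apply x -> R x + t to every atom of a structure."""
    R = np.asarray(rotation, float)
    t = np.asarray(translation, float)
    xyz = coords_array(atoms) @ R.T + t
    return tuple(a.moved_to(p) for a, p in zip(atoms, xyz))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A uniformly random proper rotation matrix (QR-based)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
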