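"""Docking-output post-processing: pose clustering, ranking, H-bond detection.

A docking campaign over many pockets and random seeds produces a cloud of
scored poses per compound.  This module groups those poses by centre of
mass (deterministic leader clustering, poses visited by ascending energy),
summarises each group (occupancy n, lowest and mean energy), labels groups
as binding the catalytic site or elsewhere relative to the binuclear
copper pair, ranks compounds, and detects intermolecular hydrogen bonds by
the geometric rule: donor-acceptor distance strictly below 4 A and
donor-hydrogen-acceptor angle strictly above 120 degrees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structures import Atom, Pose, coords_array, dha_angle

__all__ = [
    "PoseGroup",
    "HydrogenBond",
    "center_of_mass",
    "cluster_poses",
    "assign_location",
    "copper_midpoint",
    "rank_compounds",
    "list_donors_acceptors",
    "detect_hbonds",
    "DEFAULT_CLUSTER_CUTOFF",
    "DEFAULT_ACTIVE_SITE_CUTOFF",
    "HBOND_MAX_DA_DISTANCE",
    "HBOND_MIN_DHA_ANGLE",
]

DEFAULT_CLUSTER_CUTOFF = 3.5  # A, leader-clustering radius on pose COMs
DEFAULT_ACTIVE_SITE_CUTOFF = 8.0  # A from the Cu-pair midpoint
HBOND_MAX_DA_DISTANCE = 4.0  # A, strict <
HBOND_MIN_DHA_ANGLE = 120.0  # degrees, strict >
DONOR_H_COVALENT_CUTOFF = 1.2  # A, geometric N/O-H covalency inference


def center_of_mass(pose: Pose | tuple[Atom, ...], weighting: str = "geometric") -> np.ndarray:
    """Weighted mean position of a pose; geometric weighting counts atoms equally."""
    atoms = pose.atoms if isinstance(pose, Pose) else tuple(pose)
    if not atoms:
        raise ValueError("cannot take the centre of an empty structure")
    xyz = coords_array(atoms)
    if weighting == "geometric":
        return xyz.mean(axis=0)
    if weighting == "mass":
        w = np.array([a.mass for a in atoms])
        return (xyz * w[:, None]).sum(axis=0) / w.sum()
    raise ValueError(f"unknown weighting {weighting!r} (use 'geometric' or 'mass')")


@dataclass(frozen=True)
class PoseGroup:
    """A COM cluster of poses: occupancy, energy statistics, location label."""

    poses: tuple[Pose, ...]
    centroid: np.ndarray
    location: str = "unassigned"  # active | other | unassigned

    @property
    def n(self) -> int:
        return len(self.poses)

    @property
    def lowest_energy(self) -> float:
        return min(p.energy for p in self.poses)

    @property
    def mean_energy(self) -> float:
        return float(np.mean([p.energy for p in self.poses]))


def cluster_poses(
    poses,
    cutoff: float = DEFAULT_CLUSTER_CUTOFF,
    weighting: str = "geometric",
) -> list[PoseGroup]:
    """Leader clustering of poses on their centres of mass.

    Poses are visited by ascending energy (score ties broken by run order,
    which makes the procedure fully deterministic).  Each pose joins the
    first existing group whose running-mean centroid lies within *cutoff*
    of its COM, else founds a new group.  Returned groups are sorted by
    lowest energy.
    """
    poses = list(poses)
    if not poses:
        raise ValueError("need at least one pose")
    if cutoff <= 0:
        raise ValueError("cluster cutoff must be positive")
    order = sorted(range(len(poses)), key=lambda i: (poses[i].energy, i))
    members: list[list[Pose]] = []
    centroids: list[np.ndarray] = []
    for i in order:
        pose = poses[i]
        com = center_of_mass(pose, weighting)
        for gi, centroid in enumerate(centroids):
            if np.linalg.norm(com - centroid) < cutoff:
                members[gi].append(pose)
                k = len(members[gi])
                centroids[gi] = centroid + (com - centroid) / k  # running mean
                break
        else:
            members.append([pose])
            centroids.append(com.copy())
    groups = [
        PoseGroup(tuple(m), centroid=c) for m, c in zip(members, centroids)
    ]
    groups.sort(key=lambda g: g.lowest_energy)
    return groups


def copper_midpoint(receptor) -> np.ndarray:
    """Midpoint of the two copper ions defining the catalytic site."""
    metals = [a for a in receptor if a.is_metal and a.element.upper() == "CU"]
    if len(metals) < 2:
        metals = [a for a in receptor if a.is_metal]
    if len(metals) < 2:
        raise ValueError("receptor must contain at least two metal atoms (Cu pair)")
    return coords_array(metals[:2]).mean(axis=0)


def assign_location(
    group: PoseGroup, receptor, cutoff: float = DEFAULT_ACTIVE_SITE_CUTOFF
) -> PoseGroup:
    """Label a group 'active' iff its centroid is strictly within *cutoff*
    of the copper-pair midpoint, else 'other'."""
    mid = copper_midpoint(receptor)
    location = "active" if np.linalg.norm(group.centroid - mid) < cutoff else "other"
    return PoseGroup(group.poses, group.centroid, location)


def rank_compounds(groups_by_compound: dict[str, list[PoseGroup]]) -> pd.DataFrame:
    """Rank compounds by their best pose group.

    The reported group per compound is its lowest-energy active-site group
    when one exists, else its overall lowest-energy group.  Compounds are
    ordered by (lowest energy ascending, occupancy n descending, mean
    energy ascending).
    """
    if not groups_by_compound:
        raise ValueError("need at least one compound")
    rows = []
    for compound, groups in groups_by_compound.items():
        if not groups:
            raise ValueError(f"compound {compound!r} has no pose groups")
        active = [g for g in groups if g.location == "active"]
        pick = min(active or groups, key=lambda g: g.lowest_energy)
        rows.append(
            {
                "compound": compound,
                "lowest_energy_kcal_mol": pick.lowest_energy,
                "n_in_group": pick.n,
                "mean_energy_kcal_mol": pick.mean_energy,
                "binding_location": pick.location,
            }
        )
    df = pd.DataFrame(rows).sort_values(
        by=["lowest_energy_kcal_mol", "n_in_group", "mean_energy_kcal_mol"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    df.insert(0, "rank", range(1, len(df) + 1))
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Hydrogen-bond detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HydrogenBond:
    donor: Atom
    hydrogen: Atom
    acceptor: Atom
    da_distance: float
    dha_angle: float

    def __post_init__(self) -> None:
        if not (self.da_distance < HBOND_MAX_DA_DISTANCE):
            raise ValueError("hydrogen bond violates the distance criterion")
        if not (self.dha_angle > HBOND_MIN_DHA_ANGLE):
            raise ValueError("hydrogen bond violates the angle criterion")


def list_donors_acceptors(structure) -> tuple[list[tuple[Atom, Atom]], list[Atom]]:
    """Donor (N/O with covalent H) and acceptor (N/O) lists of a structure.

    Pose files carry no bond table, so donor-hydrogen covalency is
    inferred geometrically (H within 1.2 A of the heavy atom).  Returns
    ([(donor, attached H), ...], [acceptor, ...]); a donor with several
    hydrogens contributes one entry per hydrogen.
    """
    atoms = tuple(structure)
    heavies = [a for a in atoms if a.element.upper() in ("N", "O")]
    hydrogens = [a for a in atoms if a.element.upper() == "H"]
    donors: list[tuple[Atom, Atom]] = []
    for heavy in heavies:
        for h in hydrogens:
            if np.linalg.norm(heavy.xyz - h.xyz) < DONOR_H_COVALENT_CUTOFF:
                donors.append((heavy, h))
    if heavies and hydrogens == [] and any(a.element.upper() == "O" for a in heavies):
        warnings.warn(
            "structure has N/O atoms but no explicit hydrogens; donor list is empty",
            stacklevel=2,
        )
    return donors, heavies


def detect_hbonds(
    ligand,
    receptor,
    max_da_distance: float = HBOND_MAX_DA_DISTANCE,
    min_dha_angle: float = HBOND_MIN_DHA_ANGLE,
) -> list[HydrogenBond]:
    """All intermolecular hydrogen bonds between ligand and receptor.

    Both directions are scanned (ligand donor -> receptor acceptor and
    receptor donor -> ligand acceptor).  Both criteria are strict
    inequalities: distance < 4 A, angle > 120 deg.  Output sorted by
    donor-acceptor distance.
    """
    lig_donors, lig_acceptors = list_donors_acceptors(ligand)
    rec_donors, rec_acceptors = list_donors_acceptors(receptor)
    bonds: list[HydrogenBond] = []
    for donors, acceptors in ((lig_donors, rec_acceptors), (rec_donors, lig_acceptors)):
        for donor, h in donors:
            for acceptor in acceptors:
                dist = float(np.linalg.norm(donor.xyz - acceptor.xyz))
                if not (dist < max_da_distance):
                    continue
                angle = dha_angle(donor.xyz, h.xyz, acceptor.xyz)
                if not (angle > min_dha_angle):
                    continue
                bonds.append(HydrogenBond(donor, h, acceptor, dist, angle))
    bonds.sort(key=lambda b: b.da_distance)
    return bonds
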