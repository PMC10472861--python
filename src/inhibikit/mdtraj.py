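"""MD-trajectory analyses for judging whether a docked ligand stays bound.

Implements the standard stability diagnostics — Kabsch superposition RMSD
versus time for the protein backbone, per-residue C-alpha RMSF, radius of
gyration — and the ligand-contact analysis: per-frame distances between
the geometric centre (COG) of each ligand ring and the C-alpha atoms of
selected pocket residues, with a 10 A limit separating maintained contact
from dissociation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .structures import Atom, RingGroup, Trajectory, coords_array

__all__ = [
    "DistanceProfile",
    "rmsd",
    "kabsch_superpose",
    "rmsd_series",
    "rmsf",
    "radius_of_gyration",
    "distance_profiles",
    "classify_binding",
    "is_backbone",
    "is_calpha",
    "DEFAULT_CONTACT_LIMIT",
    "DEFAULT_BOUND_FRACTION",
]

DEFAULT_CONTACT_LIMIT = 10.0  # A, the contact/dissociation boundary
DEFAULT_BOUND_FRACTION = 0.9  # fraction of frames that must stay in contact

BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})


def is_backbone(atom: Atom) -> bool:
    return atom.name in BACKBONE_NAMES and atom.res_name != "LIG"


def is_calpha(atom: Atom) -> bool:
    return atom.name == "CA" and atom.element.upper() == "C"


def rmsd(coords_a, coords_b) -> float:
    """Plain coordinate RMSD between two equal-length point sets (no fitting)."""
    a, b = np.asarray(coords_a, float), np.asarray(coords_b, float)
    if a.shape != b.shape:
        raise ValueError("coordinate sets must have identical shape")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def kabsch_superpose(reference, mobile) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of *mobile* onto *reference*.

    Returns ``(R, t, rmsd)`` with the least-squares rotation R and
    translation t such that ``mobile @ R.T + t`` best matches the
    reference, and the RMSD after the transform.  Needs >= 3
    non-collinear points; collinear selections make the rotation
    ill-determined and are flagged.
    """
    ref, mob = np.asarray(reference, float), np.asarray(mobile, float)
    if ref.shape != mob.shape or ref.shape[0] < 3:
        raise ValueError("need two equal selections of at least 3 points")
    ref_c, mob_c = ref - ref.mean(axis=0), mob - mob.mean(axis=0)
    if np.linalg.matrix_rank(ref_c, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) selection; superposition undefined")
    rot, rssd = Rotation.align_vectors(ref_c, mob_c)
    R = rot.as_matrix()
    t = ref.mean(axis=0) - R @ mob.mean(axis=0)
    fitted = mob @ R.T + t
    return R, t, rmsd(ref, fitted)


def rmsd_series(traj: Trajectory, reference_frame: int = 0, selection=None) -> np.ndarray:
    """Per-frame backbone RMSD versus a reference frame after superposition."""
    idx = traj.select(is_backbone) if selection is None else np.asarray(selection, int)
    ref = traj.coords[reference_frame][idx]
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        _, _, out[f] = kabsch_superpose(ref, traj.coords[f][idx])
    return out


def rmsf(traj: Trajectory, selection=None, align_selection=None) -> np.ndarray:
    """Per-atom RMS fluctuation about the time-mean position.

    Two-pass procedure: frames are first superposed (on *align_selection*,
    default the analysis selection) to frame 0 and averaged; each frame is
    then superposed to that mean structure and deviations accumulated.
    Passing a separate rigid sub-selection as *align_selection* keeps the
    alignment from absorbing the motion under study.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    sel = traj.select(is_calpha) if selection is None else np.asarray(selection, int)
    align = sel if align_selection is None else np.asarray(align_selection, int)

    # pass 1: mean alignment-selection structure in the frame-0 frame
    tmp = np.empty((traj.n_frames, len(align), 3))
    for f in range(traj.n_frames):
        R, t, _ = kabsch_superpose(traj.coords[0][align], traj.coords[f][align])
        tmp[f] = traj.coords[f][align] @ R.T + t
    mean_align = tmp.mean(axis=0)
    # pass 2: superpose each frame onto the mean and accumulate deviations
    fitted = np.empty((traj.n_frames, len(sel), 3))
    for f in range(traj.n_frames):
        R, t, _ = kabsch_superpose(mean_align, traj.coords[f][align])
        fitted[f] = traj.coords[f][sel] @ R.T + t
    mean_pos = fitted.mean(axis=0)
    return np.sqrt(np.mean(np.sum((fitted - mean_pos) ** 2, axis=2), axis=0))


def radius_of_gyration(atoms, coords=None) -> float:
    """Mass-weighted radius of gyration of a selection (A)."""
    atoms = tuple(atoms)
    if not atoms:
        raise ValueError("empty selection")
    xyz = coords_array(atoms) if coords is None else np.asarray(coords, float)
    w = np.array([a.mass for a in atoms])
    com = (xyz * w[:, None]).sum(axis=0) / w.sum()
    return float(np.sqrt((w * np.sum((xyz - com) ** 2, axis=1)).sum() / w.sum()))


@dataclass(frozen=True)
class DistanceProfile:
    """Per-frame distance between one ring COG and one residue C-alpha."""

    ring_label: str
    residue_id: int
    series: np.ndarray  # A, one value per frame
    limit: float = DEFAULT_CONTACT_LIMIT

    def __post_init__(self) -> None:
        series = np.asarray(self.series, float)
        if np.any(series < 0):
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "series", series)


def distance_profiles(
    traj: Trajectory,
    rings: list[RingGroup],
    residues: list[int],
    limit: float = DEFAULT_CONTACT_LIMIT,
) -> list[DistanceProfile]:
    """Ring-COG to residue-C-alpha distance series for every (ring, residue) pair.

    The ring centre is the unweighted geometric mean of its member atoms.
    Residues without a C-alpha on the roster are skipped with a warning.
    """
    ca_index: dict[int, int] = {}
    for i, a in enumerate(traj.atoms):
        if is_calpha(a):
            ca_index[a.res_seq] = i
    profiles = []
    for ring in rings:
        ring_idx = np.asarray(ring.indices, int)
        cog = traj.coords[:, ring_idx, :].mean(axis=1)  # (F, 3)
        for res in residues:
            if res not in ca_index:
                warnings.warn(f"residue {res} has no C-alpha on the roster; skipped", stacklevel=2)
                continue
            ca = traj.coords[:, ca_index[res], :]
            series = np.linalg.norm(cog - ca, axis=1)
            profiles.append(DistanceProfile(ring.label, res, series, limit))
    return profiles


def classify_binding(
    profiles: list[DistanceProfile],
    limit: float = DEFAULT_CONTACT_LIMIT,
    fraction: float = DEFAULT_BOUND_FRACTION,
) -> dict:
    """Bound/dissociated verdicts from the contact profiles.

    A ring is bound when at least *fraction* of frames have its minimum
    distance over the profiled residues below *limit*.  The compound is
    bound when any ring (the anchor) is bound.
    """
    if not profiles:
        raise ValueError("no profiles to classify")
    by_ring: dict[str, list[DistanceProfile]] = {}
    for p in profiles:
        by_ring.setdefault(p.ring_label, []).append(p)
    verdicts = {}
    for label, ps in by_ring.items():
        stack = np.vstack([p.series for p in ps])
        min_dist = stack.min(axis=0)
        frac_in_contact = float(np.mean(min_dist < limit))
        verdicts[label] = {
            "status": "bound" if frac_in_contact >= fraction else "dissociated",
            "fraction_in_contact": frac_in_contact,
        }
    compound = "bound" if any(v["status"] == "bound" for v in verdicts.values()) else "dissociated"
    return {"rings": verdicts, "compound": compound}
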