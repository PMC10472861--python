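"""Seeded generators for every input the analysis stages consume.

No public data deposit exists for this kind of study — the instrument, the
docking engine and the MD engine each emit files downstream code must
digest — so this module emulates their outputs with known ground truth:

* paired control / enzyme-incubated LC-MS peak tables with per-peak true
  area reductions (multiplicative log-normal area noise keeps areas
  positive);
* dose-response, velocity-grid and slow-binding progress-curve data lying
  exactly on their governing equations at zero noise (additive Gaussian
  noise otherwise);
* isotropic Gaussian pose clouds with per-cluster energies and membership
  labels;
* receptor/ligand scenes with hydrogen bonds planted to satisfy — and
  decoys planted to violate — the geometric detection criteria;
* bound and escaping ligand trajectories over a synthetic binding pocket.

Every generator is deterministic for a given seed and returns its ground
truth alongside the data, so recovery tests can assert against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .structures import Atom, Pose, RingGroup, Trajectory, apply_rigid, random_rotation
from .ufscreen import PeakRecord, PeakTable, load_reference_table

__all__ = [
    "ScreenScenario",
    "KineticScenario",
    "PoseScenario",
    "gen_screen_tables",
    "gen_dose_response",
    "gen_velocity_data",
    "gen_progress_curves",
    "gen_pose_cloud",
    "gen_hbond_scene",
    "gen_trajectory",
]


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative log-normal noise with relative spread *cv*."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log(1.0 + cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


# ---------------------------------------------------------------------------
# Ultrafiltration screen
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenScenario:
    """Ground truth for one paired control/enzyme-incubated screen.

    ``reduction_percent`` maps peak id -> true percent area loss upon
    enzyme incubation; ``binder_ids`` marks which of those peaks are
    genuine binders.  The default scenario (:meth:`reference`) reproduces
    the nine-iridoid reference screen: its control areas, its per-peak
    reductions, and its six-binder ground truth.
    """

    peak_ids: tuple[str, ...]
    tr_min: tuple[float, ...]
    mz: tuple[float, ...]
    control_areas: tuple[float, ...]
    binder_ids: frozenset[str]
    reduction_percent: dict[str, float]
    area_cv: float = 0.02
    tr_jitter_min: float = 0.02
    mz_jitter_ppm: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        ids = set(self.peak_ids)
        if not self.binder_ids <= ids:
            raise ValueError("binder_ids must be a subset of peak ids")
        if not set(self.reduction_percent) <= ids:
            raise ValueError("reduction_percent keys must be peak ids")
        for pid, red in self.reduction_percent.items():
            if not 0.0 <= red <= 100.0:
                raise ValueError(f"reduction for peak {pid} outside [0, 100]")
        if any(a <= 0 for a in self.control_areas):
            raise ValueError("control areas must be strictly positive")
        if self.area_cv < 0:
            raise ValueError("area_cv must be non-negative")

    @property
    def n_peaks(self) -> int:
        return len(self.peak_ids)

    @classmethod
    def reference(cls, area_cv: float = 0.02, seed: int = 0, **overrides) -> "ScreenScenario":
        """Scenario reproducing the packaged nine-iridoid screen."""
        df = load_reference_table()
        reductions = {
            str(r.peak_id): 100.0 * (1.0 - r.area_treated / r.area_control)
            for r in df.itertuples()
        }
        fields = dict(
            peak_ids=tuple(str(p) for p in df["peak_id"]),
            tr_min=tuple(float(v) for v in df["tr_min"]),
            mz=tuple(float(v) for v in df["detected_mz"]),
            control_areas=tuple(float(v) for v in df["area_control"]),
            binder_ids=frozenset({"1", "2", "4", "6", "7", "8"}),
            reduction_percent=reductions,
            area_cv=area_cv,
            seed=seed,
        )
        fields.update(overrides)
        return cls(**fields)


def gen_screen_tables(scenario: ScreenScenario) -> tuple[PeakTable, PeakTable]:
    """Paired (control, treated) peak tables for a screen scenario.

    Expected treated area is ``control x (1 - reduction/100)``; both tables
    carry independent multiplicative log-normal area noise, and the treated
    table carries retention-time and m/z jitter.
    """
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n_peaks
    f_control = _lognormal_factor(rng, scenario.area_cv, n)
    f_treated = _lognormal_factor(rng, scenario.area_cv, n)
    tr_shift = rng.normal(0.0, scenario.tr_jitter_min, n) if scenario.tr_jitter_min else np.zeros(n)
    mz_shift = rng.normal(0.0, scenario.mz_jitter_ppm, n) if scenario.mz_jitter_ppm else np.zeros(n)

    control_records, treated_records = [], []
    for i, pid in enumerate(scenario.peak_ids):
        base = scenario.control_areas[i]
        red = scenario.reduction_percent.get(pid, 0.0)
        control_records.append(
            PeakRecord(pid, scenario.tr_min[i], scenario.mz[i], base * f_control[i])
        )
        treated_records.append(
            PeakRecord(
                pid,
                scenario.tr_min[i] + tr_shift[i],
                scenario.mz[i] * (1.0 + mz_shift[i] * 1e-6),
                base * (1.0 - red / 100.0) * f_treated[i],
            )
        )
    return (
        PeakTable("control", tuple(control_records)),
        PeakTable("enzyme_15min", tuple(treated_records)),
    )


# ---------------------------------------------------------------------------
# Kinetics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticScenario:
    """Generating parameters for the full kinetic characterisation.

    Defaults are the reference inhibitor's values: mushroom-tyrosinase
    L-tyrosine Km 180 uM, competitive Ki 5.1 uM, IC50 31.2 uM, and the
    enzyme-isomerisation triple k5 = 0.04496 1/s, k6 = 1.103e-5 1/s,
    Ki_app = 2.402 mM.  Vmax is in arbitrary rate units (dopachrome
    absorbance change per second) — every downstream quantity is either
    Vmax-free or scales trivially with it.
    """

    Km_uM: float = 180.0
    Vmax: float = 1.0
    Ki_uM: float = 5.1
    IC50_uM: float = 31.2
    k5_per_s: float = 0.04496
    k6_per_s: float = 0.00001103
    Ki_app_mM: float = 2.402
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("Km_uM", "Vmax", "Ki_uM", "IC50_uM", "k5_per_s", "k6_per_s", "Ki_app_mM"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _add_noise(rng, values, noise_sd):
    """Additive Gaussian noise with sd proportional to the true value."""
    values = np.asarray(values, float)
    if noise_sd == 0:
        return values.copy()
    return values + rng.normal(0.0, noise_sd * np.abs(values))


def gen_dose_response(IC50_uM, concentrations_uM, noise_sd=0.0, seed=0):
    """(I, activity) points on the fixed-slope logistic dose-response."""
    if IC50_uM <= 0:
        raise ValueError("IC50 must be positive")
    I = np.asarray(concentrations_uM, float)
    if I.size == 0:
        raise ValueError("concentration grid must be non-empty")
    rng = np.random.default_rng(seed)
    activity = 100.0 / (1.0 + I / IC50_uM)
    return I, _add_noise(rng, activity, noise_sd)


_VELOCITY_MODES = ("competitive", "uncompetitive", "noncompetitive")


def gen_velocity_data(Km_uM, Vmax, Ki_uM, S_grid_uM, I_grid_uM, mode="competitive",
                      noise_sd=0.0, seed=0):
    """Velocity points on an (S, I) grid under the chosen inhibition law.

    Rows with I = 0 reduce to plain Michaelis-Menten in every mode.
    Returns flat arrays (S, I, v).
    """
    if mode not in _VELOCITY_MODES:
        raise ValueError(f"unknown inhibition mode {mode!r}; one of {_VELOCITY_MODES}")
    if min(Km_uM, Vmax, Ki_uM) <= 0:
        raise ValueError("Km, Vmax and Ki must be positive")
    S_grid = np.asarray(S_grid_uM, float)
    I_grid = np.asarray(I_grid_uM, float)
    if S_grid.size == 0 or I_grid.size == 0:
        raise ValueError("substrate and inhibitor grids must be non-empty")
    S, I = (g.ravel() for g in np.meshgrid(S_grid, I_grid))
    if mode == "competitive":
        v = Vmax * S / (Km_uM * (1.0 + I / Ki_uM) + S)
    elif mode == "uncompetitive":
        v = Vmax * S / (Km_uM + S * (1.0 + I / Ki_uM))
    else:
        v = Vmax * S / ((Km_uM + S) * (1.0 + I / Ki_uM))
    rng = np.random.default_rng(seed)
    return S, I, _add_noise(rng, v, noise_sd)


def gen_progress_curves(k5, k6, Ki_app, I_grid, t_grid_s, vi, vs, A0=0.0,
                        noise_sd=0.0, seed=0):
    """Per-[I] slow-binding progress curves and v/v0 decay series.

    For each inhibitor concentration the onset rate is the hyperbola
    ``kobs = k6 + k5*I/(Ki_app + I)``; the absorbance curve and the
    normalised-velocity series follow exactly at zero noise.  [I] and
    Ki_app must share units (mM by convention here).
    """
    t = np.asarray(t_grid_s, float)
    if t.size < 2 or t[0] != 0 or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must increase from 0")
    rng = np.random.default_rng(seed)
    curves = []
    for conc in np.asarray(I_grid, float):
        kobs = k6 + k5 * conc / (Ki_app + conc)
        if kobs <= 0:
            raise ValueError(f"non-positive kobs at [I]={conc}; check rate constants")
        A = A0 + vs * t + (vi - vs) * (1.0 - np.exp(-kobs * t)) / kobs
        vv0 = np.exp(-kobs * t)
        curves.append(
            {
                "I": float(conc),
                "kobs_true": float(kobs),
                "t_s": t.copy(),
                "A": _add_noise(rng, A, noise_sd),
                "v_over_v0": np.clip(_add_noise(rng, vv0, noise_sd), 1e-12, None),
            }
        )
    return curves


# ---------------------------------------------------------------------------
# Docking poses
# ---------------------------------------------------------------------------

# rigid 5-atom ligand template with zero geometric centre
_POSE_TEMPLATE = np.array(
    [[0.0, 0.0, 0.0], [1.4, 0.0, 0.0], [-1.4, 0.0, 0.0], [0.0, 1.4, 0.0], [0.0, -1.4, 0.0]]
)
_POSE_TEMPLATE -= _POSE_TEMPLATE.mean(axis=0)


@dataclass(frozen=True)
class PoseScenario:
    """Isotropic Gaussian pose clouds with per-cluster energy statistics."""

    cluster_centers: tuple[tuple[float, float, float], ...]
    spreads: tuple[float, ...]
    energies_mean: tuple[float, ...]
    energies_sd: tuple[float, ...]
    n_per_cluster: tuple[int, ...]
    compound_id: str = "compound"
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.cluster_centers)
        for name in ("spreads", "energies_mean", "energies_sd", "n_per_cluster"):
            if len(getattr(self, name)) != k:
                raise ValueError(f"{name} must have one entry per cluster")
        if any(s <= 0 for s in self.spreads):
            raise ValueError("spreads must be positive")
        if any(n < 1 for n in self.n_per_cluster):
            raise ValueError("n_per_cluster must be >= 1")
        if any(sd < 0 for sd in self.energies_sd):
            raise ValueError("energy sds must be non-negative")


def gen_pose_cloud(scenario: PoseScenario) -> tuple[list[Pose], np.ndarray]:
    """Sample the pose cloud; returns (poses, true cluster label per pose)."""
    rng = np.random.default_rng(scenario.seed)
    poses, labels = [], []
    run = 0
    for ci, center in enumerate(scenario.cluster_centers):
        for _ in range(scenario.n_per_cluster[ci]):
            com = np.asarray(center, float) + rng.normal(0.0, scenario.spreads[ci], 3)
            xyz = _POSE_TEMPLATE @ random_rotation(rng).T + com
            atoms = tuple(
                Atom(j + 1, f"C{j + 1}", "C", "LIG", 900, "L", *map(float, p))
                for j, p in enumerate(xyz)
            )
            energy = float(rng.normal(scenario.energies_mean[ci], scenario.energies_sd[ci]))
            poses.append(Pose(scenario.compound_id, atoms, energy, run_id=run))
            labels.append(ci)
            run += 1
    return poses, np.array(labels)


# ---------------------------------------------------------------------------
# Hydrogen-bond scenes
# ---------------------------------------------------------------------------

def _place_hydrogen(d: float, theta_deg: float) -> np.ndarray:
    """H position (donor at origin, acceptor at (d,0,0)) giving DHA = theta."""
    r = 0.96  # O-H covalent bond length

    def dha_of(phi):
        h = np.array([r * np.cos(phi), r * np.sin(phi), 0.0])
        v_d, v_a = -h, np.array([d, 0.0, 0.0]) - h
        c = np.dot(v_d, v_a) / (np.linalg.norm(v_d) * np.linalg.norm(v_a))
        return np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))

    phi = brentq(lambda p: dha_of(p) - theta_deg, 1e-9, np.pi / 2 + 0.5)
    return np.array([r * np.cos(phi), r * np.sin(phi), 0.0])


def gen_hbond_scene(n_true: int, n_decoys: int, seed: int = 0):
    """A receptor/ligand pair with planted hydrogen bonds and decoys.

    True sites have donor-acceptor distance in [2.6, 3.4] A and DHA angle
    in [150, 180] deg; decoys violate exactly one criterion (distance
    >= 4.5 A, or angle <= 110 deg at valid distance).  Sites sit on a
    widely spaced grid (12 A pitch) so no accidental cross-site bond can
    form.  The ligand carries the donor hydroxyls; the receptor carries
    bare carbonyl-like acceptor oxygens.  Returns
    (receptor atoms, ligand atoms, planted bond descriptors).
    """
    if n_true < 0 or n_decoys < 0:
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    lig_atoms: list[Atom] = []
    rec_atoms: list[Atom] = []
    planted = []
    serial_l = serial_r = 0
    for site in range(n_true + n_decoys):
        is_true = site < n_true
        if is_true:
            d = rng.uniform(2.6, 3.4)
            theta = rng.uniform(150.0, 179.0)
        elif rng.random() < 0.5:
            d = rng.uniform(4.5, 6.0)  # distance violation
            theta = rng.uniform(150.0, 179.0)
        else:
            d = rng.uniform(2.8, 3.4)
            theta = rng.uniform(80.0, 110.0)  # angle violation
        donor = np.zeros(3)
        acceptor = np.array([d, 0.0, 0.0])
        hydrogen = _place_hydrogen(d, theta)
        # random orientation, widely spaced grid placement
        R = random_rotation(rng)
        offset = np.array(
            [12.0 * (site % 4), 12.0 * ((site // 4) % 4), 12.0 * (site // 16)]
        )
        donor, hydrogen, acceptor = (R @ p + offset for p in (donor, hydrogen, acceptor))
        serial_l += 1
        lig_atoms.append(Atom(serial_l, f"O{site + 1}", "O", "LIG", 900, "L", *map(float, donor)))
        serial_l += 1
        lig_atoms.append(Atom(serial_l, f"H{site + 1}", "H", "LIG", 900, "L", *map(float, hydrogen)))
        serial_r += 1
        rec_atoms.append(Atom(serial_r, "O", "O", "SER", 100 + site, "A", *map(float, acceptor)))
        if is_true:
            planted.append(
                {"site": site, "da_distance": float(d), "dha_angle": float(theta)}
            )
    return tuple(rec_atoms), tuple(lig_atoms), planted


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

_POCKET_RESIDUES = (
    ("HIS", 259), ("ASN", 260), ("HIS", 263), ("PHE", 264),
    ("SER", 282), ("VAL", 283), ("PRO", 284), ("ALA", 286),
)
_RING_RADIUS = 1.4  # A, six-membered ring
BOUND_RADIUS = 8.0  # A, max anchor-COG to pocket-anchor distance when bound
_ESCAPE_RADIUS = 25.0  # A, minimum ligand displacement once escaped


def _hexagon(center, radius=_RING_RADIUS):
    ang = np.linspace(0, 2 * np.pi, 6, endpoint=False)
    return np.asarray(center) + np.c_[radius * np.cos(ang), radius * np.sin(ang), np.zeros(6)]


def gen_trajectory(bound: bool, n_frames: int = 1000, escape_frame: int | None = None,
                   dt_ps: float = 100.0, seed: int = 0):
    """A synthetic protein-ligand trajectory over the pocket residues.

    The receptor contributes backbone atoms for eight pocket residues
    arranged around the origin plus the two copper ions; the ligand is
    three six-membered rings (G1 the anchor, then G2, G3).  Bound
    trajectories keep the G1 centre within ``BOUND_RADIUS`` of the pocket
    anchor (the origin) in every frame; unbound trajectories place the
    whole ligand beyond the 10 A contact limit of every pocket residue
    from ``escape_frame`` onwards.  Returns (Trajectory, meta) where meta
    carries the ring groups, pocket residue ids and ground-truth label.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    if not bound:
        if escape_frame is None:
            escape_frame = n_frames // 4
        if not 0 <= escape_frame < n_frames:
            raise ValueError("escape_frame must be in [0, n_frames)")
    rng = np.random.default_rng(seed)

    atoms: list[Atom] = []
    serial = 0
    template: list[np.ndarray] = []
    n_res = len(_POCKET_RESIDUES)
    for k, (res, seq) in enumerate(_POCKET_RESIDUES):
        ang = 2 * np.pi * k / n_res
        ca = np.array([5.0 * np.cos(ang), 5.0 * np.sin(ang), 0.0])
        for name, off in (("N", [-0.5, 0, 0.3]), ("CA", [0, 0, 0]),
                          ("C", [0.5, 0, -0.3]), ("O", [0.7, 0.5, -0.3])):
            serial += 1
            pos = ca + off
            atoms.append(Atom(serial, name, name[0], res, seq, "A", *map(float, pos)))
            template.append(pos)
    for cu_pos in ([1.5, 0.0, 1.0], [-1.5, 0.0, 1.0]):
        serial += 1
        atoms.append(Atom(serial, "CU", "CU", "CU", 400 + serial, "A", *map(float, cu_pos)))
        template.append(np.asarray(cu_pos, float))

    ring_groups = []
    lig_template = []
    for gi, cz in enumerate((0.0, 3.0, 6.0)):
        ring = _hexagon([0.0, 0.0, cz])
        start = len(atoms) + len(lig_template)
        ring_groups.append(RingGroup(f"G{gi + 1}", tuple(range(start, start + 6))))
        lig_template.extend(ring)
    lig_template = np.asarray(lig_template)
    for j, p in enumerate(lig_template):
        serial += 1
        atoms.append(Atom(serial, f"C{j + 1}", "C", "LIG", 900, "L", *map(float, p)))
    template = np.vstack([np.asarray(template), lig_template])
    n_prot = len(template) - len(lig_template)

    coords = np.empty((n_frames, len(template), 3))
    # escape direction fixed per trajectory; thermal jitter per frame
    esc_dir = rng.normal(size=3)
    esc_dir /= np.linalg.norm(esc_dir)
    for f in range(n_frames):
        frame = template.copy()
        frame[:n_prot] += rng.normal(0.0, 0.05, (n_prot, 3))
        if bound:
            drift = rng.normal(0.0, 0.4, 3)
            drift *= min(1.0, 3.0 / (np.linalg.norm(drift) + 1e-12))  # stay anchored
            frame[n_prot:] += drift
        else:
            if f < escape_frame:
                frame[n_prot:] += rng.normal(0.0, 0.3, 3)
            else:
                progress = (f - escape_frame + 1) / max(n_frames - escape_frame, 1)
                radius = _ESCAPE_RADIUS + 10.0 * progress
                frame[n_prot:] += esc_dir * radius + rng.normal(0.0, 0.3, 3)
        coords[f] = frame
    traj = Trajectory(tuple(atoms), coords, dt_ps=dt_ps)
    meta = {
        "bound": bound,
        "escape_frame": None if bound else escape_frame,
        "ring_groups": ring_groups,
        "pocket_residues": [seq for _, seq in _POCKET_RESIDUES],
        "anchor": np.zeros(3),
    }
    return traj, meta
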