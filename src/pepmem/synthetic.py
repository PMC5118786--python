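"""Synthetic membrane–peptide systems with known ground truth.

Every analysis in this package is exercised on trajectories generated here:
a planar two-leaflet bilayer of simplified lipids (one phosphorus headgroup
atom plus a single acyl chain of CH₂ carbons with explicit hydrogen pairs),
peptides built with ideal backbone geometry at prescribed (phi, psi), placed
at prescribed heights above the upper phosphate plane, and evolved over
frames with Gaussian positional noise plus optional insertion, unfolding and
aggregation schedules.  There is no physics — the point is that the
generating parameters (composition, per-carbon order, depths, dihedrals,
cluster membership) are known exactly, so analyses can be tested for
parameter recovery.

The C–H orientation sampler draws cos²θ from a Beta distribution whose mean
equals (2s+1)/3 for the signed target order s, so each carbon's expected
(3cos²θ−1)/2 equals the target; an all-trans chain aligned with z has every
C–H perpendicular to the normal (S_CD = −0.5, magnitude 0.5), which the
sampler reproduces exactly at target magnitude 0.5.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .core import AA_1TO3, Atom, Frame, Topology, Trajectory

__all__ = [
    "BilayerRecipe",
    "PeptideBuild",
    "SyntheticSystem",
    "Schedules",
    "build_ideal_peptide",
    "build_bilayer",
    "place_peptides",
    "evolve_trajectory",
    "sample_ch_orientations",
]

# Ideal backbone geometry (Å, degrees)
B_N_CA, B_CA_C, B_C_N, B_C_O, B_N_H = 1.458, 1.525, 1.329, 1.231, 1.000
ANG_N_CA_C, ANG_CA_C_N, ANG_C_N_CA, ANG_CA_C_O = 111.2, 116.2, 121.7, 120.8
OMEGA = 180.0

CHAIN_Z_STEP = 1.27          # Å per CH2 along the chain axis
CHAIN_START_OFFSET = 2.0     # Å from P to first chain carbon
CH_BOND = 1.09               # Å


class SyntheticError(ValueError):
    pass


def _nerf(a, b, c, bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom D given A-B-C, the C-D bond, B-C-D angle and A-B-C-D dihedral."""
    ang = np.radians(angle_deg)
    dih = -np.radians(dihedral_deg)   # sign matches the IUPAC convention of dihedral_angle
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(dih),
        bond * np.sin(ang) * np.sin(dih),
    ])
    return c + d[0] * bc + d[1] * m + d[2] * n


@dataclass
class PeptideBuild:
    """Raw ideal-geometry peptide coordinates plus atom bookkeeping."""

    sequence: str
    phi: np.ndarray              # per-residue, phi[0] unused
    psi: np.ndarray              # per-residue, psi[-1] used only to place the last O
    atom_names: list[str]
    atom_elements: list[str]
    atom_residues: list[int]     # 1-based
    coordinates: np.ndarray      # (n_atoms, 3)

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    def heavy_center(self) -> np.ndarray:
        heavy = [i for i, e in enumerate(self.atom_elements) if e != "H"]
        return self.coordinates[heavy].mean(axis=0)


def _as_per_residue(value, n: int) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        return np.full(n, float(arr))
    if arr.shape != (n,):
        raise SyntheticError(f"need scalar or length-{n} angle array")
    return arr


def build_ideal_peptide(sequence: str, phi=-57.0, psi=-47.0) -> PeptideBuild:
    """Build backbone (N, H, CA, C, O) with ideal geometry and uniform or
    per-residue (phi, psi); omega fixed at 180°.

    Measured dihedrals of the result reproduce the inputs to well under 0.5°.
    """
    n = len(sequence)
    if n < 1:
        raise SyntheticError("empty sequence")
    for letter in sequence:
        if letter not in AA_1TO3:
            raise SyntheticError(f"illegal amino-acid letter {letter!r}")
    phi = _as_per_residue(phi, n)
    psi = _as_per_residue(psi, n)

    N = np.zeros((n, 3))
    CA = np.zeros((n, 3))
    C = np.zeros((n, 3))
    ang = np.radians(ANG_N_CA_C)
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (B_N_CA, 0.0, 0.0)
    C[0] = CA[0] + B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, n):
        N[i] = _nerf(N[i - 1], CA[i - 1], C[i - 1], B_C_N, ANG_CA_C_N, psi[i - 1])
        CA[i] = _nerf(CA[i - 1], C[i - 1], N[i], B_N_CA, ANG_C_N_CA, OMEGA)
        C[i] = _nerf(C[i - 1], N[i], CA[i], B_CA_C, ANG_N_CA_C, phi[i])

    names, elements, residues, coords = [], [], [], []
    for i in range(n):
        res = i + 1
        entries = [("N", "N", N[i])]
        if i > 0:
            u = C[i - 1] - N[i]
            v = CA[i] - N[i]
            u = u / np.linalg.norm(u)
            v = v / np.linalg.norm(v)
            bis = u + v
            h = N[i] - B_N_H * bis / np.linalg.norm(bis)
            entries.append(("H", "H", h))
        entries.append(("CA", "C", CA[i]))
        entries.append(("C", "C", C[i]))
        o = _nerf(N[i], CA[i], C[i], B_C_O, ANG_CA_C_O, psi[i] + 180.0)
        entries.append(("O", "O", o))
        for nm, el, xyz in entries:
            names.append(nm)
            elements.append(el)
            residues.append(res)
            coords.append(xyz)
    return PeptideBuild(sequence, phi, psi, names, elements, residues, np.array(coords))


# ---------------------------------------------------------------------------
# Bilayer
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BilayerRecipe:
    """Parameters of the synthetic bilayer.

    Defaults emulate the study membrane: 16×16 lipids per leaflet (512
    total), POPE:POPG 3:1, area per lipid 56.25 Ų (a 120 Å square patch),
    phosphate-plane separation 35 Å, fluid-phase chain order magnitude 0.18.
    """

    nx: int = 16
    ny: int = 16
    fractions: tuple = (("POPE", 0.75), ("POPG", 0.25))
    area_per_lipid: float = 56.25          # Å²
    leaflet_separation: float = 35.0       # Å between P planes
    order_magnitude: float | dict = 0.18   # target |S_CD|, scalar or per-carbon
    order_concentration: float = 50.0      # Beta concentration of the tilt sampler
    box_z: float = 100.0                   # Å
    carbons: tuple = tuple(range(2, 16))   # sn-1 chain positions

    def __post_init__(self) -> None:
        total = sum(f for _t, f in self.fractions)
        if abs(total - 1.0) > 1e-9:
            raise SyntheticError("lipid fractions must sum to 1")
        mags = (self.order_magnitude.values()
                if isinstance(self.order_magnitude, dict) else [self.order_magnitude])
        for m in mags:
            if not 0.0 <= m <= 0.5:
                raise SyntheticError(f"order magnitude {m} outside [0, 0.5]")

    def target_magnitude(self, carbon: int) -> float:
        if isinstance(self.order_magnitude, dict):
            return float(self.order_magnitude[carbon])
        return float(self.order_magnitude)


def sample_ch_orientations(signed_target: float, n: int, rng: np.random.Generator,
                           concentration: float = 50.0) -> np.ndarray:
    """Unit C→H vectors whose expected (3cos²θ−1)/2 equals ``signed_target``.

    cos²θ is drawn from Beta(κm, κ(1−m)) with mean m = (2s+1)/3; the
    degenerate targets s = −0.5 (m = 0) and s = 1 (m = 1) are produced
    exactly.  Azimuth and the sign of cosθ are uniform.
    """
    if not -0.5 <= signed_target <= 1.0:
        raise SyntheticError(f"signed order target {signed_target} outside [-0.5, 1]")
    m = (2.0 * signed_target + 1.0) / 3.0
    if m <= 0.0:
        u2 = np.zeros(n)
    elif m >= 1.0:
        u2 = np.ones(n)
    else:
        u2 = rng.beta(concentration * m, concentration * (1.0 - m), size=n)
    cos_t = np.sqrt(u2) * rng.choice([-1.0, 1.0], size=n)
    sin_t = np.sqrt(np.clip(1.0 - u2, 0.0, None))
    az = rng.uniform(0.0, 2.0 * np.pi, size=n)
    return np.column_stack([sin_t * np.cos(az), sin_t * np.sin(az), cos_t])


@dataclass
class _PeptideState:
    molecule_id: int
    build: PeptideBuild
    rotation: np.ndarray          # (3, 3)
    center: np.ndarray            # (3,)
    atom_start: int
    atom_stop: int

    def local_coords(self, build: PeptideBuild | None = None) -> np.ndarray:
        b = build or self.build
        return (b.coordinates - b.heavy_center()) @ self.rotation.T

    def placed_coords(self, center=None, build=None) -> np.ndarray:
        c = self.center if center is None else np.asarray(center)
        return self.local_coords(build) + c


@dataclass
class SyntheticSystem:
    """A built system: topology, one base frame, and peptide ground truth."""

    topology: Topology
    coordinates: np.ndarray
    box: np.ndarray
    recipe: BilayerRecipe
    peptides: list[_PeptideState] = field(default_factory=list)
    upper_plane_z: float = 0.0

    def frame(self, time: float = 0.0) -> Frame:
        return Frame(self.coordinates.copy(), self.box.copy(), time)

    def trajectory(self) -> Trajectory:
        return Trajectory(self.topology, [self.frame()])


def build_bilayer(recipe: BilayerRecipe = BilayerRecipe(), seed: int = 0) -> SyntheticSystem:
    """Construct the two-leaflet bilayer frame and topology from a recipe."""
    rng = np.random.default_rng(seed)
    spacing = float(np.sqrt(recipe.area_per_lipid))
    lx, ly = recipe.nx * spacing, recipe.ny * spacing
    box = np.array([lx, ly, recipe.box_z])
    z_mid = recipe.box_z / 2.0
    z_planes = {"upper": z_mid + recipe.leaflet_separation / 2.0,
                "lower": z_mid - recipe.leaflet_separation / 2.0}

    n_per_leaflet = recipe.nx * recipe.ny
    n_total = 2 * n_per_leaflet
    counts = {}
    acc = 0
    items = list(recipe.fractions)
    for t, f in items[:-1]:
        counts[t] = round(f * n_total)
        acc += counts[t]
    counts[items[-1][0]] = n_total - acc
    type_list = [t for t, c in counts.items() for _ in range(c)]
    type_list = [type_list[i] for i in rng.permutation(n_total)]

    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    lipid_types: dict[int, str] = {}
    mol = 0
    for leaflet, sign in (("upper", -1.0), ("lower", +1.0)):
        zp = z_planes[leaflet]
        for iy in range(recipe.ny):
            for ix in range(recipe.nx):
                ltype = type_list[mol]
                lipid_types[mol] = ltype
                x = (ix + 0.5) * spacing
                y = (iy + 0.5) * spacing
                atoms.append(Atom("P", "P", 1, ltype, mol, "lipid"))
                coords.append(np.array([x, y, zp]))
                for k in recipe.carbons:
                    cz = zp + sign * (CHAIN_START_OFFSET + (k - recipe.carbons[0]) * CHAIN_Z_STEP)
                    c_xyz = np.array([x, y, cz])
                    atoms.append(Atom(f"C{k}", "C", 1, ltype, mol, "lipid"))
                    coords.append(c_xyz)
                    target = -recipe.target_magnitude(k)      # chain ⊥ C–H geometry
                    u = sample_ch_orientations(target, 2, rng, recipe.order_concentration)
                    for hsub, uvec in zip("AB", u):
                        atoms.append(Atom(f"H{k}{hsub}", "H", 1, ltype, mol, "lipid"))
                        coords.append(c_xyz + CH_BOND * uvec)
                mol += 1
    top = Topology(atoms, lipid_types=lipid_types)
    return SyntheticSystem(top, np.array(coords), box, recipe,
                           upper_plane_z=z_planes["upper"])


def add_solvent(system: SyntheticSystem, n_water: int = 0, n_sodium: int = 0,
                n_chloride: int = 0, seed: int = 0) -> SyntheticSystem:
    """Append filler water/ion atoms in the water slab (bookkeeping tests only)."""
    rng = np.random.default_rng(seed)
    atoms = list(system.topology.atoms)
    coords = list(system.coordinates)
    mol = max((a.molecule_id for a in atoms), default=-1) + 1
    z_top = system.upper_plane_z + 5.0

    def rand_pos():
        return np.array([
            rng.uniform(0, system.box[0]),
            rng.uniform(0, system.box[1]),
            rng.uniform(z_top, system.box[2]),
        ])

    for _ in range(n_water):
        atoms.append(Atom("OH2", "O", 1, "TIP3", mol, "water"))
        coords.append(rand_pos())
        mol += 1
    for _ in range(n_sodium):
        atoms.append(Atom("SOD", "Na", 1, "SOD", mol, "ion"))
        coords.append(rand_pos())
        mol += 1
    for _ in range(n_chloride):
        atoms.append(Atom("CLA", "Cl", 1, "CLA", mol, "ion"))
        coords.append(rand_pos())
        mol += 1
    top = Topology(atoms, lipid_types=dict(system.topology.lipid_types),
                   peptide_sequences=dict(system.topology.peptide_sequences))
    return replace(system, topology=top, coordinates=np.array(coords))


def place_peptides(
    system: SyntheticSystem,
    builds: list[PeptideBuild],
    height: float = 20.0,
    seed: int = 0,
    max_retries: int = 50,
    min_clearance: float = 1.5,
) -> SyntheticSystem:
    """Place peptides at ``height`` Å above the upper phosphate plane.

    Orientations are seeded-random rotations; lateral positions are drawn
    uniformly in the box and retried until no atom comes within
    ``min_clearance`` Å of an existing atom.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    atoms = list(system.topology.atoms)
    coords_list = list(system.coordinates)
    lipid_types = dict(system.topology.lipid_types)
    sequences = dict(system.topology.peptide_sequences)
    peptides = list(system.peptides)
    mol = max((a.molecule_id for a in atoms), default=-1) + 1

    existing = np.array(coords_list) if coords_list else np.empty((0, 3))
    for build in builds:
        placed = None
        for _attempt in range(max_retries):
            rot = Rotation.random(random_state=rng).as_matrix()
            center = np.array([
                rng.uniform(0, system.box[0]),
                rng.uniform(0, system.box[1]),
                system.upper_plane_z + height,
            ])
            local = (build.coordinates - build.heavy_center()) @ rot.T
            xyz = local + center
            if existing.size:
                d2 = np.min(
                    np.sum((existing[None, :, :] - xyz[:, None, :]) ** 2, axis=-1)
                )
                if d2 < min_clearance ** 2:
                    continue
            placed = (rot, center, xyz)
            break
        if placed is None:
            raise SyntheticError(
                f"could not place peptide without clash after {max_retries} retries"
            )
        rot, center, xyz = placed
        start = len(atoms)
        for nm, el, res in zip(build.atom_names, build.atom_elements, build.atom_residues):
            resname = AA_1TO3[build.sequence[res - 1]]
            atoms.append(Atom(nm, el, res, resname, mol, "peptide"))
        coords_list.extend(xyz)
        existing = np.vstack([existing, xyz]) if existing.size else xyz
        sequences[mol] = build.sequence
        peptides.append(_PeptideState(mol, build, rot, center, start, len(atoms)))
        mol += 1

    top = Topology(atoms, lipid_types=lipid_types, peptide_sequences=sequences)
    return replace(system, topology=top, coordinates=np.array(coords_list),
                   peptides=peptides)


# ---------------------------------------------------------------------------
# Trajectory evolution
# ---------------------------------------------------------------------------

def _shortest_arc_lerp(a: np.ndarray, b: np.ndarray, s: float) -> np.ndarray:
    """Interpolate angles (degrees) along the shortest arc."""
    delta = (b - a + 180.0) % 360.0 - 180.0
    return a + s * delta


@dataclass
class Schedules:
    """Per-frame evolution programmes, all optional.

    insertion: peptide molecule_id -> (dz_start, dz_end) offsets added to the
        placement z, interpolated linearly; or an explicit per-frame array
        whose length must equal n_frames.
    unfolding: peptide molecule_id -> (residues 1-based, phi_end, psi_end);
        scheduled residues drift linearly (shortest arc) from their built
        dihedrals to the targets.
    aggregation: (molecule_ids, final_radius): selected peptides drift from
        their initial xy to points on a circle of final_radius (Å) around
        their common centroid.
    """

    insertion: dict | None = None
    unfolding: dict | None = None
    aggregation: tuple | None = None


def evolve_trajectory(
    system: SyntheticSystem,
    n_frames: int,
    noise_sd: float = 0.3,
    schedules: Schedules | None = None,
    seed: int = 0,
    dt_ps: float = 10.0,
) -> Trajectory:
    """Generate an ``n_frames`` trajectory from the built system.

    Per-atom Gaussian noise of ``noise_sd`` Å is added to every frame; the
    schedule progress variable runs 0 → 1 over the frames.  With zero noise
    and no schedules every frame equals the input.
    """
    if n_frames < 1:
        raise SyntheticError("n_frames must be >= 1")
    if noise_sd < 0:
        raise SyntheticError("noise_sd must be >= 0")
    sched = schedules or Schedules()
    rng = np.random.default_rng(seed)

    ins_arrays: dict[int, np.ndarray] = {}
    if sched.insertion:
        for pid, spec in sched.insertion.items():
            arr = np.asarray(spec, dtype=float)
            if arr.shape == (2,):
                arr = np.linspace(arr[0], arr[1], n_frames)
            elif arr.ndim == 1:
                if arr.size != n_frames:
                    raise SyntheticError(
                        f"insertion schedule for peptide {pid} has {arr.size} entries "
                        f"for {n_frames} frames"
                    )
            else:
                raise SyntheticError("insertion schedule must be (dz0, dz1) or per-frame")
            ins_arrays[pid] = arr

    agg_targets: dict[int, np.ndarray] = {}
    if sched.aggregation:
        ids, radius = sched.aggregation
        states = {p.molecule_id: p for p in system.peptides}
        missing = [i for i in ids if i not in states]
        if missing:
            raise SyntheticError(f"aggregation schedule names unknown peptides {missing}")
        centroid = np.mean([states[i].center[:2] for i in ids], axis=0)
        for k, pid in enumerate(ids):
            ang = 2.0 * np.pi * k / len(ids)
            agg_targets[pid] = centroid + radius * np.array([np.cos(ang), np.sin(ang)])

    unfold = sched.unfolding or {}
    for pid, (residues, _phi_end, _psi_end) in unfold.items():
        states = {p.molecule_id: p for p in system.peptides}
        if pid not in states:
            raise SyntheticError(f"unfolding schedule names unknown peptide {pid}")
        n_res = states[pid].build.n_residues
        if min(residues) < 1 or max(residues) > n_res:
            raise SyntheticError(f"unfolding residues out of range for peptide {pid}")

    frames = []
    for f in range(n_frames):
        s = 0.0 if n_frames == 1 else f / (n_frames - 1)
        xyz = system.coordinates.copy()
        for pep in system.peptides:
            center = pep.center.copy()
            if pep.molecule_id in ins_arrays:
                center[2] += ins_arrays[pep.molecule_id][f]
            if pep.molecule_id in agg_targets:
                center[:2] = (1 - s) * pep.center[:2] + s * agg_targets[pep.molecule_id]
            build = pep.build
            if pep.molecule_id in unfold:
                residues, phi_end, psi_end = unfold[pep.molecule_id]
                phi = build.phi.copy()
                psi = build.psi.copy()
                for r in residues:
                    phi[r - 1] = _shortest_arc_lerp(build.phi[r - 1], phi_end, s)
                    psi[r - 1] = _shortest_arc_lerp(build.psi[r - 1], psi_end, s)
                build = build_ideal_peptide(build.sequence, phi, psi)
            xyz[pep.atom_start:pep.atom_stop] = pep.placed_coords(center, build)
        if noise_sd > 0:
            xyz = xyz + rng.normal(0.0, noise_sd, size=xyz.shape)
        frames.append(Frame(xyz, system.box.copy(), time=f * dt_ps))
    return Trajectory(system.topology, frames)
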