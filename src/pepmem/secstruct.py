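"""Peptide conformational analysis: dihedrals, Ramachandran classification,
circular statistics, and hydrogen-bond secondary structure.

The secondary-structure assigner follows the Kabsch–Sander scheme: a backbone
H-bond from donor NH(i) to acceptor C=O(j) is accepted when the electrostatic
energy

    E = 0.42 * 0.20 * 332 * (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)   [kcal/mol]

is below −0.5 kcal/mol.  n-turns at offsets 3/4/5 define 3₁₀-, α- and
π-helices (two consecutive turns minimum).  The default priority assigns
π-helices (I) before α (H) before 3₁₀ (G) — the behaviour of current DSSP
versions — with a legacy α-first mode for comparison; isolated turns are T,
bends (Cα virtual-bond kink > 70°) are S, everything else O.

Angles are degrees in (−180, 180]; undefined values are NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Topology, Trajectory

__all__ = [
    "DihedralSeries",
    "SecondaryStructureRecord",
    "FlexibilityProfile",
    "AlphaRegion",
    "dihedral_angle",
    "backbone_dihedrals",
    "classify_alpha_region",
    "circular_variance",
    "assign_secondary_structure",
    "helix_content_timeseries",
    "flexibility_profile",
]

Q_HBOND = 0.42 * 0.20 * 332.0          # kcal·Å/mol, Kabsch–Sander prefactor
HBOND_ENERGY_CUTOFF = -0.5             # kcal/mol
BEND_THRESHOLD_DEG = 70.0
HELIX_LABELS = frozenset("HIG")


def _wrap_deg(angle: np.ndarray) -> np.ndarray:
    """Map angles into (−180, 180]."""
    a = np.asarray(angle, dtype=float)
    wrapped = ((a - 180.0) % -360.0) + 180.0
    return np.where(wrapped == -180.0, 180.0, wrapped)


def dihedral_angle(p0, p1, p2, p3) -> np.ndarray:
    """Signed dihedral (degrees, (−180, 180]) for points or stacks of points."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    m1 = np.cross(n1, b1n)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m1 * n2, axis=-1)
    return _wrap_deg(np.degrees(np.arctan2(y, x)))


@dataclass
class DihedralSeries:
    """Per-frame, per-residue backbone (phi, psi) for one peptide."""

    phi: np.ndarray          # (n_frames, n_residues), NaN where undefined
    psi: np.ndarray
    times: np.ndarray        # ps
    peptide_id: int
    sequence: str = ""

    @property
    def n_residues(self) -> int:
        return self.phi.shape[1]


class MissingAtomError(ValueError):
    pass


def _backbone_index_table(topology: Topology, peptide_id: int, names=("N", "CA", "C", "O")):
    """Atom index per residue for each requested backbone name, NaN-free or error."""
    idx = topology.atom_indices_of_molecule(peptide_id)
    if idx.size == 0:
        raise ValueError(f"no atoms for peptide molecule {peptide_id}")
    res = topology.residue_indices[idx]
    n_res = int(res.max())
    table: dict[str, np.ndarray] = {}
    for nm in names:
        col = np.full(n_res, -1, dtype=np.int64)
        for i in idx:
            if topology.atoms[i].name == nm:
                col[topology.atoms[i].residue_index - 1] = i
        table[nm] = col
    return table, n_res


def backbone_dihedrals(trajectory: Trajectory, peptide_id: int) -> DihedralSeries:
    """Compute phi/psi time series for one peptide molecule.

    phi(i) = C(i−1)–N(i)–CA(i)–C(i); psi(i) = N(i)–CA(i)–C(i)–N(i+1).
    phi is undefined (NaN) for residue 1, psi for the last residue.
    """
    top = trajectory.topology
    table, n_res = _backbone_index_table(top, peptide_id, names=("N", "CA", "C"))
    for nm in ("N", "CA", "C"):
        missing = np.flatnonzero(table[nm] < 0)
        if missing.size:
            raise MissingAtomError(
                f"peptide {peptide_id}: residue {missing[0] + 1} lacks backbone atom {nm}"
            )
    n_frames = trajectory.n_frames
    phi = np.full((n_frames, n_res), np.nan)
    psi = np.full((n_frames, n_res), np.nan)
    iN, iCA, iC = table["N"], table["CA"], table["C"]
    for f, frame in enumerate(trajectory.frames):
        xyz = frame.coordinates
        if n_res > 1:
            phi[f, 1:] = dihedral_angle(
                xyz[iC[:-1]], xyz[iN[1:]], xyz[iCA[1:]], xyz[iC[1:]]
            )
            psi[f, :-1] = dihedral_angle(
                xyz[iN[:-1]], xyz[iCA[:-1]], xyz[iC[:-1]], xyz[iN[1:]]
            )
    return DihedralSeries(
        phi, psi, trajectory.times, peptide_id,
        sequence=top.peptide_sequences.get(peptide_id, ""),
    )


@dataclass(frozen=True)
class AlphaRegion:
    """Inclusive Ramachandran bounds for the α-helical region."""

    phi_min: float = -90.0
    phi_max: float = -35.0
    psi_min: float = -70.0
    psi_max: float = -15.0


def classify_alpha_region(phi, psi, region: AlphaRegion = AlphaRegion()):
    """True where (phi, psi) falls in the α region (bounds inclusive).

    NaN (undefined) inputs classify False; a matching ``undefined`` mask is
    returned alongside so callers can distinguish "outside" from "no angle".
    """
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    undefined = np.isnan(phi) | np.isnan(psi)
    inside = (
        (phi >= region.phi_min) & (phi <= region.phi_max)
        & (psi >= region.psi_min) & (psi <= region.psi_max)
    )
    return np.where(undefined, False, inside), undefined


def circular_variance(angles_deg) -> float:
    """CV = 1 − R̄, with R̄ the mean resultant length of the angle unit vectors.

    0 for perfectly concentrated angles, 1 for maximally dispersed; NaN
    entries are dropped; all-NaN input returns NaN (undefined sentinel).
    """
    a = np.radians(np.asarray(angles_deg, dtype=float).ravel())
    a = a[~np.isnan(a)]
    if a.size == 0:
        return float("nan")
    r = np.hypot(np.mean(np.cos(a)), np.mean(np.sin(a)))
    return float(1.0 - min(r, 1.0))


@dataclass
class FlexibilityProfile:
    """Per-residue circular variance of phi and psi over a time window."""

    cv_phi: np.ndarray
    cv_psi: np.ndarray
    window_ps: tuple[float, float]
    peptide_id: int


def flexibility_profile(series: DihedralSeries, window_ps=None) -> FlexibilityProfile:
    """Circular variance per residue over ``window_ps`` (default: all frames)."""
    t = series.times
    if window_ps is None:
        mask = np.ones_like(t, dtype=bool)
        window_ps = (float(t[0]), float(t[-1]))
    else:
        mask = (t >= window_ps[0]) & (t <= window_ps[1])
        if not mask.any():
            raise ValueError("window contains no frames")
    cv_phi = np.array([circular_variance(series.phi[mask, r]) for r in range(series.n_residues)])
    cv_psi = np.array([circular_variance(series.psi[mask, r]) for r in range(series.n_residues)])
    return FlexibilityProfile(cv_phi, cv_psi, tuple(window_ps), series.peptide_id)


# ---------------------------------------------------------------------------
# Kabsch–Sander hydrogen bonds and structure labels
# ---------------------------------------------------------------------------

@dataclass
class SecondaryStructureRecord:
    """Per-frame, per-residue structure labels plus bend angles."""

    labels: np.ndarray       # (n_frames, n_residues) of unicode labels
    kappa: np.ndarray        # (n_frames, n_residues) bend angle, NaN near termini
    times: np.ndarray
    peptide_id: int
    priority: str = "pi_first"
    notices: list = field(default_factory=list)


def reconstruct_amide_h(xyz_c_prev, xyz_n, xyz_ca) -> np.ndarray:
    """Place the amide H 1.0 Å from N, in the C(i−1)–N–CA plane, opposite the bisector."""
    u = xyz_c_prev - xyz_n
    v = xyz_ca - xyz_n
    u = u / np.linalg.norm(u, axis=-1, keepdims=True)
    v = v / np.linalg.norm(v, axis=-1, keepdims=True)
    bis = u + v
    bis = bis / np.linalg.norm(bis, axis=-1, keepdims=True)
    return xyz_n - 1.0 * bis


def hbond_energy_matrix(xyz, iN, iCA, iC, iO, iH) -> np.ndarray:
    """Kabsch–Sander energies E[i, j]: donor NH(i) → acceptor C=O(j), kcal/mol.

    Entries for residue 1 (no amide H), j == i and j == i−1 (directly bonded
    peptide unit) are +inf.
    """
    n = len(iN)
    E = np.full((n, n), np.inf)
    H = np.full((n, 3), np.nan)
    has_h = iH >= 0
    H[has_h] = xyz[iH[has_h]]
    need = ~has_h & (np.arange(n) > 0)
    if need.any():
        k = np.flatnonzero(need)
        H[k] = reconstruct_amide_h(xyz[iC[k - 1]], xyz[iN[k]], xyz[iCA[k]])
    N = xyz[iN]
    O = xyz[iO]
    C = xyz[iC]
    for i in range(1, n):                        # residue 1 has no donor H
        if np.any(np.isnan(H[i])):
            continue
        r_on = np.linalg.norm(O - N[i], axis=1)
        r_ch = np.linalg.norm(C - H[i], axis=1)
        r_oh = np.linalg.norm(O - H[i], axis=1)
        r_cn = np.linalg.norm(C - N[i], axis=1)
        with np.errstate(divide="ignore"):
            e = Q_HBOND * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
        e[i] = np.inf
        if i - 1 >= 0:
            e[i - 1] = np.inf
        E[i] = e
    return E


def _bend_kappa(ca: np.ndarray) -> np.ndarray:
    """Angle (deg) between CA(i−2)→CA(i) and CA(i)→CA(i+2); NaN at termini."""
    n = ca.shape[0]
    kappa = np.full(n, np.nan)
    for i in range(2, n - 2):
        u = ca[i] - ca[i - 2]
        v = ca[i + 2] - ca[i]
        c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        kappa[i] = np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))
    return kappa


def _assign_frame_labels(hbond: np.ndarray, kappa: np.ndarray,
                         priority_order, include_sheets: bool) -> np.ndarray:
    n = hbond.shape[0]
    labels = np.array([""] * n, dtype=object)

    # n-turn at i: CO(i) accepts an H-bond from NH(i+n)
    turn = {}
    for off in (3, 4, 5):
        t = np.zeros(n, dtype=bool)
        for i in range(n - off):
            t[i] = hbond[i + off, i]
        turn[off] = t

    for off, lab in priority_order:
        t = turn[off]
        for i in range(1, n - off):
            if t[i - 1] and t[i]:
                for k in range(i, i + off):
                    if not labels[k]:
                        labels[k] = lab

    if include_sheets:
        bridge = np.zeros(n, dtype=bool)
        for i in range(1, n - 1):
            for j in range(1, n - 1):
                if abs(i - j) < 3:
                    continue
                para = (hbond[j, i - 1] and hbond[i + 1, j]) or (hbond[i, j - 1] and hbond[j + 1, i])
                anti = (hbond[i, j] and hbond[j, i]) or (hbond[i + 1, j - 1] and hbond[j + 1, i - 1])
                if para or anti:
                    bridge[i] = True
        for i in range(n):
            if bridge[i] and not labels[i]:
                ext = (i > 0 and bridge[i - 1]) or (i + 1 < n and bridge[i + 1])
                labels[i] = "E" if ext else "B"

    # isolated turns
    for off in (3, 4, 5):
        t = turn[off]
        for i in range(n - off):
            if t[i]:
                for k in range(i + 1, i + off):
                    if not labels[k]:
                        labels[k] = "T"

    for i in range(n):
        if not labels[i] and not np.isnan(kappa[i]) and kappa[i] > BEND_THRESHOLD_DEG:
            labels[i] = "S"
    labels[labels == ""] = "O"
    return labels.astype("U1")


def assign_secondary_structure(
    trajectory: Trajectory,
    peptide_id: int,
    priority: str = "pi_first",
    include_sheets: bool = False,
) -> SecondaryStructureRecord:
    """Assign H/I/G/T/S/O labels per residue per frame.

    ``priority='pi_first'`` assigns π-helices before α (I > H > G);
    ``'alpha_first'`` is the legacy H > G > I order.  Missing amide hydrogens
    are reconstructed with a logged notice; a missing carbonyl O is an error.
    """
    if priority not in ("pi_first", "alpha_first"):
        raise ValueError("priority must be 'pi_first' or 'alpha_first'")
    order = [(5, "I"), (4, "H"), (3, "G")] if priority == "pi_first" \
        else [(4, "H"), (3, "G"), (5, "I")]
    top = trajectory.topology
    table, n_res = _backbone_index_table(top, peptide_id, names=("N", "CA", "C", "O", "H"))
    for nm in ("N", "CA", "C", "O"):
        missing = np.flatnonzero(table[nm] < 0)
        if missing.size:
            raise MissingAtomError(
                f"peptide {peptide_id}: residue {missing[0] + 1} lacks backbone atom {nm}"
            )
    notices = []
    n_missing_h = int(np.sum(table["H"][1:] < 0))
    if n_missing_h:
        notices.append(f"reconstructed {n_missing_h} amide hydrogens (none in topology)")

    n_frames = trajectory.n_frames
    labels = np.empty((n_frames, n_res), dtype="U1")
    kappa = np.full((n_frames, n_res), np.nan)
    for f, frame in enumerate(trajectory.frames):
        xyz = frame.coordinates
        E = hbond_energy_matrix(xyz, table["N"], table["CA"], table["C"],
                                table["O"], table["H"])
        hb = E < HBOND_ENERGY_CUTOFF
        kap = _bend_kappa(xyz[table["CA"]])
        labels[f] = _assign_frame_labels(hb, kap, order, include_sheets)
        kappa[f] = kap
    return SecondaryStructureRecord(labels, kappa, trajectory.times, peptide_id,
                                    priority=priority, notices=notices)


def helix_content_timeseries(record: SecondaryStructureRecord) -> np.ndarray:
    """Per-frame fraction of residues labelled H, I or G."""
    if record.labels.size == 0:
        raise ValueError("empty secondary-structure record")
    helical = np.isin(record.labels, list(HELIX_LABELS))
    return helical.mean(axis=1)
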