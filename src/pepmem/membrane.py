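"""Bilayer geometry and acyl-chain order analysis.

The bilayer normal is taken as the box z axis (planar patch).  Leaflets are
assigned from lipid phosphorus z relative to the midplane; the phosphate
plane of a leaflet (mean P z) is the reference surface for peptide insertion
depth.  Acyl-chain order is quantified by the deuterium order parameter

    S_CD = ⟨(3 cos²θ − 1) / 2⟩

with θ the angle between a C–H bond vector and the bilayer normal, averaged
over bonds, qualifying lipids and frames.  Reported profiles follow the
|S_CD| convention used on experimental axes (positive magnitudes); signed
values are retained.  The "proximal" group restricts, per frame, to lipids
with any atom within a cutoff (default 4 Å, minimum image) of any peptide
atom, emulating the peptide-associated lipid population.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .core import Frame, Topology, Trajectory, minimum_image_distance

__all__ = [
    "LeafletAssignment",
    "DepthProfile",
    "OrderParameterProfile",
    "assign_leaflets",
    "phosphate_plane_z",
    "residue_depths",
    "area_per_lipid",
    "membrane_thickness",
    "scd_profile",
    "compare_order_groups",
    "proximal_lipids",
]

#: Chain-averaged |S_CD| reference constants from steady-state deuterium NMR
#: on POPE/POPG-d31 vesicles: unchallenged anionic/zwitterionic components
#: 0.179/0.177; with 2 mol% peptide 0.151 (pleurocidin) and 0.176
#: (magainin 2).  Documented for comparison; not used in any computation.
SCD_REFERENCE = {
    "POPG_d31_unchallenged": 0.179,
    "POPE_d31_unchallenged": 0.177,
    "POPG_d31_pleurocidin_2molpct": 0.151,
    "POPG_d31_magainin2_2molpct": 0.176,
}


class MembraneError(ValueError):
    pass


@dataclass
class LeafletAssignment:
    """Per-lipid leaflet labels for one frame."""

    leaflet: dict[int, str]       # molecule_id -> 'upper' | 'lower'
    midplane_z: float

    def lipids(self, which: str) -> list[int]:
        return [m for m, s in self.leaflet.items() if s == which]


def _lipid_p_index(topology: Topology) -> dict[int, int]:
    """Atom index of the single phosphorus of each lipid molecule."""
    out: dict[int, int] = {}
    for mol in topology.molecules("lipid"):
        idx = topology.atom_indices_of_molecule(mol)
        p = idx[topology.elements[idx] == "P"]
        if p.size != 1:
            raise MembraneError(f"lipid molecule {mol} has {p.size} P atoms (expected 1)")
        out[mol] = int(p[0])
    if not out:
        raise MembraneError("topology contains no lipids")
    return out


def assign_leaflets(frame: Frame, topology: Topology) -> LeafletAssignment:
    """Assign each lipid to the upper or lower leaflet by its P z position.

    The midplane is the mean z over all lipid P atoms; a P exactly on the
    midplane goes to the upper leaflet with a warning.
    """
    p_idx = _lipid_p_index(topology)
    z = {m: frame.coordinates[i, 2] for m, i in p_idx.items()}
    mid = float(np.mean(list(z.values())))
    leaflet = {}
    for m, zm in z.items():
        if zm == mid:
            warnings.warn(f"lipid {m} P exactly on midplane; assigned upper")
        leaflet[m] = "upper" if zm >= mid else "lower"
    return LeafletAssignment(leaflet, mid)


def phosphate_plane_z(frame: Frame, topology: Topology,
                      assignment: LeafletAssignment, leaflet: str = "upper") -> float:
    """Mean z (Å) of lipid phosphorus atoms in one leaflet."""
    mols = assignment.lipids(leaflet)
    if not mols:
        raise MembraneError(f"empty {leaflet} leaflet")
    p_idx = _lipid_p_index(topology)
    return float(np.mean([frame.coordinates[p_idx[m], 2] for m in mols]))


@dataclass
class DepthProfile:
    """Per-frame, per-residue signed distance (Å) to the upper phosphate plane.

    Positive = water side of the plane, negative = inserted below it.
    """

    depth: np.ndarray        # (n_frames, n_residues)
    times: np.ndarray
    peptide_id: int
    reference: str = "heavy_com"


def residue_depths(trajectory: Trajectory, peptide_id: int,
                   reference: str = "heavy_com") -> DepthProfile:
    """Signed per-residue depth relative to the upper-leaflet phosphate plane.

    ``reference``: 'heavy_com' (centre of geometry of the residue's heavy
    atoms, the default) or 'ca' (Cα position only).
    """
    if reference not in ("heavy_com", "ca"):
        raise ValueError("reference must be 'heavy_com' or 'ca'")
    top = trajectory.topology
    idx = top.atom_indices_of_molecule(peptide_id)
    if idx.size == 0:
        raise ValueError(f"no atoms for peptide molecule {peptide_id}")
    res = top.residue_indices[idx]
    n_res = int(res.max())
    groups = []
    for r in range(1, n_res + 1):
        sub = idx[res == r]
        if reference == "ca":
            sub = sub[top.names[sub] == "CA"]
        else:
            sub = sub[top.elements[sub] != "H"]
        if sub.size == 0:
            raise MembraneError(f"residue {r} of peptide {peptide_id} has no reference atoms")
        groups.append(sub)
    depth = np.empty((trajectory.n_frames, n_res))
    for f, frame in enumerate(trajectory.frames):
        asg = assign_leaflets(frame, top)
        plane = phosphate_plane_z(frame, top, asg, "upper")
        for r, sub in enumerate(groups):
            depth[f, r] = frame.coordinates[sub, 2].mean() - plane
    return DepthProfile(depth, trajectory.times, peptide_id, reference)


def area_per_lipid(frame: Frame, n_leaflet: int) -> float:
    """Lateral box area divided by lipids per leaflet (Å²)."""
    if n_leaflet <= 0:
        raise MembraneError("leaflet lipid count must be positive")
    return float(frame.box[0] * frame.box[1] / n_leaflet)


def membrane_thickness(frame: Frame, topology: Topology,
                       assignment: LeafletAssignment | None = None) -> float:
    """Phosphate-plane separation (Å): upper plane minus lower plane, > 0."""
    asg = assignment or assign_leaflets(frame, topology)
    t = (phosphate_plane_z(frame, topology, asg, "upper")
         - phosphate_plane_z(frame, topology, asg, "lower"))
    if t <= 0:
        raise MembraneError(
            f"non-positive thickness {t:.3f} Å: leaflet assignment looks swapped"
        )
    return float(t)


# ---------------------------------------------------------------------------
# Order parameters
# ---------------------------------------------------------------------------

_CARBON_RE = re.compile(r"^C(\d+)$")
_HYDROGEN_RE = re.compile(r"^H(\d+)[A-Z]?$")


def _chain_ch_table(topology: Topology, molecule_id: int,
                    carbons: range) -> dict[int, tuple[int, list[int]]]:
    """Map carbon position -> (C atom index, attached H indices) for one lipid.

    Relies on positional atom naming (C2..C15 with H2A/H2B etc.), the
    convention the synthetic builder and CHARMM-style chains share.
    """
    idx = topology.atom_indices_of_molecule(molecule_id)
    c_of: dict[int, int] = {}
    h_of: dict[int, list[int]] = {}
    for i in idx:
        name = topology.atoms[i].name
        mc = _CARBON_RE.match(name)
        if mc and int(mc.group(1)) in carbons:
            c_of[int(mc.group(1))] = i
            continue
        mh = _HYDROGEN_RE.match(name)
        if mh and int(mh.group(1)) in carbons:
            h_of.setdefault(int(mh.group(1)), []).append(i)
    return {k: (c_of[k], h_of.get(k, [])) for k in sorted(c_of)}


def scd_of_vectors(ch_vectors: np.ndarray) -> np.ndarray:
    """Signed S_CD sample values for an (n, 3) array of C→H vectors."""
    v = np.asarray(ch_vectors, dtype=float)
    cos2 = (v[:, 2] / np.linalg.norm(v, axis=1)) ** 2
    return 1.5 * cos2 - 0.5


def proximal_lipids(frame: Frame, topology: Topology, cutoff: float = 4.0) -> set[int]:
    """Lipid molecules with any atom within ``cutoff`` (minimum image) of any peptide atom."""
    if cutoff <= 0:
        raise MembraneError("cutoff must be positive")
    kinds = topology.kinds
    lip = np.flatnonzero(kinds == "lipid")
    pep = np.flatnonzero(kinds == "peptide")
    if lip.size == 0 or pep.size == 0:
        return set()
    box = frame.box
    lip_xyz = np.mod(frame.coordinates[lip], box)
    pep_xyz = np.mod(frame.coordinates[pep], box)
    tree = cKDTree(lip_xyz, boxsize=box)
    near = tree.query_ball_point(pep_xyz, r=cutoff)
    hit = sorted({j for lst in near for j in lst})
    # strict < cutoff, re-checked explicitly
    out = set()
    mol_ids = topology.molecule_ids
    for j in hit:
        d = minimum_image_distance(pep_xyz, lip_xyz[j], box)
        if np.any(d < cutoff):
            out.add(int(mol_ids[lip[j]]))
    return out


@dataclass
class OrderParameterProfile:
    """Per-carbon S_CD for one lipid group averaged over a time window."""

    lipid_type: str | None            # None = all lipid types pooled
    group: str                        # 'all' | 'proximal'
    carbons: np.ndarray               # chain positions
    scd_signed: np.ndarray            # mean signed S_CD per carbon
    scd_magnitude: np.ndarray         # |mean| per carbon (reported convention)
    n_samples: np.ndarray             # C–H samples per carbon
    window_ps: tuple[float, float]
    skipped_frames: int = 0

    def chain_average(self) -> float:
        """Sample-weighted chain-averaged |S_CD|."""
        w = self.n_samples.astype(float)
        return float(np.sum(self.scd_magnitude * w) / np.sum(w))


def scd_profile(
    trajectory: Trajectory,
    lipid_type: str | None = None,
    group: str = "all",
    cutoff: float = 4.0,
    window_ps: tuple[float, float] | None = None,
    carbons: range = range(2, 16),
) -> OrderParameterProfile:
    """Per-carbon S_CD profile for a lipid population.

    ``group='all'`` averages every lipid (of ``lipid_type`` if given);
    ``group='proximal'`` restricts per frame to lipids within ``cutoff`` Å of
    any peptide atom.  ``window_ps`` defaults to the last half of the
    trajectory, mirroring analysis over the final portion of a production
    run; frames with no qualifying lipid are skipped and counted.
    """
    if group not in ("all", "proximal"):
        raise ValueError("group must be 'all' or 'proximal'")
    t = trajectory.times
    if window_ps is None:
        window_ps = (float(t[0] + (t[-1] - t[0]) / 2.0), float(t[-1]))
    if window_ps[0] > t[-1] or window_ps[1] < t[0]:
        raise MembraneError(f"window {window_ps} outside trajectory time range")
    top = trajectory.topology
    mols = [m for m in top.molecules("lipid")
            if lipid_type is None or top.lipid_types.get(m) == lipid_type]
    if not mols:
        raise MembraneError(f"no lipids of type {lipid_type!r}")
    tables = {m: _chain_ch_table(top, m, carbons) for m in mols}
    carbon_list = sorted({k for tb in tables.values() for k in tb})
    sums = {k: 0.0 for k in carbon_list}
    counts = {k: 0 for k in carbon_list}
    skipped = 0
    in_window = [(i, f) for i, f in enumerate(trajectory.frames)
                 if window_ps[0] <= f.time <= window_ps[1]]
    if not in_window:
        raise MembraneError("window contains no frames")
    for _i, frame in in_window:
        if group == "proximal":
            prox = proximal_lipids(frame, top, cutoff)
            frame_mols = [m for m in mols if m in prox]
            if not frame_mols:
                skipped += 1
                continue
        else:
            frame_mols = mols
        xyz = frame.coordinates
        for m in frame_mols:
            for k, (ci, his) in tables[m].items():
                if not his:
                    continue
                vec = xyz[his] - xyz[ci]
                s = scd_of_vectors(vec)
                sums[k] += float(s.sum())
                counts[k] += s.size
    carbons_arr = np.array(carbon_list)
    signed = np.array([sums[k] / counts[k] if counts[k] else np.nan for k in carbon_list])
    return OrderParameterProfile(
        lipid_type, group, carbons_arr, signed, np.abs(signed),
        np.array([counts[k] for k in carbon_list]), window_ps, skipped,
    )


# ---------------------------------------------------------------------------
# Group statistics (profile comparison)
# ---------------------------------------------------------------------------

@dataclass
class OrderComparison:
    """Paired per-carbon comparison of two order-parameter profiles."""

    n: int
    wilcoxon_stat: float
    wilcoxon_p: float
    t_stat: float
    t_p: float
    anova_f: float
    anova_p: float
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    quartiles_a: tuple[float, float, float]      # 25/50/75%
    quartiles_b: tuple[float, float, float]
    zero_variance_differences: bool = False


def compare_order_groups(profile_a: OrderParameterProfile,
                         profile_b: OrderParameterProfile,
                         use_magnitude: bool = True) -> OrderComparison:
    """Wilcoxon signed-rank, paired t and one-way ANOVA on per-carbon values.

    Profiles are paired by carbon position (must match).  The Wilcoxon test
    is exact for n ≤ 25 and uses the normal approximation with continuity
    correction above.  All-identical paired differences yield t = 0, p = 1
    (no effect); equal nonzero differences yield an infinite t flag with
    p = 0.
    """
    if not np.array_equal(profile_a.carbons, profile_b.carbons):
        raise MembraneError("profiles do not share carbon indices; cannot pair")
    a = profile_a.scd_magnitude if use_magnitude else profile_a.scd_signed
    b = profile_b.scd_magnitude if use_magnitude else profile_b.scd_signed
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    n = a.size
    if n < 3:
        raise MembraneError(f"need >= 3 paired carbons, got {n}")
    diff = a - b
    zero_var = bool(np.allclose(diff, diff[0]))
    if np.allclose(diff, 0):
        w_stat, w_p = 0.0, 1.0
        t_stat, t_p = 0.0, 1.0
    else:
        if n <= 25:
            w = stats.wilcoxon(a, b, zero_method="wilcox", method="exact")
        else:
            w = stats.wilcoxon(a, b, zero_method="wilcox", method="approx", correction=True)
        w_stat, w_p = float(w.statistic), float(w.pvalue)
        if zero_var:
            t_stat = float(np.inf * np.sign(diff[0]))
            t_p = 0.0
        else:
            t = stats.ttest_rel(a, b)
            t_stat, t_p = float(t.statistic), float(t.pvalue)
    f = stats.f_oneway(a, b)
    q = lambda x: tuple(float(v) for v in np.percentile(x, [25, 50, 75]))
    return OrderComparison(
        n=n,
        wilcoxon_stat=w_stat, wilcoxon_p=w_p,
        t_stat=t_stat, t_p=t_p,
        anova_f=float(f.statistic), anova_p=float(f.pvalue),
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)), sd_b=float(b.std(ddof=1)),
        quartiles_a=q(a), quartiles_b=q(b),
        zero_variance_differences=zero_var,
    )
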