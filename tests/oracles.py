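"""Independent brute-force oracles used to cross-check the implementations.

Everything here is written with plain loops and scalar math, deliberately
sharing no code path with the package.
"""

import math

def mi_dist(a, b, box):
    """Scalar minimum-image distance."""
    s = 0.0
    for k in range(3):
        d = a[k] - b[k]
        d -= box[k] * round(d / box[k])
        s += d * d
    return math.sqrt(s)


def brute_force_lipid_contacts(frame, topology, cutoff):
    """Per-peptide, per-lipid-type atom-contact and distinct-lipid counts."""
    xyz = frame.coordinates
    box = frame.box
    lipid_atoms = [i for i, a in enumerate(topology.atoms) if a.molecule_kind == "lipid"]
    out = {}
    for pep in topology.molecules("peptide"):
        pidx = [i for i, a in enumerate(topology.atoms) if a.molecule_id == pep]
        counts = {}
        distinct = {}
        for j in lipid_atoms:
            near = False
            for i in pidx:
                if mi_dist(xyz[i], xyz[j], box) < cutoff:
                    near = True
                    break
            if near:
                t = topology.lipid_types[topology.atoms[j].molecule_id]
                counts[t] = counts.get(t, 0) + 1
                distinct.setdefault(t, set()).add(topology.atoms[j].molecule_id)
        out[pep] = (counts, {t: len(s) for t, s in distinct.items()})
    return out


def brute_force_proximal_lipids(frame, topology, cutoff):
    xyz = frame.coordinates
    box = frame.box
    pidx = [i for i, a in enumerate(topology.atoms) if a.molecule_kind == "peptide"]
    prox = set()
    for j, a in enumerate(topology.atoms):
        if a.molecule_kind != "lipid" or a.molecule_id in prox:
            continue
        for i in pidx:
            if mi_dist(xyz[i], xyz[j], box) < cutoff:
                prox.add(a.molecule_id)
                break
    return prox


def brute_force_interpeptide(frame, topology, cutoff):
    """Cα–Cα pair counts per unordered peptide pair."""
    xyz = frame.coordinates
    box = frame.box
    peps = topology.molecules("peptide")
    ca = {
        p: [i for i, a in enumerate(topology.atoms)
            if a.molecule_id == p and a.name == "CA"]
        for p in peps
    }
    out = {}
    for ii in range(len(peps)):
        for jj in range(ii + 1, len(peps)):
            c = 0
            for i in ca[peps[ii]]:
                for j in ca[peps[jj]]:
                    if mi_dist(xyz[i], xyz[j], box) < cutoff:
                        c += 1
            out[(peps[ii], peps[jj])] = c
    return out


def ks_hbond_energy(n, h, c, o):
    """Kabsch–Sander electrostatic H-bond energy (kcal/mol), scalar math."""
    def d(p, q):
        return math.sqrt(sum((p[k] - q[k]) ** 2 for k in range(3)))

    q1q2f = 0.42 * 0.20 * 332.0
    return q1q2f * (1.0 / d(o, n) + 1.0 / d(c, h) - 1.0 / d(o, h) - 1.0 / d(c, n))


def brute_force_hbond_set(build, cutoff=-0.5):
    """Set of (donor_residue, acceptor_residue) H-bonds for an ideal build.

    Residues are 1-based; donors start at residue 2 (the free N-terminus has
    no amide H); the directly bonded acceptor j = i−1 is excluded.
    """
    idx = {}
    for k, (name, res) in enumerate(zip(build.atom_names, build.atom_residues)):
        idx[(name, res)] = k
    xyz = build.coordinates
    nres = build.n_residues
    bonds = set()
    for i in range(2, nres + 1):
        if ("H", i) not in idx:
            continue
        for j in range(1, nres + 1):
            if j == i or j == i - 1:
                continue
            e = ks_hbond_energy(xyz[idx[("N", i)]], xyz[idx[("H", i)]],
                                xyz[idx[("C", j)]], xyz[idx[("O", j)]])
            if e < cutoff:
                bonds.add((i, j))
    return bonds
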