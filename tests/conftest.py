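import numpy as np
import pytest

from pepmem.core import AA_1TO3, Atom, Frame, Topology, Trajectory
from pepmem.synthetic import PeptideBuild


def build_to_trajectory(build: PeptideBuild, n_frames: int = 1,
                        box=(300.0, 300.0, 300.0), offset=100.0,
                        dt_ps: float = 10.0) -> Trajectory:
    """Wrap a raw peptide build into a one-peptide trajectory (no membrane)."""
    atoms = [
        Atom(n, e, r, AA_1TO3[build.sequence[r - 1]], 0, "peptide")
        for n, e, r in zip(build.atom_names, build.atom_elements, build.atom_residues)
    ]
    top = Topology(atoms, peptide_sequences={0: build.sequence})
    frames = [
        Frame(build.coordinates + offset, np.asarray(box, dtype=float), time=f * dt_ps)
        for f in range(n_frames)
    ]
    return Trajectory(top, frames)


@pytest.fixture
def peptide_trajectory_factory():
    return build_to_trajectory


@pytest.fixture
def small_bilayer():
    """4×4-per-leaflet bilayer (32 lipids), fluid-phase order, fixed seed."""
    from pepmem.synthetic import BilayerRecipe, build_bilayer

    return build_bilayer(BilayerRecipe(nx=4, ny=4, order_magnitude=0.18), seed=11)


@pytest.fixture
def bilayer_with_peptides(small_bilayer):
    """Two short ideal helices 20 Å above the upper leaflet."""
    from pepmem.synthetic import build_ideal_peptide, place_peptides

    builds = [build_ideal_peptide("GIGKFLHS", -57.0, -47.0),
              build_ideal_peptide("GWGSFFKK", -57.0, -47.0)]
    return place_peptides(small_bilayer, builds, height=20.0, seed=7)
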