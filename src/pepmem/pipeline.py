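"""End-to-end analysis orchestration: compose → secstruct → membrane → contacts.

`run_pipeline` executes every analysis stage on one trajectory and writes the
tabular outputs (TSV, first column = frame time in ps for per-frame tables)
plus a JSON run report with a checksummed manifest.  Defaults encode the
study thresholds — 4 Å lipid contacts, 10 Å Cα–Cα peptide contacts, the
Ramachandran α-region phi ∈ [−90, −35] / psi ∈ [−70, −15], π-before-α helix
priority, and averaging over the last half of the trajectory — each
overridable.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, composition, contacts, membrane, secstruct
from .core import Trajectory, read_multi_model_pdb
from .secstruct import AlphaRegion

__all__ = ["AnalysisConfig", "RunReport", "run_pipeline", "compute_targets",
           "acceptance_suite"]


class ConfigError(ValueError):
    pass


@dataclass
class AnalysisConfig:
    """Validated settings for one pipeline run."""

    trajectory: str
    out_dir: str
    window: str = "last-half"            # or "full" or "t0:t1" in ps
    lipid_cutoff: float = 4.0            # Å, peptide–lipid atom contacts
    peptide_cutoff: float = 10.0         # Å, Cα–Cα aggregation contacts
    alpha_region: tuple = (-90.0, -35.0, -70.0, -15.0)
    priority: str = "pi_first"           # or "alpha_first"
    depth_reference: str = "heavy_com"   # or "ca"
    seed: int = 0
    box: tuple | None = None             # fallback when the PDB has no CRYST1

    def __post_init__(self) -> None:
        if self.lipid_cutoff <= 0 or self.peptide_cutoff <= 0:
            raise ConfigError("cutoffs must be positive")
        pmin, pmax, smin, smax = self.alpha_region
        if not (pmin < pmax and smin < smax):
            raise ConfigError("alpha-region bounds must be well-ordered")
        if self.priority not in ("pi_first", "alpha_first"):
            raise ConfigError("priority must be pi_first or alpha_first")
        if self.window not in ("last-half", "full") and ":" not in self.window:
            raise ConfigError("window must be 'last-half', 'full' or 't0:t1'")

    def window_ps(self, times: np.ndarray) -> tuple[float, float]:
        if self.window == "full":
            return float(times[0]), float(times[-1])
        if self.window == "last-half":
            return float(times[0] + (times[-1] - times[0]) / 2.0), float(times[-1])
        t0, t1 = (float(x) for x in self.window.split(":"))
        return t0, t1

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "AnalysisConfig":
        d = json.loads(Path(path).read_text())
        for key in ("alpha_region", "box"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class RunReport:
    """Manifest of one pipeline run: outputs, checksums, provenance, warnings."""

    outputs: dict = field(default_factory=dict)      # name -> {path, sha256}
    warnings: list = field(default_factory=list)
    seed: int = 0
    version: str = __version__
    python: str = platform.python_version()

    def add(self, name: str, path: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.outputs[name] = {"path": str(path), "sha256": digest}

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"outputs": self.outputs, "warnings": self.warnings,
             "seed": self.seed, "version": self.version, "python": self.python},
            indent=2, sort_keys=True) + "\n")


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.5f")


def _composition_from_topology(top) -> composition.SystemComposition:
    """Minimal neutral composition inferred from a trajectory topology."""
    types = list(top.lipid_types.values())
    n_popg = sum(1 for t in types if t == "POPG")
    n_pope = len(types) - n_popg
    peptides = []
    for mol, seq in top.peptide_sequences.items():
        peptides.append((composition.PeptideSpec(f"peptide_{mol}", seq), 1))
    pep_charge = sum(composition.peptide_net_charge(s) * n for s, n in peptides)
    n_cl = max(0, pep_charge - n_popg)
    n_na = composition.required_sodium(n_popg, pep_charge, n_cl)
    return composition.SystemComposition(
        n_lipids_total=len(types), n_anionic=n_popg, n_zwitterionic=n_pope,
        peptides=peptides, n_sodium=n_na, n_chloride=n_cl, n_water=0,
    )


def run_pipeline(config: AnalysisConfig, trajectory: Trajectory | None = None) -> RunReport:
    """Run every analysis stage and write TSVs plus report.json to out_dir.

    Idempotent: the same inputs and seed produce byte-identical outputs.
    Any stage failure aborts with the stage name; outputs written so far stay
    in the partial manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed)
    stage = "read"
    try:
        traj = trajectory or read_multi_model_pdb(config.trajectory, box=config.box)
        top = traj.topology
        times = traj.times
        window = config.window_ps(times)
        peptide_ids = top.molecules("peptide")
        region = AlphaRegion(*config.alpha_region)

        stage = "composition"
        comp = _composition_from_topology(top)
        path = out / "composition.json"
        path.write_text(json.dumps(comp.to_dict(), indent=2, sort_keys=True) + "\n")
        report.add("composition", path)

        stage = "secstruct"
        dihedral_rows, ss_rows, flex_rows, helix_rows = [], [], [], []
        for pid in peptide_ids:
            series = secstruct.backbone_dihedrals(traj, pid)
            rec = secstruct.assign_secondary_structure(traj, pid, priority=config.priority)
            report.warnings.extend(f"peptide {pid}: {n}" for n in rec.notices)
            flex = secstruct.flexibility_profile(series, window)
            frac = secstruct.helix_content_timeseries(rec)
            in_alpha, _und = secstruct.classify_alpha_region(series.phi, series.psi, region)
            for f, t in enumerate(times):
                helix_rows.append((t, pid, frac[f], float(in_alpha[f].mean())))
                for r in range(series.n_residues):
                    dihedral_rows.append((t, pid, r + 1, series.phi[f, r], series.psi[f, r]))
                    ss_rows.append((t, pid, r + 1, rec.labels[f, r], rec.kappa[f, r]))
            for r in range(series.n_residues):
                flex_rows.append((pid, r + 1, flex.cv_phi[r], flex.cv_psi[r]))
        _write_tsv(pd.DataFrame(dihedral_rows,
                   columns=["frame_ps", "peptide", "residue", "phi", "psi"]),
                   out / "dihedrals.tsv")
        _write_tsv(pd.DataFrame(ss_rows,
                   columns=["frame_ps", "peptide", "residue", "label", "kappa"]),
                   out / "ss.tsv")
        _write_tsv(pd.DataFrame(flex_rows,
                   columns=["peptide", "residue", "cv_phi", "cv_psi"]),
                   out / "flexibility.tsv")
        _write_tsv(pd.DataFrame(helix_rows,
                   columns=["frame_ps", "peptide", "helix_fraction", "alpha_region_fraction"]),
                   out / "helix.tsv")
        for name in ("dihedrals", "ss", "flexibility", "helix"):
            report.add(name, out / f"{name}.tsv")

        stage = "membrane"
        depth_rows = []
        for pid in peptide_ids:
            prof = membrane.residue_depths(traj, pid, reference=config.depth_reference)
            for f, t in enumerate(times):
                for r in range(prof.depth.shape[1]):
                    depth_rows.append((t, pid, r + 1, prof.depth[f, r]))
        _write_tsv(pd.DataFrame(depth_rows,
                   columns=["frame_ps", "peptide", "residue", "depth_A"]),
                   out / "depth.tsv")
        report.add("depth", out / "depth.tsv")

        geom_rows = []
        for frame in traj.frames:
            asg = membrane.assign_leaflets(frame, top)
            n_upper = len(asg.lipids("upper"))
            geom_rows.append((frame.time,
                              membrane.area_per_lipid(frame, n_upper),
                              membrane.membrane_thickness(frame, top, asg)))
        _write_tsv(pd.DataFrame(geom_rows, columns=["frame_ps", "apl_A2", "thickness_A"]),
                   out / "geometry.tsv")
        report.add("geometry", out / "geometry.tsv")

        scd_rows = []
        lipid_types = sorted(set(top.lipid_types.values()))
        groups = ["all"] + (["proximal"] if peptide_ids else [])
        for ltype in lipid_types:
            for grp in groups:
                prof = membrane.scd_profile(
                    traj, lipid_type=ltype, group=grp,
                    cutoff=config.lipid_cutoff, window_ps=window)
                if prof.skipped_frames:
                    report.warnings.append(
                        f"scd {ltype}/{grp}: skipped {prof.skipped_frames} frames with "
                        "no qualifying lipids")
                for k, c in enumerate(prof.carbons):
                    scd_rows.append((ltype, grp, int(c), prof.scd_signed[k],
                                     prof.scd_magnitude[k], int(prof.n_samples[k])))
        _write_tsv(pd.DataFrame(scd_rows,
                   columns=["lipid_type", "group", "carbon", "scd_signed",
                            "scd_magnitude", "n_samples"]),
                   out / "scd.tsv")
        report.add("scd", out / "scd.tsv")

        stage = "contacts"
        if peptide_ids:
            records = []
            contact_rows = []
            for frame in traj.frames:
                rec = contacts.lipid_atom_contacts(frame, top, cutoff=config.lipid_cutoff)
                records.append(rec)
                for pid in peptide_ids:
                    for ltype in lipid_types:
                        contact_rows.append((
                            frame.time, pid, ltype,
                            rec.atom_contacts[pid].get(ltype, 0),
                            rec.distinct_lipids[pid].get(ltype, 0)))
            _write_tsv(pd.DataFrame(contact_rows,
                       columns=["frame_ps", "peptide", "lipid_type",
                                "atom_contacts", "distinct_lipids"]),
                       out / "contacts.tsv")
            report.add("contacts", out / "contacts.tsv")

            in_window = [r for r in records if window[0] <= r.time <= window[1]]
            pref = contacts.lipid_type_preference(in_window or records, comp)
            _write_tsv(pd.DataFrame(
                [(window[0], window[1], pref.observed_ratio, pref.expected_ratio,
                  pref.enrichment, pref.undefined_frames)],
                columns=["window_start_ps", "window_end_ps", "observed_ratio",
                         "expected_ratio", "enrichment", "undefined_frames"]),
                out / "preference.tsv")
            report.add("preference", out / "preference.tsv")

            if len(peptide_ids) >= 2:
                agg_rows, cluster_rows = [], []
                for frame in traj.frames:
                    mat = contacts.interpeptide_contacts(frame, top,
                                                         cutoff=config.peptide_cutoff)
                    part = contacts.cluster_peptides(mat)
                    cluster_rows.append((frame.time, part.largest, part.n_clusters))
                    n = len(mat.peptide_ids)
                    for i in range(n):
                        for j in range(i + 1, n):
                            agg_rows.append((frame.time, mat.peptide_ids[i],
                                             mat.peptide_ids[j], int(mat.counts[i, j])))
                _write_tsv(pd.DataFrame(agg_rows,
                           columns=["frame_ps", "pair_i", "pair_j", "ca_contacts"]),
                           out / "aggregation.tsv")
                _write_tsv(pd.DataFrame(cluster_rows,
                           columns=["frame_ps", "largest_cluster", "n_clusters"]),
                           out / "clusters.tsv")
                report.add("aggregation", out / "aggregation.tsv")
                report.add("clusters", out / "clusters.tsv")
    except Exception as exc:
        report.warnings.append(f"aborted in stage {stage}: {exc}")
        report.write(out / "report.json")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report.write(out / "report.json")
    return report


# ---------------------------------------------------------------------------
# Acceptance-style target computation
# ---------------------------------------------------------------------------

def compute_targets(seed: int = 0) -> dict:
    """Recompute the study's bookkeeping quantities from scratch.

    Returns ``{target_id: {"value": number, "n": problem size}}``; everything
    is derived at call time from the sequences and composition parameters.
    """
    from .contacts import null_contact_ratio

    pleu = composition.pleurocidin()
    mag = composition.magainin2()
    paper_config = {
        "n_lipids": 512,
        "anionic_fraction": 0.25,
        "peptides": [{"name": mag.name, "sequence": mag.sequence, "copies": 1}],
        "n_chloride": 5,
    }
    comp1 = composition.compose_system(paper_config)
    comp8 = composition.compose_system({
        "n_lipids": 512,
        "anionic_fraction": 0.25,
        "peptides": [{"name": pleu.name, "sequence": pleu.sequence, "copies": 8}],
        "n_chloride": 0,
    })
    return {
        "t1": {"value": composition.peptide_net_charge(pleu), "n": len(pleu.sequence)},
        "t2": {"value": composition.peptide_net_charge(mag), "n": len(mag.sequence)},
        "t3": {"value": comp1.n_sodium, "n": comp1.n_lipids_total},
        "t4": {"value": comp1.anionic_percent, "n": comp1.n_lipids_total},
        "t5": {"value": null_contact_ratio(384, 128, set_size=50, n_draws=10_000,
                                           seed=seed, statistic="pooled"),
               "n": 10_000},
        "t6": {"value": composition.simulated_time(comp1.n_steps, comp1.timestep_fs),
               "n": comp1.n_steps},
        "t7": {"value": comp8.lipid_peptide_ratio, "n": comp8.n_lipids_total},
    }


def acceptance_suite(seed: int = 0) -> dict:
    """Regenerate small fixtures and evaluate the release-gate property checks.

    Failures are reported as results (False), never raised.
    """
    import numpy as np

    from . import synthetic
    from .membrane import scd_of_vectors, scd_profile
    from .secstruct import backbone_dihedrals, circular_variance

    results: dict[str, dict] = {"targets": compute_targets(seed)}
    checks: dict[str, bool] = {}
    try:
        rng = np.random.default_rng(seed)
        v = rng.normal(size=(100_000, 3))
        checks["scd_isotropic_zero"] = bool(
            abs(float(np.mean(scd_of_vectors(v)))) < 0.01)
        checks["scd_magic_angle_zero"] = bool(abs(float(
            scd_of_vectors(np.array([[np.sqrt(2.0 / 3.0), 0.0, np.sqrt(1.0 / 3.0)]]))[0]
        )) < 1e-12)

        build = synthetic.build_ideal_peptide("A" * 12, -57.0, -47.0)
        sys0 = synthetic.build_bilayer(
            synthetic.BilayerRecipe(nx=8, ny=8, order_magnitude=0.18), seed=seed)
        sys1 = synthetic.place_peptides(sys0, [build], seed=seed + 1)
        traj = synthetic.evolve_trajectory(sys1, 8, noise_sd=0.0, seed=seed + 2)
        series = backbone_dihedrals(traj, sys1.peptides[0].molecule_id)
        checks["dihedral_round_trip"] = bool(
            np.allclose(series.phi[0, 1:], -57.0, atol=0.5)
            and np.allclose(series.psi[0, :-1], -47.0, atol=0.5))

        # >=2000 C-H samples per carbon over the 8 frames
        prof = scd_profile(traj, group="all", window_ps=(0.0, traj.times[-1]))
        checks["order_recovery"] = bool(
            np.all(np.abs(prof.scd_magnitude - 0.18) < 0.02))
        checks["cv_identity"] = bool(abs(
            circular_variance([0.0, 90.0]) - (1.0 - np.sqrt(2.0) / 2.0)) < 1e-9)
    except Exception as exc:              # failures are results here
        checks["suite_error"] = False
        results["error"] = {"message": str(exc)}
    results["checks"] = checks
    results["passed"] = all(checks.values())
    return results
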