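"""System-composition bookkeeping for peptide/membrane simulations.

Covers the arithmetic a simulator has to get right before any trajectory
exists: integer formal charges of the peptides (cationic AMPs with amidated
C-termini and, against anionic membranes, protonated histidines), counterion
neutralization of the anionic lipid fraction, lipid:peptide ratios and
simulated-time bookkeeping.

Charge model: +1 free N-terminus; +1 per Lys/Arg; +1 per His when the
his_protonated flag is set; −1 per Asp/Glu; −1 free C-terminus unless
amidated.  Charges are integers; pH-dependent partial protonation is out of
scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: The two peptides this package was built around (sequences as synthesized,
#: both C-terminally amidated).
MAGAININ2_SEQUENCE = "GIGKFLHSAKKFGKAFVGEIMNS"
PLEUROCIDIN_SEQUENCE = "GWGSFFKKAAHVGKHVGKAALTHYL"


class CompositionError(ValueError):
    """Raised for inconsistent composition inputs."""


@dataclass(frozen=True)
class PeptideSpec:
    """A peptide entry: sequence plus termini/protonation state."""

    name: str
    sequence: str
    c_term_amidated: bool = True
    his_protonated: bool = True

    def __post_init__(self) -> None:
        if not self.sequence:
            raise CompositionError("empty peptide sequence")
        for pos, letter in enumerate(self.sequence, start=1):
            if letter not in STANDARD_AA:
                raise CompositionError(
                    f"illegal amino-acid letter {letter!r} at position {pos} "
                    f"in peptide {self.name!r}"
                )


def magainin2(his_protonated: bool = True) -> PeptideSpec:
    return PeptideSpec("magainin 2", MAGAININ2_SEQUENCE, True, his_protonated)


def pleurocidin(his_protonated: bool = True) -> PeptideSpec:
    return PeptideSpec("pleurocidin", PLEUROCIDIN_SEQUENCE, True, his_protonated)


def peptide_net_charge(spec: PeptideSpec) -> int:
    """Net formal charge (elementary charges) of one peptide copy."""
    seq = spec.sequence
    charge = 1                                   # free N-terminal amine
    charge += seq.count("K") + seq.count("R")
    if spec.his_protonated:
        charge += seq.count("H")
    charge -= seq.count("D") + seq.count("E")
    if not spec.c_term_amidated:
        charge -= 1                              # free C-terminal carboxylate
    return charge


def required_sodium(n_anionic_lipids: int, peptide_total_charge: int, n_chloride: int) -> int:
    """Sodium count that neutralizes the system.

    Each anionic lipid carries −1; peptides contribute their summed net
    charge; chloride −1 each.  A negative result means the cationic peptides
    already over-neutralize the lipids — adjust chloride instead.
    """
    if min(n_anionic_lipids, n_chloride) < 0:
        raise CompositionError("counts must be non-negative")
    n_na = n_anionic_lipids - peptide_total_charge + n_chloride
    if n_na < 0:
        raise CompositionError(
            f"computed sodium count {n_na} is negative; the system has excess "
            "cationic charge — increase the chloride count instead"
        )
    return n_na


def simulated_time(n_steps: int, timestep_fs: float) -> float:
    """Simulated duration in ns for a constant-timestep run."""
    if n_steps < 0:
        raise CompositionError("n_steps must be >= 0")
    try:
        dt = float(timestep_fs)
    except (TypeError, ValueError):
        raise CompositionError(
            "only a constant scalar timestep is supported (no ramps)"
        ) from None
    if dt <= 0:
        raise CompositionError("timestep must be positive")
    return n_steps * dt * 1e-6


#: Sentinel for ratios that are undefined (e.g. lipid:peptide with 0 peptides).
UNDEFINED = None


@dataclass
class SystemComposition:
    """Fully resolved composition with a closed charge ledger."""

    n_lipids_total: int
    n_anionic: int
    n_zwitterionic: int
    peptides: list[tuple[PeptideSpec, int]]       # (spec, copies)
    n_sodium: int
    n_chloride: int
    n_water: int = 13000                          # advisory; not in the charge ledger
    box: tuple[float, float, float] = (120.0, 120.0, 100.0)   # Å
    timestep_fs: float = 2.0
    n_steps: int = 50_000_000
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_lipids_total != self.n_anionic + self.n_zwitterionic:
            raise CompositionError("lipid counts do not add up")
        if self.total_charge() != 0:
            raise CompositionError(
                f"system not neutral: total charge {self.total_charge():+d}"
            )

    def peptide_total_charge(self) -> int:
        return sum(peptide_net_charge(s) * n for s, n in self.peptides)

    def total_charge(self) -> int:
        return (
            -self.n_anionic + self.peptide_total_charge()
            + self.n_sodium - self.n_chloride
        )

    @property
    def n_peptides(self) -> int:
        return sum(n for _s, n in self.peptides)

    @property
    def anionic_percent(self) -> float:
        return 100.0 * self.n_anionic / self.n_lipids_total

    @property
    def lipid_peptide_ratio(self):
        """Lipids per peptide molecule; UNDEFINED (None) when no peptides."""
        if self.n_peptides == 0:
            return UNDEFINED
        return self.n_lipids_total / self.n_peptides

    @property
    def duration_ns(self) -> float:
        return simulated_time(self.n_steps, self.timestep_fs)

    def to_dict(self) -> dict:
        return {
            "n_lipids_total": self.n_lipids_total,
            "n_anionic": self.n_anionic,
            "n_zwitterionic": self.n_zwitterionic,
            "anionic_percent": self.anionic_percent,
            "peptides": [
                {
                    "name": s.name,
                    "sequence": s.sequence,
                    "copies": n,
                    "c_term_amidated": s.c_term_amidated,
                    "his_protonated": s.his_protonated,
                    "net_charge": peptide_net_charge(s),
                }
                for s, n in self.peptides
            ],
            "n_sodium": self.n_sodium,
            "n_chloride": self.n_chloride,
            "n_water": self.n_water,
            "lipid_peptide_ratio": self.lipid_peptide_ratio,
            "box_A": list(self.box),
            "timestep_fs": self.timestep_fs,
            "n_steps": self.n_steps,
            "duration_ns": self.duration_ns,
            "notes": self.notes,
        }


def compose_system(config: Mapping) -> SystemComposition:
    """Build a neutral :class:`SystemComposition` from a flat config mapping.

    Accepted keys: ``n_lipids`` (total) plus either ``n_anionic`` or
    ``anionic_fraction``; ``peptides``: list of dicts (name, sequence, copies,
    c_term_amidated, his_protonated); ``n_chloride``; optional ``n_sodium``
    (recomputed and a discrepancy note recorded if it does not neutralize);
    ``n_water``, ``box``, ``timestep_fs``, ``n_steps``.
    """
    n_lipids = int(config["n_lipids"])
    if "n_anionic" in config:
        n_anionic = int(config["n_anionic"])
    else:
        frac = float(config["anionic_fraction"])
        exact = frac * n_lipids
        n_anionic = round(exact)
        if abs(exact - n_anionic) > 1e-9:
            raise CompositionError(
                f"anionic fraction {frac} of {n_lipids} lipids is not an integer count"
            )
    peptides = []
    for p in config.get("peptides", []):
        spec = PeptideSpec(
            p["name"], p["sequence"],
            bool(p.get("c_term_amidated", True)),
            bool(p.get("his_protonated", True)),
        )
        peptides.append((spec, int(p.get("copies", 1))))
    n_chloride = int(config.get("n_chloride", 0))
    pep_charge = sum(peptide_net_charge(s) * n for s, n in peptides)
    n_sodium = required_sodium(n_anionic, pep_charge, n_chloride)
    notes = []
    if "n_sodium" in config and int(config["n_sodium"]) != n_sodium:
        notes.append(
            f"stated_ion_discrepancy: config lists {config['n_sodium']} Na+ but "
            f"neutrality requires {n_sodium}; using the neutral count"
        )
    return SystemComposition(
        n_lipids_total=n_lipids,
        n_anionic=n_anionic,
        n_zwitterionic=n_lipids - n_anionic,
        peptides=peptides,
        n_sodium=n_sodium,
        n_chloride=n_chloride,
        n_water=int(config.get("n_water", 13000)),
        box=tuple(config.get("box", (120.0, 120.0, 100.0))),
        timestep_fs=float(config.get("timestep_fs", 2.0)),
        n_steps=int(config.get("n_steps", 50_000_000)),
        notes=notes,
    )
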