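# Methods

This note documents the models, conventions and numerical choices behind
`pepmem`, and what its synthetic-data tests do and do not demonstrate about
real trajectories.

## System model and units

Trajectories are a fixed topology plus ordered frames of coordinates in Å
with an orthorhombic box (triclinic cells are rejected); times are in ps,
residue numbering is 1-based within each molecule. Every atom belongs to
exactly one molecule of kind peptide, lipid, water or ion; kinds are
inferred from residue names through configurable tables defaulting to
CHARMM-style dialects (POPE/POPG, TIP3/HOH, SOD/NA, CLA/CL). The reference
exchange format is multi-model PDB — one MODEL/ENDMDL block per frame,
CRYST1 for the box, frame time carried on a REMARK line — chosen because it
is human-readable and round-trips coordinates at the format's native 10⁻³ Å
precision. Binary formats are deliberately out of scope; anything that can
be converted to multi-model PDB can be analysed.

## Composition arithmetic

Formal charges are integers: +1 for the free N-terminal amine, +1 per
Lys/Arg, +1 per His when the protonation flag is set, −1 per Asp/Glu, and
−1 for a free C-terminus (0 when amidated). Histidine protonation is a
single per-peptide flag: against an anionic membrane surface the His pKa is
raised enough that the protonated state is the appropriate default for
these peptides; partial, pH-dependent charges are out of scope. With these
rules amidated pleurocidin is +8 and amidated magainin 2 is +5.

Neutralization solves n_Na = n_anionic − q_peptides + n_Cl (each anionic
lipid carries −1). The composer always computes the neutral ion counts for
the system at hand; when a configuration states different counts, the
discrepancy is recorded as a note rather than silently accepted, because a
single stated ion pair can neutralize only one of the six peptide-count
variants of the membrane system. The advisory water count never enters the
charge ledger.

## Conformational analysis

Dihedrals follow the standard convention: φ(i) = C(i−1)–N(i)–CA(i)–C(i),
ψ(i) = N(i)–CA(i)–C(i)–N(i+1), degrees in (−180, 180], NaN at chain
termini. The α-region classifier uses inclusive bounds φ ∈ [−90°, −35°],
ψ ∈ [−70°, −15°]; every accepted point has φ+ψ within the band shared by
α- and π-helices, which is exactly why Ramachandran analysis alone cannot
adjudicate between them and an H-bond assignment is needed.

Circular variance is 1 − R̄ with R̄ the mean resultant length of the angle
unit vectors: 0 for a rigid residue, 1 for maximal dispersion. Undefined
angles are dropped; an all-undefined series returns NaN. The default window
is the full trajectory; any ps window can be requested.

Secondary structure follows the Kabsch–Sander electrostatic model: a
backbone H-bond from donor NH(i) to acceptor C=O(j) is accepted when
E = 0.42·0.20·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) < −0.5 kcal/mol.
These constants are the original ones; they are part of the assignment
definition, not tunables. n-turns at offsets 3/4/5 with two consecutive
turns define 3₁₀/α/π helices; the default priority is π > α > 3₁₀ (the
behaviour of current DSSP releases), with an α-first legacy mode kept for
comparison because the two priorities disagree precisely on the
helices this analysis cares about. Isolated turns are T; a bend (S) needs a
Cα(i−2)→Cα(i) / Cα(i)→Cα(i+2) kink above 70°, the original DSSP threshold.
β-bridge/ladder detection exists behind an `include_sheets` flag but is
collapsed into O by default since these peptides are helical. Donor amide
hydrogens missing from the topology are reconstructed 1.0 Å from N in the
C(i−1)–N–CA plane opposite the bisector (standard DSSP practice), with a
logged notice; residue 1 (free amine) is never a donor and proline gets no
special-casing.

## Membrane analysis

The bilayer normal is the box z axis — appropriate for a planar patch, and
no director fitting is attempted. The midplane is the mean z of all lipid P
atoms; a lipid is "upper" when its P sits at or above it (exact ties go
upper with a warning). The phosphate plane of a leaflet is the mean P z;
thickness is the upper−lower plane separation and must be positive (a
non-positive value signals leaflet mis-assignment and is an error, not a
number). Area per lipid is Lx·Ly over the per-leaflet count.

Insertion depth is z(residue reference) − z(upper phosphate plane), so
positive means water side. The reference point is the centre of geometry of
the residue's heavy atoms by default (a Cα-only mode is provided); the
choice matters by ≲1 Å for these short side chains and both are exposed
because the underlying figure convention is not uniquely determined.

Order parameters: S_CD(k) = ⟨(3cos²θ−1)/2⟩ over the C–H bonds of chain
carbon k, qualifying lipids and frames in the window. Reported profiles use
the |S_CD| magnitude convention matching experimental deuterium-NMR axes;
signed values are kept in all outputs. Carbons 2–15 of the sn-1 chain are
analysed by default, mirroring a palmitoyl-d31 reporter chain. The
"proximal" group qualifies a lipid when **any** of its atoms is within 4 Å
(minimum image) of **any** peptide atom, per frame — lipid-level
granularity, whereas contact *counting* is atom-level; both readings of a
4 Å criterion are implemented because figure captions rarely pin this down.
The averaging window defaults to the last half of the trajectory, the
steady-enough portion of a binding run. Frames with no qualifying lipid are
skipped and counted. For context, chain-averaged |S_CD| values measured on
POPE/POPG-d31 vesicles (0.179/0.177 unchallenged; 0.151 with 2 mol%
pleurocidin, 0.176 with magainin 2) ship as documented constants in
`membrane.SCD_REFERENCE`; they are comparison anchors, not test targets.

Profile comparisons pair per-carbon values: Wilcoxon signed-rank (exact for
n ≤ 25, normal approximation with continuity correction above), paired t,
and one-way ANOVA, plus means, SDs and quartile summaries. Zero-variance
paired differences (a perfectly constant shift) give an infinite-t flag
with p = 0 rather than NaN; identical profiles give t = 0, p = 1.

## Contacts and aggregation

All distances use the minimum-image convention over the orthorhombic box,
and all cutoffs compare strictly (<). Neighbor search uses a periodic
k-d tree; its results are contract-checked in the tests against a plain
O(N²) loop oracle, so the tree is an optimization, never a semantics
change. A "contacted lipid" has ≥1 atom within the cutoff in that frame;
lifetimes are out of scope.

Lipid-type preference compares the POPE:POPG ratio of contacted lipids with
the composition ratio (3 for 384:128). The headline observed ratio pools
contacted counts over the window. The Monte-Carlo null (`null_contact_ratio`)
draws contacted sets uniformly from the composition: the pooled estimator
converges to n_POPE/n_POPG = 3, while the mean of per-draw ratios carries
an upward Jensen bias (E[a/b] > E[a]/E[b]; ≈ +0.22 for draws of 50 from
384:128) — both statistics are implemented, the pooled one is the default
because it estimates the quantity the preference analysis actually compares
against.

Aggregation counts Cα pairs between distinct peptides under 10 Å; peptides
with at least `min_contacts` pairs are joined and clusters are connected
components, with the largest-cluster size as the headline per-frame
statistic.

## Synthetic systems

The generator produces the study conditions by construction: a 16×16-per-
leaflet grid (512 lipids) at POPE:POPG 3:1, area per lipid 56.25 Ų (a
120 Å square patch), phosphate planes 35 Å apart in a 100 Å box, peptides
placed 20 Å above the upper plane with seeded random orientations, and
chain order magnitude 0.18 — a typical fluid-phase value consistent with
the deuterium-NMR anchors above. Lipids are simplified to one P headgroup
atom plus a single chain of CH₂ carbons with explicit hydrogen pairs:
sufficient for every implemented observable (planes, S_CD, contacts) and
nothing more.

Per C–H bond, cos²θ is drawn from a Beta distribution with mean
(2s+1)/3 for the signed target s and concentration 50, so the expected
sample order equals the target with a per-sample SD ≈ 0.1; ~2000 samples
per carbon recover targets within ±0.02. Target magnitude 0.5 is produced
degenerately (all C–H exactly perpendicular to z, the all-trans limit).
Chains carry signed target −|s|, the physical sign for chain-ordered
lipids.

Peptide builders use ideal bond lengths/angles (N–CA 1.458, CA–C 1.525,
C–N 1.329, C=O 1.231 Å; ω = 180°) and reproduce requested dihedrals to
≪0.5°. Under this geometry an α-helix fixture is (−57, −47); (−75, −50)
yields clean i→i+5 (π) Kabsch–Sander bonding, and (−65, −55) yields both
i+4 and i+5 bonds and therefore probes the π-before-α precedence — note
that textbook "π-helix" dihedral values near (−76, −41) produce only α
bonding with ideal bond geometry, which is why the π fixtures use the
values above.

Frame evolution adds i.i.d. Gaussian positional noise and optional
schedules: rigid z-insertion (endpoint pair or per-frame offsets),
unfolding (per-residue dihedral drift to coil values along the shortest
arc, with the backbone rebuilt each frame), and aggregation (selected
peptides drift to a circle around their common centroid). Everything is
deterministic under a fixed seed.

What the synthetic tests show: that every analysis recovers known
generating parameters (composition counts exactly, order within ±0.02,
depths within noise, dihedrals within 0.5°, cluster membership exactly) and
matches independent brute-force oracles. What they do not show: correctness
on real force-field geometry (glycerol backbones, sn-2 chains, headgroup
tilt), collective lipid motions, or any physical kinetics — the generator
has no energetics, and schedule shapes are stipulated, not emergent.

## Problem sizes and tolerances

Tests run on 4×4 to 16×16 bilayers and 1–12-frame trajectories — sizes at
which the O(N²) oracles are exact and fast and at which the statistical
checks (isotropic S_CD within ±0.01 at 10⁵ samples; order recovery within
±0.02 at ≥2000 samples per carbon; the contact-ratio null within ±0.1 at
10⁴ draws) have comfortable margins under their fixed seeds. Dihedral
round-trips are asserted at 0.5°, rigid-body invariance at 10⁻⁶ degrees,
and PDB round-trips at the format's 10⁻³ Å. The acceptance script's only
stochastic quantity is the contact-ratio null; all other reported values
are exact arithmetic from the sequences and composition parameters.

## Known limitations

- Only orthorhombic boxes; no wrapped-molecule repair (inputs are assumed
  whole by molecule).
- The secondary-structure assigner labels sheets only when asked and does
  not implement DSSP's full ladder/ladder-merge bookkeeping; for helical
  peptides this is immaterial.
- S_CD carbon identification relies on positional atom naming (C2…C15 with
  H2A/H2B…); trajectories with other naming dialects need renaming or a
  custom carbon range.
- The proximity and contact analyses assume peptide and lipid molecules are
  not bonded to each other (no exclusion lists).
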