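# Methods

## The near-attack-conformation statistic

For a candidate site with carbon C and hydrogens {Hᵢ}, and ferryl oxygen O,
a frame is *active* for that site iff any Hᵢ satisfies

    d(O···Hᵢ) ≤ d_max   and   θ_lo ≤ ∠O–Hᵢ–C ≤ min(θ_hi, 180°)

with defaults d_max = 2.8 Å, θ = 170 ± 15° (θ_lo = 155°, nominal θ_hi =
185° capped at the geometric maximum 180°). All boundaries are inclusive.
The "any hydrogen" rule reflects chemistry: a methyl reacts through
whichever of its three equivalent hydrogens is presented, and the counting
unit is the conformation per site, not per hydrogen. The per-site count
n_active over N frames estimates the fraction of the ensemble that is
abstraction-competent at that site; `NACResults` attaches a Wilson score
interval to that binomial fraction. No free-energy weighting of frames is
applied — snapshots are treated as exchangeable draws from the sampled
ensemble, which is how MD snapshot sets are normally consumed.

The angle is computed at the hydrogen vertex from the two bond vectors
(arc-cosine of the clipped normalized dot product); distances are plain
Euclidean norms in Å. Rankings from `predict_sites` sort by descending
n_active, breaking ties by ascending mean qualifying O···H distance (a
closer approach is a better pre-reactive geometry), then lexically for full
determinism.

## Hydrogen treatment

MD-derived ensembles carry explicit hydrogens and those are used verbatim.
Crystal-derived models deposit no aliphatic hydrogens, so sites classified
as sp3 CH/CH₂/CH₃ get ideal-geometry placement: C–H = 1.09 Å exactly;
CH along the negated sum of unit vectors to the three heavy neighbors;
CH₂ in the plane through the external bisector perpendicular to the
heavy–C–heavy plane with H–C–H = 109.47°; CH₃ tetrahedral to the
C–neighbor axis and torsionally staggered against the lowest-index heavy
substituent on that neighbor. Placement is deterministic and commutes with
rigid-body motion to 1e-6 Å, which we prioritized over force-field realism:
the criterion tolerates ~0.1 Å of hydrogen-position error, while
minimization would make counts depend on optimizer details. The methyl
rotor orientation is the recognized approximation; `methyl_rotamers = k`
pools k staggered rotor offsets spanning the 120° period and lets the
criterion take the best candidate (default k = 1, i.e. the single staggered
rotamer). For crystal-derived ensembles this placement is a stated
surrogate for whatever hydrogen treatment produced published counts from MD
trajectories.

## Perception

Bonds: d ≤ r_cov(a) + r_cov(b) + 0.45 Å over a shipped Cordero-style radius
table; H–H never bonds; a hydrogen keeps only its nearest heavy-atom bond.
Candidate sites are substrate carbons with 1–3 heavy neighbors, excluding
carbonyl carbons (any C–O edge < 1.30 Å) and members of planar rings
(max deviation from the ring least-squares plane < 0.1 Å) whose atoms are
all sp2-plausible (≤ 3 neighbors counting hydrogens). This planarity proxy
deliberately avoids full aromaticity perception: the substrates in scope
(DKP core plus aliphatic side chains) never need Hückel counting. The limit
is real — a genuinely planar, 3-coordinate non-aromatic ring would be
excluded — and is accepted. No pKa or bond-order logic beyond the carbonyl
cutoff.

## Inherent reactivity and strategy calls

Barrier tables map site label → ΔG‡ of hydrogen abstraction in kcal mol⁻¹,
consumed as printed data (quantum chemistry is out of scope here). The
inherent site is the row with minimal barrier; exact ties are surfaced and
classification refuses to guess on a tie. The shipped default tables for
substrates 1–3 contain the text-quoted values (6.4, 5.1, 5.3 kcal mol⁻¹ at
C-2′, C-2′, C-5 respectively); fuller tables exist only as figure images
and must be transcribed by the user.

Directing-group evidence is heavy-atom only (crystal models lack polar
hydrogens): a substrate hydroxyl oxygen within 2 covalent bonds of the
reacting carbon, within 3.5 Å of any protein-side O/N. The 3.5 Å cutoff is
the conventional heavy-atom hydrogen-bond limit and the 2-bond adjacency is
abstracted from the ortho-hydroxyl relationships that define the
directing-group cases (2′-OH → C-3′, 7-OH → C-6); both are config-exposed.
The classification is a total partition — exactly one of the three
strategies fires for any (inherent, observed, evidence) triple.

## Superposition and measurements

Kabsch least-squares rigid-body fit (SVD with the determinant correction,
so the rotation is always proper). Whole-structure comparisons pair Cα
atoms of residues matched by a global identity-scored sequence alignment,
not by residue number, since the enzymes compared share only ~35–42%
identity. No outlier-rejection cycles are applied by default; tools that
iteratively discard far pairs report RMSDs lower by roughly 0.1–0.3 Å, so
cross-tool comparisons should expect that offset. Reports round distances
to 0.1 Å and angles to 1°, matching conventional crystallographic report
precision; JSON retains machine precision.

## Pocket volume

A POCASA-like grid estimate: cubic grid (spacing ≤ 1 Å, default 0.5 Å)
inside a sphere of `shell_radius` (default 8 Å) around a chosen center;
a point counts if it clears every atom's vdW + probe sphere (probe default
1.4 Å) and is *buried* — of the 26 cubic-lattice rays marched from the
point, at least `buriedness_k = 16` hit an atom within the shell radius.
Volume = count × spacing³. On an analytic spherical cavity of radius 3 Å
the estimate lands within a few percent of (4/3)π·3³. The descriptor is
meant for rank comparisons between pockets of homologous enzymes; absolute
agreement with any particular cavity server is explicitly not a goal, since
those differ in probe handling and buriedness heuristics.

## The synthetic generator

`build_theozyme` places Fe at the origin, the oxo on +z at 1.62 Å (a
conventional ferryl length, config-exposed, not a literature fit), and
fills the remaining octahedral positions with two methylimidazole N donors,
two acetate O donors and a water — enough structure for oxo identification
and NAC geometry, with no pretense of electronic realism. `build_dkp`
assembles idealized DKP substrates by internal-coordinate construction
(ring bonds ~1.45–1.47 Å, side-chain C–C 1.53 Å, C–O 1.43 Å, tetrahedral
angles), with hydroxyl decorations distinguishing substrates 2 and 3, and
explicit ideal hydrogens on every labelled site carbon.

`sample_nac_ensemble` plants ground truth *geometrically*: an active frame
poses the rigid substrate so the target hydrogen sits at d ~ U[2.0, 2.7] Å
and θ ~ U[160°, 180°] — inside the criterion with margin, so 3-decimal PDB
round-trips cannot flip a frame — while a search over the two free pose
angles keeps every other site's hydrogens ≥ 3.5 Å from the oxo; an inactive
frame places the whole substrate so every atom is > 3.2 Å away. The ledger
therefore equals the tally *exactly*, by construction rather than
statistically, which is what makes exact recovery a meaningful test.
Frames vary only by rigid substrate pose (internal geometry is fixed);
that suffices because the statistic depends only on O/H/C positions.

What the generator does **not** emulate: thermal internal motions,
force-field energetics, solvent, protein flexibility, or correlated frames.
Passing planted-recovery tests therefore demonstrates the counting
machinery is exact — not that any real enzyme's MD ensemble would give a
particular count. Real-trajectory counts require the original solvated MD
snapshots, which are outside desk scope.

## Problem sizes and determinism

The shipped test and acceptance runs use ensembles of 100–5000 frames,
mini-ensembles of ≤ 50 frames for brute-force cross-checks (50 of them), a
400-atom cavity cage, and 20–30-point Kabsch problems; these sizes exercise
every code path while keeping a full run in tens of seconds. All
randomness flows through seeded `numpy` generators; identical seeds give
bitwise-identical ensembles, and reports exclude timestamps so reruns are
byte-identical.

## Known limitations

- Ideal hydrogen placement, not ensemble-averaged hydrogen sampling; the
  methyl rotor default is a single staggered rotamer.
- The aromaticity proxy is geometric, not electronic.
- Hydrogen-bond evidence ignores donor/acceptor geometry (no angle term).
- Pocket volumes are comparative descriptors, not server-reproducible
  absolutes.
- Whole-structure RMSD depends on the pairing protocol; values from
  outlier-rejecting tools will differ systematically.
- The shipped barrier tables are limited to text-quoted values.
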