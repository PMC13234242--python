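# Methods

`snnkit` implements the computational side of a structural study of
asparagine→succinimide (SNN) conversion: how an Asn side chain cyclises
onto the backbone amide nitrogen of the following (n+1) residue, losing
ammonia (−17.027 Da) and forming the five-membered cyclic imide that can
later hydrolyse to Asp/iso-Asp (+0.984 Da relative to Asn).  The package
covers four layers: structure geometry, succinimide-site scanning,
metadynamics free-energy post-processing, and the mass-spectrometric
arithmetic that quantifies SNN/Asn/Asp populations.

## Structure model and geometry

Structures are read through gemmi (fixed-column PDB and mmCIF) into a
minimal chain→residue→atom model.  Two policies matter downstream:

* **SNN residues stay in-chain.**  The succinimide is deposited as a
  HETATM residue; stripping heteroatoms would delete the analyte.  The
  model keeps every ATOM/HETATM record of the first model at its author
  residue number.
* **Alternate locations collapse deterministically** to the
  highest-occupancy conformer, ties broken by altloc letter, so repeated
  geometry calls see a single conformer.

Torsions are IUPAC-signed angles in (−180°, +180°], computed with the
atan2 cross/dot construction and unit-tested against an independent
Newman-projection oracle.  Two invariants are property-tested: reversing
the four points preserves the torsion, and mirror reflection negates it
(plus invariance under rigid motion).  φ/ψ/ω at chain termini are
*undefined*, not errors.  χ1/χ2 use the standard fourth-atom tables
(CA–CB–CG–OD1 for Asn); the SNN ring maps CB→CB, CG→CG, OD1→OD1, so the
same formula yields its χ-equivalents.

Contacts use a cKDTree within a heavy-atom cutoff (default 4.0 Å, the
value used for the succinimide environment analysis), excluding
same-residue pairs and 1-2/1-3 neighbours across the peptide bond;
waters and ions are excluded by default.  An O(n²) all-pairs scan serves
as the test oracle.  Hydrogen bonds accept donor–acceptor < 3.5 Å and,
when hydrogens exist (MD frames), donor–H–acceptor > 140°; crystal mode
is distance-only because deposited crystal structures carry no
hydrogens.  α/β-turns are an O(i)…N(i+4)/N(i+3) hydrogen bond.
Superposition is a Kabsch fit with up to 5 outlier-rejection cycles,
each dropping pairs deviating by more than 2 × the current RMSD
(the common reading of align-style "5 cycles, cutoff 2"); both knobs are
arguments.

## Site scanning

`scan_asn_sites` reports, for every Asn/SNN residue: the CG(n)→N(n+1)
distance, φ/ψ/χ1/χ2, the n+1 residue's ψ, the Ramachandran quadrant
(sign-based, 0° assigned to the positive side), and a near-attack
verdict with per-criterion evidence.  The near-attack criteria are a
mandatory distance test (< 3.5 Å) plus optional angular windows
(χ1 ≈ +120°, χ2 ≈ ±90°, ψ ≈ −120°, tolerance ±40°).  The angular checks
default to *off*: crystal geometries that clearly precede cyclisation in
practice (χ1 ≈ 174°) fall outside the canonical χ1 window, so distance
is the only criterion that is uniformly diagnostic; strict mode is one
flag away.  The ±40° tolerance is a package choice, not a literature
constant.

Catalyst shortlisting returns every residue with a heavy atom within the
cutoff of the site's side-chain/ring atoms, with structural role hints:
*direct-base* (carboxylate O within H-bond range of the n+1 backbone N),
*relay* (hydroxyl/amine chained by an H-bond to a direct contact),
*electrostatic* (other charged-group atoms in contact), else *vdw*.
These are geometric labels only — mutagenesis, not geometry, decides
catalysis.  The ψ-based proton-affinity label ships as an editable range
table (default: ψ ∈ [−50°, −10°] → "moderately-low") because the
underlying affinity maps are external published data.

## Metadynamics post-processing

Collective variables are signed combinations of coordination numbers
built from the rational switching function
s(r) = (1 − (r/r0)^nn)/(1 − (r/r0)^mm), nn=6, mm=12 (engine defaults),
with the removable singularity at r = r0 evaluating to nn/mm.  The
default COMBINE coefficients (+0.5, −0.5) map the reactant/product
endpoints to (−0.5, −0.5)/(+0.5, +0.5).  The upper wall is a one-sided
harmonic (location 5.5 Å, k = 200 kcal/mol, exponent 2).

HILLS files use the PLUMED-style column layout (time, centers, sigmas,
height, optional ignored bias factor).  The free-energy estimator is the
nontempered one, F(s) = −ΣV(s) min-shifted to zero; each Gaussian is
deposited on the grid with support truncated at 8σ (exp(−32) ≈ 1e−14),
making reconstruction linear in the hill count.

The activation barrier is extracted as a **minimax path**: among all
8-connected grid paths from reactant to product, the one minimising the
maximum free energy met en route (ties → minimal integrated free energy,
then lexicographic order), via Dijkstra with lexicographic costs.  An
integrated-cost mode exists as an option.  Minimax was chosen because an
activation barrier is a path-maximum quantity.  The independent
cross-check is the threshold characterisation: the minimax value equals
the smallest level t at which start and end become connected through
nodes with F ≤ t (union-find over sorted levels); both routes agree to
machine precision on random grids.

Transition detection reports the earliest time all CV series exceed a
threshold (default 0) and stay above it for a dwell window (default
0.2 ps, configurable); runs reaching the end of the series count as
sustained.

## Trajectory statistics

Trajectories are a topology plus an (n_frames, n_atoms, 3) array with
strictly increasing times; supported formats are multi-model PDB and a
plain-text XYZ-like frame format.  Distance histograms use a 0.01 Å bin
width by default and report raw counts, unit-area density *and*
cumulative fraction — printed "normalized distribution" probabilities
are ambiguous between the two readings, so both are exposed.
Hydrogen-bond occupancy applies the < 3.5 Å / > 140° criteria per frame.
Frame extraction takes the nearest frame, ties to the earlier one.

## Synthetic data

* **Peptide builder** — NeRF internal-coordinate chain growth with ideal
  (Engh–Huber-like) bond lengths/angles; the CB improper (N–C–CA–CB =
  +122.7°) fixes L-chirality.  Side chains are built through the
  χ2-bearing atom (full amide/carboxylate for Asn/Asp; aromatic rings
  stop at CD1/CD2).  The fidelity target is torsion round-trip (< 0.1°
  measured), not force-field realism: bond lengths are idealised, there
  are no hydrogens, and no steric relaxation (collapses warn, not fail).
  Passing tests therefore validate the *measurement* pipeline, not
  conformational plausibility.
* **Hill streams** — the default double-well surface has two 5 kcal/mol
  Gaussian wells (σ 0.12) at (∓0.4, ∓0.4) on a wall-confined (−0.6, 0.6)²
  domain, mimicking the reactant/product basins of the deprotonation CV
  space; its true barrier is computed by dense-grid threshold search.
  Two stream constructions exist.  The *quadrature* default places hills
  on a σ-spaced lattice (±0.1-cell seeded jitter, shuffled order) with
  heights ∝ C − U(center), so −Σhills reproduces the surface to well
  under one hill height; barrier recovery across seeds 1–10 measured
  ≤ 3% error.  The *walk* mode is a Metropolis walker on U plus its own
  deposited bias — the dynamical emulation of a nontempered engine.
  Fixed-height walk streams carry an irreducible O(1 kcal/mol) regional
  fill noise (measured across kT ∈ [0.1, 3], steps 0.02–0.04, up to 80k
  hills), which a minimax path systematically exploits; walk streams are
  therefore for qualitative emulation, quadrature streams for
  quantitative ground truth.  Hill height (0.59 kcal/mol) and σ
  (0.005/0.006) follow the study conditions in both modes.
* **Trajectories** — seeded Gaussian positional noise around a reference
  with scripted displacement events (linear 5-frame ramp), e.g. a proton
  moved from a backbone N to a carboxylate O; constructed event
  fractions are recovered exactly by the analysis layer.
* **Sequences** — point mutations parsed from names like "D110V_K151L",
  from-residue checked.

## Mass layer

Monoisotopic residue masses ship as a versioned constants table
(proton = 1.007276 Da, water = 18.010565 Da); the independent test
oracle is elemental-composition summation via pyteomics.  Registered
shifts: ammonia loss at Asn −17.026549, deamidation +0.984016, Met
oxidation +15.994915, N-terminal acetylation +42.010565 Da.  Tryptic
digestion cleaves C-terminal to K/R except before P, enumerates up to
the missed-cleavage limit (default 2), and has a semi-specific mode
(one ragged terminus); zero-missed peptides tile the protein exactly.
b/y fragment ions follow the standard sums, with modifications counted
when their position lies in the fragment; b/y complementarity
(bᵢ + y₍n−i₎ = M + 2·proton) is property-tested.  Intact-protein masses
include the initiator Met unless `exclude_initiator_met` is set (the
choice is exposed because numbering conventions differ).  Population
classification assigns a deconvoluted neutral mass to the nearest of
M−17.0265 / M / M+0.984 within a tolerance (default 0.05 Da) — isotope
envelopes and deconvolution itself are out of scope.

Theoretical m/z values are compared with instrument-printed ones at
0.02 Da (≈ 15 ppm at m/z 1350), matching a 10 ppm-class search
tolerance; digit-exact agreement with observed values is not expected.

## Problem sizes and limitations

The default test suite and the acceptance script use: 10 × ~49k-hill
quadrature streams on a 241×241 FES grid; 25 random ≤ 12×12 grids for
the minimax cross-check; 200–1000-sample constructed trajectories;
≤ 20-residue synthetic peptides.  These sizes were chosen so the whole
suite runs in well under a minute per layer on one core while leaving
the estimators' error far below the asserted tolerances.

Known limitations: the peptide builder is not a conformer generator
(no sterics, no hydrogens); crystal-mode H-bonds cannot apply the angle
criterion; the FES estimator has no well-tempered rescaling (by design —
the workflow it post-processes is nontempered); walk-mode hill streams
are qualitative; deposited crystal structures and the wild-type UniProt
sequence are inputs the user must supply — the package validates its
geometry and mass layers on synthetic rebuilds of the published values,
and on the published mutant mass ladder, which is fully determined by
the mutations themselves.
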