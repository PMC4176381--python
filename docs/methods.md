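# Methods

## Scope and overall model

The package analyzes sequence-specific protein–DNA recognition under a
fixed-backbone approximation: the protein–DNA complex is taken as rigid
except for the identities of the DNA bases, which are exhaustively mutated
*in silico*. This is the standard assumption behind structure-based binding
repertoires — it captures base readout (direct contacts to base functional
groups) and steric selection, but by construction cannot capture induced
fit, backbone deformation, or shape readout that depends on
sequence-dependent DNA mechanics. Results are therefore interpreted as
*relative* binding energies over a fixed scaffold, never absolute
affinities.

## Structure model and threading

A complex is two DNA strands plus a protein, parsed from PDB (first MODEL,
altloc A, ATOM records; HETATM nucleotides accepted when paired). Strands
are paired by antiparallel complementarity; the reference strand (the one
whose 5'→3' sequence is the printed motif) is chosen at parse time and
recorded. Protein residues carry 1-based file-order indices plus a
`numbering_offset` (default 52) so that author-style residue numbers
resolve — e.g. file-order residue 170 is author residue 222 for a construct
that begins at residue 53.

Each nucleotide owns an **anchor frame**: origin at C1', x toward the
glycosidic nitrogen, +y toward the major-groove edge, recovered from the
C1'/N9-or-N1/C4-or-C2 atoms on read. Threading a motif replaces base atoms
with idealized planar templates placed on these frames — on both strands,
maintaining complementarity — and touches nothing else; the contract
`max displacement of protein and backbone atoms = 0` is tested exactly.
Side-chain repacking around the new base is deliberately not modeled (a
single rigid placement); this is the main documented simplification
relative to full protein-design energy functions. Non-canonical or modified
bases are rejected rather than coerced, because the scan space is defined
over {A, C, G, T}.

The base templates are deterministic caricatures of real base geometry
(approximate ring coordinates, correct topology of groove-edge functional
groups). Their only contract is chemical: guanine's minor-groove edge
presents an N2 donor *and* an N3 acceptor, adenine only N3, cytosine and
thymine an O2 acceptor; the major groove carries N6/O6/N4/O4/N7 and
thymine's hydrophobic C7 methyl.

## Energy function

Four additive terms; the total is their exact sum (tested to machine
precision). All terms depend only on interatomic distances and angles, so
the breakdown is invariant under rigid-body transforms (tolerance 1e-6).

* **Clash (DNA / protein)** — soft quadratic penalty
  `k (1 − d/r_cut)²` for pairs below `r_cut = 0.9 (r_i + r_j)` of the van
  der Waals radii, k = 10 kcal/mol. Bookkept separately for DNA-internal
  pairs (different nucleotides) and protein–DNA pairs, mirroring the
  two-clash-column decomposition of published scans. Backbone–backbone
  contributions are constant across motifs and cancel in ΔΔG.
* **Interaction** — pairwise attractive well `−ε min(1, (r₀/d)⁶)` for
  protein–DNA pairs within 6 Å, ε = 0.05 kcal/mol, r₀ the summed radii.
  Each pair term is ≤ 0 and bounded, so adding a contacting atom can never
  make the term less favorable — electrostatics are folded in; there are no
  explicit charges.
* **Side-chain H-bonds** — donor/acceptor pairs between protein side-chain
  polar atoms (curated per residue type) and base groove sites, accepted
  when the heavy-atom distance is in 2.5–3.5 Å and the
  antecedent–donor–acceptor angle is ≥ 120° (assumed ideal if no antecedent
  atom exists). Energy −1.0 kcal/mol per ideal bond with linear
  distance/angle attenuation. One base may contribute several contacts —
  the bidentate glutamine–guanine geometry yields two where adenine yields
  one, which is the mechanism behind the ~2 kcal/mol penalty for T at
  position 1 of the CSL motif.

These forms and constants are conventional choices, exposed in
`EnergyParameters` and hashed into a fingerprint so that ΔΔG is only ever
computed between breakdowns with identical parameters. The absolute scale
is not calibrated to any external force field: the published decomposition
table is shipped as a fixture for arithmetic checks (its columns are summed
as the total, since no printed total exists), and the published bound-set
size (220 of 65,536) is descriptive of a different scorer, not an
acceptance value for this one.

## Motif scan and bound set

`enumerate_motifs(L)` yields the 4^L sequences in lexicographic order
(guarded to L ≤ 12). The scan threads and scores every motif, subtracts the
minimum total, and ranks ascending with lexicographic tie-breaks, making
the output byte-identical across runs and execution orders. Only the
reference-strand orientation is scored; scoring both orientations would
double the space and is noted as a possible extension. The bound set is the
inclusive partition ΔΔG ≤ threshold (default 3 kcal/mol measured from the
top sequence); selection is monotone in the threshold and conserves
|bound| + residual = 4^L.

## Logo statistics

Boltzmann weights w_i ∝ exp(−ΔΔG_i/kT) are normalized **within the bound
set** (matching the convention of building the logo from the bound
sequences only). kT defaults to 0.593 kcal/mol (298 K) and is a parameter —
the weighting temperature is a presentation choice, not a physical claim.
Frequency matrices are L×4 (positions × A,C,G,T); information content is
IC_j = 2 + Σ_b p log2 p bits, bounded in [0, 2]. The conditional tensor
P(b at j | a at i) leaves zero-weight conditions (and the i = j diagonal)
as NaN rather than 0, so absent conditions cannot masquerade as
interactions; dependencies are reported as |P(b|a) − P(b)| with a
configurable report threshold (default 0.1, there being no published
criterion). The chain rule W(a∧b) = W(a)·P(b|a) holds exactly and is
tested. Logos are rendered with matplotlib as stacked scaled letters; the
numeric matrices are the primary output.

## Calorimetry

The forward model is the single-site total-heat isotherm for a
perfusion-type cell. Injection i of volume v into cell volume V₀ scales
existing cell contents by (1 − v/V₀) and adds ligand at the syringe
concentration; bound complex follows the stable root of the binding
quadratic with site concentration n·[M]; measured heat is
Q_i − (1 − v/V₀) Q_{i−1} with Q = ΔH·V₀·[MX]. The model was verified
against an independent per-injection bracketing solve of the quadratic to
1e-9. Cell volume defaults to 1.4 mL (typical for this instrument class;
configurable), protocol defaults to 10 μM macromolecule, 100 μM ligand,
twenty 14 μl injections at 10 °C. The no-displacement variant is a
one-line change of the dilution recursion and was not needed.

Fitting floats (n, log10 K, ΔH) by bounded least squares (K ∈ [10², 10¹²]),
initialized from n₀ = 1, ΔH₀ from the first-injection heat, and a small
multi-start over log10 K ∈ {4…8}. n is floated (and reported) rather than
fixed at 1 — with clean synthetic data it recovers 1.000 anyway.
Degenerate inputs (fewer than 5 injections, no measurable signal, or a
best fit explaining less than half the signal variance) return an explicit
`NoBinding` outcome, mirroring the "no binding detected" row of a
calorimetric report, never NaN parameters. Derived quantities are exact
identities by construction: ΔG° = −RT ln K (R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹),
−TΔS° = ΔG° − ΔH°, Kd = 10⁶/K μM.

## Trajectory dynamics

Trajectories are plain (F, N, 3) Cα arrays read from multi-frame XYZ or
long CSV; frame spacing is metadata only (no unit conversions are
attempted). Replica handling discards a per-replica equilibration prefix
and concatenates (3 replicas × 48 frames − 8 each → 120, the frame-count
analogue of the 3 × 40 ns macro-trajectory convention). Superposition is
Kabsch with an iterated mean-structure reference (2 passes), which
stabilizes covariance on short trajectories; RMSD superposes each frame to
the chosen reference frame, RMSF is measured about the superposed mean.
Principal motions are eigenpairs of the 3N × 3N displacement covariance
with the sign fixed by the largest-magnitude component.

The **ICRM** is defined here as the absolute normalized displacement
covariance, |⟨d_i·d_j⟩| / sqrt(⟨|d_i|²⟩⟨|d_j|²⟩), with entries set to
exactly 0 when the mean Cα–Cα distance exceeds the gate (default 30 Å,
chosen to span DNA-contacting residues to the distal domain). The exact
formula behind published eigenvalue tables for this quantity is not public
(their first eigenvalues are on a ~16,000–24,000 scale, suggesting
unnormalized covariance and/or rigidity weighting); this implementation
deliberately uses the normalized magnitude, so entries lie in [0, 1], the
first eigenvalue lies in [1, N], and **only relative orderings across
systems are claimed** — a disclaimer that also appears in output headers'
semantics. Zero-variance residues are zeroed with a warning rather than
producing NaNs.

## Synthetic data: what it emulates, what it does not

`make_toy_complex` builds an untwisted ladder duplex (rise 3.4 Å, C1'
anchors at ±9.2 Å, major groove at +y) inside a glycine-Cα shell, with a
glutamine-like probe posed at 2.9 Å hydrogen-bond geometry against the
minor-groove edge of the base complementary to position 1, and an alanine
Cβ "pocket" 2.65 Å above where thymine's methyl sits at a chosen position
(default 2). The geometry was designed once to exercise every branch of
the energy function — bidentate vs monodentate readout, steric selection,
favorable contacts — deterministically under a seed. It is **not** a
B-DNA model: no helical twist, no full atom complement, no solvent. Tests
passing on it demonstrate correctness of the operators and invariants, not
predictive accuracy on real complexes.

`make_coupled_trajectory` generates per-domain latent N(0, 1) series with
inter-domain correlation exactly equal to the requested coupling
(shared-component construction), applied along a fixed axis with
alternating per-residue signs so net rigid-body motion cancels and
superposition is near-neutral, plus isotropic Gaussian noise (σ = 0.3 Å
against 1.0 Å latent amplitude; ~0.79 within-domain correlation). Domain
clusters sit 12 Å apart, inside the default 30 Å gate. This emulates the
*statistical* structure the ICRM analysis assumes — coherent intra-domain
motion with tunable inter-domain coordination — not protein mechanics; the
monotonicity of the coordination score in the coupling is the package's
stand-in for the published consensus > intermediate > unbound ordering.

`make_itc_titration` is the forward isotherm plus Gaussian heat noise
(symmetric errors being the simplest model consistent with reported
standard deviations). Packaged fixture tables transcribe the published
energy-decomposition and calorimetric rows digit-for-digit, including the
weak-binder (Kd > 50 μM) and no-binding sentinel rows.

## Problem sizes and numerical choices

Tests and the acceptance script use scan lengths L = 2–4 (16–256 motifs;
the scan is embarrassingly parallel and a 65,536-motif enumeration is
instantaneous, while scoring cost grows linearly in motif count), 50
seeded replicates for ITC noise recovery, 20 seeds × 3 couplings × 400
frames for the coordination ordering, and F = 5000 frames for sampling
oracles. Tolerances: exact (0) for gating, conservation and threading
immobility; 1e-12 for chain-rule and ΔΔG oracle identities; 1e-6 kcal/mol
for rigid-transform invariance; statistical bounds (0.05–0.1) for sampling
oracles at the stated sizes.

## Known limitations

* Fixed protein conformation across all 4^L variants; no side-chain
  repacking or DNA deformation normalization — known to over-penalize
  variants a real interface would relax around.
* Energy scale uncalibrated; bound-set sizes depend on the threshold and
  the scorer and are not comparable across energy functions.
* Single-orientation scanning (reference strand as printed).
* ICRM absolute eigenvalues are not comparable to unnormalized published
  scales; rankings only.
* The ITC model assumes instantaneous mixing and a single site class; no
  baseline or peak-integration modeling of raw power traces.
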