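# Methods

This note records the models implemented in `enmfold`, the conventions
and defaults behind every tunable parameter, what the synthetic
structures do and do not emulate, and the numerical choices a
maintainer would otherwise have to reverse-engineer.

## Elastic network models

**GNM.** A structure is reduced to its Cα trace.  Two residues are in
contact when their Cα distance is at most `cutoff_gnm` (default 7.0 Å,
the radius of the first coordination shell around residues in folded
proteins).  All pairs within the cutoff are connected, including
sequence neighbors; the contact rule makes no sequence-separation
exception.  The Kirchhoff matrix is the graph Laplacian scaled by the
spring constant γ: off-diagonal −γ for contacts, diagonal γ×degree.
Fluctuations follow from the pseudoinverse,

    ⟨ΔR_i · ΔR_j⟩ = 3 k_BT [Γ⁺]_ij ,
    B_i = (8π²/3) ⟨ΔR_i²⟩ .

γ lives inside the matrix, so all fluctuation quantities scale as
k_BT/γ.  Internally k_BT = γ = 1: fluctuations are in arbitrary units
until calibrated (below).

**ANM.** The 3N×3N Hessian is assembled from rank-1 blocks
−(γ/d_ij²)(ΔX)(ΔX)ᵀ along the native separation vectors for pairs
within `cutoff_anm`; diagonal blocks balance the rows.  The input never
states an ANM cutoff, so the package uses the common default of
13.0 Å (configurable) and treats it as a documented divergence risk.
A connected, non-degenerate ANM network has exactly six zero modes
(rigid translations and rotations); a connected GNM network has one.

**Zero-mode tolerance.** A mode counts as zero when
|λ| < 1e−11 × λ_max.  True zero modes land at machine precision
(≈1e−15 × λ_max after `scipy.linalg.eigh`), whereas genuinely soft
internal modes — e.g. the torsion of one core of the dumbbell fixture
about its thin linker — can sit as low as ~1e−9 × λ_max.  1e−11
separates the two populations with roughly an order of magnitude of
margin on each side; a larger tolerance silently swallows soft internal
modes into the rigid-body set.

**Mode conventions.** Modes are indexed ascending by eigenvalue after
excluding zero modes (0 = slowest).  The "mass" of the first m modes is
Σ_{k≤m} λ_k⁻¹ / Σ λ_k⁻¹ — each mode's share of the total mean-square
fluctuation.  This is the standard reading of "fraction of total
motion"; no alternative weighting is offered.  ANM mode fields are
reported unit-normalized with the gauge fixed by making the
largest-magnitude component positive.

**Calibration.** `fit_gamma` least-squares-fits the scale s in
B_exp ≈ s·B_pred(γ=1) and returns γ = 1/s together with the Pearson
correlation of the fit.  The absolute hot/warm-spot thresholds
(0.03 / 0.01 Å² over the 10 fastest modes) are meaningful only on this
calibrated scale, so `hot_spots` refuses to run without it.  Constant
experimental B-factors make the fit degenerate and raise.

## Iterative-GNM unfolding

Interactions are split into covalent springs — chain-adjacent pairs
(minus chain breaks), strength c·γ, immutable, kept covalent even when
their distance exceeds the cutoff — and non-covalent contacts, all
other pairs within the GNM cutoff, strength γ.  Each step rebuilds the
Kirchhoff matrix of the current topology, computes every surviving
contact's mean-square distance fluctuation

    ⟨ΔR_ij²⟩ = ⟨ΔR_i²⟩ + ⟨ΔR_j²⟩ − 2⟨ΔR_i · ΔR_j⟩ ,

ranks non-covalent contacts by it, and removes one chosen uniformly
among the top `noise_top_k` (default 3, modelling thermal noise;
top-1 makes the walk fully deterministic).  The loss-number-of-native-
contacts (LNNC) counts removals and is the progress coordinate.

Parameter choices:

- `backbone_factor` c defaults to 10.  The original procedure fits c to
  crystallographic B-factors but never reports its value; 10 makes the
  backbone an order of magnitude stiffer than a single contact, and the
  value is overridable (a grid fit against B-factors can be run through
  `fit_gamma` on the iterative matrix by the user).
- `replicates` defaults to 100 (the full ensemble); tests and the
  pipeline default use 5–20 replicates, which is enough for the
  weakest-link and curve statistics on fixture-sized systems.
- Replicate r draws from `numpy.random.default_rng(seed + r)`, so a
  master seed fixes every event list bit-for-bit.
- Tie-breaks in the ranking are stable by (fluctuation desc, i, j) for
  reproducibility across platforms.
- The pseudoinverse is recomputed in full each step (O(steps·N³)).
  Correctness first: at fixture size this is seconds, at N≈650 a full
  replicate is hours-scale, which is why replicate counts are exposed.
  A low-rank downdate accelerator is a possible future optimization and
  is deliberately not implemented; there is therefore exactly one code
  path for the fluctuation field.
- Late-stage topologies can fragment across chain breaks; the
  decomposition then tolerates extra zero modes (strict component
  checking is disabled inside the unfolding loop only).

Weak regions: contacts whose replicate-mean break step falls at or
below a threshold (default 500 steps, ≈20% of the native contact count
at full protein size; the pipeline clamps it to the native count for
small systems) are single-linkage clustered on their native midpoint
coordinates with a 10 Å distance criterion.  Each cluster reports its
members, mean break step, geometric center and the composite domains
involved.

## Structure handling

PDB input goes through Biopython's parser: one residue per
(chain, author number, insertion code) bearing a Cα; HETATM and waters
excluded; alternate locations resolved to the highest-occupancy
conformer (first-listed on ties); the experimental B-factor taken from
the Cα record.  Author numbering is the coordinate system of every
report and domain map; internal 0-based indices never appear in
output.  Missing residues are *not* rebuilt — the package accepts
structures as given and records chain breaks (Cα–Cα > 4.5 Å), so
results never silently depend on modelled loops.  Multi-chain files
default to the first protein chain, selectable by flag.

Superposition uses the Kabsch algorithm
(`scipy.spatial.transform.Rotation.align_vectors`; proper rotations
only, degenerate/collinear inputs raise).  The iterative structural
alignment seeds from a global BLOSUM62 sequence alignment
(gap open −11 / extend −1), then alternates superposition with an
order-preserving re-pairing of residues: a dynamic program over the
distance matrix that maximizes Σ(cutoff − d_ij) over monotone pair
sets, with the prune cutoff defaulting to 3.0 Å and a 50-round cap.
When an intermediate fit straddles two rigid sub-bodies and no pair
falls within the cutoff, the farthest 10% of pairs are trimmed
(correspondence kept) and the fit repeated, which locks onto the
dominant body.  Identity is reported over the final matched pairs —
whether the published 40.0% identity was computed over matched
positions or the full alignment is not stated, and this choice is the
testable one.

## Descriptor panel conventions

- **SASA**: Shrake–Rupley as implemented in Biopython (probe 1.4 Å,
  960 sphere points by default), hydrogens ignored, aggregated per
  residue and per residue class.  The hydrophilic class is fixed
  (Asp, Asn, Glu, Gln, Lys, Arg, His); the hydrophobic set defaults to
  {Ala, Val, Leu, Ile, Met, Phe, Trp} and is configurable, because the
  published three-way split never names its hydrophobic set.
  A ±3% tolerance is appropriate when comparing against values from an
  unnamed SASA program.
- **H-bonds**: donors and acceptors are N/O atoms from fixed per-residue
  tables (sulfur excluded).  Backbone amide H is placed by ideal
  geometry (1.01 Å along the bisector of N−C_prev and N−CA; proline and
  chain-start excluded).  Side-chain donors without deposited H use the
  surrogate criterion antecedent−donor−acceptor ≥ 120°.  Each donor
  atom keeps only its nearest valid acceptor — bifurcated bonds are not
  counted, the stricter reading of an underspecified convention.
- **Salt bridges**: Asp/Glu carboxylate O within 3.5 Å of Lys NZ,
  Arg NH1/NH2/NE or His ND1/NE2, counted once per residue pair.
- **Glycine classes**: φ by the standard C(i−1)−N−CA−C convention in
  (−180°, 180°]; φ ≥ 0 is φ+ (0 counts as φ+); terminal glycines are
  "undefined".
- **Burial**: a hydrophilic residue is buried when its side-chain SASA
  is below 10% (configurable) of the same residue computed in
  isolation.  "Buried" is never defined in the source material; 10%
  relative side-chain accessibility is the common convention.
  Hydrogen-bond capacities per buried side chain come from a fixed
  table (Asp/Glu/Asn/Gln 4, Lys 3, Arg 5, His 2).
- **NCPR**: per composite domain, Cα pairs with both residues in the
  domain, |i−j| ≥ 2 and distance ≤ 7.0 Å, divided by domain length and
  reported to two decimals.  The |i−j| ≥ 2 rule (sequence neighbors
  excluded) is the convention that reproduces the published per-domain
  arithmetic and is documented as reverse-engineered.
- Domain maps are user-supplied label → interval configs; composite
  parts A1/A2/A3 aggregate to A for lengths, censuses and curves.  The
  shipped example maps for the two amylosucrases are reconstructions
  that match the reported domain lengths, with approximate boundaries —
  marked as such in the files.

## Synthetic structures: what they do and do not show

The generators produce deterministic, seed-stable models:

- *path chain* — collinear Cα trace whose GNM is the path-graph
  Laplacian with the closed-form spectrum 4 sin²(kπ/2n); the analytic
  anchor for the spectral machinery.
- *helix* — ideal α-helix; full-atom mode builds the backbone by
  internal-coordinate chain extension (NeRF) at (φ, ψ) = (−62°, −47°),
  placing carbonyl O and amide H so the canonical i→i+4 hydrogen-bond
  ladder (N···O ≈ 2.86 Å) is detectable.
- *globule* — rejection-sampled sphere at folded-protein density
  (115 Å³/residue, minimum pair distance 3.5 Å, mean contact degree
  ≈6–8 at 7 Å), chained by a greedy nearest-neighbor walk, resampled
  until the 7 Å network is connected.
- *dumbbell* — two compact lattice-blob cores whose chain runs
  center → surface → short arched linker → surface → center, so both
  free termini are buried and the linker junction contacts are provably
  the most weakly supported part of the network.  The arch gives the
  core-about-linker torsion a small positive stiffness (a perfectly
  straight linker leaves it degenerate with the rigid-body modes); a
  0.05 Å seeded jitter breaks lattice symmetry without changing the
  contact topology.
- *charged pair*, *sheet hairpin* — minimal full-atom salt-bridge
  geometry (exact closest O–N distance by construction) and an
  antiparallel two-strand Cα hairpin.

These fixtures exercise every code path with known answers, but they
are not proteins: they lack secondary-structure regularity, realistic
side chains and evolved contact topology.  Consequences observed and
accepted: the per-residue fluctuation profiles of GNM and ANM correlate
at r ≈ 0.6–0.9 on toy globules, weaker than the ≳0.8 typical of real
structures, so the consistency property is asserted at the level the
fixtures support; and absolute Å² thresholds are only exercised through
synthetic calibrations.  Passing tests demonstrate correctness of the
computations and the claimed invariants, not biological realism of the
fixtures.

## Pipeline

`run_comparison` executes metrics → GNM (+B-factor fit, spots) → ANM →
optional unfolding for both structures from one YAML config, writes
CSV artifacts with the seed recorded in every header, logs every
parameter, and reports paired deltas (A−B) for all shared scalar
metrics.  Unfolding ensembles are cached keyed by a content hash of
the structure text plus all iterative-GNM parameters, so descriptor
iteration never re-pays the expensive stage; reruns with an unchanged
config are byte-identical.  `validate_against_reference` compares a
report against a reference CSV with per-row absolute/relative
tolerances (exact for integers by default).

## Known limitations

- The descriptor stages need complete side chains; structures with
  missing heavy atoms are processed with a per-residue completeness
  warning and underestimated areas.
- mmCIF input, homology modelling, protonation beyond the ideal amide
  H, refolding/kinetics in physical time, and folding free-energy
  estimation are out of scope.
- Full-size (N≈650) unfolding runs are hours per replicate with the
  exact per-step decomposition; replicate counts are the intended
  scaling knob.
- The iterative structural alignment emulates the fixed-point behavior
  of interactive "magic fit" tools; its exact pruning schedule is not
  published, so agreement is expected at the level of matched-position
  counts and RMSD, not pair-for-pair identity.
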