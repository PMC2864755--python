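# Methods

This note records the model, the numerical choices and the limits of what
the test suite demonstrates. Units: energies kcal/mol, lengths Å, angles
degrees, entropies and mutual information nats.

## Structural model

Proteins are represented united-atom: heavy atoms plus hydrogens bound to
N/O/S. Side chains are built from internal coordinates (NeRF construction)
derived once from ideal residue geometry; bond lengths, angles and rigid-
group torsions are fixed, and the χ dihedrals are the only degrees of
freedom. Rebuilding a side chain and re-measuring its χ angles is exact to
1e-6°, and ring groups close exactly at the reference geometry because all
internal coordinates are measured from one rigid ideal structure.

The backbone is fixed throughout design. Backbones are read from PDB
(first or selected chain, highest-occupancy altlocs, missing carbonyl O
rebuilt from geometry, missing amide H placed anti to the preceding
carbonyl) or generated as ideal-geometry helix (φ,ψ = −57,−47), strand
(−119,113) or hairpin fixtures. Native Cys/Gly/Pro positions are frozen at
their input side-chain coordinates and never mutated; all other positions
design over the 17 remaining types. Coordinates are right-handed Å;
residue indexing follows the author numbering of the selected chain.

Rotamers are discrete χ-angle combinations. The built-in library is a
χ grid over {−60, 60, 180} per angle; `max_chi` caps how many χ angles are
gridded (deeper angles held at 180) to keep long side chains tractable at
desk scale. Any external library can be loaded from a one-rotamer-per-row
TSV. Proline carries a single ideal-geometry rotamer (its ring closes only
near the reference χ values).

## Parameters

The nonbonded tables (partial charges, Lennard-Jones well depths and
radii, solvation radii, atom classes) are a self-contained united-atom
parameterization in the CHARMM19 spirit: implicit aliphatic hydrogens,
explicit polar ones, net-neutral or ±1 charge groups. They are authored in
`designkit.structure` and can be exported/loaded as a documented TSV, so
alternative tables drop in. No test or acceptance property depends on the
specific values, only on the structure of the model.

LJ combination: ε_ij = √(ε_i ε_j), rmin_ij = rmin_i + rmin_j (per-atom
halves). Exclusions: 1-2 and 1-3 bonded pairs are excluded from vdW and
Coulomb; 1-4 pairs are included at full weight. The Coulomb constant is
332.0636 kcal·Å/(mol·e²).

## Surface term

`sasa_exact` implements Lee–Richards slicing: each probe-expanded sphere
is cut into latitude slices (default 400; 120 inside the energy model,
where only internal consistency matters), the accessible arc of each slice
circle is found by subtracting the azimuth intervals blocked by
neighbouring spheres, and areas use the exact hat-box weight 2πRΔz. When
an atom's neighbour caps are pairwise disjoint on its sphere, the analytic
cap formula is used instead — this is the exact slicing limit, so isolated
atoms (4π(r+1.4)²) and every two-body system are computed exactly. The
implementation is cross-checked in the tests against an independent
Shrake–Rupley computation.

`sasa_pairwise_approx` is the two-sphere contact-area approximation: each
atom's isolated area minus the analytic lens area against every
neighbour, clamped at zero. It is exact for isolated atoms and two-body
systems and degrades with multi-sphere overlap; at covalent separations
the lens sum saturates (any atom with two bonded neighbours is nominally
fully buried), which is the known failure mode that motivates scaled
variants of this approximation in the design literature.

The energy model therefore attributes surface area in a way that keeps
residue-pair decomposability without using the lens formula in its bad
regime:

* constant channel — exact areas of the backbone in the backbone-only
  context;
* singleton channel of (position, type, rotamer) — exact areas of that
  side chain in the context of its own backbone, minus the lens-approx
  burial the side chain inflicts on backbone atoms;
* pair channel — minus the lens-approx cross burial between the two side
  chains (both directions), a purely nonbonded regime where the two-sphere
  formula is accurate.

The per-atom sum is not clamped inside the energy (clamping would break
the exact decomposition); the matrix-reconstructed energy equals the
direct whole-system evaluation of the same definition to float precision.

The surface-error regression guard samples random 20-atom carbon clusters
with pairwise separations ≥ 5 Å — the mild-overlap regime the contact-area
approximation is designed for (expanded 3.3 Å spheres still interpenetrate
by up to 1.6 Å). At van-der-Waals contact spacing the plain lens sum errs
by ~35% and the guard would not hold; that regime is intentionally handled
by the exact in-context areas above, not by the lens formula.

## Pair matrix and relaxation

All design energies are precomputed: singletons per (position, type,
rotamer) and pair blocks per residue pair, each with separate (vdW,
Coulomb, surface) channels. Residue pairs whose ideal-CB anchors (CA for
Gly) are farther apart than the cutoff (default 14 Å) are omitted and
exactly zero; enlarging the cutoff never changes existing entries. Pair
entries with total energy above +100 kcal/mol are stored as computed but
flagged — the optimizer, not a pre-filter, handles clashes. Matrices
serialize to a JSON container with deterministic formatting.

Optional side-chain relaxation reproduces the two-stage pair protocol:
each side chain is first relaxed against the fixed backbone with the
partner absent, then the pair relaxes together, `pair_min_steps`
L-BFGS iterations per stage (default 15; 0 = rigid rotamers, the mode the
equivalence oracles use). The relaxation objective is vdW + screened
Coulomb plus harmonic 1-2 and 1-3 distance restraints to the input
geometry (k = 300 and 50 kcal/mol/Å²) standing in for bond/angle terms;
the surface term is evaluated on the final geometry only. Whole-structure
preparation minimizes the same objective over all atoms with the
preparation dielectric (20) for up to 500 iterations and reports the
backbone RMSD to the input.

## Unfolded reference and composition corrections

The unfolded reference of type X is the minimum CASA energy of an
Ala-X-Ala tripeptide over a fixed (φ,ψ) catalog — helix (−57,−47), sheet
(−119,113), polyproline-II-like (−75,145), extended (−180,180) — and the
rotamers of X (rigid). The catalog is configurable. Tripeptides use plain
uncharged termini (no OXT, standard N/H), a deliberate simplification of
an unfolded-state model. Empirical per-type corrections default to zero;
`calibrate_corrections` adjusts them iteratively toward a target
composition with damped steps (η/(1+round), stochastic-approximation
style, because the short-design composition estimate is noisy) and returns
the best round. The correction sign is chosen so that raising a type's
correction makes it more favourable in the folded state.

## Sequence optimization

A heuristic cycle: uniform-random initial (type, rotamer) state over the
allowed sets, then ascending-index position sweeps choosing the state that
minimizes the total folding free energy given the rest (ties go to the
lowest state index for determinism), until a pass changes nothing or
`max_passes` (default 50) is reached. `run_design` derives an independent
RNG per cycle from (seed, cycle index), so results are reproducible and
order-independent; records sort by (energy, sequence, rotamers, cycle).
Desk-scale defaults are 1000 cycles keeping the best 1000; the published
protocol corresponds to ~300,000 cycles keeping the 8,000 lowest-energy
sequences. Flavor-restrained cycles restrict each position to the types
sharing the start type's nine-class flavor; rotamer-only optimization
fixes the sequence. Frozen positions and per-position overrides (e.g.
pinning substrate-binding positions to native) are honoured everywhere.

## Ensemble statistics

* Identity: percent matching positions of equal-length sequences; by
  default over the full chain (frozen positions included).
* Similarity: Σ_l Σ_a f_l(a)·B(s_l, a) with BLOSUM62 (loaded from
  Biopython, or any NCBI-format matrix) and a flat −5 gap score; column
  frequencies include the gap fraction.
* Score overlap between two score samples: the fraction of one sample at
  or above the other's minimum (with a histogram-intersection overlap
  coefficient available as an alternative definition).
* Residual entropy: S_l = −Σ_t f_l(t) ln f_l(t) over reduced-alphabet
  classes — nine classes {LVIMC}{FY}{W}{G}{A}{STP}{EDNQ}{KR}{H} or six
  {LVIMC}{FYW}{G}{ASTP}{EDNQ}{KRH} — with gaps excluded and columns
  renormalized; all-gap columns are flagged NaN. The summary is the
  arithmetic mean of e^{S_l} (a geometric alternative is available); e^S
  reads as an effective number of tolerated classes.
* Mutual information: C_ij = Σ_ab P_ij ln(P_ij/(P_i P_j)) by direct
  counting under a reduced alphabet (nine classes by default); diagonal =
  column entropy. Plain plug-in estimates, no small-sample bias
  correction — planted-signal tests operate well above the bias floor.
* Patterns: the k most frequent flavor tuples at chosen positions, with
  exact ensemble frequencies; subsets (and complements) of an ensemble by
  pattern match.

## PSSMs and the internal search

PSSM columns use background-frequency pseudocounts
p_a = (c_a + βq_a)/(N + β) (β > 0 required) against a fixed published
background table, scored as 2·log2(p/q) half-bits; exports: an ASCII
layout with consensus (scores rounded to integers), an unrounded TSV, and
the aligned FASTA itself for external tools. The internal search scores
every ungapped window of each target, calibrates a null by
residue-shuffling each target 20 times (seeded) and fitting a Gumbel
distribution to the per-target best scores, and reports
E = N_targets · P_null(S ≥ s). Because window scores are sums of many
column scores, the true null tail is lighter than Gumbel and the E-values
are conservative — appropriate for the one-sided calibration bound tested.
Target-length dependence of the null is ignored (fixture databases are
near-uniform in length), and these E-values are not comparable to any
external search tool's statistics. The pattern-subset protocol samples 50
sequences per subset (with replacement if the subset is smaller), builds a
PSSM, searches, repeats, and unions retrieved ids; a pooled control runs
with repeats matching the total number of subset queries.

## Synthetic data

The fixture generator emulates only what the tests need: ideal-geometry
backbones with optional coordinate jitter, planted alignments with known
per-column backgrounds, exactly specified coupled-pair joints and
subfamily-defining patterns, and labelled databases of profile samples
plus shuffled or composition-drawn decoys. It does not emulate real
crystal-structure artifacts (gaps, altlocs beyond what PDB round-trip
tests construct), realistic family phylogeny, sequence weighting, or
length variation. Passing tests therefore demonstrate the internal
consistency and statistical behaviour of the machinery at toy scale — not
that the energy function reproduces experimental stabilities, nor
retrieval rates on real databases.

## Problem sizes and known limitations

Tests and the acceptance script run 5-10 residue fixtures with 4-8 type,
≤3-rotamer libraries, 100-200 design cycles, 500-3000-sequence planted
alignments and ~1000-sequence databases — sizes chosen so the full suite
completes in minutes on one core while every property stays far from its
tolerance. Known limitations: toy design ensembles converge to one or few
sequences (diversity comparisons use synthetic family profiles instead);
absolute energy components on ideal-geometry fixtures are not physical,
only comparisons within a matrix are; the hairpin fixture's turn is
approximate; Pro/ring geometry is rigid; no disulfide chemistry beyond
freezing native cysteines; no gapped alignment construction (alignments
are inputs); no iterative profile refinement or HMM scoring.
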