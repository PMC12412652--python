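# Methods

This note records the models, numerical choices and deliberate
simplifications behind each stage, and what the test suite's passing does —
and does not — establish about real data.

## Structure model and I/O

Structures are ordered chains of residues with author (1-based) numbering
preserved, so residue citations like "I50" or "BAK 90–141" index directly.
PDB parsing/serialization is delegated to gemmi; alternate locations resolve
to the highest-occupancy conformer (ties to altloc 'A'), heteroatom residues
are kept but flagged, and MSE reads as Met with a substitution note. Write
precision is the PDB's 3 decimals; serials beyond 99999 follow gemmi's
hybrid-36 handling. Internal indices are 0-based and never serialized.
Percent identity between equal-length point-mutation lineages is rounded to
the nearest integer, matching the reporting convention for binder lineages.

## Superposition

Least-squares rigid superposition uses the SVD (Kabsch) solution with a
reflection guard; collinear point sets are solved but warned about. Atom
pairing between selections is positional — residues paired in selection
order, atoms by name — and unpaired atoms are dropped, never imputed, with
the aligned count reported. No outlier trimming is applied.

## Motif grafting

The motif is a bound helical peptide reduced to backbone + Cβ, with
non-hotspot identities masked to alanine; the default hotspots are motif
positions 1, 5, 8, 9, 10 carrying Ile, Leu, Ile, Gly, Asp. Every contiguous
scaffold window of the motif's length is superposed full-backbone
(N, CA, C, O) onto the motif; the endpoint ("NC points") RMSD is evaluated
over the first and last residues' backbone atoms **under the same
transform**, without refitting — one of two defensible readings of the
endpoint tolerance; we apply it post-alignment. Defaults: full-backbone
tolerance 3.0 Å, endpoint tolerance 2.0 Å, deterministic N→C scan with
RMSD-then-window-start ordering.

The clash test reduces the scaffold to backbone N, CA, C, O (the glycine
clash-test semantics taken literally — glycine has no Cβ) and counts pairs
closer than r_vdw,i + r_vdw,j − 0.6 Å against the target, using a fixed
heavy-atom radius table (C 1.70, N 1.55, O 1.52, S 1.80 Å). The exact clash
metric of the original tool chain is unpublished; this rule is our declared
stand-in, and the default cutoff 0 means "no hard overlaps under this
rule". Atoms of the grafted window are excluded — they legitimately replace
the native bound peptide. Applying a graft threads hotspot identities onto
the window (hotspot wins on conflict, recorded in provenance) and reverts
all other positions to the scaffold's native sequence; provenance
round-trips through PDB REMARK records.

## Energy model

The design stage does not reproduce a full molecular-mechanics scoring
function. It uses a four-term pairwise-decomposable surrogate chosen so that
the pipeline's *logic* (selection shells, fixed hotspots, stochastic
optimization, filter gating) is exercised with real geometry:

* **steric**: an 8-4 Lennard-Jones on heavy-atom pairs, minimum at the
  summed vdW radii, well depth 0.15, repulsion capped at 20 per pair so the
  model stays finite inside clashes; pairs between sequence-adjacent
  residues are excluded (covalent neighbours);
* **hydrogen bond**: heavy-atom donor/acceptor pairs at 2.4–3.5 Å scored by
  a Gaussian around 2.9 Å (σ 0.3 Å) times a smooth angular gate requiring
  base–donor–acceptor ≥ 90°; no explicit hydrogens;
* **polar burial**: +1 per polar atom that is buried (≥16 heavy neighbours
  within 5.5 Å — a neighbour-count proxy, cheaper than SASA inside the
  optimizer) with no H-bond partner;
* **reference**: small per-residue-type offsets against composition drift.

Total energy of a design assignment decomposes exactly into single-body
terms (rotamer vs fixed environment) plus pair terms (rotamer vs rotamer),
which is what makes exhaustive enumeration an exact oracle for the
optimizer. The burial term is evaluated against the fixed environment only,
ignoring other designed side chains — a declared approximation.

Side chains are built from backbone N/CA/C by internal coordinates with a
simplified per-residue topology (single path plus short branches, idealized
bond lengths/angles, at most two variable χ angles; χ3+ fixed extended).
This gives donors/acceptors real geometry without a crystallographic rotamer
library.

## Interface design

Designable positions are binder residues with side-chain SASA ≥ 30 Å² in the
**isolated** binder (monomer state) at probe 2.2 Å, any heavy atom within
the shell distance of any target heavy atom, hotspots excluded; core
positions never change identity. SASA is Shrake–Rupley sphere-dot
integration (default 960 dots/atom; the selection gate uses 240 dots —
converged to within the gate's needs). Candidates per position are the 20
amino-acid types minus {Pro, Cys, Trp, Gly} (our reading of the
"disallow PCWG" composition rule) × a coarse χ grid (−60°, 60°, 180° per
variable χ), with the native identity+conformation always retained.

Optimization is Metropolis simulated annealing over single-position
substitutions (geometric temperature schedule 5 → 0.05, step count scaled to
the candidate count), followed by a greedy descent to single-move
optimality, tracking the best-encountered state; a single seeded generator
drives position/candidate picks, so runs are bitwise reproducible. The full
protocol runs design at the 8 Å shell, then the 12 Å shell, then an
identity-fixed repack — a discrete stand-in for the original
minimize–repack–minimize relaxation (no continuous or rigid-body
minimization is performed). Each stage's recorded final objective never
exceeds its own initial objective; objectives of different stages are over
different position sets and are not directly comparable.

## Filters

* **Binding energy**: E(complex) − ΣE(partner alone). Without repacking the
  partners keep bound conformations, so the value reduces to inter-partner
  interaction terms plus complexation-induced burial penalties and is
  exactly 0 for non-contacting partners; a repack mode relaxes the unbound
  partners with a fixed seed first.
* **Shape complementarity**: dots are screened for accessibility on
  probe-expanded spheres (probe 1.4 Å) and projected back to the vdW
  sphere — the contact portion of a solvent-excluded surface — at 300
  dots/atom; interface dots lie within 1.5 Å of the other partner's
  surface; each is scored against its nearest opposing dot by normal
  anti-alignment × exp(−0.5·d²); the statistic is the mean of the two
  directional medians and is deterministic.
* **Buried unsatisfied polars**: N/O donors/acceptors with SASA < 0.01 Å²
  at probe 1.4 Å in the complex, *not* buried in the isolated partner (so
  burial is interface-induced), and no heavy-atom H-bond partner
  (≤ 3.5 Å, base angle ≥ 90°). Note the deliberate two-probe policy:
  probe 2.2 Å for design-surface selection, 1.4 Å for burial.
* **Omega check**: residue i fails iff |ω_i| < 150° (ω to the following
  residue; trans = 180°); cis-proline (|ω| < 30° preceding Pro) is exempt
  by default as normal chemistry, with a flag to disable the exemption.

Filter gate values are configuration, not constants: the thresholds used to
pick real designs were never published, so `FilterThresholds` requires the
user's numbers (permissive defaults are provided for pipeline plumbing).

## Maturation analytics

Enrichment is a log2 frequency ratio with additive pseudocount p = 0.5:
e_m = log2[(c_sel+p)/(T_sel+pM) ÷ (c_naive+p)/(T_naive+pM)] over the
mutations tracked in the naive pool. A mutation is "enriched" iff e_m > 1.0
(configurable) and its naive count ≥ 10 (coverage floor). Reads with ≥ 2
substitutions or stops are discarded: SSM pools are single-substitution by
construction. Dual selection is the strict intersection of the two
conditions' enriched sets, never including wild-type identities; survivors
are ranked by min(e_aff, e_spec).

Library design chooses, per varied position, the minimal-multiplicity IUPAC
degenerate codon covering {parent} ∪ {selected} (ties: fewest extra amino
acids, then fewest stop codons, then lexicographic — which yields NNK for
the full 20). Amber stops inside degenerate codons are tolerated but
excluded from protein diversity; a strict no-stop mode exists. If the
protein diversity (exact integer product) exceeds the cap (default 4×10⁷),
mutations are greedily dropped in ascending enrichment order until it fits,
with every drop reported — the original reduction rule was not published,
so this explicit greedy rule is ours.

## Binding kinetics

The 1:1 model is fitted globally: k_on, k_off, R_max shared across all
traces of a titration, one free baseline per trace, parameters in log10
space for positivity, Levenberg–Marquardt with a 5-start multistart (fixed
seed). Whether the original fits were per-trace or global was not stated;
global matches multiple-concentration titration practice and is what we
document. K_d = k_off/k_on holds exactly by construction in every result.
Mass-transport and bivalent models are out of scope.

## Pore-formation mechanism

The mechanism is published as a schematic; the equations here are this
package's declared quantitative reading, and all acceptance on it is
property-based or order-of-magnitude — never exact wet-lab reproduction.

Per binder dose B (equilibrium, no time dependence):

1. occupancy: TB from B = B_free + T·B_free/(B_free + K_d,app), solved by
   monotone bisection to 1e-10 relative tolerance;
   K_d,app = K_d·(1 + K9), with K9 the intramolecular groove-occupancy
   constant of the target's own C-terminal (α9) helix — 0 for BAK-like and
   C-terminally truncated targets, large for full-length cytosolic BAX;
2. activation: engagement activates (partial unfolding persists after the
   binder leaves), so the activated fraction exceeds instantaneous
   occupancy: f_act = 1 − exp(−ν·θ), θ = TB/T, with turnover ν = 10
   (a hit-and-run binder samples several targets over the assay; the
   alternative strict-occupancy semantics is the flag `activation=False`).
   An external activator (cBID-like) contributes independently with a
   saturating engagement constant of 5 nM; its concentration is always
   configuration, never hard-coded;
3. dimerization: activated, currently-unbound targets partition between
   monomer and dimer, P = M + 2D with D = K_dim·M², K_dim = 1e8 M⁻¹
   (nanomolar-scale dimerization of activated effectors);
4. readout: release% = 100·D/(D + K_release) with K_release = 0.1 nM —
   a deeply saturating readout, because one pore releases an entire
   liposome's dye; this amplification is what places the inhibition IC50
   of a tight binder at the total target concentration (the stoichiometric
   threshold) rather than at its K_d.

These four defaults are fixed as the package's study conditions; with a
0.4 nM binder and 38 nM target they place the descending-branch IC50 just
above the target concentration and give a few-fold molar-excess requirement
without α9 competition versus a ≳100-fold requirement with it — the
qualitative signatures the model is meant to carry. The threshold summary
locates the interior maximum of the simulated curve and fits the 4PL to the
descending branch. The 4PL itself is y = bottom + (top−bottom)/(1+(ic50/x)^h)
with orientation auto-detected and y(ic50) = (top+bottom)/2 by construction.

## Synthetic data

Generators are deterministic per seed and emit their ground truth. They
emulate: ideal-geometry helices and groove complexes (NeRF-built backbones,
coarse side chains, poly-Ala grooves lined with hydrophobics); SSM pools
(multinomial naive pool; sorted pools pass variants through a logistic FACS
gate, survival = sigmoid(effect − 2.0)); noisy 1:1 titration traces; and
liposome time courses whose endpoints equal the equilibrium mechanism
exactly. The lineage sequences are synthetic stand-ins: generated so that
their Hamming distances and rounded percentages match the published lineage
divergences (lengths 118 and 117, the unique lengths consistent with all the
printed percentages), because the real variant sequences are not shipped.

What passing tests therefore show: the algorithms are correct against
independent oracles (brute-force window enumeration, exhaustive design
enumeration, closed forms, high-density numerical integration) and the
models have the right comparative statics. What they do not show: energy
realism against crystal structures, sequencing-error robustness (no
error/paired-end model), FACS gate realism, or agreement with any specific
wet-lab curve.

## Problem sizes and determinism

Test and acceptance runs use toy scales chosen for exactness of the
oracles: scaffolds ≤ 60 residues (100 randomized graft fixtures), design
state spaces ≤ 10⁴ (20 fixtures), SSM depth 10⁵ reads, 50-seed noise studies
for the kinetic and 4PL recovery claims, 1000 randomized chains for the ω
oracle. Every stochastic stage takes a single integer seed and is
reproducible bit-for-bit.

## Known limitations

* No backbone flexibility, loop closure, rigid-body or torsion minimization;
  relaxation is discrete repacking only.
* The energy surrogate's absolute values are model units; only orderings and
  signs are meaningful.
* The mechanism is equilibrium-only (no kinetics of activation or
  post-activation binder addition) and stops at dimers — no higher-order
  oligomer or membrane-lattice model.
* Structure support is PDB-format, single-model, protein-only; no mmCIF,
  nucleic acids, anisotropic displacement or symmetry expansion.
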